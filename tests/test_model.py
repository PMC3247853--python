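"""Twin mixed-effects model: groupings, covariance, likelihood, fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import twinvar as tv


def _random_y(design, seed=0, loc=5.0):
    meta = design.metadata(include_reference=False)
    rng = np.random.default_rng(seed)
    return pd.Series(rng.normal(loc, 1.0, len(meta)),
                     index=pd.Index(meta["aliquot_id"], name="aliquot_id"))


def dense_loglike(design, components, beta, y, model_form=1):
    """Independent oracle: full-matrix Gaussian log-density via scipy."""
    groups = tv.build_grouping(design)
    cov = tv.marginal_covariance(groups, components)
    meta = design.metadata(include_reference=False)
    order = meta["aliquot_id"]
    plates = meta["plate"].to_numpy()
    pids = np.unique(plates)
    X = (plates[:, None] == pids[None, :]).astype(float)
    if model_form == 2:
        centers = meta.groupby("plate")["well"].transform("mean")
        cwell = (meta["well"] - centers).to_numpy(float)
        X = np.hstack([X, X * cwell[:, None]])
    mean = X @ beta
    return multivariate_normal.logpdf(
        y.loc[order].to_numpy(), mean=mean,
        cov=cov.loc[order, order].to_numpy())


# -- groupings ---------------------------------------------------------
class TestGrouping:
    def test_single_mz_pair(self):
        d = tv.generate_design(1, 1, 0, 0, n_reference_wells_per_plate=0,
                               seed=0)
        g = tv.build_grouping(d)
        meta = d.metadata(include_reference=False)
        mz = meta[meta["zygosity"] == "MZ"]["aliquot_id"]
        dz = meta[meta["zygosity"] == "DZ"]["aliquot_id"]
        # MZ twins share H, M, W; differ in E, V
        for eff, joined in [("H", True), ("M", True), ("W", True),
                            ("E", False), ("V", False)]:
            labels = g.labels[eff].loc[mz]
            assert (labels.nunique() == 1) is joined, eff
        # DZ twins share H, W only
        for eff, joined in [("H", True), ("W", True), ("M", False),
                            ("E", False), ("V", False)]:
            labels = g.labels[eff].loc[dz]
            assert (labels.nunique() == 1) is joined, eff

    def test_study_design_group_counts(self, study_design):
        """Enumeration oracle: H=77 pairs, E=154 individuals, W=77+34
        pair-visits, V=154+68 individual-visits, M=56 MZ pairs + 42 DZ
        individuals."""
        g = tv.build_grouping(study_design)
        assert g.n_groups() == {"H": 77, "M": 98, "E": 154, "W": 111, "V": 222}

    def test_duplicates_share_all_labels(self, study_design):
        g = tv.build_grouping(study_design)
        for a, b in study_design.duplicate_map():
            for eff in "HMEWV":
                assert g.labels[eff].loc[a] == g.labels[eff].loc[b]

    def test_single_zygosity_refused(self):
        d = tv.generate_design(3, 0, 0, 0, n_reference_wells_per_plate=0,
                               seed=0)
        with pytest.raises(ValueError, match="combined familial"):
            tv.build_grouping(d)
        g = tv.build_grouping(d, require_both_zygosities=False)
        assert g.n_groups()["H"] == 3


# -- marginal covariance ------------------------------------------------
class TestMarginalCovariance:
    comp = tv.VarianceComponents(0.3, 0.2, 0.15, 0.1, 0.05, 0.25)

    def _block(self, n_mz, n_dz, n_dup=0):
        d = tv.generate_design(n_mz, n_dz, 0, n_dup,
                               n_reference_wells_per_plate=0, seed=0)
        g = tv.build_grouping(d, require_both_zygosities=False)
        return d, tv.marginal_covariance(g, self.comp)

    def test_mz_pair_block(self):
        d, cov = self._block(1, 0)
        c = self.comp
        off = cov.to_numpy()[0, 1]
        assert np.allclose(np.diag(cov), c.total)
        assert off == pytest.approx(c.var_H + c.var_M + c.var_W)

    def test_dz_pair_block(self):
        d, cov = self._block(0, 1)
        c = self.comp
        assert cov.to_numpy()[0, 1] == pytest.approx(c.var_H + c.var_W)

    def test_duplicate_aliquots_block(self):
        d, cov = self._block(1, 0, n_dup=1)
        c = self.comp
        dup = d.duplicate_map()[0]
        assert cov.loc[dup[0], dup[1]] == pytest.approx(c.total - c.var_eps)

    def test_block_diagonal_across_pairs(self):
        d, cov = self._block(2, 2)
        meta = d.metadata(include_reference=False).set_index("aliquot_id")
        pair = meta["pair_id"]
        for a in cov.index:
            for b in cov.columns:
                if pair[a] != pair[b]:
                    assert cov.loc[a, b] == 0.0


# -- likelihood ---------------------------------------------------------
class TestLoglike:
    @pytest.mark.parametrize("model_form", [1, 2])
    def test_blockwise_equals_dense(self, small_mixed_design, model_form):
        """Blockwise evaluation reproduces the dense multivariate-normal
        log-density at random parameter points to 1e-8."""
        d = small_mixed_design
        y = _random_y(d, seed=1)
        m = tv.TwinVarianceModel.from_design(y, d, model_form=model_form)
        rng = np.random.default_rng(3)
        for _ in range(20):
            comp = tv.VarianceComponents(*rng.uniform(0.05, 2.0, 6))
            beta = rng.normal(0, 2, m.k_fe)
            assert m.loglike(comp, fe_params=beta) == pytest.approx(
                dense_loglike(d, comp, beta, y, model_form), abs=1e-8)

    def test_profiled_beta_is_gls_optimum(self, small_mixed_design):
        d = small_mixed_design
        y = _random_y(d, seed=2)
        m = tv.TwinVarianceModel.from_design(y, d)
        comp = tv.VarianceComponents(0.2, 0.1, 0.3, 0.1, 0.2, 0.4)
        ll_prof, beta = m._profiled(np.array(list(comp.as_dict().values())))
        rng = np.random.default_rng(4)
        for _ in range(10):
            perturbed = beta + rng.normal(0, 0.1, len(beta))
            assert m.loglike(comp, fe_params=perturbed) <= ll_prof + 1e-10

    def test_mz_only_flat_in_hm_split(self):
        """With MZ pairs only, the likelihood depends on var_H + var_M but
        not the split — the identifiability gap behind the zygosity check."""
        d = tv.generate_design(4, 0, 2, 1, n_reference_wells_per_plate=0,
                               seed=6)
        g = tv.build_grouping(d, require_both_zygosities=False)
        y = _random_y(d, seed=7)
        order = g.aliquot_ids
        splits = [(0.5, 0.0), (0.25, 0.25), (0.0, 0.5), (0.1, 0.4)]
        lls = []
        for h, m_ in splits:
            comp = tv.VarianceComponents(h, m_, 0.2, 0.1, 0.1, 0.3)
            cov = tv.marginal_covariance(g, comp)
            lls.append(multivariate_normal.logpdf(
                y.loc[order], mean=np.full(len(order), 5.0),
                cov=cov.to_numpy()))
        assert np.ptp(lls) < 1e-10


# -- fitting ------------------------------------------------------------
class TestFit:
    def test_residual_only_boundary(self):
        """Pure-residual data drives the biological components to the 0
        boundary: the experimental share is ~100% once the cohort is large
        enough to pin the boundary (at study scale the boundary estimates
        scatter, as ML theory predicts)."""
        d = tv.generate_design(300, 200, 100, 100, seed=2)
        comp = tv.VarianceComponents(0, 0, 0, 0, 0, 0.5)
        spec = tv.AntibodyGeneratorSpec(
            "ab", comp, plate_means=tuple([5.0] * d.n_plates),
            boxcox_lambda=1.0)
        lat = tv.latent_intensities(d, [spec], seed=8,
                                    include_reference=False)
        res = tv.fit_variance_model(lat["ab"], d)
        prop = res.proportions()
        assert prop.exp > 95.0
        c = res.components
        assert c.var_H + c.var_M + c.var_E + c.var_W + c.var_V < 0.05 * c.total

    def test_optimum_dominates_truth_and_starts(self, study_design):
        comp = tv.VarianceComponents.from_acde(
            var_A=0.2, var_E=0.2, var_W=0.1, var_V=0.1, var_eps=0.4)
        spec = tv.AntibodyGeneratorSpec("ab", comp,
                                        plate_means=(5.0, 5.2, 4.9),
                                        boxcox_lambda=1.0)
        lat = tv.latent_intensities(study_design, [spec], seed=9,
                                    include_reference=False)
        res = tv.fit_variance_model(lat["ab"], study_design)
        assert res.llf >= res.model.loglike(comp) - 1e-6
        v0 = float(np.var(lat["ab"]))
        for frac in (1 / 6, 0.9, 0.02):
            start = tv.VarianceComponents(*np.full(6, frac * v0 / 6))
            assert res.llf >= res.model.loglike(start) - 1e-6

    def test_scale_equivariance(self, study_design):
        """y -> a*y + b scales every variance by a^2 and leaves proportions
        unchanged."""
        comp = tv.VarianceComponents.from_acde(
            var_A=0.3, var_E=0.1, var_W=0.05, var_V=0.1, var_eps=0.45)
        spec = tv.AntibodyGeneratorSpec("ab", comp,
                                        plate_means=(5.0, 5.2, 4.9),
                                        boxcox_lambda=1.0)
        lat = tv.latent_intensities(study_design, [spec], seed=10,
                                    include_reference=False)
        y = lat["ab"]
        a, b = 3.7, -12.0
        r1 = tv.fit_variance_model(y, study_design)
        r2 = tv.fit_variance_model(a * y + b, study_design)
        for k, v in r1.components.as_dict().items():
            assert r2.components.as_dict()[k] == pytest.approx(
                a * a * v, rel=1e-4, abs=1e-8), k
        p1, p2 = r1.proportions().as_dict(), r2.proportions().as_dict()
        for k in ("fam", "env", "cv", "iv", "exp"):
            assert p2[k] == pytest.approx(p1[k], rel=1e-6, abs=1e-6)

    def test_aic_identity_and_k(self, study_design):
        y = _random_y(study_design, seed=11)
        for form, k in [(1, 3 + 6), (2, 6 + 6)]:
            res = tv.fit_variance_model(y, study_design, model_form=form)
            assert res.k_params == k
            assert res.aic == pytest.approx(2 * k - 2 * res.llf, abs=1e-10)

    def test_summary_renders(self, study_design):
        y = _random_y(study_design, seed=12)
        res = tv.fit_variance_model(y, study_design)
        text = res.summary()
        assert "familial" in text and "AIC" in text


# -- model selection ----------------------------------------------------
class TestSelectModel:
    def test_aic_formula(self):
        # k = 9, ln L = 0 -> AIC = 18
        assert 2 * 9 - 2 * 0.0 == 18

    def test_drift_detected(self, study_design):
        comp = tv.VarianceComponents.from_acde(
            var_A=0.12, var_E=0.12, var_W=0.03, var_V=0.1, var_eps=0.63)
        sd_tot = np.sqrt(comp.total)
        b = 2 * sd_tot / 90  # slope spanning ~2 total SD across a plate
        spec = tv.AntibodyGeneratorSpec(
            "ab", comp, plate_means=(5.0, 5.2, 4.9),
            drift_slopes=(b, b, b), boxcox_lambda=1.0)
        lat = tv.latent_intensities(study_design, [spec], seed=13,
                                    include_reference=False)
        res = tv.select_model(lat["ab"], study_design)
        assert res.model_form == 2
        assert res.aic_by_form[2] < res.aic_by_form[1]

    def test_no_drift_prefers_model1(self, study_design):
        comp = tv.VarianceComponents.from_acde(
            var_A=0.12, var_E=0.12, var_W=0.03, var_V=0.1, var_eps=0.63)
        spec = tv.AntibodyGeneratorSpec("ab", comp,
                                        plate_means=(5.0, 5.2, 4.9),
                                        boxcox_lambda=1.0)
        lat = tv.latent_intensities(study_design, [spec], seed=14,
                                    include_reference=False)
        res = tv.select_model(lat["ab"], study_design)
        assert res.model_form == 1


# -- proportions --------------------------------------------------------
class TestProportions:
    def test_published_row(self):
        """Variance components in the printed ratio (31.3, 0.7, 0, 18, 49.9)
        reproduce that row exactly as percentages."""
        comp = tv.VarianceComponents(
            var_H=0.313 / 2, var_M=0.313 / 2, var_E=0.007, var_W=0.0,
            var_V=0.18, var_eps=0.499)
        p = tv.variance_proportions(comp)
        # the printed row sums to 99.9, so match at the printed precision
        got = tuple(round(x, 1) for x in (p.fam, p.env, p.cv, p.iv, p.exp))
        assert got == (31.3, 0.7, 0.0, 18.0, 49.9)

    def test_residual_only(self):
        p = tv.variance_proportions(tv.VarianceComponents(0, 0, 0, 0, 0, 2.0))
        assert (p.fam, p.env, p.cv, p.iv, p.exp) == (0, 0, 0, 0, 100)
        assert p.fam_ne is None

    def test_equal_components(self):
        p = tv.variance_proportions(tv.VarianceComponents(*[1.0] * 6))
        assert p.fam == pytest.approx(33.33, abs=0.005)
        for v in (p.env, p.cv, p.iv, p.exp):
            assert v == pytest.approx(16.67, abs=0.005)

    def test_sum_to_100(self, rng):
        for _ in range(50):
            comp = tv.VarianceComponents(*rng.uniform(0, 3, 6))
            p = tv.variance_proportions(comp)
            assert p.fam + p.env + p.cv + p.iv + p.exp == pytest.approx(
                100.0, abs=1e-6)
            if p.fam_ne is not None:
                assert p.fam_ne + p.env_ne + p.cv_ne + p.iv_ne == pytest.approx(
                    100.0, abs=1e-6)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError, match="zero"):
            tv.variance_proportions(tv.VarianceComponents(0, 0, 0, 0, 0, 0))
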