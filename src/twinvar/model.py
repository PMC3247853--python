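"""Maximum-likelihood variance decomposition for longitudinal twin data.

For one antibody, the transformed intensity of aliquot l of the sample
taken at visit k from twin j of pair i is modelled as

    y_ijkl = mu_p(i,j,k,l) + H_i + M + E_ij + W_ik + V_ijk + eps_ijkl

with plate means mu_p as fixed effects (model form 2 adds a linear,
plate-specific drift over well position) and independent Gaussian random
effects. H and M are the identifiable re-parameterisation of the biometric
additive/dominant/common-environment effects: M is grouped at the pair
level for monozygotic twins and at the individual level for dizygotic
twins, so that the implied co-twin covariance is Var(H)+Var(M) for MZ and
Var(H) for DZ pairs. E is individual environment, W common-visit, V
individual-visit, eps the experimental residual distinguishing duplicate
aliquots.

The marginal covariance is block-diagonal over twin pairs; the likelihood
is evaluated blockwise with fixed effects profiled out by generalised
least squares at each variance iterate, and maximised over standard
deviations (lower bound 0, so boundary estimates are attainable) from a
fixed multistart schedule.

Usage follows the statsmodels pattern::

    model = TwinVarianceModel.from_design(y, design, model_form=1)
    res = model.fit()
    res.proportions()       # percent of variance per component
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .design import CohortDesign, MZ, DZ
from .simulate import VarianceComponents

__all__ = [
    "RandomEffectGroups",
    "ProportionBreakdown",
    "TwinVarianceModel",
    "TwinVarianceResults",
    "build_grouping",
    "marginal_covariance",
    "fit_variance_model",
    "select_model",
    "variance_proportions",
]

EFFECTS = ("H", "M", "E", "W", "V")


@dataclass
class RandomEffectGroups:
    """Aliquot-to-group labels for the five structured random effects."""

    labels: dict[str, pd.Series]      # keys H, M, E, W, V; index = aliquot_id

    @property
    def aliquot_ids(self) -> pd.Index:
        return self.labels["H"].index

    def n_groups(self) -> dict[str, int]:
        return {k: int(v.nunique()) for k, v in self.labels.items()}


def build_grouping(
    metadata: pd.DataFrame | CohortDesign,
    require_both_zygosities: bool = True,
) -> RandomEffectGroups:
    """Derive random-effect group labels from aliquot metadata.

    H groups at the pair; M at the pair for MZ and the individual for DZ;
    E at the individual; W at (pair, visit); V at (individual, visit).
    Duplicate aliquots of one sample share all five labels. With a single
    zygosity the familial split H/M is not identifiable, so the default is
    to refuse such designs.
    """
    if isinstance(metadata, CohortDesign):
        metadata = metadata.metadata(include_reference=False)
    meta = metadata[metadata["individual_id"].notna()]
    zygosities = set(meta["zygosity"].unique())
    if require_both_zygosities and not {MZ, DZ} <= zygosities:
        raise ValueError(
            f"design contains only {sorted(zygosities)} pairs; Var(H) and "
            "Var(M) are confounded — request the combined familial variance "
            "(pass require_both_zygosities=False) instead of the H/M split"
        )
    idx = pd.Index(meta["aliquot_id"], name="aliquot_id")
    pair = pd.Series(meta["pair_id"].to_numpy(), index=idx)
    ind = pd.Series(meta["individual_id"].to_numpy(), index=idx)
    visit = meta["visit"].astype(str).to_numpy()
    is_mz = (meta["zygosity"] == MZ).to_numpy()
    labels = {
        "H": pair,
        "M": pair.where(is_mz, ind),
        "E": ind,
        "W": pd.Series(meta["pair_id"].to_numpy() + "|" + visit, index=idx),
        "V": pd.Series(meta["individual_id"].to_numpy() + "|" + visit, index=idx),
    }
    return RandomEffectGroups(labels=labels)


def marginal_covariance(
    groups: RandomEffectGroups,
    components: VarianceComponents,
) -> pd.DataFrame:
    """Dense marginal covariance implied by the groupings.

    Cov(y_a, y_b) = sum over effects g of var_g * 1[a, b share g's group],
    plus var_eps on the diagonal. Block-diagonal over pairs because no
    effect spans pairs. Intended for small designs and cross-checks; the
    fitter evaluates the likelihood blockwise without forming this matrix.
    """
    idx = groups.aliquot_ids
    n = len(idx)
    cov = np.zeros((n, n))
    vars_ = components.as_dict()
    for g in EFFECTS:
        lab = groups.labels[g].to_numpy()
        share = lab[:, None] == lab[None, :]
        cov += vars_[f"var_{g}"] * share
    cov += vars_["var_eps"] * np.eye(n)
    return pd.DataFrame(cov, index=idx, columns=idx)


@dataclass
class ProportionBreakdown:
    """Percent of phenotypic variance per component.

    fam = familial (H+M), env = individual environment, cv = common visit,
    iv = individual visit, exp = experimental residual. The *_ne fields
    re-express the non-experimental components as percentages of the
    non-experimental (biological) variance; they are None when the total
    variance is purely experimental.
    """

    fam: float
    env: float
    cv: float
    iv: float
    exp: float
    fam_ne: float | None = None
    env_ne: float | None = None
    cv_ne: float | None = None
    iv_ne: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {k: getattr(self, k) for k in
                ("fam", "env", "cv", "iv", "exp",
                 "fam_ne", "env_ne", "cv_ne", "iv_ne")}


def variance_proportions(components: VarianceComponents) -> ProportionBreakdown:
    """Convert variance components into percentage breakdowns."""
    c = components
    total = c.total
    if total <= 0:
        raise ValueError("all variance components are zero")
    fam = 100.0 * (c.var_H + c.var_M) / total
    env = 100.0 * c.var_E / total
    cv = 100.0 * c.var_W / total
    iv = 100.0 * c.var_V / total
    exp = 100.0 * c.var_eps / total
    ne = total - c.var_eps
    kw: dict[str, float | None] = {}
    if ne > 0:
        kw = {
            "fam_ne": 100.0 * (c.var_H + c.var_M) / ne,
            "env_ne": 100.0 * c.var_E / ne,
            "cv_ne": 100.0 * c.var_W / ne,
            "iv_ne": 100.0 * c.var_V / ne,
        }
    return ProportionBreakdown(fam=fam, env=env, cv=cv, iv=iv, exp=exp, **kw)


# fractions of the empirical variance used as deterministic multistarts,
# in effect order (H, M, E, W, V, eps)
_STARTS = np.array([
    [1 / 6, 1 / 6, 1 / 6, 1 / 6, 1 / 6, 1 / 6],
    [0.02, 0.02, 0.02, 0.02, 0.02, 0.90],
    [0.35, 0.35, 0.05, 0.05, 0.05, 0.15],
    [0.05, 0.05, 0.50, 0.05, 0.05, 0.30],
    [0.05, 0.05, 0.10, 0.30, 0.30, 0.20],
])


class TwinVarianceModel:
    """Gaussian mixed-effects model for one antibody on a twin design.

    Parameters
    ----------
    endog : per-aliquot transformed intensities, indexed by aliquot ID (or
        aligned positionally with ``metadata``).
    metadata : per-aliquot table with columns aliquot_id, pair_id,
        individual_id, zygosity, visit, plate, well (reference wells, i.e.
        rows without an individual, are excluded).
    model_form : 1 for plate means only; 2 adds a linear plate-specific
        drift over the centered well index.
    """

    def __init__(
        self,
        endog: pd.Series | np.ndarray,
        metadata: pd.DataFrame,
        model_form: int = 1,
    ) -> None:
        if model_form not in (1, 2):
            raise ValueError(f"model_form must be 1 or 2, got {model_form}")
        meta = metadata[metadata["individual_id"].notna()].reset_index(drop=True)
        if isinstance(endog, pd.Series):
            y = endog.reindex(meta["aliquot_id"]).to_numpy(float)
            if np.isnan(y).any():
                missing = meta["aliquot_id"][np.isnan(y)].tolist()
                raise ValueError(f"endog missing aliquots: {missing[:5]}")
        else:
            y = np.asarray(endog, float)
            if len(y) != len(meta):
                raise ValueError("endog length does not match metadata")
        self.model_form = model_form
        self.meta = meta
        self.endog = y
        self.nobs = len(y)
        self.groups = build_grouping(meta)

        # fixed-effect design: one mean per plate; form 2 adds per-plate
        # slopes on the within-plate-centered well index
        plates = meta["plate"].to_numpy()
        self.plate_ids = np.unique(plates)
        dummies = (plates[:, None] == self.plate_ids[None, :]).astype(float)
        names = [f"mu_plate_{p}" for p in self.plate_ids]
        X = dummies
        if model_form == 2:
            centers = meta.groupby("plate")["well"].transform("mean")
            cwell = (meta["well"] - centers).to_numpy(float)
            X = np.hstack([dummies, dummies * cwell[:, None]])
            names += [f"beta_plate_{p}" for p in self.plate_ids]
        self.exog = X
        self.exog_names = names
        self.k_fe = X.shape[1]
        self.k_params = self.k_fe + 6

        self._build_blocks()

    # -- blockwise machinery ---------------------------------------------
    def _build_blocks(self) -> None:
        meta = self.meta
        label_codes = {}
        for g in EFFECTS:
            codes, _ = pd.factorize(self.groups.labels[g].to_numpy())
            label_codes[g] = codes
        patterns: dict[tuple, dict] = {}
        for _, block_idx in meta.groupby("pair_id", sort=True).indices.items():
            block_idx = np.sort(block_idx)
            key_parts = []
            shares = []
            for g in EFFECTS:
                c = label_codes[g][block_idx]
                # canonical within-block codes (first-occurrence order)
                _, canon = np.unique(c, return_inverse=True)
                first = {v: i for i, v in enumerate(pd.unique(c))}
                canon = np.array([first[v] for v in c])
                key_parts.append(tuple(canon))
                shares.append(canon[:, None] == canon[None, :])
            key = (len(block_idx), *key_parts)
            entry = patterns.setdefault(
                key, {"share": np.array(shares, float), "idx": []}
            )
            entry["idx"].append(block_idx)
        self._patterns = []
        for key, entry in patterns.items():
            idx = np.array(entry["idx"])                    # (nb, m)
            Y = self.endog[idx]                             # (nb, m)
            X = self.exog[idx]                              # (nb, m, p)
            self._patterns.append({"share": entry["share"], "Y": Y, "X": X,
                                   "n_blocks": idx.shape[0], "m": idx.shape[1],
                                   "idx": idx})

    def loglike(
        self,
        components: VarianceComponents | np.ndarray,
        fe_params: np.ndarray | None = None,
    ) -> float:
        """Marginal Gaussian log-likelihood, blockwise over pairs.

        With ``fe_params`` omitted the fixed effects are profiled out by
        generalised least squares at the given variance components.
        """
        if isinstance(components, VarianceComponents):
            v = np.array([components.var_H, components.var_M, components.var_E,
                          components.var_W, components.var_V, components.var_eps])
        else:
            v = np.asarray(components, float)
        llf, beta = self._profiled(v, fe_params)
        return llf

    def _profiled(
        self, v: np.ndarray, fe_params: np.ndarray | None = None
    ) -> tuple[float, np.ndarray]:
        p = self.k_fe
        logdet = 0.0
        ytSy = 0.0
        XtSy = np.zeros(p)
        XtSX = np.zeros((p, p))
        if not np.all(np.isfinite(v)):
            return -np.inf, np.full(p, np.nan)
        for pat in self._patterns:
            m, nb = pat["m"], pat["n_blocks"]
            Sigma = v[5] * np.eye(m)
            Sigma += np.tensordot(v[:5], pat["share"], axes=1)
            try:
                L = np.linalg.cholesky(Sigma)
                B = np.concatenate([pat["Y"][:, :, None], pat["X"]], axis=2)
                # solve Sigma @ C = B for all blocks at once
                flat = B.transpose(1, 0, 2).reshape(m, -1)
                C = np.linalg.solve(Sigma, flat).reshape(m, nb, 1 + p)\
                    .transpose(1, 0, 2)
            except np.linalg.LinAlgError:
                return -np.inf, np.full(p, np.nan)
            logdet += nb * 2.0 * np.log(np.diag(L)).sum()
            Cy, CX = C[:, :, 0], C[:, :, 1:]
            ytSy += float(np.einsum("bm,bm->", pat["Y"], Cy))
            XtSy += np.einsum("bmp,bm->p", pat["X"], Cy)
            XtSX += np.einsum("bmp,bmq->pq", pat["X"], CX)
        if fe_params is None:
            beta = np.linalg.solve(XtSX, XtSy)
            quad = ytSy - beta @ XtSy
        else:
            beta = np.asarray(fe_params, float)
            quad = ytSy - 2.0 * beta @ XtSy + beta @ XtSX @ beta
        llf = -0.5 * (self.nobs * np.log(2.0 * np.pi) + logdet + quad)
        return float(llf), beta

    # -- fitting ----------------------------------------------------------
    def fit(
        self,
        starts: int = 5,
        gtol: float = 1e-8,
        maxiter: int = 500,
    ) -> "TwinVarianceResults":
        """Maximise the likelihood over non-negative variance components.

        The endogenous variable is standardised internally (results are
        reported on the original scale), the optimiser works on standard
        deviations with lower bound 0 under L-BFGS-B, and the best of
        ``starts`` deterministic multistarts is returned.
        """
        y = self.endog
        shift = float(np.mean(y))
        scale = float(np.std(y))
        if scale == 0:
            raise ValueError("endog is constant; variance model undefined")
        z = (y - shift) / scale
        zmodel = self._standardized(z)

        # dispersion of z around its OLS plate fit seeds the multistarts
        beta0, *_ = np.linalg.lstsq(self.exog, z, rcond=None)
        v0 = float(np.var(z - self.exog @ beta0))
        v0 = max(v0, 1e-8)

        floor = 1e-8
        bounds = [(0.0, None)] * 5 + [(floor, None)]

        def neg(sd: np.ndarray) -> float:
            llf, _ = zmodel._profiled(sd**2)
            return -llf if np.isfinite(llf) else 1e12

        best = None
        for frac in _STARTS[:starts]:
            sd0 = np.sqrt(frac * v0)
            sd0[5] = max(sd0[5], floor)
            res = optimize.minimize(
                neg, sd0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": maxiter, "ftol": 1e-12, "gtol": gtol},
            )
            if best is None or res.fun < best.fun:
                best = res
        sd = np.asarray(best.x)
        sd[np.abs(sd) < 1e-7] = 0.0        # snap numerically-zero SDs to 0
        llf_z, beta_z = zmodel._profiled(np.maximum(sd, 0.0) ** 2)
        # if snapping moved the optimum, keep the unsnapped solution
        if llf_z < -best.fun - 1e-6:
            sd = np.asarray(best.x)
            llf_z, beta_z = zmodel._profiled(sd**2)

        v = (sd * scale) ** 2
        components = VarianceComponents(*v)
        llf = llf_z - self.nobs * np.log(scale)
        beta = beta_z * scale
        beta[: len(self.plate_ids)] += shift     # plate means absorb the shift
        fe = pd.Series(beta, index=self.exog_names)
        aic = 2.0 * self.k_params - 2.0 * llf

        warnings = []
        has_dupes = self.meta.duplicated("sample_id", keep=False).any()
        if components.var_eps == 0.0 and has_dupes:
            warnings.append(
                "var_eps estimated at the 0 boundary although duplicate "
                "aliquots are present"
            )
        return TwinVarianceResults(
            model=self,
            components=components,
            fe_params=fe,
            llf=llf,
            k_params=self.k_params,
            aic=aic,
            converged=bool(best.success),
            warnings=warnings,
        )

    def _standardized(self, z: np.ndarray) -> "TwinVarianceModel":
        """Shallow clone sharing block structure but with endog replaced."""
        clone = object.__new__(TwinVarianceModel)
        clone.__dict__.update(self.__dict__)
        clone.endog = z
        clone._patterns = [
            {**pat, "Y": z[pat["idx"]]} for pat in self._patterns
        ]
        return clone

    @classmethod
    def from_design(
        cls,
        endog: pd.Series | np.ndarray,
        design: CohortDesign,
        model_form: int = 1,
    ) -> "TwinVarianceModel":
        return cls(endog, design.metadata(include_reference=False), model_form)


@dataclass
class TwinVarianceResults:
    """ML fit of the twin variance model for one antibody."""

    model: TwinVarianceModel
    components: VarianceComponents
    fe_params: pd.Series
    llf: float
    k_params: int
    aic: float
    converged: bool
    warnings: list[str] = field(default_factory=list)
    aic_by_form: dict[int, float] | None = None

    @property
    def model_form(self) -> int:
        return self.model.model_form

    def proportions(self) -> ProportionBreakdown:
        return variance_proportions(self.components)

    def summary(self) -> str:
        c = self.components
        prop = self.proportions()
        lines = [
            "Twin variance decomposition (ML)",
            "=" * 48,
            f"model form:        {self.model_form}"
            + ("  (plate means)" if self.model_form == 1
               else "  (plate means + well drift)"),
            f"aliquots:          {self.model.nobs}",
            f"log-likelihood:    {self.llf:.4f}",
            f"parameters (k):    {self.k_params}",
            f"AIC:               {self.aic:.4f}",
            f"converged:         {self.converged}",
            "-" * 48,
            f"{'component':<22}{'variance':>12}{'% of total':>12}",
        ]
        rows = [
            ("familial (H+M)", c.var_H + c.var_M, prop.fam),
            ("indiv. environment", c.var_E, prop.env),
            ("common visit", c.var_W, prop.cv),
            ("individual visit", c.var_V, prop.iv),
            ("experimental", c.var_eps, prop.exp),
        ]
        for name, var, pct in rows:
            lines.append(f"{name:<22}{var:>12.5f}{pct:>12.1f}")
        lines.append("-" * 48)
        for name, val in self.fe_params.items():
            lines.append(f"{name:<22}{val:>12.5f}")
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


def fit_variance_model(
    endog: pd.Series | np.ndarray,
    design: CohortDesign | pd.DataFrame,
    model_form: int = 1,
    **fit_kwargs,
) -> TwinVarianceResults:
    """Convenience wrapper: build the model and fit it."""
    if isinstance(design, CohortDesign):
        model = TwinVarianceModel.from_design(endog, design, model_form)
    else:
        model = TwinVarianceModel(endog, design, model_form)
    return model.fit(**fit_kwargs)


def select_model(
    endog: pd.Series | np.ndarray,
    design: CohortDesign | pd.DataFrame,
    **fit_kwargs,
) -> TwinVarianceResults:
    """Fit both model forms and return the one with smaller AIC.

    Ties go to form 1 (fewer parameters).
    """
    res1 = fit_variance_model(endog, design, model_form=1, **fit_kwargs)
    res2 = fit_variance_model(endog, design, model_form=2, **fit_kwargs)
    chosen = res1 if res1.aic <= res2.aic else res2
    chosen.aic_by_form = {1: res1.aic, 2: res2.aic}
    return chosen
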