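"""Pre-processing of raw antibody-array intensities.

The pipeline applies, in order: probabilistic quotient normalisation (PQN)
to remove per-aliquot multiplicative dilution; multivariate outlier
screening in the first two principal-component scores with a chi-squared
rule; and a per-antibody Box-Cox transformation chosen by profile maximum
likelihood to Gaussianise the intensities for the mixed-model fit.
Technical reproducibility is quantified as the per-antibody Spearman
correlation between duplicate aliquots of the same sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .design import CohortDesign
from .intensity import IntensityTable

__all__ = [
    "ConcordanceResult",
    "OutlierReport",
    "BoxCoxFit",
    "PreprocessResult",
    "pqn_normalize",
    "replicate_concordance",
    "chi2_cutoff",
    "detect_outliers",
    "boxcox_fit_transform",
    "preprocess_pipeline",
]


@dataclass
class ConcordanceResult:
    """Per-antibody duplicate-aliquot rank correlations with cohort summary."""

    r: pd.Series                      # Spearman r per antibody (NaN if undefined)
    duplicate_map: list[tuple[str, str]]

    @property
    def median(self) -> float:
        return float(self.r.dropna().median())

    @property
    def iqr(self) -> tuple[float, float]:
        q = self.r.dropna().quantile([0.25, 0.75])
        return float(q.iloc[0]), float(q.iloc[1])


@dataclass
class OutlierReport:
    """Squared Mahalanobis distances in the 2-D principal projection."""

    distances: pd.Series              # per aliquot, >= 0
    threshold: float
    scores: pd.DataFrame              # the two principal-score coordinates

    @property
    def flagged(self) -> list[str]:
        return self.distances.index[self.distances > self.threshold].tolist()


@dataclass
class BoxCoxFit:
    """Profile-ML Box-Cox transform of one antibody column."""

    lmbda: float
    loglik: float
    transformed: pd.Series


@dataclass
class PreprocessResult:
    table: IntensityTable             # transformed stage
    outliers: OutlierReport
    concordance_before: ConcordanceResult | None
    concordance_after: ConcordanceResult | None
    boxcox: dict[str, BoxCoxFit] = field(default_factory=dict)


def pqn_normalize(
    table: IntensityTable,
    reference_rows: list[str] | None = None,
) -> IntensityTable:
    """Probabilistic quotient normalisation against a median reference spectrum.

    The reference is the antibody-wise median over ``reference_rows`` (all
    aliquots by default); each aliquot is divided by the median of its
    antibody-wise quotients against that reference, removing a common
    multiplicative dilution factor per aliquot.
    """
    if table.stage != "raw":
        raise ValueError(f"PQN expects a raw-stage table, got {table.stage!r}")
    X = table.values
    if len(X) < 2:
        raise ValueError("PQN needs at least 2 aliquots")
    if X.shape[1] < 2:
        raise ValueError(
            "PQN with a single antibody is degenerate (the median quotient "
            "would erase the column)"
        )
    ref_block = X.loc[reference_rows] if reference_rows is not None else X
    reference = ref_block.median(axis=0)
    quotients = X.div(reference, axis=1)
    factors = quotients.median(axis=1)
    out = X.div(factors, axis=0)
    return table.with_stage(out, "normalized")


def replicate_concordance(
    table: IntensityTable,
    duplicate_map: list[tuple[str, str]],
) -> ConcordanceResult:
    """Spearman correlation between duplicate aliquots, per antibody.

    For antibody k, the vector of first-aliquot values across duplicated
    samples is correlated with the vector of second-aliquot values. A
    constant vector leaves r undefined; it is reported as NaN and excluded
    from the cohort median/IQR.
    """
    missing = [a for pair in duplicate_map for a in pair
               if a not in table.values.index]
    if missing:
        raise ValueError(f"duplicate aliquots absent from table: {missing}")
    if len(duplicate_map) < 3:
        raise ValueError(
            f"need >= 3 duplicate pairs for a correlation, got {len(duplicate_map)}"
        )
    first = table.values.loc[[a for a, _ in duplicate_map]].to_numpy()
    second = table.values.loc[[b for _, b in duplicate_map]].to_numpy()
    r = {}
    for j, ab in enumerate(table.antibodies):
        v1, v2 = first[:, j], second[:, j]
        if np.ptp(v1) == 0 or np.ptp(v2) == 0:
            r[ab] = np.nan
            continue
        r[ab] = stats.spearmanr(v1, v2).statistic
    return ConcordanceResult(r=pd.Series(r, name="spearman_r"),
                             duplicate_map=list(duplicate_map))


def chi2_cutoff(df: int, alpha: float) -> float:
    """Upper-alpha quantile of the chi-squared distribution with df degrees
    of freedom (for df=2 this is exactly -2 ln alpha)."""
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return float(stats.chi2.isf(alpha, df))


def detect_outliers(table: IntensityTable, alpha: float = 1e-4) -> OutlierReport:
    """Flag aliquots far from the origin in the 2-D principal projection.

    Columns are standardised to mean 0, SD 1; the standardised matrix is
    decomposed by SVD; each aliquot's squared Mahalanobis distance from the
    origin in the first two principal scores (using their empirical diagonal
    covariance) is compared to the upper-alpha chi-squared quantile with 2
    degrees of freedom.
    """
    X = table.values
    if len(X) < 3:
        raise ValueError("outlier screening needs >= 3 aliquots")
    if X.shape[1] < 2:
        raise ValueError("outlier screening needs >= 2 antibodies")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0].tolist()
        raise ValueError(f"constant antibody column(s): {bad}")
    Z = (X - X.mean(axis=0)) / sd
    U, S, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    if (S > S[0] * 1e-12).sum() < 2:
        raise ValueError("standardised matrix has rank < 2")
    scores = U[:, :2] * S[:2]
    var = scores.var(axis=0, ddof=1)
    d2 = (scores**2 / var).sum(axis=1)
    threshold = chi2_cutoff(2, alpha)
    return OutlierReport(
        distances=pd.Series(d2, index=X.index, name="mahalanobis_sq"),
        threshold=threshold,
        scores=pd.DataFrame(scores, index=X.index, columns=["pc1", "pc2"]),
    )


def boxcox_fit_transform(
    column: pd.Series,
    interval: tuple[float, float] = (-2.0, 2.0),
) -> BoxCoxFit:
    """Box-Cox transform with lambda chosen by profile maximum likelihood.

    t(y; lambda) = (y^lambda - 1)/lambda for lambda != 0, ln(y) at 0;
    lambda maximises the profile log-likelihood over the closed interval.
    """
    y = np.asarray(column, float)
    if len(y) < 10:
        raise ValueError(f"need >= 10 values to fit lambda, got {len(y)}")
    if np.any(y <= 0):
        raise ValueError(f"non-positive value in column {column.name!r}")
    if np.ptp(y) == 0:
        raise ValueError(f"constant column {column.name!r}")
    res = optimize.minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, y),
        bounds=interval, method="bounded",
        options={"xatol": 1e-6},
    )
    lam = float(res.x)
    transformed = pd.Series(stats.boxcox(y, lmbda=lam), index=column.index,
                            name=column.name)
    return BoxCoxFit(lmbda=lam, loglik=float(stats.boxcox_llf(lam, y)),
                     transformed=transformed)


def preprocess_pipeline(
    raw: IntensityTable,
    design: CohortDesign,
    alpha: float = 1e-4,
) -> PreprocessResult:
    """Normalise, screen outliers, and Gaussianise a raw table.

    Order: PQN (reference spectrum from study aliquots only), outlier
    detection on the normalised study aliquots (flagged aliquots and
    reference wells dropped), then a per-antibody Box-Cox transform.
    Duplicate-aliquot concordance is reported before and after PQN.
    """
    study_ids = [a for a in design.aliquots["aliquot_id"]
                 if a in raw.values.index]
    normalized = pqn_normalize(raw, reference_rows=study_ids)

    dup_map = [(a, b) for a, b in design.duplicate_map()
               if a in raw.values.index and b in raw.values.index]
    conc_before = conc_after = None
    if len(dup_map) >= 3:
        conc_before = replicate_concordance(raw, dup_map)
        conc_after = replicate_concordance(normalized, dup_map)

    study = IntensityTable(normalized.values.loc[study_ids], stage="normalized")
    outliers = detect_outliers(study, alpha=alpha)
    keep = [a for a in study_ids if a not in set(outliers.flagged)]
    kept = study.values.loc[keep]

    fits: dict[str, BoxCoxFit] = {}
    cols = {}
    for ab in kept.columns:
        fit = boxcox_fit_transform(kept[ab])
        fits[ab] = fit
        cols[ab] = fit.transformed
    transformed = IntensityTable(pd.DataFrame(cols, index=kept.index),
                                 stage="transformed")
    return PreprocessResult(
        table=transformed,
        outliers=outliers,
        concordance_before=conc_before,
        concordance_after=conc_after,
        boxcox=fits,
    )
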