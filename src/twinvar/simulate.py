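"""Synthetic antibody-array intensities with the twin variance structure.

Each antibody's transformed-scale value for aliquot l of the sample taken
at visit k from twin j of pair i is

    y = mu_p + beta_p * (well - plate mean well) + H_i + M + E_ij + W_ik
        + V_ijk + eps_ijkl

where mu_p is a plate mean, beta_p an optional plate-specific linear drift
over well position, and the random effects are independent Gaussians:

    H  — familial, one draw per pair;
    M  — the second familial effect, drawn per pair for MZ twins and per
         individual for DZ twins (this grouping reproduces the co-twin
         covariances Var(H)+Var(M) for MZ and Var(H) for DZ);
    E  — stable individual environment, one draw per individual;
    W  — common visit, one draw per (pair, visit);
    V  — individual visit, one draw per (individual, visit);
    eps — experimental residual, one draw per aliquot.

The familial variances may equivalently be given on the biometric A/D/C
(additive, dominant, common-environment) scale; they map to the estimable
pair via Var(H) = A/2 + D/4 + C and Var(M) = A/2 + 3D/4.

The raw fluorescence scale is the inverse Box-Cox image of the latent
value, multiplied by a per-aliquot log-normal dilution factor shared by
all antibodies of that aliquot — the multiplicative corruption that
probabilistic quotient normalisation is designed to remove. Reference
wells carry a fixed latent profile (plate effects plus residual only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import inv_boxcox

from .design import CohortDesign, MZ
from .intensity import IntensityTable

__all__ = [
    "VarianceComponents",
    "AntibodyGeneratorSpec",
    "simulate_intensities",
    "latent_intensities",
]


@dataclass(frozen=True)
class VarianceComponents:
    """The six estimable variance parameters of the twin model.

    Optionally carries the generator-only biometric variances A/D/C from
    which H and M were derived; these are never estimated.
    """

    var_H: float
    var_M: float
    var_E: float
    var_W: float
    var_V: float
    var_eps: float
    var_A: float | None = None
    var_D: float | None = None
    var_C: float | None = None

    def __post_init__(self) -> None:
        for name in ("var_H", "var_M", "var_E", "var_W", "var_V", "var_eps"):
            v = getattr(self, name)
            if v < 0 or not np.isfinite(v):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.var_A is not None:
            a, d, c = self.var_A, self.var_D or 0.0, self.var_C or 0.0
            if not np.isclose(self.var_H, 0.5 * a + 0.25 * d + c):
                raise ValueError("var_H inconsistent with A/D/C: expected A/2+D/4+C")
            if not np.isclose(self.var_M, 0.5 * a + 0.75 * d):
                raise ValueError("var_M inconsistent with A/D/C: expected A/2+3D/4")

    @classmethod
    def from_acde(
        cls,
        var_A: float = 0.0,
        var_D: float = 0.0,
        var_C: float = 0.0,
        var_E: float = 0.0,
        var_W: float = 0.0,
        var_V: float = 0.0,
        var_eps: float = 0.0,
    ) -> "VarianceComponents":
        """Build components from the biometric A/D/C parameterisation."""
        return cls(
            var_H=0.5 * var_A + 0.25 * var_D + var_C,
            var_M=0.5 * var_A + 0.75 * var_D,
            var_E=var_E, var_W=var_W, var_V=var_V, var_eps=var_eps,
            var_A=var_A, var_D=var_D, var_C=var_C,
        )

    @property
    def total(self) -> float:
        return (self.var_H + self.var_M + self.var_E
                + self.var_W + self.var_V + self.var_eps)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k)
                for k in ("var_H", "var_M", "var_E", "var_W", "var_V", "var_eps")}


@dataclass(frozen=True)
class AntibodyGeneratorSpec:
    """Generative settings for one antibody.

    plate_means/drift_slopes are per-plate (transformed scale); boxcox_lambda
    shapes the raw scale through the inverse Box-Cox map; dilution_sd is the
    SD of the shared per-aliquot log-normal dilution factor.
    """

    antibody_id: str
    components: VarianceComponents
    plate_means: tuple[float, ...]
    drift_slopes: tuple[float, ...] = ()
    boxcox_lambda: float = 0.0
    dilution_sd: float = 0.0
    reference_offset: float = 0.0

    def __post_init__(self) -> None:
        if not self.drift_slopes:
            object.__setattr__(self, "drift_slopes", (0.0,) * len(self.plate_means))
        if len(self.drift_slopes) != len(self.plate_means):
            raise ValueError("drift_slopes and plate_means must have equal length")
        if self.dilution_sd < 0:
            raise ValueError("dilution_sd must be >= 0")


def _centered_well(meta: pd.DataFrame) -> pd.Series:
    """Well index centered to mean 0 within each plate (study aliquots only
    define the center; reference wells reuse it)."""
    study = meta[meta["individual_id"].notna()]
    centers = study.groupby("plate")["well"].mean()
    return meta["well"] - meta["plate"].map(centers)


def latent_intensities(
    design: CohortDesign,
    specs: list[AntibodyGeneratorSpec],
    seed: int,
    include_reference: bool = True,
) -> pd.DataFrame:
    """Transformed-scale latent values (before inverse Box-Cox and dilution).

    Exposed separately so that the additive variance structure can be
    examined without the raw-scale distortions.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    meta = design.metadata(include_reference=include_reference)
    is_ref = meta["individual_id"].isna().to_numpy()
    cwell = _centered_well(meta).to_numpy(float)
    plates = meta["plate"].to_numpy()
    plate_ids = np.unique(plates)

    # grouping labels for the random effects (study aliquots)
    pair = meta["pair_id"]
    ind = meta["individual_id"]
    visit = meta["visit"]
    mz = meta["zygosity"] == MZ
    g_H = pair
    g_M = pair.where(mz, ind)
    g_E = ind
    g_W = pair.astype("string") + "|" + visit.astype("Int64").astype("string")
    g_V = ind.astype("string") + "|" + visit.astype("Int64").astype("string")

    rng = np.random.default_rng(seed)
    out = {}
    for spec in specs:
        if len(spec.plate_means) < len(plate_ids):
            raise ValueError(
                f"antibody {spec.antibody_id!r}: {len(spec.plate_means)} plate "
                f"means for {len(plate_ids)} plates"
            )
        mu = dict(zip(plate_ids, spec.plate_means))
        beta = dict(zip(plate_ids, spec.drift_slopes))
        c = spec.components
        y = np.array([mu[p] for p in plates], float)
        y += np.array([beta[p] for p in plates], float) * cwell
        for g, var in (
            (g_H, c.var_H), (g_M, c.var_M), (g_E, c.var_E),
            (g_W, c.var_W), (g_V, c.var_V),
        ):
            codes, uniques = pd.factorize(g)
            draws = rng.normal(0.0, np.sqrt(var), size=len(uniques))
            effect = np.where(codes >= 0, draws[np.maximum(codes, 0)], 0.0)
            y += effect
        y += rng.normal(0.0, np.sqrt(c.var_eps), size=len(y))
        if include_reference:
            # reference wells: fixed profile + plate/well/residual effects only
            y[is_ref] = (
                np.array([mu[p] for p in plates[is_ref]], float)
                + np.array([beta[p] for p in plates[is_ref]], float) * cwell[is_ref]
                + spec.reference_offset
                + rng.normal(0.0, np.sqrt(c.var_eps), size=is_ref.sum())
            )
        out[spec.antibody_id] = y
    return pd.DataFrame(out, index=pd.Index(meta["aliquot_id"], name="aliquot_id"))


def simulate_intensities(
    design: CohortDesign,
    specs: list[AntibodyGeneratorSpec],
    seed: int,
    include_reference: bool = True,
) -> IntensityTable:
    """Simulate a raw-stage intensity table for the given design.

    Latent values are drawn per antibody, mapped through the inverse
    Box-Cox transform at that antibody's lambda, then scaled by one
    log-normal dilution factor per aliquot shared across all antibodies.
    Bit-identical across runs with the same seed.
    """
    latent = latent_intensities(design, specs, seed, include_reference)
    # dilution draws come from a dedicated stream so that latent draws do
    # not depend on how many antibodies precede them
    dil_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    dilution_sds = {s.antibody_id: s.dilution_sd for s in specs}
    base = dil_rng.normal(0.0, 1.0, size=len(latent))

    raw = {}
    for spec in specs:
        z = latent[spec.antibody_id].to_numpy()
        lam = spec.boxcox_lambda
        if lam != 0 and np.any(lam * z + 1 <= 0):
            i = int(np.argmax(lam * z + 1 <= 0))
            raise ValueError(
                f"inverse Box-Cox undefined for antibody {spec.antibody_id!r} "
                f"at aliquot {latent.index[i]!r} (lambda={lam}, latent={z[i]:.4g})"
            )
        x = inv_boxcox(z, lam)
        if np.any(x <= 0) or not np.all(np.isfinite(x)):
            i = int(np.argmax((x <= 0) | ~np.isfinite(x)))
            raise ValueError(
                f"non-positive raw intensity for antibody {spec.antibody_id!r} "
                f"at aliquot {latent.index[i]!r}; adjust plate means or lambda"
            )
        raw[spec.antibody_id] = x * np.exp(base * spec.dilution_sd)
    values = pd.DataFrame(raw, index=latent.index)
    return IntensityTable(values=values, stage="raw")
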