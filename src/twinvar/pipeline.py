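"""End-to-end workflow: simulate (or ingest) -> preprocess -> fit -> summarise.

Configuration is a plain mapping (typically read from YAML); every stage
writes its tables as CSV under the output directory so that intermediate
results can be inspected or re-used, and a run log records the seed and
package versions. Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datasets import reference_panel
from .design import CohortDesign, generate_design
from .intensity import IntensityTable
from .model import select_model, fit_variance_model
from .preprocess import preprocess_pipeline
from .simulate import AntibodyGeneratorSpec, VarianceComponents, simulate_intensities
from .summarize import cohort_summary

__all__ = [
    "load_config", "specs_from_config", "run_simulate", "run_preprocess",
    "run_fit", "run_summarize", "run_all",
    "write_design", "read_design",
]

DEFAULT_DESIGN = dict(
    n_mz_pairs=56, n_dz_pairs=21, n_revisit_mz_pairs=34,
    n_duplicated_mz_pairs=24, plate_capacity=96,
    n_reference_wells_per_plate=6,
)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def specs_from_config(cfg: dict) -> list[AntibodyGeneratorSpec]:
    """Build antibody generator specs from a config mapping.

    ``antibodies: reference`` (optionally with ``n_antibodies``) uses the
    published panel; otherwise ``antibodies`` is a list of per-antibody
    mappings with variance components (either H/M or A/D/C keys),
    plate_means, and optional drift_slopes / boxcox_lambda / dilution_sd.
    """
    ab = cfg.get("antibodies", "reference")
    if ab == "reference":
        kwargs = {k: v for k, v in cfg.items()
                  if k in ("n_antibodies", "total_variance", "dilution_sd",
                           "boxcox_lambda")}
        pm = cfg.get("plate_means")
        if pm:
            kwargs["plate_means"] = tuple(pm)
        return reference_panel(**kwargs)
    specs = []
    for entry in ab:
        comp_cfg = dict(entry["components"])
        if "var_A" in comp_cfg or "var_D" in comp_cfg or "var_C" in comp_cfg:
            comp = VarianceComponents.from_acde(**comp_cfg)
        else:
            comp = VarianceComponents(**comp_cfg)
        specs.append(AntibodyGeneratorSpec(
            antibody_id=entry["antibody_id"],
            components=comp,
            plate_means=tuple(entry["plate_means"]),
            drift_slopes=tuple(entry.get("drift_slopes", ())),
            boxcox_lambda=entry.get("boxcox_lambda", 0.0),
            dilution_sd=entry.get("dilution_sd", 0.0),
        ))
    return specs


def write_design(design: CohortDesign, out_dir: Path) -> None:
    design.metadata(include_reference=True).to_csv(
        out_dir / "metadata.csv", index=False
    )


def read_design(path) -> pd.DataFrame:
    """Read a metadata CSV (the denormalised per-aliquot table)."""
    return pd.read_csv(path)


def run_simulate(cfg: dict, seed: int, out_dir: Path) -> tuple[CohortDesign, IntensityTable]:
    design_cfg = {**DEFAULT_DESIGN, **cfg.get("design", {})}
    design = generate_design(seed=seed, **design_cfg)
    specs = specs_from_config(cfg)
    table = simulate_intensities(design, specs, seed=seed)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_design(design, out_dir)
    table.to_csv(out_dir / "intensities_raw.csv")
    return design, table


def run_preprocess(design: CohortDesign, raw: IntensityTable, cfg: dict,
                   out_dir: Path):
    alpha = float(cfg.get("alpha", 1e-4))
    result = preprocess_pipeline(raw, design, alpha=alpha)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.table.to_csv(out_dir / "intensities_transformed.csv")
    rep = pd.DataFrame({
        "aliquot_id": result.outliers.distances.index,
        "distance": result.outliers.distances.to_numpy(),
        "flagged": result.outliers.distances.to_numpy() > result.outliers.threshold,
    })
    rep.to_csv(out_dir / "outliers.csv", index=False)
    if result.concordance_before is not None:
        conc = pd.DataFrame({
            "antibody_id": result.concordance_before.r.index,
            "r_before": result.concordance_before.r.to_numpy(),
            "r_after": result.concordance_after.r.to_numpy(),
        })
        conc.to_csv(out_dir / "concordance.csv", index=False)
    return result


def run_fit(table: IntensityTable, design: CohortDesign | pd.DataFrame,
            cfg: dict, out_dir: Path) -> pd.DataFrame:
    """Fit every antibody and write the per-antibody results table."""
    mode = str(cfg.get("model", "auto"))
    meta = design.metadata(include_reference=False) \
        if isinstance(design, CohortDesign) else design
    meta = meta[meta["aliquot_id"].isin(table.values.index)]
    rows = []
    for ab in table.antibodies:
        y = table.values[ab]
        if mode == "auto":
            res = select_model(y, meta)
            aic1 = res.aic_by_form[1]
            aic2 = res.aic_by_form[2]
        else:
            res = fit_variance_model(y, meta, model_form=int(mode))
            aic1 = res.aic if res.model_form == 1 else float("nan")
            aic2 = res.aic if res.model_form == 2 else float("nan")
        prop = res.proportions()
        rows.append({
            "antibody_id": ab,
            "model_selected": res.model_form,
            "aic_model1": aic1,
            "aic_model2": aic2,
            **res.components.as_dict(),
            **prop.as_dict(),
            "loglik": res.llf,
            "converged": res.converged,
        })
    results = pd.DataFrame(rows)
    out_dir.mkdir(parents=True, exist_ok=True)
    results.to_csv(out_dir / "results.csv", index=False)
    return results


def run_summarize(results: pd.DataFrame, out_dir: Path) -> pd.DataFrame:
    cols = ["fam", "env", "cv", "iv", "exp",
            "fam_ne", "env_ne", "cv_ne", "iv_ne"]
    summary = cohort_summary(results[cols])
    out_dir.mkdir(parents=True, exist_ok=True)
    summary.to_csv(out_dir / "summary.csv", index=False)
    return summary


def run_all(cfg: dict, seed: int, out_dir) -> Path:
    """Execute the full workflow and return the output directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs = cfg.get("inputs")
    try:
        if inputs:
            meta = read_design(inputs["metadata"])
            raw = IntensityTable.from_csv(inputs["intensities"], stage="raw")
            design = _design_from_metadata(meta)
        else:
            design, raw = run_simulate(cfg, seed, out_dir)
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate/ingest' failed: {exc}") from exc
    try:
        pre = run_preprocess(design, raw, cfg, out_dir)
    except Exception as exc:
        raise RuntimeError(f"stage 'preprocess' failed: {exc}") from exc
    try:
        results = run_fit(pre.table, design, cfg, out_dir)
    except Exception as exc:
        raise RuntimeError(f"stage 'fit' failed: {exc}") from exc
    try:
        run_summarize(results, out_dir)
    except Exception as exc:
        raise RuntimeError(f"stage 'summarize' failed: {exc}") from exc
    log = {
        "seed": seed,
        "twinvar_version": __version__,
        "python": sys.version.split()[0],
        "config": cfg,
        "n_antibodies": len(results),
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return out_dir


def _design_from_metadata(meta: pd.DataFrame) -> CohortDesign:
    """Reconstruct a CohortDesign from a denormalised metadata table."""
    study = meta[meta["individual_id"].notna()]
    ref = meta[meta["individual_id"].isna()]
    pairs = study[["pair_id", "zygosity"]].drop_duplicates(ignore_index=True)
    individuals = study[["individual_id", "pair_id"]].drop_duplicates(ignore_index=True)
    samples = study[["sample_id", "individual_id", "visit"]].drop_duplicates(
        ignore_index=True)
    aliquots = study[["aliquot_id", "sample_id", "replicate", "plate", "well"]]
    return CohortDesign(
        pairs=pairs,
        individuals=individuals,
        samples=samples,
        aliquots=aliquots.reset_index(drop=True),
        reference_wells=ref[["aliquot_id", "plate", "well"]].reset_index(drop=True),
    )
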