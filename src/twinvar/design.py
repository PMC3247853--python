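"""Twin-cohort sampling designs.

A design records who was sampled and where each serum aliquot ended up:
twin pairs (monozygotic or dizygotic), the individuals within them, one or
two clinic visits per pair, optional duplicate aliquots of a sample, and
the randomised assignment of aliquots to wells on 96-well assay plates.
Each plate can reserve a number of wells for a common reference sample.

The canonical study layout is 56 MZ + 21 DZ pairs all sampled at visit 1,
34 MZ pairs re-attending for visit 2 (222 samples), 48 samples from 24 MZ
pairs split into duplicate aliquots (270 aliquots), randomised onto three
96-well plates each carrying 6 reference wells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortDesign", "generate_design"]

MZ = "MZ"
DZ = "DZ"


@dataclass
class CohortDesign:
    """Sampling structure of a longitudinal twin cohort.

    Attributes
    ----------
    pairs : DataFrame with columns ``pair_id``, ``zygosity``.
    individuals : DataFrame with columns ``individual_id``, ``pair_id``.
    samples : DataFrame with columns ``sample_id``, ``individual_id``, ``visit``.
    aliquots : DataFrame with columns ``aliquot_id``, ``sample_id``,
        ``replicate``, ``plate``, ``well``.
    reference_wells : DataFrame with columns ``aliquot_id``, ``plate``, ``well``
        for wells carrying the common reference sample (no individual link).
    plate_capacity : wells per plate.
    seed : the seed used for the well randomisation.
    """

    pairs: pd.DataFrame
    individuals: pd.DataFrame
    samples: pd.DataFrame
    aliquots: pd.DataFrame
    reference_wells: pd.DataFrame
    plate_capacity: int = 96
    seed: int | None = None
    _metadata: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    # -- counts -----------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_aliquots(self) -> int:
        return len(self.aliquots)

    @property
    def n_plates(self) -> int:
        frames = [f["plate"] for f in (self.aliquots, self.reference_wells)
                  if len(f)]
        return int(pd.concat(frames).nunique())

    @property
    def n_occupied_wells(self) -> int:
        return self.n_aliquots + len(self.reference_wells)

    def metadata(self, include_reference: bool = True) -> pd.DataFrame:
        """Denormalised per-aliquot table (one row per occupied well).

        Columns: aliquot_id, sample_id, individual_id, pair_id, zygosity,
        visit, replicate, plate, well. Reference wells carry NA in the
        individual-linked fields.
        """
        if self._metadata is None:
            meta = (
                self.aliquots.merge(self.samples, on="sample_id")
                .merge(self.individuals, on="individual_id")
                .merge(self.pairs, on="pair_id")
            )
            cols = [
                "aliquot_id", "sample_id", "individual_id", "pair_id",
                "zygosity", "visit", "replicate", "plate", "well",
            ]
            self._metadata = meta[cols].sort_values("aliquot_id", ignore_index=True)
        meta = self._metadata
        if include_reference and len(self.reference_wells):
            ref = self.reference_wells.copy()
            for c in ("sample_id", "individual_id", "pair_id", "zygosity"):
                ref[c] = pd.NA
            ref["visit"] = pd.NA
            ref["replicate"] = pd.NA
            meta = pd.concat([meta, ref[meta.columns]], ignore_index=True)
        return meta.copy()

    def duplicate_map(self) -> list[tuple[str, str]]:
        """Pairs (first, second) of aliquot IDs that split one sample."""
        out = []
        for sample_id, grp in self.aliquots.groupby("sample_id", sort=True):
            if len(grp) == 2:
                g = grp.sort_values("replicate")
                out.append(tuple(g["aliquot_id"].tolist()))
        return out

    def validate(self) -> None:
        """Raise ValueError if a structural invariant is violated."""
        sizes = self.individuals.groupby("pair_id").size()
        if not (sizes == 2).all():
            raise ValueError("every pair must contain exactly 2 individuals")
        # both members of a pair attend the same visits
        visits = self.samples.merge(self.individuals, on="individual_id")
        per_ind = visits.groupby(["pair_id", "individual_id"])["visit"].agg(frozenset)
        per_pair = per_ind.groupby("pair_id").nunique()
        if not (per_pair == 1).all():
            raise ValueError("twins of a pair must share identical visit sets")
        wells = pd.concat(
            [self.aliquots[["plate", "well"]], self.reference_wells[["plate", "well"]]]
        )
        if wells.duplicated().any():
            raise ValueError("duplicate (plate, well) assignment")
        per_plate = wells.groupby("plate").size()
        if (per_plate > self.plate_capacity).any():
            raise ValueError("plate capacity exceeded")


def generate_design(
    n_mz_pairs: int,
    n_dz_pairs: int,
    n_revisit_mz_pairs: int,
    n_duplicated_mz_pairs: int,
    plate_capacity: int = 96,
    n_reference_wells_per_plate: int = 6,
    seed: int = 0,
    n_plates: int | None = None,
) -> CohortDesign:
    """Construct a twin-cohort design.

    All individuals are sampled at visit 1; the first ``n_revisit_mz_pairs``
    MZ pairs re-attend (both twins) for visit 2; the visit-1 sample of each
    individual in the first ``n_duplicated_mz_pairs`` MZ pairs is split into
    two aliquots. Aliquots are placed on plates by a seeded uniform
    permutation over the non-reference wells; reference wells are drawn per
    plate from the same stream.

    Parameters mirror the study layout; ``n_plates`` may force a plate
    count (an error names the required count if it does not fit).
    """
    if n_revisit_mz_pairs > n_mz_pairs:
        raise ValueError(
            f"n_revisit_mz_pairs ({n_revisit_mz_pairs}) exceeds "
            f"n_mz_pairs ({n_mz_pairs})"
        )
    if n_duplicated_mz_pairs > n_mz_pairs:
        raise ValueError(
            f"n_duplicated_mz_pairs ({n_duplicated_mz_pairs}) exceeds "
            f"n_mz_pairs ({n_mz_pairs})"
        )
    usable = plate_capacity - n_reference_wells_per_plate
    if usable <= 0:
        raise ValueError("reference wells leave no usable wells per plate")

    n_pairs = n_mz_pairs + n_dz_pairs
    n_samples = 2 * n_pairs + 2 * n_revisit_mz_pairs
    n_aliquots = n_samples + 2 * n_duplicated_mz_pairs

    required_plates = math.ceil(n_aliquots / usable)
    if n_plates is None:
        n_plates = required_plates
    elif n_plates < required_plates:
        raise ValueError(
            f"{n_aliquots} aliquots need {required_plates} plates of "
            f"{plate_capacity} wells ({n_reference_wells_per_plate} reserved); "
            f"got n_plates={n_plates}"
        )

    width = max(3, len(str(n_pairs)))
    pair_ids = [f"P{i:0{width}d}" for i in range(1, n_pairs + 1)]
    zygosity = [MZ] * n_mz_pairs + [DZ] * n_dz_pairs
    pairs = pd.DataFrame({"pair_id": pair_ids, "zygosity": zygosity})

    individuals = pd.DataFrame(
        [
            {"individual_id": f"{pid}_{j}", "pair_id": pid}
            for pid in pair_ids
            for j in (1, 2)
        ]
    )

    revisit_pairs = set(pair_ids[:n_revisit_mz_pairs])
    dup_pairs = set(pair_ids[:n_duplicated_mz_pairs])

    sample_rows = []
    for _, ind in individuals.iterrows():
        sample_rows.append(
            {"sample_id": f"{ind.individual_id}_V1",
             "individual_id": ind.individual_id, "visit": 1}
        )
        if ind.pair_id in revisit_pairs:
            sample_rows.append(
                {"sample_id": f"{ind.individual_id}_V2",
                 "individual_id": ind.individual_id, "visit": 2}
            )
    samples = pd.DataFrame(sample_rows)

    aliquot_rows = []
    for _, s in samples.iterrows():
        pair_id = s.individual_id.rsplit("_", 1)[0]
        n_rep = 2 if (s.visit == 1 and pair_id in dup_pairs) else 1
        for rep in range(1, n_rep + 1):
            aliquot_rows.append(
                {"aliquot_id": f"{s.sample_id}_A{rep}",
                 "sample_id": s.sample_id, "replicate": rep}
            )
    aliquots = pd.DataFrame(aliquot_rows)
    assert len(aliquots) == n_aliquots

    # plate layout: per plate, pick reference wells, pool the rest,
    # then permute aliquots over the pooled study wells
    rng = np.random.default_rng(seed)
    ref_rows = []
    study_wells: list[tuple[int, int]] = []
    for plate in range(1, n_plates + 1):
        wells = np.arange(1, plate_capacity + 1)
        ref = np.sort(
            rng.choice(wells, size=n_reference_wells_per_plate, replace=False)
        )
        for i, w in enumerate(ref, start=1):
            ref_rows.append(
                {"aliquot_id": f"REF_P{plate}_{i}", "plate": plate, "well": int(w)}
            )
        study_wells.extend((plate, int(w)) for w in wells if w not in set(ref))
    slots = [study_wells[j] for j in rng.permutation(len(study_wells))[:n_aliquots]]
    aliquots["plate"] = [s[0] for s in slots]
    aliquots["well"] = [s[1] for s in slots]

    reference_wells = pd.DataFrame(
        ref_rows, columns=["aliquot_id", "plate", "well"]
    )

    design = CohortDesign(
        pairs=pairs,
        individuals=individuals,
        samples=samples,
        aliquots=aliquots,
        reference_wells=reference_wells,
        plate_capacity=plate_capacity,
        seed=seed,
    )
    design.validate()
    return design
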