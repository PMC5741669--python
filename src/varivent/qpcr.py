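"""Relative gene expression by the 2^-ddCt method.

Triplicate Ct values are averaged per (animal, gene); dCt subtracts the
housekeeping gene (36B4) mean Ct from the target mean Ct for the same
animal. The calibrator for each gene is the arithmetic mean dCt across the
non-ventilated (NV) control animals, which makes the NV group's geometric
mean fold change exactly 1. Fold change is 2^-(dCt - dCt_calibrator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CtRecord", "FoldChange", "delta_ct", "fold_change", "fold_change_table"]

REFERENCE_GENE = "36B4"

GENES = (
    "IL-6",
    "IL-1b",
    "IL-10",
    "CINC-1",
    "amphiregulin",
    "SP-D",
    "SP-C",
    "CC16",
    "PCIII",
    REFERENCE_GENE,
)


@dataclass(frozen=True)
class CtRecord:
    """Cycle-threshold replicates for one animal x gene."""

    animal_id: str
    group: str
    gene: str
    ct_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.ct_values) == 0:
            raise ValueError("ct_values must be non-empty")
        for ct in self.ct_values:
            if not 0 < ct < 45:
                raise ValueError(f"Ct {ct} outside (0, 45)")

    def mean_ct(self, reject_outliers: bool = False, outlier_cycles: float = 0.5) -> float:
        """Mean replicate Ct, optionally dropping replicates far from the median."""
        cts = np.asarray(self.ct_values, dtype=float)
        if reject_outliers and len(cts) >= 3:
            keep = np.abs(cts - np.median(cts)) <= outlier_cycles
            if keep.any():
                cts = cts[keep]
        return float(np.mean(cts))


@dataclass(frozen=True)
class FoldChange:
    animal_id: str
    gene: str
    delta_ct: float
    delta_delta_ct: float
    fold: float

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be > 0")


def delta_ct(record: CtRecord, reference: CtRecord, reject_outliers: bool = False) -> float:
    """dCt = mean Ct(target) - mean Ct(reference) for the same animal."""
    if record.animal_id != reference.animal_id:
        raise ValueError(
            f"animal mismatch: target from {record.animal_id!r}, reference from "
            f"{reference.animal_id!r}"
        )
    if reference.gene != REFERENCE_GENE:
        raise ValueError(f"reference record must be {REFERENCE_GENE}, got {reference.gene!r}")
    return record.mean_ct(reject_outliers) - reference.mean_ct(reject_outliers)


def fold_change(dct_sample: float, dct_calibrator: float) -> float:
    """2^-(dCt_sample - dCt_calibrator)."""
    if not (np.isfinite(dct_sample) and np.isfinite(dct_calibrator)):
        raise ValueError("dCt values must be finite")
    return float(2.0 ** -(dct_sample - dct_calibrator))


def fold_change_table(
    records: list[CtRecord],
    calibrator_group: str = "NV",
    reject_outliers: bool = False,
) -> pd.DataFrame:
    """Per-animal fold changes for every target gene, calibrated to a group.

    Returns a frame with columns animal_id, group, gene, delta_ct,
    delta_delta_ct, fold.
    """
    by_animal: dict[str, dict[str, CtRecord]] = {}
    groups: dict[str, str] = {}
    for rec in records:
        by_animal.setdefault(rec.animal_id, {})[rec.gene] = rec
        groups[rec.animal_id] = rec.group

    dcts: list[dict] = []
    for animal, genes in by_animal.items():
        if REFERENCE_GENE not in genes:
            raise ValueError(f"animal {animal!r} lacks a {REFERENCE_GENE} record")
        ref = genes[REFERENCE_GENE]
        for gene, rec in genes.items():
            if gene == REFERENCE_GENE:
                continue
            dcts.append(
                {
                    "animal_id": animal,
                    "group": groups[animal],
                    "gene": gene,
                    "delta_ct": delta_ct(rec, ref, reject_outliers),
                }
            )
    df = pd.DataFrame(dcts)
    if df.empty:
        raise ValueError("no target-gene records found")

    cal = (
        df[df["group"] == calibrator_group]
        .groupby("gene")["delta_ct"]
        .mean()
        .rename("calibrator_dct")
    )
    if cal.empty:
        raise ValueError(f"no records for calibrator group {calibrator_group!r}")
    df = df.join(cal, on="gene")
    if df["calibrator_dct"].isna().any():
        missing = sorted(df.loc[df["calibrator_dct"].isna(), "gene"].unique())
        raise ValueError(f"calibrator group has no records for genes: {missing}")
    df["delta_delta_ct"] = df["delta_ct"] - df["calibrator_dct"]
    df["fold"] = 2.0 ** -df["delta_delta_ct"]
    return df[["animal_id", "group", "gene", "delta_ct", "delta_delta_ct", "fold"]]
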