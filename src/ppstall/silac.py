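"""SILAC ratio re-analysis: distribution summaries and the weak-context
computational-removal shift.

SILAC (stable isotope labelling by amino acids in cell culture) yields a
heavy/light abundance ratio per protein between a deletion strain and wild
type.  Ratios here are stored as inverted, normalized, log2-transformed
values, so that negative values mean the protein is down-regulated in the
deletion strain.  The central re-analysis asks whether removing PPP-containing
proteins whose motifs have only weak −1 contexts (which escape elongation
factor P dependence) shifts the remaining PPP distribution further down —
unmasking EF-P dependence.  The shift statistic is the change in median, with
significance from a label-permutation null; the permutation formalization is
this package's own (the original comparison was purely distributional).
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SILAC_COLUMNS = ("protein_id", "strain", "log2_ratio")

#: Histogram convention for ratio distributions: 0.25-log2-unit bins on
#: [−6, 6] with open-ended tails.
HIST_EDGES = np.concatenate(([-np.inf], np.arange(-6.0, 6.0 + 0.25, 0.25), [np.inf]))


class SilacFormatError(ValueError):
    """Raised for malformed ratio tables."""


@dataclass(frozen=True)
class DistributionSummary:
    n: int
    median: float
    q25: float
    q75: float
    bin_edges: tuple[float, ...]
    bin_counts: tuple[int, ...]


@dataclass(frozen=True)
class ShiftResult:
    """Outcome of the weak-context computational-removal re-analysis."""

    strain: str
    n_all_ppp: int
    n_filtered: int
    median_all_ppp: float
    median_filtered: float
    delta_median: float
    perm_p: float


def _validate_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SILAC_COLUMNS if c not in df.columns]
    if missing:
        raise SilacFormatError(f"ratio table is missing columns {missing}")
    df = df.loc[:, list(SILAC_COLUMNS)].copy()
    ratios = pd.to_numeric(df["log2_ratio"], errors="coerce")
    bad = df.loc[ratios.isna() | ~np.isfinite(ratios), "protein_id"]
    if len(bad):
        raise SilacFormatError(
            f"non-numeric or non-finite log2_ratio for proteins {sorted(set(bad))[:5]}"
        )
    df["log2_ratio"] = ratios.astype(float)
    dup = df.duplicated(subset=["protein_id", "strain"])
    if dup.any():
        pairs = df.loc[dup, ["protein_id", "strain"]].itertuples(index=False)
        raise SilacFormatError(f"duplicate (protein_id, strain) pairs: {list(pairs)[:5]}")
    return df


def load_ratio_table(path: str | os.PathLike, flip: bool = False) -> pd.DataFrame:
    """Load a TSV of per-protein log2 SILAC ratios.

    Expected columns: ``protein_id``, ``strain``, ``log2_ratio``.  Use
    ``flip=True`` for tables in native H/L orientation (positive = higher in
    the heavy-labelled deletion strain) to convert to the inverted convention
    where negative = down-regulated in the deletion strain.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "strain": str})
    df = _validate_table(df)
    if flip:
        df["log2_ratio"] = -df["log2_ratio"]
    return df


def write_ratio_table(table: pd.DataFrame, path: str | os.PathLike) -> None:
    _validate_table(table).to_csv(path, sep="\t", index=False)


def distribution_summary(values: Sequence[float]) -> DistributionSummary:
    """Median, quartiles (midpoint interpolation) and fixed-bin histogram."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("distribution_summary requires at least one value")
    q25, med, q75 = np.percentile(arr, [25, 50, 75], method="midpoint")
    counts, _ = np.histogram(arr, bins=HIST_EDGES)
    return DistributionSummary(
        n=int(arr.size),
        median=float(med),
        q25=float(q25),
        q75=float(q75),
        bin_edges=tuple(HIST_EDGES),
        bin_counts=tuple(int(c) for c in counts),
    )


def _strain_values(table: pd.DataFrame, strain: str) -> pd.Series:
    sub = table.loc[table["strain"] == strain]
    if sub.empty:
        raise ValueError(f"no rows for strain {strain!r}")
    return sub.set_index("protein_id")["log2_ratio"]


def removal_shift(
    table: pd.DataFrame,
    strain: str,
    ppp_ids: set[str],
    removed_ids: set[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> ShiftResult:
    """Median shift of the PPP-protein ratio distribution after removal.

    Computes the median log2 ratio of the PPP-containing proteins for one
    strain before and after removing ``removed_ids`` (typically the
    weak-context proteins), and a one-sided permutation p-value: the null
    removes the same number of proteins uniformly at random from the PPP set
    ``n_perm`` times and counts replicates whose median shift is at least as
    negative as the observed one (add-one rule).
    """
    if not removed_ids <= ppp_ids:
        raise ValueError("removed_ids must be a subset of ppp_ids")
    if n_perm < 0:
        raise ValueError("n_perm must be ≥ 0")
    values = _strain_values(table, strain)
    present_ppp = sorted(ppp_ids & set(values.index))
    if not present_ppp:
        raise ValueError(f"no PPP protein ids present in the table for {strain!r}")
    absent = (ppp_ids | removed_ids) - set(values.index)
    if absent:
        warnings.warn(
            f"{len(absent)} protein ids absent from the {strain} table; "
            "computing on the intersection",
            stacklevel=2,
        )
    present_removed = sorted(removed_ids & set(values.index))
    kept = [p for p in present_ppp if p not in set(present_removed)]
    if not kept:
        raise ValueError("removal would empty the PPP set")

    ppp_vals = values.loc[present_ppp].to_numpy()
    median_all = float(np.median(ppp_vals))
    median_filtered = float(np.median(values.loc[kept].to_numpy()))
    delta = median_filtered - median_all

    rng = np.random.default_rng(seed)
    k = len(present_removed)
    r = 0
    for _ in range(n_perm):
        drop = rng.choice(len(ppp_vals), size=k, replace=False)
        keep_mask = np.ones(len(ppp_vals), dtype=bool)
        keep_mask[drop] = False
        if float(np.median(ppp_vals[keep_mask])) - median_all <= delta:
            r += 1
    perm_p = (r + 1) / (n_perm + 1)
    return ShiftResult(
        strain=strain,
        n_all_ppp=len(present_ppp),
        n_filtered=len(kept),
        median_all_ppp=median_all,
        median_filtered=median_filtered,
        delta_median=delta,
        perm_p=perm_p,
    )


def strain_contrast(
    table: pd.DataFrame,
    ppp_ids: set[str],
    removed_ids: set[str],
    strains: Iterable[str] | None = None,
    threshold: float = 0.5,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Compare the removal shift across deletion strains.

    For each strain, computes the all-protein median, the PPP medians before
    and after weak-context removal, and flags the strain when the filtered
    PPP median lies more than ``threshold`` log2 units below the all-protein
    median.  The four strain contrasts mirror planned comparisons and are
    reported without multiplicity correction.
    """
    if strains is None:
        strains = list(pd.unique(table["strain"]))
    strains = list(strains)
    if not strains:
        raise ValueError("strain_contrast requires at least one strain")
    rows = []
    ss = np.random.SeedSequence(seed) if seed is not None else np.random.SeedSequence()
    child_seeds = ss.generate_state(len(strains))
    for strain, sub_seed in zip(strains, child_seeds):
        res = removal_shift(
            table, strain, ppp_ids, removed_ids, n_perm=n_perm, seed=int(sub_seed)
        )
        median_all_proteins = float(np.median(_strain_values(table, strain).to_numpy()))
        rows.append(
            {
                "strain": strain,
                "median_all_proteins": median_all_proteins,
                "median_all_ppp": res.median_all_ppp,
                "median_filtered": res.median_filtered,
                "delta_median": res.delta_median,
                "perm_p": res.perm_p,
                "flagged": bool(
                    res.median_filtered < median_all_proteins - threshold
                ),
            }
        )
    return pd.DataFrame(rows)
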