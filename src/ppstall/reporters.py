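"""Reporter-assay statistics: toeprint stalling efficiency and β-galactosidase
relative activity.

Toeprinting locates stalled ribosomes on an mRNA: band intensities at the two
stall sites (XPP/P, with peptidyl-Pro-Pro-tRNA in the P site, and XPPP/Z one
codon downstream) are compared with the downstream amino-acid-starvation trap
band, where ribosomes that read through the motif arrest at the first
glutamine codon.  Stalling efficiency is the percentage of ribosomes caught
at either stall site.

The in vivo reporter fuses the motif-containing N-terminus to LacZ;
β-galactosidase activity in a Δefp strain relative to wild type, normalized
to a motif-free control construct (assigned 100%), measures how strongly the
motif stalls translation in the absence of elongation factor P: strong
stalling gives low relative activity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

_TOEPRINT_COLS = ("i_site1", "i_site2", "i_trap")
_ACTIVITY_COLS = ("fusion_wt", "fusion_defp", "control_wt", "control_defp")


@dataclass(frozen=True)
class ToeprintLanes:
    """Band intensities of one toeprint lane (arbitrary units, ≥ 0).

    ``i_site1``: XPP/P stall band; ``i_site2``: XPPP/Z stall band;
    ``i_trap``: downstream glutamine-starvation trap band.
    """

    i_site1: float
    i_site2: float
    i_trap: float

    def __post_init__(self) -> None:
        vals = (self.i_site1, self.i_site2, self.i_trap)
        if any(not math.isfinite(v) for v in vals):
            raise ValueError("band intensities must be finite")
        if any(v < 0 for v in vals):
            raise ValueError("band intensities must be ≥ 0")
        if all(v == 0 for v in vals):
            raise ValueError("at least one band intensity must be > 0")


@dataclass(frozen=True)
class ReporterActivities:
    """β-galactosidase activities (Miller-type units) for one construct pair."""

    fusion_wt: float
    fusion_defp: float
    control_wt: float
    control_defp: float

    def __post_init__(self) -> None:
        vals = (self.fusion_wt, self.fusion_defp, self.control_wt, self.control_defp)
        if any(not math.isfinite(v) for v in vals):
            raise ValueError("activities must be finite")
        if self.fusion_defp < 0 or self.control_defp < 0:
            raise ValueError("Δefp activities must be ≥ 0")
        if self.fusion_wt <= 0 or self.control_wt <= 0 or self.control_defp <= 0:
            raise ValueError("wild-type and control activities must be > 0")


def stalling_efficiency(lanes: ToeprintLanes) -> float:
    """Percent of ribosomes stalled at the motif, from toeprint intensities.

    ``100 · (i_site1 + i_site2) / (i_site1 + i_site2 + i_trap)``; invariant
    to rescaling all three bands by a common factor.
    """
    stalled = lanes.i_site1 + lanes.i_site2
    return 100.0 * stalled / (stalled + lanes.i_trap)


def relative_activity(acts: ReporterActivities, invert: bool = False) -> float:
    """Relative β-galactosidase activity of a motif fusion, in percent.

    ``100 · (fusion_defp / fusion_wt) / (control_defp / control_wt)``: the
    Δefp/wild-type activity ratio of the fusion normalized by that of a
    motif-free control (no stalling, assigned 100%).  Strong stalling yields
    low values.  ``invert=True`` reports the reciprocal orientation.
    """
    fusion_ratio = acts.fusion_defp / acts.fusion_wt
    control_ratio = acts.control_defp / acts.control_wt
    value = 100.0 * fusion_ratio / control_ratio
    if invert:
        if value == 0:
            raise ValueError("cannot invert a zero relative activity")
        return 100.0 * 100.0 / value
    return value


def _statistic_for_row(row: pd.Series, kind: str, invert: bool) -> float:
    if kind == "toeprint":
        return stalling_efficiency(ToeprintLanes(*(float(row[c]) for c in _TOEPRINT_COLS)))
    return relative_activity(
        ReporterActivities(*(float(row[c]) for c in _ACTIVITY_COLS)), invert=invert
    )


def batch_reporter_table(table: pd.DataFrame, invert: bool = False) -> pd.DataFrame:
    """Per-construct replicate summary of a reporter statistic.

    ``table`` must have a ``construct`` column plus either the three toeprint
    intensity columns or the four activity columns (never both).  Returns one
    row per construct with ``n``, ``mean`` and sample standard deviation
    ``sd`` of the statistic; ``sd`` is missing for a single replicate.
    """
    cols = set(table.columns)
    has_tp = set(_TOEPRINT_COLS) <= cols
    has_act = set(_ACTIVITY_COLS) <= cols
    if has_tp == has_act:
        raise ValueError(
            "table must contain exactly one statistic's columns: "
            f"either {_TOEPRINT_COLS} or {_ACTIVITY_COLS}"
        )
    if "construct" not in cols:
        raise ValueError("table must contain a 'construct' column")
    kind = "toeprint" if has_tp else "activity"
    stats = table.apply(_statistic_for_row, axis=1, kind=kind, invert=invert)
    work = pd.DataFrame({"construct": table["construct"], "value": stats})
    out = (
        work.groupby("construct", sort=True)["value"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    out["n"] = out["n"].astype(int)
    out.loc[out["n"] == 1, "sd"] = np.nan
    out.insert(1, "statistic", "stalling_efficiency" if has_tp else "relative_activity")
    return out
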