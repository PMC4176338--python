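"""Stalling-propensity classification of the −1 residue of PPP motifs.

Reporter assays in two protein contexts (NlpD and CadC fusions to LacZ)
agree that C and T, and also G, L and S, upstream of a polyproline run
suppress ribosome stalling, whereas E, H, K, Q, R, W, Y and a fourth proline
promote it.  Residues for which the two reporter systems disagree (notably
A) or that show intermediate behaviour default to an ``intermediate`` class;
both sets are user-configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .census import TERMINUS, ProlineRun, find_proline_runs
from .io import STANDARD_RESIDUES, ProteinRecord

DEFAULT_WEAK = frozenset("CTGLS")
DEFAULT_STRONG = frozenset("EHKQRWYP")

#: Class labels ordered from weakest to strongest stalling propensity.
CLASS_ORDER = ("no_context", "weak", "intermediate", "strong")


@dataclass(frozen=True)
class ContextClassSets:
    """Partition of the 20 standard residues into stalling-propensity classes.

    ``weak`` residues at the −1 position suppress stalling; ``strong`` ones
    promote it; every other standard residue is ``intermediate`` (derived).
    """

    weak: frozenset[str] = DEFAULT_WEAK
    strong: frozenset[str] = DEFAULT_STRONG

    def __post_init__(self) -> None:
        std = set(STANDARD_RESIDUES)
        for name, s in (("weak", self.weak), ("strong", self.strong)):
            bad = set(s) - std
            if bad:
                raise ValueError(f"{name} set contains non-standard residues {sorted(bad)}")
        overlap = self.weak & self.strong
        if overlap:
            raise ValueError(f"weak and strong sets overlap: {sorted(overlap)}")

    @property
    def intermediate(self) -> frozenset[str]:
        return frozenset(STANDARD_RESIDUES) - self.weak - self.strong


@dataclass(frozen=True)
class ProteinAnnotation:
    """Context classification of every proline run in one protein."""

    protein_id: str
    runs: tuple[ProlineRun, ...]
    contexts: tuple[tuple[str, str], ...]  # (x_residue, class label) per run
    overall_class: str


def classify_context(
    x_residue: str, sets: ContextClassSets | None = None
) -> str:
    """Classify a −1 residue as ``weak``, ``intermediate`` or ``strong``.

    The terminus marker (a run with no −1 residue) maps to ``no_context``;
    any other non-standard residue is an error.
    """
    sets = sets or ContextClassSets()
    if x_residue == TERMINUS:
        return "no_context"
    if x_residue not in STANDARD_RESIDUES:
        raise ValueError(f"non-standard residue {x_residue!r}")
    if x_residue in sets.weak:
        return "weak"
    if x_residue in sets.strong:
        return "strong"
    return "intermediate"


def annotate_proteome(
    records: Sequence[ProteinRecord],
    min_run: int = 3,
    sets: ContextClassSets | None = None,
) -> list[ProteinAnnotation]:
    """Annotate every PPP-containing protein with its run contexts.

    The overall class of a protein is the strongest class among its runs
    (strong > intermediate > weak > no_context); proteins without runs are
    omitted.
    """
    if not records:
        raise ValueError("annotate_proteome requires a non-empty record list")
    sets = sets or ContextClassSets()
    out = []
    for rec in records:
        runs = find_proline_runs(rec, min_run=min_run)
        if not runs:
            continue
        contexts = tuple((r.x_residue, classify_context(r.x_residue, sets)) for r in runs)
        overall = max((c for _, c in contexts), key=CLASS_ORDER.index)
        out.append(
            ProteinAnnotation(
                protein_id=rec.id,
                runs=tuple(runs),
                contexts=contexts,
                overall_class=overall,
            )
        )
    return out


def weak_context_filter(
    annotations: Iterable[ProteinAnnotation], policy: str = "all_weak"
) -> set[str]:
    """Ids of proteins to remove from a re-analysis as weak-context.

    ``all_weak`` (default): remove a protein iff every run with a −1 residue
    is weak-context and at least one such run exists.  ``any_weak``: remove
    iff any run is weak-context.  With defaults, the ``all_weak`` removal set
    is always a subset of the ``any_weak`` one.
    """
    if policy not in ("all_weak", "any_weak"):
        raise ValueError(f"unknown policy {policy!r}")
    removed: set[str] = set()
    for ann in annotations:
        classes = [c for _, c in ann.contexts if c != "no_context"]
        if not classes:
            continue
        if policy == "any_weak":
            if "weak" in classes:
                removed.add(ann.protein_id)
        elif all(c == "weak" for c in classes):
            removed.add(ann.protein_id)
    return removed


def annotations_to_rows(annotations: Iterable[ProteinAnnotation]) -> list[dict]:
    """Flatten annotations to TSV-ready dict rows (one row per protein)."""
    return [
        {
            "protein_id": a.protein_id,
            "n_runs": len(a.runs),
            "contexts": ",".join(f"{x}:{c}" for x, c in a.contexts),
            "overall_class": a.overall_class,
        }
        for a in annotations
    ]
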