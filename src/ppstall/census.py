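"""Polyproline-motif census and composition/shuffle null models.

Translation stalls when the ribosome encounters a run of three or more
consecutive prolines (a PPP motif); the residue X immediately upstream of
the run (the −1 position) modulates stalling strength.  This module detects
maximal proline runs, tallies the XPPP census of a proteome, and compares
observed counts with two null models:

* an analytic composition null, ``expected = p**n_pro * x_X * g`` where
  ``p`` is the proline fraction, ``x_X`` the fraction of residue X and
  ``g`` the proteome size in amino acids;
* an empirical shuffle null that permutes residues within each protein.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import STANDARD_RESIDUES, ProteinRecord, ProteomeComposition, composition

#: Marker used for runs that touch a protein terminus (no −1 or +1 residue).
TERMINUS = "^"

_RUN_RE_CACHE: dict[int, re.Pattern] = {}


def _run_pattern(min_run: int) -> re.Pattern:
    if min_run not in _RUN_RE_CACHE:
        _RUN_RE_CACHE[min_run] = re.compile("P{%d,}" % min_run)
    return _RUN_RE_CACHE[min_run]


@dataclass(frozen=True)
class ProlineRun:
    """A maximal run of ≥ ``min_run`` consecutive prolines with its context.

    ``x_residue`` is the residue at ``start − 1`` (:data:`TERMINUS` when the
    run begins the protein); ``z_residue`` the residue at ``start + length``
    (:data:`TERMINUS` when the run ends the protein).  ``upstream`` holds up
    to five residues preceding the run, truncated at the N-terminus.
    """

    protein_id: str
    start: int
    length: int
    upstream: str
    x_residue: str
    z_residue: str


@dataclass
class MotifCensus:
    """Observed XPPP counts with analytic expectations for one proteome."""

    mode: str
    min_run: int
    n_pro: int
    observed: dict[str, int]
    protein_ids: dict[str, set[str]]
    n_ppp_proteins: int
    n_terminal_runs: int
    composition: ProteomeComposition
    expected: dict[str, float] = field(default_factory=dict)
    ratio: dict[str, float] = field(default_factory=dict)


@dataclass
class ShuffleNull:
    """Empirical within-protein shuffle null for one X residue."""

    x_residue: str
    observed: int
    counts: list[int]
    mean: float
    p_value: float


def find_proline_runs(record: ProteinRecord, min_run: int = 3) -> list[ProlineRun]:
    """Locate all maximal proline runs of length ≥ ``min_run`` in one protein.

    Runs are returned sorted by start position.  The upstream window covers
    positions ``start−5 .. start−1``, truncated at the N-terminus.
    """
    if min_run < 2:
        raise ValueError(f"min_run must be ≥ 2, got {min_run}")
    seq = record.sequence
    runs = []
    for m in _run_pattern(min_run).finditer(seq):
        start, end = m.start(), m.end()
        runs.append(
            ProlineRun(
                protein_id=record.id,
                start=start,
                length=end - start,
                upstream=seq[max(0, start - 5) : start],
                x_residue=seq[start - 1] if start > 0 else TERMINUS,
                z_residue=seq[end] if end < len(seq) else TERMINUS,
            )
        )
    return runs


def _windowed_counts(seq: str, min_run: int) -> dict[str, int]:
    # Every window [not-P]P{min_run} contributes to its leading residue;
    # every window P{min_run+1} contributes to X='P'.
    counts: dict[str, int] = {}
    run = "P" * min_run
    for i in range(len(seq) - min_run):
        if seq[i + 1 : i + 1 + min_run] == run and seq[i] != "P":
            counts[seq[i]] = counts.get(seq[i], 0) + 1
        if seq[i : i + min_run + 1] == run + "P":
            counts["P"] = counts.get("P", 0) + 1
    return counts


def census(
    records: Sequence[ProteinRecord],
    min_run: int = 3,
    mode: str = "per_run",
    n_pro: int | None = None,
) -> MotifCensus:
    """Build the XPPP census of a proteome.

    In ``per_run`` mode each maximal proline run contributes one occurrence
    to the residue at its −1 position (runs starting at the N-terminus are
    tallied separately under :data:`TERMINUS`).  In ``windowed`` mode every
    ``[not-P]P{min_run}`` window counts toward its leading residue and every
    ``P{min_run+1}`` window toward X='P'.  Expected counts come from the
    analytic composition null on the same records.
    """
    if not records:
        raise ValueError("census requires a non-empty record list")
    if mode not in ("per_run", "windowed"):
        raise ValueError(f"unknown census mode {mode!r}")
    if n_pro is None:
        n_pro = min_run
    observed: dict[str, int] = {}
    protein_ids: dict[str, set[str]] = {}
    ppp_proteins: set[str] = set()
    n_terminal = 0
    for rec in records:
        runs = find_proline_runs(rec, min_run=min_run)
        if runs:
            ppp_proteins.add(rec.id)
        if mode == "per_run":
            for run in runs:
                if run.x_residue == TERMINUS:
                    n_terminal += 1
                    continue
                observed[run.x_residue] = observed.get(run.x_residue, 0) + 1
                protein_ids.setdefault(run.x_residue, set()).add(rec.id)
        else:
            for x, n in _windowed_counts(rec.sequence, min_run).items():
                observed[x] = observed.get(x, 0) + n
                protein_ids.setdefault(x, set()).add(rec.id)
    comp = composition(records)
    expected = {a: expected_count(comp, a, n_pro=n_pro) for a in STANDARD_RESIDUES}
    ratio = {
        a: (observed.get(a, 0) / expected[a]) if expected[a] > 1e-12 else float("nan")
        for a in STANDARD_RESIDUES
    }
    return MotifCensus(
        mode=mode,
        min_run=min_run,
        n_pro=n_pro,
        observed=observed,
        protein_ids=protein_ids,
        n_ppp_proteins=len(ppp_proteins),
        n_terminal_runs=n_terminal,
        composition=comp,
        expected=expected,
        ratio=ratio,
    )


def expected_count(
    comp: ProteomeComposition, x_residue: str, n_pro: int = 3
) -> float:
    """Expected number of X-P^n_pro motifs under the composition null.

    Returns ``p**n_pro * x_X * g``.  ``n_pro`` is the number of prolines in
    the motif (3 for XPPP, 2 for XPP).
    """
    if x_residue not in STANDARD_RESIDUES:
        raise ValueError(f"unknown residue {x_residue!r}")
    if n_pro < 1:
        raise ValueError(f"n_pro must be ≥ 1, got {n_pro}")
    return comp.p**n_pro * comp.x[x_residue] * comp.g


def shuffle_null(
    records: Sequence[ProteinRecord],
    x_residue: str,
    min_run: int = 3,
    n_shuffles: int = 500,
    seed: int | None = None,
    mode: str = "per_run",
) -> ShuffleNull:
    """Empirical null for the XPPP count obtained by within-protein shuffling.

    Each replicate permutes the residues of every protein independently
    (preserving per-protein composition and length) and recounts motifs with
    the given X.  The two-sided empirical p-value for the observed count uses
    the add-one rule ``(r + 1) / (n_shuffles + 1)`` where ``r`` is the number
    of replicates at least as far from the null mean as the observed count.
    """
    if n_shuffles < 1:
        raise ValueError(f"n_shuffles must be ≥ 1, got {n_shuffles}")
    if mode not in ("per_run", "windowed"):
        raise ValueError(f"unknown census mode {mode!r}")
    rng = np.random.default_rng(seed)

    def count_x(seqs: list[str]) -> int:
        n = 0
        if mode == "per_run":
            pat = _run_pattern(min_run)
            for s in seqs:
                for m in pat.finditer(s):
                    if m.start() > 0 and s[m.start() - 1] == x_residue:
                        n += 1
        else:
            for s in seqs:
                n += _windowed_counts(s, min_run).get(x_residue, 0)
        return n

    obs = count_x([rec.sequence for rec in records])
    arrays = [np.frombuffer(rec.sequence.encode(), dtype="S1") for rec in records]
    counts: list[int] = []
    for _ in range(n_shuffles):
        shuffled = [rng.permutation(arr).tobytes().decode() for arr in arrays]
        counts.append(count_x(shuffled))
    mean = float(np.mean(counts))
    dev = abs(obs - mean)
    r = int(sum(abs(c - mean) >= dev for c in counts))
    p = (r + 1) / (n_shuffles + 1)
    return ShuffleNull(
        x_residue=x_residue, observed=obs, counts=counts, mean=mean, p_value=p
    )


def enrichment_table(c: MotifCensus) -> pd.DataFrame:
    """Per-residue observed/expected enrichment table, sorted by ratio.

    One row per standard residue with columns ``X``, ``observed``,
    ``expected``, ``ratio``; the ratio is reported as missing (NaN) when the
    expected count is below 1e-12.
    """
    rows = [
        {
            "X": a,
            "observed": c.observed.get(a, 0),
            "expected": c.expected[a],
            "ratio": c.ratio[a],
        }
        for a in STANDARD_RESIDUES
    ]
    df = pd.DataFrame(rows)
    return df.sort_values("ratio", ascending=False, na_position="last").reset_index(
        drop=True
    )
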