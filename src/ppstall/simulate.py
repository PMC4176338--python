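"""Synthetic data generators with known ground truth.

Every pipeline stage in this package can be exercised without external
downloads: proteomes of specified residue composition with planted XPPP
motifs, SILAC ratio tables with class-dependent shifts, and noisy reporter
replicate tables.  All generators are deterministic given their spec and
seed.

Planted motifs are inserted so that the run is maximal (the −1 residue is
the requested X, the +1 position is forced non-proline) and plants never
overlap, which makes per-run census recovery exact on a proline-free
background; on backgrounds containing proline, accidental runs add to the
planted ones and the truth is plants plus a scan of the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import STANDARD_RESIDUES, ProteinRecord
from .reporters import (
    ReporterActivities,
    ToeprintLanes,
    _ACTIVITY_COLS,
    _TOEPRINT_COLS,
)


#: Background residue frequencies shaped like a bacterial (E. coli-like)
#: proteome; used as the default study condition for synthetic proteomes.
ECOLI_LIKE_COMPOSITION: dict[str, float] = {
    "A": 0.095, "C": 0.012, "D": 0.051, "E": 0.057, "F": 0.039, "G": 0.074,
    "H": 0.022, "I": 0.060, "K": 0.044, "L": 0.106, "M": 0.028, "N": 0.040,
    "P": 0.044, "Q": 0.044, "R": 0.055, "S": 0.058, "T": 0.054, "V": 0.071,
    "W": 0.015, "Y": 0.031,
}


@dataclass(frozen=True)
class ProteomeSpec:
    """Recipe for a synthetic proteome.

    ``composition`` maps residues to background frequencies (must sum to 1);
    ``planted`` lists (x_residue, n_pro, count) motifs to insert; lengths are
    drawn normal(length_mean, length_sd), rounded, floored at ``n_pro + 2``.
    """

    n_proteins: int
    length_mean: float
    length_sd: float
    composition: Mapping[str, float]
    planted: tuple[tuple[str, int, int], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be ≥ 1")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition fractions sum to {total}, not 1")
        bad = set(self.composition) - set(STANDARD_RESIDUES)
        if bad:
            raise ValueError(f"non-standard residues in composition: {sorted(bad)}")
        for x, n_pro, count in self.planted:
            if x not in STANDARD_RESIDUES or x == "P":
                raise ValueError(
                    f"planted x_residue must be a standard non-proline residue, got {x!r}"
                )
            if n_pro < 2 or count < 0:
                raise ValueError(f"invalid plant ({x}, {n_pro}, {count})")


@dataclass(frozen=True)
class SilacSpec:
    """Recipe for a synthetic SILAC ratio table.

    ``class_means`` maps a context class to its per-strain mean log2 ratio;
    ``background_n`` motif-free proteins are drawn around 0 in every strain.
    """

    class_means: Mapping[str, Mapping[str, float]]
    sigma: float
    background_n: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.background_n < 0:
            raise ValueError("background_n must be ≥ 0")


def _draw_background(rng: np.random.Generator, residues: np.ndarray,
                     probs: np.ndarray, length: int) -> np.ndarray:
    return rng.choice(residues, size=length, p=probs)


def gen_proteome(spec: ProteomeSpec) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Generate a synthetic proteome with planted, maximal proline runs.

    Returns the records and a truth table of planted motifs with columns
    ``protein_id``, ``start`` (0-based index of the first proline),
    ``x_residue`` and ``n_pro``.  Raises :class:`ValueError` when the plants
    cannot all be placed without overlap.
    """
    rng = np.random.default_rng(spec.seed)
    residues = np.array(list(spec.composition), dtype="U1")
    probs = np.array([spec.composition[r] for r in residues], dtype=float)
    non_p = residues != "P"
    if not non_p.any():
        raise ValueError("composition must include at least one non-proline residue")
    flank_probs = probs[non_p] / probs[non_p].sum()
    flank_residues = residues[non_p]

    max_npro = max((n for _, n, c in spec.planted if c > 0), default=2)
    lengths = np.maximum(
        np.rint(rng.normal(spec.length_mean, spec.length_sd, spec.n_proteins)).astype(int),
        max_npro + 2,
    )
    seqs = [_draw_background(rng, residues, probs, int(ln)) for ln in lengths]
    occupied: list[set[int]] = [set() for _ in seqs]

    truth_rows = []
    for x, n_pro, count in spec.planted:
        placed = 0
        attempts = 0
        max_attempts = 1000 * max(count, 1)
        while placed < count:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"could not place all {count} plants of ({x}, {n_pro}): "
                    "too few eligible positions"
                )
            i = int(rng.integers(spec.n_proteins))
            ln = len(seqs[i])
            if ln < n_pro + 1:
                continue
            # run occupies [pos, pos + n_pro); x at pos-1; forced flank at pos + n_pro
            pos = int(rng.integers(1, ln - n_pro + 1))
            span = range(pos - 1, min(pos + n_pro + 1, ln))
            if any(j in occupied[i] for j in span):
                continue
            seqs[i][pos - 1] = x
            seqs[i][pos : pos + n_pro] = "P"
            if pos + n_pro < ln and seqs[i][pos + n_pro] == "P":
                seqs[i][pos + n_pro] = rng.choice(flank_residues, p=flank_probs)
            occupied[i].update(span)
            truth_rows.append(
                {"protein_id": f"syn{i:05d}", "start": pos, "x_residue": x, "n_pro": n_pro}
            )
            placed += 1

    records = [
        ProteinRecord(id=f"syn{i:05d}", description="synthetic", sequence="".join(s))
        for i, s in enumerate(seqs)
    ]
    truth = pd.DataFrame(truth_rows, columns=["protein_id", "start", "x_residue", "n_pro"])
    return records, truth


def gen_silac(
    ids_with_classes: Mapping[str, str] | Sequence[tuple[str, str]],
    spec: SilacSpec,
) -> pd.DataFrame:
    """Generate a SILAC ratio table from per-protein context classes.

    Each PPP protein's log2 ratio in each strain is drawn
    normal(class_means[class][strain], sigma); ``background_n`` additional
    motif-free proteins (ids ``bg00000`` ...) are drawn normal(0, sigma).
    """
    items = list(ids_with_classes.items()) if isinstance(ids_with_classes, Mapping) \
        else list(ids_with_classes)
    strains: list[str] = sorted({s for m in spec.class_means.values() for s in m})
    if not strains:
        raise ValueError("class_means must define at least one strain")
    rng = np.random.default_rng(spec.seed)
    rows = []
    for pid, cls in items:
        if cls not in spec.class_means:
            raise ValueError(f"unknown context class {cls!r} for protein {pid!r}")
        for strain in strains:
            mean = spec.class_means[cls].get(strain, 0.0)
            rows.append((pid, strain, rng.normal(mean, spec.sigma)))
    for b in range(spec.background_n):
        for strain in strains:
            rows.append((f"bg{b:05d}", strain, rng.normal(0.0, spec.sigma)))
    return pd.DataFrame(rows, columns=["protein_id", "strain", "log2_ratio"])


def _noise_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def gen_reporter_tables(
    true_values: Mapping[str, ToeprintLanes] | Mapping[str, ReporterActivities],
    noise_cv: float = 0.0,
    n_reps: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a replicate table of noisy band intensities or activities.

    Multiplicative log-normal noise with coefficient of variation
    ``noise_cv`` (unit mean) is applied independently to every intensity or
    activity of every replicate; with ``noise_cv=0`` the downstream statistic
    recovers the true value exactly.
    """
    if noise_cv < 0:
        raise ValueError("noise_cv must be ≥ 0")
    if n_reps < 1:
        raise ValueError("n_reps must be ≥ 1")
    if not true_values:
        raise ValueError("true_values must be non-empty")
    kinds = {type(v) for v in true_values.values()}
    if len(kinds) != 1 or kinds.pop() not in (ToeprintLanes, ReporterActivities):
        raise ValueError("true_values must be all ToeprintLanes or all ReporterActivities")
    first = next(iter(true_values.values()))
    cols = _TOEPRINT_COLS if isinstance(first, ToeprintLanes) else _ACTIVITY_COLS
    rng = np.random.default_rng(seed)
    rows = []
    for construct in sorted(true_values):
        base = np.array([getattr(true_values[construct], c) for c in cols], dtype=float)
        for rep in range(1, n_reps + 1):
            noisy = base * _noise_factors(rng, noise_cv, len(cols))
            rows.append({"construct": construct, "replicate": rep,
                         **dict(zip(cols, noisy))})
    return pd.DataFrame(rows)
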