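"""Protein FASTA input/output and proteome composition.

The composition null model used throughout the package is parameterized by
the residue frequencies of the proteome under study: ``p`` (the proline
fraction), ``x_a`` (the fraction of each residue ``a``) and ``g`` (the total
number of residues).  Only the 20 standard amino acids enter these counts;
ambiguity/rare codes (B, J, O, U, X, Z) are tolerated in sequences so that
motif positions stay aligned, but are excluded from ``g`` and the fractions.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard one-letter amino-acid codes.
STANDARD_RESIDUES: str = "ACDEFGHIKLMNPQRSTVWY"

#: Tolerated non-standard codes (kept in sequences, excluded from composition).
EXTRA_RESIDUES: str = "BJOUXZ"

_VALID = frozenset(STANDARD_RESIDUES + EXTRA_RESIDUES)


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (empty records, duplicate ids, ...)."""


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its identifier.

    Parameters
    ----------
    id
        First whitespace-delimited token of the FASTA header; non-empty.
    description
        Remainder of the header line (may be empty).
    sequence
        Uppercase amino-acid sequence; a single trailing stop ``*`` is
        stripped on construction via :func:`read_fasta`.
    """

    id: str
    description: str = ""
    sequence: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaFormatError("protein record id must be non-empty")
        if len(self.sequence) < 1:
            raise FastaFormatError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise FastaFormatError(
                f"record {self.id!r} contains invalid characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ProteomeComposition:
    """Residue fractions and total size of a proteome.

    ``g`` is the number of standard residues counted; ``x`` maps each of the
    20 standard residues to its fraction of ``g`` (fractions sum to 1).
    ``p`` is shorthand for the proline fraction ``x['P']``.
    """

    g: int
    x: Mapping[str, float] = field(default_factory=dict)
    counts: Mapping[str, int] = field(default_factory=dict)

    @property
    def p(self) -> float:
        return self.x.get("P", 0.0)


def _clean_sequence(raw: str, header: str) -> str:
    seq = raw.upper()
    if seq.endswith("*"):
        seq = seq[:-1]
    if "*" in seq:
        raise FastaFormatError(f"record {header!r} contains an internal stop '*'")
    if not seq:
        raise FastaFormatError(f"record {header!r} has an empty sequence")
    return seq


def read_fasta(path: str | os.PathLike) -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Sequences are uppercased and a single trailing ``*`` is stripped.
    Raises :class:`FileNotFoundError` for a missing file and
    :class:`FastaFormatError` for empty sequences or duplicate ids.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        seq = _clean_sequence(str(rec.seq), rec.id or rec.description)
        if rec.id in seen:
            raise FastaFormatError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id) :].strip()
        records.append(ProteinRecord(id=rec.id, description=desc, sequence=seq))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | os.PathLike) -> None:
    """Write records to ``path`` in FASTA format (companion to :func:`read_fasta`)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seq_records, os.fspath(path), "fasta")


def composition(records: Sequence[ProteinRecord]) -> ProteomeComposition:
    """Compute residue fractions over the 20 standard amino acids.

    Non-standard letters are ignored; ``g`` is the total count of standard
    residues.  Raises :class:`ValueError` on an empty record list or when no
    standard residue is present.
    """
    if not records:
        raise ValueError("composition requires at least one protein record")
    counts = dict.fromkeys(STANDARD_RESIDUES, 0)
    for rec in records:
        for ch in rec.sequence:
            if ch in counts:
                counts[ch] += 1
    g = sum(counts.values())
    if g == 0:
        raise ValueError("no standard residues found in the input records")
    x = {a: counts[a] / g for a in STANDARD_RESIDUES}
    return ProteomeComposition(g=g, x=x, counts=counts)


def composition_to_tsv(comp: ProteomeComposition, path: str | os.PathLike) -> None:
    """Export a composition as TSV with columns residue, count, fraction."""
    with open(path, "w") as fh:
        fh.write("residue\tcount\tfraction\n")
        for a in STANDARD_RESIDUES:
            fh.write(f"{a}\t{comp.counts.get(a, 0)}\t{comp.x[a]:.10g}\n")
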