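"""Protein sequence records and FASTA input/output."""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .alphabet import GAP, SequenceAlphabetError, clean_residues, encode


@dataclass(frozen=True)
class ProteinSequence:
    """A named protein sequence over the standard 20-letter alphabet.

    In alignment contexts the gap symbol ``-`` is allowed; elsewhere it is
    rejected. ``X`` marks an unknown residue and is always neutral in
    scoring.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise SequenceAlphabetError(f"{self.id}: empty sequence")
        encode(self.residues)  # validates the alphabet

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def codes(self) -> np.ndarray:
        return encode(self.residues)

    @property
    def is_aligned(self) -> bool:
        return GAP in self.residues

    def ungapped(self) -> "ProteinSequence":
        return ProteinSequence(self.id, self.residues.replace(GAP, ""))


def read_fasta(
    path: str | os.PathLike,
    *,
    map_to_x: bool = False,
    aligned: bool = False,
) -> list[ProteinSequence]:
    """Read a (multi-)FASTA file into validated :class:`ProteinSequence` records.

    The record id is the description line up to the first whitespace.
    Duplicate ids are rejected. Residues outside the 20-letter alphabet
    raise unless ``map_to_x`` converts the ambiguity codes B/Z/U/O/J to X;
    gap characters are only accepted with ``aligned=True``.
    """
    records: list[ProteinSequence] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        try:
            residues = clean_residues(str(rec.seq), map_to_x=map_to_x, allow_gap=aligned)
        except SequenceAlphabetError as exc:
            raise SequenceAlphabetError(f"record {rec.id!r}: {exc}") from None
        records.append(ProteinSequence(rec.id, residues))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(seqs: list[ProteinSequence], path: str | os.PathLike) -> None:
    SeqIO.write(
        (SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs),
        os.fspath(path),
        "fasta",
    )


def read_alignment(path: str | os.PathLike, *, map_to_x: bool = False) -> list[ProteinSequence]:
    """Read an aligned FASTA file; all records must have equal length."""
    seqs = read_fasta(path, map_to_x=map_to_x, aligned=True)
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"alignment records have unequal lengths: {sorted(lengths)}")
    return seqs
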