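"""Protein sequence records and in-silico tryptic digestion.

Trypsin cleaves C-terminally of lysine (K) and arginine (R) unless the next
residue is proline; this module implements that rule exactly, plus the
missed-cleavage enumeration used both by the synthetic-data generator and by
the iBAQ observable-peptide count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

# Observable-peptide convention used for iBAQ: fully tryptic, no missed
# cleavages, peptide length within the typical detectable range.
OBSERVABLE_MIN_LEN = 7
OBSERVABLE_MAX_LEN = 30


@dataclass(frozen=True)
class ProteinRecord:
    """A single FASTA-style protein entry."""

    accession: str
    description: str
    sequence: str


class ProteinDB:
    """An ordered collection of protein records with unique accessions.

    Sequences must be non-empty, uppercase, and restricted to the 20
    canonical residues.
    """

    def __init__(self, records: list[ProteinRecord] | tuple[ProteinRecord, ...]):
        records = list(records)
        index: dict[str, ProteinRecord] = {}
        for rec in records:
            if rec.accession in index:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            if not rec.sequence:
                raise ValueError(f"empty sequence for {rec.accession!r}")
            bad = set(rec.sequence) - _AA_SET
            if bad:
                raise ValueError(
                    f"non-canonical residues {sorted(bad)} in {rec.accession!r}"
                )
            index[rec.accession] = rec
        self.records = records
        self._index = index

    @property
    def accessions(self) -> list[str]:
        return [rec.accession for rec in self.records]

    def sequence(self, accession: str) -> str:
        return self._index[accession].sequence

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __contains__(self, accession: object) -> bool:
        return accession in self._index

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self._index[accession]

    def merged_with(self, other: "ProteinDB") -> "ProteinDB":
        return ProteinDB(self.records + other.records)


def cleavage_sites(sequence: str) -> list[int]:
    """0-based positions *after* which trypsin cuts (K/R not followed by P)."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(sequence: str, missed_cleavages: int = 0) -> list[str]:
    """Fully tryptic peptides of ``sequence`` allowing up to
    ``missed_cleavages`` internal uncut sites.

    With ``missed_cleavages=0`` the returned peptides concatenate back to the
    input sequence. Peptides are ordered by start position, then length.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    bounds = [0] + cleavage_sites(sequence) + [len(sequence)]
    n_frag = len(bounds) - 1
    peptides = []
    for i in range(n_frag):
        for j in range(i + 1, min(i + 2 + missed_cleavages, n_frag + 1)):
            peptides.append(sequence[bounds[i]:bounds[j]])
    return peptides


def count_observable_peptides(sequence: str) -> int:
    """Number of theoretically observable tryptic peptides (iBAQ denominator).

    Fully tryptic, zero missed cleavages, length in
    [OBSERVABLE_MIN_LEN, OBSERVABLE_MAX_LEN] inclusive.
    """
    return sum(
        OBSERVABLE_MIN_LEN <= len(p) <= OBSERVABLE_MAX_LEN
        for p in digest(sequence, 0)
    )
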