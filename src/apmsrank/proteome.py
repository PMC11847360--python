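"""Protein FASTA I/O and sequence-level properties.

Holds the protein database consumed by the digestion and scoring stages:
one :class:`ProteinRecord` per database entry, keyed by accession, with
residue counting and average molecular mass (the "theoretical molecular
weight" a proteomics report quotes for a protein).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Extra one-letter codes accepted in permissive mode. Their masses are
#: ambiguous (B, Z, X) or non-tabulated here (U, O), so peptides containing
#: them are excluded from mass-bearing computations rather than guessed at.
AMBIGUOUS_RESIDUES = frozenset("XBZUO")

#: Average (isotope-abundance-weighted) residue masses in Da, ExPASy values.
AVERAGE_RESIDUE_MASS: dict[str, float] = {
    "G": 57.05192,
    "A": 71.07880,
    "S": 87.07820,
    "P": 97.11668,
    "V": 99.13256,
    "T": 101.10508,
    "C": 103.13880,
    "L": 113.15944,
    "I": 113.15944,
    "N": 114.10384,
    "D": 115.08860,
    "Q": 128.13072,
    "K": 128.17408,
    "E": 129.11548,
    "M": 131.19256,
    "H": 137.14108,
    "F": 147.17656,
    "R": 156.18748,
    "Y": 163.17596,
    "W": 186.21320,
}

#: Monoisotopic residue masses in Da (available as an option; average masses
#: are the default throughout because theoretical MW is an average quantity).
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER_MASS_AVERAGE = 18.01528
WATER_MASS_MONOISOTOPIC = 18.010565


class FastaFormatError(ValueError):
    """Raised when a FASTA file is empty or structurally malformed."""


class AlphabetError(ValueError):
    """Raised when a sequence contains a character outside the allowed alphabet."""


class DuplicateAccessionError(ValueError):
    """Raised when two database records share an accession."""


class MassUndefinedError(ValueError):
    """Raised when a mass is requested for a sequence with ambiguous residues."""


def parse_accession(header: str) -> tuple[str, str]:
    """Split a FASTA header into (accession, description).

    The accession is the first whitespace-delimited token; UniProt-style
    ``db|ACC|name`` tokens are reduced to the central ``ACC``.
    """
    token, _, description = header.partition(" ")
    if "|" in token:
        parts = token.split("|")
        if len(parts) >= 2 and parts[1]:
            token = parts[1]
    return token, description.strip()


@dataclass(frozen=True)
class ProteinRecord:
    """One protein database entry.

    Parameters
    ----------
    accession : str
        Unique key within a database (e.g. a locus tag or UniProt entry).
    description : str
        Free-text remainder of the FASTA header.
    sequence : str
        Uppercase one-letter residue codes. Strict records contain only the
        20 standard residues; permissive records may also contain X/B/Z/U/O.
    permissive : bool
        Whether the record was parsed under the permissive alphabet.
    """

    accession: str
    description: str
    sequence: str
    permissive: bool = False

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.accession!r}: sequence must be non-empty")
        allowed = STANDARD_RESIDUES | AMBIGUOUS_RESIDUES if self.permissive else STANDARD_RESIDUES
        for ch in self.sequence:
            if ch not in allowed:
                raise AlphabetError(
                    f"record {self.accession!r}: character {ch!r} outside the allowed alphabet"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class ProteomeDatabase:
    """Ordered collection of :class:`ProteinRecord` with accession lookup."""

    records: list[ProteinRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._index: dict[str, ProteinRecord] = {}
        for rec in self.records:
            if rec.accession in self._index:
                raise DuplicateAccessionError(f"duplicate accession {rec.accession!r}")
            self._index[rec.accession] = rec

    def add(self, record: ProteinRecord) -> None:
        if record.accession in self._index:
            raise DuplicateAccessionError(f"duplicate accession {record.accession!r}")
        self.records.append(record)
        self._index[record.accession] = record

    def __getitem__(self, accession: str) -> ProteinRecord:
        return self._index[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._index

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def accessions(self) -> list[str]:
        return [rec.accession for rec in self.records]


def read_fasta(path: str | Path, permissive: bool = False) -> ProteomeDatabase:
    """Read a protein FASTA file into a :class:`ProteomeDatabase`.

    Sequence lines are concatenated, uppercased, and a terminal ``*``
    (stop-codon artifact from gene-model translation) is stripped.

    Raises
    ------
    FastaFormatError
        If the file contains no records.
    AlphabetError
        If a sequence contains a disallowed character.
    DuplicateAccessionError
        If two records share an accession.
    """
    path = Path(path)
    db = ProteomeDatabase()
    n = 0
    for seq_rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        accession, description = parse_accession(seq_rec.description)
        sequence = str(seq_rec.seq).upper().rstrip("*")
        db.add(
            ProteinRecord(
                accession=accession,
                description=description,
                sequence=sequence,
                permissive=permissive,
            )
        )
    if n == 0:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return db


def write_fasta(db: ProteomeDatabase, path: str | Path, width: int = 60) -> None:
    """Write the database back to FASTA, sequence lines wrapped at `width`."""
    records = [
        SeqRecord(Seq(rec.sequence), id=rec.accession, description=rec.description)
        for rec in db
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def residue_count(record: ProteinRecord) -> int:
    """Number of residues in the record's sequence."""
    return len(record.sequence)


def sequence_mass(
    sequence: str, *, monoisotopic: bool = False, permissive: bool = False
) -> float:
    """Mass in Da of a residue string: sum of residue masses plus one water.

    In strict mode any non-standard residue raises
    :class:`MassUndefinedError`; permissive callers should exclude such
    sequences from mass-bearing computations instead (see
    :func:`ProteinRecord`) — masses are never fabricated for ambiguous codes.
    """
    table = MONOISOTOPIC_RESIDUE_MASS if monoisotopic else AVERAGE_RESIDUE_MASS
    water = WATER_MASS_MONOISOTOPIC if monoisotopic else WATER_MASS_AVERAGE
    total = water
    for ch in sequence:
        try:
            total += table[ch]
        except KeyError:
            if permissive:
                raise MassUndefinedError(
                    f"residue {ch!r} has no defined mass; exclude this sequence"
                ) from None
            raise MassUndefinedError(f"residue {ch!r} has no defined mass") from None
    return total


def average_molecular_mass(record: ProteinRecord, *, monoisotopic: bool = False) -> float:
    """Molecular mass of the full protein in Da (average masses by default)."""
    return sequence_mass(record.sequence, monoisotopic=monoisotopic)
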