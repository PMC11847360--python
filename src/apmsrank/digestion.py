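"""In-silico tryptic digestion and observable-peptide counting.

The denominator of the protein abundance index (PAI) is N_observable, the
number of distinct tryptic peptides of a protein that an LC-MS/MS run could
plausibly detect. "Observable" is operationalized here as fully tryptic
peptides inside a length window and (optionally) an average-mass window;
all four thresholds and the missed-cleavage allowance are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .proteome import (
    MassUndefinedError,
    ProteinRecord,
    ProteomeDatabase,
    sequence_mass,
)

logger = logging.getLogger(__name__)

#: Enzyme rules: residues cleaved after, and residues that block cleavage
#: when they follow the site ("trypsin/P" is the usual proline-blocked rule).
CLEAVAGE_RULES: dict[str, tuple[frozenset[str], frozenset[str]]] = {
    "trypsin/P": (frozenset("KR"), frozenset("P")),
    "trypsin": (frozenset("KR"), frozenset()),
}


class UnknownRuleError(ValueError):
    """Raised for an enzyme rule identifier with no registered definition."""


@dataclass(frozen=True)
class DigestConfig:
    """Parameters of the digestion and the observability filter.

    Defaults: proline-blocked trypsin, no missed cleavages, peptide length
    7-35 residues and average mass 500-5000 Da — an instrument-agnostic
    stand-in for a typical tryptic LC-MS/MS scan range.
    """

    rule: str = "trypsin/P"
    max_missed_cleavages: int = 0
    min_length: int = 7
    max_length: int = 35
    min_mass: float = 500.0
    max_mass: float = 5000.0
    use_mass_window: bool = True

    def __post_init__(self) -> None:
        if self.rule not in CLEAVAGE_RULES:
            raise UnknownRuleError(
                f"unknown enzyme rule {self.rule!r}; known: {sorted(CLEAVAGE_RULES)}"
            )
        if self.min_length > self.max_length:
            raise ValueError("min_length must be <= max_length")
        if self.min_mass > self.max_mass:
            raise ValueError("min_mass must be <= max_mass")
        if self.max_missed_cleavages < 0:
            raise ValueError("max_missed_cleavages must be >= 0")


@dataclass(frozen=True)
class Peptide:
    """A digestion product located in its parent protein.

    ``start``/``end`` are 0-based half-open coordinates, so
    ``parent.sequence[start:end] == sequence``.
    """

    sequence: str
    start: int
    end: int
    missed_cleavages: int
    mass: float


@dataclass
class DigestResult:
    """Observable peptides of one protein and their distinct-sequence count."""

    accession: str
    peptides: list[Peptide] = field(default_factory=list)

    @property
    def n_observable(self) -> int:
        """Count of distinct observable peptide sequences (repeats count once)."""
        return len({p.sequence for p in self.peptides})


def cleavage_sites(sequence: str, rule: str = "trypsin/P") -> list[int]:
    """Internal cleavage positions under the given enzyme rule.

    A position ``i`` (``1 <= i <= len-1``) is a boundary between residues
    ``i-1`` and ``i``; the sequence end is an implicit boundary and is not
    listed.
    """
    if rule not in CLEAVAGE_RULES:
        raise UnknownRuleError(
            f"unknown enzyme rule {rule!r}; known: {sorted(CLEAVAGE_RULES)}"
        )
    if not sequence:
        raise ValueError("sequence must be non-empty")
    cut_after, blocked_by = CLEAVAGE_RULES[rule]
    return [
        i
        for i in range(1, len(sequence))
        if sequence[i - 1] in cut_after and sequence[i] not in blocked_by
    ]


def digest(
    record: ProteinRecord, config: DigestConfig | None = None, *, permissive: bool = False
) -> DigestResult:
    """Digest one protein and apply the observability filter.

    Base fragments are the maximal substrings between consecutive cleavage
    boundaries; peptides with up to ``max_missed_cleavages`` internal
    boundaries are formed by joining adjacent fragments. A peptide survives
    if its length lies in ``[min_length, max_length]`` and, when the mass
    window is enabled, its average mass lies in ``[min_mass, max_mass]``.

    In permissive mode peptides containing ambiguous residues (whose mass is
    undefined) are excluded with a warning; in strict mode they raise.
    """
    config = config or DigestConfig()
    permissive = permissive or record.permissive
    seq = record.sequence
    boundaries = [0] + cleavage_sites(seq, config.rule) + [len(seq)]
    fragments = [
        (boundaries[k], boundaries[k + 1]) for k in range(len(boundaries) - 1)
    ]

    peptides: list[Peptide] = []
    for i in range(len(fragments)):
        for mc in range(config.max_missed_cleavages + 1):
            j = i + mc
            if j >= len(fragments):
                break
            start, end = fragments[i][0], fragments[j][1]
            pep_seq = seq[start:end]
            if not (config.min_length <= len(pep_seq) <= config.max_length):
                continue
            try:
                mass = sequence_mass(pep_seq)
            except MassUndefinedError:
                if not permissive:
                    raise
                logger.warning(
                    "%s: peptide %r contains mass-undefined residues; excluded",
                    record.accession,
                    pep_seq,
                )
                continue
            if config.use_mass_window and not (
                config.min_mass <= mass <= config.max_mass
            ):
                continue
            peptides.append(
                Peptide(
                    sequence=pep_seq,
                    start=start,
                    end=end,
                    missed_cleavages=mc,
                    mass=mass,
                )
            )
    return DigestResult(accession=record.accession, peptides=peptides)


def build_observable_index(
    database: ProteomeDatabase,
    config: DigestConfig | None = None,
    *,
    permissive: bool = False,
) -> dict[str, int]:
    """Map every accession in the database to its N_observable.

    Proteins with no observable peptide are retained with value 0 so that
    downstream scoring can flag them rather than silently drop them.
    """
    config = config or DigestConfig()
    index: dict[str, int] = {}
    for rec in database:
        result = digest(rec, config, permissive=permissive)
        if result.n_observable == 0:
            logger.warning("%s: no observable peptides under current config", rec.accession)
        index[rec.accession] = result.n_observable
    return index
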