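"""PAI and emPAI label-free abundance scoring.

PAI = N_observed / N_observable, the ratio of unique peptides actually
identified for a protein in one sample to the peptides its sequence could
theoretically yield. emPAI = 10^PAI - 1, which is approximately
proportional to the protein's molar amount in the sample and is the
quantity used to rank co-purified proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class UnscorableError(ValueError):
    """Raised when PAI is requested for a protein with no observable peptides."""


class MissingAccessionError(KeyError):
    """Raised when evidence names accessions absent from the observable index."""

    def __init__(self, accessions: list[str]):
        self.accessions = accessions
        super().__init__(
            f"accessions missing from observable index: {sorted(accessions)}"
        )


@dataclass
class EvidenceTable:
    """Unique-peptide counts observed in one LC-MS/MS sample.

    Absence of an accession encodes "not observed"; stored counts are >= 1.
    """

    sample_id: str
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        for acc, n in self.counts.items():
            if not isinstance(n, int) or n < 1:
                raise ValueError(
                    f"sample {self.sample_id!r}: count for {acc!r} must be an integer >= 1, got {n!r}"
                )

    @property
    def accessions(self) -> set[str]:
        return set(self.counts)

    def __contains__(self, accession: str) -> bool:
        return accession in self.counts

    def __len__(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class EmpaiScore:
    """PAI/emPAI of one protein in one sample."""

    accession: str
    sample_id: str
    n_observed: int
    n_observable: int
    pai: float
    empai: float


def compute_pai(n_observed: int, n_observable: int) -> float:
    """Protein abundance index: exact ratio of observed to observable peptides."""
    if n_observable <= 0:
        raise UnscorableError(
            f"PAI undefined for n_observable={n_observable}; exclude this protein"
        )
    if n_observed < 0:
        raise ValueError("n_observed must be >= 0")
    return n_observed / n_observable

def compute_empai(pai: float) -> float:
    """Exponentially modified PAI: 10**pai - 1 (>= 0, roughly molar-proportional)."""
    if pai < 0:
        raise ValueError("pai must be >= 0")
    return 10.0**pai - 1.0


def score_sample(
    evidence: EvidenceTable, observable_index: dict[str, int]
) -> tuple[list[EmpaiScore], list[str]]:
    """Score every protein in one sample's evidence table.

    Returns ``(scores, skipped)`` where ``skipped`` lists accessions whose
    N_observable is zero (their PAI is undefined; they remain present-but-
    unranked downstream rather than being assigned an infinite score).

    Raises
    ------
    MissingAccessionError
        If any evidence accession is absent from the observable index.
    """
    missing = [acc for acc in evidence.counts if acc not in observable_index]
    if missing:
        raise MissingAccessionError(missing)

    scores: list[EmpaiScore] = []
    skipped: list[str] = []
    for acc, n_obs in evidence.counts.items():
        n_observable = observable_index[acc]
        if n_observable <= 0:
            skipped.append(acc)
            continue
        pai = compute_pai(n_obs, n_observable)
        scores.append(
            EmpaiScore(
                accession=acc,
                sample_id=evidence.sample_id,
                n_observed=n_obs,
                n_observable=n_observable,
                pai=pai,
                empai=compute_empai(pai),
            )
        )
    return scores, skipped
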