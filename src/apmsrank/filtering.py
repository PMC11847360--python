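"""Credible-interactor filtering and emPAI ranking for AP-MS experiments.

The filter is deliberately simple presence/absence logic: a protein is a
credible bait interactor when it is identified in EVERY bait replicate and
in NO control (mock / untagged-strain) purification. Survivors are ranked
by emPAI aggregated across the bait replicates, with the bait itself
retained and flagged rather than dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import yaml

from .digestion import DigestConfig
from .empai import EmpaiScore, EvidenceTable, score_sample

logger = logging.getLogger(__name__)

ACCESSION_COLUMN = "accession"
COUNT_COLUMN = "unique_pep_count"

AGGREGATORS: dict[str, Callable[[Sequence[float]], float]] = {
    "mean": lambda v: float(np.mean(v)),
    "median": lambda v: float(np.median(v)),
    "max": lambda v: float(np.max(v)),
}


class DesignError(ValueError):
    """Raised for structurally invalid experiment designs."""


class EvidenceFormatError(ValueError):
    """Raised for malformed evidence tables."""


@dataclass
class ExperimentDesign:
    """A bait pull-down experiment: bait replicates plus control purifications."""

    bait_accession: str
    bait_replicates: list[EvidenceTable]
    control_replicates: list[EvidenceTable] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.bait_replicates:
            raise DesignError("at least one bait replicate is required")
        ids = [t.sample_id for t in self.bait_replicates + self.control_replicates]
        if len(ids) != len(set(ids)):
            raise DesignError(f"sample_ids must be unique, got {ids}")
        if not any(self.bait_accession in t for t in self.bait_replicates):
            logger.warning(
                "bait %r not observed in any bait replicate", self.bait_accession
            )


@dataclass
class CandidateReport:
    """Ranked credible interactors.

    ``rows`` is a DataFrame with columns ``rank``, ``accession``, ``is_bait``,
    one ``n_observed_<sample>`` and one ``empai_<sample>`` column per bait
    replicate, and ``aggregate_empai``; sorted by aggregate emPAI descending
    with lexicographic accession tie-break. ``skipped`` lists accessions that
    passed the presence/absence filter but have no observable peptides, so
    their emPAI is undefined and they cannot be ranked.
    """

    rows: pd.DataFrame
    skipped: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def rank_of(self, accession: str) -> int | None:
        """1-based rank of an accession, or None if not in the ranked rows."""
        hit = self.rows.loc[self.rows[ACCESSION_COLUMN] == accession, "rank"]
        return int(hit.iloc[0]) if len(hit) else None


def intersect_replicates(
    tables: Sequence[EvidenceTable], min_unique_peptides: int = 1
) -> set[str]:
    """Accessions observed (count >= threshold) in every table."""
    if not tables:
        raise DesignError("intersection of zero replicates is undefined")
    present = [
        {acc for acc, n in t.counts.items() if n >= min_unique_peptides}
        for t in tables
    ]
    return set.intersection(*present)


def subtract_controls(
    candidates: set[str], controls: Sequence[EvidenceTable]
) -> set[str]:
    """Remove any accession observed in ANY control purification."""
    seen_in_controls: set[str] = set()
    for t in controls:
        seen_in_controls |= t.accessions
    return candidates - seen_in_controls


def credible_interactors(
    design: ExperimentDesign, min_unique_peptides: int = 1
) -> set[str]:
    """Presence/absence filter: in all bait replicates, in no control."""
    return subtract_controls(
        intersect_replicates(design.bait_replicates, min_unique_peptides),
        design.control_replicates,
    )


def rank_candidates(
    candidates: set[str],
    design: ExperimentDesign,
    observable_index: dict[str, int],
    aggregate: str = "mean",
) -> CandidateReport:
    """Score candidates per bait replicate and rank by aggregate emPAI.

    A candidate absent from one replicate (possible when the presence
    threshold differs from the filter's) contributes emPAI 0 for that
    replicate. Accessions with N_observable = 0 go to the skip list.
    """
    if aggregate not in AGGREGATORS:
        raise ValueError(f"unknown aggregate {aggregate!r}; known: {sorted(AGGREGATORS)}")
    union = set()
    for t in design.bait_replicates:
        union |= t.accessions
    stray = candidates - union
    if stray:
        raise DesignError(f"candidates not present in any bait replicate: {sorted(stray)}")

    per_sample: dict[str, dict[str, EmpaiScore]] = {}
    skipped: set[str] = set()
    for table in design.bait_replicates:
        restricted = EvidenceTable(
            sample_id=table.sample_id,
            counts={a: n for a, n in table.counts.items() if a in candidates},
        )
        scores, skip = score_sample(restricted, observable_index)
        per_sample[table.sample_id] = {s.accession: s for s in scores}
        skipped.update(skip)

    agg_fn = AGGREGATORS[aggregate]
    records = []
    for acc in sorted(candidates - skipped):
        row: dict[str, object] = {
            ACCESSION_COLUMN: acc,
            "is_bait": acc == design.bait_accession,
        }
        empais = []
        for table in design.bait_replicates:
            score = per_sample[table.sample_id].get(acc)
            n_obs = score.n_observed if score else 0
            empai = score.empai if score else 0.0
            row[f"n_observed_{table.sample_id}"] = n_obs
            row[f"empai_{table.sample_id}"] = empai
            empais.append(empai)
        row["aggregate_empai"] = agg_fn(empais)
        records.append(row)

    columns = (
        [ACCESSION_COLUMN, "is_bait"]
        + [f"n_observed_{t.sample_id}" for t in design.bait_replicates]
        + [f"empai_{t.sample_id}" for t in design.bait_replicates]
        + ["aggregate_empai"]
    )
    rows = pd.DataFrame.from_records(records, columns=columns)
    rows = rows.sort_values(
        ["aggregate_empai", ACCESSION_COLUMN], ascending=[False, True]
    ).reset_index(drop=True)
    rows.insert(0, "rank", np.arange(1, len(rows) + 1))
    return CandidateReport(rows=rows, skipped=sorted(skipped))


def prioritize(
    design: ExperimentDesign,
    observable_index: dict[str, int],
    min_unique_peptides: int = 1,
    aggregate: str = "mean",
) -> CandidateReport:
    """Filter then rank: the full prioritization of one experiment."""
    credible = credible_interactors(design, min_unique_peptides)
    return rank_candidates(credible, design, observable_index, aggregate)


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_evidence(path: str | Path, sample_id: str) -> EvidenceTable:
    """Read one sample's evidence TSV/CSV (columns accession, unique_pep_count)."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    for col in (ACCESSION_COLUMN, COUNT_COLUMN):
        if col not in df.columns:
            raise EvidenceFormatError(f"{path}: missing required column {col!r}")
    if df[ACCESSION_COLUMN].duplicated().any():
        dups = df.loc[df[ACCESSION_COLUMN].duplicated(), ACCESSION_COLUMN].tolist()
        raise EvidenceFormatError(f"{path}: duplicate accessions {dups}")
    counts: dict[str, int] = {}
    for i, (acc, n) in enumerate(zip(df[ACCESSION_COLUMN], df[COUNT_COLUMN])):
        try:
            n_int = int(n)
        except (TypeError, ValueError):
            raise EvidenceFormatError(
                f"{path} row {i}: non-integer count {n!r} for {acc!r}"
            ) from None
        if n_int != float(n) or n_int < 1:
            raise EvidenceFormatError(
                f"{path} row {i}: count for {acc!r} must be an integer >= 1, got {n!r}"
            )
        counts[str(acc)] = n_int
    return EvidenceTable(sample_id=sample_id, counts=counts)


def write_evidence(table: EvidenceTable, path: str | Path) -> None:
    """Write an evidence table as TSV (accession, unique_pep_count)."""
    df = pd.DataFrame(
        {
            ACCESSION_COLUMN: list(table.counts),
            COUNT_COLUMN: list(table.counts.values()),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_report(report: CandidateReport, path: str | Path) -> None:
    """Write a candidate report as TSV; emPAI columns rounded to 2 decimals.

    Unrankable accessions (no observable peptides) are appended after the
    ranked rows with empty rank and score fields, so presence evidence is
    never silently lost.
    """
    out = report.rows.copy()
    for col in out.columns:
        if col.startswith("empai_") or col == "aggregate_empai":
            out[col] = out[col].round(2)
    with open(path, "w") as fh:
        out.to_csv(fh, sep="\t", index=False)
        for acc in report.skipped:
            fh.write(f"\t{acc}\t{False}" + "\t" * (len(out.columns) - 3) + "\n")


def read_report(path: str | Path) -> CandidateReport:
    """Read back a report TSV written by :func:`write_report`."""
    df = pd.read_csv(path, sep="\t")
    skipped = df[df["rank"].isna()][ACCESSION_COLUMN].tolist()
    rows = df[df["rank"].notna()].copy()
    rows["rank"] = rows["rank"].astype(int)
    rows["is_bait"] = rows["is_bait"].astype(str).str.lower().isin(["true", "1"])
    return CandidateReport(rows=rows.reset_index(drop=True), skipped=skipped)


def read_design(path: str | Path) -> dict:
    """Read a YAML design config.

    Recognized keys: ``bait_accession``, ``fasta``, ``bait_evidence`` (list of
    paths), ``control_evidence`` (list of paths), ``digest`` (mapping of
    :class:`DigestConfig` fields), ``aggregate``, ``min_unique_peptides``.
    Relative paths are resolved against the config file's directory.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "bait_accession" not in cfg:
        raise DesignError(f"{path}: design config must map keys incl. 'bait_accession'")
    base = path.parent
    for key in ("bait_evidence", "control_evidence"):
        cfg[key] = [str((base / p)) for p in cfg.get(key, [])]
    if "fasta" in cfg:
        cfg["fasta"] = str(base / cfg["fasta"])
    cfg.setdefault("aggregate", "mean")
    cfg.setdefault("min_unique_peptides", 1)
    cfg["digest"] = DigestConfig(**cfg.get("digest", {}))
    return cfg
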