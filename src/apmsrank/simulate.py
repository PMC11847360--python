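"""Seeded synthetic AP-MS experiment generator.

Emulates the statistical structure a bait pull-down analysis assumes: a
random proteome with realistic tryptic (K/R) content, one high-abundance
bait, true preys detectable only in bait replicates, contaminants
detectable in bait AND control replicates under the same detection law,
and a silent background. Per-sample unique-peptide counts are binomial
over each protein's observable peptides with a saturating
abundance-dependent detection probability p = 1 - exp(-k*a), so more
abundant proteins yield more unique peptides — the behavior emPAI ranking
relies on.

Every quantity is reproducible from one root seed; per-sample streams are
derived by stable hashing of the sample id, so adding a replicate never
perturbs existing ones.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .digestion import DigestConfig, build_observable_index
from .empai import EvidenceTable
from .filtering import CandidateReport, ExperimentDesign, prioritize
from .proteome import ProteinRecord, ProteomeDatabase

RESIDUES = np.array(list("ACDEFGHILMNPQSTVWY"))  # the 18 non-K/R standard residues


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic experiment.

    Abundances are on an arbitrary scale; only k*a matters, through the
    per-peptide detection probability 1 - exp(-k*a).
    """

    n_proteins: int = 500
    length_range: tuple[int, int] = (100, 800)
    kr_fraction: float = 0.11
    n_true_preys: int = 15
    n_contaminants: int = 30
    bait_abundance: float = 50.0
    prey_abundance_range: tuple[float, float] = (5.0, 20.0)
    contaminant_abundance_range: tuple[float, float] = (10.0, 40.0)
    detection_rate_per_abundance: float = 0.05
    n_bait_reps: int = 3
    n_control_reps: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_preys + self.n_contaminants + 1 > self.n_proteins:
            raise ValueError("bait + preys + contaminants must fit in the proteome")
        if not 0 < self.kr_fraction < 1:
            raise ValueError("kr_fraction must be in (0, 1)")
        for a in (
            self.bait_abundance,
            *self.prey_abundance_range,
            *self.contaminant_abundance_range,
        ):
            if a <= 0:
                raise ValueError("abundances must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Role of every simulated protein in the experiment."""

    bait_accession: str
    true_prey_accessions: frozenset[str]
    contaminant_accessions: frozenset[str]
    background_accessions: frozenset[str]


@dataclass
class SimulatedExperiment:
    """Proteome + design + ground truth of one simulated pull-down."""

    proteome: ProteomeDatabase
    design: ExperimentDesign
    truth: GroundTruth
    abundances: dict[str, float] = field(default_factory=dict)
    observable_index: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class RecoveryMetrics:
    """How well the filter + ranking recovered the simulated ground truth."""

    prey_recall: float
    contaminant_leak: int
    bait_rank: int | None


def _child_rng(seed: int, label: str) -> np.random.Generator:
    """Stable per-label random stream derived from the root seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(label.encode())])
    )


def generate_proteome(config: SimConfig) -> ProteomeDatabase:
    """Random proteome: i.i.d. residues with expected K+R frequency kr_fraction."""
    rng = _child_rng(config.seed, "proteome")
    lo, hi = config.length_range
    p_kr = config.kr_fraction / 2.0
    letters = np.concatenate([RESIDUES, np.array(["K", "R"])])
    probs = np.concatenate(
        [np.full(len(RESIDUES), (1.0 - config.kr_fraction) / len(RESIDUES)),
         np.array([p_kr, p_kr])]
    )
    db = ProteomeDatabase()
    for i in range(config.n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length, p=probs))
        db.add(
            ProteinRecord(
                accession=f"SIM_{i + 1:06d}",
                description="synthetic protein",
                sequence=seq,
            )
        )
    return db


def assign_truth(config: SimConfig, proteome: ProteomeDatabase) -> GroundTruth:
    """Randomly partition the proteome into bait, preys, contaminants, background."""
    rng = _child_rng(config.seed, "truth")
    accs = np.array(proteome.accessions)
    chosen = rng.choice(
        len(accs), size=1 + config.n_true_preys + config.n_contaminants, replace=False
    )
    bait = accs[chosen[0]]
    preys = frozenset(accs[chosen[1 : 1 + config.n_true_preys]])
    contaminants = frozenset(accs[chosen[1 + config.n_true_preys :]])
    background = frozenset(accs) - preys - contaminants - {bait}
    return GroundTruth(
        bait_accession=str(bait),
        true_prey_accessions=preys,
        contaminant_accessions=contaminants,
        background_accessions=background,
    )


def draw_abundances(config: SimConfig, truth: GroundTruth) -> dict[str, float]:
    """One abundance per detectable protein, shared across all its samples."""
    rng = _child_rng(config.seed, "abundances")
    abundances = {truth.bait_accession: config.bait_abundance}
    for acc in sorted(truth.true_prey_accessions):
        abundances[acc] = float(rng.uniform(*config.prey_abundance_range))
    for acc in sorted(truth.contaminant_accessions):
        abundances[acc] = float(rng.uniform(*config.contaminant_abundance_range))
    return abundances


def detection_probability(abundance: float, k: float) -> float:
    """Per-peptide detection probability: saturating 1 - exp(-k*a)."""
    return 1.0 - float(np.exp(-k * abundance))


def _sample_counts(
    proteins: list[str],
    abundances: dict[str, float],
    observable_index: dict[str, int],
    k: float,
    rng: np.random.Generator,
) -> dict[str, int]:
    counts: dict[str, int] = {}
    for acc in proteins:
        n_observable = observable_index.get(acc, 0)
        if n_observable == 0:
            continue  # silently undetectable, whatever its abundance
        p = detection_probability(abundances[acc], k)
        n = int(rng.binomial(n_observable, p))
        if n >= 1:
            counts[acc] = n
    return counts


def simulate_evidence(
    proteome: ProteomeDatabase,
    truth: GroundTruth,
    config: SimConfig,
    observable_index: dict[str, int],
) -> ExperimentDesign:
    """Draw per-replicate evidence tables for the bait and control samples.

    Bait replicates can detect the bait, preys, and contaminants; control
    replicates only the contaminants (at identical detection probability);
    background proteins never appear.
    """
    abundances = draw_abundances(config, truth)
    k = config.detection_rate_per_abundance
    bait_members = (
        [truth.bait_accession]
        + sorted(truth.true_prey_accessions)
        + sorted(truth.contaminant_accessions)
    )
    control_members = sorted(truth.contaminant_accessions)

    bait_tables = []
    for i in range(1, config.n_bait_reps + 1):
        sample_id = f"bait-rep-{i}"
        rng = _child_rng(config.seed, sample_id)
        bait_tables.append(
            EvidenceTable(
                sample_id=sample_id,
                counts=_sample_counts(bait_members, abundances, observable_index, k, rng),
            )
        )
    control_tables = []
    for i in range(1, config.n_control_reps + 1):
        sample_id = f"control-rep-{i}"
        rng = _child_rng(config.seed, sample_id)
        control_tables.append(
            EvidenceTable(
                sample_id=sample_id,
                counts=_sample_counts(control_members, abundances, observable_index, k, rng),
            )
        )
    return ExperimentDesign(
        bait_accession=truth.bait_accession,
        bait_replicates=bait_tables,
        control_replicates=control_tables,
    )


def simulate_experiment(
    config: SimConfig, digest_config: DigestConfig | None = None
) -> SimulatedExperiment:
    """Full generator: proteome, ground truth, and evidence tables."""
    digest_config = digest_config or DigestConfig()
    proteome = generate_proteome(config)
    truth = assign_truth(config, proteome)
    observable_index = build_observable_index(proteome, digest_config)
    design = simulate_evidence(proteome, truth, config, observable_index)
    return SimulatedExperiment(
        proteome=proteome,
        design=design,
        truth=truth,
        abundances=draw_abundances(config, truth),
        observable_index=observable_index,
    )


def evaluate_recovery(report: CandidateReport, truth: GroundTruth) -> RecoveryMetrics:
    """Prey recall, contaminant leak count, and bait rank of one report."""
    credible = set(report.rows["accession"]) | set(report.skipped)
    preys = truth.true_prey_accessions
    recall = len(credible & preys) / len(preys) if preys else 1.0
    leak = len(credible & truth.contaminant_accessions)
    return RecoveryMetrics(
        prey_recall=recall,
        contaminant_leak=leak,
        bait_rank=report.rank_of(truth.bait_accession),
    )


def run_simulated_pipeline(
    config: SimConfig, digest_config: DigestConfig | None = None
) -> tuple[SimulatedExperiment, CandidateReport, RecoveryMetrics]:
    """Simulate, prioritize, and score recovery in one call."""
    experiment = simulate_experiment(config, digest_config)
    report = prioritize(experiment.design, experiment.observable_index)
    metrics = evaluate_recovery(report, experiment.truth)
    return experiment, report, metrics
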