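import pytest
from hypothesis import settings

from apmsrank import EvidenceTable, ExperimentDesign, ProteinRecord, ProteomeDatabase

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def toy_proteome() -> ProteomeDatabase:
    return ProteomeDatabase(
        [
            ProteinRecord("P1", "bait-like", "MKARPEPTIDEKRAGHKLMNPQRSTVWYK"),
            ProteinRecord("P2", "prey-like", "AKRPMKR"),
            ProteinRecord("P3", "no cleavage sites", "MMMGGGAAA"),
        ]
    )


@pytest.fixture
def toy_design() -> ExperimentDesign:
    """Bait + one consistent prey + one contaminant-like protein (C1)."""
    return ExperimentDesign(
        bait_accession="BAIT",
        bait_replicates=[
            EvidenceTable("rep1", {"BAIT": 9, "P1": 3, "P2": 2, "C1": 4}),
            EvidenceTable("rep2", {"BAIT": 8, "P1": 2, "C1": 5}),
            EvidenceTable("rep3", {"BAIT": 9, "P1": 4, "P3": 1, "C1": 4}),
        ],
        control_replicates=[
            EvidenceTable("ctrl1", {"C1": 3}),
            EvidenceTable("ctrl2", {"C2": 2}),
        ],
    )
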