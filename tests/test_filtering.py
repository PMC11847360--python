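"""Credibility filter, emPAI ranking, and evidence/report I/O."""

import itertools

import pandas as pd
import pytest

from apmsrank import (
    EvidenceTable,
    ExperimentDesign,
    credible_interactors,
    intersect_replicates,
    prioritize,
    rank_candidates,
    read_design,
    read_evidence,
    read_report,
    subtract_controls,
    write_report,
)
from apmsrank.filtering import DesignError, EvidenceFormatError


def table(sample_id, *accessions, count=1):
    return EvidenceTable(sample_id, {a: count for a in accessions})


class TestIntersectSubtract:
    def test_intersection(self):
        tables = [
            table("a", "A", "B", "C"),
            table("b", "A", "B"),
            table("c", "A", "B", "D"),
        ]
        assert intersect_replicates(tables) == {"A", "B"}

    def test_single_table_identity(self):
        assert intersect_replicates([table("a", "A", "B")]) == {"A", "B"}

    def test_disjoint_tables(self):
        assert intersect_replicates([table("a", "A"), table("b", "B")]) == set()

    def test_empty_collection_rejected(self):
        with pytest.raises(DesignError):
            intersect_replicates([])

    def test_min_unique_peptides_threshold(self):
        tables = [EvidenceTable("a", {"A": 3, "B": 1})]
        assert intersect_replicates(tables, min_unique_peptides=2) == {"A"}

    def test_subtraction_against_control_union(self):
        assert subtract_controls({"A", "B"}, [table("c1", "B"), table("c2", "C")]) == {"A"}
        assert subtract_controls({"A", "B"}, []) == {"A", "B"}
        assert subtract_controls(set(), [table("c1", "B")]) == set()


class TestCredibleInteractors:
    def test_toy_design(self):
        design = ExperimentDesign(
            bait_accession="BAIT",
            bait_replicates=[
                table("r1", "BAIT", "P1", "P2", "C1"),
                table("r2", "BAIT", "P1", "C1"),
                table("r3", "BAIT", "P1", "P3", "C1"),
            ],
            control_replicates=[table("c1", "C1", "C2")],
        )
        assert credible_interactors(design) == {"BAIT", "P1"}

    def test_zero_overlap_gives_empty_set(self):
        design = ExperimentDesign(
            bait_accession="BAIT",
            bait_replicates=[table("r1", "A"), table("r2", "B")],
        )
        assert credible_interactors(design) == set()

    def test_matches_exhaustive_enumeration(self):
        """Every presence/absence pattern of 4 proteins x 3 reps x 2 controls.

        Patterns are enumerated up to protein relabeling (the filter is
        symmetric in protein identity), which keeps the sweep exhaustive
        while avoiding redundant permutations.
        """
        import logging

        logging.disable(logging.WARNING)  # absent-bait warnings arise by construction
        try:
            proteins = ["P0", "P1", "P2", "P3"]
            for n_reps, n_ctrl in [(1, 0), (2, 1), (3, 2)]:
                n_samples = n_reps + n_ctrl
                # each protein independently present/absent in each sample
                for pattern in itertools.combinations_with_replacement(
                    range(2**n_samples), len(proteins)
                ):
                    membership = {
                        p: [bool(bits >> s & 1) for s in range(n_samples)]
                        for p, bits in zip(proteins, pattern)
                    }
                    reps = [
                        EvidenceTable(
                            f"r{s}", {p: 1 for p in proteins if membership[p][s]}
                        )
                        for s in range(n_reps)
                    ]
                    ctrls = [
                        EvidenceTable(
                            f"c{s}",
                            {p: 1 for p in proteins if membership[p][n_reps + s]},
                        )
                        for s in range(n_ctrl)
                    ]
                    design = ExperimentDesign("P0", reps, ctrls)
                    expected = {
                        p
                        for p in proteins
                        if all(membership[p][s] for s in range(n_reps))
                        and not any(membership[p][n_reps + s] for s in range(n_ctrl))
                    }
                    assert credible_interactors(design) == expected
        finally:
            logging.disable(logging.NOTSET)

    def test_anti_monotone_in_controls_and_replicates(self, toy_design):
        base = credible_interactors(toy_design)
        extra_ctrl = ExperimentDesign(
            toy_design.bait_accession,
            toy_design.bait_replicates,
            toy_design.control_replicates + [table("c3", "P1")],
        )
        assert credible_interactors(extra_ctrl) <= base
        extra_rep = ExperimentDesign(
            toy_design.bait_accession,
            toy_design.bait_replicates + [table("r4", "BAIT")],
            toy_design.control_replicates,
        )
        assert credible_interactors(extra_rep) <= base


class TestRankCandidates:
    INDEX = {"BAIT": 10, "P1": 10, "C1": 10}

    def test_ranks_follow_aggregate_empai(self, toy_design):
        report = prioritize(toy_design, {"BAIT": 10, "P1": 10})
        assert list(report.rows["rank"]) == [1, 2]
        assert list(report.rows["accession"]) == ["BAIT", "P1"]
        assert report.rows["aggregate_empai"].is_monotonic_decreasing
        assert bool(report.rows.loc[0, "is_bait"]) is True
        assert report.rank_of("BAIT") == 1

    def test_tie_break_is_lexicographic(self):
        design = ExperimentDesign(
            "P9",
            [EvidenceTable("r1", {"P2": 5, "P1": 5, "P9": 5})],
        )
        report = rank_candidates({"P1", "P2"}, design, {"P1": 10, "P2": 10, "P9": 10})
        assert list(report.rows["accession"]) == ["P1", "P2"]

    def test_empty_candidate_set(self, toy_design):
        report = rank_candidates(set(), toy_design, self.INDEX)
        assert len(report) == 0

    def test_unscorable_candidates_in_skip_list(self, toy_design):
        report = prioritize(toy_design, {"BAIT": 10, "P1": 0})
        assert report.skipped == ["P1"]
        assert list(report.rows["accession"]) == ["BAIT"]

    def test_candidates_outside_bait_union_rejected(self, toy_design):
        with pytest.raises(DesignError):
            rank_candidates({"NOT_THERE"}, toy_design, self.INDEX)

    def test_aggregate_alternatives(self, toy_design):
        mean_rep = prioritize(toy_design, {"BAIT": 10, "P1": 10}, aggregate="mean")
        max_rep = prioritize(toy_design, {"BAIT": 10, "P1": 10}, aggregate="max")
        row_mean = mean_rep.rows.set_index("accession").loc["P1", "aggregate_empai"]
        row_max = max_rep.rows.set_index("accession").loc["P1", "aggregate_empai"]
        assert row_max >= row_mean


class TestEvidenceIO:
    def test_read_tsv(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("accession\tunique_pep_count\nP1\t3\nP2\t1\n")
        t = read_evidence(p, "s1")
        assert t.counts == {"P1": 3, "P2": 1}

    def test_extra_columns_ignored(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("accession\tunique_pep_count\tdescription\nP1\t3\tx\n")
        assert read_evidence(p, "s1").counts == {"P1": 3}

    def test_duplicate_accession_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("accession\tunique_pep_count\nP1\t3\nP1\t2\n")
        with pytest.raises(EvidenceFormatError, match="P1"):
            read_evidence(p, "s1")

    @pytest.mark.parametrize("bad", ["0", "2.5", "abc"])
    def test_invalid_counts_rejected(self, tmp_path, bad):
        p = tmp_path / "s.tsv"
        p.write_text(f"accession\tunique_pep_count\nP1\t{bad}\n")
        with pytest.raises(EvidenceFormatError):
            read_evidence(p, "s1")

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("acc\tn\nP1\t3\n")
        with pytest.raises(EvidenceFormatError, match="accession"):
            read_evidence(p, "s1")


class TestReportIO:
    def test_round_trip_preserves_ranks_and_scores(self, tmp_path, toy_design):
        report = prioritize(toy_design, {"BAIT": 10, "P1": 10})
        out = tmp_path / "report.tsv"
        write_report(report, out)
        back = read_report(out)
        assert list(back.rows["rank"]) == list(report.rows["rank"])
        assert list(back.rows["accession"]) == list(report.rows["accession"])
        assert list(back.rows["is_bait"]) == list(report.rows["is_bait"])
        pd.testing.assert_series_equal(
            back.rows["aggregate_empai"],
            report.rows["aggregate_empai"].round(2),
            check_exact=False,
            atol=1e-9,
        )

    def test_skipped_accessions_written_at_tail(self, tmp_path, toy_design):
        report = prioritize(toy_design, {"BAIT": 10, "P1": 0})
        out = tmp_path / "report.tsv"
        write_report(report, out)
        back = read_report(out)
        assert back.skipped == ["P1"]


def test_read_design_resolves_paths(tmp_path):
    (tmp_path / "design.yaml").write_text(
        "bait_accession: BAIT\n"
        "fasta: db.fasta\n"
        "bait_evidence: [r1.tsv, r2.tsv]\n"
        "control_evidence: [c1.tsv]\n"
        "digest: {max_missed_cleavages: 1}\n"
    )
    cfg = read_design(tmp_path / "design.yaml")
    assert cfg["bait_accession"] == "BAIT"
    assert cfg["fasta"] == str(tmp_path / "db.fasta")
    assert cfg["bait_evidence"] == [str(tmp_path / "r1.tsv"), str(tmp_path / "r2.tsv")]
    assert cfg["digest"].max_missed_cleavages == 1
    assert cfg["aggregate"] == "mean"
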