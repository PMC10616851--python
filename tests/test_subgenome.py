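"""Subgenome presence/absence classification from mapping evidence."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import germbank as gb
from germbank import MISSING
from germbank.subgenome import ABSENT, AMBIGUOUS, PRESENT, _verdict

from conftest import matrix_from_calls

M = MISSING


class TestPanelLoci:
    def test_monomorphic_panel_is_empty(self):
        G = matrix_from_calls(np.zeros((4, 10), dtype=np.int8))
        assert gb.diploid_panel_loci(G, G.accession_ids) == []

    def test_hand_counted_segregating_loci(self):
        calls = np.zeros((3, 10), dtype=np.int8)
        calls[0, 2] = 2      # segregating
        calls[:, 5] = 1      # het only: both alleles observed
        calls[:, 7] = 2      # monomorphic alt
        calls[1, 8] = 2      # segregating
        G = matrix_from_calls(calls)
        assert gb.diploid_panel_loci(G, G.accession_ids) == ["loc2", "loc5", "loc8"]

    def test_subgenome_tag_restriction(self, default_panel):
        _, G, _, truth, _ = default_panel
        for genome, loci in truth.panel_loci.items():
            members = [
                a for a, sp in truth.true_species.items()
                if truth.true_formula[sp] == genome
            ]
            assert gb.diploid_panel_loci(G, members, genome) == loci

    def test_empty_panel_raises(self):
        G = matrix_from_calls([[0]])
        with pytest.raises(gb.ValidationError):
            gb.diploid_panel_loci(G, [])


class TestLociRecovery:
    def test_extremes(self):
        G = matrix_from_calls([[0, 2, 1], [M, M, M]], ["full", "none"])
        loci = G.locus_ids
        assert gb.loci_recovery(G, "full", loci) == 1.0
        assert gb.loci_recovery(G, "none", loci) == 0.0

    def test_carried_genome_recovers_near_generator_rate(self, default_panel):
        cfg, G, _, truth, _ = default_panel
        rates = [
            gb.loci_recovery(G, acc, truth.panel_loci["U"])
            for acc, sp in truth.true_species.items()
            if sp == "tet_UM"
        ]
        assert abs(np.mean(rates) - cfg.evidence.loci_present_rate) < 0.05


class TestClassification:
    @pytest.mark.parametrize(
        "read_rate, loci_rate, expected",
        [
            (0.38, 0.48, PRESENT),    # the observed M-present tetraploid regime
            (0.21, 0.10, ABSENT),     # the observed M-absent regime
            (0.38, 0.32, AMBIGUOUS),  # between the bands
            (0.29, 0.48, AMBIGUOUS),  # statistics disagree -> undecided
        ],
    )
    def test_decision_rule(self, read_rate, loci_rate, expected):
        e = gb.MappingEvidence("acc", "M", read_rate, loci_rate)
        assert _verdict(e, gb.EvidenceThresholds()) == expected

    def test_ux_formula_for_tetraploid_missing_second_genome(self):
        evidence = [
            gb.MappingEvidence("acc", "U", 0.38, 0.50),
            gb.MappingEvidence("acc", "M", 0.21, 0.12),
        ]
        call = gb.classify_subgenomes(evidence, ploidy=4)
        assert call.verdicts == {"M": ABSENT, "U": PRESENT}
        assert call.inferred_formula == "UX"

    def test_full_formula_when_both_present(self):
        evidence = [
            gb.MappingEvidence("acc", "U", 0.39, 0.50),
            gb.MappingEvidence("acc", "M", 0.37, 0.46),
        ]
        assert gb.classify_subgenomes(evidence, ploidy=4).inferred_formula == "MU"

    def test_conflicting_rows_raise(self):
        evidence = [
            gb.MappingEvidence("acc", "U", 0.38, 0.50),
            gb.MappingEvidence("acc", "U", 0.20, 0.50),
        ]
        with pytest.raises(gb.ValidationError):
            gb.classify_subgenomes(evidence)

    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(gb.ValidationError):
            gb.MappingEvidence("acc", "U", 1.2, 0.5)

    def test_degenerate_thresholds_leave_no_per_statistic_band(self):
        # with present_min = absent_max each statistic's ambiguous band is
        # empty, so any evidence where the two statistics agree is decided
        # (disagreeing statistics stay ambiguous by the AND rule)
        t = gb.EvidenceThresholds(0.30, 0.30, 0.35, 0.35)
        rng = np.random.default_rng(0)
        for _ in range(100):
            above = bool(rng.integers(2))
            read = 0.30 + (1 if above else -1) * float(rng.random()) * 0.29
            loci = 0.35 + (1 if above else -1) * float(rng.random()) * 0.34
            e = gb.MappingEvidence("a", "U", read, loci)
            assert _verdict(e, t) == (PRESENT if above else ABSENT)

    @given(
        read=st.floats(0, 1), loci=st.floats(0, 1),
        d_read=st.floats(0, 0.5), d_loci=st.floats(0, 0.5),
    )
    @settings(deadline=None, max_examples=200)
    def test_monotonicity_raising_rates_never_demotes(self, read, loci, d_read, d_loci):
        t = gb.EvidenceThresholds()
        rank = {ABSENT: 0, AMBIGUOUS: 1, PRESENT: 2}
        v1 = _verdict(gb.MappingEvidence("a", "U", read, loci), t)
        v2 = _verdict(
            gb.MappingEvidence("a", "U", min(read + d_read, 1.0), min(loci + d_loci, 1.0)), t
        )
        assert rank[v2] >= rank[v1]

    def test_calibration_from_controls_is_mid_gap(self):
        evidence = [
            gb.MappingEvidence("pos1", "M", 0.40, 0.50),
            gb.MappingEvidence("pos2", "M", 0.36, 0.46),
            gb.MappingEvidence("neg1", "M", 0.20, 0.10),
            gb.MappingEvidence("neg2", "M", 0.22, 0.14),
        ]
        t = gb.calibrate_thresholds(
            evidence, {("pos1", "M"), ("pos2", "M")}, {("neg1", "M"), ("neg2", "M")}
        )
        assert t.read_present_min == pytest.approx(0.295)
        assert t.loci_present_min == pytest.approx(0.30)
        assert t.read_absent_max == t.read_present_min  # degenerate: all calls decided


class TestEvidenceIO:
    def test_tsv_round_trip(self, tmp_path):
        rows = [
            gb.MappingEvidence("a", "U", 0.38, 0.5),
            gb.MappingEvidence("a", "M", 0.21, 0.1),
            gb.MappingEvidence("b", "U", 0.37, 0.47),
            gb.MappingEvidence("b", "M", 0.39, 0.48),
        ]
        path = tmp_path / "ev.tsv"
        gb.write_evidence_tsv(rows, path)
        assert gb.read_evidence_tsv(path) == rows

    def test_invalid_rate_rejected_on_read(self, tmp_path):
        path = tmp_path / "ev.tsv"
        path.write_text(
            "accession_id\tcandidate_genome\tread_rate\tloci_rate\nacc\tU\t1.2\t0.4\n"
        )
        with pytest.raises(gb.ValidationError):
            gb.read_evidence_tsv(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "ev.tsv"
        path.write_text("accession_id\tread_rate\nacc\t0.5\n")
        with pytest.raises(gb.ValidationError):
            gb.read_evidence_tsv(path)


class TestEndToEnd:
    def test_formula_recovery_on_default_panel(self, default_panel):
        cfg, G, _, truth, evidence = default_panel
        ploidy = {a: truth.true_ploidy[truth.true_species[a]] for a in G.accession_ids}
        calls = gb.classify_all(evidence, ploidy_by_accession=ploidy)
        assert len(calls) == 30  # two tetraploid species x 15 accessions
        correct = sum(
            c.inferred_formula == truth.true_formula[truth.true_species[c.accession_id]]
            for c in calls
        )
        assert correct >= 0.95 * len(calls)
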