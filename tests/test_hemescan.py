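"""Motif scanning, MHC classification, assembly stats and panel screening."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ferracet.hemescan import (
    PATTERNS,
    PRIMARY_PATTERN,
    assembly_stats,
    classify_protein,
    get_pattern,
    panel_presence,
    proteome_mhc_survey,
    scan_motifs,
)
from ferracet.synthetic import generate_proteome, write_proteome

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_hits(seq, patterns):
    """Position-by-position oracle, honouring '*' segment breaks."""
    seq = seq.upper()
    hits = set()
    for pat in patterns:
        for i in range(len(seq) - pat.length + 1):
            window = seq[i : i + pat.length]
            if "*" in window:
                continue
            ok = all(
                (window[k] == c) if c != "x" else True
                for k, c in enumerate(pat.name)
            )
            if ok:
                hits.add((pat.name, i + 1))
    return hits


class TestScanMotifs:
    def test_two_disjoint_matches(self):
        hits = scan_motifs("MCAACHGGGCAACHD", [PRIMARY_PATTERN])
        assert [(h.pattern, h.start) for h in hits] == [("CxxCH", 2), ("CxxCH", 10)]

    def test_overlap_greedy_vs_all_positions(self):
        greedy = scan_motifs("CAACHACH", [PRIMARY_PATTERN], "non_overlapping_greedy")
        everywhere = scan_motifs("CAACHACH", [PRIMARY_PATTERN], "all_positions")
        assert [h.start for h in greedy] == [1]
        assert [h.start for h in everywhere] == [1, 4]

    def test_variant_only_match(self):
        assert scan_motifs("CAACK", [PRIMARY_PATTERN]) == []
        hits = scan_motifs("CAACK", PATTERNS)
        assert [(h.pattern, h.start) for h in hits] == [("CxxCK", 1)]

    def test_ambiguity_codes_match_wildcards_only(self):
        # X in a wildcard slot is fine; X in an anchor slot is not a match
        assert len(scan_motifs("CXXCH", [PRIMARY_PATTERN])) == 1
        assert scan_motifs("XAACH", [PRIMARY_PATTERN]) == []
        assert scan_motifs("CAACX", [PRIMARY_PATTERN]) == []

    def test_stop_terminates_segment(self):
        assert scan_motifs("CA*CH", [PRIMARY_PATTERN]) == []
        hits = scan_motifs("CAACH*CAACH", [PRIMARY_PATTERN])
        assert [h.start for h in hits] == [1, 7]

    def test_empty_sequence_empty_hits(self):
        assert scan_motifs("", PATTERNS) == []

    def test_illegal_character_errors(self):
        with pytest.raises(ValueError, match="illegal"):
            scan_motifs("CAAC1", [PRIMARY_PATTERN])

    def test_lowercase_input_uppercased(self):
        assert len(scan_motifs("caach", [PRIMARY_PATTERN])) == 1

    @settings(max_examples=300, derandomize=True)
    @given(st.text(alphabet=AA + "XBZU*", max_size=200))
    def test_all_positions_equals_bruteforce(self, seq):
        hits = scan_motifs(seq, PATTERNS, "all_positions")
        assert {(h.pattern, h.start) for h in hits} == brute_force_hits(seq, PATTERNS)

    @settings(max_examples=200, derandomize=True)
    @given(st.text(alphabet=AA, max_size=200))
    def test_greedy_count_never_exceeds_all_positions(self, seq):
        greedy = scan_motifs(seq, PATTERNS, "non_overlapping_greedy")
        everywhere = scan_motifs(seq, PATTERNS, "all_positions")
        assert len(greedy) <= len(everywhere)

    def test_hit_positions_within_bounds(self):
        seq = "G" * 5 + "CAACH" + "G" * 5
        (hit,) = scan_motifs(seq, [PRIMARY_PATTERN])
        assert 1 <= hit.start <= len(seq) - PRIMARY_PATTERN.length + 1
        assert hit.matched == "CAACH"


@pytest.mark.parametrize(
    "count,expected",
    [(0, "none"), (1, "monoheme"), (2, "multiheme"), (5, "multiheme"), (6, "multiheme_high"), (10, "multiheme_high")],
)
def test_classification_thresholds(count, expected):
    assert classify_protein(count) == expected


class TestSurvey:
    def test_planted_proteome_recovered(self):
        records, truth = generate_proteome(
            200, [("CxxCH", 2), ("CxxCH", 3), ("CxxCH", 7)], seed=5
        )
        survey = proteome_mhc_survey(records, tier="primary_only")
        assert survey.n_proteins == 203
        assert survey.n_multiheme == 3
        assert survey.n_multiheme_high == 1
        # per-protein counts match the ground-truth table exactly
        by_id = {p.protein_id: p for p in survey.profiles}
        for _, row in truth.iterrows():
            assert by_id[row["protein_id"]].count_primary == row["planted_count"]

    def test_variant_tier_counts_variants(self):
        records, _ = generate_proteome(0, [("CxxCK", 2), ("AxxCH", 3)], seed=9)
        primary = proteome_mhc_survey(records, tier="primary_only")
        combined = proteome_mhc_survey(records, tier="with_variants")
        assert primary.n_multiheme == 0
        assert combined.n_multiheme == 2

    def test_empty_proteome(self):
        survey = proteome_mhc_survey([], tier="primary_only")
        assert survey.n_proteins == 0
        assert survey.n_multiheme == 0

    def test_invariant_to_record_order_and_wrapping(self, tmp_path):
        records, _ = generate_proteome(20, [("CxxCH", 4)], seed=11)
        p1, p2 = tmp_path / "a.faa", tmp_path / "b.faa"
        write_proteome(records, p1, width=60)
        write_proteome(list(reversed(records)), p2, width=7)
        s1 = proteome_mhc_survey(p1)
        s2 = proteome_mhc_survey(p2)
        assert s1.n_multiheme == s2.n_multiheme
        counts1 = sorted(p.count_primary for p in s1.profiles)
        counts2 = sorted(p.count_primary for p in s2.profiles)
        assert counts1 == counts2


class TestAssemblyStats:
    def test_hand_checkable(self):
        stats = assembly_stats([("c1", "A" * 100), ("c2", "G" * 300)])
        assert stats.n_contigs == 2
        assert stats.total_length_bp == 400
        assert stats.n50_bp == 300

    def test_gc_excludes_n(self):
        stats = assembly_stats([("c1", "ATGC"), ("c2", "NNNN")])
        assert stats.gc_percent == pytest.approx(50.0)
        assert stats.total_length_bp == 8

    def test_empty_assembly_errors(self):
        with pytest.raises(ValueError, match="no contigs"):
            assembly_stats([])

    def test_bad_alphabet_errors(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            assembly_stats([("c1", "ATGU")])

    def test_n50_matches_sort_and_scan_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            lengths = rng.integers(1, 5000, size=rng.integers(1, 40))
            contigs = [(f"c{i}", "A" * int(L)) for i, L in enumerate(lengths)]
            stats = assembly_stats(contigs)
            # oracle: smallest L with cumulative(desc) >= half the total
            srt = np.sort(lengths)[::-1]
            cum = np.cumsum(srt)
            n50 = int(srt[np.argmax(cum >= lengths.sum() / 2)])
            assert stats.n50_bp == n50
            assert stats.n50_bp <= lengths.max()
            assert stats.total_length_bp == int(lengths.sum())


class TestPanelPresence:
    QUERY = (
        "cymA|Q1",
        "MKKLLVSLALGAMLLAGCSDDKAAEVKAPVAEAPAAEVKAPVEKAVDTTALTCAACHGTDGNSAAP"
        "NFPKLAGQSEAYLEKQLHDFKSGARKNPIMTGMAAPLSDADMHDLAAYYASQTPKAGNATGS",
    )

    def test_self_hit_is_present(self):
        results = panel_presence([self.QUERY], [("subject1", self.QUERY[1])])
        (r,) = results
        assert r.present
        assert r.percent_identity == pytest.approx(100.0)
        assert r.evalue < 1e-10
        assert r.query_coverage == pytest.approx(100.0)

    def test_shuffled_null_all_absent(self):
        rng = np.random.default_rng(17)
        letters = np.array(list(self.QUERY[1]))
        subjects = []
        for i in range(100):
            shuffled = letters.copy()
            rng.shuffle(shuffled)
            subjects.append((f"shuf{i}", "".join(shuffled)))
        results = panel_presence([self.QUERY], subjects)
        assert not results[0].present

    def test_empty_proteome_all_absent(self):
        (r,) = panel_presence([self.QUERY], [])
        assert not r.present
        assert r.best_hit_id is None

    def test_identity_threshold_is_strict(self):
        from ferracet.hemescan import DEFAULT_THRESHOLDS, _passes_thresholds

        # exactly 30.0% identity fails the strict >30% rule
        assert not _passes_thresholds(30.0, 1e-10, 100.0, DEFAULT_THRESHOLDS, no_coverage=True)
        assert _passes_thresholds(30.1, 1e-10, 100.0, DEFAULT_THRESHOLDS, no_coverage=True)

    def test_coverage_rule_toggles_with_no_coverage(self):
        from ferracet.hemescan import DEFAULT_THRESHOLDS, _passes_thresholds

        assert not _passes_thresholds(90.0, 1e-10, 10.0, DEFAULT_THRESHOLDS, no_coverage=False)
        assert _passes_thresholds(90.0, 1e-10, 10.0, DEFAULT_THRESHOLDS, no_coverage=True)

    def test_blast_backend_agrees_on_self_hit(self):
        import shutil

        if shutil.which("blastp") is None:
            pytest.skip("blastp not on PATH")
        results = panel_presence(
            [self.QUERY], [("subject1", self.QUERY[1])], backend="blast"
        )
        (r,) = results
        assert r.present
        assert r.percent_identity == pytest.approx(100.0)


def test_get_pattern_unknown():
    with pytest.raises(KeyError):
        get_pattern("CxCH")
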