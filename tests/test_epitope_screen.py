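"""Epitope scanning, TG2 deamidation, protease digestion, resistant fragments."""

import pytest
from hypothesis import given, settings, strategies as st

from gliascan.epitope_screen import (
    EpitopeDefinition,
    annotate_deamidation,
    count_distinct_epitopes,
    count_instances,
    deamidate,
    default_epitope_registry,
    extract_epitope_context,
    find_resistant_fragments,
    load_moderate_sites,
    predict_cleavage,
    render_markup,
    scan_epitopes,
)

REPEAT_17MER = "QQPQQPFPQQPQQPFPQ"
RESISTANT_26MER = "FLQPQQPFPQQPQQPYPQQPQQPFPQ"

# Table of natural DQ2-γ-I 17-mer variants with their expected TG2 markup:
# primary (QxP) targets and curated moderate targets, 0-based positions.
GAMMA_I_VARIANTS = [
    ("QPQQPQQSFPQQQQPLI", {2, 12}, {5}),
    ("QPQQPQQSFPQQQQLMI", {2}, {5, 11, 12, 13}),
    ("QPQQPQQPFPQQQQPLI", {2, 5, 12}, set()),
    ("QPQQPQQSFPQQQQPAI", {2, 12}, {5}),
    ("QPQQPQQSFPQQQPSLI", {2, 11}, {5}),
    ("QPQQPQQSSPQQQQLLI", {2}, {11, 12, 13}),
    ("QSQQPQQSSPQQQQLLI", {2}, {11, 12, 13}),
    ("QPQQSQQSSPQQQQLLI", set(), {11, 12, 13}),
    ("QPQQPQQSFPQQQQWMI", {2}, {5, 11, 12, 13}),
    ("QPQQPQQSFPQQQRPFI", {2, 12}, {5}),
    ("QPQQPQQSFPQQQRSFI", {2}, {5, 12}),
    ("QPQQPQQSFPQQQPPFI", {2, 11}, {5}),
    ("QPQQPQQSFPQQQPPLI", {2, 11}, {5}),
]


class TestRegistry:
    def test_nine_distinct_9mer_cores(self):
        reg = default_epitope_registry()
        assert len(reg) == 9
        assert all(len(ep.core) == 9 for ep in reg)
        assert len({ep.core for ep in reg}) == 9
        assert len({ep.label for ep in reg}) == 9

    def test_known_cores_present(self):
        cores = {ep.label: ep.core for ep in default_epitope_registry()}
        assert cores["DQ2-γ-I"] == "PQQSFPQQQ"
        assert cores["DQ2-γ-VIIb"] == "QQPQQPFPQ"

    def test_bad_core_length_rejected(self):
        with pytest.raises(ValueError):
            EpitopeDefinition(label="x", core="QQQ")


class TestScanning:
    def test_17mer_repeat_three_overlapping_epitopes(self):
        matches = scan_epitopes(REPEAT_17MER)
        assert count_instances(matches) == 4
        assert count_distinct_epitopes(matches) == 3
        located = {(m.label, m.start) for m in matches}
        assert located == {
            ("DQ2-γ-VIIb", 0),
            ("DQ2-γ-VI", 3),
            ("DQ2-glia-γ2a", 6),
            ("DQ2-γ-VIIb", 8),
        }

    def test_26mer_four_epitope_cores(self):
        matches = scan_epitopes(RESISTANT_26MER)
        assert count_instances(matches) == 4
        assert count_distinct_epitopes(matches) == 4
        assert {m.label for m in matches} == {
            "DQ2-γ-VI", "DQ2-γ-III", "DQ2-glia-γ2b", "DQ2-γ-VIIb",
        }

    def test_no_match_in_plain_sequence(self):
        assert scan_epitopes("AAAA") == []
        assert count_instances([]) == 0 and count_distinct_epitopes([]) == 0

    def test_region_restriction(self):
        matches = scan_epitopes(REPEAT_17MER, region=(0, 9))
        assert {(m.label, m.start) for m in matches} == {("DQ2-γ-VIIb", 0)}

    def test_concatenation_doubles_instances(self):
        double = REPEAT_17MER + "GGGGGGGG" + REPEAT_17MER
        assert count_instances(scan_epitopes(double)) == 2 * count_instances(
            scan_epitopes(REPEAT_17MER)
        )

    @given(st.text(alphabet="QPFSYLAI", min_size=0, max_size=60))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_window_oracle(self, aa):
        registry = default_epitope_registry()
        expected = sorted(
            (i, ep.label)
            for ep in registry
            for i in range(max(0, len(aa) - 8))
            if aa[i : i + 9] == ep.core
        )
        got = sorted((m.start, m.label) for m in scan_epitopes(aa, registry))
        assert got == expected


class TestDeamidation:
    @pytest.mark.parametrize("peptide, primary, moderate", GAMMA_I_VARIANTS)
    def test_gamma_i_variant_markup(self, peptide, primary, moderate):
        prof = annotate_deamidation(peptide)
        assert set(prof.positions("primary")) == primary
        assert set(prof.positions("moderate")) == moderate

    def test_rules_recorded(self):
        prof = annotate_deamidation("QPQQPQQSFPQQQQPLI")
        assert prof.rules[2] == "R1"  # QxP
        assert prof.rules[0] == "R2"  # QP blocked
        assert prof.rules[5] == "R3"  # curated moderate

    def test_qp_is_never_a_target(self):
        prof = annotate_deamidation("QPA")
        assert prof.classes == {0: "none"}

    def test_peptide_without_q_is_empty(self):
        assert annotate_deamidation("APLSF").classes == {}

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            annotate_deamidation("QQ1")

    def test_pure_function_of_inputs(self):
        pep = "QPQQPQQSFPQQQQPLI"
        assert annotate_deamidation(pep).classes == annotate_deamidation(pep).classes
        # replacing the rule table changes the outcome deterministically
        assert annotate_deamidation(pep, {}).positions("moderate") == []

    def test_deamidated_peptide_generation(self):
        assert deamidate("QPQQPQQSFPQQQQPLI") == "QPEQPQQSFPQQEQPLI"
        assert deamidate("QPQQPQQSFPQQQQPLI", include_moderate=True) == "QPEQPEQSFPQQEQPLI"

    def test_markup_rendering(self):
        # primary underlined, moderate lower-case, everything else plain
        assert render_markup("QPQQPQQSFPQQQQPLI") == "QPQ̲QPqQSFPQQQ̲QPLI"


class TestCleavage:
    def test_trypsin_basic_and_proline_block(self):
        assert [s.position for s in predict_cleavage("AKAA", ["trypsin"])] == [1]
        assert predict_cleavage("AKPA", ["trypsin"]) == []

    def test_repeat_region_has_no_tryptic_sites(self):
        assert predict_cleavage(REPEAT_17MER, ["trypsin"]) == []
        assert predict_cleavage(RESISTANT_26MER, ["trypsin"]) == []

    def test_chymotrypsin_specificities(self):
        high = {s.position for s in predict_cleavage("AFLHA", ["chymotrypsin_high"])}
        low = {s.position for s in predict_cleavage("AFLHA", ["chymotrypsin_low"])}
        assert high == {1}
        assert low == {1, 2, 3}

    def test_chymotrypsin_low_h_blocked_before_m_or_w(self):
        # H before M (or W) is not cleaved; the M site itself still is
        positions = {s.position for s in predict_cleavage("AHMA", ["chymotrypsin_low"])}
        assert positions == {2}
        assert predict_cleavage("AHWP", ["chymotrypsin_low"]) == []


class TestResistantFragments:
    def test_uncleaved_protein_is_one_fragment(self):
        frags = find_resistant_fragments("QQQQQQQQQQ", ["trypsin"], 0)
        assert [(f.start, f.end) for f in frags] == [(0, 10)]

    def test_26mer_between_tryptic_sites(self):
        prot = "AK" + RESISTANT_26MER + "KA"
        frags = find_resistant_fragments(
            prot, ["trypsin", "chymotrypsin_high"], min_epitope_instances=4
        )
        assert len(frags) == 1
        frag = frags[0]
        assert len(frag.matches) == 4
        assert {m.label for m in frag.matches} == {
            "DQ2-γ-VI", "DQ2-γ-III", "DQ2-glia-γ2b", "DQ2-γ-VIIb",
        }
        # the fragment lies inside the 26-mer region between the tryptic cuts
        assert 2 <= frag.start and frag.end <= 2 + len(RESISTANT_26MER) + 1

    def test_zero_threshold_partitions_protein(self):
        prot = "AAKAAFAAKAA"
        frags = find_resistant_fragments(prot, ["trypsin", "chymotrypsin_high"], 0)
        assert frags[0].start == 0 and frags[-1].end == len(prot)
        for a, b in zip(frags, frags[1:]):
            assert a.end == b.start


class TestEpitopeContext:
    def test_planted_flanks_recovered(self):
        prot = "AAAA" + "PQQSFPQQQ" + "WWWW"
        assert extract_epitope_context(prot, "DQ2-γ-I") == ["AAAAPQQSFPQQQWWWW"]

    def test_match_at_protein_start_has_short_flank(self):
        prot = "PQQSFPQQQXX"
        assert extract_epitope_context(prot, "DQ2-γ-I") == ["PQQSFPQQQXX"]

    def test_thirteen_variant_contexts_are_distinct(self):
        assert len({pep for pep, _, _ in GAMMA_I_VARIANTS}) == 13

    def test_curated_moderate_table_covers_all_variants(self):
        table = load_moderate_sites()
        for pep, _, moderate in GAMMA_I_VARIANTS:
            assert table.get(pep, frozenset()) == frozenset(moderate)
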