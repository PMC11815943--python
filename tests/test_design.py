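"""Guide-pair enumeration, silent verification and ssODN design rules."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nickhdr import demo
from nickhdr.design import (
    PlannedSNV,
    RepairTemplate,
    design_template,
    find_pam_out_pairs,
    renick_check,
    silent_alternatives,
    verify_silent,
)
from nickhdr.errors import InputError
from nickhdr.locus import AmpliconDef, ReferenceLocus

from oracles import is_silent, pam_out_pairs_bruteforce

LEVELS = ("blocking", "low", "medium", "full")


class TestFindPamOutPairs:
    def test_planted_toy_pair_found_at_offset_66(self):
        locus, offset = demo.toy_pam_out_locus()
        pairs = find_pam_out_pairs(locus, (40, 160), (40, 100))
        assert len(pairs) == 1
        assert pairs[0].offset == offset == 66
        assert pairs[0].orientation == "PAM-out"

    def test_no_plus_strand_pam_means_no_pairs(self):
        # CC present (a minus-strand PAM) but the sequence has no G at all,
        # so no plus-strand NGG and therefore no PAM-out pair
        seq = list("AT" * 100)
        seq[61] = seq[62] = "C"
        sequence = "".join(seq)
        locus = ReferenceLocus(
            name="no_g", sequence=sequence, coordinate_origin=0,
            exons=((50, 150),), cds_frame=0,
            pathogenic_variant=(100, sequence[100], "G"),
            short_amplicon=AmpliconDef.from_primers((20, 40), (160, 180)),
            long_amplicon=AmpliconDef.from_primers((0, 20), (180, 200)),
        )
        assert find_pam_out_pairs(locus, (40, 160), (40, 100)) == []

    def test_window_must_contain_variant(self, locus):
        with pytest.raises(InputError):
            find_pam_out_pairs(locus, (100, 400), (40, 100))

    def test_matches_bruteforce_enumeration_on_demo_window(self, locus):
        window = (5_800, 6_200)
        pairs = find_pam_out_pairs(locus, window, (40, 100))
        got = {(p.left.nick_position, p.right.nick_position) for p in pairs}
        expected = pam_out_pairs_bruteforce(
            locus.sequence, locus.pathogenic_variant[0], window, (40, 100)
        )
        assert got == expected
        assert (5_969, 6_031) in got  # the planted pair
        # sorted by distance from the offset-range midpoint
        mid = 70
        offsets = [abs(p.offset - mid) for p in pairs]
        assert offsets == sorted(offsets)

    def test_matches_bruteforce_on_random_sequence(self):
        rng = np.random.default_rng(3)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
        locus = ReferenceLocus(
            name="rand", sequence=seq, coordinate_origin=0,
            exons=((500, 1500),), cds_frame=0,
            pathogenic_variant=(1000, seq[1000], "ACGT".replace(seq[1000], "")[0]),
            short_amplicon=AmpliconDef.from_primers((100, 120), (1880, 1900)),
            long_amplicon=AmpliconDef.from_primers((0, 20), (1980, 2000)),
        )
        window = (700, 1300)
        got = {
            (p.left.nick_position, p.right.nick_position)
            for p in find_pam_out_pairs(locus, window, (40, 100))
        }
        assert got == pam_out_pairs_bruteforce(seq, 1000, window, (40, 100))
        assert got  # a random 600 bp window should contain pairs


class TestVerifySilent:
    def test_third_position_synonymous_change(self, locus):
        # GCA -> GCG (Ala) at the engineered left blocking site
        snv = PlannedSNV(5974, "A", "G", "blocking", silent=True)
        assert verify_silent(locus, snv) is True

    def test_first_position_of_internal_methionine_not_silent(self, locus):
        # ATG codon planted at 5966
        snv = PlannedSNV(5966, locus.sequence[5966], "T", "bridging")
        assert verify_silent(locus, snv) is False

    def test_intronic_position_not_applicable(self, locus):
        with pytest.raises(InputError):
            verify_silent(locus, PlannedSNV(10, locus.sequence[10], "A" if locus.sequence[10] != "A" else "C", "bridging"))

    @given(st.data())
    def test_agrees_with_translation_table_oracle(self, locus, data):
        exon = data.draw(st.sampled_from(locus.exons))
        pos = data.draw(st.integers(exon[0], exon[1] - 1))
        ref = locus.sequence[pos]
        alt = data.draw(st.sampled_from([b for b in "ACGT" if b != ref]))
        snv = PlannedSNV(pos, ref, alt, "bridging")
        assert verify_silent(locus, snv) == is_silent(locus, pos, alt)


class TestDesignTemplate:
    def test_paper_geometry_132nt_with_40bp_arms(self, template):
        assert len(template.sequence) == 132
        assert template.arm_lengths == (40, 40)
        assert template.locus_interval == (5934, 6066)

    def test_blocking_level_roles(self, template):
        roles = sorted(s.role for s in template.snvs)
        assert roles == ["blocking", "blocking", "correction"]
        # one blocking SNV per guide, inside that guide's footprint
        by_guide = {s.guide_association: s for s in template.snvs if s.role == "blocking"}
        assert set(by_guide) == {"sgRNA1", "sgRNA2"}

    def test_bridging_series_is_nested_and_monotone(self, locus, pair):
        position_sets = []
        for level in LEVELS:
            t = design_template(locus, pair, level, total_length=132, arm_length=40)
            position_sets.append({s.position for s in t.snvs})
        for smaller, larger in zip(position_sets, position_sets[1:]):
            assert smaller <= larger
            assert len(smaller) <= len(larger)
        assert len(position_sets[0]) == 3
        assert len(position_sets[1]) == 4
        assert len(position_sets[2]) == 5
        assert len(position_sets[3]) > 5

    def test_bridging_snvs_lie_between_correction_and_proximal_nick(self, locus, pair):
        t = design_template(locus, pair, "full", total_length=132, arm_length=40)
        for s in t.snvs:
            if s.role == "bridging":
                assert locus.pathogenic_variant[0] < s.position < pair.right.nick_position

    def test_every_non_correction_snv_is_silent(self, locus, pair):
        for level in LEVELS:
            t = design_template(locus, pair, level, total_length=132, arm_length=40)
            for s in t.silent_snvs:
                assert s.silent
                assert verify_silent(locus, s) is True
                assert is_silent(locus, s.position, s.alt_base)  # oracle

    def test_design_is_deterministic(self, locus, pair):
        a = design_template(locus, pair, "medium", total_length=132, arm_length=40)
        b = design_template(locus, pair, "medium", total_length=132, arm_length=40)
        assert a == b

    def test_template_translation_matches_corrected_protein(self, locus, full_template):
        pos, _, alt = locus.pathogenic_variant
        with_all = list(locus.sequence)
        for s in full_template.snvs:
            with_all[s.position] = s.alt_base
        corrected_only = list(locus.sequence)
        corrected_only[pos] = alt
        assert locus.translate("".join(with_all)) == locus.translate("".join(corrected_only))

    def test_total_length_too_small_is_infeasible(self, locus, pair):
        from nickhdr.errors import DesignInfeasibleError

        with pytest.raises(DesignInfeasibleError):
            design_template(locus, pair, "blocking", total_length=100, arm_length=40)

    def test_oligo_strand_complements_bridging_guide_protospacer_strand(self, template, pair):
        assert pair.right.strand == "+"
        assert template.oligo_strand == "-"


class TestRenickCheck:
    def test_designed_template_blocks_both_guides(self, template, pair):
        assert renick_check(template, pair) == {"sgRNA1": True, "sgRNA2": True}

    def test_template_without_blocking_snvs_fails_both(self, locus, pair, template):
        lo, hi = template.locus_interval
        correction = template.correction
        seq = list(locus.sequence[lo:hi])
        seq[correction.position - lo] = correction.alt_base
        bare = RepairTemplate(
            name="no-blocking",
            sequence="".join(seq),
            locus_interval=(lo, hi),
            snvs=(correction,),
            arm_lengths=(66, 65),
        )
        assert renick_check(bare, pair) == {"sgRNA1": False, "sgRNA2": False}

    def test_agrees_with_direct_string_match(self, locus, pair):
        # randomised single-SNV templates: renick answer must equal a direct
        # substring comparison of the edited footprint
        rng = np.random.default_rng(4)
        lo, hi = 5930, 6070
        correction = PlannedSNV(6000, "T", "C", "correction")
        for _ in range(25):
            pos = int(rng.integers(lo, hi))
            if pos == 6000:
                continue
            ref = locus.sequence[pos]
            alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
            seq = list(locus.sequence[lo:hi])
            seq[6000 - lo] = "C"
            seq[pos - lo] = alt
            t = RepairTemplate(
                name="rand", sequence="".join(seq), locus_interval=(lo, hi),
                snvs=tuple(sorted((correction, PlannedSNV(pos, ref, alt, "bridging")),
                                  key=lambda s: s.position)),
                arm_lengths=(0, 0),
            )
            result = renick_check(t, pair)
            edited = "".join(seq)
            for guide in pair.guides:
                f_lo, f_hi = guide.footprint
                unchanged = edited[f_lo - lo : f_hi - lo] == locus.sequence[f_lo:f_hi]
                assert result[guide.name] == (not unchanged)


class TestDemoEngineering:
    def test_seed_regions_offer_exactly_one_silent_site(self, locus, pair):
        # the demo exon is engineered so each guide's seed has a unique
        # synonymous site: the design must land on 5974 / 6025
        positions = {s.position for s in demo.demo_template(locus).snvs}
        assert positions == {5974, 6000, 6025}

    def test_blocking_sites_have_silent_alternatives(self, locus):
        assert silent_alternatives(locus, 5974)
        assert silent_alternatives(locus, 6025)
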