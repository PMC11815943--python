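"""Outcome classification: decision rules, aggregation and error robustness."""

import numpy as np
import pytest

from nickhdr import demo
from nickhdr.align import align_read, align_reads
from nickhdr.classify import (
    QuantWindow,
    ReadCall,
    classify_read,
    classify_reads,
    snv_incorporation,
    summarize,
)
from nickhdr.errors import InputError
from nickhdr.simulate import (
    AlleleSpec,
    ErrorModel,
    MixtureSpec,
    allele_amplicon,
    simulate_amplicon_reads,
)

NO_ERROR = ErrorModel(sub_rate=0, ins_rate=0, del_rate=0, seed=2)


def _read_for(locus, spec):
    return allele_amplicon(locus, spec, locus.short_amplicon)


def _classify_seq(locus, template, window, seq):
    aln = align_read(seq, locus, amplicon=locus.short_amplicon)
    return classify_read(aln, template, window)


class TestDecisionRules:
    def test_error_free_reads_classify_exactly_by_allele(self, locus, template, window):
        mix, categories = demo.editing_outcome_mixture(locus, template)
        for allele in mix.alleles:
            call = _classify_seq(locus, template, window, _read_for(locus, allele))
            assert call.category == categories[allele.name], allele.name

    def test_non_target_allele_is_unedited_despite_corrective_base(
        self, locus, template, window
    ):
        # the sibling allele of the compound het carries the corrective base
        # natively; without silent SNVs it must not count as HDR
        sibling = AlleleSpec(name="c", snvs=(template.correction,))
        call = _classify_seq(locus, template, window, _read_for(locus, sibling))
        assert call.category == "unedited"

    def test_blocking_without_bridging_is_imperfect(self, locus, full_template, window):
        # read carries correction + both blocking SNVs but reference bases
        # at every bridging position: partial template integration
        partial = AlleleSpec(
            name="p",
            snvs=tuple(
                s for s in full_template.snvs if s.role in ("correction", "blocking")
            ),
        )
        call = _classify_seq(locus, full_template, window, _read_for(locus, partial))
        assert call.category == "imperfect_hdr"
        bridging = [s for s in full_template.snvs if s.role == "bridging"]
        assert all(call.snv_status[s.position] == "ref_base" for s in bridging)

    def test_full_template_with_window_indel_is_imperfect(self, locus, template, window):
        spec = AlleleSpec(name="x", snvs=template.snvs, indels=((6_010, -8),))
        call = _classify_seq(locus, template, window, _read_for(locus, spec))
        assert call.category == "imperfect_hdr"

    def test_indel_outside_window_does_not_trigger_indel_call(
        self, locus, template, window
    ):
        spec = AlleleSpec(name="far", indels=((6_200, -12),))
        call = _classify_seq(locus, template, window, _read_for(locus, spec))
        assert call.category == "unedited"

    def test_subthreshold_indel_in_window_ignored(self, locus, template, window):
        spec = AlleleSpec(name="tiny", indels=((6_010, -2),))
        call = _classify_seq(locus, template, window, _read_for(locus, spec))
        assert call.category == "unedited"

    def test_rejected_alignment_is_discarded_with_reason(self, locus, template, window):
        aln = align_read(locus.sequence[5650:6000], locus,
                         amplicon=locus.short_amplicon)
        call = classify_read(aln, template, window)
        assert call.category == "discarded"
        assert call.reason == "low_span"

    def test_window_must_be_inside_aligned_span(self, locus, template, pair):
        wide = QuantWindow(5_600, 6_400)  # wider than the amplicon
        aln = align_read(locus.sequence[5650:6350], locus,
                         amplicon=locus.short_amplicon)
        call = classify_read(aln, template, wide)
        assert call.category == "discarded"
        assert call.reason == "window_uncovered"

    def test_window_invariants(self, pair, template):
        w = QuantWindow.from_pair(pair)
        assert w.contains(pair.left.nick_position)
        assert w.contains(pair.right.nick_position)
        assert w.contains(template.correction.position)
        with pytest.raises(InputError):
            QuantWindow(100, 100)


class TestSummarize:
    def _calls(self, categories):
        return [
            ReadCall(f"r{i}", cat, {}, [], 1.0) for i, cat in enumerate(categories)
        ]

    def test_fractions_match_hand_counts_on_50_read_fixture(self):
        calls = self._calls(
            ["perfect_hdr"] * 20 + ["imperfect_hdr"] * 5 + ["indel"] * 10
            + ["unedited"] * 10 + ["discarded"] * 5
        )
        s = summarize(calls, min_reads=10)
        assert s.n_total == 50 and s.n_retained == 45
        assert s.fractions["perfect_hdr"] == pytest.approx(20 / 45)
        assert s.fractions["imperfect_hdr"] == pytest.approx(5 / 45)
        assert s.fractions["indel"] == pytest.approx(10 / 45)
        assert s.fractions["unedited"] == pytest.approx(10 / 45)
        assert s.total_editing == pytest.approx(35 / 45)
        assert sum(s.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_all_unedited_gives_zero_editing(self):
        s = summarize(self._calls(["unedited"] * 30), min_reads=10)
        assert s.fractions["perfect_hdr"] == 0.0
        assert s.total_editing == 0.0

    def test_low_coverage_flag_at_minimum_read_threshold(self):
        s = summarize(self._calls(["unedited"] * 9_999), min_reads=10_000)
        assert s.low_coverage
        s2 = summarize(self._calls(["unedited"] * 10_000), min_reads=10_000)
        assert not s2.low_coverage

    def test_empty_calls_rejected(self):
        with pytest.raises(InputError):
            summarize([])

    def test_wilson_interval_brackets_fraction(self):
        s = summarize(self._calls(["perfect_hdr"] * 30 + ["unedited"] * 70),
                      min_reads=10)
        lo, hi = s.confidence_intervals["perfect_hdr"]
        assert lo < 0.3 < hi


class TestSnvIncorporation:
    def test_all_perfect_reads_give_one(self, locus, template, window):
        spec = AlleleSpec(name="p", snvs=template.snvs)
        seq = _read_for(locus, spec)
        calls = [_classify_seq(locus, template, window, seq) for _ in range(5)]
        rates = snv_incorporation(calls, template)
        assert all(v == 1.0 for v in rates.values())

    def test_half_mixture_gives_half_incorporation(self, locus, template, window):
        mix = MixtureSpec(alleles=(
            AlleleSpec(name="p", snvs=template.snvs, weight=0.5),
            AlleleSpec(name="wt", weight=0.5),
        ))
        records, truth, _ = simulate_amplicon_reads(
            locus, mix, locus.short_amplicon, 3_000, NO_ERROR
        )
        alns = align_reads([(r[0], r[1]) for r in records], locus,
                           amplicon=locus.short_amplicon)
        calls = classify_reads(alns, template, window)
        rates = snv_incorporation(calls, template)
        expected = (truth.allele == "p").mean()
        for v in rates.values():
            assert abs(v - expected) < 1e-9  # error-free: exact recovery

    def test_gradient_mixture_preserves_monotone_ordering(
        self, locus, full_template, window
    ):
        # proximal bridging SNVs incorporated more often than the distal
        # blocking SNV, as in a conversion-tract gradient
        by_pos = sorted(full_template.snvs, key=lambda s: s.position)
        distal = by_pos[0]  # left blocking, furthest from the bridging nick
        alleles = (
            AlleleSpec(name="full", snvs=full_template.snvs, weight=0.4),
            AlleleSpec(
                name="partial",
                snvs=tuple(s for s in full_template.snvs if s is not distal),
                weight=0.3,
            ),
            AlleleSpec(name="wt", weight=0.3),
        )
        records, _, _ = simulate_amplicon_reads(
            locus, MixtureSpec(alleles=alleles), locus.short_amplicon, 2_000, NO_ERROR
        )
        alns = align_reads([(r[0], r[1]) for r in records], locus,
                           amplicon=locus.short_amplicon)
        calls = classify_reads(alns, full_template, window)
        rates = snv_incorporation(calls, full_template)
        assert rates[distal.position] < min(
            rates[s.position] for s in full_template.snvs if s is not distal
        )

    def test_uncovered_snv_reported_as_undefined(self, template):
        calls = [ReadCall("r0", "unedited",
                          {s.position: "uncovered" for s in template.snvs}, [], 1.0)]
        rates = snv_incorporation(calls, template)
        assert all(v is None for v in rates.values())

    def test_perfect_fraction_bounded_by_every_snv_rate(self, locus, template, window):
        mix, _ = demo.editing_outcome_mixture(locus, template)
        records, _, _ = simulate_amplicon_reads(
            locus, mix, locus.short_amplicon, 2_000, NO_ERROR
        )
        alns = align_reads([(r[0], r[1]) for r in records], locus,
                           amplicon=locus.short_amplicon)
        calls = classify_reads(alns, template, window)
        s = summarize(calls, min_reads=10, template=template)
        for rate in s.snv_incorporation_rates.values():
            assert s.fractions["perfect_hdr"] <= rate + 1e-9


class TestErrorRobustness:
    def test_substitution_noise_never_converts_unedited_to_indel(
        self, locus, template, window
    ):
        # indel calls require indel ops in the window; substitutions alone
        # cannot create them no matter the rate
        mix = MixtureSpec(alleles=(AlleleSpec(name="wt", weight=1.0),))
        for sub_rate in (0.02, 0.08):
            error = ErrorModel(sub_rate=sub_rate, ins_rate=0, del_rate=0, seed=6)
            records, _, _ = simulate_amplicon_reads(
                locus, mix, locus.short_amplicon, 300, error
            )
            alns = align_reads([(r[0], r[1]) for r in records], locus,
                               amplicon=locus.short_amplicon)
            calls = classify_reads(alns, template, window)
            assert all(c.category != "indel" for c in calls)

    def test_substitution_noise_never_converts_indel_to_unedited(
        self, locus, template, window
    ):
        mix = MixtureSpec(alleles=(
            AlleleSpec(name="d", indels=((6_020, -20),), weight=1.0),
        ))
        error = ErrorModel(sub_rate=0.05, ins_rate=0, del_rate=0, seed=6)
        records, _, _ = simulate_amplicon_reads(
            locus, mix, locus.short_amplicon, 300, error
        )
        alns = align_reads([(r[0], r[1]) for r in records], locus,
                           amplicon=locus.short_amplicon)
        calls = classify_reads(alns, template, window)
        retained = [c for c in calls if c.category != "discarded"]
        # indel evidence is never lost to 'unedited' under substitution
        # noise (rarely an ambiguous read drifts to imperfect instead)
        assert all(c.category != "unedited" for c in retained)
        assert sum(c.category == "indel" for c in retained) >= 0.98 * len(retained)

    def test_categories_are_exclusive_and_exhaustive(self, locus, template, window):
        mix, _ = demo.editing_outcome_mixture(locus, template)
        records, _, _ = simulate_amplicon_reads(
            locus, mix, locus.short_amplicon, 500, ErrorModel(seed=8)
        )
        alns = align_reads([(r[0], r[1]) for r in records], locus,
                           amplicon=locus.short_amplicon)
        calls = classify_reads(alns, template, window)
        s = summarize(calls, min_reads=10)
        assert sum(s.fractions.values()) == pytest.approx(1.0, abs=1e-9)
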