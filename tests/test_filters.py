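"""Somatic filter cascades: rule-by-rule behaviour and set properties."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmmltools import filters
from cmmltools.filters import (
    WesFilterConfig,
    WgsFilterConfig,
    apply_region_masks,
    consensus_combine,
    filter_wes_call,
    filter_wgs_call,
    presence_call,
)
from cmmltools.models import CandidateCall, RegionSet

from conftest import make_variant


def wes_call(somatic_p=5e-5, n_depth=50, n_alt=0, t_depth=50, t_alt=20,
             consequence="nonsynonymous", region="exonic", in_dbsnp=False):
    return CandidateCall(
        variant=make_variant(consequence=consequence, region=region),
        n_depth=n_depth, n_alt=n_alt, t_depth=t_depth, t_alt=t_alt,
        somatic_p=somatic_p, caller="varscan2", in_dbsnp=in_dbsnp,
    )


def wgs_call(caller="strelka", n_depth=20, n_alt=0, t_depth=30, t_alt=10,
             flags=(), ref="C", alt="T", **scores):
    scores.setdefault("qss" if caller == "strelka" else "somatic_score", 40)
    if caller == "varscan2":
        scores = {"somatic_p": scores.get("somatic_p", 1e-3)}
    return CandidateCall(
        variant=make_variant(ref=ref, alt=alt),
        n_depth=n_depth, n_alt=n_alt, t_depth=t_depth, t_alt=t_alt,
        caller=caller, filter_flags=frozenset(flags), **scores,
    )


class TestWesCascade:
    def test_clean_somatic_call_passes(self):
        assert filter_wes_call(wes_call(somatic_p=5e-5, t_alt=20, n_alt=0))

    def test_small_vaf_difference_is_germline_like(self):
        call = wes_call(t_alt=20, t_depth=100, n_alt=10, n_depth=100)
        decision = filter_wes_call(call)
        assert not decision and decision.reason == "vaf_diff"

    def test_threshold_relaxed_for_low_coverage_sample(self):
        call = wes_call(somatic_p=5e-4)
        assert not filter_wes_call(call, sample_mean_coverage=150)
        assert filter_wes_call(call, sample_mean_coverage=80)

    def test_threshold_relaxed_for_contaminated_control(self):
        call = wes_call(somatic_p=5e-4)
        assert filter_wes_call(call, contamination=0.20)

    def test_somatic_p_comparison_is_strict_below(self):
        at_threshold = wes_call(somatic_p=1e-4)
        assert not filter_wes_call(at_threshold, sample_mean_coverage=150)

    @pytest.mark.parametrize(
        "kwargs,reason",
        [
            (dict(in_dbsnp=True), "dbsnp"),
            (dict(region="intronic"), "region"),
            (dict(consequence="synonymous"), "synonymous"),
        ],
    )
    def test_annotation_drops_report_their_rule(self, kwargs, reason):
        decision = filter_wes_call(wes_call(**kwargs))
        assert not decision and decision.reason == reason

    def test_missing_somatic_p_is_an_error(self):
        call = wgs_call()  # no somatic_p on the strelka record
        with pytest.raises(ValueError):
            filter_wes_call(call)


class TestWgsCascade:
    def test_clean_consensus_call_passes(self):
        assert filter_wgs_call(wgs_call())

    @pytest.mark.parametrize(
        "kwargs,reason",
        [
            (dict(n_depth=10), "n_depth"),
            (dict(t_depth=5, t_alt=2), "t_depth"),
            (dict(t_alt=2), "alt_reads"),
            (dict(caller="somaticsniper", somatic_score=20), "somatic_score"),
            (dict(caller="varscan2", somatic_p=0.05), "somatic_p"),
            (dict(qss=10), "qss"),
            (dict(flags=("SpanDel",)), "filter_flag"),
            (dict(t_alt=9, t_depth=30, n_alt=12, n_depth=100), "vaf_diff"),
            (dict(n_alt=4, n_depth=20, t_alt=18, t_depth=30), "normal_vaf"),
        ],
    )
    def test_each_rule_rejects_with_its_reason(self, kwargs, reason):
        decision = filter_wgs_call(wgs_call(**kwargs))
        assert not decision and decision.reason == reason

    def test_indels_use_their_own_filter_exclusions(self):
        indel = wgs_call(ref="C", alt="CA", flags=("iHpol",))
        assert filter_wgs_call(indel).reason == "filter_flag"
        # iHpol is not an SNV exclusion
        snv = wgs_call(flags=("iHpol",))
        assert filter_wgs_call(snv)

    def test_absent_score_skips_the_score_rule(self):
        call = CandidateCall(
            variant=make_variant(), n_depth=20, n_alt=0,
            t_depth=30, t_alt=10, caller="strelka",
        )
        assert filter_wgs_call(call)

    def test_unknown_caller_is_an_error(self):
        call = CandidateCall(
            variant=make_variant(), n_depth=20, n_alt=0,
            t_depth=30, t_alt=10, caller="mutect",
        )
        with pytest.raises(ValueError):
            filter_wgs_call(call)


class TestPresence:
    @pytest.mark.parametrize(
        "t_alt,t_depth,expected",
        [(4, 100, True), (3, 100, False), (0, 50, False), (2, 50, True)],
    )
    def test_four_percent_floor_is_inclusive(self, t_alt, t_depth, expected):
        assert presence_call(t_alt, t_depth) is expected

    def test_zero_depth_is_an_error(self):
        with pytest.raises(ValueError):
            presence_call(0, 0)


class TestRegionMasks:
    def test_half_open_boundary_semantics(self):
        mask = RegionSet(name="m", intervals=[("chr1", 999, 1250)])
        inside = make_variant(pos=1100)
        boundary = make_variant(pos=1251)
        end_inclusive = make_variant(pos=1250)
        surviving, report = apply_region_masks(
            [inside, boundary, end_inclusive], [mask]
        )
        assert surviving == [boundary]
        assert report.mask_removed_fraction["m"] == pytest.approx(2 / 3)

    def test_empty_masks_are_identity(self):
        variants = [make_variant(pos=p) for p in (1, 2, 3)]
        surviving, _ = apply_region_masks(variants, [])
        assert surviving == variants

    def test_masked_fraction_recovered_on_uniform_variants(self, rng):
        # half-masked genome in 100-bp blocks; uniform placement
        length = 100_000
        blocks = [
            ("chr1", s, s + 100) for s in range(0, length, 200)
        ]
        mask = RegionSet(name="m", intervals=blocks)
        variants = [
            make_variant(pos=int(p) + 1, patient=f"P{i % 5}")
            for i, p in enumerate(rng.integers(0, length, size=4000))
        ]
        _, report = apply_region_masks(variants, [mask])
        frac = report.mask_removed_fraction["m"]
        assert frac == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / 4000))


class TestConsensus:
    def test_shared_variant_tagged_with_both_callers(self):
        a = wgs_call(caller="varscan2")
        b = wgs_call(caller="strelka")
        merged = consensus_combine({"varscan2": [a], "strelka": [b]})
        assert len(merged) == 1
        assert merged[0].callers == frozenset({"varscan2", "strelka"})

    def test_single_caller_variant_retained_in_union(self):
        indel = wgs_call(caller="strelka", ref="C", alt="CA")
        merged = consensus_combine({"strelka": [indel], "varscan2": []})
        assert len(merged) == 1 and merged[0].callers == frozenset({"strelka"})

    def test_intersection_switch_drops_singletons(self):
        a = wgs_call(caller="varscan2")
        only = wgs_call(caller="strelka", ref="C", alt="CA")
        b = wgs_call(caller="strelka")
        merged = consensus_combine(
            {"varscan2": [a], "strelka": [b, only]}, require_callers=2
        )
        assert len(merged) == 1 and merged[0].var_class == "SNV"

    def test_empty_inputs_give_empty_output(self):
        assert consensus_combine({"varscan2": [], "strelka": []}) == []

    def test_conflicting_var_class_is_an_error(self):
        v1 = CandidateCall(
            variant=make_variant(ref="C", alt="T"),
            n_depth=20, n_alt=0, t_depth=30, t_alt=10, caller="strelka",
        )
        v2 = CandidateCall(
            variant=make_variant(ref="C", alt="T", var_class=""),
            n_depth=20, n_alt=0, t_depth=30, t_alt=10, caller="varscan2",
        )
        object.__setattr__(v2.variant, "var_class", "insertion")
        with pytest.raises(ValueError):
            consensus_combine({"strelka": [v1], "varscan2": [v2]})

    def test_idempotent_and_order_invariant(self, rng):
        calls = [
            wgs_call(caller=c)
            for c in ("varscan2", "strelka", "somaticsniper")
        ]
        for c, pos in zip(calls, (5, 5, 9)):
            object.__setattr__(c.variant, "pos", pos)
        by_caller = {c.caller: [c] for c in calls}
        merged = consensus_combine(by_caller)
        shuffled = dict(reversed(list(by_caller.items())))
        assert consensus_combine(shuffled) == merged
        # feeding the merged result back in changes nothing
        again = consensus_combine(
            {"other": [
                CandidateCall(variant=v, n_depth=20, n_alt=0,
                              t_depth=30, t_alt=10, caller="other")
                for v in merged
            ]}
        )
        assert [v.key for v in again] == [v.key for v in merged]


class TestCascadeProperties:
    @staticmethod
    def random_calls(rng, n=120):
        calls = []
        callers = ("varscan2", "somaticsniper", "strelka")
        for i in range(n):
            t_depth = int(rng.integers(1, 80))
            n_depth = int(rng.integers(1, 80))
            calls.append(
                CandidateCall(
                    variant=make_variant(pos=int(rng.integers(1, 10_000))),
                    n_depth=n_depth, n_alt=int(rng.integers(0, n_depth + 1)),
                    t_depth=t_depth, t_alt=int(rng.integers(0, t_depth + 1)),
                    somatic_p=float(rng.uniform(0, 0.05)),
                    somatic_score=int(rng.integers(0, 80)),
                    qss=int(rng.integers(0, 60)),
                    caller=callers[i % 3],
                )
            )
        return calls

    @given(
        d_depth=st.integers(0, 10),
        d_vaf=st.floats(0, 0.2),
        d_score=st.integers(0, 20),
        seed=st.integers(0, 3),
    )
    @settings(max_examples=25, deadline=None)
    def test_tightening_thresholds_never_enlarges_surviving_set(
        self, d_depth, d_vaf, d_score, seed
    ):
        rng = np.random.default_rng(seed)
        calls = self.random_calls(rng)
        base = WgsFilterConfig()
        tighter = dataclasses.replace(
            base,
            min_n_depth=base.min_n_depth + d_depth,
            min_vaf_diff=min(0.99, base.min_vaf_diff + d_vaf),
            strelka_min_qss=base.strelka_min_qss + d_score,
        )
        keep_base = {
            id(c) for c in calls if filter_wgs_call(c, base)
        }
        keep_tight = {
            id(c) for c in calls if filter_wgs_call(c, tighter)
        }
        assert keep_tight <= keep_base

    def test_rejection_reasons_telescope(self, rng):
        calls = self.random_calls(rng, n=300)
        surviving, report = filters.filter_calls(
            calls, WgsFilterConfig(), mode="wgs"
        )
        assert sum(report.reason_counts.values()) == len(calls) - len(surviving)

    def test_planted_truth_survives_and_germline_does_not(self, small_cohort):
        """High-depth planted somatic variants pass the genome cascade at
        >= 95% sensitivity; germline-matched contaminants never pass."""
        cfg = WgsFilterConfig()
        germline_keys = {
            (r.patient_id, r.chrom, int(r.pos))
            for r in small_cohort.truth_genome.itertuples(index=False)
            if r.is_germline
        }
        n_true = n_pass = n_germ_pass = 0
        for caller, calls in small_cohort.wgs_calls_by_caller.items():
            for call in calls:
                v = call.variant
                is_germ = (v.patient_id, v.chrom, v.pos) in germline_keys
                passed = bool(filter_wgs_call(call, cfg))
                if is_germ:
                    n_germ_pass += passed
                elif call.t_depth >= 30 and call.n_depth >= 30:
                    n_true += 1
                    n_pass += passed
        assert n_germ_pass == 0
        assert n_pass / n_true >= 0.95
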