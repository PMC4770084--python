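"""Recurrence clustering, the uniform-placement null, regulatory census."""

import numpy as np
import pytest

from cmmltools.hotspots import (
    find_hotspots,
    null_probability,
    regulatory_census,
    simulate_null_clusters,
    simulate_null_window_occupancy,
)
from cmmltools.models import GeneModel, RegionSet
from cmmltools.simulate import CohortSimConfig, simulate_cohort

from conftest import make_variant


class TestFindHotspots:
    def test_two_patients_within_gap_form_a_cluster(self):
        variants = [
            make_variant(pos=100, patient="A"),
            make_variant(pos=300, patient="B"),
        ]
        clusters = find_hotspots(variants)
        assert len(clusters) == 1
        assert clusters[0].span == 200
        assert clusters[0].n_patients == 2

    def test_gap_above_threshold_breaks_the_chain(self):
        variants = [
            make_variant(pos=100, patient="A"),
            make_variant(pos=400, patient="B"),
        ]
        assert find_hotspots(variants) == []

    def test_single_patient_recurrence_is_not_a_hotspot(self):
        variants = [
            make_variant(pos=100, patient="A"),
            make_variant(pos=120, patient="A"),
        ]
        assert find_hotspots(variants) == []

    def test_chromosomes_never_mix(self):
        variants = [
            make_variant(chrom="chr1", pos=100, patient="A"),
            make_variant(chrom="chr2", pos=150, patient="B"),
        ]
        assert find_hotspots(variants) == []

    def test_gap_semantics_allow_long_chains(self):
        # adjacent gaps 200 each; total span 400 > 250 still one cluster
        variants = [
            make_variant(pos=100, patient="A"),
            make_variant(pos=300, patient="B"),
            make_variant(pos=500, patient="C"),
        ]
        clusters = find_hotspots(variants, mode="gap")
        assert len(clusters) == 1 and clusters[0].span == 400

    def test_span_semantics_bound_total_width(self):
        variants = [
            make_variant(pos=100, patient="A"),
            make_variant(pos=300, patient="B"),
            make_variant(pos=500, patient="C"),
        ]
        clusters = find_hotspots(variants, mode="span")
        # greedy left-to-right: [100, 300] spans 200 < 250; 500 left alone
        assert len(clusters) == 1
        assert clusters[0].span < 250

    def test_input_order_invariance(self, rng):
        variants = [
            make_variant(pos=int(p), patient=f"P{i % 6}")
            for i, p in enumerate(rng.integers(1, 50_000, size=120))
        ]
        a = find_hotspots(variants)
        b = find_hotspots([variants[i] for i in rng.permutation(120)])
        assert [(c.chrom, c.start, c.end) for c in a] == [
            (c.chrom, c.start, c.end) for c in b
        ]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_chaining_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        variants = [
            make_variant(
                chrom=("chr1", "chr2")[int(rng.integers(0, 2))],
                pos=int(p),
                patient=f"P{int(rng.integers(0, 8))}",
            )
            for p in rng.integers(1, 20_000, size=n)
        ]
        clusters = find_hotspots(variants)
        # O(n^2) oracle: transitive closure of the pairwise <=250 bp relation
        oracle = []
        for chrom in ("chr1", "chr2"):
            vs = sorted(
                (v for v in variants if v.chrom == chrom), key=lambda v: v.pos
            )
            used = [False] * len(vs)
            for i in range(len(vs)):
                if used[i]:
                    continue
                comp = {i}
                grew = True
                while grew:
                    grew = False
                    for a in list(comp):
                        for b in range(len(vs)):
                            if b not in comp and abs(vs[a].pos - vs[b].pos) <= 250:
                                comp.add(b)
                                grew = True
                for j in comp:
                    used[j] = True
                members = [vs[j] for j in sorted(comp)]
                if (
                    len(members) >= 2
                    and len({m.patient_id for m in members}) >= 2
                ):
                    oracle.append(
                        (chrom, members[0].pos, members[-1].pos, len(members))
                    )
        oracle.sort()
        got = sorted(
            (c.chrom, c.start, c.end, c.n_variants) for c in clusters
        )
        assert got == oracle

    def test_monotone_in_gap_and_patient_thresholds(self, rng):
        # widening the gap can merge clusters (so the count may drop) but
        # never removes a variant from clustered status; raising the
        # patient minimum never adds clusters
        variants = [
            make_variant(pos=int(p), patient=f"P{int(rng.integers(0, 5))}")
            for p in rng.integers(1, 30_000, size=150)
        ]
        clustered = [
            {
                v.pos
                for c in find_hotspots(variants, max_gap=g)
                for v in c.variants
            }
            for g in (50, 150, 300)
        ]
        assert clustered[0] <= clustered[1] <= clustered[2]
        n_pat = [
            len(find_hotspots(variants, min_patients=m)) for m in (2, 3, 4)
        ]
        assert n_pat == sorted(n_pat, reverse=True)


class TestNullModel:
    def test_no_variants_means_zero_probabilities(self):
        model = null_probability(0, n_windows=100, n_patients=5)
        assert model.p_window_ge2 == model.p_window_ge2_distinct == 0.0

    def test_one_window_two_patients_is_certain(self):
        model = null_probability(
            2, n_windows=1, n_patients=2, per_patient_counts=[1, 1]
        )
        assert model.p_window_ge2_distinct == pytest.approx(1.0)

    def test_poisson_identity_for_many_windows(self):
        model = null_probability(100, n_windows=1e8, n_patients=17)
        lam = model.lam
        poisson = 1 - np.exp(-lam) * (1 + lam)
        assert model.p_window_ge2 == pytest.approx(poisson, abs=1e-12)

    def test_zero_windows_is_an_error(self):
        with pytest.raises(ValueError):
            null_probability(10, n_windows=0)

    @pytest.mark.parametrize(
        "n_variants,n_windows", [(200, 5000), (500, 20_000)]
    )
    def test_analytic_matches_monte_carlo_within_3_se(
        self, n_variants, n_windows
    ):
        model = null_probability(n_variants, n_windows, n_patients=17)
        model = simulate_null_window_occupancy(model, reps=300, seed=2)
        assert abs(model.mc_estimate - model.p_window_ge2_distinct) <= (
            3 * model.mc_se
        )


class TestNullClusterSimulation:
    def test_seeded_replicates_are_reproducible(self):
        unmasked = RegionSet(name="u", intervals=[("chr1", 0, 100_000)])
        counts_a, _ = simulate_null_clusters(
            [30, 30, 30], unmasked, reps=5, seed=9
        )
        counts_b, _ = simulate_null_clusters(
            [30, 30, 30], unmasked, reps=5, seed=9
        )
        assert (counts_a == counts_b).all()

    def test_empty_unmasked_genome_is_an_error(self):
        with pytest.raises(ValueError):
            simulate_null_clusters([5], RegionSet(name="u", intervals=[]), reps=1)

    def test_exact_collision_rate_matches_closed_form(self):
        """With max_gap 0 a cluster is a position carrying >= 2 distinct
        patients: the expected count has a birthday-problem closed form,
        which is the per-window model at window size 1."""
        L = 2000
        per_patient = [40] * 5
        unmasked = RegionSet(name="u", intervals=[("chr1", 0, L)])
        reps = 400
        counts, _ = simulate_null_clusters(
            per_patient, unmasked, max_gap=0, reps=reps, seed=3
        )
        model = null_probability(
            sum(per_patient), n_windows=L, n_patients=5,
            per_patient_counts=per_patient,
        )
        expected = model.expected_clusters
        se = counts.std(ddof=1) / np.sqrt(reps)
        assert abs(counts.mean() - expected) <= 3 * se

    def test_planted_cluster_exceeds_null_99th_percentile(self):
        cfg = CohortSimConfig(
            seed=5,
            n_patients_wes=2,
            n_patients_wgs=10,
            genome_range=(2, 5),
            n_contigs=2,
            contig_length=5_000_000,
            n_germline_wgs=0,
            planted_hotspots=(
                ("chr1", None, 120, 4),
                ("chr2", None, 100, 3),
            ),
        )
        sim = simulate_cohort(cfg)
        somatic = [
            v
            for v, masked in zip(
                sim.genome_variants, sim.truth_genome.masked
            )
            if not masked
        ]
        observed = len(find_hotspots(somatic))
        truth_hot = sim.truth_genome[sim.truth_genome.hotspot_id >= 0]
        assert len(truth_hot) == 7  # both planted clusters are in the truth
        per_patient = (
            sim.truth_genome[~sim.truth_genome.is_germline]
            .groupby("patient_id")
            .size()
            .tolist()
        )
        _, null = simulate_null_clusters(
            per_patient, sim.genome.unmasked, reps=200, seed=6
        )
        assert observed > null.percentile(99)


class TestRegulatoryCensus:
    def _enhancers(self, activity):
        rs = RegionSet(
            name="enhancers", intervals=[("chr1", 20_000, 20_500)]
        )
        rs.activity = {0: activity}
        return rs

    def test_promoter_windows_strand_aware(self):
        genes = [
            GeneModel(gene="F", chrom="chr1", tss=10_000, strand="+",
                      body_start=10_000, body_end=12_000),
            GeneModel(gene="R", chrom="chr1", tss=10_100, strand="-",
                      body_start=9_000, body_end=10_100),
        ]
        variant = make_variant(pos=10_100)
        census = regulatory_census(
            [variant], genes, self._enhancers({"blood": 9, "monocytes": 9})
        )
        # pos 10,100 is inside the + gene's [8,000, 10,200] window and
        # inside the - gene's [9,900, 12,100] window
        assert {g for _, g in census.promoter_hits} == {"F", "R"}

    def test_upstream_variant_only_hits_plus_strand_window(self):
        genes = [
            GeneModel(gene="F", chrom="chr1", tss=10_000, strand="+",
                      body_start=10_000, body_end=12_000)
        ]
        enh = self._enhancers({"blood": 9, "monocytes": 9})
        hit = regulatory_census([make_variant(pos=8_000)], genes, enh)
        miss = regulatory_census([make_variant(pos=7_999)], genes, enh)
        assert hit.n_promoter_variants == 1
        assert miss.n_promoter_variants == 0

    def test_activity_must_reach_threshold_in_all_tissues(self):
        genes = [
            GeneModel(gene="F", chrom="chr1", tss=10_000, strand="+",
                      body_start=10_000, body_end=12_000)
        ]
        variant = make_variant(pos=20_100)
        permissive = regulatory_census(
            [variant], genes, self._enhancers({"blood": 6, "monocytes": 4})
        )
        assert permissive.n_enhancer_variants == 1
        assert permissive.n_active_enhancer_variants == 0
        active = regulatory_census(
            [variant], genes, self._enhancers({"blood": 6, "monocytes": 5})
        )
        assert active.n_active_enhancer_variants == 1

    def test_missing_activity_annotation_is_an_error(self):
        genes = [
            GeneModel(gene="F", chrom="chr1", tss=10_000, strand="+",
                      body_start=10_000, body_end=12_000)
        ]
        rs = RegionSet(name="enhancers", intervals=[("chr1", 20_000, 20_500)])
        with pytest.raises(ValueError, match="activity"):
            regulatory_census([make_variant(pos=20_100)], genes, rs)
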