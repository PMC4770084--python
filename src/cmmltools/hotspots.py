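"""Cross-patient recurrence hotspots and their uniform-placement null.

A hotspot is a run of somatic variants on one chromosome, contributed by
at least two distinct patients, in which consecutive variants are at most
250 bp apart (gap semantics, the default) or in which the whole run spans
fewer than 250 bp (span semantics).  The null model places the cohort's
variants uniformly over exchangeable 250-bp windows of the unmasked
genome and gives exact per-window probabilities of co-occurrence, plus a
Monte-Carlo placement simulation over an explicit mask for empirical
cluster-count distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .models import GeneModel, RegionSet, SomaticVariant


@dataclass
class HotspotCluster:
    """A multi-patient recurrence cluster of nearby variants."""

    chrom: str
    start: int  # 1-based position of the first member
    end: int  # 1-based position of the last member
    variants: list = field(default_factory=list)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_patients(self) -> int:
        return len({v.patient_id for v in self.variants})

    @property
    def span(self) -> int:
        return self.end - self.start


def find_hotspots(
    variants: Sequence[SomaticVariant],
    max_gap: int = 250,
    min_patients: int = 2,
    min_variants: int = 2,
    mode: str = "gap",
) -> List[HotspotCluster]:
    """Cluster cohort variants into recurrence hotspots.

    ``mode='gap'`` chains variants whose adjacent distance is <= max_gap
    (the chain's total span may exceed max_gap); ``mode='span'`` emits
    maximal greedy left-to-right groups whose total span is < max_gap.
    Output is independent of input order and sorted by (chrom, start).
    """
    if mode not in ("gap", "span"):
        raise ValueError(f"unknown clustering mode {mode!r}")
    by_chrom: Dict[str, List[SomaticVariant]] = {}
    for v in variants:
        by_chrom.setdefault(v.chrom, []).append(v)
    clusters: List[HotspotCluster] = []
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom], key=lambda v: (v.pos, v.ref, v.alt))
        if mode == "gap":
            runs = _chain_by_gap(members, max_gap)
        else:
            runs = _chain_by_span(members, max_gap)
        for run in runs:
            cluster = HotspotCluster(
                chrom=chrom, start=run[0].pos, end=run[-1].pos, variants=run
            )
            if (
                cluster.n_variants >= min_variants
                and cluster.n_patients >= min_patients
            ):
                clusters.append(cluster)
    return clusters


def _chain_by_gap(members, max_gap):
    runs, current = [], [members[0]]
    for v in members[1:]:
        if v.pos - current[-1].pos <= max_gap:
            current.append(v)
        else:
            runs.append(current)
            current = [v]
    runs.append(current)
    return runs


def _chain_by_span(members, max_span):
    runs, i = [], 0
    while i < len(members):
        j = i
        while j + 1 < len(members) and members[j + 1].pos - members[i].pos < max_span:
            j += 1
        runs.append(members[i : j + 1])
        i = j + 1
    return runs


@dataclass
class NullModel:
    """Exact per-window probabilities under uniform placement.

    N variants fall independently and uniformly into W exchangeable
    windows.  ``p_window_ge2_distinct`` additionally requires the >= 2
    variants in a window to come from >= 2 distinct patients, by
    inclusion-exclusion over per-patient counts.
    """

    n_variants: int
    n_windows: float
    n_patients: int
    window_size: int = 250
    lam: float = 0.0
    p_window_ge1: float = 0.0
    p_window_ge2: float = 0.0
    p_window_ge2_distinct: float = 0.0
    expected_clusters: float = 0.0
    p_any_window_ge2: float = 0.0
    mc_estimate: Optional[float] = None
    mc_se: Optional[float] = None


def null_probability(
    n_variants: int,
    n_windows: float = 6.82e6,
    n_patients: int = 17,
    per_patient_counts: Optional[Sequence[int]] = None,
    window_size: int = 250,
) -> NullModel:
    """Exact window-occupancy probabilities for uniform variant placement.

    Per-patient counts default to an equal split of ``n_variants`` over
    ``n_patients`` (remainder spread one-by-one).
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if n_variants < 0:
        raise ValueError("n_variants must be >= 0")
    W = float(n_windows)
    N = int(n_variants)
    model = NullModel(
        n_variants=N, n_windows=W, n_patients=n_patients, window_size=window_size
    )
    if N == 0:
        return model
    q = 1.0 - 1.0 / W  # P(one variant misses a fixed window)
    model.lam = N / W
    model.p_window_ge1 = 1.0 - q**N
    model.p_window_ge2 = 1.0 - q**N - N * (1.0 / W) * q ** (N - 1)
    if per_patient_counts is None:
        base, extra = divmod(N, n_patients)
        per_patient_counts = [
            base + (1 if i < extra else 0) for i in range(n_patients)
        ]
    elif sum(per_patient_counts) != N:
        raise ValueError("per-patient counts must sum to n_variants")
    q_i = np.array([q**ni for ni in per_patient_counts], dtype=float)
    q_all = float(np.prod(q_i))
    # P(window hit by >=2 distinct patients)
    #   = 1 - P(empty) - sum_i P(only patient i hits)
    only_one = float(
        sum(
            (1.0 - q_i[i]) * np.prod(np.delete(q_i, i))
            for i in range(len(q_i))
        )
    )
    model.p_window_ge2_distinct = max(0.0, 1.0 - q_all - only_one)
    model.expected_clusters = W * model.p_window_ge2_distinct
    model.p_any_window_ge2 = 1.0 - (1.0 - model.p_window_ge2_distinct) ** W
    return model


def simulate_null_window_occupancy(
    model: NullModel,
    reps: int = 1000,
    seed: int = 0,
    per_patient_counts: Optional[Sequence[int]] = None,
) -> NullModel:
    """Monte-Carlo check of ``p_window_ge2_distinct`` by direct placement.

    Each replicate throws every patient's variants uniformly into the W
    windows and counts windows hit by >= 2 distinct patients; the
    per-window rate estimate and its SE are attached to the model.
    """
    rng = np.random.default_rng(seed)
    W = int(model.n_windows)
    N = model.n_variants
    if per_patient_counts is None:
        base, extra = divmod(N, model.n_patients)
        per_patient_counts = [
            base + (1 if i < extra else 0) for i in range(model.n_patients)
        ]
    rates = np.empty(reps)
    for r in range(reps):
        patient_hits = np.zeros(W, dtype=np.int16)
        multi = np.zeros(W, dtype=bool)
        for ni in per_patient_counts:
            hit = np.unique(rng.integers(0, W, size=ni))
            multi[hit[patient_hits[hit] >= 1]] = True
            patient_hits[hit] += 1
        rates[r] = multi.sum() / W
    model.mc_estimate = float(rates.mean())
    model.mc_se = float(rates.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return model


def simulate_null_clusters(
    per_patient_counts: Sequence[int],
    unmasked: RegionSet,
    max_gap: int = 250,
    min_patients: int = 2,
    min_variants: int = 2,
    reps: int = 100,
    seed: int = 0,
    mode: str = "gap",
) -> Tuple[np.ndarray, "EmpiricalNull"]:
    """Empirical null distribution of hotspot counts.

    Variants are placed uniformly over the positions of ``unmasked``
    (the non-excluded genome), per-patient counts preserved, and
    ``find_hotspots`` is run per replicate.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    segments = [
        (chrom, start, end) for chrom, start, end, _, _ in unmasked.intervals
    ]
    lengths = np.array([end - start for _, start, end in segments], dtype=float)
    total = lengths.sum()
    if total <= 0:
        raise ValueError("unmasked genome is empty")
    probs = lengths / total
    rng = np.random.default_rng(seed)
    counts = np.empty(reps, dtype=int)
    for r in range(reps):
        variants = []
        for pi, n in enumerate(per_patient_counts):
            seg_idx = rng.choice(len(segments), size=n, p=probs)
            for si in seg_idx:
                chrom, start, end = segments[si]
                pos = int(rng.integers(start, end)) + 1  # to 1-based
                variants.append(
                    SomaticVariant(
                        chrom=chrom, pos=pos, ref="C", alt="T",
                        patient_id=f"sim{pi}",
                    )
                )
        counts[r] = len(
            find_hotspots(
                variants,
                max_gap=max_gap,
                min_patients=min_patients,
                min_variants=min_variants,
                mode=mode,
            )
        )
    return counts, EmpiricalNull(counts=counts)


@dataclass
class EmpiricalNull:
    counts: np.ndarray

    def empirical_p(self, observed: int) -> float:
        """P(null count >= observed), add-one corrected."""
        return (1 + int((self.counts >= observed).sum())) / (1 + len(self.counts))

    def percentile(self, pct: float) -> float:
        return float(np.percentile(self.counts, pct))


@dataclass
class RegulatoryCensus:
    """Variants falling in promoter windows and (active) enhancers."""

    promoter_hits: list = field(default_factory=list)  # (variant, gene)
    enhancer_hits: list = field(default_factory=list)  # variants
    active_enhancer_hits: list = field(default_factory=list)  # subset

    @property
    def n_promoter_variants(self) -> int:
        return len({v.key for v, _ in self.promoter_hits})

    @property
    def n_enhancer_variants(self) -> int:
        return len({v.key for v in self.enhancer_hits})

    @property
    def n_active_enhancer_variants(self) -> int:
        return len({v.key for v in self.active_enhancer_hits})


def regulatory_census(
    variants: Sequence[SomaticVariant],
    gene_models: Sequence[GeneModel],
    enhancers: RegionSet,
    promoter_up: int = 2000,
    promoter_down: int = 200,
    activity_min: float = 5.0,
    tissues: Sequence[str] = ("blood", "monocytes"),
) -> RegulatoryCensus:
    """Census of variants in promoters and permissive/active enhancers.

    Promoter windows run from ``promoter_up`` bp upstream to
    ``promoter_down`` bp downstream of each gene's anchor, strand-aware.
    An enhancer hit is active when the interval's activity is at least
    ``activity_min`` percent in every listed tissue; requesting activity
    on an enhancer set that carries none is an error.
    """
    census = RegulatoryCensus()
    windows = []
    for g in gene_models:
        lo, hi = g.promoter_window(promoter_up, promoter_down)
        windows.append((g.chrom, lo, hi, g))
    for v in variants:
        seen_genes = set()
        for chrom, lo, hi, g in windows:
            if v.chrom == chrom and lo <= v.pos <= hi and g.gene not in seen_genes:
                census.promoter_hits.append((v, g.gene))
                seen_genes.add(g.gene)
        idx = enhancers.hits(v.chrom, v.pos)
        if not idx:
            continue
        census.enhancer_hits.append(v)
        if tissues:
            active = False
            for i in idx:
                if i not in enhancers.activity:
                    raise ValueError(
                        f"enhancer interval {i} of {enhancers.name!r} carries "
                        "no activity annotation"
                    )
                act = enhancers.activity[i]
                if all(act.get(t, 0.0) >= activity_min for t in tissues):
                    active = True
            if active:
                census.active_enhancer_hits.append(v)
    return census
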