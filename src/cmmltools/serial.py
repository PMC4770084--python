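"""Serial-sample VAF trajectories, clone grouping and allele burden.

For each patient with two or more sequencing timepoints, the variant
universe is the union of somatic-passing variants over all timepoints;
read counts are looked up at every timepoint (a variant missing from a
timepoint's calls is assigned zero alt reads at that timepoint's median
depth, so losses remain countable).  Presence follows the 4% VAF floor.

A formal stability test -- Fisher's exact test on (alt, ref) read counts
between consecutive timepoints, BH-corrected per patient -- is this
module's addition on top of the descriptive trajectory classes and is
labelled as such in output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .filters import WesFilterConfig, presence_call
from .models import CandidateCall, SomaticVariant


@dataclass
class SerialTrajectory:
    """One variant's read counts, VAFs and presence across timepoints."""

    variant: SomaticVariant
    t_alt: list = field(default_factory=list)
    t_depth: list = field(default_factory=list)
    presence: list = field(default_factory=list)
    classification: str = "stable"
    event_timepoint: Optional[int] = None
    transition_p: list = field(default_factory=list)  # consecutive-pair Fisher p
    transition_q: list = field(default_factory=list)

    @property
    def vafs(self) -> List[float]:
        return [
            a / d if d > 0 else 0.0 for a, d in zip(self.t_alt, self.t_depth)
        ]

    @property
    def n_timepoints(self) -> int:
        return len(self.t_alt)

    @property
    def presence_bitmask(self) -> Tuple[bool, ...]:
        return tuple(self.presence)

    @property
    def delta_vaf(self) -> float:
        v = self.vafs
        return v[-1] - v[0]


def _classify(presence: Sequence[bool]) -> Tuple[str, Optional[int]]:
    """Stable / acquired(at t) / lost(at t) / fluctuating from presence."""
    if all(presence):
        return "stable", None
    if not any(presence):
        return "fluctuating", None  # never present: degenerate input
    first = presence.index(True)
    last = len(presence) - 1 - list(reversed(presence)).index(True)
    contiguous = all(presence[first : last + 1])
    if first == 0 and contiguous and last < len(presence) - 1:
        return "lost", last + 1
    if first > 0 and contiguous and last == len(presence) - 1:
        return "acquired", first
    return "fluctuating", None


def build_trajectories(
    calls_by_timepoint: Dict[int, Sequence[CandidateCall]],
    cfg: WesFilterConfig = WesFilterConfig(),
) -> List[SerialTrajectory]:
    """Assemble per-variant trajectories over a patient's timepoints.

    ``calls_by_timepoint`` maps ordinal timepoint to that sample's
    somatic-passing calls.  Requires >= 2 timepoints.
    """
    timepoints = sorted(calls_by_timepoint)
    if len(timepoints) < 2:
        raise ValueError("serial analysis requires at least two timepoints")
    counts: Dict[tuple, Dict[int, Tuple[int, int]]] = {}
    variants: Dict[tuple, SomaticVariant] = {}
    median_depth: Dict[int, int] = {}
    for t in timepoints:
        depths = [c.t_depth for c in calls_by_timepoint[t]]
        median_depth[t] = int(median(depths)) if depths else 0
        for c in calls_by_timepoint[t]:
            key = c.variant.key
            variants.setdefault(key, c.variant)
            counts.setdefault(key, {})[t] = (c.t_alt, c.t_depth)
    trajectories = []
    for key in sorted(variants):
        v = variants[key]
        traj = SerialTrajectory(variant=v)
        for t in timepoints:
            alt, depth = counts[key].get(t, (0, median_depth[t]))
            traj.t_alt.append(alt)
            traj.t_depth.append(depth)
            traj.presence.append(
                presence_call(alt, depth, cfg) if depth > 0 else False
            )
        traj.classification, traj.event_timepoint = _classify(traj.presence)
        for i in range(len(timepoints) - 1):
            table = [
                [traj.t_alt[i], traj.t_depth[i] - traj.t_alt[i]],
                [traj.t_alt[i + 1], traj.t_depth[i + 1] - traj.t_alt[i + 1]],
            ]
            traj.transition_p.append(float(fisher_exact(table)[1]))
        trajectories.append(traj)
    # BH across all transition tests of this patient
    flat = [p for traj in trajectories for p in traj.transition_p]
    if flat:
        q = multipletests(flat, method="fdr_bh")[1]
        i = 0
        for traj in trajectories:
            traj.transition_q = [float(x) for x in q[i : i + len(traj.transition_p)]]
            i += len(traj.transition_p)
    return trajectories


@dataclass
class CloneGroup:
    """Variants sharing a presence pattern and a common VAF trajectory."""

    members: list = field(default_factory=list)
    presence_bitmask: tuple = ()
    tier: str = "subclone"  # "founder" or "subclone"
    index: int = 0

    @property
    def mean_vafs(self) -> List[float]:
        arr = np.array([t.vafs for t in self.members], dtype=float)
        return list(arr.mean(axis=0))


def group_clones(
    trajectories: Sequence[SerialTrajectory],
    split_threshold: float = 0.10,
) -> List[CloneGroup]:
    """Partition one patient's trajectories into clone groups.

    Trajectories are grouped by identical presence bitmask and, within a
    bitmask, split when a member's VAF trajectory deviates from the
    group's mean trajectory by more than ``split_threshold`` (10 VAF
    points by default, above binomial noise at 100x depth) at any
    timepoint.  Splitting is recursive and two-sided around the group
    mean, so under pure read-count noise a homogeneous clone stays one
    group with an unbiased mean.  The founder is the
    all-timepoints-present group with the highest first-timepoint VAF.
    """
    by_mask: Dict[tuple, List[SerialTrajectory]] = {}
    for traj in trajectories:
        by_mask.setdefault(traj.presence_bitmask, []).append(traj)
    groups: List[CloneGroup] = []
    for mask in sorted(by_mask, reverse=True):
        members = sorted(by_mask[mask], key=lambda t: -np.mean(t.vafs))
        clusters = _split_by_trajectory(members, split_threshold)
        for cluster in _merge_clusters(clusters, split_threshold):
            groups.append(CloneGroup(members=cluster, presence_bitmask=mask))
    # founder: present everywhere, highest first-timepoint mean VAF.
    # Groups far smaller than the largest full-presence group (below half
    # its size) are not founder candidates: they are either late noise
    # split-offs or minor clones, never the founding clone.
    full = [g for g in groups if g.presence_bitmask and all(g.presence_bitmask)]
    if full:
        min_size = max(len(g.members) for g in full) / 2.0
        candidates = [g for g in full if len(g.members) >= min_size]
        founder = max(candidates, key=lambda g: g.mean_vafs[0])
        founder.tier = "founder"
    idx = 1
    for g in sorted(
        groups, key=lambda g: (-sum(g.presence_bitmask), -g.mean_vafs[0])
    ):
        if g.tier == "founder":
            g.index = 0
        else:
            g.index = idx
            idx += 1
    return groups


def _split_by_trajectory(
    members: List[SerialTrajectory], threshold: float
) -> List[List[SerialTrajectory]]:
    """Recursive mean-centred splitting of one presence-pattern cohort.

    Members within ``threshold`` of the cluster's mean trajectory at all
    timepoints stay together; deviants are split off (both directions)
    and re-clustered.  A deviation only counts when it also exceeds
    three binomial standard errors at that member's local depth, so that
    read-count noise alone cannot subdivide a clone.  When every member
    deviates -- two well-separated clones pulling the mean between them
    -- the cluster is bisected around its extreme members first.
    """
    if len(members) <= 1:
        return [list(members)]
    vafs = np.array([t.vafs for t in members], dtype=float)
    depths = np.array([t.t_depth for t in members], dtype=float)
    mean = vafs.mean(axis=0)
    noise_floor = 3.0 * np.sqrt(
        np.maximum(mean * (1.0 - mean), 1e-4)[None, :] / np.maximum(depths, 1.0)
    )
    exceeds = np.abs(vafs - mean) > np.maximum(threshold, noise_floor)
    core = ~exceeds.any(axis=1)
    if core.all():
        return [list(members)]
    if not core.any():
        # bisect around the extreme members (by overall mean VAF)
        overall = vafs.mean(axis=1)
        lo, hi = int(np.argmin(overall)), int(np.argmax(overall))
        d_lo = np.max(np.abs(vafs - vafs[lo]), axis=1)
        d_hi = np.max(np.abs(vafs - vafs[hi]), axis=1)
        left = [m for m, a, b in zip(members, d_lo, d_hi) if a <= b]
        right = [m for m, a, b in zip(members, d_lo, d_hi) if a > b]
        if not left or not right:  # degenerate; accept as one group
            return [list(members)]
        return _split_by_trajectory(left, threshold) + _split_by_trajectory(
            right, threshold
        )
    kept = [m for m, c in zip(members, core) if c]
    split = [m for m, c in zip(members, core) if not c]
    return _split_by_trajectory(kept, threshold) + _split_by_trajectory(
        split, threshold
    )


def _merge_clusters(
    clusters: List[List[SerialTrajectory]], threshold: float
) -> List[List[SerialTrajectory]]:
    """Re-merge clusters whose mean trajectories agree within threshold.

    The recursive split can strand a clone's extreme members in their
    own small cluster; if that cluster's mean sits within the threshold
    of another cluster's mean at every timepoint they are one clone.
    Closest pairs merge first; repeats until stable.
    """
    clusters = [list(c) for c in clusters]
    while len(clusters) > 1:
        means = [
            np.array([t.vafs for t in c], dtype=float).mean(axis=0)
            for c in clusters
        ]
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                gap = float(np.max(np.abs(means[i] - means[j])))
                if gap <= threshold and (best is None or gap < best[0]):
                    best = (gap, i, j)
        if best is None:
            break
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return clusters


@dataclass
class BurdenSummary:
    """Change in founding-clone allele burden between first and last WES."""

    patient: str
    arm: str
    delta_vafs: list = field(default_factory=list)
    mean_delta: float = 0.0
    ci_low: float = 0.0
    ci_high: float = 0.0
    verdict: str = "unchanged"
    low_confidence: bool = False
    n_acquired: int = 0
    n_lost: int = 0


def burden_change(
    trajectories: Sequence[SerialTrajectory],
    patient: str = "",
    treatment_arm: str = "untreated",
    n_boot: int = 2000,
    seed: int = 0,
    groups: Optional[Sequence[CloneGroup]] = None,
) -> BurdenSummary:
    """Mutated-allele-burden verdict from founder-variant VAF changes.

    The change per founder variant is last-minus-first VAF; the verdict
    is "unchanged" when the bootstrap 95% CI of the mean (resampling
    variants) contains zero.  The studentized bootstrap (bootstrap-t)
    interval is used: a founder clone typically carries only 5-20
    variants with depth-dependent, heavy-tailed VAF noise, and the plain
    percentile interval undercovers there, while studentizing each
    resample restores near-nominal coverage.  Fewer than two founder
    variants leaves the verdict flagged low-confidence.
    """
    if groups is None:
        groups = group_clones(trajectories)
    founder = next((g for g in groups if g.tier == "founder"), None)
    founder_members = founder.members if founder else []
    deltas = np.array([t.delta_vaf for t in founder_members], dtype=float)
    summary = BurdenSummary(
        patient=patient,
        arm=treatment_arm,
        delta_vafs=[float(d) for d in deltas],
        n_acquired=sum(1 for t in trajectories if t.classification == "acquired"),
        n_lost=sum(1 for t in trajectories if t.classification == "lost"),
    )
    if deltas.size == 0:
        summary.low_confidence = True
        return summary
    summary.mean_delta = float(deltas.mean())
    if deltas.size < 2:
        summary.low_confidence = True
        summary.ci_low = summary.ci_high = summary.mean_delta
        summary.verdict = "unchanged" if summary.mean_delta == 0 else "changed"
        return summary
    rng = np.random.default_rng(seed)
    n = deltas.size
    mean = deltas.mean()
    se = deltas.std(ddof=1) / np.sqrt(n)
    idx = rng.integers(0, n, size=(n_boot, n))
    samples = deltas[idx]
    boot_se = samples.std(axis=1, ddof=1) / np.sqrt(n)
    boot_se[boot_se == 0] = max(se, 1e-12)
    t_stats = (samples.mean(axis=1) - mean) / boot_se
    q_low, q_high = np.percentile(t_stats, [2.5, 97.5])
    summary.ci_low = float(mean - q_high * se)
    summary.ci_high = float(mean - q_low * se)
    summary.verdict = (
        "unchanged" if summary.ci_low <= 0.0 <= summary.ci_high else "changed"
    )
    return summary
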