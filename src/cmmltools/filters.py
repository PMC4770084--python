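"""Tumour-normal somatic filter cascades.

Two cascades are provided:

* the exome-style cascade (single caller): a somatic p-value threshold of
  1e-4, relaxed to 1e-3 for low-coverage (<100x mean) or contaminated
  (>15% in the lymphocyte control) samples, a tumour-minus-normal VAF
  difference of at least 15%, and annotation-based drops (dbSNP members,
  intergenic/intronic/UTR/ncRNA variants, synonymous SNVs);
* the genome-style cascade (three-caller consensus): depth and
  alt-support minima (15x normal, 6x tumour, 3 alt reads), one
  caller-specific score rule each for SomaticSniper (score >= 30),
  VarScan2 (somatic p <= 0.01) and Strelka (QSS/QSI >= 15), FILTER-flag
  exclusions, a VAF difference of at least 20% and a normal VAF below 15%.

Comparison operators follow each rule's original phrasing: the exome
somatic p-value rule is strict ("below"), the others are inclusive.
Rejections carry the first failing rule's name so that per-reason counts
telescope to the total removed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .models import CandidateCall, RegionSet, SomaticVariant

KNOWN_CALLERS = ("varscan2", "somaticsniper", "strelka", "other")


@dataclass
class WesFilterConfig:
    """Thresholds of the exome-style single-caller cascade."""

    somatic_p_max: float = 1e-4
    somatic_p_max_relaxed: float = 1e-3
    relax_if_mean_coverage_below: float = 100.0
    relax_if_contamination_above: float = 0.15
    min_vaf_diff: float = 0.15
    min_base_quality: int = 20  # documented; applied upstream of calling
    presence_vaf: float = 0.04
    drop_regions: frozenset = frozenset(
        {"intergenic", "intronic", "UTR3", "UTR5", "UTR", "ncRNA"}
    )
    drop_synonymous: bool = True
    drop_dbsnp: bool = True

    def __post_init__(self) -> None:
        for p in (self.somatic_p_max, self.somatic_p_max_relaxed, self.presence_vaf):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0.0 < self.min_vaf_diff < 1.0:
            raise ValueError("min_vaf_diff must lie in (0, 1)")
        self.drop_regions = frozenset(self.drop_regions)


@dataclass
class WgsFilterConfig:
    """Thresholds of the genome-style three-caller cascade."""

    min_n_depth: int = 15
    min_t_depth: int = 6
    min_alt_reads: int = 3
    somaticsniper_min_score: int = 30
    varscan_somatic_p_max: float = 0.01
    strelka_min_qss: int = 15
    min_vaf_diff: float = 0.20
    max_normal_vaf: float = 0.15
    snv_excluded_filters: frozenset = frozenset({"SpanDel", "BCNoise", "DP"})
    indel_excluded_filters: frozenset = frozenset(
        {"OVERLAP", "Repeat", "iHpol", "BCNoise", "DP"}
    )
    masks: tuple = ("low_complexity_mask", "immunoglobulin_loci", "blacklist_genes")

    def __post_init__(self) -> None:
        for v in (
            self.min_n_depth, self.min_t_depth, self.min_alt_reads,
            self.somaticsniper_min_score, self.strelka_min_qss,
        ):
            if v < 0:
                raise ValueError("depths and scores must be nonnegative")
        self.snv_excluded_filters = frozenset(self.snv_excluded_filters)
        self.indel_excluded_filters = frozenset(self.indel_excluded_filters)


@dataclass
class Decision:
    """Outcome of one filter rule cascade for one call."""

    passed: bool
    reason: Optional[str] = None  # first failing rule when rejected

    def __bool__(self) -> bool:
        return self.passed


SOMATIC = Decision(True)


@dataclass
class FilterReport:
    """Telescoping per-stage counts plus per-mask removal fractions."""

    stages: list = field(default_factory=list)  # (stage, n_in, n_out, n_removed)
    mask_removed_fraction: dict = field(default_factory=dict)
    reason_counts: Counter = field(default_factory=Counter)

    def add_stage(self, stage: str, n_in: int, n_out: int) -> None:
        self.stages.append((stage, n_in, n_out, n_in - n_out))

    def check(self) -> None:
        for stage, n_in, n_out, n_removed in self.stages:
            assert n_in == n_out + n_removed, stage


def filter_wes_call(
    call: CandidateCall,
    cfg: WesFilterConfig = WesFilterConfig(),
    sample_mean_coverage: float = float("inf"),
    contamination: float = 0.0,
) -> Decision:
    """Exome-style somatic decision for one candidate call.

    The somatic p-value is mandatory on this path; the threshold is
    relaxed when the sample's mean coverage is below 100x or the control
    contamination exceeds 15%.
    """
    if call.somatic_p is None:
        raise ValueError("exome-style filtering requires a somatic p-value")
    if call.vaf_t is None or call.vaf_n is None:
        raise ValueError("exome-style filtering requires both VAFs computable")
    relaxed = (
        sample_mean_coverage < cfg.relax_if_mean_coverage_below
        or contamination > cfg.relax_if_contamination_above
    )
    threshold = cfg.somatic_p_max_relaxed if relaxed else cfg.somatic_p_max
    if not call.somatic_p < threshold:
        return Decision(False, "somatic_p")
    if call.vaf_t - call.vaf_n < cfg.min_vaf_diff:
        return Decision(False, "vaf_diff")
    if cfg.drop_dbsnp and call.in_dbsnp:
        return Decision(False, "dbsnp")
    region = call.variant.region
    if region is not None and region in cfg.drop_regions:
        return Decision(False, "region")
    if cfg.drop_synonymous and call.variant.consequence == "synonymous":
        return Decision(False, "synonymous")
    return SOMATIC


def filter_wgs_call(
    call: CandidateCall, cfg: WgsFilterConfig = WgsFilterConfig()
) -> Decision:
    """Genome-style decision for one candidate call of one caller.

    A score rule whose field is absent from the record is skipped rather
    than failed (callers do not all emit every score).
    """
    caller = call.caller
    if caller not in KNOWN_CALLERS:
        raise ValueError(f"unknown caller label {caller!r}")
    if call.n_depth < cfg.min_n_depth:
        return Decision(False, "n_depth")
    if call.t_depth < cfg.min_t_depth:
        return Decision(False, "t_depth")
    if call.t_alt < cfg.min_alt_reads:
        return Decision(False, "alt_reads")
    if caller == "somaticsniper" and call.somatic_score is not None:
        if call.somatic_score < cfg.somaticsniper_min_score:
            return Decision(False, "somatic_score")
    if caller == "varscan2" and call.somatic_p is not None:
        if call.somatic_p > cfg.varscan_somatic_p_max:
            return Decision(False, "somatic_p")
    if caller == "strelka" and call.qss is not None:
        if call.qss < cfg.strelka_min_qss:
            return Decision(False, "qss")
    excluded = (
        cfg.snv_excluded_filters
        if call.variant.is_snv
        else cfg.indel_excluded_filters
    )
    if call.filter_flags & excluded:
        return Decision(False, "filter_flag")
    vaf_t = call.vaf_t if call.vaf_t is not None else 0.0
    vaf_n = call.vaf_n if call.vaf_n is not None else 0.0
    if vaf_t - vaf_n < cfg.min_vaf_diff:
        return Decision(False, "vaf_diff")
    if vaf_n >= cfg.max_normal_vaf:
        return Decision(False, "normal_vaf")
    return SOMATIC


def filter_calls(
    calls: Iterable[CandidateCall],
    cfg,
    mode: str = "wgs",
    **kwargs,
) -> Tuple[List[CandidateCall], FilterReport]:
    """Run one cascade over a call list, collecting a telescoping report."""
    decide = filter_wes_call if mode == "wes" else filter_wgs_call
    surviving: List[CandidateCall] = []
    report = FilterReport()
    calls = list(calls)
    for call in calls:
        decision = decide(call, cfg, **kwargs)
        if decision:
            surviving.append(call)
        else:
            report.reason_counts[decision.reason] += 1
    report.add_stage(f"{mode}_cascade", len(calls), len(surviving))
    report.check()
    return surviving, report


def apply_region_masks(
    variants: Sequence[SomaticVariant], masks: Sequence[RegionSet]
) -> Tuple[List[SomaticVariant], FilterReport]:
    """Drop variants whose anchor position lies inside any mask interval.

    The report records, per mask, the fraction of the *input* variants
    covered by that mask (a variant inside several masks counts for each).
    """
    report = FilterReport()
    variants = list(variants)
    n_in = len(variants)
    surviving = []
    removed_by_mask: Counter = Counter()
    for v in variants:
        hit = False
        for mask in masks:
            if mask.contains(v.chrom, v.pos):
                removed_by_mask[mask.name] += 1
                hit = True
        if not hit:
            surviving.append(v)
    report.add_stage("region_masks", n_in, len(surviving))
    for mask in masks:
        report.mask_removed_fraction[mask.name] = (
            removed_by_mask[mask.name] / n_in if n_in else 0.0
        )
    report.check()
    return surviving, report


def consensus_combine(
    calls_by_caller: Mapping[str, Sequence[CandidateCall]],
    require_callers: int = 1,
) -> List[SomaticVariant]:
    """Merge per-caller passing calls into one deduplicated variant list.

    Variants are keyed by (chrom, pos, ref, alt) and tagged with the set
    of callers that reported them; ``require_callers`` switches from the
    default union to an n-caller intersection.  Output order is
    (chrom, pos, alt), independent of input order.
    """
    merged: Dict[tuple, SomaticVariant] = {}
    supporters: Dict[tuple, set] = {}
    for caller in sorted(calls_by_caller):
        for call in calls_by_caller[caller]:
            v = call.variant
            key = v.key
            if key in merged:
                if merged[key].var_class != v.var_class:
                    raise ValueError(
                        f"conflicting var_class for {key}: "
                        f"{merged[key].var_class} vs {v.var_class}"
                    )
            else:
                merged[key] = v
            supporters.setdefault(key, set()).add(caller)
    out = []
    for key in sorted(merged, key=lambda k: (k[0], k[1], k[3])):
        if len(supporters[key]) < require_callers:
            continue
        v = merged[key]
        out.append(
            SomaticVariant(
                chrom=v.chrom, pos=v.pos, ref=v.ref, alt=v.alt,
                patient_id=v.patient_id, sample_id=v.sample_id,
                timepoint=v.timepoint, var_class=v.var_class,
                consequence=v.consequence, region=v.region, gene=v.gene,
                callers=frozenset(supporters[key]),
            )
        )
    return out


def presence_call(
    t_alt: int, t_depth: int, cfg: WesFilterConfig = WesFilterConfig()
) -> bool:
    """Serial-sample presence rule: present iff VAF >= the 4% floor."""
    if t_depth <= 0:
        raise ValueError("presence call requires t_depth > 0")
    return t_alt / t_depth >= cfg.presence_vaf
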