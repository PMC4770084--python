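"""Synthetic cohorts emulating the study's statistical structure.

The generators fabricate, at desk scale, the inputs every other stage
consumes: an exome-style cohort of patients carrying a founder clone
plus 0-3 subclones of coding mutations, a genome-style cohort with
variants placed uniformly over a miniature masked genome (optionally
with planted recurrence hotspots), paired-timepoint bisulfite tiles
with responder-profile (predominantly demethylating) or stable-profile
changes, and arm-structured differential-expression gene lists.

Every generator draws all randomness from one seeded generator and
emits a machine-readable truth table; downstream recovery tests read
the truth, never re-derive it.  Variants are heterozygous diploid
(VAF = clone fraction / 2); copy-number events are not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .integration import DEGeneList
from .models import CandidateCall, MethTile, RegionSet, SomaticVariant
from .spectrum import CHANNELS_96, ContextMatrix

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {
    "A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G"),
}


@dataclass
class CohortSimConfig:
    """Study-shaped defaults for the variant-cohort generator.

    The exome arm emulates 49 patients with 14 +/- 5 coding mutations
    each (truncated to 4-23, 73.3% transitions, 75.7% nonsynonymous
    overall); the genome arm emulates 17 patients with 27-854 variants
    each (66.3% transitions among SNVs, 6.3% indels) thrown uniformly
    over a miniature genome of which 45% is masked.
    """

    seed: int = 0
    # exome-style cohort
    n_patients_wes: int = 49
    coding_mean: float = 14.0
    coding_sd: float = 5.0
    coding_range: Tuple[int, int] = (4, 23)
    coding_indel_prob: float = 62 / 680  # non-SNV share of validated coding set
    transition_prob_coding: float = 453 / 618
    snv_consequence_probs: tuple = (
        ("nonsynonymous", 0.833), ("stopgain", 0.088),
        ("splice", 0.044), ("synonymous", 0.035),
    )
    wes_depth_mean: float = 100.0
    n_timepoints: int = 2
    arms: Tuple[str, ...] = ("untreated", "responder", "stable_disease")
    founder_fraction: float = 0.9
    max_subclones: int = 3
    subclone_acquire_prob: float = 0.3
    n_germline: int = 20
    # genome-style cohort
    n_patients_wgs: int = 17
    genome_range: Tuple[int, int] = (27, 854)
    genome_indel_prob: float = 0.063
    transition_prob_genome: float = 0.663
    region_probs: tuple = (
        ("intergenic", 0.635), ("intronic", 0.315), ("exonic", 0.05),
    )
    wgs_depth_mean: float = 30.0
    n_germline_wgs: int = 50
    # miniature genome
    n_contigs: int = 5
    contig_length: int = 10_000_000
    masked_fraction: float = 0.45
    mask_block: int = 50_000
    depth_dispersion: float = 10.0  # negative-binomial shape
    # (chrom, pos, width, n_patients); pos None -> random unmasked locus
    planted_hotspots: tuple = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.founder_fraction <= 1.0:
            raise ValueError("founder_fraction must lie in (0, 1]")
        if not 0.0 <= self.masked_fraction < 1.0:
            raise ValueError("masked_fraction must lie in [0, 1)")


def _nb_depth(rng: np.random.Generator, mean: float, shape: float, size=None):
    p = shape / (shape + mean)
    return np.maximum(1, rng.negative_binomial(shape, p, size=size))


def _truncnorm_int(rng, mean, sd, lo, hi):
    while True:
        x = int(round(rng.normal(mean, sd)))
        if lo <= x <= hi:
            return x


class MiniGenome:
    """Seeded random reference with a block mask covering a set fraction."""

    def __init__(self, cfg: CohortSimConfig, rng: np.random.Generator):
        self.contigs = {
            f"chr{i + 1}": cfg.contig_length for i in range(cfg.n_contigs)
        }
        self.sequences = {
            c: rng.integers(0, 4, size=n, dtype=np.uint8)
            for c, n in self.contigs.items()
        }
        masked, unmasked = [], []
        for chrom, length in self.contigs.items():
            n_blocks = length // cfg.mask_block
            n_masked = int(round(n_blocks * cfg.masked_fraction))
            masked_idx = set(
                rng.choice(n_blocks, size=n_masked, replace=False).tolist()
            )
            for b in range(n_blocks):
                start = b * cfg.mask_block
                end = min(length, start + cfg.mask_block)
                (masked if b in masked_idx else unmasked).append(
                    (chrom, start, end)
                )
        self.mask = RegionSet(name="low_complexity_mask", intervals=masked)
        self.unmasked = RegionSet(name="unmasked", intervals=unmasked)

    @property
    def total_length(self) -> int:
        return sum(self.contigs.values())

    def base(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return chr(_BASES[self.sequences[chrom][pos - 1]])

    def random_position(self, rng: np.random.Generator) -> Tuple[str, int]:
        """Uniform 1-based position over the whole genome (mask included)."""
        offset = int(rng.integers(0, self.total_length))
        for chrom, length in self.contigs.items():
            if offset < length:
                return chrom, min(offset + 1, length - 1) or 1
            offset -= length
        raise AssertionError("unreachable")

    def random_unmasked_position(self, rng: np.random.Generator) -> Tuple[str, int]:
        ivs = self.unmasked.intervals
        lengths = np.array([iv[2] - iv[1] for iv in ivs], dtype=float)
        i = int(rng.choice(len(ivs), p=lengths / lengths.sum()))
        chrom, start, end = ivs[i][0], ivs[i][1], ivs[i][2]
        return chrom, int(rng.integers(start, end)) + 1

    def write_fasta(self, path: str, line: int = 70) -> None:
        with open(path, "w") as fh:
            for chrom, seq in self.sequences.items():
                fh.write(f">{chrom}\n")
                text = _BASES[seq].tobytes().decode()
                for i in range(0, len(text), line):
                    fh.write(text[i : i + line] + "\n")


def _draw_substitution(rng, ref: str, transition_prob: float) -> str:
    if rng.random() < transition_prob:
        return _TRANSITION[ref]
    return _TRANSVERSIONS[ref][int(rng.integers(0, 2))]


@dataclass
class CohortSim:
    """Output bundle of :func:`simulate_cohort`."""

    cfg: CohortSimConfig
    genome: MiniGenome
    arms: Dict[str, str]
    wes_calls: Dict[str, Dict[int, List[CandidateCall]]]
    truth_coding: pd.DataFrame
    wgs_calls_by_caller: Dict[str, List[CandidateCall]]
    genome_variants: List[SomaticVariant]
    truth_genome: pd.DataFrame

    @property
    def coding_variants(self) -> List[SomaticVariant]:
        """True somatic coding variants, one record per patient-variant."""
        out = []
        for patient in sorted(self.wes_calls):
            seen = set()
            for t in sorted(self.wes_calls[patient]):
                for call in self.wes_calls[patient][t]:
                    key = call.variant.key
                    if key not in seen and not call.in_dbsnp:
                        seen.add(key)
        # truth is authoritative: rebuild from the truth table
        for row in self.truth_coding.itertuples(index=False):
            if row.is_germline:
                continue
            out.append(
                SomaticVariant(
                    chrom=row.chrom, pos=int(row.pos), ref=row.ref,
                    alt=row.alt, patient_id=row.patient_id,
                    consequence=row.consequence, region="exonic",
                )
            )
        return out


def simulate_cohort(cfg: CohortSimConfig = CohortSimConfig()) -> CohortSim:
    """Generate the exome- and genome-style synthetic cohorts.

    Exome arm: per patient, a truncated-normal number of coding
    mutations split between a founder clone (fraction 0.9, VAF 0.45)
    and 0-3 subclones; serial read counts are Binomial(depth, VAF(t))
    at negative-binomially distributed depths, with subclones either
    present throughout or acquired at a later timepoint.  Germline
    contaminants with matched tumour/normal VAFs are planted alongside.

    Genome arm: per patient, a uniform number of clonal variants thrown
    uniformly over the miniature genome (45% of which is masked), each
    reported by all three callers with passing-range scores; planted
    hotspot variants are placed in unmasked regions.
    """
    rng = np.random.default_rng(cfg.seed)
    genome = MiniGenome(cfg, rng)
    arms: Dict[str, str] = {}
    wes_calls: Dict[str, Dict[int, List[CandidateCall]]] = {}
    coding_rows = []
    snv_labels = [c for c, _ in cfg.snv_consequence_probs]
    snv_p = np.array([p for _, p in cfg.snv_consequence_probs])
    snv_p = snv_p / snv_p.sum()
    for i in range(cfg.n_patients_wes):
        patient = f"P{i + 1:03d}"
        arms[patient] = cfg.arms[i % len(cfg.arms)]
        n_coding = _truncnorm_int(
            rng, cfg.coding_mean, cfg.coding_sd, *cfg.coding_range
        )
        n_sub = int(rng.integers(0, cfg.max_subclones + 1))
        sub_fracs = rng.uniform(0.1, cfg.founder_fraction, size=n_sub)
        sub_acq = [
            int(rng.integers(1, cfg.n_timepoints))
            if cfg.n_timepoints > 1 and rng.random() < cfg.subclone_acquire_prob
            else 0
            for _ in range(n_sub)
        ]
        clones = [("founder", cfg.founder_fraction, 0)] + [
            (f"subclone{s + 1}", float(sub_fracs[s]), sub_acq[s])
            for s in range(n_sub)
        ]
        per_t: Dict[int, List[CandidateCall]] = {
            t: [] for t in range(cfg.n_timepoints)
        }
        for _ in range(n_coding):
            chrom, pos = genome.random_position(rng)
            ref = genome.base(chrom, pos)
            is_indel = rng.random() < cfg.coding_indel_prob
            if is_indel:
                if rng.random() < 0.5:
                    alt = ref + chr(_BASES[rng.integers(0, 4)])
                else:
                    nxt = genome.base(chrom, min(pos + 1, genome.contigs[chrom]))
                    ref, alt = ref + nxt, ref
                consequence = "frameshift"
            else:
                alt = _draw_substitution(rng, ref, cfg.transition_prob_coding)
                consequence = snv_labels[int(rng.choice(len(snv_labels), p=snv_p))]
            ci = int(rng.integers(0, len(clones)))
            clone, frac, acq = clones[ci]
            coding_rows.append(
                {
                    "patient_id": patient, "chrom": chrom, "pos": pos,
                    "ref": ref, "alt": alt, "consequence": consequence,
                    "clone": clone, "clone_fraction": frac,
                    "acquired_at": acq, "is_germline": False,
                }
            )
            for t in range(cfg.n_timepoints):
                vaf = frac / 2.0 if t >= acq else 0.0
                t_depth = int(_nb_depth(rng, cfg.wes_depth_mean, cfg.depth_dispersion))
                t_alt = int(rng.binomial(t_depth, vaf)) if vaf > 0 else 0
                n_depth = int(_nb_depth(rng, cfg.wes_depth_mean, cfg.depth_dispersion))
                n_alt = int(rng.binomial(n_depth, 0.001))
                somatic_p = (
                    float(rng.uniform(0, 1e-5))
                    if vaf > 0
                    else float(rng.uniform(0.5, 1.0))
                )
                per_t[t].append(
                    CandidateCall(
                        variant=SomaticVariant(
                            chrom=chrom, pos=pos, ref=ref, alt=alt,
                            patient_id=patient, timepoint=t,
                            consequence=consequence, region="exonic",
                        ),
                        n_depth=n_depth, n_alt=n_alt,
                        t_depth=t_depth, t_alt=t_alt,
                        somatic_p=somatic_p, caller="varscan2",
                    )
                )
        for _ in range(cfg.n_germline):
            chrom, pos = genome.random_position(rng)
            ref = genome.base(chrom, pos)
            alt = _draw_substitution(rng, ref, 0.7)
            coding_rows.append(
                {
                    "patient_id": patient, "chrom": chrom, "pos": pos,
                    "ref": ref, "alt": alt, "consequence": "nonsynonymous",
                    "clone": "germline", "clone_fraction": 1.0,
                    "acquired_at": 0, "is_germline": True,
                }
            )
            for t in range(cfg.n_timepoints):
                t_depth = int(_nb_depth(rng, cfg.wes_depth_mean, cfg.depth_dispersion))
                n_depth = int(_nb_depth(rng, cfg.wes_depth_mean, cfg.depth_dispersion))
                per_t[t].append(
                    CandidateCall(
                        variant=SomaticVariant(
                            chrom=chrom, pos=pos, ref=ref, alt=alt,
                            patient_id=patient, timepoint=t,
                            consequence="nonsynonymous", region="exonic",
                        ),
                        n_depth=n_depth,
                        n_alt=int(rng.binomial(n_depth, 0.5)),
                        t_depth=t_depth,
                        t_alt=int(rng.binomial(t_depth, 0.5)),
                        somatic_p=float(rng.uniform(0.01, 1.0)),
                        caller="varscan2",
                    )
                )
        wes_calls[patient] = per_t

    genome_variants: List[SomaticVariant] = []
    genome_rows = []
    wgs_calls: Dict[str, List[CandidateCall]] = {
        "varscan2": [], "somaticsniper": [], "strelka": [],
    }
    region_labels = [r for r, _ in cfg.region_probs]
    region_p = np.array([p for _, p in cfg.region_probs])
    region_p = region_p / region_p.sum()
    wgs_patients = [f"G{i + 1:03d}" for i in range(cfg.n_patients_wgs)]

    def _emit_genome_variant(patient, chrom, pos, hotspot_id=None):
        ref = genome.base(chrom, pos)
        is_indel = rng.random() < cfg.genome_indel_prob and hotspot_id is None
        if is_indel:
            if rng.random() < 0.5:
                alt = ref + chr(_BASES[rng.integers(0, 4)])
            else:
                nxt = genome.base(chrom, min(pos + 1, genome.contigs[chrom]))
                ref, alt = ref + nxt, ref
        else:
            alt = _draw_substitution(rng, ref, cfg.transition_prob_genome)
        region = region_labels[int(rng.choice(len(region_labels), p=region_p))]
        variant = SomaticVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt, patient_id=patient,
            region=region,
        )
        genome_variants.append(variant)
        genome_rows.append(
            {
                "patient_id": patient, "chrom": chrom, "pos": pos,
                "ref": ref, "alt": alt, "var_class": variant.var_class,
                "region": region, "is_germline": False,
                "hotspot_id": hotspot_id if hotspot_id is not None else -1,
                "masked": genome.mask.contains(chrom, pos),
            }
        )
        vaf = cfg.founder_fraction / 2.0
        t_depth = int(_nb_depth(rng, cfg.wgs_depth_mean, cfg.depth_dispersion))
        t_alt = int(rng.binomial(t_depth, vaf))
        n_depth = int(_nb_depth(rng, cfg.wgs_depth_mean, cfg.depth_dispersion))
        n_alt = int(rng.binomial(n_depth, 0.001))
        scores = {
            "varscan2": {"somatic_p": float(rng.uniform(0, 0.01))},
            "somaticsniper": {"somatic_score": int(rng.integers(30, 90))},
            "strelka": {"qss": int(rng.integers(15, 70))},
        }
        for caller, extra in scores.items():
            wgs_calls[caller].append(
                CandidateCall(
                    variant=variant, n_depth=n_depth, n_alt=n_alt,
                    t_depth=t_depth, t_alt=t_alt, caller=caller, **extra,
                )
            )

    for patient in wgs_patients:
        n_var = int(rng.integers(cfg.genome_range[0], cfg.genome_range[1] + 1))
        for _ in range(n_var):
            chrom, pos = genome.random_position(rng)
            _emit_genome_variant(patient, chrom, pos)
        for _ in range(cfg.n_germline_wgs):
            chrom, pos = genome.random_position(rng)
            ref = genome.base(chrom, pos)
            alt = _draw_substitution(rng, ref, 0.7)
            variant = SomaticVariant(
                chrom=chrom, pos=pos, ref=ref, alt=alt, patient_id=patient,
                region="intergenic",
            )
            genome_rows.append(
                {
                    "patient_id": patient, "chrom": chrom, "pos": pos,
                    "ref": ref, "alt": alt, "var_class": variant.var_class,
                    "region": "intergenic", "is_germline": True,
                    "hotspot_id": -1,
                    "masked": genome.mask.contains(chrom, pos),
                }
            )
            t_depth = int(_nb_depth(rng, cfg.wgs_depth_mean, cfg.depth_dispersion))
            n_depth = int(_nb_depth(rng, cfg.wgs_depth_mean, cfg.depth_dispersion))
            call_kwargs = dict(
                variant=variant, n_depth=n_depth,
                n_alt=int(rng.binomial(n_depth, 0.5)),
                t_depth=t_depth, t_alt=int(rng.binomial(t_depth, 0.5)),
            )
            wgs_calls["varscan2"].append(
                CandidateCall(
                    caller="varscan2",
                    somatic_p=float(rng.uniform(0.02, 1.0)),
                    **call_kwargs,
                )
            )
    for h, (chrom, pos, width, n_pat) in enumerate(cfg.planted_hotspots):
        if pos is None:
            while True:
                chrom, pos = genome.random_unmasked_position(rng)
                if genome.unmasked.contains(chrom, pos + max(1, width)):
                    break
        chosen = rng.choice(len(wgs_patients), size=n_pat, replace=False)
        for pi in chosen:
            offset = int(rng.integers(0, max(1, width)))
            _emit_genome_variant(
                wgs_patients[int(pi)], chrom, pos + offset, hotspot_id=h
            )

    return CohortSim(
        cfg=cfg,
        genome=genome,
        arms=arms,
        wes_calls=wes_calls,
        truth_coding=pd.DataFrame(coding_rows),
        wgs_calls_by_caller=wgs_calls,
        genome_variants=genome_variants,
        truth_genome=pd.DataFrame(genome_rows),
    )


@dataclass
class MethSimConfig:
    """Study-shaped defaults for the paired-timepoint methylome generator.

    ``profile`` selects the planted change structure: responders show
    predominant demethylation (loss:gain 0.9:0.1, |delta| in
    [0.25, 0.6]); stable-disease patients show sparse small symmetric
    changes; untreated patients show none.
    """

    seed: int = 0
    n_tiles: int = 10_000
    profile: str = "responder"  # responder | stable | untreated
    coverage_mean: float = 60.0
    coverage_dispersion: float = 10.0
    baseline_modes: tuple = (  # (weight, alpha, beta) hypo / mid / hyper
        (0.40, 0.8, 8.0), (0.10, 5.0, 5.0), (0.50, 8.0, 0.8),
    )
    true_dmr_fraction: float = 0.05
    responder_loss_share: float = 0.9
    responder_delta_range: Tuple[float, float] = (0.25, 0.6)
    stable_dmr_fraction: float = 0.01
    stable_delta_range: Tuple[float, float] = (0.0, 0.3)

    def __post_init__(self) -> None:
        if self.profile not in ("responder", "stable", "untreated"):
            raise ValueError(f"unknown profile {self.profile!r}")


def simulate_methylome(
    cfg: MethSimConfig = MethSimConfig(),
) -> Tuple[List[MethTile], pd.DataFrame]:
    """Paired-timepoint 25-bp tiles with planted methylation changes.

    Baseline fractions are drawn from a hypo/mid/hyper beta mixture;
    tiles selected as true DMRs get a planted delta (baseline re-drawn
    uniformly so the full delta fits inside [0, 1]); counts are
    Binomial(coverage, fraction) at negative-binomial coverages.
    Samples are named ``t1`` and ``t2``; the truth table marks each
    tile's true fractions, delta and DMR status.
    """
    rng = np.random.default_rng(cfg.seed)
    weights = np.array([w for w, _, _ in cfg.baseline_modes])
    weights = weights / weights.sum()
    tiles: List[MethTile] = []
    rows = []
    if cfg.profile == "responder":
        dmr_fraction, delta_range = cfg.true_dmr_fraction, cfg.responder_delta_range
        loss_share = cfg.responder_loss_share
    elif cfg.profile == "stable":
        dmr_fraction, delta_range = cfg.stable_dmr_fraction, cfg.stable_delta_range
        loss_share = 0.5
    else:
        dmr_fraction, delta_range, loss_share = 0.0, (0.0, 0.0), 0.5
    for i in range(cfg.n_tiles):
        chrom = "chr1"
        start = i * 25
        mode = int(rng.choice(len(cfg.baseline_modes), p=weights))
        _, a, b = cfg.baseline_modes[mode]
        f1 = float(rng.beta(a, b))
        is_dmr = rng.random() < dmr_fraction
        delta = 0.0
        if is_dmr:
            delta = float(rng.uniform(*delta_range))
            if rng.random() < loss_share:
                delta = -delta
            # re-draw the baseline so the full planted change fits in [0, 1]
            if delta < 0:
                f1 = float(rng.uniform(-delta + 0.02, 1.0))
            else:
                f1 = float(rng.uniform(0.0, 1.0 - delta - 0.02))
        f2 = min(1.0, max(0.0, f1 + delta))
        cov1 = int(_nb_depth(rng, cfg.coverage_mean, cfg.coverage_dispersion))
        cov2 = int(_nb_depth(rng, cfg.coverage_mean, cfg.coverage_dispersion))
        tiles.append(
            MethTile(
                chrom=chrom, start=start,
                counts={
                    "t1": (int(rng.binomial(cov1, f1)), cov1),
                    "t2": (int(rng.binomial(cov2, f2)), cov2),
                },
            )
        )
        rows.append(
            {
                "chrom": chrom, "start": start, "end": start + 25,
                "true_f1": f1, "true_f2": f2, "true_delta": f2 - f1,
                "is_dmr": is_dmr,
                "direction": "loss" if delta < 0 else ("gain" if delta > 0 else "none"),
            }
        )
    return tiles, pd.DataFrame(rows)


def simulate_de_lists(
    sizes: Optional[Dict[str, Tuple[int, int]]] = None,
    universe_size: int = 24_563,
    overlap_with_dmr: float = 0.3,
    n_dmr_genes: int = 500,
    seed: int = 0,
) -> Tuple[Dict[str, DEGeneList], Set[str]]:
    """Arm-structured DE gene lists plus a DMR gene set with set overlap.

    ``sizes`` maps arm to (n_up, n_down); the default mirrors the
    observed arm asymmetry (none untreated, few in stable disease, many
    in responders).  ``overlap_with_dmr`` is the fraction of each arm's
    DE genes also placed in the DMR gene set.
    """
    if sizes is None:
        sizes = {
            "untreated": (0, 0),
            "non_responder": (12, 51),
            "responder": (343, 170),
        }
    rng = np.random.default_rng(seed)
    universe = [f"GENE{i + 1:05d}" for i in range(universe_size)]
    lists: Dict[str, DEGeneList] = {}
    de_union: Set[str] = set()
    for arm, (n_up, n_down) in sizes.items():
        if n_up + n_down > universe_size:
            raise ValueError(f"{arm}: DE sizes exceed the universe")
        idx = rng.choice(universe_size, size=n_up + n_down, replace=False)
        up = {universe[i] for i in idx[:n_up]}
        down = {universe[i] for i in idx[n_up:]}
        lists[arm] = DEGeneList(
            arm=arm, up=up, down=down, universe_size=universe_size
        )
        de_union |= up | down
    n_from_de = min(int(round(overlap_with_dmr * len(de_union))), n_dmr_genes)
    if n_from_de > len(de_union):
        raise ValueError("requested DMR overlap exceeds the DE gene pool")
    de_pool = sorted(de_union)
    dmr_genes: Set[str] = set(
        de_pool[i]
        for i in rng.choice(len(de_pool), size=n_from_de, replace=False)
    ) if n_from_de else set()
    outside = sorted(set(universe) - de_union)
    extra = n_dmr_genes - len(dmr_genes)
    if extra > 0:
        dmr_genes |= {
            outside[i]
            for i in rng.choice(len(outside), size=extra, replace=False)
        }
    return lists, dmr_genes


def random_signatures(
    k: int, seed: int = 0, concentration: float = 0.1
) -> np.ndarray:
    """k sparse random probability vectors over the 96 channels."""
    rng = np.random.default_rng(seed)
    return rng.dirichlet([concentration] * len(CHANNELS_96), size=k).T


def simulate_context_mixture(
    signatures: np.ndarray,
    n_samples: int = 10,
    mean_mutations: float = 500.0,
    exposure_sigma: float = 1.0,
    seed: int = 0,
) -> Tuple[ContextMatrix, np.ndarray]:
    """Counts matrix from known signatures: the generator is the oracle.

    Exposures are log-normal around an even split of a Poisson total per
    sample; counts are multinomial over channels.  The default sigma of
    1.0 reflects the wide sample-to-sample variation in mutational
    process activity seen in real cohorts; mixtures with near-constant
    exposure ratios are not identifiable by any factorisation.  Returns
    the matrix and the true exposure matrix (k x samples).
    """
    rng = np.random.default_rng(seed)
    n_channels, k = signatures.shape
    exposures = np.empty((k, n_samples))
    counts = np.zeros((n_channels, n_samples), dtype=int)
    for j in range(n_samples):
        weights = rng.lognormal(0.0, exposure_sigma, size=k)
        weights = weights / weights.sum()
        total = rng.poisson(mean_mutations)
        exposures[:, j] = weights * total
        p = signatures @ weights
        p = p / p.sum()
        counts[:, j] = rng.multinomial(total, p)
    frame = pd.DataFrame(
        counts,
        index=list(CHANNELS_96),
        columns=[f"sample{j + 1}" for j in range(n_samples)],
    )
    return ContextMatrix(counts=frame), exposures
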