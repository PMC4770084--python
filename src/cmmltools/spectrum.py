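"""Substitution spectra, repartition summaries and trinucleotide matrices.

Single-base substitutions are reported with the pyrimidine of the mutated
base pair as reference (a G>A on the plus strand is the C>T class), giving
six classes; combined with the 16 flanking-base pairs this yields the
conventional 96 channels.  With gene models the matrix can be doubled to
192 channels by the transcriptional strand of the pyrimidine.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .io import trinucleotide_context
from .models import GeneModel, RegionSet, SomaticVariant

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
PYRIMIDINES = ("C", "T")
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}
BASES = ("A", "C", "G", "T")

#: canonical 96-channel order: class-major, then 5' base, then 3' base
CHANNELS_96 = tuple(
    f"{five}[{cls}]{three}"
    for cls in SUBSTITUTION_CLASSES
    for five in BASES
    for three in BASES
)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def classify_substitution(ref: str, alt: str) -> Tuple[str, str]:
    """Return (transition|transversion, pyrimidine-referenced class)."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"non-ACGT substitution {ref}>{alt}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    kind = "transition" if (ref, alt) in TRANSITIONS else "transversion"
    if ref not in PYRIMIDINES:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return kind, f"{ref}>{alt}"


@dataclass
class SpectrumSummary:
    """Cohort-level spectrum and repartition counts."""

    n_variants: int = 0
    n_snv: int = 0
    n_indel: int = 0
    class_counts: Counter = field(default_factory=Counter)
    transition_count: int = 0
    transversion_count: int = 0
    region_counts: Counter = field(default_factory=Counter)
    consequence_counts: Counter = field(default_factory=Counter)
    per_patient_counts: Counter = field(default_factory=Counter)

    @property
    def transition_fraction(self) -> float:
        return self.transition_count / self.n_snv if self.n_snv else 0.0

    @property
    def snv_fraction(self) -> float:
        return self.n_snv / self.n_variants if self.n_variants else 0.0

    @property
    def indel_fraction(self) -> float:
        return self.n_indel / self.n_variants if self.n_variants else 0.0

    def consequence_fraction(self, label: str) -> float:
        return (
            self.consequence_counts[label] / self.n_variants
            if self.n_variants
            else 0.0
        )

    def per_patient_mean_sd(self) -> Tuple[float, float]:
        counts = np.array(list(self.per_patient_counts.values()), dtype=float)
        if counts.size == 0:
            return 0.0, 0.0
        return float(counts.mean()), float(counts.std(ddof=1)) if counts.size > 1 else 0.0


def summarize(variants: Iterable[SomaticVariant]) -> SpectrumSummary:
    """Count classes, regions, consequences and per-patient totals."""
    s = SpectrumSummary()
    for v in variants:
        s.n_variants += 1
        s.per_patient_counts[v.patient_id] += 1
        if v.region:
            s.region_counts[v.region] += 1
        if v.consequence:
            s.consequence_counts[v.consequence] += 1
        if v.is_snv:
            s.n_snv += 1
            kind, cls = classify_substitution(v.ref, v.alt)
            s.class_counts[cls] += 1
            if kind == "transition":
                s.transition_count += 1
            else:
                s.transversion_count += 1
        else:
            s.n_indel += 1
    return s


def variants_per_gigabase(
    variants: Sequence[SomaticVariant],
    region_sizes: Mapping[str, float],
) -> pd.DataFrame:
    """Per-region variant densities (variants / Gb) with 95% CIs.

    ``region_sizes`` maps region label to span in bp (e.g. from
    ``RegionSet.total_span``).  The mean and normal-approximation CI are
    taken over patients.
    """
    patients = sorted({v.patient_id for v in variants})
    rows = []
    for label, size_bp in region_sizes.items():
        if size_bp <= 0:
            raise ValueError(f"region {label!r} has nonpositive size")
        size_gb = size_bp / 1e9
        per_patient = Counter(
            v.patient_id for v in variants if v.region == label
        )
        dens = np.array([per_patient[p] / size_gb for p in patients], dtype=float)
        mean = float(dens.mean()) if dens.size else 0.0
        sem = float(dens.std(ddof=1) / np.sqrt(dens.size)) if dens.size > 1 else 0.0
        rows.append(
            {
                "region": label,
                "density_per_gb": mean,
                "ci_low": mean - 1.96 * sem,
                "ci_high": mean + 1.96 * sem,
                "n_variants": int(sum(per_patient.values())),
            }
        )
    return pd.DataFrame(rows)


def gene_patient_counts(variants: Iterable[SomaticVariant]) -> Counter:
    """Number of distinct patients carrying >= 1 variant per gene."""
    carriers: Dict[str, set] = defaultdict(set)
    for v in variants:
        if v.gene:
            carriers[v.gene].add(v.patient_id)
    return Counter({g: len(p) for g, p in carriers.items()})


def mutation_prevalence(n_mutated: int, cohort_size: int) -> float:
    """Fraction of a cohort carrying a mutation, as a percentage."""
    if cohort_size <= 0:
        raise ValueError("cohort_size must be positive")
    if not 0 <= n_mutated <= cohort_size:
        raise ValueError("mutated count outside [0, cohort size]")
    return 100.0 * n_mutated / cohort_size


@dataclass
class ContextMatrix:
    """Trinucleotide count matrix: 96 (or 192 stranded) channels x samples."""

    counts: pd.DataFrame  # index: channel label; columns: sample ids
    n_discarded: int = 0  # contexts containing N (or ambiguous strand)

    @property
    def channels(self) -> List[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> List[str]:
        return list(self.counts.columns)

    def to_array(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)


def _pyrimidine_channel(ref: str, alt: str, context: str) -> str:
    if ref not in PYRIMIDINES:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
        context = reverse_complement(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def build_context_matrix(
    variants: Sequence[SomaticVariant],
    reference: Fasta,
    gene_models: Optional[Sequence[GeneModel]] = None,
    sample_key: str = "patient_id",
) -> ContextMatrix:
    """Count SNVs into the 96 channels (192 when gene models are given).

    Contexts are read from the reference plus strand and folded so the
    mutated base is a pyrimidine.  With gene models, each variant inside a
    gene body is split by whether the pyrimidine lies on the transcribed
    (template) or untranscribed (coding) strand; variants outside any
    gene, or inside genes on both strands, are excluded from the stranded
    matrix and tallied as discarded.
    """
    samples = sorted({getattr(v, sample_key) for v in variants})
    stranded = gene_models is not None
    if stranded:
        channels = [
            f"{ch}:{strand}"
            for ch in CHANNELS_96
            for strand in ("transcribed", "untranscribed")
        ]
        by_chrom: Dict[str, List[GeneModel]] = defaultdict(list)
        for g in gene_models:
            by_chrom[g.chrom].append(g)
    else:
        channels = list(CHANNELS_96)
    counts = pd.DataFrame(0, index=channels, columns=samples, dtype=int)
    n_discarded = 0
    for v in variants:
        if not v.is_snv:
            continue
        context = trinucleotide_context(reference, v.chrom, v.pos)
        if "N" in context:
            n_discarded += 1
            continue
        ref = v.ref.upper()
        if context[1] != ref:
            raise ValueError(
                f"reference mismatch at {v.chrom}:{v.pos}: "
                f"variant ref {ref}, reference base {context[1]}"
            )
        channel = _pyrimidine_channel(ref, v.alt.upper(), context)
        sample = getattr(v, sample_key)
        if not stranded:
            counts.loc[channel, sample] += 1
            continue
        strands = {
            g.strand
            for g in by_chrom.get(v.chrom, ())
            if g.body_start <= v.pos <= g.body_end
        }
        if len(strands) != 1:
            n_discarded += 1  # intergenic or ambiguous (genes on both strands)
            continue
        gene_strand = strands.pop()
        pyr_strand = "+" if ref in PYRIMIDINES else "-"
        label = "untranscribed" if pyr_strand == gene_strand else "transcribed"
        counts.loc[f"{channel}:{label}", sample] += 1
    return ContextMatrix(counts=counts, n_discarded=n_discarded)


def write_context_matrix(matrix: ContextMatrix, path: str) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="channel")


def read_context_matrix(path: str) -> ContextMatrix:
    frame = pd.read_csv(path, sep="\t", index_col="channel")
    return ContextMatrix(counts=frame)
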