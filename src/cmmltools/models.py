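"""Core domain types shared by every pipeline stage.

Coordinate conventions
----------------------
Variant positions are 1-based (VCF convention).  Interval sets read from
BED are converted on input and held internally as 0-based half-open
``(start, end)`` pairs; membership tests for 1-based variant positions
convert at the point of query.  Indels are anchored at their left-aligned
VCF position and interval membership uses the anchor base only.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from intervaltree import IntervalTree

VALID_VAR_CLASSES = ("SNV", "insertion", "deletion")


def infer_var_class(ref: str, alt: str) -> str:
    """Classify an allele pair as SNV / insertion / deletion by length."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNV"
    if len(alt) > len(ref):
        return "insertion"
    if len(ref) > len(alt):
        return "deletion"
    return "SNV"  # MNV of equal length; treated as substitution


def normalize_chrom(chrom: str, use_prefix: bool = True) -> str:
    """Normalise chromosome names to one prefix convention.

    Mitochondria are accepted as ``MT`` or ``chrM`` and mapped to the
    requested convention (``chrM`` with prefix, ``MT`` without).
    """
    bare = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if bare.upper() in ("M", "MT"):
        return "chrM" if use_prefix else "MT"
    return f"chr{bare}" if use_prefix else bare


@dataclass
class SomaticVariant:
    """One somatic variant of the cohort, annotated with its provenance."""

    chrom: str
    pos: int
    ref: str
    alt: str
    patient_id: str
    sample_id: str = ""
    timepoint: int = 0
    var_class: str = ""
    consequence: Optional[str] = None
    region: Optional[str] = None
    gene: Optional[str] = None
    callers: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if self.timepoint < 0:
            raise ValueError("timepoint must be >= 0")
        expected = infer_var_class(self.ref, self.alt)
        if not self.var_class:
            self.var_class = expected
        elif self.var_class != expected:
            raise ValueError(
                f"var_class {self.var_class!r} inconsistent with alleles "
                f"{self.ref}>{self.alt} at {self.chrom}:{self.pos}"
            )

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_snv(self) -> bool:
        return self.var_class == "SNV"


@dataclass
class CandidateCall:
    """Raw tumour-normal evidence for one candidate somatic call.

    Caller scores that a caller does not emit are ``None`` (absent), never
    zero: a threshold rule on an absent field is skipped, not failed.
    """

    variant: SomaticVariant
    n_depth: int
    n_alt: int
    t_depth: int
    t_alt: int
    somatic_p: Optional[float] = None
    somatic_score: Optional[int] = None
    qss: Optional[int] = None
    caller: str = "other"
    filter_flags: frozenset = frozenset()
    in_dbsnp: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.n_alt <= self.n_depth):
            raise ValueError(
                f"normal alt reads {self.n_alt} outside [0, {self.n_depth}]"
            )
        if not (0 <= self.t_alt <= self.t_depth):
            raise ValueError(
                f"tumour alt reads {self.t_alt} outside [0, {self.t_depth}]"
            )
        if self.somatic_p is not None and not (0.0 <= self.somatic_p <= 1.0):
            raise ValueError(f"somatic_p {self.somatic_p} outside [0, 1]")
        self.filter_flags = frozenset(self.filter_flags)

    @property
    def vaf_t(self) -> Optional[float]:
        return self.t_alt / self.t_depth if self.t_depth > 0 else None

    @property
    def vaf_n(self) -> Optional[float]:
        return self.n_alt / self.n_depth if self.n_depth > 0 else None


@dataclass
class RegionSet:
    """A named collection of genomic intervals (0-based half-open).

    ``activity`` optionally maps an interval index to a tissue->activity
    (percent) mapping, used for the permissive-enhancer census.
    """

    name: str
    intervals: list = field(default_factory=list)  # (chrom, start, end, strand, attrs)
    activity: dict = field(default_factory=dict)  # interval index -> {tissue: pct}

    def __post_init__(self) -> None:
        norm = []
        for iv in self.intervals:
            chrom, start, end = iv[0], int(iv[1]), int(iv[2])
            strand = iv[3] if len(iv) > 3 else None
            attrs = iv[4] if len(iv) > 4 else None
            if start >= end:
                raise ValueError(f"empty interval {chrom}:{start}-{end} in {self.name}")
            norm.append((chrom, start, end, strand, attrs))
        self.intervals = sorted(norm, key=lambda iv: (iv[0], iv[1], iv[2]))
        self._trees: dict = {}
        for i, (chrom, start, end, _, _) in enumerate(self.intervals):
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end, i)

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position (half-open end exclusive)."""
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def hits(self, chrom: str, pos: int) -> list:
        """Interval indices covering a 1-based position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.at(pos - 1))

    def total_span(self) -> int:
        """Sum of interval lengths in bp (overlaps counted once per chrom)."""
        total = 0
        for chrom, tree in self._trees.items():
            merged = tree.copy()
            merged.merge_overlaps()
            total += sum(iv.end - iv.begin for iv in merged)
        return total


@dataclass
class GeneModel:
    """Minimal gene model: a strand-aware anchor plus the gene-body span.

    ``tss`` is the 1-based anchor used for promoter windows; depending on
    the annotation source it may be a transcription or a translation start
    -- the caller decides which site populates it.
    """

    gene: str
    chrom: str
    tss: int
    strand: str
    body_start: int
    body_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.body_start > self.body_end:
            raise ValueError(f"gene {self.gene}: body_start > body_end")
        if not (self.body_start <= self.tss <= self.body_end):
            raise ValueError(f"gene {self.gene}: tss outside gene body")

    def promoter_window(self, upstream: int = 2000, downstream: int = 200) -> tuple:
        """1-based inclusive promoter window around the anchor, strand-aware."""
        if self.strand == "+":
            return (max(1, self.tss - upstream), self.tss + downstream)
        return (max(1, self.tss - downstream), self.tss + upstream)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """Any-bp intersection of a 1-based inclusive span with the body."""
        return (
            chrom == self.chrom
            and start <= self.body_end
            and end >= self.body_start
        )


TILE_SIZE = 25


@dataclass
class MethTile:
    """One fixed-grid bisulfite tile with per-sample (meth, total) counts."""

    chrom: str
    start: int  # 0-based, multiple of TILE_SIZE
    counts: dict = field(default_factory=dict)  # sample -> (meth_reads, total_reads)

    def __post_init__(self) -> None:
        if self.start % TILE_SIZE != 0:
            raise ValueError(
                f"tile start {self.start} is not on a {TILE_SIZE}-bp boundary"
            )
        for sample, (m, t) in self.counts.items():
            if not (0 <= m <= t):
                raise ValueError(
                    f"tile {self.chrom}:{self.start} sample {sample}: "
                    f"meth reads {m} outside [0, {t}]"
                )

    @property
    def end(self) -> int:
        return self.start + TILE_SIZE

    def meth_fraction(self, sample: str) -> Optional[float]:
        m, t = self.counts[sample]
        return m / t if t > 0 else None

    def total(self, sample: str) -> int:
        return self.counts[sample][1]
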