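"""Tile-based differential methylation between two timepoints.

Bisulfite counts summarised into fixed 25-bp tiles are filtered to a
10-500x coverage window in both samples, tested per tile with a
two-sided Fisher exact test on (methylated, unmethylated) x (t1, t2)
pooled counts, and called as differentially methylated regions (DMRs)
when the absolute methylation difference is >= 25% and the BH FDR is
< 10%.  DMRs are annotated to genes by three ordered rules (overlap,
neighbours within 50 kb, else nearest TSS) and tested for genomic-
context enrichment against all tested tiles.

The Fisher test on pooled counts stands in for a dispersion-aware
beta-binomial likelihood-ratio test: with single patients at two
timepoints there is no within-group replication from which to estimate
dispersion.  A different per-tile test can be swapped in via the
``test`` argument of :func:`call_dmrs`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .models import TILE_SIZE, GeneModel, MethTile, RegionSet


@dataclass
class DmrCallConfig:
    """Thresholds of the DMR calling procedure."""

    min_coverage: int = 10
    max_coverage: int = 500
    tile_size: int = TILE_SIZE
    min_abs_diff: float = 0.25
    fdr_max: float = 0.10
    annotation_window: int = 50_000

    def __post_init__(self) -> None:
        if not 0 < self.min_coverage < self.max_coverage:
            raise ValueError("need 0 < min_coverage < max_coverage")
        if not 0.0 < self.min_abs_diff < 1.0:
            raise ValueError("min_abs_diff must lie in (0, 1)")


@dataclass
class DMR:
    """A called differentially methylated 25-bp tile."""

    chrom: str
    start: int  # 0-based half-open tile span
    end: int
    meth_t1: float
    meth_t2: float
    delta: float  # t2 - t1
    p: float
    q: float
    direction: str  # "gain" or "loss"
    genes: list = field(default_factory=list)
    context: dict = field(default_factory=dict)


def filter_tiles(
    tiles: Sequence[MethTile],
    sample_t1: str,
    sample_t2: str,
    cfg: DmrCallConfig = DmrCallConfig(),
) -> List[MethTile]:
    """Keep tiles whose coverage lies in [min, max] in BOTH samples."""
    return [
        t
        for t in tiles
        if cfg.min_coverage <= t.total(sample_t1) <= cfg.max_coverage
        and cfg.min_coverage <= t.total(sample_t2) <= cfg.max_coverage
    ]


def test_tile(
    tile: MethTile, sample_t1: str, sample_t2: str
) -> Tuple[float, float]:
    """Methylation difference (t2 - t1) and two-sided Fisher p for a tile."""
    m1, n1 = tile.counts[sample_t1]
    m2, n2 = tile.counts[sample_t2]
    if n1 == 0 or n2 == 0:
        raise ValueError(
            f"tile {tile.chrom}:{tile.start} has zero coverage in a sample"
        )
    delta = m2 / n2 - m1 / n1
    p = float(fisher_exact([[m1, n1 - m1], [m2, n2 - m2]])[1])
    return delta, p


def call_dmrs(
    tiles: Sequence[MethTile],
    sample_t1: str,
    sample_t2: str,
    cfg: DmrCallConfig = DmrCallConfig(),
    test: Callable[[MethTile, str, str], Tuple[float, float]] = test_tile,
    prefiltered: bool = False,
) -> Tuple[List[DMR], pd.DataFrame]:
    """Call DMRs between two samples over a tile set.

    Returns the called DMRs plus the full per-tile test table (the
    background for context enrichment).  BH runs over all tested tiles;
    a DMR needs q < ``fdr_max`` and |delta| >= ``min_abs_diff``.
    """
    if not prefiltered:
        tiles = filter_tiles(tiles, sample_t1, sample_t2, cfg)
    rows = []
    for t in tiles:
        delta, p = test(t, sample_t1, sample_t2)
        rows.append(
            {
                "chrom": t.chrom, "start": t.start, "end": t.end,
                "meth_t1": t.counts[sample_t1][0] / t.counts[sample_t1][1],
                "meth_t2": t.counts[sample_t2][0] / t.counts[sample_t2][1],
                "delta": delta, "p": p,
            }
        )
    table = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "meth_t1", "meth_t2", "delta", "p"]
    )
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["is_dmr"] = (table["q"] < cfg.fdr_max) & (
            table["delta"].abs() >= cfg.min_abs_diff
        )
    else:
        table["q"] = []
        table["is_dmr"] = []
    dmrs = [
        DMR(
            chrom=r.chrom, start=int(r.start), end=int(r.end),
            meth_t1=float(r.meth_t1), meth_t2=float(r.meth_t2),
            delta=float(r.delta), p=float(r.p), q=float(r.q),
            direction="gain" if r.delta > 0 else "loss",
        )
        for r in table[table["is_dmr"]].itertuples(index=False)
    ]
    for d in dmrs:  # every reported DMR satisfies both thresholds
        assert abs(d.delta) >= cfg.min_abs_diff and d.q < cfg.fdr_max
    return dmrs, table


def gain_loss_counts(dmrs: Sequence[DMR]) -> Dict[str, int]:
    return {
        "gain": sum(1 for d in dmrs if d.direction == "gain"),
        "loss": sum(1 for d in dmrs if d.direction == "loss"),
    }


def annotate_dmr(
    dmr: DMR,
    gene_models: Sequence[GeneModel],
    cfg: DmrCallConfig = DmrCallConfig(),
) -> List[str]:
    """Annotate one DMR to genes by the three ordered rules.

    (i) genes whose body overlaps the tile; else (ii) all genes within
    the 50-kb window; else (iii) the gene with the nearest TSS.
    """
    if not gene_models:
        raise ValueError("gene model list is empty")
    start1, end1 = dmr.start + 1, dmr.end  # tile as 1-based inclusive
    overlapping = sorted(
        {g.gene for g in gene_models if g.overlaps(dmr.chrom, start1, end1)}
    )
    if overlapping:
        dmr.genes = overlapping
        return overlapping
    nearby = sorted(
        {
            g.gene
            for g in gene_models
            if g.chrom == dmr.chrom
            and _body_distance(g, start1, end1) <= cfg.annotation_window
        }
    )
    if nearby:
        dmr.genes = nearby
        return nearby
    nearest = min(
        (g for g in gene_models if g.chrom == dmr.chrom),
        key=lambda g: min(abs(g.tss - start1), abs(g.tss - end1)),
        default=None,
    )
    dmr.genes = [nearest.gene] if nearest else []
    return dmr.genes


def _body_distance(g: GeneModel, start1: int, end1: int) -> int:
    if start1 <= g.body_end and end1 >= g.body_start:
        return 0
    return max(g.body_start - end1, start1 - g.body_end)


def flag_contexts(
    items: Sequence, region_sets: Sequence[RegionSet]
) -> pd.DataFrame:
    """Boolean in-context flags for DMRs or tiles, one column per set.

    Membership is any-bp overlap of the 25-bp tile with an interval.
    """
    rows = []
    for it in items:
        row = {}
        start1, end1 = it.start + 1, it.end
        for rs in region_sets:
            row[rs.name] = any(
                rs.contains(it.chrom, p) for p in (start1, end1)
            ) or rs.contains(it.chrom, (start1 + end1) // 2)
        rows.append(row)
    return pd.DataFrame(rows, columns=[rs.name for rs in region_sets])


def context_enrichment(
    dmrs: Sequence[DMR],
    background: pd.DataFrame,
    region_sets: Sequence[RegionSet],
) -> pd.DataFrame:
    """Per-context enrichment of DMRs against all tested tiles.

    ``background`` is the per-tile table from :func:`call_dmrs`
    (containing the ``is_dmr`` flag).  A 2x2 Fisher exact test per
    context compares DMR vs non-DMR tiles in vs out of context; odds
    ratio < 1 means depletion.  BH across contexts.
    """
    if background is None or len(background) == 0:
        raise ValueError("background tile table is empty")

    class _Span:
        __slots__ = ("chrom", "start", "end")

        def __init__(self, chrom, start, end):
            self.chrom, self.start, self.end = chrom, int(start), int(end)

    tiles = [
        _Span(r.chrom, r.start, r.end) for r in background.itertuples(index=False)
    ]
    flags = flag_contexts(tiles, region_sets)
    is_dmr = background["is_dmr"].to_numpy(dtype=bool)
    rows = []
    for rs in region_sets:
        inside = flags[rs.name].to_numpy(dtype=bool)
        a = int(np.sum(is_dmr & inside))
        b = int(np.sum(is_dmr & ~inside))
        c = int(np.sum(~is_dmr & inside))
        d = int(np.sum(~is_dmr & ~inside))
        odds, p = fisher_exact([[a, b], [c, d]])
        rows.append(
            {
                "context": rs.name,
                "dmr_in": a, "dmr_out": b, "bg_in": c, "bg_out": d,
                "odds_ratio": float(odds), "p": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"], method="fdr_bh")[1] if len(out) else []
    return out


def dmrs_to_frame(dmrs: Sequence[DMR]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": d.chrom, "start": d.start, "end": d.end,
                "meth_t1": d.meth_t1, "meth_t2": d.meth_t2,
                "delta": d.delta, "p": d.p, "q": d.q,
                "direction": d.direction, "genes": ";".join(d.genes),
            }
            for d in dmrs
        ],
        columns=[
            "chrom", "start", "end", "meth_t1", "meth_t2", "delta", "p",
            "q", "direction", "genes",
        ],
    )
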