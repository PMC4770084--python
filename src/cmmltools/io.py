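"""Readers and writers for the formats the pipeline consumes and emits.

Tabular dialects
----------------
*Candidate-call TSV* — header row with at least ``chrom, pos, ref, alt,
patient_id, n_depth, n_alt, t_depth, t_alt``; optional ``sample_id,
timepoint, somatic_p, somatic_score, qss, caller, filter_flags`` (``;``
separated), ``consequence, region, gene, in_dbsnp``.  Coordinates 1-based.

*Methylation-tile TSV* — ``chrom, start, end`` then, per sample ``S``,
columns ``meth_S`` and ``total_S``; ``start`` 0-based on the 25-bp grid.

*Gene-model TSV* — ``gene, chrom, tss, strand, body_start, body_end``.

VCF candidate calls are read through :mod:`cyvcf2`; per-sample AD/DP
fields supply the depths and the caller-specific INFO keys ``SPV``
(somatic p-value), ``SSC`` (somatic score) and ``QSS_NT``/``QSI_NT``
(quality score) supply the scores.  FILTER strings are kept verbatim.
"""

from __future__ import annotations

import csv
from typing import Iterable, List, Optional, Sequence

import pandas as pd
from pyfaidx import Fasta

from .models import (
    TILE_SIZE,
    CandidateCall,
    GeneModel,
    MethTile,
    RegionSet,
    SomaticVariant,
)

_CALL_COLUMNS = [
    "chrom", "pos", "ref", "alt", "patient_id", "sample_id", "timepoint",
    "n_depth", "n_alt", "t_depth", "t_alt", "somatic_p", "somatic_score",
    "qss", "caller", "filter_flags", "consequence", "region", "gene",
    "in_dbsnp",
]

_REQUIRED_CALL_COLUMNS = {
    "chrom", "pos", "ref", "alt", "patient_id",
    "n_depth", "n_alt", "t_depth", "t_alt",
}


def _opt(row: dict, key: str, cast):
    val = row.get(key)
    if val is None or val == "" or str(val).upper() in ("NA", "NONE", "."):
        return None
    return cast(val)


def read_candidate_calls(path: str, caller: str = "other") -> List[CandidateCall]:
    """Read candidate somatic calls from a TSV or uncompressed VCF file.

    The file kind is chosen by extension (``.vcf`` vs anything else).
    ``caller`` labels records that do not carry their own caller column.
    """
    if str(path).endswith(".vcf") or str(path).endswith(".vcf.gz"):
        return _read_calls_vcf(path, caller)
    return _read_calls_tsv(path, caller)


def _read_calls_tsv(path: str, caller: str) -> List[CandidateCall]:
    calls: List[CandidateCall] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return []
        missing = _REQUIRED_CALL_COLUMNS - set(reader.fieldnames)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                variant = SomaticVariant(
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    patient_id=row["patient_id"],
                    sample_id=row.get("sample_id") or "",
                    timepoint=int(row.get("timepoint") or 0),
                    consequence=_opt(row, "consequence", str),
                    region=_opt(row, "region", str),
                    gene=_opt(row, "gene", str),
                )
                flags = row.get("filter_flags") or ""
                calls.append(
                    CandidateCall(
                        variant=variant,
                        n_depth=int(row["n_depth"]),
                        n_alt=int(row["n_alt"]),
                        t_depth=int(row["t_depth"]),
                        t_alt=int(row["t_alt"]),
                        somatic_p=_opt(row, "somatic_p", float),
                        somatic_score=_opt(row, "somatic_score", int),
                        qss=_opt(row, "qss", int),
                        caller=row.get("caller") or caller,
                        filter_flags=frozenset(f for f in flags.split(";") if f),
                        in_dbsnp=str(row.get("in_dbsnp", "")).lower()
                        in ("1", "true", "yes"),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path} line {lineno}: {exc}") from exc
    return calls


def _read_calls_vcf(path: str, caller: str) -> List[CandidateCall]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    try:
        t_idx = samples.index("TUMOR") if "TUMOR" in samples else len(samples) - 1
        n_idx = samples.index("NORMAL") if "NORMAL" in samples else 0
    except ValueError:  # pragma: no cover - index() cannot fail after `in`
        t_idx, n_idx = len(samples) - 1, 0
    calls: List[CandidateCall] = []
    for rec in vcf:
        if rec.ALT is None or len(rec.ALT) == 0:
            continue
        depths = rec.format("DP")
        ads = rec.format("AD")
        if depths is None or ads is None:
            raise ValueError(
                f"{path}: record {rec.CHROM}:{rec.POS} lacks DP/AD sample fields"
            )
        depths = [int(row.ravel()[0]) for row in depths]
        info = dict(rec.INFO)
        qss = info.get("QSS_NT", info.get("QSI_NT"))
        flags = frozenset(rec.FILTER.split(";")) if rec.FILTER else frozenset()
        for alt in rec.ALT:
            variant = SomaticVariant(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                patient_id=str(info.get("PATIENT", "")),
            )
            calls.append(
                CandidateCall(
                    variant=variant,
                    n_depth=depths[n_idx],
                    n_alt=int(ads[n_idx][1]),
                    t_depth=depths[t_idx],
                    t_alt=int(ads[t_idx][1]),
                    somatic_p=float(info["SPV"]) if "SPV" in info else None,
                    somatic_score=int(info["SSC"]) if "SSC" in info else None,
                    qss=int(qss) if qss is not None else None,
                    caller=caller,
                    filter_flags=flags,
                )
            )
    return calls


def write_candidate_calls(calls: Iterable[CandidateCall], path: str) -> None:
    """Write calls to the TSV dialect with deterministic column order."""
    rows = []
    for c in calls:
        v = c.variant
        rows.append(
            {
                "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
                "patient_id": v.patient_id, "sample_id": v.sample_id,
                "timepoint": v.timepoint, "n_depth": c.n_depth,
                "n_alt": c.n_alt, "t_depth": c.t_depth, "t_alt": c.t_alt,
                "somatic_p": "" if c.somatic_p is None else repr(c.somatic_p),
                "somatic_score": "" if c.somatic_score is None else c.somatic_score,
                "qss": "" if c.qss is None else c.qss,
                "caller": c.caller,
                "filter_flags": ";".join(sorted(c.filter_flags)),
                "consequence": v.consequence or "",
                "region": v.region or "",
                "gene": v.gene or "",
                "in_dbsnp": int(c.in_dbsnp),
            }
        )
    pd.DataFrame(rows, columns=_CALL_COLUMNS).to_csv(path, sep="\t", index=False)


def variants_to_frame(variants: Iterable[SomaticVariant]) -> pd.DataFrame:
    rows = [
        {
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "var_class": v.var_class, "patient_id": v.patient_id,
            "sample_id": v.sample_id, "timepoint": v.timepoint,
            "consequence": v.consequence or "", "region": v.region or "",
            "gene": v.gene or "", "callers": ";".join(sorted(v.callers)),
        }
        for v in variants
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "pos", "ref", "alt", "var_class", "patient_id",
            "sample_id", "timepoint", "consequence", "region", "gene",
            "callers",
        ],
    )


def frame_to_variants(frame: pd.DataFrame) -> List[SomaticVariant]:
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            SomaticVariant(
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                patient_id=str(row.patient_id),
                sample_id=str(getattr(row, "sample_id", "") or ""),
                timepoint=int(getattr(row, "timepoint", 0) or 0),
                consequence=str(row.consequence) or None
                if getattr(row, "consequence", "") != ""
                else None,
                region=str(row.region) or None
                if getattr(row, "region", "") != ""
                else None,
                gene=str(row.gene) or None
                if getattr(row, "gene", "") != ""
                else None,
                callers=frozenset(
                    str(getattr(row, "callers", "")).split(";")
                )
                - {""},
            )
        )
    return out


def read_variants(path: str) -> List[SomaticVariant]:
    return frame_to_variants(pd.read_csv(path, sep="\t", keep_default_na=False))


def write_variants(variants: Iterable[SomaticVariant], path: str) -> None:
    variants_to_frame(variants).to_csv(path, sep="\t", index=False)


def read_bed(path: str, name: str = "regions") -> RegionSet:
    """Read a BED3/BED6 file into a :class:`RegionSet`.

    BED is 0-based half-open on disk and stays so in memory; a 6th column
    is parsed as strand.  Overlapping intervals are retained unmerged.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path} line {lineno}: fewer than 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ValueError(
                    f"{path} line {lineno}: start {start} >= end {end}"
                )
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else None
            attrs = {"name": fields[3]} if len(fields) >= 4 else None
            intervals.append((chrom, start, end, strand, attrs))
    return RegionSet(name=name, intervals=intervals)


def write_bed(regions: RegionSet, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, strand, attrs in regions.intervals:
            name = (attrs or {}).get("name", ".")
            if strand is not None:
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def read_gene_models(path: str) -> List[GeneModel]:
    frame = pd.read_csv(path, sep="\t")
    return [
        GeneModel(
            gene=str(r.gene),
            chrom=str(r.chrom),
            tss=int(r.tss),
            strand=str(r.strand),
            body_start=int(r.body_start),
            body_end=int(r.body_end),
        )
        for r in frame.itertuples(index=False)
    ]


def write_gene_models(genes: Sequence[GeneModel], path: str) -> None:
    pd.DataFrame(
        [
            {
                "gene": g.gene, "chrom": g.chrom, "tss": g.tss,
                "strand": g.strand, "body_start": g.body_start,
                "body_end": g.body_end,
            }
            for g in genes
        ]
    ).to_csv(path, sep="\t", index=False)


def read_meth_tiles(path: str, samples: Optional[Sequence[str]] = None) -> List[MethTile]:
    """Read 25-bp methylation tiles with per-sample (meth, total) counts."""
    frame = pd.read_csv(path, sep="\t")
    if samples is None:
        samples = [c[5:] for c in frame.columns if c.startswith("meth_")]
    tiles = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        start = int(row.start)
        if start % TILE_SIZE != 0:
            raise ValueError(
                f"{path} line {i}: start {start} not on the {TILE_SIZE}-bp grid"
            )
        if int(row.end) != start + TILE_SIZE:
            raise ValueError(f"{path} line {i}: tile is not {TILE_SIZE} bp wide")
        counts = {}
        for s in samples:
            m = int(getattr(row, f"meth_{s}"))
            t = int(getattr(row, f"total_{s}"))
            if m > t:
                raise ValueError(
                    f"{path} line {i}: sample {s} meth {m} > total {t}"
                )
            counts[s] = (m, t)
        tiles.append(MethTile(chrom=str(row.chrom), start=start, counts=counts))
    return tiles


def write_meth_tiles(tiles: Sequence[MethTile], path: str) -> None:
    if not tiles:
        pd.DataFrame(columns=["chrom", "start", "end"]).to_csv(
            path, sep="\t", index=False
        )
        return
    samples = sorted({s for t in tiles for s in t.counts})
    rows = []
    for t in tiles:
        row = {"chrom": t.chrom, "start": t.start, "end": t.end}
        for s in samples:
            m, tot = t.counts.get(s, (0, 0))
            row[f"meth_{s}"] = m
            row[f"total_{s}"] = tot
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def trinucleotide_context(reference: Fasta, chrom: str, pos: int) -> str:
    """Uppercase plus-strand 3-mer centred on a 1-based position.

    Raises at contig edges; contexts containing N are returned as-is so
    the caller can tally and discard them.
    """
    contig = reference[chrom]
    if pos - 1 < 1 or pos + 1 > len(contig):
        raise ValueError(f"{chrom}:{pos} too close to the contig edge")
    return str(contig[pos - 2 : pos + 1]).upper()
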