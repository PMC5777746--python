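"""Cis-target search: coding genes within a fixed window of a lncRNA locus.

Coordinates are 1-based inclusive and strand-agnostic.  A gene is a cis
candidate when it lies on the lncRNA's chromosome and either overlaps the
lncRNA interval or its nearest edge is within the window (10 kb by
default, boundary inclusive).  ``upstream`` means the gene lies entirely
at lower coordinates than the lncRNA, ``downstream`` entirely at higher
coordinates; the gap counts the bases strictly between the nearest edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from lncarray.errors import IntegrityError, ValidationError

UPSTREAM = "upstream"
DOWNSTREAM = "downstream"
OVERLAP = "overlap"


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval."""

    chrom: str
    start: int
    end: int
    name: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValidationError(
                f"invalid interval {self.name}: 1 <= start <= end violated "
                f"({self.start}, {self.end})"
            )


@dataclass(frozen=True)
class CisConfig:
    """Search window in base pairs around the lncRNA (edge-to-edge)."""

    window: int = 10_000

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValidationError("window must be >= 0")


@dataclass(frozen=True)
class CisTarget:
    lncrna_name: str
    gene_name: str
    relation: str               # upstream / downstream / overlap
    gap_bp: int                 # 0 for overlap


def classify_relation(
    lnc: GenomicInterval, gene: GenomicInterval, cfg: CisConfig | None = None
) -> Optional[CisTarget]:
    """Classify one lncRNA/gene pair, or return None when out of range."""
    cfg = cfg or CisConfig()
    if lnc.chrom != gene.chrom:
        return None
    if gene.end >= lnc.start and gene.start <= lnc.end:
        return CisTarget(lnc.name, gene.name, OVERLAP, 0)
    if gene.end < lnc.start:
        relation, gap = UPSTREAM, lnc.start - gene.end - 1
    else:
        relation, gap = DOWNSTREAM, gene.start - lnc.end - 1
    if gap > cfg.window:
        return None
    return CisTarget(lnc.name, gene.name, relation, gap)


def find_cis_targets(
    lncs: Sequence[GenomicInterval],
    genes: Sequence[GenomicInterval],
    cfg: CisConfig | None = None,
) -> pd.DataFrame:
    """All qualifying lncRNA/gene pairs, one row each.

    lncRNAs with no hit are still reported, with empty gene/relation
    fields.  Rows are ordered by lncRNA name, then gene start.
    """
    cfg = cfg or CisConfig()
    for group, label in ((lncs, "lncRNA"), (genes, "gene")):
        names = [iv.name for iv in group]
        if len(set(names)) != len(names):
            raise IntegrityError(f"duplicate {label} interval names")
    if set(iv.name for iv in lncs) & set(iv.name for iv in genes):
        raise IntegrityError("lncRNA and gene interval names must not collide")

    gene_start = {g.name: g.start for g in genes}
    rows = []
    for lnc in sorted(lncs, key=lambda iv: iv.name):
        hits = []
        for gene in genes:
            t = classify_relation(lnc, gene, cfg)
            if t is not None:
                hits.append(t)
        hits.sort(key=lambda t: gene_start[t.gene_name])
        if not hits:
            rows.append({"lncrna_name": lnc.name, "gene_name": "",
                         "relation": "", "gap_bp": pd.NA})
        for t in hits:
            rows.append({"lncrna_name": t.lncrna_name, "gene_name": t.gene_name,
                         "relation": t.relation, "gap_bp": t.gap_bp})
    return pd.DataFrame(rows, columns=["lncrna_name", "gene_name", "relation", "gap_bp"])


def read_interval_tsv(path: str | Path) -> list[GenomicInterval]:
    """BED-like TSV with columns name, chrom, start, end (1-based inclusive)."""
    frame = pd.read_csv(path, sep="\t", dtype={"name": str, "chrom": str})
    missing = [c for c in ("name", "chrom", "start", "end") if c not in frame.columns]
    if missing:
        raise ValidationError(f"interval TSV missing column(s): {missing}")
    return [
        GenomicInterval(chrom=r.chrom, start=int(r.start), end=int(r.end), name=r.name)
        for r in frame.itertuples(index=False)
    ]


def write_interval_tsv(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    pd.DataFrame(
        [{"name": iv.name, "chrom": iv.chrom, "start": iv.start, "end": iv.end}
         for iv in intervals]
    ).to_csv(path, sep="\t", index=False)
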