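"""Probe-set annotation reconciliation: which array probe sets measure lncRNAs.

Commercial expression arrays predate most lncRNA annotation, but many of
their probe sets hybridise to non-coding transcripts.  This module
re-purposes a NetAffx-style annotation table by cross-referencing two
evidence sources per probe set:

* RefSeq transcript accessions — an ``NR_`` prefix marks a curated
  non-coding transcript, ``NM_`` a coding mRNA;
* Ensembl gene biotypes — ``lincRNA``, ``processed_transcript``,
  ``macro_lncRNA`` and ``misc_RNA`` are retained as long non-coding,
  while pseudogenes, rRNAs, microRNAs and other short RNAs (tRNA,
  snRNA, snoRNA) are removed.

A probe set is kept as lncRNA when at least one source supports the call,
no short-RNA/pseudogene biotype applies, and the two sources do not
contradict each other; contradictions are excluded explicitly rather
than silently resolved.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from lncarray.errors import IntegrityError, SchemaError

logger = logging.getLogger(__name__)

# Probe classification statuses.
LNCRNA = "lncRNA"
EXCLUDED_CODING = "excluded_coding"
EXCLUDED_SHORT_OR_PSEUDO = "excluded_short_or_pseudo"
EXCLUDED_CONFLICT = "excluded_conflict"
STATUSES = (LNCRNA, EXCLUDED_CODING, EXCLUDED_SHORT_OR_PSEUDO, EXCLUDED_CONFLICT)

# Evidence sources for a lncRNA call.
REFSEQ_ONLY = "refseq_only"
ENSEMBL_ONLY = "ensembl_only"
BOTH = "both"
NONE = "none"
SOURCES = (REFSEQ_ONLY, ENSEMBL_ONLY, BOTH)


@dataclass(frozen=True)
class ProbeAnnotation:
    """One probe set with its RefSeq and Ensembl annotation."""

    probe_set_id: str
    gene_symbol: str = ""
    gene_title: str = ""
    refseq_transcript_ids: tuple[str, ...] = ()
    ensembl_gene_ids: tuple[str, ...] = ()
    ensembl_biotypes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name in ("refseq_transcript_ids", "ensembl_gene_ids", "ensembl_biotypes"):
            vals = getattr(self, name)
            if any(v == "" for v in vals):
                raise ValueError(f"{name} must not contain empty strings")


@dataclass(frozen=True)
class ProbeClass:
    """Classification outcome for one probe set."""

    probe_set_id: str
    status: str
    source: str = NONE
    lncrna_gene_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status == LNCRNA and self.source not in SOURCES:
            raise ValueError("lncRNA status requires a supporting source")
        if self.status != LNCRNA and self.source != NONE:
            raise ValueError("excluded statuses carry no source")


@dataclass(frozen=True)
class BiotypeRules:
    """Retained / removed Ensembl biotype sets (matched case-insensitively).

    ``pseudogene_substring`` catches the whole family of pseudogene
    biotypes (``processed_pseudogene``, ``transcribed_unitary_pseudogene``,
    ...) without enumerating them.  Unknown biotypes fall back to
    ``default_status`` and are logged, never silently dropped.
    """

    retained: frozenset[str] = frozenset(
        {"lincrna", "processed_transcript", "macro_lncrna", "misc_rna"}
    )
    removed: frozenset[str] = frozenset(
        {"rrna", "mirna", "trna", "snrna", "snorna", "scarna", "srna",
         "scrna", "ribozyme", "pseudogene"}
    )
    coding: frozenset[str] = frozenset({"protein_coding"})
    pseudogene_substring: str = "pseudogene"
    default_status: str = EXCLUDED_CODING

    def is_retained(self, biotype: str) -> bool:
        return biotype.lower() in self.retained

    def is_removed(self, biotype: str) -> bool:
        b = biotype.lower()
        return b in self.removed or self.pseudogene_substring in b

    def is_coding(self, biotype: str) -> bool:
        return biotype.lower() in self.coding

    def is_known(self, biotype: str) -> bool:
        return self.is_retained(biotype) or self.is_removed(biotype) or self.is_coding(biotype)


@dataclass(frozen=True)
class CsvDialect:
    """Column names and cell conventions of a NetAffx-like annotation CSV."""

    probe_set_id: str = "Probe Set ID"
    gene_symbol: str = "Gene Symbol"
    gene_title: str = "Gene Title"
    refseq: str = "RefSeq Transcript ID"
    ensembl: str = "Ensembl Gene ID"
    biotype: str = "Ensembl Biotype"
    multi_delimiter: str = " /// "
    placeholders: frozenset[str] = frozenset({"---", ""})

    @property
    def required_columns(self) -> tuple[str, ...]:
        return (self.probe_set_id, self.gene_symbol, self.gene_title,
                self.refseq, self.ensembl)


@dataclass
class LncRNACatalog:
    """The retained lncRNA probe sets with probe/gene tallies per source."""

    entries: list[ProbeClass]
    gene_symbols: dict[str, str] = field(default_factory=dict)

    @property
    def probe_counts(self) -> dict[str, int]:
        c = Counter(e.source for e in self.entries)
        return {s: c.get(s, 0) for s in SOURCES}

    @property
    def gene_counts(self) -> dict[str, int]:
        genes: dict[str, set[str]] = {s: set() for s in SOURCES}
        for e in self.entries:
            genes[e.source].add(self._gene_key(e))
        return {s: len(g) for s, g in genes.items()}

    def _gene_key(self, entry: ProbeClass) -> str:
        sym = self.gene_symbols.get(entry.probe_set_id, "")
        if sym:
            return sym
        if entry.lncrna_gene_ids:
            return entry.lncrna_gene_ids[0]
        return entry.probe_set_id

    def gene_map(self) -> dict[str, str]:
        """probe_set_id → gene key (symbol, falling back to Ensembl id)."""
        return {e.probe_set_id: self._gene_key(e) for e in self.entries}

    def probe_ids(self) -> set[str]:
        return {e.probe_set_id for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "probe_set_id": [e.probe_set_id for e in self.entries],
                "status": [e.status for e in self.entries],
                "source": [e.source for e in self.entries],
                "gene_ids": ["|".join(e.lncrna_gene_ids) for e in self.entries],
                "gene_symbol": [self.gene_symbols.get(e.probe_set_id, "")
                                for e in self.entries],
            }
        )

    def venn_summary(self) -> dict:
        """Venn-style counts: probes and distinct genes per evidence source."""
        return {
            "probe_counts": self.probe_counts,
            "gene_counts": self.gene_counts,
            "n_probes": len(self.entries),
        }

    def write(self, catalog_tsv: str | Path, summary_json: str | Path | None = None) -> None:
        self.to_frame().to_csv(catalog_tsv, sep="\t", index=False)
        if summary_json is not None:
            Path(summary_json).write_text(json.dumps(self.venn_summary(), indent=2) + "\n")


def _split_cell(cell: object, dialect: CsvDialect) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    text = str(cell).strip()
    if text in dialect.placeholders:
        return ()
    parts = [p.strip() for p in text.split(dialect.multi_delimiter.strip())]
    return tuple(p for p in parts if p and p not in dialect.placeholders)


def parse_annotation_csv(
    path: str | Path, dialect: CsvDialect | None = None
) -> list[ProbeAnnotation]:
    """Read a NetAffx-like annotation CSV into :class:`ProbeAnnotation` records.

    Multi-valued cells are split on the dialect's delimiter and placeholder
    cells (``---``) become empty lists.  A biotype column is optional; when
    present it is split in parallel with the Ensembl gene id column.
    """
    dialect = dialect or CsvDialect()
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in dialect.required_columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"annotation CSV missing required column(s): {missing}")
    has_biotype = dialect.biotype in frame.columns

    records: list[ProbeAnnotation] = []
    seen: set[str] = set()
    for row in frame.itertuples(index=False):
        row = dict(zip(frame.columns, row))
        pid = str(row[dialect.probe_set_id]).strip()
        if pid in seen:
            raise IntegrityError(f"duplicate probe_set_id {pid!r}")
        seen.add(pid)
        symbol = str(row[dialect.gene_symbol]).strip()
        if symbol in dialect.placeholders:
            symbol = ""
        records.append(
            ProbeAnnotation(
                probe_set_id=pid,
                gene_symbol=symbol,
                gene_title=str(row[dialect.gene_title]).strip(),
                refseq_transcript_ids=_split_cell(row[dialect.refseq], dialect),
                ensembl_gene_ids=_split_cell(row[dialect.ensembl], dialect),
                ensembl_biotypes=_split_cell(row[dialect.biotype], dialect)
                if has_biotype else (),
            )
        )
    return records


def classify_probe(ann: ProbeAnnotation, rules: BiotypeRules | None = None) -> ProbeClass:
    """Assign one of four statuses to a probe set.

    A probe qualifies as lncRNA when ANY RefSeq accession is ``NR_``-prefixed
    or ANY Ensembl biotype is in the retained set; any removal-set biotype
    vetoes the call.  When one database supports lncRNA while the other
    asserts protein-coding or a removal biotype, the definitions are
    contradictory and the probe is excluded as a conflict.
    """
    rules = rules or BiotypeRules()
    refseq_nc = any(acc.startswith("NR_") for acc in ann.refseq_transcript_ids)
    refseq_coding = any(acc.startswith("NM_") for acc in ann.refseq_transcript_ids)

    for b in ann.ensembl_biotypes:
        if not rules.is_known(b):
            logger.warning(
                "probe %s: unknown biotype %r -> default status %s",
                ann.probe_set_id, b, rules.default_status,
            )
    ens_lnc = any(rules.is_retained(b) for b in ann.ensembl_biotypes)
    ens_removed = any(rules.is_removed(b) for b in ann.ensembl_biotypes)
    ens_coding = any(rules.is_coding(b) for b in ann.ensembl_biotypes)

    def excluded(status: str) -> ProbeClass:
        return ProbeClass(ann.probe_set_id, status)

    if not (refseq_nc or ens_lnc):
        if ens_removed and not (refseq_coding or ens_coding):
            return excluded(EXCLUDED_SHORT_OR_PSEUDO)
        if refseq_coding or ens_coding:
            return excluded(EXCLUDED_CODING)
        return excluded(rules.default_status)

    # lncRNA support from at least one database; check vetoes.
    cross_conflict = (refseq_nc and (ens_removed or ens_coding)) or (
        ens_lnc and refseq_coding
    )
    if cross_conflict:
        return excluded(EXCLUDED_CONFLICT)
    if ens_removed:  # same-database veto (mixed Ensembl genes)
        return excluded(EXCLUDED_SHORT_OR_PSEUDO)
    if ens_coding:
        return excluded(EXCLUDED_CODING)

    if refseq_nc and ens_lnc:
        source = BOTH
    elif refseq_nc:
        source = REFSEQ_ONLY
    else:
        source = ENSEMBL_ONLY

    if ann.ensembl_biotypes:
        gene_ids = tuple(
            g for g, b in zip(ann.ensembl_gene_ids, ann.ensembl_biotypes)
            if rules.is_retained(b)
        )
    else:
        gene_ids = ann.ensembl_gene_ids
    return ProbeClass(ann.probe_set_id, LNCRNA, source, gene_ids)


def classify_table(
    anns: Iterable[ProbeAnnotation], rules: BiotypeRules | None = None
) -> list[ProbeClass]:
    """Classify every probe of an annotation table (one status each)."""
    rules = rules or BiotypeRules()
    return [classify_probe(a, rules) for a in anns]


def build_catalog(
    classes: Sequence[ProbeClass], anns: Sequence[ProbeAnnotation]
) -> LncRNACatalog:
    """Collect lncRNA-status probes into a catalog with per-source tallies.

    Distinct-gene counts key on the gene symbol, falling back to the first
    retained Ensembl gene id when the symbol is absent.
    """
    by_id: Mapping[str, ProbeAnnotation] = {a.probe_set_id: a for a in anns}
    missing = [c.probe_set_id for c in classes if c.probe_set_id not in by_id]
    if missing:
        raise IntegrityError(f"classified probes absent from annotation: {missing}")
    entries = sorted(
        (c for c in classes if c.status == LNCRNA), key=lambda c: c.probe_set_id
    )
    symbols = {c.probe_set_id: by_id[c.probe_set_id].gene_symbol for c in entries}
    return LncRNACatalog(entries=list(entries), gene_symbols=symbols)


def catalog_from_csv(
    path: str | Path,
    dialect: CsvDialect | None = None,
    rules: BiotypeRules | None = None,
) -> tuple[LncRNACatalog, list[ProbeClass]]:
    """Convenience: parse, classify and catalog in one call."""
    anns = parse_annotation_csv(path, dialect)
    classes = classify_table(anns, rules)
    return build_catalog(classes, anns), classes
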