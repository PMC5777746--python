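"""EASE-score gene-set enrichment and PWM scanning for RNA-binding proteins.

Enrichment follows the conservative DAVID-style construction: the
one-sided hypergeometric upper tail is computed after removing one gene
from the query/term overlap (the "EASE score"), which penalises terms
supported by very few genes.  Terms are retained when at least
``count_min`` query genes hit the term and the EASE score is at most
``ease_max`` (defaults 2 and 0.1).

RNA-binding-protein sites are located by sliding each position weight
matrix along the lncRNA sequence and emitting windows whose relative
score — (S − S_min)/(S_max − S_min) over the matrix's attainable score
range — reaches the threshold (0.8 by default).  Sequences are treated as
single-stranded RNA: thymine is read as uracil and no reverse-complement
scan is performed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.stats import hypergeom

from lncarray.errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

RNA_ALPHABET = "ACGU"
_CODE = {c: i for i, c in enumerate(RNA_ALPHABET)}


# ---------------------------------------------------------------------------
# gene sets and enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSet:
    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.term_id} has no members")


def parse_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT file (term_id <TAB> description <TAB> gene1 <TAB> ...)."""
    sets = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise SchemaError(f"GMT line {lineno}: need id, description and >= 1 gene")
        members = frozenset(_norm_symbol(g) for g in parts[2:] if g.strip())
        sets.append(GeneSet(parts[0], parts[1], members))
    return sets


def _norm_symbol(symbol: str) -> str:
    return symbol.strip().upper()


def ease_p(k: int, n: int, K: int, N: int) -> float:
    """EASE score: hypergeometric upper tail with one overlap gene removed.

    ``k`` query genes of a size-``n`` list hit a term with ``K`` genes in a
    background of ``N``.  The plain enrichment p-value would be
    P(X >= k); EASE replaces k by k − 1, so single-gene overlaps are never
    significant (k <= 1 gives 1.0).
    """
    if not (0 <= k <= n <= N and 0 <= K <= N and k <= K):
        raise ValidationError(f"inconsistent counts k={k} n={n} K={K} N={N}")
    if k <= 1:
        return 1.0
    # P(X >= k-1) for X ~ Hypergeom(N, K, n)
    return float(hypergeom.sf(k - 2, N, K, n))


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """Ratio of proportions (k/n)/(K/N); NaN flags the undefined K = 0 case."""
    if n <= 0:
        raise ValidationError("query list must be non-empty")
    if K <= 0:
        logger.warning("fold enrichment undefined for empty background term")
        return math.nan
    return (k / n) / (K / N)


@dataclass(frozen=True)
class EnrichmentFilters:
    count_min: int = 2
    ease_max: float = 0.1


def enrich(
    query: Iterable[str],
    background: Iterable[str],
    sets: Sequence[GeneSet],
    filters: EnrichmentFilters | None = None,
) -> pd.DataFrame:
    """Score every gene set against the query list and apply both filters.

    Symbols are normalised to upper case.  The query must be a subset of
    the background.  One record per term intersecting the query survives
    when count >= count_min and EASE <= ease_max; output is sorted by
    EASE score, ties by term_id.
    """
    filters = filters or EnrichmentFilters()
    query_set = {_norm_symbol(g) for g in query}
    bg_set = {_norm_symbol(g) for g in background}
    if not bg_set:
        raise ValidationError("background gene list is empty")
    stray = query_set - bg_set
    if stray:
        raise ValidationError(f"query genes absent from background: {sorted(stray)[:10]}")
    n, N = len(query_set), len(bg_set)
    rows = []
    for gs in sets:
        members = {_norm_symbol(g) for g in gs.members}
        term_bg = members & bg_set
        k = len(members & query_set)
        if k == 0:
            continue
        K = len(term_bg)
        p = ease_p(k, n, K, N)
        if k < filters.count_min or p > filters.ease_max:
            continue
        rows.append(
            {
                "term_id": gs.term_id,
                "term_name": gs.term_name,
                "count": k,
                "list_size": n,
                "term_size": K,
                "background_size": N,
                "ease_p": p,
                "fold_enrichment": fold_enrichment(k, n, K, N),
            }
        )
    frame = pd.DataFrame(
        rows, columns=["term_id", "term_name", "count", "list_size", "term_size",
                       "background_size", "ease_p", "fold_enrichment"]
    )
    return frame.sort_values(["ease_p", "term_id"], ignore_index=True)


def shared_terms(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two enrichment tables on term_id, keeping both datasets'
    gene counts and fold-enrichment scores (suffixes _a and _b)."""
    cols = ["term_id", "term_name", "count", "ease_p", "fold_enrichment"]
    if not len(a) or not len(b):
        out_cols = (["term_id", "term_name"]
                    + [f"{c}_a" for c in cols[2:]] + [f"{c}_b" for c in cols[2:]])
        return pd.DataFrame(columns=out_cols)
    merged = a[cols].merge(b[cols], on="term_id", suffixes=("_a", "_b"))
    merged = merged.rename(columns={"term_name_a": "term_name"}).drop(
        columns=["term_name_b"]
    )
    return merged.sort_values("term_id", ignore_index=True)


# ---------------------------------------------------------------------------
# position weight matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PWM:
    """Per-position log-odds weights over the RNA alphabet A, C, G, U."""

    protein_name: str
    weights: np.ndarray              # width x 4

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[1] != 4 or w.shape[0] < 1:
            raise ValidationError("PWM needs a width x 4 weight matrix")
        if not np.all(np.isfinite(w)):
            raise ValidationError("PWM weights must be finite")
        object.__setattr__(self, "weights", w)

    @property
    def width(self) -> int:
        return self.weights.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(RNA_ALPHABET[i] for i in self.weights.argmax(axis=1))

    @property
    def score_range(self) -> tuple[float, float]:
        return float(self.weights.min(axis=1).sum()), float(self.weights.max(axis=1).sum())

    @classmethod
    def from_counts(
        cls, protein_name: str, counts: np.ndarray,
        background: float = 0.25, pseudocount: float = 0.01,
    ) -> "PWM":
        """Convert a count/frequency matrix to log2-odds weights against a
        uniform background."""
        c = np.asarray(counts, dtype=float)
        if np.any(c < 0):
            raise ValidationError("count matrix must be non-negative")
        totals = c.sum(axis=1, keepdims=True)
        totals[totals == 0] = 1.0
        freq = (c + pseudocount) / (totals + 4 * pseudocount)
        return cls(protein_name, np.log2(freq / background))


def encode_rna(sequence: str) -> np.ndarray:
    """Integer-encode an RNA sequence (T transparently mapped to U)."""
    seq = sequence.upper().replace("T", "U")
    codes = np.empty(len(seq), dtype=np.int64)
    for i, ch in enumerate(seq):
        if ch not in _CODE:
            raise ValidationError(f"invalid letter {ch!r} at position {i + 1}")
        codes[i] = _CODE[ch]
    return codes


def pwm_relative_score(pwm: PWM, window: str) -> float:
    """Relative score of one window: (S − S_min)/(S_max − S_min) ∈ [0, 1]."""
    if len(window) != pwm.width:
        raise ValidationError(
            f"window length {len(window)} != matrix width {pwm.width}"
        )
    codes = encode_rna(window)
    s = float(pwm.weights[np.arange(pwm.width), codes].sum())
    s_min, s_max = pwm.score_range
    if s_max == s_min:
        raise ValidationError(f"degenerate matrix {pwm.protein_name}: "
                              "all windows score identically")
    return (s - s_min) / (s_max - s_min)


def scan_sequence(pwm: PWM, name: str, sequence: str, threshold: float) -> list[dict]:
    """All windows of one sequence reaching the relative-score threshold."""
    if len(sequence) < pwm.width:
        logger.info("sequence %s shorter than matrix %s (width %d): no hits",
                    name, pwm.protein_name, pwm.width)
        return []
    codes = encode_rna(sequence)
    s_min, s_max = pwm.score_range
    if s_max == s_min:
        raise ValidationError(f"degenerate matrix {pwm.protein_name}")
    windows = np.lib.stride_tricks.sliding_window_view(codes, pwm.width)
    scores = pwm.weights[np.arange(pwm.width), windows].sum(axis=1)
    rel = (scores - s_min) / (s_max - s_min)
    # tiny tolerance so windows scoring exactly at the threshold survive rounding
    keep = np.flatnonzero(rel >= threshold - 1e-12)
    seq_rna = sequence.upper().replace("T", "U")
    return [
        {
            "protein_name": pwm.protein_name,
            "sequence_name": name,
            "offset": int(i) + 1,
            "site": seq_rna[i:i + pwm.width],
            "relative_score": float(rel[i]),
        }
        for i in keep
    ]


def scan_rbp(
    pwms: Sequence[PWM],
    sequences: Sequence[tuple[str, str]] | Mapping[str, str],
    threshold: float = 0.8,
) -> tuple[pd.DataFrame, dict[str, set[str]], set[str]]:
    """Scan every sequence with every matrix.

    Returns the hit table, the per-sequence protein sets, and the proteins
    shared by ALL sequences (intersection of the per-sequence sets).
    """
    if isinstance(sequences, Mapping):
        sequences = list(sequences.items())
    if not sequences:
        raise ValidationError("no sequences to scan")
    rows: list[dict] = []
    per_seq: dict[str, set[str]] = {name: set() for name, _ in sequences}
    for name, seq in sequences:
        for pwm in pwms:
            hits = scan_sequence(pwm, name, seq, threshold)
            rows.extend(hits)
            if hits:
                per_seq[name].add(pwm.protein_name)
    table = pd.DataFrame(
        rows, columns=["protein_name", "sequence_name", "offset", "site",
                       "relative_score"]
    )
    shared = set.intersection(*per_seq.values()) if per_seq else set()
    return table, per_seq, shared


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def parse_pwm_file(path: str | Path, kind: str = "auto") -> list[PWM]:
    """Read a TRANSFAC-like matrix file.

    Records are separated by ``//``; each has a ``NA <name>`` line, an
    optional ``P0 A C G U`` column header, and numbered position rows with
    four values.  ``kind`` selects the interpretation: ``logodds`` (used
    directly), ``counts`` (converted), or ``auto`` — treated as counts when
    every value is non-negative.
    """
    if kind not in ("auto", "logodds", "counts"):
        raise ValidationError(f"unknown PWM kind {kind!r}")
    pwms: list[PWM] = []
    name: str | None = None
    rows: list[list[float]] = []
    order = list(RNA_ALPHABET)

    def flush() -> None:
        nonlocal name, rows, order
        if name is None and not rows:
            return
        if name is None or not rows:
            raise SchemaError("PWM record missing name or matrix rows")
        mat = np.array(rows, dtype=float)
        perm = [order.index(c) for c in RNA_ALPHABET]
        mat = mat[:, perm]
        as_counts = kind == "counts" or (kind == "auto" and np.all(mat >= 0))
        pwms.append(PWM.from_counts(name, mat) if as_counts else PWM(name, mat))
        name, rows, order = None, [], list(RNA_ALPHABET)

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("//"):
            flush()
        elif line.startswith(("NA", "ID")):
            name = line.split(None, 1)[1].strip()
        elif line.startswith(("P0", "PO")):
            letters = [t.upper().replace("T", "U") for t in line.split()[1:5]]
            if sorted(letters) != sorted(RNA_ALPHABET):
                raise SchemaError(f"unsupported PWM alphabet {letters}")
            order = letters
        elif line[0].isdigit() or line[0] in "+-.":
            parts = line.split()
            vals = parts[1:5] if len(parts) >= 5 and parts[0].isdigit() else parts[:4]
            if len(vals) != 4:
                raise SchemaError(f"PWM row needs 4 values: {line!r}")
            rows.append([float(v) for v in vals])
    flush()
    if not pwms:
        raise SchemaError(f"no PWM records found in {path}")
    return pwms


def write_pwm_file(pwms: Sequence[PWM], path: str | Path) -> None:
    """Write matrices in the TRANSFAC-like layout read by parse_pwm_file."""
    chunks = []
    for pwm in pwms:
        lines = [f"NA  {pwm.protein_name}", "P0      A       C       G       U"]
        for i, row in enumerate(pwm.weights, start=1):
            lines.append(f"{i:02d}  " + "  ".join(f"{v:.6f}" for v in row))
        lines.append("//")
        chunks.append("\n".join(lines))
    Path(path).write_text("\n".join(chunks) + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
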