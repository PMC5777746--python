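"""Gene-level collapsing, cross-dataset intersection and ΔΔCt arithmetic.

Probe-level differential calls are collapsed to genes by unanimity: a gene
is up (down) only when every called probe agrees; disagreeing probes make
the gene ``ambiguous``, which is reported but excluded from concordance.
Two datasets are then intersected on the gene key, and each shared gene is
labelled concordant or discordant.  The ΔΔCt helper implements the
standard relative-quantification arithmetic used to validate array calls
by qPCR.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from lncarray.errors import IntegrityError, ValidationError
from lncarray import de as de_mod

AMBIGUOUS = "ambiguous"
CONCORDANT = "concordant"
DISCORDANT = "discordant"


def collapse_to_genes(
    de_table: pd.DataFrame,
    gene_map: Mapping[str, str],
    dataset_id: str,
) -> pd.DataFrame:
    """Collapse called probes to one record per gene.

    ``gene_map`` maps probe_set_id → gene key (typically the catalog's
    symbol-or-Ensembl-id mapping).  Probes with direction ``none`` are
    dropped first; remaining probes of a gene must be unanimous for a
    directional call, otherwise the gene is ``ambiguous``.

    Returns columns gene_symbol, dataset_id, direction, supporting_probe_ids
    (comma-joined), mean_log2fc.
    """
    called = de_table[de_table["direction"] != de_mod.NO_CALL]
    missing = [p for p in called["probe_set_id"] if p not in gene_map]
    if missing:
        raise IntegrityError(f"DE probes absent from catalog: {missing}")
    rows = []
    genes = sorted({gene_map[p] for p in called["probe_set_id"]})
    by_gene = {g: [] for g in genes}
    for rec in called.itertuples(index=False):
        by_gene[gene_map[rec.probe_set_id]].append(rec)
    for gene in genes:
        recs = by_gene[gene]
        directions = {r.direction for r in recs}
        direction = directions.pop() if len(directions) == 1 else AMBIGUOUS
        rows.append(
            {
                "gene_symbol": gene,
                "dataset_id": dataset_id,
                "direction": direction,
                "supporting_probe_ids": ",".join(sorted(r.probe_set_id for r in recs)),
                "mean_log2fc": float(np.mean([r.log2fc for r in recs])),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_symbol", "dataset_id", "direction",
                       "supporting_probe_ids", "mean_log2fc"]
    )


def intersect_shared(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Inner-join two gene-level tables into the shared-lncRNA table.

    Output columns: gene_symbol, direction_a, direction_b, concordance
    (``concordant`` iff both directions are equal and neither is
    ambiguous), sorted by gene_symbol.
    """
    if not len(a) or not len(b):
        return pd.DataFrame(columns=["gene_symbol", "direction_a", "direction_b",
                                     "concordance"])
    ids_a, ids_b = set(a["dataset_id"]), set(b["dataset_id"])
    if ids_a & ids_b:
        raise ValidationError("tables must come from distinct datasets")
    merged = a.merge(b, on="gene_symbol", suffixes=("_a", "_b"))
    concordance = np.where(
        (merged["direction_a"] == merged["direction_b"])
        & (merged["direction_a"] != AMBIGUOUS),
        CONCORDANT,
        DISCORDANT,
    )
    out = pd.DataFrame(
        {
            "gene_symbol": merged["gene_symbol"],
            "direction_a": merged["direction_a"],
            "direction_b": merged["direction_b"],
            "concordance": concordance,
        }
    )
    return out.sort_values("gene_symbol", ignore_index=True)


@dataclass(frozen=True)
class DdctResult:
    """Relative expression of a target gene by the 2^(−ΔΔCt) method."""

    target_case_ct: float
    target_control_ct: float
    reference_case_ct: float
    reference_control_ct: float
    delta_delta_ct: float
    relative_expression: float


def ddct_relative_expression(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    case_label: str = "case",
    control_label: str = "control",
) -> DdctResult:
    """ΔΔCt over replicate means: (Ct_t − Ct_ref)_case − (Ct_t − Ct_ref)_ctrl.

    ``ct`` needs columns sample, group, gene, ct.  The relative expression
    is 2^(−ΔΔCt), so a target amplifying one cycle earlier in cases (with
    the reference unchanged) doubles.
    """
    for col in ("group", "gene", "ct"):
        if col not in ct.columns:
            raise ValidationError(f"Ct table missing column {col!r}")

    def cell_mean(gene: str, group: str) -> float:
        vals = ct.loc[(ct["gene"] == gene) & (ct["group"] == group), "ct"]
        if vals.empty:
            which = "reference" if gene == reference else "target"
            raise ValidationError(f"no Ct replicates for {which} gene {gene!r} "
                                  f"in group {group!r}")
        return float(vals.mean())

    t_case = cell_mean(target, case_label)
    t_ctrl = cell_mean(target, control_label)
    r_case = cell_mean(reference, case_label)
    r_ctrl = cell_mean(reference, control_label)
    ddct = (t_case - r_case) - (t_ctrl - r_ctrl)
    return DdctResult(
        target_case_ct=t_case,
        target_control_ct=t_ctrl,
        reference_case_ct=r_case,
        reference_control_ct=r_ctrl,
        delta_delta_ct=ddct,
        relative_expression=2.0 ** (-ddct),
    )
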