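"""Threshold-based differential-expression screening and sample clustering.

A probe set is called differentially expressed only when three conditions
hold jointly: BH-adjusted FDR below 20%, two-sided pooled-variance Student
t-test p-value below 0.01, and a linear fold change of at least 2 (i.e.
|log2 fold change| ≥ 1).  The defaults encode exactly those thresholds;
all three are configurable.

Sample structure is inspected with agglomerative average-linkage
clustering, by default on the 1 − Pearson-correlation distance between
samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from lncarray.errors import ValidationError
from lncarray.preprocess import ProbesetExpressionMatrix

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
NO_CALL = "none"


@dataclass(frozen=True)
class DEThresholds:
    """The three conjunctive screening thresholds."""

    fdr_max: float = 0.20       # adjusted FDR must be < fdr_max
    fold_min: float = 2.0       # linear fold change must be >= fold_min
    p_max: float = 0.01         # raw p-value must be < p_max

    def __post_init__(self) -> None:
        if not (0 < self.fdr_max <= 1):
            raise ValidationError("fdr_max must be in (0, 1]")
        if self.fold_min < 1:
            raise ValidationError("fold_min must be >= 1")
        if not (0 < self.p_max <= 1):
            raise ValidationError("p_max must be in (0, 1]")

    @property
    def log2_fold_min(self) -> float:
        return math.log2(self.fold_min)


class TTestResult(NamedTuple):
    log2fc: float
    t_stat: float
    p_value: float
    degenerate: bool = False


def probe_t_test(case: Sequence[float], control: Sequence[float]) -> TTestResult:
    """Two-sided pooled-variance Student t-test on log2 expression values.

    ``log2fc`` is mean(case) − mean(control).  Zero pooled variance is
    degenerate: equal means give t = 0, p = 1; unequal means give the p = 0
    sentinel with the ``degenerate`` flag set.
    """
    x = np.asarray(case, dtype=float)
    y = np.asarray(control, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValidationError("each group needs at least 2 samples")
    log2fc = float(x.mean() - y.mean())
    df = x.size + y.size - 2
    pooled_var = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / df
    if pooled_var == 0.0:
        if log2fc == 0.0:
            return TTestResult(0.0, 0.0, 1.0, degenerate=True)
        return TTestResult(log2fc, math.copysign(math.inf, log2fc), 0.0, degenerate=True)
    se = math.sqrt(pooled_var * (1.0 / x.size + 1.0 / y.size))
    t = log2fc / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(log2fc, float(t), float(p))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _row_t_tests(case: np.ndarray, control: np.ndarray) -> tuple[np.ndarray, ...]:
    """Vectorised pooled t-test across matrix rows (same semantics as
    :func:`probe_t_test`)."""
    n1, n2 = case.shape[1], control.shape[1]
    df = n1 + n2 - 2
    log2fc = case.mean(axis=1) - control.mean(axis=1)
    pooled = ((n1 - 1) * case.var(axis=1, ddof=1)
              + (n2 - 1) * control.var(axis=1, ddof=1)) / df
    se = np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = log2fc / se
    degenerate = se == 0.0
    t = np.where(degenerate & (log2fc == 0), 0.0, t)
    p = np.where(
        degenerate,
        np.where(log2fc == 0, 1.0, 0.0),
        2.0 * stats.t.sf(np.abs(np.where(degenerate, 0.0, t)), df),
    )
    return log2fc, t, p, degenerate


def screen_de(
    expr: ProbesetExpressionMatrix,
    thresholds: DEThresholds | None = None,
    case_label: str = "case",
    control_label: str = "control",
) -> pd.DataFrame:
    """Screen every probe set against the three DE thresholds.

    Returns a table with columns probe_set_id, log2fc, t, p, fdr and
    direction (``up``/``down``/``none``); direction is non-none iff
    fdr < fdr_max AND p < p_max AND |log2fc| ≥ log2(fold_min).
    """
    thresholds = thresholds or DEThresholds()
    labels = np.asarray(expr.group_labels)
    case_idx = np.flatnonzero(labels == case_label)
    ctrl_idx = np.flatnonzero(labels == control_label)
    if case_idx.size == 0 or ctrl_idx.size == 0:
        raise ValidationError(
            f"both groups required; found {sorted(set(labels))}"
        )
    if case_idx.size < 2 or ctrl_idx.size < 2:
        raise ValidationError("each group needs at least 2 samples")
    log2fc, t, p, _ = _row_t_tests(expr.values[:, case_idx], expr.values[:, ctrl_idx])
    fdr = bh_fdr(p)
    called = (
        (fdr < thresholds.fdr_max)
        & (p < thresholds.p_max)
        & (np.abs(log2fc) >= thresholds.log2_fold_min)
    )
    direction = np.where(called, np.where(log2fc > 0, UP, DOWN), NO_CALL)
    return pd.DataFrame(
        {
            "probe_set_id": expr.probeset_ids,
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "fdr": fdr,
            "direction": direction,
        }
    )


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Average-linkage merge tree over samples."""

    linkage: np.ndarray             # scipy linkage matrix
    sample_ids: list[str]           # leaf order as passed to linkage
    distance: str                   # metric actually used

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int = 2) -> dict[str, int]:
        """k-group cut; returns sample_id → cluster label (1-based)."""
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.sample_ids, labels.tolist()))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def build(node, parent_height: float) -> str:
            length = parent_height - (node.dist if not node.is_leaf() else 0.0)
            if node.is_leaf():
                return f"{self.sample_ids[node.id]}:{length:.10g}"
            left = build(node.left, node.dist)
            right = build(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return f"({build(tree.left, tree.dist)},{build(tree.right, tree.dist)});"


def average_linkage_cluster(
    expr: ProbesetExpressionMatrix, distance: str = "correlation"
) -> Dendrogram:
    """Agglomerative average-linkage clustering of samples.

    ``distance="correlation"`` uses 1 − Pearson correlation between sample
    expression profiles; a constant matrix makes correlation undefined, in
    which case the metric falls back to Euclidean with a warning.  Samples
    are ordered lexicographically before clustering so that ties in merge
    order resolve deterministically.
    """
    if len(expr.sample_ids) < 2:
        raise ValidationError("clustering needs at least 2 samples")
    order = np.argsort(np.asarray(expr.sample_ids, dtype=object))
    ids = [expr.sample_ids[i] for i in order]
    data = expr.values[:, order].T        # samples x probe sets
    metric = distance
    if distance == "correlation" and np.any(data.std(axis=1) == 0):
        logger.warning("constant sample profile: correlation distance undefined, "
                       "falling back to euclidean")
        metric = "euclidean"
    dists = pdist(data, metric=metric)
    linkage = hierarchy.linkage(dists, method="average")
    return Dendrogram(linkage=linkage, sample_ids=ids, distance=metric)
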