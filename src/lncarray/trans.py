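"""Trans-target screening by Spearman rank correlation.

Every differentially expressed lncRNA probe is correlated against every
coding-gene probe across the retained samples (cases and controls
pooled).  A pair is a trans candidate when |rho| ≥ 0.8 and the two-sided
p-value is below 0.05 — the screening thresholds used throughout this
pipeline.

Rho is the Pearson correlation of average ranks.  The p-value uses the
exact permutation null for small sample counts (n ≤ 9, where the t
approximation is poor) and the t approximation above that.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from lncarray.errors import ValidationError

EXACT_MAX_N = 9
POSITIVE = "positive"
NEGATIVE = "negative"


@dataclass(frozen=True)
class TransConfig:
    """Retention thresholds for a candidate pair."""

    rho_min: float = 0.8
    p_max: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.rho_min <= 1):
            raise ValidationError("rho_min must be in (0, 1]")
        if not (0 < self.p_max <= 1):
            raise ValidationError("p_max must be in (0, 1]")


class SpearmanResult(NamedTuple):
    rho: float
    p_value: float
    valid: bool = True


@lru_cache(maxsize=8)
def _permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.int8)


@lru_cache(maxsize=8)
def _tie_free_null(n: int) -> np.ndarray:
    """Sorted null distribution of rho over all n! rank permutations
    (no ties)."""
    ranks = np.arange(1, n + 1, dtype=float)
    perms = _permutations(n)
    rho = _rho_from_ranks(ranks, ranks[perms])
    return np.sort(rho)


def _rho_from_ranks(xr: np.ndarray, yr: np.ndarray) -> np.ndarray:
    """Pearson correlation of rank vectors; yr may be a matrix of rows."""
    xc = xr - xr.mean()
    yc = yr - yr.mean(axis=-1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum(axis=-1))
    return (yc @ xc) / denom


def _exact_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value, P(|rho_perm| >= |rho_obs|)."""
    n = xr.size
    tol = 1e-12
    tied = (np.unique(xr).size < n) or (np.unique(yr).size < n)
    if not tied:
        null = _tie_free_null(n)
        count = int(np.count_nonzero(np.abs(null) >= abs(rho_obs) - tol))
        return count / null.size
    perms = _permutations(n)
    rho = _rho_from_ranks(xr, yr[perms])
    return float(np.mean(np.abs(rho) >= abs(rho_obs) - tol))


def spearman(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    Returns ``valid=False`` (rho and p NaN) when either vector is constant,
    where the coefficient is undefined.  Exact enumeration supplies the
    p-value for n ≤ 9; the two-sided t approximation is used above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValidationError("vectors must have equal length")
    n = x.size
    if n < 3:
        raise ValidationError("spearman needs at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return SpearmanResult(math.nan, math.nan, valid=False)
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    rho = float(_rho_from_ranks(xr, yr))
    if n <= EXACT_MAX_N:
        p = _exact_p(xr, yr, rho)
    else:
        p = _t_approx_p(np.array([rho]), n)[0]
    return SpearmanResult(rho, float(p))


def _t_approx_p(rho: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def find_trans_targets(
    lnc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    cfg: TransConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Test every lncRNA-probe × gene-probe pair; keep pairs passing both
    thresholds.

    The two matrices (rows = probes, columns = samples) must share their
    sample columns.  Returns the retained-pair table (lncrna_probe_id,
    gene_probe_id, rho, p, sign) and the positive/negative tallies.
    Constant probe rows have undefined rank correlation and never match.
    """
    cfg = cfg or TransConfig()
    if list(lnc_expr.columns) != list(gene_expr.columns):
        raise ValidationError("lncRNA and gene matrices must share sample columns")
    n = lnc_expr.shape[1]
    if n < 3:
        raise ValidationError("need at least 3 shared samples")

    lnc_ranks = np.apply_along_axis(stats.rankdata, 1, lnc_expr.to_numpy(dtype=float))
    gene_ranks = np.apply_along_axis(stats.rankdata, 1, gene_expr.to_numpy(dtype=float))

    def standardize(r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        c = r - r.mean(axis=1, keepdims=True)
        norm = np.sqrt((c ** 2).sum(axis=1, keepdims=True))
        ok = norm[:, 0] > 0
        safe = np.where(norm > 0, norm, 1.0)
        return c / safe, ok

    zl, ok_l = standardize(lnc_ranks)
    zg, ok_g = standardize(gene_ranks)
    rho = zl @ zg.T                       # lnc probes x gene probes
    valid = np.outer(ok_l, ok_g)

    candidate = valid & (np.abs(rho) >= cfg.rho_min)
    rows = []
    li_idx, gi_idx = np.nonzero(candidate)
    for li, gi in zip(li_idx, gi_idx):
        r = float(rho[li, gi])
        if n <= EXACT_MAX_N:
            p = _exact_p(lnc_ranks[li], gene_ranks[gi], r)
        else:
            p = float(_t_approx_p(np.array([r]), n)[0])
        if p < cfg.p_max:
            rows.append(
                {
                    "lncrna_probe_id": str(lnc_expr.index[li]),
                    "gene_probe_id": str(gene_expr.index[gi]),
                    "rho": r,
                    "p": p,
                    "sign": POSITIVE if r > 0 else NEGATIVE,
                }
            )
    table = pd.DataFrame(
        rows, columns=["lncrna_probe_id", "gene_probe_id", "rho", "p", "sign"]
    )
    tallies = {
        POSITIVE: int((table["sign"] == POSITIVE).sum()) if len(table) else 0,
        NEGATIVE: int((table["sign"] == NEGATIVE).sum()) if len(table) else 0,
        "total": len(table),
    }
    return table, tallies
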