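"""Spearman screening of features against log-EMP levels.

Each expressed miRNA is tested for monotone association with the
(log-transformed) circulating EMP count; candidates are selected at
raw p < alpha (0.05), with Benjamini-Hochberg q-values reported alongside
for transparency and an optional q-based selection mode.

The Spearman statistic is the Pearson correlation of mid-ranks.  P-values
use the t approximation ``t = rho * sqrt((n-2) / (1-rho^2))`` for n >= 10
and exact enumeration of all n! rank permutations below that; a perfect
monotone relationship gets the exact permutation value 2/n!.
"""

from __future__ import annotations

import itertools
import math
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ioformats import ExpressionMatrix

__all__ = ["spearman", "bh_adjust", "screen"]

_EXACT_N_MAX = 9  # below 10 samples, enumerate all rank permutations


class ConstantInputError(ValueError):
    """Correlation is undefined for a constant vector."""


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


@lru_cache(maxsize=8)
def _all_permutations(n: int) -> np.ndarray:
    return np.array(list(itertools.permutations(range(n))), dtype=np.intp)


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("correlation undefined for a constant vector")

    rx, ry = _midranks(x), _midranks(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])

    if abs(rho) >= 1.0 - 1e-12:
        return float(np.sign(rho)), 2.0 / math.factorial(n)

    if n <= _EXACT_N_MAX:
        perms = _all_permutations(n)
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float((rxc**2).sum() * (ryc**2).sum()))
        stats_all = (ryc[perms] @ rxc) / denom
        p = float((np.abs(stats_all) >= abs(rho) - 1e-12).mean())
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
    return rho, min(1.0, p)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), clipped to 1."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def screen(
    expr: ExpressionMatrix,
    samples: pd.DataFrame,
    alpha: float = 0.05,
    use_fdr: bool = False,
) -> pd.DataFrame:
    """Screen every feature for Spearman association with log-EMP.

    Returns one row per feature: ``feature_id, rho, p, q, selected``.
    Constant features yield NA rows (detection-filtered real data can
    contain them) rather than aborting the screen.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if "log_emp" not in samples.columns:
        raise ValueError("sample table lacks log_emp; run log_transform_emp first")
    order = {s: i for i, s in enumerate(samples["sample_id"])}
    missing = [s for s in expr.sample_ids if s not in order]
    if missing:
        raise ValueError(f"samples missing from the sample table: {missing[:5]}")
    log_emp = samples.set_index("sample_id").loc[expr.sample_ids, "log_emp"].to_numpy()

    rows = []
    for i, fid in enumerate(expr.feature_ids):
        try:
            rho, p = spearman(expr.values[i], log_emp)
        except ConstantInputError:
            rows.append({"feature_id": fid, "rho": np.nan, "p": np.nan})
            continue
        rows.append({"feature_id": fid, "rho": rho, "p": p})
    table = pd.DataFrame(rows, columns=["feature_id", "rho", "p"])

    q = np.full(len(table), np.nan)
    valid = table["p"].notna().to_numpy()
    if valid.any():
        q[valid] = bh_adjust(table.loc[valid, "p"].to_numpy())
    table["q"] = q
    crit = table["q"] if use_fdr else table["p"]
    table["selected"] = crit.lt(alpha).fillna(False)
    return table
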