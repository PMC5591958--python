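"""Detection filtering, EMP transformation and cohort-level EMP comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ioformats import ExpressionMatrix

__all__ = [
    "FilterReport",
    "filter_expressed",
    "log_transform_emp",
    "compare_emp_groups",
]


@dataclass
class FilterReport:
    n_input: int
    n_expressed: int
    kept_ids: list[str]
    threshold_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "n_input": [self.n_input],
                "n_expressed": [self.n_expressed],
                "threshold_fraction": [self.threshold_fraction],
            }
        )


def filter_expressed(
    expr: ExpressionMatrix, min_fraction: float = 0.05
) -> tuple[ExpressionMatrix, FilterReport]:
    """Keep features detected in at least ``min_fraction`` of the samples.

    The boundary is inclusive ("at least"): with 20 samples a feature
    detected in exactly one (5%) is kept.  Idempotent; feature order
    preserved.
    """
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError(f"min_fraction must be in (0, 1], got {min_fraction}")
    if expr.n_samples == 0:
        raise ValueError("expression matrix has no samples")
    frac = expr.detected.sum(axis=1) / expr.n_samples
    kept = [f for f, ok in zip(expr.feature_ids, frac >= min_fraction) if ok]
    filtered = expr.subset(kept)
    report = FilterReport(
        n_input=expr.n_features,
        n_expressed=len(kept),
        kept_ids=kept,
        threshold_fraction=min_fraction,
    )
    return filtered, report


def log_transform_emp(samples: pd.DataFrame) -> pd.DataFrame:
    """Add/refresh the natural-log EMP column (counts are right-skewed)."""
    out = samples.copy()
    bad = out["emp_per_ul"] <= 0
    if bad.any():
        sid = out.loc[bad, "sample_id"].iloc[0]
        raise ValueError(f"non-positive EMP count for sample {sid!r}")
    out["log_emp"] = np.log(out["emp_per_ul"].to_numpy(dtype=float))
    return out


def compare_emp_groups(samples: pd.DataFrame) -> dict:
    """One-way ANOVA on log-EMP across groups plus Tukey HSD pairwise tests.

    Degenerate all-equal input (zero variance within and between groups)
    returns F=0, p=1 instead of erroring, so synthetic edge cases do not
    crash pipelines.
    """
    if "log_emp" not in samples.columns:
        samples = log_transform_emp(samples)
    grouped = {g: df["log_emp"].to_numpy(dtype=float) for g, df in samples.groupby("group", observed=True)}
    if len(grouped) < 2:
        raise ValueError("need at least two groups")
    small = [g for g, v in grouped.items() if v.size < 2]
    if small:
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")
    values = list(grouped.values())
    labels = list(grouped.keys())

    pooled = np.concatenate(values)
    if np.ptp(pooled) == 0:
        tukey = _tukey_frame(labels, None)
        return {"F": 0.0, "p": 1.0, "tukey": tukey}

    f_stat, p_val = stats.f_oneway(*values)
    res = stats.tukey_hsd(*values)
    tukey = _tukey_frame(labels, res)
    return {"F": float(f_stat), "p": float(p_val), "tukey": tukey}


def _tukey_frame(labels: list[str], res) -> pd.DataFrame:
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append(
                {
                    "group_a": labels[i],
                    "group_b": labels[j],
                    "diff": float(res.statistic[i, j]) if res is not None else 0.0,
                    "p": float(res.pvalue[i, j]) if res is not None else 1.0,
                }
            )
    return pd.DataFrame(rows, columns=["group_a", "group_b", "diff", "p"])
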