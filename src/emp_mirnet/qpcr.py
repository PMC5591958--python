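"""Relative quantification of qPCR validation assays (2^-ddCt).

Each target miRNA is normalized to an endogenous control (U6 snRNA by
default): dCt = Ct_target - Ct_reference.  ddCt references the mean dCt of
a control group (the healthy TAV cohort by default), so fold change =
2^-ddCt and log2 fold change = -ddCt.  Technical replicates, if present,
are averaged on the Ct scale before dCt.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assoc import spearman

__all__ = ["fold_change", "validate_correlations", "read_ct", "write_ct"]

REQUIRED_CT_COLUMNS = {
    "sample_id", "target_id", "reference_id", "ct_target", "ct_reference", "group",
}


def _validate_ct(ct: pd.DataFrame) -> pd.DataFrame:
    missing = REQUIRED_CT_COLUMNS - set(ct.columns)
    if missing:
        raise ValueError(f"Ct table lacks columns {sorted(missing)}")
    bad = ~np.isfinite(ct["ct_target"]) | ~np.isfinite(ct["ct_reference"])
    if bad.any():
        sid = ct.loc[bad, "sample_id"].iloc[0]
        raise ValueError(f"non-finite Ct for sample {sid!r}")
    if (ct["ct_target"] < 0).any() or (ct["ct_reference"] < 0).any():
        raise ValueError("negative cycle thresholds")
    return ct


def fold_change(ct: pd.DataFrame, reference_group: str = "TAV") -> pd.DataFrame:
    """Per-sample, per-target relative expression via 2^-ddCt.

    ddCt = 1 halves the fold change; ddCt = -1 doubles it.  Samples in the
    reference group average to log2 fold change 0 by construction.
    """
    ct = _validate_ct(ct)
    # technical replicates: average on the Ct scale
    ct = (
        ct.groupby(["sample_id", "target_id", "reference_id", "group"], sort=True, observed=True)
        [["ct_target", "ct_reference"]]
        .mean()
        .reset_index()
    )
    if not (ct["group"] == reference_group).any():
        raise ValueError(f"reference group {reference_group!r} has no samples")

    out = ct.copy()
    out["delta_ct"] = out["ct_target"] - out["ct_reference"]
    ref_means = (
        out[out["group"] == reference_group]
        .groupby("target_id", observed=True)["delta_ct"]
        .mean()
    )
    missing_ref = sorted(set(out["target_id"]) - set(ref_means.index))
    if missing_ref:
        raise ValueError(
            f"target(s) without reference-group wells: {missing_ref[:5]}"
        )
    out["delta_delta_ct"] = out["delta_ct"] - out["target_id"].map(ref_means)
    out["fold_change"] = 2.0 ** (-out["delta_delta_ct"])
    out["log2_fc"] = -out["delta_delta_ct"]
    return out


def validate_correlations(
    fold_changes: pd.DataFrame, samples: pd.DataFrame, use: str = "log2_fc"
) -> pd.DataFrame:
    """Spearman correlation of each target's relative expression vs log-EMP.

    ``use`` selects the quantity correlated with log-EMP: ``log2_fc``
    (default) or ``delta_ct`` (both are monotone transforms of one
    another, so rho differs only in sign convention).
    """
    if use not in ("log2_fc", "delta_ct"):
        raise ValueError("use must be 'log2_fc' or 'delta_ct'")
    if "log_emp" not in samples.columns:
        raise ValueError("sample table lacks log_emp; run log_transform_emp first")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicated sample row {dup!r}")
    log_emp = samples.set_index("sample_id")["log_emp"]

    rows = []
    for target, df in fold_changes.groupby("target_id", sort=True, observed=True):
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicated sample row {dup!r} for target {target!r}")
        matched = df[df["sample_id"].isin(log_emp.index)]
        if len(matched) < 4:
            raise ValueError(
                f"target {target!r}: only {len(matched)} samples match the sample table"
            )
        rho, p = spearman(
            matched[use].to_numpy(),
            log_emp.loc[matched["sample_id"]].to_numpy(),
        )
        rows.append({"target_id": target, "rho": rho, "p": p, "n": len(matched)})
    return pd.DataFrame(rows, columns=["target_id", "rho", "p", "n"])


def read_ct(path: str) -> pd.DataFrame:
    ct = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return _validate_ct(ct)


def write_ct(ct: pd.DataFrame, path: str) -> None:
    ct.to_csv(path, sep="\t", index=False)
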