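"""Relative qPCR quantification by the 2^-ΔΔCt method.

ΔCt is the target gene's mean Ct minus the geometric mean Ct of the
reference genes (default GAPDH and TBP) within the same sample; ΔΔCt is the
condition-mean ΔCt minus the control-condition mean; relative expression is
2^-ΔΔCt, assuming perfect (factor-2 per cycle) amplification efficiency.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

__all__ = ["validate_ct_table", "delta_ct", "fold_change_ddct"]

REQUIRED_COLUMNS = ("gene", "sample", "condition", "replicate", "ct")
DEFAULT_REFERENCES = ("GAPDH", "TBP")


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if (table["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return table


def delta_ct(
    table: pd.DataFrame, ref_genes: Sequence[str] = DEFAULT_REFERENCES
) -> pd.DataFrame:
    """Per-(gene, sample) ΔCt against the geometric-mean reference baseline.

    Technical replicates are averaged per (gene, sample) first; the
    reference baseline for a sample is the geometric mean of its reference
    genes' mean Cts.  Raises when a sample lacks any reference gene, naming
    the sample.
    """
    validate_ct_table(table)
    ref_genes = list(ref_genes)
    mean_ct = (
        table.groupby(["gene", "sample", "condition"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    baselines = {}
    for sample, sub in mean_ct.groupby("sample", sort=False):
        refs = sub[sub["gene"].isin(ref_genes)]
        if set(refs["gene"]) != set(ref_genes):
            absent = sorted(set(ref_genes) - set(refs["gene"]))
            raise ValueError(
                f"sample {sample!r} is missing reference gene(s) {absent}"
            )
        baselines[sample] = float(gmean(refs["ct"]))
    targets = mean_ct[~mean_ct["gene"].isin(ref_genes)].copy()
    targets["delta_ct"] = targets["ct"] - targets["sample"].map(baselines)
    return targets[["gene", "sample", "condition", "delta_ct"]]


def fold_change_ddct(
    dct: pd.DataFrame, control_condition: str, per_sample: bool = False
) -> pd.DataFrame:
    """Per-gene fold changes 2^-ΔΔCt relative to the control condition.

    Default mode compares condition means of ΔCt; ``per_sample=True``
    instead averages 2^-ΔΔCt computed per sample against the control mean,
    preserving between-replicate spread for downstream group tests.
    """
    if control_condition not in set(dct["condition"]):
        raise ValueError(f"control condition {control_condition!r} not in table")
    rows = []
    for gene, sub in dct.groupby("gene", sort=False):
        ctrl = sub[sub["condition"] == control_condition]["delta_ct"]
        if ctrl.empty:
            raise ValueError(f"gene {gene!r} has no control-condition observations")
        ctrl_mean = float(ctrl.mean())
        for cond, csub in sub.groupby("condition", sort=False):
            if csub.empty:
                raise ValueError(f"condition {cond!r} has no observations")
            if per_sample:
                fc = float(np.mean(2.0 ** -(csub["delta_ct"] - ctrl_mean)))
                ddct = float(np.mean(csub["delta_ct"] - ctrl_mean))
            else:
                ddct = float(csub["delta_ct"].mean() - ctrl_mean)
                fc = float(2.0**-ddct)
            rows.append({"gene": gene, "condition": cond,
                         "delta_delta_ct": ddct, "fold_change": fc})
    return pd.DataFrame(rows)
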