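"""Relative quantification of qPCR data by the 2^-ddCt method and
platform agreement with array fold changes.

Each sample's target Ct is normalized against a housekeeping gene measured
in the same sample (dCt = Ct_target - Ct_housekeeping); the group contrast
ddCt = mean dCt(treated) - mean dCt(control) converts to a fold change
2^-ddCt.  Replicate wells are averaged on the Ct scale first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = ["DeltaDeltaCt", "delta_delta_ct", "platform_concordance"]

CT_COLUMNS = ("sample_id", "group", "gene", "replicate", "ct")


@dataclass
class DeltaDeltaCt:
    gene: str
    dct_treated: float
    dct_control: float
    ddct: float
    fold_change: float
    sd_dct_treated: float
    sd_dct_control: float
    n_treated: int
    n_control: int


def _validate_ct_table(table: pd.DataFrame) -> None:
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"Ct table missing columns: {missing}")
    ct = table["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
        raise ValidationError("Ct values must be finite and > 0")


def delta_delta_ct(
    table: pd.DataFrame, target: str, housekeeping: str = "18S"
) -> DeltaDeltaCt:
    """Group-level ddCt and fold change for one target gene.

    Replicate Cts are averaged per (sample, gene); each sample's dCt is
    target minus housekeeping; group dCt is the mean over samples; the
    reported fold change is ``2**-ddct``.  Missing housekeeping measurements
    are an error naming the sample.
    """
    _validate_ct_table(table)
    mean_ct = (
        table.groupby(["sample_id", "group", "gene"], sort=True)["ct"].mean().reset_index()
    )
    tgt = mean_ct[mean_ct["gene"] == target].set_index("sample_id")
    hk = mean_ct[mean_ct["gene"] == housekeeping].set_index("sample_id")
    if tgt.empty:
        raise ValidationError(f"target gene {target!r} absent from the Ct table")
    missing_hk = sorted(set(tgt.index) - set(hk.index))
    if missing_hk:
        raise ValidationError(
            f"housekeeping gene {housekeeping!r} not measured for sample(s) "
            f"{missing_hk}"
        )
    dct = tgt["ct"] - hk.loc[tgt.index, "ct"]
    group = tgt["group"]
    per_group = {}
    for g in ("control", "treated"):
        vals = dct[group == g]
        if vals.empty:
            raise ValidationError(f"no {g} samples measured for target {target!r}")
        per_group[g] = vals
    dct_c = float(per_group["control"].mean())
    dct_t = float(per_group["treated"].mean())
    ddct = dct_t - dct_c
    return DeltaDeltaCt(
        gene=target,
        dct_treated=dct_t,
        dct_control=dct_c,
        ddct=ddct,
        fold_change=float(2.0 ** (-ddct)),
        sd_dct_treated=float(per_group["treated"].std(ddof=1))
        if len(per_group["treated"]) > 1
        else float("nan"),
        sd_dct_control=float(per_group["control"].std(ddof=1))
        if len(per_group["control"]) > 1
        else float("nan"),
        n_treated=int(len(per_group["treated"])),
        n_control=int(len(per_group["control"])),
    )


def platform_concordance(
    qpcr_folds: pd.Series, array_log2fc: pd.Series
) -> tuple[float, pd.DataFrame]:
    """Direction agreement between qPCR fold changes and array log2FC.

    Compares ``sign(log2 fold_qpcr)`` with ``sign(log2FC_array)`` per shared
    gene; returns the agreement fraction and the paired table.
    """
    shared = sorted(set(qpcr_folds.index) & set(array_log2fc.index))
    if not shared:
        raise ValidationError("no genes shared between qPCR and array results")
    q_sign = np.sign(np.log2(qpcr_folds.loc[shared].to_numpy(dtype=float)))
    a_sign = np.sign(array_log2fc.loc[shared].to_numpy(dtype=float))
    agree = q_sign == a_sign
    table = pd.DataFrame(
        {
            "gene": shared,
            "qpcr_fold": qpcr_folds.loc[shared].to_numpy(),
            "array_log2fc": array_log2fc.loc[shared].to_numpy(),
            "agree": agree,
        }
    )
    return float(agree.mean()), table
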