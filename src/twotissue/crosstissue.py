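"""Cross-tissue concordance: genes similarly differentially regulated (SDRG)
in both the target tissue (heart) and the surrogate tissue (blood PBMC).

A gene qualifies when it passes the significance gates in *both* tissues;
by default it must also change in the same direction — the discordant
remainder is reported separately rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .differential import TissueResult
from .errors import ValidationError

__all__ = ["ConcordanceResult", "ConcordanceSummary", "intersect_sdrg", "concordance_summary"]


@dataclass
class ConcordanceResult:
    """Genes significant in both tissues, partitioned by direction agreement."""

    table: pd.DataFrame          # gene, log2fc/call per tissue, concordant flag
    sdrg: list[str]              # the SDRG list (direction-agreeing by default)
    n_total: int                 # all both-significant genes
    n_up_both: int
    n_down_both: int
    n_discordant: int
    require_same_direction: bool


@dataclass
class ConcordanceSummary:
    pearson_r: float | None
    quadrants: dict[str, int]
    mean_abs_log2fc: dict[str, float]
    table: pd.DataFrame


def intersect_sdrg(
    heart: TissueResult, pbmc: TissueResult, require_same_direction: bool = True
) -> ConcordanceResult:
    """Intersect the two tissues' significant calls on a shared gene universe."""
    gh = set(heart.table.index)
    gp = set(pbmc.table.index)
    if gh != gp:
        diff = len(gh.symmetric_difference(gp))
        raise ValidationError(
            f"gene universes differ between tissues ({diff} genes in the "
            "symmetric difference); run both tissues on the same expressed set"
        )
    h = heart.table
    p = pbmc.table.loc[h.index]
    both = (h["call"] != "ns") & (p["call"] != "ns")
    table = pd.DataFrame(
        {
            "log2fc_heart": h.loc[both, "log2fc"],
            "log2fc_pbmc": p.loc[both, "log2fc"],
            "call_heart": h.loc[both, "call"],
            "call_pbmc": p.loc[both, "call"],
        }
    )
    table["concordant"] = table["call_heart"] == table["call_pbmc"]
    n_up = int(((table["call_heart"] == "up") & table["concordant"]).sum())
    n_down = int(((table["call_heart"] == "down") & table["concordant"]).sum())
    n_disc = int((~table["concordant"]).sum())
    sdrg_mask = table["concordant"] if require_same_direction else pd.Series(
        True, index=table.index
    )
    return ConcordanceResult(
        table=table,
        sdrg=sorted(table.index[sdrg_mask]),
        n_total=int(both.sum()),
        n_up_both=n_up,
        n_down_both=n_down,
        n_discordant=n_disc,
        require_same_direction=require_same_direction,
    )


def concordance_summary(result: ConcordanceResult) -> ConcordanceSummary:
    """Effect-size agreement over the SDRG: correlation, quadrants, magnitudes.

    With fewer than two SDRG the correlation is undefined and reported as
    ``None``.  Mean |log2FC| per tissue makes a "stronger in tissue X"
    statement directly assertable.
    """
    sub = result.table.loc[result.sdrg]
    if len(sub) >= 2 and sub["log2fc_heart"].nunique() > 1 and sub["log2fc_pbmc"].nunique() > 1:
        r = float(np.corrcoef(sub["log2fc_heart"], sub["log2fc_pbmc"])[0, 1])
    else:
        r = None
    quadrants = {
        "up_up": int(((sub["log2fc_heart"] > 0) & (sub["log2fc_pbmc"] > 0)).sum()),
        "down_down": int(((sub["log2fc_heart"] < 0) & (sub["log2fc_pbmc"] < 0)).sum()),
        "up_down": int(((sub["log2fc_heart"] > 0) & (sub["log2fc_pbmc"] < 0)).sum()),
        "down_up": int(((sub["log2fc_heart"] < 0) & (sub["log2fc_pbmc"] > 0)).sum()),
    }
    mean_abs = {
        "heart": float(sub["log2fc_heart"].abs().mean()) if len(sub) else float("nan"),
        "pbmc": float(sub["log2fc_pbmc"].abs().mean()) if len(sub) else float("nan"),
    }
    return ConcordanceSummary(pearson_r=r, quadrants=quadrants, mean_abs_log2fc=mean_abs, table=sub)
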