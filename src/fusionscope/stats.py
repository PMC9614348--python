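"""Shared statistical plumbing: one-way ANOVA with Dunnett-style comparisons.

Per-condition replicate summaries (one value per supported bilayer / experiment)
are compared across conditions by one-way ANOVA, with every condition compared
against the control à la Dunnett.  Used by the fusion-probability, binding and
FLIC distance-change reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["AnovaResult", "one_way_anova_vs_control"]


@dataclass
class AnovaResult:
    """One-way ANOVA across conditions plus per-condition contrasts vs control."""

    f_statistic: float
    p_value: float
    control: str
    comparisons: pd.DataFrame = field(repr=False)  # condition, p_value, significant

    def significant_conditions(self, alpha: float = 0.05) -> list[str]:
        mask = self.comparisons["p_value"] <= alpha
        return list(self.comparisons.loc[mask, "condition"])


def one_way_anova_vs_control(
    groups: dict[str, "np.ndarray | list[float]"],
    control: str,
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way ANOVA over replicate values per condition, Dunnett vs control.

    Parameters
    ----------
    groups : dict
        Condition label -> replicate values (one per independent experiment).
    control : str
        Label of the control condition in ``groups``.
    alpha : float
        Significance level used for the per-condition flags.

    Raises
    ------
    ValueError
        Fewer than two conditions, unknown control, or any condition with
        fewer than two replicates (a single replicate gives no within-group
        variance estimate).
    """
    if control not in groups:
        raise ValueError(f"control condition {control!r} not among groups")
    if len(groups) < 2:
        raise ValueError("need at least two conditions")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.ndim != 1 or v.size < 2:
            raise ValueError(f"condition {k!r} needs >=2 replicates, got {v.size}")

    f_stat, p_val = sps.f_oneway(*arrays.values())
    if not np.isfinite(f_stat):  # all values identical in every group
        f_stat, p_val = 0.0, 1.0

    others = [k for k in arrays if k != control]
    if others:
        with np.errstate(invalid="ignore"):  # zero within-group variance
            res = sps.dunnett(*(arrays[k] for k in others), control=arrays[control])
        pvals = np.asarray(res.pvalue, dtype=float)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)  # degenerate: no evidence
    else:
        pvals = np.empty(0)
    comparisons = pd.DataFrame(
        {
            "condition": others,
            "p_value": pvals,
            "significant": pvals <= alpha,
        }
    )
    return AnovaResult(float(f_stat), float(p_val), control, comparisons)
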