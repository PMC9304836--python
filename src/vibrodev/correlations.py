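"""Inter-task correlation matrices and task-pair ratio trends.

In young adults, tactile development has plateaued, so adult inter-task
correlations reflect person-level coupling between tasks.  Pooling children
and adolescents instead mixes steep shared age trajectories into every
pair, which inflates correlations; comparing the adult matrix with the
under-18 matrix separates the two sources.

Task-pair ratios (e.g. RT/RTVar, sqAD/smAD, TOJ/DD) collapse two outcomes
into one number per observer; regressing each ratio on age asks whether the
two tasks develop at different rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .curves import MEASURES

__all__ = [
    "CorrelationMatrix",
    "RatioTrend",
    "DEFAULT_RATIO_PAIRS",
    "correlation_matrix",
    "ratio_vs_age",
    "ratio_trend_table",
]

#: canonical task pairs for the ratio-versus-age analysis
DEFAULT_RATIO_PAIRS: tuple[tuple[str, str], ...] = (
    ("RT", "RTVar"),
    ("RT", "sqAD"),
    ("RT", "smAD"),
    ("RT", "TOJ"),
    ("RT", "DD"),
    ("sqAD", "smAD"),
    ("sqAD", "TOJ"),
    ("TOJ", "DD"),
)

ADULT_AGE_CUTOFF = 18.0


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations over a cohort subgroup."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    subgroup: str

    def offdiagonal_abs(self) -> np.ndarray:
        """The |r| values of the upper triangle (NaN cells dropped)."""
        values = self.r.to_numpy()
        iu = np.triu_indices_from(values, k=1)
        out = np.abs(values[iu])
        return out[np.isfinite(out)]


def _subgroup_mask(table: pd.DataFrame, subgroup) -> pd.Series:
    if isinstance(subgroup, tuple):
        lo, hi = subgroup
        return (table["age"] >= lo) & (table["age"] < hi)
    if subgroup == "adult":
        return table["age"] >= ADULT_AGE_CUTOFF
    if subgroup == "under-18":
        return table["age"] < ADULT_AGE_CUTOFF
    if subgroup == "all":
        return pd.Series(True, index=table.index)
    raise ValueError(f"unknown subgroup {subgroup!r}")


def correlation_matrix(
    table: pd.DataFrame,
    subgroup="adult",
    measures: Sequence[str] = MEASURES,
    min_n: int = 3,
) -> CorrelationMatrix:
    """Pearson correlation matrix over pairwise-complete observations.

    ``subgroup`` is ``"adult"`` (age >= 18), ``"under-18"``, ``"all"`` or an
    explicit ``(lo, hi)`` age band.  Cells with fewer than ``min_n``
    complete pairs are reported as NaN.
    """
    sub = table[_subgroup_mask(table, subgroup)]
    k = len(measures)
    r = pd.DataFrame(np.eye(k), index=measures, columns=measures)
    p = pd.DataFrame(np.full((k, k), math.nan), index=measures, columns=measures)
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=measures, columns=measures)
    for m in measures:
        n.loc[m, m] = int(sub[m].notna().sum())
    for m1, m2 in combinations(measures, 2):
        pair = sub[[m1, m2]].dropna()
        n.loc[m1, m2] = n.loc[m2, m1] = len(pair)
        if len(pair) < min_n or pair[m1].nunique() < 2 or pair[m2].nunique() < 2:
            r.loc[m1, m2] = r.loc[m2, m1] = math.nan
            continue
        result = stats.pearsonr(pair[m1], pair[m2])
        r.loc[m1, m2] = r.loc[m2, m1] = float(result.statistic)
        p.loc[m1, m2] = p.loc[m2, m1] = float(result.pvalue)
    label = subgroup if isinstance(subgroup, str) else f"{subgroup[0]}-{subgroup[1]}"
    return CorrelationMatrix(r=r, p=p, n=n, subgroup=label)


@dataclass
class RatioTrend:
    """Linear trend of a task-pair outcome ratio against age."""

    pair: tuple[str, str]
    ratios: pd.Series  # indexed by observer_id
    ages: pd.Series
    slope: float
    intercept: float
    p_value: float
    r_value: float
    n_used: int
    n_dropped: int  # rows lost to missing outcomes or non-positive denominators

    @property
    def label(self) -> str:
        return f"{self.pair[0]}/{self.pair[1]}"


def ratio_vs_age(table: pd.DataFrame, pair: tuple[str, str]) -> RatioTrend:
    """OLS regression of the ``numerator/denominator`` ratio on age.

    Rows with a missing outcome or a non-positive denominator are dropped
    (and counted).  Requires at least 4 usable observers.
    """
    num, den = pair
    sub = table[["observer_id", "age", num, den]].dropna()
    usable = sub[sub[den] > 0]
    n_dropped = len(table) - len(usable)
    if len(usable) < 4:
        raise ValueError(f"ratio {num}/{den}: need >= 4 observers, have {len(usable)}")
    ratios = usable[num] / usable[den]
    if np.allclose(ratios, ratios.iloc[0]):
        # constant ratio: slope exactly zero, no sampling distribution
        slope, intercept, r_value, p_value = 0.0, float(ratios.iloc[0]), 0.0, 1.0
    else:
        res = stats.linregress(usable["age"], ratios)
        slope, intercept = float(res.slope), float(res.intercept)
        r_value, p_value = float(res.rvalue), float(res.pvalue)
    return RatioTrend(
        pair=pair,
        ratios=pd.Series(ratios.to_numpy(), index=usable["observer_id"].to_numpy()),
        ages=pd.Series(usable["age"].to_numpy(), index=usable["observer_id"].to_numpy()),
        slope=slope,
        intercept=intercept,
        p_value=p_value,
        r_value=r_value,
        n_used=len(usable),
        n_dropped=n_dropped,
    )


def ratio_trend_table(
    table: pd.DataFrame,
    pairs: Sequence[tuple[str, str]] = DEFAULT_RATIO_PAIRS,
    bonferroni: bool = True,
) -> pd.DataFrame:
    """Trend summary for each task pair (slope, p, optional Bonferroni p)."""
    rows = []
    for pair in pairs:
        try:
            trend = ratio_vs_age(table, pair)
        except ValueError:
            rows.append(
                {
                    "pair": f"{pair[0]}/{pair[1]}",
                    "slope": math.nan,
                    "intercept": math.nan,
                    "p_value": math.nan,
                    "n_used": 0,
                    "n_dropped": len(table),
                }
            )
            continue
        rows.append(
            {
                "pair": trend.label,
                "slope": trend.slope,
                "intercept": trend.intercept,
                "p_value": trend.p_value,
                "n_used": trend.n_used,
                "n_dropped": trend.n_dropped,
            }
        )
    frame = pd.DataFrame(rows)
    if bonferroni:
        frame["p_bonferroni"] = np.minimum(frame["p_value"] * len(pairs), 1.0)
    return frame
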