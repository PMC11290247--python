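"""Reproductive-fitness statistics.

P2 is the proportion of offspring sired by the last male to mate with a
doubly-mated female; in the offense design the focal genotype mates second
(P2 = n_het / (n_het + n_wt) when the focal allele marks heterozygous
offspring), in the defense design it mates first (P2 of the wild-type rival =
n_wt / total).  Clopper-Pearson intervals accompany each estimate.

Fisher's exact two-sided p is computed by the small-p method: sum over the
hypergeometric support of all point probabilities not exceeding the observed
one, with exact integer tie comparison (no floating-point tie tolerance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class GenotypeCounts:
    n_het: int
    n_wt: int
    assay: str  # 'offense' | 'defense'
    replicate: str = "r1"

    def __post_init__(self) -> None:
        if self.n_het < 0 or self.n_wt < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.assay not in ("offense", "defense"):
            raise ValueError("assay must be 'offense' or 'defense'")


@dataclass(frozen=True)
class P2Estimate:
    value: float
    n: int
    ci_low: float
    ci_high: float
    assay: str


@dataclass(frozen=True)
class RetentionRatio:
    n_before: int
    n_after: int

    @property
    def ratio(self) -> float:
        return self.n_after / self.n_before


def p2_estimate(counts: GenotypeCounts, ci_level: float = 0.95) -> P2Estimate:
    """P2 from offspring genotype counts with an exact binomial CI.

    offense: P2 = n_het / (n_het + n_wt); defense: P2 = n_wt / (n_het + n_wt).
    """
    n = counts.n_het + counts.n_wt
    if n == 0:
        raise ValueError("cannot estimate P2 from zero offspring")
    k = counts.n_het if counts.assay == "offense" else counts.n_wt
    ci = stats.binomtest(k, n).proportion_ci(confidence_level=ci_level, method="exact")
    return P2Estimate(k / n, n, ci.low, ci.high, counts.assay)


def p2_pooled(counts: Sequence[GenotypeCounts], ci_level: float = 0.95) -> P2Estimate:
    """P2 over pooled counts across replicates (all same assay)."""
    assays = {c.assay for c in counts}
    if len(assays) != 1:
        raise ValueError("pooled counts must share one assay")
    assay = assays.pop()
    total = GenotypeCounts(sum(c.n_het for c in counts), sum(c.n_wt for c in counts), assay)
    return p2_estimate(total, ci_level)


def retention_ratio(n_before: int, n_after: int) -> RetentionRatio:
    """Sperm-bundle retention = bundles in testes after mating / before."""
    if n_before <= 0:
        raise ValueError("n_before must be positive")
    if n_after < 0:
        raise ValueError("n_after must be non-negative")
    return RetentionRatio(n_before, n_after)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> dict:
    """Two-sided Fisher's exact test on a 2x2 table (small-p method).

    Returns {'p': two-sided p, 'odds_ratio': ad/bc (inf when bc = 0)}.
    Ties between point probabilities are resolved by exact integer
    comparison of hypergeometric weights.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table entries must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if n == 0:
        raise ValueError("at least one positive margin required")
    lo, hi = max(0, c1 - r2), min(c1, r1)
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    w_obs = weights[a]
    num = sum(w for w in weights.values() if w <= w_obs)
    den = sum(weights.values())
    p = num / den
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    if a * d == 0 and b * c == 0:
        odds = math.nan
    return {"p": min(p, 1.0), "odds_ratio": odds}


def student_t(x: Sequence[float], y: Sequence[float], mode: str = "pooled") -> dict:
    """Two-sample t test; pooled-variance by default, Welch optional.

    Returns {'t', 'df', 'p'} (two-sided).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if mode not in ("pooled", "welch"):
        raise ValueError("mode must be 'pooled' or 'welch'")
    if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
        raise ValueError("zero pooled variance: t undefined")
    equal_var = mode == "pooled"
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    if equal_var:
        df = len(x) + len(y) - 2
    else:
        df = float(res.df)
    if np.isnan(res.statistic):
        raise ValueError("zero pooled variance: t undefined")
    return {"t": float(res.statistic), "df": df, "p": float(res.pvalue)}


def competition_gradient_summary(values: pd.DataFrame,
                                 group_col: str = "competition",
                                 time_col: str = "time",
                                 value_col: str = "value",
                                 groups: Sequence[str] = ("none", "low", "high"),
                                 mode: str = "pooled") -> pd.DataFrame:
    """Pairwise t comparisons of expression across competition intensities.

    One row per (time point, group pair) with means, direction label and p.
    Every group must be present at every time point.
    """
    for g in groups:
        if g not in set(values[group_col]):
            raise ValueError(f"missing competition group {g!r}")
    rows = []
    for t, sub in values.groupby(time_col):
        by_group = {g: sub.loc[sub[group_col] == g, value_col].to_numpy() for g in groups}
        for g1, g2 in combinations(groups, 2):
            if len(by_group[g1]) == 0 or len(by_group[g2]) == 0:
                raise ValueError(f"missing group {g1!r} or {g2!r} at time {t!r}")
            res = student_t(by_group[g1], by_group[g2], mode=mode)
            m1, m2 = by_group[g1].mean(), by_group[g2].mean()
            rows.append({
                time_col: t, "group1": g1, "group2": g2,
                "mean1": m1, "mean2": m2,
                "direction": f"{g1}>{g2}" if m1 > m2 else f"{g1}<{g2}" if m1 < m2 else "=",
                "t": res["t"], "p": res["p"],
            })
    return pd.DataFrame(rows)
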