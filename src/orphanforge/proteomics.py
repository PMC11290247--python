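"""Spectral-count proteomics: NSAF abundance, confidence filter, ranking.

NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j) within a run, where SpC is the
spectral count and L the protein length in residues.  Pooled NSAF is computed
from replicate-summed spectral counts by default (a mean-of-replicate-NSAFs
mode is available).  High-confidence proteins are those observed (SpC > 0)
in every replicate.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import TabularDataset
from .repro_stats import student_t


def _wide_counts(counts: TabularDataset) -> pd.DataFrame:
    df = counts.df.pivot(index="protein", columns="replicate", values="spc").fillna(0)
    return df.astype(float)


def compute_nsaf(counts: TabularDataset, lengths: Mapping[str, int],
                 pooled_mode: str = "summed") -> pd.DataFrame:
    """NSAF per replicate plus a pooled column.

    pooled_mode='summed' (default) computes pooled NSAF from replicate-summed
    SpC; 'mean' averages the per-replicate NSAFs and renormalizes.
    Raises if a counted protein has no length.
    """
    wide = _wide_counts(counts)
    missing = [p for p in wide.index if p not in lengths]
    if missing:
        raise ValueError(f"no length for counted protein(s): {missing[:5]}")
    L = pd.Series({p: float(lengths[p]) for p in wide.index})
    saf = wide.div(L, axis=0)
    nsaf = saf.div(saf.sum(axis=0), axis=1)
    out = nsaf.copy()
    out.columns = [f"nsaf_{c}" for c in nsaf.columns]
    if pooled_mode == "summed":
        pooled_saf = wide.sum(axis=1).div(L)
        out["nsaf_pooled"] = pooled_saf / pooled_saf.sum()
    elif pooled_mode == "mean":
        m = nsaf.mean(axis=1)
        out["nsaf_pooled"] = m / m.sum()
    else:
        raise ValueError("pooled_mode must be 'summed' or 'mean'")
    for c in wide.columns:
        out[f"spc_{c}"] = wide[c].astype(int)
    return out


def high_confidence_filter(counts: TabularDataset) -> set[str]:
    """Proteins with SpC > 0 in every replicate."""
    wide = _wide_counts(counts)
    return set(wide.index[(wide > 0).all(axis=1)])


def rank_and_flag(nsaf: pd.DataFrame, top_fraction: float = 0.05) -> pd.DataFrame:
    """Rank by pooled NSAF descending (ties broken by protein id) and flag
    the top ceil(top_fraction * n) proteins as high-abundance."""
    df = nsaf.copy()
    order_idx = np.lexsort((df.index.to_numpy(), -df["nsaf_pooled"].to_numpy()))
    ranked_ids = df.index.to_numpy()[order_idx]
    df["rank"] = pd.Series(np.arange(1, len(df) + 1), index=ranked_ids)
    n = len(df)
    df["percentile"] = df["rank"] / n
    n_flag = int(np.ceil(top_fraction * n))
    df["high_abundance"] = df["rank"] <= n_flag
    return df.sort_values("rank")


def compare_abundance(group_a: Sequence[Sequence[float]],
                      group_b: Sequence[Sequence[float]],
                      protein: str, lengths: Mapping[str, int] | None = None) -> dict:
    """Two-sample t test on per-replicate NSAF values of one protein.

    group_a / group_b are per-replicate NSAF values (e.g. before vs after
    mating).  n = 1 per group is an error (no variance).
    """
    a = np.asarray(group_a, float).ravel()
    b = np.asarray(group_b, float).ravel()
    res = student_t(a, b)
    return {"protein": protein, "mean_a": a.mean(), "mean_b": b.mean(), **res}
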