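"""Expression quantification and the screening filters.

RPKM = 1e9 * C / (N * L) with C mapped reads on the gene, N library size and
L summed exon length in bp.  The screening thresholds are strict: a gene is
expressed when RPKM > 2 in at least one sample, highly expressed when
RPKM > 100 in at least one stage, and stage-specifically high when it is
high in that stage and at least specificity_fold times its maximum anywhere
else.  Relative qPCR quantities use the comparative 2^-ddCt method.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import TabularDataset


@dataclass
class RelativeExpression:
    target: str
    reference: str
    calibrator: str | None
    sample_values: dict[str, float]  # sample -> 2^-ddCt (or 2^-dCt)
    replicate_values: dict[str, list[float]] = field(default_factory=dict)

    def mean(self, sample: str) -> float:
        reps = self.replicate_values.get(sample)
        return float(np.mean(reps)) if reps else self.sample_values[sample]

    def sd(self, sample: str) -> float:
        reps = self.replicate_values.get(sample)
        return float(np.std(reps, ddof=1)) if reps and len(reps) > 1 else 0.0


@dataclass(frozen=True)
class CopyNumberCall:
    gene: str
    ratio: float  # male : female relative copy number
    call: str     # 'Z-linked' | 'autosomal' | 'ambiguous'


def compute_rpkm(read_counts: pd.DataFrame, exon_lengths: Mapping[str, int],
                 library_sizes: Mapping[str, int]) -> TabularDataset:
    """RPKM matrix from a gene x sample count matrix."""
    lengths = pd.Series({g: exon_lengths[g] for g in read_counts.index}, dtype=float)
    libs = pd.Series({s: library_sizes[s] for s in read_counts.columns}, dtype=float)
    rpkm = 1e9 * read_counts.div(lengths, axis=0).div(libs, axis=1)
    return TabularDataset("expression", rpkm)


def filter_expression_classes(expr: TabularDataset, expressed_cut: float = 2.0,
                              high_cut: float = 100.0,
                              specificity_fold: float = 5.0) -> dict[str, object]:
    """Expressed / high / stage-specific-high gene sets (strict thresholds)."""
    df = expr.df
    expressed = set(df.index[(df > expressed_cut).any(axis=1)])
    high = set(df.index[(df > high_cut).any(axis=1)])
    stage_specific: dict[str, set[str]] = {}
    for stage in df.columns:
        others = df.drop(columns=[stage])
        other_max = others.max(axis=1) if others.shape[1] else pd.Series(0.0, index=df.index)
        mask = (df[stage] > high_cut) & (df[stage] >= specificity_fold * other_max)
        stage_specific[stage] = set(df.index[mask])
    return {"expressed": expressed, "high": high, "stage_specific_high": stage_specific}


def relative_expression_ddct(ct: TabularDataset, target: str, reference: str,
                             calibrator: str | None = None) -> RelativeExpression:
    """Comparative 2^-ddCt (or 2^-dCt without a calibrator).

    dCt = Ct_target - Ct_reference per sample (replicate means); with a
    calibrator sample, ddCt = dCt_sample - dCt_calibrator.
    """
    df = ct.df
    samples = sorted(df["sample"].unique())

    def mean_ct(sample: str, gene: str) -> float:
        sub = df[(df["sample"] == sample) & (df["gene"] == gene)]["ct"]
        if sub.empty:
            raise ValueError(f"no Ct for gene {gene!r} in sample {sample!r}")
        return float(sub.mean())

    dct = {s: mean_ct(s, target) - mean_ct(s, reference) for s in samples}
    if calibrator is not None:
        if calibrator not in dct:
            raise ValueError(f"calibrator sample {calibrator!r} not measured")
        values = {s: 2.0 ** (-(dct[s] - dct[calibrator])) for s in samples}
    else:
        values = {s: 2.0 ** (-dct[s]) for s in samples}

    # per-replicate values when replicates align between target and reference
    replicate_values: dict[str, list[float]] = {}
    for s in samples:
        t_sub = df[(df["sample"] == s) & (df["gene"] == target)].set_index("replicate")["ct"]
        r_sub = df[(df["sample"] == s) & (df["gene"] == reference)].set_index("replicate")["ct"]
        common = t_sub.index.intersection(r_sub.index)
        if len(common):
            d = (t_sub.loc[common] - r_sub.loc[common]).astype(float)
            if calibrator is not None:
                vals = 2.0 ** (-(d - dct[calibrator]))
            else:
                vals = 2.0 ** (-d)
            replicate_values[s] = list(vals)
    return RelativeExpression(target, reference, calibrator, values, replicate_values)


def call_z_linkage_from_ratio(gene: str, ratio: float,
                              z_band: tuple[float, float] = (1.5, 8.0 / 3.0),
                              autosomal_band: tuple[float, float] = (0.75, 4.0 / 3.0)) -> CopyNumberCall:
    """Classify a male:female relative copy ratio.

    A Z-linked gene has two copies in males (ZZ) and one in females (ZW),
    hence an expected ratio of 2; an autosomal gene an expected ratio of 1.
    Default bands are symmetric on the log scale (a factor of 4/3 around the
    expected ratio), matching the multiplicative error structure of
    2^-ddCt estimates; ratios between the bands are ambiguous.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    if z_band[0] <= ratio <= z_band[1]:
        call = "Z-linked"
    elif autosomal_band[0] <= ratio <= autosomal_band[1]:
        call = "autosomal"
    else:
        call = "ambiguous"
    return CopyNumberCall(gene, ratio, call)


def call_z_linkage(ct: TabularDataset, gene: str, reference: str,
                   male_sample: str = "male", female_sample: str = "female",
                   **bands) -> CopyNumberCall:
    """Genomic-qPCR Z-linkage call: 2^-ddCt of male vs female against an
    autosomal reference gene, female as calibrator."""
    rel = relative_expression_ddct(ct, gene, reference, calibrator=female_sample)
    return call_z_linkage_from_ratio(gene, rel.sample_values[male_sample], **bands)


def filter_deg_table(deg: pd.DataFrame, p_col: str = "padj",
                     lfc_col: str = "log2fc", p_cut: float = 0.05,
                     lfc_cut: float = 1.5) -> pd.DataFrame:
    """Differential-expression cutoff filter: p < 0.05 and |log2FC| > 1.5,
    both strict.  Takes whichever p column it is given."""
    mask = (deg[p_col] < p_cut) & (deg[lfc_col].abs() > lfc_cut)
    return deg[mask]
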