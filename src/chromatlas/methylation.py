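"""Methylation beta-value classification and group comparison.

Beta values (methylation fraction in [0,1] per CpG per sample) are
classified as hypomethylated (0-0.2), intermediate, or hypermethylated
(0.8-1); boundary betas 0.2 and 0.8 belong to the outer classes.  Promoter
methylation uses windows of TSS +/- 2,000 bp (independent of the +/-1,000
bp activity windows) and averages the betas of CpGs falling inside;
group-wise comparisons use a two-sided Mann-Whitney U test on per-sample
mean levels over a promoter set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .genomic import GenomicInterval, ValidationError

HYPO_MAX = 0.2
HYPER_MIN = 0.8


def classify_beta(beta) -> np.ndarray | str:
    """Classify beta value(s) into hypo/intermediate/hypermethylated."""
    arr = np.asarray(beta, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValidationError("beta values must lie in [0, 1]")
    out = np.where(
        arr <= HYPO_MAX, "hypomethylated",
        np.where(arr >= HYPER_MIN, "hypermethylated", "intermediate"),
    )
    return out.item() if np.isscalar(beta) else out


def read_beta_table(path) -> pd.DataFrame:
    """TSV with columns id, chrom, pos, then one beta column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"id", "chrom", "pos"}
    if required - set(df.columns):
        raise ValidationError("beta table requires id, chrom, pos columns")
    betas = df.drop(columns=["id", "chrom", "pos"])
    if ((betas < 0) | (betas > 1)).any().any():
        raise ValidationError("beta values must lie in [0, 1]")
    return df.set_index("id")


def promoter_methylation(
    betas: pd.DataFrame,
    windows: dict[str, GenomicInterval],
) -> pd.DataFrame:
    """Mean beta per promoter window per sample; promoters whose window
    contains no CpG are omitted.  CpG order is irrelevant."""
    sample_cols = [c for c in betas.columns if c not in ("chrom", "pos")]
    rows = {}
    by_chrom = {c: g for c, g in betas.groupby("chrom")}
    for pid, iv in windows.items():
        g = by_chrom.get(iv.chrom)
        if g is None:
            continue
        inside = g[(g["pos"] >= iv.start) & (g["pos"] < iv.end)]
        if len(inside) == 0:
            continue
        rows[pid] = inside[sample_cols].mean(axis=0)
    return pd.DataFrame(rows).T


def group_methylation_compare(
    pm: pd.DataFrame,
    promoter_set: list[str],
    group_a: list[str],
    group_b: list[str],
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between groups on per-sample mean
    methylation over a promoter set.  Returns (U, p); exact for small
    samples."""
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("each group needs >=2 samples")
    sub = pm.loc[pm.index.intersection(promoter_set)]
    if sub.empty:
        raise ValidationError("no promoters from the set carry CpGs")
    a = sub[group_a].mean(axis=0).to_numpy()
    b = sub[group_b].mean(axis=0).to_numpy()
    method = "exact" if max(len(a), len(b)) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
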