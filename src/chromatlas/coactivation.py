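"""Regulatory-element signal versus transcript expression.

Promoter histone-mark coverage and enhancer H3K27ac coverage are related
to transcript expression by Spearman correlation, after quantile
normalization.  Enhancer-transcript pairs come from two sources: the
closest transcript (stratified by distance: <20 kb, 20-200 kb, >200 kb)
and chromatin-contact calls.  A resampling null compares contact-derived
pairs against distance-matched closest pairs, and the final significant
pairs satisfy FDR < 0.1, Spearman R > 0.7 and a minimum transcript count
in the sample with highest expression (default 20).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genomic import GenomicInterval, ValidationError, closest_tss_distance

logger = logging.getLogger(__name__)

PROXIMAL_MAX = 20_000    # strictly less than -> proximal
DISTAL_MIN = 200_000     # strictly greater than -> distal


def quantile_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of row-wise means of
    sorted columns; tied values receive the mean over their rank range."""
    if df.shape[1] < 2:
        raise ValidationError("quantile normalization needs >=2 columns")
    vals = df.to_numpy(dtype=float)
    sorted_means = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty(len(col))
        ranked[order] = sorted_means
        # average within ties
        s = pd.Series(ranked)
        out[:, j] = s.groupby(pd.Series(col)).transform("mean").to_numpy()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def pooled_spearman(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman R over flattened (observation, sample) pairs."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2 or len(set(x[ok])) < 2 or len(set(y[ok])) < 2:
        return float("nan")
    return float(stats.spearmanr(x[ok], y[ok]).statistic)


@dataclass
class CorrelationResult:
    label: str
    n_pairs: int
    spearman_r: float
    p: float | None = None


def promoter_mark_expression_corr(
    promoter_cov: pd.DataFrame,
    expr: pd.DataFrame,
    gene_of: dict[str, str],
    protein_coding: set[str] | None = None,
    n_quantiles: int = 10,
) -> tuple[CorrelationResult, pd.DataFrame]:
    """Spearman between promoter ChIP coverage and transcript expression.

    Both matrices (transcript-indexed, same sample columns) are quantile
    normalized; for genes with several transcripts the one with the
    highest mean normalized coverage is kept; the correlation pools all
    (promoter, sample) points.  Also returns per-expression-quantile mean
    coverage summaries for visualization.
    """
    if list(promoter_cov.columns) != list(expr.columns):
        raise ValidationError("coverage and expression sample sets differ")
    shared = promoter_cov.index.intersection(expr.index)
    if protein_coding is not None:
        shared = shared[[t in protein_coding for t in shared]]
    cov = quantile_normalize(promoter_cov.loc[shared])
    ex = quantile_normalize(expr.loc[shared])
    # per gene keep the transcript with the highest coverage
    mean_cov = cov.mean(axis=1)
    keep = (
        mean_cov.groupby(pd.Index([gene_of[t] for t in shared]))
        .idxmax()
        .to_numpy()
    )
    cov, ex = cov.loc[keep], ex.loc[keep]
    r = pooled_spearman(cov.to_numpy(), ex.to_numpy())
    n = cov.size
    # expression-quantile summaries
    flat = pd.DataFrame({
        "expression": ex.to_numpy().ravel(),
        "coverage": cov.to_numpy().ravel(),
    })
    flat["quantile"] = pd.qcut(
        flat["expression"].rank(method="first"), n_quantiles, labels=False
    ) + 1
    summary = flat.groupby("quantile").agg(
        mean_expression=("expression", "mean"),
        mean_coverage=("coverage", "mean"),
        n=("coverage", "size"),
    )
    return CorrelationResult("promoter_mark_vs_expression", n, r), summary


def _stratum(distance: float) -> str:
    if np.isnan(distance) or distance > DISTAL_MIN:
        return "distal"
    if distance < PROXIMAL_MAX:
        return "proximal"
    return "mid"


def assign_closest(
    enhancers: list[GenomicInterval], tss_records: list
) -> pd.DataFrame:
    """Closest transcript per enhancer, with distance stratum.

    Transcripts are treated as their TSS point; distance is 0 when the TSS
    falls inside the enhancer, otherwise the gap to the nearer edge.  Ties
    go to the smaller TSS coordinate.  Enhancers on a chromosome without
    transcripts get an undefined distance and the distal stratum.
    """
    if not tss_records:
        raise ValidationError("TSS table is empty")
    by_chrom: dict[str, list] = {}
    for r in tss_records:
        by_chrom.setdefault(r.chrom, []).append(r)
    pos = {}
    ids = {}
    for c, rs in by_chrom.items():
        rs = sorted(rs, key=lambda r: (r.tss, r.transcript_id))
        pos[c] = np.array([r.tss for r in rs])
        ids[c] = [r.transcript_id for r in rs]
    rows = []
    for e in enhancers:
        if e.chrom not in pos:
            logger.warning("enhancer %s on chromosome without transcripts", e.name)
            rows.append((e.name, None, float("nan"), "closest", "distal"))
            continue
        i, d = closest_tss_distance(e, pos[e.chrom])
        rows.append((e.name, ids[e.chrom][i], float(d), "closest", _stratum(d)))
    return pd.DataFrame(
        rows,
        columns=["enhancer_id", "transcript_id", "distance", "source", "stratum"],
    )


def contact_pairs_table(
    candidate_pairs: pd.DataFrame,
    enhancers: dict[str, GenomicInterval],
    tss_by_transcript: dict[str, int],
) -> pd.DataFrame:
    """Shape contact-derived (enhancer, transcript) candidates into the
    standard pair table with distances and strata."""
    rows = []
    for r in candidate_pairs.itertuples():
        iv = enhancers[r.anchor_id]
        tss = tss_by_transcript[r.transcript_id]
        if iv.start <= tss < iv.end:
            d = 0
        elif tss < iv.start:
            d = iv.start - tss
        else:
            d = tss - iv.end
        rows.append((r.anchor_id, r.transcript_id, float(d), "contact",
                     _stratum(d)))
    return pd.DataFrame(
        rows,
        columns=["enhancer_id", "transcript_id", "distance", "source", "stratum"],
    )


def _pair_points(
    pairs: pd.DataFrame,
    enhancer_cov: pd.DataFrame,
    expr: pd.DataFrame,
    aggregate_contacts: bool = True,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Pooled (coverage, expression) points for a pair group.

    Contact-derived enhancers linked to several transcripts contribute one
    point set per enhancer with the mean expression over their contacted
    transcripts as the pairing value.
    """
    xs, ys = [], []
    n_pairs = 0
    pairs = pairs.dropna(subset=["transcript_id"])
    contact = pairs[pairs["source"] == "contact"] if aggregate_contacts else pairs.iloc[0:0]
    rest = pairs.drop(contact.index)
    for r in rest.itertuples():
        if r.enhancer_id not in enhancer_cov.index or r.transcript_id not in expr.index:
            continue
        xs.append(enhancer_cov.loc[r.enhancer_id].to_numpy())
        ys.append(expr.loc[r.transcript_id].to_numpy())
        n_pairs += 1
    if len(contact):
        for eid, grp in contact.groupby("enhancer_id", sort=True):
            tids = [t for t in grp["transcript_id"] if t in expr.index]
            if eid not in enhancer_cov.index or not tids:
                continue
            xs.append(enhancer_cov.loc[eid].to_numpy())
            ys.append(expr.loc[tids].to_numpy().mean(axis=0))
            n_pairs += len(tids)
    if not xs:
        return np.empty(0), np.empty(0), 0
    return np.concatenate(xs), np.concatenate(ys), n_pairs


def correlate_pairs(
    pairs: pd.DataFrame,
    enhancer_cov: pd.DataFrame,
    expr: pd.DataFrame,
    by: tuple[str, ...] = ("source", "stratum"),
) -> list[CorrelationResult]:
    """One pooled Spearman R per (source, stratum) group."""
    results = []
    for key, grp in pairs.groupby(list(by), sort=True):
        label = "/".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        x, y, n = _pair_points(grp, enhancer_cov, expr)
        if n < 2:
            results.append(CorrelationResult(label, n, float("nan")))
            continue
        results.append(CorrelationResult(label, n, pooled_spearman(x, y)))
    return results


def resampling_pvalue(
    reference_pairs: pd.DataFrame,
    focal_pairs: pd.DataFrame,
    enhancer_cov: pd.DataFrame,
    expr: pd.DataFrame,
    draw_size: int = 260,
    reps: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Upper-tail empirical p for the focal pairs' pooled Spearman R
    against draws (without replacement) from the reference pair set.

    Returns (observed R, p) with add-one smoothing:
    p = (1 + #{null R >= observed}) / (1 + reps).
    """
    if draw_size > len(reference_pairs):
        raise ValidationError("draw_size exceeds reference pair count")
    if reps < 1:
        raise ValidationError("reps must be >= 1")
    x, y, _ = _pair_points(focal_pairs, enhancer_cov, expr)
    observed = pooled_spearman(x, y)
    # pre-extract one (coverage, expression) row per reference pair so each
    # draw is an index operation
    ref = reference_pairs.dropna(subset=["transcript_id"])
    ref = ref[
        ref["enhancer_id"].isin(enhancer_cov.index)
        & ref["transcript_id"].isin(expr.index)
    ]
    X = enhancer_cov.loc[ref["enhancer_id"]].to_numpy(dtype=float)
    Y = expr.loc[ref["transcript_id"]].to_numpy(dtype=float)
    if draw_size > len(X):
        raise ValidationError("draw_size exceeds usable reference pairs")
    rng = np.random.default_rng(seed)
    null = np.empty(reps)
    idx = np.arange(len(ref))
    for i in range(reps):
        take = rng.choice(idx, size=draw_size, replace=False)
        null[i] = pooled_spearman(X[take], Y[take])
    p = (1 + int(np.sum(null >= observed))) / (1 + reps)
    return observed, float(p)


def _spearman_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation between matched rows of X and Y."""
    rx = stats.rankdata(X, axis=1)
    ry = stats.rankdata(Y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    num = (rx * ry).sum(axis=1)
    den = np.sqrt((rx ** 2).sum(axis=1) * (ry ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _spearman_pvalues(r: np.ndarray, n: int, X: np.ndarray,
                      Y: np.ndarray) -> np.ndarray:
    """Two-sided per-pair p-values: exact permutation distribution when
    n <= 9 samples, t-approximation otherwise."""
    if n <= 9:
        from itertools import permutations

        perms = np.array(list(permutations(range(n))))
        out = np.empty(len(r))
        for i in range(len(r)):
            null = _spearman_rows(
                np.broadcast_to(X[i], (len(perms), n)), Y[i][perms]
            )
            out[i] = np.mean(np.abs(null) >= abs(r[i]) - 1e-12)
        return out
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1 - r ** 2, 1e-300, None))
    return 2 * stats.t.sf(np.abs(t), n - 2)


def filter_significant_pairs(
    pairs: pd.DataFrame,
    enhancer_cov: pd.DataFrame,
    expr_norm: pd.DataFrame,
    expr_counts: pd.DataFrame,
    fdr_max: float = 0.1,
    r_min: float = 0.7,
    min_peak_count: int = 20,
) -> pd.DataFrame:
    """Per-pair Spearman across samples, BH-FDR over all tested pairs, and
    the three gates: fdr < fdr_max, R > r_min, and max-over-samples raw
    transcript count >= min_peak_count.  Returns the pair table with
    columns R, p, fdr, max_count, kept."""
    pairs = pairs.dropna(subset=["transcript_id"]).copy()
    ok = pairs["enhancer_id"].isin(enhancer_cov.index) & pairs[
        "transcript_id"
    ].isin(expr_norm.index)
    pairs = pairs[ok].reset_index(drop=True)
    X = enhancer_cov.loc[pairs["enhancer_id"]].to_numpy(dtype=float)
    Y = expr_norm.loc[pairs["transcript_id"]].to_numpy(dtype=float)
    n = X.shape[1]
    r = _spearman_rows(X, Y)
    p = _spearman_pvalues(r, n, X, Y)
    tested = ~np.isnan(r)
    fdr = np.full(len(r), np.nan)
    if tested.any():
        fdr[tested] = multipletests(p[tested], method="fdr_bh")[1]
    max_count = (
        expr_counts.reindex(pairs["transcript_id"]).max(axis=1).to_numpy()
    )
    out = pairs.copy()
    out["R"] = r
    out["p"] = p
    out["fdr"] = fdr
    out["max_count"] = max_count
    out["kept"] = (
        tested & (fdr < fdr_max) & (r > r_min) & (max_count >= min_peak_count)
    )
    return out


def read_expression(path) -> pd.DataFrame:
    """Transcript x sample counts TSV (first column = transcript id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if (df.to_numpy() < 0).any():
        raise ValidationError("negative expression counts")
    return df
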