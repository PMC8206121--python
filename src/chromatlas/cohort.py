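"""Sample clustering on promoter activity, group-specific promoter calling,
TF-binding-site enrichment, and conservation comparison.

Samples are compared by the Jaccard index of their active-promoter sets and
clustered by UPGMA (unweighted average linkage) on distance 1 - J.  A
promoter is "specifically active" in a focal group when it clears the count
gates (at least ``min_active_a`` of the focal group, at most
``max_active_b`` of the contrast group) and a one-sided Fisher exact test
on the 2x2 group-by-activity table falls below ``p_threshold`` (default
0.003, matching the published calling rule of >=4/5 vs <=2/13).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomic import GenomicInterval, ScoredTrack, ValidationError


def jaccard_similarity(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Jaccard index of active-element sets between samples.

    J = |A ∩ B| / |A ∪ B|; two samples with empty active sets get J = 1.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("need at least two samples")
    X = matrix.values.astype(bool)
    inter = X.T.astype(int) @ X.astype(int)
    sizes = X.sum(axis=0)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        J = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return pd.DataFrame(J, index=matrix.columns, columns=matrix.columns)


@dataclass
class Dendrogram:
    """Average-linkage merge history on distance 1 - similarity.

    ``merges`` lists (left, right, height, size); internal nodes are
    numbered n, n+1, ... in merge order as in a scipy linkage matrix.
    """

    labels: list[str]
    merges: list[tuple[int, int, float, int]]

    def linkage_matrix(self) -> np.ndarray:
        return np.array(
            [[l, r, h, s] for l, r, h, s in self.merges], dtype=float
        )

    def to_newick(self) -> str:
        """Newick string with branch lengths equal to merge-height
        differences (ultrametric tree)."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        node = {i: self.labels[i] for i in range(n)}
        for k, (l, r, h, _s) in enumerate(self.merges):
            bl_l = h - height[l]
            bl_r = h - height[r]
            node[n + k] = f"({node[l]}:{bl_l:g},{node[r]}:{bl_r:g})"
            height[n + k] = h
        return node[n + len(self.merges) - 1] + ";"


def upgma(similarity: pd.DataFrame) -> Dendrogram:
    """UPGMA agglomeration on d = 1 - J with a deterministic tie-break
    (lexicographically smallest cluster-index pair)."""
    labels = list(similarity.index)
    n = len(labels)
    D = 1.0 - similarity.values.astype(float)
    # active clusters: id -> (member count); distances kept in a dict keyed
    # by frozen pair of cluster ids
    size = {i: 1 for i in range(n)}
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    active = set(range(n))
    merges = []
    nxt = n
    while len(active) > 1:
        best = min(dist.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), h = best
        sa, sb = size[a], size[b]
        new = nxt
        nxt += 1
        active.discard(a)
        active.discard(b)
        for c in active:
            da = dist.pop((min(a, c), max(a, c)))
            db = dist.pop((min(b, c), max(b, c)))
            dist[(min(new, c), max(new, c))] = (sa * da + sb * db) / (sa + sb)
        del dist[(a, b)]
        active.add(new)
        size[new] = sa + sb
        merges.append((a, b, h, sa + sb))
    return Dendrogram(labels, merges)


@dataclass
class GroupSpec:
    """Calling rule for promoters specifically active in group A versus
    group B.  Defaults mirror the published rule for the benign (PA)
    cluster against 13 higher-grade samples."""

    group_a: list[str]
    group_b: list[str]
    min_active_a: int = 4
    max_active_b: int = 2
    p_threshold: float = 0.003
    # reverse direction (specific in B)
    max_active_a: int = 1
    min_active_b: int = 11

    def __post_init__(self):
        if set(self.group_a) & set(self.group_b):
            raise ValidationError("groups must be disjoint")
        if not (0 < self.min_active_a <= len(self.group_a)):
            raise ValidationError("min_active_a outside group size")
        if not (0 <= self.max_active_b <= len(self.group_b)):
            raise ValidationError("max_active_b outside group size")
        if not (0 < self.min_active_b <= len(self.group_b)):
            raise ValidationError("min_active_b outside group size")


def _fisher_one_sided(k_focal: int, n_focal: int, k_other: int,
                      n_other: int) -> float:
    """One-sided Fisher exact p for enrichment of activity in the focal
    group."""
    table = [[k_focal, n_focal - k_focal], [k_other, n_other - k_other]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def call_specific_promoters(
    matrix: pd.DataFrame, spec: GroupSpec
) -> dict[str, list[str]]:
    """Promoters specifically active in group A (and, symmetrically, in
    group B) under count gates plus a one-sided Fisher exact test."""
    missing = (set(spec.group_a) | set(spec.group_b)) - set(matrix.columns)
    if missing:
        raise ValidationError(f"samples absent from matrix: {sorted(missing)}")
    ka = matrix[spec.group_a].sum(axis=1)
    kb = matrix[spec.group_b].sum(axis=1)
    na, nb = len(spec.group_a), len(spec.group_b)
    specific_a, specific_b = [], []
    for pid in matrix.index:
        a, b = int(ka[pid]), int(kb[pid])
        if a >= spec.min_active_a and b <= spec.max_active_b:
            if _fisher_one_sided(a, na, b, nb) < spec.p_threshold:
                specific_a.append(pid)
        if a <= spec.max_active_a and b >= spec.min_active_b:
            if _fisher_one_sided(b, nb, a, na) < spec.p_threshold:
                specific_b.append(pid)
    return {"specific_in_a": specific_a, "specific_in_b": specific_b}


def tfbs_enrichment(
    target_promoters: list[GenomicInterval],
    reference_promoters: list[GenomicInterval],
    tfbs_by_factor: dict[str, list[GenomicInterval]],
) -> pd.DataFrame:
    """Per-factor fold change of binding-site intersections per megabase:
    (hits_target / target_Mb) / (hits_reference / reference_Mb).

    Hits count once per (site, promoter) intersection event.  A factor
    with reference hits = 0 but target hits > 0 is reported as +inf; a
    factor absent from both sets is NaN.
    """
    if not target_promoters or not reference_promoters:
        raise ValidationError("promoter sets must be non-empty")
    t_mb = sum(len(iv) for iv in target_promoters) / 1e6
    r_mb = sum(len(iv) for iv in reference_promoters) / 1e6
    rows = []
    for factor, sites in sorted(tfbs_by_factor.items()):
        ht = _count_intersections(sites, target_promoters)
        hr = _count_intersections(sites, reference_promoters)
        if ht == 0 and hr == 0:
            fold = float("nan")
        elif hr == 0:
            fold = float("inf")
        else:
            fold = (ht / t_mb) / (hr / r_mb)
        rows.append((factor, ht, hr, fold))
    return pd.DataFrame(
        rows, columns=["factor", "hits_target", "hits_reference", "fold"]
    ).set_index("factor")


def _count_intersections(sites, promoters) -> int:
    """Number of (site, promoter) overlapping pairs."""
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for p in promoters:
        by_chrom.setdefault(p.chrom, []).append(p)
    total = 0
    for c, ps in by_chrom.items():
        ps_sorted = sorted(ps, key=lambda p: p.start)
        s = np.array([p.start for p in ps_sorted])
        e = np.array([p.end for p in ps_sorted])
        max_len = int((e - s).max())
        for site in (x for x in sites if x.chrom == c):
            # candidate promoters: start < site.end and end > site.start
            hi = np.searchsorted(s, site.end, side="left")
            lo = np.searchsorted(s, site.start - max_len, side="left")
            total += int(np.sum(e[lo:hi] > site.start))
    return total


def interval_mean_scores(
    intervals: list[GenomicInterval], track: ScoredTrack
) -> np.ndarray:
    """Per-interval mean score over covered bases of a sparse score track."""
    return np.array([track.mean_over(iv) for iv in intervals])


def conservation_compare(
    element_scores: np.ndarray, shuffled_scores: np.ndarray
) -> tuple[float, float]:
    """One-sided Mann-Whitney U (elements > shuffled) on per-interval mean
    conservation scores.  Returns (U, p); exact for small samples, tie-
    corrected normal approximation otherwise."""
    x = np.asarray(element_scores, dtype=float)
    y = np.asarray(shuffled_scores, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both score samples must be non-empty")
    method = "exact" if max(len(x), len(y)) <= 20 else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)
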