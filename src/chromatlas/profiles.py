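"""Binned abundance (ChIP minus input), anomalous-position masking, TSS
metaprofiles, and top-decile differential region selection.

Reads are represented as arrays of mapped positions per chromosome.
Positions whose read count exceeds the z-score threshold (default 7,
statistics over covered positions) are masked and their reads discarded;
the remaining reads are counted in fixed-width non-overlapping bins
(default 500 bp) and normalized per one million mapped reads, with the
library size counted before masking.  Abundance of a TSS-proximal region
(TSS +/- 2 kb) is the mean of (chip - input) over all bins overlapping the
window; windows overlapping the span of a different gene are excluded.
Metaprofiles use 10-bp bins smoothed with a centered running mean, k=15.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic import GenomeLayout, GenomicInterval, ValidationError

logger = logging.getLogger(__name__)

Reads = Mapping[str, np.ndarray]  # chrom -> sorted-or-not 1-D positions


@dataclass
class PositionMask:
    """Masked genomic positions per chromosome, plus the threshold used."""

    positions: dict[str, np.ndarray]
    z_threshold: float = 7.0

    def n_masked(self) -> int:
        return int(sum(len(p) for p in self.positions.values()))


def mask_anomalous(reads: Reads, z_threshold: float = 7.0) -> PositionMask:
    """Flag positions whose read count has z > threshold.

    Mean and standard deviation are computed over positions carrying at
    least one read (the covered positions of the sample); zero variance
    yields an empty mask.
    """
    counts_all = []
    pos_all = []
    for chrom, pos in reads.items():
        pos = np.asarray(pos, dtype=np.int64)
        upos, cnt = np.unique(pos, return_counts=True)
        pos_all.append((chrom, upos))
        counts_all.append(cnt)
    if not counts_all or sum(len(c) for c in counts_all) < 2:
        return PositionMask({}, z_threshold)
    cat = np.concatenate(counts_all)
    mu, sd = cat.mean(), cat.std()
    if sd == 0:
        logger.info("uniform coverage: empty anomaly mask")
        return PositionMask({}, z_threshold)
    masked = {}
    for (chrom, upos), cnt in zip(pos_all, counts_all):
        bad = upos[(cnt - mu) / sd > z_threshold]
        if len(bad):
            masked[chrom] = bad
    return PositionMask(masked, z_threshold)


@dataclass
class BinnedTrack:
    """Fixed-width-bin vectors of normalized read frequency (reads per
    million mapped) per chromosome."""

    values: dict[str, np.ndarray]
    bin_width: int
    library_size: int

    def grid_matches(self, other: "BinnedTrack") -> bool:
        return (
            self.bin_width == other.bin_width
            and set(self.values) == set(other.values)
            and all(len(self.values[c]) == len(other.values[c]) for c in self.values)
        )


def bin_normalize(
    reads: Reads,
    layout: GenomeLayout,
    bin_width: int = 500,
    mask: PositionMask | None = None,
    library_size: int | None = None,
) -> BinnedTrack:
    """Per-bin retained-read count x 1e6 / library size.  The library size
    defaults to the total read count before masking."""
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    if library_size is None:
        library_size = int(sum(len(np.asarray(p)) for p in reads.values()))
    if library_size <= 0:
        raise ValidationError("library size must be positive")
    values = {}
    for chrom in layout.chrom_names:
        n_bins = math.ceil(layout.length_of(chrom) / bin_width)
        pos = np.asarray(reads.get(chrom, np.empty(0, dtype=np.int64)),
                         dtype=np.int64)
        if mask is not None and chrom in mask.positions:
            pos = pos[~np.isin(pos, mask.positions[chrom])]
        counts = np.bincount(pos // bin_width, minlength=n_bins).astype(float)
        values[chrom] = counts * 1e6 / library_size
    return BinnedTrack(values, bin_width, library_size)


def write_binned_bedgraph(track: BinnedTrack, path) -> None:
    """Write nonzero bins of a BinnedTrack as bedGraph."""
    w = track.bin_width
    with open(path, "w") as fh:
        for chrom, vec in track.values.items():
            nz = np.flatnonzero(vec)
            starts = nz * w
            for b, s in zip(nz, starts):
                fh.write(f"{chrom}\t{s}\t{s + w}\t{vec[b]:.6g}\n")


def read_binned_bedgraph(
    path, layout: GenomeLayout, bin_width: int, library_size: int
) -> BinnedTrack:
    """Read a bin-aligned bedGraph back into a BinnedTrack (absent bins
    are zero)."""
    values = {
        c: np.zeros(math.ceil(layout.length_of(c) / bin_width))
        for c in layout.chrom_names
    }
    for line in open(path):
        if not line.strip() or line.startswith(("track", "#")):
            continue
        chrom, s, e, v = line.split("\t")
        values[chrom][int(s) // bin_width] = float(v)
    return BinnedTrack(values, bin_width, library_size)


def binned_difference(chip: BinnedTrack, input_: BinnedTrack) -> BinnedTrack:
    """Per-bin chip - input (may be negative)."""
    if not chip.grid_matches(input_):
        raise ValidationError("chip and input bin grids differ")
    return BinnedTrack(
        {c: chip.values[c] - input_.values[c] for c in chip.values},
        chip.bin_width,
        chip.library_size,
    )


def tss_windows(
    tss_records: Sequence,
    layout: GenomeLayout,
    flank: int = 2000,
    gene_spans: Mapping[str, GenomicInterval] | None = None,
) -> dict[str, GenomicInterval]:
    """TSS-proximal windows (TSS +/- flank) keyed by transcript id;
    windows intersecting the annotated span of a *different* gene are
    excluded when spans are supplied."""
    out = {}
    for r in tss_records:
        clen = layout.length_of(r.chrom)
        w = GenomicInterval(r.chrom, max(0, r.tss - flank),
                            min(clen, r.tss + flank), name=r.transcript_id)
        if gene_spans is not None:
            clash = any(
                g != r.gene_id and w.overlaps(span)
                for g, span in gene_spans.items()
            )
            if clash:
                continue
        out[r.transcript_id] = w
    return out


def abundance(
    chip: BinnedTrack,
    input_: BinnedTrack,
    regions: Mapping[str, GenomicInterval],
) -> pd.Series:
    """Mean (chip - input) over all bins overlapping each region.  Bins
    partially overlapping the window count fully (no fractional weight)."""
    diff = binned_difference(chip, input_)
    w = chip.bin_width
    out = {}
    for rid, iv in regions.items():
        vec = diff.values.get(iv.chrom)
        if vec is None:
            raise ValidationError(f"region {rid} on unknown chromosome {iv.chrom}")
        lo = iv.start // w
        hi = (iv.end - 1) // w + 1
        out[rid] = float(vec[lo:hi].mean())
    return pd.Series(out, name="abundance")


def region_mean(track: BinnedTrack, regions: Mapping[str, GenomicInterval]) -> pd.Series:
    """Mean normalized coverage over all bins overlapping each region
    (no input subtraction)."""
    w = track.bin_width
    out = {}
    for rid, iv in regions.items():
        vec = track.values[iv.chrom]
        out[rid] = float(vec[iv.start // w:(iv.end - 1) // w + 1].mean())
    return pd.Series(out, name="coverage")


def select_top_decile(
    group_a: pd.Series, group_b: pd.Series, fraction: float = 0.10
) -> list[str]:
    """Regions with the largest (a - b) abundance difference; top
    ceil(fraction * N), ties broken by region id."""
    if len(group_a) == 0:
        raise ValidationError("empty region universe")
    if set(group_a.index) != set(group_b.index):
        raise ValidationError("region universes differ")
    diff = group_a - group_b.reindex(group_a.index)
    k = math.ceil(fraction * len(diff))
    order = sorted(diff.index, key=lambda r: (-diff[r], r))
    return order[:k]


def runmean(x: np.ndarray, k: int = 15) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    x = np.asarray(x, dtype=float)
    h = k // 2
    csum = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    i = np.arange(n)
    lo = np.maximum(i - h, 0)
    hi = np.minimum(i + h + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


@dataclass
class TssProfile:
    """Mean signal per 10-bp offset across TSS +/- 2 kb, smoothed, with a
    normal-approximation confidence band for the mean."""

    offsets: np.ndarray           # bin-center offsets relative to TSS
    mean: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n: int                        # number of (region, sample) rows averaged


def tss_metaprofile(
    chip_tracks: Sequence[BinnedTrack],
    input_tracks: Sequence[BinnedTrack],
    tss_list: Sequence[tuple[str, int]],
    layout: GenomeLayout,
    flank: int = 2000,
    bin_width: int = 10,
    k: int = 15,
) -> TssProfile:
    """Average (chip - input) profile around TSSs for a sample group.

    ``chip_tracks``/``input_tracks`` must be binned at ``bin_width``;
    ``tss_list`` holds (chrom, tss) anchors.  Offsets run across
    [-flank, flank) in ``bin_width`` steps (400 bins at the defaults).
    """
    if len(chip_tracks) != len(input_tracks):
        raise ValidationError("one input track per chip track required")
    n_off = 2 * flank // bin_width
    rows = []
    for chip, inp in zip(chip_tracks, input_tracks):
        diff = binned_difference(chip, inp)
        for chrom, tss in tss_list:
            vec = diff.values[chrom]
            b0 = (tss - flank) // bin_width
            idx = np.arange(b0, b0 + n_off)
            ok = (idx >= 0) & (idx < len(vec))
            row = np.full(n_off, np.nan)
            row[ok] = vec[idx[ok]]
            rows.append(row)
    stack = np.array(rows)
    mean = np.nanmean(stack, axis=0)
    with np.errstate(invalid="ignore"):
        sem = np.nanstd(stack, axis=0) / np.sqrt(
            np.maximum(np.sum(~np.isnan(stack), axis=0), 1)
        )
    mean_s = runmean(mean, k)
    sem_s = runmean(sem, k)
    offsets = np.arange(-flank, flank, bin_width) + bin_width // 2
    return TssProfile(offsets, mean_s, mean_s - 1.96 * sem_s,
                      mean_s + 1.96 * sem_s, len(rows))


def percent_recovery(ct_input: float, ct_ip: float,
                     input_dilution: float) -> float:
    """ChIP-qPCR enrichment as percent of input chromatin recovered:
    2^(Ct_input - log2(dilution) - Ct_IP) * 100."""
    if not (0 < input_dilution <= 1):
        raise ValidationError("input dilution must be in (0, 1]")
    return float(2.0 ** (ct_input - math.log2(input_dilution) - ct_ip) * 100.0)
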