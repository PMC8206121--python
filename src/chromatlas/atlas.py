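"""Active-promoter and putative-enhancer definition, per-sample activity,
and common/variable stratification.

Promoters are symmetric windows around every transcription start site
(default +/-1,000 bp); an element carries a mark in a sample iff it shares
at least one base with any peak called for that sample.  Putative enhancers
are the merged union, across samples, of H3K27ac peaks that do not overlap
any promoter window at all (whole-peak exclusion).  Elements active in at
least ``threshold`` samples are "common", the rest "variable"; the default
thresholds are 20 (H3K4me3 promoters/genes), 10 (H3K27ac promoters/genes)
and 4 (enhancers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genomic import (
    GenomeLayout,
    GenomicInterval,
    ValidationError,
    intersect_any,
    merge_intervals,
    sort_intervals,
)

logger = logging.getLogger(__name__)

#: default commonality thresholds per (element kind, mark)
DEFAULT_THRESHOLDS = {
    ("promoter", "H3K4me3"): 20,
    ("gene", "H3K4me3"): 20,
    ("promoter", "H3K27ac"): 10,
    ("gene", "H3K27ac"): 10,
    ("enhancer", "H3K27ac"): 4,
}


@dataclass(frozen=True)
class TSSRecord:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    tss: int
    biotype: str = "protein_coding"

    @property
    def protein_coding(self) -> bool:
        return self.biotype == "protein_coding"


def read_tss_table(path) -> list[TSSRecord]:
    """TSV with columns transcript_id, gene_id, chrom, strand, tss, biotype."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"transcript_id", "gene_id", "chrom", "strand", "tss", "biotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"TSS table missing columns: {sorted(missing)}")
    if df["transcript_id"].duplicated().any():
        raise ValidationError("duplicate transcript_id in TSS table")
    return [
        TSSRecord(r.transcript_id, r.gene_id, r.chrom, r.strand,
                  int(r.tss), r.biotype)
        for r in df.itertuples()
    ]


def write_tss_table(records: Sequence[TSSRecord], path) -> None:
    pd.DataFrame(
        [
            (r.transcript_id, r.gene_id, r.chrom, r.strand, r.tss, r.biotype)
            for r in records
        ],
        columns=["transcript_id", "gene_id", "chrom", "strand", "tss", "biotype"],
    ).to_csv(path, sep="\t", index=False)


class PromoterSet:
    """One promoter window per transcript, mapped to its gene.

    Strand is carried on the record but unused: the window is symmetric
    around the TSS, so orientation cannot change it.
    """

    def __init__(self, records: Sequence[TSSRecord], flank: int,
                 layout: GenomeLayout):
        if flank <= 0:
            raise ValidationError("flank must be positive")
        self.flank = flank
        self.records = list(records)
        self.windows: dict[str, GenomicInterval] = {}
        for r in records:
            clen = layout.length_of(r.chrom)
            if not (0 <= r.tss < clen):
                raise ValidationError(
                    f"TSS {r.transcript_id} at {r.chrom}:{r.tss} outside chromosome"
                )
            start = max(0, r.tss - flank)
            end = min(clen, r.tss + flank)
            self.windows[r.transcript_id] = GenomicInterval(
                r.chrom, start, end, name=r.transcript_id, strand=r.strand
            )

    @property
    def transcript_ids(self) -> list[str]:
        return [r.transcript_id for r in self.records]

    @property
    def gene_of(self) -> dict[str, str]:
        return {r.transcript_id: r.gene_id for r in self.records}

    def genes(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for r in self.records:
            out.setdefault(r.gene_id, []).append(r.transcript_id)
        return out

    def intervals(self) -> list[GenomicInterval]:
        return [self.windows[t] for t in self.transcript_ids]


def define_promoters(
    tss: Sequence[TSSRecord], layout: GenomeLayout, flank: int = 1000
) -> PromoterSet:
    """Window [tss - flank, tss + flank) per transcript, clipped at
    chromosome edges."""
    return PromoterSet(tss, flank, layout)


class EnhancerCatalog:
    """Merged non-promoter H3K27ac intervals with deterministic ids
    (``enh|chrom:start-end``) and per-sample provenance."""

    def __init__(self, elements: list[GenomicInterval],
                 provenance: pd.DataFrame):
        self.elements = elements
        self.by_id = {iv.name: iv for iv in elements}
        self.provenance = provenance  # element id x sample bool

    @property
    def ids(self) -> list[str]:
        return [iv.name for iv in self.elements]

    def write_bed(self, path) -> None:
        from .genomic import write_bed

        write_bed(self.elements, path)


def call_enhancers(
    h3k27ac_peaksets: Mapping[str, Sequence[GenomicInterval]],
    promoters: PromoterSet,
    layout: GenomeLayout,
) -> EnhancerCatalog:
    """Per sample, discard whole peaks overlapping any promoter window by
    >=1 bp; pool survivors across samples, merge, and record which samples
    contributed to each merged element."""
    windows = promoters.intervals()
    survivors: dict[str, list[GenomicInterval]] = {}
    pooled: list[GenomicInterval] = []
    for sample, peaks in h3k27ac_peaksets.items():
        if len(peaks) == 0:
            survivors[sample] = []
            continue
        keep_mask = ~intersect_any(peaks, windows, layout)
        kept = [p for p, k in zip(peaks, keep_mask) if k]
        survivors[sample] = kept
        pooled.extend(kept)
    merged = merge_intervals(pooled, layout)
    elements = [
        GenomicInterval(iv.chrom, iv.start, iv.end,
                        name=f"enh|{iv.chrom}:{iv.start}-{iv.end}")
        for iv in sort_intervals(merged, layout)
    ]
    prov = pd.DataFrame(
        False, index=[iv.name for iv in elements], columns=list(h3k27ac_peaksets)
    )
    for sample in h3k27ac_peaksets:
        if survivors[sample]:
            prov[sample] = intersect_any(elements, survivors[sample], layout)
    return EnhancerCatalog(elements, prov)


def mark_activity(
    elements: Mapping[str, GenomicInterval],
    peaksets: Mapping[str, Sequence[GenomicInterval]],
    layout: GenomeLayout,
    mark: str = "",
) -> pd.DataFrame:
    """Boolean element x sample matrix: element active in a sample iff it
    overlaps any of that sample's peaks.  A sample with zero peaks yields
    an all-false column (warning, not an error)."""
    ids = list(elements)
    ivs = [elements[i] for i in ids]
    mat = pd.DataFrame(False, index=ids, columns=list(peaksets))
    mat.attrs["mark"] = mark
    for sample, peaks in peaksets.items():
        if len(peaks) == 0:
            logger.warning("sample %s has zero %s peaks", sample, mark)
            continue
        mat[sample] = intersect_any(ivs, peaks, layout)
    return mat


def gene_activity(promoter_matrix: pd.DataFrame,
                  promoters: PromoterSet) -> pd.DataFrame:
    """Gene-level activity: OR over the gene's promoter rows."""
    gene_of = promoters.gene_of
    grouped = promoter_matrix.groupby(
        promoter_matrix.index.map(gene_of.get)
    ).any()
    grouped.attrs["mark"] = promoter_matrix.attrs.get("mark", "")
    return grouped


def stratify(matrix: pd.DataFrame, threshold: int) -> pd.Series:
    """Partition elements into {common, variable}: common iff active in at
    least ``threshold`` samples."""
    n = matrix.shape[1]
    if not (1 <= threshold <= n):
        raise ValidationError(
            f"threshold {threshold} outside [1, {n}]"
        )
    counts = matrix.sum(axis=1)
    return pd.Series(
        np.where(counts >= threshold, "common", "variable"),
        index=matrix.index,
        name="commonality",
    )


def write_activity_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.astype(int).to_csv(path, sep="\t")


def read_activity_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0).astype(bool)
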