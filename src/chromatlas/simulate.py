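"""Self-contained synthetic multi-omics cohort with planted structure.

The generator emulates the statistical structure the atlas analysis
assumes: a small genome (default 2 chromosomes x 5 Mb) carrying genes and
intergenic enhancer loci on an interleaved slot lattice; per-sample peak
calls for H3K4me3 / H3K27ac / ATAC with planted common, variable and
group-specific activity; ChIP and input coverage with signal proportional
to planted per-sample intensities plus Poisson read noise and a few
anomalous hot positions; negative-binomial transcript counts coupled to
element intensities through a Gaussian copula on ranks (so Spearman
targets are planted exactly up to noise); a banded contact map with
power-law distance decay (mu_d ~ mu_1 / d) and planted loops at a stated
fold; TF-binding sites enriched at a designated promoter set; a
conservation track elevated at regulatory elements; and CpG beta values
with a planted group shift.  Every output is a plain-text file in the
formats the consuming modules read, and a ground-truth JSON records the
planted labels for recovery scoring.

Noise model: planted-active entries drop out with probability ``dropout``
(peak false negatives); planted-inactive entries of common/variable
elements activate spuriously with probability ``spurious``.  The
group-specific promoter design is kept free of spurious activation in the
contrast groups — its activity pattern *is* the planted design.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import TSSRecord, write_tss_table
from .genomic import GenomeLayout, GenomicInterval, ValidationError, write_bed
from .profiles import BinnedTrack, bin_normalize, mask_anomalous, write_binned_bedgraph


class GenerationError(ValueError):
    """The requested cohort does not fit the genome."""


@dataclass
class CohortConfig:
    seed: int = 0
    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 5_000_000, "chr2": 5_000_000}
    )
    n_pa: int = 5
    n_da: int = 6
    n_gb: int = 13
    n_genes: int = 300
    n_enhancers: int = 400
    fraction_common_promoters: float = 0.5
    fraction_common_enhancers: float = 0.45
    n_specific_pa: int = 30
    n_specific_gb: int = 30
    n_linked: int = 20             # correlated enhancer->transcript loops
    n_decoy_loops: int = 200       # loops with no expression coupling
    loop_fold: float = 10.0
    link_rho: float = 0.9          # planted Spearman for correlated links
    promoter_rho: float = 0.6      # promoter mark vs expression Spearman
    contact_mu1: float = 100.0     # expected count at 1-bin distance
    decay_exponent: float = 1.0
    resolution: int = 10_000
    max_dist: int = 2_000_000
    dropout: float = 0.05          # peak false-negative rate
    spurious: float = 0.01         # peak false-positive rate
    library_size: int = 100_000
    background_fraction: float = 0.3
    nb_dispersion: float = 0.1
    methylation_delta: float = 0.3
    n_cpg_per_promoter: int = 5
    n_hot_positions: int = 3       # anomalous positions per chip track

    def __post_init__(self):
        for p in (self.fraction_common_promoters, self.fraction_common_enhancers,
                  self.dropout, self.spurious, self.background_fraction):
            if not (0 <= p <= 1):
                raise GenerationError("probabilities must lie in [0, 1]")
        if min(self.n_genes, self.n_enhancers, self.n_pa, self.n_da,
               self.n_gb) < 0:
            raise GenerationError("counts must be non-negative")

    @property
    def samples(self) -> dict[str, str]:
        out = {}
        for g, n in (("PA", self.n_pa), ("DA", self.n_da), ("GB", self.n_gb)):
            for i in range(1, n + 1):
                out[f"{g}{i:02d}"] = g
        return out


def _latent_pearson(spearman: float) -> float:
    """Gaussian-copula latent correlation giving a target Spearman rho."""
    return 2.0 * math.sin(math.pi * spearman / 6.0)


@dataclass
class GroundTruth:
    samples: dict[str, str]
    promoter_commonality: dict[str, str]       # transcript id -> label
    enhancer_commonality: dict[str, str]       # "chrom:start-end" -> label
    pa_specific_transcripts: list[str]
    gb_specific_transcripts: list[str]
    links: list[dict]                          # correlated enhancer->transcript
    decoy_loops: list[dict]
    ezh2_transcripts: list[str]
    methylation_shift_transcripts: list[str]
    enhancers: dict[str, list]                 # key -> [chrom, start, end]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class Cohort:
    """In-memory handle to a generated cohort."""

    config: CohortConfig
    layout: GenomeLayout
    tss: list[TSSRecord]
    truth: GroundTruth
    outdir: Path
    manifest: dict


def _place_slots(rng, layout: GenomeLayout, n_genes: int, n_enh: int):
    """Interleave gene and enhancer slots on a lattice per chromosome.

    Slot geometry guarantees promoter windows (+/-2 kb), gene spans and
    enhancers never collide across slots.
    """
    chroms = layout.chrom_names
    genes_per = [n_genes // len(chroms)] * len(chroms)
    enh_per = [n_enh // len(chroms)] * len(chroms)
    genes_per[0] += n_genes - sum(genes_per)
    enh_per[0] += n_enh - sum(enh_per)
    gene_slots, enh_slots = [], []
    for ci, chrom in enumerate(chroms):
        n_slots = genes_per[ci] + enh_per[ci]
        slot = layout.length_of(chrom) // n_slots if n_slots else 0
        if n_slots and slot < 14_000:
            raise GenerationError(
                f"{chrom}: slot width {slot} bp too small for the planted "
                "element geometry; reduce n_genes/n_enhancers or enlarge "
                "the genome"
            )
        kinds = np.array(["gene"] * genes_per[ci] + ["enh"] * enh_per[ci])
        rng.shuffle(kinds)
        for k, kind in enumerate(kinds):
            s = k * slot
            (gene_slots if kind == "gene" else enh_slots).append((chrom, s))
    return gene_slots, enh_slots


def generate(config: CohortConfig, outdir) -> Cohort:
    """Generate the cohort on disk and return the in-memory handle."""
    rng = np.random.default_rng(config.seed)
    outdir = Path(outdir)
    (outdir / "peaks").mkdir(parents=True, exist_ok=True)
    (outdir / "coverage" / "groups").mkdir(parents=True, exist_ok=True)
    layout = GenomeLayout.from_dict(dict(config.chrom_lengths))
    samples = config.samples
    sample_ids = list(samples)
    groups: dict[str, list[str]] = {}
    for s, g in samples.items():
        groups.setdefault(g, []).append(s)
    n_samples = len(sample_ids)

    # ------------------------------------------------------------------ genes
    gene_slots, enh_slots = _place_slots(
        rng, layout, config.n_genes, config.n_enhancers
    )
    tss_records: list[TSSRecord] = []
    gene_tss: dict[str, int] = {}
    gene_chrom: dict[str, str] = {}
    gene_transcripts: dict[str, list[str]] = {}
    t_counter = 0
    for gi, (chrom, s) in enumerate(gene_slots):
        gid = f"G{gi + 1:04d}"
        tss1 = s + 3000 + int(rng.integers(0, 1000))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_chrom[gid], gene_tss[gid] = chrom, tss1
        tx_positions = [tss1]
        if gi % 5 == 4:
            tx_positions.append(tss1 + 300)
        gene_transcripts[gid] = []
        for tp in tx_positions:
            t_counter += 1
            tid = f"T{t_counter:04d}"
            gene_transcripts[gid].append(tid)
            tss_records.append(
                TSSRecord(tid, gid, chrom, strand, tp, "protein_coding")
            )
    gene_ids = list(gene_tss)

    enhancers: list[GenomicInterval] = []
    for chrom, s in enh_slots:
        start = s + 5000 + int(rng.integers(0, 500))
        length = int(rng.integers(800, 2001))
        enhancers.append(GenomicInterval(chrom, start, start + length))
    enh_keys = [f"{e.chrom}:{e.start}-{e.end}" for e in enhancers]

    # ------------------------------------------------------ planted activity
    perm = rng.permutation(len(gene_ids))
    pa_specific = [gene_ids[i] for i in perm[: config.n_specific_pa]]
    gb_specific = [
        gene_ids[i]
        for i in perm[config.n_specific_pa: config.n_specific_pa + config.n_specific_gb]
    ]
    rest = [gene_ids[i] for i in perm[config.n_specific_pa + config.n_specific_gb:]]
    n_common = int(round(config.fraction_common_promoters * len(gene_ids)))
    common_genes = rest[:n_common]
    variable_genes = rest[n_common:]

    design = pd.DataFrame(False, index=gene_ids, columns=sample_ids)
    design.loc[common_genes] = True
    for g in variable_genes:
        k = int(rng.integers(1, 6))
        design.loc[g, rng.choice(sample_ids, size=k, replace=False)] = True
    design.loc[pa_specific, groups["PA"]] = True
    design.loc[gb_specific, groups["DA"] + groups["GB"]] = True

    eperm = rng.permutation(len(enhancers))
    n_common_e = int(round(config.fraction_common_enhancers * len(enhancers)))
    common_enh_idx = sorted(eperm[:n_common_e])
    variable_enh_idx = sorted(eperm[n_common_e:])
    edesign = pd.DataFrame(False, index=range(len(enhancers)), columns=sample_ids)
    edesign.loc[common_enh_idx] = True
    for ei in variable_enh_idx:
        k = int(rng.integers(1, 4))
        edesign.loc[ei, rng.choice(sample_ids, size=k, replace=False)] = True

    specific = set(pa_specific) | set(gb_specific)

    def noisy(designed: pd.DataFrame, protect: set | None = None) -> pd.DataFrame:
        act = designed.to_numpy().copy()
        drop = rng.random(act.shape) < config.dropout
        spur = rng.random(act.shape) < config.spurious
        out = act & ~drop
        if config.spurious > 0:
            add = ~act & spur
            if protect:
                prot = np.array([i in protect for i in designed.index])
                add[prot] = False
            out = out | add
        return pd.DataFrame(out, index=designed.index, columns=designed.columns)

    activity = {
        "H3K4me3": noisy(design, specific),
        "H3K27ac": noisy(design, specific),
        "ATAC": noisy(design, specific),
    }
    enh_activity = noisy(edesign)

    # ------------------------------------------------------------- expression
    r_link = _latent_pearson(config.link_rho)
    r_prom = _latent_pearson(config.promoter_rho)
    gene_latent = pd.DataFrame(
        rng.standard_normal((len(gene_ids), n_samples)),
        index=gene_ids, columns=sample_ids,
    )
    enh_latent = pd.DataFrame(
        rng.standard_normal((len(enhancers), n_samples)),
        index=range(len(enhancers)), columns=sample_ids,
    )

    # planted loops: correlated links anchored at common enhancers
    res = config.resolution
    tss_by_tid = {r.transcript_id: r.tss for r in tss_records}
    chrom_of_tid = {r.transcript_id: r.chrom for r in tss_records}
    tx_bins = {
        t: (chrom_of_tid[t], tss_by_tid[t] // res) for t in tss_by_tid
    }

    gene_of_tid = {r.transcript_id: r.gene_id for r in tss_records}
    common_gene_set = set(common_genes)

    def pick_targets(e_idx: list[int], d_lo: int, d_hi: int, n: int,
                     allowed_genes: set | None = None):
        chosen = []
        used_tx = set()
        for ei in e_idx:
            if len(chosen) >= n:
                break
            e = enhancers[ei]
            ebin = ((e.start + e.end) // 2) // res
            cands = [
                t for t, (c, b) in tx_bins.items()
                if c == e.chrom and d_lo <= abs(b - ebin) <= d_hi
                and t not in used_tx
                and (allowed_genes is None or gene_of_tid[t] in allowed_genes)
            ]
            if not cands:
                continue
            t = sorted(cands)[int(rng.integers(len(cands)))]
            used_tx.add(t)
            chosen.append((ei, t, ebin, tx_bins[t][1]))
        return chosen

    shuffled_common = [int(i) for i in rng.permutation(common_enh_idx)]
    # correlated links target constitutively active (common) promoters so
    # the planted copula ranks survive into the emitted counts
    linked = pick_targets(shuffled_common, 5, 40, config.n_linked,
                          common_gene_set)
    linked_enh = {ei for ei, *_ in linked}
    other_idx = [int(i) for i in rng.permutation(len(enhancers))
                 if i not in linked_enh]
    decoys = pick_targets(other_idx, 5, 150, config.n_decoy_loops)

    link_of_tx = {t: ei for ei, t, *_ in linked}
    tx_ids = [r.transcript_id for r in tss_records]
    base_mean = pd.Series(
        np.exp(rng.normal(math.log(50.0), 1.0, len(tx_ids))), index=tx_ids
    )
    base_mean[list(link_of_tx)] = np.exp(
        rng.normal(math.log(200.0), 0.3, len(link_of_tx))
    )
    # group effects on specific genes; promoters designed inactive in a
    # sample are lowly expressed there (mark presence tracks expression)
    shift = pd.DataFrame(1.0, index=tx_ids, columns=sample_ids)
    for g in gene_ids:
        inactive = [s for s in sample_ids if not design.at[g, s]]
        if inactive:
            shift.loc[gene_transcripts[g], inactive] = 0.05
    for g in pa_specific:
        shift.loc[gene_transcripts[g], groups["PA"]] = 6.0
    for g in gb_specific:
        shift.loc[gene_transcripts[g], groups["DA"] + groups["GB"]] = 6.0

    eps = rng.standard_normal((len(tx_ids), n_samples))
    u = np.empty((len(tx_ids), n_samples))
    for i, t in enumerate(tx_ids):
        if t in link_of_tx:
            z = enh_latent.loc[link_of_tx[t]].to_numpy()
            lat = r_link * z + math.sqrt(1 - r_link ** 2) * eps[i]
        else:
            z = gene_latent.loc[tss_records[i].gene_id].to_numpy()
            lat = r_prom * z + math.sqrt(1 - r_prom ** 2) * eps[i]
        u[i] = stats.norm.cdf(lat)
    disp = config.nb_dispersion
    r_nb = 1.0 / disp
    mean = base_mean.to_numpy()[:, None] * shift.to_numpy()
    p_nb = r_nb / (r_nb + mean)
    counts = stats.nbinom.ppf(np.clip(u, 1e-12, 1 - 1e-12), r_nb, p_nb)
    expr = pd.DataFrame(counts.astype(int), index=tx_ids, columns=sample_ids)

    # ------------------------------------------------------------- peak files
    peak_paths = {}
    for mark in ("H3K4me3", "H3K27ac", "ATAC"):
        act = activity[mark]
        for s in sample_ids:
            rows = []
            for g in gene_ids:
                if act.at[g, s]:
                    tss1 = gene_tss[g]
                    a = tss1 - 500 - int(rng.integers(0, 100))
                    b = tss1 + 800 + int(rng.integers(0, 200))
                    rows.append(GenomicInterval(gene_chrom[g], a, b,
                                                name=f"{g}_pk"))
            if mark == "H3K27ac":
                for ei in range(len(enhancers)):
                    if enh_activity.at[ei, s]:
                        e = enhancers[ei]
                        a = e.start - int(rng.integers(0, 100))
                        b = e.end + int(rng.integers(0, 100))
                        rows.append(GenomicInterval(e.chrom, a, b,
                                                    name=f"E{ei:04d}_pk"))
            path = outdir / "peaks" / f"{s}.{mark}.bed"
            write_bed(sorted(rows, key=lambda iv: (iv.chrom, iv.start)), path)
            peak_paths[(s, mark)] = str(path.relative_to(outdir))

    # ------------------------------------------------------- coverage tracks
    lengths = layout.lengths
    chrom_offsets = np.concatenate(
        [[0], np.cumsum([lengths[c] for c in layout.chrom_names])]
    )
    total_len = int(chrom_offsets[-1])

    def split_positions(flat: np.ndarray) -> dict[str, np.ndarray]:
        out = {}
        for ci, c in enumerate(layout.chrom_names):
            sel = (flat >= chrom_offsets[ci]) & (flat < chrom_offsets[ci + 1])
            out[c] = (flat[sel] - chrom_offsets[ci]).astype(np.int64)
        return out

    def signal_reads(elements, intensities, n_reads, spread):
        """Distribute n_reads over elements proportional to intensity."""
        if not elements or n_reads <= 0:
            return np.empty(0, dtype=np.int64)
        w = np.asarray(intensities, dtype=float)
        w = w / w.sum()
        alloc = rng.multinomial(n_reads, w)
        pos = []
        for (chrom, center, width), k in zip(elements, alloc):
            if k == 0:
                continue
            ci = layout.chrom_names.index(chrom)
            if width == 0:  # promoter-style: gaussian around center
                p = center + rng.normal(0, spread, k)
            else:           # enhancer-style: uniform over the element
                p = center + rng.uniform(-width / 2, width / 2, k)
            p = np.clip(np.round(p), 0, lengths[chrom] - 1).astype(np.int64)
            pos.append(p + chrom_offsets[ci])
        return np.concatenate(pos) if pos else np.empty(0, dtype=np.int64)

    n_bg = int(config.library_size * config.background_fraction)
    n_sig = config.library_size - n_bg
    cov_paths = {}
    fine_reads: dict[tuple[str, str, str], dict[str, np.ndarray]] = {}

    for s in sample_ids:
        for mark in ("H3K4me3", "H3K27ac", "input"):
            flat_bg = rng.integers(0, total_len, n_bg)
            if mark == "input":
                flat = flat_bg
            else:
                # coverage follows the planted design: peak dropout models a
                # caller miss, the underlying signal persists
                elements, inten = [], []
                for g in gene_ids:
                    if design.at[g, s]:
                        elements.append((gene_chrom[g], gene_tss[g], 0))
                        inten.append(math.exp(0.5 * gene_latent.at[g, s]))
                if mark == "H3K27ac":
                    for ei in range(len(enhancers)):
                        if edesign.at[ei, s]:
                            e = enhancers[ei]
                            elements.append(
                                (e.chrom, (e.start + e.end) // 2, len(e))
                            )
                            inten.append(math.exp(0.5 * enh_latent.at[ei, s]))
                flat = np.concatenate(
                    [flat_bg, signal_reads(elements, inten, n_sig, 300.0)]
                )
            # plant anomalous hot positions
            if mark != "input" and config.n_hot_positions > 0:
                hot = rng.integers(0, total_len, config.n_hot_positions)
                flat = np.concatenate(
                    [flat, np.repeat(hot, 400)]
                )
            reads = split_positions(np.sort(flat))
            mask = mask_anomalous(reads)
            track = bin_normalize(reads, layout, 500, mask,
                                  library_size=len(flat))
            path = outdir / "coverage" / f"{s}.{mark}.bedgraph"
            write_binned_bedgraph(track, path)
            cov_paths[(s, mark)] = str(path.relative_to(outdir))
            fine_reads[(s, mark, "raw")] = reads

    # pooled 10-bp tracks within TSS +/- 2 kb windows, per group
    window_mask = {c: np.zeros(lengths[c] // 10 + 1, dtype=bool)
                   for c in layout.chrom_names}
    for r in tss_records:
        lo = max(0, (r.tss - 2000)) // 10
        hi = min(lengths[r.chrom] - 1, r.tss + 2000) // 10
        window_mask[r.chrom][lo:hi + 1] = True
    group_paths = {}
    for gname, members in groups.items():
        for mark in ("H3K4me3", "H3K27ac"):
            for kind, src in (("chip", mark), ("input", "input")):
                pooled_lib = 0
                vec = {c: np.zeros(math.ceil(lengths[c] / 10))
                       for c in layout.chrom_names}
                for s in members:
                    reads = fine_reads[(s, src, "raw")]
                    pooled_lib += sum(len(p) for p in reads.values())
                    for c, pos in reads.items():
                        np.add.at(vec[c], pos // 10, 1.0)
                for c in vec:
                    keep = window_mask[c][: len(vec[c])]
                    vec[c] = np.where(keep, vec[c], 0.0) * 1e6 / pooled_lib
                track = BinnedTrack(vec, 10, pooled_lib)
                path = (outdir / "coverage" / "groups" /
                        f"{gname}.{mark}.{kind}.10bp.bedgraph")
                write_binned_bedgraph(track, path)
                group_paths[(gname, mark, kind)] = str(path.relative_to(outdir))

    # ------------------------------------------------------------ contact map
    contact_path = outdir / "contacts.tsv"
    band = config.max_dist // res
    loop_lut = {}
    for ei, t, eb, tb in linked + decoys:
        c = enhancers[ei].chrom
        i, j = min(eb, tb), max(eb, tb)
        loop_lut[(c, i, j)] = config.loop_fold
    with open(contact_path, "w") as fh:
        for chrom in layout.chrom_names:
            n_bins = lengths[chrom] // res
            for d in range(1, min(band, n_bins - 1) + 1):
                mu = config.contact_mu1 / d ** config.decay_exponent
                i = np.arange(0, n_bins - d)
                c = rng.poisson(mu, len(i))
                for (cc, li, lj), fold in loop_lut.items():
                    if cc == chrom and lj - li == d:
                        c[li] = rng.poisson(fold * mu)
                nz = c > 0
                for ii, cc_ in zip(i[nz], c[nz]):
                    fh.write(f"{chrom}\t{ii * res}\t{(ii + d) * res}\t{cc_}\n")

    # ------------------------------------------------------------------- TFBS
    ezh2_genes = pa_specific[0::2]
    suz12_genes = pa_specific[0::6]
    tfbs_rows = []
    for factor, site_genes, n_bg_sites in (
        ("EZH2", ezh2_genes, 100),
        ("SUZ12", suz12_genes, 100),
        ("CTCF", [], 150),
    ):
        for g in site_genes:
            p = gene_tss[g] - 100
            tfbs_rows.append(GenomicInterval(gene_chrom[g], p, p + 200,
                                             name=factor))
        for _ in range(n_bg_sites):
            ci = int(rng.integers(len(layout.chrom_names)))
            chrom = layout.chrom_names[ci]
            p = int(rng.integers(0, lengths[chrom] - 200))
            tfbs_rows.append(GenomicInterval(chrom, p, p + 200, name=factor))
    tfbs_path = outdir / "tfbs.bed"
    write_bed(sorted(tfbs_rows, key=lambda iv: (iv.chrom, iv.start)), tfbs_path)

    # ---------------------------------------------------------- conservation
    cons_path = outdir / "conservation.bedgraph"
    elem_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in layout.chrom_names}
    for r in tss_records:
        elem_spans[r.chrom].append((max(0, r.tss - 1000), r.tss + 1000))
    for e in enhancers:
        elem_spans[e.chrom].append((e.start, e.end))
    with open(cons_path, "w") as fh:
        w = 100
        for chrom in layout.chrom_names:
            nb = lengths[chrom] // w
            vals = np.clip(rng.normal(0.06, 0.02, nb), 0.0, 1.0)
            hot = np.zeros(nb, dtype=bool)
            for a, b in elem_spans[chrom]:
                hot[a // w:(b - 1) // w + 1] = True
            vals[hot] = np.clip(rng.normal(0.5, 0.1, int(hot.sum())), 0.0, 1.0)
            for k in range(nb):
                fh.write(f"{chrom}\t{k * w}\t{(k + 1) * w}\t{vals[k]:.4f}\n")

    # ------------------------------------------------------------ methylation
    meth_genes = ezh2_genes  # designated set: PA-specific with EZH2 sites
    meth_tx = [t for g in meth_genes for t in gene_transcripts[g]]
    cpg_rows = []
    for gi, g in enumerate(gene_ids):
        tss1 = gene_tss[g]
        positions = tss1 + rng.integers(-1500, 1501, config.n_cpg_per_promoter)
        shifted = g in meth_genes
        for pj, p in enumerate(sorted(positions)):
            betas = []
            for s in sample_ids:
                if shifted and samples[s] == "PA":
                    m = 0.15
                elif shifted:
                    m = 0.15 + config.methylation_delta
                else:
                    m = 0.5
                conc = 30.0
                betas.append(rng.beta(m * conc, (1 - m) * conc))
            cpg_rows.append([f"cpg_{g}_{pj}", gene_chrom[g], int(p)] + betas)
    beta_path = outdir / "methylation.tsv"
    pd.DataFrame(
        cpg_rows, columns=["id", "chrom", "pos"] + sample_ids
    ).to_csv(beta_path, sep="\t", index=False, float_format="%.4f")

    # ------------------------------------------------------------ tables etc.
    layout_path = outdir / "layout.tsv"
    layout.write(layout_path)
    tss_path = outdir / "tss.tsv"
    write_tss_table(tss_records, tss_path)
    expr_path = outdir / "expression.tsv"
    expr.to_csv(expr_path, sep="\t", index_label="transcript_id")
    meta_path = outdir / "samples.tsv"
    pd.DataFrame(
        {"sample_id": sample_ids, "group": [samples[s] for s in sample_ids]}
    ).to_csv(meta_path, sep="\t", index=False)

    prom_common = {}
    for g in gene_ids:
        if g in common_genes:
            lab = "common"
        else:
            lab = "variable"
        for t in gene_transcripts[g]:
            prom_common[t] = lab
    enh_common = {
        enh_keys[i]: ("common" if i in set(common_enh_idx) else "variable")
        for i in range(len(enhancers))
    }
    truth = GroundTruth(
        samples=samples,
        promoter_commonality=prom_common,
        enhancer_commonality=enh_common,
        pa_specific_transcripts=[t for g in pa_specific
                                 for t in gene_transcripts[g]],
        gb_specific_transcripts=[t for g in gb_specific
                                 for t in gene_transcripts[g]],
        links=[
            {"enhancer": enh_keys[ei], "transcript": t, "rho": config.link_rho,
             "chrom": enhancers[ei].chrom, "bin_i": int(min(eb, tb)),
             "bin_j": int(max(eb, tb))}
            for ei, t, eb, tb in linked
        ],
        decoy_loops=[
            {"enhancer": enh_keys[ei], "transcript": t,
             "chrom": enhancers[ei].chrom, "bin_i": int(min(eb, tb)),
             "bin_j": int(max(eb, tb))}
            for ei, t, eb, tb in decoys
        ],
        ezh2_transcripts=[t for g in ezh2_genes for t in gene_transcripts[g]],
        methylation_shift_transcripts=meth_tx,
        enhancers={enh_keys[i]: [enhancers[i].chrom, enhancers[i].start,
                                 enhancers[i].end]
                   for i in range(len(enhancers))},
    )
    truth_path = outdir / "ground_truth.json"
    truth.to_json(truth_path)

    manifest = {
        "layout": str(layout_path.relative_to(outdir)),
        "tss": str(tss_path.relative_to(outdir)),
        "expression": str(expr_path.relative_to(outdir)),
        "samples": str(meta_path.relative_to(outdir)),
        "contacts": str(contact_path.relative_to(outdir)),
        "tfbs": str(tfbs_path.relative_to(outdir)),
        "conservation": str(cons_path.relative_to(outdir)),
        "methylation": str(beta_path.relative_to(outdir)),
        "ground_truth": str(truth_path.relative_to(outdir)),
        "peaks": {f"{s}.{m}": p for (s, m), p in peak_paths.items()},
        "coverage": {f"{s}.{m}": p for (s, m), p in cov_paths.items()},
        "group_coverage": {f"{g}.{m}.{k}": p
                           for (g, m, k), p in group_paths.items()},
        "library_size": config.library_size,
        "resolution": config.resolution,
        "max_dist": config.max_dist,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     sort_keys=True))
    return Cohort(config, layout, tss_records, truth, outdir, manifest)


# ---------------------------------------------------------------------------
# recovery scoring


def match_elements(
    planted: dict[str, list], catalog: list[GenomicInterval]
) -> dict[str, str]:
    """Map planted enhancer keys to catalog element ids by overlap."""
    out = {}
    for key, (chrom, start, end) in planted.items():
        planted_iv = GenomicInterval(chrom, start, end)
        for iv in catalog:
            if iv.overlaps(planted_iv):
                out[key] = iv.name
                break
    return out


def recovery_metrics(truth_set: set, called_set: set) -> dict:
    """Sensitivity and false-discovery proportion of a called set against
    a planted truth set."""
    tp = len(truth_set & called_set)
    sens = tp / len(truth_set) if truth_set else float("nan")
    fdp = (len(called_set) - tp) / len(called_set) if called_set else 0.0
    return {
        "n_true": len(truth_set),
        "n_called": len(called_set),
        "sensitivity": sens,
        "fdp": fdp,
    }


def truth_report(truth: GroundTruth, outputs: dict[str, set]) -> dict:
    """Recovery metrics per planted structure class.

    ``outputs`` maps class names (subset of: promoter_common,
    enhancer_common, pa_specific, gb_specific, links) to called id sets.
    """
    report = {}
    if "promoter_common" in outputs:
        t = {k for k, v in truth.promoter_commonality.items() if v == "common"}
        report["promoter_common"] = recovery_metrics(t, outputs["promoter_common"])
    if "enhancer_common" in outputs:
        t = {k for k, v in truth.enhancer_commonality.items() if v == "common"}
        report["enhancer_common"] = recovery_metrics(t, outputs["enhancer_common"])
    if "pa_specific" in outputs:
        report["pa_specific"] = recovery_metrics(
            set(truth.pa_specific_transcripts), outputs["pa_specific"]
        )
    if "gb_specific" in outputs:
        report["gb_specific"] = recovery_metrics(
            set(truth.gb_specific_transcripts), outputs["gb_specific"]
        )
    if "links" in outputs:
        t = {(l["enhancer"], l["transcript"]) for l in truth.links}
        report["links"] = recovery_metrics(t, outputs["links"])
    return report
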