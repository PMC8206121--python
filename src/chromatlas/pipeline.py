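"""End-to-end orchestration of the atlas stages on a cohort directory.

Each stage reads its inputs from the cohort/output directories, writes
its outputs plus a stamp file recording a hash of parameters and input
files, and is skipped on rerun when the stamp is unchanged (use
``force=True`` to override).  Stage order: generate -> atlas -> profiles
-> structure -> contacts -> coactivation -> methylation -> report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import atlas, coactivation, cohort as cohort_stats, contacts, methylation
from . import profiles, simulate
from .genomic import (
    GenomeLayout,
    GenomicInterval,
    ScoredTrack,
    read_bed,
    shuffle_intervals,
    write_bed,
)

logger = logging.getLogger(__name__)

STAGES = ["generate", "atlas", "profiles", "structure", "contacts",
          "coactivation", "methylation", "report"]

DEFAULT_PARAMS = {
    "promoter_flank": 1000,
    "methylation_flank": 2000,
    "abundance_flank": 2000,
    "thresholds": {"promoter_H3K4me3": 20, "gene_H3K4me3": 20,
                   "promoter_H3K27ac": 10, "gene_H3K27ac": 10,
                   "enhancer_H3K27ac": 4},
    "z_threshold": 7.0,
    "bin_width": 500,
    "profile_bin": 10,
    "runmean_k": 15,
    "top_fraction": 0.10,
    "resolution": 10_000,
    "max_dist": 2_000_000,
    "contact_alpha": 0.001,
    "specific": {"min_active_a": 4, "max_active_b": 2,
                 "max_active_a": 1, "min_active_b": 11,
                 "p_threshold": 0.003},
    "strata_kb": [20, 200],
    "filter": {"fdr_max": 0.1, "r_min": 0.7, "min_peak_count": 20},
    "resampling": {"draw_size": 260, "reps": 1000},
    "n_shuffles": 200,
    "seed": 0,
}


class DependencyError(RuntimeError):
    """A stage's upstream artifact is missing."""


def _merge_params(overrides: dict | None) -> dict:
    params = json.loads(json.dumps(DEFAULT_PARAMS))
    for k, v in (overrides or {}).items():
        if isinstance(v, dict) and isinstance(params.get(k), dict):
            params[k].update(v)
        else:
            params[k] = v
    return params


def _stamp(outdir: Path, stage: str, params: dict, inputs: list[Path]) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(params, sort_keys=True).encode())
    for p in sorted(str(x) for x in inputs):
        pp = Path(p)
        if not pp.exists():
            raise DependencyError(f"stage {stage}: missing input {p}")
        h.update(p.encode())
        h.update(str(pp.stat().st_size).encode())
        h.update(hashlib.sha256(pp.read_bytes()).hexdigest().encode())
    return h.hexdigest()


def _up_to_date(outdir: Path, stage: str, digest: str) -> bool:
    f = outdir / f".stamp.{stage}"
    return f.exists() and f.read_text() == digest


def _write_stamp(outdir: Path, stage: str, digest: str) -> None:
    (outdir / f".stamp.{stage}").write_text(digest)



def _res(cohort_dir: Path, p) -> Path:
    """Resolve a (possibly relative) manifest path against the cohort dir."""
    q = Path(p)
    return q if q.is_absolute() else Path(cohort_dir) / q

def _load_cohort(cohort_dir: Path):
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    layout = GenomeLayout.read(cohort_dir / "layout.tsv")
    tss = atlas.read_tss_table(cohort_dir / "tss.tsv")
    meta = pd.read_csv(cohort_dir / "samples.tsv", sep="\t")
    groups: dict[str, list[str]] = {}
    for r in meta.itertuples():
        groups.setdefault(r.group, []).append(r.sample_id)
    return manifest, layout, tss, groups


def run(
    cohort_dir,
    outdir,
    stages: list[str] | None = None,
    params: dict | None = None,
    generate_config: "simulate.CohortConfig | None" = None,
    force: bool = False,
) -> dict:
    """Execute the requested stages in dependency order; returns a
    manifest of artifacts per executed stage."""
    cohort_dir, outdir = Path(cohort_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = _merge_params(params)
    wanted = stages or STAGES
    unknown = set(wanted) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    executed: dict[str, dict] = {}
    for stage in STAGES:
        if stage not in wanted:
            continue
        fn = globals()[f"_stage_{stage}"]
        executed[stage] = fn(cohort_dir, outdir, params, generate_config, force)

    def _relativize(x):
        if isinstance(x, dict):
            return {k: _relativize(v) for k, v in x.items()}
        if isinstance(x, str):
            for base in (str(outdir), str(cohort_dir)):
                if x.startswith(base):
                    return str(Path(x).relative_to(base))
        return x

    (outdir / "run_manifest.json").write_text(
        json.dumps(_relativize(executed), indent=1, sort_keys=True, default=str)
    )
    return executed


def _stage_generate(cohort_dir, outdir, params, gen_config, force):
    cfg = gen_config or simulate.CohortConfig(seed=params["seed"])
    digest = _stamp(outdir, "generate",
                    {"cfg": cfg.__dict__, "seed": cfg.seed}, [])
    if not force and _up_to_date(outdir, "generate", digest) and (
        cohort_dir / "manifest.json"
    ).exists():
        logger.info("generate: up to date, skipping")
        return {"skipped": True}
    simulate.generate(cfg, cohort_dir)
    _write_stamp(outdir, "generate", digest)
    return {"cohort_dir": str(cohort_dir)}


def _activity_inputs(cohort_dir):
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    return manifest


def _stage_atlas(cohort_dir, outdir, params, gen_config, force):
    manifest, layout, tss, groups = _load_cohort(cohort_dir)
    inputs = [cohort_dir / "tss.tsv", cohort_dir / "layout.tsv"] + [
        _res(cohort_dir, p) for p in manifest["peaks"].values()
    ]
    digest = _stamp(outdir, "atlas", {"flank": params["promoter_flank"],
                                      "thresholds": params["thresholds"]},
                    inputs)
    if not force and _up_to_date(outdir, "atlas", digest):
        logger.info("atlas: up to date, skipping")
        return {"skipped": True}
    promoters = atlas.define_promoters(tss, layout, params["promoter_flank"])
    samples = [s for g in groups.values() for s in g]
    artifacts = {}
    peaks_by_mark: dict[str, dict] = {}
    for mark in ("H3K4me3", "H3K27ac", "ATAC"):
        peaks_by_mark[mark] = {
            s: read_bed(_res(cohort_dir, manifest["peaks"][f"{s}.{mark}"]), layout)
            for s in samples
        }
        mat = atlas.mark_activity(promoters.windows, peaks_by_mark[mark],
                                  layout, mark)
        path = outdir / f"promoter_activity.{mark}.tsv"
        atlas.write_activity_matrix(mat, path)
        artifacts[f"promoter_activity.{mark}"] = str(path)
        gmat = atlas.gene_activity(mat, promoters)
        gpath = outdir / f"gene_activity.{mark}.tsv"
        atlas.write_activity_matrix(gmat, gpath)
        artifacts[f"gene_activity.{mark}"] = str(gpath)
        thr = params["thresholds"].get(f"promoter_{mark}")
        if thr:
            strat = atlas.stratify(mat, thr)
            spath = outdir / f"promoter_commonality.{mark}.tsv"
            strat.to_csv(spath, sep="\t")
            artifacts[f"promoter_commonality.{mark}"] = str(spath)
    catalog = atlas.call_enhancers(peaks_by_mark["H3K27ac"], promoters, layout)
    cpath = outdir / "enhancers.bed"
    catalog.write_bed(cpath)
    artifacts["enhancers"] = str(cpath)
    epath = outdir / "enhancer_activity.tsv"
    atlas.write_activity_matrix(catalog.provenance, epath)
    artifacts["enhancer_activity"] = str(epath)
    strat = atlas.stratify(catalog.provenance,
                           params["thresholds"]["enhancer_H3K27ac"])
    spath = outdir / "enhancer_commonality.tsv"
    strat.to_csv(spath, sep="\t")
    artifacts["enhancer_commonality"] = str(spath)
    _write_stamp(outdir, "atlas", digest)
    return artifacts


def _read_tracks(cohort_dir, layout, samples, mark, params):
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    lib = manifest["library_size"]
    return {
        s: profiles.read_binned_bedgraph(
            _res(cohort_dir, manifest["coverage"][f"{s}.{mark}"]), layout,
            params["bin_width"], lib
        )
        for s in samples
    }


def _stage_profiles(cohort_dir, outdir, params, gen_config, force):
    manifest, layout, tss, groups = _load_cohort(cohort_dir)
    samples = [s for g in groups.values() for s in g]
    inputs = [_res(cohort_dir, p) for p in manifest["coverage"].values()]
    inputs += [_res(cohort_dir, p) for p in manifest["group_coverage"].values()]
    digest = _stamp(outdir, "profiles",
                    {k: params[k] for k in ("bin_width", "abundance_flank",
                                            "top_fraction", "profile_bin",
                                            "runmean_k")},
                    inputs)
    if not force and _up_to_date(outdir, "profiles", digest):
        logger.info("profiles: up to date, skipping")
        return {"skipped": True}
    windows = profiles.tss_windows(tss, layout, params["abundance_flank"])
    artifacts = {}
    abundance_by_mark = {}
    for mark in ("H3K4me3", "H3K27ac"):
        chip = _read_tracks(cohort_dir, layout, samples, mark, params)
        inp = _read_tracks(cohort_dir, layout, samples, "input", params)
        tab = pd.DataFrame({
            s: profiles.abundance(chip[s], inp[s], windows) for s in samples
        })
        path = outdir / f"abundance.{mark}.tsv"
        tab.to_csv(path, sep="\t")
        artifacts[f"abundance.{mark}"] = str(path)
        abundance_by_mark[mark] = tab
    pa = groups.get("PA", [])
    dagb = groups.get("DA", []) + groups.get("GB", [])
    if pa and dagb:
        a = abundance_by_mark["H3K27ac"][pa].mean(axis=1)
        b = abundance_by_mark["H3K27ac"][dagb].mean(axis=1)
        # regions with H3K27ac higher in the benign group, top decile
        selected = profiles.select_top_decile(a, b, params["top_fraction"])
        spath = outdir / "top_decile_regions.tsv"
        pd.Series(selected, name="region").to_csv(spath, sep="\t", index=False)
        artifacts["top_decile_regions"] = str(spath)
        # metaprofiles around the selected TSSs from pooled group tracks
        sel_tss = [(w.chrom, (w.start + w.end) // 2)
                   for rid, w in windows.items() if rid in set(selected)]
        prof_rows = []
        for gname in groups:
            chip_t = profiles.read_binned_bedgraph(
                _res(cohort_dir, manifest["group_coverage"][f"{gname}.H3K27ac.chip"]), layout,
                params["profile_bin"], manifest["library_size"])
            inp_t = profiles.read_binned_bedgraph(
                _res(cohort_dir, manifest["group_coverage"][f"{gname}.H3K27ac.input"]), layout,
                params["profile_bin"], manifest["library_size"])
            prof = profiles.tss_metaprofile(
                [chip_t], [inp_t], sel_tss, layout,
                flank=params["abundance_flank"],
                bin_width=params["profile_bin"], k=params["runmean_k"])
            for off, m, lo, hi in zip(prof.offsets, prof.mean,
                                      prof.ci_low, prof.ci_high):
                prof_rows.append((gname, int(off), m, lo, hi))
        ppath = outdir / "tss_metaprofiles.tsv"
        pd.DataFrame(prof_rows, columns=["group", "offset", "mean",
                                         "ci_low", "ci_high"]).to_csv(
            ppath, sep="\t", index=False)
        artifacts["tss_metaprofiles"] = str(ppath)
    _write_stamp(outdir, "profiles", digest)
    return artifacts


def _stage_structure(cohort_dir, outdir, params, gen_config, force):
    manifest, layout, tss, groups = _load_cohort(cohort_dir)
    act_path = outdir / "promoter_activity.H3K4me3.tsv"
    if not act_path.exists():
        raise DependencyError("structure: run the atlas stage first "
                              f"(missing {act_path})")
    inputs = [act_path, _res(cohort_dir, manifest["tfbs"]),
              _res(cohort_dir, manifest["conservation"])]
    digest = _stamp(outdir, "structure", params["specific"], inputs)
    if not force and _up_to_date(outdir, "structure", digest):
        logger.info("structure: up to date, skipping")
        return {"skipped": True}
    artifacts = {}
    mat = atlas.read_activity_matrix(act_path)
    sim = cohort_stats.jaccard_similarity(mat)
    jpath = outdir / "sample_jaccard.tsv"
    sim.to_csv(jpath, sep="\t")
    artifacts["sample_jaccard"] = str(jpath)
    dendro = cohort_stats.upgma(sim)
    npath = outdir / "sample_dendrogram.newick"
    Path(npath).write_text(dendro.to_newick() + "\n")
    artifacts["sample_dendrogram"] = str(npath)
    sp = params["specific"]
    spec = cohort_stats.GroupSpec(
        group_a=groups.get("PA", []), group_b=groups.get("GB", []),
        min_active_a=sp["min_active_a"], max_active_b=sp["max_active_b"],
        max_active_a=sp["max_active_a"], min_active_b=sp["min_active_b"],
        p_threshold=sp["p_threshold"],
    )
    calls = cohort_stats.call_specific_promoters(mat, spec)
    cpath = outdir / "specific_promoters.json"
    Path(cpath).write_text(json.dumps(calls, indent=1))
    artifacts["specific_promoters"] = str(cpath)

    # TFBS enrichment: group-specific promoters vs promoters active in all
    promoters = atlas.define_promoters(tss, layout, params["promoter_flank"])
    target = [promoters.windows[t] for t in calls["specific_in_a"]]
    always_active = mat.index[mat.all(axis=1)]
    reference = [promoters.windows[t] for t in always_active]
    tfbs = read_bed(_res(cohort_dir, manifest["tfbs"]), layout)
    by_factor: dict[str, list] = {}
    for iv in tfbs:
        by_factor.setdefault(iv.name or "NA", []).append(iv)
    if target and reference:
        enr = cohort_stats.tfbs_enrichment(target, reference, by_factor)
        tpath = outdir / "tfbs_enrichment.tsv"
        enr.to_csv(tpath, sep="\t")
        artifacts["tfbs_enrichment"] = str(tpath)

    # conservation of common elements versus shuffled intervals
    track = ScoredTrack.read_bedgraph(_res(cohort_dir, manifest["conservation"]))
    cons_rows = []
    for label, path in (("promoter", outdir / "promoter_commonality.H3K4me3.tsv"),
                        ("enhancer", outdir / "enhancer_commonality.tsv")):
        if not path.exists():
            continue
        strat = pd.read_csv(path, sep="\t", index_col=0)["commonality"]
        common_ids = set(strat[strat == "common"].index)
        if label == "promoter":
            ivs = [promoters.windows[t] for t in common_ids
                   if t in promoters.windows]
        else:
            cat = read_bed(outdir / "enhancers.bed", layout)
            ivs = [iv for iv in cat if iv.name in common_ids]
        if not ivs:
            continue
        shuffled = shuffle_intervals(ivs, layout, params["seed"])
        obs = cohort_stats.interval_mean_scores(ivs, track)
        rnd = cohort_stats.interval_mean_scores(shuffled, track)
        u, p = cohort_stats.conservation_compare(obs, rnd)
        cons_rows.append((label, len(ivs), float(np.nanmean(obs)),
                          float(np.nanmean(rnd)), u, p))
    if cons_rows:
        cpath2 = outdir / "conservation.tsv"
        pd.DataFrame(cons_rows, columns=["elements", "n", "mean_score",
                                         "mean_shuffled", "U", "p"]).to_csv(
            cpath2, sep="\t", index=False)
        artifacts["conservation"] = str(cpath2)
    _write_stamp(outdir, "structure", digest)
    return artifacts


def _stage_contacts(cohort_dir, outdir, params, gen_config, force):
    manifest, layout, tss, groups = _load_cohort(cohort_dir)
    enh_path = outdir / "enhancers.bed"
    if not enh_path.exists():
        raise DependencyError("contacts: run the atlas stage first "
                              f"(missing {enh_path})")
    inputs = [_res(cohort_dir, manifest["contacts"]), enh_path]
    digest = _stamp(outdir, "contacts",
                    {"alpha": params["contact_alpha"],
                     "resolution": params["resolution"],
                     "max_dist": params["max_dist"]}, inputs)
    if not force and _up_to_date(outdir, "contacts", digest):
        logger.info("contacts: up to date, skipping")
        return {"skipped": True}
    enh = read_bed(enh_path, layout)
    promoters = atlas.define_promoters(tss, layout, params["promoter_flank"])
    calls_path = outdir / "contact_calls.tsv"
    pairs_frames = []
    enrich_rows = []
    first = True
    for chrom in layout.chrom_names:
        cmap = contacts.ContactMap.read_triplets(
            _res(cohort_dir, manifest["contacts"]), chrom, layout.length_of(chrom),
            params["resolution"], params["max_dist"])
        if len(cmap.count) == 0:
            continue
        null = contacts.fit_decay_null(cmap)
        anchors = [iv for iv in enh if iv.chrom == chrom]
        calls = contacts.call_contacts(cmap, anchors, null,
                                       params["contact_alpha"])
        calls.write_tsv(calls_path, mode="w" if first else "a", header=first)
        first = False
        pairs_frames.append(
            contacts.map_targets_to_promoters(calls, promoters.windows)
        )
        fold, p = contacts.target_promoter_enrichment(
            calls, promoters.windows, layout,
            n_shuffles=params["n_shuffles"], seed=params["seed"])
        enrich_rows.append((chrom, fold, p))
    pairs = (
        pd.concat(pairs_frames, ignore_index=True)
        if pairs_frames else pd.DataFrame(
            columns=["anchor_id", "transcript_id", "target_bin"])
    )
    ppath = outdir / "contact_pairs.tsv"
    pairs.to_csv(ppath, sep="\t", index=False)
    epath = outdir / "target_promoter_enrichment.tsv"
    pd.DataFrame(enrich_rows, columns=["chrom", "fold", "p"]).to_csv(
        epath, sep="\t", index=False)
    _write_stamp(outdir, "contacts", digest)
    return {"contact_calls": str(calls_path), "contact_pairs": str(ppath),
            "target_promoter_enrichment": str(epath)}


def _stage_coactivation(cohort_dir, outdir, params, gen_config, force):
    manifest, layout, tss, groups = _load_cohort(cohort_dir)
    samples = [s for g in groups.values() for s in g]
    need = [outdir / "contact_pairs.tsv", outdir / "enhancers.bed"]
    for p in need:
        if not p.exists():
            raise DependencyError(f"coactivation: missing {p}")
    inputs = need + [_res(cohort_dir, manifest["expression"])]
    digest = _stamp(outdir, "coactivation",
                    {"filter": params["filter"],
                     "resampling": params["resampling"]}, inputs)
    if not force and _up_to_date(outdir, "coactivation", digest):
        logger.info("coactivation: up to date, skipping")
        return {"skipped": True}
    artifacts = {}
    expr_counts = coactivation.read_expression(_res(cohort_dir, manifest["expression"]))
    expr_counts = expr_counts[samples]
    expr_norm = coactivation.quantile_normalize(expr_counts)
    promoters = atlas.define_promoters(tss, layout, params["promoter_flank"])

    # promoter mark coverage vs expression
    chip = _read_tracks(cohort_dir, layout, samples, "H3K4me3", params)
    prom_cov = pd.DataFrame({
        s: profiles.region_mean(chip[s], promoters.windows) for s in samples
    })
    pc = {r.transcript_id for r in tss if r.protein_coding}
    res, summary = coactivation.promoter_mark_expression_corr(
        prom_cov, expr_counts, promoters.gene_of, pc)
    qpath = outdir / "promoter_expression_quantiles.tsv"
    summary.to_csv(qpath, sep="\t")
    artifacts["promoter_expression_quantiles"] = str(qpath)

    # enhancer coverage (chip - input abundance over the element)
    cat = read_bed(outdir / "enhancers.bed", layout)
    regions = {iv.name: iv for iv in cat}
    k27 = _read_tracks(cohort_dir, layout, samples, "H3K27ac", params)
    inp = _read_tracks(cohort_dir, layout, samples, "input", params)
    enh_cov = pd.DataFrame({
        s: profiles.abundance(k27[s], inp[s], regions) for s in samples
    })

    closest = coactivation.assign_closest(cat, tss)
    cpairs_raw = pd.read_csv(outdir / "contact_pairs.tsv", sep="\t")
    tss_pos = {r.transcript_id: r.tss for r in tss}
    cpairs = coactivation.contact_pairs_table(cpairs_raw, regions, tss_pos)
    all_pairs = pd.concat([closest, cpairs], ignore_index=True)
    group_results = coactivation.correlate_pairs(all_pairs, enh_cov, expr_norm)
    rows = [(res.label, res.n_pairs, res.spearman_r)]
    rows += [(g.label, g.n_pairs, g.spearman_r) for g in group_results]
    rpath = outdir / "coactivation_correlations.tsv"
    pd.DataFrame(rows, columns=["group", "n", "spearman_r"]).to_csv(
        rpath, sep="\t", index=False)
    artifacts["coactivation_correlations"] = str(rpath)

    # resampling comparison: contact pairs vs distal closest pairs
    distal = closest[closest["stratum"] == "distal"].dropna(
        subset=["transcript_id"])
    rs = params["resampling"]
    if len(distal) < rs["draw_size"]:
        # gene-dense genomes may lack distal closest pairs; fall back to
        # the full closest-pair set as the reference population
        logger.info("resampling: only %d distal closest pairs, using all "
                    "closest pairs as reference", len(distal))
        distal = closest.dropna(subset=["transcript_id"])
    if len(cpairs) >= 2 and len(distal) >= 2:
        draw = min(rs["draw_size"], len(distal))
        obs_r, pval = coactivation.resampling_pvalue(
            distal, cpairs, enh_cov, expr_norm,
            draw_size=draw, reps=rs["reps"], seed=params["seed"])
        spath = outdir / "resampling.json"
        Path(spath).write_text(json.dumps(
            {"observed_R": obs_r, "p": pval, "draw_size": draw,
             "reps": rs["reps"], "n_reference": len(distal)}, indent=1))
        artifacts["resampling"] = str(spath)

    flt = params["filter"]
    sig = coactivation.filter_significant_pairs(
        cpairs, enh_cov, expr_norm, expr_counts,
        fdr_max=flt["fdr_max"], r_min=flt["r_min"],
        min_peak_count=flt["min_peak_count"])
    fpath = outdir / "significant_pairs.tsv"
    sig.to_csv(fpath, sep="\t", index=False)
    artifacts["significant_pairs"] = str(fpath)
    _write_stamp(outdir, "coactivation", digest)
    return artifacts


def _stage_methylation(cohort_dir, outdir, params, gen_config, force):
    manifest, layout, tss, groups = _load_cohort(cohort_dir)
    spath = outdir / "specific_promoters.json"
    if not spath.exists():
        raise DependencyError(f"methylation: missing {spath}")
    inputs = [_res(cohort_dir, manifest["methylation"]), spath]
    digest = _stamp(outdir, "methylation",
                    {"flank": params["methylation_flank"]}, inputs)
    if not force and _up_to_date(outdir, "methylation", digest):
        logger.info("methylation: up to date, skipping")
        return {"skipped": True}
    betas = methylation.read_beta_table(_res(cohort_dir, manifest["methylation"]))
    promoters = atlas.define_promoters(tss, layout, params["methylation_flank"])
    pm = methylation.promoter_methylation(betas, promoters.windows)
    mpath = outdir / "promoter_methylation.tsv"
    pm.to_csv(mpath, sep="\t")
    calls = json.loads(spath.read_text())
    results = {}
    focal = calls["specific_in_a"]
    if focal and "PA" in groups and "GB" in groups:
        u, p = methylation.group_methylation_compare(
            pm, focal, groups["PA"], groups["GB"])
        results["pa_specific_promoters"] = {"U": u, "p": p,
                                            "n_promoters": len(focal)}
    rpath = outdir / "methylation_comparison.json"
    Path(rpath).write_text(json.dumps(results, indent=1))
    _write_stamp(outdir, "methylation", digest)
    return {"promoter_methylation": str(mpath),
            "methylation_comparison": str(rpath)}


def _stage_report(cohort_dir, outdir, params, gen_config, force):
    truth_path = cohort_dir / "ground_truth.json"
    if not truth_path.exists():
        return {"skipped": True, "reason": "no ground truth"}
    truth = simulate.GroundTruth.from_json(truth_path)
    _, layout, tss, groups = _load_cohort(cohort_dir)
    outputs: dict[str, set] = {}
    pc_path = outdir / "promoter_commonality.H3K4me3.tsv"
    if pc_path.exists():
        strat = pd.read_csv(pc_path, sep="\t", index_col=0)["commonality"]
        outputs["promoter_common"] = set(strat[strat == "common"].index)
    ec_path = outdir / "enhancer_commonality.tsv"
    if ec_path.exists():
        strat = pd.read_csv(ec_path, sep="\t", index_col=0)["commonality"]
        cat = read_bed(outdir / "enhancers.bed", layout)
        mapping = simulate.match_elements(truth.enhancers, cat)
        inv = {v: k for k, v in mapping.items()}
        outputs["enhancer_common"] = {
            inv[i] for i in strat[strat == "common"].index if i in inv
        }
    sp_path = outdir / "specific_promoters.json"
    if sp_path.exists():
        calls = json.loads(sp_path.read_text())
        outputs["pa_specific"] = set(calls["specific_in_a"])
        outputs["gb_specific"] = set(calls["specific_in_b"])
    sig_path = outdir / "significant_pairs.tsv"
    if sig_path.exists():
        sig = pd.read_csv(sig_path, sep="\t")
        kept = sig[sig["kept"]]
        cat = read_bed(outdir / "enhancers.bed", layout)
        mapping = simulate.match_elements(truth.enhancers, cat)
        inv = {v: k for k, v in mapping.items()}
        outputs["links"] = {
            (inv.get(r.enhancer_id, r.enhancer_id), r.transcript_id)
            for r in kept.itertuples()
        }
    report = simulate.truth_report(truth, outputs)
    rpath = outdir / "recovery_report.json"
    Path(rpath).write_text(json.dumps(report, indent=1, sort_keys=True))
    return {"recovery_report": str(rpath)}
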