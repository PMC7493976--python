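"""End-to-end orchestration: manifest in, per-stage outputs + summary out.

Stages run in dependency order (atlas -> constitutive -> specificity ->
domains, then Hi-C / methylation / mutation / enrichment as inputs permit);
modalities absent from the manifest are skipped with an explicit status
rather than failing, since real cohorts rarely have every data type.  Each
stage writes only to its own subdirectory, and ``run_metadata.json``
snapshots the config, input checksums, stage statuses and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io as cio
from .atlas import (UnionAtlas, annotate_motifs, build_union_atlas,
                    compute_occupancy)
from .config import PipelineConfig, load_config
from .constitutive import (OccupancyDistribution, determine_cutoff,
                           fit_power_law, select_constitutive)
from .domains import build_domains
from .enrichment import RegulatoryRepertoire, overlap_repertoire, tf_rank_enrichment
from .hic import differential_interaction_table, find_differential_regions, normalize_by_distance
from .methylation import binding_methylation_association, region_methylation_table
from .mutation import motif_disruption_table, mutation_rate_profile
from .pwm import PWM
from .specificity import (CohortDesign, call_cancer_specific_sites,
                          compute_rpkm, differential_binding, quantile_normalize)
from .synthetic import ScenarioConfig, generate_scenario, write_scenario

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(manifest_path: str | Path, outdir: str | Path) -> Path:
    """Run every stage the manifest provides inputs for.

    The manifest is a YAML mapping with (relative) paths: ``peaks`` (mapping
    dataset id -> file), ``design``, ``counts``, ``site_regions``,
    ``site_lengths``, ``library_sizes``, ``cancer_type`` and optionally
    ``genome``, ``pfm``, ``hic_cancer``/``hic_normal``, ``methylation_*``,
    ``mutations``, ``genes``, ``de_table``, ``repertoire``/``tf_profiles``
    and ``config``.  Missing required inputs fail before any compute.
    """
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    with open(manifest_path) as fh:
        man = yaml.safe_load(fh)

    def path_of(key):
        v = man.get(key)
        return (base / v) if v else None

    required = ["peaks", "design", "counts", "site_regions", "cancer_type"]
    missing = [k for k in required if k not in man]
    if missing:
        raise ValueError(f"manifest missing required keys: {missing}")

    cfg = load_config(path_of("config")) if man.get("config") else PipelineConfig()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict = {}
    checksums = {}

    # ---------------- atlas ----------------
    stage = out / "atlas"
    stage.mkdir(exist_ok=True)
    datasets = []
    for ds_id, rel in man["peaks"].items():
        p = base / rel
        checksums[str(rel)] = _sha256(p)
        datasets.append(cio.read_peak_dataset(p, cfg, dataset_id=ds_id))
    excluded = [d.dataset_id for d in datasets if not d.included]
    if excluded:
        logger.warning("excluded datasets: %s", excluded)
    chrom_sizes = (cio.read_chrom_sizes(path_of("chrom_sizes"))
                   if man.get("chrom_sizes") else None)
    atlas = build_union_atlas(datasets, cfg, chrom_sizes)
    atlas = compute_occupancy(atlas, datasets, cfg)
    genome = pfm = None
    if man.get("genome") and man.get("pfm"):
        genome = cio.read_fasta(path_of("genome"))
        name, counts_pfm = cio.read_pfm_jaspar(path_of("pfm"))
        pfm = PWM.from_counts(counts_pfm, background=cfg.pwm_background,
                              pseudocount=cfg.pwm_pseudocount, name=name)
        atlas = annotate_motifs(atlas, genome, pfm, cfg)
        status["motif_scan"] = "ok"
    else:
        status["motif_scan"] = "skipped"
    cio.write_atlas_table(atlas, stage / "atlas.tsv")
    cio.write_sites_bed(atlas, stage / "atlas.bed")
    status["atlas"] = f"ok ({len(atlas)} sites, {atlas.n_datasets} datasets)"

    # ---------------- constitutive ----------------
    stage = out / "constitutive"
    stage.mkdir(exist_ok=True)
    hc = atlas.high_confidence(cfg)
    dist = OccupancyDistribution.from_atlas(hc)
    A = None
    fit_info: dict = {}
    try:
        fit = fit_power_law(dist, (cfg.high_confidence_min_occupancy,
                                   max(1, int(0.6 * atlas.n_datasets))))
        A = determine_cutoff(dist, fit, cfg.excess_factor)
        fit_info = {"a": fit.a, "b": fit.b, "c": fit.c, "residual": fit.residual,
                    "fit_range": list(fit.fit_range)}
    except Exception as exc:  # degenerate desk-scale distributions
        logger.warning("power-law fit unavailable (%s); frequency fallback", exc)
    constitutive = select_constitutive(hc, A, cfg)
    cio.write_sites_bed(constitutive, stage / "constitutive.bed")
    cio.write_json({"A": A, "fit": fit_info,
                    "n_constitutive": len(constitutive)}, stage / "fit.json")
    status["constitutive"] = f"ok (A={A}, {len(constitutive)} sites)"

    # ---------------- specificity ----------------
    stage = out / "specificity"
    stage.mkdir(exist_ok=True)
    design = CohortDesign(cio.read_design_table(path_of("design")))
    counts = cio.read_matrix_tsv(path_of("counts"))
    regions = cio.read_bed(path_of("site_regions"))
    lengths = (pd.read_csv(path_of("site_lengths"), sep="\t", index_col=0)
               .iloc[:, 0] if man.get("site_lengths")
               else pd.Series((regions["end"] - regions["start"]).to_numpy(float),
                              index=regions["name"]))
    libs = (pd.read_csv(path_of("library_sizes"), sep="\t", index_col=0).iloc[:, 0]
            if man.get("library_sizes")
            else pd.Series(1e6, index=counts.columns))
    keep_cols = [d.dataset_id for d in datasets if d.included]
    counts = counts[[c for c in counts.columns if c in keep_cols]]
    rpkm = compute_rpkm(counts, lengths.loc[counts.index], libs.loc[counts.columns])
    norm = quantile_normalize(rpkm)
    # map the quantification regions onto atlas sites by region center
    arrays = atlas.chrom_arrays()
    region_site = {}
    for r in regions.itertuples(index=False):
        site = atlas.locate(r.chrom, (r.start + r.end) // 2, arrays)
        if site is not None:
            region_site[r.name] = site.site_id
    norm_sites = norm.loc[[n for n in norm.index if n in region_site]]
    norm_sites.index = [region_site[n] for n in norm_sites.index]
    norm_sites = norm_sites[~norm_sites.index.duplicated()]
    cancer_type = man["cancer_type"]
    call_atlas = atlas.subset(norm_sites.index)
    calls = call_cancer_specific_sites(call_atlas, datasets, norm_sites,
                                       design, cancer_type, cfg)
    calls.to_csv(stage / "calls.tsv", sep="\t")
    status["specificity"] = (f"{calls.attrs.get('status')} "
                             f"({(calls['call'] == 'lost').sum()} lost, "
                             f"{(calls['call'] == 'gained').sum()} gained)")
    called = calls[calls["call"] != "none"]
    called_sites = [atlas[s] for s in called.index]

    # ---------------- domains ----------------
    stage = out / "domains"
    stage.mkdir(exist_ok=True)
    domains = build_domains(called_sites, constitutive, cfg)
    rows = [(d.chrom, d.left_pos, d.right_pos, sid)
            for sid, d in domains.items()]
    cio.write_bed(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]),
                  stage / "domains.bed")
    status["domains"] = f"ok ({len(domains)}/{len(called_sites)} sites with domains)"

    # ---------------- Hi-C ----------------
    stage = out / "hic"
    stage.mkdir(exist_ok=True)
    hic_diff = None
    if man.get("hic_cancer") and man.get("hic_normal"):
        maps_c = {c: normalize_by_distance(m)
                  for c, m in cio.read_contact_tsv(path_of("hic_cancer")).items()}
        maps_n = {c: normalize_by_distance(m)
                  for c, m in cio.read_contact_tsv(path_of("hic_normal")).items()}
        hic_diff = differential_interaction_table(called_sites, maps_c, maps_n, cfg)
        hic_diff.to_csv(stage / "differential_interaction.tsv", sep="\t")
        gained_sites = [atlas[s] for s in called[called["call"] == "gained"].index]
        lost_sites = [atlas[s] for s in called[called["call"] == "lost"].index]
        inc = find_differential_regions(gained_sites, maps_c, maps_n, domains,
                                        cfg, "increased")
        dec = find_differential_regions(lost_sites, maps_c, maps_n, domains,
                                        cfg, "decreased")
        inc.to_csv(stage / "increased_regions.tsv", sep="\t", index=False)
        dec.to_csv(stage / "decreased_regions.tsv", sep="\t", index=False)
        status["hic"] = f"ok ({len(inc)} increased, {len(dec)} decreased bins)"
    else:
        inc = None
        status["hic"] = "skipped"

    # ---------------- methylation ----------------
    stage = out / "methylation"
    stage.mkdir(exist_ok=True)
    meth_table = None
    if man.get("methylation_cancer") and man.get("methylation_normal"):
        meth_c = cio.read_cpg_table(path_of("methylation_cancer"))
        meth_n = cio.read_cpg_table(path_of("methylation_normal"))
        all_sites = [atlas[s] for s in norm_sites.index]
        meth_table = region_methylation_table(all_sites, meth_c, meth_n, cfg)
        meth_table.to_csv(stage / "region_methylation.tsv", sep="\t")
        vs_others = differential_binding(
            norm_sites, design.cancer_datasets(cancer_type),
            design.other_datasets(cancer_type))
        assoc_in = meth_table.join(vs_others[["t_statistic"]])
        try:
            assoc = binding_methylation_association(assoc_in)
            assoc.to_csv(stage / "binding_methylation_association.tsv",
                         sep="\t", index=False)
            status["methylation"] = "ok"
        except ValueError as exc:
            status["methylation"] = f"association skipped: {exc}"
    else:
        status["methylation"] = "skipped"

    # ---------------- mutations ----------------
    stage = out / "mutations"
    stage.mkdir(exist_ok=True)
    if man.get("mutations"):
        muts = cio.read_mutations(path_of("mutations"))
        profiles = {}
        for label, group in (("lost", "lost"), ("gained", "gained")):
            sel = [atlas[s] for s in called[called["call"] == group].index]
            if sel:
                profiles[label] = mutation_rate_profile(sel, muts, cfg)
        if profiles:
            pd.DataFrame(profiles).to_csv(stage / "mutation_profiles.tsv", sep="\t")
        if genome is not None and pfm is not None and called_sites:
            deltas = motif_disruption_table(called_sites, muts, genome, pfm, cfg)
            deltas.to_csv(stage / "motif_deltas.tsv", sep="\t", index=False)
        status["mutations"] = "ok"
    else:
        status["mutations"] = "skipped"

    # ---------------- enrichment ----------------
    stage = out / "enrichment"
    stage.mkdir(exist_ok=True)
    if man.get("repertoire") and man.get("tf_profiles") and inc is not None \
            and len(inc):
        rep = RegulatoryRepertoire(cio.read_bed(path_of("repertoire")))
        profiles = cio.read_matrix_tsv(path_of("tf_profiles")).reset_index(drop=True)
        sel = overlap_repertoire(inc, rep)
        if sel.any():
            ranking = tf_rank_enrichment(sel, profiles)
            ranking.to_csv(stage / "tf_ranking.tsv", sep="\t", index=False)
            status["enrichment"] = f"ok (top: {ranking.iloc[0]['tf']})"
        else:
            status["enrichment"] = "skipped (no repertoire overlap)"
    else:
        status["enrichment"] = "skipped"

    # ---------------- summary ----------------
    summary = calls[["call", "cancer_freq", "overall_freq", "normal_freq",
                     "t_vs_others", "fdr_vs_others", "t_vs_normal",
                     "fdr_vs_normal", "mean_cancer_signal"]].copy()
    summary["domain"] = [
        f"{domains[s].left_pos}-{domains[s].right_pos}" if s in domains else ""
        for s in summary.index]
    if hic_diff is not None:
        summary = summary.join(hic_diff[["p_value"]].rename(
            columns={"p_value": "hic_p_value"}))
    if meth_table is not None:
        summary = summary.join(meth_table[["status", "mean_delta"]].rename(
            columns={"status": "methylation_status", "mean_delta": "meth_delta"}))
    summary.to_csv(out / "summary.tsv", sep="\t")

    cio.write_json({
        "version": __version__, "config": cfg.to_dict(),
        "seed": cfg.random_seed, "stages": status,
        "input_checksums": checksums,
    }, out / "run_metadata.json")
    logger.info("pipeline complete: %s", status)
    return out


def make_demo(seed: int, outdir: str | Path,
              scenario_cfg: ScenarioConfig | None = None) -> Path:
    """Write a default synthetic scenario plus a ready-to-run manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = scenario_cfg if scenario_cfg is not None else ScenarioConfig(seed=seed)
    scenario = generate_scenario(cfg)
    write_scenario(scenario, out)
    with open(out / "scenario.json") as fh:
        import json
        files = json.load(fh)["files"]
    manifest = {
        "peaks": files["peaks"],
        "design": files["design"],
        "counts": files["counts"],
        "site_regions": files["site_regions"],
        "site_lengths": files["site_lengths"],
        "library_sizes": files["library_sizes"],
        "chrom_sizes": files["chrom_sizes"],
        "genome": files["genome"],
        "pfm": files["pfm"],
        "cancer_type": cfg.cancer_type,
        "config": files["pipeline_config"],
        "hic_cancer": files.get("hic_cancer"),
        "hic_normal": files.get("hic_normal"),
        "methylation_cancer": files.get("methylation_cancer"),
        "methylation_normal": files.get("methylation_normal"),
        "mutations": files.get("mutations"),
        "genes": files["genes"],
        "de_table": files["de_table"],
        "repertoire": files["repertoire"],
        "tf_profiles": files["tf_profiles"],
    }
    manifest = {k: v for k, v in manifest.items() if v is not None}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return out / "manifest.yaml"
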