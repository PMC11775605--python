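"""End-to-end orchestration: simulate/load -> normalize -> classify ->
shift tests -> distances, with a manifest recording parameters and seed."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .config import NormalizationParams, PipelineConfig
from .containers import CountMatrix, MORPH_TO_CLASS, validate_metadata
from .de import annotate_chromosome, classify_tissues, classify_wholebody
from .distance import (
    bootstrap_support,
    filter_variants,
    focal_mode_divergence,
    genotype_pca,
    mantel_test,
    nei_distance,
    nj_tree,
    transcriptomic_distance,
)
from .normalization import (
    lineage_average,
    normalize_and_filter,
    two_stage_average,
)
from .shift import (
    leave_one_out_check,
    pairwise_lineage_ratios,
    shift_table,
    subdivide_and_test,
    class_tests,
)
from .simulate import simulate_counts, simulate_genotypes, simulate_outgroup

log = logging.getLogger("morphshift")

SHIFT_MORPHS = ("parthenogenetic_female", "male")


def _jsonable(obj):
    """Make nested config structures JSON-serializable (tuple keys -> str)."""
    if isinstance(obj, dict):
        return {
            "|".join(map(str, k)) if isinstance(k, tuple) else str(k): _jsonable(v)
            for k, v in obj.items()
        }
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(_jsonable(dataclasses.asdict(config)), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def build_class_table(
    outgroup_counts: pd.DataFrame,
    outgroup_meta: pd.DataFrame,
    tissue_counts: pd.DataFrame | None,
    tissue_meta: pd.DataFrame | None,
    annotation: pd.Series | None,
    norm_params: NormalizationParams,
    class_params,
) -> pd.DataFrame:
    """Full per-gene classification table from the reference datasets.

    Columns: morph_bias, degree, tissue_bias (the biased tissue in the
    gene's own bias morph, 'none' otherwise), chromosome_class.
    """
    ref_norm = dataclasses.replace(norm_params, min_libraries=2)
    classes = classify_wholebody(outgroup_counts, outgroup_meta, ref_norm,
                                 class_params)
    tissue_label = pd.Series("none", index=classes.index, dtype=object)
    if tissue_counts is not None:
        tissue_classes = classify_tissues(tissue_counts, tissue_meta, ref_norm,
                                          class_params)
        for morph in tissue_classes.columns:
            sel = classes.index[classes["morph_bias"] == morph]
            sel = sel.intersection(tissue_classes.index)
            lab = tissue_classes.loc[sel, morph]
            tissue_label.loc[sel] = lab.where(lab != "none", "none")
    classes["tissue_bias"] = tissue_label
    if annotation is not None:
        classes["chromosome_class"] = annotate_chromosome(classes.index, annotation)
    else:
        classes["chromosome_class"] = "unplaced"
    return classes


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage and write the result bundle under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    chash = config_hash(config)
    bundle: dict = {"config_hash": chash, "seed": config.seed}

    # ------------------------------------------------------------------ inputs
    if config.simulate:
        sim = dataclasses.replace(config.sim, seed=config.sim.seed or config.seed)
        gsim = dataclasses.replace(
            config.genotype_sim, seed=config.genotype_sim.seed or config.seed
        )
        log.info("simulating focal, outgroup and genotype data (seed=%s)", sim.seed)
        focal, meta, truth = simulate_counts(sim)
        out_wb, out_tissue, out_meta = simulate_outgroup(sim)
        genotypes_raw = simulate_genotypes(gsim)
        vcf_path = outdir / "genotypes.vcf"
        msio.write_vcf(genotypes_raw, vcf_path)
        annotation = truth["chromosome"]
        msio.write_counts(focal, outdir / "focal_counts.tsv")
        msio.write_table(meta, outdir / "focal_metadata.tsv")
        msio.write_table(truth, outdir / "gene_truth.tsv")
        msio.write_counts(out_wb, outdir / "outgroup_wholebody_counts.tsv")
        msio.write_counts(out_tissue, outdir / "outgroup_tissue_counts.tsv")
        msio.write_table(out_meta, outdir / "outgroup_metadata.tsv")
        bundle["truth"] = truth
    else:
        focal = msio.read_counts(config.counts_path)
        meta = msio.read_metadata(config.metadata_path)
        out_wb = msio.read_counts(config.outgroup_counts_path)
        out_meta = msio.read_metadata(config.outgroup_metadata_path)
        out_tissue = (
            msio.read_counts(config.tissue_counts_path)
            if config.tissue_counts_path
            else None
        )
        annotation = (
            msio.read_annotation(config.annotation_path)
            if config.annotation_path
            else None
        )
        vcf_path = Path(config.vcf_path) if config.vcf_path else None
    validate_metadata(meta)
    wb_meta = out_meta[out_meta["dataset"] == "outgroup_wholebody"]
    tissue_meta = out_meta[out_meta["dataset"] == "outgroup_tissue"]

    # --------------------------------------------------------------- normalize
    log.info("normalizing focal libraries (TMM) and filtering")
    cpm_focal, factors, kept = normalize_and_filter(focal, config.normalization)
    bundle["n_genes_retained"] = int(len(kept))
    bundle["norm_factors"] = factors
    msio.write_table(cpm_focal, outdir / "focal_cpm.tsv")
    (outdir / "normalization_report.json").write_text(
        json.dumps(
            {
                "config_hash": chash,
                "seed": config.seed,
                "n_genes_retained": int(len(kept)),
                "norm_factors": factors.round(6).to_dict(),
            },
            indent=2,
        )
    )

    # ---------------------------------------------------------------- classify
    log.info("classifying morph/tissue bias on the reference datasets")
    class_table = build_class_table(
        out_wb.counts,
        wb_meta,
        out_tissue.counts if out_tissue is not None else None,
        tissue_meta if out_tissue is not None else None,
        annotation,
        config.normalization,
        config.classification,
    )
    bundle["class_table"] = class_table
    msio.write_table(class_table, outdir / "class_table.tsv")

    # ------------------------------------------------------------------- shift
    shift_tables, class_test_rows, subdivisions = {}, [], []
    for morph in SHIFT_MORPHS:
        log.info("shift analysis for %s", morph)
        avg = two_stage_average(cpm_focal, meta, morph)
        st = shift_table(avg, morph, class_table, config.shift)
        shift_tables[morph] = st
        msio.write_table(st, outdir / f"shift_{morph}.tsv")
        for res in class_tests(st):
            class_test_rows.append({"morph": morph, **res.as_dict()})
        for by in ("degree", "chromosome_class", "tissue_bias"):
            for res in subdivide_and_test(st, by):
                subdivisions.append({"morph": morph, "by": by, **res.as_dict()})
    bundle["shift_tables"] = shift_tables
    bundle["class_tests"] = pd.DataFrame(class_test_rows)
    bundle["subdivisions"] = pd.DataFrame(subdivisions)
    msio.write_table(bundle["class_tests"], outdir / "class_tests.tsv", index=False)
    msio.write_table(bundle["subdivisions"], outdir / "subdivision_tests.tsv",
                     index=False)

    pairwise = {}
    for morph in SHIFT_MORPHS:
        by_lineage = lineage_average(cpm_focal, meta, morph)
        pairwise[morph] = pairwise_lineage_ratios(
            by_lineage, meta, class_table, config.shift
        )
        msio.write_table(pairwise[morph], outdir / f"pairwise_{morph}.tsv",
                         index=False)
    bundle["pairwise"] = pairwise

    if config.run_leave_one_out:
        log.info("leave-one-out circularity check")
        bundle["leave_one_out"] = leave_one_out_check(
            focal, meta, annotation, config.normalization,
            config.classification, config.shift,
        )
        msio.write_table(bundle["leave_one_out"], outdir / "leave_one_out.tsv",
                         index=False)

    # --------------------------------------------------------------- distances
    if vcf_path is not None:
        log.info("genetic distances, tree, PCA and mode divergence")
        genotypes = filter_variants(vcf_path, config.variant_filter)
        bundle["n_snps_retained"] = int(genotypes.n_snps)
        genetic = nei_distance(genotypes)
        bundle["genetic_distance"] = genetic
        msio.write_table(genetic.to_frame(), outdir / "nei_distances.tsv")
        tree = nj_tree(genetic)
        supports = bootstrap_support(
            genotypes, n_boot=config.n_bootstrap, seed=config.seed
        )
        bundle["tree_newick"] = str(tree).strip()
        bundle["bootstrap_support"] = supports
        (outdir / "nj_tree.nwk").write_text(bundle["tree_newick"] + "\n")
        coords, var_frac = genotype_pca(genotypes)
        bundle["pca_coords"] = coords
        bundle["pca_variance_fraction"] = var_frac
        msio.write_table(coords, outdir / "pca_coordinates.tsv")

        lineage_mode = meta.drop_duplicates("lineage").set_index("lineage")["mode"]
        gen_div, gen_p = focal_mode_divergence(genetic, lineage_mode)
        divergence = {
            "genetic": {
                "per_lineage": gen_div,
                "p_value": gen_p,
                "mode_means": gen_div.groupby("mode")["mean_distance"]
                .mean()
                .to_dict(),
            }
        }
        mantel_results = {}
        for morph in SHIFT_MORPHS:
            by_lineage = lineage_average(cpm_focal, meta, morph)
            trans = transcriptomic_distance(
                by_lineage, config.transcriptomic_standardize
            )
            r, p = mantel_test(
                genetic, trans, n_perm=config.n_permutations, seed=config.seed
            )
            mantel_results[morph] = {"r_spearman": r, "p_value": p}
            raw_div, raw_p = focal_mode_divergence(trans, lineage_mode)
            corr_div, corr_p = focal_mode_divergence(
                trans, lineage_mode, correct_by=genetic
            )
            divergence[f"transcriptomic_{morph}"] = {
                "per_lineage": raw_div,
                "p_value": raw_p,
                "mode_means": raw_div.groupby("mode")["mean_distance"]
                .mean()
                .to_dict(),
            }
            divergence[f"corrected_{morph}"] = {
                "per_lineage": corr_div,
                "p_value": corr_p,
                "mode_means": corr_div.groupby("mode")["mean_distance"]
                .mean()
                .to_dict(),
            }
            msio.write_table(trans.to_frame(),
                             outdir / f"transcriptomic_distances_{morph}.tsv")
        bundle["mantel"] = mantel_results
        bundle["divergence"] = divergence
        (outdir / "distance_tests.json").write_text(
            json.dumps(
                {
                    "config_hash": chash,
                    "seed": config.seed,
                    "n_snps_retained": bundle["n_snps_retained"],
                    "bootstrap_support": {
                        "|".join(sorted(k)): v for k, v in supports.items()
                    },
                    "pca_variance_fraction": [float(v) for v in var_frac],
                    "mantel": mantel_results,
                    "divergence": {
                        k: {
                            "p_value": v["p_value"],
                            "mode_means": v["mode_means"],
                        }
                        for k, v in divergence.items()
                    },
                },
                indent=2,
            )
        )

    # ---------------------------------------------------------------- manifest
    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "elapsed_s": round(time.time() - t0, 2),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
        "config": _jsonable(dataclasses.asdict(config)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    return bundle


def render_report(bundle: dict) -> dict[str, pd.DataFrame]:
    """Summary tables: per-class Mdn/n/p panels and the divergence table."""
    report: dict[str, pd.DataFrame] = {}
    if "class_tests" in bundle:
        t = bundle["class_tests"].copy()
        t["class"] = [MORPH_TO_CLASS.get(c, "ub" if c == "unbiased" else c)
                      for c in t["class"]]
        report["class_panel"] = t
    if "subdivisions" in bundle and len(bundle["subdivisions"]):
        report["subdivision_panel"] = bundle["subdivisions"].copy()
    if "divergence" in bundle:
        rows = []
        for kind, v in bundle["divergence"].items():
            row = {"kind": kind, "p_value": v["p_value"]}
            row.update({f"mean_{m}": x for m, x in v["mode_means"].items()})
            rows.append(row)
        report["divergence_panel"] = pd.DataFrame(rows)
    missing = {"class_tests", "divergence"} - set(bundle)
    if missing:
        report["gaps"] = pd.DataFrame(
            {"missing_section": sorted(missing)}
        )
    return report
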