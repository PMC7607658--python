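"""End-to-end orchestration: filter -> M -> per-location paired fits ->
catalog -> MI -> clocks -> enrichment -> report."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from methdrift import clocks as clockmod
from methdrift import diffmeth, enrichment, preprocess, stats
from methdrift.core_io import (
    AnalysisConfig,
    BetaMatrix,
    LOCATIONS,
    SampleSheet,
    file_sha256,
    read_beta_matrix,
    read_probe_annotation,
    read_sample_sheet,
    stage_timer,
)
from methdrift.errors import MethdriftError

logger = logging.getLogger("methdrift")


def _round_sig(x: float, digits: int = 3) -> float:
    """P-values are reported to 3 significant digits; counts stay exact."""
    if x == 0 or not np.isfinite(x):
        return float(x)
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + digits - 1)


def _test_to_dict(res: stats.TestResult) -> dict:
    return {
        "statistic": round(float(res.statistic), 6),
        "p": _round_sig(float(res.p)),
        "method": res.method,
        "n": res.n,
    }


def _paired_by_subject(mi: pd.DataFrame, group: str, location: str) -> tuple[np.ndarray, np.ndarray]:
    sub = mi[(mi["location"] == location)]
    t1 = sub[sub["timepoint"] == "t1"].set_index("subject_id")
    t2 = sub[sub["timepoint"] == "t2"].set_index("subject_id")
    # group label taken at t2 (paired analysis excludes switchers upstream)
    subjects = [s for s in t1.index if s in t2.index and t2.loc[s, "aspirin"] == group]
    return (
        t1.loc[subjects, "mi"].to_numpy(dtype=float),
        t2.loc[subjects, "mi"].to_numpy(dtype=float),
    )


def run_pipeline(
    config: AnalysisConfig,
    beta: BetaMatrix | None = None,
    sheet: SampleSheet | None = None,
    annotation=None,
    clock_defs: list | None = None,
    detection_p: pd.DataFrame | None = None,
    mask: set[str] | None = None,
    gene_sets: enrichment.GeneSetAnnotation | None = None,
    write_outputs: bool = True,
) -> dict:
    """Run the full analysis; inputs may be passed in memory or via paths in
    the config. Returns the RunReport dict (also written as report.json)."""
    outdir = Path(config.output_dir)
    input_hashes = {}
    if beta is None:
        beta = read_beta_matrix(config.beta_path)
        input_hashes["beta"] = file_sha256(config.beta_path)
    if sheet is None:
        sheet = read_sample_sheet(config.sample_sheet_path)
        input_hashes["sample_sheet"] = file_sha256(config.sample_sheet_path)
    if annotation is None and config.annotation_path:
        annotation = read_probe_annotation(config.annotation_path)
        input_hashes["annotation"] = file_sha256(config.annotation_path)
    if clock_defs is None:
        clock_defs = [clockmod.read_clock(p) for p in config.clock_paths]
        for p in config.clock_paths:
            input_hashes[f"clock:{Path(p).name}"] = file_sha256(p)
    if mask is None and config.mask_path:
        mask = {
            line.strip()
            for line in open(config.mask_path, encoding="utf-8")
            if line.strip()
        }
        input_hashes["mask"] = file_sha256(config.mask_path)
    if detection_p is None and config.detection_p_path:
        detection_p = pd.read_csv(config.detection_p_path, sep="\t", index_col=0)
        input_hashes["detection_p"] = file_sha256(config.detection_p_path)
    if gene_sets is None and config.gene_set_path and annotation is not None:
        gene_sets = enrichment.read_gene_sets(config.gene_set_path, annotation.universe)
        input_hashes["gene_sets"] = file_sha256(config.gene_set_path)

    if write_outputs:
        outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "seed": config.seed,
        "config": {
            "fdr_alpha": config.fdr_alpha,
            "detection_p_threshold": config.detection_p_threshold,
            "beta_clamp_epsilon": config.beta_clamp_epsilon,
            "n_variable_cpgs_for_pca": config.n_variable_cpgs_for_pca,
            "knn_k": config.knn_k,
        },
        "input_hashes": input_hashes,
    }

    # -- filtering -----------------------------------------------------------
    with stage_timer("filter", n_probes=len(beta.probe_ids)):
        filtered, filt_report = preprocess.filter_probes(
            beta, detection_p, mask, threshold=config.detection_p_threshold
        )
    report["filter"] = {
        "n_input_probes": filt_report.n_input_probes,
        "n_failed_detection": filt_report.n_failed_detection,
        "n_masked": filt_report.n_masked,
        "n_kept": filt_report.n_kept,
    }
    if write_outputs:
        filt_report.to_frame().to_csv(outdir / "filter_report.tsv", sep="\t", index=False)

    # -- PCA -----------------------------------------------------------------
    k = min(config.n_variable_cpgs_for_pca, len(filtered.probe_ids))
    with stage_timer("pca", k=k):
        top = preprocess.select_most_variable(filtered, k)
        pca = preprocess.pca_scores(filtered, top, n_components=2)
    report["pca"] = {
        "explained_variance_ratio": [round(float(r), 6) for r in pca.explained_variance_ratio],
        "n_probes_used": len(top),
    }
    if write_outputs:
        pca.to_frame().to_csv(outdir / "pca_scores.tsv", sep="\t", index=False)

    # -- per-location differential methylation -------------------------------
    m = preprocess.MValueMatrix.from_beta(filtered, config.beta_clamp_epsilon)
    catalogs: dict[str, diffmeth.LocationCatalog] = {}
    report["locations"] = {}
    for location in LOCATIONS:
        loc_sheet = sheet.location(location)
        if not len(loc_sheet):
            continue
        order = loc_sheet.sample_ids
        m_loc = preprocess.MValueMatrix(
            list(m.probe_ids),
            order,
            preprocess.MValueMatrix.from_beta(
                filtered.subset_samples(order), config.beta_clamp_epsilon
            ).values,
        )
        beta_loc = filtered.subset_samples(order)
        with stage_timer(f"fit:{location}", n_probes=len(m.probe_ids)):
            design = diffmeth.build_design(loc_sheet)
            fits = diffmeth.fit_per_probe(m_loc, design)
            params, tables = diffmeth.ebayes_moderate(fits)
        loc_report: dict = {
            "design_rank": design.rank,
            "dropped_columns": design.dropped,
            "d0": float(params.d0) if np.isfinite(params.d0) else "inf",
            "s02": round(float(params.s02), 8),
        }
        fit_tables = {}
        for group_key, level in (("user", diffmeth.USER), ("nonuser", diffmeth.NONUSER)):
            tbl = diffmeth.probe_fit_table(tables[group_key], beta_loc, loc_sheet, level)
            fit_tables[group_key] = tbl
            if write_outputs:
                tbl.to_csv(
                    outdir / f"probe_fits_{location}_{group_key}.tsv",
                    sep="\t",
                    index=False,
                    float_format="%.6g",
                )
        catalog = diffmeth.classify_dmcpgs(
            fit_tables["user"], fit_tables["nonuser"], alpha=config.fdr_alpha
        )
        catalogs[location] = catalog
        counts = catalog.counts()
        n_u = counts["u_hyper"] + counts["u_hypo"]
        n_nu = counts["nu_hyper"] + counts["nu_hypo"]
        loc_report["dmcpg_counts"] = counts
        loc_report["percent_hyper"] = {
            "u": round(100.0 * counts["u_hyper"] / n_u, 2) if n_u else None,
            "nu": round(100.0 * counts["nu_hyper"] / n_nu, 2) if n_nu else None,
        }
        for set_name, df in (("u", catalog.u), ("nu", catalog.nu)):
            if len(df):
                loc_report[f"{set_name}_change_summary"] = {
                    k2: (round(v, 4) if np.isfinite(v) else None)
                    for k2, v in diffmeth.change_summary(df).items()
                }
        report["locations"][location] = loc_report
        if write_outputs:
            catalog.u.to_csv(outdir / f"catalog_u_{location}.tsv", sep="\t", index=False)
            catalog.nu.to_csv(outdir / f"catalog_nu_{location}.tsv", sep="\t", index=False)

    # -- methylation index ---------------------------------------------------
    usable = {loc: cat for loc, cat in catalogs.items() if cat.union_probes}
    if usable:
        mi = diffmeth.methylation_index(filtered, sheet, usable, exclude_switchers=True)
        if write_outputs:
            mi.to_csv(outdir / "methylation_index.tsv", sep="\t", index=False, float_format="%.6g")
        mi_report: dict = {}
        for location in usable:
            entry: dict = {}
            for group_key, level in (("user", diffmeth.USER), ("nonuser", diffmeth.NONUSER)):
                v1, v2 = _paired_by_subject(mi, level, location)
                if len(v1) >= 2 and np.any(v2 - v1 != 0):
                    entry[f"paired_{group_key}"] = _test_to_dict(
                        stats.paired_signed_rank(v1, v2)
                    )
                    entry[f"mean_mi_change_{group_key}"] = round(float(np.mean(v2 - v1)), 4)
            at_t2 = mi[(mi["location"] == location) & (mi["timepoint"] == "t2")]
            u_vals = at_t2.loc[at_t2["aspirin"] == diffmeth.USER, "mi"].to_numpy()
            n_vals = at_t2.loc[at_t2["aspirin"] == diffmeth.NONUSER, "mi"].to_numpy()
            if len(u_vals) >= 3 and len(n_vals) >= 3:
                entry["user_vs_nonuser_t2"] = _test_to_dict(stats.rank_sum(u_vals, n_vals))
                entry["normality_t2"] = _test_to_dict(
                    stats.normality_check(at_t2["mi"].to_numpy())
                )
            mi_report[location] = entry
        report["methylation_index"] = mi_report

    # -- clocks --------------------------------------------------------------
    ages = dict(zip(sheet.frame["sample_id"], sheet.frame["age"].astype(float)))
    clock_report: dict = {}
    for clock in clock_defs or []:
        with stage_timer(f"clock:{clock.name}"):
            mage = clockmod.compute_mage(beta, clock, knn_k=config.knn_k)
            mage = clockmod.age_acceleration(mage, ages)
        frame = mage.frame.merge(
            sheet.frame[["sample_id", "subject_id", "timepoint", "location", "aspirin", "switched_at_t2"]],
            on="sample_id",
        )
        if write_outputs:
            frame.to_csv(
                outdir / f"mage_{clock.name}.tsv", sep="\t", index=False, float_format="%.6g"
            )
        entry = {
            "coverage": mage.coverage,
            "mage_age_correlation": round(
                float(np.corrcoef(frame["mage"], frame["age"])[0, 1]), 4
            ),
        }
        # AAR drift per group (paired t2 vs t1 within subject, proximal+distal mean)
        for group_key, level in (("user", diffmeth.USER), ("nonuser", diffmeth.NONUSER)):
            sub = frame[(frame["aspirin"] == level) & ~frame["switched_at_t2"]]
            piv = sub.pivot_table(index="subject_id", columns="timepoint", values="aar")
            piv = piv.dropna()
            if len(piv) >= 2 and np.any(piv["t2"] != piv["t1"]):
                entry[f"aar_paired_{group_key}"] = _test_to_dict(
                    stats.paired_signed_rank(piv["t1"].to_numpy(), piv["t2"].to_numpy())
                )
            t2 = sub[sub["timepoint"] == "t2"]["aar"].to_numpy()
            entry[f"mean_aar_t2_{group_key}"] = (
                round(float(np.mean(t2)), 4) if len(t2) else None
            )
        # clock-CpG change on the filtered matrix, compared across groups
        try:
            chg_u = clockmod.clock_cpg_change(filtered, sheet, clock, diffmeth.USER)
            chg_n = clockmod.clock_cpg_change(filtered, sheet, clock, diffmeth.NONUSER)
            entry["cpg_change_rank_sum"] = _test_to_dict(
                stats.rank_sum(
                    chg_u["percent_change"].to_numpy(), chg_n["percent_change"].to_numpy()
                )
            )
            entry["median_cpg_change"] = {
                "user": round(float(chg_u["percent_change"].median()), 4),
                "nonuser": round(float(chg_n["percent_change"].median()), 4),
            }
        except MethdriftError:
            entry["cpg_change_rank_sum"] = None
        clock_report[clock.name] = entry
    if clock_report:
        report["clocks"] = clock_report

    # -- enrichment ----------------------------------------------------------
    if annotation is not None and usable:
        enr_report: dict = {}
        for location, catalog in usable.items():
            background = [
                p for p in filtered.probe_ids if p in set(annotation.probe_ids)
            ]
            if not background:
                continue
            region = enrichment.region_enrichment(catalog, annotation, background)
            if write_outputs:
                region.to_csv(
                    outdir / f"region_enrichment_{location}.tsv", sep="\t", index=False
                )
            sig_regions = region.loc[region["adj_p"] < config.fdr_alpha]
            entry = {
                "n_region_tests": len(region),
                "n_region_significant": int(len(sig_regions)),
            }
            if gene_sets is not None:
                for set_name, df in (("u", catalog.u), ("nu", catalog.nu)):
                    genes = annotation.genes_for(df["probe_id"].tolist())
                    pw = enrichment.pathway_enrichment(genes, gene_sets)
                    if write_outputs:
                        pw.to_csv(
                            outdir / f"pathways_{set_name}_{location}.tsv",
                            sep="\t",
                            index=False,
                        )
                    entry[f"n_pathways_significant_{set_name}"] = int(
                        pw["significant"].sum()
                    ) if len(pw) else 0
            overlap = enrichment.functional_overlap(catalog, annotation)
            if write_outputs:
                overlap.to_csv(
                    outdir / f"functional_overlap_{location}.tsv", sep="\t", index=False
                )
            entry["n_flagged_overlap_rows"] = int(len(overlap))
            enr_report[location] = entry
        report["enrichment"] = enr_report

    if write_outputs:
        with open(outdir / "report.json", "w", encoding="utf-8") as fh:
            json.dump(report, fh, sort_keys=True, indent=2)
            fh.write("\n")
    return report
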