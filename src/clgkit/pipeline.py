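"""End-to-end orchestration: orthology -> linkage-group inference ->
enrichment -> painting -> retention/asymmetry.

Stages exchange plain data frames and are pure functions of (inputs,
config, seed); `analyze` runs them all in memory and `analyze_dataset`
wraps it with directory input/output and a run manifest.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .clg import (
    CLGPartition,
    consensus_breakpoints,
    detect_breakpoints,
    discontinuity,
    indicator_profile,
    merge_segments,
    segments_from_breakpoints,
)
from .dip import dip_test
from .enrichment import chromosome_enrichment, significance_tier, window_enrichment
from .model import AnalysisConfig, GeneMap, OrthogroupTable, Segment, SimilarityTable
from .orthology import AnchorSet, build_anchor_set, mutual_best_hits
from .painting import CellAssignment, assign_copies, paint_windows, partition_blocks
from .retention import (
    assign_alpha_beta,
    asymmetry_test,
    fusion_concordance_test,
    retention_correlation,
    retention_fraction,
)

logger = logging.getLogger("clgkit")


@dataclass
class AnalysisResult:
    anchors: AnchorSet
    partition: CLGPartition
    cells: CellAssignment
    retention: pd.DataFrame
    pairs: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    summary: dict


def family_clg_map(orthogroups: OrthogroupTable, partition: CLGPartition) -> pd.Series:
    """family_id -> CLG letter by majority vote of outgroup member genes
    (ties are left unassigned)."""
    out_species = partition.species
    members = orthogroups.members
    sub = members[members["species"] == out_species].copy()
    sub["clg"] = sub["gene_id"].map(partition.assignment)
    sub = sub[sub["clg"].notna()]
    counts = sub.groupby(["family_id", "clg"]).size().reset_index(name="n")
    counts = counts.sort_values(["family_id", "n", "clg"], ascending=[True, False, True])
    best = counts.drop_duplicates("family_id", keep="first")
    top2 = counts.groupby("family_id").head(2)
    tied = (
        top2.groupby("family_id")["n"].nunique().eq(1)
        & top2.groupby("family_id").size().gt(1)
    )
    keep = best[~best["family_id"].map(tied).fillna(False)]
    return pd.Series(keep["clg"].values, index=keep["family_id"].values)


def infer_clgs(
    outgroup_map: GeneMap,
    anchors: AnchorSet,
    config: AnalysisConfig,
) -> tuple[CLGPartition, dict, pd.DataFrame, pd.DataFrame]:
    """Breakpoint detection and segment merging along the outgroup."""
    indicators = {t: indicator_profile(anchors, t) for t in anchors.targets}
    per_comp = {}
    rows = []
    for comp, ind in indicators.items():
        prof = discontinuity(ind, config.window_W)
        bk = detect_breakpoints(prof, config.peak_threshold, config.separation)
        per_comp[comp] = bk
        bk = bk.copy()
        bk.insert(0, "comparator", comp)
        rows.append(bk)
    breakpoints = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["comparator", "chromosome", "junction", "D"])
    )
    support = min(config.min_breakpoint_support, max(1, len(anchors.targets)))
    consensus = consensus_breakpoints(per_comp, tolerance=config.window_W // 2, min_support=support)
    segments = segments_from_breakpoints(outgroup_map, consensus)
    partition = merge_segments(segments, indicators, outgroup_map, threshold=config.merge_cosine)
    logger.info(
        "clg_inference: %d anchors, %d consensus breakpoints, %d CLGs",
        len(anchors), len(consensus), len(partition.letters),
    )
    return partition, indicators, breakpoints, consensus


def _dotplot(anchors: AnchorSet, partition: CLGPartition, target: str, target_map: GeneMap) -> pd.DataFrame:
    sub = anchors.with_target(target).copy()
    sub["outgroup_index"] = np.arange(len(sub))
    pos = target_map.position_index()
    sub["target_ordinal"] = sub[f"{target}_gene"].map(pos["ordinal"])
    order = sub.sort_values([f"{target}_chromosome", "target_ordinal"], kind="mergesort").index
    sub.loc[order, "target_index"] = np.arange(len(sub))
    sub["clg"] = sub["outgroup_gene"].map(partition.assignment)
    out = sub[["outgroup_index", "target_index", "clg"]].copy()
    out.insert(0, "target", target)
    out["target_index"] = out["target_index"].astype(int)
    return out


def analyze(
    gene_maps: Mapping[str, GeneMap],
    similarities: Mapping[tuple[str, str], SimilarityTable],
    orthogroups: OrthogroupTable,
    outgroup: str,
    ingroups: Sequence[str],
    config: AnalysisConfig,
) -> AnalysisResult:
    ingroups = sorted(ingroups)
    # --- stage: orthology
    mbh_out = {}
    for t in ingroups:
        mbh_out[t] = mutual_best_hits(similarities[(outgroup, t)], similarities[(t, outgroup)])
    mbh_in = {}
    for a, b in itertools.combinations(ingroups, 2):
        mbh_in[(a, b)] = mutual_best_hits(similarities[(a, b)], similarities[(b, a)])
    anchors = build_anchor_set(gene_maps[outgroup], mbh_out, {t: gene_maps[t] for t in ingroups})
    logger.info("orthology: %d anchors across %d targets", len(anchors), len(ingroups))

    # --- stage: CLG inference
    partition, indicators, breakpoints, consensus = infer_clgs(gene_maps[outgroup], anchors, config)

    # --- stage: enrichment
    enr_chrom, enr_win, tiers = [], {w: [] for w in config.enrich_windows}, []
    for t in ingroups:
        ce = chromosome_enrichment(partition, anchors, t, gene_maps[t], config.alpha_levels)
        enr_chrom.append(ce)
        wins = {}
        for w in config.enrich_windows:
            we = window_enrichment(partition, anchors, t, gene_maps[t], w, levels=config.alpha_levels)
            enr_win[w].append(we)
            wins[w] = we
        w50 = wins[min(config.enrich_windows)]
        w100 = wins[max(config.enrich_windows)]
        tier = significance_tier(ce, w50, w100)
        tier.insert(0, "target", t)
        tiers.append(tier)
    enr_chrom_df = pd.concat(enr_chrom, ignore_index=True)
    tiers_df = pd.concat(tiers, ignore_index=True)

    # --- stage: painting
    fam_clg = family_clg_map(orthogroups, partition)
    gene_clg = {}
    for t in ingroups:
        fam_of = orthogroups.family_of(t)
        gene_clg[t] = fam_of.map(fam_clg)
    paint = pd.concat(
        [paint_windows(gene_maps[t], gene_clg[t], config.paint_min_window) for t in ingroups],
        ignore_index=True,
    )
    blocks = pd.concat(
        [
            partition_blocks(
                gene_maps[t], gene_clg[t],
                min_gap=config.paint_min_window, threshold=config.peak_threshold,
            )
            for t in ingroups
        ],
        ignore_index=True,
    )
    cells = assign_copies(blocks, {t: gene_maps[t] for t in ingroups}, gene_clg, mbh_in)
    n_blocks = len(blocks[["species", "chromosome", "block"]].drop_duplicates())
    logger.info("painting: %d blocks, %d cells, %d groups",
                n_blocks, len(cells.cells), len(cells.groups))

    # --- stage: retention & asymmetry
    ret_rows = []
    for _, cell in cells.cells.iterrows():
        segs = cells.segments[cells.segments["cell_id"] == cell["cell_id"]]
        for sp, sub in segs.groupby("species"):
            seg_objs = [
                Segment(sp, r["chromosome"], int(r["start"]), int(r["end"]))
                for _, r in sub.iterrows()
            ]
            n_ret, n_def, r = retention_fraction(
                seg_objs, cell["clg"], partition, orthogroups, gene_maps[sp]
            )
            ret_rows.append(
                (cell["cell_id"], cell["clg"], cell["group_id"], sp, n_ret, n_def, r)
            )
    retention = pd.DataFrame(
        ret_rows,
        columns=["cell_id", "clg", "group_id", "species", "n_retained", "n_defining", "retention"],
    )

    group_ret = retention.groupby("group_id")["retention"].mean()
    groups = cells.groups.copy()
    groups["retention"] = groups["group_id"].map(group_ret).fillna(0.0)
    groups = assign_alpha_beta(groups)
    cell_meta = cells.cells.merge(
        groups[["group_id", "signature", "subgenome", "pair_id", "unpaired"]], on="group_id"
    )
    retention = retention.merge(
        cell_meta[["cell_id", "subgenome", "pair_id", "unpaired"]], on="cell_id"
    )

    # copy enumeration per CLG: pairing units ordered by gene content
    unit_of_cell = {}
    for _, row in cell_meta.iterrows():
        unit_of_cell[row["cell_id"]] = row["pair_id"] or f"solo:{row['group_id']}"
    sizes = cells.segments.groupby("cell_id")["n_genes"].sum()
    copy_rows = []
    for clg, sub in cell_meta.groupby("clg"):
        units: dict[str, int] = {}
        for _, row in sub.iterrows():
            u = unit_of_cell[row["cell_id"]]
            units[u] = units.get(u, 0) + int(sizes.get(row["cell_id"], 0))
        ranked = sorted(units, key=lambda u: (-units[u], u))
        for _, row in sub.iterrows():
            copy_rows.append(
                (row["cell_id"], ranked.index(unit_of_cell[row["cell_id"]]) + 1)
            )
    copy_df = pd.DataFrame(copy_rows, columns=["cell_id", "copy"])
    retention = retention.merge(copy_df, on="cell_id", how="left")
    cell_meta = cell_meta.merge(copy_df, on="cell_id", how="left")

    # alpha-beta pairs: per CLG per species within each paired group pair
    pair_rows = []
    paired = cell_meta[cell_meta["pair_id"] != ""]
    for pid, sub in paired.groupby("pair_id"):
        a_cells = sub[sub["subgenome"] == "alpha"]
        b_cells = sub[sub["subgenome"] == "beta"]
        for clg in sorted(set(a_cells["clg"]) & set(b_cells["clg"])):
            ca = a_cells[a_cells["clg"] == clg].iloc[0]["cell_id"]
            cb = b_cells[b_cells["clg"] == clg].iloc[0]["cell_id"]
            ra = retention[retention["cell_id"] == ca].set_index("species")["retention"]
            rb = retention[retention["cell_id"] == cb].set_index("species")["retention"]
            for sp in sorted(set(ra.index) & set(rb.index)):
                pair_rows.append((pid, clg, sp, ca, cb, ra[sp], rb[sp]))
    pairs = pd.DataFrame(
        pair_rows,
        columns=["pair_id", "clg", "species", "alpha_cell", "beta_cell", "r_alpha", "r_beta"],
    )

    all_values = retention["retention"].to_numpy()
    n_excluded = int((retention["unpaired"]).sum())
    summary: dict = {
        "n_anchors": len(anchors),
        "n_clgs": len(partition.letters),
        "n_cells": len(cells.cells),
        "n_pairs": len(pairs),
        "n_excluded_unpaired": n_excluded,
    }
    if len(pairs) >= 2:
        asym = asymmetry_test(
            pairs["r_alpha"], pairs["r_beta"],
            reps=config.bootstrap_reps, seed=config.seed,
            all_values=all_values, n_excluded=n_excluded,
        )
        summary.update(
            asymmetry_observed=asym.observed, asymmetry_null_mean=asym.null_mean,
            asymmetry_null_sd=asym.null_sd, asymmetry_z=asym.z, asymmetry_p=asym.p,
            asymmetry_c=asym.c,
        )
        alpha_vals = retention.loc[retention["subgenome"] == "alpha", "retention"]
        beta_vals = retention.loc[retention["subgenome"] == "beta", "retention"]
        summary["alpha_mean_retention"] = float(alpha_vals.mean())
        summary["beta_mean_retention"] = float(beta_vals.mean())
    if len(all_values) >= 4:
        dres = dip_test(all_values, n_boot=config.dip_bootstrap, seed=config.seed)
        summary.update(dip_statistic=dres.statistic, dip_p=dres.p_value)
    corr_rows = []
    for a, b in itertools.combinations(ingroups, 2):
        try:
            r, n = retention_correlation(retention, a, b)
        except ValueError:
            continue
        corr_rows.append((a, b, r, n))
    correlations = pd.DataFrame(corr_rows, columns=["species_a", "species_b", "pearson_r", "n_cells"])
    if len(correlations):
        summary["mean_retention_correlation"] = float(correlations["pearson_r"].mean())

    def fused_pairs(sub: pd.DataFrame) -> list[tuple[str, str]]:
        out = []
        for _, g in sub.iterrows():
            parts = g["signature"].split("+")
            if len(parts) >= 2:
                out.extend(itertools.combinations(parts, 2))
        return out

    a_pairs = fused_pairs(groups[groups["subgenome"] == "alpha"])
    b_pairs = fused_pairs(groups[groups["subgenome"] == "beta"])
    if b_pairs:
        p_conc, stat, method = fusion_concordance_test(a_pairs, b_pairs, seed=config.seed)
        summary.update(
            fusion_concordance_p=p_conc,
            fusion_concordance_stat=stat,
            fusion_concordance_method=method,
        )

    dotplots = pd.concat(
        [_dotplot(anchors, partition, t, gene_maps[t]) for t in ingroups], ignore_index=True
    )

    tables = {
        "anchors": anchors.table,
        "breakpoints": breakpoints,
        "consensus_breakpoints": consensus,
        "clg_assignment": partition.assignment.rename_axis("gene_id").reset_index(),
        "clg_segments": partition.segments,
        "enrichment_chromosome": enr_chrom_df,
        "tiers": tiers_df,
        "painting": paint,
        "blocks": blocks,
        "cells": cell_meta,
        "cell_segments": cells.segments,
        "groups": groups,
        "retention": retention,
        "pairs": pairs,
        "correlations": correlations,
        "dotplot": dotplots,
        "summary": pd.DataFrame(
            sorted(summary.items()), columns=["metric", "value"]
        ),
    }
    for w, frames in enr_win.items():
        tables[f"enrichment_window{w}"] = pd.concat(frames, ignore_index=True)
    return AnalysisResult(anchors, partition, cells, retention, pairs, tables, summary)


def analyze_dataset(
    dataset_dir,
    config: AnalysisConfig,
    out_dir,
    seed: Optional[int] = None,
) -> AnalysisResult:
    """Load a dataset directory, run all stages and write results + manifest."""
    from .simulate import load_dataset

    gene_maps, similarities, orthogroups, meta = load_dataset(dataset_dir)
    if seed is not None:
        config = AnalysisConfig.from_dict({**config.to_dict(), "seed": seed})
    result = analyze(
        gene_maps, similarities, orthogroups, meta["outgroup"], meta["ingroups"], config
    )
    inputs = {p.name: p for p in sorted(Path(dataset_dir).glob("*.tsv"))}
    cio.write_results(result.tables, out_dir, config, config.seed, inputs=inputs)
    return result
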