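"""Chromosome painting by linkage-group ancestry and segment-copy assignment.

Duplicated (ingroup) chromosomes are painted by the local fraction of genes
deriving from each linkage group in non-overlapping windows of at least a
minimum gene count, then partitioned into blocks of homogeneous ancestry by
iteratively splitting at the largest remaining discontinuity peak (with new
breakpoints kept a minimum number of genes from accepted ones). Blocks with
the same linkage-group content are linked across ingroup species into
orthologous cells using cross-ingroup 1:1 orthology, and cells co-resident
on the same chromosomes are grouped; those chromosome groups are the units
later paired into alpha/beta subgenomes by the retention analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .clg import _windowed_means
from .model import GeneMap, OrthologyTable, Segment

__all__ = ["paint_windows", "partition_blocks", "assign_copies", "CellAssignment"]


def _clg_sequence(gene_map: GeneMap, gene_clg: pd.Series, chromosome: str):
    sub = gene_map.genes_on(chromosome)
    labels = sub["gene_id"].map(gene_clg)
    mask = labels.notna()
    return sub["ordinal"].to_numpy()[mask.to_numpy()], labels[mask].to_numpy()


def paint_windows(
    gene_map: GeneMap,
    gene_clg: pd.Series,
    min_window: int = 20,
) -> pd.DataFrame:
    """Per-window linkage-group gene fractions along each chromosome.

    Chromosomes are tiled with non-overlapping windows of at least
    ``min_window`` genes (n // min_window windows of near-equal size);
    fractions are taken over all genes in the window, so genes without a
    linkage-group assignment leave the fractions summing below one. A
    chromosome with fewer than ``min_window`` genes becomes one window.
    """
    rows = []
    for chrom in gene_map.chromosomes():
        sub = gene_map.genes_on(chrom)
        n = len(sub)
        k = n // min_window
        if k == 0:
            warnings.warn(
                f"{gene_map.species}:{chrom} has {n} < {min_window} genes; "
                "using a single whole-chromosome window",
                stacklevel=2,
            )
            k = 1
        bounds = np.linspace(0, n, k + 1).round().astype(int)
        labels = sub["gene_id"].map(gene_clg)
        for start, end in zip(bounds[:-1], bounds[1:]):
            window = labels.iloc[start:end]
            frac = window.value_counts() / (end - start)
            for clg, f in sorted(frac.items()):
                rows.append((gene_map.species, chrom, int(start), int(end), clg, float(f)))
    return pd.DataFrame(
        rows, columns=["species", "chromosome", "start", "end", "clg", "fraction"]
    )


def partition_blocks(
    gene_map: GeneMap,
    gene_clg: pd.Series,
    min_gap: int = 20,
    threshold: float = 0.5,
    window: Optional[int] = None,
) -> pd.DataFrame:
    """Split chromosomes into blocks of homogeneous linkage-group ancestry.

    The discontinuity statistic D is computed on the chromosome's sequence
    of linkage-group labels (linkage groups playing the role of comparator
    classes, window ``window`` defaulting to ``min_gap``). Breakpoints are
    taken greedily at the largest remaining peak with D >= threshold,
    rejecting candidates within ``min_gap`` labelled genes of an accepted
    breakpoint, which yields blocks of at least ~``min_gap`` genes. Blocks
    tile each chromosome exactly. Returns one row per (block, clg) with
    the block's gene span and composition.
    """
    W = window or min_gap
    margin = W  # full windows on both sides; truncated windows spike D at edges
    rows = []
    for chrom in gene_map.chromosomes():
        ords, labels = _clg_sequence(gene_map, gene_clg, chrom)
        n_all = gene_map.chromosome_size(chrom)
        m = len(labels)
        cuts: list[int] = []
        if m >= 2:
            cats = sorted(set(labels))
            one_hot = np.zeros((m, len(cats)))
            idx = {c: j for j, c in enumerate(cats)}
            for i, lab in enumerate(labels):
                one_hot[i, idx[lab]] = 1.0
            left, right = _windowed_means(one_hot, W)
            diff = right[1:] - left[:-1]
            d = np.einsum("ij,ij->i", diff, diff)
            i = np.arange(m - 1)
            eligible = (i + 1 >= margin) & (m - 1 - i >= margin)
            order = np.argsort(-d, kind="stable")
            accepted: list[int] = []
            for j in order:
                if d[j] < threshold:
                    break
                if not eligible[j]:
                    continue
                if all(abs(j - a) >= min_gap for a in accepted):
                    accepted.append(int(j))
            cuts = sorted(int(ords[j + 1]) for j in accepted)
        bounds = [0] + cuts + [n_all]
        sub = gene_map.genes_on(chrom)
        lab_all = sub["gene_id"].map(gene_clg)
        for bi, (start, end) in enumerate(zip(bounds[:-1], bounds[1:])):
            window_labels = lab_all.iloc[start:end]
            counts = window_labels.value_counts()
            total = end - start
            if counts.empty:
                rows.append(
                    (gene_map.species, chrom, bi, start, end, "none", 0, 0.0)
                )
                continue
            for clg, cnt in sorted(counts.items()):
                rows.append(
                    (
                        gene_map.species, chrom, bi, start, end,
                        clg, int(cnt), float(cnt / total),
                    )
                )
    return pd.DataFrame(
        rows,
        columns=[
            "species", "chromosome", "block", "start", "end", "clg",
            "n_genes", "fraction",
        ],
    )


@dataclass(frozen=True)
class CellAssignment:
    """Orthologous segment cells across ingroup species.

    cells: cell_id, clg, group_id, ambiguous;
    segments: cell_id, species, chromosome, start, end, n_genes;
    groups: group_id, signature (sorted '+'-joined CLG content of the
    linked chromosomes), n_genes.
    """

    cells: pd.DataFrame
    segments: pd.DataFrame
    groups: pd.DataFrame


def _occurrences(
    blocks: pd.DataFrame, clg: str, min_genes: int
) -> list[dict]:
    """Maximal runs of consecutive blocks containing >= min_genes of clg."""
    occ = []
    sub = blocks[(blocks["clg"] == clg) & (blocks["n_genes"] >= min_genes)]
    for (species, chrom), grp in sub.groupby(["species", "chromosome"], sort=True):
        block_ids = sorted(grp["block"])
        run: list[int] = []
        spans = grp.set_index("block")
        for b in block_ids:
            if run and b != run[-1] + 1:
                occ.append(_run_to_occ(species, chrom, run, spans))
                run = []
            run.append(b)
        if run:
            occ.append(_run_to_occ(species, chrom, run, spans))
    return occ


def _run_to_occ(species, chrom, run, spans) -> dict:
    start = int(spans.loc[run[0], "start"])
    end = int(spans.loc[run[-1], "end"])
    n = int(spans.loc[run, "n_genes"].sum())
    return {
        "species": species,
        "chromosome": chrom,
        "start": start,
        "end": end,
        "n_genes": n,
    }


def assign_copies(
    blocks: pd.DataFrame,
    gene_maps: Mapping[str, GeneMap],
    gene_clg: Mapping[str, pd.Series],
    orthologies: Mapping[tuple[str, str], OrthologyTable],
    min_genes: int = 5,
) -> CellAssignment:
    """Link same-ancestry blocks across species into orthologous cells.

    For each linkage group, per-species occurrences (runs of blocks holding
    at least ``min_genes`` of the group; two separated runs on one
    chromosome stay distinct sub-cells) are matched greedily across species
    by shared 1:1 orthologue count, seeded on the species with the most
    occurrences. Occurrences with tied best partners are flagged ambiguous;
    unmatched occurrences become cells with gaps. Cells co-resident on a
    chromosome in any species are then united into chromosome groups.
    """
    species_list = sorted(gene_maps)
    clgs = sorted(set(blocks["clg"]) - {"none"})
    pair_maps: dict[tuple[str, str], dict[str, str]] = {}
    for (sa, sb), table in orthologies.items():
        pair_maps[(sa, sb)] = table.as_dict()
        pair_maps[(sb, sa)] = {v: k for k, v in table.as_dict().items()}

    def genes_in(occ: dict, clg: str) -> set[str]:
        gm = gene_maps[occ["species"]]
        sub = gm.genes_on(occ["chromosome"])
        sub = sub[(sub["ordinal"] >= occ["start"]) & (sub["ordinal"] < occ["end"])]
        lab = sub["gene_id"].map(gene_clg[occ["species"]])
        return set(sub["gene_id"][(lab == clg).to_numpy()])

    cell_rows, seg_rows = [], []
    counter = 0
    for clg in clgs:
        occ_by_species = {
            sp: _occurrences(blocks[blocks["species"] == sp], clg, min_genes)
            for sp in species_list
        }
        ref = max(species_list, key=lambda sp: (len(occ_by_species[sp]), sp))
        ref_occs = occ_by_species[ref]
        cells = []
        for occ in ref_occs:
            cells.append({"clg": clg, "members": [occ], "ambiguous": False})
        for sp in species_list:
            if sp == ref:
                continue
            others = occ_by_species[sp]
            if not others:
                continue
            omap = pair_maps.get((ref, sp), {})
            other_sets = [genes_in(o, clg) for o in others]
            weights = []
            for ci, cell in enumerate(cells):
                ref_genes = genes_in(cell["members"][0], clg)
                partners = {omap[g] for g in ref_genes if g in omap}
                for oi, oset in enumerate(other_sets):
                    w = len(partners & oset)
                    if w > 0:
                        weights.append((w, ci, oi))
            weights.sort(key=lambda t: (-t[0], t[1], t[2]))
            used_c: set[int] = set()
            used_o: set[int] = set()
            for idx, (w, ci, oi) in enumerate(weights):
                if ci in used_c or oi in used_o:
                    continue
                # an occurrence pulled equally toward two different cells (or a
                # cell toward two occurrences) cannot be resolved from the data
                tied = any(
                    w2 == w and (ci2, oi2) != (ci, oi) and (ci2 == ci or oi2 == oi)
                    and ci2 not in used_c and oi2 not in used_o
                    for w2, ci2, oi2 in weights[idx + 1 :]
                )
                if tied:
                    cells[ci]["ambiguous"] = True
                used_c.add(ci)
                used_o.add(oi)
                cells[ci]["members"].append(others[oi])
            for oi, occ in enumerate(others):
                if oi not in used_o:
                    cells.append({"clg": clg, "members": [occ], "ambiguous": False})
        for cell in cells:
            cell_id = f"{clg}.{counter:03d}"
            counter += 1
            cell_rows.append((cell_id, clg, cell["ambiguous"]))
            for occ in cell["members"]:
                seg_rows.append(
                    (
                        cell_id, occ["species"], occ["chromosome"],
                        occ["start"], occ["end"], occ["n_genes"],
                    )
                )
    cells_df = pd.DataFrame(cell_rows, columns=["cell_id", "clg", "ambiguous"])
    segs_df = pd.DataFrame(
        seg_rows, columns=["cell_id", "species", "chromosome", "start", "end", "n_genes"]
    )

    # chromosome groups: union cells sharing any (species, chromosome)
    parent: dict[str, str] = {c: c for c in cells_df["cell_id"]}

    def find(c: str) -> str:
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    by_key: dict[tuple[str, str], list[str]] = {}
    for _, row in segs_df.iterrows():
        by_key.setdefault((row["species"], row["chromosome"]), []).append(row["cell_id"])
    for key in sorted(by_key):
        members = by_key[key]
        for other in members[1:]:
            parent[find(members[0])] = find(other)

    group_of = {c: find(c) for c in cells_df["cell_id"]}
    cells_df["group_id"] = cells_df["cell_id"].map(group_of)
    sizes = segs_df.groupby("cell_id")["n_genes"].sum()
    group_rows = []
    for gid, sub in cells_df.groupby("group_id", sort=True):
        signature = "+".join(sorted(set(sub["clg"])))
        n_genes = int(sizes.reindex(sub["cell_id"]).fillna(0).sum())
        group_rows.append((gid, signature, n_genes))
    groups_df = pd.DataFrame(group_rows, columns=["group_id", "signature", "n_genes"])
    return CellAssignment(cells_df, segs_df, groups_df)
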