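"""Mutual-best-hit orthology and the one-member-per-chromosome counting rule.

Mutual best hits (MBH) give a conservative 1:1 orthologue set: a pair (a, b)
is kept iff b is a's *unique* top-scoring subject and a is b's unique
top-scoring subject. Genes whose top score is tied between two or more
subjects have no unique best and are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model import GeneMap, OrthologyTable, SimilarityTable

__all__ = ["mutual_best_hits", "build_anchor_set", "collapse_per_chromosome", "AnchorSet"]


def _unique_best(hits: pd.DataFrame, min_score: Optional[float]) -> dict[str, str]:
    """query -> subject for queries with a unique top-scoring subject."""
    df = hits
    if min_score is not None:
        df = df[df["score"] >= min_score]
    if df.empty:
        return {}
    best = df.groupby("query")["score"].transform("max")
    top = df[df["score"] == best]
    counts = top.groupby("query")["subject"].nunique()
    unique_queries = counts[counts == 1].index
    top = top.drop_duplicates("query")
    top = top[top["query"].isin(unique_queries)]
    return dict(zip(top["query"], top["subject"]))


def mutual_best_hits(
    fwd: SimilarityTable,
    rev: SimilarityTable,
    min_score: Optional[float] = None,
) -> OrthologyTable:
    """Reciprocal-best-hit orthologue pairs from two directed searches.

    ``fwd`` and ``rev`` must cover the same species pair in opposite
    directions. ``min_score`` optionally filters hits before taking bests
    (no filter by default).
    """
    if (fwd.species_from, fwd.species_to) != (rev.species_to, rev.species_from):
        raise ValueError(
            f"similarity tables do not cover one species pair in opposite "
            f"directions: {fwd.species_from}->{fwd.species_to} vs "
            f"{rev.species_from}->{rev.species_to}"
        )
    fbest = _unique_best(fwd.hits, min_score)
    rbest = _unique_best(rev.hits, min_score)
    pairs = [(a, b) for a, b in fbest.items() if rbest.get(b) == a]
    pairs.sort()
    df = pd.DataFrame(pairs, columns=["gene_a", "gene_b"])
    return OrthologyTable(fwd.species_from, fwd.species_to, df)


@dataclass(frozen=True)
class AnchorSet:
    """Outgroup-anchored orthologue table.

    One row per outgroup gene having an MBH orthologue in at least one
    target species, ordered by outgroup (chromosome, ordinal). For each
    target ``t`` the frame has columns ``{t}_gene`` and ``{t}_chromosome``
    (NA when the outgroup gene has no orthologue in that target).
    """

    outgroup: str
    targets: tuple[str, ...]
    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    def with_target(self, target: str) -> pd.DataFrame:
        """Anchor rows restricted to those with an orthologue in ``target``."""
        if target not in self.targets:
            raise KeyError(f"{target!r} is not an anchor target")
        col = f"{target}_gene"
        return self.table[self.table[col].notna()].reset_index(drop=True)


def build_anchor_set(
    outgroup_map: GeneMap,
    mbh_tables: Mapping[str, OrthologyTable],
    target_maps: Mapping[str, GeneMap],
) -> AnchorSet:
    """Join per-target MBH tables on the outgroup gene map.

    ``mbh_tables[target]`` must have the outgroup as one member; its
    orientation is normalised so gene_a is the outgroup gene. Outgroup genes
    with no orthologue in any target are dropped.
    """
    base = outgroup_map.records[["gene_id", "chromosome", "ordinal"]].rename(
        columns={"gene_id": "outgroup_gene"}
    )
    targets = sorted(mbh_tables)
    for target in targets:
        table = mbh_tables[target]
        if table.species_a == outgroup_map.species:
            pass
        elif table.species_b == outgroup_map.species:
            table = table.transpose()
        else:
            raise ValueError(
                f"MBH table for {target!r} does not involve outgroup "
                f"{outgroup_map.species!r}"
            )
        pos = target_maps[target].position_index()
        sub = table.pairs.rename(
            columns={"gene_a": "outgroup_gene", "gene_b": f"{target}_gene"}
        )
        sub[f"{target}_chromosome"] = (
            sub[f"{target}_gene"].map(pos["chromosome"]).astype(object)
        )
        base = base.merge(sub, on="outgroup_gene", how="left")
    gene_cols = [f"{t}_gene" for t in targets]
    keep = base[gene_cols].notna().any(axis=1) if gene_cols else pd.Series(False, index=base.index)
    base = base[keep]
    base = base.sort_values(["chromosome", "ordinal"], kind="mergesort").reset_index(drop=True)
    return AnchorSet(outgroup_map.species, tuple(targets), base)


def collapse_per_chromosome(family_genes, gene_map: GeneMap) -> dict[str, int]:
    """Count a gene family once per chromosome.

    Tandem (linked) duplicates therefore never raise retention values;
    only unlinked copies on distinct chromosomes are counted. Idempotent
    and invariant to tandem-duplication augmentation of the family.
    """
    pos = gene_map.position_index()
    chroms: set[str] = set()
    for gene in family_genes:
        if gene in pos.index:
            chroms.add(pos.loc[gene, "chromosome"])
    return {c: 1 for c in sorted(chroms)}
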