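"""Conserved-linkage-group inference along the outgroup genome.

For each anchored outgroup gene *i* and comparator chromosome *a*, the
synteny indicator x_a(i) is 1 iff the gene's orthologue lies on chromosome
*a* of the comparator. With left/right windowed averages

    X^L_a(i) = mean of x_a over the W genes ending at i
    X^R_a(i) = mean of x_a over the W genes starting at i

the discontinuity between adjacent anchored genes i and i+1 is the squared
Euclidean norm of the difference,

    D(i, i+1) = sum_a (X^R_a(i+1) - X^L_a(i))^2 ,

which is 0 on homogeneous stretches and attains its maximum of 2 only for a
complete switch from one comparator chromosome to another. Local peaks of D
mark synteny breakpoints; segments between consensus breakpoints whose
comparator profiles remain closely aligned are combined into a single
syntenic unit, and the resulting units are the conserved linkage groups,
lettered in decreasing order of gene content.
"""

from __future__ import annotations

import string
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .model import GeneMap, Segment
from .orthology import AnchorSet

__all__ = [
    "SyntenyIndicator",
    "DiscontinuityProfile",
    "CLGPartition",
    "indicator_profile",
    "discontinuity",
    "detect_breakpoints",
    "consensus_breakpoints",
    "segments_from_breakpoints",
    "merge_segments",
    "clg_letters",
]


@dataclass(frozen=True)
class SyntenyIndicator:
    """Comparator-chromosome labels of anchored genes, per outgroup chromosome.

    ``per_chromosome[c]`` holds columns outgroup_gene, ordinal, target_chromosome
    in outgroup gene order; ``categories`` is the ordered set of comparator
    chromosomes (the coordinates of the indicator vectors).
    """

    comparator: str
    per_chromosome: Mapping[str, pd.DataFrame]
    categories: tuple[str, ...]

    def one_hot(self, chromosome: str) -> np.ndarray:
        sub = self.per_chromosome[chromosome]
        cat_index = {c: j for j, c in enumerate(self.categories)}
        m = np.zeros((len(sub), len(self.categories)))
        for row, label in enumerate(sub["target_chromosome"]):
            m[row, cat_index[label]] = 1.0
        return m


@dataclass(frozen=True)
class DiscontinuityProfile:
    """Per-junction discontinuity D along each outgroup chromosome.

    Each frame has one row per adjacent anchored pair: junction (rank of the
    left gene among the chromosome's anchors), D, eligible (enough genes on
    both sides), left_ordinal/right_ordinal (outgroup gene ordinals flanking
    the junction).
    """

    comparator: str
    window: int
    per_chromosome: Mapping[str, pd.DataFrame]


def indicator_profile(anchors: AnchorSet, comparator: str) -> SyntenyIndicator:
    """One indicator row per anchor gene with an orthologue in ``comparator``."""
    if comparator not in anchors.targets:
        raise ValueError(f"comparator {comparator!r} absent from anchor set")
    sub = anchors.with_target(comparator)
    sub = sub[["outgroup_gene", "chromosome", "ordinal", f"{comparator}_chromosome"]]
    sub = sub.rename(columns={f"{comparator}_chromosome": "target_chromosome"})
    categories = tuple(sorted(set(sub["target_chromosome"])))
    per_chrom = {
        chrom: grp.drop(columns="chromosome").reset_index(drop=True)
        for chrom, grp in sub.groupby("chromosome", sort=False)
    }
    return SyntenyIndicator(comparator, per_chrom, categories)


def _windowed_means(one_hot: np.ndarray, W: int) -> tuple[np.ndarray, np.ndarray]:
    """Truncated left/right window means of the rows of ``one_hot``.

    Windows shorter than W at chromosome ends average over the genes that
    exist (truncation rule).
    """
    n = one_hot.shape[0]
    csum = np.vstack([np.zeros((1, one_hot.shape[1])), np.cumsum(one_hot, axis=0)])
    idx = np.arange(n)
    lo = np.maximum(idx - W + 1, 0)
    left = (csum[idx + 1] - csum[lo]) / (idx + 1 - lo)[:, None]
    hi = np.minimum(idx + W, n)
    right = (csum[hi] - csum[idx]) / (hi - idx)[:, None]
    return left, right


def discontinuity(indicator: SyntenyIndicator, W: int) -> DiscontinuityProfile:
    """D(i, i+1) profiles for every outgroup chromosome, computed independently.

    Junctions with fewer than W anchored genes on either side are flagged
    ineligible: truncated windows average fewer genes, and their inflated
    variance otherwise produces spurious near-edge peaks. Chromosomes with
    < 2 anchors yield an empty profile.
    """
    if W < 2:
        raise ValueError("window W must be >= 2")
    margin = W
    out: dict[str, pd.DataFrame] = {}
    for chrom, sub in indicator.per_chromosome.items():
        n = len(sub)
        if n < 2:
            out[chrom] = pd.DataFrame(
                columns=["junction", "D", "eligible", "left_ordinal", "right_ordinal"]
            )
            continue
        m = indicator.one_hot(chrom)
        left, right = _windowed_means(m, W)
        diff = right[1:] - left[:-1]
        d = np.einsum("ij,ij->i", diff, diff)
        i = np.arange(n - 1)
        eligible = (i + 1 >= margin) & (n - 1 - i >= margin)
        out[chrom] = pd.DataFrame(
            {
                "junction": i,
                "D": d,
                "eligible": eligible,
                "left_ordinal": sub["ordinal"].to_numpy()[:-1],
                "right_ordinal": sub["ordinal"].to_numpy()[1:],
            }
        )
    return DiscontinuityProfile(indicator.comparator, W, out)


def detect_breakpoints(
    profile: DiscontinuityProfile,
    threshold: float,
    min_separation: int,
) -> pd.DataFrame:
    """Greedy peak calling on the discontinuity profile.

    Breakpoints are local maxima of D with D >= threshold among eligible
    junctions, accepted in decreasing D order subject to a pairwise
    separation of at least ``min_separation`` genes.
    """
    if not (0 < threshold <= 2):
        raise ValueError("threshold must lie in (0, 2]")
    if min_separation < 1:
        raise ValueError("min_separation must be >= 1")
    rows = []
    for chrom, sub in profile.per_chromosome.items():
        if sub.empty:
            continue
        d = sub["D"].to_numpy()
        n = len(d)
        is_peak = np.ones(n, dtype=bool)
        if n > 1:
            is_peak[1:] &= d[1:] >= d[:-1]
            is_peak[:-1] &= d[:-1] >= d[1:]
        cand = sub[is_peak & sub["eligible"] & (d >= threshold)]
        cand = cand.sort_values(["D", "junction"], ascending=[False, True])
        accepted: list[pd.Series] = []
        for _, row in cand.iterrows():
            if all(abs(row["junction"] - a["junction"]) >= min_separation for a in accepted):
                accepted.append(row)
        for row in sorted(accepted, key=lambda r: r["junction"]):
            rows.append(
                (
                    chrom,
                    int(row["junction"]),
                    float(row["D"]),
                    int(row["left_ordinal"]),
                    int(row["right_ordinal"]),
                )
            )
    return pd.DataFrame(
        rows, columns=["chromosome", "junction", "D", "left_ordinal", "right_ordinal"]
    )


def consensus_breakpoints(
    per_comparator: Mapping[str, pd.DataFrame],
    tolerance: int,
    min_support: int = 2,
) -> pd.DataFrame:
    """Combine per-comparator breakpoints into consensus boundaries.

    Breakpoints within ``tolerance`` outgroup-gene ordinals of each other are
    clustered (single linkage on the junction ordinal); a consensus boundary
    requires support from at least ``min_support`` distinct comparators and
    is placed at the median member position.
    """
    entries = []
    for comparator, df in per_comparator.items():
        for _, row in df.iterrows():
            entries.append((row["chromosome"], int(row["right_ordinal"]), comparator, float(row["D"])))
    out = []
    by_chrom: dict[str, list] = {}
    for chrom, pos, comp, d in entries:
        by_chrom.setdefault(chrom, []).append((pos, comp, d))
    for chrom in sorted(by_chrom):
        members = sorted(by_chrom[chrom])
        cluster: list[tuple[int, str, float]] = []
        clusters = []
        for item in members:
            if cluster and item[0] - cluster[-1][0] > tolerance:
                clusters.append(cluster)
                cluster = []
            cluster.append(item)
        if cluster:
            clusters.append(cluster)
        for cl in clusters:
            comps = sorted({c for _, c, _ in cl})
            if len(comps) < min_support:
                continue
            positions = sorted(p for p, _, _ in cl)
            pos = positions[(len(positions) - 1) // 2]
            out.append((chrom, pos, len(comps), ",".join(comps), float(np.mean([d for _, _, d in cl]))))
    return pd.DataFrame(out, columns=["chromosome", "position", "support", "comparators", "mean_D"])


def segments_from_breakpoints(
    outgroup_map: GeneMap, consensus: pd.DataFrame
) -> list[Segment]:
    """Tile every outgroup chromosome into segments split at the consensus
    boundaries (boundary ordinal starts the right-hand segment)."""
    segments = []
    for chrom in outgroup_map.chromosomes():
        n = outgroup_map.chromosome_size(chrom)
        cuts = sorted(
            int(p)
            for p in consensus.loc[consensus["chromosome"] == chrom, "position"]
            if 0 < int(p) < n
        )
        bounds = [0] + cuts + [n]
        for start, end in zip(bounds[:-1], bounds[1:]):
            segments.append(Segment(outgroup_map.species, chrom, start, end))
    return segments


@dataclass(frozen=True)
class CLGPartition:
    """Assignment of outgroup genes and segments to lettered linkage groups.

    Letters are assigned in decreasing order of gene count (ties broken by
    smallest chromosome identifier). ``assignment`` maps every outgroup gene
    inside a partition segment to its CLG letter; ``segments`` lists the
    member segments per CLG.
    """

    species: str
    assignment: pd.Series  # gene_id -> letter
    segments: pd.DataFrame  # clg, chromosome, start, end, n_genes

    @property
    def letters(self) -> list[str]:
        counts = self.assignment.value_counts()
        return sorted(counts.index, key=_letter_sort_key)

    def defining_counts(self) -> pd.Series:
        """Number of CLG-defining outgroup genes per letter (denominators of
        all retention fractions)."""
        return self.assignment.value_counts().sort_index(key=lambda ix: ix.map(_letter_sort_key))

    def merge_letters(self, groups: Sequence[Sequence[str]]) -> "CLGPartition":
        """Apply a user-supplied merge list (manual regroupings); merged units
        are relabelled by their first member letter joined with '+'."""
        mapping = {}
        for group in groups:
            label = "+".join(sorted(group))
            for letter in group:
                mapping[letter] = label
        assignment = self.assignment.map(lambda x: mapping.get(x, x))
        segs = self.segments.copy()
        segs["clg"] = segs["clg"].map(lambda x: mapping.get(x, x))
        return CLGPartition(self.species, assignment, segs)


def clg_letters(n: int) -> list[str]:
    """A, B, ..., Z, AA, AB, ... — labels in decreasing gene-count order."""
    letters = list(string.ascii_uppercase)
    out = letters[:]
    while len(out) < n:
        k = len(out) // 26 - 1
        out += [letters[k] + x for x in letters]
    return out[:n]


def _letter_sort_key(letter: str) -> tuple[int, str]:
    return (len(letter), letter)


def _segment_profiles(
    segments: Sequence[Segment],
    indicators: Mapping[str, SyntenyIndicator],
) -> dict[str, np.ndarray]:
    """Mean indicator vector of each segment, per comparator; rows align with
    ``segments``; zero vectors for segments with no anchored genes."""
    profiles = {}
    for comparator, ind in indicators.items():
        cats = {c: j for j, c in enumerate(ind.categories)}
        mat = np.zeros((len(segments), len(ind.categories)))
        for si, seg in enumerate(segments):
            sub = ind.per_chromosome.get(seg.chromosome)
            if sub is None:
                continue
            inside = sub[(sub["ordinal"] >= seg.start) & (sub["ordinal"] < seg.end)]
            if inside.empty:
                continue
            counts = inside["target_chromosome"].value_counts()
            for label, cnt in counts.items():
                mat[si, cats[label]] = cnt
            mat[si] /= mat[si].sum()
        profiles[comparator] = mat
    return profiles


def merge_segments(
    segments: Sequence[Segment],
    indicators: Mapping[str, SyntenyIndicator],
    outgroup_map: GeneMap,
    threshold: float = 0.75,
) -> CLGPartition:
    """Single-linkage merging of segments with closely aligned profiles.

    Two segments are linked when the cosine similarity of their mean
    indicator vectors is >= ``threshold`` in a majority of comparators;
    connected groups become one syntenic unit (a CLG). Units are lettered
    by descending outgroup gene count.
    """
    if not segments:
        raise ValueError("no segments to merge")
    profiles = _segment_profiles(segments, indicators)
    n = len(segments)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    comparators = sorted(indicators)
    need = len(comparators) // 2 + 1
    for i in range(n):
        for j in range(i + 1, n):
            votes = 0
            for comp in comparators:
                a, b = profiles[comp][i], profiles[comp][j]
                na, nb = np.linalg.norm(a), np.linalg.norm(b)
                if na == 0 or nb == 0:
                    continue
                if float(a @ b) / (na * nb) >= threshold:
                    votes += 1
            if votes >= need:
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    gmap = outgroup_map.records
    sizes = []
    for root, idxs in groups.items():
        total = 0
        chroms = []
        for i in idxs:
            seg = segments[i]
            total += int(
                (
                    (gmap["chromosome"] == seg.chromosome)
                    & (gmap["ordinal"] >= seg.start)
                    & (gmap["ordinal"] < seg.end)
                ).sum()
            )
            chroms.append(seg.chromosome)
        sizes.append((root, total, min(chroms)))
    # letters in decreasing order of gene count; ties to smallest chromosome id
    sizes.sort(key=lambda t: (-t[1], t[2]))
    letters = clg_letters(len(sizes))
    letter_of_root = {root: letters[k] for k, (root, _, _) in enumerate(sizes)}

    seg_rows = []
    assign: dict[str, str] = {}
    for root, idxs in groups.items():
        letter = letter_of_root[root]
        for i in idxs:
            seg = segments[i]
            inside = gmap[
                (gmap["chromosome"] == seg.chromosome)
                & (gmap["ordinal"] >= seg.start)
                & (gmap["ordinal"] < seg.end)
            ]
            for g in inside["gene_id"]:
                assign[g] = letter
            seg_rows.append((letter, seg.chromosome, seg.start, seg.end, len(inside)))
    seg_df = (
        pd.DataFrame(seg_rows, columns=["clg", "chromosome", "start", "end", "n_genes"])
        .sort_values(["clg", "chromosome", "start"], kind="mergesort")
        .reset_index(drop=True)
    )
    assignment = pd.Series(assign, name="clg").sort_index()
    return CLGPartition(outgroup_map.species, assignment, seg_df)
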