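"""Hypergeometric enrichment of orthologue sharing, with Bonferroni control.

Under the null that 1:1 orthologues are randomly distributed across the two
genomes, the number of orthologues shared between a linkage group and a
target chromosome (or a window within a chromosome) is hypergeometric in the
universe of anchors shared by the species pair. Tests are one-sided (upper
tail, enrichment only) and Bonferroni-corrected by the number of tests
actually performed, which is recorded in the output so that the correction
is auditable.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .clg import CLGPartition
from .model import GeneMap
from .orthology import AnchorSet

__all__ = [
    "hypergeom_upper_tail",
    "chromosome_enrichment",
    "window_enrichment",
    "summarize_windows",
    "significance_tier",
]


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), summed in log space.

    N: universe size; K: marked items; n: draws; k: observed overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K, n)]")
    if k == 0:
        return 1.0
    j = np.arange(k, min(K, n) + 1)
    logp = hypergeom.logpmf(j, N, K, n)
    return float(min(1.0, np.exp(logsumexp(logp))))


def _flag_columns(df: pd.DataFrame, levels: Sequence[float]) -> pd.DataFrame:
    for level in levels:
        df[f"significant_{level:g}"] = df["p_bonferroni"] < level
    return df


def chromosome_enrichment(
    partition: CLGPartition,
    anchors: AnchorSet,
    target: str,
    target_map: GeneMap,
    levels: Sequence[float] = (0.05, 0.01),
) -> pd.DataFrame:
    """Whole-chromosome CLG x target-chromosome hypergeometric tests.

    The universe N is the per-species-pair anchor count (anchors of the
    outgroup with an orthologue in ``target``); m = #CLGs x #target
    chromosomes, counting every chromosome of the target gene map.
    """
    sub = anchors.with_target(target).copy()
    sub["clg"] = sub["outgroup_gene"].map(partition.assignment)
    sub = sub[sub["clg"].notna()]
    N = len(sub)
    clgs = partition.letters
    chroms = target_map.chromosomes()
    m = len(clgs) * len(chroms)
    k_clg = sub.groupby("clg").size()
    k_chrom = sub.groupby(f"{target}_chromosome").size()
    k_both = sub.groupby(["clg", f"{target}_chromosome"]).size()
    rows = []
    for clg in clgs:
        K = int(k_clg.get(clg, 0))
        for chrom in chroms:
            n = int(k_chrom.get(chrom, 0))
            k = int(k_both.get((clg, chrom), 0))
            p = hypergeom_upper_tail(N, K, n, k) if N else 1.0
            rows.append((clg, target, chrom, N, K, n, k, p, min(1.0, p * m), m))
    df = pd.DataFrame(
        rows,
        columns=[
            "clg", "target", "chromosome", "n_universe", "n_clg",
            "n_window", "n_overlap", "p_raw", "p_bonferroni", "m_tests",
        ],
    )
    return _flag_columns(df, levels)


def window_enrichment(
    partition: CLGPartition,
    anchors: AnchorSet,
    target: str,
    target_map: GeneMap,
    window_size: int,
    step: Optional[int] = None,
    levels: Sequence[float] = (0.05, 0.01),
) -> pd.DataFrame:
    """Sliding-window CLG enrichment along the target chromosomes.

    Windows of ``window_size`` genes slide by ``step`` (default
    window_size // 2) in target gene ordinals, pooled across chromosomes of
    the species pair for the Bonferroni denominator m = #windows x #CLGs.
    Windows containing no anchored genes are skipped and not counted in m.
    """
    if window_size < 2:
        raise ValueError("window_size must be >= 2")
    step = step or max(1, window_size // 2)
    sub = anchors.with_target(target).copy()
    sub["clg"] = sub["outgroup_gene"].map(partition.assignment)
    sub = sub[sub["clg"].notna()]
    N = len(sub)
    clgs = partition.letters
    pos = target_map.position_index()
    sub["target_ordinal"] = sub[f"{target}_gene"].map(pos["ordinal"])
    k_clg = sub.groupby("clg").size()

    windows = []  # (chromosome, start, end, window frame)
    for chrom in target_map.chromosomes():
        size = target_map.chromosome_size(chrom)
        on_chrom = sub[sub[f"{target}_chromosome"] == chrom]
        starts = list(range(0, max(size - window_size, 0) + 1, step))
        if not starts:
            starts = [0]
        for start in starts:
            end = min(start + window_size, size)
            inside = on_chrom[
                (on_chrom["target_ordinal"] >= start) & (on_chrom["target_ordinal"] < end)
            ]
            if inside.empty:
                continue
            windows.append((chrom, start, end, inside))
    m = len(windows) * len(clgs)
    rows = []
    for chrom, start, end, inside in windows:
        n = len(inside)
        counts = inside.groupby("clg").size()
        for clg in clgs:
            K = int(k_clg.get(clg, 0))
            k = int(counts.get(clg, 0))
            p = hypergeom_upper_tail(N, K, n, k) if N else 1.0
            rows.append(
                (clg, target, chrom, start, end, N, K, n, k, p, min(1.0, p * m), m)
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "clg", "target", "chromosome", "window_start", "window_end",
            "n_universe", "n_clg", "n_window", "n_overlap", "p_raw",
            "p_bonferroni", "m_tests",
        ],
    )
    return _flag_columns(df, levels)


def summarize_windows(window_results: pd.DataFrame) -> pd.DataFrame:
    """Best (minimum corrected p) window per (CLG, chromosome)."""
    if window_results.empty:
        return window_results
    idx = window_results.groupby(["clg", "chromosome"])["p_bonferroni"].idxmin()
    return window_results.loc[sorted(idx)].reset_index(drop=True)


def significance_tier(
    chrom_results: pd.DataFrame,
    win50_results: pd.DataFrame,
    win100_results: pd.DataFrame,
) -> pd.DataFrame:
    """Per-cell significance tier combining the three scales.

    strong: 50-gene window p_bonf < 0.01 (the asterisk annotation);
    weak: 50-gene p_bonf < 0.05, or 100-gene p_bonf < 0.01, or
    whole-chromosome p_bonf < 0.05 (the plus annotation); none otherwise.
    Strong subsumes weak.
    """
    w50 = summarize_windows(win50_results)
    w100 = summarize_windows(win100_results)

    def best(df: pd.DataFrame) -> dict:
        if df.empty:
            return {}
        return df.set_index(["clg", "chromosome"])["p_bonferroni"].to_dict()

    p50, p100 = best(w50), best(w100)
    pchrom = chrom_results.set_index(["clg", "chromosome"])["p_bonferroni"].to_dict()
    rows = []
    for (clg, chrom), pc in sorted(pchrom.items()):
        a = p50.get((clg, chrom), 1.0)
        b = p100.get((clg, chrom), 1.0)
        if a < 0.01:
            tier = "strong"
        elif a < 0.05 or b < 0.01 or pc < 0.05:
            tier = "weak"
        else:
            tier = "none"
        rows.append((clg, chrom, a, b, pc, tier))
    return pd.DataFrame(
        rows, columns=["clg", "chromosome", "p50_bonf", "p100_bonf", "pchrom_bonf", "tier"]
    )
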