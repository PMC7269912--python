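"""Retention fractions, subgenome assignment, and the asymmetry statistics.

After a genome duplication most duplicated genes are lost. The retention
fraction of a linkage group (CLG) on a descendant chromosome segment is the
number of CLG gene families with a member on that segment (counting one
member per chromosome, so tandem duplicates never inflate it) divided by the
number of CLG-defining genes in the unduplicated outgroup. Autotetraploidy
predicts symmetric loss across the duplicated copies; allotetraploidy
predicts asymmetric loss between the two parental subgenomes (alpha = high
retention, beta = low). The asymmetry test compares the observed mean
alpha-minus-beta difference of paired segments against a null in which the
two members of each pair are drawn from a single retention class — by
default uniform on (0, c) with c twice the overall retention mean — and the
larger of the two is labelled alpha. Closed forms for that null are
E[max-min] = c/3 and sd[max-min] = c/sqrt(18); the test estimates them by
(seeded) bootstrap for fidelity and reports a one-sided normal z/p.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clg import CLGPartition
from .model import GeneMap, OrthogroupTable, Segment

__all__ = [
    "retention_fraction",
    "assign_alpha_beta",
    "asymmetry_test",
    "AsymmetryResult",
    "uniform_null_mean",
    "uniform_null_pair_sd",
    "retention_correlation",
    "fusion_concordance_test",
    "single_survivor_retention",
    "simulate_retention_pairs",
]


# ---------------------------------------------------------------------------
# retention fractions


def retention_fraction(
    segments: Sequence[Segment],
    clg: str,
    partition: CLGPartition,
    orthogroups: OrthogroupTable,
    gene_map: GeneMap,
) -> tuple[int, int, float]:
    """(n_retained, n_defining, r) for one cell of one species.

    n_defining is the CLG-defining outgroup gene count; n_retained is the
    number of defining families with at least one member inside the cell's
    segments (membership is by segment, not chromosome, so two paralogous
    sub-cells on one chromosome are counted apart).
    """
    defining_genes = partition.assignment[partition.assignment == clg].index
    n_defining = len(defining_genes)
    if n_defining == 0:
        raise ValueError(f"CLG {clg!r} has no defining genes")
    out_species = partition.species
    fam_out = orthogroups.family_of(out_species)
    defining_families = set(fam_out.reindex(defining_genes).dropna())
    fam_target = orthogroups.family_of(gene_map.species)
    pos = gene_map.position_index()
    present: set[str] = set()
    for seg in segments:
        if seg.species != gene_map.species:
            raise ValueError("segment species does not match gene map")
        genes = pos[(pos["chromosome"] == seg.chromosome)]
        inside = genes[(genes["ordinal"] >= seg.start) & (genes["ordinal"] < seg.end)]
        fams = fam_target.reindex(inside.index).dropna()
        present.update(f for f in fams if f in defining_families)
    n_ret = len(present)
    return n_ret, n_defining, n_ret / n_defining


# ---------------------------------------------------------------------------
# alpha/beta assignment


def assign_alpha_beta(groups: pd.DataFrame) -> pd.DataFrame:
    """Pair chromosome groups by fusion concordance and order each pair.

    ``groups`` needs one row per linked cross-species chromosome group with
    columns group_id, signature (sorted '+'-joined CLG content of the
    group), retention (mean cell retention of the group) and n_genes.

    Groups sharing a signature are fusion-concordant candidates. Within a
    signature class the i-th highest-retention group is paired with the
    i-th lowest; the higher member of each pair becomes alpha, the lower
    beta, so every chromosome is wholly alpha or wholly beta. A leftover
    (odd) group is alpha-without-beta. Returns the input with subgenome,
    pair_id and unpaired columns added.
    """
    out = groups.copy()
    out["subgenome"] = "unassigned"
    out["pair_id"] = ""
    out["unpaired"] = False
    pair_counter = itertools.count()
    for signature, sub in out.groupby("signature", sort=True):
        order = sub.sort_values(
            ["retention", "group_id"], ascending=[False, True]
        ).index.to_list()
        g = len(order)
        k = g // 2
        for i in range(k):
            hi, lo = order[i], order[g - 1 - i]
            pid = f"{signature}:{next(pair_counter)}"
            out.loc[hi, ["subgenome", "pair_id"]] = ("alpha", pid)
            out.loc[lo, ["subgenome", "pair_id"]] = ("beta", pid)
        if g % 2:
            mid = order[k]
            out.loc[mid, "subgenome"] = "alpha"
            out.loc[mid, "unpaired"] = True
    return out


# ---------------------------------------------------------------------------
# asymmetry test


def uniform_null_mean(c: float) -> float:
    """E[max - min] for two iid uniforms on (0, c)."""
    return c / 3.0


def uniform_null_pair_sd(c: float) -> float:
    """sd[max - min] for two iid uniforms on (0, c)."""
    return c / np.sqrt(18.0)


@dataclass(frozen=True)
class AsymmetryResult:
    observed: float  # mean(alpha - beta) over complete pairs
    null_mean: float
    null_sd: float  # sd of the null mean over m pairs
    z: float
    p: float
    m_pairs: int
    c: float
    null_family: str
    reps: int
    n_excluded: int


@lru_cache(maxsize=32)
def _null_moments(m: int, reps: int, seed: int, family: str) -> tuple[float, float]:
    """Bootstrap mean and sd of mean(high - low) over m unit-scale pairs.

    Unit scale means uniform(0, 1) or standard normal; results rescale
    linearly with c (uniform) or the observed sd (normal).
    """
    rng = np.random.default_rng(seed)
    total = 0.0
    total2 = 0.0
    done = 0
    chunk = max(1, min(reps, 2_000_000 // max(m, 1)))
    while done < reps:
        b = min(chunk, reps - done)
        if family == "uniform":
            u = rng.random((b, m))
            v = rng.random((b, m))
        elif family == "normal":
            u = rng.standard_normal((b, m))
            v = rng.standard_normal((b, m))
        else:
            raise ValueError(f"unknown null family {family!r}")
        means = np.abs(u - v).mean(axis=1)
        total += means.sum()
        total2 += (means**2).sum()
        done += b
    mean = total / reps
    var = max(total2 / reps - mean**2, 0.0)
    return mean, float(np.sqrt(var))


def asymmetry_test(
    alpha: Sequence[float],
    beta: Sequence[float],
    reps: int = 1_000_000,
    seed: int = 0,
    null: str = "uniform",
    c: Optional[float] = None,
    all_values: Optional[Sequence[float]] = None,
    n_excluded: int = 0,
) -> AsymmetryResult:
    """One-sided test of alpha-over-beta retention asymmetry.

    ``alpha``/``beta`` are the paired retention fractions (unpaired cells
    are excluded beforehand; pass their count as ``n_excluded``). The null
    scale c defaults to twice the mean of ``all_values`` (or of the paired
    values if not given); pass ``c`` explicitly to condition on a known
    scale. Deterministic for fixed seed and reps.
    """
    a = np.asarray(alpha, dtype=float)
    b = np.asarray(beta, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("alpha and beta must be 1-d arrays of equal length")
    m = len(a)
    if m < 2:
        raise ValueError("asymmetry test needs at least 2 complete pairs")
    pool = np.asarray(all_values, float) if all_values is not None else np.concatenate([a, b])
    if c is None:
        c = 2.0 * float(pool.mean())
    observed = float((a - b).mean())
    unit_mean, unit_sd = _null_moments(m, reps, seed, null)
    if null == "uniform":
        scale = c
    else:
        scale = float(pool.std(ddof=1))
    null_mean = unit_mean * scale
    null_sd = unit_sd * scale
    if null_sd == 0:
        raise ValueError("degenerate null (zero sd)")
    z = (observed - null_mean) / null_sd
    p = float(stats.norm.sf(z))
    return AsymmetryResult(
        observed, null_mean, null_sd, float(z), p, m, float(c), null, reps, n_excluded
    )


# ---------------------------------------------------------------------------
# cross-species correlation


def retention_correlation(
    table: pd.DataFrame, species_a: str, species_b: str
) -> tuple[float, int]:
    """Pearson correlation of per-cell retention between two species.

    ``table`` needs columns cell_id, species, retention. Returns (r, n
    shared cells); r is NaN when either side has zero variance.
    """
    wide = table.pivot_table(index="cell_id", columns="species", values="retention")
    if species_a not in wide.columns or species_b not in wide.columns:
        raise ValueError("species absent from retention table")
    sub = wide[[species_a, species_b]].dropna()
    n = len(sub)
    if n < 3:
        raise ValueError("need at least 3 shared cells")
    x, y = sub[species_a].to_numpy(), sub[species_b].to_numpy()
    if x.std() == 0 or y.std() == 0:
        return float("nan"), n
    r, _ = stats.pearsonr(x, y)
    return float(r), n


# ---------------------------------------------------------------------------
# fusion concordance


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def _count_concordant(pairs: Sequence[tuple[str, str]], alpha_counter: Counter) -> int:
    avail = alpha_counter.copy()
    hits = 0
    for p in pairs:
        key = _pair_key(*p)
        if avail[key] > 0:
            avail[key] -= 1
            hits += 1
    return hits


def fusion_concordance_test(
    alpha_pairs: Sequence[tuple[str, str]],
    beta_pairs: Sequence[tuple[str, str]],
    n_perm: int = 100_000,
    seed: int = 0,
    exact_limit: int = 1_000_000,
) -> tuple[float, int, str]:
    """Permutation test that beta fusions repeat the alpha fusion pattern.

    The statistic is the number of beta fused pairs identical (as unordered
    CLG pairs) to an alpha fused pair. The null pairs the beta segments by
    a uniformly random perfect matching; p is the fraction of matchings
    with a statistic at least as large as observed — enumerated exactly
    when the matching count (2k-1)!! is at most ``exact_limit``, otherwise
    Monte-Carlo sampled with ``n_perm`` draws.

    Returns (p, observed statistic, method).
    """
    alpha_counter = Counter(_pair_key(*p) for p in alpha_pairs)
    observed = _count_concordant(list(beta_pairs), alpha_counter)
    elements = [x for p in beta_pairs for x in p]
    k = len(beta_pairs)
    if k == 0:
        return 1.0, 0, "degenerate"
    n_matchings = 1
    for i in range(2 * k - 1, 0, -2):
        n_matchings *= i

    def matchings(items: list[str]):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for i in range(len(rest)):
            partner = rest[i]
            for tail in matchings(rest[:i] + rest[i + 1 :]):
                yield [(first, partner)] + tail

    if n_matchings <= exact_limit:
        hits = sum(
            1
            for match in matchings(elements)
            if _count_concordant(match, alpha_counter) >= observed
        )
        return hits / n_matchings, observed, "exact"
    rng = np.random.default_rng(seed)
    hits = 0
    arr = np.array(elements)
    for _ in range(n_perm):
        perm = rng.permutation(len(arr))
        match = [(arr[perm[2 * i]], arr[perm[2 * i + 1]]) for i in range(k)]
        if _count_concordant(match, alpha_counter) >= observed:
            hits += 1
    return (hits + 1) / (n_perm + 1), observed, "sampled"


# ---------------------------------------------------------------------------
# reference simulations


def single_survivor_retention(
    n_families: int, n_copies: int = 4, seed: int = 0
) -> np.ndarray:
    """Per-copy retention when each family keeps exactly one of ``n_copies``
    duplicated copies, chosen uniformly — the fully symmetric-loss limit
    where every segment is expected to retain 1/n_copies of families."""
    rng = np.random.default_rng(seed)
    survivor = rng.integers(0, n_copies, size=n_families)
    counts = np.bincount(survivor, minlength=n_copies)
    return counts / n_families


def simulate_retention_pairs(
    n_pairs: int,
    mechanism: str,
    seed: int = 0,
    r_alpha: float = 0.39,
    r_beta: float = 0.15,
    r_mean: float = 0.27,
    n_families: int = 1600,
) -> np.ndarray:
    """Cell-level retention pairs under an allo- or autotetraploid model.

    allo: every pair has fixed true rates (r_alpha, r_beta) — two retention
    classes. auto: both members draw their true rate iid from a single
    class, uniform on (0, 2*r_mean), as expected when duplicated copies are
    exchangeable but chromosome-level retention varies. Observed fractions
    add binomial sampling noise with ``n_families`` families per cell
    (defaults to the scale of CLG-defining gene counts in a chordate-sized
    genome). Returns an (n_pairs, 2) array ordered high, low within pairs.
    """
    rng = np.random.default_rng(seed)
    if mechanism == "allo":
        true = np.tile([r_alpha, r_beta], (n_pairs, 1))
    elif mechanism == "auto":
        true = rng.uniform(0.0, 2.0 * r_mean, size=(n_pairs, 2))
    else:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    obs = rng.binomial(n_families, true) / n_families
    obs.sort(axis=1)
    return obs[:, ::-1]
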