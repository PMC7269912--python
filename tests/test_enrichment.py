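from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clgkit.clg import CLGPartition
from clgkit.enrichment import (
    chromosome_enrichment,
    hypergeom_upper_tail,
    significance_tier,
    summarize_windows,
    window_enrichment,
)
from clgkit.model import GeneMap
from clgkit.orthology import AnchorSet

from conftest import make_gene_map


def exact_upper_tail(N, K, n, k):
    total = comb(N, n)
    return sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1)) / total


def test_hypergeom_known_values():
    assert hypergeom_upper_tail(20, 5, 5, 5) == pytest.approx(1 / comb(20, 5), rel=1e-12)
    assert hypergeom_upper_tail(10, 5, 5, 0) == 1.0
    assert hypergeom_upper_tail(10, 5, 5, 3) == pytest.approx(0.5, abs=1e-12)


def test_hypergeom_rejects_bad_parameters():
    with pytest.raises(ValueError):
        hypergeom_upper_tail(10, 12, 5, 1)
    with pytest.raises(ValueError):
        hypergeom_upper_tail(10, 5, 5, 6)


@given(st.integers(2, 25), st.data())
def test_hypergeom_matches_enumeration_and_is_monotone(N, data):
    K = data.draw(st.integers(0, N))
    n = data.draw(st.integers(0, N))
    top = min(K, n)
    ps = [hypergeom_upper_tail(N, K, n, k) for k in range(top + 1)]
    for k, p in enumerate(ps):
        assert p == pytest.approx(exact_upper_tail(N, K, n, k), abs=1e-10)
    assert all(a >= b - 1e-12 for a, b in zip(ps, ps[1:]))


def _toy_partition_and_anchors(extra_chrom=False):
    """Outgroup of 2 CLGs (20 genes each); target mirrors them 1:1."""
    outg = make_gene_map("out", {"c1": 20, "c2": 20})
    assignment = pd.Series(
        ["A"] * 20 + ["B"] * 20, index=outg.records["gene_id"].to_numpy()
    )
    segments = pd.DataFrame(
        {"clg": ["A", "B"], "chromosome": ["c1", "c2"], "start": [0, 0],
         "end": [20, 20], "n_genes": [20, 20]}
    )
    partition = CLGPartition("out", assignment, segments)
    sizes = {"t1": 20, "t2": 20}
    if extra_chrom:
        sizes["t3"] = 5
    target = make_gene_map("tgt", sizes, prefix="t")
    table = outg.records[["gene_id", "chromosome", "ordinal"]].rename(
        columns={"gene_id": "outgroup_gene"}
    )
    table["tgt_gene"] = [f"t{i:05d}" for i in range(40)]
    table["tgt_chromosome"] = ["t1"] * 20 + ["t2"] * 20
    anchors = AnchorSet("out", ("tgt",), table)
    return partition, anchors, target


def test_chromosome_enrichment_true_cells_significant():
    partition, anchors, target = _toy_partition_and_anchors()
    res = chromosome_enrichment(partition, anchors, "tgt", target)
    res = res.set_index(["clg", "chromosome"])
    assert res.loc[("A", "t1"), "p_bonferroni"] < 0.01
    assert res.loc[("B", "t2"), "p_bonferroni"] < 0.01
    assert res.loc[("A", "t2"), "p_raw"] == pytest.approx(1.0)


def test_bonferroni_scales_with_chromosome_count():
    partition, anchors, target = _toy_partition_and_anchors()
    partition2, anchors2, target_extra = _toy_partition_and_anchors(extra_chrom=True)
    base = chromosome_enrichment(partition, anchors, "tgt", target).set_index(["clg", "chromosome"])
    extra = chromosome_enrichment(partition2, anchors2, "tgt", target_extra).set_index(["clg", "chromosome"])
    p0 = base.loc[("A", "t1")]
    p1 = extra.loc[("A", "t1")]
    assert p1["m_tests"] == p0["m_tests"] * 1.5  # 3 chromosomes instead of 2
    assert p1["p_bonferroni"] == pytest.approx(min(1.0, p0["p_raw"] * p1["m_tests"]))


def test_degenerate_universe_gives_p_one():
    outg = make_gene_map("out", {"c1": 5})
    partition = CLGPartition(
        "out",
        pd.Series(["A"] * 5, index=outg.records["gene_id"].to_numpy()),
        pd.DataFrame({"clg": ["A"], "chromosome": ["c1"], "start": [0], "end": [5], "n_genes": [5]}),
    )
    target = make_gene_map("tgt", {"t1": 5}, prefix="t")
    table = outg.records[["gene_id", "chromosome", "ordinal"]].rename(columns={"gene_id": "outgroup_gene"})
    table["tgt_gene"] = [f"t{i:05d}" for i in range(5)]
    table["tgt_chromosome"] = "t1"
    anchors = AnchorSet("out", ("tgt",), table)
    res = chromosome_enrichment(partition, anchors, "tgt", target)
    assert res.iloc[0]["p_raw"] == pytest.approx(1.0)


def test_single_window_equals_chromosome_scale():
    partition, anchors, target = _toy_partition_and_anchors()
    chrom = chromosome_enrichment(partition, anchors, "tgt", target)
    win = window_enrichment(partition, anchors, "tgt", target, window_size=20, step=20)
    c = chrom.set_index(["clg", "chromosome"])
    w = win.set_index(["clg", "chromosome"])
    assert w.loc[("A", "t1"), "p_raw"] == pytest.approx(c.loc[("A", "t1"), "p_raw"])
    # m differs only through the number of scopes, which coincides here
    assert sorted(w["m_tests"]) == sorted(c["m_tests"])


def test_windows_without_anchors_are_skipped():
    partition, anchors, target = _toy_partition_and_anchors(extra_chrom=True)
    win = window_enrichment(partition, anchors, "tgt", target, window_size=5, step=5)
    assert not (win["chromosome"] == "t3").any()  # t3 has no anchors
    # m counts only windows that were actually tested
    n_windows = len(win[["chromosome", "window_start"]].drop_duplicates())
    assert (win["m_tests"] == n_windows * 2).all()


def test_significance_tier_rules():
    def frame(p50, p100, pchrom):
        base = {"clg": ["A"], "chromosome": ["t1"], "n_universe": [10], "n_clg": [5],
                "n_window": [5], "n_overlap": [3]}
        c = pd.DataFrame({**base, "p_raw": [pchrom], "p_bonferroni": [pchrom], "m_tests": [1]})
        w50 = pd.DataFrame({**base, "window_start": [0], "window_end": [5],
                            "p_raw": [p50], "p_bonferroni": [p50], "m_tests": [1]})
        w100 = pd.DataFrame({**base, "window_start": [0], "window_end": [5],
                             "p_raw": [p100], "p_bonferroni": [p100], "m_tests": [1]})
        return c, w50, w100

    strong = significance_tier(*frame(0.005, 1.0, 1.0))
    assert strong.iloc[0]["tier"] == "strong"
    weak = significance_tier(*frame(0.2, 1.0, 0.03))
    assert weak.iloc[0]["tier"] == "weak"
    weak2 = significance_tier(*frame(0.2, 0.005, 1.0))
    assert weak2.iloc[0]["tier"] == "weak"
    none = significance_tier(*frame(1.0, 1.0, 1.0))
    assert none.iloc[0]["tier"] == "none"


def test_null_calibration_of_raw_p_values():
    """Shuffled orthologue placements reject at close to the nominal rate.

    Large balanced counts keep the hypergeometric near-continuous so the
    discrete super-uniformity of p values is negligible.
    """
    rng = np.random.default_rng(0)
    N, half = 2400, 1200
    alpha = 0.05
    hits = 0
    trials = 200
    for _ in range(trials):
        clg = np.zeros(N, dtype=bool)
        clg[:half] = True
        chrom = rng.permutation(np.arange(N) < half)
        k = int(np.sum(clg & chrom))
        p = hypergeom_upper_tail(N, half, half, k)
        hits += p < alpha
    rate = hits / trials
    assert 0.02 <= rate <= 0.09
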