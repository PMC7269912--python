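import numpy as np
import pandas as pd
import pytest

from clgkit.clg import CLGPartition
from clgkit.model import GeneMap, OrthogroupTable, Segment
from clgkit.retention import (
    assign_alpha_beta,
    asymmetry_test,
    fusion_concordance_test,
    retention_correlation,
    retention_fraction,
    simulate_retention_pairs,
    single_survivor_retention,
    uniform_null_mean,
    uniform_null_pair_sd,
    _null_moments,
)

from conftest import make_gene_map


def _setup_retention(n_defining=10, retained=4, tandem=False):
    outg = make_gene_map("out", {"c1": n_defining})
    assignment = pd.Series(["A"] * n_defining, index=outg.records["gene_id"].to_numpy())
    partition = CLGPartition(
        "out", assignment,
        pd.DataFrame({"clg": ["A"], "chromosome": ["c1"], "start": [0],
                      "end": [n_defining], "n_genes": [n_defining]}),
    )
    rows = []
    fams = []
    tcount = 0
    for i in range(retained):
        fam = f"f{i}"
        fams.append((fam, "out", f"g{i:05d}"))
        copies = 3 if (tandem and i == 0) else 1
        for c in range(copies):
            gid = f"t{tcount:05d}"
            rows.append((gid, "tc1", (tcount + 1) * 100))
            fams.append((fam, "tgt", gid))
            tcount += 1
    for i in range(retained, n_defining):
        fams.append((f"f{i}", "out", f"g{i:05d}"))
    target = GeneMap.from_rows("tgt", rows)
    og = OrthogroupTable(pd.DataFrame(fams, columns=["family_id", "species", "gene_id"]))
    return partition, og, target, tcount


def test_retention_fraction_arithmetic():
    partition, og, target, n = _setup_retention(n_defining=10, retained=4)
    segs = [Segment("tgt", "tc1", 0, n)]
    n_ret, n_def, r = retention_fraction(segs, "A", partition, og, target)
    assert (n_ret, n_def) == (4, 10)
    assert r == pytest.approx(0.4)


def test_tandem_copies_count_once():
    partition, og, target, n = _setup_retention(n_defining=10, retained=4, tandem=True)
    segs = [Segment("tgt", "tc1", 0, n)]
    n_ret, _, r = retention_fraction(segs, "A", partition, og, target)
    assert n_ret == 4 and r == pytest.approx(0.4)


def test_retention_membership_is_by_segment():
    partition, og, target, n = _setup_retention(n_defining=10, retained=4)
    half = [Segment("tgt", "tc1", 0, 2)]
    n_ret, _, _ = retention_fraction(half, "A", partition, og, target)
    assert n_ret == 2


def test_retention_zero_denominator_is_error():
    partition, og, target, n = _setup_retention()
    with pytest.raises(ValueError, match="no defining genes"):
        retention_fraction([Segment("tgt", "tc1", 0, n)], "Z", partition, og, target)


def _groups(rows):
    return pd.DataFrame(rows, columns=["group_id", "signature", "retention", "n_genes"])


def test_alpha_beta_pairing_orders_by_retention():
    groups = assign_alpha_beta(_groups([("g1", "A", 0.40, 100), ("g2", "A", 0.14, 40)]))
    by = groups.set_index("group_id")
    assert by.loc["g1", "subgenome"] == "alpha"
    assert by.loc["g2", "subgenome"] == "beta"
    assert by.loc["g1", "pair_id"] == by.loc["g2", "pair_id"] != ""


def test_alpha_beta_four_groups_make_two_pairs():
    groups = assign_alpha_beta(
        _groups([("g1", "A", 0.41, 1), ("g2", "A", 0.38, 1), ("g3", "A", 0.16, 1), ("g4", "A", 0.13, 1)])
    )
    by = groups.set_index("group_id")
    assert list(by["subgenome"]) == ["alpha", "alpha", "beta", "beta"]
    assert by.loc["g1", "pair_id"] == by.loc["g4", "pair_id"]
    assert by.loc["g2", "pair_id"] == by.loc["g3", "pair_id"]


def test_unpaired_group_is_alpha_without_beta():
    groups = assign_alpha_beta(
        _groups([("g1", "A", 0.40, 1), ("g2", "A", 0.39, 1), ("g3", "A", 0.15, 1)])
    )
    by = groups.set_index("group_id")
    assert by.loc["g2", "unpaired"] and by.loc["g2", "subgenome"] == "alpha"
    assert not by.loc["g1", "unpaired"] and not by.loc["g3", "unpaired"]
    # different signatures never pair
    sep = assign_alpha_beta(_groups([("g1", "A", 0.4, 1), ("g2", "B", 0.1, 1)]))
    assert (sep["unpaired"]).all()


def test_asymmetry_closed_forms_match_bootstrap():
    mean1, sd1 = _null_moments(24, 200_000, 0, "uniform")
    assert mean1 == pytest.approx(1 / 3, rel=0.01)
    assert sd1 * np.sqrt(24) == pytest.approx(1 / np.sqrt(18), rel=0.02)
    assert uniform_null_mean(0.54) == pytest.approx(0.18)
    assert uniform_null_pair_sd(0.54) == pytest.approx(0.54 / np.sqrt(18))


def test_asymmetry_z_for_paper_scale_pairs():
    # 24 identical pairs (0.39, 0.15): closed forms give z ~ 2.31 at c = 0.54
    alpha = np.full(24, 0.39)
    beta = np.full(24, 0.15)
    res = asymmetry_test(alpha, beta, reps=200_000, seed=1)
    assert res.c == pytest.approx(0.54)
    assert res.observed == pytest.approx(0.24)
    assert res.z == pytest.approx(2.31, abs=0.15)
    assert 0.005 < res.p < 0.05


def test_asymmetry_symmetric_pairs_give_negative_z():
    vals = np.full(10, 0.27)
    res = asymmetry_test(vals, vals, reps=50_000, seed=2)
    assert res.observed == 0.0
    assert res.z < 0 and res.p > 0.5


def test_asymmetry_is_deterministic_and_validates():
    a, b = np.array([0.4, 0.35, 0.42]), np.array([0.1, 0.2, 0.15])
    r1 = asymmetry_test(a, b, reps=10_000, seed=5)
    r2 = asymmetry_test(a, b, reps=10_000, seed=5)
    assert r1 == r2
    with pytest.raises(ValueError, match="at least 2"):
        asymmetry_test([0.4], [0.1], reps=100, seed=0)


def test_retention_correlation_directions():
    def table(vals_a, vals_b):
        rows = []
        for i, (va, vb) in enumerate(zip(vals_a, vals_b)):
            rows.append((f"c{i}", "spA", va))
            rows.append((f"c{i}", "spB", vb))
        return pd.DataFrame(rows, columns=["cell_id", "species", "retention"])

    vals = [0.1, 0.2, 0.3, 0.4]
    r, n = retention_correlation(table(vals, vals), "spA", "spB")
    assert r == pytest.approx(1.0)
    r2, _ = retention_correlation(table(vals, vals[::-1]), "spA", "spB")
    assert r2 < 0
    flat, _ = retention_correlation(table([0.2] * 4, vals), "spA", "spB")
    assert np.isnan(flat)
    with pytest.raises(ValueError, match="at least 3"):
        retention_correlation(table(vals[:2], vals[:2]), "spA", "spB")


def test_fusion_concordance_exact_small_case():
    p, stat, method = fusion_concordance_test([("A", "B"), ("C", "D")], [("A", "B"), ("C", "D")])
    assert method == "exact"
    assert stat == 2
    assert p == pytest.approx(1 / 3)


def test_fusion_concordance_disjoint_patterns():
    p, stat, _ = fusion_concordance_test([("A", "B")], [("C", "D")])
    assert stat == 0 and p == 1.0


def test_fusion_concordance_seven_identical_pairs():
    pairs = [(f"X{i}", f"Y{i}") for i in range(7)]
    p, stat, method = fusion_concordance_test(pairs, pairs)
    assert method == "exact" and stat == 7
    assert p == pytest.approx(1 / 135135)  # 13!! perfect matchings, one concordant
    assert p < 1e-5


def test_single_survivor_expected_quarter():
    r = single_survivor_retention(100_000, seed=0)
    assert r.sum() == pytest.approx(1.0)
    assert np.all(np.abs(r - 0.25) < 0.006)  # ~4.4 sigma at n = 1e5


def test_simulated_pair_mechanisms():
    allo = simulate_retention_pairs(50, "allo", seed=0)
    assert allo.shape == (50, 2)
    assert allo[:, 0].mean() == pytest.approx(0.39, abs=0.01)
    assert allo[:, 1].mean() == pytest.approx(0.15, abs=0.01)
    auto = simulate_retention_pairs(400, "auto", seed=0)
    # one retention class: mean of both members matches the overall mean
    assert auto.mean() == pytest.approx(0.27, abs=0.02)
    with pytest.raises(ValueError):
        simulate_retention_pairs(5, "nope")
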