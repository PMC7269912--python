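import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from clgkit.clg import (
    SyntenyIndicator,
    consensus_breakpoints,
    detect_breakpoints,
    discontinuity,
    indicator_profile,
    merge_segments,
    segments_from_breakpoints,
)
from clgkit.model import GeneMap, Segment
from clgkit.pipeline import infer_clgs
from clgkit.model import AnalysisConfig

from conftest import make_gene_map


def make_indicator(labels_by_chrom, comparator="comp"):
    cats = sorted({l for labs in labels_by_chrom.values() for l in labs})
    per = {}
    for chrom, labs in labels_by_chrom.items():
        per[chrom] = pd.DataFrame(
            {
                "outgroup_gene": [f"{chrom}g{i}" for i in range(len(labs))],
                "ordinal": np.arange(len(labs)),
                "target_chromosome": labs,
            }
        )
    return SyntenyIndicator(comparator, per, tuple(cats))


def test_indicator_profile_rows_follow_orthologues(small_dataset):
    from clgkit.orthology import build_anchor_set, mutual_best_hits

    ds = small_dataset
    out = ds.config.outgroup_name
    t = ds.config.ingroup_names[0]
    mbh = mutual_best_hits(ds.similarities[(out, t)], ds.similarities[(t, out)])
    anchors = build_anchor_set(ds.gene_maps[out], {t: mbh}, {t: ds.gene_maps[t]})
    ind = indicator_profile(anchors, t)
    # each anchored gene's indicator names the chromosome of its true orthologue
    truth = ds.truth.genes
    pos = truth[truth["species"] == t].set_index("gene_id")["chromosome"]
    mbh_map = mbh.as_dict()
    for chrom, sub in ind.per_chromosome.items():
        expected = sub["outgroup_gene"].map(mbh_map).map(pos)
        assert (sub["target_chromosome"] == expected).all()
    with pytest.raises(ValueError, match="absent"):
        indicator_profile(anchors, "nope")


def test_discontinuity_zero_on_homogeneous_chromosome():
    ind = make_indicator({"c1": ["A"] * 60})
    prof = discontinuity(ind, 25)
    assert np.allclose(prof.per_chromosome["c1"]["D"], 0.0)


def test_discontinuity_maximal_at_clean_switch():
    ind = make_indicator({"c1": ["A"] * 40 + ["B"] * 40})
    prof = discontinuity(ind, 25)
    d = prof.per_chromosome["c1"]
    junction = d[d["junction"] == 39]
    assert junction["D"].iloc[0] == pytest.approx(2.0)


def test_discontinuity_truncated_windows_hand_case():
    # W=2 over [A, A, B, B]: D at the junction = 2; one position away = 0.5
    ind = make_indicator({"c1": ["A", "A", "B", "B"]})
    prof = discontinuity(ind, 2)
    d = prof.per_chromosome["c1"].set_index("junction")["D"]
    assert d[1] == pytest.approx(2.0)
    assert d[0] == pytest.approx(0.5)  # (1-0.5)^2 + (0-0.5)^2
    assert d[2] == pytest.approx(0.5)


def test_discontinuity_short_chromosome_yields_empty_profile():
    ind = make_indicator({"c1": ["A"]})
    prof = discontinuity(ind, 25)
    assert prof.per_chromosome["c1"].empty


@given(st.lists(st.sampled_from("ABC"), min_size=2, max_size=60))
def test_discontinuity_bounds_and_symmetries(labels):
    ind = make_indicator({"c1": labels})
    d = discontinuity(ind, 5).per_chromosome["c1"]["D"].to_numpy()
    assert np.all(d >= -1e-12) and np.all(d <= 2 + 1e-12)
    # relabelling comparator chromosomes leaves D unchanged
    relabeled = ["X" if l == "A" else ("Y" if l == "B" else "Z") for l in labels]
    d2 = discontinuity(make_indicator({"c1": relabeled}), 5).per_chromosome["c1"]["D"].to_numpy()
    assert np.allclose(d, d2)
    # reversing the whole chromosome reverses the profile
    d3 = discontinuity(make_indicator({"c1": labels[::-1]}), 5).per_chromosome["c1"]["D"].to_numpy()
    assert np.allclose(d, d3[::-1])


def test_detect_breakpoints_single_peak_and_threshold():
    ind = make_indicator({"c1": ["A"] * 3 + ["B"] * 3})
    prof = discontinuity(ind, 2)
    bk = detect_breakpoints(prof, threshold=0.5, min_separation=1)
    assert len(bk) == 1 and bk.iloc[0]["junction"] == 2
    none = detect_breakpoints(prof, threshold=2.0, min_separation=1)
    assert len(none) <= 1  # a full switch still reaches 2.0
    flat = discontinuity(make_indicator({"c1": ["A"] * 10}), 2)
    assert detect_breakpoints(flat, 0.5, 1).empty


def test_detect_breakpoints_enforces_separation():
    labels = ["A"] * 30 + ["B"] * 4 + ["A"] * 30
    prof = discontinuity(make_indicator({"c1": labels}), 4)
    bk = detect_breakpoints(prof, threshold=0.5, min_separation=10)
    assert len(bk) == 1  # the two junctions are 4 genes apart


def test_consensus_requires_support_and_uses_median():
    bk = lambda pos: pd.DataFrame(
        {"chromosome": ["c1"], "junction": [0], "D": [1.0],
         "left_ordinal": [pos - 1], "right_ordinal": [pos]}
    )
    per_comp = {"t1": bk(100), "t2": bk(103), "t3": bk(97)}
    cons = consensus_breakpoints(per_comp, tolerance=12, min_support=2)
    assert len(cons) == 1
    assert cons.iloc[0]["position"] == 100  # median of 97,100,103
    assert cons.iloc[0]["support"] == 3
    lonely = consensus_breakpoints({"t1": bk(100), "t2": bk(400)}, 12, min_support=2)
    assert lonely.empty


def test_merge_segments_profiles_rules():
    # two chromosomes, each one segment; comparator profiles disjoint -> no merge
    gm = make_gene_map("out", {"c1": 30, "c2": 30})
    segs = [Segment("out", "c1", 0, 30), Segment("out", "c2", 0, 30)]
    ind_disjoint = make_indicator({"c1": ["X"] * 30, "c2": ["Y"] * 30})
    part = merge_segments(segs, {"comp": ind_disjoint}, gm, threshold=0.5)
    assert len(part.letters) == 2
    # identical profiles -> merged into one unit
    ind_same = make_indicator({"c1": ["X"] * 30, "c2": ["X"] * 30})
    part2 = merge_segments(segs, {"comp": ind_same}, gm, threshold=0.5)
    assert len(part2.letters) == 1
    assert set(part2.assignment.unique()) == {"A"}


def test_clg_letters_ordered_by_size_with_chromosome_tiebreak():
    gm = make_gene_map("out", {"c1": 10, "c2": 30, "c3": 10})
    segs = [Segment("out", c, 0, gm.chromosome_size(c)) for c in ("c1", "c2", "c3")]
    ind = make_indicator({"c1": ["X"] * 10, "c2": ["Y"] * 30, "c3": ["Z"] * 10})
    part = merge_segments(segs, {"comp": ind}, gm, threshold=0.9)
    seg_df = part.segments
    assert seg_df.loc[seg_df["clg"] == "A", "chromosome"].iloc[0] == "c2"  # largest
    assert seg_df.loc[seg_df["clg"] == "B", "chromosome"].iloc[0] == "c1"  # tie -> smaller id


def test_clg_recovery_on_small_simulation(small_dataset):
    from clgkit.orthology import build_anchor_set, mutual_best_hits

    ds = small_dataset
    out = ds.config.outgroup_name
    cfg = AnalysisConfig()
    mbh = {
        t: mutual_best_hits(ds.similarities[(out, t)], ds.similarities[(t, out)])
        for t in ds.config.ingroup_names
    }
    anchors = build_anchor_set(
        ds.gene_maps[out], mbh, {t: ds.gene_maps[t] for t in ds.config.ingroup_names}
    )
    partition, _, _, consensus = infer_clgs(ds.gene_maps[out], anchors, cfg)
    assert len(partition.letters) == ds.config.n_clgs
    true_j = ds.truth.junctions
    true_out = true_j[true_j["species"] == out]
    assert len(consensus) == len(true_out) == ds.config.outgroup_fusions
    for _, row in true_out.iterrows():
        near = consensus[
            (consensus["chromosome"] == row["chromosome"])
            & ((consensus["position"] - row["ordinal"]).abs() <= 5)
        ]
        assert len(near) == 1


def test_segments_tile_chromosomes():
    gm = make_gene_map("out", {"c1": 50, "c2": 20})
    cons = pd.DataFrame({"chromosome": ["c1"], "position": [30], "support": [2],
                         "comparators": ["a,b"], "mean_D": [1.0]})
    segs = segments_from_breakpoints(gm, cons)
    spans = {(s.chromosome, s.start, s.end) for s in segs}
    assert spans == {("c1", 0, 30), ("c1", 30, 50), ("c2", 0, 20)}
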