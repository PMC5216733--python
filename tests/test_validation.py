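"""Candidate ranking, qPCR quantification, median-split chi2, MSI calls."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clocknet import (TargetMap, ddct, gene_mirna_correlation,
                      median_split_association, msi_classify, rank_candidates)
from clocknet.algebra import partition_signed_pairs
from clocknet.validation import QpcrRecord, ct_ratio, delta_ct


def _de_table(rows):
    frame = pd.DataFrame(rows, columns=["symbol", "mean_log2_diff", "direction"])
    return frame.set_index("symbol")


def _topo(entries):
    frame = pd.DataFrame({"degree_centrality": pd.Series(entries, dtype=float)})
    frame.index.name = "node"
    return frame


def test_single_eligible_symbol_is_rank_one():
    de = _de_table([("m1", -2.0, "down"), ("m2", -3.0, "down")])
    targets = TargetMap(targets={"m1": {"TIMELESS"}})
    part = partition_signed_pairs({}, {("m1", "m2"): "+"})
    ranked = rank_candidates(de, part, targets, _topo({"m1": 0.1}), _topo({}))
    assert list(ranked.index) == ["m1"]
    assert ranked.loc["m1", "rank"] == 1
    assert ranked.loc["m1", "lost_edge_fraction"] == 1.0  # its one control edge vanished


def test_no_eligible_symbols_gives_empty_ranking():
    de = _de_table([("m1", -2.0, "ns"), ("m2", 1.0, "up")])
    targets = TargetMap(targets={"m1": {"PER1"}})  # m1 is ns, m2 untargeted
    part = partition_signed_pairs({}, {})
    ranked = rank_candidates(de, part, targets, _topo({}), _topo({}))
    assert ranked.empty


def test_score_components_and_ordering():
    de = _de_table([("m1", -2.766, "down"), ("m2", -2.0, "down")])
    targets = TargetMap(targets={"m1": {"TIMELESS"}, "m2": {"PER1"}})
    control = {("m1", "x"): "+", ("m1", "y"): "+", ("m2", "x"): "+"}
    tumor = {("m2", "x"): "+"}
    part = partition_signed_pairs(tumor, control)
    topo_c = _topo({"m1": 0.4, "m2": 0.2, "x": 0.3, "y": 0.1})
    topo_t = _topo({"m2": 0.2, "x": 0.2})
    ranked = rank_candidates(de, part, targets, topo_c, topo_t)
    assert list(ranked.index) == ["m1", "m2"]
    m1 = ranked.loc["m1"]
    assert m1["lost_edge_fraction"] == 1.0 and m1["hub_delta"] == pytest.approx(0.4)
    assert m1["score"] == pytest.approx(2.766 + 1.0 + 0.4)
    m2 = ranked.loc["m2"]
    assert m2["lost_edge_fraction"] == 0.0 and m2["score"] == pytest.approx(2.0)


def test_weight_scale_equivariance_and_validation():
    de = _de_table([("m1", -2.766, "down"), ("m2", -2.0, "down")])
    targets = TargetMap(targets={"m1": {"TIMELESS"}, "m2": {"PER1"}})
    part = partition_signed_pairs({}, {("m1", "m2"): "+"})
    base = rank_candidates(de, part, targets, _topo({}), _topo({}))
    scaled = rank_candidates(de, part, targets, _topo({}), _topo({}),
                             weights=(3.0, 3.0, 3.0))
    assert list(base.index) == list(scaled.index)
    np.testing.assert_allclose(scaled["score"], 3 * base["score"])
    for bad in [(1, 1), (1, 1, -1), (1, 1, 1, 1)]:
        with pytest.raises(ValueError):
            rank_candidates(de, part, targets, _topo({}), _topo({}), weights=bad)


def test_gene_mirna_inverse_correlation():
    rng = np.random.default_rng(0)
    mirna = rng.normal(size=30)
    r, p = gene_mirna_correlation(-mirna, mirna)
    assert r == pytest.approx(-1.0) and p == 0.0


def test_coupling_recovery_at_cohort_scale():
    """Planted rho=-0.32 with n=210 samples lands in the expected r band."""
    from clocknet import SyntheticConfig, generate_cohort
    cfg = SyntheticConfig(n_patients=210, n_mirnas=5, clock_genes=("TIMELESS",),
                          coupling=(("hsa-miR-139-5p", "TIMELESS", -0.32),), seed=13)
    pset, _ = generate_cohort(cfg)
    r, p = gene_mirna_correlation(pset.tumor.loc["TIMELESS"].to_numpy(),
                                  pset.tumor.loc["hsa-miR-139-5p"].to_numpy())
    assert -0.45 <= r <= -0.19
    assert p < 0.05


def test_independent_vectors_stay_weak():
    rng = np.random.default_rng(1)
    hits = sum(abs(gene_mirna_correlation(rng.normal(size=50), rng.normal(size=50))[0]) < 0.28
               for _ in range(100))
    assert hits >= 93  # ~95% of null draws at n=50


def test_ddct_conventions():
    assert ddct(5.0, 5.0, "reciprocal") == 1.0 and ddct(5.0, 5.0, "livak") == 1.0
    assert ddct(8.0, 6.0, "reciprocal") == pytest.approx(0.25)
    assert ddct(8.0, 6.0, "livak") == pytest.approx(4.0)
    with pytest.raises(ValueError):
        ddct(1.0, 1.0, "other")


def test_ddct_reciprocity_and_exponent_law():
    rng = np.random.default_rng(2)
    for cal, tgt in rng.uniform(1, 20, size=(20, 2)):
        assert ddct(cal, tgt, "reciprocal") == pytest.approx(1 / ddct(cal, tgt, "livak"))
        assert ddct(cal, tgt + 1, "reciprocal") == pytest.approx(2 * ddct(cal, tgt, "reciprocal"))


def test_delta_ct_and_record_guards():
    records = [QpcrRecord("s1", 24.0, 18.0), QpcrRecord("s2", 26.0, 18.0)]
    assert delta_ct(records) == pytest.approx(7.0)
    assert ct_ratio(18.0, 24.0) == pytest.approx(0.75)
    with pytest.raises(ValueError):
        QpcrRecord("s", 0.0, 18.0)
    with pytest.raises(ValueError):
        QpcrRecord("s", 46.0, 18.0)


def test_median_split_rule_assigns_ties_low():
    values = [1, 2, 3, 4, 5]
    labels = ["a", "a", "a", "b", "b"]
    table, chi2, p, flag = median_split_association(values, labels)
    assert table.loc["low"].sum() == 3 and table.loc["high"].sum() == 2


def test_chi2_hand_example():
    """Perfectly separated 2x2 [[10,0],[0,10]]: chi2 = 20, p ~ 7.7e-6."""
    values = list(range(20))
    labels = ["a"] * 10 + ["b"] * 10
    table, chi2, p, flag = median_split_association(values, labels)
    assert table.to_numpy().tolist() == [[10, 0], [0, 10]]
    assert chi2 == pytest.approx(20.0)
    assert p == pytest.approx(stats.chi2.sf(20.0, df=1), rel=1e-9)
    assert p == pytest.approx(7.7e-6, rel=0.05)


def test_chi2_equals_textbook_formula():
    rng = np.random.default_rng(3)
    for _ in range(20):
        values = rng.normal(size=40)
        labels = rng.choice(["a", "b", "c"], size=40)
        table, chi2, p, flag = median_split_association(values, labels)
        obs = table.to_numpy(dtype=float)
        expected = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        assert chi2 == pytest.approx(((obs - expected) ** 2 / expected).sum(), rel=1e-12)


def test_chi2_null_calibration():
    rng = np.random.default_rng(4)
    ps = []
    for _ in range(300):
        values = rng.normal(size=40)
        labels = rng.choice(["a", "b"], size=40)
        ps.append(median_split_association(values, labels)[2])
    assert 0.01 <= np.mean(np.asarray(ps) <= 0.05) <= 0.10


def test_median_split_guards():
    with pytest.raises(ValueError, match="2 phenotype"):
        median_split_association([1, 2, 3, 4], ["a", "a", "a", "a"])
    with pytest.raises(ValueError, match="4 subjects"):
        median_split_association([1, 2], ["a", "b"])


@pytest.mark.parametrize("count,call,interpolated", [
    (5, "MSI-H", False), (4, "MSI-H", False),
    (3, "MSI-L", True), (2, "MSI-L", False), (1, "MSI-L", True),
    (0, "MSS", False),
])
def test_msi_classification(count, call, interpolated):
    result = msi_classify(count)
    assert result.call == call and result.rule_interpolated == interpolated


def test_msi_out_of_range():
    for bad in (-1, 6):
        with pytest.raises(ValueError):
            msi_classify(bad)
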