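"""Edge partition, alias resolution and clock-controller tagging."""

import random

import pytest

from clocknet import AliasTable, EdgePartition, TargetMap, partition_networks, resolve_symbol, tag_clock_controllers
from clocknet.algebra import partition_signed_pairs
from clocknet.corrnet import CorrelationEdge, CorrelationNetwork
from oracles import partition_reference


def _net(condition, signed_pairs, r_cut=0.8, alpha=0.05):
    edges = {}
    for (a, b), sign in signed_pairs.items():
        r = 0.9 if sign == "+" else -0.9
        edges[(a, b)] = CorrelationEdge(a, b, r, 0.01, 14)
    return CorrelationNetwork(condition, r_cut, alpha, edges=edges)


def test_hand_worked_partition():
    """control {ab+, bc+, cd-}, tumor {ab+, bc-, de+}."""
    control = _net("control", {("a", "b"): "+", ("b", "c"): "+", ("c", "d"): "-"})
    tumor = _net("tumor", {("a", "b"): "+", ("b", "c"): "-", ("d", "e"): "+"})
    part = partition_networks(tumor, control)
    assert part.common == {("a", "b")}
    assert part.sign_flip == {("b", "c")}
    assert part.control_exclusive == {("c", "d")}
    assert part.tumor_exclusive == {("d", "e")}
    assert part.venn_counts == {"common": 1, "sign_flip": 1,
                                "tumor_exclusive": 1, "control_exclusive": 1}


def test_identical_and_disjoint_networks():
    signs = {("a", "b"): "+", ("c", "d"): "-"}
    same = partition_networks(_net("tumor", signs), _net("control", signs))
    assert same.common == set(signs) and not same.sign_flip
    assert not same.tumor_exclusive and not same.control_exclusive
    other = {("e", "f"): "+"}
    disjoint = partition_networks(_net("tumor", other), _net("control", signs))
    assert not disjoint.common and not disjoint.sign_flip
    assert disjoint.tumor_exclusive == set(other)


def test_threshold_mismatch_rejected():
    with pytest.raises(ValueError, match="threshold mismatch"):
        partition_networks(_net("tumor", {}, r_cut=0.8), _net("control", {}, r_cut=0.6))


def _random_signed_pairs(rng, n_symbols=12, n_pairs=18):
    symbols = [f"s{i}" for i in range(n_symbols)]
    pairs = {}
    for _ in range(n_pairs):
        a, b = rng.sample(symbols, 2)
        pairs[tuple(sorted((a, b)))] = rng.choice("+-")
    return pairs


def test_partition_properties_against_reference():
    """Disjointness, cover, and mirror symmetry on random signed edge sets."""
    rng = random.Random(0)
    for _ in range(300):
        t_signs = _random_signed_pairs(rng)
        c_signs = _random_signed_pairs(rng)
        part = partition_signed_pairs(t_signs, c_signs)
        ref = partition_reference(t_signs, c_signs)
        assert part.common == ref["common"]
        assert part.sign_flip == ref["sign_flip"]
        assert part.tumor_exclusive == ref["tumor_exclusive"]
        assert part.control_exclusive == ref["control_exclusive"]
        sets = [part.common, part.sign_flip, part.tumor_exclusive, part.control_exclusive]
        assert sum(map(len, sets)) == len(part.all_pairs())  # pairwise disjoint
        assert part.all_pairs() == set(t_signs) | set(c_signs)  # cover
        mirror = partition_signed_pairs(c_signs, t_signs)
        assert mirror.common == part.common and mirror.sign_flip == part.sign_flip
        assert mirror.tumor_exclusive == part.control_exclusive
        assert mirror.control_exclusive == part.tumor_exclusive


def test_partition_json_round_trip(tmp_path):
    part = partition_signed_pairs({("a", "b"): "+"}, {("a", "b"): "-", ("c", "d"): "+"})
    part.write_json(tmp_path / "p.json")
    import json
    loaded = EdgePartition.from_jsonable(json.loads((tmp_path / "p.json").read_text()))
    assert loaded.sign_flip == part.sign_flip == {("a", "b")}
    assert loaded.control_exclusive == {("c", "d")}


# ---------------------------------------------------------------------------
# Alias resolution
# ---------------------------------------------------------------------------

def test_alias_resolution_rules(alias_file):
    table = AliasTable.from_file(alias_file)
    # unique match resolves to the latest (last-listed) alias
    assert resolve_symbol("hsa-miR-139", table) == "hsa-miR-139-5p"
    # missing species prefix and case both normalized
    assert resolve_symbol("mir-325", table) == "hsa-miR-325-5p"
    # ambiguous across the -5p and -3p product rows: kept with its original name
    assert resolve_symbol("miR-378", table) == "miR-378"
    # no matching row: unchanged
    assert resolve_symbol("hsa-miR-99999", table) == "hsa-miR-99999"
    # canonical names are fixed points, so resolution is idempotent
    for raw in ("hsa-miR-139", "miR-378", "hsa-let-7e", "hsa-miR-139-5p"):
        once = table.resolve(raw)
        assert table.resolve(once) == once


def test_alias_duplicate_within_row_rejected():
    with pytest.raises(ValueError, match="duplicate alias"):
        AliasTable(rows=[("ACC", ("hsa-miR-1", "hsa-miR-1"))])


# ---------------------------------------------------------------------------
# Clock-controller tagging
# ---------------------------------------------------------------------------

def test_validated_target_map_contents():
    targets = TargetMap.validated()
    assert targets.targets_of("let-7e-5p") == {"PER1", "CLOCK"}
    assert targets.targets_of("hsa-miR-139-5p") == {"TIMELESS"}
    assert not targets.is_clock_targeting("hsa-miR-20a-5p")


def test_target_map_from_tsv_and_universe_guard(tmp_path):
    path = tmp_path / "targets.tsv"
    path.write_text("hsa-miR-139-5p\tTIMELESS\nhsa-let-7e-5p\tPER1\nhsa-let-7e-5p\tCLOCK\n")
    targets = TargetMap.from_tsv(path)
    assert targets.targets_of("hsa-let-7e-5p") == {"PER1", "CLOCK"}
    bad = tmp_path / "bad.tsv"
    bad.write_text("hsa-miR-1\tMYC\n")
    with pytest.raises(ValueError, match="outside the clock universe"):
        TargetMap.from_tsv(bad)


def test_pair_and_node_tagging():
    targets = TargetMap(targets={"m1": {"PER1", "CLOCK"}})
    net = _net("tumor", {("m1", "m2"): "+", ("m2", "m3"): "+"})
    pair_tags = tag_clock_controllers(net, targets)
    assert pair_tags[("m1", "m2")] is True       # one targeting member suffices
    assert pair_tags[("m2", "m3")] is False      # neither member in the map
    assert net.node_attrs["m1"].clock_target and not net.node_attrs["m2"].clock_target

    part = partition_signed_pairs({("m1", "m2"): "+"}, {("m2", "m3"): "+"})
    pair_tags, node_flags = tag_clock_controllers(part, targets)
    assert pair_tags == {("m1", "m2"): True, ("m2", "m3"): False}
    assert node_flags == {"m1": True, "m2": False, "m3": False}
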