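"""Expression I/O and quantile normalization."""

import numpy as np
import pandas as pd
import pytest

from clocknet import PairedExpressionSet, load_paired_set, quantile_normalize
from clocknet.expression import write_paired_set


def _write(tmp_path, matrix_lines, sheet_lines, stem=""):
    mpath = tmp_path / f"matrix{stem}.tsv"
    spath = tmp_path / f"sheet{stem}.tsv"
    mpath.write_text("\n".join(matrix_lines) + "\n")
    spath.write_text("\n".join(sheet_lines) + "\n")
    return mpath, spath


SHEET_3P = ["sample_id\tpatient_id\ttissue",
            "s1\tP1\ttumor", "s2\tP1\tcontrol",
            "s3\tP2\ttumor", "s4\tP2\tcontrol",
            "s5\tP3\ttumor", "s6\tP3\tcontrol"]


def _matrix_3p(values_fn):
    header = "symbol\ts1\ts2\ts3\ts4\ts5\ts6"
    lines = [header]
    for i in range(1, 6):
        vals = "\t".join(str(values_fn(i, j)) for j in range(6))
        lines.append(f"f{i}\t{vals}")
    return lines


def test_load_three_patients_five_features(tmp_path):
    mpath, spath = _write(tmp_path, _matrix_3p(lambda i, j: 8 + 0.1 * i + 0.01 * j),
                          SHEET_3P)
    pset = load_paired_set(mpath, spath)
    assert pset.control.shape == (5, 3) and pset.tumor.shape == (5, 3)
    assert pset.patients == ["P1", "P2", "P3"]  # sample-sheet order
    assert pset.tumor.loc["f2", "P2"] == pytest.approx(8.22)
    assert pset.control.loc["f2", "P2"] == pytest.approx(8.23)


def test_unpaired_patient_dropped_with_warning(tmp_path):
    sheet = SHEET_3P[:6] + ["s6\tP4\tcontrol"]  # P3 lacks control, P4 lacks tumor
    mpath, spath = _write(tmp_path, _matrix_3p(lambda i, j: 8.0 + j), sheet)
    with pytest.warns(UserWarning, match="P4"):
        pset = load_paired_set(mpath, spath)
    assert pset.patients == ["P1", "P2"]


def test_duplicate_symbol_is_error(tmp_path):
    lines = _matrix_3p(lambda i, j: 8.0)
    lines.append(lines[1])  # duplicate f1
    mpath, spath = _write(tmp_path, lines, SHEET_3P)
    with pytest.raises(ValueError, match="f1"):
        load_paired_set(mpath, spath)


def test_two_tumor_samples_is_error(tmp_path):
    sheet = SHEET_3P[:6] + ["s6\tP1\ttumor"]
    mpath, spath = _write(tmp_path, _matrix_3p(lambda i, j: 8.0), sheet)
    with pytest.raises(ValueError, match="two tumor"):
        load_paired_set(mpath, spath)


def test_linear_scale_detected_and_logged(tmp_path):
    mpath, spath = _write(tmp_path, _matrix_3p(lambda i, j: 1023.0), SHEET_3P)
    with pytest.warns(UserWarning, match="log2"):
        pset = load_paired_set(mpath, spath)
    assert pset.control.to_numpy() == pytest.approx(10.0)


def test_heavily_missing_feature_dropped(tmp_path):
    lines = _matrix_3p(lambda i, j: 8.0)
    lines[1] = "f1\t8.0\t\t\t8.0\t\t"  # 4/6 missing
    mpath, spath = _write(tmp_path, lines, SHEET_3P)
    with pytest.warns(UserWarning, match="dropping 1"):
        pset = load_paired_set(mpath, spath)
    assert "f1" not in pset.symbols


def test_loading_is_order_independent(tmp_path):
    rng = np.random.default_rng(0)
    vals = rng.normal(8, 1, size=(5, 6)).round(4)
    lines = _matrix_3p(lambda i, j: vals[i - 1, j])
    mpath, spath = _write(tmp_path, lines, SHEET_3P)
    base = load_paired_set(mpath, spath)
    shuffled = [lines[0]] + [lines[i] for i in (3, 1, 5, 2, 4)]
    mpath2, spath2 = _write(tmp_path, shuffled, SHEET_3P, stem="2")
    perm = load_paired_set(mpath2, spath2)
    pd.testing.assert_frame_equal(perm.control.loc[base.symbols], base.control)
    pd.testing.assert_frame_equal(perm.tumor.loc[base.symbols], base.tumor)


def _pset(control, tumor):
    sym = [f"g{i}" for i in range(len(control))]
    pats = [f"P{j}" for j in range(len(control[0]))]
    return PairedExpressionSet(
        control=pd.DataFrame(control, index=sym, columns=pats, dtype=float),
        tumor=pd.DataFrame(tumor, index=sym, columns=pats, dtype=float))


def test_quantile_normalize_hand_example():
    """Columns [1,2,3] and [4,5,6] both become [2.5, 3.5, 4.5]."""
    pset = _pset([[1], [2], [3]], [[4], [5], [6]])
    out = quantile_normalize(pset)
    assert out.control["P0"].tolist() == [2.5, 3.5, 4.5]
    assert out.tumor["P0"].tolist() == [2.5, 3.5, 4.5]


def test_quantile_normalize_identical_columns_unchanged():
    pset = _pset([[1, 1], [5, 5], [9, 9]], [[1, 1], [5, 5], [9, 9]])
    out = quantile_normalize(pset)
    pd.testing.assert_frame_equal(out.control, pset.control)
    pd.testing.assert_frame_equal(out.tumor, pset.tumor)


def test_quantile_normalize_defining_property_and_idempotence():
    rng = np.random.default_rng(1)
    pset = _pset(rng.normal(8, 2, (30, 4)), rng.normal(8, 2, (30, 4)))
    out = quantile_normalize(pset)
    cols = pd.concat([out.control, out.tumor], axis=1).to_numpy()
    ref = np.sort(cols[:, 0])
    for j in range(cols.shape[1]):
        np.testing.assert_allclose(np.sort(cols[:, j]), ref)
        # within-column ranks preserved
        assert (np.argsort(cols[:, j]) == np.argsort(
            pd.concat([pset.control, pset.tumor], axis=1).to_numpy()[:, j])).all()
    again = quantile_normalize(out)
    np.testing.assert_allclose(again.control.to_numpy(), out.control.to_numpy(),
                               atol=1e-12)


def test_quantile_normalize_tie_handling():
    """Ties receive the mean reference value over their rank positions."""
    pset = _pset([[1], [1], [3]], [[2], [4], [6]])
    out = quantile_normalize(pset)
    ref = np.sort(np.stack([[1, 1, 3], [2, 4, 6]]), axis=1).mean(axis=0)
    assert out.control["P0"].iloc[0] == pytest.approx(ref[:2].mean())
    assert out.control["P0"].iloc[1] == pytest.approx(ref[:2].mean())


def test_write_read_round_trip_exact(tmp_path):
    rng = np.random.default_rng(2)
    pset = _pset(rng.normal(8, 1, (7, 3)), rng.normal(8, 1, (7, 3)))
    write_paired_set(pset, tmp_path / "m.tsv", tmp_path / "s.tsv")
    loaded = load_paired_set(tmp_path / "m.tsv", tmp_path / "s.tsv")
    pd.testing.assert_frame_equal(loaded.control, pset.control)
    pd.testing.assert_frame_equal(loaded.tumor, pset.tumor)


def test_misaligned_matrices_rejected():
    with pytest.raises(ValueError):
        PairedExpressionSet(
            control=pd.DataFrame(np.zeros((2, 2)), index=["a", "b"], columns=["P1", "P2"]),
            tumor=pd.DataFrame(np.zeros((2, 2)), index=["a", "c"], columns=["P1", "P2"]))
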