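"""Profile matrices, shuffle-null Z-scores, anchor grouping."""

import itertools
import warnings

import numpy as np
import pytest

from simmap.interactions import InteractionRecord
from simmap.profiles import (
    InteractionProfile,
    build_profiles,
    group_anchors,
    moiety_preferences,
    residue_zscores,
    select_top_compounds,
)
from simmap.structure import ResidueRef
from simmap.synthetic import make_planted_profile


def refs(n):
    return [ResidueRef("A", j + 1, "ALA") for j in range(n)]


def rec(cid, ref, itype, moiety="x", point=(0.0, 0.0, 0.0)):
    return InteractionRecord(cid, ref, itype, (0,), moiety, point)


# -- build_profiles ------------------------------------------------------------


def test_build_profiles_single_record():
    rs = refs(1)
    profiles = build_profiles({"c1": [rec("c1", rs[0], "H")]}, rs)
    assert profiles["H"].matrix.tolist() == [[1]]
    assert profiles["E"].matrix.tolist() == [[0]]
    assert profiles["V"].matrix.tolist() == [[0]]


def test_build_profiles_planted_pattern():
    rs = refs(2)
    records = {
        "c1": [rec("c1", rs[0], "H"), rec("c1", rs[1], "V")],
        "c2": [rec("c2", rs[1], "V")],
        "c3": [],
    }
    profiles = build_profiles(records, rs)
    assert profiles["H"].matrix.tolist() == [[1, 0], [0, 0], [0, 0]]
    assert profiles["V"].matrix.tolist() == [[0, 1], [0, 1], [0, 0]]
    assert (profiles["E"].matrix == 0).all()
    assert profiles["H"].frequencies.tolist() == [1 / 3, 0.0]


# -- select_top_compounds ------------------------------------------------------


def test_top_k_selection_and_ties():
    scores = {"a": -10.0, "b": -30.0, "c": -20.0, "d": -30.0, "e": -5.0}
    assert select_top_compounds(scores, 2) == ["b", "d"]  # tie -> lexicographic
    assert select_top_compounds(scores, 3) == ["b", "d", "c"]
    with pytest.warns(UserWarning, match="only 5"):
        assert len(select_top_compounds(scores, 10)) == 5


# -- residue_zscores -----------------------------------------------------------


def exhaustive_null(m: np.ndarray):
    """Exact null mean/sd of column frequencies over all row permutations.

    Independent oracle: enumerates the (R!)^N equally likely matrices
    obtained by permuting each row independently. Because rows are
    independent, per-column moments add across rows, so it suffices to
    enumerate R! permutations per row.
    """
    n, r = m.shape
    perms = list(itertools.permutations(range(r)))
    # per row: mean and second moment of the cell value landing in column j
    mean_rows = np.zeros((n, r))
    var_rows = np.zeros((n, r))
    for i in range(n):
        vals = np.array([[m[i, p[j]] for j in range(r)] for p in perms], dtype=float)
        mean_rows[i] = vals.mean(axis=0)
        var_rows[i] = vals.var(axis=0)
    mu = mean_rows.mean(axis=0)
    sd = np.sqrt(var_rows.sum(axis=0)) / n
    return mu, sd


def test_zscores_match_exhaustive_enumeration():
    m = np.array([[1, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=np.uint8)
    prof = InteractionProfile("H", m, [f"c{i}" for i in range(4)], refs(3))
    mu_exact, sd_exact = exhaustive_null(m)
    n_shuffles = 10_000
    stats = residue_zscores(prof, n_shuffles=n_shuffles, seed=42)
    for j, s in enumerate(stats):
        se_mu = sd_exact[j] / np.sqrt(n_shuffles)
        assert abs(s.null_mean - mu_exact[j]) <= 3 * se_mu
        se_sd = sd_exact[j] / np.sqrt(2 * n_shuffles)
        assert abs(s.null_sd - sd_exact[j]) <= 3 * se_sd
    # the dense first column must stand out
    assert stats[0].zscore > max(stats[1].zscore, stats[2].zscore)


def test_zscore_degenerate_matrices():
    ones = InteractionProfile("H", np.ones((4, 3), dtype=np.uint8), list("abcd"), refs(3))
    for s in residue_zscores(ones, n_shuffles=50, seed=0):
        assert s.degenerate and s.zscore == 0.0 and not s.significant
    zeros = InteractionProfile("H", np.zeros((4, 3), dtype=np.uint8), list("abcd"), refs(3))
    for s in residue_zscores(zeros, n_shuffles=50, seed=0):
        assert s.degenerate and s.zscore == 0.0 and not s.significant


def test_zscore_single_column_sigma_zero_path():
    m = np.array([[1], [0], [1]], dtype=np.uint8)
    prof = InteractionProfile("H", m, list("abc"), refs(1))
    (s,) = residue_zscores(prof, n_shuffles=20, seed=0)
    assert s.degenerate and s.zscore == 0.0  # f == mu when R = 1


def test_null_mean_converges_to_density(rng):
    # E[f_j] under within-row shuffles = mean row density, every column
    m = (rng.random((30, 6)) < 0.3).astype(np.uint8)
    prof = InteractionProfile("V", m, [f"c{i}" for i in range(30)], refs(6))
    stats = residue_zscores(prof, n_shuffles=10_000, seed=9)
    expected = m.mean()  # (sum_i rowsum_i / R) / N
    for s in stats:
        se = s.null_sd / np.sqrt(10_000)
        assert abs(s.null_mean - expected) <= max(3 * se, 1e-12)


def test_row_sums_conserved_under_shuffle(rng):
    # the null permutes within rows, so every shuffle preserves row sums
    m = (rng.random((10, 5)) < 0.4).astype(np.uint8)
    perm = np.argsort(rng.random((20, 10, 5)), axis=2)
    shuffled = np.take_along_axis(np.broadcast_to(m, (20, 10, 5)), perm, axis=2)
    np.testing.assert_array_equal(
        shuffled.sum(axis=2), np.broadcast_to(m.sum(axis=1), (20, 10))
    )


def test_planted_columns_significant():
    prof = make_planted_profile(200, 12, hot_columns=[1, 5, 9], p_hot=0.8, p_bg=0.1, seed=3)
    stats = residue_zscores(prof, n_shuffles=1000, seed=3)
    sig = {j for j, s in enumerate(stats) if s.significant}
    assert sig == {1, 5, 9}


# -- group_anchors & moiety_preferences ---------------------------------------


def stat(ref, itype, significant=True):
    from simmap.profiles import ResidueStatistic

    return ResidueStatistic(ref, itype, 0.5, 0.1, 0.05, 8.0 if significant else 0.0,
                            significant)


def test_close_residues_merge_into_one_anchor():
    rs = refs(2)
    records = [
        rec("c1", rs[0], "H", point=(0.0, 0.0, 0.0)),
        rec("c1", rs[1], "H", point=(2.0, 0.0, 0.0)),
    ]
    anchors = group_anchors({"H": [stat(rs[0], "H"), stat(rs[1], "H")]}, records)
    assert len(anchors) == 1
    assert anchors[0].itype == "H" and len(anchors[0].residues) == 2
    np.testing.assert_allclose(anchors[0].centroid, (1.0, 0.0, 0.0))


def test_distant_residues_stay_separate_anchors():
    rs = refs(2)
    records = [
        rec("c1", rs[0], "V", point=(0.0, 0.0, 0.0)),
        rec("c1", rs[1], "V", point=(10.0, 0.0, 0.0)),
    ]
    anchors = group_anchors({"V": [stat(rs[0], "V"), stat(rs[1], "V")]}, records)
    assert [a.anchor_id for a in anchors] == ["V1", "V2"]


def test_same_residue_e_and_h_merge_to_eh():
    rs = refs(1)
    records = [
        rec("c1", rs[0], "E", point=(0.0, 0.0, 0.0)),
        rec("c1", rs[0], "H", point=(0.5, 0.0, 0.0)),
    ]
    anchors = group_anchors(
        {"E": [stat(rs[0], "E")], "H": [stat(rs[0], "H")]}, records
    )
    assert len(anchors) == 1
    assert anchors[0].itype == "EH"
    assert anchors[0].anchor_id == "EH1"


def test_no_significant_residues_warns_empty():
    rs = refs(1)
    with pytest.warns(UserWarning, match="no significant"):
        anchors = group_anchors({"H": [stat(rs[0], "H", significant=False)]}, [])
    assert anchors == []


def test_group_anchors_invariant_to_residue_order():
    rs = refs(3)
    records = [
        rec("c1", rs[0], "V", point=(0.0, 0.0, 0.0)),
        rec("c1", rs[1], "V", point=(1.0, 0.0, 0.0)),
        rec("c1", rs[2], "V", point=(9.0, 0.0, 0.0)),
    ]
    stats = [stat(r, "V") for r in rs]
    a1 = group_anchors({"V": stats}, records, pocket_order=rs)
    a2 = group_anchors({"V": stats[::-1]}, records, pocket_order=rs)
    sets1 = {frozenset(r.key for r in a.residues) for a in a1}
    sets2 = {frozenset(r.key for r in a.residues) for a in a2}
    assert sets1 == sets2


def test_moiety_preference_counting():
    rs = refs(1)
    anchors = group_anchors({"V": [stat(rs[0], "V")]}, [rec("c1", rs[0], "V")])
    records = [
        rec("c1", rs[0], "V", moiety="aromatic ring"),
        rec("c2", rs[0], "V", moiety="aromatic ring"),
        rec("c3", rs[0], "V", moiety="alcohol"),
    ]
    prefs = moiety_preferences(anchors[0], records, ["c1", "c2", "c3"])
    assert prefs == [("aromatic ring", pytest.approx(2 / 3)), ("alcohol", pytest.approx(1 / 3))]
    # anchor with no interacting compounds -> empty list
    assert moiety_preferences(anchors[0], [], ["c1"]) == []
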