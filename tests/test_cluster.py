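"""Fingerprint clustering and anchor conservation averaging."""

import numpy as np
import pytest

from simmap.cluster import (
    anchor_conservation,
    centroid_cluster,
    cut_clusters,
    novelty_report,
    pearson_distance,
    read_conservation_table,
)
from simmap.moieties import MoietyFingerprint
from simmap.profiles import Anchor
from simmap.structure import ResidueRef


def fp(cid, on_bits):
    bits = [0] * 90
    for b in on_bits:
        bits[b] = 1
    return MoietyFingerprint(cid, tuple(bits), "simmap-90.v1")


def analog_families(rng, n_members=10):
    """Two planted families with high within- and low across-family overlap."""
    support = {0: list(range(0, 20)), 1: list(range(25, 45))}
    shared = [60, 61]  # small across-family overlap
    fps, labels = [], {}
    for fam in (0, 1):
        for m in range(n_members):
            on = [b for b in support[fam] if rng.random() < 0.9] + [
                b for b in shared if rng.random() < 0.5
            ]
            cid = f"f{fam}m{m}"
            fps.append(fp(cid, on))
            labels[cid] = fam
    return fps, labels


def test_pearson_distance_identical_and_complementary():
    a = fp("a", range(10))
    b = fp("b", range(10))
    d = pearson_distance([a, b]).d
    assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
    # complementary vectors: r = -1, d = 2
    c = fp("c", range(0, 45))
    e = fp("e", range(45, 90))
    d2 = pearson_distance([c, e]).d
    assert d2[0, 1] == pytest.approx(2.0)


def test_pearson_distance_matches_textbook_formula(rng):
    x = rng.integers(0, 2, 90)
    y = rng.integers(0, 2, 90)
    a = fp("a", np.nonzero(x)[0])
    b = fp("b", np.nonzero(y)[0])
    r = np.sum((x - x.mean()) * (y - y.mean())) / (
        np.sqrt(np.sum((x - x.mean()) ** 2)) * np.sqrt(np.sum((y - y.mean()) ** 2))
    )
    assert pearson_distance([a, b]).d[0, 1] == pytest.approx(1 - r)


def test_distance_matrix_validity(rng):
    fps, _ = analog_families(rng, 5)
    dm = pearson_distance(fps)
    assert np.allclose(dm.d, dm.d.T)
    assert np.allclose(np.diag(dm.d), 0.0)
    assert dm.d.min() >= 0.0 and dm.d.max() <= 2.0


def test_zero_variance_fingerprint_rejected():
    with pytest.raises(ValueError, match="allon"):
        pearson_distance([fp("allon", range(90)), fp("b", range(10))])


def test_two_items_single_merge():
    tree = centroid_cluster([fp("a", range(5)), fp("b", range(3, 9))])
    assert tree.merges.shape == (1, 4)


def test_identical_pair_merges_first():
    fps = [fp("a", range(10)), fp("b", range(10)), fp("c", range(40, 80))]
    tree = centroid_cluster(fps)
    first = sorted(int(i) for i in tree.merges[0, :2])
    assert [tree.ids[i] for i in first] == ["a", "b"]
    assert tree.merges[0, 2] == pytest.approx(0.0)


def test_planted_families_recovered_at_k2(rng):
    fps, labels = analog_families(rng)
    tree = centroid_cluster(fps)
    assignment = cut_clusters(tree, k=2)
    by_cluster: dict[int, set] = {}
    for cid, lab in assignment.items():
        by_cluster.setdefault(lab, set()).add(labels[cid])
    assert all(len(fams) == 1 for fams in by_cluster.values())
    assert len(by_cluster) == 2


def test_first_merges_are_within_family(rng):
    fps, labels = analog_families(rng, n_members=3)
    tree = centroid_cluster(fps)
    n = tree.n_leaves

    def leaf_family(node_id, memo={}):
        if node_id < n:
            return {labels[tree.ids[node_id]]}
        row = tree.merges[node_id - n]
        return leaf_family(int(row[0])) | leaf_family(int(row[1]))

    for k in range(4):  # first merges join same-family members
        a, b = int(tree.merges[k, 0]), int(tree.merges[k, 1])
        assert len(leaf_family(a) | leaf_family(b)) == 1


def test_cut_extremes_and_errors(rng):
    fps, _ = analog_families(rng, 3)
    tree = centroid_cluster(fps)
    assert len(set(cut_clusters(tree, k=1).values())) == 1
    allsing = cut_clusters(tree, k=tree.n_leaves)
    assert len(set(allsing.values())) == tree.n_leaves
    with pytest.raises(ValueError):
        cut_clusters(tree, k=tree.n_leaves + 1)
    with pytest.raises(ValueError):
        cut_clusters(tree)


def test_clustering_invariant_to_input_order(rng):
    fps, _ = analog_families(rng)
    t1 = centroid_cluster(fps)
    t2 = centroid_cluster(fps[::-1])
    assert t1.ids == t2.ids
    np.testing.assert_allclose(t1.merges, t2.merges)


def test_newick_export_has_all_leaves(rng):
    fps, _ = analog_families(rng, 4)
    tree = centroid_cluster(fps)
    nwk = tree.to_newick()
    assert nwk.endswith(";")
    for cid in tree.ids:
        assert cid in nwk


def test_novelty_report_flags_singletons(rng):
    fps, _ = analog_families(rng, 4)
    fps.append(fp("query", [70, 75, 80, 85]))  # unlike either family
    tree = centroid_cluster(fps)
    assignment = cut_clusters(tree, k=3)
    report = novelty_report(assignment, ["query"])
    assert report["query"]["novel"]


def _anchor(aid, ns):
    return Anchor(aid, "V", [ResidueRef("A", n, "ALA") for n in ns], (0.0, 0.0, 0.0))


def test_anchor_conservation_means():
    table = {"A:1": 9, "A:2": 9, "A:3": 7, "A:4": 1, "A:5": 2, "A:6": 5}
    cons = anchor_conservation(
        [_anchor("EH1", [1, 2]), _anchor("V5", [3, 1, 2]), _anchor("V4", [4, 5, 6])],
        table,
    )
    assert cons["EH1"] == 9.0
    assert cons["V5"] == 8.3  # (7+9+9)/3
    assert cons["V4"] == 2.7  # (1+2+5)/3
    # single-residue anchor equals its own grade
    assert anchor_conservation([_anchor("x", [3])], table)["x"] == 7.0


def test_anchor_conservation_errors():
    with pytest.raises(ValueError, match="missing"):
        anchor_conservation([_anchor("a", [99])], {"A:1": 5})
    with pytest.raises(ValueError, match="range"):
        anchor_conservation([_anchor("a", [1])], {"A:1": 12})


def test_conservation_table_io(tmp_path):
    p = tmp_path / "grades.tsv"
    p.write_text("residue\tgrade\nA:368\t9\nA:373\t9\n")
    assert read_conservation_table(p) == {"A:368": 9, "A:373": 9}
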