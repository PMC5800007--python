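"""RF distances, pruning, ultrametricization, node depths, depth bias."""

import numpy as np
import pytest

from mscsampling import (
    SampleMap,
    bipartition_set,
    depth_bias,
    make_ultrametric,
    one_tip_per_taxon,
    read_newick,
    relative_node_depths,
    rf_distance,
    rf_matrix,
    root_at_midpoint,
    write_newick,
)
from mscsampling.comparison import prune_to_tips
from mscsampling.errors import InputError
from mscsampling.trees import tip_distance_matrix, unrooted_copy

from conftest import random_tree


def dendropy_rf(t1, t2) -> int:
    """Independent oracle via dendropy's symmetric difference."""
    import dendropy

    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=write_newick(t1), schema="newick", taxon_namespace=tns)
    d2 = dendropy.Tree.get(data=write_newick(t2), schema="newick", taxon_namespace=tns)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(d1, d2)


class TestRfDistance:
    def test_identical_and_nni_neighbor(self):
        t1 = read_newick("(((A,B),C),(D,E));")
        assert rf_distance(t1, read_newick("(((A,B),C),(D,E));")) == 0
        assert rf_distance(t1, read_newick("(((A,C),B),(D,E));")) == 2

    def test_tip_mismatch_lists_difference(self):
        with pytest.raises(InputError, match="X"):
            rf_distance(read_newick("((A,B),(C,D));"), read_newick("((A,B),(C,X));"))

    def test_matches_dendropy_on_random_pairs(self):
        rng = np.random.default_rng(13)
        labels = [f"t{i}" for i in range(8)]
        for _ in range(60):
            t1, t2 = random_tree(labels, rng), random_tree(labels, rng)
            assert rf_distance(t1, t2) == dendropy_rf(t1, t2)

    def test_metric_properties(self):
        rng = np.random.default_rng(29)
        labels = [f"t{i}" for i in range(7)]
        for _ in range(25):
            a, b, c = (random_tree(labels, rng) for _ in range(3))
            assert rf_distance(a, a) == 0
            assert rf_distance(a, b) == rf_distance(b, a)
            assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)

    def test_rf_matrix_symmetric_and_consistent(self):
        rng = np.random.default_rng(3)
        labels = [f"t{i}" for i in range(6)]
        trees = [(f"m{i}", random_tree(labels, rng)) for i in range(4)]
        mat = rf_matrix(trees)
        assert (mat.values == mat.values.T).all()
        assert (np.diag(mat.values) == 0).all()
        assert mat.loc["m1", "m3"] == rf_distance(trees[1][1], trees[3][1])
        perm = rf_matrix(trees[::-1])
        assert perm.loc["m1", "m3"] == mat.loc["m1", "m3"]


def sample_map_for(tips_per_taxon: dict) -> SampleMap:
    haps = {}
    for taxon, tips in tips_per_taxon.items():
        for k in range(0, len(tips), 2):
            ind = f"{taxon}_i{k//2}"
            for tip in tips[k : k + 2]:
                haps[tip] = (ind, f"{taxon}_L1", taxon)
    return SampleMap(haps)


class TestOneTipPerTaxon:
    def test_relabel_only_when_one_tip_each(self):
        t = read_newick("((x1:1,y1:2):1,(z1:1,w1:1):2);")
        sm = sample_map_for({"X": ["x1", "y1"], "Z": ["z1", "w1"]})
        # one tip per taxon requires taxa with single candidates
        sm2 = SampleMap(
            {
                "x1": ("iX", "LX", "X"),
                "y1": ("iX", "LX", "Y"),
                "z1": ("iZ", "LZ", "Z"),
                "w1": ("iZ", "LZ", "W"),
            }
        )
        out = one_tip_per_taxon(t, sm2, seed=0)
        assert sorted(out.tip_labels()) == ["W", "X", "Y", "Z"]
        assert rf_distance(out, read_newick("((X,Y),(W,Z));")) == 0

    def test_choice_frequencies_uniform(self):
        t = read_newick("(((a1:1,a2:2):1,a3:4):1,b1:3);")
        sm = SampleMap(
            {
                "a1": ("ia1", "LA", "A"),
                "a2": ("ia1", "LA", "A"),
                "a3": ("ia2", "LA", "A"),
                "a4": ("ia2", "LA", "A"),
                "b1": ("ib", "LB", "B"),
                "b2": ("ib", "LB", "B"),
            }
        )
        counts = {"a1": 0, "a2": 0, "a3": 0}
        for seed in range(900):
            out = one_tip_per_taxon(t, sm, seed=seed)
            # which original tip became "A"? identify by distance to B
            (chosen,) = [c for c in counts if c in write_newick_keep(t, out)]
            counts[chosen] += 1
        assert all(abs(v / 900 - 1 / 3) < 0.06 for v in counts.values())

    def test_path_lengths_preserved(self):
        rng = np.random.default_rng(17)
        t = random_tree([f"s{i}" for i in range(8)], rng)
        keep = ["s0", "s3", "s5", "s7"]
        pruned = prune_to_tips(t, keep)
        la, da = tip_distance_matrix(t)
        lb, db = tip_distance_matrix(pruned)
        for i, x in enumerate(keep):
            for j, y in enumerate(keep):
                assert db[lb.index(x), lb.index(y)] == pytest.approx(
                    da[la.index(x), la.index(y)]
                )

    def test_taxon_without_tips_errors(self):
        t = read_newick("((a1,a2),b1);")
        sm = SampleMap(
            {
                "a1": ("ia", "LA", "A"),
                "a2": ("ia", "LA", "A"),
                "c1": ("ic", "LC", "C"),
                "c2": ("ic", "LC", "C"),
            }
        )
        with pytest.raises(InputError, match="C"):
            one_tip_per_taxon(t, sm, seed=0)


def write_newick_keep(original, reduced):
    """Helper: which original 'a' tip survived, by matching distance to b1."""
    la, da = tip_distance_matrix(original)
    lb, db = tip_distance_matrix(reduced)
    d_ab = db[lb.index("A"), lb.index("B")]
    for cand in ("a1", "a2", "a3"):
        if abs(da[la.index(cand), la.index("b1")] - d_ab) < 1e-9:
            return cand
    raise AssertionError("no matching tip")


class TestUltrametric:
    def test_fixed_point_on_ultrametric_input(self):
        t = read_newick("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")
        out = make_ultrametric(t)
        _, d1 = tip_distance_matrix(t)
        _, d2 = tip_distance_matrix(out)
        assert np.allclose(d1, d2, atol=1e-12)

    def test_two_tip_mean(self):
        out = make_ultrametric(read_newick("(A:1,B:3);"))
        assert out.max_height() == pytest.approx(2.0)
        assert out.is_ultrametric()

    def test_root_height_is_least_squares_optimal(self):
        """The smoothed root height minimizes the squared tip-depth distortion
        (it is the mean of the original root-to-tip path lengths)."""
        rng = np.random.default_rng(23)
        for _ in range(20):
            t = random_tree([f"x{i}" for i in range(6)], rng)
            out = make_ultrametric(t)
            assert out.is_ultrametric(rel_tol=1e-9)
            depths = []

            def walk(node, d):
                if node.is_leaf:
                    depths.append(d)
                for c in node.children:
                    walk(c, d + (c.length or 0.0))

            walk(t.root, 0.0)
            h = out.max_height()
            assert h == pytest.approx(np.mean(depths))
            base = sum((h - d) ** 2 for d in depths)
            for other in np.linspace(min(depths), max(depths), 7):
                assert base <= sum((other - d) ** 2 for d in depths) + 1e-9

    def test_missing_lengths_rejected(self):
        with pytest.raises(InputError):
            make_ultrametric(read_newick("((A,B),C);"))


class TestNodeDepths:
    def test_cherry_depth_and_scale_invariance(self):
        t = read_newick("(((A:1,B:1):1,C:2):2,(D:3,E:3):1);")
        depths = relative_node_depths(t)
        from mscsampling import Bipartition

        rest = {"C", "D", "E"}
        assert depths[Bipartition({"A", "B"}, rest)] == pytest.approx(0.25)
        scaled = t.copy()
        for n in scaled.nodes():
            if n.length is not None:
                n.length *= 7.5
        assert relative_node_depths(scaled) == pytest.approx(depths)

    def test_non_ultrametric_rejected(self):
        with pytest.raises(InputError, match="deviation"):
            relative_node_depths(read_newick("((A:1,B:5):1,C:9);"))


class TestMidpointRoot:
    def test_recovers_clock_root(self):
        t = read_newick("((A:1,B:1):2,(C:2,D:2):1);")
        unrooted = unrooted_copy(t)
        rerooted = root_at_midpoint(unrooted)
        assert rerooted.is_ultrametric(rel_tol=1e-9)
        assert bipartition_set(rerooted) == bipartition_set(t)

    def test_distances_preserved(self):
        rng = np.random.default_rng(41)
        t = unrooted_copy(random_tree([f"m{i}" for i in range(7)], rng))
        r = root_at_midpoint(t)
        la, da = tip_distance_matrix(t)
        lb, db = tip_distance_matrix(r)
        idx = [lb.index(l) for l in la]
        assert np.allclose(db[np.ix_(idx, idx)], da, atol=1e-9)


class TestDepthBias:
    def test_self_comparison_is_zero(self):
        t = read_newick("((A:1,B:1):3,((C:2,D:2):1,E:3):1);")
        sm = SampleMap(
            {
                f"{x.lower()}{h}": (f"i{x}", f"L{x}", x)
                for x in "ABCDE"
                for h in (1, 2)
            }
        )
        result = depth_bias(t, t, samples=None, tree_a_id="x", tree_b_id="x")
        assert len(result.table) == 2
        assert np.allclose(result.table["bias"], 0.0, atol=1e-12)

    def test_uniform_scaling_has_zero_bias(self):
        t = read_newick("((A:1,B:1):3,((C:2,D:2):1,E:3):1);")
        doubled = t.copy()
        for n in doubled.nodes():
            if n.length is not None:
                n.length *= 2
        result = depth_bias(t, doubled)
        assert np.allclose(result.table["bias"], 0.0, atol=1e-12)

    def test_warns_on_disjoint_topologies(self):
        a = read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        b = read_newick("((A:1,C:1):1,(B:1,D:1):1);")
        with pytest.warns(UserWarning, match="shared"):
            result = depth_bias(a, b)
        assert result.table.empty
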