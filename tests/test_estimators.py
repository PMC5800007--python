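"""Distance/NJ estimation, quartet machinery, bootstrap support, theta."""

import itertools

import numpy as np
import pytest

from mscsampling import (
    Alignment,
    ClockModel,
    Locus,
    Treatment,
    assign_alleles,
    bipartition_set,
    build_quartet_table,
    coalescent_branch_lengths,
    concatenation_tree,
    estimate_gene_trees,
    jc_distance_matrix,
    multilocus_bootstrap_support,
    neighbor_joining,
    per_taxon_theta,
    quartet_species_tree,
    read_newick,
    rf_distance,
    simulate_gene_tree,
)
from mscsampling._seeds import spawn_rng
from mscsampling.errors import InputError, SizingError
from mscsampling.estimators import DistanceMatrix, QuartetTable, score_topology
from mscsampling.trees import tip_distance_matrix

from conftest import haploid_sample_map, random_tree, species_model_from_newick


def dm_from_tree(tree) -> DistanceMatrix:
    labels, d = tip_distance_matrix(tree)
    return DistanceMatrix(labels, d, np.ones_like(d), np.zeros_like(d, bool))


class TestJcDistance:
    def test_identical_sequences(self):
        aln = Alignment.from_records([("a", "ACGT" * 10), ("b", "ACGT" * 10)])
        assert jc_distance_matrix(aln).d[0, 1] == 0.0

    def test_p_ten_percent(self):
        seq_a = "A" * 100
        seq_b = "C" * 10 + "A" * 90
        dm = jc_distance_matrix(Alignment.from_records([("a", seq_a), ("b", seq_b)]))
        assert dm.d[0, 1] == pytest.approx(-0.75 * np.log(1 - 0.4 / 3), abs=1e-9)
        assert dm.d[0, 1] == pytest.approx(0.1073, abs=1e-4)

    def test_saturation_capped_and_flagged(self):
        dm = jc_distance_matrix(
            Alignment.from_records([("a", "ACGT"), ("b", "CAAC")])
        )
        assert dm.saturated[0, 1]
        assert dm.d[0, 1] == 5.0

    def test_pairwise_deletion_and_empty_overlap(self):
        aln = Alignment.from_records([("a", "AC--"), ("b", "--GT"), ("c", "ACGT")])
        with pytest.raises(InputError, match="'a' and 'b'"):
            jc_distance_matrix(aln)


class TestNeighborJoining:
    def test_three_taxon_analytic(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float)
        dm = DistanceMatrix(["a", "b", "c"], d, np.ones_like(d), np.zeros_like(d, bool))
        t = neighbor_joining(dm)
        _, dd = tip_distance_matrix(t)
        assert np.allclose(dd, d)

    def test_exact_on_additive_matrices(self):
        rng = np.random.default_rng(11)
        for n in (5, 6, 8):
            for _ in range(10):
                true = random_tree([f"t{i}" for i in range(n)], rng)
                est = neighbor_joining(dm_from_tree(true))
                assert bipartition_set(est) == bipartition_set(true)
                la, da = tip_distance_matrix(true)
                lb, db = tip_distance_matrix(est)
                idx = [lb.index(l) for l in la]
                assert np.allclose(db[np.ix_(idx, idx)], da, atol=1e-9)

    def test_negative_lengths_clamped(self):
        d = np.array(
            [[0, 1, 6, 6], [1, 0, 6, 6], [6, 6, 0, 1], [6, 6, 1, 0]], float
        )
        d[0, 1] = 0.01  # near-zero cherry promotes a negative limb estimate
        d[1, 0] = 0.01
        dm = DistanceMatrix(list("abcd"), d, np.ones_like(d), np.zeros_like(d, bool))
        t = neighbor_joining(dm)
        assert all((n.length or 0) >= 0 for n in t.nodes())


class TestGeneTreeEstimation:
    def test_bootstrap_count_and_degenerate_flag(self):
        aln = Alignment.from_records(
            [(f"s{i}", "ACGT" * 25) for i in range(4)], frame=None
        )
        ests = estimate_gene_trees([Locus("L", aln)], bootstrap_replicates=7, seed=1)
        assert len(ests["L"].bootstraps) == 7
        assert ests["L"].degenerate

    def test_recovers_true_gene_tree_on_clean_data(self, small_study):
        from mscsampling import SubstitutionModel, simulate_alignment

        model = species_model_from_newick(
            "((A:2000000,B:2000000):2000000,(C:2000000,D:2000000):2000000);", 1000.0
        )
        sm = haploid_sample_map(["A", "B", "C", "D"]).subset(
            ["A_i0_h0", "B_i0_h0", "C_i0_h0", "D_i0_h0"]
        )
        from mscsampling import scale_to_substitutions

        gt = simulate_gene_tree(model, sm, seed=4)
        scaled, _ = scale_to_substitutions(gt, ClockModel(mu=1e-8, rate_sd=0.0), seed=0)
        aln = simulate_alignment(scaled, SubstitutionModel(), 2000, seed=5)
        ests = estimate_gene_trees([Locus("L", aln)], bootstrap_replicates=0, seed=0)
        assert rf_distance(ests["L"].tree, gt) == 0


def brute_force_quartet_table(gene_trees, allele_to_taxon) -> dict:
    """Independent oracle: enumerate every allele combination and resolve each
    quartet by bipartition containment, not by path distances."""
    taxa = sorted(set(allele_to_taxon.values()))
    out = {q: np.zeros(3) for q in itertools.combinations(taxa, 4)}
    for tree in gene_trees:
        labels = tree.tip_labels()
        splits = bipartition_set(tree)
        by_taxon = {}
        for lab in labels:
            by_taxon.setdefault(allele_to_taxon[lab], []).append(lab)
        for q in out:
            if not all(t in by_taxon for t in q):
                continue
            combos = list(itertools.product(*(by_taxon[t] for t in q)))
            w = 1.0 / len(combos)
            for combo in combos:
                a, b, c, d = combo
                res = None
                for pair_idx, (x, y) in enumerate(((a, b), (a, c), (a, d))):
                    rest = [z for z in combo if z not in (x, y)]
                    for s in splits:
                        if (
                            {x, y} <= s.side_a and set(rest) <= s.side_b
                        ) or ({x, y} <= s.side_b and set(rest) <= s.side_a):
                            res = pair_idx
                            break
                    if res is not None:
                        break
                if res is not None:
                    out[q][res] += w
    return out


class TestQuartetTable:
    def test_single_tree_single_allele(self):
        t = read_newick("((A,B),(C,D));")
        qt = build_quartet_table([t], {x: x for x in "ABCD"})
        assert qt.weights[("A", "B", "C", "D")].tolist() == [1.0, 0.0, 0.0]

    def test_two_alleles_grouped_by_taxon(self):
        t = read_newick("((a1,a2),((b1,b2),((c1,c2),(d1,d2))));")
        mapping = {f"{x}{i}": x.upper() for x in "abcd" for i in (1, 2)}
        qt = build_quartet_table([t], mapping)
        w = qt.weights[("A", "B", "C", "D")]
        assert w.sum() == pytest.approx(1.0)
        assert w[0] == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        taxa = list("ABCDEF")
        mapping = {f"{t}{i}": t for t in taxa for i in (1, 2)}
        labels = list(mapping)
        for _ in range(5):
            trees = [random_tree(labels, rng) for _ in range(4)]
            qt = build_quartet_table(trees, mapping)
            oracle = brute_force_quartet_table(trees, mapping)
            for q in oracle:
                assert np.allclose(qt.weights[q], oracle[q], atol=1e-9), q

    def test_unmapped_tip_named(self):
        t = read_newick("((A,B),(C,D));")
        with pytest.raises(InputError, match="'D'"):
            build_quartet_table([t], {"A": "A", "B": "B", "C": "C"})


class TestQuartetSpeciesTree:
    def test_unanimous_gene_trees_recovered_with_full_score(self):
        t = read_newick("(((A,B),C),((D,E),F));")
        qt = build_quartet_table([t] * 5, {x: x for x in "ABCDEF"})
        tree, score = quartet_species_tree(qt, search="exact")
        assert rf_distance(tree, t) == 0
        assert score == pytest.approx(1.0)

    def test_nni_matches_exact_on_random_weights(self):
        rng = np.random.default_rng(31)
        taxa = [f"t{i}" for i in range(7)]
        equal = 0
        trials = 12
        for trial in range(trials):
            qt = QuartetTable(taxa)
            for q in qt.weights:
                w = rng.dirichlet([1, 1, 1]) * rng.uniform(5, 10)
                qt.weights[q] = w
            exact_tree, exact_score = quartet_species_tree(qt, search="exact")
            nni_tree, nni_score = quartet_species_tree(qt, search="nni", seed=trial)
            assert nni_score <= exact_score + 1e-9
            equal += abs(nni_score - exact_score) < 1e-9
        assert equal >= int(0.9 * trials)

    def test_exact_search_size_limit(self):
        qt = QuartetTable([f"t{i}" for i in range(10)])
        with pytest.raises(SizingError):
            quartet_species_tree(qt, search="exact")


class TestCoalescentBranchLengths:
    def test_full_discordance_gives_zero(self):
        qt = QuartetTable(list("ABCD"))
        qt.weights[("A", "B", "C", "D")] = np.array([1.0, 1.0, 1.0])
        topo = read_newick("((A,B),(C,D));")
        cu = coalescent_branch_lengths(topo, qt)
        internal = [n for n in cu.nodes() if not n.is_leaf and n is not cu.root]
        assert internal[0].length == 0.0

    def test_unanimous_support_capped(self):
        qt = QuartetTable(list("ABCD"))
        qt.weights[("A", "B", "C", "D")] = np.array([9.0, 0.0, 0.0])
        cu = coalescent_branch_lengths(read_newick("((A,B),(C,D));"), qt)
        internal = [n for n in cu.nodes() if not n.is_leaf and n is not cu.root]
        assert internal[0].length == pytest.approx(10.0)
        assert cu.length_units == "coalescent_units"

    @pytest.mark.parametrize("tau", [0.5, 2.0])
    def test_inverts_known_internal_branch(self, tau):
        ne = 10000.0
        t_ab = 2 * ne
        t_int = tau * 2 * ne
        nwk = (
            f"((A:{t_ab},B:{t_ab}):{t_int},"
            f"(C:{t_ab},D:{t_ab}):{t_int});"
        )
        model = species_model_from_newick(nwk, ne)
        sm = haploid_sample_map(list("ABCD")).subset(
            [f"{x}_i0_h0" for x in "ABCD"]
        )
        rng = spawn_rng(55)
        trees = [simulate_gene_tree(model, sm, rng=rng) for _ in range(3000)]
        qt = build_quartet_table(trees, {f"{x}_i0_h0": x for x in "ABCD"})
        topo, _ = quartet_species_tree(qt, search="exact")
        cu = coalescent_branch_lengths(topo, qt)
        internal = [n for n in cu.nodes() if not n.is_leaf and n is not cu.root]
        # the split spans two internal branches of tau each
        est = sum(n.length for n in internal)
        p = 1 - (2 / 3) * np.exp(-2 * tau)
        se_p = np.sqrt(p * (1 - p) / 3000)
        tol = 3 * se_p / (1.5 * (1 - p))  # delta method on -ln(1.5(1-p))
        assert est == pytest.approx(2 * tau, abs=max(tol, 0.05))


class TestConcatenationAndBootstrap:
    def test_single_locus_equals_gene_tree(self, small_study):
        locus = small_study.loci[0]
        labels = locus.labels()
        concat = concatenation_tree([locus], labels)
        gene = estimate_gene_trees([locus], bootstrap_replicates=0, seed=0)[locus.id].tree
        assert rf_distance(concat, gene) == 0

    def test_pairwise_deletion_on_disjoint_blocks(self):
        aln1 = Alignment.from_records([("a", "AAAA"), ("b", "AAAA"), ("c", "AANN")])
        aln2 = Alignment.from_records([("a", "CCCC"), ("b", "NNCC"), ("c", "CCCC")])
        loci = [Locus("l1", aln1), Locus("l2", aln2)]
        from mscsampling.estimators import concatenated_alignment

        cat = concatenated_alignment(loci, ["a", "b", "c"])
        dm = jc_distance_matrix(cat)
        # brute-force per-pair site counts over jointly non-missing columns
        assert dm.comparable[0, 1] == 6 and dm.comparable[0, 2] == 6
        assert dm.comparable[1, 2] == 4
        assert np.all(dm.d == 0.0)

    def test_identical_signal_gives_full_support(self, small_study):
        loci = small_study.loci[:3]
        labels = sorted(set(loci[0].labels()))
        # three copies of the same locus: every replicate sees the same signal
        clones = [Locus(f"c{i}", loci[0].alignment) for i in range(3)]
        point, support = multilocus_bootstrap_support(
            clones, estimator="concatenation", replicates=25, seed=3, labels=labels
        )
        assert len(support) > 0
        assert all(v == 1.0 for v in support.values())


class TestTheta:
    def test_identical_haplotypes_give_zero(self):
        aln = Alignment.from_records([("x_h0", "ACGT" * 5), ("x_h1", "ACGT" * 5)])
        from mscsampling import AlleleAssignment

        asn = AlleleAssignment(
            Treatment.ONE_SAMPLE, 0, {"tx": ("x_h0", "x_h1")}, {"tx": []}
        )
        assert per_taxon_theta([Locus("L", aln)], asn) == {"tx": 0.0}

    def test_panmictic_expectation_4_ne_mu(self):
        """E[theta] = 4*Ne*mu for two haplotypes from one population."""
        from mscsampling import (
            AlleleAssignment,
            SubstitutionModel,
            scale_to_substitutions,
            simulate_alignment,
        )
        from conftest import one_population_model

        ne, mu = 100000.0, 1e-8
        model = one_population_model(ne)
        sm = haploid_sample_map(["P"]).subset(["P_i0_h0", "P_i0_h1"])
        rng = spawn_rng(77)
        loci = []
        for i in range(120):
            gt = simulate_gene_tree(model, sm, rng=rng)
            scaled, _ = scale_to_substitutions(gt, ClockModel(mu=mu, rate_sd=0.0), seed=0)
            aln = simulate_alignment(scaled, SubstitutionModel(kappa=1.0), 900, rng=rng)
            loci.append(Locus(f"L{i}", aln))
        asn = AlleleAssignment(
            Treatment.ONE_SAMPLE, 0, {"pop": ("P_i0_h0", "P_i0_h1")}, {"pop": []}
        )
        theta = per_taxon_theta(loci, asn)["pop"]
        # per-locus theta has sd ~ theta (exponential TMRCA dominates)
        expected = 4 * ne * mu
        assert abs(theta - expected) < 3.5 * expected / np.sqrt(120)

    def test_missing_haplotype_named(self):
        aln = Alignment.from_records([("x_h0", "AAAA"), ("y_h0", "AAAA")])
        from mscsampling import AlleleAssignment

        asn = AlleleAssignment(
            Treatment.ONE_SAMPLE, 0, {"tz": ("z_h0", "z_h1")}, {"tz": []}
        )
        with pytest.raises(InputError, match="tz"):
            per_taxon_theta([Locus("L", aln)], asn)
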