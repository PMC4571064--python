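"""Gene-genealogy simulation within species trees and networks."""

import math

import numpy as np
import pytest

from netcoal import (
    KINGMAN,
    GeneTreeNode,
    ValidationError,
    assign_branch_attributes,
    convert_units,
    parse_network,
    rescale_tree,
    route_at_hybrid,
    simulate_gene_tree,
    simulate_within_branch,
    write_newick,
)


def _tips(n):
    return [GeneTreeNode(label=f"a_{i+1}") for i in range(n)]


class TestWithinBranch:
    def test_single_lineage_passes_through(self, rng):
        (tip,) = _tips(1)
        out, events = simulate_within_branch([tip], 5.0, KINGMAN, rng)
        assert out == [tip] and events == []

    def test_zero_duration_is_identity(self, rng):
        tips = _tips(6)
        out, events = simulate_within_branch(tips, 0.0, KINGMAN, rng)
        assert out == tips and events == []

    def test_pairwise_coalescence_time_mean_one(self, rng):
        times = []
        for _ in range(10_000):
            out, _ = simulate_within_branch(_tips(2), math.inf, KINGMAN, rng)
            times.append(out[0].height)
        mean = np.mean(times)
        se = np.std(times, ddof=1) / np.sqrt(len(times))
        assert abs(mean - 1.0) <= 3 * se

    def test_censoring_hands_survivors_to_parent(self, rng):
        # a very short branch almost never coalesces 2 lineages
        out, _ = simulate_within_branch(_tips(2), 1e-9, KINGMAN, rng)
        assert len(out) == 2


class TestHybridRouting:
    def test_gamma_one_sends_all_left(self, rng):
        tips = _tips(5)
        left, right = route_at_hybrid(tips, 1.0, rng)
        assert left == tips and right == []

    def test_gamma_zero_sends_all_right(self, rng):
        tips = _tips(5)
        left, right = route_at_hybrid(tips, 0.0, rng)
        assert left == [] and right == tips

    def test_routing_fraction_matches_gamma(self, rng):
        n = 10_000
        left, right = route_at_hybrid(_tips(n), 0.5, rng)
        assert len(left) + len(right) == n
        assert abs(len(left) / n - 0.5) <= 3 * math.sqrt(0.25 / n)


class TestSimulateGeneTree:
    def test_single_sample_single_species(self, rng):
        tree = simulate_gene_tree(parse_network("A;"), 1, rng)
        assert tree.root.label == "A_1"
        assert tree.root.children == []
        assert tree.sample_map == {"A_1": "A"}

    def test_tip_labels_and_counts(self, rng):
        net = parse_network("(A:1,B:1);")
        tree = simulate_gene_tree(net, {"A": 3, "B": 2}, rng)
        assert sorted(tree.sample_map) == ["A_1", "A_2", "A_3", "B_1", "B_2"]
        assert tree.num_tips == 5
        assert all(t.height == 0 for t in tree.tips())

    def test_kingman_trees_strictly_binary(self, rng):
        net = parse_network("(A:1,B:1);")
        for _ in range(200):
            tree = simulate_gene_tree(net, 3, rng)
            for node in tree.preorder():
                assert len(node.children) in (0, 2)

    def test_multiple_mergers_occur_under_point_mass(self, rng, hybrid_net_with_lengths):
        net = hybrid_net_with_lengths
        assign_branch_attributes(net, 0.23, "coalescent_parameter")
        polytomies = 0
        for _ in range(500):
            tree = simulate_gene_tree(net, {"A": 3, "B": 1, "C": 2, "D": 1}, rng)
            if any(len(n.children) > 2 for n in tree.preorder()):
                polytomies += 1
        assert polytomies >= 1

    def test_lineage_conservation(self, rng, hybrid_net_with_lengths):
        net = hybrid_net_with_lengths
        assign_branch_attributes(net, 0.23, "coalescent_parameter")
        for _ in range(50):
            tree = simulate_gene_tree(net, 2, rng)
            internal = [n for n in tree.preorder() if n.children]
            merged = sum(len(n.children) - 1 for n in internal)
            assert tree.num_tips - merged == 1

    def test_heights_increase_rootward(self, rng, hybrid_net_with_lengths):
        net = hybrid_net_with_lengths
        assign_branch_attributes(net, 0.5, "coalescent_parameter")
        tree = simulate_gene_tree(net, 2, rng)
        for node in tree.preorder():
            for child in node.children:
                assert child.height < node.height

    def test_no_coalescence_younger_than_population_divergence(self, rng):
        # samples from A and B cannot share an ancestor more recently than
        # the split tau
        tau = 2.5
        net = parse_network(f"(A:{tau},B:{tau});")
        for _ in range(200):
            tree = simulate_gene_tree(net, 2, rng)
            for node in tree.preorder():
                if not node.children:
                    continue
                species = {tree.sample_map[t.label] for t in node.tips()}
                if len(species) == 2:
                    assert node.height >= tau

    def test_same_seed_reproducible(self):
        net = parse_network("((A:1,B:1)x:1,C:2)r;")
        out = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            trees = [simulate_gene_tree(net, 2, rng) for _ in range(10)]
            out.append([write_newick(t, "coalescent", precision=17) for t in trees])
        assert out[0] == out[1]

    def test_mean_tmrca_single_population(self, rng):
        # E[TMRCA] = 2(1 - 1/n) for n Kingman samples from one population
        net, n = parse_network("A;"), 4
        heights = [simulate_gene_tree(net, n, rng).root.height for _ in range(4000)]
        mean = np.mean(heights)
        se = np.std(heights, ddof=1) / np.sqrt(len(heights))
        assert abs(mean - 2 * (1 - 1 / n)) <= 3 * se

    def test_split_model_times_match_independent_simulator(self, rng):
        # cross-check against msprime: two Kingman populations that split
        # tau units ago; E[T_w] = 1 (memoryless) and E[T_b] = tau + 1
        import msprime

        tau, reps = 1.5, 3000
        net = parse_network(f"(A:{tau},B:{tau});")
        tw, tb = [], []

        def mrca_height(tree, l1, l2):
            tips = {n.label: n for n in tree.tips()}
            seen = set()
            x = tips[l1]
            while x is not None:
                seen.add(id(x))
                x = x.parent
            x = tips[l2]
            while id(x) not in seen:
                x = x.parent
            return x.height

        for _ in range(reps):
            t = simulate_gene_tree(net, 2, rng, check_ultra=False)
            tw.append(mrca_height(t, "A_1", "A_2"))
            tw.append(mrca_height(t, "B_1", "B_2"))
            tb.append(mrca_height(t, "A_1", "B_1"))

        demog = msprime.Demography()
        for name in ("A", "B", "AB"):
            demog.add_population(name=name, initial_size=0.5)
        demog.add_population_split(time=tau, derived=["A", "B"], ancestral="AB")
        ms_tw, ms_tb = [], []
        for ts in msprime.sim_ancestry(
            samples={"A": 1, "B": 1}, demography=demog, ploidy=2,
            num_replicates=reps, random_seed=11,
        ):
            tree = ts.first()
            ms_tw.append(tree.time(tree.mrca(0, 1)))
            ms_tw.append(tree.time(tree.mrca(2, 3)))
            ms_tb.append(tree.time(tree.mrca(0, 2)))

        for ours, theirs, truth in ((tw, ms_tw, 1.0), (tb, ms_tb, tau + 1.0)):
            se = math.hypot(
                np.std(ours, ddof=1) / math.sqrt(len(ours)),
                np.std(theirs, ddof=1) / math.sqrt(len(theirs)),
            )
            assert abs(np.mean(ours) - np.mean(theirs)) <= 3 * se
            assert abs(np.mean(ours) - truth) <= 3 * np.std(ours, ddof=1) / math.sqrt(len(ours))

    def test_non_ultrametric_warns_but_simulates(self, rng):
        net = parse_network("(A:1,B:2);")
        with pytest.warns(UserWarning, match="not ultrametric"):
            tree = simulate_gene_tree(net, 1, rng)
        assert tree.num_tips == 2

    def test_generations_units_rejected(self, rng):
        net = parse_network("(A:100,B:100);", unit_tag="generations")
        with pytest.raises(ValidationError, match="convert_units"):
            simulate_gene_tree(net, 1, rng)

    def test_missing_inheritance_probability_rejected(self, rng):
        net = parse_network("((((B:1,C:1)s1:1)h1#H1:1,A:3)s2:1,(h1#H1:1,D:3)s3:1)r;")
        with pytest.raises(ValidationError, match="inheritance"):
            simulate_gene_tree(net, 1, rng)


class TestRescale:
    def test_unit_population_all_scalings_equal(self, rng):
        net = parse_network("(A:1,B:1);")
        tree = rescale_tree(simulate_gene_tree(net, 2, rng), mu=1.0)
        for node in tree.preorder():
            if node.parent is None:
                continue
            assert node.length_gen == pytest.approx(node.length_coal, rel=1e-9)
            assert node.length_mut == pytest.approx(node.length_coal, rel=1e-9)

    def test_generations_scale_with_population_size(self, rng):
        net = parse_network("(A:1,B:1);")
        assign_branch_attributes(net, 10_000.0, "pop_size")
        tree = rescale_tree(simulate_gene_tree(net, 2, rng), mu=1e-5)
        for node in tree.preorder():
            if node.parent is None:
                continue
            # N is constant across the whole network here
            assert node.length_gen == pytest.approx(
                node.length_coal * 10_000, rel=1e-9
            )
            assert node.length_mut == pytest.approx(node.length_gen * 1e-5, rel=1e-9)

    def test_zero_mutation_rate_zeroes_mutation_lengths(self, rng):
        net = parse_network("(A:1,B:1);")
        tree = rescale_tree(simulate_gene_tree(net, 3, rng), mu=0.0)
        assert all(
            n.length_mut == 0.0 for n in tree.preorder() if n.parent is not None
        )

    def test_segments_cover_each_branch(self, rng, hybrid_net_with_lengths):
        net = hybrid_net_with_lengths
        assign_branch_attributes(net, 0.23, "coalescent_parameter")
        for _ in range(20):
            tree = simulate_gene_tree(net, 2, rng)
            for node in tree.preorder():
                if node.parent is None:
                    continue
                covered = sum(h1 - h0 for h0, h1, _ in node.segments)
                assert covered == pytest.approx(node.length_coal, rel=1e-9, abs=1e-12)

    def test_beta_branch_uses_alpha_timescale(self, rng):
        # generations = coalescent * N**(alpha-1) on Beta branches
        net = parse_network("(A:1,B:1);")
        assign_branch_attributes(net, 1.5, "coalescent_parameter")
        assign_branch_attributes(net, 10_000.0, "pop_size")
        tree = rescale_tree(simulate_gene_tree(net, 2, rng), mu=0.0)
        for node in tree.preorder():
            if node.parent is None:
                continue
            assert node.length_gen == pytest.approx(
                node.length_coal * 100.0, rel=1e-9
            )
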