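import itertools

import numpy as np
import pytest

from ankevo import (
    Alignment,
    ClusterPair,
    Sequence,
    SiteCounts,
    candidate_sites_type1,
    estimate_type1,
    estimate_type2,
    fitch_counts,
    property_change_label,
    property_class,
    sample_counts,
    taxonomic_grouping,
)
from ankevo.tree import Tree, TreeError, TreeNode
from ankevo.synthetic_data import simulate_family, two_clade_tree


def cluster_pair(rows: dict[str, str], newick: str, a, b, **kw) -> ClusterPair:
    msa = Alignment([Sequence(k, v) for k, v in rows.items()])
    return ClusterPair(msa, Tree.from_newick(newick), frozenset(a),
                       frozenset(b), **kw)


EIGHT_TAXON_NWK = (
    "(((a1:1,a2:1):1,(a3:1,a4:1):1):1,((b1:1,b2:1):1,(b3:1,b4:1):1):1);"
)
A4 = ["a1", "a2", "a3", "a4"]
B4 = ["b1", "b2", "b3", "b4"]


def brute_force_parsimony(tree_node, states):
    """Minimum substitutions over all internal-state assignments."""
    internal = [n for n in tree_node.walk() if not n.is_leaf]
    leaves = [n for n in tree_node.walk() if n.is_leaf]
    observed = sorted(
        {states[l.label] for l in leaves if states[l.label] not in "-X?"}
    )
    if not observed:
        return 0
    best = np.inf
    for assign in itertools.product(observed, repeat=len(internal)):
        mapping = dict(zip((id(n) for n in internal), assign))
        cost = 0
        for n in tree_node.walk():
            if n is tree_node:
                continue
            s_child = (
                states[n.label] if n.is_leaf else mapping[id(n)]
            )
            s_parent = mapping[id(n.parent)]
            if n.is_leaf and s_child in "-X?":
                continue
            if s_child != s_parent:
                cost += 1
        best = min(best, cost)
    return int(best)


class TestFitchCounts:
    def test_invariant_column_counts_zero(self):
        pair = cluster_pair(
            {t: "A" for t in A4 + B4}, EIGHT_TAXON_NWK, A4, B4
        )
        counts = fitch_counts(pair)
        assert counts.x_a[0] == 0 and counts.x_b[0] == 0

    def test_textbook_two_state_column(self):
        rows = {"a1": "A", "a2": "A", "a3": "T", "a4": "T"}
        rows.update({t: "A" for t in B4})
        pair = cluster_pair(rows, EIGHT_TAXON_NWK, A4, B4)
        counts = fitch_counts(pair)
        assert counts.x_a[0] == 1
        assert counts.x_b[0] == 0

    def test_missing_states_excluded_and_all_missing_masked(self):
        rows = {"a1": "A", "a2": "-", "a3": "X", "a4": "A"}
        rows.update({t: "-" for t in B4})
        pair = cluster_pair(rows, EIGHT_TAXON_NWK, A4, B4)
        counts = fitch_counts(pair)
        assert counts.x_a[0] == 0
        assert counts.masked[0]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_minimization(self, seed):
        rng = np.random.default_rng(seed)
        letters = list("ACDEF")
        tree = Tree.from_newick(
            "((((a1:1,a2:1):1,a3:1):1,(a4:1,(a5:1,a6:1):1):1):1,"
            "((b1:1,b2:1):1,(b3:1,b4:1):1):1);"
        )
        rows = {
            t: "".join(rng.choice(letters, size=12))
            for t in tree.leaf_names
        }
        msa = Alignment([Sequence(k, v) for k, v in rows.items()])
        pair = ClusterPair(
            msa, tree,
            frozenset(["a1", "a2", "a3", "a4", "a5", "a6"]),
            frozenset(["b1", "b2", "b3", "b4"]),
        )
        counts = fitch_counts(pair)
        from ankevo.functional_divergence import _subtree_for

        sub_a = _subtree_for(pair.tree, pair.cluster_a)
        for col in range(12):
            states = {t: rows[t][col] for t in rows}
            assert counts.x_a[col] == brute_force_parsimony(sub_a, states)

    def test_non_monophyletic_cluster_rejected(self):
        with pytest.raises(TreeError):
            cluster_pair(
                {t: "A" for t in A4 + B4},
                EIGHT_TAXON_NWK,
                ["a1", "a2", "a3", "b1"],
                ["a4", "b2", "b3", "b4"],
            )

    def test_small_clusters_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            cluster_pair(
                {t: "A" for t in A4 + B4}, EIGHT_TAXON_NWK,
                ["a1", "a2", "a3"], B4,
            )


class TestType1:
    def test_identical_count_vectors_give_null_result(self):
        rng = np.random.default_rng(0)
        x = rng.poisson(1.5, size=500)
        counts = SiteCounts(x, x, np.zeros(500, bool))
        res = estimate_type1(counts, seed=0)
        assert res.theta < 0.1
        assert res.p_value > 0.05

    @pytest.mark.parametrize("theta", [0.3, 0.6])
    def test_parameter_recovery_from_model_sampler(self, theta):
        hats = []
        for seed in range(6):
            counts = sample_counts(
                theta=theta, alpha=0.5, t_a=2.0, t_b=2.0, L=1000, seed=seed
            )
            hats.append(estimate_type1(counts, seed=seed).theta)
        assert abs(np.mean(hats) - theta) < 0.15

    def test_swapping_clusters_leaves_estimates_unchanged(self):
        counts = sample_counts(
            theta=0.5, alpha=0.5, t_a=1.0, t_b=3.0, L=600, seed=3
        )
        fwd = estimate_type1(counts, seed=1)
        swapped = SiteCounts(counts.x_b, counts.x_a, counts.masked)
        rev = estimate_type1(swapped, seed=1)
        assert fwd.theta == pytest.approx(rev.theta, abs=1e-3)
        assert fwd.lrt == pytest.approx(rev.lrt, abs=1e-2)
        np.testing.assert_allclose(fwd.posterior, rev.posterior, atol=1e-3)

    def test_theta_bounds_and_posterior_range(self):
        counts = sample_counts(
            theta=0.9, alpha=0.3, t_a=2.0, t_b=2.0, L=400, seed=9
        )
        res = estimate_type1(counts, seed=0)
        assert 0.0 <= res.theta <= 1.0
        assert res.lrt >= -1e-8
        assert np.all((res.posterior >= 0) & (res.posterior <= 1))

    def test_warns_below_recommended_length(self):
        counts = sample_counts(theta=0.0, alpha=1.0, t_a=1.0, t_b=1.0,
                               L=20, seed=0)
        with pytest.warns(UserWarning, match="informative columns"):
            estimate_type1(counts, seed=0, restarts=1)


class TestCandidateSites:
    def make_result(self, posteriors):
        return type(
            "R", (), {"posterior": np.asarray(posteriors, dtype=float)}
        )()

    def test_no_posterior_signal_gives_empty_list(self):
        assert candidate_sites_type1(self.make_result([0.0, 0.0])) == []

    def test_cutoff_is_strict(self):
        res = self.make_result([0.2, 0.86, 0.85])
        assert candidate_sites_type1(res, cutoff=0.85) == [2]

    def test_mapping_through_gapped_reference(self):
        msa = Alignment([Sequence("ref", "A-C"), Sequence("x", "AAC"),
                         Sequence("y", "AAC")])
        res = self.make_result([0.0, 0.0, 0.99])
        assert candidate_sites_type1(
            res, cutoff=0.85, reference="ref", msa=msa
        ) == [2]


class TestType2:
    def test_property_map_examples(self):
        assert property_change_label("Q", "K") == "Hydrophilic/+"
        assert property_change_label("Y", "N") == "Hydrophilic/Hydrophilic"
        assert property_change_label("D", "F") == "-/Hydrophobic"
        assert property_class("G") == "Hydrophilic"
        assert property_class("W") == "Hydrophobic"

    def test_identical_consensus_yields_no_sites(self):
        rows = {t: "MKVLWDEQ" for t in A4 + B4}
        pair = cluster_pair(rows, EIGHT_TAXON_NWK, A4, B4)
        res = estimate_type2(pair)
        assert res.sites == []
        assert res.radical_sites == []

    def test_fixed_radical_difference_scores_highest(self):
        rng = np.random.default_rng(2)
        letters = list("AVLIM")
        L = 60
        base = rng.choice(letters, size=L)
        rows = {}
        for t in A4 + B4:
            row = base.copy()
            flips = rng.choice(L, size=6, replace=False)
            for f in flips:
                row[f] = str(rng.choice(letters))
            rows[t] = "".join(row)
        # plant a conserved-but-divergent column: Q in A, K in B
        for t in A4:
            rows[t] = "Q" + rows[t][1:]
        for t in B4:
            rows[t] = "K" + rows[t][1:]
        pair = cluster_pair(rows, EIGHT_TAXON_NWK, A4, B4)
        res = estimate_type2(pair, cutoff=0.0)
        assert res.site_score[0] == max(res.site_score)
        if res.sites:
            assert res.property_change[res.sites[0]][:2] == ("Q", "K")

    def test_consensus_tie_excluded_and_logged(self):
        rows = {t: "A" for t in A4 + B4}
        rows["a1"], rows["a2"] = "C", "C"  # 2 C vs 2 A in cluster A: tie
        pair = cluster_pair(rows, EIGHT_TAXON_NWK, A4, B4)
        res = estimate_type2(pair)
        assert res.excluded_columns == [1]


class TestGroupingRoster:
    def make_msa(self, n_groups, per_group):
        rows = {
            f"g{g}t{i}": "MKVLW"
            for g in range(n_groups)
            for i in range(per_group)
        }
        return Alignment([Sequence(k, v) for k, v in rows.items()])

    def test_ten_groups_give_45_comparisons(self):
        msa = self.make_msa(10, 4)
        labels = {t: t.split("t")[0] for t in msa.taxa}
        assert len(taxonomic_grouping(msa, labels)) == 45

    def test_two_groups_give_one_comparison(self):
        msa = self.make_msa(2, 4)
        labels = {t: t.split("t")[0] for t in msa.taxa}
        assert len(taxonomic_grouping(msa, labels)) == 1

    def test_undersized_group_dropped_with_warning(self):
        msa = self.make_msa(3, 4)
        labels = {t: t.split("t")[0] for t in msa.taxa}
        for t in list(labels):
            if labels[t] == "g2" and t.endswith("t3"):
                labels.pop(t)  # g2 now has 3 taxa
        with pytest.warns(UserWarning, match="dropped"):
            roster = taxonomic_grouping(msa, labels)
        assert len(roster) == 1
        assert {r[0] for r in roster} | {r[1] for r in roster} == {"g0", "g1"}


class TestEndToEndRecovery:
    def test_alignment_level_theta_signal_is_monotone(self):
        """Planted rate decoupling through the full sequence route
        (simulate → Fitch → estimate) never decreases mean theta."""
        tree = two_clade_tree(5, inner=0.3, stem=0.4)
        cluster_a = frozenset(t for t in tree.leaf_names if t.startswith("A"))
        cluster_b = frozenset(t for t in tree.leaf_names if t.startswith("B"))
        means = []
        for theta in (0.0, 0.6):
            hats = []
            for seed in range(3):
                msa, _ = simulate_family(
                    tree, 600, alpha=0.5, cluster_b=cluster_b, theta=theta,
                    shift_factor=4.0, seed=seed,
                )
                pair = ClusterPair(msa, tree, cluster_a, cluster_b)
                res = estimate_type1(fitch_counts(pair), seed=seed,
                                     restarts=2)
                hats.append(res.theta)
            means.append(np.mean(hats))
        assert means[1] > means[0]
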