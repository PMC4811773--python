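"""Error models, annotator matching, gold-standard scoring and lint."""

import math

import numpy as np
import pytest
from arbortwig.reliability import (
    compare_to_gold,
    consensus_synapse_weights,
    edge_omission_probability,
    error_spatial_clustering,
    expected_false_synapses,
    false_edge_probability,
    false_edge_probability_exact,
    lint_reconstruction,
    match_skeletons,
    simulate_edge_omission,
)
from arbortwig.compartments import split_backbone_twigs, twig_statistics
from arbortwig.skeleton import (
    Connector,
    PartnerRelation,
    Reconstruction,
    Skeleton,
    SkeletonError,
    SkeletonNode,
    TagSet,
)
from arbortwig.synthgen import (
    SynthParams,
    corrupt_reconstruction,
    generate_neuron,
)

from conftest import chain_skeleton, monadic_connector

# twigs long enough to be distinguishable at the 600 nm match radius
DETECTABLE = SynthParams(
    twig_depth_median_um=5.0,
    twig_depth_min_um=3.0,
    twig_branch_prob=0.0,
    twig_rate_per_um=0.1,
    backbone_cable_um=200.0,
    backbone_branch_rate_per_um=0.01,
    n_inputs=150,
    n_outputs=30,
)


class TestEdgeOmission:
    def test_single_twig_case(self):
        assert edge_omission_probability({1: {1: 1.0}}, 0.88, 1) == pytest.approx(
            0.12
        )

    def test_two_twig_mixture(self):
        dist = {2: {1: 0.5, 2: 0.5}}
        assert edge_omission_probability(dist, 0.88, 2) == pytest.approx(
            0.5 * 0.12 + 0.5 * 0.12**2
        )

    def test_perfect_recall_no_loss(self):
        dist = {3: {1: 0.2, 2: 0.3, 3: 0.5}}
        assert edge_omission_probability(dist, 1.0, 3) == 0.0

    def test_backbone_mass_is_immune(self):
        dist = {2: {0: 0.4, 1: 0.6}}
        assert edge_omission_probability(dist, 0.5, 2) == pytest.approx(0.3)

    def test_monotone_in_recall(self):
        dist = {3: {1: 0.3, 2: 0.4, 3: 0.3}}
        values = [
            edge_omission_probability(dist, q, 3)
            for q in (0.0, 0.25, 0.5, 0.75, 1.0)
        ]
        assert values == sorted(values, reverse=True)

    def test_simulation_agrees_with_analytic(self):
        q, trials = 0.88, 100_000
        edge_twigs = {
            ("a", "b"): (2, [1, 1], 0),
            ("c", "d"): (2, [2], 0),
            ("e", "f"): (1, [1], 0),
            ("g", "h"): (2, [1], 1),  # backbone contact: never lost
        }
        sim = simulate_edge_omission(edge_twigs, q, trials, seed=5)
        # m=2 edges pool one two-twig and one one-twig edge plus the immune
        # backbone edge: analytic mean over the three
        p2 = ((1 - q) ** 2 + (1 - q) + 0.0) / 3
        sigma2 = math.sqrt(p2 * (1 - p2) / (3 * trials))
        assert abs(sim[2] - p2) < 3 * sigma2 + 1e-9
        p1 = 1 - q
        sigma1 = math.sqrt(p1 * (1 - p1) / trials)
        assert abs(sim[1] - p1) < 3 * sigma1


class TestFalseSynapses:
    def test_printed_parameterization(self):
        m, exact = expected_false_synapses(6 / 1630.0, 257.0, 5.0)
        assert m == 5
        assert exact == pytest.approx(4.73, abs=0.005)

    def test_zero_rate(self):
        assert expected_false_synapses(0.0, 100.0, 5.0)[0] == 0

    def test_direct_product(self):
        assert expected_false_synapses(0.01, 100.0, 3.0)[0] == 3


class TestFalseEdges:
    def test_degenerate_cases(self):
        assert false_edge_probability(5, 0, 3, 1, 1000, seed=0) == 0.0
        assert false_edge_probability(5, 3, 0, 1, 1000, seed=0) == 0.0

    def test_two_axon_coin_flip(self):
        assert false_edge_probability_exact(2, 2, 1, 1) == 0.5
        mc = false_edge_probability(2, 2, 1, 1, iterations=100_000, seed=3)
        assert mc == pytest.approx(0.5, abs=0.01)

    def test_monte_carlo_matches_enumeration(self):
        for N in (2, 3, 4):
            for N_0 in (1, N):
                for m in (1, 2, 3):
                    for k_theta in (1, 2):
                        exact = false_edge_probability_exact(N, N_0, m, k_theta)
                        mc = false_edge_probability(
                            N, N_0, m, k_theta, iterations=40_000, seed=11
                        )
                        sigma = math.sqrt(max(exact * (1 - exact), 1e-6) / 40_000)
                        assert abs(mc - exact) < 4 * sigma + 1e-3

    def test_monotonicity(self):
        base = false_edge_probability(10, 4, 4, 2, 30_000, seed=7)
        more_syn = false_edge_probability(10, 4, 6, 2, 30_000, seed=7)
        more_axons = false_edge_probability(10, 6, 4, 2, 30_000, seed=7)
        higher_thresh = false_edge_probability(10, 4, 4, 3, 30_000, seed=7)
        assert more_syn >= base
        assert more_axons >= base
        assert higher_thresh <= base

    def test_strict_criterion_flag(self):
        # with strict inequality a single synapse can never pass k_theta = 1
        assert false_edge_probability_exact(2, 2, 1, 1, strict=True) == 0.0


class TestMatching:
    def test_identical_duplicates_fully_supported(self):
        skel = chain_skeleton([1.0] * 20)
        corr = match_skeletons([skel, skel])
        assert all(v == 2 for v in corr.support[0].values())
        assert len(corr.chunks[0]) == 1

    def test_deleted_branch_has_support_one(self):
        nodes = [SkeletonNode(1, None, (0, 0, 0))]
        for i in range(2, 22):
            nodes.append(SkeletonNode(i, i - 1, ((i - 1) * 1000.0, 0, 0)))
        # branch of 10 nodes hanging off node 10, well away from the chain
        for j in range(10):
            nodes.append(
                SkeletonNode(
                    22 + j, 10 if j == 0 else 21 + j, (9000.0, (j + 1) * 1000.0, 0)
                )
            )
        full = Skeleton("full", nodes)
        pruned = Skeleton("pruned", nodes[:21])
        corr = match_skeletons([full, pruned])
        unsupported = {
            nid
            for nid, s in corr.support[0].items()
            if s == 1 and nid in full
        }
        # original branch node ids are all unsupported beyond the radius
        assert {23, 24, 25, 26, 27, 28, 29, 30, 31} <= unsupported

    def test_displaced_node_unsupported(self):
        a = chain_skeleton([0.05, 0.05])
        moved = [
            SkeletonNode(1, None, (0, 0, 0)),
            SkeletonNode(2, 1, (50.0, 0, 0)),
            SkeletonNode(3, 2, (100.0, 700.0, 0)),  # 700 nm off
        ]
        b = Skeleton("b", moved)
        corr = match_skeletons([a, b], resample_nm=80.0, radius_nm=600.0)
        # b's displaced tip is farther than the radius from every a node
        assert corr.support[1][3] == 1
        assert corr.support[1][2] == 2

    def test_needs_two_reconstructions(self):
        with pytest.raises(SkeletonError):
            match_skeletons([chain_skeleton([1.0])])


class TestConsensusWeights:
    def _recons(self, n):
        nodes = [SkeletonNode(1, None, (0, 0, 0))]
        for i in range(2, 32):
            nodes.append(SkeletonNode(i, i - 1, ((i - 1) * 500.0, 0, 0)))
        return [Skeleton(f"r{k}", nodes) for k in range(n)]

    def _synapse(self, recon_id, node=15):
        return Connector(
            f"c_{recon_id}",
            ((node - 1) * 500.0, 0.0, 0.0),
            presynaptic=PartnerRelation("ext", 1),
            postsynaptic=(PartnerRelation(recon_id, node),),
        )

    def test_two_of_three_weight(self):
        recs = self._recons(3)
        corr = match_skeletons(recs)
        weights = consensus_synapse_weights(
            corr, [[self._synapse("r0")], [self._synapse("r1")], []]
        )
        assert len(weights) == 1
        assert weights[0]["weight"] == pytest.approx(2 / 3)

    def test_unanimous_weight_one(self):
        recs = self._recons(4)
        corr = match_skeletons(recs)
        weights = consensus_synapse_weights(
            corr, [[self._synapse(f"r{k}")] for k in range(4)]
        )
        assert weights[0]["weight"] == pytest.approx(1.0)

    def test_weight_bounded_in_unit_interval(self):
        recs = self._recons(3)
        corr = match_skeletons(recs)
        weights = consensus_synapse_weights(
            corr, [[self._synapse("r0")], [], []]
        )
        assert 0.0 < weights[0]["weight"] <= 1.0


class TestCompareToGold:
    def _gold(self, seed=11):
        recon, truth = generate_neuron(DETECTABLE, seed=seed)
        skel = recon.skeletons["n1"]
        labels = split_backbone_twigs(skel, recon.tags["n1"])
        twig_statistics(labels, skel, recon.connectors)
        return recon, truth, skel, labels

    def test_identical_reconstruction_is_clean(self):
        recon, _truth, skel, labels = self._gold()
        report = compare_to_gold(
            skel, labels, recon.connectors, skel, recon.connectors
        )
        assert report.missed_branches == []
        assert report.false_continuations == []
        assert report.postsyn_recall == pytest.approx(1.0)
        assert report.twig_recall == pytest.approx(1.0)
        assert report.postsyn_partition["gold_only"] == 0
        assert report.postsyn_partition["test_only"] == 0

    def test_recovers_planted_deletions(self):
        recon, truth, skel, labels = self._gold(seed=0)
        test, ct = corrupt_reconstruction(
            recon, {"n1": truth}, q=0.7, seed=100
        )
        report = compare_to_gold(
            skel, labels, recon.connectors,
            test.skeletons["n1"], test.connectors,
        )
        n_deleted = len(ct.deleted_twigs["n1"])
        assert n_deleted > 0
        assert len(report.missed_branches) == n_deleted
        assert report.n_twigs_gold - report.n_twigs_found == n_deleted
        assert report.errors_by_compartment["twig"] == n_deleted
        # each missed branch sits inside exactly one planted deleted twig;
        # its synapse count is bounded by that twig's planted inputs (nodes
        # within the match radius of the surviving base count as found)
        deleted_members = {
            ti: truth.twigs[ti].members for ti in ct.deleted_twigs["n1"]
        }
        for branch in report.missed_branches:
            owners = [
                ti
                for ti, members in deleted_members.items()
                if branch.nodes <= members
            ]
            assert len(owners) == 1
            planted = sum(
                1
                for n in truth.input_nodes
                if n in deleted_members[owners[0]]
            )
            assert branch.inputs <= planted

    def test_partition_identity(self):
        recon, truth, skel, labels = self._gold(seed=2)
        test, _ct = corrupt_reconstruction(recon, {"n1": truth}, q=0.8, seed=3)
        report = compare_to_gold(
            skel, labels, recon.connectors,
            test.skeletons["n1"], test.connectors,
        )
        gold_total = sum(
            1
            for c in recon.connectors
            for r in c.postsynaptic
            if r.skeleton_id == "n1"
        )
        part = report.postsyn_partition
        assert part["both"] + part["gold_only"] == gold_total

    def test_false_branches_detected(self):
        recon, truth, skel, labels = self._gold(seed=5)
        test, ct = corrupt_reconstruction(
            recon, {"n1": truth}, q=1.0, r=0.02, k_bar=3.0, seed=8
        )
        report = compare_to_gold(
            skel, labels, recon.connectors,
            test.skeletons["n1"], test.connectors,
        )
        assert len(report.missed_branches) == 0
        assert len(report.false_continuations) == ct.false_branches["n1"]
        assert report.postsyn_partition["test_only"] == sum(
            b.inputs for b in report.false_continuations
        )

    def test_disjoint_skeletons_rejected(self):
        a = chain_skeleton([1.0] * 5, "a")
        far = [
            SkeletonNode(1, None, (0, 1e6, 0)),
            SkeletonNode(2, 1, (1000.0, 1e6, 0)),
        ]
        b = Skeleton("b", far)
        labels = split_backbone_twigs(a, TagSet())
        with pytest.raises(SkeletonError, match="overlap"):
            compare_to_gold(a, labels, [], b, [])


class TestLint:
    def _recon(self):
        skel = chain_skeleton([1.0] * 4, "A")
        other = chain_skeleton([1.0] * 4, "B")
        recon = Reconstruction(skeletons={"A": skel, "B": other})
        recon.tags["A"] = TagSet({1: {"soma"}, 5: {"ends"}})
        recon.tags["B"] = TagSet({1: {"soma"}, 5: {"ends"}})
        return recon

    def _cats(self, recon, **kwargs):
        return [i.category for i in lint_reconstruction(recon, **kwargs)]

    def test_clean_reconstruction(self):
        assert self._cats(self._recon()) == []

    def test_autapse_detected(self):
        recon = self._recon()
        recon.connectors.append(monadic_connector("c", ("A", 2), ("A", 4)))
        assert "autapse" in self._cats(recon)

    def test_untagged_leaf(self):
        recon = self._recon()
        recon.tags["A"] = TagSet({1: {"soma"}})
        assert "untagged-leaf" in self._cats(recon)

    def test_ends_on_non_leaf(self):
        recon = self._recon()
        recon.tags["A"].add(3, "ends")
        assert "ends-not-leaf" in self._cats(recon)

    def test_open_tags(self):
        recon = self._recon()
        recon.tags["A"].add(3, "uncertain continuation")
        assert "open-tag" in self._cats(recon)

    def test_duplicated_synapse_by_distance(self):
        recon = self._recon()
        recon.connectors.append(monadic_connector("c1", ("A", 2), ("B", 2)))
        recon.connectors.append(monadic_connector("c2", ("A", 3), ("B", 2)))
        assert "duplicated-synapse" in self._cats(recon)
        # far apart: clean
        recon2 = self._recon()
        recon2.connectors.append(monadic_connector("c1", ("A", 2), ("B", 1)))
        recon2.connectors.append(monadic_connector("c2", ("A", 3), ("B", 5)))
        assert "duplicated-synapse" not in self._cats(recon2)

    def test_duplicated_postsynaptic_relation(self):
        recon = self._recon()
        recon.connectors.append(
            Connector(
                "c",
                (0, 0, 0),
                presynaptic=PartnerRelation("A", 2),
                postsynaptic=(
                    PartnerRelation("B", 2),
                    PartnerRelation("B", 4),
                ),
            )
        )
        assert "duplicated-postsynaptic" in self._cats(recon)

    def test_soma_checks(self):
        recon = self._recon()
        recon.tags["A"] = TagSet({5: {"ends"}})
        assert "no-soma" in self._cats(recon)
        recon.tags["A"] = TagSet({3: {"soma"}, 5: {"ends"}})
        assert "root-not-soma" in self._cats(recon)


class TestErrorClustering:
    def _setting(self):
        recon, truth = generate_neuron(
            SynthParams(twig_rate_per_um=0.8, backbone_cable_um=150.0),
            seed=40,
        )
        skel = recon.skeletons["n1"]
        labels = split_backbone_twigs(skel, recon.tags["n1"])
        return skel, labels, truth

    def test_two_errors_single_distance_pair(self):
        skel, labels, _ = self._setting()
        errors = {"n1": [labels.twigs[0].base, labels.twigs[1].base]}
        observed, _count = error_spatial_clustering(
            errors, {"n1": labels}, {"n1": skel}, n_samples=10, seed=1
        )
        assert len(observed) == 2
        assert observed[0] == pytest.approx(observed[1])

    def test_coincident_errors_distance_zero(self):
        skel, labels, _ = self._setting()
        node = sorted(labels.twigs[0].members)[0]
        observed, _ = error_spatial_clustering(
            {"n1": [node, node]}, {"n1": labels}, {"n1": skel},
            n_samples=5, seed=1,
        )
        assert observed == [0.0, 0.0]

    def test_null_calibration(self):
        skel, labels, _ = self._setting()
        rng = np.random.default_rng(9)
        # errors drawn by the same scheme as the null: one node per twig
        chosen = rng.choice(len(labels.twigs), size=20, replace=False)
        errors = {
            "n1": [
                sorted(labels.twigs[i].members)[
                    rng.integers(len(labels.twigs[i].members))
                ]
                for i in chosen
            ]
        }
        n_samples = 400
        _obs, significant = error_spatial_clustering(
            errors, {"n1": labels}, {"n1": skel}, n_samples=n_samples, seed=2
        )
        # expect ~5% significant; allow generous binomial slack
        assert significant < 0.05 * n_samples + 3 * math.sqrt(
            0.05 * 0.95 * n_samples
        ) + 5

    def test_needs_two_errors(self):
        skel, labels, _ = self._setting()
        with pytest.raises(SkeletonError):
            error_spatial_clustering(
                {"n1": [1]}, {"n1": labels}, {"n1": skel}, n_samples=5, seed=0
            )
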