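"""Reconstruction-error models and multi-annotator validation accounting.

Two analytic error models translate per-twig error rates into wiring-
diagram consequences:

* **Edge omission.**  If a reconstruction recovers each twig with
  probability q, an edge whose m synapses span n_b distinct twigs is lost
  whenever all n_b twigs are missed, so
  P_loss(m) = sum over n_b >= 1 of p(n_b; m) (1-q)^n_b,
  where p(n_b; m) is the empirical twig-span distribution.  Edges that
  touch backbone (n_b = 0) are immune to twig omission.

* **False edges.**  Erroneous branches add m false synapses per neuron,
  each landing uniformly on one of N nearby axons, N_0 of which are truly
  unconnected.  A false edge appears in a stereotypy-checked diagram only
  if both members of a homologous pair accumulate at least k_theta
  synapses from the same unconnected axon.  The expected m itself is
  r * L_t * k-bar (error rate per µm of twig cable, twig cable, synapses
  per false branch).

The module also scores a test reconstruction against a gold standard
(after 80 nm resampling and 600 nm node matching), computes consensus
synapse weights across annotators, lints skeletons for systematic-review
issues, and tests whether observed errors cluster in space.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import ks_2samp

from .compartments import CompartmentLabels
from .skeleton import (
    Connector,
    Reconstruction,
    Skeleton,
    SkeletonError,
    TagSet,
    cable_length,
    geodesic_matrix,
    resample,
)

RESAMPLE_NM = 80.0
MATCH_RADIUS_NM = 600.0


# ---------------------------------------------------------------------------
# Edge-omission model
# ---------------------------------------------------------------------------


def edge_omission_probability(
    dist: dict[int, dict[int, float]] | dict[int, float], q: float, m: int
) -> float:
    """P_loss(m): probability of losing an m-synapse edge at twig recall q.

    ``dist`` is either the full twig-span distribution {m: {n_b: p}} or
    the single-m slice {n_b: p}.  Mass at n_b = 0 (backbone contact)
    contributes zero loss.
    """
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"twig recall q must be in [0,1], got {q}")
    if m in dist and isinstance(dist[m], dict):
        slice_m = dist[m]
    elif all(isinstance(v, (int, float)) for v in dist.values()):
        slice_m = dist
    else:
        raise KeyError(f"twig-span distribution undefined at m = {m}")
    return float(
        sum(p * (1.0 - q) ** n_b for n_b, p in slice_m.items() if n_b >= 1)
    )


def simulate_edge_omission(
    edge_twigs: dict[tuple[str, str], tuple[int, list[int], int]],
    q: float,
    trials: int,
    seed: int,
) -> dict[int, float]:
    """Monte-Carlo edge loss under independent twig omission.

    ``edge_twigs`` maps each edge to (m, twig synapse counts per distinct
    twig, backbone synapse count).  Per trial every twig is deleted
    independently with probability 1-q; an edge is lost when all its
    synapses were on deleted twigs.  Returns loss fraction grouped by m.
    """
    rng = np.random.default_rng(seed)
    lost_by_m: dict[int, list[int]] = {}
    for (_u, _v), (m, twig_counts, backbone_count) in sorted(edge_twigs.items()):
        rec = lost_by_m.setdefault(m, [0, 0])
        rec[1] += trials
        if backbone_count > 0 or not twig_counts:
            continue  # backbone synapses survive every trial
        n_b = len(twig_counts)
        # lost in a trial iff all n_b twigs deleted
        losses = (rng.random((trials, n_b)) > q).all(axis=1).sum()
        rec[0] += int(losses)
    return {m: lost / total for m, (lost, total) in sorted(lost_by_m.items())}


def expected_false_synapses(
    r: float, L_t: float, k_bar: float
) -> tuple[int, float]:
    """Expected false synapses per neuron, m = r * L_t * k-bar.

    ``r`` is the false-branch rate per µm of twig cable, ``L_t`` the twig
    cable in µm and ``k_bar`` the mean synapses per false branch.
    Returns (nearest-integer m, unrounded value).
    """
    if r < 0 or L_t < 0 or k_bar < 0:
        raise ValueError("rate, cable and synapse count must be non-negative")
    exact = r * L_t * k_bar
    return int(round(exact)), exact


def false_edge_probability(
    N: int,
    N_0: int,
    m: int,
    k_theta: int,
    iterations: int = 100_000,
    seed: int = 0,
    strict: bool = False,
) -> float:
    """P(a false edge of >= k_theta synapses appears in both homologs).

    Each of two same-type neurons receives m false synapses thrown
    uniformly over N candidate axons; success is any truly unconnected
    axon (i <= N_0) reaching the threshold on both neurons.  ``strict``
    switches the criterion to > k_theta.
    """
    if N < 1 or not 0 <= N_0 <= N or m < 0:
        raise ValueError("invalid counts for false-edge model")
    if N_0 == 0 or m == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    hits = 0
    batch = 10_000
    done = 0
    thresh = k_theta + 1 if strict else k_theta
    while done < iterations:
        n = min(batch, iterations - done)
        # counts onto the N_0 unconnected axons for each neuron
        k1 = _multinomial_counts(rng, n, m, N, N_0)
        k2 = _multinomial_counts(rng, n, m, N, N_0)
        hits += int(((k1 >= thresh) & (k2 >= thresh)).any(axis=1).sum())
        done += n
    return hits / iterations


def _multinomial_counts(rng, n_trials, m, N, N_0):
    draws = rng.integers(0, N, size=(n_trials, m))
    counts = np.zeros((n_trials, N_0), dtype=int)
    for i in range(N_0):
        counts[:, i] = (draws == i).sum(axis=1)
    return counts


def false_edge_probability_exact(
    N: int, N_0: int, m: int, k_theta: int, strict: bool = False
) -> float:
    """Exhaustive enumeration of the false-edge model (small N, m only).

    Enumerates all N^m assignments per neuron (N <= 6, m <= 4), serving
    as the independent check of the Monte-Carlo estimator.
    """
    if N > 6 or m > 4:
        raise ValueError("exact enumeration limited to N <= 6, m <= 4")
    if N_0 == 0 or m == 0:
        return 0.0
    thresh = k_theta + 1 if strict else k_theta
    assignments = list(itertools.product(range(N), repeat=m))
    vectors = []
    for a in assignments:
        k = [0] * N_0
        for axon in a:
            if axon < N_0:
                k[axon] += 1
        vectors.append(tuple(k))
    hits = 0
    for k1 in vectors:
        for k2 in vectors:
            if any(
                k1[i] >= thresh and k2[i] >= thresh for i in range(N_0)
            ):
                hits += 1
    return hits / len(vectors) ** 2


# ---------------------------------------------------------------------------
# Multi-annotator matching and consensus weights
# ---------------------------------------------------------------------------


@dataclass
class Correspondence:
    """Node-level support of each reconstruction by the others.

    ``support`` maps skeleton index -> {node_id: number of reconstructions
    (including its own) with a node within the match radius}.  ``chunks``
    lists, per skeleton, the maximal connected runs of nodes whose support
    reaches a majority of the reconstructions.
    """

    resampled: list[Skeleton]
    support: list[dict[int, int]]
    chunks: list[list[set[int]]]
    radius_nm: float
    n_reconstructions: int

    def chunk_support(self, skel_index: int, node_id: int) -> int:
        return self.support[skel_index].get(node_id, 0)


def match_skeletons(
    recons: list[Skeleton],
    resample_nm: float = RESAMPLE_NM,
    radius_nm: float = MATCH_RADIUS_NM,
) -> Correspondence:
    """Match independent reconstructions of one neuron by spatial proximity.

    All skeletons are first resampled so adjacent nodes are no further
    than ``resample_nm`` apart; a node is then supported by another
    reconstruction when that reconstruction has any node within
    ``radius_nm``.  Consensus chunks are maximal connected runs of nodes
    supported by at least half (rounded up) of the reconstructions.
    """
    if len(recons) < 2:
        raise SkeletonError("matching needs at least two reconstructions")
    rs = [resample(s, resample_nm) for s in recons]
    trees = [cKDTree(s.positions()) for s in rs]
    n = len(rs)
    threshold = math.ceil(n / 2)
    support: list[dict[int, int]] = []
    chunks: list[list[set[int]]] = []
    for i, skel in enumerate(rs):
        ids = skel.node_ids
        pos = skel.positions(ids)
        sup = np.ones(len(ids), dtype=int)  # every node supports itself
        for j, tree in enumerate(trees):
            if j == i:
                continue
            d, _ = tree.query(pos, k=1)
            sup += (d <= radius_nm).astype(int)
        sup_map = {nid: int(s) for nid, s in zip(ids, sup)}
        support.append(sup_map)
        chunks.append(_connected_runs(skel, {n_ for n_, s in sup_map.items() if s >= threshold}))
    return Correspondence(
        resampled=rs,
        support=support,
        chunks=chunks,
        radius_nm=radius_nm,
        n_reconstructions=n,
    )


def _connected_runs(skeleton: Skeleton, node_set: set[int]) -> list[set[int]]:
    """Maximal connected components of ``node_set`` in the skeleton tree."""
    remaining = set(node_set)
    comps = []
    while remaining:
        seed_node = remaining.pop()
        comp = {seed_node}
        stack = [seed_node]
        while stack:
            nid = stack.pop()
            for nb in skeleton.neighbors(nid):
                if nb in remaining:
                    remaining.remove(nb)
                    comp.add(nb)
                    stack.append(nb)
        comps.append(comp)
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def consensus_synapse_weights(
    corr: Correspondence,
    connectors_per_recon: list[list[Connector]],
    radius_nm: float = MATCH_RADIUS_NM,
) -> list[dict]:
    """Weight consensus synapses by annotator agreement.

    Synapses from different reconstructions are identified when they have
    the same polarity and connector positions within ``radius_nm``
    (first-come grouping over position-sorted relations).  Each group's
    weight is (annotating reconstructions) / (reconstructions supporting
    the chunk at that location), so a synapse annotated by every
    contributor present weighs exactly 1.
    """
    records = []
    for i, conns in enumerate(connectors_per_recon):
        own = corr.resampled[i].skeleton_id
        for conn in conns:
            pols = [("pre", conn.presynaptic)] + [
                ("post", r) for r in conn.postsynaptic
            ]
            for polarity, rel in pols:
                if rel.skeleton_id != own:
                    continue  # relations onto partner skeletons
                records.append(
                    {
                        "recon": i,
                        "polarity": polarity,
                        "position": np.asarray(conn.position, dtype=float),
                        "node": rel.node_id,
                    }
                )
    records.sort(key=lambda r: (r["polarity"], *r["position"].tolist(), r["recon"]))
    groups: list[dict] = []
    for rec in records:
        placed = False
        for grp in groups:
            if grp["polarity"] != rec["polarity"]:
                continue
            if (
                np.linalg.norm(grp["position"] - rec["position"]) <= radius_nm
                and rec["recon"] not in grp["recons"]
            ):
                grp["recons"].add(rec["recon"])
                placed = True
                break
        if not placed:
            groups.append(
                {
                    "polarity": rec["polarity"],
                    "position": rec["position"],
                    "recons": {rec["recon"]},
                    "anchor": (rec["recon"], rec["node"]),
                }
            )
    out = []
    for grp in groups:
        skel_idx, node = grp["anchor"]
        # support at the anchor's nearest resampled node
        skel = corr.resampled[skel_idx]
        if node in skel:
            support = corr.chunk_support(skel_idx, node)
        else:  # anchor node id absent after resampling: nearest node
            tree = cKDTree(skel.positions())
            _, idx = tree.query(grp["position"], k=1)
            support = corr.chunk_support(skel_idx, skel.node_ids[int(idx)])
        if support == 0 or not any(
            node in ch for ch in corr.chunks[skel_idx]
        ) and node in skel:
            raise SkeletonError(
                f"synapse at node {node} lies outside every consensus chunk"
            )
        out.append(
            {
                "polarity": grp["polarity"],
                "position": tuple(grp["position"]),
                "n_annotating": len(grp["recons"]),
                "support": support,
                "weight": len(grp["recons"]) / support,
            }
        )
    return out


# ---------------------------------------------------------------------------
# Gold-standard comparison
# ---------------------------------------------------------------------------


@dataclass
class BranchError:
    """One maximal connected mismatching component."""

    nodes: set[int]
    cable_um: float
    inputs: int
    branch_points: int
    compartment: str  # gold label at the attachment point


@dataclass
class ValidationReport:
    missed_branches: list[BranchError] = field(default_factory=list)
    false_continuations: list[BranchError] = field(default_factory=list)
    errors_by_compartment: dict[str, int] = field(default_factory=dict)
    um_per_error: dict[str, float] = field(default_factory=dict)
    presyn_recall: float = float("nan")
    postsyn_recall: float = float("nan")
    postsyn_partition: dict[str, int] = field(default_factory=dict)
    twig_recall: float = float("nan")
    n_twigs_gold: int = 0
    n_twigs_found: int = 0

    def summary(self) -> dict:
        return {
            "missed_branches": len(self.missed_branches),
            "false_continuations": len(self.false_continuations),
            "errors_by_compartment": dict(self.errors_by_compartment),
            "um_per_error": dict(self.um_per_error),
            "presyn_recall": self.presyn_recall,
            "postsyn_recall": self.postsyn_recall,
            "postsyn_partition": dict(self.postsyn_partition),
            "twig_recall": self.twig_recall,
            "n_twigs_gold": self.n_twigs_gold,
            "n_twigs_found": self.n_twigs_found,
        }


def compare_to_gold(
    gold_skel: Skeleton,
    gold_labels: CompartmentLabels,
    gold_connectors: list[Connector],
    test_skel: Skeleton,
    test_connectors: list[Connector],
    resample_nm: float = RESAMPLE_NM,
    radius_nm: float = MATCH_RADIUS_NM,
) -> ValidationReport:
    """Score a test reconstruction of one neuron against its gold standard.

    Both skeletons are resampled and matched; gold-only connected
    components are missed branches (false negatives), test-only
    components are false continuations (false positives).  Errors are
    attributed to twig or backbone by the gold compartment label at the
    attachment point, and synapse recall is the fraction of gold
    relations whose node lies in the matched (both) region.
    """
    if not (set(gold_skel.node_ids) or set(test_skel.node_ids)):
        raise SkeletonError("empty skeletons")
    gold_tree = cKDTree(gold_skel.positions())
    test_tree = cKDTree(test_skel.positions())

    def supported(skel: Skeleton, other_tree: cKDTree) -> dict[int, bool]:
        rs = resample(skel, resample_nm)
        ids = rs.node_ids
        d, _ = other_tree.query(rs.positions(ids), k=1)
        ok = {nid: bool(di <= radius_nm) for nid, di in zip(ids, d)}
        # project back to original nodes (originals keep their ids)
        return {nid: ok[nid] for nid in skel.node_ids}

    gold_ok = supported(gold_skel, test_tree)
    test_ok = supported(test_skel, gold_tree)
    if not any(gold_ok.values()):
        raise SkeletonError("gold and test reconstructions do not overlap")

    def gold_label_at(position: np.ndarray) -> str:
        _, idx = gold_tree.query(position, k=1)
        return gold_labels.label(gold_skel.node_ids[int(idx)])

    missed = []
    for comp in _connected_runs(gold_skel, {n for n, ok in gold_ok.items() if not ok}):
        attach = _attachment_node(gold_skel, comp)
        inputs = sum(
            1
            for c in gold_connectors
            for rel in c.postsynaptic
            if rel.skeleton_id == gold_skel.skeleton_id and rel.node_id in comp
        )
        missed.append(
            BranchError(
                nodes=comp,
                cable_um=cable_length(gold_skel, comp),
                inputs=inputs,
                branch_points=sum(
                    1 for n in comp if len(gold_skel.children(n)) > 1
                ),
                compartment=gold_labels.label(attach)
                if attach is not None
                else gold_labels.label(min(comp)),
            )
        )
    false_cont = []
    for comp in _connected_runs(test_skel, {n for n, ok in test_ok.items() if not ok}):
        attach = _attachment_node(test_skel, comp)
        anchor_pos = (
            test_skel.position(attach)
            if attach is not None
            else test_skel.position(min(comp))
        )
        inputs = sum(
            1
            for c in test_connectors
            for rel in c.postsynaptic
            if rel.skeleton_id == test_skel.skeleton_id and rel.node_id in comp
        )
        false_cont.append(
            BranchError(
                nodes=comp,
                cable_um=cable_length(test_skel, comp),
                inputs=inputs,
                branch_points=sum(
                    1 for n in comp if len(test_skel.children(n)) > 1
                ),
                compartment=gold_label_at(anchor_pos),
            )
        )
    by_comp = {"twig": 0, "backbone": 0}
    for err in missed + false_cont:
        by_comp[err.compartment] += 1
    twig_cable = sum(t.cable_um for t in gold_labels.twigs)
    backbone_cable = cable_length(gold_skel) - twig_cable
    um_per_error = {}
    for comp, cab in (("twig", twig_cable), ("backbone", backbone_cable)):
        um_per_error[comp] = (
            cab / by_comp[comp] if by_comp[comp] else float("inf")
        )
    # synapse recall and partition
    sid = gold_skel.skeleton_id
    gold_post = [
        rel.node_id
        for c in gold_connectors
        for rel in c.postsynaptic
        if rel.skeleton_id == sid
    ]
    gold_pre = [
        c.presynaptic.node_id
        for c in gold_connectors
        if c.presynaptic.skeleton_id == sid
    ]
    tid = test_skel.skeleton_id
    test_post = [
        rel.node_id
        for c in test_connectors
        for rel in c.postsynaptic
        if rel.skeleton_id == tid
    ]
    both_post = sum(1 for n in gold_post if gold_ok[n])
    partition = {
        "both": both_post,
        "gold_only": len(gold_post) - both_post,
        "test_only": sum(1 for n in test_post if not test_ok[n]),
    }
    report = ValidationReport(
        missed_branches=missed,
        false_continuations=false_cont,
        errors_by_compartment=by_comp,
        um_per_error=um_per_error,
        presyn_recall=(
            sum(1 for n in gold_pre if gold_ok[n]) / len(gold_pre)
            if gold_pre
            else float("nan")
        ),
        postsyn_recall=(
            both_post / len(gold_post) if gold_post else float("nan")
        ),
        postsyn_partition=partition,
        n_twigs_gold=len(gold_labels.twigs),
        n_twigs_found=sum(
            1
            for t in gold_labels.twigs
            if gold_ok[_deepest_member(gold_skel, t.base, t.members)]
        ),
    )
    report.twig_recall = (
        report.n_twigs_found / report.n_twigs_gold
        if report.n_twigs_gold
        else float("nan")
    )
    return report


def _deepest_member(skeleton: Skeleton, base: int, members: frozenset[int]) -> int:
    """Twig member at maximal cable depth from the base.

    A twig counts as recovered when this deepest point was found: missing
    it means the twig is absent or incomplete at its tip.
    """
    mem = sorted(members)
    depths = geodesic_matrix(skeleton, [base], mem)[0]
    return mem[int(np.argmax(depths))]


def _attachment_node(skeleton: Skeleton, comp: set[int]) -> int | None:
    """Parent node just proximal to a connected component, if any."""
    for nid in sorted(comp):
        p = skeleton.parent(nid)
        if p is not None and p not in comp:
            return p
    return None


# ---------------------------------------------------------------------------
# Skeleton lint
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LintIssue:
    category: str
    skeleton_id: str
    detail: str
    node_id: int | None = None
    connector_id: str | None = None


def lint_reconstruction(
    recon: Reconstruction, duplicate_radius_um: float = 1.0
) -> list[LintIssue]:
    """Detect systematic-review issues across a reconstruction.

    Seven checks: 'ends' tags on non-leaves; open-question tags (TODO,
    uncertain end/continuation); untagged leaves; autapses; potentially
    duplicated synapses (same ordered skeleton pair twice within a small
    cable distance); duplicated postsynaptic relations from one
    connector; and a root that is not the 'soma'-tagged node.
    """
    issues: list[LintIssue] = []
    for sid, skel in recon.skeletons.items():
        tags = recon.tags.get(sid, TagSet())
        leaves = set(skel.leaves())
        for nid, labels in tags.items():
            if "ends" in labels and nid not in leaves:
                issues.append(
                    LintIssue("ends-not-leaf", sid, "'ends' tag on non-leaf", nid)
                )
            for bad in ("TODO", "uncertain end", "uncertain continuation"):
                if bad in labels:
                    issues.append(
                        LintIssue("open-tag", sid, f"node tagged {bad!r}", nid)
                    )
        tagged = {nid for nid, labels in tags.items() if labels & {"ends", "not a branch"}}
        for leaf in sorted(leaves - tagged):
            issues.append(
                LintIssue(
                    "untagged-leaf", sid, "leaf without 'ends'/'not a branch'", leaf
                )
            )
        soma_nodes = tags.nodes_with("soma")
        if not soma_nodes:
            issues.append(LintIssue("no-soma", sid, "no node tagged 'soma'"))
        elif skel.root not in soma_nodes:
            issues.append(
                LintIssue(
                    "root-not-soma",
                    sid,
                    "'soma' tag not at the root node",
                    skel.root,
                )
            )
    for conn in recon.connectors:
        pre = conn.presynaptic
        post_sids = [r.skeleton_id for r in conn.postsynaptic]
        for sid in set(post_sids):
            if sid == pre.skeleton_id:
                issues.append(
                    LintIssue(
                        "autapse",
                        sid,
                        "skeleton is pre- and postsynaptic at one connector",
                        connector_id=conn.connector_id,
                    )
                )
            if post_sids.count(sid) > 1:
                issues.append(
                    LintIssue(
                        "duplicated-postsynaptic",
                        sid,
                        "multiple postsynaptic relations from one connector",
                        connector_id=conn.connector_id,
                    )
                )
    # potentially duplicated synapses: same ordered pair, close on the target
    by_pair: dict[tuple[str, str], list[tuple[str, int]]] = {}
    for conn in recon.connectors:
        for rel in conn.postsynaptic:
            by_pair.setdefault(
                (conn.presynaptic.skeleton_id, rel.skeleton_id), []
            ).append((conn.connector_id, rel.node_id))
    for (pre_sid, post_sid), rels in by_pair.items():
        if len(rels) < 2 or post_sid not in recon.skeletons:
            continue
        skel = recon.skeletons[post_sid]
        nodes = [n for _c, n in rels]
        dmat = geodesic_matrix(skel, nodes, nodes)
        for i in range(len(rels)):
            for j in range(i + 1, len(rels)):
                if rels[i][0] == rels[j][0]:
                    continue  # same connector: covered by check 6
                if dmat[i, j] <= duplicate_radius_um:
                    issues.append(
                        LintIssue(
                            "duplicated-synapse",
                            post_sid,
                            f"two {pre_sid}->{post_sid} synapses within "
                            f"{dmat[i, j]:.2f} µm of cable",
                            connector_id=rels[i][0],
                        )
                    )
    return issues


# ---------------------------------------------------------------------------
# Error spatial clustering
# ---------------------------------------------------------------------------


def error_spatial_clustering(
    error_nodes: dict[str, list[int]],
    labels: dict[str, CompartmentLabels],
    skeletons: dict[str, Skeleton],
    n_samples: int = 1000,
    seed: int = 0,
) -> tuple[list[float], int]:
    """Test whether reconstruction errors cluster along the cable.

    Observed statistic: each error's geodesic distance to the nearest
    other error on the same skeleton.  Null: ``n_samples`` draws of the
    same number of nodes uniformly from twig nodes, at most one node per
    twig, re-scored the same way and compared with a two-sample
    Kolmogorov-Smirnov test.  Returns the observed distances and the
    number of null samples with p < 0.05.
    """
    n_errors = sum(len(v) for v in error_nodes.values())
    if n_errors < 2:
        raise SkeletonError("need at least two error nodes")

    def nearest_distances(nodes_by_skel: dict[str, list[int]]) -> list[float]:
        out = []
        for sid, nodes in nodes_by_skel.items():
            if len(nodes) < 2:
                continue
            dmat = geodesic_matrix(skeletons[sid], nodes, nodes)
            np.fill_diagonal(dmat, np.inf)
            out.extend(dmat.min(axis=1).tolist())
        return out

    observed = nearest_distances(error_nodes)
    if not observed:
        raise SkeletonError(
            "no skeleton carries two or more error nodes; nearest-error "
            "distances undefined"
        )
    # twig pools: (skeleton, twig members) tuples across the whole set
    pools = []
    for sid, lab in labels.items():
        for twig in lab.twigs:
            pools.append((sid, sorted(twig.members)))
    if len(pools) < n_errors:
        raise SkeletonError("fewer twigs than error nodes")
    rng = np.random.default_rng(seed)
    significant = 0
    obs_arr = np.asarray(observed)
    for _ in range(n_samples):
        chosen = rng.choice(len(pools), size=n_errors, replace=False)
        sample: dict[str, list[int]] = {}
        for idx in chosen:
            sid, members = pools[idx]
            sample.setdefault(sid, []).append(
                members[rng.integers(len(members))]
            )
        null = nearest_distances(sample)
        if not null:
            continue
        if ks_2samp(obs_arr, np.asarray(null)).pvalue < 0.05:
            significant += 1
    return observed, significant
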