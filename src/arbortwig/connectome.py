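"""Wiring diagrams: synapse-count-weighted directed graphs over skeletons,
compartment-typed edges, ranked-input curves, path search and morphology
summaries.

An edge A -> B aggregates every postsynaptic relation of B fed by a
presynaptic relation of A; its weight is the number of such relations (a
polyadic connector contacting the same target twice contributes two).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.optimize import least_squares

from .compartments import CompartmentLabels
from .polarity import PolaritySplit
from .skeleton import (
    Connector,
    Reconstruction,
    Skeleton,
    SkeletonError,
    cable_length,
)

EDGE_TYPES = ("axo-dendritic", "axo-axonic", "dendro-dendritic", "dendro-axonic")


def build_wiring_graph(recon: Reconstruction) -> nx.DiGraph:
    """Aggregate connector relations into a directed wiring graph.

    Nodes are skeleton ids; each edge stores ``weight`` (synapse count)
    and ``relations``, the contributing (connector_id, pre_node,
    post_node) triples.  Self-edges are kept and flagged ``autapse``.
    """
    g = nx.DiGraph()
    g.add_nodes_from(recon.skeletons)
    for conn in recon.connectors:
        pre = conn.presynaptic
        for rel in conn.postsynaptic:
            u, v = pre.skeleton_id, rel.skeleton_id
            if not g.has_edge(u, v):
                g.add_edge(u, v, weight=0, relations=[], autapse=(u == v))
            data = g[u][v]
            data["weight"] += 1
            data["relations"].append(
                (conn.connector_id, pre.node_id, rel.node_id)
            )
    return g


def classify_edge_compartments(
    graph: nx.DiGraph, splits: dict[str, PolaritySplit]
) -> dict:
    """Type every synapse by the compartments of its two endpoints.

    A synapse whose presynaptic node sits in the axon of its source and
    whose postsynaptic node sits in the dendrite of its target is
    axo-dendritic, and so on.  Synapses with an endpoint on a skeleton
    without a valid split are 'untyped'.  Returns per-edge type counts
    plus a global summary of counts and fractions.
    """
    per_edge: dict[tuple[str, str], dict[str, int]] = {}
    totals = {t: 0 for t in EDGE_TYPES}
    untyped = 0
    for u, v, data in graph.edges(data=True):
        counts = {t: 0 for t in EDGE_TYPES}
        for _cid, pre_node, post_node in data["relations"]:
            su, sv = splits.get(u), splits.get(v)
            if su is None or sv is None:
                untyped += 1
                continue
            pre_part = "axo" if pre_node in su.axon else "dendro"
            post_part = "dendritic" if post_node in sv.dendrite else "axonic"
            counts[f"{pre_part}-{post_part}"] += 1
        per_edge[(u, v)] = counts
        for t in EDGE_TYPES:
            totals[t] += counts[t]
    n_typed = sum(totals.values())
    fractions = {
        t: (totals[t] / n_typed if n_typed else float("nan"))
        for t in EDGE_TYPES
    }
    return {
        "per_edge": per_edge,
        "counts": totals,
        "fractions": fractions,
        "untyped": untyped,
        "n_typed": n_typed,
    }


@dataclass
class RankCurve:
    """Cumulative input fraction by ranked presynaptic partner."""

    target: str
    partners: list[str]
    weights: list[int]
    cumulative: list[float]
    rho: float

    def model(self, r: float) -> float:
        return rank_curve_model(r, self.rho)


def rank_curve_model(r, rho: float):
    """Saturating-exponential model of cumulative input share by rank."""
    return 1.0 - np.exp(-np.asarray(r, dtype=float) / rho)


def fit_rank_curve(cumulative: list[float]) -> float:
    """Least-squares fit of rho in 1 - exp(-r/rho) over ranks 1..K."""
    ranks = np.arange(1, len(cumulative) + 1, dtype=float)
    frac = np.asarray(cumulative, dtype=float)

    def resid(params):
        return rank_curve_model(ranks, params[0]) - frac

    guess = max(1.0, len(cumulative) / 3.0)
    sol = least_squares(resid, x0=[guess], bounds=([1e-9], [np.inf]))
    return float(sol.x[0])


def rank_input_curve(graph: nx.DiGraph, target: str) -> RankCurve:
    """Cumulative fraction of a neuron's inputs by ranked partner.

    Partners sort by synapse weight descending (ties by skeleton id);
    rho comes from an unweighted least-squares fit of the saturating
    exponential over all ranks.
    """
    in_edges = [(u, d["weight"]) for u, _v, d in graph.in_edges(target, data=True)]
    if not in_edges:
        raise SkeletonError(f"skeleton {target!r} has no inbound edges")
    in_edges.sort(key=lambda t: (-t[1], t[0]))
    partners = [u for u, _ in in_edges]
    weights = [w for _, w in in_edges]
    total = sum(weights)
    cumulative = list(np.cumsum(weights) / total)
    rho = fit_rank_curve(cumulative)
    return RankCurve(
        target=target,
        partners=partners,
        weights=weights,
        cumulative=cumulative,
        rho=rho,
    )


def path_search(
    graph: nx.DiGraph,
    sources: list[str],
    targets: list[str],
    max_hops: int,
    min_weight: int = 1,
) -> list[list[str]]:
    """All simple directed paths of <= max_hops over sufficiently strong edges.

    Edges below ``min_weight`` synapses are excluded before the search,
    the filter used when tracing multi-hop pathways between identified
    neurons.
    """
    if max_hops < 1:
        raise ValueError("max_hops must be >= 1")
    strong = nx.DiGraph()
    strong.add_nodes_from(graph.nodes)
    for u, v, d in graph.edges(data=True):
        if d["weight"] >= min_weight:
            strong.add_edge(u, v)
    paths = []
    target_set = set(targets)
    for src in sources:
        if src not in strong:
            continue
        for path in nx.all_simple_paths(
            strong, src, target_set & set(strong.nodes), cutoff=max_hops
        ):
            paths.append(list(path))
    paths.sort(key=lambda p: (len(p), p))
    return paths


def edge_twig_span(
    graph: nx.DiGraph, labels: dict[str, CompartmentLabels]
) -> tuple[dict[tuple[str, str], int], dict[int, dict[int, float]]]:
    """Number of distinct postsynaptic twigs each edge contacts (n_b).

    Synapses landing on backbone contribute no twig, so a backbone-only
    edge has n_b = 0.  Also returns the empirical twig-span distribution
    p(n_b; m): for each synapse count m, the fraction of m-synapse edges
    contacting each number of twigs.  This distribution parameterizes the
    edge-omission error model.
    """
    n_b: dict[tuple[str, str], int] = {}
    by_m: dict[int, dict[int, int]] = {}
    for u, v, data in graph.edges(data=True):
        lab = labels.get(v)
        if lab is None:
            continue
        twigs = set()
        for _cid, _pre_node, post_node in data["relations"]:
            t = lab.twig_of(post_node)
            if t is not None:
                twigs.add(t)
        m = data["weight"]
        n_b[(u, v)] = len(twigs)
        by_m.setdefault(m, {}).setdefault(len(twigs), 0)
        by_m[m][len(twigs)] += 1
    dist = {
        m: {nb: c / sum(cnt.values()) for nb, c in sorted(cnt.items())}
        for m, cnt in by_m.items()
    }
    return n_b, dist


def morphology_summary(
    skeleton: Skeleton, connectors: list[Connector]
) -> dict:
    """Coordinate-free morphology metrics of one arbor.

    Includes the two metrics most informative for matching hemisegmental
    homologs: cable off the main branch (total minus the longest
    root-to-leaf cable path) and the normalized input/output balance
    (inputs - outputs) / (inputs + outputs).
    """
    total = cable_length(skeleton)
    main_branch = 0.0
    for leaf in skeleton.leaves():
        main_branch = max(main_branch, skeleton.depth_nm(leaf) / 1000.0)
    from .polarity import synapse_io_nodes

    inputs, outputs = synapse_io_nodes(skeleton, connectors)
    n_in, n_out = len(inputs), len(outputs)
    balance = (n_in - n_out) / (n_in + n_out) if n_in + n_out else None
    return {
        "cable_um": total,
        "main_branch_um": main_branch,
        "off_main_branch_um": total - main_branch,
        "inputs": n_in,
        "outputs": n_out,
        "synapse_balance": balance,
        "n_branch_points": len(skeleton.branch_points()),
        "n_leaves": len(skeleton.leaves()),
        "n_nodes": len(skeleton),
    }


def edge_table(
    graph: nx.DiGraph,
    n_b: dict[tuple[str, str], int] | None = None,
    types: dict | None = None,
):
    """Edge list as a pandas DataFrame (pre, post, weight, n_b, type counts)."""
    import pandas as pd

    rows = []
    for u, v, d in graph.edges(data=True):
        row = {"pre": u, "post": v, "weight": d["weight"], "autapse": d["autapse"]}
        if n_b is not None:
            row["n_b"] = n_b.get((u, v))
        if types is not None:
            for t, c in types["per_edge"].get((u, v), {}).items():
                row[t] = c
        rows.append(row)
    return pd.DataFrame(rows).sort_values(
        ["weight", "pre", "post"], ascending=[False, True, True], ignore_index=True
    ) if rows else pd.DataFrame(
        columns=["pre", "post", "weight", "autapse"]
    )
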