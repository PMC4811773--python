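"""Shared fixtures: random tree factories and small reconstruction builders."""

from __future__ import annotations

import numpy as np
import pytest

from arbortwig.skeleton import (
    Connector,
    PartnerRelation,
    Reconstruction,
    Skeleton,
    SkeletonNode,
)


def make_random_tree(
    rng: np.random.Generator, n_nodes: int, spacing_nm: float = 1000.0
) -> Skeleton:
    """Random rooted tree with random edge lengths around ``spacing_nm``."""
    nodes = [SkeletonNode(1, None, (0.0, 0.0, 0.0))]
    positions = {1: np.zeros(3)}
    for nid in range(2, n_nodes + 1):
        parent = int(rng.integers(1, nid))
        step = rng.normal(size=3)
        step *= spacing_nm * rng.uniform(0.3, 2.0) / np.linalg.norm(step)
        pos = positions[parent] + step
        positions[nid] = pos
        nodes.append(SkeletonNode(nid, parent, tuple(pos)))
    return Skeleton("rand", nodes)


def chain_skeleton(
    edge_lengths_um: list[float], skeleton_id: str = "chain"
) -> Skeleton:
    """Unbranched chain with the given edge lengths, along +x."""
    nodes = [SkeletonNode(1, None, (0.0, 0.0, 0.0))]
    x = 0.0
    for i, length in enumerate(edge_lengths_um, start=2):
        x += length * 1000.0
        nodes.append(SkeletonNode(i, i - 1, (x, 0.0, 0.0)))
    return Skeleton(skeleton_id, nodes)


def monadic_connector(
    cid: str,
    pre: tuple[str, int],
    post: tuple[str, int],
    position=(0.0, 0.0, 0.0),
) -> Connector:
    return Connector(
        connector_id=cid,
        position=position,
        presynaptic=PartnerRelation(*pre),
        postsynaptic=(PartnerRelation(*post),),
    )


def synapses_on(
    skeleton_id: str,
    input_nodes: list[int],
    output_nodes: list[int],
    posts_per_output: int = 1,
) -> list[Connector]:
    """Connectors realizing the given input/output relation nodes.

    Inputs come from a placeholder skeleton 'ext'; outputs go to 'ext'.
    Callers that resolve against a Reconstruction must add 'ext'.
    """
    conns = []
    for i, nid in enumerate(input_nodes):
        conns.append(
            Connector(
                f"in{i}",
                (0.0, 0.0, 0.0),
                presynaptic=PartnerRelation("ext", 1),
                postsynaptic=(PartnerRelation(skeleton_id, nid),),
            )
        )
    for i, nid in enumerate(output_nodes):
        conns.append(
            Connector(
                f"out{i}",
                (0.0, 0.0, 0.0),
                presynaptic=PartnerRelation(skeleton_id, nid),
                postsynaptic=tuple(
                    PartnerRelation("ext", 1) for _ in range(posts_per_output)
                ),
            )
        )
    return conns


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
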