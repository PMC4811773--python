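"""Configuration-driven orchestration of the analysis modules.

``run_pipeline`` reads a reconstruction, runs the selected analyses with
explicit parameters and seeds, and writes deterministic CSV/JSON
artifacts plus a manifest; ``render_report`` condenses a bundle into one
Markdown + JSON summary.  Orchestration adds no numerics of its own —
every reported number is produced by a library function.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import pandas as pd

from . import __version__
from .compartments import (
    classify_spines,
    compartment_input_fractions,
    split_backbone_twigs,
    twig_statistics,
)
from .connectome import (
    build_wiring_graph,
    classify_edge_compartments,
    edge_table,
    edge_twig_span,
    morphology_summary,
)
from .polarity import (
    axon_dendrite_split,
    cluster_synapses,
    synapse_flow_centrality,
)
from .reliability import lint_reconstruction
from .skeleton import Reconstruction, SkeletonError, load_reconstruction, root_at_soma

logger = logging.getLogger("arbortwig")

ALL_MODULES = ("compartments", "polarity", "clustering", "graph", "lint")


@dataclass
class RunConfig:
    sidecar: str
    out_dir: str
    modules: tuple[str, ...] = ALL_MODULES
    bandwidth_um: float = 10.0
    spine_depth_um: float = 3.0
    seed: int = 0

    @staticmethod
    def from_file(path: str) -> "RunConfig":
        """Parse a TOML or JSON run configuration."""
        with open(path, "rb") as fh:
            raw = fh.read()
        if path.endswith(".toml"):
            import tomllib

            doc = tomllib.loads(raw.decode())
        else:
            doc = json.loads(raw.decode())
        return RunConfig(
            sidecar=doc["sidecar"],
            out_dir=doc.get("out_dir", "arbortwig_out"),
            modules=tuple(doc.get("modules", ALL_MODULES)),
            bandwidth_um=float(doc.get("bandwidth_um", 10.0)),
            spine_depth_um=float(doc.get("spine_depth_um", 3.0)),
            seed=int(doc.get("seed", 0)),
        )


def _analysis_skeletons(recon: Reconstruction) -> list[str]:
    """Skeletons worth analyzing: more than one node (not placeholders)."""
    return sorted(
        sid for sid, skel in recon.skeletons.items() if len(skel) > 1
    )


def run_pipeline(
    config: RunConfig, recon: Reconstruction | None = None
) -> dict:
    """Execute the configured analyses and write the artifact bundle.

    Returns the bundle: a dict of artifact names to file paths plus the
    in-memory results, with a manifest recording version, parameters and
    seeds for reproducibility.
    """
    unknown = set(config.modules) - set(ALL_MODULES)
    if unknown:
        raise SkeletonError(f"unknown pipeline modules: {sorted(unknown)}")
    if recon is None:
        recon = load_reconstruction(config.sidecar)
    os.makedirs(config.out_dir, exist_ok=True)
    bundle: dict = {"artifacts": {}, "results": {}}
    analysis_ids = _analysis_skeletons(recon)

    # re-root at the soma before any analysis
    for sid in analysis_ids:
        recon.skeletons[sid] = root_at_soma(
            recon.skeletons[sid], recon.tagset(sid)
        )

    labels = {}
    if {"compartments", "graph"} & set(config.modules):
        for sid in analysis_ids:
            lab = split_backbone_twigs(recon.skeletons[sid], recon.tagset(sid))
            twig_statistics(lab, recon.skeletons[sid], recon.connectors)
            lab.twigs = classify_spines(lab.twigs, config.spine_depth_um)
            labels[sid] = lab

    if "compartments" in config.modules:
        rows = []
        fractions = {}
        for sid in analysis_ids:
            for twig in labels[sid].twigs:
                rows.append(
                    {
                        "skeleton": sid,
                        "base": twig.base,
                        "cable_um": twig.cable_um,
                        "depth_um": twig.max_depth_um,
                        "inputs": twig.inputs,
                        "outputs": twig.outputs,
                        "is_spine": twig.is_spine,
                    }
                )
            try:
                fractions[sid] = compartment_input_fractions(
                    labels[sid], recon.connectors
                )
            except SkeletonError:
                fractions[sid] = None
        path = os.path.join(config.out_dir, "twigs.csv")
        pd.DataFrame(
            rows,
            columns=[
                "skeleton", "base", "cable_um", "depth_um",
                "inputs", "outputs", "is_spine",
            ],
        ).to_csv(path, index=False)
        bundle["artifacts"]["twigs"] = path
        bundle["results"]["twigs"] = rows
        bundle["results"]["input_fractions"] = fractions
        logger.info("compartments: %d twigs across %d skeletons",
                    len(rows), len(analysis_ids))

    splits = {}
    if {"polarity", "graph"} & set(config.modules):
        for sid in analysis_ids:
            skel = recon.skeletons[sid]
            flow = synapse_flow_centrality(skel, recon.connectors)
            try:
                splits[sid] = axon_dendrite_split(flow, skel, recon.connectors)
            except SkeletonError:
                splits[sid] = None

    if "polarity" in config.modules:
        out = {}
        for sid, split in splits.items():
            out[sid] = (
                None
                if split is None
                else {
                    "split_node": split.split_node,
                    "n_axon": len(split.axon),
                    "n_dendrite": len(split.dendrite),
                    "linker_cable_um": split.linker_cable_um,
                    "segregation_index": split.segregation,
                }
            )
        path = os.path.join(config.out_dir, "polarity.json")
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1, sort_keys=True)
        bundle["artifacts"]["polarity"] = path
        bundle["results"]["polarity"] = out

    if "clustering" in config.modules:
        rows = []
        for sid in analysis_ids:
            clustering = cluster_synapses(
                recon.skeletons[sid], recon.connectors, config.bandwidth_um
            )
            for i, cl in enumerate(clustering.clusters):
                rows.append(
                    {
                        "skeleton": sid,
                        "cluster": i,
                        "peak_node": cl["peak"],
                        "n_synapses": len(cl["synapses"]),
                    }
                )
        path = os.path.join(config.out_dir, "clusters.csv")
        pd.DataFrame(
            rows, columns=["skeleton", "cluster", "peak_node", "n_synapses"]
        ).to_csv(path, index=False)
        bundle["artifacts"]["clusters"] = path
        bundle["results"]["clusters"] = rows

    if "graph" in config.modules:
        graph = build_wiring_graph(recon)
        n_b, _dist = edge_twig_span(graph, labels)
        types = classify_edge_compartments(
            graph, {s: sp for s, sp in splits.items() if sp is not None}
        )
        table = edge_table(graph, n_b, types)
        path = os.path.join(config.out_dir, "edges.csv")
        table.to_csv(path, index=False)
        bundle["artifacts"]["edges"] = path
        bundle["results"]["edge_types"] = {
            "counts": types["counts"],
            "fractions": types["fractions"],
            "untyped": types["untyped"],
        }
        morph = {
            sid: morphology_summary(recon.skeletons[sid], recon.connectors)
            for sid in analysis_ids
        }
        bundle["results"]["morphology"] = morph

    if "lint" in config.modules:
        issues = lint_reconstruction(recon)
        out = [
            {
                "category": i.category,
                "skeleton": i.skeleton_id,
                "node": i.node_id,
                "connector": i.connector_id,
                "detail": i.detail,
            }
            for i in issues
        ]
        path = os.path.join(config.out_dir, "lint.json")
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1, sort_keys=True)
        bundle["artifacts"]["lint"] = path
        bundle["results"]["lint"] = out

    manifest = {
        "version": __version__,
        "modules": list(config.modules),
        "parameters": {
            "bandwidth_um": config.bandwidth_um,
            "spine_depth_um": config.spine_depth_um,
        },
        "seed": config.seed,
        "artifacts": dict(sorted(bundle["artifacts"].items())),
    }
    mpath = os.path.join(config.out_dir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    bundle["manifest"] = manifest
    bundle["artifacts"]["manifest"] = mpath
    return bundle


def render_report(bundle: dict) -> tuple[str, dict]:
    """Render a bundle as a Markdown document plus a JSON summary.

    Sections missing from the bundle are reported as absent rather than
    failing, so partial pipelines still produce a complete document.
    """
    results = bundle.get("results", {})
    lines = ["# arbortwig report", ""]
    summary: dict = {"sections": {}}

    def section(title: str, key: str, renderer) -> None:
        lines.append(f"## {title}")
        if key not in results:
            lines.append("_absent_")
            summary["sections"][key] = None
        else:
            renderer(results[key])
            summary["sections"][key] = results[key]
        lines.append("")

    section(
        "Morphology", "morphology",
        lambda m: lines.extend(
            f"- `{sid}`: {v['cable_um']:.1f} µm cable, "
            f"{v['inputs']} inputs / {v['outputs']} outputs"
            for sid, v in sorted(m.items())
        ),
    )
    section(
        "Compartments", "twigs",
        lambda rows: lines.append(
            f"{len(rows)} twigs; "
            f"{sum(1 for r in rows if r['is_spine'])} spine-like"
        ),
    )
    section(
        "Polarity", "polarity",
        lambda p: lines.extend(
            f"- `{sid}`: "
            + (
                "unpolarized"
                if v is None
                else f"split at node {v['split_node']}, "
                f"H = {v['segregation_index']:.3f}"
            )
            for sid, v in sorted(p.items())
        ),
    )
    section(
        "Synapse clusters", "clusters",
        lambda rows: lines.append(f"{len(rows)} clusters"),
    )
    section(
        "Wiring diagram", "edge_types",
        lambda t: lines.append(
            ", ".join(f"{k}: {v}" for k, v in sorted(t["counts"].items()))
            + f" ({t['untyped']} untyped)"
        ),
    )
    section(
        "Validation", "validation",
        lambda v: lines.append(json.dumps(v, sort_keys=True)),
    )
    section(
        "Lint", "lint",
        lambda rows: lines.append(f"{len(rows)} issues"),
    )
    for name, path in sorted(bundle.get("artifacts", {}).items()):
        lines.append(f"- artifact `{name}`: `{path}`")
    return "\n".join(lines) + "\n", summary
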