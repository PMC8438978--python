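"""End-to-end orchestration: counts -> network -> modules -> enrichment ->
perturbation, with a JSON run manifest for reproducibility auditing."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, enrichment, graph, inference, perturb, preprocess
from .data import CountMatrix, SampleSheet

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline inputs and stage parameters (published defaults)."""

    counts: str = ""
    samples: str = ""
    outdir: str = "run"
    gmt: str | None = None
    de_table: str | None = None

    max_zero_fraction: float = 0.25
    de_alpha: float = 0.05
    min_comparisons: int = 3
    ward_k: int = 6

    n_trees: int = 1000
    k_rule: str = "sqrt"
    min_weight: float | None = 0.00858
    top_density: float | None = None

    min_module_size: int = 12
    module_resolution: float = 1.0
    seed_gene: str | None = None
    neighborhood_order: int = 2

    perturb_classes: tuple[str, ...] = ()
    perturb_iterations: int = 10

    seed: int = 0

    @classmethod
    def from_yaml(cls, path, overrides: dict | None = None) -> "RunConfig":
        import yaml

        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload.update(overrides or {})
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "perturb_classes" in payload:
            payload["perturb_classes"] = tuple(payload["perturb_classes"])
        return cls(**payload)

    def stage_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(4)
        names = ["inference", "modules", "perturb", "extra"]
        return {n: int(s % (2**31 - 1)) for n, s in zip(names, state)}


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    manifest: dict = {
        "version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(config).items()},
        "stage_seeds": seeds,
        "inputs": {},
        "stages": {},
        "outputs": {},
    }

    def record_output(name: str, path: Path) -> None:
        manifest["outputs"][name] = str(path)

    stage = "read_inputs"
    try:
        cm = CountMatrix.from_tsv(config.counts)
        sheet = SampleSheet.from_tsv(config.samples)
        manifest["inputs"]["counts"] = {
            "path": config.counts,
            "sha256": _sha256(config.counts),
        }
        manifest["inputs"]["samples"] = {
            "path": config.samples,
            "sha256": _sha256(config.samples),
        }

        stage = "preprocess"
        logger.info(
            "preprocess: zero-filter=%.2f de_alpha=%.3g min_comparisons=%d",
            config.max_zero_fraction,
            config.de_alpha,
            config.min_comparisons,
        )
        cm_f = preprocess.filter_low_expression(cm, config.max_zero_fraction)
        if config.de_table:
            det = preprocess.differential_expression(
                cm_f, sheet, method="external_table", external_path=config.de_table
            )
        else:
            det = preprocess.differential_expression(cm_f, sheet)
        genes = preprocess.filter_de_genes(
            det, min_comparisons=config.min_comparisons, alpha=config.de_alpha
        )
        fc = preprocess.build_fc_matrix(det, genes)
        det.to_tsv(out / "de_table.tsv")
        fc.to_csv(out / "fc_matrix.tsv", sep="\t")
        record_output("de_table", out / "de_table.tsv")
        record_output("fc_matrix", out / "fc_matrix.tsv")
        k = min(config.ward_k, fc.shape[1])
        _, clusters = preprocess.ward_cluster_treatments(fc, k=k)
        clusters.rename_axis("treatment").to_frame().to_csv(
            out / "treatment_clusters.tsv", sep="\t"
        )
        record_output("treatment_clusters", out / "treatment_clusters.tsv")
        manifest["stages"]["preprocess"] = {
            "genes_input": cm.shape[0],
            "genes_after_zero_filter": cm_f.shape[0],
            "genes_after_de_filter": len(genes),
            "treatments": fc.shape[1],
        }

        stage = "infer"
        params = inference.InferenceParams(
            n_trees=config.n_trees, k_rule=config.k_rule, seed=seeds["inference"]
        )
        logger.info(
            "infer: trees=%d k_rule=%s threshold=%s top_density=%s",
            config.n_trees,
            config.k_rule,
            config.min_weight,
            config.top_density,
        )
        fc_std = inference.standardize_profiles(fc)
        wm = inference.infer_weight_matrix(fc_std, params)
        wm.to_sparse_tsv(out / "weights_sparse.tsv")
        record_output("weights_sparse", out / "weights_sparse.tsv")
        if wm.w.shape[0] <= 2000:
            wm.to_tsv(out / "weights.tsv")
            record_output("weights", out / "weights.tsv")
        el = inference.threshold_edges(
            wm, min_weight=config.min_weight, top_density=config.top_density
        )
        el.to_tsv(out / "edges.tsv")
        el.to_sif(out / "edges.sif")
        record_output("edges", out / "edges.tsv")
        record_output("edges_sif", out / "edges.sif")
        manifest["stages"]["infer"] = {
            "genes": wm.w.shape[0],
            "edges": len(el),
            "threshold": el.threshold,
        }

        stage = "analyze"
        net = graph.build_graph(el)
        main = graph.main_component(net)
        # Modules over the whole graph: planted structure can split into
        # disjoint components, and restricting to the main component would
        # silently drop entire modules.
        part = graph.detect_modules(
            net,
            min_size=config.min_module_size,
            seed=seeds["modules"],
            resolution=config.module_resolution,
        )
        ctab = graph.centrality(net, part)
        part.to_tsv(out / "modules.tsv")
        ctab.to_csv(out / "centrality.tsv", sep="\t", index=False)
        record_output("modules", out / "modules.tsv")
        record_output("centrality", out / "centrality.tsv")
        manifest["stages"]["analyze"] = {
            "nodes_total": net.number_of_nodes(),
            "nodes_main_component": main.number_of_nodes(),
            "edges_main_component": main.number_of_edges(),
            "n_modules": len(part.module_ids()),
            "module_sizes": [part.sizes()[m] for m in part.module_ids()],
        }
        if config.seed_gene and config.seed_gene in net:
            sub = graph.neighborhood(
                net, config.seed_gene, order=config.neighborhood_order
            )
            sub_el = inference.EdgeList(
                pd.DataFrame(
                    [
                        {"regulator": u, "target": v, "weight": d.get("weight", 1.0)}
                        for u, v, d in sub.subgraph.edges(data=True)
                    ],
                    columns=["regulator", "target", "weight"],
                ),
                threshold=el.threshold,
            )
            sub_el.to_sif(out / "subnetwork.sif")
            sub.node_table().to_csv(out / "subnetwork_nodes.tsv", sep="\t", index=False)
            record_output("subnetwork_sif", out / "subnetwork.sif")
            record_output("subnetwork_nodes", out / "subnetwork_nodes.tsv")
            manifest["stages"]["neighborhood"] = {
                "seed_gene": config.seed_gene,
                "order": config.neighborhood_order,
                "nodes": len(sub.nodes),
                "edges": sub.subgraph.number_of_edges(),
            }

        if config.gmt:
            stage = "enrich"
            manifest["inputs"]["gmt"] = {
                "path": config.gmt,
                "sha256": _sha256(config.gmt),
            }
            gsc = enrichment.read_gmt(config.gmt, universe=set(genes))
            module_genes = {m: set(part.genes_of(m)) for m in part.module_ids()}
            if module_genes and gsc.sets:
                enr = enrichment.overrepresentation(module_genes, gsc, alpha=0.05)
                enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                record_output("enrichment", out / "enrichment.tsv")
                manifest["stages"]["enrich"] = {
                    "n_tests": len(enr),
                    "n_enriched": int(enr["enriched"].sum()),
                }

            if config.perturb_classes:
                stage = "perturb"
                for cls in config.perturb_classes:
                    table = perturb.leave_class_out(
                        cm_f,
                        sheet,
                        cls,
                        genes,
                        gsc,
                        params,
                        iterations=config.perturb_iterations,
                        seed=seeds["perturb"],
                    )
                    path = out / f"perturbation_{cls}.tsv"
                    table.to_csv(path, sep="\t", index=False)
                    record_output(f"perturbation_{cls}", path)
                    manifest["stages"][f"perturb_{cls}"] = {"n_sets": len(table)}
        else:
            logger.warning("no GMT provided; enrichment and perturbation skipped")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
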