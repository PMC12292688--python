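"""End-to-end orchestration: catalog → network → centrality → core →
hubs → enrichment, with a JSON run manifest.

Every stage writes its artifact to the output directory before the next
stage starts, so a failed run leaves partial outputs behind (flagged in
the manifest). Outputs are deterministic for identical config + inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from netpharm import catalog, centrality, core, enrichment, hubs, ppi
from netpharm.config import RunConfig
from netpharm.errors import NetpharmError

logger = logging.getLogger(__name__)


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns (and writes) the run manifest."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "parameters": {
            "confidence": cfg.confidence,
            "core_metrics": list(cfg.core_metrics),
            "core_rounds": cfg.core_rounds,
            "core_comparison": cfg.core_comparison,
            "hub_k": cfg.hub_k,
            "hub_consensus": cfg.hub_consensus,
            "min_overlap": cfg.min_overlap,
            "seed": cfg.seed,
        },
        "inputs": {},
        "stages": {},
        "experimental_verification": "out of scope: in-silico analysis only",
        "status": "running",
    }
    for name in ("genecards", "drugbank", "pharmgkb", "pubchem", "edges", "gmt", "background"):
        p = getattr(cfg, name)
        if p is not None:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(Path(p))}

    stage = "catalog"
    try:
        # --- stage 1: gene catalog -------------------------------------
        disease_sources = [catalog.read_source_table(cfg.genecards, "genecards")]
        if cfg.pharmgkb:
            disease_sources.append(catalog.read_source_table(cfg.pharmgkb, "pharmgkb"))
        if cfg.pubchem:
            disease_sources.append(catalog.read_source_table(cfg.pubchem, "pubchem"))
        disease_catalog = catalog.merge_catalogs(disease_sources)
        catalog.write_catalog(disease_catalog, out / "disease_catalog.tsv")

        compound_targets = None
        if cfg.drugbank:
            compound_targets = [
                r.symbol for r in catalog.read_source_table(cfg.drugbank, "drugbank")
            ]
        gene_list = catalog.analysis_gene_list(disease_catalog, compound_targets)
        (out / "analysis_genes.txt").write_text(
            "\n".join(sorted(gene_list)) + "\n", encoding="utf-8"
        )
        manifest["stages"]["catalog"] = {
            "disease_genes": len(disease_catalog),
            "compound_targets": len(compound_targets) if compound_targets else None,
            "analysis_genes": len(gene_list),
            "artifact": "disease_catalog.tsv",
        }

        # --- stage 2: PPI network --------------------------------------
        stage = "network"
        edges = ppi.read_string_edges(cfg.edges)
        graph = ppi.build_graph(
            edges,
            gene_list,
            threshold=cfg.confidence,
            keep_isolates=cfg.keep_isolates,
            lcc_only=cfg.lcc_only,
            source=str(cfg.edges),
        )
        ppi.export_graph(graph, out / "network.graphml", "graphml")
        ppi.export_graph(graph, out / "network_edges.tsv", "edge-tsv")
        manifest["stages"]["network"] = {
            "nodes": graph.number_of_nodes(),
            "edges": graph.number_of_edges(),
            "threshold": cfg.confidence,
            "artifact": "network.graphml",
        }

        # --- stage 3: centrality profiles ------------------------------
        stage = "centrality"
        profiles = centrality.profile_all(graph)
        centrality.write_profiles(profiles, out / "centrality.tsv")
        manifest["stages"]["centrality"] = {
            "nodes": len(profiles),
            "artifact": "centrality.tsv",
        }

        # --- stage 4: core extraction ----------------------------------
        stage = "core"
        core_cfg = core.CoreExtractionConfig(
            metrics=cfg.core_metrics,
            rounds=cfg.core_rounds,
            comparison=cfg.core_comparison,
            combine=cfg.core_combine,
        )
        core_graph, reports = core.extract_core(graph, core_cfg)
        pd.DataFrame(core.report_rows(reports)).to_csv(
            out / "core_rounds.tsv", sep="\t", index=False
        )
        ppi.export_graph(core_graph, out / "core_edges.tsv", "edge-tsv")
        manifest["stages"]["core"] = {
            "nodes_per_round": [r.nodes_after for r in reports],
            "core_nodes": core_graph.number_of_nodes(),
            "artifact": "core_edges.tsv",
        }

        # --- stage 5: hub ranking (on the full network) ----------------
        stage = "hubs"
        by_degree = hubs.rank_hubs(graph, "degree", cfg.hub_k)
        by_mcc = hubs.rank_hubs(graph, "mcc", cfg.hub_k)
        hubs.write_ranking(by_degree, out / "hubs_degree.tsv")
        hubs.write_ranking(by_mcc, out / "hubs_mcc.tsv")
        consensus = hubs.consensus_hubs(by_degree, by_mcc, cfg.hub_consensus)
        (out / "hubs_consensus.txt").write_text(
            "\n".join(sorted(consensus)) + "\n", encoding="utf-8"
        )
        subnet = hubs.hub_subnetwork(graph, consensus & set(graph.nodes()))
        if subnet.number_of_nodes():
            ppi.export_graph(subnet, out / "hub_subnetwork.graphml", "graphml")
        manifest["stages"]["hubs"] = {
            "degree_top": [s for _, s, _ in by_degree.entries],
            "mcc_top": [s for _, s, _ in by_mcc.entries],
            "consensus": sorted(consensus),
            "artifact": "hubs_degree.tsv",
        }

        # --- stage 6: pathway enrichment -------------------------------
        stage = "enrichment"
        pathways = enrichment.read_gmt(cfg.gmt)
        if cfg.background:
            background = {
                line.strip().upper()
                for line in Path(cfg.background).read_text(encoding="utf-8").splitlines()
                if line.strip()
            }
        else:
            # default universe: every gene the GMT collection mentions,
            # plus the list itself so the containment precondition holds
            background = set().union(*(p.members for p in pathways)) | set(gene_list)
        rows = enrichment.run_ora(gene_list, pathways, background, cfg.min_overlap)
        enrichment.export_enrichment(rows, out / "enrichment.tsv")
        manifest["stages"]["enrichment"] = {
            "pathways_tested": len(pathways),
            "pathways_reported": len(rows),
            "background_size": len(background),
            "artifact": "enrichment.tsv",
        }
    except NetpharmError as err:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = str(err)
        _write_manifest(manifest, out)
        raise NetpharmError(f"stage {stage!r} failed: {err}") from err

    manifest["status"] = "ok"
    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
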