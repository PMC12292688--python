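"""Synthetic dataset generator with planted, recoverable structure.

Produces everything the pipeline consumes — a relevance-scored disease-gene
table, a drug→target table, two plain gene tables, a STRING-style scored
edge list, and a GMT pathway collection — together with the planted truth
(hub genes and enriched pathways) needed for recovery testing.

Design of the planted structure:

* The PPI network lives on the disease ∩ compound gene list and follows a
  preferential-attachment scheme (Barabási–Albert, m=2) so the degree
  distribution is heavy-tailed. Planted hubs occupy the earliest (and
  therefore highest-expected-degree) attachment positions and are
  additionally wired into a clique, which gives them top MCC as well as
  top degree.
* True edges carry combined scores drawn uniformly from {401..999}; an
  equal number of decoy non-edges is added with scores in {1..399}, so the
  0.400 confidence threshold is exercised by every scenario.
* Each planted-enriched pathway draws a controllable fraction of its
  members from the analysis gene list (stochastic rounding keeps the
  expected fraction exact) and the remainder uniformly from outside the
  list; null pathways draw uniformly from the whole background.

All randomness derives from one explicit integer seed; identical seeds
yield byte-identical scenario files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from netpharm.errors import ParameterError
from netpharm.ppi import InteractionEdge

TRUE_SCORE_RANGE = (401, 999)
DECOY_SCORE_RANGE = (1, 399)

#: fraction of min(n_dis, n_cmp) that ends up in the disease ∩ compound list
OVERLAP_FRACTION = 0.6
#: fraction of pathways that carry planted enrichment (at least one)
ENRICHED_FRACTION = 0.25
#: extra neighbors per planted hub, as a fraction of the analysis list
HUB_BOOST_FRACTION = 0.25
PATHWAY_SIZE_RANGE = (20, 80)


@dataclass(frozen=True)
class SyntheticScenario:
    universe: tuple[str, ...]
    disease_genes: dict[str, float]  # symbol -> relevance score
    compound_targets: tuple[str, ...]
    edges: tuple[InteractionEdge, ...]
    pathways: dict[str, frozenset[str]]
    planted_hubs: tuple[str, ...]
    planted_enriched_pathways: tuple[str, ...]
    seed: int

    @property
    def analysis_list(self) -> frozenset[str]:
        return frozenset(self.disease_genes) & frozenset(self.compound_targets)


def _gene_symbols(n: int) -> list[str]:
    return [f"SYN{i:05d}" for i in range(n)]


def generate_scenario(
    n_bg: int = 1000,
    n_dis: int = 120,
    n_cmp: int = 90,
    n_hubs: int = 5,
    n_pathways: int = 20,
    enrichment_effect: float = 0.5,
    seed: int = 0,
) -> SyntheticScenario:
    """Generate one fully specified scenario from a single seed."""
    if n_hubs > min(n_dis, n_cmp):
        raise ParameterError(f"n_hubs={n_hubs} exceeds min(n_dis, n_cmp)")
    if not 0.0 < enrichment_effect <= 1.0:
        raise ParameterError(f"enrichment_effect must be in (0, 1], got {enrichment_effect}")
    if n_bg < n_dis + n_cmp:
        raise ParameterError(f"n_bg={n_bg} too small for n_dis + n_cmp")
    if min(n_bg, n_dis, n_cmp, n_pathways) < 1 or n_hubs < 1:
        raise ParameterError("all sizes must be positive")

    rng = np.random.default_rng(seed)
    universe = _gene_symbols(n_bg)

    disease_symbols = sorted(rng.choice(n_bg, size=n_dis, replace=False).tolist())
    disease = [universe[i] for i in disease_symbols]
    scores = {g: round(float(s), 2) for g, s in zip(disease, rng.uniform(1.0, 100.0, n_dis))}

    n_overlap = max(n_hubs, int(round(OVERLAP_FRACTION * min(n_dis, n_cmp))))
    overlap = [disease[i] for i in rng.choice(n_dis, size=n_overlap, replace=False)]
    hubs = sorted(overlap[:n_hubs])
    non_disease = [g for g in universe if g not in scores]
    outside = rng.choice(len(non_disease), size=n_cmp - n_overlap, replace=False)
    compound = sorted(overlap + [non_disease[i] for i in outside])

    edges = _planted_edges(sorted(overlap), hubs, rng)
    pathways, enriched = _planted_pathways(
        universe, sorted(set(overlap)), n_pathways, enrichment_effect, rng
    )

    return SyntheticScenario(
        universe=tuple(universe),
        disease_genes=scores,
        compound_targets=tuple(compound),
        edges=tuple(edges),
        pathways=pathways,
        planted_hubs=tuple(hubs),
        planted_enriched_pathways=tuple(enriched),
        seed=seed,
    )


def _planted_edges(
    analysis: list[str], hubs: list[str], rng: np.random.Generator
) -> list[InteractionEdge]:
    """Scale-free topology over the analysis list, hubs attached first."""
    n = len(analysis)
    ba_m = min(2, n - 1) if n > 1 else 0
    if ba_m == 0:
        return []
    # node order: hubs first so preferential attachment concentrates on them
    others = [g for g in analysis if g not in set(hubs)]
    order = list(hubs) + [others[i] for i in rng.permutation(len(others))]
    ba_seed = int(rng.integers(0, 2**31 - 1))
    topology = nx.barabasi_albert_graph(n, ba_m, seed=ba_seed)
    relabel = {i: order[i] for i in range(n)}
    topology = nx.relabel_nodes(topology, relabel)
    for i, a in enumerate(hubs):
        for b in hubs[i + 1 :]:
            topology.add_edge(a, b)
    # boost each hub with extra random attachments so planted hubs clearly
    # dominate every centrality, not just expected degree
    n_boost = int(round(HUB_BOOST_FRACTION * n))
    for hub in hubs:
        candidates = [g for g in others if not topology.has_edge(hub, g)]
        if not candidates or n_boost == 0:
            continue
        picked = rng.choice(len(candidates), size=min(n_boost, len(candidates)), replace=False)
        for i in picked:
            topology.add_edge(hub, candidates[i])

    true_pairs = sorted(tuple(sorted(e)) for e in topology.edges())
    lo, hi = TRUE_SCORE_RANGE
    edges = [
        InteractionEdge(a, b, int(s))
        for (a, b), s in zip(true_pairs, rng.integers(lo, hi + 1, len(true_pairs)))
    ]

    # decoy (sub-threshold) edges at a 1:1 ratio with true edges
    taken = set(true_pairs)
    candidates = [
        (analysis[i], analysis[j])
        for i in range(n)
        for j in range(i + 1, n)
        if (analysis[i], analysis[j]) not in taken
    ]
    n_decoys = min(len(true_pairs), len(candidates))
    picked = rng.choice(len(candidates), size=n_decoys, replace=False)
    lo, hi = DECOY_SCORE_RANGE
    decoy_scores = rng.integers(lo, hi + 1, n_decoys)
    edges += [
        InteractionEdge(*candidates[i], int(s)) for i, s in zip(picked, decoy_scores)
    ]
    return sorted(edges)


def _planted_pathways(
    universe: list[str],
    analysis: list[str],
    n_pathways: int,
    effect: float,
    rng: np.random.Generator,
) -> tuple[dict[str, frozenset[str]], list[str]]:
    n_enriched = max(1, int(round(ENRICHED_FRACTION * n_pathways)))
    n_enriched = min(n_enriched, n_pathways)
    off_list = [g for g in universe if g not in set(analysis)]
    lo, hi = PATHWAY_SIZE_RANGE

    pathways: dict[str, frozenset[str]] = {}
    enriched_ids: list[str] = []
    for p in range(n_pathways):
        pid = f"PW{p:04d}"
        size = int(rng.integers(lo, hi + 1))
        if p < n_enriched:
            # stochastic rounding keeps the expected on-list fraction = effect
            target = effect * size
            n_on = int(target) + (1 if rng.random() < target - int(target) else 0)
            n_on = min(n_on, len(analysis), size)
            on = rng.choice(len(analysis), size=n_on, replace=False)
            n_off = min(size - n_on, len(off_list))
            off = rng.choice(len(off_list), size=n_off, replace=False)
            members = {analysis[i] for i in on} | {off_list[i] for i in off}
            enriched_ids.append(pid)
        else:
            picked = rng.choice(len(universe), size=min(size, len(universe)), replace=False)
            members = {universe[i] for i in picked}
        pathways[pid] = frozenset(members)
    return pathways, enriched_ids


def write_scenario(scenario: SyntheticScenario, directory: str | Path) -> dict[str, Path]:
    """Write the scenario as the seven plain-text pipeline inputs.

    Returns a manifest mapping logical names to paths: genecards,
    drugbank, pharmgkb, pubchem, string_edges, pathways, truth.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scenario.seed + 1)  # file-composition randomness only

    paths = {
        "genecards": directory / "genecards.tsv",
        "drugbank": directory / "drugbank.tsv",
        "pharmgkb": directory / "pharmgkb.tsv",
        "pubchem": directory / "pubchem.tsv",
        "string_edges": directory / "string_edges.tsv",
        "pathways": directory / "pathways.gmt",
        "truth": directory / "truth.json",
    }

    disease = sorted(scenario.disease_genes)
    with open(paths["genecards"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("symbol\trelevance_score\n")
        for g in disease:
            fh.write(f"{g}\t{scenario.disease_genes[g]}\n")

    with open(paths["drugbank"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("drug\ttarget\n")
        for i, g in enumerate(scenario.compound_targets):
            fh.write(f"DRUG{i % 7:02d}\t{g}\n")

    # the two plain gene tables are random disease subsets: they exercise
    # multi-source merging without changing the disease gene set
    for name in ("pharmgkb", "pubchem"):
        subset = sorted(
            disease[i] for i in rng.choice(len(disease), size=len(disease) // 2, replace=False)
        )
        with open(paths[name], "w", encoding="utf-8", newline="\n") as fh:
            fh.write("symbol\n")
            fh.writelines(f"{g}\n" for g in subset)

    with open(paths["string_edges"], "w", encoding="utf-8", newline="\n") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for a, b, s in scenario.edges:
            fh.write(f"{a}\t{b}\t{s}\n")

    with open(paths["pathways"], "w", encoding="utf-8", newline="\n") as fh:
        for pid in sorted(scenario.pathways):
            members = "\t".join(sorted(scenario.pathways[pid]))
            fh.write(f"{pid}\tsynthetic pathway {pid}\t{members}\n")

    truth = {
        "seed": scenario.seed,
        "planted_hubs": list(scenario.planted_hubs),
        "planted_enriched_pathways": list(scenario.planted_enriched_pathways),
        "analysis_list": sorted(scenario.analysis_list),
        "n_background": len(scenario.universe),
    }
    with open(paths["truth"], "w", encoding="utf-8", newline="\n") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
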