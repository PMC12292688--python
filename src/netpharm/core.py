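"""Critical-subnetwork extraction by iterated median-threshold filtering.

Each round computes a panel of centralities on the *current* graph, takes
the per-metric median over its nodes, and keeps only nodes whose value
exceeds the median on every selected metric (strict comparison by default;
an inclusive fallback exists for degenerate ties). The induced subgraph is
then re-profiled for the next round, so repeating the identical filter
keeps narrowing the core.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

import networkx as nx

from netpharm import centrality
from netpharm.errors import EmptyCoreError, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_METRICS = ("degree", "betweenness", "closeness", "eigenvector", "lac")


@dataclass(frozen=True)
class CoreExtractionConfig:
    metrics: tuple[str, ...] = DEFAULT_METRICS
    rounds: int = 2
    comparison: str = "strict"  # strict: > median; inclusive: >= median
    combine: str = "all"  # all: conjunction over metrics; any: disjunction

    def __post_init__(self) -> None:
        if not self.metrics:
            raise ParameterError("core extraction needs at least one metric")
        for m in self.metrics:
            if m not in centrality.PROFILE_COLUMNS[1:]:
                raise ParameterError(f"unknown core metric {m!r}")
        if self.rounds < 1:
            raise ParameterError(f"rounds must be >= 1, got {self.rounds}")
        if self.comparison not in ("strict", "inclusive"):
            raise ParameterError(f"comparison must be strict|inclusive, got {self.comparison!r}")
        if self.combine not in ("all", "any"):
            raise ParameterError(f"combine must be all|any, got {self.combine!r}")


@dataclass
class RoundReport:
    round_index: int
    medians: dict[str, float] = field(default_factory=dict)
    nodes_before: int = 0
    nodes_after: int = 0


def median_filter_round(
    g: nx.Graph,
    cfg: CoreExtractionConfig,
    round_index: int = 1,
) -> tuple[nx.Graph, RoundReport]:
    """Apply one median-threshold round; returns the induced subgraph.

    Medians are taken over the current graph's own nodes. Raises
    :class:`EmptyCoreError` naming the responsible metric if no node
    survives.
    """
    if g.number_of_nodes() == 0:
        raise EmptyCoreError(f"round {round_index}: input graph is empty")
    report = RoundReport(round_index=round_index, nodes_before=g.number_of_nodes())

    passed_per_metric: dict[str, set[str]] = {}
    for metric in cfg.metrics:
        values = centrality.metric_values(g, metric)
        med = statistics.median(values.values())
        report.medians[metric] = float(med)
        if cfg.comparison == "strict":
            passed = {v for v, x in values.items() if x > med}
        else:
            passed = {v for v, x in values.items() if x >= med}
        passed_per_metric[metric] = passed

    if cfg.combine == "all":
        survivors = set(g.nodes())
        for passed in passed_per_metric.values():
            survivors &= passed
    else:
        survivors = set()
        for passed in passed_per_metric.values():
            survivors |= passed

    if not survivors:
        emptiers = [m for m, p in passed_per_metric.items() if not p]
        culprit = emptiers[0] if emptiers else "the conjunction of " + ",".join(cfg.metrics)
        raise EmptyCoreError(
            f"round {round_index}: no node exceeds the median on {culprit} "
            f"(medians: {report.medians}); consider comparison='inclusive'"
        )
    report.nodes_after = len(survivors)
    logger.info(
        "core round %d: %d -> %d nodes (medians %s)",
        round_index,
        report.nodes_before,
        report.nodes_after,
        report.medians,
    )
    sub = g.subgraph(survivors).copy()
    return sub, report


def extract_core(
    g: nx.Graph, cfg: CoreExtractionConfig | None = None
) -> tuple[nx.Graph, list[RoundReport]]:
    """Run ``cfg.rounds`` median-filter rounds, re-profiling each time."""
    cfg = cfg or CoreExtractionConfig()
    reports: list[RoundReport] = []
    current = g
    for i in range(1, cfg.rounds + 1):
        try:
            current, report = median_filter_round(current, cfg, round_index=i)
        except EmptyCoreError as err:
            raise EmptyCoreError(f"core extraction aborted at round {i}: {err}") from err
        reports.append(report)
    return current, reports


def report_rows(reports: list[RoundReport]) -> list[dict]:
    """Flatten round reports to (round, metric, median, nodes_before, nodes_after)."""
    rows = []
    for rep in reports:
        for metric, med in rep.medians.items():
            rows.append(
                {
                    "round": rep.round_index,
                    "metric": metric,
                    "median": med,
                    "nodes_before": rep.nodes_before,
                    "nodes_after": rep.nodes_after,
                }
            )
    return rows
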