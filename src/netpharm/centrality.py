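"""Node centrality measures for undirected PPI graphs.

Six measures: degree, betweenness, closeness, eigenvector, LAC (local
average connectivity — the mean degree of a node's neighbors within the
subgraph those neighbors induce), and MCC (maximal clique centrality —
the sum of (|C| − 1)! over the maximal cliques C containing the node).

Degree, betweenness and closeness are delegated to networkx; eigenvector
centrality is a deterministic per-component power iteration so that scores
have unit Euclidean norm within each connected component; LAC and MCC are
implemented here (MCC on top of Bron–Kerbosch maximal-clique enumeration).
All measures treat the graph as unweighted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from netpharm.errors import CliqueCapError, ConvergenceError

#: fixed column order for profile tables
PROFILE_COLUMNS = (
    "node",
    "degree",
    "betweenness",
    "closeness",
    "eigenvector",
    "lac",
    "mcc",
)


@dataclass(frozen=True)
class CentralityProfile:
    node: str
    degree: int
    betweenness: float
    closeness: float
    eigenvector: float
    lac: float
    mcc: int


def degree_centrality(g: nx.Graph) -> dict[str, int]:
    """Raw degree: the number of immediate neighbors."""
    return {v: int(d) for v, d in g.degree()}


def betweenness_centrality(g: nx.Graph, normalized: bool = False) -> dict[str, float]:
    """Shortest-path betweenness over unordered node pairs.

    Unnormalized by default; ``normalized`` divides by (n−1)(n−2)/2.
    """
    return {
        v: float(c)
        for v, c in nx.betweenness_centrality(g, normalized=normalized).items()
    }


def closeness_centrality(g: nx.Graph, harmonic: bool = False) -> dict[str, float]:
    """Within-component closeness: (k−1)/Σd over a component of size k.

    Singleton components score 0. With ``harmonic`` the harmonic variant
    Σ 1/d(v,u) is returned instead (also confined to the component).
    """
    if harmonic:
        return {v: float(c) for v, c in nx.harmonic_centrality(g).items()}
    return {
        v: float(c)
        for v, c in nx.closeness_centrality(g, wf_improved=False).items()
    }


def eigenvector_centrality(
    g: nx.Graph, tol: float = 1e-10, max_iter: int = 10000
) -> dict[str, float]:
    """Principal-eigenvector centrality by per-component power iteration.

    Each connected component with at least one edge is iterated separately
    from an all-ones start vector until successive L2-normalized score
    vectors differ by less than ``tol`` in max-norm; the component's scores
    are nonnegative with unit Euclidean norm. Isolated nodes score 0.
    """
    scores: dict[str, float] = {v: 0.0 for v in g.nodes()}
    for component in nx.connected_components(g):
        nodes = sorted(component)
        if len(nodes) == 1:
            continue
        # iterate on A + I: same principal eigenvector as A, but the spectral
        # shift prevents oscillation on bipartite components
        adjacency = nx.to_numpy_array(g, nodelist=nodes, dtype=float)
        adjacency += np.eye(len(nodes))
        x = np.ones(len(nodes)) / math.sqrt(len(nodes))
        for _ in range(max_iter):
            y = adjacency @ x
            norm = np.linalg.norm(y)
            if norm == 0.0:  # pragma: no cover - only bipartite degenerate starts
                break
            y /= norm
            if np.max(np.abs(y - x)) < tol:
                x = y
                break
            x = y
        else:
            raise ConvergenceError(
                f"eigenvector power iteration did not converge in {max_iter} "
                f"iterations on a component of {len(nodes)} nodes"
            )
        for v, value in zip(nodes, x):
            scores[v] = float(abs(value))
    return scores


def lac(g: nx.Graph) -> dict[str, float]:
    """Local average connectivity.

    LAC(v) = mean induced degree of v's neighbors in the subgraph induced
    by N(v); degree-0 nodes score 0.
    """
    out: dict[str, float] = {}
    for v in g.nodes():
        neighbors = list(g.neighbors(v))
        if not neighbors:
            out[v] = 0.0
            continue
        neighborhood = set(neighbors)
        induced_degree_sum = 0
        for u in neighbors:
            induced_degree_sum += sum(1 for w in g.neighbors(u) if w in neighborhood)
        out[v] = induced_degree_sum / len(neighbors)
    return out


def mcc(g: nx.Graph, clique_cap: int = 2_000_000) -> dict[str, int]:
    """Maximal clique centrality: Σ (|C|−1)! over maximal cliques C ∋ v.

    Maximal cliques are enumerated exactly (Bron–Kerbosch with pivoting);
    enumeration aborts with :class:`CliqueCapError` past ``clique_cap``
    cliques to guard against pathological inputs. Isolated nodes score 0.
    For a node whose maximal cliques are all edges, MCC equals its degree.
    """
    out: dict[str, int] = {v: 0 for v in g.nodes()}
    for count, clique in enumerate(nx.find_cliques(g), start=1):
        if count > clique_cap:
            raise CliqueCapError(
                f"more than {clique_cap} maximal cliques; raise clique_cap "
                "if this graph is legitimate"
            )
        if len(clique) == 1:
            continue
        weight = math.factorial(len(clique) - 1)
        for v in clique:
            out[v] += weight
    return out


_METRIC_FUNCTIONS = {
    "degree": degree_centrality,
    "betweenness": betweenness_centrality,
    "closeness": closeness_centrality,
    "eigenvector": eigenvector_centrality,
    "lac": lac,
    "mcc": mcc,
}


def metric_values(g: nx.Graph, metric: str) -> Mapping[str, float]:
    """Compute one named centrality map (metric ∈ PROFILE_COLUMNS[1:])."""
    try:
        fn = _METRIC_FUNCTIONS[metric]
    except KeyError:
        raise ValueError(f"unknown centrality metric {metric!r}") from None
    return fn(g)


def profile_all(g: nx.Graph) -> list[CentralityProfile]:
    """One profile per node, in lexicographic node order."""
    if g.number_of_nodes() == 0:
        return []
    deg = degree_centrality(g)
    btw = betweenness_centrality(g)
    clo = closeness_centrality(g)
    eig = eigenvector_centrality(g)
    lac_ = lac(g)
    mcc_ = mcc(g)
    return [
        CentralityProfile(
            node=v,
            degree=deg[v],
            betweenness=btw[v],
            closeness=clo[v],
            eigenvector=eig[v],
            lac=lac_[v],
            mcc=mcc_[v],
        )
        for v in sorted(g.nodes())
    ]


def profiles_frame(profiles: list[CentralityProfile]) -> pd.DataFrame:
    """Profiles as a DataFrame in the fixed column order."""
    return pd.DataFrame(
        [
            [p.node, p.degree, p.betweenness, p.closeness, p.eigenvector, p.lac, p.mcc]
            for p in profiles
        ],
        columns=list(PROFILE_COLUMNS),
    )


def write_profiles(profiles: list[CentralityProfile], path: str | Path) -> None:
    """Write the profile table as TSV, reals at 6 significant digits."""
    frame = profiles_frame(profiles)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
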