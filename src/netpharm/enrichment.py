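"""Pathway over-representation analysis with fold enrichment and BH-FDR.

Given a gene list, a GMT pathway collection and a background universe,
each pathway is tested with the one-sided (upper-tail) hypergeometric
test; p-values are adjusted with the Benjamini–Hochberg step-up procedure
across all tested pathways. Fold enrichment is the effect size
(m/k)/(K/N): the fraction of list genes in the pathway over the fraction
of background genes in the pathway.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from netpharm.errors import ParameterError, ParseError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PathwayAnnotation:
    pathway_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.pathway_id}: pathway has no members")


@dataclass(frozen=True)
class EnrichmentRow:
    """One pathway's ORA result.

    m = overlap count, K = pathway size (within background), k = list
    size, N = background size.
    """

    pathway_id: str
    name: str
    n_genes_overlap: int
    pathway_size: int
    list_size: int
    background_size: int
    fold_enrichment: float
    p_value: float
    fdr: float

    @property
    def neg_log10_fdr(self) -> float:
        return -math.log10(self.fdr)


def read_gmt(path: str | Path) -> list[PathwayAnnotation]:
    """Read a GMT file: one gene set per line (id, description, members)."""
    path = Path(path)
    annotations: list[PathwayAnnotation] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}: line {lineno}: GMT lines need >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            members = frozenset(f.strip().upper() for f in fields[2:] if f.strip())
            if not members:
                raise ParseError(f"{path}: line {lineno}: gene set has no members")
            annotations.append(
                PathwayAnnotation(pathway_id=fields[0], name=fields[1], members=members)
            )
    if not annotations:
        logger.warning("%s: empty GMT file", path)
    return annotations


def _check_counts(m: int, k: int, K: int, N: int) -> None:
    if not (0 <= m <= min(k, K)):
        raise ParameterError(f"infeasible overlap m={m} for k={k}, K={K}")
    if not (0 < k <= N and 0 < K <= N):
        raise ParameterError(f"infeasible sizes k={k}, K={K}, N={N}")


def hypergeom_pvalue(m: int, k: int, K: int, N: int) -> float:
    """Upper-tail P(X >= m) for X ~ Hypergeometric(N, K, k)."""
    _check_counts(m, k, K, N)
    if m == 0:
        return 1.0
    return float(stats.hypergeom.sf(m - 1, N, K, k))


def fold_enrichment(m: int, k: int, K: int, N: int) -> float:
    """(m/k) / (K/N): list-fraction over background-fraction."""
    _check_counts(m, k, K, N)
    return (m / k) / (K / N)


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    n = len(pvalues)
    for p in pvalues:
        if not 0.0 < p <= 1.0:
            raise ParameterError(f"p-value {p} outside (0, 1]")
    order = sorted(range(n), key=lambda i: pvalues[i])
    adjusted = [0.0] * n
    running_min = 1.0
    for rank_from_end in range(n, 0, -1):
        i = order[rank_from_end - 1]
        # multiply by the ratio so rank n maps p -> p exactly
        running_min = min(running_min, pvalues[i] * (n / rank_from_end))
        adjusted[i] = running_min
    return adjusted


def run_ora(
    gene_list: Iterable[str],
    pathways: Sequence[PathwayAnnotation],
    background: Iterable[str],
    min_overlap: int = 2,
) -> list[EnrichmentRow]:
    """Test every pathway against the gene list; rows sorted by FDR.

    Pathway members outside the background are dropped before testing;
    pathways with overlap below ``min_overlap`` (or emptied by the
    background restriction) are excluded. FDR is adjusted across *all*
    tested pathways, not only the reported ones.
    """
    background = frozenset(background)
    if not background:
        raise ParameterError("empty background universe")
    gene_list = frozenset(gene_list)
    if not gene_list <= background:
        raise ParameterError(
            f"{len(gene_list - background)} list genes missing from the background"
        )
    if min_overlap < 0:
        raise ParameterError(f"min_overlap must be >= 0, got {min_overlap}")

    N = len(background)
    k = len(gene_list)
    tested: list[tuple[PathwayAnnotation, int, int, float]] = []
    for pw in pathways:
        members = pw.members & background
        if not members:
            continue
        m = len(gene_list & members)
        K = len(members)
        tested.append((pw, m, K, hypergeom_pvalue(m, k, K, N)))

    fdrs = bh_fdr([p for *_, p in tested])
    rows = [
        EnrichmentRow(
            pathway_id=pw.pathway_id,
            name=pw.name,
            n_genes_overlap=m,
            pathway_size=K,
            list_size=k,
            background_size=N,
            fold_enrichment=fold_enrichment(m, k, K, N),
            p_value=p,
            fdr=fdr,
        )
        for (pw, m, K, p), fdr in zip(tested, fdrs)
        if m >= min_overlap
    ]
    rows.sort(key=lambda r: (r.fdr, r.p_value, r.pathway_id))
    return rows


def export_enrichment(rows: Sequence[EnrichmentRow], path: str | Path) -> None:
    """Write the enrichment table as TSV.

    Columns follow the conventional report layout (FDR in scientific
    notation, gene count, pathway size, fold enrichment at 1 decimal
    place, pathway name) plus pathway_id, p_value and -log10(FDR).
    """
    frame = pd.DataFrame(
        {
            "enrichment_fdr": [f"{r.fdr:.1e}" for r in rows],
            "n_genes": [r.n_genes_overlap for r in rows],
            "pathway_genes": [r.pathway_size for r in rows],
            "fold_enrichment": [f"{r.fold_enrichment:.1f}" for r in rows],
            "pathway": [r.name for r in rows],
            "pathway_id": [r.pathway_id for r in rows],
            "p_value": [f"{r.p_value:.3e}" for r in rows],
            "neg_log10_fdr": [f"{r.neg_log10_fdr:.3f}" for r in rows],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cross-consistency helpers for published enrichment tables.
#
# A printed ORA table with (overlap m, pathway size K, fold enrichment FE)
# per row determines the unprinted background/list ratio N/k, since
# FE = (N/k) * m/K. These helpers recover that ratio from a set of rows and
# predict one row's fold enrichment from the others, which is how a table's
# internal consistency is validated when k and N themselves are not given.
# ---------------------------------------------------------------------------


def implied_background_ratio(rows: Sequence[tuple[int, int, float]]) -> float:
    """Median of FE*K/m over (m, K, FE) rows: the implied N/k ratio."""
    if not rows:
        raise ParameterError("need at least one (m, K, FE) row")
    ratios = []
    for m, K, fe in rows:
        if m <= 0 or K <= 0:
            raise ParameterError(f"invalid row (m={m}, K={K})")
        ratios.append(fe * K / m)
    ratios.sort()
    n = len(ratios)
    mid = n // 2
    return ratios[mid] if n % 2 else (ratios[mid - 1] + ratios[mid]) / 2.0


def predict_fold_enrichment(m: int, K: int, background_ratio: float) -> float:
    """FE predicted from overlap, pathway size and the N/k ratio."""
    if m < 0 or K <= 0 or background_ratio <= 0:
        raise ParameterError(f"invalid prediction inputs m={m}, K={K}, r={background_ratio}")
    return background_ratio * m / K


def cross_predict_fold_enrichment(
    rows: Sequence[tuple[int, int, float]], index: int
) -> float:
    """Leave-one-out prediction of row ``index``'s fold enrichment."""
    if not 0 <= index < len(rows):
        raise ParameterError(f"row index {index} out of range")
    others = [r for i, r in enumerate(rows) if i != index]
    ratio = implied_background_ratio(others)
    m, K, _ = rows[index]
    return predict_fold_enrichment(m, K, ratio)
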