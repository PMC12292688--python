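"""Read, normalize and merge multi-source gene/target tables.

Four tabular sources are supported: a relevance-scored disease-gene table
(``genecards`` style), a drug→target table (``drugbank`` style), and two
plain gene-symbol tables (``pharmgkb`` / ``pubchem`` style). Symbols are
normalized by uppercasing and whitespace trimming only — no alias or ID
mapping is attempted, so results are deterministic and fully offline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from netpharm.errors import SchemaError

logger = logging.getLogger(__name__)

SOURCES = ("genecards", "drugbank", "pharmgkb", "pubchem")

#: required columns per source tag; the symbol-bearing column is listed first
_SOURCE_COLUMNS = {
    "genecards": ("symbol", "relevance_score"),
    "drugbank": ("target", "drug"),
    "pharmgkb": ("symbol",),
    "pubchem": ("symbol",),
}


@dataclass(frozen=True)
class GeneRecord:
    """One gene symbol with its per-source evidence."""

    symbol: str
    sources: frozenset[str]
    relevance_score: float | None = None

    def __post_init__(self) -> None:
        if not self.symbol:
            raise ValueError("empty gene symbol")
        if not self.sources:
            raise ValueError(f"{self.symbol}: record has no sources")


@dataclass(frozen=True)
class TargetIntersection:
    """Venn partition of disease targets against compound targets."""

    disease_only: frozenset[str]
    compound_only: frozenset[str]
    common: frozenset[str]


def _normalize_symbol(raw: object) -> str:
    return str(raw).strip().upper()


def read_source_table(path: str | Path, source: str) -> list[GeneRecord]:
    """Read one source TSV into normalized, deduplicated gene records.

    Duplicate symbols within a file are collapsed; for the scored source the
    maximum relevance score is kept. Returns records sorted by symbol.
    """
    if source not in SOURCES:
        raise ValueError(f"unknown source tag {source!r}; expected one of {SOURCES}")
    path = Path(path)
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = _SOURCE_COLUMNS[source]
    for column in required:
        if column not in table.columns:
            raise SchemaError(
                f"{path}: {source} table is missing required column {column!r}"
            )
    if table.empty:
        logger.warning("%s: empty %s table", path, source)
        return []

    symbol_col = required[0]
    records: dict[str, GeneRecord] = {}
    for _, row in table.iterrows():
        symbol = _normalize_symbol(row[symbol_col])
        if not symbol or symbol == "NAN":
            continue
        score = None
        if source == "genecards":
            score = float(row["relevance_score"])
            if score < 0:
                raise SchemaError(f"{path}: negative relevance_score for {symbol}")
        previous = records.get(symbol)
        if previous is not None and source == "genecards":
            score = max(score, previous.relevance_score)
        records[symbol] = GeneRecord(
            symbol=symbol, sources=frozenset({source}), relevance_score=score
        )
    return [records[s] for s in sorted(records)]


def merge_catalogs(catalogs: Sequence[Sequence[GeneRecord]]) -> list[GeneRecord]:
    """Merge per-source catalogs into one record per symbol.

    Sources are unioned; the relevance score is carried from the scored
    source when present (maximum across conflicting scores). The result is
    independent of the order of the input catalogs.
    """
    if not catalogs:
        raise ValueError("merge_catalogs requires at least one catalog")
    merged: dict[str, GeneRecord] = {}
    for cat in catalogs:
        for rec in cat:
            previous = merged.get(rec.symbol)
            if previous is None:
                merged[rec.symbol] = rec
                continue
            scores = [
                s
                for s in (previous.relevance_score, rec.relevance_score)
                if s is not None
            ]
            merged[rec.symbol] = GeneRecord(
                symbol=rec.symbol,
                sources=previous.sources | rec.sources,
                relevance_score=max(scores) if scores else None,
            )
    return [merged[s] for s in sorted(merged)]


def intersect_targets(
    disease: Iterable[str], compound: Iterable[str]
) -> TargetIntersection:
    """Partition disease vs compound targets into the three Venn regions."""
    disease = frozenset(disease)
    compound = frozenset(compound)
    common = disease & compound
    result = TargetIntersection(
        disease_only=disease - compound,
        compound_only=compound - disease,
        common=common,
    )
    logger.info(
        "target intersection: %d disease-only, %d compound-only, %d common",
        len(result.disease_only),
        len(result.compound_only),
        len(result.common),
    )
    return result


def analysis_gene_list(
    disease_catalog: Sequence[GeneRecord],
    compound_targets: Iterable[str] | None = None,
) -> frozenset[str]:
    """Gene list passed downstream: disease ∩ compound when a compound
    table is supplied, else the full disease catalog."""
    disease = frozenset(rec.symbol for rec in disease_catalog)
    if compound_targets is None:
        return disease
    return intersect_targets(disease, compound_targets).common


def write_catalog(records: Sequence[GeneRecord], path: str | Path) -> None:
    """Write a merged catalog as TSV (symbol, relevance_score, sources)."""
    frame = pd.DataFrame(
        {
            "symbol": [r.symbol for r in records],
            "relevance_score": [r.relevance_score for r in records],
            "sources": [",".join(sorted(r.sources)) for r in records],
        }
    )
    frame.to_csv(path, sep="\t", index=False)
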