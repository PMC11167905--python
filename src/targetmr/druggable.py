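"""Druggable-genome list consolidation.

The druggable genome is assembled from multiple curated sources
(drug-gene interaction databases, published tractability reviews);
sources disagree on naming, so symbols are normalized (uppercase,
trimmed) and optionally mapped through an alias table before the
union is taken. No live nomenclature service is consulted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

logger = logging.getLogger(__name__)


def canonicalize_symbol(symbol: str, alias_map: Mapping[str, str] | None = None) -> str:
    s = symbol.strip().upper()
    if alias_map:
        s = alias_map.get(s, s)
    return s


@dataclass
class GeneSetCatalog:
    """One source's gene symbols with optional alias resolution."""

    source_name: str
    symbols: set[str]
    alias_map: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_symbols(
        cls,
        source_name: str,
        symbols: Iterable[str],
        alias_map: Mapping[str, str] | None = None,
    ) -> "GeneSetCatalog":
        alias = {
            canonicalize_symbol(k): canonicalize_symbol(v)
            for k, v in (alias_map or {}).items()
        }
        canon = {canonicalize_symbol(s, alias) for s in symbols if s.strip()}
        if not canon:
            raise ValueError(f"catalog {source_name!r} contains no usable symbols")
        return cls(source_name, canon, alias)


def merge_druggable_lists(catalogs: Iterable[GeneSetCatalog]) -> list[str]:
    """Union of canonicalized symbols across sources, sorted alphabetically.

    Duplicates and aliases collapse; an empty union is rejected with a
    diagnostic naming the offending sources.
    """
    catalogs = list(catalogs)
    if not catalogs:
        raise ValueError("at least one druggable-gene catalog is required")
    merged: set[str] = set()
    for cat in catalogs:
        merged |= {canonicalize_symbol(s, cat.alias_map) for s in cat.symbols}
    merged.discard("")
    if not merged:
        names = ", ".join(c.source_name for c in catalogs)
        raise ValueError(f"druggable-gene union is empty (sources: {names})")
    logger.info(
        "merged %d druggable sources into %d unique symbols", len(catalogs), len(merged)
    )
    return sorted(merged)


def intersect_with_eqtl_genes(
    druggable: Iterable[str], eqtl_genes: Iterable[str]
) -> list[str]:
    """Druggable genes actually measured in an eQTL dataset (MR candidates)."""
    result = sorted(set(druggable) & set(eqtl_genes))
    if not result:
        logger.warning("druggable genes and eQTL genes are disjoint")
    return result
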