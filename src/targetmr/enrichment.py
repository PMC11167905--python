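"""Over-representation analysis against user-supplied gene sets.

A hit list (e.g. the MR+colocalization significant genes) is tested
against each gene set in a GMT catalog with the hypergeometric upper
tail, after restricting every set to the analysis universe (the genes
that were actually testable). BH correction runs across the tested
sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .druggable import canonicalize_symbol
from .mr import bh_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentRow:
    set_name: str
    overlap_k: int
    set_size_K: int
    hits_n: int
    universe_N: int
    pvalue: float
    fdr_pvalue: float
    overlapping_symbols: tuple[str, ...]


def read_gmt(path: str | Path) -> dict[str, tuple[str, tuple[str, ...]]]:
    """Parse a GMT file into ``{name: (description, members)}``.

    GMT lines are tab-separated: set name, description, then member
    symbols. Member symbols are canonicalized and de-duplicated; empty
    sets are dropped with a warning; a line with fewer than two fields
    raises with its line number.
    """
    catalog: dict[str, tuple[str, tuple[str, ...]]] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{lineno}: malformed GMT line (needs name and description)")
        name, desc, *members = fields
        symbols = sorted({canonicalize_symbol(m) for m in members if m.strip()})
        if not symbols:
            logger.warning("%s:%d: gene set %r is empty; dropped", path, lineno, name)
            continue
        catalog[name] = (desc, tuple(symbols))
    if not catalog:
        logger.warning("%s: no usable gene sets", path)
    return catalog


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora(
    hits: Iterable[str],
    universe: Iterable[str],
    catalog: Mapping[str, tuple[str, tuple[str, ...]]],
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Hypergeometric over-representation test of ``hits`` per gene set.

    Sets are intersected with the universe first and skipped below
    ``min_set_size``. Returns one row per tested set, sorted by
    p-value, with BH-adjusted p-values across the tested sets.
    """
    hits = {canonicalize_symbol(h) for h in hits}
    universe = {canonicalize_symbol(u) for u in universe}
    if not hits <= universe:
        raise ValueError(f"hits outside the universe: {sorted(hits - universe)[:5]}")
    N, n = len(universe), len(hits)
    rows = []
    for name, (_, members) in catalog.items():
        in_universe = set(members) & universe
        K = len(in_universe)
        if K < min_set_size:
            continue
        overlap = sorted(in_universe & hits)
        k = len(overlap)
        rows.append(
            {
                "set_name": name,
                "overlap_k": k,
                "set_size_K": K,
                "hits_n": n,
                "universe_N": N,
                "pvalue": hypergeom_tail(k, N, K, n),
                "overlapping_symbols": ",".join(overlap),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["set_name", "overlap_k", "set_size_K", "hits_n", "universe_N",
                 "pvalue", "overlapping_symbols"],
    )
    if len(df):
        df["fdr_pvalue"] = bh_adjust(df["pvalue"])
        df = df.sort_values(["pvalue", "set_name"], kind="mergesort").reset_index(drop=True)
    else:
        df["fdr_pvalue"] = pd.Series(dtype=float)
    return df[["set_name", "overlap_k", "set_size_K", "hits_n", "universe_N",
               "pvalue", "fdr_pvalue", "overlapping_symbols"]]
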