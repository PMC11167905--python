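"""Cis-instrument selection: significance + window filter, LD clumping,
and the exclusion screen.

Instruments are cis-eQTL SNPs: FDR-significant within a closed
+/-100 kb window around the gene's TSS, greedily pruned so no retained
pair exceeds the r^2 threshold, then screened against a user-supplied
exclusion list (variants with known direct associations to the outcome
or to closely related traits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .mr import bh_adjust
from .records import LDMatrix

logger = logging.getLogger(__name__)


@dataclass
class InstrumentSet:
    """Retained instruments for one gene with a per-SNP audit trail."""

    gene: str
    snps: pd.DataFrame
    window_bp: int
    r2_threshold: float
    provenance: list[dict] = field(default_factory=list)

    def record(self, snp_id: str, stage: str, status: str, reason: str = "") -> None:
        self.provenance.append(
            {"snp_id": snp_id, "stage": stage, "status": status, "reason": reason}
        )


def select_cis_instruments(
    exposure: pd.DataFrame,
    gene_tss: int,
    window_bp: int = 100_000,
    fdr_threshold: float = 0.05,
    use_fdr_column: bool | None = None,
) -> pd.DataFrame:
    """SNPs within the closed cis window passing the FDR threshold.

    The window is ``[tss - window_bp, tss + window_bp]``, both ends
    inclusive. If the table carries a precomputed ``fdr`` column it is
    used directly (``use_fdr_column=None`` auto-detects); otherwise
    Benjamini-Hochberg is applied to the raw p-values within the
    window. An empty result is not an error — the caller drops the
    gene from MR with a logged reason.
    """
    lo, hi = gene_tss - window_bp, gene_tss + window_bp
    win = exposure[(exposure["pos"] >= lo) & (exposure["pos"] <= hi)].copy()
    if len(win) == 0:
        return win
    if use_fdr_column is None:
        use_fdr_column = "fdr" in win.columns
    if use_fdr_column:
        if "fdr" not in win.columns:
            raise ValueError("use_fdr_column=True but no 'fdr' column present")
        fdr = win["fdr"].to_numpy()
    else:
        fdr = bh_adjust(win["pvalue"].to_numpy())
        win["fdr"] = fdr
    return win[fdr < fdr_threshold].reset_index(drop=True)


def clump(
    snps: pd.DataFrame,
    ld: LDMatrix,
    r2_threshold: float = 0.001,
    missing: str = "strict",
) -> pd.DataFrame:
    """Greedy LD clumping at an r^2 threshold.

    SNPs are ranked by p-value (ties broken by snp_id, lexicographic);
    the best remaining SNP is kept and everything with r^2 >= threshold
    against it is discarded, until the list is exhausted. Output rows
    keep the retention order. SNPs absent from the LD matrix either
    raise (``missing='strict'``) or are dropped with a warning
    (``missing='drop'``).
    """
    if missing not in ("strict", "drop"):
        raise ValueError(f"missing must be 'strict' or 'drop', got {missing!r}")
    present = snps["snp_id"].map(ld.__contains__)
    if not present.all():
        absent = snps.loc[~present, "snp_id"].tolist()
        if missing == "strict":
            raise KeyError(f"SNPs missing from LD matrix: {absent}")
        logger.warning("dropping %d SNPs missing from LD matrix: %s", len(absent), absent)
        snps = snps[present]
    ranked = snps.sort_values(["pvalue", "snp_id"], kind="mergesort")
    remaining = list(ranked["snp_id"])
    kept: list[str] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [s for s in remaining if ld.r2(best, s) < r2_threshold]
    order = {s: i for i, s in enumerate(kept)}
    out = snps[snps["snp_id"].isin(order)].copy()
    return out.sort_values("snp_id", key=lambda c: c.map(order), kind="mergesort").reset_index(drop=True)


def apply_exclusions(
    snps: pd.DataFrame, exclusion_list: Mapping[str, str] | pd.DataFrame
) -> tuple[pd.DataFrame, list[dict]]:
    """Remove screened-out SNPs; return (kept, dropped-with-reason records)."""
    if isinstance(exclusion_list, pd.DataFrame):
        reasons = dict(zip(exclusion_list["snp_id"], exclusion_list["reason"]))
    else:
        reasons = dict(exclusion_list)
    mask = snps["snp_id"].isin(reasons)
    dropped = [
        {"snp_id": s, "stage": "exclusion_screen", "status": "dropped",
         "reason": reasons[s]}
        for s in snps.loc[mask, "snp_id"]
    ]
    return snps[~mask].reset_index(drop=True), dropped


def build_instrument_set(
    gene: str,
    exposure: pd.DataFrame,
    gene_tss: int,
    ld: LDMatrix,
    exclusion_list: Mapping[str, str] | pd.DataFrame | None = None,
    window_bp: int = 100_000,
    fdr_threshold: float = 0.05,
    r2_threshold: float = 0.001,
    use_fdr_column: bool | None = None,
    missing_ld: str = "strict",
) -> InstrumentSet:
    """Full instrument stage for one gene: select, clump, screen."""
    inst = InstrumentSet(gene, exposure.iloc[0:0], window_bp, r2_threshold)
    selected = select_cis_instruments(
        exposure, gene_tss, window_bp, fdr_threshold, use_fdr_column
    )
    for s in selected["snp_id"]:
        inst.record(s, "cis_selection", "retained")
    if len(selected) == 0:
        logger.info("gene %s: no FDR-significant cis SNPs; dropped from MR", gene)
        return inst
    clumped = clump(selected, ld, r2_threshold, missing=missing_ld)
    kept_ids = set(clumped["snp_id"])
    for s in selected["snp_id"]:
        if s not in kept_ids:
            inst.record(s, "clumping", "dropped", f"r2 >= {r2_threshold} with a better SNP")
    if exclusion_list is not None:
        clumped, dropped = apply_exclusions(clumped, exclusion_list)
        inst.provenance.extend(dropped)
        if len(clumped) == 0:
            logger.info("gene %s: all instruments excluded by screen; dropped from MR", gene)
    inst.snps = clumped
    return inst
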