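"""Bayesian colocalization of an eQTL and a GWAS signal in one region.

Each SNP gets a Wakefield-style approximate Bayes factor per trait,
computed from its effect estimate, standard error and a prior effect
variance. Assuming at most one causal variant per trait, the five
hypotheses are

    H0: no association with either trait
    H1: associated with expression only
    H2: associated with the outcome only
    H3: both traits, distinct causal variants
    H4: both traits, one shared causal variant

whose unnormalized weights are sums of per-SNP Bayes-factor products
scaled by the per-SNP priors p1, p2, p12. All sums run in log space
with log-sum-exp reductions; the H3 term ``S1*S2 - S12`` uses a
guarded log-difference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .records import ColocResult

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities and prior effect variances.

    ``p1``/``p2`` are the prior probabilities that a given SNP is
    causal for trait 1 (expression) / trait 2 (outcome) only, ``p12``
    for both. ``w_quant`` and ``w_cc`` are prior effect variances for
    quantitative (per-SD) and case-control (log-odds) traits: the
    defaults are sd 0.15 and 0.2 squared.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w_quant: float = 0.15**2
    w_cc: float = 0.2**2

    def __post_init__(self) -> None:
        if min(self.p1, self.p2, self.p12) <= 0:
            raise ValueError("priors must be positive")
        if self.p12 > min(self.p1, self.p2):
            raise ValueError("p12 must not exceed min(p1, p2)")
        if min(self.w_quant, self.w_cc) <= 0:
            raise ValueError("prior effect variances must be positive")

    def check_region_size(self, m: int) -> None:
        if m * (self.p1 + self.p2 + self.p12) >= 1:
            logger.warning(
                "region of %d SNPs makes per-SNP priors sum past 1; "
                "posteriors remain defined but the prior model is strained", m,
            )

    def w_for(self, trait_type: str) -> float:
        if trait_type == "quantitative":
            return self.w_quant
        if trait_type == "case_control":
            return self.w_cc
        raise ValueError(f"unknown trait type {trait_type!r}")


def log_abf(beta: float, se: float, w: float) -> float:
    """Log approximate Bayes factor for one SNP-trait association.

    With V = se^2, z = beta/se and shrinkage r = w/(V+w):
    ``lABF = 0.5 * (log(1 - r) + r * z^2)``. As w -> 0 the prior
    admits no effect and the Bayes factor tends to 1 (lABF -> 0).
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    if w <= 0:
        raise ValueError("prior effect variance w must be positive")
    V = se**2
    r = w / (V + w)
    z = beta / se
    out = 0.5 * (np.log1p(-r) + r * z**2)
    return float(out) if out.ndim == 0 else out


def _log_diff_exp(a: float, b: float) -> float:
    """log(exp(a) - exp(b)), clamped to -inf when b >= a within rounding."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


def coloc_abf(
    eqtl: pd.DataFrame,
    gwas: pd.DataFrame,
    priors: ColocPriors | None = None,
    gene: str = "",
    trait_type_1: str = "quantitative",
    trait_type_2: str = "case_control",
    pph4_threshold: float = 0.75,
) -> ColocResult:
    """Posterior probabilities of H0..H4 for one region.

    The two tables are inner-joined on ``snp_id``; rows lacking a beta
    or se are dropped with a logged count. Raises ``ValueError`` when
    the SNP intersection is empty (the gene is not colocalizable).
    """
    priors = priors or ColocPriors()
    merged = eqtl.merge(gwas, on="snp_id", suffixes=("_1", "_2"))
    usable = merged.dropna(subset=["beta_1", "se_1", "beta_2", "se_2"])
    if len(usable) < len(merged):
        logger.info(
            "%s: dropped %d SNPs lacking beta/se", gene, len(merged) - len(usable)
        )
    m = len(usable)
    if m == 0:
        raise ValueError(f"gene {gene or '<region>'}: no shared SNPs — not colocalizable")
    priors.check_region_size(m)

    l1 = log_abf(usable["beta_1"].to_numpy(), usable["se_1"].to_numpy(),
                 priors.w_for(trait_type_1))
    l2 = log_abf(usable["beta_2"].to_numpy(), usable["se_2"].to_numpy(),
                 priors.w_for(trait_type_2))
    log_s1 = float(logsumexp(l1))
    log_s2 = float(logsumexp(l2))
    log_s12 = float(logsumexp(l1 + l2))

    log_w = np.array([
        0.0,
        np.log(priors.p1) + log_s1,
        np.log(priors.p2) + log_s2,
        np.log(priors.p1) + np.log(priors.p2) + _log_diff_exp(log_s1 + log_s2, log_s12),
        np.log(priors.p12) + log_s12,
    ])
    post = np.exp(log_w - logsumexp(log_w))
    post = post / post.sum()
    return ColocResult(
        gene=gene, n_snps=m,
        pph0=float(post[0]), pph1=float(post[1]), pph2=float(post[2]),
        pph3=float(post[3]), pph4=float(post[4]),
        threshold=pph4_threshold,
    )


def coloc_window_extract(
    gwas_all: pd.DataFrame,
    eqtl_all: pd.DataFrame,
    gene_tss: int,
    window_bp: int = 100_000,
    chrom: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Closed-window filter on both studies, keeping only shared SNPs.

    Returns (eqtl_region, gwas_region) restricted to the inner join on
    snp_id; either may be empty, in which case the gene is reported
    not-colocalizable by the caller.
    """
    lo, hi = gene_tss - window_bp, gene_tss + window_bp

    def _window(df: pd.DataFrame) -> pd.DataFrame:
        mask = (df["pos"] >= lo) & (df["pos"] <= hi)
        if chrom is not None:
            mask &= df["chrom"].astype(str) == str(chrom)
        return df[mask]

    eqtl_w, gwas_w = _window(eqtl_all), _window(gwas_all)
    shared = set(eqtl_w["snp_id"]) & set(gwas_w["snp_id"])
    eqtl_r = eqtl_w[eqtl_w["snp_id"].isin(shared)].reset_index(drop=True)
    gwas_r = gwas_w[gwas_w["snp_id"].isin(shared)].reset_index(drop=True)
    return eqtl_r, gwas_r
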