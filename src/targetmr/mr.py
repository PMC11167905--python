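"""Per-gene Mendelian randomization estimators and diagnostics.

Single-instrument genes get a Wald ratio; multi-instrument genes an
inverse-variance-weighted (IVW) meta-analysis of per-SNP ratios with a
random-effects correction, Cochran's Q heterogeneity statistic and —
with three or more instruments — the MR-Egger intercept as a
directional-pleiotropy diagnostic. Study-wide multiplicity is
controlled with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import HarmonizedPair, MRResult


def wald_ratio(pair: HarmonizedPair) -> tuple[float, float, float]:
    """Single-instrument causal estimate: beta_outcome / beta_exposure.

    The standard error is the first-order delta approximation
    ``se_outcome / |beta_exposure|`` (exposure uncertainty ignored);
    p is the two-sided normal tail.
    """
    if pair.beta_exposure == 0:
        raise ValueError(f"{pair.snp_id}: zero exposure effect — Wald ratio undefined")
    beta = pair.beta_outcome / pair.beta_exposure
    se = pair.se_outcome / abs(pair.beta_exposure)
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return beta, se, float(p)


def wald_ratio_second_order(pair: HarmonizedPair) -> tuple[float, float, float]:
    """Wald ratio with a second-order delta se including exposure error."""
    if pair.beta_exposure == 0:
        raise ValueError(f"{pair.snp_id}: zero exposure effect — Wald ratio undefined")
    beta = pair.beta_outcome / pair.beta_exposure
    var = (
        pair.se_outcome**2 / pair.beta_exposure**2
        + pair.beta_outcome**2 * pair.se_exposure**2 / pair.beta_exposure**4
    )
    se = float(np.sqrt(var))
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return beta, se, float(p)


def ivw_random_effects(
    pairs: Sequence[HarmonizedPair],
    flavor: str = "multiplicative",
) -> tuple[float, float, float, float, int, float]:
    """IVW meta-analysis of per-SNP Wald ratios with random effects.

    Weights are inverse ratio variances (delta-method). The default
    multiplicative flavor scales the fixed-effect se by
    ``sqrt(max(1, Q/df))``; ``flavor='additive'`` uses a
    DerSimonian-Laird between-SNP variance instead. Returns
    (beta, se, pvalue, Q, q_df, q_pvalue).
    """
    if len(pairs) < 2:
        raise ValueError("IVW requires at least two instruments")
    if flavor not in ("multiplicative", "additive"):
        raise ValueError(f"unknown random-effects flavor {flavor!r}")
    ratios = np.array([wald_ratio(p)[0] for p in pairs])
    ses = np.array([wald_ratio(p)[1] for p in pairs])
    w = 1.0 / ses**2
    beta = float(np.sum(w * ratios) / np.sum(w))
    se_fe = float(1.0 / np.sqrt(np.sum(w)))
    q = float(np.sum(w * (ratios - beta) ** 2))
    q_df = len(pairs) - 1
    q_pvalue = float(stats.chi2.sf(q, q_df))
    if flavor == "multiplicative":
        se = se_fe * float(np.sqrt(max(1.0, q / q_df)))
    else:
        denom = np.sum(w) - np.sum(w**2) / np.sum(w)
        tau2 = max(0.0, (q - q_df) / denom) if denom > 0 else 0.0
        w_re = 1.0 / (ses**2 + tau2)
        beta = float(np.sum(w_re * ratios) / np.sum(w_re))
        se = float(1.0 / np.sqrt(np.sum(w_re)))
    p = 2.0 * stats.norm.sf(abs(beta) / se)
    return beta, se, float(p), q, q_df, q_pvalue


def egger_intercept(pairs: Sequence[HarmonizedPair]) -> tuple[float, float, float]:
    """MR-Egger intercept: directional-pleiotropy diagnostic.

    All pairs are oriented so the exposure effect is positive (both
    betas flipped jointly), then beta_outcome is regressed on
    beta_exposure with an intercept, weighted by inverse outcome
    variance. Inference uses a t reference with n-2 df and residual
    over-dispersion floored at 1. Returns (intercept, se, pvalue).
    """
    n = len(pairs)
    if n < 3:
        raise ValueError("Egger intercept requires at least three instruments")
    sign = np.array([1.0 if p.beta_exposure > 0 else -1.0 for p in pairs])
    x = sign * np.array([p.beta_exposure for p in pairs])
    y = sign * np.array([p.beta_outcome for p in pairs])
    w = 1.0 / np.array([p.se_outcome for p in pairs]) ** 2
    X = np.column_stack([np.ones(n), x])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = y - X @ coef
    phi = float(np.sum(w * resid**2) / (n - 2))
    cov = np.linalg.inv(xtwx) * max(1.0, phi)
    intercept = float(coef[0])
    se = float(np.sqrt(cov[0, 0]))
    p = 2.0 * stats.t.sf(abs(intercept) / se, df=n - 2)
    return intercept, se, float(p)


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_mr_gene(
    pairs: Sequence[HarmonizedPair],
    gene: str,
    tissue_label: str = "",
    re_flavor: str = "multiplicative",
    wald_se: str = "first_order",
) -> MRResult:
    """Estimate one gene's causal effect from its harmonized instruments.

    One pair routes to the Wald ratio; two or more to IVW with random
    effects; the Egger intercept is attached from three instruments
    up. ``fdr_pvalue`` is left unset — it is filled in across the
    gene family by :func:`bh_adjust`.
    """
    if len(pairs) == 0:
        raise ValueError(f"gene {gene}: no harmonized pairs — not testable")
    if len(pairs) == 1:
        fn = wald_ratio if wald_se == "first_order" else wald_ratio_second_order
        beta, se, p = fn(pairs[0])
        result = MRResult(
            gene=gene, tissue_label=tissue_label, method="wald_ratio",
            n_snps=1, beta=beta, se=se, pvalue=p,
            snp_ids=tuple(pr.snp_id for pr in pairs),
        )
    else:
        beta, se, p, q, q_df, q_p = ivw_random_effects(pairs, flavor=re_flavor)
        result = MRResult(
            gene=gene, tissue_label=tissue_label, method="ivw_random_effects",
            n_snps=len(pairs), beta=beta, se=se, pvalue=p,
            q_statistic=q, q_df=q_df, q_pvalue=q_p,
            snp_ids=tuple(pr.snp_id for pr in pairs),
        )
        if len(pairs) >= 3:
            ei, ei_se, ei_p = egger_intercept(pairs)
            result.egger_intercept = ei
            result.egger_intercept_se = ei_se
            result.egger_intercept_pvalue = ei_p
    return result
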