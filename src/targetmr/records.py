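"""Shared data containers for the MR + colocalization pipeline.

Per-SNP summary statistics travel as pandas DataFrames with the fixed
column set :data:`SUMMARY_COLUMNS` (the on-disk TSV schema). Small typed
containers (LD matrices, simulation truths, harmonized pairs, per-gene
results) are dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

#: Fixed column order of a summary-statistics table (exposure or outcome).
SUMMARY_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
]

#: Fixed column order of a gene annotation table.
GENE_COLUMNS = ["symbol", "chrom", "tss", "strand"]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

SCENARIOS = ("H0", "H1", "H2", "H3", "H4")


def validate_summary_frame(df: pd.DataFrame, *, check_pvalues: bool = False) -> None:
    """Check a summary-statistics frame against the schema invariants.

    Raises ``ValueError`` on a missing column, non-positive standard
    error, out-of-range allele frequency, or identical allele pair.
    With ``check_pvalues`` the p-value column is additionally compared
    with the two-sided normal tail of beta/se (1e-6 relative slack).
    """
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"summary table missing columns: {missing}")
    if len(df) == 0:
        return
    if (df["se"] <= 0).any():
        raise ValueError("summary table contains non-positive standard errors")
    if ((df["eaf"] <= 0) | (df["eaf"] >= 1)).any():
        raise ValueError("summary table contains eaf outside (0, 1)")
    if (df["effect_allele"] == df["other_allele"]).any():
        raise ValueError("summary table contains identical effect/other alleles")
    if check_pvalues:
        from scipy import stats

        expect = 2.0 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
        ok = np.isclose(df["pvalue"], expect, rtol=1e-6, atol=1e-300)
        if not ok.all():
            raise ValueError("p-values inconsistent with beta/se normal tails")


@dataclass(frozen=True)
class LDMatrix:
    """SNP-by-SNP correlation matrix for one cis region.

    ``r`` holds signed correlations (r, not r^2); clumping thresholds
    apply to the squared entries. The matrix must be symmetric with a
    unit diagonal and at most numerically negative eigenvalues.
    """

    snp_ids: tuple[str, ...]
    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        object.__setattr__(self, "r", r)
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        m = len(self.snp_ids)
        if r.shape != (m, m):
            raise ValueError(f"LD matrix shape {r.shape} != ({m}, {m})")
        if not np.allclose(np.diag(r), 1.0, atol=1e-12):
            raise ValueError("LD matrix diagonal is not 1")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("LD matrix is not symmetric")
        if m:
            lo = float(np.linalg.eigvalsh(r)[0])
            if lo < -1e-8:
                raise ValueError(f"LD matrix is not PSD (min eigenvalue {lo:.3e})")

    @property
    def m(self) -> int:
        return len(self.snp_ids)

    def index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in LD matrix") from None

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.snp_ids

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self.index(a), self.index(b)] ** 2)

    def subset(self, snp_ids: Iterable[str]) -> "LDMatrix":
        idx = [self.index(s) for s in snp_ids]
        return LDMatrix(tuple(self.snp_ids[i] for i in idx), self.r[np.ix_(idx, idx)])

    def repaired(self, floor: float = 1e-8) -> "LDMatrix":
        """Clip negative eigenvalues to ``floor`` and rescale to unit diagonal."""
        w, v = np.linalg.eigh(self.r)
        if w[0] >= floor:
            return self
        r = (v * np.maximum(w, floor)) @ v.T
        d = np.sqrt(np.diag(r))
        r = r / np.outer(d, d)
        r = (r + r.T) / 2.0
        np.fill_diagonal(r, 1.0)
        return LDMatrix(self.snp_ids, r)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth for one simulated gene region.

    ``scenario`` follows the five colocalization hypotheses: H0 no
    association with either trait, H1 expression only, H2 outcome only,
    H3 both traits with distinct causal variants, H4 a shared causal
    variant. ``theta`` is the true causal effect of expression on the
    outcome (log-odds per expression SD) and is nonzero only when the
    outcome signal is routed through the exposure (H4).
    ``beta_outcome_direct`` is the direct per-allele outcome effect at
    the outcome causal variant for H2/H3.
    """

    gene: str
    scenario: str
    causal_exposure_snp: str | None = None
    causal_outcome_snp: str | None = None
    beta_exposure_causal: float = 0.0
    theta: float = 0.0
    beta_outcome_direct: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        s = self.scenario
        ce, co = self.causal_exposure_snp, self.causal_outcome_snp
        if s == "H0" and (ce is not None or co is not None):
            raise ValueError("H0 admits no causal SNPs")
        if s == "H1" and (ce is None or co is not None):
            raise ValueError("H1 requires an exposure causal SNP only")
        if s == "H2" and (co is None or ce is not None):
            raise ValueError("H2 requires an outcome causal SNP only")
        if s == "H3" and (ce is None or co is None or ce == co):
            raise ValueError("H3 requires distinct exposure and outcome causal SNPs")
        if s == "H4" and (ce is None or co != ce):
            raise ValueError("H4 requires a single shared causal SNP")
        if self.theta != 0.0 and s != "H4":
            raise ValueError("theta must be zero unless outcome signal routes through exposure (H4)")


@dataclass(frozen=True)
class HarmonizedPair:
    """One SNP's exposure and outcome effects on a common effect allele."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: float | None
    eaf_outcome: float | None
    action_taken: str  # none | sign_flip | strand_flip | strand_flip_and_sign_flip | dropped(<reason>)

    @property
    def dropped(self) -> bool:
        return self.action_taken.startswith("dropped")


@dataclass
class MRResult:
    """Per-gene causal estimate with heterogeneity/pleiotropy diagnostics."""

    gene: str
    tissue_label: str
    method: str  # wald_ratio | ivw_random_effects
    n_snps: int
    beta: float
    se: float
    pvalue: float
    q_statistic: float | None = None
    q_df: int | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    egger_intercept_pvalue: float | None = None
    fdr_pvalue: float | None = None
    snp_ids: tuple[str, ...] = ()

    @property
    def or_value(self) -> float:
        return float(np.exp(self.beta))

    @property
    def ci95_low(self) -> float:
        return float(np.exp(self.beta - 1.959963984540054 * self.se))

    @property
    def ci95_high(self) -> float:
        return float(np.exp(self.beta + 1.959963984540054 * self.se))


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    gene: str
    n_snps: int
    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    threshold: float = 0.75

    def __post_init__(self) -> None:
        pp = self.posteriors
        if not np.all((pp >= 0) & (pp <= 1)):
            raise ValueError("posterior outside [0, 1]")
        if abs(pp.sum() - 1.0) > 1e-12:
            raise ValueError(f"posteriors sum to {pp.sum()!r}, not 1")

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2, self.pph3, self.pph4])

    @property
    def passes_threshold(self) -> bool:
        return self.pph4 >= self.threshold


def mr_results_frame(results: Iterable[MRResult]) -> pd.DataFrame:
    """Tabulate MRResults, one row per gene, in the on-disk column order."""
    rows = []
    for r in results:
        rows.append(
            {
                "gene": r.gene,
                "tissue_label": r.tissue_label,
                "method": r.method,
                "n_snps": r.n_snps,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "or_value": r.or_value,
                "ci95_low": r.ci95_low,
                "ci95_high": r.ci95_high,
                "q_statistic": r.q_statistic,
                "q_df": r.q_df,
                "q_pvalue": r.q_pvalue,
                "egger_intercept": r.egger_intercept,
                "egger_intercept_se": r.egger_intercept_se,
                "egger_intercept_pvalue": r.egger_intercept_pvalue,
                "fdr_pvalue": r.fdr_pvalue,
            }
        )
    cols = [
        "gene", "tissue_label", "method", "n_snps", "beta", "se", "pvalue",
        "or_value", "ci95_low", "ci95_high", "q_statistic", "q_df", "q_pvalue",
        "egger_intercept", "egger_intercept_se", "egger_intercept_pvalue", "fdr_pvalue",
    ]
    return pd.DataFrame(rows, columns=cols)


def coloc_results_frame(results: Iterable[ColocResult]) -> pd.DataFrame:
    rows = [
        {
            "gene": r.gene,
            "n_snps": r.n_snps,
            "pph0": r.pph0,
            "pph1": r.pph1,
            "pph2": r.pph2,
            "pph3": r.pph3,
            "pph4": r.pph4,
            "passes_threshold": r.passes_threshold,
        }
        for r in results
    ]
    cols = ["gene", "n_snps", "pph0", "pph1", "pph2", "pph3", "pph4", "passes_threshold"]
    return pd.DataFrame(rows, columns=cols)
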