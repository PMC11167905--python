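"""LD-structured two-trait summary-statistics simulator with known truth.

The generator emulates the statistical shape of a cis-eQTL study paired
with a disease GWAS: per-SNP marginal effect estimates that are
correlated through LD, standard errors scaling as 1/sqrt(n), and five
region-level scenarios (H0..H4) mirroring the colocalization
hypotheses. Genotypes are standardized (effects per genotype SD), so
the marginal-effect vector of a region is exactly ``r @ b`` for causal
vector ``b``, and observed effects are multivariate normal around it
with covariance ``r / n``.

The simulator gives every downstream stage — instrument selection,
clumping, harmonization, MR estimation, colocalization, the two-tissue
intersection — a parameter-recovery test surface with known ground
truth. It is a statistical stand-in, not a population-genetic model:
LD is a parametric AR-1 kernel, allele frequencies are a uniform draw
used only by harmonization logic, and the case-control outcome is
represented directly on the log-odds scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import subseed
from .records import (
    GENE_COLUMNS,
    SCENARIOS,
    SUMMARY_COLUMNS,
    LDMatrix,
    SimulationTruth,
)

# Ordered, non-palindromic allele pairs (effect, other); the generator
# avoids A/T and C/G variants so harmonization never has to drop a
# simulated SNP for strand ambiguity.
_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


def make_ld_matrix(
    m: int,
    rho: float,
    seed: int = 0,
    snp_ids: Sequence[str] | None = None,
) -> LDMatrix:
    """AR-1 LD matrix: r[i, j] = rho^|i-j|.

    Deterministic given its arguments; ``seed`` only namespaces the
    default SNP identifiers so regions built from different seeds do
    not collide.
    """
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if not (0.0 <= rho < 1.0):
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if snp_ids is None:
        snp_ids = tuple(f"rs{int(seed)}_{j + 1}" for j in range(m))
    else:
        snp_ids = tuple(snp_ids)
        if len(snp_ids) != m:
            raise ValueError("snp_ids length does not match m")
    idx = np.arange(m)
    r = rho ** np.abs(idx[:, None] - idx[None, :]).astype(float)
    return LDMatrix(snp_ids, r)


def _causal_vector(ld: LDMatrix, snp: str | None, effect: float) -> np.ndarray:
    b = np.zeros(ld.m)
    if snp is not None:
        b[ld.index(snp)] = effect
    return b


def _marginal_table(
    rng: np.random.Generator,
    ld: LDMatrix,
    chol: np.ndarray,
    b_causal: np.ndarray,
    n: int,
    meta: pd.DataFrame,
) -> pd.DataFrame:
    mu = ld.r @ b_causal
    se = 1.0 / np.sqrt(float(n))
    beta = mu + se * (chol @ rng.standard_normal(ld.m))
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    out = meta.copy()
    out["beta"] = beta
    out["se"] = se
    out["pvalue"] = p
    out["n"] = int(n)
    return out[SUMMARY_COLUMNS]


def simulate_region(
    truth: SimulationTruth,
    ld: LDMatrix,
    n_exposure: int,
    n_outcome: int,
    seed: int,
    *,
    chrom: str = "1",
    tss: int = 1_000_000,
    case_fraction: float = 0.17,
    variant_seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cis region for an exposure (eQTL) and outcome (GWAS) study.

    Returns two summary tables over ``ld.snp_ids``: marginal effects are
    ``r @ b`` for the scenario's causal vector, observed effects are
    MVN with covariance ``r/n``, and se = 1/sqrt(n). Under H4 the
    outcome causal effect at the shared SNP is ``theta *
    beta_exposure_causal``. Variant metadata (positions spanning the
    +/-100 kb window, alleles, frequencies) is reproducible from
    ``variant_seed`` (defaults to a sub-seed of ``seed``), so two
    studies of the same region describe the same variants.
    """
    for snp in (truth.causal_exposure_snp, truth.causal_outcome_snp):
        if snp is not None and snp not in ld:
            raise ValueError(f"causal SNP {snp!r} is not in the LD matrix")
    repaired = ld.repaired()
    try:
        chol = np.linalg.cholesky(repaired.r)
    except np.linalg.LinAlgError:
        raise ValueError("LD matrix is singular after PSD repair") from None

    m = ld.m
    if variant_seed is None:
        variant_seed = subseed(seed, "variants")
    vrng = np.random.default_rng(variant_seed)
    pos = (
        np.full(m, tss)
        if m == 1
        else tss - 100_000 + np.round(np.arange(m) * (200_000 / (m - 1))).astype(int)
    )
    pair_idx = vrng.integers(0, len(_ALLELE_PAIRS), size=m)
    eaf = vrng.uniform(0.05, 0.95, size=m)
    meta = pd.DataFrame(
        {
            "snp_id": list(ld.snp_ids),
            "chrom": str(chrom),
            "pos": pos,
            "effect_allele": [_ALLELE_PAIRS[i][0] for i in pair_idx],
            "other_allele": [_ALLELE_PAIRS[i][1] for i in pair_idx],
            "eaf": eaf,
        }
    )

    b_exp = _causal_vector(ld, truth.causal_exposure_snp, truth.beta_exposure_causal)
    if truth.scenario == "H4":
        out_effect = truth.theta * truth.beta_exposure_causal
        b_out = _causal_vector(ld, truth.causal_outcome_snp, out_effect)
    else:
        b_out = _causal_vector(ld, truth.causal_outcome_snp, truth.beta_outcome_direct)

    exp_rng = np.random.default_rng(subseed(seed, "exposure"))
    out_rng = np.random.default_rng(subseed(seed, "outcome"))
    exposure = _marginal_table(exp_rng, repaired, chol, b_exp, n_exposure, meta)
    outcome = _marginal_table(out_rng, repaired, chol, b_out, n_outcome, meta)
    return exposure, outcome


def largest_remainder_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Apportion ``n`` items to categories by the largest-remainder rule.

    Ties in the fractional remainders break toward the earlier category,
    making the apportionment deterministic.
    """
    p = np.asarray(proportions, dtype=float)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"proportions sum to {p.sum()!r}, not 1")
    raw = n * p
    base = np.floor(raw).astype(int)
    short = n - int(base.sum())
    order = sorted(range(len(p)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return base.tolist()


@dataclass(frozen=True)
class SimulationParams:
    """Study-level conditions for :func:`simulate_study`.

    Defaults mirror a blood eQTL study of 31,684 donors, a prefrontal
    cortex eQTL study of 1,387 donors, and a migraine GWAS of 589,356
    individuals. ``beta_eqtl`` is the planted per-allele expression
    effect at the causal eQTL (SD units, the scale of a strong lead
    cis-eQTL), identical in both tissues; ``theta`` is the causal
    effect of expression on outcome log-odds planted in H4 genes;
    ``beta_gwas`` is the direct per-allele outcome effect (log-odds)
    at H2/H3 outcome causal variants.
    """

    m_snps: int = 50
    rho: float = 0.5
    n_exposure: Mapping[str, int] = field(
        default_factory=lambda: {"blood": 31_684, "brain": 1_387}
    )
    n_outcome: int = 589_356
    beta_eqtl: float = 0.5
    beta_gwas: float = 0.02
    theta: float = 0.4
    case_fraction: float = 0.17
    window_bp: int = 100_000
    decoys_per_list: int = 8


@dataclass
class StudyBundle:
    """Everything a pipeline run consumes, plus the generating truth."""

    genes: pd.DataFrame  # symbol, chrom, tss, strand
    exposures: dict[str, pd.DataFrame]  # tissue -> summary table
    outcomes: dict[str, pd.DataFrame]  # tissue -> summary table
    ld: dict[str, LDMatrix]  # gene -> region LD
    druggable: dict[str, list[str]]  # source name -> symbols
    exclusions: pd.DataFrame  # snp_id, reason
    gene_sets: dict[str, tuple[str, tuple[str, ...]]]  # name -> (description, members)
    # simulation-only fields; empty when the bundle is loaded from user files
    truths: dict[tuple[str, str], SimulationTruth] = field(default_factory=dict)
    scenarios: dict[str, str] = field(default_factory=dict)
    params: SimulationParams | None = None
    seed: int = 0

    def truth_frame(self) -> pd.DataFrame:
        rows = [
            {
                "tissue": tissue,
                "gene": t.gene,
                "scenario": t.scenario,
                "causal_exposure_snp": t.causal_exposure_snp or "",
                "causal_outcome_snp": t.causal_outcome_snp or "",
                "beta_exposure_causal": t.beta_exposure_causal,
                "theta": t.theta,
                "beta_outcome_direct": t.beta_outcome_direct,
                "seed": t.seed,
            }
            for (tissue, _), t in sorted(self.truths.items())
        ]
        return pd.DataFrame(rows)


def _scenario_assignment(
    n_genes: int, scenario_mix: Sequence[float], rng: np.random.Generator
) -> list[str]:
    counts = largest_remainder_counts(n_genes, scenario_mix)
    # guarantee an H4 gene whenever the mix asks for any H4 mass, so the
    # cross-tissue intersection stage always has something to recover
    h4 = SCENARIOS.index("H4")
    if scenario_mix[h4] > 0 and counts[h4] == 0:
        counts[int(np.argmax(counts))] -= 1
        counts[h4] += 1
    labels = [s for s, c in zip(SCENARIOS, counts) for _ in range(c)]
    perm = rng.permutation(n_genes)
    return [labels[i] for i in perm]


def _region_truth(
    gene: str,
    scenario: str,
    ld: LDMatrix,
    params: SimulationParams,
    seed: int,
) -> SimulationTruth:
    m = ld.m
    center = ld.snp_ids[m // 2]
    e_idx, o_idx = ld.snp_ids[m // 5], ld.snp_ids[(4 * m) // 5]
    beta_exp = params.beta_eqtl
    beta_out = params.beta_gwas
    if scenario == "H0":
        return SimulationTruth(gene, "H0", seed=seed)
    if scenario == "H1":
        return SimulationTruth(gene, "H1", causal_exposure_snp=center,
                               beta_exposure_causal=beta_exp, seed=seed)
    if scenario == "H2":
        return SimulationTruth(gene, "H2", causal_outcome_snp=center,
                               beta_outcome_direct=beta_out, seed=seed)
    if scenario == "H3":
        return SimulationTruth(gene, "H3", causal_exposure_snp=e_idx,
                               causal_outcome_snp=o_idx,
                               beta_exposure_causal=beta_exp,
                               beta_outcome_direct=beta_out, seed=seed)
    return SimulationTruth(gene, "H4", causal_exposure_snp=center,
                           causal_outcome_snp=center,
                           beta_exposure_causal=beta_exp,
                           theta=params.theta, seed=seed)


def simulate_study(
    n_genes: int,
    scenario_mix: Sequence[float],
    params: SimulationParams | None = None,
    seed: int = 0,
) -> StudyBundle:
    """Generate a full two-tissue dataset bundle with known ground truth.

    ``scenario_mix`` gives the H0..H4 proportions (summing to 1); gene
    counts per scenario follow deterministic largest-remainder rounding
    and genes are assigned scenarios by a seeded permutation. A gene
    keeps the same scenario and causal variants in both tissues, with
    tissue-specific effect sizes scaled so causal SNPs reach
    ``params.z_target`` in each exposure study. The bundle includes two
    partially overlapping druggable lists covering every simulated
    gene, a small SNP exclusion list, and GMT gene sets (one enriched
    for the planted shared-causal genes, the rest random).
    """
    if n_genes < 1:
        raise ValueError(f"n_genes must be >= 1, got {n_genes}")
    params = params or SimulationParams()
    if len(scenario_mix) != len(SCENARIOS):
        raise ValueError("scenario_mix must have 5 entries (H0..H4)")

    assign_rng = np.random.default_rng(subseed(seed, "scenarios"))
    scenarios = _scenario_assignment(n_genes, scenario_mix, assign_rng)

    genes_rows, ld_map, truths = [], {}, {}
    exposures: dict[str, list[pd.DataFrame]] = {t: [] for t in params.n_exposure}
    outcomes: dict[str, list[pd.DataFrame]] = {t: [] for t in params.n_exposure}
    scen_map: dict[str, str] = {}

    for g in range(n_genes):
        gene = f"GENE{g + 1:04d}"
        chrom = str((g % 22) + 1)
        tss = 1_000_000 + (g // 22) * 1_000_000
        snp_ids = [f"rs{g + 1:04d}_{j + 1:03d}" for j in range(params.m_snps)]
        ld = make_ld_matrix(params.m_snps, params.rho, snp_ids=snp_ids)
        genes_rows.append({"symbol": gene, "chrom": chrom, "tss": tss, "strand": "+"})
        ld_map[gene] = ld
        scen_map[gene] = scenarios[g]
        variant_seed = subseed(seed, "variants", g)
        for tissue, n_exp in params.n_exposure.items():
            region_seed = subseed(seed, "region", g, tissue)
            truth = _region_truth(gene, scenarios[g], ld, params, region_seed)
            exp_df, out_df = simulate_region(
                truth, ld, n_exp, params.n_outcome, region_seed,
                chrom=chrom, tss=tss, case_fraction=params.case_fraction,
                variant_seed=variant_seed,
            )
            truths[(tissue, gene)] = truth
            exposures[tissue].append(exp_df)
            outcomes[tissue].append(out_df)

    genes = pd.DataFrame(genes_rows, columns=GENE_COLUMNS)
    all_symbols = genes["symbol"].tolist()

    # two overlapping druggable sources covering every simulated gene,
    # plus decoy symbols absent from the eQTL data
    cut_lo, cut_hi = n_genes // 3, max(1, (2 * n_genes + 2) // 3)
    list_a = all_symbols[:cut_hi] + [f"DECOY{i + 1:03d}A" for i in range(params.decoys_per_list)]
    list_b = all_symbols[cut_lo:] + [f"DECOY{i + 1:03d}B" for i in range(params.decoys_per_list)]

    # exclusion list: flank SNPs of the first gene, standing in for
    # variants with known direct disease/headache associations
    first_ids = ld_map[all_symbols[0]].snp_ids
    exclusions = pd.DataFrame(
        {"snp_id": [first_ids[0], first_ids[-1]], "reason": ["migraine", "headache"]}
    )

    set_rng = np.random.default_rng(subseed(seed, "gene_sets"))
    h4_genes = [s for s in all_symbols if scen_map[s] == "H4"]
    causal_members = sorted(
        set(h4_genes)
        | set(set_rng.choice(all_symbols, size=min(3, n_genes), replace=False))
    )
    gene_sets: dict[str, tuple[str, tuple[str, ...]]] = {
        "SHARED_CAUSAL_PATHWAY": (
            "genes enriched for planted shared-causal signals",
            tuple(causal_members),
        )
    }
    for k in range(4):
        size = min(n_genes, max(3, n_genes // 4))
        members = sorted(set_rng.choice(all_symbols, size=size, replace=False))
        gene_sets[f"RANDOM_PATHWAY_{k + 1}"] = ("random gene set", tuple(members))

    return StudyBundle(
        genes=genes,
        exposures={t: pd.concat(v, ignore_index=True) for t, v in exposures.items()},
        outcomes={t: pd.concat(v, ignore_index=True) for t, v in outcomes.items()},
        ld=ld_map,
        druggable={"source_a": list_a, "source_b": list_b},
        exclusions=exclusions,
        gene_sets=gene_sets,
        truths=truths,
        scenarios=scen_map,
        params=params,
        seed=seed,
    )
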