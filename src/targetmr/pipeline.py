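"""Two-tissue discovery pipeline.

Orchestrates candidate selection -> cis-instrument construction ->
harmonization -> MR estimation -> study-wide FDR -> colocalization ->
cross-tissue intersection -> enrichment, with per-stage gene counts
recorded in a run manifest. A gene is declared significant in a tissue
only when it passes both the MR FDR threshold and the PPH4
colocalization threshold; the cross-tissue table lists genes
significant in every tissue.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .coloc import coloc_abf, coloc_window_extract
from .config import RunConfig
from .druggable import GeneSetCatalog, intersect_with_eqtl_genes, merge_druggable_lists
from .enrichment import ora
from .harmonize import harmonize_set
from .instruments import build_instrument_set
from .io import load_study, write_tsv
from .mr import bh_adjust, run_mr_gene
from .records import ColocResult, MRResult, coloc_results_frame, mr_results_frame
from .synthetic import StudyBundle

logger = logging.getLogger(__name__)


@dataclass
class TissueResult:
    tissue: str
    mr_results: list[MRResult] = field(default_factory=list)
    coloc_results: list[ColocResult] = field(default_factory=list)
    dropped: list[dict] = field(default_factory=list)  # gene, stage, reason
    counts: dict[str, int] = field(default_factory=dict)
    mr_significant: list[str] = field(default_factory=list)
    significant: list[str] = field(default_factory=list)

    def mr_frame(self) -> pd.DataFrame:
        return mr_results_frame(self.mr_results)

    def coloc_frame(self) -> pd.DataFrame:
        return coloc_results_frame(self.coloc_results)

    def forest_frame(self) -> pd.DataFrame:
        df = self.mr_frame()
        return df[["gene", "n_snps", "or_value", "ci95_low", "ci95_high",
                   "pvalue", "fdr_pvalue"]]


@dataclass
class PipelineResult:
    tissues: dict[str, TissueResult]
    cross_tissue: list[str]
    enrichment: pd.DataFrame
    comparators: pd.DataFrame
    manifest: dict


def _tissue_mr_stage(
    data: StudyBundle, tissue: str, config: RunConfig, druggable: list[str]
) -> TissueResult:
    """Candidates -> instruments -> harmonization -> MR for one tissue."""
    th, opt = config.thresholds, config.options
    res = TissueResult(tissue)
    expo = data.exposures[tissue]
    outc = data.outcomes[tissue]
    ann = data.genes.set_index("symbol")

    # genes measured in this tissue: annotation genes with >=1 exposure
    # record inside their cis window
    eqtl_genes = []
    for symbol, row in ann.iterrows():
        sub = expo[expo["chrom"].astype(str) == str(row["chrom"])]
        lo, hi = row["tss"] - th.window_bp, row["tss"] + th.window_bp
        if ((sub["pos"] >= lo) & (sub["pos"] <= hi)).any():
            eqtl_genes.append(symbol)
    res.counts["druggable_merged"] = len(druggable)
    res.counts["eqtl_genes"] = len(eqtl_genes)
    candidates = intersect_with_eqtl_genes(druggable, eqtl_genes)
    res.counts["candidates"] = len(candidates)

    for gene in candidates:
        row = ann.loc[gene]
        sub = expo[expo["chrom"].astype(str) == str(row["chrom"])]
        if gene not in data.ld:
            res.dropped.append({"gene": gene, "stage": "instruments",
                                "reason": "no LD matrix for region"})
            continue
        inst = build_instrument_set(
            gene, sub, int(row["tss"]), data.ld[gene],
            exclusion_list=data.exclusions,
            window_bp=th.window_bp, fdr_threshold=th.eqtl_fdr,
            r2_threshold=th.clump_r2, use_fdr_column=opt.use_fdr_column,
            missing_ld=opt.missing_ld,
        )
        if len(inst.snps) == 0:
            res.dropped.append({"gene": gene, "stage": "instruments",
                                "reason": "no instruments after selection/screen"})
            continue
        out_sub = outc[outc["snp_id"].isin(set(inst.snps["snp_id"]))]
        pairs, _ = harmonize_set(inst.snps, out_sub, opt.palindrome_eaf_limit)
        if len(pairs) == 0:
            res.dropped.append({"gene": gene, "stage": "harmonization",
                                "reason": "no harmonizable exposure/outcome pairs"})
            continue
        try:
            res.mr_results.append(
                run_mr_gene(pairs, gene, tissue, re_flavor=opt.re_flavor,
                            wald_se=opt.wald_se)
            )
        except Exception as exc:  # keep going past per-gene failures
            logger.error("gene %s (%s): MR failed: %s", gene, tissue, exc)
            res.dropped.append({"gene": gene, "stage": "mr", "reason": str(exc)})
    res.counts["mr_tested"] = len(res.mr_results)
    res.counts["dropped_before_mr"] = len(res.dropped)
    return res


def _tissue_coloc_stage(
    data: StudyBundle, tissue: str, config: RunConfig, res: TissueResult
) -> None:
    th = config.thresholds
    ann = data.genes.set_index("symbol")
    targets = (
        [r.gene for r in res.mr_results]
        if config.options.coloc_all_genes
        else list(res.mr_significant)
    )
    res.counts["coloc_candidates"] = len(targets)
    for gene in targets:
        row = ann.loc[gene]
        eqtl_r, gwas_r = coloc_window_extract(
            data.outcomes[tissue], data.exposures[tissue],
            int(row["tss"]), th.window_bp, chrom=str(row["chrom"]),
        )
        if len(eqtl_r) == 0:
            res.dropped.append({"gene": gene, "stage": "coloc",
                                "reason": "no shared SNPs in cis window"})
            continue
        res.coloc_results.append(
            coloc_abf(eqtl_r, gwas_r, config.priors, gene=gene,
                      pph4_threshold=th.pph4_min)
        )
    res.counts["coloc_computed"] = len(res.coloc_results)


def comparator_report(
    gene_list: Iterable[str],
    tissue_results: Mapping[str, TissueResult],
    mr_fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-tissue MR rows for named comparator genes, significance-flagged.

    Comparators absent from a tissue's MR results get a ``not-testable``
    row; tested genes are flagged ``significant`` (FDR below threshold),
    ``nominal-only`` (raw p below but FDR above), or ``not-significant``.
    """
    rows = []
    for tissue in sorted(tissue_results):
        frame = tissue_results[tissue].mr_frame().set_index("gene")
        for gene in gene_list:
            if gene not in frame.index:
                rows.append({"gene": gene, "tissue_label": tissue, "status": "not-testable"})
                continue
            r = frame.loc[gene]
            if r["fdr_pvalue"] < mr_fdr:
                status = "significant"
            elif r["pvalue"] < mr_fdr:
                status = "nominal-only"
            else:
                status = "not-significant"
            rows.append({
                "gene": gene, "tissue_label": tissue, "status": status,
                "n_snps": r["n_snps"], "or_value": r["or_value"],
                "ci95_low": r["ci95_low"], "ci95_high": r["ci95_high"],
                "pvalue": r["pvalue"], "fdr_pvalue": r["fdr_pvalue"],
            })
    cols = ["gene", "tissue_label", "status", "n_snps", "or_value",
            "ci95_low", "ci95_high", "pvalue", "fdr_pvalue"]
    return pd.DataFrame(rows, columns=cols)


def run_study(data: StudyBundle, config: RunConfig) -> PipelineResult:
    """Execute the full discovery pipeline on an in-memory bundle."""
    config.validate()
    th, opt = config.thresholds, config.options
    catalogs = [
        GeneSetCatalog.from_symbols(name, symbols)
        for name, symbols in sorted(data.druggable.items())
    ]
    druggable = merge_druggable_lists(catalogs)

    tissues: dict[str, TissueResult] = {}
    for tissue in sorted(data.exposures):
        tissues[tissue] = _tissue_mr_stage(data, tissue, config, druggable)

    # FDR family: each tissue separately (default) or all tested genes at once
    if opt.fdr_family == "per_tissue":
        for res in tissues.values():
            if res.mr_results:
                adj = bh_adjust([r.pvalue for r in res.mr_results])
                for r, a in zip(res.mr_results, adj):
                    r.fdr_pvalue = float(a)
    else:
        flat = [r for res in tissues.values() for r in res.mr_results]
        if flat:
            adj = bh_adjust([r.pvalue for r in flat])
            for r, a in zip(flat, adj):
                r.fdr_pvalue = float(a)

    for res in tissues.values():
        res.mr_significant = sorted(
            r.gene for r in res.mr_results
            if r.fdr_pvalue is not None and r.fdr_pvalue < th.mr_fdr
        )
        res.counts["mr_fdr_significant"] = len(res.mr_significant)

    for tissue, res in tissues.items():
        _tissue_coloc_stage(data, tissue, config, res)
        coloc_pass = {c.gene for c in res.coloc_results if c.passes_threshold}
        res.counts["coloc_pass"] = len(coloc_pass)
        res.significant = sorted(set(res.mr_significant) & coloc_pass)
        res.counts["significant"] = len(res.significant)

    cross = sorted(
        set.intersection(*(set(res.significant) for res in tissues.values()))
        if tissues else set()
    )

    hits = sorted(set().union(*(res.significant for res in tissues.values())))
    universe = sorted(
        set().union(*({r.gene for r in res.mr_results} for res in tissues.values()))
    )
    if data.gene_sets and hits:
        enrichment = ora(hits, universe, data.gene_sets, opt.min_set_size)
    else:
        enrichment = pd.DataFrame(
            columns=["set_name", "overlap_k", "set_size_K", "hits_n",
                     "universe_N", "pvalue", "fdr_pvalue", "overlapping_symbols"]
        )

    comparators = comparator_report(opt.comparators, tissues, th.mr_fdr)

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "tissues": {
            t: {
                "counts": res.counts,
                "dropped": res.dropped,
                "mr_significant": res.mr_significant,
                "significant": res.significant,
            }
            for t, res in tissues.items()
        },
        "cross_tissue": cross,
        "n_cross_tissue": len(cross),
        "enrichment_sets_tested": int(len(enrichment)),
    }
    return PipelineResult(tissues, cross, enrichment, comparators, manifest)


def write_results(result: PipelineResult, out_dir: str | Path) -> None:
    """Write all result tables and the manifest; byte-stable across reruns."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tissue in sorted(result.tissues):
        res = result.tissues[tissue]
        write_tsv(res.mr_frame(), out / f"mr_{tissue}.tsv")
        write_tsv(res.forest_frame(), out / f"forest_{tissue}.tsv")
        write_tsv(res.coloc_frame(), out / f"coloc_{tissue}.tsv")
        (out / f"significant_{tissue}.txt").write_text(
            "".join(f"{g}\n" for g in res.significant)
        )
    write_tsv(
        pd.DataFrame({"gene": result.cross_tissue}), out / "cross_tissue.tsv"
    )
    write_tsv(result.enrichment, out / "enrichment.tsv")
    if len(result.comparators):
        write_tsv(result.comparators, out / "comparators.tsv")
    (out / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load inputs from the config's paths, run the study, write outputs."""
    data = load_study(config)
    result = run_study(data, config)
    write_results(result, config.out_dir)
    return result
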