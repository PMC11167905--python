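"""Readers and writers for the pipeline's plain-text formats.

Summary statistics, gene annotations and exclusion lists are TSV; LD
matrices are whitespace-delimited square matrices with a SNP-id header
row; gene lists are one symbol per line; gene sets are GMT. Floats are
written with a fixed ``%.10g`` format so identical runs produce
byte-identical files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .config import Paths, RunConfig
from .records import GENE_COLUMNS, SUMMARY_COLUMNS, LDMatrix
from .synthetic import StudyBundle

FLOAT_FMT = "%.10g"


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def read_summary_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing summary columns {missing}")
    return df


def read_genes_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"symbol": str, "chrom": str})
    missing = [c for c in GENE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing gene annotation columns {missing}")
    return df


def read_gene_list(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def write_gene_list(symbols, path: str | Path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in symbols))


def read_exclusions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "snp_id" not in df.columns:
        raise ValueError(f"{path}: exclusion list needs a snp_id column")
    if "reason" not in df.columns:
        df["reason"] = "excluded"
    return df[["snp_id", "reason"]]


def write_ld_matrix(ld: LDMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(ld.snp_ids) + "\n")
        for row in ld.r:
            fh.write(" ".join(FLOAT_FMT % v for v in row) + "\n")


def read_ld_matrix(path: str | Path) -> LDMatrix:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty LD matrix file")
    snp_ids = tuple(lines[0].split())
    r = np.loadtxt(lines[1:], dtype=float, ndmin=2)
    return LDMatrix(snp_ids, r)


def write_gmt(catalog: Mapping[str, tuple[str, tuple[str, ...]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in catalog.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_bundle(bundle: StudyBundle, out_dir: str | Path) -> RunConfig:
    """Write a simulated study to disk and return a ready-to-run config.

    Layout: exposure_<tissue>.tsv, outcome_<tissue>.tsv, genes.tsv,
    druggable_<source>.txt, exclusions.tsv, gene_sets.gmt,
    ld/<gene>.ld, truth.tsv, config.yaml.
    """
    out = Path(out_dir)
    (out / "ld").mkdir(parents=True, exist_ok=True)
    paths = Paths(annotations=str(out / "genes.tsv"), ld_dir=str(out / "ld"))
    write_tsv(bundle.genes, out / "genes.tsv")
    outcome_paths: dict[str, str] = {}
    for tissue in sorted(bundle.exposures):
        p_exp = out / f"exposure_{tissue}.tsv"
        p_out = out / f"outcome_{tissue}.tsv"
        write_tsv(bundle.exposures[tissue], p_exp)
        write_tsv(bundle.outcomes[tissue], p_out)
        paths.exposure[tissue] = str(p_exp)
        outcome_paths[tissue] = str(p_out)
    paths.outcome = outcome_paths
    for source in sorted(bundle.druggable):
        p = out / f"druggable_{source}.txt"
        write_gene_list(bundle.druggable[source], p)
        paths.druggable.append(str(p))
    write_tsv(bundle.exclusions, out / "exclusions.tsv")
    paths.exclusions = str(out / "exclusions.tsv")
    write_gmt(bundle.gene_sets, out / "gene_sets.gmt")
    paths.gene_sets = str(out / "gene_sets.gmt")
    for gene in sorted(bundle.ld):
        write_ld_matrix(bundle.ld[gene], out / "ld" / f"{gene}.ld")
    if bundle.truths:
        write_tsv(bundle.truth_frame(), out / "truth.tsv")
    cfg = RunConfig(paths=paths, seed=bundle.seed, out_dir=str(out / "results"))
    (out / "config.yaml").write_text(cfg.to_yaml())
    return cfg


def load_study(config: RunConfig) -> StudyBundle:
    """Load the input bundle a RunConfig points at."""
    paths = config.paths
    if not paths.exposure:
        raise ValueError("config.paths.exposure must name at least one tissue")
    exposures = {t: read_summary_tsv(p) for t, p in sorted(paths.exposure.items())}
    outcomes = {t: read_summary_tsv(paths.outcome_for(t)) for t in exposures}
    genes = read_genes_tsv(paths.annotations)
    druggable = {
        Path(p).stem: read_gene_list(p) for p in paths.druggable
    }
    if not druggable:
        raise ValueError("config.paths.druggable must name at least one list")
    ld_dir = Path(paths.ld_dir)
    ld = {
        f.stem: read_ld_matrix(f) for f in sorted(ld_dir.glob("*.ld"))
    }
    exclusions = (
        read_exclusions(paths.exclusions)
        if paths.exclusions
        else pd.DataFrame(columns=["snp_id", "reason"])
    )
    gene_sets = {}
    if paths.gene_sets:
        from .enrichment import read_gmt

        gene_sets = read_gmt(paths.gene_sets)
    return StudyBundle(
        genes=genes,
        exposures=exposures,
        outcomes=outcomes,
        ld=ld,
        druggable=druggable,
        exclusions=exclusions,
        gene_sets=gene_sets,
    )
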