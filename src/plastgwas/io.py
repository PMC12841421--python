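"""Readers and writers for the panel, phenotype, and truth-registry formats.

Genotype panels round-trip through either a minimal VCF (one pseudo-contig
per chromosome, GT-only, ``0/0``/``1/1``/``./.`` for the inbred coding) or a
PLINK-like pair of TSVs (wide genotype table + marker map).  Phenotypes and
QTL registries are plain long-format TSVs.  Missing genotypes are preserved
on export; imputation is an in-memory concern only.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import GenotypePanel, QTLRegistry

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
    "write_registry_tsv",
    "read_registry_tsv",
]


def write_vcf(panel: GenotypePanel, path: str | os.PathLike) -> None:
    path = Path(path)
    chroms = panel.markers["chrom"].unique()
    max_pos = panel.markers.groupby("chrom", sort=False)["pos"].max()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=plastgwas-simdata\n")
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={int(max_pos[c]) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(panel.line_ids)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        gt_code = {0.0: "0/0", 2.0: "1/1"}
        for j, (mid, chrom, pos) in enumerate(
            panel.markers[["marker_id", "chrom", "pos"]].itertuples(index=False)
        ):
            col = panel.genotypes[:, j]
            gts = "\t".join("./." if np.isnan(v) else gt_code[v] for v in col)
            fh.write(f"{chrom}\t{int(pos)}\t{mid}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str | os.PathLike) -> GenotypePanel:
    """Load a biallelic GT-only VCF into a panel.

    Family labels are recovered from the ``<family>_<line>`` sample-name
    convention; samples without an underscore fall into one family ``F00``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, geno_cols = [], []
    for var in vcf:
        rows.append((var.ID, var.CHROM, var.POS))
        # cyvcf2 gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        gt = var.gt_types
        col = np.where(gt == 0, 0.0, np.where(gt == 3, 2.0, np.nan))
        if (gt == 1).any():
            raise ValueError(f"heterozygous call at {var.ID}: panel must be inbred-coded")
        geno_cols.append(col)
    markers = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos"])
    geno = np.column_stack(geno_cols) if geno_cols else np.empty((len(samples), 0))
    fams = pd.Series(
        [s.split("_")[0] if "_" in s else "F00" for s in samples], index=samples, name="family"
    )
    return GenotypePanel(genotypes=geno, markers=markers, line_ids=samples, families=fams)


def write_genotypes_tsv(panel: GenotypePanel, prefix: str | os.PathLike) -> tuple[Path, Path]:
    """Write ``<prefix>_geno.tsv`` (wide, lines x markers) and ``<prefix>_map.tsv``."""
    prefix = Path(prefix)
    geno_path = prefix.with_name(prefix.name + "_geno.tsv")
    map_path = prefix.with_name(prefix.name + "_map.tsv")
    wide = pd.DataFrame(
        panel.genotypes, index=panel.line_ids, columns=panel.markers["marker_id"]
    )
    wide.insert(0, "family", panel.families.reindex(panel.line_ids).to_numpy())
    wide.to_csv(geno_path, sep="\t", index_label="line_id", na_rep="NA")
    panel.markers.to_csv(map_path, sep="\t", index=False)
    return geno_path, map_path


def read_genotypes_tsv(prefix: str | os.PathLike) -> GenotypePanel:
    prefix = Path(prefix)
    wide = pd.read_csv(prefix.with_name(prefix.name + "_geno.tsv"), sep="\t", index_col="line_id")
    markers = pd.read_csv(prefix.with_name(prefix.name + "_map.tsv"), sep="\t")
    fams = wide.pop("family")
    geno = wide.to_numpy(dtype=float)
    if list(wide.columns) != list(markers["marker_id"]):
        raise ValueError("genotype columns do not match marker map order")
    return GenotypePanel(
        genotypes=geno,
        markers=markers,
        line_ids=list(wide.index),
        families=pd.Series(fams.to_numpy(), index=wide.index, name="family"),
    )


def write_phenotypes_tsv(phenotypes: pd.DataFrame, path: str | os.PathLike) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"genotype", "trait", "env", "rep", "value"}
    if not expected.issubset(df.columns):
        raise ValueError(f"phenotype table needs columns {sorted(expected)}")
    return df


def write_registry_tsv(registry: QTLRegistry, path: str | os.PathLike) -> None:
    registry.entries.to_csv(path, sep="\t", index=False)


def read_registry_tsv(path: str | os.PathLike) -> QTLRegistry:
    df = pd.read_csv(path, sep="\t")
    df["antagonistic"] = df["antagonistic"].astype(bool)
    return QTLRegistry(entries=df[QTLRegistry.COLUMNS])
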