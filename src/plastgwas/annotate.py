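"""SNP region classification, GO overrepresentation, karyogram export, and
allele-direction (antagonistic-pleiotropy) analysis.

Region classes partition markers three ways against a GFF3 annotation: a
marker inside any CDS interval of a gene is ``coding``, inside a gene body
but outside every CDS is ``intronic`` (UTR variants land here too), and
``intergenic`` otherwise, with the distance to the nearest gene.  GO
overrepresentation is the one-sided Fisher exact test (hypergeometric upper
tail) per term with Benjamini–Hochberg FDR across terms, counting genes
once regardless of SNP multiplicity.  Allele-direction analysis flags
antagonistic pleiotropy when a marker's estimated per-environment effects
have opposite signs and each clears a noise floor of k standard errors.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simdata import GenotypePanel

__all__ = [
    "classify_region",
    "go_enrichment",
    "allele_direction",
    "karyogram_export",
    "read_bed_track",
    "synthetic_annotation",
]


def _validate_gff3(path: str | os.PathLike) -> None:
    """Structural check with line numbers (the downstream parser reports none)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"malformed GFF3 at line {lineno}: expected 9 tab-separated "
                    f"fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError:
                raise ValueError(
                    f"malformed GFF3 at line {lineno}: non-integer coordinates"
                ) from None
            if start < 1 or end < start:
                raise ValueError(
                    f"malformed GFF3 at line {lineno}: invalid interval "
                    f"[{start}, {end}]"
                )


def _load_gene_models(gff3_path: str | os.PathLike):
    """Gene and union-of-CDS intervals per chromosome from a GFF3 file."""
    import gffutils

    _validate_gff3(gff3_path)
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: dict[str, list[tuple[int, int, str]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    for gene in db.features_of_type("gene"):
        genes.setdefault(gene.seqid, []).append((gene.start, gene.end, gene.id))
        intervals = sorted(
            (c.start, c.end)
            for c in db.children(gene, featuretype="CDS")
        )
        merged: list[tuple[int, int]] = []
        for s, e in intervals:  # union across transcripts
            if merged and s <= merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        cds[gene.id] = merged
    return genes, cds


def classify_region(markers: pd.DataFrame, gff3_path: str | os.PathLike) -> pd.DataFrame:
    """Classify each marker as coding / intronic / intergenic.

    ``markers`` needs columns marker_id, chrom, pos (1-based).  Returns a
    DataFrame with marker_id, region, gene_id (NaN when intergenic) and the
    bp distance to the nearest gene (0 when inside one).
    """
    genes, cds = _load_gene_models(gff3_path)
    rows = []
    for mid, chrom, pos in markers[["marker_id", "chrom", "pos"]].itertuples(index=False):
        region, gene_id, dist = "intergenic", None, np.inf
        for start, end, gid in genes.get(chrom, []):
            if start <= pos <= end:
                dist = 0
                gene_id = gid
                region = (
                    "coding"
                    if any(s <= pos <= e for s, e in cds.get(gid, []))
                    else "intronic"
                )
                break
            dist = min(dist, abs(pos - start), abs(pos - end))
        if region == "intergenic":
            gene_id = None
            dist = int(dist) if np.isfinite(dist) else -1
        rows.append(
            {"marker_id": mid, "region": region, "gene_id": gene_id, "distance": dist}
        )
    return pd.DataFrame(rows, columns=["marker_id", "region", "gene_id", "distance"])


def go_enrichment(
    study_genes: set[str] | list[str],
    population_genes: set[str] | list[str],
    gene2go: pd.DataFrame,
) -> pd.DataFrame:
    """One-sided Fisher overrepresentation test per GO term, BH-corrected.

    ``gene2go`` needs columns gene_id, go_id.  Genes are the counting unit.
    Terms with zero study genes are skipped.  The one-sided Fisher p for a
    2x2 table with fixed margins equals the hypergeometric upper tail
    P(X >= k) with N = population size, K = term genes, n = study size.
    """
    study = set(study_genes)
    population = set(population_genes)
    if not study <= population:
        raise ValueError("study genes must be a subset of the population")
    g2g = gene2go[gene2go["gene_id"].isin(population)]
    n_pop = len(population)
    n_study = len(study)
    rows = []
    for term, genes in g2g.groupby("go_id")["gene_id"]:
        term_genes = set(genes)
        k = len(term_genes & study)
        if k == 0:
            continue
        K = len(term_genes)
        p = float(stats.hypergeom.sf(k - 1, n_pop, K, n_study))
        a, b = k, n_study - k
        c, d = K - k, n_pop - n_study - (K - k)
        odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append(
            {
                "go_id": term,
                "study_count": k,
                "study_size": n_study,
                "pop_count": K,
                "pop_size": n_pop,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "go_id",
            "study_count",
            "study_size",
            "pop_count",
            "pop_size",
            "odds_ratio",
            "p_value",
        ],
    )
    if len(out):
        out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values("p_value").reset_index(drop=True)
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


def allele_direction(
    panel: GenotypePanel,
    plasticity: pd.DataFrame,
    effects_ww: pd.DataFrame,
    effects_wl: pd.DataFrame,
    markers: list[str],
    trait: str,
    k_se: float = 2.0,
) -> pd.DataFrame:
    """Allele-stratified plasticity means plus the antagonism flag.

    ``effects_ww``/``effects_wl`` are scan tables (marker_id, score, se) for
    the per-environment responses.  A marker is flagged antagonistic when
    its WW and WL effect estimates have opposite signs and each exceeds
    ``k_se`` standard errors in magnitude.  Monomorphic markers are skipped
    with a warning.
    """
    eww = effects_ww.set_index("marker_id")
    ewl = effects_wl.set_index("marker_id")
    est_cols = [c for c in ("WW", "WL", "Ratio", "RDPI", "Linear") if c in plasticity.columns]
    try:
        plast = plasticity.xs(trait, level="trait")
    except KeyError:
        raise KeyError(f"trait {trait!r} absent from plasticity table") from None

    rows = []
    for mk in markers:
        j = panel.marker_index([mk])[0]
        x = panel.genotypes[:, j]
        alleles = np.unique(x[np.isfinite(x)])
        if len(alleles) < 2:
            warnings.warn(f"marker {mk} is monomorphic; skipped")
            continue
        b_ww, s_ww = float(eww.loc[mk, "score"]), float(eww.loc[mk, "se"])
        b_wl, s_wl = float(ewl.loc[mk, "score"]), float(ewl.loc[mk, "se"])
        antagonistic = bool(
            np.sign(b_ww) * np.sign(b_wl) < 0
            and abs(b_ww) > k_se * s_ww
            and abs(b_wl) > k_se * s_wl
        )
        for est in est_cols:
            vals = plast[est].reindex(panel.line_ids).to_numpy(dtype=float)
            for allele in alleles:
                sel = x == allele
                rows.append(
                    {
                        "marker_id": mk,
                        "trait": trait,
                        "estimator": est,
                        "allele": int(allele),
                        "mean_value": float(np.nanmean(vals[sel])),
                        "n_lines": int(sel.sum()),
                        "effect_WW": b_ww,
                        "effect_WL": b_wl,
                        "sign_WW": int(np.sign(b_ww)),
                        "sign_WL": int(np.sign(b_wl)),
                        "antagonistic": antagonistic,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "marker_id",
            "trait",
            "estimator",
            "allele",
            "mean_value",
            "n_lines",
            "effect_WW",
            "effect_WL",
            "sign_WW",
            "sign_WL",
            "antagonistic",
        ],
    )


def karyogram_export(
    markers: pd.DataFrame,
    chrom_lengths: dict[str, int],
    path: str | os.PathLike | None = None,
) -> pd.DataFrame:
    """BED track (0-based half-open) of significant markers for plotting.

    ``markers`` needs columns marker_id, chrom, pos (1-based) and trait (the
    BED name field).  A 1-based position p becomes the interval [p-1, p).
    """
    rows = []
    for mid, chrom, pos, trait in markers[["marker_id", "chrom", "pos", "trait"]].itertuples(
        index=False
    ):
        if chrom not in chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if pos < 1 or pos > chrom_lengths[chrom]:
            raise ValueError(
                f"marker {mid} at {chrom}:{pos} beyond chromosome length "
                f"{chrom_lengths[chrom]}"
            )
        rows.append({"chrom": chrom, "start": int(pos) - 1, "end": int(pos), "name": trait})
    bed = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    if path is not None:
        bed.to_csv(path, sep="\t", header=False, index=False)
    return bed


def read_bed_track(path: str | os.PathLike) -> pd.DataFrame:
    """Inverse of ``karyogram_export``: recover 1-based map positions."""
    bed = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "name"])
    out = bed.copy()
    out["pos"] = out["start"] + 1
    return out[["chrom", "pos", "name"]]


def synthetic_annotation(
    panel: GenotypePanel,
    seed: int = 0,
    gene_fraction: float = 0.4,
    coding_fraction: float = 0.5,
    n_go_terms: int = 12,
    out_dir: str | os.PathLike | None = None,
) -> tuple[str, pd.DataFrame]:
    """Synthetic GFF3 + gene-to-GO fixture generator.

    Builds gene models around a random subset of markers so that roughly
    ``gene_fraction`` of markers fall inside genes and ``coding_fraction``
    of those inside CDS, then assigns each gene 1-3 GO terms.  Returns the
    GFF3 text and the gene2go DataFrame; optionally writes
    ``annotation.gff3`` and ``gene2go.tsv`` under ``out_dir``.  Synthetic
    stand-ins, not a real genome annotation.
    """
    rng = np.random.default_rng(seed)
    lines = ["##gff-version 3"]
    g2g_rows = []
    gene_n = 0
    for chrom, sub in panel.markers.groupby("chrom", sort=False):
        for _, row in sub.iterrows():
            if rng.random() > gene_fraction:
                continue
            gene_n += 1
            gid = f"GENE{gene_n:05d}"
            pos = int(row["pos"])
            start = max(1, pos - int(rng.integers(200, 2000)))
            end = pos + int(rng.integers(200, 2000))
            lines.append(
                f"{chrom}\tsynthetic\tgene\t{start}\t{end}\t.\t+\t.\tID={gid}"
            )
            mid = f"{gid}.m1"
            lines.append(
                f"{chrom}\tsynthetic\tmRNA\t{start}\t{end}\t.\t+\t.\tID={mid};Parent={gid}"
            )
            if rng.random() < coding_fraction:
                c_start, c_end = min(pos, end - 1), min(pos + 50, end)
            else:  # CDS blocks that exclude the marker position
                c_start, c_end = start, max(start + 1, pos - 100)
                if c_end >= pos:
                    c_start, c_end = min(pos + 100, end - 1), end
            lines.append(
                f"{chrom}\tsynthetic\tCDS\t{c_start}\t{c_end}\t.\t+\t0\t"
                f"ID={gid}.cds;Parent={mid}"
            )
            for _ in range(int(rng.integers(1, 4))):
                g2g_rows.append(
                    {
                        "gene_id": gid,
                        "go_id": f"GO:{int(rng.integers(0, n_go_terms)):07d}",
                        "namespace": "biological_process",
                    }
                )
    gff_text = "\n".join(lines) + "\n"
    gene2go = pd.DataFrame(g2g_rows, columns=["gene_id", "go_id", "namespace"]).drop_duplicates()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "annotation.gff3").write_text(gff_text)
        gene2go.to_csv(out_dir / "gene2go.tsv", sep="\t", index=False)
    return gff_text, gene2go
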