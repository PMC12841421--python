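"""Classify consensus SNPs against a synthetic GFF3 annotation, run GO
overrepresentation on the genes they hit, export the karyogram track, and
test each consensus SNP for antagonistic (sign-flipping) allele effects
across water regimes."""

import pandas as pd
from _common import SEED, outdir

from plastgwas import annotate, popgen, scans
from plastgwas import io as pio
from plastgwas.plasticity import env_means, plasticity_table

src_sim = outdir("01_simulate")
src_cons = outdir("06_consensus")
out = outdir("07_annotation")

panel = pio.read_vcf(src_sim / "panel.vcf")
qc_panel, _ = popgen.marker_qc(panel)
cons = pd.read_csv(src_cons / "consensus.tsv", sep="\t")

gff_text, gene2go = annotate.synthetic_annotation(qc_panel, seed=SEED + 13, out_dir=out)
regions = annotate.classify_region(qc_panel.markers, out / "annotation.gff3")
regions.to_csv(out / "regions.tsv", sep="\t", index=False)
print("marker region classes:", regions["region"].value_counts().to_dict())

lookup = regions.set_index("marker_id")
study = set(lookup.reindex(cons["marker_id"])["gene_id"].dropna())
population = set(regions["gene_id"].dropna())
if study:
    enr = annotate.go_enrichment(study, population, gene2go)
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    print(f"GO terms tested: {len(enr)}; min FDR = "
          f"{enr['fdr'].min():.3f}" if len(enr) else "no terms")

sig = cons.merge(qc_panel.markers, on="marker_id")
chrom_lengths = {c: int(s["pos"].max()) + 1000
                 for c, s in qc_panel.markers.groupby("chrom")}
annotate.karyogram_export(sig[["marker_id", "chrom", "pos", "trait"]],
                          chrom_lengths, path=out / "karyogram.bed")

phen = pio.read_phenotypes_tsv(src_sim / "phenotypes.tsv")
plast = plasticity_table(env_means(phen))
K = popgen.kinship(qc_panel)
eff_ww = scans.mlm_scan(qc_panel, plast.xs("GY", level="trait")["WW"], K).table
eff_wl = scans.mlm_scan(qc_panel, plast.xs("GY", level="trait")["WL"], K).table
direction = annotate.allele_direction(
    qc_panel, plast, eff_ww, eff_wl, sorted(set(cons["marker_id"])), "GY")
direction.to_csv(out / "allele_direction.tsv", sep="\t", index=False)
flagged = direction.loc[direction["antagonistic"], "marker_id"].unique()
print(f"antagonistic-pleiotropy flags: {sorted(flagged)}")
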