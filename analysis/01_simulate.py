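"""Simulate the study population: a multi-family inbred barley-like panel
genotyped on 7 chromosomes, phenotyped for grain yield under well-watered
(WW) and water-limited (WL) regimes, with three planted QTLs (main-effect,
WW-specific plastic, antagonistic) whose identities are kept in a truth
registry for downstream recovery checks."""

from _common import CONFIG, QTL_SPECS, SEED, outdir

from plastgwas import io as pio
from plastgwas import simdata

out = outdir("01_simulate")

panel = simdata.simulate_genotypes(CONFIG)
registry = simdata.plant_qtls(
    panel, QTL_SPECS, seed=SEED + 7,
    sigma2_poly=CONFIG.sigma2_poly, sigma2_resid=CONFIG.sigma2_resid,
)
phenotypes = simdata.simulate_phenotypes(panel, registry, CONFIG)

pio.write_vcf(panel, out / "panel.vcf")
pio.write_genotypes_tsv(panel, out / "panel")
pio.write_phenotypes_tsv(phenotypes, out / "phenotypes.tsv")
pio.write_registry_tsv(registry, out / "qtl_truth.tsv")

print(f"panel: {panel.n_lines} lines x {panel.n_markers} markers, "
      f"{panel.markers['chrom'].nunique()} chromosomes")
print(f"planted QTLs:\n{registry.entries}")
print(f"phenotype records: {len(phenotypes)}")
print(f"outputs in {out}")
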