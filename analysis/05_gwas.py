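"""Run the four association-scan families (kinship mixed model, iterative
multilocus, Random Forest, gradient boosting) over every plasticity
estimator of the focal trait, calling significance at BH FDR 0.05 for
model-based p-values and empirical 0.05 for permutation p-values."""

import json

import pandas as pd
from _common import SEED, outdir

from plastgwas import io as pio
from plastgwas import popgen
from plastgwas.pipeline import scan_suite
from plastgwas.plasticity import env_means, plasticity_table

src_sim = outdir("01_simulate")
out = outdir("05_gwas")

panel = pio.read_vcf(src_sim / "panel.vcf")
qc_panel, _ = popgen.marker_qc(panel)
K = popgen.kinship(qc_panel)
phen = pio.read_phenotypes_tsv(src_sim / "phenotypes.tsv")
plast = plasticity_table(env_means(phen))

calls, results = scan_suite(
    qc_panel, plast, K, trait="GY", seed=SEED,
    n_permutations=100, n_estimators=100,
)
summary = []
for (method, est), res in results.items():
    res.table.to_csv(out / f"scan_{method}_GY_{est}.tsv", sep="\t", index=False)
    (out / f"scan_{method}_GY_{est}.meta.json").write_text(
        json.dumps(res.meta, default=str, indent=2))
    n_sig = len(res.significant_markers())
    summary.append({"method": method, "estimator": est, "n_significant": n_sig})
summary = pd.DataFrame(summary)
summary.to_csv(out / "scan_summary.tsv", sep="\t", index=False)
print(summary.pivot(index="method", columns="estimator", values="n_significant"))
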