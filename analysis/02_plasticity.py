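"""Compute the five plasticity estimators (WW, WL, Ratio, RDPI, Linear) plus
CV per genotype, confirm the WW/WL contrast with the Wilcoxon signed-rank
test, and run the estimator redundancy screen."""

import pandas as pd
from _common import outdir

from plastgwas import io as pio
from plastgwas import plasticity

src = outdir("01_simulate")
out = outdir("02_plasticity")

phen = pio.read_phenotypes_tsv(src / "phenotypes.tsv")
means = plasticity.env_means(phen)
table = plasticity.plasticity_table(means)
table.reset_index().to_csv(out / "plasticity.tsv", sep="\t", index=False)

rows = []
for trait in phen["trait"].unique():
    stat, p = plasticity.wilcoxon_env(means, trait)
    retained, corr = plasticity.estimator_screen(table.xs(trait, level="trait").dropna())
    corr.to_csv(out / f"estimator_corr_{trait}.tsv", sep="\t")
    rows.append({"trait": trait, "wilcoxon_stat": stat, "wilcoxon_p": p,
                 "retained_estimators": ",".join(retained)})
    print(f"{trait}: WW vs WL Wilcoxon p = {p:.3g}; "
          f"screen retains {retained} (dropped: "
          f"{sorted(set(plasticity.ESTIMATORS) - set(retained))})")
pd.DataFrame(rows).to_csv(out / "wilcoxon.tsv", sep="\t", index=False)
print(f"mean Finlay-Wilkinson slope: {table['Linear'].mean():.6f} (identity: 1)")
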