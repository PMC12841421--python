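"""Shared paths and study-design constants for the analysis drivers."""

from pathlib import Path

from plastgwas import simdata

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SEED = 1

#: Desk-scale study design used throughout the drivers: 4 families x 50
#: recombinant inbred lines, 140 SNPs on 7 chromosomes, 2 replicates per
#: environment, a 5-unit WW->WL shift on the grain-yield scale.
CONFIG = simdata.SimConfig(
    n_families=4,
    lines_per_family=50,
    markers_per_chromosome=20,
    missing_rate=0.02,
    n_replicates=2,
    env_effect=5.0,
    sigma2_poly=1.0,
    sigma2_resid=1.0,
    seed=SEED,
)

#: Planted truth: main (10%), WW-specific plastic (20%), antagonistic (15%).
QTL_SPECS = [
    simdata.QTLSpec(kind="main", trait="GY", var_frac=0.10),
    simdata.QTLSpec(kind="plastic", trait="GY", var_frac=0.20, env="WW"),
    simdata.QTLSpec(kind="antagonistic", trait="GY", var_frac=0.15),
]


def outdir(name: str) -> Path:
    path = RESULTS / name
    path.mkdir(parents=True, exist_ok=True)
    return path
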