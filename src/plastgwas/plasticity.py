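"""Per-genotype plasticity estimators for a two-environment contrast.

Five estimators structure the downstream association scans: the absolute
environment means (WW, WL), their Ratio (WW/WL), the relative distance
plasticity index RDPI = |WW - WL| / (WW + WL), and the Finlay–Wilkinson
"Linear" slope b_i from regressing each genotype's values on the centered
environmental index.  A sixth candidate, the between-environment coefficient
of variation (CV), is computed as well and typically removed by the
redundancy screen.  With exactly two environments the Finlay–Wilkinson slope
reduces to b_i = (y_iWW - y_iWL) / (E_WW - E_WL), and the average slope over
genotypes with complete data is identically 1.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ESTIMATORS",
    "env_means",
    "rdpi",
    "ratio_cv",
    "fw_slopes",
    "wilcoxon_env",
    "plasticity_table",
    "estimator_screen",
]

#: Column order of the full estimator battery; the screen's priority order.
ESTIMATORS = ["WW", "WL", "Linear", "RDPI", "Ratio", "CV"]

#: The five estimators the association scans use once CV is screened out.
SCAN_ESTIMATORS = ["WW", "WL", "Ratio", "RDPI", "Linear"]


def env_means(phenotypes: pd.DataFrame) -> pd.DataFrame:
    """Replicate means per (genotype, trait, environment), wide over env.

    Returns columns WW, WL, n_WW, n_WL indexed by (genotype, trait).  A
    missing (genotype, trait, env) cell is NaN with count 0 — flagged absent,
    never imputed to zero.
    """
    if phenotypes.empty:
        raise ValueError("phenotype table is empty")
    g = phenotypes.groupby(["genotype", "trait", "env"])["value"]
    means = g.mean().unstack("env")
    counts = g.size().unstack("env", fill_value=0)
    out = pd.DataFrame(index=means.index)
    for env in ("WW", "WL"):
        out[env] = means[env] if env in means else np.nan
        out[f"n_{env}"] = counts[env] if env in counts else 0
    return out


def rdpi(x_ww, x_wl):
    """Relative distance plasticity index |WW - WL| / (WW + WL).

    Vectorized; defined for nonnegative inputs not both zero, NaN otherwise.
    Symmetric and scale-invariant; 0 = no plasticity, 1 = maximal.
    """
    x_ww = np.asarray(x_ww, dtype=float)
    x_wl = np.asarray(x_wl, dtype=float)
    denom = x_ww + x_wl
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.abs(x_ww - x_wl) / denom
    out = np.where(denom == 0, np.nan, out)
    return out.item() if out.ndim == 0 else out


def ratio_cv(x_ww, x_wl):
    """(WW/WL ratio, between-environment CV) for one genotype.

    Ratio > 1 means reduction under water limitation.  CV is the sample
    (n-1 denominator) standard deviation of the two environment means over
    their mean.  Undefined cells (WL = 0 for the ratio, zero mean for the
    CV) are NaN.
    """
    x_ww = np.asarray(x_ww, dtype=float)
    x_wl = np.asarray(x_wl, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(x_wl == 0, np.nan, x_ww / x_wl)
        mean = (x_ww + x_wl) / 2.0
        sd = np.abs(x_ww - x_wl) / np.sqrt(2.0)  # sample sd of two points
        cv = np.where(mean == 0, np.nan, sd / mean)
    if ratio.ndim == 0:
        return ratio.item(), cv.item()
    return ratio, cv


def fw_slopes(means: pd.DataFrame, trait: str) -> tuple[pd.Series, dict[str, float]]:
    """Finlay–Wilkinson slopes b_i and the environmental index E_j.

    E_j is the across-genotype mean in environment j minus the grand mean,
    computed over genotypes with complete data so that mean(b_i) == 1
    exactly.  Raises if the two environments do not differ (degenerate
    index).
    """
    sub = means.xs(trait, level="trait")[["WW", "WL"]].dropna()
    if len(sub) < 1:
        raise ValueError(f"no genotype has complete data for trait {trait!r}")
    env_mean = sub.mean()
    grand = float(env_mean.mean())
    e = {env: float(env_mean[env] - grand) for env in ("WW", "WL")}
    contrast = e["WW"] - e["WL"]
    if contrast == 0:
        raise ValueError("degenerate environmental index: E_WW == E_WL")
    b = (sub["WW"] - sub["WL"]) / contrast
    b.name = "fw_slope"
    return b, e


def wilcoxon_env(means: pd.DataFrame, trait: str) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of paired WW vs WL genotype means.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 untied differences, the tie-corrected normal approximation
    otherwise.  Returns (statistic, p).
    """
    sub = means.xs(trait, level="trait")[["WW", "WL"]].dropna()
    d = (sub["WW"] - sub["WL"]).to_numpy()
    if len(d) < 5:
        raise ValueError("need >= 5 paired genotypes for the signed-rank test")
    nz = d[d != 0]
    if len(nz) == 0:
        warnings.warn("all paired differences are zero; no environmental contrast")
        return 0.0, 1.0
    has_ties = len(np.unique(np.abs(nz))) < len(nz)
    method = "exact" if (len(nz) <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(nz, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def plasticity_table(means: pd.DataFrame) -> pd.DataFrame:
    """Assemble the full estimator battery per (genotype, trait).

    Columns: WW, WL, Ratio, RDPI, CV, Linear.  Genotypes missing either
    environment get NaN in every derived column (excluded from paired
    metrics, present for the absolute ones).
    """
    out = means[["WW", "WL"]].copy()
    ratio, cv = ratio_cv(out["WW"].to_numpy(), out["WL"].to_numpy())
    out["Ratio"] = ratio
    out["RDPI"] = rdpi(out["WW"].to_numpy(), out["WL"].to_numpy())
    out["CV"] = cv
    lin = pd.Series(np.nan, index=out.index, name="Linear")
    for trait in out.index.get_level_values("trait").unique():
        b, _ = fw_slopes(means, trait)
        idx = pd.MultiIndex.from_arrays(
            [b.index, [trait] * len(b)], names=["genotype", "trait"]
        )
        lin.loc[idx] = b.to_numpy()
    out["Linear"] = lin
    return out


def estimator_screen(
    table: pd.DataFrame, threshold: float = 0.95
) -> tuple[list[str], pd.DataFrame]:
    """Redundancy screen over the estimator battery.

    Computes pairwise Spearman correlations on pairwise-complete genotypes
    and iteratively drops the lowest-priority member of any pair with
    |r| > threshold (priority WW > WL > Linear > RDPI > Ratio > CV).
    Returns (retained estimator names, correlation matrix).  The retained
    set is never empty.
    """
    cols = [c for c in ESTIMATORS if c in table.columns]
    if len(cols) < 2:
        return cols, pd.DataFrame()
    sub = table[cols]
    if sub.dropna().shape[0] < 3:
        raise ValueError("need >= 3 complete genotypes for the redundancy screen")
    corr = sub.corr(method="spearman")
    retained = list(cols)
    while True:
        worst = None
        for a, b in itertools.combinations(retained, 2):
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) > threshold:
                # b is lower priority than a by construction of ESTIMATORS order
                low = b if ESTIMATORS.index(b) > ESTIMATORS.index(a) else a
                if worst is None or ESTIMATORS.index(low) > ESTIMATORS.index(worst):
                    worst = low
        if worst is None:
            break
        retained.remove(worst)
    return retained, corr
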