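"""REML variance partitioning of replicate-level traits and trait retention.

The model is the two-way crossed random-effects decomposition

    y_ijk = mu + G_i + E_j + (GE)_ij + eps_ijk

with genotype, environment and (optionally) their interaction all random.
By default the interaction is pooled into the residual (the common situation
when a two-level environment factor leaves (GE) weakly identified); pass
``include_gxe=True`` to estimate it, which requires within-cell replication.

For balanced data the REML criterion is evaluated on the exact ANOVA strata
(the eigenspaces of the marginal covariance), so estimation is a tiny
bounded optimization over the stratum variances and coincides with the
closed-form method-of-moments estimators whenever those are nonnegative.
Unbalanced data fall back to a dense multivariate-normal REML.  Component
significance uses the restricted likelihood-ratio test with the boundary
chi-square mixture 0.5*(chi2_0 + chi2_1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "VarianceDecomposition",
    "RetentionRules",
    "fit_variance_components",
    "retention_filter",
]


@dataclass
class VarianceDecomposition:
    trait: str
    var_g: float
    var_env: float
    var_gxe: float  # NaN when pooled into residual
    var_resid: float
    prop_g: float
    prop_env: float
    prop_gxe: float
    prop_resid: float
    p_value_g: float
    p_value_env: float
    gxe_pooled: bool
    #: fixed-effect environment share of the total sum of squares — reported
    #: alongside because a 2-level random environment variance is unstable
    prop_env_fixed: float

    def as_row(self) -> dict:
        return {
            "trait": self.trait,
            "Var.G": self.var_g,
            "Prop.G": self.prop_g,
            "p-valueG": self.p_value_g,
            "Var.ENV": self.var_env,
            "Prop.ENV": self.prop_env,
            "p-valueENV": self.p_value_env,
            "Var.Residual": self.var_resid,
            "Prop.Residual": self.prop_resid,
        }


@dataclass
class RetentionRules:
    """Trait-retention thresholds.

    Traits whose genotypic component is not significant at ``alpha_g`` are
    dropped, as are traits with an environmental share below ``min_prop_env``
    percent; with ``drop_max_residual`` the single surviving trait with the
    largest residual share is removed as well.
    """

    alpha_g: float = 0.05
    min_prop_env: float = 5.0
    drop_max_residual: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha_g < 1.0:
            raise ValueError("alpha_g must be in (0, 1)")
        if not 0.0 <= self.min_prop_env < 100.0:
            raise ValueError("min_prop_env must be in [0, 100)")


def _balanced_layout(df: pd.DataFrame):
    """Return (a, b, r, cell table) if the (genotype, env) layout is balanced."""
    counts = df.groupby(["genotype", "env"])["value"].size().unstack("env")
    if counts.isna().any().any():
        return None
    vals = counts.to_numpy()
    if not (vals == vals[0, 0]).all():
        return None
    return len(counts.index), counts.shape[1], int(vals[0, 0])


def _strata(df: pd.DataFrame, a: int, b: int, r: int):
    """Balanced two-way ANOVA sums of squares and degrees of freedom."""
    y = df["value"].to_numpy()
    grand = y.mean()
    gm = df.groupby("genotype")["value"].mean().to_numpy()
    em = df.groupby("env")["value"].mean().to_numpy()
    cm = df.groupby(["genotype", "env"])["value"].mean().unstack("env")
    ss_g = b * r * np.sum((gm - grand) ** 2)
    ss_e = a * r * np.sum((em - grand) ** 2)
    resid_cell = cm.to_numpy() - gm[:, None] - em[None, :] + grand
    ss_ge = r * np.sum(resid_cell**2)
    cell_means = cm.stack().reindex(
        pd.MultiIndex.from_frame(df[["genotype", "env"]])
    ).to_numpy()
    ss_w = np.sum((y - cell_means) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    return {
        "G": (ss_g, a - 1),
        "E": (ss_e, b - 1),
        "GE": (ss_ge, (a - 1) * (b - 1)),
        "W": (ss_w, a * b * max(r - 1, 0)),
        "total": ss_tot,
    }


def _reml_balanced(strata, a, b, r, include_gxe, fix_zero=()):
    """Minimize the balanced stratum REML criterion.

    Parameters are (sg2, se2, sge2, sr2); names in ``fix_zero`` are pinned
    at 0 (for the nested LRT models).  Returns (estimates dict, -2*restricted
    log-likelihood up to an additive constant).
    """
    names = ["g", "e"] + (["ge"] if include_gxe else []) + ["resid"]
    free = [n for n in names if n not in fix_zero]

    def lambdas(theta):
        v = dict.fromkeys(["g", "e", "ge", "resid"], 0.0)
        v.update(dict(zip(free, theta)))
        lam_ge = v["resid"] + (r * v["ge"] if include_gxe else 0.0)
        return {
            "G": lam_ge + b * r * v["g"],
            "E": lam_ge + a * r * v["e"],
            "GE": lam_ge,
            "W": v["resid"],
        }, v

    if include_gxe:
        use = ["G", "E", "GE", "W"]
    else:
        # GE pooled: its stratum shares the residual eigenvalue
        use = ["G", "E", "GEW"]

    def neg2ll(theta):
        lam, _ = lambdas(theta)
        total = 0.0
        for s in use:
            if s == "GEW":
                ss = strata["GE"][0] + strata["W"][0]
                df_s = strata["GE"][1] + strata["W"][1]
                lam_s = lam["W"]
            else:
                ss, df_s = strata[s]
                lam_s = lam[s]
            if df_s == 0:
                continue
            if lam_s <= 0:
                return np.inf
            total += df_s * np.log(lam_s) + ss / lam_s
        return total

    # method-of-moments start, truncated at a small positive floor
    ms = {
        s: (strata[s][0] / strata[s][1] if strata[s][1] else 0.0)
        for s in ("G", "E", "GE", "W")
    }
    if include_gxe:
        ms_err, ms_ge = ms["W"], ms["GE"]
    else:
        df_pool = strata["GE"][1] + strata["W"][1]
        ms_err = (strata["GE"][0] + strata["W"][0]) / df_pool if df_pool else 0.0
        ms_ge = ms_err
    start_all = {
        "g": max((ms["G"] - ms_ge) / (b * r), 1e-8),
        "e": max((ms["E"] - ms_ge) / (a * r), 1e-8),
        "ge": max((ms_ge - ms_err) / r, 1e-8),
        "resid": max(ms_err, 1e-8),
    }
    x0 = np.array([start_all[n] for n in free])
    res = optimize.minimize(
        neg2ll, x0, method="L-BFGS-B", bounds=[(0.0, None)] * len(free)
    )
    _, est = lambdas(res.x)
    return est, float(res.fun)


def _reml_dense(df, include_gxe, fix_zero=()):
    """Generic REML by direct evaluation of the restricted likelihood."""
    y = df["value"].to_numpy()
    n = len(y)
    if n > 4000:
        raise ValueError("unbalanced REML limited to 4000 observations")
    g_codes, _ = pd.factorize(df["genotype"])
    e_codes, _ = pd.factorize(df["env"])
    zg = np.eye(g_codes.max() + 1)[g_codes]
    ze = np.eye(e_codes.max() + 1)[e_codes]
    designs = {"g": zg @ zg.T, "e": ze @ ze.T}
    if include_gxe:
        ge_codes, _ = pd.factorize(df["genotype"].astype(str) + "|" + df["env"].astype(str))
        zge = np.eye(ge_codes.max() + 1)[ge_codes]
        designs["ge"] = zge @ zge.T
    names = list(designs) + ["resid"]
    free = [m for m in names if m not in fix_zero]
    x = np.ones((n, 1))

    def neg2ll(theta):
        v = dict.fromkeys(names, 0.0)
        v.update(dict(zip(free, theta)))
        V = v["resid"] * np.eye(n)
        for m, zz in designs.items():
            V += v[m] * zz
        try:
            c = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return np.inf
        logdet_v = 2 * np.sum(np.log(np.diag(c)))
        vi_y = np.linalg.solve(V, y)
        vi_x = np.linalg.solve(V, x)
        xtvix = x.T @ vi_x
        beta = np.linalg.solve(xtvix, x.T @ vi_y)
        resid = y - (x @ beta).ravel()
        quad = resid @ np.linalg.solve(V, resid)
        return float(logdet_v + np.log(np.linalg.det(xtvix)) + quad)

    var0 = np.var(y, ddof=1)
    x0 = np.full(len(free), max(var0 / len(names), 1e-8))
    res = optimize.minimize(
        neg2ll, x0, method="L-BFGS-B", bounds=[(0.0, None)] * len(free)
    )
    est = dict.fromkeys(names, 0.0)
    est.update(dict(zip(free, res.x)))
    est.setdefault("ge", 0.0)
    return est, float(res.fun)


def _boundary_lrt_p(neg2ll_null: float, neg2ll_full: float) -> float:
    lrt = neg2ll_null - neg2ll_full
    if lrt <= 0:
        return 1.0
    return 0.5 * float(stats.chi2.sf(lrt, df=1))


def fit_variance_components(
    phenotypes: pd.DataFrame, trait: str, include_gxe: bool = False
) -> VarianceDecomposition:
    """REML decomposition of one trait into G, ENV (optionally GxE) and residual.

    Negative component estimates are impossible by construction (bounded
    optimization); boundary estimates of exactly 0 play that role.
    """
    df = phenotypes[phenotypes["trait"] == trait]
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}")
    if df["genotype"].nunique() < 2 or df["env"].nunique() < 2:
        raise ValueError("need >= 2 genotypes and 2 environments")
    if np.var(df["value"].to_numpy()) == 0:
        raise ValueError(f"zero total variance for trait {trait!r}")

    layout = _balanced_layout(df)
    gxe_requested = include_gxe
    pooled = not include_gxe
    if include_gxe:
        reps = df.groupby(["genotype", "env"])["value"].size()
        if (reps <= 1).all():
            warnings.warn(
                "no within-cell replication: (GE) is confounded with the "
                "residual and has been pooled"
            )
            include_gxe = False
            pooled = True

    if layout is not None:
        a, b, r = layout
        strata = _strata(df, a, b, r)
        fit = lambda fz: _reml_balanced(strata, a, b, r, include_gxe, fix_zero=fz)
        ss_e, ss_tot = strata["E"][0], strata["total"]
    else:
        fit = lambda fz: _reml_dense(df, include_gxe, fix_zero=fz)
        grand = df["value"].mean()
        em = df.groupby("env")["value"].agg(["mean", "size"])
        ss_e = float((em["size"] * (em["mean"] - grand) ** 2).sum())
        ss_tot = float(((df["value"] - grand) ** 2).sum())

    est, n2ll = fit(())
    _, n2ll_no_g = fit(("g",))
    _, n2ll_no_e = fit(("e",))
    p_g = _boundary_lrt_p(n2ll_no_g, n2ll)
    p_e = _boundary_lrt_p(n2ll_no_e, n2ll)

    var_gxe = est.get("ge", 0.0) if include_gxe else np.nan
    comps = [est["g"], est["e"], (var_gxe if include_gxe else 0.0), est["resid"]]
    total = float(np.sum(comps))
    props = [100.0 * c / total for c in comps]
    return VarianceDecomposition(
        trait=trait,
        var_g=est["g"],
        var_env=est["e"],
        var_gxe=var_gxe,
        var_resid=est["resid"],
        prop_g=props[0],
        prop_env=props[1],
        prop_gxe=props[2] if include_gxe else np.nan,
        prop_resid=props[3] + (0.0 if include_gxe else 0.0),
        p_value_g=p_g,
        p_value_env=p_e,
        gxe_pooled=pooled or not gxe_requested,
        prop_env_fixed=100.0 * ss_e / ss_tot,
    )


def retention_filter(
    decompositions: pd.DataFrame, rules: RetentionRules | None = None
) -> tuple[list[str], dict[str, str]]:
    """Apply the trait-retention rules to a decomposition table.

    ``decompositions`` needs columns trait, prop_g, p_value_g, prop_env,
    prop_resid (``VarianceDecomposition`` rows or a published-style table).
    Returns (retained trait list in input order, {trait: drop reason}).
    """
    rules = rules or RetentionRules()
    if decompositions.empty:
        return [], {}
    reasons: dict[str, str] = {}
    surviving = []
    for row in decompositions.itertuples(index=False):
        if row.p_value_g > rules.alpha_g:
            reasons[row.trait] = (
                f"genotypic variance not significant (p={row.p_value_g:.3g} > "
                f"{rules.alpha_g})"
            )
        elif row.prop_env < rules.min_prop_env:
            reasons[row.trait] = (
                f"environmental share {row.prop_env:.2f}% below "
                f"{rules.min_prop_env}% floor"
            )
        else:
            surviving.append(row)
    if rules.drop_max_residual and surviving:
        worst = max(surviving, key=lambda r: r.prop_resid)
        reasons[worst.trait] = (
            f"largest residual share among survivors ({worst.prop_resid:.2f}%)"
        )
        surviving = [r for r in surviving if r.trait != worst.trait]
    return [r.trait for r in surviving], reasons
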