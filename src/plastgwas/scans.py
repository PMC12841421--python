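"""Genome-wide association scans over trait x plasticity-estimator responses.

Four method families, two paradigms:

* ``mlm_scan`` — per-marker mixed linear model y = mu + x b + g + e with a
  polygenic term g ~ N(0, sg^2 K).  The variance ratio is estimated once on
  the null model via the eigendecomposition of K (the "population parameters
  previously determined" shortcut), after which every marker is a weighted
  least-squares Wald test in the rotated basis.
* ``multilocus_scan`` — iterative multi-locus procedure in the FarmCPU/BLINK
  family: single-marker fixed-effect tests, pseudo-QTN candidate selection
  by ascending p with an LD-exclusion rule, model-size choice by BIC, and
  re-testing of every marker with the selected pseudo-QTNs as covariates,
  iterated to convergence of the selected set.
* ``ml_importance_scan`` — Random-Forest or gradient-boosting importance
  with a max-statistic permutation null giving family-wise-valid empirical
  p-values.

``call_significant`` turns p-values into calls by Bonferroni, BH FDR, or a
direct threshold on empirical permutation p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .simdata import GenotypePanel

__all__ = ["ScanResult", "mlm_scan", "multilocus_scan", "ml_importance_scan", "call_significant"]

METHODS = ("MLM", "MULTILOCUS", "RF", "GB")


@dataclass
class ScanResult:
    method: str
    trait: str
    estimator: str
    table: pd.DataFrame  # marker_id, chrom, pos, score, se, p_value, significant
    meta: dict = field(default_factory=dict)

    def significant_markers(self) -> set[str]:
        t = self.table
        return set(t.loc[t["significant"].fillna(False).astype(bool), "marker_id"])


def _align_response(panel: GenotypePanel, response) -> tuple[np.ndarray, np.ndarray]:
    """Return (line mask, response vector) aligned to panel lines, NaN dropped."""
    if isinstance(response, pd.Series):
        y = response.reindex(panel.line_ids).to_numpy(dtype=float)
    else:
        y = np.asarray(response, dtype=float)
        if len(y) != panel.n_lines:
            raise ValueError(
                f"response length {len(y)} does not match {panel.n_lines} lines"
            )
    keep = np.isfinite(y)
    if keep.sum() < 10:
        raise ValueError("fewer than 10 lines with a finite response")
    return keep, y[keep]


def _result(panel, method, trait, estimator, score, se, p, meta) -> ScanResult:
    table = panel.markers[["marker_id", "chrom", "pos"]].copy()
    table["score"] = score
    table["se"] = se
    table["p_value"] = p
    table["significant"] = False
    return ScanResult(method=method, trait=trait, estimator=estimator, table=table, meta=meta)


def mlm_scan(
    panel: GenotypePanel,
    response,
    K: pd.DataFrame | np.ndarray,
    trait: str = "",
    estimator: str = "",
) -> ScanResult:
    """Kinship mixed-model scan with a single null-model variance-ratio fit.

    Rotates into the eigenbasis of K, profiles the REML criterion over the
    ratio delta = sg^2/se^2 on the intercept-only model, then Wald-tests each
    marker by weighted least squares.  Monomorphic markers get NaN p-values.
    """
    keep, y = _align_response(panel, response)
    k = K.to_numpy() if isinstance(K, pd.DataFrame) else np.asarray(K, dtype=float)
    k = k[np.ix_(keep, keep)]
    geno = panel.imputed()[keep]
    n = len(y)

    s, u = np.linalg.eigh(k)
    s = np.clip(s, 0.0, None)
    ys = u.T @ y
    ones = u.T @ np.ones(n)

    def neg_reml(log_delta: float) -> float:
        w = np.exp(log_delta) * s + 1.0
        wi = 1.0 / w
        a = np.sum(wi * ones**2)
        b = np.sum(wi * ones * ys)
        rss = np.sum(wi * ys**2) - b**2 / a
        return (n - 1) * np.log(rss / (n - 1)) + np.sum(np.log(w)) + np.log(a)

    opt = optimize.minimize_scalar(neg_reml, bounds=(-10.0, 10.0), method="bounded")
    delta = float(np.exp(opt.x))
    w = delta * s + 1.0
    wi = 1.0 / w

    xr = u.T @ geno  # rotated marker matrix
    a11 = np.sum(wi * ones**2)
    a12 = xr.T @ (wi * ones)
    a22 = np.einsum("ij,ij->j", xr, wi[:, None] * xr)
    b1 = np.sum(wi * ones * ys)
    b2 = xr.T @ (wi * ys)
    det = a11 * a22 - a12**2
    yy = np.sum(wi * ys**2)

    with np.errstate(divide="ignore", invalid="ignore"):
        beta0 = (a22 * b1 - a12 * b2) / det
        beta1 = (a11 * b2 - a12 * b1) / det
        rss = yy - beta0 * b1 - beta1 * b2
        sigma2 = rss / (n - 2)
        var_b1 = sigma2 * a11 / det
        se_b1 = np.sqrt(var_b1)
        tstat = beta1 / se_b1
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    degenerate = ~np.isfinite(det) | (det <= 1e-10 * np.maximum(a11 * a22, 1e-300))
    mono = np.nanvar(geno, axis=0) == 0
    bad = degenerate | mono
    beta1[bad] = np.nan
    se_b1[bad] = np.nan
    p[bad] = np.nan
    meta = {"method": "MLM", "delta": delta, "n_lines": n}
    return _result(panel, "MLM", trait, estimator, beta1, se_b1, p, meta)


def _ols_marker_tests(
    y: np.ndarray, geno: np.ndarray, cov_idx: list[int], r2_to_cov: np.ndarray | None
, r2_max: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-marker OLS t-tests of y on [1, covariates, x_m].

    Covariates equal to, or in LD (r^2 > r2_max) with, the tested marker are
    dropped for that marker's test.  Returns (beta, se, p) arrays.
    """
    n, m = geno.shape
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    p = np.full(m, np.nan)
    ones = np.ones((n, 1))
    for j in range(m):
        x = geno[:, j]
        if np.var(x) == 0:
            continue
        use_cov = [
            c
            for ci, c in enumerate(cov_idx)
            if c != j and (r2_to_cov is None or r2_to_cov[ci, j] <= r2_max)
        ]
        design = np.column_stack([ones, geno[:, use_cov], x]) if use_cov else np.column_stack([ones, x])
        coef, res, rank, _ = np.linalg.lstsq(design, y, rcond=None)
        dof = n - design.shape[1]
        if dof <= 0 or rank < design.shape[1]:
            continue
        resid = y - design @ coef
        sigma2 = resid @ resid / dof
        xtx_inv = np.linalg.pinv(design.T @ design)
        se_j = float(np.sqrt(sigma2 * xtx_inv[-1, -1]))
        if se_j == 0:
            continue
        beta[j] = coef[-1]
        se[j] = se_j
        p[j] = 2.0 * stats.t.sf(abs(coef[-1] / se_j), df=dof)
    return beta, se, p


def multilocus_scan(
    panel: GenotypePanel,
    response,
    K=None,
    trait: str = "",
    estimator: str = "",
    entry_p: float = 0.01,
    r2_max: float = 0.7,
    max_iter: int = 10,
    max_candidates: int = 20,
) -> ScanResult:
    """Iterative pseudo-QTN multi-locus scan (FarmCPU/BLINK family).

    ``K`` is accepted for interface symmetry but unused: confounding is
    absorbed by the selected pseudo-QTN covariates instead of a polygenic
    term.  With no marker below ``entry_p`` the output is the plain
    single-marker scan.
    """
    keep, y = _align_response(panel, response)
    geno = panel.imputed()[keep]
    n, m = geno.shape

    corr = np.corrcoef(geno, rowvar=False)
    r2_all = np.nan_to_num(corr**2, nan=1.0)

    selected: list[int] = []
    history = [tuple(selected)]
    beta, se, p = _ols_marker_tests(y, geno, [], None, r2_max)
    for _ in range(max_iter):
        order = np.argsort(p)
        cands: list[int] = []
        for j in order:
            if not np.isfinite(p[j]) or p[j] >= entry_p:
                break
            if all(r2_all[j, c] <= r2_max for c in cands):
                cands.append(int(j))
            if len(cands) >= max_candidates:
                break
        # BIC over nested pseudo-QTN model sizes
        best_k, best_bic = 0, np.inf
        ones = np.ones((n, 1))
        for kk in range(len(cands) + 1):
            design = np.column_stack([ones, geno[:, cands[:kk]]]) if kk else ones
            coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
            rss = float(np.sum((y - design @ coef) ** 2))
            if rss <= 0:
                break
            bic = n * np.log(rss / n) + (kk + 1) * np.log(n)
            if bic < best_bic:
                best_bic, best_k = bic, kk
        new_selected = cands[:best_k]
        r2_to_cov = r2_all[new_selected, :] if new_selected else None
        beta, se, p = _ols_marker_tests(y, geno, new_selected, r2_to_cov, r2_max)
        if tuple(new_selected) in history:
            selected = new_selected
            break
        history.append(tuple(new_selected))
        selected = new_selected

    meta = {
        "method": "MULTILOCUS",
        "pseudo_qtns": [panel.markers["marker_id"].iloc[j] for j in selected],
        "entry_p": entry_p,
        "r2_max": r2_max,
        "n_lines": n,
    }
    return _result(panel, "MULTILOCUS", trait, estimator, beta, se, p, meta)


def ml_importance_scan(
    panel: GenotypePanel,
    response,
    learner: str,
    n_permutations: int = 100,
    seed: int = 0,
    trait: str = "",
    estimator: str = "",
    n_estimators: int | None = None,
) -> ScanResult:
    """Tree-ensemble importance scan with a max-statistic permutation null.

    Fits the ensemble on markers -> response, then refits on
    ``n_permutations`` response-permuted copies; the empirical p-value of a
    marker is (1 + #{permutation maxima >= its importance}) /
    (n_permutations + 1), which is family-wise valid and conservative.
    Deterministic given ``seed``.  Default hyperparameters: 500 trees for
    RF; 500 rounds, learning rate 0.05, depth 4 for boosting.
    """
    if learner not in {"RF", "GB"}:
        raise ValueError(f"learner must be RF or GB, got {learner!r}")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100 for stable empirical p-values")
    keep, y = _align_response(panel, response)
    if np.var(y) == 0:
        raise ValueError("constant response: importance scan undefined")
    geno = panel.imputed()[keep]
    rng = np.random.default_rng(seed)

    def make_model(state: int):
        if learner == "RF":
            from sklearn.ensemble import RandomForestRegressor

            return RandomForestRegressor(
                n_estimators=n_estimators or 500,
                random_state=state,
                n_jobs=1,
                min_samples_leaf=2,
            )
        from xgboost import XGBRegressor

        return XGBRegressor(
            n_estimators=n_estimators or 500,
            learning_rate=0.05,
            max_depth=4,
            random_state=state,
            n_jobs=1,
            tree_method="hist",
            verbosity=0,
        )

    model = make_model(int(rng.integers(2**31 - 1)))
    model.fit(geno, y)
    imp = np.asarray(model.feature_importances_, dtype=float)

    null_max = np.empty(n_permutations)
    for b in range(n_permutations):
        yp = rng.permutation(y)
        mb = make_model(int(rng.integers(2**31 - 1)))
        mb.fit(geno, yp)
        null_max[b] = float(np.max(mb.feature_importances_))
    p = (1.0 + np.sum(null_max[None, :] >= imp[:, None], axis=1)) / (n_permutations + 1.0)

    meta = {
        "method": learner,
        "n_permutations": n_permutations,
        "seed": seed,
        "n_estimators": n_estimators or 500,
        "n_lines": len(y),
    }
    return _result(panel, learner, trait, estimator, imp, np.full(len(imp), np.nan), p, meta)


def call_significant(result: ScanResult, procedure: str, alpha: float = 0.05) -> ScanResult:
    """Attach significance calls under the named procedure.

    ``bonferroni``: p <= alpha/m over the m testable markers; ``bh_fdr``:
    Benjamini–Hochberg step-up at level alpha; ``empirical``: p <= alpha on
    permutation p-values directly.
    """
    if procedure not in {"bonferroni", "bh_fdr", "empirical"}:
        raise ValueError(f"unknown procedure {procedure!r}")
    table = result.table.copy()
    p = table["p_value"].to_numpy(dtype=float)
    ok = np.isfinite(p)
    calls = np.zeros(len(p), dtype=bool)
    if ok.any():
        if procedure == "bonferroni":
            calls[ok] = p[ok] <= alpha / ok.sum()
        elif procedure == "bh_fdr":
            calls[ok] = multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]
        else:
            calls[ok] = p[ok] <= alpha
    table["significant"] = calls
    meta = dict(result.meta)
    meta.update({"procedure": procedure, "alpha": alpha, "m": int(ok.sum())})
    return ScanResult(
        method=result.method,
        trait=result.trait,
        estimator=result.estimator,
        table=table,
        meta=meta,
    )
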