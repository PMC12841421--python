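"""Two-stage consensus retention of associated markers and QTL variance.

Stage one keeps, within each GWAS method and trait, only markers significant
for at least two of the five response estimators (the absolute WW and WL
values count toward the tally).  Stage two unions the per-method survivors
and flags markers supported by two or more methods as high-confidence.
``intersection_counts`` produces the exact-subset (disjoint) combination
counts used for upset-style summaries, and ``qtl_variance_explained``
quantifies the variance a retained marker set captures in a response.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .simdata import GenotypePanel

__all__ = [
    "estimator_intersection",
    "method_prioritization",
    "consensus_pipeline",
    "intersection_counts",
    "qtl_variance_explained",
]

CallSet = dict  # (method, trait, estimator) -> set of marker_ids


def estimator_intersection(calls: CallSet, trait: str, method: str) -> dict[str, set[str]]:
    """Markers significant for >= 2 estimators within one method and trait.

    Returns {marker_id: set of supporting estimators}.
    """
    support: dict[str, set[str]] = {}
    seen_estimators = 0
    for (m, t, est), markers in calls.items():
        if m == method and t == trait:
            seen_estimators += 1
            for mk in markers:
                support.setdefault(mk, set()).add(est)
    if seen_estimators < 2:
        raise ValueError(f"need calls for >= 2 estimators ({method}, {trait})")
    return {mk: ests for mk, ests in support.items() if len(ests) >= 2}


def method_prioritization(
    per_method: dict[str, dict[str, set[str]]], trait: str
) -> pd.DataFrame:
    """Union per-method retained sets; >= 2 supporting methods = high confidence.

    ``per_method`` maps method -> {marker: estimator support} (the output of
    ``estimator_intersection``).  Returns a DataFrame with columns trait,
    marker_id, estimator_support, method_support, high_confidence.
    """
    if len(per_method) < 2:
        raise ValueError("need retained sets from >= 2 methods")
    rows: dict[str, dict] = {}
    for method, retained in per_method.items():
        for mk, ests in retained.items():
            rec = rows.setdefault(
                mk, {"trait": trait, "marker_id": mk, "estimators": set(), "methods": set()}
            )
            rec["estimators"] |= ests
            rec["methods"].add(method)
    out = pd.DataFrame(
        [
            {
                "trait": r["trait"],
                "marker_id": r["marker_id"],
                "estimator_support": ",".join(sorted(r["estimators"])),
                "method_support": ",".join(sorted(r["methods"])),
                "n_methods": len(r["methods"]),
                "high_confidence": len(r["methods"]) >= 2,
            }
            for r in rows.values()
        ],
        columns=[
            "trait",
            "marker_id",
            "estimator_support",
            "method_support",
            "n_methods",
            "high_confidence",
        ],
    )
    return out.sort_values("marker_id").reset_index(drop=True)


def consensus_pipeline(calls: CallSet, trait: str) -> pd.DataFrame:
    """Full two-stage rule for one trait: within-method >= 2 estimators,
    then cross-method union with the high-confidence flag."""
    methods = sorted({m for (m, t, _) in calls if t == trait})
    per_method = {m: estimator_intersection(calls, trait, m) for m in methods}
    return method_prioritization(per_method, trait)


def _exact_subset_counts(membership: dict[str, set[str]]) -> pd.DataFrame:
    """Count markers whose supporting set is exactly each non-empty subset."""
    groups = sorted(membership)
    marker_support: dict[str, frozenset] = {}
    for g in groups:
        for mk in membership[g]:
            marker_support[mk] = frozenset(
                marker_support.get(mk, frozenset()) | {g}
            )
    rows = []
    for r in range(1, len(groups) + 1):
        for combo in itertools.combinations(groups, r):
            key = frozenset(combo)
            count = sum(1 for s in marker_support.values() if s == key)
            rows.append({"subset": ",".join(combo), "degree": r, "count": count})
    return pd.DataFrame(rows, columns=["subset", "degree", "count"])


def intersection_counts(calls: CallSet, trait: str) -> dict[str, pd.DataFrame]:
    """Upset-style exact-subset counts by method and by estimator.

    A marker belongs to a method if it is significant under that method for
    any estimator (and symmetrically for estimators).  Counts over all
    subsets sum to the size of the union.
    """
    by_method: dict[str, set[str]] = {}
    by_estimator: dict[str, set[str]] = {}
    for (m, t, est), markers in calls.items():
        if t != trait:
            continue
        by_method.setdefault(m, set()).update(markers)
        by_estimator.setdefault(est, set()).update(markers)
    return {
        "methods": _exact_subset_counts(by_method),
        "estimators": _exact_subset_counts(by_estimator),
    }


def qtl_variance_explained(
    panel: GenotypePanel,
    response,
    markers: list[str],
    env: pd.Series | np.ndarray | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> dict[str, float]:
    """Variance proportions captured by a retained marker set, in percent.

    Fits the response on the marker genotypes by ordinary least squares
    (plus an environment term when ``env`` is given, attributed first) and
    partitions the total sum of squares into marker (G), environment (E) and
    residual shares.  In-sample proportions over-fit at small n, so an
    adjusted-R^2 analogue and a cross-validated R^2 are reported alongside.
    """
    if isinstance(response, pd.Series):
        y_full = response.reindex(panel.line_ids).to_numpy(dtype=float) if env is None else response.to_numpy(dtype=float)
    else:
        y_full = np.asarray(response, dtype=float)
    keep = np.isfinite(y_full)
    y = y_full[keep]
    n = len(y)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("constant response")

    if not markers:
        warnings.warn("empty marker set: QTL variance proportion is zero")
        return {
            "prop_g": 0.0,
            "prop_e": 0.0,
            "prop_resid": 100.0,
            "prop_g_adj": 0.0,
            "r2_cv": 0.0,
            "n": n,
        }

    idx = panel.marker_index(markers)
    geno = panel.imputed()[:, idx]
    if env is not None:
        env = np.asarray(env)
        if len(env) != len(y_full):
            raise ValueError("env vector must align with response")
        # response rows are (line, env) pairs; map genotypes by line order
        if len(y_full) % panel.n_lines == 0:
            reps = len(y_full) // panel.n_lines
            geno = np.tile(geno, (reps, 1))
        else:
            raise ValueError("response length is not a multiple of panel lines")
        env_dummy = (env == env[np.argsort(env)[0]]).astype(float)[:, None]
    geno = geno[keep]

    ones = np.ones((n, 1))
    if env is not None:
        x_e = np.column_stack([ones, env_dummy[keep]])
        coef_e, _, _, _ = np.linalg.lstsq(x_e, y, rcond=None)
        ss_resid_e = float(np.sum((y - x_e @ coef_e) ** 2))
        prop_e = 100.0 * (ss_tot - ss_resid_e) / ss_tot
        base = x_e
        ss_base = ss_resid_e
    else:
        prop_e = 0.0
        base = ones
        ss_base = ss_tot

    x_full = np.column_stack([base, geno])
    coef, _, rank, _ = np.linalg.lstsq(x_full, y, rcond=None)
    ss_resid = float(np.sum((y - x_full @ coef) ** 2))
    prop_g = 100.0 * (ss_base - ss_resid) / ss_tot
    prop_resid = 100.0 * ss_resid / ss_tot

    k = x_full.shape[1] - 1
    r2 = 1.0 - ss_resid / ss_tot
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - k - 1, 1)
    prop_g_adj = max(100.0 * r2_adj - prop_e, 0.0)

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, n_folds)
    press = 0.0
    for f in folds:
        train = np.setdiff1d(order, f)
        cf, _, _, _ = np.linalg.lstsq(x_full[train], y[train], rcond=None)
        press += float(np.sum((y[f] - x_full[f] @ cf) ** 2))
    r2_cv = 1.0 - press / ss_tot

    return {
        "prop_g": prop_g,
        "prop_e": prop_e,
        "prop_resid": prop_resid,
        "prop_g_adj": prop_g_adj,
        "r2_cv": r2_cv,
        "n": n,
    }
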