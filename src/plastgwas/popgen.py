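"""Marker QC, kinship, PCA structure summary, and LD decay.

QC applies the panel inclusion rules: fewer than 10% missing calls, not
monomorphic, and no complete linkage disequilibrium (r^2 = 1 on complete
cases) with an earlier marker in map order.  Kinship is the VanRaden genomic
relationship matrix; LD decay is the mean pairwise r^2 per physical-distance
bin within chromosomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import GenotypePanel

__all__ = ["QCReport", "marker_qc", "kinship", "pca", "ld_decay"]


@dataclass
class QCReport:
    n_input_markers: int
    n_removed_missing: int
    n_removed_monomorphic: int
    n_removed_duplicate_ld: int
    n_retained: int

    def __post_init__(self) -> None:
        removed = (
            self.n_removed_missing + self.n_removed_monomorphic + self.n_removed_duplicate_ld
        )
        if self.n_input_markers != self.n_retained + removed:
            raise ValueError("QC counts do not balance")


def _pairwise_r2(geno: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between marker columns on pairwise
    complete cases (missing as NaN)."""
    mask = np.isfinite(geno).astype(float)
    x = np.nan_to_num(geno, nan=0.0)
    n = mask.T @ mask  # complete-case counts per pair
    sx = x.T @ mask
    sy = mask.T @ x
    sxy = x.T @ x
    sxx = (x**2).T @ mask
    syy = mask.T @ (x**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx**2 / n
        vy = syy - sy**2 / n
        r2 = cov**2 / (vx * vy)
    r2[~np.isfinite(r2)] = np.nan
    r2[n < 2] = np.nan
    return r2


def marker_qc(
    panel: GenotypePanel, max_missing: float = 0.10
) -> tuple[GenotypePanel, QCReport]:
    """Filter markers by missingness, monomorphism and complete LD.

    Markers with missing fraction >= ``max_missing`` go first, then
    monomorphic markers, then for every pair in complete LD (r^2 == 1) only
    the first in map order is kept.  Idempotent.  Original missing values are
    preserved in the returned panel.
    """
    g = panel.genotypes
    n_input = g.shape[1]
    miss_frac = np.mean(np.isnan(g), axis=0)
    keep_missing = miss_frac < max_missing
    n_rm_missing = int((~keep_missing).sum())

    poly = panel.polymorphic_mask()
    keep_poly = keep_missing & poly
    n_rm_mono = int((keep_missing & ~poly).sum())

    idx = np.flatnonzero(keep_poly)
    n_rm_dup = 0
    if len(idx) > 1:
        r2 = _pairwise_r2(g[:, idx])
        keep_dup = np.ones(len(idx), dtype=bool)
        # keep the first (lowest map position within the marker table) member
        for j in range(1, len(idx)):
            earlier = np.flatnonzero(keep_dup[:j])
            if len(earlier) and np.any(r2[earlier, j] >= 1.0 - 1e-12):
                keep_dup[j] = False
        n_rm_dup = int((~keep_dup).sum())
        idx = idx[keep_dup]

    if len(idx) == 0:
        raise ValueError("all markers removed by QC")
    report = QCReport(
        n_input_markers=n_input,
        n_removed_missing=n_rm_missing,
        n_removed_monomorphic=n_rm_mono,
        n_removed_duplicate_ld=n_rm_dup,
        n_retained=len(idx),
    )
    return panel.subset_markers(idx), report


def kinship(panel: GenotypePanel) -> pd.DataFrame:
    """VanRaden genomic relationship matrix.

    K = W W' / (2 * sum p(1-p)) with W the mean-imputed allele-count matrix
    centered by twice the allele frequency.  Symmetric and PSD up to
    numerical tolerance.
    """
    geno = panel.imputed()
    p = geno.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("kinship undefined: panel has no polymorphic markers")
    w = geno - 2.0 * p
    k = (w @ w.T) / denom
    return pd.DataFrame(k, index=panel.line_ids, columns=panel.line_ids)


def pca(panel: GenotypePanel, n_components: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the centered, mean-imputed genotype matrix.

    Returns (scores DataFrame with PC1.. columns, percent variance per
    component).  Requests beyond the matrix rank are truncated with a
    warning.
    """
    geno = panel.imputed()
    x = geno - geno.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = max(x.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    rank = int(np.sum(s > tol))
    if n_components > rank:
        warnings.warn(f"n_components={n_components} exceeds rank {rank}; truncated")
        n_components = max(rank, 1)
    total_var = float(np.sum(s**2))
    scores = u[:, :n_components] * s[:n_components]
    pct = (
        100.0 * s[:n_components] ** 2 / total_var
        if total_var > 0
        else np.zeros(n_components)
    )
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return pd.DataFrame(scores, index=panel.line_ids, columns=cols), pct


def ld_decay(
    panel: GenotypePanel, max_distance: float = 5e6, bin_width: float = 5e5
) -> pd.DataFrame:
    """Mean r^2 per physical-distance bin over within-chromosome marker pairs.

    Bins are half-open [lo, hi).  Returns columns bin_lo, bin_hi, mean_r2,
    n_pairs; an empty frame (with a warning) when no pair is within
    ``max_distance``.
    """
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    dists, r2s = [], []
    for _, sub in panel.markers.groupby("chrom", sort=False):
        cols = sub.index.to_numpy()
        if len(cols) < 2:
            continue
        pos = sub["pos"].to_numpy(dtype=float)
        r2 = _pairwise_r2(panel.genotypes[:, cols])
        iu, ju = np.triu_indices(len(cols), k=1)
        d = pos[ju] - pos[iu]
        ok = (d <= max_distance) & np.isfinite(r2[iu, ju])
        dists.append(d[ok])
        r2s.append(r2[iu, ju][ok])
    if not dists or sum(len(d) for d in dists) == 0:
        warnings.warn("no eligible marker pairs within max_distance")
        return pd.DataFrame(columns=["bin_lo", "bin_hi", "mean_r2", "n_pairs"])
    d = np.concatenate(dists)
    r2 = np.concatenate(r2s)
    which = np.digitize(d, edges) - 1
    rows = []
    for b in range(len(edges) - 1):
        sel = which == b
        if sel.any():
            rows.append((edges[b], edges[b + 1], float(r2[sel].mean()), int(sel.sum())))
        else:
            rows.append((edges[b], edges[b + 1], np.nan, 0))
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "mean_r2", "n_pairs"])
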