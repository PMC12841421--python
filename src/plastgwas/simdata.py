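"""Synthetic multi-family genotype/phenotype generator with planted QTLs.

Emulates a nested association mapping (NAM-like) barley panel: each family
descends from a cross between one shared recurrent parent and a
family-specific donor, advanced to near-complete inbreeding.  Genotypes are
coded {0, 2} (homozygote allele counts, no heterozygotes).  Phenotypes are
generated under an additive two-environment model

    y = mu_trait + env_shift(env) + sum_q beta_q(env) * x_q + u_line + eps

with a line-level polygenic deviate ``u`` shared across environments and
i.i.d. residual noise per replicate, so every downstream stage (plasticity
estimation, variance partitioning, association scans, consensus retention,
antagonism detection) can be exercised against planted truth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SimConfig",
    "GenotypePanel",
    "QTLSpec",
    "QTLRegistry",
    "TRAIT_BASELINES",
    "simulate_genotypes",
    "plant_qtls",
    "simulate_phenotypes",
]

#: Baseline (well-watered) trait means used as intercepts so synthetic
#: phenotypes land on familiar agronomic scales: grain-filling period (days),
#: grain yield (g/plant), total dry matter (g), days to maturity, grain
#: number, and harvest index (%).
TRAIT_BASELINES: dict[str, float] = {
    "GFP": 36.01,
    "GY": 18.33,
    "TDM": 59.93,
    "MAT": 136.8,
    "GN": 300.3,
    "HI": 31.6,
}

ENVIRONMENTS = ("WW", "WL")


class ConfigurationError(ValueError):
    """Raised when a SimConfig violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Design parameters for one synthetic panel + phenotype draw.

    ``recombination_rate`` is the expected number of crossovers per
    chromosome per meiosis (a 150 cM barley chromosome corresponds to 1.5).
    ``env_effect`` is the mean trait-unit drop from WW to WL.
    """

    n_families: int = 25
    lines_per_family: int = 12
    n_chromosomes: int = 7
    markers_per_chromosome: int = 100
    chromosome_length: int = 500_000_000
    recombination_rate: float = 1.5
    missing_rate: float = 0.02
    n_replicates: int = 2
    env_effect: float = 5.0
    sigma2_poly: float = 1.0
    sigma2_resid: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_families": self.n_families,
            "lines_per_family": self.lines_per_family,
            "n_chromosomes": self.n_chromosomes,
            "markers_per_chromosome": self.markers_per_chromosome,
            "chromosome_length": self.chromosome_length,
            "n_replicates": self.n_replicates,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ConfigurationError(f"{name} must be an integer >= 1, got {value!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError(f"missing_rate must be in [0, 1), got {self.missing_rate}")
        if self.recombination_rate < 0:
            raise ConfigurationError("recombination_rate must be >= 0")
        if self.sigma2_poly < 0 or self.sigma2_resid < 0:
            raise ConfigurationError("variance components must be >= 0")
        if int(self.seed) != self.seed:
            raise ConfigurationError("seed must be an integer")


@dataclass
class GenotypePanel:
    """Biallelic inbred marker panel.

    genotypes: float matrix (lines x markers) with values in {0.0, 2.0, nan}.
    markers:   DataFrame with columns marker_id, chrom (``1H``..), pos (1-based bp).
    families:  Series mapping line_id -> family label.
    """

    genotypes: np.ndarray
    markers: pd.DataFrame
    line_ids: list[str]
    families: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        g = self.genotypes
        ok = np.isnan(g) | (g == 0.0) | (g == 2.0)
        if not ok.all():
            raise ValueError("genotype values must be 0, 2 or missing")
        if self.markers["marker_id"].duplicated().any():
            raise ValueError("marker_ids must be unique")
        for _, sub in self.markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not (np.diff(pos) > 0).all():
                raise ValueError("positions must be strictly increasing within a chromosome")
        if g.shape != (len(self.line_ids), len(self.markers)):
            raise ValueError("genotype matrix shape does not match line/marker counts")

    @property
    def n_lines(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def marker_index(self, marker_ids: Iterable[str]) -> np.ndarray:
        lookup = {m: i for i, m in enumerate(self.markers["marker_id"])}
        try:
            return np.array([lookup[m] for m in marker_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message matters, not path
            raise KeyError(f"marker {exc.args[0]!r} not present in panel") from exc

    def imputed(self) -> np.ndarray:
        """Marker-mean imputed copy for numeric work (missingness preserved here)."""
        g = self.genotypes.copy()
        col_mean = np.nanmean(g, axis=0)
        idx = np.where(np.isnan(g))
        g[idx] = np.take(col_mean, idx[1])
        return g

    def polymorphic_mask(self) -> np.ndarray:
        g = self.genotypes
        with np.errstate(invalid="ignore"):
            mn = np.nanmin(g, axis=0)
            mx = np.nanmax(g, axis=0)
        return mn != mx

    def subset_markers(self, keep: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            genotypes=self.genotypes[:, keep],
            markers=self.markers.iloc[keep].reset_index(drop=True),
            line_ids=list(self.line_ids),
            families=self.families,
        )


@dataclass(frozen=True)
class QTLSpec:
    """Request for one planted QTL.

    kind: ``main`` (same effect both environments), ``plastic`` (effect in the
    designated environment only) or ``antagonistic`` (opposite-sign effects).
    var_frac: target fraction of total phenotypic variance explained in the
    designated environment.
    """

    kind: str
    trait: str = "GY"
    var_frac: float = 0.10
    env: str = "WW"

    def __post_init__(self) -> None:
        if self.kind not in {"main", "plastic", "antagonistic"}:
            raise ValueError(f"unknown QTL kind {self.kind!r}")
        if not 0.0 < self.var_frac < 1.0:
            raise ValueError("var_frac must be in (0, 1)")
        if self.env not in ENVIRONMENTS:
            raise ValueError(f"env must be one of {ENVIRONMENTS}")


@dataclass
class QTLRegistry:
    """Planted-truth ledger: one row per (marker, trait) effect pair."""

    entries: pd.DataFrame  # marker_id, trait, effect_WW, effect_WL, antagonistic

    COLUMNS = ["marker_id", "trait", "effect_WW", "effect_WL", "antagonistic"]

    def __post_init__(self) -> None:
        missing = set(self.COLUMNS) - set(self.entries.columns)
        if missing:
            raise ValueError(f"registry missing columns {sorted(missing)}")
        e = self.entries
        expect = (np.sign(e["effect_WW"]) * np.sign(e["effect_WL"]) < 0) & (
            (e["effect_WW"] != 0) & (e["effect_WL"] != 0)
        )
        if not (e["antagonistic"].astype(bool) == expect).all():
            raise ValueError("antagonistic flag inconsistent with effect signs")

    def traits(self) -> list[str]:
        return sorted(self.entries["trait"].unique())

    def for_trait(self, trait: str) -> pd.DataFrame:
        return self.entries[self.entries["trait"] == trait]


def simulate_genotypes(config: SimConfig) -> GenotypePanel:
    """Simulate a multi-family inbred panel with distance-dependent LD.

    Each family has two founder haplotypes: the shared recurrent parent and a
    family-specific donor.  Lines are single inbred mosaics of the two
    founders with a Poisson number of crossovers per chromosome, so r^2
    between markers decays with physical distance at a rate set by
    ``recombination_rate``.
    """
    rng = np.random.default_rng(config.seed)
    n_lines = config.n_families * config.lines_per_family
    m_per = config.markers_per_chromosome
    n_markers = config.n_chromosomes * m_per

    markers = []
    for c in range(config.n_chromosomes):
        # distinct 1-based positions without materializing the whole range
        pos = np.unique(rng.integers(1, config.chromosome_length + 1, size=2 * m_per + 8))
        while len(pos) < m_per:
            extra = rng.integers(1, config.chromosome_length + 1, size=2 * m_per)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, size=m_per, replace=False))
        for j, p in enumerate(pos):
            markers.append((f"snp_{c + 1}H_{j:04d}", f"{c + 1}H", int(p)))
    marker_df = pd.DataFrame(markers, columns=["marker_id", "chrom", "pos"])

    # Founder alleles: recurrent parent vs donor differ at every marker, so a
    # line's allele is determined by which founder each segment descends from.
    geno = np.empty((n_lines, n_markers), dtype=float)
    line_ids, fam_labels = [], []
    row = 0
    for f in range(config.n_families):
        fam = f"F{f + 1:02d}"
        for l in range(config.lines_per_family):
            line_ids.append(f"{fam}_L{l + 1:03d}")
            fam_labels.append(fam)
            offset = 0
            for c in range(config.n_chromosomes):
                pos = marker_df["pos"].to_numpy()[offset : offset + m_per]
                n_x = rng.poisson(config.recombination_rate)
                breaks = np.sort(rng.uniform(1, config.chromosome_length, size=n_x))
                # segment index at each marker; parity + random start founder
                seg = np.searchsorted(breaks, pos)
                start = rng.integers(0, 2)
                from_donor = (seg + start) % 2 == 1
                geno[row, offset : offset + m_per] = np.where(from_donor, 2.0, 0.0)
                offset += m_per
            row += 1

    if config.missing_rate > 0:
        mask = rng.random(geno.shape) < config.missing_rate
        geno[mask] = np.nan

    return GenotypePanel(
        genotypes=geno,
        markers=marker_df,
        line_ids=line_ids,
        families=pd.Series(fam_labels, index=line_ids, name="family"),
    )


def plant_qtls(
    panel: GenotypePanel,
    specs: Sequence[QTLSpec],
    seed: int,
    sigma2_poly: float = 1.0,
    sigma2_resid: float = 1.0,
) -> QTLRegistry:
    """Pick polymorphic markers and scale allele effects to target variance
    fractions on the *realized* genotype frequencies.

    The target fraction is interpreted against the total phenotypic variance
    of a single replicate in the QTL's designated environment:
    sum of per-QTL variances + sigma2_poly + sigma2_resid.
    """
    rng = np.random.default_rng(seed)
    poly = np.flatnonzero(panel.polymorphic_mask())
    if len(specs) > len(poly):
        raise ValueError(
            f"requested {len(specs)} QTLs but only {len(poly)} polymorphic markers available"
        )
    chosen = rng.choice(poly, size=len(specs), replace=False)

    # Solve for per-QTL genetic variances: v_q = f_q * T with
    # T = (sigma2_poly + sigma2_resid) / (1 - F_env), F_env the summed target
    # fractions of QTLs active in that environment.  Using the max over
    # environments keeps every realized fraction <= its target; with one
    # environment per spec (the common case) it is exact.
    frac_by_env = {env: 0.0 for env in ENVIRONMENTS}
    for s in specs:
        if s.kind == "main" or s.kind == "antagonistic":
            for env in ENVIRONMENTS:
                frac_by_env[env] += s.var_frac
        else:
            frac_by_env[s.env] += s.var_frac
    f_max = max(frac_by_env.values())
    if f_max >= 1.0:
        raise ValueError("summed target variance fractions must be < 1 per environment")
    base = sigma2_poly + sigma2_resid
    scale_total = base / (1.0 - f_max)

    rows = []
    for s, j in zip(specs, chosen):
        x = panel.genotypes[:, j]
        var_x = float(np.nanvar(x))
        beta = np.sqrt(s.var_frac * scale_total / var_x)
        sign = rng.choice([-1.0, 1.0])
        beta *= sign
        if s.kind == "main":
            eww, ewl = beta, beta
        elif s.kind == "plastic":
            eww, ewl = (beta, 0.0) if s.env == "WW" else (0.0, beta)
        else:  # antagonistic
            eww, ewl = beta, -beta
        rows.append(
            {
                "marker_id": panel.markers["marker_id"].iloc[j],
                "trait": s.trait,
                "effect_WW": eww,
                "effect_WL": ewl,
                "antagonistic": s.kind == "antagonistic",
            }
        )
    return QTLRegistry(entries=pd.DataFrame(rows, columns=QTLRegistry.COLUMNS))


def simulate_phenotypes(
    panel: GenotypePanel,
    registry: QTLRegistry,
    config: SimConfig,
    traits: Sequence[str] | None = None,
    baselines: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Draw replicate-level phenotypes under the additive two-environment model.

    Returns a long-format DataFrame with columns
    genotype, trait, env, rep, value.  The WL environment mean sits
    ``config.env_effect`` trait units below WW.  The polygenic deviate is per
    line and shared across environments (it contributes to G, not GxE).
    """
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from genotypes
    if traits is None:
        traits = registry.traits() or ["GY"]
    base = dict(TRAIT_BASELINES)
    if baselines:
        base.update(baselines)

    missing = set(registry.entries["marker_id"]) - set(panel.markers["marker_id"])
    if missing:
        raise KeyError(f"registry references markers absent from panel: {sorted(missing)[:5]}")

    geno = panel.imputed()
    n = panel.n_lines
    records = []
    for trait in traits:
        mu = base.get(trait, 0.0)
        qtl = registry.for_trait(trait)
        g_ww = np.zeros(n)
        g_wl = np.zeros(n)
        if len(qtl):
            idx = panel.marker_index(qtl["marker_id"])
            x = geno[:, idx] - np.nanmean(geno[:, idx], axis=0)  # centered allele counts
            g_ww = x @ qtl["effect_WW"].to_numpy()
            g_wl = x @ qtl["effect_WL"].to_numpy()
        u = rng.normal(0.0, np.sqrt(config.sigma2_poly), size=n)
        for env, g_env, shift in (("WW", g_ww, 0.0), ("WL", g_wl, -config.env_effect)):
            for rep in range(1, config.n_replicates + 1):
                eps = rng.normal(0.0, np.sqrt(config.sigma2_resid), size=n)
                vals = mu + shift + g_env + u + eps
                records.append(
                    pd.DataFrame(
                        {
                            "genotype": panel.line_ids,
                            "trait": trait,
                            "env": env,
                            "rep": rep,
                            "value": vals,
                        }
                    )
                )
    out = pd.concat(records, ignore_index=True)
    assert np.isfinite(out["value"]).all()
    return out
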