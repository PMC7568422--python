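"""Synthetic count matrices and phenotype tables with known ground truth.

Emulates the study design the screen targets: a small panel of
conditions (default 5, e.g. tumor cell lines) with a few biological
replicates each (default 4), gene-level negative-binomial counts with
per-sample library-size factors, gene-specific means and dispersions,
and a configurable fraction of genes whose condition means follow a
chosen equality/ordering pattern.  Every stage of the screen can then be
verified against the recorded truth without any external dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .patterns import PatternSpec, all_equal_pattern

__all__ = ["SimConfig", "SyntheticTruth", "simulate_counts", "simulate_phenotype"]

DEFAULT_CONDITIONS = ("OV90", "OVCAR4", "OVCAR3", "OVCAR5", "OVCA432")


@dataclass
class SimConfig:
    """Configuration of one synthetic count experiment.

    Defaults mirror the emulated study design: 5 conditions x 4
    replicates, gene means log-uniform between 10 and 5000 normalized
    counts, per-gene NB dispersion drawn from Gamma(2, 0.05) (mean 0.1,
    a typical bulk RNA-seq scale), library-size factors uniform in
    (0.7, 1.3), and at least a 2-fold separation between adjacent
    unequal blocks so that differential patterns are detectable.
    """

    n_genes: int = 2000
    n_conditions: int = 5
    replicates_per_condition: int = 4
    pattern_mixture: Mapping[PatternSpec, float] | None = None
    mean_log_range: tuple[float, float] = (np.log(10.0), np.log(5000.0))
    dispersion_shape: float = 2.0
    dispersion_scale: float = 0.05
    size_factor_range: tuple[float, float] = (0.7, 1.3)
    effect_size_min: float = 2.0
    seed: int = 0
    condition_labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_conditions <= 0 or self.replicates_per_condition <= 0:
            raise ValueError("dimensions must be positive")
        if not self.condition_labels:
            if self.n_conditions == len(DEFAULT_CONDITIONS):
                self.condition_labels = DEFAULT_CONDITIONS
            else:
                self.condition_labels = tuple(
                    f"C{i}" for i in range(1, self.n_conditions + 1)
                )
        if len(self.condition_labels) != self.n_conditions:
            raise ValueError("condition_labels length must equal n_conditions")
        if self.pattern_mixture is None:
            self.pattern_mixture = {all_equal_pattern(self.condition_labels): 1.0}
        total = sum(self.pattern_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern mixture proportions sum to {total}, not 1")
        if any(p < 0 for p in self.pattern_mixture.values()):
            raise ValueError("mixture proportions must be non-negative")
        for pat in self.pattern_mixture:
            if set(pat.conditions) != set(self.condition_labels):
                raise ValueError(
                    f"pattern {pat.name} does not cover the configured conditions"
                )
        if self.effect_size_min <= 1:
            raise ValueError("effect_size_min must exceed 1 (a fold change)")
        lo, hi = self.size_factor_range
        if not (0 < lo <= hi):
            raise ValueError("size_factor_range must be within (0, inf)")
        if self.dispersion_shape <= 0 or self.dispersion_scale <= 0:
            raise ValueError("dispersion prior parameters must be positive")

    @property
    def samples(self) -> list[str]:
        return [
            f"{c}_r{j}"
            for c in self.condition_labels
            for j in range(1, self.replicates_per_condition + 1)
        ]

    @property
    def condition_map(self) -> dict[str, str]:
        return {s: s.rsplit("_r", 1)[0] for s in self.samples}


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated experiment: one record per gene."""

    pattern: pd.Series  # gene -> pattern name
    means: pd.DataFrame  # gene x condition true (unnormalized-scale) means
    size_factors: pd.Series  # sample -> true factor
    dispersions: pd.Series  # gene -> NB dispersion (1/size)
    patterns: dict[str, PatternSpec]  # name -> spec used


def _block_levels(
    rng: np.random.Generator, base: float, pattern: PatternSpec, effect_min: float
) -> np.ndarray:
    """Distinct block mean levels, adjacent levels >= effect_min fold apart."""
    n = pattern.n_blocks
    folds = rng.uniform(effect_min, 1.5 * effect_min, size=max(n - 1, 0))
    levels = base * np.concatenate([[1.0], np.cumprod(folds)])
    if pattern.ordering == "increasing":
        return levels
    if pattern.ordering == "decreasing":
        return levels[::-1]
    return rng.permutation(levels)


def simulate_counts(config: SimConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a genes x samples NB count matrix with recorded truth.

    Counts for gene g, sample i follow NB(mean = mu_g,cond(i) * l_i,
    size = 1/phi_g).  Identical config and seed reproduce the matrix
    bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    conds = list(config.condition_labels)
    samples = config.samples
    G, K = config.n_genes, config.n_conditions

    lo, hi = config.size_factor_range
    l = rng.uniform(lo, hi, size=len(samples))

    pats = list(config.pattern_mixture.keys())
    props = np.array([config.pattern_mixture[p] for p in pats], dtype=float)
    assign = rng.choice(len(pats), size=G, p=props / props.sum())

    base = np.exp(rng.uniform(*config.mean_log_range, size=G))
    phi = rng.gamma(config.dispersion_shape, config.dispersion_scale, size=G)
    phi = np.maximum(phi, 1e-6)

    mu = np.empty((G, K))
    for g in range(G):
        pat = pats[assign[g]]
        levels = _block_levels(rng, base[g], pat, config.effect_size_min)
        for j, block in enumerate(pat.blocks):
            for c in block:
                mu[g, conds.index(c)] = levels[j]

    cond_of_sample = np.array([conds.index(config.condition_map[s]) for s in samples])
    mean_mat = mu[:, cond_of_sample] * l[None, :]
    r = (1.0 / phi)[:, None]
    p = r / (r + mean_mat)
    counts = rng.negative_binomial(r, p)

    counts_df = pd.DataFrame(
        counts, index=[f"gene{g + 1}" for g in range(G)], columns=samples
    )
    truth = SyntheticTruth(
        pattern=pd.Series(
            [pats[a].name for a in assign], index=counts_df.index, name="pattern"
        ),
        means=pd.DataFrame(mu, index=counts_df.index, columns=conds),
        size_factors=pd.Series(l, index=samples, name="size_factor"),
        dispersions=pd.Series(phi, index=counts_df.index, name="dispersion"),
        patterns={p.name: p for p in pats},
    )
    return counts_df, truth


def simulate_phenotype(
    order: Sequence[str],
    noise_sd: float = 0.0,
    n_donors: int = 3,
    seed: int = 0,
    markers: Sequence[str] = ("CD68", "CD163"),
    marker_orders: Mapping[str, Sequence[str]] | None = None,
    base: float = 20.0,
    fold: float = 1.7,
) -> pd.DataFrame:
    """Donor x condition phenotype counts following a known ordering.

    Condition means for each marker are geometrically spaced (``base``
    times ``fold`` per rank) along ``order`` (overridable per marker via
    ``marker_orders``), with additive Gaussian noise per donor.  With
    small ``noise_sd`` the donor-averaged means sort back into the
    requested order.
    """
    order = list(order)
    if len(set(order)) != len(order):
        raise ValueError("condition labels must be distinct")
    if n_donors <= 0:
        raise ValueError("n_donors must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    rank = {m: {c: i for i, c in enumerate(order)} for m in markers}
    if marker_orders:
        for m, o in marker_orders.items():
            if set(o) != set(order):
                raise ValueError(f"marker order for {m} must cover the same conditions")
            rank[m] = {c: i for i, c in enumerate(o)}
    for d in range(1, n_donors + 1):
        for c in order:
            row: dict = {"donor": f"donor{d}", "condition": c}
            for m in markers:
                mean = base * fold ** rank[m][c]
                row[m] = max(mean + rng.normal(0.0, noise_sd), 0.0)
            rows.append(row)
    return pd.DataFrame(rows)
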