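"""Negative-binomial–beta empirical-Bayes pattern-posterior model.

Observation model: count x_gi for gene g in sample i is negative binomial
with size r_gi = r0_g * l_i (l_i the sample's library size factor) and
success probability q_g shared within an equality block of conditions,
with a conjugate Beta(alpha, beta) prior on q_g.  Integrating q out gives
the block predictive density

    log f(x | r, alpha, beta) = sum_i log C(x_i + r_i - 1, x_i)
                                + log B(alpha + sum r_i, beta + sum x_i)
                                - log B(alpha, beta)

A gene's likelihood under an equality pattern is the product of this
predictive over the pattern's blocks (samples pooled within a block).
Posterior pattern probabilities follow by Bayes' rule with mixture
weights p_k; (alpha, beta, p) are estimated by EM, r0_g by method of
moments.  Gene selection controls the FDR via the posterior
probabilities themselves: select the largest posterior-ranked set whose
mean misassignment probability stays below the nominal level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import betaln, gammaln, logsumexp

from .normalize import median_ratio_size_factors, normalized_counts
from .patterns import PatternSpec

__all__ = [
    "EBModelParams",
    "NBBetaPatternModel",
    "NBBetaPatternResults",
    "FdrSelection",
    "nb_beta_block_loglik",
    "fdr_select",
]


def nb_beta_block_loglik(
    x: Sequence[float], r: Sequence[float], alpha: float, beta: float
) -> float:
    """Predictive log-density of one equality block.

    ``x`` are the observed counts of the pooled samples, ``r`` their NB
    sizes (r0 scaled by each sample's size factor).  An empty block has
    log-density 0.  Computed entirely in log space.
    """
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    if x.size == 0:
        return 0.0
    if np.any(x < 0) or np.any(x != np.floor(x)):
        raise ValueError("counts must be non-negative integers")
    if np.any(r <= 0) or alpha <= 0 or beta <= 0:
        raise ValueError("r, alpha, beta must be positive")
    comb = np.sum(gammaln(x + r) - gammaln(r) - gammaln(x + 1))
    return float(
        comb + betaln(alpha + r.sum(), beta + x.sum()) - betaln(alpha, beta)
    )


@dataclass
class EBModelParams:
    """Hyperparameters of the NB-beta pattern model.

    alpha, beta : Beta-prior hyperparameters on the NB probability q.
    r0          : per-gene NB size before size-factor scaling.
    mixture     : per-pattern prior proportions, summing to 1.
    """

    alpha: float
    beta: float
    r0: pd.Series
    mixture: pd.Series

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if (self.r0 <= 0).any():
            raise ValueError("r0 must be positive")
        if abs(float(self.mixture.sum()) - 1.0) > 1e-9:
            raise ValueError("mixture proportions must sum to 1")


@dataclass
class FdrSelection:
    """Outcome of posterior-probability FDR selection."""

    genes: list
    estimated_fdr: float
    target: str
    level: float
    posterior: pd.Series = field(repr=False)

    def __len__(self) -> int:
        return len(self.genes)


def fdr_select(
    posteriors: pd.DataFrame,
    target_pattern: PatternSpec | str,
    fdr_level: float,
) -> FdrSelection:
    """Select the largest gene set with posterior-estimated FDR <= level.

    Genes are ranked by decreasing posterior probability of the target
    pattern; the running mean of (1 - PP) over the top-m genes estimates
    the FDR of selecting those m, and the largest m keeping it at or
    below ``fdr_level`` is returned.  Ties in PP break by gene
    identifier (lexicographic) for determinism.
    """
    if not 0 < fdr_level < 1:
        raise ValueError("fdr_level must be in (0, 1)")
    name = target_pattern.name if isinstance(target_pattern, PatternSpec) else target_pattern
    if name not in posteriors.columns:
        raise KeyError(f"target pattern {name!r} not in posterior table")
    pp = posteriors[name]
    order = sorted(pp.index, key=lambda g: (-pp[g], str(g)))
    pp_sorted = pp.loc[order].to_numpy()
    cum_fdr = np.cumsum(1.0 - pp_sorted) / np.arange(1, len(pp_sorted) + 1)
    keep = np.nonzero(cum_fdr <= fdr_level)[0]
    if keep.size == 0:
        return FdrSelection([], 0.0, name, fdr_level, pp)
    m = int(keep[-1]) + 1
    return FdrSelection(list(order[:m]), float(cum_fdr[m - 1]), name, fdr_level, pp)


class NBBetaPatternModel:
    """Multi-condition pattern-posterior model for a count matrix.

    Parameters
    ----------
    counts
        Integer counts, genes x samples.  Genes with all-zero counts are
        dropped before fitting (recorded on the results object).
    condition_map
        sample -> condition label for every column.
    patterns
        Candidate equality patterns over the conditions.
    size_factors
        Optional per-sample factors; computed by median-of-ratios when
        omitted (falling back to a positive-entry pseudo-reference, with
        a warning, if no gene row is all-positive).
    r0_bounds
        (min, max) clamp for the method-of-moments size estimate.
    dispersion_floor_quantile
        The genewise dispersion estimates are floored at this quantile
        of their panel-wide distribution (default: the median) to keep
        chance-underdispersed genes from looking spuriously precise.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        condition_map: Mapping[str, str],
        patterns: Sequence[PatternSpec],
        size_factors: pd.Series | None = None,
        r0_bounds: tuple[float, float] = (1e-3, 1e4),
        dispersion_floor_quantile: float = 0.5,
    ) -> None:
        if len(patterns) == 0:
            raise ValueError("need at least one pattern")
        x = counts.to_numpy()
        if (np.asarray(x) < 0).any() or not np.issubdtype(np.asarray(x).dtype, np.number):
            raise ValueError("counts must be non-negative numbers")
        missing = [s for s in counts.columns if s not in condition_map]
        if missing:
            raise ValueError(f"samples without a condition: {missing}")

        self.all_counts = counts
        self.dropped_genes = list(counts.index[(counts == 0).all(axis=1)])
        self.counts = counts.drop(index=self.dropped_genes)
        self.condition_map = dict(condition_map)
        self.patterns = list(patterns)
        self.r0_bounds = r0_bounds
        self.dispersion_floor_quantile = dispersion_floor_quantile

        cond_order: list[str] = []
        for s in counts.columns:
            c = condition_map[s]
            if c not in cond_order:
                cond_order.append(c)
        self.conditions = cond_order
        for p in self.patterns:
            if set(p.conditions) != set(cond_order):
                raise ValueError(
                    f"pattern {p.name} conditions {p.conditions} do not match data"
                )

        if size_factors is None:
            try:
                size_factors = median_ratio_size_factors(self.counts)
            except ValueError:
                warnings.warn(
                    "no all-positive gene row; using pseudo-reference size factors"
                )
                size_factors = median_ratio_size_factors(
                    self.counts, allow_pseudo_reference=True
                )
        self.size_factors = size_factors.reindex(counts.columns)

        self._prepare_sufficient_stats()

    # ------------------------------------------------------------------
    def _prepare_sufficient_stats(self) -> None:
        x = self.counts.to_numpy(dtype=float)
        l = self.size_factors.to_numpy(dtype=float)
        cond_idx = {c: i for i, c in enumerate(self.conditions)}
        sample_cond = np.array(
            [cond_idx[self.condition_map[s]] for s in self.counts.columns]
        )
        K = len(self.conditions)
        G = x.shape[0]
        self._Sx = np.zeros((G, K))  # per-condition count sums
        self._Lk = np.zeros(K)  # per-condition size-factor sums
        for k in range(K):
            cols = sample_cond == k
            self._Sx[:, k] = x[:, cols].sum(axis=1)
            self._Lk[k] = l[cols].sum()
        self._x = x
        self._l = l
        # block -> condition index lists, per pattern
        self._block_idx = [
            [np.array([cond_idx[c] for c in b]) for b in p.blocks]
            for p in self.patterns
        ]

    def _moment_r0(self) -> pd.Series:
        """Method-of-moments NB size r0 = m^2 / (v - m).

        m is the gene's mean normalized count; v its within-condition
        variance pooled across conditions (per-condition sample
        variances, degrees-of-freedom weighted).  Pooling within
        conditions keeps genuine between-condition differences out of
        the dispersion estimate; a variance computed across all samples
        would absorb a differential gene's signal as overdispersion.
        """
        norm = normalized_counts(self.counts, self.size_factors)
        m = norm.to_numpy().mean(axis=1)
        cond_of = [self.condition_map[s] for s in norm.columns]
        num = np.zeros(m.shape)
        dof = 0
        for c in self.conditions:
            cols = [s for s, cc in zip(norm.columns, cond_of) if cc == c]
            if len(cols) < 2:
                continue
            num += norm[cols].to_numpy().var(axis=1, ddof=1) * (len(cols) - 1)
            dof += len(cols) - 1
        if dof == 0:  # single replicate per condition: fall back to global
            v = norm.to_numpy().var(axis=1, ddof=1)
            dof = max(len(norm.columns) - 1, 1)
        else:
            v = num / dof
        lo, hi = self.r0_bounds
        # Floor the per-gene dispersion phi = 1/r0 at the panel-typical
        # value (a quantile of the genewise estimates, default the
        # median).  With a handful of replicates the raw moment
        # estimate is noisy, and a gene whose variance is
        # underestimated by chance looks spuriously precise and
        # inflates the pattern-selection FDR; flooring trades a little
        # power for calibration, in the spirit of DESeq's conservative
        # dispersion sharing.
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_raw = np.clip((v - m) / m**2, 0.0, None)
        phi_raw = np.nan_to_num(phi_raw, nan=0.0, posinf=0.0)
        n_zero = int(np.sum(phi_raw == 0))
        if n_zero:
            warnings.warn(
                f"{n_zero} gene(s) with variance <= mean; "
                f"dispersion floored at the panel-typical value"
            )
        positive = phi_raw[phi_raw > 0]
        if positive.size:
            phi0 = float(np.quantile(positive, self.dispersion_floor_quantile))
            phi = np.maximum(phi_raw, phi0)
        else:  # effectively Poisson data
            phi = np.full_like(phi_raw, 1.0 / hi)
        r0 = np.clip(1.0 / phi, lo, hi)
        return pd.Series(r0, index=self.counts.index, name="r0")

    def _comb_term(self, r0: np.ndarray) -> np.ndarray:
        """Per-gene pattern-independent log binomial coefficient sum."""
        r = r0[:, None] * self._l[None, :]
        return (gammaln(self._x + r) - gammaln(r) - gammaln(self._x + 1)).sum(axis=1)

    def _beta_terms(self, r0: np.ndarray, alpha: float, beta: float) -> np.ndarray:
        """(G, P) matrix of the pattern-dependent Beta-function terms."""
        G = self._Sx.shape[0]
        out = np.empty((G, len(self.patterns)))
        lb0 = betaln(alpha, beta)
        for j, blocks in enumerate(self._block_idx):
            acc = np.zeros(G)
            for idx in blocks:
                bx = self._Sx[:, idx].sum(axis=1)
                br = r0 * self._Lk[idx].sum()
                acc += betaln(alpha + br, beta + bx)
            out[:, j] = acc - len(blocks) * lb0
        return out

    def loglik_matrix(
        self, r0: np.ndarray, alpha: float, beta: float
    ) -> np.ndarray:
        """Full per-gene, per-pattern log-likelihood (G x P)."""
        return self._beta_terms(r0, alpha, beta) + self._comb_term(r0)[:, None]

    # ------------------------------------------------------------------
    def fit(
        self,
        max_iter: int = 100,
        tol: float = 1e-4,
        em: bool = True,
        start: EBModelParams | None = None,
    ) -> "NBBetaPatternResults":
        """Fit by EM; or, with ``em=False``, evaluate posteriors at ``start``.

        The E-step computes posterior pattern probabilities by Bayes'
        rule; the M-step re-estimates the mixture as the posterior means
        and (alpha, beta) by numerical maximization of the expected
        log-marginal.  Stops when the largest change in (alpha, beta,
        mixture) drops below ``tol``.  Non-convergence returns the last
        iterate flagged ``converged=False``.
        """
        P = len(self.patterns)
        names = [p.name for p in self.patterns]
        if start is not None:
            alpha, beta = start.alpha, start.beta
            r0 = start.r0.reindex(self.counts.index).to_numpy(dtype=float)
            mix = start.mixture.reindex(names).to_numpy(dtype=float)
        else:
            alpha, beta = 1.0, 1.0
            r0 = self._moment_r0().to_numpy()
            mix = np.full(P, 1.0 / P)

        comb = self._comb_term(r0)
        trace: list[float] = []
        converged = not em
        n_iter = 0
        bt = self._beta_terms(r0, alpha, beta)

        for n_iter in range(1, max_iter + 1 if em else 1):
            if not em:
                break
            log_joint = bt + np.log(mix)[None, :]
            post = np.exp(log_joint - logsumexp(log_joint, axis=1)[:, None])
            trace.append(float(np.sum(logsumexp(log_joint, axis=1) + comb)))

            new_mix = post.mean(axis=0)
            new_mix = np.clip(new_mix, 1e-12, None)
            new_mix /= new_mix.sum()

            def neg_q(theta: np.ndarray) -> float:
                a, b = np.exp(theta)
                return -float(np.sum(post * self._beta_terms(r0, a, b)))

            res = minimize(
                neg_q,
                x0=np.log([alpha, beta]),
                method="Nelder-Mead",
                options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 200},
            )
            cand_a, cand_b = np.exp(res.x)
            if neg_q(res.x) <= neg_q(np.log([alpha, beta])):
                new_alpha, new_beta = float(cand_a), float(cand_b)
            else:  # keep current point if the search failed to improve
                new_alpha, new_beta = alpha, beta

            delta = max(
                abs(new_alpha - alpha),
                abs(new_beta - beta),
                float(np.max(np.abs(new_mix - mix))),
            )
            alpha, beta, mix = new_alpha, new_beta, new_mix
            bt = self._beta_terms(r0, alpha, beta)
            if delta < tol:
                converged = True
                break
        if em and not converged:
            warnings.warn(
                f"EM did not converge in {max_iter} iterations; returning last iterate"
            )

        log_joint = bt + np.log(mix)[None, :]
        log_norm = logsumexp(log_joint, axis=1)
        post = np.exp(log_joint - log_norm[:, None])
        trace.append(float(np.sum(log_norm + comb)))

        params = EBModelParams(
            alpha=alpha,
            beta=beta,
            r0=pd.Series(r0, index=self.counts.index, name="r0"),
            mixture=pd.Series(mix, index=names, name="mixture"),
        )
        posteriors = pd.DataFrame(post, index=self.counts.index, columns=names)
        return NBBetaPatternResults(
            model=self,
            params=params,
            posteriors=posteriors,
            converged=converged,
            n_iter=n_iter,
            loglik_trace=trace,
        )


@dataclass
class NBBetaPatternResults:
    """Fitted pattern-posterior model.

    ``posteriors`` holds per-gene posterior probabilities over the
    candidate patterns (rows sum to 1); ``params`` the fitted
    hyperparameters.  ``fdr_select`` ranks genes by the posterior of a
    target pattern and returns the largest set whose estimated FDR stays
    below a nominal level.
    """

    model: NBBetaPatternModel
    params: EBModelParams
    posteriors: pd.DataFrame
    converged: bool
    n_iter: int
    loglik_trace: list[float]

    @property
    def map_pattern(self) -> pd.Series:
        return self.posteriors.idxmax(axis=1).rename("map_pattern")

    def fdr_select(
        self, target_pattern: PatternSpec | str, fdr_level: float = 0.05
    ) -> FdrSelection:
        return fdr_select(self.posteriors, target_pattern, fdr_level)

    def de_universe(self, threshold: float = 0.05) -> list:
        """Genes unlikely to be pattern-flat: PP(all-equal) < threshold.

        Requires the single-block (all-equal) pattern among the
        candidates.
        """
        flat = [p for p in self.model.patterns if p.n_blocks == 1]
        if not flat:
            raise ValueError("no all-equal pattern among the candidates")
        pp = self.posteriors[flat[0].name]
        return list(pp.index[pp < threshold])

    def summary(self) -> str:
        lines = [
            "NB-beta pattern-posterior model",
            "=" * 46,
            f"genes: {self.posteriors.shape[0]}"
            + (f" (+{len(self.model.dropped_genes)} all-zero dropped)"
               if self.model.dropped_genes else ""),
            f"samples: {len(self.model.counts.columns)}  "
            f"conditions: {len(self.model.conditions)}",
            f"patterns: {len(self.model.patterns)}",
            f"alpha: {self.params.alpha:.4f}  beta: {self.params.beta:.4f}",
            f"EM iterations: {self.n_iter}  converged: {self.converged}",
            f"log-likelihood: {self.loglik_trace[-1]:.2f}",
            "",
            "mixture proportions / MAP share:",
        ]
        map_share = self.map_pattern.value_counts(normalize=True)
        for name, p in self.params.mixture.items():
            lines.append(
                f"  {name:<20s} p={p:.4f}  map={map_share.get(name, 0.0):.4f}"
            )
        return "\n".join(lines)
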