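"""Evaluation statistics for the retrospective analyses.

Covers the locus-level classification metrics, Fisher's exact test on the
constrained-vs-unconstrained success proportions, the beta-binomial Monte
Carlo posterior probability that the constrained set converts to genome-wide
significance more often, and the empirical positive-predictive-value
distribution obtained by randomly sampling unconstrained loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .retrospective import ConfusionCounts


@dataclass(frozen=True, slots=True)
class MetricSet:
    """Classification metrics; ``None`` marks an undefined (0/0) ratio."""

    ppv: float | None
    sensitivity: float | None
    specificity: float | None
    fnr: float | None
    fpr: float | None


@dataclass(frozen=True, slots=True)
class PosteriorResult:
    prob_constrained_better: float
    iterations: int
    seed: int


@dataclass(frozen=True, slots=True)
class EmpiricalDistribution:
    sampled_ppvs: np.ndarray
    observed_ppv: float
    percentile_of_observed: float
    seed: int


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """PPV, sensitivity, specificity, FNR and FPR from locus-level counts.

    Undefined denominators yield ``None`` rather than zero, so an empty cell
    is distinguishable from a genuinely zero rate.
    """
    return MetricSet(
        ppv=_ratio(c.tp, c.tp + c.fp),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        fnr=_ratio(c.fn, c.tp + c.fn),
        fpr=_ratio(c.fp, c.fp + c.tn),
    )


def _log_comb(n: "np.ndarray | int", k: "np.ndarray | int") -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def fisher_exact(
    k1: int, n1: int, k2: int, n2: int, alternative: str = "two-sided"
) -> float:
    """Exact (hypergeometric) Fisher p for the 2x2 table [[k1, n1-k1], [k2, n2-k2]].

    The null distribution of the first cell with all margins fixed is
    hypergeometric; the two-sided p-value sums the probabilities of every
    table no more probable than the observed one (with the customary 1e-7
    relative tie tolerance). ``alternative`` may also be ``"greater"`` or
    ``"less"`` for the one-sided tails of the first group's proportion.
    """
    for k, n, name in ((k1, n1, "1"), (k2, n2, "2")):
        if k < 0 or n < 0 or k > n:
            raise ValueError(f"need 0 <= k{name} <= n{name}, got k={k}, n={n}")
    k = k1 + k2
    lo, hi = max(0, k - n2), min(n1, k)
    x = np.arange(lo, hi + 1)
    logp = _log_comb(n1, x) + _log_comb(n2, k - x) - _log_comb(n1 + n2, k)
    p = np.exp(logp)
    obs = p[k1 - lo]
    if alternative == "two-sided":
        total = p[p <= obs * (1.0 + 1e-7)].sum()
    elif alternative == "greater":
        total = p[x >= k1].sum()
    elif alternative == "less":
        total = p[x <= k1].sum()
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(min(1.0, total))


def beta_binomial_posterior(
    k1: int, n1: int, k2: int, n2: int, iterations: int = 100_000, seed: int = 0
) -> PosteriorResult:
    """Monte Carlo estimate of P(theta1 > theta2) under flat-prior binomials.

    With a uniform Beta(1, 1) prior on each success proportion, the
    posteriors are Beta(k+1, n-k+1); ``iterations`` independent draws from
    each estimate the probability that the first proportion (the constrained
    conversion rate) exceeds the second.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    for k, n in ((k1, n1), (k2, n2)):
        if k < 0 or n < 0 or k > n:
            raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    theta1 = rng.beta(k1 + 1, n1 - k1 + 1, size=iterations)
    theta2 = rng.beta(k2 + 1, n2 - k2 + 1, size=iterations)
    return PosteriorResult(
        prob_constrained_better=float(np.mean(theta1 > theta2)),
        iterations=iterations,
        seed=seed,
    )


def empirical_ppv_distribution(
    labels: "np.ndarray | list[bool]",
    n_select: int,
    observed_ppv: float,
    n_iter: int = 10_000,
    seed: int = 0,
) -> EmpiricalDistribution:
    """Random-sampling PPV distribution over the unconstrained locus pool.

    Each iteration draws ``n_select`` loci without replacement from the pool
    (``labels`` marks which loci achieve future genome-wide significance) and
    records the fraction positive. The observed PPV's percentile is the
    fraction of sampled PPVs strictly below it, times 100.
    """
    labels = np.asarray(labels, dtype=bool)
    if n_select <= 0:
        raise ValueError("n_select must be positive")
    if n_select > labels.size:
        raise ValueError(f"n_select={n_select} exceeds pool size {labels.size}")
    rng = np.random.default_rng(seed)
    idx = np.argsort(rng.random((n_iter, labels.size)), axis=1)[:, :n_select]
    sampled = labels[idx].mean(axis=1)
    percentile = float(np.mean(sampled < observed_ppv) * 100.0)
    return EmpiricalDistribution(
        sampled_ppvs=sampled,
        observed_ppv=observed_ppv,
        percentile_of_observed=percentile,
        seed=seed,
    )
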