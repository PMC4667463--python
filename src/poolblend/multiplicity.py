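"""False-discovery-rate control: Storey pi0 estimation and q-values.

``pi0`` (the proportion of true null hypotheses) is estimated on the grid
``lambda = 0.05, 0.10, ..., 0.95`` as ``#{p > lambda} / (m (1 - lambda))``;
the bootstrap selects the grid point minimizing the estimated mean squared
error against the most optimistic (smallest) plug-in estimate.  Q-values
are the step-up transformed ``pi0 * m * p_(i) / i`` made monotone from the
largest p-value downward; with ``pi0 = 1`` they reduce exactly to
Benjamini-Hochberg adjusted p-values.

RLRT p-values carry a point mass at 1 (half of the null distribution);
they enter the estimator unmodified.  Since the null p-value law is
uniform-dominated (``P(p <= t) <= t``), the estimator stays conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FDRResult", "estimate_pi0_bootstrap", "qvalues", "fdr_analysis"]

DEFAULT_LAMBDAS = np.round(np.arange(0.05, 0.96, 0.05), 2)


@dataclass
class FDRResult:
    """pi0/pi1 estimate and q-values for one family of p-values."""

    pi0: float
    q_values: np.ndarray
    alpha: float
    significant: np.ndarray  # boolean mask, q <= alpha

    @property
    def pi1(self) -> float:
        return 1.0 - self.pi0

    @property
    def n_significant(self) -> int:
        return int(np.sum(self.significant))


def estimate_pi0_bootstrap(
    pvals: np.ndarray,
    lambdas: np.ndarray | None = None,
    n_boot: int = 100,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Bootstrap estimate of the proportion of true null hypotheses.

    For each candidate truncation point ``lambda`` the plug-in estimate is
    ``pi0(lambda) = #{p > lambda} / (m (1 - lambda))``; ``n_boot``
    resamples of the p-values estimate ``MSE(lambda)`` against
    ``min_lambda pi0(lambda)`` and the minimizer is returned, clipped to
    ``[0, 1]``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    lambdas = DEFAULT_LAMBDAS if lambdas is None else np.asarray(lambdas)
    rng = rng if isinstance(rng, np.random.Generator) \
        else np.random.default_rng(rng)
    m = p.size
    pi0_lam = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    pi0_min = pi0_lam.min()
    mse = np.zeros(lambdas.size)
    for _ in range(n_boot):
        pb = p[rng.integers(0, m, size=m)]
        pi0_b = np.array([np.mean(pb > lam) / (1.0 - lam) for lam in lambdas])
        mse += (pi0_b - pi0_min) ** 2
    best = int(np.argmin(mse))
    return float(np.clip(pi0_lam[best], 0.0, 1.0))


def qvalues(pvals: np.ndarray, pi0: float = 1.0) -> np.ndarray:
    """Q-values from p-values at a given pi0 (pi0 = 1 gives BH).

    ``q(p_(i)) = min_{j >= i} pi0 * m * p_(j) / j`` on the sorted
    p-values, mapped back to the input order and clipped to [0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if not 0.0 <= pi0 <= 1.0:
        raise ValueError("pi0 must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def fdr_analysis(
    pvals: np.ndarray,
    alpha: float = 0.05,
    pi0_method: str = "bootstrap",
    rng: np.random.Generator | int | None = None,
) -> FDRResult:
    """pi0 estimate, q-values and the significant set for one p-value family."""
    p = np.asarray(pvals, dtype=float)
    if pi0_method == "bootstrap":
        pi0 = estimate_pi0_bootstrap(p, rng=rng)
    elif pi0_method == "bh":
        pi0 = 1.0
    else:
        raise ValueError(f"unknown pi0 method {pi0_method!r}")
    q = qvalues(p, pi0)
    return FDRResult(pi0=pi0, q_values=q, alpha=alpha, significant=q <= alpha)
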