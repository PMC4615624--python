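"""Reconstruct output distributions p(y, t | x+) from their first two moments.

Copy-number marginals are constrained to a two-parameter family chosen by the
mean/spread ratio: a moment-matched negative binomial when the mean is small
relative to the spread (mu < 3*sqrt(C), the regime where a normal would put
appreciable mass at negative counts) and a normal otherwise.  The negative
binomial requires super-Poissonian variance; on the boundary C <= mu the
Poisson - the NB limit - is used.  Joint observables are always modelled as
multivariate normals, which is the regime (high copy number) where joint
computations are performed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["DistributionModel", "MultivariateNormalModel", "from_moments", "pmf_on_support", "joint_normal", "dump_pmf"]


@dataclass(frozen=True)
class DistributionModel:
    """Scalar conditional output law reconstructed from (mu, C)."""

    family: str  # "negative-binomial" | "normal" | "poisson"
    mu: float
    C: float

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.C))

    @property
    def support(self) -> str:
        return "real-line" if self.family == "normal" else "integer-counts"

    def frozen(self):
        """The scipy frozen distribution behind this model."""
        if self.family == "negative-binomial":
            r = self.mu**2 / (self.C - self.mu)
            return stats.nbinom(r, self.mu / self.C)
        if self.family == "poisson":
            return stats.poisson(self.mu)
        return stats.norm(self.mu, self.sd)

    def pmf_integer(self, k: np.ndarray) -> np.ndarray:
        """Probability of integer counts; normals are binned on half-integers."""
        k = np.asarray(k)
        if self.family == "normal":
            d = self.frozen()
            return d.cdf(k + 0.5) - d.cdf(k - 0.5)
        if self.family == "poisson" and self.mu == 0.0:
            return (k == 0).astype(float)
        return self.frozen().pmf(k)


def from_moments(mu: float, C: float) -> DistributionModel:
    """Apply the mu-versus-3*sqrt(C) family rule to one (mean, variance) pair."""
    if not np.isfinite(mu) or not np.isfinite(C):
        raise ValueError(f"non-finite moments (mu={mu}, C={C})")
    if -1e-6 < mu < 0.0:  # integrator dust around hard zeros
        mu = 0.0
    if -1e-6 < C < 0.0:
        C = 0.0
    if mu < 0:
        raise ValueError(f"negative mean {mu}")
    if C < 0:
        raise ValueError(f"negative variance {C} (mean {mu}): upstream moment state invalid")
    if C == 0.0 or mu == 0.0:
        # degenerate law (e.g. the zero-input circuit before any response);
        # Poisson(mu) keeps integer support and is exact for mu = 0.
        return DistributionModel("poisson", mu, mu)
    if mu < 3.0 * np.sqrt(C):
        if C > mu:
            return DistributionModel("negative-binomial", mu, C)
        # NB regime but moment matching impossible (C <= mu): Poisson limit
        return DistributionModel("poisson", mu, mu)
    return DistributionModel("normal", mu, C)


def pmf_on_support(d: DistributionModel, tail_mass: float = 1e-10, bins_per_sd: int = 20):
    """Discretize ``d`` to a probability vector summing to one.

    Integer-count families are truncated where the remaining tail mass drops
    below ``tail_mass``; normals are discretized on [mu - 8 sd, mu + 8 sd]
    with bin width <= sd/bins_per_sd.  Returns ``(support, p)``.
    """
    if d.family in ("negative-binomial", "poisson"):
        if d.family == "poisson" and d.mu == 0.0:
            return np.array([0.0]), np.array([1.0])
        fr = d.frozen()
        hi = int(fr.isf(tail_mass)) + 1
        support = np.arange(0, hi + 1, dtype=float)
        p = fr.pmf(support.astype(int))
    else:
        sd = d.sd
        lo, hi = d.mu - 8.0 * sd, d.mu + 8.0 * sd
        n_bins = max(int(np.ceil((hi - lo) / (sd / bins_per_sd))), 2)
        edges = np.linspace(lo, hi, n_bins + 1)
        support = 0.5 * (edges[1:] + edges[:-1])
        cdf = d.frozen().cdf(edges)
        p = np.diff(cdf)
    total = p.sum()
    if not total > 0:
        raise ValueError(f"no probability mass captured for {d}")
    return support, p / total


@dataclass(frozen=True)
class MultivariateNormalModel:
    """Joint normal over k observables, used for the joint-MI integrands."""

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float)
        cov = 0.5 * (np.asarray(self.cov, dtype=float) + np.asarray(self.cov, dtype=float).T)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", cov)
        w = np.linalg.eigvalsh(cov)
        if w.min() < -1e-9 * max(np.trace(cov), 1.0):
            raise ValueError(f"covariance not PSD after symmetrization (eigenvalues {w})")

    @property
    def k(self) -> int:
        return self.mean.size

    def marginal(self, idx) -> "MultivariateNormalModel":
        idx = np.atleast_1d(idx)
        return MultivariateNormalModel(self.mean[idx], self.cov[np.ix_(idx, idx)])

    def conditional(self, given_idx: int, value: float) -> "MultivariateNormalModel":
        """Condition on one coordinate; degenerate (perfectly correlated)
        conditionals are guarded with a zero-clipped Schur complement."""
        n = self.k
        rest = [i for i in range(n) if i != given_idx]
        s_gg = self.cov[given_idx, given_idx]
        if s_gg <= 0.0:
            return self.marginal(rest)
        s_rg = self.cov[np.ix_(rest, [given_idx])]
        mu = self.mean[rest] + (s_rg[:, 0] / s_gg) * (value - self.mean[given_idx])
        cov = self.cov[np.ix_(rest, rest)] - s_rg @ s_rg.T / s_gg
        cov = np.maximum(0.5 * (cov + cov.T), 0.0) if cov.shape == (1, 1) else 0.5 * (cov + cov.T)
        return MultivariateNormalModel(mu, cov)

    def logpdf(self, y: np.ndarray) -> np.ndarray:
        return stats.multivariate_normal(self.mean, self.cov, allow_singular=True).logpdf(y)


def joint_normal(mean, cov) -> MultivariateNormalModel:
    """Multivariate normal from a mean vector and (PSD) covariance matrix.

    With zero cross-covariance the joint factorizes into its marginals, so the
    expected conditional mutual information reduces to the marginal one.
    """
    return MultivariateNormalModel(np.asarray(mean, float), np.asarray(cov, float))


def dump_pmf(d: DistributionModel, path) -> None:
    """Debug export of the discretized law as CSV (support, probability)."""
    import pandas as pd

    support, p = pmf_on_support(d)
    pd.DataFrame({"support": support, "probability": p}).to_csv(path, index=False)
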