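"""Exact stochastic simulation (Gillespie direct method) of a ReactionNetwork.

This is the brute-force oracle used to validate the moment closure and the
moment-reconstructed distributions: every sample path is a statistically
exact draw from the chemical master equation.  The inner loop is compiled
with numba when available; a pure-Python fallback keeps small cases usable
without it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import ReactionNetwork, SECONDS_PER_MINUTE
from .moments import MomentState, MomentTrajectory

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


__all__ = [
    "SsaTrajectory",
    "simulate",
    "ensemble_states",
    "ensemble_summary",
    "max_normalized_distance",
]


@dataclass
class SsaTrajectory:
    """Jump times (s), integer states after each jump, and the RNG seed."""

    times_s: np.ndarray
    states: np.ndarray  # (n_jumps + 1, N), row 0 is the initial state
    seed: int

    def state_at(self, t_min: float) -> np.ndarray:
        t = t_min * SECONDS_PER_MINUTE
        i = int(np.searchsorted(self.times_s, t, side="right")) - 1
        return self.states[max(i, 0)]


@njit(cache=True)
def _states_at_times(kind, c, ii, jj, base, hill_n, hill_kn, stoich, y0, t_sample, seed):
    np.random.seed(seed)
    N = y0.size
    M = kind.size
    y = y0.copy()
    out = np.zeros((t_sample.size, N), dtype=np.int64)
    a = np.zeros(M)
    t = 0.0
    k = 0
    while k < t_sample.size:
        atot = 0.0
        for m in range(M):
            if kind[m] == 0:
                am = c[m]
            elif kind[m] == 1:
                am = c[m] * y[ii[m]]
            elif kind[m] == 2:
                am = c[m] * y[ii[m]] * y[jj[m]]
            else:
                yi = float(y[ii[m]])
                if yi <= 0.0:
                    am = base[m]
                else:
                    yn = yi ** hill_n[m]
                    am = base[m] + c[m] * yn / (yn + hill_kn[m])
            a[m] = am
            atot += am
        if atot <= 0.0:
            while k < t_sample.size:
                for n in range(N):
                    out[k, n] = y[n]
                k += 1
            break
        t_next = t - np.log(np.random.random()) / atot
        while k < t_sample.size and t_sample[k] < t_next:
            for n in range(N):
                out[k, n] = y[n]
            k += 1
        if k >= t_sample.size:
            break
        t = t_next
        r = np.random.random() * atot
        s = 0.0
        m_sel = M - 1
        for m in range(M):
            s += a[m]
            if r < s:
                m_sel = m
                break
        for n in range(N):
            y[n] += stoich[m_sel, n]
            if y[n] < 0:
                raise ValueError("SSA produced a negative copy number")
    return out


def simulate(
    net: ReactionNetwork,
    init,
    t_end_min: float,
    seed: int,
    x: float = 0.0,
    max_events: int = 50_000_000,
) -> SsaTrajectory:
    """One exact sample path from integer state ``init`` up to ``t_end_min``.

    Records every jump; reproducible given ``seed``.
    """
    init = np.asarray(init)
    if np.any(init < 0) or not np.all(init == np.round(init)):
        raise ValueError("initial state must be non-negative integers")
    y = init.astype(np.int64).copy()
    t_end = t_end_min * SECONDS_PER_MINUTE
    rng = np.random.default_rng(seed)
    S = np.array([r.stoich for r in net.reactions], dtype=np.int64)
    times = [0.0]
    states = [y.copy()]
    t = 0.0
    for _ in range(max_events):
        a = net.propensities(y.astype(float), x)
        if not np.all(np.isfinite(a)):
            raise OverflowError(f"propensity overflow at state {y}")
        atot = a.sum()
        if atot <= 0.0:
            break
        t += rng.exponential(1.0 / atot)
        if t > t_end:
            break
        m = rng.choice(a.size, p=a / atot)
        y = y + S[m]
        if np.any(y < 0):  # pragma: no cover - unreachable for well-formed nets
            raise RuntimeError(f"negative state after reaction {net.reactions[m].name}")
        times.append(t)
        states.append(y.copy())
    else:  # pragma: no cover
        raise RuntimeError(f"exceeded {max_events} events before t_end")
    return SsaTrajectory(np.array(times), np.array(states), seed)


def ensemble_states(
    net: ReactionNetwork,
    init_states: np.ndarray,
    times_min,
    seed: int,
    x: float = 0.0,
) -> np.ndarray:
    """States of n independent runs at the requested times: (n, T, N) array.

    Run ``i`` starts from ``init_states[i]``; per-run streams are derived from
    ``seed`` so the whole ensemble is reproducible bit-for-bit.
    """
    init_states = np.asarray(init_states, dtype=np.int64)
    if init_states.ndim != 2:
        raise ValueError("init_states must be (n_runs, N)")
    times_s = np.asarray(times_min, dtype=float) * SECONDS_PER_MINUTE
    arrays = net.compile_arrays(x)
    seeds = np.random.SeedSequence(seed).generate_state(init_states.shape[0]) % (2**31 - 1)
    out = np.zeros((init_states.shape[0], times_s.size, net.n_species), dtype=np.int64)
    for i in range(init_states.shape[0]):
        out[i] = _states_at_times(*arrays, init_states[i], times_s, int(seeds[i]))
    return out


def max_normalized_distance(sample: np.ndarray, law, bandwidth: float | None = None) -> float:
    """Sup distance between max-normalized empirical and model distributions.

    Both curves are smoothed with the same Gaussian kernel (default bandwidth
    half the model SD) before max-normalization, so kernel bias cancels and
    only genuine shape/location disagreement plus residual sampling noise
    remains - the comparison used for the simulation-versus-moments figures.
    ``law`` is a scalar DistributionModel.
    """
    sample = np.asarray(sample, dtype=float)
    sd = max(law.sd, sample.std(), 1.0)
    bw = bandwidth if bandwidth is not None else sd / 2.0
    lo = min(sample.min(), law.mu - 6.0 * sd) - 2.0 * bw
    hi = max(sample.max(), law.mu + 6.0 * sd) + 2.0 * bw
    grid = np.linspace(lo, hi, 600)
    # empirical kernel density
    z = (grid[:, None] - sample[None, :]) / bw
    f_emp = np.exp(-0.5 * z**2).sum(axis=1)
    # model law convolved with the same kernel
    ks = np.arange(0, int(law.mu + 10.0 * sd) + 2)
    p = law.pmf_integer(ks)
    zk = (grid[:, None] - ks[None, :]) / bw
    f_mod = (np.exp(-0.5 * zk**2) * p[None, :]).sum(axis=1)
    return float(np.abs(f_emp / f_emp.max() - f_mod / f_mod.max()).max())


def ensemble_summary(
    net: ReactionNetwork,
    init_states: np.ndarray,
    times_min,
    seed: int,
    x: float = 0.0,
):
    """Empirical moment trajectory plus max-normalized histograms.

    Returns ``(trajectory, histograms)`` where ``histograms[(species, t_min)]``
    is a ``(values, p_over_pmax)`` pair of integer support and the histogram
    normalized by its maximum, the form used for distribution comparisons.
    """
    if np.asarray(init_states).shape[0] < 2:
        raise ValueError("ensemble needs n_runs >= 2")
    times_min = np.asarray(times_min, dtype=float)
    X = ensemble_states(net, init_states, times_min, seed, x)
    states = []
    hists = {}
    for k, tm in enumerate(times_min):
        sample = X[:, k, :].astype(float)
        mean = sample.mean(axis=0)
        cov = np.cov(sample, rowvar=False)
        states.append(MomentState(tm, mean, np.atleast_2d(cov)))
        for s_idx, name in enumerate(net.species):
            vals, counts = np.unique(X[:, k, s_idx], return_counts=True)
            hists[(name, tm)] = (vals, counts / counts.max())
    return MomentTrajectory(states), hists
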