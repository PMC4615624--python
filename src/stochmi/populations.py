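"""Initial-condition regimes for the population-versus-single-cell comparisons.

A population carrying a slow global variable G decomposes into subpopulations
conditioned on G.  The regimes used throughout:

* S1, S2, S3 - homogeneous point states (zero covariance) with G at its mean
  gbar, gbar - sqrt(gbar) and gbar + sqrt(gbar) respectively, and every other
  species at its conditional stationary mean given that G;
* Sg - G pinned at gbar but the other species carrying their conditional
  stationary (intrinsic) covariance;
* heterogeneous - the full stationary population including G fluctuations.

The G-conditioning grid carries the stationary law of G (Poisson with mean
gbar) on integer support, which is what turns conditional-MI computations
into expectations over subpopulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.integrate import solve_ivp
from scipy.linalg import solve_continuous_lyapunov
from scipy.optimize import root

from . import distributions
from .models import GlobalVariableSpec, ReactionNetwork
from .moments import MomentState, stationary_moments

__all__ = ["InitialCondition", "GConditioningGrid", "make_initial", "conditional_stationary", "g_grid"]

KINDS = ("S1", "S2", "S3", "Sg", "heterogeneous")


@dataclass
class InitialCondition:
    """A named initial regime realized as a moment state (plus SSA recipe)."""

    kind: str
    state: MomentState
    net: ReactionNetwork

    def sample_states(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Integer initial states for SSA runs.

        Point regimes replicate the rounded mean.  Spread regimes draw each
        species from its stationary marginal law (negative binomial / normal /
        Poisson by the family rule) conditioned on a sampled G; cross-species
        intrinsic correlations are not reproduced by this recipe, which is the
        documented sampling scheme.
        """
        mean, cov = self.state.mean, self.state.cov
        if not np.any(np.diag(cov) > 0):
            return np.tile(np.round(mean).astype(np.int64), (n, 1))
        gspec = self.net.global_spec
        if self.kind == "heterogeneous" and gspec is not None:
            gi = self.net.species_index("G")
            gs = rng.poisson(gspec.gbar, size=n)
            out = np.zeros((n, self.net.n_species), dtype=np.int64)
            for g in np.unique(gs):
                sel = np.where(gs == g)[0]
                cond = conditional_stationary(self.net, float(g))
                out[sel] = _sample_marginals(cond, sel.size, rng)
                out[sel, gi] = g
            return out
        return _sample_marginals(self.state, n, rng)


def _sample_marginals(state: MomentState, n: int, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros((n, state.mean.size), dtype=np.int64)
    for k in range(state.mean.size):
        mu, C = float(state.mean[k]), float(state.cov[k, k])
        if C <= 0:
            out[:, k] = int(round(mu))
            continue
        d = distributions.from_moments(mu, C)
        if d.family == "normal":
            out[:, k] = np.maximum(np.round(rng.normal(mu, np.sqrt(C), size=n)), 0).astype(np.int64)
        elif d.family == "negative-binomial":
            r = mu**2 / (C - mu)
            out[:, k] = rng.negative_binomial(r, mu / C, size=n)
        else:
            out[:, k] = rng.poisson(mu, size=n)
    return out


_COND_CACHE: dict = {}


def _net_key(net: ReactionNetwork) -> tuple:
    g = net.global_spec
    return (
        net.model,
        tuple(sorted(net.params.items())),
        net.adh1_estradiol_dependence,
        None if g is None else (g.beta_g, g.gamma_g, g.coupled),
    )


def conditional_stationary(net: ReactionNetwork, g: float, x: float = 0.0) -> MomentState:
    """Stationary moments of the network with G pinned at ``g``.

    The G birth/death reactions are frozen, the remaining mean equations are
    solved at fixed G = g, and the conditional covariance comes from the
    Lyapunov equation of the reduced (G-free) affine flow; G carries zero
    variance in the returned state.  Results are memoized per (network, g, x).
    """
    if net.global_spec is None:
        raise ValueError("network has no global variable to condition on")
    key = (_net_key(net), float(g), float(x))
    hit = _COND_CACHE.get(key)
    if hit is not None:
        return MomentState(0.0, hit.mean.copy(), hit.cov.copy())
    pinned = net.pin_global()
    gi = net.species_index("G")
    n = net.n_species
    free = np.array([i for i in range(n) if i != gi])
    S = pinned.stoich_matrix

    def embed(zr: np.ndarray) -> np.ndarray:
        z = np.empty(n)
        z[gi] = g
        z[free] = zr
        return z

    def fun(zr):
        return (S.T @ pinned.propensities(embed(zr), x))[free]

    def jac(zr):
        A = S.T @ pinned.propensity_jacobian(embed(zr), x)
        return A[np.ix_(free, free)]

    # a direct root solve from zero usually lands on the (unique) fixed point;
    # fall back to relaxation integration when it does not
    zr = np.zeros(free.size)
    res = root(fun, zr, jac=jac, method="hybr", tol=1e-13)
    good = res.success and np.all(res.x >= -1e-6)
    if good:
        zr = res.x
    else:
        T = 1e6
        for _ in range(8):
            sol = solve_ivp(
                lambda t, v: fun(v), (0.0, T), zr, method="LSODA", rtol=1e-10, atol=1e-12
            )
            if not sol.success:
                raise RuntimeError(f"conditional stationary warm start failed: {sol.message}")
            zr = sol.y[:, -1]
            if np.linalg.norm(fun(zr)) / max(np.linalg.norm(zr), 1.0) < 1e-12:
                break
            T *= 10.0
        res = root(fun, zr, jac=jac, method="hybr", tol=1e-13)
        if res.success:
            zr = res.x
    zr = np.maximum(zr, 0.0)

    z = embed(zr)
    a = pinned.propensities(z, x)
    A_full = S.T @ pinned.propensity_jacobian(z, x)
    B_full = (S.T * a) @ S
    A_rr = A_full[np.ix_(free, free)]
    B_rr = B_full[np.ix_(free, free)]
    C_rr = solve_continuous_lyapunov(A_rr, -B_rr)
    C = np.zeros((n, n))
    C[np.ix_(free, free)] = 0.5 * (C_rr + C_rr.T)
    state = MomentState(0.0, z, C)
    _COND_CACHE[key] = state
    return MomentState(0.0, state.mean.copy(), state.cov.copy())


def make_initial(kind: str, net: ReactionNetwork, x: float = 0.0) -> InitialCondition:
    """Realize one of the initial regimes on ``net`` (input held at ``x``)."""
    if kind not in KINDS:
        raise ValueError(f"kind must be one of {KINDS}, got {kind!r}")
    gspec = net.global_spec
    if gspec is None:
        if kind == "S1":
            st = stationary_moments(net, x)
            state = MomentState.point(st.mean)
        elif kind == "heterogeneous":
            state = stationary_moments(net, x)
        else:
            raise ValueError(f"state {kind} requires a network with a global variable")
        return InitialCondition(kind, state, net)

    gbar = gspec.gbar
    if kind in ("S1", "S2", "S3"):
        g0 = {"S1": gbar, "S2": gbar - np.sqrt(gbar), "S3": gbar + np.sqrt(gbar)}[kind]
        cond = conditional_stationary(net, g0, x)
        state = MomentState.point(cond.mean)
    elif kind == "Sg":
        state = conditional_stationary(net, gbar, x)
    else:
        state = stationary_moments(net, x)
    return InitialCondition(kind, state, net)


@dataclass
class GConditioningGrid:
    """Integer G nodes with stationary Poisson(gbar) weights."""

    gs: np.ndarray
    weights: np.ndarray
    gbar: float

    def mean(self) -> float:
        return float(self.gs @ self.weights)


def g_grid(
    gspec: GlobalVariableSpec,
    n_nodes: int | None = None,
    coverage: float = 1.0 - 1e-9,
) -> GConditioningGrid:
    """Quadrature grid over the stationary law of G.

    The full grid keeps every integer G covering at least ``coverage`` of the
    Poisson(gbar) mass; when ``n_nodes`` is given, the nodes with the largest
    weights are kept (ties broken toward gbar) and weights renormalized.  A
    single node degenerates to the S1 state G = round(gbar).
    """
    gbar = gspec.gbar
    law = stats.poisson(gbar)
    tail = 0.5 * (1.0 - coverage)
    lo = int(law.ppf(tail))
    hi = int(law.isf(tail)) + 1
    gs = np.arange(lo, hi + 1)
    w = law.pmf(gs)
    if n_nodes is not None:
        if n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        order = sorted(range(gs.size), key=lambda i: (-w[i], abs(gs[i] - gbar)))
        keep = np.sort(np.array(order[: min(n_nodes, gs.size)]))
        gs, w = gs[keep], w[keep]
    return GConditioningGrid(gs=gs, weights=w / w.sum(), gbar=gbar)
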