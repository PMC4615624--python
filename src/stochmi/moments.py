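"""First-two-moment (locally affine) approximation of the chemical master equation.

Propensities are expanded to first order about the instantaneous mean z(t),

    a_j(y) ~ a_j(z) + grad a_j|_z . (y - z),

which closes the moment hierarchy: the means follow the deterministic rate
equations dz_k/dt = sum_j nu_jk a_j(z) and the covariance matrix C obeys the
linear flow dC/dt = A C + C A^T + B with A = S^T J(z) and the diffusion
matrix B = S^T diag(a(z)) S, where S stacks the stoichiometric change vectors
and J is the propensity Jacobian.  For networks whose propensities are affine
in the state this closure is exact.

Times at the public surface are minutes; integration runs in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.linalg import solve_continuous_lyapunov
from scipy.optimize import root

from .models import ReactionNetwork, SECONDS_PER_MINUTE

__all__ = [
    "MomentState",
    "MomentTrajectory",
    "linearize_propensities",
    "integrate_moments",
    "stationary_moments",
]

#: default integrator tolerances; the rate constants span roughly six orders
#: of magnitude (gamma_g = 3e-8 /s against theta_y1 = 1.5 /s) so a stiff
#: solver with tight tolerances is used throughout.
RTOL = 1e-8
ATOL = 1e-10


@dataclass
class MomentState:
    """Mean vector (molecules) and covariance matrix (molecules^2) at a time."""

    t_min: float
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        n = self.mean.shape[0]
        if self.cov.shape != (n, n):
            raise ValueError(f"covariance shape {self.cov.shape} != ({n}, {n})")

    @property
    def var(self) -> np.ndarray:
        return np.diag(self.cov).copy()

    def symmetrized(self) -> "MomentState":
        return MomentState(self.t_min, self.mean.copy(), 0.5 * (self.cov + self.cov.T))

    @classmethod
    def point(cls, mean, t_min: float = 0.0) -> "MomentState":
        mean = np.asarray(mean, dtype=float)
        return cls(t_min, mean, np.zeros((mean.size, mean.size)))


@dataclass
class MomentTrajectory:
    """Ordered sequence of moment states at strictly increasing times."""

    states: list[MomentState]

    def __post_init__(self):
        t = self.times
        if np.any(np.diff(t) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.t_min for s in self.states])

    @property
    def means(self) -> np.ndarray:
        return np.array([s.mean for s in self.states])

    @property
    def covs(self) -> np.ndarray:
        return np.array([s.cov for s in self.states])

    def at(self, t_min: float) -> MomentState:
        i = int(np.argmin(np.abs(self.times - t_min)))
        if not np.isclose(self.times[i], t_min):
            raise KeyError(f"time {t_min} min not in trajectory (have {self.times})")
        return self.states[i]

    def to_frame(self, net: ReactionNetwork) -> pd.DataFrame:
        """Tidy per-species means/variances: (time_min, species, mean, variance)."""
        rows = []
        for s in self.states:
            for k, name in enumerate(net.species):
                rows.append((s.t_min, name, s.mean[k], s.cov[k, k]))
        return pd.DataFrame(rows, columns=["time_min", "species", "mean", "variance"])

    def cov_frame(self, net: ReactionNetwork) -> pd.DataFrame:
        """Tidy covariance pairs: (time_min, species_i, species_j, covariance)."""
        rows = []
        for s in self.states:
            for i, ni in enumerate(net.species):
                for j in range(i, net.n_species):
                    rows.append((s.t_min, ni, net.species[j], s.cov[i, j]))
        return pd.DataFrame(rows, columns=["time_min", "species_i", "species_j", "covariance"])


def linearize_propensities(net: ReactionNetwork, z: np.ndarray, x: float = 0.0):
    """Propensity values and exact analytic gradients at the mean ``z``.

    Negative mean components are clipped to zero before evaluation (the state
    itself is never altered).  Returns ``(a, J)`` with shapes (M,) and (M, N).
    """
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError(f"non-finite mean vector {z!r}")
    return net.propensities(z, x), net.propensity_jacobian(z, x)


def _rhs_factory(net: ReactionNetwork, x: float):
    n = net.n_species
    S = net.stoich_matrix  # (M, N)

    def rhs(t, state):
        z = state[:n]
        C = state[n:].reshape(n, n)
        a, J = linearize_propensities(net, z, x)
        dz = S.T @ a
        A = S.T @ J
        B = (S.T * a) @ S
        dC = A @ C + C @ A.T + B
        return np.concatenate([dz, dC.ravel()])

    return rhs


def _integrate_split(net, init, t_sec, x, rtol, atol):
    """Two-stage integration: means first, then the covariance flow.

    The closure means do not depend on C, and given z(t) the covariance obeys
    a linear matrix ODE dC/dt = A(t) C + C A(t)^T + B(t) whose Jacobian
    (A (+) A in Kronecker form) is exact - handing it to the stiff integrator
    avoids the step-size collapse a naive joint integration exhibits when
    fast activation modes coexist with slow synthesis rates.
    """
    n = net.n_species
    S = net.stoich_matrix
    eye = np.eye(n)

    def z_rhs(t, z):
        return S.T @ net.propensities(z, x)

    def z_jac(t, z):
        return S.T @ net.propensity_jacobian(z, x)

    sol_z = solve_ivp(
        z_rhs,
        (t_sec[0], t_sec[-1]),
        init.mean,
        method="LSODA",
        jac=z_jac,
        dense_output=True,
        rtol=rtol,
        atol=atol,
    )
    if not sol_z.success:
        raise RuntimeError(
            f"mean integration failed at t = {sol_z.t[-1] / SECONDS_PER_MINUTE:.3f} min: "
            f"{sol_z.message}"
        )

    def c_rhs(t, c):
        z = sol_z.sol(t)
        a, J = linearize_propensities(net, z, x)
        A = S.T @ J
        B = (S.T * a) @ S
        C = c.reshape(n, n)
        return (A @ C + C @ A.T + B).ravel()

    def c_jac(t, c):
        A = S.T @ net.propensity_jacobian(sol_z.sol(t), x)
        return np.kron(A, eye) + np.kron(eye, A)

    # once the means have settled the covariance flow is linear and
    # time-invariant; switching to its closed form there avoids marching the
    # stiff integrator across astronomically long horizons
    def drift(t):
        z = sol_z.sol(t)
        return np.linalg.norm(z_rhs(t, z)) / (np.linalg.norm(z) + 1.0)

    t0, t_end = t_sec[0], t_sec[-1]
    t_settle = np.inf
    if t_end > t0:
        for probe in np.geomspace(max(t0, 1.0) + 1.0, t_end, 24):
            if drift(probe) < 1e-13:
                t_settle = probe
                break

    eval_direct = [t for t in t_sec[1:] if t <= t_settle]
    eval_lti = [t for t in t_sec[1:] if t > t_settle]
    t_stop = t_settle if eval_lti else (eval_direct[-1] if eval_direct else t0)

    # absolute tolerance for covariances scales with the state magnitude:
    # stationary variances here are O(mean), so anchor atol to the means
    c_scale = max(float(np.max(np.abs(init.cov))), float(np.max(np.abs(init.mean))), 1.0)
    cols = []
    c_last = init.cov.ravel()
    if t_stop > t0:
        sol_c = solve_ivp(
            c_rhs,
            (t0, t_stop),
            init.cov.ravel(),
            method="BDF",
            jac=c_jac,
            t_eval=eval_direct + ([t_stop] if eval_lti else []),
            rtol=0.1 * rtol,  # BDF needs a modest margin to deliver rtol overall
            atol=max(0.1 * atol, 0.01 * rtol * c_scale),
        )
        if not sol_c.success:
            raise RuntimeError(
                f"covariance integration failed at t = {sol_c.t[-1] / SECONDS_PER_MINUTE:.3f}"
                f" min: {sol_c.message}"
            )
        cols = [sol_c.y[:, k] for k in range(len(eval_direct))]
        c_last = sol_c.y[:, -1]
    else:
        cols = [init.cov.ravel() for _ in eval_direct]

    if eval_lti:
        from scipy.linalg import expm

        z_inf = sol_z.sol(t_stop)
        a, J = linearize_propensities(net, z_inf, x)
        A = S.T @ J
        B = (S.T * a) @ S
        # pinned/frozen species (zero stoichiometry column) carry no dynamics;
        # the closed form acts on the active block (their cross-covariances
        # are zero in every pinned regime this path serves)
        active = np.where(np.any(S != 0, axis=0))[0]
        Aa = A[np.ix_(active, active)]
        Ba = B[np.ix_(active, active)]
        C_a_inf = solve_continuous_lyapunov(Aa, -Ba)
        C_last = c_last.reshape(n, n)
        C_dev = C_last[np.ix_(active, active)] - C_a_inf
        for t in eval_lti:
            E = expm(Aa * (t - t_stop))
            C_full = C_last.copy()
            C_full[np.ix_(active, active)] = C_a_inf + E @ C_dev @ E.T
            cols.append(C_full.ravel())

    z_out = np.column_stack([sol_z.sol(t) for t in t_sec[1:]])
    return z_out, np.column_stack(cols)


def integrate_moments(
    net: ReactionNetwork,
    init: MomentState,
    times_min,
    x: float = 0.0,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> MomentTrajectory:
    """Integrate the coupled mean/covariance ODEs at fixed step amplitude ``x``.

    ``times_min`` are the requested output times in minutes; the first entry
    is where ``init`` applies.  Raises with a diagnostic (time reached) if the
    stiff integrator fails.
    """
    times_min = np.asarray(times_min, dtype=float)
    if times_min.ndim != 1 or times_min.size < 1:
        raise ValueError("need at least one output time")
    if np.any(np.diff(times_min) <= 0):
        raise ValueError("output times must be strictly increasing")
    n = net.n_species
    if init.mean.shape[0] != n:
        raise ValueError(f"initial condition has {init.mean.shape[0]} species, network has {n}")

    t_sec = times_min * SECONDS_PER_MINUTE
    states = [MomentState(times_min[0], init.mean.copy(), init.cov.copy()).symmetrized()]
    if times_min.size > 1:
        z_out, c_out = _integrate_split(net, init, t_sec, x, rtol, atol)
        for k, tm in enumerate(times_min[1:]):
            C = c_out[:, k].reshape(n, n)
            states.append(MomentState(tm, z_out[:, k], C).symmetrized())
    return MomentTrajectory(states)


def _slowest_rate(A: np.ndarray) -> float:
    ev = np.linalg.eigvals(A)
    rates = -ev.real
    rates = rates[rates > 0]
    return float(rates.min()) if rates.size else 1e-6


def stationary_moments(
    net: ReactionNetwork,
    x: float = 0.0,
    method: str = "direct",
    guess: MomentState | None = None,
    tol: float = 1e-9,
) -> MomentState:
    """Stationary mean and covariance of the moment closure at input ``x``.

    method="direct" (default): integrate the means to a warm start, polish the
    fixed point of the rate equations by root finding, then obtain the
    stationary covariance from the continuous Lyapunov equation
    A C + C A^T + B = 0 of the affine-closure flow.

    method="integrate": integrate means and covariances together until the
    relative time derivatives fall below ``tol`` (per second), capping at
    ten times the slowest relaxation time.
    """
    n = net.n_species
    S = net.stoich_matrix
    z0 = guess.mean if guess is not None else np.zeros(n)
    C0 = guess.cov if guess is not None else np.zeros((n, n))

    def mean_rhs(t, z):
        return S.T @ net.propensities(z, x)

    def mean_fun(z):
        return S.T @ net.propensities(z, x)

    def mean_jac(z):
        return S.T @ net.propensity_jacobian(z, x)

    # direct root solve first; relax the means over progressively longer
    # horizons only when it fails or lands outside the physical orthant
    z = np.asarray(z0, dtype=float)
    res = root(mean_fun, z, jac=mean_jac, method="hybr", tol=1e-13)
    if res.success and np.all(res.x >= -1e-6):
        z = res.x
    else:
        T = 1e6
        for _ in range(8):
            sol = solve_ivp(mean_rhs, (0.0, T), z, method="LSODA", rtol=1e-10, atol=1e-12)
            if not sol.success:
                raise RuntimeError(f"stationary warm start failed: {sol.message}")
            z = sol.y[:, -1]
            rel = np.linalg.norm(mean_fun(z)) / max(np.linalg.norm(z), 1.0)
            if rel < 1e-12:
                break
            T *= 10.0
        res = root(mean_fun, z, jac=mean_jac, method="hybr", tol=1e-13)
        if res.success:
            z = res.x
    z = np.maximum(z, 0.0)

    a, J = linearize_propensities(net, z, x)
    A = S.T @ J
    B = (S.T * a) @ S

    if method == "direct":
        C = solve_continuous_lyapunov(A, -B)
        C = 0.5 * (C + C.T)
        resid = np.abs(A @ C + C @ A.T + B).max()
        scale = max(np.abs(B).max(), 1e-30)
        if resid > 1e-6 * scale:
            raise RuntimeError(f"Lyapunov residual {resid:.3e} too large (scale {scale:.3e})")
        return MomentState(0.0, z, C)

    if method == "integrate":
        slow = _slowest_rate(A)
        horizon = 10.0 / slow
        state = MomentState(0.0, np.asarray(z0, dtype=float), np.asarray(C0, dtype=float))
        rhs = _rhs_factory(net, x)
        t_now, y = 0.0, np.concatenate([state.mean, state.cov.ravel()])
        chunk = horizon / 16.0
        while t_now < horizon:
            sol = solve_ivp(rhs, (t_now, t_now + chunk), y, method="LSODA", rtol=RTOL, atol=ATOL)
            if not sol.success:
                raise RuntimeError(
                    f"stationary integration failed at t = {sol.t[-1]:.3e} s: {sol.message}"
                )
            t_now, y = sol.t[-1], sol.y[:, -1]
            d = rhs(t_now, y)
            dz, dC = d[:n], d[n:]
            rel_z = np.linalg.norm(dz) / max(np.linalg.norm(y[:n]), 1.0)
            rel_C = np.linalg.norm(dC) / max(np.linalg.norm(y[n:]), 1.0)
            if rel_z < tol and rel_C < tol:
                break
        else:
            raise RuntimeError(
                f"no stationary point within 10 slowest relaxation times "
                f"(rel. mean drift {rel_z:.2e}, rel. cov drift {rel_C:.2e})"
            )
        return MomentState(0.0, y[:n], y[n:].reshape(n, n)).symmetrized()

    raise ValueError(f"unknown method {method!r}")
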