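"""Time-dependent mutual information between step inputs and network readouts.

The channel is the map from a step amplitude x+ (drawn uniformly over the
dose range) to a snapshot measurement y at time t.  Conditional output laws
p(y, t | x+) are reconstructed from propagated first/second moments through
the negative-binomial/normal family rule; between sampled doses the moments
are linearly interpolated, and the continuous uniform input is realized as a
fine interpolated dose grid (501 points by default, refinable).  All
information quantities are reported in bits.

Scalar (copy-number) observables are evaluated on their natural integer
support, so the mutual information is that of the discrete molecular channel;
joint observables use multivariate-normal conditionals with Gauss-Hermite
quadrature per dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import distributions
from .models import ReactionNetwork
from .moments import MomentState, MomentTrajectory, integrate_moments
from .populations import GConditioningGrid, InitialCondition, conditional_stationary, g_grid

__all__ = [
    "DoseResponseSurface",
    "MIResult",
    "build_surface",
    "surface_from_samples",
    "mutual_information",
    "mi_curve",
    "joint_mi",
    "choose_N",
    "converged_n",
    "expected_conditional_mi",
    "joint_mi_slow_variable",
    "conditional_mi_given_input",
    "add_measurement_background",
    "equalize_reporter_means",
]

LOG2 = math.log(2.0)
#: fine-grid resolution realizing the continuous uniform input distribution
N_DOSE_GRID = 501
#: one-molecule variance floor applied to multivariate-normal conditionals;
#: copy numbers below this granularity are not distinguishable measurements
VAR_FLOOR = 1.0


# ---------------------------------------------------------------------------
# Dose-response surfaces
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseSurface:
    """Observable moments on a (dose, time) grid with linear interpolation."""

    doses: np.ndarray  # (D,) sorted ascending
    times: np.ndarray  # (T,) minutes
    observables: tuple[str, ...]  # K names
    means: np.ndarray  # (D, T, K)
    covs: np.ndarray  # (D, T, K, K)
    conditioning: str = "population"

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        if np.any(np.diff(self.doses) <= 0):
            raise ValueError("doses must be sorted strictly ascending")
        if not (np.all(np.isfinite(self.means)) and np.all(np.isfinite(self.covs))):
            raise ValueError("surface moments must be finite")

    def time_index(self, t_min: float) -> int:
        i = int(np.argmin(np.abs(self.times - t_min)))
        if not np.isclose(self.times[i], t_min):
            raise KeyError(f"time {t_min} min not on surface (have {self.times})")
        return i

    def interpolate(self, x: float, t_min: float):
        """(mu, C) at an arbitrary dose inside the sampled range."""
        if x < self.doses[0] or x > self.doses[-1]:
            raise ValueError(f"dose {x} outside sampled range [{self.doses[0]}, {self.doses[-1]}]")
        ti = self.time_index(t_min)
        j = int(np.searchsorted(self.doses, x, side="right"))
        j = min(max(j, 1), self.doses.size - 1)
        x0, x1 = self.doses[j - 1], self.doses[j]
        w = (x - x0) / (x1 - x0)
        mu = (1 - w) * self.means[j - 1, ti] + w * self.means[j, ti]
        C = (1 - w) * self.covs[j - 1, ti] + w * self.covs[j, ti]
        return mu, C

    def fine_grid(self, t_min: float, n_grid: int = N_DOSE_GRID):
        """Moments on a uniform dose grid spanning the sampled range."""
        ti = self.time_index(t_min)
        xs = np.linspace(self.doses[0], self.doses[-1], n_grid)
        K = len(self.observables)
        mus = np.empty((n_grid, K))
        covs = np.empty((n_grid, K, K))
        for a in range(K):
            mus[:, a] = np.interp(xs, self.doses, self.means[:, ti, a])
            for b in range(K):
                covs[:, a, b] = np.interp(xs, self.doses, self.covs[:, ti, a, b])
        return xs, mus, covs

    def subset(self, observables) -> "DoseResponseSurface":
        idx = [self.observables.index(o) for o in observables]
        return replace(
            self,
            observables=tuple(observables),
            means=self.means[:, :, idx],
            covs=self.covs[:, :, idx][:, :, :, idx],
        )


@dataclass
class MIResult:
    """MI values (bits) over time for one conditioning and observable subset."""

    times: np.ndarray
    bits: np.ndarray
    conditioning: str
    observables: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.times,
                "conditioning": self.conditioning,
                "observables": "+".join(self.observables),
                "bits": self.bits,
            }
        )


def build_surface(
    net: ReactionNetwork,
    doses,
    times_min,
    init: InitialCondition | MomentState,
    observables,
    conditioning: str | None = None,
) -> DoseResponseSurface:
    """Propagate moments from ``init`` for every dose and collect observables.

    The input steps on at t = 0, so the first requested time should be 0 and
    its row is dose-independent by construction.
    """
    doses = np.sort(np.asarray(doses, dtype=float))
    if doses.size < 2:
        raise ValueError("need at least 2 doses")
    times_min = np.asarray(times_min, dtype=float)
    if isinstance(init, InitialCondition):
        state, tag = init.state, init.kind
    else:
        state, tag = init, "custom"
    obs_idx = [net.species_index(o) for o in observables]
    D, T, K = doses.size, times_min.size, len(obs_idx)
    means = np.empty((D, T, K))
    covs = np.empty((D, T, K, K))
    for di, x in enumerate(doses):
        try:
            traj = integrate_moments(net, state, times_min, x=x)
        except RuntimeError as err:
            raise RuntimeError(f"moment propagation failed at dose {x} nM: {err}") from err
        for ti, s in enumerate(traj.states):
            means[di, ti] = s.mean[obs_idx]
            covs[di, ti] = s.cov[np.ix_(obs_idx, obs_idx)]
    return DoseResponseSurface(
        doses, times_min, tuple(observables), means, covs, conditioning or tag
    )


def surface_from_samples(
    table: pd.DataFrame,
    channels=("y2",),
    dose_col: str = "dose_nM",
    time_col: str = "time_min",
) -> DoseResponseSurface:
    """Sample-moment surface from a per-cell table (synthetic cytometry)."""
    doses = np.sort(table[dose_col].unique())
    times = np.sort(table[time_col].unique())
    K = len(channels)
    means = np.zeros((doses.size, times.size, K))
    covs = np.zeros((doses.size, times.size, K, K))
    for di, d in enumerate(doses):
        for ti, t in enumerate(times):
            sub = table[(table[dose_col] == d) & (table[time_col] == t)][list(channels)].to_numpy()
            means[di, ti] = sub.mean(axis=0)
            covs[di, ti] = np.atleast_2d(np.cov(sub, rowvar=False))
    return DoseResponseSurface(doses, times, tuple(channels), means, covs, "samples")


# ---------------------------------------------------------------------------
# Scalar MI on integer support
# ---------------------------------------------------------------------------


def _integer_pmf_matrix(mus: np.ndarray, variances: np.ndarray):
    """(D, Y) conditional probabilities on a shared integer support."""
    sds = np.sqrt(np.maximum(variances, 0.0))
    hi = int(np.ceil((mus + 10.0 * sds).max())) + 10
    if hi > 2_000_000:
        raise ValueError(f"integer support too large ({hi}); rescale the observable")
    support = np.arange(0, hi + 1)
    P = np.zeros((mus.size, support.size))
    for d in range(mus.size):
        law = distributions.from_moments(float(mus[d]), float(variances[d]))
        # each law's mass lives within ~12 sd of its mean; skip the rest
        half = 12.0 * max(np.sqrt(law.C), 1.0) + 5.0
        lo = max(int(law.mu - half), 0)
        hi_d = min(int(law.mu + half) + 1, support.size - 1)
        window = support[lo : hi_d + 1]
        P[d, lo : hi_d + 1] = law.pmf_integer(window)
        tot = P[d].sum()
        if not tot > 0:
            raise ValueError(f"degenerate output law at dose index {d} (mu={mus[d]}, C={variances[d]})")
        P[d] /= tot
    return support, P


def _discrete_mi(P: np.ndarray, weights: np.ndarray) -> float:
    pbar = weights @ P
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(P > 0, P / np.maximum(pbar, 1e-300), 1.0)
        terms = np.where(P > 0, P * np.log2(ratio), 0.0)
    return float(max(weights @ terms.sum(axis=1), 0.0))


def mutual_information(
    surface: DoseResponseSurface,
    t_min: float,
    n_grid: int = N_DOSE_GRID,
    observable: str | None = None,
) -> float:
    """I(x+; y, t) in bits for a scalar observable, uniform input over the range.

    The continuous uniform input is realized as ``n_grid`` equally weighted
    interpolated doses; conditional laws follow the family rule on integer
    support and the output marginal is their mixture.
    """
    surf = surface if observable is None else surface.subset([observable])
    if len(surf.observables) != 1:
        raise ValueError("mutual_information handles one observable; use joint_mi for subsets")
    xs, mus, covs = surf.fine_grid(t_min, n_grid)
    mus, variances = mus[:, 0], covs[:, 0, 0]
    if np.allclose(mus, mus[0]) and np.allclose(variances, variances[0]):
        return 0.0
    if np.all(variances <= 0.0) and not np.allclose(mus, mus[0]):
        raise ValueError(f"zero-variance output laws with distinct means at t = {t_min} min")
    _, P = _integer_pmf_matrix(mus, variances)
    return _discrete_mi(P, np.full(xs.size, 1.0 / xs.size))


def mi_curve(
    surface: DoseResponseSurface,
    n_grid: int = N_DOSE_GRID,
    observable: str | None = None,
) -> MIResult:
    surf = surface if observable is None else surface.subset([observable])
    bits = np.array([mutual_information(surf, t, n_grid) for t in surf.times])
    return MIResult(surf.times.copy(), bits, surf.conditioning, surf.observables)


# ---------------------------------------------------------------------------
# Joint (multivariate) MI via Gauss-Hermite quadrature
# ---------------------------------------------------------------------------


def _floor_covs(covs: np.ndarray, var_floor=VAR_FLOOR) -> np.ndarray:
    """Apply the count-granularity variance floor, preserving correlations.

    ``var_floor`` may be a scalar or a per-dimension vector (a slowly drifting
    conditioning variable needs a much smaller floor than a noisy readout)."""
    covs = covs.copy()
    D, K, _ = covs.shape
    floor = np.broadcast_to(np.asarray(var_floor, dtype=float), (K,))
    for d in range(D):
        sd_old = np.sqrt(np.maximum(np.diag(covs[d]), 0.0))
        sd_new = np.sqrt(np.maximum(np.diag(covs[d]), floor))
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = covs[d] / np.outer(sd_old, sd_old)
        corr[~np.isfinite(corr)] = 0.0
        np.fill_diagonal(corr, 1.0)
        corr = np.clip(corr, -0.999, 0.999)
        np.fill_diagonal(corr, 1.0)
        covs[d] = corr * np.outer(sd_new, sd_new)
    return covs


def _gh_nodes(k: int, order: int):
    x, w = np.polynomial.hermite_e.hermegauss(order)
    w = w / w.sum()
    if k == 1:
        return x[:, None], w
    xs = np.meshgrid(*([x] * k), indexing="ij")
    ws = np.meshgrid(*([w] * k), indexing="ij")
    nodes = np.stack([g.ravel() for g in xs], axis=1)
    weights = np.prod(np.stack([g.ravel() for g in ws], axis=1), axis=1)
    return nodes, weights


def _log_mixture_pdf(points: np.ndarray, mus: np.ndarray, chols: np.ndarray, log_w: np.ndarray):
    """log pbar at ``points`` (P, k) for a mixture of D Gaussians."""
    P, k = points.shape
    D = mus.shape[0]
    out = np.empty(P)
    log_norm = -0.5 * k * math.log(2.0 * math.pi) - np.array(
        [np.log(np.diag(L)).sum() for L in chols]
    )
    chunk = max(1, int(5_000_000 // max(D, 1)))
    inv_chols = np.array([np.linalg.inv(L) for L in chols])  # (D, k, k)
    for s in range(0, P, chunk):
        pts = points[s : s + chunk]  # (p, k)
        diff = pts[:, None, :] - mus[None, :, :]  # (p, D, k)
        z = np.einsum("dkj,pdj->pdk", inv_chols, diff)
        q = np.einsum("pdk,pdk->pd", z, z)
        out[s : s + chunk] = logsumexp(log_w[None, :] + log_norm[None, :] - 0.5 * q, axis=1)
    return out


def _mixture_mi_mvn(
    mus: np.ndarray,
    covs: np.ndarray,
    weights: np.ndarray,
    gh_order: int = 32,
    var_floor: float = VAR_FLOOR,
) -> float:
    """MI of a channel with Gaussian conditionals (any dimension) in bits."""
    covs = _floor_covs(np.atleast_3d(covs), var_floor)
    D, k, _ = covs.shape
    chols = np.linalg.cholesky(covs)
    nodes, node_w = _gh_nodes(k, gh_order)  # (Q, k), (Q,)
    Q = nodes.shape[0]
    pts = mus[:, None, :] + np.einsum("dij,qj->dqi", chols, nodes)  # (D, Q, k)
    log_pbar = _log_mixture_pdf(pts.reshape(D * Q, k), mus, chols, np.log(weights)).reshape(D, Q)
    cross = (log_pbar @ node_w) / LOG2  # E_d[log2 pbar], (D,)
    ent = 0.5 * k * (1.0 + math.log(2.0 * math.pi)) / LOG2 + np.array(
        [np.log(np.diag(L)).sum() for L in chols]
    ) / LOG2  # differential entropies in bits
    return float(max(weights @ (-ent - cross), 0.0))


def joint_mi(
    surface: DoseResponseSurface,
    t_min: float,
    n_grid: int = N_DOSE_GRID,
    gh_order: int = 32,
) -> float:
    """I(x+; [y1 ... yK], t) with multivariate-normal conditionals."""
    xs, mus, covs = surface.fine_grid(t_min, n_grid)
    if np.allclose(mus, mus[0]) and np.allclose(covs, covs[0]):
        return 0.0
    return _mixture_mi_mvn(mus, covs, np.full(xs.size, 1.0 / xs.size), gh_order)


def joint_mi_chain(
    surface: DoseResponseSurface,
    t_min: float,
    n_grid: int = N_DOSE_GRID,
    gh_order: int = 32,
    n_cond_nodes: int = 161,
):
    """Chain-rule decomposition I(x;[y1 y2]) = I(x;y1) + E[I(x;y2|y1)].

    An independent route to the joint MI: the first term is the marginal MI of
    the conditioning observable, the second averages the conditional-channel
    MI over the marginal mixture of y1 using analytic Gaussian conditionals.
    Returns ``(total, marginal_y1, expected_conditional)``.
    """
    if len(surface.observables) != 2:
        raise ValueError("chain decomposition needs exactly two observables")
    xs, mus, covs = surface.fine_grid(t_min, n_grid)
    D = xs.size
    w = np.full(D, 1.0 / D)
    covs = _floor_covs(covs)
    mu1, v1 = mus[:, 0], covs[:, 0, 0]
    i_y1 = _mixture_mi_mvn(mus[:, :1], covs[:, :1, :1], w, gh_order, var_floor=0.0)

    s1 = np.sqrt(v1)
    lo, hi = (mu1 - 8.0 * s1).min(), (mu1 + 8.0 * s1).max()
    y1 = np.linspace(lo, hi, n_cond_nodes)
    dy = y1[1] - y1[0]
    # mixture marginal of y1 and posterior input weights at each node
    log_comp = (
        -0.5 * ((y1[:, None] - mu1[None, :]) ** 2) / v1[None, :]
        - 0.5 * np.log(2.0 * math.pi * v1)[None, :]
        + np.log(w)[None, :]
    )  # (n, D)
    log_p1 = logsumexp(log_comp, axis=1)
    post = np.exp(log_comp - log_p1[:, None])  # (n, D)
    # conditional laws y2 | y1, dose
    slope = covs[:, 0, 1] / v1
    v2c = np.maximum(covs[:, 1, 1] - covs[:, 0, 1] ** 2 / v1, VAR_FLOOR)  # (D,)
    mu2c = mus[None, :, 1] + slope[None, :] * (y1[:, None] - mu1[None, :])  # (n, D)
    s2c = np.sqrt(v2c)
    gx, gw = _gh_nodes(1, gh_order)
    ent = 0.5 * (1.0 + math.log(2.0 * math.pi)) / LOG2 + np.log(s2c) / LOG2  # (D,)
    log_norm2 = -0.5 * np.log(2.0 * math.pi * v2c)  # (D',)
    with np.errstate(divide="ignore"):
        log_post = np.where(post > 0, np.log(post), -np.inf)
    inner = np.empty(n_cond_nodes)
    chunk = max(1, int(2e7 // (D * D * gh_order)))
    for s in range(0, n_cond_nodes, chunk):
        sl = slice(s, min(s + chunk, n_cond_nodes))
        m = mu2c[sl]  # (c, D)
        pts = m[:, :, None] + s2c[None, :, None] * gx[None, None, :, 0]  # (c, D, Q)
        diff = pts[:, :, :, None] - m[:, None, None, :]  # (c, D, Q, D')
        logn = -0.5 * diff**2 / v2c[None, None, None, :] + log_norm2[None, None, None, :]
        log_pbar = logsumexp(logn + log_post[sl][:, None, None, :], axis=3)  # (c, D, Q)
        cross = (log_pbar @ gw) / LOG2  # (c, D)
        inner[sl] = np.einsum("cd,cd->c", post[sl], -ent[None, :] - cross)
    inner = np.maximum(inner, 0.0)
    e_cond = float(np.exp(log_p1) @ inner * dy)
    return i_y1 + e_cond, i_y1, e_cond


# ---------------------------------------------------------------------------
# N-convergence (how many step experiments suffice)
# ---------------------------------------------------------------------------


def converged_n(ns, mis, rel_tol: float = 0.01):
    """Three-point geometric extrapolation of the MI-versus-N sequence.

    For each window (N-2, N-1, N) the convergence ratio
    r = (MI_N - MI_{N-1}) / (MI_{N-1} - MI_{N-2}) extrapolates the bound
    MI_inf = MI_N + r (MI_N - MI_{N-1}) / (1 - r); the first N whose MI lies
    within ``rel_tol`` of MI_inf is accepted.  Returns
    ``(n, mi_inf, converged)``; if no window qualifies the last N is returned
    with ``converged = False``.
    """
    ns = list(ns)
    mis = list(mis)
    if len(ns) < 3 or len(ns) != len(mis):
        raise ValueError("need aligned sequences of at least 3 candidate Ns")
    for k in range(2, len(ns)):
        d1 = mis[k - 1] - mis[k - 2]
        d2 = mis[k] - mis[k - 1]
        if d1 == 0.0 and d2 == 0.0:
            return ns[k], mis[k], True
        if d1 == 0.0:
            continue
        r = d2 / d1
        if abs(r) >= 1.0:
            continue
        mi_inf = mis[k] + d2 * r / (1.0 - r)
        if mi_inf != 0.0 and abs(mis[k] - mi_inf) <= rel_tol * abs(mi_inf):
            return ns[k], mi_inf, True
    return ns[-1], mis[-1], False


def choose_N(
    net: ReactionNetwork,
    init: InitialCondition | MomentState,
    xmax: float,
    t_min: float,
    candidates=range(3, 26),
    observable: str = "Y2",
    ratio: float = 2.0 / 3.0,
    n_grid: int = N_DOSE_GRID,
    rel_tol: float = 0.01,
):
    """Smallest number of sampled step experiments meeting the 1 % criterion.

    Doses for N experiments are the nested geometric series
    xmax * ratio^k (k = 0..N-2) plus a zero dose, so per-dose moment
    propagations are shared across candidates.
    """
    candidates = list(candidates)
    if len(candidates) < 3 or any(b <= a for a, b in zip(candidates, candidates[1:])):
        raise ValueError("candidates must be increasing with at least 3 entries")
    state = init.state if isinstance(init, InitialCondition) else init
    obs = net.species_index(observable)
    n_max = candidates[-1]
    all_doses = sorted({0.0} | {xmax * ratio**k for k in range(n_max - 1)})
    cache: dict[float, tuple[float, float]] = {}
    for x in all_doses:
        traj = integrate_moments(net, state, [0.0, t_min] if t_min > 0 else [0.0], x=x)
        s = traj.states[-1]
        cache[x] = (s.mean[obs], s.cov[obs, obs])
    mis = []
    for n in candidates:
        doses = np.array(sorted({0.0} | {xmax * ratio**k for k in range(n - 1)}))
        mus = np.array([cache[x][0] for x in doses])
        cvs = np.array([cache[x][1] for x in doses])
        surf = DoseResponseSurface(
            doses, np.array([t_min]), (observable,), mus[:, None, None], cvs[:, None, None, None]
        )
        mis.append(mutual_information(surf, t_min, n_grid))
    n_star, mi_inf, ok = converged_n(candidates, mis, rel_tol)
    return {"n": n_star, "mi_inf": mi_inf, "converged": ok, "candidates": candidates, "mi": mis}


# ---------------------------------------------------------------------------
# Conditional-MI machinery (slow-variable decompositions)
# ---------------------------------------------------------------------------


def expected_conditional_mi(
    net: ReactionNetwork,
    doses,
    times_min,
    observable: str = "Y2",
    grid: GConditioningGrid | None = None,
    n_nodes: int | None = 21,
    n_grid: int = N_DOSE_GRID,
    pin: bool = True,
    rtol: float = 1e-8,
) -> MIResult:
    """E over the stationary law of G of the G-conditioned MI, per time.

    Each subpopulation starts from its conditional stationary state and is
    propagated with G pinned (frozen birth/death), which is exact in the
    slow-fluctuation limit the decomposition assumes; ``pin=False`` keeps the
    G dynamics live during propagation instead.
    """
    if net.global_spec is None:
        raise ValueError("expected conditional MI needs a network with a global variable")
    if grid is None:
        grid = g_grid(net.global_spec, n_nodes=n_nodes, coverage=1.0 - 1e-6)
    times_min = np.asarray(times_min, dtype=float)
    prop_net = net.pin_global() if pin else net
    obs = net.species_index(observable)
    total = np.zeros(times_min.size)
    for g, wg in zip(grid.gs, grid.weights):
        cond = conditional_stationary(net, float(g))
        mus = np.zeros((len(doses), times_min.size))
        cvs = np.zeros((len(doses), times_min.size))
        for di, x in enumerate(np.sort(np.asarray(doses, dtype=float))):
            traj = integrate_moments(prop_net, cond, times_min, x=x, rtol=rtol, atol=rtol * 1e-2)
            for ti, s in enumerate(traj.states):
                mus[di, ti] = s.mean[obs]
                cvs[di, ti] = s.cov[obs, obs]
        surf = DoseResponseSurface(
            np.sort(np.asarray(doses, dtype=float)),
            times_min,
            (observable,),
            mus[:, :, None],
            cvs[:, :, None, None],
            f"given-G={g}",
        )
        total += wg * np.array([mutual_information(surf, t, n_grid) for t in times_min])
    return MIResult(times_min, total, "E[conditional|G]", (observable,))


def joint_mi_slow_variable(
    net: ReactionNetwork,
    doses,
    times_min,
    observable: str = "Y2",
    grid: GConditioningGrid | None = None,
    n_nodes: int | None = 21,
    gh_order: int = 24,
    pin: bool = True,
    n_grid: int = 51,
    rtol: float = 1e-8,
) -> MIResult:
    """I(x+; [y, G], t): joint MI over the readout and the global variable.

    The joint conditional p(y, G, t | x) is represented as a mixture over the
    stationary law of G of bivariate normals - each component is locally
    Gaussian while the mixture keeps the curved (y, G) ridge a single
    Gaussian would smear.  With G pinned during propagation (the slow-
    fluctuation idealization, default) the decomposition into the expected
    G-conditioned MI is exact up to quadrature, since G carries no
    information about the input; ``pin=False`` keeps the G dynamics live, in
    which case the drift of G over the experiment makes the recorded G an
    imperfect readout of the cell's state and the joint MI drops below the
    expected conditional MI.
    """
    if net.global_spec is None:
        raise ValueError("requires a network with a global variable")
    if grid is None:
        grid = g_grid(net.global_spec, n_nodes=n_nodes, coverage=1.0 - 1e-6)
    times_min = np.asarray(times_min, dtype=float)
    doses = np.sort(np.asarray(doses, dtype=float))
    obs = net.species_index(observable)
    gi = net.species_index("G")
    idx = np.array([obs, gi])
    D, G, T = doses.size, grid.gs.size, times_min.size
    prop_net = net.pin_global() if pin else net
    mus = np.zeros((D, G, T, 2))
    covs = np.zeros((D, G, T, 2, 2))
    for ki, g in enumerate(grid.gs):
        cond = conditional_stationary(net, float(g))
        for di, x in enumerate(doses):
            traj = integrate_moments(prop_net, cond, times_min, x=x, rtol=rtol, atol=rtol * 1e-2)
            for ti, s in enumerate(traj.states):
                mus[di, ki, ti] = s.mean[idx]
                covs[di, ki, ti] = s.cov[np.ix_(idx, idx)]
    # realize the continuous uniform input on an interpolated dose grid,
    # exactly as the scalar pipeline does (the identity holds per channel)
    xs = np.linspace(doses[0], doses[-1], n_grid)
    mus_f = np.empty((n_grid, G, T, 2))
    covs_f = np.empty((n_grid, G, T, 2, 2))
    for ki in range(G):
        for ti in range(T):
            for a in range(2):
                mus_f[:, ki, ti, a] = np.interp(xs, doses, mus[:, ki, ti, a])
                for b in range(2):
                    covs_f[:, ki, ti, a, b] = np.interp(xs, doses, covs[:, ki, ti, a, b])
    w_x = np.full(n_grid, 1.0 / n_grid)
    bits = np.empty(T)
    for ti in range(T):
        if np.allclose(mus_f[:, :, ti], mus_f[0, :, ti]):
            bits[ti] = 0.0
            continue
        bits[ti] = _mixture_channel_mi(
            mus_f[:, :, ti], covs_f[:, :, ti], grid.weights, w_x, gh_order,
            var_floor=(VAR_FLOOR, 1e-4),
        )
    return MIResult(times_min, bits, "joint(y,G)", (observable, "G"))


def _mixture_channel_mi(mus, covs, w_comp, w_x, gh_order: int, var_floor=VAR_FLOOR) -> float:
    """MI of a channel whose conditionals are Gaussian mixtures.

    ``mus``/``covs`` have shape (D, G, k)/(D, G, k, k): per input symbol d a
    mixture over components g with fixed weights ``w_comp``.
    """
    D, G, k = mus.shape
    flat_mus = mus.reshape(D * G, k)
    flat_covs = _floor_covs(covs.reshape(D * G, k, k), var_floor)
    chols = np.linalg.cholesky(flat_covs)
    nodes, node_w = _gh_nodes(k, gh_order)
    pts = flat_mus[:, None, :] + np.einsum("dij,qj->dqi", chols, nodes)  # (D*G, Q, k)
    Q = nodes.shape[0]
    points = pts.reshape(D * G * Q, k)
    # log p(y | x = d) for every d, and log pbar(y), at all points
    log_wc = np.log(w_comp)
    log_cond = np.empty((points.shape[0], D))
    for d in range(D):
        sl = slice(d * G, (d + 1) * G)
        log_cond[:, d] = _log_mixture_pdf(points, flat_mus[sl], chols[sl], log_wc)
    log_pbar = logsumexp(np.log(w_x)[None, :] + log_cond, axis=1)
    # E_{y ~ p(.|d)} [ log2 p(y|d) - log2 pbar(y) ] via the GH nodes of d's own components
    diff = (log_cond[np.arange(points.shape[0]), np.repeat(np.arange(D), G * Q)] - log_pbar) / LOG2
    diff = diff.reshape(D, G, Q)
    per_symbol = np.einsum("g,dgq,q->d", w_comp, diff, node_w)
    return float(max(w_x @ per_symbol, 0.0))


def conditional_mi_given_input(
    net: ReactionNetwork,
    x_plus: float,
    times_min,
    observable: str = "Y2",
    grid: GConditioningGrid | None = None,
    n_nodes: int | None = 21,
) -> MIResult:
    """I(y; G, t | x(t)): response diversity induced by the slow variable.

    At fixed step amplitude, mixes the G-conditioned output laws over the
    stationary law of G and measures how much a snapshot of the output reveals
    about the cell's G state.
    """
    if net.global_spec is None:
        raise ValueError("requires a network with a global variable")
    if grid is None:
        grid = g_grid(net.global_spec, n_nodes=n_nodes, coverage=1.0 - 1e-6)
    times_min = np.asarray(times_min, dtype=float)
    pinned = net.pin_global()
    obs = net.species_index(observable)
    mus = np.zeros((grid.gs.size, times_min.size))
    cvs = np.zeros((grid.gs.size, times_min.size))
    for gi, g in enumerate(grid.gs):
        cond = conditional_stationary(net, float(g))
        traj = integrate_moments(pinned, cond, times_min, x=x_plus)
        for ti, s in enumerate(traj.states):
            mus[gi, ti] = s.mean[obs]
            cvs[gi, ti] = s.cov[obs, obs]
    bits = np.empty(times_min.size)
    for ti in range(times_min.size):
        if np.allclose(mus[:, ti], mus[0, ti]) and np.allclose(cvs[:, ti], cvs[0, ti]):
            bits[ti] = 0.0
            continue
        _, P = _integer_pmf_matrix(mus[:, ti], cvs[:, ti])
        bits[ti] = _discrete_mi(P, grid.weights)
    return MIResult(times_min, bits, f"given-x={x_plus}", (observable, "G"))


def add_measurement_background(
    surface: DoseResponseSurface, background: dict[str, tuple[float, float]]
) -> DoseResponseSurface:
    """Shift surface moments to the measured-fluorescence channel.

    ``background`` maps observable name to (mean, sd) of an additive,
    channel-independent autofluorescence term: means shift by the background
    mean and variances grow by its variance (cross-covariances unchanged).
    """
    means = surface.means.copy()
    covs = surface.covs.copy()
    for name, (b_mean, b_sd) in background.items():
        k = surface.observables.index(name)
        means[:, :, k] += b_mean
        covs[:, :, k, k] += b_sd**2
    return replace(surface, means=means, covs=covs, conditioning=surface.conditioning + "+bg")


def equalize_reporter_means(surface: DoseResponseSurface, reporter: str = "Y1r") -> DoseResponseSurface:
    """Remove the input dependence of the reporter mean, preserving its noise.

    Per time and dose the reporter mean is set to its zero-dose value and the
    variance rescaled so SD/mean is unchanged; reporter-output covariance is
    rescaled to keep the correlation coefficient.  By construction the
    transformed reporter alone carries zero information about the input.
    """
    ri = surface.observables.index(reporter)
    if not np.isclose(surface.doses[0], 0.0):
        raise ValueError("equalization needs the zero-dose column")
    means = surface.means.copy()
    covs = surface.covs.copy()
    for ti in range(surface.times.size):
        m0 = surface.means[0, ti, ri]
        if m0 <= 0:
            if np.allclose(surface.means[:, ti, ri], 0.0):
                continue  # reporter silent at this time; nothing to equalize
            raise ValueError(f"zero reporter mean at zero dose, t = {surface.times[ti]} min")
        for di in range(surface.doses.size):
            m = means[di, ti, ri]
            if m <= 0:
                raise ValueError(f"zero reporter mean at dose {surface.doses[di]}")
            scale = m0 / m
            means[di, ti, ri] = m0
            covs[di, ti, ri, ri] *= scale**2
            for k in range(len(surface.observables)):
                if k != ri:
                    covs[di, ti, ri, k] *= scale
                    covs[di, ti, k, ri] *= scale
    return replace(surface, means=means, covs=covs, conditioning=surface.conditioning + "+equalized")
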