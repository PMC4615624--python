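"""Declarative reaction-network models of the signaling cascade and synthetic circuit.

Three stochastic models are provided:

* a simple signaling cascade (input-activated conversion Y1* -> Y1 driving
  transcription of My2 and translation of Y2),
* the same cascade/circuit augmented with a slowly fluctuating global
  birth/death variable G that multiplicatively couples into every protein
  translation rate (extrinsic, "global" noise), and
* a purely intrinsic variant of the synthetic estradiol-inducible circuit.

All rate constants are stored in s^-1 (and per-molecule s^-1) exactly as
printed in the parameter tables; public APIs elsewhere in the package accept
and report times in minutes.  The conversion factor lives here so it is
defined exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

SECONDS_PER_MINUTE = 60.0

__all__ = [
    "SECONDS_PER_MINUTE",
    "Constant",
    "EstradiolRepressedConstant",
    "Linear",
    "InputScaledLinear",
    "Bilinear",
    "HillActivation",
    "Reaction",
    "GlobalVariableSpec",
    "ReactionNetwork",
    "StepInputProtocol",
    "build_simple_cascade",
    "attach_global_variable",
    "build_synthetic_circuit",
    "load_table",
    "network_to_config",
    "network_from_config",
    "save_config",
    "load_config",
]


class MissingParameterError(KeyError):
    """A builder was handed a parameter set lacking a required rate constant."""


def _require(params: dict, keys: tuple[str, ...], model: str) -> None:
    missing = [k for k in keys if k not in params]
    if missing:
        raise MissingParameterError(
            f"model '{model}' requires parameters {missing!r}; got {sorted(params)!r}"
        )


# ---------------------------------------------------------------------------
# Propensity forms
# ---------------------------------------------------------------------------
#
# Each form evaluates a_j(y; x) >= 0 for non-negative states together with its
# exact analytic gradient with respect to the state vector; the gradients feed
# the locally-affine moment closure.


@dataclass(frozen=True)
class Constant:
    """Zero-order propensity a = c (synthesis at a fixed rate)."""

    c: float

    def value(self, y: np.ndarray, x: float) -> float:
        return self.c

    def grad(self, y: np.ndarray, x: float) -> np.ndarray:
        return np.zeros(len(y))


@dataclass(frozen=True)
class EstradiolRepressedConstant:
    """ADH1-like promoter activity beta * [(1-alpha) + alpha*K^n/(K^n + x^n)].

    Equals ``beta`` at x = 0 and ``beta*(1-alpha)`` at saturating input: a
    modest input-dependent repression of an otherwise constitutive promoter.
    """

    beta: float
    alpha: float
    xe: float
    nx: float

    def value(self, y: np.ndarray, x: float) -> float:
        kn = self.xe**self.nx
        return self.beta * ((1.0 - self.alpha) + self.alpha * kn / (kn + x**self.nx))

    def grad(self, y: np.ndarray, x: float) -> np.ndarray:
        return np.zeros(len(y))


@dataclass(frozen=True)
class Linear:
    """First-order mass action a = c * y_i."""

    c: float
    i: int

    def value(self, y: np.ndarray, x: float) -> float:
        return self.c * y[self.i]

    def grad(self, y: np.ndarray, x: float) -> np.ndarray:
        g = np.zeros(len(y))
        g[self.i] = self.c
        return g


@dataclass(frozen=True)
class InputScaledLinear:
    """Input-driven conversion a = c * x * y_i (e.g. theta_x * x * y1*)."""

    c: float
    i: int

    def value(self, y: np.ndarray, x: float) -> float:
        return self.c * x * y[self.i]

    def grad(self, y: np.ndarray, x: float) -> np.ndarray:
        g = np.zeros(len(y))
        g[self.i] = self.c * x
        return g


@dataclass(frozen=True)
class Bilinear:
    """Second-order form a = c * y_i * y_j (G-coupled translation)."""

    c: float
    i: int
    j: int

    def value(self, y: np.ndarray, x: float) -> float:
        return self.c * y[self.i] * y[self.j]

    def grad(self, y: np.ndarray, x: float) -> np.ndarray:
        g = np.zeros(len(y))
        g[self.i] += self.c * y[self.j]
        g[self.j] += self.c * y[self.i]
        return g


@dataclass(frozen=True)
class HillActivation:
    """Activated transcription a = base + amp * y_i^n / (y_i^n + k^n)."""

    base: float
    amp: float
    n: float
    k: float
    i: int

    def value(self, y: np.ndarray, x: float) -> float:
        yn = y[self.i] ** self.n
        return self.base + self.amp * yn / (yn + self.k**self.n)

    def grad(self, y: np.ndarray, x: float) -> np.ndarray:
        g = np.zeros(len(y))
        yi = y[self.i]
        kn = self.k**self.n
        if yi > 0.0:
            yn = yi**self.n
            g[self.i] = self.amp * self.n * kn * yi ** (self.n - 1.0) / (yn + kn) ** 2
        return g


PROPENSITY_KINDS = {
    "constant": Constant,
    "estradiol-repressed-constant": EstradiolRepressedConstant,
    "mass-action-linear": Linear,
    "input-scaled-linear": InputScaledLinear,
    "bilinear": Bilinear,
    "hill-activation": HillActivation,
}
_KIND_BY_CLASS = {cls: name for name, cls in PROPENSITY_KINDS.items()}


# ---------------------------------------------------------------------------
# Network container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    name: str
    stoich: tuple[int, ...]  # change vector nu_j over the species list
    propensity: object


@dataclass(frozen=True)
class GlobalVariableSpec:
    """Birth/death global variable G with mean gbar = beta_g/gamma_g.

    ``coupled`` names the protein-creation reactions whose propensities are
    multiplied by G/gbar, so each coupled rate keeps its nominal mean while
    fluctuating with G.  The coefficient of variation of G at stationarity is
    eta_g = 1/sqrt(gbar).
    """

    beta_g: float
    gamma_g: float
    coupled: tuple[str, ...]

    @property
    def gbar(self) -> float:
        return self.beta_g / self.gamma_g

    @property
    def eta_g(self) -> float:
        return 1.0 / math.sqrt(self.gbar)

    @classmethod
    def from_mean(cls, gbar: float, gamma_g: float, coupled: tuple[str, ...]) -> "GlobalVariableSpec":
        return cls(beta_g=gbar * gamma_g, gamma_g=gamma_g, coupled=tuple(coupled))


@dataclass(frozen=True)
class ReactionNetwork:
    """Species list plus elementary reactions with analytic propensities.

    The external input x (nM, dimensionless inside propensities) is passed to
    every evaluation; it enters only through the input-dependent forms.
    """

    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    model: str = "custom"
    params: dict = field(default_factory=dict)
    global_spec: GlobalVariableSpec | None = None
    adh1_estradiol_dependence: bool = True

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    def species_index(self, name: str) -> int:
        try:
            return self.species.index(name)
        except ValueError as err:
            raise KeyError(f"unknown species {name!r}; have {self.species}") from err

    @property
    def stoich_matrix(self) -> np.ndarray:
        """(M, N) array of change vectors nu_j."""
        return np.array([r.stoich for r in self.reactions], dtype=float)

    def propensities(self, y: np.ndarray, x: float) -> np.ndarray:
        """Evaluate all a_j at state ``y`` (negative components clipped to 0)."""
        y = np.maximum(np.asarray(y, dtype=float), 0.0)
        return np.array([r.propensity.value(y, x) for r in self.reactions])

    def propensity_jacobian(self, y: np.ndarray, x: float) -> np.ndarray:
        """(M, N) array of exact gradients da_j/dy_i at the clipped state."""
        y = np.maximum(np.asarray(y, dtype=float), 0.0)
        return np.array([r.propensity.grad(y, x) for r in self.reactions])

    def pin_global(self) -> "ReactionNetwork":
        """Freeze the global variable: drop its birth/death reactions.

        G remains a species (so state shapes are unchanged) but no reaction
        moves it; initial conditions then hold it at a fixed copy number.
        """
        if self.global_spec is None:
            raise ValueError("network has no global variable to pin")
        keep = tuple(r for r in self.reactions if r.name not in ("g_birth", "g_death"))
        return replace(self, reactions=keep)

    # -- encoding for the numba SSA kernel ---------------------------------
    def compile_arrays(self, x: float):
        """Flatten propensities into parallel arrays for the SSA kernel.

        Input-dependent forms are folded into plain coefficients at the given
        fixed step amplitude ``x``.
        """
        M, N = self.n_reactions, self.n_species
        kind = np.zeros(M, dtype=np.int64)
        c = np.zeros(M)
        ii = np.zeros(M, dtype=np.int64)
        jj = np.zeros(M, dtype=np.int64)
        base = np.zeros(M)
        hill_n = np.zeros(M)
        hill_kn = np.zeros(M)
        for m, r in enumerate(self.reactions):
            p = r.propensity
            if isinstance(p, Constant):
                kind[m], c[m] = 0, p.c
            elif isinstance(p, EstradiolRepressedConstant):
                kind[m], c[m] = 0, p.value(np.zeros(N), x)
            elif isinstance(p, Linear):
                kind[m], c[m], ii[m] = 1, p.c, p.i
            elif isinstance(p, InputScaledLinear):
                kind[m], c[m], ii[m] = 1, p.c * x, p.i
            elif isinstance(p, Bilinear):
                kind[m], c[m], ii[m], jj[m] = 2, p.c, p.i, p.j
            elif isinstance(p, HillActivation):
                kind[m], c[m], ii[m] = 3, p.amp, p.i
                base[m] = p.base
                hill_n[m] = p.n
                hill_kn[m] = p.k**p.n
            else:  # pragma: no cover - new forms must be registered here
                raise TypeError(f"cannot compile propensity {p!r}")
        stoich = np.array([r.stoich for r in self.reactions], dtype=np.int64)
        return kind, c, ii, jj, base, hill_n, hill_kn, stoich


# ---------------------------------------------------------------------------
# Step-input protocols
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StepInputProtocol:
    """Step inputs x(t) = 0 for t < 0 and x(t) = X+ for t >= 0.

    Amplitudes carry uniform probability; for the synthetic-circuit
    experiment the amplitudes are the 12-well series 100*(2/3)^(c-1) nM for
    columns c = 1..11 plus a 0 nM well.
    """

    amplitudes: tuple[float, ...]
    xmax: float

    def __post_init__(self):
        if any(a < 0 or a > self.xmax for a in self.amplitudes):
            raise ValueError("amplitudes must lie in [0, xmax]")

    @property
    def weights(self) -> np.ndarray:
        n = len(self.amplitudes)
        return np.full(n, 1.0 / n)

    @property
    def doses(self) -> np.ndarray:
        """Amplitudes sorted ascending (the dose axis of response surfaces)."""
        return np.sort(np.asarray(self.amplitudes, dtype=float))

    @classmethod
    def estradiol_12(cls) -> "StepInputProtocol":
        amps = tuple(100.0 * (2.0 / 3.0) ** (c - 1) for c in range(1, 12)) + (0.0,)
        return cls(amplitudes=amps, xmax=100.0)

    @classmethod
    def geometric(cls, xmax: float, n: int, ratio: float = 2.0 / 3.0) -> "StepInputProtocol":
        """n amplitudes: xmax*ratio^k for k = 0..n-2, plus a zero dose."""
        if n < 2:
            raise ValueError("need at least 2 amplitudes")
        amps = tuple(xmax * ratio ** k for k in range(n - 1)) + (0.0,)
        return cls(amplitudes=amps, xmax=xmax)


# ---------------------------------------------------------------------------
# Model builders
# ---------------------------------------------------------------------------

_CASCADE_KEYS = (
    "beta_y1s",
    "gamma_y1s",
    "theta_x",
    "theta_y1",
    "n1",
    "y1_0",
    "beta_m2s",
    "beta_m2",
    "gamma_m2",
    "beta_y2",
    "gamma_y2",
)


def _downstream_reactions(params: dict, idx: dict[str, int]) -> list[Reaction]:
    """Activation / transcription / translation chain shared by all models."""

    def nu(**changes) -> tuple[int, ...]:
        v = [0] * len(idx)
        for name, d in changes.items():
            v[idx[name]] = d
        return tuple(v)

    gamma_y1 = params.get("gamma_y1", params["gamma_y1s"])
    return [
        Reaction("y1s_degradation", nu(Y1s=-1), Linear(params["gamma_y1s"], idx["Y1s"])),
        Reaction("activation", nu(Y1s=-1, Y1=+1), InputScaledLinear(params["theta_x"], idx["Y1s"])),
        Reaction("deactivation", nu(Y1s=+1, Y1=-1), Linear(params["theta_y1"], idx["Y1"])),
        Reaction("y1_degradation", nu(Y1=-1), Linear(gamma_y1, idx["Y1"])),
        Reaction(
            "my2_transcription",
            nu(My2=+1),
            HillActivation(params["beta_m2s"], params["beta_m2"], params["n1"], params["y1_0"], idx["Y1"]),
        ),
        Reaction("my2_degradation", nu(My2=-1), Linear(params["gamma_m2"], idx["My2"])),
        Reaction("y2_translation", nu(Y2=+1), Linear(params["beta_y2"], idx["My2"])),
        Reaction("y2_degradation", nu(Y2=-1), Linear(params["gamma_y2"], idx["Y2"])),
    ]


def build_simple_cascade(params: dict) -> ReactionNetwork:
    """Simple cascade: species {Y1*, Y1, My2, Y2} with the 9 elementary reactions.

    The input x enters only through the activation propensity theta_x*x*y1*;
    transcription of My2 follows the Hill form
    f1(y1) = beta_m2s + beta_m2*y1^n1/(y1^n1 + y1_0^n1).
    """
    _require(params, _CASCADE_KEYS, "simple_cascade")
    species = ("Y1*", "Y1", "My2", "Y2")
    idx = {"Y1s": 0, "Y1": 1, "My2": 2, "Y2": 3}
    birth = Reaction("y1s_synthesis", (1, 0, 0, 0), Constant(params["beta_y1s"]))
    reactions = (birth, *_downstream_reactions(params, idx))
    return ReactionNetwork(
        species=species, reactions=tuple(reactions), model="simple_cascade", params=dict(params)
    )


def attach_global_variable(net: ReactionNetwork, gspec: GlobalVariableSpec) -> ReactionNetwork:
    """Add the birth/death species G and couple the named creation rates.

    Each coupled propensity is multiplied by G/gbar: a zero-order synthesis
    rate c becomes the G-linear rate (c/gbar)*G, and a first-order translation
    rate c*y_i becomes the bilinear (c/gbar)*y_i*G.  With G pinned at gbar the
    coupled propensities reduce exactly to their nominal values.
    """
    names = {r.name for r in net.reactions}
    unknown = [n for n in gspec.coupled if n not in names]
    if unknown:
        raise KeyError(f"coupled rate name(s) {unknown!r} not in network reactions")
    gi = net.n_species
    gbar = gspec.gbar
    new_reactions: list[Reaction] = []
    for r in net.reactions:
        stoich = r.stoich + (0,)
        p = r.propensity
        if r.name in gspec.coupled:
            if isinstance(p, Constant):
                p = Linear(p.c / gbar, gi)
            elif isinstance(p, Linear):
                p = Bilinear(p.c / gbar, p.i, gi)
            else:
                raise TypeError(
                    f"reaction {r.name!r} has propensity {type(p).__name__}; "
                    "only constant or linear creation rates can couple to G"
                )
        new_reactions.append(Reaction(r.name, stoich, p))
    zero = (0,) * gi
    new_reactions.append(Reaction("g_birth", zero + (1,), Constant(gspec.beta_g)))
    new_reactions.append(Reaction("g_death", zero + (-1,), Linear(gspec.gamma_g, gi)))
    return replace(
        net,
        species=net.species + ("G",),
        reactions=tuple(new_reactions),
        global_spec=gspec,
    )


_CIRCUIT_EXTRA_KEYS = ("beta_m1", "gamma_m1", "gamma_y1r", "alpha_x", "x_e", "n_x")

CASCADE_COUPLED = ("y1s_synthesis", "y2_translation")
CIRCUIT_COUPLED = ("y1s_translation", "y1r_translation", "y2_translation")


def build_synthetic_circuit(
    params: dict,
    variant: str = "global",
    adh1_estradiol_dependence: bool = True,
    gspec: GlobalVariableSpec | None = None,
) -> ReactionNetwork:
    """Synthetic estradiol circuit: cascade plus an mRNA step and a reporter.

    Species {M1, Y1*, Y1, Y1r, My2, Y2} (plus G for the global variant).  M1
    (ADH1 mRNA) is transcribed at beta_m1*(x) - the modest estradiol-repressed
    form when ``adh1_estradiol_dependence`` is on, the plain constant beta_m1
    when off.  Y1* and the fluorescent reporter Y1r are both translated from
    M1 at rate beta_y1s (G-coupled in the global variant); Y1r degrades at its
    own rate gamma_y1r.  Downstream of Y1 the circuit is the simple cascade
    with beta_m2s = 0.
    """
    if variant not in ("global", "intrinsic"):
        raise ValueError(f"variant must be 'global' or 'intrinsic', got {variant!r}")
    _require(params, _CASCADE_KEYS[:1] + _CASCADE_KEYS[1:] + _CIRCUIT_EXTRA_KEYS, f"circuit_{variant}")
    species = ("M1", "Y1*", "Y1", "Y1r", "My2", "Y2")
    idx = {"M1": 0, "Y1s": 1, "Y1": 2, "Y1r": 3, "My2": 4, "Y2": 5}

    def nu(**changes) -> tuple[int, ...]:
        v = [0] * len(species)
        for name, d in changes.items():
            v[idx[name]] = d
        return tuple(v)

    if adh1_estradiol_dependence:
        m1_prop = EstradiolRepressedConstant(
            params["beta_m1"], params["alpha_x"], params["x_e"], params["n_x"]
        )
    else:
        m1_prop = Constant(params["beta_m1"])
    reactions = [
        Reaction("m1_transcription", nu(M1=+1), m1_prop),
        Reaction("m1_degradation", nu(M1=-1), Linear(params["gamma_m1"], idx["M1"])),
        Reaction("y1s_translation", nu(Y1s=+1), Linear(params["beta_y1s"], idx["M1"])),
        Reaction("y1r_translation", nu(Y1r=+1), Linear(params["beta_y1s"], idx["M1"])),
        Reaction("y1r_degradation", nu(Y1r=-1), Linear(params["gamma_y1r"], idx["Y1r"])),
        *_downstream_reactions(params, idx),
    ]
    net = ReactionNetwork(
        species=species,
        reactions=tuple(reactions),
        model=f"circuit_{variant}",
        params=dict(params),
        adh1_estradiol_dependence=adh1_estradiol_dependence,
    )
    if variant == "global":
        if gspec is None:
            gspec = GlobalVariableSpec.from_mean(42.0, 3e-6, CIRCUIT_COUPLED)
        elif not gspec.coupled:
            gspec = replace(gspec, coupled=CIRCUIT_COUPLED)
        net = attach_global_variable(net, gspec)
        net = replace(net, model="circuit_global")
    elif gspec is not None:
        raise ValueError("intrinsic variant takes no global-variable spec")
    return net


# ---------------------------------------------------------------------------
# Parameter tables and config serialization
# ---------------------------------------------------------------------------


def load_table(name: str) -> dict:
    """Load a shipped parameter table ('table1', 'table2' or 'table3')."""
    from importlib.resources import files

    path = files("stochmi.data").joinpath(f"{name}.yaml")
    with path.open("r") as fh:
        return yaml.safe_load(fh)["parameters"]


def network_to_config(net: ReactionNetwork) -> dict:
    cfg: dict = {"model": net.model, "parameters": dict(net.params)}
    if net.global_spec is not None:
        cfg["global_variable"] = {
            "beta_g": net.global_spec.beta_g,
            "gamma_g": net.global_spec.gamma_g,
            "coupled": list(net.global_spec.coupled),
        }
    if net.model.startswith("circuit"):
        cfg["adh1_estradiol_dependence"] = net.adh1_estradiol_dependence
    return cfg


def network_from_config(cfg: dict) -> ReactionNetwork:
    model = cfg["model"]
    params = cfg["parameters"]
    gcfg = cfg.get("global_variable")
    gspec = None
    if gcfg is not None:
        gspec = GlobalVariableSpec(gcfg["beta_g"], gcfg["gamma_g"], tuple(gcfg["coupled"]))
    if model == "simple_cascade":
        net = build_simple_cascade(params)
        if gspec is not None:
            net = attach_global_variable(net, gspec)
        return net
    if model == "circuit_global":
        return build_synthetic_circuit(
            params, "global", cfg.get("adh1_estradiol_dependence", True), gspec
        )
    if model == "circuit_intrinsic":
        return build_synthetic_circuit(
            params, "intrinsic", cfg.get("adh1_estradiol_dependence", True)
        )
    raise ValueError(f"unknown model {model!r}")


def save_config(net: ReactionNetwork, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_config(net), fh, sort_keys=True)


def load_config(path) -> ReactionNetwork:
    with open(path) as fh:
        return network_from_config(yaml.safe_load(fh))
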