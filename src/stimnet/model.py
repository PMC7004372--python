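"""Modified Wilson-Cowan node with divisive inhibition, and the coupled network.

Each brain region is a three-population neural mass: one excitatory
population ``E``, one subtractive-inhibitory population ``Is`` (interneurons
targeting the dendrites, shifting the excitatory threshold), and one
divisive-inhibitory population ``Id`` (interneurons targeting the soma,
flattening the excitatory gain).  The populations evolve by

    tau_e dE/dt  = -E  + (k_e - E)  F_e(w1 E + C_i(t) + P_e, w2 Is, w3 Id)
    tau_i dIs/dt = -Is + (k_i - Is) F_i(w4 E + P_s, 0, 0)
    tau_i dId/dt = -Id + (k_i - Id) F_i(w5 E + P_d, w6 Is + w7 Id, 0)

where ``C_i(t) = sum_{j != i} W_ji E_j(t - del_ij)`` is the delayed input
from the rest of the network, and the input-output function is the
divisively-modulated sigmoid

    F_j(x, theta, a) = 1 / (1 + exp[-(a_j/(1+a)) (x - (theta_j + theta))])
                       - 1 / (1 + exp[a_j theta_j / (1+a)])

whose saturation level ``k_j = lim_{x->inf} F_j`` has the closed form
``logistic(a_j theta_j / (1+a))``.  The subtractive argument ``theta``
shifts the response right; the divisive argument ``a`` flattens its slope
(shunting inhibition).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .connectome import Connectome, CouplingInit, coupling_init

__all__ = [
    "SigmoidConstants",
    "NodeParams",
    "NodeState",
    "NetworkModel",
    "HEALTHY_WEIGHTS",
    "sigmoid",
    "saturation_constant",
    "node_derivatives",
    "coupling_term",
    "make_node_params",
    "calibrate_healthy_params",
    "simulate_single_node",
    "sustained_oscillation_amplitude",
    "build_network_model",
]


@dataclass(frozen=True)
class SigmoidConstants:
    """Sigmoid displacement and slope constants (dimensionless)."""

    theta_e: float = 4.0
    theta_i: float = 3.7
    a_e: float = 1.3
    a_i: float = 2.0

    def __post_init__(self) -> None:
        if min(self.theta_e, self.theta_i, self.a_e, self.a_i) <= 0:
            raise ValueError("sigmoid constants must be strictly positive")

    def pick(self, population: str) -> tuple[float, float]:
        """(a_j, theta_j) for population 'e' or 'i'."""
        if population == "e":
            return self.a_e, self.theta_e
        if population == "i":
            return self.a_i, self.theta_i
        raise ValueError(f"population must be 'e' or 'i', got {population!r}")


# Internal connections, by weight index (0-based), as (pre, post) populations.
# w5 (E->Id) and w7 (Id->Id) carry inhibitory-to-inhibitory context for which
# no plasticity rule is applied; they appear here for completeness.
INTERNAL_WIRING: dict[int, tuple[str, str]] = {
    0: ("E", "E"),    # w1
    1: ("Is", "E"),   # w2
    2: ("Id", "E"),   # w3
    3: ("E", "Is"),   # w4
    4: ("E", "Id"),   # w5
    5: ("Is", "Id"),  # w6
    6: ("Id", "Id"),  # w7
}

EXCITATORY_WEIGHT_INDICES = (0, 3, 4)      # w1, w4, w5 (presynaptic E)
INHIBITORY_WEIGHT_INDICES = (1, 2, 5, 6)   # w2, w3, w6, w7

#: Healthy internal weights (w1..w7), produced by
#: :func:`calibrate_healthy_params` over the oscillatory range [8, 21]
#: (calibrated values, recorded in the default run config; not taken from
#: any published table).
HEALTHY_WEIGHTS: tuple[float, ...] = (
    18.798209, 11.374136, 9.979835, 10.590951, 13.619445, 14.657939, 10.529922,
)


@dataclass(frozen=True)
class NodeParams:
    """Per-region parameters: internal weights, drives and time constants."""

    w: tuple[float, ...] = HEALTHY_WEIGHTS
    P_e: float = 2.0
    P_s: float = 1.0
    P_d: float = 1.0
    tau_e: float = 20.0  # ms
    tau_i: float = 20.0  # ms
    node_kind: str = "healthy"

    def __post_init__(self) -> None:
        if len(self.w) != 7:
            raise ValueError(f"expected 7 internal weights, got {len(self.w)}")
        if min(self.w) < 0:
            raise ValueError("internal weights must be nonnegative")
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("time constants must be positive")
        if self.node_kind not in ("healthy", "epileptogenic"):
            raise ValueError(f"unknown node_kind {self.node_kind!r}")


@dataclass
class NodeState:
    """Activity triple of one region."""

    E: float = 0.1
    Is: float = 0.1
    Id: float = 0.1

    def as_array(self) -> np.ndarray:
        return np.array([self.E, self.Is, self.Id])


def sigmoid(
    x,
    theta,
    a,
    constants: SigmoidConstants = SigmoidConstants(),
    population: str = "e",
):
    """Divisively-modulated sigmoid response F_j(x, theta, a).

    ``theta`` is the subtractive modulation (rightward shift), ``a`` the
    divisive modulation (slope flattening).  Strictly increasing in ``x``;
    F_j(0, 0, 0) = 0.
    """
    a = np.asarray(a, dtype=float)
    if np.any(a <= -1.0):
        raise ValueError("divisive modulation a must exceed -1")
    a_j, theta_j = constants.pick(population)
    slope = a_j / (1.0 + a)
    with np.errstate(over="ignore"):
        rise = 1.0 / (1.0 + np.exp(-slope * (np.asarray(x, dtype=float) - (theta_j + theta))))
    offset = 1.0 / (1.0 + np.exp(slope * theta_j))
    out = rise - offset
    return float(out) if np.isscalar(x) and out.ndim == 0 else out


def saturation_constant(
    constants: SigmoidConstants = SigmoidConstants(),
    population: str = "e",
    a: float = 0.0,
) -> float:
    """Saturation level k_j = lim_{x -> inf} F_j(x, theta, a).

    Closed form logistic(a_j * theta_j / (1 + a)); approaches 1/2 as the
    divisive modulation grows without bound.
    """
    if a <= -1.0:
        raise ValueError("divisive modulation a must exceed -1")
    a_j, theta_j = constants.pick(population)
    z = a_j * theta_j / (1.0 + a)
    return 1.0 / (1.0 + np.exp(-z))


def coupling_term(i: int, delayed_E: np.ndarray, W: np.ndarray) -> float:
    """Delayed network input to node ``i``: sum_j W_ji * E_j(t - del_ij).

    ``delayed_E[j]`` holds E_j evaluated at ``t - del_ij``; the weight
    orientation is source-first (W[j, i] couples source j into target i) and
    the diagonal of W is zero, so j = i contributes nothing.
    """
    return float(np.dot(W[:, i], delayed_E))


def node_derivatives(
    state,
    coupling_input: float,
    params: NodeParams,
    constants: SigmoidConstants = SigmoidConstants(),
    k_e: float | None = None,
    k_i: float | None = None,
) -> tuple[float, float, float]:
    """Right-hand side (dE/dt, dIs/dt, dId/dt) of one node.

    ``state`` is a NodeState or (E, Is, Id) triple; the saturation constants
    default to their divisive-modulation-free values k_j(a=0), held fixed
    during integration.
    """
    if isinstance(state, NodeState):
        E, Is, Id = state.E, state.Is, state.Id
    else:
        E, Is, Id = state
    if not (np.isfinite(E) and np.isfinite(Is) and np.isfinite(Id)):
        raise FloatingPointError(f"non-finite node state (E={E}, Is={Is}, Id={Id})")
    if not np.isfinite(coupling_input):
        raise FloatingPointError(f"non-finite coupling input {coupling_input}")
    if k_e is None:
        k_e = saturation_constant(constants, "e", 0.0)
    if k_i is None:
        k_i = saturation_constant(constants, "i", 0.0)
    w1, w2, w3, w4, w5, w6, w7 = params.w
    Fe = sigmoid(w1 * E + coupling_input + params.P_e, w2 * Is, w3 * Id, constants, "e")
    Fi_s = sigmoid(w4 * E + params.P_s, 0.0, 0.0, constants, "i")
    Fi_d = sigmoid(w5 * E + params.P_d, w6 * Is + w7 * Id, 0.0, constants, "i")
    dE = (-E + (k_e - E) * Fe) / params.tau_e
    dIs = (-Is + (k_i - Is) * Fi_s) / params.tau_i
    dId = (-Id + (k_i - Id) * Fi_d) / params.tau_i
    return dE, dIs, dId


def make_node_params(
    kind: str = "healthy",
    excitatory_factor: float = 1.1,
    inhibitory_factor: float = 0.9,
    overrides: dict | None = None,
) -> NodeParams:
    """Healthy or epileptogenic node parameters.

    Epileptogenic regions are more excitable: the excitatory internal weights
    (w1, w4, w5) are scaled up and the inhibitory ones (w2, w3, w6, w7)
    scaled down relative to the healthy calibration (default +/-10%).
    """
    overrides = dict(overrides or {})
    w = list(overrides.pop("w", HEALTHY_WEIGHTS))
    if kind == "epileptogenic":
        if excitatory_factor < 0 or inhibitory_factor < 0:
            raise ValueError("scale factors must be nonnegative")
        for k in EXCITATORY_WEIGHT_INDICES:
            w[k] *= excitatory_factor
        for k in INHIBITORY_WEIGHT_INDICES:
            w[k] *= inhibitory_factor
    elif kind != "healthy":
        raise ValueError(f"unknown node kind {kind!r}")
    return NodeParams(w=tuple(w), node_kind=(
        "epileptogenic" if kind == "epileptogenic" else "healthy"
    ), **overrides)


# ---------------------------------------------------------------------------
# Single-node probes and calibration
# ---------------------------------------------------------------------------

def simulate_single_node(
    params: NodeParams,
    constants: SigmoidConstants = SigmoidConstants(),
    duration_ms: float = 4000.0,
    dt: float = 0.5,
    initial_state: tuple[float, float, float] = (0.1, 0.1, 0.1),
) -> np.ndarray:
    """Integrate one isolated (self-coupled, network-free) node with RK4.

    Without network coupling the delays drop out and the node is an ODE.
    Returns the E trace sampled at every step (length n_steps + 1).
    """
    import math

    k_e = saturation_constant(constants, "e", 0.0)
    k_i = saturation_constant(constants, "i", 0.0)
    n_steps = int(round(duration_ms / dt))
    E, Is, Id = initial_state
    trace = np.empty(n_steps + 1)
    trace[0] = E
    w1, w2, w3, w4, w5, w6, w7 = params.w
    Pe, Ps, Pd = params.P_e, params.P_s, params.P_d
    te, ti = params.tau_e, params.tau_i
    a_e, th_e = constants.a_e, constants.theta_e
    a_i, th_i = constants.a_i, constants.theta_i

    def F(x, theta_mod, a_mod, a_j, th_j):
        slope = a_j / (1.0 + a_mod)
        return 1.0 / (1.0 + math.exp(-slope * (x - (th_j + theta_mod)))) - \
            1.0 / (1.0 + math.exp(slope * th_j))

    def f(E, Is, Id):
        Fe = F(w1 * E + Pe, w2 * Is, w3 * Id, a_e, th_e)
        Fis = F(w4 * E + Ps, 0.0, 0.0, a_i, th_i)
        Fid = F(w5 * E + Pd, w6 * Is + w7 * Id, 0.0, a_i, th_i)
        return ((-E + (k_e - E) * Fe) / te,
                (-Is + (k_i - Is) * Fis) / ti,
                (-Id + (k_i - Id) * Fid) / ti)

    for s in range(n_steps):
        a1, b1, c1 = f(E, Is, Id)
        a2, b2, c2 = f(E + 0.5 * dt * a1, Is + 0.5 * dt * b1, Id + 0.5 * dt * c1)
        a3, b3, c3 = f(E + 0.5 * dt * a2, Is + 0.5 * dt * b2, Id + 0.5 * dt * c2)
        a4, b4, c4 = f(E + dt * a3, Is + dt * b3, Id + dt * c3)
        E += (dt / 6.0) * (a1 + 2 * a2 + 2 * a3 + a4)
        Is += (dt / 6.0) * (b1 + 2 * b2 + 2 * b3 + b4)
        Id += (dt / 6.0) * (c1 + 2 * c2 + 2 * c3 + c4)
        trace[s + 1] = E
    return trace


def sustained_oscillation_amplitude(trace: np.ndarray) -> float:
    """Peak-to-peak amplitude of the final quarter of a probe trace."""
    tail = trace[3 * len(trace) // 4:]
    return float(np.ptp(tail))


def calibrate_healthy_params(
    search_range: tuple[float, float] = (8.0, 21.0),
    n_candidates: int = 96,
    amplitude_floor: float = 0.05,
    probe_duration_ms: float = 4000.0,
    dt: float = 0.5,
    seed: int = 0,
    constants: SigmoidConstants = SigmoidConstants(),
) -> NodeParams:
    """Search the oscillatory internal-weight range for a healthy node.

    Draws ``n_candidates`` weight vectors uniformly from
    ``search_range ** 7`` (plus the shipped default as candidate zero),
    probes each with a short isolated-node run, and returns the candidate
    with the largest sustained peak-to-peak E amplitude over the final
    quarter of the probe, provided it clears ``amplitude_floor``.
    Deterministic given ``seed``.
    """
    lo, hi = search_range
    if lo > hi:
        raise ValueError("empty search range")
    rng = np.random.default_rng(seed)
    candidates = [np.clip(np.array(HEALTHY_WEIGHTS, dtype=float), lo, hi)]
    candidates += list(rng.uniform(lo, hi, size=(n_candidates, 7)))

    best_w, best_amp = None, -np.inf
    for w in candidates:
        params = NodeParams(w=tuple(w))
        trace = simulate_single_node(params, constants, probe_duration_ms, dt)
        amp = sustained_oscillation_amplitude(trace)
        if amp > best_amp:
            best_w, best_amp = w, amp
    if best_amp < amplitude_floor:
        raise RuntimeError(
            f"no sustained oscillation found in range {search_range} over "
            f"{len(candidates)} candidates (best amplitude {best_amp:.4g} < "
            f"floor {amplitude_floor})"
        )
    return NodeParams(w=tuple(float(x) for x in best_w))


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

@dataclass
class NetworkModel:
    """Delay-coupled network over one subject's connectome.

    State dimension is 3 per region (E, Is, Id), hence ``n_equations = 3 n``
    delayed differential equations (246 for the 82-region parcellation).
    """

    params: list[NodeParams]
    W: np.ndarray
    delays_ms: np.ndarray
    structural_mask: np.ndarray
    constants: SigmoidConstants = field(default_factory=SigmoidConstants)
    k_e: float = 0.0
    k_i: float = 0.0

    def __post_init__(self) -> None:
        n = len(self.params)
        if self.W.shape != (n, n):
            raise ValueError("weight matrix shape does not match node count")
        if np.any(self.W < 0):
            raise ValueError("inter-region weights must be nonnegative")
        if np.any(self.W[~self.structural_mask] != 0):
            raise ValueError("weights must vanish off the structural mask")
        if self.k_e == 0.0:
            self.k_e = saturation_constant(self.constants, "e", 0.0)
        if self.k_i == 0.0:
            self.k_i = saturation_constant(self.constants, "i", 0.0)
        if not (0.0 < self.k_e < 1.0 and 0.0 < self.k_i < 1.0):
            raise ValueError("saturation constants must lie in (0, 1)")

    @property
    def n(self) -> int:
        return len(self.params)

    @property
    def n_equations(self) -> int:
        return 3 * self.n

    def w_internal(self) -> np.ndarray:
        """n x 7 matrix of internal weights."""
        return np.array([p.w for p in self.params], dtype=float)

    def P_vectors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        Pe = np.array([p.P_e for p in self.params])
        Ps = np.array([p.P_s for p in self.params])
        Pd = np.array([p.P_d for p in self.params])
        return Pe, Ps, Pd

    def tau_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        te = np.array([p.tau_e for p in self.params])
        ti = np.array([p.tau_i for p in self.params])
        return te, ti


def build_network_model(
    connectome: Connectome,
    epileptogenic_nodes: list[int] | None = None,
    healthy: NodeParams | None = None,
    excitatory_factor: float = 1.1,
    inhibitory_factor: float = 0.9,
    constants: SigmoidConstants = SigmoidConstants(),
    coupling: CouplingInit | None = None,
) -> NetworkModel:
    """Assemble the network model for one subject.

    ``epileptogenic_nodes`` lists 0-based region indices to parameterize as
    epileptogenic (the stimulated regions of epilepsy patients); all other
    regions use the healthy calibration.
    """
    init = coupling or coupling_init(connectome)
    healthy = healthy or make_node_params("healthy")
    epileptogenic = make_node_params(
        "epileptogenic",
        excitatory_factor=excitatory_factor,
        inhibitory_factor=inhibitory_factor,
        overrides={"w": healthy.w, "P_e": healthy.P_e, "P_s": healthy.P_s,
                   "P_d": healthy.P_d, "tau_e": healthy.tau_e, "tau_i": healthy.tau_i},
    )
    epi = set(epileptogenic_nodes or [])
    params = [epileptogenic if i in epi else healthy for i in range(connectome.n)]
    W = init.W0.copy()
    np.fill_diagonal(W, 0.0)
    return NetworkModel(
        params=params,
        W=W,
        delays_ms=init.delays_ms,
        structural_mask=init.structural_mask,
        constants=constants,
    )
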