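"""Delay-coupled network integration with interleaved plasticity.

The 3n-dimensional delayed differential equation system is advanced by the
method of steps with a fixed-step classical Runge-Kutta (RK4) scheme.  Only
the excitatory activities enter delayed terms, so the integrator keeps a
ring buffer of past E vectors on the step grid and evaluates every required
lag ``t + c dt - del_ij`` by linear interpolation between grid samples (the
step size is constrained to ``dt <= min positive delay``, so every stage
lookup lies in the recorded past).  Before t = 0 the history is constant and
equal to the initial state.

Every 10 ms of simulated time the integrator pauses, applies the Hebbian
updates and normalizations of :mod:`stimnet.plasticity` (weights are held
piecewise constant in between), and resumes.  Snapshots of the inter-region
weight matrix and the per-node internal weights are recorded every 50 s
(both intervals rescale together with the protocol in scaled-down runs).
The whole procedure is deterministic: a fixed configuration reproduces the
trajectory bit for bit.

A stimulation session is a pure input modulation: cathodal transcranial
current stimulation is modelled as a multiplicative reduction (default 50%)
of the external excitatory drive ``P_e`` of the three target regions during
the stimulation window (default onset 200 s, duration 30 min).
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from numba import njit

from .connectome import Connectome, DEFAULT_STIMULATION_TARGETS, coupling_init
from .model import NetworkModel, build_network_model
from .plasticity import (
    ActivitySamples,
    PlasticityConfig,
    external_weight_update,
    internal_weight_update,
    normalize_external,
    normalize_internal,
)

__all__ = [
    "StimulationProtocol",
    "SimulationConfig",
    "SnapshotSeries",
    "ConfigError",
    "integrate",
    "effective_P_e",
    "run_paired",
    "write_snapshots",
    "read_snapshots",
]

SECOND_MS = 1000.0
MINUTE_MS = 60_000.0
HOUR_MS = 3_600_000.0


logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Inconsistent simulation configuration."""


@dataclass(frozen=True)
class StimulationProtocol:
    """A single cathodal stimulation session.

    ``factor`` multiplies the excitatory drive P_e of the target regions
    while ``onset <= t < onset + duration``; cathodal stimulation reduces
    excitability, so the factor lies in [0, 1] (default 0.5, a 50% drop).
    """

    target_labels: tuple[str, ...] = DEFAULT_STIMULATION_TARGETS
    target_hemisphere: str = "left"
    onset_ms: float = 200.0 * SECOND_MS
    duration_ms: float = 30.0 * MINUTE_MS
    factor: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.factor <= 1.0):
            raise ConfigError("stimulation factor must lie in [0, 1] (cathodal)")
        if self.onset_ms < 0:
            raise ConfigError("stimulation onset must be nonnegative")
        if self.duration_ms <= 0:
            raise ConfigError("stimulation duration must be positive")

    def resolve_targets(self, connectome: Connectome) -> list[int]:
        return connectome.regions.resolve_targets(self.target_labels, self.target_hemisphere)


@dataclass(frozen=True)
class SimulationConfig:
    """Integration clocking and initial conditions.

    All times are milliseconds of simulated time.  ``time_scale`` compresses
    the protocol for desk-scale runs: onset, duration, total duration and
    snapshot interval are all multiplied by it (and snapped to the plasticity
    grid), so a 24 h study shrinks coherently.
    """

    total_duration_ms: float = 24.0 * HOUR_MS
    dt_ms: float = 1.0
    plasticity_interval_ms: float = 10.0
    snapshot_interval_ms: float = 50.0 * SECOND_MS
    initial_state: tuple[float, float, float] = (0.1, 0.1, 0.1)
    time_scale: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_ms <= 0 or self.total_duration_ms < 0:
            raise ConfigError("dt must be positive and total duration nonnegative")
        if self.time_scale <= 0:
            raise ConfigError("time_scale must be positive")
        steps = self.plasticity_interval_ms / self.dt_ms
        if abs(steps - round(steps)) > 1e-9 or round(steps) < 1:
            raise ConfigError(
                f"dt ({self.dt_ms} ms) must divide the plasticity interval "
                f"({self.plasticity_interval_ms} ms)"
            )
        snaps = self.snapshot_interval_ms / self.plasticity_interval_ms
        if abs(snaps - round(snaps)) > 1e-9 or round(snaps) < 1:
            raise ConfigError(
                "plasticity interval must divide the snapshot interval"
            )

    def _snap(self, t_ms: float, minimum: float) -> float:
        """Scale a protocol time and snap it to the plasticity grid."""
        scaled = t_ms * self.time_scale
        snapped = round(scaled / self.plasticity_interval_ms) * self.plasticity_interval_ms
        return max(snapped, minimum)

    def effective_times(self, protocol: StimulationProtocol | None):
        """(total, snapshot, onset, duration) after time scaling, in ms."""
        total = self._snap(self.total_duration_ms, 0.0)
        snapshot = self._snap(self.snapshot_interval_ms, self.plasticity_interval_ms)
        if protocol is None:
            return total, snapshot, None, None
        onset_floor = 50.0 * self.dt_ms  # keep a settling period before stimulation
        onset = self._snap(protocol.onset_ms, onset_floor)
        duration = self._snap(protocol.duration_ms, self.plasticity_interval_ms)
        return total, snapshot, onset, duration

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SnapshotSeries:
    """Time-stamped weight snapshots from one simulation run."""

    times_ms: np.ndarray
    W_series: np.ndarray            # (T, n, n)
    w_internal_series: np.ndarray   # (T, n, 7)
    run_kind: str                   # "stimulated" | "unstimulated"
    provenance: dict = field(default_factory=dict)
    final_state: np.ndarray | None = None  # (3, n) activities at run end

    @property
    def n_snapshots(self) -> int:
        return len(self.times_ms)

    @property
    def n(self) -> int:
        return self.W_series.shape[1]


def effective_P_e(
    base_P_e: float,
    t_ms: float,
    protocol: StimulationProtocol | None,
    is_target: bool,
    onset_ms: float | None = None,
    duration_ms: float | None = None,
) -> float:
    """External excitatory drive at time t under the stimulation protocol.

    Target regions receive ``base * factor`` inside the window
    ``[onset, onset + duration)``; everyone else, and every time outside the
    window, receives the base drive.  ``onset_ms``/``duration_ms`` override
    the protocol's nominal times when a time-scaled run supplies them.
    """
    if protocol is None or not is_target:
        return base_P_e
    onset = protocol.onset_ms if onset_ms is None else onset_ms
    duration = protocol.duration_ms if duration_ms is None else duration_ms
    if onset <= t_ms < onset + duration:
        return base_P_e * protocol.factor
    return base_P_e


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _F(x, theta_mod, a_mod, a_j, theta_j):
    slope = a_j / (1.0 + a_mod)
    return 1.0 / (1.0 + math.exp(-slope * (x - (theta_j + theta_mod)))) - \
        1.0 / (1.0 + math.exp(slope * theta_j))


@njit(cache=True)
def _derivs(E, Is, Id, H, s, off_idx, ifl, fr, W, mask, w_int, Pe, Ps, Pd,
            tau_e, tau_i, ke, ki, a_e, a_i, th_e, th_i, nbuf,
            dE, dIs, dId):
    n = E.shape[0]
    for i in range(n):
        c = 0.0
        for j in range(n):
            if mask[j, i]:
                k0 = (s + ifl[off_idx, i, j]) % nbuf
                k1 = (k0 + 1) % nbuf
                f = fr[off_idx, i, j]
                ed = (1.0 - f) * H[k0, j] + f * H[k1, j]
                c += W[j, i] * ed
        xe = w_int[i, 0] * E[i] + c + Pe[i]
        Fe = _F(xe, w_int[i, 1] * Is[i], w_int[i, 2] * Id[i], a_e, th_e)
        Fis = _F(w_int[i, 3] * E[i] + Ps[i], 0.0, 0.0, a_i, th_i)
        Fid = _F(w_int[i, 4] * E[i] + Pd[i],
                 w_int[i, 5] * Is[i] + w_int[i, 6] * Id[i], 0.0, a_i, th_i)
        dE[i] = (-E[i] + (ke - E[i]) * Fe) / tau_e[i]
        dIs[i] = (-Is[i] + (ki - Is[i]) * Fis) / tau_i[i]
        dId[i] = (-Id[i] + (ki - Id[i]) * Fid) / tau_i[i]


@njit(cache=True)
def _advance(E, Is, Id, H, s, n_steps, dt, W, mask, ifl, fr, w_int,
             Pe, Ps, Pd, tau_e, tau_i, ke, ki, a_e, a_i, th_e, th_i, nbuf):
    """Advance ``n_steps`` RK4 steps; returns the new absolute step index."""
    n = E.shape[0]
    dE1 = np.empty(n); dIs1 = np.empty(n); dId1 = np.empty(n)
    dE2 = np.empty(n); dIs2 = np.empty(n); dId2 = np.empty(n)
    dE3 = np.empty(n); dIs3 = np.empty(n); dId3 = np.empty(n)
    dE4 = np.empty(n); dIs4 = np.empty(n); dId4 = np.empty(n)
    E2 = np.empty(n); Is2 = np.empty(n); Id2 = np.empty(n)
    for _ in range(n_steps):
        H[s % nbuf, :] = E
        _derivs(E, Is, Id, H, s, 0, ifl, fr, W, mask, w_int, Pe, Ps, Pd,
                tau_e, tau_i, ke, ki, a_e, a_i, th_e, th_i, nbuf, dE1, dIs1, dId1)
        for i in range(n):
            E2[i] = E[i] + 0.5 * dt * dE1[i]
            Is2[i] = Is[i] + 0.5 * dt * dIs1[i]
            Id2[i] = Id[i] + 0.5 * dt * dId1[i]
        _derivs(E2, Is2, Id2, H, s, 1, ifl, fr, W, mask, w_int, Pe, Ps, Pd,
                tau_e, tau_i, ke, ki, a_e, a_i, th_e, th_i, nbuf, dE2, dIs2, dId2)
        for i in range(n):
            E2[i] = E[i] + 0.5 * dt * dE2[i]
            Is2[i] = Is[i] + 0.5 * dt * dIs2[i]
            Id2[i] = Id[i] + 0.5 * dt * dId2[i]
        _derivs(E2, Is2, Id2, H, s, 1, ifl, fr, W, mask, w_int, Pe, Ps, Pd,
                tau_e, tau_i, ke, ki, a_e, a_i, th_e, th_i, nbuf, dE3, dIs3, dId3)
        for i in range(n):
            E2[i] = E[i] + dt * dE3[i]
            Is2[i] = Is[i] + dt * dIs3[i]
            Id2[i] = Id[i] + dt * dId3[i]
        _derivs(E2, Is2, Id2, H, s, 2, ifl, fr, W, mask, w_int, Pe, Ps, Pd,
                tau_e, tau_i, ke, ki, a_e, a_i, th_e, th_i, nbuf, dE4, dIs4, dId4)
        for i in range(n):
            E[i] += (dt / 6.0) * (dE1[i] + 2.0 * dE2[i] + 2.0 * dE3[i] + dE4[i])
            Is[i] += (dt / 6.0) * (dIs1[i] + 2.0 * dIs2[i] + 2.0 * dIs3[i] + dIs4[i])
            Id[i] += (dt / 6.0) * (dId1[i] + 2.0 * dId2[i] + 2.0 * dId3[i] + dId4[i])
        s += 1
    return s


@njit(cache=True)
def _delayed_presynaptic(H, s, ifl0, fr0, mask, nbuf, out):
    """out[i, j] = E_i(t - del_ij): source activity at the edge delay."""
    n = out.shape[0]
    for i in range(n):
        for j in range(n):
            if mask[i, j]:
                # delays are symmetric; reuse the (i, j)-indexed lag tables
                k0 = (s + ifl0[i, j]) % nbuf
                k1 = (k0 + 1) % nbuf
                f = fr0[i, j]
                out[i, j] = (1.0 - f) * H[k0, i] + f * H[k1, i]
            else:
                out[i, j] = 0.0


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def _config_hash(model: NetworkModel, cfg: SimulationConfig,
                 protocol: StimulationProtocol | None,
                 plasticity: PlasticityConfig) -> str:
    payload = {
        "n": model.n,
        "cfg": cfg.to_dict(),
        "protocol": asdict(protocol) if protocol is not None else None,
        "plasticity": asdict(plasticity),
        "W0_digest": hashlib.sha256(np.ascontiguousarray(model.W).tobytes()).hexdigest(),
        "delays_digest": hashlib.sha256(
            np.ascontiguousarray(model.delays_ms).tobytes()
        ).hexdigest(),
        "w_internal": model.w_internal().tolist(),
    }
    blob = json.dumps(payload, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def integrate(
    model: NetworkModel,
    cfg: SimulationConfig,
    protocol: StimulationProtocol | None = None,
    plasticity: PlasticityConfig | None = None,
    target_nodes: list[int] | None = None,
    on_plasticity=None,
) -> SnapshotSeries:
    """Run one simulation and return its snapshot series.

    ``target_nodes`` must be the resolved stimulation targets when a
    protocol is given.  ``on_plasticity(t_ms, W, w_int)`` is an optional
    diagnostic callback fired after every plasticity update.
    """
    plasticity = plasticity or PlasticityConfig()
    n = model.n
    dt = cfg.dt_ms
    mask = np.ascontiguousarray(model.structural_mask)
    delays = model.delays_ms

    pos = delays[mask]
    min_delay = float(pos.min()) if pos.size else np.inf
    if dt > min_delay + 1e-12:
        raise ConfigError(
            f"dt = {dt} ms exceeds the minimum positive delay {min_delay:.4g} ms; "
            "reduce dt so every delayed lookup lies in the recorded past"
        )
    if protocol is not None and target_nodes is None:
        raise ConfigError("target_nodes must be resolved when a protocol is given")

    total, snap_int, onset, duration = cfg.effective_times(protocol)
    steps_per_interval = int(round(cfg.plasticity_interval_ms / dt))
    n_intervals = int(round(total / cfg.plasticity_interval_ms))
    snap_every = int(round(snap_int / cfg.plasticity_interval_ms))

    # Lag tables: for stage offset o in {0, 0.5, 1} the delayed sample index
    # is s + o - del/dt; the integer and fractional parts are constant.
    del_steps = np.where(mask, delays / dt, 1.0)
    nbuf = int(np.ceil(del_steps.max())) + 3
    offsets = np.array([0.0, 0.5, 1.0])
    q = offsets[:, None, None] - del_steps[None, :, :]
    ifl = np.floor(q).astype(np.int64)
    fr = np.ascontiguousarray(q - ifl)
    ifl = np.ascontiguousarray(ifl)

    # State and constant history
    E = np.full(n, cfg.initial_state[0], dtype=float)
    Is = np.full(n, cfg.initial_state[1], dtype=float)
    Id = np.full(n, cfg.initial_state[2], dtype=float)
    H = np.tile(E, (nbuf, 1))
    s = nbuf  # absolute step index; starts past the buffer so lags stay valid

    W = normalize_external(model.W.copy())
    w_int = normalize_internal(model.w_internal(), plasticity)
    Pe_base, Ps, Pd = model.P_vectors()
    tau_e, tau_i = model.tau_vectors()
    ke, ki = model.k_e, model.k_i
    sc = model.constants
    target_arr = np.zeros(n, dtype=bool)
    if target_nodes:
        target_arr[np.asarray(target_nodes, dtype=int)] = True

    prev = np.stack([E, Is, Id]).copy()
    Epre = np.zeros((n, n))

    times = [0.0]
    W_snaps = [W.copy()]
    w_snaps = [w_int.copy()]

    t = 0.0
    stim_active = False
    for interval in range(n_intervals):
        Pe = Pe_base.copy()
        in_window = protocol is not None and onset <= t < onset + duration
        if in_window:
            Pe[target_arr] = Pe_base[target_arr] * protocol.factor
        if in_window != stim_active:
            logger.info(json.dumps({
                "event": "stimulation_on" if in_window else "stimulation_off",
                "t_ms": t,
            }))
            stim_active = in_window
        s = _advance(E, Is, Id, H, s, steps_per_interval, dt, W, mask, ifl, fr,
                     np.ascontiguousarray(w_int), Pe, Ps, Pd, tau_e, tau_i,
                     ke, ki, sc.a_e, sc.a_i, sc.theta_e, sc.theta_i, nbuf)
        t = (interval + 1) * cfg.plasticity_interval_ms

        if not (np.all(np.isfinite(E)) and np.all(np.isfinite(Is)) and np.all(np.isfinite(Id))):
            bad = int(np.argmax(~np.isfinite(E + Is + Id)))
            raise FloatingPointError(
                f"non-finite state at t = {t / SECOND_MS:.3f} s (node {bad}; "
                f"last snapshot at {times[-1] / SECOND_MS:.3f} s)"
            )

        _delayed_presynaptic(H, s, ifl[0], fr[0], mask, nbuf, Epre)
        samples = ActivitySamples(
            current=np.stack([E, Is, Id]), previous=prev, delayed_E=Epre
        )
        W = normalize_external(external_weight_update(W, samples, plasticity, mask))
        w_int = normalize_internal(internal_weight_update(w_int, samples, plasticity),
                                   plasticity)
        prev = samples.current.copy()
        if on_plasticity is not None:
            on_plasticity(t, W, w_int)

        if (interval + 1) % snap_every == 0:
            times.append(t)
            W_snaps.append(W.copy())
            w_snaps.append(w_int.copy())
            if logger.isEnabledFor(logging.DEBUG):
                delta = np.abs(W_snaps[-1] - W_snaps[-2]).max()
                logger.debug(json.dumps({
                    "event": "snapshot", "t_ms": t,
                    "max_weight_change": float(delta),
                }))

    provenance = {
        "config_hash": _config_hash(model, cfg, protocol, plasticity),
        "seed": cfg.seed,
        "n_equations": model.n_equations,
        "time_scale": cfg.time_scale,
        "onset_ms": onset,
        "duration_ms": duration,
        "total_ms": total,
        "snapshot_interval_ms": snap_int,
        "targets": list(map(int, target_nodes or [])),
    }
    return SnapshotSeries(
        times_ms=np.array(times),
        W_series=np.array(W_snaps),
        w_internal_series=np.array(w_snaps),
        run_kind="unstimulated" if protocol is None else "stimulated",
        provenance=provenance,
        final_state=np.stack([E, Is, Id]),
    )


def run_paired(
    connectome: Connectome,
    group: str,
    cfg: SimulationConfig,
    protocol: StimulationProtocol | None = None,
    plasticity: PlasticityConfig | None = None,
    excitatory_factor: float = 1.1,
    inhibitory_factor: float = 0.9,
) -> tuple[SnapshotSeries, SnapshotSeries]:
    """Run the stimulated and unstimulated twins for one subject.

    Group semantics: ``healthy`` and ``control`` use all-healthy node
    parameters (control differs only in coming from an epileptic subject's
    connectome); ``epileptic`` parameterizes the stimulated regions as
    epileptogenic.  Both runs share initial state, history, weights and
    clocks and differ only through the stimulation input.
    """
    if group not in ("healthy", "epileptic", "control"):
        raise ValueError(f"unknown group {group!r}")
    protocol = protocol or StimulationProtocol()
    targets = protocol.resolve_targets(connectome)
    epi_nodes = targets if group == "epileptic" else []
    model = build_network_model(
        connectome,
        epileptogenic_nodes=epi_nodes,
        excitatory_factor=excitatory_factor,
        inhibitory_factor=inhibitory_factor,
    )
    stim = integrate(model, cfg, protocol, plasticity, target_nodes=targets)
    nostim = integrate(model, cfg, None, plasticity)
    # both series stem from the same model/config pairing
    pair_hash = stim.provenance["config_hash"] + "/" + nostim.provenance["config_hash"]
    for series in (stim, nostim):
        series.provenance["pair_hash"] = pair_hash
        series.provenance["group"] = group
        series.provenance["subject_id"] = connectome.subject_id
    return stim, nostim


# ---------------------------------------------------------------------------
# Snapshot container I/O (HDF5)
# ---------------------------------------------------------------------------

def write_snapshots(series: SnapshotSeries, path) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.create_dataset("times_ms", data=series.times_ms)
        h5.create_dataset("W", data=series.W_series)
        h5.create_dataset("w_internal", data=series.w_internal_series)
        if series.final_state is not None:
            h5.create_dataset("final_state", data=series.final_state)
        h5.attrs["run_kind"] = series.run_kind
        h5.attrs["provenance"] = json.dumps(series.provenance)
        h5.attrs["n_snapshots"] = series.n_snapshots


def read_snapshots(path) -> SnapshotSeries:
    import h5py

    with h5py.File(path, "r") as h5:
        for key in ("times_ms", "W", "w_internal"):
            if key not in h5:
                raise OSError(f"snapshot container {path} is missing dataset {key!r}")
        times = h5["times_ms"][:]
        W = h5["W"][:]
        w_int = h5["w_internal"][:]
        declared = int(h5.attrs.get("n_snapshots", -1))
        if declared != len(times) or len(W) != len(times) or len(w_int) != len(times):
            raise OSError(f"snapshot container {path} is truncated or inconsistent")
        return SnapshotSeries(
            times_ms=times,
            W_series=W,
            w_internal_series=w_int,
            run_kind=str(h5.attrs["run_kind"]),
            provenance=json.loads(h5.attrs["provenance"]),
            final_state=h5["final_state"][:] if "final_state" in h5 else None,
        )
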