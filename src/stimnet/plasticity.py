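"""Hebbian plasticity with synaptic normalization on a 10 ms update clock.

Both the inter-region weights and five of the seven internal weights of each
node follow the same rule: every 10 ms of simulated time,

    delta_w = c * Pre(t) * (Post(t) - Post(t-1))

i.e. presynaptic activity times the change of postsynaptic activity over one
update interval (``t-1`` denotes the previous tick of the update clock).
For inter-region weights the presynaptic activity is read at the conduction
delay, ``Pre(t) = E_i(t - del_ij)``, and the learning rate is c = 0.1; for
internal weights both populations are local, c = 0.05, and the
inhibitory-to-inhibitory weights w5 and w7 are exempt from the rule.

Unchecked Hebbian growth is runaway-unstable, so every update is followed by
sum normalization: each node's incoming inter-region weights are rescaled to
sum to 1, and each node's seven internal weights (including the frozen w5,
w7, which are rescaled but never Hebbian-updated) are rescaled to sum to 1.
Negative weights produced by the rule are clipped to zero before
normalization, which keeps the plain-sum normalization well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PlasticityConfig",
    "ActivitySamples",
    "external_weight_update",
    "normalize_external",
    "internal_weight_update",
    "normalize_internal",
]

logger = logging.getLogger(__name__)


class _OncePerMessageFilter(logging.Filter):
    """Suppress repeats of identical messages (plasticity runs at 100 Hz)."""

    def __init__(self) -> None:
        super().__init__()
        self._seen: set[str] = set()

    def filter(self, record: logging.LogRecord) -> bool:
        key = record.getMessage()
        if key in self._seen:
            return False
        self._seen.add(key)
        return True


logger.addFilter(_OncePerMessageFilter())

#: Internal weight indices (0-based) that follow the Hebbian rule, and the
#: (pre, post) population of each: w1 E->E, w2 Is->E, w3 Id->E, w4 E->Is,
#: w6 Is->Id.
PLASTIC_INTERNAL = ((0, "E", "E"), (1, "Is", "E"), (2, "Id", "E"),
                    (3, "E", "Is"), (5, "Is", "Id"))
FROZEN_INTERNAL = (4, 6)  # w5 (E->Id), w7 (Id->Id)


@dataclass(frozen=True)
class PlasticityConfig:
    """Learning rates and clocking of the Hebbian updates."""

    c_external: float = 0.1
    c_internal: float = 0.05
    update_interval_ms: float = 10.0
    #: Normalize all seven internal weights (the literal rule).  When False,
    #: only the plastic entries are renormalized and w5, w7 keep their values
    #: (sensitivity-analysis mode).
    renormalize_frozen: bool = True

    def __post_init__(self) -> None:
        if self.c_external < 0 or self.c_internal < 0:
            raise ValueError("learning rates must be nonnegative")
        if self.update_interval_ms <= 0:
            raise ValueError("update interval must be positive")


@dataclass
class ActivitySamples:
    """Activities needed by one plasticity update.

    current, previous : (3, n) arrays of (E, Is, Id) at this update tick and
        at the previous one (the initial history at the first tick).
    delayed_E : (n, n) matrix with ``delayed_E[i, j] = E_i(t - del_ij)``, the
        presynaptic activity of source i read at the delay of edge i -> j.
    """

    current: np.ndarray
    previous: np.ndarray
    delayed_E: np.ndarray

    def pop(self, which: str, when: str = "current") -> np.ndarray:
        idx = {"E": 0, "Is": 1, "Id": 2}[which]
        arr = self.current if when == "current" else self.previous
        return arr[idx]


def external_weight_update(
    W: np.ndarray,
    samples: ActivitySamples,
    cfg: PlasticityConfig,
    mask: np.ndarray,
) -> np.ndarray:
    """One Hebbian update of the inter-region weight matrix (pre-normalization).

    For every structurally present ordered edge i -> j:
    ``delta_W[i, j] = c * E_i(t - del_ij) * (E_j(t) - E_j(t-1))``.
    Entries off the structural mask stay exactly zero; negative results are
    clipped to zero.  Returns a new matrix.
    """
    if np.any(np.isnan(W)):
        raise FloatingPointError("NaN in weight matrix")
    dE_post = samples.pop("E") - samples.pop("E", "previous")
    delta = cfg.c_external * samples.delayed_E * dE_post[np.newaxis, :]
    W_new = np.where(mask, np.maximum(W + delta, 0.0), 0.0)
    return W_new


def normalize_external(W: np.ndarray) -> np.ndarray:
    """Rescale each node's incoming weights (columns) to sum to 1.

    All-zero columns are left untouched (logged once per call); the
    operation is a projection, hence idempotent.
    """
    if np.any(np.isnan(W)):
        raise FloatingPointError("NaN in weight matrix")
    col_sums = W.sum(axis=0)
    zero = col_sums <= 0.0
    if np.any(zero):
        logger.warning(
            "normalize_external: %d node(s) with no incoming weight left as zero",
            int(zero.sum()),
        )
    safe = np.where(zero, 1.0, col_sums)
    return W / safe[np.newaxis, :]


def internal_weight_update(
    w: np.ndarray,
    samples: ActivitySamples,
    cfg: PlasticityConfig,
) -> np.ndarray:
    """One Hebbian update of the internal weights (pre-normalization).

    ``w`` is (n, 7) (or a single 7-vector); the plastic entries w1, w2, w3,
    w4, w6 change by ``c * Pre(t) * (Post(t) - Post(t-1))`` with the wiring
    of each connection; w5 and w7 are returned bit-identical.  Negative
    results are clipped to zero.
    """
    w = np.asarray(w, dtype=float)
    single = w.ndim == 1
    w2d = w[np.newaxis, :] if single else w
    out = w2d.copy()
    for k, pre, post in PLASTIC_INTERNAL:
        pre_t = samples.pop(pre)
        dpost = samples.pop(post) - samples.pop(post, "previous")
        out[:, k] = np.maximum(w2d[:, k] + cfg.c_internal * pre_t * dpost, 0.0)
    return out[0] if single else out


def internal_normalization_scope(cfg: PlasticityConfig) -> tuple[int, ...]:
    """Indices included in the internal normalization sum."""
    if cfg.renormalize_frozen:
        return tuple(range(7))
    return tuple(k for k, _, _ in PLASTIC_INTERNAL)


def normalize_internal(w: np.ndarray, cfg: PlasticityConfig | None = None) -> np.ndarray:
    """Rescale each node's internal weights to sum to 1.

    By default the sum runs over all seven weights (the rule as written), so
    the frozen w5 and w7 are rescaled by the same factor as the plastic
    entries.  With ``renormalize_frozen=False`` only the plastic entries are
    rescaled (to 1 minus the frozen mass) and w5, w7 are untouched.
    """
    w = np.asarray(w, dtype=float)
    single = w.ndim == 1
    w2d = w[np.newaxis, :] if single else w
    if np.any(w2d < 0):
        raise ValueError("internal weights must be nonnegative before normalization")
    cfg = cfg or PlasticityConfig()
    out = w2d.astype(float).copy()
    if cfg.renormalize_frozen:
        totals = w2d.sum(axis=1)
        if np.any(totals <= 0):
            raise FloatingPointError("internal weight vector with non-positive sum")
        out = w2d / totals[:, np.newaxis]
    else:
        plastic = [k for k, _, _ in PLASTIC_INTERNAL]
        frozen_mass = w2d[:, list(FROZEN_INTERNAL)].sum(axis=1)
        plastic_sum = w2d[:, plastic].sum(axis=1)
        if np.any(plastic_sum <= 0):
            raise FloatingPointError("plastic internal weights with non-positive sum")
        target = np.maximum(1.0 - frozen_mass, 0.0)
        out[:, plastic] = w2d[:, plastic] * (target / plastic_sum)[:, np.newaxis]
    return out[0] if single else out
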