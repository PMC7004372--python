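"""Stimulation-effect measures and secondary-node connectivity metrics.

A stimulation effect is always measured against the paired unstimulated
twin of the same subject.  The global effect is the percentage L1
difference of the inter-region weight matrices at each snapshot,

    D(t) = 100 * sum_ij |W'_ij(t) - W_ij(t)| / sum_ij |W_ij(t)|

and the local effect of region i is the same quantity over its seven
internal weights,

    d_i(t) = 100 * sum_k |w'_k(i)(t) - w_k(i)(t)| / sum_k |w_k(i)(t)|.

Derived summaries: the persistence rate r = D(t0)/D(t1) comparing the
effect at stimulation end with the effect at the end of the run;
stabilization detection (a trace is stabilized at t once the coefficient of
variation over the preceding 5 minutes drops below 0.3); per-node Jaccard
similarity with the stimulated regions (shared structural neighbours); and
a per-node ranking table of candidate explanations for secondary
(non-stimulated) excitation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectome import Connectome
from .engine import MINUTE_MS, SnapshotSeries

__all__ = [
    "EffectSeries",
    "PairingError",
    "global_effect",
    "local_effect",
    "effect_series",
    "persistence_rate",
    "stabilization_time",
    "jaccard_pair",
    "secondary_jaccard",
    "node_ranking",
    "detect_secondary_excitation",
]


class PairingError(ValueError):
    """Snapshot series that cannot be compared."""


@dataclass
class EffectSeries:
    """D(t) and d_i(t) traces for one stimulated/unstimulated pair."""

    times_ms: np.ndarray
    D: np.ndarray          # (T,)
    d: np.ndarray          # (T, n)
    subject_id: str = "unknown"
    group: str = "unknown"
    provenance: dict = field(default_factory=dict)


def _check_pair(stim: SnapshotSeries, nostim: SnapshotSeries) -> None:
    if stim.times_ms.shape != nostim.times_ms.shape or np.any(
        stim.times_ms != nostim.times_ms
    ):
        raise PairingError("snapshot timestamps differ between the paired runs")
    ph_s = stim.provenance.get("pair_hash")
    ph_n = nostim.provenance.get("pair_hash")
    if ph_s is not None and ph_n is not None and ph_s != ph_n:
        raise PairingError(
            "refusing to compare runs from different configurations "
            f"({ph_s} vs {ph_n})"
        )


def global_effect(stim: SnapshotSeries, nostim: SnapshotSeries) -> np.ndarray:
    """Global effect trace D(t), in percent, one value per snapshot."""
    _check_pair(stim, nostim)
    num = np.abs(stim.W_series - nostim.W_series).sum(axis=(1, 2))
    den = np.abs(nostim.W_series).sum(axis=(1, 2))
    return 100.0 * num / den


def local_effect(stim: SnapshotSeries, nostim: SnapshotSeries) -> np.ndarray:
    """Local effect traces d_i(t), in percent, shape (T, n)."""
    _check_pair(stim, nostim)
    num = np.abs(stim.w_internal_series - nostim.w_internal_series).sum(axis=2)
    den = np.abs(nostim.w_internal_series).sum(axis=2)
    return 100.0 * num / den


def effect_series(stim: SnapshotSeries, nostim: SnapshotSeries) -> EffectSeries:
    return EffectSeries(
        times_ms=stim.times_ms.copy(),
        D=global_effect(stim, nostim),
        d=local_effect(stim, nostim),
        subject_id=stim.provenance.get("subject_id", "unknown"),
        group=stim.provenance.get("group", "unknown"),
        provenance=dict(stim.provenance),
    )


def _nearest(times: np.ndarray, t: float) -> int:
    return int(np.argmin(np.abs(times - t)))


def persistence_rate(
    times_ms: np.ndarray, D: np.ndarray, t0_ms: float, t1_ms: float
) -> float:
    """Persistence rate r = D(t0)/D(t1), snapshots nearest t0 and t1.

    t0 is the end of the stimulation session and t1 the end of the run; with
    a growing effect the rate is below 1.
    """
    d1 = D[_nearest(times_ms, t1_ms)]
    if d1 == 0:
        raise ZeroDivisionError("D(t1) = 0: persistence rate undefined")
    return float(D[_nearest(times_ms, t0_ms)] / d1)


def stabilization_time(
    times_ms: np.ndarray,
    trace: np.ndarray,
    window_ms: float = 5.0 * MINUTE_MS,
    cv_threshold: float = 0.3,
) -> float | None:
    """Earliest time at which a trace counts as stabilized, or None.

    A trace is stabilized at snapshot time t when the coefficient of
    variation (sample SD / mean) of its values in ``(t - window, t]`` is
    below ``cv_threshold``.  Only t >= window is scanned; a zero-mean window
    is treated as not stabilized.
    """
    times_ms = np.asarray(times_ms, dtype=float)
    trace = np.asarray(trace, dtype=float)
    if len(times_ms) < 2 or window_ms > times_ms[-1] - times_ms[0]:
        warnings.warn("trace shorter than the stabilization window", stacklevel=2)
        return None
    for idx in range(len(times_ms)):
        t = times_ms[idx]
        if t < window_ms:
            continue
        sel = (times_ms > t - window_ms) & (times_ms <= t)
        vals = trace[sel]
        if len(vals) < 2:
            continue
        mean = vals.mean()
        if mean == 0:
            continue
        cv = vals.std(ddof=1) / mean
        if cv < cv_threshold:
            return float(t)
    return None


def jaccard_pair(mask: np.ndarray, i: int, j: int) -> float:
    """Jaccard similarity of the structural neighbourhoods of two nodes.

    Neighbourhoods are unweighted sets read off the binary structural
    adjacency; an empty union scores 0.
    """
    if i == j:
        raise ValueError("jaccard_pair requires two distinct nodes")
    gi = np.asarray(mask[i], dtype=bool)
    gj = np.asarray(mask[j], dtype=bool)
    union = int(np.sum(gi | gj))
    if union == 0:
        return 0.0
    return float(np.sum(gi & gj) / union)


def secondary_jaccard(
    mask: np.ndarray,
    i: int,
    stimulated: list[int] | tuple[int, ...],
    allow_any_arity: bool = False,
) -> float:
    """Mean Jaccard similarity of node i with the stimulated regions.

    The protocol stimulates exactly three regions; other arities are
    rejected unless explicitly allowed.
    """
    if i in stimulated:
        raise ValueError("secondary Jaccard is defined for non-stimulated nodes")
    if len(stimulated) != 3 and not allow_any_arity:
        raise ValueError(
            f"expected exactly 3 stimulated nodes, got {len(stimulated)} "
            "(pass allow_any_arity=True to generalize)"
        )
    return float(np.mean([jaccard_pair(mask, s, i) for s in stimulated]))


def _rank(values: np.ndarray, ascending: bool) -> np.ndarray:
    """Dense 1-based ranks; ties broken by node order (stable sort)."""
    order = np.argsort(values if ascending else -values, kind="stable")
    ranks = np.empty(len(values), dtype=int)
    ranks[order] = np.arange(1, len(values) + 1)
    return ranks


def node_ranking(
    connectome: Connectome,
    effect: EffectSeries,
    stimulated: list[int],
    protocol_end_ms: float,
    W_initial: np.ndarray | None = None,
    use_post_peak: bool = False,
    weighted_degree: bool = False,
) -> pd.DataFrame:
    """Rank non-stimulated regions by candidate drivers of secondary effects.

    Columns (value_* and rank_*): local effect right after stimulation end
    (or the post-window peak with ``use_post_peak``), final local effect,
    structural degree (or weighted strength), number of stimulated
    neighbours, fraction of connection weight shared with stimulated regions
    (on the initial weight matrix, symmetrized), mean Euclidean centroid
    distance to the stimulated regions (mm), and the secondary Jaccard
    index.  Rank 1 marks the largest effect / strongest connectivity /
    smallest distance.
    """
    mask = connectome.mask
    n = connectome.n
    others = np.array([i for i in range(n) if i not in set(stimulated)])

    end_idx = _nearest(effect.times_ms, protocol_end_ms)
    if use_post_peak:
        after = effect.times_ms >= protocol_end_ms
        d_after = effect.d[after][:, others].max(axis=0)
    else:
        d_after = effect.d[end_idx, others]
    d_final = effect.d[-1, others]

    if weighted_degree:
        from .connectome import init_weight_matrix

        strength = init_weight_matrix(connectome.S).sum(axis=1)
        degree = strength[others]
    else:
        degree = mask.sum(axis=1)[others]
    stim_neighbours = mask[:, stimulated].sum(axis=1)[others]

    if W_initial is None:
        from .connectome import init_weight_matrix

        W_initial = init_weight_matrix(connectome.S)
    Wsym = 0.5 * (W_initial + W_initial.T)
    tot = Wsym.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(tot > 0, Wsym[:, stimulated].sum(axis=1) / tot, 0.0)[others]

    xyz = connectome.regions.centroids()
    dist = np.linalg.norm(
        xyz[others][:, None, :] - xyz[list(stimulated)][None, :, :], axis=-1
    ).mean(axis=1)

    jac = np.array(
        [secondary_jaccard(mask, int(i), list(stimulated), allow_any_arity=True)
         for i in others]
    )

    labels = connectome.regions.table["label"].to_numpy()[others]
    hemis = connectome.regions.table["hemisphere"].to_numpy()[others]
    df = pd.DataFrame(
        {
            "node": others,
            "label": labels,
            "hemisphere": hemis,
            "value_effect_after_stim": d_after,
            "value_effect_final": d_final,
            "value_degree": degree,
            "value_stim_neighbours": stim_neighbours,
            "value_stim_weight_ratio": ratio,
            "value_distance_mm": dist,
            "value_jaccard": jac,
        }
    )
    df["rank_effect_after_stim"] = _rank(d_after, ascending=False)
    df["rank_effect_final"] = _rank(d_final, ascending=False)
    df["rank_degree"] = _rank(degree.astype(float), ascending=False)
    df["rank_stim_neighbours"] = _rank(stim_neighbours.astype(float), ascending=False)
    df["rank_stim_weight_ratio"] = _rank(ratio, ascending=False)
    df["rank_distance_mm"] = _rank(dist, ascending=True)
    df["rank_jaccard"] = _rank(jac, ascending=False)
    return df


def detect_secondary_excitation(
    effect: EffectSeries,
    stimulated: list[int],
    onset_ms: float,
    k_mad: float = 3.0,
    stabilization_window_ms: float = 5.0 * MINUTE_MS,
    cv_threshold: float = 0.3,
) -> pd.DataFrame:
    """Flag non-stimulated nodes with outlying post-onset local effects.

    A node is flagged when its post-onset peak d_i exceeds the robust
    threshold median + k_mad * MAD over all non-stimulated nodes' peaks.  A
    node whose trace first stabilizes and later rises above the same
    threshold again is flagged as late re-excitation.  Returns a frame with
    node, flag kind and onset time of the excursion.
    """
    n = effect.d.shape[1]
    others = [i for i in range(n) if i not in set(stimulated)]
    after = effect.times_ms >= onset_ms
    peaks = effect.d[after][:, others].max(axis=0)
    med = np.median(peaks)
    mad = np.median(np.abs(peaks - med))
    threshold = med + k_mad * mad

    rows = []
    for pos, node in enumerate(others):
        trace = effect.d[:, node]
        if peaks[pos] <= threshold:
            continue
        exceed = after & (trace > threshold)
        t_on = float(effect.times_ms[np.argmax(exceed)])
        # a node that had already stabilized before its excursion is a late
        # re-excitation rather than an immediate secondary response
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t_stab = stabilization_time(
                effect.times_ms, trace, stabilization_window_ms, cv_threshold
            )
        kind = "late_reexcitation" if t_stab is not None and t_stab < t_on else "secondary"
        rows.append({"node": node, "kind": kind, "onset_ms": t_on,
                     "peak": float(peaks[pos]), "threshold": float(threshold)})
    return pd.DataFrame(rows, columns=["node", "kind", "onset_ms", "peak", "threshold"])
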