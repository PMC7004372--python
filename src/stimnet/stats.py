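"""Group-level statistics: t-tests, effect sizes and trace correlations."""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps

__all__ = ["two_sample_test", "cohens_d", "matched_vs_random_correlation"]


def two_sample_test(values_a, values_b) -> tuple[float, float]:
    """Student's pooled-variance two-sample t-test, two-tailed.

    Returns (t statistic, p value).  Degenerate input — both samples
    constant — gives t = 0, p = 1 when the values coincide (with a warning)
    and t = +/-inf, p = 0 when they differ.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        warnings.warn("zero pooled variance in two-sample test", stacklevel=2)
        if a.mean() == b.mean():
            return 0.0, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = sps.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


def cohens_d(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Cohen's d from summary statistics with equal-weight variance pooling.

    d = (mean_a - mean_b) / sqrt((sd_a^2 + sd_b^2) / 2).
    """
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be nonnegative")
    if sd_a == 0 and sd_b == 0:
        raise ZeroDivisionError("both standard deviations are zero: effect size undefined")
    return float((mean_a - mean_b) / np.sqrt((sd_a**2 + sd_b**2) / 2.0))


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if x.std() == 0 or y.std() == 0:
        warnings.warn("constant trace skipped in correlation", stacklevel=3)
        return None
    return float(np.corrcoef(x, y)[0, 1])


def matched_vs_random_correlation(
    control_traces: dict[str, np.ndarray],
    epileptic_traces: dict[str, np.ndarray],
) -> dict[str, tuple[float, float]]:
    """Pearson correlations of global-effect traces, matched vs random pairs.

    Both dicts are keyed by the shared connectome/subject identifier.
    Matched pairs correlate the control and epileptic runs initialized with
    the same connectome; the random baseline pools all non-matched
    control-epileptic pairs.  Returns
    ``{"matched": (mean, sd), "random": (mean, sd)}``; constant traces are
    skipped with a warning.
    """
    matched, random_pairs = [], []
    for cid, ctrace in control_traces.items():
        for eid, etrace in epileptic_traces.items():
            r = _pearson(np.asarray(ctrace, float), np.asarray(etrace, float))
            if r is None:
                continue
            (matched if cid == eid else random_pairs).append(r)
    if not matched:
        raise ValueError("no matched control-epileptic pairs with usable traces")

    def _summ(vals):
        arr = np.asarray(vals)
        if len(arr) == 0:
            return float("nan"), float("nan")
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
        return float(arr.mean()), sd

    return {"matched": _summ(matched), "random": _summ(random_pairs)}
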