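"""Quantitative characterization of step-response trajectories.

Definitions (all on the activity/output channel ``a(t)`` with prestimulus value
``a_pre`` taken just before the step):

* **response time** -- time from stimulus onset to the extremum of
  |a(t) - a_pre| (ties broken by the earliest sample).
* **adaptation time** -- first time after the peak at which |a(t) - a_pre|
  returns to half of the peak displacement, with linear interpolation between
  samples.
* **sensitivity** -- |(a_peak - a_pre)/a_pre| / |(c1 - c0)/c0|, the
  relative-change ratio convention of Ma et al.
* **imprecision** -- |(a_ss - a_pre)/a_pre| / |(c1 - c0)/c0|, zero for perfect
  adaptation; requires the trajectory to have reached steady state.
* **FCD distance** -- sup-norm of the difference between two activity
  trajectories after aligning their step onsets; zero means exact fold-change
  detection.

Using the extremum of |a - a_pre| handles activity drops (one-component
positive steps) and rises uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "MetricError",
    "AdaptationSummary",
    "adaptation_time",
    "response_time",
    "sensitivity",
    "imprecision",
    "fcd_distance",
    "summarize",
]


class MetricError(ValueError):
    """Raised when a metric is undefined for the given trajectory."""


@dataclass(frozen=True)
class AdaptationSummary:
    adaptation_time: float
    response_time: float
    sensitivity: float
    imprecision: float
    peak_activity: float
    prestimulus_activity: float
    steady_activity: float

    def to_dict(self) -> dict:
        return asdict(self)


def _activity(traj) -> tuple[np.ndarray, np.ndarray]:
    """(t, a) arrays from a Trajectory-like object (uses A2 for two-component)."""
    a = getattr(traj, "activity", None)
    if a is None:
        a = getattr(traj, "A2", None)
    if a is None:
        raise MetricError("trajectory exposes neither 'activity' nor 'A2'")
    return np.asarray(traj.t, dtype=float), np.asarray(a, dtype=float)


def _prestimulus(t: np.ndarray, a: np.ndarray, t_step: float) -> float:
    pre = t < t_step
    return float(a[pre][-1]) if np.any(pre) else float(a[0])


def _peak_index(t, a, t_step, flat_tol=0.0):
    a_pre = _prestimulus(t, a, t_step)
    post = np.flatnonzero(t >= t_step)
    disp = np.abs(a[post] - a_pre)
    if disp.max() <= flat_tol:
        raise MetricError("flat response: metrics undefined")
    k = int(np.argmax(disp))  # argmax returns the first maximum: earliest tie
    return a_pre, post, disp, k


def response_time(traj, t_step: float) -> float:
    """Time from stimulus onset to the peak displacement of the output."""
    t, a = _activity(traj)
    _, post, _, k = _peak_index(t, a, t_step)
    return float(t[post[k]] - t_step)


def adaptation_time(traj, t_step: float) -> float:
    """Time for the output to return halfway from its peak to the prestimulus value."""
    t, a = _activity(traj)
    a_pre, post, disp, k = _peak_index(t, a, t_step)
    half = disp[k] / 2.0
    after = disp[k:]
    below = np.flatnonzero(after <= half)
    if below.size == 0:
        raise MetricError("response does not recover to half displacement on this grid")
    j = below[0]
    if j == 0:
        return float(t[post[k]] - t_step)
    # linear interpolation of the crossing between samples j-1 and j
    t0, t1 = t[post[k + j - 1]], t[post[k + j]]
    d0, d1 = after[j - 1], after[j]
    t_cross = t0 + (d0 - half) / (d0 - d1) * (t1 - t0)
    return float(t_cross - t_step)


def sensitivity(traj, stimulus) -> float:
    """Relative peak output change over relative input change (Ma et al. convention)."""
    if stimulus.c0 <= 0:
        raise MetricError("sensitivity undefined for zero baseline concentration")
    if stimulus.c1 == stimulus.c0:
        raise MetricError("sensitivity undefined for a zero step")
    t, a = _activity(traj)
    a_pre, post, disp, k = _peak_index(t, a, stimulus.t_step)
    if a_pre == 0:
        raise MetricError("sensitivity undefined for zero prestimulus output")
    rel_out = disp[k] / abs(a_pre)
    rel_in = abs(stimulus.c1 - stimulus.c0) / stimulus.c0
    return float(rel_out / rel_in)


def imprecision(traj, stimulus, steady_tol: float = 1e-7) -> float:
    """Normalized residual displacement of the adapted steady state.

    Requires the trajectory to be steady at its end (|da/dt| below
    ``steady_tol`` per grid step over the final 5% of samples).
    """
    if stimulus.c0 <= 0 or stimulus.c1 == stimulus.c0:
        raise MetricError("imprecision needs c0 > 0 and a nonzero step")
    t, a = _activity(traj)
    tail = max(2, len(a) // 20)
    if np.max(np.abs(np.diff(a[-tail:]))) > steady_tol:
        raise MetricError("trajectory has not reached steady state")
    a_pre = _prestimulus(t, a, stimulus.t_step)
    if a_pre == 0:
        raise MetricError("imprecision undefined for zero prestimulus output")
    rel_out = abs(a[-1] - a_pre) / abs(a_pre)
    rel_in = abs(stimulus.c1 - stimulus.c0) / stimulus.c0
    return float(rel_out / rel_in)


def fcd_distance(traj_a, traj_b, t_step_a: float = 0.0, t_step_b: float = 0.0) -> float:
    """Sup-norm distance between two responses after aligning their step onsets.

    Trajectories are compared on the overlap of their onset-aligned time grids;
    the second is linearly resampled onto the first where the grids differ.
    """
    ta, aa = _activity(traj_a)
    tb, ab = _activity(traj_b)
    ta = ta - t_step_a
    tb = tb - t_step_b
    lo, hi = max(ta[0], tb[0]), min(ta[-1], tb[-1])
    if hi <= lo:
        raise MetricError("trajectories share no overlapping time range")
    sel = (ta >= lo) & (ta <= hi)
    if not np.any(sel):
        raise MetricError("incompatible grids after resampling")
    b_on_a = np.interp(ta[sel], tb, ab)
    return float(np.max(np.abs(aa[sel] - b_on_a)))


def summarize(traj, stimulus) -> AdaptationSummary:
    """All step-response metrics in one record."""
    t, a = _activity(traj)
    a_pre, post, disp, k = _peak_index(t, a, stimulus.t_step)
    return AdaptationSummary(
        adaptation_time=adaptation_time(traj, stimulus.t_step),
        response_time=response_time(traj, stimulus.t_step),
        sensitivity=sensitivity(traj, stimulus),
        imprecision=imprecision(traj, stimulus),
        peak_activity=float(a[post[k]]),
        prestimulus_activity=a_pre,
        steady_activity=float(a[-1]),
    )
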