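"""Two-component model: a non-adapting receptor feeding a second component.

The first component (a receptor biased toward off by ``epsilon1``) responds to
the external concentration instantaneously:

    F1 = epsilon1 + ln[(1 + c/K_off1)] - ln[(1 + c/K_on1)],   A1 = 1/(1 + e^F1)

with K_on1 < K_off1, so ligand stabilizes the on state and A1 *tracks* the
stimulus without adapting.  An active receptor releases alpha and betagamma
subunits, clamped at source concentration k_release * A1; each diffuses to the
second component (length scale L2, sampling radius rho2) with its own
diffusivity, D_alpha > D_betagamma.  The second component binds both subunits
with mirrored affinities,

    F2 = epsilon2 + ln[(1 + c_bg/K_tight)] - ln[(1 + c_bg/K_weak)]
                  + ln[(1 + c_a /K_weak )] - ln[(1 + c_a /K_tight)]

so alpha binding raises its activity A2 = 1/(1 + e^F2) while betagamma binding
compensates exactly: whenever c_alpha = c_betagamma, F2 = epsilon2.  Because
both subunit concentrations converge to k_release * A1 at steady state, A2
adapts precisely; the transient pulse comes from alpha arriving first.

Time-varying sources are handled by Duhamel superposition of step responses,
exact for the linear diffusion equation and reducing to the single-step
solution for step stimuli.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .config import CellGeometry, SimulationConfig, StepStimulus, TwoComponentParams
from .diffusion import relaxation_factor

__all__ = [
    "first_component_activity",
    "subunit_concentrations",
    "second_component_activity",
    "simulate_two_component",
    "TwoComponentTrajectory",
]


@dataclass
class TwoComponentTrajectory:
    t: np.ndarray
    c_out: np.ndarray
    A1: np.ndarray
    c_alpha: np.ndarray
    c_betagamma: np.ndarray
    A2: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "t": self.t,
                "c_out": self.c_out,
                "A1": self.A1,
                "c_alpha": self.c_alpha,
                "c_betagamma": self.c_betagamma,
                "A2": self.A2,
            }
        )


def first_component_activity(c_out, params: TwoComponentParams):
    """Activity A1 of the receptor: instantaneous, monotone in c_out, non-adapting."""
    c = np.asarray(c_out, dtype=float)
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise ValueError("c_out must be finite and >= 0")
    F1 = params.epsilon1 + np.log1p(c / params.K_off1) - np.log1p(c / params.K_on1)
    out = expit(-F1)
    return out if out.ndim else float(out)


def _step_profile(t: np.ndarray, D: float, params: TwoComponentParams) -> np.ndarray:
    """Unit-step arrival profile 1 - phi at the second component (0 for t < 0)."""
    out = np.zeros_like(t)
    pos = t >= 0
    tau = t[pos] * D / params.L2**2
    out[pos] = 1.0 - relaxation_factor(params.rho2, tau)
    return out


def subunit_concentrations(
    A1_history: np.ndarray,
    params: TwoComponentParams,
    geom: CellGeometry,
    t: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Subunit concentrations (mM) at the second component for a given A1 history.

    The source is clamped at ``k_release * A1``; the arrival at the second
    component is the Duhamel superposition of diffusion step responses, one per
    change in A1 (the history is treated as piecewise constant, equilibrated at
    its initial value for t < 0).  ``geom`` is accepted for interface symmetry;
    the transit geometry is set by ``params.L2`` and ``params.rho2``.
    """
    t = np.asarray(t, dtype=float)
    A1 = np.asarray(A1_history, dtype=float)
    if A1.shape != t.shape:
        raise ValueError("A1_history must be defined on the full time grid")
    src = params.k_release * A1
    jumps = np.flatnonzero(np.diff(src) != 0.0) + 1
    out = []
    for D in (params.D_alpha, params.D_betagamma):
        c = np.full_like(t, src[0])
        for j in jumps:
            dc = src[j] - src[j - 1]
            c = c + dc * _step_profile(t - t[j], D, params)
        out.append(c)
    return out[0], out[1]


def second_component_activity(c_alpha, c_betagamma, params: TwoComponentParams):
    """Activity A2 of the second component; baseline whenever c_alpha = c_betagamma."""
    ca = np.asarray(c_alpha, dtype=float)
    cb = np.asarray(c_betagamma, dtype=float)
    if np.any(ca < 0) or np.any(cb < 0):
        raise ValueError("subunit concentrations must be >= 0")
    F2 = (
        params.epsilon2
        + np.log1p(cb / params.K_tight)
        - np.log1p(cb / params.K_weak)
        + np.log1p(ca / params.K_weak)
        - np.log1p(ca / params.K_tight)
    )
    out = expit(-F2)
    return out if out.ndim else float(out)


def simulate_two_component(config: SimulationConfig) -> TwoComponentTrajectory:
    """Step-response pipeline: stimulus -> A1 -> diffusing subunits -> A2."""
    stim = config.stimulus
    if not isinstance(stim, StepStimulus):
        raise TypeError("simulate_two_component requires a StepStimulus configuration")
    p = config.two_component
    sol = config.solver
    t = np.arange(0.0, sol.t_end + 0.5 * sol.dt, sol.dt)
    c_out = np.where(t < stim.t_step, stim.c0, stim.c1)
    A1 = first_component_activity(c_out, p)
    c_a, c_bg = subunit_concentrations(A1, p, config.geometry, t)
    A2 = second_component_activity(c_a, c_bg, p)
    return TwoComponentTrajectory(
        t=t, c_out=c_out, A1=A1, c_alpha=c_a, c_betagamma=c_bg, A2=A2
    )
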