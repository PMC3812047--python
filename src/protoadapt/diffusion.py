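"""Spherically symmetric diffusion into a cell after an external concentration step.

The interior concentration u(rho, t) of a sphere of radius R whose surface is
held at the external concentration c_out, starting from a uniform interior
value c_init, is

    u(rho, t) = c_out + (c_init - c_out) * phi(rho, Dt/R^2)

with rho = r/R the normalized radius and phi the dimensionless relaxation
factor.  phi has two exact representations: the classical eigenfunction
(Fourier) series

    phi(rho, tau) = -(2/(pi*rho)) * sum_n ((-1)^n / n) sin(n*pi*rho) exp(-n^2*pi^2*tau)

which converges fast for large tau, and the method-of-images (erfc) form

    phi(rho, tau) = 1 - (1/rho) * sum_m [erfc((2m+1-rho)/(2*sqrt(tau)))
                                         - erfc((2m+1+rho)/(2*sqrt(tau)))]

which converges fast for small tau.  Both diverge at rho = 0 only through the
1/rho prefactor; the limit exists but is not implemented (callers sample the
receptor site at rho > 0).

An independent Crank-Nicolson finite-difference solver of the same problem is
provided as a numerical oracle, together with the Fick's-law membrane flux used
by the thermodynamic accounting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import erfc

from .config import CellGeometry

__all__ = [
    "relaxation_factor",
    "interior_concentration",
    "radial_pde_oracle",
    "membrane_flux",
    "RadialProfile",
]

# Switch point between the image (small tau) and Fourier (large tau) branches.
_TAU_SWITCH = 0.02
# Terms giving remainder < 1e-14 at tau = _TAU_SWITCH for the Fourier branch
# and at all tau below it for the image branch.
_N_FOURIER = 48
_N_IMAGES = 8


@dataclass(frozen=True)
class RadialProfile:
    """Radial concentration profile at one time (rho dimensionless, c in mM)."""

    rho: np.ndarray
    concentration: np.ndarray
    time: float


def _phi_fourier(rho: float, tau: np.ndarray) -> np.ndarray:
    n = np.arange(1, _N_FOURIER + 1)
    coeff = -(2.0 / (np.pi * rho)) * ((-1.0) ** n / n) * np.sin(n * np.pi * rho)
    return coeff @ np.exp(-np.outer(n**2 * np.pi**2, tau))


def _phi_image(rho: float, tau: np.ndarray) -> np.ndarray:
    tau = np.asarray(tau, dtype=float)
    out = np.ones_like(tau)
    pos = tau > 0
    if np.any(pos):
        s = 2.0 * np.sqrt(tau[pos])
        acc = np.zeros_like(s)
        for m in range(_N_IMAGES):
            acc += erfc((2 * m + 1 - rho) / s) - erfc((2 * m + 1 + rho) / s)
        out[pos] = 1.0 - acc / rho
    return out


def relaxation_factor(rho: float, tau) -> np.ndarray:
    """Dimensionless relaxation phi(rho, tau), tau = D*t/R^2.

    phi(rho, 0) = 1 and phi -> 0 as tau -> infinity; the interior value is
    ``c_out + (c_init - c_out) * phi``.
    """
    if not np.isfinite(rho) or not (0.0 < rho <= 1.0):
        raise ValueError(
            f"rho must lie in (0, 1]; got {rho!r} (the series carries a 1/rho "
            "prefactor; use the known central-limit form for rho = 0)"
        )
    tau_arr = np.atleast_1d(np.asarray(tau, dtype=float))
    if not np.all(np.isfinite(tau_arr)) or np.any(tau_arr < 0):
        raise ValueError("tau must be finite and >= 0")
    out = np.empty_like(tau_arr)
    small = tau_arr < _TAU_SWITCH
    if np.any(small):
        out[small] = _phi_image(rho, tau_arr[small])
    if np.any(~small):
        out[~small] = _phi_fourier(rho, tau_arr[~small])
    out = np.clip(out, 0.0, 1.0)
    return out if np.ndim(tau) else float(out[0])


def interior_concentration(
    geom: CellGeometry,
    c_init: float,
    c_out: float,
    D: float,
    t,
    rho: float | None = None,
):
    """Interior concentration (mM) at normalized radius rho and time(s) t.

    Parameters are in package units (um, s, mM).  ``rho`` defaults to the
    geometry's receptor sampling radius.  Accepts scalar or array ``t``.
    """
    if rho is None:
        rho = geom.rho
    for name, val in (("c_init", c_init), ("c_out", c_out), ("D", D)):
        if not np.isfinite(val):
            raise ValueError(f"{name} must be finite, got {val!r}")
    if c_init < 0 or c_out < 0:
        raise ValueError("concentrations must be >= 0")
    if D <= 0:
        raise ValueError("D must be > 0")
    tau = np.asarray(t, dtype=float) * D / geom.radius**2
    phi = relaxation_factor(rho, tau)
    return c_out + (c_init - c_out) * phi


def radial_pde_oracle(
    geom: CellGeometry,
    c_init: float,
    c_out: float,
    D: float,
    t_grid,
    n_shells: int = 200,
) -> list[RadialProfile]:
    """Crank-Nicolson finite-difference solution of the radial diffusion problem.

    Solves d u/dt = D (u_rr + 2 u_r / r) on (0, R) with u(R) = c_out and
    u(r, 0) = c_init, via the substitution v = r*u which reduces the problem to
    the 1D heat equation with v(0) = 0, v(R) = R*c_out.  The first steps after
    the boundary discontinuity use backward Euler (Rannacher smoothing) to damp
    Crank-Nicolson oscillations.  Independent of the analytic series by
    construction; used as its cross-validation oracle.
    """
    if n_shells < 50:
        raise ValueError("n_shells must be >= 50 for a trustworthy oracle")
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if np.any(np.diff(t_grid) <= 0) or t_grid[0] < 0:
        raise ValueError("t_grid must be strictly increasing and nonnegative")
    R = geom.radius
    dr = R / n_shells
    r = np.linspace(0.0, R, n_shells + 1)
    # target uniform step: resolve the fastest retained mode comfortably
    dt = min(0.25 * dr**2 / D, (t_grid[-1] or 1.0) / 400)

    # interior unknowns v_1..v_{n-1}
    m = n_shells - 1
    v = r * c_init
    v[-1] = R * c_out
    profiles: list[RadialProfile] = []
    t_now = 0.0
    targets = iter(t_grid)
    target = next(targets)
    done = False
    n_startup = 4

    def emit(time: float, v: np.ndarray) -> None:
        u = np.empty_like(v)
        u[1:] = v[1:] / r[1:]
        u[0] = u[1] + (u[1] - u[2]) * 0.5  # central value by extrapolation
        profiles.append(RadialProfile(rho=r / R, concentration=u.copy(), time=time))

    if target == 0.0:
        emit(0.0, v)
        target = next(targets, None)
        if target is None:
            done = True

    step_count = 0
    while not done:
        h = min(dt, target - t_now)
        if h <= 0:
            raise RuntimeError("degenerate time step in oracle")
        theta = 1.0 if step_count < n_startup else 0.5
        lam_h = D / dr**2
        ab = np.zeros((3, m))
        ab[0, 1:] = -theta * lam_h * h
        ab[1, :] = 1.0 + 2 * theta * lam_h * h
        ab[2, :-1] = -theta * lam_h * h
        rhs = v[1:-1] + (1 - theta) * h * lam_h * (v[2:] - 2 * v[1:-1] + v[:-2])
        # boundary contributions (v[0] = 0 fixed, v[-1] fixed)
        rhs[-1] += theta * lam_h * h * v[-1]
        v_new = solve_banded((1, 1), ab, rhs)
        if not np.all(np.isfinite(v_new)):
            raise RuntimeError("oracle time stepping became unstable")
        v[1:-1] = v_new
        t_now += h
        step_count += 1
        if abs(t_now - target) < 1e-15 * max(1.0, target):
            emit(target, v)
            target = next(targets, None)
            if target is None:
                done = True
    return profiles


def membrane_flux(
    c_out: float, c_in: float, D_m: float, d: float
) -> tuple[float, float]:
    """Fick's-first-law one-way fluxes across the membrane, per unit area.

    Returns ``(J_plus, J_minus) = (D_m/d * c_out, D_m/d * c_in)`` in
    mM * um / s; the net influx is their difference.
    """
    if d <= 0:
        raise ValueError("membrane thickness d must be > 0")
    if c_out < 0 or c_in < 0:
        raise ValueError("concentrations must be >= 0")
    k = D_m / d
    return k * c_out, k * c_in
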