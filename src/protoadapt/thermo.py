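"""Entropy production and energy dissipation of the one-component model.

For a process with one-way forward and reverse rates J+ and J-, the entropy
production rate is (J+ - J-) * ln(J+/J-), in units of k_B per time.  For
transmembrane ligand diffusion the one-way fluxes follow Fick's first law,
J+ = (D_m/d) c_out and J- = (D_m/d) c_in per unit membrane area, giving for
the whole cell of radius R

    sigma = 4 pi R^2 (D_m/d) nu (c_out - c_in) ln(c_out / c_in)    [k_B / s]

with nu the number density of a 1 mM solution (6.022e5 molecules/um^3), zero
exactly at steady state (c_in = c_out) and positive only while a concentration
gradient across the membrane persists.  The energy dissipation rate is the
entropy rate times the temperature: numerically equal in k_B*T/s.  This energy
is paid by the changing environment, not by the cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import CellGeometry, DiffusionParams

__all__ = [
    "NUMBER_DENSITY_PER_MM",
    "entropy_production_pair",
    "cell_dissipation_rate",
    "dissipation_series",
    "DissipationSeries",
]

#: molecules per um^3 in a 1 mM solution
NUMBER_DENSITY_PER_MM = 6.02214076e5

#: concentration floor (mM) applied before logarithms
FLOOR_MM = 1e-12


@dataclass
class DissipationSeries:
    """Entropy (k_B/s) and energy (k_B T/s) dissipation rates along a trajectory."""

    t: np.ndarray
    entropy_rate: np.ndarray
    energy_rate: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, "entropy_rate": self.entropy_rate, "energy_rate": self.energy_rate}
        )


def entropy_production_pair(J_plus, J_minus):
    """Entropy production rate (J+ - J-) ln(J+/J-) of one forward/reverse pair.

    Nonnegative, zero iff J+ = J-, symmetric under swapping the arguments.
    Units: k_B per unit time, for rates in events per unit time.
    """
    jp = np.asarray(J_plus, dtype=float)
    jm = np.asarray(J_minus, dtype=float)
    if np.any(jp <= 0) or np.any(jm <= 0):
        raise ValueError(
            "one-way rates must be > 0 (the log diverges); floor concentrations first"
        )
    out = (jp - jm) * np.log(jp / jm)
    return out if out.ndim else float(out)


def cell_dissipation_rate(
    c_out,
    c_in,
    diffusion: DiffusionParams,
    geom: CellGeometry,
) -> tuple:
    """Whole-cell entropy (k_B/s) and energy (k_B T/s) dissipation rates.

    Applies the Fick's-law flux pair over the full membrane area 4*pi*R^2.
    Concentrations are floored at 1e-12 mM before the log ratio so that zero
    stimuli remain well defined; equal concentrations give exactly zero.
    """
    co = np.maximum(np.asarray(c_out, dtype=float), FLOOR_MM)
    ci = np.maximum(np.asarray(c_in, dtype=float), FLOOR_MM)
    area = 4.0 * np.pi * geom.radius**2
    k = diffusion.permeability * NUMBER_DENSITY_PER_MM
    entropy = area * k * (co - ci) * np.log(co / ci)
    if entropy.ndim == 0:
        entropy = float(entropy)
    return entropy, entropy  # energy rate = T * entropy rate, in k_B T/s


def dissipation_series(trajectory, diffusion: DiffusionParams, geom: CellGeometry):
    """Dissipation accounting along a simulated one-component trajectory."""
    s, e = cell_dissipation_rate(trajectory.c_out, trajectory.c_in, diffusion, geom)
    return DissipationSeries(t=trajectory.t, entropy_rate=s, energy_rate=e)
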