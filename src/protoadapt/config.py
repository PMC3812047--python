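"""Domain types, configuration parsing and standard-scenario fixtures.

Units are fixed throughout the package: lengths in micrometres (um), times in
seconds (s), concentrations in millimolar (mM), energies in units of k_B*T and
entropy in units of k_B.  No unit conversion framework is provided.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = [
    "CellGeometry",
    "ReceptorParams",
    "StepStimulus",
    "GradientStimulus",
    "DiffusionParams",
    "TwoComponentParams",
    "SolverSettings",
    "SimulationConfig",
    "ConfigError",
    "load_config",
    "write_config",
    "make_fixture",
    "list_fixtures",
]


class ConfigError(ValueError):
    """Malformed configuration file or invariant violation."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class CellGeometry:
    """Spherical (or, in 2D, circular) cell geometry.

    Attributes
    ----------
    radius : float
        Cell radius R in um.
    receptor_inner_length : float
        Length l of the receptor's intracellular portion in um.  The internal
        ligand-binding site sits at radius R - l.
    """

    radius: float = 5.0
    receptor_inner_length: float = 0.5

    def __post_init__(self) -> None:
        _require(self.radius > 0, f"geometry.radius must be > 0, got {self.radius}")
        _require(
            0 < self.receptor_inner_length < self.radius,
            "geometry.receptor_inner_length must lie in (0, radius), got "
            f"{self.receptor_inner_length} with radius {self.radius}",
        )

    @property
    def rho(self) -> float:
        """Normalized radius (R - l)/R of the intracellular binding site."""
        return (self.radius - self.receptor_inner_length) / self.radius


@dataclass(frozen=True)
class ReceptorParams:
    """Two-site receptor dissociation constants and bias energy (one-component model).

    External ligand binding favors the *off* (inactive) receptor state, so the
    off-state external dissociation constant is the smaller one; internal binding
    favors the *on* (active) state.  The default constants are chosen symmetric
    (``K_off_out == K_on_in`` and ``K_on_out == K_off_in``), which makes the free
    energy collapse to the bias ``epsilon`` whenever the internal concentration
    equals the external one -- the analytic root of precise adaptation.
    """

    K_off_out: float = 0.01
    K_on_out: float = 100.0
    K_off_in: float = 100.0
    K_on_in: float = 0.01
    epsilon: float = 0.0  # k_B T, bias toward off in absence of ligand

    def __post_init__(self) -> None:
        for name in ("K_off_out", "K_on_out", "K_off_in", "K_on_in"):
            _require(getattr(self, name) > 0, f"receptor.{name} must be > 0")
        _require(
            self.K_off_out < self.K_on_out,
            "external binding must favor the off state (K_off_out < K_on_out)",
        )
        _require(
            self.K_on_in < self.K_off_in,
            "internal binding must favor the on state (K_on_in < K_off_in)",
        )


@dataclass(frozen=True)
class StepStimulus:
    """External concentration step c0 -> c1 at time t_step (concentrations in mM)."""

    c0: float = 1.0
    c1: float = 1.5
    t_step: float = 0.1

    def __post_init__(self) -> None:
        _require(self.c0 >= 0, f"stimulus.c0 must be >= 0, got {self.c0}")
        _require(self.c1 >= 0, f"stimulus.c1 must be >= 0, got {self.c1}")
        _require(self.t_step >= 0, "stimulus.t_step must be >= 0")


@dataclass(frozen=True)
class GradientStimulus:
    """Linear spatial gradient across the cell, switched on at ``onset``.

    Before onset the external field is uniform at ``c_init``; afterwards it is
    linear in x, equal to ``c_rear`` at x = -R and ``c_front`` at x = +R.
    """

    c_init: float = 0.5
    c_rear: float = 0.0
    c_front: float = 1.0
    onset: float = 0.0

    def __post_init__(self) -> None:
        _require(self.c_init >= 0, "stimulus.c_init must be >= 0")
        _require(self.c_rear >= 0, "stimulus.c_rear must be >= 0")
        _require(self.c_front >= 0, "stimulus.c_front must be >= 0")
        _require(self.c_rear <= self.c_front, "stimulus requires c_rear <= c_front")

    def external(self, x: Any, R: float) -> Any:
        """External concentration at position(s) x (um) after onset."""
        return self.c_rear + (self.c_front - self.c_rear) * (x + R) / (2.0 * R)


@dataclass(frozen=True)
class DiffusionParams:
    """Diffusivities (um^2/s) and membrane geometry (um).

    ``D_alpha > D_betagamma`` is required: the small alpha subunit of the
    two-component model diffuses faster than the betagamma subunit, which is
    what delays the inhibitory arm of the incoherent feedforward loop.
    """

    D_ligand: float = 100.0
    D_alpha: float = 200.0
    D_betagamma: float = 20.0
    D_membrane: float = 1.0
    membrane_thickness: float = 0.005

    def __post_init__(self) -> None:
        for name in (
            "D_ligand",
            "D_alpha",
            "D_betagamma",
            "D_membrane",
            "membrane_thickness",
        ):
            _require(getattr(self, name) > 0, f"diffusion.{name} must be > 0")
        _require(
            self.D_alpha > self.D_betagamma,
            "diffusion requires D_alpha > D_betagamma",
        )

    @property
    def permeability(self) -> float:
        """Membrane permeability D_m/d in um/s."""
        return self.D_membrane / self.membrane_thickness


@dataclass(frozen=True)
class TwoComponentParams:
    """Parameters of the two-component (G-protein-like) model.

    The first component is a receptor biased off by ``epsilon1`` whose activity
    A1 follows the external concentration instantaneously.  It releases alpha
    and betagamma subunits at source concentration ``k_release * A1`` (mM); they
    diffuse over length scale ``L2`` to the second component, sampled at
    normalized radius ``rho2``.  The second component's subunit dissociation
    constants are symmetric (alpha tight-on / betagamma tight-off share
    ``K_tight``; the weak constants share ``K_weak``) so that equal alpha and
    betagamma concentrations cancel exactly in its free energy.
    """

    epsilon1: float = 2.0
    epsilon2: float = 0.0
    k_release: float = 0.1
    K_on1: float = 0.01
    K_off1: float = 100.0
    D_alpha: float = 200.0
    D_betagamma: float = 20.0
    L2: float = 2.5
    rho2: float = 0.5
    K_tight: float = 10.0
    K_weak: float = 1000.0

    def __post_init__(self) -> None:
        _require(
            self.D_alpha > self.D_betagamma,
            "two_component requires D_alpha > D_betagamma",
        )
        for name in ("k_release", "K_on1", "K_off1", "L2", "K_tight", "K_weak"):
            _require(getattr(self, name) > 0, f"two_component.{name} must be > 0")
        _require(0 < self.rho2 < 1, "two_component.rho2 must lie in (0, 1)")
        _require(
            self.K_on1 < self.K_off1,
            "first-component ligand binding must favor the on state (K_on1 < K_off1)",
        )
        _require(self.K_tight < self.K_weak, "two_component requires K_tight < K_weak")


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings shared by the simulators.

    ``dt``/``t_end`` define the uniform output time grid; ``series_tol`` is the
    absolute (mM) truncation tolerance of the diffusion series; ``floor`` is the
    concentration floor applied before logarithms in the thermodynamic accounting.
    """

    dt: float = 1e-3
    t_end: float = 2.0
    series_tol: float = 1e-12
    series_max_terms: int = 100_000
    floor: float = 1e-12
    # gradient2d settings
    n_r: int = 40
    n_theta: int = 96
    bc_mode: str = "dirichlet"  # or "robin"

    def __post_init__(self) -> None:
        _require(self.dt > 0, "solver.dt must be > 0")
        _require(self.t_end > self.dt, "solver.t_end must exceed solver.dt")
        _require(self.series_tol > 0, "solver.series_tol must be > 0")
        _require(self.floor > 0, "solver.floor must be > 0")
        _require(self.n_r >= 4, "solver.n_r must be >= 4")
        _require(self.n_theta >= 32, "solver.n_theta must yield >= 32 boundary nodes")
        _require(
            self.bc_mode in ("dirichlet", "robin"),
            f"solver.bc_mode must be 'dirichlet' or 'robin', got {self.bc_mode!r}",
        )


_SECTION_TYPES = {
    "geometry": CellGeometry,
    "receptor": ReceptorParams,
    "diffusion": DiffusionParams,
    "two_component": TwoComponentParams,
    "solver": SolverSettings,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full declarative simulation configuration (YAML-serializable).

    ``sweep`` carries optional scenario-level parameter sweeps (e.g. a list of
    post-step concentrations for the adaptation-time ladder, or the pair of
    equal-fold steps for the fold-change-detection comparison).
    """

    geometry: CellGeometry = field(default_factory=CellGeometry)
    receptor: ReceptorParams = field(default_factory=ReceptorParams)
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    two_component: TwoComponentParams = field(default_factory=TwoComponentParams)
    solver: SolverSettings = field(default_factory=SolverSettings)
    stimulus: StepStimulus | GradientStimulus = field(default_factory=StepStimulus)
    sweep: dict = field(default_factory=dict)

    def replace(self, **kwargs: Any) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d: dict[str, Any] = {}
        for name, typ in _SECTION_TYPES.items():
            d[name] = dataclasses.asdict(getattr(self, name))
        stim = dataclasses.asdict(self.stimulus)
        stim["kind"] = "gradient" if isinstance(self.stimulus, GradientStimulus) else "step"
        d["stimulus"] = stim
        if self.sweep:
            d["sweep"] = dict(self.sweep)
        return d


def _build_section(name: str, typ: type, data: Mapping[str, Any]) -> Any:
    valid = {f.name for f in dataclasses.fields(typ)}
    for key in data:
        if key not in valid:
            raise ConfigError(f"unknown key '{name}.{key}' (valid: {sorted(valid)})")
    return typ(**data)


def config_from_dict(raw: Mapping[str, Any]) -> SimulationConfig:
    """Build a validated :class:`SimulationConfig` from a plain mapping.

    Unset sections and keys receive the documented defaults.
    """
    if not isinstance(raw, Mapping):
        raise ConfigError("top-level config must be a mapping of sections")
    known = set(_SECTION_TYPES) | {"stimulus", "sweep"}
    for key in raw:
        if key not in known:
            raise ConfigError(f"unknown config section '{key}' (valid: {sorted(known)})")
    kwargs: dict[str, Any] = {}
    for name, typ in _SECTION_TYPES.items():
        kwargs[name] = _build_section(name, typ, raw.get(name, {}) or {})
    stim_raw = dict(raw.get("stimulus", {}) or {})
    kind = stim_raw.pop("kind", "step")
    if kind == "step":
        kwargs["stimulus"] = _build_section("stimulus", StepStimulus, stim_raw)
    elif kind == "gradient":
        kwargs["stimulus"] = _build_section("stimulus", GradientStimulus, stim_raw)
    else:
        raise ConfigError(f"stimulus.kind must be 'step' or 'gradient', got {kind!r}")
    kwargs["sweep"] = dict(raw.get("sweep", {}) or {})
    return SimulationConfig(**kwargs)


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a YAML configuration file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:  # pragma: no cover - message passthrough
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return config_from_dict(raw or {})


def write_config(config: SimulationConfig, path: str | Path) -> None:
    """Write a configuration as YAML; ``load_config`` round-trips it exactly."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


# ---------------------------------------------------------------------------
# Standard scenarios
# ---------------------------------------------------------------------------

_FIG6_STEPS = [0.1, 0.5, 1.0, 2.0, 3.0, 5.0]


def _fig3_step() -> SimulationConfig:
    return SimulationConfig(
        stimulus=StepStimulus(c0=1.0, c1=2.0, t_step=0.1),
        solver=SolverSettings(dt=1e-4, t_end=1.0),
        sweep={"rho_values": [0.5, 0.7, 0.9]},
    )


def _fig4_dissipation() -> SimulationConfig:
    return SimulationConfig(
        stimulus=StepStimulus(c0=1.0, c1=1.5, t_step=0.1),
        solver=SolverSettings(dt=1e-4, t_end=2.0),
    )


def _fig6_positive_steps() -> SimulationConfig:
    return SimulationConfig(
        stimulus=StepStimulus(c0=0.0, c1=_FIG6_STEPS[0], t_step=0.01),
        solver=SolverSettings(dt=2e-6, t_end=0.6),
        sweep={"c1_values": list(_FIG6_STEPS)},
    )


def _fig6_negative_steps() -> SimulationConfig:
    return SimulationConfig(
        stimulus=StepStimulus(c0=_FIG6_STEPS[0], c1=0.0, t_step=0.01),
        solver=SolverSettings(dt=2e-6, t_end=0.6),
        sweep={"c0_values": list(_FIG6_STEPS)},
    )


def _fig6_fcd_pair() -> SimulationConfig:
    return SimulationConfig(
        stimulus=StepStimulus(c0=0.1, c1=0.5, t_step=0.01),
        solver=SolverSettings(dt=1e-4, t_end=0.5),
        sweep={"pairs": [[0.1, 0.5], [0.2, 1.0]]},
    )


def _fig8_gradient() -> SimulationConfig:
    return SimulationConfig(
        stimulus=GradientStimulus(c_init=0.5, c_rear=0.0, c_front=1.0, onset=0.0),
        diffusion=DiffusionParams(D_ligand=10.0),
        solver=SolverSettings(dt=2e-3, t_end=6.0),
    )


_FIXTURES = {
    "fig3_step": _fig3_step,
    "fig4_dissipation": _fig4_dissipation,
    "fig6_positive_steps": _fig6_positive_steps,
    "fig6_negative_steps": _fig6_negative_steps,
    "fig6_fcd_pair": _fig6_fcd_pair,
    "fig8_gradient": _fig8_gradient,
}


def list_fixtures() -> list[str]:
    """Names of the documented standard scenarios."""
    return sorted(_FIXTURES)


def make_fixture(name: str) -> SimulationConfig:
    """Configuration reproducing one of the standard model scenarios.

    * ``fig3_step`` -- one-component step 1 -> 2 mM, receptor-length sweep.
    * ``fig4_dissipation`` -- step 1 -> 1.5 mM with dissipation accounting.
    * ``fig6_positive_steps`` -- steps 0 -> {0.1, 0.5, 1, 2, 3, 5} mM.
    * ``fig6_negative_steps`` -- the reverse steps down to 0 mM.
    * ``fig6_fcd_pair`` -- equal-fold steps 0.1 -> 0.5 and 0.2 -> 1 mM.
    * ``fig8_gradient`` -- uniform 0.5 mM, then 0 mM (rear) to 1 mM (front).
    """
    try:
        factory = _FIXTURES[name]
    except KeyError:
        raise ConfigError(
            f"unknown scenario {name!r}; available: {', '.join(list_fixtures())}"
        ) from None
    return factory()
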