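"""Model parameters, experiment settings, and TOML config I/O.

All quantities are nondimensional.  The single cell radius sets the length
unit, the movement-cycle timestep the time unit, and the ligand–receptor
force/energy scales are expressed in the matching nondimensional units.
Dimensional anchors reported for the reference parameter set (documentation
only, never used in computation): a cell radius of order 10 um, a movement
cycle of order 10 min, and traction forces of order pN per ligand–receptor
complex.
"""

from __future__ import annotations

import dataclasses
import io
import tomllib
from dataclasses import dataclass, field, fields
from typing import Literal

__all__ = [
    "ModelParams",
    "ExperimentSpec",
    "ConfigError",
    "case_to_modes",
    "load_params",
    "loads_params",
    "save_params",
    "dumps_params",
]

SiteMode = Literal["static", "dynamic"]

#: Case label -> (C-C site mode, C-M site mode).
_CASE_MODES: dict[str, tuple[SiteMode, SiteMode]] = {
    "I": ("static", "static"),
    "II": ("static", "dynamic"),
    "III": ("dynamic", "static"),
    "IV": ("dynamic", "dynamic"),
}


class ConfigError(ValueError):
    """Raised for unparsable configs, unknown keys, or invariant violations."""


@dataclass(frozen=True)
class ModelParams:
    """Complete nondimensional parameter set for one simulation run.

    Defaults are the reference parameter set of the model: cell radius 1,
    timestep 0.01, 100 sites of each receptor type, ECM viscosity 0.0016,
    cutoff radius 1, adhesion energy scale 0.004, repulsive energy scale
    0.025, compressibility 0.5, adhesivity 1, force per ligand–receptor
    complex 0.01.

    Attributes
    ----------
    R : float
        Cell radius (length unit).
    dt : float
        Integration timestep; one timestep is one complete movement cycle
        (protrusion, attachment, traction, detachment), synchronous for
        all cells.
    n_cc, n_cm : int
        Number of cell–cell adhesion sites and cell–matrix traction sites
        per cell.
    eta : float
        Viscosity of the extracellular matrix; enters the Stokes drag
        ``6*pi*eta*R``.
    r_cut : float
        Largest site–site separation at which a C-C adhesion bond acts.
    sigma0 : float
        Cell–cell adhesion energy scale.  This is a per-cell budget shared
        by the ``n_cc`` adhesion sites: each engaged site pair carries the
        energy scale ``sigma0 / n_cc`` (see :mod:`adhesim.forces`).
    eps : float
        Cell–cell repulsive energy scale (deformation cost).
    alpha : float
        Compressibility: fraction of the radius that can deform.  Centers
        can never approach closer than the core diameter ``2*R*(1-alpha)``.
    K : float
        Adhesivity function value, identical for all C-M sites.
    f_lr : float
        Traction force per ligand–receptor complex; each matrix-exposed C-M
        site contributes ``K*f_lr`` radially outward.
    cc_mode, cm_mode : {"static", "dynamic"}
        Whether C-C / C-M sites are resampled uniformly on the sphere after
        every completed timestep.
    decay_exponent : float or None
        Exponent ``p`` of the adhesion depletion law
        ``sigma(t) = sigma0 * (1 - (t/t_total)**p)``; ``None`` keeps the
        adhesion scale constant.
    t_total : float
        Total simulated time.
    wall_force_cap : float
        Finite magnitude standing in for the infinite wall force of the
        incompressible core; keeps the ODE integrable.
    seed : int
        Seed of the run's random stream.
    """

    R: float = 1.0
    dt: float = 0.01
    n_cc: int = 100
    n_cm: int = 100
    eta: float = 0.0016
    r_cut: float = 1.0
    sigma0: float = 0.004
    eps: float = 0.025
    alpha: float = 0.5
    K: float = 1.0
    f_lr: float = 0.01
    cc_mode: SiteMode = "static"
    cm_mode: SiteMode = "static"
    decay_exponent: float | None = None
    t_total: float = 8.0
    wall_force_cap: float = 1e3
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def core_diameter(self) -> float:
        """Center distance below which the infinite-wall force acts."""
        return 2.0 * self.R * (1.0 - self.alpha)

    @property
    def drag(self) -> float:
        """Stokes drag coefficient ``6*pi*eta*R``."""
        import math

        return 6.0 * math.pi * self.eta * self.R

    def with_case(self, case: str) -> "ModelParams":
        """Return a copy with ``cc_mode``/``cm_mode`` set from a case label."""
        cc, cm = case_to_modes(case)
        return self.replace(cc_mode=cc, cm_mode=cm)

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    # -- validation ---------------------------------------------------------
    def validate(self) -> None:
        """Check every invariant; raise :class:`ConfigError` naming the field."""

        def positive(name: str) -> None:
            v = getattr(self, name)
            if not (v > 0):
                raise ConfigError(f"{name} must be > 0, got {v!r}")

        def nonneg(name: str) -> None:
            v = getattr(self, name)
            if not (v >= 0):
                raise ConfigError(f"{name} must be >= 0, got {v!r}")

        for name in ("R", "dt", "eta", "r_cut", "wall_force_cap"):
            positive(name)
        for name in ("sigma0", "eps", "f_lr", "K"):
            nonneg(name)
        for name in ("n_cc", "n_cm"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 0):
                raise ConfigError(f"{name} must be a nonnegative integer, got {v!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(
                f"alpha must lie strictly in (0, 1), got {self.alpha!r}"
            )
        if self.t_total < self.dt:
            raise ConfigError(
                f"t_total must be >= dt, got t_total={self.t_total!r}, dt={self.dt!r}"
            )
        for name in ("cc_mode", "cm_mode"):
            v = getattr(self, name)
            if v not in ("static", "dynamic"):
                raise ConfigError(f"{name} must be 'static' or 'dynamic', got {v!r}")
        p = self.decay_exponent
        if p is not None and not (p > 0):
            raise ConfigError(f"decay_exponent must be > 0 or None, got {p!r}")
        if not isinstance(self.seed, int):
            raise ConfigError(f"seed must be an integer, got {self.seed!r}")


@dataclass(frozen=True)
class ExperimentSpec:
    """A sweep protocol: a list of parameter points with replicate runs.

    Each *point* is a mapping of :class:`ModelParams` field names to values,
    overriding ``base`` at that grid point.  Run ``k`` at point ``i`` uses
    seed ``base_seed + i * runs_per_point + k``, so seed sets are disjoint
    across points and independent of iteration order.
    """

    base: ModelParams = field(default_factory=ModelParams)
    points: tuple[dict, ...] = ((),)
    runs_per_point: int = 100
    case: str = "I"
    init_kind: Literal["pair", "cluster"] = "pair"
    d0: float | None = None  # pair separation; None -> touching (2R)
    n_cells: int = 2
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.runs_per_point < 1:
            raise ConfigError(
                f"runs_per_point must be >= 1, got {self.runs_per_point!r}"
            )
        if self.case not in _CASE_MODES:
            raise ConfigError(f"unknown case label {self.case!r}; expected I-IV")
        if self.init_kind not in ("pair", "cluster"):
            raise ConfigError(f"init_kind must be 'pair' or 'cluster'")
        if self.d0 is not None and self.d0 <= self.base.core_diameter:
            raise ConfigError(
                f"d0 must exceed the core-exclusion distance "
                f"{self.base.core_diameter}, got {self.d0!r}"
            )
        object.__setattr__(self, "points", tuple(dict(p) for p in self.points))

    def params_at(self, point_index: int, run_index: int) -> ModelParams:
        """Resolved parameters for one run of one grid point."""
        if not 0 <= point_index < len(self.points):
            raise IndexError(point_index)
        if not 0 <= run_index < self.runs_per_point:
            raise IndexError(run_index)
        overrides = dict(self.points[point_index])
        overrides["seed"] = (
            self.base_seed + point_index * self.runs_per_point + run_index
        )
        cc, cm = case_to_modes(self.case)
        overrides.setdefault("cc_mode", cc)
        overrides.setdefault("cm_mode", cm)
        return self.base.replace(**overrides)


def case_to_modes(case: str) -> tuple[SiteMode, SiteMode]:
    """Map a site-dynamics case label I-IV to ``(cc_mode, cm_mode)``.

    Case I holds both receptor families fixed (persistent motion), case II
    resamples C-M sites each movement cycle, case III resamples C-C sites,
    and case IV resamples both.
    """
    try:
        return _CASE_MODES[case]
    except KeyError:
        raise ConfigError(
            f"unknown case label {case!r}; expected one of I, II, III, IV"
        ) from None


# ---------------------------------------------------------------------------
# Config file I/O.  Dialect: TOML with a [model] table (ModelParams fields),
# and optional [experiment] / [output] tables passed through unvalidated to
# the experiment layer.
# ---------------------------------------------------------------------------

_MODEL_FIELDS = {f.name for f in fields(ModelParams)}
_INT_FIELDS = {"n_cc", "n_cm", "seed"}


def loads_params(text: str) -> ModelParams:
    """Parse a TOML config string into a validated :class:`ModelParams`.

    An empty document (or one without a ``[model]`` table) yields the full
    default parameter set.  Unknown keys in ``[model]`` are rejected by name;
    ``decay_exponent = "none"`` is accepted as the constant-adhesion setting.
    """
    try:
        doc = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"config parse failure: {exc}") from exc
    model = doc.get("model", {})
    if not isinstance(model, dict):
        raise ConfigError("[model] must be a table of key/value pairs")
    unknown = set(model) - _MODEL_FIELDS
    if unknown:
        raise ConfigError(
            "unknown keys in [model]: " + ", ".join(sorted(unknown))
        )
    kwargs = {}
    for key, value in model.items():
        if key == "decay_exponent" and value == "none":
            value = None
        if key in _INT_FIELDS:
            if not isinstance(value, int):
                raise ConfigError(f"{key} must be an integer, got {value!r}")
        elif key not in ("cc_mode", "cm_mode", "decay_exponent"):
            value = float(value)
        kwargs[key] = value
    return ModelParams(**kwargs)


def load_params(path) -> ModelParams:
    """Read and validate a TOML config file (see :func:`loads_params`)."""
    with open(path, "r", encoding="utf-8") as fh:
        return loads_params(fh.read())


def _toml_scalar(value) -> str:
    if value is None:
        return '"none"'
    if isinstance(value, bool):  # pragma: no cover - no bool fields today
        return "true" if value else "false"
    if isinstance(value, str):
        return '"' + value.replace("\\", "\\\\").replace('"', '\\"') + '"'
    return repr(value)


def dumps_params(params: ModelParams) -> str:
    """Serialize to the TOML dialect read by :func:`loads_params`.

    Keys are emitted in sorted order so equal parameter sets serialize to
    byte-identical documents.
    """
    out = io.StringIO()
    out.write("[model]\n")
    for name in sorted(_MODEL_FIELDS):
        out.write(f"{name} = {_toml_scalar(getattr(params, name))}\n")
    return out.getvalue()


def save_params(params: ModelParams, path) -> None:
    """Write :func:`dumps_params` output to ``path``."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(dumps_params(params))
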