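"""Scenario configuration: schema, loading, and built-in fixtures.

A scenario is one JSON document describing the geometry, the window set,
the source, the simulation parameters and the task to run.  The built-in
fixtures reproduce the package's reference scenarios (two windows on the
half-plane boundary swept over source distance and angle; three and five
windows for source recovery; the disk Re/Ro stability sweep; a disk in a
strip) so that nothing needs to be downloaded or checked in as data.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .errors import ConfigurationError, RegimeWarning
from .geometry import (
    ExteriorDisk,
    Geometry,
    HalfPlane,
    SourceSpec,
    StripWithDisk,
    WindowSet,
)
from .hybrid import HybridConfig

__all__ = [
    "ScenarioConfig",
    "load_config",
    "make_fixture",
    "fig3_scenarios",
    "FIG3_L_VALUES",
    "FIG3_THETA_GRID",
    "FIG6_RE_VALUES",
    "FIG6_RO_VALUES",
]

SCHEMA_VERSION = 1

# Reference sweeps: two windows a unit distance apart on the boundary line,
# source at distance L and angle theta from the perpendicular axis.
FIG3_L_VALUES = (2.0, 5.0, 10.0)
FIG3_THETA_GRID = tuple(np.linspace(-1.2, 1.2, 9))
# Inner/outer artificial-boundary sweep for the stability study (disk R=1).
FIG6_RE_VALUES = (1.3, 2.0, 3.0)
FIG6_RO_VALUES = (3.5, 5.0)


class GeometryBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    kind: Literal["half_plane", "exterior_disk", "strip_with_disk"]
    R: Optional[float] = None
    a: Optional[float] = None
    side: int = 1

    def build(self) -> Geometry:
        if self.kind == "half_plane":
            return HalfPlane(side=self.side)
        if self.kind == "exterior_disk":
            if self.R is None:
                raise ConfigurationError("exterior_disk requires field 'R'")
            return ExteriorDisk(R=self.R)
        if self.R is None or self.a is None:
            raise ConfigurationError("strip_with_disk requires fields 'R' and 'a'")
        return StripWithDisk(R=self.R, a=self.a)


class WindowsBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    eps: float = Field(gt=0)
    centers: Optional[list[tuple[float, float]]] = None
    angles: Optional[list[float]] = None
    ys: Optional[list[float]] = None

    @model_validator(mode="after")
    def _one_of(self):
        given = [v is not None for v in (self.centers, self.angles, self.ys)]
        if sum(given) != 1:
            raise ValueError("give exactly one of 'centers', 'angles', 'ys'")
        return self

    def build(self, geom: Geometry) -> WindowSet:
        if self.centers is not None:
            ws = WindowSet(np.asarray(self.centers, dtype=float), self.eps)
        elif self.ys is not None:
            ws = WindowSet.on_line(self.ys, self.eps)
        else:
            R = getattr(geom, "R", None)
            if R is None:
                raise ConfigurationError("'angles' windows need a disk geometry")
            ws = WindowSet.from_angles(self.angles, self.eps, R)
        return ws


class SourceBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    x0: tuple[float, float]
    D: float = Field(default=1.0, gt=0)
    Q: float = Field(default=1.0, gt=0)

    def build(self) -> SourceSpec:
        return SourceSpec(x0=np.asarray(self.x0), Q=self.Q, D=self.D)


class SimulationBlock(BaseModel):
    model_config = ConfigDict(extra="forbid")
    re: Optional[float] = None
    ro: Optional[float] = None
    dt: Optional[float] = None
    n: int = Field(default=100_000, ge=1)
    seed: int = 0
    max_reinjections: int = Field(default=10_000, ge=1)
    adaptive: bool = True
    cap_factor: float = Field(default=9.0, ge=1.0)

    def build(self) -> HybridConfig:
        return HybridConfig(re=self.re, ro=self.ro, dt=self.dt, n=self.n,
                            seed=self.seed,
                            max_reinjections=self.max_reinjections,
                            adaptive=self.adaptive, cap_factor=self.cap_factor)


class ScenarioConfig(BaseModel):
    """Validated scenario description (schema version 1)."""

    model_config = ConfigDict(extra="forbid")
    schema_version: int = SCHEMA_VERSION
    task: Literal["flux", "simulate", "recover", "sensitivity-map"] = "flux"
    geometry: GeometryBlock
    windows: WindowsBlock
    source: SourceBlock
    simulation: SimulationBlock = SimulationBlock()
    observed: Optional[list[float]] = None
    eta: float = Field(default=0.0, ge=0.0)

    @model_validator(mode="after")
    def _check(self):
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema_version {self.schema_version}")
        geom = self.geometry.build()
        ws = self.windows.build(geom)
        ws.validate(geom)  # may emit RegimeWarning at load time
        src = self.source.build()
        src.validate(geom, ws)
        return self

    def build(self):
        """-> (geometry, windows, source, hybrid config)."""
        geom = self.geometry.build()
        ws = self.windows.build(geom)
        return geom, ws, self.source.build(), self.simulation.build()

    def canonical_json(self) -> str:
        return json.dumps(self.model_dump(), sort_keys=True, separators=(",", ":"))


def load_config(path) -> ScenarioConfig:
    """Load and validate a scenario JSON file; unknown keys are rejected."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{path} is not valid JSON: {exc}") from exc
    try:
        return ScenarioConfig.model_validate(payload)
    except Exception as exc:
        raise ConfigurationError(f"invalid scenario config {path}: {exc}") from exc


_FIXTURES = ("fig3_halfplane", "fig4_three_windows", "fig4_five_windows",
             "fig6_disk_stability", "strip_demo")


def make_fixture(name: str, *, L: float = 5.0, theta: float = 0.5,
                 n: int = 100_000, seed: int = 0) -> ScenarioConfig:
    """Built-in reference scenarios.

    ``fig3_halfplane`` accepts the source polar coordinates ``L`` and
    ``theta`` (distance from the window midpoint, angle from the
    perpendicular-to-boundary axis) so the full sweep over
    ``FIG3_L_VALUES x FIG3_THETA_GRID`` can be generated.
    """
    if name == "fig3_halfplane":
        x0 = (L * np.cos(theta), L * np.sin(theta))
        return ScenarioConfig(
            task="simulate",
            geometry=GeometryBlock(kind="half_plane", side=1),
            windows=WindowsBlock(ys=[0.5, -0.5], eps=0.1),
            source=SourceBlock(x0=x0),
            simulation=SimulationBlock(n=n, seed=seed),
        )
    if name == "fig4_three_windows":
        return ScenarioConfig(
            task="recover",
            geometry=GeometryBlock(kind="half_plane", side=-1),
            windows=WindowsBlock(ys=[-1.0, 0.0, 1.0], eps=0.1),
            source=SourceBlock(x0=(-2.0, 8.0)),
            simulation=SimulationBlock(n=n, seed=seed),
        )
    if name == "fig4_five_windows":
        return ScenarioConfig(
            task="recover",
            geometry=GeometryBlock(kind="half_plane", side=-1),
            windows=WindowsBlock(ys=[-2.0, -1.0, 0.0, 1.0, 2.0], eps=0.1),
            source=SourceBlock(x0=(-2.0, 8.0)),
            simulation=SimulationBlock(n=n, seed=seed),
        )
    if name == "fig6_disk_stability":
        return ScenarioConfig(
            task="simulate",
            geometry=GeometryBlock(kind="exterior_disk", R=1.0),
            windows=WindowsBlock(angles=[0.0, 2.0 * np.pi / 3.0], eps=0.1),
            source=SourceBlock(x0=(5.0 * np.cos(0.5), 5.0 * np.sin(0.5))),
            simulation=SimulationBlock(n=n, seed=seed,
                                       re=FIG6_RE_VALUES[0], ro=FIG6_RO_VALUES[0]),
        )
    if name == "strip_demo":
        return ScenarioConfig(
            task="simulate",
            geometry=GeometryBlock(kind="strip_with_disk", R=1.0, a=2.0),
            windows=WindowsBlock(angles=[0.5, -0.5], eps=0.1),
            source=SourceBlock(x0=(6.0, 0.5)),
            simulation=SimulationBlock(n=n, seed=seed, re=2.0, ro=4.0),
        )
    raise ConfigurationError(f"unknown fixture {name!r}; choose from {_FIXTURES}")


def fig3_scenarios(*, n: int = 100_000, seed: int = 0):
    """The full (L, theta) sweep of the two-window half-plane study."""
    out = []
    for L in FIG3_L_VALUES:
        for th in FIG3_THETA_GRID:
            out.append(((L, th), make_fixture("fig3_halfplane", L=L, theta=th,
                                              n=n, seed=seed)))
    return out
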