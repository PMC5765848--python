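"""Result containers shared by the analytic and stochastic routes."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class SplittingResult:
    """Per-window splitting probabilities with provenance.

    ``probabilities`` always sums to one: analytically by construction,
    in simulations because every trajectory is absorbed at exactly one
    window (the last entry is computed as one minus the rest to keep the
    floating-point sum exact).
    """

    probabilities: np.ndarray
    provenance: str  # "analytic" | "simulated"
    stderr: Optional[np.ndarray] = None
    n: Optional[int] = None
    seed: Optional[int] = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)

    @property
    def n_windows(self) -> int:
        return self.probabilities.size

    def to_frame(self) -> pd.DataFrame:
        data = {
            "window": np.arange(self.n_windows),
            "probability": self.probabilities,
        }
        if self.stderr is not None:
            data["stderr"] = self.stderr
        return pd.DataFrame(data)

    def to_dict(self) -> dict:
        return {
            "probabilities": self.probabilities.tolist(),
            "stderr": None if self.stderr is None else self.stderr.tolist(),
            "n": self.n,
            "seed": self.seed,
            "provenance": self.provenance,
            "diagnostics": dict(self.diagnostics),
        }


@dataclass
class WindowSystemSolution:
    """Solution of the matched-asymptotic linear system.

    ``A`` holds the window flux coefficients A_1..A_N, ``C`` the matching
    constant; the splitting probabilities are ``P_i = pi * A_i`` and sum to
    one.  ``delta123`` carries the determinant diagnostic of the explicit
    three-window solution when applicable.
    """

    A: np.ndarray
    C: float
    delta123: Optional[float] = None
    cond: Optional[float] = None

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)

    @property
    def probabilities(self) -> np.ndarray:
        return np.pi * self.A

    def as_splitting_result(self) -> SplittingResult:
        return SplittingResult(self.probabilities, provenance="analytic",
                               diagnostics={"C": self.C, "cond": self.cond})


@dataclass
class SensitivityResult:
    """Directional sensitivity of a two-window receptor pair."""

    ratio: float                    # |P1 - P2|
    threshold: Optional[float] = None   # max over window placements
    threshold_asymptotic: Optional[float] = None
    two_class_product: Optional[float] = None
    L: Optional[float] = None
    theta: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class UncertaintyRegion:
    """Image of a multiplicative flux-perturbation box under recovery."""

    points: np.ndarray          # (M, 2) recovered positions
    hull_vertices: np.ndarray   # (K, 2) convex hull, closed order
    area: float
    eta: float
    partial: bool = False       # some perturbation corners were unsolvable

    def contains_point(self, p, tol: float = 1e-9) -> bool:
        """Point-in-convex-hull test (supports degenerate hulls)."""
        p = np.asarray(p, dtype=float)
        if self.points.shape[0] == 1:
            return bool(np.hypot(*(self.points[0] - p)) <= tol)
        verts = self.hull_vertices
        if verts.shape[0] < 3:
            d = self.points - p
            return bool(np.min(np.hypot(d[:, 0], d[:, 1])) <= tol)
        v = np.roll(verts, -1, axis=0) - verts
        w = p - verts
        cross = v[:, 0] * w[:, 1] - v[:, 1] * w[:, 0]
        return bool(np.all(cross >= -tol) or np.all(cross <= tol))


@dataclass
class RecoveryResult:
    """Recovered source position and diagnostics."""

    position: np.ndarray
    residual_norm: float
    candidates: np.ndarray      # (k, 2) distinct converged roots
    ambiguous: bool = False
    n_starts_converged: int = 0
    region: Optional[UncertaintyRegion] = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.candidates = np.atleast_2d(np.asarray(self.candidates, dtype=float))

    def to_dict(self) -> dict:
        d = {
            "position": self.position.tolist(),
            "residual_norm": self.residual_norm,
            "candidates": self.candidates.tolist(),
            "ambiguous": self.ambiguous,
            "n_starts_converged": self.n_starts_converged,
        }
        if self.region is not None:
            d["region"] = {
                "eta": self.region.eta,
                "area": self.region.area,
                "hull_vertices": self.region.hull_vertices.tolist(),
                "partial": self.region.partial,
            }
        return d
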