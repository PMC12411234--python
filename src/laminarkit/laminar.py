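"""Equivolume depth construction and data-driven laminar compartmentalization.

Depth convention: index 0 is the CSF/GM boundary (superficial), the last index
the GM/WM boundary (deep).  Profiles carry D = 21 depths; compartmentalization
first removes the two deepest depths and works on the retained 19-point grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import NoLaminarStructureError

__all__ = [
    "N_DEPTHS",
    "N_RETAINED",
    "DepthProfileField",
    "LayerCompartments",
    "ThicknessRecord",
    "equivolume_depths",
    "compartmentalize_profile",
    "compartment_thickness",
]

N_DEPTHS = 21
N_RETAINED = 19  # after dropping the two deepest depths


@dataclass
class DepthProfileField:
    """Per-vertex depth profiles (vertices x D) with a modality tag."""

    values: np.ndarray
    modality: str = "qt1_ms"  # qt1_ms | qsm_ppm | amplitude_pct

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != N_DEPTHS:
            raise ValueError(f"expected {N_DEPTHS} depths, got {self.values.shape[1]}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("profile contains non-finite entries")
        if self.modality == "qt1_ms" and np.any(self.values <= 0):
            raise ValueError("qT1 values must be positive")

    def mean_profile(self) -> np.ndarray:
        return self.values.mean(axis=0)


@dataclass
class LayerCompartments:
    """Outer/middle/inner boundaries on the retained 19-depth grid.

    ``b1``/``b2`` are the integer grid indices of the derivative extrema;
    ``b1_frac``/``b2_frac`` are the sub-grid-refined boundary positions
    expressed as fractions of the retained depth range (0 = superficial edge,
    1 = deep edge of the retained grid).
    """

    b1: int
    b2: int
    b1_frac: float
    b2_frac: float

    def __post_init__(self):
        if not (0 < self.b1 < self.b2 < N_RETAINED):
            raise ValueError(f"require 0 < b1 < b2 < {N_RETAINED}")
        if not (0.0 < self.b1_frac < self.b2_frac < 1.0):
            raise ValueError("fractional boundaries must satisfy 0 < b1 < b2 < 1")

    @classmethod
    def from_spans(cls, outer: float, middle: float, inner: float) -> "LayerCompartments":
        total = outer + middle + inner
        b1f = outer / total
        b2f = (outer + middle) / total
        b1 = max(1, int(round(b1f * (N_RETAINED - 1))))
        b2 = min(N_RETAINED - 1 - 1, max(b1 + 1, int(round(b2f * (N_RETAINED - 1)))))
        return cls(b1, b2, b1f, b2f)

    def spans(self) -> tuple[float, float, float]:
        """Depth-fraction spans (outer, middle, inner); sum to 1."""
        return (self.b1_frac, self.b2_frac - self.b1_frac, 1.0 - self.b2_frac)

    def depth_indices(self, compartment: str) -> np.ndarray:
        """Depth indices (on the 21-depth grid) covered by a compartment."""
        if compartment == "outer":
            return np.arange(0, self.b1 + 1)
        if compartment == "middle":
            return np.arange(self.b1, self.b2 + 1)
        if compartment == "inner":
            return np.arange(self.b2, N_RETAINED)
        raise ValueError(f"unknown compartment {compartment!r}")

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "b1": int(self.b1),
                "b2": int(self.b2),
                "b1_frac": self.b1_frac,
                "b2_frac": self.b2_frac,
            },
            indent=2,
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str) -> "LayerCompartments":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                d = json.load(fh)
        return cls(d["b1"], d["b2"], d["b1_frac"], d["b2_frac"])


@dataclass
class ThicknessRecord:
    """Total and compartment thickness in mm."""

    total: float
    outer: float
    middle: float
    inner: float

    def __post_init__(self):
        if min(self.total, self.outer, self.middle, self.inner) < 0:
            raise ValueError("thickness values must be >= 0")
        if abs(self.outer + self.middle + self.inner - self.total) > 1e-9:
            raise ValueError("compartment thicknesses must sum to total")


def equivolume_depths(
    inner_boundary_area: float, outer_boundary_area: float, n_depths: int = N_DEPTHS
) -> np.ndarray:
    """Equivolume depth fractions for equispaced volume fractions.

    For volume fraction rho the normalized distance from the inner boundary is

        alpha(rho) = (sqrt(rho*A_out^2 + (1-rho)*A_in^2) - A_in) / (A_out - A_in)

    reducing to the equidistant grid when A_in == A_out (flat cortex limit).
    """
    a_in, a_out = float(inner_boundary_area), float(outer_boundary_area)
    if a_in <= 0 or a_out <= 0:
        raise ValueError("boundary areas must be > 0")
    if n_depths < 2:
        raise ValueError("n_depths must be >= 2")
    rho = np.linspace(0.0, 1.0, n_depths)
    if np.isclose(a_in, a_out):
        return rho
    return (np.sqrt(rho * a_out**2 + (1 - rho) * a_in**2) - a_in) / (a_out - a_in)


def _interior_extrema(d: np.ndarray) -> list[tuple[int, str]]:
    """Interior local extrema of a 1-D array; plateau ties resolved to the
    most superficial (lowest-index) plateau sample."""
    out = []
    for i in range(1, len(d) - 1):
        if d[i] > d[i - 1] and d[i] >= d[i + 1]:
            out.append((i, "max"))
        elif d[i] < d[i - 1] and d[i] <= d[i + 1]:
            out.append((i, "min"))
    return out


def _refine_extremum(d: np.ndarray, i: int, kind: str) -> float:
    """Sub-grid extremum location via a cubic-spline fit of the derivative,
    searched within one grid step of the integer extremum."""
    from scipy.interpolate import CubicSpline

    cs = CubicSpline(np.arange(len(d)), d)
    xs = np.linspace(max(0, i - 1), min(len(d) - 1, i + 1), 401)
    ys = cs(xs)
    j = int(np.argmax(ys)) if kind == "max" else int(np.argmin(ys))
    return float(xs[j])


def compartmentalize_profile(profile: np.ndarray | DepthProfileField) -> LayerCompartments:
    """Three-compartment segmentation of a 21-depth qT1 profile.

    The two deepest depths are removed, the first derivative is taken by
    second-order central differences on the retained 19 depths (one-sided
    stencils at the ends), and the two most prominent interior extrema of the
    derivative — ranked by absolute deviation of the derivative from its
    median — become the outer/middle and middle/inner boundaries, ordered
    superficial to deep.  Boundary locations are refined to sub-grid
    precision by a cubic-spline extremum search on the derivative, since
    thickness and AUC metrics are metric quantities.

    Raises
    ------
    NoLaminarStructureError
        If the derivative has fewer than two interior extrema (e.g. a
        strictly linear profile).
    """
    if isinstance(profile, DepthProfileField):
        profile = profile.mean_profile()
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (N_DEPTHS,):
        raise ValueError(f"expected a {N_DEPTHS}-depth profile")
    if np.any(profile <= 0):
        raise ValueError("qT1 profile values must be positive")

    retained = profile[:N_RETAINED]
    d = np.gradient(retained)
    extrema = _interior_extrema(d)
    if len(extrema) < 2:
        raise NoLaminarStructureError(
            "first derivative has fewer than two interior extrema; "
            "no laminar structure detected"
        )
    med = np.median(d)
    scored = sorted(extrema, key=lambda e: abs(d[e[0]] - med), reverse=True)
    picked = sorted(scored[:2], key=lambda e: e[0])
    (i1, k1), (i2, k2) = picked
    if i1 == i2:
        raise NoLaminarStructureError("boundary candidates collapse to one depth")
    f1 = _refine_extremum(d, i1, k1) / (N_RETAINED - 1)
    f2 = _refine_extremum(d, i2, k2) / (N_RETAINED - 1)
    return LayerCompartments(i1, i2, f1, f2)


def compartment_thickness(
    total_thickness: float,
    compartments: LayerCompartments,
    inner_boundary_area: float | None = None,
    outer_boundary_area: float | None = None,
) -> ThicknessRecord:
    """Convert depth-fraction spans to millimetre thickness.

    Without boundary areas the retained depth grid is treated as equidistant
    in physical depth.  When both areas are supplied the grid is treated as
    equivolume-placed: grid fractions are volume fractions and are mapped
    through the equivolume distance function before span computation.
    """
    if total_thickness <= 0:
        raise ValueError("total thickness must be > 0")

    b1f, b2f = compartments.b1_frac, compartments.b2_frac
    if inner_boundary_area is not None and outer_boundary_area is not None:
        # retained grid covers volume fractions [0, 0.9] of the full cortex,
        # measured from the superficial (outer) boundary
        full = (N_RETAINED - 1) / (N_DEPTHS - 1)

        def alpha(rho: float) -> float:
            # distance fraction from the superficial side for volume
            # fraction rho from the superficial side
            return 1.0 - _alpha_scalar(
                inner_boundary_area, outer_boundary_area, 1.0 - rho
            )

        top = alpha(full)
        b1f = alpha(b1f * full) / top
        b2f = alpha(b2f * full) / top

    outer = total_thickness * b1f
    middle = total_thickness * (b2f - b1f)
    inner = total_thickness - outer - middle
    return ThicknessRecord(total_thickness, outer, middle, inner)


def _alpha_scalar(a_in: float, a_out: float, rho: float) -> float:
    if np.isclose(a_in, a_out):
        return rho
    return (np.sqrt(rho * a_out**2 + (1 - rho) * a_in**2) - a_in) / (a_out - a_in)
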