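"""Parabolic strut geometry.

A freshly deposited strut on a flat substrate takes a parabolic cap
profile h(x) = H * (1 - (2x/a)^2), fully described by its vertex height
``H`` and width ``a``.  Two derived scalars drive everything downstream:

* vertex curvature  rho = 8 H / a**2   (the strut acts as a cylindrical
  lens of this surface curvature, which is what the striped-background
  imaging reads out), and
* cross-section area  kappa = (2/3) H a, whose product with the print
  speed gives the volumetric throughput Q.

All geometry is carried in millimetres; conversion to SI happens only at
the elongational-viscosity boundary (:mod:`strutkit.trajectory`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ParabolicStrut",
    "StrutGeometryReport",
    "PrintConditions",
    "height_profile",
    "vertex_curvature",
    "cross_section_area",
    "strut_from_observables",
    "throughput",
    "geometry_report",
]


@dataclass(frozen=True)
class ParabolicStrut:
    """Parabolic strut cross-section profile.

    Parameters
    ----------
    H : float
        Vertex height in mm (>= 0; H = 0 is the degenerate flat film).
    a : float
        Strut width in mm (> 0); the profile meets the substrate at
        x = +/- a/2.
    """

    H: float
    a: float

    def __post_init__(self) -> None:
        if not (self.H >= 0):
            raise ValueError(f"vertex height H must be >= 0, got {self.H}")
        if not (self.a > 0):
            raise ValueError(f"strut width a must be > 0, got {self.a}")


@dataclass(frozen=True)
class StrutGeometryReport:
    """Derived observables of a strut: curvature, area, throughput."""

    rho: float  # vertex curvature, 1/mm
    kappa: float  # cross-section area, mm^2
    Q: float  # volumetric throughput, mm^3/s

    def to_json(self, strut: ParabolicStrut | None = None) -> str:
        rec = {
            "rho_per_mm": self.rho,
            "kappa_mm2": self.kappa,
            "Q_mm3_per_s": self.Q,
        }
        if strut is not None:
            rec = {"H_mm": strut.H, "a_mm": strut.a, **rec}
        return json.dumps(rec)


@dataclass(frozen=True)
class PrintConditions:
    """Process conditions of a print run.

    ``density`` is the bulk ink density in kg/m^3 (default: water, the
    solvent of dilute alginate inks); ``gamma`` is the surface tension
    in N/m and may be zero when surface tension is neglected;
    ``nozzle_od`` is the nozzle outer diameter in mm used for image
    scale calibration (0.82 mm for a 21G needle).
    """

    v_p: float  # print speed, mm/s
    Q: float  # throughput, mm^3/s
    density: float = 1000.0  # kg/m^3
    g: float = 9.81  # m/s^2
    gamma: float = 0.0  # N/m
    nozzle_od: float = 0.82  # mm

    def __post_init__(self) -> None:
        if not (self.v_p > 0):
            raise ValueError("print speed v_p must be > 0")
        if not (self.Q > 0):
            raise ValueError("throughput Q must be > 0")
        if not (self.density > 0 and self.g > 0 and self.nozzle_od > 0):
            raise ValueError("density, g and nozzle_od must be > 0")
        if self.gamma < 0:
            raise ValueError("surface tension gamma must be >= 0")


def height_profile(strut: ParabolicStrut, x):
    """Height h(x) = H * (1 - (2x/a)^2) of the strut at lateral position x (mm).

    Raises
    ------
    ValueError
        If any |x| exceeds the half-width a/2.
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > strut.a / 2 + 1e-12):
        raise ValueError(f"|x| must be <= a/2 = {strut.a / 2} mm")
    h = strut.H * (1.0 - (2.0 * x / strut.a) ** 2)
    # clip the tiny negative values the epsilon-tolerance at x = +/- a/2 admits
    h = np.clip(h, 0.0, None)
    return h if h.ndim else float(h)


def vertex_curvature(strut: ParabolicStrut) -> float:
    """Vertex curvature rho = 8 H / a^2 (1/mm), reported as a magnitude.

    The signed second derivative of the profile is -8H/a^2 (concave
    down); by convention the positive value is returned.
    """
    return 8.0 * strut.H / strut.a**2


def cross_section_area(strut: ParabolicStrut) -> float:
    """Cross-section area kappa = (2/3) H a (mm^2), the integral of h(x)."""
    return 2.0 / 3.0 * strut.H * strut.a


def strut_from_observables(rho: float, kappa: float) -> ParabolicStrut:
    """Invert (rho, kappa) back to the strut: a = (12 kappa/rho)^(1/3), H = rho a^2 / 8."""
    if not (rho > 0):
        raise ValueError(f"rho must be > 0, got {rho}")
    if not (kappa > 0):
        raise ValueError(f"kappa must be > 0, got {kappa}")
    a = (12.0 * kappa / rho) ** (1.0 / 3.0)
    H = rho * a**2 / 8.0
    return ParabolicStrut(H=H, a=a)


def throughput(kappa: float, v_p: float) -> float:
    """Volumetric throughput Q = kappa * v_p (mm^3/s)."""
    if kappa < 0:
        raise ValueError("kappa must be >= 0")
    if not (v_p > 0):
        raise ValueError("v_p must be > 0")
    return kappa * v_p


def geometry_report(strut: ParabolicStrut, v_p: float) -> StrutGeometryReport:
    """Bundle curvature, area and throughput for a strut at print speed v_p."""
    kappa = cross_section_area(strut)
    return StrutGeometryReport(
        rho=vertex_curvature(strut),
        kappa=kappa,
        Q=throughput(kappa, v_p),
    )
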