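"""Elongational viscosity from the hanging strut's trajectory.

Between nozzle and substrate the extruded strut hangs freely and is
stretched by its own weight.  Dividing it into small cylindrical
elements and balancing elongational stress against gravity (and
optionally the Laplace pressure of the surface) gives, per element,

    eta_E = ( rho_m * g / (d alpha / d x)  -  2 * gamma / d(s) ) / (dv/ds)

where alpha is the pitch angle of the centerline against the horizontal,
d(s) the local diameter, gamma the surface tension and rho_m the mass
density.  Volume continuity closes the system: v(s) = 4 Q / (pi d(s)^2),
so the strain rate eps_dot = dv/ds follows from the diameter profile and
the set throughput Q alone.

Following the measurement protocol, derivatives are taken on fitted
parametric models rather than raw differences: the diameter profile is
fitted with an offset exponential decay

    d(s) = d_inf + (d0 - d_inf) * exp(-s / s_c)

and the pitch angle with a straight line in x, restricted to the viscous
stretching window near the nozzle (the region before the diameter
minimum, where elastic recovery takes over).  A raw finite-difference
mode is retained for diagnostics.

Geometry enters in mm; every quantity is converted to SI at this
module's boundary so eta_E emerges in Pa s.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter
from scipy.optimize import least_squares

__all__ = [
    "StrutTrajectory",
    "KinematicsProfile",
    "TrajectoryFit",
    "ViscosityCurve",
    "NonDecayingProfileError",
    "RegimeSelectionError",
    "PhysicalValidityError",
    "velocity_profile",
    "strain_rate",
    "select_viscous_regime",
    "fit_diameter_profile",
    "fit_pitch_angle",
    "fit_trajectory",
    "elongational_viscosity",
    "raw_viscosity_curve",
    "analyze_trajectory",
]


class NonDecayingProfileError(ValueError):
    """Diameter profile does not decay over the requested window."""


class RegimeSelectionError(ValueError):
    """No viscous-stretching window could be identified."""


class PhysicalValidityError(ValueError):
    """Force-balance inputs violate the stretching assumptions (m <= 0 or dv/ds <= 0)."""


@dataclass(frozen=True)
class StrutTrajectory:
    """Centerline and diameter of the hanging strut.

    ``s``: arc length from the nozzle exit (mm, strictly increasing);
    ``x``: horizontal coordinate (mm); ``alpha``: pitch angle against
    the x-axis (radians, positive downward-sagging); ``d``: local
    diameter (mm, > 0).  Externally alpha is stored in degrees
    (column ``alpha_deg``); radians internally.
    """

    s: np.ndarray
    x: np.ndarray
    alpha: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        for name in ("s", "x", "alpha", "d"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.s)
        if any(len(getattr(self, f)) != n for f in ("x", "alpha", "d")):
            raise ValueError("s, x, alpha, d must have equal length")
        if n < 8:
            raise ValueError("a trajectory needs at least 8 points")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("s must be strictly increasing")
        if np.any(self.d <= 0):
            raise ValueError("diameters must be > 0")

    def __len__(self) -> int:
        return len(self.s)

    @classmethod
    def from_csv(cls, path) -> "StrutTrajectory":
        df = pd.read_csv(path)
        return cls(
            s=df["s_mm"].to_numpy(),
            x=df["x_mm"].to_numpy(),
            alpha=np.deg2rad(df["alpha_deg"].to_numpy()),
            d=df["d_mm"].to_numpy(),
        )

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "s_mm": self.s,
                "x_mm": self.x,
                "alpha_deg": np.rad2deg(self.alpha),
                "d_mm": self.d,
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class KinematicsProfile:
    """Axial velocity, cross-section area and strain rate along the strut."""

    v: np.ndarray  # mm/s
    A: np.ndarray  # mm^2
    eps_dot: np.ndarray | None = None  # 1/s


@dataclass(frozen=True)
class TrajectoryFit:
    """Fitted parametric models of the trajectory over the viscous regime."""

    d0: float  # diameter at nozzle exit, mm
    d_inf: float  # asymptotic diameter, mm
    s_c: float  # decay length, mm
    m: float  # pitch-angle slope d alpha / d x, rad/mm
    regime: tuple[float, float]  # [s_start, s_end], mm

    def __post_init__(self) -> None:
        if not (self.d0 > self.d_inf >= 0):
            raise ValueError("stretching requires d0 > d_inf >= 0")
        if not (self.s_c > 0):
            raise ValueError("decay length s_c must be > 0")
        if not (self.regime[1] > self.regime[0]):
            raise ValueError("regime must be a nonempty interval")

    def diameter(self, s) -> np.ndarray:
        """Fitted d(s) = d_inf + (d0 - d_inf) exp(-s/s_c), mm."""
        s = np.asarray(s, dtype=float)
        return self.d_inf + (self.d0 - self.d_inf) * np.exp(-s / self.s_c)

    def to_json(self) -> str:
        return json.dumps(
            {
                "d0_mm": self.d0,
                "d_inf_mm": self.d_inf,
                "s_c_mm": self.s_c,
                "m_rad_per_mm": self.m,
                "regime_mm": list(self.regime),
            }
        )


@dataclass(frozen=True)
class ViscosityCurve:
    """Elongational viscosity versus strain rate along the strut."""

    eps_dot: np.ndarray  # 1/s
    eta_E: np.ndarray  # Pa s
    s: np.ndarray  # mm, sampling positions
    has_negative: bool = False  # some eta_E < 0 (model violated locally)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"eps_dot_per_s": self.eps_dot, "eta_E_Pa_s": self.eta_E, "s_mm": self.s}
        ).to_csv(path, index=False)


def velocity_profile(d, Q: float) -> KinematicsProfile:
    """Axial velocity from volume continuity: v = 4 Q / (pi d^2), A = pi d^2 / 4.

    d in mm, Q in mm^3/s; v in mm/s.  v * A = Q identically.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameters must be > 0")
    if not (Q > 0):
        raise ValueError("throughput Q must be > 0")
    A = math.pi * d**2 / 4.0
    return KinematicsProfile(v=Q / A, A=A)


def strain_rate(
    profile: KinematicsProfile, s, fit: TrajectoryFit | None = None
) -> np.ndarray:
    """Strain rate eps_dot = dv/ds (1/s) on the grid s (mm).

    With a diameter fit supplied, the closed form of the fitted
    exponential is used:

        eps_dot = (8 Q / (pi d^3)) * ((d0 - d_inf)/s_c) * exp(-s/s_c)

    otherwise v is differentiated numerically (second-order central
    differences; needs >= 3 points).
    """
    s = np.asarray(s, dtype=float)
    if fit is not None:
        Q = float(profile.v[0] * profile.A[0])  # mm^3/s, constant by construction
        d = fit.diameter(s)
        return (8.0 * Q / (math.pi * d**3)) * ((fit.d0 - fit.d_inf) / fit.s_c) * np.exp(
            -s / fit.s_c
        )
    if len(s) < 3:
        raise ValueError("numeric differentiation needs >= 3 points")
    return np.gradient(profile.v, s)


def select_viscous_regime(
    traj: StrutTrajectory,
    exclusion_points: int = 2,
    window: int = 5,
    rise_fraction: float = 0.05,
) -> tuple[float, float]:
    """Locate the viscous-stretching window [s_start, s_end].

    The diameter profile is smoothed with a moving median; its minimum
    marks the onset of elastic recovery and closes the window, provided
    the profile genuinely rises again afterwards (by more than
    ``rise_fraction`` of the profile's total range — below that the
    "minimum" is noise in a flat tail and the window extends to the last
    point).  The first ``exclusion_points`` grid points after the nozzle
    exit are excluded (die-swell / attachment region).  A profile that
    only grows has no stretching phase and is rejected.
    """
    d_s = median_filter(traj.d, size=window, mode="nearest")
    i_min = int(np.argmin(d_s))
    i_start = exclusion_points
    if i_min <= i_start:
        raise RegimeSelectionError(
            "no decaying section: smoothed diameter minimum at/before the exclusion zone"
        )
    rise = d_s[i_min:].max() - d_s[i_min]
    if rise < rise_fraction * np.ptp(d_s):
        i_min = len(d_s) - 1  # monotone decrease within noise: no recovery onset
    return float(traj.s[i_start]), float(traj.s[i_min])


def _regime_mask(s: np.ndarray, regime: tuple[float, float]) -> np.ndarray:
    s0, s1 = regime
    return (s >= s0 - 1e-12) & (s <= s1 + 1e-12)


def fit_diameter_profile(
    traj: StrutTrajectory, regime: tuple[float, float] | None = None
) -> tuple[float, float, float]:
    """Fit d(s) = d_inf + (d0 - d_inf) exp(-s/s_c) over the regime.

    Returns (d0, d_inf, s_c) in mm.  A window over which the diameter
    does not decrease (elastic recovery) raises
    :class:`NonDecayingProfileError`.
    """
    mask = _regime_mask(traj.s, regime) if regime is not None else np.ones(len(traj), bool)
    if mask.sum() < 5:
        raise ValueError("regime must contain >= 5 points")
    s, d = traj.s[mask], traj.d[mask]
    slope = np.polyfit(s, d, 1)[0]
    if slope >= 0:
        raise NonDecayingProfileError(
            "diameter does not decay over the window (elastic recovery?)"
        )

    span = s[-1] - s[0]
    x0 = [float(d[0]), float(max(d.min() * 0.9, 1e-6)), float(span / 3.0)]

    def resid(p):
        d0, d_inf, s_c = p
        return d_inf + (d0 - d_inf) * np.exp(-s / s_c) - d

    res = least_squares(
        resid,
        x0=x0,
        bounds=([1e-9, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
        xtol=1e-15, ftol=1e-15, gtol=1e-15,
    )
    if not res.success:
        raise RuntimeError(f"diameter fit did not converge: {res.message}")
    d0, d_inf, s_c = map(float, res.x)
    if d0 <= d_inf:
        raise NonDecayingProfileError("fitted profile has d0 <= d_inf")
    return d0, d_inf, s_c


def fit_pitch_angle(
    traj: StrutTrajectory, regime: tuple[float, float] | None = None
) -> float:
    """Slope m = d alpha / d x (rad/mm): ordinary least squares of alpha on x."""
    mask = _regime_mask(traj.s, regime) if regime is not None else np.ones(len(traj), bool)
    if mask.sum() < 3:
        raise ValueError("regime must contain >= 3 points")
    x, alpha = traj.x[mask], traj.alpha[mask]
    if np.ptp(x) <= 0:
        raise ValueError("degenerate x-range for the pitch-angle fit")
    return float(np.polyfit(x, alpha, 1)[0])


def fit_trajectory(
    traj: StrutTrajectory,
    regime: tuple[float, float] | None = None,
    exclusion_points: int = 2,
    window: int = 5,
) -> TrajectoryFit:
    """Select the viscous regime (unless given) and fit both parametric models."""
    if regime is None:
        regime = select_viscous_regime(traj, exclusion_points=exclusion_points, window=window)
    d0, d_inf, s_c = fit_diameter_profile(traj, regime)
    m = fit_pitch_angle(traj, regime)
    return TrajectoryFit(d0=d0, d_inf=d_inf, s_c=s_c, m=m, regime=regime)


def elongational_viscosity(
    traj: StrutTrajectory,
    fit: TrajectoryFit,
    cond,
    include_gamma: bool = True,
    axis: str = "x",
) -> ViscosityCurve:
    """Pointwise elongational viscosity over the viscous regime, Pa s.

    axis="x" evaluates

        eta_E = ( rho_m g / m - 2 gamma / d(s) ) / (dv/ds)

    with the constant pitch slope m; axis="s" evaluates the arc-length
    form with its cos(alpha) factor and d alpha/ds = m cos(alpha), which
    coincides with axis="x" for a linear pitch angle.  With gamma = 0 or
    ``include_gamma`` false the surface-tension term drops.

    All inputs are converted to SI here (mm -> m, rad/mm -> rad/m).
    Negative eta_E values are kept and flagged, not dropped.
    """
    if axis not in ("x", "s"):
        raise ValueError("axis must be 'x' or 's'")
    if fit.m <= 0:
        raise PhysicalValidityError("pitch-angle slope m <= 0: no gravity-driven stretching")

    mask = _regime_mask(traj.s, fit.regime)
    s_mm = traj.s[mask]
    d_m = fit.diameter(s_mm) * 1e-3
    Q_si = cond.Q * 1e-9  # mm^3/s -> m^3/s
    s_c_m = fit.s_c * 1e-3
    dd_m = (fit.d0 - fit.d_inf) * 1e-3

    # dv/ds of the fitted exponential, in 1/s (SI throughout)
    dvds = (8.0 * Q_si / (math.pi * d_m**3)) * (dd_m / s_c_m) * np.exp(
        -(s_mm * 1e-3) / s_c_m
    )
    if np.any(dvds <= 0):
        raise PhysicalValidityError("dv/ds <= 0 inside the viscous regime")

    gamma = cond.gamma if include_gamma else 0.0
    m_si = fit.m * 1e3  # rad/mm -> rad/m
    rho_g = cond.density * cond.g

    if axis == "x":
        eta = (rho_g / m_si - 2.0 * gamma / d_m) / dvds
    else:
        alpha = np.interp(s_mm, traj.s, traj.alpha)
        dalpha_ds = m_si * np.cos(alpha)  # chain rule with cos(alpha) = dx/ds
        eta = rho_g * np.cos(alpha) / (dalpha_ds * dvds) - 2.0 * gamma / (d_m * dvds)

    return ViscosityCurve(
        eps_dot=dvds, eta_E=eta, s=s_mm, has_negative=bool(np.any(eta < 0))
    )


def raw_viscosity_curve(
    traj: StrutTrajectory,
    cond,
    include_gamma: bool = True,
    regime: tuple[float, float] | None = None,
) -> ViscosityCurve:
    """Diagnostic: eta_E from raw finite differences, no parametric fits.

    Uses local d alpha/dx and dv/ds from second-order differences of the
    measured arrays.  Noisier than the fitted route but free of the
    linear-pitch / exponential-diameter assumptions, so it resolves a
    strain-rate-dependent (e.g. power-law thinning) viscosity.
    """
    mask = _regime_mask(traj.s, regime) if regime is not None else np.ones(len(traj), bool)
    s_mm, x_mm = traj.s[mask], traj.x[mask]
    alpha, d_mm = traj.alpha[mask], traj.d[mask]

    prof = velocity_profile(d_mm, cond.Q)
    v_si = prof.v * 1e-3
    dvds = np.gradient(v_si, s_mm * 1e-3)
    dalpha_dx = np.gradient(alpha, x_mm * 1e-3)
    with np.errstate(divide="ignore", invalid="ignore"):
        gamma = cond.gamma if include_gamma else 0.0
        eta = (cond.density * cond.g / dalpha_dx - 2.0 * gamma / (d_mm * 1e-3)) / dvds
    return ViscosityCurve(
        eps_dot=dvds, eta_E=eta, s=s_mm, has_negative=bool(np.any(eta < 0))
    )


def analyze_trajectory(
    traj: StrutTrajectory,
    cond,
    include_gamma: bool = True,
    axis: str = "x",
    regime: tuple[float, float] | None = None,
    exclusion_points: int = 2,
    window: int = 5,
) -> tuple[TrajectoryFit, ViscosityCurve]:
    """Full pipeline: regime selection, parametric fits, viscosity curve."""
    fit = fit_trajectory(
        traj, regime=regime, exclusion_points=exclusion_points, window=window
    )
    curve = elongational_viscosity(traj, fit, cond, include_gamma=include_gamma, axis=axis)
    return fit, curve
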