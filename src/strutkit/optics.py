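"""Cylindrical-lens pattern refraction: curvature from apparent stripe rotation.

The deposited strut sits on a transparent substrate above a diagonally
striped background.  Seen from below, the strut acts as a plano-convex
cylindrical lens of vertex surface curvature ``rho``: the stripes appear
magnified across the strut axis by a factor M and therefore rotated from
their true angle theta to an apparent angle theta'.

The model used here is a paraxial thin lens with an orthographic camera,
with all unmodelled interfaces folded into one lumped calibration
constant z_bg * (n_strut - n_medium):

    M = 1 / (1 - z_bg * rho * dn),      tan(theta') = tan(theta) / M

which inverts in closed form to

    rho = (1 - tan(theta') / tan(theta)) / (z_bg * dn).

The lumped constant is individually unidentifiable from a single image;
it should be calibrated once from a reference strut of known geometry
(``lumped_zdn`` override).  Absolute curvatures are only as good as that
calibration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .geometry import ParabolicStrut

__all__ = [
    "OpticalConfig",
    "PatternObservation",
    "BeyondFocusError",
    "InconsistentObservationError",
    "apparent_rotation",
    "invert_curvature",
    "strut_from_pattern",
]


class BeyondFocusError(ValueError):
    """Background plane at or beyond the lens focus: image inverted, unusable."""


class InconsistentObservationError(ValueError):
    """Apparent stripe angle exceeds the true angle; not producible by the lens model."""


@dataclass(frozen=True)
class OpticalConfig:
    """Parameters of the stripe-refraction imaging model.

    Parameters
    ----------
    n_strut : float
        Refractive index of the ink (default 1.34, dilute hydrogel).
    n_medium : float
        Index of the surrounding medium (default 1.0, air).
    z_bg : float
        Effective optical distance from the strut base to the background
        pattern plane, in mm.
    pattern_angle_deg : float
        True stripe angle theta versus the strut axis, degrees, in (0, 90).
    pattern_pitch : float
        Stripe spacing in mm.
    lumped_zdn : float, optional
        Calibrated override for the product z_bg * (n_strut - n_medium)
        in mm.  When set it supersedes the individual values.
    """

    n_strut: float = 1.34
    n_medium: float = 1.0
    z_bg: float = 0.5
    pattern_angle_deg: float = 45.0
    pattern_pitch: float = 0.5
    lumped_zdn: float | None = None

    def __post_init__(self) -> None:
        if not (self.n_strut > self.n_medium >= 1.0):
            raise ValueError("require n_strut > n_medium >= 1")
        if not (self.z_bg > 0):
            raise ValueError("z_bg must be > 0")
        if not (0.0 < self.pattern_angle_deg < 90.0):
            raise ValueError("pattern_angle_deg must be in (0, 90)")
        if not (self.pattern_pitch > 0):
            raise ValueError("pattern_pitch must be > 0")
        if self.lumped_zdn is not None and not (self.lumped_zdn > 0):
            raise ValueError("lumped_zdn must be > 0 when set")

    @property
    def zdn(self) -> float:
        """Lumped calibration constant z_bg * (n_strut - n_medium), mm."""
        if self.lumped_zdn is not None:
            return self.lumped_zdn
        return self.z_bg * (self.n_strut - self.n_medium)


@dataclass(frozen=True)
class PatternObservation:
    """Measured stripe appearance inside the strut."""

    apparent_angle_deg: float  # theta', degrees
    magnification: float  # M, dimensionless

    def __post_init__(self) -> None:
        if not (0.0 < self.apparent_angle_deg < 90.0):
            raise ValueError("apparent_angle_deg must be in (0, 90)")
        if not (self.magnification > 0):
            raise ValueError("magnification must be > 0")


def apparent_rotation(rho: float, config: OpticalConfig) -> PatternObservation:
    """Forward model: apparent stripe angle and magnification for curvature rho.

    M = 1/(1 - zdn * rho); tan(theta') = tan(theta)/M.  rho = 0 leaves
    the pattern untouched.

    Raises
    ------
    BeyondFocusError
        If zdn * rho >= 1 (background at/beyond focus).
    """
    if rho < 0:
        raise ValueError("rho must be >= 0")
    zr = config.zdn * rho
    if zr >= 1.0:
        raise BeyondFocusError(
            f"z_bg*rho*dn = {zr:.4g} >= 1: background beyond focus, "
            "pattern inverted and the measurement is invalid"
        )
    M = 1.0 / (1.0 - zr)
    theta = math.radians(config.pattern_angle_deg)
    theta_p = math.atan(math.tan(theta) / M)
    return PatternObservation(apparent_angle_deg=math.degrees(theta_p), magnification=M)


def invert_curvature(observation: PatternObservation, config: OpticalConfig) -> float:
    """Recover vertex curvature rho (1/mm) from an observed stripe rotation.

    rho = (1 - tan(theta')/tan(theta)) / zdn.  An apparent angle above
    the true pattern angle cannot be produced by the lens model and is
    rejected.
    """
    theta = math.radians(config.pattern_angle_deg)
    theta_p = math.radians(observation.apparent_angle_deg)
    ratio = math.tan(theta_p) / math.tan(theta)
    if ratio > 1.0 + 1e-12:
        raise InconsistentObservationError(
            f"apparent angle {observation.apparent_angle_deg:.3f} deg exceeds the "
            f"pattern angle {config.pattern_angle_deg:.3f} deg"
        )
    return max(0.0, (1.0 - min(ratio, 1.0)) / config.zdn)


def strut_from_pattern(
    observation: PatternObservation, width_a: float, config: OpticalConfig
) -> ParabolicStrut:
    """Build the full strut from the stripe rotation plus the measured width.

    The rotation gives rho; with the width a from the edge contours in
    the same image, H = rho * a^2 / 8.  A vanishing rotation yields the
    degenerate flat film H = 0.
    """
    if not (width_a > 0):
        raise ValueError("width_a must be > 0")
    rho = invert_curvature(observation, config)
    return ParabolicStrut(H=rho * width_a**2 / 8.0, a=width_a)
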