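"""Ground-truthed synthetic data and imagery.

Every estimator in the package is exercised against scenes generated
here: width-versus-time spreading series, bottom-view renders of a
strand over a diagonally striped background (with the stripe rotation
produced by the strut's cylindrical-lens action), and hanging-strut
trajectories with matching side-view silhouettes.

The generating parameters mirror the experimental regime the package
targets: strut widths 0.4-1.1 mm, spreading times up to 12 s, print
speed 5 mm/s at ~0.25 mm^3/s throughput, a 21G nozzle (0.82 mm OD) for
scale calibration, and a pixel scale of about 0.025 mm/px.  Noise is
additive Gaussian with stated standard deviations; all randomness flows
through one seeded generator, so a fixed seed reproduces every array
and image byte for byte.  Renders carry a machine-readable ground-truth
sidecar; end-to-end tests consume only the render and compare only
against the sidecar.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy.integrate import cumulative_trapezoid, solve_ivp

from .geometry import PrintConditions
from .optics import BeyondFocusError, OpticalConfig
from .spreading import SpreadingSeries, eval_complete_wetting, eval_partial_wetting
from .trajectory import StrutTrajectory, ViscosityCurve

__all__ = [
    "DEFAULT_SCALE",
    "gen_spreading_series",
    "gen_trajectory",
    "gen_power_law_trajectory",
    "render_bottom_view",
    "render_spreading_snapshot",
    "render_side_view",
    "save_scene",
    "load_scene",
]

DEFAULT_SCALE = 0.025  # mm per pixel

# stripe rendering constants: mean/amplitude chosen so the strut edge
# lines (multiplicative dip to ~0.03) stay darker than the darkest stripe
_STRIPE_MEAN = 0.65
_STRIPE_AMP = 0.30
_EDGE_DEPTH = 0.95
_EDGE_WIDTH_PX = 1.5


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_spreading_series(
    model: str,
    params: dict,
    t_grid,
    noise_sd: float = 0.0,
    seed=0,
) -> tuple[SpreadingSeries, dict]:
    """Sample a width series from one of the wetting laws plus Gaussian noise.

    ``model`` is "complete" (params K, t0) or "partial" (params a_s, B,
    t0).  Widths are clipped positive.  Returns the series and a ground
    truth dict.
    """
    t = np.asarray(t_grid, dtype=float)
    if model == "complete":
        a = eval_complete_wetting(params["K"], params.get("t0", 0.0), t)
    elif model == "partial":
        a = eval_partial_wetting(params["a_s"], params["B"], params.get("t0", 0.0), t)
    else:
        raise ValueError(f"unknown model {model!r}")
    a = np.asarray(a, dtype=float)
    if noise_sd > 0:
        a = a + _rng(seed).normal(0.0, noise_sd, size=a.shape)
    a = np.clip(a, 1e-6, None)
    truth = {"model": model, "params": dict(params), "noise_sd": noise_sd}
    return SpreadingSeries(t=t, a=a), truth


def _pitch_angle_closed_form(s, alpha0: float, m_per_mm: float) -> np.ndarray:
    """alpha(s) for a pitch angle linear in x: alpha = alpha0 + m x.

    With cos(alpha) = dx/ds the ODE d(alpha)/ds = m cos(alpha) has the
    closed-form solution alpha(s) = gd(m s + gd^-1(alpha0)), written via
    asinh(tan) / atan(sinh).
    """
    c0 = math.asinh(math.tan(alpha0))
    return np.arctan(np.sinh(m_per_mm * np.asarray(s, dtype=float) + c0))


def gen_trajectory(
    cond: PrintConditions,
    d0: float,
    d_inf: float,
    s_c: float,
    alpha0: float,
    m: float,
    s_max: float,
    n_points: int = 60,
    noise_px: float = 0.0,
    scale: float = DEFAULT_SCALE,
    seed=0,
) -> tuple[StrutTrajectory, ViscosityCurve]:
    """Hanging-strut trajectory with exponential diameter and linear pitch.

    d(s) = d_inf + (d0 - d_inf) exp(-s/s_c)  (mm),
    alpha(x) = alpha0 + m x  (rad, m in rad/mm > 0),

    with the arc length consistent with cos(alpha) = dx/ds.  Gaussian
    jitter of noise_px * scale (mm) is applied to the centerline
    coordinates (alpha is then re-measured from the jittered polyline)
    and to the diameters.  Returns the trajectory together with the
    analytic elongational-viscosity curve of the force-balance model on
    the clean geometry.
    """
    if not (d0 > d_inf > 0):
        raise ValueError("require d0 > d_inf > 0")
    if m < 1e-4:
        raise ValueError("pitch slope m below 1e-4 rad/mm: eta_E diverges, refusing")
    if not (s_c > 0 and s_max > 0):
        raise ValueError("s_c and s_max must be > 0")
    if n_points < 8:
        raise ValueError("n_points must be >= 8")

    s = np.linspace(0.0, s_max, n_points)
    alpha = _pitch_angle_closed_form(s, alpha0, m)
    if alpha[-1] > math.radians(89.0):
        raise ValueError("pitch angle reaches ~90 deg before s_max")
    x = (alpha - alpha0) / m  # inverse of alpha = alpha0 + m x
    d = d_inf + (d0 - d_inf) * np.exp(-s / s_c)

    # analytic force-balance curve on the clean geometry (SI)
    truth = _analytic_curve(cond, d0, d_inf, s_c, m, s, d)

    if noise_px > 0:
        from scipy.signal import savgol_filter

        rng = _rng(seed)
        sd = noise_px * scale
        y = cumulative_trapezoid(np.sin(alpha), s, initial=0.0)
        xp = x + rng.normal(0.0, sd, size=x.shape)
        yp = y + rng.normal(0.0, sd, size=y.shape)
        # extraction pipelines smooth the centerline before differentiating;
        # emulate the same local-quadratic smoothing here, spanning ~10% of
        # the strut length (the angle, not the position, carries the signal)
        win = max(11, (n_points // 10) | 1)
        win = min(win, n_points if n_points % 2 else n_points - 1)
        xs_ = savgol_filter(xp, win, 2)
        ys_ = savgol_filter(yp, win, 2)
        dxy = np.hypot(np.diff(xs_), np.diff(ys_))
        sp = np.concatenate([[0.0], np.cumsum(dxy)])
        alpha_p = np.arctan2(np.gradient(ys_, sp), np.gradient(xs_, sp))
        dp = np.clip(d + rng.normal(0.0, sd, size=d.shape), 1e-6, None)
        traj = StrutTrajectory(s=sp, x=xs_, alpha=alpha_p, d=dp)
    else:
        traj = StrutTrajectory(s=s, x=x, alpha=alpha, d=d)
    return traj, truth


def _analytic_curve(cond, d0, d_inf, s_c, m, s, d) -> ViscosityCurve:
    Q_si = cond.Q * 1e-9
    d_m = d * 1e-3
    eps = (8.0 * Q_si / (math.pi * d_m**3)) * ((d0 - d_inf) * 1e-3 / (s_c * 1e-3)) * np.exp(
        -s / s_c
    )
    eta = (cond.density * cond.g / (m * 1e3) - 2.0 * cond.gamma / d_m) / eps
    return ViscosityCurve(eps_dot=eps, eta_E=eta, s=np.asarray(s, float),
                          has_negative=bool(np.any(eta < 0)))


def gen_power_law_trajectory(
    cond: PrintConditions,
    C: float,
    n: float,
    d0: float,
    d_inf: float,
    s_c: float,
    s_max: float,
    n_points: int = 200,
    alpha0: float = 0.05,
    noise_px: float = 0.0,
    scale: float = DEFAULT_SCALE,
    seed=0,
) -> tuple[StrutTrajectory, ViscosityCurve]:
    """Trajectory whose force balance encodes a power-law viscosity.

    Prescribes eta_E(eps_dot) = C * eps_dot^(n-1) (Pa s, eps_dot in 1/s)
    with gamma = 0.  The diameter profile fixes eps_dot(s); the pitch
    angle is then integrated from the force balance,
    d alpha/dx = rho_m g / (C eps_dot^n), so the raw-derivative pipeline
    recovers the prescribed curve.
    """
    if not (d0 > d_inf > 0 and s_c > 0 and s_max > 0 and C > 0):
        raise ValueError("invalid generator parameters")

    Q_si = cond.Q * 1e-9
    rho_g = cond.density * cond.g

    def eps_of_s(s_mm):
        d_m = (d_inf + (d0 - d_inf) * math.exp(-s_mm / s_c)) * 1e-3
        return (8.0 * Q_si / (math.pi * d_m**3)) * ((d0 - d_inf) * 1e-3 / (s_c * 1e-3)) \
            * math.exp(-s_mm / s_c)

    def rhs(s_mm, y):
        x_mm, alpha = y
        dalpha_dx_si = rho_g / (C * eps_of_s(s_mm) ** n)  # rad/m
        ca = math.cos(alpha)
        return [ca, dalpha_dx_si * 1e-3 * ca]  # dx/ds, dalpha/ds (per mm)

    s = np.linspace(0.0, s_max, n_points)
    sol = solve_ivp(rhs, (0.0, s_max), [0.0, alpha0], t_eval=s, rtol=1e-10, atol=1e-12)
    if not sol.success:
        raise RuntimeError(f"trajectory integration failed: {sol.message}")
    x, alpha = sol.y
    if alpha[-1] > math.radians(89.0):
        raise ValueError("pitch angle reaches ~90 deg before s_max")
    d = d_inf + (d0 - d_inf) * np.exp(-s / s_c)

    eps = np.array([eps_of_s(si) for si in s])
    truth = ViscosityCurve(eps_dot=eps, eta_E=C * eps ** (n - 1.0), s=s)

    if noise_px > 0:
        rng = _rng(seed)
        sd = noise_px * scale
        d = np.clip(d + rng.normal(0.0, sd, size=d.shape), 1e-6, None)
    return StrutTrajectory(s=s, x=x, alpha=alpha, d=d), truth


def _stripe_field(x_mm: np.ndarray, y_mm: np.ndarray, optics: OpticalConfig) -> np.ndarray:
    """Sinusoidal diagonal stripes: angle measured against the x axis."""
    th = math.radians(optics.pattern_angle_deg)
    u = x_mm * math.sin(th) - y_mm * math.cos(th)
    return _STRIPE_MEAN + _STRIPE_AMP * np.sin(2.0 * math.pi * u / optics.pattern_pitch)


def render_bottom_view(
    station_x: np.ndarray,
    widths: np.ndarray,
    heights: np.ndarray,
    optics: OpticalConfig,
    scale: float = DEFAULT_SCALE,
    pad_mm: float = 1.0,
    noise_sd: float = 0.0,
    seed=0,
    edge_lines: bool = True,
) -> tuple[np.ndarray, dict]:
    """Bottom view of a straight horizontal strand over diagonal stripes.

    With ``edge_lines`` false no contact-line darkening is drawn: the
    strut is visible only through the displaced stripes, emulating
    in-gel printing of a transparent ink into a transparent support
    bath.

    The strand runs along the image x axis; local width a(x) and height
    H(x) are linearly interpolated between stations.  Inside the strand
    band the background is remapped across-strut by the local lens
    magnification M = 1/(1 - zdn * rho) with rho = 8H/a^2, so the
    stripes appear rotated to tan(theta') = tan(theta)/M.  The contact
    lines at +/- a/2 are drawn as dark edge lines.  Returns a float
    image in [0, 1] plus a ground-truth sidecar dict.
    """
    station_x = np.asarray(station_x, dtype=float)
    widths = np.asarray(widths, dtype=float)
    heights = np.asarray(heights, dtype=float)
    if not (len(station_x) == len(widths) == len(heights)):
        raise ValueError("station_x, widths, heights must have equal length")

    a_max = float(widths.max())
    x_min, x_max = float(station_x.min()), float(station_x.max())
    width_mm = (x_max - x_min) + 2 * pad_mm
    height_mm = a_max + 2 * pad_mm
    n_cols = int(round(width_mm / scale))
    n_rows = int(round(height_mm / scale))
    if a_max >= height_mm:
        raise ValueError("strut wider than the image")

    cols = np.arange(n_cols) * scale + x_min - pad_mm  # x in strand coordinates
    rows = np.arange(n_rows) * scale
    y_c = rows.mean()
    X, Y = np.meshgrid(cols, rows)

    base = _stripe_field(X, Y, optics)

    a_col = np.interp(cols, station_x, widths, left=np.nan, right=np.nan)
    H_col = np.interp(cols, station_x, heights, left=np.nan, right=np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_col = 8.0 * H_col / a_col**2
        zr = optics.zdn * rho_col
        if np.nanmax(zr) >= 1.0:
            raise BeyondFocusError("local z*rho*dn >= 1 in the render")
        M_col = 1.0 / (1.0 - zr)

    Y_remap = y_c + M_col[None, :] * (Y - y_c)
    inside = np.abs(Y - y_c) <= (a_col[None, :] / 2.0)
    inside &= np.isfinite(a_col)[None, :]
    img = np.where(inside, _stripe_field(X, Y_remap, optics), base)

    if edge_lines:
        # contact-line darkening at +/- a/2
        with np.errstate(invalid="ignore"):
            edge_dist = np.abs(np.abs(Y - y_c) - a_col[None, :] / 2.0)
        w = _EDGE_WIDTH_PX * scale
        edge = np.where(np.isfinite(edge_dist), np.exp(-((edge_dist / w) ** 2)), 0.0)
        img = img * (1.0 - _EDGE_DEPTH * edge)

    if noise_sd > 0:
        img = img + _rng(seed).normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    truth = {
        "kind": "bottom_view",
        "scale_mm_per_px": scale,
        "y_center_mm": float(y_c),
        "x_origin_mm": float(x_min - pad_mm),
        "station_x_mm": station_x.tolist(),
        "widths_mm": widths.tolist(),
        "heights_mm": heights.tolist(),
        "rho_per_mm": (8.0 * heights / widths**2).tolist(),
        "optics": {
            "pattern_angle_deg": optics.pattern_angle_deg,
            "pattern_pitch_mm": optics.pattern_pitch,
            "zdn_mm": optics.zdn,
        },
        "noise_sd": noise_sd,
    }
    return img, truth


def render_spreading_snapshot(
    K: float,
    v_p: float,
    kappa: float,
    optics: OpticalConfig,
    t_min: float = 0.5,
    t_max: float = 12.0,
    n_stations: int = 48,
    scale: float = DEFAULT_SCALE,
    noise_sd: float = 0.0,
    seed=0,
) -> tuple[np.ndarray, dict]:
    """Snapshot of a straight strand at print end, widths aging along it.

    Strand position x (mm, from the oldest end) has age
    t(x) = t_max - x / v_p; the local width follows the complete-wetting
    law a = K t^(1/7) and the height keeps the cross-section kappa
    constant (H = 3 kappa / (2 a)), emulating spreading at conserved
    volume.  Ground truth records the age mapping for re-fitting K.
    """
    if not (t_max > t_min > 0):
        raise ValueError("require t_max > t_min > 0")
    t = np.linspace(t_max, t_min, n_stations)  # oldest at x = 0
    x = (t_max - t) * v_p
    a = np.asarray(eval_complete_wetting(K, 0.0, t))
    H = 3.0 * kappa / (2.0 * a)
    img, truth = render_bottom_view(
        x, a, H, optics, scale=scale, noise_sd=noise_sd, seed=seed
    )
    truth.update(
        {
            "kind": "spreading_snapshot",
            "K_mm": K,
            "v_p_mm_per_s": v_p,
            "kappa_mm2": kappa,
            "t_of_station_s": t.tolist(),
        }
    )
    return img, truth


def render_side_view(
    traj: StrutTrajectory,
    nozzle_od: float = 0.82,
    scale: float = DEFAULT_SCALE,
    pad_mm: float = 0.8,
    nozzle_len_mm: float = 0.6,
    noise_sd: float = 0.0,
    seed=0,
) -> tuple[np.ndarray, dict]:
    """Side-view silhouette of the hanging strut, nozzle at the top.

    Image y points downward (the direction of gravity); the strut starts
    at the nozzle exit and sags to the right and down.  The silhouette
    is the centerline offset by +/- d/2 along the local normal, drawn
    with a ~1.5 px anti-aliased edge; the nozzle is a dark vertical bar
    of width ``nozzle_od`` so the image is self-calibrating.
    """
    from scipy.spatial import cKDTree

    y = cumulative_trapezoid(np.sin(traj.alpha), traj.s, initial=0.0)
    x = traj.x - traj.x[0]

    # dense resampling of the centerline for distance queries
    s_dense = np.linspace(traj.s[0], traj.s[-1], max(8 * len(traj), 800))
    xd = np.interp(s_dense, traj.s, x)
    yd = np.interp(s_dense, traj.s, y)
    dd = np.interp(s_dense, traj.s, traj.d)

    # extend the strut tangentially past the trajectory end so no end cap
    # is rendered (a hanging strut continues out of the analysed region)
    ext = 1.5 * float(traj.d.max())
    n_ext = 200
    tx = xd[-1] - xd[-2]
    ty = yd[-1] - yd[-2]
    norm = math.hypot(tx, ty)
    if norm > 0:
        step = np.arange(1, n_ext + 1) * (ext / n_ext)
        xd = np.concatenate([xd, xd[-1] + step * tx / norm])
        yd = np.concatenate([yd, yd[-1] + step * ty / norm])
        dd = np.concatenate([dd, np.full(n_ext, dd[-1])])

    x0_mm = pad_mm  # image x of the nozzle exit
    y0_mm = nozzle_len_mm + pad_mm * 0.5  # image y of the nozzle exit
    width_mm = x.max() + traj.d.max() + 2 * pad_mm
    height_mm = y0_mm + y.max() + traj.d.max() + pad_mm
    n_cols = int(round(width_mm / scale))
    n_rows = int(round(height_mm / scale))
    if n_cols < 8 or n_rows < 8:
        raise ValueError("trajectory extent too small to render")

    cols = np.arange(n_cols) * scale
    rows = np.arange(n_rows) * scale
    X, Y = np.meshgrid(cols, rows)

    tree = cKDTree(np.column_stack([xd + x0_mm, yd + y0_mm]))
    dist, idx = tree.query(np.column_stack([X.ravel(), Y.ravel()]), k=1)
    signed = dist.reshape(X.shape) - dd[idx].reshape(X.shape) / 2.0

    bg, dark = 0.90, 0.12
    aa = 1.5 * scale
    frac = np.clip(signed / aa + 0.5, 0.0, 1.0)  # 0 inside strut, 1 outside
    img = dark + (bg - dark) * frac

    # nozzle bar: darkest vertical structure at the image top
    noz_cols = np.abs(cols - x0_mm) <= nozzle_od / 2.0
    noz_rows = rows <= y0_mm
    img[np.ix_(noz_rows, noz_cols)] = 0.04

    if noise_sd > 0:
        img = img + _rng(seed).normal(0.0, noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)

    truth = {
        "kind": "side_view",
        "scale_mm_per_px": scale,
        "nozzle_od_mm": nozzle_od,
        "nozzle_exit_xy_mm": [x0_mm, y0_mm],
        "s_mm": traj.s.tolist(),
        "x_mm": x.tolist(),
        "y_mm": y.tolist(),
        "alpha_deg": np.rad2deg(traj.alpha).tolist(),
        "d_mm": traj.d.tolist(),
        "noise_sd": noise_sd,
    }
    return img, truth


def save_scene(out_dir, name: str, image: np.ndarray, truth: dict) -> tuple[Path, Path]:
    """Write a render as 16-bit PNG plus its JSON ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    png = out / f"{name}.png"
    sidecar = out / f"{name}.json"
    iio.imwrite(png, (np.clip(image, 0, 1) * 65535).astype(np.uint16))
    sidecar.write_text(json.dumps(truth, indent=1))
    return png, sidecar


def load_scene(png_path) -> tuple[np.ndarray, dict]:
    """Read a render and its sidecar back as (float image in [0,1], truth)."""
    png_path = Path(png_path)
    img = iio.imread(png_path).astype(np.float64) / 65535.0
    truth = json.loads(png_path.with_suffix(".json").read_text())
    return img, truth
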