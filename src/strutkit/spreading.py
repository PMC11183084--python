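"""Strut-spreading kinetics: 1/7-power wetting laws and their fits.

After deposition a liquid strut keeps spreading on the substrate.  On a
completely wetting substrate (alginate in water on glass) the width
grows without bound,

    a(t) = K * ((t + t0) / 1 s)^(1/7),

while on a partially wetting substrate (PBS-based inks) it saturates at
a final width a_s,

    a(t) = a_s * (1 - exp(-B (t + t0)))^(1/7).

The complete-wetting prefactor absorbs the material constants,
K = (gamma_L * 18 * 7 * kappa^3 / (lambda * eta))^(1/7), so at fixed
throughput K scales as eta^(-1/7).  The first-order expansion of the
partial-wetting law, a(t) ~ a_s * B^(1/7) * t^(1/7), makes a_s*B^(1/7)
directly comparable with K as the initial-spreading speed.

Time is nondimensionalized by the unit second before exponentiation so
both prefactors carry plain mm units.  The experimental delay t0 is
fixed to zero by default: on the data this family of fits targets its
fitted value is consistently smaller than its own standard error, and a
free t0 is retained only as a diagnostic.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "SpreadingSeries",
    "CompleteWettingFit",
    "PartialWettingFit",
    "MaterialParams",
    "ModelSelection",
    "FitError",
    "eval_complete_wetting",
    "eval_partial_wetting",
    "fit_complete_wetting",
    "fit_partial_wetting",
    "fit_free_exponent",
    "initial_prefactor",
    "viscosity_from_concentration",
    "prefactor_ratio_from_viscosity",
    "full_form_prefactor",
    "partial_wetting_rate",
    "model_selection",
    "cell_volume_fraction",
]

_SEVENTH = 1.0 / 7.0


class FitError(RuntimeError):
    """Nonlinear fit failed to converge or the series is degenerate."""


@dataclass(frozen=True)
class SpreadingSeries:
    """Measured strut width versus time since deposition.

    ``t`` in seconds (strictly increasing, >= 0), ``a`` in mm (> 0),
    optional per-point width uncertainty ``sigma_a`` in mm.
    """

    t: np.ndarray
    a: np.ndarray
    sigma_a: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "t", np.asarray(self.t, dtype=float))
        object.__setattr__(self, "a", np.asarray(self.a, dtype=float))
        if self.sigma_a is not None:
            object.__setattr__(self, "sigma_a", np.asarray(self.sigma_a, dtype=float))
        if self.t.ndim != 1 or self.a.ndim != 1 or len(self.t) != len(self.a):
            raise ValueError("t and a must be 1-D arrays of equal length")
        if len(self.t) < 3:
            raise ValueError("a spreading series needs at least 3 points")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if self.t[0] < 0:
            raise ValueError("t must be >= 0")
        if np.any(self.a <= 0):
            raise ValueError("widths a must be > 0")
        if self.sigma_a is not None and (
            len(self.sigma_a) != len(self.t) or np.any(self.sigma_a <= 0)
        ):
            raise ValueError("sigma_a must be positive and match the series length")

    def __len__(self) -> int:
        return len(self.t)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SpreadingSeries":
        """Read columns t_s, a_mm (optional sigma_mm)."""
        df = pd.read_csv(path)
        sigma = df["sigma_mm"].to_numpy() if "sigma_mm" in df.columns else None
        return cls(t=df["t_s"].to_numpy(), a=df["a_mm"].to_numpy(), sigma_a=sigma)

    def to_csv(self, path: str | Path) -> None:
        cols = {"t_s": self.t, "a_mm": self.a}
        if self.sigma_a is not None:
            cols["sigma_mm"] = self.sigma_a
        pd.DataFrame(cols).to_csv(path, index=False)


@dataclass(frozen=True)
class CompleteWettingFit:
    """Result of fitting a(t) = K ((t+t0)/s)^(1/7)."""

    K: float  # mm
    t0: float  # s
    se_K: float
    se_t0: float
    rss: float  # mm^2
    t0_fixed: bool
    n_points: int
    aicc: float
    degenerate: bool = False  # widths statistically constant over time

    def evaluate(self, t) -> np.ndarray:
        return eval_complete_wetting(self.K, self.t0, t)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "complete",
                "K_mm": self.K,
                "t0_s": self.t0,
                "se_K": self.se_K,
                "se_t0": self.se_t0,
                "rss": self.rss,
                "aicc": self.aicc,
                "n_points": self.n_points,
                "t0_fixed": self.t0_fixed,
                "degenerate": self.degenerate,
            }
        )


@dataclass(frozen=True)
class PartialWettingFit:
    """Result of fitting a(t) = a_s (1 - exp(-B (t+t0)))^(1/7)."""

    a_s: float  # mm, final strut width
    B: float  # 1/s
    t0: float  # s
    se_a_s: float
    se_B: float
    se_t0: float
    rss: float
    t0_fixed: bool
    n_points: int
    aicc: float

    def evaluate(self, t) -> np.ndarray:
        return eval_partial_wetting(self.a_s, self.B, self.t0, t)

    def to_json(self) -> str:
        return json.dumps(
            {
                "model": "partial",
                "a_s_mm": self.a_s,
                "B_per_s": self.B,
                "t0_s": self.t0,
                "se_a_s": self.se_a_s,
                "se_B": self.se_B,
                "se_t0": self.se_t0,
                "rss": self.rss,
                "aicc": self.aicc,
                "n_points": self.n_points,
                "t0_fixed": self.t0_fixed,
            }
        )


@dataclass(frozen=True)
class MaterialParams:
    """Material constants entering the full-form spreading prefactor.

    gamma_L: surface tension (N/m); eta: ink viscosity (Pa s);
    eta_S: solvent viscosity (Pa s); intrinsic_viscosity: [eta] in
    reciprocal concentration units matching c; c: polymer concentration
    (% w/v); lambda_const: the universal dissipation constant of the
    wetting theory (dimensionless, no published value — must be supplied
    by the caller for absolute prefactors).
    """

    gamma_L: float | None = None
    eta: float | None = None
    eta_S: float | None = None
    intrinsic_viscosity: float | None = None
    c: float | None = None
    lambda_const: float | None = None

    def __post_init__(self) -> None:
        for name in ("gamma_L", "eta", "eta_S", "intrinsic_viscosity", "lambda_const"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise ValueError(f"{name} must be > 0 when set")
        if self.c is not None and self.c < 0:
            raise ValueError("concentration c must be >= 0")


def eval_complete_wetting(K: float, t0: float, t) -> np.ndarray | float:
    """Complete-wetting width a = K ((t + t0)/1 s)^(1/7), mm."""
    t = np.asarray(t, dtype=float)
    tt = t + t0
    if np.any(tt < 0):
        raise ValueError("t + t0 must be >= 0")
    a = K * tt**_SEVENTH
    return a if a.ndim else float(a)


def eval_partial_wetting(a_s: float, B: float, t0: float, t) -> np.ndarray | float:
    """Partial-wetting width a = a_s (1 - exp(-B (t + t0)))^(1/7), mm."""
    t = np.asarray(t, dtype=float)
    tt = t + t0
    if np.any(tt < 0):
        raise ValueError("t + t0 must be >= 0")
    a = a_s * (-np.expm1(-B * tt)) ** _SEVENTH
    return a if a.ndim else float(a)


def _aicc(rss: float, n: int, k: int) -> float:
    """Small-sample corrected Akaike criterion for Gaussian residuals."""
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    else:
        aic = math.inf
    return aic


def _weights(series: SpreadingSeries) -> np.ndarray:
    if series.sigma_a is None:
        return np.ones_like(series.a)
    return 1.0 / series.sigma_a


def _standard_errors(res, n: int, weighted: bool) -> np.ndarray:
    """Gauss-Newton covariance at the optimum: (J^T J)^-1 scaled by s^2.

    The residual variance estimate 2*cost/dof is applied in both the
    weighted and unweighted case (in the weighted case this rescales the
    stated sigmas by the observed scatter).
    """
    J = res.jac
    k = J.shape[1]
    dof = max(n - k, 1)
    JtJ_inv = np.linalg.pinv(J.T @ J)
    s2 = 2.0 * res.cost / dof
    return np.sqrt(np.clip(s2 * np.diag(JtJ_inv), 0.0, None))


def fit_complete_wetting(series: SpreadingSeries, fix_t0: bool = True) -> CompleteWettingFit:
    """Least-squares fit of the complete-wetting law to a width series.

    With ``fix_t0`` (default) t0 = 0 exactly and only K is adjusted; the
    free-t0 mode is a diagnostic and allows t0 of either sign (bounded
    below so t + t0 stays nonnegative).
    """
    n = len(series)
    if fix_t0 and n < 2:
        raise FitError("need >= 2 points to fit K")
    w = _weights(series)
    t, a = series.t, series.a

    # degenerate series: a constant explains the widths at least as well as
    # the power law (no spreading signal; K and t0 are then meaningless)
    rss_const = float(np.sum((a - a.mean()) ** 2))

    t_pos = np.where(t > 0, t, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        k0 = np.nanmedian(a / t_pos**_SEVENTH)
    if not np.isfinite(k0) or k0 <= 0:
        k0 = float(np.max(a))

    if fix_t0:
        def resid(p):
            return w * (eval_complete_wetting(p[0], 0.0, t) - a)

        res = least_squares(resid, x0=[k0], bounds=([1e-12], [np.inf]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not res.success:
            raise FitError(f"complete-wetting fit did not converge: {res.message}")
        se = _standard_errors(res, n, series.sigma_a is not None)
        K = float(res.x[0])
        rss = float(np.sum((eval_complete_wetting(K, 0.0, t) - a) ** 2))
        return CompleteWettingFit(K=K, t0=0.0, se_K=float(se[0]), se_t0=0.0,
                                  rss=rss, t0_fixed=True, n_points=n,
                                  aicc=_aicc(rss, n, 1), degenerate=rss >= rss_const)

    if n < 3:
        raise FitError("need >= 3 points for a free-t0 fit")

    def resid(p):
        return w * (eval_complete_wetting(p[0], p[1], t) - a)

    t0_lo = -float(t[0])  # keep t + t0 >= 0
    res = least_squares(resid, x0=[k0, 1e-3], bounds=([1e-12, t0_lo], [np.inf, np.inf]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success:
        raise FitError(f"complete-wetting fit did not converge: {res.message}")
    se = _standard_errors(res, n, series.sigma_a is not None)
    K, t0 = map(float, res.x)
    rss = float(np.sum((eval_complete_wetting(K, t0, t) - a) ** 2))
    return CompleteWettingFit(K=K, t0=t0, se_K=float(se[0]), se_t0=float(se[1]),
                              rss=rss, t0_fixed=False, n_points=n,
                              aicc=_aicc(rss, n, 2), degenerate=rss >= rss_const)


def fit_partial_wetting(series: SpreadingSeries, fix_t0: bool = True) -> PartialWettingFit:
    """Least-squares fit of the partial-wetting law.

    Initialization: a_s = 1.05 * max(a); B from the time at which the
    series crosses (1 - 1/e)^(1/7) * a_s.
    """
    n = len(series)
    if n < 3:
        raise FitError("need >= 3 points to fit the partial-wetting law")
    w = _weights(series)
    t, a = series.t, series.a

    a_s0 = 1.05 * float(np.max(a))
    level = (1.0 - math.exp(-1.0)) ** _SEVENTH * a_s0
    above = np.nonzero(a >= level)[0]
    if len(above) and t[above[0]] > 0:
        b0 = 1.0 / float(t[above[0]])
    else:
        b0 = 1.0 / float(t[-1]) if t[-1] > 0 else 1.0

    if fix_t0:
        def resid(p):
            return w * (eval_partial_wetting(p[0], p[1], 0.0, t) - a)

        res = least_squares(resid, x0=[a_s0, b0], bounds=([1e-12, 1e-12], [np.inf, np.inf]),
                            xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if not res.success and res.status != 0:
            raise FitError(f"partial-wetting fit did not converge: {res.message}")
        # status 0 (max evaluations) happens on the flat a_s -> inf, B -> 0
        # ridge of unbounded t^{1/7} data; the point found is a valid
        # least-squares solution on the ridge and is returned as-is
        se = _standard_errors(res, n, series.sigma_a is not None)
        a_s, B = map(float, res.x)
        rss = float(np.sum((eval_partial_wetting(a_s, B, 0.0, t) - a) ** 2))
        return PartialWettingFit(a_s=a_s, B=B, t0=0.0, se_a_s=float(se[0]),
                                 se_B=float(se[1]), se_t0=0.0, rss=rss,
                                 t0_fixed=True, n_points=n, aicc=_aicc(rss, n, 2))

    if n < 4:
        raise FitError("need >= 4 points for a free-t0 partial-wetting fit")

    def resid(p):
        return w * (eval_partial_wetting(p[0], p[1], p[2], t) - a)

    t0_lo = -float(t[0])
    res = least_squares(resid, x0=[a_s0, b0, 1e-3],
                        bounds=([1e-12, 1e-12, t0_lo], [np.inf, np.inf, np.inf]),
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not res.success and res.status != 0:
        raise FitError(f"partial-wetting fit did not converge: {res.message}")
    se = _standard_errors(res, n, series.sigma_a is not None)
    a_s, B, t0 = map(float, res.x)
    rss = float(np.sum((eval_partial_wetting(a_s, B, t0, t) - a) ** 2))
    return PartialWettingFit(a_s=a_s, B=B, t0=t0, se_a_s=float(se[0]), se_B=float(se[1]),
                             se_t0=float(se[2]), rss=rss, t0_fixed=False,
                             n_points=n, aicc=_aicc(rss, n, 3))


def fit_free_exponent(series: SpreadingSeries) -> tuple[float, float]:
    """Diagnostic power-law fit a = K t^p with a free exponent.

    Ordinary least squares in log-log space (requires t > 0).  Returns
    (K, p).  On data generated by the complete-wetting law the exponent
    comes back as exactly 1/7.
    """
    mask = series.t > 0
    if mask.sum() < 3:
        raise FitError("need >= 3 points with t > 0 for a free-exponent fit")
    lt = np.log(series.t[mask])
    la = np.log(series.a[mask])
    p, logK = np.polyfit(lt, la, 1)
    return float(np.exp(logK)), float(p)


def initial_prefactor(fit: PartialWettingFit) -> float:
    """Initial-spreading prefactor a_s * B^(1/7) (mm).

    The first-order expansion of the partial-wetting law is
    a(t) ~ a_s B^(1/7) t^(1/7), so this quantity is directly comparable,
    unit for unit, with the complete-wetting prefactor K.
    """
    return fit.a_s * fit.B**_SEVENTH


def viscosity_from_concentration(params: MaterialParams) -> float:
    """Dilute-solution viscosity eta(c) = eta_S (1 + [eta] c / 3)^3, Pa s."""
    if params.eta_S is None or params.intrinsic_viscosity is None or params.c is None:
        raise ValueError("eta_S, intrinsic_viscosity and c must all be set")
    return params.eta_S * (1.0 + params.intrinsic_viscosity * params.c / 3.0) ** 3


def prefactor_ratio_from_viscosity(eta1: float, eta2: float) -> float:
    """K2/K1 = (eta1/eta2)^(1/7) at constant surface tension and throughput."""
    if not (eta1 > 0 and eta2 > 0):
        raise ValueError("viscosities must be > 0")
    return (eta1 / eta2) ** _SEVENTH


def full_form_prefactor(params: MaterialParams, kappa: float) -> float:
    """Complete-wetting prefactor from material constants.

    K = (gamma_L * 18 * 7 * kappa^3 / (lambda * eta))^(1/7), evaluated
    in SI (kappa converted from mm^2) and returned in mm.  Requires the
    universal constant lambda, for which no published value exists.
    """
    if params.lambda_const is None:
        raise ValueError("lambda required: the universal constant lambda_const is unset")
    if params.gamma_L is None or params.eta is None:
        raise ValueError("gamma_L and eta must be set")
    if not (kappa > 0):
        raise ValueError("kappa must be > 0")
    kappa_m2 = kappa * 1e-6
    K_m = (params.gamma_L * 18.0 * 7.0 * kappa_m2**3
           / (params.lambda_const * params.eta)) ** _SEVENTH
    return K_m * 1e3


def partial_wetting_rate(params: MaterialParams, kappa: float, a_s: float) -> float:
    """Partial-wetting rate constant B = 4 gamma_L 18 kappa^3 / (lambda eta a_s^7), 1/s.

    Same material constants as :func:`full_form_prefactor`; kappa in
    mm^2 and a_s in mm are converted to SI internally.  For identical
    parameters K^7 / (B a_s^7) = 7/4.
    """
    if params.lambda_const is None:
        raise ValueError("lambda required: the universal constant lambda_const is unset")
    if params.gamma_L is None or params.eta is None:
        raise ValueError("gamma_L and eta must be set")
    if not (kappa > 0 and a_s > 0):
        raise ValueError("kappa and a_s must be > 0")
    kappa_m2 = kappa * 1e-6
    a_s_m = a_s * 1e-3
    return (4.0 * params.gamma_L * 18.0 * kappa_m2**3
            / (params.lambda_const * params.eta * a_s_m**7))


@dataclass(frozen=True)
class ModelSelection:
    """Outcome of comparing the two wetting laws on one series by AICc."""

    chosen: str  # "complete" | "partial" | "tie"
    complete: CompleteWettingFit
    partial: PartialWettingFit
    delta_aicc: float  # aicc(partial) - aicc(complete)

    def to_json(self) -> str:
        return json.dumps(
            {
                "chosen": self.chosen,
                "delta_aicc": self.delta_aicc,
                "complete": json.loads(self.complete.to_json()),
                "partial": json.loads(self.partial.to_json()),
            }
        )


def model_selection(series: SpreadingSeries, tie_threshold: float = 2.0) -> ModelSelection:
    """Fit both wetting laws (t0 = 0) and pick the lower-AICc model.

    An AICc gap below ``tie_threshold`` is reported as a tie; both fits
    are always returned.  Unbounded t^(1/7) growth selects complete
    wetting, saturating data select partial wetting.
    """
    if len(series) < 4:
        raise FitError("model selection needs >= 4 points")
    cw = fit_complete_wetting(series, fix_t0=True)
    pw = fit_partial_wetting(series, fix_t0=True)
    delta = pw.aicc - cw.aicc
    if abs(delta) < tie_threshold:
        chosen = "tie"
    else:
        chosen = "complete" if delta > 0 else "partial"
    return ModelSelection(chosen=chosen, complete=cw, partial=pw, delta_aicc=delta)


def cell_volume_fraction(density_per_ml: float, mean_volume_um3: float) -> float:
    """Volume fraction (% vol) occupied by cells of a given mean volume.

    density in cells/ml, mean single-cell volume in um^3; 1 ml = 1e12 um^3.
    """
    if density_per_ml < 0 or mean_volume_um3 < 0:
        raise ValueError("inputs must be nonnegative")
    return density_per_ml * mean_volume_um3 * 1e-12 * 100.0
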