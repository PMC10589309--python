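"""Closed-form speckle contrast models, sensitivity analysis and tau_c fitting.

Three dynamics regimes are covered, each with its own field correlation
shape g1 and exposure-integrated contrast law K(x), x = T/tau_c:

``SO``
    single scattering, ordered motion ("large vessels"); Gaussian g1.
``MO_SU``
    multiple scattering ordered / single scattering unordered motion
    ("medium-sized vessels"); exponential g1.
``MU``
    multiple scattering, unordered motion ("parenchyma");
    g1 = exp(-sqrt(tau/tau_c)).

Each contrast law has the form

    K = sqrt(beta) * sqrt( rho^2 * D(x) + a * rho(1-rho) * X(x) + (1-rho)^2 ) + C

with a dynamic term D, a dynamic-static cross term X, the static floor
(1-rho)^2, the coherence degree beta, the dynamic scattering fraction rho
and a noise offset C.  At x -> 0 the bracket sums to (rho + (1-rho))^2 = 1,
so K -> sqrt(beta) + C.

Flow sensitivity is defined against the flow speed v ~ 1/tau_c:
absolute S_a = |dK/dv| and relative S_r = |dK/K / (dv/v)| = x*|dK/dx|/K.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.optimize import curve_fit, minimize_scalar
from scipy.special import erf

from .errors import DomainError, FitError, ParameterError
from .field_synthesis import FrameStack

__all__ = [
    "Regime",
    "ModelParams",
    "G2Curve",
    "FitResult",
    "contrast_K",
    "absolute_sensitivity",
    "relative_sensitivity",
    "optimal_exposure",
    "g2_autocorrelation",
    "fit_tau_c",
    "SENSITIVITY_PRESETS",
]


class Regime(enum.Enum):
    """Dynamics regime: scattering order crossed with motion type."""

    SO = "single_ordered"          # large vessels
    MO_SU = "multiple_ordered"     # medium vessels / single unordered
    MU = "multiple_unordered"      # parenchyma


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the contrast laws.

    beta : coherence degree in (0, 1]; 1 for ideal polarised detection.
    rho  : dynamic scattering fraction in [0, 1]; 1-rho is the static floor.
    C    : additive contrast offset caused by noise, >= 0.
    tau_c: decorrelation time (us), > 0.
    """

    beta: float = 1.0
    rho: float = 1.0
    C: float = 0.0
    tau_c: float = 20.0

    def __post_init__(self):
        if not (0 < self.beta <= 1):
            raise ParameterError("beta must be in (0, 1]")
        if not (0 <= self.rho <= 1):
            raise ParameterError("rho must be in [0, 1]")
        if self.C < 0:
            raise ParameterError("C must be >= 0")
        if self.tau_c <= 0:
            raise DomainError("tau_c must be positive")


# ---------------------------------------------------------------------------
# bracket terms, with small-x series to avoid catastrophic cancellation
# ---------------------------------------------------------------------------

_SMALL_X = 1e-3


def _terms_mo_su(x):
    dyn = np.where(
        x < _SMALL_X,
        1.0 - 2.0 * x / 3.0 + x * x / 3.0,
        (np.expm1(-2.0 * x) + 2.0 * x) / (2.0 * x * x),
    )
    cross = np.where(
        x < _SMALL_X,
        0.5 - x / 6.0 + x * x / 24.0,
        (np.expm1(-x) + x) / (x * x),
    )
    return dyn, 4.0, cross


def _terms_mu(x):
    s = np.sqrt(x)
    dyn = np.where(
        x < _SMALL_X,
        1.0 - 16.0 * s / 15.0 + 2.0 * x / 3.0 - 32.0 * s * x / 105.0,
        (np.exp(-2.0 * s) * (4.0 * x + 6.0 * s + 3.0) + 2.0 * x - 3.0)
        / (2.0 * x * x),
    )
    cross = np.where(
        x < _SMALL_X,
        0.25 - 2.0 * s / 15.0 + x / 24.0 - s * x / 105.0,
        (np.exp(-s) * (2.0 * x + 6.0 * s + 6.0) + x - 6.0) / (x * x),
    )
    return dyn, 8.0, cross


def _terms_so(x):
    x2 = x * x
    dyn = np.where(
        x < _SMALL_X,
        1.0 - x2 / 3.0 + 2.0 * x2 * x2 / 15.0,
        (np.exp(-2.0 * x2) + np.sqrt(2.0 * np.pi) * erf(np.sqrt(2.0) * x) * x - 1.0)
        / (2.0 * x2),
    )
    cross = np.where(
        x < _SMALL_X,
        1.0 - x2 / 6.0 + x2 * x2 / 30.0,
        (np.exp(-x2) + np.sqrt(np.pi) * erf(x) * x - 1.0) / x2,
    )
    return dyn, 2.0, cross


_TERMS = {Regime.SO: _terms_so, Regime.MO_SU: _terms_mo_su, Regime.MU: _terms_mu}


def _bracket(x, rho: float, regime: Regime):
    with np.errstate(divide="ignore", invalid="ignore"):
        dyn, a, cross = _TERMS[regime](np.asarray(x, dtype=np.float64))
    return rho * rho * dyn + a * rho * (1.0 - rho) * cross + (1.0 - rho) ** 2


def contrast_K(
    T, params: ModelParams, regime: Regime = Regime.MO_SU
) -> Union[float, np.ndarray]:
    """Exposure-integrated contrast K(T) for the given regime.

    Below x = T/tau_c = 1e-3 the bracket terms are evaluated by their Taylor
    series (the closed forms lose all significant digits to cancellation).
    """
    T = np.asarray(T, dtype=np.float64)
    if np.any(T < 0):
        raise ParameterError("exposure T must be >= 0")
    x = T / params.tau_c
    out = math.sqrt(params.beta) * np.sqrt(
        np.maximum(_bracket(x, params.rho, regime), 0.0)
    ) + params.C
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# sensitivity
# ---------------------------------------------------------------------------

_REL_STEP = 1e-5


def absolute_sensitivity(
    T: float, params: ModelParams, regime: Regime = Regime.MO_SU
) -> float:
    """Absolute flow sensitivity S_a = |dK/dv| with v = 1/tau_c.

    Central finite difference on v with relative step 1e-5.  Independent of
    the offset C.
    """
    if T <= 0:
        raise ParameterError("T must be positive")
    v = 1.0 / params.tau_c
    h = v * _REL_STEP

    def k_of_v(vv):
        return contrast_K(
            T,
            ModelParams(params.beta, params.rho, params.C, 1.0 / vv),
            regime,
        )

    return abs((k_of_v(v + h) - k_of_v(v - h)) / (2.0 * h))


def relative_sensitivity(
    T: float, params: ModelParams, regime: Regime = Regime.MO_SU
) -> float:
    """Relative flow sensitivity S_r = |dK/K / (dv/v)| = x*|dK/dx|/K."""
    K = contrast_K(T, params, regime)
    if K == 0:
        raise DomainError("K = 0; relative sensitivity undefined")
    v = 1.0 / params.tau_c
    return v * absolute_sensitivity(T, params, regime) / K


@dataclass(frozen=True)
class OptimalExposure:
    x_star: float
    T_star: float
    S_r_max: float
    on_boundary: bool


def optimal_exposure(
    params: ModelParams,
    regime: Regime = Regime.MO_SU,
    x_range: tuple = (1e-2, 1e3),
    n_grid: int = 200,
) -> OptimalExposure:
    """Exposure ratio x* = T*/tau_c maximising the relative sensitivity.

    Log-spaced grid search followed by bounded local refinement.  When the
    argmax sits at the edge of ``x_range`` (the saturating C=0, rho=1 case
    has no interior maximum) the result is flagged ``on_boundary``.
    """
    lo, hi = x_range
    if not (0 < lo < hi) or not np.isfinite(hi):
        raise ParameterError("x_range must be positive and finite")
    xs = np.geomspace(lo, hi, n_grid)
    sr = np.array(
        [relative_sensitivity(x * params.tau_c, params, regime) for x in xs]
    )
    i = int(np.argmax(sr))
    if i in (0, n_grid - 1):
        return OptimalExposure(
            x_star=float(xs[i]),
            T_star=float(xs[i] * params.tau_c),
            S_r_max=float(sr[i]),
            on_boundary=True,
        )
    res = minimize_scalar(
        lambda lx: -relative_sensitivity(math.exp(lx) * params.tau_c, params, regime),
        bounds=(math.log(xs[i - 1]), math.log(xs[i + 1])),
        method="bounded",
        options={"xatol": 1e-8},
    )
    x_star = math.exp(res.x)
    return OptimalExposure(
        x_star=float(x_star),
        T_star=float(x_star * params.tau_c),
        S_r_max=float(-res.fun),
        on_boundary=False,
    )


# ---------------------------------------------------------------------------
# g2 and tau_c fitting
# ---------------------------------------------------------------------------

@dataclass
class G2Curve:
    """Pixel-averaged intensity autocorrelation g2(tau)."""

    lags: np.ndarray  # us
    values: np.ndarray
    beta_hat: Optional[float] = None


def g2_autocorrelation(
    stack: Union[FrameStack, np.ndarray], max_lag: int, dt: Optional[float] = None
) -> G2Curve:
    """g2(tau) = <I(t) I(t+tau)>_t / <I(t)>_t^2 per pixel, averaged over pixels.

    ``max_lag`` is in frames; requires an instantaneous, stationary stack of
    length >= 10 x max_lag.  Pixels with zero temporal mean are excluded.
    For fully developed polarised speckle g2(0) ~ 2 (Siegert zero lag 1+beta).
    """
    if isinstance(stack, FrameStack):
        frames, dt = stack.frames, stack.dt
    else:
        frames = np.asarray(stack)
        if dt is None:
            dt = 1.0
    T = frames.shape[0]
    if max_lag < 1 or T < 10 * max_lag:
        raise ParameterError("stack length must be >= 10 x max_lag")
    I = frames.reshape(T, -1).astype(np.float64)
    mean = I.mean(axis=0)
    keep = mean > 0
    if not keep.any():
        raise DomainError("all pixels have zero mean")
    I = I[:, keep]
    mean2 = mean[keep] ** 2
    g2 = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        a = I[: T - lag] if lag else I
        b = I[lag:] if lag else I
        g2[lag] = ((a * b).mean(axis=0) / mean2).mean()
    return G2Curve(lags=np.arange(max_lag + 1) * dt, values=g2)


_G1 = {
    Regime.SO: lambda t, tc: np.exp(-((t / tc) ** 2)),
    Regime.MO_SU: lambda t, tc: np.exp(-t / tc),
    Regime.MU: lambda t, tc: np.exp(-np.sqrt(t / tc)),
}


@dataclass
class FitResult:
    tau_c: float
    beta: float
    regime: Regime


def fit_tau_c(
    curve: G2Curve,
    regime: Regime = Regime.SO,
    beta: Union[str, float] = "free",
    fit_window: bool = True,
) -> FitResult:
    """Least-squares fit of the Siegert relation g2 = 1 + beta*|g1|^2.

    g1 is the regime's field correlation (Gaussian for SO, exponential for
    MO_SU, stretched-exponential for MU).  ``beta`` may be fixed or fitted.
    With ``fit_window`` the fit is restricted to the decaying part of the
    curve (down to 5% of the zero-lag amplitude): the long-lag tail of a
    finite-series estimate is dominated by normalisation bias, not by g1.

    Raises `FitError` when the curve does not decay below 1 + 0.05*beta
    within the lag window.
    """
    lags = np.asarray(curve.lags, dtype=np.float64)
    vals = np.asarray(curve.values, dtype=np.float64)
    amp = vals[0] - 1.0
    beta_ref = amp if beta == "free" else float(beta)
    if amp <= 0 or not np.any(vals < 1.0 + 0.05 * max(beta_ref, 1e-9)):
        raise FitError("g2 curve does not decay within the lag window")
    if fit_window:
        below = np.where(vals < 1.0 + 0.05 * amp)[0]
        end = int(below[0]) + 1 if len(below) else len(vals)
        lags, vals = lags[: max(end, 4)], vals[: max(end, 4)]
    g1 = _G1[regime]
    tc0 = lags[min(len(lags) // 2, len(lags) - 1)] or 1.0

    if beta == "free":
        def model(t, b, tc):
            return 1.0 + b * g1(t, tc) ** 2

        p0 = [max(amp, 0.1), tc0]
        bounds = ([1e-6, 1e-9], [2.5, np.inf])
    else:
        def model(t, tc):
            return 1.0 + float(beta) * g1(t, tc) ** 2

        p0 = [tc0]
        bounds = ([1e-9], [np.inf])
    try:
        popt, _ = curve_fit(model, lags, vals, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover
        raise FitError(f"tau_c fit failed to converge: {exc}") from exc
    if beta == "free":
        return FitResult(tau_c=float(popt[1]), beta=float(popt[0]), regime=regime)
    return FitResult(tau_c=float(popt[0]), beta=float(beta), regime=regime)


# ---------------------------------------------------------------------------
# named parameterizations of the sensitivity analysis
# ---------------------------------------------------------------------------

#: Vessel-type presets for the sensitivity curves: tau_c (us) by tissue
#: compartment, with 'simplified' (rho=1, C=0) and 'realistic' (C=0.01;
#: rho=0.8 in parenchyma) parameterizations.
SENSITIVITY_PRESETS = {
    "simplified": {
        "large_vessel": (Regime.SO, ModelParams(beta=1.0, rho=1.0, C=0.0, tau_c=75.0)),
        "medium_vessel": (
            Regime.MO_SU,
            ModelParams(beta=1.0, rho=1.0, C=0.0, tau_c=150.0),
        ),
        "parenchyma": (Regime.MU, ModelParams(beta=1.0, rho=1.0, C=0.0, tau_c=250.0)),
    },
    "realistic": {
        "large_vessel": (Regime.SO, ModelParams(beta=1.0, rho=1.0, C=0.01, tau_c=75.0)),
        "medium_vessel": (
            Regime.MO_SU,
            ModelParams(beta=1.0, rho=1.0, C=0.01, tau_c=150.0),
        ),
        "parenchyma": (Regime.MU, ModelParams(beta=1.0, rho=0.8, C=0.01, tau_c=250.0)),
    },
}
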