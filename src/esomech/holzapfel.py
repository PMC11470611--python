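"""Holzapfel-type anisotropic hyperelasticity for planar-biaxial membranes.

Strain energy density (kPa, equivalently kJ/m^3)::

    W = c/2 (I1 - 3) + k1/k2 [exp(k2 (I4 - 1)^2) - 1]

with ``I1 = l_t^2 + l_z^2 + l_r^2`` and ``I4 = l_t^2 cos^2(theta) +
l_z^2 sin^2(theta)``, where ``l_t``/``l_z`` are the circumferential/axial
stretch ratios, ``l_r = 1/(l_t l_z)`` by incompressibility, and ``theta``
is the collagen-fiber angle measured from the circumferential axis.
``c`` and ``k1`` are stress-like (kPa), ``k2`` is the dimensionless
stiffening exponent.

The in-plane Cauchy stresses follow by eliminating the hydrostatic
pressure with the plane-stress condition ``sigma_rr = 0``::

    sigma_tt = 2 (l_t^2 - l_t^-2 l_z^-2) dW/dI1 + 2 l_t^2 cos^2(theta) dW/dI4
    sigma_zz = 2 (l_z^2 - l_z^-2 l_t^-2) dW/dI1 + 2 l_z^2 sin^2(theta) dW/dI4

The ``l_z^2`` factor in the fiber term of ``sigma_zz`` is the chain-rule
consistent form (``dI4/dl_z = 2 l_z sin^2 theta``); a published variant that
uses ``l_t^2`` in that slot is available through ``zz_fiber_factor="theta"``
for comparison, but it breaks the equality between the analytic stresses and
the stretch-derivatives of W.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .curves import AXIAL, CIRCUMFERENTIAL, DIRECTIONS, BiaxialTest

_EXP_GUARD = 700.0  # exp argument beyond which float64 overflows
_EXP_CLIP = 60.0  # soft cap used inside optimisation residuals


@dataclass(frozen=True)
class HolzapfelParams:
    """Constitutive parameter vector ``(c, k1, k2, theta)``.

    c : isotropic (ground-matrix) stiffness, kPa, strictly positive
    k1 : fiber stiffness, kPa, non-negative
    k2 : dimensionless fiber stiffening exponent, strictly positive
    theta : fiber angle from the circumferential axis, radians, in [0, pi]
    """

    c: float
    k1: float
    k2: float
    theta: float

    def __post_init__(self) -> None:
        if not self.c > 0:
            raise ValueError("c must be positive")
        if self.k1 < 0:
            raise ValueError("k1 must be non-negative")
        if not self.k2 > 0:
            raise ValueError("k2 must be positive")
        if not 0.0 <= self.theta <= math.pi:
            raise ValueError("theta must lie in [0, pi]")

    def as_array(self) -> np.ndarray:
        return np.array([self.c, self.k1, self.k2, self.theta])


@dataclass(frozen=True)
class StretchState:
    """Incompressible biaxial stretch state; ``lambda_r`` is derived."""

    lambda_theta: float
    lambda_z: float

    def __post_init__(self) -> None:
        if not (self.lambda_theta > 0 and self.lambda_z > 0):
            raise ValueError("stretches must be positive")

    @property
    def lambda_r(self) -> float:
        return 1.0 / (self.lambda_theta * self.lambda_z)


@dataclass(frozen=True)
class StressPair:
    sigma_thetatheta: float
    sigma_zz: float


@dataclass
class FitMetrics:
    """Per-direction goodness of fit: normalized error and correlation."""

    epsilon_axial: float
    epsilon_circ: float
    r2_axial: float
    r2_circ: float
    n: int
    q: int


def invariants(state: StretchState, theta: float) -> tuple[float, float]:
    """Deformation invariants ``(I1, I4)`` for an incompressible biaxial state."""
    lt, lz = state.lambda_theta, state.lambda_z
    i1 = lt**2 + lz**2 + (lt * lz) ** -2
    i4 = lt**2 * math.cos(theta) ** 2 + lz**2 * math.sin(theta) ** 2
    return i1, i4


def _fiber_exponent(params: HolzapfelParams, i4):
    return params.k2 * (np.asarray(i4) - 1.0) ** 2


def strain_energy(
    params: HolzapfelParams,
    state: StretchState,
    tension_only: bool = True,
    split_prefactor: bool = False,
) -> float:
    """Strain energy density W in kPa.

    ``tension_only`` zeroes the fiber term for ``I4 < 1`` (fibers do not
    support compression); irrelevant on equibiaxial paths with stretch >= 1.
    ``split_prefactor`` uses the common ``k1/(2 k2)`` prefactor instead of
    the ``k1/k2`` default.
    """
    i1, i4 = invariants(state, params.theta)
    expo = float(_fiber_exponent(params, i4))
    if expo > _EXP_GUARD:
        raise OverflowError(
            f"fiber term overflows: k2 (I4-1)^2 = {expo:.3g} at state {state}"
        )
    pref = params.k1 / (2.0 * params.k2) if split_prefactor else params.k1 / params.k2
    fiber = 0.0 if (tension_only and i4 < 1.0) else pref * (math.exp(expo) - 1.0)
    return params.c / 2.0 * (i1 - 3.0) + fiber


def _dW_dI4(params: HolzapfelParams, i4, tension_only: bool = True, clip: bool = False):
    """dW/dI4 = 2 k1 (I4-1) exp(k2 (I4-1)^2), zero in compression."""
    i4 = np.asarray(i4, dtype=float)
    expo = _fiber_exponent(params, i4)
    if clip:
        expo = np.minimum(expo, _EXP_CLIP)
    elif np.any(expo > _EXP_GUARD):
        raise OverflowError(f"fiber term overflows: k2 (I4-1)^2 = {np.max(expo):.3g}")
    out = 2.0 * params.k1 * (i4 - 1.0) * np.exp(expo)
    if tension_only:
        out = np.where(i4 < 1.0, 0.0, out)
    return out


def cauchy_stresses(
    params: HolzapfelParams,
    state: StretchState,
    tension_only: bool = True,
    zz_fiber_factor: str = "z",
) -> StressPair:
    """In-plane Cauchy stresses (kPa) with the pressure eliminated.

    ``zz_fiber_factor='z'`` (default) uses the chain-rule factor
    ``l_z^2 sin^2 theta`` in the axial fiber term; ``'theta'`` reproduces the
    variant with ``l_t^2`` in that slot.
    """
    lt, lz = state.lambda_theta, state.lambda_z
    _, i4 = invariants(state, params.theta)
    dW1 = params.c / 2.0
    dW4 = float(_dW_dI4(params, i4, tension_only))
    iso_tt = 2.0 * (lt**2 - lt**-2 * lz**-2) * dW1
    iso_zz = 2.0 * (lz**2 - lz**-2 * lt**-2) * dW1
    fib_tt = 2.0 * lt**2 * math.cos(params.theta) ** 2 * dW4
    zz_sq = lz**2 if zz_fiber_factor == "z" else lt**2
    fib_zz = 2.0 * zz_sq * math.sin(params.theta) ** 2 * dW4
    return StressPair(sigma_thetatheta=iso_tt + fib_tt, sigma_zz=iso_zz + fib_zz)


def equibiaxial_stresses(
    params: HolzapfelParams,
    lam: np.ndarray,
    tension_only: bool = True,
    clip: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized ``(sigma_tt, sigma_zz)`` along an equibiaxial path.

    On the equibiaxial path ``l_t = l_z = lam`` the invariants reduce to
    ``I1 = 2 lam^2 + lam^-4`` and ``I4 = lam^2``; the fiber angle enters the
    stresses only through the ``cos^2``/``sin^2`` weights.
    """
    lam = np.asarray(lam, dtype=float)
    i4 = lam**2
    dW1 = params.c / 2.0
    dW4 = _dW_dI4(params, i4, tension_only, clip=clip)
    iso = 2.0 * (lam**2 - lam**-4) * dW1
    sig_tt = iso + 2.0 * lam**2 * math.cos(params.theta) ** 2 * dW4
    sig_zz = iso + 2.0 * lam**2 * math.sin(params.theta) ** 2 * dW4
    return sig_tt, sig_zz


def predicted_test_stresses(
    params_axial: HolzapfelParams,
    params_circ: HolzapfelParams,
    lam: np.ndarray,
    clip: bool = False,
) -> dict[str, np.ndarray]:
    """Model curves for both directions, each from its own parameter set."""
    _, sig_zz = equibiaxial_stresses(params_axial, lam, clip=clip)
    sig_tt, _ = equibiaxial_stresses(params_circ, lam, clip=clip)
    return {AXIAL: sig_zz, CIRCUMFERENTIAL: sig_tt}


def theta_degrees(params: HolzapfelParams | float) -> float:
    """Fiber angle in degrees from the circumferential axis."""
    theta = params.theta if isinstance(params, HolzapfelParams) else float(params)
    return math.degrees(theta)


# ---------------------------------------------------------------------------
# objective and fit metrics
# ---------------------------------------------------------------------------


def objective(params: HolzapfelParams, test: BiaxialTest) -> float:
    """Joint sum of squared stress residuals over both directions."""
    lam = test.stretch
    pred = predicted_test_stresses(params, params, lam)
    r_ax = test.axial.stress - pred[AXIAL]
    r_ci = test.circumferential.stress - pred[CIRCUMFERENTIAL]
    return float(np.sum(r_ax**2) + np.sum(r_ci**2))


def fit_error_metric(pred: np.ndarray, obs: np.ndarray, q: int = 0) -> float:
    """Normalized RMS fitting error.

    ``eps = sqrt(sum((obs - pred)^2) / (n - q)) / mean(pred)`` -- the
    normalisation uses the mean of the *predicted* stresses, and ``q``
    counts parameters fitted to this very record (0 when scoring a model on
    fresh data).
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    n = pred.size
    if obs.size != n:
        raise ValueError("pred and obs must have equal length")
    if n <= q:
        raise ValueError(f"need n > q, got n={n}, q={q}")
    sigma_ref = pred.mean()
    if sigma_ref == 0:
        raise ZeroDivisionError("mean predicted stress is zero")
    return float(np.sqrt(np.sum((obs - pred) ** 2) / (n - q)) / sigma_ref)


def correlation_coefficient(pred: np.ndarray, obs: np.ndarray) -> float:
    """Pearson correlation R between predicted and observed stresses."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.size < 2 or pred.size != obs.size:
        raise ValueError("need two sequences of equal length >= 2")
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise ValueError("correlation undefined for a constant sequence")
    return float(np.corrcoef(pred, obs)[0, 1])


def correlation_r2(pred: np.ndarray, obs: np.ndarray) -> float:
    """Squared Pearson correlation."""
    return correlation_coefficient(pred, obs) ** 2


# ---------------------------------------------------------------------------
# Levenberg-Marquardt fitting
# ---------------------------------------------------------------------------

_LOWER = np.array([1e-8, 0.0, 1e-8, 0.0])
_UPPER = np.array([np.inf, np.inf, 1e3, math.pi])


@dataclass
class FitResult:
    """Outcome of a constitutive fit.

    ``params`` maps direction -> parameter set (per-direction mode) or holds
    the single shared set under both keys (joint mode).
    """

    params: dict[str, HolzapfelParams]
    metrics: FitMetrics
    converged: bool
    objective_value: float
    mode: str
    messages: dict[str, str]


def default_init(test: BiaxialTest, direction: str = AXIAL) -> HolzapfelParams:
    """Scale-aware starting point: c = (toe-region secant modulus)/2.

    The toe-region secant is taken over stretch 1..1.4 (or the curve's range
    if shorter); k1 starts equal to c, k2 at 1, theta at 45 degrees.
    """
    curve = test.curve(direction)
    hi = min(1.4, curve.stretch[-1])
    secant = (curve.stress_at(hi) - curve.stress[0]) / (hi - 1.0)
    c0 = max(float(secant) / 2.0, 1e-3)
    return HolzapfelParams(c=c0, k1=c0, k2=1.0, theta=math.pi / 4)


def _clip_to_bounds(x: np.ndarray) -> np.ndarray:
    return np.clip(x, _LOWER + 1e-12, np.minimum(_UPPER, 1e12))


def _direction_residuals(x, lam, obs, direction, theta_fixed):
    c, k1, k2 = x[0], x[1], x[2]
    theta = theta_fixed if theta_fixed is not None else x[3]
    p = HolzapfelParams(c=max(c, 1e-12), k1=max(k1, 0.0), k2=max(k2, 1e-12), theta=theta)
    sig_tt, sig_zz = equibiaxial_stresses(p, lam, clip=True)
    pred = sig_zz if direction == AXIAL else sig_tt
    return pred - obs


def _joint_residuals(x, lam, obs_ax, obs_ci):
    p = HolzapfelParams(c=max(x[0], 1e-12), k1=max(x[1], 0.0), k2=max(x[2], 1e-12), theta=x[3])
    sig_tt, sig_zz = equibiaxial_stresses(p, lam, clip=True)
    return np.concatenate([sig_tt - obs_ci, sig_zz - obs_ax])


def fit_holzapfel(
    test: BiaxialTest,
    init: HolzapfelParams | None = None,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
    mode: str = "per-direction",
    fix_theta: bool = False,
    max_iterations: int = 500,
) -> FitResult:
    """Least-squares estimation of the constitutive parameters.

    ``mode='per-direction'`` runs two independent fits, one per direction's
    stress curve (each with its own parameter set); ``mode='joint'``
    minimises the combined residual of both directions with a single shared
    set.  Trust-region Levenberg-Marquardt steps with simple bounds keep
    ``c > 0``, ``k1 >= 0``, ``k2 > 0`` and ``theta`` in ``[0, pi]``.

    Note on identifiability: on a strictly equibiaxial path a single
    direction's curve constrains only ``c``, ``k2`` and the *product* of
    ``k1`` with the angular weight (``sin^2 theta`` axially, ``cos^2 theta``
    circumferentially), so per-direction estimates of ``k1`` and ``theta``
    individually depend on the starting point.  ``fix_theta=True`` freezes
    ``theta`` at its initial value and fits the remaining three parameters,
    which are then fully identified.  The joint mode identifies all four.
    """
    if test.stretch.size < 8:
        raise ValueError("fit requires at least 8 samples")
    if not (np.any(test.axial.stress != 0) or np.any(test.circumferential.stress != 0)):
        raise ValueError("all stresses are zero; fit is ill-posed")
    lo, hi = bounds if bounds is not None else (_LOWER, _UPPER)
    lam = test.stretch

    def metrics_for(params_by_dir: dict[str, HolzapfelParams], q: int = 4) -> FitMetrics:
        pred = predicted_test_stresses(params_by_dir[AXIAL], params_by_dir[CIRCUMFERENTIAL], lam)
        return FitMetrics(
            epsilon_axial=fit_error_metric(pred[AXIAL], test.axial.stress, q=q),
            epsilon_circ=fit_error_metric(pred[CIRCUMFERENTIAL], test.circumferential.stress, q=q),
            r2_axial=correlation_r2(pred[AXIAL], test.axial.stress),
            r2_circ=correlation_r2(pred[CIRCUMFERENTIAL], test.circumferential.stress),
            n=lam.size,
            q=q,
        )

    if mode == "joint":
        p0 = init if init is not None else default_init(test)
        x0 = _clip_to_bounds(p0.as_array())
        res = least_squares(
            _joint_residuals,
            x0,
            bounds=(lo, hi),
            args=(lam, test.axial.stress, test.circumferential.stress),
            method="trf",
            max_nfev=max_iterations * 4,
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        p = HolzapfelParams(*res.x)
        params = {AXIAL: p, CIRCUMFERENTIAL: p}
        return FitResult(
            params=params,
            metrics=metrics_for(params),
            converged=res.status > 0,
            objective_value=float(2 * res.cost),
            mode=mode,
            messages={"joint": res.message},
        )

    if mode != "per-direction":
        raise ValueError(f"unknown mode {mode!r}")

    params: dict[str, HolzapfelParams] = {}
    messages: dict[str, str] = {}
    total = 0.0
    ok = True
    for direction in DIRECTIONS:
        p0 = init if init is not None else default_init(test, direction)
        theta_fixed = p0.theta if fix_theta else None
        x0_full = _clip_to_bounds(p0.as_array())
        if fix_theta:
            x0, blo, bhi = x0_full[:3], lo[:3], hi[:3]
        else:
            x0, blo, bhi = x0_full, lo, hi
        obs = test.curve(direction).stress
        res = least_squares(
            _direction_residuals,
            x0,
            bounds=(blo, bhi),
            args=(lam, obs, direction, theta_fixed),
            method="trf",
            max_nfev=max_iterations * 4,
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        theta = theta_fixed if fix_theta else float(res.x[3])
        params[direction] = HolzapfelParams(
            c=float(res.x[0]), k1=float(res.x[1]), k2=float(res.x[2]), theta=theta
        )
        messages[direction] = res.message
        ok = ok and res.status > 0
        total += float(2 * res.cost)

    return FitResult(
        params=params,
        metrics=metrics_for(params),
        converged=ok,
        objective_value=total,
        mode=mode,
        messages=messages,
    )
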