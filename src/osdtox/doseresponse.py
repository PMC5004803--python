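"""Dose-response models, nonlinear fitting, acceptance rules and ECx extraction.

This module is the shared engine for both analysis branches: per-OTU absolute
abundance (single-copy 16S gene equivalents) and functional endpoints such as
net nitrate production expressed as percent of control.

Two models are supported:

* ``loglogistic4`` -- the four-parameter log-logistic (sigmoidal) curve
  ``y = c + (d - c) / (1 + (x / e)**b)``, where ``d`` is the control (upper
  asymptote), ``c`` the lower asymptote, ``e`` the inflection dose (the EC50
  of the span) and ``b`` the slope around ``e``.
* ``hormesis5`` -- the Brain-Cousens extension
  ``y = c + (d - c + f*x) / (1 + (x / e)**b)`` whose extra parameter ``f``
  is the initial rate of stimulation at low doses.  With ``f = 0`` the two
  models are pointwise identical; under hormesis ``b`` and ``e`` lose their
  interpretation as slope and inflection point.

Fits are screened with three acceptance criteria before any ECx is trusted:
(1) ``b > 0`` (a declining response, i.e. inhibition), (2) ``e`` below the
maximum spiking concentration, and (3) ``R^2 > 0.65``.

No file I/O happens here; the module consumes and produces plain numbers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

ModelName = Literal["loglogistic4", "hormesis5"]
EcxMode = Literal["upper_asymptote", "span"]

#: Default coefficient-of-determination threshold for fit acceptance.
R2_MIN_DEFAULT = 0.65

#: Rejection reason labels.
SLOPE_NONPOSITIVE = "slope_nonpositive"
E_EXCEEDS_MAX_DOSE = "e_exceeds_max_dose"
R2_BELOW_THRESHOLD = "r2_below_threshold"
FIT_FAILED = "fit_failed"


class EcxNotAttainedError(ValueError):
    """The fitted curve never reaches the requested percent reduction."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogLogisticParams:
    """Parameters of the four-parameter log-logistic curve.

    b: slope around the inflection (dimensionless; positive = inhibition).
    c: lower asymptote (response units).
    d: upper asymptote, the control response (response units).
    e: inflection dose in mg kg^-1 (> 0); the EC50 of the c..d span.
    """

    b: float
    c: float
    d: float
    e: float

    def __post_init__(self) -> None:
        vec = (self.b, self.c, self.d, self.e)
        if not all(math.isfinite(v) for v in vec):
            raise ValueError(f"non-finite log-logistic parameters: {vec}")
        if self.e <= 0:
            raise ValueError(f"inflection dose e must be positive, got {self.e}")

    def as_array(self) -> np.ndarray:
        return np.array([self.b, self.c, self.d, self.e], dtype=float)


@dataclass(frozen=True)
class HormesisParams:
    """Parameters of the five-parameter Brain-Cousens hormesis curve.

    b, c, d, e as in :class:`LogLogisticParams`; f is the initial rate of
    increase at low doses (response units per mg kg^-1).  f = 0 recovers the
    log-logistic model exactly.
    """

    b: float
    c: float
    d: float
    e: float
    f: float

    def __post_init__(self) -> None:
        vec = (self.b, self.c, self.d, self.e, self.f)
        if not all(math.isfinite(v) for v in vec):
            raise ValueError(f"non-finite hormesis parameters: {vec}")
        if self.e <= 0:
            raise ValueError(f"parameter e must be positive, got {self.e}")

    def as_array(self) -> np.ndarray:
        return np.array([self.b, self.c, self.d, self.e, self.f], dtype=float)


@dataclass
class DoseSeries:
    """One endpoint observed along a toxicant dose gradient.

    doses: total metal concentration, mg Ag kg^-1 soil (>= 0, finite).
    responses: endpoint values (absolute OTU abundance, percent of control,
        or gene copies), one per dose.
    treatment: arm label (e.g. ``Ag+``, ``AgNP``, ``Ag2S-NP``).
    control_dose: background concentration of the untreated control soil
        (0.1 mg kg^-1 in the reference design); used as the control's dose so
        log-scale quantities stay defined.
    """

    doses: np.ndarray
    responses: np.ndarray
    treatment: str = ""
    control_dose: float = 0.1

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.doses.shape != self.responses.shape or self.doses.ndim != 1:
            raise ValueError("doses and responses must be equal-length 1-D arrays")
        if self.doses.size < 6:
            raise ValueError(
                f"need >= 6 observations for dose-response fitting, got {self.doses.size}"
            )
        if not np.all(np.isfinite(self.doses)) or np.any(self.doses < 0):
            raise ValueError("doses must be finite and >= 0")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses must be finite")
        if self.doses.max() <= self.control_dose:
            raise ValueError("maximum dose must exceed the control background dose")

    @property
    def max_dose(self) -> float:
        return float(self.doses.max())


@dataclass
class DoseResponseFit:
    """A fitted dose-response model with diagnostics and acceptance state.

    ``accepted`` is True iff ``rejection_reasons`` is empty; a fresh fit that
    converged starts accepted and may be rejected by
    :func:`apply_acceptance_criteria`.  ``covariance`` is the estimated
    parameter covariance s^2 (J^T J)^-1 on the natural parameter scale, or
    None when the Jacobian was singular at the optimum.
    """

    model: ModelName
    params: Optional[LogLogisticParams | HormesisParams]
    covariance: Optional[np.ndarray]
    r_squared: float
    residual_df: int
    accepted: bool
    rejection_reasons: list[str] = field(default_factory=list)
    hormesis_significant: Optional[bool] = None
    max_dose: float = math.nan
    control_dose: float = 0.1
    n_obs: int = 0
    ss_res: float = math.nan

    @property
    def failed(self) -> bool:
        return FIT_FAILED in self.rejection_reasons


@dataclass
class EcEstimate:
    """An ECx point estimate with optional delta-method confidence bounds.

    level: percent reduction p in (0, 100).
    value: dose (mg kg^-1) producing that reduction.
    mode: reference for the reduction -- ``upper_asymptote`` measures the
        drop from the control response d, ``span`` from the d..c span.
    below_background: True when the estimate falls below the control soil's
        background concentration (kept, but a numerical artefact).
    """

    level: float
    value: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    mode: EcxMode = "upper_asymptote"
    below_background: bool = False


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------


def eval_loglogistic(params: LogLogisticParams, dose):
    """Evaluate the four-parameter log-logistic curve at ``dose`` (scalar or array).

    Dose 0 returns the upper asymptote d for b > 0 (the zero-dose limit).
    """
    x = np.asarray(dose, dtype=float)
    if np.any(x < 0):
        raise ValueError("dose must be >= 0")
    with np.errstate(divide="ignore"):
        t = np.power(x / params.e, params.b)
    y = params.c + (params.d - params.c) / (1.0 + t)
    return y if y.ndim else float(y)


def eval_hormesis(params: HormesisParams, dose):
    """Evaluate the Brain-Cousens hormesis curve at ``dose`` (scalar or array).

    With f = 0 this is pointwise identical to :func:`eval_loglogistic`.
    """
    x = np.asarray(dose, dtype=float)
    if np.any(x < 0):
        raise ValueError("dose must be >= 0")
    with np.errstate(divide="ignore"):
        t = np.power(x / params.e, params.b)
    y = params.c + (params.d - params.c + params.f * x) / (1.0 + t)
    return y if y.ndim else float(y)


def _eval_vector(model: ModelName, theta: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Evaluate a model from a raw parameter vector (no validation)."""
    b, c, d, e = theta[0], theta[1], theta[2], theta[3]
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = np.power(np.asarray(x, dtype=float) / e, b)
        num = d - c if model == "loglogistic4" else d - c + theta[4] * np.asarray(x, dtype=float)
        return c + num / (1.0 + t)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _default_init(series: DoseSeries, model: ModelName) -> np.ndarray:
    """Robust starting values for automated batch fitting.

    d from the mean response at the two lowest doses, c floored at 0, e at
    the geometric mean of the positive doses, unit slope, no stimulation.
    """
    order = np.argsort(series.doses)
    d0 = float(np.mean(series.responses[order[:2]]))
    c0 = min(0.0, float(series.responses.min()))
    pos = series.doses[series.doses > 0]
    e0 = float(np.exp(np.mean(np.log(pos)))) if pos.size else 1.0
    theta = [1.0, c0, d0, e0]
    if model == "hormesis5":
        theta.append(0.0)
    return np.array(theta, dtype=float)


def _perturbed_inits(theta0: np.ndarray) -> list[np.ndarray]:
    """Three deterministic perturbations used as a multi-start fallback."""
    outs = []
    for b_mult, e_mult in ((2.0, 0.3), (0.5, 3.0), (3.0, 1.0)):
        t = theta0.copy()
        t[0] *= b_mult
        t[3] *= e_mult
        outs.append(t)
    return outs


def _to_internal(theta: np.ndarray) -> np.ndarray:
    """Natural -> internal parameterization (e fitted on the log scale)."""
    t = theta.copy()
    t[3] = math.log(theta[3])
    return t


def _from_internal(theta_int: np.ndarray) -> np.ndarray:
    t = theta_int.copy()
    # clamp so wandering optimizer steps cannot overflow exp
    t[3] = math.exp(min(max(theta_int[3], -200.0), 200.0))
    return t


def fit_dose_response(
    series: DoseSeries,
    model: ModelName = "loglogistic4",
    init: Optional[Sequence[float]] = None,
) -> DoseResponseFit:
    """Least-squares fit of a dose-response model to one series.

    The inflection dose is optimized on the log scale so positivity is
    structural.  Convergence failure is recorded as rejection reason
    ``fit_failed`` rather than raised.  The parameter covariance is
    ``s^2 (J^T J)^-1`` with the Jacobian taken on the natural scale at the
    optimum; a singular Jacobian leaves ``covariance`` as None.
    """
    p = 4 if model == "loglogistic4" else 5
    n = series.doses.size
    if n < p + 1:
        raise ValueError(f"{model} needs at least {p + 1} observations, got {n}")

    x, y = series.doses, series.responses
    ss_tot = float(np.sum((y - y.mean()) ** 2))

    def _failed() -> DoseResponseFit:
        return DoseResponseFit(
            model=model,
            params=None,
            covariance=None,
            r_squared=math.nan,
            residual_df=n - p,
            accepted=False,
            rejection_reasons=[FIT_FAILED],
            max_dose=series.max_dose,
            control_dose=series.control_dose,
            n_obs=n,
        )

    if ss_tot == 0.0:
        # Flat input: any parameter set with d = c = k fits perfectly but the
        # model is unidentifiable; treat as a degenerate failure.
        logger.warning("constant responses: dose-response fit is degenerate")
        return _failed()

    logx = np.log(np.where(x > 0, x, 1.0))  # placeholder at x=0; masked below
    zero = x == 0

    def residuals(theta_int: np.ndarray) -> np.ndarray:
        return _eval_vector(model, _from_internal(theta_int), x) - y

    def jacobian(theta_int: np.ndarray) -> np.ndarray:
        # analytic d(residual)/d(b, c, d, log e[, f]); t = (x/e)^b
        theta = _from_internal(theta_int)
        b, c, d, e = theta[0], theta[1], theta[2], theta[3]
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            lr = logx - math.log(e)  # log(x/e)
            t = np.exp(np.clip(b * lr, -700.0, 700.0))
            t = np.where(zero, 0.0 if b > 0 else np.inf, t)
            g = 1.0 / (1.0 + t)
            num = d - c + (theta[4] * x if model == "hormesis5" else 0.0)
            tg2 = np.where(np.isfinite(t), t * g * g, 0.0)
            cols = [
                np.where(zero, 0.0, -num * tg2 * lr),  # d/db
                1.0 - g,                               # d/dc
                g,                                     # d/dd
                np.where(zero, 0.0, num * tg2 * b),    # d/d(log e)
            ]
            if model == "hormesis5":
                cols.append(x * g)                     # d/df
        return np.nan_to_num(np.column_stack(cols))

    theta0 = _default_init(series, model)
    primary = [np.asarray(init, dtype=float)] if init is not None else [theta0]
    # perturbed inits are a fallback, tried only when the primary start fails
    fallback = _perturbed_inits(theta0)

    def _solve(start: np.ndarray):
        start = start.copy()
        if start[3] <= 0:
            start[3] = 1.0
        try:
            res = optimize.least_squares(
                residuals,
                _to_internal(start),
                jac=jacobian,
                method="lm",
                xtol=1e-10,
                ftol=1e-10,
                gtol=1e-10,
                max_nfev=10_000,
            )
        except (ValueError, FloatingPointError):
            return None
        if not np.all(np.isfinite(res.x)):
            return None
        # status 0 = evaluation budget exhausted: keep the best-so-far point
        # (LM descends monotonically); the R^2 criterion screens its quality
        if not res.success and res.status != 0:
            return None
        return res

    best = None
    for start in primary:
        res = _solve(start)
        if res is not None and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        for start in fallback:
            res = _solve(start)
            if res is not None and (best is None or res.cost < best.cost):
                best = res

    if best is None:
        return _failed()

    theta = _from_internal(best.x)
    ss_res = float(2.0 * best.cost)
    r2 = 1.0 - ss_res / ss_tot

    # Jacobian on the natural scale: only the e-column changes (chain rule).
    jac = best.jac.copy()
    jac[:, 3] = jac[:, 3] / theta[3]
    dof = n - p
    covariance = None
    if dof > 0:
        jtj = jac.T @ jac
        s2 = ss_res / dof
        try:
            covariance = s2 * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            logger.warning("singular Jacobian at optimum: covariance unavailable")

    params: LogLogisticParams | HormesisParams
    try:
        if model == "loglogistic4":
            params = LogLogisticParams(*theta)
        else:
            params = HormesisParams(*theta)
    except ValueError:
        return _failed()

    return DoseResponseFit(
        model=model,
        params=params,
        covariance=covariance,
        r_squared=r2,
        residual_df=dof,
        accepted=True,
        rejection_reasons=[],
        max_dose=series.max_dose,
        control_dose=series.control_dose,
        n_obs=n,
        ss_res=ss_res,
    )


# ---------------------------------------------------------------------------
# Acceptance and model selection
# ---------------------------------------------------------------------------


def apply_acceptance_criteria(
    fit: DoseResponseFit,
    max_dose: Optional[float] = None,
    r2_min: float = R2_MIN_DEFAULT,
) -> DoseResponseFit:
    """Screen a fit with the three acceptance criteria.

    Rejects when (1) b <= 0 (no inhibition), (2) e at or above the maximum
    spiking concentration, or (3) R^2 not strictly above ``r2_min``.  The
    e-criterion is applied to hormesis fits too, even though e loses its
    EC50 interpretation there.  Returns a new fit; the input is unchanged.
    """
    if max_dose is None:
        max_dose = fit.max_dose
    if fit.failed or fit.params is None:
        return replace(fit, accepted=False, rejection_reasons=[FIT_FAILED])
    reasons = []
    if fit.params.b <= 0:
        reasons.append(SLOPE_NONPOSITIVE)
    if fit.params.e >= max_dose:
        reasons.append(E_EXCEEDS_MAX_DOSE)
    if not fit.r_squared > r2_min:
        reasons.append(R2_BELOW_THRESHOLD)
    return replace(fit, accepted=not reasons, rejection_reasons=reasons)


def test_hormesis_significance(fit: DoseResponseFit, alpha: float = 0.05) -> bool:
    """Wald t-test on the stimulation parameter f.

    True iff the (1 - alpha) confidence interval
    ``f +/- t(df, 1 - alpha/2) * SE(f)`` excludes zero.  An unavailable
    covariance yields False with a logged warning.
    """
    if fit.model != "hormesis5":
        raise ValueError("hormesis significance requires a hormesis5 fit")
    if fit.covariance is None or fit.params is None:
        logger.warning("covariance unavailable: hormesis significance set to False")
        return False
    f = fit.params.f
    var_f = float(fit.covariance[4, 4])
    if var_f < 0 or not math.isfinite(var_f):
        logger.warning("invalid Var(f): hormesis significance set to False")
        return False
    se = math.sqrt(var_f)
    if se == 0.0:
        return f != 0.0
    tcrit = stats.t.ppf(1.0 - alpha / 2.0, fit.residual_df)
    return bool(abs(f) - tcrit * se > 0)


def select_model(
    fit_ll: DoseResponseFit, fit_h: DoseResponseFit
) -> Optional[DoseResponseFit]:
    """Conservative model choice for EC20 extraction.

    Hormesis is preferred whenever both models pass the acceptance screen
    (its EC20 is the more conservative); otherwise the single accepted fit
    is used; None marks the series as excluded from SSD construction.
    """
    if fit_ll.model != "loglogistic4" or fit_h.model != "hormesis5":
        raise ValueError("expected a (loglogistic4, hormesis5) fit pair")
    if fit_h.accepted:
        return fit_h
    if fit_ll.accepted:
        return fit_ll
    return None


# ---------------------------------------------------------------------------
# ECx computation
# ---------------------------------------------------------------------------


def _ecx_loglogistic(theta: np.ndarray, p: float, mode: EcxMode) -> float:
    b, c, d, e = theta[:4]
    if mode == "span":
        return float(e * (p / (100.0 - p)) ** (1.0 / b))
    # upper_asymptote: solve c + (d - c)/(1 + (x/e)^b) = (1 - p/100) d
    target = (1.0 - p / 100.0) * d
    if target <= c:
        raise EcxNotAttainedError(
            f"EC{p:g} target response {target:g} is at or below the lower "
            f"asymptote c={c:g}; the curve never attains that reduction"
        )
    if target >= d:
        raise EcxNotAttainedError(
            f"EC{p:g} target response {target:g} is not below the control response d={d:g}"
        )
    return float(e * ((d - target) / (target - c)) ** (1.0 / b))


def _hormesis_peak(theta: np.ndarray, upper: float) -> tuple[float, float]:
    """Locate the maximum of the fitted hormesis curve on [0, upper]."""
    grid = np.concatenate([[0.0], np.geomspace(upper * 1e-6, upper, 512)])
    vals = _eval_vector("hormesis5", theta, grid)
    i = int(np.nanargmax(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda x: -_eval_vector("hormesis5", theta, np.array([x]))[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10 * max(upper, 1.0)},
        )
        if res.success and -res.fun >= vals[i]:
            return float(res.x), float(-res.fun)
    return float(grid[i]), float(vals[i])


def _ecx_hormesis(
    theta: np.ndarray, p: float, mode: EcxMode, max_dose: float
) -> float:
    b, c, d = theta[0], theta[1], theta[2]
    target = (1.0 - p / 100.0) * d if mode == "upper_asymptote" else c + (1.0 - p / 100.0) * (d - c)
    upper = max_dose * 10.0
    x_peak, y_peak = _hormesis_peak(theta, upper)
    if y_peak < target:
        raise EcxNotAttainedError(
            f"fitted hormesis curve never reaches the EC{p:g} target response"
        )
    y_upper = _eval_vector("hormesis5", theta, np.array([upper]))[0]
    if y_upper > target:
        raise EcxNotAttainedError(
            f"EC{p:g} not attained within (0, {upper:g}] on the descending limb"
        )
    lo = max(x_peak, upper * 1e-12)
    f_lo = _eval_vector("hormesis5", theta, np.array([lo]))[0] - target
    if f_lo <= 0.0:
        # target sits at/above the peak response; root is at the peak itself
        if abs(f_lo) <= 1e-9 * max(abs(target), 1.0):
            return lo
        raise EcxNotAttainedError(f"no descending-limb crossing for EC{p:g}")
    root = optimize.brentq(
        lambda x: _eval_vector("hormesis5", theta, np.array([x]))[0] - target,
        lo,
        upper,
        rtol=1e-8,
        maxiter=200,
    )
    return float(root)


def _ecx_value(
    model: ModelName, theta: np.ndarray, p: float, mode: EcxMode, max_dose: float
) -> float:
    if model == "loglogistic4":
        return _ecx_loglogistic(theta, p, mode)
    return _ecx_hormesis(theta, p, mode, max_dose)


def compute_ecx(
    fit: DoseResponseFit, p: float = 20.0, mode: EcxMode = "upper_asymptote"
) -> EcEstimate:
    """Dose producing a p% reduction of the endpoint, from an accepted fit.

    ``upper_asymptote`` (default) measures the reduction from the control
    response d; ``span`` measures it across the d..c span (the drc ``ED``
    convention).  Log-logistic fits use closed forms; hormesis fits are
    root-found on the descending limb to 1e-8 relative tolerance.  Estimates
    below the control background dose are returned but flagged.
    """
    if not 0.0 < p < 100.0:
        raise ValueError(f"percent reduction must lie in (0, 100), got {p}")
    if not fit.accepted or fit.params is None:
        raise ValueError("ECx requires an accepted fit")
    value = _ecx_value(fit.model, fit.params.as_array(), p, mode, fit.max_dose)
    if value <= 0:
        raise EcxNotAttainedError(f"EC{p:g} computed non-positive ({value:g})")
    below = value < fit.control_dose
    if below:
        logger.info(
            "EC%g = %.4g below control background %.3g (numerical artefact flag)",
            p, value, fit.control_dose,
        )
    return EcEstimate(level=p, value=value, mode=mode, below_background=below)


def ecx_confidence_interval(
    fit: DoseResponseFit, p: float = 20.0, mode: EcxMode = "upper_asymptote"
) -> EcEstimate:
    """ECx with a delta-method 95% confidence interval.

    The gradient of ECx with respect to the model parameters (analytic for
    the log-logistic span form, central differences otherwise) is propagated
    through the fitted covariance; the lower bound is floored at 0.  Without
    a covariance the point estimate is returned with a logged warning.
    """
    est = compute_ecx(fit, p, mode)
    if fit.covariance is None:
        logger.warning("covariance unavailable: ECx returned without CI")
        return est
    theta = fit.params.as_array()
    if fit.model == "loglogistic4" and mode == "span":
        b, e = theta[0], theta[3]
        ratio = p / (100.0 - p)
        grad = np.zeros(4)
        grad[0] = -est.value * math.log(ratio) / b**2  # d/db
        grad[3] = ratio ** (1.0 / b)  # d/de
    else:
        grad = np.zeros(theta.size)
        for i in range(theta.size):
            h = 1e-6 * max(abs(theta[i]), 1e-3)
            up, dn = theta.copy(), theta.copy()
            up[i] += h
            dn[i] -= h
            try:
                v_up = _ecx_value(fit.model, up, p, mode, fit.max_dose)
                v_dn = _ecx_value(fit.model, dn, p, mode, fit.max_dose)
            except EcxNotAttainedError:
                logger.warning("ECx gradient undefined at perturbed parameters: no CI")
                return est
            grad[i] = (v_up - v_dn) / (2.0 * h)
    var = float(grad @ fit.covariance @ grad)
    if var < 0 or not math.isfinite(var):
        logger.warning("negative/non-finite delta-method variance: no CI")
        return est
    half = stats.norm.ppf(0.975) * math.sqrt(var)
    est.ci_low = max(0.0, est.value - half)
    est.ci_high = est.value + half
    return est
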