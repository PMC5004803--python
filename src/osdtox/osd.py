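"""OTU sensitivity distributions: Burr Type III fits and hazardous concentrations.

An OTU sensitivity distribution (OSD) is a species sensitivity distribution
built from per-OTU EC20 values: the cumulative fraction of OTUs affected as a
function of soil Ag concentration.  EC20s are fitted by maximum likelihood to
a Burr Type III distribution with CDF

    F(x) = (1 + (b / x)^c)^(-k),   x > 0,

the parameterization used by the Burrlioz SSD software (parameterizations of
the Burr III family vary across the literature; this one is fixed here).
Hazardous concentrations HCp -- the concentration affecting p% of OTUs,
protecting the remaining (100 - p)% -- are quantiles of the fitted
distribution, with 95% confidence intervals from a nonparametric bootstrap
over the EC20 records.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

#: Minimum number of EC20 values for a Burr III fit.  Below this Burrlioz
#: switches to small-sample fallback distributions, which are out of scope.
MIN_EC20_FOR_FIT = 8


class BurrFitError(RuntimeError):
    """Burr III maximum-likelihood fitting failed to converge."""


@dataclass(frozen=True)
class Ec20Record:
    """One accepted OTU's EC20 with provenance."""

    otu_id: str
    treatment: str
    ec20: float
    model_used: str = "loglogistic4"
    hormesis_significant: bool = False
    below_background: bool = False
    taxonomy: Optional[str] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ec20) and self.ec20 > 0):
            raise ValueError(f"EC20 must be positive and finite, got {self.ec20}")


@dataclass(frozen=True)
class BurrIIIParams:
    """Burr Type III parameters: F(x) = (1 + (scale_b/x)^shape_c)^(-shape_k)."""

    scale_b: float
    shape_c: float
    shape_k: float
    log_likelihood: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("scale_b", "shape_c", "shape_k"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v}")


@dataclass
class HcEstimate:
    """A hazardous concentration HCp with bootstrap confidence bounds."""

    protection_percent: float
    value: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    n_ec20: int = 0
    treatment: str = ""
    n_boot_failed: int = 0
    degenerate_ci: bool = False


# ---------------------------------------------------------------------------
# Distribution functions
# ---------------------------------------------------------------------------


def burr3_cdf(params: BurrIIIParams, x):
    """Burr III CDF at concentration x (> 0); strictly increasing, limits 0/1."""
    arr = np.asarray(x, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("Burr III is supported on x > 0")
    out = (1.0 + (params.scale_b / arr) ** params.shape_c) ** (-params.shape_k)
    return out if out.ndim else float(out)


def burr3_quantile(params: BurrIIIParams, p):
    """Inverse CDF: x such that F(x) = p, for p in (0, 1)."""
    arr = np.asarray(p, dtype=float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        raise ValueError("quantile level must lie strictly inside (0, 1)")
    # log-space: p^(-1/k) - 1 = e^u - 1 with u = -log(p)/k, so
    # log(e^u - 1) = u + log1p(-e^-u) stays finite for extreme shapes
    u = -np.log(arr) / params.shape_k
    with np.errstate(divide="ignore"):
        # log(e^u - 1): ~log(u) as u -> 0, else u + log1p(-e^-u)
        log_term = np.where(
            u < 1e-8, np.log(u), u + np.log1p(-np.exp(-np.maximum(u, 1e-300)))
        )
    out = np.exp(math.log(params.scale_b) - log_term / params.shape_c)
    return out if out.ndim else float(out)


def _negloglik_grad(logtheta: np.ndarray, logx: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and its gradient in (log b, log c, log k).

    With t_i = (b/x_i)^c the density is
    f(x) = k c (b/x)^c / (x (1 + t)^(k+1)); everything is kept in log space
    so extreme shapes do not overflow.
    """
    logb, logc, logk = np.clip(logtheta, -60.0, 60.0)
    c, k = math.exp(logc), math.exp(logk)
    n = logx.size
    with np.errstate(over="ignore", invalid="ignore"):
        u = logb - logx
        logt = np.clip(c * u, -700.0, 700.0)
        log1pt = np.logaddexp(0.0, logt)  # log(1 + t)
        s = np.exp(logt - log1pt)  # t / (1 + t)
        ll = n * (logk + logc) + logt.sum() - logx.sum() - (k + 1.0) * log1pt.sum()
        if not math.isfinite(ll):
            return 1e300, np.zeros(3)
        grad = -np.array(
            [
                c * (n - (k + 1.0) * s.sum()),
                n + c * u.sum() - (k + 1.0) * c * (s * u).sum(),
                n - k * log1pt.sum(),
            ]
        )
    if not np.all(np.isfinite(grad)):
        return 1e300, np.zeros(3)
    return -ll, grad


def _moment_inits(x: np.ndarray) -> list[np.ndarray]:
    """Quantile-matching starting points (k fixed, b at the implied median)."""
    q25, q50, q75 = np.quantile(x, [0.25, 0.5, 0.75])
    spread = math.log(q75 / q25) if q75 > q25 else 1.0
    # at k=1 the quartile ratio is 9^(1/c)
    c0 = max(math.log(9.0) / max(spread, 1e-6), 0.05)
    inits = []
    for k0 in (1.0, 0.5, 2.0):
        b0 = q50 * (2.0 ** (1.0 / k0) - 1.0) ** (1.0 / c0)
        inits.append(np.log([max(b0, 1e-12), c0, k0]))
    return inits


def fit_burr3(
    ec20s: Iterable[Ec20Record] | Sequence[float],
    init: Optional[BurrIIIParams] = None,
) -> BurrIIIParams:
    """Maximum-likelihood Burr III fit to a set of EC20 values.

    Parameters are optimized on the log scale (positivity is structural) from
    several quantile-matching starts; ``init`` adds a warm start (e.g. the
    full-data fit when refitting bootstrap resamples), guarding against
    local optima.  Requires at least 8 positive EC20
    values; with fewer, SSD software falls back to other distributions and
    this implementation refuses rather than silently switching family.
    """
    x = np.array(
        [r.ec20 if isinstance(r, Ec20Record) else float(r) for r in ec20s], dtype=float
    )
    if x.size < MIN_EC20_FOR_FIT:
        raise ValueError(
            f"Burr III fitting needs >= {MIN_EC20_FOR_FIT} EC20 values, got {x.size}; "
            "small-sample SSDs require fallback distributions not provided here"
        )
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError("EC20 values must be positive and finite")
    if np.all(x == x[0]):
        raise ValueError("degenerate input: all EC20 values identical")

    logx = np.log(x)
    best = None
    best_nll = math.inf
    starts = _moment_inits(x)
    if init is not None:
        starts.insert(0, np.log([init.scale_b, init.shape_c, init.shape_k]))
    for start in starts:
        res = optimize.minimize(
            _negloglik_grad,
            start,
            args=(logx,),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-10},
        )
        if math.isfinite(res.fun) and res.fun < best_nll:
            best, best_nll = res, res.fun
    if best is not None and (not best.success or np.linalg.norm(best.jac) > 1e-5):
        # polish: derivative-free refinement guards against early L-BFGS stops
        res = optimize.minimize(
            lambda t: _negloglik_grad(t, logx)[0],
            best.x,
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 400},
        )
        if math.isfinite(res.fun) and res.fun <= best_nll:
            best, best_nll = res, res.fun
    if best is None or not np.all(np.isfinite(best.x)):
        raise BurrFitError(
            f"Burr III MLE did not converge from any start (n={x.size}, "
            f"range {x.min():.3g}-{x.max():.3g})"
        )
    b, c, k = np.exp(best.x)
    return BurrIIIParams(scale_b=b, shape_c=c, shape_k=k, log_likelihood=-best_nll)


def hazardous_concentration(params: BurrIIIParams, protection_percent: float) -> HcEstimate:
    """HCp point estimate: the p/100 quantile of the fitted OSD."""
    if not 0.0 < protection_percent < 100.0:
        raise ValueError("protection percent must lie in (0, 100)")
    value = burr3_quantile(params, protection_percent / 100.0)
    return HcEstimate(protection_percent=protection_percent, value=value)


def bootstrap_hc(
    ec20s: Sequence[Ec20Record] | Sequence[float],
    protection_percents: Sequence[float] = (5.0, 10.0, 20.0, 80.0),
    n_boot: int = 1000,
    seed: int = 0,
    treatment: str = "",
) -> list[HcEstimate]:
    """HCp estimates with percentile bootstrap 95% confidence intervals.

    EC20 records are resampled with replacement ``n_boot`` times and the Burr
    III fit and quantiles recomputed; the 2.5th/97.5th percentiles of the
    bootstrap HCp distribution form the CI.  Resamples whose fit fails are
    dropped and counted: above 10% a warning escalates, above 50% the
    bootstrap errors out.  Deterministic for a fixed seed.
    """
    values = np.array(
        [r.ec20 if isinstance(r, Ec20Record) else float(r) for r in ec20s], dtype=float
    )
    point = fit_burr3(values)
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    boot_hc = {p: [] for p in protection_percents}
    failed = 0
    for _ in range(n_boot):
        resample = rng.choice(values, size=values.size, replace=True)
        try:
            fit = fit_burr3(resample, init=point)
        except (ValueError, BurrFitError):
            failed += 1
            continue
        for p in protection_percents:
            boot_hc[p].append(burr3_quantile(fit, p / 100.0))
    if failed > 0.5 * n_boot:
        raise BurrFitError(
            f"{failed}/{n_boot} bootstrap resamples failed to fit: CIs unreliable"
        )
    if failed > 0.1 * n_boot:
        logger.warning("%d/%d bootstrap resamples failed to fit", failed, n_boot)

    out = []
    for p in protection_percents:
        est = hazardous_concentration(point, p)
        est.treatment = treatment
        est.n_ec20 = values.size
        est.n_boot_failed = failed
        draws = np.array(boot_hc[p])
        if draws.size >= 2:
            est.ci_low, est.ci_high = np.percentile(draws, [2.5, 97.5])
        elif draws.size == 1:
            est.ci_low = est.ci_high = float(draws[0])
            est.degenerate_ci = True
            logger.warning("single bootstrap draw: degenerate CI for HC%g", p)
        out.append(est)
    return out


def compare_treatments(a: HcEstimate, b: HcEstimate) -> str:
    """CI-overlap significance rule between two treatments' HCp values.

    Returns ``"significant"`` iff the 95% confidence intervals do not
    overlap; symmetric in its arguments.
    """
    if a.protection_percent != b.protection_percent:
        raise ValueError("can only compare HC estimates at the same protection level")
    for est in (a, b):
        if est.ci_low is None or est.ci_high is None:
            raise ValueError("both estimates need confidence intervals")
    disjoint = a.ci_high < b.ci_low or b.ci_high < a.ci_low
    return "significant" if disjoint else "not_significant"


def osd_plot_data(
    ec20s: Sequence[Ec20Record] | Sequence[float],
    params: BurrIIIParams,
    n_curve: int = 200,
) -> pd.DataFrame:
    """Plot-ready OSD table: sorted EC20s with empirical ranks + fitted curve.

    Empirical cumulative fractions use the Hazen plotting position
    (i - 0.5)/n.  The fitted CDF is sampled on a log-spaced grid spanning the
    data with half a decade of margin either side.
    """
    values = np.sort(
        np.array([r.ec20 if isinstance(r, Ec20Record) else float(r) for r in ec20s])
    )
    n = values.size
    emp = pd.DataFrame(
        {
            "kind": "empirical",
            "concentration": values,
            "cumulative_fraction": (np.arange(1, n + 1) - 0.5) / n,
        }
    )
    grid = np.geomspace(values.min() / math.sqrt(10), values.max() * math.sqrt(10), n_curve)
    fitted = pd.DataFrame(
        {
            "kind": "fitted",
            "concentration": grid,
            "cumulative_fraction": burr3_cdf(params, grid),
        }
    )
    return pd.concat([emp, fitted], ignore_index=True)
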