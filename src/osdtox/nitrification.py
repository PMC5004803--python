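"""Functional endpoint branch: soil nitrification toxicity (ECx table).

Net nitrate production over the 28-day substrate-induced nitrification assay
is the endpoint: NO3- at t=28 d minus NO3- at t=0, per replicate.  The t0
subtraction is the sole correction -- it removes both the background NO3- of
the soil and the NO3- co-added with AgNO3 in the ionic treatment.  Responses
are expressed as percent of the untreated control's mean production and
fitted with the shared dose-response engine.

Unlike the per-OTU branch (which prefers the hormesis model whenever it
fits), this branch selects the hormesis model only when the stimulation
parameter f is statistically significant; otherwise the plain sigmoidal
model is reported.  Gene-copy endpoints (e.g. bacterial amoA per g soil) run
through the same machinery via a precomputed ``response`` column.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from osdtox.doseresponse import (
    DoseResponseFit,
    DoseSeries,
    EcEstimate,
    EcxMode,
    EcxNotAttainedError,
    apply_acceptance_criteria,
    ecx_confidence_interval,
    fit_dose_response,
    test_hormesis_significance,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NitrateMeasurement:
    """One replicate's nitrate concentrations at assay start and day 28.

    Concentrations in mg NO3- kg^-1 dry soil; dose in mg Ag kg^-1.
    """

    sample_id: str
    treatment: str
    dose: float
    no3_t0: float
    no3_t28: float
    replicate: int = 1

    def __post_init__(self) -> None:
        for name in ("no3_t0", "no3_t28"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"{name} missing or non-finite for {self.sample_id}")
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v} for {self.sample_id}")
        if self.dose < 0 or not math.isfinite(self.dose):
            raise ValueError(f"dose must be finite and >= 0 for {self.sample_id}")


def net_nitrate(m: NitrateMeasurement) -> float:
    """Net NO3- production over 28 d: t28 minus t0 (may be negative)."""
    net = m.no3_t28 - m.no3_t0
    if net < 0:
        logger.warning(
            "net nitrate consumption (%.3g) in sample %s: retained", net, m.sample_id
        )
    return net


def percent_of_control(values, control_mean: float) -> np.ndarray:
    """Scale responses to percent of the control mean (control averages 100)."""
    if not (math.isfinite(control_mean) and control_mean > 0):
        raise ValueError(f"control mean must be positive, got {control_mean}")
    return 100.0 * np.asarray(values, dtype=float) / control_mean


@dataclass
class EndpointResult:
    """One treatment's fitted nitrification (or gene-copy) dose-response."""

    treatment: str
    fit: Optional[DoseResponseFit]
    model_used: Optional[str]
    hormesis_significant: bool
    ecs: dict[float, EcEstimate]
    error: Optional[str] = None


def _measurements_to_frame(
    measurements: Sequence[NitrateMeasurement] | pd.DataFrame,
) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        df = measurements.copy()
        if "response" not in df.columns:
            if not {"no3_t0", "no3_t28"}.issubset(df.columns):
                raise ValueError(
                    "need either a 'response' column or 'no3_t0'/'no3_t28' columns"
                )
            ms = [
                NitrateMeasurement(
                    sample_id=str(r.get("sample_id", i)),
                    treatment=str(r["treatment"]),
                    dose=float(r["dose"]),
                    no3_t0=float(r["no3_t0"]),
                    no3_t28=float(r["no3_t28"]),
                    replicate=int(r.get("replicate", 1)),
                )
                for i, r in df.iterrows()
            ]
            df["response"] = [net_nitrate(m) for m in ms]
        return df[["treatment", "dose", "response"]].copy()
    rows = [
        {"treatment": m.treatment, "dose": m.dose, "response": net_nitrate(m)}
        for m in measurements
    ]
    return pd.DataFrame(rows)


def _fit_endpoint(
    series: DoseSeries,
    ecx_levels: Sequence[float],
    mode: EcxMode,
    alpha: float = 0.05,
) -> EndpointResult:
    fit_ll = apply_acceptance_criteria(fit_dose_response(series, "loglogistic4"))
    fit_h = apply_acceptance_criteria(fit_dose_response(series, "hormesis5"))
    horm_sig = False
    if not fit_h.failed and fit_h.covariance is not None:
        horm_sig = test_hormesis_significance(fit_h, alpha)
        fit_h.hormesis_significant = horm_sig
    # hormesis only when it both passes the screen and shows significant f
    if fit_h.accepted and horm_sig:
        chosen = fit_h
    elif fit_ll.accepted:
        chosen = fit_ll
    else:
        return EndpointResult(
            treatment=series.treatment,
            fit=None,
            model_used=None,
            hormesis_significant=horm_sig,
            ecs={},
            error="no accepted fit: "
            + "; ".join(
                f"{f.model}: {','.join(f.rejection_reasons) or 'ok'}"
                for f in (fit_ll, fit_h)
            ),
        )
    ecs: dict[float, EcEstimate] = {}
    for level in ecx_levels:
        try:
            ecs[level] = ecx_confidence_interval(chosen, level, mode)
        except EcxNotAttainedError as exc:
            logger.warning("EC%g not attainable for %s: %s", level, series.treatment, exc)
    return EndpointResult(
        treatment=series.treatment,
        fit=chosen,
        model_used=chosen.model,
        hormesis_significant=horm_sig,
        ecs=ecs,
    )


def significance_letters(
    names: Sequence[str],
    intervals: dict[str, tuple[float, float, float]],
) -> dict[str, str]:
    """Compact letter display from CI overlap.

    ``intervals`` maps name -> (estimate, ci_low, ci_high); groups whose CIs
    all mutually overlap share a letter, non-overlapping pairs get distinct
    letters.  Missing entries get an empty string.
    """
    present = [n for n in names if n in intervals]
    # CIs overlap pairwise iff they share a point, so the non-significance
    # graph is an interval graph: its maximal cliques are the interval sets
    # covering a common point, and each clique gets one letter.
    cliques: list[frozenset[str]] = []
    for n in present:
        point = intervals[n][1]  # each clique is anchored at some ci_low
        clique = frozenset(
            m for m in present if intervals[m][1] <= point <= intervals[m][2]
        )
        if clique and clique not in cliques:
            cliques.append(clique)
    cliques = [c for c in cliques if not any(c < d for d in cliques)]
    cliques.sort(key=lambda c: min(intervals[m][0] for m in c))
    letters = {n: "" for n in names}
    for i, clique in enumerate(cliques):
        tag = chr(ord("a") + i) if i < 26 else f"z{i}"
        for n in sorted(clique):
            letters[n] += tag
    return letters


def run_nitrification_analysis(
    measurements: Sequence[NitrateMeasurement] | pd.DataFrame,
    control_label: str = "control",
    control_dose: float = 0.1,
    ecx_levels: Sequence[float] = (10.0, 20.0, 50.0),
    mode: EcxMode = "upper_asymptote",
    normalize: bool = True,
) -> tuple[pd.DataFrame, dict[str, EndpointResult]]:
    """Per-treatment ECx table for the nitrification (or gene-copy) endpoint.

    Control replicates (treatment == ``control_label``) are shared across
    arms at the background dose.  Each arm needs at least 6 dose levels.
    Returns the report table (one row per treatment with ECx values, 95% CI
    bounds, significance letters per level, model and R^2) and the per-
    treatment fit results.
    """
    df = _measurements_to_frame(measurements)
    is_ctrl = df["treatment"] == control_label
    if normalize:
        if not is_ctrl.any():
            raise ValueError(f"no control samples (treatment == {control_label!r})")
        control_mean = float(df.loc[is_ctrl, "response"].mean())
        df["response"] = percent_of_control(df["response"], control_mean)

    results: dict[str, EndpointResult] = {}
    treatments = [t for t in df["treatment"].unique() if t != control_label]
    for trt in treatments:
        sub = df[(df["treatment"] == trt) | is_ctrl].copy()
        sub.loc[sub["treatment"] == control_label, "dose"] = control_dose
        n_levels = sub["dose"].nunique()
        if n_levels < 6:
            results[trt] = EndpointResult(
                treatment=trt, fit=None, model_used=None, hormesis_significant=False,
                ecs={}, error=f"only {n_levels} dose levels (need >= 6)",
            )
            continue
        series = DoseSeries(
            doses=sub["dose"].to_numpy(dtype=float),
            responses=sub["response"].to_numpy(dtype=float),
            treatment=trt,
            control_dose=control_dose,
        )
        results[trt] = _fit_endpoint(series, ecx_levels, mode)

    rows = []
    for trt in treatments:
        res = results[trt]
        row: dict[str, object] = {"treatment": trt}
        for level in ecx_levels:
            key = f"ec{level:g}"
            est = res.ecs.get(level)
            row[key] = est.value if est else np.nan
            row[f"{key}_ci_low"] = est.ci_low if est else np.nan
            row[f"{key}_ci_high"] = est.ci_high if est else np.nan
        row["model"] = res.model_used
        row["hormesis_significant"] = res.hormesis_significant
        row["r_squared"] = res.fit.r_squared if res.fit else np.nan
        row["note"] = res.error or ""
        rows.append(row)
    table = pd.DataFrame(rows)

    for level in ecx_levels:
        key = f"ec{level:g}"
        intervals = {}
        for trt in treatments:
            est = results[trt].ecs.get(level)
            if est and est.ci_low is not None and est.ci_high is not None:
                intervals[trt] = (est.value, est.ci_low, est.ci_high)
        letters = significance_letters(treatments, intervals)
        table[f"{key}_letters"] = [letters[t] for t in treatments]

    return table, results
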