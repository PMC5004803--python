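"""End-to-end orchestration: OTU table -> EC20 table -> OSD -> HCx report.

The full chain is: low-count filtering, rarefaction, copy-number correction
to genome-equivalent abundance, per-treatment eligibility screening, dual
(log-logistic + hormesis) model fitting per OTU with acceptance screening,
EC20 extraction, Burr III OSD per treatment, bootstrap HCx, and CI-overlap
treatment comparison.  Every stage logs in/out tallies and every rejection
reason is counted, since those tallies are first-class results of this kind
of study (how many OTUs were fittable, and why the rest were not).
"""

from __future__ import annotations

import dataclasses
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

import osdtox
from osdtox import io as oio
from osdtox.abundance import (
    CopyNumberMap,
    DoseDesign,
    OtuTable,
    QpcrTotals,
    eligible_otus,
    filter_low_count_otus,
    otu_dose_series,
    rarefy,
    to_absolute_abundance,
)
from osdtox.doseresponse import (
    EcxNotAttainedError,
    apply_acceptance_criteria,
    compute_ecx,
    fit_dose_response,
    select_model,
    test_hormesis_significance,
)
from osdtox.nitrification import significance_letters
from osdtox.osd import Ec20Record, bootstrap_hc, compare_treatments, fit_burr3, osd_plot_data

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and offending record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All knobs of the OSD pipeline; each study constant is overridable."""

    otu_table: Optional[str] = None
    taxonomy: Optional[str] = None
    copy_numbers: Optional[str] = None
    qpcr_totals: Optional[str] = None
    design: Optional[str] = None
    out_dir: str = "osdtox_out"
    rarefaction_depth: int = 9000
    min_samples: int = 6
    r2_min: float = 0.65
    ecx_level: float = 20.0
    ecx_mode: str = "upper_asymptote"
    protection_percents: Sequence[float] = (5.0, 10.0, 20.0, 80.0)
    n_boot: int = 1000
    seed: int = 0
    filter_max_total: int = 2
    default_copy_number: float = 1.0
    control_label: str = "control"
    control_dose: float = 0.1
    exclude_below_background: bool = False
    require_hormesis_significance: bool = False

    def validate(self) -> None:
        if self.rarefaction_depth <= 0:
            raise ValueError("rarefaction depth must be positive")
        if not 0.0 <= self.r2_min < 1.0:
            raise ValueError("r2_min must lie in [0, 1)")
        if not 0.0 < self.ecx_level < 100.0:
            raise ValueError("ecx_level must lie in (0, 100)")
        if self.ecx_mode not in ("upper_asymptote", "span"):
            raise ValueError(f"unknown ecx mode {self.ecx_mode!r}")
        for p in self.protection_percents:
            if not 0.0 < p < 100.0:
                raise ValueError("protection percents must lie in (0, 100)")
        if self.n_boot < 1 or self.min_samples < 6:
            raise ValueError("n_boot must be >= 1 and min_samples >= 6")


def preprocess(
    table: OtuTable,
    cn: CopyNumberMap,
    totals: QpcrTotals,
    config: PipelineConfig,
) -> OtuTable:
    """raw -> filtered -> rarefied -> absolute, with the configured settings."""
    filtered = filter_low_count_otus(table, max_total=config.filter_max_total)
    rarefied = rarefy(filtered, depth=config.rarefaction_depth, seed=config.seed)
    return to_absolute_abundance(rarefied, cn, totals)


def fit_otus(
    absolute: OtuTable,
    design: DoseDesign,
    config: PipelineConfig,
    taxonomy: Optional[dict[str, str]] = None,
) -> tuple[list[Ec20Record], dict]:
    """Dual-model fitting + acceptance + EC20 for every eligible OTU.

    Returns the EC20 records and a diagnostics dict with per-treatment
    eligible/fitted counts and a rejection-reason histogram.
    """
    eligible = eligible_otus(absolute, design, min_samples=config.min_samples)
    records: list[Ec20Record] = []
    diagnostics: dict = {"treatments": {}}
    for trt, otus in eligible.items():
        reasons: dict[str, int] = {}
        fitted = 0
        for otu in otus:
            series = otu_dose_series(absolute, design, otu, trt)
            max_dose = series.max_dose
            fit_ll = apply_acceptance_criteria(
                fit_dose_response(series, "loglogistic4"), max_dose, config.r2_min
            )
            fit_h = fit_dose_response(series, "hormesis5")
            horm_sig = False
            if not fit_h.failed and fit_h.covariance is not None:
                horm_sig = test_hormesis_significance(fit_h)
            fit_h = apply_acceptance_criteria(fit_h, max_dose, config.r2_min)
            fit_h.hormesis_significant = horm_sig
            if config.require_hormesis_significance and not horm_sig:
                chosen = fit_ll if fit_ll.accepted else None
            else:
                chosen = select_model(fit_ll, fit_h)
            if chosen is None:
                for r in set(fit_ll.rejection_reasons) | set(fit_h.rejection_reasons):
                    reasons[r] = reasons.get(r, 0) + 1
                continue
            try:
                est = compute_ecx(chosen, config.ecx_level, config.ecx_mode)  # type: ignore[arg-type]
            except EcxNotAttainedError:
                reasons["ecx_not_attained"] = reasons.get("ecx_not_attained", 0) + 1
                continue
            fitted += 1
            records.append(
                Ec20Record(
                    otu_id=otu,
                    treatment=trt,
                    ec20=est.value,
                    model_used=chosen.model,
                    hormesis_significant=horm_sig,
                    below_background=est.below_background,
                    taxonomy=(taxonomy or {}).get(otu),
                )
            )
        diagnostics["treatments"][trt] = {
            "eligible": len(otus),
            "fitted": fitted,
            "rejection_reasons": reasons,
        }
        logger.info("treatment %s: %d eligible, %d fitted (%s)", trt, len(otus), fitted, reasons)
    return records, diagnostics


def ec20_records_to_frame(records: Sequence[Ec20Record]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "otu_id": r.otu_id,
                "treatment": r.treatment,
                "ec20": r.ec20,
                "model_used": r.model_used,
                "hormesis_significant": r.hormesis_significant,
                "below_background": r.below_background,
                "taxonomy": r.taxonomy or "",
            }
            for r in records
        ]
    )


def ec20_frame_to_records(df: pd.DataFrame) -> list[Ec20Record]:
    return [
        Ec20Record(
            otu_id=str(row["otu_id"]),
            treatment=str(row["treatment"]),
            ec20=float(row["ec20"]),
            model_used=str(row.get("model_used", "loglogistic4")),
            hormesis_significant=bool(row.get("hormesis_significant", False)),
            below_background=bool(row.get("below_background", False)),
            taxonomy=str(row["taxonomy"]) if row.get("taxonomy") else None,
        )
        for _, row in df.iterrows()
    ]


def build_osd(
    records: Sequence[Ec20Record],
    config: PipelineConfig,
) -> tuple[dict, dict[str, pd.DataFrame]]:
    """Per-treatment Burr III OSD + bootstrap HCx + CI-overlap comparisons.

    Returns (HC report dict, {treatment: OSD plot-data frame}).  Treatments
    with too few EC20s are reported as skipped, not fatal.
    """
    if config.exclude_below_background:
        records = [r for r in records if not r.below_background]
    by_trt: dict[str, list[Ec20Record]] = {}
    for r in records:
        by_trt.setdefault(r.treatment, []).append(r)

    report: dict = {"treatments": {}, "comparisons": {}}
    plots: dict[str, pd.DataFrame] = {}
    hc_by_level: dict[float, dict[str, object]] = {p: {} for p in config.protection_percents}
    for trt, recs in sorted(by_trt.items()):
        try:
            params = fit_burr3(recs)
            hcs = bootstrap_hc(
                recs,
                protection_percents=config.protection_percents,
                n_boot=config.n_boot,
                seed=config.seed,
                treatment=trt,
            )
        except (ValueError, RuntimeError) as exc:
            logger.warning("OSD skipped for %s: %s", trt, exc)
            report["treatments"][trt] = {"skipped": str(exc), "n_ec20": len(recs)}
            continue
        report["treatments"][trt] = {
            "n_ec20": len(recs),
            "burr3": {
                "scale_b": params.scale_b,
                "shape_c": params.shape_c,
                "shape_k": params.shape_k,
                "log_likelihood": params.log_likelihood,
            },
            "hc": {
                f"HC{hc.protection_percent:g}": {
                    "value": hc.value,
                    "ci_low": hc.ci_low,
                    "ci_high": hc.ci_high,
                    "n_boot_failed": hc.n_boot_failed,
                }
                for hc in hcs
            },
        }
        for hc in hcs:
            hc_by_level[hc.protection_percent][trt] = hc
        plots[trt] = osd_plot_data(recs, params)

    for p, per_trt in hc_by_level.items():
        names = sorted(per_trt)
        pairs = {}
        intervals = {}
        for i, a in enumerate(names):
            ha = per_trt[a]
            if ha.ci_low is not None:
                intervals[a] = (ha.value, ha.ci_low, ha.ci_high)
            for b in names[i + 1:]:
                try:
                    pairs[f"{a} vs {b}"] = compare_treatments(per_trt[a], per_trt[b])
                except ValueError as exc:
                    pairs[f"{a} vs {b}"] = f"unavailable: {exc}"
        report["comparisons"][f"HC{p:g}"] = {
            "pairs": pairs,
            "letters": significance_letters(names, intervals),
        }
    return report, plots


def run_osd_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline from files named in ``config``.

    Writes to ``config.out_dir``: ``ec20.csv``, ``hc_report.json``, per-
    treatment ``osd_<treatment>.csv`` plot data, ``diagnostics.json`` and a
    ``manifest.json`` (config + versions) sufficient to reproduce the run.
    Partial outputs are retained on stage failure.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": dataclasses.asdict(config),
        "versions": {
            "osdtox": osdtox.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "python": platform.python_version(),
        },
    }
    oio.write_json(manifest, out / "manifest.json")

    stage = "read-inputs"
    try:
        table = oio.read_otu_table(config.otu_table)
        cn = oio.read_copy_numbers(config.copy_numbers, default=config.default_copy_number)
        totals = oio.read_qpcr_totals(config.qpcr_totals)
        design = oio.read_design(
            config.design, control_label=config.control_label, control_dose=config.control_dose
        )
        taxonomy = oio.read_taxonomy(config.taxonomy) if config.taxonomy else {}
    except (OSError, ValueError, KeyError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "preprocess"
    try:
        absolute = preprocess(table, cn, totals, config)
    except (ValueError, KeyError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "fit-otus"
    try:
        records, diagnostics = fit_otus(absolute, design, config, taxonomy)
        ec20_records_to_frame(records).to_csv(out / "ec20.csv", index=False)
        oio.write_json(diagnostics, out / "diagnostics.json")
    except (ValueError, KeyError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "osd"
    try:
        report, plots = build_osd(records, config)
        oio.write_json(report, out / "hc_report.json")
        for trt, frame in plots.items():
            safe = "".join(ch if ch.isalnum() else "_" for ch in trt)
            frame.to_csv(out / f"osd_{safe}.csv", index=False)
    except (ValueError, RuntimeError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    summary = {
        "n_ec20": len(records),
        "diagnostics": diagnostics,
        "hc_report": report,
        "out_dir": str(out),
    }
    return summary
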