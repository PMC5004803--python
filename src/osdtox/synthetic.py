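"""Synthetic dose-series communities with known ground truth.

Every downstream module is exercised against data generated here: a soil
community observed along a geometric Ag dose gradient (14 rates spanning
0.1 to 5590 mg kg^-1 by default, one sequenced sample per rate), where each
OTU's true absolute abundance follows one of three response classes:

* ``insensitive`` -- constant abundance across doses;
* ``loglogistic`` -- declining four-parameter log-logistic response with a
  known EC50 (parameter e);
* ``hormetic`` -- Brain-Cousens response whose stimulation parameter f is
  calibrated to produce a 10-50% peak above the control abundance.

Observation noise mimics the real measurement chain: amplicon reads are a
multinomial draw (optionally Dirichlet-multinomial for overdispersion) from
the community's 16S-copy pool at the configured sequencing depth, and the
per-sample qPCR total is a lognormal perturbation of the true 16S pool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from osdtox.abundance import CopyNumberMap, DoseDesign, OtuTable, QpcrTotals
from osdtox.doseresponse import HormesisParams, LogLogisticParams
from osdtox.nitrification import NitrateMeasurement

CLASSES = ("insensitive", "loglogistic", "hormetic")

#: Default 14-rate geometric dose grid, 0.1 (control background) to 5590 mg/kg.
DEFAULT_DOSE_GRID = tuple(np.geomspace(0.1, 5590.0, 14))


def _default_ec50_sampler(rng: np.random.Generator, size: int) -> np.ndarray:
    # Median 20 mg/kg with ~1.2 log-sd: EC50s span roughly 1-400 mg/kg,
    # placing most inside the dose gradient with realistic tails outside it.
    return rng.lognormal(mean=math.log(20.0), sigma=1.2, size=size)


@dataclass
class SyntheticTruth:
    """Ground truth for one simulated treatment arm."""

    response_class: np.ndarray  # per-OTU label from CLASSES
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray  # control absolute abundance (genome equivalents)
    e: np.ndarray
    f: np.ndarray
    base_rel: np.ndarray  # control relative abundances, sum to 1
    copy_number: np.ndarray
    dose_grid: np.ndarray
    depth: int
    qpcr_total: float
    qpcr_cv: float
    seed: int
    treatment: str = "Ag+"
    control_dose: float = 0.1

    @property
    def n_otus(self) -> int:
        return self.base_rel.size

    @property
    def otu_ids(self) -> list[str]:
        return [f"OTU_{i:05d}" for i in range(self.n_otus)]


def _calibrate_f(b: float, e: float, peak_rel: float, max_dose: float) -> float:
    """Stimulation rate f (per unit d) giving a (1 + peak_rel) peak over d.

    The peak is taken over the dose range (0, max_dose]: for shallow slopes
    (b <= 1) the Brain-Cousens numerator term f*x dominates at extreme doses,
    so a global peak is not well defined, but within the assayed range the
    peak height is monotone in f and can be bisected.  Works with d = 1,
    c = 0; scale by d afterwards.
    """
    grid = np.geomspace(min(e, max_dose) * 1e-4, max_dose, 512)

    def peak(fv: float) -> float:
        y = (1.0 + fv * grid) / (1.0 + (grid / e) ** b)
        return float(y.max()) - 1.0

    lo, hi = 0.0, 1.0 / e
    while peak(hi) < peak_rel:
        hi *= 2.0
        if hi > 1e12:
            raise RuntimeError("hormesis calibration failed to bracket")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if peak(mid) < peak_rel:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_truth(
    n_otus: int = 100,
    class_proportions: Sequence[float] = (0.4, 0.4, 0.2),
    ec50_distribution: Optional[Callable[[np.random.Generator, int], np.ndarray] | float] = None,
    seed: int = 0,
    dose_grid: Optional[Sequence[float]] = None,
    depth: int = 20_000,
    qpcr_total: float = 1e8,
    qpcr_cv: float = 0.02,
    treatment: str = "Ag+",
    control_dose: float = 0.1,
) -> SyntheticTruth:
    """Draw a ground-truth community, fully determined by ``seed``.

    ``class_proportions`` orders (insensitive, loglogistic, hormetic).
    ``ec50_distribution`` may be a float (point mass) or a callable
    ``(rng, size) -> doses``; the default is lognormal with median 20 mg/kg.
    Slopes b are Uniform(0.8, 4); hormetic stimulation peaks are Uniform(10%,
    50%) above control; base abundances are lognormal renormalized to 1;
    16S copy numbers are integers in 1..10.
    """
    if n_otus < 10:
        raise ValueError("need at least 10 OTUs for a meaningful community")
    props = np.asarray(class_proportions, dtype=float)
    if props.size != 3 or np.any(props < 0) or not math.isclose(props.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("class proportions must be 3 non-negative values summing to 1")

    rng = np.random.default_rng(seed)
    labels = rng.choice(np.array(CLASSES, dtype=object), size=n_otus, p=props)

    base = rng.lognormal(mean=0.0, sigma=1.5, size=n_otus)
    base /= base.sum()
    d_abs = base * qpcr_total
    copy_number = rng.integers(1, 11, size=n_otus).astype(float)

    b = rng.uniform(0.8, 4.0, size=n_otus)
    if ec50_distribution is None:
        e = _default_ec50_sampler(rng, n_otus)
    elif callable(ec50_distribution):
        e = np.asarray(ec50_distribution(rng, n_otus), dtype=float)
    else:
        e = np.full(n_otus, float(ec50_distribution))
    grid = np.asarray(dose_grid if dose_grid is not None else DEFAULT_DOSE_GRID, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError("dose grid must be strictly increasing")

    c = np.zeros(n_otus)
    f = np.zeros(n_otus)
    peaks = rng.uniform(0.10, 0.50, size=n_otus)
    for i in range(n_otus):
        if labels[i] == "hormetic":
            f[i] = _calibrate_f(b[i], e[i], peaks[i], float(grid[-1])) * d_abs[i]
    return SyntheticTruth(
        response_class=labels,
        b=b, c=c, d=d_abs, e=e, f=f,
        base_rel=base,
        copy_number=copy_number,
        dose_grid=grid,
        depth=depth,
        qpcr_total=qpcr_total,
        qpcr_cv=qpcr_cv,
        seed=seed,
        treatment=treatment,
        control_dose=control_dose,
    )


def expected_abundance(truth: SyntheticTruth, dose: float) -> np.ndarray:
    """True genome-equivalent abundance of every OTU at one dose."""
    x = float(dose)
    out = np.empty(truth.n_otus)
    with np.errstate(divide="ignore"):
        t = (x / truth.e) ** truth.b
    for i in range(truth.n_otus):
        if truth.response_class[i] == "insensitive":
            out[i] = truth.d[i]
        elif truth.response_class[i] == "loglogistic":
            out[i] = truth.c[i] + (truth.d[i] - truth.c[i]) / (1.0 + t[i])
        else:
            out[i] = truth.c[i] + (truth.d[i] - truth.c[i] + truth.f[i] * x) / (1.0 + t[i])
    return out


def true_ec20(truth: SyntheticTruth, i: int, mode: str = "upper_asymptote") -> float:
    """Closed-form/numeric EC20 of OTU i's true response curve."""
    from osdtox import doseresponse as dr

    cls = truth.response_class[i]
    if cls == "insensitive":
        raise ValueError("insensitive OTUs have no EC20")
    theta = np.array([truth.b[i], truth.c[i], truth.d[i], truth.e[i], truth.f[i]])
    if cls == "loglogistic":
        return dr._ecx_loglogistic(theta, 20.0, mode)
    return dr._ecx_hormesis(theta, 20.0, mode, float(truth.dose_grid.max()))


def simulate_observed(
    truth: SyntheticTruth,
    n_replicates: int = 1,
    overdispersion: Optional[float] = None,
) -> tuple[OtuTable, QpcrTotals, CopyNumberMap, DoseDesign]:
    """Simulate the observed data for one treatment arm.

    Per dose (and replicate): reads are multinomial at ``truth.depth`` over
    the 16S-copy pool shares (abundance x copy number), and the qPCR total is
    a lognormal draw around the true pool with CV ``truth.qpcr_cv``.  The
    lowest dose of the grid is the untreated control and is labelled as such
    in the design.  Outputs feed the abundance module directly.
    """
    rng = np.random.default_rng([truth.seed, 1])
    otu_ids = truth.otu_ids
    counts: dict[str, np.ndarray] = {}
    totals: dict[str, float] = {}
    design_rows = []

    for j, dose in enumerate(truth.dose_grid):
        abundance = expected_abundance(truth, dose)
        pool = abundance * truth.copy_number
        pool_total = pool.sum()
        probs = pool / pool_total if pool_total > 0 else np.full(truth.n_otus, 1.0 / truth.n_otus)
        is_control = j == 0
        for rep in range(n_replicates):
            sid = f"S{j:02d}" if n_replicates == 1 else f"S{j:02d}r{rep + 1}"
            p = probs
            if overdispersion is not None:
                p = rng.dirichlet(np.maximum(probs * overdispersion, 1e-12))
            counts[sid] = rng.multinomial(truth.depth, p)
            sigma = math.sqrt(math.log(1.0 + truth.qpcr_cv**2))
            totals[sid] = float(
                pool_total * math.exp(rng.normal(-0.5 * sigma**2, sigma))
            ) if truth.qpcr_cv > 0 else float(pool_total)
            design_rows.append(
                {
                    "sample_id": sid,
                    "treatment": "control" if is_control else truth.treatment,
                    "dose": float(dose),
                }
            )

    table = OtuTable(counts=pd.DataFrame(counts, index=otu_ids), stage="raw")
    design = DoseDesign(
        table=pd.DataFrame(design_rows),
        control_label="control",
        control_dose=truth.control_dose,
    )
    cn = CopyNumberMap(
        copies=dict(zip(otu_ids, truth.copy_number)), default_copy_number=1.0
    )
    return table, QpcrTotals(totals=totals), cn, design


#: Default 8-rate nitrification dose grid, 0.1 to 72 mg/kg (ionic Ag range).
NITRIF_DOSE_GRID = tuple(np.geomspace(0.1, 72.0, 8))


def simulate_nitrification(
    params: LogLogisticParams | HormesisParams,
    seed: int = 0,
    dose_grid: Sequence[float] = NITRIF_DOSE_GRID,
    n_replicates: int = 3,
    noise_cv: float = 0.0,
    t0: float = 8.2,
    control_net: float = 145.5,
    treatment: str = "Ag+",
    control_dose: float = 0.1,
) -> list[NitrateMeasurement]:
    """Triplicate nitrate measurements from a known dose-response truth.

    ``params`` describes the percent-of-control response (d near 100); the
    control soil produces ``control_net`` mg NO3- kg^-1 over 28 d starting
    from ``t0``.  Gaussian noise of relative size ``noise_cv`` is applied to
    each replicate's net production.  The lowest grid dose is emitted as the
    untreated control arm.
    """
    from osdtox.doseresponse import eval_hormesis, eval_loglogistic

    rng = np.random.default_rng(seed)
    evalf = eval_hormesis if isinstance(params, HormesisParams) else eval_loglogistic
    out = []
    for j, dose in enumerate(dose_grid):
        y_pct = evalf(params, float(dose))
        net_true = control_net * y_pct / 100.0
        label = "control" if j == 0 else treatment
        for rep in range(1, n_replicates + 1):
            net = net_true * (1.0 + rng.normal(0.0, noise_cv)) if noise_cv > 0 else net_true
            out.append(
                NitrateMeasurement(
                    sample_id=f"N{j:02d}r{rep}",
                    treatment=label,
                    dose=float(dose) if label != "control" else control_dose,
                    no3_t0=t0,
                    no3_t28=max(t0 + net, 0.0),
                    replicate=rep,
                )
            )
    return out
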