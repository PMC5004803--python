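"""OTU table preprocessing: filtering, rarefaction, copy-number correction.

The preprocessing pipeline is strictly ordered and the stage of a table is
tracked explicitly:

    raw -> filtered (drop singleton/doubleton OTUs)
        -> rarefied (subsample every sample to a common depth)
        -> absolute (scale relative abundances by the sample's total 16S
           load from qPCR and divide by per-OTU 16S gene copy number, giving
           genome-equivalent, i.e. single-copy 16S, abundances)

Calling a step on a table in the wrong stage raises, which keeps automated
runs honest about what a number means.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Stage = Literal["raw", "filtered", "rarefied", "absolute"]


@dataclass
class OtuTable:
    """A community matrix of OTUs (rows) by samples (columns).

    ``counts`` holds integer reads in the raw/filtered/rarefied stages and
    continuous genome-equivalent abundances in the absolute stage.
    """

    counts: pd.DataFrame
    stage: Stage = "raw"

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            raise TypeError("counts must be a pandas DataFrame (OTUs x samples)")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.stage in ("raw", "filtered", "rarefied"):
            vals = self.counts.to_numpy()
            if not np.allclose(vals, np.round(vals)):
                raise ValueError(f"stage '{self.stage}' requires integer counts")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]


@dataclass
class DoseDesign:
    """Maps each sample to its treatment arm and dose (mg Ag kg^-1 soil).

    Samples labelled with ``control_label`` are the untreated background and
    are shared across arms: they count toward every treatment when screening
    eligibility and enter every arm's dose series at ``control_dose``.
    """

    table: pd.DataFrame  # columns: sample_id, treatment, dose
    control_label: str = "control"
    control_dose: float = 0.1

    def __post_init__(self) -> None:
        need = {"sample_id", "treatment", "dose"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"design table needs columns {sorted(need)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in design")
        if (self.table["dose"] < 0).any() or not np.isfinite(self.table["dose"]).all():
            raise ValueError("doses must be finite and >= 0")

    @property
    def treatments(self) -> list[str]:
        t = [x for x in self.table["treatment"].unique() if x != self.control_label]
        return t

    def samples_for(self, treatment: str, include_control: bool = True) -> pd.DataFrame:
        mask = self.table["treatment"] == treatment
        if include_control:
            mask |= self.table["treatment"] == self.control_label
        sub = self.table.loc[mask].copy()
        ctrl = sub["treatment"] == self.control_label
        sub.loc[ctrl, "dose"] = self.control_dose
        return sub.sort_values("dose").reset_index(drop=True)

    def dose_of(self, sample_id: str) -> float:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in design")
        if row["treatment"].iloc[0] == self.control_label:
            return self.control_dose
        return float(row["dose"].iloc[0])


@dataclass
class CopyNumberMap:
    """Per-OTU 16S rRNA gene copies per genome (>= 1), with a default."""

    copies: Mapping[str, float]
    default_copy_number: float = 1.0

    def __post_init__(self) -> None:
        if self.default_copy_number < 1:
            raise ValueError("default copy number must be >= 1")
        bad = {k: v for k, v in self.copies.items() if not (np.isfinite(v) and v >= 1)}
        if bad:
            raise ValueError(f"copy numbers must be finite and >= 1; offending: {bad}")

    def get(self, otu_id: str) -> float:
        return float(self.copies.get(otu_id, self.default_copy_number))


@dataclass
class QpcrTotals:
    """Per-sample total 16S copy load from qPCR (positive, finite)."""

    totals: Mapping[str, float]
    units: str = "copies per g soil"

    def __post_init__(self) -> None:
        bad = {k: v for k, v in self.totals.items() if not (np.isfinite(v) and v > 0)}
        if bad:
            raise ValueError(f"qPCR totals must be positive and finite; offending: {bad}")

    def get(self, sample_id: str) -> float:
        if sample_id not in self.totals:
            raise KeyError(f"no qPCR total for sample {sample_id!r}")
        return float(self.totals[sample_id])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def filter_low_count_otus(table: OtuTable, max_total: int = 2) -> OtuTable:
    """Drop OTUs whose summed count across all samples is <= ``max_total``.

    The default removes singletons and doubletons.  Stage: raw -> filtered.
    """
    if table.stage != "raw":
        raise ValueError(f"filter expects a raw table, got stage '{table.stage}'")
    totals = table.counts.sum(axis=1)
    keep = totals > max_total
    removed = int((~keep).sum())
    logger.info("filtered %d low-count OTUs (total <= %d); %d retained",
                removed, max_total, int(keep.sum()))
    if keep.sum() == 0:
        logger.warning("all OTUs removed by low-count filter")
    return OtuTable(counts=table.counts.loc[keep].copy(), stage="filtered")


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # Stream derived from (seed, sample_id) so per-sample draws are stable
    # regardless of sample order or which samples are present.
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode())])


def rarefy(table: OtuTable, depth: int = 9000, seed: int = 0) -> OtuTable:
    """Subsample each sample without replacement to exactly ``depth`` reads.

    Multivariate hypergeometric draw per sample; samples with fewer than
    ``depth`` reads are dropped with a warning.  Deterministic for a fixed
    seed.  Stage: filtered -> rarefied.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    if table.stage != "filtered":
        raise ValueError(f"rarefy expects a filtered table, got stage '{table.stage}'")
    out = {}
    for sid in table.sample_ids:
        col = table.counts[sid].to_numpy().astype(np.int64)
        total = int(col.sum())
        if total < depth:
            logger.warning("sample %s has %d < %d reads: dropped", sid, total, depth)
            continue
        rng = _sample_rng(seed, sid)
        out[sid] = rng.multivariate_hypergeometric(col, depth, method="marginals")
    if not out:
        logger.warning("no samples reach rarefaction depth %d", depth)
    rarefied = pd.DataFrame(out, index=table.counts.index)
    return OtuTable(counts=rarefied, stage="rarefied")


def to_absolute_abundance(
    table: OtuTable, cn: CopyNumberMap, totals: QpcrTotals
) -> OtuTable:
    """Convert rarefied reads to genome-equivalent absolute abundances.

    For OTU i in sample s: ``A(i,s) = T(s) * r(i,s) / CN(i)`` with r the read
    relative abundance, T the sample's total 16S load and CN the per-OTU 16S
    gene copy number -- i.e. single-copy 16S (cell) equivalents.  Note the
    16S pool is conserved: sum_i A(i,s) * CN(i) = T(s).
    Stage: rarefied -> absolute.
    """
    if table.stage != "rarefied":
        raise ValueError(
            f"copy-number correction expects a rarefied table, got stage '{table.stage}'"
        )
    missing_cn = [o for o in table.otu_ids if o not in cn.copies]
    if missing_cn:
        logger.info("%d OTUs missing from copy-number map: default %.2f used",
                    len(missing_cn), cn.default_copy_number)
    cn_vec = np.array([cn.get(o) for o in table.otu_ids], dtype=float)
    abs_cols = {}
    for sid in table.sample_ids:
        t_s = totals.get(sid)  # raises KeyError naming the sample
        col = table.counts[sid].to_numpy().astype(float)
        rel = col / col.sum()
        abs_cols[sid] = t_s * rel / cn_vec
    return OtuTable(
        counts=pd.DataFrame(abs_cols, index=table.counts.index), stage="absolute"
    )


def eligible_otus(
    table: OtuTable, design: DoseDesign, min_samples: int = 6
) -> dict[str, list[str]]:
    """Per-treatment OTUs observed in enough samples to support a 5-parameter fit.

    An OTU is eligible for an arm when it has nonzero abundance in at least
    ``min_samples`` of that arm's samples; control samples count toward every
    arm.  Returns {treatment: [otu_id, ...]}.
    """
    if table.stage != "absolute":
        raise ValueError(
            f"eligibility expects an absolute table, got stage '{table.stage}'"
        )
    out: dict[str, list[str]] = {}
    for trt in design.treatments:
        samples = design.samples_for(trt, include_control=True)["sample_id"]
        present = [s for s in samples if s in table.counts.columns]
        sub = table.counts[present]
        n_nonzero = (sub > 0).sum(axis=1)
        chosen = n_nonzero[n_nonzero >= min_samples].index.tolist()
        logger.info("treatment %s: %d/%d OTUs eligible (>= %d nonzero samples)",
                    trt, len(chosen), table.n_otus, min_samples)
        out[trt] = chosen
    return out


def otu_dose_series(
    table: OtuTable,
    design: DoseDesign,
    otu_id: str,
    treatment: str,
):
    """Assemble the (dose, absolute abundance) series for one OTU and arm."""
    from osdtox.doseresponse import DoseSeries

    if table.stage != "absolute":
        raise ValueError("dose series require an absolute-stage table")
    sub = design.samples_for(treatment, include_control=True)
    sub = sub[sub["sample_id"].isin(table.counts.columns)]
    doses = sub["dose"].to_numpy(dtype=float)
    responses = table.counts.loc[otu_id, sub["sample_id"]].to_numpy(dtype=float)
    return DoseSeries(
        doses=doses,
        responses=responses,
        treatment=treatment,
        control_dose=design.control_dose,
    )
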