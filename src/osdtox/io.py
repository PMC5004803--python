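"""Readers and writers for the plain-text table formats the pipeline uses.

OTU tables are tab-separated with OTU ids in the first column and sample ids
in the header; the classic BIOM flattening (``biom convert --to-tsv`` output
with a leading ``# Constructed from biom file`` comment and an ``#OTU ID``
header) is accepted.  Taxonomy and copy numbers are two-column TSV, qPCR
totals and the dose design are CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from osdtox.abundance import CopyNumberMap, DoseDesign, OtuTable, QpcrTotals

PathLike = Union[str, Path]


def read_otu_table(path: PathLike, stage: str = "raw") -> OtuTable:
    """Read a TSV OTU table (first column OTU id, header row sample ids).

    Leading ``#`` comment lines are skipped except for a ``#OTU ID`` header
    line, which the BIOM flat export uses as the column header.
    """
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    header_idx = 0
    for i, line in enumerate(lines):
        if line.startswith("#OTU ID"):
            header_idx = i
            break
        if not line.startswith("#"):
            header_idx = i
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[header_idx:])), sep="\t", index_col=0)
    # BIOM exports sometimes carry a trailing taxonomy column
    if "taxonomy" in df.columns:
        df = df.drop(columns=["taxonomy"])
    df.index = df.index.astype(str)
    return OtuTable(counts=df, stage=stage)  # type: ignore[arg-type]


def write_otu_table(table: OtuTable, path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("#OTU ID\t" + "\t".join(table.sample_ids) + "\n")
        table.counts.to_csv(fh, sep="\t", header=False)


def read_taxonomy(path: PathLike) -> dict[str, str]:
    """Two-column TSV: OTU id, semicolon-delimited lineage string."""
    df = pd.read_csv(path, sep="\t", header=None, names=["otu_id", "lineage"],
                     comment="#", dtype=str)
    return dict(zip(df["otu_id"], df["lineage"]))


def write_taxonomy(tax: dict[str, str], path: PathLike) -> None:
    pd.DataFrame(
        {"otu_id": list(tax), "lineage": [tax[k] for k in tax]}
    ).to_csv(path, sep="\t", header=False, index=False)


def read_copy_numbers(path: PathLike, default: float = 1.0) -> CopyNumberMap:
    """Two-column TSV: OTU id, 16S copies per genome."""
    df = pd.read_csv(path, sep="\t", header=None, names=["otu_id", "copies"],
                     comment="#", dtype={"otu_id": str})
    return CopyNumberMap(
        copies=dict(zip(df["otu_id"], df["copies"].astype(float))),
        default_copy_number=default,
    )


def write_copy_numbers(cn: CopyNumberMap, path: PathLike) -> None:
    pd.DataFrame(
        {"otu_id": list(cn.copies), "copies": [cn.copies[k] for k in cn.copies]}
    ).to_csv(path, sep="\t", header=False, index=False)


def read_qpcr_totals(path: PathLike) -> QpcrTotals:
    """Two-column CSV: sample_id, total 16S copies."""
    df = pd.read_csv(path, header=None, names=["sample_id", "total"],
                     comment="#", dtype={"sample_id": str})
    try:  # tolerate an optional header row
        float(df["total"].iloc[0])
    except (TypeError, ValueError):
        df = df.iloc[1:]
    return QpcrTotals(totals=dict(zip(df["sample_id"], df["total"].astype(float))))


def write_qpcr_totals(totals: QpcrTotals, path: PathLike) -> None:
    pd.DataFrame(
        {"sample_id": list(totals.totals), "total": [totals.totals[k] for k in totals.totals]}
    ).to_csv(path, header=False, index=False)


def read_design(path: PathLike, control_label: str = "control",
                control_dose: float = 0.1) -> DoseDesign:
    """CSV with columns sample_id, treatment, dose."""
    df = pd.read_csv(path, dtype={"sample_id": str, "treatment": str})
    df["dose"] = df["dose"].astype(float)
    return DoseDesign(table=df, control_label=control_label, control_dose=control_dose)


def write_design(design: DoseDesign, path: PathLike) -> None:
    design.table.to_csv(path, index=False)


def read_nitrate_csv(path: PathLike) -> pd.DataFrame:
    """Nitrification input CSV.

    Columns: sample_id, treatment, dose (or dose_mg_per_kg), replicate, and
    either no3_t0/no3_t28 or a precomputed ``response`` column.
    """
    df = pd.read_csv(path, dtype={"sample_id": str, "treatment": str})
    if "dose_mg_per_kg" in df.columns and "dose" not in df.columns:
        df = df.rename(columns={"dose_mg_per_kg": "dose"})
    if "dose" not in df.columns:
        raise ValueError("nitrification CSV needs a 'dose' or 'dose_mg_per_kg' column")
    return df


def write_json(obj, path: PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
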