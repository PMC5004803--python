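import logging

import numpy as np
import pandas as pd
import pytest

from osdtox.abundance import CopyNumberMap, DoseDesign, OtuTable, QpcrTotals
from osdtox.doseresponse import DoseSeries, LogLogisticParams, eval_loglogistic

# per-OTU fitting emits expected warnings (singular Jacobians on junk OTUs)
logging.getLogger("osdtox").setLevel(logging.ERROR)


@pytest.fixture
def dose_grid_14():
    """14-rate geometric Ag gradient, 0.1 (control) to 5590 mg/kg."""
    return np.geomspace(0.1, 5590.0, 14)


@pytest.fixture
def clean_loglogistic_series(dose_grid_14):
    """Noise-free declining series from a known log-logistic truth."""
    truth = LogLogisticParams(b=1.5, c=5.0, d=120.0, e=8.0)
    y = eval_loglogistic(truth, dose_grid_14)
    return DoseSeries(doses=dose_grid_14, responses=y), truth


@pytest.fixture
def toy_table():
    """5-sample raw OTU table with known singleton/doubleton structure."""
    counts = pd.DataFrame(
        {
            "S1": [1, 1, 2, 9000, 12000, 500],
            "S2": [0, 1, 1, 9500, 11000, 600],
            "S3": [0, 0, 0, 9800, 10000, 700],
            "S4": [0, 0, 0, 10000, 9000, 800],
            "S5": [0, 0, 0, 8000, 950, 50],
        },
        index=[f"OTU{i}" for i in range(1, 7)],
    )
    return OtuTable(counts=counts, stage="raw")


@pytest.fixture
def small_design():
    rows = [{"sample_id": "C0", "treatment": "control", "dose": 0.1}]
    rows += [
        {"sample_id": f"A{i}", "treatment": "Ag+", "dose": d}
        for i, d in enumerate([1, 3, 10, 30, 100, 300, 1000])
    ]
    rows += [
        {"sample_id": f"B{i}", "treatment": "AgNP", "dose": d}
        for i, d in enumerate([1, 3, 10, 30, 100, 300, 1000])
    ]
    return DoseDesign(table=pd.DataFrame(rows), control_label="control", control_dose=0.1)
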