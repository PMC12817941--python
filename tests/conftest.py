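import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from lncperturb.counts import CountMatrix, SampleDesign
from lncperturb.pulldown import (
    cytoplasmic_table_path,
    nuclear_table_path,
    read_pulldown_table,
)

#: Printed one-decimal enrichment values of the nuclear golden table
#: ("N/A" = unique binding).  ELAVL1's printed 6.0 matches the unfloored
#: ratio only; the floored chain yields 4.0 and flags the row.
NUCLEAR_PRINTED = {
    "LRPPRC": "N/A", "PCBP2": "N/A", "CSTF3": "N/A", "CELF1": "N/A",
    "CSTF2": "N/A", "TARDBP": "N/A", "CPSF7": "N/A",
    "FUBP1": "7.9", "KHSRP": "7.3", "FUBP3": "6.7", "ELAVL1": "6.0",
    "CSTF1": "5.5", "SYMPK": "5.3", "SF1": "4.2", "HNRNPM": "4.1",
    "PUF60": "3.1", "CPSF1": "3.1", "CPSF2": "2.8", "SCAF11": "2.3",
}

CYTOPLASMIC_PRINTED = {
    "IFIT3": "N/A", "LARS1": "13.7", "IFIT1": "11.0", "QARS1": "8.6",
    "AIMP1": "7.3", "MARS1": "6.1", "HNRNPK": "4.7", "RARS1": "4.6",
    "KARS1": "4.3", "PCBP2": "3.7", "FUBP1": "3.2", "IARS1": "3.1",
    "SART3": "3.0", "PUF60": "2.5", "U2AF2": "2.5", "DARS1": "2.3",
    "LRPPRC": "2.3", "EPRS1": "2.3", "SF3B3": "2.2",
}


@pytest.fixture(scope="session")
def nuclear_records():
    return read_pulldown_table(nuclear_table_path())


@pytest.fixture(scope="session")
def cytoplasmic_records():
    return read_pulldown_table(cytoplasmic_table_path())


@pytest.fixture()
def toy_design():
    """One-experiment design: control + one perturbed line, 3 doses, 3 reps."""
    rows = []
    for line in ("control", "pertA"):
        for dose in ("mock", "low", "high"):
            for rep in (1, 2, 3):
                rows.append(
                    {
                        "sample_id": f"{line}_{dose}_{rep}",
                        "experiment": "OE",
                        "perturbation": line,
                        "dose": dose,
                        "replicate": rep,
                    }
                )
    return SampleDesign(pd.DataFrame(rows))


@pytest.fixture()
def toy_matrix(toy_design):
    rng = np.random.default_rng(0)
    ids = toy_design.table["sample_id"]
    counts = rng.poisson(100, size=(50, len(ids)))
    return CountMatrix(
        pd.DataFrame(counts, index=[f"g{i}" for i in range(50)], columns=list(ids))
    )
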