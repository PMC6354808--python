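"""Published reference values packaged with the library.

``REFERENCE_MEDIANS`` / ``REFERENCE_CV_PCT`` are the reported population
medians and coefficients of variation of the final four-compartment lag
model for cefepime in the rat. ``load_table3`` returns the reported
per-animal Bayesian exposure table (plasma/CSF AUC and Cmax, CSF Tmax,
half-life, penetration percentages) together with a flag for the four
animals whose intracisternal catheter failed before any CSF sample.

These are fixtures for cross-checks and defaults, not fit outputs.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .models import PKParams

__all__ = [
    "REFERENCE_MEDIANS",
    "REFERENCE_CV_PCT",
    "PLASMA_ERROR_POLY",
    "CSF_ERROR_POLY",
    "LLOQ",
    "load_table3",
    "load_table3_summary",
    "fixture_sha256",
]

#: reported population medians of the final model (rates 1/h, volumes liters)
REFERENCE_MEDIANS = PKParams(
    kel=3.15,
    Vc=0.11,
    V_CSF=0.14,
    K12=18.20,
    K21=41.98,
    K13=0.13,
    K34=2.96,
    K41=0.47,
)

#: reported coefficient of variation (percent) per parameter
REFERENCE_CV_PCT = {
    "kel": 7.5,
    "Vc": 22.9,
    "V_CSF": 64.4,
    "K12": 40.2,
    "K21": 10.0,
    "K13": 23.4,
    "K34": 116.3,
    "K41": 54.9,
}

#: assay error polynomial SD = C0 + C1*Y per matrix (ug/ml)
PLASMA_ERROR_POLY = (0.25, 0.15)
CSF_ERROR_POLY = (0.0625, 0.15)

#: lower limit of quantification per matrix (ug/ml)
LLOQ = {"plasma": 0.5, "csf": 0.125}


def _read(name: str) -> pd.DataFrame:
    with resources.files("neuropk.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_table3() -> pd.DataFrame:
    """Per-animal exposure fixture (11 rows, printed precision)."""
    df = _read("table3_exposures.csv")
    df["csf_sampled"] = df["csf_sampled"].astype(bool)
    return df


def load_table3_summary() -> pd.DataFrame:
    """Printed median/IQR summary rows of the exposure table."""
    return _read("table3_summary.csv")


def fixture_sha256(name: str = "table3_exposures.csv") -> str:
    """Checksum of a packaged fixture, to pin transcriptions in tests."""
    data = resources.files("neuropk.data").joinpath(name).read_bytes()
    return hashlib.sha256(data).hexdigest()
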