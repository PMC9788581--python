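"""Packaged clinical reference table.

The package ships the clinical characteristics of the 26-patient dual-tracer
reference cohort (14 metastatic "M" patients, Arabic identifiers; 12
lesion-free "N" controls, Roman identifiers): age, Gleason score, TNM stage,
initial serum PSA at diagnosis, treatment history, and serum PSA at the time
of the PET studies.  The image data themselves are not distributable; this
table supports the worked clinical-summary examples and the cohort-statistics
interfaces.
"""

from __future__ import annotations

import importlib.resources
import re

import numpy as np
import pandas as pd

_T34 = re.compile(r"^T3|^T4")


def load_reference_cohort() -> pd.DataFrame:
    """Load the packaged clinical table as a tidy DataFrame.

    Columns beyond the raw table:

    ``t_stage``
        Leading T-token of the TNM string (e.g. "T3a").
    ``t3_t4``
        Boolean, stage T3 or T4 disease.
    ``psa_at_pet`` / ``psa_at_pet_censored``
        Serum PSA (ug/L) at PET; one control value is reported only as an
        upper bound ("<0.05") and is stored at that bound with the censored
        flag set.

    ``initial_psa`` is NaN where the source records it as not available.
    """
    ref = importlib.resources.files("skelburden.data") / "clinical_table.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, dtype={"patient_id": str})

    df["t_stage"] = df["tnm"].str.extract(r"^(T\d[a-c]?)")
    df["t3_t4"] = df["tnm"].str.match(_T34)
    censored = df["psa_at_pet"].astype(str).str.startswith("<")
    df["psa_at_pet_censored"] = censored
    df["psa_at_pet"] = (
        df["psa_at_pet"].astype(str).str.lstrip("<").replace("nan", np.nan).astype(float)
    )
    df["initial_psa"] = pd.to_numeric(df["initial_psa"], errors="coerce")
    return df
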