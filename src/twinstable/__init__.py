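"""twinstable: stability, heritability and conservation of longitudinal
NMR metabolomic profiles in a classic twin design.

Submodules
----------
synthetic_data
    Twin cohorts and per-bin values with known ACE covariance structure.
preprocessing
    0.02-ppm spectral binning, total-area normalization, Johnson transform.
variance_decomposition
    Per-bin mixed-model variance components, ICC, covariate tests with FDR.
stability
    ICC stability bands and the stable-metabolome set.
twin_sem
    Longitudinal Cholesky ACE modeling, profile CIs, power simulation.
conservation
    Per-individual metabolome conservation indices.
pipeline_io
    Configuration and end-to-end orchestration.
"""

from importlib.resources import files

import pandas as pd

__version__ = "0.1.0"


def load_reference_stable_icc() -> pd.DataFrame:
    """Published reference ICC values for the 81 stable urinary bins.

    Columns ``bin_ppm`` (0.02-ppm bin center label) and ``icc``; the stable
    urinary NMR metabolome comprises these bins out of 400 analyzed.
    """
    path = files("twinstable").joinpath("data/stable_bins_icc.csv")
    return pd.read_csv(path, dtype={"bin_ppm": str})
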