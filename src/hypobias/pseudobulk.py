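"""Pseudo-bulk aggregation of single-cell UMI counts.

Raw UMI counts are summed over each patient's (filtered) cells per gene,
normalised to counts per million (CPM) and log2-transformed with a
pseudocount of 1. Summation happens before normalisation, so the profile is
library-size weighted like a true bulk library.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import sparse


def pseudo_bulk(
    counts,
    genes,
    cell_patients,
    cell_filter=None,
) -> pd.DataFrame:
    """Patients x genes log2(CPM + 1) matrix from summed UMI counts.

    Parameters
    ----------
    counts : genes x cells matrix (dense array or scipy sparse).
    genes : gene identifiers, length = counts.shape[0].
    cell_patients : per-cell patient ids, length = counts.shape[1].
    cell_filter : optional boolean mask over cells (e.g. cancer cells only).
    """
    counts = counts.tocsc() if sparse.issparse(counts) else np.asarray(counts)
    patients = np.asarray(cell_patients)
    if counts.shape[1] != len(patients):
        raise ValueError("cell_patients length does not match count columns")
    keep = np.ones(len(patients), dtype=bool) if cell_filter is None else np.asarray(cell_filter, dtype=bool)
    uniq = sorted(set(patients[keep]))
    sums = np.zeros((len(uniq), counts.shape[0]))
    for i, p in enumerate(uniq):
        cols = np.flatnonzero((patients == p) & keep)
        block = counts[:, cols]
        sums[i] = np.asarray(block.sum(axis=1)).ravel()
    lib = sums.sum(axis=1, keepdims=True)
    if np.any(lib == 0):
        raise ValueError("a patient has zero total counts after filtering")
    cpm = 1e6 * sums / lib
    return pd.DataFrame(np.log2(cpm + 1.0), index=uniq, columns=list(genes))


def acs_opc_ratio(
    scores: pd.DataFrame,
    acs_col: str = "ACS",
    opc_cols=("OPC_ENRICHED_300", "OPC_SPECIFIC_300"),
) -> pd.Series:
    """Per-patient ACS score divided by the mean of the two OPC scores.

    A zero OPC mean yields NaN (explicit undefined), never an exception.
    """
    opc_cols = list(opc_cols)
    if len(opc_cols) != 2:
        raise ValueError("exactly two OPC score columns expected")
    opc_mean = scores[opc_cols].mean(axis=1)
    ratio = scores[acs_col] / opc_mean.replace(0.0, math.nan)
    return ratio.rename("acs_opc_ratio")
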