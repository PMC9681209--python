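"""Methylation data model: probe manifests, beta matrices and M-value transforms.

Beta values are the fraction of methylated signal at a CpG probe, in (0, 1).
M values are the log2-odds transform, ``M = log2(beta / (1 - beta))``, the
scale on which per-probe differences are summarised. Coordinates are 0-based
point positions of the CpG; BED export is 0-based half-open.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: beta values are clamped to [BETA_EPS, 1 - BETA_EPS] before the M transform
#: so that boundary values coming out of upstream normalisation stay finite.
BETA_EPS = 1e-6

MANIFEST_COLUMNS = ["chrom", "pos", "strand"]


def read_manifest(path) -> pd.DataFrame:
    """Read a probe manifest TSV (probe_id, chrom, pos, strand).

    Returns a DataFrame indexed by probe_id, sorted by (chrom, pos).
    Raises ``ValueError`` on duplicate probe ids or negative positions.
    """
    man = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    missing = {"probe_id", "chrom", "pos"} - set(man.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    if "strand" not in man.columns:
        man["strand"] = "unknown"
    man = man.set_index("probe_id")
    validate_manifest(man)
    return man.sort_values(["chrom", "pos"])


def write_manifest(man: pd.DataFrame, path) -> None:
    man.loc[:, MANIFEST_COLUMNS].to_csv(path, sep="\t", index_label="probe_id")


def validate_manifest(man: pd.DataFrame) -> None:
    if man.index.duplicated().any():
        dups = man.index[man.index.duplicated()].unique().tolist()[:5]
        raise ValueError(f"duplicate probe ids in manifest: {dups}")
    if (man["pos"] < 0).any():
        raise ValueError("manifest contains negative positions")


def read_beta(path) -> pd.DataFrame:
    """Read a probes x samples beta matrix TSV; errors on duplicate ids or
    non-numeric cells."""
    beta = pd.read_csv(path, sep="\t", index_col=0)
    if beta.index.duplicated().any():
        raise ValueError("duplicate probe ids in beta matrix")
    if not all(np.issubdtype(dt, np.number) for dt in beta.dtypes):
        bad = [c for c, dt in beta.dtypes.items() if not np.issubdtype(dt, np.number)]
        raise ValueError(f"non-numeric columns in beta matrix: {bad}")
    return beta


def write_beta(beta: pd.DataFrame, path) -> None:
    beta.to_csv(path, sep="\t", index_label="probe_id")


def check_probes_in_manifest(beta: pd.DataFrame, man: pd.DataFrame) -> None:
    missing = beta.index.difference(man.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} beta-matrix probes absent from manifest "
            f"(e.g. {missing[:3].tolist()})"
        )


def beta_to_m(beta, eps: float = BETA_EPS):
    """log2-odds transform of beta; inputs at the 0/1 boundary are clamped to
    ``eps`` first. Values outside [0, 1] are a domain error."""
    arr = np.asarray(beta, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("beta values must lie in [0, 1]")
    clamped = np.clip(arr, eps, 1.0 - eps)
    m = np.log2(clamped / (1.0 - clamped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index)
    return m if arr.shape else float(m)


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    arr = np.asarray(m, dtype=float)
    b = 1.0 / (1.0 + np.exp2(-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(b, index=m.index)
    return b if arr.shape else float(b)


def median_delta_m(tumour_m: pd.DataFrame, control_m: pd.DataFrame) -> pd.Series:
    """Per-probe median of M differences over all tumour/control replicate
    pairings.

    For probe p with tumour replicates t_1..t_a and control replicates
    c_1..c_b the statistic is ``median over (i, j) of t_i - c_j``. Probes are
    intersected between the two matrices; an empty intersection is an error.
    """
    shared = tumour_m.index.intersection(control_m.index)
    if len(shared) == 0:
        raise ValueError("no shared probes between tumour and control matrices")
    t = tumour_m.loc[shared].to_numpy(dtype=float)
    c = control_m.loc[shared].to_numpy(dtype=float)
    # probes x (n_t * n_c) matrix of all replicate pairings
    diffs = (t[:, :, None] - c[:, None, :]).reshape(len(shared), -1)
    return pd.Series(np.median(diffs, axis=1), index=shared, name="median_delta_m")


def mean_delta_beta(tumour: pd.DataFrame, control: pd.DataFrame) -> pd.Series:
    """Per-probe mean(tumour) - mean(control) on the beta scale, over shared
    probes. Probes with any missing value are dropped listwise."""
    shared = tumour.index.intersection(control.index)
    if len(shared) == 0:
        raise ValueError("no shared probes between tumour and control matrices")
    t = tumour.loc[shared]
    c = control.loc[shared]
    delta = t.mean(axis=1, skipna=False) - c.mean(axis=1, skipna=False)
    return delta.dropna()


def probes_to_bed(man: pd.DataFrame, probe_ids, path) -> None:
    """Write a probe subset as BED (0-based half-open single-base intervals)."""
    sub = man.loc[list(probe_ids)].sort_values(["chrom", "pos"])
    with open(path, "w") as fh:
        for pid, row in sub.iterrows():
            fh.write(f"{row['chrom']}\t{int(row['pos'])}\t{int(row['pos']) + 1}\t{pid}\n")
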