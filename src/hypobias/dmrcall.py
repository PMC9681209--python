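"""Differentially methylated region (DMR) calling from two-group beta matrices.

Per-probe group differences in beta are smoothed along each chromosome with a
Gaussian kernel of bandwidth ``lambda`` (sd = lambda / C), probes whose
smoothed difference exceeds the beta cutoff become candidates, and runs of
candidates separated by at most ``lambda`` bp form regions. Regions with at
least ``min_probes`` candidate probes are emitted, with a direction taken
from the sign of the mean raw difference over the region's candidate probes.

This is a deliberately simplified regional statistic: the moderated-t /
FDR machinery of full DMR callers is replaced by effect-size thresholding on
the smoothed mean delta-beta, which is the quantity the downstream bias
statistic consumes. Defaults: min_probes=6, beta_cutoff=0.3, lambda=1000 bp,
C=2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .methylome import mean_delta_beta

DMR_COLUMNS = ["chrom", "start", "end", "n_probes", "mean_delta_beta", "direction"]


@dataclass(frozen=True)
class DmrParams:
    """Region-calling parameters; kernel sd is ``lam / C``."""

    min_probes: int = 6
    beta_cutoff: float = 0.3
    lam: float = 1000.0
    C: float = 2.0

    def __post_init__(self):
        if self.min_probes < 2:
            raise ValueError("min_probes must be >= 2")
        if not 0 < self.beta_cutoff < 1:
            raise ValueError("beta_cutoff must be in (0, 1)")
        if self.lam <= 0 or self.C <= 0:
            raise ValueError("lam and C must be positive")

    @property
    def sigma(self) -> float:
        return self.lam / self.C


def smooth_delta(positions, delta, lam: float = 1000.0, C: float = 2.0):
    """Gaussian-kernel smooth per-probe differences along one chromosome.

    ``smoothed_i = sum_j K((p_j - p_i)/sigma) * delta_j / sum_j K(...)`` with
    sigma = lam / C, restricted to probes with ``|p_j - p_i| <= lam``.
    Positions must be sorted ascending; a single probe smooths to itself.
    """
    pos = np.asarray(positions, dtype=float)
    d = np.asarray(delta, dtype=float)
    if pos.shape != d.shape:
        raise ValueError("positions and delta must have the same length")
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted ascending")
    sigma = lam / C
    out = np.empty_like(d)
    lo = np.searchsorted(pos, pos - lam, side="left")
    hi = np.searchsorted(pos, pos + lam, side="right")
    for i in range(len(pos)):
        w = np.exp(-0.5 * ((pos[lo[i]:hi[i]] - pos[i]) / sigma) ** 2)
        out[i] = np.dot(w, d[lo[i]:hi[i]]) / w.sum()
    return out


def probe_calls(
    manifest: pd.DataFrame,
    tumour: pd.DataFrame,
    control: pd.DataFrame,
    params: DmrParams = DmrParams(),
) -> pd.DataFrame:
    """Per-probe table of raw and smoothed delta-beta with candidate flags.

    Columns: chrom, pos, delta, smoothed, candidate (|smoothed| >= cutoff,
    ties included). Sorted by (chrom, pos). The hypo/hyper proportions of
    Fig-style probe panels can be tallied either from the raw sign or from
    the candidate calls; both are derivable from this table.
    """
    delta = mean_delta_beta(tumour, control)
    shared = delta.index.intersection(manifest.index)
    man = manifest.loc[shared, ["chrom", "pos"]].copy()
    man["delta"] = delta.loc[shared]
    man = man.sort_values(["chrom", "pos"])
    smoothed = np.empty(len(man))
    for _, idx in man.groupby("chrom", sort=False).groups.items():
        block = man.loc[idx]
        loc = man.index.get_indexer(idx)
        smoothed[loc] = smooth_delta(
            block["pos"].to_numpy(), block["delta"].to_numpy(), params.lam, params.C
        )
    man["smoothed"] = smoothed
    man["candidate"] = np.abs(man["smoothed"]) >= params.beta_cutoff
    return man


def probe_direction_summary(calls: pd.DataFrame) -> dict:
    """Hypo/hyper probe tallies, both raw-sign and candidate-only.

    Whether probe-level proportions should count every probe by raw sign or
    only probes passing the smoothed cutoff is a presentation choice; both
    are reported.
    """
    nonzero = calls[calls["delta"] != 0]
    cand = calls[calls["candidate"]]
    return {
        "n_probes": int(len(calls)),
        "raw_hypo": int((nonzero["delta"] < 0).sum()),
        "raw_hyper": int((nonzero["delta"] > 0).sum()),
        "candidate_hypo": int((cand["smoothed"] < 0).sum()),
        "candidate_hyper": int((cand["smoothed"] > 0).sum()),
    }


def call_dmrs(
    manifest: pd.DataFrame,
    tumour: pd.DataFrame,
    control: pd.DataFrame,
    params: DmrParams = DmrParams(),
) -> pd.DataFrame:
    """Call DMRs between a tumour and a control beta matrix.

    Returns a DataFrame with columns chrom, start, end (0-based half-open),
    n_probes (candidate probes in the region), mean_delta_beta (mean raw
    delta over candidate probes) and direction ('hypo' iff mean raw delta
    < 0, else 'hyper'), sorted by (chrom, start). Empty input gives an empty
    frame, not an error.
    """
    if len(tumour.index.intersection(control.index).intersection(manifest.index)) == 0:
        if len(tumour.index) == 0 or len(control.index) == 0:
            return pd.DataFrame(columns=DMR_COLUMNS)
        raise ValueError("no probes shared between matrices and manifest")
    calls = probe_calls(manifest, tumour, control, params)
    regions = []
    for chrom, block in calls.groupby("chrom", sort=False):
        cand = block[block["candidate"]]
        if cand.empty:
            continue
        pos = cand["pos"].to_numpy(dtype=float)
        # split runs of candidates where the gap exceeds lambda
        breaks = np.flatnonzero(np.diff(pos) > params.lam)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(pos)]])
        for s, e in zip(starts, ends):
            if e - s < params.min_probes:
                continue
            run = cand.iloc[s:e]
            mdb = float(run["delta"].mean())
            regions.append(
                {
                    "chrom": chrom,
                    "start": int(run["pos"].iloc[0]),
                    "end": int(run["pos"].iloc[-1]) + 1,
                    "n_probes": int(e - s),
                    "mean_delta_beta": mdb,
                    "direction": "hypo" if mdb < 0 else "hyper",
                }
            )
    dmrs = pd.DataFrame(regions, columns=DMR_COLUMNS)
    return dmrs.sort_values(["chrom", "start"]).reset_index(drop=True)


def dmr_summary(dmrs: pd.DataFrame) -> dict:
    """Counts of hypo/hyper regions and candidate probes for one comparison."""
    hypo = dmrs[dmrs["direction"] == "hypo"]
    hyper = dmrs[dmrs["direction"] == "hyper"]
    return {
        "n_dmrs": int(len(dmrs)),
        "n_hypo": int(len(hypo)),
        "n_hyper": int(len(hyper)),
        "n_probes_hypo": int(hypo["n_probes"].sum()),
        "n_probes_hyper": int(hyper["n_probes"].sum()),
    }


def write_dmrs_bed(dmrs: pd.DataFrame, path) -> None:
    """BED export: name = direction, score = |mean_delta_beta| * 1000."""
    with open(path, "w") as fh:
        for _, r in dmrs.iterrows():
            score = int(round(abs(r["mean_delta_beta"]) * 1000))
            fh.write(
                f"{r['chrom']}\t{int(r['start'])}\t{int(r['end'])}\t"
                f"{r['direction']}\t{score}\n"
            )


def read_dmrs_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, name, score = line.rstrip("\n").split("\t")
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(start),
                    "end": int(end),
                    "direction": name,
                    "score": int(score),
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "score"])
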