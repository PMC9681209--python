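"""Hypo-methylation-bias statistic and spectrum classification.

For one tumour line vs one comparator, the statistic is the fraction of its
DMRs whose direction is hypo (tumour less methylated). A line is 'bias'
under the syngeneic rule when its (mean) hypo fraction strictly exceeds
60%, and under the lenient all-comparators rule when every per-comparator
fraction strictly exceeds 50%. Mean fractions place the line on a spectrum:
none (<50%), very_low, low, medium, high, very_high in 10-point steps.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

LABEL_BIAS = "bias"
LABEL_NON_BIAS = "non-bias"
LABEL_NA = "non-classifiable"

SPECTRUM_BINS = (
    (0.9, "very_high"),
    (0.8, "high"),
    (0.7, "medium"),
    (0.6, "low"),
    (0.5, "very_low"),
)

#: absolute tolerance for threshold comparisons, so that a mean of exactly
#: representable fractions (e.g. mean(0.7, 0.7, 0.7) = 0.699...98) does not
#: straddle a bin edge through accumulation error
EPS = 1e-9


def hypo_fraction(dmrs: pd.DataFrame) -> float:
    """(# hypo DMRs) / (# DMRs); NaN (never 0) when there are no DMRs."""
    if dmrs is None or len(dmrs) == 0:
        return math.nan
    return float((dmrs["direction"] == "hypo").mean())


def classify_syngeneic(fraction: float) -> str:
    """Bias iff the hypo fraction strictly exceeds 0.60."""
    if fraction is None or math.isnan(fraction):
        return LABEL_NA
    return LABEL_BIAS if fraction > 0.60 + EPS else LABEL_NON_BIAS


def classify_all_comparators(fractions) -> str:
    """Bias iff every comparator's hypo fraction strictly exceeds 0.50.

    Missing (NaN) fractions make the call non-classifiable when they are
    the majority; otherwise they are ignored.
    """
    fr = np.asarray(list(fractions), dtype=float)
    if len(fr) < 2:
        raise ValueError("all-comparators rule needs >= 2 comparators")
    valid = fr[~np.isnan(fr)]
    if len(valid) == 0 or len(valid) < len(fr) / 2:
        return LABEL_NA
    return LABEL_BIAS if bool(np.all(valid > 0.50 + EPS)) else LABEL_NON_BIAS


def spectrum_bin(mean_fraction: float) -> str:
    """Half-open spectrum bins; boundary values fall in the upper bin."""
    if mean_fraction is None or math.isnan(mean_fraction):
        return "none"
    if not -EPS <= mean_fraction <= 1 + EPS:
        raise ValueError("fraction must be in [0, 1]")
    for lo, name in SPECTRUM_BINS:
        if mean_fraction >= lo - EPS:
            return name
    return "none"


def patient_specific(dmrs_by_patient: dict) -> dict:
    """Restrict each patient's DMR set to regions private to that patient.

    A DMR is removed when it overlaps (>= 1 bp) any DMR called in any other
    patient's comparison. Overlap is on 0-based half-open intervals.
    """
    out = {}
    for patient, dmrs in dmrs_by_patient.items():
        others = [d for p, d in dmrs_by_patient.items() if p != patient and len(d)]
        if not others or len(dmrs) == 0:
            out[patient] = dmrs.copy() if dmrs is not None else dmrs
            continue
        other = pd.concat(others, ignore_index=True)
        keep = []
        for i, r in dmrs.iterrows():
            same = other[other["chrom"] == r["chrom"]]
            hit = ((same["start"] < r["end"]) & (same["end"] > r["start"])).any()
            keep.append(not hit)
        out[patient] = dmrs[np.asarray(keep, dtype=bool)].reset_index(drop=True)
    return out


def run_cohort(comparisons: dict, mode: str = "syngeneic") -> pd.DataFrame:
    """Classify every tumour line of a cohort.

    Parameters
    ----------
    comparisons
        Mapping ``sample_id -> {comparator_id -> DMR DataFrame}``. The
        comparator count is taken from the input; nothing is hard-coded.
    mode
        'syngeneic' applies the >60% rule to the mean fraction;
        'all_comparators' requires >50% in every comparator.

    Returns one row per line with columns sample_id, n_comparators,
    mean_hypo_fraction, label, spectrum, mode, plus one ``frac_<comparator>``
    column per comparator. Rows are sorted by sample_id, comparator columns
    by comparator id, so output is independent of input ordering.
    """
    if mode not in ("syngeneic", "all_comparators"):
        raise ValueError(f"unknown mode: {mode}")
    rows = []
    all_comp = sorted({c for d in comparisons.values() for c in d})
    for sample in sorted(comparisons):
        fracs = {c: hypo_fraction(d) for c, d in comparisons[sample].items()}
        vec = [fracs.get(c, math.nan) for c in all_comp if c in fracs]
        valid = [f for f in vec if not math.isnan(f)]
        mean_frac = float(np.mean(valid)) if valid else math.nan
        if len(valid) < len(vec) / 2:
            label = LABEL_NA
        elif mode == "syngeneic" or len(vec) < 2:
            label = classify_syngeneic(mean_frac)
        else:
            label = classify_all_comparators(vec)
        row = {
            "sample_id": sample,
            "n_comparators": len(vec),
            "mean_hypo_fraction": mean_frac,
            "label": label,
            "spectrum": spectrum_bin(mean_frac),
            "mode": mode,
        }
        for c in all_comp:
            if c in fracs:
                row[f"frac_{c}"] = fracs[c]
        rows.append(row)
    return pd.DataFrame(rows)
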