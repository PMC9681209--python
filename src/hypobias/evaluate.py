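"""Recovery evaluation of the pipeline on planted synthetic cohorts.

These procedures generate synthetic data at the package's study-condition
defaults, run the corresponding pipeline stage, and measure agreement with
the planted truth. They back both the test suite and the reproduction
script.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .biascall import (
    classify_all_comparators,
    hypo_fraction,
    run_cohort,
    spectrum_bin,
)
from .dmrcall import DmrParams, call_dmrs
from .enrichment import classify_enrichment
from .invadex import run_section
from .modulescore import assign_cells, module_scores
from .signatures import default_acs, opc_signatures
from .ssgsea import ssgsea_scores
from .synth import (
    gen_expression,
    gen_invasion_phantom,
    gen_methyl_cohort,
    gen_single_cell,
    gen_tumour_mask,
    match_planted_regions,
)

CANCER_SIG_TO_LABEL = {
    "ACS": "cancer-AC-like",
    "OPC_ENRICHED_300": "cancer-OPC-like",
    "OPC_SPECIFIC_300": "cancer-OPC-like",
}


def dmr_recovery(seeds, n_regions: int = 40, n_probes: int = 2000,
                 delta_beta: float = 0.4, noise_sd: float = 0.05) -> dict:
    """Precision/recall of planted DMRs and the hypo-fraction error, pooled
    over one cohort per seed."""
    precs, recs, frac_err = [], [], []
    for seed in seeds:
        man, pairs, truth = gen_methyl_cohort(
            n_probes=n_probes, n_regions=n_regions,
            delta_beta_magnitude=delta_beta, noise_sd=noise_sd,
            hypo_fraction=0.5, seed=seed,
        )
        dmrs = call_dmrs(man, *pairs[0], DmrParams())
        p, r = match_planted_regions(dmrs, truth)
        precs.append(p)
        recs.append(r)
        frac_err.append(abs(hypo_fraction(dmrs) - truth.planted_hypo_fraction))
    return {
        "precision": float(np.mean(precs)),
        "recall": float(np.mean(recs)),
        "max_hypo_fraction_error": float(np.max(frac_err)),
        "mean_hypo_fraction_error": float(np.mean(frac_err)),
    }


def bias_recovery(seeds, n_comparators: int = 3, n_regions: int = 40,
                  n_probes: int = 1000) -> dict:
    """Label and spectrum recovery for lines with planted hypo fractions
    spanning 0.2-0.9 (12 lines), classified in all-comparators mode."""
    fractions = np.round(np.linspace(0.2, 0.9, 12), 3)
    label_hits = spectrum_hits = total = 0
    for seed in seeds:
        comparisons = {}
        expected = {}
        for i, f in enumerate(fractions):
            line = f"L{i:02d}"
            man, pairs, truth = gen_methyl_cohort(
                n_probes=n_probes, n_pairs=n_comparators, n_regions=n_regions,
                hypo_fraction=float(f), seed=int(seed * 1000 + i),
            )
            comparisons[line] = {
                f"c{j}": call_dmrs(man, *pairs[j]) for j in range(n_comparators)
            }
            planted = truth.planted_hypo_fraction
            expected[line] = (
                classify_all_comparators([planted] * n_comparators),
                spectrum_bin(planted),
            )
        table = run_cohort(comparisons, "all_comparators").set_index("sample_id")
        for line, (exp_label, exp_spec) in expected.items():
            total += 1
            label_hits += int(table.loc[line, "label"] == exp_label)
            spectrum_hits += int(table.loc[line, "spectrum"] == exp_spec)
    return {
        "label_accuracy": label_hits / total,
        "spectrum_accuracy": spectrum_hits / total,
        "n_lines": total,
    }


def enrichment_recovery(seeds, planted_log2fc: float = 2.0) -> dict:
    """Accuracy of the two-rule enrichment call on planted ACS-up samples."""
    acs = default_acs()
    opcs = opc_signatures()
    hits = total = 0
    for seed in seeds:
        tpm, truth = gen_expression(
            signature=acs, planted_log2fc=planted_log2fc, seed=seed
        )
        scores = ssgsea_scores(tpm, [acs, *opcs])
        dec = classify_enrichment(scores, acs_col="ACS")
        enriched_truth = set(truth["enriched_samples"])
        for sample, row in dec.iterrows():
            total += 1
            hits += int(bool(row["enriched"]) == (sample in enriched_truth))
    return {"accuracy": hits / total, "n_samples": total}


def cell_assignment_recovery(seeds, effect_fold: float = 4.0,
                             cells_per_patient: int = 150) -> dict:
    """Arg-max module-score assignment accuracy on planted cancer cells."""
    acs = default_acs()
    opcs = opc_signatures()
    hits = total = 0
    for seed in seeds:
        counts, genes, barcodes, truth = gen_single_cell(
            effect_fold=effect_fold, cells_per_patient=cells_per_patient,
            seed=seed,
        )
        dense = counts.toarray().T.astype(float)
        lib = dense.sum(axis=1, keepdims=True)
        logn = np.log1p(dense / lib * 1e4)
        expr = pd.DataFrame(logn, index=barcodes, columns=genes)
        scores = module_scores(expr, [acs, *opcs], random_state=seed)
        labels = assign_cells(scores)["label"].map(CANCER_SIG_TO_LABEL)
        true = pd.Series(truth.cell_labels, index=barcodes)
        cancer = true.isin(["cancer-AC-like", "cancer-OPC-like"])
        hits += int((labels[cancer] == true[cancer]).sum())
        total += int(cancer.sum())
    return {"accuracy": hits / total, "n_cells": total}


def phantom_invasiveness(pixel_sizes=(0.5, 1.0, 2.0)) -> dict:
    """Invasiveness indices of the analytic disk phantoms at several
    resolutions, plus the no-halo control."""
    out: dict = {"by_pixel_size": {}}
    for px in pixel_sizes:
        tissue, stain, truth = gen_invasion_phantom(
            core_radius=100.0, gross_radius=141.42, pixel_size=px
        )
        res = run_section(tissue, stain)
        out["by_pixel_size"][px] = res.invasiveness_index
    tissue, stain, _ = gen_tumour_mask(halo=())
    out["no_halo_ii"] = run_section(tissue, stain).invasiveness_index
    out["truth_ii"] = (141.42 / 100.0) ** 2
    return out
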