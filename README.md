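# hypobias

Analytical machinery for identifying a hypo-methylation-biased,
astrocyte-signature-enriched subset of glioblastoma from patient-derived
cell-line cohorts, and for quantifying its functional correlates. The
package is aimed at computational biologists working with Illumina
EPIC-style methylation arrays, bulk/single-cell RNA-seq and calibrated
histology masks, and chains five stages:

1. **DMR calling** (`hypobias.dmrcall`) — per-probe group differences in
   beta (Δβ = mean tumour − mean comparator) are Gaussian-kernel smoothed
   along each chromosome (bandwidth λ = 1000 bp, kernel sd λ/C with C = 2);
   probes with |smoothed Δβ| ≥ 0.3 are grouped into regions when separated
   by ≤ λ bp, and regions with ≥ 6 such probes are emitted as
   differentially methylated regions (DMRs) with a hypo/hyper direction.
2. **Hypo-methylation-bias classification** (`hypobias.biascall`) — for a
   tumour line, the statistic is the fraction of its DMRs that are hypo.
   The syngeneic rule calls "bias" when the fraction strictly exceeds 60%;
   the lenient all-comparators rule requires > 50% in *every* comparator.
   Mean fractions are binned onto a spectrum: none (< 50%), very_low, low,
   medium, high, very_high in 10-point steps.
3. **Signature scoring** (`hypobias.ssgsea`, `hypobias.enrichment`,
   `hypobias.modulescore`, `hypobias.pseudobulk`) — single-sample GSEA
   (rank-weighted running-sum area statistic, α = 0.25, table-range
   normalisation), the astrocyte composite signature (ACS) as the union of
   six astrocyte component gene sets, the two-rule enrichment call
   (ACS score above the cohort mean *and* ≥ 10% greater than every OPC
   score), per-cell additive module scores with bin-matched control genes,
   arg-max cell assignment, and patient-level pseudo-bulk
   (summed UMI → CPM → log2(x+1)).
4. **Immune-composition correlation** (`hypobias.stats`) — Spearman
   correlations (exact permutation p for n ≤ 9) between ACS/OPC score
   ratios and per-patient cell-type fractions; hypergeometric
   over-representation tests for gene-list overlaps.
5. **Invasiveness quantification** (`hypobias.invadex`) — from calibrated
   binary staining masks: tissue-edge exclusion (35 μm erosion), tumour
   core (10 μm opening, 10,000 μm² island filter), gross tumour
   (75 μm dilate → 100 μm erode → 25 μm dilate, core-containment rule) and
   the invasiveness index II = gross area / core area.

A synthetic-data module (`hypobias.synth`) generates every input with
planted ground truth — direction-biased DMRs of known effect and fraction,
signature-up-shifted expression, labelled cell mixtures, and disk phantoms
with analytic areas — so the whole pipeline is testable end to end without
any external data.

## Worked example

```python
from hypobias import call_dmrs, hypo_fraction, classify_syngeneic, spectrum_bin
from hypobias.synth import gen_methyl_cohort

manifest, pairs, truth = gen_methyl_cohort(
    n_probes=2000, n_regions=40, hypo_fraction=0.75, seed=1)
tumour, control = pairs[0]
dmrs = call_dmrs(manifest, tumour, control)
frac = hypo_fraction(dmrs)
print(len(dmrs), round(frac, 3), classify_syngeneic(frac), spectrum_bin(frac))
```

prints

```
40 0.75 bias medium
```

All 40 planted regions are recovered; 30 of them were planted hypo, so the
hypo fraction is 0.75, which exceeds the strict 60% rule ("bias") and falls
in the ≥ 70% "medium" spectrum bin.

The same stages are available from the shell via the `hypobias` console
script (`simulate`, `dmr`, `bias`, `score`, `cells`, `invade`, `correlate`,
`report`); every command writes a provenance sidecar with its parameters
and seed.

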