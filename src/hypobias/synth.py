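"""Synthetic cohorts with planted ground truth for every pipeline stage.

Each generator is a pure function of its arguments including the seed, and
returns a truth object sufficient to compute every downstream expected value
without re-inspecting the generated data.

Study-condition defaults: planted DMRs carry |delta beta| = 0.4 on a
bimodal Beta(2,10)/Beta(10,2) baseline with per-sample Gaussian noise of sd
0.05; planted expression effects are log2 fold-change 2; single-cell UMI
counts are negative binomial with dispersion 0.5 and a 4-fold marker
up-shift. These are the effect sizes the recovery guarantees of the rest of
the package are stated under.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmwrite

from .invadex import CalibratedMask
from .signatures import GeneSignature, default_acs, opc_signatures

# ---------------------------------------------------------------------------
# methylation cohorts


@dataclass
class MethylSimTruth:
    """Planted DMR ground truth for one synthetic methylation cohort."""

    planted_regions: list  # dicts: chrom, start, end, n_probes, delta_beta
    planted_hypo_fraction: float
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


_CHROMS = ("chr1", "chr2", "chr3", "chr4")
_PROBES_PER_REGION = 8
_INTRA_SPACING = (120, 180)  # bp between planted-cluster probes (<= 200)
_BG_GAP = (2200, 3000)  # bp between background probes (> lambda)
_REGION_FLANK = 3000  # bp clearance around each planted cluster


def gen_methyl_cohort(
    n_probes: int = 2000,
    n_pairs: int = 1,
    n_regions: int = 40,
    hypo_fraction: float = 0.5,
    delta_beta_magnitude: float = 0.4,
    noise_sd: float = 0.05,
    seed: int = 0,
    replicates: int = 2,
):
    """Two-group methylome cohort with planted direction-biased DMRs.

    Returns ``(manifest, pairs, truth)`` where ``pairs`` is a list of
    ``(tumour, control)`` beta DataFrames (one per sample pair, sharing the
    planted regions) and ``truth`` a :class:`MethylSimTruth`.

    Planted clusters hold ``_PROBES_PER_REGION`` probes spaced under 200 bp
    so a 1000 bp bandwidth keeps each cluster in one region; background
    probes sit more than the bandwidth apart. Hypo regions start from high
    baseline beta and shift down by the magnitude; hyper regions the
    reverse. Raises ``ValueError`` when the probe budget cannot host the
    requested regions.
    """
    if not 0 <= hypo_fraction <= 1:
        raise ValueError("hypo_fraction must be in [0, 1]")
    if n_regions * _PROBES_PER_REGION > n_probes:
        raise ValueError(
            f"cannot pack {n_regions} regions of {_PROBES_PER_REGION} probes "
            f"into {n_probes} probes"
        )
    rng = np.random.default_rng(seed)
    n_bg = n_probes - n_regions * _PROBES_PER_REGION
    n_hypo = int(round(hypo_fraction * n_regions))

    # interleave region clusters among background probes, split over chroms
    items = ["bg"] * n_bg + ["region"] * n_regions
    rng.shuffle(items)
    per_chrom = np.array_split(np.asarray(items, dtype=object), len(_CHROMS))

    probe_rows = []
    region_probe_idx = []  # list of lists of manifest row numbers
    pid = 0
    for chrom, chrom_items in zip(_CHROMS, per_chrom):
        pos = 1000
        for item in chrom_items:
            if item == "bg":
                pos += int(rng.integers(*_BG_GAP))
                probe_rows.append((f"cg{pid:07d}", chrom, pos))
                pid += 1
            else:
                pos += _REGION_FLANK
                idxs = []
                for k in range(_PROBES_PER_REGION):
                    if k:
                        pos += int(rng.integers(*_INTRA_SPACING))
                    probe_rows.append((f"cg{pid:07d}", chrom, pos))
                    idxs.append(len(probe_rows) - 1)
                    pid += 1
                region_probe_idx.append(idxs)
                pos += _REGION_FLANK
    manifest = pd.DataFrame(
        probe_rows, columns=["probe_id", "chrom", "pos"]
    ).set_index("probe_id")
    manifest["strand"] = "+"

    # assign directions to regions (shuffled), record truth
    directions = np.array([-1] * n_hypo + [1] * (n_regions - n_hypo))
    rng.shuffle(directions)
    planted = []
    for idxs, sign in zip(region_probe_idx, directions):
        rows = manifest.iloc[idxs]
        planted.append(
            {
                "chrom": rows["chrom"].iloc[0],
                "start": int(rows["pos"].iloc[0]),
                "end": int(rows["pos"].iloc[-1]) + 1,
                "n_probes": len(idxs),
                "delta_beta": float(sign * delta_beta_magnitude),
            }
        )
    planted.sort(key=lambda r: (r["chrom"], r["start"]))

    # baseline betas: bimodal background; planted probes start where the
    # shift stays inside (0, 1)
    baseline = np.where(
        rng.random(n_probes) < 0.5,
        rng.beta(2, 10, size=n_probes),
        rng.beta(10, 2, size=n_probes),
    )
    shift = np.zeros(n_probes)
    for idxs, sign in zip(region_probe_idx, directions):
        lo, hi = (0.62, 0.92) if sign < 0 else (0.08, 0.38)
        baseline[idxs] = rng.uniform(lo, hi, size=len(idxs))
        shift[idxs] = sign * delta_beta_magnitude

    def _noisy(base):
        if noise_sd == 0:
            mat = np.tile(base[:, None], (1, replicates))
        else:
            mat = base[:, None] + rng.normal(0, noise_sd, size=(n_probes, replicates))
        return np.clip(mat, 1e-4, 1 - 1e-4)

    pairs = []
    for p in range(n_pairs):
        control = _noisy(baseline)
        tumour = _noisy(baseline + shift)
        ctrl = pd.DataFrame(
            control,
            index=manifest.index,
            columns=[f"ctrl{p}_r{r}" for r in range(replicates)],
        )
        tum = pd.DataFrame(
            tumour,
            index=manifest.index,
            columns=[f"tum{p}_r{r}" for r in range(replicates)],
        )
        pairs.append((tum, ctrl))
    truth = MethylSimTruth(planted, n_hypo / n_regions if n_regions else math.nan, seed)
    return manifest, pairs, truth


def match_planted_regions(dmrs: pd.DataFrame, truth: MethylSimTruth):
    """Precision/recall of called DMRs against planted regions.

    A planted region is recovered when a called DMR of the same direction
    overlaps it (>= 1 bp); a called DMR is a true positive when it overlaps
    a same-direction planted region.
    """
    planted = truth.planted_regions
    rec = 0
    for reg in planted:
        d = "hypo" if reg["delta_beta"] < 0 else "hyper"
        hit = dmrs[
            (dmrs["chrom"] == reg["chrom"])
            & (dmrs["direction"] == d)
            & (dmrs["start"] < reg["end"])
            & (dmrs["end"] > reg["start"])
        ]
        rec += int(len(hit) > 0)
    tp = 0
    for _, r in dmrs.iterrows():
        hit = any(
            reg["chrom"] == r["chrom"]
            and ("hypo" if reg["delta_beta"] < 0 else "hyper") == r["direction"]
            and r["start"] < reg["end"]
            and r["end"] > reg["start"]
            for reg in planted
        )
        tp += int(hit)
    recall = rec / len(planted) if planted else math.nan
    precision = tp / len(dmrs) if len(dmrs) else math.nan
    return precision, recall


# ---------------------------------------------------------------------------
# bulk expression


def gen_expression(
    n_genes: int = 500,
    groups: dict | None = None,
    signature: GeneSignature | None = None,
    background_signatures=None,
    planted_log2fc: float = 2.0,
    seed: int = 0,
):
    """TPM expression matrix with a planted signature up-regulation.

    ``groups`` maps sample id -> True (enriched) / False (control); the
    default is 8 samples, half enriched. The gene universe contains the
    planted signature's genes, the genes of any ``background_signatures``
    (default: the packaged OPC signatures, not up-shifted) and filler genes
    up to ``n_genes``. Enriched samples' signature genes are up-shifted by
    ``planted_log2fc``; columns are then normalised to sum to 1e6 (TPM).
    Returns ``(tpm, truth)``.
    """
    if signature is None:
        signature = default_acs()
    if background_signatures is None:
        background_signatures = opc_signatures()
    if groups is None:
        groups = {f"S{i}": i % 2 == 0 for i in range(8)}
    rng = np.random.default_rng(seed)
    sig_genes = sorted(signature.genes)
    bg_genes = sorted(
        frozenset().union(*(s.genes for s in background_signatures), frozenset())
        - signature.genes
    )
    if len(sig_genes) + len(bg_genes) > n_genes:
        raise ValueError("n_genes smaller than the signature universe")
    filler = [f"FILLER{i:05d}" for i in range(n_genes - len(sig_genes) - len(bg_genes))]
    genes = sig_genes + bg_genes + filler
    base = rng.lognormal(mean=2.0, sigma=1.0, size=n_genes)
    cols = {}
    for sample, enriched in groups.items():
        vals = base * rng.lognormal(0.0, 0.3, size=n_genes)
        if enriched:
            vals[: len(sig_genes)] *= 2.0**planted_log2fc
        cols[sample] = vals
    tpm = pd.DataFrame(cols, index=genes)
    tpm = tpm / tpm.sum(axis=0) * 1e6
    truth = {
        "enriched_samples": sorted(s for s, e in groups.items() if e),
        "signature": signature.name,
        "planted_log2fc": planted_log2fc,
        "seed": seed,
    }
    return tpm, truth


# ---------------------------------------------------------------------------
# single cells

IMMUNE_MARKERS = {
    "TAM": ["CD68", "AIF1", "MRC1", "CD163", "ITGAM", "CSF1R", "MSR1", "TYROBP"],
    "T cell": ["CD3D", "CD3E", "CD2", "CD8A", "IL7R", "TRAC", "CCL5", "GZMK"],
    "monocyte": ["CD14", "FCN1", "S100A8", "S100A9", "LYZ", "VCAN", "FCGR3A", "CTSS"],
}

DEFAULT_FRACTIONS = {
    "cancer-AC-like": 0.35,
    "cancer-OPC-like": 0.25,
    "TAM": 0.2,
    "T cell": 0.1,
    "monocyte": 0.1,
}


@dataclass
class CellMixTruth:
    """Planted single-cell ground truth: per-cell labels, per-patient
    fractions and the marker fold-change."""

    cell_labels: list
    cell_patients: list
    patient_fractions: dict
    effect_fold: float
    seed: int

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def gen_single_cell(
    n_patients: int = 4,
    cells_per_patient: int = 150,
    fractions: dict | None = None,
    effect_fold: float = 4.0,
    n_filler_genes: int = 400,
    dispersion: float = 0.5,
    seed: int = 0,
):
    """Negative-binomial UMI counts for a mixture of planted cell types.

    AC-like cancer cells up-regulate the ACS genes, OPC-like cells the OPC
    signature genes and each immune type its marker panel, all by
    ``effect_fold``. Counts are gamma-Poisson with the given dispersion.
    Returns ``(counts, genes, barcodes, truth)`` with ``counts`` a genes x
    cells CSR matrix.
    """
    fractions = dict(DEFAULT_FRACTIONS if fractions is None else fractions)
    tot = sum(fractions.values())
    if abs(tot - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1 (got {tot})")
    rng = np.random.default_rng(seed)
    acs = sorted(default_acs().genes)
    opc = sorted(frozenset().union(*(s.genes for s in opc_signatures())))
    marker_sets = {
        "cancer-AC-like": acs,
        "cancer-OPC-like": opc,
        **{k: v for k, v in IMMUNE_MARKERS.items()},
    }
    genes = sorted({g for v in marker_sets.values() for g in v})
    genes += [f"FILLER{i:05d}" for i in range(n_filler_genes)]
    gene_idx = {g: i for i, g in enumerate(genes)}

    base = rng.lognormal(mean=0.0, sigma=0.7, size=len(genes))
    labels, patients = [], []
    types = sorted(fractions)
    for p in range(n_patients):
        n_by_type = {t: int(math.floor(fractions[t] * cells_per_patient)) for t in types}
        short = cells_per_patient - sum(n_by_type.values())
        for t in sorted(types, key=lambda t: -fractions[t])[:short]:
            n_by_type[t] += 1
        plabels = [t for t in types for _ in range(n_by_type[t])]
        rng.shuffle(plabels)
        labels.extend(plabels)
        patients.extend([f"P{p}"] * cells_per_patient)

    n_cells = len(labels)
    cols = []
    shape = 1.0 / dispersion
    for lab in labels:
        mean = base.copy()
        for g in marker_sets.get(lab, ()):
            if g in gene_idx:
                mean[gene_idx[g]] *= effect_fold
        lam = rng.gamma(shape, mean * dispersion)
        cols.append(rng.poisson(lam))
    counts = sparse.csr_matrix(np.column_stack(cols))
    barcodes = [f"{patients[i]}_C{i:05d}" for i in range(n_cells)]
    pf = {}
    for p in sorted(set(patients)):
        sub = [labels[i] for i in range(n_cells) if patients[i] == p]
        pf[p] = {t: sub.count(t) / len(sub) for t in types}
    truth = CellMixTruth(labels, patients, pf, effect_fold, seed)
    return counts, genes, barcodes, truth


def write_single_cell(counts, genes, barcodes, outdir) -> None:
    """MTX + features.tsv + barcodes.tsv triplet."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mmwrite(str(outdir / "matrix.mtx"), sparse.coo_matrix(counts))
    pd.Series(genes).to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.Series(barcodes).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# tumour masks


def _disk(mask: np.ndarray, cy: float, cx: float, r_px: float) -> None:
    y, x = np.ogrid[: mask.shape[0], : mask.shape[1]]
    mask[(y - cy) ** 2 + (x - cx) ** 2 <= r_px**2] = True


def gen_tumour_mask(
    image_size: int = 512,
    pixel_size: float = 1.0,
    core_radius: float = 100.0,
    halo=((8.0, 30),),
    halo_band: tuple = (20.0, 100.0),
    seed: int = 0,
):
    """Binary staining phantom: a solid central core disk plus scattered
    halo disks of infiltrating cells, inside a full-frame tissue rectangle.

    ``halo`` is a list of (radius um, count); halo centres are
    rejection-sampled in an annulus ``halo_band`` um beyond the core edge so
    no halo disk touches the core. Returns ``(tissue, staining, truth)``
    with analytic truth areas in the dict.
    """
    extent = image_size * pixel_size
    if core_radius * 2 >= extent:
        raise ValueError("core does not fit in the image")
    rng = np.random.default_rng(seed)
    stain = np.zeros((image_size, image_size), dtype=bool)
    c = (image_size - 1) / 2.0
    _disk(stain, c, c, core_radius / pixel_size)
    halo_truth = []
    for r_um, count in halo:
        placed = 0
        attempts = 0
        while placed < count:
            attempts += 1
            if attempts > 10_000:
                raise ValueError("cannot place halo disks without core overlap")
            dist = core_radius + r_um + rng.uniform(*halo_band)
            ang = rng.uniform(0, 2 * math.pi)
            cy = c + dist * math.sin(ang) / pixel_size
            cx = c + dist * math.cos(ang) / pixel_size
            r_px = r_um / pixel_size
            if not (r_px <= cy <= image_size - 1 - r_px and r_px <= cx <= image_size - 1 - r_px):
                continue
            _disk(stain, cy, cx, r_px)
            halo_truth.append({"cy": cy, "cx": cx, "radius_um": r_um})
            placed += 1
    tissue = np.ones_like(stain)
    truth = {
        "core_area_um2": math.pi * core_radius**2,
        "core_radius_um": core_radius,
        # with no halo the gross tumour is the core itself
        "gross_area_um2": math.pi * core_radius**2 if not halo_truth else None,
        "halo": halo_truth,
        "pixel_size": pixel_size,
        "seed": seed,
    }
    return (
        CalibratedMask(tissue, pixel_size, "tissue"),
        CalibratedMask(stain, pixel_size, "staining"),
        truth,
    )


def gen_invasion_phantom(
    core_radius: float = 100.0,
    gross_radius: float = 141.42,
    pixel_size: float = 1.0,
    image_size: int | None = None,
    speck_radius: float = 5.0,
    speck_spacing: float = 15.0,
):
    """Deterministic phantom whose detected core and gross tumour have known
    analytic areas.

    The staining is a solid core disk plus a dense ring of small specks
    whose outer edge sits at ``gross_radius``: the 10 um opening removes the
    specks (leaving the core disk exactly), while the 75/100/25 um gross
    recipe bridges core and ring into one quasi-disk of radius
    ``gross_radius``. Truth invasiveness index = (gross_radius /
    core_radius)^2.
    """
    # margin must absorb the intermediate 75 um gross dilation plus the
    # 35 um tissue-edge exclusion, or border clipping distorts the areas
    if image_size is None:
        image_size = int(math.ceil((gross_radius + 120) * 2 / pixel_size))
    extent = image_size * pixel_size
    if (gross_radius + 110) * 2 >= extent:
        raise ValueError("phantom does not fit in the image")
    stain = np.zeros((image_size, image_size), dtype=bool)
    c = (image_size - 1) / 2.0
    _disk(stain, c, c, core_radius / pixel_size)
    ring_r = gross_radius - speck_radius
    n_specks = max(8, int(math.ceil(2 * math.pi * ring_r / speck_spacing)))
    for k in range(n_specks):
        ang = 2 * math.pi * k / n_specks
        cy = c + ring_r * math.sin(ang) / pixel_size
        cx = c + ring_r * math.cos(ang) / pixel_size
        _disk(stain, cy, cx, speck_radius / pixel_size)
    tissue = np.ones_like(stain)
    truth = {
        "core_area_um2": math.pi * core_radius**2,
        "gross_area_um2": math.pi * gross_radius**2,
        "invasiveness_index": (gross_radius / core_radius) ** 2,
        "pixel_size": pixel_size,
    }
    return (
        CalibratedMask(tissue, pixel_size, "tissue"),
        CalibratedMask(stain, pixel_size, "staining"),
        truth,
    )
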