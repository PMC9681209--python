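"""Whole-slide morphology: tumour core, gross tumour and invasiveness index.

All radii are physical (micrometres); erosion and dilation are implemented
by thresholding the Euclidean distance transform, so a radius means the same
thing at any pixel size. The pipeline on a calibrated binary staining mask:

1. the tissue mask is eroded by 35 um and staining outside it discarded,
   excluding tumours at the section edge;
2. the tumour core is the morphological opening of the staining by a 10 um
   radius (erode then dilate), with connected components smaller than
   10,000 um^2 discarded as islands;
3. the gross tumour is dilate 75 um -> erode 100 um -> dilate 25 um (fill
   gaps, then shrink/re-expand to the original border), keeping only
   components that contain (intersect) a tumour core;
4. the invasiveness index II = gross tumour area / tumour core area, a
   size-independent measure of infiltration beyond the core (II = 1 means
   none).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage

import tifffile

#: 8-connectivity for component labelling
_STRUCT = np.ones((3, 3), dtype=bool)


@dataclass
class CalibratedMask:
    """A binary pixel grid with physical calibration (um per pixel)."""

    pixels: np.ndarray
    pixel_size: float
    role: str = "staining"

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        self.pixels = np.asarray(self.pixels).astype(bool)

    @property
    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size**2


@dataclass
class MorphParams:
    tissue_margin_um: float = 35.0
    core_open_um: float = 10.0
    min_core_area_um2: float = 10_000.0
    gross_dilate1_um: float = 75.0
    gross_erode_um: float = 100.0
    gross_dilate2_um: float = 25.0


@dataclass
class InvasivenessResult:
    core_area_um2: float
    gross_area_um2: float
    invasiveness_index: float  # NaN when no core
    n_core_components: int
    n_gross_components: int
    border_components: int = 0
    extras: dict = field(default_factory=dict)


def erode(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Euclidean erosion: keep pixels farther than ``radius_px`` from
    background. radius 0 is the identity."""
    if radius_px <= 0:
        return mask.copy()
    return ndimage.distance_transform_edt(mask) > radius_px


def dilate(mask: np.ndarray, radius_px: float) -> np.ndarray:
    """Euclidean dilation: add background pixels within ``radius_px`` of the
    mask. radius 0 is the identity."""
    if radius_px <= 0:
        return mask.copy()
    if not mask.any():
        return mask.copy()
    return ndimage.distance_transform_edt(~mask) <= radius_px


def opening(mask: np.ndarray, radius_px: float) -> np.ndarray:
    return dilate(erode(mask, radius_px), radius_px)


def erode_tissue(tissue: CalibratedMask, margin_um: float = 35.0) -> CalibratedMask:
    """Shrink the tissue annotation by ``margin_um`` so that staining at the
    section edge is subsequently ignored."""
    r = margin_um / tissue.pixel_size
    return CalibratedMask(erode(tissue.pixels, r), tissue.pixel_size, "tissue")


def detect_core(
    staining: CalibratedMask,
    open_um: float = 10.0,
    min_area_um2: float = 10_000.0,
) -> np.ndarray:
    """Tumour-core label image: opening by ``open_um`` then discarding
    components below ``min_area_um2``. Returns an int label array (0 =
    background)."""
    px = staining.pixel_size
    opened = opening(staining.pixels, open_um / px)
    labels, n = ndimage.label(opened, structure=_STRUCT)
    if n == 0:
        return labels
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    small = np.flatnonzero(areas * px**2 < min_area_um2) + 1
    if len(small):
        labels[np.isin(labels, small)] = 0
        labels, _ = ndimage.label(labels > 0, structure=_STRUCT)
    return labels


def detect_gross(
    staining: CalibratedMask,
    core_labels: np.ndarray,
    dilate1_um: float = 75.0,
    erode_um: float = 100.0,
    dilate2_um: float = 25.0,
) -> np.ndarray:
    """Gross-tumour label image: dilate/erode/dilate, then discard
    components that do not contain (intersect) any tumour core."""
    px = staining.pixel_size
    m = dilate(staining.pixels, dilate1_um / px)
    m = erode(m, erode_um / px)
    m = dilate(m, dilate2_um / px)
    labels, n = ndimage.label(m, structure=_STRUCT)
    if n == 0:
        return labels
    with_core = np.unique(labels[(labels > 0) & (core_labels > 0)])
    labels[~np.isin(labels, with_core)] = 0
    labels, _ = ndimage.label(labels > 0, structure=_STRUCT)
    return labels


def invasiveness_index(core_area: float, gross_area: float) -> float:
    """Gross tumour area / tumour core area; NaN when there is no core."""
    if core_area <= 0:
        return float("nan")
    return gross_area / core_area


def run_section(
    tissue: CalibratedMask,
    staining: CalibratedMask,
    params: MorphParams = MorphParams(),
) -> InvasivenessResult:
    """Full per-section pipeline; see the module docstring for the steps.

    Components touching the image border are kept and counted in
    ``border_components``.
    """
    if tissue.pixels.shape != staining.pixels.shape:
        raise ValueError("tissue and staining masks must have the same shape")
    if tissue.pixel_size != staining.pixel_size:
        raise ValueError("tissue and staining masks must share a pixel size")
    px = staining.pixel_size
    eroded_tissue = erode_tissue(tissue, params.tissue_margin_um)
    inside = CalibratedMask(staining.pixels & eroded_tissue.pixels, px, "staining")
    cores = detect_core(inside, params.core_open_um, params.min_core_area_um2)
    gross = detect_gross(
        inside,
        cores,
        params.gross_dilate1_um,
        params.gross_erode_um,
        params.gross_dilate2_um,
    )
    core_area = float((cores > 0).sum()) * px**2
    gross_area = float((gross > 0).sum()) * px**2
    border = np.zeros_like(gross, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    n_border = len(np.unique(gross[border & (gross > 0)]))
    return InvasivenessResult(
        core_area_um2=core_area,
        gross_area_um2=gross_area,
        invasiveness_index=invasiveness_index(core_area, gross_area),
        n_core_components=int(cores.max()),
        n_gross_components=int(gross.max()),
        border_components=int(n_border),
    )


def aggregate_sections(results, method: str = "mean") -> float:
    """Specimen-level invasiveness index across stained section levels
    (mean by default, median by flag)."""
    vals = np.asarray([r.invasiveness_index for r in results], dtype=float)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return float("nan")
    if method == "mean":
        return float(vals.mean())
    if method == "median":
        return float(np.median(vals))
    raise ValueError(f"unknown aggregation: {method}")


def read_mask(path, pixel_size: float, role: str = "staining") -> CalibratedMask:
    """Read an 8-bit single-channel PNG/TIFF; any non-zero pixel is mask."""
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path).convert("L"))
    return CalibratedMask(arr > 0, pixel_size, role)


def write_mask(mask: CalibratedMask, path) -> None:
    path = str(path)
    arr = (mask.pixels.astype(np.uint8)) * 255
    if path.lower().endswith((".tif", ".tiff")):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr, mode="L").save(path)


def mask_from_grayscale(
    image: np.ndarray, threshold: float, pixel_size: float, role: str = "staining"
) -> CalibratedMask:
    """Threshold a greyscale image into a calibrated binary mask. The
    threshold is explicit — no automatic pixel classification is attempted."""
    return CalibratedMask(np.asarray(image, dtype=float) >= threshold, pixel_size, role)
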