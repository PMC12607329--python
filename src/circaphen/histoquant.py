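"""Per-nucleus quantification of histone-mark immunofluorescence.

Nuclei are segmented on the DAPI channel by adaptive (local-mean)
thresholding: a pixel is foreground when it exceeds the mean intensity of its
surrounding window (default 61 x 61 px, reflective borders).  The binary mask
is refined by iterated morphological opening (default 5 iterations, 3 x 3
cross), then 8-connected components of at least ``min_area`` pixels become
nuclei.  Touching nuclei are not split; counts are of connected components.

The mark signal of each nucleus is its mean intensity over the segmented
pixels divided by the mean DAPI intensity over the same pixels — a
dimensionless ratio robust to field-to-field illumination differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

from .io_phenomaster import ValidationError

MARKS = ("H3K36me3", "H3K27me3", "H3K9me2")


@dataclass(frozen=True)
class FieldImagePair:
    """One field of view: DAPI and histone-mark channels, same dimensions."""

    animal_id: str
    field_id: str
    dapi: np.ndarray
    mark: np.ndarray
    mark_name: str
    group: str = ""

    def __post_init__(self):
        dapi = np.asarray(self.dapi)
        mark = np.asarray(self.mark)
        object.__setattr__(self, "dapi", dapi)
        object.__setattr__(self, "mark", mark)
        if dapi.ndim != 2 or dapi.shape != mark.shape:
            raise ValidationError("dapi and mark must be 2-D rasters of equal shape")
        if dapi.min() < 0 or mark.min() < 0:
            raise ValidationError("intensities must be non-negative")


@dataclass(frozen=True)
class NucleusRecord:
    """One segmented nucleus: area and DAPI-normalized mark intensity."""

    nucleus_id: int
    area: int
    mean_dapi: float
    mean_mark: float
    ratio: float


@dataclass(frozen=True)
class AnimalMarkSummary:
    """Nuclei pooled across an animal's fields for one mark."""

    animal_id: str
    mark_name: str
    mean_ratio: float
    n_nuclei: int
    sd_ratio: float
    group: str = ""


@dataclass
class Segmentation:
    """Labelled nucleus mask plus traced outer contours (row, col polylines)."""

    labels: np.ndarray
    n_nuclei: int
    contours: list[np.ndarray]


# 3x3 cross (4-connected) structuring element for opening
_CROSS = ndi.generate_binary_structure(2, 1)


def segment_nuclei(
    dapi: np.ndarray,
    window: int = 61,
    open_iterations: int = 5,
    min_area: int = 50,
    offset: float = 0.0,
    border_mode: str = "reflect",
) -> Segmentation:
    """Adaptive local-mean segmentation of nuclei on the DAPI channel.

    A pixel is foreground when strictly above (its window-local mean +
    ``offset``); a tolerance of 1e-9 of the intensity scale guards the strict
    comparison against sliding-sum rounding, so a perfectly uniform image
    yields an empty mask.
    """
    img = np.asarray(dapi, dtype=float)
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if img.ndim != 2 or min(img.shape) <= window:
        raise ValidationError(
            f"raster {img.shape} must be 2-D and larger than the {window}px window"
        )
    local_mean = ndi.uniform_filter(img, size=window, mode=border_mode)
    tol = 1e-9 * max(1.0, float(np.abs(img).max()))
    mask = (img - local_mean) > (offset + tol)
    if open_iterations > 0:
        mask = ndi.binary_opening(mask, structure=_CROSS, iterations=open_iterations)

    labels = measure.label(mask, connectivity=2)
    if labels.max():
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < min_area)
        if len(small):
            labels[np.isin(labels, small)] = 0
        labels = measure.label(labels > 0, connectivity=2)

    contours = []
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        crop = np.pad(labels[r0:r1, c0:c1] == region.label, 1)
        for cont in measure.find_contours(crop.astype(float), 0.5):
            contours.append(cont + [r0 - 1, c0 - 1])
    return Segmentation(labels, int(labels.max()), contours)


def quantify_field(pair: FieldImagePair, seg: Segmentation) -> list[NucleusRecord]:
    """Per-nucleus area, mean DAPI, mean mark, and mark/DAPI ratio.

    Nuclei whose mean DAPI intensity is zero (ratio undefined) are dropped
    with a warning.
    """
    if seg.labels.shape != pair.dapi.shape:
        raise ValidationError("mask and images have different shapes")
    records = []
    index = np.arange(1, seg.n_nuclei + 1)
    if seg.n_nuclei == 0:
        return records
    areas = ndi.sum_labels(np.ones_like(seg.labels), seg.labels, index)
    mean_dapi = ndi.mean(pair.dapi.astype(float), seg.labels, index)
    mean_mark = ndi.mean(pair.mark.astype(float), seg.labels, index)
    for nid, area, md, mm in zip(index, areas, mean_dapi, mean_mark):
        if md <= 0:
            warnings.warn(
                f"nucleus {nid} in field {pair.field_id!r} has zero mean DAPI; dropped",
                stacklevel=2,
            )
            continue
        records.append(
            NucleusRecord(int(nid), int(area), float(md), float(mm), float(mm / md))
        )
    return records


def aggregate_animal(
    animal_id: str,
    mark_name: str,
    records: Sequence[NucleusRecord],
    group: str = "",
) -> AnimalMarkSummary:
    """Pool nuclei across all of an animal's fields: mean ratio, count, SD."""
    if not records:
        raise ValidationError(f"no nuclei for animal {animal_id!r}")
    ratios = np.array([r.ratio for r in records], float)
    sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0
    return AnimalMarkSummary(
        animal_id, mark_name, float(ratios.mean()), len(ratios), sd, group=group
    )


# -- file handling ------------------------------------------------------------

MANIFEST_COLUMNS = ("animal_id", "field_id", "dapi_path", "mark_path", "mark_name")


def _read_raster(path) -> np.ndarray:
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        return tifffile.imread(path)
    from imageio.v3 import imread

    return imread(path)


def read_manifest(path, group_column: str = "group") -> list[FieldImagePair]:
    """Load field image pairs listed in a manifest CSV
    (animal_id, field_id, dapi_path, mark_path, mark_name[, group]);
    relative paths resolve against the manifest's directory."""
    from pathlib import Path

    base = Path(path).parent
    df = pd.read_csv(path)
    for col in MANIFEST_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"manifest missing column {col!r}")
    pairs = []
    for r in df.itertuples():
        pairs.append(
            FieldImagePair(
                str(r.animal_id),
                str(r.field_id),
                _read_raster(base / r.dapi_path),
                _read_raster(base / r.mark_path),
                str(r.mark_name),
                group=str(getattr(r, group_column, "")),
            )
        )
    return pairs
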