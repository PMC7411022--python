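"""Field/mask I/O and per-cell pixel extraction.

The assay images fluorescently tagged ephrinA1 on a supported lipid bilayer
under each adherent cell, one grayscale field per well-of-view, together with
an integer label mask that outlines every cell (labels 1..K, background 0,
no gaps).  This module reads and writes those images losslessly, validates
the labeling convention, estimates the off-cell background, and extracts the
per-cell intensity multisets that the clustering score consumes.

Segmentation in the original assay was manual; :func:`segment_cells` is an
automated stand-in (Otsu + connected components + optional watershed) so that
synthetic fixtures can run unattended.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile
from scipy import ndimage
from skimage import feature, filters, measure, segmentation

logger = logging.getLogger(__name__)

#: default minimum cell area in pixels; smaller ROIs are dropped and logged
DEFAULT_MIN_AREA = 200


class FormatError(ValueError):
    """Raised for images that are not single-channel grayscale of a supported depth."""


class MaskValidationError(ValueError):
    """Raised when a label mask violates the 0..K no-gap labeling convention."""


@dataclass
class FluorescenceField:
    """A single grayscale fluorescence image.

    Attributes
    ----------
    pixels : 2-D non-negative array of intensities.
    bit_depth : nominal acquisition depth (8 or 16).
    pixel_size_um : physical pixel size, or None if unknown.
    """

    pixels: np.ndarray
    bit_depth: int = 16
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError(f"field must be 2-D grayscale, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("field contains non-finite intensities")
        if np.any(self.pixels < 0):
            raise ValueError("field contains negative intensities")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class LabelMask:
    """Integer cell labeling: 0 = background, cells labeled 1..K with no gaps."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise MaskValidationError("mask must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FormatError(f"mask must be integer-typed, got {self.labels.dtype}")
        present = np.unique(self.labels)
        if present.size and present[0] < 0:
            raise MaskValidationError("mask contains negative labels")
        k = int(present.max(initial=0))
        expected = np.arange(1, k + 1)
        missing = np.setdiff1d(expected, present)
        if missing.size:
            raise MaskValidationError(
                "missing label" + ("s " if missing.size > 1 else " ") + ", ".join(map(str, missing))
            )
        self.n_cells = k

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape


@dataclass
class CellRecord:
    """The intensity multiset of one outlined cell, with provenance identifiers."""

    cell_id: int
    chip_id: str
    well_id: str
    population_id: str
    intensities: np.ndarray = field(repr=False)
    area_px: int = 0
    background_estimate: float = 0.0
    touches_border: bool = False

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float).ravel()
        if self.area_px == 0:
            self.area_px = self.intensities.size


def read_field(path) -> FluorescenceField:
    """Read a grayscale 8/16-bit TIFF as a :class:`FluorescenceField`."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected single-channel grayscale TIFF, got shape {arr.shape}")
    if arr.dtype not in (np.uint8, np.uint16):
        raise FormatError(f"{path}: expected 8- or 16-bit grayscale, got dtype {arr.dtype}")
    return FluorescenceField(pixels=arr, bit_depth=8 * arr.dtype.itemsize)


def write_field(fieldobj: FluorescenceField, path) -> None:
    """Write a field to TIFF at its declared bit depth (lossless round-trip)."""
    dtype = np.uint8 if fieldobj.bit_depth == 8 else np.uint16
    px = fieldobj.pixels
    if not np.issubdtype(px.dtype, np.integer):
        px = np.rint(px)
    px = np.clip(px, 0, np.iinfo(dtype).max).astype(dtype)
    tifffile.imwrite(path, px)


def read_mask(path) -> LabelMask:
    """Read an integer label-mask TIFF, validating the no-gap labeling invariant."""
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected 2-D mask, got shape {arr.shape}")
    if not np.issubdtype(arr.dtype, np.integer):
        raise FormatError(f"{path}: mask must be integer-valued, got dtype {arr.dtype}")
    return LabelMask(labels=arr.astype(np.int32))


def write_mask(mask: LabelMask, path) -> None:
    tifffile.imwrite(path, mask.labels.astype(np.uint16))


def estimate_background(fieldobj: FluorescenceField, mask: LabelMask) -> float:
    """Median intensity over background (label-0) pixels.

    The median is robust to stray foreground bleeding into the background
    region, and an additive offset is exactly what the entropy score is
    sensitive to, so a conservative estimator matters here.
    """
    if fieldobj.shape != mask.shape:
        raise ValueError("field and mask shapes differ")
    bg = fieldobj.pixels[mask.labels == 0]
    if bg.size == 0:
        raise ValueError("mask has no background pixels; cannot estimate background")
    return float(np.median(bg))


def extract_cells(
    fieldobj: FluorescenceField,
    mask: LabelMask,
    chip_id: str = "chip0",
    well_id: str = "W0",
    population_id: str = "unknown",
    min_area: int = DEFAULT_MIN_AREA,
) -> list[CellRecord]:
    """One :class:`CellRecord` per labeled cell with area >= ``min_area``.

    Under-sized cells are dropped with a logged message.  Cells touching the
    field border are kept but flagged.
    """
    if fieldobj.shape != mask.shape:
        raise ValueError(f"field shape {fieldobj.shape} != mask shape {mask.shape}")
    background = estimate_background(fieldobj, mask) if (mask.labels == 0).any() else 0.0
    border = np.zeros(mask.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    records: list[CellRecord] = []
    for label in range(1, mask.n_cells + 1):
        sel = mask.labels == label
        area = int(sel.sum())
        if area < min_area:
            logger.info("dropping cell %d (%d px < min_area %d)", label, area, min_area)
            continue
        records.append(
            CellRecord(
                cell_id=label,
                chip_id=chip_id,
                well_id=well_id,
                population_id=population_id,
                intensities=fieldobj.pixels[sel].astype(float),
                area_px=area,
                background_estimate=background,
                touches_border=bool((sel & border).any()),
            )
        )
    return records


def segment_cells(
    fieldobj: FluorescenceField,
    bright_field: FluorescenceField | None = None,
    smoothing_sigma: float = 2.0,
    min_area: int = 64,
    split_touching: bool = False,
) -> LabelMask:
    """Automatic segmentation: smoothed Otsu threshold, hole filling, labeling.

    ``bright_field``, when given, is averaged with the fluorescence channel
    before thresholding (the manual procedure outlined cells on a composite).
    ``split_touching`` enables a distance-transform watershed.
    """
    img = fieldobj.pixels.astype(float)
    if bright_field is not None:
        img = 0.5 * (img + bright_field.pixels.astype(float))
    smooth = filters.gaussian(img, sigma=smoothing_sigma, preserve_range=True)
    if np.ptp(smooth) == 0:
        warnings.warn("blank field: no foreground found", stacklevel=2)
        return LabelMask(labels=np.zeros(fieldobj.shape, dtype=np.int32))
    thresh = filters.threshold_otsu(smooth)
    fg = ndimage.binary_fill_holes(smooth > thresh)
    if not fg.any():
        warnings.warn("empty foreground after thresholding", stacklevel=2)
        return LabelMask(labels=np.zeros(fieldobj.shape, dtype=np.int32))
    labels = measure.label(fg)
    if split_touching:
        dist = ndimage.distance_transform_edt(fg)
        peaks = feature.peak_local_max(dist, labels=labels, min_distance=15, exclude_border=False)
        markers = np.zeros(fg.shape, dtype=np.int32)
        markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
        labels = segmentation.watershed(-dist, markers, mask=fg)
    # drop specks, then compact labels to 1..K
    for region in measure.regionprops(labels):
        if region.area < min_area:
            labels[labels == region.label] = 0
    labels, _, _ = segmentation.relabel_sequential(labels)
    return LabelMask(labels=labels.astype(np.int32))
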