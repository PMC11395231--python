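"""Nucleus detection and whole-cell segmentation for multichannel fields.

Cells are found from the DAPI channel (Gaussian smoothing, Otsu threshold,
distance-transform watershed) and grown outward on the pixelwise maximum of
the CK and CD45 channels, which acts as a membrane/cytoplasm evidence map.
The segmenter is deliberately pluggable: any callable mapping an
:class:`ImageField` to an integer label image can replace
:func:`segment_field` downstream, e.g. a trained deep model.

Conventions: 0-based (row, col) coordinates, half-open bounding boxes,
label 0 is background and labels 1..K are contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import remove_small_objects
from skimage.segmentation import expand_labels, relabel_sequential, watershed

from .errors import DataError

CHANNELS: tuple[str, str, str] = ("CK", "CD45", "DAPI")

#: channel indices by name, fixed across the whole package
CK, CD45, DAPI = 0, 1, 2


@dataclass
class ImageField:
    """One imaged field of adhered PBMCs.

    pixels
        ``(H, W, 3)`` nonnegative float intensities, channels ordered
        (CK, CD45, DAPI).
    control_mask
        boolean ``(H, W)``; True inside the unstained-control region of the
        slide used to establish gating thresholds.
    provenance
        free-text sample identifier.
    """

    pixels: np.ndarray
    control_mask: np.ndarray
    provenance: str = ""
    channel_names: tuple[str, str, str] = CHANNELS

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        self.control_mask = np.asarray(self.control_mask, dtype=bool)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise DataError(f"field must be (H, W, 3), got {self.pixels.shape}")
        if self.control_mask.shape != self.pixels.shape[:2]:
            raise DataError("control_mask shape does not match field")
        if not np.isfinite(self.pixels).all():
            raise DataError("field contains non-finite intensities")
        if (self.pixels < 0).any():
            raise DataError("field contains negative intensities")

    @property
    def membrane_projection(self) -> np.ndarray:
        """Pixelwise max of CK and CD45, the whole-cell evidence map."""
        return np.maximum(self.pixels[..., CK], self.pixels[..., CD45])


@dataclass
class CellRecord:
    """Per-cell measurements extracted from a label mask."""

    cell_id: int
    centroid: tuple[float, float]
    bbox: tuple[int, int, int, int]
    area_px: int
    mean_intensity: dict[str, float] = field(default_factory=dict)
    is_control: bool = False
    touches_border: bool = False


def segment_nuclei(
    dapi: np.ndarray,
    min_area: int = 20,
    smoothing_sigma: float = 1.5,
    peak_min_distance: int = 5,
) -> np.ndarray:
    """Label nuclei in a DAPI image.

    Pipeline: Gaussian smoothing -> Otsu threshold -> hole filling ->
    removal of sub-``min_area`` debris -> distance transform -> peak
    seeding -> watershed. Returns an int32 label image with contiguous
    labels 1..K; an all-zero image yields zero labels.
    """
    dapi = np.asarray(dapi, dtype=np.float64)
    if dapi.ndim != 2:
        raise DataError("dapi must be a 2-D image")
    if not np.isfinite(dapi).all():
        raise DataError("dapi contains non-finite pixels")
    if np.ptp(dapi) == 0:
        return np.zeros(dapi.shape, dtype=np.int32)

    smoothed = gaussian(dapi, sigma=smoothing_sigma, preserve_range=True)
    mask = smoothed > threshold_otsu(smoothed)
    mask = ndi.binary_fill_holes(mask)
    mask = remove_small_objects(mask, max_size=min_area - 1)
    if not mask.any():
        return np.zeros(dapi.shape, dtype=np.int32)

    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=peak_min_distance, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    # enumeration order of peaks fixes watershed tie-breaking deterministically
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-distance, markers, mask=mask)

    # watershed can split a component into fragments below min_area; drop them
    sizes = np.bincount(labels.ravel())
    small = np.flatnonzero(sizes < min_area)
    labels[np.isin(labels, small[small > 0])] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def expand_to_cells(
    nuclei_labels: np.ndarray,
    membrane_projection: np.ndarray,
    max_expand_px: int = 8,
    membrane_threshold: float | None = None,
) -> np.ndarray:
    """Grow nucleus labels into whole-cell labels.

    Expansion is limited to ``max_expand_px`` beyond the nucleus and to
    pixels above the membrane background.  ``membrane_threshold`` sets
    that background level explicitly (e.g. referenced to the unstained
    control region); when None it falls back to Otsu on the projection.
    Every nucleus keeps its own label, so cells stay pairwise disjoint.
    With no membrane signal anywhere, cell labels equal nucleus labels.
    """
    nuclei_labels = np.asarray(nuclei_labels)
    membrane_projection = np.asarray(membrane_projection, dtype=np.float64)
    if membrane_projection.shape != nuclei_labels.shape:
        raise DataError("membrane projection shape does not match nuclei labels")

    if membrane_threshold is not None:
        foreground = membrane_projection > membrane_threshold
    elif np.ptp(membrane_projection) == 0:
        foreground = np.zeros(nuclei_labels.shape, dtype=bool)
    else:
        foreground = membrane_projection > threshold_otsu(membrane_projection)

    expanded = expand_labels(nuclei_labels, distance=max_expand_px)
    keep = foreground | (nuclei_labels > 0)
    cells = np.where(keep, expanded, 0)
    return cells.astype(np.int32)


def extract_cell_records(field: ImageField, cell_labels: np.ndarray) -> list[CellRecord]:
    """One :class:`CellRecord` per label, with per-channel mean intensities.

    ``is_control`` is set from membership of the (rounded) centroid in the
    field's control mask; border-touching cells are kept but flagged.
    """
    cell_labels = np.asarray(cell_labels)
    if cell_labels.shape != field.pixels.shape[:2]:
        raise DataError("cell labels shape does not match field")
    h, w = cell_labels.shape
    records: list[CellRecord] = []
    for prop in regionprops(cell_labels, intensity_image=field.pixels):
        r0, c0, r1, c1 = prop.bbox
        cr, cc = prop.centroid
        means = prop.intensity_mean  # (3,) channel means over the mask
        ir = min(h - 1, max(0, int(round(cr))))
        ic = min(w - 1, max(0, int(round(cc))))
        records.append(
            CellRecord(
                cell_id=int(prop.label),
                centroid=(float(cr), float(cc)),
                bbox=(int(r0), int(c0), int(r1), int(c1)),
                area_px=int(prop.area),
                mean_intensity={
                    name: float(means[i]) for i, name in enumerate(field.channel_names)
                },
                is_control=bool(field.control_mask[ir, ic]),
                touches_border=bool(r0 == 0 or c0 == 0 or r1 == h or c1 == w),
            )
        )
    return records


def segment_field(
    field: ImageField,
    min_area: int = 20,
    smoothing_sigma: float = 1.5,
    max_expand_px: int = 8,
    background_percentile: float = 99.9,
) -> tuple[np.ndarray, list[CellRecord]]:
    """Convenience wrapper: DAPI nuclei -> whole cells -> records.

    When the field carries an unstained-control region, the membrane
    background level for cell expansion is taken from it (a high
    percentile of control-region membrane pixels), so dim cells keep
    their cytoplasm instead of being cut back to the nucleus by a
    brightness-dominated global threshold.
    """
    nuclei = segment_nuclei(
        field.pixels[..., DAPI], min_area=min_area, smoothing_sigma=smoothing_sigma
    )
    membrane = field.membrane_projection
    threshold = None
    if field.control_mask.any():
        threshold = float(np.percentile(membrane[field.control_mask], background_percentile))
    cells = expand_to_cells(
        nuclei, membrane, max_expand_px=max_expand_px, membrane_threshold=threshold
    )
    return cells, extract_cell_records(field, cells)


def records_to_frame(records: Sequence[CellRecord]):
    """Cell records as a tidy DataFrame (one row per cell)."""
    rows = []
    for rec in records:
        rows.append(
            {
                "cell_id": rec.cell_id,
                "centroid_row": rec.centroid[0],
                "centroid_col": rec.centroid[1],
                "bbox_r0": rec.bbox[0],
                "bbox_c0": rec.bbox[1],
                "bbox_r1": rec.bbox[2],
                "bbox_c1": rec.bbox[3],
                "area_px": rec.area_px,
                "mean_ck": rec.mean_intensity.get("CK", np.nan),
                "mean_cd45": rec.mean_intensity.get("CD45", np.nan),
                "mean_dapi": rec.mean_intensity.get("DAPI", np.nan),
                "is_control": rec.is_control,
                "touches_border": rec.touches_border,
            }
        )
    import pandas as pd

    return pd.DataFrame(
        rows,
        columns=[
            "cell_id",
            "centroid_row",
            "centroid_col",
            "bbox_r0",
            "bbox_c0",
            "bbox_r1",
            "bbox_c1",
            "area_px",
            "mean_ck",
            "mean_cd45",
            "mean_dapi",
            "is_control",
            "touches_border",
        ],
    )


def frame_to_records(df) -> list[CellRecord]:
    """Inverse of :func:`records_to_frame`."""
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CellRecord(
                cell_id=int(row.cell_id),
                centroid=(float(row.centroid_row), float(row.centroid_col)),
                bbox=(int(row.bbox_r0), int(row.bbox_c0), int(row.bbox_r1), int(row.bbox_c1)),
                area_px=int(row.area_px),
                mean_intensity={
                    "CK": float(row.mean_ck),
                    "CD45": float(row.mean_cd45),
                    "DAPI": float(row.mean_dapi),
                },
                is_control=bool(row.is_control),
                touches_border=bool(row.touches_border),
            )
        )
    return records
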