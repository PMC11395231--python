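"""Cell-crop extraction, padding and per-sample median normalization.

Each detected hybrid cell is cut from its field as a fixed-size
``(64, 64, 3)`` tensor centered on the cell centroid, zero-padded where the
window leaves the field.  Before training, every channel of a crop is
divided by the median per-cell mean intensity of that channel within the
crop's source sample, which cancels sample-to-sample staining and
illumination differences (a crop from a 2x-brighter replicate normalizes
to the same tensor).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ..errors import DataError
from ..segment import CHANNELS, CellRecord, ImageField

CROP_SIZE = 64

#: floor for normalization divisors, keeps division finite for empty channels
MEDIAN_EPS = 1e-6

PHASES = ("responsive", "resistant", "unknown")


@dataclass
class Crop:
    """A ``(64, 64, 3)`` cell image with provenance and phase annotation."""

    tensor: np.ndarray
    provenance: tuple[str, int]  # (sample_id, cell_id)
    phase: str = "unknown"
    punctate: bool = False

    def __post_init__(self) -> None:
        self.tensor = np.asarray(self.tensor, dtype=np.float32)
        if self.tensor.shape != (CROP_SIZE, CROP_SIZE, 3):
            raise DataError(f"crop must be (64, 64, 3), got {self.tensor.shape}")
        if not np.isfinite(self.tensor).all():
            raise DataError("crop contains non-finite values")
        if (self.tensor < 0).any():
            raise DataError("crop contains negative values")
        if self.phase not in PHASES:
            raise DataError(f"unknown phase {self.phase!r}")


def crop_and_pad(field: ImageField, record: CellRecord) -> Crop:
    """Cut a 64x64 window around the cell centroid, zero-padding outside.

    Cells larger than the window are center-cropped; cells at the field
    border produce zero-filled out-of-field quadrants.
    """
    h, w = field.pixels.shape[:2]
    cr, cc = record.centroid
    if not (0 <= cr < h and 0 <= cc < w):
        raise DataError(f"centroid {record.centroid} outside field ({h}, {w})")
    r0 = int(round(cr)) - CROP_SIZE // 2
    c0 = int(round(cc)) - CROP_SIZE // 2
    out = np.zeros((CROP_SIZE, CROP_SIZE, 3), dtype=np.float32)
    src_r0, src_r1 = max(r0, 0), min(r0 + CROP_SIZE, h)
    src_c0, src_c1 = max(c0, 0), min(c0 + CROP_SIZE, w)
    out[src_r0 - r0 : src_r1 - r0, src_c0 - c0 : src_c1 - c0] = field.pixels[
        src_r0:src_r1, src_c0:src_c1
    ]
    return Crop(tensor=out, provenance=(field.provenance, record.cell_id))


def channel_medians(records: Sequence[CellRecord]) -> np.ndarray:
    """Median per-cell mean intensity per channel over non-control cells."""
    cells = [r for r in records if not r.is_control]
    if not cells:
        raise DataError("no non-control cells to compute sample medians")
    values = np.array(
        [[r.mean_intensity[ch] for ch in CHANNELS] for r in cells], dtype=np.float64
    )
    return np.median(values, axis=0)


def _medians_from_crops(crops: Sequence[Crop]) -> dict[str, np.ndarray]:
    """Per-sample median of crop channel means, for record-less crop sets."""
    by_sample: dict[str, list[np.ndarray]] = {}
    for crop in crops:
        by_sample.setdefault(crop.provenance[0], []).append(crop.tensor.mean(axis=(0, 1)))
    return {sid: np.median(np.stack(vals), axis=0) for sid, vals in by_sample.items()}


def normalize_crops(
    crops: Sequence[Crop],
    sample_cell_records: Mapping[str, Sequence[CellRecord]]
    | Sequence[CellRecord]
    | None = None,
) -> list[Crop]:
    """Divide each crop channel by its sample's median channel intensity.

    ``sample_cell_records`` maps sample id to that sample's segmented cell
    records; a flat record list is accepted when all crops share one
    sample, and ``None`` falls back to medians of the crops' own channel
    means (for standalone crop sets without segmentation records).
    Divisors are floored at a small epsilon.
    """
    if sample_cell_records is None:
        raw_medians = _medians_from_crops(crops)
    else:
        if not isinstance(sample_cell_records, Mapping):
            sample_cell_records = {
                crop.provenance[0]: sample_cell_records for crop in crops
            }
        raw_medians = {
            sid: channel_medians(records)
            for sid, records in sample_cell_records.items()
        }
    medians = {sid: np.maximum(m, MEDIAN_EPS) for sid, m in raw_medians.items()}
    out = []
    for crop in crops:
        sid = crop.provenance[0]
        if sid not in medians:
            raise DataError(f"no cell records for sample {sid!r}")
        out.append(
            Crop(
                tensor=crop.tensor / medians[sid].astype(np.float32),
                provenance=crop.provenance,
                phase=crop.phase,
                punctate=crop.punctate,
            )
        )
    return out


def estimate_area_px(crop: Crop, floor: float = 0.0) -> int:
    """Foreground-pixel count of a standalone crop.

    Used for the feature table when no segmentation record accompanies the
    crop: a pixel is foreground when its max-channel intensity clears half
    the Otsu threshold of the max projection (or ``floor`` if larger).
    """
    from skimage.filters import threshold_otsu

    proj = crop.tensor.max(axis=2)
    if np.ptp(proj) == 0:
        return 0
    thr = max(float(threshold_otsu(proj)), floor)
    return int((proj > thr).sum())


def crops_to_array(crops: Sequence[Crop]) -> np.ndarray:
    """Stack crops into an ``(n, 64, 64, 3)`` float32 batch tensor."""
    if not crops:
        raise DataError("empty crop list")
    return np.stack([c.tensor for c in crops]).astype(np.float32)
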