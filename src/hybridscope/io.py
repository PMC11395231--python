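"""File dialects shared across pipeline stages.

* Fields: multi-page TIFF (one page per channel, order CK/CD45/DAPI) plus
  a JSON sidecar with channel order, control-region bounding box and — for
  synthetic fields — the planted ground truth.
* Cell records / calls: CSV, one row per cell.
* Enumerations: CSV, one row per sample, shared by the synthetic cohort
  generator and the gating stage so real and simulated data interchange.
  Normalized counts are rounded to 2 decimals at this boundary only.
* Crops: directory of 3-page TIFFs plus an index CSV with provenance and
  phase; embeddings as CSV; training history as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import DataError
from .gate import SampleEnumeration
from .cohort import SubjectTimeline
from .latent.crops import Crop
from .latent.vae import EmbeddingSet
from .segment import CHANNELS, ImageField
from .simgen import GroundTruth, GroundTruthEntry

ENUM_COLUMNS = [
    "subject_id",
    "cohort",
    "sample_id",
    "sample_index",
    "days_from_treatment_start",
    "raw_chc",
    "raw_ctc",
    "total_pbmcs",
    "chc_per_50k",
    "ctc_per_50k",
    "treatment_start",
    "trial_end",
    "regime",
    "event",
]


def _mask_bbox(mask: np.ndarray) -> list[int] | None:
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return None
    return [int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1]


def write_field(field: ImageField, path: str | Path, ground_truth: GroundTruth | None = None) -> Path:
    """Write a field as channel-paged TIFF + JSON sidecar; returns TIFF path."""
    path = Path(path)
    pages = np.moveaxis(field.pixels, -1, 0)  # (3, H, W)
    tifffile.imwrite(path, pages.astype(np.float32), photometric="minisblack")
    sidecar = {
        "channel_order": list(field.channel_names),
        "provenance": field.provenance,
        "control_bbox": _mask_bbox(field.control_mask),
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = {
            "entries": [dataclasses.asdict(e) for e in ground_truth.entries],
            "control_entries": [
                dataclasses.asdict(e) for e in ground_truth.control_entries
            ],
        }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_field(path: str | Path) -> tuple[ImageField, GroundTruth | None]:
    """Read a field written by :func:`write_field`."""
    path = Path(path)
    pages = tifffile.imread(path)
    if pages.ndim != 3 or pages.shape[0] != 3:
        raise DataError(f"expected a 3-page field TIFF, got shape {pages.shape}")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    if tuple(sidecar["channel_order"]) != CHANNELS:
        raise DataError(f"unexpected channel order {sidecar['channel_order']}")
    pixels = np.moveaxis(pages, 0, -1)
    control_mask = np.zeros(pixels.shape[:2], dtype=bool)
    bbox = sidecar.get("control_bbox")
    if bbox is not None:
        r0, c0, r1, c1 = bbox
        control_mask[r0:r1, c0:c1] = True
    field = ImageField(
        pixels=pixels, control_mask=control_mask, provenance=sidecar.get("provenance", "")
    )
    gt = None
    if "ground_truth" in sidecar:
        gt = GroundTruth(
            entries=[GroundTruthEntry(**e) for e in sidecar["ground_truth"]["entries"]],
            control_entries=[
                GroundTruthEntry(**e)
                for e in sidecar["ground_truth"]["control_entries"]
            ],
        )
    return field, gt


def write_mask(labels: np.ndarray, path: str | Path) -> Path:
    """Label mask as 16-bit single-page TIFF."""
    path = Path(path)
    if labels.max() >= 2**16:
        raise DataError("more than 65535 labels; 16-bit mask overflow")
    tifffile.imwrite(path, labels.astype(np.uint16))
    return path


def timelines_to_frame(timelines: Sequence[SubjectTimeline]) -> pd.DataFrame:
    rows = []
    for t in timelines:
        for i, s in enumerate(t.samples):
            rows.append(
                {
                    "subject_id": t.subject_id,
                    "cohort": t.cohort,
                    "sample_id": s.sample_id,
                    "sample_index": i,
                    "days_from_treatment_start": s.days_from_treatment_start,
                    "raw_chc": s.raw_counts.get("CHC", 0),
                    "raw_ctc": s.raw_counts.get("CTC", 0),
                    "total_pbmcs": s.total_pbmcs,
                    "chc_per_50k": round(s.chc_per_50k, 2),
                    "ctc_per_50k": round(s.ctc_per_50k, 2),
                    "treatment_start": t.treatment_start,
                    "trial_end": t.trial_end if t.trial_end is not None else "",
                    "regime": t.regime or "",
                    "event": s.event,
                }
            )
    return pd.DataFrame(rows, columns=ENUM_COLUMNS)


def write_enumerations(timelines: Sequence[SubjectTimeline], path: str | Path) -> Path:
    path = Path(path)
    timelines_to_frame(timelines).to_csv(path, index=False)
    return path


def read_enumerations(path: str | Path) -> list[SubjectTimeline]:
    """Rebuild subject timelines from the shared enumeration CSV.

    Raw counts and PBMC totals are authoritative; normalized counts are
    recomputed at full precision rather than trusted from the rounded
    file values.
    """
    df = pd.read_csv(Path(path), keep_default_na=False)
    timelines = []
    for (subject_id, cohort), group in df.groupby(["subject_id", "cohort"], sort=False):
        group = group.sort_values("sample_index")
        samples = []
        for row in group.itertuples(index=False):
            raw_chc = int(row.raw_chc)
            raw_ctc = int(row.raw_ctc)
            total = int(row.total_pbmcs)
            samples.append(
                SampleEnumeration(
                    sample_id=str(row.sample_id),
                    subject_id=str(subject_id),
                    days_from_treatment_start=float(row.days_from_treatment_start),
                    raw_counts={
                        "CHC": raw_chc,
                        "CTC": raw_ctc,
                        "leukocyte": max(0, total - raw_chc - raw_ctc),
                        "negative": 0,
                    },
                    total_pbmcs=total,
                    event=str(row.event),
                )
            )
        first = group.iloc[0]
        trial_end = first["trial_end"]
        timelines.append(
            SubjectTimeline(
                subject_id=str(subject_id),
                cohort=str(cohort),
                samples=samples,
                treatment_start=float(first["treatment_start"]),
                trial_end=float(trial_end) if trial_end != "" else None,
                regime=str(first["regime"]) or None,
            )
        )
    return timelines


def write_crops(crops: Sequence[Crop], directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, crop in enumerate(crops):
        name = f"crop_{i:05d}.tiff"
        tifffile.imwrite(
            directory / name, np.moveaxis(crop.tensor, -1, 0), photometric="minisblack"
        )
        rows.append(
            {
                "file": name,
                "sample_id": crop.provenance[0],
                "cell_id": crop.provenance[1],
                "phase": crop.phase,
                "punctate": crop.punctate,
            }
        )
    pd.DataFrame(rows).to_csv(directory / "index.csv", index=False)
    return directory


def read_crops(directory: str | Path) -> list[Crop]:
    directory = Path(directory)
    index = pd.read_csv(directory / "index.csv", keep_default_na=False)
    crops = []
    for row in index.itertuples(index=False):
        pages = tifffile.imread(directory / row.file)
        crops.append(
            Crop(
                tensor=np.moveaxis(pages, 0, -1),
                provenance=(str(row.sample_id), int(row.cell_id)),
                phase=str(row.phase),
                punctate=bool(row.punctate),
            )
        )
    return crops


def write_embeddings(eset: EmbeddingSet, path: str | Path) -> Path:
    path = Path(path)
    n, d = eset.matrix.shape
    df = pd.DataFrame(eset.matrix, columns=[f"z{i:02d}" for i in range(d)])
    df.insert(0, "sample_id", [p[0] for p in eset.provenance])
    df.insert(1, "cell_id", [p[1] for p in eset.provenance])
    df.insert(2, "phase", eset.labels)
    if eset.umap_coords is not None:
        df["umap_0"] = eset.umap_coords[:, 0]
        df["umap_1"] = eset.umap_coords[:, 1]
    df.to_csv(path, index=False)
    return path


def write_history(history: list[dict], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(history, indent=1))
    return path
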