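"""Marker gating and per-sample enumeration.

Positivity thresholds for CK and CD45 are taken from the unstained control
cells imaged on the same slide: the threshold for a channel is a high
percentile (default 99.5) of the control cells' per-cell mean intensities
on that channel.  Each non-control cell is then called by strict
thresholding:

    CK+/CD45+  -> CHC   (circulating hybrid cell)
    CK+/CD45-  -> CTC   (circulating tumor cell)
    CK-/CD45+  -> leukocyte
    CK-/CD45-  -> negative

Counts are reported normalized to 50,000 total PBMCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigError, DataError
from .segment import CellRecord

LABELS = ("CHC", "CTC", "leukocyte", "negative")

#: reporting denominator, cells
PBMC_DENOMINATOR = 50_000

#: fewest control cells accepted for threshold estimation
MIN_CONTROL_CELLS = 30


@dataclass
class GatingThresholds:
    """Per-channel positivity cutoffs derived from unstained controls."""

    threshold: dict[str, float]
    percentile_used: float
    n_control_cells: int


@dataclass
class CellCall:
    cell_id: int
    label: str


@dataclass
class SampleEnumeration:
    """Raw and per-50,000-PBMC-normalized counts for one blood sample."""

    sample_id: str
    subject_id: str
    days_from_treatment_start: float
    raw_counts: dict[str, int]
    total_pbmcs: int
    normalized: dict[str, float] = field(default_factory=dict)
    event: str = ""

    def __post_init__(self) -> None:
        if self.total_pbmcs <= 0:
            raise DataError("total_pbmcs must be positive")
        if not self.normalized:
            self.normalized = {
                label: normalize_per_50k(count, self.total_pbmcs)
                for label, count in self.raw_counts.items()
            }

    @property
    def chc_per_50k(self) -> float:
        return self.normalized.get("CHC", 0.0)

    @property
    def ctc_per_50k(self) -> float:
        return self.normalized.get("CTC", 0.0)


def establish_thresholds(
    control_records: Sequence[CellRecord],
    percentile: float = 99.5,
    min_control_cells: int = MIN_CONTROL_CELLS,
    channels: Sequence[str] = ("CK", "CD45"),
) -> GatingThresholds:
    """Percentile of control-cell mean intensities, per channel.

    The percentile interpolates the empirical CDF linearly (numpy's
    ``interpolated_inverted_cdf`` convention), so control intensities
    1..100 at percentile 99.5 give a threshold of exactly 99.5.
    """
    if not 50 < percentile < 100:
        raise ConfigError("percentile must lie in (50, 100)")
    if any(not rec.is_control for rec in control_records):
        raise DataError("establish_thresholds received a non-control cell")
    n = len(control_records)
    if n < min_control_cells:
        raise DataError(
            f"need at least {min_control_cells} control cells, got {n}"
        )
    thresholds = {}
    for channel in channels:
        values = np.array([rec.mean_intensity[channel] for rec in control_records])
        thresholds[channel] = float(
            np.percentile(values, percentile, method="interpolated_inverted_cdf")
        )
    return GatingThresholds(
        threshold=thresholds, percentile_used=percentile, n_control_cells=n
    )


def classify_cells(
    records: Iterable[CellRecord], thresholds: GatingThresholds
) -> list[CellCall]:
    """Call every non-control cell; positivity is strict (mean > threshold)."""
    t_ck = thresholds.threshold["CK"]
    t_cd45 = thresholds.threshold["CD45"]
    calls = []
    for rec in records:
        if rec.is_control:
            continue
        ck_pos = rec.mean_intensity["CK"] > t_ck
        cd45_pos = rec.mean_intensity["CD45"] > t_cd45
        if ck_pos and cd45_pos:
            label = "CHC"
        elif ck_pos:
            label = "CTC"
        elif cd45_pos:
            label = "leukocyte"
        else:
            label = "negative"
        calls.append(CellCall(cell_id=rec.cell_id, label=label))
    return calls


def normalize_per_50k(raw_count: int, total_pbmcs: int) -> float:
    """Scale a raw count to the per-50,000-PBMC reporting unit.

    Full precision is kept internally; rounding to 2 decimals happens only
    at I/O boundaries (e.g. 1 cell in 30,000 PBMCs prints as 1.67).
    """
    if total_pbmcs <= 0:
        raise DataError("total_pbmcs must be positive")
    if raw_count < 0:
        raise DataError("raw_count must be nonnegative")
    return raw_count * PBMC_DENOMINATOR / total_pbmcs


def enumerate_sample(
    calls: Sequence[CellCall],
    metadata: Mapping[str, object],
    total_pbmcs: int,
) -> SampleEnumeration:
    """Tally calls for one sample into raw and normalized counts.

    ``metadata`` must provide ``sample_id``, ``subject_id`` and
    ``days_from_treatment_start``.  Raw counts over all labels sum to the
    number of calls (every non-control cell is counted exactly once).
    """
    ids = [c.cell_id for c in calls]
    if len(ids) != len(set(ids)):
        raise DataError("duplicate cell_id in calls")
    raw = {label: 0 for label in LABELS}
    for call in calls:
        raw[call.label] += 1
    return SampleEnumeration(
        sample_id=str(metadata["sample_id"]),
        subject_id=str(metadata["subject_id"]),
        days_from_treatment_start=float(metadata["days_from_treatment_start"]),
        raw_counts=raw,
        total_pbmcs=int(total_pbmcs),
        event=str(metadata.get("event", "")),
    )
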