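"""Synthetic immunofluorescence fields, cell crops and longitudinal cohorts.

This module generates data with the statistical structure the downstream
analysis assumes, so the whole pipeline is testable end to end without any
patient material:

* **Fields** — multichannel (CK, CD45, DAPI) images of adhered PBMCs with
  an unstained-control strip, planted leukocytes (CD45+), hybrid cells
  (CK+/CD45+) and tumor cells (CK+/CD45-), and a full ground-truth
  listing.  Cells are rendered as isotropic Gaussian disks (nucleus on
  DAPI, cytoplasm on the marker channels at 1.6x the nuclear radius) over
  additive, zero-clipped Gaussian noise.
* **Crops** — standalone 64x64x3 cell images in two phenotypes:
  treatment-responsive (CD45 high, CK low) and treatment-resistant
  (CK high, CD45 low, optionally as a punctate CK pattern of 3-6 discrete
  puncta instead of a diffuse disk).
* **Cohorts** — per-subject count trajectories: patient baselines of
  7.6-15.5 hybrid cells per 50,000 PBMCs falling to exactly zero within
  two post-treatment samples, regime-specific rebounds of 2.0-49.6 cells,
  healthy subjects at 0-1.67, and zero tumor cells throughout.

All randomness flows from the single seed in each config; identical
configs give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .cohort import REGIMES, SubjectTimeline
from .errors import ConfigError, PlacementError
from .gate import SampleEnumeration
from .latent.crops import CROP_SIZE, Crop
from .segment import CHANNELS, ImageField

CLASSES = ("leukocyte", "CHC", "CTC")

#: per-class per-channel Gaussian peak amplitudes (arbitrary units)
DEFAULT_AMPLITUDES: dict[str, dict[str, float]] = {
    "leukocyte": {"CK": 0.0, "CD45": 120.0, "DAPI": 150.0},
    "CHC": {"CK": 110.0, "CD45": 120.0, "DAPI": 150.0},
    "CTC": {"CK": 110.0, "CD45": 0.0, "DAPI": 150.0},
    "control": {"CK": 0.0, "CD45": 0.0, "DAPI": 150.0},
}

#: cytoplasm radius as a multiple of the nuclear radius
CYTOPLASM_FACTOR = 1.6

#: multiplicative per-cell amplitude jitter bounds
JITTER = (0.85, 1.15)

PLACEMENT_RETRIES = 100


@dataclass
class FieldConfig:
    """Geometry and intensity settings for one synthetic field."""

    height_px: int = 512
    width_px: int = 512
    n_leukocytes: int = 60
    n_chc: int = 3
    n_ctc: int = 0
    # a threshold percentile this high needs a sizeable control sample to
    # be a stable quantile rather than a noisy sample maximum
    n_control_cells: int = 100
    cell_radius_px: tuple[float, float] = (5.0, 8.0)
    amplitude_means: dict[str, dict[str, float]] | None = None
    noise_sd: float = 4.0
    punctate_fraction: float = 0.0
    seed: int = 0
    control_strip_px: int | None = None  # default: width // 4

    def __post_init__(self) -> None:
        if self.amplitude_means is None:
            self.amplitude_means = DEFAULT_AMPLITUDES
        self.validate()

    def validate(self) -> None:
        if min(self.n_leukocytes, self.n_chc, self.n_ctc, self.n_control_cells) < 0:
            raise ConfigError("cell counts must be nonnegative")
        if self.height_px < 64 or self.width_px < 64:
            raise ConfigError("field must be at least 64x64")
        lo, hi = self.cell_radius_px
        if not 0 < lo <= hi:
            raise ConfigError("cell_radius_px must satisfy 0 < min <= max")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be nonnegative")
        if not 0 <= self.punctate_fraction <= 1:
            raise ConfigError("punctate_fraction must lie in [0, 1]")
        # separability guarantee: positive-marker amplitude clears the
        # noise floor by more than five standard deviations
        floor = 5.0 * self.noise_sd
        for cls, amps in self.amplitude_means.items():
            for ch in ("CK", "CD45"):
                amp = amps.get(ch, 0.0)
                if 0 < amp <= floor:
                    raise ConfigError(
                        f"{cls}/{ch} amplitude {amp} does not exceed "
                        f"background + 5*noise_sd = {floor}"
                    )

    @property
    def strip_px(self) -> int:
        """Width of the unstained-control strip.

        Defaults to the width needed to hold ``n_control_cells`` at
        conservative spacing, clamped to [64, width/2].
        """
        if self.control_strip_px:
            return self.control_strip_px
        rmax = self.cell_radius_px[1]
        spacing = 2 * CYTOPLASM_FACTOR * rmax
        margin = CYTOPLASM_FACTOR * rmax
        rows = max(1, int((self.height_px - 2 * margin) // spacing))
        cols = math.ceil(max(1, self.n_control_cells) / rows)
        need = int(math.ceil(cols * spacing + 2 * margin))
        return min(self.width_px // 2, max(64, need))


@dataclass
class GroundTruthEntry:
    cell_id: int
    cls: str  # leukocyte | CHC | CTC | negative
    centroid_row: float
    centroid_col: float
    radius_px: float
    amplitude: dict[str, float] = dc_field(default_factory=dict)
    punctate: bool = False


@dataclass
class GroundTruth:
    """Planted cells of one synthetic field.

    ``entries`` lists the stained cells in the analysis region;
    ``control_entries`` the unstained cells in the control strip.
    """

    entries: list[GroundTruthEntry]
    control_entries: list[GroundTruthEntry] = dc_field(default_factory=list)

    def class_counts(self) -> dict[str, int]:
        counts = {cls: 0 for cls in CLASSES}
        for e in self.entries:
            counts[e.cls] = counts.get(e.cls, 0) + 1
        return counts


def _add_gaussian(
    img: np.ndarray, row: float, col: float, sigma: float, amplitude: float
) -> None:
    """Accumulate an isotropic Gaussian blob into ``img`` (local window only)."""
    h, w = img.shape
    half = int(math.ceil(4 * sigma))
    r0, r1 = max(0, int(row) - half), min(h, int(row) + half + 1)
    c0, c1 = max(0, int(col) - half), min(w, int(col) + half + 1)
    if r0 >= r1 or c0 >= c1:
        return
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    img[r0:r1, c0:c1] += amplitude * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))


def _place_cells(
    rng: np.random.Generator,
    n: int,
    bounds: tuple[float, float, float, float],
    radii: np.ndarray,
    exclusion_factor: float,
    occupied: list[tuple[float, float, float]],
) -> list[tuple[float, float]]:
    """Rejection-sample non-overlapping centers inside ``bounds``.

    ``occupied`` holds (row, col, exclusion_radius) of already-placed
    cells and is extended in place.  Raises PlacementError after
    PLACEMENT_RETRIES failed draws for a single cell.
    """
    r0, c0, r1, c1 = bounds
    centers = []
    for i in range(n):
        excl = exclusion_factor * radii[i]
        lo_r, hi_r = r0 + excl, r1 - excl
        lo_c, hi_c = c0 + excl, c1 - excl
        if lo_r >= hi_r or lo_c >= hi_c:
            raise PlacementError("field region too small for requested cell radius")
        for _ in range(PLACEMENT_RETRIES):
            row = rng.uniform(lo_r, hi_r)
            col = rng.uniform(lo_c, hi_c)
            if all(
                (row - orow) ** 2 + (col - ocol) ** 2 >= (excl + oexcl) ** 2
                for orow, ocol, oexcl in occupied
            ):
                occupied.append((row, col, excl))
                centers.append((row, col))
                break
        else:
            raise PlacementError(
                f"could not place cell {i + 1}/{n} after {PLACEMENT_RETRIES} retries; "
                "enlarge the field or reduce cell counts"
            )
    return centers


def _render_puncta(
    rng: np.random.Generator,
    img: np.ndarray,
    row: float,
    col: float,
    cyto_radius: float,
    amplitude: float,
    n_puncta: int | None = None,
    sigma: float = 2.5,
    min_sep: float = 9.0,
) -> None:
    """Render CK as 3-6 discrete puncta inside the cytoplasm disk."""
    k = int(n_puncta if n_puncta is not None else rng.integers(3, 7))
    reach = max(cyto_radius * 0.9, min_sep * 0.75)
    placed: list[tuple[float, float]] = []
    for _ in range(k):
        for _ in range(200):
            ang = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(0.15, 1.0) * reach
            pr, pc = row + rad * math.sin(ang), col + rad * math.cos(ang)
            if all((pr - a) ** 2 + (pc - b) ** 2 >= min_sep**2 for a, b in placed):
                placed.append((pr, pc))
                break
        else:  # fall back to an evenly spaced ring position
            ang = 2 * math.pi * len(placed) / k
            placed.append((row + reach * math.sin(ang), col + reach * math.cos(ang)))
    for pr, pc in placed:
        _add_gaussian(img, pr, pc, sigma, amplitude * rng.uniform(0.9, 1.1))


def generate_field(config: FieldConfig) -> tuple[ImageField, GroundTruth]:
    """Render one synthetic field and its ground truth.

    The left strip of the field is the unstained-control region holding
    ``n_control_cells`` DAPI-only cells; stained cells are planted to its
    right with pairwise-disjoint footprints (rejection sampling).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.height_px, config.width_px
    pixels = np.zeros((h, w, 3), dtype=np.float64)
    strip = config.strip_px
    control_mask = np.zeros((h, w), dtype=bool)
    control_mask[:, :strip] = True

    lo_r, hi_r = config.cell_radius_px
    occupied: list[tuple[float, float, float]] = []

    # unstained controls: nucleus only, small exclusion footprint
    # nucleus-only footprints: 1.3x radius spacing keeps nuclei resolvable
    ctrl_radii = rng.uniform(lo_r, hi_r, size=config.n_control_cells)
    ctrl_centers = _place_cells(
        rng, config.n_control_cells, (0, 0, h, strip), ctrl_radii, 1.3, occupied
    )

    classes = (
        ["CHC"] * config.n_chc + ["CTC"] * config.n_ctc + ["leukocyte"] * config.n_leukocytes
    )
    radii = rng.uniform(lo_r, hi_r, size=len(classes))
    # exclusion at 2.6x the nuclear radius (~1.6x the cytoplasm radius)
    # keeps neighboring nuclei far beyond the watershed's resolving power
    # while leaving room for realistic cell densities
    centers = _place_cells(
        rng,
        len(classes),
        (0, strip + 4, h, w),
        radii,
        2.6,
        occupied,
    )

    entries: list[GroundTruthEntry] = []
    cell_id = 0
    for (row, col), radius, cls in zip(centers, radii, classes):
        cell_id += 1
        amps = config.amplitude_means[cls]
        realized = {}
        punctate = bool(cls == "CHC" and rng.uniform() < config.punctate_fraction)
        sigma_n = radius / 2.0
        sigma_c = CYTOPLASM_FACTOR * sigma_n
        for ci, ch in enumerate(CHANNELS):
            base = amps.get(ch, 0.0)
            if base <= 0:
                realized[ch] = 0.0
                continue
            amp = base * rng.uniform(*JITTER)
            realized[ch] = amp
            if ch == "DAPI":
                _add_gaussian(pixels[..., ci], row, col, sigma_n, amp)
            elif ch == "CK" and punctate:
                _render_puncta(
                    rng, pixels[..., ci], row, col, CYTOPLASM_FACTOR * radius, amp * 1.8
                )
            else:
                _add_gaussian(pixels[..., ci], row, col, sigma_c, amp)
        entries.append(
            GroundTruthEntry(
                cell_id=cell_id,
                cls=cls,
                centroid_row=row,
                centroid_col=col,
                radius_px=radius,
                amplitude=realized,
                punctate=punctate,
            )
        )

    control_entries: list[GroundTruthEntry] = []
    ctrl_amp = config.amplitude_means.get("control", DEFAULT_AMPLITUDES["control"])
    for (row, col), radius in zip(ctrl_centers, ctrl_radii):
        cell_id += 1
        amp = ctrl_amp.get("DAPI", 150.0) * rng.uniform(*JITTER)
        _add_gaussian(pixels[..., 2], row, col, radius / 2.0, amp)
        control_entries.append(
            GroundTruthEntry(
                cell_id=cell_id,
                cls="negative",
                centroid_row=row,
                centroid_col=col,
                radius_px=radius,
                amplitude={"CK": 0.0, "CD45": 0.0, "DAPI": amp},
            )
        )

    if config.noise_sd > 0:
        pixels += rng.normal(0.0, config.noise_sd, size=pixels.shape)
    np.clip(pixels, 0.0, None, out=pixels)

    field = ImageField(
        pixels=pixels.astype(np.float32),
        control_mask=control_mask,
        provenance=f"simfield-{config.seed}",
    )
    return field, GroundTruth(entries=entries, control_entries=control_entries)


# ---------------------------------------------------------------------------
# crop phenotypes

#: rendering profile for the two crop phenotypes (peak amplitudes)
CROP_PROFILES = {
    "responsive": {"CK": 20.0, "CD45": 130.0, "DAPI": 150.0},
    "resistant": {"CK": 130.0, "CD45": 20.0, "DAPI": 150.0},
}
PUNCTATE_CD45 = 15.0
PUNCTATE_CK = 160.0
CROP_NOISE_SD = 2.0


def _render_crop(
    rng: np.random.Generator, phase: str, punctate: bool
) -> np.ndarray:
    tensor = np.zeros((CROP_SIZE, CROP_SIZE, 3), dtype=np.float64)
    center = CROP_SIZE / 2.0
    row = center + rng.uniform(-3, 3)
    col = center + rng.uniform(-3, 3)
    radius = rng.uniform(5.0, 8.0)
    sigma_n = radius / 2.0
    sigma_c = 1.2 * radius
    amps = dict(CROP_PROFILES[phase])
    if punctate:
        amps["CK"], amps["CD45"] = PUNCTATE_CK, PUNCTATE_CD45
    for ci, ch in enumerate(CHANNELS):
        amp = amps[ch] * rng.uniform(*JITTER)
        if ch == "DAPI":
            _add_gaussian(tensor[..., ci], row, col, sigma_n, amp)
        elif ch == "CK" and punctate:
            _render_puncta(
                rng, tensor[..., ci], row, col, 2.0 * radius, amp,
                n_puncta=int(rng.integers(4, 7)),
            )
        else:
            _add_gaussian(tensor[..., ci], row, col, sigma_c, amp)
    tensor += rng.normal(0.0, CROP_NOISE_SD, size=tensor.shape)
    np.clip(tensor, 0.0, None, out=tensor)
    return tensor.astype(np.float32)


def generate_crop_set(
    n_responsive: int,
    n_resistant: int,
    punctate_fraction: float = 0.0,
    seed: int = 0,
) -> list[Crop]:
    """Labeled 64x64x3 crops of the two treatment phenotypes.

    Responsive crops have mean CD45 above mean CK; resistant crops the
    opposite.  A ``punctate_fraction`` of resistant crops renders CK as
    discrete puncta rather than a diffuse cytoplasmic disk.
    """
    if n_responsive < 0 or n_resistant < 0:
        raise ConfigError("crop counts must be nonnegative")
    if not 0 <= punctate_fraction <= 1:
        raise ConfigError("punctate_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    crops: list[Crop] = []
    for i in range(n_responsive):
        crops.append(
            Crop(
                tensor=_render_crop(rng, "responsive", False),
                provenance=("simcrops", i),
                phase="responsive",
            )
        )
    for j in range(n_resistant):
        punctate = bool(rng.uniform() < punctate_fraction)
        crops.append(
            Crop(
                tensor=_render_crop(rng, "resistant", punctate),
                provenance=("simcrops", n_responsive + j),
                phase="resistant",
                punctate=punctate,
            )
        )
    return crops


# ---------------------------------------------------------------------------
# longitudinal cohorts


@dataclass
class CohortConfig:
    """Study-condition settings for synthetic longitudinal cohorts."""

    n_patients: int = 5
    n_healthy: int = 15
    samples_per_patient: tuple[int, int] = (7, 10)
    baseline_range: tuple[float, float] = (7.6, 15.5)
    healthy_range: tuple[float, float] = (0.0, 1.67)
    healthy_zero_prob: float = 0.8
    regimes: Sequence[str] | None = None  # per patient; None -> drawn uniformly
    interval_increase_range: tuple[float, float] = (2.0, 49.6)
    pbmcs_per_sample: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 0 or self.n_healthy < 0:
            raise ConfigError("cohort sizes must be nonnegative")
        lo, hi = self.samples_per_patient
        if lo < 3:
            raise ConfigError("samples_per_patient must allow at least 3 samples")
        if lo > hi:
            raise ConfigError("samples_per_patient range must satisfy min <= max")
        for name in ("baseline_range", "healthy_range", "interval_increase_range"):
            a, b = getattr(self, name)
            if a < 0 or a > b:
                raise ConfigError(f"{name} must be nonnegative with min <= max")
        if not 0 <= self.healthy_zero_prob <= 1:
            raise ConfigError("healthy_zero_prob must lie in [0, 1]")
        if self.pbmcs_per_sample <= 0:
            raise ConfigError("pbmcs_per_sample must be positive")
        if self.regimes is not None:
            unknown = set(self.regimes) - set(REGIMES)
            if unknown:
                raise ConfigError(f"unknown regimes: {sorted(unknown)}")


def _raw_in_normalized_range(
    rng: np.random.Generator, lo: float, hi: float, pbmcs: int
) -> int:
    """Integer raw count whose per-50k normalization falls inside [lo, hi]."""
    raw_lo = math.ceil(lo * pbmcs / 50_000)
    raw_hi = math.floor(hi * pbmcs / 50_000)
    if raw_lo > raw_hi:
        raise ConfigError(
            f"no integer count in [{lo}, {hi}] per 50k at {pbmcs} PBMCs; "
            "increase pbmcs_per_sample"
        )
    return int(rng.integers(raw_lo, raw_hi + 1))


def _make_enumeration(
    subject_id: str, index: int, day: float, raw_chc: int, pbmcs: int, event: str = ""
) -> SampleEnumeration:
    return SampleEnumeration(
        sample_id=f"{subject_id}-s{index:02d}",
        subject_id=subject_id,
        days_from_treatment_start=day,
        raw_counts={
            "CHC": raw_chc,
            "CTC": 0,
            "leukocyte": max(0, pbmcs - raw_chc),
            "negative": 0,
        },
        total_pbmcs=pbmcs,
        event=event,
    )


def _patient_timeline(
    rng: np.random.Generator, subject_id: str, regime: str, config: CohortConfig
) -> SubjectTimeline:
    p = config.pbmcs_per_sample
    lo_n, hi_n = config.samples_per_patient
    n_total = int(rng.integers(lo_n, hi_n + 1))
    needs_post = regime in ("post_trial_progression", "long_term_stable")
    if regime == "sustained_response":
        n_post = 0
        n_total = min(n_total, 7)  # all samples on trial; match on-trial sampling depth
    elif needs_post:
        n_post = max(1, n_total - 7)
    else:  # on_trial_resistance
        n_post = max(0, n_total - 7)
    n_on = n_total - n_post  # baseline + on-trial samples
    if n_on < 3:
        n_on, n_post = 3, n_total - 3

    baseline_raw = _raw_in_normalized_range(rng, *config.baseline_range, p)
    rebound = lambda: _raw_in_normalized_range(rng, *config.interval_increase_range, p)

    # counts on trial: baseline, decline to zero within two samples, zeros
    raw = [baseline_raw]
    slow_decline = n_on > 3 and rng.uniform() < 0.5
    if slow_decline:
        raw.append(max(1, int(round(baseline_raw * rng.uniform(0.2, 0.5)))))
    raw += [0] * (n_on - len(raw))
    if regime == "on_trial_resistance":
        raw[-1] = rebound()

    # post-trial surveillance counts
    if regime == "post_trial_progression" and n_post:
        first = rebound()
        raw += [first] + [
            max(1, int(round(first * rng.uniform(1.0, 1.8)))) for _ in range(n_post - 1)
        ]
    elif regime == "on_trial_resistance" and n_post:
        raw += [max(1, int(round(raw[-1] * rng.uniform(0.8, 1.5)))) for _ in range(n_post)]
    else:
        raw += [0] * n_post

    days = [28.0 * i for i in range(n_on)]
    trial_end = days[-1]
    days += [trial_end + 56.0 * (j + 1) for j in range(n_post)]

    samples = []
    for i, (day, count) in enumerate(zip(days, raw)):
        event = "treatment_start" if i == 0 else ("trial_end" if day == trial_end else "")
        samples.append(_make_enumeration(subject_id, i, day, count, p, event))
    return SubjectTimeline(
        subject_id=subject_id,
        cohort="patient",
        samples=samples,
        treatment_start=0.0,
        trial_end=trial_end,
        regime=regime,
    )


def _healthy_timeline(
    rng: np.random.Generator, subject_id: str, config: CohortConfig
) -> SubjectTimeline:
    n = int(rng.integers(1, 4))
    lo, hi = config.healthy_range
    samples = []
    for i in range(n):
        if rng.uniform() < config.healthy_zero_prob or hi == 0:
            samples.append(_make_enumeration(subject_id, i, 90.0 * i, 0, config.pbmcs_per_sample))
        else:
            # a single detected cell at a sampling depth chosen so the
            # normalized count lands in (lo, hi]; depth capped at 250k cells
            target = rng.uniform(max(lo, 0.2), hi)
            pbmcs = min(250_000, math.ceil(50_000 / target))
            samples.append(_make_enumeration(subject_id, i, 90.0 * i, 1, pbmcs))
    return SubjectTimeline(
        subject_id=subject_id, cohort="healthy", samples=samples, treatment_start=0.0
    )


def generate_cohort(config: CohortConfig) -> list[SubjectTimeline]:
    """Simulate patient and healthy-subject count trajectories.

    Patients start at a baseline drawn from ``baseline_range``, drop to
    exactly zero within two post-treatment samples, and then follow their
    regime: sustained response and long-term stability stay at zero,
    on-trial resistance rebounds before the end of trial, post-trial
    progression rebounds during surveillance.  Healthy subjects stay
    within ``healthy_range``; no sample anywhere contains tumor cells
    without the immune marker (CTC count is always zero).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if config.regimes is None:
        regimes = [REGIMES[int(rng.integers(len(REGIMES)))] for _ in range(config.n_patients)]
    else:
        regimes = [config.regimes[i % len(config.regimes)] for i in range(config.n_patients)]
    timelines = [
        _patient_timeline(rng, f"P{i + 1:02d}", regimes[i], config)
        for i in range(config.n_patients)
    ]
    timelines += [
        _healthy_timeline(rng, f"H{i + 1:02d}", config) for i in range(config.n_healthy)
    ]
    return timelines
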