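"""Ground-truthed synthetic data: beating-heart videos/traces and labeled
serial-section kidney stacks.

These generators reproduce the statistical structure the analysis modules
assume, so the whole chain is testable without original recordings:

* A cardiac intensity trace at 300 fps whose per-beat intervals come from a
  renewal process (mean ``60 / true_hr_bpm`` s, configurable coefficient of
  variation), contaminated by a ventilation sinusoid that is common-mode
  across all ROIs and by independent Gaussian noise.  The cardiac pulse is
  an asymmetric raised cosine — a fast systolic dip followed by a slow
  diastolic recovery — so each beat has a single well-defined intensity
  minimum at the end of the dip.
* An ellipsoidal "kidney" voxelized into 5-um-thick sections, with
  blood-cell label assigned per kidney voxel by independent Bernoulli draws
  whose probability can be depleted inside a dorsal band (localized beam
  damage) or over the whole organ (whole-body reference exposure), and with
  per-section integer alignment jitter.

Every generator takes a seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .cardiometry import FrameStack, IntensityTrace, Rect, RoiSet
from .morphometry3d import SectionStack

__all__ = [
    "HeartSimParams",
    "SectionSimParams",
    "HeartTraceTruth",
    "SectionStackTruth",
    "gen_heart_trace",
    "gen_heart_video",
    "gen_section_stack",
]


@dataclass(frozen=True)
class HeartSimParams:
    """Conditions of a simulated heart recording.

    Defaults match the recording protocol the pipeline is designed for:
    300 fps, 3-minute collection, ventilation artifact at 2 Hz with half the
    cardiac amplitude, Gaussian noise at a tenth of the cardiac amplitude,
    and 2% beat-to-beat interval variability.
    """

    true_hr_bpm: float = 165.0
    fps: float = 300.0
    duration_s: float = 180.0
    baseline: float = 100.0
    cardiac_amplitude: float = 10.0
    systolic_fraction: float = 0.3
    waveform: Literal["asymmetric", "cosine"] = "asymmetric"
    ventilation_hz: float = 2.0
    ventilation_amplitude: float | None = None  # default 0.5 x cardiac
    ventilation_gain_mismatch: float = 0.0  # relative gain spread across ROIs
    noise_sd: float | None = None  # default 0.1 x cardiac
    hr_jitter_cv: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.duration_s <= 0 or self.cardiac_amplitude <= 0:
            raise ValueError("fps, duration and cardiac amplitude must be > 0")
        if not (30.0 <= self.true_hr_bpm <= 300.0):
            raise ValueError("true_hr_bpm must lie in [30, 300]")
        if not (0 < self.systolic_fraction < 1):
            raise ValueError("systolic_fraction must lie in (0, 1)")
        if self.hr_jitter_cv < 0:
            raise ValueError("hr_jitter_cv must be >= 0")

    @property
    def vent_amp(self) -> float:
        return (
            0.5 * self.cardiac_amplitude
            if self.ventilation_amplitude is None
            else self.ventilation_amplitude
        )

    @property
    def noise(self) -> float:
        return 0.1 * self.cardiac_amplitude if self.noise_sd is None else self.noise_sd


@dataclass(frozen=True)
class HeartTraceTruth:
    """Ground truth accompanying a generated recording."""

    beat_times_s: np.ndarray  # systole onset of each beat
    minima_times_s: np.ndarray  # end of the systolic dip (intensity minimum)
    true_mean_hr_bpm: float  # 60 / mean realized interbeat interval
    nominal_hr_bpm: float
    seed: int


def _beat_times(params: HeartSimParams, rng: np.random.Generator) -> np.ndarray:
    """Renewal-process beat onsets covering [0, duration] with margin."""
    mean_ibi = 60.0 / params.true_hr_bpm
    n = int(np.ceil(params.duration_s / mean_ibi)) + 4
    if params.hr_jitter_cv > 0:
        ibis = rng.normal(mean_ibi, params.hr_jitter_cv * mean_ibi, size=n)
        ibis = np.clip(ibis, 0.2 * mean_ibi, 3.0 * mean_ibi)
    else:
        ibis = np.full(n, mean_ibi)
    onsets = np.concatenate([[0.0], np.cumsum(ibis)])
    return onsets


def _cardiac_waveform(t: np.ndarray, onsets: np.ndarray, params: HeartSimParams) -> np.ndarray:
    """Evaluate the pulse train at sample times ``t`` (negative-going)."""
    k = np.searchsorted(onsets, t, side="right") - 1
    k = np.clip(k, 0, len(onsets) - 2)
    span = onsets[k + 1] - onsets[k]
    phase = (t - onsets[k]) / span
    if params.waveform == "cosine":
        return -params.cardiac_amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    sf = params.systolic_fraction
    depth = np.where(
        phase < sf,
        0.5 * (1.0 - np.cos(np.pi * phase / sf)),
        0.5 * (1.0 + np.cos(np.pi * (phase - sf) / (1.0 - sf))),
    )
    return -params.cardiac_amplitude * depth


def gen_heart_trace(
    params: HeartSimParams,
) -> tuple[list[IntensityTrace], IntensityTrace, HeartTraceTruth]:
    """Generate 3 heart-ROI traces, 1 reference trace and the ground truth.

    Heart traces carry baseline + cardiac pulse train + ventilation sinusoid
    + independent Gaussian noise; the reference trace carries the same
    ventilation sinusoid (no cardiac term) + independent noise, so the
    subtraction step cancels ventilation exactly when the gain mismatch is 0.
    """
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fps))
    t = np.arange(n) / params.fps
    onsets = _beat_times(params, rng)
    cardiac = _cardiac_waveform(t, onsets, params)
    vent = params.vent_amp * np.sin(2.0 * np.pi * params.ventilation_hz * t)

    gains = np.ones(4)
    if params.ventilation_gain_mismatch > 0:
        gains = 1.0 + rng.normal(0.0, params.ventilation_gain_mismatch, size=4)

    heart = [
        IntensityTrace(
            values=params.baseline
            + cardiac
            + gains[i] * vent
            + rng.normal(0.0, params.noise, size=n),
            fps=params.fps,
        )
        for i in range(3)
    ]
    ref = IntensityTrace(
        values=params.baseline + gains[3] * vent + rng.normal(0.0, params.noise, size=n),
        fps=params.fps,
    )

    last = np.searchsorted(onsets, params.duration_s)
    used = onsets[: last + 1]
    realized_ibis = np.diff(used)
    true_mean = 60.0 / float(realized_ibis.mean()) if realized_ibis.size else params.true_hr_bpm
    if params.waveform == "cosine":
        minima = used[:-1] + 0.5 * realized_ibis
    else:
        minima = used[:-1] + params.systolic_fraction * realized_ibis
    truth = HeartTraceTruth(
        beat_times_s=used,
        minima_times_s=minima,
        true_mean_hr_bpm=true_mean,
        nominal_hr_bpm=params.true_hr_bpm,
        seed=params.seed,
    )
    return heart, ref, truth


def _default_rois(frame_shape: tuple[int, int], heart_region: Rect) -> RoiSet:
    """Three small ROIs tiling the heart region plus a distant reference."""
    h0, h1 = heart_region.row0, heart_region.row1
    c0, c1 = heart_region.col0, heart_region.col1
    third = max(1, (c1 - c0) // 3)
    hearts = tuple(
        Rect(h0, c0 + i * third, h1, min(c0 + (i + 1) * third, c1)) for i in range(3)
    )
    H, W = frame_shape
    ref_h = max(1, (h1 - h0) // 2)
    ref_w = max(1, (c1 - c0) // 2)
    if h0 >= ref_h + 2:
        ref = Rect(0, 0, ref_h, ref_w)
    else:
        ref = Rect(H - ref_h, W - ref_w, H, W)
    return RoiSet(heart_rois=hearts, reference_roi=ref)  # type: ignore[arg-type]


def gen_heart_video(
    params: HeartSimParams,
    frame_shape: tuple[int, int] = (384, 512),
    heart_region: Rect | None = None,
    rois: RoiSet | None = None,
) -> tuple[FrameStack, RoiSet, HeartTraceTruth]:
    """Render the trace model spatially into a grayscale frame stack.

    Pixels inside ``heart_region`` carry cardiac + ventilation signal; all
    other body pixels carry ventilation only; every pixel gets independent
    Gaussian noise.  ``roi_mean_trace`` on the output reproduces the trace
    model up to noise averaging.
    """
    H, W = frame_shape
    if heart_region is None:
        heart_region = Rect(H // 2, W // 2, H // 2 + max(2, H // 8), W // 2 + max(3, W // 6))
    if not heart_region.within(H, W):
        raise ValueError("heart_region outside frame bounds")
    if rois is None:
        rois = _default_rois(frame_shape, heart_region)
    for r in rois.heart_rois:
        if not (
            heart_region.row0 <= r.row0
            and r.row1 <= heart_region.row1
            and heart_region.col0 <= r.col0
            and r.col1 <= heart_region.col1
        ):
            raise ValueError("heart ROIs must lie inside the heart region")
    if rois.reference_roi.overlaps(heart_region):
        raise ValueError("reference ROI must lie outside the heart region")

    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.fps))
    t = np.arange(n) / params.fps
    onsets = _beat_times(params, rng)
    cardiac = _cardiac_waveform(t, onsets, params)
    vent = params.vent_amp * np.sin(2.0 * np.pi * params.ventilation_hz * t)

    frames = np.empty((n, H, W), dtype=float)
    frames[:] = params.baseline + vent[:, None, None]
    frames[
        :, heart_region.row0 : heart_region.row1, heart_region.col0 : heart_region.col1
    ] += cardiac[:, None, None]
    if params.noise > 0:
        frames += rng.normal(0.0, params.noise, size=frames.shape)

    last = np.searchsorted(onsets, params.duration_s)
    used = onsets[: last + 1]
    realized_ibis = np.diff(used)
    true_mean = 60.0 / float(realized_ibis.mean()) if realized_ibis.size else params.true_hr_bpm
    if params.waveform == "cosine":
        minima = used[:-1] + 0.5 * realized_ibis
    else:
        minima = used[:-1] + params.systolic_fraction * realized_ibis
    truth = HeartTraceTruth(
        beat_times_s=used,
        minima_times_s=minima,
        true_mean_hr_bpm=true_mean,
        nominal_hr_bpm=params.true_hr_bpm,
        seed=params.seed,
    )
    return FrameStack(frames=frames, fps=params.fps), rois, truth


@dataclass(frozen=True)
class SectionSimParams:
    """Conditions of a simulated labeled serial-section stack.

    The organ is an ellipsoid with semi-axes in um, voxelized on an
    H x W in-plane grid at ``pixel_size_um`` with ``n_sections`` sections of
    ``section_thickness_um``.  Row 0 is the dorsal body surface.  Blood-cell
    labeling is Bernoulli per kidney voxel at ``baseline_blood_fraction``,
    multiplied by ``1 - depletion_factor`` inside the depletion region.
    """

    semi_axes_um: tuple[float, float, float] = (150.0, 120.0, 120.0)  # (z, y, x)
    center_um: tuple[float, float, float] | None = None  # defaults to grid center
    grid_shape: tuple[int, int] = (64, 64)  # (H, W)
    pixel_size_um: float = 5.0
    n_sections: int = 70
    section_thickness_um: float = 5.0
    baseline_blood_fraction: float = 0.25
    depletion: Literal["none", "dorsal-band", "whole"] = "none"
    depletion_depth_um: float = 2200.0  # dorsal-band depth from the dorsal surface
    depletion_factor: float = 1.0
    jitter_sd_px: float = 0.0
    margin_px: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0 or self.section_thickness_um <= 0:
            raise ValueError("pixel size and section thickness must be > 0")
        if not (0.0 <= self.baseline_blood_fraction <= 1.0):
            raise ValueError("baseline_blood_fraction must lie in [0, 1]")
        if not (0.0 <= self.depletion_factor <= 1.0):
            raise ValueError("depletion_factor must lie in [0, 1]")
        if self.jitter_sd_px < 0 or self.margin_px < 0:
            raise ValueError("jitter and margin must be >= 0")
        H, W = self.grid_shape
        cz, cy, cx = self.center()
        az, ay, ax = self.semi_axes_um
        if (
            cy - ay < self.margin_px * self.pixel_size_um
            or cy + ay > (H - self.margin_px) * self.pixel_size_um
            or cx - ax < self.margin_px * self.pixel_size_um
            or cx + ax > (W - self.margin_px) * self.pixel_size_um
        ):
            raise ValueError("organ does not fit in the grid with the stated margin")

    def center(self) -> tuple[float, float, float]:
        if self.center_um is not None:
            return self.center_um
        H, W = self.grid_shape
        return (
            self.n_sections * self.section_thickness_um / 2.0,
            H * self.pixel_size_um / 2.0,
            W * self.pixel_size_um / 2.0,
        )

    @property
    def analytic_volume_um3(self) -> float:
        az, ay, ax = self.semi_axes_um
        return 4.0 / 3.0 * np.pi * az * ay * ax


@dataclass(frozen=True)
class SectionStackTruth:
    """Ground truth accompanying a generated section stack."""

    unjittered_sections: list[np.ndarray]
    applied_shifts: np.ndarray  # (n_sections, 2) integer (d_row, d_col)
    voxel_volume_um3: float  # kidney+blood voxel count x voxel volume
    analytic_volume_um3: float
    per_section_blood_fraction: np.ndarray  # NaN where a section has no organ
    blood_probability_used: np.ndarray  # per-section mean Bernoulli p over organ
    seed: int


def _integer_shift(img: np.ndarray, d_row: int, d_col: int) -> np.ndarray:
    """Shift a label image by whole pixels, padding with background (0)."""
    out = np.zeros_like(img)
    h, w = img.shape
    r0s, r1s = max(0, -d_row), min(h, h - d_row)
    c0s, c1s = max(0, -d_col), min(w, w - d_col)
    r0d, c0d = max(0, d_row), max(0, d_col)
    out[r0d : r0d + (r1s - r0s), c0d : c0d + (c1s - c0s)] = img[r0s:r1s, c0s:c1s]
    return out


def gen_section_stack(params: SectionSimParams) -> tuple[SectionStack, SectionStackTruth]:
    """Voxelize a labeled ellipsoidal kidney with optional depletion and jitter."""
    rng = np.random.default_rng(params.seed)
    H, W = params.grid_shape
    cz, cy, cx = params.center()
    az, ay, ax = params.semi_axes_um

    y = (np.arange(H) + 0.5) * params.pixel_size_um
    x = (np.arange(W) + 0.5) * params.pixel_size_um
    yy, xx = np.meshgrid(y, x, indexing="ij")

    sections: list[np.ndarray] = []
    per_frac = np.full(params.n_sections, np.nan)
    p_used = np.full(params.n_sections, np.nan)
    for s in range(params.n_sections):
        z = (s + 0.5) * params.section_thickness_um
        organ = ((z - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
        labels = organ.astype(np.uint8)
        n_organ = int(organ.sum())
        if n_organ:
            p = np.full((H, W), params.baseline_blood_fraction)
            if params.depletion == "whole":
                p *= 1.0 - params.depletion_factor
            elif params.depletion == "dorsal-band":
                band = yy <= params.depletion_depth_um
                p[band] *= 1.0 - params.depletion_factor
            draw = rng.random((H, W)) < p
            blood = organ & draw
            labels[blood] = 2
            per_frac[s] = blood.sum() / n_organ
            p_used[s] = float(p[organ].mean())
        sections.append(labels)

    if params.jitter_sd_px > 0:
        shifts = np.rint(rng.normal(0.0, params.jitter_sd_px, size=(params.n_sections, 2)))
        shifts = np.clip(shifts, -params.margin_px, params.margin_px).astype(int)
    else:
        shifts = np.zeros((params.n_sections, 2), dtype=int)

    jittered = [
        _integer_shift(img, int(dr), int(dc)) for img, (dr, dc) in zip(sections, shifts)
    ]
    voxel = params.pixel_size_um**2 * params.section_thickness_um
    n_voxels = int(sum((img > 0).sum() for img in sections))
    truth = SectionStackTruth(
        unjittered_sections=sections,
        applied_shifts=shifts,
        voxel_volume_um3=n_voxels * voxel,
        analytic_volume_um3=params.analytic_volume_um3,
        per_section_blood_fraction=per_frac,
        blood_probability_used=p_used,
        seed=params.seed,
    )
    stack = SectionStack(
        sections=jittered,
        pixel_size_um=params.pixel_size_um,
        section_thickness_um=params.section_thickness_um,
    )
    return stack, truth
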