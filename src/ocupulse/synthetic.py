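"""Synthetic multimodal eye-pulsation scenes with known ground truth.

Generates the four modalities the pipeline analyzes — fast-TR BOLD volume
series of the eye/orbit, eye-surface video, retinal video, and
belt/SpO2 monitor traces — from one shared physiological model:

    x(t) = baseline + Σ_bands Σ_k a·d^(k−1) · sin(2π k f t + φ_k) + ε(t)

with a very-low-frequency vasomotor component (default 0.05 Hz), a
respiratory component (default 0.25 Hz), and a cardiac component (default
1.10 Hz), each optionally carrying geometrically decaying harmonics, plus
white Gaussian noise. The defaults follow the representative in-scanner
values: TR = 100 ms (10 Hz) two-slice 128×128 BOLD with the second slice at
a higher baseline, 640×480 @ 30 fps video, 3-minute epochs (30 s for the
eye-surface camera clips).

Structured artifacts are rendered on demand so every cleanup stage has a
ground-truth test surface: whole-frame blink darkening, integer-pixel
saccadic scene translation, a fixed central hot-spot oscillating at its own
frequency in retinal video, and — in single-slice scan mode only — the
global 10 Hz scanner flicker that contaminates the camera signal.

Determinism: one seeded generator per dataset; phases are drawn in a fixed
documented order (VLF harmonics, RESP harmonics, CARD harmonics, then
flicker, hot-spot, saccade events, blink events, noise), so enabling a later
component never perturbs earlier draws.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (
    AcquisitionMeta,
    FrameStack,
    ROIMask,
    TimeTrace,
    VolumeSeries,
    write_frame_stack,
    write_physio_table,
    write_volume_series,
)

__all__ = [
    "OscSpec",
    "FlickerSpec",
    "BlinkSpec",
    "SaccadeSpec",
    "HotspotSpec",
    "ScenarioConfig",
    "GroundTruth",
    "generate_physio_trace",
    "generate_fmreye_series",
    "generate_eye_video",
    "generate_monitor_traces",
    "optic_disc_annulus",
    "simulate_dataset",
]

# stream offsets so each product of one scenario has its own substream
_STREAM = {"physio": 0, "fmreye": 1, "fec": 2, "mrcvo": 3, "monitor": 4}


@dataclass
class OscSpec:
    """One oscillatory component: fundamental + geometric harmonics.

    Harmonic k (k = 1..n_harmonics, k = 1 being the fundamental) sits at
    k·freq with amplitude ``amplitude * harmonic_decay**(k-1)``.
    """

    freq: float
    amplitude: float
    n_harmonics: int = 1
    harmonic_decay: float = 0.5

    def __post_init__(self) -> None:
        if self.freq <= 0:
            raise ValueError("oscillator frequency must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.n_harmonics < 1:
            raise ValueError("n_harmonics counts the fundamental; must be >= 1")

    @property
    def max_freq(self) -> float:
        return self.n_harmonics * self.freq


@dataclass
class FlickerSpec:
    """Global scanner-interference flicker (single-slice scan mode only)."""

    freq: float = 10.0
    amplitude: float = 0.1


@dataclass
class BlinkSpec:
    """Whole-frame blink darkening events."""

    rate: float = 0.25  # events per second (~15 blinks/min)
    dark_fraction: float = 0.6
    duration_frames: int = 3  # ~100 ms at 30 fps


@dataclass
class SaccadeSpec:
    """Integer-pixel saccadic scene translations."""

    rate: float = 0.1  # events per second
    max_shift: int = 5  # px per axis


@dataclass
class HotspotSpec:
    """Central reflection hot-spot in retinal video."""

    radius: int = 5  # px
    amplitude: float = 0.1
    freq: float = 3.0  # Hz, distinct from the physiological bands


def _default_roi_band_gains() -> dict[str, dict[str, float]]:
    # Relative band strength per region: the eye and optic nerve pulsate
    # most prominently in the respiratory band with a weak cardiac
    # component; brain tissue carries all three bands; background is
    # noise only.
    return {
        "eye": {"vlf": 0.5, "resp": 1.5, "card": 0.3},
        "on": {"vlf": 1.0, "resp": 1.5, "card": 0.3},
        "brain": {"vlf": 1.0, "resp": 1.0, "card": 1.0},
        "background": {"vlf": 0.0, "resp": 0.0, "card": 0.0},
    }


@dataclass
class ScenarioConfig:
    """Full description of one synthetic multimodal scanning session."""

    duration: float = 180.0  # s (3-minute epochs)
    seed: int = 0
    vlf: OscSpec = field(default_factory=lambda: OscSpec(0.05, 0.5))
    resp: OscSpec = field(default_factory=lambda: OscSpec(0.25, 1.0, n_harmonics=2))
    card: OscSpec = field(default_factory=lambda: OscSpec(1.10, 0.5, n_harmonics=2))
    noise_sd: float = 0.05
    baseline: float = 100.0
    slice_mode: int = 2
    slice2_baseline_gain: float = 1.2
    flicker: FlickerSpec = field(default_factory=FlickerSpec)
    blink: BlinkSpec = field(default_factory=BlinkSpec)
    saccade: SaccadeSpec = field(default_factory=SaccadeSpec)
    hotspot: HotspotSpec = field(default_factory=HotspotSpec)
    volume_shape: tuple[int, int] = (128, 128)
    frame_shape: tuple[int, int] = (480, 640)  # rows, cols
    fps: float = 30.0
    tr: float = 0.1  # s -> 10 Hz BOLD sampling
    fec_duration: float = 30.0  # s, eye-surface camera clip length
    video_mod_depth: float = 0.05  # fractional intensity per unit amplitude
    roi_band_gains: dict[str, dict[str, float]] = field(
        default_factory=_default_roi_band_gains
    )

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.slice_mode not in (1, 2):
            raise ValueError("slice_mode must be 1 or 2")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.slice2_baseline_gain <= 1 and self.slice_mode == 2:
            raise ValueError("slice2_baseline_gain must be > 1")
        if min(self.volume_shape) < 4:
            raise ValueError("volume grid must be at least 4x4")

    @property
    def bands(self) -> dict[str, OscSpec]:
        return {"vlf": self.vlf, "resp": self.resp, "card": self.card}

    @property
    def fmreye_fs(self) -> float:
        return 1.0 / self.tr

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAM[stream]])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        for key, sub in (
            ("vlf", OscSpec), ("resp", OscSpec), ("card", OscSpec),
            ("flicker", FlickerSpec), ("blink", BlinkSpec),
            ("saccade", SaccadeSpec), ("hotspot", HotspotSpec),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        for key in ("volume_shape", "frame_shape"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """Realized generator state, for parameter-recovery testing."""

    frequencies: dict[str, float]
    roi_amplitudes: dict[str, dict[str, float]] | None = None
    blink_frames: np.ndarray | None = None
    saccade_shifts: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "frequencies": self.frequencies,
            "roi_amplitudes": self.roi_amplitudes,
            "blink_frames": (
                None if self.blink_frames is None else self.blink_frames.tolist()
            ),
            "saccade_shifts": (
                None if self.saccade_shifts is None
                else self.saccade_shifts.tolist()
            ),
        }


def _check_nyquist(config: ScenarioConfig, fs: float, bands=None) -> None:
    for name, osc in config.bands.items():
        if bands is not None and name not in bands:
            continue
        if osc.amplitude > 0 and not osc.max_freq < fs / 2:
            raise ValueError(
                f"{name} component reaches {osc.max_freq} Hz, at or above "
                f"Nyquist ({fs / 2} Hz)"
            )


def _oscillation(
    t: np.ndarray,
    osc: OscSpec,
    rng: np.random.Generator,
    gain: float = 1.0,
) -> np.ndarray:
    """Render one component; always draws its phases to keep streams aligned."""
    out = np.zeros_like(t)
    for k in range(1, osc.n_harmonics + 1):
        phase = rng.uniform(0.0, 2 * np.pi)
        amp = gain * osc.amplitude * osc.harmonic_decay ** (k - 1)
        if amp > 0:
            out += amp * np.sin(2 * np.pi * k * osc.freq * t + phase)
    return out


def _component_sum(
    t: np.ndarray,
    config: ScenarioConfig,
    rng: np.random.Generator,
    band_gains: dict[str, float] | None = None,
    amplitude_scale: float = 1.0,
) -> np.ndarray:
    """Sum all three bands in the fixed draw order vlf, resp, card."""
    gains = band_gains or {}
    out = np.zeros_like(t)
    for name in ("vlf", "resp", "card"):
        out += _oscillation(
            t, config.bands[name], rng,
            gain=amplitude_scale * gains.get(name, 1.0),
        )
    return out


def generate_physio_trace(
    config: ScenarioConfig,
    fs: float,
    duration: float | None = None,
    rng: np.random.Generator | None = None,
    label: str = "physio",
) -> tuple[TimeTrace, GroundTruth]:
    """One realization of the physiological signal model at rate ``fs``.

    samples = baseline + Σ components + N(0, noise_sd); phases come from
    the scenario's seeded generator.
    """
    _check_nyquist(config, fs)
    if duration is None:
        duration = config.duration
    if rng is None:
        rng = config.rng("physio")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    samples = config.baseline + _component_sum(t, config, rng)
    if config.noise_sd > 0:
        samples = samples + rng.normal(0.0, config.noise_sd, n)
    gt = GroundTruth(
        frequencies={name: osc.freq for name, osc in config.bands.items()}
    )
    return TimeTrace(samples, fs=fs, label=label), gt


def _volume_rois(shape: tuple[int, int]) -> dict[str, np.ndarray]:
    """Disjoint rectangular regions on the in-plane grid.

    Top-left quarter-band: eye; top-right: optic nerve; bottom half: brain;
    the remaining middle band: background. Non-empty for any grid >= 4x4.
    """
    nx, ny = shape
    eye = np.zeros(shape, dtype=bool)
    on = np.zeros(shape, dtype=bool)
    brain = np.zeros(shape, dtype=bool)
    q = max(1, nx // 4)
    eye[:q, : ny // 2] = True
    on[:q, ny // 2:] = True
    brain[nx // 2:, :] = True
    background = ~(eye | on | brain)
    rois = {"eye": eye, "on": on, "brain": brain, "background": background}
    stacked = np.stack(list(rois.values()))
    if stacked.sum(axis=0).max() > 1:
        raise ValueError("overlapping ROI definitions")
    for name, m in rois.items():
        if not m.any():
            raise ValueError(f"ROI {name!r} is empty on grid {shape}")
    return rois


def generate_fmreye_series(
    config: ScenarioConfig,
) -> tuple[VolumeSeries, dict[str, ROIMask], GroundTruth]:
    """Synthetic fast-TR BOLD series with disjoint eye/ON/brain/background ROIs.

    Each ROI receives an independent physiological trace (own phases) whose
    band amplitudes are scaled by ``config.roi_band_gains``; every voxel
    adds independent Gaussian noise. In two-slice mode the second slice's
    baseline is the first slice's times ``slice2_baseline_gain``.
    """
    fs = config.fmreye_fs
    _check_nyquist(config, fs)
    rng = config.rng("fmreye")
    nx, ny = config.volume_shape
    n_slices = config.slice_mode
    n = int(round(config.duration * fs))
    t = np.arange(n) / fs

    rois = _volume_rois((nx, ny))
    # in the fixed order eye, on, brain: one trace per ROI
    signal = np.zeros((nx, ny, n), dtype=np.float32)
    roi_amplitudes: dict[str, dict[str, float]] = {}
    for name in ("eye", "on", "brain", "background"):
        gains = config.roi_band_gains.get(name, {})
        roi_amplitudes[name] = {
            b: config.bands[b].amplitude * gains.get(b, 0.0) for b in config.bands
        }
        if name == "background":
            continue
        trace = _component_sum(t, config, rng, band_gains=gains)
        signal[rois[name]] = trace.astype(np.float32)

    data = np.empty((nx, ny, n_slices, n), dtype=np.float32)
    for s in range(n_slices):
        base = config.baseline * (config.slice2_baseline_gain if s == 1 else 1.0)
        data[:, :, s, :] = base + signal
    if config.noise_sd > 0:
        data += rng.normal(
            0.0, config.noise_sd, size=data.shape
        ).astype(np.float32)

    series = VolumeSeries(
        data=data,
        meta=AcquisitionMeta(tr=config.tr, modality="fmreye", n_slices=n_slices),
        voxel_size=(2.64, 2.64, 3.0),
    )
    masks = {
        name: ROIMask(np.repeat(m[:, :, np.newaxis], n_slices, axis=2), name=name)
        for name, m in rois.items()
    }
    gt = GroundTruth(
        frequencies={name: osc.freq for name, osc in config.bands.items()},
        roi_amplitudes=roi_amplitudes,
    )
    return series, masks, gt


def _disk(shape: tuple[int, int], center: tuple[float, float], radius: float):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _video_scene(config: ScenarioConfig, modality: str) -> np.ndarray:
    """Static scene: eye surface (iris + pupil) or fundus (disc + vessels)."""
    h, w = config.frame_shape
    scale = min(h, w)
    scene = np.full((h, w), 0.3)
    center = (h / 2, w / 2)
    if modality == "fec":
        scene[_disk((h, w), center, 0.35 * scale)] = 0.6  # iris
        scene[_disk((h, w), center, 0.12 * scale)] = 0.08  # pupil
    else:  # mrcvo: fundus with optic disc and radial vessel ridges
        scene[:] = 0.45
        scene[_disk((h, w), center, 0.12 * scale)] = 0.8
        rr, cc = np.mgrid[:h, :w]
        theta = np.arctan2(rr - center[0], cc - center[1])
        radial = np.hypot(rr - center[0], cc - center[1])
        ridges = (np.cos(6 * theta) > 0.92) & (radial > 0.12 * scale)
        scene[ridges] += 0.15
    return scene


def generate_eye_video(
    config: ScenarioConfig,
    modality: str = "fec",
    duration: float | None = None,
) -> tuple[FrameStack, GroundTruth]:
    """Synthetic eye-surface (fec) or retinal (mrcvo) video.

    The static scene's intensity is modulated multiplicatively by the
    physiological model (scaled by ``video_mod_depth``); blinks darken
    whole frames, saccades translate the scene by persistent integer
    offsets (circular shift), retinal video adds a fixed central hot-spot
    oscillating at its own frequency, and single-slice scan mode adds the
    global scanner flicker. Duration defaults to the 30 s eye-camera clip
    for fec and the full epoch for mrcvo.
    """
    if modality not in ("fec", "mrcvo"):
        raise ValueError("modality must be 'fec' or 'mrcvo'")
    fps = config.fps
    _check_nyquist(config, fps)
    if config.slice_mode == 1 and not config.flicker.freq < fps / 2:
        raise ValueError(
            f"flicker frequency {config.flicker.freq} Hz is at or above "
            f"Nyquist ({fps / 2} Hz)"
        )
    if duration is None:
        duration = config.fec_duration if modality == "fec" else config.duration
    rng = config.rng(modality)
    n = int(round(duration * fps))
    t = np.arange(n) / fps
    h, w = config.frame_shape

    # fixed draw order: band phases, flicker, hotspot, saccades, blinks, noise
    mod = _component_sum(t, config, rng, amplitude_scale=config.video_mod_depth)
    flicker_phase = rng.uniform(0.0, 2 * np.pi)
    hotspot_phase = rng.uniform(0.0, 2 * np.pi)

    n_sacc = rng.poisson(config.saccade.rate * duration)
    shifts = np.zeros((n, 2), dtype=int)
    if n_sacc > 0 and n > 1 and config.saccade.max_shift > 0:
        event_frames = np.unique(rng.integers(1, n, size=n_sacc))
        offset = np.zeros(2, dtype=int)
        prev = 0
        for ev in event_frames:
            shifts[prev:ev] = offset
            offset = rng.integers(
                -config.saccade.max_shift, config.saccade.max_shift + 1, size=2
            )
            prev = ev
        shifts[prev:] = offset
        shifts[0] = 0

    n_blinks = rng.poisson(config.blink.rate * duration)
    blink_frames = np.zeros(0, dtype=int)
    if n_blinks > 0 and config.blink.dark_fraction > 0:
        starts = rng.integers(0, n, size=n_blinks)
        spans = [
            np.arange(s, min(s + config.blink.duration_frames, n)) for s in starts
        ]
        blink_frames = np.unique(np.concatenate(spans))

    scene = _video_scene(config, modality).astype(np.float32)
    frames = scene[:, :, np.newaxis] * (1.0 + mod).astype(np.float32)
    for k in range(n):
        if shifts[k].any():
            frames[:, :, k] = np.roll(frames[:, :, k], shifts[k], axis=(0, 1))
    if modality == "mrcvo" and config.hotspot.amplitude > 0:
        if not config.hotspot.freq < fps / 2:
            raise ValueError("hot-spot frequency at or above Nyquist")
        spot = _disk((h, w), (h / 2, w / 2), config.hotspot.radius)
        hot = config.hotspot.amplitude * np.sin(
            2 * np.pi * config.hotspot.freq * t + hotspot_phase
        )
        frames[spot] += hot.astype(np.float32)
    if config.slice_mode == 1 and config.flicker.amplitude > 0:
        flick = config.flicker.amplitude * np.sin(
            2 * np.pi * config.flicker.freq * t + flicker_phase
        )
        frames += flick.astype(np.float32)
    if blink_frames.size:
        frames[:, :, blink_frames] *= 1.0 - config.blink.dark_fraction
    if config.noise_sd > 0:
        frames += rng.normal(0.0, config.noise_sd, size=frames.shape).astype(
            np.float32
        )

    gt = GroundTruth(
        frequencies={name: osc.freq for name, osc in config.bands.items()},
        blink_frames=blink_frames,
        saccade_shifts=shifts,
    )
    return FrameStack(frames=frames, fps=fps), gt


def optic_disc_annulus(
    config: ScenarioConfig, width_fraction: float = 0.15
) -> ROIMask:
    """Annulus around the optic disc excluding the central hot-spot pixels."""
    h, w = config.frame_shape
    scale = min(h, w)
    inner = config.hotspot.radius + 2
    outer = inner + width_fraction * scale
    center = (h / 2, w / 2)
    mask = _disk((h, w), center, outer) & ~_disk((h, w), center, inner)
    return ROIMask(mask, name="optic_disc_annulus")


def generate_monitor_traces(
    config: ScenarioConfig,
    fs: float = 50.0,
    duration: float | None = None,
) -> tuple[TimeTrace, TimeTrace]:
    """Respiratory-belt and SpO2 pulse traces sharing the scene's frequencies.

    belt = respiratory component + noise; spo2 = cardiac component + noise.
    Both reuse the scenario's exact component frequencies with independent
    phases and noise (draw order: belt phases, spo2 phases, belt noise,
    spo2 noise).
    """
    for osc in (config.resp, config.card):
        if not osc.max_freq < fs / 2:
            raise ValueError("component frequency at or above monitor Nyquist")
    if duration is None:
        duration = config.duration
    rng = config.rng("monitor")
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    belt = _oscillation(t, config.resp, rng)
    spo2 = _oscillation(t, config.card, rng)
    if config.noise_sd > 0:
        belt = belt + rng.normal(0.0, config.noise_sd, n)
        spo2 = spo2 + rng.normal(0.0, config.noise_sd, n)
    return (
        TimeTrace(belt, fs=fs, label="belt"),
        TimeTrace(spo2, fs=fs, label="spo2"),
    )


def simulate_dataset(config: ScenarioConfig, outdir: str | Path) -> dict:
    """Write a full synthetic session to ``outdir``; returns a manifest.

    Emits the BOLD series (NIfTI), eye-surface and retinal videos (AVI and
    NIfTI-wrapped), monitor traces (CSV), per-ROI masks (NIfTI), and a
    ``ground_truth.json`` with the realized generator state.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    series, masks, gt_vol = generate_fmreye_series(config)
    write_volume_series(series, outdir / "fmreye.nii.gz")
    for name, mask in masks.items():
        vol = VolumeSeries(
            data=mask.mask[..., np.newaxis].astype(np.uint8),
            meta=series.meta,
            voxel_size=series.voxel_size,
        )
        write_volume_series(vol, outdir / f"roi_{name}.nii.gz")

    truth = {"config": config.to_dict(), "fmreye": gt_vol.to_dict()}
    for modality in ("fec", "mrcvo"):
        stack, gt = generate_eye_video(config, modality=modality)
        write_frame_stack(stack, outdir / f"{modality}.avi")
        write_frame_stack(stack, outdir / f"{modality}.nii.gz")
        truth[modality] = gt.to_dict()

    belt, spo2 = generate_monitor_traces(config)
    write_physio_table({"belt": belt, "spo2": spo2}, outdir / "physio.csv")

    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return truth
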