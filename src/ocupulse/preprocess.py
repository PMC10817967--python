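"""Signal and video conditioning ahead of spectral analysis.

The chain mirrors standard fast-fMRI / eye-video practice: drop the initial
frames acquired before steady state (default 20), high-pass at 0.008 Hz
(125 s period) with a zero-phase 2nd-order Butterworth filter, replace
transient spikes against a running median/MAD baseline, flag and
interpolate blink-darkened video frames, and undo saccadic translations by
phase-correlation registration on the border-cropped frame interior
(default 10-pixel border excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.signal
from skimage.registration import phase_cross_correlation

from .io_formats import FrameStack, ROIMask, TimeTrace, VolumeSeries

__all__ = [
    "PreprocessConfig",
    "trim_initial",
    "highpass",
    "despike",
    "detect_blinks",
    "register_frames",
    "apply_roi",
]

#: Consistency factor relating MAD to the standard deviation of a normal.
MAD_SCALE = 1.4826


@dataclass
class PreprocessConfig:
    """Preprocessing parameters with the pipeline's stated defaults."""

    n_trim: int = 20
    hp_cutoff: float = 0.008  # Hz; 125 s period
    despike_window: int = 5
    despike_thresh: float = 3.5  # MAD units
    blink_thresh: float = 3.5  # MAD units
    register_reference: int = 0  # first frame
    register_border: int = 10  # px excluded from phase correlation

    def __post_init__(self) -> None:
        if self.n_trim < 0:
            raise ValueError("n_trim must be >= 0")
        if not self.hp_cutoff > 0:
            raise ValueError("hp_cutoff must be positive")
        if self.despike_window % 2 == 0 or self.despike_window < 3:
            raise ValueError("despike window must be odd and >= 3")
        if self.register_border < 0:
            raise ValueError("register border must be >= 0")


def trim_initial(series, n: int):
    """Drop the first ``n`` time points of a trace, volume series, or video.

    Output sample k equals input sample k + n along the time axis.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if isinstance(series, TimeTrace):
        if len(series) <= n:
            raise ValueError(f"cannot trim {n} samples from length {len(series)}")
        return TimeTrace(
            series.samples[n:], fs=series.fs,
            t0=series.t0 + n / series.fs, label=series.label,
        )
    if isinstance(series, VolumeSeries):
        if series.n_timepoints <= n:
            raise ValueError(
                f"cannot trim {n} volumes from length {series.n_timepoints}"
            )
        return VolumeSeries(
            data=series.data[..., n:], meta=series.meta,
            voxel_size=series.voxel_size,
        )
    if isinstance(series, FrameStack):
        if series.n_frames <= n:
            raise ValueError(f"cannot trim {n} frames from length {series.n_frames}")
        return FrameStack(
            frames=series.frames[..., n:], fps=series.fps, valid=series.valid[n:],
        )
    raise TypeError(f"unsupported container {type(series).__name__}")


def highpass(trace: TimeTrace, cutoff: float = 0.008) -> TimeTrace:
    """Zero-phase 2nd-order Butterworth high-pass filter.

    Applied forward-backward (``sosfiltfilt``), so the effective magnitude
    response is the square of the single-pass response and the phase is
    zero. Rejects DC: the output mean is ~0 for any input.
    """
    if not cutoff < trace.fs / 2:
        raise ValueError(
            f"cutoff ({cutoff} Hz) must be below Nyquist ({trace.fs / 2} Hz)"
        )
    sos = scipy.signal.butter(2, cutoff, btype="highpass", fs=trace.fs, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, trace.samples)
    return TimeTrace(filtered, fs=trace.fs, t0=trace.t0, label=trace.label)


def _running_median_mad(x: np.ndarray, window: int):
    """Centered running median and running MAD with reflect padding."""
    half = window // 2
    padded = np.pad(x, half, mode="reflect")
    windows = np.lib.stride_tricks.sliding_window_view(padded, window)
    med = np.median(windows, axis=1)
    mad = np.median(np.abs(windows - med[:, None]), axis=1)
    return med, mad


def despike(
    trace: TimeTrace, window: int = 5, thresh: float = 3.5
) -> tuple[TimeTrace, np.ndarray]:
    """Replace outliers against a running median/MAD baseline.

    Samples deviating from the centered running median by more than
    ``thresh * 1.4826 * running MAD`` are replaced with that median; all
    other samples pass through unchanged. Returns the cleaned trace and the
    indices of the replaced samples.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be odd and >= 3")
    if window > len(trace):
        raise ValueError(f"window ({window}) exceeds trace length ({len(trace)})")
    x = trace.samples
    med, mad = _running_median_mad(x, window)
    spikes = np.abs(x - med) > thresh * MAD_SCALE * mad
    cleaned = np.where(spikes, med, x)
    out = TimeTrace(cleaned, fs=trace.fs, t0=trace.t0, label=trace.label)
    return out, np.flatnonzero(spikes)


def detect_blinks(stack: FrameStack, thresh: float = 3.5) -> FrameStack:
    """Flag blink-darkened frames and repair them by linear interpolation.

    A frame is a blink candidate when its global mean intensity falls below
    ``median − thresh · 1.4826 · MAD`` of the frame means. Flagged frames
    are marked invalid and replaced per pixel by linear interpolation
    between the nearest valid neighbors; leading/trailing invalid frames
    copy the nearest valid frame.
    """
    if stack.n_frames < 3:
        raise ValueError("need at least 3 frames for blink detection")
    means = stack.frames.mean(axis=(0, 1))
    med = np.median(means)
    mad = np.median(np.abs(means - med))
    valid = means >= med - thresh * MAD_SCALE * mad
    if not valid.any():
        raise ValueError("all frames flagged as blinks; threshold too aggressive")
    frames = np.array(stack.frames, dtype=float)
    if not valid.all():
        t = np.arange(stack.n_frames)
        good = np.flatnonzero(valid)
        bad = np.flatnonzero(~valid)
        flat = frames.reshape(-1, stack.n_frames)
        # np.interp clamps to the nearest valid frame outside [good0, goodN]
        flat[:, bad] = np.stack(
            [np.interp(t[bad], good, row[good]) for row in flat]
        )
    return FrameStack(frames=frames, fps=stack.fps, valid=stack.valid & valid)


def _shift_with_fill(frame: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Translate a frame by integer (row, col), filling edges with its median."""
    dr, dc = int(shift[0]), int(shift[1])
    out = np.full_like(frame, np.median(frame))
    h, w = frame.shape
    src_r = slice(max(0, -dr), min(h, h - dr))
    src_c = slice(max(0, -dc), min(w, w - dc))
    dst_r = slice(max(0, dr), min(h, h + dr))
    dst_c = slice(max(0, dc), min(w, w + dc))
    out[dst_r, dst_c] = frame[src_r, src_c]
    return out


def register_frames(
    stack: FrameStack, ref: int = 0, border: int = 10
) -> tuple[FrameStack, np.ndarray]:
    """Undo per-frame integer translations estimated by phase correlation.

    Each frame's displacement relative to the reference frame (default: the
    first frame) is estimated on the border-cropped interior and undone by
    shifting, with edges filled by the frame's median intensity. Returns
    the registered stack and the per-frame (row, col) displacements.
    """
    h, w = stack.spatial_shape
    if h <= 2 * border or w <= 2 * border:
        raise ValueError(
            f"frames ({h}x{w}) must be larger than twice the border ({border})"
        )
    interior = (slice(border, h - border), slice(border, w - border))
    ref_img = stack.frames[:, :, ref][interior]
    if np.ptp(ref_img) == 0:
        raise ValueError("degenerate (constant) reference frame")
    frames = np.empty_like(stack.frames, dtype=float)
    shifts = np.zeros((stack.n_frames, 2), dtype=int)
    for t in range(stack.n_frames):
        frame = stack.frames[:, :, t]
        if t == ref:
            frames[:, :, t] = frame
            continue
        # phase_cross_correlation returns the shift that maps the moving
        # frame onto the reference, i.e. minus the frame's displacement
        correction, _, _ = phase_cross_correlation(
            ref_img, frame[interior], upsample_factor=1, normalization=None
        )
        correction = np.round(correction).astype(int)
        shifts[t] = -correction
        frames[:, :, t] = _shift_with_fill(frame, tuple(correction))
    return (
        FrameStack(frames=frames, fps=stack.fps, valid=stack.valid.copy()),
        shifts,
    )


def apply_roi(
    container: VolumeSeries | FrameStack, mask: ROIMask
) -> tuple[list[TimeTrace], TimeTrace]:
    """Extract per-element traces and the ROI-mean trace under a mask."""
    if isinstance(container, VolumeSeries):
        data, fs = container.data, container.fs
    elif isinstance(container, FrameStack):
        data, fs = container.frames, container.fps
    else:
        raise TypeError(f"unsupported container {type(container).__name__}")
    if mask.mask.shape != data.shape[:-1]:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match container "
            f"spatial shape {data.shape[:-1]}"
        )
    element_data = data[mask.mask]  # (n_elements, T)
    traces = [
        TimeTrace(row, fs=fs, label=f"{mask.name}[{i}]")
        for i, row in enumerate(np.asarray(element_data, dtype=float))
    ]
    mean_trace = TimeTrace(
        element_data.mean(axis=0), fs=fs, label=f"{mask.name} mean"
    )
    return traces, mean_trace
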