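"""Signal containers and readers/writers for the formats the pipeline touches.

The pipeline works with four in-memory containers:

* :class:`TimeTrace` -- a uniformly sampled 1-D signal (BOLD ROI mean,
  video global-mean intensity, respiratory belt, SpO2 pulse).
* :class:`VolumeSeries` -- a 4-D BOLD voxel grid ``(x, y, slice, t)`` from
  fast (TR = 100 ms) echo-planar eye imaging, stored as NIfTI-1.
* :class:`FrameStack` -- a grayscale eye-surface or retinal video
  ``(row, col, t)`` with per-frame validity flags, stored as AVI or as a
  NIfTI-wrapped volume ``(width, height, 1, frames)``.
* :class:`ROIMask` -- a boolean mask over the spatial grid of either
  container.

Video intensities are kept as floats in ``[0, 1]`` internally regardless of
the input bit depth. Physio traces use a plain CSV dialect with a
``# fs=<Hz>`` comment line, since the acquisition software's native format
is proprietary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd

from . import _avi

__all__ = [
    "TimeTrace",
    "AcquisitionMeta",
    "VolumeSeries",
    "FrameStack",
    "ROIMask",
    "to_grayscale",
    "read_volume_series",
    "write_volume_series",
    "read_frame_stack",
    "write_frame_stack",
    "read_physio_table",
    "write_physio_table",
]

#: Rec. 601 luma weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])

MODALITIES = ("fmreye", "fec", "mrcvo", "belt", "spo2")


@dataclass
class TimeTrace:
    """A uniformly sampled 1-D signal.

    Parameters
    ----------
    samples : ndarray
        Signal values x(n), arbitrary units.
    fs : float
        Sampling rate in Hz (> 0). Uniform sampling is implied; no
        per-sample timestamps are stored.
    t0 : float
        Start offset in seconds.
    label : str
        Free-text description.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("TimeTrace requires a non-empty 1-D sample array")
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs


@dataclass
class AcquisitionMeta:
    """Acquisition metadata: repetition time / frame interval and modality."""

    tr: float
    modality: str = "fmreye"
    n_slices: int | None = None

    def __post_init__(self) -> None:
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "fmreye":
            if self.n_slices not in (1, 2):
                raise ValueError("fmreye data must declare n_slices in {1, 2}")
        elif self.n_slices is not None:
            raise ValueError("n_slices applies only to fmreye data")

    @property
    def fs(self) -> float:
        """Sampling rate in Hz (1 / tr)."""
        return 1.0 / self.tr


@dataclass
class VolumeSeries:
    """A 4-D voxel grid over time, indexed ``(x, y, slice, t)``."""

    data: np.ndarray
    meta: AcquisitionMeta
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"VolumeSeries data must be 4-D, got {self.data.ndim}-D")
        if self.data.shape[3] < 1:
            raise ValueError("VolumeSeries requires at least one time point")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def fs(self) -> float:
        return self.meta.fs


@dataclass
class FrameStack:
    """A grayscale video, indexed ``(row, col, t)``, with validity flags."""

    frames: np.ndarray
    fps: float
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(f"FrameStack frames must be 3-D, got {self.frames.ndim}-D")
        if not self.fps > 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if self.valid is None:
            self.valid = np.ones(self.frames.shape[2], dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (self.frames.shape[2],):
                raise ValueError("valid must hold one flag per frame")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.frames.shape[:2]

    def global_mean_trace(self, label: str = "global mean") -> TimeTrace:
        """Mean intensity of each frame as a :class:`TimeTrace`."""
        return TimeTrace(self.frames.mean(axis=(0, 1)), fs=self.fps, label=label)


@dataclass
class ROIMask:
    """A named boolean mask over the spatial grid of a container."""

    mask: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError(f"ROI mask {self.name!r} has no true elements")

    @property
    def n_elements(self) -> int:
        return int(self.mask.sum())


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Convert an RGB(A) array to grayscale by Rec. 601 luma weights.

    Already-grayscale input is returned unchanged (the conversion is
    idempotent).
    """
    arr = np.asarray(arr)
    if arr.ndim >= 3 and arr.shape[-1] in (3, 4):
        rgb = arr[..., :3]
        # gray content stored as RGB collapses exactly, bypassing the
        # weighted sum's floating-point rounding
        if (rgb[..., 0] == rgb[..., 1]).all() and (rgb[..., 1] == rgb[..., 2]).all():
            return rgb[..., 0].astype(float)
        return rgb.astype(float) @ LUMA_WEIGHTS
    return arr


# ---------------------------------------------------------------------------
# NIfTI volume series
# ---------------------------------------------------------------------------

def write_volume_series(series: VolumeSeries, path: str | os.PathLike) -> None:
    """Write a :class:`VolumeSeries` to a NIfTI-1 file.

    The repetition time is stored in the time-axis zoom (pixdim[4]) with
    second units, the voxel size in the spatial zooms.
    """
    affine = np.diag([*series.voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(series.data), affine)
    img.header.set_zooms((*series.voxel_size, series.meta.tr))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, os.fspath(path))


def read_volume_series(
    path: str | os.PathLike, modality: str = "fmreye"
) -> VolumeSeries:
    """Read a 4-D NIfTI-1 file into a :class:`VolumeSeries`.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        For non-4D images or a non-positive recorded time step.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(os.fspath(path))
    if img.ndim != 4:
        raise ValueError(f"non-4D image ({img.ndim}-D): {path}")
    zooms = img.header.get_zooms()
    # pixdim is float32 in the header; round to its 7 significant digits so
    # a TR written as 0.1 s reads back as exactly 0.1 s
    tr = float(f"{float(zooms[3]):.7g}")
    _, t_unit = img.header.get_xyzt_units()
    if t_unit == "msec":
        tr /= 1e3
    elif t_unit == "usec":
        tr /= 1e6
    if not tr > 0:
        raise ValueError(f"non-positive time step ({tr} s) recorded in {path}")
    data = np.asarray(img.dataobj)
    n_slices = data.shape[2] if modality == "fmreye" and data.shape[2] in (1, 2) else None
    if modality == "fmreye" and n_slices is None:
        # more than two slices: still fMRI data, treat slice count as 2-like
        raise ValueError(
            f"fmreye volume must have 1 or 2 slices, got {data.shape[2]}"
        )
    meta = AcquisitionMeta(tr=tr, modality=modality, n_slices=n_slices)
    return VolumeSeries(
        data=data, meta=meta, voxel_size=tuple(float(z) for z in zooms[:3])
    )


# ---------------------------------------------------------------------------
# Video frame stacks
# ---------------------------------------------------------------------------

def write_frame_stack(stack: FrameStack, path: str | os.PathLike) -> None:
    """Write a :class:`FrameStack` to AVI (8-bit) or NIfTI (float).

    AVI output quantizes intensities to the 8-bit grid; NIfTI output wraps
    the video as a ``(width, height, 1, frames)`` volume with frame interval
    1/fps, mirroring the usual video-as-NIfTI conversion.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if path.suffix.lower() == ".avi":
        frames8 = np.clip(np.asarray(stack.frames, dtype=float), 0.0, 1.0)
        frames8 = np.round(frames8 * 255.0).astype(np.uint8)
        _avi.write_avi(path, np.moveaxis(frames8, 2, 0), fps=stack.fps)
    elif ".nii" in suffixes:
        vol = np.transpose(stack.frames, (1, 0, 2))[:, :, np.newaxis, :]
        series = VolumeSeries(
            data=vol,
            meta=AcquisitionMeta(tr=1.0 / stack.fps, modality="fec"),
        )
        write_volume_series(series, path)
    else:
        raise ValueError(f"unsupported frame-stack container: {path.suffix}")


def read_frame_stack(
    path: str | os.PathLike, fps_override: float | None = None
) -> FrameStack:
    """Read an AVI file, NIfTI-wrapped video, or a directory of frames.

    Frames are converted to grayscale (Rec. 601 luma) if needed and scaled
    to floats in ``[0, 1]``; all validity flags start true. ``fps`` comes
    from the container metadata unless ``fps_override`` is given. Directory
    stacks carry no rate metadata, so ``fps_override`` is required there.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such video source: {path}")
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir()
            if p.suffix.lower() in (".png", ".tif", ".tiff", ".bmp", ".jpg")
        )
        if not files:
            raise ValueError(f"no image frames found in directory {path}")
        if fps_override is None:
            raise ValueError("fps_override is required for directory stacks")
        imgs = [to_grayscale(iio.imread(p)).astype(float) for p in files]
        frames = np.stack(imgs, axis=2)
        if frames.max() > 1.0:
            frames = frames / 255.0
        return FrameStack(frames=frames, fps=fps_override)
    suffixes = "".join(path.suffixes).lower()
    if path.suffix.lower() == ".avi":
        raw, fps = _avi.read_avi(path)  # (t, h, w, 3) uint8
        if raw.shape[0] == 0:
            raise ValueError(f"zero frames in {path}")
        gray = to_grayscale(raw) / 255.0
        return FrameStack(
            frames=np.moveaxis(gray, 0, 2), fps=fps_override or fps
        )
    if ".nii" in suffixes:
        series = read_volume_series(path, modality="fec")
        if series.data.shape[2] != 1:
            raise ValueError("NIfTI-wrapped video must have a singleton slice axis")
        frames = np.transpose(series.data[:, :, 0, :], (1, 0, 2)).astype(float)
        return FrameStack(frames=frames, fps=fps_override or series.fs)
    raise ValueError(f"unreadable video container: {path}")


# ---------------------------------------------------------------------------
# Physiological monitor traces (respiratory belt, SpO2)
# ---------------------------------------------------------------------------

def write_physio_table(
    traces: dict[str, TimeTrace], path: str | os.PathLike
) -> None:
    """Write one or more equal-rate traces as CSV with a ``# fs=<Hz>`` header."""
    rates = {t.fs for t in traces.values()}
    if len(rates) != 1:
        raise ValueError("all traces in one table must share the sampling rate")
    fs = rates.pop()
    df = pd.DataFrame({name: t.samples for name, t in traces.items()})
    with open(path, "w") as fh:
        fh.write(f"# fs={fs!r}\n")
        df.to_csv(fh, index=False)


def read_physio_table(
    path: str | os.PathLike, channel: str | None = None
) -> TimeTrace | dict[str, TimeTrace]:
    """Read physio traces from a delimited text table.

    The header must carry the sampling rate as a ``# fs=<Hz>`` comment line
    and a header row naming the channels. Returns a single
    :class:`TimeTrace` when ``channel`` is given, else a dict of all
    channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such physio table: {path}")
    fs = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if body.startswith("fs"):
                try:
                    fs = float(body.split("=", 1)[1])
                except (IndexError, ValueError) as exc:
                    raise ValueError(f"invalid fs header in {path}: {line!r}") from exc
    if fs is None or not fs > 0:
        raise ValueError(f"missing or invalid '# fs=<Hz>' header in {path}")
    df = pd.read_csv(path, comment="#")
    traces = {
        str(col): TimeTrace(df[col].to_numpy(dtype=float), fs=fs, label=str(col))
        for col in df.columns
    }
    if channel is None:
        return traces
    if channel not in traces:
        raise ValueError(
            f"channel {channel!r} not in table (has {sorted(traces)})"
        )
    return traces[channel]
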