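"""Tapered-periodogram spectral core: band selection, band power, power maps.

The power spectrum estimator is the Hamming-tapered periodogram

    S(f_k) = sum_n w(n) (x(n) - x̄) e^{-i 2π k n / NFFT},
    P(f_k) = |S(f_k)|² / K,   K = Σ w(n)²,

evaluated on the one-sided zero-padded grid f_k = k · fs / NFFT. The taper
energy K normalizes the squared transform (the division keeps power
estimates independent of the taper scale). The signal mean is subtracted
before tapering so DC does not leak into the very-low-frequency band.

Physiological bands follow the eye/brain pulsation convention: a fixed
very-low-frequency (vasomotor) band 0.01–0.1 Hz, and respiratory / cardiac
bands that are 0.1 Hz wide, centered on the individual spectral peak found
inside a physiological search range (0.12–0.35 Hz for RESP, 0.8–1.3 Hz for
CARD). Band power is the plain sum of P(f_k) over bins inside the band
(closed interval, DC bin always excluded).

Per-voxel/pixel power maps select the band once on the ROI (or global) mean
spectrum and then integrate each element's own spectrum over that shared
band, so all elements of a map describe the same frequency interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import FrameStack, ROIMask, TimeTrace, VolumeSeries

__all__ = [
    "SpectralConfig",
    "TaperWeights",
    "Spectrum",
    "BandSpec",
    "BandPowerMap",
    "NFFT_FMREYE",
    "NFFT_VIDEO",
    "BAND_NAMES",
    "hamming_weights",
    "periodogram",
    "roi_mean_spectrum",
    "mean_power_spectrum",
    "select_band",
    "band_power",
    "band_power_map",
    "remove_bins",
    "normalize_spectrum",
]

NFFT_FMREYE = 2048  #: FFT length for TR = 100 ms BOLD series
NFFT_VIDEO = 3000   #: FFT length for 30 fps video (aligns bins to 0.01 Hz)

#: Fixed vasomotor band (Hz).
VLF_BAND = (0.01, 0.1)
#: Peak search ranges (Hz) for the adaptive bands.
SEARCH_RANGES = {"resp": (0.12, 0.35), "card": (0.8, 1.3)}
#: Half-width of the adaptive bands: peak ± 0.05 Hz.
BAND_HALFWIDTH = 0.05

BAND_NAMES = ("vlf", "resp", "card")


@dataclass(frozen=True)
class SpectralConfig:
    """Periodogram settings: FFT length, taper, sidedness."""

    nfft: int = NFFT_FMREYE
    window: str = "hamming"
    onesided: bool = True

    def __post_init__(self) -> None:
        if self.nfft <= 0:
            raise ValueError("nfft must be positive")
        if self.window != "hamming":
            raise ValueError("only the Hamming taper is supported")
        if not self.onesided:
            raise ValueError("only one-sided spectra are supported")


@dataclass
class TaperWeights:
    """Taper weights w(n) and their energy K = Σ w(n)²."""

    w: np.ndarray
    k_norm: float


@dataclass
class Spectrum:
    """One-sided power values on the grid f_k = k·fs/nfft, k = 0..nfft/2."""

    power: np.ndarray
    freqs: np.ndarray
    fs: float
    config: SpectralConfig

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.power.shape != self.freqs.shape:
            raise ValueError("power and freqs must align")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def delta_f(self) -> float:
        """Spectral resolution fs / NFFT in Hz."""
        return self.fs / self.config.nfft


@dataclass
class BandSpec:
    """A named physiological band with resolved edges and peak."""

    name: str
    lo: float
    hi: float
    search_lo: float
    search_hi: float
    peak: float | None = None
    halfwidth: float | None = None

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError("band requires lo < hi")


@dataclass
class BandPowerMap:
    """Per-voxel (or per-pixel) band power over a shared band."""

    values: np.ndarray
    band: BandSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("band power must be non-negative")


def hamming_weights(n: int) -> TaperWeights:
    """Hamming taper w(k) = 0.54 − 0.46·cos(2πk/(n−1)); w = [1] for n = 1."""
    if n <= 0:
        raise ValueError("taper length must be positive")
    if n == 1:
        w = np.ones(1)
    else:
        k = np.arange(n)
        w = 0.54 - 0.46 * np.cos(2 * np.pi * k / (n - 1))
    return TaperWeights(w=w, k_norm=float(np.sum(w**2)))


def periodogram(trace: TimeTrace, config: SpectralConfig | None = None) -> Spectrum:
    """Hamming-tapered one-sided periodogram of a trace.

    The trace is mean-subtracted, tapered, zero-padded to ``config.nfft``
    and transformed; power is |S|²/K on the one-sided grid. The DC bin is
    retained in the output but excluded from every band operation.
    """
    if config is None:
        config = SpectralConfig()
    x = trace.samples
    n = x.size
    if n == 0:
        raise ValueError("empty trace")
    if n > config.nfft:
        raise ValueError(f"nfft ({config.nfft}) must be >= trace length ({n})")
    taper = hamming_weights(n)
    s = np.fft.rfft((x - x.mean()) * taper.w, n=config.nfft)
    power = np.abs(s) ** 2 / taper.k_norm
    freqs = np.fft.rfftfreq(config.nfft, d=1.0 / trace.fs)
    return Spectrum(power=power, freqs=freqs, fs=trace.fs, config=config)


def roi_mean_spectrum(spectra: list[Spectrum]) -> Spectrum:
    """Elementwise arithmetic mean of power over a set of spectra."""
    if not spectra:
        raise ValueError("need at least one spectrum")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.freqs.shape != ref.freqs.shape or not np.allclose(s.freqs, ref.freqs):
            raise ValueError("spectra must share the frequency grid")
    mean_power = np.mean([s.power for s in spectra], axis=0)
    return Spectrum(power=mean_power, freqs=ref.freqs, fs=ref.fs, config=ref.config)


# ---------------------------------------------------------------------------
# container helpers
# ---------------------------------------------------------------------------

def _element_traces(container: VolumeSeries | FrameStack, mask: ROIMask | None):
    """Flatten a container to (n_elements, T) plus fs and spatial info."""
    if isinstance(container, VolumeSeries):
        data = container.data
        fs = container.fs
    elif isinstance(container, FrameStack):
        data = container.frames
        fs = container.fps
    else:
        raise TypeError(f"unsupported container {type(container).__name__}")
    spatial_shape = data.shape[:-1]
    flat = data.reshape(-1, data.shape[-1])
    if mask is not None:
        if mask.mask.shape != spatial_shape:
            raise ValueError("mask shape does not match container")
        idx = np.flatnonzero(mask.mask.reshape(-1))
    else:
        idx = np.arange(flat.shape[0])
    return flat, idx, fs, spatial_shape


def _chunked_power(flat, idx, fs, config, chunk=2048):
    """Yield (indices, per-element power block) over selected elements."""
    n = flat.shape[1]
    if n > config.nfft:
        raise ValueError(f"nfft ({config.nfft}) must be >= series length ({n})")
    taper = hamming_weights(n)
    for start in range(0, idx.size, chunk):
        sel = idx[start : start + chunk]
        block = flat[sel].astype(float)
        block -= block.mean(axis=1, keepdims=True)
        s = np.fft.rfft(block * taper.w, n=config.nfft, axis=1)
        yield sel, np.abs(s) ** 2 / taper.k_norm


def mean_power_spectrum(
    container: VolumeSeries | FrameStack,
    config: SpectralConfig | None = None,
    mask: ROIMask | None = None,
) -> Spectrum:
    """ROI (or global) mean power spectrum of a 4-D series or video.

    Computes each element's periodogram and averages the *power* across
    elements, as in voxelwise periodogram mapping followed by ROI mean
    extraction. Averaging power (not complex spectra) keeps out-of-phase
    but co-frequent elements from cancelling.
    """
    if config is None:
        config = SpectralConfig()
    flat, idx, fs, _ = _element_traces(container, mask)
    acc = None
    for _, power in _chunked_power(flat, idx, fs, config):
        acc = power.sum(axis=0) if acc is None else acc + power.sum(axis=0)
    freqs = np.fft.rfftfreq(config.nfft, d=1.0 / fs)
    return Spectrum(power=acc / idx.size, freqs=freqs, fs=fs, config=config)


def select_band(spectrum: Spectrum, name: str) -> BandSpec:
    """Resolve a physiological band on a spectrum.

    ``vlf`` is the fixed 0.01–0.1 Hz band. ``resp``/``card`` find the
    highest-power bin inside their search range and center a 0.1 Hz wide
    band on it (peak ± 0.05 Hz). Ties break toward the lower frequency.
    """
    if name == "vlf":
        return BandSpec(
            name="vlf", lo=VLF_BAND[0], hi=VLF_BAND[1],
            search_lo=VLF_BAND[0], search_hi=VLF_BAND[1],
        )
    if name not in SEARCH_RANGES:
        raise ValueError(f"unknown band {name!r} (use vlf, resp, or card)")
    lo_s, hi_s = SEARCH_RANGES[name]
    nyquist = spectrum.fs / 2
    if hi_s > nyquist:
        raise ValueError(f"{name} search range exceeds Nyquist ({nyquist} Hz)")
    in_range = (spectrum.freqs >= lo_s) & (spectrum.freqs <= hi_s)
    in_range[0] = False  # DC never participates
    if not in_range.any():
        raise ValueError(f"spectrum has no bins in the {name} search range")
    candidates = np.flatnonzero(in_range)
    peak = float(spectrum.freqs[candidates[np.argmax(spectrum.power[candidates])]])
    return BandSpec(
        name=name,
        lo=peak - BAND_HALFWIDTH,
        hi=peak + BAND_HALFWIDTH,
        search_lo=lo_s,
        search_hi=hi_s,
        peak=peak,
        halfwidth=BAND_HALFWIDTH,
    )


def _band_bins(freqs: np.ndarray, band: BandSpec) -> np.ndarray:
    sel = (freqs >= band.lo) & (freqs <= band.hi)
    sel[0] = False  # DC bin never included
    return sel


def band_power(spectrum: Spectrum, band: BandSpec) -> float:
    """Sum of P(f_k) over bins with lo ≤ f_k ≤ hi (closed interval, no DC)."""
    sel = _band_bins(spectrum.freqs, band)
    if not sel.any():
        raise ValueError(
            f"no spectral bins inside band [{band.lo}, {band.hi}] Hz"
        )
    return float(spectrum.power[sel].sum())


def band_power_map(
    container: VolumeSeries | FrameStack,
    band_name: str,
    config: SpectralConfig | None = None,
    mask: ROIMask | None = None,
) -> BandPowerMap:
    """Per-element band power over a band chosen once on the mean spectrum.

    The band is resolved on the ROI/global mean spectrum; each element's
    own periodogram is then summed over that shared band. Elements outside
    the mask are zero.
    """
    if config is None:
        config = SpectralConfig()
    mean_spec = mean_power_spectrum(container, config=config, mask=mask)
    band = select_band(mean_spec, band_name)
    sel = _band_bins(mean_spec.freqs, band)
    if not sel.any():
        raise ValueError(f"no spectral bins inside the {band_name} band")
    flat, idx, fs, spatial_shape = _element_traces(container, mask)
    out = np.zeros(flat.shape[0])
    for element_idx, power in _chunked_power(flat, idx, fs, config):
        out[element_idx] = power[:, sel].sum(axis=1)
    return BandPowerMap(values=out.reshape(spatial_shape), band=band)


def remove_bins(
    spectrum: Spectrum, freqs_to_remove, tol: float | None = None
) -> Spectrum:
    """Zero the power at bins within ``tol`` of each target frequency.

    Used to excise narrowband artifacts (scanner flicker, retinal hot-spot)
    before band-power integration. Targets matching no bin are no-ops with
    a warning. Default tolerance is half a bin spacing.
    """
    if tol is None:
        tol = spectrum.delta_f / 2
    power = spectrum.power.copy()
    for f0 in np.atleast_1d(np.asarray(freqs_to_remove, dtype=float)):
        hit = np.abs(spectrum.freqs - f0) <= tol
        if not hit.any():
            warnings.warn(
                f"no spectral bin within {tol} Hz of {f0} Hz; nothing removed",
                stacklevel=2,
            )
        power[hit] = 0.0
    return Spectrum(
        power=power, freqs=spectrum.freqs, fs=spectrum.fs, config=spectrum.config
    )


def normalize_spectrum(spectrum: Spectrum) -> Spectrum:
    """Min–max normalize power to [0, 1]: z = (x − min x)/(max x − min x)."""
    p = spectrum.power
    lo, hi = p.min(), p.max()
    if hi == lo:
        raise ValueError("degenerate normalization: constant spectrum")
    return Spectrum(
        power=(p - lo) / (hi - lo),
        freqs=spectrum.freqs,
        fs=spectrum.fs,
        config=spectrum.config,
    )
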