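"""Cross-modal verification of pulsation signals.

Band-limits two modalities' time courses, aligns them by maximal lagged
correlation (the recordings share no hardware synchronization trigger, so
alignment within a physiological lag window is the contract), and measures
per-subject peak-frequency agreement between modalities with Spearman rank
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

from .io_formats import TimeTrace
from .spectral import BandSpec

__all__ = [
    "bandpass",
    "resample_to",
    "xcorr_max",
    "peak_agreement",
    "make_peak_table",
]

#: Default lag window: one respiratory period.
DEFAULT_MAX_LAG = 4.0


def bandpass(trace: TimeTrace, band: BandSpec) -> TimeTrace:
    """Zero-phase 2nd-order Butterworth band-pass over [band.lo, band.hi]."""
    nyq = trace.fs / 2
    if not (0 < band.lo < band.hi < nyq):
        raise ValueError(
            f"band [{band.lo}, {band.hi}] Hz outside (0, {nyq}) Hz"
        )
    sos = scipy.signal.butter(
        2, [band.lo, band.hi], btype="bandpass", fs=trace.fs, output="sos"
    )
    filtered = scipy.signal.sosfiltfilt(sos, trace.samples)
    return TimeTrace(filtered, fs=trace.fs, t0=trace.t0, label=trace.label)


def resample_to(trace: TimeTrace, fs: float) -> TimeTrace:
    """Linear resampling onto a uniform grid at rate ``fs``."""
    if fs <= 0:
        raise ValueError("target rate must be positive")
    if fs == trace.fs:
        return trace
    n_out = int(np.floor((len(trace) - 1) * fs / trace.fs)) + 1
    t_out = np.arange(n_out) / fs
    t_in = np.arange(len(trace)) / trace.fs
    return TimeTrace(
        np.interp(t_out, t_in, trace.samples),
        fs=fs, t0=trace.t0, label=trace.label,
    )


def xcorr_max(
    a: TimeTrace, b: TimeTrace, max_lag: float = DEFAULT_MAX_LAG
) -> tuple[float, float]:
    """Maximum normalized cross-correlation within ±max_lag seconds.

    Traces at different native rates are first linearly resampled to the
    lower rate. For every integer-sample lag the Pearson correlation of the
    overlapping segments is evaluated; returns ``(r, lag_seconds)`` at the
    maximizing lag, ties broken toward the smallest |lag|. A positive lag
    means ``b`` trails ``a`` (``b`` is a delayed copy of ``a``).
    """
    fs = min(a.fs, b.fs)
    a, b = resample_to(a, fs), resample_to(b, fs)
    if np.ptp(a.samples) == 0 or np.ptp(b.samples) == 0:
        raise ValueError("constant input: correlation undefined")
    max_shift = int(round(max_lag * fs))
    best_r, best_lag = -np.inf, 0
    # scan lags by increasing |lag| so the first maximum wins ties
    for lag in sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), s)):
        if lag >= 0:
            # compare a(t) with b(t + lag): b delayed by `lag` samples
            xa, xb = a.samples[: len(a) - lag or None], b.samples[lag:]
        else:
            xa, xb = a.samples[-lag:], b.samples[:lag]
        m = min(len(xa), len(xb))
        if m < 10:
            continue
        xa, xb = xa[:m], xb[:m]
        if np.ptp(xa) == 0 or np.ptp(xb) == 0:
            continue
        r = float(np.corrcoef(xa, xb)[0, 1])
        if r > best_r:
            best_r, best_lag = r, lag
    if not np.isfinite(best_r):
        raise ValueError("no lag with >= 10 overlapping samples")
    return best_r, best_lag / fs


def make_peak_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble a peak table from dicts of (subject, modality, band, peak_hz)."""
    df = pd.DataFrame(rows, columns=["subject", "modality", "band", "peak_hz"])
    if df.isna().any().any():
        raise ValueError("peak table rows must provide all four fields")
    return df


def peak_agreement(
    table: pd.DataFrame, modality_a: str, modality_b: str, band: str
) -> tuple[float, int]:
    """Spearman rank correlation of per-subject peaks between two modalities.

    Returns ``(spearman_r, n_subjects)`` over subjects present in both
    modalities for the given band; average ranks handle ties.
    """
    sub = table[table["band"] == band]
    pivot = sub.pivot_table(
        index="subject", columns="modality", values="peak_hz"
    ).dropna(subset=[modality_a, modality_b])
    n = len(pivot)
    if n < 3:
        raise ValueError(f"need >= 3 paired subjects, got {n}")
    r, _ = scipy.stats.spearmanr(pivot[modality_a], pivot[modality_b])
    return float(r), n
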