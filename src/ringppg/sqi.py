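"""Signal-quality indices and the composite figure of merit (FoM) for PPG.

A recording is cut into non-overlapping 6-second segments.  Each segment
yields eight indices spanning amplitude (AC, DC, perfusion index PI, SNR),
the frequency domain (skewness S_PSD and kurtosis K_PSD of the power
spectrum), and periodicity (standard deviations of autocorrelation peak
heights and peak-to-peak intervals).  The FoM combines six of them:

    FoM = (PI · AC · S_PSD · K_PSD) / (STD_periods · STD_peaks)

evaluated on per-session min–max-normalized indices, so a high FoM means a
strong, spectrally concentrated, steadily periodic pulse.  SNR is reported
alongside but does not enter the product.

Formula conventions implemented literally (see docs/methods.md for the
rationale): DC is the mean of the *raw* segment while AC is computed on the
band-passed one; the SNR denominator is the difference of two residual
powers and may be non-positive (NaN result); the PSD moment sums carry no
1/NF factor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .records import PPGRecord

__all__ = [
    "Segment",
    "WindowStats",
    "PSDMoments",
    "AutocorrProfile",
    "SnrDecomposition",
    "SQIVector",
    "FoMResult",
    "segment_and_filter",
    "compute_ac",
    "compute_dc",
    "compute_pi",
    "compute_snr",
    "compute_psd_moments",
    "compute_autocorr_profile",
    "compute_sqi",
    "compute_fom",
]

log = logging.getLogger(__name__)

SEGMENT_SECONDS = 6
BAND = (0.5, 5.0)  # Hz, pass band of the SQI conditioning filter


def _sos_bandpass(low: float, high: float, fs: float, order: int = 4):
    # scipy doubles the order for band filters; order//2 keeps the overall
    # transfer function at the stated order
    return sps.butter(order // 2, [low, high], btype="bandpass", fs=fs, output="sos")


def _sos_highpass(cut: float, fs: float, order: int = 4):
    return sps.butter(order, cut, btype="highpass", fs=fs, output="sos")


def _sos_lowpass(cut: float, fs: float, order: int = 4):
    return sps.butter(order, cut, btype="lowpass", fs=fs, output="sos")


@dataclass
class Segment:
    """One 6-second analysis window: raw samples and their band-passed copy."""

    raw: np.ndarray
    filtered: np.ndarray
    fs: float
    index: int = 0

    def __post_init__(self) -> None:
        if len(self.raw) != len(self.filtered):
            raise ValueError("raw and filtered must have equal length")

    @property
    def n_windows(self) -> int:
        return int(len(self.filtered) // self.fs)


@dataclass(frozen=True)
class WindowStats:
    """Per-1-second window extrema of the filtered segment."""

    wmax: np.ndarray
    wmin: np.ndarray

    @property
    def L(self) -> int:
        return len(self.wmax)


@dataclass(frozen=True)
class PSDMoments:
    """One-sided FFT power values and their standardized 3rd/4th moment sums."""

    power: np.ndarray
    fmean: float
    fstd: float
    spsd: float
    kpsd: float

    @property
    def nf(self) -> int:
        return len(self.power)


@dataclass(frozen=True)
class AutocorrProfile:
    """One-sided normalized autocorrelation with detected periodicity peaks."""

    R: np.ndarray
    peak_lags: np.ndarray      # samples
    peak_heights: np.ndarray
    std_periods: float         # sample SD of peak-to-peak intervals (s); NaN if <3 peaks
    std_peaks: float           # sample SD of peak heights; NaN if <3 peaks


@dataclass(frozen=True)
class SnrDecomposition:
    xhigh: np.ndarray
    xlow: np.ndarray
    snr_db: float


@dataclass
class SQIVector:
    """The eight per-segment indices. NaN marks an undefined (flagged) index."""

    ac: float
    dc: float
    pi: float
    snr_db: float
    spsd: float
    kpsd: float
    std_periods: float
    std_peaks: float
    index: int = 0

    _FOM_FIELDS = ("pi", "ac", "spsd", "kpsd", "std_periods", "std_peaks")

    @property
    def flagged(self) -> bool:
        """True when the segment cannot enter the FoM.

        Either some ingredient is undefined (NaN: zero DC, flat spectrum,
        too few autocorrelation peaks) or a periodicity SD is exactly zero
        — e.g. a strictly periodic pulse train — which collapses the FoM
        denominator (degenerate; the ratio carries no information).
        """
        if any(math.isnan(getattr(self, f)) for f in self._FOM_FIELDS):
            return True
        return self.std_periods == 0.0 or self.std_peaks == 0.0


@dataclass(frozen=True)
class FoMResult:
    fom: np.ndarray               # per segment, NaN where flagged
    normalized: dict              # index name -> per-segment normalized values
    segment_indices: np.ndarray
    mean: float
    std: float


def segment_and_filter(
    record: PPGRecord, band: tuple[float, float] = BAND, order: int = 4
) -> list[Segment]:
    """Cut into N = floor(len / 6·fs) segments and band-pass each one.

    The filter is a zero-phase (forward–backward) 4th-order Butterworth
    band-pass at 0.5–5 Hz; the trailing remainder shorter than one segment
    is discarded.
    """
    seg_len = int(round(SEGMENT_SECONDS * record.fs))
    n = len(record.samples) // seg_len
    if n < 1:
        raise ValueError(
            f"record of {len(record.samples)} samples is shorter than one "
            f"{SEGMENT_SECONDS}-s segment ({seg_len} samples)"
        )
    sos = _sos_bandpass(band[0], band[1], record.fs, order)
    segments = []
    for i in range(n):
        raw = record.samples[i * seg_len : (i + 1) * seg_len].copy()
        filtered = sps.sosfiltfilt(sos, raw)
        segments.append(Segment(raw=raw, filtered=filtered, fs=record.fs, index=i))
    return segments


def window_stats(segment: Segment) -> WindowStats:
    """Max/min of each non-overlapping 1-second window of the filtered signal."""
    w = int(round(segment.fs))
    y = segment.filtered
    L = len(y) // w
    blocks = y[: L * w].reshape(L, w)
    return WindowStats(wmax=blocks.max(axis=1), wmin=blocks.min(axis=1))


def compute_ac(segment: Segment) -> float:
    """Pulse amplitude: mean over 1-s windows of (window max − window min)."""
    ws = window_stats(segment)
    return float(np.mean(ws.wmax - ws.wmin))


def compute_dc(segment: Segment) -> float:
    """Static level: arithmetic mean of the raw (unfiltered) segment."""
    return float(np.mean(segment.raw))


def compute_pi(ac: float, dc: float) -> float:
    """Perfusion index AC/DC; NaN when DC = 0 (segment gets flagged)."""
    if dc == 0:
        return math.nan
    return ac / dc


def compute_snr(segment: Segment, order: int = 4) -> SnrDecomposition:
    """Band-power SNR in dB.

    10·log10( Σy² / (Σ(y − x_high)² − Σ(y − x_low)²) ) where x_high/x_low are
    the raw segment high-passed at 0.5 Hz / low-passed at 5 Hz (zero-phase
    Butterworth).  The denominator is a difference of residual powers and can
    be non-positive, in which case the SNR is NaN (logged, not raised).
    """
    x = segment.raw
    y = segment.filtered
    xhigh = sps.sosfiltfilt(_sos_highpass(BAND[0], segment.fs, order), x)
    xlow = sps.sosfiltfilt(_sos_lowpass(BAND[1], segment.fs, order), x)
    num = float(np.sum(y**2))
    den = float(np.sum((y - xhigh) ** 2) - np.sum((y - xlow) ** 2))
    if den <= 0 or num == 0:
        log.debug(
            "segment %d: degenerate SNR (num=%.3g, den=%.3g)", segment.index, num, den
        )
        snr = math.nan
    else:
        snr = 10.0 * math.log10(num / den)
    return SnrDecomposition(xhigh=xhigh, xlow=xlow, snr_db=snr)


def compute_psd_moments(segment: Segment) -> PSDMoments:
    """Standardized 3rd/4th moment sums of the one-sided FFT power values.

    power[nf] = |FFT(y)[nf]|² over the NF = T//2 + 1 one-sided components;
    the sums Σ((f − f̄)/σ_f)³ and Σ(·)⁴ carry no 1/NF factor.  A flat
    spectrum (σ_f = 0) leaves both undefined (NaN → segment flagged).
    """
    y = segment.filtered
    power = np.abs(np.fft.rfft(y)) ** 2
    fmean = float(power.mean())
    fstd = float(power.std())
    if fstd == 0:
        return PSDMoments(power, fmean, fstd, math.nan, math.nan)
    zscores = (power - fmean) / fstd
    return PSDMoments(
        power=power,
        fmean=fmean,
        fstd=fstd,
        spsd=float(np.sum(zscores**3)),
        kpsd=float(np.sum(zscores**4)),
    )


def compute_autocorr_profile(
    segment: Segment,
    prominence_frac: float = 0.1,
    min_spacing_s: float = 0.25,
) -> AutocorrProfile:
    """One-sided normalized autocorrelation of the filtered segment.

    The unbiased estimator R[k] = Σₜ y[t]·y[t+k] / (T−k), normalized to
    R[0] = 1, is used so that an exactly periodic segment shows equally
    high peaks at every period multiple (the biased sum decays linearly in
    lag, which would spuriously inflate the peak-height dispersion of clean
    quasi-periodic pulses).  Lags are kept below T/2, where the estimator's
    own variance is controlled.

    Periodicity peaks are local maxima with prominence above
    ``prominence_frac`` of R[0] and at least ``min_spacing_s`` apart (peak
    picker parameters are not standardized in the SQI literature; both are
    exposed).  The STDs are sample standard deviations, so at least three
    peaks (two intervals) are required — fewer leaves both undefined and
    the segment flagged as aperiodic.
    """
    y = segment.filtered
    T = len(y)
    r = sps.correlate(y, y, mode="full")[T - 1 :]
    if r[0] == 0:
        return AutocorrProfile(r, np.array([]), np.array([]), math.nan, math.nan)
    R = (r / (T - np.arange(T))) * T / r[0]
    R = R[: T // 2 + 1]
    distance = max(1, int(round(min_spacing_s * segment.fs)))
    peaks, _ = sps.find_peaks(R, prominence=prominence_frac, distance=distance)
    heights = R[peaks]
    if len(peaks) < 3:
        return AutocorrProfile(R, peaks, heights, math.nan, math.nan)
    intervals = np.diff(peaks) / segment.fs
    return AutocorrProfile(
        R=R,
        peak_lags=peaks,
        peak_heights=heights,
        std_periods=float(np.std(intervals, ddof=1)),
        std_peaks=float(np.std(heights, ddof=1)),
    )


def compute_sqi(segment: Segment) -> SQIVector:
    """All eight indices of one segment."""
    ac = compute_ac(segment)
    dc = compute_dc(segment)
    pi = compute_pi(ac, dc)
    snr = compute_snr(segment).snr_db
    psd = compute_psd_moments(segment)
    acp = compute_autocorr_profile(segment)
    return SQIVector(
        ac=ac,
        dc=dc,
        pi=pi,
        snr_db=snr,
        spsd=psd.spsd,
        kpsd=psd.kpsd,
        std_periods=acp.std_periods,
        std_peaks=acp.std_peaks,
        index=segment.index,
    )


def _minmax(values: np.ndarray, eps: float) -> np.ndarray:
    lo, hi = np.min(values), np.max(values)
    if hi == lo:
        return np.ones_like(values)
    return eps + (1.0 - eps) * (values - lo) / (hi - lo)


def compute_fom(sqis: list[SQIVector], eps: float = 1e-6) -> FoMResult:
    """Session FoM: normalize each index over the session, form the product.

    Each of the six ingredients is min–max normalized to [eps, 1] across the
    session's unflagged segments (the floor prevents zero products and
    division blow-ups; a constant index normalizes to 1).  Flagged segments
    — NaN in any ingredient — are excluded; an all-flagged session raises.
    The summary is mean ± SD of the per-segment FoM.
    """
    unflagged = [s for s in sqis if not s.flagged]
    if not unflagged:
        raise ValueError("every segment is flagged; FoM undefined for this session")
    norm = {
        f: _minmax(np.array([getattr(s, f) for s in unflagged]), eps)
        for f in SQIVector._FOM_FIELDS
    }
    fom_vals = (norm["pi"] * norm["ac"] * norm["spsd"] * norm["kpsd"]) / (
        norm["std_periods"] * norm["std_peaks"]
    )
    full = np.full(len(sqis), np.nan)
    pos = {s.index: i for i, s in enumerate(sqis)}
    for j, s in enumerate(unflagged):
        full[pos[s.index]] = fom_vals[j]
    return FoMResult(
        fom=full,
        normalized=norm,
        segment_indices=np.array([s.index for s in unflagged]),
        mean=float(np.mean(fom_vals)),
        std=float(np.std(fom_vals)),
    )
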