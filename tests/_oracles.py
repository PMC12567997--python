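"""Independent brute-force transcriptions of the SQI formulas.

These deliberately re-derive every quantity with explicit loops/sums (no
reuse of the implementation's vectorized paths) so the tests compare two
independent routes to the same definition.
"""

import math

import numpy as np
from scipy import signal as sps


def ac_bruteforce(filtered: np.ndarray, fs: float) -> float:
    w = int(round(fs))
    L = len(filtered) // w
    total = 0.0
    for l in range(L):
        block = filtered[l * w : (l + 1) * w]
        total += max(block) - min(block)
    return total / L


def dc_bruteforce(raw: np.ndarray) -> float:
    return sum(float(v) for v in raw) / len(raw)


def snr_bruteforce(raw: np.ndarray, filtered: np.ndarray, fs: float) -> float:
    """Literal transcription of the band-power SNR definition."""
    sos_hp = sps.butter(4, 0.5, btype="highpass", fs=fs, output="sos")
    sos_lp = sps.butter(4, 5.0, btype="lowpass", fs=fs, output="sos")
    xhigh = sps.sosfiltfilt(sos_hp, raw)
    xlow = sps.sosfiltfilt(sos_lp, raw)
    num = sum(float(v) ** 2 for v in filtered)
    den = sum((float(y) - float(h)) ** 2 for y, h in zip(filtered, xhigh)) - sum(
        (float(y) - float(l)) ** 2 for y, l in zip(filtered, xlow)
    )
    if den <= 0 or num == 0:
        return math.nan
    return 10.0 * math.log10(num / den)


def psd_moments_bruteforce(filtered: np.ndarray) -> tuple[float, float]:
    spectrum = np.fft.rfft(filtered)
    power = [abs(c) ** 2 for c in spectrum]
    nf = len(power)
    fmean = sum(power) / nf
    fstd = math.sqrt(sum((p - fmean) ** 2 for p in power) / nf)
    if fstd == 0:
        return math.nan, math.nan
    spsd = sum(((p - fmean) / fstd) ** 3 for p in power)
    kpsd = sum(((p - fmean) / fstd) ** 4 for p in power)
    return spsd, kpsd


def autocorr_bruteforce(filtered: np.ndarray) -> np.ndarray:
    """Unbiased one-sided normalized autocorrelation, lag-by-lag dot products."""
    y = np.asarray(filtered, dtype=float)
    T = len(y)
    r = np.empty(T // 2 + 1)
    for k in range(T // 2 + 1):
        r[k] = float(np.dot(y[k:], y[: T - k])) / (T - k)
    return r / r[0]


def sd_bruteforce(values, ddof: int = 1) -> float:
    vals = [float(v) for v in values]
    n = len(vals)
    if n - ddof <= 0:
        return math.nan
    mean = sum(vals) / n
    return math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - ddof))
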