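"""Time-domain and frequency-domain HRV indices.

Time domain follows the Task Force conventions: meanNN, sdNN (sample
standard deviation) and rmssd, all in ms.  The spectrum is a single
full-segment periodogram of the linearly interpolated interval function
resampled at 2 Hz, mean removed, with a 4-term Blackman-Harris window
and window-power compensation so that the integral of the density over
frequency equals the signal variance (Parseval).  Band powers:

* VLF: (0, 0.04] Hz (DC excluded),
* LF:  (0.04, 0.15] Hz,
* HF:  (0.15, 0.4] Hz,

with P = VLF + LF + HF, LF/HF, VLF/P and, for completeness, the
normalized powers LFn = LF/(LF+HF), HFn = HF/(LF+HF).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import InsufficientDataError, RatioUndefinedError
from .io_preprocess import NNSeries

__all__ = [
    "SpectrumEstimate",
    "time_domain_indices",
    "power_spectrum",
    "frequency_indices",
    "BANDS",
]

#: Band edges in Hz, half-open (low, high].
BANDS = {"VLF": (0.0, 0.04), "LF": (0.04, 0.15), "HF": (0.15, 0.4)}

RESAMPLE_HZ = 2.0


@dataclass
class SpectrumEstimate:
    freqs: np.ndarray  # Hz, strictly increasing up to 1 Hz
    psd: np.ndarray  # ms^2/Hz
    total_power_ms2: float  # integral over the analysis band (0, 0.4] Hz


def time_domain_indices(nn: NNSeries) -> dict:
    if len(nn) < 2:
        raise InsufficientDataError("time-domain indices need >= 2 intervals")
    x = nn.nn
    d = np.diff(x)
    return {
        "meanNN": float(np.mean(x)),
        "sdNN": float(np.std(x, ddof=1)),
        "rmssd": float(np.sqrt(np.mean(d**2))),
    }


def power_spectrum(nn: NNSeries, min_duration_s: float = 300.0) -> SpectrumEstimate:
    """Periodogram of the 2-Hz resampled NN interval function.

    Zero-padded to the next power of two; the Blackman-Harris window's
    power is compensated so that ``sum(psd) * df`` equals the variance
    of the detrended resampled signal.
    """
    if nn.duration_s < min_duration_s:
        raise InsufficientDataError(
            f"spectrum needs >= {min_duration_s:.0f} s of beats, have {nn.duration_s:.0f} s"
        )
    grid = np.arange(0.0, nn.duration_s, 1.0 / RESAMPLE_HZ)
    sig = np.interp(grid, nn.t, nn.nn)
    nfft = 1 << int(np.ceil(np.log2(len(sig))))
    freqs, psd = signal.periodogram(
        sig,
        fs=RESAMPLE_HZ,
        window="blackmanharris",
        nfft=nfft,
        detrend="constant",
        scaling="density",
    )
    df = freqs[1] - freqs[0]
    mask = (freqs > 0) & (freqs <= BANDS["HF"][1])
    total = float(np.sum(psd[mask]) * df)
    return SpectrumEstimate(freqs=freqs, psd=psd, total_power_ms2=total)


def _band_power(sp: SpectrumEstimate, lo: float, hi: float) -> float:
    df = sp.freqs[1] - sp.freqs[0]
    mask = (sp.freqs > lo) & (sp.freqs <= hi)
    return float(np.sum(sp.psd[mask]) * df)


def frequency_indices(sp: SpectrumEstimate) -> dict:
    """Band powers and ratios from a spectrum covering 0-0.4 Hz."""
    if sp.freqs[-1] < BANDS["HF"][1]:
        raise InsufficientDataError("spectrum does not cover 0-0.4 Hz")
    vlf = _band_power(sp, *BANDS["VLF"])
    lf = _band_power(sp, *BANDS["LF"])
    hf = _band_power(sp, *BANDS["HF"])
    p = vlf + lf + hf
    if hf == 0.0:
        raise RatioUndefinedError("HF power is zero; LF/HF undefined")
    if p == 0.0:
        raise RatioUndefinedError("total power is zero; VLF/P undefined")
    return {
        "LF/HF": lf / hf,
        "VLF/P": vlf / p,
        "P": p,
        "LFn": lf / (lf + hf),
        "HFn": hf / (lf + hf),
    }
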