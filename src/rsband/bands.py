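"""Frequency-band registry and ideal FFT band-pass filtering.

The six bands partition 0–0.25 Hz (the Nyquist frequency at TR = 2 s):
conventional (0.01–0.08), Slow-6 (0–0.01), Slow-5 (0.01–0.027),
Slow-4 (0.027–0.073), Slow-3 (0.073–0.198) and Slow-2 (0.198–0.25).

Bin-edge convention: a DFT bin at frequency f belongs to band [low, high)
half-open, so Slow-6..Slow-2 tile the spectrum without double counting. The
single exception is a band whose upper edge equals Nyquist (Slow-2 at
TR = 2 s): the Nyquist bin itself is included there, and nowhere else. The
0 Hz bin is never passed — filtered output is zero-mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FrequencyBand", "BAND_REGISTRY", "get_band", "band_bin_mask", "bandpass_fft"]


@dataclass(frozen=True)
class FrequencyBand:
    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0 <= self.low_hz < self.high_hz):
            raise ValueError(f"need 0 <= low < high, got [{self.low_hz}, {self.high_hz})")

    def validate_for_tr(self, tr_seconds: float) -> None:
        nyq = 0.5 / tr_seconds
        if self.high_hz > nyq + 1e-12:
            raise ValueError(
                f"band {self.name} upper edge {self.high_hz} Hz exceeds "
                f"Nyquist {nyq} Hz at TR={tr_seconds}s"
            )


#: The band registry: conventional plus the five sub-bands tiling 0–0.25 Hz.
BAND_REGISTRY: dict[str, FrequencyBand] = {
    b.name: b
    for b in (
        FrequencyBand("conventional", 0.01, 0.08),
        FrequencyBand("slow6", 0.0, 0.01),
        FrequencyBand("slow5", 0.01, 0.027),
        FrequencyBand("slow4", 0.027, 0.073),
        FrequencyBand("slow3", 0.073, 0.198),
        FrequencyBand("slow2", 0.198, 0.25),
    )
}

#: the five sub-bands, lowest first
SUB_BANDS = ("slow6", "slow5", "slow4", "slow3", "slow2")


def get_band(band: "FrequencyBand | str") -> FrequencyBand:
    """Resolve a band by name (case-insensitive, 'Slow-4' == 'slow4')."""
    if isinstance(band, FrequencyBand):
        return band
    key = str(band).lower().replace("-", "").replace("_", "")
    if key not in BAND_REGISTRY:
        raise KeyError(f"unknown band {band!r}; known: {sorted(BAND_REGISTRY)}")
    return BAND_REGISTRY[key]


def band_bin_mask(n_timepoints: int, band: "FrequencyBand | str", tr_seconds: float) -> np.ndarray:
    """Boolean pass mask over the rfft bins of an n-point series.

    Half-open [low, high); the Nyquist bin is included only when the band's
    upper edge equals Nyquist; the 0 Hz bin is always excluded.
    """
    band = get_band(band)
    band.validate_for_tr(tr_seconds)
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
    nyq = 0.5 / tr_seconds
    keep = (freqs >= band.low_hz - 1e-12) & (freqs < band.high_hz - 1e-12)
    if abs(band.high_hz - nyq) < 1e-12:
        keep |= np.isclose(freqs, nyq)
    keep[0] = False
    return keep


def bandpass_fft(
    series: np.ndarray, band: "FrequencyBand | str", tr_seconds: float
) -> np.ndarray:
    """Ideal (rectangular) frequency-domain band-pass along the last axis.

    Real FFT, zero every bin outside the band per :func:`band_bin_mask`,
    inverse FFT. Output is zero-mean (the DC bin is always removed).

    Parameters
    ----------
    series
        Array with time on the last axis, length >= 8.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if n < 8:
        raise ValueError(f"series too short for band-pass filtering ({n} < 8 points)")
    keep = band_bin_mask(n, band, tr_seconds)
    spec = np.fft.rfft(series, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)
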