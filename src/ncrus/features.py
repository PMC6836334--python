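"""Resonance-derived parameters of a transmission-coefficient spectrum.

Four parameters summarize the first thickness resonance: the maximum of the
dB magnitude, the frequency and the phase at that maximum, and the normalized
-6 dB bandwidth — the separation of the frequencies at which the magnitude
first falls 6 dB below the peak, divided by the peak frequency. The bandwidth
is a damping (inverse-Q) proxy and grows as a leaf dries and its attenuation
rises.

For the sub-wavelength leaves measured here the fundamental dominates the
whole analyzed window, so the "first resonance" is operationalized as the
global magnitude maximum; a first-local-maximum alternative is available via
``peak_mode="first-local"`` for spectra where higher resonances compete.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateSpectrumError
from .preprocess import ResampledSpectrum

__all__ = [
    "ResonanceFeatures",
    "locate_peak",
    "bandwidth_minus6db",
    "extract_features",
    "features_table",
    "write_features_csv",
]

#: Bandwidth threshold below the peak, in dB on the magnitude channel.
BANDWIDTH_DROP_DB = 6.0


@dataclass(frozen=True)
class ResonanceFeatures:
    """The four resonance-derived parameters of one sample.

    ``norm_bandwidth`` is NaN and ``defined`` False when a -6 dB crossing is
    missing on either side of the peak within the grid; such samples are
    excluded from feature-based regression.
    """

    peak_magnitude: float
    peak_frequency: float
    peak_phase: float
    norm_bandwidth: float
    defined: bool

    def as_vector(self) -> np.ndarray:
        return np.array(
            [self.peak_magnitude, self.peak_frequency, self.peak_phase, self.norm_bandwidth]
        )


def locate_peak(
    spec: ResampledSpectrum, peak_mode: str = "global"
) -> tuple[int, float, float, float]:
    """Locate the resonance peak of the magnitude channel.

    Returns ``(index, peak_frequency, peak_magnitude, peak_phase)``. Ties are
    broken toward the lowest frequency. ``peak_mode="first-local"`` returns
    the lowest-frequency strict local maximum instead of the global one.
    """
    mag = np.asarray(spec.magnitude_db)
    if mag.size == 0:
        raise DegenerateSpectrumError("empty magnitude channel")
    if np.all(mag == mag[0]):
        raise DegenerateSpectrumError("flat magnitude spectrum has no peak")
    if peak_mode == "global":
        idx = int(np.argmax(mag))  # argmax returns the first (lowest-f) maximum
    elif peak_mode == "first-local":
        interior = np.flatnonzero(
            (mag[1:-1] > mag[:-2]) & (mag[1:-1] >= mag[2:])
        )
        idx = int(interior[0]) + 1 if interior.size else int(np.argmax(mag))
    else:
        raise ValueError(f"unknown peak_mode {peak_mode!r}")
    return idx, float(spec.grid[idx]), float(mag[idx]), float(spec.phase_rad[idx])


def bandwidth_minus6db(spec: ResampledSpectrum, peak_index: int) -> float:
    """Normalized -6 dB bandwidth around the peak.

    Scans outward from the peak for the first sample on each side whose
    magnitude falls below ``peak - 6 dB``; the crossing frequency is found by
    linear interpolation between that sample and its inward neighbour.
    Returns ``(f_hi - f_lo) / f_peak``, or NaN when either side never crosses
    within the grid (one-sided-undefined).
    """
    mag = np.asarray(spec.magnitude_db)
    f = np.asarray(spec.grid)
    peak_mag = mag[peak_index]
    threshold = peak_mag - BANDWIDTH_DROP_DB

    def crossing(direction: int) -> float:
        i = peak_index
        while 0 <= i + direction < mag.size:
            i += direction
            if mag[i] < threshold:
                inner = i - direction
                # linear interpolation between the bracketing samples
                frac = (mag[inner] - threshold) / (mag[inner] - mag[i])
                return float(f[inner] + frac * (f[i] - f[inner]))
            if mag[i] == threshold:
                return float(f[i])
        return np.nan

    f_lo = crossing(-1)
    f_hi = crossing(+1)
    if np.isnan(f_lo) or np.isnan(f_hi):
        return np.nan
    return (f_hi - f_lo) / float(f[peak_index])


def extract_features(spec: ResampledSpectrum, peak_mode: str = "global") -> ResonanceFeatures:
    """The four resonance parameters of one resampled spectrum."""
    idx, f_peak, m_peak, p_peak = locate_peak(spec, peak_mode)
    bw = bandwidth_minus6db(spec, idx)
    return ResonanceFeatures(
        peak_magnitude=m_peak,
        peak_frequency=f_peak,
        peak_phase=p_peak,
        norm_bandwidth=float(bw),
        defined=bool(np.isfinite(bw)),
    )


def features_table(samples: Iterable[ResampledSpectrum]) -> pd.DataFrame:
    """Feature rows for a sequence of samples (one row per interpolated sample)."""
    rows = []
    for s in samples:
        ft = extract_features(s)
        rows.append(
            dict(
                leaf_id=s.source[0],
                measurement_idx=s.source[1],
                method=s.method,
                peak_magnitude_db=ft.peak_magnitude,
                peak_frequency_hz=ft.peak_frequency,
                peak_phase_rad=ft.peak_phase,
                norm_bandwidth=ft.norm_bandwidth,
                defined_flag=ft.defined,
            )
        )
    return pd.DataFrame(rows)


def write_features_csv(samples: Sequence[ResampledSpectrum], path: str | Path) -> None:
    features_table(samples).to_csv(path, index=False)
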