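"""Assembly of fixed-size two-channel model inputs from band spectra.

The three transducer bands of one acquisition are concatenated into a single
frequency-sorted transmission coefficient, then interpolated onto a common
601-point grid (100 kHz to 1.6 MHz, 2.5 kHz step) with seven different
interpolation methods. The seven interpolants of one measurement are treated
as seven distinct samples — a x7 data-augmentation strategy in which the
small perturbations stand in for acquisition-time variability.

Phase is unwrapped per band before concatenation; interpolating wrapped phase
across +/-pi discontinuities is meaningless. Below the lowest measured
frequency (the grid starts at 100 kHz, the lowest transducer at 150 kHz),
every method holds the nearest measured value — splines extrapolate wildly
and no method has data there.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import Akima1DInterpolator, CubicSpline, PchipInterpolator

from .errors import (
    AlignmentError,
    ConfigurationError,
    DataQualityError,
    IncompleteMeasurementError,
)
from .simulate import BandSpectrum, LeafRecord

__all__ = [
    "GRID",
    "INTERPOLATION_METHODS",
    "ConcatSpectrum",
    "ResampledSpectrum",
    "apply_calibration",
    "concatenate_bands",
    "resample",
    "augment",
    "augment_dataset",
    "write_samples_csv",
    "read_samples_csv",
]

#: The common model-input frequency grid: 601 points, 100 kHz .. 1.6 MHz, 2.5 kHz step.
GRID: np.ndarray = np.linspace(100e3, 1.6e6, 601)
GRID.setflags(write=False)

#: Fixed augmentation order of the seven interpolation methods.
INTERPOLATION_METHODS: tuple[str, ...] = (
    "linear", "cubic", "splines", "nearest", "next", "previous", "akima",
)

#: Minimum frequency support a measurement must cover to be resampled.
_MIN_SUPPORT = (0.35e6, 1.2e6)


@dataclass(frozen=True)
class ConcatSpectrum:
    """Three bands pooled into one frequency-sorted transmission coefficient."""

    frequencies: np.ndarray
    magnitude_db: np.ndarray
    phase_rad: np.ndarray


@dataclass(frozen=True)
class ResampledSpectrum:
    """One interpolated [601 x 2] model input.

    ``grid`` is the shared read-only :data:`GRID`; ``method`` tags which of the
    seven interpolants produced it; ``source`` is ``(leaf_id, measurement_idx)``.
    """

    grid: np.ndarray
    magnitude_db: np.ndarray
    phase_rad: np.ndarray
    method: str
    source: tuple[str, int]


def apply_calibration(raw_band: BandSpectrum, calibration_band: BandSpectrum) -> BandSpectrum:
    """Reference a raw band spectrum to its no-sample calibration.

    The transmission coefficient is the element-wise difference
    measurement - calibration in both dB magnitude and phase; both spectra
    must share one frequency grid. The synthetic generator emits
    already-calibrated coefficients, so this is the real-data ingestion path.
    """
    if raw_band.frequencies.shape != calibration_band.frequencies.shape or not np.array_equal(
        raw_band.frequencies, calibration_band.frequencies
    ):
        raise AlignmentError("measurement and calibration grids differ")
    return BandSpectrum(
        band_id=raw_band.band_id,
        frequencies=raw_band.frequencies,
        magnitude_db=raw_band.magnitude_db - calibration_band.magnitude_db,
        phase_rad=raw_band.phase_rad - calibration_band.phase_rad,
    )


def concatenate_bands(bands: Sequence[BandSpectrum]) -> ConcatSpectrum:
    """Pool three band spectra into one ascending-frequency spectrum.

    Phase is unwrapped within each band first. Points are sorted by frequency;
    where two bands sample *exactly* the same frequency the channels are
    averaged so the result is strictly increasing. Overlapping band ranges
    with distinct frequencies are all retained. Output is independent of the
    input band order (ties across bands are averaged, not ordered).
    """
    if len(bands) != 3 or len({b.band_id for b in bands}) != 3:
        raise IncompleteMeasurementError("need exactly 3 spectra with distinct band ids")
    f = np.concatenate([b.frequencies for b in bands])
    m = np.concatenate([b.magnitude_db for b in bands])
    p = np.concatenate([np.unwrap(b.phase_rad) for b in bands])
    order = np.argsort(f, kind="stable")
    f, m, p = f[order], m[order], p[order]
    uniq, inverse, counts = np.unique(f, return_inverse=True, return_counts=True)
    if uniq.size != f.size:
        m = np.bincount(inverse, weights=m) / counts
        p = np.bincount(inverse, weights=p) / counts
        f = uniq
    return ConcatSpectrum(frequencies=f, magnitude_db=m, phase_rad=p)


def _step_interp(x: np.ndarray, y: np.ndarray, q: np.ndarray, kind: str) -> np.ndarray:
    """Piecewise-constant interpolation: nearest / next / previous knot value."""
    if kind == "previous":
        idx = np.searchsorted(x, q, side="right") - 1
    elif kind == "next":
        idx = np.searchsorted(x, q, side="left")
    else:  # nearest; ties toward the lower knot
        right = np.clip(np.searchsorted(x, q, side="left"), 1, x.size - 1)
        left = right - 1
        idx = np.where(q - x[left] <= x[right] - q, left, right)
    return y[np.clip(idx, 0, x.size - 1)]


def _interp_channel(x: np.ndarray, y: np.ndarray, q: np.ndarray, method: str) -> np.ndarray:
    if method == "linear":
        return np.interp(q, x, y)
    if method == "cubic":
        return PchipInterpolator(x, y)(q)
    if method == "splines":
        return CubicSpline(x, y, bc_type="not-a-knot")(q)
    if method == "akima":
        return Akima1DInterpolator(x, y)(q)
    if method in ("nearest", "next", "previous"):
        return _step_interp(x, y, q, method)
    raise ConfigurationError(f"unknown interpolation method {method!r}")


def resample(spec: ConcatSpectrum, method: str,
             source: tuple[str, int] = ("", -1)) -> ResampledSpectrum:
    """Interpolate a concatenated spectrum onto the common 601-point grid.

    ``method`` is one of :data:`INTERPOLATION_METHODS`; ``cubic`` is the
    shape-preserving piecewise-cubic Hermite family and ``splines`` the
    not-a-knot cubic spline, the two distinct cubic families of common
    numerical tool-kits. Outside the measured support the nearest measured
    value is held for all methods.
    """
    if method not in INTERPOLATION_METHODS:
        raise ConfigurationError(
            f"unknown interpolation method {method!r}; expected one of {INTERPOLATION_METHODS}"
        )
    f, m, p = spec.frequencies, spec.magnitude_db, spec.phase_rad
    if f.size < 4:
        raise DataQualityError("need at least 4 points to resample")
    if f[0] > _MIN_SUPPORT[0] or f[-1] < _MIN_SUPPORT[1]:
        raise DataQualityError(
            f"support [{f[0]:.3g}, {f[-1]:.3g}] Hz narrower than "
            f"[{_MIN_SUPPORT[0]:.3g}, {_MIN_SUPPORT[1]:.3g}] Hz"
        )
    q = np.clip(GRID, f[0], f[-1])  # nearest-value hold outside the support
    return ResampledSpectrum(
        grid=GRID,
        magnitude_db=_interp_channel(f, m, q, method),
        phase_rad=_interp_channel(f, p, q, method),
        method=method,
        source=source,
    )


def augment(spec: ConcatSpectrum, source: tuple[str, int] = ("", -1)) -> list[ResampledSpectrum]:
    """All seven interpolated versions of one measurement, in the fixed order."""
    return [resample(spec, method, source) for method in INTERPOLATION_METHODS]


def augment_dataset(records: Iterable[LeafRecord]) -> list[ResampledSpectrum]:
    """Concatenate and augment every measurement of a dataset (x7 samples)."""
    samples: list[ResampledSpectrum] = []
    for rec in records:
        for m_idx, meas in enumerate(rec.measurements):
            spec = concatenate_bands(meas.bands)
            samples.extend(augment(spec, (rec.leaf_id, m_idx)))
    return samples


def write_samples_csv(samples: Sequence[ResampledSpectrum], path: str | Path) -> None:
    """Write resampled samples as one wide CSV row per sample."""
    cols = (
        ["leaf_id", "measurement_idx", "method"]
        + [f"mag_{i:03d}" for i in range(GRID.size)]
        + [f"phase_{i:03d}" for i in range(GRID.size)]
    )
    rows = [
        [s.source[0], s.source[1], s.method, *s.magnitude_db, *s.phase_rad] for s in samples
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_samples_csv(path: str | Path) -> list[ResampledSpectrum]:
    """Read samples written by :func:`write_samples_csv`."""
    df = pd.read_csv(path)
    n = GRID.size
    mag_cols = [f"mag_{i:03d}" for i in range(n)]
    phase_cols = [f"phase_{i:03d}" for i in range(n)]
    return [
        ResampledSpectrum(
            grid=GRID,
            magnitude_db=row[mag_cols].to_numpy(dtype=float),
            phase_rad=row[phase_cols].to_numpy(dtype=float),
            method=row["method"],
            source=(row["leaf_id"], int(row["measurement_idx"])),
        )
        for _, row in df.iterrows()
    ]
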