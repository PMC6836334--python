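"""Synthetic drying experiments for air-coupled resonant ultrasound spectroscopy.

A leaf placed between a pair of air-coupled transducers acts, acoustically, as a
thin lossy plate: the through-transmission coefficient shows maxima at the
thickness resonances f_n = n*c/(2h) and the position, height and width of the
first resonance track the leaf's hydration state. This module generates fully
annotated synthetic drying experiments with that structure: per-leaf acoustic
traits, descending relative-water-content (RWC) trajectories, the associated
masses, and per-band transmission-coefficient spectra from a normal-incidence
single-layer forward model plus measurement noise.

The generator emits *calibrated* transmission coefficients (the through-air
reference already subtracted), which is what the downstream preprocessing
consumes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, IntegrityError, InvalidAnnotationError

__all__ = [
    "AIR_IMPEDANCE",
    "ATTENUATION_REF_HZ",
    "BAND_DEFS",
    "BandSpectrum",
    "LayerState",
    "LeafTraits",
    "Measurement",
    "LeafRecord",
    "NoiseConfig",
    "TraitPriors",
    "compute_rwc",
    "plate_transmission",
    "traits_at_rwc",
    "first_resonance_frequency",
    "simulate_measurement",
    "sample_leaf_traits",
    "simulate_dataset",
    "write_dataset_csv",
    "read_dataset_csv",
]

#: Characteristic acoustic impedance of air at room conditions (Pa s/m).
AIR_IMPEDANCE = 415.0

#: Reference frequency for the attenuation coefficient (Hz); attenuation is
#: specified at this frequency and scales linearly with frequency.
ATTENUATION_REF_HZ = 1.0e6

#: Nominal transducer bands: id -> (f_min Hz, f_max Hz, native grid points).
#: Native grids are log-uniform so the later fixed-step resampling is a genuine
#: interpolation rather than a copy.
BAND_DEFS: dict[str, tuple[float, float, int]] = {
    "low": (0.15e6, 0.35e6, 81),
    "mid": (0.35e6, 0.95e6, 121),
    "high": (0.5e6, 1.6e6, 111),
}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LeafTraits:
    """Acoustic and gravimetric endpoints of one leaf.

    The ``*_turgid`` fields describe the fully hydrated leaf (RWC = 1) and the
    ``*_dry`` fields the oven-dry leaf (RWC = 0); intermediate hydration states
    are obtained by :func:`traits_at_rwc`. Attenuation values are in Np/m at
    :data:`ATTENUATION_REF_HZ`.
    """

    leaf_id: str
    thickness_turgid: float
    thickness_dry: float
    speed_turgid: float
    speed_dry: float
    density_turgid: float
    density_dry: float
    attenuation_turgid: float
    attenuation_dry: float
    turgid_mass: float
    dry_mass: float

    def __post_init__(self) -> None:
        vals = [
            self.thickness_turgid, self.thickness_dry,
            self.speed_turgid, self.speed_dry,
            self.density_turgid, self.density_dry,
            self.attenuation_turgid, self.attenuation_dry,
            self.turgid_mass, self.dry_mass,
        ]
        if any(v <= 0 for v in vals):
            raise InvalidAnnotationError(f"leaf {self.leaf_id}: all traits must be positive")
        if self.thickness_dry >= self.thickness_turgid:
            raise InvalidAnnotationError(f"leaf {self.leaf_id}: dry thickness must be below turgid")
        if self.dry_mass >= self.turgid_mass:
            raise InvalidAnnotationError(f"leaf {self.leaf_id}: dry mass must be below turgid mass")


@dataclass(frozen=True)
class LayerState:
    """Effective single-layer acoustic state of a leaf at one hydration level."""

    thickness: float
    speed: float
    density: float
    attenuation: float
    rwc: float

    def __post_init__(self) -> None:
        if min(self.thickness, self.speed, self.density) <= 0 or self.attenuation < 0:
            raise InvalidAnnotationError("layer state quantities must be positive "
                                         "(attenuation may be zero for the lossless limit)")
        if not 0 < self.rwc <= 1.02:
            raise InvalidAnnotationError(f"rwc {self.rwc} outside (0, 1.02]")


@dataclass(frozen=True)
class BandSpectrum:
    """One transducer band's sampled, calibration-referenced transmission coefficient."""

    band_id: str
    frequencies: np.ndarray
    magnitude_db: np.ndarray
    phase_rad: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        m = np.asarray(self.magnitude_db, dtype=float)
        p = np.asarray(self.phase_rad, dtype=float)
        if not (f.shape == m.shape == p.shape) or f.size < 2:
            raise IntegrityError("band channels must share one length >= 2")
        if np.any(np.diff(f) <= 0):
            raise IntegrityError("band frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "magnitude_db", m)
        object.__setattr__(self, "phase_rad", p)


@dataclass(frozen=True)
class Measurement:
    """One paired mass + three-band spectral acquisition during drying."""

    fresh_mass: float
    rwc: float
    bands: tuple[BandSpectrum, ...]

    def __post_init__(self) -> None:
        ids = [b.band_id for b in self.bands]
        if len(self.bands) != 3 or len(set(ids)) != 3:
            raise IntegrityError("a measurement needs exactly 3 distinct-band spectra")


@dataclass(frozen=True)
class LeafRecord:
    """One leaf's identity, reference masses and drying sequence."""

    leaf_id: str
    turgid_mass: float
    dry_mass: float
    measurements: tuple[Measurement, ...]

    def __post_init__(self) -> None:
        if self.dry_mass >= self.turgid_mass:
            raise InvalidAnnotationError(f"leaf {self.leaf_id}: DM must be < TM")
        for m in self.measurements:
            expected = compute_rwc(m.fresh_mass, self.turgid_mass, self.dry_mass)
            if abs(expected - m.rwc) > 1e-12:
                raise IntegrityError(
                    f"leaf {self.leaf_id}: annotated rwc {m.rwc} inconsistent with masses"
                )


@dataclass(frozen=True)
class NoiseConfig:
    """Additive measurement-noise model.

    Gaussian noise is added independently to the dB magnitude and to the phase;
    its standard deviation is doubled over the outer ``edge_fraction`` of each
    band's points to mimic transducer sensitivity roll-off near the band edges.
    """

    magnitude_db_std: float = 0.5
    phase_rad_std: float = 0.05
    edge_fraction: float = 0.10
    edge_factor: float = 2.0


# ---------------------------------------------------------------------------
# Core physics
# ---------------------------------------------------------------------------


def compute_rwc(fm: float, tm: float, dm: float) -> float:
    """Relative water content RWC = (FM - DM) / (TM - DM).

    FM is the fresh mass at measurement time, TM the fully turgid mass and DM
    the oven-dry mass, all in grams. The value is returned unclamped; values
    outside [-0.02, 1.05] trigger a measurement-artifact warning.
    """
    if tm <= dm:
        raise InvalidAnnotationError(f"turgid mass {tm} must exceed dry mass {dm}")
    if fm <= 0:
        raise InvalidAnnotationError(f"fresh mass must be positive, got {fm}")
    rwc = (fm - dm) / (tm - dm)
    if not -0.02 <= rwc <= 1.05:
        warnings.warn(
            f"RWC {rwc:.4f} outside [-0.02, 1.05]; likely a measurement artifact",
            stacklevel=2,
        )
    return rwc


def plate_transmission(
    frequencies: np.ndarray,
    state: LayerState,
    medium_impedance: float = AIR_IMPEDANCE,
) -> tuple[np.ndarray, np.ndarray]:
    """Normal-incidence transmission coefficient of a homogeneous lossy plate.

    For a plate of thickness h, sound speed c, density rho and attenuation
    alpha(f) = alpha_ref * f / f_ref immersed in a medium of impedance Z,

        T(f) = 1 / [cos(k h) + (i/2) (z + 1/z) sin(k h)],

    with impedance ratio z = rho c / Z and complex wavenumber
    k = 2 pi f / c - i alpha(f) (exp(+i omega t) time convention, so a
    positive alpha attenuates). Returns ``(magnitude_db, phase_rad)`` where
    the magnitude is 20 log10 |T| and the phase is the unwrapped argument of T.
    |T| <= 1 for every passive (alpha >= 0) state.
    """
    if medium_impedance <= 0:
        raise ConfigurationError(f"medium impedance must be positive, got {medium_impedance}")
    f = np.asarray(frequencies, dtype=float)
    if f.ndim != 1 or np.any(f <= 0) or np.any(np.diff(f) <= 0):
        raise ConfigurationError("frequencies must be a positive ascending 1-D sequence")
    z = state.density * state.speed / medium_impedance
    alpha = state.attenuation * f / ATTENUATION_REF_HZ
    k = 2.0 * np.pi * f / state.speed - 1j * alpha
    kh = k * state.thickness
    denom = np.cos(kh) + 0.5j * (z + 1.0 / z) * np.sin(kh)
    t = 1.0 / denom
    magnitude_db = 20.0 * np.log10(np.abs(t))
    phase_rad = np.unwrap(np.angle(t))
    return magnitude_db, phase_rad


def traits_at_rwc(traits: LeafTraits, rwc: float) -> LayerState:
    """Effective layer state of a leaf at hydration ``rwc``.

    Thickness, speed, density and attenuation interpolate linearly between the
    dry (rwc = 0) and turgid (rwc = 1) endpoints; values slightly above 1
    (supersaturated leaves, up to 1.02) extrapolate the same line. Because the
    dry->turgid thickness contrast always exceeds the speed contrast under the
    default priors, the first-resonance frequency c/(2h) is strictly decreasing
    in rwc.
    """
    if not 0 < rwc <= 1.02:
        raise InvalidAnnotationError(f"rwc {rwc} outside (0, 1.02]")

    def lerp(dry: float, turgid: float) -> float:
        return dry + rwc * (turgid - dry)

    return LayerState(
        thickness=lerp(traits.thickness_dry, traits.thickness_turgid),
        speed=lerp(traits.speed_dry, traits.speed_turgid),
        density=lerp(traits.density_dry, traits.density_turgid),
        attenuation=lerp(traits.attenuation_dry, traits.attenuation_turgid),
        rwc=rwc,
    )


def first_resonance_frequency(state: LayerState) -> float:
    """Lossless first thickness-resonance frequency f_1 = c / (2 h)."""
    return state.speed / (2.0 * state.thickness)


# ---------------------------------------------------------------------------
# Measurement and dataset synthesis
# ---------------------------------------------------------------------------


def band_grid(band_id: str) -> np.ndarray:
    """Native log-uniform frequency grid of one transducer band."""
    try:
        f_min, f_max, n = BAND_DEFS[band_id]
    except KeyError:
        raise ConfigurationError(f"unknown band id {band_id!r}") from None
    return np.geomspace(f_min, f_max, n)


def simulate_measurement(
    traits: LeafTraits,
    rwc: float,
    noise_cfg: NoiseConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[BandSpectrum, ...]:
    """Three-band noisy acquisition of one leaf at one hydration state.

    Evaluates :func:`plate_transmission` on each band's native grid and adds
    independent Gaussian noise per :class:`NoiseConfig`. With a zero-noise
    config the output is bit-identical to the forward model.
    """
    noise_cfg = noise_cfg or NoiseConfig()
    state = traits_at_rwc(traits, rwc)
    needs_rng = noise_cfg.magnitude_db_std > 0 or noise_cfg.phase_rad_std > 0
    if rng is None and needs_rng:
        raise ConfigurationError("an rng is required when noise is enabled")
    bands = []
    for band_id in BAND_DEFS:
        f = band_grid(band_id)
        mag, ph = plate_transmission(f, state)
        if needs_rng:
            n = f.size
            scale = np.ones(n)
            edge = int(np.floor(noise_cfg.edge_fraction * n))
            if edge > 0:
                scale[:edge] = noise_cfg.edge_factor
                scale[-edge:] = noise_cfg.edge_factor
            mag = mag + rng.normal(0.0, noise_cfg.magnitude_db_std, n) * scale
            ph = ph + rng.normal(0.0, noise_cfg.phase_rad_std, n) * scale
        bands.append(BandSpectrum(band_id, f, mag, ph))
    return tuple(bands)


@dataclass(frozen=True)
class TraitPriors:
    """Sampling ranges for per-leaf traits.

    Thickness in metres, speed in m/s, density in kg/m^3, attenuation in Np/m
    at 1 MHz, masses in grams. ``*_ratio`` ranges give the dry value as a
    multiple of the turgid one. The defaults keep the first thickness
    resonance inside the measured 0.15-1.6 MHz window over RWC in [0.5, 1] and
    guarantee a strictly decreasing f_1(rwc) (thickness shrinks faster on
    drying than sound speed drops).

    The spread of the ranges models mature leaves of a single species grown at
    one site (trait coefficients of variation of a few percent). That keeps
    the leaf-to-leaf variation of the spectra comparable to, not larger than,
    the hydration-driven variation within a leaf — the structure that makes a
    model trained on some leaves transferable to an unseen one, which is the
    regime this dataset emulates.
    """

    thickness_turgid: tuple[float, float] = (360e-6, 410e-6)
    thickness_dry_ratio: tuple[float, float] = (0.54, 0.60)
    speed_turgid: tuple[float, float] = (295.0, 325.0)
    speed_dry_ratio: tuple[float, float] = (0.85, 0.89)
    density_turgid: tuple[float, float] = (950.0, 1050.0)
    density_dry_ratio: tuple[float, float] = (0.58, 0.66)
    attenuation_turgid: tuple[float, float] = (480.0, 620.0)
    attenuation_dry_ratio: tuple[float, float] = (1.9, 2.2)
    dry_mass: tuple[float, float] = (0.2, 0.5)
    turgid_over_dry_mass: tuple[float, float] = (2.2, 3.2)


def sample_leaf_traits(
    leaf_id: str, rng: np.random.Generator, priors: TraitPriors | None = None
) -> LeafTraits:
    """Draw one leaf's traits from the priors."""
    p = priors or TraitPriors()
    u = lambda lohi: rng.uniform(*lohi)  # noqa: E731
    h_t = u(p.thickness_turgid)
    c_t = u(p.speed_turgid)
    rho_t = u(p.density_turgid)
    a_t = u(p.attenuation_turgid)
    dm = u(p.dry_mass)
    return LeafTraits(
        leaf_id=leaf_id,
        thickness_turgid=h_t,
        thickness_dry=h_t * u(p.thickness_dry_ratio),
        speed_turgid=c_t,
        speed_dry=c_t * u(p.speed_dry_ratio),
        density_turgid=rho_t,
        density_dry=rho_t * u(p.density_dry_ratio),
        attenuation_turgid=a_t,
        attenuation_dry=a_t * u(p.attenuation_dry_ratio),
        turgid_mass=dm * u(p.turgid_over_dry_mass),
        dry_mass=dm,
    )


def _draw_rwc(rng: np.random.Generator, size: int, mixture: tuple[float, float, float, float]
              ) -> np.ndarray:
    """Two-component uniform mixture over RWC.

    ``mixture = (p_upper, lower_min, split, upper_max)``: mass ``p_upper`` is
    uniform on [split, upper_max] and the rest uniform on [lower_min, split).
    """
    p_upper, lo, split, hi = mixture
    upper = rng.random(size) < p_upper
    vals = np.where(
        upper,
        rng.uniform(split, hi, size),
        rng.uniform(lo, split, size),
    )
    return vals


def simulate_dataset(
    n_leaves: int = 31,
    measurements_per_leaf_range: tuple[int, int] = (7, 11),
    rwc_mixture: tuple[float, float, float, float] = (0.63, 0.52, 0.88, 1.0),
    seed: int = 0,
    noise_cfg: NoiseConfig | None = None,
    priors: TraitPriors | None = None,
    total_measurements: int | None = None,
) -> list[LeafRecord]:
    """Generate a full annotated drying experiment.

    Defaults emulate the study conditions: 31 leaves, around nine drying
    states each for 280 measurements in total, and an RWC distribution with
    63% of its mass above the turgor-loss point (RWC in [0.88, 1]) and the
    rest on [0.52, 0.88). Each leaf's RWC trajectory is sorted descending
    (drying order) and fresh masses are back-computed as
    FM = DM + rwc * (TM - DM) so :func:`compute_rwc` round-trips exactly.
    The output is fully determined by ``seed``.
    """
    if n_leaves < 2:
        raise ConfigurationError("need at least 2 leaves")
    lo, hi = measurements_per_leaf_range
    if not (1 <= lo <= hi):
        raise ConfigurationError(f"invalid measurements-per-leaf range {measurements_per_leaf_range}")
    p_upper, r_lo, r_split, r_hi = rwc_mixture
    if not (0 < p_upper < 1 and 0.0 < r_lo < r_split < r_hi <= 1.02):
        raise ConfigurationError(f"invalid rwc mixture {rwc_mixture}")
    if total_measurements is None:
        total_measurements = int(round(n_leaves * 280 / 31))
    if not lo * n_leaves <= total_measurements <= hi * n_leaves:
        raise ConfigurationError(
            f"total {total_measurements} infeasible for {n_leaves} leaves in range {lo}-{hi}"
        )

    rng = np.random.default_rng(seed)
    counts = rng.integers(lo, hi + 1, n_leaves)
    # Nudge random counts until the configured total is hit exactly.
    while counts.sum() != total_measurements:
        i = int(rng.integers(n_leaves))
        if counts.sum() < total_measurements and counts[i] < hi:
            counts[i] += 1
        elif counts.sum() > total_measurements and counts[i] > lo:
            counts[i] -= 1

    records = []
    for i in range(n_leaves):
        leaf_id = f"leaf{i + 1:02d}"
        traits = sample_leaf_traits(leaf_id, rng, priors)
        rwcs = np.sort(_draw_rwc(rng, int(counts[i]), rwc_mixture))[::-1]
        measurements = []
        for rwc in rwcs:
            fm = traits.dry_mass + rwc * (traits.turgid_mass - traits.dry_mass)
            rwc_exact = compute_rwc(fm, traits.turgid_mass, traits.dry_mass)
            bands = simulate_measurement(traits, rwc_exact, noise_cfg, rng)
            measurements.append(Measurement(fresh_mass=fm, rwc=rwc_exact, bands=bands))
        records.append(
            LeafRecord(
                leaf_id=leaf_id,
                turgid_mass=traits.turgid_mass,
                dry_mass=traits.dry_mass,
                measurements=tuple(measurements),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def write_dataset_csv(records: Sequence[LeafRecord], out_dir: str | Path,
                      config: dict | None = None) -> None:
    """Write a dataset as long-format CSVs plus a JSON config sidecar.

    ``spectra.csv``: leaf_id, measurement_idx, band_id, frequency_hz,
    magnitude_db, phase_rad. ``annotations.csv``: leaf_id, measurement_idx,
    fm_g, tm_g, dm_g, rwc. ``generator.json``: the generator configuration.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spec_rows, ann_rows = [], []
    for rec in records:
        for m_idx, m in enumerate(rec.measurements):
            ann_rows.append(
                dict(leaf_id=rec.leaf_id, measurement_idx=m_idx, fm_g=m.fresh_mass,
                     tm_g=rec.turgid_mass, dm_g=rec.dry_mass, rwc=m.rwc)
            )
            for band in m.bands:
                for f, mag, ph in zip(band.frequencies, band.magnitude_db, band.phase_rad):
                    spec_rows.append(
                        dict(leaf_id=rec.leaf_id, measurement_idx=m_idx, band_id=band.band_id,
                             frequency_hz=f, magnitude_db=mag, phase_rad=ph)
                    )
    pd.DataFrame(spec_rows).to_csv(out / "spectra.csv", index=False)
    pd.DataFrame(ann_rows).to_csv(out / "annotations.csv", index=False)
    (out / "generator.json").write_text(json.dumps(config or {}, indent=2))


def read_dataset_csv(in_dir: str | Path) -> list[LeafRecord]:
    """Read a dataset written by :func:`write_dataset_csv`."""
    src = Path(in_dir)
    spectra = pd.read_csv(src / "spectra.csv")
    ann = pd.read_csv(src / "annotations.csv")
    records = []
    for leaf_id, leaf_ann in ann.groupby("leaf_id", sort=False):
        leaf_spec = spectra[spectra["leaf_id"] == leaf_id]
        measurements = []
        for _, row in leaf_ann.sort_values("measurement_idx").iterrows():
            m_spec = leaf_spec[leaf_spec["measurement_idx"] == row["measurement_idx"]]
            bands = []
            for band_id, b in m_spec.groupby("band_id", sort=False):
                b = b.sort_values("frequency_hz")
                bands.append(
                    BandSpectrum(
                        band_id=str(band_id),
                        frequencies=b["frequency_hz"].to_numpy(),
                        magnitude_db=b["magnitude_db"].to_numpy(),
                        phase_rad=b["phase_rad"].to_numpy(),
                    )
                )
            order = {"low": 0, "mid": 1, "high": 2}
            bands.sort(key=lambda s: order.get(s.band_id, 99))
            measurements.append(
                Measurement(fresh_mass=row["fm_g"], rwc=row["rwc"], bands=tuple(bands))
            )
        records.append(
            LeafRecord(
                leaf_id=str(leaf_id),
                turgid_mass=float(leaf_ann["tm_g"].iloc[0]),
                dry_mass=float(leaf_ann["dm_g"].iloc[0]),
                measurements=tuple(measurements),
            )
        )
    return records
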