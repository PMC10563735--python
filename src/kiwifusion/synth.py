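"""Synthetic postharvest storage experiments.

Generates the full data layout of a kiwifruit ripening study: eight storage
time points (days 0, 2, 5, 8, 11, 14, 17 and 20) with 15 fruits per day
(120 fruits), destructive quality attributes per fruit (flesh firmness in N,
soluble solids content in degrees Brix, titratable acidity in % citric
acid), one 13-channel e-nose recording per fruit, and one 568-band 400-950
nm reflectance spectrum (optionally a small hypercube) per fruit.

Generative model
----------------
* Day-mean attribute trajectories are logistic in storage day (ripening
  plateaus late in storage); each fruit adds an independent Gaussian
  residual per attribute.  The default ranges are calibrated in closed form
  so a one-way ANOVA on the defaults reproduces the between-day sums of
  squares and error mean squares of the reference storage experiment
  (firmness 470.9 / 0.042, SSC 341.1 / 0.089, TA 4.02 / 0.00027 at
  8 x 15 fruits).
* Each fruit emits a single latent aroma intensity: the common logistic
  ripening progress of its storage day plus fruit-level aroma noise.  MOS
  channels respond with first-order exponential rise during headspace
  exposure and exponential decay during purging.
* Reflectance is a smooth continuum plus planted Gaussian absorption
  features whose amplitudes are linear in exactly one quality attribute
  each, plus band noise.  Planted centers lie inside the 450-900 nm working
  range, so they survive trimming.

All randomness flows through ``numpy.random.SeedSequence``; a fixed seed
gives bit-reproducible bundles.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .enose import SENSOR_IDS, Phases, SensorRecording, write_recording_csv
from .hsi import Hypercube, ReflectanceSpectrum, SpectralGrid

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentDesign",
    "AttributeTrajectory",
    "TrajectoryParams",
    "SensorPanel",
    "PlantedBand",
    "SpectralModelParams",
    "ExperimentBundle",
    "ATTRIBUTES",
    "logistic_mean",
    "ripening_progress",
    "generate_quality_trajectories",
    "generate_enose_recording",
    "generate_reflectance_spectrum",
    "generate_hypercube",
    "generate_experiment",
]

ATTRIBUTES: tuple[str, ...] = ("firmness", "ssc", "ta")

#: clip floor for attributes accidentally driven non-positive
_CLIP_FLOOR = 1e-6


def _as_seedseq(seed, default: int = 0) -> np.random.SeedSequence:
    if seed is None:
        seed = default
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


@dataclass(frozen=True)
class ExperimentDesign:
    """Storage experiment layout: sampling days and fruits per day."""

    day_offsets: tuple[int, ...] = (0, 2, 5, 8, 11, 14, 17, 20)
    fruits_per_day: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.day_offsets)
        if len(days) < 2 or any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("day_offsets must be strictly increasing with >= 2 entries")
        if self.fruits_per_day < 1:
            raise ValueError("fruits_per_day must be positive")
        object.__setattr__(self, "day_offsets", days)

    @property
    def n_samples(self) -> int:
        return len(self.day_offsets) * self.fruits_per_day


@dataclass(frozen=True)
class AttributeTrajectory:
    """Logistic day-mean trajectory plus within-day residual SD for one attribute."""

    start: float
    end: float
    midpoint_day: float = 6.0
    rate: float = 0.5          # 1/day
    residual_sd: float = 0.0   # attribute units; 0 gives the noise-free fixture

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual SD must be non-negative")
        if self.rate <= 0:
            raise ValueError("logistic rate must be positive")


def logistic_mean(day, traj: AttributeTrajectory):
    """Day-mean attribute value: ``start + (end - start) * g(day)`` with a
    logistic ``g`` rising from 0 to 1 around ``midpoint_day``."""
    day = np.asarray(day, dtype=float)
    g = 1.0 / (1.0 + np.exp(-traj.rate * (day - traj.midpoint_day)))
    return traj.start + (traj.end - traj.start) * g


def ripening_progress(day, midpoint_day: float = 6.0, rate: float = 0.5):
    """Common logistic ripening progress in [0, 1] shared by all attributes."""
    day = np.asarray(day, dtype=float)
    return 1.0 / (1.0 + np.exp(-rate * (day - midpoint_day)))


@dataclass(frozen=True)
class TrajectoryParams:
    """Per-attribute trajectory parameters.

    Default ranges are solved from ``SS_between = n_per_day * delta^2 *
    sum_d (g_d - g_bar)^2`` with the logistic shape fixed (midpoint day 6,
    rate 0.5/day, shape sum 1.1525 over the default days), matching the
    reference between-day sums of squares; residual SDs are the square roots
    of the reference error mean squares.
    """

    firmness: AttributeTrajectory = field(
        default_factory=lambda: AttributeTrajectory(7.8, 2.6, residual_sd=0.206))
    ssc: AttributeTrajectory = field(
        default_factory=lambda: AttributeTrajectory(7.0, 11.44, residual_sd=0.299))
    ta: AttributeTrajectory = field(
        default_factory=lambda: AttributeTrajectory(1.30, 0.82, residual_sd=0.0164))

    def __post_init__(self) -> None:
        if self.firmness.end >= self.firmness.start:
            raise ValueError("firmness must decrease during storage")
        if self.ssc.end <= self.ssc.start:
            raise ValueError("SSC must increase during storage")
        if self.ta.end >= self.ta.start:
            raise ValueError("TA must decrease during storage")

    def __getitem__(self, attribute: str) -> AttributeTrajectory:
        if attribute not in ATTRIBUTES:
            raise KeyError(attribute)
        return getattr(self, attribute)

    def noise_free(self) -> "TrajectoryParams":
        """Copy with all residual SDs zeroed (exactness fixture)."""
        from dataclasses import replace
        return TrajectoryParams(
            *(replace(self[a], residual_sd=0.0) for a in ATTRIBUTES)
        )


def generate_quality_trajectories(
    design: ExperimentDesign,
    params: TrajectoryParams,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-fruit firmness/SSC/TA table: logistic day mean + Gaussian residual.

    Returns a DataFrame with columns ``fruit_id, day, firmness, ssc, ta``.
    Attributes accidentally driven non-positive are clipped (with a logged
    warning) rather than rejected.
    """
    rng = np.random.default_rng(_as_seedseq(seed, design.seed))
    records = []
    for day in design.day_offsets:
        for k in range(design.fruits_per_day):
            rec = {"fruit_id": f"d{day:02d}f{k + 1:02d}", "day": day}
            for attr in ATTRIBUTES:
                traj = params[attr]
                value = logistic_mean(day, traj) + traj.residual_sd * rng.standard_normal()
                rec[attr] = float(value)
            records.append(rec)
    table = pd.DataFrame.from_records(records)
    low = table[list(ATTRIBUTES)] <= 0
    if low.to_numpy().any():
        n_bad = int(low.to_numpy().sum())
        logger.warning("clipped %d non-positive generated attribute values", n_bad)
        warnings.warn(f"clipped {n_bad} non-positive generated attribute values")
        table[list(ATTRIBUTES)] = table[list(ATTRIBUTES)].clip(lower=_CLIP_FLOOR)
    return table


@dataclass(frozen=True)
class SensorPanel:
    """MOS panel response parameters per channel.

    Baselines are raw response levels; gains are dimensionless aroma
    couplings (the hydrocarbon-sensitive TGS822, TGS2610 and MQ9 carry the
    largest gains by default); rise/decay time constants are in seconds.
    """

    sensor_ids: tuple[str, ...] = SENSOR_IDS
    baseline: tuple[float, ...] = (
        2.0, 1.8, 2.2, 2.1, 1.9, 2.3, 2.4, 2.0, 1.7, 2.6, 2.5, 1.6, 2.2)
    gain: tuple[float, ...] = (
        0.35, 0.30, 0.25, 0.28, 0.20, 0.18, 0.70, 0.32, 0.38, 0.80, 0.75, 0.22, 0.40)
    tau_rise_s: float = 8.0
    tau_decay_s: float = 15.0
    noise_sd: float = 0.02     # raw units

    def __post_init__(self) -> None:
        n = len(self.sensor_ids)
        if n != 13:
            raise ValueError("panel must have exactly 13 channels")
        if len(self.baseline) != n or len(self.gain) != n:
            raise ValueError("per-channel parameter lengths must match the panel")
        if any(b <= 0 for b in self.baseline):
            raise ValueError("baselines must be positive (fractional normalization divides by them)")
        if self.tau_rise_s <= 0 or self.tau_decay_s <= 0:
            raise ValueError("time constants must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")


def generate_enose_recording(
    aroma_intensity: float,
    panel: SensorPanel | None = None,
    rate: float = 1.0,
    seed: int | None = None,
    fruit_id: str | None = None,
) -> SensorRecording:
    """Simulate one 310 s acquisition at ``rate`` samples/s.

    Channels sit at baseline during cleaning, rise first-order toward
    ``baseline * (1 + gain * intensity)`` during the 40 s headspace exposure,
    and decay exponentially back toward baseline during purging.  Gaussian
    sensor noise is added throughout.
    """
    if panel is None:
        panel = SensorPanel()
    if not np.isfinite(aroma_intensity):
        raise ValueError("aroma intensity must be finite")
    if rate <= 0:
        raise ValueError("sampling rate must be positive")
    phases = Phases()
    n = int(round(phases.total * rate)) + 1
    t = np.arange(n) / rate
    base = np.asarray(panel.baseline)[:, None]
    gain = np.asarray(panel.gain)[:, None]
    plateau = base * gain * aroma_intensity       # asymptotic excess response

    x = np.broadcast_to(base, (13, n)).copy()
    rise = (t >= phases.clean_end) & (t <= phases.expose_end)
    x[:, rise] = base + plateau * (
        1.0 - np.exp(-(t[rise] - phases.clean_end) / panel.tau_rise_s))
    at_expose_end = plateau * (
        1.0 - np.exp(-(phases.expose_end - phases.clean_end) / panel.tau_rise_s))
    decay = t > phases.expose_end
    x[:, decay] = base + at_expose_end * np.exp(
        -(t[decay] - phases.expose_end) / panel.tau_decay_s)
    if panel.noise_sd > 0:
        rng = np.random.default_rng(_as_seedseq(seed))
        x = x + panel.noise_sd * rng.standard_normal(x.shape)
    return SensorRecording(x, t, panel.sensor_ids, phases, fruit_id)


@dataclass(frozen=True)
class PlantedBand:
    """One informative Gaussian absorption feature tied to a single driver.

    The driver is one of the three quality attributes, or ``"day"`` for
    optical aging that keeps progressing late in storage (chlorophyll-style
    degradation) after the quality attributes have plateaued.
    """

    center_nm: float
    attribute: str
    gain: float                 # reflectance units per driver unit
    reference: float            # driver level at which the feature vanishes

    def __post_init__(self) -> None:
        if self.attribute not in ATTRIBUTES + ("day",):
            raise ValueError(f"unknown attribute {self.attribute!r}")


def _default_planted() -> tuple[PlantedBand, ...]:
    # Centers >= 20 nm apart inside 450-900 nm, so trimmed spectra keep all
    # of them and neighbouring features barely overlap (sigma = 5 nm).
    return (
        PlantedBand(480.0, "firmness", 0.040, 5.2),
        PlantedBand(530.0, "ssc", 0.028, 9.2),
        PlantedBand(580.0, "ta", 0.60, 1.06),
        PlantedBand(640.0, "firmness", 0.040, 5.2),
        PlantedBand(660.0, "day", 0.004, 10.0),
        PlantedBand(700.0, "ssc", 0.028, 9.2),
        PlantedBand(740.0, "day", 0.004, 10.0),
        PlantedBand(760.0, "ta", 0.60, 1.06),
        PlantedBand(820.0, "firmness", 0.040, 5.2),
        PlantedBand(880.0, "ssc", 0.028, 9.2),
    )


@dataclass(frozen=True)
class SpectralModelParams:
    """Reflectance model: sigmoidal continuum + planted features + noise.

    Two noise sources with different roles: ``noise_sd`` is independent
    per-band read noise, while ``mismatch_sd`` (one SD per attribute, in
    attribute units, ordered firmness/ssc/ta) is a per-fruit optical
    mismatch shared by all bands of that attribute - the skin optics track
    a noisy proxy of the destructive reference value.  Band averaging can
    defeat read noise but not the mismatch, so the mismatch sets the floor
    of spectra-only prediction error.
    """

    grid: SpectralGrid = field(default_factory=SpectralGrid.default)
    planted: tuple[PlantedBand, ...] = field(default_factory=_default_planted)
    sigma_nm: float = 5.0
    noise_sd: float = 0.005
    mismatch_sd: tuple[float, float, float] = (0.5, 0.45, 0.045)
    day_mismatch_sd: float = 0.75
    pixel_noise_sd: float = 0.02
    continuum_base: float = 0.30
    continuum_amplitude: float = 0.35
    continuum_center_nm: float = 550.0
    continuum_scale_nm: float = 60.0

    def __post_init__(self) -> None:
        if (self.noise_sd < 0 or self.pixel_noise_sd < 0
                or min(self.mismatch_sd) < 0 or self.day_mismatch_sd < 0):
            raise ValueError("noise SDs must be non-negative")
        if self.sigma_nm <= 0:
            raise ValueError("planted band width must be positive")
        for band in self.planted:
            if not 450.0 <= band.center_nm <= 900.0:
                raise ValueError(
                    f"planted center {band.center_nm} nm outside the 450-900 nm working range")

    def continuum(self, wavelengths: np.ndarray) -> np.ndarray:
        return self.continuum_base + self.continuum_amplitude / (
            1.0 + np.exp(-(wavelengths - self.continuum_center_nm) / self.continuum_scale_nm))

    def clean_spectrum(self, attributes: Mapping[str, float]) -> np.ndarray:
        """Noise-free reflectance for one fruit (before clipping).

        ``attributes`` must contain every driver used by the planted bands
        (the three quality attributes and, with day-coupled bands, "day").
        """
        wl = self.grid.wavelengths
        r = self.continuum(wl).copy()
        for band in self.planted:
            amp = band.gain * (float(attributes[band.attribute]) - band.reference)
            r -= amp * np.exp(-0.5 * ((wl - band.center_nm) / self.sigma_nm) ** 2)
        return r

    @property
    def drivers(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(b.attribute for b in self.planted))

    def planted_centers(self, attribute: str | None = None) -> np.ndarray:
        centers = [b.center_nm for b in self.planted
                   if attribute is None or b.attribute == attribute]
        return np.asarray(centers)


def _clip_reflectance(r: np.ndarray) -> np.ndarray:
    if (r < 0).any() or (r > 1).any():
        n_bad = int(((r < 0) | (r > 1)).sum())
        logger.warning("clipped %d reflectance values outside [0, 1]", n_bad)
        warnings.warn(f"clipped {n_bad} reflectance values outside [0, 1]")
        r = np.clip(r, 0.0, 1.0)
    return r


def generate_reflectance_spectrum(
    attributes: Mapping[str, float],
    params: SpectralModelParams | None = None,
    seed: int | None = None,
    fruit_id: str | None = None,
) -> ReflectanceSpectrum:
    """ROI-level reflectance spectrum of one fruit (band noise included)."""
    if params is None:
        params = SpectralModelParams()
    required = list(ATTRIBUTES) + (["day"] if "day" in params.drivers else [])
    missing = [a for a in required if a not in attributes]
    if missing:
        raise ValueError(f"attribute record incomplete: missing {missing}")
    rng = np.random.default_rng(_as_seedseq(seed))
    proxy = {a: float(attributes[a]) + sd * rng.standard_normal()
             for a, sd in zip(ATTRIBUTES, params.mismatch_sd)}
    if "day" in params.drivers:
        proxy["day"] = float(attributes["day"]) + params.day_mismatch_sd * rng.standard_normal()
    r = params.clean_spectrum(proxy)
    if params.noise_sd > 0:
        r = r + params.noise_sd * rng.standard_normal(r.shape)
    return ReflectanceSpectrum(_clip_reflectance(r), params.grid, fruit_id=fruit_id)


def generate_hypercube(
    attributes: Mapping[str, float],
    params: SpectralModelParams | None = None,
    shape: tuple[int, int] = (32, 32),
    seed: int | None = None,
) -> tuple[Hypercube, np.ndarray]:
    """Small calibrated hypercube with per-pixel noise, plus a circular fruit mask."""
    if params is None:
        params = SpectralModelParams()
    rows, cols = shape
    rng = np.random.default_rng(_as_seedseq(seed))
    proxy = {a: float(attributes[a]) + sd * rng.standard_normal()
             for a, sd in zip(ATTRIBUTES, params.mismatch_sd)}
    if "day" in params.drivers:
        proxy["day"] = float(attributes["day"]) + params.day_mismatch_sd * rng.standard_normal()
    r = params.clean_spectrum(proxy)
    data = r[None, None, :] + params.pixel_noise_sd * rng.standard_normal((rows, cols, r.size))
    data = _clip_reflectance(data)
    yy, xx = np.mgrid[:rows, :cols]
    radius = 0.45 * min(rows, cols)
    mask = (yy - (rows - 1) / 2) ** 2 + (xx - (cols - 1) / 2) ** 2 <= radius**2
    return Hypercube(data, params.grid, calibrated=True), mask


@dataclass
class ExperimentBundle:
    """One simulated storage experiment: attributes, recordings and spectra."""

    attributes: pd.DataFrame
    recordings: list[SensorRecording]
    spectra: pd.DataFrame               # fruits x bands, columns = wavelength (nm)
    grid: SpectralGrid
    aroma_intensity: pd.Series          # latent scalar per fruit

    def save(self, directory: str | Path) -> None:
        """Serialize to ``attributes.csv``, ``enose/<fruit_id>.csv`` and
        ``spectra.csv`` with stable float formatting."""
        directory = Path(directory)
        (directory / "enose").mkdir(parents=True, exist_ok=True)
        out = self.attributes.rename(columns={
            "firmness": "firmness_N", "ssc": "ssc_brix", "ta": "ta_pct"})
        out.to_csv(directory / "attributes.csv", index=False, float_format="%.9g")
        for rec in self.recordings:
            write_recording_csv(directory / "enose" / f"{rec.fruit_id}.csv", rec)
        spectra = self.spectra.copy()
        spectra.columns = [f"{w:.6f}" for w in self.grid.wavelengths]
        spectra.to_csv(directory / "spectra.csv", float_format="%.9g")


def generate_experiment(
    design: ExperimentDesign | None = None,
    trajectory_params: TrajectoryParams | None = None,
    panel: SensorPanel | None = None,
    spectral_params: SpectralModelParams | None = None,
    seed: int | None = None,
    aroma_noise_sd: float = 0.03,
) -> ExperimentBundle:
    """Generate a full experiment: one recording and one spectrum per fruit.

    The latent aroma intensity of a fruit is the logistic ripening progress
    of its storage day plus fruit-level aroma noise (the nose senses the
    overall ripening state, not the individual attribute residuals).
    """
    design = design or ExperimentDesign()
    trajectory_params = trajectory_params or TrajectoryParams()
    panel = panel or SensorPanel()
    spectral_params = spectral_params or SpectralModelParams()
    root = _as_seedseq(seed, design.seed)
    ss_attr, ss_aroma, ss_enose, ss_spectra = root.spawn(4)

    attributes = generate_quality_trajectories(
        design, trajectory_params, seed=ss_attr)
    mid = trajectory_params.firmness.midpoint_day
    rate = trajectory_params.firmness.rate
    rng_aroma = np.random.default_rng(ss_aroma)
    intensity = ripening_progress(attributes["day"].to_numpy(), mid, rate)
    if aroma_noise_sd < 0:
        raise ValueError("aroma noise SD must be non-negative")
    if aroma_noise_sd > 0:
        intensity = intensity + aroma_noise_sd * rng_aroma.standard_normal(intensity.size)
    intensity = pd.Series(intensity, index=attributes["fruit_id"], name="aroma_intensity")

    recordings = []
    spectra_rows = []
    enose_children = ss_enose.spawn(len(attributes))
    spectra_children = ss_spectra.spawn(len(attributes))
    for (_, row), e_seed, s_seed in zip(attributes.iterrows(), enose_children, spectra_children):
        fid = row["fruit_id"]
        recordings.append(generate_enose_recording(
            float(intensity[fid]), panel, seed=e_seed, fruit_id=fid))
        spec = generate_reflectance_spectrum(
            row[list(ATTRIBUTES) + ["day"]], spectral_params, seed=s_seed, fruit_id=fid)
        spectra_rows.append(spec.values)
    spectra = pd.DataFrame(
        np.vstack(spectra_rows),
        index=pd.Index(attributes["fruit_id"], name="fruit_id"),
        columns=spectral_params.grid.wavelengths,
    )
    return ExperimentBundle(attributes, recordings, spectra, spectral_params.grid, intensity)
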