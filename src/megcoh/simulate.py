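"""Coupled oscillatory source simulation and SNR-calibrated sensor noise.

The study's data generator: two alpha-band (9–14 Hz) oscillators with a
common base frequency whose instantaneous frequency is jittered by smoothed
Gaussian noise.  Independent jitter realizations make the phase relation
between the two oscillators wander, so their magnitude-squared coherence
falls below 1; re-drawing the second oscillator's jitter in a loop until the
band coherence hits a target value produces pairs with prescribed coupling
(0.1 / 0.2 / 0.4 in the study).

Sensor data follow M = L·S + N with white Gaussian noise N rescaled so that
the amplitude SNR, 20·log10(‖L·S‖_F / ‖N‖_F), equals the requested decibel
level exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    ConfigurationError,
    ConvergenceError,
    ParameterError,
    ShapeError,
    UndefinedSNRError,
)
from .geometry import LeadField, Patch
from .spectral import WelchParams, band_bin_indices, segment_fft, _band_coherence_from_fft

__all__ = [
    "OscillatorSpec",
    "CoupledPair",
    "NoiseCovariance",
    "SimRealization",
    "generate_jittered_oscillation",
    "generate_coupled_pair",
    "build_source_activity",
    "project_to_sensors",
    "add_noise_at_snr",
]


@dataclass(frozen=True)
class OscillatorSpec:
    """Frequency-jittered oscillator settings.

    ``jitter_scale`` is the standard deviation (Hz) of the smoothed
    instantaneous-frequency perturbation; ``smoothing_window`` is the length
    of the moving-average smoother in samples.
    """

    base_frequency: float = 12.0
    band: tuple[float, float] = (9.0, 14.0)
    jitter_scale: float = 0.5
    n_samples: int = 7000
    sampling_rate: float = 600.0
    smoothing_window: int = 50

    def __post_init__(self) -> None:
        if not self.band[0] < self.base_frequency < self.band[1]:
            raise ParameterError("base_frequency must lie inside the band")
        if self.jitter_scale < 0:
            raise ParameterError("jitter_scale must be >= 0")
        if self.n_samples < 2 * self.sampling_rate / self.band[0]:
            raise ParameterError("need at least ~2 cycles of the lowest band frequency")
        if self.smoothing_window < 1:
            raise ParameterError("smoothing_window must be >= 1")


@dataclass
class CoupledPair:
    """A pair of unit-RMS oscillator series with calibrated band coherence."""

    series_1: np.ndarray
    series_2: np.ndarray
    target_coherence: float
    achieved_coherence: float
    iterations_used: int
    rng_seed: int


@dataclass
class NoiseCovariance:
    """Empirical channel covariance Q of the realized sensor noise."""

    q: np.ndarray
    n_samples_used: int

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if not np.allclose(self.q, self.q.T, atol=1e-12 * max(1.0, np.abs(self.q).max())):
            raise ParameterError("noise covariance must be symmetric")


@dataclass
class SimRealization:
    """One simulated cell: sources, clean/noisy sensor data and provenance."""

    config_id: str
    patch_1: Patch
    patch_2: Patch
    source_activity: np.ndarray
    clean_sensor_data: np.ndarray
    noise: np.ndarray
    noisy_sensor_data: np.ndarray
    noise_cov: NoiseCovariance
    snr_db: float
    coupling: float
    achieved_coherence: float
    rng_seed: int

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            for name in ("source_activity", "clean_sensor_data", "noise",
                         "noisy_sensor_data"):
                f.create_dataset(name, data=getattr(self, name))
            f.create_dataset("noise_cov", data=self.noise_cov.q)
            f.create_dataset("patch_1_members", data=self.patch_1.member_vertices)
            f.create_dataset("patch_2_members", data=self.patch_2.member_vertices)
        sidecar = {
            "config_id": self.config_id,
            "snr_db": self.snr_db,
            "coupling": self.coupling,
            "achieved_coherence": self.achieved_coherence,
            "rng_seed": int(self.rng_seed),
            "patch_1": {"seed": int(self.patch_1.seed_vertex),
                        "target_area": self.patch_1.target_area,
                        "achieved_area": self.patch_1.achieved_area},
            "patch_2": {"seed": int(self.patch_2.seed_vertex),
                        "target_area": self.patch_2.target_area,
                        "achieved_area": self.patch_2.achieved_area},
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def from_hdf5(cls, path) -> "SimRealization":
        import h5py

        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
        with h5py.File(path, "r") as f:
            arrays = {k: f[k][()] for k in ("source_activity", "clean_sensor_data",
                                            "noise", "noisy_sensor_data")}
            q = f["noise_cov"][()]
            m1 = f["patch_1_members"][()]
            m2 = f["patch_2_members"][()]
        p1 = Patch(meta["patch_1"]["seed"], m1, meta["patch_1"]["target_area"],
                   meta["patch_1"]["achieved_area"])
        p2 = Patch(meta["patch_2"]["seed"], m2, meta["patch_2"]["target_area"],
                   meta["patch_2"]["achieved_area"])
        return cls(meta["config_id"], p1, p2, noise_cov=NoiseCovariance(q, arrays["noise"].shape[1]),
                   snr_db=meta["snr_db"], coupling=meta["coupling"],
                   achieved_coherence=meta["achieved_coherence"],
                   rng_seed=meta["rng_seed"], **arrays)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _normalize(series: np.ndarray) -> np.ndarray:
    series = series - series.mean()
    rms = np.sqrt(np.mean(series**2))
    if rms == 0:
        raise ParameterError("cannot normalize an all-zero series")
    return series / rms


def _smoothed_jitter(spec: OscillatorSpec, rng: np.random.Generator) -> np.ndarray:
    """Moving-average smoothed Gaussian noise, standardized to unit std."""
    raw = rng.standard_normal(spec.n_samples)
    kernel = np.ones(spec.smoothing_window) / spec.smoothing_window
    smooth = np.convolve(raw, kernel, mode="same")
    std = smooth.std()
    return smooth / std if std > 0 else np.zeros(spec.n_samples)


def _oscillate(spec: OscillatorSpec, perturbation: np.ndarray) -> np.ndarray:
    """Phase-integrated oscillator for a given frequency perturbation (Hz)."""
    freq = spec.base_frequency + perturbation
    phase = 2.0 * np.pi * np.cumsum(freq) / spec.sampling_rate
    return _normalize(np.cos(phase))


def generate_jittered_oscillation(spec: OscillatorSpec, rng_seed=0) -> np.ndarray:
    """One frequency-jittered oscillator: s(t) = Re exp(i·φ(t)).

    The instantaneous frequency is the base frequency plus moving-average
    smoothed Gaussian noise rescaled to std ``jitter_scale``; the phase is
    its cumulative sum (φ(t) = 2π Σ f(t')/fs).  Output is normalized to zero
    mean and unit RMS and is deterministic given the seed.
    """
    rng = _as_rng(rng_seed)
    if spec.jitter_scale > 0:
        pert = spec.jitter_scale * _smoothed_jitter(spec, rng)
    else:
        pert = np.zeros(spec.n_samples)
    return _oscillate(spec, pert)


def generate_coupled_pair(
    spec: OscillatorSpec,
    target_coherence: float,
    tolerance: float = 0.02,
    max_iterations: int = 2000,
    rng_seed=0,
    welch_params: WelchParams | None = None,
) -> CoupledPair:
    """Draw an oscillator pair whose band MS coherence hits a target value.

    The first series is fixed.  The second oscillator's instantaneous
    frequency mixes the first oscillator's jitter with a fresh independent
    jitter realization,

        pert₂ = ρ·pert₁ + √(1 − ρ²)·pert_fresh,

    re-drawn in a loop; the phase relationship between the oscillators
    therefore wanders by an amount controlled by ρ, and the loop adapts ρ
    until the Welch band coherence (same estimator as the analysis) lands
    within ``tolerance`` of the target.  The shared component is what makes
    high coherence targets reachable: with fully independent jitter the
    coherence ceiling depends on the first series' own phase drift.

    ``target_coherence == 1`` returns the identical-copy shortcut
    (coherence exactly 1 at iteration 0).
    """
    if not 0 < target_coherence <= 1:
        raise ParameterError("target_coherence must lie in (0, 1]")
    if tolerance < 0:
        raise ParameterError("tolerance must be >= 0")
    params = welch_params or WelchParams(sampling_rate=spec.sampling_rate)
    rng = _as_rng(rng_seed)
    seed_value = rng_seed if isinstance(rng_seed, (int, np.integer)) else -1
    jitter = spec.jitter_scale if spec.jitter_scale > 0 else 0.25
    spec_j = replace(spec, jitter_scale=jitter)
    pert_1 = _smoothed_jitter(spec_j, rng)
    series_1 = _oscillate(spec_j, jitter * pert_1)

    if target_coherence == 1.0:
        return CoupledPair(series_1, series_1.copy(), 1.0, 1.0, 0, int(seed_value))

    bins = band_bin_indices(params, spec.band)
    Z1 = segment_fft(series_1, params)[..., bins]

    rho = float(np.sqrt(target_coherence))  # starting guess for the mixing
    best_c, best_err = np.nan, np.inf
    recent: list[float] = []
    adapt_every = 10
    for iteration in range(1, max_iterations + 1):
        fresh = _smoothed_jitter(spec_j, rng)
        pert_2 = rho * pert_1 + np.sqrt(1.0 - rho**2) * fresh
        series_2 = _oscillate(spec_j, jitter * pert_2)
        Z2 = segment_fft(series_2, params)[..., bins]
        c = _band_coherence_from_fft(Z1, Z2)
        if abs(c - target_coherence) <= tolerance:
            return CoupledPair(series_1, series_2, target_coherence, c,
                               iteration, int(seed_value))
        if abs(c - target_coherence) < best_err:
            best_c, best_err = c, abs(c - target_coherence)
        recent.append(c)
        if len(recent) >= adapt_every:
            # coherence increases with the shared-jitter weight ρ
            rho = float(np.clip(rho + 0.4 * (target_coherence - np.mean(recent)),
                                0.0, 0.999))
            recent.clear()
    raise ConvergenceError(
        f"coupling loop exhausted {max_iterations} iterations "
        f"(best achieved coherence {best_c:.3f} for target {target_coherence})",
        best_achieved=best_c,
    )


def build_source_activity(
    pair: CoupledPair,
    patch_1: Patch,
    patch_2: Patch,
    n_sources: int,
    amplitude: float = 1.0,
) -> np.ndarray:
    """Place identical copies of each series on its patch's vertices.

    Returns a dense (n_sources, n_samples) array that is zero outside the
    two patches.
    """
    m1 = set(int(v) for v in patch_1.member_vertices)
    m2 = set(int(v) for v in patch_2.member_vertices)
    if m1 & m2:
        raise ConfigurationError(f"patches overlap at vertices {sorted(m1 & m2)}")
    activity = np.zeros((n_sources, pair.series_1.size))
    activity[patch_1.member_vertices] = amplitude * pair.series_1
    activity[patch_2.member_vertices] = amplitude * pair.series_2
    return activity


def project_to_sensors(lf: LeadField, source_activity: np.ndarray) -> np.ndarray:
    """Noiseless sensor data L·S."""
    source_activity = np.asarray(source_activity, float)
    if source_activity.ndim != 2 or source_activity.shape[0] != lf.n_sources:
        raise ShapeError(
            f"source activity has {source_activity.shape[0]} rows, "
            f"lead field expects {lf.n_sources}"
        )
    return lf.gain @ source_activity


def add_noise_at_snr(
    clean: np.ndarray, snr_db: float, rng_seed=0
) -> tuple[np.ndarray, np.ndarray, NoiseCovariance]:
    """Add white Gaussian sensor noise at an exact Frobenius amplitude SNR.

    The noise is rescaled so that 20·log10(‖clean‖_F/‖noise‖_F) = snr_db
    exactly; Q is the empirical channel covariance of the realized noise.
    Returns (noisy, noise, NoiseCovariance).
    """
    clean = np.asarray(clean, float)
    clean_norm = np.linalg.norm(clean)
    if clean_norm == 0:
        raise UndefinedSNRError("SNR undefined for all-zero clean data")
    rng = _as_rng(rng_seed)
    noise = rng.standard_normal(clean.shape)
    target_norm = clean_norm / 10.0 ** (snr_db / 20.0)
    noise *= target_norm / np.linalg.norm(noise)
    q = np.cov(noise)
    q = 0.5 * (q + q.T)
    return clean + noise, noise, NoiseCovariance(q, clean.shape[1])
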