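"""Welch cross-spectra, band power maps and seed-based coherence maps.

Magnitude-squared coherence between source locations r1, r2 at frequency f:

    Coh(r1, r2, f) = |Cs(r1, r2, f)|² / (P(r1, f) · P(r2, f)),

with P(r, f) = Cs(r, r, f) the autospectrum, all estimated with Welch's
averaged modified periodogram.  Band statistics are the arithmetic mean over
the frequency bins whose centers fall inside the band (inclusive).

Scalar cross-spectra go through :func:`scipy.signal.csd`; the vectorized
band-limited helpers used by the Monte-Carlo pipeline implement the same
estimator (identical segmentation, Hann taper, constant detrend, density
scaling) and are tested for exact agreement with scipy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import (
    InsufficientDataError,
    ParameterError,
    ShapeError,
    UndefinedCoherenceError,
)

__all__ = [
    "WelchParams",
    "SpectralMap",
    "welch_cross_spectrum",
    "ms_coherence",
    "power_map",
    "coherence_map",
    "band_bin_indices",
    "segment_fft",
    "welch_csd_matrix",
]

ALPHA_BAND = (9.0, 14.0)


@dataclass(frozen=True)
class WelchParams:
    """Welch estimator settings.

    Defaults give 1 Hz resolution at 600 Hz sampling (1 s Hann segments,
    50% overlap → 22 segments of a 7000-sample series).
    """

    segment_length: int = 600
    overlap_fraction: float = 0.5
    window: str = "hann"
    sampling_rate: float = 600.0

    def __post_init__(self) -> None:
        if self.segment_length < 2:
            raise ParameterError("segment_length must be >= 2")
        if not 0 <= self.overlap_fraction < 1:
            raise ParameterError("overlap_fraction must lie in [0, 1)")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be positive")

    @property
    def noverlap(self) -> int:
        return int(round(self.segment_length * self.overlap_fraction))

    @property
    def step(self) -> int:
        return self.segment_length - self.noverlap

    def frequencies(self) -> np.ndarray:
        return np.fft.rfftfreq(self.segment_length, d=1.0 / self.sampling_rate)

    def n_segments(self, n_samples: int) -> int:
        if n_samples < self.segment_length:
            raise InsufficientDataError(
                f"series of {n_samples} samples shorter than one "
                f"{self.segment_length}-sample segment"
            )
        return (n_samples - self.segment_length) // self.step + 1


@dataclass
class SpectralMap:
    """Per-vertex band power or seed-based coherence values.

    Excluded vertices (the coherence reference patch) carry NaN sentinels and
    are listed in ``excluded_vertices``.
    """

    values: np.ndarray
    kind: str
    band: tuple[float, float] = ALPHA_BAND
    seed_vertex: int | None = None
    excluded_vertices: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("power", "coherence"):
            raise ParameterError("kind must be 'power' or 'coherence'")
        ev = np.asarray(sorted(self.excluded_vertices), dtype=int)
        ok = np.ones(self.values.shape[0], dtype=bool)
        ok[ev] = False
        vals = self.values[ok]
        if self.kind == "power" and np.any(vals < -1e-12):
            raise ParameterError("power values must be nonnegative")
        if self.kind == "coherence" and np.any((vals < -1e-12) | (vals > 1 + 1e-12)):
            raise ParameterError("coherence values must lie in [0, 1]")

    @property
    def evaluable(self) -> np.ndarray:
        mask = np.ones(self.values.shape[0], dtype=bool)
        if self.excluded_vertices:
            mask[np.asarray(sorted(self.excluded_vertices), dtype=int)] = False
        return mask


def band_bin_indices(params: WelchParams, band: tuple[float, float]) -> np.ndarray:
    """Indices of rfft bins whose center frequency lies in [low, high]."""
    freqs = params.frequencies()
    idx = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]))
    if idx.size == 0:
        raise ParameterError(f"no frequency bins inside band {band}")
    return idx


def welch_cross_spectrum(
    x: np.ndarray, y: np.ndarray, params: WelchParams
) -> tuple[np.ndarray, np.ndarray]:
    """Welch cross-spectral density of two equal-length series.

    Returns (frequencies, complex CSD); ``welch_cross_spectrum(x, x)`` is the
    real nonnegative autospectrum.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeError("x and y must be equal-length 1-D series")
    params.n_segments(x.size)  # raises InsufficientDataError if too short
    freqs, pxy = signal.csd(
        x,
        y,
        fs=params.sampling_rate,
        window=params.window,
        nperseg=params.segment_length,
        noverlap=params.noverlap,
    )
    return freqs, pxy


def segment_fft(data: np.ndarray, params: WelchParams) -> np.ndarray:
    """Tapered, detrended segment spectra of (..., time) data.

    Returns Z with shape (..., n_segments, n_rfft_bins), scaled so that
    ``mean_k conj(Z[k, f]) Z[k, f]`` is scipy's one-sided density-scaled
    autospectrum.
    """
    data = np.asarray(data, float)
    n = data.shape[-1]
    nseg = params.n_segments(n)
    L, step = params.segment_length, params.step
    idx = np.arange(L)[None, :] + step * np.arange(nseg)[:, None]
    segs = data[..., idx]  # (..., nseg, L)
    segs = segs - segs.mean(axis=-1, keepdims=True)  # constant detrend
    win = signal.get_window(params.window, L)
    Z = np.fft.rfft(segs * win, axis=-1)
    # one-sided density scaling: 2 / (fs * sum(win²)), no doubling at DC/Nyquist
    scale = np.full(Z.shape[-1], 2.0 / (params.sampling_rate * (win @ win)))
    scale[0] = scale[0] / 2.0
    if L % 2 == 0:
        scale[-1] = scale[-1] / 2.0
    return Z * np.sqrt(scale)


def welch_csd_matrix(
    data: np.ndarray, params: WelchParams, bins: np.ndarray | None = None
) -> np.ndarray:
    """Full cross-spectral density matrix of multichannel (ch, time) data.

    Returns a Hermitian (n_bins, ch, ch) array; entry [f, i, j] equals
    ``scipy.signal.csd(data[i], data[j])`` at that bin.
    """
    Z = segment_fft(data, params)  # (ch, nseg, nf)
    if bins is not None:
        Z = Z[..., np.asarray(bins, int)]
    Zf = np.ascontiguousarray(Z.transpose(2, 0, 1))  # (nf, ch, nseg)
    return (Zf.conj() @ Zf.transpose(0, 2, 1)) / Zf.shape[-1]


def _band_coherence_from_fft(
    Zx: np.ndarray, Zy: np.ndarray
) -> float:
    """Band-mean MS coherence from band-limited segment spectra (nseg, nbins)."""
    pxx = np.mean(np.abs(Zx) ** 2, axis=0)
    pyy = np.mean(np.abs(Zy) ** 2, axis=0)
    if np.any(pxx <= 0) or np.any(pyy <= 0):
        raise UndefinedCoherenceError("an autospectrum vanishes inside the band")
    pxy = np.mean(Zx.conj() * Zy, axis=0)
    return float(np.mean(np.abs(pxy) ** 2 / (pxx * pyy)))


def ms_coherence(
    x: np.ndarray, y: np.ndarray, band: tuple[float, float], params: WelchParams
) -> float:
    """Band-averaged magnitude-squared coherence of two series, in [0, 1]."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ShapeError("x and y must be equal-length 1-D series")
    bins = band_bin_indices(params, band)
    Z = segment_fft(np.stack([x, y]), params)[..., bins]
    return _band_coherence_from_fft(Z[0], Z[1])


def power_map(
    estimated_sources: np.ndarray,
    band: tuple[float, float] = ALPHA_BAND,
    params: WelchParams = WelchParams(),
) -> SpectralMap:
    """Band-averaged Welch autospectrum per source vertex."""
    est = np.atleast_2d(np.asarray(estimated_sources, float))
    bins = band_bin_indices(params, band)
    Z = segment_fft(est, params)[..., bins]
    power = np.mean(np.mean(np.abs(Z) ** 2, axis=-2), axis=-1)
    return SpectralMap(np.maximum(power, 0.0), "power", band=band)


def coherence_map(
    estimated_sources: np.ndarray,
    seed_vertex: int,
    band: tuple[float, float] = ALPHA_BAND,
    params: WelchParams = WelchParams(),
    excluded=frozenset(),
) -> SpectralMap:
    """Seed-based MS coherence of every vertex with the reconstructed seed.

    Vertices in ``excluded`` (the reference patch) are marked NaN and never
    scored.  The seed itself is normally a member of the excluded set.
    """
    est = np.atleast_2d(np.asarray(estimated_sources, float))
    n_src = est.shape[0]
    if not 0 <= seed_vertex < n_src:
        raise ParameterError(f"seed vertex {seed_vertex} out of range")
    bins = band_bin_indices(params, band)
    Z = segment_fft(est, params)[..., bins]  # (src, nseg, nb)
    Zs = Z[seed_vertex]
    pss = np.mean(np.abs(Zs) ** 2, axis=0)
    if np.any(pss <= 0):
        raise UndefinedCoherenceError("seed autospectrum vanishes inside the band")
    pvv = np.mean(np.abs(Z) ** 2, axis=1)  # (src, nb)
    pvs = np.mean(Z.conj() * Zs[None], axis=1)  # (src, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        coh = np.abs(pvs) ** 2 / (pvv * pss[None])
    coh = np.where(pvv > 0, coh, 0.0)  # silent vertices: zero coupling by convention
    values = np.clip(np.mean(coh, axis=1), 0.0, 1.0)
    excluded = frozenset(int(v) for v in excluded)
    if excluded:
        values[np.asarray(sorted(excluded), int)] = np.nan
    return SpectralMap(values, "coherence", band=band, seed_vertex=seed_vertex,
                       excluded_vertices=excluded)


def write_map_table(smap: SpectralMap, path, threshold_fraction: float | None = None) -> None:
    """Export a map as a vertex/value TSV.

    With ``threshold_fraction`` (e.g. 0.2), values are normalized to the map
    maximum and zeroed below that fraction, mirroring the usual thresholded
    display of source maps.
    """
    values = smap.values.copy()
    if threshold_fraction is not None:
        finite = np.isfinite(values)
        peak = np.nanmax(values) if finite.any() else np.nan
        if peak > 0:
            values = values / peak
            values[finite & (values < threshold_fraction)] = 0.0
    with open(path, "w") as fh:
        fh.write("vertex\tvalue\n")
        for i, v in enumerate(values):
            fh.write(f"{i}\t{'NA' if not np.isfinite(v) else f'{v:.10g}'}\n")
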