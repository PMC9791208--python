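"""Frequency-domain features of RF signals.

Two families of features are produced per case:

* **Sub-band statistics.** The 0–25 MHz analysis range is split into seven
  fixed sub-bands chosen so the probe's 4 MHz fundamental and its harmonics
  (8, 12, 16, 20, 24 MHz) sit at sub-band centers rather than edges. For
  each sub-band, five statistics of the estimated power spectral density
  are computed: signal power, spectral centroid, spectral bandwidth,
  spectral flatness and crest factor. The PSD is estimated from
  Hamming-windowed 1 mm x 1 mm patches of the ROI, averaged over patches.
* **Regression features.** Each RF time series (slow time, i.e. the
  frame-to-frame sequence at one pixel) is mean-removed, zero-padded,
  Fourier-transformed and max-normalized; a least-squares line fitted to
  the normalized magnitude spectrum versus normalized frequency yields an
  intercept (S1) and slope (S2).

With 5 statistics x 7 bands + S1 + S2 this is a 37-element vector per case.

Spectral bandwidth is reported as the square root of the PSD-weighted mean
squared deviation from the centroid, so its units are Hz (a standard
deviation in frequency), consistent with reporting centroid and bandwidth
on a common MHz scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal.windows import hamming

from .errors import (
    DegenerateSpectrumError,
    ROITooSmallError,
    UndefinedFeatureError,
)
from .rf_io import AcquisitionMeta, RFFrameStack, mm_to_pixels

__all__ = [
    "SubBand",
    "PowerSpectrum",
    "SpectralConfig",
    "BAND_EDGES_MHZ",
    "BAND_FEATURE_NAMES",
    "SPECTRAL_FEATURE_NAMES",
    "partition_band",
    "patch_psd",
    "band_features",
    "regression_features",
    "spectral_feature_vector",
]

#: Sub-band edges in MHz. The lowest band ([0, 1.5]) isolates the
#: white-noise-dominated low end; the middle five bands are 4 MHz wide and
#: centered on the harmonic frequencies; the top band closes the range at
#: 25 MHz.
BAND_EDGES_MHZ: tuple[float, ...] = (0.0, 1.5, 6.5, 10.5, 14.5, 18.5, 22.5, 25.0)

BAND_FEATURE_NAMES: tuple[str, ...] = (
    "signal_power",
    "spectral_centroid",
    "spectral_bandwidth",
    "spectral_flatness",
    "crest_factor",
)

#: Canonical 37-name order of the spectral feature vector.
SPECTRAL_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"band{b}_{name}" for b in range(1, 8) for name in BAND_FEATURE_NAMES
) + ("s1_intercept", "s2_slope")


@dataclass(frozen=True)
class SubBand:
    """A frequency interval [f_l, f_u) in Hz."""

    f_l: float
    f_u: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_l < self.f_u):
            raise ValueError(f"invalid sub-band [{self.f_l}, {self.f_u})")

    @property
    def center(self) -> float:
        return 0.5 * (self.f_l + self.f_u)


@dataclass
class PowerSpectrum:
    """A one-sided PSD estimate on a uniform frequency grid."""

    frequencies: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.psd = np.asarray(self.psd, dtype=np.float64)
        if self.frequencies.shape != self.psd.shape or self.frequencies.ndim != 1:
            raise ValueError("frequencies and psd must be 1-D arrays of equal length")
        if self.frequencies.size < 2:
            raise ValueError("a power spectrum needs at least 2 bins")
        steps = np.diff(self.frequencies)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
            raise ValueError("frequency grid must be uniform")
        if np.any(self.psd < 0):
            raise ValueError("psd values must be non-negative")

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass
class SpectralConfig:
    """Configuration of the spectral feature extractor.

    patch_mm : side length of the square analysis patches (default 1 mm).
    band_edges_mhz : sub-band edges; the default is the seven-band scheme.
    aggregation : reducer across patches / pixel locations ("mean").
    timeseries_axis : "slow" fits S1/S2 on frame-to-frame series; "axial"
        fits them on fast-time beam columns (automatic fallback when fewer
        than 4 frames are available).
    """

    patch_mm: float = 1.0
    band_edges_mhz: tuple[float, ...] = BAND_EDGES_MHZ
    aggregation: str = "mean"
    timeseries_axis: str = "slow"


def partition_band(band_edges_mhz: tuple[float, ...] = BAND_EDGES_MHZ) -> list[SubBand]:
    """Return the ordered, contiguous list of analysis sub-bands (in Hz)."""
    edges_hz = [e * 1e6 for e in band_edges_mhz]
    return [SubBand(lo, hi) for lo, hi in zip(edges_hz[:-1], edges_hz[1:])]


def _next_pow2(n: int) -> int:
    return 1 << int(np.ceil(np.log2(max(2, n))))


def patch_psd(
    roi_rf: np.ndarray,
    meta: AcquisitionMeta,
    patch_mm: float = 1.0,
) -> list[PowerSpectrum]:
    """Per-patch PSD estimates from a 2-D RF ROI.

    The ROI is tiled into non-overlapping ``patch_mm`` x ``patch_mm``
    patches anchored at the ROI origin (partial edge patches discarded).
    Within a patch, each beam segment is mean-removed, Hamming-windowed,
    zero-padded to the next power of two >= twice its length and FFT'd;
    the patch PSD is the mean over its beams of ``|FFT|^2 / (sum(w^2) * N)``.
    """
    roi_rf = np.asarray(roi_rf, dtype=np.float64)
    if roi_rf.ndim != 2:
        raise ValueError("patch_psd expects a 2-D [axial, beam] RF ROI")
    ax_px, beam_px = mm_to_pixels(patch_mm, meta)
    n_ax, n_beam = roi_rf.shape
    if n_ax < ax_px or n_beam < beam_px:
        raise ROITooSmallError(
            f"ROI {roi_rf.shape} smaller than one {ax_px}x{beam_px} patch"
        )
    window = hamming(ax_px, sym=False)
    wpow = float(np.sum(window**2))
    nfft = _next_pow2(2 * ax_px)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / meta.sample_rate)
    spectra: list[PowerSpectrum] = []
    for r0 in range(0, n_ax - ax_px + 1, ax_px):
        for c0 in range(0, n_beam - beam_px + 1, beam_px):
            seg = roi_rf[r0 : r0 + ax_px, c0 : c0 + beam_px]
            seg = seg - seg.mean(axis=0, keepdims=True)
            spec = np.fft.rfft(seg * window[:, None], n=nfft, axis=0)
            psd = (np.abs(spec) ** 2 / (wpow * ax_px)).mean(axis=1)
            spectra.append(PowerSpectrum(frequencies=freqs.copy(), psd=psd))
    return spectra


def _in_band(ps: PowerSpectrum, band: SubBand) -> np.ndarray:
    # Half-open [f_l, f_u) so a partition of the range never double-counts.
    return (ps.frequencies >= band.f_l) & (ps.frequencies < band.f_u)


def band_features(ps: PowerSpectrum, band: SubBand) -> dict[str, float]:
    """The five sub-band statistics of a PSD restricted to ``band``.

    signal power      sum P(f) df
    spectral centroid sum f P(f) df / sum P(f) df
    spectral bandwidth sqrt( sum (f - SC)^2 P(f) df / sum P(f) df )
    spectral flatness geometric mean / arithmetic mean of P(f)
    crest factor      max P(f) / arithmetic mean of P(f)
    """
    mask = _in_band(ps, band)
    if mask.sum() < 2:
        raise UndefinedFeatureError(
            f"band [{band.f_l}, {band.f_u}) covers {int(mask.sum())} bins (< 2)"
        )
    f = ps.frequencies[mask]
    p = ps.psd[mask]
    df = ps.df
    total = float(np.sum(p) * df)
    if total <= 0:
        raise UndefinedFeatureError("zero total power in band; features undefined")
    power = total
    centroid = float(np.sum(f * p) * df / total)
    bandwidth = float(np.sqrt(np.sum((f - centroid) ** 2 * p) * df / total))
    amean = float(np.mean(p))
    if np.any(p == 0):
        gmean = 0.0
    else:
        gmean = float(np.exp(np.mean(np.log(p))))
    flatness = gmean / amean
    crest = float(np.max(p) / amean)
    return {
        "signal_power": power,
        "spectral_centroid": centroid,
        "spectral_bandwidth": bandwidth,
        "spectral_flatness": flatness,
        "crest_factor": crest,
    }


def regression_features(series: np.ndarray) -> tuple[float, float]:
    """Intercept S1 and slope S2 of a line fit to the normalized spectrum.

    The series is mean-removed, zero-padded to the next power of two >=
    twice its length, and its one-sided FFT magnitude spectrum is
    normalized to unit maximum. An ordinary least-squares line is fitted
    against frequency normalized to [0, 1]. The DC bin is excluded from
    the fit: after mean removal it is identically zero by construction,
    so keeping it would tilt every fitted slope upward regardless of the
    data.
    """
    series = np.asarray(series, dtype=np.float64).ravel()
    n = series.size
    if n < 4:
        raise ValueError("series must have at least 4 samples")
    x = series - series.mean()
    if np.all(x == 0):
        raise DegenerateSpectrumError("constant series has a degenerate spectrum")
    nfft = _next_pow2(2 * n)
    mag = np.abs(np.fft.rfft(x, n=nfft))
    mag = mag / mag.max()
    nu = np.linspace(0.0, 1.0, mag.size)
    slope, intercept = np.polyfit(nu[1:], mag[1:], 1)
    return float(intercept), float(slope)


def _regression_features_batch(series_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (S1, S2) for many series (rows). Constant rows -> NaN."""
    X = np.asarray(series_matrix, dtype=np.float64)
    n = X.shape[1]
    X = X - X.mean(axis=1, keepdims=True)
    nfft = _next_pow2(2 * n)
    mag = np.abs(np.fft.rfft(X, n=nfft, axis=1))
    peak = mag.max(axis=1)
    ok = peak > 0
    mag[ok] = mag[ok] / peak[ok, None]
    nu = np.linspace(0.0, 1.0, mag.shape[1])
    # closed-form simple OLS per row, DC bin excluded (structurally zero)
    nu, mag = nu[1:], mag[:, 1:]
    nu_c = nu - nu.mean()
    denom = float(np.sum(nu_c**2))
    slope = (mag @ nu_c) / denom
    intercept = mag.mean(axis=1) - slope * nu.mean()
    slope[~ok] = np.nan
    intercept[~ok] = np.nan
    return intercept, slope


def spectral_feature_vector(
    roi_stack: RFFrameStack | np.ndarray,
    meta: AcquisitionMeta | None = None,
    config: SpectralConfig | None = None,
) -> pd.Series:
    """The canonical 37-element spectral feature vector for one ROI.

    The 35 sub-band statistics are computed on the patch-averaged PSD of
    the first frame. S1/S2 are the mean over pixel locations of per-series
    regression features, fitted on slow-time (frame-to-frame) series when
    at least 4 frames are available, else on axial beam columns of the
    first frame.

    Sub-bands extending above the data's Nyquist frequency yield zeros for
    their five statistics (with a warning) so the 37-length contract holds
    on any input.
    """
    config = config or SpectralConfig()
    if isinstance(roi_stack, RFFrameStack):
        samples = roi_stack.samples
        meta = roi_stack.meta
    else:
        samples = np.asarray(roi_stack, dtype=np.float64)
        if samples.ndim == 2:
            samples = samples[:, :, None]
        if meta is None:
            raise ValueError("meta is required when passing a bare array")
    if samples.ndim != 3 or samples.shape[2] < 1:
        raise ValueError("roi_stack must be [axial, beam, frame] with >= 1 frame")

    frame0 = samples[:, :, 0]
    spectra = patch_psd(frame0, meta, config.patch_mm)
    mean_psd = PowerSpectrum(
        frequencies=spectra[0].frequencies,
        psd=np.mean([s.psd for s in spectra], axis=0),
    )
    if config.aggregation != "mean":
        raise ValueError(f"unsupported aggregation {config.aggregation!r}")

    values: dict[str, float] = {}
    bands = partition_band(config.band_edges_mhz)
    nyquist = meta.nyquist
    for i, band in enumerate(bands, start=1):
        if band.f_u > nyquist:
            warnings.warn(
                f"sub-band {i} [{band.f_l/1e6:.1f}, {band.f_u/1e6:.1f}] MHz exceeds "
                f"Nyquist {nyquist/1e6:.1f} MHz; its features are set to 0",
                stacklevel=2,
            )
            feats = {name: 0.0 for name in BAND_FEATURE_NAMES}
        else:
            feats = band_features(mean_psd, band)
        for name in BAND_FEATURE_NAMES:
            values[f"band{i}_{name}"] = feats[name]

    n_frames = samples.shape[2]
    use_slow = config.timeseries_axis == "slow" and n_frames >= 4
    if config.timeseries_axis == "slow" and not use_slow:
        warnings.warn(
            f"only {n_frames} frame(s); falling back to axial series for S1/S2",
            stacklevel=2,
        )
    if use_slow:
        series_matrix = samples.reshape(-1, n_frames)
    else:
        series_matrix = frame0.T  # one series per beam column
    s1, s2 = _regression_features_batch(series_matrix)
    if not np.any(np.isfinite(s1)):
        raise DegenerateSpectrumError("all RF time series are constant")
    values["s1_intercept"] = float(np.nanmean(s1))
    values["s2_slope"] = float(np.nanmean(s2))

    out = pd.Series(values, dtype=float).reindex(list(SPECTRAL_FEATURE_NAMES))
    assert not out.isna().any()
    return out
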