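"""Parametric feature maps computed from one RF ROI.

Three maps summarize complementary tissue properties:

* **NDM** — Nakagami distribution mean map. The Nakagami shape parameter
  ``m = (E[R^2])^2 / Var[R^2]`` of the local backscattered envelope is
  estimated in a sliding window; ``m < 1`` indicates pre-Rayleigh (sparse
  scatterer) statistics, ``m = 1`` fully developed Rayleigh speckle and
  ``m > 1`` post-Rayleigh conditions.
* **DEA** — direct energy attenuation map. At each point of each beam, the
  direct energy coefficient (DEC) compares the total spectral energy E0 of
  a fixed-length RF segment starting at that point with the energy E1 of
  an equally long segment shifted deeper by a fixed interval:
  ``DEC = 10*log10(E0/E1) / d`` where ``d = interval * c / (2 * fs)`` is
  the two-way depth increment in cm, giving dB/cm. The per-segment "total
  spectral energy" is the Parseval sum of squared FFT magnitudes of the
  unwindowed segment, so the energy ratio reduces to the ratio of
  time-domain sums of squares.
* **RF-I** — RF skewness intensity map: the third standardized moment of
  raw RF samples in a sliding window, mapping local amplitude asymmetry
  (raw RF is near-symmetric, so skewness isolates asymmetry such as
  nonlinear waveform distortion).

All moments use population (divide-by-n) conventions. Maps are computed
with an edge policy of "crop": only fully interior windows produce values,
and each map records where its values sit inside the source ROI
(``valid_region``) instead of padding — padded values would contaminate
the radiomics statistics computed downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import (
    ConfigError,
    DegenerateWindowError,
    ROITooSmallError,
    UndefinedDECError,
)
from .rf_io import AcquisitionMeta, EnvelopeImage, ROIRect

__all__ = [
    "MapConfig",
    "FeatureMap",
    "MAP_KINDS",
    "nakagami_m",
    "nakagami_map",
    "dec_at_point",
    "dea_map",
    "skewness",
    "skewness_map",
    "export_feature_map",
]

MAP_KINDS = ("NDM", "DEA", "RFI")


@dataclass
class MapConfig:
    """Window geometry for the three parametric maps.

    The Nakagami window defaults to ~3 pulse lengths axially by 3 beams
    laterally (the established resolution/stability compromise in Nakagami
    imaging); use :meth:`for_meta` to derive it from acquisition metadata.
    The skewness window defaults to the Nakagami window. DEA segment
    length and interval are in axial samples.
    """

    nak_window_axial: int = 31
    nak_window_beams: int = 3
    nak_step: int = 1
    dea_length_segment: int = 64
    dea_seg_interval: int = 16
    skew_window_axial: int | None = None
    skew_window_beams: int | None = None
    edge_policy: str = "crop"

    def __post_init__(self) -> None:
        if self.nak_window_axial < 3 or self.nak_window_beams < 1:
            raise ConfigError("Nakagami window too small")
        if self.nak_step < 1:
            raise ConfigError("nak_step must be >= 1")
        if self.dea_length_segment <= 0 or self.dea_seg_interval <= 0:
            raise ConfigError("DEA segment length and interval must be > 0")
        if self.skew_window_axial is None:
            self.skew_window_axial = self.nak_window_axial
        if self.skew_window_beams is None:
            self.skew_window_beams = self.nak_window_beams
        if self.edge_policy != "crop":
            raise ConfigError(f"unsupported edge_policy {self.edge_policy!r}")

    @classmethod
    def for_meta(
        cls,
        meta: AcquisitionMeta,
        pulse_cycles: float = 3.0,
        pulse_lengths: float = 3.0,
        **overrides,
    ) -> "MapConfig":
        """Derive the Nakagami window from the acquisition geometry.

        The axial pulse extent is ``pulse_cycles * wavelength / 2`` (two-way
        travel); the window spans ``pulse_lengths`` of those extents.
        """
        wavelength_mm = (meta.sound_speed * 10.0) / meta.center_frequency
        pulse_mm = pulse_cycles * wavelength_mm / 2.0
        axial = max(3, int(round(pulse_lengths * pulse_mm / meta.axial_spacing_mm)))
        return cls(nak_window_axial=axial, nak_window_beams=3, **overrides)


@dataclass
class FeatureMap:
    """A 2-D parametric image plus the sub-ROI its values correspond to."""

    kind: str
    values: np.ndarray
    valid_region: ROIRect

    def __post_init__(self) -> None:
        if self.kind not in MAP_KINDS:
            raise ValueError(f"unknown map kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("feature map values must be 2-D")
        if self.values.shape != (self.valid_region.height, self.valid_region.width):
            raise ValueError("values shape does not match valid_region")


def nakagami_m(envelope_window: np.ndarray) -> tuple[float, float]:
    """Moment estimate of the Nakagami shape m and scale Omega.

    ``m = (E[R^2])^2 / E[(R^2 - E[R^2])^2]``, ``Omega = E[R^2]``, with
    expectations taken as sample (divide-by-n) averages.
    """
    r = np.asarray(envelope_window, dtype=np.float64).ravel()
    if r.size < 16:
        raise ValueError("need at least 16 envelope samples for a stable estimate")
    if np.any(r < 0):
        raise ValueError("envelope samples must be non-negative")
    r2 = r**2
    omega = float(r2.mean())
    var = float(((r2 - omega) ** 2).mean())
    if var <= 0:
        raise DegenerateWindowError("zero variance of squared envelope")
    return omega**2 / var, omega


def _sliding_moments(x: np.ndarray, win: tuple[int, int], powers: tuple[int, ...]) -> list[np.ndarray]:
    """Sliding-window means of x**p for each p, on the valid (cropped) grid."""
    views = sliding_window_view(x, win)
    out = []
    for p in powers:
        v = views if p == 1 else views**p
        out.append(v.mean(axis=(2, 3)))
    return out


def _valid_region(shape: tuple[int, int], win: tuple[int, int], step: int) -> ROIRect:
    h = shape[0] - win[0] + 1
    w = shape[1] - win[1] + 1
    hh = len(range(0, h, step))
    ww = len(range(0, w, step))
    return ROIRect(row0=win[0] // 2, col0=win[1] // 2, height=hh, width=ww)


def nakagami_map(env: EnvelopeImage | np.ndarray, cfg: MapConfig) -> FeatureMap:
    """Sliding-window Nakagami-m map of an envelope image.

    Smaller windows raise resolution but destabilize (overestimate) m; only
    fully interior windows produce values, so the map shrinks by the
    half-window margins relative to the source ROI.
    """
    values = env.values if isinstance(env, EnvelopeImage) else np.asarray(env, dtype=np.float64)
    win = (cfg.nak_window_axial, cfg.nak_window_beams)
    if values.shape[0] < win[0] or values.shape[1] < win[1]:
        raise ConfigError(f"Nakagami window {win} larger than image {values.shape}")
    r2 = values.astype(np.float64) ** 2
    m2, m4 = _sliding_moments(r2, win, (1, 2))
    var = m4 - m2**2
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(var > 0, m2**2 / var, np.nan)
    m = m[:: cfg.nak_step, :: cfg.nak_step]
    region = _valid_region(values.shape, win, cfg.nak_step)
    return FeatureMap(kind="NDM", values=m, valid_region=region)


def _dec_distance_cm(cfg: MapConfig, meta: AcquisitionMeta) -> float:
    # two-way depth increment of the segment shift, in cm
    return cfg.dea_seg_interval * meta.sound_speed / (2.0 * meta.sample_rate)


def dec_at_point(
    beam_rf: np.ndarray,
    idx: int,
    cfg: MapConfig,
    meta: AcquisitionMeta,
) -> float:
    """Direct energy coefficient at one axial sample of one beam, in dB/cm."""
    beam = np.asarray(beam_rf, dtype=np.float64).ravel()
    L, S = cfg.dea_length_segment, cfg.dea_seg_interval
    if idx < 0 or idx + S + L > beam.size:
        raise ValueError(
            f"segments [{idx}, {idx+L}) and [{idx+S}, {idx+S+L}) exceed beam length {beam.size}"
        )
    seg0 = beam[idx : idx + L]
    seg1 = beam[idx + S : idx + S + L]
    # Parseval: sum |FFT|^2 = N * sum x^2, so the ratio is the ratio of
    # time-domain energies.
    e0 = float(np.sum(seg0**2))
    e1 = float(np.sum(seg1**2))
    if e1 <= 0 or e0 <= 0:
        raise UndefinedDECError("zero segment energy; DEC undefined")
    return 10.0 * np.log10(e0 / e1) / _dec_distance_cm(cfg, meta)


def dea_map(roi_rf: np.ndarray, cfg: MapConfig, meta: AcquisitionMeta) -> FeatureMap:
    """DEC evaluated at every admissible (sample, beam) of a 2-D RF ROI.

    The valid region excludes the trailing ``length + interval`` samples of
    every beam; with the 64/16 defaults the map is 80 rows shorter than the
    ROI. Points where either segment has zero energy yield NaN.
    """
    rf = np.asarray(roi_rf, dtype=np.float64)
    if rf.ndim != 2:
        raise ValueError("dea_map expects a 2-D [axial, beam] RF ROI")
    L, S = cfg.dea_length_segment, cfg.dea_seg_interval
    n_ax, n_beam = rf.shape
    height = n_ax - (L + S)
    if height < 1:
        raise ROITooSmallError(
            f"ROI axial extent {n_ax} < segment length {L} + interval {S} + 1"
        )
    sq = rf**2
    cs = np.vstack([np.zeros((1, n_beam)), np.cumsum(sq, axis=0)])
    start = np.arange(height)
    e0 = cs[start + L, :] - cs[start, :]
    e1 = cs[start + S + L, :] - cs[start + S, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        dec = 10.0 * np.log10(e0 / e1) / _dec_distance_cm(cfg, meta)
    dec[(e0 <= 0) | (e1 <= 0)] = np.nan
    region = ROIRect(row0=0, col0=0, height=height, width=n_beam)
    return FeatureMap(kind="DEA", values=dec, valid_region=region)


def skewness(window: np.ndarray) -> float:
    """Third standardized sample moment (population convention)."""
    x = np.asarray(window, dtype=np.float64).ravel()
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    mu = x.mean()
    var = ((x - mu) ** 2).mean()
    if var <= 0:
        raise DegenerateWindowError("zero standard deviation; skewness undefined")
    k3 = ((x - mu) ** 3).mean()
    return float(k3 / var**1.5)


def skewness_map(roi_rf: np.ndarray, cfg: MapConfig) -> FeatureMap:
    """Sliding-window skewness of raw RF samples (step 1, interior-only)."""
    rf = np.asarray(roi_rf, dtype=np.float64)
    if rf.ndim != 2:
        raise ValueError("skewness_map expects a 2-D [axial, beam] RF ROI")
    win = (int(cfg.skew_window_axial), int(cfg.skew_window_beams))
    if rf.shape[0] < win[0] or rf.shape[1] < win[1]:
        raise ConfigError(f"skewness window {win} larger than ROI {rf.shape}")
    m1, m2, m3 = _sliding_moments(rf, win, (1, 2, 3))
    var = m2 - m1**2
    k3 = m3 - 3.0 * m1 * m2 + 2.0 * m1**3
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(var > 0, k3 / var**1.5, np.nan)
    region = _valid_region(rf.shape, win, 1)
    return FeatureMap(kind="RFI", values=skew, valid_region=region)


def export_feature_map(fmap: FeatureMap, tiff_path, csv_path=None) -> None:
    """Write a feature map as 32-bit float TIFF, optionally with a CSV summary.

    The CSV summary row holds the map kind, mean, std and valid dimensions
    (NaN pixels excluded from the statistics).
    """
    import pandas as pd
    import tifffile

    tifffile.imwrite(str(tiff_path), fmap.values.astype(np.float32))
    if csv_path is not None:
        summary = pd.DataFrame([{
            "kind": fmap.kind,
            "mean": float(np.nanmean(fmap.values)),
            "std": float(np.nanstd(fmap.values)),
            "valid_height": fmap.valid_region.height,
            "valid_width": fmap.valid_region.width,
        }])
        summary.to_csv(csv_path, index=False)
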