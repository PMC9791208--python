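"""Synthetic RF phantom generator.

Produces labeled multi-frame RF stacks whose envelope statistics, depth
attenuation and amplitude asymmetry are controlled by a few physical
dials, so every downstream stage (envelope, parametric maps, spectral
features, radiomics, classification) can be exercised and validated
without clinical data.

Model
-----
Each beam is a 1-D discrete scattering problem: scatterer sites occur on
the axial sample grid as a Poisson process (``scatterer_density`` mean
scatterers per axial resolution cell), with gamma-distributed amplitudes
(shape ``amplitude_shape``, mean 1) and random signs. The reflectivity
train is convolved axially with a Gaussian-modulated cosine pulse at
``pulse_center`` with fractional bandwidth ``pulse_bandwidth``.

Frequency-weighted depth attenuation is applied in two parts: the beam is
split into depth bands whose pulses receive a spectral tilt
``10^(-alpha (f - f0) 2 d / 20)`` (unit gain at the center frequency, so
the spectrum downshifts with depth), and a smooth per-sample amplitude
decay ``10^(-alpha f0 2 d / 20)`` carries the center-frequency energy
loss. ``alpha`` is in dB/(cm MHz) and ``d`` is depth in cm (two-way
travel already absorbed in the factor 2).

Amplitude asymmetry is injected as a quadratic waveform distortion
``x -> x + a (x^2 - E[x^2]) / rms(x)``, emulating the compression/
rarefaction asymmetry of finite-amplitude (nonlinear) propagation; its
sign sets the sign of the RF skewness. (Sign-asymmetric reflectivity
alone would not do: band-pass convolution with a zero-mean pulse
suppresses the third moment of an asymmetric impulse train almost
entirely.)

White Gaussian noise is added at ``noise_db`` SNR. Frames share scatterer
positions; each non-reference frame re-draws a fraction ``frame_jitter``
of the amplitudes, emulating slow-time decorrelation during a multi-second
capture.

The default sample rate is 64 MHz so the full 0-25 MHz analysis range
sits below Nyquist; the package's clinical-unit defaults (32 MHz, 154,000
cm/s) remain available through :class:`~rfqus.rf_io.AcquisitionMeta`.
The pulse is purely axial (no lateral point-spread function): no
downstream feature depends on lateral resolution shape, and the
simplification keeps the generator transparent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.fft import irfft, next_fast_len, rfft
from scipy.signal import gausspulse
from scipy.signal import hilbert as _hilbert

from .rf_io import (
    AcquisitionMeta,
    RFFrameStack,
    ROIRect,
    read_rf_stack,
    write_rf_stack,
    write_roi_table,
)

__all__ = [
    "PhantomSpec",
    "ClassParams",
    "CohortSpec",
    "CaseRecord",
    "CohortData",
    "simulate_rf",
    "simulate_cohort",
    "write_cohort",
    "load_cohort",
]

_N_DEPTH_BANDS = 16


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters for one synthetic case.

    scatterer_density is the mean number of scatterers per axial
    resolution cell (one pulse extent); ~10/cell or more gives fully
    developed Rayleigh speckle (Nakagami m = 1), well below 1/cell gives
    pre-Rayleigh statistics (m < 1).
    """

    n_axial: int = 768
    n_beams: int = 48
    n_frames: int = 4
    sample_rate: float = 6.4e7
    pulse_center: float = 4.0e6
    pulse_bandwidth: float = 0.6
    pulse_cycles: float = 2.0
    sound_speed: float = 154_000.0
    beam_pitch: float = 0.3
    frame_rate: float = 20.0
    scatterer_density: float = 4.0
    amplitude_shape: float = 50.0
    attenuation: float = 0.5
    asymmetry: float = 0.0
    noise_db: float = 30.0
    frame_jitter: float = 0.1
    seed: int = 0
    label: str = "benign"

    def __post_init__(self) -> None:
        if min(self.n_axial, self.n_beams, self.n_frames) < 1:
            raise ValueError("dimensions must be >= 1")
        if min(self.sample_rate, self.pulse_center, self.scatterer_density,
               self.amplitude_shape, self.sound_speed) <= 0:
            raise ValueError("rates, density and shape must be > 0")
        if not (0.0 <= self.frame_jitter <= 1.0):
            raise ValueError("frame_jitter must be in [0, 1]")
        if self.attenuation < 0:
            raise ValueError("attenuation must be >= 0")

    @property
    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta(
            sample_rate=self.sample_rate,
            center_frequency=self.pulse_center,
            sound_speed=self.sound_speed,
            beam_pitch=self.beam_pitch,
            frame_rate=self.frame_rate,
            n_axial=self.n_axial,
            n_beams=self.n_beams,
            n_frames=self.n_frames,
        )

    @property
    def cell_samples(self) -> int:
        """Axial resolution-cell extent in samples.

        Defined as the intensity-effective length of the transmit pulse,
        ``(sum e^2)^2 / sum e^4`` of its envelope ``e`` — the number of
        samples that contribute effectively to one speckle realization.
        With this definition ``scatterer_density`` is the mean number of
        scatterers acting within one resolution cell, which is the
        quantity that controls the envelope statistics.
        """
        pulse = _pulse(self)
        env2 = np.abs(_hilbert(pulse)) ** 2
        return max(1, int(round(env2.sum() ** 2 / np.sum(env2**2))))


def _pulse(spec: PhantomSpec) -> np.ndarray:
    """Gaussian-modulated cosine pulse, centered, truncated at low amplitude."""
    half_t = 4.0 / (spec.pulse_bandwidth * spec.pulse_center)
    half_n = int(np.ceil(half_t * spec.sample_rate))
    t = np.arange(-half_n, half_n + 1) / spec.sample_rate
    return gausspulse(t, fc=spec.pulse_center, bw=spec.pulse_bandwidth)


def simulate_rf(spec: PhantomSpec) -> RFFrameStack:
    """Simulate one multi-frame RF stack. Deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n_ax, n_beam, n_fr = spec.n_axial, spec.n_beams, spec.n_frames

    # Poisson scatterer sites on the sample grid
    lam = spec.scatterer_density / spec.cell_samples
    n_scat = rng.poisson(lam * n_ax * n_beam)
    pos_ax = rng.integers(0, n_ax, size=n_scat)
    pos_beam = rng.integers(0, n_beam, size=n_scat)
    signs = rng.choice((-1.0, 1.0), size=n_scat)
    base_amp = rng.gamma(spec.amplitude_shape, 1.0 / spec.amplitude_shape, size=n_scat)

    # per-frame amplitudes: frame 0 is the base draw; later frames re-draw
    # a fraction frame_jitter of the amplitudes
    amps = np.empty((n_scat, n_fr))
    amps[:, 0] = base_amp
    for f in range(1, n_fr):
        redraw = rng.random(n_scat) < spec.frame_jitter
        fresh = rng.gamma(spec.amplitude_shape, 1.0 / spec.amplitude_shape, size=n_scat)
        amps[:, f] = np.where(redraw, fresh, base_amp)

    pulse = _pulse(spec)
    half = pulse.size // 2
    nfft = next_fast_len(n_ax + pulse.size - 1)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / spec.sample_rate)
    pulse_fft = rfft(pulse, n=nfft)

    depth_cm_per_sample = spec.sound_speed / (2.0 * spec.sample_rate)
    band_len = int(np.ceil(n_ax / _N_DEPTH_BANDS))
    band_of = pos_ax // band_len

    rf = np.zeros((nfft, n_beam, n_fr))
    for b in range(_N_DEPTH_BANDS):
        in_band = band_of == b
        if not np.any(in_band):
            continue
        train = np.zeros((n_ax, n_beam, n_fr))
        np.add.at(
            train,
            (pos_ax[in_band], pos_beam[in_band]),
            signs[in_band, None] * amps[in_band, :],
        )
        d_cm = (b + 0.5) * band_len * depth_cm_per_sample
        # spectral tilt, unit gain at the center frequency
        tilt = 10.0 ** (
            -spec.attenuation * (freqs - spec.pulse_center) / 1e6 * 2.0 * d_cm / 20.0
        )
        spec_fft = rfft(train, n=nfft, axis=0) * (pulse_fft * tilt)[:, None, None]
        rf += irfft(spec_fft, n=nfft, axis=0)

    rf = rf[half : half + n_ax]

    # smooth center-frequency amplitude decay with depth
    depth_cm = np.arange(n_ax) * depth_cm_per_sample
    gain = 10.0 ** (-spec.attenuation * spec.pulse_center / 1e6 * 2.0 * depth_cm / 20.0)
    rf *= gain[:, None, None]

    # quadratic waveform distortion -> amplitude asymmetry (RF skewness)
    if spec.asymmetry != 0.0:
        rms = np.sqrt(np.mean(rf**2))
        if rms > 0:
            rf = rf + spec.asymmetry * (rf**2 - np.mean(rf**2)) / rms

    # additive white noise at the requested SNR
    rms = np.sqrt(np.mean(rf**2))
    sigma = rms * 10.0 ** (-spec.noise_db / 20.0) if rms > 0 else 1e-6
    rf = rf + rng.normal(0.0, sigma, size=rf.shape)

    return RFFrameStack(samples=rf.astype(np.float32), meta=spec.meta)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassParams:
    """Per-class generative parameter distributions (normal, clipped)."""

    density_mean: float = 4.0
    density_sd: float = 1.5
    attenuation_mean: float = 0.5
    attenuation_sd: float = 0.15
    asymmetry_mean: float = 0.0
    asymmetry_sd: float = 0.05
    amplitude_shape: float = 1.0


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a labeled synthetic cohort."""

    n_benign: int = 20
    n_malignant: int = 20
    benign: ClassParams = field(default_factory=ClassParams)
    malignant: ClassParams = field(default_factory=ClassParams)
    master_seed: int = 0
    template: PhantomSpec = field(default_factory=PhantomSpec)
    roi: ROIRect = field(default_factory=lambda: ROIRect(row0=160, col0=8, height=384, width=32))

    def __post_init__(self) -> None:
        if self.n_benign < 2 or self.n_malignant < 2:
            raise ValueError("need >= 2 cases per class for cross-validation")

    @classmethod
    def null_cohort(cls, n_per_class: int = 20, master_seed: int = 0, **kw) -> "CohortSpec":
        """A pure no-signal null: every case in both classes is generated
        with identical parameters (zero within-class spread), so labels are
        independent of everything except the speckle realization.

        With a nonzero within-class spread, the finite-sample difference
        between the two groups' drawn parameters is real, learnable signal
        inside the cohort; a calibration null must exclude it.
        """
        params = ClassParams(density_sd=0.0, attenuation_sd=0.0, asymmetry_sd=0.0)
        return cls(n_benign=n_per_class, n_malignant=n_per_class,
                   benign=params, malignant=params, master_seed=master_seed, **kw)

    @classmethod
    def separated_cohort(cls, n_per_class: int = 20, master_seed: int = 0, **kw) -> "CohortSpec":
        """Well-separated classes: dense/weakly-attenuating benign tissue
        (8 scatterers per cell, 0.3 dB/cm/MHz) versus sparse/strongly-
        attenuating malignant tissue (1 per cell, 1.0 dB/cm/MHz).
        """
        benign = ClassParams(density_mean=8.0, density_sd=0.5,
                             attenuation_mean=0.3, attenuation_sd=0.05)
        malignant = ClassParams(density_mean=1.0, density_sd=0.2,
                                attenuation_mean=1.0, attenuation_sd=0.05,
                                asymmetry_mean=0.1, asymmetry_sd=0.02)
        return cls(n_benign=n_per_class, n_malignant=n_per_class,
                   benign=benign, malignant=malignant, master_seed=master_seed, **kw)


@dataclass
class CaseRecord:
    case_id: str
    label: str
    spec: PhantomSpec
    stack: RFFrameStack
    roi: ROIRect


@dataclass
class CohortData:
    cases: list[CaseRecord]
    manifest: pd.DataFrame


def _draw_spec(
    template: PhantomSpec,
    params: ClassParams,
    label: str,
    rng: np.random.Generator,
    seed: int,
) -> PhantomSpec:
    density = max(0.1, rng.normal(params.density_mean, params.density_sd))
    attenuation = max(0.0, rng.normal(params.attenuation_mean, params.attenuation_sd))
    asymmetry = rng.normal(params.asymmetry_mean, params.asymmetry_sd)
    return replace(
        template,
        scatterer_density=density,
        attenuation=attenuation,
        asymmetry=asymmetry,
        amplitude_shape=params.amplitude_shape,
        seed=seed,
        label=label,
    )


def simulate_cohort(cohort: CohortSpec) -> CohortData:
    """Simulate all cases of a cohort; fully deterministic from master_seed.

    The manifest logs the drawn generative parameters per case so that
    parameter-recovery tests can compare estimates against ground truth.
    """
    ss = np.random.SeedSequence(cohort.master_seed)
    n_total = cohort.n_benign + cohort.n_malignant
    children = ss.spawn(n_total + 1)
    param_rng = np.random.default_rng(children[0])
    labels = ["benign"] * cohort.n_benign + ["malignant"] * cohort.n_malignant

    cases: list[CaseRecord] = []
    rows = []
    for idx, label in enumerate(labels):
        params = cohort.benign if label == "benign" else cohort.malignant
        case_seed = int(children[idx + 1].generate_state(1)[0] % (2**31))
        spec = _draw_spec(cohort.template, params, label, param_rng, case_seed)
        stack = simulate_rf(spec)
        case_id = f"case{idx:03d}"
        cases.append(CaseRecord(case_id=case_id, label=label, spec=spec,
                                stack=stack, roi=cohort.roi))
        rows.append({
            "case_id": case_id,
            "label": label,
            "true_density": spec.scatterer_density,
            "true_attenuation": spec.attenuation,
            "true_asymmetry": spec.asymmetry,
            "seed": spec.seed,
        })
    return CohortData(cases=cases, manifest=pd.DataFrame(rows))


def write_cohort(data: CohortData, out_dir: str | Path) -> None:
    """Write a simulated cohort to disk in the package's open RF format."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    roi_rows = []
    for case in data.cases:
        write_rf_stack(case.stack, out / f"{case.case_id}.rf", out / f"{case.case_id}.meta")
        roi_rows.append({
            "case_id": case.case_id,
            "row0": case.roi.row0,
            "col0": case.roi.col0,
            "height": case.roi.height,
            "width": case.roi.width,
            "label": case.label,
        })
    write_roi_table(pd.DataFrame(roi_rows), out / "rois.csv")
    data.manifest.to_csv(out / "manifest.csv", index=False)


def load_cohort(data_dir: str | Path) -> CohortData:
    """Read back a cohort written by :func:`write_cohort`."""
    root = Path(data_dir)
    rois = pd.read_csv(root / "rois.csv")
    manifest = pd.read_csv(root / "manifest.csv")
    cases = []
    for _, row in rois.iterrows():
        stack = read_rf_stack(root / f"{row.case_id}.rf", root / f"{row.case_id}.meta")
        roi = ROIRect(int(row.row0), int(row.col0), int(row.height), int(row.width))
        cases.append(CaseRecord(case_id=row.case_id, label=row.label,
                                spec=None, stack=stack, roi=roi))
    return CohortData(cases=cases, manifest=manifest)
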