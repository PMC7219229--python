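"""Forward-model simulator for CW Doppler radar vital-sign recordings.

The generator produces everything the detection chain consumes, with
known ground truth: a heartbeat event train, a chest-displacement
waveform (breathing sinusoid plus a compact two-lobe per-beat kernel
standing in for the ballistocardiographic J-wave recoil), quadrature
baseband channels

    I(t) = A_I * cos(theta0 + 4*pi*x(t)/lambda + dtheta(t)) + DC_I + n_I(t)
    Q(t) = A_Q * sin(theta0 + 4*pi*x(t)/lambda + dtheta(t) + dphi) + DC_Q + n_Q(t)

with amplitude/phase imbalance, DC offsets and additive white noise,
and a matched synthetic single-lead ECG whose R apexes sit exactly on
the beat times.  Only the baseband is synthesized: the RF transmit and
receive waves enter solely through ``theta0``, the amplitudes and the
residual phase-noise term, which is what the detector observes.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .signal_core import BeatTrain, SubjectRecording, TimeSeries

__all__ = [
    "SPEED_OF_LIGHT",
    "RadarParams",
    "VitalModel",
    "generate_beat_train",
    "chest_displacement",
    "beat_kernel_waveform",
    "synthesize_iq",
    "synthesize_ecg",
    "generate_cohort",
]

SPEED_OF_LIGHT = 299_792_458.0  # m/s

#: resting heart-rate range (beats/min) used for RR truncation
HR_RANGE = (40.0, 120.0)


@dataclass
class RadarParams:
    """Physical and front-end parameters of the quadrature radar.

    Defaults model the study conditions: a 24 GHz carrier (wavelength
    ~12.5 mm, so a 0.3 mm chest excursion spans ~0.3 rad of baseband
    phase), a subject at 0.75 m, ADC-scale unit amplitudes with a few
    percent I/Q amplitude imbalance, small DC offsets, ~0.1 rad phase
    imbalance, and additive white measurement noise.  Residual
    oscillator phase noise is negligible at this range and defaults to
    off.
    """

    carrier_f: float = 24e9          # Hz
    wavelength: Optional[float] = None  # m; c / carrier_f when omitted
    d0: float = 0.75                 # nominal radar-target distance, m
    theta0: float = 0.6              # constant phase offset, rad
    A_I: float = 1.0                 # in-phase baseband amplitude
    A_Q: float = 0.93                # quadrature amplitude (imbalance)
    DC_I: float = 0.12
    DC_Q: float = -0.09
    dphi: float = 0.10               # I/Q phase imbalance, rad
    phase_noise_sd: float = 0.0      # rad per sample, random-walk scale
    noise_sd: float = 0.02           # additive white noise, channel units
    A_T: float = 1.0                 # transmit amplitude (bookkeeping only)
    fs: float = 1000.0               # sampling rate, Hz

    def __post_init__(self) -> None:
        if not self.carrier_f > 0:
            raise ValueError("carrier frequency must be positive")
        lam = SPEED_OF_LIGHT / self.carrier_f
        if self.wavelength is None:
            self.wavelength = lam
        elif abs(self.wavelength - lam) > 1e-9 * lam:
            raise ValueError("wavelength inconsistent with carrier_f")
        if not self.fs > 0:
            raise ValueError("sampling rate must be positive")
        if self.phase_noise_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise scales must be non-negative")


@dataclass
class VitalModel:
    """Physiological model of one subject.

    ``beat_amp`` is the peak heartbeat chest excursion (sub-millimeter,
    order 1e-4 m); ``breath_amp`` the breathing excursion (order 1e-3 m).
    ``rj_delay_range`` is the electro-mechanical R-J delay interval the
    mechanical beat onset is drawn from, per beat.
    """

    mean_hr: float = 75.0            # beats/min, within HR_RANGE
    hrv_sd: float = 0.05             # s, RR-interval jitter
    breath_rate: float = 0.25        # Hz
    breath_amp: float = 1.2e-3       # m
    beat_amp: float = 3.0e-4         # m
    kernel_shape: str = "double_gaussian"
    kernel_params: dict = field(default_factory=dict)
    rj_delay_range: tuple = (0.203, 0.290)  # s

    def __post_init__(self) -> None:
        if not (HR_RANGE[0] <= self.mean_hr <= HR_RANGE[1]):
            raise ValueError(f"mean_hr must lie in {HR_RANGE}")
        if self.hrv_sd < 0:
            raise ValueError("hrv_sd must be non-negative")
        lo, hi = self.rj_delay_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError("rj_delay_range must lie within [0, 0.5] s")
        if self.breath_amp > 0 and not self.beat_amp < self.breath_amp:
            raise ValueError("beat_amp must be smaller than breath_amp")

    @property
    def mean_rr(self) -> float:
        return 60.0 / self.mean_hr


def generate_beat_train(model: VitalModel, duration: float,
                        seed: int) -> BeatTrain:
    """Draw R-event times with jittered RR intervals.

    RR intervals are ``60/mean_hr + N(0, hrv_sd)`` truncated to
    [0.5, 1.5] s (the 40-120 beats/min resting range); the first event
    falls uniformly inside the first mean RR interval.
    """
    if model.hrv_sd < 0:
        raise ValueError("hrv_sd must be non-negative")
    if not duration > 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    rr_mean = model.mean_rr
    t = rng.uniform(0.0, rr_mean)
    times = []
    while t < duration:
        times.append(t)
        rr = rr_mean + rng.normal(0.0, model.hrv_sd)
        rr = float(np.clip(rr, 60.0 / HR_RANGE[1], 60.0 / HR_RANGE[0]))
        t += rr
    return BeatTrain(np.asarray(times))


# -- per-beat displacement kernels ------------------------------------------
# All kernels vanish outside [0, 0.4] s after onset and are normalized to
# unit peak magnitude before scaling by beat_amp.

_KERNEL_SUPPORT = 0.4  # s


def _double_gaussian(tau, c1=0.075, c2=0.185, sigma=0.030):
    k = (np.exp(-0.5 * ((tau - c1) / sigma) ** 2)
         - np.exp(-0.5 * ((tau - c2) / sigma) ** 2))
    return k


def _single_gaussian(tau, c=0.10, sigma=0.040):
    return np.exp(-0.5 * ((tau - c) / sigma) ** 2)


def _damped_sine(tau, freq=8.0, decay=0.06):
    return np.sin(2 * np.pi * freq * tau) * np.exp(-tau / decay)


_KERNELS = {
    "double_gaussian": _double_gaussian,
    "gaussian": _single_gaussian,
    "damped_sine": _damped_sine,
}


def beat_kernel_waveform(model: VitalModel, fs: float) -> np.ndarray:
    """Sampled per-beat displacement kernel, peak-scaled to ``beat_amp``."""
    if model.kernel_shape not in _KERNELS:
        raise ValueError(f"unknown beat kernel '{model.kernel_shape}'")
    fn = _KERNELS[model.kernel_shape]
    tau = np.arange(int(round(_KERNEL_SUPPORT * fs)) + 1) / fs
    k = fn(tau, **model.kernel_params)
    peak = np.max(np.abs(k))
    if peak == 0:
        return k
    return k * (model.beat_amp / peak)


def chest_displacement(beats: BeatTrain, model: VitalModel, fs: float,
                       duration: float, seed: int) -> TimeSeries:
    """Chest-wall displacement x(t): breathing sinusoid + per-beat kernels.

    Each beat contributes one kernel delayed by an R-J interval drawn
    uniformly from ``model.rj_delay_range``; the breathing phase is
    random per call.
    """
    if not fs >= 50:
        raise ValueError("fs too low for the beat kernel bandwidth")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    phi_b = rng.uniform(0.0, 2 * np.pi)
    if model.breath_amp > 0:
        x = model.breath_amp * np.sin(2 * np.pi * model.breath_rate * t + phi_b)
    else:
        x = np.zeros(n)
    kern = beat_kernel_waveform(model, fs)
    lo, hi = model.rj_delay_range
    for tb in beats.times:
        d = rng.uniform(lo, hi)
        i0 = int(round((tb + d) * fs))
        i1 = min(i0 + len(kern), n)
        if i0 >= n:
            continue
        seg = slice(max(i0, 0), i1)
        x[seg] += kern[max(i0, 0) - i0:i1 - i0]
    return TimeSeries(x, fs, 0.0)


def synthesize_iq(x: TimeSeries, params: RadarParams,
                  seed: int) -> tuple:
    """Quadrature baseband channels for a displacement trace (metres).

    Implements the baseband model with amplitude/phase imbalance, DC
    offsets, an optional first-order random-walk residual phase noise,
    and additive white Gaussian measurement noise.
    """
    rng = np.random.default_rng(seed)
    n = len(x)
    phase = params.theta0 + 4 * np.pi * x.values / params.wavelength
    if params.phase_noise_sd > 0:
        phase = phase + np.cumsum(rng.normal(0.0, params.phase_noise_sd, n))
    i = params.A_I * np.cos(phase) + params.DC_I
    q = params.A_Q * np.sin(phase + params.dphi) + params.DC_Q
    if params.noise_sd > 0:
        i = i + rng.normal(0.0, params.noise_sd, n)
        q = q + rng.normal(0.0, params.noise_sd, n)
    return (TimeSeries(i, x.rate, x.t0), TimeSeries(q, x.rate, x.t0))


# -- synthetic ECG -----------------------------------------------------------

#: (amplitude, center offset from R in s, width sigma in s) per wave
_ECG_WAVES = (
    (0.12, -0.200, 0.025),   # P
    (-0.08, -0.025, 0.010),  # Q
    (1.00, 0.000, 0.012),    # R
    (-0.12, 0.025, 0.010),   # S
    (0.18, 0.250, 0.040),    # T
)


def synthesize_ecg(beats: BeatTrain, fs: float, duration: float, seed: int,
                   noise_sd: float = 0.01) -> TimeSeries:
    """Stereotyped P-QRS-T trace with the R apex exactly on each beat time.

    The R amplitude (1 mV) is more than five times the P/T amplitudes,
    so an amplitude threshold separates beats from baseline noise.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    v = rng.normal(0.0, noise_sd, n) if noise_sd > 0 else np.zeros(n)
    for tb in beats.times:
        for amp, off, sig in _ECG_WAVES:
            c = tb + off
            i0 = max(int(np.floor((c - 5 * sig) * fs)), 0)
            i1 = min(int(np.ceil((c + 5 * sig) * fs)) + 1, n)
            if i0 >= i1:
                continue
            v[i0:i1] += amp * np.exp(-0.5 * ((t[i0:i1] - c) / sig) ** 2)
    return TimeSeries(v, fs, 0.0)


# -- cohort ------------------------------------------------------------------

#: multiplicative jitter span applied per subject to rates/amplitudes
COHORT_JITTER = 0.15


def _jit(rng, value, frac=COHORT_JITTER):
    return value * rng.uniform(1 - frac, 1 + frac)


def generate_cohort(n_subjects: int = 21, duration: float = 200.0,
                    base_model: Optional[VitalModel] = None,
                    base_params: Optional[RadarParams] = None,
                    seed: int = 0) -> List[SubjectRecording]:
    """Simulate a cohort of aligned ECG (250 Hz) + I/Q (1 kHz) recordings.

    Per subject the vital and front-end parameters are perturbed by
    +/-15% multiplicative jitter (heart and breathing rates, breathing
    and beat amplitudes, channel amplitudes and noise), the DC offsets
    and phase imbalance by small additive jitter, and the operating
    phase ``theta0`` is drawn uniformly -- centimetre-scale differences
    in subject distance randomize the operating point completely.
    Ground-truth beat times are stored on every recording.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    base_model = base_model or VitalModel()
    base_params = base_params or RadarParams()
    out = []
    root = np.random.SeedSequence(seed)
    for idx, ss in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(ss)
        model = dataclasses.replace(
            base_model,
            mean_hr=float(np.clip(_jit(rng, base_model.mean_hr),
                                  HR_RANGE[0], HR_RANGE[1])),
            breath_rate=_jit(rng, base_model.breath_rate),
            breath_amp=_jit(rng, base_model.breath_amp),
            beat_amp=_jit(rng, base_model.beat_amp),
        )
        params = dataclasses.replace(
            base_params,
            wavelength=None,
            theta0=rng.uniform(0.0, 2 * np.pi),
            A_I=_jit(rng, base_params.A_I),
            A_Q=_jit(rng, base_params.A_Q),
            DC_I=base_params.DC_I + rng.uniform(-0.05, 0.05),
            DC_Q=base_params.DC_Q + rng.uniform(-0.05, 0.05),
            dphi=base_params.dphi + rng.uniform(-0.05, 0.05),
            noise_sd=_jit(rng, base_params.noise_sd),
        )
        s_beats, s_disp, s_iq, s_ecg = rng.integers(2 ** 31, size=4)
        beats = generate_beat_train(model, duration, int(s_beats))
        x = chest_displacement(beats, model, params.fs, duration, int(s_disp))
        i_ch, q_ch = synthesize_iq(x, params, int(s_iq))
        ecg = synthesize_ecg(beats, 250.0, duration, int(s_ecg))
        out.append(SubjectRecording(
            subject_id=f"S{idx + 1:02d}",
            ecg=ecg, i_ch=i_ch, q_ch=q_ch, truth_beats=beats,
        ))
    return out
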