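"""Forward simulation of two-wavelength fNIRS recordings with known ground truth.

The generative chain mirrors the physics of continuous-wave fNIRS in reverse
order of the analysis: a piecewise-constant neural drive derived from the
session timeline is convolved with a canonical double-gamma hemodynamic
response to give oxy-/deoxy-hemoglobin concentration changes per channel;
the modified Beer–Lambert law maps concentrations to optical density at
760 and 850 nm; physiological nuisance terms (cardiac, respiratory and
Mayer-wave oscillations, slow drift, white noise, motion spikes) are added
in optical-density space; and detected intensity is I0 * 10**(-OD), which is
strictly positive by construction.

A session-wise learning profile scales the regulation-segment neural drive
of selected channels, emulating the gradual acquisition of self-regulation
over the training programme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .protocol import EventTimeline, ProtocolConfig, build_session_timeline

__all__ = [
    "Montage", "HRFParams", "NoiseParams", "LearningProfile", "RawRecording",
    "ConditionDesign", "canonical_hrf", "neural_design",
    "simulate_concentrations", "forward_mbll", "synthesize_intensity",
    "simulate_session", "simulate_programme",
]

WAVELENGTHS = (760.0, 850.0)
DEFAULT_SAMPLING_RATE = 10.2

# source-detector pairs of the default 8x8 prefrontal headband montage;
# includes the four channels reported to show training-related changes
_DEFAULT_PAIRS = [
    (1, 1), (1, 2), (2, 1), (2, 2), (2, 3), (3, 2), (3, 3), (3, 5),
    (4, 3), (4, 4), (5, 4), (5, 5), (5, 6), (6, 5), (6, 6), (6, 7),
    (7, 6), (7, 7), (8, 7), (8, 8),
]
_REGIONS = {"S3-D2": "left dlPFC", "S3-D5": "left dlPFC",
            "S5-D5": "left dlPFC", "S5-D4": "dmPFC"}


@dataclass(frozen=True)
class Montage:
    """Optode layout: source-detector channel pairs with separations in mm."""

    channels: tuple[tuple[int, int, float, str], ...]
    n_sources: int = 8
    n_detectors: int = 8

    def __post_init__(self) -> None:
        labels = self.labels
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        for _, _, sep, _ in self.channels:
            if not 20.0 <= sep <= 45.0:
                raise ValueError(f"implausible source-detector separation {sep} mm")

    @property
    def labels(self) -> list[str]:
        return [f"S{s}-D{d}" for s, d, _, _ in self.channels]

    @property
    def separations_mm(self) -> np.ndarray:
        return np.array([sep for _, _, sep, _ in self.channels])

    @classmethod
    def default(cls) -> "Montage":
        chans = []
        for s, d in _DEFAULT_PAIRS:
            sep = 30.0 + (s + d) % 6          # 30-35 mm
            region = _REGIONS.get(f"S{s}-D{d}", "PFC")
            chans.append((s, d, sep, region))
        return cls(channels=tuple(chans))

    def subset(self, labels: list[str]) -> "Montage":
        keep = {lab: ch for lab, ch in zip(self.labels, self.channels)}
        missing = [lab for lab in labels if lab not in keep]
        if missing:
            raise ValueError(f"unknown channel labels {missing}; available: {self.labels}")
        return Montage(channels=tuple(keep[lab] for lab in labels),
                       n_sources=self.n_sources, n_detectors=self.n_detectors)


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma hemodynamic response parameters (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    hbr_scale: float = -1.0 / 3.0
    response_amplitude: float = 1e-6  # molar HbO change at sustained unit drive

    def __post_init__(self) -> None:
        if self.peak_dispersion <= 0 or self.undershoot_dispersion <= 0:
            raise ValueError("dispersions must be positive")
        if self.hbr_scale >= 0:
            raise ValueError("hbr_scale must be negative (HbR anticorrelated with HbO)")


@dataclass(frozen=True)
class NoiseParams:
    """Physiological and instrumental noise, amplitudes in optical-density units."""

    cardiac_freq: float = 1.1
    resp_freq: float = 0.25
    mayer_freq: float = 0.1
    cardiac_amp: float = 0.010
    resp_amp: float = 0.008
    mayer_amp: float = 0.005
    drift_slope: float = 1e-5      # OD per second, linear
    drift_amp: float = 0.005       # very-low-frequency random drift
    white_sd: float = 0.002
    motion_spike_rate: float = 0.5   # events per minute
    motion_spike_amplitude: float = 0.05
    motion_spike_tau: float = 1.0    # exponential decay, seconds
    rng_seed: int = 0

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2.0
        for name in ("cardiac_freq", "resp_freq", "mayer_freq"):
            f = getattr(self, name)
            if not 0 < f < nyq:
                raise ValueError(f"{name}={f} Hz outside (0, Nyquist={nyq} Hz)")
        for name in ("cardiac_amp", "resp_amp", "mayer_amp", "white_sd",
                     "motion_spike_rate", "motion_spike_amplitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def silent(cls, rng_seed: int = 0) -> "NoiseParams":
        """All noise amplitudes zero (for oracle/round-trip checks)."""
        return cls(cardiac_amp=0, resp_amp=0, mayer_amp=0, drift_slope=0,
                   drift_amp=0, white_sd=0, motion_spike_rate=0,
                   motion_spike_amplitude=0, rng_seed=rng_seed)


# session-wise multipliers of the regulation-segment neural drive; the
# default emulates the reported pattern: response rising up to session 3
# then plateauing, except S5-D5 which keeps rising through session 4
_PLATEAU = (1.0, 1.5, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0)
_RISING = (1.0, 1.45, 1.9, 2.4, 2.4, 2.4, 2.4, 2.4)


@dataclass(frozen=True)
class LearningProfile:
    """Per-channel, per-session amplitude multipliers for the regulation drive."""

    multipliers: dict[str, tuple[float, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for lab, mults in self.multipliers.items():
            if any(m <= 0 for m in mults):
                raise ValueError(f"multipliers for {lab} must be > 0")

    @property
    def affected_channels(self) -> list[str]:
        return list(self.multipliers)

    def multiplier(self, channel: str, session_index: int) -> float:
        mults = self.multipliers.get(channel)
        if mults is None:
            return 1.0
        return mults[min(session_index, len(mults)) - 1]

    @classmethod
    def default(cls) -> "LearningProfile":
        return cls(multipliers={
            "S3-D2": _PLATEAU, "S3-D5": _PLATEAU, "S5-D4": _PLATEAU,
            "S5-D5": _RISING,
        })

    @classmethod
    def flat(cls) -> "LearningProfile":
        return cls(multipliers={})

    def subset(self, labels: list[str]) -> "LearningProfile":
        """Restrict the profile to the channels present in a (sub-)montage."""
        return LearningProfile(multipliers={
            k: v for k, v in self.multipliers.items() if k in labels})


@dataclass
class RawRecording:
    """Two-wavelength raw intensity recording plus simulation ground truth.

    intensity and ground_truth are (n_channels, 2, n_samples) arrays; axis 1
    is wavelength (760, 850 nm) for intensity and chromophore (HbO, HbR) for
    ground truth. ``pad_pre``/``pad_post`` are seconds of extra signal before
    the baseline onset and after the training end.
    """

    sampling_rate: float
    intensity: np.ndarray
    montage: Montage
    timeline: EventTimeline
    ground_truth: np.ndarray | None = None
    wavelengths: tuple[float, float] = WAVELENGTHS
    pad_pre: float = 0.0
    pad_post: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.intensity <= 0):
            raise ValueError("intensity must be strictly positive")
        n_expected = int(round((self.timeline.total_duration + self.pad_pre
                                + self.pad_post) * self.sampling_rate))
        if abs(self.intensity.shape[-1] - n_expected) > 1:
            raise ValueError(
                f"sample count {self.intensity.shape[-1]} inconsistent with "
                f"duration x rate = {n_expected}")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[-1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate - self.pad_pre


def canonical_hrf(params: HRFParams = HRFParams(),
                  sampling_rate: float = DEFAULT_SAMPLING_RATE,
                  duration: float = 32.0) -> np.ndarray:
    """Double-gamma hemodynamic response kernel, peak normalized to 1.

    The positive lobe is a gamma density with mode at ``peak_delay``; the
    undershoot is a second gamma with mode at ``undershoot_delay``, scaled by
    ``undershoot_ratio`` and subtracted.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if params.peak_dispersion <= 0 or params.undershoot_dispersion <= 0:
        raise ValueError("dispersions must be positive")
    t = np.arange(int(round(duration * sampling_rate))) / sampling_rate

    def gamma_lobe(delay: float, disp: float) -> np.ndarray:
        shape = 1.0 + delay / disp          # mode = (shape-1)*scale = delay
        y = np.power(np.maximum(t, 0) / disp, shape - 1) * np.exp(-t / disp)
        return y / y.max()

    kernel = gamma_lobe(params.peak_delay, params.peak_dispersion)
    if params.undershoot_ratio != 0:
        kernel = kernel - params.undershoot_ratio * gamma_lobe(
            params.undershoot_delay, params.undershoot_dispersion)
    return kernel / np.abs(kernel).max()


@dataclass(frozen=True)
class ConditionDesign:
    """Per-condition neural drives aligned to the sampling grid.

    ``induction``/``regulation`` are the sustained segment-level boxcars;
    the ``*_phasic`` arrays hold the brief prompt-locked bursts evoked by
    each verbal phrase, which give the drive its event-related structure.
    """

    induction: np.ndarray
    regulation: np.ndarray
    induction_phasic: np.ndarray
    regulation_phasic: np.ndarray
    sampling_rate: float

    @property
    def combined(self) -> np.ndarray:
        return self.induction + self.regulation


def neural_design(timeline: EventTimeline,
                  condition_gains: dict[str, float] | None = None,
                  sampling_rate: float = DEFAULT_SAMPLING_RATE,
                  pad_pre: float = 0.0, pad_post: float = 0.0,
                  phasic_duration: float = 5.0,
                  phasic_gain: float = 1.0) -> ConditionDesign:
    """Piecewise-constant neural drive from the session timeline.

    Induction segments sit at the induction gain and regulation segments at
    the regulation gain; baseline and contextualisation are zero. On top of
    the sustained level, every verbal prompt evokes a short phasic burst
    (``phasic_duration`` seconds at ``phasic_gain`` times the segment gain),
    reflecting the transient engagement each phrase elicits.
    """
    gains = {"induction_prompt": 1.0, "regulation_prompt": 0.5}
    if condition_gains is not None:
        gains.update(condition_gains)
    n = int(round((timeline.total_duration + pad_pre + pad_post) * sampling_rate))
    ind, reg = np.zeros(n), np.zeros(n)
    ind_ph, reg_ph = np.zeros(n), np.zeros(n)
    n_phasic = int(round(phasic_duration * sampling_rate))
    for ev in timeline.events:
        if ev.event_type not in ("induction_prompt", "regulation_prompt"):
            continue
        g = gains[ev.event_type]
        i0 = int(round((ev.onset + pad_pre) * sampling_rate))
        i1 = int(round((ev.onset + ev.duration + pad_pre) * sampling_rate))
        sustained, phasic = ((ind, ind_ph) if ev.event_type == "induction_prompt"
                             else (reg, reg_ph))
        sustained[i0:min(i1, n)] = g
        phasic[i0:min(i0 + n_phasic, n)] = g * phasic_gain
    return ConditionDesign(induction=ind, regulation=reg,
                           induction_phasic=ind_ph, regulation_phasic=reg_ph,
                           sampling_rate=sampling_rate)


def simulate_concentrations(design: ConditionDesign, hrf: HRFParams,
                            learning: LearningProfile, session_index: int,
                            montage: Montage) -> np.ndarray:
    """Convolve the neural drive with the HRF kernel per channel.

    Returns (n_channels, 2, n) concentration changes; axis 1 is (HbO, HbR).
    The learning multiplier scales only the regulation-segment drive, so
    training-related gains change the balance between conditions rather than
    the overall signal scale (which later normalization would cancel).
    """
    unknown = [c for c in learning.affected_channels if c not in montage.labels]
    if unknown:
        raise ValueError(f"learning profile names unknown channels {unknown}; "
                         f"montage has {montage.labels}")
    kernel = canonical_hrf(hrf, design.sampling_rate)
    kernel = kernel / kernel.sum()  # sustained unit drive -> unit response
    n = design.induction.size
    conc = np.zeros((len(montage.channels), 2, n))
    base_ind = fftconvolve(design.induction + design.induction_phasic, kernel)[:n]
    base_reg = fftconvolve(design.regulation + design.regulation_phasic, kernel)[:n]
    for i, lab in enumerate(montage.labels):
        mult = learning.multiplier(lab, session_index)
        hbo = hrf.response_amplitude * (base_ind + mult * base_reg)
        conc[i, 0] = hbo
        conc[i, 1] = hrf.hbr_scale * hbo
    return conc


@dataclass(frozen=True)
class ExtinctionSpec:
    """2x2 molar extinction matrix, rows wavelength (760, 850), cols (HbO, HbR)."""

    matrix: tuple[tuple[float, float], tuple[float, float]] = (
        (645.5, 1548.52), (1669.0, 691.32))

    def as_array(self) -> np.ndarray:
        a = np.asarray(self.matrix, dtype=float)
        if abs(np.linalg.det(a)) < 1e-12 * np.abs(a).max() ** 2:
            raise np.linalg.LinAlgError("extinction matrix is singular")
        return a


def forward_mbll(concentrations: np.ndarray,
                 dpf: tuple[float, float] = (7.25, 6.38),
                 extinction: ExtinctionSpec = ExtinctionSpec(),
                 montage: Montage | None = None,
                 separations_cm: np.ndarray | None = None) -> np.ndarray:
    """Map concentration changes to optical density via the modified Beer-Lambert law.

    dOD(lambda, t) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR] * L * DPF(lambda)
    with L the source-detector separation in cm. Exact linear map; input and
    output are (n_channels, 2, n).
    """
    eps = extinction.as_array()
    if separations_cm is None:
        if montage is None:
            raise ValueError("provide montage or separations_cm")
        separations_cm = montage.separations_mm / 10.0
    conc = np.asarray(concentrations)
    od = np.einsum("wc,kcn->kwn", eps, conc)
    od *= separations_cm[:, None, None]
    od *= np.asarray(dpf)[None, :, None]
    return od


def synthesize_intensity(od_clean: np.ndarray, noise: NoiseParams,
                         sampling_rate: float = DEFAULT_SAMPLING_RATE,
                         baseline_intensity: float = 1.0,
                         rng: np.random.Generator | None = None) -> np.ndarray:
    """Detected intensity I0 * 10**-(OD_clean + OD_noise), strictly positive.

    Noise is drawn per channel and wavelength: sinusoidal cardiac/respiratory/
    Mayer components with random phases, a linear plus very-low-frequency
    random drift, white noise, and Poisson-timed motion spikes with
    exponential decay (shared across both wavelengths of a channel, as real
    motion is).
    """
    if baseline_intensity <= 0:
        raise ValueError("baseline_intensity must be positive")
    noise.validate(sampling_rate)
    if rng is None:
        rng = np.random.default_rng(noise.rng_seed)
    n_ch, n_wl, n = od_clean.shape
    t = np.arange(n) / sampling_rate
    od_noise = np.zeros_like(od_clean)

    for c in range(n_ch):
        # motion affects the optode pair: same spike train on both wavelengths
        spikes = np.zeros(n)
        lam = noise.motion_spike_rate * (n / sampling_rate) / 60.0
        n_spikes = rng.poisson(lam)
        if n_spikes > 0 and noise.motion_spike_amplitude > 0:
            onsets = rng.integers(0, n, size=n_spikes)
            signs = rng.choice([-1.0, 1.0], size=n_spikes)
            decay = np.exp(-np.arange(int(5 * noise.motion_spike_tau * sampling_rate))
                           / (noise.motion_spike_tau * sampling_rate))
            for o, s in zip(onsets, signs):
                seg = decay[: n - o]
                spikes[o:o + seg.size] += s * noise.motion_spike_amplitude * seg
        for w in range(n_wl):
            comp = np.zeros(n)
            for f, a in ((noise.cardiac_freq, noise.cardiac_amp),
                         (noise.resp_freq, noise.resp_amp),
                         (noise.mayer_freq, noise.mayer_amp)):
                phase = rng.uniform(0, 2 * np.pi)
                comp += a * np.sin(2 * np.pi * f * t + phase)
            comp += noise.drift_slope * t
            if noise.drift_amp > 0:
                phase = rng.uniform(0, 2 * np.pi)
                f_slow = 0.002
                comp += noise.drift_amp * np.sin(2 * np.pi * f_slow * t + phase)
            if noise.white_sd > 0:
                comp += rng.normal(0, noise.white_sd, size=n)
            od_noise[c, w] = comp + spikes

    return baseline_intensity * np.power(10.0, -(od_clean + od_noise))


def simulate_session(config: ProtocolConfig, session_index: int,
                     montage: Montage | None = None,
                     hrf: HRFParams = HRFParams(),
                     noise: NoiseParams = NoiseParams(),
                     learning: LearningProfile | None = None,
                     sampling_rate: float = DEFAULT_SAMPLING_RATE,
                     seed: int = 0,
                     pad_pre: float = 0.0, pad_post: float = 0.0,
                     condition_gains: dict[str, float] | None = None) -> RawRecording:
    """Simulate one session's raw two-wavelength recording with ground truth."""
    montage = montage or Montage.default()
    if learning is None:
        learning = LearningProfile.default().subset(montage.labels)
    timeline = build_session_timeline(config, session_index)
    design = neural_design(timeline, condition_gains, sampling_rate,
                           pad_pre=pad_pre, pad_post=pad_post)
    conc = simulate_concentrations(design, hrf, learning, session_index, montage)
    od = forward_mbll(conc, montage=montage)
    rng = np.random.default_rng(np.random.SeedSequence([seed, session_index]))
    intensity = synthesize_intensity(od, noise, sampling_rate, rng=rng)
    return RawRecording(sampling_rate=sampling_rate, intensity=intensity,
                        montage=montage, timeline=timeline, ground_truth=conc,
                        pad_pre=pad_pre, pad_post=pad_post, seed=seed)


def simulate_programme(config: ProtocolConfig,
                       n_sessions: int | None = None,
                       montage: Montage | None = None,
                       hrf: HRFParams = HRFParams(),
                       noise: NoiseParams = NoiseParams(),
                       learning: LearningProfile | None = None,
                       sampling_rate: float = DEFAULT_SAMPLING_RATE,
                       seed: int = 0,
                       condition_gains: dict[str, float] | None = None) -> list[RawRecording]:
    """One RawRecording per session; per-session seeds derived deterministically."""
    n = config.n_sessions if n_sessions is None else n_sessions
    if n > config.n_sessions:
        raise ValueError(f"n_sessions {n} exceeds configured {config.n_sessions}")
    return [simulate_session(config, s, montage, hrf, noise, learning,
                             sampling_rate, seed=seed,
                             condition_gains=condition_gains)
            for s in range(1, n + 1)]
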