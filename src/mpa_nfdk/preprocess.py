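"""Offline preprocessing chain for raw two-wavelength fNIRS intensity.

Stage order: crop to the protocol span, zero-phase FIR bandpass
(0.01-0.1 Hz, order-1000 Blackman windowed sinc), Symlet-4 wavelet
denoising (10 levels, detail levels D1-D5 removed), conversion to optical
density, modified Beer-Lambert inversion to HbO/HbR concentration changes,
and per-channel demeaning plus RMS normalization.

Because the bandpass is applied to intensity before the optical-density
conversion, each channel's pre-filter temporal mean is stored at crop time
and reintroduced inside the log ratio; this keeps the logarithm defined
while preserving the stated stage order. One consequence of the RMS
normalization is that the whole chain is invariant to any positive
rescaling of the raw intensities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy import signal

from .simulate import ExtinctionSpec, RawRecording

__all__ = [
    "FilterSpec", "WaveletSpec", "MbllParams", "HemoSeries",
    "DegenerateChannelError", "crop_to_protocol", "design_fir",
    "apply_zero_phase", "wavelet_denoise", "to_optical_density",
    "mbll_invert", "demean_rms_normalize", "preprocess_pipeline",
]


class DegenerateChannelError(ValueError):
    """A channel is constant (zero RMS after demeaning) and cannot be normalized."""


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase FIR bandpass: ``order`` is taps-1; default 1001-tap Blackman."""

    order: int = 1000
    window: str = "blackman"
    band: tuple[float, float] = (0.01, 0.1)

    def __post_init__(self) -> None:
        low, high = self.band
        if not 0 < low < high:
            raise ValueError(f"band must satisfy 0 < low < high, got {self.band}")
        if self.order < 2:
            raise ValueError("filter order must be >= 2")


@dataclass(frozen=True)
class WaveletSpec:
    """Multilevel wavelet denoise: zero listed detail levels, reconstruct."""

    family: str = "sym4"
    levels: int = 10
    removed_details: frozenset[int] = frozenset({1, 2, 3, 4, 5})
    boundary_mode: str = "symmetric"

    def __post_init__(self) -> None:
        bad = [d for d in self.removed_details if not 1 <= d <= self.levels]
        if bad:
            raise ValueError(f"removed detail levels {bad} outside 1..{self.levels}")


@dataclass(frozen=True)
class MbllParams:
    """Modified Beer-Lambert inversion parameters.

    ``dpf`` are the differential pathlength factors at (760, 850) nm;
    ``extinction`` is the wavelength x chromophore molar extinction matrix
    (only the HbO column is printed in most device manuals; the HbR column
    defaults to the standard compiled values in the same unit system);
    ``separation_cm`` is the geometric source-detector distance.
    """

    dpf: tuple[float, float] = (7.25, 6.38)
    extinction: ExtinctionSpec = field(default_factory=ExtinctionSpec)
    separation_cm: float = 3.0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.dpf):
            raise ValueError("DPF values must be positive")
        if self.separation_cm <= 0:
            raise ValueError("separation must be positive")
        self.extinction.as_array()  # raises if singular

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.extinction.as_array()))


@dataclass
class HemoSeries:
    """Preprocessed per-channel HbO/HbR series in normalized units.

    After the final stage every non-degenerate channel has |mean| <= 1e-9
    and |RMS - 1| <= 1e-9. ``provenance`` lists the applied stages with
    their parameters; ``qc`` carries clipped-sample counts and degenerate
    channel flags.
    """

    sampling_rate: float
    hbo: np.ndarray
    hbr: np.ndarray
    channels: list[str]
    timeline: object = None
    provenance: list[dict] = field(default_factory=list)
    qc: dict = field(default_factory=dict)

    def get(self, channel: str, chromophore: str = "hbo") -> np.ndarray:
        arr = {"hbo": self.hbo, "hbr": self.hbr}[chromophore.lower()]
        return arr[self.channels.index(channel)]


def crop_to_protocol(recording: RawRecording) -> RawRecording:
    """Trim samples outside [baseline onset, end of active training]."""
    fs = recording.sampling_rate
    n_total = recording.n_samples
    i0 = int(round(recording.pad_pre * fs))
    i1 = i0 + int(round(recording.timeline.total_duration * fs))
    if i0 < 0 or i1 > n_total:
        raise ValueError(
            f"protocol span [{i0}, {i1}) exceeds recording of {n_total} samples")
    if i0 == 0 and i1 == n_total:
        return recording
    gt = recording.ground_truth
    return replace(
        recording,
        intensity=recording.intensity[..., i0:i1],
        ground_truth=None if gt is None else gt[..., i0:i1],
        pad_pre=0.0, pad_post=0.0,
    )


def design_fir(spec: FilterSpec, sampling_rate: float) -> np.ndarray:
    """Windowed-sinc linear-phase bandpass taps (length order+1, symmetric)."""
    nyq = sampling_rate / 2.0
    low, high = spec.band
    if not 0 < low < high < nyq:
        raise ValueError(f"band {spec.band} outside (0, Nyquist={nyq} Hz)")
    order = spec.order if spec.order % 2 == 0 else spec.order + 1
    if order != spec.order:
        warnings.warn(f"filter order rounded up to even value {order} "
                      "for symmetric linear phase", stacklevel=2)
    return signal.firwin(order + 1, [low, high], window=spec.window,
                         pass_zero=False, fs=sampling_rate)


def apply_zero_phase(x: np.ndarray, coefficients: np.ndarray) -> np.ndarray:
    """Forward-backward FIR application: zero group delay, squared magnitude."""
    x = np.asarray(x, dtype=float)
    ntaps = len(coefficients)
    padlen = min(3 * ntaps, x.shape[-1] - 1)
    if x.shape[-1] < ntaps // 4:
        raise ValueError(
            f"series of {x.shape[-1]} samples too short for a {ntaps}-tap "
            "zero-phase filter")
    return signal.filtfilt(coefficients, [1.0], x, padlen=padlen)


def wavelet_denoise(x: np.ndarray, spec: WaveletSpec = WaveletSpec()) -> np.ndarray:
    """Zero the selected detail levels of a multilevel DWT and reconstruct.

    Detail level 1 holds the highest frequency band (fs/4..fs/2); each
    further level halves the band. Removing D1-D5 at 10.2 Hz suppresses
    everything above roughly 0.16 Hz, including cardiac pulsation and sharp
    motion transients. Output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    wavelet = pywt.Wavelet(spec.family)
    max_level = pywt.dwt_max_level(x.shape[-1], wavelet.dec_len)
    levels = spec.levels
    if max_level < 1:
        raise ValueError(
            f"series of {x.shape[-1]} samples too short for any '{spec.family}' "
            f"decomposition; need at least {wavelet.dec_len} samples")
    if max_level < levels:
        warnings.warn(
            f"series of {x.shape[-1]} samples supports only {max_level} of the "
            f"requested {levels} levels; decomposing to {max_level}", stacklevel=2)
        levels = max_level
    coeffs = pywt.wavedec(x, wavelet, mode=spec.boundary_mode, level=levels)
    # coeffs = [A_L, D_L, ..., D_1]; detail level d sits at index -d
    for d in spec.removed_details:
        if d <= levels:
            coeffs[-d] = np.zeros_like(coeffs[-d])
    out = pywt.waverec(coeffs, wavelet, mode=spec.boundary_mode)
    return out[..., : x.shape[-1]]


def to_optical_density(intensity_filtered: np.ndarray, stored_channel_mean: float,
                       clip_floor: float = 1e-6) -> tuple[np.ndarray, int]:
    """dOD(t) = -log10((filtered + mean)/mean); returns (series, n_clipped).

    ``stored_channel_mean`` is the channel's pre-filter temporal mean, which
    restores the DC level the bandpass removed. Arguments of the log at or
    below ``clip_floor * mean`` are clipped there and counted.
    """
    if stored_channel_mean <= 0:
        raise ValueError("stored channel mean must be positive")
    ratio = (np.asarray(intensity_filtered, dtype=float) + stored_channel_mean) \
        / stored_channel_mean
    n_clipped = int(np.count_nonzero(ratio <= clip_floor))
    ratio = np.maximum(ratio, clip_floor)
    return -np.log10(ratio), n_clipped


def mbll_invert(od_760: np.ndarray, od_850: np.ndarray,
                params: MbllParams = MbllParams()) -> tuple[np.ndarray, np.ndarray]:
    """Solve the 2x2 modified Beer-Lambert system per sample.

    dOD(lambda) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR] * L * DPF(lambda);
    exact inverse of the forward model for the same parameters.
    """
    od_760 = np.asarray(od_760, dtype=float)
    od_850 = np.asarray(od_850, dtype=float)
    if od_760.shape != od_850.shape:
        raise ValueError("wavelength series must have equal length")
    eps = params.extinction.as_array()
    a = eps * params.separation_cm * np.asarray(params.dpf)[:, None]
    rhs = np.stack([od_760, od_850])
    conc = np.linalg.solve(a, rhs)
    return conc[0], conc[1]


def demean_rms_normalize(x: np.ndarray, rms_tol: float = 1e-300) -> np.ndarray:
    """Subtract the mean and scale to unit root-mean-square amplitude."""
    x = np.asarray(x, dtype=float)
    centered = x - x.mean(axis=-1, keepdims=True)
    rms = np.sqrt(np.mean(centered ** 2, axis=-1, keepdims=True))
    if np.any(rms <= rms_tol):
        raise DegenerateChannelError(
            "constant channel: zero RMS after demeaning")
    return centered / rms


def preprocess_pipeline(recording: RawRecording,
                        filter_spec: FilterSpec = FilterSpec(),
                        wavelet_spec: WaveletSpec = WaveletSpec(),
                        mbll_params: MbllParams | None = None) -> HemoSeries:
    """Run the full chain: crop, FIR bandpass, wavelet denoise, OD, MBLL
    inversion, demean + RMS normalization.

    Degenerate (constant) channels are flagged in ``qc['degenerate_channels']``
    and carried through as NaN rather than silently passed.
    """
    cropped = crop_to_protocol(recording)
    fs = cropped.sampling_rate
    taps = design_fir(filter_spec, fs)
    labels = cropped.montage.labels
    seps_cm = cropped.montage.separations_mm / 10.0

    n_ch, _, n = cropped.intensity.shape
    hbo = np.full((n_ch, n), np.nan)
    hbr = np.full((n_ch, n), np.nan)
    clipped_counts: dict[str, int] = {}
    degenerate: list[str] = []

    for i, lab in enumerate(labels):
        od = np.empty((2, n))
        for w in range(2):
            raw = cropped.intensity[i, w]
            stored_mean = float(raw.mean())
            filtered = apply_zero_phase(raw - stored_mean, taps)
            denoised = wavelet_denoise(filtered, wavelet_spec)
            od[w], n_clip = to_optical_density(denoised, stored_mean)
            clipped_counts[f"{lab}@{int(round([760, 850][w]))}"] = n_clip
        params = mbll_params or MbllParams()
        params = replace(params, separation_cm=float(seps_cm[i]))
        c_hbo, c_hbr = mbll_invert(od[0], od[1], params)
        try:
            hbo[i] = demean_rms_normalize(c_hbo)
            hbr[i] = demean_rms_normalize(c_hbr)
        except DegenerateChannelError:
            degenerate.append(lab)

    provenance = [
        {"stage": "crop", "duration_s": cropped.timeline.total_duration},
        {"stage": "fir_bandpass", "order": filter_spec.order,
         "window": filter_spec.window, "band_hz": list(filter_spec.band),
         "application": "forward-backward (zero phase)"},
        {"stage": "wavelet_denoise", "family": wavelet_spec.family,
         "levels": wavelet_spec.levels,
         "removed_details": sorted(wavelet_spec.removed_details),
         "boundary_mode": wavelet_spec.boundary_mode},
        {"stage": "optical_density", "reference": "stored pre-filter channel mean"},
        {"stage": "mbll_invert",
         "dpf": list((mbll_params or MbllParams()).dpf),
         "extinction": [list(r) for r in (mbll_params or MbllParams()).extinction.matrix],
         "separation": "per-channel montage value (cm)"},
        {"stage": "demean_rms_normalize"},
    ]
    return HemoSeries(
        sampling_rate=fs, hbo=hbo, hbr=hbr, channels=labels,
        timeline=cropped.timeline, provenance=provenance,
        qc={"clipped_samples": clipped_counts, "degenerate_channels": degenerate},
    )
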