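"""Closed-loop thermometer feedback simulation.

The online path differs from the offline analysis chain: a real-time display
can only filter causally, so the region-of-interest signal is band-passed
with a recursive (Butterworth, second-order-section) filter over the
0.01-0.3 Hz hemodynamic band and mapped, relative to the session baseline,
onto a quantized thermometer with a fixed number of levels. A pluggable
"responder" closes the loop: it maps the displayed level to the regulation
drive of the next update interval, emulating a participant who learns (or
fails to learn) to self-regulate from the feedback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy import signal

from .protocol import EventTimeline
from .simulate import (DEFAULT_SAMPLING_RATE, HRFParams, canonical_hrf,
                       neural_design)

__all__ = ["FeedbackConfig", "OnlineBandpass", "online_filter",
           "BaselineStats", "thermometer_level", "run_closed_loop",
           "null_responder", "positive_responder"]


@dataclass(frozen=True)
class FeedbackConfig:
    """Online feedback parameters.

    ``online_band`` is the real-time bandpass (Hz); ``z_span`` sets the
    baseline z-score range mapped linearly onto the thermometer, clipped at
    the ends.
    """

    online_band: tuple[float, float] = (0.01, 0.3)
    roi_channels: tuple[str, ...] = ("S5-D5",)
    baseline_window: float = 180.0
    update_interval: float = 1.0
    thermometer_levels: int = 10
    z_span: tuple[float, float] = (-2.0, 2.0)
    filter_order: int = 4

    def __post_init__(self) -> None:
        low, high = self.online_band
        if not 0 < low < high:
            raise ValueError(f"online band must satisfy 0 < low < high, got {self.online_band}")
        if self.thermometer_levels < 2:
            raise ValueError("thermometer needs at least 2 levels")


class OnlineBandpass:
    """Causal recursive bandpass with streaming state (one channel)."""

    def __init__(self, config: FeedbackConfig, sampling_rate: float):
        low, high = config.online_band
        nyq = sampling_rate / 2.0
        if high >= nyq:
            raise ValueError(f"online band {config.online_band} exceeds Nyquist {nyq} Hz")
        self.sos = signal.butter(config.filter_order, [low, high],
                                 btype="bandpass", fs=sampling_rate, output="sos")
        self.zi = np.zeros((self.sos.shape[0], 2))

    def process(self, chunk: np.ndarray) -> np.ndarray:
        out, self.zi = signal.sosfilt(self.sos, np.asarray(chunk, dtype=float),
                                      zi=self.zi)
        return out


def online_filter(stream: np.ndarray, config: FeedbackConfig,
                  sampling_rate: float) -> np.ndarray:
    """Filter a whole series causally (output at t depends only on samples <= t)."""
    return OnlineBandpass(config, sampling_rate).process(np.asarray(stream, dtype=float))


@dataclass(frozen=True)
class BaselineStats:
    mean: float
    sd: float

    @classmethod
    def from_window(cls, samples: np.ndarray) -> "BaselineStats":
        samples = np.asarray(samples, dtype=float)
        if samples.size == 0:
            raise ValueError("empty baseline window")
        sd = float(samples.std())
        return cls(mean=float(samples.mean()), sd=sd if sd > 0 else 1.0)


def thermometer_level(roi_value: float, baseline_stats: BaselineStats | None,
                      config: FeedbackConfig = FeedbackConfig()) -> int:
    """Quantize a baseline-referenced signal change onto the thermometer.

    Linear in baseline z-units over ``z_span``, clipped at the range ends;
    the baseline mean maps to the middle level. Monotone non-decreasing in
    the input by construction.
    """
    if baseline_stats is None:
        raise RuntimeError("baseline statistics missing: collect the baseline "
                           "window before displaying feedback")
    z = (roi_value - baseline_stats.mean) / baseline_stats.sd
    lo, hi = config.z_span
    frac = (z - lo) / (hi - lo)
    level = int(np.floor(frac * config.thermometer_levels))
    return int(np.clip(level, 0, config.thermometer_levels - 1))


def null_responder(level: int, config: FeedbackConfig) -> float:
    """Ignores the display: constant regulation gain."""
    return 1.0


def positive_responder(level: int, config: FeedbackConfig,
                       gain_step: float = 0.15, max_gain: float = 3.0) -> float:
    """Regulation gain grows with the displayed level (successful learning)."""
    return float(min(max_gain, 1.0 + gain_step * level))


def run_closed_loop(timeline: EventTimeline,
                    responder: Callable[[int, FeedbackConfig], float] = null_responder,
                    config: FeedbackConfig = FeedbackConfig(),
                    hrf: HRFParams = HRFParams(),
                    sampling_rate: float = DEFAULT_SAMPLING_RATE,
                    noise_sd: float = 0.05,
                    seed: int = 0,
                    base_regulation_gain: float = 0.5) -> tuple[pd.DataFrame, np.ndarray]:
    """Feedback-coupled simulation of one session's ROI signal.

    The session is stepped in update intervals. Within regulation segments
    the neural drive of each upcoming interval is ``base_regulation_gain``
    times the responder's output for the currently displayed level; induction
    segments keep their fixed drive. The ROI concentration signal is the
    causal convolution of the accumulating drive with the HRF kernel plus
    white measurement noise, band-passed causally; thermometer levels are
    emitted once per interval after the baseline window.

    Returns the thermometer trace (time_s, roi_value, level) and the
    feedback-modulated ground-truth drive.
    """
    rng = np.random.default_rng(seed)
    kernel = canonical_hrf(hrf, sampling_rate)
    design = neural_design(timeline, {"regulation_prompt": 1.0}, sampling_rate)
    n = design.induction.size
    step = max(1, int(round(config.update_interval * sampling_rate)))
    n_base = int(round(config.baseline_window * sampling_rate))

    drive = np.zeros(n)
    conc = np.zeros(n)  # causal convolution, accumulated incrementally
    noise = rng.normal(0.0, noise_sd, size=n)
    bp = OnlineBandpass(config, sampling_rate)
    roi = np.zeros(n)

    level = config.thermometer_levels // 2
    gain = responder(level, config)
    _check_gain(gain)
    baseline_stats: BaselineStats | None = None
    rows = []

    for i0 in range(0, n, step):
        i1 = min(i0 + step, n)
        seg = slice(i0, i1)
        drive[seg] = design.induction[seg] \
            + base_regulation_gain * gain * design.regulation[seg]
        # causal contribution of this interval's drive onto the future
        for j in range(i0, i1):
            if drive[j] != 0.0:
                m = min(kernel.size, n - j)
                conc[j:j + m] += drive[j] * hrf.response_amplitude * kernel[:m]
        roi[seg] = bp.process(conc[seg] + noise[seg])
        if i1 >= n_base and baseline_stats is None:
            baseline_stats = BaselineStats.from_window(roi[:n_base])
        if baseline_stats is not None:
            level = thermometer_level(float(roi[i1 - 1]), baseline_stats, config)
            rows.append({"time_s": (i1 - 1) / sampling_rate,
                         "roi_value": float(roi[i1 - 1]), "level": level})
            gain = responder(level, config)
            _check_gain(gain)

    trace = pd.DataFrame(rows, columns=["time_s", "roi_value", "level"])
    return trace, drive


def _check_gain(gain: float) -> None:
    if not 0.0 <= gain <= 10.0:
        raise ValueError(f"responder returned out-of-range gain {gain}")
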