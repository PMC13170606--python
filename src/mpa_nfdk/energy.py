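"""Epoching and epoch-to-mean energy-ratio analysis of preprocessed series.

Fifteen-second epochs are locked to prompt onsets: induction prompts define
stressor epochs, regulation prompts define control epochs. For each epoch
the energy E = sum_n |x(n)|^2 is computed over its samples; the epoch's
ratio is E divided by the mean epoch energy of its (channel, chromophore,
session) group, both conditions pooled, which makes the group mean of the
ratios exactly 1 and turns the statistic into a within-session relative
activation measure. Ratios are then averaged per condition and summarized
per session with boxplot five-number summaries, and the session trajectory
of condition means is classified as rising-then-plateau, rising-throughout,
flat, or other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import HemoSeries
from .protocol import EventTimeline

__all__ = [
    "Epoch", "EpochSet", "extract_epochs", "epoch_energy", "energy_ratios",
    "average_by_event", "summarize_sessions", "classify_trend",
    "DEFAULT_CONDITION_MAP", "analyze_programme",
]

DEFAULT_CONDITION_MAP = {"induction_prompt": "stressor",
                         "regulation_prompt": "control"}

DEFAULT_EPOCH_DURATION = 15.0


@dataclass(frozen=True)
class Epoch:
    """A fixed-length signal window locked to an event onset."""

    channel: str
    chromophore: str
    condition: str
    onset: float
    samples: np.ndarray
    session_index: int


@dataclass(frozen=True)
class EpochSet:
    epochs: tuple[Epoch, ...]
    n_discarded: int


def extract_epochs(series: HemoSeries, timeline: EventTimeline,
                   epoch_duration: float = DEFAULT_EPOCH_DURATION,
                   condition_map: dict[str, str] | None = None,
                   chromophores: tuple[str, ...] = ("hbo", "hbr")) -> EpochSet:
    """Cut one epoch per mapped event per channel per chromophore.

    Epochs that would extend past the end of the recording are discarded and
    counted, never zero-padded.
    """
    if condition_map is None:
        condition_map = DEFAULT_CONDITION_MAP
    mapped = [e for e in timeline.events if e.event_type in condition_map]
    if not mapped:
        raise ValueError("timeline contains no mapped events to epoch")
    fs = series.sampling_rate
    n_samp = int(round(epoch_duration * fs))
    n_total = series.hbo.shape[-1]

    epochs: list[Epoch] = []
    n_discarded = 0
    for ev in mapped:
        i0 = int(round(ev.onset * fs))
        if i0 < 0 or i0 + n_samp > n_total:
            n_discarded += len(series.channels) * len(chromophores)
            continue
        for chrom in chromophores:
            data = {"hbo": series.hbo, "hbr": series.hbr}[chrom]
            for ci, ch in enumerate(series.channels):
                epochs.append(Epoch(
                    channel=ch, chromophore=chrom,
                    condition=condition_map[ev.event_type],
                    onset=ev.onset, samples=data[ci, i0:i0 + n_samp],
                    session_index=timeline.session_index))
    return EpochSet(epochs=tuple(epochs), n_discarded=n_discarded)


def epoch_energy(epoch: Epoch | np.ndarray) -> float:
    """Signal energy: sum of squared sample values over the epoch.

    Accumulated left-to-right in sample order, so any straightforward
    reimplementation of the sum reproduces the value bit-for-bit.
    """
    x = epoch.samples if isinstance(epoch, Epoch) else np.asarray(epoch)
    if x.size == 0:
        raise ValueError("empty epoch has no energy")
    acc = 0.0
    for v in x.tolist():
        acc += v * v
    return acc


def energy_ratios(epochs: list[Epoch] | EpochSet) -> pd.DataFrame:
    """Per-epoch energies and epoch-to-mean energy ratios.

    The denominator is the mean energy over all epochs (both conditions) of
    the same channel, chromophore and session, so within each such group the
    mean ratio is 1 by construction.
    """
    if isinstance(epochs, EpochSet):
        epochs = list(epochs.epochs)
    if not epochs:
        raise ValueError("no epochs to analyse")
    rows = [{
        "channel": e.channel, "chromophore": e.chromophore,
        "session": e.session_index, "condition": e.condition,
        "onset": e.onset, "energy": epoch_energy(e),
    } for e in epochs]
    df = pd.DataFrame(rows).sort_values(
        ["channel", "chromophore", "session", "onset"], kind="stable")
    group = df.groupby(["channel", "chromophore", "session"], sort=False)
    mean_energy = group["energy"].transform("mean")
    if np.any(mean_energy.to_numpy() <= 0):
        bad = df.loc[mean_energy <= 0, ["channel", "chromophore", "session"]]
        raise ValueError(
            f"zero mean energy (all-zero signal) in groups:\n{bad.drop_duplicates()}")
    df["ratio"] = df["energy"] / mean_energy
    df["epoch_index"] = group.cumcount()
    return df.reset_index(drop=True)


def average_by_event(records: pd.DataFrame) -> pd.DataFrame:
    """Mean ratio per (channel, chromophore, session, condition)."""
    if records.empty:
        raise ValueError("no records to average")
    out = (records.groupby(["channel", "chromophore", "session", "condition"],
                           sort=True)
           .agg(n_epochs=("ratio", "size"), mean_ratio=("ratio", "mean"))
           .reset_index())
    return out


def summarize_sessions(records: pd.DataFrame,
                       channels_of_interest: list[str] | None = None) -> pd.DataFrame:
    """Boxplot five-number summaries per channel x chromophore x session x condition."""
    if channels_of_interest is not None:
        available = set(records["channel"].unique())
        unknown = [c for c in channels_of_interest if c not in available]
        if unknown:
            raise ValueError(
                f"unknown channels {unknown}; available: {sorted(available)}")
        records = records[records["channel"].isin(channels_of_interest)]

    def five_number(g: pd.Series) -> pd.Series:
        q1, med, q3 = np.percentile(g, [25, 50, 75])
        iqr = q3 - q1
        lo = g[g >= q1 - 1.5 * iqr].min()
        hi = g[g <= q3 + 1.5 * iqr].max()
        return pd.Series({"n_epochs": g.size, "mean_ratio": g.mean(),
                          "q1": q1, "median": med, "q3": q3,
                          "whisker_low": lo, "whisker_high": hi})

    out = (records.groupby(["channel", "chromophore", "session", "condition"],
                           sort=True)["ratio"]
           .apply(five_number).unstack().reset_index())
    out["n_epochs"] = out["n_epochs"].astype(int)
    return out


def classify_trend(per_session_means: np.ndarray | list[float],
                   plateau_tol: float = 0.05) -> str:
    """Classify a session trajectory of condition means.

    Successive relative changes d_i = (m_{i+1} - m_i) / m_i are compared to
    the plateau tolerance: all |d| <= tol is ``flat``; all d > tol is
    ``rising_throughout``; one or more rises followed only by
    within-tolerance changes is ``rising_then_plateau``; anything else
    (drops, dips, late rises after a plateau) is ``other``.
    """
    m = np.asarray(per_session_means, dtype=float)
    if m.size < 3:
        raise ValueError("need means from at least 3 sessions to classify a trend")
    d = np.diff(m) / m[:-1]
    rising = d > plateau_tol
    flat = np.abs(d) <= plateau_tol
    if flat.all():
        return "flat"
    if rising.all():
        return "rising_throughout"
    k = int(np.argmax(~rising))  # first non-rising step
    if k >= 1 and rising[:k].all() and flat[k:].all():
        return "rising_then_plateau"
    return "other"


def analyze_programme(hemo_list: list[HemoSeries],
                      epoch_duration: float = DEFAULT_EPOCH_DURATION,
                      condition_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Energy-ratio records for a whole programme of preprocessed sessions."""
    frames = []
    for hemo in hemo_list:
        es = extract_epochs(hemo, hemo.timeline, epoch_duration, condition_map)
        frames.append(energy_ratios(es))
    return pd.concat(frames, ignore_index=True)
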