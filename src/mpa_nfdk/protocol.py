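"""Session scheduling and stimulus assignment for the neurofeedback training programme.

The training programme consists of biweekly sessions, each built from three
phases: a resting-state baseline, a contextualisation phase in which the
participant listens to a performance scenario drawn from their personal
anxiety hierarchy, and an active-training phase of consecutive blocks that
alternate a short anxiety-induction segment with a longer self-regulation
segment. Verbal prompts are delivered on a fixed cadence inside each block;
every prompt carries a phrase drawn without replacement from a finite
stimulus pool so that no phrase repeats across the whole programme.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ProtocolConfig",
    "Event",
    "EventTimeline",
    "StimulusPool",
    "ExposureHierarchy",
    "build_session_timeline",
    "build_programme",
    "count_prompts",
    "assign_stimuli",
    "rank_hierarchy",
    "select_context_scenario",
    "PoolExhaustedError",
]

STAGES = ("Adaptation", "Symptom Identification", "Refinement", "Conditioning")

EVENT_TYPES = ("baseline", "contextualisation", "induction_prompt", "regulation_prompt")


class PoolExhaustedError(RuntimeError):
    """Raised when a stimulus pool has fewer phrases than prompts to serve."""


def _default_stage_map(n_sessions: int) -> dict[int, str]:
    """Partition sessions 1..n into the four training stages, in order."""
    chunks = np.array_split(np.arange(1, n_sessions + 1), min(4, n_sessions))
    return {int(s): STAGES[i] for i, chunk in enumerate(chunks) for s in chunk}


@dataclass(frozen=True)
class ProtocolConfig:
    """All timing and counting parameters of the training programme.

    Durations are in seconds. Defaults reproduce the published protocol:
    3 min baseline, 1 min contextualisation, five 3-min blocks of
    30 s induction + 2.5 min regulation, prompts every 30 s, eight sessions,
    a 40-phrase induction pool and 200-phrase control pool, and a
    19-situation exposure hierarchy.
    """

    baseline_duration: float = 180.0
    contextualisation_duration: float = 60.0
    n_blocks: int = 5
    block_duration: float = 180.0
    induction_duration: float = 30.0
    regulation_duration: float = 150.0
    prompt_interval: float = 30.0
    n_sessions: int = 8
    stage_map: dict[int, str] | None = None
    n_induction_phrases: int = 40
    n_control_phrases: int = 200
    n_hierarchy_items: int = 19

    def __post_init__(self) -> None:
        for name in ("baseline_duration", "contextualisation_duration",
                     "block_duration", "induction_duration",
                     "regulation_duration", "prompt_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_blocks < 0:
            raise ValueError("n_blocks must be non-negative")
        if self.n_sessions < 1:
            raise ValueError("n_sessions must be at least 1")
        if abs(self.block_duration - (self.induction_duration + self.regulation_duration)) > 1e-9:
            raise ValueError(
                "block_duration must equal induction_duration + regulation_duration "
                f"({self.block_duration} != {self.induction_duration} + {self.regulation_duration})"
            )
        if self.stage_map is None:
            object.__setattr__(self, "stage_map", _default_stage_map(self.n_sessions))

    @property
    def session_duration(self) -> float:
        """Total session length in seconds."""
        return (self.baseline_duration + self.contextualisation_duration
                + self.n_blocks * self.block_duration)

    @property
    def active_training_onset(self) -> float:
        return self.baseline_duration + self.contextualisation_duration

    @property
    def prompts_per_block(self) -> tuple[int, int]:
        """(induction, regulation) prompt counts per block."""
        n_reg = int(np.floor(self.regulation_duration / self.prompt_interval + 1e-9))
        return 1, n_reg


@dataclass(frozen=True)
class Event:
    """A single timestamped protocol event, onset in seconds from session start."""

    onset: float
    duration: float
    event_type: str
    block_index: int | None = None
    stim_id: str | None = None

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"event onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"event duration must be > 0, got {self.duration}")
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event_type {self.event_type!r}")


@dataclass(frozen=True)
class EventTimeline:
    """Ordered events of one session."""

    session_index: int
    stage: str
    events: tuple[Event, ...]
    total_duration: float

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if onsets != sorted(onsets):
            raise ValueError("events must be sorted by onset")

    def by_type(self, event_type: str) -> list[Event]:
        return [e for e in self.events if e.event_type == event_type]


@dataclass(frozen=True)
class StimulusPool:
    """Finite pools of induction and control phrase identifiers."""

    induction_ids: tuple[str, ...]
    control_ids: tuple[str, ...]
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name, ids in (("induction", self.induction_ids), ("control", self.control_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate identifiers in {name} pool")

    @classmethod
    def default(cls, config: ProtocolConfig, rng_seed: int = 0) -> "StimulusPool":
        return cls(
            induction_ids=tuple(f"ind{i:03d}" for i in range(1, config.n_induction_phrases + 1)),
            control_ids=tuple(f"ctl{i:03d}" for i in range(1, config.n_control_phrases + 1)),
            rng_seed=rng_seed,
        )


@dataclass(frozen=True)
class ExposureHierarchy:
    """A participant's performance situations ordered from least to most anxiety-inducing."""

    items: tuple[tuple[str, float], ...]
    participant_id: str

    def __post_init__(self) -> None:
        ratings = [r for _, r in self.items]
        if ratings != sorted(ratings):
            raise ValueError("hierarchy items must be sorted ascending by anxiety rating")


def build_session_timeline(config: ProtocolConfig, session_index: int) -> EventTimeline:
    """Build the event timeline of one session.

    One baseline event, one contextualisation event, then per block an
    induction prompt at block start followed by regulation prompts every
    ``prompt_interval`` seconds up to (exclusive) the block end.
    """
    if not 1 <= session_index <= config.n_sessions:
        raise IndexError(
            f"session_index {session_index} outside 1..{config.n_sessions}")
    events = [
        Event(0.0, config.baseline_duration, "baseline"),
        Event(config.baseline_duration, config.contextualisation_duration, "contextualisation"),
    ]
    n_ind, n_reg = config.prompts_per_block
    for b in range(1, config.n_blocks + 1):
        block_start = config.active_training_onset + (b - 1) * config.block_duration
        events.append(Event(block_start, config.induction_duration, "induction_prompt", b))
        for k in range(1, n_reg + 1):
            onset = block_start + config.induction_duration + (k - 1) * config.prompt_interval
            events.append(Event(onset, config.prompt_interval, "regulation_prompt", b))
    return EventTimeline(
        session_index=session_index,
        stage=config.stage_map[session_index],
        events=tuple(events),
        total_duration=config.session_duration,
    )


def build_programme(config: ProtocolConfig, n_sessions: int | None = None) -> list[EventTimeline]:
    """Timelines for sessions 1..n (defaults to the full programme)."""
    n = config.n_sessions if n_sessions is None else n_sessions
    return [build_session_timeline(config, s) for s in range(1, n + 1)]


def count_prompts(timeline: EventTimeline) -> tuple[int, int]:
    """Return (number of induction prompts, number of regulation prompts)."""
    return (len(timeline.by_type("induction_prompt")),
            len(timeline.by_type("regulation_prompt")))


def assign_stimuli(config: ProtocolConfig, pool: StimulusPool,
                   timelines: Sequence[EventTimeline]) -> list[EventTimeline]:
    """Assign a unique phrase id to every prompt across the programme.

    Controlled randomization: each pool is shuffled once with the pool's
    seeded generator and then dealt to prompts in session order, so no
    phrase repeats anywhere in the programme and the assignment is a
    deterministic function of (config, pool, seed).
    """
    n_ind_total = sum(count_prompts(t)[0] for t in timelines)
    n_reg_total = sum(count_prompts(t)[1] for t in timelines)
    if n_ind_total > len(pool.induction_ids):
        raise PoolExhaustedError(
            f"induction pool exhausted: {n_ind_total} prompts but only "
            f"{len(pool.induction_ids)} phrases")
    if n_reg_total > len(pool.control_ids):
        raise PoolExhaustedError(
            f"control pool exhausted: {n_reg_total} prompts but only "
            f"{len(pool.control_ids)} phrases")

    rng = np.random.default_rng(pool.rng_seed)
    ind_order = [pool.induction_ids[i] for i in rng.permutation(len(pool.induction_ids))]
    ctl_order = [pool.control_ids[i] for i in rng.permutation(len(pool.control_ids))]
    ind_iter, ctl_iter = iter(ind_order), iter(ctl_order)

    assigned = []
    for timeline in timelines:
        new_events = []
        for ev in timeline.events:
            if ev.event_type == "induction_prompt":
                new_events.append(replace(ev, stim_id=next(ind_iter)))
            elif ev.event_type == "regulation_prompt":
                new_events.append(replace(ev, stim_id=next(ctl_iter)))
            else:
                new_events.append(ev)
        assigned.append(replace(timeline, events=tuple(new_events)))
    return assigned


def rank_hierarchy(ratings: Sequence[tuple[str, float]], participant_id: str,
                   n_items: int = 19,
                   scale: tuple[float, float] = (0.0, 10.0)) -> ExposureHierarchy:
    """Order performance situations by anxiety rating (ascending).

    Ties are broken by input order (stable sort), so a shuffled copy of the
    same (situation, rating) pairs yields the same hierarchy.
    """
    if len(ratings) != n_items:
        raise ValueError(f"expected {n_items} ratings, got {len(ratings)}")
    lo, hi = scale
    for sid, r in ratings:
        if not lo <= r <= hi:
            raise ValueError(f"rating {r} for {sid!r} outside scale [{lo}, {hi}]")
    ordered = sorted(sorted(ratings, key=lambda it: it[0]), key=lambda it: it[1])
    return ExposureHierarchy(items=tuple(ordered), participant_id=participant_id)


def select_context_scenario(hierarchy: ExposureHierarchy, session_index: int,
                            config: ProtocolConfig) -> str:
    """Pick the contextualisation scenario for a session.

    Gradual exposure: hierarchy rank increases linearly across the programme,
    from the least anxiety-inducing situation in session 1 to the most in the
    final session. A compact programme spreads its sessions evenly over the
    full hierarchy.
    """
    if not 1 <= session_index <= config.n_sessions:
        raise IndexError(
            f"session_index {session_index} outside 1..{config.n_sessions}")
    n_items = len(hierarchy.items)
    if config.n_sessions == 1:
        rank = 0
    else:
        frac = (session_index - 1) / (config.n_sessions - 1)
        rank = int(round(frac * (n_items - 1)))
    return hierarchy.items[rank][0]
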