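"""Cold-pressor stimulation timeline.

The experiment records 60 s of rest, then immerses the right hand in 25 C
water (innocuous, primary stimulus) for up to 30 s, rests 2 min, and repeats
with 5 C water (noxious, secondary stimulus).  The 30 s immediately before
the primary onset define the baseline window; the 15 s after each stimulus
end define the post-stimulus window used by the deactivation measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "InvalidParadigmError",
    "StimulusEvent",
    "ParadigmTimeline",
    "make_paradigm",
    "window_indices",
    "PRIMARY_LABEL",
    "SECONDARY_LABEL",
]

PRIMARY_LABEL = "primary_25C"
SECONDARY_LABEL = "secondary_5C"

#: stimulus label -> temperature tag used in feature tables
TEMPERATURE_OF = {PRIMARY_LABEL: "25C", SECONDARY_LABEL: "5C"}


class InvalidParadigmError(ValueError):
    """Raised for non-positive durations or overlapping events."""


@dataclass(frozen=True)
class StimulusEvent:
    label: str
    onset: float   # s from recording start
    duration: float  # s

    @property
    def end(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class ParadigmTimeline:
    rest_duration: float = 60.0
    baseline_window: float = 30.0
    events: tuple[StimulusEvent, ...] = field(default_factory=tuple)
    inter_stimulus_rest: float = 120.0
    post_window: float = 15.0

    def __post_init__(self) -> None:
        for name in ("rest_duration", "baseline_window", "inter_stimulus_rest",
                     "post_window"):
            if getattr(self, name) <= 0:
                raise InvalidParadigmError(f"{name} must be > 0")
        prev_end = -np.inf
        for ev in self.events:
            if ev.duration <= 0:
                raise InvalidParadigmError(
                    f"event {ev.label!r} has non-positive duration"
                )
            if ev.onset < prev_end:
                raise InvalidParadigmError(
                    f"event {ev.label!r} overlaps the preceding event"
                )
            prev_end = ev.end

    @property
    def primary(self) -> StimulusEvent:
        return next(e for e in self.events if e.label == PRIMARY_LABEL)

    @property
    def secondary(self) -> StimulusEvent:
        return next(e for e in self.events if e.label == SECONDARY_LABEL)

    @property
    def total_duration(self) -> float:
        """Recording length: last event end plus a final rest block."""
        return self.events[-1].end + self.inter_stimulus_rest

    def n_samples(self, sampling_rate: float) -> int:
        return int(round(self.total_duration * sampling_rate))


def make_paradigm(
    primary_duration: float = 30.0,
    secondary_duration: float = 30.0,
    rest_duration: float = 60.0,
    baseline_window: float = 30.0,
    inter_stimulus_rest: float = 120.0,
    post_window: float = 15.0,
) -> ParadigmTimeline:
    """Build the two-stimulus cold-pressor timeline.

    Onsets are derived: the primary stimulus starts when the initial rest
    ends, the secondary after the inter-stimulus rest.  With the defaults the
    secondary onset falls at 60 + 30 + 120 = 210 s.
    """
    if primary_duration <= 0 or secondary_duration <= 0:
        raise InvalidParadigmError("stimulus durations must be > 0")
    primary = StimulusEvent(PRIMARY_LABEL, rest_duration, primary_duration)
    secondary = StimulusEvent(
        SECONDARY_LABEL, primary.end + inter_stimulus_rest, secondary_duration
    )
    return ParadigmTimeline(
        rest_duration=rest_duration,
        baseline_window=baseline_window,
        events=(primary, secondary),
        inter_stimulus_rest=inter_stimulus_rest,
        post_window=post_window,
    )


def window_indices(
    start: float, stop: float, sampling_rate: float, n_samples: int
) -> np.ndarray:
    """Sample indices of the half-open time window [start, stop).

    This single helper defines the window convention for the whole package
    (baseline, peak-search and post-stimulus windows all use it), so the
    synthesis and the feature extraction see byte-identical windows.
    """
    if stop <= start:
        raise ValueError("window stop must exceed start")
    idx = np.arange(n_samples)
    t = idx / sampling_rate
    sel = idx[(t >= start) & (t < stop)]
    return sel
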