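"""Optode montage and region-of-interest (ROI) channel map.

The probe layout is a 16-source / 16-detector cap over bilateral prefrontal
(PFC) and motor (MC) cortex forming 40 channels at a fixed 3 cm
source-detector separation.  Channels are grouped into four ROIs; channels 9
and 12 sit on the midline of the prefrontal strip and belong to both PFC
ROIs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ROI_LABELS",
    "DEFAULT_ROI_MAP",
    "InvalidMontageError",
    "Montage",
    "build_montage",
]

ROI_LABELS = ("left_PFC", "right_PFC", "right_MC", "left_MC")

#: Default channel -> ROI assignment.  Channels 9 and 12 are shared between
#: the two prefrontal ROIs.
DEFAULT_ROI_MAP: dict[str, frozenset[int]] = {
    "left_PFC": frozenset(range(1, 10)) | frozenset({11, 12}),
    "right_PFC": frozenset(range(12, 21)) | frozenset({9, 10}),
    "right_MC": frozenset(range(21, 31)),
    "left_MC": frozenset(range(31, 41)),
}

N_CHANNELS = 40


class InvalidMontageError(ValueError):
    """Raised when a montage description violates the layout constraints."""


@dataclass(frozen=True)
class Montage:
    """A 40-channel dual-wavelength optode layout.

    Parameters
    ----------
    channels : tuple of (channel_id, source_id, detector_id)
    separation : source-detector distance in cm.
    roi_map : mapping of ROI label to the set of member channel ids.
    """

    channels: tuple[tuple[int, int, int], ...]
    separation: float = 3.0
    roi_map: dict[str, frozenset[int]] = field(
        default_factory=lambda: dict(DEFAULT_ROI_MAP)
    )

    def __post_init__(self) -> None:
        ids = [c[0] for c in self.channels]
        if len(ids) != N_CHANNELS or sorted(ids) != list(range(1, N_CHANNELS + 1)):
            raise InvalidMontageError(
                f"montage must define channels 1..{N_CHANNELS} exactly once"
            )
        if self.separation <= 0:
            raise InvalidMontageError("separation must be positive")
        covered: set[int] = set()
        for label, members in self.roi_map.items():
            bad = [ch for ch in members if not 1 <= ch <= N_CHANNELS]
            if bad:
                raise InvalidMontageError(
                    f"ROI {label!r} references channel(s) outside 1..{N_CHANNELS}: {bad}"
                )
            covered |= set(members)
        if covered != set(range(1, N_CHANNELS + 1)):
            missing = sorted(set(range(1, N_CHANNELS + 1)) - covered)
            raise InvalidMontageError(f"channels not assigned to any ROI: {missing}")

    @property
    def channel_ids(self) -> tuple[int, ...]:
        return tuple(c[0] for c in self.channels)

    @property
    def source_count(self) -> int:
        return len({c[1] for c in self.channels})

    @property
    def detector_count(self) -> int:
        return len({c[2] for c in self.channels})

    def rois_of(self, channel_id: int) -> frozenset[str]:
        """Return the set of ROI labels a channel belongs to."""
        if not 1 <= channel_id <= N_CHANNELS:
            raise InvalidMontageError(
                f"channel id {channel_id} outside 1..{N_CHANNELS}"
            )
        return frozenset(
            label for label, members in self.roi_map.items() if channel_id in members
        )

    def roi_channels(self, roi: str) -> tuple[int, ...]:
        """Sorted member channel ids of one ROI."""
        if roi not in self.roi_map:
            raise InvalidMontageError(f"unknown ROI label {roi!r}")
        return tuple(sorted(self.roi_map[roi]))


def build_montage(
    separation: float = 3.0,
    roi_map: dict[str, frozenset[int]] | None = None,
) -> Montage:
    """Construct the default 40-channel bilateral PFC/MC montage.

    The source/detector indices follow a deterministic 16x16 assignment;
    only channel ids and the ROI grouping matter downstream.
    """
    channels = tuple(
        (ch, (ch - 1) % 16 + 1, ((ch - 1) // 16 + (ch - 1) % 16) % 16 + 1)
        for ch in range(1, N_CHANNELS + 1)
    )
    mapping = dict(DEFAULT_ROI_MAP) if roi_map is None else {
        k: frozenset(v) for k, v in roi_map.items()
    }
    return Montage(channels=channels, separation=separation, roi_map=mapping)
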