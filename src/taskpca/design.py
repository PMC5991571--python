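"""Event-related task designs: timing of stimulus presentations within a scan.

A design records event onsets and durations on the scanner clock (seconds from
the start of the first analysed frame) together with the frame grid (TR and
number of frames).  Designs are generated pseudorandomly -- a fixed event
duration separated by gaps drawn uniformly from a configured range -- or read
from a BIDS-style events table (TSV with ``onset``/``duration`` columns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TaskDesign", "generate_task_design", "read_events_tsv", "write_events_tsv"]


@dataclass(frozen=True)
class TaskDesign:
    """Timing of an event-related acquisition.

    Parameters
    ----------
    onsets
        Event onset times in seconds from scan start, strictly increasing.
    durations
        Event durations in seconds (same length as ``onsets``).
    tr
        Repetition time: seconds per frame.
    n_frames
        Number of analysed frames.
    seed
        Seed used to generate the design, if any (bookkeeping only).
    """

    onsets: np.ndarray
    durations: np.ndarray
    tr: float = 2.0
    n_frames: int = 224
    seed: int | None = None
    trial_type: str = field(default="manipulate", compare=False)

    def __post_init__(self) -> None:
        onsets = np.asarray(self.onsets, dtype=float)
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "onsets", onsets)
        object.__setattr__(self, "durations", durations)
        if onsets.ndim != 1 or onsets.shape != durations.shape:
            raise ValueError("onsets and durations must be 1-D and equal length")
        if onsets.size == 0:
            raise ValueError("a design must contain at least one event")
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")
        if np.any(durations <= 0):
            raise ValueError("durations must be positive")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")
        if np.any(onsets + durations > self.scan_duration + 1e-9):
            raise ValueError("every event must end before the scan does")

    @property
    def scan_duration(self) -> float:
        """Total scan length in seconds."""
        return self.tr * self.n_frames

    @property
    def n_events(self) -> int:
        return int(self.onsets.size)

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition time of each frame (start-of-frame convention)."""
        return np.arange(self.n_frames) * self.tr

    def fundamental_frequency(self) -> float:
        """Mean event repetition frequency in Hz (1 / mean onset-to-onset interval)."""
        if self.n_events < 2:
            return 1.0 / self.scan_duration
        return 1.0 / float(np.mean(np.diff(self.onsets)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "onset": self.onsets,
                "duration": self.durations,
                "trial_type": self.trial_type,
            }
        )


def generate_task_design(
    n_frames: int = 224,
    tr: float = 2.0,
    event_duration: float = 6.0,
    gap_range: tuple[float, float] = (8.0, 12.0),
    seed: int | None = None,
    start_offset: float = 10.0,
) -> TaskDesign:
    """Pack events pseudorandomly into a scan.

    Events of fixed ``event_duration`` are placed one after another starting at
    ``start_offset``; consecutive events are separated by gaps drawn uniformly
    from ``gap_range``.  Packing stops when the next event would not finish
    before the end of the scan, so the number of events is a consequence of the
    timing parameters, not an input.

    Deterministic for a given ``seed``.
    """
    lo, hi = gap_range
    if lo > hi:
        raise ValueError("gap_range low must not exceed high")
    if lo < 0:
        raise ValueError("gaps must be nonnegative")
    if event_duration <= 0:
        raise ValueError("event_duration must be positive")
    rng = np.random.default_rng(seed)
    total = n_frames * tr
    onsets: list[float] = []
    t = float(start_offset)
    while t + event_duration <= total:
        onsets.append(t)
        t += event_duration + float(rng.uniform(lo, hi))
    if not onsets:
        raise ValueError(
            f"no event of duration {event_duration}s fits a {total}s scan "
            f"starting at offset {start_offset}s"
        )
    arr = np.asarray(onsets)
    return TaskDesign(
        onsets=arr,
        durations=np.full(arr.size, float(event_duration)),
        tr=tr,
        n_frames=n_frames,
        seed=seed,
    )


def read_events_tsv(path) -> pd.DataFrame:
    """Read a BIDS-style events table (columns onset, duration, trial_type)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"onset", "duration"} - set(df.columns)
    if missing:
        raise ValueError(f"events table missing columns: {sorted(missing)}")
    return df


def write_events_tsv(design: TaskDesign, path) -> None:
    design.to_frame().to_csv(path, sep="\t", index=False)


def design_from_events(
    events: pd.DataFrame, tr: float, n_frames: int
) -> TaskDesign:
    """Build a :class:`TaskDesign` from an events table and the frame grid."""
    return TaskDesign(
        onsets=events["onset"].to_numpy(float),
        durations=events["duration"].to_numpy(float),
        tr=tr,
        n_frames=n_frames,
    )
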