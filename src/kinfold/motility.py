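"""Single-molecule motility statistics from kymograph event tables.

An event is one motor binding a microtubule: frames and positions of its
start and end.  From filtered events the module computes the landing rate
(events per um of microtubule, per second, per uM of motor), per-event dwell
times (kymograph time-axis extent, frame intervals x frame time) and
velocities (|displacement| / dwell), and compares groups of per-microtubule
landing rates against a control with one-way ANOVA followed by Dunnett's
many-to-one test.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SchemaError

DEFAULT_FRAME_INTERVAL = 0.2  # s; acquisition every 200 ms
DEFAULT_MIN_FRAMES = 3  # events must span >= 3 frames (600 ms)

_REQUIRED_COLUMNS = (
    "mt_id",
    "mt_length_um",
    "start_frame",
    "end_frame",
    "start_pos_um",
    "end_pos_um",
)


@dataclass(frozen=True)
class MotilityEvent:
    """One binding event on a microtubule."""

    mt_id: str
    mt_length: float  # um
    start_frame: int
    end_frame: int
    start_pos: float  # um along the microtubule
    end_pos: float
    group: str = ""
    censored: bool = False

    def __post_init__(self) -> None:
        if self.end_frame < self.start_frame:
            raise ValueError("end_frame must be >= start_frame")
        if not (0 <= self.start_pos <= self.mt_length + 1e-9):
            raise ValueError("start_pos outside the microtubule")
        if not (0 <= self.end_pos <= self.mt_length + 1e-9):
            raise ValueError("end_pos outside the microtubule")

    @property
    def n_frames(self) -> int:
        """Number of frames the event appears in (inclusive)."""
        return self.end_frame - self.start_frame + 1


def parse_events(path: str | Path) -> list[MotilityEvent]:
    """Read an event table (CSV with the documented header) into events."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"event table missing columns: {', '.join(missing)}")
    return events_from_frame(df)


def events_from_frame(df: pd.DataFrame) -> list[MotilityEvent]:
    return [
        MotilityEvent(
            mt_id=str(r.mt_id),
            mt_length=float(r.mt_length_um),
            start_frame=int(r.start_frame),
            end_frame=int(r.end_frame),
            start_pos=float(r.start_pos_um),
            end_pos=float(r.end_pos_um),
            group=str(getattr(r, "group", "")),
            censored=bool(getattr(r, "censored", False)),
        )
        for r in df.itertuples(index=False)
    ]


def filter_events(
    events: Sequence[MotilityEvent], min_frames: int = DEFAULT_MIN_FRAMES
) -> list[MotilityEvent]:
    """Keep events spanning at least ``min_frames`` frames (inclusive count)."""
    if min_frames < 1:
        raise ValueError("min_frames must be >= 1")
    return [e for e in events if e.n_frames >= min_frames]


def landing_rate(
    events: Sequence[MotilityEvent],
    total_mt_length: float,
    duration: float,
    concentration: float,
) -> float:
    """Events per um of microtubule per second per uM of motor."""
    for name, v in [
        ("total_mt_length", total_mt_length),
        ("duration", duration),
        ("concentration", concentration),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return len(events) / (total_mt_length * duration * concentration)


def per_mt_landing_rates(
    events: Sequence[MotilityEvent],
    mt_lengths: Mapping[str, float],
    duration: float,
    concentration: float,
) -> dict[str, float]:
    """Landing rate per microtubule — the unit of replication for statistics.

    Microtubules in ``mt_lengths`` with no events get rate 0.
    """
    counts: dict[str, int] = {mt: 0 for mt in mt_lengths}
    for e in events:
        if e.mt_id not in counts:
            raise KeyError(f"event on unknown microtubule {e.mt_id!r}")
        counts[e.mt_id] += 1
    return {
        mt: counts[mt] / (mt_lengths[mt] * duration * concentration)
        for mt in mt_lengths
    }


def dwell_times(
    events: Sequence[MotilityEvent],
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> np.ndarray:
    """Per-event dwell in seconds: (end - start) frame intervals.

    The interval convention matches the kymograph's y-axis extent: a 3-frame
    event spans 2 intervals, 0.4 s at 200 ms/frame.
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    return np.array(
        [(e.end_frame - e.start_frame) * frame_interval for e in events]
    )


def velocities(
    events: Sequence[MotilityEvent],
    frame_interval: float = DEFAULT_FRAME_INTERVAL,
) -> np.ndarray:
    """Per-event speed in um/s: |end - start position| / dwell.

    Events with zero dwell are excluded (a warning is emitted); stationary
    events contribute 0.
    """
    import warnings

    out = []
    n_dropped = 0
    for e in events:
        dwell = (e.end_frame - e.start_frame) * frame_interval
        if dwell <= 0:
            n_dropped += 1
            continue
        out.append(abs(e.end_pos - e.start_pos) / dwell)
    if n_dropped:
        warnings.warn(
            f"excluded {n_dropped} zero-dwell events from velocity", stacklevel=2
        )
    return np.array(out)


@dataclass
class MotilityStats:
    """Summary statistics for one group of events."""

    landing_rate: float
    dwell_times: np.ndarray
    velocities: np.ndarray
    n_events: int
    n_mts: int

    @classmethod
    def from_events(
        cls,
        events: Sequence[MotilityEvent],
        mt_lengths: Mapping[str, float],
        duration: float,
        concentration: float,
        frame_interval: float = DEFAULT_FRAME_INTERVAL,
        min_frames: int = DEFAULT_MIN_FRAMES,
    ) -> "MotilityStats":
        kept = filter_events(events, min_frames)
        return cls(
            landing_rate=landing_rate(
                kept, sum(mt_lengths.values()), duration, concentration
            ),
            dwell_times=dwell_times(kept, frame_interval),
            velocities=velocities(kept, frame_interval),
            n_events=len(kept),
            n_mts=len(mt_lengths),
        )


def compare_groups(
    per_mt_rates: Mapping[str, Sequence[float]],
    control: str,
) -> pd.DataFrame:
    """One-way ANOVA plus Dunnett's many-to-one comparison against a control.

    ``per_mt_rates`` maps group name to its per-microtubule landing rates.
    Returns a table of (group, n, mean, sem, p_adjusted) where p_adjusted is
    Dunnett-adjusted (NaN for the control row).  The ANOVA p-value is stored
    in ``DataFrame.attrs["anova_p"]``.
    """
    if control not in per_mt_rates:
        raise ValueError(f"control group {control!r} not present")
    if len(per_mt_rates) < 2:
        raise ValueError("need at least two groups")
    for g, vals in per_mt_rates.items():
        if len(vals) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")
    groups = [g for g in per_mt_rates if g != control]
    control_vals = np.asarray(per_mt_rates[control], dtype=float)
    treatment_vals = [np.asarray(per_mt_rates[g], dtype=float) for g in groups]

    anova = stats.f_oneway(control_vals, *treatment_vals)
    dunnett = stats.dunnett(*treatment_vals, control=control_vals)

    rows = [
        {
            "group": control,
            "n": len(control_vals),
            "mean": control_vals.mean(),
            "sem": stats.sem(control_vals),
            "p_adjusted": np.nan,
        }
    ]
    for g, vals, p in zip(groups, treatment_vals, dunnett.pvalue):
        rows.append(
            {
                "group": g,
                "n": len(vals),
                "mean": vals.mean(),
                "sem": stats.sem(vals),
                "p_adjusted": float(p),
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["anova_p"] = float(anova.pvalue)
    return table
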