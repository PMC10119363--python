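"""Rotational behaviour, locomotion, and dyskinesia scoring.

Keypoint tables (7 body parts x frames, with x, y, likelihood) are reduced
to a centroid (mean of all 7 parts), a front point (mean of nose, ears and
head top), and a heading (direction of the line from the tail base through
the front).  Full 360-degree turns are counted by binning the heading into
8 fixed 45-degree sectors and requiring a traversal of all 8 sectors in a
consistent rotational sense; an incomplete rotation resets the sector count
and the last angle of the discarded rotation seeds the next count.
Locomotion is summarized by 1x1 cm occupancy per minute and centroid speed
over a sliding 1-s window.  Abnormal-involuntary-movement (AIM) sheets are
scored as composite = severity x amplitude per subtype, summed to global
per-period, session-total and peak-window scores.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AIM_SUBTYPES = ("axial", "limb", "orolingual")

FRONT_PARTS = ("nose", "left_ear", "right_ear", "head_top")

LIKELIHOOD_MIN = 0.9  # frames at or below this are discarded

SECTOR_DEG = 45.0  # 8 sectors of 45 degrees

#: Peak-dyskinesia windows per treatment (min post injection), reused from the
#: oscillation analysis presets.
from .oscdetect import PEAK_WINDOWS_MIN  # noqa: E402


# ---------------------------------------------------------------------------
# pose derivation


@dataclass
class TrajectoryRecord:
    fps: float
    n_frames: int
    valid: np.ndarray  # bool per frame (all 7 keypoints above likelihood)
    centroid_cm: np.ndarray  # (n_frames, 2), NaN where invalid
    front_cm: np.ndarray
    heading_deg: np.ndarray  # [0, 360), NaN where invalid
    excluded_frames: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.excluded_frames is None:
            self.excluded_frames = np.flatnonzero(~self.valid)


def _flatten_keypoints(table: pd.DataFrame) -> pd.DataFrame:
    """Accept either a flat (part, coord) frame or the 3-level pose dialect."""
    if isinstance(table.columns, pd.MultiIndex):
        if table.columns.nlevels == 3:
            table = table.droplevel(0, axis=1)
        return table
    raise ValueError("keypoint table must have (bodyparts, coords) columns")


def derive_pose(
    table: pd.DataFrame,
    fps: float,
    likelihood_min: float = LIKELIHOOD_MIN,
    smooth_frames: int = 5,
) -> TrajectoryRecord:
    """Centroid, front and heading per retained frame.

    Frames where any keypoint's likelihood is at or below the threshold are
    excluded from every derived series.  Heading is the direction from the
    tail base to the front of the animal, in degrees [0, 360).

    Keypoint coordinates are smoothed with a centered ``smooth_frames``
    moving average (NaN-aware, 0.2 s at 25 fps by default) before deriving
    kinematics: raw per-frame keypoint jitter otherwise dithers the heading
    across sector boundaries and triggers spurious reversal resets in the
    turn counter.  Set smooth_frames=1 to disable.
    """
    kp = _flatten_keypoints(table)
    parts = list(dict.fromkeys(kp.columns.get_level_values(0)))
    if len(parts) != 7:
        raise ValueError(f"expected 7 body parts, got {len(parts)}")
    n = len(kp)
    xs = np.column_stack([kp[(p, "x")].to_numpy(float) for p in parts])
    ys = np.column_stack([kp[(p, "y")].to_numpy(float) for p in parts])
    lk = np.column_stack([kp[(p, "likelihood")].to_numpy(float) for p in parts])
    valid = (lk > likelihood_min).all(axis=1)
    if not valid.any():
        raise ValueError("all frames excluded by the likelihood filter")
    if valid.mean() < 0.5:
        warnings.warn("more than 50% of frames excluded by the likelihood filter", RuntimeWarning)

    if smooth_frames > 1:
        xs = xs.copy()
        ys = ys.copy()
        xs[~valid] = np.nan
        ys[~valid] = np.nan
        roll = dict(window=smooth_frames, center=True, min_periods=1)
        xs = pd.DataFrame(xs).rolling(**roll).mean().to_numpy()
        ys = pd.DataFrame(ys).rolling(**roll).mean().to_numpy()

    centroid = np.column_stack([xs.mean(axis=1), ys.mean(axis=1)])
    fidx = [parts.index(p) for p in FRONT_PARTS if p in parts]
    if len(fidx) != 4:
        fidx = list(range(4))  # fall back to the first four parts as the head
    front = np.column_stack([xs[:, fidx].mean(axis=1), ys[:, fidx].mean(axis=1)])
    tail_idx = parts.index("tail_base") if "tail_base" in parts else 5
    tail = np.column_stack([xs[:, tail_idx], ys[:, tail_idx]])
    heading = np.degrees(np.arctan2(front[:, 1] - tail[:, 1], front[:, 0] - tail[:, 0])) % 360.0

    centroid[~valid] = np.nan
    front[~valid] = np.nan
    heading = heading.astype(float)
    heading[~valid] = np.nan
    return TrajectoryRecord(
        fps=fps, n_frames=n, valid=valid,
        centroid_cm=centroid, front_cm=front, heading_deg=heading,
    )


# ---------------------------------------------------------------------------
# turn counting


@dataclass
class TurnEvent:
    direction: str  # 'contralateral' or 'ipsilateral'
    start_frame: int
    end_frame: int
    duration_s: float
    distance_cm: float = float("nan")


def count_full_turns(
    heading_deg: np.ndarray,
    fps: float,
    contralateral_sense: int = +1,
    max_gap_s: float = 1.0,
) -> list[TurnEvent]:
    """Count full 360-degree turns with the 8-sector traversal rule.

    The heading is binned into fixed sectors [0,45), [45,90), ...  A full
    turn is 8 consecutive sector transitions in one rotational sense
    (skipped sectors during fast rotation count as traversed); a transition
    in the opposite sense resets the count, re-seeding it from the current
    sector.  Gaps (NaN frames) longer than ``max_gap_s`` also reset the
    count; shorter gaps are bridged.  ``contralateral_sense`` maps the
    positive (counter-clockwise) rotational sense to contralateral turns.
    """
    heading = np.asarray(heading_deg, dtype=float)
    max_gap = int(round(max_gap_s * fps))
    events: list[TurnEvent] = []

    run = 0  # signed sector transitions in the current rotation
    prev_sector = None
    prev_frame = None
    anchor_frame = None  # frame where the current count started
    for i, h in enumerate(heading):
        if not np.isfinite(h):
            continue
        sector = int(h // SECTOR_DEG) % 8
        if prev_sector is None:
            prev_sector, prev_frame, anchor_frame = sector, i, i
            continue
        if i - prev_frame > max_gap:
            run, prev_sector, prev_frame, anchor_frame = 0, sector, i, i
            continue
        step = (sector - prev_sector + 4) % 8 - 4
        frame_before = prev_frame
        prev_sector, prev_frame = sector, i
        if step == 0:
            continue
        if run == 0 or (step > 0) == (run > 0):
            run += step
        else:
            # reversal: the last angle of the discarded rotation seeds the
            # next count
            run = step
            anchor_frame = frame_before
        while abs(run) >= 8:
            sense = 1 if run > 0 else -1
            direction = (
                "contralateral" if sense == contralateral_sense else "ipsilateral"
            )
            events.append(
                TurnEvent(
                    direction=direction,
                    start_frame=anchor_frame,
                    end_frame=i,
                    duration_s=(i - anchor_frame) / fps,
                )
            )
            run -= sense * 8
            anchor_frame = i
    return events


def turn_metrics(
    turns: list[TurnEvent], centroid_cm: np.ndarray, fps: float
) -> list[TurnEvent]:
    """Attach per-turn centroid path length (cm) and duration (s).

    Distance sums frame-to-frame displacements over valid frames within the
    turn; missing frames inside a turn contribute nothing (flagged by NaN
    gaps in the centroid series).
    """
    centroid = np.asarray(centroid_cm, dtype=float)
    for ev in turns:
        seg = centroid[ev.start_frame : ev.end_frame + 1]
        d = np.diff(seg, axis=0)
        step = np.hypot(d[:, 0], d[:, 1])
        ev.distance_cm = float(np.nansum(step))
        ev.duration_s = (ev.end_frame - ev.start_frame) / fps
    return turns


# ---------------------------------------------------------------------------
# occupancy and speed


@dataclass
class OccupancySeries:
    bin_starts_s: np.ndarray
    fraction: np.ndarray
    total_squares: int


def arena_square_count(arena_diameter_cm: float = 55.0) -> int:
    """Number of 1x1 cm squares whose centre lies inside the arena circle."""
    r = arena_diameter_cm / 2.0
    m = int(math.ceil(r)) + 1
    idx = np.arange(-m, m)
    cx, cy = np.meshgrid(idx + 0.5, idx + 0.5)
    return int(((cx**2 + cy**2) < r**2).sum())


def occupancy_fraction(
    centroid_cm: np.ndarray,
    fps: float,
    arena_diameter_cm: float = 55.0,
    bin_s: float = 60.0,
) -> OccupancySeries:
    """Fraction of arena 1x1 cm squares visited by the centroid per time bin.

    The grid is anchored at the arena centre (assumed at the origin of the
    centroid coordinates); the denominator counts squares whose centre lies
    inside the arena circle.
    """
    centroid = np.asarray(centroid_cm, dtype=float)
    total = arena_square_count(arena_diameter_cm)
    n_per_bin = int(round(bin_s * fps))
    n_bins = max(1, math.ceil(len(centroid) / n_per_bin))
    fracs = np.empty(n_bins)
    starts = np.arange(n_bins) * bin_s
    for b in range(n_bins):
        seg = centroid[b * n_per_bin : (b + 1) * n_per_bin]
        ok = np.isfinite(seg).all(axis=1)
        squares = {
            (int(math.floor(x)), int(math.floor(y))) for x, y in seg[ok]
        }
        fracs[b] = len(squares) / total
    return OccupancySeries(bin_starts_s=starts, fraction=fracs, total_squares=total)


def compute_speed(centroid_cm: np.ndarray, fps: float, window_s: float = 1.0) -> np.ndarray:
    """Centroid translation speed (cm/s) over a sliding window.

    speed[i] is the displacement between frames i and i + window, divided by
    the window duration; NaN where either endpoint is missing.
    """
    centroid = np.asarray(centroid_cm, dtype=float)
    w = int(round(window_s * fps))
    if len(centroid) <= w:
        raise ValueError("need at least one window of data")
    d = centroid[w:] - centroid[:-w]
    return np.hypot(d[:, 0], d[:, 1]) / window_s


# ---------------------------------------------------------------------------
# AIM scoring


@dataclass
class AIMSeries:
    """Scored AIM sheet: composite, global and summed dyskinesia measures."""

    periods_min: list[int]
    severity: pd.DataFrame  # index period_min, columns subtypes
    amplitude: pd.DataFrame
    composite: pd.DataFrame  # severity * amplitude, 0..16
    global_score: pd.Series  # per period, 0..48
    session_total: int

    def peak_score(self, treatment_or_window) -> int:
        """Sum of global scores over the treatment's peak-dyskinesia window
        (inclusive); accepts a treatment name or a (start, stop) tuple in min."""
        if isinstance(treatment_or_window, str):
            lo, hi = PEAK_WINDOWS_MIN[treatment_or_window]
        else:
            lo, hi = treatment_or_window
        sel = [p for p in self.periods_min if lo <= p <= hi]
        return int(self.global_score.loc[sel].sum())


def score_aims(sheet: pd.DataFrame) -> AIMSeries:
    """Score a tidy AIM sheet (period_min, subtype, severity, amplitude).

    Composite per subtype = severity x amplitude (each 0-4, so composite
    0-16); global per period = sum of the three composites (0-48); the
    session total sums global scores over all monitoring periods.
    """
    required = {"period_min", "subtype", "severity", "amplitude"}
    if not required.issubset(sheet.columns):
        raise ValueError(f"sheet must have columns {sorted(required)}")
    for col in ("severity", "amplitude"):
        vals = sheet[col].to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            if not np.all(vals == np.floor(vals)):
                raise ValueError(f"{col} scores must be integers")
            vals = vals.astype(int)
        if vals.min() < 0 or vals.max() > 4:
            raise ValueError(f"{col} scores must lie in 0-4")
    sev = sheet.pivot_table(index="period_min", columns="subtype", values="severity").astype(int)
    amp = sheet.pivot_table(index="period_min", columns="subtype", values="amplitude").astype(int)
    composite = sev * amp
    global_score = composite.sum(axis=1)
    return AIMSeries(
        periods_min=list(sev.index),
        severity=sev, amplitude=amp, composite=composite,
        global_score=global_score,
        session_total=int(global_score.sum()),
    )
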