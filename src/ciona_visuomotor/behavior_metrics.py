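"""Behavioral endpoints computed from tracked trajectories.

Swim bouts are contiguous episodes of above-threshold locomotion between
stationary periods.  Bout candidates are found on a 3-frame moving-average
speed trace (which bridges single-frame dips) and their edges are then
refined on the raw speed trace, so smoothing does not inflate durations.
Downstream endpoints mirror the standard larval assays: per-larva bout
frequency, duration and inter-bout-interval statistics (with their standard
deviations, the stereotypy readout), arc-chord tortuosity, the
stationary-then-swim->3 s dimming-response criterion, the >10 s
sustained-swim filter, and the distal-third phototaxis fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SwimBout",
    "AssaySummary",
    "BoutParams",
    "segment_bouts",
    "tortuosity",
    "dimming_response",
    "sustained_swims",
    "phototaxis_distal_fraction",
    "swim_stats",
    "compare_groups",
]

SUSTAINED_SWIM_S = 10.0     # sustained swims last longer than 10 s (strict)
DIM_RESPONSE_MIN_S = 3.0    # evoked swim must exceed a tail-flick (3 s, strict)
MIN_BOUTS_FOR_SD = 4        # larvae with <4 bouts excluded from SD analyses


@dataclass(frozen=True)
class SwimBout:
    larva_id: int
    start_s: float
    end_s: float
    path_length_mm: float
    net_displacement_mm: float
    mean_speed_mm_s: float

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def tortuosity(self) -> float:
        """Arc-chord ratio; NaN when the path returns to its start."""
        if self.net_displacement_mm <= 1e-12:
            return float("nan")
        return self.path_length_mm / self.net_displacement_mm


@dataclass
class AssaySummary:
    group: str
    per_larva: pd.DataFrame   # larva_id, n_bouts, bouts_per_min,
                              # duration_mean_s, duration_sd_s, interval_sd_s


@dataclass
class BoutParams:
    speed_on_mm_s: float = 0.5
    min_duration_s: float = 0.3
    merge_gap_s: float = 0.2
    smooth_frames: int = 3


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, stop) index pairs."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return list(zip(edges[::2], edges[1::2]))


def segment_bouts(
    positions_mm: np.ndarray,
    fps: float,
    larva_id: int = 0,
    params: BoutParams | None = None,
    t0_s: float = 0.0,
) -> list[SwimBout]:
    """Segment a trajectory (N, 2 in mm) into swim bouts.

    Speed is the backward difference (one sample per frame after the first).
    Runs are found where the smoothed speed >= ``speed_on``; runs separated
    by less than ``merge_gap_s`` are merged; runs shorter than
    ``min_duration_s`` are dropped.  Edges are refined against the raw speed
    trace.  A bout whose speed samples span frames a..b has duration
    (b - a + 1)/fps; its start time is the time of the first moving frame.
    """
    params = params or BoutParams()
    p = np.asarray(positions_mm, float).reshape(-1, 2)
    if len(p) < 2:
        return []
    speed = np.linalg.norm(np.diff(p, axis=0), axis=1) * fps   # sample k = frame k+1
    k = max(1, int(params.smooth_frames))
    kernel = np.ones(k) / k
    smooth = np.convolve(speed, kernel, mode="same")

    raw_on = speed >= params.speed_on_mm_s
    runs = _runs(smooth >= params.speed_on_mm_s)

    # refine each smoothed run against the raw trace
    refined: list[tuple[int, int]] = []
    for a, b in runs:
        idx = np.flatnonzero(raw_on[a:b])
        if idx.size == 0:
            continue
        refined.append((a + idx[0], a + idx[-1] + 1))

    # merge runs separated by less than merge_gap_s
    merged: list[tuple[int, int]] = []
    gap = params.merge_gap_s * fps
    for a, b in refined:
        if merged and a - merged[-1][1] < gap:
            merged[-1] = (merged[-1][0], b)
        else:
            merged.append((a, b))

    bouts: list[SwimBout] = []
    for a, b in merged:
        duration = (b - a) / fps
        if duration < params.min_duration_s:
            continue
        # speed sample k covers motion between frames k and k+1
        seg = p[a : b + 1]
        path = float(np.sum(np.linalg.norm(np.diff(seg, axis=0), axis=1)))
        net = float(np.linalg.norm(seg[-1] - seg[0]))
        bouts.append(SwimBout(
            larva_id=larva_id,
            start_s=t0_s + a / fps,
            end_s=t0_s + b / fps,
            path_length_mm=path,
            net_displacement_mm=net,
            mean_speed_mm_s=path / duration,
        ))
    return bouts


def tortuosity(path_mm: np.ndarray) -> float:
    """Arc length over start-to-end chord; 1 is perfectly straight.

    Returns NaN (missing) when the net displacement is ~zero.
    """
    p = np.asarray(path_mm, float)
    if p.ndim != 2 or len(p) < 2:
        raise ValueError("path must have >= 2 points")
    arc = float(np.sum(np.linalg.norm(np.diff(p, axis=0), axis=1)))
    chord = float(np.linalg.norm(p[-1] - p[0]))
    if chord <= 1e-12:
        return float("nan")
    return arc / chord


def sustained_swims(bouts: list[SwimBout],
                    min_duration_s: float = SUSTAINED_SWIM_S) -> list[SwimBout]:
    """Bouts lasting strictly longer than 10 s (a 10.0 s bout is excluded)."""
    return [b for b in bouts if b.duration_s > min_duration_s]


def dimming_response(
    bouts_by_larva: dict[int, list[SwimBout]],
    positions_by_larva: dict[int, np.ndarray],
    fps: float,
    dim_time_s: float,
    contact_flags: dict[int, bool] | None = None,
    speed_on_mm_s: float = 0.5,
    stationary_window_s: float = 1.0,
    response_window_s: float = 5.0,
) -> tuple[dict[int, bool], float]:
    """Score the dimming response per larva.

    A larva is a responder iff (1) it was stationary at the time of dimming —
    mean speed below ``speed_on`` over the second preceding the dim — and
    (2) its evoked bout (first bout starting within ``response_window_s``
    after the dim) lasted strictly longer than 3 s.  Larvae flagged as in
    contact, and larvae already swimming at dim time, are excluded from the
    denominator.  Returns (per-larva responder flags, responding fraction).
    """
    contact_flags = contact_flags or {}
    flags: dict[int, bool] = {}
    n_scored = 0
    n_resp = 0
    for lid, pos in positions_by_larva.items():
        if contact_flags.get(lid, False):
            continue
        p = np.asarray(pos, float)
        speed = np.linalg.norm(np.diff(p, axis=0), axis=1) * fps
        k_dim = int(round(dim_time_s * fps))
        k_pre = max(0, k_dim - int(round(stationary_window_s * fps)))
        pre = speed[k_pre:k_dim]
        if pre.size == 0 or pre.mean() >= speed_on_mm_s:
            continue   # moving (or unobserved) at dim time: excluded
        n_scored += 1
        evoked = [b for b in bouts_by_larva.get(lid, [])
                  if dim_time_s <= b.start_s <= dim_time_s + response_window_s]
        responded = bool(evoked and evoked[0].duration_s > DIM_RESPONSE_MIN_S)
        flags[lid] = responded
        n_resp += responded
    fraction = n_resp / n_scored if n_scored else float("nan")
    return flags, fraction


def phototaxis_distal_fraction(
    positions_mm: np.ndarray,
    dish_center_mm: tuple[float, float],
    dish_radius_mm: float,
    light_direction: tuple[float, float],
) -> float:
    """Fraction of larvae in the third of the dish farthest from the light.

    ``light_direction`` points from the light source into the dish.  The dish
    diameter along that axis is split into equal thirds by two chords; the
    distal third is where the projection onto the light axis exceeds r/3
    (boundary positions count as distal).
    """
    p = np.asarray(positions_mm, float).reshape(-1, 2)
    if p.size == 0:
        return float("nan")
    u = np.asarray(light_direction, float)
    norm = np.linalg.norm(u)
    if norm < 1e-12:
        raise ValueError("light_direction must be non-zero")
    u = u / norm
    proj = (p - np.asarray(dish_center_mm, float)) @ u
    return float(np.mean(proj >= dish_radius_mm / 3.0))


def swim_stats(
    bouts_by_larva: dict[int, list[SwimBout]],
    recording_s: float = 60.0,
    group: str = "",
) -> AssaySummary:
    """Per-larva bout frequency, duration and interval statistics.

    SDs (duration, inter-bout interval) are reported only for larvae with at
    least 4 bouts; others carry NaN there but keep their counts.  Intervals
    are measured from the end of one bout to the start of the next.
    """
    rows = []
    for lid, bouts in bouts_by_larva.items():
        bouts = sorted(bouts, key=lambda b: b.start_s)
        durations = np.array([b.duration_s for b in bouts])
        intervals = np.array([
            b2.start_s - b1.end_s for b1, b2 in zip(bouts, bouts[1:])
        ])
        n = len(bouts)
        enough = n >= MIN_BOUTS_FOR_SD
        rows.append({
            "larva_id": lid,
            "n_bouts": n,
            "bouts_per_min": n / (recording_s / 60.0),
            "duration_mean_s": durations.mean() if n else float("nan"),
            "duration_sd_s": durations.std(ddof=1) if enough else float("nan"),
            "interval_mean_s": intervals.mean() if n >= 2 else float("nan"),
            "interval_sd_s": (intervals.std(ddof=1)
                              if enough and len(intervals) >= 2 else float("nan")),
        })
    return AssaySummary(group=group,
                        per_larva=pd.DataFrame(rows).set_index("larva_id"))


def compare_groups(a, b, test: str = "rank_sum") -> dict[str, float]:
    """Two-group comparison (thin wrappers over standard tests).

    ``rank_sum``: Wilcoxon rank-sum; ``t``: Student's t (equal variance);
    ``F``: two-sided variance-ratio F test.  Returns the statistic, p-value,
    and the effect direction (sign of mean(a) - mean(b), or of the variance
    difference for the F test).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if test == "rank_sum":
        res = stats.ranksums(a, b)
        statistic, p = float(res.statistic), float(res.pvalue)
        direction = float(np.sign(np.mean(a) - np.mean(b)))
    elif test == "t":
        res = stats.ttest_ind(a, b)
        statistic, p = float(res.statistic), float(res.pvalue)
        direction = float(np.sign(np.mean(a) - np.mean(b)))
    elif test == "F":
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        if vb <= 0 or va <= 0:
            raise ValueError("degenerate (zero-variance) group for F test")
        statistic = float(va / vb)
        dfa, dfb = len(a) - 1, len(b) - 1
        cdf = stats.f.cdf(statistic, dfa, dfb)
        p = float(2 * min(cdf, 1 - cdf))
        direction = float(np.sign(va - vb))
    else:
        raise ValueError(f"unknown test {test!r}")
    return {"statistic": statistic, "p_value": p, "direction": direction}
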