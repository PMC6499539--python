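"""Swim-larva tracking from grayscale time-lapse stacks.

The tracker follows the classic background-subtraction recipe used for
larval swim assays: build a background image by averaging all frames,
subtract it from each frame, keep the connected components above threshold
inside the region of interest as detections, and link trajectories by
nearest-neighbor matching frame to frame, one initial object at a time.

Trajectories are rejected (whole-track, the track is not analyzed) when the
implied speed exceeds 6.5 mm/s between consecutive frames, when the object
leaves the ROI, or when it fails to move beyond a small stationarity radius
for a full minute.  Tracks of larvae that come into contact are flagged so
downstream assays (dimming response) can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.measure import regionprops

__all__ = [
    "FrameStack",
    "DetectedObject",
    "Trajectory",
    "TrackingParams",
    "preprocess_frames",
    "background_mean",
    "detect_objects",
    "link_trajectories",
    "track_stack",
    "trajectories_to_frame",
    "load_stack",
]

SPEED_LIMIT_MM_S = 6.5          # faster-than-larva steps are tracking errors
STATIONARY_WINDOW_S = 60.0      # "did not move after a set time (1 min)"
STATIONARY_RADIUS_PX = 2.0      # sub-pixel centroid jitter is not movement


@dataclass
class FrameStack:
    frames: np.ndarray            # (T, H, W) grayscale
    fps: float
    mm_per_pixel: float
    roi: tuple[int, int, int, int] | None = None   # (r0, c0, r1, c1), half-open

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise ValueError("frames must be (T>=2, H, W)")
        if self.fps <= 0 or self.mm_per_pixel <= 0:
            raise ValueError("fps and mm_per_pixel must be positive")
        if self.roi is not None:
            r0, c0, r1, c1 = self.roi
            H, W = self.frames.shape[1:]
            if not (0 <= r0 < r1 <= H and 0 <= c0 < c1 <= W):
                raise ValueError("roi outside frame bounds")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def in_roi(self, pos) -> bool:
        if self.roi is None:
            H, W = self.frames.shape[1:]
            return 0 <= pos[0] < H and 0 <= pos[1] < W
        r0, c0, r1, c1 = self.roi
        return r0 <= pos[0] < r1 and c0 <= pos[1] < c1


@dataclass(frozen=True)
class DetectedObject:
    frame_index: int
    centroid: tuple[float, float]   # (row, col), 0-based pixels
    area: int


@dataclass
class Trajectory:
    larva_id: int
    start_frame: int
    positions: list[tuple[float, float]]   # (row, col) per frame from start
    status: str = "complete"   # complete | rejected_speed | rejected_roi |
                               # rejected_stationary
    contact: bool = False

    @property
    def end_frame(self) -> int:
        return self.start_frame + len(self.positions) - 1

    def positions_mm(self, mm_per_pixel: float) -> np.ndarray:
        return np.asarray(self.positions, float) * mm_per_pixel

    def speeds_mm_s(self, fps: float, mm_per_pixel: float) -> np.ndarray:
        """Backward-difference speed, one sample per frame after the first."""
        p = np.asarray(self.positions, float)
        if len(p) < 2:
            return np.zeros(0)
        step = np.linalg.norm(np.diff(p, axis=0), axis=1)
        return step * mm_per_pixel * fps


@dataclass
class TrackingParams:
    threshold: float | None = None        # None -> Otsu on first difference
    min_area: int = 5
    speed_limit_mm_s: float = SPEED_LIMIT_MM_S
    stationary_window_s: float = STATIONARY_WINDOW_S
    stationary_radius_px: float = STATIONARY_RADIUS_PX
    contact_radius_px: float | None = None   # None disables contact flagging


def preprocess_frames(stack: FrameStack) -> FrameStack:
    """Subtract the minimum Z-projection from all frames, then invert.

    The Fiji-style preparation step: removes the static background floor and
    flips black/white so dark larvae become bright.  Output is clipped to the
    stack's intensity range.
    """
    frames = np.asarray(stack.frames)
    if not np.all(np.isfinite(frames)):
        raise ValueError("non-finite pixel values")
    f = frames.astype(float)
    floor = f.min(axis=0)
    sub = f - floor
    if np.issubdtype(frames.dtype, np.integer):
        top = float(np.iinfo(frames.dtype).max)
    else:
        top = float(sub.max()) if sub.max() > 0 else 1.0
    out = np.clip(top - np.clip(sub, 0, top), 0, top)
    return FrameStack(out.astype(frames.dtype if
                                 np.issubdtype(frames.dtype, np.integer)
                                 else float),
                      stack.fps, stack.mm_per_pixel, stack.roi)


def background_mean(stack: FrameStack) -> np.ndarray:
    """Background image: pixelwise arithmetic mean over all frames."""
    return np.asarray(stack.frames, dtype=float).mean(axis=0)


def detect_objects(
    frame: np.ndarray,
    background: np.ndarray,
    threshold: float | None = None,
    min_area: int = 5,
    roi: tuple[int, int, int, int] | None = None,
) -> list[DetectedObject]:
    """Connected components of (frame - background > threshold).

    Centroids are intensity-weighted by the background-subtracted signal.
    Components smaller than ``min_area`` or centered outside the ROI are
    dropped.  With ``threshold=None`` an Otsu threshold of the difference
    image is used.
    """
    frame = np.asarray(frame, dtype=float)
    background = np.asarray(background, dtype=float)
    if frame.shape != background.shape:
        raise ValueError("frame and background shapes differ")
    diff = frame - background
    if threshold is None:
        vals = diff[np.isfinite(diff)]
        if vals.max() <= vals.min():
            return []
        threshold = float(threshold_otsu(vals))
    mask = diff > threshold
    if not mask.any():
        return []
    labeled = cc_label(mask, connectivity=2)
    out: list[DetectedObject] = []
    frame_index = -1  # caller assigns; kept explicit via helper below
    for rp in regionprops(labeled, intensity_image=np.where(mask, diff, 0.0)):
        if rp.area < min_area:
            continue
        centroid = rp.centroid_weighted
        if roi is not None:
            r0, c0, r1, c1 = roi
            if not (r0 <= centroid[0] < r1 and c0 <= centroid[1] < c1):
                continue
        out.append(DetectedObject(frame_index, (float(centroid[0]),
                                                float(centroid[1])),
                                  int(rp.area)))
    return out


def detect_all(stack: FrameStack, params: TrackingParams
               ) -> list[list[DetectedObject]]:
    """Per-frame detections against the mean background."""
    bg = background_mean(stack)
    detections: list[list[DetectedObject]] = []
    threshold = params.threshold
    if threshold is None:
        diff0 = np.asarray(stack.frames[0], float) - bg
        vals = diff0[np.isfinite(diff0)]
        threshold = (float(threshold_otsu(vals))
                     if vals.max() > vals.min() else np.inf)
    for t in range(stack.n_frames):
        objs = detect_objects(stack.frames[t], bg, threshold,
                              params.min_area, stack.roi)
        detections.append([DetectedObject(t, o.centroid, o.area) for o in objs])
    return detections


def link_trajectories(
    stack: FrameStack,
    detections: list[list[DetectedObject]],
    params: TrackingParams | None = None,
) -> list[Trajectory]:
    """Greedy nearest-neighbor linking of each initial-frame object.

    Each object present in the first frame is followed frame by frame to the
    Euclidean-nearest detection.  A track is terminated and marked rejected
    if the implied speed exceeds the limit, if it leaves the ROI, or if it
    stays within the stationarity radius for the full stationarity window.
    Frames with no detections keep the last position (the larva is treated as
    unmoved rather than teleported to a distant object).
    """
    params = params or TrackingParams()
    if not detections:
        return []
    window = int(round(params.stationary_window_s * stack.fps))
    max_step_px = params.speed_limit_mm_s / stack.mm_per_pixel / stack.fps

    trajectories: list[Trajectory] = []
    for lid, obj in enumerate(detections[0]):
        positions = [obj.centroid]
        status = "complete"
        anchor_idx = 0           # start of the current stationarity window
        for t in range(1, len(detections)):
            cands = detections[t]
            prev = positions[-1]
            if cands:
                d = [np.hypot(c.centroid[0] - prev[0], c.centroid[1] - prev[1])
                     for c in cands]
                j = int(np.argmin(d))
                nxt = cands[j].centroid
                if d[j] > max_step_px:
                    status = "rejected_speed"
                    positions.append(nxt)
                    break
            else:
                nxt = prev
            if not stack.in_roi(nxt):
                status = "rejected_roi"
                positions.append(nxt)
                break
            positions.append(nxt)
            # stationarity: displacement from the window anchor
            a = positions[anchor_idx]
            if np.hypot(nxt[0] - a[0], nxt[1] - a[1]) >= params.stationary_radius_px:
                anchor_idx = len(positions) - 1
            elif len(positions) - 1 - anchor_idx >= window:
                status = "rejected_stationary"
                break
        trajectories.append(Trajectory(larva_id=lid, start_frame=0,
                                       positions=positions, status=status))

    if params.contact_radius_px is not None:
        _flag_contacts(trajectories, params.contact_radius_px)
    return trajectories


def _flag_contacts(trajectories: list[Trajectory], radius: float) -> None:
    for i in range(len(trajectories)):
        for j in range(i + 1, len(trajectories)):
            a, b = trajectories[i], trajectories[j]
            n = min(len(a.positions), len(b.positions))
            pa = np.asarray(a.positions[:n], float)
            pb = np.asarray(b.positions[:n], float)
            if n and np.any(np.linalg.norm(pa - pb, axis=1) < radius):
                a.contact = True
                b.contact = True


def track_stack(
    stack: FrameStack, params: TrackingParams | None = None
) -> list[Trajectory]:
    """Detect and link in one call."""
    params = params or TrackingParams()
    return link_trajectories(stack, detect_all(stack, params), params)


def trajectories_to_frame(
    trajectories: list[Trajectory], fps: float, mm_per_pixel: float
) -> pd.DataFrame:
    """Long-format trajectory table (one row per larva per frame)."""
    rows = []
    for tr in trajectories:
        for k, (r, c) in enumerate(tr.positions):
            rows.append({
                "larva_id": tr.larva_id,
                "frame": tr.start_frame + k,
                "time_s": (tr.start_frame + k) / fps,
                "row_px": r, "col_px": c,
                "x_mm": c * mm_per_pixel, "y_mm": r * mm_per_pixel,
                "status": tr.status, "contact": tr.contact,
            })
    return pd.DataFrame(rows)


def load_stack(path, fps: float, mm_per_pixel: float,
               roi: tuple[int, int, int, int] | None = None) -> FrameStack:
    """Read a multi-page TIFF (or any imageio-readable video) as a FrameStack."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        frames = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        frames = iio.imread(path)
        if frames.ndim == 4:      # RGB video -> grayscale
            frames = frames.mean(axis=-1)
    return FrameStack(np.asarray(frames), fps, mm_per_pixel, roi)
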