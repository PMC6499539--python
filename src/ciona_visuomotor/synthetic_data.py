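"""Synthetic inputs with known ground truth for both analysis chains.

Two generators:

* labeled 3-D centroid clouds emulating HCR in situ datasets of the ocellus
  and relay-neuron cluster — rows-of-somata geometry, anchor cells, a
  neurotransmitter label model following the consensus assignments (PR-I
  glutamatergic except two ventral GABAergic cells, PR-II GABAergic with a
  co-expressing subset, relay cluster split 16 VGAT / 11 VACHT), and
  pseudo-larvae derived by sampled affine pose + jitter + dropout;

* rendered swim videos — larvae alternating stationary periods and swim
  bouts (run-and-turn steps whose heading noise sets tortuosity), optional
  light-dimming-evoked bouts and phototactic drift, drawn as Gaussian blobs
  over a noisy background, with frame-quantized ground-truth trajectories
  and a bout log.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ciona_visuomotor.centroid_io import CentroidDataset
from ciona_visuomotor.circuit_model import (
    CircuitFixture,
    default_circuit,
    fixture_anchors,
    fixture_points,
)
from ciona_visuomotor.tracking import FrameStack

__all__ = [
    "CloudConfig",
    "SwimSceneConfig",
    "make_reference_cloud",
    "perturb_dataset",
    "reference_label_map",
    "simulate_swim_video",
    "SwimTruth",
]

OCELLUS_CLASSES = ["PR-I", "PR-II"]
RELAY_CLASSES = ["prRN", "pr-AMG RN", "AntRN", "PBRN", "PCRN", "PNRN"]


# ---------------------------------------------------------------------------
# Centroid clouds

@dataclass
class CloudConfig:
    region: str = "ocellus"          # ocellus | relay | all
    rotation_max_deg: float = 60.0   # affine pose sampling for pseudo-larvae
    shear_max: float = 0.2
    translation_max_um: float = 20.0
    jitter_um: float = 0.5
    dropout: float = 0.0             # per-cell drop probability (+-1 cell)
    seed: int = 0

    def __post_init__(self):
        if self.region not in ("ocellus", "relay", "all"):
            raise ValueError(f"unknown region {self.region!r}")
        if self.jitter_um < 0 or not 0 <= self.dropout <= 1:
            raise ValueError("jitter_um >= 0 and dropout in [0, 1] required")


def _region_classes(region: str) -> list[str]:
    if region == "ocellus":
        return list(OCELLUS_CLASSES)
    if region == "relay":
        return list(RELAY_CLASSES)
    return OCELLUS_CLASSES + RELAY_CLASSES


def reference_label_map(fixture: CircuitFixture | None = None,
                        region: str = "all") -> dict[str, frozenset[str]]:
    """Ground-truth marker labels for the reference cells.

    Ocellus: PR-II cells are VGAT-positive with the two anterior-most cells
    VGAT-only and the rest co-expressing VGLUT; PR-I cells are VGLUT-only
    except the two most ventral cells — one VGAT-only (the PR-9 analog) and
    one VGAT+VGLUT (the PR-10 analog).  Relay cluster: prRNs evenly mixed
    3 VGAT / 3 VACHT; pr-AMG RNs 5 VGAT + 2 VACHT + 1 unlabeled (the
    pr-AMG RN 157 analog); AntRNs 8 VGAT + 2 VACHT; PBRN/PCRN cholinergic;
    PNRN unlabeled — totalling 16 VGAT and 11 VACHT relay cells.
    """
    fixture = fixture or default_circuit()
    labels: dict[str, frozenset[str]] = {}
    classes = _region_classes(region)

    if "PR-II" in classes:
        ids, pts = fixture_points(fixture, ["PR-II"])
        order = np.argsort(pts[:, 0])          # anterior first
        for rank, i in enumerate(order):
            labels[ids[i]] = (frozenset({"VGAT"}) if rank < 2
                              else frozenset({"VGAT", "VGLUT"}))
    if "PR-I" in classes:
        ids, pts = fixture_points(fixture, ["PR-I"])
        order = np.argsort(pts[:, 1])[::-1]    # most ventral (largest y) first
        for rank, i in enumerate(order):
            if rank == 0:
                labels[ids[i]] = frozenset({"VGAT"})          # PR-9 analog
            elif rank == 1:
                labels[ids[i]] = frozenset({"VGAT", "VGLUT"})  # PR-10 analog
            else:
                labels[ids[i]] = frozenset({"VGLUT"})

    relay_model = {
        "prRN": ["VGAT"] * 3 + ["VACHT"] * 3,
        "pr-AMG RN": ["VGAT"] * 5 + ["VACHT"] * 2 + [None],
        "AntRN": ["VGAT"] * 8 + ["VACHT"] * 2,
        "PBRN": ["VACHT"] * 2,
        "PCRN": ["VACHT"] * 2,
        "PNRN": [None] * 2,
    }
    for cls, model in relay_model.items():
        if cls not in classes:
            continue
        ids, pts = fixture_points(fixture, [cls])
        order = np.argsort(pts[:, 0])
        for rank, i in enumerate(order):
            m = model[rank]
            labels[ids[i]] = frozenset({m}) if m else frozenset()
    return labels


def make_reference_cloud(
    config: CloudConfig | None = None,
    fixture: CircuitFixture | None = None,
) -> tuple[CentroidDataset, dict[str, frozenset[str]]]:
    """The noise-free reference dataset for a region, with ground-truth labels.

    Deterministic given the fixture: geometry comes straight from the packaged
    circuit centroids (rows of somata), anchors from the antenna cells/ddNs.
    """
    config = config or CloudConfig()
    fixture = fixture or default_circuit()
    classes = _region_classes(config.region)
    ids, pts = fixture_points(fixture, classes)
    label_map = reference_label_map(fixture, config.region)
    ds = CentroidDataset(
        dataset_id=f"reference-{config.region}",
        cell_ids=list(ids),
        positions=pts.copy(),
        labels={cid: label_map[cid] for cid in ids if label_map.get(cid)},
        anchors=fixture_anchors(fixture),
    )
    return ds, label_map


@dataclass(frozen=True)
class TruePose:
    """The affine actually applied to a pseudo-larva (for oracle checks)."""

    B: np.ndarray
    t: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.B.T + self.t


def _random_rotation(rng: np.random.Generator, max_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.uniform(0, max_deg))
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * K + (1 - np.cos(angle)) * (K @ K)


def perturb_dataset(
    reference: CentroidDataset,
    config: CloudConfig | None = None,
    rng: np.random.Generator | None = None,
    dataset_id: str | None = None,
) -> tuple[CentroidDataset, TruePose]:
    """A pseudo-larva: sampled affine pose + isotropic jitter + dropout.

    The pose (rotation about the cloud centroid, off-diagonal shear, and
    translation) stands in for inter-larva variation the registration must
    absorb; anchors are transformed identically (and jittered like cells).
    Cells are dropped independently with probability ``dropout``; anchors are
    never dropped.  Returns the dataset and the true transform.
    """
    config = config or CloudConfig()
    rng = rng or np.random.default_rng(config.seed)

    R = _random_rotation(rng, config.rotation_max_deg)
    E = rng.uniform(-config.shear_max, config.shear_max, size=(3, 3))
    np.fill_diagonal(E, 0.0)
    B = R @ (np.eye(3) + E)
    center = reference.positions.mean(axis=0)
    shift = rng.uniform(-config.translation_max_um,
                        config.translation_max_um, size=3)
    t = center + shift - B @ center
    pose = TruePose(B=B, t=t)

    keep = rng.random(len(reference.cell_ids)) >= config.dropout
    cell_ids = [c for c, k in zip(reference.cell_ids, keep) if k]
    pts = pose.apply(reference.positions[keep])
    if config.jitter_um > 0:
        pts = pts + rng.normal(0, config.jitter_um, size=pts.shape)
    anchors = {}
    for name, pos in reference.anchors.items():
        a = pose.apply(pos[None, :])[0]
        if config.jitter_um > 0:
            a = a + rng.normal(0, config.jitter_um, size=3)
        anchors[name] = a
    return (
        CentroidDataset(
            dataset_id=dataset_id or f"{reference.dataset_id}-pseudo",
            cell_ids=cell_ids,
            positions=pts,
            labels={c: reference.label_of(c) for c in cell_ids
                    if reference.label_of(c)},
            anchors=anchors,
        ),
        pose,
    )


# ---------------------------------------------------------------------------
# Swim videos

@dataclass
class SwimSceneConfig:
    n_larvae: int = 10
    frame_shape: tuple[int, int] = (200, 200)
    fps: float = 8.9                  # spontaneous-swim recordings; dimming: 5
    duration_s: float = 60.0
    mm_per_pixel: float = 0.1
    bout_rate_per_min: float = 8.0    # the spontaneous-oscillator regime
    bout_duration_mean_s: float = 1.5
    bout_duration_sd_s: float = 0.5
    bout_speed_mm_s: float = 3.0
    bout_speed_sd_mm_s: float = 0.3
    turn_noise_rad: float = 0.25      # heading diffusion per step: tortuosity
    clock_like: bool = False          # fixed interval & duration (frm regime)
    dim_time_s: float | None = None
    dim_response_duration_s: float = 5.0
    dim_response_prob: float = 1.0
    phototaxis_bias: float = 0.0      # 0..1 pull of heading along +x (light ->)
    blob_sigma_px: float = 1.5
    blob_amplitude: float = 120.0
    background_level: float = 20.0
    noise_sd: float = 2.0
    margin_px: float = 15.0
    confine_half_px: float | None = None   # private cell half-width per larva:
                                           # guarantees a non-colliding scene
    seed: int = 0

    def __post_init__(self):
        if self.n_larvae < 1 or self.fps <= 0 or self.mm_per_pixel <= 0:
            raise ValueError("invalid scene configuration")
        if self.bout_rate_per_min <= 0 or self.bout_duration_mean_s <= 0:
            raise ValueError("bout process rates/scales must be positive")


@dataclass
class SwimTruth:
    positions_px: np.ndarray     # (n_larvae, T, 2) ground-truth (row, col)
    bouts: pd.DataFrame          # larva_id, start_s, end_s, duration_s, evoked
    responders: dict[int, bool]  # larvae given a dim-evoked bout

    def bout_log(self, larva_id: int) -> pd.DataFrame:
        return self.bouts[self.bouts.larva_id == larva_id]


def _sample_schedule(cfg: SwimSceneConfig, rng, T, dt):
    """Per-frame movement plan for one larva: True where it moves that step."""
    moving = np.zeros(T, dtype=bool)   # moving[k]: displaces between k-1 and k
    mean_interval = 60.0 / cfg.bout_rate_per_min
    min_duration = 0.5       # the shortest tail flick the process emits
    min_gap = 1.0            # larvae pause perceptibly between bouts
    t = 0.0
    # first onset mid-interval so larvae are initially stationary
    t += (mean_interval * 0.5 if cfg.clock_like
          else rng.exponential(mean_interval * 0.5))
    while t < cfg.duration_s:
        if cfg.clock_like:
            dur = cfg.bout_duration_mean_s
        else:
            dur = max(min_duration, rng.normal(cfg.bout_duration_mean_s,
                                               cfg.bout_duration_sd_s))
        a = int(round(t / dt)) + 1
        b = min(T - 1, a + max(1, int(round(dur / dt))) - 1)
        if a >= T:
            break
        moving[a : b + 1] = True
        t = b * dt
        t += max(min_gap,
                 mean_interval if cfg.clock_like
                 else rng.exponential(mean_interval))
    return moving


def simulate_swim_video(
    config: SwimSceneConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[FrameStack, SwimTruth]:
    """Render a swim scene and return the stack plus frame-quantized truth.

    Larvae alternate stationary periods and bouts; during a bout they take
    run-and-turn steps (Gaussian heading noise sets tortuosity, an optional
    bias pulls headings toward +x to emulate taxis).  If ``dim_time_s`` is
    set, larvae stationary at that moment receive an evoked bout shortly
    after.  The truth bout log is quantized to the frame grid: a bout whose
    displacements occupy frames a..b is logged with start a/fps and duration
    (b - a + 1)/fps, which is exactly what a tracker sees.
    """
    cfg = config or SwimSceneConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    H, W = cfg.frame_shape
    dt = 1.0 / cfg.fps
    T = int(round(cfg.duration_s * cfg.fps))

    # non-colliding starts on a jittered grid
    n = cfg.n_larvae
    grid = int(np.ceil(np.sqrt(n)))
    rr = np.linspace(cfg.margin_px, H - cfg.margin_px, grid + 2)[1:-1]
    cc = np.linspace(cfg.margin_px, W - cfg.margin_px, grid + 2)[1:-1]
    starts = [(r, c) for r in rr for c in cc][:n]

    positions = np.zeros((n, T, 2))
    bout_rows = []
    responders: dict[int, bool] = {}
    dim_frame = (int(round(cfg.dim_time_s * cfg.fps))
                 if cfg.dim_time_s is not None else None)

    for i in range(n):
        moving = _sample_schedule(cfg, rng, T, dt)
        if dim_frame is not None:
            stationary_at_dim = not moving[max(0, dim_frame - 3): dim_frame + 1].any()
            if stationary_at_dim and rng.random() < cfg.dim_response_prob:
                a = dim_frame + 2          # short latency after the dim
                b = min(T - 1, a + int(round(cfg.dim_response_duration_s / dt)) - 1)
                moving[a : b + 1] = True
                responders[i] = True
            else:
                responders[i] = False
        start = np.array(starts[i], float)
        if cfg.confine_half_px is not None:
            h = cfg.confine_half_px
            rlo, rhi = max(cfg.margin_px, start[0] - h), min(H - cfg.margin_px,
                                                             start[0] + h)
            clo, chi = max(cfg.margin_px, start[1] - h), min(W - cfg.margin_px,
                                                             start[1] + h)
        else:
            rlo, rhi = cfg.margin_px, H - cfg.margin_px
            clo, chi = cfg.margin_px, W - cfg.margin_px
        pos = start + rng.uniform(-2, 2, size=2)
        heading = rng.uniform(0, 2 * np.pi)
        speed = max(0.3, rng.normal(cfg.bout_speed_mm_s, cfg.bout_speed_sd_mm_s))
        positions[i, 0] = pos
        prev_moving = False
        for k in range(1, T):
            if moving[k]:
                if not prev_moving:
                    heading = rng.uniform(0, 2 * np.pi)
                    speed = max(0.3, rng.normal(cfg.bout_speed_mm_s,
                                                cfg.bout_speed_sd_mm_s))
                heading += rng.normal(0, cfg.turn_noise_rad)
                if cfg.phototaxis_bias > 0:
                    # pull the heading toward +col (away from a light at -col)
                    heading += cfg.phototaxis_bias * np.sin(-heading) * 0.5
                step_px = speed * dt / cfg.mm_per_pixel
                cand = pos + step_px * np.array([np.sin(heading),
                                                 np.cos(heading)])
                # reflect off the walls so the step is never lost
                if cand[0] < rlo or cand[0] > rhi:
                    cand[0] = np.clip(2 * rlo - cand[0] if cand[0] < rlo
                                      else 2 * rhi - cand[0], rlo, rhi)
                    heading = -heading
                if cand[1] < clo or cand[1] > chi:
                    cand[1] = np.clip(2 * clo - cand[1] if cand[1] < clo
                                      else 2 * chi - cand[1], clo, chi)
                    heading = np.pi - heading
                pos = cand
            positions[i, k] = pos
            prev_moving = moving[k]

        for a, b in _bool_runs(moving):
            evoked = dim_frame is not None and a - 2 <= dim_frame <= a + 1 \
                and responders.get(i, False)
            bout_rows.append({
                "larva_id": i,
                "start_s": a / cfg.fps,
                "end_s": (b + 1) / cfg.fps,
                "duration_s": (b - a + 1) / cfg.fps,
                "evoked": bool(evoked),
            })

    frames = np.zeros((T, H, W), dtype=np.uint8)
    rgrid, cgrid = np.mgrid[0:H, 0:W]
    for k in range(T):
        img = np.full((H, W), cfg.background_level, dtype=float)
        for i in range(n):
            r, c = positions[i, k]
            d2 = (rgrid - r) ** 2 + (cgrid - c) ** 2
            img += cfg.blob_amplitude * np.exp(-d2 / (2 * cfg.blob_sigma_px ** 2))
        img += rng.normal(0, cfg.noise_sd, size=(H, W))
        frames[k] = np.clip(img, 0, 255).astype(np.uint8)

    stack = FrameStack(frames, fps=cfg.fps, mm_per_pixel=cfg.mm_per_pixel)
    truth = SwimTruth(
        positions_px=positions,
        bouts=pd.DataFrame(
            bout_rows,
            columns=["larva_id", "start_s", "end_s", "duration_s", "evoked"]),
        responders=responders,
    )
    return stack, truth


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Closed-interval runs of True."""
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(int)))
    return [(a, b - 1) for a, b in zip(edges[::2], edges[1::2])]
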