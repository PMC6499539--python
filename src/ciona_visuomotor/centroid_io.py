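"""Read/write per-larva centroid datasets.

A centroid dataset is one larva's segmented nuclei (3-D positions in
micrometres), each optionally carrying marker labels (VGAT / VGLUT / VACHT,
a *set* — co-expression is first class), plus named anchor cells (antenna
cells and ddNs) used to initialize registration.

CSV dialect: comma separated with header ``cell_id,x,y,z,labels,anchor_flag``;
the labels field is semicolon-joined.  A JSON mirror schema is supported via
the same pair of functions.  Positions given in voxel units are converted to
micrometres on ingest when a voxel size is supplied.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ANCHOR_NAMES",
    "MARKER_VOCABULARY",
    "CentroidDataset",
    "CentroidIOError",
    "read_centroid_dataset",
    "write_centroid_dataset",
]

log = logging.getLogger(__name__)

MARKER_VOCABULARY = ("VGAT", "VGLUT", "VACHT")
ANCHOR_NAMES = ("antenna_L", "antenna_R", "ddN_L", "ddN_R")


class CentroidIOError(ValueError):
    pass


@dataclass
class CentroidDataset:
    """Segmented nuclei of one larva with marker labels and anchors."""

    dataset_id: str
    cell_ids: list[str]
    positions: np.ndarray  # (N, 3) micrometres
    labels: dict[str, frozenset[str]] = field(default_factory=dict)
    anchors: dict[str, np.ndarray] = field(default_factory=dict)
    voxel_size: tuple[float, float, float] | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        if len(self.cell_ids) != len(self.positions):
            raise CentroidIOError("cell_ids and positions length mismatch")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            seen = set()
            for c in self.cell_ids:
                if c in seen:
                    raise CentroidIOError(f"duplicate cell_id {c!r}")
                seen.add(c)
        if self.positions.size and not np.all(np.isfinite(self.positions)):
            raise CentroidIOError("non-finite centroid coordinates")
        for cid, labs in self.labels.items():
            bad = set(labs) - set(MARKER_VOCABULARY)
            if bad:
                raise CentroidIOError(
                    f"cell {cid!r}: labels outside marker vocabulary: {sorted(bad)}"
                )
        for name, pos in list(self.anchors.items()):
            if name not in ANCHOR_NAMES:
                raise CentroidIOError(f"unknown anchor name {name!r}")
            self.anchors[name] = np.asarray(pos, dtype=float).reshape(3)

    def __len__(self) -> int:
        return len(self.cell_ids)

    def label_of(self, cell_id: str) -> frozenset[str]:
        return self.labels.get(cell_id, frozenset())

    def index_of(self, cell_id: str) -> int:
        return self.cell_ids.index(cell_id)

    def copy(self) -> "CentroidDataset":
        return CentroidDataset(
            dataset_id=self.dataset_id,
            cell_ids=list(self.cell_ids),
            positions=self.positions.copy(),
            labels={k: frozenset(v) for k, v in self.labels.items()},
            anchors={k: v.copy() for k, v in self.anchors.items()},
            voxel_size=self.voxel_size,
        )


def _parse_labels(text: str) -> frozenset[str]:
    text = (text or "").strip()
    if not text:
        return frozenset()
    return frozenset(tok.strip() for tok in text.split(";") if tok.strip())


def read_centroid_dataset(
    path, voxel_size: tuple[float, float, float] | None = None,
    dataset_id: str | None = None,
) -> CentroidDataset:
    """Read a centroid table (CSV or JSON).

    ``voxel_size`` (micrometres per voxel along x, y, z), when given, scales
    the coordinates voxel -> micrometre.  Anchor rows are flagged in the
    ``anchor_flag`` column with one of ``antenna_L/antenna_R/ddN_L/ddN_R``;
    anchor rows are stored in ``anchors`` and excluded from the point list.
    """
    path = Path(path)
    if dataset_id is None:
        dataset_id = path.stem

    if path.suffix == ".json":
        with open(path) as fh:
            doc = json.load(fh)
        rows = [
            (r["cell_id"], r["x"], r["y"], r["z"],
             ";".join(r.get("labels", [])), r.get("anchor_flag", ""))
            for r in doc["cells"]
        ]
        voxel_size = voxel_size or (tuple(doc["voxel_size"])
                                    if doc.get("voxel_size") else None)
        dataset_id = doc.get("dataset_id", dataset_id)
    else:
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            required = {"cell_id", "x", "y", "z"}
            if reader.fieldnames is None or not required <= set(reader.fieldnames):
                raise CentroidIOError(
                    f"{path}: header must contain {sorted(required)}"
                )
            rows = [
                (r["cell_id"], r["x"], r["y"], r["z"],
                 r.get("labels", ""), r.get("anchor_flag", ""))
                for r in reader
            ]

    scale = np.asarray(voxel_size, float) if voxel_size is not None else None

    cell_ids: list[str] = []
    positions: list[np.ndarray] = []
    labels: dict[str, frozenset[str]] = {}
    anchors: dict[str, np.ndarray] = {}
    for cid, x, y, z, labtext, aflag in rows:
        try:
            pos = np.array([float(x), float(y), float(z)])
        except (TypeError, ValueError) as exc:
            raise CentroidIOError(
                f"{path}: non-numeric coordinate for cell {cid!r}"
            ) from exc
        if scale is not None:
            pos = pos * scale
        aflag = (aflag or "").strip()
        if aflag:
            if aflag not in ANCHOR_NAMES:
                raise CentroidIOError(f"{path}: unknown anchor flag {aflag!r}")
            anchors[aflag] = pos
        else:
            cell_ids.append(cid)
            positions.append(pos)
            labs = _parse_labels(labtext)
            if labs:
                labels[cid] = labs

    return CentroidDataset(
        dataset_id=dataset_id,
        cell_ids=cell_ids,
        positions=np.array(positions).reshape(-1, 3),
        labels=labels,
        anchors=anchors,
        voxel_size=tuple(voxel_size) if voxel_size is not None else None,
    )


def write_centroid_dataset(dataset: CentroidDataset, path) -> None:
    """Write a dataset (micrometre units) as CSV or JSON.

    Round-trips: ``read_centroid_dataset(write(...))`` reproduces the dataset.
    Datasets without anchors are written with an empty anchor block and a
    warning, since they cannot be registered later.
    """
    path = Path(path)
    if not dataset.anchors:
        warnings.warn(
            f"dataset {dataset.dataset_id!r} has no anchors; it can be stored "
            "but not registered", stacklevel=2)
        log.warning("writing dataset %s without anchors", dataset.dataset_id)

    if path.suffix == ".json":
        doc = {
            "dataset_id": dataset.dataset_id,
            "voxel_size": None,
            "cells": [
                {"cell_id": cid, "x": p[0], "y": p[1], "z": p[2],
                 "labels": sorted(dataset.label_of(cid)), "anchor_flag": ""}
                for cid, p in zip(dataset.cell_ids, dataset.positions)
            ] + [
                {"cell_id": name, "x": p[0], "y": p[1], "z": p[2],
                 "labels": [], "anchor_flag": name}
                for name, p in sorted(dataset.anchors.items())
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
            fh.write("\n")
        return

    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["cell_id", "x", "y", "z", "labels", "anchor_flag"])
        for cid, p in zip(dataset.cell_ids, dataset.positions):
            wr.writerow([cid, repr(float(p[0])), repr(float(p[1])),
                         repr(float(p[2])),
                         ";".join(sorted(dataset.label_of(cid))), ""])
        for name, p in sorted(dataset.anchors.items()):
            wr.writerow([name, repr(float(p[0])), repr(float(p[1])),
                         repr(float(p[2])), "", name])
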