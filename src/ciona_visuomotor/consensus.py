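"""Consensus over per-dataset label transfers: heat maps, neurotransmitter
calls, and cross-dataset confusion matrices.

A heat map entry is the proportion of datasets whose transferred label set
for a reference cell contains a given marker; an extra ``no-call`` column
tracks the fraction of datasets in which no source cell mapped to the cell.
Counts are kept exact (every proportion is k/n_datasets); a row-normalized
view is only a rendering concern.

The confusion matrix cross-validates the registration: every ordered pair of
datasets is registered to the reference and to each other, and each matched
cell pair votes for the (reference cell assigned by A, reference cell
assigned by B) entry.  Diagonal mass is cross-dataset agreement.  Pooling
cells by class gives the class-level view used when single-cell identity is
uncertain but class clustering is strong (the relay-neuron situation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ciona_visuomotor.centroid_io import CentroidDataset
from ciona_visuomotor.registration import (
    LabeledAssignment,
    RegistrationParams,
    map_nearest,
    register_dataset,
)

__all__ = [
    "HeatMap",
    "ConfusionMatrix",
    "GroupedConfusion",
    "build_heatmap",
    "consensus_call",
    "pairwise_confusion",
    "group_confusion",
]

NO_CALL = "no-call"


@dataclass
class HeatMap:
    cells: list[str]
    label_vocab: list[str]          # markers followed by the no-call column
    values: np.ndarray              # (n_cells, n_labels) proportions in [0, 1]
    n_datasets: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.cells,
                            columns=self.label_vocab)

    def proportions(self, cell_id: str) -> dict[str, float]:
        i = self.cells.index(cell_id)
        return dict(zip(self.label_vocab, self.values[i]))


@dataclass
class ConfusionMatrix:
    cells: list[str]
    counts: np.ndarray              # (n_cells, n_cells) non-negative ints
    n_comparisons: int              # number of ordered dataset pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.cells, columns=self.cells)

    @property
    def diagonal_fraction(self) -> float:
        total = self.counts.sum()
        if total == 0:
            return float("nan")
        return float(np.trace(self.counts) / total)

    def row_normalized(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.counts / self.counts.sum(axis=1, keepdims=True)
        return np.nan_to_num(out)


@dataclass
class GroupedConfusion:
    classes: list[str]
    counts: np.ndarray
    n_comparisons: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes,
                            columns=self.classes)

    @property
    def diagonal_fraction(self) -> float:
        total = self.counts.sum()
        if total == 0:
            return float("nan")
        return float(np.trace(self.counts) / total)


def build_heatmap(
    assignments: list[LabeledAssignment],
    label_vocab: list[str],
) -> HeatMap:
    """Per-cell marker proportions over datasets, plus the no-call fraction."""
    if not assignments:
        raise ValueError("need at least one assignment")
    if not label_vocab:
        raise ValueError("empty label vocabulary")
    cells = assignments[0].reference_ids
    for a in assignments[1:]:
        if a.reference_ids != cells:
            raise ValueError(
                f"assignment {a.dataset_id!r} is over a different reference")
    n = len(assignments)
    vocab = list(label_vocab) + [NO_CALL]
    values = np.zeros((len(cells), len(vocab)))
    for a in assignments:
        for i, cell in enumerate(cells):
            if cell not in a.labels:
                values[i, -1] += 1
                continue
            labs = a.labels[cell]
            for j, lab in enumerate(label_vocab):
                if lab in labs:
                    values[i, j] += 1
    values /= n
    return HeatMap(cells=list(cells), label_vocab=vocab, values=values,
                   n_datasets=n)


def consensus_call(
    heatmap: HeatMap, majority_threshold: float = 0.6
) -> dict[str, frozenset[str] | str]:
    """Call each marker present where its proportion reaches the threshold.

    Cells where no marker reaches threshold are ``"unresolved"`` — the
    behavior of evenly split cells (a 0.5/0.5 cell cannot be resolved).
    Several markers above threshold yield a co-expression call.
    """
    if not 0.5 < majority_threshold <= 1.0:
        raise ValueError("majority_threshold must be in (0.5, 1]")
    markers = [l for l in heatmap.label_vocab if l != NO_CALL]
    out: dict[str, frozenset[str] | str] = {}
    for i, cell in enumerate(heatmap.cells):
        called = frozenset(
            lab for j, lab in enumerate(heatmap.label_vocab)
            if lab in markers and heatmap.values[i, j] >= majority_threshold
        )
        out[cell] = called if called else "unresolved"
    return out


def pairwise_confusion(
    datasets: list[CentroidDataset],
    reference,
    params: RegistrationParams | None = None,
    pairing: str = "direct",
) -> ConfusionMatrix:
    """Cross-dataset registration agreement.

    For every ordered pair (A, B): A and B are each registered to the
    reference; a correspondence between A's and B's cells is then obtained
    either by a fresh registration A->B (``pairing="direct"``, the default)
    or by nearest neighbors between the two clouds transformed into the
    reference frame (``pairing="via-reference"``).  Each corresponded cell
    pair increments ``counts[ref_cell(A's cell), ref_cell(B's cell)]``.
    """
    if len(datasets) < 2:
        raise ValueError("need at least two datasets")
    if pairing not in ("direct", "via-reference"):
        raise ValueError(f"unknown pairing mode {pairing!r}")
    params = params or RegistrationParams()

    to_ref = [register_dataset(d, reference, params) for d in datasets]
    cells = to_ref[0].reference_ids
    index = {c: i for i, c in enumerate(cells)}
    counts = np.zeros((len(cells), len(cells)), dtype=int)
    n_pairs = 0

    for ai, A in enumerate(datasets):
        for bi, B in enumerate(datasets):
            if ai == bi:
                continue
            n_pairs += 1
            ref_a = to_ref[ai].registration.correspondence
            ref_b = to_ref[bi].registration.correspondence
            if pairing == "direct":
                # dataset-to-dataset registration uses no target_classes
                # (the reference cloud is B's own cells)
                ab_params = RegistrationParams(
                    w=params.w, max_iterations=params.max_iterations,
                    tolerance=params.tolerance,
                    anchor_names=params.anchor_names,
                    one_to_one=params.one_to_one)
                ab = register_dataset(A, B, ab_params)
                a_to_b = ab.registration.correspondence
            else:
                Ta = to_ref[ai].registration.transform.apply(A.positions)
                Tb = to_ref[bi].registration.transform.apply(B.positions)
                a_to_b, _ = map_nearest(Ta, A.cell_ids, Tb, B.cell_ids)
            for a_cell, b_cell in a_to_b.items():
                counts[index[ref_a[a_cell]], index[ref_b[b_cell]]] += 1

    return ConfusionMatrix(cells=list(cells), counts=counts,
                           n_comparisons=n_pairs)


def group_confusion(
    cm: ConfusionMatrix, class_map: dict[str, str]
) -> GroupedConfusion:
    """Pool a per-cell confusion matrix by cell class; mass is conserved."""
    missing = [c for c in cm.cells if c not in class_map]
    if missing:
        raise ValueError(f"cells missing from class_map: {missing[:5]}")
    classes = sorted(set(class_map[c] for c in cm.cells))
    cindex = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for i, ci in enumerate(cm.cells):
        for j, cj in enumerate(cm.cells):
            counts[cindex[class_map[ci]], cindex[class_map[cj]]] += cm.counts[i, j]
    return GroupedConfusion(classes=classes, counts=counts,
                            n_comparisons=cm.n_comparisons)
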