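"""Minimal visuomotor circuit of the Ciona larva as a registration reference.

The larval Ciona CNS (~170 neurons) contains a fully reconstructed synaptic
connectome.  This module packages the *minimal visuomotor circuit* — the two
ocellus photoreceptor groups, the posterior brain-vesicle relay-neuron
cluster, the motor-ganglion interneurons and motor neurons, plus the landmark
cells used as registration anchors (antenna cells, ddNs) — as a small typed
fixture: neuron identities, class labels, reference centroids and class-level
connectivity.

The reference centroids are synthetic stand-ins laid out to respect the
described anatomy (photoreceptor somata arranged in rows around the pigment
cup, PR-II anterior of PR-I, relay-neuron classes clustered along the
anterior-posterior axis, antenna-cell relay neurons at the rear of the brain
vesicle); the connectome's own coordinate table is not published.  All
registration tests are self-consistent against these coordinates.

Coordinate convention: right-handed, micrometres; +x anterior->posterior,
+y dorsal->ventral, +z left->right.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "CLASS_VOCABULARY",
    "SIDES",
    "NeuronRecord",
    "SynapseEdge",
    "CircuitFixture",
    "CircuitValidationError",
    "default_circuit",
    "load_circuit_fixture",
    "write_circuit_fixture",
    "class_counts",
    "projection_targets",
    "fixture_anchors",
    "fixture_points",
]

CLASS_VOCABULARY = (
    "PR-I", "PR-II", "PR-III",
    "prRN", "pr-AMG RN", "AntRN", "PBRN", "PCRN", "PNRN",
    "MGIN", "MN", "ddN", "AMG", "ACIN",
    "antenna_cell", "eminens",
)

SIDES = ("left", "right", "medial", "unknown")

NT_VOCABULARY = ("VGAT", "VGLUT", "VACHT")


class CircuitValidationError(ValueError):
    """Raised when a fixture violates its schema or referential integrity."""


@dataclass(frozen=True)
class NeuronRecord:
    """One neuron of the minimal circuit.

    ``centroid`` is in micrometres; ``nt_annotation`` holds the consensus
    neurotransmitter call (empty until assigned by the consensus stage).
    """

    neuron_id: str
    class_label: str
    side: str
    centroid: tuple[float, float, float]
    nt_annotation: frozenset[str] = frozenset()

    def __post_init__(self):
        if self.class_label not in CLASS_VOCABULARY:
            raise CircuitValidationError(
                f"neuron {self.neuron_id!r}: unknown class {self.class_label!r}"
            )
        if self.side not in SIDES:
            raise CircuitValidationError(
                f"neuron {self.neuron_id!r}: unknown side {self.side!r}"
            )
        c = np.asarray(self.centroid, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise CircuitValidationError(
                f"neuron {self.neuron_id!r}: centroid must be a finite 3-vector"
            )
        bad = set(self.nt_annotation) - set(NT_VOCABULARY)
        if bad:
            raise CircuitValidationError(
                f"neuron {self.neuron_id!r}: unknown NT annotation {sorted(bad)}"
            )


@dataclass(frozen=True)
class SynapseEdge:
    pre_id: str
    post_id: str
    kind: str = "chemical"  # chemical | electrical
    weight: float = 1.0

    def __post_init__(self):
        if self.kind not in ("chemical", "electrical"):
            raise CircuitValidationError(f"unknown synapse kind {self.kind!r}")
        if self.kind == "chemical" and self.pre_id == self.post_id:
            raise CircuitValidationError(
                f"chemical self-edge on {self.pre_id!r}"
            )
        if self.weight < 0:
            raise CircuitValidationError(
                f"edge {self.pre_id}->{self.post_id}: negative weight"
            )


@dataclass
class CircuitFixture:
    neurons: list[NeuronRecord]
    edges: list[SynapseEdge]
    provenance: str = ""

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ids = [n.neuron_id for n in self.neurons]
        if len(ids) != len(set(ids)):
            seen, dup = set(), None
            for i in ids:
                if i in seen:
                    dup = i
                    break
                seen.add(i)
            raise CircuitValidationError(f"duplicate neuron_id {dup!r}")
        known = set(ids)
        for e in self.edges:
            for endpoint in (e.pre_id, e.post_id):
                if endpoint not in known:
                    raise CircuitValidationError(
                        f"edge {e.pre_id}->{e.post_id}: dangling endpoint "
                        f"{endpoint!r}"
                    )

    def neuron(self, neuron_id: str) -> NeuronRecord:
        for n in self.neurons:
            if n.neuron_id == neuron_id:
                return n
        raise KeyError(f"unknown neuron_id {neuron_id!r}")

    def ids_of_class(self, class_label: str) -> list[str]:
        return [n.neuron_id for n in self.neurons if n.class_label == class_label]


def class_counts(fixture: CircuitFixture) -> dict[str, int]:
    """Number of neurons of each class; every vocabulary class present."""
    counts = {c: 0 for c in CLASS_VOCABULARY}
    for n in fixture.neurons:
        counts[n.class_label] += 1
    return counts


def projection_targets(
    fixture: CircuitFixture, neuron_id: str, kind: str = "chemical"
) -> list[str]:
    """Post-synaptic partners of ``neuron_id`` of the given synapse kind,
    ordered by neuron_id."""
    fixture.neuron(neuron_id)  # raises KeyError for unknown ids
    targets = {
        e.post_id for e in fixture.edges if e.pre_id == neuron_id and e.kind == kind
    }
    return sorted(targets)


def fixture_anchors(fixture: CircuitFixture) -> dict[str, np.ndarray]:
    """Anchor-cell positions keyed by the registration anchor vocabulary.

    Antenna cells and ddNs serve as landmarks shared between the connectome
    and in situ datasets.
    """
    side_tag = {"left": "L", "right": "R"}
    anchors: dict[str, np.ndarray] = {}
    for n in fixture.neurons:
        if n.class_label == "antenna_cell" and n.side in side_tag:
            anchors[f"antenna_{side_tag[n.side]}"] = np.asarray(n.centroid, float)
        elif n.class_label == "ddN" and n.side in side_tag:
            anchors[f"ddN_{side_tag[n.side]}"] = np.asarray(n.centroid, float)
    return anchors


def fixture_points(
    fixture: CircuitFixture, classes: list[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Cell ids and an (N, 3) centroid array, optionally restricted to classes."""
    recs = [
        n for n in fixture.neurons if classes is None or n.class_label in classes
    ]
    ids = [n.neuron_id for n in recs]
    pts = np.array([n.centroid for n in recs], dtype=float).reshape(len(recs), 3)
    return ids, pts


# ---------------------------------------------------------------------------
# Default fixture construction

def _row_layout(n, rows, x0, dx, y0, dy, z_half_span):
    """Cells arranged in rows: the ocellus photoreceptor somata are known to
    sit in ordered rows, which is what makes cross-larva registration viable."""
    pts = []
    per_row = int(np.ceil(n / rows))
    k = 0
    for r in range(rows):
        m = min(per_row, n - k)
        zs = np.linspace(-z_half_span, z_half_span, m) if m > 1 else [0.0]
        for j in range(m):
            # slight curvature so rows are non-coplanar
            pts.append((x0 + r * dx + 0.3 * abs(zs[j]), y0 + r * dy, zs[j]))
            k += 1
    return pts


def default_circuit() -> CircuitFixture:
    """The packaged minimal visuomotor circuit.

    Class inventory (from the connectome): 23 PR-I, 7 PR-II, 6 PR-III,
    6 prRN, 8 pr-AMG RN, 10 AntRN, 2 PBRN, 2 PCRN, 2 PNRN (a ~30-cell relay
    cluster), 6 MGIN, 10 MN, 2 ddN, 7 AMG, 3 ACIN (the connectome animal's
    unpaired third ACIN is kept), 2 antenna cells, 2 eminens cells.

    Edges are class-level connectivity expanded to all member pairs with
    uniform weight 1.0 (placeholders; the registration and consensus stages
    never read weights).
    """
    neurons: list[NeuronRecord] = []

    def add(prefix, class_label, pts, sides=None):
        for i, p in enumerate(pts):
            side = sides[i] if sides else ("left" if p[2] < -0.5 else
                                           "right" if p[2] > 0.5 else "medial")
            neurons.append(NeuronRecord(f"{prefix}-{i + 1:02d}", class_label,
                                        side, tuple(np.round(p, 3))))

    # Ocellus: PR-II anterior (x ~ 48-53), PR-I rows around the pigment cup
    # (x ~ 58-75), PR-III distal.
    add("PR-II", "PR-II", _row_layout(7, 2, 48.0, 4.5, 18.0, 2.0, 7.0))
    add("PR", "PR-I", _row_layout(23, 4, 58.0, 4.5, 20.0, 1.5, 11.0))
    add("PR-III", "PR-III", _row_layout(6, 1, 80.0, 4.5, 14.0, 0.0, 10.0))

    # Posterior brain-vesicle relay cluster, classes ordered along A-P;
    # AntRNs clustered at the rear of the brain vesicle.
    add("prRN", "prRN", _row_layout(6, 2, 92.0, 4.0, 24.0, 3.0, 6.0))
    add("pr-AMG-RN", "pr-AMG RN", _row_layout(8, 2, 99.0, 4.0, 26.0, 3.0, 7.0))
    add("PBRN", "PBRN", _row_layout(2, 1, 104.0, 4.0, 22.0, 0.0, 4.0))
    add("PCRN", "PCRN", _row_layout(2, 1, 107.0, 4.0, 30.0, 0.0, 4.0))
    add("PNRN", "PNRN", _row_layout(2, 1, 110.0, 4.0, 25.0, 0.0, 4.0))
    add("AntRN", "AntRN", _row_layout(10, 2, 112.0, 4.0, 27.0, 3.0, 8.0))

    # Landmarks: antenna cells near the otolith, ddNs at the MG entrance.
    add("antenna", "antenna_cell", [(70.0, 34.0, -4.0), (70.0, 34.0, 4.0)],
        sides=["left", "right"])
    add("ddN", "ddN", [(145.0, 26.0, -3.0), (145.0, 26.0, 3.0)],
        sides=["left", "right"])
    add("eminens", "eminens", [(88.0, 14.0, -5.0), (88.0, 14.0, 5.0)],
        sides=["left", "right"])

    # Motor ganglion: 3 MGIN + 5 MN per side, 7 AMG dorsal, 3 ACIN
    # (anterior ACIN unpaired in the connectome animal).
    mgin = [(150.0 + 5 * i, 24.0, z) for z in (-3.0, 3.0) for i in range(3)]
    add("MGIN", "MGIN", mgin,
        sides=["left"] * 3 + ["right"] * 3)
    mn = [(152.0 + 5 * i, 30.0, z) for z in (-3.5, 3.5) for i in range(5)]
    add("MN", "MN", mn, sides=["left"] * 5 + ["right"] * 5)
    add("AMG", "AMG", _row_layout(7, 2, 148.0, 4.0, 16.0, 2.0, 5.0))
    add("ACIN", "ACIN", [(166.0, 27.0, 0.0), (172.0, 27.0, -2.5),
                         (172.0, 27.0, 2.5)],
        sides=["medial", "left", "right"])

    by_class: dict[str, list[str]] = {}
    for n in neurons:
        by_class.setdefault(n.class_label, []).append(n.neuron_id)

    # Class-level chemical connectivity of the minimal circuit:
    # PR-I -> prRN and pr-AMG RN; PR-II -> pr-AMG RN only (prRNs receive
    # input exclusively from PR-I); relay classes -> MGIN; MGIN -> MN;
    # AMGs ascend to the pr-AMG RNs and project within the MG;
    # antenna cells -> AntRN; ddN -> MN (startle pathway); ACIN -> MN.
    chemical = [
        ("PR-I", "prRN"), ("PR-I", "pr-AMG RN"),
        ("PR-II", "pr-AMG RN"),
        ("prRN", "pr-AMG RN"), ("pr-AMG RN", "prRN"),
        ("prRN", "MGIN"), ("pr-AMG RN", "MGIN"),
        ("AntRN", "MGIN"),
        ("MGIN", "MN"),
        ("AMG", "pr-AMG RN"), ("AMG", "MGIN"), ("AMG", "MN"),
        ("antenna_cell", "AntRN"),
        ("ddN", "MN"),
        ("ACIN", "MN"),
    ]
    edges: list[SynapseEdge] = []
    for pre_c, post_c in chemical:
        for a in by_class.get(pre_c, []):
            for b in by_class.get(post_c, []):
                edges.append(SynapseEdge(a, b, "chemical", 1.0))
    # sparse electrical coupling in the motor ganglion
    for a, b in zip(by_class["MGIN"], by_class["MN"]):
        edges.append(SynapseEdge(a, b, "electrical", 1.0))

    return CircuitFixture(
        neurons=neurons,
        edges=edges,
        provenance=(
            "Minimal Ciona larval visuomotor circuit; class inventory from the "
            "larval connectome; centroids are SYNTHETIC stand-ins respecting "
            "the described anatomy (micrometres; +x ant->post, +y dor->vent, "
            "+z left->right)."
        ),
    )


# ---------------------------------------------------------------------------
# Serialization

def _fixture_to_dict(fixture: CircuitFixture) -> dict:
    return {
        "provenance": fixture.provenance,
        "coordinate_convention": "um; +x ant->post, +y dor->vent, +z L->R",
        "neurons": [
            {
                "id": n.neuron_id,
                "class": n.class_label,
                "side": n.side,
                "centroid": list(n.centroid),
                "nt": sorted(n.nt_annotation),
            }
            for n in fixture.neurons
        ],
        "edges": [
            [e.pre_id, e.post_id, e.kind, e.weight] for e in fixture.edges
        ],
    }


def write_circuit_fixture(fixture: CircuitFixture, path) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        import csv

        with open(path, "w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["id", "class", "side", "x", "y", "z", "nt"])
            for n in fixture.neurons:
                wr.writerow([n.neuron_id, n.class_label, n.side,
                             *n.centroid, ";".join(sorted(n.nt_annotation))])
        return
    doc = _fixture_to_dict(fixture)
    with open(path, "w") as fh:
        # one record per line: diffable but compact
        fh.write('{"provenance": %s,\n"coordinate_convention": %s,\n'
                 % (json.dumps(doc["provenance"]),
                    json.dumps(doc["coordinate_convention"])))
        fh.write('"neurons": [\n')
        fh.write(",\n".join(json.dumps(n, separators=(",", ":"))
                            for n in doc["neurons"]))
        fh.write('\n],\n"edges": [\n')
        fh.write(",\n".join(json.dumps(e, separators=(",", ":"))
                            for e in doc["edges"]))
        fh.write("\n]}\n")


def _fixture_from_dict(doc: dict) -> CircuitFixture:
    try:
        neurons = [
            NeuronRecord(
                neuron_id=rec["id"],
                class_label=rec["class"],
                side=rec.get("side", "unknown"),
                centroid=tuple(float(v) for v in rec["centroid"]),
                nt_annotation=frozenset(rec.get("nt", [])),
            )
            for rec in doc["neurons"]
        ]
        edges = [
            SynapseEdge(pre, post, kind, float(w))
            for pre, post, kind, w in doc.get("edges", [])
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise CircuitValidationError(f"malformed fixture record: {exc}") from exc
    return CircuitFixture(neurons=neurons, edges=edges,
                          provenance=doc.get("provenance", ""))


def load_circuit_fixture(path=None) -> CircuitFixture:
    """Load a circuit fixture from JSON; with no path, the packaged default."""
    if path is None:
        ref = resources.files("ciona_visuomotor") / "data" / "minimal_circuit.json"
        with ref.open() as fh:
            return _fixture_from_dict(json.load(fh))
    with open(path) as fh:
        return _fixture_from_dict(json.load(fh))
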