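#!/usr/bin/env python
"""Package the minimal visuomotor circuit and summarize its inventory.

Writes the circuit fixture (JSON + CSV) and a class-count table, and prints
the connectivity facts downstream stages rely on: both photoreceptor groups
reach the pr-AMG relay neurons, but only PR-I cells reach the prRNs.
"""

from pathlib import Path

import pandas as pd

from ciona_visuomotor.circuit_model import (
    class_counts,
    default_circuit,
    projection_targets,
    write_circuit_fixture,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)


def main() -> None:
    fixture = default_circuit()
    write_circuit_fixture(fixture, OUT / "minimal_circuit.json")
    write_circuit_fixture(fixture, OUT / "minimal_circuit.csv")

    counts = class_counts(fixture)
    pd.Series(counts, name="n_cells").rename_axis("class").to_csv(
        OUT / "circuit_class_counts.csv")
    print("Minimal visuomotor circuit:", len(fixture.neurons), "neurons,",
          len(fixture.edges), "edges")
    for cls, n in counts.items():
        if n:
            print(f"  {cls:14s} {n}")

    relay = ["prRN", "pr-AMG RN", "AntRN", "PBRN", "PCRN", "PNRN"]
    print("relay-neuron cluster:", sum(counts[c] for c in relay), "cells")

    pr1 = {fixture.neuron(t).class_label
           for t in projection_targets(fixture, "PR-01")}
    pr2 = {fixture.neuron(t).class_label
           for t in projection_targets(fixture, "PR-II-01")}
    print("PR-I chemical targets:", sorted(pr1))
    print("PR-II chemical targets:", sorted(pr2),
          "(no prRN: dimming pathway enters via the pr-AMG RNs)")


if __name__ == "__main__":
    main()
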