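#!/usr/bin/env python
"""Size and gradient layers: derive discharge thresholds, bin every reach.

Derives size thresholds as midpoints between per-order median discharges on
the generated network, compares them with the shipped national defaults,
and writes the per-reach size/gradient table.
"""

from pathlib import Path

from streamclass.network import read_network
from streamclass.size_gradient import (
    DEFAULT_SIZE_BREAKS,
    derive_size_thresholds,
    size_gradient_table,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    net = read_network(OUT / "reaches.csv", OUT / "fromto.csv")
    thr = derive_size_thresholds(net)
    print("per-order median discharge (m^3/s):",
          {o: round(m, 4) for o, m in thr.medians.items()})
    print("derived breaks:", [round(float(b), 4) for b in thr.breaks])
    print("national default breaks:", list(DEFAULT_SIZE_BREAKS))

    table = size_gradient_table(net)  # defaults: the national thresholds
    table.to_csv(OUT / "size_gradient.csv", index=False)
    print("size class shares:",
          table["size_class"].value_counts(normalize=True).round(3).to_dict())
    print("gradient class shares:",
          table["gradient_class"].value_counts(normalize=True).round(3).to_dict())


if __name__ == "__main__":
    main()
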