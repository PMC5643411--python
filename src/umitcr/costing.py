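"""Per-sample reagent cost of the library-preparation protocol.

The bundled table lists the reagent line items (pounds sterling per
sample, excluding sequencing) for the UMI-ligation TCR library protocol.
Summing the line items gives the per-sample cost; rounded to the nearest
pound it is 14.
"""

from __future__ import annotations

import csv
from importlib import resources


def reagent_table() -> list[tuple[str, float]]:
    ref = resources.files("umitcr").joinpath("data/reagent_costs.csv")
    with ref.open(newline="") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        return [(row[0], float(row[1])) for row in reader if row]


def per_sample_cost() -> float:
    """Summed reagent cost per sample, in pounds sterling."""
    return sum(cost for _, cost in reagent_table())
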