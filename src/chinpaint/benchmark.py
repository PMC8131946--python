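"""Reference results of the MNIST damage-restoration benchmark.

Published accuracy pairs (without / with the Cahn-Hilliard filter) and the
reported integer improvement percentages for each damage setting of the
full 10 000-image MNIST benchmark: four customized line damages, random row
damage of increasing count, and random pixel damage of increasing fraction.
The baseline accuracy of the dense classifier on the undamaged test set is
0.97.

These rows serve as ground truth for the improvement metric's rounding
convention (every printed percentage must be reproduced exactly from its
accuracy pair) and as the reference profile for optional full-scale
reproductions with user-supplied MNIST files.
"""

from __future__ import annotations

__all__ = [
    "BASELINE_ACCURACY",
    "CUSTOMIZED_ROWS",
    "RANDOM_ROWS",
    "RANDOM_PIXELS",
    "all_rows",
]

BASELINE_ACCURACY = 0.97

# (damage label, accuracy without filter, accuracy with filter, improvement %)
CUSTOMIZED_ROWS = [
    ("A", 0.84, 0.96, 14),
    ("B", 0.71, 0.93, 31),
    ("C", 0.64, 0.82, 28),
    ("D", 0.90, 0.96, 7),
]

# (damaged row count k, accuracy without, accuracy with, improvement %)
RANDOM_ROWS = [
    (6, 0.89, 0.96, 8),
    (8, 0.82, 0.93, 13),
    (10, 0.73, 0.91, 25),
    (12, 0.66, 0.87, 32),
    (14, 0.60, 0.87, 45),
    (16, 0.55, 0.81, 47),
    (18, 0.47, 0.68, 45),
    (20, 0.40, 0.48, 20),
    (22, 0.39, 0.45, 15),
    (24, 0.33, 0.26, -21),
    (26, 0.20, 0.12, -40),
]

# (damaged pixel fraction p, accuracy without, accuracy with, improvement %)
RANDOM_PIXELS = [
    (0.30, 0.93, 0.93, 0),
    (0.40, 0.96, 0.96, 0),
    (0.50, 0.91, 0.95, 4),
    (0.60, 0.80, 0.94, 18),
    (0.70, 0.75, 0.93, 24),
    (0.80, 0.55, 0.80, 45),
    (0.90, 0.39, 0.46, 18),
    (0.92, 0.32, 0.37, 16),
    (0.94, 0.33, 0.34, 3),
    (0.96, 0.20, 0.23, 15),
]


def all_rows() -> list[tuple[str, float, float, int]]:
    """Every benchmark row as (label, acc_without, acc_with, improvement_pct)."""
    rows = [(f"custom_{k}", wo, wi, imp) for k, wo, wi, imp in CUSTOMIZED_ROWS]
    rows += [(f"rows={k}", wo, wi, imp) for k, wo, wi, imp in RANDOM_ROWS]
    rows += [(f"pixels={p}", wo, wi, imp) for p, wo, wi, imp in RANDOM_PIXELS]
    return rows
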