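"""Reference datasets.

`metha_micromotion()` returns the published per-specimen torsional relative
micromotions (mdeg/Nm) of twelve cadaveric femora implanted with a cementless
calcar-guided short stem under three anchorage conditions (n = 4 each):
insufficient press-fit (loose), surgeon-judged optimal seating (fit), and
over-press-fit to cortical fracture (fracture).  rm1 is the proximal and rm2
the distal relative micromotion.  These values serve as the benchmark for
the group-summary and rank-statistics routines and as the default moments of
the micromotion simulator.
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    ("loose", 1, 95.95, 187.83),
    ("loose", 2, 13.27, 27.16),
    ("loose", 3, 384.55, 270.02),
    ("loose", 4, 37.35, 13.74),
    ("fit", 1, 6.59, 12.32),
    ("fit", 2, 3.14, 5.65),
    ("fit", 3, 6.30, 2.21),
    ("fit", 4, 1.63, 2.19),
    ("fracture", 1, 1.25, 0.96),
    ("fracture", 2, 2.04, 4.32),
    ("fracture", 3, 1.08, 1.07),
    ("fracture", 4, 2.32, 4.53),
]


def metha_micromotion() -> pd.DataFrame:
    """Per-specimen relative micromotions, columns: condition, specimen,
    rm1_mdeg_per_nm, rm2_mdeg_per_nm."""
    return pd.DataFrame(_ROWS, columns=["condition", "specimen", "rm1_mdeg_per_nm", "rm2_mdeg_per_nm"])
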