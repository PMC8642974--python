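"""Published reference values for the maize x teosinte PEDS study system.

These small tables transcribe summary statistics reported for the field
evaluations of advanced maize x teosinte backcross populations
segregating for PEDS (single vs. paired spikelets): per-environment
phenotype totals, the per-environment estimates of the major QTL on
chromosome 3, and the epistatic-QTL effects of the BC4F2 test.  They
serve as worked-example inputs for the summary and bookkeeping
routines; the sequencing-level results of that study are not
reproducible from printed numbers and are not transcribed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Field evaluations of the BC3F2 populations: environment label,
#: number of plants scored, and number with PEDS = 0.
BC3F2_FIELD_TOTALS = pd.DataFrame(
    [
        {"environment": "14WJ", "total": 4320, "n_peds_zero": 4048},
        {"environment": "14EEDS", "total": 5022, "n_peds_zero": 4683},
        {"environment": "14JH", "total": 7990, "n_peds_zero": 7466},
        {"environment": "15JH", "total": 6720, "n_peds_zero": 6336},
    ]
)

#: The major chromosome-3 QTL as estimated in each of the three
#: linkage-mapping tests (two BC3F2 environments and one BC4F2).
MAJOR_QTL_PVE = pd.DataFrame(
    [
        {"environment": "14JH", "population": "BC3F2", "lod": 34.81,
         "pve": 38.05, "add": -0.18, "dom": -0.20},
        {"environment": "18WJ", "population": "BC3F2", "lod": 52.97,
         "pve": 33.92, "add": -0.34, "dom": -0.24},
        {"environment": "15WJ", "population": "BC4F2", "lod": 31.17,
         "pve": 33.91, "add": -0.14, "dom": -0.14},
    ]
)

#: Epistatic QTL pairs of the BC4F2 (15WJ) test: LOD, PVE and
#: additive-by-additive effect.
EPISTATIC_QTL_15WJ = pd.DataFrame(
    [
        {"pair": 1, "lod": 10.54, "pve": 3.87, "aa": 0.08},
        {"pair": 2, "lod": 10.30, "pve": 10.53, "aa": 0.10},
        {"pair": 3, "lod": 5.36, "pve": 7.54, "aa": -0.10},
        {"pair": 4, "lod": 7.74, "pve": 21.31, "aa": -0.01},
        {"pair": 5, "lod": 5.47, "pve": 4.32, "aa": 0.11},
    ]
)


def reconstruct_peds_vector(total: int, n_zero: int,
                            positive_value: float = 5.0) -> np.ndarray:
    """A synthetic PEDS vector with the given zero count.

    Plants with PEDS > 0 are assigned a nominal positive value; only
    statistics that depend on the zero/non-zero split (class counts and
    the total : PEDS>0 ratio) are meaningful on the result.
    """
    out = np.zeros(total)
    out[:total - n_zero] = positive_value
    return out
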