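"""Published validation numbers for the Cape Range buffel-grass survey.

The pipeline implemented here was originally validated on a UAV RGB
orthomosaic of Cape Range National Park (WA, Australia) that was never
deposited publicly. What the survey did publish is its 6×6 confusion
matrix over 85,657 held-out labelled pixels. That matrix is reproduced
below as an input fixture so the report arithmetic (class report, error
decomposition) can be exercised against known published output without
the imagery.

Row/column order is by class code: buffel, soil, bushes, shadow,
dry vegetation, spinifex; rows are labelled (true) classes.
"""

from __future__ import annotations

import numpy as np

from .metrics import ConfusionMatrix

#: Held-out test-set confusion matrix of the tuned classifier on the
#: Cape Range imagery (85,657 labelled pixels).
CAPE_RANGE_CONFUSION = ConfusionMatrix(
    np.array(
        [
            [25256, 17, 156, 0, 4, 362],
            [15, 25196, 1, 0, 1, 0],
            [632, 1, 3913, 2, 21, 81],
            [0, 1, 0, 7729, 0, 0],
            [8, 10, 6, 2, 5734, 159],
            [508, 2, 20, 0, 171, 15649],
        ],
        dtype=np.int64,
    )
)

#: Total pixel samples extracted from the ten labelled survey tiles,
#: before the 75/25 train/test split.
CAPE_RANGE_TOTAL_SAMPLES = 342_626

#: Dimensions (height implied second) and tiling of the survey orthomosaic.
CAPE_RANGE_ORTHOMOSAIC = (44_800, 17_200)
CAPE_RANGE_TILE_SIZE = 400
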