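"""Published per-participant result tables used as worked-example inputs.

These are printed values from the study report: the right-vs-left
investigation's best-IC percentage accuracies per frequency band, and the
corresponding ROI-activity indicator matrix.  They serve as inputs to the
aggregation operations, whose outputs are checked against the published
aggregates.
"""

import numpy as np
import pandas as pd

BANDS = ("delta-theta", "mu-beta", "low-gamma", "high-gamma")

#: Best-IC accuracy (%) per participant and band, right-vs-left
#: investigation.
RLI_ACCURACY = pd.DataFrame(
    np.array([
        [74.53, 90.00, 89.22, 90.00],
        [65.84, 81.36, 80.34, 70.54],
        [80.60, 91.88, 88.02, 89.32],
        [81.60, 85.32, 87.56, 85.13],
        [83.35, 91.04, 92.41, 88.26],
        [79.47, 94.44, 83.88, 84.06],
        [78.93, 99.74, 92.30, 94.16],
        [82.04, 87.79, 77.48, 80.18],
        [87.91, 99.44, 87.76, 91.75],
        [81.09, 87.25, 83.57, 78.17],
        [78.57, 78.66, 82.69, 78.38],
        [87.68, 91.65, 71.83, 93.64],
    ]),
    index=[f"P{i}" for i in range(1, 13)],
    columns=list(BANDS),
)

ROI_COLUMNS = ("r-M1-H", "l-M1-H", "r-PMv", "l-PMv", "r-PFC", "l-PFC", "SMA")

#: ROI-activity indicator matrix for the right-vs-left investigation
#: (activity above the 77% screen).
RLI_ROI_INDICATOR = pd.DataFrame(
    np.array([
        [0, 0, 0, 0, 1, 1, 0],
        [0, 1, 0, 0, 1, 0, 0],
        [0, 1, 0, 0, 1, 1, 0],
        [0, 1, 0, 0, 1, 1, 0],
        [0, 1, 1, 1, 1, 1, 0],
        [0, 1, 0, 1, 1, 1, 0],
        [0, 0, 0, 1, 1, 1, 0],
        [1, 1, 1, 1, 1, 1, 0],
        [1, 1, 1, 1, 1, 1, 1],
        [0, 1, 0, 1, 1, 1, 0],
        [0, 1, 0, 1, 1, 1, 1],
        [1, 1, 1, 1, 1, 1, 1],
    ], dtype=bool),
    index=[f"P{i}" for i in range(1, 13)],
    columns=list(ROI_COLUMNS),
)
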