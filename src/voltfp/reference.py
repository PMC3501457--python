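"""Reference results reported for the original nine-tissue rat study.

``REFERENCE_CONFUSION`` is the published pooled confusion matrix of the
level-5 wavelet decision-tree experiment (rows = predicted tissue,
columns = true tissue, 10-fold cross-validation).  It serves as a worked
example for the confusion-matrix metrics: the printed per-class precision
and recall percentages can be recomputed from the cell counts.  A few of
the published percentages are inconsistent with the printed counts
(predicted heart and brain precision, gonad recall); only the consistent
cells should be used as checks.
"""

import numpy as np

REFERENCE_TISSUE_ORDER = ("liver", "blood", "kidney", "brain", "eye",
                          "spleen", "heart", "muscle", "gonad")

REFERENCE_CONFUSION = np.array([
    # true: liver blood kidney brain eye spleen heart muscle gonad
    [40, 0,  0,  0,  0,  0,  0,  0,  0],   # pred. liver
    [0, 39,  1,  0,  0,  0,  0,  0,  0],   # pred. blood
    [0,  0, 37,  1,  0,  0,  0,  0,  0],   # pred. kidney
    [0,  0,  2, 34,  0,  0,  0,  0,  0],   # pred. brain
    [0,  0,  0,  1, 39,  0,  1,  0,  0],   # pred. eye
    [0,  0,  0,  0,  0, 38,  0,  0,  0],   # pred. spleen
    [0,  0,  0,  4,  1,  0, 37,  0,  0],   # pred. heart
    [0,  0,  0,  0,  0,  1,  0, 38,  0],   # pred. muscle
    [0,  0,  0,  0,  0,  0,  0,  0, 37],   # pred. gonad
], dtype=int)

#: printed percentages that agree with the cell counts, for checking
CONSISTENT_PRECISION = {"liver": 100.0, "blood": 97.50, "kidney": 97.37,
                        "eye": 95.12, "spleen": 100.0, "muscle": 97.44,
                        "gonad": 100.0}
CONSISTENT_RECALL = {"liver": 100.0, "blood": 100.0, "kidney": 92.50,
                     "brain": 85.00, "eye": 97.50, "spleen": 97.44,
                     "muscle": 100.0}
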