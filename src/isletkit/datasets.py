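"""Published validation counts for the mouse and monkey islet confocal
datasets the toolbox was originally scored on.

The raw image stacks are not distributed; what is reproducible from print is
the arithmetic of the validation layer, so the object counts are embedded
here as worked-example inputs: per-stack nuclei detection counts
(TP/FP/FN), the cell-type confusion matrices (rows = actual, columns =
predicted, order alpha/beta/delta/unlabeled) and the per-stack cell-type
composition counts.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "NUCLEI_DETECTION_COUNTS",
    "CONFUSION_MATRICES",
    "COMPOSITION_COUNTS",
]

#: dataset -> (true positives, false positives, false negatives)
NUCLEI_DETECTION_COUNTS: dict[str, tuple[int, int, int]] = {
    "Mouse1-a": (459, 2, 17),
    "Mouse1-b": (847, 1, 16),
    "Mouse1-c": (915, 2, 29),
    "Mouse2": (568, 5, 20),
    "Mouse3": (993, 2, 19),
    "Mouse4": (194, 3, 20),
    "Mouse5": (568, 5, 22),
    "Mouse6": (494, 5, 19),
    "TotalMouse": (5038, 25, 162),
    "Monkey1": (695, 12, 9),
    "Monkey2": (754, 16, 21),
    "Monkey3": (605, 27, 21),
    "Monkey4": (561, 5, 18),
    "Monkey5": (580, 15, 9),
    "Monkey6": (604, 6, 17),
    "TotalMonkey": (3799, 81, 95),
}

#: rows = actual, cols = predicted; class order alpha, beta, delta, unlabeled
CONFUSION_MATRICES: dict[str, np.ndarray] = {
    "mouse": np.array(
        [
            [490, 3, 4, 2],
            [0, 2146, 5, 16],
            [9, 3, 135, 2],
            [20, 44, 11, 2021],
        ]
    ),
    "monkey": np.array(
        [
            [332, 5, 2, 5],
            [9, 1119, 4, 19],
            [2, 5, 190, 3],
            [24, 27, 8, 2123],
        ]
    ),
}

#: dataset -> (alpha, beta, delta) cell counts (unlabeled excluded)
COMPOSITION_COUNTS: dict[str, tuple[int, int, int]] = {
    "Mouse1-a": (15, 165, 22),
    "Mouse1-b": (124, 261, 44),
    "Mouse1-c": (19, 269, 41),
    "Mouse2": (118, 398, 9),
    "Mouse3": (146, 384, 20),
    "Mouse4": (32, 138, 7),
    "Mouse5": (23, 358, 5),
    "Mouse6": (46, 222, 7),
    "TotalMouse": (523, 2195, 155),
    "Monkey1": (55, 309, 19),
    "Monkey2": (136, 170, 90),
    "Monkey3": (57, 126, 36),
    "Monkey4": (46, 128, 15),
    "Monkey5": (33, 172, 33),
    "Monkey6": (40, 251, 11),
    "TotalMonkey": (367, 1156, 204),
}
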