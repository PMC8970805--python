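"""Worked-example inputs for the reporting module.

A reference evaluation of a two-class (left/right hand) motor-imagery decoder
on a 140-trial balanced test set, repeated over five independent iterations,
plus a per-subject accuracy table from a nine-subject, five-run experiment.
These serve as fixed inputs for exercising the confusion-matrix metrics and
table-averaging machinery; the package recomputes every derived number from
them at run time.
"""

import numpy as np

#: Five iterations' confusion matrices on a 70/70 left-right test split;
#: rows = true (left, right), columns = predicted.
ITERATION_CONFUSIONS = [
    np.array([[67, 3], [2, 68]]),
    np.array([[67, 3], [2, 68]]),
    np.array([[69, 1], [2, 68]]),
    np.array([[68, 2], [5, 65]]),
    np.array([[67, 3], [4, 66]]),
]

#: Per-run (rows, 5) x per-subject (columns, 9) accuracies in percent.
SUBJECT_RUN_ACCURACIES = np.array([
    [87.0, 85.0, 88.0, 86.0, 84.0, 76.0, 83.0, 96.0, 83.0],
    [71.0, 83.0, 80.0, 94.0, 85.0, 79.0, 91.0, 83.0, 92.0],
    [84.0, 96.0, 94.0, 98.0, 88.0, 90.0, 85.0, 89.0, 87.0],
    [82.0, 91.0, 75.0, 89.0, 91.0, 92.0, 81.0, 88.0, 95.0],
    [82.0, 81.0, 86.0, 91.0, 81.0, 87.0, 95.0, 89.0, 81.0],
])

__all__ = ["ITERATION_CONFUSIONS", "SUBJECT_RUN_ACCURACIES"]
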