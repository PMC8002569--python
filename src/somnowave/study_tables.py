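"""Reference figures for the CAP sleep database experiments.

Published epoch distributions, per-trial cross-validation accuracies
and confusion matrices for the experiments this package reimplements.
They serve as *inputs* to the evaluation arithmetic (aggregation,
accuracy/kappa/F1 reconstruction) -- none of the package's own results
are read from here.

Stage order everywhere: (W, S1, S2, S3, S4, REM).
"""

from __future__ import annotations

#: Per-group per-stage epoch counts of the unbalanced database
#: (80 recordings at 512 Hz; 80,667 epochs in total).
UNBALANCED_COUNTS: dict[str, dict[str, int]] = {
    "healthy": {"W": 445, "S1": 280, "S2": 2172, "S3": 573, "S4": 1184, "REM": 1409},
    "insomnia": {"W": 3801, "S1": 223, "S2": 2456, "S3": 670, "S4": 415, "REM": 986},
    "bruxism": {"W": 44, "S1": 34, "S2": 144, "S3": 39, "S4": 99, "REM": 67},
    "narcolepsy": {"W": 1303, "S1": 301, "S2": 1708, "S3": 476, "S4": 568, "REM": 1258},
    "NFLE": {"W": 3155, "S1": 1098, "S2": 10630, "S3": 2987, "S4": 4108, "REM": 4905},
    "PLM": {"W": 1332, "S1": 266, "S2": 2748, "S3": 955, "S4": 956, "REM": 1317},
    "RBD": {"W": 5266, "S1": 1048, "S2": 7446, "S3": 2880, "S4": 2506, "REM": 3530},
    "SDB": {"W": 495, "S1": 269, "S2": 1324, "S3": 224, "S4": 352, "REM": 215},
}

#: Balanced per-class targets per group (see also balancing.STUDY_TARGETS).
BALANCED_TARGETS: dict[str, int] = {
    "healthy": 1000, "insomnia": 1400, "bruxism": 71, "narcolepsy": 935,
    "NFLE": 4480, "PLM": 1262, "RBD": 3779, "SDB": 480,
}

#: Healthy-group combined-channel per-trial CV accuracies (percent).
HEALTHY_COMBINED_TRIALS: tuple[float, ...] = (76.26, 77.66, 79.06, 79.66, 78.86)

#: Healthy-group unbalanced confusion matrix, row percentages.
HEALTHY_UNBALANCED_ROW_PERCENT: list[list[float]] = [
    [68.8, 15.7, 5.4, 0.9, 0.4, 8.8],
    [21.4, 42.5, 23.2, 0.0, 0.7, 12.1],
    [1.3, 2.3, 80.9, 6.0, 1.2, 8.4],
    [0.9, 0.2, 28.6, 56.9, 12.6, 0.9],
    [0.3, 0.1, 1.9, 5.7, 91.7, 0.2],
    [1.1, 1.8, 11.8, 0.9, 0.5, 84.0],
]

#: Insomnia-group balanced confusion matrix (1400 epochs per class),
#: row percentages.
INSOMNIA_BALANCED_ROW_PERCENT: list[list[float]] = [
    [92.1, 4.0, 2.7, 0.2, 0.3, 0.6],
    [0.0, 100.0, 0.0, 0.0, 0.0, 0.0],
    [5.6, 4.5, 74.1, 7.1, 0.7, 7.9],
    [0.3, 0.0, 1.1, 97.1, 1.4, 0.0],
    [0.0, 0.0, 0.0, 0.0, 100.0, 0.0],
    [1.1, 1.1, 3.9, 0.1, 0.1, 93.6],
]

INSOMNIA_BALANCED_ROW_TOTAL = 1400
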