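"""Published benchmark scores used as fixtures for metric identities.

Per-class precision/recall/IoU/F1 (percent) reported for an attention
U-net leukocyte-segmentation benchmark on the BCISC blood-smear dataset,
plus aggregate rows from its multi-dataset robustness comparison.  The
values serve as inputs to consistency checks: F1 must equal the harmonic
mean of the printed P and R, and the per-class IoU spread is recomputed
from the printed IoUs.
"""

#: per-class scores (percent) on the five leukocyte types
BCISC_CLASS_SCORES = {
    "basophil":   {"precision": 93.04, "recall": 88.57, "iou": 91.31, "f1": 90.75},
    "eosinophil": {"precision": 91.17, "recall": 91.15, "iou": 90.08, "f1": 91.16},
    "lymphocyte": {"precision": 92.71, "recall": 80.26, "iou": 88.94, "f1": 86.04},
    "monocyte":   {"precision": 86.32, "recall": 92.60, "iou": 89.24, "f1": 89.35},
    "neutrophil": {"precision": 92.46, "recall": 95.88, "iou": 92.07, "f1": 94.14},
}

#: aggregate rows (percent) from the multi-dataset comparison
DATASET_SCORES = {
    "dataset2": {"precision": 99.15, "recall": 98.79, "f1": 98.97},
    "dataset4": {"precision": 98.64, "recall": 98.01, "f1": 98.32},
}

#: reported per-class IoU spread (max - min, percentage points)
REPORTED_IOU_SPREAD = 3.13
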