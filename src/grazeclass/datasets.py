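"""Bundled reference tables.

The collar confusion matrix below is the published truth-by-prediction
table (percent of the dataset per cell) for a random-forest classifier of
sheep eating behaviour trained on 39 collar-IMU features; rows are the
observed behaviour, columns the predicted one. It is the exactly
reproducible surface for the metric derivations in
:mod:`grazeclass.metrics`: feeding it through ``confusion_to_metrics``
recovers the published per-class precision/recall/F-score/specificity
after integer-percent rounding, and an overall accuracy of 92 %.
"""

from __future__ import annotations

import numpy as np

from .metrics import DEFAULT_CLASSES, ConfusionMatrix

# rows: observed grazing, non-eating, ruminating; columns: predicted same order
_COLLAR_CONFUSION_PCT = [
    [30.06, 1.65, 0.53],
    [0.68, 39.16, 1.55],
    [0.42, 2.96, 22.98],
]

# ear-sensor analogue; its printed diagonal is internally inconsistent with
# the accompanying summary metrics, so it is shipped for orientation only
_EAR_CONFUSION_PCT = [
    [27.3, 2.3, 0.3],
    [2.6, 43.0, 2.1],
    [0.4, 3.3, 18.7],
]


def load_collar_confusion() -> ConfusionMatrix:
    """Published collar random-forest confusion matrix, percent units."""
    return ConfusionMatrix(np.array(_COLLAR_CONFUSION_PCT),
                           DEFAULT_CLASSES, unit="percent")


def load_ear_confusion() -> ConfusionMatrix:
    """Published ear random-forest confusion matrix, percent units."""
    return ConfusionMatrix(np.array(_EAR_CONFUSION_PCT),
                           DEFAULT_CLASSES, unit="percent")
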