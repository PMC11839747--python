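"""Per-label overlap and volume-agreement metrics between two segmentations.

Each muscle label is scored one-vs-rest over the full image domain:
Sørensen–Dice, Jaccard, conformity coefficient, true positive rate,
true negative rate, positive predictive value and volume ratio. The
conformity coefficient 1 - (FP+FN)/TP (equivalently (3*Dice-2)/Dice) is
undefined when TP = 0 and reported missing. The TNR is computed over the
whole field of view, which is background-dominated, so values near 1 are
expected by construction and should not be over-interpreted.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core_io import LabelMap

logger = logging.getLogger(__name__)

METRIC_NAMES = ("dice", "jaccard", "conformity", "tpr", "tnr", "ppv",
                "volume_ratio")


def confusion_counts(candidate: LabelMap, reference: LabelMap, label: int
                     ) -> tuple[int, int, int, int]:
    """One-vs-rest (tp, fp, fn, tn) voxel counts for one label."""
    candidate.geometry.require_match(reference.geometry,
                                     what="candidate and reference maps")
    c = candidate.labels == label
    r = reference.labels == label
    tp = int(np.count_nonzero(c & r))
    fp = int(np.count_nonzero(c & ~r))
    fn = int(np.count_nonzero(~c & r))
    tn = int(c.size - tp - fp - fn)
    if tp + fp + fn == 0:
        logger.warning("label %d absent from both masks", label)
    return tp, fp, fn, tn


def metrics_from_counts(tp: int, fp: int, fn: int, tn: int) -> dict[str, float]:
    """The seven segmentation metrics from one confusion quadruple.

    0/0 cases are returned as NaN (missing), never raised.
    """
    def ratio(num, den):
        return num / den if den > 0 else np.nan

    dice = ratio(2 * tp, 2 * tp + fp + fn)
    return {
        "dice": dice,
        "jaccard": ratio(tp, tp + fp + fn),
        "conformity": (3 * dice - 2) / dice if tp > 0 else np.nan,
        "tpr": ratio(tp, tp + fn),
        "tnr": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "volume_ratio": ratio(tp + fp, tp + fn),
    }


def score_segmentation(candidate: LabelMap, reference: LabelMap,
                       labels: list[int] | None = None) -> pd.DataFrame:
    """Score every label (default: union of labels present in either map).

    Returns one row per label with the confusion counts and all seven
    metrics; 0/0-undefined metrics are NaN with a logged warning.
    """
    candidate.geometry.require_match(reference.geometry,
                                     what="candidate and reference maps")
    if labels is None:
        labels = sorted(set(candidate.present_labels) | set(reference.present_labels))
    rows = []
    for lab in labels:
        tp, fp, fn, tn = confusion_counts(candidate, reference, lab)
        m = metrics_from_counts(tp, fp, fn, tn)
        if any(np.isnan(v) for v in m.values()):
            logger.warning("label %d: some metrics undefined (0/0), reported missing", lab)
        name, side = reference.label_table.get(
            lab, candidate.label_table.get(lab, ("unknown", "unknown")))
        rows.append({"label": lab, "muscle": name, "side": side,
                     "tp": tp, "fp": fp, "fn": fn, "tn": tn, **m})
    return pd.DataFrame(rows)


def mean_scores(scores: pd.DataFrame) -> pd.Series:
    """Unweighted mean of each metric across labels (NaNs excluded)."""
    return scores[list(METRIC_NAMES)].mean()
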