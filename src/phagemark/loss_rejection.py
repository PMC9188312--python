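"""Per-sequence loss scoring and cutoff-based open-set rejection.

The classifier's softmax assigns every input to some category, including
inputs from protein families it never saw.  The cross-entropy loss of a
prediction against its own predicted class, ``L = -ln p_argmax``, acts as a
confidence score: sequences genuinely from a trained category score tiny
losses, while out-of-set sequences that happen to win a target category's
argmax score large ones.  Calibrating a per-category threshold on the log10
losses of known true positives, and re-assigning any target-category
prediction above that threshold to "others", trades a little recall for a
large precision gain on imbalanced inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from phagemark.sequence_io import OTHERS

PROB_CLAMP = 1e-12  # keeps -ln p finite for saturated softmax outputs
LOG10_FLOOR = 1e-12  # loss floor before taking log10


@dataclass(frozen=True)
class PerSequenceLoss:
    """Cross-entropy of one sequence against its scoring class."""

    id: str
    predicted_category: str
    loss: float  # natural-log cross-entropy, >= 0
    log10_loss: float  # log10(loss), floored so it is always finite


@dataclass
class LossCutoffs:
    """Per-target-category thresholds on log10 loss.

    Predictions of category c with ``log10_loss <= cutoffs[c]`` are
    accepted; larger losses are re-assigned to "others".  Cutoffs exist
    only for the categories of interest, never for "others" itself.
    """

    cutoffs: dict[str, float]
    calibration_quantile: float = 0.99
    provenance: str = ""

    def __post_init__(self) -> None:
        if OTHERS in self.cutoffs:
            raise ValueError('"others" cannot carry a cutoff')
        bad = [c for c, v in self.cutoffs.items() if not np.isfinite(v)]
        if bad:
            raise ValueError(f"non-finite cutoffs for: {bad}")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# quantile={self.calibration_quantile}\n")
            if self.provenance:
                fh.write(f"# provenance={self.provenance}\n")
            for cat, val in self.cutoffs.items():
                fh.write(f"{cat}={val:.6f}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "LossCutoffs":
        quantile, provenance, cutoffs = 0.99, "", {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("=")
                    if key == "quantile":
                        quantile = float(val)
                    elif key == "provenance":
                        provenance = val
                    continue
                cat, _, val = line.partition("=")
                cutoffs[cat] = float(val)
        return cls(cutoffs=cutoffs, calibration_quantile=quantile, provenance=provenance)


def per_sequence_loss(
    p: Sequence[float], class_index: int, id: str = "", category_order: Sequence[str] | None = None
) -> PerSequenceLoss:
    """Cross-entropy of probability vector ``p`` against ``class_index``.

    With a one-hot truth vector the cross-entropy sum collapses to
    ``-ln p_k`` for the single scoring class k.  The probability is clamped
    to [1e-12, 1-1e-12] before the log and the loss floored at 1e-12
    before log10, so both scores are always finite and orderable.
    """
    p = np.asarray(p, dtype=np.float64)
    if not (0 <= class_index < len(p)):
        raise IndexError(f"class_index {class_index} out of range for K={len(p)}")
    pk = float(np.clip(p[class_index], PROB_CLAMP, 1.0 - PROB_CLAMP))
    loss = -np.log(pk)
    log10_loss = float(np.log10(max(loss, LOG10_FLOOR)))
    name = category_order[class_index] if category_order is not None else str(class_index)
    return PerSequenceLoss(id=id, predicted_category=name,
                           loss=float(loss), log10_loss=log10_loss)


def score_probabilities(
    probs: np.ndarray, ids: Sequence[str], category_order: Sequence[str]
) -> list[PerSequenceLoss]:
    """Score each row of a probability matrix against its own argmax class."""
    probs = np.asarray(probs, dtype=np.float64)
    k = probs.argmax(axis=1)
    pk = np.clip(probs[np.arange(len(k)), k], PROB_CLAMP, 1.0 - PROB_CLAMP)
    loss = -np.log(pk)
    log10_loss = np.log10(np.maximum(loss, LOG10_FLOOR))
    return [
        PerSequenceLoss(id=str(ids[i]), predicted_category=category_order[k[i]],
                        loss=float(loss[i]), log10_loss=float(log10_loss[i]))
        for i in range(len(k))
    ]


def score_predictions(model, X: np.ndarray, ids: Sequence[str]) -> list[PerSequenceLoss]:
    """Predict a batch and score every sequence against its predicted class."""
    from phagemark.cnn_classifier import predict_proba

    probs = predict_proba(model, X)
    return score_probabilities(probs, ids, model.category_order)


def calibrate_cutoffs(
    scored: Sequence[PerSequenceLoss],
    truth: Sequence[str],
    quantile: float = 0.99,
    target_categories: Sequence[str] | None = None,
    rule: str = "quantile",
) -> LossCutoffs:
    """Choose per-category cutoffs from true-positive loss distributions.

    For each target category c the calibration set's true positives
    (predicted c and truly c) contribute their log10 losses; the cutoff is
    the smallest order statistic whose empirical CDF reaches ``quantile``,
    so at least that fraction of calibration TP satisfy
    ``log10_loss <= cutoff`` by construction.  ``rule="whisker"`` instead
    uses the upper boxplot whisker, min(max, Q3 + 1.5 IQR).
    """
    if not (0.0 < quantile <= 1.0):
        raise ValueError(f"quantile must be in (0, 1], got {quantile}")
    if len(scored) != len(truth):
        raise ValueError("scored and truth differ in length")
    if target_categories is None:
        target_categories = sorted(
            ({s.predicted_category for s in scored} | set(truth)) - {OTHERS}
        )
    cutoffs: dict[str, float] = {}
    for cat in target_categories:
        if cat == OTHERS:
            continue
        tp = np.array(
            [s.log10_loss for s, t in zip(scored, truth)
             if s.predicted_category == cat and t == cat]
        )
        if tp.size == 0:
            raise ValueError(f"no true positives for category {cat!r}; cannot calibrate")
        if rule == "quantile":
            cutoffs[cat] = float(np.quantile(tp, quantile, method="inverted_cdf"))
        elif rule == "whisker":
            q1, q3 = np.quantile(tp, [0.25, 0.75])
            cutoffs[cat] = float(min(tp.max(), q3 + 1.5 * (q3 - q1)))
        else:
            raise ValueError(f"unknown rule {rule!r}")
    return LossCutoffs(
        cutoffs=cutoffs,
        calibration_quantile=quantile,
        provenance=f"{len(scored)} scored sequences, rule={rule}",
    )


def apply_cutoffs(
    scored: Sequence[PerSequenceLoss], cutoffs: LossCutoffs
) -> list[dict]:
    """Re-assign over-threshold target predictions to "others".

    Returns one row per sequence: id, predicted_category, log10_loss,
    accepted (1 if the raw prediction stands), final_category.  "others"
    predictions pass through untouched; the boundary is inclusive
    (log10_loss equal to the cutoff is accepted).
    """
    rows = []
    for s in scored:
        if s.predicted_category == OTHERS:
            accepted, final = 1, OTHERS
        else:
            if s.predicted_category not in cutoffs.cutoffs:
                raise KeyError(
                    f"no cutoff for predicted category {s.predicted_category!r}"
                )
            ok = s.log10_loss <= cutoffs.cutoffs[s.predicted_category]
            accepted = int(ok)
            final = s.predicted_category if ok else OTHERS
        rows.append(
            dict(id=s.id, predicted_category=s.predicted_category,
                 log10_loss=s.log10_loss, accepted=accepted, final_category=final)
        )
    return rows


def loss_distribution_summary(
    scored: Sequence[PerSequenceLoss], truth: Sequence[str]
) -> pd.DataFrame:
    """Per-category TP/FP five-number summaries of log10 losses.

    One row per (category, TP/FP) with min, Q1, median, Q3, the upper
    whisker (largest value <= Q3 + 1.5 IQR) and max; empty groups yield NA
    rows with count 0.
    """
    if len(scored) != len(truth):
        raise ValueError("scored and truth differ in length")
    cats = sorted({s.predicted_category for s in scored} - {OTHERS})
    rows = []
    for cat in cats:
        for kind in ("TP", "FP"):
            vals = np.array(
                [s.log10_loss for s, t in zip(scored, truth)
                 if s.predicted_category == cat and (t == cat) == (kind == "TP")]
            )
            if vals.size == 0:
                rows.append(dict(category=cat, kind=kind, count=0, min=np.nan,
                                 q1=np.nan, median=np.nan, q3=np.nan,
                                 whisker=np.nan, max=np.nan))
                continue
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
            upper = vals[vals <= q3 + 1.5 * (q3 - q1)]
            rows.append(dict(category=cat, kind=kind, count=int(vals.size),
                             min=float(vals.min()), q1=float(q1), median=float(med),
                             q3=float(q3), whisker=float(upper.max()),
                             max=float(vals.max())))
    return pd.DataFrame(rows)
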