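"""Confusion counts, per-category metrics, and the class-imbalance sweep.

Metrics are one-vs-rest per category: Accuracy (TP+TN)/(TP+FP+TN+FN),
Precision TP/(TP+FP), Recall TP/(TP+FN), F1 the harmonic mean of the two.
A zero denominator yields a flagged 0 so tables remain total and
machine-readable.  The sweep measures how Precision erodes as the "others"
pool grows around a fixed positive set — the regime that motivates the
loss-cutoff rejection — using *nested* negative subsets so that Recall is
exactly constant across pool sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from phagemark.sequence_io import OTHERS
from phagemark.loss_rejection import LossCutoffs, apply_cutoffs, score_predictions

METRIC_COLS = ["accuracy", "precision", "recall", "f1"]


@dataclass(frozen=True)
class ConfusionCounts:
    category: str
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class MetricsReport:
    """Per-category metric rows plus macro averages over target categories."""

    table: pd.DataFrame
    multiclass_accuracy: float
    fold: int | None = None

    def row(self, category: str) -> pd.Series:
        return self.table.set_index("category").loc[category]

    @property
    def macro(self) -> pd.Series:
        return self.row("macro")

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def confusion_counts(
    truth: Sequence[str], predictions: Sequence[str], category: str
) -> ConfusionCounts:
    """One-vs-rest counts for one category over aligned label lists."""
    if len(truth) != len(predictions):
        raise ValueError(
            f"truth ({len(truth)}) and predictions ({len(predictions)}) differ in length"
        )
    t = np.asarray(truth) == category
    p = np.asarray(predictions) == category
    return ConfusionCounts(
        category=category,
        TP=int((t & p).sum()),
        FP=int((~t & p).sum()),
        TN=int((~t & ~p).sum()),
        FN=int((t & ~p).sum()),
    )


def compute_metrics(counts: ConfusionCounts) -> dict:
    """The four one-vs-rest metrics from raw counts.

    Undefined ratios (empty denominator) are reported as 0 and named in
    the ``flags`` field.
    """
    flags = []
    if counts.TP + counts.FP > 0:
        precision = counts.TP / (counts.TP + counts.FP)
    else:
        precision = 0.0
        flags.append("precision_undefined")
    if counts.TP + counts.FN > 0:
        recall = counts.TP / (counts.TP + counts.FN)
    else:
        recall = 0.0
        flags.append("recall_undefined")
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
        flags.append("f1_undefined")
    accuracy = (counts.TP + counts.TN) / counts.total if counts.total else 0.0
    return dict(
        category=counts.category, TP=counts.TP, FP=counts.FP, TN=counts.TN,
        FN=counts.FN, accuracy=accuracy, precision=precision, recall=recall,
        f1=f1, flags=";".join(flags),
    )


def evaluate(
    truth: Sequence[str], predictions: Sequence[str], category_order: Sequence[str]
) -> MetricsReport:
    """Full report: one row per category plus an unweighted macro row.

    The macro row averages over the categories of interest only (i.e.
    excluding "others"), since those are what the classifier exists to
    find.  Plain multiclass accuracy is reported separately.
    """
    rows = [compute_metrics(confusion_counts(truth, predictions, c))
            for c in category_order]
    df = pd.DataFrame(rows)
    targets = df[df["category"] != OTHERS]
    macro = {"category": "macro", "TP": targets["TP"].sum(), "FP": targets["FP"].sum(),
             "TN": targets["TN"].sum(), "FN": targets["FN"].sum(), "flags": ""}
    macro.update({m: targets[m].mean() for m in METRIC_COLS})
    df = pd.concat([df, pd.DataFrame([macro])], ignore_index=True)
    mc_acc = float((np.asarray(truth) == np.asarray(predictions)).mean()) if len(truth) else 0.0
    return MetricsReport(table=df, multiclass_accuracy=mc_acc)


def mean_reports(reports: Sequence[MetricsReport]) -> MetricsReport:
    """Element-wise mean of metric columns across folds (counts summed)."""
    cat = reports[0].table["category"]
    stacked = pd.concat([r.table for r in reports])
    grouped = stacked.groupby("category", sort=False)
    out = grouped[METRIC_COLS].mean()
    out[["TP", "FP", "TN", "FN"]] = grouped[["TP", "FP", "TN", "FN"]].sum()
    out = out.reindex(cat).reset_index()
    out["flags"] = ""
    return MetricsReport(
        table=out,
        multiclass_accuracy=float(np.mean([r.multiclass_accuracy for r in reports])),
    )


def imbalance_sweep(
    model,
    X_pos: np.ndarray,
    truth_pos: Sequence[str],
    ids_pos: Sequence[str],
    X_pool: np.ndarray,
    sizes: Sequence[int],
    cutoffs: LossCutoffs | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Precision/Recall/F1 versus "others"-pool size, with and without cutoffs.

    The positive set is fixed; for each requested size a seeded random
    subset of the negative pool is added, and the subsets are nested (each
    larger one contains every smaller one).  Nesting makes two properties
    exact rather than statistical: Recall over the positives is identical
    at every size, and raw false positives can only accumulate, so raw
    Precision is non-increasing in pool size.
    """
    sizes = sorted(sizes)
    if sizes and sizes[-1] > X_pool.shape[0]:
        raise ValueError(
            f"requested pool size {sizes[-1]} exceeds pool of {X_pool.shape[0]}"
        )
    order = np.random.default_rng(seed).permutation(X_pool.shape[0])

    scored_pos = score_predictions(model, X_pos, ids_pos)
    scored_pool_all = score_predictions(
        model, X_pool[order[: sizes[-1]]], [f"pool_{i}" for i in order[: sizes[-1]]]
    )

    categories = [c for c in model.category_order if c != OTHERS]
    rows = []
    for size in sizes:
        scored = scored_pos + scored_pool_all[:size]
        truth = list(truth_pos) + [OTHERS] * size
        raw_final = [s.predicted_category for s in scored]
        modes = {"raw": raw_final}
        if cutoffs is not None:
            modes["cutoff"] = [r["final_category"] for r in apply_cutoffs(scored, cutoffs)]
        for mode, finals in modes.items():
            rep = evaluate(truth, finals, model.category_order)
            for cat in categories + ["macro"]:
                r = rep.row(cat)
                rows.append(dict(pool_size=size, category=cat, mode=mode,
                                 TP=int(r["TP"]), FP=int(r["FP"]),
                                 precision=float(r["precision"]),
                                 recall=float(r["recall"]), f1=float(r["f1"])))
    return pd.DataFrame(rows)
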