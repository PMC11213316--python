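"""Scoring called regions against ground truth: EO/AO confusion and metrics.

Two overlap criteria grade a call against the true-DMR set:

* equal overlap (EO) — the call's chromosome, start and end must match a
  true region exactly (integer equality of both endpoints);
* any overlap (AO) — the call's closed interval must share at least one
  base pair with a true region.

TP counts the true regions detected under the criterion (so TP + FN always
equals the number of true regions, matching the fixed margins of a
region-level confusion table); FP counts the calls that detect no true
region; TN counts the null candidate regions never matched (EO) or never
intersected (AO) by any call.  From the confusion counts: precision =
TP/(TP+FP), recall = TP/(TP+FN), F1 their harmonic mean, and the
region-level type-I error = FP / number of null regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .array_model import InputError

logger = logging.getLogger("nkdmr")

CRITERIA = ("EO", "AO")


@dataclass
class RegionConfusion:
    criterion: str
    TP: int
    FP: int
    FN: int
    TN: int
    n_true: int
    n_null: int


@dataclass
class MetricSet:
    precision: float | None
    recall: float | None
    f1: float | None
    type1: float | None


def classify_calls(called: pd.DataFrame, truth: pd.DataFrame,
                   criterion: str) -> RegionConfusion:
    """Confusion counts for one set of calls against labeled candidate regions.

    ``called`` needs columns ``chrom, start, end``; ``truth`` is the
    candidate-region table with a ``label`` column where anything other
    than "null" marks a true DMR.  A single call overlapping several true
    regions credits each of them as detected.
    """
    if criterion not in CRITERIA:
        raise InputError(f"criterion must be one of {CRITERIA}, got {criterion!r}")
    for frame, name in ((called, "called"), (truth, "truth")):
        for col in ("chrom", "start", "end"):
            if col not in frame.columns:
                raise InputError(f"{name} table missing column {col!r}")

    true_regions = truth.loc[truth["label"] != "null"]
    null_regions = truth.loc[truth["label"] == "null"]
    n_true, n_null = len(true_regions), len(null_regions)

    if len(called) == 0:
        return RegionConfusion(criterion, 0, 0, n_true, n_null, n_true, n_null)

    if criterion == "EO":
        true_keys = set(zip(true_regions["chrom"], true_regions["start"],
                            true_regions["end"]))
        null_keys = set(zip(null_regions["chrom"], null_regions["start"],
                            null_regions["end"]))
        call_keys = list(zip(called["chrom"], called["start"], called["end"]))
        detected_true = {k for k in call_keys if k in true_keys}
        fp = sum(1 for k in call_keys if k not in true_keys)
        touched_null = {k for k in call_keys if k in null_keys}
        tp = len(detected_true)
        tn = n_null - len(touched_null)
    else:  # AO: closed-interval intersection, >= 1 shared bp
        trees: dict[str, IntervalTree] = {}
        for which, frame in (("true", true_regions), ("null", null_regions)):
            for idx, row in frame.iterrows():
                trees.setdefault(row["chrom"], IntervalTree()).addi(
                    int(row["start"]), int(row["end"]) + 1, (which, idx))
        detected_true: set = set()
        touched_null: set = set()
        fp = 0
        for _, row in called.iterrows():
            tree = trees.get(row["chrom"])
            hits = tree.overlap(int(row["start"]), int(row["end"]) + 1) if tree else set()
            hit_true = {iv.data[1] for iv in hits if iv.data[0] == "true"}
            touched_null |= {iv.data[1] for iv in hits if iv.data[0] == "null"}
            if hit_true:
                detected_true |= hit_true
            else:
                fp += 1
        tp = len(detected_true)
        tn = n_null - len(touched_null)

    fn = n_true - tp
    return RegionConfusion(criterion, tp, fp, fn, tn, n_true, n_null)


def compute_metrics(conf: RegionConfusion) -> MetricSet:
    """Precision, recall, F1 and region-level type-I error from counts.

    Undefined ratios (zero denominators) are reported as ``None`` rather
    than 0 so that replicate aggregation can exclude them explicitly.
    """
    precision = conf.TP / (conf.TP + conf.FP) if (conf.TP + conf.FP) > 0 else None
    recall = conf.TP / (conf.TP + conf.FN) if (conf.TP + conf.FN) > 0 else None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2.0 * precision * recall / (precision + recall)
    elif precision is not None and recall is not None:
        f1 = 0.0
    else:
        f1 = None
    type1 = conf.FP / conf.n_null if conf.n_null > 0 else None
    return MetricSet(precision=precision, recall=recall, f1=f1, type1=type1)


def aggregate_replicates(per_replicate: pd.DataFrame,
                         metrics: tuple[str, ...] = ("precision", "recall",
                                                     "f1", "type1")) -> pd.DataFrame:
    """Per-metric mean and five-number summary across replicates.

    ``per_replicate`` is the long-format frame from ``run_replicates``.
    Replicates where a metric is undefined (None/NaN) are excluded from
    that metric's summary with a logged count.  Grouped by (mode,
    criterion) when those columns are present.
    """
    if len(per_replicate) == 0:
        raise ValueError("need at least one replicate")
    group_cols = [c for c in ("mode", "criterion") if c in per_replicate.columns]
    rows = []
    grouped = per_replicate.groupby(group_cols) if group_cols else [((), per_replicate)]
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        for metric in metrics:
            vals = pd.to_numeric(sub[metric], errors="coerce").dropna()
            n_missing = len(sub) - len(vals)
            if n_missing:
                logger.info("%s: %d replicates with undefined %s excluded",
                            key, n_missing, metric)
            if len(vals) == 0:
                continue
            q = np.percentile(vals, [0, 25, 50, 75, 100])
            rows.append(dict(zip(group_cols, key)) | {
                "metric": metric, "n": len(vals), "mean": vals.mean(),
                "min": q[0], "q1": q[1], "median": q[2], "q3": q[3], "max": q[4],
            })
    return pd.DataFrame(rows)
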