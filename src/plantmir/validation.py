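"""Similarity-aware leave-one-out validation and taxon-exclusion tests.

Leave-one-out here means: for each control, train on every control that is
NOT highly similar to it (the held-out case always excludes itself), then
test the trained model on the held-out case.  Tallied truth/prediction
pairs give sensitivity = 100*TP/(TP+FN) and specificity = 100*TN/(TN+FP).

Group exclusion asks the cross-species question: hold out every control of
one taxonomic group, train on the rest, and measure how well the held-out
group's miRNAs are recognized.  Negatives are held out alongside their
group to prevent leakage through shared source sequence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Callable, Mapping

import numpy as np

from .attributes import ControlDataset, LABEL_MIRNA, LABEL_NOT_MIRNA
from .classifier import (
    BoostedModel,
    CostMatrix,
    TreeParams,
    boost,
    build_sort_cache,
    dataset_to_matrix,
    predict_matrix,
)
from .errors import DegenerateTrainingError
from .seqio import MISSING

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_metrics(counts: ConfusionCounts):
    """(sensitivity %, specificity %); a 0/0 denominator yields the missing
    marker rather than an exception."""
    sens = (
        100.0 * counts.tp / (counts.tp + counts.fn)
        if counts.tp + counts.fn > 0
        else MISSING
    )
    spec = (
        100.0 * counts.tn / (counts.tn + counts.fp)
        if counts.tn + counts.fp > 0
        else MISSING
    )
    return sens, spec


def percent_correct(error_count: int, total: int) -> float:
    """Share of a held-out group classified correctly, as printed in the
    group-exclusion report tables."""
    if total <= 0:
        raise ValueError("empty group")
    return 100.0 * (total - error_count) / total


@dataclass
class ValidationReport:
    counts: ConfusionCounts
    sensitivity: float | None
    specificity: float | None
    per_group: dict = field(default_factory=dict)
    mode: str = ""
    n_training_runs: int = 0
    config: dict = field(default_factory=dict)
    folds: list | None = None  # optional (test_ids, train_ids) audit trail

    def to_json(self, path) -> None:
        doc = {
            "counts": asdict(self.counts),
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "per_group": self.per_group,
            "mode": self.mode,
            "n_training_runs": self.n_training_runs,
            "config": self.config,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, sort_keys=True, indent=1)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        """Group table: group, error count, total, % correct, % excluded."""
        with open(path, "w") as fh:
            fh.write(
                "group\terror_count\ttotal_count\tpct_correct\tpct_of_set_excluded\n"
            )
            for g in sorted(self.per_group):
                row = self.per_group[g]
                fh.write(
                    f"{g}\t{row['error_count']}\t{row['total']}\t"
                    f"{row['pct_correct']:.2f}\t{row['pct_excluded']:.2f}\n"
                )


def loocv(
    dataset: ControlDataset,
    exclusion: Mapping[str, set[str]],
    trials: int = 10,
    cost: CostMatrix = CostMatrix(),
    params: TreeParams = TreeParams(),
    seed: int = 0,
    grouped: bool | None = None,
    collect_folds: bool = False,
    trainer: Callable | None = None,
) -> ValidationReport:
    """Similarity-aware leave-one-out cross-validation.

    For each case i the training set is every case whose id is not in
    ``exclusion[i]`` (exclusion sets are reflexive, so i itself is always
    held out).  ``grouped`` trains once per block of cases with identical
    exclusion sets -- fold hygiene is unchanged, only redundant retraining
    is skipped; it is the default above 200 cases and is recorded in the
    report.  ``trainer`` may override model construction (testing hook):
    it receives (X_train, y_train) and returns an object usable by
    :func:`predict_matrix`.
    """
    vectors = dataset.vectors
    X, y, ids = dataset_to_matrix(vectors)
    n = len(vectors)
    if grouped is None:
        grouped = n > 200
    id_to_pos = {vid: i for i, vid in enumerate(ids)}
    if len(id_to_pos) != n:
        raise ValueError("duplicate vector ids")
    for vid in ids:
        if vid not in exclusion:
            raise ValueError(f"id {vid} missing from the exclusion index")

    blocks: dict[frozenset, list[int]] = {}
    for i, vid in enumerate(ids):
        key = frozenset(exclusion[vid]) if grouped else frozenset({i})
        blocks.setdefault(key, []).append(i)

    tp = fp = tn = fn = 0
    folds = [] if collect_folds else None
    runs = 0
    sort_cache = build_sort_cache(X)
    for key, members in blocks.items():
        excluded = exclusion[ids[members[0]]] if grouped else {
            e for m in members for e in exclusion[ids[m]]
        }
        mask = np.array([vid not in excluded for vid in ids], dtype=bool)
        ytr = y[mask]
        if ytr.size == 0 or ytr.min() == ytr.max():
            raise DegenerateTrainingError("training fold lacks both classes")
        if trainer is not None:
            model = trainer(X[mask], ytr)
        else:
            model = boost(
                X, y, trials, cost, params, seed, mask=mask, sort_cache=sort_cache
            )
        runs += 1
        labels, _ = predict_matrix(model, X[members])
        for m, pred in zip(members, labels):
            if y[m] == 1:
                tp += int(pred == 1)
                fn += int(pred == 0)
            else:
                tn += int(pred == 0)
                fp += int(pred == 1)
        if folds is not None:
            folds.append(
                ([ids[m] for m in members], [ids[j] for j in np.nonzero(mask)[0]])
            )

    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    sens, spec = confusion_metrics(counts)
    return ValidationReport(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        mode="grouped" if grouped else "full",
        n_training_runs=runs,
        config={"trials": trials, "cost": [cost.fp_cost, cost.fn_cost], "seed": seed},
        folds=folds,
    )


def group_exclusion_eval(
    dataset: ControlDataset,
    grouping: Mapping[str, str] | None = None,
    trials: int = 10,
    cost: CostMatrix = CostMatrix(),
    params: TreeParams = TreeParams(),
    seed: int = 0,
) -> ValidationReport:
    """Systematic taxon-exclusion: hold out each group, train on the rest.

    ``grouping`` maps vector id -> group; by default each vector's own
    ``taxon_group`` field is used.  Held-out positives are tallied per
    group (error count, total, % correctly classified, % of the full set
    excluded); held-out negatives contribute to the specificity side.
    """
    vectors = dataset.vectors
    X, y, ids = dataset_to_matrix(vectors)
    if grouping is None:
        grouping = {v.id: v.taxon_group for v in vectors}
    groups = sorted({grouping[v.id] for v in vectors if v.label == LABEL_MIRNA})
    if len(groups) < 2:
        raise ValueError("need at least 2 groups among positives")

    n = len(vectors)
    total_pos = int((y == 1).sum())
    tp = fp = tn = fn = 0
    per_group: dict[str, dict] = {}
    for g in groups:
        test_idx = np.array(
            [i for i in range(n) if grouping[ids[i]] == g], dtype=np.intp
        )
        train_idx = np.array(
            [i for i in range(n) if grouping[ids[i]] != g], dtype=np.intp
        )
        ytr = y[train_idx]
        if train_idx.size == 0 or ytr.min() == ytr.max():
            raise DegenerateTrainingError(f"excluding {g} leaves one class only")
        model = boost(X[train_idx], ytr, trials, cost, params, seed)
        labels, _ = predict_matrix(model, X[test_idx])
        g_pos = int((y[test_idx] == 1).sum())
        g_err = 0
        for i, pred in zip(test_idx, labels):
            if y[i] == 1:
                tp += int(pred == 1)
                fn += int(pred == 0)
                g_err += int(pred == 0)
            else:
                tn += int(pred == 0)
                fp += int(pred == 1)
        per_group[g] = {
            "error_count": g_err,
            "total": g_pos,
            "pct_correct": percent_correct(g_err, g_pos) if g_pos else MISSING,
            "pct_excluded": 100.0 * g_pos / total_pos if total_pos else MISSING,
        }
    counts = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
    sens, spec = confusion_metrics(counts)
    return ValidationReport(
        counts=counts,
        sensitivity=sens,
        specificity=spec,
        per_group=per_group,
        mode="group_exclusion",
        n_training_runs=len(groups),
        config={"trials": trials, "cost": [cost.fp_cost, cost.fn_cost], "seed": seed},
    )
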