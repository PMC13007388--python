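"""Evaluation metrics and paired statistics for tract parcellation.

Accuracy is the proportion of correctly classified streamlines (outlier
class included). Per-tract precision/recall/F1 are one-vs-rest at the
streamline level; the macro-F1 is the unweighted mean of per-tract F1
over the anatomical tracts, always excluding the outlier class and any
explicitly excluded tracts (e.g. cerebellar tracts with a reduced field
of view, or surgically disconnected commissural tracts). False accept is
the fraction of true-outlier streamlines predicted as any tract; false
reject is the fraction of true-tract streamlines predicted as outlier.
Model pairs are compared per tract with two-sided Wilcoxon signed-rank
tests, Bonferroni-corrected across all tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_fscore_support

__all__ = [
    "EvalReport",
    "accuracy",
    "per_tract_prf",
    "macro_f1",
    "false_accept_reject",
    "paired_compare",
    "evaluate_predictions",
]


def _check_pair(y_true, y_pred):
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"label vectors differ in length: {y_true.shape} vs {y_pred.shape}"
        )
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    return y_true, y_pred


def accuracy(y_true, y_pred) -> float:
    """Fraction of streamlines whose predicted label exactly matches the truth."""
    y_true, y_pred = _check_pair(y_true, y_pred)
    return float(np.mean(y_true == y_pred))


def per_tract_prf(y_true, y_pred, tract_ids: Optional[Sequence[int]] = None
                  ) -> pd.DataFrame:
    """One-vs-rest precision, recall, F1, and support per tract id.

    F1 is 0 when precision + recall = 0 (and a metric is 0 when its
    denominator is 0), so tracts absent from both truth and prediction
    score P = R = F1 = 0 with support 0.
    """
    y_true, y_pred = _check_pair(y_true, y_pred)
    if tract_ids is None:
        tract_ids = np.unique(np.concatenate([y_true, y_pred]))
    tract_ids = np.asarray(sorted(tract_ids))
    p, r, f1, support = precision_recall_fscore_support(
        y_true, y_pred, labels=tract_ids, zero_division=0
    )
    return pd.DataFrame(
        {"precision": p, "recall": r, "f1": f1, "support": support},
        index=pd.Index(tract_ids, name="tract_id"),
    )


def macro_f1(per_tract: pd.DataFrame, exclude: Iterable[int] = (),
             outlier_id: Optional[int] = None) -> float:
    """Unweighted mean F1 over non-excluded tracts (outlier always excluded)."""
    drop = set(int(i) for i in exclude)
    if outlier_id is not None:
        drop.add(int(outlier_id))
    keep = [i for i in per_tract.index if int(i) not in drop]
    if not keep:
        raise ValueError("all tracts excluded from macro-F1")
    return float(per_tract.loc[keep, "f1"].mean())


def false_accept_reject(y_true, y_pred, outlier_id: int):
    """(false_accept, false_reject) rates w.r.t. the outlier class.

    false_accept: true outliers predicted as some tract; None when the
    truth contains no outliers. false_reject: true-tract streamlines
    predicted as outlier; None when the truth contains no tract members.
    """
    y_true, y_pred = _check_pair(y_true, y_pred)
    is_out = y_true == outlier_id
    fa = float(np.mean(y_pred[is_out] != outlier_id)) if is_out.any() else None
    fr = float(np.mean(y_pred[~is_out] == outlier_id)) if (~is_out).any() else None
    return fa, fr


def paired_compare(scores_a: pd.DataFrame, scores_b: pd.DataFrame,
                   n_tests: Optional[int] = None) -> pd.DataFrame:
    """Per-tract two-sided Wilcoxon signed-rank test with Bonferroni correction.

    ``scores_a`` / ``scores_b`` are aligned subject x tract metric tables
    (e.g. per-subject F1 for two models). Zero differences are dropped;
    the exact null distribution is used for n <= 25 without ties, the
    tie-corrected normal approximation otherwise. The Bonferroni divisor
    ``n_tests`` defaults to the number of tracts compared here but can be
    set to the total number of tests across all model pairs.

    Returns a table with columns raw_p, adjusted_p, n_pairs, degenerate.
    """
    if not scores_a.columns.equals(scores_b.columns) or len(scores_a) != len(scores_b):
        raise ValueError("score tables must be aligned (same subjects and tracts)")
    if n_tests is None:
        n_tests = scores_a.shape[1]
    rows = []
    for tract in scores_a.columns:
        d = np.asarray(scores_a[tract], dtype=float) - np.asarray(
            scores_b[tract], dtype=float)
        d = d[~np.isnan(d)]
        nz = d[d != 0]
        if nz.size == 0:
            rows.append((tract, 1.0, 1.0, 0, True))
            continue
        has_ties = len(np.unique(np.abs(nz))) < nz.size
        method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
        res = stats.wilcoxon(nz, alternative="two-sided", method=method)
        raw = float(res.pvalue)
        rows.append((tract, raw, min(1.0, raw * n_tests), int(nz.size), False))
    return pd.DataFrame(
        rows, columns=["tract_id", "raw_p", "adjusted_p", "n_pairs", "degenerate"]
    ).set_index("tract_id")


@dataclass
class EvalReport:
    """Bundle of evaluation results for one prediction/truth pair."""

    accuracy: float
    per_tract: pd.DataFrame
    macro_f1: float
    false_accept_rate: Optional[float]
    false_reject_rate: Optional[float]
    excluded_tracts: list = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            f"accuracy       : {self.accuracy:.4f}",
            f"macro-F1       : {self.macro_f1:.4f} "
            f"(outlier excluded; also excluded: {self.excluded_tracts or 'none'})",
        ]
        if self.false_accept_rate is not None:
            lines.append(f"false accept   : {self.false_accept_rate:.4f}")
        if self.false_reject_rate is not None:
            lines.append(f"false reject   : {self.false_reject_rate:.4f}")
        lines.append(f"tracts scored  : {len(self.per_tract)}")
        return "\n".join(lines)


def evaluate_predictions(y_true, y_pred, outlier_id: int,
                         exclude: Iterable[int] = (),
                         drop_unsupported: bool = True) -> EvalReport:
    """Full evaluation: accuracy, per-tract P/R/F1, macro-F1, FA/FR rates.

    With ``drop_unsupported`` (default), tracts with zero true support are
    dropped from the per-tract table (and hence the macro-F1) rather than
    scored zero, so aggregate scores are not dominated by absent anatomy;
    the exclusion is recorded in the report.
    """
    y_true, y_pred = _check_pair(y_true, y_pred)
    table = per_tract_prf(y_true, y_pred)
    excluded = sorted(int(i) for i in exclude)
    if drop_unsupported:
        unsupported = [int(i) for i in table.index[table["support"] == 0]]
        excluded = sorted(set(excluded) | set(unsupported))
    fa, fr = false_accept_reject(y_true, y_pred, outlier_id)
    return EvalReport(
        accuracy=accuracy(y_true, y_pred),
        per_tract=table,
        macro_f1=macro_f1(table, exclude=excluded, outlier_id=outlier_id),
        false_accept_rate=fa,
        false_reject_rate=fr,
        excluded_tracts=excluded,
    )
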