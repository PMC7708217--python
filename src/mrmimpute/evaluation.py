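"""Scoring of imputations against hidden truth, and method comparisons.

Per subject, the hidden (deleted) values are pooled over all regions and
scored by RMSE, Pearson correlation, and the area under the ROC curve with
the truth binarized at 0.5 (imputed values enter the ROC as raw scores).
Methods are compared by paired two-sided t-tests across subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .io import MethylationDataset

__all__ = ["SubjectScore", "EvalReport", "score_subject", "compare_methods",
           "benchmark"]

METRICS = ("rmse", "correlation", "auc")


@dataclass
class SubjectScore:
    rmse: float
    correlation: float
    auc: float
    n_points: int


@dataclass
class EvalReport:
    per_subject: pd.DataFrame          # subject, method, rmse, correlation, auc, n_points
    comparisons: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["metric", "method_a", "method_b", "t_statistic", "p_value"]))

    def tidy(self) -> pd.DataFrame:
        """Long format: one row per subject x method x metric."""
        return self.per_subject.melt(
            id_vars=["subject", "method"], value_vars=list(METRICS),
            var_name="metric", value_name="value")


def score_subject(truth, imputed) -> SubjectScore:
    """Score one subject's pooled hidden points.

    RMSE follows sqrt(sum (y - yhat)^2 / n); the correlation is the pooled
    Pearson coefficient; the AUC binarizes the truth at 0.5 (>= 0.5 -> 1)
    and uses the raw imputed values as scores.  Undefined metrics (constant
    vectors, one-class truth) are reported as NaN.
    """
    truth = np.asarray(truth, dtype=float).ravel()
    imputed = np.asarray(imputed, dtype=float).ravel()
    if truth.shape != imputed.shape:
        raise ValueError("truth and imputed must have the same length")
    n = truth.size
    if n == 0:
        return SubjectScore(np.nan, np.nan, np.nan, 0)
    rmse = float(np.sqrt(np.mean((truth - imputed) ** 2)))
    if n >= 2 and np.std(truth) > 0 and np.std(imputed) > 0:
        corr = float(stats.pearsonr(truth, imputed).statistic)
    else:
        corr = np.nan
    labels = (truth >= 0.5).astype(int)
    if labels.min() == labels.max():
        auc = np.nan
    else:
        auc = float(roc_auc_score(labels, imputed))
    return SubjectScore(rmse, corr, auc, n)


def compare_methods(scores_a: Sequence[float], scores_b: Sequence[float],
                    paired: bool = True):
    """Two-sided t-test between two methods' per-subject scores.

    Returns (t, p, degenerate): paired across the same subjects by default;
    a zero-variance difference vector sets the degenerate flag.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b) if paired else None
    if paired:
        a, b = a[ok], b[ok]
        if a.size < 2:
            return np.nan, np.nan, True
        d = a - b
        if np.std(d) <= 1e-12 * (1.0 + np.abs(d).max()):
            # identical vectors: t = 0, p = 1 by convention; a constant
            # nonzero shift has no finite t and is flagged degenerate
            if np.allclose(d, 0):
                return 0.0, 1.0, False
            return np.nan, np.nan, True
        res = stats.ttest_rel(a, b)
    else:
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if min(a.size, b.size) < 2:
            return np.nan, np.nan, True
        res = stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue), False


def _collect_subject_arrays(dataset: MethylationDataset,
                            hidden: Dict[str, np.ndarray],
                            imputed: Dict[str, np.ndarray]):
    """Yield (subject_index, truth_vector, imputed_vector) pooled over regions."""
    n = dataset.n_subjects
    for s in range(n):
        t_parts, p_parts = [], []
        for region in dataset:
            h = hidden.get(region.region_id)
            if h is None:
                continue
            cells = np.isfinite(h[s])
            if not cells.any():
                continue
            t_parts.append(h[s][cells])
            p_parts.append(imputed[region.region_id][s][cells])
        if t_parts:
            yield s, np.concatenate(t_parts), np.concatenate(p_parts)
        else:
            yield s, np.empty(0), np.empty(0)


def benchmark(dataset: MethylationDataset, hidden: Dict[str, np.ndarray],
              methods: Sequence[str], config=None, seed: int = 0,
              compare: bool = True) -> EvalReport:
    """Run the requested imputers on masked data and score them per subject.

    ``dataset`` is the masked data; ``hidden`` maps region_id to (N, I)
    arrays holding the deleted truth (NaN elsewhere).  Methods: "regional",
    "subject", "stacked", "average", "knn".  One method failing does not
    abort the others.
    """
    from .imputation import run_method  # deferred: imputation imports this module

    rows = []
    for method in methods:
        try:
            imputed = run_method(dataset, method, config=config, seed=seed)
        except Exception as exc:  # noqa: BLE001 - isolate per-method failures
            warnings.warn(f"method {method!r} failed: {exc}")
            continue
        for s, truth, pred in _collect_subject_arrays(dataset, hidden, imputed):
            sc = score_subject(truth, pred)
            rows.append(dict(subject=dataset.subject_ids[s], method=method,
                             rmse=sc.rmse, correlation=sc.correlation,
                             auc=sc.auc, n_points=sc.n_points))
    per_subject = pd.DataFrame(rows)
    report = EvalReport(per_subject=per_subject)
    if compare and not per_subject.empty:
        done = list(per_subject["method"].unique())
        comp_rows = []
        for i, ma in enumerate(done):
            for mb in done[i + 1:]:
                for metric in METRICS:
                    va = per_subject.query("method == @ma").set_index("subject")[metric]
                    vb = per_subject.query("method == @mb").set_index("subject")[metric]
                    vb = vb.reindex(va.index)
                    t, p, _ = compare_methods(va.to_numpy(), vb.to_numpy())
                    comp_rows.append(dict(metric=metric, method_a=ma, method_b=mb,
                                          t_statistic=t, p_value=p))
        report.comparisons = pd.DataFrame(comp_rows)
    return report
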