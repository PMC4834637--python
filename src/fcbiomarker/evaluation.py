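"""Classifier evaluation: confusion metrics, AUC, and significance tests."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from fcbiomarker import pipeline as _pipeline

__all__ = [
    "EvaluationReport",
    "confusion_metrics",
    "roc_auc",
    "binomial_pvalue",
    "permutation_test",
    "disorder_generalization",
]


@dataclass
class EvaluationReport:
    """Confusion counts and the derived diagnostic metrics."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    dor: float
    dor_corrected: bool = False
    auc: float | None = None
    pvalues: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_metrics(labels: np.ndarray, predictions: np.ndarray) -> EvaluationReport:
    """Confusion counts, accuracy/sensitivity/specificity and the DOR.

    The diagnostic odds ratio is (TP*TN)/(FN*FP). If any cell is zero the
    Haldane–Anscombe +0.5 continuity correction is applied to all four cells
    and the report is flagged (``dor_corrected``).
    """
    labels = np.asarray(labels).astype(int).ravel()
    predictions = np.asarray(predictions).astype(int).ravel()
    if labels.size == 0 or labels.shape != predictions.shape:
        raise ValueError("labels and predictions must be equal-length, nonempty")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    corrected = 0 in (tp, fn, tn, fp)
    if corrected:
        dor = ((tp + 0.5) * (tn + 0.5)) / ((fn + 0.5) * (fp + 0.5))
    else:
        dor = (tp * tn) / (fn * fp)
    n = len(labels)
    return EvaluationReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / n,
        sensitivity=tp / (tp + fn) if tp + fn else float("nan"),
        specificity=tn / (tn + fp) if tn + fp else float("nan"),
        dor=float(dor),
        dor_corrected=corrected,
    )


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann–Whitney) area under the ROC curve; ties half credit."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    rank_sum = ranks[: len(pos)].sum()
    u = rank_sum - len(pos) * (len(pos) + 1) / 2
    return float(u / (len(pos) * len(neg)))


def binomial_pvalue(k_correct: int, n: int, p0: float = 0.5) -> float:
    """Exact one-sided upper-tail binomial probability P(X >= k | n, p0)."""
    if not 0 <= k_correct <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    # survival function of k-1 = upper tail including k; scipy evaluates the
    # regularized incomplete beta in log-stable form
    return float(stats.binom.sf(k_correct - 1, n, p0))


def permutation_test(
    attributes: pd.DataFrame | np.ndarray,
    fc_matrix: np.ndarray,
    plan: "_pipeline.NestedFsPlan | None" = None,
    n_perm: int = 100,
    seed: int = 0,
    observed_accuracy: float | None = None,
    freeze_features: bool = False,
) -> dict:
    """Permutation p-value for the nested-LOOCV accuracy.

    Diagnosis labels are permuted once per replicate and, by default, the
    *entire* selection + training pipeline is rerun under the permuted
    labels (the conservative scheme). ``freeze_features=True`` reuses the
    observed run's feature sets and only retrains the classifier — much
    faster but anticonservative, since selection saw the true labels.

    Returns ``{"observed": acc, "permuted": array, "p_value": p}`` with
    ``p = (1 + #{perm >= observed}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    plan = plan or _pipeline.NestedFsPlan()
    x1 = _pipeline._attribute_matrix(attributes)
    x2 = np.asarray(fc_matrix, dtype=float)
    rng = np.random.default_rng(seed)
    observed_run = None
    if observed_accuracy is None or freeze_features:
        observed_run = _pipeline.nested_loocv(x1, x2, plan)
        observed_accuracy = observed_run.accuracy
    permuted = np.empty(n_perm)
    for i in range(n_perm):
        x1_perm = x1.copy()
        x1_perm[:, 0] = rng.permutation(x1[:, 0])
        if freeze_features:
            labels = x1_perm[:, 0].astype(int)
            n = len(labels)
            correct = 0
            from fcbiomarker import scca, slr

            for fold in range(plan.n_outer):
                sel = observed_run.fold_features[fold]
                z_all = scca.project(x2, sel)
                for subject in np.flatnonzero(observed_run.outer_fold == fold):
                    rest = np.ones(n, dtype=bool)
                    rest[subject] = False
                    model = slr.slr_fit(z_all[rest], labels[rest])
                    score = slr.wls_score(model, z_all[subject][None, :])
                    correct += int(score.label[0] == labels[subject])
            permuted[i] = correct / n
        else:
            perm_plan = _pipeline.NestedFsPlan(
                n_outer=plan.n_outer,
                n_inner=plan.n_inner,
                lambda_grid=plan.lambda_grid,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            permuted[i] = _pipeline.nested_loocv(x1_perm, x2, perm_plan).accuracy
    p = (1 + int(np.sum(permuted >= observed_accuracy))) / (1 + n_perm)
    return {"observed": observed_accuracy, "permuted": permuted, "p_value": p}


def disorder_generalization(
    wls_by_group: dict[str, tuple[np.ndarray, np.ndarray]],
) -> pd.DataFrame:
    """Per-dataset AUC and KS comparison of case vs control WLS distributions.

    Parameters
    ----------
    wls_by_group : dict mapping dataset name -> (case_scores, control_scores)

    Returns a DataFrame with KS statistic, raw p, Benjamini–Hochberg-adjusted
    p across datasets, and the case-vs-control AUC. The KS test uses the
    exact two-sample distribution for small samples (< 25 per group) and the
    asymptotic one otherwise.
    """
    names, ks_stat, ks_p, aucs = [], [], [], []
    for name, (case, control) in wls_by_group.items():
        case = np.asarray(case, dtype=float).ravel()
        control = np.asarray(control, dtype=float).ravel()
        if min(len(case), len(control)) < 3:
            warnings.warn(f"{name}: fewer than 3 subjects in a group")
        method = "exact" if min(len(case), len(control)) < 25 else "asymp"
        res = stats.ks_2samp(case, control, method=method)
        names.append(name)
        ks_stat.append(float(res.statistic))
        ks_p.append(float(res.pvalue))
        scores = np.concatenate([case, control])
        labels = np.concatenate([np.ones(len(case)), np.zeros(len(control))])
        aucs.append(roc_auc(scores, labels))
    adjusted = multipletests(ks_p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "dataset": names,
            "auc": aucs,
            "ks_statistic": ks_stat,
            "p_raw": ks_p,
            "p_bh": adjusted,
        }
    )
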