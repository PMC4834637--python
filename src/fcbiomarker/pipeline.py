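"""Nested 9x9 feature selection + leave-one-out cross-validation.

The protocol keeps feature selection strictly separated from the subject
being predicted:

* the cohort is split into 9 stratified *outer* folds;
* for each outer fold (the "testing pool"), the remaining 8 folds are
  re-partitioned into 9 stratified *inner* folds; dropping each inner fold
  in turn, L1-SCCA runs on every (lambda1, lambda2) pair of the grid and the
  diagnosis-specific FC features are accumulated by union (summed xi);
* every subject in the testing pool is then predicted by an ARD sparse
  logistic classifier trained on all other N-1 subjects restricted to that
  outer fold's feature set — the held-out subject never enters
  standardization, feature selection or training for its own prediction.

The union over all nine outer-fold feature sets trains the final classifier
on the whole cohort; that model is applied unchanged (stored standardization
statistics, no refitting) to external cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fcbiomarker import scca, slr

__all__ = [
    "NestedFsPlan",
    "LoocvResult",
    "default_lambda_grid",
    "stratified_kfold",
    "inner_feature_selection",
    "nested_loocv",
    "train_final",
    "apply_to_cohort",
]


def default_lambda_grid(
    values: np.ndarray | None = None,
) -> list[tuple[float, float]]:
    """All (lambda1, lambda2) with lambda1 <= lambda2 from {0.1, ..., 0.9}.

    The default 9-value ladder yields the 45 pair combinations swept by the
    inner feature-selection loop.
    """
    if values is None:
        values = np.round(np.arange(0.1, 1.0, 0.1), 10)
    return [(float(a), float(b)) for a in values for b in values if a <= b]


@dataclass
class NestedFsPlan:
    """Configuration of the nested feature-selection + LOOCV protocol."""

    n_outer: int = 9
    n_inner: int = 9
    lambda_grid: list[tuple[float, float]] = field(default_factory=default_lambda_grid)
    seed: int = 0


@dataclass
class LoocvResult:
    """Per-subject LOOCV predictions and per-fold bookkeeping."""

    wls: np.ndarray
    probability: np.ndarray
    predicted: np.ndarray
    labels: np.ndarray
    outer_fold: np.ndarray
    fold_features: list[scca.FeatureSelection]
    active_counts: np.ndarray  # SLR active-set size per LOOCV iteration

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.predicted == self.labels))

    @property
    def sensitivity(self) -> float:
        case = self.labels == 1
        return float(np.mean(self.predicted[case] == 1))

    @property
    def specificity(self) -> float:
        ctrl = self.labels == 0
        return float(np.mean(self.predicted[ctrl] == 0))


def _attribute_matrix(attributes: pd.DataFrame | np.ndarray) -> np.ndarray:
    if isinstance(attributes, pd.DataFrame):
        return attributes[list(scca.ATTRIBUTE_COLUMNS)].to_numpy(dtype=float)
    return np.asarray(attributes, dtype=float)


def _strata(x1: np.ndarray) -> np.ndarray:
    """(diagnosis, sex, site) stratum id per subject."""
    diagnosis = x1[:, 0].astype(int)
    site = np.argmax(x1[:, 1:4], axis=1)
    sex = x1[:, 5].astype(int)
    return diagnosis * 100 + sex * 10 + site


def stratified_kfold(
    attributes: pd.DataFrame | np.ndarray, k: int = 9, seed: int = 0
) -> np.ndarray:
    """Fold assignment stratified by (diagnosis, sex, site).

    Members of each stratum are dealt round-robin (after a seeded shuffle)
    into folds, starting at a rotating offset so that small strata spread
    evenly instead of piling onto fold 0. Per-stratum fold counts differ by
    at most 1.
    """
    x1 = _attribute_matrix(attributes)
    n = x1.shape[0]
    if k > n:
        raise ValueError("more folds than subjects")
    rng = np.random.default_rng(seed)
    strata = _strata(x1)
    folds = np.empty(n, dtype=int)
    offset = 0
    for s in np.unique(strata):
        members = np.flatnonzero(strata == s)
        rng.shuffle(members)
        for i, subject in enumerate(members):
            folds[subject] = (offset + i) % k
        offset = (offset + len(members)) % k
    return folds


def _scca_union_for_training(
    x1: np.ndarray,
    x2: np.ndarray,
    plan: NestedFsPlan,
    seed: int,
) -> scca.FeatureSelection:
    """Inner 9-fold x lambda-grid L1-SCCA union on one training cohort."""
    inner = stratified_kfold(x1, k=plan.n_inner, seed=seed)
    xi = np.zeros(x2.shape[1])
    for fold in range(plan.n_inner):
        keep = inner != fold
        cohort = scca.standardize(x1[keep], x2[keep])
        for lam1, lam2 in plan.lambda_grid:
            res = scca.scca_fit(cohort, lam1, lam2)
            xi += scca.diagnostic_feature_union(res).xi
    return scca.FeatureSelection(xi=xi, selected_indices=np.flatnonzero(xi))


def inner_feature_selection(
    attributes: pd.DataFrame | np.ndarray,
    fc_matrix: np.ndarray,
    plan: NestedFsPlan | None = None,
    seed: int | None = None,
) -> scca.FeatureSelection:
    """Run the inner FS loop on a training cohort (no outer split).

    Standardization happens per inner fold on the retained rows only. The
    returned xi is the sum over all inner-fold x lambda-pair runs.
    """
    plan = plan or NestedFsPlan()
    x1 = _attribute_matrix(attributes)
    x2 = np.asarray(fc_matrix, dtype=float)
    return _scca_union_for_training(
        x1, x2, plan, plan.seed if seed is None else seed
    )


def nested_loocv(
    attributes: pd.DataFrame | np.ndarray,
    fc_matrix: np.ndarray,
    plan: NestedFsPlan | None = None,
) -> LoocvResult:
    """Full nested feature-selection + leave-one-out cross-validation.

    Every subject is predicted exactly once, by a model whose feature set
    was chosen without the subject's outer fold and whose SLR training set
    excludes the subject itself. LOOCV iterations within one testing pool
    share the pool's feature set.
    """
    plan = plan or NestedFsPlan()
    x1 = _attribute_matrix(attributes)
    x2 = np.asarray(fc_matrix, dtype=float)
    n = x1.shape[0]
    labels = x1[:, 0].astype(int)
    outer = stratified_kfold(x1, k=plan.n_outer, seed=plan.seed)
    wls = np.zeros(n)
    probability = np.zeros(n)
    predicted = np.zeros(n, dtype=int)
    active_counts = np.zeros(n, dtype=int)
    fold_features: list[scca.FeatureSelection] = []
    for fold in range(plan.n_outer):
        train_pool = outer != fold
        selection = _scca_union_for_training(
            x1[train_pool], x2[train_pool], plan, seed=plan.seed + 1 + fold
        )
        fold_features.append(selection)
        z_all = scca.project(x2, selection)
        # Pool-reference ARD fit on the 8 training folds: it excludes every
        # testing-pool subject, so warm-starting the per-subject fits from it
        # leaks nothing about the subject being predicted while skipping the
        # expensive high-dimensional pruning phase of each LOOCV fit.
        reference = slr.slr_fit(z_all[train_pool], labels[train_pool])
        for subject in np.flatnonzero(outer == fold):
            rest = np.ones(n, dtype=bool)
            rest[subject] = False
            model = slr.slr_fit(
                z_all[rest],
                labels[rest],
                alpha0=reference.alphas,
                w0=reference.weights,
            )
            score = slr.wls_score(model, z_all[subject][None, :])
            wls[subject] = score.wls[0]
            probability[subject] = score.probability[0]
            predicted[subject] = score.label[0]
            active_counts[subject] = len(model.active_set)
    return LoocvResult(
        wls=wls,
        probability=probability,
        predicted=predicted,
        labels=labels,
        outer_fold=outer,
        fold_features=fold_features,
        active_counts=active_counts,
    )


def train_final(
    attributes: pd.DataFrame | np.ndarray,
    fc_matrix: np.ndarray,
    plan: NestedFsPlan | None = None,
    loocv: LoocvResult | None = None,
) -> tuple[slr.SlrModel, scca.FeatureSelection]:
    """Train the deployable classifier on the whole cohort.

    The feature set is the union (summed xi) of the nine outer-fold feature
    sets from the nested FS; SLR then prunes within it. Pass a completed
    ``loocv`` result to reuse its fold feature sets, otherwise the nested FS
    is recomputed.
    """
    plan = plan or NestedFsPlan()
    x1 = _attribute_matrix(attributes)
    x2 = np.asarray(fc_matrix, dtype=float)
    if loocv is None:
        loocv = nested_loocv(attributes, fc_matrix, plan)
    xi = np.sum([fs.xi for fs in loocv.fold_features], axis=0)
    union = scca.FeatureSelection(xi=xi, selected_indices=np.flatnonzero(xi))
    z = scca.project(x2, union)
    model = slr.slr_fit(z, x1[:, 0].astype(int))
    model.feature_indices = union.selected_indices.copy()
    return model, union


def apply_to_cohort(
    model: slr.SlrModel, external_fc_matrix: np.ndarray
) -> slr.ClassifierScore:
    """Score an external cohort with a trained model — no refitting.

    The FC matrix must share the training index map; the model's stored
    ``feature_indices`` pick out its columns and the stored training
    standardization statistics are applied.
    """
    x2 = np.asarray(external_fc_matrix, dtype=float)
    if model.feature_indices is None:
        raise ValueError("model carries no FC feature indices")
    if len(model.feature_indices) and x2.shape[1] <= model.feature_indices.max():
        raise ValueError("external FC matrix does not match the model's index map")
    z = x2[:, model.feature_indices]
    return slr.wls_score(model, z)
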