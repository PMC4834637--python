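"""L1-regularized sparse canonical correlation analysis (L1-SCCA).

Finds paired sparse projection vectors v1 (attribute block X1) and v2 (FC
block X2) maximizing ``v1' X1' X2 v2`` subject to ``||v||_2 <= 1`` and
``||v||_1 <= c``. The L1 bound is parameterized as ``c_j = max(1, lambda_j *
sqrt(p_j))`` with ``lambda_j`` in (0, 1], so lambda interpolates from a
single-coordinate solution (lambda -> 0) to the unconstrained unit-norm
solution (lambda = 1).

The *diagnostic canonical constraint* then keeps only canonical components
whose attribute loading is nonzero solely on the diagnosis column: the FC
loadings of those components accumulate into a nonnegative selection weight
vector (xi), and the union of its support across fits is the
diagnosis-specific FC subset. Components loading on any nuisance column
(site, age, sex, eye condition, medication) contribute nothing, which is the
mechanism that keeps nuisance-linked FCs out of the biomarker.

Expected attribute column order (p1 = 10): diagnosis, site A, site B,
site C, age, sex, eye condition, and three medication flags.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ATTRIBUTE_COLUMNS",
    "StandardizedCohort",
    "SccaResult",
    "FeatureSelection",
    "standardize",
    "l1_l2_project",
    "scca_fit",
    "diagnostic_feature_union",
    "project",
]

ATTRIBUTE_COLUMNS = (
    "diagnosis",
    "site_a",
    "site_b",
    "site_c",
    "age",
    "sex",
    "eye",
    "med1",
    "med2",
    "med3",
)


@dataclass
class StandardizedCohort:
    """Column-standardized attribute and FC blocks with the training stats."""

    x1: np.ndarray
    x2: np.ndarray
    x1_mean: np.ndarray
    x1_sd: np.ndarray
    x2_mean: np.ndarray
    x2_sd: np.ndarray
    constant_columns: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class SccaResult:
    """Sparse projection matrices and canonical values of one (λ1, λ2) fit."""

    v1: np.ndarray  # p1 x q
    v2: np.ndarray  # p2 x q
    canonical_values: np.ndarray  # q
    lambda1: float
    lambda2: float
    converged: np.ndarray | None = None


@dataclass
class FeatureSelection:
    """Accumulated diagnostic FC weights and their support."""

    xi: np.ndarray
    selected_indices: np.ndarray

    @property
    def m(self) -> int:
        return len(self.selected_indices)


def _standardize_block(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    constant = sd == 0
    sd = np.where(constant, 1.0, sd)
    return (x - mean) / sd, mean, sd, constant


def standardize(x1: np.ndarray, x2: np.ndarray) -> StandardizedCohort:
    """Centre and scale every column of both blocks to mean 0, SD 1.

    Constant columns (e.g. a site flag in single-site training data) get SD
    set to 1 so they standardize to an all-zero, inert column; they are
    recorded in ``constant_columns``.
    """
    z1, m1, s1, c1 = _standardize_block(x1)
    z2, m2, s2, c2 = _standardize_block(x2)
    return StandardizedCohort(
        x1=z1, x2=z2, x1_mean=m1, x1_sd=s1, x2_mean=m2, x2_sd=s2,
        constant_columns={"x1": np.flatnonzero(c1), "x2": np.flatnonzero(c2)},
    )


def l1_l2_project(a: np.ndarray, c: float, tol: float = 1e-8) -> np.ndarray:
    """Soft-threshold-and-normalize projection onto {||v||2 <= 1, ||v||1 <= c}.

    Returns ``v = soft(a, d) / ||soft(a, d)||_2`` with the smallest threshold
    ``d >= 0`` (found by bisection) such that ``||v||_1 <= c``. Feasibility
    requires ``c >= 1`` since any unit-L2 vector has L1 norm >= 1. An all-zero
    input returns the zero vector.
    """
    a = np.asarray(a, dtype=float)
    if c < 1:
        raise ValueError("c must be >= 1 (any unit-L2 vector has L1 >= 1)")
    amax = np.max(np.abs(a)) if a.size else 0.0
    if amax == 0:
        return np.zeros_like(a)

    def normalized(delta: float) -> np.ndarray:
        v = np.sign(a) * np.maximum(np.abs(a) - delta, 0.0)
        nrm = np.linalg.norm(v)
        if nrm == 0:
            # threshold at or above the max: keep only the largest coordinate
            v = np.zeros_like(a)
            i = int(np.argmax(np.abs(a)))
            v[i] = np.sign(a[i])
            return v
        return v / nrm

    v = normalized(0.0)
    if np.abs(v).sum() <= c:
        return v
    lo, hi = 0.0, amax
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if np.abs(normalized(mid)).sum() <= c:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol * amax:
            break
    return normalized(hi)


def _leading_right_singular(s: np.ndarray, n_steps: int = 20) -> np.ndarray:
    """Estimate S's leading right singular direction by plain power steps."""
    p2 = s.shape[1]
    v = np.full(p2, 1.0 / np.sqrt(p2))
    for _ in range(n_steps):
        v = s.T @ (s @ v)  # factored S'S product: O(p1 p2) per step
        nrm = np.linalg.norm(v)
        if nrm == 0:
            return np.zeros(p2)
        v /= nrm
    # deterministic sign: largest-magnitude entry positive
    i = int(np.argmax(np.abs(v)))
    if v[i] < 0:
        v = -v
    return v


def scca_fit(
    cohort: StandardizedCohort,
    lambda1: float,
    lambda2: float,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> SccaResult:
    """Fit all q = min(p1, p2) sparse canonical components.

    Each component alternates the two constrained projections on the current
    cross-product matrix ``S = X1' X2`` until the objective ``v1' S v2``
    changes by less than ``tol``; the fitted rank-1 term ``d_k v1 v2'`` is
    then deflated from S before the next component.
    """
    for lam, name in ((lambda1, "lambda1"), (lambda2, "lambda2")):
        if not (0 < lam <= 1):
            raise ValueError(f"{name} must be in (0, 1]")
    x1, x2 = cohort.x1, cohort.x2
    p1, p2 = x1.shape[1], x2.shape[1]
    q = min(p1, p2)
    c1 = max(1.0, lambda1 * np.sqrt(p1))
    c2 = max(1.0, lambda2 * np.sqrt(p2))
    s = x1.T @ x2
    v1_mat = np.zeros((p1, q))
    v2_mat = np.zeros((p2, q))
    d = np.zeros(q)
    converged = np.zeros(q, dtype=bool)
    for k in range(q):
        if not np.any(s):
            break
        v2 = _leading_right_singular(s)
        if not np.any(v2):
            break
        v1 = l1_l2_project(s @ v2, c1)
        obj = float(v1 @ s @ v2)
        for _ in range(max_iter):
            v1 = l1_l2_project(s @ v2, c1)
            v2 = l1_l2_project(s.T @ v1, c2)
            new_obj = float(v1 @ s @ v2)
            if abs(new_obj - obj) < tol * max(1.0, abs(new_obj)):
                converged[k] = True
                obj = new_obj
                break
            obj = new_obj
        else:
            logger.debug("component %d: no convergence in %d iterations", k, max_iter)
        d[k] = float(v1 @ s @ v2)
        v1_mat[:, k] = v1
        v2_mat[:, k] = v2
        s = s - d[k] * np.outer(v1, v2)
    return SccaResult(
        v1=v1_mat, v2=v2_mat, canonical_values=d,
        lambda1=lambda1, lambda2=lambda2, converged=converged,
    )


def diagnostic_columns(result: SccaResult) -> np.ndarray:
    """Component indices whose attribute loading is on the diagnosis row only.

    Row 0 of v1 must correspond to the diagnosis column. "Nonzero" means
    exactly nonzero: the soft-thresholding projection produces exact zeros,
    so no epsilon is involved.
    """
    nonzero = result.v1 != 0
    return np.flatnonzero(nonzero[0] & ~nonzero[1:].any(axis=0))


def diagnostic_feature_union(results: list[SccaResult] | SccaResult) -> FeatureSelection:
    """Accumulate |v2| over diagnostic components of every fit; take support.

    Per fit, xi = sum over diagnostic components of |v2[:, k]|; fits with no
    diagnostic component contribute nothing. The total xi is the sum across
    fits and the selected FC indices are its support (an empty union is a
    valid outcome).
    """
    if isinstance(results, SccaResult):
        results = [results]
    xi: np.ndarray | None = None
    for res in results:
        cols = diagnostic_columns(res)
        contrib = np.abs(res.v2[:, cols]).sum(axis=1) if len(cols) else np.zeros(res.v2.shape[0])
        xi = contrib if xi is None else xi + contrib
    if xi is None:
        raise ValueError("no results given")
    return FeatureSelection(xi=xi, selected_indices=np.flatnonzero(xi))


def project(x2_row: np.ndarray, selection: FeatureSelection) -> np.ndarray:
    """Project an FC vector onto the selected subspace: z_k = x2[i_k]."""
    x2_row = np.asarray(x2_row, dtype=float)
    idx = selection.selected_indices
    if len(idx) and (idx.min() < 0 or idx.max() >= x2_row.shape[-1]):
        raise IndexError("selected index out of range")
    return x2_row[..., idx]


def selection_table(
    selection: FeatureSelection,
    index_map: list[tuple[int, int]] | None = None,
):
    """Selected features as a table: FC index, xi weight, region-pair label.

    ``index_map`` is the FC-vector position -> region-pair mapping from
    :func:`fcbiomarker.connectivity.fc_index_pairs`; without it the pair
    column is omitted.
    """
    import pandas as pd

    data = {
        "fc_index": selection.selected_indices,
        "xi": selection.xi[selection.selected_indices],
    }
    if index_map is not None:
        data["region_pair"] = [
            f"r{index_map[i][0]}-r{index_map[i][1]}" for i in selection.selected_indices
        ]
    return pd.DataFrame(data)
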