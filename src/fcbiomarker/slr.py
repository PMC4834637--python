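"""Sparse logistic regression with automatic relevance determination (ARD).

Each weight w_i carries an independent Gaussian prior N(0, 1/alpha_i) whose
precision alpha_i is learned from the data by evidence maximization: the
posterior over w is approximated by a Laplace (Gaussian) approximation around
the penalized-likelihood mode, and each precision is re-estimated with the
MacKay fixed-point rule

    alpha_i  <-  gamma_i / mu_i^2,      gamma_i = 1 - alpha_i * Sigma_ii,

where mu is the posterior mode and Sigma the Laplace covariance. Precisions
of irrelevant features diverge, the corresponding weights collapse onto zero
and are pruned exactly (alpha_i > 1e8), leaving a small active set. The bias
term rides on a fixed broad prior and is never pruned.

Features are standardized internally with training-set statistics that are
stored in the model, so a trained classifier can be applied to external
subjects without touching their data during training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SlrModel", "ClassifierScore", "slr_fit", "wls_score"]

PRUNE_ALPHA = 1e8
BIAS_ALPHA = 1e-6


@dataclass
class SlrModel:
    """Fitted ARD logistic-regression classifier.

    ``weights`` has length m+1: one weight per (standardized) feature plus
    the bias for the augmented constant input, stored last. Pruned weights
    are exactly 0.
    """

    weights: np.ndarray
    alphas: np.ndarray
    active_set: np.ndarray
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    fit_log: dict = field(default_factory=dict)
    feature_indices: np.ndarray | None = None  # FC-vector indices, if known

    @property
    def n_features(self) -> int:
        return len(self.weights) - 1

    def to_json(self, path: str) -> None:
        payload = {
            "weights": self.weights.tolist(),
            "alphas": self.alphas.tolist(),
            "active_set": self.active_set.tolist(),
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
            "fit_log": self.fit_log,
            "feature_indices": None
            if self.feature_indices is None
            else self.feature_indices.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str) -> "SlrModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            weights=np.asarray(payload["weights"], dtype=float),
            alphas=np.asarray(payload["alphas"], dtype=float),
            active_set=np.asarray(payload["active_set"], dtype=int),
            feature_mean=np.asarray(payload["feature_mean"], dtype=float),
            feature_sd=np.asarray(payload["feature_sd"], dtype=float),
            fit_log=payload["fit_log"],
            feature_indices=None
            if payload["feature_indices"] is None
            else np.asarray(payload["feature_indices"], dtype=int),
        )


@dataclass
class ClassifierScore:
    """Weighted linear summation (WLS) and the derived probability/label.

    Positive WLS classifies as case (label 1), negative as control (0);
    ``probability = logistic(wls)`` is the case probability.
    """

    wls: np.ndarray
    probability: np.ndarray
    label: np.ndarray


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _map_estimate(
    x: np.ndarray,
    y: np.ndarray,
    alpha: np.ndarray,
    w0: np.ndarray,
    max_newton: int = 50,
    tol: float = 1e-7,
    xa: np.ndarray | None = None,
    kernel: np.ndarray | None = None,
) -> np.ndarray:
    """Penalized-logistic mode via damped Newton iterations.

    When there are more features than samples the Newton system
    ``(X'WX + A) step = g`` is solved in the n-dimensional dual space via the
    Woodbury identity; the alpha-scaled design ``xa = X A^-1`` and kernel
    ``X A^-1 X'`` depend only on alpha and may be passed in precomputed.
    """
    n, m = x.shape
    w = w0.copy()
    dual = m > n
    if dual and kernel is None:
        xa = x / alpha  # n x m, columns scaled by 1/alpha_i
        kernel = xa @ x.T  # X A^-1 X'

    def objective(wv: np.ndarray) -> float:
        eta = x @ wv
        ll = np.sum(y * eta - np.logaddexp(0.0, eta))
        return -ll + 0.5 * np.sum(alpha * wv**2)

    for _ in range(max_newton):
        p = _sigmoid(x @ w)
        g = x.T @ (p - y) + alpha * w
        if np.max(np.abs(g)) < tol * max(1.0, np.max(np.abs(w))):
            break
        wdiag = np.maximum(p * (1 - p), 1e-10)
        if dual:
            ag = g / alpha
            core = kernel + np.diag(1.0 / wdiag)
            step = ag - xa.T @ np.linalg.solve(core, x @ ag)
        else:
            h = (x.T * wdiag) @ x
            h[np.diag_indices_from(h)] += alpha
            step = np.linalg.solve(h, g)
        f0 = objective(w)
        accept_tol = 1e-10 * (1.0 + abs(f0))
        t = 1.0
        w_new = w
        for _ in range(30):
            cand = w - t * step
            if objective(cand) <= f0 + accept_tol:
                w_new = cand
                break
            t *= 0.5
        if np.array_equal(w_new, w):
            break  # no descent possible: already at the mode to float precision
        w = w_new
    return w


def _posterior_variances(
    x: np.ndarray,
    w: np.ndarray,
    alpha: np.ndarray,
    xa: np.ndarray | None = None,
    kernel: np.ndarray | None = None,
) -> np.ndarray:
    """Diagonal of the Laplace covariance (X'WX + A)^-1.

    Uses the Woodbury identity when there are more features than samples, so
    the cost is O(n^2 m) rather than O(m^3); the alpha-scaled design and
    kernel may be passed in precomputed.
    """
    n, m = x.shape
    p = _sigmoid(x @ w)
    wdiag = np.maximum(p * (1 - p), 1e-10)
    if m <= n:
        h = (x.T * wdiag) @ x
        h[np.diag_indices_from(h)] += alpha
        return np.diag(np.linalg.inv(h))
    # Sigma = A^-1 - A^-1 X' (W^-1 + X A^-1 X')^-1 X A^-1
    if kernel is None:
        xa = x / alpha  # n x m, columns scaled by 1/alpha_i
        kernel = xa @ x.T
    core = kernel + np.diag(1.0 / wdiag)
    sol = np.linalg.solve(core, xa)  # n x m
    return 1.0 / alpha - np.einsum("ij,ij->j", xa, sol)


def slr_fit(
    z_matrix: np.ndarray,
    labels: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-4,
    prune_alpha: float = PRUNE_ALPHA,
    alpha0: np.ndarray | None = None,
    w0: np.ndarray | None = None,
) -> SlrModel:
    """Fit the ARD logistic classifier.

    Parameters
    ----------
    z_matrix : ndarray, shape (n, m)
        Reduced feature matrix (m = 0 gives a bias-only model whose bias is
        the log class-odds).
    labels : ndarray of 0/1
        Diagnosis labels; both classes must be present.
    alpha0, w0 : ndarray of length m+1, optional
        Warm-start precisions and weights (bias last). The default is the
        cold start: all precisions 1, weights 0. A warm start from a model
        fitted on a subset of the same training rows speeds convergence
        without changing what data the fit sees.
    """
    z_matrix = np.asarray(z_matrix, dtype=float)
    if z_matrix.ndim == 1:
        z_matrix = z_matrix[:, None]
    y = np.asarray(labels, dtype=float).ravel()
    n = len(y)
    if z_matrix.shape[0] != n:
        raise ValueError("feature matrix and labels disagree on n")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    m = z_matrix.shape[1]

    mean = z_matrix.mean(axis=0) if m else np.zeros(0)
    sd = z_matrix.std(axis=0, ddof=0) if m else np.zeros(0)
    sd = np.where(sd == 0, 1.0, sd)
    x_full = np.column_stack([(z_matrix - mean) / sd, np.ones(n)])

    if alpha0 is not None:
        alpha_full = np.asarray(alpha0, dtype=float).copy()
        if alpha_full.shape != (m + 1,):
            raise ValueError("alpha0 must have length m+1")
    else:
        alpha_full = np.ones(m + 1)
    alpha_full[-1] = BIAS_ALPHA
    weights_full = (
        np.zeros(m + 1) if w0 is None else np.asarray(w0, dtype=float).copy()
    )
    active = np.flatnonzero(alpha_full <= prune_alpha)  # position m is the bias
    if m not in active:
        active = np.append(active, m)
    w = weights_full[active]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        x = x_full[:, active]
        alpha = alpha_full[active]
        if x.shape[1] > len(y):
            xa = x / alpha
            kernel = xa @ x.T
        else:
            xa = kernel = None
        w = _map_estimate(x, y, alpha, w, xa=xa, kernel=kernel)
        sigma_diag = _posterior_variances(x, w, alpha, xa=xa, kernel=kernel)
        gamma = np.clip(1.0 - alpha * sigma_diag, 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_new = np.where(w**2 > 0, gamma / w**2, np.inf)
        alpha_new = np.clip(alpha_new, 1e-12, 1e12)
        alpha_new[active == m] = BIAS_ALPHA  # bias prior fixed, never pruned
        rel = np.abs(alpha_new - alpha) / alpha
        rel[active == m] = 0.0
        alpha_full[active] = alpha_new
        keep = (alpha_new <= prune_alpha) | (active == m)
        if not np.all(keep):
            weights_full[:] = 0.0
            active = active[keep]
            w = w[keep]
        if np.max(rel, initial=0.0) < tol:
            converged = True
            break
    # final mode at the converged precisions
    x = x_full[:, active]
    w = _map_estimate(x, y, alpha_full[active], w)
    weights_full[:] = 0.0
    weights_full[active] = w
    feature_active = active[active < m]
    return SlrModel(
        weights=weights_full,
        alphas=alpha_full,
        active_set=feature_active,
        feature_mean=mean,
        feature_sd=sd,
        fit_log={"iterations": it, "converged": bool(converged)},
    )


def wls_score(model: SlrModel, z: np.ndarray) -> ClassifierScore:
    """Weighted linear summation of a subject's reduced feature vector.

    The input is standardized with the model's training statistics,
    augmented with the constant 1, and dotted with the weights; the label is
    1 iff the WLS is strictly positive (threshold WLS = 0).
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    if z.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {z.shape[1]}"
        )
    if model.n_features:
        zhat = (z - model.feature_mean) / model.feature_sd
    else:
        zhat = z
    x = np.column_stack([zhat, np.ones(z.shape[0])])
    wls = x @ model.weights
    return ClassifierScore(
        wls=wls, probability=_sigmoid(wls), label=(wls > 0).astype(int)
    )
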