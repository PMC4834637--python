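"""Statistics characterizing an identified FC set.

Works on per-FC annotation tables: the two terminal regions of each FC, their
lateralities (L/R/M), intrinsic-network labels (CO, DM, FP, SM, OC, CB),
optional MNI centroids, and the group-mean correlations r_control / r_case.
A packaged fixture (``load_classifier_annotations``) transcribes the
published 16-FC autism classifier table so the composition statistics can be
recomputed from printed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from fcbiomarker.evaluation import binomial_pvalue

__all__ = [
    "ScorePredictionResult",
    "load_classifier_annotations",
    "laterality_counts",
    "laterality_binomial_test",
    "network_enrichment",
    "under_over_test",
    "distance_stats",
    "predict_domain_score",
    "bootstrap_score_null",
]

LATERALITIES = frozenset({"L", "R", "M"})
NETWORKS = frozenset({"CO", "DM", "FP", "SM", "OC", "CB"})


def load_classifier_annotations() -> pd.DataFrame:
    """Packaged annotation table of the published 16-FC autism classifier."""
    with resources.files("fcbiomarker.data").joinpath(
        "classifier_fc_annotations.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def _check_lateralities(annotations: pd.DataFrame) -> None:
    seen = set(annotations["lat1"]) | set(annotations["lat2"])
    unknown = seen - LATERALITIES
    if unknown:
        raise ValueError(f"unknown laterality codes: {sorted(unknown)}")


def laterality_counts(annotations: pd.DataFrame) -> dict[str, int]:
    """Counts of left-intra, right-intra and inter-hemispheric FCs.

    Both terminals left -> left-intra; both right -> right-intra; any other
    combination — including a medial (M) terminal — counts as
    inter-hemispheric.
    """
    _check_lateralities(annotations)
    counts = {"left_intra": 0, "right_intra": 0, "inter": 0}
    for lat1, lat2 in zip(annotations["lat1"], annotations["lat2"]):
        if lat1 == lat2 == "L":
            counts["left_intra"] += 1
        elif lat1 == lat2 == "R":
            counts["right_intra"] += 1
        else:
            counts["inter"] += 1
    return counts


def laterality_binomial_test(
    annotations: pd.DataFrame,
    category: str = "left_intra",
    null_fraction: float | None = None,
    n_regions_per_side: tuple[int, int, int] = (67, 67, 6),
) -> dict:
    """One-sided binomial test on a laterality category's count.

    The published analysis reports the absence of left-intra-hemispheric FCs
    as significant without stating the null proportion. Two candidate nulls
    are supported: pass ``null_fraction`` explicitly, or leave it ``None`` to
    use the fraction of left–left pairs among all region pairs implied by
    ``n_regions_per_side`` (left, right, medial counts). The test is
    lower-tailed for an observed count below expectation, upper-tailed
    otherwise.
    """
    counts = laterality_counts(annotations)
    if category not in counts:
        raise ValueError(f"unknown category {category!r}")
    n = int(sum(counts.values()))
    k = counts[category]
    if null_fraction is None:
        n_left, n_right, n_medial = n_regions_per_side
        total = n_left + n_right + n_medial
        pairs = total * (total - 1) / 2
        if category == "left_intra":
            cat_pairs = n_left * (n_left - 1) / 2
        elif category == "right_intra":
            cat_pairs = n_right * (n_right - 1) / 2
        else:
            cat_pairs = pairs - n_left * (n_left - 1) / 2 - n_right * (n_right - 1) / 2
        null_fraction = cat_pairs / pairs
    if k < n * null_fraction:
        p = float(stats.binom.cdf(k, n, null_fraction))
        side = "lower"
    else:
        p = binomial_pvalue(k, n, null_fraction)
        side = "upper"
    return {
        "count": k,
        "n": n,
        "null_fraction": float(null_fraction),
        "p_value": p,
        "tail": side,
    }


def network_enrichment(
    annotations: pd.DataFrame,
    network: str,
    n_network_regions: int,
    n_total_regions: int,
) -> dict:
    """Enrichment of one network among the FC terminals.

    Terminals are counted with duplicates (2 per FC), the expected fraction
    is ``n_network_regions / n_total_regions`` and the p-value is the exact
    one-sided upper-tail binomial probability.
    """
    if network not in NETWORKS:
        raise ValueError(f"unknown network {network!r}")
    terminals = pd.concat([annotations["net1"], annotations["net2"]])
    observed = int((terminals == network).sum())
    n_terminals = len(terminals)
    expected = n_network_regions / n_total_regions
    return {
        "observed": observed,
        "n_terminals": n_terminals,
        "observed_fraction": observed / n_terminals,
        "expected_fraction": expected,
        "p_value": binomial_pvalue(observed, n_terminals, expected),
    }


def under_over_test(
    annotations: pd.DataFrame,
    case_col: str = "r_asd",
    control_col: str = "r_td",
) -> dict:
    """Counts of under- vs over-connected FCs and a chi-square test.

    Under-connectivity means the case-group mean correlation is below the
    control-group mean (r_case < r_control). Ties are excluded from the
    goodness-of-fit test (against equal expected counts, df = 1) and
    reported separately.
    """
    diff = annotations[case_col].to_numpy() - annotations[control_col].to_numpy()
    under = int(np.sum(diff < 0))
    over = int(np.sum(diff > 0))
    ties = int(np.sum(diff == 0))
    chi2, p = stats.chisquare([under, over])
    return {
        "under": under,
        "over": over,
        "ties": ties,
        "chi2": float(chi2),
        "p_value": float(p),
    }


def distance_stats(
    annotations: pd.DataFrame | None = None,
    case_col: str = "r_asd",
    control_col: str = "r_td",
    summary: tuple[tuple[float, float, int], tuple[float, float, int]] | None = None,
) -> dict:
    """Distance analyses of an FC set.

    With per-FC centroids (columns ``x1,y1,z1,x2,y2,z2`` in mm), computes the
    Euclidean terminal-to-terminal distance of each FC and correlates it with
    the connectivity change (r_case - r_control) and with the absolute-
    strength change (|r_case| - |r_control|), plus a pooled-variance
    two-sample t-test of under- vs over-connected FC distances.

    Alternatively ``summary`` supplies ((mean, sd, n), (mean, sd, n)) for the
    under/over groups directly and only the t-test is computed.
    """
    out: dict = {}
    if summary is not None:
        (m1, s1, n1), (m2, s2, n2) = summary
        t, p = stats.ttest_ind_from_stats(m1, s1, n1, m2, s2, n2, equal_var=True)
        out["t"] = float(t)
        out["df"] = n1 + n2 - 2
        out["p_value"] = float(p)
        return out
    if annotations is None:
        raise ValueError("need annotations with centroids or summary stats")
    needed = ["x1", "y1", "z1", "x2", "y2", "z2"]
    if not all(c in annotations.columns for c in needed):
        raise ValueError("annotations lack centroid columns and no summary given")
    a = annotations[["x1", "y1", "z1"]].to_numpy(dtype=float)
    b = annotations[["x2", "y2", "z2"]].to_numpy(dtype=float)
    dist = np.linalg.norm(a - b, axis=1)
    r_case = annotations[case_col].to_numpy(dtype=float)
    r_ctrl = annotations[control_col].to_numpy(dtype=float)
    diff = r_case - r_ctrl
    abs_diff = np.abs(r_case) - np.abs(r_ctrl)
    r1, p1 = stats.pearsonr(dist, diff)
    r2, p2 = stats.pearsonr(dist, abs_diff)
    out["r_vs_change"] = (float(r1), float(p1))
    out["r_vs_abs_change"] = (float(r2), float(p2))
    under = dist[diff < 0]
    over = dist[diff > 0]
    if len(under) >= 2 and len(over) >= 2:
        t, p = stats.ttest_ind(under, over, equal_var=True)
        out["t"] = float(t)
        out["df"] = len(under) + len(over) - 2
        out["p_value"] = float(p)
    out["distances"] = dist
    return out


@dataclass
class ScorePredictionResult:
    """Leave-one-out clinical-score prediction from an FC subset."""

    predicted: np.ndarray
    measured: np.ndarray
    pearson_r: float
    p_value: float
    bootstrap_p: float | None = None


def predict_domain_score(
    fc_subset_matrix: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    scores: np.ndarray,
) -> ScorePredictionResult:
    """Leave-one-out linear prediction of a clinical domain score.

    For every subject an ordinary least-squares model (FC values + age + sex
    + intercept) is fit on the other N-1 subjects and used to predict the
    held-out score; agreement is the Pearson correlation between measured
    and predicted scores with its two-sided p-value.
    """
    x = np.column_stack(
        [np.asarray(fc_subset_matrix, dtype=float), age, sex, np.ones(len(scores))]
    )
    y = np.asarray(scores, dtype=float).ravel()
    n = len(y)
    if n <= x.shape[1] + 1:
        raise ValueError("too few subjects for the number of predictors")
    if np.ptp(y) == 0:
        raise ValueError("constant measured scores: correlation undefined")
    # Exact leave-one-out OLS via the hat-matrix identity: deleting subject i
    # changes its prediction to y_i - e_i / (1 - h_ii), identical to refitting
    # on the other N-1 subjects but a single decomposition for all subjects.
    q, _ = np.linalg.qr(x)
    leverage = np.einsum("ij,ij->i", q, q)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    residual = y - x @ beta
    predicted = y - residual / np.clip(1.0 - leverage, 1e-12, None)
    r, p = stats.pearsonr(y, predicted)
    return ScorePredictionResult(
        predicted=predicted, measured=y, pearson_r=float(r), p_value=float(p)
    )


def bootstrap_score_null(
    full_fc_matrix: np.ndarray,
    excluded_indices: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    all_domain_scores: list[np.ndarray],
    observed_r: float,
    n_select: int = 16,
    n_boot: int = 10000,
    seed: int = 0,
) -> dict:
    """Bootstrap null for a clinical-score correlation.

    Each repetition samples ``n_select`` FCs uniformly without replacement
    from the eligible pool (all FC columns minus ``excluded_indices`` — the
    ever-selected classifier FCs), runs the leave-one-out score prediction
    for every clinical domain, and records the maximum of the domain
    correlations. The p-value is the fraction of repetitions whose pooled
    maximum reaches the observed correlation. Domains with missing subjects
    are handled by listwise deletion per domain (NaN scores dropped).
    """
    x2 = np.asarray(full_fc_matrix, dtype=float)
    excluded = np.asarray(excluded_indices, dtype=int)
    eligible = np.setdiff1d(np.arange(x2.shape[1]), excluded)
    if len(eligible) < n_select:
        raise ValueError("fewer eligible FCs than the selection size")
    rng = np.random.default_rng(seed)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    max_r = np.empty(n_boot)
    for b in range(n_boot):
        cols = rng.choice(eligible, size=n_select, replace=False)
        best = -np.inf
        for scores in all_domain_scores:
            scores = np.asarray(scores, dtype=float)
            ok = np.isfinite(scores)
            res = predict_domain_score(
                x2[np.ix_(ok, cols)], age[ok], sex[ok], scores[ok]
            )
            best = max(best, res.pearson_r)
        max_r[b] = best
    p = float(np.mean(max_r >= observed_r))
    return {"p_value": p, "null_max_r": max_r, "pool_size": len(eligible)}
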