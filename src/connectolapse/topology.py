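"""Shortest weighted path lengths and connection-atrophy scores.

Topological connection length between two regions is the shortest weighted
path length on the (healthy-control-averaged) network: each edge gets length
1/weight — stronger connections are shorter — and Dijkstra's algorithm
yields all-pairs minimum summed lengths.  Pairs with no connecting path are
infinite and excluded (with a logged count) from correlation analyses.

Atrophy is standardized per connection against the control distribution:

    Z_C = (C_k - mean(C_controls)) / sd(C_controls)        cross-sectional
    Z_R = (R_k - mean(R_controls)) / sd(R_controls)        longitudinal

where C is (residualized) connection strength at baseline and R the
per-subject least-squares slope of strength over time.  Z-scores are mapped
to a bounded (0, 1) atrophy score by a logistic transform, oriented so that
weaker-than-control strength (Z < 0) scores above 0.5 — higher score, more
atrophy.  The literal symmetric variant 1/(exp(-Z) + exp(+Z)) (= sech(Z)/2)
is exposed for comparison; it is non-monotone and peaks at Z = 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from connectolapse.io import LongDataset
from connectolapse.subtypes import SubtypeLabel, analysed_pairs, classify_pair

logger = logging.getLogger(__name__)

__all__ = [
    "to_length_matrix",
    "shortest_paths",
    "zscore_cross",
    "zscore_rate",
    "transform_score",
    "fit_subject_slope",
    "residualize",
    "length_atrophy_correlation",
    "anova_subtypes",
    "tukey_kramer",
    "compute_atrophy_table",
    "CorrelationResult",
]


def to_length_matrix(W: np.ndarray) -> np.ndarray:
    """Connection-lengths matrix: 1/W off-diagonal (inf where W=0), 0 diagonal."""
    W = np.asarray(W, dtype=float)
    if not np.allclose(W, W.T):
        raise ValueError("W must be symmetric")
    if (W < 0).any():
        raise ValueError("W must be nonnegative")
    with np.errstate(divide="ignore"):
        L = np.where(W > 0, 1.0 / np.where(W > 0, W, 1.0), np.inf)
    np.fill_diagonal(L, 0.0)
    return L


def shortest_paths(length_matrix: np.ndarray) -> np.ndarray:
    """All-pairs shortest weighted path lengths (Dijkstra); inf = disconnected."""
    Lm = np.asarray(length_matrix, dtype=float)
    if (Lm < 0).any():
        raise ValueError("edge lengths must be nonnegative")
    finite = np.isfinite(Lm) & (Lm > 0)
    graph = csr_matrix((Lm[finite], np.nonzero(finite)), shape=Lm.shape)
    D = dijkstra(graph, directed=False)
    n_disconnected = int(np.isinf(D[np.triu_indices_from(D, k=1)]).sum())
    if n_disconnected:
        logger.warning("%d region pairs are disconnected (infinite path length)", n_disconnected)
    return D


def zscore_cross(c_k: float, controls: Sequence[float]) -> float:
    """Cross-sectional atrophy Z-score against the control distribution (sample SD)."""
    controls = np.asarray(controls, dtype=float)
    if controls.size < 2:
        raise ValueError("need at least 2 control values")
    sd = controls.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate connection: zero control variance")
    return float((c_k - controls.mean()) / sd)


def zscore_rate(r_k: float, control_rates: Sequence[float]) -> float:
    """Longitudinal atrophy Z-score of a strength-change rate; same convention."""
    return zscore_cross(r_k, control_rates)


def transform_score(z, variant: str = "logistic"):
    """Map an atrophy Z-score into (0, 1].

    ``logistic`` (default): 1/(1 + e^z), strictly decreasing in z, so that
    below-control strength (z < 0) maps above 0.5.  ``literal``:
    1/(e^-z + e^z), the symmetric bell variant (max 0.5 at z = 0).
    """
    z = np.asarray(z, dtype=float)
    if variant == "logistic":
        out = 1.0 / (1.0 + np.exp(z))
    elif variant == "literal":
        out = 1.0 / (np.exp(-z) + np.exp(z))
    else:
        raise ValueError(f"unknown transform variant {variant!r}")
    return float(out) if out.ndim == 0 else out


def fit_subject_slope(times: Sequence[float], values: Sequence[float]) -> float:
    """Ordinary least-squares slope of values over time (the atrophy rate)."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2 or np.unique(t).size < 2:
        raise ValueError("need >= 2 distinct time points for a slope")
    tc = t - t.mean()
    return float(tc @ (y - y.mean()) / (tc @ tc))


def residualize(values: np.ndarray, age: Sequence[float], sex: Sequence) -> np.ndarray:
    """OLS residuals of per-subject values on intercept + age + sex.

    ``values`` may be 1-D (one connection) or 2-D (subjects x connections);
    ``sex`` may be numeric or 'M'/'F' codes.
    """
    values = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    if sex.dtype.kind in "US":
        sex = (sex == "F").astype(float)
    sex = sex.astype(float)
    n = age.shape[0]
    if values.shape[0] != n or sex.shape[0] != n:
        raise ValueError("values, age and sex must agree on the number of subjects")
    if n < 3:
        raise ValueError("need >= 3 subjects to residualize")
    X = np.column_stack([np.ones(n), age, sex])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient design (constant age or sex)")
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p: float
    df: int
    n: int
    n_excluded: int


def length_atrophy_correlation(
    lengths: Sequence[float], scores: Sequence[float]
) -> CorrelationResult:
    """Spearman rank correlation between path length and mean atrophy score.

    Pairs with non-finite length or score (disconnected or degenerate
    connections) are excluded; the count is reported and logged.
    """
    L = np.asarray(lengths, dtype=float)
    s = np.asarray(scores, dtype=float)
    if L.shape != s.shape:
        raise ValueError("lengths and scores must be paired")
    keep = np.isfinite(L) & np.isfinite(s)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("excluding %d non-finite connection pairs from correlation", n_excluded)
    L, s = L[keep], s[keep]
    if L.size < 3:
        raise ValueError("need >= 3 finite pairs for a correlation")
    res = stats.spearmanr(L, s)
    return CorrelationResult(
        rho=float(res.statistic), p=float(res.pvalue), df=L.size - 2, n=L.size, n_excluded=n_excluded
    )


def anova_subtypes(groups: Mapping[str, Sequence[float]]) -> tuple[float, int, int, float]:
    """One-way ANOVA of path length across connection subtypes: (F, df1, df2, p)."""
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 members each")
    F, p = stats.f_oneway(*arrays)
    df1 = len(arrays) - 1
    df2 = sum(a.size for a in arrays) - len(arrays)
    return float(F), df1, df2, float(p)


def tukey_kramer(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Tukey-Kramer pairwise comparisons (honest significant differences
    with the unequal-sample-size correction); one row per group pair."""
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in names]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 members each")
    res = stats.tukey_hsd(*arrays)
    rows = []
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            rows.append(
                {
                    "group_a": names[a],
                    "group_b": names[b],
                    "mean_diff": float(arrays[a].mean() - arrays[b].mean()),
                    "p_adj": float(res.pvalue[a, b]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# edge-level atrophy table


def _strength_matrix(dataset: LongDataset, visit: int, pairs: np.ndarray, subjects: list[str]) -> np.ndarray:
    """Subjects x pairs strengths at one visit; NaN where the visit is missing."""
    out = np.full((len(subjects), pairs.shape[0]), np.nan)
    index = {s: i for i, s in enumerate(subjects)}
    for obs in dataset.observations:
        if obs.visit == visit and obs.subject_id in index:
            out[index[obs.subject_id]] = obs.W[pairs[:, 0], pairs[:, 1]]
    return out


def compute_atrophy_table(
    dataset: LongDataset,
    partition: Mapping[int, int],
    path_lengths: np.ndarray,
    transform: str = "logistic",
    adjust_age_sex: bool = True,
) -> pd.DataFrame:
    """Per-connection atrophy scores paired with path lengths.

    For every analysed region pair (cortical-cortical and striatal-cortical):

    - cross-sectional: baseline strengths, optionally residualized on age and
      sex across all subjects, are Z-scored per preHD subject against the
      control distribution, transformed, and averaged over the preHD group;
    - longitudinal: per-subject least-squares slopes over time (subjects with
      every visit only), residualized, Z-scored and transformed the same way.

    Returns a DataFrame with columns i, j, subtype, L, score_cross,
    score_long (NaN where the control SD is zero — degenerate connections).
    """
    atlas = dataset.atlas
    pairs = np.asarray(analysed_pairs(atlas), dtype=int)
    records = dataset.records_by_subject
    subjects = [c.subject_id for c in dataset.cohort]
    is_control = np.array([records[s].group == "control" for s in subjects])
    is_prehd = ~is_control
    age = np.array([records[s].age for s in subjects])
    sex = np.array([records[s].sex for s in subjects])

    # --- cross-sectional: baseline strengths
    S = _strength_matrix(dataset, 1, pairs, subjects)
    have_base = ~np.isnan(S).any(axis=1)
    score_cross = _group_scores(
        S[have_base], is_control[have_base], is_prehd[have_base],
        age[have_base], sex[have_base], transform, adjust_age_sex,
    )

    # --- longitudinal: slopes for subjects with all visits
    all_visits = sorted({obs.visit for obs in dataset.observations})
    per_visit = [_strength_matrix(dataset, v, pairs, subjects) for v in all_visits]
    complete = ~np.any([np.isnan(m).any(axis=1) for m in per_visit], axis=0)
    times = np.array([float(v - 1) for v in all_visits])
    stacked = np.stack([m[complete] for m in per_visit])  # visits x subjects x pairs
    tc = times - times.mean()
    slopes = np.tensordot(tc, stacked - stacked.mean(axis=0), axes=(0, 0)) / (tc @ tc)
    score_long = _group_scores(
        slopes, is_control[complete], is_prehd[complete],
        age[complete], sex[complete], transform, adjust_age_sex,
    )

    subtype = [classify_pair(int(i), int(j), atlas, partition).value for i, j in pairs]
    return pd.DataFrame(
        {
            "i": pairs[:, 0],
            "j": pairs[:, 1],
            "subtype": subtype,
            "L": path_lengths[pairs[:, 0], pairs[:, 1]],
            "score_cross": score_cross,
            "score_long": score_long,
        }
    )


def _group_scores(
    values: np.ndarray,
    is_control: np.ndarray,
    is_prehd: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    transform: str,
    adjust_age_sex: bool,
) -> np.ndarray:
    """Mean transformed Z-score over the preHD group, per connection (column)."""
    if is_control.sum() < 2 or is_prehd.sum() < 1:
        raise ValueError("need >= 2 controls and >= 1 preHD subject")
    if adjust_age_sex:
        values = residualize(values, age, sex)
    mu = values[is_control].mean(axis=0)
    sd = values[is_control].std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        logger.info("%d degenerate connections (zero control SD) flagged NaN", int(degenerate.sum()))
    sd = np.where(degenerate, np.nan, sd)
    Z = (values[is_prehd] - mu) / sd
    return transform_score(Z, variant=transform).mean(axis=0)
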