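"""Human-evaluation mathematics: majority-vote consensus, micro-averaged
confusion-matrix metrics with Wald and Wilson confidence intervals,
topic-level accuracy summaries, Likert/SSI aggregation, and inter-rater
reliability coefficients (Fleiss' and pairwise Cohen's kappa,
Krippendorff's alpha at nominal/ordinal level, and two-way random-effects
ICC in single- and average-measure form).

All coefficients are implemented from their defining formulas.  Degenerate
cases (zero expected disagreement, undefined precision) surface as explicit
``undefined`` flags rather than silent zeros.

Two interval constructions are reported for each proportion because the
literature this framework serves rarely states which one was used: the
Wald interval p +/- 1.96*sqrt(p(1-p)/n) and the Wilson score interval.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Coefficient:
    """A reliability coefficient that may be undefined for degenerate data."""

    value: float | None
    undefined: bool = False
    reason: str = ""

    def __float__(self) -> float:
        if self.undefined or self.value is None:
            raise ValueError(f"coefficient is undefined: {self.reason}")
        return self.value


@dataclass
class RatingRecord:
    query_id: str
    reviewer_id: str
    correct: int  # binary
    completeness: int  # 1-5 Likert
    consistency: int  # 1-5 Likert
    ssi: int  # 0-3

    def __post_init__(self) -> None:
        if self.correct not in (0, 1):
            raise ValueError("correct must be binary")
        if not 1 <= self.completeness <= 5 or not 1 <= self.consistency <= 5:
            raise ValueError("Likert ratings must lie in 1-5")
        if not 0 <= self.ssi <= 3:
            raise ValueError("SSI must lie in 0-3")


def consensus(labels: dict[str, list[int]], n_reviewers: int = 3) -> dict[str, int]:
    """Majority-vote consensus per query (ties impossible with 3 reviewers)."""
    out: dict[str, int] = {}
    for qid, votes in labels.items():
        if len(votes) != n_reviewers:
            raise ValueError(f"query {qid!r} has {len(votes)} labels, expected {n_reviewers}")
        out[qid] = int(sum(votes) >= (n_reviewers / 2 + 0.5))
    return out


def _wald_ci(p: float, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    half = z * math.sqrt(p * (1.0 - p) / n)
    return max(0.0, p - half), min(1.0, p + half)


def _wilson_ci(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    p = k / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1.0 - p) / n + z * z / (4 * n * n))
    return max(0.0, centre - half), min(1.0, centre + half)


def classification_metrics(cm: ConfusionMatrix) -> dict:
    """Micro-averaged accuracy/precision/recall/F1 with 95% CIs.

    Precision with tp+fp = 0 is reported as undefined, never as 0.
    """
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    accuracy = (cm.tp + cm.tn) / cm.n
    pos = cm.tp + cm.fn
    recall = cm.tp / pos if pos else None
    pred_pos = cm.tp + cm.fp
    precision = cm.tp / pred_pos if pred_pos else None
    if precision is not None and recall is not None and (precision + recall) > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = None
    out = {
        "accuracy": accuracy,
        "precision": precision,
        "precision_undefined": pred_pos == 0,
        "recall": recall,
        "f1": f1,
        "n": cm.n,
        "accuracy_ci_wald": _wald_ci(accuracy, cm.n),
        "accuracy_ci_wilson": _wilson_ci(cm.tp + cm.tn, cm.n),
    }
    if recall is not None:
        out["recall_ci_wald"] = _wald_ci(recall, pos)
        out["recall_ci_wilson"] = _wilson_ci(cm.tp, pos)
    return out


def topic_accuracy(per_topic: dict[str, tuple[int, int]]) -> dict:
    """Per-topic accuracy with unweighted mean, sample SD (n-1) and range."""
    if not per_topic:
        raise ValueError("no topics")
    acc: dict[str, float] = {}
    for topic, (correct, total) in per_topic.items():
        if total <= 0:
            raise ValueError(f"topic {topic!r} has no evaluated queries")
        acc[topic] = correct / total
    values = np.array(list(acc.values()))
    return {
        "per_topic": acc,
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        "range": (float(values.min()), float(values.max())),
    }


def likert_summary(records: list[RatingRecord], fieldname: str) -> dict:
    if fieldname not in ("completeness", "consistency", "ssi"):
        raise ValueError("field must be completeness, consistency or ssi")
    if not records:
        raise ValueError("no ratings")
    values = [getattr(r, fieldname) for r in records]
    by_reviewer: dict[str, list[int]] = {}
    dist: dict[int, int] = {}
    for r in records:
        v = getattr(r, fieldname)
        by_reviewer.setdefault(r.reviewer_id, []).append(v)
        dist[v] = dist.get(v, 0) + 1
    return {
        "mean": float(np.mean(values)),
        "per_reviewer": {k: float(np.mean(v)) for k, v in sorted(by_reviewer.items())},
        "distribution": dict(sorted(dist.items())),
        "n": len(values),
    }


def fleiss_kappa(table: np.ndarray) -> Coefficient:
    """Fleiss' kappa from an items x categories count matrix.

    Each row must sum to the (constant) number of raters n:
    ``P_i = (sum_j n_ij^2 - n) / (n(n-1))``, ``kappa = (Pbar - Pe)/(1 - Pe)``
    with ``Pe = sum_j p_j^2`` from pooled category proportions.
    """
    table = np.asarray(table, dtype=float)
    if table.ndim != 2 or table.shape[0] < 1:
        raise ValueError("need an items x categories matrix")
    n_raters = table[0].sum()
    if n_raters < 2 or not np.allclose(table.sum(axis=1), n_raters):
        raise ValueError("every item must have the same number (>=2) of ratings")
    n_items = table.shape[0]
    p_i = (np.square(table).sum(axis=1) - n_raters) / (n_raters * (n_raters - 1))
    p_bar = float(p_i.mean())
    p_j = table.sum(axis=0) / (n_items * n_raters)
    p_e = float(np.square(p_j).sum())
    if math.isclose(p_e, 1.0):
        return Coefficient(None, undefined=True, reason="expected agreement is 1 (single category)")
    return Coefficient(float((p_bar - p_e) / (1.0 - p_e)))


def cohen_kappa(a: np.ndarray, b: np.ndarray) -> Coefficient:
    """Cohen's kappa for two raters over the same items (any category set)."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1 or len(a) == 0:
        raise ValueError("need two equal-length label vectors")
    cats = sorted(set(a.tolist()) | set(b.tolist()))
    n = len(a)
    p_o = float(np.mean(a == b))
    p_e = sum(
        (np.sum(a == c) / n) * (np.sum(b == c) / n) for c in cats
    )
    if math.isclose(p_e, 1.0):
        return Coefficient(None, undefined=True, reason="expected agreement is 1")
    return Coefficient(float((p_o - p_e) / (1.0 - p_e)))


def pairwise_cohen_kappa(labels: np.ndarray) -> dict:
    """Per-pair Cohen's kappa over a reviewers x items matrix, plus mean/range."""
    labels = np.asarray(labels)
    if labels.ndim != 2 or labels.shape[0] < 2:
        raise ValueError("need >=2 reviewers")
    pairs = {}
    for i, j in itertools.combinations(range(labels.shape[0]), 2):
        pairs[(i, j)] = cohen_kappa(labels[i], labels[j])
    defined = [float(c) for c in pairs.values() if not c.undefined]
    return {
        "per_pair": pairs,
        "mean": float(np.mean(defined)) if defined else None,
        "range": (min(defined), max(defined)) if defined else None,
    }


def _ordinal_distance_sq(n_c: np.ndarray) -> np.ndarray:
    """Krippendorff ordinal distance^2 matrix from category margins n_c."""
    k = len(n_c)
    d = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            span = n_c[i : j + 1].sum() - (n_c[i] + n_c[j]) / 2.0
            d[i, j] = d[j, i] = span * span
    return d


def krippendorff_alpha(data: np.ndarray, level: str = "nominal") -> Coefficient:
    """Krippendorff's alpha from a raters x items matrix (NaN = missing).

    Built on the coincidence matrix: ``alpha = 1 - D_o / D_e`` where the
    observed disagreement pools value pairs within items (each item
    weighted by 1/(m_u - 1)) and the expected disagreement uses all value
    pairs.  Distance is 0/1 for nominal data and the squared cumulative
    margin for ordinal data.
    """
    if level not in ("nominal", "ordinal"):
        raise ValueError("level must be nominal or ordinal")
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("need a raters x items matrix")
    values = sorted({v for v in data.ravel() if not np.isnan(v)})
    if not values:
        raise ValueError("no ratings present")
    v_index = {v: i for i, v in enumerate(values)}
    k = len(values)
    coincidence = np.zeros((k, k))
    for item in data.T:
        present = [v for v in item if not np.isnan(v)]
        m = len(present)
        if m < 2:
            continue
        for a, b in itertools.permutations(present, 2):
            coincidence[v_index[a], v_index[b]] += 1.0 / (m - 1)
    n_c = coincidence.sum(axis=1)
    n_total = n_c.sum()
    if n_total < 2:
        return Coefficient(None, undefined=True, reason="fewer than 2 pairable values")
    if level == "nominal":
        dist = 1.0 - np.eye(k)
    else:
        dist = _ordinal_distance_sq(n_c)
    d_o = float((coincidence * dist).sum()) / n_total
    d_e = float((np.outer(n_c, n_c) * dist).sum()) / (n_total * (n_total - 1.0))
    if math.isclose(d_e, 0.0):
        return Coefficient(None, undefined=True, reason="zero expected disagreement (single shared category)")
    return Coefficient(float(1.0 - d_o / d_e))


def icc_two_way(ratings: np.ndarray, form: str = "single") -> Coefficient:
    """Two-way random-effects ICC from a complete items x raters matrix.

    ``ICC(2,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + k (MS_C - MS_E)/n)``
    ``ICC(2,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E)/n)``
    with MS_R/MS_C/MS_E the rows/columns/error mean squares of the two-way
    ANOVA decomposition (n items, k raters).
    """
    if form not in ("single", "average"):
        raise ValueError("form must be 'single' or 'average'")
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2 or np.isnan(x).any():
        raise ValueError("need a complete items x raters matrix with >=2 rows and columns")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * float(np.square(row_means - grand).sum())
    ss_cols = n * float(np.square(col_means - grand).sum())
    ss_total = float(np.square(x - grand).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    if form == "single":
        denom = ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n
    else:
        denom = ms_r + (ms_c - ms_e) / n
    if math.isclose(denom, 0.0):
        return Coefficient(None, undefined=True, reason="zero denominator (no variance)")
    return Coefficient(float((ms_r - ms_e) / denom))


@dataclass
class ReliabilityReport:
    fleiss_kappa: Coefficient
    pairwise_cohen: dict
    krippendorff_nominal: Coefficient
    krippendorff_ordinal: Coefficient | None = None
    icc_2_1: Coefficient | None = None
    icc_2_k: Coefficient | None = None


def reliability_report(
    binary_labels: np.ndarray,
    ordinal_ratings: np.ndarray | None = None,
) -> ReliabilityReport:
    """Full agreement suite from a reviewers x items binary matrix, plus an
    optional items x raters ordinal matrix (e.g. completeness) for ICC."""
    labels = np.asarray(binary_labels)
    n_rev, n_items = labels.shape
    table = np.zeros((n_items, 2))
    for i in range(n_items):
        ones = int(labels[:, i].sum())
        table[i] = (n_rev - ones, ones)
    report = ReliabilityReport(
        fleiss_kappa=fleiss_kappa(table),
        pairwise_cohen=pairwise_cohen_kappa(labels),
        krippendorff_nominal=krippendorff_alpha(labels.astype(float), "nominal"),
    )
    if ordinal_ratings is not None:
        report.krippendorff_ordinal = krippendorff_alpha(
            np.asarray(ordinal_ratings, dtype=float).T, "ordinal"
        )
        report.icc_2_1 = icc_two_way(ordinal_ratings, "single")
        report.icc_2_k = icc_two_way(ordinal_ratings, "average")
    return report
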