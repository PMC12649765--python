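"""Agreement coefficients and classification mathematics, each checked
against an independent oracle (manual arithmetic, brute-force pair
counting, or an established library implementation)."""

import itertools

import numpy as np
import pytest

from postopqa.eval_stats import (
    ConfusionMatrix,
    RatingRecord,
    classification_metrics,
    cohen_kappa,
    consensus,
    fleiss_kappa,
    icc_two_way,
    krippendorff_alpha,
    likert_summary,
    pairwise_cohen_kappa,
    reliability_report,
    topic_accuracy,
)

# ---------------------------------------------------------------------------
# consensus and classification
# ---------------------------------------------------------------------------


def test_majority_vote_consensus():
    labels = {"a": [1, 1, 0], "b": [0, 0, 0], "c": [1, 1, 1], "d": [0, 1, 0]}
    assert consensus(labels) == {"a": 1, "b": 0, "c": 1, "d": 0}


def test_consensus_matches_counting_oracle():
    rng = np.random.default_rng(0)
    labels = {f"q{i}": rng.integers(0, 2, size=3).tolist() for i in range(250)}
    got = consensus(labels)
    for qid, votes in labels.items():
        assert got[qid] == int(sum(votes) > 1.5)


def test_consensus_requires_complete_panels():
    with pytest.raises(ValueError):
        consensus({"a": [1, 0]})


def test_classification_metrics_headline_matrix():
    m = classification_metrics(ConfusionMatrix(tp=196, fp=0, fn=4, tn=50))
    assert m["accuracy"] == pytest.approx(0.984)
    assert m["precision"] == pytest.approx(1.0)
    assert m["recall"] == pytest.approx(0.98)
    assert round(m["f1"], 4) == 0.9899


def test_classification_metrics_perfect_and_degenerate():
    perfect = classification_metrics(ConfusionMatrix(10, 0, 0, 10))
    assert perfect["accuracy"] == perfect["precision"] == perfect["recall"] == perfect["f1"] == 1.0
    degenerate = classification_metrics(ConfusionMatrix(0, 0, 5, 5))
    assert degenerate["recall"] == 0.0
    assert degenerate["precision"] is None and degenerate["precision_undefined"]
    with pytest.raises(ValueError):
        classification_metrics(ConfusionMatrix(0, 0, 0, 0))


def test_confidence_intervals_match_statsmodels():
    from statsmodels.stats.proportion import proportion_confint

    m = classification_metrics(ConfusionMatrix(tp=196, fp=0, fn=4, tn=50))
    lo, hi = proportion_confint(246, 250, alpha=0.05, method="wilson")
    assert m["accuracy_ci_wilson"] == pytest.approx((lo, hi), abs=1e-9)
    lo, hi = proportion_confint(246, 250, alpha=0.05, method="normal")
    assert m["accuracy_ci_wald"] == pytest.approx((lo, hi), abs=1e-9)


def test_topic_accuracy_headline_summary():
    table = {f"t{i}": (10, 10) for i in range(18)}
    table.update({f"u{i}": (9, 10) for i in range(4)})
    summary = topic_accuracy(table)
    assert round(100 * summary["mean"], 1) == 98.2
    assert round(100 * summary["sd"], 1) == 3.9
    assert summary["range"] == (0.9, 1.0)


def test_topic_accuracy_constant_and_oracle():
    assert topic_accuracy({"a": (5, 5), "b": (7, 7)})["sd"] == 0.0
    rng = np.random.default_rng(1)
    table = {f"t{i}": (int(rng.integers(0, 11)), 10) for i in range(15)}
    summary = topic_accuracy(table)
    values = [c / t for c, t in table.values()]
    assert summary["mean"] == pytest.approx(np.mean(values))
    assert summary["sd"] == pytest.approx(np.std(values, ddof=1))


def make_ratings(values, fieldname="completeness"):
    out = []
    for i, v in enumerate(values):
        kwargs = {"completeness": 5, "consistency": 5, "ssi": 3, fieldname: v}
        out.append(RatingRecord(f"q{i % 3}", f"R{i % 3 + 1}", 1, **kwargs))
    return out


def test_likert_summary_arithmetic():
    assert likert_summary(make_ratings([5, 5, 5]), "completeness")["mean"] == 5.0
    assert likert_summary(make_ratings([5, 5, 4]), "completeness")["mean"] == pytest.approx(14 / 3)
    rng = np.random.default_rng(2)
    values = rng.integers(1, 6, size=60).tolist()
    got = likert_summary(make_ratings(values), "completeness")
    assert got["mean"] == pytest.approx(np.mean(values))
    assert sum(got["distribution"].values()) == 60


# ---------------------------------------------------------------------------
# Fleiss' kappa
# ---------------------------------------------------------------------------


def fleiss_pair_counting_oracle(table):
    """Count agreeing rater pairs directly (independent of the formula)."""
    table = np.asarray(table, dtype=int)
    n = table[0].sum()
    agree = sum(sum(c * (c - 1) for c in row) for row in table)
    total = len(table) * n * (n - 1)
    p_bar = agree / total
    p_j = table.sum(axis=0) / table.sum()
    p_e = float(np.square(p_j).sum())
    return (p_bar - p_e) / (1 - p_e)


def test_fleiss_kappa_perfect_agreement():
    table = np.array([[3, 0], [0, 3], [3, 0]])
    assert float(fleiss_kappa(table)) == pytest.approx(1.0)


def test_fleiss_kappa_single_item_formula_constant():
    # an item rated (2,1) across 3 raters has P_i = 1/3
    table = np.array([[2, 1]])
    n = 3
    p_i = (np.square(table[0]).sum() - n) / (n * (n - 1))
    assert p_i == pytest.approx(1 / 3)


def test_fleiss_kappa_matches_pair_counting_and_statsmodels():
    from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

    table = np.array(
        [[0, 0, 0, 4], [0, 2, 2, 0], [1, 1, 1, 1], [0, 0, 4, 0], [2, 0, 2, 0], [4, 0, 0, 0]]
    )
    got = float(fleiss_kappa(table))
    assert got == pytest.approx(fleiss_pair_counting_oracle(table))
    assert got == pytest.approx(sm_fleiss(table), abs=1e-12)


def test_fleiss_kappa_undefined_for_single_category():
    assert fleiss_kappa(np.array([[3, 0], [3, 0]])).undefined


# ---------------------------------------------------------------------------
# Cohen's kappa
# ---------------------------------------------------------------------------


def test_cohen_kappa_identity_and_toy_table():
    a = np.array([1, 0, 1, 1, 0, 0])
    assert float(cohen_kappa(a, a)) == pytest.approx(1.0)
    # hand computation on a fixed 2x2 table
    x = np.array([1, 1, 1, 1, 0, 0, 0, 0, 1, 0])
    y = np.array([1, 1, 1, 0, 0, 0, 0, 1, 1, 1])
    p_o = 0.7
    p_e = 0.5 * 0.6 + 0.5 * 0.4  # marginal products
    assert float(cohen_kappa(x, y)) == pytest.approx((p_o - p_e) / (1 - p_e))


def test_cohen_kappa_matches_sklearn():
    from sklearn.metrics import cohen_kappa_score

    rng = np.random.default_rng(3)
    a = rng.integers(0, 3, size=200)
    b = np.where(rng.random(200) < 0.7, a, rng.integers(0, 3, size=200))
    assert float(cohen_kappa(a, b)) == pytest.approx(cohen_kappa_score(a, b), abs=1e-12)


def test_cohen_kappa_near_zero_for_independent_raters():
    rng = np.random.default_rng(4)
    a = rng.integers(0, 2, size=10_000)
    b = rng.integers(0, 2, size=10_000)
    assert abs(float(cohen_kappa(a, b))) < 0.05  # Monte-Carlo error band


def test_pairwise_cohen_mean_and_range():
    labels = np.array([[1, 0, 1, 1, 0], [1, 0, 1, 1, 0], [0, 1, 1, 0, 0]])
    got = pairwise_cohen_kappa(labels)
    per_pair = [float(v) for v in got["per_pair"].values()]
    assert got["mean"] == pytest.approx(np.mean(per_pair))
    assert got["range"] == (min(per_pair), max(per_pair))
    assert float(got["per_pair"][(0, 1)]) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Krippendorff's alpha
# ---------------------------------------------------------------------------


def krippendorff_bruteforce(data, level="nominal"):
    """Enumerate all pairable value pairs within and across units."""
    data = np.asarray(data, dtype=float)
    values = sorted({v for v in data.ravel() if not np.isnan(v)})
    # coincidence counts by enumeration
    pairs = {}
    n_c = {v: 0.0 for v in values}
    for col in data.T:
        present = [v for v in col if not np.isnan(v)]
        m = len(present)
        if m < 2:
            continue
        for x, y in itertools.permutations(present, 2):
            pairs[(x, y)] = pairs.get((x, y), 0.0) + 1.0 / (m - 1)
    for (x, _), c in pairs.items():
        n_c[x] += c
    n = sum(n_c.values())
    if level == "nominal":
        def d(x, y):
            return 0.0 if x == y else 1.0
    else:
        def d(x, y):
            if x == y:
                return 0.0
            i, j = sorted((values.index(x), values.index(y)))
            margins = [n_c[values[g]] for g in range(i, j + 1)]
            return (sum(margins) - (margins[0] + margins[-1]) / 2) ** 2
    d_o = sum(c * d(x, y) for (x, y), c in pairs.items()) / n
    d_e = sum(
        n_c[x] * n_c[y] * d(x, y) for x in values for y in values
    ) / (n * (n - 1))
    return 1.0 - d_o / d_e


def test_krippendorff_perfect_agreement_mixed_values():
    data = np.array([[1, 0, 1, 0], [1, 0, 1, 0], [1, 0, 1, 0]], dtype=float)
    assert float(krippendorff_alpha(data, "nominal")) == pytest.approx(1.0)


def test_krippendorff_single_category_undefined():
    data = np.ones((3, 5))
    assert krippendorff_alpha(data, "nominal").undefined


def test_krippendorff_with_missing_matches_bruteforce():
    data = np.array(
        [[1, 2, 3, 3, 2, 1, 4, 1, 2, np.nan],
         [1, 2, 3, 3, 2, 2, 4, 1, 2, 5],
         [np.nan, 3, 3, 3, 2, 3, 4, 2, 2, 5]],
        dtype=float,
    )
    for level in ("nominal", "ordinal"):
        got = float(krippendorff_alpha(data, level))
        assert got == pytest.approx(krippendorff_bruteforce(data, level), abs=1e-12)


# ---------------------------------------------------------------------------
# ICC
# ---------------------------------------------------------------------------


def icc_anova_oracle(x):
    """Explicit mean-squares computation, independently written."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.mean()
    msr = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
    mse = (np.sum((x - grand) ** 2) - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
    icc21 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    icc2k = (msr - mse) / (msr + (msc - mse) / n)
    return icc21, icc2k


TOY_ICC = np.array(
    [[9, 2, 5], [6, 1, 3], [8, 4, 6], [7, 1, 2], [10, 5, 6], [6, 2, 4]], dtype=float
)


def test_icc_matches_anova_oracle_and_pingouin():
    import pandas as pd
    import pingouin as pg

    icc21, icc2k = icc_anova_oracle(TOY_ICC)
    assert float(icc_two_way(TOY_ICC, "single")) == pytest.approx(icc21)
    assert float(icc_two_way(TOY_ICC, "average")) == pytest.approx(icc2k)

    long = pd.DataFrame(
        [
            {"item": i, "rater": j, "score": TOY_ICC[i, j]}
            for i in range(TOY_ICC.shape[0])
            for j in range(TOY_ICC.shape[1])
        ]
    )
    table = pg.intraclass_corr(long, targets="item", raters="rater", ratings="score")
    # two-way random absolute-agreement forms; label differs across versions
    def pick(labels):
        mask = table["Type"].isin(labels)
        return float(table.loc[mask, "ICC"].iloc[0])

    pg_icc2 = pick(["ICC2", "ICC(A,1)"])
    pg_icc2k = pick(["ICC2k", "ICC(A,k)"])
    assert float(icc_two_way(TOY_ICC, "single")) == pytest.approx(pg_icc2, abs=1e-9)
    assert float(icc_two_way(TOY_ICC, "average")) == pytest.approx(pg_icc2k, abs=1e-9)


def test_icc_average_is_one_for_duplicated_raters():
    items = np.arange(8, dtype=float)
    x = np.column_stack([items, items, items])  # identical columns, item variance
    assert float(icc_two_way(x, "average")) == pytest.approx(1.0)
    assert float(icc_two_way(x, "single")) == pytest.approx(1.0)


def _component_matrix(rng, n, k, sd_item, sd_rater, sd_err):
    """Additive two-way data with realized component variances pinned to
    their targets (the rater draw has only k-1 df, so raw draws would put
    enormous sampling noise on the recovered ratio)."""

    def pinned(draw, sd):
        return (draw - draw.mean()) / draw.std(ddof=0) * sd

    items = pinned(rng.normal(size=n), sd_item)[:, None]
    raters = pinned(rng.normal(size=k), sd_rater)[None, :]
    err = rng.normal(0, sd_err, size=(n, k))
    return items + raters + err


def test_icc_parameter_recovery_on_simulated_components():
    """sigma_item^2=4, sigma_rater^2=1, sigma_err^2=1 -> ICC(2,1)=4/6."""
    rng = np.random.default_rng(5)
    x = _component_matrix(rng, n=500, k=3, sd_item=2.0, sd_rater=1.0, sd_err=1.0)
    assert float(icc_two_way(x, "single")) == pytest.approx(4 / 6, abs=0.05)


# ---------------------------------------------------------------------------
# cross-estimator consistency
# ---------------------------------------------------------------------------


def test_two_rater_fleiss_equals_cohen_with_identical_marginals():
    """With two raters Fleiss' kappa pools marginals (Scott's pi); when the
    raters share identical marginals it coincides with Cohen's kappa."""
    a = np.array([1, 1, 0, 0, 1, 0, 1, 0])
    b = np.array([1, 0, 1, 0, 0, 1, 1, 0])  # same number of 1s as a
    table = np.zeros((len(a), 2))
    for i in range(len(a)):
        table[i, 0] = int(a[i] == 0) + int(b[i] == 0)
        table[i, 1] = int(a[i] == 1) + int(b[i] == 1)
    assert float(fleiss_kappa(table)) == pytest.approx(float(cohen_kappa(a, b)), abs=1e-12)


def test_krippendorff_converges_to_fleiss_on_large_balanced_data():
    rng = np.random.default_rng(6)
    n_items, n_raters = 5000, 3
    truth = rng.integers(0, 2, size=n_items)
    labels = np.array(
        [np.where(rng.random(n_items) < 0.8, truth, 1 - truth) for _ in range(n_raters)]
    )
    table = np.zeros((n_items, 2))
    for i in range(n_items):
        ones = labels[:, i].sum()
        table[i] = (n_raters - ones, ones)
    fk = float(fleiss_kappa(table))
    ka = float(krippendorff_alpha(labels.astype(float), "nominal"))
    assert abs(fk - ka) < 0.02


def test_reliability_report_bundles_all_coefficients():
    rng = np.random.default_rng(7)
    labels = rng.integers(0, 2, size=(3, 40))
    ordinal = rng.integers(1, 6, size=(40, 3)).astype(float)
    rep = reliability_report(labels, ordinal)
    for coeff in (rep.fleiss_kappa, rep.krippendorff_nominal, rep.icc_2_1, rep.icc_2_k):
        assert coeff.value is not None and coeff.value <= 1.0
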