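"""Diagnostic-accuracy metrics, weighted kappa (with independent oracles),
confidence intervals, and small-cell suppression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from claimsbmi.metrics import (
    AgreementTable,
    agreement_table,
    confusion_2x2,
    kappa_ci,
    kappa_from_joint,
    kappa_weights,
    per_level_metrics,
    suppress_small_cells,
    weighted_kappa,
)


def naive_weighted_kappa(O: np.ndarray, scheme: str) -> float:
    """Double-loop reference implementation, straight from the definition."""
    O = np.asarray(O, dtype=float)
    k, n = O.shape[0], O.sum()
    row = O.sum(axis=1) / n
    col = O.sum(axis=0) / n
    po = pe = 0.0
    for i in range(k):
        for j in range(k):
            d = abs(i - j) / (k - 1) if k > 1 else 0.0
            w = 1.0 - (d if scheme == "linear" else d ** 2)
            po += w * O[i, j] / n
            pe += w * row[i] * col[j]
    return (po - pe) / (1.0 - pe)


def random_table(rng, k=None, nmax=10_000) -> np.ndarray:
    k = k or rng.integers(2, 11)
    n = rng.integers(k, nmax)
    probs = rng.dirichlet(np.ones(k * k) * rng.uniform(0.2, 2.0))
    return rng.multinomial(n, probs).reshape(k, k)


# ---------------------------------------------------------------------------
# 2x2


def test_confusion_perfect_classifier():
    res = confusion_2x2([True] * 50 + [False] * 30, [True] * 50 + [False] * 30)
    assert (res.tp, res.fp, res.tn, res.fn) == (50, 0, 30, 0)
    assert res.sensitivity == res.specificity == res.ppv == res.npv == 1.0


def test_confusion_hand_computed():
    claims = [True] * 100 + [False] * 100
    ref = [True] * 90 + [False] * 10 + [True] * 40 + [False] * 60
    res = confusion_2x2(claims, ref)
    assert (res.tp, res.fp, res.tn, res.fn) == (90, 10, 60, 40)
    assert res.sensitivity == pytest.approx(90 / 130)
    assert res.specificity == pytest.approx(60 / 70)
    assert res.ppv == pytest.approx(0.90)
    assert res.npv == pytest.approx(0.60)


def test_confusion_undefined_flagged_not_zero():
    res = confusion_2x2([True, False], [True, True])
    assert res.specificity is None and "specificity_undefined" in res.flags
    with pytest.raises(ValueError):
        confusion_2x2([], [])


# ---------------------------------------------------------------------------
# agreement tables


def test_agreement_table_single_cell():
    t = agreement_table([3] * 10, [3] * 10, k=10)
    assert t.observed[3, 3] == 10 and t.n == 10


def test_agreement_table_marginals_hand_count():
    t = agreement_table([0, 0, 1], [0, 1, 1], k=3)
    assert list(t.row_marginals) == [2, 1, 0]
    assert list(t.col_marginals) == [1, 2, 0]
    assert np.isclose(t.expected.sum(), t.n)


def test_agreement_table_rejects_empty_and_mixed():
    with pytest.raises(ValueError, match="no comparable pairs"):
        agreement_table([], [], k=4)
    with pytest.raises(ValueError):
        agreement_table([0, 5], [0, 1], k=4)   # label outside the scheme


# ---------------------------------------------------------------------------
# weighted kappa


@pytest.mark.parametrize("scheme", ["linear", "quadratic"])
def test_diagonal_table_gives_kappa_one(scheme):
    t = AgreementTable(np.diag([5, 7, 9, 3]))
    assert weighted_kappa(t, scheme).kappa == pytest.approx(1.0)


def test_2x2_linear_kappa_equals_unweighted_cohen():
    O = np.array([[20, 5], [10, 65]])
    # unweighted Cohen's kappa computed from first principles
    n = O.sum()
    po = (20 + 65) / n
    pe = (25 * 30 + 75 * 70) / n ** 2
    expected = (po - pe) / (1 - pe)
    for scheme in ("linear", "quadratic"):
        assert weighted_kappa(AgreementTable(O), scheme).kappa == pytest.approx(expected, abs=1e-12)


def test_independence_table_gives_zero():
    O = np.array([[2, 4], [4, 8]])   # O == E exactly
    assert weighted_kappa(AgreementTable(O)).kappa == pytest.approx(0.0, abs=1e-12)


def test_degenerate_table_flagged():
    t = AgreementTable(np.array([[7]]))
    res = weighted_kappa(t)
    assert res.kappa is None and "degenerate_table" in res.flags


def test_matches_naive_reference_and_statsmodels():
    """Dual-route check: the closed-form implementation against the naive
    double-loop and against statsmodels' weighted kappa (incl. variance)."""
    from statsmodels.stats.inter_rater import cohens_kappa
    rng = np.random.default_rng(2024)
    for _ in range(60):
        O = random_table(rng)
        t = AgreementTable(O)
        for scheme, wt in (("linear", "linear"), ("quadratic", "quadratic")):
            mine = kappa_ci(t, scheme)
            assert mine.kappa == pytest.approx(naive_weighted_kappa(O, scheme), abs=1e-12)
            sm = cohens_kappa(O, wt=wt)
            assert mine.kappa == pytest.approx(float(sm.kappa), abs=1e-10)
            if sm.var_kappa >= 0:
                assert mine.se == pytest.approx(float(np.sqrt(sm.var_kappa)), rel=1e-8)
            else:
                # the large-sample variance can go (slightly) negative on
                # near-perfect tables; we clamp at zero
                assert mine.se == 0.0


def test_matches_sklearn_on_paired_labels():
    """Second independent route: scikit-learn's weighted kappa computed
    from the raw paired labels."""
    from sklearn.metrics import cohen_kappa_score
    rng = np.random.default_rng(77)
    k = 6
    a = rng.integers(0, k, size=400)
    b = np.clip(a + rng.integers(-1, 2, size=400), 0, k - 1)
    t = agreement_table(a, b, k)
    for scheme in ("linear", "quadratic"):
        skl = cohen_kappa_score(a, b, labels=list(range(k)), weights=scheme)
        assert weighted_kappa(t, scheme).kappa == pytest.approx(skl, abs=1e-12)


@settings(max_examples=150, deadline=None)
@given(st.integers(2, 8), st.integers(0, 2 ** 32 - 1),
       st.sampled_from(["linear", "quadratic"]))
def test_kappa_bounded(k, seed, scheme):
    rng = np.random.default_rng(seed)
    O = random_table(rng, k=k, nmax=500)
    res = weighted_kappa(AgreementTable(O), scheme)
    if res.kappa is not None:
        assert -1.0 - 1e-12 <= res.kappa <= 1.0 + 1e-12


def test_kappa_invariant_under_order_reversal():
    rng = np.random.default_rng(7)
    for _ in range(20):
        O = random_table(rng)
        rev = O[::-1, ::-1].copy()
        for scheme in ("linear", "quadratic"):
            assert weighted_kappa(AgreementTable(O), scheme).kappa == pytest.approx(
                weighted_kappa(AgreementTable(rev), scheme).kappa, abs=1e-12)


def test_monotone_degradation():
    """Moving mass from a diagonal cell to any off-diagonal cell in the
    same row never increases kappa."""
    rng = np.random.default_rng(13)
    for _ in range(40):
        O = random_table(rng, k=5, nmax=2000)
        i = int(rng.integers(5))
        O[i, i] += 50                      # ensure something to move
        j = int((i + 1 + rng.integers(4)) % 5)
        base = weighted_kappa(AgreementTable(O)).kappa
        O2 = O.copy()
        O2[i, i] -= 10
        O2[i, j] += 10
        worse = weighted_kappa(AgreementTable(O2)).kappa
        assert worse <= base + 1e-12


def test_kappa_from_joint_consistent_with_table():
    rng = np.random.default_rng(3)
    O = random_table(rng, k=6)
    assert kappa_from_joint(O / O.sum()) == pytest.approx(
        weighted_kappa(AgreementTable(O)).kappa, abs=1e-12)


# ---------------------------------------------------------------------------
# confidence intervals


def test_perfect_agreement_ci_degenerate():
    res = kappa_ci(AgreementTable(np.diag([40, 60])))
    assert res.kappa == pytest.approx(1.0)
    assert res.ci_lower == res.ci_upper == 1.0
    assert "degenerate_interval" in res.flags


def test_bootstrap_ci_reproducible():
    rng = np.random.default_rng(8)
    t = AgreementTable(random_table(rng, k=4))
    a = kappa_ci(t, method="bootstrap", n_boot=500, seed=123)
    b = kappa_ci(t, method="bootstrap", n_boot=500, seed=123)
    assert (a.ci_lower, a.ci_upper) == (b.ci_lower, b.ci_upper)


def test_asymptotic_and_bootstrap_agree_large_n():
    """The bootstrap acts as the oracle for the asymptotic variance
    formula on a large simulated 10-level table."""
    rng = np.random.default_rng(5)
    probs = np.full((10, 10), 0.001)
    np.fill_diagonal(probs, 0.05)
    probs[np.arange(9), np.arange(1, 10)] += 0.02
    probs /= probs.sum()
    O = rng.multinomial(3000, probs.ravel()).reshape(10, 10)
    t = AgreementTable(O)
    asym = kappa_ci(t, method="asymptotic")
    boot = kappa_ci(t, method="bootstrap", n_boot=2000, seed=42)
    assert asym.ci_lower == pytest.approx(boot.ci_lower, abs=0.02)
    assert asym.ci_upper == pytest.approx(boot.ci_upper, abs=0.02)


def test_small_sample_warning_flag():
    t = AgreementTable(np.array([[3, 1], [2, 4]]))
    assert "small_sample_asymptotics" in kappa_ci(t).flags


# ---------------------------------------------------------------------------
# per-level metrics and suppression


def test_per_level_diagonal_table_all_perfect():
    res = per_level_metrics(AgreementTable(np.diag([20, 30, 40])))
    for r in res:
        assert r.sensitivity == r.specificity == r.ppv == r.npv == 1.0


def test_per_level_hand_collapse():
    O = np.zeros((3, 3), dtype=int)
    O[0, 0], O[0, 1], O[1, 1] = 8, 2, 10
    res = per_level_metrics(AgreementTable(O))
    assert res[0].ppv == pytest.approx(0.8)
    assert res[0].sensitivity == pytest.approx(1.0)
    assert (res[0].tp, res[0].fp, res[0].fn, res[0].tn) == (8, 2, 0, 10)


def test_per_level_zero_reference_sensitivity_not_calculated():
    O = np.zeros((3, 3), dtype=int)
    O[2, 0], O[0, 0] = 5, 10       # nothing in reference column 2
    res = per_level_metrics(AgreementTable(O))
    assert res[2].sensitivity is None
    assert "sensitivity_not_calculated" in res[2].flags


def test_suppression_boundary():
    from claimsbmi.metrics import MetricResult
    res = MetricResult(tp=10, fp=11, tn=200, fn=100)
    masked = suppress_small_cells(res, threshold=10)
    assert masked["tp"] == "*" and masked["fp"] == 11


def test_suppression_bounds():
    from claimsbmi.metrics import MetricResult
    # masked complement (fn <= 10): sensitivity becomes a lower bound
    res = MetricResult(tp=90, fp=50, tn=200, fn=8)
    masked = suppress_small_cells(res, threshold=10)
    assert masked["sensitivity"] == ">90"      # 90/(90+10) = 90%
    # masked numerator: ppv becomes an upper bound
    res2 = MetricResult(tp=9, fp=91, tn=200, fn=100)
    masked2 = suppress_small_cells(res2, threshold=10)
    assert masked2["ppv"].startswith("<")
    # untouched metric renders as a plain percentage
    assert masked2["npv"] == f"{100 * 200 / 300:.0f}"


def test_suppression_never_alters_inputs():
    from claimsbmi.metrics import MetricResult
    res = MetricResult(tp=5, fp=6, tn=7, fn=8)
    suppress_small_cells(res)
    assert (res.tp, res.fp, res.tn, res.fn) == (5, 6, 7, 8)


def test_weights_matrix_properties():
    for k in (2, 5, 10):
        for scheme in ("linear", "quadratic"):
            W = kappa_weights(k, scheme)
            assert np.allclose(W, W.T)
            assert np.allclose(np.diag(W), 1.0)
            assert ((W >= 0) & (W <= 1)).all()
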