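"""Kappa, pair analysis and the exact r×c Fisher test."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score
from scipy.stats import fisher_exact as scipy_fisher

import pleograde as pg
from pleograde.agreement import enumeration_probability_total


def assignments_from_matrix(matrix):
    """Expand a confusion matrix into per-case GradeAssignments."""
    out = []
    k = 0
    for i, row in enumerate(matrix):
        for j, count in enumerate(row):
            for _ in range(count):
                k += 1
                out.append(pg.GradeAssignment(
                    case_id=f"c{k}", score_lns=i + 1, score_nsd=i + 1,
                    score_combined=i + 1, original_score=j + 1))
    return out


def matrix_to_labels(matrix):
    arr = np.asarray(matrix)
    rows, cols = [], []
    for i, j in np.ndindex(arr.shape):
        rows += [i] * arr[i, j]
        cols += [j] * arr[i, j]
    return np.array(rows), np.array(cols)


small_matrices = st.lists(
    st.lists(st.integers(0, 8), min_size=3, max_size=3), min_size=3, max_size=3
).map(lambda rows: tuple(map(tuple, rows))).filter(
    lambda m: sum(map(sum, m)) >= 2
    and not all(v == 0 for r in m for v in r)
)


class TestConfusionMatrix:
    def test_from_assignments(self, table5_matrix):
        m = pg.confusion_matrix(assignments_from_matrix(table5_matrix.counts))
        assert m == table5_matrix and m.n == 53

    def test_missing_originals_excluded(self):
        a = assignments_from_matrix([[2, 0, 0], [0, 3, 0], [0, 0, 1]])
        a.append(pg.GradeAssignment("x", 1, 1, 1, original_score=None))
        m = pg.confusion_matrix(a)
        assert m.n == 6

    def test_empty_input_rejected(self):
        with pytest.raises(pg.InputError):
            pg.confusion_matrix([])

    def test_single_cell(self):
        a = assignments_from_matrix([[0, 0, 0], [0, 4, 0], [0, 0, 0]])
        m = pg.confusion_matrix(a)
        assert m.counts[1][1] == 4 and m.n == 4

    def test_invariants_rejected(self):
        with pytest.raises(pg.InputError):
            pg.ConfusionMatrix(((1, 2), (3, 4), (5, 6)))
        with pytest.raises(pg.InputError):
            pg.ConfusionMatrix(((1, -1), (0, 2)))


class TestCohenKappa:
    def test_perfect_agreement(self):
        r = pg.cohen_kappa(pg.ConfusionMatrix(((5, 0, 0), (0, 5, 0), (0, 0, 5))))
        assert r.kappa == pytest.approx(1.0)
        assert r.interpretation == "almost perfect"
        assert r.good_reliability

    def test_independence_gives_zero(self):
        # margins-product table (with a padding zero row/column): po == pe
        r = pg.cohen_kappa(pg.ConfusionMatrix(((1, 1, 0), (1, 1, 0), (0, 0, 0))))
        assert r.kappa == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_all_mass_one_cell(self):
        with pytest.raises(pg.DegenerateStatisticsError):
            pg.cohen_kappa(pg.ConfusionMatrix(((4, 0), (0, 0))))

    @given(m=small_matrices)
    def test_matches_sklearn_oracle(self, m):
        rows, cols = matrix_to_labels(m)
        if len(set(rows)) < 2 and set(rows) == set(cols):
            return  # pe = 1: kappa undefined, covered above
        try:
            got = pg.cohen_kappa(pg.ConfusionMatrix(m)).kappa
        except pg.DegenerateStatisticsError:
            return
        want = cohen_kappa_score(rows, cols, labels=[0, 1, 2])
        assert got == pytest.approx(want, abs=1e-12)

    @given(m=small_matrices)
    def test_weighted_matches_sklearn_oracle(self, m):
        rows, cols = matrix_to_labels(m)
        for weights in ("linear", "quadratic"):
            try:
                got = pg.cohen_kappa(pg.ConfusionMatrix(m), weights=weights).kappa
            except pg.DegenerateStatisticsError:
                return
            want = cohen_kappa_score(rows, cols, labels=[0, 1, 2], weights=weights)
            assert got == pytest.approx(want, abs=1e-10)

    @given(m=small_matrices)
    def test_row_column_permutation_invariance(self, m):
        arr = np.asarray(m)
        perm = [2, 0, 1]
        permuted = arr[np.ix_(perm, perm)]
        try:
            a = pg.cohen_kappa(pg.ConfusionMatrix(m))
            b = pg.cohen_kappa(pg.ConfusionMatrix(tuple(map(tuple, permuted))))
        except pg.DegenerateStatisticsError:
            return
        assert a.kappa == pytest.approx(b.kappa, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    @given(m=small_matrices)
    def test_kappa_never_exceeds_po(self, m):
        try:
            r = pg.cohen_kappa(pg.ConfusionMatrix(m))
        except pg.DegenerateStatisticsError:
            return
        assert r.kappa <= r.po + 1e-12
        assert -1 <= r.kappa <= 1
        off_diag = sum(v for i, row in enumerate(m) for j, v in enumerate(row) if i != j)
        assert (r.kappa == pytest.approx(1.0)) == (off_diag == 0)

    @pytest.mark.parametrize("kappa,label", [
        (-0.2, "poor"), (0.1, "slight"), (0.367, "fair"),
        (0.453, "moderate"), (0.7, "substantial"), (0.9, "almost perfect"),
    ])
    def test_landis_koch_bands(self, kappa, label):
        assert pg.interpret_kappa(kappa) == label


class TestPairAnalysis:
    def test_published_validation_table(self, table5_matrix):
        pct, adjacent, critical = pg.pair_analysis(table5_matrix)
        assert pct == pytest.approx(100 * 35 / 53)
        assert adjacent == 17
        assert critical == 1  # the single grade-1 -> grade-3 discordance

    def test_diagonal_fully_concordant(self):
        pct, adj, crit = pg.pair_analysis(pg.ConfusionMatrix(((2, 0, 0), (0, 3, 0), (0, 0, 4))))
        assert (pct, adj, crit) == (100.0, 0, 0)

    def test_single_extreme_cell_all_critical(self):
        pct, adj, crit = pg.pair_analysis(pg.ConfusionMatrix(((0, 0, 7), (0, 0, 0), (0, 0, 0))))
        assert pct == 0.0 and adj == 0 and crit == 7

    @given(m=small_matrices)
    def test_counts_partition_n(self, m):
        matrix = pg.ConfusionMatrix(m)
        pct, adj, crit = pg.pair_analysis(matrix)
        concordant = round(pct * matrix.n / 100)
        assert concordant + adj + crit == matrix.n


class TestFisherExact:
    def test_2x2_example(self):
        p, se = pg.fisher_exact_rxc(np.array([[3, 1], [1, 3]]))
        assert se is None
        assert p == pytest.approx(0.48571, abs=5e-6)

    @given(
        a=st.integers(0, 6), b=st.integers(0, 6),
        c=st.integers(0, 6), d=st.integers(0, 6),
    )
    def test_2x2_matches_scipy_oracle(self, a, b, c, d):
        table = np.array([[a, b], [c, d]])
        p, _ = pg.fisher_exact_rxc(table)
        want = scipy_fisher(table).pvalue
        assert p == pytest.approx(want, rel=1e-9, abs=1e-12)

    def test_empty_rows_and_columns_are_neutral(self, table5_matrix):
        base, _ = pg.fisher_exact_rxc(table5_matrix)
        padded = np.zeros((4, 4), np.int64)
        padded[:3, :3] = table5_matrix.as_array()
        p, _ = pg.fisher_exact_rxc(padded)
        assert p == pytest.approx(base, rel=1e-12)

    @pytest.mark.parametrize("rows,cols", [
        ((4, 4), (4, 4)),
        ((3, 30, 20), (4, 31, 18)),
        ((5, 5, 5), (7, 4, 4)),
    ])
    def test_enumeration_probabilities_sum_to_one(self, rows, cols):
        assert enumeration_probability_total(rows, cols) == pytest.approx(1.0, abs=1e-9)

    def test_monte_carlo_agrees_with_enumeration(self, table5_matrix):
        exact, _ = pg.fisher_exact_rxc(table5_matrix, method="enumerate")
        mc, se = pg.fisher_exact_rxc(table5_matrix, method="monte_carlo",
                                     mc_draws=20_000, seed=5)
        assert se is not None
        assert abs(mc - exact) < 3 * se

    def test_monte_carlo_deterministic_under_seed(self, table5_matrix):
        p1, _ = pg.fisher_exact_rxc(table5_matrix, method="monte_carlo",
                                    mc_draws=5000, seed=11)
        p2, _ = pg.fisher_exact_rxc(table5_matrix, method="monte_carlo",
                                    mc_draws=5000, seed=11)
        assert p1 == p2

    def test_budget_exceeded_without_fallback(self, table5_matrix):
        with pytest.raises(pg.InputError):
            pg.fisher_exact_rxc(table5_matrix, method="enumerate", table_budget=5)

    def test_budget_exceeded_auto_falls_back(self, table5_matrix):
        p, se = pg.fisher_exact_rxc(table5_matrix, method="auto", table_budget=5,
                                    mc_draws=5000, seed=3)
        assert se is not None and 0 <= p <= 1
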