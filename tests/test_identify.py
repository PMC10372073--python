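import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from immunocall.identify import (
    BoundaryParams,
    align_to_signature,
    correlation_matrix,
    fit_boundary,
    profile_correlations,
    roc_auc,
    roc_curve,
    score_cells,
)
from immunocall.matrix_io import CellMatrix
from immunocall.preprocess import PreprocessConfig, normalize_cells
from immunocall.signature import SignatureMatrix
from tests.conftest import auc_brute, pearson_brute


def normalized_matrix(columns, genes=None):
    cols = np.asarray(columns, dtype=float).T
    m = CellMatrix(
        genes=genes or [f"G{i}" for i in range(cols.shape[0])],
        barcodes=[f"c{j}" for j in range(cols.shape[1])],
        counts=sp.csc_matrix(np.round(cols)),
    )
    return normalize_cells(m, PreprocessConfig(min_total_count=0))


class TestDecisionRule:
    @pytest.mark.parametrize(
        "rho_max,T,immune",
        [
            (0.0, 414.0, True),   # just above the threshold
            (0.0, 412.0, False),  # just below
            (0.0, 413.0, False),  # exactly at: strict inequality
            (1.0, 0.0, True),     # slope alone clears the threshold
            (0.2, 50.0, False),   # 1580.7*0.2+50 = 366.14
        ],
    )
    def test_default_constants(self, rho_max, T, immune):
        params = BoundaryParams()
        assert bool(params.is_immune(rho_max, T)) is immune

    def test_linear_score_arithmetic(self):
        params = BoundaryParams()
        assert params.linear_score(1.0, 0.0) == pytest.approx(1580.7)
        assert params.linear_score(0.2, 50.0) == pytest.approx(366.14)

    def test_monotone_in_both_metrics(self):
        params = BoundaryParams()
        rng = np.random.default_rng(0)
        rho = rng.uniform(0, 1, 200)
        T = rng.uniform(0, 10_000, 200)
        base = params.is_immune(rho, T)
        assert np.all(params.is_immune(rho + 0.01, T) >= base)
        assert np.all(params.is_immune(rho, T + 10) >= base)

    def test_non_finite_params_rejected(self):
        with pytest.raises(ValueError):
            BoundaryParams(A=np.inf)


class TestCorrelations:
    def test_matches_brute_force_on_given_example(self, toy_sig):
        # cell [1,2,3,4] against TypeB's column [0,0,1,0]
        got = profile_correlations([1, 2, 3, 4], toy_sig)
        for j, t in enumerate(toy_sig.types):
            expected = pearson_brute([1, 2, 3, 4], toy_sig.values[:, j])
            assert got[j] == pytest.approx(expected, abs=1e-12)

    def test_scaled_profile_gives_coefficient_one(self, toy_sig):
        cell = 37.5 * toy_sig.values[:, 0]
        got = profile_correlations(cell, toy_sig)
        assert got[0] == pytest.approx(1.0)

    def test_constant_cell_returns_zero_by_convention(self, toy_sig):
        assert profile_correlations([2, 2, 2, 2], toy_sig).tolist() == [0, 0]
        assert profile_correlations([0, 0, 0, 0], toy_sig).tolist() == [0, 0]

    def test_brute_force_agreement_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            G = rng.integers(4, 12)
            K = rng.integers(1, 4)
            values = rng.integers(0, 2, size=(G, K))
            values[rng.integers(G), :] = 1  # no empty columns
            sig = SignatureMatrix(
                genes=[f"G{i}" for i in range(G)],
                types=[f"T{k}" for k in range(K)],
                values=values,
            )
            cell = rng.uniform(0, 50, G) * rng.integers(0, 2, G)
            got = profile_correlations(cell, sig)
            for j in range(K):
                want = pearson_brute(cell, values[:, j])
                assert got[j] == pytest.approx(want, abs=1e-10)

    def test_all_ones_profile_has_zero_variance(self):
        sig = SignatureMatrix(genes=["A", "B"], types=["T"], values=np.ones((2, 1)))
        assert profile_correlations([1.0, 5.0], sig)[0] == 0.0


class TestAlign:
    def test_full_overlap_is_pure_reordering(self, toy_sig):
        m = normalized_matrix([[10, 20, 30, 40]], genes=["G3", "G1", "G4", "G2"])
        aligned, n_missing = align_to_signature(m, toy_sig)
        assert n_missing == 0
        assert aligned.genes == toy_sig.genes
        np.testing.assert_allclose(
            aligned.counts.toarray().ravel(), [2000, 4000, 1000, 3000]
        )

    def test_missing_gene_becomes_zero_row(self, toy_sig):
        m = normalized_matrix([[10, 20, 30]], genes=["G1", "G2", "G3"])
        aligned, n_missing = align_to_signature(m, toy_sig)
        assert n_missing == 1
        assert aligned.counts[3, 0] == 0.0

    def test_zero_overlap_is_an_error(self, toy_sig):
        m = normalized_matrix([[10, 20]], genes=["X1", "X2"])
        with pytest.raises(ValueError, match="no signature genes"):
            align_to_signature(m, toy_sig)

    def test_majority_missing_requires_override(self):
        sig = SignatureMatrix(
            genes=[f"G{i}" for i in range(10)], types=["T"],
            values=np.ones((10, 1)),
        )
        m = normalized_matrix([[5, 5, 5]], genes=["G0", "G1", "G2"])
        with pytest.raises(ValueError, match="allow_sparse_signature"):
            align_to_signature(m, sig)
        aligned, n_missing = align_to_signature(m, sig, allow_sparse_signature=True)
        assert n_missing == 7


class TestScoreCells:
    def test_gene_row_permutation_leaves_records_unchanged(self, toy_sig):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 30, size=(4, 6))
        counts[0] += 1
        base = normalized_matrix(counts.T)
        perm = rng.permutation(4)
        shuffled = normalize_cells(
            CellMatrix(
                genes=[f"G{i}" for i in perm],
                barcodes=[f"c{j}" for j in range(6)],
                counts=sp.csc_matrix(counts[perm].astype(float)),
            ),
            PreprocessConfig(min_total_count=0),
        )
        a = score_cells(base, toy_sig)
        b = score_cells(shuffled, toy_sig)
        for col in ("rho_max", "total_immune_expression", "linear_score"):
            np.testing.assert_allclose(a[col], b[col], atol=1e-12)
        assert (a["argmax_type"] == b["argmax_type"]).all()

    def test_requires_normalized_layer(self, toy_sig):
        m = CellMatrix(genes=list(toy_sig.genes), barcodes=["c0"],
                       counts=sp.csc_matrix(np.ones((4, 1))))
        with pytest.raises(ValueError, match="normalized"):
            score_cells(m, toy_sig)

    def test_total_immune_expression_bounded_by_scale(self, toy_sig):
        # all mass on signature genes -> T equals the scale exactly
        m = normalized_matrix([[5, 5, 5, 5]], genes=list(toy_sig.genes))
        scores = score_cells(m, toy_sig)
        assert scores["total_immune_expression"][0] == pytest.approx(10_000.0)

    def test_argmax_tie_broken_by_column_order(self):
        sig = SignatureMatrix(
            genes=["A", "B", "C", "D"], types=["T1", "T2"],
            values=np.array([[1, 0], [0, 1], [0, 0], [0, 0]]),
        )
        # symmetric cell: equal correlation to both columns
        m = normalized_matrix([[7, 7, 1, 1]], genes=["A", "B", "C", "D"])
        assert score_cells(m, sig)["argmax_type"][0] == "T1"


class TestRoc:
    def test_perfect_ranking(self):
        assert roc_auc([3, 2, 1], [True, True, False]) == 1.0

    def test_tie_convention_half(self):
        assert roc_auc([1, 1], [True, False]) == 0.5

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2], [True, True])
        with pytest.raises(ValueError):
            roc_curve([1, 2], [False, False])

    def test_trapezoid_equals_concordance_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = 20
            scores = rng.integers(0, 10, n).astype(float)  # ties likely
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                auc_brute(scores, labels), abs=1e-12
            )

    def test_curve_is_monotone_staircase(self):
        rng = np.random.default_rng(8)
        curve = roc_curve(rng.normal(size=50), rng.integers(0, 2, 50).astype(bool))
        assert (np.diff(curve["sensitivity"]) >= 0).all()
        assert (np.diff(curve["one_minus_specificity"]) >= 0).all()


class TestFitBoundary:
    def test_separable_clouds(self):
        immune = [(0.9, 9000.0)] * 20
        nonimmune = [(0.05, 100.0)] * 20
        params, auc, sens, spec = fit_boundary(immune, nonimmune)
        assert (auc, sens, spec) == (1.0, 1.0, 1.0)

    def test_identical_distributions_auc_near_half(self):
        rng = np.random.default_rng(9)
        pts = [(rng.uniform(), rng.uniform(0, 5000)) for _ in range(300)]
        params, auc, sens, spec = fit_boundary(pts[:150], pts[150:])
        assert 0.4 < auc < 0.6

    def test_auc_matches_pairwise_concordance_small_instance(self):
        immune = [(0.0, 30.0), (0.0, 20.0), (0.0, 25.0)]
        nonimmune = [(0.0, 10.0), (0.0, 22.0), (0.0, 5.0)]
        params, auc, _, _ = fit_boundary(immune, nonimmune)
        scores = [params.linear_score(r, t) for r, t in immune + nonimmune]
        labels = [True] * 3 + [False] * 3
        assert auc == pytest.approx(auc_brute(scores, labels))

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            fit_boundary([], [(0.1, 10.0)])

    def test_degenerate_grid_rejected(self):
        from immunocall.identify import BoundaryGrid

        with pytest.raises(ValueError):
            BoundaryGrid(coarse_steps=1)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    st.lists(st.floats(0, 1), min_size=3, max_size=3),
    st.lists(st.floats(0, 10_000), min_size=3, max_size=3),
)
def test_correlation_matrix_entries_bounded(rhos, ts):
    X = sp.csc_matrix(np.array([rhos, ts, rhos]).T)
    S = np.array([[1, 0], [0, 1], [1, 1]])
    r = correlation_matrix(X, S)
    assert np.all(np.abs(r) <= 1.0)
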