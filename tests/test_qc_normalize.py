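"""QC chain: filters, normalization, log1p, HVG selection, regress-out, plots."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from snvmap import (
    PipelineConfig,
    UserInputError,
    filter_cells_min_genes,
    filter_cells_upper_percentile,
    filter_genes_min_cells,
    log1p,
    normalize_total,
    regress_out_total,
    run_qc,
    select_hvg,
    upper_percentile_threshold,
)
from snvmap.errors import SnvmapError
from snvmap.qc_normalize import gene_support, genes_per_cell, qc_plots
from snvmap.variant_ingest import MutationMatrix

from conftest import SMALL_CONFIG, percentile_oracle


def mk_matrix(arr, cell_ids=None, gene_ids=None):
    arr = np.asarray(arr)
    n, g = arr.shape
    cell_ids = cell_ids or [f"c{i}" for i in range(n)]
    gene_ids = gene_ids or [f"g{j}" for j in range(g)]
    ann = pd.DataFrame(
        {"sample_id": [c.split("_")[0] for c in cell_ids]},
        index=pd.Index(cell_ids, name="cell_id"),
    )
    return MutationMatrix(
        counts=sp.csr_matrix(arr.astype(np.int64)),
        cell_ids=cell_ids,
        gene_ids=gene_ids,
        cell_annotations=ann,
    )


# ---------------------------------------------------------------------------
# step 1-3 filters
# ---------------------------------------------------------------------------


class TestGeneFilter:
    def test_support_threshold(self):
        # gene support: g0 in 3 cells, g1 in 2, g2 in 1
        m = mk_matrix([[1, 1, 1], [2, 3, 0], [1, 0, 0]])
        out = filter_genes_min_cells(m, 3)
        assert out.gene_ids == ["g0"]
        assert gene_support(out).min() >= 3

    def test_k1_without_empty_genes_is_identity(self, small_matrix):
        out = filter_genes_min_cells(small_matrix, 1)
        assert out.equals(small_matrix)

    def test_k_above_n_cells_errors(self):
        m = mk_matrix([[1, 1], [1, 1]])
        with pytest.raises(UserInputError):
            filter_genes_min_cells(m, 3)

    def test_all_filtered_errors(self):
        m = mk_matrix([[1, 0], [0, 1]])
        with pytest.raises(UserInputError, match="all genes filtered"):
            filter_genes_min_cells(m, 2)


class TestCellFilter:
    def test_boundary_is_inclusive(self):
        # cells with exactly k mutated genes are kept ("less than k" removed)
        arr = np.zeros((2, 30), dtype=int)
        arr[0, :30] = 1
        arr[1, :29] = 1
        out = filter_cells_min_genes(mk_matrix(arr), 30)
        assert out.cell_ids == ["c0"]

    def test_no_empty_cells_k1_identity(self, small_matrix):
        assert filter_cells_min_genes(small_matrix, 1).equals(small_matrix)

    def test_all_below_threshold_errors(self):
        m = mk_matrix([[1, 0], [0, 1]])
        with pytest.raises(UserInputError, match="min_genes_per_cell=5"):
            filter_cells_min_genes(m, 5)


class TestPercentileFilter:
    def test_printed_example(self):
        # per-cell gene counts [30, 40, 50, 60, 1000] at p=98
        arr = np.zeros((5, 1000), dtype=int)
        for i, k in enumerate([30, 40, 50, 60, 1000]):
            arr[i, :k] = 1
        m = mk_matrix(arr)
        t = upper_percentile_threshold(m, 98)
        assert t == pytest.approx(924.8)
        out = filter_cells_upper_percentile(m, 98)
        assert out.cell_ids == ["c0", "c1", "c2", "c3"]

    def test_p100_removes_nothing(self, small_matrix):
        assert filter_cells_upper_percentile(small_matrix, 100).equals(small_matrix)

    def test_equal_counts_no_removal(self):
        m = mk_matrix(np.ones((4, 10), dtype=int))
        assert filter_cells_upper_percentile(m, 98).n_cells == 4

    @pytest.mark.parametrize("seed", range(5))
    def test_threshold_matches_sort_interpolate_oracle(self, seed):
        rng = np.random.default_rng(seed)
        arr = (rng.random((20, 50)) < 0.3).astype(int)
        arr[:, 0] = 1  # no empty cells
        m = mk_matrix(arr)
        t = upper_percentile_threshold(m, 98)
        assert t == pytest.approx(percentile_oracle(genes_per_cell(m), 98))
        out = filter_cells_upper_percentile(m, 98)
        assert genes_per_cell(out).max() <= t


# ---------------------------------------------------------------------------
# normalization / log
# ---------------------------------------------------------------------------


class TestNormalize:
    def test_median_target_closed_form(self):
        X = np.array([[5.0, 5.0], [10.0, 10.0]])
        out, target = normalize_total(X, "median")
        assert target == 15.0
        np.testing.assert_allclose(out[0], [7.5, 7.5])
        np.testing.assert_allclose(out[1], [7.5, 7.5])

    def test_equal_totals_identity(self):
        X = np.array([[1.0, 2.0], [2.0, 1.0]])
        out, _ = normalize_total(X, "median")
        np.testing.assert_allclose(out, X)

    def test_single_cell_unchanged(self):
        X = np.array([[3.0, 4.0]])
        out, _ = normalize_total(X)
        np.testing.assert_allclose(out, X)

    def test_conservation_within_tolerance(self, small_matrix):
        X = small_matrix.counts.toarray().astype(float)
        X = X[X.sum(axis=1) > 0]
        out, target = normalize_total(X, "median")
        np.testing.assert_allclose(out.sum(axis=1), target, rtol=1e-9)

    def test_all_zero_cell_is_internal_error(self):
        with pytest.raises(SnvmapError):
            normalize_total(np.array([[0.0, 0.0], [1.0, 1.0]]))


class TestLog1p:
    def test_closed_forms(self):
        assert log1p(np.array([0.0]))[0] == 0.0
        assert log1p(np.array([np.e - 1]))[0] == pytest.approx(1.0)

    def test_negative_rejected(self):
        with pytest.raises(SnvmapError):
            log1p(np.array([-0.5]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=30))
    def test_monotone(self, xs):
        v = np.array(xs)
        order = np.argsort(v, kind="stable")
        out = log1p(v)
        assert np.array_equal(np.argsort(out, kind="stable"), order)


# ---------------------------------------------------------------------------
# HVG selection
# ---------------------------------------------------------------------------


def hvg_brute_force(X, n, n_bins=20):
    """Independent HVG oracle: explicit per-gene loops over the same
    definition (expm1-scale dispersion, rank-based equal-count mean bins,
    within-bin z-score, stable top-k)."""
    raw = np.expm1(X)
    n_genes = X.shape[1]
    # plain reductions for the summary statistics (bit-identical inputs);
    # the binning / z-scoring / ranking below is all explicit loops
    means = list(raw.mean(axis=0))
    variances = list(raw.var(axis=0, ddof=1))
    disp = [v / m if m > 0 else 0.0 for m, v in zip(means, variances)]
    log_mean = [np.log1p(m) for m in means]
    log_disp = [np.log(d) if d > 0 else 0.0 for d in disp]
    # contiguous equal-count chunks of the mean-sorted gene list
    by_mean = sorted(range(n_genes), key=lambda j: (log_mean[j], j))
    k_bins = min(n_bins, n_genes)
    base, extra = divmod(n_genes, k_bins)
    bins = [0] * n_genes
    pos = 0
    for b in range(k_bins):
        size = base + (1 if b < extra else 0)
        for j in by_mean[pos : pos + size]:
            bins[j] = b
        pos += size
    z = [0.0] * n_genes
    for b in sorted(set(bins)):
        members = [j for j in range(n_genes) if bins[j] == b]
        if len(members) < 2:
            continue
        vals = [log_disp[j] for j in members]
        mu = sum(vals) / len(vals)
        sd = (sum((v - mu) ** 2 for v in vals) / (len(vals) - 1)) ** 0.5
        if sd > 0:
            for j in members:
                z[j] = (log_disp[j] - mu) / sd
    ranked = sorted(range(n_genes), key=lambda j: (-z[j], j))
    return set(ranked[: min(n, n_genes)])


class TestSelectHVG:
    def test_saturation_selects_all(self):
        rng = np.random.default_rng(0)
        X = np.log1p(rng.poisson(2, size=(10, 8)).astype(float))
        mask, _ = select_hvg(X, 100)
        assert mask.all()

    def test_inflated_variance_gene_ranks_first(self):
        rng = np.random.default_rng(1)
        X = rng.poisson(3, size=(40, 200)).astype(float)
        # same mean (~3) as its bin-mates but far larger dispersion
        X[:, 7] = rng.choice([0.0, 30.0], size=40, p=[0.9, 0.1])
        Xl = np.log1p(X)
        mask, table = select_hvg(Xl, 5)
        assert table["dispersion_norm"].idxmax() == 7
        assert mask[7]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_genes = int(rng.integers(30, 200))
        X = np.log1p(rng.poisson(rng.uniform(0.5, 4), size=(25, n_genes)).astype(float))
        n = int(rng.integers(5, n_genes))
        mask, _ = select_hvg(X, n)
        assert set(np.flatnonzero(mask)) == hvg_brute_force(X, n)

    def test_ties_broken_by_stable_gene_order(self):
        # identical gene columns => identical z; earlier genes win
        col = np.log1p(np.array([0.0, 1, 2, 3, 4, 5], dtype=float))
        X = np.tile(col[:, None], (1, 10))
        mask, _ = select_hvg(X, 4)
        assert np.flatnonzero(mask).tolist() == [0, 1, 2, 3]

    def test_single_gene_errors(self):
        with pytest.raises(UserInputError):
            select_hvg(np.ones((5, 1)), 1)


# ---------------------------------------------------------------------------
# regress-out
# ---------------------------------------------------------------------------


class TestRegressOut:
    def test_linear_gene_residuals_zero(self):
        totals = np.array([10.0, 20, 30, 40])
        X = np.column_stack([2 * totals + 5, -0.5 * totals + 1])
        out = regress_out_total(X, totals)
        np.testing.assert_allclose(out, 0, atol=1e-10)

    def test_orthogonal_gene_only_recentred(self):
        totals = np.array([1.0, 2, 3, 4])
        g = np.array([1.0, -1, -1, 1])  # orthogonal to centred totals
        out = regress_out_total(g[:, None], totals)
        np.testing.assert_allclose(out.ravel(), g - g.mean(), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_residuals_match_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        totals = rng.uniform(10, 100, size=30)
        X = rng.normal(size=(30, 12)) + np.outer(totals, rng.normal(size=12))
        out = regress_out_total(X, totals)
        # explicit 2x2 normal equations per gene
        A = np.column_stack([np.ones(30), totals])
        AtA = A.T @ A
        for j in range(12):
            beta = np.linalg.solve(AtA, A.T @ X[:, j])
            np.testing.assert_allclose(out[:, j], X[:, j] - A @ beta, atol=1e-9)
            r = np.corrcoef(out[:, j], totals)[0, 1]
            assert abs(r) < 1e-8

    def test_constant_covariate_skipped_with_warning(self, caplog):
        X = np.random.default_rng(0).normal(size=(5, 3))
        out = regress_out_total(X, np.full(5, 7.0))
        np.testing.assert_array_equal(out, X)


# ---------------------------------------------------------------------------
# full chain + report + plots
# ---------------------------------------------------------------------------


class TestRunQC:
    def test_report_telescopes_and_matches_shapes(self, small_matrix):
        qc = run_qc(small_matrix, SMALL_CONFIG)
        steps = qc.report.steps
        for prev, cur in zip(steps, steps[1:]):
            assert cur.n_cells_before == prev.n_cells_after
            assert cur.n_genes_before == prev.n_genes_after
        assert steps[0].n_cells_before == small_matrix.n_cells
        assert steps[2].n_cells_after == qc.matrix.n_cells
        assert qc.values.shape == (qc.matrix.n_cells, qc.hvg_mask.sum())

    def test_removed_cell_lists_disjoint(self, small_matrix):
        qc = run_qc(small_matrix, SMALL_CONFIG)
        removed = [set(s.removed_cells) for s in qc.report.steps]
        for i in range(len(removed)):
            for j in range(i + 1, len(removed)):
                assert not (removed[i] & removed[j])

    def test_deterministic_across_runs(self, small_matrix):
        a = run_qc(small_matrix, SMALL_CONFIG)
        b = run_qc(small_matrix, SMALL_CONFIG)
        np.testing.assert_array_equal(a.values, b.values)
        assert a.report.to_json() == b.report.to_json()

    def test_mean_retained_equals_row_sum_mean(self, small_matrix):
        qc = run_qc(small_matrix, SMALL_CONFIG)
        assert qc.report.mean_retained_per_cell == pytest.approx(
            qc.matrix.counts.toarray().sum(axis=1).mean()
        )

    def test_qc_plots_exist_and_are_byte_stable(self, small_matrix, tmp_path):
        qc = run_qc(small_matrix, SMALL_CONFIG)
        p1 = qc_plots(qc, small_matrix, tmp_path / "a")
        p2 = qc_plots(qc, small_matrix, tmp_path / "b")
        assert set(p1) == {"cells_per_gene.png", "genes_per_cell.png", "hvg_dispersion.png"}
        for name in p1:
            assert p1[name].stat().st_size > 0
            assert p1[name].read_bytes() == p2[name].read_bytes()

    def test_cutoff_lines_at_configured_thresholds(self, small_matrix):
        from snvmap.qc_normalize import fig_cells_per_gene, fig_genes_per_cell

        fig = fig_cells_per_gene(small_matrix, SMALL_CONFIG.min_cells_per_gene)
        vlines = [l.get_xdata()[0] for l in fig.axes[0].lines]
        assert SMALL_CONFIG.min_cells_per_gene in vlines

        t = upper_percentile_threshold(
            filter_genes_min_cells(small_matrix, SMALL_CONFIG.min_cells_per_gene),
            SMALL_CONFIG.upper_percentile,
        )
        fig2 = fig_genes_per_cell(small_matrix, SMALL_CONFIG.min_genes_per_cell, t)
        vlines2 = [l.get_xdata()[0] for l in fig2.axes[0].lines]
        assert SMALL_CONFIG.min_genes_per_cell in vlines2
        assert any(v == pytest.approx(t) for v in vlines2)
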