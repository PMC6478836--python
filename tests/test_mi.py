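"""Mutual-information estimator, discretization and the single-cell pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epicoherence.mi import (
    bulk_coordination_mi,
    downsample_cells,
    mi_uplift_report,
    mutual_information,
    mutual_information_pairs,
    promoter_meth_rate,
    quantile_discretize,
    sc_gene_filter,
    sc_matched_mi,
    sc_qc,
    sc_scrambled_mi,
)
from epicoherence.synthetic import SingleCellJoint


def _mi_oracle(table):
    """Brute-force double sum, independent of the implementation."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    total = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            pxy = table[i, j] / n
            if pxy > 0:
                px = table[i].sum() / n
                py = table[:, j].sum() / n
                total += pxy * np.log2(pxy / (px * py))
    return total


class TestMutualInformation:
    @pytest.mark.parametrize(
        "table, expected",
        [
            ([[4, 0], [0, 4]], 1.0),
            ([[2, 2], [2, 2]], 0.0),
            ([[3, 1], [1, 3]], 0.18872187554086717),
        ],
    )
    def test_known_tables(self, table, expected):
        assert mutual_information(np.array(table)) == pytest.approx(expected, abs=1e-12)

    def test_brute_force_oracle_on_random_tables(self, rng):
        for _ in range(1000):
            shape = (int(rng.integers(2, 6)), int(rng.integers(2, 6)))
            table = rng.integers(0, 20, size=shape)
            if table.sum() == 0:
                continue
            assert mutual_information(table) == pytest.approx(_mi_oracle(table), abs=1e-12)

    def test_self_information_equals_entropy(self, rng):
        x = rng.integers(0, 4, 500)
        labels, counts = np.unique(x, return_counts=True)
        p = counts / counts.sum()
        h = -(p * np.log2(p)).sum()
        assert mutual_information_pairs(x, x) == pytest.approx(h, abs=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(0, 30), min_size=4, max_size=4))
    def test_non_negative_and_relabel_invariant(self, cells):
        table = np.array(cells).reshape(2, 2)
        if table.sum() == 0:
            return
        mi = mutual_information(table)
        assert mi >= -1e-12
        assert mutual_information(table[::-1]) == pytest.approx(mi, abs=1e-12)
        assert mutual_information(table[:, ::-1]) == pytest.approx(mi, abs=1e-12)


class TestQuantileDiscretize:
    def test_equal_frequency(self):
        labels = quantile_discretize(np.arange(1, 101, dtype=float), 4)
        assert np.bincount(labels).tolist() == [25, 25, 25, 25]

    def test_constant_collapses_with_warning(self):
        with pytest.warns(UserWarning, match="distinct"):
            labels = quantile_discretize(np.full(10, 3.0), 4)
        assert len(np.unique(labels)) == 1

    def test_monotone_pair_reaches_log2_bins(self, rng):
        x = rng.normal(size=400)
        lx = quantile_discretize(x, 4)
        assert mutual_information_pairs(lx, lx) == pytest.approx(2.0, abs=1e-9)


class TestBulkCoordination:
    def test_monotone_function_saturates_mi(self, rng):
        m = pd.DataFrame({"s1": rng.random(400)})
        s = pd.DataFrame({"s1": np.exp(m["s1"])})
        res = bulk_coordination_mi(m, s, n_bins=4)
        assert res["mi"].iloc[0] == pytest.approx(2.0, abs=1e-9)

    def test_shuffled_pairing_below_permutation_null(self, rng):
        x = rng.random(300)
        y = rng.permutation(np.exp(x))  # independent pairing
        mi_obs = bulk_coordination_mi(
            pd.DataFrame({"s": x}), pd.DataFrame({"s": y})
        )["mi"].iloc[0]
        null = []
        for _ in range(200):
            null.append(
                bulk_coordination_mi(
                    pd.DataFrame({"s": x}), pd.DataFrame({"s": rng.permutation(y)})
                )["mi"].iloc[0]
            )
        assert mi_obs < np.quantile(null, 0.95)

    def test_too_few_regions_skipped(self):
        res = bulk_coordination_mi(
            pd.DataFrame({"s": np.arange(5.0)}), pd.DataFrame({"s": np.arange(5.0)})
        )
        assert res.empty

    def test_degraded_coupling_lowers_mi(self):
        from epicoherence.synthetic import simulate_bulk_coupled_methylation

        rng = np.random.default_rng(4)
        signal = rng.lognormal(1, 1, 500)
        levels, groups = simulate_bulk_coupled_methylation(signal, seed=4)
        sig = pd.DataFrame({s: signal for s in levels.columns})
        res = bulk_coordination_mi(levels, sig)
        res["group"] = res["sample"].map(groups)
        means = res.groupby("group")["mi"].mean()
        assert means["case"] < means["control"]


def _tiny_joint(expr, meth, total, groups=None):
    cells = [f"c{i}" for i in range(expr.shape[0])]
    genes = [f"g{j}" for j in range(expr.shape[1])]
    expr = pd.DataFrame(expr, index=cells, columns=genes)
    gene_meta = pd.DataFrame(
        {"is_mito": False, "is_ribo": False, "gene_length": 1000,
         "tss": np.arange(len(genes)) * 10_000, "chrom": "chr1"},
        index=pd.Index(genes, name="gene"),
    )
    totals = expr.sum(axis=1)
    cell_meta = pd.DataFrame({
        "total_reads": totals,
        "genes_detected": (expr > 0).sum(axis=1),
        "mito_frac": 0.0, "ribo_frac": 0.0,
        "group": groups if groups is not None else "g",
    })
    return SingleCellJoint(
        expression=expr,
        meth_cpg=pd.DataFrame(meth, index=cells, columns=genes),
        total_cpg=pd.DataFrame(total, index=cells, columns=genes),
        cell_meta=cell_meta,
        gene_meta=gene_meta,
    )


class TestScQc:
    def test_gene_count_boundary(self):
        n_genes = 600
        expr = np.ones((2, n_genes))
        expr[0, 500:] = 0  # cell 0 detects 500 genes, cell 1 detects 600
        expr[0, 499] = 0   # now cell 0 detects 499 -> removed
        joint = _tiny_joint(expr, np.zeros_like(expr), np.zeros_like(expr))
        qc = sc_qc(joint, drop_bottom_decile=False)
        assert list(qc.expression.index) == ["c1"]

    def test_mito_ribo_fraction(self):
        expr = np.ones((2, 10))
        joint = _tiny_joint(expr, np.zeros_like(expr), np.zeros_like(expr))
        joint.cell_meta.loc["c0", "mito_frac"] = 0.15
        joint.cell_meta.loc["c0", "ribo_frac"] = 0.10  # 0.25 > 0.2 -> removed
        qc = sc_qc(joint, min_genes=5, drop_bottom_decile=False)
        assert list(qc.expression.index) == ["c1"]

    def test_decile_removes_exactly_one_of_ten_ties(self):
        expr = np.ones((10, 10))
        joint = _tiny_joint(expr, np.zeros_like(expr), np.zeros_like(expr))
        qc = sc_qc(joint, min_genes=5)
        assert len(qc.expression) == 9
        assert "c0" not in qc.expression.index  # tie broken by cell id

    def test_all_removed_raises(self):
        expr = np.zeros((3, 10))
        joint = _tiny_joint(expr, np.zeros_like(expr), np.zeros_like(expr))
        with pytest.raises(ValueError, match="attrition"):
            sc_qc(joint, min_genes=5)


class TestDownsample:
    def test_cell_at_cutoff_unchanged_and_expectation(self, rng):
        expr = pd.DataFrame({"g0": [800, 0], "g1": [0, 1000]}, index=["a", "b"]).T.T
        expr = pd.DataFrame([[800, 0], [0, 1000]], index=["a", "b"], columns=["g0", "g1"])
        out = downsample_cells(expr, seed=1, cutoff=800)
        assert out.loc["a"].sum() == 800  # at cutoff: untouched
        thinned = [downsample_cells(expr, seed=s, cutoff=800).loc["b"].sum() for s in range(40)]
        assert np.mean(thinned) == pytest.approx(800, rel=0.02)

    def test_deterministic(self, rng):
        expr = pd.DataFrame(rng.integers(0, 50, (5, 20)))
        a = downsample_cells(expr, seed=7)
        b = downsample_cells(expr, seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestPromoterMethRate:
    def test_min_cpg_rule(self):
        meth = np.array([[9, 5, 0]])
        total = np.array([[10, 9, 0]])
        joint = _tiny_joint(np.ones((1, 3)), meth, total)
        rate = promoter_meth_rate(joint)
        assert rate.iloc[0, 0] == pytest.approx(0.9)
        assert np.isnan(rate.iloc[0, 1])  # 9 < 10 observations
        assert np.isnan(rate.iloc[0, 2])


class TestScGeneFilter:
    def test_detection_and_meth_call_rules(self):
        n_cells = 100
        expr = np.zeros((n_cells, 3))
        expr[:4, 0] = 1          # gene 0: 4 cells -> removed
        expr[:12, 1] = 1         # gene 1: 12 cells (12%) -> kept if meth ok
        expr[:12, 2] = 1
        total = np.zeros((n_cells, 3))
        total[:, 1] = 12
        total[:9, 2] = 12        # gene 2: only 9 cells with meth calls -> removed
        meth = np.zeros_like(total)
        joint = _tiny_joint(expr, meth, total)
        rate = promoter_meth_rate(joint)
        kept = sc_gene_filter(joint.expression, rate)
        assert list(kept) == ["g1"]


class TestSingleCellMi:
    def test_deterministic_relation_equals_expression_entropy(self):
        # methylated genes are exactly the silent genes
        n = 40
        expr = np.zeros((1, n))
        expr[0, : n // 4] = 5
        meth = np.where(expr > 0, 0, 12)
        total = np.full_like(meth, 12)
        joint = _tiny_joint(expr, meth, total)
        rate = promoter_meth_rate(joint)
        mi = sc_matched_mi(joint.expression, rate)
        p = 0.25
        h = -(p * np.log2(p) + (1 - p) * np.log2(1 - p))
        assert mi.iloc[0] == pytest.approx(h, abs=1e-12)

    def test_cell_below_gene_minimum_excluded(self):
        expr = np.ones((1, 5))
        total = np.full((1, 5), 12)
        joint = _tiny_joint(expr, np.zeros_like(total), total)
        rate = promoter_meth_rate(joint)
        assert np.isnan(sc_matched_mi(joint.expression, rate).iloc[0])

    def test_scrambled_deterministic_and_independent_of_matched(self, rng):
        expr = pd.DataFrame(rng.integers(0, 3, (30, 60)))
        total = pd.DataFrame(np.full((30, 60), 12))
        meth = pd.DataFrame(rng.integers(0, 13, (30, 60)))
        rate = (meth / total).where(total >= 10)
        a = sc_scrambled_mi(expr, rate, seed=3, n_rounds=20)
        b = sc_scrambled_mi(expr, rate, seed=3, n_rounds=20)
        pd.testing.assert_series_equal(a, b)


class TestUpliftReport:
    def test_zero_uplift_when_equal(self, rng):
        mi = pd.Series(rng.random(20))
        groups = pd.Series(["a"] * 10 + ["b"] * 10, index=mi.index)
        rep = mi_uplift_report(mi, mi.copy(), groups, n_boot=50, seed=0)
        assert rep.per_group["uplift_percent"].abs().max() == pytest.approx(0.0, abs=1e-12)
        assert (rep.per_cell["uplift_percent"].abs() < 1e-12).all()

    def test_group_comparison_p(self, rng):
        matched = pd.Series(np.r_[rng.normal(2, 0.1, 30), rng.normal(1.2, 0.1, 30)])
        scrambled = pd.Series(np.full(60, 1.0))
        groups = pd.Series(["case"] * 30 + ["control"] * 30)
        rep = mi_uplift_report(matched, scrambled, groups, n_boot=50, seed=0)
        assert rep.between_group_p < 1e-6
        case = rep.per_group.set_index("group").loc["case"]
        assert case["ci_low"] <= case["uplift_percent"] <= case["ci_high"]
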