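import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from citegate import (
    Assay,
    OmicsContainer,
    ValidationError,
    coexpression_table,
    compute_qc,
    group_compare,
    midpoint_threshold,
)


def _container(adt=None, rna=None, meta=None, n=None):
    mats = {}
    if rna is not None:
        rna = np.asarray(rna)
        mats["RNA"] = Assay(pd.Index([f"g{i}" for i in range(rna.shape[1])]),
                            sp.csr_matrix(rna))
        n = rna.shape[0]
    if adt is not None:
        adt = np.asarray(adt)
        mats["ADT"] = Assay(pd.Index([f"ab{i}" for i in range(adt.shape[1])]),
                            sp.csr_matrix(adt))
        n = adt.shape[0]
    barcodes = pd.Index([f"b{i}" for i in range(n)])
    return OmicsContainer(barcodes=barcodes, assays=mats,
                          cell_meta=None if meta is None
                          else pd.DataFrame(meta, index=barcodes))


class TestComputeQc:
    def test_detection_is_raw_count_positive(self):
        qc = compute_qc(_container(adt=[[0, 2, 0, 7]]))
        assert qc["n_antibodies_detected"].iloc[0] == 2
        assert qc["total_adt_counts"].iloc[0] == 9

    def test_all_zero_cell(self):
        qc = compute_qc(_container(adt=[[0, 0]], rna=np.zeros((1, 3))))
        assert (qc.iloc[0][["total_rna_counts", "n_genes_detected",
                            "total_adt_counts", "n_antibodies_detected"]] == 0).all()

    def test_absent_assay_metrics_omitted_not_zero_filled(self):
        qc = compute_qc(_container(adt=[[1, 2]]))
        assert "total_rna_counts" not in qc.columns
        assert "total_adt_counts" in qc.columns

    def test_matches_generator_bookkeeping(self, pbmc_small):
        container, _ = pbmc_small
        qc = compute_qc(container)
        rna = container.assays["RNA"].raw.toarray()
        adt = container.assays["ADT"].raw.toarray()
        np.testing.assert_array_equal(qc["total_rna_counts"], rna.sum(axis=1))
        np.testing.assert_array_equal(qc["n_genes_detected"], (rna > 0).sum(axis=1))
        np.testing.assert_array_equal(qc["total_adt_counts"], adt.sum(axis=1))
        np.testing.assert_array_equal(qc["n_antibodies_detected"], (adt > 0).sum(axis=1))
        assert qc["n_genes_detected"].max() <= rna.shape[1]

    def test_invariant_to_normalization(self, pbmc_small):
        container, _ = pbmc_small
        qc1 = compute_qc(container)
        stripped = container.subset(container.barcodes)
        stripped.assays["ADT"].normalized = None
        qc2 = compute_qc(stripped)
        pd.testing.assert_frame_equal(qc1, qc2, check_categorical=False)


class TestGroupCompare:
    @staticmethod
    def _qc(values_by_group):
        rows = [(v, g) for g, vals in values_by_group.items() for v in vals]
        return pd.DataFrame(rows, columns=["metric", "grp"],
                            index=[f"b{i}" for i in range(len(rows))])

    def test_degenerate_zero_between_group_variance(self):
        qc = self._qc({"a": [5, 5], "b": [5, 5], "c": [5, 5]})
        res = group_compare(qc, "metric", "grp")
        assert res.anova_f == 0.0 and res.anova_p == 1.0
        assert (res.pairs["padj"] == 1.0).all()
        assert len(res.pairs) == 3  # k(k-1)/2

    def test_two_group_tukey_equals_anova_p(self):
        rng = np.random.default_rng(8)
        qc = self._qc({"a": rng.normal(0, 1, 40), "b": rng.normal(0.4, 1, 35)})
        res = group_compare(qc, "metric", "grp")
        assert res.pairs["padj"].iloc[0] == pytest.approx(res.anova_p, abs=1e-6)

    def test_matches_statsmodels_tukey(self):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        rng = np.random.default_rng(3)
        data = {g: rng.normal(mu, 1.0, 30) for g, mu in
                [("a", 0.0), ("b", 0.5), ("c", 0.2), ("d", 1.0)]}
        qc = self._qc(data)
        res = group_compare(qc, "metric", "grp")
        values = np.concatenate([data[g] for g in sorted(data)])
        labels = np.repeat(sorted(data), [len(data[g]) for g in sorted(data)])
        sm = pairwise_tukeyhsd(values, labels)
        np.testing.assert_allclose(res.pairs["mean_diff"], sm.meandiffs, atol=1e-10)
        # statsmodels interpolates a lookup table; agree to its precision
        np.testing.assert_allclose(res.pairs["padj"], sm.pvalues, atol=5e-3)

    def test_power_three_sd_shift(self):
        # two groups whose means differ by 3 within-group SDs at n=100
        # should essentially always be flagged
        for seed in range(25):
            rng = np.random.default_rng(100 + seed)
            qc = self._qc({"a": rng.normal(0, 1, 100), "b": rng.normal(3, 1, 100)})
            res = group_compare(qc, "metric", "grp")
            assert res.pairs["padj"].iloc[0] < 0.05

    def test_small_group_dropped_with_warning(self):
        qc = self._qc({"a": [1, 2, 3], "b": [2, 3, 4], "c": [9]})
        with pytest.warns(UserWarning, match="'c'"):
            res = group_compare(qc, "metric", "grp")
        assert set(res.groups["group"]) == {"a", "b"}

    def test_fewer_than_two_groups_is_error(self):
        qc = self._qc({"a": [1, 2, 3], "b": [9]})
        with pytest.warns(UserWarning):
            with pytest.raises(ValidationError, match=">= 2 groups"):
                group_compare(qc, "metric", "grp")

    def test_padj_bounds_and_pair_count(self, pbmc_small):
        from citegate import compute_qc

        container, _ = pbmc_small
        res = group_compare(compute_qc(container), "n_antibodies_detected", "donor")
        k = len(res.groups)
        assert len(res.pairs) == k * (k - 1) // 2
        assert res.pairs["padj"].between(0, 1).all()


class TestCoexpression:
    def test_minus_inf_thresholds_all_double_positive(self, pbmc_small):
        container, _ = pbmc_small
        t = coexpression_table(container, "ADT", "CD14", "ADT", "CD16",
                               thresholds=(-np.inf, -np.inf))
        assert (t["quadrant"] == "double_positive").all()

    def test_quadrant_counts_sum_to_n(self, pbmc_small):
        container, _ = pbmc_small
        t = coexpression_table(container, "ADT", "CD14", "ADT", "CD16")
        assert t["quadrant"].value_counts().sum() == container.n_cells

    def test_intermediate_monocytes_land_double_positive(self, pbmc_small):
        container, truth = pbmc_small
        thr = tuple(
            midpoint_threshold(container.feature_values("ADT", f))
            for f in ("CD14", "CD16")
        )
        t = coexpression_table(container, "ADT", "CD14", "ADT", "CD16", thresholds=thr)
        inter = truth.index[truth["population"] == "CD14_CD16_mono"]
        frac = (t.loc[inter, "quadrant"] == "double_positive").mean()
        assert frac >= 0.90

    def test_cross_assay_pair(self, pbmc_small):
        container, _ = pbmc_small
        t = coexpression_table(container, "RNA", "gene0000", "ADT", "CD3")
        assert len(t) == container.n_cells
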