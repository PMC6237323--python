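"""RPKM, cell QC and the four-comparison signature procedure."""

import math

import numpy as np
import pandas as pd
import pytest

from tcrprofile import (QCThresholds, compute_rpkm, de_compare, qc_filter,
                        signature_intersection, simulate_expression)


def _rpkm_inputs(counts):
    genes = [f"G{i}" for i in range(counts.shape[0])]
    cells = [f"c{i}" for i in range(counts.shape[1])]
    return pd.DataFrame(counts, index=genes, columns=cells), genes, cells


class TestComputeRpkm:
    @pytest.mark.parametrize("count,length,total,expected", [
        (10, 1000, 1_000_000, 10.0),
        (0, 1000, 1_000_000, 0.0),
        (100, 2000, 10_000_000, 5.0),
    ])
    def test_unit_arithmetic(self, count, length, total, expected):
        counts, genes, cells = _rpkm_inputs(np.array([[count]]))
        rpkm = compute_rpkm(counts, pd.Series([length], index=genes),
                            pd.Series([total], index=cells))
        assert rpkm.iloc[0, 0] == pytest.approx(expected)

    def test_linear_in_counts_and_inverse_in_depth(self):
        counts, genes, cells = _rpkm_inputs(np.array([[10, 20]]))
        lengths = pd.Series([500], index=genes)
        r1 = compute_rpkm(counts, lengths, pd.Series([1e6, 1e6], index=cells))
        r2 = compute_rpkm(2 * counts, lengths, pd.Series([2e6, 2e6], index=cells))
        pd.testing.assert_frame_equal(r1, r2)
        assert r1.iloc[0, 1] == 2 * r1.iloc[0, 0]

    def test_zero_total_cell_excluded(self):
        counts, genes, cells = _rpkm_inputs(np.array([[5, 5]]))
        rpkm = compute_rpkm(counts, pd.Series([500], index=genes),
                            pd.Series([1e6, 0.0], index=cells))
        assert list(rpkm.columns) == [cells[0]]

    def test_nonpositive_length_rejected(self):
        counts, genes, cells = _rpkm_inputs(np.array([[5]]))
        with pytest.raises(ValueError, match="length"):
            compute_rpkm(counts, pd.Series([0], index=genes),
                         pd.Series([1e6], index=cells))


class TestQcFilter:
    def test_total_read_boundary(self):
        em = simulate_expression(["a"] * 4 + ["b"] * 4, 20, 0, 0.0, seed=0)
        em.cell_metrics.loc[em.cells[0], "total_reads"] = 9.9e5
        em.cell_metrics.loc[em.cells[1], "total_reads"] = 1.0e6
        report = qc_filter(em)
        assert not report.loc[em.cells[0], "total_reads_ok"]
        assert report.loc[em.cells[1], "total_reads_ok"]

    def test_keep_is_conjunction_of_rules(self):
        em = simulate_expression(["a"] * 4 + ["b"] * 4, 20, 0, 0.0, seed=1)
        report = qc_filter(em)
        rules = report[["marker_positive", "total_reads_ok",
                        "exon_ratio_ok", "mito_ok"]]
        assert report["keep"].equals(rules.all(axis=1))

    def test_missing_metric_rejected(self):
        em = simulate_expression(["a"] * 4 + ["b"] * 4, 20, 0, 0.0, seed=2)
        em.cell_metrics = em.cell_metrics.drop(columns=["mito_fraction"])
        with pytest.raises(ValueError, match="mito_fraction"):
            qc_filter(em)

    def test_thresholds_configurable(self):
        em = simulate_expression(["a"] * 4 + ["b"] * 4, 20, 0, 0.0, seed=3)
        strict = qc_filter(em, thresholds=QCThresholds(min_total_reads=5e6))
        assert not strict["total_reads_ok"].any()


class TestDeCompare:
    def _planted(self, seed=0, effect=2.0):
        em = simulate_expression(["a"] * 50 + ["b"] * 50, 300, 30, effect, seed=seed)
        rpkm = compute_rpkm(em.counts, em.gene_lengths,
                            em.cell_metrics["total_reads"])
        a = [c for c in em.cells if em.cell_labels[c] == "a"]
        b = [c for c in em.cells if em.cell_labels[c] == "b"]
        return em, rpkm, a, b

    def test_planted_four_fold_genes_flagged(self):
        em, rpkm, a, b = self._planted()
        de = de_compare(rpkm, a, b)
        flagged = de.loc[em.de_genes, "significant"]
        assert flagged.mean() > 0.9

    def test_presence_rule_excludes_sporadic_genes(self):
        """A gene below 1 RPKM in >50% of the higher-expressing group is
        excluded regardless of fold change."""
        cells = [f"c{i}" for i in range(10)]
        a, b = cells[:5], cells[5:]
        row = [3.0, 2.5, 0.0, 0.0, 0.0, 0.1, 0.1, 0.1, 0.1, 0.1]
        rpkm = pd.DataFrame([row], index=["G0"], columns=cells)
        de = de_compare(rpkm, a, b)
        assert not de.loc["G0", "tested"]
        assert not de.loc["G0", "significant"]

    def test_null_type_one_error_near_nominal(self):
        """Identical group distributions: the t-test flags ~5% of tested
        genes at p <= 0.05 (within 3 binomial SDs over 2000 null genes)."""
        em = simulate_expression(["a"] * 50 + ["b"] * 50, 2000, 0, 0.0, seed=7)
        rpkm = compute_rpkm(em.counts, em.gene_lengths,
                            em.cell_metrics["total_reads"])
        a = [c for c in em.cells if em.cell_labels[c] == "a"]
        b = [c for c in em.cells if em.cell_labels[c] == "b"]
        de = de_compare(rpkm, a, b)
        tested = de["tested"]
        rate = (de.loc[tested, "p_value"] <= 0.05).mean()
        sd = math.sqrt(0.05 * 0.95 / tested.sum())
        assert abs(rate - 0.05) < 3 * sd

    def test_small_group_rejected(self):
        em, rpkm, a, b = self._planted()
        with pytest.raises(ValueError, match="at least 2"):
            de_compare(rpkm, a[:1], b)


class TestSignatureIntersection:
    def _de(self, seed):
        em = simulate_expression(["a"] * 20 + ["b"] * 20, 100, 10, 2.0, seed=seed)
        rpkm = compute_rpkm(em.counts, em.gene_lengths,
                            em.cell_metrics["total_reads"])
        a = [c for c in em.cells if em.cell_labels[c] == "a"]
        b = [c for c in em.cells if em.cell_labels[c] == "b"]
        return de_compare(rpkm, a, b)

    def test_four_identical_results_return_their_set(self):
        de = self._de(0)
        sig = signature_intersection([de] * 4)
        assert set(sig.index) == set(de.index[de["significant"]])

    def test_one_empty_set_empties_intersection(self):
        de = self._de(1)
        null = de.copy()
        null["significant"] = False
        assert len(signature_intersection([de, de, de, null])) == 0

    def test_order_invariance(self):
        des = [self._de(s) for s in (2, 3, 4, 5)]
        s1 = signature_intersection(des)
        s2 = signature_intersection(des[::-1])
        assert list(s1.index) == list(s2.index)

    def test_requires_exactly_four(self):
        de = self._de(6)
        with pytest.raises(ValueError, match="4"):
            signature_intersection([de, de])

    def test_mismatched_universe_rejected(self):
        de = self._de(7)
        other = de.iloc[:-1]
        with pytest.raises(ValueError, match="universe"):
            signature_intersection([de, de, de, other])

    def test_ranked_by_average_fold_change(self):
        de = self._de(8)
        sig = signature_intersection([de] * 4)
        keys = sig["rank_key"].to_numpy()
        assert (np.diff(keys) <= 1e-12).all()
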