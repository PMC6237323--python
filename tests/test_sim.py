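"""Repertoire generation and the observation layers (cells, reads, callers,
expression)."""

import math

import numpy as np
import pytest
from scipy import stats

from tcrprofile import (EXPANDED_HEAD, SamplingConfig, emulate_callers,
                        make_repertoire, sample_bulk_reads, sample_cells,
                        simulate_expression)


class TestMakeRepertoire:
    def test_custom_head_plus_singletons_sums_to_one(self):
        """The tumour census head (13..2 cells of 89) plus 39 singleton
        clones of 1/89 is a valid frequency vector."""
        rep = make_repertoire("custom", 49, freqs=EXPANDED_HEAD, seed=0)
        assert rep.frequencies.sum() == pytest.approx(1.0, abs=1e-9)
        assert rep.clones[0].frequency == pytest.approx(13 / 89)
        assert rep.clones[-1].frequency == pytest.approx(1 / 89)

    def test_diverse_uniform_case(self):
        rep = make_repertoire("diverse", 4, max_freq=1.0, seed=0)
        assert np.allclose(rep.frequencies, 0.25)

    def test_diverse_max_frequency_cap(self):
        rep = make_repertoire("diverse", 5000, max_freq=1e-3,
                              diverse_sigma=0.8, seed=0)
        assert rep.frequencies.max() <= 1e-3 + 1e-12
        assert rep.frequencies.sum() == pytest.approx(1.0)

    def test_expanded_head_and_geometric_tail(self):
        rep = make_repertoire("expanded", 100, seed=0)
        f = rep.frequencies
        assert f[0] == pytest.approx(13 / 89)
        assert f.sum() == pytest.approx(1.0, abs=1e-9)
        tail = f[10:]
        assert np.allclose(tail[1:] / tail[:-1], tail[1] / tail[0])

    def test_same_seed_identical_repertoires(self):
        r1 = make_repertoire("expanded", 50, seed=42)
        r2 = make_repertoire("expanded", 50, seed=42)
        assert r1.clones == r2.clones

    def test_overweight_vector_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            make_repertoire("custom", 3, freqs=[0.9, 0.9], seed=0)

    def test_pairs_distinct(self):
        rep = make_repertoire("diverse", 500, max_freq=1.0, seed=1)
        pairs = {(c.alpha, c.beta) for c in rep.clones}
        assert len(pairs) == 500


class TestSampleCells:
    def test_noiseless_limit_one_call_per_chain(self):
        rep = make_repertoire("diverse", 10, max_freq=1.0, seed=0)
        cfg = SamplingConfig(n_cells=50, p_detect_alpha=1.0, p_detect_beta=1.0,
                             biallelic_rate={"alpha": 0.0, "beta": 0.0})
        cells = sample_cells(rep, cfg, seed=1)
        assert all(len(c.alpha_calls) == 1 and len(c.beta_calls) == 1
                   for c in cells)

    def test_zero_detection_means_zero_calls(self):
        rep = make_repertoire("diverse", 10, max_freq=1.0, seed=0)
        cfg = SamplingConfig(n_cells=50, p_detect_beta=0.0)
        cells = sample_cells(rep, cfg, seed=1)
        assert all(not c.beta_calls for c in cells)

    def test_zero_cells_is_empty_not_error(self):
        rep = make_repertoire("diverse", 10, max_freq=1.0, seed=0)
        assert sample_cells(rep, SamplingConfig(n_cells=0), seed=1) == []

    def test_detection_rate_binomial_oracle(self):
        rep = make_repertoire("diverse", 10, max_freq=1.0, seed=0)
        cfg = SamplingConfig(n_cells=10_000, p_detect_beta=0.85,
                             biallelic_rate={"alpha": 0.0, "beta": 0.0})
        cells = sample_cells(rep, cfg, seed=2)
        frac = sum(bool(c.beta_calls) for c in cells) / len(cells)
        sd = math.sqrt(0.85 * 0.15 / 10_000)
        assert abs(frac - 0.85) < 3 * sd

    def test_cell_frequencies_converge_to_repertoire(self):
        """Chi-square goodness of fit to the clone distribution is not
        rejected at alpha=0.001 for 1e5 cells on a 10-clone repertoire."""
        rep = make_repertoire("custom", 10,
                              freqs=[0.3, 0.2, 0.15, 0.1, 0.08, 0.07, 0.04,
                                     0.03, 0.02, 0.01], seed=0)
        cfg = SamplingConfig(n_cells=100_000, p_detect_alpha=1.0,
                             p_detect_beta=1.0,
                             biallelic_rate={"alpha": 0.0, "beta": 0.0})
        cells = sample_cells(rep, cfg, seed=3)
        counts = {}
        for c in cells:
            counts[c.beta_calls[0]] = counts.get(c.beta_calls[0], 0) + 1
        observed = [counts.get(cl.beta, 0) for cl in rep.clones]
        expected = [cl.frequency * len(cells) for cl in rep.clones]
        _, p = stats.chisquare(observed, expected)
        assert p > 0.001


class TestSampleBulkReads:
    def test_read_count_binomial_oracle(self):
        """~150M total reads at a 2e-5 beta CDR3 fraction yield ~3000 CDR3
        reads; the mean over replicates sits within 3 SEs of the mean."""
        rep = make_repertoire("expanded", 100, seed=0)
        cfg = SamplingConfig(total_reads=150_000_000,
                             cdr3_read_fraction={"alpha": 1e-5, "beta": 2e-5})
        n_rep = 10
        draws = [sample_bulk_reads(rep, cfg, "beta", seed=40 + i).total_reads()
                 for i in range(n_rep)]
        expected = 150e6 * 2e-5
        se = math.sqrt(expected * (1 - 2e-5) / n_rep)
        assert abs(np.mean(draws) - expected) < 3 * se

    def test_no_ambiguity_means_all_single_candidate(self):
        rep = make_repertoire("expanded", 50, seed=0)
        cfg = SamplingConfig(ambiguous_v_rate={"alpha": 0.0, "beta": 0.0})
        t = sample_bulk_reads(rep, cfg, "beta", seed=5)
        assert all(r.candidate_v_count == 1 for r in t.rows)

    def test_single_clone_repertoire_all_reads_on_it(self):
        rep = make_repertoire("custom", 1, freqs=[1.0], seed=0)
        t = sample_bulk_reads(rep, SamplingConfig(), "beta", seed=6)
        keys = {r.clonotype.chain_key for r in t.rows}
        assert keys == {rep.clones[0].beta.chain_key}

    def test_ambiguous_rows_include_true_v(self):
        rep = make_repertoire("expanded", 50, seed=0)
        cfg = SamplingConfig(ambiguous_v_rate={"alpha": 0.3, "beta": 0.3})
        t = sample_bulk_reads(rep, cfg, "beta", seed=7)
        assert any(r.candidate_v_count > 1 for r in t.rows)
        for r in t.rows:
            assert r.true_clonotype.v_genes <= r.clonotype.v_genes

    def test_read_conservation_over_rows(self):
        rep = make_repertoire("expanded", 50, seed=0)
        cfg = SamplingConfig(ambiguous_v_rate={"alpha": 0.2, "beta": 0.2})
        rng = np.random.default_rng(8)
        n_before = rng.binomial(cfg.total_reads, cfg.cdr3_read_fraction["beta"])
        t = sample_bulk_reads(rep, cfg, "beta", seed=8)
        # same seed: the first binomial draw is the CDR3 read count
        assert t.total_reads() == n_before


class TestEmulateCallers:
    def test_noiseless_callers_reproduce_truth(self):
        rep = make_repertoire("expanded", 50, seed=0)
        t = sample_bulk_reads(rep, SamplingConfig(), "beta", seed=9)
        callers = emulate_callers(t, 3, dropout_rate=0.0, spurious_rate=0.0,
                                  v_widening_rate=0.0, seed=10)
        truth_ids = {(r.clonotype, r.read_count) for r in t.rows}
        for c in callers:
            assert {(r.clonotype, r.read_count) for r in c.rows} == truth_ids

    def test_total_dropout_leaves_only_spurious(self):
        rep = make_repertoire("expanded", 50, seed=0)
        t = sample_bulk_reads(rep, SamplingConfig(), "beta", seed=11)
        callers = emulate_callers(t, 2, dropout_rate=1.0, spurious_rate=0.1,
                                  v_widening_rate=0.0, seed=12)
        for c in callers:
            assert all(r.true_clonotype is None for r in c.rows)

    def test_retained_count_binomial_oracle(self):
        rep = make_repertoire("diverse", 200, max_freq=1.0, seed=0)
        cfg = SamplingConfig(total_reads=50_000_000,
                             cdr3_read_fraction={"alpha": 2e-4, "beta": 2e-4},
                             ambiguous_v_rate={"alpha": 0.0, "beta": 0.0})
        t = sample_bulk_reads(rep, cfg, "beta", seed=13)
        n_true = len(t.unique_clonotypes())
        counts = []
        for rep_i in range(10):
            callers = emulate_callers(t, 3, dropout_rate=0.2, spurious_rate=0.0,
                                      v_widening_rate=0.0, seed=100 + rep_i)
            counts.extend(sum(1 for r in c.rows if r.true_clonotype) for c in callers)
        mean_kept = np.mean(counts)
        sd = math.sqrt(n_true * 0.8 * 0.2) / math.sqrt(len(counts))
        assert abs(mean_kept - 0.8 * n_true) < 3 * sd

    def test_rates_validated(self):
        rep = make_repertoire("expanded", 20, seed=0)
        t = sample_bulk_reads(rep, SamplingConfig(), "beta", seed=14)
        with pytest.raises(ValueError, match="rates"):
            emulate_callers(t, 2, dropout_rate=1.5)
        with pytest.raises(ValueError, match="k_callers"):
            emulate_callers(t, 1)


class TestSimulateExpression:
    def test_null_effect_has_no_de_truth(self):
        em = simulate_expression(["a"] * 5 + ["b"] * 5, 50, 0, 0.0, seed=0)
        assert em.de_genes == []

    def test_fixed_seed_is_bit_reproducible(self):
        em1 = simulate_expression(["a"] * 5 + ["b"] * 5, 50, 5, 1.0, seed=1)
        em2 = simulate_expression(["a"] * 5 + ["b"] * 5, 50, 5, 1.0, seed=1)
        assert em1.counts.equals(em2.counts)
        assert em1.cell_metrics.equals(em2.cell_metrics)

    def test_planted_fold_change_recovered(self):
        """A 4-fold planted gene with 50 cells per group shows an empirical
        group mean-RPKM ratio within 3 SD of 4."""
        from tcrprofile.signature import compute_rpkm

        em = simulate_expression(["a"] * 50 + ["b"] * 50, 200, 20, 2.0,
                                 noise_params={"sigma": 0.3}, seed=2)
        rpkm = compute_rpkm(em.counts, em.gene_lengths,
                            em.cell_metrics["total_reads"])
        a_cols = em.cells[:50]
        b_cols = em.cells[50:]
        ratios = []
        for g in em.de_genes:
            ra, rb = rpkm.loc[g, a_cols], rpkm.loc[g, b_cols]
            ratio = ra.mean() / rb.mean()
            se = ratio * math.sqrt((ra.std() / ra.mean()) ** 2 / 50
                                   + (rb.std() / rb.mean()) ** 2 / 50)
            ratios.append((ratio, se))
        within = sum(abs(r - 4.0) < 3 * se for r, se in ratios)
        assert within >= 18  # ~all 20, allowing rare 3-SD excursions

    def test_n_de_validated(self):
        with pytest.raises(ValueError, match="n_de"):
            simulate_expression(["a", "a", "b", "b"], 10, 11, 1.0, seed=0)

    def test_planted_qc_failures_recovered(self):
        from tcrprofile.signature import qc_filter

        em = simulate_expression(["a"] * 200 + ["b"] * 200, 30, 0, 0.0, seed=3,
                                 qc_fail_fractions={"total": 0.1, "exon": 0.1,
                                                    "mito": 0.1, "marker": 0.1})
        report = qc_filter(em)
        n = len(report)
        sd = math.sqrt(0.1 * 0.9 / n)
        for col in ("marker_positive", "total_reads_ok", "exon_ratio_ok", "mito_ok"):
            frac_fail = 1.0 - report[col].mean()
            assert abs(frac_fail - 0.1) < 3 * sd, col
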