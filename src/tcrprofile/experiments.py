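"""Reusable study drivers: the worked examples computed from the printed
single-cell/bulk censuses, and the seeded simulation experiments.

These functions are the single source for the analysis scripts, the test
suite and the acceptance script, so every reported number is recomputed by
the same code path.
"""

from __future__ import annotations

import numpy as np

from .abundance import (ambiguity_correlation, cell_detection_stats,
                        clonal_frequencies, fractional_counts, to_frequencies)
from .compare import overlap_report
from .consensus import consensus_call
from .io import ALPHA, BETA, CellCallSet, Clonotype
from .sim import (EXPANDED_HEAD, Repertoire, SamplingConfig, emulate_callers,
                  make_repertoire, sample_bulk_reads, sample_cells)

# Clone cell counts observed among the 89 tumour-infiltrating cells with a
# TCR detected: the top ten clones and 39 singletons.
TUMOR_CLONE_CELL_COUNTS: tuple[int, ...] = (13, 12, 6, 5, 3, 3, 2, 2, 2, 2) + (1,) * 39

# Single-cell detection census: per tissue and locus, (cells sequenced,
# cells with a TCR called, of which biallelic).
SINGLE_CELL_CENSUS = {
    "tumor": {"n_cells": 92, ALPHA: (63, 7), BETA: (78, 1)},
    "spleen": {"n_cells": 103, ALPHA: (59, 3), BETA: (79, 4)},
}

# Unique-TCRb counts from the bulk-vs-targeted platform comparison:
# (platform-A-only, overlap, platform-B-only) with A = bulk RNA-seq and
# B = targeted 5' RACE sequencing.
BULK_VS_TARGETED_UNIQUE = {
    "challenged": (841, 1682, 16697),
    "naive": (2590, 606, 82169),
}


_ENC = "ACDEFGHIKLMNPQRSTVWY"


def _dummy_clonotype(locus: str, i: int) -> Clonotype:
    """Distinct placeholder clonotype #i (CDR3 encodes i in base 20)."""
    v = "TRAV1" if locus == ALPHA else "TRBV1"
    j = "TRAJ2" if locus == ALPHA else "TRBJ1-1"
    digits = []
    x = i
    for _ in range(6):
        digits.append(_ENC[x % 20])
        x //= 20
    return Clonotype(locus=locus, v_genes=frozenset([v]),
                     cdr3_aa="CASS" + "".join(digits) + "F", j_gene=j)


def clone_census_cells(counts=TUMOR_CLONE_CELL_COUNTS) -> list[CellCallSet]:
    """Cells realising a clone-size census (one distinct alpha/beta pair per
    clone, every cell with both chains called)."""
    cells = []
    i = 0
    for ci, n in enumerate(counts):
        alpha = _dummy_clonotype(ALPHA, ci)
        beta = _dummy_clonotype(BETA, ci)
        for _ in range(n):
            cells.append(CellCallSet(f"cell{i:04d}", (alpha,), (beta,)))
            i += 1
    return cells


def clonal_abundance_percentages(counts=TUMOR_CLONE_CELL_COUNTS) -> list[float]:
    """Clone-level percentages (1 d.p.) from a cell census, ranked."""
    vec = clonal_frequencies(clone_census_cells(counts), level="clone")
    return [vec.percent(key) for key, _ in vec.ranked()]


def census_cells(n_cells: int, per_locus: dict[str, tuple[int, int]]) -> list[CellCallSet]:
    """Cells realising a per-locus detection census (called, biallelic)."""
    cells = []
    for i in range(n_cells):
        calls: dict[str, tuple] = {ALPHA: (), BETA: ()}
        for locus, (n_called, n_bi) in per_locus.items():
            if i < n_called:
                first = _dummy_clonotype(locus, i)
                if i < n_bi:
                    calls[locus] = (first, _dummy_clonotype(locus, n_cells + i))
                else:
                    calls[locus] = (first,)
        cells.append(CellCallSet(f"cell{i:04d}", calls[ALPHA], calls[BETA]))
    return cells


def detection_census_stats(tissue: str) -> dict[str, dict[str, float]]:
    """Detection/biallelic percentages recomputed from a tissue's census."""
    spec = SINGLE_CELL_CENSUS[tissue]
    cells = census_cells(spec["n_cells"], {ALPHA: spec[ALPHA], BETA: spec[BETA]})
    return cell_detection_stats(cells)


# ---------------------------------------------------------------------------
# Seeded simulation experiments

def consensus_recovery_experiment(n_clonotypes: int = 200, k_callers: int = 3,
                                  dropout: float = 0.2, n_reps: int = 20,
                                  seed: int = 0) -> dict[str, float]:
    """Fraction of true clonotypes surviving >= 2-of-k consensus under
    independent per-caller dropout, against the closed form
    1 - [d^3 + 3 d^2 (1-d)] for k = 3.
    """
    rng = np.random.default_rng(seed)
    recovered = 0
    total = 0
    for _ in range(n_reps):
        rep = make_repertoire("diverse", n_clonotypes, max_freq=1.0, rng=rng)
        config = SamplingConfig(total_reads=10_000_000,
                                cdr3_read_fraction={ALPHA: 2e-4, BETA: 2e-4},
                                ambiguous_v_rate={ALPHA: 0.0, BETA: 0.0})
        truth = sample_bulk_reads(rep, config, BETA, rng=rng)
        truth_keys = {r.clonotype.chain_key for r in truth.rows}
        callers = emulate_callers(truth, k_callers, dropout_rate=dropout,
                                  spurious_rate=0.0, v_widening_rate=0.0, rng=rng)
        cons = consensus_call(callers, min_agree=2)
        cons_keys = {r.clonotype.chain_key for r in cons.rows}
        recovered += len(truth_keys & cons_keys)
        total += len(truth_keys)
    d = dropout
    expected = 1.0 - (d ** 3 + 3 * d ** 2 * (1 - d))
    rate = recovered / total
    sd = float(np.sqrt(expected * (1 - expected) / total))
    return {"rate": rate, "expected": expected, "sd": sd, "n": total}


def topclone_recovery_experiment(n_seeds: int = 100, n_cells: int = 92,
                                 seed: int = 0) -> dict[str, float]:
    """Estimate the top clone's beta-chain clonal frequency by sampling
    cells from the tumour-like repertoire, pooled across seeds."""
    rng = np.random.default_rng(seed)
    rep = make_repertoire("custom", 49, freqs=EXPANDED_HEAD, rng=rng)
    truth = rep.clones[0].frequency
    top_beta = rep.clones[0].beta
    config = SamplingConfig(n_cells=n_cells, p_detect_beta=0.85,
                            biallelic_rate={ALPHA: 0.11, BETA: 0.01})
    top_calls = 0
    beta_cells = 0
    for _ in range(n_seeds):
        cells = sample_cells(rep, config, rng=rng)
        vec = clonal_frequencies(cells, level=BETA)
        top_calls += vec.entries.get(top_beta, 0.0)
        beta_cells += vec.denominator or 0.0
    estimate = top_calls / beta_cells
    sd = float(np.sqrt(truth * (1 - truth) / beta_cells))
    return {"estimate": estimate, "truth": truth, "sd": sd, "n": beta_cells}


def _platform_run(rep: Repertoire, config: SamplingConfig,
                  rng: np.random.Generator, dropout: float = 0.2,
                  spurious: float = 0.05, v_widening: float = 0.05):
    """One seeded single-cell-vs-bulk comparison at the beta locus.

    The bulk side is typed by 3 emulated callers followed by >= 2-caller
    consensus, mirroring how every platform was typed in the study; the
    single-cell side's detection probabilities already model the post-
    consensus per-cell call rates.
    """
    cells = sample_cells(rep, config, rng=rng)
    cell_vec = clonal_frequencies(cells, level=BETA)
    truth = sample_bulk_reads(rep, config, BETA, rng=rng)
    callers = emulate_callers(truth, 3, dropout_rate=dropout,
                              spurious_rate=spurious,
                              v_widening_rate=v_widening, rng=rng)
    cons = consensus_call(callers, min_agree=2)
    bulk_vec = fractional_counts(cons)
    return overlap_report(bulk_vec, cell_vec, label_a="bulk", label_b="single_cell")


def platform_contrast_experiment(n_runs: int = 100, seed: int = 0,
                                 n_clones_expanded: int = 1000,
                                 n_clones_diverse: int = 80_000) -> dict[str, float]:
    """The expanded-vs-diverse headline contrast as a sampling property.

    Expanded (tumour-like) repertoire, 100 cells vs ~3000 bulk CDR3 reads:
    fraction of runs in which the overlap carries >= 50% of bulk reads.
    Diverse repertoire (8e4 clones, max frequency 1e-3): fraction of runs
    with <= 5 overlapping unique clonotypes.
    """
    rng = np.random.default_rng(seed)
    rep_exp = make_repertoire("expanded", n_clones_expanded, rng=rng)
    rep_div = make_repertoire("diverse", n_clones_diverse, rng=rng)
    cfg_exp = SamplingConfig(n_cells=100)
    cfg_div = SamplingConfig.spleen_like(n_cells=100)
    exp_hits = 0
    div_hits = 0
    exp_pcts, div_overlaps = [], []
    for _ in range(n_runs):
        ov = _platform_run(rep_exp, cfg_exp, rng)
        exp_pcts.append(ov.pct_reads_overlap_a)
        exp_hits += ov.pct_reads_overlap_a >= 50.0
        ov = _platform_run(rep_div, cfg_div, rng)
        div_overlaps.append(ov.n_overlap)
        div_hits += ov.n_overlap <= 5
    return {
        "n_runs": n_runs,
        "expanded_runs_ge50pct": exp_hits,
        "expanded_mean_pct": float(np.mean(exp_pcts)),
        "diverse_runs_le5": div_hits,
        "diverse_mean_overlap": float(np.mean(div_overlaps)),
    }


def signature_experiment(seed: int = 0, n_null: int = 2000,
                         n_consistent: int = 20, n_partial: int = 30,
                         log2_effect: float = 2.0) -> dict[str, float]:
    """Planted four-comparison signature design.

    Cell groups mirror the study layout: the two largest clones (13 and 12
    cells), the singleton clones (39 cells) and the reference tissue (100
    cells).  ``n_consistent`` genes are shifted in both top clones (so they
    survive all four comparisons), ``n_partial`` genes in the first clone
    only (they must drop out of the intersection), the rest are null.
    Returns the recovery of the consistent set, false positives, and the
    null per-comparison false-positive rate.
    """
    from .signature import compute_rpkm, de_compare, signature_intersection
    from .sim import simulate_expression

    labels = (["cloneA"] * 13 + ["cloneB"] * 12 + ["singleton"] * 39
              + ["spleen"] * 100)
    n_genes = n_null + n_consistent + n_partial
    eff_a = np.zeros(n_genes)
    eff_a[: n_consistent + n_partial] = log2_effect
    eff_b = np.zeros(n_genes)
    eff_b[:n_consistent] = log2_effect
    em = simulate_expression(labels, n_genes, 0, 0.0, seed=seed,
                             group_effects={"cloneA": eff_a, "cloneB": eff_b})
    rpkm = compute_rpkm(em.counts, em.gene_lengths,
                        em.cell_metrics["total_reads"])
    by_group: dict[str, list[str]] = {}
    for cell, lab in em.cell_labels.items():
        by_group.setdefault(lab, []).append(cell)
    comparisons = [
        de_compare(rpkm, by_group["cloneA"], by_group["spleen"]),
        de_compare(rpkm, by_group["cloneB"], by_group["spleen"]),
        de_compare(rpkm, by_group["cloneA"], by_group["singleton"]),
        de_compare(rpkm, by_group["cloneB"], by_group["singleton"]),
    ]
    recovered = set(signature_intersection(comparisons).index)
    genes = list(em.counts.index)
    consistent = set(genes[:n_consistent])
    planted = set(genes[: n_consistent + n_partial])
    null_de = comparisons[0].iloc[n_consistent + n_partial: n_genes]
    tested = null_de["tested"]
    fpr = float((null_de.loc[tested, "p_value"] <= 0.05).mean())
    return {
        "recall": len(recovered & consistent) / n_consistent,
        "n_false": len(recovered - consistent),
        "n_partial_recovered": len(recovered & (planted - consistent)),
        "null_fpr": fpr,
        "n_null_tested": int(tested.sum()),
    }


def beta_ambiguity_experiment(seed: int = 0, n_clones: int = 500) -> float:
    """Pearson r between beta-chain transcript frequencies measured with
    (1/N-weighted) and without the ambiguously annotated reads, at the
    default TRBV ambiguity rate (<= 1%)."""
    rng = np.random.default_rng(seed)
    rep = make_repertoire("expanded", n_clones, rng=rng)
    config = SamplingConfig()
    table = sample_bulk_reads(rep, config, BETA, rng=rng)
    with_amb = to_frequencies(fractional_counts(table))
    without = to_frequencies(fractional_counts(table, drop_ambiguous=True))
    return ambiguity_correlation(with_amb, without)
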