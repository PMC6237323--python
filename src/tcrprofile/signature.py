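"""Single-cell QC filtering and the clone-signature DE procedure.

Expression is normalised to RPKM (reads per kilobase per million total
reads).  A cell passes QC when it is positive for a T-cell marker gene,
has >= 1 million total reads, a uniquely-mapped-exon ratio >= 0.5 and a
mitochondrial read fraction <= 0.25.  Differential expression between two
cell groups uses a two-sided Student's t-test on log2(RPKM + 1), a
mean-RPKM fold change, a presence filter (RPKM >= 1 in at least half the
cells of the higher-expressing group) and the thresholds |FC| >= 1.5,
p <= 0.05.  A clone-specific signature is the direction-consistent
intersection of four such comparisons, ranked by average fold change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix
from .sim import MARKER_GENES


def compute_rpkm(counts: pd.DataFrame, gene_lengths: pd.Series,
                 total_reads: pd.Series) -> pd.DataFrame:
    """RPKM = 1e9 * count / (length_bp * total_reads).

    Cells with a non-positive total are excluded from the result (their
    RPKM is undefined).
    """
    lengths = gene_lengths.reindex(counts.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("gene lengths must be positive for every gene")
    totals = total_reads.reindex(counts.columns)
    bad = totals.isna() | (totals <= 0)
    if bad.any():
        counts = counts.loc[:, ~bad.to_numpy()]
        totals = totals[~bad]
    return 1e9 * counts.div(lengths, axis=0).div(totals, axis=1)


@dataclass
class QCThresholds:
    marker_rpkm: float = 1.0
    min_total_reads: float = 1_000_000
    min_exon_ratio: float = 0.5
    max_mito_fraction: float = 0.25


def qc_filter(em: ExpressionMatrix,
              marker_genes: Sequence[str] = MARKER_GENES,
              thresholds: QCThresholds | None = None) -> pd.DataFrame:
    """Per-cell QC report: one boolean column per rule plus ``keep``.

    Rules: marker-positive (RPKM >= 1 for at least one marker gene),
    total reads >= 1e6, unique-exon ratio >= 0.5, mitochondrial
    fraction <= 0.25.  ``keep`` is their conjunction.
    """
    th = thresholds or QCThresholds()
    for col in ("total_reads", "unique_exon_ratio", "mito_fraction"):
        if col not in em.cell_metrics.columns:
            raise ValueError(f"missing metric column {col!r}")
    metrics = em.cell_metrics
    rpkm = compute_rpkm(em.counts, em.gene_lengths, metrics["total_reads"])
    markers = [g for g in marker_genes if g in em.counts.index]
    if markers:
        marker_pos = (rpkm.reindex(markers).fillna(0.0) >= th.marker_rpkm).any(axis=0)
        marker_pos = marker_pos.reindex(em.cells, fill_value=False)
    else:
        marker_pos = pd.Series(True, index=em.cells)
    report = pd.DataFrame({
        "marker_positive": marker_pos,
        "total_reads_ok": metrics["total_reads"] >= th.min_total_reads,
        "exon_ratio_ok": metrics["unique_exon_ratio"] >= th.min_exon_ratio,
        "mito_ok": metrics["mito_fraction"] <= th.max_mito_fraction,
    })
    report["keep"] = report.all(axis=1)
    return report


def de_compare(rpkm: pd.DataFrame, group_a: Sequence[str], group_b: Sequence[str],
               fc_threshold: float = 1.5, alpha: float = 0.05,
               presence_rpkm: float = 1.0, presence_fraction: float = 0.5,
               pseudocount: float = 1.0, equal_var: bool = True) -> pd.DataFrame:
    """Differential expression between two cell groups.

    Per gene: presence fractions (RPKM >= 1) in each group; genes not
    present in at least half the cells of the higher-expressing group are
    excluded (``tested`` False).  Fold change is the ratio of group mean
    RPKMs (A/B); p-values come from a two-sided Student's t-test on
    log2(RPKM + pseudocount).  ``significant`` requires tested, p <= alpha
    and FC >= 1.5 or <= 1/1.5.
    """
    a = list(group_a)
    b = list(group_b)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 cells")
    if set(a) & set(b):
        raise ValueError("groups must be disjoint")
    ra = rpkm[a].to_numpy()
    rb = rpkm[b].to_numpy()
    pres_a = (ra >= presence_rpkm).mean(axis=1)
    pres_b = (rb >= presence_rpkm).mean(axis=1)
    mean_a = ra.mean(axis=1)
    mean_b = rb.mean(axis=1)
    higher_presence = np.where(mean_a >= mean_b, pres_a, pres_b)
    tested = higher_presence >= presence_fraction

    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_b > 0, mean_a / mean_b, np.inf)
        fc = np.where(mean_a == 0, np.where(mean_b == 0, np.nan, 0.0), fc)
    la = np.log2(ra + pseudocount)
    lb = np.log2(rb + pseudocount)
    t, p = stats.ttest_ind(la, lb, axis=1, equal_var=equal_var)
    p = np.where(np.isnan(p), 1.0, p)

    with np.errstate(invalid="ignore"):
        fc_hit = (fc >= fc_threshold) | (fc <= 1.0 / fc_threshold)
    fc_hit = np.nan_to_num(fc_hit.astype(float), nan=0.0).astype(bool)
    significant = tested & (p <= alpha) & fc_hit
    return pd.DataFrame({
        "mean_rpkm_a": mean_a,
        "mean_rpkm_b": mean_b,
        "presence_a": pres_a,
        "presence_b": pres_b,
        "tested": tested,
        "fold_change": fc,
        "p_value": p,
        "significant": significant,
        "direction": np.where(fc > 1.0, "up", "down"),
    }, index=rpkm.index)


def signature_intersection(de_results: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Clone-specific signature: genes significant, with a consistent
    direction, in all four comparisons, ranked by average fold change.

    Down-regulated genes are ranked by the mean of the reciprocal fold
    changes so larger means always mean stronger perturbation.
    """
    if len(de_results) != 4:
        raise ValueError("the signature procedure intersects exactly 4 comparisons")
    universe = de_results[0].index
    for r in de_results[1:]:
        if not r.index.equals(universe):
            raise ValueError("mismatched gene universes across comparisons")
    sig = np.column_stack([r["significant"].to_numpy() for r in de_results])
    up = np.column_stack([(r["direction"] == "up").to_numpy() for r in de_results])
    fc = np.column_stack([r["fold_change"].to_numpy() for r in de_results])
    all_sig = sig.all(axis=1)
    consistent_up = all_sig & up.all(axis=1)
    consistent_down = all_sig & (~up).all(axis=1)
    keep = consistent_up | consistent_down
    with np.errstate(divide="ignore"):
        rank_key = np.where(consistent_up, fc.mean(axis=1), (1.0 / fc).mean(axis=1))
    out = pd.DataFrame({
        "direction": np.where(consistent_up, "up", "down"),
        "mean_fold_change": fc.mean(axis=1),
        "rank_key": rank_key,
    }, index=universe)[keep]
    return out.sort_values("rank_key", ascending=False)
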