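"""Cross-platform repertoire comparison statistics.

Two platforms (e.g. single-cell vs cell-pool RNA-seq, or bulk RNA-seq vs
targeted amplicon sequencing) each yield an abundance vector over V-CDR3-J
clonotypes.  Overlap uses the same identity rule as consensus calling:
identical CDR3 + J with a non-empty V-set intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .abundance import AbundanceVector, _sort_label
from .consensus import ConsensusTable
from .io import CallerTable, CellCallSet, Clonotype, LOCI


def _match_sets(A: AbundanceVector, B: AbundanceVector) -> tuple[set, set, list[tuple]]:
    """Clonotypes of A and of B that overlap, plus the matched pairs."""
    index: dict[tuple, list[Clonotype]] = {}
    for kb in B.entries:
        index.setdefault(kb.chain_key, []).append(kb)
    matched_a, matched_b, pairs = set(), set(), []
    for ka in A.entries:
        for kb in index.get(ka.chain_key, ()):
            if ka.v_genes & kb.v_genes:
                matched_a.add(ka)
                matched_b.add(kb)
                pairs.append((ka, kb))
    return matched_a, matched_b, pairs


@dataclass
class OverlapReport:
    """Unique-clonotype and read-share overlap between two platforms."""

    label_a: str
    label_b: str
    n_only_a: int
    n_overlap: int
    n_only_b: int
    pct_reads_overlap_a: float
    pct_reads_overlap_b: float

    def __post_init__(self):
        if min(self.n_only_a, self.n_overlap, self.n_only_b) < 0:
            raise ValueError("counts must be non-negative")
        for p in (self.pct_reads_overlap_a, self.pct_reads_overlap_b):
            if not (0.0 <= p <= 100.0):
                raise ValueError("percentages must lie in [0, 100]")

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def overlap_report(A: AbundanceVector, B: AbundanceVector,
                   label_a: str = "A", label_b: str = "B") -> OverlapReport:
    """Overlap between two abundance vectors on the same locus.

    Overlap identity: identical CDR3 + J with a non-empty V intersection.
    ``pct_reads_overlap_x`` is the percentage of side x's total weight
    carried by its overlapping clonotypes (1 decimal place).
    """
    if A.locus and B.locus and A.locus != B.locus:
        raise ValueError(f"mismatched loci: {A.locus} vs {B.locus}")
    matched_a, matched_b, _ = _match_sets(A, B)
    tot_a, tot_b = A.total(), B.total()
    wa = sum(A.entries[k] for k in matched_a)
    wb = sum(B.entries[k] for k in matched_b)
    return OverlapReport(
        label_a=label_a, label_b=label_b,
        n_only_a=len(A.entries) - len(matched_a),
        n_overlap=len(matched_a),
        n_only_b=len(B.entries) - len(matched_b),
        pct_reads_overlap_a=round(100.0 * wa / tot_a, 1) if tot_a > 0 else 0.0,
        pct_reads_overlap_b=round(100.0 * wb / tot_b, 1) if tot_b > 0 else 0.0,
    )


def detection_ratio(a_total_unique: int, b_total_unique: int) -> int:
    """100 * A/B to the nearest integer: what share of platform B's unique
    clonotypes platform A detected."""
    if b_total_unique <= 0:
        raise ValueError("denominator must be positive")
    return int(round(100.0 * a_total_unique / b_total_unique))


@dataclass
class TopkConcordance:
    n_shared: int
    pairs: list[tuple[Clonotype, Clonotype]] = field(default_factory=list)
    # shared between the platforms overall but top-k on only one side
    shared_topk_one_side: list[Clonotype] = field(default_factory=list)


def _topk(vec: AbundanceVector, k: int) -> list[Clonotype]:
    return [key for key, _ in vec.ranked()[:k]]


def topk_concordance(A: AbundanceVector, B: AbundanceVector, k: int = 10) -> TopkConcordance:
    """Matches between the top-k abundant clonotypes of each platform.

    Ranking is by weight, ties broken by the V|CDR3|J label.  Also reports
    clonotypes shared overall but ranked top-k by only one platform.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    top_a, top_b = _topk(A, k), _topk(B, k)
    sub_a = AbundanceVector({c: A.entries[c] for c in top_a}, locus=A.locus)
    sub_b = AbundanceVector({c: B.entries[c] for c in top_b}, locus=B.locus)
    matched_a, _, pairs = _match_sets(sub_a, sub_b)
    one_side = []
    for ka, kb in _match_sets(A, B)[2]:
        in_a = ka in set(top_a)
        in_b = kb in set(top_b)
        if in_a != in_b:
            one_side.append(ka if in_a else kb)
    return TopkConcordance(n_shared=len(matched_a), pairs=sorted(pairs, key=lambda p: p[0].label),
                           shared_topk_one_side=sorted(set(one_side), key=_sort_label))


@dataclass
class VJUsage:
    """Joint V x J usage frequencies (summing to 1)."""

    matrix: pd.DataFrame  # V genes x J genes
    basis: str  # 'reads' or 'cells'

    def __post_init__(self):
        vals = self.matrix.to_numpy()
        if (vals < 0).any():
            raise ValueError("usage entries must be non-negative")
        if vals.size and not np.isclose(vals.sum(), 1.0):
            raise ValueError("usage entries must sum to 1")

    def frequency(self, v: str, j: str) -> float:
        try:
            return float(self.matrix.at[v, j])
        except KeyError:
            return 0.0


def vj_usage(source: CallerTable | ConsensusTable | Sequence[CellCallSet],
             basis: str = "reads", locus: str | None = None) -> VJUsage:
    """V-J pair usage weighted by reads (1/N per ambiguous candidate) or cells.

    For the cell basis pass the cell call sets and the locus; every allele
    call contributes one cell count to its V-J pair.
    """
    weights: dict[tuple[str, str], float] = {}

    def add(clon: Clonotype, w: float):
        for cand in clon.split_candidates():
            (v,) = cand.v_genes
            key = (v, clon.j_gene)
            weights[key] = weights.get(key, 0.0) + w / len(clon.v_genes)

    if basis == "reads":
        if not isinstance(source, (CallerTable, ConsensusTable)):
            raise ValueError("reads basis requires a caller or consensus table")
        for row in source.rows:
            add(row.clonotype, row.read_count)
    elif basis == "cells":
        if locus not in LOCI:
            raise ValueError("cells basis requires locus='alpha' or 'beta'")
        for cell in source:
            for clon in cell.calls(locus):
                add(clon, 1.0)
    else:
        raise ValueError("basis must be 'reads' or 'cells'")

    if not weights:
        return VJUsage(matrix=pd.DataFrame(), basis=basis)
    total = sum(weights.values())
    vs = sorted({v for v, _ in weights})
    js = sorted({j for _, j in weights})
    mat = pd.DataFrame(0.0, index=vs, columns=js)
    for (v, j), w in weights.items():
        mat.at[v, j] = w / total
    return VJUsage(matrix=mat, basis=basis)


def abundance_spectrum(frequencies: Sequence[float], n_log_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of clonotype counts per log10-frequency bin.

    Returns (counts, bin_edges); bin edges are logarithmic between the
    minimum and maximum frequency, and the counts sum to the number of
    clonotypes.
    """
    f = np.asarray(list(frequencies), dtype=float)
    if f.size == 0:
        return np.array([], dtype=int), np.array([])
    if (f <= 0).any() or (f > 1).any():
        raise ValueError("frequencies must lie in (0, 1]")
    if n_log_bins < 1:
        raise ValueError("n_log_bins must be >= 1")
    lo, hi = f.min(), f.max()
    if lo == hi:
        return np.array([f.size]), np.array([lo, hi])
    edges = np.logspace(np.log10(lo), np.log10(hi), n_log_bins + 1)
    edges[0], edges[-1] = lo, hi  # guard against fp drift at the extremes
    counts, edges = np.histogram(f, bins=edges)
    return counts, edges
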