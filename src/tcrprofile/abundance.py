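"""Clonotype abundance: transcript-level fractional read weighting and
clone-level cell counting.

A read annotated with N ambiguous V genes contributes 1/N of a read to each
of the N candidate V-CDR3-J identities, so total weight is conserved at the
read count.  Clonal abundance counts cells instead: a biallelic cell
contributes one cell-count to each of its two alleles but only once to the
cell denominator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
from scipy import stats

from .consensus import ConsensusTable
from .io import ALPHA, BETA, LOCI, CallerTable, CellCallSet, Clonotype


class UndefinedCorrelationError(ValueError):
    """Pearson correlation is undefined (zero variance on one side)."""


@dataclass
class AbundanceVector:
    """Clonotype -> non-negative weight, with the normalising denominator.

    For transcript-level vectors the denominator is the total read weight;
    for clone-level vectors it is the number of detected cells (which can
    be less than the summed weights when biallelic cells contribute one
    count per allele).
    """

    entries: dict[Hashable, float] = field(default_factory=dict)
    denominator: float | None = None
    locus: str | None = None

    def __post_init__(self):
        if any(w < 0 for w in self.entries.values()):
            raise ValueError("weights must be non-negative")

    def total(self) -> float:
        return math.fsum(self.entries.values())

    def frequency(self, key: Hashable) -> float:
        den = self.denominator if self.denominator else self.total()
        return self.entries[key] / den

    def frequencies(self) -> dict[Hashable, float]:
        den = self.denominator if self.denominator else self.total()
        return {k: w / den for k, w in self.entries.items()}

    def percent(self, key: Hashable, ndigits: int = 1) -> float:
        """Abundance as a percentage, reported at 1 decimal place."""
        return round(100.0 * self.frequency(key), ndigits)

    def ranked(self) -> list[tuple[Hashable, float]]:
        """Entries by descending weight; ties broken by identity label."""
        return sorted(self.entries.items(), key=lambda kv: (-kv[1], _sort_label(kv[0])))

    def __len__(self) -> int:
        return len(self.entries)


def _sort_label(key: Hashable) -> str:
    if isinstance(key, Clonotype):
        return key.label
    if isinstance(key, tuple):
        return "|".join(_sort_label(k) if k is not None else "-" for k in key)
    return str(key)


def fractional_counts(table: CallerTable | ConsensusTable,
                      drop_ambiguous: bool = False) -> AbundanceVector:
    """Transcript abundance with 1/N fractional weighting of ambiguous reads.

    Each row's read count is split evenly over its candidate V genes: a read
    with N candidates contributes 1/N of a read to each single-V clonotype.
    With ``drop_ambiguous`` rows with N > 1 are discarded instead (the
    stricter option some callers expose).
    """
    entries: dict[Clonotype, float] = {}
    loci = set()
    for row in table.rows:
        if row.candidate_v_count < 1:
            raise ValueError("candidate_v_count must be >= 1")
        candidates = row.clonotype.split_candidates()
        n = len(candidates)
        if drop_ambiguous and n > 1:
            continue
        loci.add(row.clonotype.locus)
        share = row.read_count / n
        for cand in candidates:
            entries[cand] = entries.get(cand, 0.0) + share
    locus = loci.pop() if len(loci) == 1 else None
    vec = AbundanceVector(entries=entries, locus=locus)
    vec.denominator = vec.total()
    return vec


def to_frequencies(weights: AbundanceVector) -> AbundanceVector:
    """Normalise weights to frequencies summing to 1."""
    total = weights.total()
    if not weights.entries or total <= 0:
        if weights.entries:
            warnings.warn("all-zero weights: returning empty frequency vector")
        return AbundanceVector(entries={}, denominator=None, locus=weights.locus)
    return AbundanceVector(
        entries={k: w / total for k, w in weights.entries.items()},
        denominator=1.0,
        locus=weights.locus,
    )


def clonal_frequencies(cells: Sequence[CellCallSet], level: str = "clone") -> AbundanceVector:
    """Clone-level (cell-count) abundance.

    ``level='clone'`` keys entries by the (alpha, beta) clonotype pairing
    (``None`` for an undetected chain) over cells with at least one chain
    detected; ``level='alpha'``/``'beta'`` keys by the chain clonotype over
    cells with that chain detected.  Biallelic cells contribute one count
    per allele but one cell to the denominator.
    """
    if level not in ("clone", ALPHA, BETA):
        raise ValueError(f"level must be 'clone', '{ALPHA}' or '{BETA}'")
    entries: dict[Hashable, float] = {}
    denom = 0
    for cell in cells:
        if level == "clone":
            if not cell.detected:
                continue
            denom += 1
            alphas: tuple = cell.alpha_calls or (None,)
            betas: tuple = cell.beta_calls or (None,)
            for a in alphas:
                for b in betas:
                    key = (a, b)
                    entries[key] = entries.get(key, 0.0) + 1.0
        else:
            calls = cell.calls(level)
            if not calls:
                continue
            denom += 1
            for c in calls:
                entries[c] = entries.get(c, 0.0) + 1.0
    return AbundanceVector(entries=entries, denominator=float(denom) or None,
                           locus=None if level == "clone" else level)


def cell_detection_stats(cells: Sequence[CellCallSet]) -> dict[str, dict[str, float]]:
    """Per-locus detection census in the shape of a single-cell summary table.

    For each locus: number of cells sequenced, cells with a TCR called (and
    % of sequenced), cells with a single allele / biallelic (and % of
    called).  Percentages are rounded to the nearest integer.
    """
    out: dict[str, dict[str, float]] = {}
    n_total = len(cells)
    for locus in LOCI:
        called = [c for c in cells if c.calls(locus)]
        biallelic = [c for c in called if c.biallelic(locus)]
        n_called, n_bi = len(called), len(biallelic)
        out[locus] = {
            "n_cells": n_total,
            "n_called": n_called,
            "pct_called": round(100.0 * n_called / n_total) if n_total else 0.0,
            "n_single": n_called - n_bi,
            "pct_single": round(100.0 * (n_called - n_bi) / n_called) if n_called else 0.0,
            "n_biallelic": n_bi,
            "pct_biallelic": round(100.0 * n_bi / n_called) if n_called else 0.0,
        }
    return out


def ambiguity_correlation(freq_with: AbundanceVector | Mapping[Hashable, float],
                          freq_without: AbundanceVector | Mapping[Hashable, float]) -> float:
    """Pearson r between two frequency vectors over the union of clonotypes.

    Clonotypes absent from one side enter as 0.  Measures how much the
    1/N-weighted ambiguous reads perturb the abundance profile.
    """
    a = freq_with.entries if isinstance(freq_with, AbundanceVector) else dict(freq_with)
    b = freq_without.entries if isinstance(freq_without, AbundanceVector) else dict(freq_without)
    keys = sorted(set(a) | set(b), key=_sort_label)
    if len(keys) < 2:
        raise ValueError("need at least 2 clonotypes in the union")
    x = np.array([a.get(k, 0.0) for k in keys])
    y = np.array([b.get(k, 0.0) for k in keys])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance on one side; Pearson r undefined")
    r, _ = stats.pearsonr(x, y)
    return float(r)
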