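"""Core identity types and TSV readers/writers.

Clonotype tables travel as a subset of the AIRR Rearrangement TSV dialect
(columns ``locus``, ``v_call``, ``j_call``, ``junction``, ``junction_aa``,
``duplicate_count`` plus the extensions ``cell_id`` and
``candidate_v_count``).  Expression data travel as a TSV trio: a gene x cell
count matrix, a gene-length table and a per-cell QC-metric table.

The unit of clonotype identity throughout the package is the V-CDR3-J
triple: the V gene(s) at the gene level, the CDR3 junction and the J gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genes import GenePairMap, consolidate_gene

logger = logging.getLogger(__name__)

ALPHA = "alpha"
BETA = "beta"
LOCI = (ALPHA, BETA)

_LOCUS_TO_AIRR = {ALPHA: "TRA", BETA: "TRB"}
_AIRR_TO_LOCUS = {"TRA": ALPHA, "TRB": BETA, "alpha": ALPHA, "beta": BETA}

_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "AGC", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT", "*": "TAA",
}

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*")
NT_ALPHABET = frozenset("ACGT")


class FormatError(ValueError):
    """A table file is missing a mandatory column or is malformed."""


def translate_nt(nt: str) -> str:
    """Translate a nucleotide string (length multiple of 3) to amino acids."""
    from Bio.Seq import Seq

    if len(nt) % 3 != 0:
        raise ValueError(f"nucleotide length {len(nt)} is not a multiple of 3")
    return str(Seq(nt).translate())


def reverse_translate(aa: str) -> str:
    """Deterministic back-translation using one codon per amino acid."""
    return "".join(_CODON[a] for a in aa)


@dataclass(frozen=True)
class Clonotype:
    """One V-CDR3-J identity on a single chain locus.

    ``v_genes`` may hold several gene-level candidates when the supporting
    reads were ambiguous; a merged identical-sequence group ("A/B") counts
    as a single candidate.
    """

    locus: str
    v_genes: frozenset[str]
    cdr3_aa: str
    j_gene: str
    cdr3_nt: str | None = None

    def __post_init__(self):
        if self.locus not in LOCI:
            raise ValueError(f"locus must be one of {LOCI}, got {self.locus!r}")
        if not isinstance(self.v_genes, frozenset):
            object.__setattr__(self, "v_genes", frozenset(self.v_genes))
        if not self.v_genes:
            raise ValueError("v_genes must be non-empty")
        for g in self.v_genes | {self.j_gene}:
            if "*" in g:
                raise ValueError(f"gene name {g!r} carries an allele suffix")
        if not self.cdr3_aa:
            raise ValueError("cdr3_aa must be non-empty")
        if self.cdr3_nt is not None:
            if len(self.cdr3_nt) % 3 != 0:
                raise ValueError("cdr3_nt length must be a multiple of 3")
            if translate_nt(self.cdr3_nt) != self.cdr3_aa:
                raise ValueError("cdr3_nt does not translate to cdr3_aa")

    @property
    def chain_key(self) -> tuple[str, str, str]:
        """Matching key ignoring the V candidates: (locus, CDR3, J)."""
        return (self.locus, self.cdr3_aa, self.j_gene)

    @property
    def v_label(self) -> str:
        return ",".join(sorted(self.v_genes))

    @property
    def label(self) -> str:
        """Deterministic V|CDR3|J identity label (used for tie-breaks)."""
        return f"{self.v_label}:{self.cdr3_aa}:{self.j_gene}"

    def with_v(self, v: str | Iterable[str]) -> "Clonotype":
        vs = frozenset([v]) if isinstance(v, str) else frozenset(v)
        return replace(self, v_genes=vs)

    def split_candidates(self) -> list["Clonotype"]:
        """One single-V clonotype per candidate V gene."""
        return [self.with_v(v) for v in sorted(self.v_genes)]


@dataclass(frozen=True)
class CallerRow:
    """One clonotype call: candidate identity, read support and per-read
    candidate-V multiplicity N (>= 1)."""

    clonotype: Clonotype
    read_count: float = 1.0
    candidate_v_count: int = 1
    true_clonotype: Clonotype | None = None  # simulation truth label

    def __post_init__(self):
        if self.candidate_v_count < 1:
            raise ValueError("candidate_v_count must be >= 1")
        if self.read_count < 0:
            raise ValueError("read_count must be non-negative")


@dataclass
class CallerTable:
    """One caller's clonotype calls for one sample and locus."""

    caller_id: str
    sample_id: str
    rows: list[CallerRow] = field(default_factory=list)

    @property
    def loci(self) -> frozenset[str]:
        return frozenset(r.clonotype.locus for r in self.rows)

    def total_reads(self) -> float:
        return float(sum(r.read_count for r in self.rows))

    def unique_clonotypes(self) -> set[Clonotype]:
        return {r.clonotype for r in self.rows}


@dataclass(frozen=True)
class CellCallSet:
    """Per-cell alpha/beta clonotype calls (0-2 per locus).

    Two calls at a locus mean the cell is biallelic there.
    """

    cell_id: str
    alpha_calls: tuple[Clonotype, ...] = ()
    beta_calls: tuple[Clonotype, ...] = ()

    def __post_init__(self):
        for calls, locus in ((self.alpha_calls, ALPHA), (self.beta_calls, BETA)):
            if len(calls) > 2:
                raise ValueError(f"at most 2 {locus} calls per cell")
            if any(c.locus != locus for c in calls):
                raise ValueError(f"{locus}_calls contains a clonotype of the wrong locus")

    def calls(self, locus: str) -> tuple[Clonotype, ...]:
        return self.alpha_calls if locus == ALPHA else self.beta_calls

    def biallelic(self, locus: str) -> bool:
        return len(self.calls(locus)) == 2

    @property
    def detected(self) -> bool:
        return bool(self.alpha_calls or self.beta_calls)


@dataclass
class ExpressionMatrix:
    """Gene x cell counts with gene lengths and per-cell QC metrics.

    ``cell_metrics`` columns: ``total_reads``, ``unique_exon_ratio``,
    ``mito_fraction`` and optionally ``group`` (cell label).
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    cell_metrics: pd.DataFrame
    de_genes: list[str] | None = None  # simulation truth label

    def __post_init__(self):
        if not self.gene_lengths.index.equals(self.counts.index):
            self.gene_lengths = self.gene_lengths.reindex(self.counts.index)
        if self.gene_lengths.isna().any() or (self.gene_lengths <= 0).any():
            raise ValueError("gene lengths must be positive for every gene")
        if not self.cell_metrics.index.equals(self.counts.columns):
            self.cell_metrics = self.cell_metrics.reindex(self.counts.columns)
        if (np.asarray(self.counts) < 0).any():
            raise ValueError("counts must be non-negative")
        for col in ("unique_exon_ratio", "mito_fraction"):
            v = self.cell_metrics[col]
            if ((v < 0) | (v > 1)).any():
                raise ValueError(f"{col} must lie in [0, 1]")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def cells(self) -> pd.Index:
        return self.counts.columns

    @property
    def cell_labels(self) -> pd.Series | None:
        if "group" in self.cell_metrics.columns:
            return self.cell_metrics["group"]
        return None


# ---------------------------------------------------------------------------
# Rearrangement TSV I/O

REQUIRED_COLUMNS = ("locus", "v_call", "j_call", "junction_aa")
_WRITE_COLUMNS = ("cell_id", "locus", "v_call", "j_call", "junction",
                  "junction_aa", "duplicate_count", "candidate_v_count")


def _parse_v_call(v_call: str, pair_map: GenePairMap | None) -> frozenset[str]:
    candidates = {consolidate_gene(c, pair_map) for c in str(v_call).split(",") if c.strip()}
    if not candidates:
        raise ValueError(f"no V candidates in {v_call!r}")
    return frozenset(candidates)


def read_rearrangements(path, caller_id: str | None = None,
                        sample_id: str | None = None,
                        pair_map: GenePairMap | None = None) -> CallerTable:
    """Read an AIRR-dialect rearrangement TSV into a CallerTable.

    ``v_call`` may hold comma-separated candidates; they are consolidated to
    the gene level and ``candidate_v_count`` is the number of distinct
    candidates after consolidation (identical-sequence pair members merge to
    one).  Rows with an empty ``junction_aa`` are rejected and counted.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    n_rejected = 0
    rows: list[CallerRow] = []
    for rec in df.itertuples(index=False):
        junction_aa = getattr(rec, "junction_aa")
        if not junction_aa:
            n_rejected += 1
            continue
        v_genes = _parse_v_call(getattr(rec, "v_call"), pair_map)
        junction = getattr(rec, "junction", "") or None
        clon = Clonotype(
            locus=_AIRR_TO_LOCUS[getattr(rec, "locus")],
            v_genes=v_genes,
            cdr3_aa=junction_aa,
            j_gene=consolidate_gene(getattr(rec, "j_call"), pair_map),
            cdr3_nt=junction,
        )
        count = float(getattr(rec, "duplicate_count", "") or 1)
        n_stored = getattr(rec, "candidate_v_count", "") if "candidate_v_count" in df.columns else ""
        n = int(n_stored) if n_stored else len(v_genes)
        rows.append(CallerRow(clon, read_count=count, candidate_v_count=n))
    if n_rejected:
        logger.info("rejected %d rows with empty junction_aa in %s", n_rejected, path)
    return CallerTable(
        caller_id=caller_id or path.stem,
        sample_id=sample_id or "",
        rows=rows,
    )


def write_rearrangements(table: CallerTable, path, cell_ids: Sequence[str] | None = None):
    """Write a CallerTable as an AIRR-dialect TSV; round-trips exactly."""
    recs = []
    for i, row in enumerate(table.rows):
        c = row.clonotype
        recs.append({
            "cell_id": cell_ids[i] if cell_ids is not None else "",
            "locus": _LOCUS_TO_AIRR[c.locus],
            "v_call": ",".join(sorted(c.v_genes)),
            "j_call": c.j_gene,
            "junction": c.cdr3_nt or "",
            "junction_aa": c.cdr3_aa,
            "duplicate_count": row.read_count,
            "candidate_v_count": row.candidate_v_count,
        })
    df = pd.DataFrame(recs, columns=_WRITE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return path


def cells_to_table(cells: Iterable[CellCallSet]) -> tuple[CallerTable, list[str]]:
    """Flatten per-cell calls into one table row per allele call."""
    rows, ids = [], []
    for cell in cells:
        for locus in LOCI:
            for clon in cell.calls(locus):
                rows.append(CallerRow(clon, read_count=1.0,
                                      candidate_v_count=len(clon.v_genes)))
                ids.append(cell.cell_id)
    return CallerTable(caller_id="single_cell", sample_id="", rows=rows), ids


def write_cell_calls(cells: Sequence[CellCallSet], path):
    """Write per-cell calls as an AIRR-dialect TSV with a cell_id column.

    Cells with no calls are preserved as a row with empty junction fields so
    the cell census round-trips.
    """
    table, ids = cells_to_table(cells)
    write_rearrangements(table, path, cell_ids=ids)
    empties = [c.cell_id for c in cells if not c.detected]
    if empties:
        with open(path, "a") as fh:
            for cid in empties:
                fh.write(f"{cid}\tTRA\t\t\t\t\t\t\n")
    return path


def read_cell_calls(path, pair_map: GenePairMap | None = None) -> list[CellCallSet]:
    """Read a per-cell call TSV (inverse of write_cell_calls)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("cell_id",) + REQUIRED_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r} in {path}")
    cells: dict[str, dict[str, list[Clonotype]]] = {}
    for rec in df.itertuples(index=False):
        cid = rec.cell_id
        slot = cells.setdefault(cid, {ALPHA: [], BETA: []})
        if not rec.junction_aa:
            continue
        clon = Clonotype(
            locus=_AIRR_TO_LOCUS[rec.locus],
            v_genes=_parse_v_call(rec.v_call, pair_map),
            cdr3_aa=rec.junction_aa,
            j_gene=consolidate_gene(rec.j_call, pair_map),
            cdr3_nt=rec.junction or None,
        )
        slot[clon.locus].append(clon)
    return [CellCallSet(cid, tuple(s[ALPHA]), tuple(s[BETA]))
            for cid, s in cells.items()]


# ---------------------------------------------------------------------------
# Expression matrix I/O (TSV trio)

def write_expression(em: ExpressionMatrix, prefix) -> dict[str, Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": prefix.with_name(prefix.name + "_counts.tsv"),
        "genes": prefix.with_name(prefix.name + "_genes.tsv"),
        "cells": prefix.with_name(prefix.name + "_cells.tsv"),
    }
    em.counts.to_csv(paths["counts"], sep="\t", index_label="gene_id")
    em.gene_lengths.rename("length_bp").to_csv(paths["genes"], sep="\t", index_label="gene_id")
    em.cell_metrics.to_csv(paths["cells"], sep="\t", index_label="cell_id")
    return paths


def read_expression(prefix) -> ExpressionMatrix:
    prefix = Path(prefix)
    counts = pd.read_csv(prefix.with_name(prefix.name + "_counts.tsv"),
                         sep="\t", index_col="gene_id")
    counts.columns.name = "cell_id"
    lengths = pd.read_csv(prefix.with_name(prefix.name + "_genes.tsv"),
                          sep="\t", index_col="gene_id")["length_bp"]
    metrics = pd.read_csv(prefix.with_name(prefix.name + "_cells.tsv"),
                          sep="\t", index_col="cell_id")
    return ExpressionMatrix(counts=counts, gene_lengths=lengths, cell_metrics=metrics)
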