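"""Consensus clonotype calling across multiple imperfect callers.

TCR typing programs disagree; to stabilise calls, a clonotype is retained
only when at least ``min_agree`` callers report it.  Candidates match on
identical CDR3 and J; their V-gene sets are then intersected across the
agreeing callers and only a non-empty overlapping subset is kept.  An empty
V intersection means the candidates are different V-CDR3-J identities and
do not form a consensus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

from .genes import consolidate_gene  # noqa: F401  (module surface)
from .io import AA_ALPHABET, NT_ALPHABET, CallerTable, Clonotype, translate_nt


def is_productive(seq: str) -> bool:
    """True iff the CDR3 is in frame and stop-free.

    Accepts either a nucleotide junction (in-frame means length divisible
    by 3; its translation must contain no stop) or an amino-acid junction
    (no ``*``).  A string over {A,C,G,T} only is treated as nucleotides.
    """
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    if set(s) <= NT_ALPHABET:
        if len(s) % 3 != 0:
            return False
        return "*" not in translate_nt(s)
    if not set(s) <= AA_ALPHABET:
        bad = sorted(set(s) - AA_ALPHABET)
        raise ValueError(f"characters outside the amino-acid alphabet: {bad}")
    return "*" not in s


def productive_only(table: CallerTable) -> CallerTable:
    """Drop rows whose CDR3 is out of frame or contains a stop."""
    rows = [r for r in table.rows
            if is_productive(r.clonotype.cdr3_nt or r.clonotype.cdr3_aa)]
    return replace_rows(table, rows)


def replace_rows(table: CallerTable, rows) -> CallerTable:
    return CallerTable(caller_id=table.caller_id, sample_id=table.sample_id,
                       rows=list(rows))


@dataclass(frozen=True)
class ConsensusRow:
    """A consensus clonotype: intersected V set, agreeing callers, mean support."""

    clonotype: Clonotype
    callers: frozenset[str]
    support: float

    @property
    def read_count(self) -> float:
        return self.support

    @property
    def candidate_v_count(self) -> int:
        return len(self.clonotype.v_genes)


@dataclass
class ConsensusTable:
    sample_id: str
    min_agree: int
    rows: list[ConsensusRow] = field(default_factory=list)

    def unique_clonotypes(self) -> set[Clonotype]:
        return {r.clonotype for r in self.rows}

    def total_reads(self) -> float:
        return float(sum(r.support for r in self.rows))


class _CallerView:
    """One caller's calls for one (locus, CDR3, J) junction.

    ``v_union`` is every V candidate the caller reported for the junction
    (drives cross-caller agreement); ``by_vset`` keeps the read-group
    granularity (candidate V set -> summed support) so that per-read 1/N
    ambiguity weighting survives consensus.  Junctions are matched on the
    amino-acid CDR3 (tools differ in emitting nucleotides).
    """

    __slots__ = ("v_union", "by_vset", "support", "cdr3_nt")

    def __init__(self):
        self.v_union: set[str] = set()
        self.by_vset: dict[frozenset[str], float] = {}
        self.support = 0.0
        self.cdr3_nt: str | None = None


def _per_caller_view(table: CallerTable) -> dict[tuple, _CallerView]:
    view: dict[tuple, _CallerView] = {}
    for row in table.rows:
        c = row.clonotype
        v = view.setdefault(c.chain_key, _CallerView())
        v.v_union |= c.v_genes
        v.by_vset[c.v_genes] = v.by_vset.get(c.v_genes, 0.0) + row.read_count
        v.support += row.read_count
        if v.cdr3_nt is None:
            v.cdr3_nt = c.cdr3_nt
    return view


def _best_agreeing_subset(caller_sets: dict[str, frozenset[str]],
                          supports: dict[str, float]) -> tuple[tuple[str, ...], frozenset[str]]:
    """Largest caller subset with a non-empty V intersection.

    Ties broken by total support, then by sorted caller ids, so the result
    is deterministic.
    """
    callers = sorted(caller_sets)
    best: tuple[tuple[str, ...], frozenset[str]] | None = None
    for size in range(len(callers), 0, -1):
        cands = []
        for combo in combinations(callers, size):
            inter = frozenset.intersection(*(caller_sets[c] for c in combo))
            if inter:
                cands.append((combo, inter))
        if cands:
            best = max(cands, key=lambda ci: (sum(supports[c] for c in ci[0]), ci[0]))
            break
    if best is None:  # unreachable: singleton subsets always intersect
        raise AssertionError("no agreeing subset")
    return best


def consensus_call(tables: Sequence[CallerTable], min_agree: int = 2) -> ConsensusTable:
    """Consensus clonotypes supported by >= min_agree callers.

    Candidates match on identical CDR3 + J; V sets are intersected across
    the agreeing callers and only a non-empty overlapping subset is
    retained.  Consensus read support is the arithmetic mean of the
    agreeing callers' supports.
    """
    if len(tables) < min_agree:
        raise ValueError(f"need at least min_agree={min_agree} caller tables, got {len(tables)}")
    if min_agree < 1:
        raise ValueError("min_agree must be >= 1")
    sample_ids = {t.sample_id for t in tables}
    if len(sample_ids) > 1:
        raise ValueError(f"tables span multiple samples: {sorted(sample_ids)}")
    caller_ids = [t.caller_id for t in tables]
    if len(set(caller_ids)) != len(caller_ids):
        raise ValueError("caller_id values must be distinct")

    views = {t.caller_id: _per_caller_view(t) for t in tables}
    all_keys = sorted(set().union(*(v.keys() for v in views.values())))
    rows: list[ConsensusRow] = []
    for key in all_keys:
        caller_sets = {cid: frozenset(v[key].v_union)
                       for cid, v in views.items() if key in v}
        if len(caller_sets) < min_agree:
            continue
        supports = {cid: views[cid][key].support for cid in caller_sets}
        combo, v_inter = _best_agreeing_subset(caller_sets, supports)
        if len(combo) < min_agree:
            continue
        locus, cdr3_aa, j_gene = key
        nts = [views[cid][key].cdr3_nt for cid in combo]
        nt = next((x for x in nts if x is not None), None)
        # Restrict each read-group's candidate set to the cross-caller
        # intersection; candidates no caller subset agreed on (e.g. one
        # caller's spuriously widened V) drop out, while ambiguity shared
        # by every caller is reported as is and stays 1/N-weighted.
        by_vset: dict[frozenset[str], float] = {}
        for cid in combo:
            for vset, sup in views[cid][key].by_vset.items():
                restricted = vset & v_inter
                if not restricted:
                    continue
                by_vset[restricted] = by_vset.get(restricted, 0.0) + sup
        for vset in sorted(by_vset, key=sorted):
            clon = Clonotype(locus=locus, v_genes=vset, cdr3_aa=cdr3_aa,
                             j_gene=j_gene, cdr3_nt=nt)
            rows.append(ConsensusRow(clon, frozenset(combo),
                                     by_vset[vset] / len(combo)))
    return ConsensusTable(sample_id=tables[0].sample_id, min_agree=min_agree, rows=rows)
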