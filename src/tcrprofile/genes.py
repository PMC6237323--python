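"""Mouse TCR V/J gene name pools and gene-level name consolidation.

Clonotype identity is defined at the *gene* level: allele suffixes
(``*01`` etc.) are stripped, and members of a declared identical-sequence
V-gene pair (the mouse TRAV locus carries many N-paralog duplications with
identical coding sequence) are merged into a single group rendered
``"A/B"``.  A read annotated with both members of such a pair is therefore
*not* ambiguous.
"""

from __future__ import annotations

import re
import warnings
from typing import Iterable, Mapping

import yaml

# Seventeen mouse TRAV N-paralog pairs sharing identical sequences.
# Default configuration for the simulator and for gene-level consolidation;
# override with a YAML table (see load_gene_pairs) for other references.
DEFAULT_IDENTICAL_V_PAIRS: tuple[tuple[str, str], ...] = (
    ("TRAV3-3", "TRAV3N-3"),
    ("TRAV5-4", "TRAV5N-4"),
    ("TRAV6-3", "TRAV6N-3"),
    ("TRAV6-5", "TRAV6N-5"),
    ("TRAV6-6", "TRAV6N-6"),
    ("TRAV6-7", "TRAV6N-7"),
    ("TRAV7-2", "TRAV7N-2"),
    ("TRAV7-4", "TRAV7N-4"),
    ("TRAV7-5", "TRAV7N-5"),
    ("TRAV8-1", "TRAV8N-1"),
    ("TRAV8-2", "TRAV8N-2"),
    ("TRAV9-2", "TRAV9N-2"),
    ("TRAV9-3", "TRAV9N-3"),
    ("TRAV9-4", "TRAV9N-4"),
    ("TRAV12-1", "TRAV12N-1"),
    ("TRAV13-4", "TRAV13N-4"),
    ("TRAV14-1", "TRAV14N-1"),
)

# Name pools used by the repertoire simulator.  These mimic the mouse
# IMGT gene-level nomenclature; pair members above are drawn as their
# merged group so simulated identities match consolidated real calls.
TRAV_POOL: tuple[str, ...] = tuple(
    ["TRAV1", "TRAV2", "TRAV3-1", "TRAV4-2", "TRAV4-3", "TRAV4-4-DV10",
     "TRAV5-1", "TRAV6-1", "TRAV6-2", "TRAV6-4", "TRAV7-1", "TRAV7-3",
     "TRAV7-6", "TRAV8-1", "TRAV9-1", "TRAV10", "TRAV11", "TRAV12-2",
     "TRAV12-3", "TRAV13-1", "TRAV13-2", "TRAV13-3", "TRAV14-2", "TRAV14-3",
     "TRAV15-1-DV6-1", "TRAV16", "TRAV17", "TRAV18", "TRAV19", "TRAV21-DV12"]
)

TRBV_POOL: tuple[str, ...] = (
    "TRBV1", "TRBV2", "TRBV3", "TRBV4", "TRBV5", "TRBV12-1", "TRBV12-2",
    "TRBV13-1", "TRBV13-2", "TRBV13-3", "TRBV14", "TRBV15", "TRBV16",
    "TRBV17", "TRBV19", "TRBV20", "TRBV23", "TRBV24", "TRBV26", "TRBV29",
    "TRBV30", "TRBV31",
)

TRAJ_POOL: tuple[str, ...] = tuple(f"TRAJ{i}" for i in range(2, 59) if i not in (8, 14, 19, 20, 25, 29, 36, 41, 46, 51, 55))

TRBJ_POOL: tuple[str, ...] = (
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-7",
)

_GENE_RE = re.compile(r"^TR[AB][VJ]")


class GenePairMap:
    """Maps members of declared identical-sequence V pairs to a merged group id.

    The group id is the sorted members joined with ``/`` (e.g.
    ``TRAV14-1/TRAV14N-1``), matching how such genes are reported as one.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]] = DEFAULT_IDENTICAL_V_PAIRS):
        self._member_to_group: dict[str, str] = {}
        for pair in pairs:
            members = sorted(pair)
            group = "/".join(members)
            for m in members:
                self._member_to_group[m] = group

    def group_of(self, gene: str) -> str:
        return self._member_to_group.get(gene, gene)

    def __contains__(self, gene: str) -> bool:
        return gene in self._member_to_group

    @property
    def groups(self) -> frozenset[str]:
        return frozenset(self._member_to_group.values())


DEFAULT_PAIR_MAP = GenePairMap()


def load_gene_pairs(path) -> GenePairMap:
    """Load identical-sequence pairs from a YAML file.

    Expected layout: ``identical_v_pairs: [[A, B], [C, D], ...]`` or a bare
    top-level list of pairs.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, Mapping):
        pairs = doc.get("identical_v_pairs", [])
    else:
        pairs = doc or []
    return GenePairMap(tuple(p) for p in pairs)


def strip_allele(call: str) -> str:
    """Drop an IMGT allele suffix: ``TRBV13-1*02`` -> ``TRBV13-1``."""
    return call.split("*", 1)[0].strip()


def consolidate_gene(raw_call: str, pair_map: GenePairMap | None = None) -> str:
    """Consolidate a raw V/J call to the gene level.

    Strips the allele suffix and maps members of a declared
    identical-sequence pair to their merged group id.  Calls that do not
    look like TR loci names are passed through verbatim with a warning.
    """
    if not raw_call or not raw_call.strip():
        raise ValueError("empty gene call")
    name = strip_allele(raw_call)
    if not _GENE_RE.match(name):
        warnings.warn(f"unrecognised gene call format: {raw_call!r}; passed through",
                      stacklevel=2)
        return name
    pm = pair_map if pair_map is not None else DEFAULT_PAIR_MAP
    return pm.group_of(name)
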