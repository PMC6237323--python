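import numpy as np
import pytest

from tcrprofile import CallerRow, CallerTable, Clonotype


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def bclon(cdr3="CASSEGNYNSPLYF", v="TRBV13-3", j="TRBJ1-6", nt=None):
    """Beta clonotype shorthand; v may be a name or an iterable of names."""
    vs = frozenset([v]) if isinstance(v, str) else frozenset(v)
    return Clonotype(locus="beta", v_genes=vs, cdr3_aa=cdr3, j_gene=j, cdr3_nt=nt)


def aclon(cdr3="CAVSNTNKVVF", v="TRAV14-2", j="TRAJ34", nt=None):
    vs = frozenset([v]) if isinstance(v, str) else frozenset(v)
    return Clonotype(locus="alpha", v_genes=vs, cdr3_aa=cdr3, j_gene=j, cdr3_nt=nt)


def table(rows, caller_id="caller", sample_id="s1"):
    return CallerTable(caller_id=caller_id, sample_id=sample_id,
                       rows=[r if isinstance(r, CallerRow) else
                             CallerRow(r[0], read_count=r[1],
                                       candidate_v_count=len(r[0].v_genes))
                             for r in rows])
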