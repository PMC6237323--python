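"""Cell-number power analysis for single-cell repertoire profiling.

Under i.i.d. multinomial sampling of cells from clone frequencies, a clone
of frequency f is seen at least once among n cells with probability
1 - (1 - f)^n.  The joint probability of seeing each of the top-k clones is
available both in closed form (inclusion-exclusion) and by Monte-Carlo;
negative association under the multinomial makes the joint probability at
most the smallest per-clone probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np


def p_detect(f: float, n: int) -> float:
    """Probability a clone of frequency f is sampled at least once in n cells."""
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    if n < 0:
        raise ValueError("n must be >= 0")
    return 1.0 - (1.0 - f) ** n


def min_cells(f: float, target_p: float) -> int:
    """Smallest n with p_detect(f, n) >= target_p."""
    if not 0.0 < target_p < 1.0:
        raise ValueError("target_p must lie in (0, 1)")
    if f <= 0.0:
        raise ValueError("f = 0: detection infeasible at any cell number")
    if f >= 1.0:
        return 1
    n = math.ceil(math.log(1.0 - target_p) / math.log(1.0 - f))
    # guard against floating error at the boundary
    while n > 1 and p_detect(f, n - 1) >= target_p:
        n -= 1
    while p_detect(f, n) < target_p:
        n += 1
    return n


def _validate_freqs(frequencies: Sequence[float]) -> np.ndarray:
    f = np.asarray(list(frequencies), dtype=float)
    if (f < 0).any() or (f > 1).any():
        raise ValueError("frequencies must lie in [0, 1]")
    if f.sum() > 1.0 + 1e-9:
        raise ValueError("frequencies must sum to <= 1")
    return f


def _topk_freqs(frequencies: Sequence[float], k: int) -> np.ndarray:
    f = _validate_freqs(frequencies)
    if not 1 <= k <= f.size:
        raise ValueError("k must satisfy 1 <= k <= number of clones")
    return np.sort(f)[::-1][:k]


def p_all_topk(frequencies: Sequence[float], k: int, n: int,
               n_sims: int = 10000, seed: int | None = None) -> tuple[float, float]:
    """Monte-Carlo probability that each of the top-k clones is sampled at
    least once among n multinomially drawn cells.

    Returns (estimate, standard error); deterministic under a fixed seed.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    fk = _topk_freqs(frequencies, k)
    if n == 0:
        return 0.0, 0.0
    rng = np.random.default_rng(seed)
    f = np.sort(np.asarray(list(frequencies), dtype=float))[::-1]
    rest = max(0.0, 1.0 - float(f.sum()))
    probs = np.concatenate([fk, f[k:], [rest]])
    probs = probs / probs.sum()
    counts = rng.multinomial(n, probs, size=n_sims)
    hits = (counts[:, :k] > 0).all(axis=1)
    p_hat = float(hits.mean())
    se = math.sqrt(p_hat * (1.0 - p_hat) / n_sims)
    return p_hat, se


def p_all_topk_exact(frequencies: Sequence[float], k: int, n: int) -> float:
    """Closed-form joint detection probability by inclusion-exclusion.

    P(all top-k seen) = sum over subsets S of the top-k of
    (-1)^|S| (1 - F_S)^n, with F_S the summed frequency of S.  Exact under
    i.i.d. multinomial cell sampling; practical for k <= ~20.
    """
    fk = _topk_freqs(frequencies, k)
    if k > 20:
        raise ValueError("inclusion-exclusion limited to k <= 20")
    total = 0.0
    for size in range(0, k + 1):
        sign = -1.0 if size % 2 else 1.0
        for combo in combinations(range(k), size):
            fs = float(fk[list(combo)].sum())
            total += sign * (1.0 - fs) ** n
    return min(max(total, 0.0), 1.0)


@dataclass
class PowerCurve:
    """Detection power across a grid of cell numbers.

    ``per_clone[i, j]``: probability clone j (rank order) is seen at least
    once among ``n_values[i]`` cells; ``joint_topk[i]``: probability all of
    the top-k are seen.
    """

    n_values: np.ndarray
    k: int
    per_clone: np.ndarray
    joint_topk: np.ndarray
    joint_se: np.ndarray
    method: str

    def min_cells_for_joint(self, target_p: float) -> int | None:
        """Smallest grid n whose joint top-k power reaches target_p."""
        ok = np.nonzero(self.joint_topk >= target_p)[0]
        return int(self.n_values[ok[0]]) if ok.size else None


def power_curve(frequencies: Sequence[float], n_values: Sequence[int], k: int,
                method: str = "analytic", n_sims: int = 10000,
                seed: int | None = None) -> PowerCurve:
    """Per-clone and joint top-k detection power over a grid of cell counts."""
    fk = _topk_freqs(frequencies, k)
    ns = np.asarray(list(n_values), dtype=int)
    per = np.array([[p_detect(float(f), int(n)) for f in fk] for n in ns])
    joint = np.empty(ns.size)
    se = np.zeros(ns.size)
    for i, n in enumerate(ns):
        if method == "analytic":
            joint[i] = p_all_topk_exact(frequencies, k, int(n))
        elif method == "monte_carlo":
            joint[i], se[i] = p_all_topk(frequencies, k, int(n), n_sims=n_sims,
                                         seed=None if seed is None else seed + i)
        else:
            raise ValueError("method must be 'analytic' or 'monte_carlo'")
    return PowerCurve(n_values=ns, k=k, per_clone=per, joint_topk=joint,
                      joint_se=se, method=method)
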