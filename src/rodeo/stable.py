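"""Stable-gene detection via longest increasing subsequences of rank orders.

A gene is *stable* across two samples when it is active (receives reads) in
both and its relative expression rank is preserved. Per resampling iteration
i, genes active in both samples are ordered by decreasing assigned count in
sample a; reading off their ranks under sample b's ordering gives a
permutation whose longest increasing subsequence (LIS) picks out a maximal
set of genes whose relative order agrees between the samples. The final
stable set is the intersection of the per-iteration sets, so a gene must
keep its rank in every iteration to qualify. Stable and DE sets need not
partition the gene universe — both involve confidence thresholds — but they
are disjoint in practice.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import numpy as np

from .io import ValidationError
from .phi import PhiDistribution

__all__ = [
    "StableSet",
    "longest_increasing_subsequence",
    "lis_union",
    "stable_pair",
    "stable_genes",
]


def longest_increasing_subsequence(seq) -> list[int]:
    """Indices of one maximum-length strictly increasing subsequence.

    Patience sorting, O(n log n). Deterministic backtrace: each element
    placed on pile k records the element currently topping pile k-1 as its
    predecessor, and the trace starts from the final pile's current top.
    """
    values = list(seq)
    if len(values) != len(set(values)):
        raise ValidationError("sequence elements must be distinct")
    if not values:
        return []
    tops: list = []          # current top value of each pile
    top_idx: list[int] = []  # index of that value in seq
    pred = [-1] * len(values)
    for i, v in enumerate(values):
        k = bisect_left(tops, v)
        if k == len(tops):
            tops.append(v)
            top_idx.append(i)
        else:
            tops[k] = v
            top_idx[k] = i
        pred[i] = top_idx[k - 1] if k > 0 else -1
    out = []
    i = top_idx[-1]
    while i != -1:
        out.append(i)
        i = pred[i]
    return out[::-1]


def lis_union(seq) -> list[int]:
    """Indices of every element lying on *some* maximum-length increasing
    subsequence (an element qualifies iff the longest run ending at it plus
    the longest run starting at it spans the LIS length)."""
    values = list(seq)
    n = len(values)
    if n == 0:
        return []
    f = _lis_lengths(values)                       # LIS ending at i
    g = _lis_lengths([-v for v in reversed(values)])  # LIS starting at i
    g = g[::-1]
    best = max(fi + gi - 1 for fi, gi in zip(f, g))
    return [i for i in range(n) if f[i] + g[i] - 1 == best]


def _lis_lengths(values: list) -> list[int]:
    tops: list = []
    out = []
    for v in values:
        k = bisect_left(tops, v)
        if k == len(tops):
            tops.append(v)
        else:
            tops[k] = v
        out.append(k + 1)
    return out


def _rank_order(assigned: np.ndarray, active: np.ndarray,
                tie_rank: np.ndarray) -> np.ndarray:
    """Active gene indices ordered by decreasing count (tie: gene id)."""
    idx = np.flatnonzero(active)
    order = np.lexsort((tie_rank[idx], -assigned[idx]))
    return idx[order]


def stable_pair(assigned_a: np.ndarray, assigned_b: np.ndarray,
                gene_ids: list[str],
                tie_rank: np.ndarray | None = None) -> set[str]:
    """Stable genes of one iteration pair.

    Restricts to genes with at least one assigned read in both samples,
    orders them by decreasing count in a (gene-id tie-break), forms the
    sequence of their ranks under b's ordering, and returns the genes on the
    deterministic LIS of that sequence.
    """
    assigned_a = np.asarray(assigned_a)
    assigned_b = np.asarray(assigned_b)
    if assigned_a.shape != assigned_b.shape or assigned_a.size != len(gene_ids):
        raise ValidationError("assigned-count vectors must align with the gene universe")
    if tie_rank is None:
        tie_rank = np.argsort(np.argsort(np.asarray(gene_ids)))
    active = (assigned_a > 0) & (assigned_b > 0)
    if not active.any():
        return set()
    order_a = _rank_order(assigned_a, active, tie_rank)
    order_b = _rank_order(assigned_b, active, tie_rank)
    rank_b = np.empty(len(gene_ids), dtype=np.int64)
    rank_b[order_b] = np.arange(order_b.size)
    seq = rank_b[order_a]
    keep = longest_increasing_subsequence(seq.tolist())
    return {gene_ids[order_a[i]] for i in keep}


@dataclass
class StableSet:
    """Final stable genes plus per-iteration sets for diagnostics."""

    genes: set[str]
    per_iteration: list[set[str]] = field(default_factory=list)
    I: int = 0


def stable_genes(phiA: PhiDistribution, phiB: PhiDistribution) -> StableSet:
    """Intersect the per-iteration stable sets over matched iterations.

    Iteration i of sample a is paired with iteration i of sample b; both
    distributions must retain their raw assigned-count matrices.
    """
    if phiA.gene_ids != phiB.gene_ids:
        raise ValidationError("stable detection requires identical gene sets")
    if phiA.assigned is None or phiB.assigned is None:
        raise ValidationError("stable detection needs retained assigned counts "
                              "(estimate with keep_assigned=True)")
    I = min(phiA.assigned.shape[1], phiB.assigned.shape[1])
    if I < 1:
        raise ValidationError("need at least one iteration on both sides")
    tie_rank = np.argsort(np.argsort(np.asarray(phiA.gene_ids)))
    per_iter: list[set[str]] = []
    final: set[str] | None = None
    for i in range(I):
        s = stable_pair(phiA.assigned[:, i], phiB.assigned[:, i],
                        phiA.gene_ids, tie_rank=tie_rank)
        per_iter.append(s)
        final = s if final is None else (final & s)
        if not final:
            final = set()
    return StableSet(genes=final or set(), per_iteration=per_iter, I=I)
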