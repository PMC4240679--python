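"""Character-function estimation: multinomial read resampling + segmentation.

A character function maps each gene's context-dependent abundance onto one of
``P`` ordered expression bins, subject to two constraints inside every
resampled realisation: a gene with more assigned reads never lands in a lower
bin than one with fewer, and genes with equal assigned reads share a bin.
Because the map is scale-invariant it has no useful closed form; the
distribution of the bin of each gene is estimated by simulation:

1. assign ``R`` reads to genes with probability ``c_g / M`` — one
   multinomial draw, i.e. a parametric bootstrap of the read-sampling
   process itself;
2. order genes by decreasing assigned count; genes with no reads get bin 1;
3. least-squares segment the cumulative sum of the ordered counts into
   ``P - 1`` contiguous pieces, each fitted by its own regression line; the
   piece with the largest counts becomes bin P, the next bin P - 1, and so on.

Repeating for ``I`` iterations yields, per gene, an empirical histogram over
bins — the object every downstream comparison works with.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CountTable, RodeoParams, ValidationError, resolve_R

__all__ = [
    "AssignedCounts",
    "PhiDistribution",
    "assignment_probabilities",
    "resample_reads",
    "least_squares_segmentation",
    "segment_bins",
    "estimate_phi",
    "average_phi",
]

log = logging.getLogger("rodeo.phi")


@dataclass
class AssignedCounts:
    """Result of one resampling iteration: reads per gene, summing to R."""

    assigned: np.ndarray
    probabilities: np.ndarray
    iteration: int | None = None


def assignment_probabilities(counts) -> np.ndarray:
    """Per-gene read-assignment probabilities p_g = c_g / M.

    The observed library is treated as one realisation of a multinomial
    read-sampling process with gene probabilities c_g / M; resampling reads
    under these probabilities bootstraps that process. Zero-count genes get
    probability exactly 0 — they can never receive a resampled read,
    consistent with the bin-1 rule.
    """
    c = np.asarray(counts, dtype=np.float64)
    if c.ndim != 1 or c.size == 0:
        raise ValidationError("counts must be a non-empty 1-D vector")
    if (c < 0).any():
        raise ValidationError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise ValidationError("all counts are zero; assignment probabilities undefined")
    return c / total


def resample_reads(probabilities, R: int, rng: np.random.Generator,
                   iteration: int | None = None) -> AssignedCounts:
    """Draw one multinomial assignment of ``R`` reads to genes."""
    p = np.asarray(probabilities, dtype=np.float64)
    if R < 1:
        raise ValidationError("R must be >= 1")
    if (p < 0).any() or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValidationError("probabilities must be non-negative and sum to 1")
    assigned = rng.multinomial(int(R), p / p.sum())
    return AssignedCounts(assigned=assigned, probabilities=p, iteration=iteration)


# ---------------------------------------------------------------------------
# least-squares linear segmentation


def _segment_cost_matrix(y: np.ndarray) -> np.ndarray:
    """C[i, j] = SSE of the best line through points i..j (inclusive).

    Computed for all pairs via prefix sums in O(n^2). The sequence is first
    detrended by its global least-squares line — the per-segment SSE is
    invariant under subtracting any global linear function of position, and
    working on residuals avoids catastrophic cancellation when the cumulative
    sums are large.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    x = np.arange(n, dtype=np.float64) - (n - 1) / 2.0
    if n > 1:
        slope = (x @ y) / (x @ x)
    else:
        slope = 0.0
    z = y - y.mean() - slope * x

    def pref(v):
        out = np.empty(n + 1)
        out[0] = 0.0
        np.cumsum(v, out=out[1:])
        return out

    Px, Pxx = pref(x), pref(x * x)
    Pz, Pzz, Pxz = pref(z), pref(z * z), pref(x * z)

    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    m = (j - i + 1).astype(np.float64)
    Sx = Px[j + 1] - Px[i]
    Sxx = Pxx[j + 1] - Pxx[i]
    Sz = Pz[j + 1] - Pz[i]
    Szz = Pzz[j + 1] - Pzz[i]
    Sxz = Pxz[j + 1] - Pxz[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        vx = Sxx - Sx * Sx / m
        vz = Szz - Sz * Sz / m
        cxz = Sxz - Sx * Sz / m
        cost = vz - cxz * cxz / vx
    np.maximum(cost, 0.0, out=cost)
    cost[m.astype(int) <= 2] = 0.0  # <=2 points: a line fits exactly
    cost[j < i] = np.inf
    return cost


def _dp_levels(C: np.ndarray, k: int) -> np.ndarray:
    """E[p-1, j] = min cost of segmenting points 0..j into p segments, p=1..k."""
    n = C.shape[0]
    E = np.full((k, n), np.inf)
    E[0] = C[0]
    for p in range(1, k):
        # last segment starts at i in 1..n-1; predecessor cost E[p-1][i-1]
        V = E[p - 1, :-1][:, None] + C[1:, :]
        E[p] = V.min(axis=0)
    return E


def least_squares_segmentation(y, k: int, tol: float = 1e-9):
    """Optimal split of ``y`` into ``k`` contiguous segments, each fitted by
    its own least-squares line, minimising total squared residual.

    Returns ``(breakpoints, total_error)`` where breakpoints are the end
    indices (inclusive) of the first ``k - 1`` segments. Among equal-error
    segmentations (within relative tolerance ``tol``) the lexicographically
    smallest breakpoint vector is returned.
    """
    y = np.asarray(y, dtype=np.float64)
    n = y.size
    if k < 1:
        raise ValidationError("need at least one segment")
    if n < k:
        raise ValidationError(f"cannot split {n} points into {k} non-empty segments")
    C = _segment_cost_matrix(y)
    if k == 1:
        return [], float(C[0, -1])
    # suffix table from the DP on the reversed sequence (line-fit SSE is
    # invariant under reversing a segment)
    Crev = C[::-1, ::-1].T
    Erev = _dp_levels(Crev, k)
    best = float(Erev[k - 1, n - 1])
    eps = tol * max(1.0, best)
    breaks: list[int] = []
    prev, cum = -1, 0.0
    for t in range(1, k):
        rem = k - t
        bs = np.arange(prev + 1, n - rem)
        suffix = Erev[rem - 1, n - 2 - bs]  # cost of points b+1..n-1 in rem segments
        vals = cum + C[prev + 1, bs] + suffix
        ok = np.flatnonzero(vals <= best + eps)
        b = int(bs[ok[0]]) if ok.size else int(bs[np.argmin(vals)])
        breaks.append(b)
        cum += C[prev + 1, b]
        prev = b
    return breaks, best


def segment_bins(assigned, P: int, *, subsample_step: int = 10,
                 subsample_threshold: int = 2000,
                 tie_rank: np.ndarray | None = None) -> np.ndarray:
    """Assign each gene a bin in 1..P from one iteration's read counts.

    Genes with zero assigned reads get bin 1. The remaining genes are ordered
    by decreasing count (ties broken by ``tie_rank``, default input position,
    for determinism); their cumulative-count curve is segmented into ``P - 1``
    least-squares pieces, the top piece mapping to bin P. Runs of genes with
    identical counts that straddle a segment boundary are reassigned the bin
    held by the majority of the run (higher bin on a tie), so equal counts
    always imply equal bins.

    When the number of expressed genes exceeds ``subsample_threshold`` the DP
    sees only every ``subsample_step``-th gene and the breakpoints are mapped
    back to all genes through the count value at each breakpoint.
    """
    a = assigned.assigned if isinstance(assigned, AssignedCounts) else np.asarray(assigned)
    if P < 2:
        raise ValidationError("P must be >= 2")
    n = a.size
    bins = np.ones(n, dtype=np.int64)
    nz = np.flatnonzero(a > 0)
    if nz.size == 0:
        return bins
    key = tie_rank[nz] if tie_rank is not None else nz
    order = np.lexsort((key, -a[nz]))
    s = nz[order]                      # gene indices, decreasing assigned count
    vals = a[s].astype(np.float64)
    m = s.size
    k = P - 1
    if m < k:
        warnings.warn(
            f"only {m} expressed genes for {k} segments; collapsing to one "
            "gene per segment from the top", RuntimeWarning, stacklevel=2)
        seg = np.arange(1, m + 1)
    else:
        y = np.cumsum(vals)
        if m > subsample_threshold:
            sub = np.arange(0, m, subsample_step)
            if sub[-1] != m - 1:
                sub = np.append(sub, m - 1)
            bks, _ = least_squares_segmentation(y[sub], k)
            cuts = vals[sub[np.asarray(bks, dtype=int)]]
            # gene with value v falls in segment 1 + #(cut values > v)
            seg = 1 + np.searchsorted(-cuts, -vals, side="left")
        else:
            bks, _ = least_squares_segmentation(y, k)
            seg = np.searchsorted(bks, np.arange(m), side="left") + 1
    b_sorted = (P - seg + 1).astype(np.int64)

    # equalise runs of equal counts straddling a boundary
    boundary = np.flatnonzero(np.diff(b_sorted) != 0)
    if boundary.size:
        run_start = np.r_[0, np.flatnonzero(np.diff(vals) != 0) + 1]
        for pos in boundary:
            ri = np.searchsorted(run_start, pos, side="right") - 1
            st = run_start[ri]
            en = run_start[ri + 1] if ri + 1 < run_start.size else m
            if vals[pos] == vals[pos + 1]:  # boundary inside a run
                run = b_sorted[st:en]
                u, cnt = np.unique(run, return_counts=True)
                b_sorted[st:en] = u[cnt == cnt.max()].max()
    bins[s] = b_sorted
    return bins


# ---------------------------------------------------------------------------
# the per-sample distribution of bins


@dataclass
class PhiDistribution:
    """Empirical distribution of each gene's expression bin.

    ``bin_matrix`` holds the raw per-iteration bins (L x I, values 1..P);
    ``histogram`` the per-gene empirical frequencies (L x P, rows sum to 1).
    ``assigned`` optionally retains the raw per-iteration read assignments,
    needed by the dispersion and stable-gene steps. ``averaged`` marks a
    K-replicate mean histogram.
    """

    gene_ids: list[str]
    P: int
    bin_matrix: np.ndarray
    histogram: np.ndarray
    assigned: np.ndarray | None = None
    averaged: bool = False
    sample: str | None = None

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def I(self) -> int:
        return self.bin_matrix.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"bin{p}" for p in range(1, self.P + 1)]
        return pd.DataFrame(self.histogram, index=pd.Index(self.gene_ids, name="gene"),
                            columns=cols)

    def write(self, hist_path, bins_path=None) -> None:
        """Serialise the histogram (and optionally the raw bin matrix) as TSV."""
        self.to_frame().to_csv(hist_path, sep="\t", float_format="%.6g")
        if bins_path is not None:
            pd.DataFrame(self.bin_matrix,
                         index=pd.Index(self.gene_ids, name="gene")).to_csv(
                bins_path, sep="\t")


def _histogram_from_bins(bin_matrix: np.ndarray, P: int) -> np.ndarray:
    L, I = bin_matrix.shape
    idx = (bin_matrix.astype(np.int64) - 1) + P * np.arange(L)[:, None]
    hist = np.bincount(idx.ravel(), minlength=L * P).reshape(L, P)
    return hist / float(I)


def _lexicographic_rank(ids: list[str]) -> np.ndarray:
    return np.argsort(np.argsort(np.asarray(ids)))


def estimate_phi(table: CountTable, sample: str, params: RodeoParams,
                 *, keep_assigned: bool = True) -> PhiDistribution:
    """Estimate the bin distribution of every gene in one sample.

    Runs ``params.I`` independent resampling + segmentation iterations. Each
    iteration's random stream is derived from ``(seed, sample index,
    iteration)``, so results are reproducible and independent of the order in
    which samples or iterations are computed.
    """
    si = table.sample_index(sample)
    counts = table.counts[:, si]
    R = resolve_R(table, params, sample)
    probs = assignment_probabilities(counts)
    tie_rank = _lexicographic_rank(table.gene_ids)
    L = table.n_genes
    bin_matrix = np.empty((L, params.I), dtype=np.int16)
    assigned_m = np.empty((L, params.I), dtype=np.int64) if keep_assigned else None
    for i in range(params.I):
        rng = np.random.default_rng(np.random.SeedSequence((params.seed, si, i)))
        ac = resample_reads(probs, R, rng, iteration=i)
        if assigned_m is not None:
            assigned_m[:, i] = ac.assigned
        bin_matrix[:, i] = segment_bins(
            ac, params.P, subsample_step=params.subsample_step,
            subsample_threshold=params.subsample_threshold, tie_rank=tie_rank)
    hist = _histogram_from_bins(bin_matrix, params.P)
    log.debug("phi estimated for sample %s: %d genes, I=%d, R=%d", sample, L, params.I, R)
    return PhiDistribution(list(table.gene_ids), params.P, bin_matrix, hist,
                           assigned=assigned_m, sample=sample)


def average_phi(phis: list[PhiDistribution]) -> PhiDistribution:
    """Average K replicate distributions (histogram mean; bin matrices and
    assigned counts concatenated for downstream dispersion / stable use)."""
    if not phis:
        raise ValidationError("need at least one distribution to average")
    first = phis[0]
    if len(phis) == 1:
        return first
    for other in phis[1:]:
        if other.gene_ids != first.gene_ids:
            raise ValidationError("replicate distributions cover different gene sets")
        if other.P != first.P or other.I != first.I:
            raise ValidationError("replicate distributions differ in P or I")
    hist = np.mean([p.histogram for p in phis], axis=0)
    bin_matrix = np.hstack([p.bin_matrix for p in phis])
    assigned = (np.hstack([p.assigned for p in phis])
                if all(p.assigned is not None for p in phis) else None)
    return PhiDistribution(list(first.gene_ids), first.P, bin_matrix, hist,
                           assigned=assigned, averaged=True, sample=first.sample)
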