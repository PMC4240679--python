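"""Cultivar phylogenies from allele matrices.

Loci are filtered on read coverage and on showing at least one divergence
from the reference; pairwise sample distances are normalised Hamming
distances over the loci where both samples have calls; the dendrogram is
built by average-linkage agglomerative clustering (UPGMA), which yields a
rooted ultrametric tree. Subsetting the loci to transcript classes (DE /
stable / all) lets the same machinery compare the phylogenies of different
functional parts of the transcriptome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import FLOAT_FMT, ValidationError

__all__ = [
    "AlleleMatrix",
    "TreeNode",
    "UPGMATree",
    "read_allele_matrix",
    "write_allele_matrix",
    "filter_loci",
    "subset_loci",
    "hamming_matrix",
    "upgma",
    "to_newick",
]

log = logging.getLogger("rodeo.phylo")

MISSING = {"", "-", ".", "N", "n", None}


@dataclass
class AlleleMatrix:
    """Loci x samples allele calls with per-cell read coverage.

    A locus id is ``<transcript>:<0-based position>``. Calls are single
    symbols; ``N`` (or empty) means missing — ambiguous consensus calls must
    be encoded as IUPAC symbols or N upstream.
    """

    locus_ids: list[str]
    reference: list[str]
    sample_ids: list[str]
    calls: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        L, S = len(self.locus_ids), len(self.sample_ids)
        if len(set(self.locus_ids)) != L:
            raise ValidationError("duplicate locus ids")
        if np.asarray(self.calls).shape != (L, S):
            raise ValidationError("calls shape does not match loci x samples")
        if np.asarray(self.coverage).shape != (L, S):
            raise ValidationError("coverage shape does not match loci x samples")
        if (np.asarray(self.coverage) < 0).any():
            raise ValidationError("coverage must be non-negative")
        self.coverage = np.asarray(self.coverage, dtype=np.int64)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def present(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return ~np.isin(self.calls.astype(str), sorted(str(m) for m in MISSING if m))  # noqa: E501

    def transcripts(self) -> np.ndarray:
        return np.array([lid.rsplit(":", 1)[0] for lid in self.locus_ids])


def _present_mask(calls: np.ndarray) -> np.ndarray:
    flat = np.array([c is not None and str(c) not in {"", "-", ".", "N", "n"}
                     for c in calls.ravel()])
    return flat.reshape(calls.shape)


def read_allele_matrix(path: str | Path) -> AlleleMatrix:
    """Read the TSV layout written by :func:`write_allele_matrix`."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "locus" or df.columns[1] != "reference":
        raise ValidationError("allele matrix must start with locus, reference columns")
    samples = sorted({c[:-7] for c in df.columns if c.endswith(".allele")})
    calls = np.column_stack([df[f"{s}.allele"].to_numpy(dtype=object) for s in samples])
    coverage = np.column_stack([df[f"{s}.coverage"].astype(int).to_numpy() for s in samples])
    return AlleleMatrix(df["locus"].tolist(), df["reference"].tolist(),
                        samples, calls, coverage)


def write_allele_matrix(matrix: AlleleMatrix, path: str | Path) -> None:
    data: dict[str, object] = {"locus": matrix.locus_ids, "reference": matrix.reference}
    for j, s in enumerate(matrix.sample_ids):
        data[f"{s}.allele"] = matrix.calls[:, j]
        data[f"{s}.coverage"] = matrix.coverage[:, j]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def filter_loci(matrix: AlleleMatrix, min_coverage: int = 100,
                require_all: bool = True) -> AlleleMatrix:
    """Keep variant loci with sufficient coverage.

    A locus survives when (a) every non-missing sample reaches
    ``min_coverage`` reads (or any one sample, with ``require_all=False``)
    and (b) at least one sample's call differs from the reference.
    """
    present = _present_mask(matrix.calls)
    cov_ok_cells = matrix.coverage >= min_coverage
    if require_all:
        cov_ok = np.where(present, cov_ok_cells, True).all(axis=1) & present.any(axis=1)
    else:
        cov_ok = (present & cov_ok_cells).any(axis=1)
    ref = np.asarray(matrix.reference, dtype=object)[:, None]
    variant = (present & (matrix.calls != ref)).any(axis=1)
    keep = np.flatnonzero(cov_ok & variant)
    if keep.size == 0:
        log.warning("all %d loci removed by filtering", matrix.n_loci)
    return AlleleMatrix(
        [matrix.locus_ids[i] for i in keep],
        [matrix.reference[i] for i in keep],
        list(matrix.sample_ids),
        matrix.calls[keep],
        matrix.coverage[keep],
    )


def subset_loci(matrix: AlleleMatrix, transcript_ids: set[str]) -> AlleleMatrix:
    """Restrict to loci whose transcript id is in the given set."""
    tx = matrix.transcripts()
    keep = np.flatnonzero(np.isin(tx, sorted(transcript_ids)))
    return AlleleMatrix(
        [matrix.locus_ids[i] for i in keep],
        [matrix.reference[i] for i in keep],
        list(matrix.sample_ids),
        matrix.calls[keep],
        matrix.coverage[keep],
    )


def hamming_matrix(matrix: AlleleMatrix) -> pd.DataFrame:
    """Pairwise-complete normalised Hamming distances between samples.

    d(s, t) = (# loci where both calls are present and differ) / (# loci
    where both are present). A pair with no co-called loci has no defined
    distance and raises, naming the pair.
    """
    S = len(matrix.sample_ids)
    if S < 2 or matrix.n_loci < 1:
        raise ValidationError("need at least 2 samples and 1 locus")
    present = _present_mask(matrix.calls)
    D = np.zeros((S, S))
    for i in range(S):
        for j in range(i + 1, S):
            both = present[:, i] & present[:, j]
            n = int(both.sum())
            if n == 0:
                raise ValidationError(
                    f"samples {matrix.sample_ids[i]!r} and "
                    f"{matrix.sample_ids[j]!r} share no called loci")
            diff = int((matrix.calls[both, i] != matrix.calls[both, j]).sum())
            D[i, j] = D[j, i] = diff / n
    return pd.DataFrame(D, index=matrix.sample_ids, columns=matrix.sample_ids)


# ---------------------------------------------------------------------------
# UPGMA


@dataclass
class TreeNode:
    name: str | None
    height: float
    children: tuple["TreeNode", ...] = ()

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        return [n for c in self.children for n in c.leaf_names()]


@dataclass
class UPGMATree:
    root: TreeNode
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = field(default_factory=list)

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = []

        def walk(node: TreeNode, up: float) -> None:
            if node.is_leaf:
                depths.append(up + node.height)
            for c in node.children:
                walk(c, up)

        walk(self.root, 0.0)
        return max(depths) - min(depths) <= tol


def upgma(dist, labels: list[str] | None = None) -> UPGMATree:
    """Average-linkage agglomerative clustering of a distance matrix.

    Repeatedly merges the closest pair of clusters at height d/2; the
    distance between clusters is the arithmetic mean over member pairs.
    Ties merge the lexicographically smallest pair (clusters compared by
    their sorted leaf-name tuples), making the tree deterministic.
    """
    if isinstance(dist, pd.DataFrame):
        labels = list(dist.index)
        D = dist.to_numpy(dtype=float)
    else:
        D = np.asarray(dist, dtype=float)
        if labels is None:
            labels = [f"s{i+1}" for i in range(D.shape[0])]
    n = D.shape[0]
    if n < 2:
        raise ValidationError("UPGMA needs at least 2 samples")
    if D.shape != (n, n) or not np.allclose(D, D.T) or (np.diag(D) != 0).any():
        raise ValidationError("distance matrix must be symmetric with zero diagonal")
    if (D < 0).any():
        raise ValidationError("distances must be non-negative")

    clusters: dict[tuple[str, ...], tuple[TreeNode, int]] = {
        (lab,): (TreeNode(name=lab, height=0.0), 1) for lab in labels
    }
    dists: dict[frozenset, float] = {}
    keys = sorted(clusters)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            dists[frozenset((a, b))] = D[labels.index(a[0]), labels.index(b[0])]
    merges: list[tuple[tuple[str, ...], tuple[str, ...], float]] = []

    while len(clusters) > 1:
        best = min(
            ((d, tuple(sorted(pair))) for pair, d in dists.items()),
            key=lambda t: (t[0], t[1]),
        )
        d, (a, b) = best
        node_a, size_a = clusters.pop(a)
        node_b, size_b = clusters.pop(b)
        height = d / 2.0
        merged_key = tuple(sorted(a + b))
        first, second = (node_a, node_b) if a <= b else (node_b, node_a)
        new_node = TreeNode(name=None, height=height, children=(first, second))
        merges.append((a, b, height))
        for other in list(clusters):
            da = dists.pop(frozenset((a, other)))
            db = dists.pop(frozenset((b, other)))
            dists[frozenset((merged_key, other))] = (
                (size_a * da + size_b * db) / (size_a + size_b))
        dists.pop(frozenset((a, b)))
        clusters[merged_key] = (new_node, size_a + size_b)

    (root, _), = clusters.values()
    return UPGMATree(root=root, merges=merges)


def to_newick(tree: UPGMATree | TreeNode) -> str:
    """Newick string with branch lengths = parent height - child height."""
    root = tree.root if isinstance(tree, UPGMATree) else tree

    def fmt(node: TreeNode, parent_height: float | None) -> str:
        if node.is_leaf:
            body = node.name
        else:
            body = "(" + ",".join(fmt(c, node.height) for c in node.children) + ")"
        if parent_height is None:
            return body
        return f"{body}:{FLOAT_FMT % (parent_height - node.height)}"

    return fmt(root, None) + ";"
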