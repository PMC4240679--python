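"""Synthetic fixtures: count tables with planted DE and allele matrices with
a known generating tree.

The count generator deliberately draws baseline abundances from a log-normal
rather than the negative binomial assumed by parametric DE callers, so
benchmarks against those callers (or against this tool) are not biased
toward any method's own generative model. Planted fold changes alternate
up/down, keeping the global DE signal unbiased as the framework assumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io import CountTable, ExperimentDesign, ValidationError
from .phylo import AlleleMatrix

__all__ = [
    "SyntheticTruth",
    "generate_two_condition_counts",
    "two_condition_design",
    "generate_allele_matrix",
]

BASES = np.array(["A", "C", "G", "T"])


@dataclass
class SyntheticTruth:
    """Ground truth of a generated count table.

    ``frame`` holds per-gene baseline mean, planted fold change (1 = null;
    the stored value is the multiplicative change applied in condition b, so
    down-regulated genes carry 1/fold), log2 fold change and the DE flag.
    """

    frame: pd.DataFrame
    library_size: int
    seed: int

    @property
    def de_genes(self) -> set[str]:
        return set(self.frame.loc[self.frame.is_de, "gene"])

    @property
    def null_genes(self) -> set[str]:
        return set(self.frame.loc[~self.frame.is_de, "gene"])

    def write(self, path: str | Path) -> None:
        df = self.frame.copy()
        for col in ("baseline", "fold", "log2fc"):
            df[col] = df[col].map(lambda v: "%.6g" % v)
        df.to_csv(path, sep="\t", index=False)


def generate_two_condition_counts(
    n_genes: int,
    n_de: int,
    fold: float,
    library_size: int,
    k_replicates: int = 1,
    seed: int = 0,
    meanlog: float = 1.5,
    sdlog: float = 1.5,
) -> tuple[CountTable, SyntheticTruth]:
    """Generate a two-condition count table with planted fold changes.

    Baseline means are log-normal(meanlog, sdlog); the first ``n_de`` genes
    are planted DE, alternating up (x fold) and down (x 1/fold) in condition
    b. Per-sample counts are one multinomial draw of ``library_size`` reads
    with probabilities proportional to the condition means, so library size
    is exact and genes compete for reads as in a sequencing run.
    Samples are named ``a_1..a_K`` and ``b_1..b_K``.
    """
    if n_de > n_genes:
        raise ValidationError("n_de cannot exceed n_genes")
    if fold <= 0:
        raise ValidationError("fold must be positive")
    if n_genes < 2 or library_size < 1 or k_replicates < 1:
        raise ValidationError("invalid problem size")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0)))
    genes = [f"g{i+1:05d}" for i in range(n_genes)]
    baseline = rng.lognormal(mean=meanlog, sigma=sdlog, size=n_genes)
    fold_per_gene = np.ones(n_genes)
    for j in range(n_de):
        fold_per_gene[j] = fold if j % 2 == 0 else 1.0 / fold
    mean_a = baseline
    mean_b = baseline * fold_per_gene
    cols: dict[str, np.ndarray] = {}
    for cond, means in (("a", mean_a), ("b", mean_b)):
        p = means / means.sum()
        for k in range(1, k_replicates + 1):
            cols[f"{cond}_{k}"] = rng.multinomial(library_size, p)
    table = CountTable(genes, list(cols), np.column_stack(list(cols.values())))
    frame = pd.DataFrame({
        "gene": genes,
        "baseline": baseline,
        "fold": fold_per_gene,
        "log2fc": np.log2(fold_per_gene),
        "is_de": fold_per_gene != 1.0,
    })
    return table, SyntheticTruth(frame=frame, library_size=library_size, seed=seed)


def two_condition_design(k_replicates: int = 1) -> ExperimentDesign:
    """Design matching :func:`generate_two_condition_counts` sample naming."""
    assignments = {}
    for cond in ("a", "b"):
        for k in range(1, k_replicates + 1):
            assignments[f"{cond}_{k}"] = (cond, k)
    return ExperimentDesign(assignments, comparisons=[("a", "b")])


def generate_allele_matrix(
    tree: "dendropy.Tree | str",
    n_loci: int,
    mutation_rate: float,
    coverage_range: tuple[int, int] = (100, 200),
    seed: int = 0,
) -> tuple[AlleleMatrix, dendropy.Tree]:
    """Evolve allele calls for the leaves of an ultrametric tree.

    The root carries a random reference base per locus. On each branch the
    number of substitution events per locus is Poisson(rate x length); a
    locus hit at least once switches to a uniformly chosen different base
    (multiple hits on one branch collapse to a single switch — adequate at
    the low per-branch rates this generator targets). Per-locus, per-sample
    coverage is uniform over ``coverage_range``. Loci are named
    ``t<k>:<pos>``, grouping ten positions per synthetic transcript.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(leaves) < 3:
        raise ValidationError("need at least 3 leaves")
    lengths = [e.length or 0.0 for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node]
    if not any(l > 0 for l in lengths):
        raise ValidationError("tree has no positive branch lengths")
    if mutation_rate < 0 or n_loci < 1:
        raise ValidationError("invalid mutation rate or locus count")
    lo, hi = coverage_range
    if lo < 0 or hi < lo:
        raise ValidationError("invalid coverage range")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 1)))
    reference = rng.integers(0, 4, size=n_loci)
    seqs: dict[int, np.ndarray] = {id(tree.seed_node): reference.copy()}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_seq = seqs[id(node.parent_node)]
        seq = parent_seq.copy()
        length = node.edge.length or 0.0
        hits = rng.poisson(mutation_rate * length, size=n_loci) > 0
        idx = np.flatnonzero(hits)
        if idx.size:
            seq[idx] = (seq[idx] + rng.integers(1, 4, size=idx.size)) % 4
        seqs[id(node)] = seq
    samples = sorted(leaves)
    calls = np.empty((n_loci, len(samples)), dtype=object)
    by_label = {lf.taxon.label: seqs[id(lf)] for lf in tree.leaf_node_iter()}
    for j, s in enumerate(samples):
        calls[:, j] = BASES[by_label[s]]
    coverage = rng.integers(lo, hi + 1, size=(n_loci, len(samples)))
    locus_ids = [f"t{i // 10 + 1:04d}:{i % 10}" for i in range(n_loci)]
    matrix = AlleleMatrix(
        locus_ids=locus_ids,
        reference=[str(b) for b in BASES[reference]],
        sample_ids=samples,
        calls=calls,
        coverage=coverage,
    )
    return matrix, tree
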