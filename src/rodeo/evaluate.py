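"""Benchmark harness for ranked DE gene lists against fold-change truth.

Any method that emits a ranked gene list (most DE first) can be scored
against qRT-PCR-style measured log fold changes: genes with |logFC| above a
DE cutoff are true positives, those below a (smaller) non-DE cutoff are true
negatives, and the band in between stays unassigned and is excluded from
every metric. The panels mirror the standard comparison layout: false
discoveries among the top-x calls, ROC with AUC, recovery of the truth's own
top-x genes, and AUC as the DE cutoff is swept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = [
    "TruthLabels",
    "label_truth",
    "false_positive_curve",
    "roc_auc",
    "auc_threshold_sweep",
    "top_x_recovery",
]


@dataclass
class TruthLabels:
    """Per-gene measured log fold change and derived DE / nonDE / unassigned label."""

    frame: pd.DataFrame  # columns: gene, logfc, label
    de_cutoff: float
    nonde_cutoff: float

    @property
    def de_genes(self) -> set[str]:
        return set(self.frame.loc[self.frame.label == "DE", "gene"])

    @property
    def nonde_genes(self) -> set[str]:
        return set(self.frame.loc[self.frame.label == "nonDE", "gene"])

    def label_of(self) -> dict[str, str]:
        return dict(zip(self.frame.gene, self.frame.label))

    def logfc_of(self) -> dict[str, float]:
        return dict(zip(self.frame.gene, self.frame.logfc))


def label_truth(logfc: Mapping[str, float] | pd.Series,
                de_cutoff: float = 1.5,
                nonde_cutoff: float = 1.0) -> TruthLabels:
    """Label genes DE (|logFC| > de_cutoff), nonDE (|logFC| < nonde_cutoff)
    or unassigned (in between; excluded from evaluation)."""
    if de_cutoff < nonde_cutoff:
        raise ValidationError("de_cutoff must be >= nonde_cutoff")
    if isinstance(logfc, pd.Series):
        items = list(logfc.items())
    else:
        items = list(logfc.items())
    rows = []
    for gene, v in items:
        a = abs(float(v))
        label = "DE" if a > de_cutoff else ("nonDE" if a < nonde_cutoff else "unassigned")
        rows.append({"gene": str(gene), "logfc": float(v), "label": label})
    return TruthLabels(pd.DataFrame(rows), de_cutoff, nonde_cutoff)


def _labeled_ranking(ranked_genes: Sequence[str], labels: TruthLabels) -> list[str]:
    """Ranked genes restricted to labeled (DE or nonDE) ones, order kept."""
    lab = labels.label_of()
    return [g for g in ranked_genes if lab.get(g) in ("DE", "nonDE")]


def false_positive_curve(ranked_genes: Sequence[str], labels: TruthLabels,
                         x_max: int) -> np.ndarray:
    """FP(x) = nonDE genes among the top x labeled genes, x = 1..x_max.

    Unassigned genes are skipped without consuming rank positions.
    """
    lab = labels.label_of()
    kept = _labeled_ranking(ranked_genes, labels)
    flags = np.array([lab[g] == "nonDE" for g in kept], dtype=int)
    cum = np.cumsum(flags)
    xs = np.arange(1, x_max + 1)
    return cum[np.minimum(xs, len(kept)) - 1] if len(kept) else np.zeros(x_max, int)


def roc_auc(ranked_genes: Sequence[str], labels: TruthLabels):
    """ROC points and AUC of the ranking against the labels.

    AUC is the Mann–Whitney probability that a randomly chosen DE gene
    outranks a randomly chosen nonDE gene (rank ties would contribute 1/2,
    but positions in a ranked list are unique).
    """
    kept = _labeled_ranking(ranked_genes, labels)
    lab = labels.label_of()
    y = np.array([lab[g] == "DE" for g in kept], dtype=bool)
    n_de, n_non = int(y.sum()), int((~y).sum())
    if n_de == 0 or n_non == 0:
        raise ValidationError("ROC needs at least one DE and one nonDE gene")
    # ranks: position 0 is the best; count concordant (DE before nonDE) pairs
    non_seen = np.cumsum(~y)
    discordant = int(non_seen[y].sum())  # nonDE genes ranked above each DE gene
    auc = 1.0 - discordant / (n_de * n_non)
    tpr = np.concatenate([[0.0], np.cumsum(y) / n_de])
    fpr = np.concatenate([[0.0], np.cumsum(~y) / n_non])
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return points, float(auc)


def auc_threshold_sweep(ranked_genes: Sequence[str],
                        logfc: Mapping[str, float],
                        thresholds: Sequence[float],
                        nonde_ratio: float | None = None) -> pd.DataFrame:
    """AUC at a sweep of DE-calling cutoffs.

    At each threshold t the truth is relabeled with de_cutoff = t and
    nonde_cutoff = t * nonde_ratio (default keeps the 1.0/1.5 proportion of
    the base labeling). Thresholds where either class is empty are reported
    as missing.
    """
    ts = list(thresholds)
    if sorted(ts) != ts:
        raise ValidationError("thresholds must be ascending")
    if nonde_ratio is None:
        nonde_ratio = 1.0 / 1.5
    rows = []
    for t in ts:
        labels = label_truth(logfc, de_cutoff=t, nonde_cutoff=t * nonde_ratio)
        try:
            _, auc = roc_auc(ranked_genes, labels)
        except ValidationError:
            auc = np.nan
        rows.append({"threshold": t, "auc": auc})
    return pd.DataFrame(rows)


def top_x_recovery(ranked_genes: Sequence[str], labels: TruthLabels,
                   x_max: int) -> np.ndarray:
    """y(x) = true DE genes with truth rank <= x inside the method's top x.

    The truth ranking orders the DE-labeled genes by decreasing |logFC|; the
    method's top x is taken over labeled genes. An ideal method attains
    y = x up to the number of DE genes.
    """
    lab = labels.label_of()
    fc = labels.logfc_of()
    truth_sorted = sorted(labels.de_genes, key=lambda g: (-abs(fc[g]), g))
    truth_rank = {g: i + 1 for i, g in enumerate(truth_sorted)}
    kept = _labeled_ranking(ranked_genes, labels)
    out = np.zeros(x_max, dtype=int)
    for x in range(1, x_max + 1):
        top = kept[:x]
        out[x - 1] = sum(1 for g in top if lab[g] == "DE" and truth_rank[g] <= x)
    return out
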