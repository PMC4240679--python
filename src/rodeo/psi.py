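"""Dispersion distributions: how expression bins map between two samples.

For a bin p occupied in sample a, the dispersion row psi_p is the conditional
distribution of the bin the same gene occupies in sample b, aggregated over
all genes and all ordered pairs of resampling iterations. Summing the mass
strictly above / below p gives over- and under-expression probabilities O_p
and U_p; within one sample (a compared against itself) the self-map mass
N_p = 1 - (O_p + U_p) is the *neutrality*, an intrinsic measure of how stably
the bins are estimated, useful for choosing P.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import ValidationError
from .phi import PhiDistribution

__all__ = ["PsiMatrix", "compute_psi", "dispersion_summaries", "summaries_frame"]


class OUN(NamedTuple):
    O: float
    U: float
    N: float


@dataclass
class PsiMatrix:
    """P x P conditional dispersion distribution.

    Row p (0-indexed p-1) is Pr(psi_p = q); rows with zero support are all
    zeros and flagged through :attr:`support`. ``self_mode`` records that the
    two sides were the same sample with matched iteration pairs excluded.
    """

    P: int
    matrix: np.ndarray
    support: np.ndarray
    self_mode: bool = False

    def row(self, p: int) -> np.ndarray:
        if not 1 <= p <= self.P:
            raise ValidationError(f"bin {p} outside 1..{self.P}")
        return self.matrix[p - 1]

    def occupied(self, p: int) -> bool:
        return bool(self.support[p - 1] > 0)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(range(1, self.P + 1), name="p")
        return pd.DataFrame(self.matrix, index=idx,
                            columns=[f"q{q}" for q in range(1, self.P + 1)])


def _bin_counts(bin_matrix: np.ndarray, P: int) -> np.ndarray:
    L = bin_matrix.shape[0]
    idx = (bin_matrix.astype(np.int64) - 1) + P * np.arange(L)[:, None]
    return np.bincount(idx.ravel(), minlength=L * P).reshape(L, P)


def compute_psi(phiA: PhiDistribution, phiB: PhiDistribution,
                self_mode: bool = False) -> PsiMatrix:
    """Aggregate (bin in a, bin in b) events over genes and iteration pairs.

    Entry (p, q) counts events where a gene sits in bin p at iteration i of
    sample a and bin q at iteration i' of sample b, over all ordered pairs
    (i, i'), then normalises each row. With ``self_mode`` (a compared against
    itself) the matched pairs i = i' are excluded so the diagonal is not
    trivially inflated.
    """
    if phiA.gene_ids != phiB.gene_ids:
        raise ValidationError("dispersion requires identical gene sets")
    if phiA.P != phiB.P:
        raise ValidationError("dispersion requires identical P")
    if self_mode:
        if phiA.I != phiB.I:
            raise ValidationError("self-mode requires matched iteration counts")
        if phiA.I < 2:
            raise ValidationError("self-mode needs at least 2 iterations")
    P = phiA.P
    CA = _bin_counts(phiA.bin_matrix, P).astype(np.float64)
    CB = _bin_counts(phiB.bin_matrix, P).astype(np.float64)
    pair = CA.T @ CB
    if self_mode:
        J = np.zeros((P, P))
        np.add.at(J, (phiA.bin_matrix.ravel() - 1, phiB.bin_matrix.ravel() - 1), 1.0)
        pair -= J
    support = pair.sum(axis=1)
    matrix = np.zeros_like(pair)
    occ = support > 0
    matrix[occ] = pair[occ] / support[occ, None]
    return PsiMatrix(P=P, matrix=matrix, support=support, self_mode=self_mode)


def dispersion_summaries(psi: PsiMatrix, p: int) -> OUN | None:
    """Over-/under-expression and neutrality of bin p; None if the row is empty.

    N is defined as 1 - (O + U), so the three always sum to 1 exactly.
    """
    if not psi.occupied(p):
        return None
    row = psi.row(p)
    O = float(row[p:].sum())        # q >= p+1
    U = float(row[:p - 1].sum())    # q <= p-1
    return OUN(O=O, U=U, N=1.0 - (O + U))


def summaries_frame(psi: PsiMatrix) -> pd.DataFrame:
    """Per-bin (p, O, U, N) table; unoccupied bins carry NaN."""
    rows = []
    for p in range(1, psi.P + 1):
        s = dispersion_summaries(psi, p)
        rows.append({"p": p, "O": s.O if s else np.nan,
                     "U": s.U if s else np.nan, "N": s.N if s else np.nan})
    return pd.DataFrame(rows)
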