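"""DE calling: max-norm distance between bin histograms, ranking, robust sets.

The distance between a gene's two bin histograms is the largest absolute
difference between their cumulative distributions — the Kolmogorov–Smirnov
statistic on the discrete bins (the K-S *test* itself does not apply).
Because finitely many iterations produce many exact ties at distance 1.0,
genes are further ordered by the distance between their histogram modes.
A gene is called DE when its max-norm distance reaches the threshold δ and
its mode distance reaches the mode threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io import RodeoParams, ValidationError
from .phi import PhiDistribution

__all__ = [
    "DERecord",
    "maxnorm_distance",
    "mode_of",
    "de_records",
    "rank_genes",
    "call_de",
    "robust_sets",
    "RobustSets",
]


@dataclass
class DERecord:
    """Per-gene comparison summary between samples a and b."""

    gene: str
    maxnorm: float
    mode_a: int
    mode_b: int
    mode_distance: int = field(default=-1)
    direction: str = "none"
    rank: int | None = None
    is_de: bool = False

    def __post_init__(self) -> None:
        if self.mode_distance < 0:
            self.mode_distance = abs(self.mode_a - self.mode_b)


def maxnorm_distance(hA, hB) -> float:
    """Max absolute difference between the cumulative histograms (in [0, 1])."""
    a = np.asarray(hA, dtype=np.float64)
    b = np.asarray(hB, dtype=np.float64)
    if a.shape != b.shape:
        raise ValidationError(f"histogram length mismatch: {a.shape} vs {b.shape}")
    return float(np.abs(np.cumsum(a) - np.cumsum(b)).max())


def mode_of(h) -> int:
    """Smallest bin (1-based) attaining the maximum frequency."""
    return int(np.argmax(np.asarray(h))) + 1


def de_records(phiA: PhiDistribution, phiB: PhiDistribution) -> list[DERecord]:
    """Build one comparison record per gene (vectorised over the gene axis).

    Direction is relative to sample b: ``up`` means the mode in b exceeds the
    mode in a. With K replicates, pass replicate-averaged distributions.
    """
    if phiA.gene_ids != phiB.gene_ids:
        raise ValidationError("comparison requires identical gene sets")
    if phiA.P != phiB.P:
        raise ValidationError("comparison requires identical P")
    ca = np.cumsum(phiA.histogram, axis=1)
    cb = np.cumsum(phiB.histogram, axis=1)
    maxnorm = np.abs(ca - cb).max(axis=1)
    mode_a = np.argmax(phiA.histogram, axis=1) + 1
    mode_b = np.argmax(phiB.histogram, axis=1) + 1
    out = []
    for g, d, ma, mb in zip(phiA.gene_ids, maxnorm, mode_a, mode_b):
        direction = "none" if ma == mb else ("up" if mb > ma else "down")
        out.append(DERecord(gene=g, maxnorm=float(d), mode_a=int(ma),
                            mode_b=int(mb), direction=direction))
    return out


def rank_genes(records: list[DERecord]) -> list[DERecord]:
    """Order by decreasing max-norm, then decreasing mode distance, then gene
    id ascending; assign ranks 1..L."""
    ordered = sorted(records, key=lambda r: (-r.maxnorm, -r.mode_distance, r.gene))
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


def call_de(records: list[DERecord], params: RodeoParams) -> list[DERecord]:
    """Set ``is_de`` on each record from the δ and mode-distance thresholds.

    The δ comparison allows a small epsilon so a distance of 1.0 assembled
    from I frequency increments survives floating-point accumulation.
    """
    for r in records:
        r.is_de = (r.maxnorm >= params.dist_threshold - params.epsilon
                   and r.mode_distance >= params.mode_threshold)
    return records


@dataclass
class RobustSets:
    """Intersections of per-member DE sets within each group, per direction."""

    robust: dict[tuple[str, str], set[str]]
    overlaps: dict[tuple[str, str, str], set[str]]


def robust_sets(group_sets: Mapping[str, Mapping[str, Mapping[str, set]]]) -> RobustSets:
    """Intersect member DE gene sets within each group and direction.

    ``group_sets`` maps group label -> member label -> {"up": set, "down":
    set}. A transcript is *robust* for a group/direction when every member of
    the group calls it DE in that direction. Cross-group overlaps of the
    robust sets are reported per direction.
    """
    robust: dict[tuple[str, str], set[str]] = {}
    for group, members in group_sets.items():
        if len(members) < 2:
            raise ValidationError(
                f"group {group!r} has {len(members)} member(s); robust sets "
                "need at least 2")
        for direction in ("up", "down"):
            sets = [set(m.get(direction, set())) for m in members.values()]
            robust[(group, direction)] = set.intersection(*sets)
    overlaps: dict[tuple[str, str, str], set[str]] = {}
    groups = sorted(group_sets)
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            for direction in ("up", "down"):
                overlaps[(g1, g2, direction)] = (
                    robust[(g1, direction)] & robust[(g2, direction)])
    return RobustSets(robust=robust, overlaps=overlaps)
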