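"""Reading, validation and serialisation of count tables, designs and parameters.

The tool consumes *raw* per-gene read counts (plain TSV, one integer column
per sample). Normalised units such as FPKM/RPKM are deliberately rejected:
the resampling model operates on read counts, and gene length is absorbed
upstream in the mapping step.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ValidationError",
    "CountTable",
    "ExperimentDesign",
    "RodeoParams",
    "PROFILES",
    "read_count_table",
    "write_count_table",
    "read_design",
    "resolve_R",
    "write_de_table",
    "read_de_table",
]

FLOAT_FMT = "%.6g"


class ValidationError(ValueError):
    """An input violates a structural invariant; the message names the offender."""


@dataclass
class CountTable:
    """Genes x samples matrix of non-negative integer read counts.

    ``gene_ids`` (the gene universe G, |G| = L) and ``sample_ids`` are ordered
    and unique; ``counts`` has shape (L, S). Per-sample totals (library sizes
    M) are exposed via :attr:`totals`.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValidationError("counts must be a 2-D genes x samples matrix")
        if arr.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"counts shape {arr.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if len(self.gene_ids) < 2:
            raise ValidationError("a count table needs at least 2 genes")
        if np.issubdtype(arr.dtype, np.floating):
            frac = arr % 1 != 0
            if frac.any():
                r, c = np.argwhere(frac)[0]
                raise ValidationError(
                    f"non-integer count {arr[r, c]!r} at gene "
                    f"{self.gene_ids[r]!r}, sample {self.sample_ids[c]!r}"
                )
        elif not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError(f"counts must be integers, got dtype {arr.dtype}")
        if (arr < 0).any():
            r, c = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count {arr[r, c]} at gene {self.gene_ids[r]!r}, "
                f"sample {self.sample_ids[c]!r}"
            )
        self.counts = arr.astype(np.int64)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def totals(self) -> np.ndarray:
        """Per-sample mapped-read totals M."""
        return self.counts.sum(axis=0)

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise KeyError(f"unknown sample {sample!r}") from None

    def counts_for(self, sample: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.gene_ids, name="gene"),
                            columns=self.sample_ids)


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} id {x!r}")
        seen.add(x)


def read_count_table(path: str | Path) -> CountTable:
    """Parse a TSV count table (header of sample ids, first column gene ids).

    Input gene order is preserved. Raises :class:`ValidationError` naming the
    offending cell for duplicate ids, negative or non-integer counts.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", header=0, dtype={0: str})
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise ValidationError(f"{path}: empty or malformed count table")
    gene_col = df.columns[0]
    genes = df[gene_col].tolist()
    samples = [str(c) for c in df.columns[1:]]
    values = df.iloc[:, 1:]
    for col in values.columns:
        if not np.issubdtype(values[col].dtype, np.number):
            bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()]
            row = bad.index[0]
            raise ValidationError(
                f"non-numeric count {bad.iloc[0]!r} at gene {genes[row]!r}, "
                f"sample {col!r}"
            )
    return CountTable(genes, samples, values.to_numpy())


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# experiment design


@dataclass
class ExperimentDesign:
    """Maps samples to (condition, replicate) and lists condition comparisons.

    ``groups`` optionally labels conditions with a response/time class (used
    when intersecting per-cultivar DE sets into robust sets).
    """

    assignments: dict[str, tuple[str, int]]
    comparisons: list[tuple[str, str]] = field(default_factory=list)
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        per_cond: dict[str, list[int]] = {}
        for s, (cond, k) in self.assignments.items():
            per_cond.setdefault(cond, []).append(int(k))
        for cond, ks in per_cond.items():
            if sorted(ks) != list(range(1, len(ks) + 1)):
                raise ValidationError(
                    f"replicate indices for condition {cond!r} must be 1..K "
                    f"with no gaps, got {sorted(ks)}"
                )
        for a, b in self.comparisons:
            if a == b:
                raise ValidationError(f"comparison ({a!r}, {b!r}) must reference two distinct conditions")
            for cond in (a, b):
                if cond not in per_cond:
                    raise ValidationError(f"comparison references unknown condition {cond!r}")

    @property
    def conditions(self) -> list[str]:
        out: list[str] = []
        for cond, _ in self.assignments.values():
            if cond not in out:
                out.append(cond)
        return out

    def samples_for(self, condition: str) -> list[str]:
        """Samples of a condition ordered by replicate index."""
        pairs = [(k, s) for s, (c, k) in self.assignments.items() if c == condition]
        if not pairs:
            raise KeyError(f"unknown condition {condition!r}")
        return [s for _, s in sorted(pairs)]

    def validate_against(self, table: CountTable) -> None:
        for s in self.assignments:
            if s not in table.sample_ids:
                raise ValidationError(f"design sample {s!r} missing from count table")


def read_design(path: str | Path) -> ExperimentDesign:
    """Read a design TSV with columns sample, condition, replicate[, group]."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"sample", "condition", "replicate"}
    if not need.issubset(df.columns):
        raise ValidationError(f"design file must have columns {sorted(need)}")
    assignments = {
        row["sample"]: (row["condition"], int(row["replicate"]))
        for _, row in df.iterrows()
    }
    groups: dict[str, str] = {}
    if "group" in df.columns:
        for _, row in df.iterrows():
            g = row.get("group")
            if isinstance(g, str) and g:
                groups[row["condition"]] = g
    return ExperimentDesign(assignments, groups=groups)


def write_design(design: ExperimentDesign, path: str | Path) -> None:
    rows = [
        {"sample": s, "condition": c, "replicate": k, "group": design.groups.get(c, "")}
        for s, (c, k) in design.assignments.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# parameters


@dataclass
class RodeoParams:
    """Run parameters.

    P
        number of ordered expression bins (> 1).
    I
        resampling iterations per sample.
    R
        reads drawn per iteration; ``"auto"`` resolves per sample to that
        sample's mapped-read total.
    subsample_step / subsample_threshold
        the segmentation DP runs on every ``subsample_step``-th gene once the
        number of expressed genes exceeds ``subsample_threshold``.
    dist_threshold
        max-norm distance δ required to call a gene DE.
    mode_threshold
        minimum distance between histogram modes required to call DE.
    epsilon
        float tolerance used in the δ comparison.
    """

    P: int = 15
    I: int = 100
    R: int | str = "auto"
    seed: int = 0
    subsample_step: int = 10
    subsample_threshold: int = 2000
    dist_threshold: float = 1.0
    mode_threshold: int = 5
    epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if self.P < 2:
            raise ValidationError("P must be >= 2")
        if self.I < 1:
            raise ValidationError("I must be >= 1")
        if self.R != "auto":
            self.R = int(self.R)
            if self.R < 1:
                raise ValidationError("R must be a positive integer or 'auto'")
        if self.seed < 0:
            raise ValidationError("seed must be non-negative")
        if self.subsample_step < 1:
            raise ValidationError("subsample_step must be positive")
        if not 0 < self.dist_threshold <= 1:
            raise ValidationError("dist_threshold must lie in (0, 1]")
        if not 0 <= self.mode_threshold <= self.P - 1:
            raise ValidationError("mode_threshold must lie in [0, P-1]")


#: Named parameter profiles for the two published settings.
PROFILES: dict[str, dict] = {
    "phalaris": dict(P=15, I=100, R="auto", dist_threshold=1.0, mode_threshold=5),
    "maqc": dict(P=20, I=100, R=10_000_000),
}


def load_params(config: str | Path | Mapping | None = None,
                profile: str | None = None, **overrides) -> RodeoParams:
    """Build parameters from an optional YAML config, profile and overrides.

    Precedence (low to high): profile named in the config file, ``profile``
    argument, remaining config keys, keyword overrides.
    """
    cfg: dict = {}
    if config is not None:
        if isinstance(config, (str, Path)):
            with open(config) as fh:
                cfg = yaml.safe_load(fh) or {}
        else:
            cfg = dict(config)
    name = profile or cfg.pop("profile", None)
    merged: dict = {}
    if name is not None:
        if name not in PROFILES:
            raise ValidationError(f"unknown profile {name!r}; choose from {sorted(PROFILES)}")
        merged.update(PROFILES[name])
    known = {f.name for f in dataclasses.fields(RodeoParams)}
    for k, v in cfg.items():
        if k == "comparisons":
            continue
        if k not in known:
            raise ValidationError(f"unknown config key {k!r}")
        merged[k] = v
    merged.update({k: v for k, v in overrides.items() if v is not None})
    return RodeoParams(**merged)


def resolve_R(table: CountTable, params: RodeoParams, sample: str) -> int:
    """Resolve the per-iteration read budget for one sample.

    A numeric R applies to every sample; ``"auto"`` uses the sample's own
    mapped-read total M. A sample with zero total reads cannot be resampled.
    """
    total = int(table.counts_for(sample).sum())
    if total == 0:
        raise ValidationError(f"sample {sample!r} has zero total reads; cannot resample")
    if params.R == "auto":
        return total
    return int(params.R)


# ---------------------------------------------------------------------------
# result tables

DE_COLUMNS = ["gene", "maxnorm", "mode_a", "mode_b", "mode_distance",
              "direction", "rank", "is_DE"]


def write_de_table(records, path: str | Path) -> None:
    """Write ranked DE records as TSV; row order is rank order."""
    rows = [
        {
            "gene": r.gene,
            "maxnorm": FLOAT_FMT % r.maxnorm,
            "mode_a": r.mode_a,
            "mode_b": r.mode_b,
            "mode_distance": r.mode_distance,
            "direction": r.direction,
            "rank": r.rank,
            "is_DE": int(bool(r.is_de)),
        }
        for r in records
    ]
    df = pd.DataFrame(rows, columns=DE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_de_table(path: str | Path):
    """Parse a written DE table back into records (for round-trips and eval)."""
    from .de import DERecord  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(DERecord(
            gene=str(row["gene"]),
            maxnorm=float(row["maxnorm"]),
            mode_a=int(row["mode_a"]),
            mode_b=int(row["mode_b"]),
            direction=str(row["direction"]),
            rank=int(row["rank"]),
            is_de=bool(int(row["is_DE"])),
        ))
    return out
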