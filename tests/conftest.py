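import numpy as np
import pytest

from rodeo.io import CountTable, RodeoParams


@pytest.fixture
def small_table() -> CountTable:
    return CountTable(
        gene_ids=["gA", "gB", "gC", "gD"],
        sample_ids=["ctrl", "stress"],
        counts=np.array([[100, 10], [50, 50], [10, 100], [0, 0]]),
    )


@pytest.fixture
def quick_params() -> RodeoParams:
    return RodeoParams(P=5, I=20, seed=7, mode_threshold=3)


def brute_force_segmentation(y, k, tol=1e-9):
    """Independent oracle: enumerate every breakpoint placement, score each
    segment with a numpy least-squares line fit, return the lexicographically
    smallest placement within ``tol`` of the optimum and its error."""
    from itertools import combinations

    y = np.asarray(y, dtype=float)
    n = y.size
    results = []
    for bks in combinations(range(n - 1), k - 1):
        bounds = [-1, *bks, n - 1]
        err = 0.0
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            seg = y[lo + 1:hi + 1]
            if seg.size > 2:
                x = np.arange(seg.size, dtype=float)
                _, res, *_ = np.polyfit(x, seg, 1, full=True)
                err += float(res[0]) if len(res) else 0.0
        results.append((err, bks))
    best = min(e for e, _ in results)
    eps = tol * max(1.0, best)
    ties = sorted(bks for e, bks in results if e <= best + eps)
    return list(ties[0]), best


def brute_force_lis_length(seq) -> int:
    """Independent oracle: longest strictly increasing subsequence length by
    enumerating candidate subsequences, longest first."""
    from itertools import combinations

    seq = list(seq)
    for k in range(len(seq), 0, -1):
        for combo in combinations(seq, k):
            if all(a < b for a, b in zip(combo, combo[1:])):
                return k
    return 0
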