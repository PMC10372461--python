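"""Independent brute-force oracles used to validate the fast implementations.

Everything here works at per-base-pair resolution or by exhaustive
enumeration, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats


def merge_oracle(
    intervals: list[tuple[str, int, int]], gap: int
) -> list[tuple[str, int, int]]:
    """Transitive pairwise closure: repeatedly fuse any mergeable pair."""
    work = [list(iv) for iv in intervals]
    changed = True
    while changed:
        changed = False
        for i in range(len(work)):
            for j in range(len(work)):
                if i == j or work[i] is None or work[j] is None:
                    continue
                a, b = work[i], work[j]
                if a[0] != b[0]:
                    continue
                lo, hi = (a, b) if a[1] <= b[1] else (b, a)
                if hi[1] - lo[2] <= gap:
                    lo[2] = max(lo[2], hi[2])
                    work[work.index(hi)] = None
                    changed = True
                    break
            if changed:
                break
        work = [w for w in work if w is not None]
    return sorted((c, s, e) for c, s, e in work)


def coverage_bp(intervals: list[tuple[str, int, int]], chrom: str, length: int) -> np.ndarray:
    cov = np.zeros(length, dtype=bool)
    for c, s, e in intervals:
        if c == chrom:
            cov[s:e] = True
    return cov


def complement_oracle(
    intervals: list[tuple[str, int, int]], chrom_sizes: list[tuple[str, int]]
) -> list[tuple[str, int, int]]:
    """Per-bp scan of the uncovered regions."""
    out = []
    for chrom, length in chrom_sizes:
        cov = coverage_bp(intervals, chrom, length)
        start = None
        for pos in range(length):
            if not cov[pos] and start is None:
                start = pos
            elif cov[pos] and start is not None:
                out.append((chrom, start, pos))
                start = None
        if start is not None:
            out.append((chrom, start, length))
    return out


def overlap_fraction_oracle(
    query: list[tuple[str, int, int]],
    reference: list[tuple[str, int, int]],
    chrom_sizes: list[tuple[str, int]],
) -> list[float]:
    """Per-query covered fraction, counted base by base across the ref union."""
    covs = {c: coverage_bp(reference, c, n) for c, n in chrom_sizes}
    fracs = []
    for chrom, s, e in query:
        fracs.append(float(covs[chrom][s:e].sum()) / (e - s))
    return fracs


def confusion_oracle(
    query: list[tuple[str, int, int]],
    reference: list[tuple[str, int, int]],
    chrom_sizes: list[tuple[str, int]],
    min_fraction: float,
) -> tuple[int, int, int]:
    """(TP, FP, TN) by exhaustive per-interval coverage-fraction checks."""
    fr = overlap_fraction_oracle(query, reference, chrom_sizes)
    tp = sum(1 for f in fr if f >= min_fraction)
    fp = len(fr) - tp
    ref_comp = complement_oracle(reference, chrom_sizes)
    query_comp = complement_oracle(query, chrom_sizes)
    fr_tn = overlap_fraction_oracle(ref_comp, query_comp, chrom_sizes)
    tn = sum(1 for f in fr_tn if f >= min_fraction)
    return tp, fp, tn


def ranksum_exact_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p by enumerating every assignment of pooled ranks."""
    pooled = np.concatenate([x, y])
    n = len(x)
    ranks = stats.rankdata(pooled)
    obs_u = float(np.sum(ranks[:n]) - n * (n + 1) / 2)
    us = []
    for comb in itertools.combinations(range(len(pooled)), n):
        us.append(float(np.sum(ranks[list(comb)]) - n * (n + 1) / 2))
    us = np.array(us)
    cdf = np.mean(us <= obs_u)
    sf = np.mean(us >= obs_u)
    return float(min(1.0, 2 * min(cdf, sf)))


def crossing_grid_oracle(
    cells: np.ndarray, sens: np.ndarray, spec: np.ndarray, n_grid: int = 2_000_001
) -> float | None:
    """Dense-grid search for the highest sensitivity/specificity crossing."""
    t = np.log10(np.asarray(cells, dtype=float))
    grid = np.linspace(t[0], t[-1], n_grid)
    gap = np.interp(grid, t, sens) - np.interp(grid, t, spec)
    sign_change = np.flatnonzero(np.diff(np.sign(gap)) != 0)
    zeros = np.flatnonzero(gap == 0)
    candidates = []
    if len(sign_change):
        candidates.append(grid[sign_change[-1] + (1 if abs(gap[sign_change[-1] + 1]) < abs(gap[sign_change[-1]]) else 0)])
    if len(zeros):
        candidates.append(grid[zeros[-1]])
    if not candidates:
        return None
    return float(10 ** max(candidates))


def random_intervals(
    rng: np.random.Generator,
    chrom_sizes: list[tuple[str, int]],
    n: int,
    max_len: int = 200,
) -> list[tuple[str, int, int]]:
    out = []
    for _ in range(n):
        chrom, length = chrom_sizes[rng.integers(0, len(chrom_sizes))]
        w = int(rng.integers(1, max_len))
        s = int(rng.integers(0, max(1, length - w)))
        out.append((chrom, s, s + w))
    return out
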