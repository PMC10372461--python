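"""Scaled metagene enrichment profiles and profile/RPKM comparisons.

Each gene is mapped onto a common axis: a fixed number of upstream flank
bins, a fixed number of gene-body bins scaled to the gene length, and the
mirrored downstream flank. Minus-strand genes are flipped so the axis always
runs 5' -> 3'. Enrichment is the natural log of observed over expected
signal; positions with no observed signal are reported missing (NaN), not
as negative infinity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .genome import GenomeLayout, Interval, IntervalError, PeakSet, merge_adjacent

__all__ = [
    "GeneModel",
    "BinGrid",
    "MetageneProfile",
    "RankSumResult",
    "BinnedCounts",
    "read_genes_bed6",
    "read_genes_gff3",
    "occupancy_profile",
    "compare_profiles",
    "rpkm_summary",
    "compare_rpkm",
    "count_correlation",
    "rank_sum_test",
]

DEFAULT_BIN_SIZE = 1000
DEFAULT_FLANK = 5000
DEFAULT_BODY_BINS = 50
DEFAULT_FLANK_BINS = 25


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene span in half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise IntervalError(f"gene {self.id!r}: start >= end")
        if self.strand not in {"+", "-"}:
            raise IntervalError(f"gene {self.id!r}: invalid strand {self.strand!r}")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end


@dataclass
class BinGrid:
    """Sliding windows tiled across a genome layout.

    By default the step is half the bin size, so interior base pairs are
    covered by two overlapping windows; windows are clipped at chromosome
    ends.
    """

    layout: GenomeLayout
    bin_size: int = DEFAULT_BIN_SIZE
    step_size: int | None = None
    chroms: list[str] = field(init=False)
    starts: np.ndarray = field(init=False)
    ends: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.step_size is None:
            self.step_size = self.bin_size // 2
        if self.bin_size <= 0 or self.step_size <= 0:
            raise ValueError("bin_size and step_size must be positive")
        chroms: list[str] = []
        starts: list[int] = []
        ends: list[int] = []
        for name, length in self.layout.chromosomes:
            pos = 0
            while pos < length:
                chroms.append(name)
                starts.append(pos)
                ends.append(min(pos + self.bin_size, length))
                pos += self.step_size
        self.chroms = chroms
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)

    @property
    def n_bins(self) -> int:
        return len(self.starts)


@dataclass
class BinnedCounts:
    """Per-bin read counts for one or more libraries on a shared grid."""

    grid: BinGrid
    counts: np.ndarray  # shape (n_bins, n_libraries)
    library_labels: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim == 1:
            self.counts = self.counts[:, None]
        if self.counts.shape[0] != self.grid.n_bins:
            raise ValueError(
                f"counts rows ({self.counts.shape[0]}) != grid bins ({self.grid.n_bins})"
            )
        if self.counts.shape[1] != len(self.library_labels):
            raise ValueError("one label required per library column")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    def column(self, label: str) -> np.ndarray:
        return self.counts[:, self.library_labels.index(label)]


@dataclass
class MetageneProfile:
    """log(observed/expected) along the scaled gene axis."""

    positions: list[str]
    axis: np.ndarray  # numeric axis, body positions in [0, 1], flanks beyond
    enrichment: np.ndarray  # NaN where observed == 0
    observed: np.ndarray
    expected: float
    n_genes: int
    flank: int
    body_bins: int
    flank_bins: int


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    p_value: float
    defined: bool = True


def read_genes_bed6(path: str | Path, layout: GenomeLayout) -> list[GeneModel]:
    """Read genes from BED6 (strand in column 6)."""
    lengths = layout.lengths
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise IntervalError(f"{path}:{lineno}: BED6 requires 6 columns")
            chrom, start, end, name, _, strand = parts[:6]
            if chrom not in lengths:
                raise IntervalError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            genes.append(GeneModel(chrom, int(start), int(end), strand, id=name))
    return genes


def read_genes_gff3(path: str | Path, layout: GenomeLayout) -> list[GeneModel]:
    """Read ``gene`` features from a minimal GFF3 (1-based inclusive -> half-open)."""
    lengths = layout.lengths
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise IntervalError(f"{path}:{lineno}: GFF3 requires 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts[:9]
            if ftype != "gene":
                continue
            if chrom not in lengths:
                raise IntervalError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            gid = ""
            for token in attrs.split(";"):
                if token.startswith("ID="):
                    gid = token[3:]
            genes.append(GeneModel(chrom, int(start) - 1, int(end), strand, id=gid))
    return genes


def _gene_bin_boundaries(
    gene: GeneModel, flank: int, body_bins: int, flank_bins: int
) -> np.ndarray:
    """Genomic boundaries (ascending) of the scaled bins for one gene."""
    up = np.linspace(gene.start - flank, gene.start, flank_bins + 1)
    body = np.linspace(gene.start, gene.end, body_bins + 1)
    down = np.linspace(gene.end, gene.end + flank, flank_bins + 1)
    b = np.concatenate([up[:-1], body[:-1], down])
    return np.rint(b).astype(np.int64)


def _axis_labels(body_bins: int, flank_bins: int) -> tuple[list[str], np.ndarray]:
    labels = (
        [f"u{flank_bins - i}" for i in range(flank_bins)]
        + [f"b{i + 1}" for i in range(body_bins)]
        + [f"d{i + 1}" for i in range(flank_bins)]
    )
    axis = np.concatenate(
        [
            -np.arange(flank_bins, 0, -1) / flank_bins,
            (np.arange(body_bins) + 0.5) / body_bins,
            1.0 + np.arange(1, flank_bins + 1) / flank_bins,
        ]
    )
    return labels, axis


def _grid_step_values(counts: BinnedCounts, label: str | None) -> dict[str, np.ndarray]:
    """Per-chromosome per-bp signal at step resolution.

    The per-bp value is the mean of count/width over the sliding windows
    covering that base; with step = bin/2 this is a 2-window average except
    at chromosome edges.
    """
    grid = counts.grid
    col = counts.column(label) if label else counts.counts[:, 0]
    step = grid.step_size
    dens: dict[str, np.ndarray] = {}
    cover: dict[str, np.ndarray] = {}
    for name, length in grid.layout.chromosomes:
        n_steps = (length + step - 1) // step
        dens[name] = np.zeros(n_steps)
        cover[name] = np.zeros(n_steps)
    chrom_arr = np.asarray(grid.chroms)
    for name in dens:
        mask = chrom_arr == name
        ws, we, wc = grid.starts[mask], grid.ends[mask], col[mask]
        for s, e, c in zip(ws, we, wc):
            k0, k1 = s // step, (e + step - 1) // step
            dens[name][k0:k1] += c / (e - s)
            cover[name][k0:k1] += 1
    out: dict[str, np.ndarray] = {}
    for name in dens:
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = np.where(cover[name] > 0, dens[name] / cover[name], 0.0)
    return out


def occupancy_profile(
    signal: PeakSet | BinnedCounts,
    genes: list[GeneModel],
    layout: GenomeLayout,
    flank: int = DEFAULT_FLANK,
    body_bins: int = DEFAULT_BODY_BINS,
    flank_bins: int = DEFAULT_FLANK_BINS,
    library: str | None = None,
) -> MetageneProfile:
    """Metagene profile of *signal* over *genes*.

    For a :class:`PeakSet` signal, the observed value at a position is the
    fraction of genes whose bin there overlaps a peak, and the expected value
    is the genome-wide covered fraction. For :class:`BinnedCounts`, observed
    is the mean per-bp count density over genes and expected its genome-wide
    mean. Genes shorter than ``body_bins`` bp are dropped (their body bins
    would be sub-bp); flank bins falling off a chromosome end are skipped for
    that gene.
    """
    if not genes:
        raise ValueError("empty gene list")
    usable = [g for g in genes if (g.end - g.start) >= body_bins]
    if not usable:
        raise ValueError("no gene is at least body_bins bp long")
    n_pos = 2 * flank_bins + body_bins
    labels, axis = _axis_labels(body_bins, flank_bins)
    lengths = layout.lengths

    if isinstance(signal, PeakSet):
        merged = merge_adjacent(signal, gap=0)
        by_chrom = merged.by_chrom()
        expected = merged.total_bp() / layout.total_size
        obs_sum = np.zeros(n_pos)
        obs_n = np.zeros(n_pos)
        for gene in usable:
            b = _gene_bin_boundaries(gene, flank, body_bins, flank_bins)
            s = b[:-1]
            e = b[1:]
            if gene.strand == "-":
                s, e = s[::-1], e[::-1]
            clen = lengths[gene.chrom]
            valid = (e > 0) & (s < clen) & (e > s)
            cs = np.clip(s, 0, clen)
            ce = np.clip(e, 0, clen)
            if gene.chrom in by_chrom:
                ps, pe = by_chrom[gene.chrom]
                idx = np.searchsorted(pe, cs, side="right")
                covered = np.zeros(n_pos, dtype=bool)
                in_range = idx < len(ps)
                covered[in_range] = ps[idx[in_range]] < ce[in_range]
            else:
                covered = np.zeros(n_pos, dtype=bool)
            obs_sum += np.where(valid, covered.astype(float), 0.0)
            obs_n += valid.astype(float)
    else:
        dens = _grid_step_values(signal, library)
        step = signal.grid.step_size
        total = sum(
            float(np.sum(v[:-1]) * step + v[-1] * (lengths[name] - (len(v) - 1) * step))
            for name, v in dens.items()
        )
        expected = total / layout.total_size
        prefix = {
            name: np.concatenate(([0.0], np.cumsum(v) * step)) for name, v in dens.items()
        }
        obs_sum = np.zeros(n_pos)
        obs_n = np.zeros(n_pos)
        for gene in usable:
            b = _gene_bin_boundaries(gene, flank, body_bins, flank_bins)
            s = b[:-1].astype(float)
            e = b[1:].astype(float)
            if gene.strand == "-":
                s, e = s[::-1], e[::-1]
            clen = lengths[gene.chrom]
            valid = (e > 0) & (s < clen) & (e > s)
            cs = np.clip(s, 0, clen)
            ce = np.clip(e, 0, clen)
            P = prefix[gene.chrom]
            v = dens[gene.chrom]

            def integral(x: np.ndarray) -> np.ndarray:
                k = np.clip((x // step).astype(int), 0, len(v) - 1)
                return P[k] + v[k] * (x - k * step)

            area = integral(ce) - integral(cs)
            with np.errstate(invalid="ignore", divide="ignore"):
                mean_val = np.where(valid, area / np.maximum(ce - cs, 1e-12), 0.0)
            obs_sum += np.where(valid, mean_val, 0.0)
            obs_n += valid.astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        observed = np.where(obs_n > 0, obs_sum / np.maximum(obs_n, 1), np.nan)
        enrichment = np.where(
            (observed > 0) & (expected > 0), np.log(observed / expected), np.nan
        )
    return MetageneProfile(
        positions=labels,
        axis=axis,
        enrichment=enrichment,
        observed=observed,
        expected=float(expected),
        n_genes=len(usable),
        flank=flank,
        body_bins=body_bins,
        flank_bins=flank_bins,
    )


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> RankSumResult:
    """Two-sided unpaired rank-sum test.

    Exact null distribution when both samples are small (< 50) and tie-free,
    mirroring the R default; otherwise the normal approximation with tie
    correction (no continuity correction, so identical samples give p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[np.isfinite(x)]
    y = y[np.isfinite(y)]
    if len(x) < 3 or len(y) < 3:
        return RankSumResult(statistic=math.nan, p_value=math.nan, defined=False)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties and len(x) < 50 and len(y) < 50:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return RankSumResult(statistic=float(res.statistic), p_value=float(res.pvalue))


def compare_profiles(a: MetageneProfile, b: MetageneProfile) -> RankSumResult:
    """Rank-sum comparison of two enrichment profiles.

    Positions missing (NaN) in either profile are dropped pairwise before
    the unpaired test.
    """
    if len(a.enrichment) != len(b.enrichment):
        raise ValueError("profiles have different numbers of positions")
    keep = np.isfinite(a.enrichment) & np.isfinite(b.enrichment)
    return rank_sum_test(a.enrichment[keep], b.enrichment[keep])


def rpkm_summary(counts: BinnedCounts, library: str) -> tuple[np.ndarray, float]:
    """Per-bin RPKM for one library and the mean over bins.

    RPKM = count * 1e9 / (bin width in bp * library total count).
    """
    col = counts.column(library).astype(float)
    total = col.sum()
    if total <= 0:
        raise ValueError(f"library {library!r} has zero total counts")
    widths = (counts.grid.ends - counts.grid.starts).astype(float)
    rpkm = col * 1e9 / (widths * total)
    return rpkm, float(rpkm.mean())


def compare_rpkm(a: np.ndarray, b: np.ndarray) -> RankSumResult:
    """Rank-sum comparison of two RPKM vectors."""
    return rank_sum_test(np.asarray(a), np.asarray(b))


def count_correlation(counts: BinnedCounts) -> np.ndarray:
    """Pairwise Pearson correlation of per-bin counts between libraries.

    Zero-variance libraries get NaN rows/columns (undefined), the diagonal
    is 1 for every library with positive variance.
    """
    if counts.counts.shape[1] < 2:
        raise ValueError("count_correlation requires at least 2 libraries")
    X = counts.counts.astype(float)
    var = X.var(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr[var == 0, :] = np.nan
    corr[:, var == 0] = np.nan
    for i in np.flatnonzero(var > 0):
        corr[i, i] = 1.0
    return corr
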