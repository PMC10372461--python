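"""Synthetic genomes, annotations, peak sets and counts with known truth.

Every generator is a pure function of its configuration and seed: the global
seed feeds named per-stage substreams, so stages can be regenerated
independently and reruns are byte-identical. Query peak sets are degraded
copies of a reference set with a planted recall, boundary jitter, peak
splitting, and background false peaks placed off the reference — so
sensitivity, specificity and PPV have unambiguous ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .genome import GenomeLayout, Interval, PeakSet, write_bed
from .metagene import BinGrid, BinnedCounts, GeneModel

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "simulate_reference_peaks",
    "simulate_query_peaks",
    "simulate_binned_counts",
    "write_simulation",
]

MIN_PEAK_WIDTH = 50
# reference peaks are kept at least this far apart so that downstream
# merging (gap <= 150) can never fuse two planted peaks
MIN_PEAK_SEPARATION = 151


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic benchmark; all randomness flows from ``seed``."""

    n_chrom: int = 4
    chrom_length: int = 1_000_000
    n_genes: int = 500
    gene_length: tuple[float, float] = (3000.0, 1000.0)  # mean, sd
    p_tss_peak: float = 0.5
    peak_width: tuple[float, float] = (900.0, 300.0)  # mean, sd
    planted_recall: float = 1.0
    background_rate: float = 0.0  # false peaks per Mb
    jitter_sd: float = 0.0
    split_prob: float = 0.0
    split_gap: int = 150
    depth: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_tss_peak", "planted_recall", "split_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_chrom <= 0 or self.chrom_length <= 0:
            raise ValueError("n_chrom and chrom_length must be positive")
        if self.n_genes < 0 or self.depth < 0:
            raise ValueError("n_genes and depth must be >= 0")
        if self.peak_width[0] <= 0 or self.gene_length[0] <= 0:
            raise ValueError("mean widths must be positive")
        if self.background_rate < 0 or self.jitter_sd < 0 or self.split_gap < 0:
            raise ValueError("rates, jitter and gaps must be >= 0")


def _rng(seed: int, stage: str) -> np.random.Generator:
    key = zlib.crc32(stage.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def simulate_genome(config: SimulationConfig) -> tuple[GenomeLayout, list[GeneModel]]:
    """Uniformly place non-overlapping stranded genes on equal-length chromosomes.

    Genes are assigned to chromosomes uniformly; within a chromosome the free
    space left after summing gene lengths is split into uniform random gaps,
    which for sparse genomes approximates uniform placement. Fails if a
    chromosome cannot hold its genes.
    """
    rng = _rng(config.seed, "genome")
    layout = GenomeLayout(
        tuple((f"chr{i + 1}", config.chrom_length) for i in range(config.n_chrom))
    )
    if config.n_genes == 0:
        return layout, []
    chrom_of = rng.integers(0, config.n_chrom, size=config.n_genes)
    mean, sd = config.gene_length
    lengths = np.maximum(200, np.rint(rng.normal(mean, sd, size=config.n_genes))).astype(
        np.int64
    )
    strands = rng.choice(["+", "-"], size=config.n_genes)
    genes: list[GeneModel] = []
    gidx = 0
    for ci, (name, clen) in enumerate(layout.chromosomes):
        mask = chrom_of == ci
        k = int(mask.sum())
        if k == 0:
            continue
        glens = lengths[mask]
        gstr = strands[mask]
        free = clen - int(glens.sum())
        if free < 0:
            raise ValueError(
                f"cannot place {k} genes totalling {glens.sum()} bp on "
                f"{name} of length {clen}"
            )
        cuts = np.sort(rng.uniform(0, free, size=k))
        starts = (cuts + np.concatenate(([0], np.cumsum(glens[:-1])))).astype(np.int64)
        for j in range(k):
            gidx += 1
            genes.append(
                GeneModel(
                    chrom=name,
                    start=int(starts[j]),
                    end=int(starts[j] + glens[j]),
                    strand=str(gstr[j]),
                    id=f"g{gidx:06d}",
                )
            )
    return layout, genes


def simulate_reference_peaks(
    genes: list[GeneModel], layout: GenomeLayout, config: SimulationConfig
) -> PeakSet:
    """TSS-centered reference peaks for a random subset of genes.

    Each gene carries a peak with probability ``p_tss_peak``; widths are
    normal, truncated at 50 bp, clipped to the chromosome. Peaks closer than
    the minimum separation to their left neighbour are trimmed (and dropped
    if trimming leaves them under 50 bp), so planted peaks never merge.
    """
    if not genes:
        raise ValueError("simulate_reference_peaks: empty gene list")
    rng = _rng(config.seed, "reference")
    keep = rng.random(len(genes)) < config.p_tss_peak
    mean, sd = config.peak_width
    widths = np.maximum(
        MIN_PEAK_WIDTH, np.rint(rng.normal(mean, sd, size=len(genes)))
    ).astype(np.int64)
    lengths = layout.lengths
    raw: list[Interval] = []
    for g, k, w in zip(genes, keep, widths):
        if not k:
            continue
        half = int(w) // 2
        start = max(0, g.tss - half)
        end = min(lengths[g.chrom], g.tss + (int(w) - half))
        if end - start >= MIN_PEAK_WIDTH:
            raw.append(Interval(g.chrom, start, end))
    raw.sort(key=lambda iv: (layout.rank(iv.chrom), iv.start, iv.end))
    out: list[Interval] = []
    prev_end: dict[str, int] = {}
    for iv in raw:
        floor = prev_end.get(iv.chrom, -MIN_PEAK_SEPARATION) + MIN_PEAK_SEPARATION
        start = max(iv.start, floor)
        if iv.end - start >= MIN_PEAK_WIDTH:
            out.append(Interval(iv.chrom, start, iv.end))
            prev_end[iv.chrom] = iv.end
    return PeakSet(intervals=out, label="reference", sorted=True, chrom_order=layout.names)


def simulate_query_peaks(
    reference: PeakSet, layout: GenomeLayout, config: SimulationConfig
) -> PeakSet:
    """Degrade *reference* into a query call with known recall and background.

    Each reference peak is retained with probability ``planted_recall``;
    retained peaks get independent normal jitter on both boundaries, are
    split in two around their midpoint with probability ``split_prob``
    (pieces ``split_gap`` bp apart), and a Poisson number of background
    peaks per Mb is added, rejecting positions within merge range of any
    reference peak.
    """
    rng = _rng(config.seed, "query")
    lengths = layout.lengths
    out: list[Interval] = []
    for iv in reference.intervals:
        if rng.random() >= config.planted_recall:
            continue
        start, end = iv.start, iv.end
        if config.jitter_sd > 0:
            start = start + int(round(rng.normal(0, config.jitter_sd)))
            end = end + int(round(rng.normal(0, config.jitter_sd)))
            if end - start < MIN_PEAK_WIDTH:
                mid = (start + end) // 2
                start = mid - MIN_PEAK_WIDTH // 2
                end = start + MIN_PEAK_WIDTH
            start = max(0, start)
            end = min(lengths[iv.chrom], end)
            if end <= start:
                continue
        do_split = rng.random() < config.split_prob
        if do_split:
            mid = (start + end) // 2
            left_end = mid - config.split_gap // 2
            right_start = left_end + config.split_gap
            if left_end - start >= 1 and end - right_start >= 1:
                out.append(Interval(iv.chrom, start, left_end))
                out.append(Interval(iv.chrom, right_start, end))
                continue
        out.append(Interval(iv.chrom, start, end))

    if config.background_rate > 0:
        genome_mb = layout.total_size / 1e6
        n_bg = int(rng.poisson(config.background_rate * genome_mb))
        mean, sd = config.peak_width
        ref_by = reference.by_chrom()
        placed_by: dict[str, list[tuple[int, int]]] = {}
        names = layout.names
        attempts = 0
        placed = 0
        while placed < n_bg and attempts < 1000 * max(n_bg, 1):
            attempts += 1
            chrom = names[rng.integers(0, len(names))]
            clen = lengths[chrom]
            w = max(MIN_PEAK_WIDTH, int(round(rng.normal(mean, sd))))
            if w >= clen:
                continue
            start = int(rng.integers(0, clen - w))
            end = start + w
            pad = MIN_PEAK_SEPARATION
            if chrom in ref_by:
                rs, re_ = ref_by[chrom]
                i = np.searchsorted(re_, start - pad, side="right")
                if i < len(rs) and rs[i] < end + pad:
                    continue
            clash = any(
                s < end + pad and e + pad > start
                for s, e in placed_by.get(chrom, [])
            )
            if clash:
                continue
            placed_by.setdefault(chrom, []).append((start, end))
            out.append(Interval(chrom, start, end))
            placed += 1
    return PeakSet.from_intervals(out, label="query", layout=layout)


def simulate_binned_counts(
    peaks: PeakSet,
    layout: GenomeLayout,
    grid: BinGrid,
    enrichment: float,
    depth: int,
    seed: int,
    labels: tuple[str, ...] = ("lib1",),
) -> BinnedCounts:
    """Poisson counts per grid bin: background rate outside peaks, scaled up
    ``enrichment``-fold inside, with the base rate set so each library's
    expected total is ``depth``. Multiple labels give independent replicates
    sharing the same rate field.
    """
    if enrichment <= 0:
        raise ValueError("enrichment must be positive")
    from .genome import merge_adjacent

    merged = merge_adjacent(peaks, gap=0) if len(peaks) else peaks
    by_chrom = merged.by_chrom()
    frac = np.zeros(grid.n_bins)
    chrom_arr = np.asarray(grid.chroms)
    for chrom, (ps, pe) in by_chrom.items():
        mask = chrom_arr == chrom
        bs, be = grid.starts[mask], grid.ends[mask]
        cum = np.concatenate(([0], np.cumsum(pe - ps)))
        i0 = np.searchsorted(pe, bs, side="right")
        i1 = np.searchsorted(ps, be, side="left")
        full = cum[i1] - cum[i0]
        has = i1 > i0
        left = np.zeros(len(bs), dtype=np.int64)
        right = np.zeros(len(bs), dtype=np.int64)
        left[has] = np.maximum(0, bs[has] - ps[i0[has]])
        right[has] = np.maximum(0, pe[i1[has] - 1] - be[has])
        ov = np.where(has, full - left - right, 0)
        frac[mask] = ov / (be - bs)
    weight = 1.0 + (enrichment - 1.0) * frac
    total_weight = weight.sum()
    lam = depth * weight / total_weight if total_weight > 0 else np.zeros_like(weight)
    rng = _rng(seed, "counts")
    counts = np.column_stack([rng.poisson(lam) for _ in labels])
    return BinnedCounts(grid=grid, counts=counts, library_labels=list(labels))


def write_simulation(outdir: str | Path, config: SimulationConfig) -> dict[str, Path]:
    """Generate a full synthetic dataset and write it as plain-text files.

    Emits chrom.sizes, genes.bed (BED6), reference.bed, query.bed,
    counts.tsv, and a manifest.json echoing the configuration. Returns the
    mapping of artifact names to paths. Byte-identical across reruns with
    the same config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout, genes = simulate_genome(config)
    reference = simulate_reference_peaks(genes, layout, config) if genes else PeakSet(
        [], label="reference", sorted=True, chrom_order=layout.names
    )
    query = simulate_query_peaks(reference, layout, config)
    grid = BinGrid(layout)
    counts = simulate_binned_counts(
        reference, layout, grid, enrichment=10.0, depth=config.depth,
        seed=config.seed, labels=("rep1", "rep2"),
    )
    paths = {
        "chrom_sizes": outdir / "chrom.sizes",
        "genes": outdir / "genes.bed",
        "reference": outdir / "reference.bed",
        "query": outdir / "query.bed",
        "counts": outdir / "counts.tsv",
        "manifest": outdir / "manifest.json",
    }
    with open(paths["chrom_sizes"], "w") as fh:
        for name, length in layout.chromosomes:
            fh.write(f"{name}\t{length}\n")
    with open(paths["genes"], "w") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}\n")
    write_bed(reference, paths["reference"])
    write_bed(query, paths["query"])
    with open(paths["counts"], "w") as fh:
        fh.write("chrom\tstart\tend\t" + "\t".join(counts.library_labels) + "\n")
        for i in range(grid.n_bins):
            row = "\t".join(str(int(v)) for v in counts.counts[i])
            fh.write(f"{grid.chroms[i]}\t{grid.starts[i]}\t{grid.ends[i]}\t{row}\n")
    with open(paths["manifest"], "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
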