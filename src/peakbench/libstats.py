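"""Sequencing-library accounting arithmetic.

Covers the per-library bookkeeping around deduplication and depth matching:
the unique non-duplicated percentage (denominator = total reads = 2x read
pairs), the fraction of reads to keep when downsampling to a fixed
uniquely-aligned target, the single-value read-extension midpoint, and the
qPCR amplification-cycle rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rounding import percent_ratio

__all__ = [
    "LibraryCounts",
    "QpcrCurve",
    "percent_unique_nondup",
    "downsample_fraction",
    "extension_midpoint",
    "amplification_cycles",
    "augment_library_table",
]

DEFAULT_TARGET_READS = 3_800_000


@dataclass(frozen=True)
class LibraryCounts:
    """Read-pair / aligned / deduplicated counts for one library."""

    read_pairs: int
    uniquely_aligned: int
    after_dedup: int
    target: int = DEFAULT_TARGET_READS

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.after_dedup > self.uniquely_aligned:
            raise ValueError(
                f"after_dedup ({self.after_dedup}) exceeds "
                f"uniquely_aligned ({self.uniquely_aligned})"
            )


@dataclass(frozen=True)
class QpcrCurve:
    """A qPCR amplification curve: fluorescence sampled at integer cycles."""

    cycles: tuple[int, ...]
    fluorescence: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.cycles) != len(self.fluorescence):
            raise ValueError("cycles and fluorescence must have equal length")
        if len(self.cycles) < 5:
            raise ValueError("a qPCR curve needs at least 5 points")
        if any(b <= a for a, b in zip(self.cycles, self.cycles[1:])):
            raise ValueError("cycles must be strictly increasing")
        if any(f < 0 for f in self.fluorescence):
            raise ValueError("fluorescence must be non-negative")


def percent_unique_nondup(lib: LibraryCounts) -> int:
    """Deduplicated reads as an integer percentage of total reads (2x pairs)."""
    if lib.read_pairs == 0:
        raise ValueError("read_pairs must be > 0")
    return percent_ratio(lib.after_dedup, 2 * lib.read_pairs)


def downsample_fraction(lib: LibraryCounts) -> int:
    """Integer percentage of deduplicated reads to keep to hit the target depth.

    Capped at 100 when the library already holds fewer reads than the target.
    """
    if lib.after_dedup == 0:
        raise ValueError("after_dedup must be > 0")
    return min(100, percent_ratio(lib.target, lib.after_dedup))


def extension_midpoint(min_frag: int, max_frag: int) -> float:
    """Single-value read extension from a fragment size range: min + (max-min)/2."""
    if min_frag > max_frag:
        raise ValueError(f"min_frag ({min_frag}) > max_frag ({max_frag})")
    return min_frag + (max_frag - min_frag) / 2


def amplification_cycles(
    curve: QpcrCurve,
    mode: str = "plateau",
    plateau_slope_frac: float = 0.05,
) -> int:
    """Number of amplification cycles read off a qPCR curve.

    mode="plateau" (default): the smallest measured cycle at which
    fluorescence reaches one third of the plateau fluorescence — the
    practical reading of "1/3 of the amplification curve" that picks a cycle
    in the exponential phase. mode="slope": the smallest cycle whose local
    slope first reaches one third of the maximum slope.

    The plateau is the trailing run of cycles whose slope has dropped below
    ``plateau_slope_frac`` of the maximum slope; a curve that never flattens
    (or never rises) is rejected.
    """
    f = np.asarray(curve.fluorescence, dtype=float)
    c = np.asarray(curve.cycles, dtype=float)
    slopes = np.diff(f) / np.diff(c)
    max_slope = slopes.max()
    if max_slope <= 0:
        raise ValueError("no plateau detected: curve never rises")
    flat = slopes < plateau_slope_frac * max_slope
    if not flat[-1]:
        raise ValueError(
            "no plateau detected: curve still rising at the last cycle "
            f"(final slope {slopes[-1]:.3g} vs max {max_slope:.3g})"
        )
    i = len(flat)
    while i > 0 and flat[i - 1]:
        i -= 1
    plateau_f = float(f[i:].mean())

    if mode == "plateau":
        threshold = plateau_f / 3.0
        idx = np.flatnonzero(f >= threshold)
        if len(idx) == 0:
            raise ValueError("fluorescence never reaches a third of the plateau")
        return int(curve.cycles[idx[0]])
    if mode == "slope":
        threshold = max_slope / 3.0
        idx = np.flatnonzero(slopes >= threshold)
        return int(curve.cycles[idx[0] + 1])
    raise ValueError(f"unknown mode {mode!r}")


_COLMAP = {
    "Read pairs": "read_pairs",
    "Uniquely aligned": "uniquely_aligned",
    "After deduplication": "after_dedup",
}


def augment_library_table(
    table: pd.DataFrame, target: int = DEFAULT_TARGET_READS
) -> pd.DataFrame:
    """Add the derived percentage columns to a library-accounting table.

    Expects 'Read pairs', 'Uniquely aligned' and 'After deduplication'
    columns (thousands separators tolerated); appends '% unique non-dup'
    and '% to keep'.
    """
    missing = [c for c in _COLMAP if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    out = table.copy()
    uniq, keep = [], []
    for _, row in table.iterrows():
        vals = {
            dst: int(str(row[src]).replace(",", "").replace(" ", ""))
            for src, dst in _COLMAP.items()
        }
        lib = LibraryCounts(target=target, **vals)
        uniq.append(percent_unique_nondup(lib))
        keep.append(downsample_fraction(lib))
    out["% unique non-dup"] = uniq
    out["% to keep"] = keep
    return out
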