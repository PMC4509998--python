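"""Sloping-shore profiling and slope statistics.

Flanking CpGs are addressed by their 1-based offset from the island's
outermost base (offset 1 is the first base outside the island, on either
side).  The 2-kb flank on each side is the *shore*, 2-4 kb the *shelf*,
beyond 4 kb the *open sea*.  Shore CpGs are binned (250 bp default, eight
bins across the 2-kb shore) and averaged per island, then across islands.

The slope statistic measures the change in percent methylation over each of
the four 500-bp shore ranges (1-500, 500-1000, 1000-1500, 1500-2000): for a
range (a, b), y1 is the mean per-CpG percent over offsets [a, a+w) and y2
over (b-w, b] with a 10-bp endpoint window w, and slope = y2 - y1.  A range
with an empty endpoint window is not-determined.  Slopes are pooled over all
islands of a class and both sides by default (matching genome-average
curves); a per-island variant is available.

CpGs that fall inside *any* island never contribute to a bin, a slope
window, or a shore difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import CpGIsland
from .io import Methylome

__all__ = [
    "DEFAULT_RANGES",
    "BinStat",
    "ShoreProfile",
    "AggregateProfile",
    "SlopeEntry",
    "SlopeTable",
    "ShoreDiffScore",
    "assign_zone",
    "bin_flanking",
    "shore_profiles",
    "aggregate",
    "compute_slopes",
    "pooled_slopes",
    "shore_difference",
    "rank_shore_differences",
    "island_mask",
]

DEFAULT_RANGES: tuple[tuple[int, int], ...] = (
    (1, 500),
    (500, 1000),
    (1000, 1500),
    (1500, 2000),
)

SHORE_EXTENT = 2000
SHELF_EXTENT = 4000


def assign_zone(offset: int) -> str:
    """shore (1-2000), shelf (2001-4000) or open_sea (>4000) by offset."""
    if offset <= 0:
        raise ValueError(f"offset {offset} is inside the island")
    if offset <= SHORE_EXTENT:
        return "shore"
    if offset <= SHELF_EXTENT:
        return "shelf"
    return "open_sea"


@dataclass(frozen=True)
class BinStat:
    offset_start: int  # bp from the island boundary; bin covers (start, start+width]
    mean_percent: float | None
    n_cpgs: int


@dataclass(frozen=True)
class ShoreProfile:
    """Binned flanking methylation for one island and one side."""

    island: CpGIsland
    side: str  # 'upstream' | 'downstream'
    bin_width: int
    bins: tuple[BinStat, ...]


@dataclass(frozen=True)
class AggregateBin:
    offset_start: int
    grand_mean_percent: float | None
    sem: float | None
    n_islands: int


@dataclass(frozen=True)
class AggregateProfile:
    """Per-bin grand mean across islands, each island weighted equally."""

    bin_width: int
    bins: tuple[AggregateBin, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (b.offset_start, b.grand_mean_percent, b.sem, b.n_islands)
                for b in self.bins
            ],
            columns=["offset_start", "grand_mean_percent", "sem", "n_islands"],
        )


@dataclass(frozen=True)
class SlopeEntry:
    range: tuple[int, int]
    y1: float | None
    y2: float | None
    n1: int
    n2: int

    @property
    def slope(self) -> float | None:
        """% methylation change across the range; None when not determined."""
        if self.y1 is None or self.y2 is None:
            return None
        return self.y2 - self.y1

    @property
    def determined(self) -> bool:
        return self.slope is not None


@dataclass(frozen=True)
class SlopeTable:
    endpoint_window: int
    entries: tuple[SlopeEntry, ...]

    @property
    def ranges(self) -> tuple[tuple[int, int], ...]:
        return tuple(e.range for e in self.entries)

    @property
    def slopes(self) -> tuple[float | None, ...]:
        return tuple(e.slope for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (e.range[0], e.range[1], e.y1, e.y2, e.n1, e.n2, e.slope)
                for e in self.entries
            ],
            columns=["range_start", "range_end", "y1", "y2", "n1", "n2", "slope"],
        )


@dataclass(frozen=True)
class ShoreDiffScore:
    """Signed cumulative per-CpG difference between two methylomes for one shore."""

    island: CpGIsland
    side: str
    cumulative_difference: float | None
    n_common_cpgs: int

    @property
    def mean_difference(self) -> float | None:
        if self.n_common_cpgs == 0 or self.cumulative_difference is None:
            return None
        return self.cumulative_difference / self.n_common_cpgs

    @property
    def determined(self) -> bool:
        return self.n_common_cpgs > 0


# -- helpers ------------------------------------------------------------------


def island_mask(methylome: Methylome, islands: Sequence[CpGIsland]) -> dict[str, np.ndarray]:
    """Boolean in-any-island flag aligned to each chromosome's site arrays."""
    by_chrom: dict[str, list[CpGIsland]] = {}
    for isl in islands:
        by_chrom.setdefault(isl.chrom, []).append(isl)
    masks = {}
    for chrom in methylome.chromosomes():
        pos = methylome.arrays(chrom)["pos"]
        mask = np.zeros(pos.size, dtype=bool)
        for isl in by_chrom.get(chrom, ()):
            lo, hi = np.searchsorted(pos, [isl.start, isl.end])
            mask[lo:hi] = True
        masks[chrom] = mask
    return masks


def _flank_sites(
    methylome: Methylome,
    island: CpGIsland,
    side: str,
    max_offset: int,
    mask: dict[str, np.ndarray] | None,
):
    """(offsets, percents) of flanking CpGs on one side, islands excluded.

    Offsets are 1-based distances from the island's outermost base.
    """
    arr = methylome.arrays(island.chrom)
    pos = arr["pos"]
    if side == "downstream":
        lo, hi = np.searchsorted(pos, [island.end, island.end + max_offset])
        offsets = pos[lo:hi] - island.end + 1
    elif side == "upstream":
        lo, hi = np.searchsorted(pos, [island.start - max_offset, island.start])
        offsets = island.start - pos[lo:hi]
    else:
        raise ValueError(f"side must be 'upstream' or 'downstream', got {side!r}")
    pct = arr["percent"][lo:hi]
    keep = ~np.isnan(pct)
    if mask is not None and island.chrom in mask:
        keep &= ~mask[island.chrom][lo:hi]
    return offsets[keep], pct[keep]


def bin_flanking(
    methylome: Methylome,
    island: CpGIsland,
    all_islands: Sequence[CpGIsland] | None = None,
    flank: int = 5000,
    bin_width: int = 250,
    _mask: dict[str, np.ndarray] | None = None,
) -> tuple[ShoreProfile, ShoreProfile]:
    """Bin flanking CpGs of one island into (upstream, downstream) profiles.

    A CpG at offset d joins bin ceil(d / bin_width); bin k is labelled by its
    starting offset (k-1)*bin_width.  CpGs inside this or any other island
    are excluded; empty bins carry n_cpgs=0 and a None mean.
    """
    if flank % bin_width != 0:
        raise ValueError(f"flank {flank} is not a multiple of bin_width {bin_width}")
    n_bins = flank // bin_width
    if _mask is None:
        _mask = island_mask(methylome, all_islands if all_islands is not None else [island])
    profiles = []
    for side in ("upstream", "downstream"):
        offsets, pct = _flank_sites(methylome, island, side, flank, _mask)
        bin_idx = (offsets - 1) // bin_width  # 0-based bin index
        sums = np.bincount(bin_idx, weights=pct, minlength=n_bins)
        counts = np.bincount(bin_idx, minlength=n_bins)
        bins = tuple(
            BinStat(
                offset_start=k * bin_width,
                mean_percent=(sums[k] / counts[k]) if counts[k] else None,
                n_cpgs=int(counts[k]),
            )
            for k in range(n_bins)
        )
        profiles.append(ShoreProfile(island, side, bin_width, bins))
    return profiles[0], profiles[1]


def shore_profiles(
    methylome: Methylome,
    islands: Sequence[CpGIsland],
    flank: int = 5000,
    bin_width: int = 250,
) -> list[ShoreProfile]:
    """Both-side profiles for many islands, sharing one exclusion mask."""
    mask = island_mask(methylome, islands)
    out = []
    for isl in islands:
        up, down = bin_flanking(
            methylome, isl, flank=flank, bin_width=bin_width, _mask=mask
        )
        out.extend((up, down))
    return out


def aggregate(profiles: Sequence[ShoreProfile]) -> AggregateProfile:
    """Grand mean per bin over islands with >=1 CpG in that bin.

    Each island-side profile is weighted equally; sem = sd / sqrt(n), with
    the n=1 case defined as sem 0.
    """
    if not profiles:
        raise ValueError("no profiles to aggregate")
    widths = {p.bin_width for p in profiles}
    if len(widths) > 1:
        raise ValueError(f"mixed bin widths: {sorted(widths)}")
    n_bins = {len(p.bins) for p in profiles}
    if len(n_bins) > 1:
        raise ValueError("profiles have differing bin counts")
    bin_width = profiles[0].bin_width
    agg = []
    for k in range(n_bins.pop()):
        values = [
            p.bins[k].mean_percent for p in profiles if p.bins[k].n_cpgs > 0
        ]
        n = len(values)
        if n == 0:
            agg.append(AggregateBin(k * bin_width, None, None, 0))
            continue
        mean = float(np.mean(values))
        sem = float(np.std(values, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        agg.append(AggregateBin(k * bin_width, mean, sem, n))
    return AggregateProfile(bin_width, tuple(agg))


def pooled_slopes(
    offsets: np.ndarray,
    percents: np.ndarray,
    ranges: Sequence[tuple[int, int]] = DEFAULT_RANGES,
    endpoint_window: int = 10,
    min_cpgs_per_window: int = 1,
) -> SlopeTable:
    """Slope table from pooled (offset, percent) pairs.

    For range (a, b): y1 averages offsets in [a, a+w), y2 in (b-w, b].
    """
    entries = []
    for a, b in ranges:
        m1 = (offsets >= a) & (offsets < a + endpoint_window)
        m2 = (offsets > b - endpoint_window) & (offsets <= b)
        n1, n2 = int(m1.sum()), int(m2.sum())
        y1 = float(percents[m1].mean()) if n1 >= min_cpgs_per_window else None
        y2 = float(percents[m2].mean()) if n2 >= min_cpgs_per_window else None
        entries.append(SlopeEntry((a, b), y1, y2, n1, n2))
    return SlopeTable(endpoint_window, tuple(entries))


def compute_slopes(
    methylome: Methylome,
    islands: Sequence[CpGIsland],
    endpoint_window: int = 10,
    ranges: Sequence[tuple[int, int]] = DEFAULT_RANGES,
    per_island: bool = False,
    min_cpgs_per_window: int = 1,
    all_islands: Sequence[CpGIsland] | None = None,
):
    """Shore slopes for a set of islands.

    Default mode pools CpGs across all islands and both sides.  With
    ``per_island=True`` a {island: SlopeTable} mapping is returned instead.
    ``all_islands`` supplies the full island set for the exclusion rule when
    *islands* is a subset (e.g. one methylation class).
    """
    exclusion = all_islands if all_islands is not None else islands
    mask = island_mask(methylome, exclusion)
    max_offset = max(b for _, b in ranges)
    if per_island:
        out = {}
        for isl in islands:
            offs, pcts = [], []
            for side in ("upstream", "downstream"):
                o, p = _flank_sites(methylome, isl, side, max_offset, mask)
                offs.append(o)
                pcts.append(p)
            out[isl] = pooled_slopes(
                np.concatenate(offs),
                np.concatenate(pcts),
                ranges,
                endpoint_window,
                min_cpgs_per_window,
            )
        return out
    offs, pcts = [np.empty(0, dtype=np.int64)], [np.empty(0)]
    for isl in islands:
        for side in ("upstream", "downstream"):
            o, p = _flank_sites(methylome, isl, side, max_offset, mask)
            offs.append(o)
            pcts.append(p)
    return pooled_slopes(
        np.concatenate(offs),
        np.concatenate(pcts),
        ranges,
        endpoint_window,
        min_cpgs_per_window,
    )


def shore_difference(
    methylome_a: Methylome,
    methylome_b: Methylome,
    island: CpGIsland,
    side: str,
    all_islands: Sequence[CpGIsland] | None = None,
    shore_extent: int = SHORE_EXTENT,
) -> ShoreDiffScore:
    """Cumulative per-CpG difference (a - b) over one shore (offsets 1-2000).

    Only CpGs covered in *both* methylomes count; zero common CpGs gives a
    not-determined score.
    """
    exclusion = all_islands if all_islands is not None else [island]
    mask_a = island_mask(methylome_a, exclusion)
    off_a, pct_a = _flank_sites(methylome_a, island, side, shore_extent, mask_a)
    mask_b = island_mask(methylome_b, exclusion)
    off_b, pct_b = _flank_sites(methylome_b, island, side, shore_extent, mask_b)
    common, ia, ib = np.intersect1d(off_a, off_b, return_indices=True)
    n = int(common.size)
    if n == 0:
        return ShoreDiffScore(island, side, None, 0)
    cum = float(np.sum(pct_a[ia] - pct_b[ib]))
    return ShoreDiffScore(island, side, cum, n)


def rank_shore_differences(
    methylome_a: Methylome,
    methylome_b: Methylome,
    islands: Sequence[CpGIsland],
    shore_extent: int = SHORE_EXTENT,
) -> pd.DataFrame:
    """All shores ranked by |cumulative difference| (DMR candidate list).

    Not-determined shores sort last.  One row per (island, side).
    """
    rows = []
    for isl in islands:
        for side in ("upstream", "downstream"):
            score = shore_difference(
                methylome_a, methylome_b, isl, side, all_islands=islands,
                shore_extent=shore_extent,
            )
            rows.append(
                {
                    "chrom": isl.chrom,
                    "start": isl.start,
                    "end": isl.end,
                    "side": side,
                    "cumulative_difference": score.cumulative_difference,
                    "n_common_cpgs": score.n_common_cpgs,
                    "mean_difference": score.mean_difference,
                }
            )
    frame = pd.DataFrame(rows)
    frame["abs_cumulative"] = frame["cumulative_difference"].abs()
    frame = frame.sort_values(
        "abs_cumulative", ascending=False, na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    return frame
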