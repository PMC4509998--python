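"""Paired-CGI analysis: pair discovery, typing, and intervening profiles.

A pair is two *adjacent* islands on one chromosome whose edge-to-edge
separation falls in a half-open stratum [min_sep, max_sep); in clusters of
three or more islands, pairing is between nearest neighbours only, so an
island may belong to two pairs.  Pairs are typed low_low / low_high /
high_high from the two islands' methylation classes (orientation
normalised — low_high covers both orders); a pair with an intermediate or
undetermined member falls into 'other'.

The intervening profile bins the CpGs between the two islands by distance
from the left island's right boundary (100-bp bins by default), averaging
per pair and then across pairs, exactly mirroring the shore aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .detect import CpGIsland
from .intervals import interval_gap
from .io import Methylome
from .profiles import CGIMethylation
from .shores import (
    DEFAULT_RANGES,
    AggregateBin,
    AggregateProfile,
    SlopeTable,
    island_mask,
    pooled_slopes,
)

__all__ = [
    "CGIPair",
    "find_pairs",
    "classify_pair",
    "intervening_profile",
    "intervening_slopes",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CGIPair:
    """Two neighbouring islands; ``left`` precedes ``right`` on the chromosome."""

    left: CpGIsland
    right: CpGIsland
    separation: int
    left_class: str | None = None
    right_class: str | None = None

    def __post_init__(self) -> None:
        if self.left.chrom != self.right.chrom:
            raise ValueError("pair members on different chromosomes")
        if self.left.start > self.right.start:
            raise ValueError("left island must precede right island")


def _meth_class_of(value) -> str | None:
    if value is None or isinstance(value, str):
        return value
    if isinstance(value, CGIMethylation):
        return value.meth_class
    raise TypeError(f"cannot read a methylation class from {type(value)}")


def find_pairs(
    islands: Sequence[CpGIsland],
    min_sep: int,
    max_sep: int,
    meth_classes: Mapping[CpGIsland, object] | None = None,
) -> list[CGIPair]:
    """Adjacent-island pairs with min_sep <= separation < max_sep.

    *meth_classes* may map islands to class strings or to
    :class:`CGIMethylation` summaries; when given, the classes are attached
    to the returned pairs so :func:`classify_pair` can type them.
    """
    if min_sep >= max_sep:
        raise ValueError(f"min_sep {min_sep} must be < max_sep {max_sep}")
    by_chrom: dict[str, list[CpGIsland]] = {}
    for isl in islands:
        by_chrom.setdefault(isl.chrom, []).append(isl)
    pairs = []
    for chrom in sorted(by_chrom):
        group = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        for left, right in zip(group, group[1:]):
            sep = interval_gap(left.interval, right.interval)
            if min_sep <= sep < max_sep:
                lc = _meth_class_of(meth_classes.get(left)) if meth_classes else None
                rc = _meth_class_of(meth_classes.get(right)) if meth_classes else None
                pairs.append(CGIPair(left, right, sep, lc, rc))
    return pairs


def classify_pair(pair: CGIPair) -> str:
    """low_low / low_high / high_high from the members' classes, else 'other'.

    An undetermined member (class None) yields 'other' with a warning.
    """
    classes = (pair.left_class, pair.right_class)
    if None in classes:
        logger.warning(
            "pair %s / %s has an undetermined member; classed 'other'",
            pair.left.interval,
            pair.right.interval,
        )
        return "other"
    ordered = tuple(sorted(classes))
    if ordered == ("low", "low"):
        return "low_low"
    if ordered == ("high", "low"):
        return "low_high"
    if ordered == ("high", "high"):
        return "high_high"
    return "other"


def _intervening_sites(pair, methylome, mask):
    """(0-based distances from left island's end, percents) between the islands."""
    arr = methylome.arrays(pair.left.chrom)
    pos = arr["pos"]
    lo, hi = np.searchsorted(pos, [pair.left.end, pair.right.start])
    dist = pos[lo:hi] - pair.left.end
    pct = arr["percent"][lo:hi]
    keep = ~np.isnan(pct)
    if mask is not None and pair.left.chrom in mask:
        keep &= ~mask[pair.left.chrom][lo:hi]
    return dist[keep], pct[keep]


def intervening_profile(
    pairs: Sequence[CGIPair],
    methylome: Methylome,
    bin_width: int = 100,
    all_islands: Sequence[CpGIsland] | None = None,
) -> AggregateProfile:
    """Binned methylation of CpGs between paired islands.

    Bin k covers distances [k*bin_width, (k+1)*bin_width) from the left
    island's right boundary.  Per-pair bin means are averaged across pairs
    with the same equal-weight convention as shore aggregation; bins with no
    contributing pair are not-determined (None mean).
    """
    if not pairs:
        raise ValueError("no pairs given")
    if all_islands is None:
        seen = {}
        for p in pairs:
            seen[(p.left.chrom, p.left.start, p.left.end)] = p.left
            seen[(p.right.chrom, p.right.start, p.right.end)] = p.right
        all_islands = list(seen.values())
    mask = island_mask(methylome, all_islands)
    n_bins = max(-(-p.separation // bin_width) for p in pairs)
    sums = np.zeros(n_bins)
    sq_sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    for pair in pairs:
        dist, pct = _intervening_sites(pair, methylome, mask)
        if dist.size == 0:
            continue
        bin_idx = dist // bin_width
        s = np.bincount(bin_idx, weights=pct, minlength=n_bins)
        c = np.bincount(bin_idx, minlength=n_bins)
        with np.errstate(invalid="ignore"):
            means = np.where(c > 0, s / np.maximum(c, 1), 0.0)
        has = c > 0
        sums[has] += means[has]
        sq_sums[has] += means[has] ** 2
        counts[has] += 1
    bins = []
    for k in range(n_bins):
        n = int(counts[k])
        if n == 0:
            bins.append(AggregateBin(k * bin_width, None, None, 0))
            continue
        mean = sums[k] / n
        if n > 1:
            var = (sq_sums[k] - n * mean**2) / (n - 1)
            sem = float(np.sqrt(max(var, 0.0) / n))
        else:
            sem = 0.0
        bins.append(AggregateBin(k * bin_width, float(mean), sem, n))
    return AggregateProfile(bin_width, tuple(bins))


def intervening_slopes(
    pairs: Sequence[CGIPair],
    methylome: Methylome,
    ranges: Sequence[tuple[int, int]] = DEFAULT_RANGES,
    endpoint_window: int = 10,
    all_islands: Sequence[CpGIsland] | None = None,
) -> SlopeTable:
    """Slopes over the intervening CpGs, pooled across pairs.

    Offsets are 1-based distances from the left island's boundary, with the
    same endpoint-window semantics as shore slopes; ranges that outrun the
    separation simply come back not-determined.
    """
    if all_islands is None:
        all_islands = [p.left for p in pairs] + [p.right for p in pairs]
    mask = island_mask(methylome, all_islands)
    offs, pcts = [np.empty(0, dtype=np.int64)], [np.empty(0)]
    for pair in pairs:
        dist, pct = _intervening_sites(pair, methylome, mask)
        offs.append(dist + 1)
        pcts.append(pct)
    return pooled_slopes(
        np.concatenate(offs), np.concatenate(pcts), ranges, endpoint_window
    )
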