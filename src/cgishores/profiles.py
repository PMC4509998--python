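"""Per-CpG and per-CGI methylation levels and the island classifications.

A CGI's methylation level is the unweighted mean of the per-CpG percent
values over its covered CpGs (robust to coverage heterogeneity; a
read-pooled variant is available).  Islands are "low" below 20% mean
methylation, "high" above 80%, and "intermediate" otherwise — the strict
inequalities place exactly 20.0 and 80.0 in the intermediate class.
Islands are "paired" when another island lies within 10 kb (edge-to-edge),
else "single".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .detect import CpGIsland
from .intervals import interval_gap
from .io import Methylome

__all__ = [
    "CGIMethylation",
    "percent_methylation",
    "classify_meth",
    "cgi_methylation",
    "classify_islands",
    "classify_neighbor",
    "assign_future_class",
    "LOW_THRESHOLD",
    "HIGH_THRESHOLD",
]

logger = logging.getLogger(__name__)

LOW_THRESHOLD = 20.0
HIGH_THRESHOLD = 80.0


def percent_methylation(n_meth: int, n_unmeth: int) -> float:
    """100 * n_meth / (n_meth + n_unmeth); zero coverage is an error."""
    if n_meth < 0 or n_unmeth < 0:
        raise ValueError("counts must be non-negative")
    coverage = n_meth + n_unmeth
    if coverage == 0:
        raise ValueError("percent methylation undefined at zero coverage")
    return 100.0 * n_meth / coverage


def classify_meth(
    mean_percent: float,
    low: float = LOW_THRESHOLD,
    high: float = HIGH_THRESHOLD,
) -> str:
    """'low' (< low), 'high' (> high) or 'intermediate' (boundaries included)."""
    if not 0.0 <= mean_percent <= 100.0:
        raise ValueError(f"mean_percent out of [0, 100]: {mean_percent}")
    if mean_percent < low:
        return "low"
    if mean_percent > high:
        return "high"
    return "intermediate"


@dataclass(frozen=True)
class CGIMethylation:
    """Methylation summary of one island.

    ``meth_class`` is None when the island is not-determined (fewer covered
    CpGs than ``min_cpgs``); not-determined is a value, not an error.
    """

    island: CpGIsland
    mean_percent: float | None
    n_cpgs: int
    mean_coverage: float
    meth_class: str | None
    neighbor_class: str | None = None

    @property
    def determined(self) -> bool:
        return self.meth_class is not None


def cgi_methylation(
    methylome: Methylome,
    island: CpGIsland,
    min_cpgs: int = 3,
    weighted: bool = False,
    low: float = LOW_THRESHOLD,
    high: float = HIGH_THRESHOLD,
) -> CGIMethylation:
    """Summarise one island's CpGs in one methylome.

    With ``weighted=True`` the level pools read counts instead of averaging
    per-CpG percents.
    """
    if min_cpgs < 1:
        raise ValueError("min_cpgs must be >= 1")
    sites = methylome.in_range(island.chrom, island.start, island.end)
    covered = sites["coverage"] > 0
    n_cpgs = int(covered.sum())
    mean_cov = float(sites["coverage"][covered].mean()) if n_cpgs else 0.0
    if n_cpgs < min_cpgs:
        return CGIMethylation(island, None, n_cpgs, mean_cov, None)
    if weighted:
        mean_percent = float(
            100.0 * sites["n_meth"][covered].sum() / sites["coverage"][covered].sum()
        )
    else:
        mean_percent = float(np.mean(sites["percent"][covered]))
    return CGIMethylation(
        island, mean_percent, n_cpgs, mean_cov, classify_meth(mean_percent, low, high)
    )


def classify_islands(
    methylome: Methylome,
    islands: Sequence[CpGIsland],
    min_cpgs: int = 3,
    neighbor_window: int = 10_000,
    **kwargs,
) -> dict[CpGIsland, CGIMethylation]:
    """Methylation summary plus single/paired status for every island."""
    neighbors = classify_neighbor(islands, window=neighbor_window)
    out = {}
    for isl in islands:
        summary = cgi_methylation(methylome, isl, min_cpgs=min_cpgs, **kwargs)
        out[isl] = CGIMethylation(
            isl,
            summary.mean_percent,
            summary.n_cpgs,
            summary.mean_coverage,
            summary.meth_class,
            neighbor_class=neighbors[isl],
        )
    return out


def classify_neighbor(
    islands: Sequence[CpGIsland], window: int = 10_000
) -> dict[CpGIsland, str]:
    """'paired' iff another island's edge-to-edge gap is < window, else 'single'."""
    by_chrom: dict[str, list[CpGIsland]] = {}
    for isl in islands:
        by_chrom.setdefault(isl.chrom, []).append(isl)
    out = {}
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda i: (i.start, i.end))
        for i, isl in enumerate(group):
            paired = False
            if i > 0 and interval_gap(group[i - 1].interval, isl.interval) < window:
                paired = True
            if (
                i + 1 < len(group)
                and interval_gap(isl.interval, group[i + 1].interval) < window
            ):
                paired = True
            out[isl] = "paired" if paired else "single"
    return out


def assign_future_class(
    islands: Sequence[CpGIsland],
    terminal_methylome: Methylome,
    min_cpgs: int = 3,
) -> dict[CpGIsland, str]:
    """Mark islands by their class in the terminal (latest) methylome.

    future_low/future_high mirror low/high in the terminal methylome;
    intermediate or not-determined islands become 'other' (not-determined
    ones are counted in a warning).
    """
    out = {}
    n_undetermined = 0
    for isl in islands:
        summary = cgi_methylation(terminal_methylome, isl, min_cpgs=min_cpgs)
        if not summary.determined:
            n_undetermined += 1
            out[isl] = "other"
        elif summary.meth_class == "low":
            out[isl] = "future_low"
        elif summary.meth_class == "high":
            out[isl] = "future_high"
        else:
            out[isl] = "other"
    if n_undetermined:
        logger.warning(
            "%d island(s) not determined in terminal methylome %r; assigned 'other'",
            n_undetermined,
            terminal_methylome.label,
        )
    return out
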