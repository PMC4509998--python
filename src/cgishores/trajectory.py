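"""Shore dynamics across an ordered methylome series (reprogramming).

Islands are labelled future_low / future_high from their class in a
designated *terminal* methylome (e.g. the last developmental time point),
then shore profiles and slope tables are computed for each class at every
time point.  Slope fold-changes between consecutive time points quantify the
flattening and re-steepening of the shores as the genome-wide methylation
level falls and rises; a fold-change is only reported when both slopes are
determined and the denominator magnitude clears a floor, since ratios of
near-zero slopes are unstable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .detect import CpGIsland
from .io import Methylome
from .profiles import assign_future_class, cgi_methylation
from .shores import (
    DEFAULT_RANGES,
    AggregateProfile,
    SlopeTable,
    aggregate,
    compute_slopes,
    shore_profiles,
)

__all__ = [
    "TrajectorySeries",
    "TrajectoryResult",
    "run_trajectory",
    "slope_fold_change",
]

FUTURE_CLASSES = ("future_low", "future_high")


@dataclass(frozen=True)
class TrajectorySeries:
    """Ordered (label, methylome) time points; terminal_index names the
    methylome that defines the future classes (default: the last)."""

    timepoints: tuple[tuple[str, Methylome], ...]
    terminal_index: int = -1

    def __post_init__(self) -> None:
        if len(self.timepoints) < 2:
            raise ValueError("a trajectory needs at least 2 time points")
        n = len(self.timepoints)
        idx = self.terminal_index
        if not -n <= idx < n:
            raise ValueError(f"terminal_index {idx} out of range for {n} time points")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(label for label, _ in self.timepoints)

    @property
    def terminal(self) -> tuple[str, Methylome]:
        return self.timepoints[self.terminal_index]


def slope_fold_change(
    slope_a: float | None, slope_b: float | None, floor: float = 0.5
) -> float | None:
    """slope_b / slope_a, or None when either is undetermined or |slope_a| < floor."""
    if slope_a is None or slope_b is None:
        return None
    if abs(slope_a) < floor:
        return None
    return slope_b / slope_a


@dataclass
class TrajectoryResult:
    """Per-(future class, time point) profiles, slopes and island means."""

    future_classes: dict[CpGIsland, str]
    labels: tuple[str, ...]
    profiles: dict[tuple[str, str], AggregateProfile] = field(default_factory=dict)
    slopes: dict[tuple[str, str], SlopeTable] = field(default_factory=dict)
    island_means: dict[tuple[str, str], float | None] = field(default_factory=dict)
    fold_changes: dict[tuple[str, tuple[int, int]], list] = field(default_factory=dict)
    n_unclassified: int = 0
    undetermined_counts: dict[str, int] = field(default_factory=dict)

    def islands_of(self, future_class: str) -> list[CpGIsland]:
        return [i for i, c in self.future_classes.items() if c == future_class]


def run_trajectory(
    series: TrajectorySeries,
    islands: Sequence[CpGIsland],
    flank: int = 5000,
    bin_width: int = 250,
    min_cpgs: int = 3,
    endpoint_window: int = 10,
    ranges: Sequence[tuple[int, int]] = DEFAULT_RANGES,
    fold_floor: float = 0.5,
) -> TrajectoryResult:
    """Trace future_low / future_high shore behaviour through the series.

    Future classes are a function of the terminal methylome only;
    intermediate or undetermined islands are excluded from both groups.
    For every time point the per-class aggregate shore profile, pooled slope
    table and mean island-body methylation are computed, plus slope
    fold-changes between consecutive time points per range.
    """
    _, terminal_methylome = series.terminal
    classes = assign_future_class(islands, terminal_methylome, min_cpgs=min_cpgs)
    result = TrajectoryResult(
        future_classes=classes,
        labels=series.labels,
        n_unclassified=sum(1 for c in classes.values() if c == "other"),
    )
    groups = {fc: result.islands_of(fc) for fc in FUTURE_CLASSES}
    for label, methylome in series.timepoints:
        undetermined = 0
        for fc, group in groups.items():
            key = (fc, label)
            if not group:
                result.island_means[key] = None
                continue
            profiles = shore_profiles(methylome, group, flank=flank, bin_width=bin_width)
            covered = [p for p in profiles if any(b.n_cpgs for b in p.bins)]
            if covered:
                result.profiles[key] = aggregate(covered)
            result.slopes[key] = compute_slopes(
                methylome,
                group,
                endpoint_window=endpoint_window,
                ranges=ranges,
                all_islands=islands,
            )
            summaries = [cgi_methylation(methylome, i, min_cpgs=min_cpgs) for i in group]
            det = [s.mean_percent for s in summaries if s.determined]
            undetermined += sum(1 for s in summaries if not s.determined)
            result.island_means[key] = (
                sum(det) / len(det) if det else None
            )
        result.undetermined_counts[label] = undetermined
    for fc in FUTURE_CLASSES:
        for rng in ranges:
            changes = []
            for (la, _), (lb, _) in zip(series.timepoints, series.timepoints[1:]):
                sa = _slope_at(result.slopes.get((fc, la)), rng)
                sb = _slope_at(result.slopes.get((fc, lb)), rng)
                changes.append((la, lb, slope_fold_change(sa, sb, floor=fold_floor)))
            result.fold_changes[(fc, rng)] = changes
    return result


def _slope_at(table: SlopeTable | None, rng: tuple[int, int]) -> float | None:
    if table is None:
        return None
    for entry in table.entries:
        if entry.range == rng:
            return entry.slope
    return None
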