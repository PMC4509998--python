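"""Genomic-interval primitives.

Every coordinate in this package is 0-based, half-open (BED convention):
an interval covers positions ``start .. end-1`` and ``length == end - start``.
"""

from __future__ import annotations

from dataclasses import dataclass

REPEAT_CLASSES = frozenset(
    {"SINE", "LINE", "LTR", "DNA", "simple", "low_complexity", "other"}
)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        """True if *other* lies entirely within this interval."""
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class RepeatAnnotation:
    """A RepeatMasker-style repeat interval with a coarse class label."""

    interval: GenomicInterval
    repeat_class: str = "other"

    def __post_init__(self) -> None:
        if self.repeat_class not in REPEAT_CLASSES:
            raise ValueError(
                f"repeat_class {self.repeat_class!r} not in {sorted(REPEAT_CLASSES)}"
            )


def interval_gap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Edge-to-edge gap in bp between two intervals on one chromosome.

    Adjacent or overlapping intervals have gap 0.  Symmetric in its
    arguments; intervals on different chromosomes are an error.
    """
    if a.chrom != b.chrom:
        raise ValueError(f"intervals on different chromosomes: {a.chrom} vs {b.chrom}")
    left, right = (a, b) if a.start <= b.start else (b, a)
    return max(0, right.start - left.end)


def sort_intervals(intervals):
    """Sort by (chrom, start, end)."""
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
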