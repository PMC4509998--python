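"""CpG-island detection and repeat classification.

Islands are found by maximal-scoring-segment scanning of the nucleotide
sequence: every CpG dinucleotide rewards the running score (+17 by default)
and every other position penalises it (-1), and the reported islands are the
Ruzzo–Tompa maximal scoring subsequences of that score sequence with segment
score >= ``min_score``.  This is the classic "cpgseek" scanner family scheme;
the constants are configurable.  Each reported island carries the
Gardiner-Garden statistics (GC fraction and observed/expected CpG ratio) of
its sequence so the canonical >50% GC / >0.6 O/E criteria can be applied
downstream.

Unique-vs-repeat classification compares islands detected on a repeat-masked
genome with those from the unmasked twin: an unmasked island is "unique" only
if a masked island with *identical* coordinates exists.  Repeat islands are
then typed by how RepeatMasker repeats overlap them (types 1-4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .intervals import GenomicInterval, RepeatAnnotation
from .io import ValidationError

__all__ = [
    "CpGIsland",
    "RepeatTypeResult",
    "REPEAT_CGI_TYPES",
    "score_segments",
    "gardiner_garden_stats",
    "filter_islands",
    "classify_unique_repeat",
    "classify_repeat_type",
    "detect_islands",
]

REPEAT_CGI_TYPES = ("type1", "type2", "type3", "type4")

_VALID = frozenset(b"ACGTN")


@dataclass(frozen=True)
class CpGIsland:
    """A detected CGI segment with its scan score and composition stats."""

    interval: GenomicInterval
    score: int
    gc_fraction: float
    obs_exp_ratio: float
    source: str = "unmasked"

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


def gardiner_garden_stats(sequence: str, interval: GenomicInterval | None = None):
    """GC fraction and observed/expected CpG ratio of a sequence window.

    gc = (#C + #G) / L; O/E = (#CpG * L) / (#C * #G), 0 when #C*#G == 0.
    CpG dinucleotides are counted at every position i, i+1 (they can never
    overlap one another).
    """
    if interval is not None:
        sequence = sequence[interval.start : interval.end]
    sequence = sequence.upper()
    length = len(sequence)
    if length == 0:
        raise ValueError("zero-length interval")
    n_c = sequence.count("C")
    n_g = sequence.count("G")
    n_cg = sequence.count("CG")
    gc_fraction = (n_c + n_g) / length
    if n_c * n_g == 0:
        return gc_fraction, 0.0
    return gc_fraction, n_cg * length / (n_c * n_g)


def _tokenize(arr: np.ndarray, cg_reward: int, per_base_penalty: int):
    """Collapse the base array into scan tokens.

    A CG dinucleotide becomes one token of score +cg_reward spanning 2 bases;
    every other position is one token of score -per_base_penalty.  N never
    forms a CpG and is penalised like any other base, so masked regions
    cannot seed islands.
    """
    n = arr.size
    cg = np.zeros(n, dtype=bool)
    if n > 1:
        cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    consumed = np.zeros(n, dtype=bool)
    consumed[1:] = cg[:-1]
    keep = ~consumed
    tok_base = np.flatnonzero(keep)
    is_cg = cg[keep]
    tok_score = np.where(is_cg, cg_reward, -per_base_penalty).astype(np.int64)
    tok_span = np.where(is_cg, 2, 1).astype(np.int64)
    return tok_base, tok_score, tok_span


def _maximal_token_segments(tok_score: np.ndarray) -> list[tuple[int, int, int]]:
    """Ruzzo-Tompa all-maximal-scoring-subsequences over token scores.

    Returns (start_token, end_token, score) triples, left to right.
    """
    cum = np.concatenate(([0], np.cumsum(tok_score)))
    # entries [start_tok, end_tok, L, R, ps]; ps is the stack index of the
    # nearest earlier entry with a smaller L-value (-1 if none), so the
    # backward search hops a strictly-decreasing-L chain in amortized O(1)
    # instead of scanning the list
    stack: list[list[int]] = []
    for t in np.flatnonzero(tok_score > 0):
        s, e = int(t), int(t) + 1
        L, R = int(cum[t]), int(cum[t + 1])
        j = len(stack) - 1
        while True:
            while j >= 0 and stack[j][2] >= L:
                j = stack[j][4]
            if j < 0 or stack[j][3] >= R:
                stack.append([s, e, L, R, j])
                break
            # merge: absorb stack[j:] into the growing subsequence
            s, L, ps = stack[j][0], stack[j][2], stack[j][4]
            del stack[j:]
            j = ps
    return [(s, e, R - L) for s, e, L, R, _ in stack]


def score_segments(
    sequence: str,
    cg_reward: int = 17,
    per_base_penalty: int = 1,
    min_score: int = 17,
    chrom: str = "seq",
    source: str = "unmasked",
) -> list[CpGIsland]:
    """Scan one sequence for CpG islands.

    Returns non-overlapping maximal-scoring segments with score >= min_score,
    annotated with Gardiner-Garden statistics.  Empty sequence yields an
    empty list; symbols outside {A,C,G,T,N} are a validation error.
    """
    if cg_reward <= 0 or per_base_penalty <= 0:
        raise ValueError("cg_reward and per_base_penalty must be positive")
    sequence = sequence.upper()
    if not sequence:
        return []
    arr = np.frombuffer(sequence.encode("ascii", errors="strict"), dtype=np.uint8)
    bad = ~np.isin(arr, np.frombuffer(b"ACGTN", dtype=np.uint8))
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise ValidationError(f"invalid symbol {sequence[pos]!r} at position {pos}")
    tok_base, tok_score, tok_span = _tokenize(arr, cg_reward, per_base_penalty)
    islands = []
    for s_tok, e_tok, score in _maximal_token_segments(tok_score):
        if score < min_score:
            continue
        start = int(tok_base[s_tok])
        end = int(tok_base[e_tok - 1] + tok_span[e_tok - 1])
        iv = GenomicInterval(chrom, start, end)
        gc, oe = gardiner_garden_stats(sequence, iv)
        islands.append(CpGIsland(iv, score, gc, oe, source=source))
    return islands


def detect_islands(
    sequences: Mapping[str, str],
    cg_reward: int = 17,
    per_base_penalty: int = 1,
    min_score: int = 17,
    min_length: int = 200,
    source: str = "unmasked",
) -> list[CpGIsland]:
    """Scan every contig of a genome and apply the length filter."""
    islands: list[CpGIsland] = []
    for chrom in sequences:
        islands.extend(
            score_segments(
                sequences[chrom],
                cg_reward=cg_reward,
                per_base_penalty=per_base_penalty,
                min_score=min_score,
                chrom=chrom,
                source=source,
            )
        )
    return filter_islands(islands, min_length=min_length)


def filter_islands(islands: Iterable[CpGIsland], min_length: int = 200) -> list[CpGIsland]:
    """Retain islands of length >= min_length (the >=200 bp protocol filter)."""
    return [isl for isl in islands if isl.length >= min_length]


def classify_unique_repeat(
    masked_islands: Sequence[CpGIsland], unmasked_islands: Sequence[CpGIsland]
) -> dict[CpGIsland, str]:
    """Classify unmasked-genome islands as unique vs repeat-associated.

    An island is "unique" iff a masked-genome island exists with identical
    start and end coordinates; any coordinate difference, or absence from the
    masked set, makes it "repeat".
    """
    for name, group in (("masked", masked_islands), ("unmasked", unmasked_islands)):
        coords = [(i.chrom, i.start, i.end) for i in group]
        if len(coords) != len(set(coords)):
            raise ValidationError(f"duplicate island coordinates in {name} set")
    masked_coords = {(i.chrom, i.start, i.end) for i in masked_islands}
    return {
        isl: ("unique" if (isl.chrom, isl.start, isl.end) in masked_coords else "repeat")
        for isl in unmasked_islands
    }


@dataclass(frozen=True)
class RepeatTypeResult:
    """Repeat-CGI type plus the classes of the repeats involved."""

    repeat_type: str
    repeat_classes: tuple[str, ...] = field(default_factory=tuple)


def classify_repeat_type(
    island: CpGIsland, repeats: Sequence[RepeatAnnotation]
) -> RepeatTypeResult:
    """Type a repeat-associated CGI by its repeat overlap geometry.

    type1: island fully inside a repeat; type2: partial boundary overlap
    only; type3: fully-contained repeat(s) only; type4: both a contained
    repeat and a partial boundary overlap.  Overlap is decided on half-open
    intervals; an island with no overlapping repeat is inconsistent with its
    "repeat" classification and raises ValueError.
    """
    iv = island.interval
    overlapping = [r for r in repeats if r.interval.overlaps(iv)]
    if not overlapping:
        raise ValueError(f"island {iv} has no overlapping repeat")
    classes = tuple(r.repeat_class for r in overlapping)
    if any(r.interval.contains(iv) for r in overlapping):
        return RepeatTypeResult("type1", classes)
    contained = [r for r in overlapping if iv.contains(r.interval)]
    partial = [
        r
        for r in overlapping
        if not iv.contains(r.interval) and not r.interval.contains(iv)
    ]
    if contained and partial:
        return RepeatTypeResult("type4", classes)
    if partial:
        return RepeatTypeResult("type2", classes)
    return RepeatTypeResult("type3", classes)
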