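"""Readers and writers for methylomes, BED intervals and FASTA.

The native methylome format is a 4-column tab-separated count table:

    chrom <TAB> pos <TAB> n_meth <TAB> n_unmeth

``pos`` is the 0-based position of the C of a CpG on the plus strand.
Counts are bisulfite observations: ``n_meth`` reads reported C (methylated),
``n_unmeth`` reported T (unmethylated).  A Bismark-coverage-style 6-column
dialect is importable; its precomputed percentage column is ignored because
the counts are the primary datum.
"""

from __future__ import annotations

import io as _io
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, RepeatAnnotation

__all__ = [
    "Methylome",
    "MethylomeParseError",
    "ValidationError",
    "read_methylome",
    "read_bismark_coverage",
    "write_methylome",
    "read_intervals_bed",
    "write_intervals_bed",
    "read_repeats_bed",
    "read_fasta",
    "write_fasta",
]


class MethylomeParseError(ValueError):
    """A malformed row in a methylome table (message names the line)."""


class ValidationError(ValueError):
    """Input that parses but violates an invariant (e.g. duplicate site)."""


_METH_COLUMNS = ("chrom", "pos", "n_meth", "n_unmeth")


class Methylome:
    """Per-CpG bisulfite counts for one sample, indexed by (chrom, pos).

    Internally sites are held per chromosome as sorted numpy arrays so that
    range queries (shore windows, island interiors) are O(log n).  Percent
    methylation is 100 * n_meth / (n_meth + n_unmeth); sites with zero
    coverage carry NaN and are normally filtered out at read time.
    """

    def __init__(self, frame: pd.DataFrame, label: str = ""):
        missing = [c for c in _METH_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"methylome frame missing columns {missing}")
        frame = frame.loc[:, list(_METH_COLUMNS)].copy()
        frame["pos"] = frame["pos"].astype(np.int64)
        frame["n_meth"] = frame["n_meth"].astype(np.int64)
        frame["n_unmeth"] = frame["n_unmeth"].astype(np.int64)
        if (frame["pos"] < 0).any():
            raise ValidationError("negative position in methylome")
        if (frame[["n_meth", "n_unmeth"]] < 0).any().any():
            raise ValidationError("negative count in methylome")
        if frame.duplicated(subset=["chrom", "pos"]).any():
            dup = frame[frame.duplicated(subset=["chrom", "pos"], keep=False)]
            site = dup.iloc[0]
            raise ValidationError(
                f"duplicate methylome site {site['chrom']}:{site['pos']}"
            )
        frame = frame.sort_values(["chrom", "pos"], kind="mergesort")
        frame = frame.reset_index(drop=True)
        self.label = label
        self._frame = frame
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        for chrom, sub in frame.groupby("chrom", sort=True):
            pos = sub["pos"].to_numpy()
            nm = sub["n_meth"].to_numpy()
            nu = sub["n_unmeth"].to_numpy()
            cov = nm + nu
            with np.errstate(invalid="ignore", divide="ignore"):
                pct = np.where(cov > 0, 100.0 * nm / np.maximum(cov, 1), np.nan)
            self._by_chrom[str(chrom)] = {
                "pos": pos,
                "n_meth": nm,
                "n_unmeth": nu,
                "coverage": cov,
                "percent": pct,
            }

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_arrays(cls, chrom, pos, n_meth, n_unmeth, label=""):
        """Build from parallel arrays for a single chromosome."""
        frame = pd.DataFrame(
            {
                "chrom": np.repeat(chrom, len(pos)) if np.isscalar(chrom) else chrom,
                "pos": np.asarray(pos),
                "n_meth": np.asarray(n_meth),
                "n_unmeth": np.asarray(n_unmeth),
            }
        )
        return cls(frame, label=label)

    @classmethod
    def from_records(cls, records: Iterable[tuple], label=""):
        """Build from (chrom, pos, n_meth, n_unmeth) tuples."""
        frame = pd.DataFrame(list(records), columns=list(_METH_COLUMNS))
        return cls(frame, label=label)

    # -- queries --------------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self._frame)

    def chromosomes(self) -> list[str]:
        return list(self._by_chrom)

    def arrays(self, chrom: str) -> dict[str, np.ndarray]:
        """Sorted site arrays for one chromosome (empty arrays if absent)."""
        if chrom in self._by_chrom:
            return self._by_chrom[chrom]
        empty = np.empty(0, dtype=np.int64)
        return {
            "pos": empty,
            "n_meth": empty,
            "n_unmeth": empty,
            "coverage": empty,
            "percent": np.empty(0, dtype=float),
        }

    def in_range(self, chrom: str, start: int, end: int) -> dict[str, np.ndarray]:
        """Sites with start <= pos < end, as array views."""
        arr = self.arrays(chrom)
        lo, hi = np.searchsorted(arr["pos"], [start, end])
        return {k: v[lo:hi] for k, v in arr.items()}

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def filter_coverage(self, min_coverage: int) -> "Methylome":
        cov = self._frame["n_meth"] + self._frame["n_unmeth"]
        return Methylome(self._frame[cov >= min_coverage], label=self.label)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Methylome):
            return NotImplemented
        return self._frame.equals(other._frame)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Methylome(label={self.label!r}, n_sites={self.n_sites})"

    def write(self, path, header: bool = True) -> None:
        write_methylome(self, path, header=header)


def _has_header(first_fields: Sequence[str]) -> bool:
    if len(first_fields) < 2:
        return True
    try:
        int(first_fields[1])
    except ValueError:
        return True
    return False


def read_methylome(path, min_coverage: int = 1, label: str | None = None) -> Methylome:
    """Read a native 4-column methylome table.

    Sites with coverage below *min_coverage* are dropped.  Malformed rows
    raise :class:`MethylomeParseError` naming the offending line; duplicate
    (chrom, pos) rows raise :class:`ValidationError`.
    """
    with open(path, "rt") as fh:
        text = fh.read()
    lines = text.splitlines()
    start_line = 1
    if lines and _has_header(lines[0].split("\t")):
        lines = lines[1:]
        start_line = 2
    records = []
    for offset, line in enumerate(lines):
        if not line.strip():
            continue
        fields = line.split("\t")
        lineno = start_line + offset
        if len(fields) < 4:
            raise MethylomeParseError(
                f"line {lineno}: expected 4 tab-separated fields, got {len(fields)}"
            )
        try:
            pos, nm, nu = int(fields[1]), int(fields[2]), int(fields[3])
        except ValueError as exc:
            raise MethylomeParseError(f"line {lineno}: non-integer field ({exc})") from exc
        if pos < 0 or nm < 0 or nu < 0:
            raise MethylomeParseError(f"line {lineno}: negative value")
        records.append((fields[0], pos, nm, nu))
    frame = pd.DataFrame(records, columns=list(_METH_COLUMNS))
    meth = Methylome(frame, label=label if label is not None else str(path))
    return meth.filter_coverage(min_coverage)


def read_bismark_coverage(
    path, min_coverage: int = 1, label: str | None = None, merge_adjacent: bool = True
) -> Methylome:
    """Import a Bismark-coverage-style table.

    Expected columns: chrom, start (1-based), end, percent, n_meth, n_unmeth.
    The precomputed percent column is ignored.  With *merge_adjacent*, records
    at consecutive positions (the two strands of one CpG dyad) are pooled onto
    the plus-strand C position; strand merging is this package's convention
    since CpG methylation is symmetric.
    """
    frame = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "percent", "n_meth", "n_unmeth"],
        dtype={"chrom": str},
    )
    frame["pos"] = frame["start"].astype(np.int64) - 1
    frame = frame.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    if merge_adjacent and len(frame) > 1:
        same_chrom = frame["chrom"].shift(-1) == frame["chrom"]
        adjacent = (frame["pos"].shift(-1) == frame["pos"] + 1) & same_chrom
        drop = adjacent.shift(1, fill_value=False) & ~adjacent
        partner = adjacent & ~adjacent.shift(1, fill_value=False)
        nm = frame["n_meth"].to_numpy().copy()
        nu = frame["n_unmeth"].to_numpy().copy()
        idx = np.flatnonzero(partner.to_numpy())
        nm[idx] += nm[idx + 1]
        nu[idx] += nu[idx + 1]
        frame["n_meth"] = nm
        frame["n_unmeth"] = nu
        frame = frame[~drop.to_numpy()]
    meth = Methylome(frame[["chrom", "pos", "n_meth", "n_unmeth"]],
                     label=label if label is not None else str(path))
    return meth.filter_coverage(min_coverage)


def write_methylome(methylome: Methylome, path, header: bool = True) -> None:
    """Write the native 4-column table, sorted by (chrom, pos)."""
    frame = methylome.to_frame()
    with open(path, "wt", newline="\n") as fh:
        frame.to_csv(fh, sep="\t", index=False, header=header, lineterminator="\n")


# -- BED ----------------------------------------------------------------------


def read_intervals_bed(path) -> list[GenomicInterval]:
    """Read a BED3+ file into intervals (extra columns are ignored)."""
    intervals = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MethylomeParseError(
                    f"line {lineno}: BED needs >= 3 fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise MethylomeParseError(f"line {lineno}: non-integer coordinate") from exc
            try:
                intervals.append(GenomicInterval(fields[0], start, end))
            except ValueError as exc:
                raise ValidationError(f"line {lineno}: {exc}") from exc
    return intervals


def write_intervals_bed(intervals, path, names=None, extra_columns=None) -> None:
    """Write BED3 (+ optional name and extra columns), in sorted order."""
    rows = []
    for i, iv in enumerate(intervals):
        row = [iv.chrom, str(iv.start), str(iv.end)]
        if names is not None:
            row.append(str(names[i]))
        if extra_columns is not None:
            row.extend(str(x) for x in extra_columns[i])
        rows.append((iv.chrom, iv.start, iv.end, row))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "wt", newline="\n") as fh:
        for *_, row in rows:
            fh.write("\t".join(row) + "\n")


_REPEAT_PREFIX = {
    "SINE": "SINE",
    "LINE": "LINE",
    "LTR": "LTR",
    "DNA": "DNA",
    "Simple_repeat": "simple",
    "simple": "simple",
    "Low_complexity": "low_complexity",
    "low_complexity": "low_complexity",
}


def read_repeats_bed(path) -> list[RepeatAnnotation]:
    """Read a BED4 of RepeatMasker repeats; name column holds the class.

    RepeatMasker family strings like ``SINE/Alu`` map on their leading token;
    unrecognised labels fall back to ``other``.
    """
    repeats = []
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise MethylomeParseError(f"line {lineno}: repeat BED needs 4 fields")
            iv = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
            key = fields[3].split("/")[0]
            repeats.append(RepeatAnnotation(iv, _REPEAT_PREFIX.get(key, "other")))
    return repeats


# -- FASTA --------------------------------------------------------------------


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    from pyfaidx import Fasta

    fa = Fasta(str(path), rebuild=True, build_index=True)
    try:
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
    finally:
        fa.close()


def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "wt", newline="\n") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
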