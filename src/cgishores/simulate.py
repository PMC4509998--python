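"""Synthetic genomes and single-base WGBS methylomes with ground truth.

The generator emits three linked artifacts: (1) a genome sequence with a
CpG-depleted background and implanted CpG-rich islands (optionally with
repeat annotations and a repeat-masked twin); (2) per-CpG bisulfite count
tables with a configurable noise model; (3) a truth manifest recording every
island's position, class and shore parameters, so recovery tests can compare
pipeline output against what was simulated.

Methylation model, per CpG: a true probability p comes from the island level
inside islands, the genomic plateau in the open sea, and a shore model
(linear ramp by default, logistic or flat available) within ``ramp_length``
of an island boundary.  Counts are the standard minimal WGBS model:
coverage n ~ Poisson(lambda) (zero-coverage sites omitted) and
n_meth ~ Binomial(n, p).

Crosstalk switch: OFF means a CpG in reach of several islands takes the
isolated shore value of the *nearest* island; ON combines the islands'
influences as independent protection events, p = plateau * prod(p_i/plateau),
so two overlapping hypomethylated shores depress intervening CpGs below
either single-island value — the direction the crosstalk analyses probe.

Everything is deterministic for a fixed seed (numpy PCG64 seeded from the
config seed plus a fixed stream key per artifact).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .detect import CpGIsland
from .intervals import GenomicInterval, RepeatAnnotation
from .io import Methylome

__all__ = [
    "IslandSpec",
    "PairSpec",
    "RepeatSpec",
    "SimulationConfig",
    "TrueIsland",
    "SimTruth",
    "SimulatedGenome",
    "simulate_genome",
    "simulate_methylome",
    "simulate_trajectory",
]

_A, _C, _G, _T = ord("A"), ord("C"), ord("G"), ord("T")


@dataclass(frozen=True)
class IslandSpec:
    """One island to implant: composition, class and shore behaviour.

    ``meth_level`` is the island-body percent methylation; None means the
    island tracks the genomic plateau (the future-high behaviour).  The
    linear shore model ramps from the island level to the plateau over
    ``ramp_length`` bp, i.e. a true slope of
    (plateau - level) * 500 / ramp_length percent per 500 bp.
    """

    length: int = 1000
    gc_fraction: float = 0.65
    obs_exp: float = 1.0
    true_class: str = "low"  # 'low' | 'high'
    meth_level: float | None = 0.0
    shore_model: str = "linear"  # 'linear' | 'logistic' | 'flat'
    ramp_length: int = 2000
    logistic_midpoint: float = 1000.0
    logistic_scale: float = 250.0

    def __post_init__(self) -> None:
        if self.true_class not in ("low", "high"):
            raise ValueError(f"true_class must be low|high, got {self.true_class!r}")
        if self.shore_model not in ("linear", "logistic", "flat"):
            raise ValueError(f"unknown shore_model {self.shore_model!r}")
        if self.meth_level is not None and not 0 <= self.meth_level <= 100:
            raise ValueError("meth_level must be in [0, 100]")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")

    def level(self, plateau: float) -> float:
        return plateau if self.meth_level is None else self.meth_level

    def shore_value(self, d, plateau: float, model: str | None = None):
        """Isolated shore methylation (percent) at offset(s) d >= 1."""
        model = model or self.shore_model
        level = self.level(plateau)
        d = np.asarray(d, dtype=float)
        if model == "flat":
            return np.full_like(d, plateau)
        if model == "linear":
            frac = np.minimum(d, self.ramp_length) / self.ramp_length
            return level + (plateau - level) * frac
        # logistic
        z = (d - self.logistic_midpoint) / self.logistic_scale
        return level + (plateau - level) / (1.0 + np.exp(-z))

    def true_slope_per_500(self, plateau: float) -> float:
        """Ground-truth shore slope in percent per 500 bp (0 for flat shores)."""
        if self.shore_model == "flat":
            return 0.0
        return (plateau - self.level(plateau)) * 500.0 / self.ramp_length


@dataclass(frozen=True)
class PairSpec:
    """Two islands separated edge-to-edge by ``separation`` bp."""

    left: IslandSpec
    right: IslandSpec
    separation: int

    def __post_init__(self) -> None:
        if self.separation < 0:
            raise ValueError("separation must be >= 0")


@dataclass(frozen=True)
class RepeatSpec:
    """Attach repeat annotation(s) to island ``island_index`` in one of the
    four overlap layouts (type1..type4)."""

    island_index: int
    layout: str = "type1"
    repeat_class: str = "SINE"

    def __post_init__(self) -> None:
        if self.layout not in ("type1", "type2", "type3", "type4"):
            raise ValueError(f"unknown layout {self.layout!r}")


@dataclass
class SimulationConfig:
    """Study conditions for one simulation.

    Densities are CpG dinucleotides per kb: ``background_cpg_per_kb`` in the
    open sea, ``shore_cpg_per_kb`` within ``ramp_length`` of an island (CpG
    density is elevated near real islands; the default 20/kb keeps the
    scanner's expected score negative in shores with a wide margin, so island
    boundaries stay crisp and spurious shore segments are rare).
    ``plateau`` is the genome-wide background methylation percent (80
    somatic-like; 90 sperm-like); ``coverage`` the Poisson mean read depth.
    ``timepoints`` optionally lists (label, plateau) pairs for a
    reprogramming series.
    """

    seed: int = 0
    chrom: str = "chrS"
    background_gc: float = 0.40
    background_cpg_per_kb: float = 10.0
    shore_cpg_per_kb: float = 20.0
    islands: list[IslandSpec] = field(default_factory=list)
    pairs: list[PairSpec] = field(default_factory=list)
    repeats: list[RepeatSpec] = field(default_factory=list)
    spacing: int = 12_000
    margin: int = 6_000
    min_length: int = 0
    plateau: float = 80.0
    coverage: float = 30.0
    crosstalk: bool = False
    timepoints: list[tuple[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not 0 <= self.plateau <= 100:
            raise ValueError("plateau must be in [0, 100]")
        if self.spacing < 0 or self.margin < 0:
            raise ValueError("spacing and margin must be >= 0")

    @classmethod
    def default(cls, seed: int = 0) -> "SimulationConfig":
        """The stock demo conditions: 150 low + 150 high single islands,
        20 close low-low pairs, and repeats exercising all four types."""
        low = IslandSpec(true_class="low", meth_level=5.0)
        high = IslandSpec(true_class="high", meth_level=95.0, shore_model="flat")
        islands = [low, high] * 150
        pairs = [PairSpec(low, low, 800)] * 20
        repeats = [
            RepeatSpec(0, "type1", "SINE"),
            RepeatSpec(1, "type2", "SINE"),
            RepeatSpec(2, "type3", "simple"),
            RepeatSpec(3, "type4", "low_complexity"),
        ]
        return cls(seed=seed, islands=islands, pairs=pairs, repeats=repeats)


@dataclass(frozen=True)
class TrueIsland:
    """Ground truth for one implanted island."""

    interval: GenomicInterval
    spec: IslandSpec
    pair_id: int | None = None  # index into SimTruth.pair_separations, or None

    def as_cpg_island(self, source: str = "truth") -> CpGIsland:
        return CpGIsland(
            self.interval,
            score=0,
            gc_fraction=self.spec.gc_fraction,
            obs_exp_ratio=self.spec.obs_exp,
            source=source,
        )


@dataclass
class SimTruth:
    """Generator ground truth: island positions/classes/shore parameters,
    repeat intervals, and the methylome-level settings."""

    islands: list[TrueIsland]
    repeats: list[RepeatAnnotation]
    pair_separations: list[int]
    chrom: str
    chrom_length: int
    plateau: float
    timepoint_plateaus: list[tuple[str, float]] | None = None

    def island_intervals(self) -> list[GenomicInterval]:
        return [t.interval for t in self.islands]

    def as_cpg_islands(self) -> list[CpGIsland]:
        return [t.as_cpg_island() for t in self.islands]

    def islands_of_class(self, true_class: str) -> list[TrueIsland]:
        return [t for t in self.islands if t.spec.true_class == true_class]

    def singles(self) -> list[TrueIsland]:
        return [t for t in self.islands if t.pair_id is None]

    def to_json(self, path) -> None:
        payload = {
            "chrom": self.chrom,
            "chrom_length": self.chrom_length,
            "plateau": self.plateau,
            "timepoint_plateaus": self.timepoint_plateaus,
            "islands": [
                {
                    "start": t.interval.start,
                    "end": t.interval.end,
                    "pair_id": t.pair_id,
                    **asdict(t.spec),
                }
                for t in self.islands
            ],
            "repeats": [
                {
                    "start": r.interval.start,
                    "end": r.interval.end,
                    "repeat_class": r.repeat_class,
                }
                for r in self.repeats
            ],
        }
        with open(path, "wt") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimulatedGenome:
    sequences: dict[str, str]
    truth: SimTruth
    config: SimulationConfig

    def masked_sequences(self) -> dict[str, str]:
        """Repeat-masked twin: repeat intervals hard-masked to N."""
        out = {}
        for chrom, seq in self.sequences.items():
            arr = bytearray(seq, "ascii")
            for rep in self.truth.repeats:
                if rep.interval.chrom == chrom:
                    s = max(0, rep.interval.start)
                    e = min(len(arr), rep.interval.end)
                    arr[s:e] = b"N" * (e - s)
            out[chrom] = arr.decode("ascii")
        return out

    def cpg_positions(self, chrom: str | None = None) -> np.ndarray:
        chrom = chrom or self.truth.chrom
        arr = np.frombuffer(self.sequences[chrom].encode("ascii"), dtype=np.uint8)
        return np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G))


def _rng(seed: int, stream: int, salt: str = "") -> np.random.Generator:
    # one PCG64 stream per artifact; salt folds a label into the key
    key = [int(seed) & 0x7FFFFFFF, stream]
    if salt:
        key.append(zlib.adler32(salt.encode()) & 0x7FFFFFFF)
    return np.random.default_rng(key)


def _layout(config: SimulationConfig):
    """Place islands left to right; returns (true islands, chrom length)."""
    cursor = config.margin
    placed: list[TrueIsland] = []
    for spec in config.islands:
        iv = GenomicInterval(config.chrom, cursor, cursor + spec.length)
        placed.append(TrueIsland(iv, spec, None))
        cursor = iv.end + config.spacing
    seps = []
    for pair_id, pair in enumerate(config.pairs):
        left = GenomicInterval(config.chrom, cursor, cursor + pair.left.length)
        rstart = left.end + pair.separation
        right = GenomicInterval(config.chrom, rstart, rstart + pair.right.length)
        placed.append(TrueIsland(left, pair.left, pair_id))
        placed.append(TrueIsland(right, pair.right, pair_id))
        seps.append(pair.separation)
        cursor = right.end + config.spacing
    length = cursor - (config.spacing if placed else 0) + config.margin
    length = max(length, config.min_length)
    return placed, length


def _repeat_annotations(config: SimulationConfig, islands: Sequence[TrueIsland]):
    repeats = []
    for spec in config.repeats:
        if not 0 <= spec.island_index < len(islands):
            raise ValueError(f"repeat refers to missing island {spec.island_index}")
        iv = islands[spec.island_index].interval
        s, e, chrom = iv.start, iv.end, iv.chrom
        if spec.layout == "type1":
            geoms = [(s - 150, e + 150)]
        elif spec.layout == "type2":
            geoms = [(e - 100, e + 300)]
        elif spec.layout == "type3":
            geoms = [(s + 50, min(s + 250, e - 50))]
        else:  # type4: contained + boundary-crossing
            geoms = [(s + 50, min(s + 200, e - 50)), (e - 100, e + 300)]
        for rs, re in geoms:
            repeats.append(
                RepeatAnnotation(GenomicInterval(chrom, max(0, rs), re), spec.repeat_class)
            )
    return repeats


def _fill_bases(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(
        np.array([_A, _C, _G, _T], dtype=np.uint8), size=length, p=probs
    )


def _implant_positions(rng, rate: np.ndarray) -> np.ndarray:
    """Sample CG start positions at per-position rate, min spacing 2."""
    cand = np.flatnonzero(rng.random(rate.size) < rate)
    kept = []
    last = -2
    for p in cand:
        if p - last >= 2:
            kept.append(p)
            last = p
    return np.asarray(kept, dtype=np.int64)


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Build the genome sequence and its truth manifest.

    Islands must not overlap (layout places them left to right with the
    configured spacing/separations, so overlap indicates a bad config).
    The emitted sequence's CpGs are exactly the implanted ones: the CG-free
    fill is scrubbed before implantation and implants cannot recreate CG
    dinucleotides by collision.
    """
    islands, length = _layout(config)
    for a, b in zip(islands, islands[1:]):
        if a.interval.end > b.interval.start:
            raise ValueError(f"island layout overlaps: {a.interval} vs {b.interval}")
    rng = _rng(config.seed, 0)

    # per-position CG-start rate: background, then shores, then islands
    rate = np.full(length, config.background_cpg_per_kb / 1000.0)
    ramp = max((t.spec.ramp_length for t in islands), default=0)
    for t in islands:
        s, e = t.interval.start, t.interval.end
        rate[max(0, s - t.spec.ramp_length) : s] = config.shore_cpg_per_kb / 1000.0
        rate[e : e + t.spec.ramp_length] = config.shore_cpg_per_kb / 1000.0
    for t in islands:
        s, e = t.interval.start, t.interval.end
        island_rate = t.spec.obs_exp * (t.spec.gc_fraction / 2.0) ** 2
        rate[s:e] = island_rate

    # CG-free fill; composition corrected for the CpGs to be implanted
    def eff_gc(gc, r):
        return max(0.02, (gc - 2.0 * r) / (1.0 - 2.0 * r))

    bases = _fill_bases(rng, length, eff_gc(config.background_gc,
                                            config.background_cpg_per_kb / 1000.0))
    for t in islands:
        s, e = t.interval.start, t.interval.end
        island_rate = t.spec.obs_exp * (t.spec.gc_fraction / 2.0) ** 2
        bases[s:e] = _fill_bases(rng, e - s, eff_gc(t.spec.gc_fraction, island_rate))
    # scrub accidental CGs from the fill by swapping each CG to GC: exact
    # composition preservation, and each pass strictly moves Gs leftward so
    # the loop terminates (cap + T-fallback kept as a safety net)
    for _ in range(10_000):
        cg = (bases[:-1] == _C) & (bases[1:] == _G)
        if not cg.any():
            break
        idx = np.flatnonzero(cg)
        bases[idx] = _G
        bases[idx + 1] = _C
    else:  # pragma: no cover - unreachable given the potential argument
        cg = (bases[:-1] == _C) & (bases[1:] == _G)
        bases[1:][cg] = _T

    pos = _implant_positions(rng, rate[:-1])
    bases[pos] = _C
    bases[pos + 1] = _G

    truth = SimTruth(
        islands=islands,
        repeats=_repeat_annotations(config, islands),
        pair_separations=[p.separation for p in config.pairs],
        chrom=config.chrom,
        chrom_length=length,
        plateau=config.plateau,
        timepoint_plateaus=list(config.timepoints) if config.timepoints else None,
    )
    seq = bases.tobytes().decode("ascii")
    return SimulatedGenome({config.chrom: seq}, truth, config)


def _true_probabilities(
    genome: SimulatedGenome,
    plateau: float,
    crosstalk: bool,
    shore_overrides: dict[tuple[int, str], str] | None,
    cpg_pos: np.ndarray,
) -> np.ndarray:
    """Percent methylation probability for every CpG position."""
    truth = genome.truth
    n = cpg_pos.size
    p = np.full(n, float(plateau))
    in_island = np.zeros(n, dtype=bool)
    island_level = np.empty(n)
    nearest = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    multiplier = np.ones(n)
    overrides = shore_overrides or {}
    for idx, t in enumerate(truth.islands):
        s, e = t.interval.start, t.interval.end
        lo, hi = np.searchsorted(cpg_pos, [s, e])
        in_island[lo:hi] = True
        island_level[lo:hi] = t.spec.level(plateau)
        for side in ("upstream", "downstream"):
            model = overrides.get((idx, side), t.spec.shore_model)
            if side == "upstream":
                wlo, whi = np.searchsorted(cpg_pos, [s - t.spec.ramp_length, s])
                d = s - cpg_pos[wlo:whi]
            else:
                wlo, whi = np.searchsorted(cpg_pos, [e, e + t.spec.ramp_length])
                d = cpg_pos[wlo:whi] - e + 1
            if wlo == whi:
                continue
            v = t.spec.shore_value(d, plateau, model=model)
            if crosstalk:
                if plateau > 0:
                    multiplier[wlo:whi] *= v / plateau
            else:
                closer = d < nearest[wlo:whi]
                sel = np.arange(wlo, whi)[closer]
                p[sel] = v[closer]
                nearest[sel] = d[closer]
    if crosstalk:
        p = plateau * multiplier
    p[in_island] = island_level[in_island]
    return np.clip(p, 0.0, 100.0)


def simulate_methylome(
    genome: SimulatedGenome,
    label: str = "sim",
    plateau: float | None = None,
    coverage: float | None = None,
    crosstalk: bool | None = None,
    shore_overrides: dict[tuple[int, str], str] | None = None,
) -> Methylome:
    """Draw a WGBS count table from the genome's truth.

    ``shore_overrides`` maps (island index, side) to a shore-model name and
    substitutes it for that shore only — e.g. {"(3, 'downstream')": 'flat'}
    removes one ramp, implanting a differential shore between two samples.
    Determinism: the RNG stream is keyed by (config seed, label), so the
    same label always reproduces the same counts and distinct labels are
    independent.
    """
    config = genome.config
    plateau = config.plateau if plateau is None else plateau
    coverage = config.coverage if coverage is None else coverage
    crosstalk = config.crosstalk if crosstalk is None else crosstalk
    rng = _rng(config.seed, 1, salt=label)
    cpg_pos = genome.cpg_positions()
    p = _true_probabilities(genome, plateau, crosstalk, shore_overrides, cpg_pos)
    depth = rng.poisson(coverage, size=cpg_pos.size)
    covered = depth > 0
    n_meth = np.zeros(cpg_pos.size, dtype=np.int64)
    n_meth[covered] = rng.binomial(depth[covered], p[covered] / 100.0)
    return Methylome.from_arrays(
        genome.truth.chrom,
        cpg_pos[covered],
        n_meth[covered],
        depth[covered] - n_meth[covered],
        label=label,
    )


def simulate_trajectory(
    genome: SimulatedGenome, config: SimulationConfig | None = None
) -> list[tuple[str, Methylome]]:
    """One methylome per configured time point.

    Each time point applies its own plateau: islands with ``meth_level``
    None (future-high) track the plateau with flat shores, islands with a
    fixed low level (future-low) keep it, their ramps rescaling to each
    plateau — the bookmarking structure of reprogramming series.
    """
    config = config or genome.config
    if not config.timepoints:
        raise ValueError("config.timepoints is empty")
    return [
        (label, simulate_methylome(genome, label=label, plateau=tp_plateau))
        for label, tp_plateau in config.timepoints
    ]
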