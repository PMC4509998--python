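"""End-to-end pipeline configuration and the self-contained demo.

``run_demo`` simulates a genome and methylomes, then drives every analysis
stage — detection, unique/repeat typing, island classification, shore
profiles and slopes, paired-CGI profiles, a reprogramming trajectory, and
two-sample shore scoring — writing figure-style TSV tables plus a JSON
summary of recovery checks against the generator's truth.  It is the
programmatic backbone of the ``cgishores demo`` CLI subcommand.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import detect, io, pairs, profiles, shores, simulate, trajectory

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_demo"]


@dataclasses.dataclass
class PipelineConfig:
    """All analysis thresholds, at their protocol defaults, overridable."""

    min_length: int = 200
    low: float = 20.0
    high: float = 80.0
    neighbor_window: int = 10_000
    flank: int = 5_000
    bin_width: int = 250
    endpoint_window: int = 10
    min_coverage: int = 1
    min_cpgs: int = 3
    cg_reward: int = 17
    per_base_penalty: int = 1
    min_score: int = 17
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.low < self.high <= 100:
            raise ValueError(
                f"need 0 <= low < high <= 100, got low={self.low} high={self.high}"
            )
        if self.flank % self.bin_width != 0:
            raise ValueError("flank must be a multiple of bin_width")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load from YAML (JSON is a YAML subset and also accepted)."""
        with open(path, "rt") as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _overlap_fraction(truth_iv, detected) -> float:
    """Largest fraction of a truth interval covered by one detected island."""
    best = 0.0
    for isl in detected:
        if isl.chrom != truth_iv.chrom:
            continue
        ov = min(isl.end, truth_iv.end) - max(isl.start, truth_iv.start)
        if ov > 0:
            best = max(best, ov / truth_iv.length)
    return best


def run_demo(
    outdir,
    seed: int = 0,
    sim_config: simulate.SimulationConfig | None = None,
    pipe: PipelineConfig | None = None,
) -> dict:
    """Simulate, analyse, write tables, and check recovery against truth.

    Returns the summary dict (also written to ``summary.json``); the
    ``checks`` entry maps each recovery property to a boolean and ``all_ok``
    reports their conjunction.  Tolerances here are demo-scale: ramp slopes
    within 5 points of truth, flat shores within 4 points of zero, all
    implanted differential shores inside the top 1.25*k ranks.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pipe = pipe or PipelineConfig(seed=seed)
    cfg = sim_config or simulate.SimulationConfig.default(seed)
    if cfg.timepoints is None:
        cfg.timepoints = [("t0", 20.0), ("t1", 45.0), ("t2", 85.0)]

    summary: dict = {"seed": seed, "stages": {}}
    checks: dict[str, bool] = {}

    # -- simulate -------------------------------------------------------------
    genome = simulate.simulate_genome(cfg)
    truth = genome.truth
    io.write_fasta(genome.sequences, outdir / "genome.fa")
    io.write_fasta(genome.masked_sequences(), outdir / "genome.masked.fa")
    truth.to_json(outdir / "truth.json")
    io.write_intervals_bed(
        truth.island_intervals(),
        outdir / "islands.truth.bed",
        names=[t.spec.true_class for t in truth.islands],
    )
    if truth.repeats:
        io.write_intervals_bed(
            [r.interval for r in truth.repeats],
            outdir / "repeats.bed",
            names=[r.repeat_class for r in truth.repeats],
        )
    methylome = simulate.simulate_methylome(genome, label="soma")
    io.write_methylome(methylome, outdir / "methylome.soma.tsv")
    summary["stages"]["simulate"] = {
        "chrom_length": truth.chrom_length,
        "n_islands": len(truth.islands),
        "n_cpgs": methylome.n_sites,
    }

    # -- detect ---------------------------------------------------------------
    unmasked = detect.detect_islands(
        genome.sequences,
        cg_reward=pipe.cg_reward,
        per_base_penalty=pipe.per_base_penalty,
        min_score=pipe.min_score,
        min_length=pipe.min_length,
        source="unmasked",
    )
    masked = detect.detect_islands(
        genome.masked_sequences(),
        cg_reward=pipe.cg_reward,
        per_base_penalty=pipe.per_base_penalty,
        min_score=pipe.min_score,
        min_length=pipe.min_length,
        source="masked",
    )
    io.write_intervals_bed(
        [i.interval for i in unmasked],
        outdir / "islands.detected.bed",
        names=[f"score={i.score}" for i in unmasked],
        extra_columns=[
            (f"{i.gc_fraction:.3f}", f"{i.obs_exp_ratio:.3f}") for i in unmasked
        ],
    )
    recovery = [
        _overlap_fraction(t.interval, unmasked) for t in truth.islands
    ]
    gg_ok = [
        i.gc_fraction > 0.5 and i.obs_exp_ratio > 0.6 for i in unmasked
    ]
    uniq_rep = detect.classify_unique_repeat(masked, unmasked)
    n_repeat = sum(1 for v in uniq_rep.values() if v == "repeat")
    summary["stages"]["detect"] = {
        "n_detected": len(unmasked),
        "n_detected_masked": len(masked),
        "truth_recovery_fraction": float(np.mean([r >= 0.8 for r in recovery]))
        if recovery
        else None,
        "gg_valid_fraction": float(np.mean(gg_ok)) if gg_ok else None,
        "n_unique": len(uniq_rep) - n_repeat,
        "n_repeat": n_repeat,
    }
    checks["detection_recovers_truth"] = (
        summary["stages"]["detect"]["truth_recovery_fraction"] is not None
        and summary["stages"]["detect"]["truth_recovery_fraction"] >= 0.95
    )
    checks["gardiner_garden_valid"] = (
        summary["stages"]["detect"]["gg_valid_fraction"] is not None
        and summary["stages"]["detect"]["gg_valid_fraction"] >= 0.9
    )

    # -- repeat typing --------------------------------------------------------
    if truth.repeats:
        repeat_islands = [
            t.as_cpg_island()
            for t in truth.islands
            if any(r.interval.overlaps(t.interval) for r in truth.repeats)
        ]
        typed = [
            detect.classify_repeat_type(isl, truth.repeats) for isl in repeat_islands
        ]
        type_counts = pd.Series([t.repeat_type for t in typed]).value_counts()
        summary["stages"]["repeat_types"] = type_counts.to_dict()

    # -- classify -------------------------------------------------------------
    islands = truth.as_cpg_islands()
    classified = profiles.classify_islands(
        methylome,
        islands,
        min_cpgs=pipe.min_cpgs,
        neighbor_window=pipe.neighbor_window,
        low=pipe.low,
        high=pipe.high,
    )
    rows = []
    for t, isl in zip(truth.islands, islands):
        s = classified[isl]
        rows.append(
            {
                "chrom": isl.chrom,
                "start": isl.start,
                "end": isl.end,
                "true_class": t.spec.true_class,
                "mean_percent": s.mean_percent,
                "meth_class": s.meth_class,
                "neighbor_class": s.neighbor_class,
                "n_cpgs": s.n_cpgs,
                "mean_coverage": s.mean_coverage,
            }
        )
    class_table = pd.DataFrame(rows)
    class_table.to_csv(outdir / "islands.classified.tsv", sep="\t", index=False)
    determined = class_table.dropna(subset=["meth_class"])
    n_errors = int((determined["true_class"] != determined["meth_class"]).sum())
    counts = determined["meth_class"].value_counts()
    neighbor_counts = class_table["neighbor_class"].value_counts()
    summary["stages"]["classify"] = {
        "n_classified": int(len(determined)),
        "class_counts": counts.to_dict(),
        "neighbor_counts": neighbor_counts.to_dict(),
        "n_misclassified": n_errors,
    }
    checks["classification_errors_zero"] = n_errors == 0
    checks["class_partition"] = int(counts.sum()) == len(determined)
    checks["neighbor_partition"] = int(neighbor_counts.sum()) == len(islands)

    # -- shore profiles and slopes -------------------------------------------
    singles = {
        cls: [
            t.as_cpg_island()
            for t in truth.singles()
            if t.spec.true_class == cls
        ]
        for cls in ("low", "high")
    }
    slope_rows = []
    slope_ok = {"low": True, "high": True}
    for cls, group in singles.items():
        if not group:
            continue
        prof = shores.aggregate(
            shores.shore_profiles(
                methylome, group, flank=pipe.flank, bin_width=pipe.bin_width
            )
        )
        prof.to_frame().to_csv(
            outdir / f"shore_profile.{cls}.tsv", sep="\t", index=False
        )
        table = shores.compute_slopes(
            methylome, group, endpoint_window=pipe.endpoint_window, all_islands=islands
        )
        spec0 = next(t.spec for t in truth.singles() if t.spec.true_class == cls)
        true_slope = spec0.true_slope_per_500(truth.plateau)
        for entry in table.entries:
            slope_rows.append(
                {
                    "meth_class": cls,
                    "range_start": entry.range[0],
                    "range_end": entry.range[1],
                    "slope": entry.slope,
                    "true_slope": true_slope,
                }
            )
            if entry.slope is None:
                slope_ok[cls] = False
            elif abs(entry.slope - true_slope) > (5.0 if cls == "low" else 4.0):
                slope_ok[cls] = False
    pd.DataFrame(slope_rows).to_csv(outdir / "slopes.tsv", sep="\t", index=False)
    summary["stages"]["slopes"] = {
        "n_ranges": len(shores.DEFAULT_RANGES),
        "bins_per_2kb_shore": shores.SHORE_EXTENT // pipe.bin_width,
        "table": slope_rows,
    }
    checks["eight_bins_four_ranges"] = (
        shores.SHORE_EXTENT // pipe.bin_width == 8
        and len(shores.DEFAULT_RANGES) == 4
    )
    checks["low_slope_recovered"] = slope_ok["low"]
    checks["high_shores_flat"] = slope_ok["high"]

    # -- pairs ----------------------------------------------------------------
    if truth.pair_separations:
        meth_classes = {isl: classified[isl] for isl in islands}
        found = pairs.find_pairs(islands, 500, 1000, meth_classes=meth_classes)
        pair_classes = [pairs.classify_pair(p) for p in found]
        low_low = [p for p, c in zip(found, pair_classes) if c == "low_low"]
        summary["stages"]["pairs"] = {
            "n_pairs_500_1000": len(found),
            "pair_class_counts": pd.Series(pair_classes).value_counts().to_dict(),
        }
        if low_low:
            prof = pairs.intervening_profile(
                low_low, methylome, bin_width=100, all_islands=islands
            )
            prof.to_frame().to_csv(
                outdir / "pairs.low_low.intervening.tsv", sep="\t", index=False
            )

    # -- two-sample shore differences (DMR implants) --------------------------
    low_single_idx = [
        i
        for i, t in enumerate(truth.islands)
        if t.pair_id is None and t.spec.true_class == "low"
    ]
    k = min(10, len(low_single_idx))
    implant = {(i, "downstream"): "flat" for i in low_single_idx[:k]}
    meth_b = simulate.simulate_methylome(
        genome, label="soma_b", shore_overrides=implant
    )
    ranked = shores.rank_shore_differences(methylome, meth_b, islands)
    ranked.to_csv(outdir / "shore_differences.tsv", sep="\t", index=False)
    implanted_coords = {
        (truth.islands[i].interval.start, "downstream") for i in low_single_idx[:k]
    }
    top = ranked.head(max(1, int(np.ceil(1.25 * k))))
    n_hit = sum(
        1
        for _, row in top.iterrows()
        if (row["start"], row["side"]) in implanted_coords
    )
    summary["stages"]["shore_diff"] = {"n_implanted": k, "n_in_top": int(n_hit)}
    checks["dmr_recovery"] = n_hit == k

    # -- trajectory -----------------------------------------------------------
    series = trajectory.TrajectorySeries(
        tuple(simulate.simulate_trajectory(genome, cfg)), terminal_index=-1
    )
    result = trajectory.run_trajectory(
        series,
        islands,
        flank=pipe.flank,
        bin_width=pipe.bin_width,
        min_cpgs=pipe.min_cpgs,
        endpoint_window=pipe.endpoint_window,
    )
    traj_rows = []
    for (fc, label), table in result.slopes.items():
        for entry in table.entries:
            traj_rows.append(
                {
                    "future_class": fc,
                    "timepoint": label,
                    "range_start": entry.range[0],
                    "range_end": entry.range[1],
                    "slope": entry.slope,
                    "island_mean": result.island_means.get((fc, label)),
                }
            )
    pd.DataFrame(traj_rows).to_csv(outdir / "trajectory.tsv", sep="\t", index=False)
    flat_high = all(
        abs(entry.slope) <= 5.0
        for (fc, _), table in result.slopes.items()
        if fc == "future_high"
        for entry in table.entries
        if entry.slope is not None
    )
    plateaus = [p for _, p in cfg.timepoints]
    low_slopes = [
        result.slopes[("future_low", label)].entries[0].slope
        for label, _ in cfg.timepoints
        if ("future_low", label) in result.slopes
    ]
    rank_match = (
        len(low_slopes) == len(plateaus)
        and all(s is not None for s in low_slopes)
        and list(np.argsort(low_slopes)) == list(np.argsort(plateaus))
    )
    summary["stages"]["trajectory"] = {
        "labels": list(result.labels),
        "n_future_low": len(result.islands_of("future_low")),
        "n_future_high": len(result.islands_of("future_high")),
    }
    checks["future_high_flat"] = flat_high
    checks["future_low_rank_matches_plateau"] = rank_match

    summary["checks"] = checks
    summary["all_ok"] = all(checks.values())
    with open(outdir / "summary.json", "wt") as fh:
        json.dump(summary, fh, indent=1, default=float)
    for stage, info in summary["stages"].items():
        logger.info("stage %s: %s", stage, {k: v for k, v in info.items() if k != "table"})
    return summary
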