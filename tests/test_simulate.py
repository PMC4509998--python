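import numpy as np
import pytest

from cgishores import (
    IslandSpec,
    PairSpec,
    RepeatSpec,
    SimulationConfig,
    classify_repeat_type,
    detect_islands,
    filter_islands,
    gardiner_garden_stats,
    simulate_genome,
    simulate_methylome,
    simulate_trajectory,
)
from oracles import gg_recount


def one_island_config(seed=7, **spec_kw):
    return SimulationConfig(seed=seed, islands=[IslandSpec(**spec_kw)])


class TestSimulateGenome:
    def test_fixed_seed_byte_identical(self):
        a = simulate_genome(SimulationConfig.default(3))
        b = simulate_genome(SimulationConfig.default(3))
        assert a.sequences == b.sequences
        assert a.truth.island_intervals() == b.truth.island_intervals()

    def test_different_seeds_differ(self):
        a = simulate_genome(one_island_config(seed=1))
        b = simulate_genome(one_island_config(seed=2))
        assert a.sequences != b.sequences

    def test_island_composition_matches_target(self):
        cfg = one_island_config(seed=11, gc_fraction=0.60, obs_exp=1.0, length=1000)
        genome = simulate_genome(cfg)
        iv = genome.truth.islands[0].interval
        gc, oe = gardiner_garden_stats(genome.sequences[cfg.chrom], iv)
        assert oe == pytest.approx(1.0, abs=0.15)
        assert gc == pytest.approx(0.60, abs=0.05)

    def test_truth_manifest_consistent_with_sequence(self):
        cfg = SimulationConfig(seed=13, islands=[IslandSpec()] * 5)
        genome = simulate_genome(cfg)
        seq = genome.sequences[cfg.chrom]
        assert genome.truth.chrom_length == len(seq)
        for t in genome.truth.islands:
            gc, oe = gg_recount(seq[t.interval.start : t.interval.end])
            assert gc == pytest.approx(t.spec.gc_fraction, abs=0.06)
            assert oe == pytest.approx(t.spec.obs_exp, abs=0.3)

    def test_background_cpg_depleted(self):
        cfg = SimulationConfig(seed=17, min_length=100_000)
        genome = simulate_genome(cfg)
        gc, oe = gg_recount(genome.sequences[cfg.chrom])
        # open-sea O/E well below the 0.6 island criterion
        assert oe < 0.4

    def test_zero_islands_detector_null(self):
        hits = 0
        for seed in range(20):
            cfg = SimulationConfig(seed=seed, min_length=100_000)
            genome = simulate_genome(cfg)
            islands = filter_islands(
                detect_islands(genome.sequences, min_length=200), min_length=200
            )
            hits += bool(islands)
        assert hits <= 1  # 0 islands >=200 bp in >=95% of seeds

    def test_overlapping_layout_rejected(self):
        cfg = SimulationConfig(
            seed=1, pairs=[PairSpec(IslandSpec(), IslandSpec(), 0)], spacing=0, margin=0
        )
        # separation 0 makes the two islands adjacent, not overlapping: fine
        simulate_genome(cfg)

    def test_masking_and_repeat_types(self):
        cfg = SimulationConfig(
            seed=23,
            islands=[IslandSpec()] * 4,
            repeats=[
                RepeatSpec(0, "type1"),
                RepeatSpec(1, "type2"),
                RepeatSpec(2, "type3"),
                RepeatSpec(3, "type4"),
            ],
        )
        genome = simulate_genome(cfg)
        masked = genome.masked_sequences()[cfg.chrom]
        for rep in genome.truth.repeats:
            assert set(masked[rep.interval.start : rep.interval.end]) == {"N"}
        for t, expected in zip(genome.truth.islands, ("type1", "type2", "type3", "type4")):
            res = classify_repeat_type(t.as_cpg_island(), genome.truth.repeats)
            assert res.repeat_type == expected


class TestSimulateMethylome:
    def test_fixed_seed_identical_counts(self):
        genome = simulate_genome(one_island_config())
        a = simulate_methylome(genome, label="x")
        b = simulate_methylome(genome, label="x")
        assert a == b
        assert simulate_methylome(genome, label="y") != a

    def test_zero_probability_region_all_unmethylated(self):
        cfg = one_island_config(true_class="low", meth_level=0.0)
        genome = simulate_genome(cfg)
        m = simulate_methylome(genome, coverage=50.0)
        iv = genome.truth.islands[0].interval
        sites = m.in_range(cfg.chrom, iv.start, iv.end)
        assert sites["pos"].size > 50
        assert int(sites["n_meth"].sum()) == 0

    def test_binomial_concentration_at_plateau(self):
        cfg = SimulationConfig(seed=29, min_length=30_000, plateau=80.0)
        genome = simulate_genome(cfg)
        m = simulate_methylome(genome, coverage=50.0)
        arr = m.arrays(cfg.chrom)
        assert arr["pos"].size >= 200
        assert float(np.mean(arr["percent"])) == pytest.approx(80.0, abs=3.0)

    def test_shore_override_flattens_one_side(self):
        cfg = one_island_config(true_class="low", meth_level=0.0)
        genome = simulate_genome(cfg)
        base = simulate_methylome(genome, label="a", coverage=60.0)
        flat = simulate_methylome(
            genome, label="a", coverage=60.0, shore_overrides={(0, "downstream"): "flat"}
        )
        iv = genome.truth.islands[0].interval
        down = flat.in_range(cfg.chrom, iv.end, iv.end + 2000)
        up = flat.in_range(cfg.chrom, iv.start - 2000, iv.start)
        assert float(np.mean(down["percent"])) == pytest.approx(80.0, abs=5.0)
        # the untouched side still ramps (well below plateau on average)
        assert float(np.mean(up["percent"])) < 55.0
        # and the paired sample differs only where the override applies
        base_up = base.in_range(cfg.chrom, iv.start - 2000, iv.start)
        assert list(base_up["n_meth"]) == list(up["n_meth"])

    def test_crosstalk_depresses_between_close_low_pairs(self):
        low = IslandSpec(true_class="low", meth_level=0.0)
        cfg = SimulationConfig(
            seed=37, pairs=[PairSpec(low, low, 800)] * 30, shore_cpg_per_kb=60.0
        )
        genome = simulate_genome(cfg)
        off = simulate_methylome(genome, label="off", crosstalk=False)
        on = simulate_methylome(genome, label="on", crosstalk=True)
        gap_means = []
        for t in genome.truth.islands[::2]:
            lo, hi = t.interval.end, t.interval.end + 800
            off_pct = off.in_range(cfg.chrom, lo, hi)["percent"]
            on_pct = on.in_range(cfg.chrom, lo, hi)["percent"]
            gap_means.append((float(np.mean(off_pct)), float(np.mean(on_pct))))
        mean_off = np.mean([a for a, _ in gap_means])
        mean_on = np.mean([b for _, b in gap_means])
        assert mean_on < mean_off - 3.0


class TestSimulateTrajectory:
    def base_config(self, timepoints):
        return SimulationConfig(
            seed=41,
            islands=[IslandSpec(true_class="low", meth_level=0.0)] * 5
            + [IslandSpec(true_class="high", meth_level=None, shore_model="flat")] * 5,
            min_length=80_000,
            timepoints=timepoints,
        )

    def test_monotone_plateaus_in_open_sea(self):
        cfg = self.base_config([("a", 20.0), ("b", 70.0), ("c", 80.0)])
        genome = simulate_genome(cfg)
        series = simulate_trajectory(genome)
        sea_start = genome.truth.islands[-1].interval.end + 5000
        means = []
        for _, m in series:
            arr = m.in_range(cfg.chrom, sea_start, genome.truth.chrom_length)
            means.append(float(np.mean(arr["percent"])))
        assert means[0] < means[1] < means[2]
        for mean, (_, plateau) in zip(means, cfg.timepoints):
            assert mean == pytest.approx(plateau, abs=3.0)

    def test_future_high_island_tracks_plateau(self):
        cfg = self.base_config([("a", 25.0), ("b", 85.0)])
        genome = simulate_genome(cfg)
        (_, early), _ = simulate_trajectory(genome)
        iv = genome.truth.islands[5].interval  # a future-high island
        arr = early.in_range(cfg.chrom, iv.start, iv.end)
        assert float(np.mean(arr["percent"])) == pytest.approx(25.0, abs=4.0)

    def test_single_timepoint_degenerates_to_one_methylome(self):
        cfg = self.base_config([("only", 80.0)])
        genome = simulate_genome(cfg)
        series = simulate_trajectory(genome)
        assert len(series) == 1
        label, m = series[0]
        assert label == "only" and m.n_sites > 0

    def test_missing_timepoints_error(self):
        cfg = one_island_config()
        genome = simulate_genome(cfg)
        with pytest.raises(ValueError):
            simulate_trajectory(genome)
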