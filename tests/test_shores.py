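import numpy as np
import pandas as pd
import pytest

from cgishores import (
    Methylome,
    aggregate,
    assign_zone,
    bin_flanking,
    compute_slopes,
    rank_shore_differences,
    shore_difference,
    shore_profiles,
)
from cgishores.shores import DEFAULT_RANGES, pooled_slopes
from conftest import make_island, make_methylome
from oracles import binned_means_groupby, reverse_interval, reverse_methylome_frame


class TestAssignZone:
    @pytest.mark.parametrize(
        "offset,zone",
        [
            (1, "shore"),
            (1500, "shore"),
            (2000, "shore"),
            (2001, "shelf"),
            (3000, "shelf"),
            (4000, "shelf"),
            (4001, "open_sea"),
            (6000, "open_sea"),
        ],
    )
    def test_zones(self, offset, zone):
        assert assign_zone(offset) == zone

    def test_inside_island_error(self):
        with pytest.raises(ValueError):
            assign_zone(0)


class TestBinFlanking:
    def test_eight_bins_across_2kb_shore(self, island):
        m = make_methylome([(2100, 50)])
        up, down = bin_flanking(m, island, flank=2000, bin_width=250)
        assert len(up.bins) == len(down.bins) == 8
        assert [b.offset_start for b in down.bins] == [250 * k for k in range(8)]

    def test_bin_mean_arithmetic(self, island):
        # island ends at 2000; offsets +100 and +200 fall in downstream bin 1
        m = make_methylome([(2099, 50), (2199, 70)])
        _, down = bin_flanking(m, island, flank=2000, bin_width=250)
        assert down.bins[0].mean_percent == pytest.approx(60.0)
        assert down.bins[0].n_cpgs == 2
        assert down.bins[1].n_cpgs == 0 and down.bins[1].mean_percent is None

    def test_flank_must_be_multiple_of_bin_width(self, island):
        with pytest.raises(ValueError):
            bin_flanking(make_methylome([]), island, flank=2100, bin_width=250)

    def test_cpgs_inside_any_island_excluded(self):
        focal = make_island(start=1000, end=2000)
        neighbor = make_island(start=2400, end=2800)
        m = make_methylome([(2100, 50), (2500, 100), (2900, 70)])
        _, down = bin_flanking(m, focal, all_islands=[focal, neighbor], flank=2000, bin_width=250)
        contributing = sum(b.n_cpgs for b in down.bins)
        assert contributing == 2  # the CpG at 2500 sits inside the neighbour

    def test_matches_groupby_recount_on_random_fixtures(self, rng):
        for _ in range(20):
            islands = [make_island(start=5000, end=6000), make_island(start=7500, end=8200)]
            pos = np.sort(rng.choice(12_000, size=300, replace=False))
            frame = pd.DataFrame(
                {
                    "chrom": "chr1",
                    "pos": pos,
                    "n_meth": rng.integers(0, 20, pos.size),
                    "n_unmeth": rng.integers(1, 20, pos.size),
                }
            )
            m = Methylome(frame)
            up, down = bin_flanking(m, islands[0], all_islands=islands, flank=5000, bin_width=250)
            expected = binned_means_groupby(frame, islands[0], islands, 5000, 250)
            for side, prof in (("upstream", up), ("downstream", down)):
                for k, b in enumerate(prof.bins):
                    exp = expected.get((side, k))
                    if exp is None:
                        assert b.n_cpgs == 0
                    else:
                        assert b.n_cpgs == exp[1]
                        assert b.mean_percent == pytest.approx(exp[0])


class TestAggregate:
    def test_grand_mean_equal_island_weights(self, island):
        m1 = make_methylome([(2100, 40)])
        m2 = make_methylome([(2050, 50), (2150, 70)])
        p1 = bin_flanking(m1, island, flank=2000, bin_width=250)[1]
        p2 = bin_flanking(m2, island, flank=2000, bin_width=250)[1]
        agg = aggregate([p1, p2])
        assert agg.bins[0].grand_mean_percent == pytest.approx(50.0)
        assert agg.bins[0].n_islands == 2

    def test_single_profile_sem_zero(self, island):
        p = bin_flanking(make_methylome([(2100, 40)]), island, flank=2000, bin_width=250)[1]
        agg = aggregate([p])
        assert agg.bins[0].sem == 0.0 and agg.bins[0].n_islands == 1

    def test_identical_profiles_idempotent(self, island):
        p = bin_flanking(make_methylome([(2100, 40)]), island, flank=2000, bin_width=250)[1]
        agg = aggregate([p, p, p])
        assert agg.bins[0].grand_mean_percent == p.bins[0].mean_percent
        assert agg.bins[0].sem == 0.0

    def test_mixed_bin_widths_rejected(self, island):
        m = make_methylome([(2100, 40)])
        a = bin_flanking(m, island, flank=2000, bin_width=250)[1]
        b = bin_flanking(m, island, flank=2000, bin_width=100)[1]
        with pytest.raises(ValueError):
            aggregate([a, b])

    def test_grand_mean_within_contributing_range(self, rng):
        islands = [make_island(start=s, end=s + 1000) for s in range(5000, 65_000, 15_000)]
        sites = []
        for isl in islands:
            for off in rng.choice(np.arange(1, 2001), size=30, replace=False):
                sites.append(("chr1", isl.end + int(off) - 1, int(rng.integers(0, 10)), 10))
        m = Methylome.from_records(sites)
        profs = shore_profiles(m, islands, flank=2000, bin_width=250)
        agg = aggregate(profs)
        for k, bin_ in enumerate(agg.bins):
            if bin_.n_islands == 0:
                continue
            vals = [p.bins[k].mean_percent for p in profs if p.bins[k].n_cpgs]
            assert min(vals) - 1e-9 <= bin_.grand_mean_percent <= max(vals) + 1e-9


class TestComputeSlopes:
    def test_four_ranges(self):
        assert DEFAULT_RANGES == ((1, 500), (500, 1000), (1000, 1500), (1500, 2000))

    def test_slope_is_y2_minus_y1(self):
        offsets = np.array([3, 495, 505, 995])
        percents = np.array([10.0, 40.0, 50.0, 80.0])
        table = pooled_slopes(offsets, percents)
        assert table.entries[0].slope == pytest.approx(30.0)
        assert table.entries[1].slope == pytest.approx(30.0)
        assert not table.entries[2].determined  # no CpGs beyond 1000

    def test_flat_methylome_zero_slope(self, island):
        sites = [(island.end + d - 1, 80) for d in range(1, 2001, 7)]
        m = make_methylome(sites)
        table = compute_slopes(m, [island])
        assert all(e.slope == pytest.approx(0.0) for e in table.entries)

    def test_exact_linear_ramp(self):
        island = make_island(start=10_000, end=11_000)
        sites = []
        for d in range(1, 2001):
            # n_meth=d of 2000 reads makes percent exactly d/20
            sites.append(("chr1", island.end + d - 1, d, 2000 - d))
            sites.append(("chr1", island.start - d, d, 2000 - d))
        m = Methylome.from_records(sites)
        table = compute_slopes(m, [island])
        for entry in table.entries:
            # offsets [a, a+10) vs (b-10, b]: centres 4.5 bp in from each end
            assert entry.slope == pytest.approx(0.05 * (entry.range[1] - entry.range[0] - 9), abs=0.1)

    def test_per_island_mode(self, island):
        m = make_methylome([(island.end + d, 50) for d in range(0, 2000, 5)])
        tables = compute_slopes(m, [island], per_island=True)
        assert set(tables) == {island}
        assert tables[island].entries[0].slope == pytest.approx(0.0)

    def test_mirror_symmetry(self, rng):
        L = 30_000
        island = make_island(start=12_000, end=13_000)
        pos = np.sort(rng.choice(L - 1, size=800, replace=False))
        frame = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": pos,
                "n_meth": rng.integers(0, 12, pos.size),
                "n_unmeth": rng.integers(1, 12, pos.size),
            }
        )
        m = Methylome(frame)
        rev = Methylome(reverse_methylome_frame(frame, L))
        rs, re = reverse_interval(island.start, island.end, L)
        rev_island = make_island(start=rs, end=re)
        up, down = bin_flanking(m, island, flank=2000, bin_width=250)
        rup, rdown = bin_flanking(rev, rev_island, flank=2000, bin_width=250)
        for fwd, mirrored in ((up, rdown), (down, rup)):
            for b, rb in zip(fwd.bins, mirrored.bins):
                assert b.n_cpgs == rb.n_cpgs
                # summation order differs after reflection; allow round-off
                assert b.mean_percent == pytest.approx(rb.mean_percent)
        t = compute_slopes(m, [island])
        rt = compute_slopes(rev, [rev_island])
        for e, f in zip(t.entries, rt.entries):
            assert e.slope == pytest.approx(f.slope)


class TestShoreDifference:
    def test_identical_methylomes_zero(self, island):
        m = make_methylome([(island.end + d, 50) for d in (10, 500, 1500)])
        score = shore_difference(m, m, island, "downstream")
        assert score.cumulative_difference == pytest.approx(0.0)
        assert score.n_common_cpgs == 3

    def test_cumulative_and_mean(self, island):
        pos = [island.end + d for d in (10, 500, 1500)]
        a = make_methylome(zip(pos, (50, 60, 70)))
        b = make_methylome(zip(pos, (40, 40, 40)))
        score = shore_difference(a, b, island, "downstream")
        assert score.cumulative_difference == pytest.approx(60.0)
        assert score.mean_difference == pytest.approx(20.0)

    def test_only_common_cpgs_count(self, island):
        a = make_methylome([(island.end + 10, 50), (island.end + 600, 90)])
        b = make_methylome([(island.end + 10, 30)])
        score = shore_difference(a, b, island, "downstream")
        assert score.n_common_cpgs == 1
        assert score.cumulative_difference == pytest.approx(20.0)

    def test_no_common_cpgs_not_determined(self, island):
        a = make_methylome([(island.end + 10, 50)])
        b = make_methylome([(island.end + 20, 50)])
        score = shore_difference(a, b, island, "downstream")
        assert not score.determined and score.mean_difference is None

    def test_ranking_orders_by_magnitude(self):
        islands = [make_island(start=s, end=s + 500) for s in (10_000, 30_000)]
        pos0 = [islands[0].end + d for d in (10, 100, 200)]
        pos1 = [islands[1].end + d for d in (10, 100, 200)]
        a = make_methylome(
            list(zip(pos0, (80, 80, 80))) + list(zip(pos1, (50, 50, 50)))
        )
        b = make_methylome(
            list(zip(pos0, (10, 10, 10))) + list(zip(pos1, (40, 40, 40)))
        )
        ranked = rank_shore_differences(a, b, islands)
        assert ranked.iloc[0]["start"] == islands[0].start
        assert ranked.iloc[0]["abs_cumulative"] == pytest.approx(210.0)
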