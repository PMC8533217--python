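import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from scdtraj import landscape
from scdtraj.geometry import Series
from scdtraj.landscape import (
    basins, bin2d, free_energy, hist1d, level_populations, minimum,
    modal_bin, pool, surface_to_dataframe,
)
from scdtraj.trajio import Frame


def series(label, values, rep="rep"):
    return Series(label, rep, np.asarray(values, dtype=float))


def surface_from_counts(counts, x_origin=2.0, y_origin=2.2, width=0.1,
                        empty=10.0):
    counts = np.asarray(counts)
    hist = landscape.Histogram2D("x", "y", width, x_origin, y_origin,
                                 counts, int(counts.sum()))
    return free_energy(hist, empty)


# ----------------------------------------------------------------- brute force
def brute_force_landscape(xs, ys, width, empty=10.0):
    """Independent per-observation enumeration in exact rational arithmetic:
    each value is snapped to 6 decimals (the documented edge convention) and
    assigned to [k·width, (k+1)·width) by Fraction floor division; the ΔG
    definition is then applied bin by bin."""
    from fractions import Fraction

    wq = Fraction(width).limit_denominator(10**6)

    def bin_of(v):
        return int(Fraction(round(v * 10**6), 10**6) // wq)

    bins = {}
    for x, y in zip(xs, ys):
        key = (bin_of(x), bin_of(y))
        bins[key] = bins.get(key, 0) + 1
    total = len(xs)
    max_count = max(bins.values())
    dG = {k: -math.log(c / max_count) for k, c in bins.items()}
    levels = {}
    for k, c in bins.items():
        n = max(1, math.ceil(dG[k] - 1e-12))
        levels[n] = levels.get(n, 0) + c
    level_pct = {n: 100.0 * c / total for n, c in levels.items()}
    return bins, dG, level_pct


class TestBin2d:
    def test_single_observation(self):
        h = bin2d(series("x", [2.05]), series("y", [2.25]), 0.1)
        assert h.total == 1
        assert h.x_origin == pytest.approx(2.0)
        assert h.y_origin == pytest.approx(2.2)
        assert h.counts.sum() == 1

    def test_conservation_identical_pairs(self):
        h = bin2d(series("x", [3.14] * 1000), series("y", [2.72] * 1000), 0.1)
        assert h.counts.max() == 1000 and h.total == 1000

    def test_boundary_half_open(self):
        h = bin2d(series("x", [2.10]), series("y", [2.10]), 0.1)
        assert h.x_origin == pytest.approx(2.1)
        assert h.y_origin == pytest.approx(2.1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            bin2d(series("x", [1.0, 2.0]), series("y", [1.0]))

    @given(st.lists(st.tuples(st.floats(0.5, 9.5), st.floats(0.5, 9.5)),
                    min_size=1, max_size=20))
    def test_oracle_equivalence_small_inputs(self, obs):
        xs = [x for x, _ in obs]
        ys = [y for _, y in obs]
        h = bin2d(series("x", xs), series("y", ys), 0.1)
        surf = free_energy(h)
        ref_bins, ref_dG, ref_levels = brute_force_landscape(xs, ys, 0.1)
        assert h.total == len(obs)
        for (kx, ky), c in ref_bins.items():
            ix = kx - round(h.x_origin / 0.1)
            iy = ky - round(h.y_origin / 0.1)
            assert h.counts[ix, iy] == c
            assert surf.dG[ix, iy] == pytest.approx(ref_dG[(kx, ky)], abs=1e-9)
        got = {n: p for n, p in level_populations(surf).levels if p > 0}
        for n, pct in ref_levels.items():
            assert got.pop(n) == pytest.approx(pct, abs=1e-9)
        assert not got


class TestFreeEnergy:
    def test_single_populated_bin(self):
        surf = surface_from_counts([[100]])
        assert surf.dG[0, 0] == 0.0

    def test_worked_grid(self):
        surf = surface_from_counts([[100, 50], [0, 25]])
        np.testing.assert_allclose(
            surf.dG, [[0.0, math.log(2)], [10.0, math.log(4)]], atol=5e-4)
        assert surf.dG[0, 0] == 0.0  # exact at the argmax

    def test_empty_bin_sentinel_exact(self):
        surf = surface_from_counts([[5, 0], [0, 1]])
        assert surf.dG[0, 1] == 10.0 and surf.dG[1, 0] == 10.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            surface_from_counts([[0, 0]])

    @given(st.lists(st.lists(st.integers(0, 50), min_size=3, max_size=3),
                    min_size=3, max_size=3))
    def test_monotone_and_nonnegative(self, grid):
        counts = np.array(grid)
        if counts.sum() == 0:
            return
        surf = surface_from_counts(counts)
        assert np.all(surf.dG >= 0)
        pop = counts > 0
        flat_c = counts[pop]
        flat_g = surf.dG[pop]
        order = np.argsort(flat_c)
        assert np.all(np.diff(flat_g[order]) <= 1e-12)  # more counts, lower dG


class TestLevelPopulations:
    def test_single_bin_is_level_one(self):
        lp = level_populations(surface_from_counts([[42]]))
        assert lp.as_dict()[1] == pytest.approx(100.0)

    def test_worked_grid(self):
        lp = level_populations(surface_from_counts([[100, 50], [0, 25]]))
        d = lp.as_dict()
        assert d[1] == pytest.approx(100 * 150 / 175, abs=1e-3)
        assert d[2] == pytest.approx(100 * 25 / 175, abs=1e-3)

    def test_minimum_population_bounds_its_level(self):
        counts = np.array([[36] + [34] * 28])  # argmax bin holds 3.6% of 988
        surf = surface_from_counts(counts)
        _, _, pct = minimum(surf)
        level1 = level_populations(surf).as_dict()[1]
        assert level1 >= pct == pytest.approx(3.6, abs=0.1)

    @given(st.lists(st.lists(st.integers(0, 30), min_size=4, max_size=4),
                    min_size=4, max_size=4))
    def test_percents_sum_to_100(self, grid):
        counts = np.array(grid)
        if counts.sum() == 0:
            return
        lp = level_populations(surface_from_counts(counts))
        assert sum(p for _, p in lp.levels) == pytest.approx(100.0, abs=1e-6)


class TestMinimum:
    def test_worked_grid(self):
        x, y, pct = minimum(surface_from_counts([[100, 50], [0, 25]]))
        assert (x, y) == (pytest.approx(2.05), pytest.approx(2.25))
        assert pct == pytest.approx(100 * 100 / 175, abs=1e-3)

    def test_tie_break_smallest_center_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="scdtraj.landscape"):
            x, y, _ = minimum(surface_from_counts(np.ones((3, 3), dtype=int)))
        assert (x, y) == (pytest.approx(2.05), pytest.approx(2.25))
        assert "tie" in caplog.text

    def test_parameter_recovery_two_state(self, rng):
        # kinked basin at (2.0, 2.2), occupancy 0.9, sd 0.15
        n = 50_000
        kinked = rng.random(n) < 0.9
        x = np.where(kinked, rng.normal(2.0, 0.15, n), rng.normal(4.1, 0.15, n))
        y = np.where(kinked, rng.normal(2.2, 0.15, n), rng.normal(5.6, 0.15, n))
        surf = free_energy(bin2d(series("x", x), series("y", y), 0.1))
        mx, my, _ = minimum(surf)
        assert abs(mx - 2.0) <= 0.1 and abs(my - 2.2) <= 0.1


class TestPool:
    def _pairs(self, k=5, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return [(series("x", rng.normal(2.0, 0.2, n), f"r{i}"),
                 series("y", rng.normal(2.2, 0.2, n), f"r{i}"))
                for i in range(k)]

    def test_total_conservation(self):
        assert pool(self._pairs()).total == 500

    def test_pooling_with_itself_doubles_counts(self):
        pairs = self._pairs(k=1)
        single = bin2d(*pairs[0])
        double = pool(pairs * 2)
        assert double.total == 2 * single.total
        # compare on the common grid
        np.testing.assert_array_equal(double.counts, 2 * single.counts)

    def test_pool_equals_sum_of_replicate_histograms(self):
        pairs = self._pairs(k=3, n=200)
        pooled = pool(pairs)
        manual = np.zeros_like(pooled.counts)
        for x, y in pairs:
            h = bin2d(x, y)
            ox = round((h.x_origin - pooled.x_origin) / 0.1)
            oy = round((h.y_origin - pooled.y_origin) / 0.1)
            manual[ox:ox + h.counts.shape[0], oy:oy + h.counts.shape[1]] += h.counts
        np.testing.assert_array_equal(pooled.counts, manual)

    def test_label_mismatch(self):
        with pytest.raises(ValueError, match="label"):
            pool([(series("x", [1.0]), series("y", [1.0])),
                  (series("x", [1.0]), series("z", [1.0]))])

    def test_pooled_minimum_recovery_across_seeds(self):
        pairs = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            n = 5000
            kinked = rng.random(n) < 0.9
            x = np.where(kinked, rng.normal(2.0, 0.15, n), rng.normal(4.1, 0.15, n))
            y = np.where(kinked, rng.normal(2.2, 0.15, n), rng.normal(5.6, 0.15, n))
            pairs.append((series("d1", x, f"r{seed}"), series("d2", y, f"r{seed}")))
        mx, my, _ = minimum(free_energy(pool(pairs)))
        assert abs(mx - 2.0) <= 0.1 and abs(my - 2.2) <= 0.1


class TestBasins:
    def test_two_state_top2_recovery(self, rng):
        n = 50_000
        kinked = rng.random(n) < 0.7
        x = np.where(kinked, rng.normal(2.0, 0.15, n), rng.normal(4.1, 0.15, n))
        y = np.where(kinked, rng.normal(2.2, 0.15, n), rng.normal(5.6, 0.15, n))
        surf = free_energy(bin2d(series("x", x), series("y", y), 0.1))
        found = basins(surf, barrier_kT=1.0)
        assert len(found) >= 2
        primary, secondary = found[0], found[1]
        assert abs(primary.x_center - 2.0) <= 0.1
        assert abs(primary.y_center - 2.2) <= 0.1
        assert abs(secondary.x_center - 4.1) <= 0.1
        assert abs(secondary.y_center - 5.6) <= 0.1
        assert secondary.barrier >= 1.0

    def test_single_basin_has_no_secondary(self, rng):
        x = rng.normal(2.0, 0.15, 20_000)
        y = rng.normal(2.2, 0.15, 20_000)
        surf = free_energy(bin2d(series("x", x), series("y", y), 0.1))
        found = basins(surf, barrier_kT=1.0)
        assert len(found) == 1 and found[0].barrier == 0.0


class TestHist1d:
    def test_constant_series_modal_bin(self):
        h = hist1d(series("fe", [7.6] * 10), 0.3)
        assert modal_bin(h) == (pytest.approx(7.5), pytest.approx(7.8))

    def test_mode_recovery_truncated_normal(self, rng):
        vals = rng.normal(7.65, 0.5, 40_000)
        vals = vals[(vals >= 6.5) & (vals <= 10.5)][:10_000]
        h = hist1d(series("fe", vals), 0.3)
        lo, hi = modal_bin(h)
        assert (lo, hi) == (pytest.approx(7.5), pytest.approx(7.8))
        assert h.value_min >= 6.5 and h.value_max <= 10.5

    def test_bimodal_heavier_mode_wins(self, rng):
        vals = np.concatenate([rng.normal(7.0, 0.1, 2000),
                               rng.normal(8.4, 0.1, 8000)])
        lo, hi = modal_bin(hist1d(series("fe", vals), 0.3))
        assert lo <= 8.4 <= hi


def test_surface_dataframe_layout():
    surf = surface_from_counts([[100, 50], [0, 25]])
    df = surface_to_dataframe(surf)
    assert set(df.columns) >= {"x_bin_start", "y_bin_start", "count", "rho", "dG_kT"}
    assert len(df) == 4
    assert df["count"].sum() == 175
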