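"""Encounter engine: truncated encounter tables, the within-night capture
process, trap saturation, and multi-night replicate dynamics."""

import numpy as np
import pytest

from multitrap import (
    DetectionParams,
    LayoutSpec,
    PopulationState,
    build_encounter_table,
    build_trap_grid,
    capture_probability,
    resolve_night,
    simulate_replicate,
)
from multitrap.config import ScenarioConfig, scenario_from_dict
from multitrap.engine import replicate_rng, simulate_scenario
from multitrap.immigration import ImmigrationSpec
from multitrap.population import STATUS_CAPTURED
from multitrap.summaries import population_capture_proportion


def _pop_at(centres):
    centres = np.atleast_2d(centres)
    n = len(centres)
    return PopulationState(
        centres=centres, status=np.zeros(n, int), origin=np.zeros(n, int)
    )


def _one_trap_layout(buffer=200.0):
    return LayoutSpec(
        trap_spacing=50, line_spacing=100, traps_per_line=1, n_lines=1,
        buffer=buffer, buffered_area=(2 * buffer) ** 2 / 1e4,
    )


class TestEncounterTable:
    def test_animal_on_trap_has_probability_g0(self, possum_params):
        grid = build_trap_grid(_one_trap_layout(), capacity=1)
        table = build_encounter_table(
            grid, _pop_at(grid.positions[0]), possum_params
        )
        cols, probs = table.row(0)
        assert cols.tolist() == [0]
        assert probs[0] == pytest.approx(possum_params.g0)

    def test_far_animal_has_empty_row(self, possum_params):
        grid = build_trap_grid(_one_trap_layout(), capacity=1)
        far = grid.positions[0] + [6 * possum_params.sigma, 0]
        table = build_encounter_table(grid, _pop_at(far), possum_params, 5.0)
        cols, _ = table.row(0)
        assert len(cols) == 0

    def test_pairs_match_brute_force_distance_scan(self, possum_params):
        cfg = scenario_from_dict({"species": "possum", "density": 1.0})
        grid = build_trap_grid(cfg.layout, capacity=1)
        w, h = cfg.layout.extent
        animal = np.array([w / 2, h / 2])
        table = build_encounter_table(grid, _pop_at(animal), possum_params, 5.0)
        cols, probs = table.row(0)
        d = np.linalg.norm(grid.positions - animal, axis=1)
        expected = np.flatnonzero(d <= 5.0 * possum_params.sigma)
        assert sorted(cols.tolist()) == expected.tolist()
        order = np.argsort(cols)
        np.testing.assert_allclose(
            probs[order], capture_probability(d[expected], possum_params)
        )

    def test_truncation_below_home_range_rejected(self, possum_params):
        grid = build_trap_grid(_one_trap_layout(), capacity=1)
        with pytest.raises(ValueError):
            build_encounter_table(grid, _pop_at(grid.positions[0]),
                                  possum_params, truncation=2.0)


class TestResolveNight:
    def test_single_pair_capture_frequency_matches_probability(self, rng):
        """One animal, one trap: nightly captures are Bernoulli(P)."""
        params = DetectionParams(g0=0.5, sigma=63.0)
        layout = _one_trap_layout()
        grid = build_trap_grid(layout, capacity=1)
        pop0 = _pop_at(grid.positions[0] + [40.0, 0.0])
        table = build_encounter_table(grid, pop0, params)
        p = table.row(0)[1][0]
        n, caught = 10_000, 0
        for _ in range(n):
            grid.reset()
            pop = _pop_at(pop0.centres)
            caught += len(resolve_night(table, grid, pop, rng))
        se = np.sqrt(p * (1 - p) / n)
        assert abs(caught / n - p) < 3 * se

    def test_saturated_trap_never_captures(self, possum_params, rng):
        grid = build_trap_grid(_one_trap_layout(), capacity=1)
        pop = _pop_at(grid.positions[0])
        table = build_encounter_table(grid, pop, possum_params)
        grid.remaining[:] = 0
        grid.active[:] = False
        for _ in range(200):
            assert resolve_night(table, grid, pop, rng) == []

    @pytest.mark.parametrize("assignment", ["hazard", "bernoulli"])
    def test_equidistant_traps_split_evenly(self, assignment, rng):
        """Conditional on capture, two identical equidistant traps are
        chosen 50/50 under either within-night rule."""
        params = DetectionParams(g0=0.5, sigma=63.0)
        layout = LayoutSpec(
            trap_spacing=50, line_spacing=100, traps_per_line=2, n_lines=1,
            buffer=100, buffered_area=10.0,
        )
        counts = np.zeros(2)
        grid = build_trap_grid(layout, capacity=1)
        mid = grid.positions.mean(axis=0)
        pop0 = _pop_at(mid)
        table = build_encounter_table(grid, pop0, params)
        trials = 4000
        for _ in range(trials):
            grid.reset()
            pop = _pop_at(mid)
            for a, t in resolve_night(table, grid, pop, rng,
                                      assignment=assignment):
                counts[t] += 1
        n = counts.sum()
        se = np.sqrt(0.25 * n)
        assert abs(counts[0] - n / 2) < 3 * se


class TestReplicates:
    def _small_cfg(self, small_layout, **kw):
        base = dict(
            detection=DetectionParams(g0=0.05, sigma=63.0),
            layout=small_layout, density=1.2, capacity=2, nights=30,
            replicates=1, seed=7,
        )
        base.update(kw)
        return ScenarioConfig(**base)

    def test_capacity_ceiling_and_conservation(self, small_layout):
        cfg = self._small_cfg(
            small_layout, immigration=ImmigrationSpec(total_immigrants=40)
        )
        res = simulate_replicate(cfg, replicate_rng(cfg.seed, 0))
        assert res.trap_counts.max() <= cfg.capacity
        assert res.trap_counts.sum() == res.n_captured
        assert res.n_exposed == res.n_residents + 40
        # captured + never-captured = exposed, and fates are consistent
        never = res.fate_night == -1
        assert never.sum() + res.n_captured == res.n_exposed
        assert np.all((res.fate_trap == -1) == never)
        assert res.fate_night[~never].min() >= 1
        assert res.fate_night[~never].max() <= cfg.nights

    def test_capacity_one_counts_are_binary(self, small_layout):
        cfg = self._small_cfg(small_layout, capacity=1)
        res = simulate_replicate(cfg, replicate_rng(cfg.seed, 0))
        assert set(np.unique(res.trap_counts)) <= {0, 1}

    def test_single_animal_matches_analytic_escape_probability(self):
        """One animal at distance d from one trap for n nights is captured
        with probability 1 - (1 - P)^n."""
        params = DetectionParams(g0=0.3, sigma=63.0)
        layout = _one_trap_layout(buffer=50.0)
        nights, reps = 5, 4000
        grid = build_trap_grid(layout, capacity=1)
        centre = grid.positions[0] + [50.0, 0.0]
        p = capture_probability(50.0, params)
        expected = 1 - (1 - p) ** nights
        rng = np.random.default_rng(99)
        caught = 0
        pop0 = _pop_at(centre)
        table = build_encounter_table(grid, pop0, params)
        for _ in range(reps):
            grid.reset()
            pop = _pop_at(centre)
            for _night in range(nights):
                if resolve_night(table, grid, pop, rng):
                    caught += 1
                    break
        se = np.sqrt(expected * (1 - expected) / reps)
        assert abs(caught / reps - expected) < 3 * se

    def test_zero_g0_limit_and_zero_density(self, small_layout):
        cfg = self._small_cfg(
            small_layout, detection=DetectionParams(g0=1e-12, sigma=63.0)
        )
        res = simulate_replicate(cfg, replicate_rng(0, 0))
        assert res.n_captured == 0
        cfg0 = self._small_cfg(small_layout, density=0.0)
        res0 = simulate_replicate(cfg0, replicate_rng(0, 0))
        assert res0.n_exposed == 0 and res0.trap_counts.sum() == 0

    def test_expected_captures_monotone(self, small_layout):
        """Mean total captures rise with capacity, g0, nights and density."""
        reps = 50

        def mean_captures(**kw):
            cfg = self._small_cfg(small_layout, replicates=reps, **kw)
            return np.mean(
                [r.n_captured for r in simulate_scenario(cfg)]
            )

        assert mean_captures(capacity=1) <= mean_captures(capacity=3)
        assert (
            mean_captures(detection=DetectionParams(g0=0.02, sigma=63.0))
            <= mean_captures(detection=DetectionParams(g0=0.08, sigma=63.0))
        )
        assert mean_captures(nights=5) <= mean_captures(nights=30)
        assert mean_captures(density=0.4) <= mean_captures(density=1.6)

    def test_truncation_radius_insensitive_beyond_default(self, small_layout):
        """Kill proportion moves < 0.1 percentage point between 5 and 10
        sigma truncation (common random streams)."""
        kills = []
        for trunc in (5.0, 10.0):
            cfg = self._small_cfg(
                small_layout, capacity=1, replicates=60, truncation_sigma=trunc
            )
            kills.append(
                population_capture_proportion(simulate_scenario(cfg))["mean"]
            )
        assert abs(kills[0] - kills[1]) < 0.001

    def test_same_seed_reproduces_replicate(self, small_layout):
        cfg = self._small_cfg(small_layout)
        a = simulate_replicate(cfg, replicate_rng(cfg.seed, 3))
        b = simulate_replicate(cfg, replicate_rng(cfg.seed, 3))
        np.testing.assert_array_equal(a.trap_counts, b.trap_counts)
        np.testing.assert_array_equal(a.fate_night, b.fate_night)
        np.testing.assert_array_equal(a.fate_trap, b.fate_trap)

    def test_immigration_off_is_bit_identical_to_closed_population(
        self, small_layout
    ):
        cfg_none = self._small_cfg(small_layout, immigration=None)
        cfg_zero = self._small_cfg(
            small_layout, immigration=ImmigrationSpec(total_immigrants=0)
        )
        a = simulate_replicate(cfg_none, replicate_rng(11, 0))
        b = simulate_replicate(cfg_zero, replicate_rng(11, 0))
        np.testing.assert_array_equal(a.trap_counts, b.trap_counts)
        np.testing.assert_array_equal(a.fate_night, b.fate_night)

    def test_serialisation_round_trip(self, small_layout, tmp_path):
        cfg = self._small_cfg(small_layout)
        res = simulate_replicate(cfg, replicate_rng(cfg.seed, 0))
        frame = res.to_trap_frame()
        assert list(frame.columns) == ["trap_id", "x", "y", "captures"]
        assert frame["captures"].sum() == res.n_captured
        fates = res.to_fates_dict()
        assert len(fates["animals"]) == res.n_exposed
        captured = [a for a in fates["animals"] if a["night"] is not None]
        assert len(captured) == res.n_captured

    def test_captured_animals_never_return(self, small_layout):
        """Removal trapping: a captured animal's status is terminal."""
        cfg = self._small_cfg(small_layout, capacity=12)
        res = simulate_replicate(cfg, replicate_rng(5, 0))
        # each animal appears at most once across all trap counts
        assert res.trap_counts.sum() == np.sum(res.fate_night != -1)
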