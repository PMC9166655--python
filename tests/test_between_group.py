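import numpy as np
import pytest

from pleiosim.between_group import (
    AgeGrid,
    GlobalSummaries,
    PopulationDensity,
    StackedProfiles,
    advect_age_step,
    apply_sources_sinks,
    global_trait_averages,
    group_birth_rate,
    group_death_rate,
    initial_density,
    mutational_load,
    offspring_type_distribution,
    run_to_steady_state,
    summaries_to_frame,
)
from pleiosim.genotype_space import enumerate_group_types
from pleiosim.within_group import GroupTypeProfile, ModelParams, average_profile


def make_profile(gtype, grid: AgeGrid, freqs, size=100.0):
    """Synthetic profile with age-constant genotype frequencies."""
    freqs = np.asarray(freqs, dtype=float)
    freqs = freqs / freqs.sum()
    m = grid.n_cells
    return GroupTypeProfile(
        gtype=tuple(gtype),
        age_grid=grid.centers,
        mean_counts=np.tile(freqs * size, (m, 1)),
        mean_freqs=np.tile(freqs, (m, 1)),
        n_replicates=1,
        seed=0,
    )


def clonal_profiles(grid: AgeGrid, sizes=None):
    profiles = {}
    for i in range(1, 9):
        freqs = np.zeros(8)
        freqs[i - 1] = 1.0
        size = 100.0 if sizes is None else sizes[i - 1]
        profiles[(i,)] = make_profile((i,), grid, freqs, size=size)
    return profiles


class TestAgeGrid:
    def test_geometry(self):
        g = AgeGrid(dy=0.1, n_cells=50)
        assert g.y_max == pytest.approx(5.0)
        assert len(g.edges) == 51
        np.testing.assert_allclose(g.centers[0], 0.05)

    def test_for_params_spans_ten_lifespans(self):
        g = AgeGrid.for_params(ModelParams(lam=20.0), dy=0.1)
        assert g.y_max == pytest.approx(200.0)


class TestAdvection:
    def test_constant_profile_unchanged_interior(self):
        n = np.full((2, 60), 3.0)
        out = advect_age_step(n, 0.1, 0.09)
        np.testing.assert_allclose(out[:, 1:], n[:, 1:], atol=1e-14)

    def test_pulse_translates_with_mass_conserved(self):
        g = AgeGrid(dy=0.05, n_cells=400)
        n = np.zeros((1, 400))
        n[0, 50:60] = 1.0
        dt = 0.045
        cur = n.copy()
        for _ in range(100):
            cur = advect_age_step(cur, g.dy, dt)
        assert cur.sum() * g.dy == pytest.approx(n.sum() * g.dy, abs=1e-12)
        c0 = (n[0] * g.centers).sum() / n[0].sum()
        c1 = (cur[0] * g.centers).sum() / cur[0].sum()
        assert c1 - c0 == pytest.approx(100 * dt, abs=g.dy)

    def test_total_variation_diminishing(self, rng):
        n = rng.random((1, 200))
        cur = n.copy()
        for _ in range(50):
            new = advect_age_step(cur, 0.1, 0.09)
            tv_old = np.abs(np.diff(cur[0])).sum()
            tv_new = np.abs(np.diff(new[0])).sum()
            assert tv_new <= tv_old + 1e-12
            cur = new

    def test_non_negativity_preserved(self, rng):
        cur = rng.random((3, 100))
        for _ in range(200):
            cur = advect_age_step(cur, 0.1, 0.09)
            assert np.all(cur >= -1e-14)

    def test_outflow_reduces_mass_only_at_boundary(self):
        n = np.zeros((1, 20))
        n[0, -1] = 1.0
        out = advect_age_step(n, 0.1, 0.09)
        assert out.sum() < n.sum()

    def test_cfl_violation_raises(self):
        with pytest.raises(ValueError):
            advect_age_step(np.ones((1, 10)), 0.1, 0.2)


class TestSourcesSinks:
    def test_zero_rates_identity(self, rng):
        n = rng.random((2, 30))
        zero = np.zeros_like(n)
        h = np.zeros((2, 30, 2))
        np.testing.assert_array_equal(
            apply_sources_sinks(n, 0.05, zero, zero, h, 0.1), n
        )

    def test_stationary_balance_single_type(self):
        # constant b = d = rho on an exponential profile: no mass change
        rho = 0.05
        g = AgeGrid(dy=0.1, n_cells=200)
        n = np.exp(-rho * g.centers)[None, :]
        b = np.full_like(n, rho)
        d = np.full_like(n, rho)
        h = np.ones((1, g.n_cells, 1))
        out = apply_sources_sinks(n, 0.09, b, d, h, g.dy)
        assert out.sum() * g.dy == pytest.approx(n.sum() * g.dy, rel=1e-12)

    def test_births_land_in_age_zero_cell(self):
        g = AgeGrid(dy=0.1, n_cells=50)
        n = np.zeros((2, 50))
        n[0, 25] = 1.0
        b = np.full_like(n, 0.1)
        d = np.zeros_like(n)
        # all offspring of type 0 become type-1 groups
        h = np.zeros((2, 50, 2))
        h[:, :, 1] = 1.0
        out = apply_sources_sinks(n, 0.05, b, d, h, g.dy)
        expected = 1.0 * 0.1 * g.dy * 0.05 / g.dy
        assert out[1, 0] == pytest.approx(expected)
        assert out[1, 1:].sum() == 0.0

    def test_negative_density_raises(self):
        n = np.ones((1, 10))
        d = np.full_like(n, 100.0)
        with pytest.raises(ValueError):
            apply_sources_sinks(n, 0.05, np.zeros_like(n), d, np.ones((1, 10, 1)), 0.1)


class TestGroupRates:
    def summaries(self, zbar_r=0.5, zbar_f=0.5):
        return GlobalSummaries(
            time=0.0, zbar_u=0, zbar_v=0, zbar_p=0,
            zbar_f=zbar_f, zbar_r=zbar_r, genotype_freqs=np.zeros(8),
        )

    def test_all_mature_birth_rate_is_rho(self):
        p = ModelParams(alpha=0.0, lam=20.0)
        s = self.summaries(zbar_r=1.0)
        assert group_birth_rate((8,), 3.0, s, p) == pytest.approx(p.rho)

    def test_no_group_selection_birth_rate_rho(self):
        p = ModelParams(s_g=0.0, alpha=0.5, lam=20.0)
        s = self.summaries(zbar_r=0.3)
        assert group_birth_rate((8,), 1.0, s, p) == pytest.approx(p.rho)

    def test_mature_group_birth_rate_by_substitution(self):
        # lam=20, mature group, zbar_r=0.5, s_g=0.95: 0.05 * 1 / 0.525
        p = ModelParams(lam=20.0, alpha=0.5, s_g=0.95)
        s = self.summaries(zbar_r=0.5)
        assert group_birth_rate((8,), 15.0, s, p) == pytest.approx(0.05 * 1.0 / 0.525)

    def test_death_rate_no_selection(self):
        p = ModelParams(s_g=0.0, lam=20.0)
        assert group_death_rate(0.3, self.summaries(), p) == pytest.approx(p.rho)

    def test_death_rate_average_function_is_rho(self):
        p = ModelParams(lam=20.0)
        assert group_death_rate(1.0, self.summaries(zbar_f=1.0), p) == pytest.approx(p.rho)

    def test_death_rate_by_substitution(self):
        # z_f = 0, zbar_f = 0.5, s_g = 0.95, lam = 20: 0.05 * 1 / 0.525
        p = ModelParams(lam=20.0, s_g=0.95)
        assert group_death_rate(0.0, self.summaries(zbar_f=0.5), p) == pytest.approx(
            0.05 / 0.525
        )


class TestOffspringTypes:
    def test_germline_returns_matrix_row(self):
        p = ModelParams(gamma=1.0, mu=0.001)
        g = AgeGrid(dy=0.5, n_cells=10)
        # profile far from clonal: germ line must ignore it
        profiles = {(i,): make_profile((i,), g, np.ones(8)) for i in range(1, 9)}
        stacked = StackedProfiles(profiles, enumerate_group_types(1), g, p)
        h = p.mutation_matrix()
        for y in (0.0, 3.0):
            np.testing.assert_allclose(
                offspring_type_distribution((8,), y, stacked, g), h[7], atol=1e-12
            )

    def test_clonal_group_at_birth_returns_matrix_row(self):
        p = ModelParams(gamma=0.0, mu=0.001)
        g = AgeGrid(dy=0.5, n_cells=10)
        stacked = StackedProfiles(clonal_profiles(g), enumerate_group_types(1), g, p)
        h = p.mutation_matrix()
        np.testing.assert_allclose(
            offspring_type_distribution((8,), 0.0, stacked, g), h[7], atol=1e-12
        )

    def test_degraded_group_transmits_cheater_fraction(self):
        # x_g4 = 0.3, x_g8 = 0.7, mu -> 0: descendant is g4 with prob ~0.3
        p = ModelParams(gamma=0.0, mu=1e-9)
        g = AgeGrid(dy=0.5, n_cells=10)
        profiles = clonal_profiles(g)
        freqs = np.zeros(8)
        freqs[3], freqs[7] = 0.3, 0.7
        profiles[(8,)] = make_profile((8,), g, freqs)
        stacked = StackedProfiles(profiles, enumerate_group_types(1), g, p)
        dist = offspring_type_distribution((8,), 2.0, stacked, g)
        assert dist[3] == pytest.approx(0.3, abs=1e-6)
        assert dist[7] == pytest.approx(0.7, abs=1e-6)

    def test_two_founder_pair_distribution(self):
        p = ModelParams(gamma=0.0, mu=1e-9)
        g = AgeGrid(dy=0.5, n_cells=10)
        gtypes = enumerate_group_types(2)
        profiles = {}
        for gt in gtypes:
            freqs = np.zeros(8)
            freqs[gt[0] - 1] += 0.5
            freqs[gt[1] - 1] += 0.5
            profiles[gt] = make_profile(gt, g, freqs)
        stacked = StackedProfiles(profiles, gtypes, g, p)
        dist = offspring_type_distribution((4, 8), 1.0, stacked, g)
        assert dist.sum() == pytest.approx(1.0, abs=1e-9)
        # unordered pair {g4, g8} from a 50/50 mix: 2 * 0.5 * 0.5
        assert dist[gtypes.index((4, 8))] == pytest.approx(0.5, abs=1e-6)
        assert dist[gtypes.index((4, 4))] == pytest.approx(0.25, abs=1e-6)
        assert dist[gtypes.index((8, 8))] == pytest.approx(0.25, abs=1e-6)

    def test_missing_profile_raises(self):
        p = ModelParams()
        g = AgeGrid(dy=0.5, n_cells=10)
        profiles = clonal_profiles(g)
        del profiles[(5,)]
        with pytest.raises(KeyError):
            StackedProfiles(profiles, enumerate_group_types(1), g, p)


class TestGlobalSummaries:
    def test_clonal_g8_population_all_traits_one(self):
        p = ModelParams()
        g = AgeGrid(dy=0.5, n_cells=10)
        stacked = StackedProfiles(clonal_profiles(g), enumerate_group_types(1), g, p)
        pop = initial_density(enumerate_group_types(1), g, init_type=(8,))
        s = global_trait_averages(pop, stacked)
        assert (s.zbar_u, s.zbar_v, s.zbar_p) == (1.0, 1.0, 1.0)
        np.testing.assert_allclose(s.genotype_freqs[7], 1.0)

    def test_equal_mass_symmetric_mean(self):
        p = ModelParams()
        g = AgeGrid(dy=0.5, n_cells=10)
        stacked = StackedProfiles(clonal_profiles(g), enumerate_group_types(1), g, p)
        density = np.zeros((8, g.n_cells))
        density[0, 0] = 1.0  # g1 groups: all traits 0
        density[7, 0] = 1.0  # g8 groups: all traits 1
        pop = PopulationDensity(density, g, enumerate_group_types(1))
        s = global_trait_averages(pop, stacked)
        assert s.zbar_u == pytest.approx(0.5)
        assert s.zbar_r == 1.0

    def test_cell_weighting_shifts_mean(self):
        # doubling one type's group size shifts the cell-weighted mean
        p = ModelParams()
        g = AgeGrid(dy=0.5, n_cells=10)
        sizes = np.full(8, 100.0)
        sizes[7] = 200.0
        stacked = StackedProfiles(
            clonal_profiles(g, sizes=sizes), enumerate_group_types(1), g, p
        )
        density = np.zeros((8, g.n_cells))
        density[0, 0] = 1.0
        density[7, 0] = 1.0
        pop = PopulationDensity(density, g, enumerate_group_types(1))
        s = global_trait_averages(pop, stacked)
        assert s.zbar_u == pytest.approx(200 / 300)

    def test_mutational_load_zero_for_clonal_profiles(self):
        p = ModelParams()
        g = AgeGrid(dy=0.5, n_cells=10)
        stacked = StackedProfiles(clonal_profiles(g), enumerate_group_types(1), g, p)
        pop = initial_density(enumerate_group_types(1), g, init_type=(8,))
        assert mutational_load(pop, stacked) == (0.0, 0.0, 0.0)

    def test_mutational_load_weighted_sum(self):
        # g8-founded groups degraded to x_g4 = 0.3 at every age:
        # load_u = 1 - 0.7 = 0.3; v and p retained
        p = ModelParams()
        g = AgeGrid(dy=0.5, n_cells=10)
        profiles = clonal_profiles(g)
        freqs = np.zeros(8)
        freqs[3], freqs[7] = 0.3, 0.7
        profiles[(8,)] = make_profile((8,), g, freqs)
        stacked = StackedProfiles(profiles, enumerate_group_types(1), g, p)
        pop = initial_density(enumerate_group_types(1), g, init_type=(8,))
        load = mutational_load(pop, stacked)
        assert load[0] == pytest.approx(0.3)
        assert load[1] == pytest.approx(0.0, abs=1e-12)
        assert load[2] == pytest.approx(0.0, abs=1e-12)


class TestSteadyState:
    def test_neutral_exponential_age_profile(self):
        # single effective type, constant rates b = d = rho:
        # stationary profile is n(y) ~ exp(-rho * y)
        p = ModelParams(lam=20.0, s_g=0.0, mu=1e-9)
        g = AgeGrid(dy=0.1, n_cells=1000)  # y_max = 100 = 5 lam
        stacked = StackedProfiles(clonal_profiles(g), enumerate_group_types(1), g, p)
        pop = initial_density(enumerate_group_types(1), g, init_type=(8,))
        density = pop.density
        dt = 0.09
        rho = p.rho
        b = np.full_like(density, rho)
        d = np.full_like(density, rho)
        for _ in range(int(400 / dt)):
            density = advect_age_step(density, g.dy, dt)
            density = apply_sources_sinks(
                density, dt, b, d, stacked.offspring_types, g.dy
            )
            density /= density.sum() * g.dy
        prof = density.sum(axis=0)
        exact = rho * np.exp(-rho * g.centers)
        exact /= exact.sum() * g.dy
        l2 = np.sqrt(((prof - exact) ** 2).sum() * g.dy)
        assert l2 < 5e-3

    def test_frozen_population_stays_put(self):
        # s_g = 0, mu ~ 0, pure g1: trait means stay at zero forever
        p = ModelParams(lam=5.0, s_g=0.0, mu=1e-12)
        g = AgeGrid.for_params(p, dy=0.1)
        stacked_profiles = clonal_profiles(g)
        pop, summaries = run_to_steady_state(
            p, stacked_profiles, g, t_max=50.0, record_every=5.0
        )
        for s in summaries:
            assert s.zbar_u == pytest.approx(0.0, abs=1e-9)
            assert s.zbar_v == pytest.approx(0.0, abs=1e-9)
            assert s.zbar_p == pytest.approx(0.0, abs=1e-9)

    def test_mass_conserved_without_renormalization(self):
        # normalized rates: population-mean birth = death = rho exactly
        p = ModelParams(lam=5.0, s_g=0.95, mu=1e-6)
        g = AgeGrid.for_params(p, dy=0.1)
        profiles = clonal_profiles(g)
        grid_types = enumerate_group_types(1)
        stacked = StackedProfiles(profiles, grid_types, g, p)
        density = initial_density(grid_types, g).density
        dt = 0.09
        for _ in range(int(2 * p.lam / dt)):
            zbar_f = float((density * stacked.z_f).sum() / density.sum())
            zbar_r = float((density * stacked.z_r[None, :]).sum() / density.sum())
            s = p.s_g
            b = p.rho * (1 - s + s * stacked.z_r[None, :]) / (1 - s + s * zbar_r)
            d = p.rho * (1 - s * stacked.z_f) / (1 - s * zbar_f)
            density = advect_age_step(density, g.dy, dt)
            density = apply_sources_sinks(
                density, dt, np.broadcast_to(b, density.shape), d,
                stacked.offspring_types, g.dy,
            )
        mass = density.sum() * g.dy
        assert mass == pytest.approx(1.0, abs=2e-6)

    def test_real_dynamics_smoke(self):
        # end-to-end at miniature scale: profiles + PDE, non-negative density
        p = ModelParams(K=30, lam=5.0, mu=0.001, phi=1.0)
        g = AgeGrid.for_params(p, dy=0.25)
        profiles = {
            (i,): average_profile((i,), p, 30, g.centers, seed=i)
            for i in range(1, 9)
        }
        pop, summaries = run_to_steady_state(
            p, profiles, g, t_max=100.0, record_every=10.0
        )
        assert np.all(pop.density >= 0)
        assert pop.total_mass == pytest.approx(1.0, rel=1e-9)
        frame = summaries_to_frame(summaries)
        assert {"time", "zbar_u", "freq_g1"} <= set(frame.columns)
        freq_cols = [c for c in frame.columns if c.startswith("freq_")]
        np.testing.assert_allclose(frame[freq_cols].sum(axis=1), 1.0, atol=1e-9)

    def test_incompatible_profile_grid_raises(self):
        p = ModelParams(lam=5.0)
        g = AgeGrid.for_params(p, dy=0.1)
        bad = AgeGrid(dy=0.3, n_cells=30)
        profiles = clonal_profiles(bad)
        with pytest.raises(ValueError):
            run_to_steady_state(p, profiles, g, t_max=1.0)
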