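"""Simulator sub-models against closed-form and distributional oracles."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from larch2s.climate import MonthlyClimateYear
from larch2s.simulator import (
    GMELINII,
    SIBIRICA,
    SPECIES_INDEX,
    PlotState,
    ScenarioSpec,
    SimConfig,
    WeatherIndices,
    competition_index,
    derive_weather_indices,
    disperse_seeds,
    establish,
    grow,
    introduce_seeds,
    mortality_ageing,
    produce_seeds,
    run_scenario,
    stand_density,
    step_year,
)
from larch2s.species import default_species_params

from conftest import constant_series

SIB = SPECIES_INDEX[SIBIRICA]
GME = SPECIES_INDEX[GMELINII]
NO_PREC_LIMIT = SimConfig(prec_ref=None)


def make_plot(Lx=100.0, Ly=100.0, seed=0):
    return PlotState(Lx, Ly, year=0, rng=np.random.default_rng(seed))


def one_tree_plot(height=10.0, species=GME, x=50.0, y=50.0, seed=0, Lx=100.0, Ly=100.0):
    p = make_plot(Lx, Ly, seed=seed)
    p.add_trees([species], [x], [y], [height], [50])
    return p


def flat_params(params, **overrides):
    """Both species share the overridden vital rates (isolates one mechanism)."""
    return {k: dataclasses.replace(v, **overrides) for k, v in params.items()}


# -------------------------------------------------------- weather indices
@pytest.mark.parametrize(
    "tmean, gdd, summer",
    [
        (np.full(12, 5.0), 0.0, 5.0),                       # base-temperature boundary
        (np.full(12, 6.0), 365.0, 6.0),                     # 1 degC x 365 d
        ([0] * 5 + [10, 12, 14] + [0] * 4, None, 12.0),     # Jun-Aug mean
    ],
)
def test_weather_indices(tmean, gdd, summer):
    w = derive_weather_indices(MonthlyClimateYear(2000, np.asarray(tmean, float), np.full(12, 10.0)))
    if gdd is not None:
        assert w.gdd == pytest.approx(gdd)
    assert w.summer_temp == pytest.approx(summer)
    assert w.annual_prec == pytest.approx(120.0)


# ------------------------------------------------------------ competition
def test_competition_empty_plot_is_zero():
    assert competition_index(make_plot(), 50, 50, 10) == 0.0


def test_competition_single_tree_hand_value():
    p = one_tree_plot(height=10.0, x=55.0, y=50.0)
    assert competition_index(p, 50.0, 50.0, 10.0) == pytest.approx(2.0)  # 10 / 5


def test_competition_additivity_symmetric_pair():
    p = make_plot()
    p.add_trees([GME, GME], [45.0, 55.0], [50.0, 50.0], [10.0, 10.0], [50, 50])
    single = competition_index(one_tree_plot(x=55.0), 50.0, 50.0, 10.0)
    assert competition_index(p, 50.0, 50.0, 10.0) == pytest.approx(2 * single)


def test_competition_excludes_tree_at_query_point_and_rejects_bad_radius():
    p = one_tree_plot(x=50.0, y=50.0)
    assert competition_index(p, 50.0, 50.0, 10.0) == 0.0
    with pytest.raises(ValueError):
        competition_index(p, 1.0, 1.0, 0.0)


# ------------------------------------------------------------------ grow
def test_grow_zero_below_gdd_min(params):
    p = one_tree_plot()
    h0 = p.tree_height.copy()
    cold = WeatherIndices(gdd=100.0, summer_temp=2.0, annual_prec=250.0)
    assert all(100.0 <= sp.gdd_min for sp in params.values())
    grow(p, cold, params)
    np.testing.assert_array_equal(p.tree_height, h0)


def test_grow_half_saturation_closed_form(params):
    for sp_name, sp_idx in SPECIES_INDEX.items():
        sp = params[sp_name]
        p = one_tree_plot(species=sp_idx)
        w = WeatherIndices(gdd=sp.gdd_min + sp.gdd_halfsat, summer_temp=10.0, annual_prec=250.0)
        h0 = p.tree_height[0]
        grow(p, w, params)
        assert p.tree_height[0] - h0 == pytest.approx(sp.height_growth_max / 2)


def test_grow_monotone_competition_penalty(params, benign_weather):
    lone = one_tree_plot(height=5.0)
    crowded = one_tree_plot(height=5.0)
    crowded.add_trees([GME], [52.0], [50.0], [20.0], [80])
    grow(lone, benign_weather, params)
    grow(crowded, benign_weather, params)
    assert crowded.tree_height[0] < lone.tree_height[0]


def test_grow_caps_at_max_height(params, benign_weather):
    p = one_tree_plot(height=params[GMELINII].max_height, species=GME)
    grow(p, benign_weather, params)
    assert p.tree_height[0] == params[GMELINII].max_height


# --------------------------------------------------------------- seeds
def test_no_seeds_below_maturity_or_cold(params, benign_weather):
    p = one_tree_plot(height=1.0)
    produce_seeds(p, benign_weather, params)
    assert p.n_seeds == 0
    p2 = one_tree_plot(height=10.0)
    produce_seeds(p2, WeatherIndices(gdd=0.0, summer_temp=0.0, annual_prec=250.0), params)
    assert p2.n_seeds == 0


def test_seed_production_poisson_oracle(params, benign_weather):
    """Sample mean of per-tree seed counts within 3 SE of the Poisson mean."""
    sp = params[GMELINII]
    t = max(0.0, benign_weather.gdd - sp.gdd_min)
    t = t / (t + sp.gdd_halfsat)
    height = sp.maturity_height + 1.0
    mu = sp.fecundity * 1.0 * t
    n = 10_000
    p = make_plot(Lx=100_000.0, Ly=100_000.0, seed=11)
    rng = np.random.default_rng(21)
    p.add_trees([GME] * n, rng.uniform(0, 100_000, n), rng.uniform(0, 100_000, n),
                [height] * n, [50] * n)
    produce_seeds(p, benign_weather, params)
    se = np.sqrt(mu / n)  # mean of n iid Poisson(mu) draws
    assert abs(p.n_seeds / n - mu) < 3 * se


def test_dispersal_degenerate_kernel(params):
    p = make_plot(seed=2)
    p.add_seeds([GME] * 100, [50.0] * 100, [50.0] * 100)
    tiny = flat_params(params, dispersal_mean=1e-9)
    disperse_seeds(p, tiny)
    assert p.n_seeds == 100
    assert np.all(np.hypot(p.seed_x - 50, p.seed_y - 50) < 1e-6)


def test_dispersal_exponential_oracle(params):
    n = 10_000
    p = make_plot(Lx=10_000.0, Ly=10_000.0, seed=3)
    p.add_seeds([SIB] * n, [5000.0] * n, [5000.0] * n)
    disperse_seeds(p, params)
    mean_disp = params[SIBIRICA].dispersal_mean
    d = np.hypot(p.seed_x - 5000, p.seed_y - 5000)
    se = mean_disp / np.sqrt(n)  # exponential: sd = mean
    assert abs(d.mean() - mean_disp) < 3 * se


def test_dispersal_edge_loss_about_half(params):
    """Isotropic kernel from a point on the boundary loses ~50% off-plot."""
    n = 10_000
    p = make_plot(Lx=1000.0, Ly=1000.0, seed=4)
    p.add_seeds([GME] * n, [0.0] * n, [500.0] * n)
    disperse_seeds(p, params)
    lost = n - p.n_seeds
    se = np.sqrt(n * 0.25)
    assert abs(lost - n / 2) < 3 * se


def test_establish_zero_probability(params, benign_weather):
    p = make_plot(seed=5)
    p.add_seeds([GME] * 50, list(np.linspace(1, 99, 50)), [50.0] * 50)
    zero = flat_params(params, estab_prob=0.0)
    establish(p, benign_weather, zero, config=NO_PREC_LIMIT)
    assert p.n_trees == 0 and p.n_seeds == 50


def test_establish_binomial_oracle(params, benign_weather):
    """Establishment count within 3 SE of n*p for isolated seeds."""
    sp = params[GMELINII]
    t = max(0.0, benign_weather.gdd - sp.gdd_min)
    t = t / (t + sp.gdd_halfsat)
    prob = sp.estab_prob * t
    n = 10_000
    p = make_plot(Lx=1000.0, Ly=1000.0, seed=6)
    rng = np.random.default_rng(7)
    p.add_seeds([GME] * n, rng.uniform(0, 1000, n), rng.uniform(0, 1000, n))
    establish(p, benign_weather, params, config=NO_PREC_LIMIT)
    se = np.sqrt(n * prob * (1 - prob))
    assert abs(p.n_trees - n * prob) < 3 * se
    assert p.n_trees + p.n_seeds == n  # established seeds left the bank


def test_establish_crowding_lowers_frequency(params, benign_weather):
    """Two-proportion comparison: empty vs crowded neighbourhoods."""
    n = 4000
    empty = make_plot(seed=8)
    empty.add_seeds([GME] * n, np.full(n, 50.0), np.full(n, 50.0))
    crowded = make_plot(seed=8)
    crowded.add_trees([GME] * 8, list(48 + 4 * np.random.default_rng(1).random(8)),
                      list(48 + 4 * np.random.default_rng(2).random(8)),
                      [20.0] * 8, [100] * 8)
    crowded.add_seeds([GME] * n, np.full(n, 50.0), np.full(n, 50.0))
    establish(empty, benign_weather, params, config=NO_PREC_LIMIT)
    establish(crowded, benign_weather, params, config=NO_PREC_LIMIT)
    p1, p2 = empty.n_trees / n, (crowded.n_trees - 8) / n
    pool = (empty.n_trees + crowded.n_trees - 8) / (2 * n)
    z = (p1 - p2) / np.sqrt(2 * pool * (1 - pool) / n)
    assert z > 3


# ------------------------------------------------------------- mortality
def test_no_mortality_limit(params, benign_weather):
    p = make_plot(seed=9)
    p.add_trees([GME] * 5, list(np.linspace(10, 90, 5)), [50.0] * 5, [5.0] * 5, [10] * 5)
    immortal = flat_params(params, background_mort=0.0, comp_mort_coeff=0.0)
    ages = p.tree_age.copy()
    mortality_ageing(p, benign_weather, immortal)
    assert p.n_trees == 5
    np.testing.assert_array_equal(p.tree_age, ages + 1)


def test_certain_death(params, benign_weather):
    p = make_plot(seed=10)
    p.add_trees([SIB] * 10, list(np.linspace(10, 90, 10)), [50.0] * 10, [5.0] * 10, [10] * 10)
    lethal = flat_params(params, background_mort=1.0)
    mortality_ageing(p, benign_weather, lethal)
    assert p.n_trees == 0


def test_max_age_enforced(params, benign_weather):
    p = make_plot(seed=12)
    p.add_trees([GME], [50.0], [50.0], [10.0], [int(params[GMELINII].max_age)])
    safe = flat_params(params, background_mort=0.0, comp_mort_coeff=0.0)
    mortality_ageing(p, benign_weather, safe)
    assert p.n_trees == 0


def test_mortality_binomial_oracle(params, benign_weather):
    n = 10_000
    p = make_plot(Lx=100_000.0, Ly=100_000.0, seed=13)
    rng = np.random.default_rng(14)
    # isolated trees: spread over a huge plot so NCI = 0
    p.add_trees([GME] * n, rng.uniform(0, 100_000, n), rng.uniform(0, 100_000, n),
                [5.0] * n, [10] * n)
    q = flat_params(params, background_mort=0.02, comp_mort_coeff=0.0)
    mortality_ageing(p, benign_weather, q)
    deaths = n - p.n_trees
    se = np.sqrt(n * 0.02 * 0.98)
    assert abs(deaths - 200) < 3 * se


# ---------------------------------------------------------- introduction
def test_introduce_empty_set_noop(params):
    p = make_plot(seed=15)
    introduce_seeds(p, (), 100.0)
    assert p.n_seeds == 0


def test_introduce_poisson_oracle():
    reps, rate = 400, 100.0
    totals = {SIBIRICA: 0, GMELINII: 0}
    p = make_plot(seed=16)
    for _ in range(reps):
        p._filter_seeds(np.zeros(p.n_seeds, dtype=bool))
        introduce_seeds(p, (SIBIRICA, GMELINII), rate)
        c = p.species_seed_counts()
        for k in totals:
            totals[k] += c[k]
    se = np.sqrt(rate / reps)
    for k in totals:
        assert abs(totals[k] / reps - rate) < 3 * se


def test_introduce_species_closure(params):
    p = make_plot(seed=17)
    introduce_seeds(p, (GMELINII,), 500.0)
    assert np.all(p.seed_species == GME)


# -------------------------------------------------------------- stepping
def test_empty_plot_absorbing(params, benign_weather):
    p = make_plot(seed=18)
    for _ in range(5):
        step_year(p, benign_weather, params)
    assert p.n_trees == 0 and p.n_seeds == 0


def test_step_year_determinism(params, benign_weather):
    def run(seed):
        p = make_plot(seed=seed)
        p.add_trees([GME], [50.0], [50.0], [10.0], [50])
        for _ in range(20):
            step_year(p, benign_weather, params, introduce=(GMELINII,), introduction_rate=100.0)
        return p

    a, b = run(42), run(42)
    assert np.array_equal(a.tree_x, b.tree_x)
    assert np.array_equal(a.tree_height, b.tree_height)
    assert np.array_equal(a.seed_x, b.seed_x)
    assert a.year == b.year


def test_regeneration_from_single_mature_tree(params, benign_weather):
    """A lone mature tree under benign weather leaves descendants within
    50 years in >= 95% of replicate runs."""
    success = 0
    reps = 100
    immortal = {k: dataclasses.replace(v, background_mort=0.0, max_age=10_000)
                for k, v in params.items()}
    for seed in range(reps):
        p = make_plot(Lx=40.0, Ly=40.0, seed=seed)
        p.add_trees([GME], [20.0], [20.0], [10.0], [50])
        for _ in range(50):
            step_year(p, benign_weather, immortal)
            if p.n_trees > 1:
                success += 1
                break
    assert success >= 95


def test_plot_invariants_hold_over_steps(params, benign_weather):
    p = make_plot(seed=19)
    p.add_trees([GME, SIB], [30.0, 70.0], [50.0, 50.0], [10.0, 10.0], [50, 50])
    for _ in range(30):
        step_year(p, benign_weather, params, introduce=(SIBIRICA, GMELINII), introduction_rate=200.0)
        p.check_invariants()


# --------------------------------------------------------------- density
def test_stand_density_counting():
    p = make_plot()
    assert stand_density(p) == {SIBIRICA: 0.0, GMELINII: 0.0}
    p.add_trees([GME] * 137, list(np.linspace(1, 99, 137)), [50.0] * 137, [5.0] * 137, [50] * 137)
    d = stand_density(p, 1.3)
    assert d[GMELINII] == pytest.approx(137.0)
    assert stand_density(p, 6.0)[GMELINII] == 0.0  # cutoff above tallest


# --------------------------------------------------------------- runner
@pytest.fixture(scope="module")
def short_forcing():
    return constant_series(2000, 2049, offset=2.0)


def test_run_scenario_stab_length_and_sim_years(params, short_forcing):
    spec = ScenarioSpec(forcing=short_forcing, stab_years=12, stab_species=(GMELINII,),
                        sim_species=(GMELINII,), replicates=1, seed=1,
                        plot_size=(30.0, 30.0), log_stabilisation=True)
    df = run_scenario(spec, params)[0]
    assert (df["phase"] == "stabilisation").sum() == 12
    assert (df["phase"] == "simulation").sum() == 50


def test_run_scenario_species_closure(params, short_forcing):
    spec = ScenarioSpec(forcing=short_forcing, stab_years=30, stab_species=(GMELINII,),
                        sim_species=(GMELINII,), replicates=2, seed=2, plot_size=(30.0, 30.0))
    for df in run_scenario(spec, params):
        assert (df["density_sibirica"] == 0).all()
        assert (df["seedbank_sibirica"] == 0).all()


def test_run_scenario_deterministic(params, short_forcing):
    spec = ScenarioSpec(forcing=short_forcing, stab_years=20, stab_species=(GMELINII,),
                        sim_species=(GMELINII,), replicates=2, seed=3, plot_size=(30.0, 30.0))
    a = run_scenario(spec, params)
    b = run_scenario(spec, params)
    for x, y in zip(a, b):
        pd.testing.assert_frame_equal(x, y)


def test_run_scenario_extinction_absorbing(params, short_forcing):
    spec = ScenarioSpec(forcing=short_forcing, stab_years=0, stab_species=(),
                        sim_species=(), introduction_rate=0.0, replicates=1, seed=4)
    df = run_scenario(spec, params)[0]
    assert (df[["density_sibirica", "density_gmelinii"]].to_numpy() == 0).all()


def test_run_scenario_rejects_empty_forcing(params, short_forcing):
    with pytest.raises(ValueError):
        ScenarioSpec(forcing=short_forcing, stab_years=-1)
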