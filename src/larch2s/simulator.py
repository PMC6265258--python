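"""Two-species individual-based larch stand simulator.

Spatially explicit, yearly time step.  Each year the sub-models are
invoked in a fixed order — seed introduction (when a scenario phase
prescribes it), growth, seed production, seed dispersal, establishment,
mortality/ageing — on a bounded plot with open (absorbing) boundaries.

Mechanisms, one parameter each:

* temperature response ``T(gdd) = max(0, gdd-gdd_min) /
  (max(0, gdd-gdd_min) + gdd_halfsat)`` — a saturating growing-degree-day
  response shared by growth, seed production and establishment;
* a neighbourhood competition index (NCI) ``sum_j h_j / max(d_j, d_floor)``
  over trees within a radius, penalising growth and establishment
  exponentially and adding to mortality linearly;
* an isotropic exponential dispersal kernel;
* Poisson seed production and Bernoulli establishment/mortality.

Runs are driven by :class:`~larch2s.climate.ClimateSeries` forcing: a
stabilisation phase with weather resampled at random from the first
years of the forcing precedes the forced simulation phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .climate import ClimateSeries, MonthlyClimateYear
from .species import GMELINII, SIBIRICA, SPECIES, SpeciesParams

__all__ = [
    "WeatherIndices",
    "PlotState",
    "SimConfig",
    "ScenarioSpec",
    "derive_weather_indices",
    "competition_index",
    "grow",
    "produce_seeds",
    "disperse_seeds",
    "establish",
    "mortality_ageing",
    "introduce_seeds",
    "step_year",
    "run_scenario",
    "stand_density",
]

DAYS_IN_MONTH = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
GDD_BASE = 5.0  # degC
SPECIES_INDEX = {SIBIRICA: 0, GMELINII: 1}
ESTABLISH_HEIGHT = 0.05  # m, height of a newly established tree


@dataclass(frozen=True)
class WeatherIndices:
    """Yearly weather drivers derived from one monthly record."""

    gdd: float          # degC day above 5 degC
    summer_temp: float  # Jun-Aug mean, degC
    annual_prec: float  # mm

    def __post_init__(self):
        if self.gdd < 0 or self.annual_prec < 0:
            raise ValueError("gdd and annual_prec must be >= 0")


def derive_weather_indices(year_record: MonthlyClimateYear) -> WeatherIndices:
    """Growing-degree-days (base 5 degC, non-leap month lengths),
    June-August mean temperature, and annual precipitation sum."""
    t = np.asarray(year_record.tmean, dtype=float)
    gdd = float(np.sum(np.maximum(0.0, t - GDD_BASE) * DAYS_IN_MONTH))
    return WeatherIndices(
        gdd=gdd,
        summer_temp=float(t[5:8].mean()),
        annual_prec=float(np.sum(year_record.prec)),
    )


@dataclass
class SimConfig:
    """Simulator-level knobs (shared by both species)."""

    nci_radius: float = 10.0    # m
    nci_dist_floor: float = 0.5  # m, avoids singular contributions
    prec_ref: float | None = 250.0  # mm; None disables the precipitation scalar
    density_height_cutoff: float = 1.3  # m, breast height

    def prec_factor(self, annual_prec: float) -> float:
        # establishment scalar, clamped to [0.5, 1]
        if self.prec_ref is None:
            return 1.0
        return float(np.clip(annual_prec / self.prec_ref, 0.5, 1.0))


class PlotState:
    """Spatially explicit stand state: individual trees and a seed bank
    on a bounded ``Lx`` x ``Ly`` plot (m), plus the RNG driving all
    stochastic sub-models."""

    def __init__(self, Lx: float = 100.0, Ly: float = 100.0, year: int = 0, rng=None):
        self.Lx = float(Lx)
        self.Ly = float(Ly)
        self.year = int(year)
        self.rng = rng if rng is not None else np.random.default_rng(0)
        self.tree_species = np.empty(0, dtype=np.int8)
        self.tree_x = np.empty(0)
        self.tree_y = np.empty(0)
        self.tree_height = np.empty(0)
        self.tree_age = np.empty(0, dtype=np.int32)
        self.tree_birth = np.empty(0, dtype=np.int32)  # plot year of establishment
        self.seed_species = np.empty(0, dtype=np.int8)
        self.seed_x = np.empty(0)
        self.seed_y = np.empty(0)
        self.seed_age = np.empty(0, dtype=np.int32)

    # -- bookkeeping --------------------------------------------------
    @property
    def area_ha(self) -> float:
        return self.Lx * self.Ly / 1e4

    @property
    def n_trees(self) -> int:
        return len(self.tree_x)

    @property
    def n_seeds(self) -> int:
        return len(self.seed_x)

    def add_trees(self, species_idx, x, y, height, age, birth=None):
        species_idx = np.asarray(species_idx, dtype=np.int8)
        n = len(species_idx)
        if n == 0:
            return
        self.tree_species = np.concatenate([self.tree_species, species_idx])
        self.tree_x = np.concatenate([self.tree_x, np.asarray(x, dtype=float)])
        self.tree_y = np.concatenate([self.tree_y, np.asarray(y, dtype=float)])
        self.tree_height = np.concatenate([self.tree_height, np.asarray(height, dtype=float)])
        self.tree_age = np.concatenate([self.tree_age, np.asarray(age, dtype=np.int32)])
        if birth is None:
            birth = np.full(n, self.year, dtype=np.int32)
        self.tree_birth = np.concatenate([self.tree_birth, np.asarray(birth, dtype=np.int32)])

    def add_seeds(self, species_idx, x, y, age=None):
        species_idx = np.asarray(species_idx, dtype=np.int8)
        n = len(species_idx)
        if n == 0:
            return
        if age is None:
            age = np.zeros(n, dtype=np.int32)
        self.seed_species = np.concatenate([self.seed_species, species_idx])
        self.seed_x = np.concatenate([self.seed_x, np.asarray(x, dtype=float)])
        self.seed_y = np.concatenate([self.seed_y, np.asarray(y, dtype=float)])
        self.seed_age = np.concatenate([self.seed_age, np.asarray(age, dtype=np.int32)])

    def _filter_trees(self, keep: np.ndarray):
        self.tree_species = self.tree_species[keep]
        self.tree_x = self.tree_x[keep]
        self.tree_y = self.tree_y[keep]
        self.tree_height = self.tree_height[keep]
        self.tree_age = self.tree_age[keep]
        self.tree_birth = self.tree_birth[keep]

    def _filter_seeds(self, keep: np.ndarray):
        self.seed_species = self.seed_species[keep]
        self.seed_x = self.seed_x[keep]
        self.seed_y = self.seed_y[keep]
        self.seed_age = self.seed_age[keep]

    def check_invariants(self):
        """Assert non-negative counts and in-plot coordinates."""
        assert np.all((self.tree_x >= 0) & (self.tree_x < self.Lx))
        assert np.all((self.tree_y >= 0) & (self.tree_y < self.Ly))
        assert np.all((self.seed_x >= 0) & (self.seed_x < self.Lx))
        assert np.all((self.seed_y >= 0) & (self.seed_y < self.Ly))
        assert np.all(self.tree_height > 0)
        assert np.all(self.tree_age >= 0)

    def species_tree_counts(self) -> dict[str, int]:
        return {sp: int(np.sum(self.tree_species == i)) for sp, i in SPECIES_INDEX.items()}

    def species_seed_counts(self) -> dict[str, int]:
        return {sp: int(np.sum(self.seed_species == i)) for sp, i in SPECIES_INDEX.items()}


# ---------------------------------------------------------------------
# Parameter vectorisation helpers
# ---------------------------------------------------------------------

class _ParamArrays:
    """Per-field arrays indexed by species index, for vectorised sub-models."""

    def __init__(self, params: Mapping[str, SpeciesParams]):
        for sp in SPECIES:
            if sp not in params:
                raise ValueError(f"missing parameters for species {sp!r}")
        from dataclasses import fields as _fields

        for f in _fields(SpeciesParams):
            if f.name == "species_id":
                continue
            setattr(self, f.name, np.array([getattr(params[sp], f.name) for sp in SPECIES]))


def _as_param_arrays(params) -> _ParamArrays:
    return params if isinstance(params, _ParamArrays) else _ParamArrays(params)


def _temp_response(gdd: float, gdd_min: np.ndarray, gdd_halfsat: np.ndarray) -> np.ndarray:
    x = np.maximum(0.0, gdd - gdd_min)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(x > 0, x / (x + gdd_halfsat), 0.0)
    return t


# ---------------------------------------------------------------------
# Competition
# ---------------------------------------------------------------------

def competition_index(plot: PlotState, x: float, y: float, radius: float = 10.0,
                      dist_floor: float = 0.5) -> float:
    """Neighbourhood competition index at a point: sum over trees within
    ``radius`` of ``height / max(distance, dist_floor)``, excluding any
    tree at the exact query point."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if plot.n_trees == 0:
        return 0.0
    dx = plot.tree_x - x
    dy = plot.tree_y - y
    d2 = dx * dx + dy * dy
    within = (d2 <= radius * radius) & (d2 > 0)
    if not np.any(within):
        return 0.0
    d = np.sqrt(d2[within])
    return float(np.sum(plot.tree_height[within] / np.maximum(d, dist_floor)))


def _tree_nci(plot: PlotState, radius: float, dist_floor: float) -> np.ndarray:
    """NCI at every tree (excluding itself), via KD-tree neighbour pairs."""
    n = plot.n_trees
    if n < 2:
        return np.zeros(n)
    xy = np.column_stack([plot.tree_x, plot.tree_y])
    tree = cKDTree(xy)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    nci = np.zeros(n)
    if len(pairs) == 0:
        return nci
    i, j = pairs[:, 0], pairs[:, 1]
    d = np.sqrt(np.sum((xy[i] - xy[j]) ** 2, axis=1))
    keep = d > 0  # co-located trees do not see each other (exact-point rule)
    i, j, d = i[keep], j[keep], d[keep]
    d = np.maximum(d, dist_floor)
    np.add.at(nci, i, plot.tree_height[j] / d)
    np.add.at(nci, j, plot.tree_height[i] / d)
    return nci


def _point_nci(plot: PlotState, px: np.ndarray, py: np.ndarray,
               radius: float, dist_floor: float) -> np.ndarray:
    """NCI at arbitrary points (e.g. seed positions)."""
    m = len(px)
    nci = np.zeros(m)
    if plot.n_trees == 0 or m == 0:
        return nci
    txy = np.column_stack([plot.tree_x, plot.tree_y])
    pxy = np.column_stack([px, py])
    ttree = cKDTree(txy)
    ptree = cKDTree(pxy)
    neighbours = ptree.query_ball_tree(ttree, radius)
    counts = np.fromiter((len(nb) for nb in neighbours), dtype=np.int64, count=m)
    if counts.sum() == 0:
        return nci
    flat = np.concatenate([np.asarray(nb, dtype=np.int64) for nb in neighbours if nb])
    rows = np.repeat(np.arange(m), counts)
    d = np.sqrt(np.sum((pxy[rows] - txy[flat]) ** 2, axis=1))
    keep = d > 0
    rows, flat, d = rows[keep], flat[keep], d[keep]
    d = np.maximum(d, dist_floor)
    np.add.at(nci, rows, plot.tree_height[flat] / d)
    return nci


# ---------------------------------------------------------------------
# Sub-models (applied in place, in the yearly order)
# ---------------------------------------------------------------------

def grow(plot: PlotState, weather: WeatherIndices, params, config: SimConfig | None = None) -> PlotState:
    """Height growth: ``height_growth_max * T(gdd) * exp(-comp_sens_growth
    * NCI)``, capped at ``max_height``."""
    config = config or SimConfig()
    p = _as_param_arrays(params)
    if plot.n_trees == 0:
        return plot
    sp = plot.tree_species
    t = _temp_response(weather.gdd, p.gdd_min, p.gdd_halfsat)[sp]
    nci = _tree_nci(plot, config.nci_radius, config.nci_dist_floor)
    inc = p.height_growth_max[sp] * t * np.exp(-p.comp_sens_growth[sp] * nci)
    plot.tree_height = np.minimum(plot.tree_height + inc, p.max_height[sp])
    return plot


def produce_seeds(plot: PlotState, weather: WeatherIndices, params, config: SimConfig | None = None) -> PlotState:
    """Poisson seed production by mature trees, mean ``fecundity *
    (height - maturity_height) * T(gdd)``; seeds start at the parent's
    coordinates with age 0."""
    p = _as_param_arrays(params)
    if plot.n_trees == 0:
        return plot
    sp = plot.tree_species
    excess = plot.tree_height - p.maturity_height[sp]
    mature = excess > 0
    if not np.any(mature):
        return plot
    t = _temp_response(weather.gdd, p.gdd_min, p.gdd_halfsat)[sp[mature]]
    lam = p.fecundity[sp[mature]] * excess[mature] * t
    counts = plot.rng.poisson(lam)
    if counts.sum() == 0:
        return plot
    rep = np.repeat(np.flatnonzero(mature), counts)
    plot.add_seeds(sp[rep], plot.tree_x[rep], plot.tree_y[rep])
    return plot


def disperse_seeds(plot: PlotState, params, rng=None) -> PlotState:
    """Displace every age-0 seed by an exponential distance (mean
    ``dispersal_mean``) in a uniform random direction; seeds landing
    outside the plot are lost (open boundary)."""
    p = _as_param_arrays(params)
    rng = rng if rng is not None else plot.rng
    new = plot.seed_age == 0
    n = int(np.sum(new))
    if n == 0:
        return plot
    sp = plot.seed_species[new]
    r = rng.exponential(p.dispersal_mean[sp])
    theta = rng.uniform(0.0, 2.0 * np.pi, size=n)
    x = plot.seed_x[new] + r * np.cos(theta)
    y = plot.seed_y[new] + r * np.sin(theta)
    plot.seed_x[new] = x
    plot.seed_y[new] = y
    inside = (plot.seed_x >= 0) & (plot.seed_x < plot.Lx) & (plot.seed_y >= 0) & (plot.seed_y < plot.Ly)
    plot._filter_seeds(inside)
    return plot


def establish(plot: PlotState, weather: WeatherIndices, params,
              rng=None, config: SimConfig | None = None) -> PlotState:
    """Each seed germinates into a 0.05 m tree with probability
    ``estab_prob * T(gdd) * exp(-comp_sens_estab * NCI)`` (times an
    optional precipitation scalar); established seeds leave the bank."""
    config = config or SimConfig()
    p = _as_param_arrays(params)
    rng = rng if rng is not None else plot.rng
    if plot.n_seeds == 0:
        return plot
    sp = plot.seed_species
    t = _temp_response(weather.gdd, p.gdd_min, p.gdd_halfsat)[sp]
    nci = _point_nci(plot, plot.seed_x, plot.seed_y, config.nci_radius, config.nci_dist_floor)
    prob = p.estab_prob[sp] * t * np.exp(-p.comp_sens_estab[sp] * nci)
    prob *= config.prec_factor(weather.annual_prec)
    germ = rng.random(len(sp)) < prob
    if np.any(germ):
        plot.add_trees(
            sp[germ], plot.seed_x[germ], plot.seed_y[germ],
            np.full(int(np.sum(germ)), ESTABLISH_HEIGHT), np.zeros(int(np.sum(germ)), dtype=np.int32),
        )
        plot._filter_seeds(~germ)
    return plot


def mortality_ageing(plot: PlotState, weather: WeatherIndices, params,
                     rng=None, config: SimConfig | None = None) -> PlotState:
    """Tree death with probability ``min(1, background_mort +
    comp_mort_coeff * NCI)`` plus certain death at ``max_age``; seed-bank
    death at ``seed_mort``; survivors age by one year, over-age seeds are
    removed."""
    config = config or SimConfig()
    p = _as_param_arrays(params)
    rng = rng if rng is not None else plot.rng
    if plot.n_trees > 0:
        sp = plot.tree_species
        nci = _tree_nci(plot, config.nci_radius, config.nci_dist_floor)
        pdie = np.minimum(1.0, p.background_mort[sp] + p.comp_mort_coeff[sp] * nci)
        die = rng.random(plot.n_trees) < pdie
        die |= plot.tree_age >= p.max_age[sp]
        plot._filter_trees(~die)
        plot.tree_age = plot.tree_age + 1
    if plot.n_seeds > 0:
        sps = plot.seed_species
        die_s = rng.random(plot.n_seeds) < p.seed_mort[sps]
        plot._filter_seeds(~die_s)
        plot.seed_age = plot.seed_age + 1
        plot._filter_seeds(plot.seed_age <= p.max_seed_age[plot.seed_species])
    return plot


def introduce_seeds(plot: PlotState, species_set: Iterable[str], rate: float, rng=None) -> PlotState:
    """Seed rain: per introduced species, Poisson(rate x plot area in ha)
    seeds at uniform random positions, age 0."""
    if rate < 0:
        raise ValueError("introduction rate must be >= 0")
    rng = rng if rng is not None else plot.rng
    for sp in species_set:
        n = int(rng.poisson(rate * plot.area_ha))
        if n == 0:
            continue
        plot.add_seeds(
            np.full(n, SPECIES_INDEX[sp], dtype=np.int8),
            rng.uniform(0.0, plot.Lx, size=n),
            rng.uniform(0.0, plot.Ly, size=n),
        )
    return plot


def step_year(plot: PlotState, weather: WeatherIndices, params,
              introduce: Iterable[str] = (), introduction_rate: float = 0.0,
              config: SimConfig | None = None) -> PlotState:
    """One yearly cycle: introduction (if any), then growth, seed
    production, dispersal, establishment, mortality/ageing, in that
    order; the plot year advances by one."""
    config = config or SimConfig()
    p = _as_param_arrays(params)
    introduce = tuple(introduce)
    if introduce:
        introduce_seeds(plot, introduce, introduction_rate)
    grow(plot, weather, p, config)
    produce_seeds(plot, weather, p, config)
    disperse_seeds(plot, p)
    establish(plot, weather, p, config=config)
    mortality_ageing(plot, weather, p, config=config)
    plot.year += 1
    return plot


def stand_density(plot: PlotState, height_cutoff: float = 1.3) -> dict[str, float]:
    """Trees at or above ``height_cutoff`` per hectare, per species."""
    if height_cutoff < 0:
        raise ValueError("height_cutoff must be >= 0")
    out = {}
    qualifying = plot.tree_height >= height_cutoff
    for sp, i in SPECIES_INDEX.items():
        out[sp] = float(np.sum(qualifying & (plot.tree_species == i)) / plot.area_ha)
    return out


# ---------------------------------------------------------------------
# Scenario runner
# ---------------------------------------------------------------------

@dataclass
class ScenarioSpec:
    """A stabilisation-plus-simulation experiment.

    The stabilisation phase runs ``stab_years`` steps with weather
    resampled uniformly (with replacement) from the first
    ``stab_source_years`` forcing years, introducing ``stab_species``
    seed rain; the simulation phase then steps through the forcing years
    in order with ``sim_species`` introduction.
    """

    forcing: ClimateSeries
    stab_years: int = 1000
    stab_species: tuple[str, ...] = ()
    sim_species: tuple[str, ...] = ()
    introduction_rate: float = 100.0  # seeds/ha/yr per species
    replicates: int = 1
    seed: int = 0
    density_height_cutoff: float = 1.3
    plot_size: tuple[float, float] = (100.0, 100.0)
    stab_source_years: int = 30
    log_stabilisation: bool = False
    tree_cap: int | None = None  # abort a replicate above this tree count

    def __post_init__(self):
        if self.stab_years < 0:
            raise ValueError("stab_years must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for sp in tuple(self.stab_species) + tuple(self.sim_species):
            if sp not in SPECIES:
                raise ValueError(f"unknown species {sp!r}")


def _record_row(plot, weather, cutoff):
    dens = stand_density(plot, cutoff)
    seeds = plot.species_seed_counts()
    total = dens[SIBIRICA] + dens[GMELINII]
    comp = {
        sp: (dens[sp] / total if total > 0 else np.nan) for sp in SPECIES
    }
    # sibirica recruits this year = trees with birth == the year just stepped
    recruits = int(np.sum((plot.tree_species == SPECIES_INDEX[SIBIRICA]) & (plot.tree_birth == plot.year - 1)))
    cohort10 = bool(np.any((plot.tree_species == SPECIES_INDEX[SIBIRICA]) & (plot.tree_birth == plot.year - 1 - 10)))
    return {
        "year": plot.year - 1,
        "density_sibirica": dens[SIBIRICA],
        "density_gmelinii": dens[GMELINII],
        "comp_sibirica": comp[SIBIRICA],
        "comp_gmelinii": comp[GMELINII],
        "seedbank_sibirica": seeds[SIBIRICA],
        "seedbank_gmelinii": seeds[GMELINII],
        "summer_temp": weather.summer_temp,
        "recruits_sibirica": recruits,
        "sib_cohort10_alive": cohort10,
    }


def run_scenario(spec: ScenarioSpec, params, config: SimConfig | None = None) -> list[pd.DataFrame]:
    """Run all replicates of a scenario; returns one yearly stand series
    (a DataFrame) per replicate, covering the simulation phase (and the
    stabilisation phase too when ``log_stabilisation``).

    A replicate whose tree count exceeds ``spec.tree_cap`` is stopped and
    its series flagged ``aborted`` in ``DataFrame.attrs``; other
    replicates are unaffected.
    """
    if len(spec.forcing) < 1:
        raise ValueError("forcing must cover at least one year")
    config = config or SimConfig(density_height_cutoff=spec.density_height_cutoff)
    p = _as_param_arrays(params)
    forcing = spec.forcing
    n_src = min(spec.stab_source_years, len(forcing))
    weather_by_year = [derive_weather_indices(rec) for rec in forcing]

    out = []
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.replicates)
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        plot = PlotState(spec.plot_size[0], spec.plot_size[1], year=int(forcing.start) - spec.stab_years, rng=rng)
        rows = []
        aborted = False
        # stabilisation phase: randomised weather
        for _ in range(spec.stab_years):
            w = weather_by_year[int(rng.integers(0, n_src))]
            step_year(plot, w, p, spec.stab_species, spec.introduction_rate, config)
            if spec.log_stabilisation:
                rows.append({**_record_row(plot, w, spec.density_height_cutoff), "phase": "stabilisation"})
            if spec.tree_cap is not None and plot.n_trees > spec.tree_cap:
                aborted = True
                break
        # simulation phase: forcing years in order
        if not aborted:
            for i in range(len(forcing)):
                w = weather_by_year[i]
                plot.year = int(forcing.years[i])
                step_year(plot, w, p, spec.sim_species, spec.introduction_rate, config)
                row = _record_row(plot, w, spec.density_height_cutoff)
                if spec.log_stabilisation:
                    row["phase"] = "simulation"
                rows.append(row)
                if spec.tree_cap is not None and plot.n_trees > spec.tree_cap:
                    aborted = True
                    break
        df = pd.DataFrame(rows)
        df.attrs["replicate"] = rep
        df.attrs["aborted"] = aborted
        out.append(df)
    return out
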