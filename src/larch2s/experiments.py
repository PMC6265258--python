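"""Experiment orchestration: the spatial seed-introduction matrix and
the multi-millennial temporal runs, with manifests for exact replay.

Two experiment families mirror the simulator's intended use:

* **spatial** — stands under current climate at several sites, crossing
  all 3 x 3 combinations of seed introduction (sibirica / gmelinii /
  both) in the stabilisation and the simulation phase, summarised as the
  mean stand density and composition over the final century;
* **temporal** — mixed-seed runs driven by the bootstrap paleo forcing,
  with an emergence summary: the total stand density in the year of the
  first successful *L. sibirica* establishment (a recruit cohort
  surviving >= 10 years) after the initial *L. gmelinii* dominance.

Default scale is reduced for desk use (0.25-ha plot, 3 replicates,
forcing truncated to the final 2000 years); ``full_scale`` restores the
1-ha, full-span configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import tempfile
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .climate import ClimateSeries, ForcingRecipe, assemble_master_forcing, overlap_means, site_adjust_series
from .simulator import GMELINII, SIBIRICA, ScenarioSpec, SimConfig, run_scenario
from .species import default_species_params
from .synth import ClimateGenSpec, gen_paleo_series, gen_recent_climate

__all__ = [
    "SiteDef",
    "ExperimentConfig",
    "RunManifest",
    "build_site_forcing",
    "run_spatial_matrix",
    "run_temporal_experiment",
    "emergence_summary",
    "write_outputs",
]

INTRO_SETS = {"sibirica": (SIBIRICA,), "gmelinii": (GMELINII,), "both": (SIBIRICA, GMELINII)}


@dataclass(frozen=True)
class SiteDef:
    """A site as an offset from the master grid cell over the overlap
    years: temperature additively (degC), precipitation as a ratio."""

    label: str
    temp_offset: float = 0.0
    prec_factor: float = 1.0


# Khatanga-relative defaults: CH06 in the southern light taiga (warmer),
# CH12 in the northern ecotone, site 4 on single-tree tundra well north
# of the treeline.  Offsets chosen so the simulated recent-epoch stands
# match those field descriptions (dense taiga / sparse ecotone / single
# trees).
DEFAULT_SITES = (
    SiteDef("CH06", temp_offset=1.5),
    SiteDef("CH12", temp_offset=-0.75),
    SiteDef("site4", temp_offset=-1.5),
)


@dataclass
class ExperimentConfig:
    """Shared configuration for both experiment families."""

    sites: tuple[SiteDef, ...] = DEFAULT_SITES
    replicates: int = 3
    seed: int = 0
    stab_years: int = 1000
    introduction_rate: float = 100.0
    density_height_cutoff: float = 1.3
    plot_size: tuple[float, float] = (50.0, 50.0)  # 0.25 ha desk scale
    forcing_truncate: int | None = 2000  # temporal: keep final N years; None = full 5996
    spatial_sim_years: int = 200         # spatial: simulation-phase length
    summary_window: int = 100            # final years averaged for the matrix summary
    tree_cap: int = 1_000_000
    full_scale: bool = False

    def __post_init__(self):
        if self.full_scale:
            self.plot_size = (100.0, 100.0)
            self.forcing_truncate = None

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sites"] = [dataclasses.asdict(s) for s in self.sites]
        return d


@dataclass
class RunManifest:
    """Everything needed to byte-replay a run."""

    experiment: str
    config: dict
    seeds: dict
    package_version: str = __version__
    timestamp: str = ""
    input_checksums: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.timestamp:
            self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())

    @staticmethod
    def checksum(path) -> str:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)

    def verify_inputs(self):
        for path, digest in self.input_checksums.items():
            actual = self.checksum(path)
            if actual != digest:
                raise ValueError(f"checksum mismatch for {path}: {actual} != {digest}")


# ---------------------------------------------------------------------
# Forcing construction for the experiments
# ---------------------------------------------------------------------

def build_master_forcing(seed: int, recipe: ForcingRecipe | None = None,
                         climate_spec: ClimateGenSpec | None = None) -> ClimateSeries:
    """Synthetic recent + paleo series spliced into the 5996-yr master
    forcing (-3982..2013)."""
    recipe = recipe or ForcingRecipe(rng_seed=seed)
    base = climate_spec or ClimateGenSpec()
    recent = dataclasses.replace(base, span=(recipe.overlap[0], recipe.overlap[1]), seed=seed + 1)
    paleo = dataclasses.replace(base, span=(recipe.target_start, recipe.overlap[1]), seed=seed + 2)
    real = gen_recent_climate(recent)
    simulated = gen_paleo_series(paleo)
    return assemble_master_forcing(real, simulated, recipe)


def build_site_forcing(master: ClimateSeries, site: SiteDef,
                       overlap: tuple[int, int] = (1934, 2013)) -> ClimateSeries:
    """Apply a site's overlap-mean offsets to the master series."""
    mt, mp = overlap_means(master, overlap)
    return site_adjust_series(
        master, (mt, mp), (mt + site.temp_offset, mp * site.prec_factor), label=site.label
    )


# ---------------------------------------------------------------------
# Spatial 3 x 3 matrix
# ---------------------------------------------------------------------

def run_spatial_matrix(config: ExperimentConfig, params=None, master: ClimateSeries | None = None) -> pd.DataFrame:
    """Current-climate stands for every site and every stab x sim seed
    introduction combination; per cell and replicate, mean density per
    species and composition over the final ``summary_window`` years.

    Replicates whose tree count exceeds ``config.tree_cap`` are flagged
    aborted and excluded from the cell means; other cells are unaffected.
    """
    params = params or default_species_params()
    base = ClimateGenSpec()
    recent = gen_recent_climate(dataclasses.replace(base, seed=config.seed + 11))
    rows = []
    for s_i, site in enumerate(config.sites):
        site_forcing = build_site_forcing(recent, site, overlap=(recent.start, recent.end))
        # recycle the recent record to the requested simulation length
        reps = -(-config.spatial_sim_years // len(site_forcing))
        years = np.arange(site_forcing.start, site_forcing.start + len(site_forcing) * reps)[: config.spatial_sim_years]
        tm = np.tile(site_forcing.tmean, (reps, 1))[: config.spatial_sim_years]
        pr = np.tile(site_forcing.prec, (reps, 1))[: config.spatial_sim_years]
        forcing = ClimateSeries(years, tm, pr, label=site.label)
        for g_i, stab in enumerate(("sibirica", "gmelinii", "both")):
            for h_i, sim in enumerate(("sibirica", "gmelinii", "both")):
                spec = ScenarioSpec(
                    forcing=forcing,
                    stab_years=config.stab_years,
                    stab_species=INTRO_SETS[stab],
                    sim_species=INTRO_SETS[sim],
                    introduction_rate=config.introduction_rate,
                    replicates=config.replicates,
                    seed=config.seed + 1000 * s_i + 100 * g_i + 10 * h_i,
                    density_height_cutoff=config.density_height_cutoff,
                    plot_size=config.plot_size,
                    tree_cap=config.tree_cap,
                )
                for series in run_scenario(spec, params):
                    aborted = series.attrs["aborted"]
                    tail = series.tail(config.summary_window)
                    d_sib = float(tail["density_sibirica"].mean()) if not aborted else np.nan
                    d_gme = float(tail["density_gmelinii"].mean()) if not aborted else np.nan
                    total = (d_sib or 0) + (d_gme or 0)
                    rows.append(
                        {
                            "site": site.label,
                            "stab_species": stab,
                            "sim_species": sim,
                            "replicate": series.attrs["replicate"],
                            "density_sibirica": d_sib,
                            "density_gmelinii": d_gme,
                            "comp_sibirica": d_sib / total if total else np.nan,
                            "aborted": aborted,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Temporal experiment
# ---------------------------------------------------------------------

def emergence_summary(series: pd.DataFrame) -> dict:
    """First successful sibirica establishment after initial gmelinii
    dominance, and the total stand density in that year.

    A cohort established in year y is successful when at least one of
    its recruits is still alive ten years later; dominance onset is the
    first recorded year with gmelinii present and sibirica absent.
    """
    years = series["year"].to_numpy()
    ok = series["sib_cohort10_alive"].to_numpy(dtype=bool)
    dom = (series["density_gmelinii"] > 0) & (series["density_sibirica"] == 0)
    onset = years[np.argmax(dom.to_numpy())] if dom.any() else None
    out = {"onset_year": onset, "emergence_year": None, "emergence_density": np.nan}
    if onset is None:
        return out
    cohort_years = years[ok] - 10
    cohort_years = cohort_years[cohort_years > onset]
    if len(cohort_years) == 0:
        return out
    y = int(cohort_years.min())
    row = series.loc[series["year"] == y]
    if len(row) == 0:
        return out
    out["emergence_year"] = y
    out["emergence_density"] = float(
        row["density_sibirica"].iloc[0] + row["density_gmelinii"].iloc[0]
    )
    return out


def run_temporal_experiment(config: ExperimentConfig, params=None,
                            sites: tuple[SiteDef, ...] | None = None):
    """Mixed-introduction paleo-forced runs per site.

    Returns ``(series_by_site, summary)``: the per-replicate yearly stand
    series and a summary table with one row per site x replicate holding
    the sibirica emergence year and the total density in that year.
    """
    params = params or default_species_params()
    sites = sites if sites is not None else config.sites
    master = build_master_forcing(config.seed)
    series_by_site: dict[str, list[pd.DataFrame]] = {}
    rows = []
    for s_i, site in enumerate(sites):
        forcing = build_site_forcing(master, site)
        if config.forcing_truncate is not None and config.forcing_truncate < len(forcing):
            forcing = forcing.slice_years(forcing.end - config.forcing_truncate + 1, forcing.end)
        spec = ScenarioSpec(
            forcing=forcing,
            stab_years=config.stab_years,
            stab_species=INTRO_SETS["both"],
            sim_species=INTRO_SETS["both"],
            introduction_rate=config.introduction_rate,
            replicates=config.replicates,
            seed=config.seed + 7919 * (s_i + 1),
            density_height_cutoff=config.density_height_cutoff,
            plot_size=config.plot_size,
            tree_cap=config.tree_cap,
        )
        reps = run_scenario(spec, params)
        series_by_site[site.label] = reps
        for series in reps:
            summ = emergence_summary(series)
            rows.append(
                {
                    "site": site.label,
                    "replicate": series.attrs["replicate"],
                    "aborted": series.attrs["aborted"],
                    **summ,
                }
            )
    return series_by_site, pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Output writing
# ---------------------------------------------------------------------

def _atomic_write(text: str, path: Path):
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=path.name + ".")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_outputs(results: dict[str, pd.DataFrame], manifest: RunManifest, outdir) -> list[Path]:
    """Write result tables as TSV and the manifest as JSON, atomically
    (no partial files on error); returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not os.access(outdir, os.W_OK):
        raise PermissionError(f"output directory {outdir} is not writable")
    written = []
    for name, df in results.items():
        path = outdir / f"{name}.tsv"
        _atomic_write(df.to_csv(sep="\t", index=False), path)
        written.append(path)
    mpath = outdir / "manifest.json"
    _atomic_write(manifest.to_json(), mpath)
    written.append(mpath)
    return written
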