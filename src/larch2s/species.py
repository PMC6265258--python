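"""Per-species vital-rate parameter sets.

Two species are modelled: *Larix sibirica* (fast-growing, far-dispersing,
but competition- and cold-sensitive) and *Larix gmelinii* (slower but
more tolerant of competition and of short, cold growing seasons).  The
shipped defaults are calibrated so that the simulator reproduces the
field's qualitative pattern — gmelinii dominance in dense stands, mixed
stands only where cooling keeps the stand sparse — rather than
transcribed from any single source.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, fields
from typing import Mapping

import yaml

SIBIRICA = "sibirica"
GMELINII = "gmelinii"
SPECIES = (SIBIRICA, GMELINII)

_PROB_FIELDS = {"estab_prob", "background_mort", "seed_mort"}
_NONNEG_FIELDS = {
    "height_growth_max", "gdd_min", "gdd_halfsat", "comp_sens_growth",
    "comp_sens_estab", "comp_mort_coeff", "fecundity", "maturity_height",
    "dispersal_mean", "max_seed_age", "max_age", "max_height",
}


@dataclass(frozen=True)
class SpeciesParams:
    """Vital rates of one larch species.

    Units: heights/distances in m, rates per year, temperature sums in
    growing-degree-days (degC day above 5 degC).

    ``fecundity`` is seeds per metre of height above ``maturity_height``
    per year at the temperature optimum; ``comp_sens_*`` are exponential
    penalties per unit of the neighbourhood competition index; and
    ``comp_mort_coeff`` adds mortality linearly in that index.
    """

    species_id: str
    height_growth_max: float   # m/yr at temperature optimum, no competition
    gdd_min: float             # degC day; no growth/establishment below
    gdd_halfsat: float         # degC day; half-saturation above gdd_min
    comp_sens_growth: float
    comp_sens_estab: float
    comp_mort_coeff: float     # 1/yr per unit NCI
    fecundity: float           # seeds per m above maturity per yr
    maturity_height: float     # m
    dispersal_mean: float      # m, mean of 2-D exponential kernel
    estab_prob: float          # per-seed per-yr at optimum
    background_mort: float     # 1/yr
    seed_mort: float           # 1/yr in seed bank
    max_seed_age: float        # yr
    max_age: float             # yr
    max_height: float          # m

    def __post_init__(self):
        if self.species_id not in SPECIES:
            raise ValueError(f"unknown species_id {self.species_id!r}")
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in _PROB_FIELDS and not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name} must be a probability in [0,1], got {v}")
            if f.name in _NONNEG_FIELDS and v < 0:
                raise ValueError(f"{f.name} must be >= 0, got {v}")


def load_species_params(path) -> dict[str, SpeciesParams]:
    """Load a YAML parameter file with one block per species."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return _params_from_mapping(raw)


def _params_from_mapping(raw: Mapping) -> dict[str, SpeciesParams]:
    blocks = raw.get("species", raw)
    out = {}
    for sp, block in blocks.items():
        if sp in ("version",):
            continue
        out[sp] = SpeciesParams(species_id=sp, **block)
    missing = set(SPECIES) - set(out)
    if missing:
        raise ValueError(f"parameter file missing species {sorted(missing)}")
    return out


def default_species_params() -> dict[str, SpeciesParams]:
    """The versioned default parameter file shipped in-package."""
    ref = importlib.resources.files("larch2s.data").joinpath("species_params.yaml")
    with importlib.resources.as_file(ref) as p:
        return load_species_params(p)
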