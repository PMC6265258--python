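"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here so that every
stage runs offline:

* recent monthly climate (CRU-grid-cell-like, 1934-2013) with AR(1)
  interannual anomalies;
* a multi-millennial paleo series emulating an earth-system-model run —
  the same noise structure plus a smooth Holocene cooling trend of
  ~2 degC whose minimum sits ~200 years before the series end, followed
  by a partial recent recovery;
* amplicon reads of the 61-bp nad4 fragment as a two-variant mixture
  with i.i.d. per-base substitution error, with a per-read truth table;
* coupled DNA/pollen taxa count tables driven by one shared latent
  vegetation-turnover gradient (softmax taxon responses, multinomial
  counts at each proxy's depth).

All generators are deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import ClimateSeries
from .seddna import AmpliconReference, TaxaTable, default_reference
from .species import GMELINII, SIBIRICA

__all__ = [
    "ClimateGenSpec",
    "ReadGenSpec",
    "TableGenSpec",
    "gen_recent_climate",
    "gen_paleo_series",
    "gen_amplicon_reads",
    "gen_coupled_taxa_tables",
    "KHATANGA_NORMALS_T",
    "KHATANGA_NORMALS_P",
]

# Monthly climate normals emulating the Khatanga-area CRU grid cell
# (71.75N, 102.25E): strongly continental, ~460 degC day GDD5, ~280 mm/yr.
KHATANGA_NORMALS_T = np.array(
    [-33.0, -31.0, -24.0, -14.0, -4.0, 7.0, 13.0, 10.0, 3.0, -9.0, -24.0, -30.0]
)
KHATANGA_NORMALS_P = np.array(
    [16.0, 13.0, 15.0, 14.0, 20.0, 32.0, 44.0, 42.0, 34.0, 25.0, 16.0, 14.0]
)


@dataclass
class ClimateGenSpec:
    """Stochastic monthly climate: normals + AR(1) yearly temperature
    anomaly + monthly white noise; precipitation gets multiplicative
    noise.  ``trend_amplitude`` (degC) and ``trend_min_before_end`` (yr)
    describe the long-term cooling used by :func:`gen_paleo_series`:
    temperatures start ``trend_amplitude`` above the minimum, reach the
    minimum ``trend_min_before_end`` years before the series end, and
    recover by ``trend_recovery`` degC afterwards."""

    span: tuple[int, int] = (1934, 2013)
    monthly_normals_t: np.ndarray = field(default_factory=lambda: KHATANGA_NORMALS_T.copy())
    monthly_normals_p: np.ndarray = field(default_factory=lambda: KHATANGA_NORMALS_P.copy())
    interannual_sd: float = 0.8   # degC, stationary SD of the yearly anomaly
    ar1_coeff: float = 0.3
    monthly_sd: float = 0.5       # degC, white monthly noise
    prec_cv: float = 0.3          # multiplicative precipitation noise CV
    trend_amplitude: float = 2.0  # degC cooling from series start to minimum
    trend_min_before_end: int = 200
    trend_recovery: float = 1.0   # degC regained between minimum and end
    seed: int = 0

    def __post_init__(self):
        if self.span[1] < self.span[0]:
            raise ValueError("empty span")
        if self.interannual_sd < 0 or self.monthly_sd < 0 or self.prec_cv < 0:
            raise ValueError("noise scales must be >= 0")
        if not abs(self.ar1_coeff) < 1:
            raise ValueError("|ar1_coeff| must be < 1")


def _noise_series(spec: ClimateGenSpec, rng, n: int):
    """Yearly AR(1) anomaly (stationary SD = interannual_sd) and monthly
    white noise."""
    if spec.interannual_sd > 0:
        innov_sd = spec.interannual_sd * np.sqrt(1.0 - spec.ar1_coeff**2)
        eps = rng.normal(0.0, innov_sd, size=n)
        anom = np.empty(n)
        a = rng.normal(0.0, spec.interannual_sd)
        for i in range(n):
            a = spec.ar1_coeff * a + eps[i]
            anom[i] = a
    else:
        anom = np.zeros(n)
        rng.normal(size=n + 1)  # keep the stream aligned across settings
    monthly = rng.normal(0.0, spec.monthly_sd, size=(n, 12)) if spec.monthly_sd > 0 else np.zeros((n, 12))
    if spec.prec_cv > 0:
        pnoise = np.maximum(0.0, rng.normal(1.0, spec.prec_cv, size=(n, 12)))
    else:
        pnoise = np.ones((n, 12))
    return anom, monthly, pnoise


def gen_recent_climate(spec: ClimateGenSpec, label: str = "synthetic-recent") -> ClimateSeries:
    """Stationary synthetic climate over ``spec.span``; the realised
    yearly anomalies are stored in ``series.meta['yearly_anomaly']``."""
    rng = np.random.default_rng(spec.seed)
    y0, y1 = spec.span
    n = y1 - y0 + 1
    anom, monthly, pnoise = _noise_series(spec, rng, n)
    tmean = spec.monthly_normals_t[None, :] + anom[:, None] + monthly
    prec = spec.monthly_normals_p[None, :] * pnoise
    s = ClimateSeries(np.arange(y0, y1 + 1), tmean, prec, label=label)
    s.meta["yearly_anomaly"] = anom
    return s


def _cooling_trend(spec: ClimateGenSpec, n: int) -> np.ndarray:
    """Smooth cosine decline of ``trend_amplitude`` degC from the series
    start to a minimum ``trend_min_before_end`` years before the end,
    then a linear recovery of ``trend_recovery`` degC."""
    i_min = n - 1 - spec.trend_min_before_end
    if i_min <= 0:
        raise ValueError("trend minimum lies before the series start")
    t = np.arange(n, dtype=float)
    trend = np.empty(n)
    ramp = 0.5 * (1.0 - np.cos(np.pi * t[: i_min + 1] / i_min))
    trend[: i_min + 1] = -spec.trend_amplitude * ramp
    n_rec = n - 1 - i_min
    recov = min(spec.trend_recovery, spec.trend_amplitude)
    trend[i_min + 1 :] = -spec.trend_amplitude + recov * (t[i_min + 1 :] - i_min) / n_rec
    return trend


def gen_paleo_series(spec: ClimateGenSpec, label: str = "synthetic-paleo") -> ClimateSeries:
    """Paleo series: stationary noise plus the long-term cooling trend
    (applied to all months).  The trend is stored in
    ``series.meta['trend']``; the summer-mean difference between the
    first year and the coolest year equals ``trend_amplitude`` up to
    noise."""
    y0, y1 = spec.span
    n = y1 - y0 + 1
    if n < 1000:
        raise ValueError("paleo span must cover at least 1000 years")
    rng = np.random.default_rng(spec.seed)
    anom, monthly, pnoise = _noise_series(spec, rng, n)
    trend = _cooling_trend(spec, n) if spec.trend_amplitude != 0 else np.zeros(n)
    tmean = spec.monthly_normals_t[None, :] + (anom + trend)[:, None] + monthly
    prec = spec.monthly_normals_p[None, :] * pnoise
    s = ClimateSeries(np.arange(y0, y1 + 1), tmean, prec, label=label)
    s.meta["yearly_anomaly"] = anom
    s.meta["trend"] = trend
    return s


# ---------------------------------------------------------------------
# Amplicon reads
# ---------------------------------------------------------------------

@dataclass
class ReadGenSpec:
    """A two-variant read mixture with i.i.d. substitution errors."""

    n_reads: int = 1000
    mixture: float = 0.5      # fraction sibirica
    error_rate: float = 0.01  # per base
    length: int = 61
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.mixture <= 1.0:
            raise ValueError("mixture must be in [0,1]")
        if not 0.0 <= self.error_rate <= 0.25:
            raise ValueError("error_rate must be in [0, 0.25]")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def gen_amplicon_reads(spec: ReadGenSpec, ref: AmpliconReference | None = None):
    """Generate reads and a truth table.

    Returns ``(reads, truth)``: ``reads`` is a list of ``(read_id,
    sequence)`` tuples and ``truth`` a DataFrame with the source variant
    per read id.
    """
    ref = ref or default_reference()
    rng = np.random.default_rng(spec.seed)
    variants = {
        SIBIRICA: np.frombuffer(ref.variant_sequence(SIBIRICA).encode(), dtype="S1"),
        GMELINII: np.frombuffer(ref.variant_sequence(GMELINII).encode(), dtype="S1"),
    }
    is_sib = rng.random(spec.n_reads) < spec.mixture
    reads, labels = [], []
    for i in range(spec.n_reads):
        variant = SIBIRICA if is_sib[i] else GMELINII
        seq = variants[variant].copy()
        if spec.error_rate > 0:
            hit = rng.random(len(seq)) < spec.error_rate
            k = int(hit.sum())
            if k:
                # substitute with one of the three other bases
                cur = seq[hit]
                repl = _BASES[rng.integers(0, 4, size=k)]
                same = repl == cur
                while np.any(same):
                    repl[same] = _BASES[rng.integers(0, 4, size=int(same.sum()))]
                    same = repl == cur
                seq[hit] = repl
        reads.append((f"read_{i}", seq.tobytes().decode()))
        labels.append(variant)
    truth = pd.DataFrame({"read_id": [r[0] for r in reads], "variant": labels})
    return reads, truth


def write_fastq(reads, path, quality: int = 38) -> None:
    """Write ``(read_id, sequence)`` tuples as FASTQ with constant
    quality."""
    with open(path, "w") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{chr(quality + 33) * len(seq)}\n")


# ---------------------------------------------------------------------
# Coupled taxa tables
# ---------------------------------------------------------------------

_DEFAULT_TAXA = {
    # taxon -> (genus, baseline log-abundance, response to the gradient)
    "Larix": ("Larix", 0.5, 2.0),
    "Picea obovata": ("Picea", -1.0, 1.2),
    "Betula nana": ("Betula", 0.8, -0.8),
    "Betula pubescens": ("Betula", -0.5, 0.6),
    "Alnus": ("Alnus", 0.0, 0.4),
    "Salix": ("Salix", 0.2, -0.6),
    "Ericaceae": ("Ericaceae", 0.3, -1.2),
    "Cyperaceae": ("Cyperaceae", 0.6, -1.5),
    "Poaceae": ("Poaceae", 0.4, -1.0),
    "Artemisia": ("Artemisia", -0.3, -0.9),
}


@dataclass
class TableGenSpec:
    """Coupled DNA/pollen tables: per-sample taxon probabilities are a
    softmax of taxon responses to one shared latent gradient, sampled
    multinomially at each proxy's count depth with proxy-specific
    response jitter."""

    n_samples: int = 20
    taxa: dict = field(default_factory=lambda: dict(_DEFAULT_TAXA))
    gradient: np.ndarray | None = None  # default: linear turnover, forest -> tundra
    jitter_sd: float = 0.3    # per-proxy, per-taxon-and-sample log-abundance noise
    dna_depth: int = 5000     # reads per sample
    pollen_depth: int = 300   # grains per sample (field-standard minimum count)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("need at least 1 sample")
        if self.dna_depth < 1 or self.pollen_depth < 1:
            raise ValueError("count depths must be >= 1")
        if self.gradient is None:
            self.gradient = np.linspace(1.0, -1.0, self.n_samples)
        self.gradient = np.asarray(self.gradient, dtype=float)
        if len(self.gradient) != self.n_samples or not np.all(np.isfinite(self.gradient)):
            raise ValueError("gradient must be finite with one value per sample")


def gen_coupled_taxa_tables(spec: TableGenSpec):
    """Returns ``(dna_table, pollen_table, gradient)``; both
    :class:`~larch2s.seddna.TaxaTable` share the latent gradient."""
    rng = np.random.default_rng(spec.seed)
    taxa = list(spec.taxa)
    genus_map = {t: spec.taxa[t][0] for t in taxa}
    alpha = np.array([spec.taxa[t][1] for t in taxa])
    beta = np.array([spec.taxa[t][2] for t in taxa])
    g = spec.gradient

    sample_ids = [f"S{i:02d}" for i in range(spec.n_samples)]
    ages = np.linspace(0.0, 7000.0, spec.n_samples)
    tables = {}
    for proxy, depth in (("DNA", spec.dna_depth), ("pollen", spec.pollen_depth)):
        logit = alpha[None, :] + np.outer(g, beta)
        if spec.jitter_sd > 0:
            logit = logit + rng.normal(0.0, spec.jitter_sd, size=logit.shape)
        p = np.exp(logit - logit.max(axis=1, keepdims=True))
        p /= p.sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(depth, p[i]) for i in range(spec.n_samples)])
        meta = pd.DataFrame(
            {"depth_cm": np.linspace(0.0, 100.0, spec.n_samples), "age_calbp": ages, "proxy": proxy},
            index=sample_ids,
        )
        tables[proxy] = TaxaTable(
            counts=pd.DataFrame(counts, index=sample_ids, columns=taxa),
            meta=meta,
            genus_map=dict(genus_map),
        )
    return tables["DNA"], tables["pollen"], g.copy()
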