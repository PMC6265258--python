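# Methods

## 1. Scientific setting

Two larch species meet at the treeline ecotone of the southern Taymyr
peninsula: *Larix sibirica* to the west/south and *L. gmelinii* to the
east.  Because the larch seed carries the mitochondrial genome, the
diagnostic mitochondrial *nad4* SNP separates the two lineages in
sediment-archived DNA, and stand simulations can ask under which
conditions the two species coexist.  The package implements both lines
of evidence — an individual-based two-species stand simulator with its
climate forcing, and the sedaDNA variant/ordination analysis — plus
generators that produce every input synthetically with known truth.

## 2. Climate forcing

A forcing series is a contiguous run of years, each with 12 monthly
temperature means (°C) and precipitation sums (mm).

**Window bootstrap.**  The master series spans −3982–2013 (5996 years).
The pre-observational part (−3982–1933) is a concatenation of 19-year
windows drawn uniformly at random (with replacement, seeded) from the
observed 1934–2013 record; the observed years themselves are appended
verbatim.  Each window is adjusted to the corresponding window of a
long simulated (paleo) series: all monthly temperatures are shifted by
one additive offset so that the pooled window mean matches, and all
monthly precipitation values are multiplied by one factor so that the
pooled window mean matches (floored at `prec_floor ≥ 0`).  Design
choices where the procedure is under-determined:

* 5916 pre-overlap years are not divisible by 19; the final block is
  truncated to the remaining 7 years and adjusted against the same
  truncated span of the simulated series (312 blocks in total).
* "Window mean" is the pooled all-months mean per variable; a
  per-calendar-month mode is available (`mean_mode="per_month"`).
* Temperature is adjusted additively, precipitation multiplicatively —
  this preserves non-negativity; an additive precipitation mode exists.
* One integer seed drives all randomness; the chosen window start years
  are stored in the output's metadata for exact replay.

**Site variants** shift the master series by the difference of site and
master means over the overlap years (1934–2013): additive for
temperature, ratio for precipitation.  A zero master precipitation mean
with a non-zero site mean is an error (undefined ratio).

**Synthetic climate.**  Monthly normals emulate the Khatanga-area grid
cell (≈460 °C·day growing season, ≈280 mm/yr).  Recent climate adds an
AR(1) yearly temperature anomaly (stationary SD 0.8 °C, lag-1 0.3),
monthly white noise (SD 0.5 °C), and multiplicative precipitation noise
(CV 0.3).  The paleo series adds a smooth cosine cooling of 2 °C from
the series start to a minimum 200 years before the end, followed by a
1 °C linear recovery — the Holocene pattern the simulations require
(gradual cooling with the coolest century roughly two centuries ago).

## 3. Stand simulator

State: individual trees (species, position, height, age) and a seed
bank on a bounded plot (default 100 × 100 m; open boundary — seeds
leaving the plot are lost).  Each year, with weather reduced to growing
degree days above 5 °C (GDD), June–August mean temperature, and annual
precipitation, the sub-models run in a fixed order: seed introduction
(when the experiment phase prescribes seed rain), growth, seed
production, dispersal, establishment, mortality/ageing.

One mechanism, one parameter:

| mechanism | form |
|---|---|
| temperature response | `T(g) = (g−g₀)₊ / ((g−g₀)₊ + h)` with threshold `g₀` (`gdd_min`) and half-saturation `h` |
| competition index | `NCI = Σ_j h_j / max(d_j, 0.5 m)` over trees within 10 m (a tree at the exact query point is excluded) |
| height growth | `Δh = hmax · T · exp(−c_g · NCI)`, capped at `max_height` |
| seed production | Poisson with mean `f · (h − h_mat)₊ · T` per tree |
| dispersal | exponential distance (mean `dispersal_mean`), uniform angle; only age-0 seeds move |
| establishment | Bernoulli `p_e · T · exp(−c_e · NCI) · w(P)` per seed; recruits start at 0.05 m |
| mortality | Bernoulli `min(1, m₀ + m_c · NCI)`; certain death at `max_age`; seed-bank mortality and maximum seed age |

`w(P)` is an optional precipitation scalar `clip(P/250 mm, 0.5, 1)` on
establishment (disable with `SimConfig(prec_ref=None)`).  Scenario runs
precede the forced simulation phase with a stabilisation phase (default
1000 years) whose weather is resampled uniformly with replacement from
the first 30 forcing years.  One root seed per scenario spawns
independent, replayable replicate streams.

**Species asymmetry (shipped defaults, `data/species_params.yaml`).**
*L. sibirica* grows and disperses faster (0.40 m/yr, 12 m vs 0.25 m/yr,
8 m) and needs a marginally longer season (`gdd_min` 220 vs
200 °C·day), but is far more competition-sensitive (establishment
penalty 1.8 vs 0.12 per NCI unit; competition mortality 0.08 vs
0.008 yr⁻¹ per NCI unit).  The original simulator's equations and
literature parameter tables are not available; these values are this
package's own minimal-form calibration, chosen once so that the model
reproduces the qualitative field pattern: equilibrium stand density
increases monotonically with temperature (≈25 trees/ha at −3 °C from
the normals, ≈330 at −1 °C, ≈450 at +1 °C on a 0.25-ha plot);
warm dense stands exclude sibirica entirely; cold sparse stands
(< 100 trees/ha) carry sibirica in a substantial fraction of years.

**Sites.**  Site variants are temperature offsets from the Khatanga
master cell: CH06 +1.5 °C (southern light taiga, dense), CH12 −0.75 °C
(northern ecotone), site 4 −1.5 °C (single-tree tundra north of the
treeline).  The offsets are not observed quantities; they were chosen
so the simulated recent-epoch stands match the published site
descriptions.

**Emergence summary.**  In temporal runs, "successful establishment" of
sibirica is a recruit cohort with at least one member alive ten years
after establishment; the emergence year is the first such cohort after
the onset of gmelinii dominance (first recorded year with gmelinii
present and sibirica absent), and the reported quantity is the total
stand density in that year.  With the shipped defaults, at the cold
northern site this median lies at ~20–50 trees/ha (below the ~100
trees/ha level at which mixed stands become possible), CH12 sits near
the threshold, and CH06 shows no emergence at all.

**Scale.**  The desk-scale defaults are a 0.25-ha plot, 3 replicates,
and forcing truncated to the final 2000 years; `full_scale` restores
1 ha and the full 5996-year span.  Replicates exceeding a tree-count
cap (default 10⁶) are flagged aborted and excluded from summaries
without affecting other cells.

## 4. sedaDNA analysis

**Classification.**  Reads are dereplicated (identical sequences
merged, counts summed, output sorted by count then sequence, hence
order-independent), filtered to the exact 61-nt amplicon length and a
minimum multiplicity of 2.  A read is assigned to a variant when its
Hamming distance to the reference backbone — ignoring the diagnostic
position — is at most 3 and its diagnostic base maps to a variant; an N
at the diagnostic position, any other base, excess mismatches, or wrong
length leave it unassigned.  The upstream read-cleaning of the original
laboratory workflow is not reproduced; the explicit length/count/
mismatch filters stand in for it and are all configurable.  The shipped
61-nt reference is a synthetic stand-in (the deposited sequences are
not redistributed); real references load from a 2-record FASTA whose
single differing position defines the diagnostic offset.

**Dominance.**  A sample with fewer than 10 assigned reads is called
`none`; a variant holding ≥ 90 % of assigned reads dominates; anything
else is `mixed`.  The original criterion is in an unavailable
supplement; these thresholds are declared, not transcribed, and a
threshold ≤ 0.5 is rejected as ambiguous.

**Ordination.**  Counts are aggregated to genus, converted to
per-sample percentages, filtered to taxa reaching ≥ 0.5 % in ≥ 2
samples, square-root transformed, and ordinated by PCA on the
column-centred (unscaled) matrix — centring without scaling is the
standard treatment for percentage paleo-data; scaling is not applied
because the square-rooted percentages already share units.  PC1 is
sign-oriented so the *Larix* loading is non-negative, making "more
larch" a consistent direction across proxies; DNA and pollen PC1 series
are then compared by Pearson and Spearman correlation over matched
samples (≥ 3 pairs required).

## 5. Synthetic data: what it does and does not establish

The read generator draws each read's variant from the mixture fraction
and applies i.i.d. substitution errors (default 1 %/base); the coupled
table generator produces DNA and pollen counts multinomially (5000
reads / 300 grains per sample — the pollen depth mirrors the
field-standard minimum count) from softmax taxon responses to one
shared latent gradient with per-proxy response jitter (SD 0.3).  Green
tests therefore establish that the pipeline recovers known mixtures,
gradients and thresholds under its own generative assumptions — they do
not establish PCR/amplification bias robustness, chimera handling, DNA
damage patterns, pollen-production biases, or the behaviour of the real
deposited data, none of which are modelled.

## 6. Numerical choices and limitations

* Distances in the competition index are floored at 0.5 m to avoid
  singular contributions; co-located trees do not interact.
* Establishment heights start at 0.05 m; stand density counts trees at
  or above 1.3 m (breast height) by default — the published simulation
  figures do not state a cutoff, so it is configurable.
* Month lengths use the non-leap convention (365-day year) for GDD.
* Seed-bank seeds disperse only in their first year (one dispersal
  event per cohort).
* Climate CSVs round-trip bit-exactly (`repr` formatting on write,
  round-trip float parsing on read).
* The stochastic acceptance-level checks (distributional oracles at
  n = 10⁴, 3 SE; ensemble monotonicity with 20 replicates) use fixed
  seeds; at these tolerances seed sensitivity is negligible but not
  zero.
* Fire and insect disturbances, permafrost dynamics, hybridisation and
  chloroplast markers, and age-depth modelling are out of scope; sample
  ages are consumed as given metadata.
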