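# Methods

This note records the model, the estimation choices, and the synthetic-data
conditions behind `ctitrack`, including every place where the design was
genuinely open and a choice had to be made.

## Thermal preference

A species' realized thermal distribution is summarised by the midpoint of
its 5th and 95th occurrence-temperature percentiles. Percentiles use linear
interpolation between closest order statistics (Hyndman–Fan type 7, numpy's
default); the convention is fixed so midpoints are bit-for-bit reproducible.
Exact-duplicate occurrence rows are removed before estimation. Species with
fewer than `min_records = 20` deduplicated records are excluded (degenerate
percentile pairs at low n say more about sampling than about the niche);
the floor is configurable. The temperature attached to each occurrence is
taken as given — whether it is SST or depth-integrated is input metadata,
not recomputed.

## Community Temperature Index

CTI weights each species' midpoint `T_s` by `w_s = log(A_s + 1)`, with
`A_s` its relative abundance. The default **normalized** form divides by
`Σ w_s`, making CTI a weighted average in °C: it satisfies the monoculture
identity, stays inside `[min T_s, max T_s]`, and is invariant to the
logarithm base (a base change rescales all weights by one constant). A
**literal** unnormalized sum is retained behind a flag because the
weighted-sum form appears in the literature without a denominator; it fails
the monoculture identity (a single-species community returns `T·log 2`) and
depends on the log base, which is why it is not the default. Species
present in a sample but lacking a preference are dropped from that year's
CTI and counted, never imputed. Missing species-years are absences
(abundance 0), consistent with relative abundance over the observed
community.

## Trend estimation

*Per site.* `CTI_r` is the slope of value on year. Serial correlation is
assessed on the OLS-detrended residuals: the lag-1 partial autocorrelation
(equal to the lag-1 autocorrelation) is compared with the large-sample
threshold `z_{1−α/2}/√n`, α = 0.05, for series of at least 10 years.
When flagged, the fit switches to GLS with AR(1) correlation
`R_ij = φ^{|year_i − year_j|}` (year gaps decay geometrically, as a
stationary AR(1) observed with gaps), with φ set to the residual lag-1
autocorrelation clipped to ±0.95 in a single Prais–Winsten-style step —
iterating φ changes third-decimal slope digits on realistic series and is
not worth the fragility on 9-year records. With φ = 0 the fit reduces
exactly to OLS. Wald tests use a t reference with n − 2 degrees of freedom.
Residuals that are numerically zero (noiseless series) short-circuit the
gate.

*Pooled and factor models.* The across-site model is a linear mixed model:
year fixed effect, site random intercepts, AR(1) within-site residuals.
It is fitted by exact marginal maximum likelihood — per-site covariance
`V_i = σ_b² 11' + σ_e² R_i(φ)` — profiling β and σ_e² analytically and
searching (σ_b²/σ_e², φ) by Nelder–Mead from two starts. ML (not REML) is
used so AICc is comparable across fixed-effect structures; the Wald scale
uses the RSS/(n − p) variance estimate and a t reference with
n_obs − k_fixed degrees of freedom, an nlme-style approximation (coverage
is verified by simulation below). Random intercepts are BLUPs
`b̂_i = λ 1' W_i⁻¹ (y_i − X_i β̂)`; partial residuals are observed values
minus the site BLUP. Factor contrasts use cell-means coding (one intercept
and one slope per level) so each level's slope, SE and two-sided Wald test
read directly off the fit; model selection fits every factor subset with
treatment-coded year interactions, ranks by AICc (ties: fewer parameters,
then lexicographic), and records aliased or otherwise unfittable candidates
as failed rather than aborting (basin type is aliased with region in the
bundled survey, as it often is in real networks). `k` counts fixed effects
plus σ_b, σ_e and φ.

## Decomposition

The station reference CTI defaults to the time-mean of the annual CTI (the
more stable choice); a first-year alternative is provided since a baseline
convention is equally defensible. Abundance change defaults to the OLS
slope of the species' weight `log(A_s + 1)` over years — the same scale CTI
uses, keeping the decomposition commensurate with the index — with an
endpoint-difference estimator behind a flag. The quadrant rule maps sign
pairs to processes; an exact zero in either coordinate is labelled `none`
with zero contribution, which preserves both the partition and the
conservation identity `trop + deb − bor − det = Σ bias·change` (intensities
are stored as non-negative magnitudes; contributions within a process share
a sign). Dominance ties break by the fixed order tropicalization >
deborealization > borealization > detropicalization and are logged.
The tropicalization-minus-deborealization contrast is computed on sites
with rising CTI; gains-minus-losses `(trop + bor) − (det + deb)` uses all
sites. Per-site contrasts use ordinary linear models (cell means, pooled
residual variance); the per-species variant adds a site random intercept.

## Synthetic data: what it emulates, and what it does not

Species respond to temperature through Gaussian curves
`a_s(T) = A_max exp(−(T − opt)²/2σ²)` — the simplest unimodal form with the
ascending and descending limbs the decomposition logic needs. Temperature
follows a linear warming trend plus stationary AR(1) noise. Observation
noise is multiplicative lognormal (abundances are non-negative, spanning
orders of magnitude), and abundances below a detection floor (default 10⁻³
of the species' maximum) read zero. Default conditions: 30 species, 30
annual samples (realistic series run 9–43 years), warming 0.032 °C yr⁻¹
(≈0.3 °C decade⁻¹, a typical recent ocean-surface rate), breadths 2–4 °C,
lognormal σ = 0.3, φ = 0.3.

Connectivity is a hard mask: in an enclosed basin, species absent in year 1
whose optima exceed every optimum present in year 1 remain absent forever
(no warm pool upstream); species present in year 1 are never altered. This
is the simplest mechanism separating the two regimes — real connectivity is
a continuum with dispersal lags, which the simulator does not model, nor
does it include species interactions, phenology, or depth shifts.
Consequently, passing tests show the estimators do what they claim under
niche tracking with independent species; they do not certify behaviour
under interaction-driven or lagged dynamics.

Ground-truth labels accompany each simulated community, derived from the
noiseless expected curves (optimum minus the noiseless community reference,
and the noiseless weight slope).

## Study conditions for the simulation studies

* **Autocorrelation gate** — 500 replicates, n = 40 years: empirical size
  under white noise (the detrending induces a small negative lag-1 bias, so
  size sits slightly above/below nominal depending on tail; observed ≈ 3–6%)
  and power against φ = 0.8 (observed ≈ 98%).
* **Pooled recovery** — 200 replicates of 20 sites × 25 years, common slope
  0.023 °C yr⁻¹, site intercepts ~ N(0, 1), AR(1) noise φ = 0.4, innovation
  SD 0.15. CI coverage of the year slope ≈ 94%.
* **Factor recovery** — as above with two 10-site levels at slopes 0.03 and
  0.00; per-level coverage is assessed separately (joint coverage of two
  independent 95% intervals is ~90% by construction and is not the target).
* **Open vs enclosed** — 200 paired replicates of 30 stations, warming
  0.03 °C yr⁻¹, each pair sharing seeds (same pools, same noise) across the
  two basin regimes. This scenario uses narrow niches (breadth 0.5–0.7 °C
  over a dense 12–20 °C pool, 40 years): the colonization mask only has
  consequences when the detectability boundary sweeps across several
  species' niches within the simulated warming, which requires breadth
  commensurate with the ~1.2 °C sweep. With the default 2–4 °C breadths any
  species absent at year 1 remains ecologically negligible under a 1 °C
  warming whether or not it is blocked, and the regimes are
  indistinguishable — the narrow-niche setting is what makes this an
  experiment about connectivity rather than about the detection floor.
  Compared per pair: tropicalization dominance share and mean
  gains-minus-losses.
* **Niche tracking** — 200 replicates of 5 stations, dense evenly spaced
  60-species pool spanning 4–26 °C, low noise (lognormal σ = 0.05,
  φ = 0.1), open basin; the full chain (occurrences → preferences → CTI →
  pooled mixed model) recovers the imposed warming rate with mean ratio
  ≈ 0.98.
* **Synthetic survey** — 18 stations across three regions (semi-enclosed
  Mediterranean and Baltic warming at 0.05 and 0.04 °C yr⁻¹, open Atlantic
  at 0.025), three habitats, six biological groups, 20–40 year series.
  Headline outputs (pooled rates per decade, share of positive sites,
  dominance shares, AICc ranking) are recomputed by
  `scripts/acceptance.py`; panel sizes keep the whole run to minutes on one
  CPU.

## Numerical notes and limitations

* The mixed-model likelihood caches one Cholesky per unique within-site
  year grid, so balanced panels cost one decomposition per evaluation.
* λ = σ_b²/σ_e² is optimised on the log scale; a variance component shrinks
  to ~e⁻³⁰ rather than exactly 0, which is numerically equivalent.
* Degenerate inputs: constant or exactly linear series bypass the
  autocorrelation gate; all-zero communities, empty niche pools, single-year
  sites and unknown factor levels raise explicit errors; a single site falls
  back from the mixed model to per-site GLS with a warning.
* Wald t with n_obs − k_fixed df understates uncertainty when sites are few
  and variance parameters poorly determined; coverage was verified at the
  study conditions above, not for very small networks.
* The AR structure is fixed at order 1; higher-order or spatial correlation
  is out of scope.
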