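# ctitrack

Tools for asking whether marine communities are reorganising in response to
ocean warming, and through which ecological door the change is entering.
The package targets long-term biodiversity monitoring data — annual species
abundance records at fixed stations — together with species
occurrence–temperature records and per-site annual temperature series, and
is aimed at community ecologists and climate-impact analysts working with
multi-decadal survey programmes.

## The method

**Thermal preference.** Each species' thermal affinity `T_s` is the midpoint
between the 5th and 95th percentiles of the temperatures observed at its
occurrence records (percentiles by linear order-statistic interpolation).

**Community Temperature Index.** For a community sample with relative
abundances `A_s`,

    CTI = Σ_s T_s · log(A_s + 1) / Σ_s log(A_s + 1)

an abundance-weighted average thermal affinity in °C, directly comparable
with sea temperature. An unnormalized variant (no denominator) is available
behind a flag for auditing; it is not an average and fails the monoculture
identity `CTI = T_s`.

**Trends.** The temporal rate `CTI_r` is estimated per site by generalized
least squares, switching to an AR(1) residual correlation when the lag-1
partial autocorrelation of the detrended residuals exceeds `z_{1-α/2}/√n`.
The pooled rate across sites comes from a linear mixed model with year as
fixed effect, site random intercepts, and AR(1) within-site residuals
(exact marginal maximum likelihood). Factor contrasts (biological group,
habitat, region, basin type) use year-by-factor interactions; competing
factor subsets are ranked by AICc.

**Decomposition.** At each site, every species gets a thermal bias
(`T_s − CTI_station`) and an abundance change (trend of its CTI weight).
The sign pair classifies it: (+,+) tropicalization, (−,−) deborealization,
(−,+) borealization, (+,−) detropicalization. Per-process intensities are
magnitudes of the summed bias×change contributions and satisfy

    trop + deb − bor − det = Σ_s bias_s · change_s

tying the decomposition back to the direction of CTI change.

**Synthetic data.** Because real monitoring data are access-restricted, a
simulator generates community time series from Gaussian thermal response
curves under a warming trend with AR(1) noise, lognormal observation error,
a detection floor, and an open-vs-enclosed basin switch that blocks
colonization by warm-adapted species absent at the start of the series.
Every stage of the chain is tested against it.

## Worked example

```python
import ctitrack as ct

prefs = {"cold": 8.0, "mid": 12.0, "warm": 20.0}        # °C midpoints
value = ct.compute_cti({"cold": 70, "mid": 20, "warm": 10}, prefs)
print(round(value.cti, 4))                               # 10.3173
```

The community is dominated by the cold-affinity species, so its CTI
(10.32 °C) sits near the cold end of the preference range. The analysis
drivers run the full chain on a simulated 18-station survey:

```
$ python analysis/01_survey_trends.py
sites simulated:                 18
SST trend (pooled mixed model):  +0.352 °C/decade  (t = 14.01)
CTI trend (pooled mixed model):  +0.325 °C/decade  (t = 12.96)
sites with positive CTI_r:       100.0 %
  ... significantly positive:    88.9 %
CTI ~ SST slope across sites:    0.953  (t = 63.18)
```

The pooled CTI rate tracks the pooled warming rate and the CTI–SST slope is
near 1: simulated communities follow their thermal niches. The remaining
drivers (`02_factor_contrasts.py`, `03_decomposition.py`,
`04_operating_characteristics.py`) compare rates across factors with AICc
selection, decompose CTI change into the four processes, and measure the
estimators' empirical size, power and CI coverage. Tables land in
`results/`.

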