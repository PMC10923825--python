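"""Synthetic community time series with the structure the analysis assumes.

The generative picture: each species has a Gaussian abundance response to
temperature (optimum, breadth, maximum abundance). A monitoring station sees
a warming trend with AR(1) interannual noise; as the local temperature moves,
species on the warm side of the pool rise in expected abundance and species
on the cold side decline — the niche-tracking premise under which CTI trends
mirror warming. Observation noise is multiplicative lognormal (abundances are
non-negative and span orders of magnitude) and a detection floor zeroes
trace abundances.

Basin connectivity is a hard colonization mask: in an ``enclosed`` basin,
species absent at the start of the series whose optima lie above every
optimum present in year 1 can never arrive (no warm-adapted pool upstream);
an ``open`` basin imposes no mask. The mask never alters species present in
year 1. This is deliberately the simplest mechanism that separates the two
regimes; real connectivity is a continuum.

Default scenario values are the study conditions emulated throughout:
multi-decadal annual sampling (default 30 years; realistic range 9-43),
warming 0.032 °C yr⁻¹ (≈0.3 °C per decade), niche breadths 2-4 °C.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("ctitrack")

__all__ = [
    "SpeciesNiche", "ScenarioConfig", "sample_niche_pool",
    "simulate_temperature_series", "simulate_community_series",
    "generate_occurrences", "simulate_annual_panel",
]


@dataclass(frozen=True)
class SpeciesNiche:
    species_id: str
    optimum: float  # °C
    breadth: float  # °C, Gaussian SD; > 0
    max_abundance: float  # > 0

    def __post_init__(self):
        if self.breadth <= 0:
            raise ValueError("breadth must be > 0")
        if self.max_abundance <= 0:
            raise ValueError("max_abundance must be > 0")

    def expected_abundance(self, temperature: np.ndarray) -> np.ndarray:
        t = np.asarray(temperature, dtype=float)
        return self.max_abundance * np.exp(
            -((t - self.optimum) ** 2) / (2.0 * self.breadth ** 2))


@dataclass(frozen=True)
class ScenarioConfig:
    n_species: int = 30
    n_years: int = 30
    start_temp: float = 14.0  # °C
    warming_rate: float = 0.032  # °C per year (≈0.3 °C per decade)
    basin: str = "open"  # "open" | "enclosed"
    pool_optima_range: tuple[float, float] = (6.0, 26.0)
    observation_noise_sd: float = 0.3  # lognormal sigma / AR(1) innovation SD
    ar1_phi: float = 0.3
    detection_floor: float = 1e-3  # fraction of each species' max_abundance
    seed: int = 0
    start_year: int = 1990
    site_id: str = "S1"

    def __post_init__(self):
        if self.n_years < 9:
            raise ValueError("n_years must be >= 9 (shortest realistic series)")
        if not 0.0 <= self.warming_rate <= 0.1:
            raise ValueError("warming_rate must lie in [0, 0.1] °C/yr")
        if self.basin not in ("open", "enclosed"):
            raise ValueError(f"unknown basin {self.basin!r}")
        if not 0.0 <= self.ar1_phi < 1.0:
            raise ValueError("ar1_phi must lie in [0, 1)")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.start_year + self.n_years)


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Independent, reproducible stream per purpose for one scenario seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed,
                                                        spawn_key=(stream,)))


def sample_niche_pool(
    config: ScenarioConfig,
    breadth_range: tuple[float, float] = (2.0, 4.0),
    max_abundance_range: tuple[float, float] = (10.0, 100.0),
    spacing: str = "uniform",
    prefix: str = "sp",
) -> list[SpeciesNiche]:
    """Draw the regional species pool for a scenario.

    ``spacing="uniform"`` draws optima uniformly over the pool range;
    ``"even"`` places them on a regular grid (a dense, gap-free pool).
    """
    rng = _rng(config.seed, 0)
    n = config.n_species
    lo, hi = config.pool_optima_range
    if spacing == "even":
        optima = np.linspace(lo, hi, n)
    elif spacing == "uniform":
        optima = np.sort(rng.uniform(lo, hi, n))
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    breadths = rng.uniform(*breadth_range, n)
    max_ab = rng.uniform(*max_abundance_range, n)
    return [SpeciesNiche(f"{prefix}{i:03d}", float(o), float(b), float(m))
            for i, (o, b, m) in enumerate(zip(optima, breadths, max_ab))]


def _ar1_noise(rng: np.random.Generator, n: int, phi: float, innov_sd: float) -> np.ndarray:
    """Stationary AR(1) noise: e_t = phi e_{t-1} + innovation."""
    e = np.empty(n)
    if innov_sd == 0.0:
        return np.zeros(n)
    e[0] = rng.normal(0.0, innov_sd / np.sqrt(1.0 - phi ** 2) if phi else innov_sd)
    innov = rng.normal(0.0, innov_sd, n - 1)
    for t in range(1, n):
        e[t] = phi * e[t - 1] + innov[t - 1]
    return e


def simulate_temperature_series(config: ScenarioConfig) -> pd.DataFrame:
    """Annual SST series: linear warming plus stationary AR(1) noise.

    ``st100m`` is included as a damped version of the SST anomaly (sub-surface
    warming is slower), giving the reader of the tables both columns.
    """
    t = np.arange(config.n_years, dtype=float)
    noise = _ar1_noise(_rng(config.seed, 1), config.n_years,
                       config.ar1_phi, config.observation_noise_sd)
    sst = config.start_temp + config.warming_rate * t + noise
    st100m = config.start_temp - 1.0 + 0.5 * (config.warming_rate * t + noise)
    return pd.DataFrame({"site_id": config.site_id, "year": config.years,
                         "sst": sst, "st100m": st100m})


def simulate_community_series(
    config: ScenarioConfig, niches: list[SpeciesNiche],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate one station's community time series.

    Returns ``(abundance, temperature, truth)``:

    * ``abundance`` — long table (site_id, year, species_id, abundance) with
      only detected (positive) abundances, as a survey would record;
    * ``temperature`` — the simulated annual temperature series;
    * ``truth`` — per-species ground-truth labels derived from the noiseless
      expected curves (bias of the optimum against the year-window mean
      community optimum, noiseless weight slope, and the implied process).
    """
    if not niches:
        raise ValueError("empty niche set")
    temp = simulate_temperature_series(config)
    sst = temp["sst"].to_numpy()
    n_y, n_s = config.n_years, len(niches)

    expected = np.column_stack([nic.expected_abundance(sst) for nic in niches])
    noise_rng = _rng(config.seed, 2)
    noise = np.exp(noise_rng.normal(0.0, config.observation_noise_sd,
                                    size=(n_y, n_s)))
    observed = expected * noise
    floors = np.array([config.detection_floor * nic.max_abundance for nic in niches])
    observed[observed < floors] = 0.0

    if config.basin == "enclosed":
        present0 = observed[0] > 0
        if present0.any():
            max_opt0 = max(nic.optimum for nic, pres in zip(niches, present0) if pres)
        else:
            max_opt0 = -np.inf
        blocked = ~present0 & np.array([nic.optimum > max_opt0 for nic in niches])
        observed[:, blocked] = 0.0
    else:
        blocked = np.zeros(n_s, dtype=bool)

    years = config.years
    rows = []
    for j, nic in enumerate(niches):
        for i in range(n_y):
            if observed[i, j] > 0:
                rows.append((config.site_id, int(years[i]), nic.species_id,
                             float(observed[i, j])))
    abundance = pd.DataFrame(rows, columns=["site_id", "year", "species_id",
                                            "abundance"])

    truth = _ground_truth(config, niches, expected, blocked)
    return abundance, temp, truth


def _ground_truth(config: ScenarioConfig, niches: list[SpeciesNiche],
                  expected: np.ndarray, blocked: np.ndarray) -> pd.DataFrame:
    """Process labels from the noiseless expected curves (mask applied)."""
    from .decomposition import classify_process

    exp_eff = expected.copy()
    exp_eff[:, blocked] = 0.0
    totals = exp_eff.sum(axis=1)
    totals[totals == 0] = np.nan
    weights = np.log1p(exp_eff / totals[:, None])
    t = np.arange(config.n_years, dtype=float)
    tc = t - t.mean()
    slopes = (tc @ (weights - weights.mean(axis=0))) / (tc @ tc)
    optima = np.array([nic.optimum for nic in niches])
    # reference: noiseless community CTI (optima weighted by mean weights)
    wbar = np.nanmean(weights, axis=0)
    ref = float((optima * wbar).sum() / wbar.sum()) if wbar.sum() > 0 else np.nan
    rows = []
    for j, nic in enumerate(niches):
        bias = nic.optimum - ref
        change = float(slopes[j])
        label = ("blocked" if blocked[j]
                 else classify_process(bias, change))
        rows.append({"site_id": config.site_id, "species_id": nic.species_id,
                     "optimum": nic.optimum, "breadth": nic.breadth,
                     "max_abundance": nic.max_abundance,
                     "true_bias": bias, "true_change": change,
                     "true_process": label})
    return pd.DataFrame(rows)


def generate_occurrences(
    niches: list[SpeciesNiche], config: ScenarioConfig,
    n_per_species: int = 200, temp_range: tuple[float, float] = (-2.0, 35.0),
) -> pd.DataFrame:
    """Occurrence-temperature records for thermal-preference estimation.

    Temperatures are drawn per species from Normal(optimum, breadth)
    truncated to ``temp_range`` — the realistic span of sea temperatures.
    """
    rng = _rng(config.seed, 3)
    lo, hi = temp_range
    rows = []
    for nic in niches:
        a = (lo - nic.optimum) / nic.breadth
        b = (hi - nic.optimum) / nic.breadth
        temps = stats.truncnorm.rvs(a, b, loc=nic.optimum, scale=nic.breadth,
                                    size=n_per_species, random_state=rng)
        rows.append(pd.DataFrame({"species_id": nic.species_id,
                                  "temperature": temps}))
    return pd.concat(rows, ignore_index=True)


def simulate_annual_panel(
    n_sites: int, n_years: int, slope: float | np.ndarray,
    intercept_sd: float = 1.0, noise_sd: float = 0.15, phi: float = 0.0,
    seed: int = 0, start_year: int = 1990, base_level: float = 14.0,
) -> pd.DataFrame:
    """Balanced multi-site panel for parameter-recovery studies.

    Each site i gets value_it = base + b_i + slope_i * (year - first year)
    plus stationary AR(1) noise (innovation SD ``noise_sd``), with site
    intercepts b_i ~ Normal(0, intercept_sd²). ``slope`` may be a scalar
    (common trend) or one value per site. Returns a long table with columns
    ``site_id, year, value``.
    """
    rng = np.random.default_rng(seed)
    slopes = np.broadcast_to(np.asarray(slope, dtype=float), (n_sites,))
    intercepts = rng.normal(0.0, intercept_sd, n_sites)
    years = np.arange(start_year, start_year + n_years)
    t = np.arange(n_years, dtype=float)
    frames = []
    for i in range(n_sites):
        noise = _ar1_noise(rng, n_years, phi, noise_sd)
        vals = base_level + intercepts[i] + slopes[i] * t + noise
        frames.append(pd.DataFrame({"site_id": f"site{i:02d}", "year": years,
                                    "value": vals}))
    return pd.concat(frames, ignore_index=True)


def scenario_with(config: ScenarioConfig, **kwargs) -> ScenarioConfig:
    """A copy of ``config`` with fields replaced (dataclasses.replace wrapper)."""
    return replace(config, **kwargs)
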