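"""Monte-Carlo studies over the synthetic scenarios.

Each function here is a self-contained simulation study: it generates data
with :mod:`ctitrack.simulate`, runs the corresponding estimator, and returns
the summary the study is about (empirical size/power, CI coverage, paired
contrasts, recovery ratios). The analysis drivers and the test suite both
call these, so the numbers they report are always recomputed.

Study sizes (replicates, sites per replicate, panel lengths) are fixed here
as the package's study conditions; see docs/methods.md for the rationale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from . import cti as cti_mod
from . import decomposition as dec
from .mixed import fit_factor_trends, fit_pooled_trend
from .simulate import (
    ScenarioConfig,
    sample_niche_pool,
    simulate_annual_panel,
    simulate_community_series,
    generate_occurrences,
)
from .thermal_niche import estimate_all_preferences
from .trends import detect_autocorrelation

log = logging.getLogger("ctitrack")

_SEED_MOD = 2**31 - 1


def _spawn_seeds(seed: int, *shape: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return rng.integers(0, _SEED_MOD, size=shape)


# ---------------------------------------------------------------------------
# autocorrelation gate: empirical size and power


def gate_size_power(
    n_reps: int = 500, n_years: int = 40, phi_alt: float = 0.8,
    alpha: float = 0.05, seed: int = 0,
) -> dict[str, float]:
    """Empirical size (white noise) and power (AR(1) phi_alt) of the gate.

    Residual series are generated around a fixed linear trend; the gate sees
    the same detrended-residual path it would in production.
    """
    rng = np.random.default_rng(seed)
    years = np.arange(1980, 1980 + n_years)
    t = np.arange(n_years, dtype=float)
    hits_null = hits_alt = 0
    for _ in range(n_reps):
        white = rng.normal(0.0, 1.0, n_years)
        flag, _ = detect_autocorrelation(years, 0.02 * t + white, alpha=alpha)
        hits_null += flag
        e = np.empty(n_years)
        e[0] = rng.normal(0.0, 1.0 / np.sqrt(1 - phi_alt**2))
        innov = rng.normal(0.0, 1.0, n_years - 1)
        for i in range(1, n_years):
            e[i] = phi_alt * e[i - 1] + innov[i - 1]
        flag, _ = detect_autocorrelation(years, 0.02 * t + e, alpha=alpha)
        hits_alt += flag
    return {"size_pct": 100.0 * hits_null / n_reps,
            "power_pct": 100.0 * hits_alt / n_reps,
            "n_reps": n_reps}


# ---------------------------------------------------------------------------
# mixed-model parameter recovery


def pooled_recovery(
    n_reps: int = 200, n_sites: int = 20, n_years: int = 25,
    slope: float = 0.023, intercept_sd: float = 1.0, noise_sd: float = 0.15,
    phi: float = 0.4, seed: int = 0,
) -> dict[str, float]:
    """CI coverage of the pooled mixed-model slope for a known common trend."""
    seeds = _spawn_seeds(seed, n_reps)
    covered = 0
    estimates = []
    for s in seeds:
        panel = simulate_annual_panel(n_sites, n_years, slope, intercept_sd,
                                      noise_sd, phi, seed=int(s))
        fit = fit_pooled_trend(panel, value_col="value")
        est, se, _, _ = fit.fixed_effects["year"]
        tc = stats.t.ppf(0.975, fit.df_resid)
        covered += bool(est - tc * se <= slope <= est + tc * se)
        estimates.append(est)
    return {"coverage_pct": 100.0 * covered / n_reps,
            "mean_slope": float(np.mean(estimates)),
            "true_slope": slope, "n_reps": n_reps}


def factor_recovery(
    n_reps: int = 200, slopes: tuple[float, float] = (0.03, 0.0),
    n_sites_per_level: int = 10, n_years: int = 25,
    intercept_sd: float = 1.0, noise_sd: float = 0.15, phi: float = 0.4,
    seed: int = 0,
) -> dict[str, float]:
    """Per-level CI coverage of factor-specific slopes (two-level design)."""
    n_sites = 2 * n_sites_per_level
    site_ids = [f"site{i:02d}" for i in range(n_sites)]
    levels = ["levelA"] * n_sites_per_level + ["levelB"] * n_sites_per_level
    metadata = pd.DataFrame({"site_id": site_ids, "group": levels})
    per_site = np.repeat(slopes, n_sites_per_level)
    seeds = _spawn_seeds(seed, n_reps)
    covered = {"levelA": 0, "levelB": 0}
    for s in seeds:
        panel = simulate_annual_panel(n_sites, n_years, per_site, intercept_sd,
                                      noise_sd, phi, seed=int(s))
        table, fit = fit_factor_trends(panel, metadata, "group",
                                       value_col="value")
        tc = stats.t.ppf(0.975, fit.df_resid)
        for lev, true in zip(("levelA", "levelB"), slopes):
            row = table[table["level"] == lev].iloc[0]
            lo = row["slope"] - tc * row["se"]
            hi = row["slope"] + tc * row["se"]
            covered[lev] += bool(lo <= true <= hi)
    return {"coverage_levelA_pct": 100.0 * covered["levelA"] / n_reps,
            "coverage_levelB_pct": 100.0 * covered["levelB"] / n_reps,
            "n_reps": n_reps}


# ---------------------------------------------------------------------------
# open vs enclosed colonization contrast


def colonization_config(seed: int, basin: str, site_id: str = "S1",
                        warming_rate: float = 0.03) -> ScenarioConfig:
    """Scenario for the connectivity experiment.

    Narrow thermal niches (0.5-0.7 °C breadth, vs the 2-4 °C default) over a
    dense pool, so that the detectability boundary sweeps across several
    species' niches during the 40-year warming — the regime in which
    colonization (and hence its suppression in an enclosed basin) matters.
    """
    return ScenarioConfig(
        n_species=80, n_years=40, warming_rate=warming_rate,
        pool_optima_range=(12.0, 20.0), basin=basin, seed=seed,
        site_id=site_id,
    )


def _site_process_summary(cfg: ScenarioConfig,
                          breadth_range: tuple[float, float]) -> dec.SiteProcessSummary:
    niches = sample_niche_pool(cfg, breadth_range=breadth_range)
    abundance, _, _ = simulate_community_series(cfg, niches)
    prefs = pd.DataFrame({"species_id": [n.species_id for n in niches],
                          "midpoint": [n.optimum for n in niches]})
    cti = cti_mod.cti_time_series(abundance, prefs)
    records = dec.decompose_site(abundance, prefs, cti)
    return dec.process_intensities(records, site_id=cfg.site_id)


def open_vs_enclosed(
    n_pairs: int = 200, n_sites: int = 30, warming_rate: float = 0.03,
    seed: int = 0, breadth_range: tuple[float, float] = (0.5, 0.7),
) -> dict[str, float]:
    """Paired open-vs-enclosed runs of the colonization scenario.

    Each pair simulates ``n_sites`` stations under identical seeds (same
    niches, same noise) in both basin regimes; per pair we compare the
    tropicalization dominance share and the mean (trop+bor)-(det+deb).
    Returns the percentage of pairs where the open basin is strictly greater
    on each statistic.
    """
    site_seeds = _spawn_seeds(seed, n_pairs, n_sites)
    share_wins = gml_wins = 0
    share_diffs, gml_diffs = [], []
    for r in range(n_pairs):
        stats_by_basin = {}
        for basin in ("open", "enclosed"):
            summaries, gml = [], []
            for k in range(n_sites):
                cfg = colonization_config(int(site_seeds[r, k]), basin,
                                          site_id=f"s{k:02d}",
                                          warming_rate=warming_rate)
                s = _site_process_summary(cfg, breadth_range)
                summaries.append(s.as_dict())
                gml.append(dec.gain_minus_loss(s))
            sdf = pd.DataFrame(summaries)
            stats_by_basin[basin] = (
                dec.dominance_shares(sdf)["tropicalization"],
                float(np.mean(gml)),
            )
        share_open, gml_open = stats_by_basin["open"]
        share_enc, gml_enc = stats_by_basin["enclosed"]
        share_wins += share_open > share_enc
        gml_wins += gml_open > gml_enc
        share_diffs.append(share_open - share_enc)
        gml_diffs.append(gml_open - gml_enc)
    return {"share_open_greater_pct": float(100.0 * share_wins / n_pairs),
            "gain_loss_open_greater_pct": float(100.0 * gml_wins / n_pairs),
            "mean_share_diff_pct_points": float(np.mean(share_diffs)),
            "mean_gain_loss_diff": float(np.mean(gml_diffs)),
            "n_pairs": n_pairs}


# ---------------------------------------------------------------------------
# end-to-end niche tracking


def tracking_config(seed: int, site_id: str = "S1",
                    warming_rate: float = 0.03) -> ScenarioConfig:
    """Dense-pool, low-noise, open-basin scenario for niche tracking."""
    return ScenarioConfig(
        n_species=60, n_years=30, warming_rate=warming_rate,
        pool_optima_range=(4.0, 26.0), basin="open",
        observation_noise_sd=0.05, ar1_phi=0.1, seed=seed, site_id=site_id,
    )


def niche_tracking(
    n_reps: int = 200, n_sites: int = 5, warming_rate: float = 0.03,
    seed: int = 0,
) -> dict[str, float]:
    """End-to-end recovery of the warming rate by the pooled CTI trend.

    The full chain runs per replicate: occurrence records -> thermal
    preferences -> CTI series per site -> pooled mixed-model CTI_r. Returns
    the mean ratio of estimated CTI_r to the imposed warming rate.
    """
    site_seeds = _spawn_seeds(seed, n_reps, n_sites)
    ratios = []
    for r in range(n_reps):
        frames = []
        for k in range(n_sites):
            cfg = tracking_config(int(site_seeds[r, k]), site_id=f"s{k:02d}",
                                  warming_rate=warming_rate)
            niches = sample_niche_pool(cfg, breadth_range=(2.0, 4.0),
                                       spacing="even")
            abundance, _, _ = simulate_community_series(cfg, niches)
            occ = generate_occurrences(niches, cfg, n_per_species=150)
            prefs = estimate_all_preferences(occ)
            frames.append(cti_mod.cti_time_series(abundance, prefs))
        cti_all = pd.concat(frames, ignore_index=True)
        fit = fit_pooled_trend(cti_all)
        ratios.append(fit.fixed_effects["year"][0] / warming_rate)
    ratios = np.asarray(ratios)
    return {"mean_ratio": float(ratios.mean()),
            "sd_ratio": float(ratios.std(ddof=1)),
            "pct_within_30": float(100.0 * np.mean(np.abs(ratios - 1) <= 0.3)),
            "n_reps": n_reps}


# ---------------------------------------------------------------------------
# headline synthetic survey: the full chain over a multi-factor site network


#: site layout of the synthetic survey: (region, habitat, biological group)
_SURVEY_SITES = [
    ("NE Atlantic", "benthic/demersal", "fish"),
    ("NE Atlantic", "benthic/demersal", "CSB benthos"),
    ("NE Atlantic", "benthic/demersal", "demersal crustaceans"),
    ("NE Atlantic", "pelagic", "zooplankton"),
    ("NE Atlantic", "pelagic", "cephalopods"),
    ("NE Atlantic", "estuarine", "fish"),
    ("NE Atlantic", "benthic/demersal", "CHB benthos"),
    ("NE Atlantic", "benthic/demersal", "fish"),
    ("Mediterranean", "benthic/demersal", "CHB benthos"),
    ("Mediterranean", "benthic/demersal", "fish"),
    ("Mediterranean", "pelagic", "zooplankton"),
    ("Mediterranean", "benthic/demersal", "CSB benthos"),
    ("Mediterranean", "benthic/demersal", "cephalopods"),
    ("Mediterranean", "estuarine", "fish"),
    ("Baltic", "benthic/demersal", "CSB benthos"),
    ("Baltic", "pelagic", "zooplankton"),
    ("Baltic", "benthic/demersal", "fish"),
    ("Baltic", "benthic/demersal", "demersal crustaceans"),
]

#: regional warming rates (°C/yr) and baseline temperatures: semi-enclosed
#: basins warm faster than the open Atlantic
_REGION_CLIMATE = {
    "NE Atlantic": (0.025, 13.0, "open"),
    "Mediterranean": (0.05, 18.0, "enclosed"),
    "Baltic": (0.04, 8.0, "enclosed"),
}


def synthetic_survey(seed: int = 0) -> dict:
    """Run the whole analysis chain on a synthetic multi-site survey.

    Eighteen stations spanning three regions (the two semi-enclosed basins
    warming faster than the open Atlantic), three habitats and six biological
    groups are simulated under the niche-tracking model, then analysed
    exactly as a real survey would be: thermal preferences from occurrence
    records, CTI per site-year, per-site GLS trends, the pooled mixed model,
    factor contrasts with AICc selection, and the process decomposition.

    Returns a dict with the tidy tables and a ``headline`` sub-dict of the
    summary numbers (rates per decade, percentage of positive sites,
    dominance shares, ...).
    """
    rng = np.random.default_rng(seed)
    site_seeds = _spawn_seeds(seed, len(_SURVEY_SITES))
    meta_rows, ab_frames, temp_frames, occ_frames = [], [], [], []
    for i, (region, habitat, group) in enumerate(_SURVEY_SITES):
        warming, base_temp, basin = _REGION_CLIMATE[region]
        site = f"site{i:02d}"
        cfg = ScenarioConfig(
            n_species=30, n_years=int(rng.integers(20, 41)),
            start_temp=base_temp, warming_rate=warming, basin=basin,
            pool_optima_range=(base_temp - 8.0, base_temp + 12.0),
            seed=int(site_seeds[i]), site_id=site,
        )
        niches = sample_niche_pool(cfg, prefix=f"{site}_sp")
        abundance, temperature, _ = simulate_community_series(cfg, niches)
        occ_frames.append(generate_occurrences(niches, cfg, n_per_species=100))
        ab_frames.append(abundance)
        temp_frames.append(temperature)
        meta_rows.append({"site_id": site, "biological_group": group,
                          "habitat": habitat, "region": region,
                          "basin_type": ("non-enclosed" if basin == "open"
                                         else "semi-enclosed")})
    abundance = pd.concat(ab_frames, ignore_index=True)
    temperature = pd.concat(temp_frames, ignore_index=True)
    metadata = pd.DataFrame(meta_rows)

    preferences = estimate_all_preferences(pd.concat(occ_frames,
                                                     ignore_index=True))
    cti = cti_mod.cti_time_series(abundance, preferences)

    from .trends import fit_site_trend
    site_rows = []
    for site, grp in cti.groupby("site_id"):
        grp = grp.sort_values("year")
        est = fit_site_trend(grp["year"].to_numpy(), grp["cti"].to_numpy(),
                             site_id=site)
        site_rows.append(est.__dict__)
    site_trends = pd.DataFrame(site_rows)

    pooled_cti = fit_pooled_trend(cti)
    pooled_sst = fit_pooled_trend(temperature, value_col="sst")
    records, summaries = dec.decompose_all(abundance, preferences, cti)
    shares = dec.dominance_shares(summaries)

    from .mixed import relate_cti_to_temperature, select_best_model
    cti_vs_sst = relate_cti_to_temperature(cti, temperature)
    factors = ["biological_group", "habitat", "region", "basin_type"]
    ranking = select_best_model(cti, metadata, factors)

    factor_tables = []
    for factor in factors:
        table, _ = fit_factor_trends(cti, metadata, factor)
        factor_tables.append(table)
    factor_trends = pd.concat(factor_tables, ignore_index=True)

    # trop - deb contrast restricted to sites with rising CTI
    pos_sites = site_trends.loc[site_trends["slope"] > 0, "site_id"]
    tmd = summaries[summaries["site_id"].isin(pos_sites)].copy()
    tmd["value"] = tmd.apply(dec.trop_minus_deb, axis=1)
    tmd_by_basin = dec.compare_processes_across_factors(
        tmd[["site_id", "value"]], metadata, "basin_type")
    gml = summaries.copy()
    gml["value"] = gml.apply(dec.gain_minus_loss, axis=1)
    gml_by_basin = dec.compare_processes_across_factors(
        gml[["site_id", "value"]], metadata, "basin_type")

    n_sites = len(site_trends)
    headline = {
        "sst_trend_per_decade": 10.0 * pooled_sst.fixed_effects["year"][0],
        "cti_trend_per_decade": 10.0 * pooled_cti.fixed_effects["year"][0],
        "pct_sites_cti_positive": 100.0 * float((site_trends["slope"] > 0).mean()),
        "pct_sites_cti_significantly_positive": 100.0 * float(
            ((site_trends["slope"] > 0) & (site_trends["p_value"] < 0.05)).mean()),
        "tropicalization_share_pct": shares["tropicalization"],
        "deborealization_share_pct": shares["deborealization"],
        "cti_sst_slope": cti_vs_sst.fixed_effects["sst"][0],
        "cti_sst_t": cti_vs_sst.fixed_effects["sst"][2],
        "best_model_factors": ranking.iloc[0]["factors"],
        "n_sites": n_sites,
    }
    return {"abundance": abundance, "temperature": temperature,
            "metadata": metadata, "preferences": preferences, "cti": cti,
            "site_trends": site_trends, "pooled_cti": pooled_cti,
            "pooled_sst": pooled_sst, "records": records,
            "summaries": summaries, "shares": shares,
            "factor_trends": factor_trends, "model_ranking": ranking,
            "trop_minus_deb_by_basin": tmd_by_basin,
            "gain_minus_loss_by_basin": gml_by_basin,
            "cti_vs_sst": cti_vs_sst, "headline": headline}
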