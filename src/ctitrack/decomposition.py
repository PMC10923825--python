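"""Decomposition of CTI change into its four underlying ecological processes.

At a warming site, CTI can rise because warm-affinity species increase
(tropicalization) or cold-affinity species decrease (deborealization); it can
fall through the mirror processes (borealization, detropicalization). Each
species at a site is classified from the sign pair of

* thermal bias — its thermal preference minus the station's reference CTI,
* abundance change — the per-year trend of its weight log(A_s + 1) on the
  same scale CTI uses (A_s relative abundance, absences counted as 0),

and its contribution is the product of the two. Per-site process intensities
are the magnitudes of the within-process contribution sums, which satisfy the
conservation identity

    trop + deb - bor - det = sum_s bias_s * change_s.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger("ctitrack")

PROCESSES = ("tropicalization", "deborealization", "borealization",
             "detropicalization")
#: deterministic tie-break order for the dominant process
DOMINANCE_ORDER = PROCESSES


@dataclass(frozen=True)
class SiteProcessSummary:
    site_id: str
    tropicalization: float  # intensities, non-negative magnitudes
    deborealization: float
    borealization: float
    detropicalization: float
    signed_total: float  # trop + deb - bor - det = sum bias*change
    dominant: str

    def as_dict(self) -> dict:
        return {"site_id": self.site_id, **{p: getattr(self, p) for p in PROCESSES},
                "signed_total": self.signed_total, "dominant": self.dominant}


def station_reference_cti(cti_values: pd.Series | np.ndarray,
                          convention: str = "time_mean") -> float:
    """The station's reference CTI against which thermal bias is measured.

    ``time_mean`` (default) averages the annual CTI values — the more stable
    reference; ``first_year`` uses the earliest value (caller must pass values
    in year order for this convention).
    """
    vals = np.asarray(cti_values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty CTI series")
    if convention == "time_mean":
        return float(vals.mean())
    if convention == "first_year":
        return float(vals[0])
    raise ValueError(f"unknown convention {convention!r}")


def weight_matrix(abundance_site: pd.DataFrame) -> pd.DataFrame:
    """Per-year species weights log(relative abundance + 1) for one site.

    Missing species-years are absences (weight 0). Rows are years ascending,
    columns species.
    """
    wide = (abundance_site.pivot_table(index="year", columns="species_id",
                                       values="abundance", aggfunc="sum",
                                       fill_value=0.0)
            .sort_index())
    totals = wide.sum(axis=1)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"year(s) with zero total abundance: {bad}")
    rel = wide.div(totals, axis=0)
    return np.log1p(rel)


def species_abundance_change(years: np.ndarray, weights: np.ndarray,
                             estimator: str = "ols_slope") -> float:
    """Per-year change in a species' weight series.

    ``ols_slope`` (default) is the least-squares slope over years;
    ``endpoint`` is (last - first) / (year span).
    """
    years = np.asarray(years, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if years.size < 3:
        raise ValueError("need >= 3 years of community samples")
    if estimator == "ols_slope":
        xc = years - years.mean()
        return float(xc @ (weights - weights.mean()) / (xc @ xc))
    if estimator == "endpoint":
        return float((weights[-1] - weights[0]) / (years[-1] - years[0]))
    raise ValueError(f"unknown estimator {estimator!r}")


def classify_process(thermal_bias: float, abundance_change: float) -> str:
    """Quadrant rule on the (thermal bias, abundance change) sign pair.

    (+,+) tropicalization, (-,-) deborealization, (-,+) borealization,
    (+,-) detropicalization; an exact zero in either argument gives ``none``
    (zero contribution), preserving the partition and conservation identity.
    """
    if not (np.isfinite(thermal_bias) and np.isfinite(abundance_change)):
        raise ValueError("thermal bias and abundance change must be finite")
    if thermal_bias == 0.0 or abundance_change == 0.0:
        return "none"
    if thermal_bias > 0:
        return "tropicalization" if abundance_change > 0 else "detropicalization"
    return "borealization" if abundance_change > 0 else "deborealization"


def decompose_site(
    abundance_site: pd.DataFrame,
    preferences: pd.DataFrame,
    cti_series: pd.DataFrame,
    reference: str = "time_mean",
    estimator: str = "ols_slope",
) -> pd.DataFrame:
    """Per-species process records for one site.

    Species lacking a thermal preference are excluded (they do not enter CTI
    either); species absent in every year are excluded. Returns columns
    ``site_id, species_id, thermal_bias, abundance_change, process,
    contribution``.
    """
    site = abundance_site["site_id"].iloc[0]
    pref_map = dict(zip(preferences["species_id"], preferences["midpoint"]))
    cti_sorted = cti_series.sort_values("year")["cti"]
    ref_cti = station_reference_cti(cti_sorted.to_numpy(), reference)
    W = weight_matrix(abundance_site)
    years = W.index.to_numpy(dtype=float)
    rows = []
    for sp in W.columns:
        if sp not in pref_map:
            continue
        w = W[sp].to_numpy(dtype=float)
        if not np.any(w > 0):
            continue
        bias = float(pref_map[sp] - ref_cti)
        change = species_abundance_change(years, w, estimator=estimator)
        rows.append({
            "site_id": site, "species_id": sp, "thermal_bias": bias,
            "abundance_change": change,
            "process": classify_process(bias, change),
            "contribution": bias * change,
        })
    return pd.DataFrame(rows, columns=["site_id", "species_id", "thermal_bias",
                                       "abundance_change", "process",
                                       "contribution"])


def process_intensities(records: pd.DataFrame,
                        site_id: str | None = None) -> SiteProcessSummary:
    """Per-site process intensities from one site's species records.

    Each intensity is |sum of that process's contributions| (contributions
    within a process share a sign); ``signed_total`` is the plain sum of
    bias x change over all species, equal to trop + deb - bor - det.
    """
    if site_id is None:
        site_id = records["site_id"].iloc[0] if len(records) else ""
    sums = {p: 0.0 for p in PROCESSES}
    if len(records):
        by = records.groupby("process")["contribution"].sum()
        for p in PROCESSES:
            sums[p] = abs(float(by.get(p, 0.0)))
    signed = float(records["contribution"].sum()) if len(records) else 0.0
    ranked = sorted(PROCESSES, key=lambda p: -sums[p])
    top = [p for p in PROCESSES if sums[p] == sums[ranked[0]]]
    if len(top) > 1:
        log.debug("site %s: dominance tie among %s, broken by fixed order",
                  site_id, top)
    dominant = next(p for p in DOMINANCE_ORDER if p in top)
    return SiteProcessSummary(
        site_id=str(site_id),
        tropicalization=sums["tropicalization"],
        deborealization=sums["deborealization"],
        borealization=sums["borealization"],
        detropicalization=sums["detropicalization"],
        signed_total=signed, dominant=dominant,
    )


def decompose_all(abundance: pd.DataFrame, preferences: pd.DataFrame,
                  cti: pd.DataFrame, reference: str = "time_mean",
                  estimator: str = "ols_slope") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species records and per-site summaries for every site."""
    rec_frames, summaries = [], []
    for site, grp in abundance.groupby("site_id", sort=True):
        cti_site = cti[cti["site_id"] == site]
        if cti_site.empty:
            log.warning("site %s has no CTI series; skipped", site)
            continue
        recs = decompose_site(grp, preferences, cti_site,
                              reference=reference, estimator=estimator)
        rec_frames.append(recs)
        summaries.append(process_intensities(recs, site_id=site).as_dict())
    records = (pd.concat(rec_frames, ignore_index=True) if rec_frames
               else pd.DataFrame())
    return records, pd.DataFrame(summaries)


def dominance_shares(summaries: pd.DataFrame) -> dict[str, float]:
    """Percentage of sites whose dominant process is each of the four."""
    if summaries.empty:
        raise ValueError("no site summaries")
    counts = summaries["dominant"].value_counts()
    n = len(summaries)
    return {p: 100.0 * float(counts.get(p, 0)) / n for p in PROCESSES}


def trop_minus_deb(summary: SiteProcessSummary | pd.Series) -> float:
    """Tropicalization minus deborealization intensity (CTI_r > 0 contrast)."""
    if isinstance(summary, SiteProcessSummary):
        return summary.tropicalization - summary.deborealization
    return float(summary["tropicalization"] - summary["deborealization"])


def gain_minus_loss(summary: SiteProcessSummary | pd.Series) -> float:
    """(trop + bor) - (det + deb): abundance gains minus losses."""
    if isinstance(summary, SiteProcessSummary):
        return (summary.tropicalization + summary.borealization
                - summary.detropicalization - summary.deborealization)
    return float(summary["tropicalization"] + summary["borealization"]
                 - summary["detropicalization"] - summary["deborealization"])


def compare_processes_across_factors(
    values: pd.DataFrame, metadata: pd.DataFrame, factor: str,
    value_col: str = "value", basis: str = "per_site",
) -> pd.DataFrame:
    """Per-level means of a process statistic with two-sided Wald tests.

    ``per_site`` fits an ordinary linear model of the per-site statistic on
    the factor (cell means, pooled residual variance, df = n - n_levels).
    ``per_species`` adds a site random intercept (per-species contributions
    as rows) via the mixed-model machinery. Levels with one observation are
    flagged ``unreliable``.
    """
    from scipy import stats as _st

    if factor not in metadata.columns:
        raise KeyError(f"unknown factor {factor!r}")
    df = values.merge(metadata[["site_id", factor]], on="site_id", how="left")
    if df[factor].isna().any():
        missing = sorted(df.loc[df[factor].isna(), "site_id"].unique())
        raise KeyError(f"site(s) without metadata: {missing}")

    if basis == "per_species":
        return _compare_per_species(df, factor, value_col)
    if basis != "per_site":
        raise ValueError(f"unknown basis {basis!r}")

    levels = sorted(df[factor].unique())
    n = len(df)
    k = len(levels)
    # pooled residual variance from the cell-means fit
    rss = sum(((g[value_col] - g[value_col].mean()) ** 2).sum()
              for _, g in df.groupby(factor))
    dof = n - k
    s2 = rss / dof if dof > 0 else np.nan
    rows = []
    for lev in levels:
        sub = df.loc[df[factor] == lev, value_col]
        m = float(sub.mean())
        se = float(np.sqrt(s2 / len(sub))) if dof > 0 else np.nan
        if se and se > 0:
            t = m / se
            p = 2.0 * _st.t.sf(abs(t), dof)
        else:
            t, p = np.nan, np.nan
        rows.append({"factor": factor, "level": lev, "n": len(sub), "mean": m,
                     "se": se, "t_stat": t, "p_value": p,
                     "unreliable": len(sub) <= 1})
    return pd.DataFrame(rows)


def _compare_per_species(df: pd.DataFrame, factor: str, value_col: str) -> pd.DataFrame:
    from .mixed import _factor_design, _fit_marginal

    work = df.rename(columns={value_col: "cti"}).copy()
    if "year" not in work.columns:  # per-species rows carry no time axis
        work["year"] = 0
    fac = work[factor]
    X, terms, levels = _factor_design(work, fac)
    # cell-means design: keep only the level intercepts (no time trend here)
    keep = [i for i, t in enumerate(terms) if t.startswith("intercept")]
    fit = _fit_marginal(work, X[:, keep], [terms[i] for i in keep],
                        estimate_phi=False)
    rows = []
    for lev in levels:
        term = "intercept" if len(levels) == 1 else f"intercept[{lev}]"
        est, se, t, p = fit.fixed_effects[term]
        n_lev = int((fac == lev).sum())
        rows.append({"factor": factor, "level": lev, "n": n_lev, "mean": est,
                     "se": se, "t_stat": t, "p_value": p,
                     "unreliable": n_lev <= 1})
    return pd.DataFrame(rows)
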