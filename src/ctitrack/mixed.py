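"""Linear mixed models with site random intercepts and AR(1) residuals.

The pooled trend across monitoring sites is estimated with the marginal form
of the random-intercept model

    y_it = x_it' beta + b_i + e_it,   b_i ~ N(0, sigma_b^2),
    e_it AR(1) within site: corr(e_it, e_is) = phi ** |t - s|,

i.e. per-site covariance V_i = sigma_b^2 J + sigma_e^2 R_i(phi). The fit
maximises the exact marginal likelihood by profiling beta and sigma_e^2
analytically and searching over (lambda = sigma_b^2/sigma_e^2, phi) with
Nelder-Mead. Maximum likelihood (not REML) is used throughout so AICc values
are comparable across fixed-effect structures.

Wald tests use a t reference with n_obs - k_fixed degrees of freedom, an
approximation in the style of the large-sample output of nlme-type software.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .trends import aicc as _aicc
from .trends import ar1_correlation, fit_site_trend, TrendEstimate

log = logging.getLogger("ctitrack")

_PHI_BOUND = 0.99


@dataclass
class MixedModelFit:
    fixed_effects: dict[str, tuple[float, float, float, float]]  # (est, se, t, p)
    random_intercepts: dict[str, float]
    residual_sd: float
    intercept_sd: float
    ar1_phi: float
    loglik: float
    k_params: int
    n_obs: int
    aicc: float
    df_resid: int
    terms: list[str] = field(default_factory=list)
    fitted_fixed: np.ndarray | None = None  # X @ beta, aligned to input rows
    converged: bool = True

    def coef(self, term: str) -> float:
        return self.fixed_effects[term][0]


def _group_arrays(df: pd.DataFrame, X: np.ndarray, y: np.ndarray):
    """Split design/response by site, keeping within-site year order."""
    groups = []
    for site, idx in df.groupby("site_id", sort=True).indices.items():
        idx = np.asarray(idx)
        order = np.argsort(df["year"].to_numpy()[idx], kind="mergesort")
        idx = idx[order]
        groups.append((site, idx, X[idx], y[idx],
                       df["year"].to_numpy(dtype=float)[idx]))
    return groups


def _profiled_nll(lam: float, phi: float, groups, p: int):
    """Negative profiled log-likelihood; also returns the profiled estimates."""
    n = sum(len(g[3]) for g in groups)
    XtX = np.zeros((p, p))
    Xty = np.zeros(p)
    yty = 0.0
    logdet = 0.0
    chols = []
    cache: dict[bytes, np.ndarray] = {}  # sites sharing a year grid share W
    for _, _, Xi, yi, ti in groups:
        key = ti.tobytes()
        L = cache.get(key)
        if L is None:
            W = lam * np.ones((len(yi), len(yi))) + ar1_correlation(ti, phi)
            L = np.linalg.cholesky(W)
            cache[key] = L
        chols.append(L)
        Xw = np.linalg.solve(L, Xi)
        yw = np.linalg.solve(L, yi)
        XtX += Xw.T @ Xw
        Xty += Xw.T @ yw
        yty += yw @ yw
        logdet += 2.0 * np.sum(np.log(np.diag(L)))
    beta = np.linalg.solve(XtX, Xty)
    rss = max(float(yty - beta @ Xty), 0.0)
    sigma2_ml = max(rss / n, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi) + np.log(sigma2_ml) + 1.0) - 0.5 * logdet
    return -ll, beta, XtX, rss, chols


def _fit_marginal(
    df: pd.DataFrame, X: np.ndarray, terms: list[str],
    estimate_phi: bool = True,
) -> MixedModelFit:
    y = df["cti"].to_numpy(dtype=float) if "cti" in df.columns else df["value"].to_numpy(dtype=float)
    p = X.shape[1]
    n = len(y)
    if np.linalg.matrix_rank(X) < p:
        raise np.linalg.LinAlgError(
            "aliased fixed-effect design (collinear factor combination)")
    groups = _group_arrays(df, X, y)

    def unpack(u):
        lam = np.exp(np.clip(u[0], -30.0, 30.0))
        phi = _PHI_BOUND * np.tanh(u[1]) if estimate_phi else 0.0
        return lam, phi

    def objective(u):
        lam, phi = unpack(u)
        try:
            return _profiled_nll(lam, phi, groups, p)[0]
        except np.linalg.LinAlgError:
            return np.inf

    starts = ([np.array([np.log(0.5), 0.0]), np.array([np.log(2.0), 0.31])]
              if estimate_phi else
              [np.array([np.log(0.5), 0.0]), np.array([np.log(2.0), 0.0])])
    best = None
    for u0 in starts:
        res = optimize.minimize(objective, u0, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-9,
                                         "maxiter": 2000})
        if best is None or res.fun < best.fun:
            best = res
    lam, phi = unpack(best.x)
    nll, beta, XtX, rss, chols = _profiled_nll(lam, phi, groups, p)
    loglik = -nll

    sigma2_ml = max(rss / n, 0.0)
    dof = n - p
    sigma2_unb = rss / dof if dof > 0 else np.nan
    cov_beta = sigma2_unb * np.linalg.inv(XtX)
    fixed = {}
    for j, term in enumerate(terms):
        est = float(beta[j])
        se = float(np.sqrt(max(cov_beta[j, j], 0.0)))
        if se > 0:
            t = est / se
            pv = 2.0 * stats.t.sf(abs(t), dof)
        else:
            t = np.inf if est != 0 else 0.0
            pv = 0.0 if est != 0 else 1.0
        fixed[term] = (est, se, float(t), float(pv))

    # BLUPs: b_i = sigma_b^2 1' V_i^{-1} (y_i - X_i beta) = lam 1' W_i^{-1} r_i
    blups = {}
    fitted = np.empty(n)
    for (site, idx, Xi, yi, ti), L in zip(groups, chols):
        ri = yi - Xi @ beta
        wi = np.linalg.solve(L.T, np.linalg.solve(L, ri))
        blups[site] = float(lam * wi.sum())
        fitted[idx] = Xi @ beta

    k = p + (3 if estimate_phi else 2)  # beta + sigma_b + sigma_e (+ phi)
    return MixedModelFit(
        fixed_effects=fixed,
        random_intercepts=blups,
        residual_sd=float(np.sqrt(sigma2_ml)),
        intercept_sd=float(np.sqrt(lam * sigma2_ml)),
        ar1_phi=float(phi),
        loglik=float(loglik),
        k_params=k,
        n_obs=n,
        aicc=float(_aicc(loglik, k, n)),
        df_resid=dof,
        terms=list(terms),
        fitted_fixed=fitted,
        converged=bool(best.success),
    )


def _year_centered(df: pd.DataFrame) -> np.ndarray:
    yr = df["year"].to_numpy(dtype=float)
    return yr - yr.mean()


def fit_pooled_trend(cti: pd.DataFrame, value_col: str = "cti",
                     estimate_phi: bool = True) -> MixedModelFit:
    """Pooled trend: value ~ year, site random intercepts, AR(1) residuals.

    ``cti`` needs columns ``site_id, year`` and ``value_col``. The slope is
    reported under the term name ``"year"`` (years centred internally; the
    intercept is the fitted value at the mean year). With a single site the
    random intercept is unidentifiable and the per-site GLS fit is returned
    instead, with a warning.
    """
    df = cti.rename(columns={value_col: "cti"})[["site_id", "year", "cti"]]
    sites = df["site_id"].unique()
    if len(sites) < 2:
        log.warning("single site: falling back to per-site GLS trend")
        sub = df.sort_values("year")
        est = fit_site_trend(sub["year"].to_numpy(), sub["cti"].to_numpy(),
                             site_id=str(sites[0]))
        return _trend_as_mixed(est, df)
    X = np.column_stack([np.ones(len(df)), _year_centered(df)])
    return _fit_marginal(df, X, ["intercept", "year"], estimate_phi=estimate_phi)


def _trend_as_mixed(est: TrendEstimate, df: pd.DataFrame) -> MixedModelFit:
    """Wrap a single-site GLS trend in the MixedModelFit container."""
    yr = _year_centered(df)
    fitted = df["cti"].mean() + est.slope * yr  # intercept at mean year
    return MixedModelFit(
        fixed_effects={"intercept": (float(df["cti"].mean()), np.nan, np.nan, np.nan),
                       "year": (est.slope, est.se, est.t_stat, est.p_value)},
        random_intercepts={est.site_id: 0.0},
        residual_sd=np.nan, intercept_sd=0.0,
        ar1_phi=est.phi if est.ar1_used else 0.0,
        loglik=np.nan, k_params=2, n_obs=est.n_years, aicc=np.nan,
        df_resid=est.n_years - 2, terms=["intercept", "year"],
        fitted_fixed=np.asarray(fitted), converged=True,
    )


def compute_partial_residuals(fit: MixedModelFit, cti: pd.DataFrame,
                              value_col: str = "cti") -> pd.DataFrame:
    """Observed values minus the site random intercept (BLUP).

    Partial residuals isolate the temporal signal shared across sites: the
    fixed-effect prediction plus the within-site residual.
    """
    unknown = sorted(set(cti["site_id"]) - set(fit.random_intercepts))
    if unknown:
        raise KeyError(f"site(s) not in fitted model: {unknown}")
    out = cti.copy()
    offsets = cti["site_id"].map(fit.random_intercepts).to_numpy(dtype=float)
    out["partial_residual"] = cti[value_col].to_numpy(dtype=float) - offsets
    return out


def _factor_design(df: pd.DataFrame, factor_values: pd.Series):
    """Cell-means design: one intercept and one year slope per factor level."""
    yearc = _year_centered(df)
    levels = sorted(factor_values.unique())
    if len(levels) == 1:
        X = np.column_stack([np.ones(len(df)), yearc])
        return X, ["intercept", "year"], levels
    cols, terms = [], []
    for lev in levels:
        ind = (factor_values == lev).to_numpy(dtype=float)
        cols.append(ind)
        terms.append(f"intercept[{lev}]")
    for lev in levels:
        ind = (factor_values == lev).to_numpy(dtype=float)
        cols.append(ind * yearc)
        terms.append(f"year[{lev}]")
    return np.column_stack(cols), terms, levels


def fit_factor_trends(
    cti: pd.DataFrame, metadata: pd.DataFrame, factor: str,
    value_col: str = "cti", estimate_phi: bool = True,
) -> tuple[pd.DataFrame, MixedModelFit]:
    """Per-level year slopes from a mixed model with a year-by-factor interaction.

    Each factor level gets its own intercept and slope (cell-means coding), so
    the per-level slope, SE and two-sided Wald test read directly off the fit.
    Returns a tidy per-level table and the underlying ``MixedModelFit``.
    Levels represented by a single site are flagged ``low_replication``.
    """
    if factor not in metadata.columns:
        raise KeyError(f"unknown factor {factor!r}")
    df = cti.rename(columns={value_col: "cti"})[["site_id", "year", "cti"]].copy()
    fac = df["site_id"].map(metadata.set_index("site_id")[factor])
    if fac.isna().any():
        missing = sorted(df.loc[fac.isna(), "site_id"].unique())
        raise KeyError(f"site(s) without metadata: {missing}")
    X, terms, levels = _factor_design(df, fac)
    fit = _fit_marginal(df, X, terms, estimate_phi=estimate_phi)

    sites_per_level = metadata.groupby(factor)["site_id"].nunique()
    rows = []
    for lev in levels:
        term = "year" if len(levels) == 1 else f"year[{lev}]"
        est, se, t, p = fit.fixed_effects[term]
        n_sites = int(sites_per_level.get(lev, 0))
        rows.append({"factor": factor, "level": lev, "slope": est, "se": se,
                     "t_stat": t, "p_value": p, "n_sites": n_sites,
                     "low_replication": n_sites <= 1})
    return pd.DataFrame(rows), fit


def _subset_design(df: pd.DataFrame, metadata: pd.DataFrame,
                   factors: tuple[str, ...]):
    """Treatment-coded design with year interactions for a factor subset."""
    yearc = _year_centered(df)
    cols = [np.ones(len(df)), yearc]
    terms = ["intercept", "year"]
    meta_ix = metadata.set_index("site_id")
    for factor in factors:
        fac = df["site_id"].map(meta_ix[factor])
        levels = sorted(fac.unique())
        for lev in levels[1:]:  # first level is the reference
            ind = (fac == lev).to_numpy(dtype=float)
            cols.append(ind)
            terms.append(f"{factor}[{lev}]")
            cols.append(ind * yearc)
            terms.append(f"year:{factor}[{lev}]")
    return np.column_stack(cols), terms


def select_best_model(
    cti: pd.DataFrame, metadata: pd.DataFrame,
    factors: list[str], value_col: str = "cti",
    candidates: list[tuple[str, ...]] | None = None,
    estimate_phi: bool = True,
) -> pd.DataFrame:
    """Fit all factor-subset models and rank them by AICc (ascending).

    Every combination of the given factors (including the intercept-plus-year
    only model) enters a mixed model with year-by-factor interactions; models
    are ranked by AICc, ties broken by fewer parameters then lexicographic
    factor names. Candidates that fail to fit are recorded and excluded.
    """
    df = cti.rename(columns={value_col: "cti"})[["site_id", "year", "cti"]].copy()
    if candidates is None:
        candidates = [tuple(sorted(c)) for r in range(len(factors) + 1)
                      for c in itertools.combinations(sorted(factors), r)]
    if not candidates:
        raise ValueError("no candidate models")
    rows = []
    for cand in candidates:
        name = " + ".join(cand) if cand else "(none)"
        try:
            X, terms = _subset_design(df, metadata, tuple(cand))
            fit = _fit_marginal(df, X, terms, estimate_phi=estimate_phi)
            rows.append({"factors": name, "aicc": fit.aicc, "k_params": fit.k_params,
                         "loglik": fit.loglik, "failed": False})
        except Exception as err:  # noqa: BLE001 — a failed candidate must not stop the run
            log.warning("candidate %s failed to fit: %s", name, err)
            rows.append({"factors": name, "aicc": np.nan, "k_params": np.nan,
                         "loglik": np.nan, "failed": True})
    ranking = pd.DataFrame(rows)
    ok = ranking[~ranking["failed"]].sort_values(
        ["aicc", "k_params", "factors"], kind="mergesort")
    bad = ranking[ranking["failed"]]
    out = pd.concat([ok, bad], ignore_index=True)
    out["rank"] = [*range(1, len(ok) + 1), *[np.nan] * len(bad)]
    return out


def relate_cti_to_temperature(
    cti: pd.DataFrame, temperature: pd.DataFrame,
    temp_col: str = "sst", estimate_phi: bool = True,
) -> MixedModelFit:
    """Mixed model of CTI on sea temperature across matched site-years.

    Site random intercepts with AR(1) residuals; the slope of interest is
    reported under the term name ``temp_col``.
    """
    merged = cti.merge(temperature[["site_id", "year", temp_col]],
                       on=["site_id", "year"], how="inner").dropna(subset=[temp_col])
    if merged.empty:
        raise ValueError("no matched site-years between CTI and temperature")
    if merged["site_id"].nunique() < 2:
        log.warning("single matched site in CTI~temperature model")
    x = merged[temp_col].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(merged)), x - x.mean()])
    return _fit_marginal(merged[["site_id", "year", "cti"]].assign(cti=merged["cti"]),
                         X, ["intercept", temp_col], estimate_phi=estimate_phi)
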