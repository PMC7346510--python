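"""Regression and non-parametric models linking energy stores to
departure decisions, plus the end-to-end study pipeline.

The centrepiece is a beta regression for the proportion of night at
departure (logit mean link, constant precision, maximum likelihood)
with observed-information standard errors, alongside ordinary linear
models on (optionally log10-transformed) departure timing,
Mann-Whitney/Fisher tests using the same conventions under which the
field results are usually printed (W equals the rank-sum U of the
first sample, as in R's ``wilcox.test``), weather matching at the
sunset hour, and :func:`run_study`, which reproduces the whole analysis
from a capture table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from datetime import date, timedelta
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from scipy.special import digamma, gammaln

from . import circular, solar
from .energetics import add_energy_columns

logger = logging.getLogger(__name__)

SPECIES_REF = "CR"  # redstart = reference level; robin enters as indicator


# --------------------------------------------------------------------------
# Beta regression
# --------------------------------------------------------------------------

@dataclass
class BetaRegFit:
    names: Sequence[str]
    params: np.ndarray
    se: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    phi: float
    pseudo_r2: float
    loglik: float
    n: int
    converged: bool

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.se, "z": self.z_values, "p": self.p_values},
            index=list(self.names),
        )


def _beta_negloglik_grad(theta: np.ndarray, x: np.ndarray, y: np.ndarray):
    k = x.shape[1]
    beta, logphi = theta[:k], theta[k]
    phi = np.exp(logphi)
    eta = x @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    a, b = mu * phi, (1.0 - mu) * phi
    ll = np.sum(gammaln(phi) - gammaln(a) - gammaln(b) + (a - 1) * np.log(y) + (b - 1) * np.log1p(-y))
    ystar = np.log(y) - np.log1p(-y)
    mustar = digamma(a) - digamma(b)
    dbeta = x.T @ (phi * (ystar - mustar) * mu * (1.0 - mu))
    dphi_raw = np.sum(
        digamma(phi) - mu * digamma(a) - (1.0 - mu) * digamma(b)
        + mu * np.log(y) + (1.0 - mu) * np.log1p(-y)
    )
    grad = np.concatenate([dbeta, [dphi_raw * phi]])
    return -ll, -grad


def fit_beta_regression(y: Sequence[float], design: pd.DataFrame) -> BetaRegFit:
    """ML beta regression with logit mean link and constant precision.

    ``design`` must already contain the intercept column.  Standard
    errors come from the observed information (numerical Hessian of the
    log-likelihood at the optimum); the pseudo-R^2 is the squared
    Pearson correlation between the fitted linear predictor and
    logit(y), the convention of the reference beta-regression software.
    """
    yv = np.asarray(y, dtype=float)
    x = np.asarray(design, dtype=float)
    names = list(design.columns) if isinstance(design, pd.DataFrame) else [
        f"x{i}" for i in range(x.shape[1])
    ]
    if np.any((yv <= 0) | (yv >= 1)):
        raise ValueError(
            "beta regression requires responses strictly inside (0, 1); "
            "transform or exclude boundary observations first"
        )
    n, k = x.shape
    # Warm start: OLS of logit(y), method-of-moments precision.
    ylogit = np.log(yv) - np.log1p(-yv)
    beta0, *_ = np.linalg.lstsq(x, ylogit, rcond=None)
    mu0 = 1.0 / (1.0 + np.exp(-(x @ beta0)))
    resid_var = max(np.var(yv - mu0, ddof=k), 1e-8)
    phi0 = max(float(np.mean(mu0 * (1 - mu0)) / resid_var - 1.0), 1.0)
    theta0 = np.concatenate([beta0, [np.log(phi0)]])
    res = scipy.optimize.minimize(
        _beta_negloglik_grad,
        theta0,
        args=(x, yv),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 500, "gtol": 1e-8, "ftol": 1e-12},
    )
    if not res.success and np.linalg.norm(res.jac) > 1e-3:
        raise RuntimeError(f"beta regression did not converge: {res.message}")
    theta = res.x
    # Observed information on (beta, log phi); delta-method not needed for
    # beta SEs because the phi block is separate only after inversion.
    hess = _numerical_hessian(lambda t: _beta_negloglik_grad(t, x, yv)[0], theta)
    cov = np.linalg.inv(hess)
    se_all = np.sqrt(np.clip(np.diag(cov), 0, None))
    beta, se = theta[:k], se_all[:k]
    zvals = beta / se
    pvals = 2.0 * scipy.stats.norm.sf(np.abs(zvals))
    eta = x @ beta
    with np.errstate(invalid="ignore"):
        r = np.corrcoef(eta, ylogit)[0, 1] if np.std(eta) > 0 else 0.0
    return BetaRegFit(
        names=names,
        params=beta,
        se=se,
        z_values=zvals,
        p_values=pvals,
        phi=float(np.exp(theta[k])),
        pseudo_r2=float(r**2),
        loglik=float(-res.fun),
        n=n,
        converged=bool(res.success),
    )


def _numerical_hessian(f, x0: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    k = x0.size
    h = np.zeros((k, k))
    steps = eps * np.maximum(1.0, np.abs(x0))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            fpp = f(x0 + ei + ej)
            fpm = f(x0 + ei - ej)
            fmp = f(x0 - ei + ej)
            fmm = f(x0 - ei - ej)
            h[i, j] = h[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * steps[i] * steps[j])
    return h


# --------------------------------------------------------------------------
# Linear models and non-parametric tests
# --------------------------------------------------------------------------

@dataclass
class LinearFit:
    names: Sequence[str]
    params: np.ndarray
    se: np.ndarray
    t_values: np.ndarray
    p_values: np.ndarray
    r2: float
    f_stat: float
    f_p: float
    df_model: int
    df_resid: int
    n: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.se, "t": self.t_values, "p": self.p_values},
            index=list(self.names),
        )


def fit_linear_model(
    response: Sequence[float], design: pd.DataFrame, transform: Optional[str] = None
) -> LinearFit:
    """OLS with optional log10 response transform (``transform="log10"``)."""
    import statsmodels.api as sm

    yv = np.asarray(response, dtype=float)
    if transform == "log10":
        if np.any(yv <= 0):
            raise ValueError("log10 transform requires positive responses")
        yv = np.log10(yv)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    x = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("singular design matrix")
    fit = sm.OLS(yv, x).fit()
    return LinearFit(
        names=list(design.columns),
        params=fit.params,
        se=fit.bse,
        t_values=fit.tvalues,
        p_values=fit.pvalues,
        r2=float(fit.rsquared),
        f_stat=float(fit.fvalue) if x.shape[1] > 1 else float("nan"),
        f_p=float(fit.f_pvalue) if x.shape[1] > 1 else float("nan"),
        df_model=int(fit.df_model),
        df_resid=int(fit.df_resid),
        n=len(yv),
    )


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> Dict[str, float]:
    """Mann-Whitney U test; W follows the R ``wilcox.test`` convention
    (number of pairs a_i > b_j, plus half-ties), exact p for small
    untied samples."""
    av, bv = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if av.size == 0 or bv.size == 0:
        raise ValueError("both samples must be non-empty")
    ties = np.intersect1d(av, bv).size > 0 or (
        np.unique(np.concatenate([av, bv])).size < av.size + bv.size
    )
    method = "exact" if (min(av.size, bv.size) < 50 and not ties) else "asymptotic"
    res = scipy.stats.mannwhitneyu(av, bv, alternative="two-sided", method=method)
    return {"W": float(res.statistic), "p": float(res.pvalue), "n_a": int(av.size), "n_b": int(bv.size)}


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p for a 2x2 count table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 integer table")
    return float(scipy.stats.fisher_exact(t, alternative="two-sided")[1])


# --------------------------------------------------------------------------
# Weather
# --------------------------------------------------------------------------

def attach_weather(
    days: Sequence[date],
    weather: pd.DataFrame,
    latitude: float,
    longitude: float,
    max_gap_h: float = 3.0,
) -> pd.DataFrame:
    """Weather at the sunset hour for each requested day.

    ``weather`` needs a UTC ``ts`` column plus ``wind_speed`` (m/s),
    ``wind_dir`` (degrees, meteorological blowing-FROM), ``precip``
    (mm) and ``temp`` (degC).  The row nearest the computed sunset is
    used; beyond ``max_gap_h`` hours the day is flagged missing.  A
    blowing-toward direction is derived for plotting conventions.
    """
    w = weather.copy()
    w["ts"] = pd.to_datetime(w["ts"], utc=True)
    rows = []
    for d in days:
        sunset, _ = solar.sun_events(d, latitude, longitude)
        target = pd.Timestamp(sunset)
        gaps = (w["ts"] - target).abs()
        i = gaps.idxmin() if len(w) else None
        if i is None or gaps.loc[i] > pd.Timedelta(hours=max_gap_h):
            rows.append({"date": d, "sunset": target, "missing": True})
            continue
        r = w.loc[i]
        rows.append(
            {
                "date": d,
                "sunset": target,
                "missing": False,
                "wind_speed": float(r["wind_speed"]),
                "wind_dir": float(r["wind_dir"]) % 360.0,
                "wind_toward": (float(r["wind_dir"]) + 180.0) % 360.0,
                "precip": float(r.get("precip", np.nan)),
                "temp": float(r.get("temp", np.nan)),
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# End-to-end study
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class StudyConfig:
    site_lat: float = 54.183
    site_lon: float = 7.883
    randomization_reps: int = 10_000
    randomization_seed: int = 1
    min_n_circular: int = 4
    min_n_model: int = 4


def _clean_directions(series: pd.Series) -> np.ndarray:
    return series.dropna().to_numpy(dtype=float) % 360.0


def _lm_report(fit: LinearFit) -> dict:
    return {
        "coefficients": {
            name: {"estimate": float(e), "se": float(s), "t": float(t), "p": float(p)}
            for name, e, s, t, p in zip(fit.names, fit.params, fit.se, fit.t_values, fit.p_values)
        },
        "r2": fit.r2,
        "f": fit.f_stat,
        "f_p": fit.f_p,
        "df": [fit.df_model, fit.df_resid],
        "n": fit.n,
    }


def _beta_report(fit: BetaRegFit) -> dict:
    return {
        "coefficients": {
            name: {"estimate": float(e), "se": float(s), "z": float(z), "p": float(p)}
            for name, e, s, z, p in zip(fit.names, fit.params, fit.se, fit.z_values, fit.p_values)
        },
        "phi": fit.phi,
        "pseudo_r2": fit.pseudo_r2,
        "n": fit.n,
    }


def run_study(birds: pd.DataFrame, config: StudyConfig = StudyConfig()) -> dict:
    """Reproduce the full stopover analysis from a capture table.

    Expects the capture-table schema (Time, Species, Muscle, Wing,
    Bodymass, take.off, dep.dir, days.on.island, dep.min.sunset,
    dep.realtive.night, wind.speed, wind.dir; the historical file's
    misspelling ``dep.realtive.night`` is accepted alongside the
    corrected ``dep.relative.night``).  Emits a nested, JSON-ready
    report; analyses whose subset falls below the minimum n are skipped
    with a logged reason.  Models containing an energy-store term are
    restricted to birds departing the first night after capture,
    because stores change over a stopover.
    """
    df = birds.copy()
    if "dep.relative.night" in df.columns and "dep.realtive.night" not in df.columns:
        df = df.rename(columns={"dep.relative.night": "dep.realtive.night"})
    df = add_energy_columns(df)
    df["first_night"] = df["days.on.island"] == 1
    df["is_robin"] = (df["Species"] == "ER").astype(float)
    report: dict = {"n": {sp: int(n) for sp, n in df["Species"].value_counts().items()}}
    exclusions: list = []

    cr = df[df["Species"] == "CR"]
    er = df[df["Species"] == "ER"]
    fn = df[df["first_night"]]

    # Energy stores by species (LM on raw stores).
    if len(df) > 2 and cr.size and er.size:
        design = pd.DataFrame({"intercept": 1.0, "species_robin": df["is_robin"]})
        report["stores_by_species_lm"] = _lm_report(fit_linear_model(df["energy_stores"], design))

    # Capture-time effect on stores, per species.
    cap_lms = {}
    for name, sub in (("CR", cr), ("ER", er)):
        if len(sub) < config.min_n_model:
            exclusions.append(f"capture-time LM skipped for {name} (n={len(sub)})")
            continue
        hours = pd.to_datetime(sub["Time"], format="%H:%M").dt.hour + pd.to_datetime(
            sub["Time"], format="%H:%M"
        ).dt.minute / 60.0
        design = pd.DataFrame({"intercept": 1.0, "capture_hour": hours.to_numpy()})
        cap_lms[name] = _lm_report(fit_linear_model(sub["energy_stores"], design))
    report["stores_vs_capture_time_lm"] = cap_lms

    # Minimum stopover by species.
    cr_days = cr["days.on.island"].dropna()
    er_days = er["days.on.island"].dropna()
    if len(cr_days) and len(er_days):
        report["stopover_mann_whitney"] = mann_whitney(cr_days, er_days)
    else:
        exclusions.append("stopover comparison skipped (no ascertainable departures)")

    # First-night departure vs stores per species; departure fractions.
    fn_tests = {}
    for name, sub in (("CR", cr), ("ER", er)):
        dep = sub[sub["first_night"]]["energy_stores"]
        stay = sub[~sub["first_night"]]["energy_stores"]
        if dep.empty or stay.empty:
            exclusions.append(f"first-night stores comparison skipped for {name}")
            continue
        fn_tests[name] = mann_whitney(dep, stay)
    report["first_night_stores_mann_whitney"] = fn_tests
    table = [
        [int(cr["first_night"].sum()), int((~cr["first_night"]).sum())],
        [int(er["first_night"].sum()), int((~er["first_night"]).sum())],
    ]
    report["departure_fraction"] = {
        "table": table,
        "fisher_p": fisher_exact_2x2(table),
        "fraction_cr": table[0][0] / max(len(cr), 1),
        "fraction_er": table[1][0] / max(len(er), 1),
    }

    # Beta regressions on proportion of night (Table 1 analogues).
    prop = df["dep.realtive.night"]
    ok = prop.notna() & (prop > 0) & (prop < 1)
    sub = df[ok]
    if len(sub) >= config.min_n_model:
        design = pd.DataFrame(
            {"intercept": 1.0, "species_robin": sub["is_robin"].to_numpy()}, index=sub.index
        )
        report["beta_all_birds"] = _beta_report(
            fit_beta_regression(sub["dep.realtive.night"], design)
        )
    sub_fn = fn[fn["dep.realtive.night"].notna() & (fn["dep.realtive.night"] > 0) & (fn["dep.realtive.night"] < 1)]
    if len(sub_fn) >= config.min_n_model + 1:
        design = pd.DataFrame(
            {
                "intercept": 1.0,
                "species_robin": sub_fn["is_robin"].to_numpy(),
                "stores_scaled": sub_fn["stores_scaled"].to_numpy(),
            },
            index=sub_fn.index,
        )
        fit = fit_beta_regression(sub_fn["dep.realtive.night"], design)
        report["beta_first_night"] = _beta_report(fit)
        report["beta_first_night"]["n_by_species"] = {
            sp: int(n) for sp, n in sub_fn["Species"].value_counts().items()
        }
    else:
        exclusions.append(f"first-night beta regression skipped (n={len(sub_fn)})")

    # Linear models on log10 minutes after sunset (Table 2 analogues).
    mins = df["dep.min.sunset"]
    ok = mins.notna() & (mins > 0)
    sub = df[ok]
    if len(sub) >= config.min_n_model:
        design = pd.DataFrame(
            {"intercept": 1.0, "species_robin": sub["is_robin"].to_numpy()}, index=sub.index
        )
        report["lm_minutes_all_birds"] = _lm_report(
            fit_linear_model(sub["dep.min.sunset"], design, transform="log10")
        )
    sub_fn = fn[fn["dep.min.sunset"].notna() & (fn["dep.min.sunset"] > 0)]
    if len(sub_fn) >= config.min_n_model + 1:
        design = pd.DataFrame(
            {
                "intercept": 1.0,
                "species_robin": sub_fn["is_robin"].to_numpy(),
                "stores_scaled": sub_fn["stores_scaled"].to_numpy(),
            },
            index=sub_fn.index,
        )
        report["lm_minutes_first_night"] = _lm_report(
            fit_linear_model(sub_fn["dep.min.sunset"], design, transform="log10")
        )

    # Redstart-only LM: minutes after sunset ~ scaled stores (first night).
    cr_fn = cr[cr["first_night"] & cr["dep.min.sunset"].notna()]
    if len(cr_fn) >= config.min_n_model:
        design = pd.DataFrame(
            {"intercept": 1.0, "stores_scaled": cr_fn["stores_scaled"].to_numpy()},
            index=cr_fn.index,
        )
        report["lm_minutes_redstart_first_night"] = _lm_report(
            fit_linear_model(cr_fn["dep.min.sunset"], design)
        )
    else:
        exclusions.append(f"redstart first-night minutes LM skipped (n={len(cr_fn)})")

    # Directions: Rayleigh + mean per species (all and first-night),
    # Watson between species (first night), circular-linear correlations.
    directions: dict = {}
    for label, subset in (
        ("CR_all", cr),
        ("ER_all", er),
        ("CR_first_night", cr[cr["first_night"]]),
        ("ER_first_night", er[er["first_night"]]),
    ):
        dirs = _clean_directions(subset["dep.dir"])
        if dirs.size < max(2, config.min_n_circular):
            exclusions.append(f"Rayleigh skipped for {label} (n={dirs.size})")
            continue
        rho, p = circular.rayleigh_test(dirs)
        mean, _ = circular.circular_mean_and_rho(dirs)
        entry = {"n": int(dirs.size), "rho": rho, "rayleigh_p": p}
        # Convention: report the mean direction only alongside a
        # significant Rayleigh test.
        entry["mean_direction"] = float(mean) if (p < 0.05 and mean is not None) else None
        directions[label] = entry
    a = _clean_directions(cr[cr["first_night"]]["dep.dir"])
    b = _clean_directions(er[er["first_night"]]["dep.dir"])
    if a.size >= 4 and b.size >= 4:
        w = circular.watson_two_sample(a, b)
        directions["watson_first_night"] = {
            "u2": w.u2,
            "p_range": [w.p_lower, w.p_upper],
            "n": [int(a.size), int(b.size)],
        }
    corr: dict = {}
    seed = config.randomization_seed
    for name, subset in (("CR", cr[cr["first_night"]]), ("ER", er[er["first_night"]])):
        sub2 = subset[subset["dep.dir"].notna()]
        if len(sub2) < 4 or sub2["energy_stores"].std() == 0:
            exclusions.append(f"stores-direction correlation skipped for {name}")
            continue
        r, p = circular.circ_linear_correlation(
            sub2["dep.dir"], sub2["energy_stores"],
            n_reps=config.randomization_reps, seed=seed,
        )
        corr[name] = {"r": r, "p": p, "n": int(len(sub2))}
    directions["stores_vs_direction"] = corr
    wind_sub = df[df["dep.dir"].notna() & df["wind.speed"].notna()]
    if len(wind_sub) >= 4 and wind_sub["wind.speed"].std() > 0:
        r, p = circular.circ_linear_correlation(
            wind_sub["dep.dir"], wind_sub["wind.speed"],
            n_reps=config.randomization_reps, seed=seed,
        )
        directions["wind_speed_vs_direction"] = {"r": r, "p": p, "n": int(len(wind_sub))}
    report["directions"] = directions

    report["exclusions"] = exclusions
    for msg in exclusions:
        logger.info(msg)
    return report
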