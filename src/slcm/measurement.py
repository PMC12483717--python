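"""Per-age-bin measurement-model selection battery.

Mirrors the cross-sectional workflow used to choose between Poisson and NB2
conditional response distributions before any longitudinal model is fit:

1. bin assessments into 3-month age windows and keep at most one record per
   individual per window (uniform random selection among duplicates), after
   dropping records below the minimum-exposure floor;
2. summarize empirical dispersion (mean vs variance of raw counts) per bin;
3. fit intercept-only Poisson and NB2 GLMs per bin with the log exposure as
   an offset (coefficient fixed at one);
4. compare the families on the Pearson statistic vs its degrees of freedom,
   the Kullback-Leibler divergence between the empirical and model-implied
   marginal count distributions, and AIC/BIC.

The GLM fits are delegated to statsmodels (GLM/Poisson and the NB2 discrete
model with jointly estimated dispersion); everything downstream of the fits
(Pearson, KLD, the selection report) is computed here.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator

from .distributions import CountDistributionSpec, logpmf, variance_function

__all__ = [
    "BinnedData",
    "BinFit",
    "SelectionReport",
    "bin_and_dedupe",
    "empirical_dispersion_summary",
    "fit_bin_glm",
    "pearson_statistic",
    "marginal_kld",
    "select_measurement_model",
    "MeasurementModelSelector",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("id", "age_months", "count", "exposure")


@dataclass
class BinnedData:
    """Long-format table binned into assessment windows.

    ``table`` has columns id, bin_t (months since origin, lower bin bound),
    count, exposure; at most one row per (id, bin_t); all exposures at or
    above the floor.
    """

    table: pd.DataFrame
    origin: float = 18.0
    bin_width: float = 3.0
    min_exposure: int = 25
    n_rejected_age: int = 0
    n_rejected_exposure: int = 0

    @property
    def bin_times(self) -> np.ndarray:
        return np.sort(self.table["bin_t"].unique())

    @property
    def W(self) -> int:
        return len(self.bin_times)

    @property
    def n_individuals(self) -> int:
        return self.table["id"].nunique()


def bin_and_dedupe(
    records: pd.DataFrame,
    bin_width: float = 3.0,
    origin: float = 18.0,
    max_age: float = 72.0,
    min_exposure: int = 25,
    rng: np.random.Generator | None = None,
) -> BinnedData:
    """Bin ages into half-open windows and enforce the study-design rules.

    Ages outside [origin, max_age) are rejected with a logged warning.
    Records below the exposure floor are dropped first; then, when an
    individual has several records in one window, one is chosen uniformly
    at random with the supplied generator. Bin codes are the window's lower
    bound minus the origin (0, 3, ..., for 3-month windows).
    """
    if rng is None:
        rng = np.random.default_rng()
    df = records.copy()
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")

    in_range = (df["age_months"] >= origin) & (df["age_months"] < max_age)
    n_bad_age = int((~in_range).sum())
    if n_bad_age:
        logger.warning(
            "rejecting %d record(s) with age outside [%g, %g)", n_bad_age, origin, max_age
        )
    df = df[in_range]

    ok_exp = df["exposure"] >= min_exposure
    n_bad_exp = int((~ok_exp).sum())
    df = df[ok_exp].copy()

    df["bin_t"] = (np.floor((df["age_months"] - origin) / bin_width) * bin_width).astype(float)

    # uniform random selection among within-(id, bin) duplicates
    shuffled = df.sample(frac=1.0, random_state=rng).reset_index(drop=True)
    deduped = shuffled.groupby(["id", "bin_t"], as_index=False, sort=True).first()
    out = deduped[["id", "bin_t", "count", "exposure"]].sort_values(["id", "bin_t"]).reset_index(drop=True)
    return BinnedData(
        table=out,
        origin=origin,
        bin_width=bin_width,
        min_exposure=min_exposure,
        n_rejected_age=n_bad_age,
        n_rejected_exposure=n_bad_exp,
    )


def empirical_dispersion_summary(binned: BinnedData) -> pd.DataFrame:
    """Per-bin sample mean/variance of raw counts with dispersion flags.

    Variance is the unbiased sample variance; bins with a single record get
    NaN variance and flag "undefined".
    """
    rows = []
    for bin_t, grp in binned.table.groupby("bin_t"):
        y = grp["count"].to_numpy(dtype=float)
        n = len(y)
        mean = y.mean()
        var = y.var(ddof=1) if n > 1 else np.nan
        if n == 1:
            flag = "undefined"
        elif var > mean:
            flag = "overdispersed"
        elif var < mean:
            flag = "underdispersed"
        else:
            flag = "equidispersed"
        rows.append({"bin_t": bin_t, "n": n, "mean": mean, "variance": var, "flag": flag})
    return pd.DataFrame(rows)


@dataclass
class BinFit:
    """One per-bin GLM fit and its diagnostics."""

    bin_t: float
    family: str
    intercept: float
    dispersion: float | None
    loglik: float
    n: int
    k: int
    pearson: float
    df: int
    aic: float
    bic: float
    kld: float
    converged: bool = True
    message: str = ""


def _mu_hat(intercept: float, exposure: np.ndarray) -> np.ndarray:
    return exposure * np.exp(intercept)


def fit_bin_glm(records: pd.DataFrame, family: str) -> BinFit:
    """Fit an intercept-only count GLM with log-exposure offset to one bin.

    The linear predictor is log mu = log u + intercept with the offset
    coefficient fixed at one. For "nb2" the dispersion is estimated jointly
    by maximum likelihood. All-zero counts make the NB2 dispersion
    unidentified; a Poisson-degenerate fit is returned with a warning.
    """
    y = records["count"].to_numpy(dtype=float)
    u = records["exposure"].to_numpy(dtype=float)
    n = len(y)
    bin_t = float(records["bin_t"].iloc[0]) if "bin_t" in records else np.nan
    offset = np.log(u)
    X = np.ones((n, 1))

    converged, message = True, ""
    if family == "poisson":
        if not np.any(y > 0):
            # MLE sits at intercept -> -inf; report a continuity-corrected
            # boundary fit rather than crashing
            warnings.warn("all-zero counts: Poisson intercept at the boundary, "
                          "using a +0.5 continuity correction")
            intercept = float(np.log(0.5 / u.sum()))
            mu = u * np.exp(intercept)
            ll = float(np.sum(-mu))
            return BinFit(bin_t=bin_t, family="poisson", intercept=intercept,
                          dispersion=None, loglik=ll, n=n, k=1,
                          pearson=np.nan, df=n - 1,
                          aic=-2 * ll + 2, bic=-2 * ll + np.log(n), kld=np.nan,
                          converged=True, message="boundary fit (all zeros)")
        res = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        intercept = float(res.params[0])
        phi = None
        ll = float(res.llf)
        k = 1
    elif family == "nb2":
        if not np.any(y > 0):
            warnings.warn("all-zero counts: NB2 dispersion unidentified, returning Poisson-degenerate fit")
            pois = fit_bin_glm(records, "poisson")
            return BinFit(
                bin_t=bin_t, family="nb2", intercept=pois.intercept, dispersion=0.0,
                loglik=pois.loglik, n=n, k=2, pearson=pois.pearson, df=n - 2,
                aic=-2 * pois.loglik + 4, bic=-2 * pois.loglik + 2 * np.log(n),
                kld=pois.kld, converged=True, message="dispersion unidentified (all zeros)",
            )
        mod = sm.NegativeBinomial(y, X, offset=offset, loglike_method="nb2")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = mod.fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
        if not converged:
            message = "NB2 MLE did not converge"
        intercept = float(res.params[0])
        phi = float(max(res.params[1], 1e-10))
        ll = float(res.llf)
        k = 2
    else:
        raise ValueError(f"unknown family {family!r}")

    fit = BinFit(
        bin_t=bin_t, family=family, intercept=intercept, dispersion=phi,
        loglik=ll, n=n, k=k, pearson=np.nan, df=n - k,
        aic=-2 * ll + 2 * k, bic=-2 * ll + k * np.log(n), kld=np.nan,
        converged=converged, message=message,
    )
    if converged:
        fit.pearson, fit.df = pearson_statistic(fit, records)
        fit.kld = marginal_kld(fit, records)
    return fit


def _fit_spec(fit: BinFit) -> CountDistributionSpec:
    if fit.family == "poisson" or (fit.dispersion is not None and fit.dispersion <= 0):
        return CountDistributionSpec("poisson")
    return CountDistributionSpec("nb2", fit.dispersion)


def pearson_statistic(fit: BinFit, records: pd.DataFrame):
    """Pearson statistic sum (y - mu)^2 / V(mu) and its df = n - k."""
    y = records["count"].to_numpy(dtype=float)
    u = records["exposure"].to_numpy(dtype=float)
    mu = _mu_hat(fit.intercept, u)
    spec = _fit_spec(fit)
    stat = float(np.sum((y - mu) ** 2 / variance_function(mu, spec)))
    return stat, len(y) - fit.k


def marginal_kld(fit: BinFit, records: pd.DataFrame) -> float:
    """KLD between the empirical count pmf and the model-implied marginal.

    The model-implied marginal q(y) averages the fitted pmf over the bin's
    per-record exposures: q(y) = (1/n) sum_i pmf(y; mu_i, phi). Support runs
    from 0 to the max observed count, extended until q's cumulative mass
    exceeds 1 - 1e-9; the empirical pmf is zero beyond observed values so
    those terms contribute nothing to the sum p * log(p/q).
    """
    y = records["count"].to_numpy(dtype=int)
    u = records["exposure"].to_numpy(dtype=float)
    n = len(y)
    mu = _mu_hat(fit.intercept, u)
    spec = _fit_spec(fit)

    hi = int(y.max())
    q = None
    while True:
        ys = np.arange(hi + 1)
        pmfs = np.exp(logpmf(ys[:, None], mu[None, :], spec))
        q = pmfs.mean(axis=1)
        if q.sum() > 1.0 - 1e-9 or hi > 1_000_000:
            break
        hi = max(2 * hi, hi + 50)

    p_hat = np.bincount(y, minlength=hi + 1) / n
    mask = p_hat > 0
    q_obs = q[mask]
    if np.any(q_obs <= 0):
        warnings.warn("model-implied marginal underflow; flooring at 1e-300")
        q_obs = np.maximum(q_obs, 1e-300)
    return float(np.sum(p_hat[mask] * (np.log(p_hat[mask]) - np.log(q_obs))))


@dataclass
class SelectionReport:
    """Per-bin family comparison plus an overall recommendation."""

    table: pd.DataFrame
    recommendation: str
    n_bins: int
    detail: dict = field(default_factory=dict)


def select_measurement_model(binfits) -> SelectionReport:
    """Compare paired Poisson/NB2 bin fits and recommend a family.

    ``binfits`` is an iterable of (poisson BinFit, nb2 BinFit) pairs (or a
    dict bin_t -> {"poisson": fit, "nb2": fit}). NB2 is recommended when it
    wins a majority of bins on AIC and its Pearson/df ratio is closer to 1
    in a majority of bins.
    """
    if isinstance(binfits, dict):
        pairs = []
        for bin_t, d in sorted(binfits.items()):
            if "poisson" not in d or "nb2" not in d:
                warnings.warn(f"bin {bin_t}: missing a family, skipped")
                continue
            pairs.append((d["poisson"], d["nb2"]))
    else:
        pairs = list(binfits)
    if not pairs:
        raise ValueError("no paired bin fits to compare")

    rows = []
    for pois, nb2 in pairs:
        if pois is None or nb2 is None:
            warnings.warn("incomplete pair skipped")
            continue
        rows.append({
            "bin_t": pois.bin_t,
            "n": pois.n,
            "kld_poisson": pois.kld, "kld_nb2": nb2.kld,
            "pearson_poisson": pois.pearson, "df_poisson": pois.df,
            "pearson_nb2": nb2.pearson, "df_nb2": nb2.df,
            "pearson_ratio_poisson": pois.pearson / pois.df if pois.df > 0 else np.nan,
            "pearson_ratio_nb2": nb2.pearson / nb2.df if nb2.df > 0 else np.nan,
            "aic_poisson": pois.aic, "aic_nb2": nb2.aic,
            "bic_poisson": pois.bic, "bic_nb2": nb2.bic,
            "phi_nb2": nb2.dispersion,
        })
    if not rows:
        raise ValueError("no complete pairs to compare")
    tab = pd.DataFrame(rows)

    aic_wins = int((tab["aic_nb2"] < tab["aic_poisson"]).sum())
    align_wins = int(
        (np.abs(tab["pearson_ratio_nb2"] - 1.0) < np.abs(tab["pearson_ratio_poisson"] - 1.0)).sum()
    )
    n_bins = len(tab)
    rec = "nb2" if (aic_wins > n_bins / 2 and align_wins > n_bins / 2) else "poisson"
    detail = {
        "aic_wins_nb2": aic_wins,
        "pearson_alignment_wins_nb2": align_wins,
        "bic_wins_nb2": int((tab["bic_nb2"] < tab["bic_poisson"]).sum()),
        "kld_wins_nb2": int((tab["kld_nb2"] < tab["kld_poisson"]).sum()),
        "n_bins": n_bins,
    }
    return SelectionReport(table=tab, recommendation=rec, n_bins=n_bins, detail=detail)


class MeasurementModelSelector(BaseEstimator):
    """Per-bin Poisson-vs-NB2 selection battery as an estimator.

    Parameters follow the study design: 3-month windows from 18 to 72
    months and a minimum exposure of 25 sampled units per assessment.

    After ``fit``: ``binned_``, ``dispersion_summary_``, ``bin_fits_``
    (dict bin_t -> {family: BinFit}), ``report_``, ``recommendation_``.
    """

    def __init__(self, bin_width=3.0, origin=18.0, max_age=72.0,
                 min_exposure=25, families=("poisson", "nb2"), random_state=None):
        self.bin_width = bin_width
        self.origin = origin
        self.max_age = max_age
        self.min_exposure = min_exposure
        self.families = families
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None):
        rng = np.random.default_rng(self.random_state)
        if "bin_t" in X.columns and "age_months" not in X.columns:
            X = X.assign(age_months=X["bin_t"] + self.origin)
        self.binned_ = bin_and_dedupe(
            X, bin_width=self.bin_width, origin=self.origin,
            max_age=self.max_age, min_exposure=self.min_exposure, rng=rng,
        )
        self.dispersion_summary_ = empirical_dispersion_summary(self.binned_)
        self.bin_fits_ = {}
        for bin_t, grp in self.binned_.table.groupby("bin_t"):
            self.bin_fits_[float(bin_t)] = {
                fam: fit_bin_glm(grp, fam) for fam in self.families
            }
        if set(self.families) >= {"poisson", "nb2"}:
            self.report_ = select_measurement_model(self.bin_fits_)
            self.recommendation_ = self.report_.recommendation
        else:
            self.report_ = None
            self.recommendation_ = None
        return self
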