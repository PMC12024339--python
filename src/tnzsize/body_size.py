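"""Stage classification, record filters, and gamma identity-link mixed models.

Body length and mass are positive and right-skewed, so they are modelled as
gamma responses whose *mean* is linear in the predictors (identity link):

    y_i ~ Gamma(shape, mean = a + b*x_i + sex_i + stage_i + u_{g(i)}),
    u_g ~ Normal(0, sigma^2)

with a single random intercept per site (spatial analyses) or year (temporal
analyses).  Estimation is by the Laplace approximation to the marginal
likelihood; by default the variance parameters maximise the criterion with
the fixed effects integrated out as well (REML-flavoured, as in glmmTMB's
REML option), which matters when the random-effect dimension is small.
Fixed effects are the joint posterior mode; their covariance comes from the
corresponding block of the inverse joint information.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln
from sklearn.base import BaseEstimator, RegressorMixin

from .config import STAGE_BANDS, STAGES
from .errors import DataError, FitError

logger = logging.getLogger(__name__)

__all__ = [
    "classify_stage",
    "filter_records",
    "standardize",
    "cyear",
    "GammaGLMM",
    "ModelSpec",
    "GLMMFit",
    "fit_gamma_glmm",
    "trend_and_effect_suite",
]

#: Stages retained for modelling (juvenile and old are dropped).
MODEL_STAGES = ("sub-adult", "adult I", "adult II")
STAGE_REFERENCE = "sub-adult"
SEX_REFERENCE = "female"


def classify_stage(body_mass, ambiguous_band: str = "sub-adult"):
    """Stage class from body mass (g).

    Bands: [0, 16) juvenile, [16, 23] sub-adult, (23, 29] adult I,
    (29, 37] adult II, (37, inf) old.  The printed adult-I band starts at
    16 g, overlapping sub-adult; ``ambiguous_band`` decides which class
    claims (16, 23] (default sub-adult, treating the overlap as a slip).
    """
    scalar = np.isscalar(body_mass)
    m = np.asarray(body_mass, dtype=float).reshape(-1)
    if np.any(m <= 0):
        raise ValueError("body mass must be > 0")
    if ambiguous_band not in ("sub-adult", "adult I"):
        raise ValueError("ambiguous_band must be 'sub-adult' or 'adult I'")
    out = np.empty(m.shape, dtype=object)
    out[m < 16] = "juvenile"
    mid = (m >= 16) & (m <= 23)
    out[mid] = ambiguous_band
    out[(m > 23) & (m <= 29)] = "adult I"
    out[(m > 29) & (m <= 37)] = "adult II"
    out[m > 37] = "old"
    return out[0] if scalar else out


def filter_records(records: pd.DataFrame) -> pd.DataFrame:
    """Drop juvenile, old, and pregnant records; log per-reason counts.

    Juveniles and old individuals are absent in some site-years and pregnancy
    inflates body mass, so all three are excluded before modelling.
    """
    juvenile = records["stage"] == "juvenile"
    old = records["stage"] == "old"
    pregnant = records.get("pregnant", pd.Series(False, index=records.index)).astype(bool)
    pregnant_only = pregnant & ~(juvenile | old)
    keep = ~(juvenile | old | pregnant)
    logger.info(
        "filter_records: dropped %d juvenile, %d old, %d pregnant; retained %d of %d",
        int(juvenile.sum()), int(old.sum()), int(pregnant_only.sum()),
        int(keep.sum()), len(records),
    )
    out = records.loc[keep].copy()
    if out.empty:
        raise DataError("all records excluded by the stage/pregnancy filters")
    out.attrs["filter_counts"] = {
        "juvenile": int(juvenile.sum()),
        "old": int(old.sum()),
        "pregnant": int(pregnant_only.sum()),
        "retained": int(keep.sum()),
    }
    return out


def standardize(values) -> np.ndarray:
    """Centre to mean 0 and scale to sample SD 1 (n-1 denominator)."""
    x = np.asarray(values, dtype=float).reshape(-1)
    if len(np.unique(x)) < 2:
        raise DataError("cannot standardize a constant vector")
    return (x - x.mean()) / x.std(ddof=1)


def cyear(years, origin: int | None = None) -> np.ndarray:
    """Years elapsed since the study start (first year becomes 0)."""
    y = np.asarray(years, dtype=int)
    if origin is None:
        origin = int(y.min())
    return y - origin


# --------------------------------------------------------------------------
# Gamma identity-link GLMM
# --------------------------------------------------------------------------

def _gamma_loglik(y: np.ndarray, mu: np.ndarray, nu: float) -> float:
    return float(
        np.sum(nu * np.log(nu) - gammaln(nu) + (nu - 1) * np.log(y)
               - nu * np.log(mu) - nu * y / mu)
    )


class GammaGLMM(BaseEstimator, RegressorMixin):
    """Gamma GLMM with identity link and one scalar random intercept.

    Parameters
    ----------
    method : {"reml", "ml"}
        "reml" (default) integrates the fixed effects out of the Laplace
        criterion when estimating the shape and random-intercept SD; "ml"
        maximises the ordinary Laplace marginal likelihood.
    force_zero_variance : bool
        Profile the random-intercept variance at exactly zero; the fit then
        reduces to a plain gamma identity-link GLM.
    max_inner_iter, inner_tol : joint-mode Newton controls.
    maxiter : outer optimiser iteration cap.

    Attributes
    ----------
    params_, se_, wald_p_ : natural-scale coefficients (intercept first),
        standard errors and two-sided Wald p-values.
    params_internal_, se_internal_ : the same on the internally scaled axes
        (response divided by its mean, predictors standardised).
    random_intercept_sd_, shape_, loglik_, converged_, n_obs_, n_groups_.
    inner_ll_trace_ : accepted joint penalised log-likelihood values of the
        final inner Newton solve (non-decreasing by construction).
    """

    def __init__(self, method: str = "reml", force_zero_variance: bool = False,
                 max_inner_iter: int = 200, inner_tol: float = 1e-10,
                 maxiter: int = 400):
        self.method = method
        self.force_zero_variance = force_zero_variance
        self.max_inner_iter = max_inner_iter
        self.inner_tol = inner_tol
        self.maxiter = maxiter

    # -- internals ---------------------------------------------------------
    def _joint_mode(self, X, y, gidx, G, nu, sigma, beta0, b0, trace=False):
        """Fisher-scoring Newton for the joint (beta, b) penalised mode.

        Steps are halved until they keep all conditional means positive and
        do not decrease the penalised log-likelihood (monotone line search).
        """
        n, p = X.shape
        use_re = sigma is not None
        beta = beta0.copy()
        b = b0.copy() if use_re else np.zeros(G)
        mu = X @ beta + (b[gidx] if use_re else 0.0)
        if np.any(mu <= 0):
            beta = np.r_[np.mean(y), np.zeros(p - 1)]
            b = np.zeros(G)
            mu = X @ beta + (b[gidx] if use_re else 0.0)

        def pen_ll(mu_, b_):
            ll = _gamma_loglik(y, mu_, nu)
            if use_re:
                ll -= 0.5 * np.sum(b_ ** 2) / sigma ** 2
            return ll

        ll = pen_ll(mu, b)
        trace_vals = [ll]
        converged = False
        for _ in range(self.max_inner_iter):
            s = nu * (y - mu) / mu ** 2
            w = nu / mu ** 2                      # Fisher weights, always > 0
            gb = X.T @ s
            XW = X * w[:, None]
            A = X.T @ XW
            if use_re:
                gg = np.bincount(gidx, weights=s, minlength=G) - b / sigma ** 2
                Bmat = np.empty((p, G))
                for j in range(p):
                    Bmat[j] = np.bincount(gidx, weights=XW[:, j], minlength=G)
                D = np.bincount(gidx, weights=w, minlength=G) + 1.0 / sigma ** 2
                H = np.block([[A, Bmat], [Bmat.T, np.diag(D)]])
                g = np.r_[gb, gg]
            else:
                H, g = A, gb
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
            gnorm = np.max(np.abs(g))
            if gnorm < self.inner_tol * max(1.0, nu):
                converged = True
                break
            t = 1.0
            accepted = False
            for _ in range(50):
                nb = beta + t * step[:p]
                nbb = b + t * step[p:] if use_re else b
                mu_n = X @ nb + (nbb[gidx] if use_re else 0.0)
                if np.all(mu_n > 0):
                    ll_n = pen_ll(mu_n, nbb)
                    if ll_n >= ll - 1e-12 * max(1.0, abs(ll)):
                        accepted = True
                        break
                t /= 2.0
            if not accepted:
                break
            beta, b, mu, ll = nb, nbb, mu_n, ll_n
            trace_vals.append(ll)
        if trace:
            self.inner_ll_trace_ = np.asarray(trace_vals)
        return beta, b, mu, converged

    @staticmethod
    def _joint_hessian(X, y, gidx, G, nu, sigma, mu):
        """Negative observed second derivative of the joint penalised log-lik.

        Falls back to the (always positive) expected information when an
        observation's observed weight is non-positive.
        """
        n, p = X.shape
        w = nu * (2 * y - mu) / mu ** 3
        bad = w <= 0
        if np.any(bad):
            w = np.where(bad, nu / mu ** 2, w)
        XW = X * w[:, None]
        A = X.T @ XW
        if sigma is None:
            return A
        Bmat = np.empty((p, G))
        for j in range(p):
            Bmat[j] = np.bincount(gidx, weights=XW[:, j], minlength=G)
        D = np.bincount(gidx, weights=w, minlength=G) + 1.0 / sigma ** 2
        return np.block([[A, Bmat], [Bmat.T, np.diag(D)]])

    def _glm_start(self, X, y):
        import statsmodels.api as sm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                glm = sm.GLM(y, X, family=sm.families.Gamma(sm.families.links.Identity())).fit()
                if np.all(X @ glm.params > 0):
                    return np.asarray(glm.params), float(1.0 / glm.scale), np.asarray(glm.resid_response)
            except Exception:  # pragma: no cover - statsmodels start failure
                pass
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        if np.any(X @ beta <= 0):
            beta = np.r_[np.mean(y), np.zeros(X.shape[1] - 1)]
        resid = y - X @ beta
        nu0 = max(np.mean(X @ beta) ** 2 / max(np.var(resid), 1e-12), 1.0)
        return beta, float(nu0), resid

    # -- sklearn API -------------------------------------------------------
    def fit(self, X, y, groups=None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).reshape(-1)
        n = len(y)
        if X.shape[0] != n:
            raise ValueError("X and y have incompatible shapes")
        if np.any(y <= 0):
            raise DataError("gamma responses must be strictly positive")

        if self.force_zero_variance:
            gidx = np.zeros(n, dtype=int)
            G = 1
        else:
            if groups is None:
                raise ValueError("groups is required unless force_zero_variance=True")
            codes, uniques = pd.factorize(pd.Series(groups), sort=True)
            gidx, G = codes.astype(int), len(uniques)
            self.group_labels_ = list(uniques)
            if G < 2:
                raise FitError(
                    "need >= 2 groups for a random intercept; "
                    "use force_zero_variance=True for a plain GLM"
                )

        # internal scaling: response by its mean, non-constant columns to z-scores
        ybar = y.mean()
        yy = y / ybar
        Xd = np.column_stack([np.ones(n), X])
        means = Xd.mean(axis=0)
        sds = Xd.std(axis=0)
        scale_col = sds > 0
        scale_col[0] = False
        Xs = Xd.copy()
        Xs[:, scale_col] = (Xd[:, scale_col] - means[scale_col]) / sds[scale_col]
        p = Xs.shape[1]

        beta0, nu0, resid0 = self._glm_start(Xs, yy)
        state = {"beta": beta0, "b": np.zeros(G)}
        outer_iters = {"count": 0}

        if self.force_zero_variance:
            def nll(theta):
                nu = float(np.exp(theta[0]))
                if not 1e-3 < nu < 1e8:
                    return 1e10
                beta, b, mu, _ = self._joint_mode(Xs, yy, gidx, G, nu, None,
                                                  state["beta"], state["b"])
                if np.any(mu <= 0):
                    return 1e10
                state["beta"] = beta
                return -_gamma_loglik(yy, mu, nu)

            res = optimize.minimize_scalar(
                lambda t: nll([t]), bounds=(np.log(1e-2), np.log(1e7)),
                method="bounded", options={"xatol": 1e-8},
            )
            nu_hat, sigma_hat = float(np.exp(res.x)), 0.0
            beta, b, mu, inner_ok = self._joint_mode(
                Xs, yy, gidx, G, nu_hat, None, state["beta"], state["b"], trace=True
            )
            H = self._joint_hessian(Xs, yy, gidx, G, nu_hat, None, mu)
            cov_b = np.linalg.inv(H)
            loglik_scaled = _gamma_loglik(yy, mu, nu_hat)
            outer_ok = True
        else:
            if self.method not in ("reml", "ml"):
                raise ValueError("method must be 'reml' or 'ml'")
            reml = self.method == "reml"

            def nll(theta):
                nu = float(np.exp(theta[0]))
                sigma = float(np.exp(theta[1]))
                if not (1e-3 < nu < 1e8) or not (1e-8 < sigma < 1e3):
                    return 1e10
                beta, b, mu, _ = self._joint_mode(Xs, yy, gidx, G, nu, sigma,
                                                  state["beta"], state["b"])
                if np.any(mu <= 0):
                    return 1e10
                state["beta"], state["b"] = beta, b
                ll = (_gamma_loglik(yy, mu, nu)
                      - 0.5 * np.sum(b ** 2) / sigma ** 2
                      - G * 0.5 * np.log(2 * np.pi * sigma ** 2))
                H = self._joint_hessian(Xs, yy, gidx, G, nu, sigma, mu)
                Hblock = H if reml else H[p:, p:]
                sign, logdet = np.linalg.slogdet(Hblock)
                if sign <= 0:
                    return 1e10
                k = Hblock.shape[0]
                return -(ll + 0.5 * k * np.log(2 * np.pi) - 0.5 * logdet)

            site_resid = (np.bincount(gidx, weights=resid0, minlength=G)
                          / np.maximum(np.bincount(gidx, minlength=G), 1))
            s0 = float(np.clip(np.std(site_resid), 1e-3, 1.0))
            th0 = np.array([np.log(nu0), np.log(s0)])
            res = optimize.minimize(
                nll, th0, method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-9, "maxiter": self.maxiter},
            )
            nu_hat = float(np.exp(res.x[0]))
            sigma_hat = float(np.exp(res.x[1]))
            beta, b, mu, inner_ok = self._joint_mode(
                Xs, yy, gidx, G, nu_hat, sigma_hat, state["beta"], state["b"], trace=True
            )
            H = self._joint_hessian(Xs, yy, gidx, G, nu_hat, sigma_hat, mu)
            cov = np.linalg.inv(H)
            cov_b = cov[:p, :p]
            # marginal (ML) Laplace log-likelihood at the estimates
            Hbb = H[p:, p:]
            sign, logdet = np.linalg.slogdet(Hbb)
            loglik_scaled = (
                _gamma_loglik(yy, mu, nu_hat)
                - 0.5 * np.sum(b ** 2) / sigma_hat ** 2
                - G * 0.5 * np.log(2 * np.pi * sigma_hat ** 2)
                + 0.5 * G * np.log(2 * np.pi) - 0.5 * logdet
            )
            outer_ok = bool(res.success)

        # back-transform to the natural scale
        a = np.eye(p)
        a[0, scale_col] = -means[scale_col] / sds[scale_col]
        scale_vec = np.ones(p)
        scale_vec[scale_col] = 1.0 / sds[scale_col]
        T = a * scale_vec[None, :] * ybar          # params_nat = T' mapping
        # mu_nat = ybar * (beta0 + sum beta_j (x-m)/s) = params_nat . [1, x]
        params_nat = np.empty(p)
        params_nat[0] = ybar * (beta[0] - np.sum(beta[scale_col] * means[scale_col] / sds[scale_col]))
        params_nat[1:] = ybar * beta[1:] * scale_vec[1:]
        J = np.zeros((p, p))                        # d params_nat / d beta
        J[0, 0] = ybar
        J[0, scale_col] = -ybar * means[scale_col] / sds[scale_col]
        for j in range(1, p):
            J[j, j] = ybar * scale_vec[j]
        cov_nat = J @ cov_b @ J.T

        self.params_internal_ = beta
        self.se_internal_ = np.sqrt(np.maximum(np.diag(cov_b), 0.0))
        self.params_ = params_nat
        self.se_ = np.sqrt(np.maximum(np.diag(cov_nat), 0.0))
        # between-within denominator df (as in nlme): coefficients of columns
        # that are constant within every group are judged against t with
        # G - (number of group-level columns) df; the rest against n - p
        if self.force_zero_variance:
            dof = np.full(p, max(n - p, 1))
        else:
            group_constant = np.array([
                all(
                    np.ptp(Xd[gidx == g, j]) == 0
                    for g in range(G)
                )
                for j in range(p)
            ])
            q = int(group_constant.sum())
            dof = np.where(group_constant, max(G - q, 1), max(n - p, 1))
        self.wald_df_ = dof
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(self.se_ > 0, self.params_ / self.se_, np.inf)
        self.wald_p_ = 2.0 * stats.t.sf(np.abs(z), dof)
        self.intercept_ = float(params_nat[0])
        self.coef_ = params_nat[1:]
        self.random_intercept_sd_ = sigma_hat * ybar
        self.shape_ = nu_hat
        self.loglik_ = loglik_scaled - n * np.log(ybar)
        self.converged_ = bool(outer_ok and inner_ok)
        self.n_obs_ = n
        self.n_groups_ = G if not self.force_zero_variance else 0
        self.ranef_ = b * ybar
        self._scale_info = (ybar, means, sds, scale_col)
        self.n_features_in_ = X.shape[1]
        if not self.converged_:
            logger.warning("GammaGLMM fit flagged non-converged")
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return self.intercept_ + X @ self.coef_

    def conditional_residuals(self, X, y, groups) -> np.ndarray:
        """Observation-level residuals around the group-conditional mean."""
        codes = pd.Categorical(groups, categories=self.group_labels_).codes
        return np.asarray(y, dtype=float) - (self.predict(X) + self.ranef_[codes])


# --------------------------------------------------------------------------
# Model-battery plumbing
# --------------------------------------------------------------------------

RESPONSE_COLUMNS = {"length": "body_length_mm", "mass": "body_mass_g"}


@dataclass
class ModelSpec:
    """One gamma-GLMM specification: response, continuous predictor, grouping."""

    response: str                       # "length" or "mass"
    predictor: str | None               # column name in the modelling frame
    random_group: str = "site"          # "site" or "year"
    standardize_predictor: bool = True

    def __post_init__(self) -> None:
        if self.response not in RESPONSE_COLUMNS:
            raise ValueError("response must be 'length' or 'mass'")
        if self.random_group not in ("site", "year"):
            raise ValueError("random_group must be 'site' or 'year'")
        if self.predictor is not None and self.predictor == self.random_group:
            raise ValueError("predictor cannot equal the random grouping column")


@dataclass
class GLMMFit:
    """Named coefficient summary of one fitted gamma GLMM."""

    spec: ModelSpec
    coefficients: dict                   # name -> {estimate, se, p} (natural scale)
    slope_natural: float | None
    slope_se_natural: float | None
    slope_standardized: float | None
    slope_se_standardized: float | None
    slope_p: float | None
    random_intercept_sd: float
    gamma_shape_estimate: float
    log_likelihood: float
    n_obs: int
    n_groups: int
    converged: bool
    model: GammaGLMM = field(repr=False, default=None)
    n_parameters: int = 0


def build_design(df: pd.DataFrame, spec: ModelSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Design matrix (no intercept column), response, groups, feature names.

    Sex enters as a male dummy (reference female); stage as dummies against
    the sub-adult reference, using only stages present after filtering.
    """
    ycol = RESPONSE_COLUMNS[spec.response]
    for col in (ycol, "sex", "stage", spec.random_group):
        if col not in df.columns:
            raise DataError(f"modelling frame lacks column '{col}'")
    y = df[ycol].to_numpy(dtype=float)
    cols, names = [], []
    if spec.predictor is not None:
        x = df[spec.predictor].to_numpy(dtype=float)
        if spec.standardize_predictor:
            x = standardize(x)
        cols.append(x)
        names.append(spec.predictor)
    cols.append((df["sex"] == "male").to_numpy(dtype=float))
    names.append("sex[male]")
    stages_present = [s for s in STAGES if s in set(df["stage"]) and s != STAGE_REFERENCE]
    for s in stages_present:
        cols.append((df["stage"] == s).to_numpy(dtype=float))
        names.append(f"stage[{s}]")
    X = np.column_stack(cols)
    groups = df[spec.random_group].to_numpy()
    return X, y, groups, names


def fit_gamma_glmm(df: pd.DataFrame, spec: ModelSpec, **glmm_kwargs) -> GLMMFit:
    """Fit one gamma identity-link GLMM described by ``spec`` on ``df``.

    ``df`` must already be filtered and carry the predictor column (e.g. a
    joined AnnMinTemp or TNZ breadth).  Slopes are reported on both the
    natural per-unit scale and the standardised-predictor scale.
    """
    X, y, groups, names = build_design(df, spec)
    est = GammaGLMM(**glmm_kwargs).fit(X, y, groups=groups)
    all_names = ["intercept"] + names
    coefficients = {
        nm: {"estimate": float(est.params_[i]), "se": float(est.se_[i]),
             "p": float(est.wald_p_[i])}
        for i, nm in enumerate(all_names)
    }
    slope_nat = slope_se_nat = slope_std = slope_se_std = slope_p = None
    if spec.predictor is not None:
        raw = df[spec.predictor].to_numpy(dtype=float)
        sd = raw.std(ddof=1)
        i = all_names.index(spec.predictor)
        est_i, se_i = est.params_[i], est.se_[i]
        if spec.standardize_predictor:
            slope_std, slope_se_std = float(est_i), float(se_i)
            slope_nat, slope_se_nat = float(est_i / sd), float(se_i / sd)
        else:
            slope_nat, slope_se_nat = float(est_i), float(se_i)
            slope_std, slope_se_std = float(est_i * sd), float(se_i * sd)
        slope_p = float(est.wald_p_[i])
    n_params = len(all_names) + 2      # + gamma shape + random-intercept var
    return GLMMFit(
        spec=spec,
        coefficients=coefficients,
        slope_natural=slope_nat,
        slope_se_natural=slope_se_nat,
        slope_standardized=slope_std,
        slope_se_standardized=slope_se_std,
        slope_p=slope_p,
        random_intercept_sd=est.random_intercept_sd_,
        gamma_shape_estimate=est.shape_,
        log_likelihood=est.loglik_,
        n_obs=est.n_obs_,
        n_groups=est.n_groups_,
        converged=est.converged_,
        model=est,
        n_parameters=n_params,
    )


def trend_and_effect_suite(
    records: pd.DataFrame,
    sites: pd.DataFrame,
    site_climate: pd.DataFrame,
    tnz_estimates: pd.DataFrame | None = None,
    spatial_years: Sequence[int] | None = None,
) -> pd.DataFrame:
    """The full battery of body-size models, as a tidy coefficient table.

    Temporal battery (random intercept = year): cYear and site-year
    AnnMinTemp as predictors.  Spatial battery (random intercept = site,
    records restricted to ``spatial_years``): latitude, longitude, altitude,
    spatial AnnMinTemp, and TNZ breadth when estimates are supplied.
    Individual failed fits are logged and skipped.
    """
    records = filter_records(records)
    rows = []

    def try_fit(df, spec, dataset):
        try:
            fit = fit_gamma_glmm(df, spec)
        except (DataError, FitError, ValueError) as exc:
            logger.warning("%s %s ~ %s failed: %s", dataset, spec.response,
                           spec.predictor, exc)
            return
        rows.append(
            {
                "dataset": dataset,
                "response": spec.response,
                "predictor": spec.predictor,
                "slope": fit.slope_natural,
                "se": fit.slope_se_natural,
                "p": fit.slope_p,
                "slope_std": fit.slope_standardized,
                "se_std": fit.slope_se_standardized,
                "random_intercept_sd": fit.random_intercept_sd,
                "n": fit.n_obs,
                "n_groups": fit.n_groups,
                "converged": fit.converged,
            }
        )

    # temporal: all records, year random effect
    temporal = records.merge(site_climate, on=["site", "year"], how="inner")
    if not temporal.empty and temporal["year"].nunique() >= 2:
        temporal = temporal.assign(cYear=cyear(temporal["year"]))
        for response in ("length", "mass"):
            for predictor in ("cYear", "ann_min_temp"):
                try_fit(temporal, ModelSpec(response, predictor, "year"), "temporal")
    else:
        logger.warning("temporal battery skipped: fewer than 2 years")

    # spatial: restrict to the spatial years, site random effect
    if spatial_years is None:
        spatial_years = sorted(records["year"].unique())[-2:]
    spatial = records[records["year"].isin(list(spatial_years))]
    spat_climate = (
        site_climate[site_climate["year"].isin(list(spatial_years))]
        .groupby("site", as_index=False)["ann_min_temp"].mean()
    )
    spatial = spatial.merge(sites[["site", "lat", "lon", "alt_km"]], on="site")
    spatial = spatial.merge(spat_climate, on="site", how="inner")
    if tnz_estimates is not None and not tnz_estimates.empty:
        spatial = spatial.merge(
            tnz_estimates[["site", "tnz_b_C"]].rename(columns={"tnz_b_C": "tnz_b"}),
            on="site", how="left",
        )
    if spatial.empty:
        raise DataError("spatial battery: join of records, sites and climate is empty")
    predictors = ["lat", "lon", "alt_km", "ann_min_temp"]
    if "tnz_b" in spatial.columns and spatial["tnz_b"].notna().all():
        predictors.append("tnz_b")
    for response in ("length", "mass"):
        for predictor in predictors:
            try_fit(spatial, ModelSpec(response, predictor, "site"), "spatial")

    return pd.DataFrame(rows)
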