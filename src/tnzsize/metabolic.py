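"""From oxygen-consumption traces to thermoneutral-zone estimates.

The chain is: minimal 5-minute window mean of each trace (temperature-specific
RMR), division by body mass (mass-specific RMR, mL O2 g-1 h-1), a polynomial
fit of mass-specific RMR against chamber temperature by gradient descent, and
derivative-threshold detection of the lower and upper limit temperatures
(LLT/ULT) around the curve minimum.  TNZ breadth is ULT - LLT.

The polynomial is fit on a mean-centred, unit-variance temperature axis with
column-normalised monomials, using heavy-ball gradient descent whose step and
momentum come from the extreme eigenvalues of the normal matrix; coefficients
are mapped back to the degC scale by polynomial composition, so the result
agrees with the closed-form least-squares solution to numerical precision.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import Polynomial
from sklearn.base import BaseEstimator

from .errors import FitError, NoTNZError, TraceTooShortError

logger = logging.getLogger(__name__)

__all__ = [
    "MetabolicCurve",
    "TNZEstimate",
    "PolynomialRMRCurve",
    "min_window_rmr",
    "to_mass_specific",
    "fit_rmr_curve",
    "derive_tnz",
    "estimate_population_tnz",
]


def min_window_rmr(
    readings: np.ndarray | pd.Series, window_minutes: int = 5, trace_id: str = "?"
) -> float:
    """Minimum over all contiguous windows of ``window_minutes`` of the window mean.

    The operative window length is exactly ``window_minutes``: the minimum
    over any longer window can never be smaller.
    """
    r = np.asarray(readings, dtype=float)
    if r.ndim != 1:
        raise ValueError("readings must be one-dimensional")
    if len(r) < window_minutes:
        raise TraceTooShortError(
            f"trace {trace_id}: {len(r)} readings < window of {window_minutes} minutes"
        )
    kernel = np.ones(window_minutes) / window_minutes
    means = np.convolve(r, kernel, mode="valid")
    return float(means.min())


def to_mass_specific(rmr: float, body_mass: float) -> float:
    """Whole-animal mL O2 h-1 divided by body mass in g."""
    if body_mass <= 0:
        raise ValueError(f"body_mass must be > 0, got {body_mass}")
    return rmr / body_mass


@dataclass
class MetabolicCurve:
    """Fitted RMR-temperature polynomial (coefficients ascending, degC scale)."""

    coefficients: np.ndarray
    fit_domain: tuple[float, float]
    sse: float
    converged: bool
    n_iterations: int

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def polynomial(self) -> Polynomial:
        return Polynomial(self.coefficients)

    def __call__(self, temp):
        return self.polynomial()(np.asarray(temp, dtype=float))


class PolynomialRMRCurve(BaseEstimator):
    """Least-squares polynomial of mass-specific RMR vs temperature, by gradient descent.

    Parameters
    ----------
    degree : polynomial degree (2-6 are sensible for Scholander-type U-curves;
        a quadratic cannot represent a flat-bottomed zone with asymmetric limbs,
        hence the quartic default).
    learning_rate : step size on the internally normalised problem.  ``None``
        selects the optimal heavy-ball step from the extreme eigenvalues of the
        normal matrix; a float requests plain gradient descent with that step
        and no momentum.
    max_iter, tol : iteration cap and infinity-norm gradient threshold;
        ``converged_`` records whether ``tol`` was reached before the cap.

    Attributes (after ``fit``)
    --------------------------
    coef_ : ascending polynomial coefficients on the degC scale.
    fit_domain_, sse_, converged_, n_iter_.
    """

    def __init__(self, degree: int = 4, learning_rate: float | None = None,
                 max_iter: int = 200_000, tol: float = 1e-12):
        self.degree = degree
        self.learning_rate = learning_rate
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.shape != y.shape:
            raise ValueError("temperature and RMR arrays must have the same length")
        if self.degree < 2:
            raise ValueError("degree must be >= 2")
        n_distinct = len(np.unique(t))
        if n_distinct <= self.degree:
            raise FitError(
                f"need more than degree={self.degree} distinct temperatures, got {n_distinct}"
            )
        if n_distinct < 3:
            raise FitError("points must span at least 3 distinct temperatures")

        mean, sd = t.mean(), t.std()
        z = (t - mean) / sd
        V = np.vander(z, self.degree + 1, increasing=True)
        col_norms = np.linalg.norm(V, axis=0) / np.sqrt(len(t))
        Vn = V / col_norms
        n = len(t)
        A = Vn.T @ Vn / n
        c = Vn.T @ y / n

        eigs = np.linalg.eigvalsh(A)
        lam_min, lam_max = float(eigs[0]), float(eigs[-1])
        if lam_min <= 1e-13 * lam_max:
            raise FitError("design is numerically rank deficient; add more distinct temperatures")

        if self.learning_rate is None:
            sqmax, sqmin = np.sqrt(lam_max), np.sqrt(lam_min)
            alpha = 4.0 / (sqmax + sqmin) ** 2
            beta = ((sqmax - sqmin) / (sqmax + sqmin)) ** 2
        else:
            alpha, beta = float(self.learning_rate), 0.0

        w = np.zeros(self.degree + 1)
        w_prev = w.copy()
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            grad = A @ w - c
            if np.max(np.abs(grad)) < self.tol:
                converged = True
                break
            w_new = w - alpha * grad + beta * (w - w_prev)
            w_prev, w = w, w_new
        if not converged:
            warnings.warn(
                "gradient descent did not reach the gradient tolerance; "
                "result returned with converged_=False",
                RuntimeWarning,
                stacklevel=2,
            )

        coef_z = w / col_norms
        poly_c = Polynomial(coef_z)(Polynomial([-mean / sd, 1.0 / sd]))
        coef = np.zeros(self.degree + 1)
        coef[: len(poly_c.coef)] = poly_c.coef

        self.coef_ = coef
        self.z_coef_ = coef_z
        self.fit_domain_ = (float(t.min()), float(t.max()))
        fitted = V @ coef_z
        self.sse_ = float(np.sum((y - fitted) ** 2))
        self.converged_ = converged
        self.n_iter_ = it
        return self

    def predict(self, X):
        return Polynomial(self.coef_)(np.asarray(X, dtype=float).reshape(-1))

    def as_curve(self) -> MetabolicCurve:
        return MetabolicCurve(
            coefficients=self.coef_,
            fit_domain=self.fit_domain_,
            sse=self.sse_,
            converged=self.converged_,
            n_iterations=self.n_iter_,
        )


def fit_rmr_curve(
    temps, rmr, degree: int = 4, learning_rate: float | None = None,
    max_iter: int = 200_000, tol: float = 1e-12,
) -> MetabolicCurve:
    """Functional wrapper around :class:`PolynomialRMRCurve`."""
    est = PolynomialRMRCurve(degree=degree, learning_rate=learning_rate,
                             max_iter=max_iter, tol=tol)
    return est.fit(temps, rmr).as_curve()


@dataclass
class TNZEstimate:
    """TNZ limits derived from a fitted curve; ``tnz_b = ult - llt`` exactly."""

    llt: float
    ult: float
    tnz_b: float
    bmr: float
    t_min: float
    boundary_clipped: bool = False


def _real_roots_in(poly: Polynomial, lo: float, hi: float) -> np.ndarray:
    roots = poly.roots()
    real = roots[np.abs(roots.imag) < 1e-8].real
    return real[(real >= lo) & (real <= hi)]


def derive_tnz(
    curve: MetabolicCurve, slope_threshold: float = 0.03, grid_step: float = 0.01
) -> TNZEstimate:
    """LLT/ULT from derivative-threshold crossings around the curve minimum.

    ``t_min`` is the interior argmin of the fitted polynomial; the LLT is the
    largest temperature below ``t_min`` where dRMR/dT = -threshold and the ULT
    the smallest above it where dRMR/dT = +threshold.  Crossings are located
    from polynomial roots of the derivative (well below 1e-4 degC error),
    seeded by a grid scan.  When a limb never reaches the threshold inside the
    fit domain, the estimate is clipped to the domain edge and flagged.
    """
    delta = float(slope_threshold)
    if delta <= 0:
        raise ValueError("slope_threshold must be > 0")
    lo, hi = curve.fit_domain
    p = curve.polynomial()
    d = p.deriv()

    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    values = p(grid)
    idx = int(np.argmin(values))
    if idx == 0 or idx == len(grid) - 1:
        raise NoTNZError(
            "fitted curve has no interior minimum in the fit domain (monotone RMR)"
        )
    # refine the argmin via the derivative's roots near the grid minimum
    t_min = float(grid[idx])
    croots = _real_roots_in(d, lo, hi)
    if len(croots):
        mins = croots[p.deriv(2)(croots) > 0]
        if len(mins):
            t_min = float(mins[np.argmin(np.abs(mins - t_min))])

    clipped = False
    left = _real_roots_in(d + delta, lo, t_min - 1e-12)
    if len(left):
        llt = float(left.max())
    else:
        llt, clipped = lo, True
    right = _real_roots_in(d - delta, t_min + 1e-12, hi)
    if len(right):
        ult = float(right.min())
    else:
        ult, clipped = hi, True

    return TNZEstimate(
        llt=llt,
        ult=ult,
        tnz_b=ult - llt,
        bmr=float(p(t_min)),
        t_min=t_min,
        boundary_clipped=clipped,
    )


def estimate_population_tnz(
    traces: pd.DataFrame,
    degree: int = 4,
    slope_threshold: float = 0.03,
    window_minutes: int = 5,
    grid_step: float = 0.01,
) -> pd.DataFrame:
    """Per-site TNZ estimates from pooled per-animal RMR points.

    For every animal and chamber temperature the trace is reduced to its
    minimal ``window_minutes`` mean and divided by body mass; all points of a
    site are pooled into one curve fit (one LLT/ULT per population).  Sites
    with too few distinct temperatures are skipped with a logged reason.

    ``traces`` columns: animal_id, site, mass_g, chamber_temp_C, minute,
    o2_ml_per_h (the layout written by the synthetic generator).
    """
    required = {"animal_id", "site", "mass_g", "chamber_temp_C", "o2_ml_per_h"}
    missing = required - set(traces.columns)
    if missing:
        raise ValueError(f"traces table lacks columns: {sorted(missing)}")

    out = []
    for site, site_df in traces.groupby("site", sort=True):
        pts_t, pts_r = [], []
        animals = site_df["animal_id"].unique()
        if len(animals) < 2:
            logger.warning("site %s: only %d animal(s); estimate will be imprecise",
                           site, len(animals))
        for (animal, temp), grp in site_df.groupby(["animal_id", "chamber_temp_C"], sort=True):
            grp = grp.sort_values("minute") if "minute" in grp else grp
            rmr = min_window_rmr(grp["o2_ml_per_h"].to_numpy(), window_minutes,
                                 trace_id=f"{animal}@{temp}")
            mass = float(grp["mass_g"].iloc[0])
            pts_t.append(float(temp))
            pts_r.append(to_mass_specific(rmr, mass))
        try:
            curve = fit_rmr_curve(pts_t, pts_r, degree=degree)
            est = derive_tnz(curve, slope_threshold=slope_threshold, grid_step=grid_step)
        except (FitError, NoTNZError) as exc:
            logger.warning("site %s skipped: %s", site, exc)
            continue
        out.append(
            {
                "site": site,
                "llt_C": est.llt,
                "ult_C": est.ult,
                "tnz_b_C": est.tnz_b,
                "bmr": est.bmr,
                "t_min_C": est.t_min,
                "converged": curve.converged,
                "boundary_clipped": est.boundary_clipped,
                "n_animals": len(animals),
            }
        )
    return pd.DataFrame(out)
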