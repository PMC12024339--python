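"""Piecewise structural equation models over temperature, TNZ breadth and body length.

Each candidate causal graph ("pathway") is fitted piecewise: every endogenous
node gets its own local regression — body length as a gamma identity-link
GLMM with sex and stage fixed effects and a site random intercept, TNZ
breadth as a site-level linear model — and global fit is judged through the
graph's d-separation claims.  Each claim is tested by adding the putatively
independent variable to the component model of the claim's response and
taking its Wald (or F) p-value; the claims combine into Fisher's C
(``-2 * sum(log p)``, chi-square with 2k df), and models are ranked by
``AIC = C + 2K`` where K counts the parameters of the component models.

The three standard pathways share the direct effects of AnnMinTemp on body
length and TNZ breadth; the second adds a directed TNZ-breadth -> length
effect, the third instead a residual correlation between the two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .body_size import (
    STAGE_REFERENCE,
    GammaGLMM,
    filter_records,
    standardize,
)
from .config import STAGES
from .errors import DataError, FitError

logger = logging.getLogger(__name__)

__all__ = [
    "PathwaySpec",
    "IndependenceClaim",
    "SEMFit",
    "default_pathways",
    "basis_set",
    "fishers_c",
    "sem_aic",
    "standardized_estimate",
    "fit_pathways",
]

TEMP, TNZB, LENGTH, SEX, STAGE = "ann_min_temp", "tnz_b", "body_length", "sex", "stage"


@dataclass(frozen=True)
class PathwaySpec:
    """A directed acyclic pathway plus optional correlated-error pairs."""

    name: str
    edges: tuple[tuple[str, str], ...]
    correlated_errors: tuple[frozenset, ...] = ()

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @property
    def nodes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for a, b in self.edges:
            seen.setdefault(a)
            seen.setdefault(b)
        for pair in self.correlated_errors:
            for v in sorted(pair):
                seen.setdefault(v)
        return tuple(seen)


@dataclass(frozen=True)
class IndependenceClaim:
    x: str
    y: str
    given: frozenset
    response: str          # which member's component model hosts the test


def default_pathways(include_covariates: bool = True) -> list[PathwaySpec]:
    """The three nested pathways of increasing complexity.

    All include AnnMinTemp -> body length and AnnMinTemp -> TNZ breadth (and,
    when ``include_covariates``, the exogenous sex/stage effects on length).
    Pathway 2 adds TNZ breadth -> length; pathway 3 instead correlates the
    two responses' errors.
    """
    base = [(TEMP, LENGTH), (TEMP, TNZB)]
    if include_covariates:
        base += [(SEX, LENGTH), (STAGE, LENGTH)]
    return [
        PathwaySpec("pathway1", tuple(base)),
        PathwaySpec("pathway2", tuple(base + [(TNZB, LENGTH)])),
        PathwaySpec("pathway3", tuple(base),
                    correlated_errors=(frozenset({TNZB, LENGTH}),)),
    ]


def basis_set(spec: PathwaySpec) -> list[IndependenceClaim]:
    """The d-separation basis: one claim per non-adjacent variable pair.

    Pairs joined by an edge (either direction) or a correlated error are
    adjacent; pairs of two exogenous variables (no parents) are excluded
    because their joint distribution is not modelled.  Each claim conditions
    on the union of the pair's parents; the test lives in the component model
    of the pair member with the larger parent set (topologically later on
    ties, lexicographic last).
    """
    g = spec.graph()
    if not nx.is_directed_acyclic_graph(g):
        raise DataError("pathway graph is cyclic")
    adjacent = {frozenset(e) for e in spec.edges} | set(spec.correlated_errors)
    order = {v: i for i, v in enumerate(nx.lexicographical_topological_sort(g))}
    claims = []
    nodes = sorted(g.nodes)
    for i, xv in enumerate(nodes):
        for yv in nodes[i + 1:]:
            if frozenset({xv, yv}) in adjacent:
                continue
            pa_x, pa_y = set(g.predecessors(xv)), set(g.predecessors(yv))
            if not pa_x and not pa_y:
                continue       # both exogenous
            given = frozenset((pa_x | pa_y) - {xv, yv})
            key = lambda v, pa: (len(pa), order[v], v)
            response = xv if key(xv, pa_x) > key(yv, pa_y) else yv
            claims.append(IndependenceClaim(xv, yv, given, response))
    return claims


def fishers_c(p_values: Iterable[float]) -> tuple[float, int, float]:
    """Fisher's C over independence-claim p-values: (C, df, global p)."""
    ps = np.asarray(list(p_values), dtype=float)
    if np.any((ps <= 0) | (ps > 1)):
        raise DataError(
            "claim p-values must lie in (0, 1]; a zero p-value means a claim "
            "is decisively violated (C would be infinite)"
        )
    if len(ps) == 0:
        return 0.0, 0, 1.0
    c = float(-2.0 * np.sum(np.log(ps)))
    df = 2 * len(ps)
    return c, df, float(stats.chi2.sf(c, df))


def sem_aic(c: float, k: int) -> float:
    """AIC of a piecewise SEM: Fisher's C plus twice the parameter count."""
    if c < 0:
        raise ValueError("Fisher's C must be >= 0")
    if k < 0 or int(k) != k:
        raise ValueError("K must be a non-negative integer")
    return float(c) + 2.0 * int(k)


def standardized_estimate(slope: float, sd_x: float, sd_y: float) -> float:
    """Rescale a natural-scale path coefficient to SD units."""
    if sd_y <= 0:
        raise DataError("response SD must be > 0 to standardize an estimate")
    if sd_x < 0:
        raise ValueError("predictor SD must be >= 0")
    return slope * sd_x / sd_y


# --------------------------------------------------------------------------
# Pathway fitting
# --------------------------------------------------------------------------


@dataclass
class SEMFit:
    pathway: PathwaySpec
    component_fits: dict
    claims: list
    fisher_c: float
    df: int
    c_p_value: float
    K: int
    aic: float
    std_estimates: dict
    path_table: pd.DataFrame
    converged: bool
    rank: int | None = None


class _SEMData:
    """Joined observation-level and site-level frames for SEM component fits."""

    def __init__(self, records: pd.DataFrame, site_climate: pd.DataFrame,
                 tnz_estimates: pd.DataFrame):
        recs = filter_records(records)
        tnz = tnz_estimates.rename(
            columns={"tnz_b_C": TNZB}
        )[["site", TNZB]] if "tnz_b_C" in tnz_estimates else tnz_estimates[["site", TNZB]]
        clim = site_climate[["site", "ann_min_temp"]].drop_duplicates("site")
        obs = recs.merge(clim, on="site").merge(tnz, on="site")
        if obs.empty:
            raise DataError("join of records, climate and TNZ estimates is empty")
        if obs["site"].nunique() < 3:
            raise DataError("need >= 3 sites for the site-level component model")
        self.obs = obs.reset_index(drop=True)
        agg = self.obs.groupby("site", sort=True)
        site = agg.agg(
            ann_min_temp=("ann_min_temp", "first"),
            tnz_b=(TNZB, "first"),
            body_length=("body_length_mm", "mean"),
            prop_male=("sex", lambda s: float(np.mean(s == "male"))),
        ).reset_index()
        stages_present = [s for s in STAGES
                          if s in set(self.obs["stage"]) and s != STAGE_REFERENCE]
        for s in stages_present:
            share = agg["stage"].apply(lambda v, s=s: float(np.mean(v == s)))
            site[f"share[{s}]"] = share.to_numpy()
        self.site = site
        self.sd_obs = {
            TEMP: float(self.obs["ann_min_temp"].std(ddof=1)),
            TNZB: float(self.obs[TNZB].std(ddof=1)),
            LENGTH: float(self.obs["body_length_mm"].std(ddof=1)),
        }
        self.sd_site = {
            TEMP: float(site["ann_min_temp"].std(ddof=1)),
            TNZB: float(site[TNZB].std(ddof=1)),
        }

    # -- component models --------------------------------------------------
    def length_glmm(self, continuous: Sequence[str]) -> dict:
        """Gamma GLMM for body length with the given continuous parents."""
        colmap = {TEMP: "ann_min_temp", TNZB: TNZB}
        cols, names = [], []
        for node in continuous:
            cols.append(standardize(self.obs[colmap[node]]))
            names.append(node)
        cols.append((self.obs["sex"] == "male").to_numpy(dtype=float))
        names.append("sex[male]")
        stages_present = [s for s in STAGES
                          if s in set(self.obs["stage"]) and s != STAGE_REFERENCE]
        for s in stages_present:
            cols.append((self.obs["stage"] == s).to_numpy(dtype=float))
            names.append(f"stage[{s}]")
        X = np.column_stack(cols)
        y = self.obs["body_length_mm"].to_numpy(dtype=float)
        est = GammaGLMM().fit(X, y, groups=self.obs["site"].to_numpy())
        return {
            "model": est, "X": X, "y": y, "names": ["intercept"] + names,
            "n_parameters": 1 + len(names) + 2,    # + shape + RE variance
        }

    def tnz_lm(self, extra_cols: Sequence[str] = ()) -> dict:
        """Site-level OLS for TNZ breadth on standardised AnnMinTemp."""
        x = standardize(self.site["ann_min_temp"])
        cols = [x]
        names = [TEMP]
        for c in extra_cols:
            cols.append(self.site[c].to_numpy(dtype=float))
            names.append(c)
        X = sm.add_constant(np.column_stack(cols))
        y = self.site[TNZB].to_numpy(dtype=float)
        res = sm.OLS(y, X).fit()
        return {"model": res, "names": ["intercept"] + names,
                "n_parameters": X.shape[1] + 1}    # + residual variance


def _claim_p(data: _SEMData, claim: IndependenceClaim, pathway: PathwaySpec) -> float:
    """p-value of one independence claim, tested in the response's model."""
    pair_other = claim.x if claim.response == claim.y else claim.y
    g = pathway.graph()
    if claim.response == LENGTH:
        parents = [v for v in g.predecessors(LENGTH) if v in (TEMP, TNZB)]
        if pair_other not in (TEMP, TNZB):
            raise NotImplementedError(
                f"claim {claim} needs a non-continuous test in the length model"
            )
        comp = data.length_glmm(parents + [pair_other])
        i = comp["names"].index(pair_other)
        return float(comp["model"].wald_p_[i])
    if claim.response == TNZB:
        if pair_other == SEX:
            comp = data.tnz_lm(["prop_male"])
            i = comp["names"].index("prop_male")
            return float(comp["model"].pvalues[i])
        if pair_other == STAGE:
            # joint F test of the stage-share columns via nested models
            extra = [c for c in data.site.columns if c.startswith("share[")]
            full = data.tnz_lm(extra)["model"]
            null = data.tnz_lm()["model"]
            q = len(extra)
            df_resid = full.df_resid
            if df_resid <= 0:
                raise FitError("too few sites for the stage claim test")
            f = ((null.ssr - full.ssr) / q) / (full.ssr / df_resid)
            return float(stats.f.sf(f, q, df_resid))
        if pair_other == LENGTH:
            comp = data.tnz_lm(["body_length"])
            i = comp["names"].index("body_length")
            return float(comp["model"].pvalues[i])
    raise NotImplementedError(f"no test rule for claim {claim}")


def fit_pathways(
    records: pd.DataFrame,
    site_climate: pd.DataFrame,
    tnz_estimates: pd.DataFrame,
    pathways: Sequence[PathwaySpec] | None = None,
) -> list[SEMFit]:
    """Fit, test and AIC-rank the candidate pathways.

    Records are filtered, joined with site-level AnnMinTemp and TNZ breadth;
    each pathway's component models are fitted, its basis-set claims tested,
    and the fits returned sorted by AIC (ties broken by fewer parameters).
    """
    data = _SEMData(records, site_climate, tnz_estimates)
    if pathways is None:
        pathways = default_pathways()

    fits = []
    for pw in pathways:
        g = pw.graph()
        length_parents = [v for v in g.predecessors(LENGTH) if v in (TEMP, TNZB)]
        comp_len = data.length_glmm(length_parents)
        comp_tnz = data.tnz_lm()
        converged = bool(comp_len["model"].converged_)
        if not converged:
            logger.warning("%s: length component flagged non-converged", pw.name)

        # path estimates
        paths = []
        std_estimates = {}
        mdl = comp_len["model"]
        sd_len = data.sd_obs[LENGTH]
        for node in length_parents:
            i = comp_len["names"].index(node)
            slope_std_pred = float(mdl.params_[i])     # predictor standardised
            est_std = slope_std_pred / sd_len
            std_estimates[(node, LENGTH)] = est_std
            paths.append({
                "pathway": pw.name, "edge": f"{node}->{LENGTH}",
                "estimate": slope_std_pred / data.sd_obs[node],
                "std_estimate": est_std, "p": float(mdl.wald_p_[i]),
            })
        lm = comp_tnz["model"]
        i = comp_tnz["names"].index(TEMP)
        slope_std_pred = float(lm.params[i])
        est_std = slope_std_pred / data.sd_site[TNZB]
        std_estimates[(TEMP, TNZB)] = est_std
        paths.append({
            "pathway": pw.name, "edge": f"{TEMP}->{TNZB}",
            "estimate": slope_std_pred / data.sd_site[TEMP],
            "std_estimate": est_std, "p": float(lm.pvalues[i]),
        })

        if pw.correlated_errors:
            # residual correlation between site-mean marginal length residuals
            # and the TNZ model's residuals
            resid_len = data.obs["body_length_mm"].to_numpy() - mdl.predict(comp_len["X"])
            site_resid = (
                pd.DataFrame({"site": data.obs["site"], "r": resid_len})
                .groupby("site", sort=True)["r"].mean()
                .loc[data.site["site"]].to_numpy()
            )
            r = float(np.corrcoef(site_resid, lm.resid)[0, 1])
            G = len(site_resid)
            tstat = r * np.sqrt(max(G - 2, 1) / max(1.0 - r * r, 1e-12))
            p_corr = float(2 * stats.t.sf(abs(tstat), max(G - 2, 1)))
            std_estimates[tuple(sorted(next(iter(pw.correlated_errors))))] = r
            paths.append({
                "pathway": pw.name, "edge": f"{TNZB}<->{LENGTH}",
                "estimate": r, "std_estimate": r, "p": p_corr,
            })

        claims = basis_set(pw)
        claim_rows = []
        pvals = []
        for claim in claims:
            p = _claim_p(data, claim, pw)
            p = min(max(p, np.finfo(float).tiny), 1.0)
            pvals.append(p)
            claim_rows.append({
                "x": claim.x, "y": claim.y,
                "given": ",".join(sorted(claim.given)),
                "response": claim.response, "p": p,
            })
        c, df, c_p = fishers_c(pvals)
        K = comp_len["n_parameters"] + comp_tnz["n_parameters"]
        fits.append(
            SEMFit(
                pathway=pw,
                component_fits={"body_length": comp_len, "tnz_b": comp_tnz},
                claims=claim_rows,
                fisher_c=c,
                df=df,
                c_p_value=c_p,
                K=K,
                aic=sem_aic(c, K),
                std_estimates=std_estimates,
                path_table=pd.DataFrame(paths),
                converged=converged,
            )
        )
    fits.sort(key=lambda f: (f.aic, f.K))
    for i, f in enumerate(fits):
        f.rank = i + 1
    return fits
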