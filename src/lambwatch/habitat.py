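"""Habitat-use and habitat-selection analyses.

Two designs, both fitted as random-intercept logistic regressions:

LSD (latent selection difference)
    Contrasts habitat attributes of the 15 days before versus after each
    inferred lambing date (prepartum = 0, postpartum = 1).  It measures a
    change in *use*, not selection — availability is not characterized.

RSF (resource selection function)
    Used (1) versus available (0) sites over the pooled seasonal home range
    (a 95% minimum convex polygon around all animals' fixes; the same
    habitat is available to every ewe), with available points sampled
    uniformly in the polygon at a 10:1 ratio to used points.  Separate
    models per reproductive status; selection differences are read off a
    covariate-wise comparison of coefficient confidence intervals.

Distances to roads and trails pass through an exponential decay
``exp(-3 d / 500 m)`` so that the influence of these features saturates
(~5% of its at-feature value) beyond 500 m.  Continuous covariates are
z-scored over the pooled design table so coefficient magnitudes are
comparable.

The mixed model is a logistic regression with one Gaussian random
intercept per animal; the marginal likelihood is integrated by adaptive
Gauss–Hermite quadrature (nodes recentred on each animal's posterior mode)
and maximized with L-BFGS-B.  Confidence intervals are Wald.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
import statsmodels.api as sm
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from shapely.geometry import MultiPoint, Polygon

from .landscape import CovariateStack
from .parturition import LambingCall

__all__ = [
    "FittedGlmm",
    "decay_transform",
    "build_lsd_table",
    "build_rsf_table",
    "pool_and_standardize",
    "pooled_mcp",
    "fit_random_intercept_logistic",
    "compare_selection",
]

DEFAULT_DECAY_COLS = ("dist_road", "dist_trail")


def decay_transform(d, range_m: float = 500.0):
    """Exponential-decay transform of a distance: exp(-3 d / range_m).

    Equals 1 at the feature and ~= exp(-3) ~= 0.05 at ``range_m``, so the
    covariate is effectively saturated beyond that range.  Raises on
    negative distances.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    out = np.exp(-3.0 * d / range_m)
    return float(out) if out.ndim == 0 else out


def _extract_covariates(
    x: np.ndarray,
    y: np.ndarray,
    stack: CovariateStack,
    decay_cols: tuple[str, ...] = DEFAULT_DECAY_COLS,
    decay_range_m: float = 500.0,
) -> pd.DataFrame:
    cov = stack.extract(x, y)
    for col in decay_cols:
        if col in cov.columns:
            cov[col] = decay_transform(cov[col].to_numpy(), range_m=decay_range_m)
    return cov


def build_lsd_table(
    traj: pd.DataFrame,
    call: LambingCall,
    stack: CovariateStack,
    span_days: float = 15.0,
    decay_cols: tuple[str, ...] = DEFAULT_DECAY_COLS,
    decay_range_m: float = 500.0,
) -> pd.DataFrame:
    """Design rows for one animal: prepartum (0) vs postpartum (1) fixes.

    Fixes in [call - span, call) are prepartum, [call, call + span)
    postpartum (the lambing timestamp itself is postpartum).  Covariates are
    extracted at the fix coordinates; road/trail distances are
    decay-transformed.  Standardization is deferred to
    :func:`pool_and_standardize` so it happens over the pooled table.
    ``attrs['unbalanced']`` flags a window truncated to zero rows on either
    side.
    """
    if not call.detected or call.lambing_datetime is None:
        raise ValueError("LSD table requires a detected lambing call")
    t = pd.to_datetime(traj["timestamp"])
    t0 = pd.Timestamp(call.lambing_datetime)
    span = pd.Timedelta(days=span_days)
    pre = (t >= t0 - span) & (t < t0)
    post = (t >= t0) & (t < t0 + span)
    sel = traj.loc[pre | post]
    response = np.where(t.loc[pre | post] >= t0, 1, 0)
    cov = _extract_covariates(
        sel["x"].to_numpy(), sel["y"].to_numpy(), stack, decay_cols, decay_range_m
    )
    out = pd.concat(
        [
            pd.DataFrame(
                {"response": response, "animal_id": sel["animal_id"].to_numpy()}
            ).reset_index(drop=True),
            cov.reset_index(drop=True),
        ],
        axis=1,
    )
    out.attrs["design"] = "LSD"
    out.attrs["unbalanced"] = bool(pre.sum() == 0 or post.sum() == 0)
    return out


def pooled_mcp(fixes: pd.DataFrame, level: float = 0.95) -> Polygon:
    """Seasonal home range: ``level`` MCP over all animals' fixes pooled."""
    xy = fixes[["x", "y"]].to_numpy(dtype=float)
    if len(np.unique(xy, axis=0)) < 3:
        raise ValueError("need at least 3 distinct fix locations for an MCP")
    m = int(np.floor((1.0 - level) * len(xy)))
    if m > 0:
        centroid = xy.mean(axis=0)
        dist = np.hypot(*(xy - centroid).T)
        keep = np.argsort(-dist, kind="stable")[m:]
        xy = xy[keep]
    hull = MultiPoint(np.unique(xy, axis=0)).convex_hull
    if hull.geom_type != "Polygon" or hull.area == 0:
        raise ValueError("degenerate (zero-area) home-range polygon")
    return hull


def build_rsf_table(
    used: pd.DataFrame,
    stack: CovariateStack,
    ratio: int = 10,
    seed: int = 0,
    mcp_level: float = 0.95,
    decay_cols: tuple[str, ...] = DEFAULT_DECAY_COLS,
    decay_range_m: float = 500.0,
    home_range: Polygon | None = None,
) -> pd.DataFrame:
    """Used/available design table for one reproductive status.

    ``used`` holds all season fixes of the status group (columns animal_id,
    x, y).  Available points are drawn uniformly (rejection sampling from
    the bounding box) inside the pooled-MCP home range, ``ratio`` per used
    point, allocated to animals in proportion to their used counts so the
    random intercept remains estimable.
    """
    hr = home_range if home_range is not None else pooled_mcp(used)
    rng = np.random.default_rng(seed)
    n_avail = ratio * len(used)
    pts = np.empty((0, 2))
    minx, miny, maxx, maxy = hr.bounds
    while len(pts) < n_avail:
        cand = np.column_stack(
            [
                rng.uniform(minx, maxx, size=2 * n_avail),
                rng.uniform(miny, maxy, size=2 * n_avail),
            ]
        )
        inside = shapely.contains(hr, shapely.points(cand))
        pts = np.vstack([pts, cand[inside]])
    pts = pts[:n_avail]

    avail_animals = np.repeat(
        used["animal_id"].to_numpy(), ratio
    )  # ratio available rows per used row, same animal
    used_cov = _extract_covariates(
        used["x"].to_numpy(), used["y"].to_numpy(), stack, decay_cols, decay_range_m
    )
    avail_cov = _extract_covariates(pts[:, 0], pts[:, 1], stack, decay_cols, decay_range_m)
    out = pd.concat(
        [
            pd.DataFrame(
                {
                    "response": np.concatenate(
                        [np.ones(len(used), dtype=int), np.zeros(n_avail, dtype=int)]
                    ),
                    "animal_id": np.concatenate(
                        [used["animal_id"].to_numpy(), avail_animals]
                    ),
                }
            ),
            pd.concat([used_cov, avail_cov], ignore_index=True),
        ],
        axis=1,
    )
    out.attrs["design"] = "RSF"
    return out


def pool_and_standardize(
    tables: list[pd.DataFrame],
    covariate_cols: list[str] | None = None,
    standardize: bool = True,
) -> pd.DataFrame:
    """Concatenate per-animal design tables and z-score covariates pooled."""
    pooled = pd.concat(tables, ignore_index=True)
    attrs = tables[0].attrs.copy()
    if covariate_cols is None:
        covariate_cols = [
            c for c in pooled.columns if c not in ("response", "animal_id")
        ]
    if standardize:
        for c in covariate_cols:
            v = pooled[c].to_numpy(dtype=float)
            sd = v.std()
            if sd == 0:
                raise ValueError(f"covariate {c} is constant; cannot standardize")
            pooled[c] = (v - v.mean()) / sd
    pooled.attrs = attrs
    pooled.attrs["covariate_cols"] = covariate_cols
    return pooled


# ----------------------------------------------------------------------------
# Random-intercept logistic regression (adaptive Gauss-Hermite quadrature)
# ----------------------------------------------------------------------------


@dataclass
class FittedGlmm:
    params: pd.DataFrame  # index: term; columns: coef, se, ci_low, ci_high
    sigma_animal: float
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool

    @property
    def coefs(self) -> pd.Series:
        return self.params["coef"]


def _glmm_nll(
    theta: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    group_slices: list[tuple[int, int]],
    z: np.ndarray,
    w: np.ndarray,
) -> float:
    """Negative marginal log-likelihood, adaptive GH over the random intercept."""
    beta = theta[:-1]
    sigma = np.exp(theta[-1])
    xb = X @ beta
    nll = 0.0
    for lo, hi in group_slices:
        xb_g = xb[lo:hi]
        y_g = y[lo:hi]

        def h_parts(b):
            eta = xb_g + b
            # log p(y | eta) summed + log-prior of b
            ll = np.sum(y_g * eta - np.logaddexp(0.0, eta))
            return ll - 0.5 * b * b / (sigma * sigma)

        # Newton for the posterior mode of b.
        b = 0.0
        for _ in range(50):
            eta = xb_g + b
            p = 1.0 / (1.0 + np.exp(-eta))
            g = np.sum(y_g - p) - b / (sigma * sigma)
            hcurv = np.sum(p * (1 - p)) + 1.0 / (sigma * sigma)
            step = g / hcurv
            b += step
            if abs(step) < 1e-10:
                break
        eta = xb_g + b
        p = 1.0 / (1.0 + np.exp(-eta))
        hcurv = np.sum(p * (1 - p)) + 1.0 / (sigma * sigma)
        scale = 1.0 / np.sqrt(hcurv)
        nodes = b + scale * z  # (K,)
        eta_k = xb_g[:, None] + nodes[None, :]
        ll_k = np.sum(y_g[:, None] * eta_k - np.logaddexp(0.0, eta_k), axis=0)
        log_integrand = ll_k - 0.5 * nodes**2 / (sigma * sigma) + 0.5 * z**2
        m = log_integrand.max()
        integral = np.log(np.sum(w * np.exp(log_integrand - m))) + m + np.log(scale)
        nll -= integral - 0.5 * np.log(2 * np.pi) - np.log(sigma)
    return nll


def fit_random_intercept_logistic(
    table: pd.DataFrame,
    covariate_cols: list[str] | None = None,
    group_col: str = "animal_id",
    response_col: str = "response",
    n_quad: int = 15,
    min_log_sigma: float = -7.0,
) -> FittedGlmm:
    """ML fit of a logistic regression with a Gaussian random intercept per animal.

    Fixed effects: intercept plus ``covariate_cols`` (default: every column
    other than response and group).  Marginal likelihood by adaptive
    Gauss-Hermite quadrature (``n_quad`` nodes, recentred per group);
    optimization over (beta, log sigma) by L-BFGS-B, started at the plain
    logistic fit.  Wald 95% CIs from the numerical Hessian.  Complete
    separation raises (the plain-logistic start detects it).
    """
    if covariate_cols is None:
        covariate_cols = [
            c for c in table.columns if c not in (response_col, group_col)
        ]
    if table[group_col].nunique() < 2:
        raise ValueError("need at least 2 animals for a random intercept")
    tab = table.sort_values(group_col, kind="stable").reset_index(drop=True)
    X = np.column_stack(
        [np.ones(len(tab))] + [tab[c].to_numpy(dtype=float) for c in covariate_cols]
    )
    y = tab[response_col].to_numpy(dtype=float)
    groups = tab[group_col].to_numpy()
    # contiguous slices per group
    change = np.flatnonzero(np.concatenate([[True], groups[1:] != groups[:-1]]))
    bounds_idx = np.concatenate([change, [len(tab)]])
    group_slices = [(int(bounds_idx[i]), int(bounds_idx[i + 1])) for i in range(len(change))]

    # Separation check + starting values via plain logistic regression.  A
    # singular Hessian or runaway coefficient marks (quasi-)complete
    # separation; name the worst covariate.
    with np.errstate(divide="ignore", over="ignore"):
        try:
            start_fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            start_params, start_bse = start_fit.params, start_fit.bse
        except np.linalg.LinAlgError:
            start_params = sm.Logit(y, X).fit(disp=0, maxiter=200, method="bfgs").params
            start_bse = np.full(X.shape[1], np.inf)
    if np.any(~np.isfinite(start_bse)) or np.any(np.abs(start_params) > 30):
        worst = int(np.argmax(np.abs(start_params)))
        term = (["intercept"] + covariate_cols)[worst]
        raise ValueError(f"complete or quasi-complete separation (covariate {term})")

    # Probabilists' Gauss-Hermite rule: int exp(-z^2/2) g(z) dz ~= sum w_k g(z_k);
    # the integrand in _glmm_nll carries the exp(+z^2/2) correction explicitly.
    z, w = hermegauss(n_quad)

    theta0 = np.concatenate([start_params, [np.log(0.5)]])
    res = minimize(
        _glmm_nll,
        theta0,
        args=(X, y, group_slices, z, w),
        method="L-BFGS-B",
        bounds=[(None, None)] * X.shape[1] + [(min_log_sigma, 5.0)],
        options={"maxiter": 500, "ftol": 1e-10},
    )
    theta = res.x

    # Numerical Hessian (central differences) for Wald SEs of the betas.
    p = len(theta)
    eps = 1e-4 * np.maximum(np.abs(theta), 1.0)
    H = np.zeros((p, p))
    f0 = _glmm_nll(theta, X, y, group_slices, z, w)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = eps[i]
            ej[j] = eps[j]
            fpp = _glmm_nll(theta + ei + ej, X, y, group_slices, z, w)
            fpm = _glmm_nll(theta + ei - ej, X, y, group_slices, z, w)
            fmp = _glmm_nll(theta - ei + ej, X, y, group_slices, z, w)
            fmm = _glmm_nll(theta - ei - ej, X, y, group_slices, z, w)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * eps[i] * eps[j])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[: X.shape[1]], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(X.shape[1], np.nan)

    terms = ["intercept"] + list(covariate_cols)
    beta = theta[: X.shape[1]]
    params = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "ci_low": beta - 1.959963984540054 * se,
            "ci_high": beta + 1.959963984540054 * se,
        },
        index=pd.Index(terms, name="term"),
    )
    return FittedGlmm(
        params=params,
        sigma_animal=float(np.exp(theta[-1])),
        loglik=-float(res.fun),
        n_obs=len(tab),
        n_groups=len(group_slices),
        converged=bool(res.success),
    )


def compare_selection(fit_a: FittedGlmm, fit_b: FittedGlmm) -> pd.DataFrame:
    """Covariate-wise comparison of two fitted models (e.g. parturient vs not).

    Returns a table sorted by covariate name with both estimates, both 95%
    CIs, the estimate difference (a - b), and whether the CIs overlap.
    """
    terms_a = [t for t in fit_a.params.index if t != "intercept"]
    terms_b = [t for t in fit_b.params.index if t != "intercept"]
    if set(terms_a) != set(terms_b):
        raise ValueError("fits have mismatched covariate rosters")
    rows = []
    for t in sorted(terms_a):
        a = fit_a.params.loc[t]
        b = fit_b.params.loc[t]
        rows.append(
            {
                "covariate": t,
                "coef_a": a["coef"],
                "ci_low_a": a["ci_low"],
                "ci_high_a": a["ci_high"],
                "coef_b": b["coef"],
                "ci_low_b": b["ci_low"],
                "ci_high_b": b["ci_high"],
                "difference": a["coef"] - b["coef"],
                "ci_overlap": not (
                    a["ci_low"] > b["ci_high"] or b["ci_low"] > a["ci_high"]
                ),
            }
        )
    return pd.DataFrame(rows).set_index("covariate")
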