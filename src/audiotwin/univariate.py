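"""Univariate ACE variance-component estimation for twin-pair data.

A phenotype measured on MZ and DZ twin pairs (plus singletons) is modelled
as bivariate normal per pair with a common mean, total variance
``a^2 + c^2 + e^2`` and within-pair covariance ``a^2 + c^2`` (MZ) or
``a^2/2 + c^2`` (DZ).  Parameters are estimated as path coefficients
(a, c, e >= 0) by maximum likelihood with seeded random restarts; the
closed-form estimates from the MZ/DZ intraclass correlations serve as an
independent oracle:

    a^2 = 2 (r_MZ - r_DZ),   c^2 = 2 r_DZ - r_MZ,   e^2 = 1 - r_MZ

95% confidence intervals for the standardized shares use the profile
likelihood (bound at a -2 log L rise of 3.84).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

LOG2PI = np.log(2.0 * np.pi)
_PENALTY = 1e12  # finite penalty keeps optimizers off invalid regions without NaN warnings

MODEL_PARAMS = {
    "ACE": ("a", "c", "e"),
    "AE": ("a", "e"),
    "CE": ("c", "e"),
    "E": ("e",),
}
CHI2_95_1DF = 3.841458820694124  # chi2.ppf(0.95, 1)


class FitError(RuntimeError):
    pass


@dataclass
class ZygosityCorrelations:
    r_mz: float
    r_dz: float
    n_mz_pairs: int
    n_dz_pairs: int


@dataclass
class VarianceComponents:
    a2: float
    c2: float
    e2: float
    clipped: bool = False


@dataclass
class UnivariateFit:
    model: str
    minus2logl: float
    df: int
    components: VarianceComponents | None = None
    ci95: dict[str, tuple[float, float]] | None = None
    mean: float | None = None
    total_var: float | None = None
    paths: dict[str, float] | None = None
    boundary: bool = False
    n_obs: int | None = None
    column: str | None = None


@dataclass
class ModelComparison:
    delta_minus2logl: float
    delta_df: int
    p_value: float
    aic: float


# ---------------------------------------------------------------------------
# Correlations and the closed-form oracle
# ---------------------------------------------------------------------------

def _pair_values(table: pd.DataFrame, column: str, zygosity: str) -> np.ndarray:
    """(n_pairs, 2) array of complete pairs for one zygosity."""
    sub = table[(table["zygosity"] == zygosity) & table[column].notna()]
    pairs = []
    for _, grp in sub.groupby("pair_id", sort=True):
        if len(grp) == 2:
            pairs.append(grp[column].to_numpy(dtype=float))
    return np.asarray(pairs) if pairs else np.empty((0, 2))


def zygosity_correlations(table: pd.DataFrame, column: str) -> ZygosityCorrelations:
    """Double-entered Pearson intraclass correlations per zygosity."""
    vals = table[column].dropna().to_numpy(dtype=float)
    if vals.size and np.all(vals == vals[0]):
        raise FitError(f"phenotype {column!r} is constant")
    out = {}
    ns = {}
    for zyg in ("MZ", "DZ"):
        pairs = _pair_values(table, column, zyg)
        if len(pairs) < 2:
            raise FitError(f"need >= 2 complete {zyg} pairs, got {len(pairs)}")
        x = np.concatenate([pairs[:, 0], pairs[:, 1]])
        y = np.concatenate([pairs[:, 1], pairs[:, 0]])
        out[zyg] = float(np.corrcoef(x, y)[0, 1])
        ns[zyg] = len(pairs)
    return ZygosityCorrelations(
        r_mz=out["MZ"], r_dz=out["DZ"], n_mz_pairs=ns["MZ"], n_dz_pairs=ns["DZ"]
    )


def falconer_estimates(
    corr: ZygosityCorrelations, clip: bool = False
) -> VarianceComponents:
    """Closed-form A/C/E shares from the MZ/DZ correlations.

    ``a2 = 2(r_mz - r_dz)``, ``c2 = 2 r_dz - r_mz``, ``e2 = 1 - r_mz``.
    With ``clip=True`` negative shares are set to zero and the triple is
    renormalized to sum to 1, with the ``clipped`` flag set.
    """
    if not (np.isfinite(corr.r_mz) and np.isfinite(corr.r_dz)):
        raise FitError("correlations must be finite")
    a2 = 2.0 * (corr.r_mz - corr.r_dz)
    c2 = 2.0 * corr.r_dz - corr.r_mz
    e2 = 1.0 - corr.r_mz
    clipped = False
    if clip and min(a2, c2, e2) < 0:
        a2, c2, e2 = (max(v, 0.0) for v in (a2, c2, e2))
        total = a2 + c2 + e2
        if total == 0:
            raise FitError("all components clipped to zero")
        a2, c2, e2 = a2 / total, c2 / total, e2 / total
        clipped = True
    return VarianceComponents(a2=a2, c2=c2, e2=e2, clipped=clipped)


# ---------------------------------------------------------------------------
# Likelihood machinery (sufficient statistics; O(1) per evaluation)
# ---------------------------------------------------------------------------

@dataclass
class _SuffStats:
    n_mz: int
    n_dz: int
    n_single: int
    mz_sum: float  # sum over pairs of y1 + y2
    mz_ss: float  # sum of y1^2 + y2^2
    mz_cross: float  # sum of y1 * y2
    dz_sum: float
    dz_ss: float
    dz_cross: float
    s_sum: float
    s_ss: float
    grand_mean: float
    grand_var: float
    n_values: int


def _suffstats(table: pd.DataFrame, column: str) -> _SuffStats:
    mz = _pair_values(table, column, "MZ")
    dz = _pair_values(table, column, "DZ")
    singles = table[(table["zygosity"] == "singleton") & table[column].notna()][
        column
    ].to_numpy(dtype=float)
    all_vals = np.concatenate([mz.ravel(), dz.ravel(), singles])
    return _SuffStats(
        n_mz=len(mz),
        n_dz=len(dz),
        n_single=len(singles),
        mz_sum=float(mz.sum()),
        mz_ss=float((mz**2).sum()),
        mz_cross=float((mz[:, 0] * mz[:, 1]).sum()) if len(mz) else 0.0,
        dz_sum=float(dz.sum()),
        dz_ss=float((dz**2).sum()),
        dz_cross=float((dz[:, 0] * dz[:, 1]).sum()) if len(dz) else 0.0,
        s_sum=float(singles.sum()),
        s_ss=float((singles**2).sum()),
        grand_mean=float(all_vals.mean()),
        grand_var=float(all_vals.var(ddof=1)),
        n_values=len(all_vals),
    )


def _m2ll(ss: _SuffStats, mu: float, v: float, cov_mz: float, cov_dz: float) -> float:
    """-2 log likelihood given mean, total variance and per-zygosity covariances."""
    if v <= 0:
        return _PENALTY
    total = 0.0
    for n, s, s2, cross, cov in (
        (ss.n_mz, ss.mz_sum, ss.mz_ss, ss.mz_cross, cov_mz),
        (ss.n_dz, ss.dz_sum, ss.dz_ss, ss.dz_cross, cov_dz),
    ):
        if n == 0:
            continue
        det = v * v - cov * cov
        if det <= 0:
            return _PENALTY
        alpha = v / det
        beta = -cov / det
        q_diag = s2 - 2.0 * mu * s + 2.0 * n * mu * mu
        q_cross = cross - mu * s + n * mu * mu
        total += n * (2.0 * LOG2PI + np.log(det)) + alpha * q_diag + 2.0 * beta * q_cross
    if ss.n_single:
        q = ss.s_ss - 2.0 * mu * ss.s_sum + ss.n_single * mu * mu
        total += ss.n_single * (LOG2PI + np.log(v)) + q / v
    return float(total)


def _m2ll_paths(ss: _SuffStats, mu: float, paths: dict[str, float]) -> float:
    a2 = paths.get("a", 0.0) ** 2
    c2 = paths.get("c", 0.0) ** 2
    e2 = paths.get("e", 0.0) ** 2
    return _m2ll(ss, mu, a2 + c2 + e2, a2 + c2, 0.5 * a2 + c2)


def fit_univariate(
    table: pd.DataFrame,
    column: str,
    model: str = "ACE",
    standardize: bool = True,
    compute_ci: bool = True,
    ci_components: tuple[str, ...] | None = None,
    n_restarts: int = 5,
    seed: int = 0,
) -> UnivariateFit:
    """Maximum-likelihood A/C/E fit of one phenotype column.

    Pairs enter as bivariate-normal observations, singletons as univariate
    ones; path coefficients keep variance components non-negative.  The
    input column should already be age-adjusted (see :func:`age_adjust`);
    with ``standardize=True`` it is z-scored first (estimated mean and total
    variance remain free parameters).
    """
    if model not in MODEL_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    work = table.copy()
    vals = work[column].to_numpy(dtype=float)
    if standardize:
        m, s = np.nanmean(vals), np.nanstd(vals, ddof=1)
        if s == 0:
            raise FitError(f"phenotype {column!r} is constant")
        work[column] = (vals - m) / s
    ss = _suffstats(work, column)
    if ss.n_mz < 10 or ss.n_dz < 10:
        raise FitError(
            f"need >= 10 complete pairs per zygosity (have MZ={ss.n_mz}, DZ={ss.n_dz})"
        )
    names = MODEL_PARAMS[model]
    sd0 = np.sqrt(ss.grand_var)

    def objective(x: np.ndarray) -> float:
        mu = x[0]
        paths = dict(zip(names, x[1:]))
        return _m2ll_paths(ss, mu, paths)

    rng = np.random.default_rng(seed)
    best = None
    for restart in range(n_restarts):
        if restart == 0:
            shares = np.full(len(names), 1.0 / len(names))
        else:
            shares = rng.dirichlet(np.ones(len(names)))
        x0 = np.concatenate([[ss.grand_mean], sd0 * np.sqrt(shares)])
        bounds = [(None, None)] + [(0.0, 10.0 * sd0 + 1.0)] * len(names)
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 2000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"optimization failed for {column!r} ({model})")
    mu_hat = float(best.x[0])
    paths = {k: abs(float(v)) for k, v in zip(names, best.x[1:])}
    a2 = paths.get("a", 0.0) ** 2
    c2 = paths.get("c", 0.0) ** 2
    e2 = paths.get("e", 0.0) ** 2
    total_var = a2 + c2 + e2
    if total_var <= 0:
        raise FitError("degenerate fit: zero total variance")
    shares = VarianceComponents(a2=a2 / total_var, c2=c2 / total_var, e2=e2 / total_var)
    boundary = any(
        paths.get(k, 0.0) ** 2 / total_var < 1e-6 for k in names if k != "e"
    )
    n_free = 1 + len(names)
    fit = UnivariateFit(
        model=model,
        minus2logl=float(best.fun),
        df=ss.n_values - n_free,
        components=shares,
        mean=mu_hat,
        total_var=total_var,
        paths=paths,
        boundary=boundary,
        n_obs=ss.n_values,
        column=column,
    )
    if compute_ci:
        wanted = ci_components if ci_components is not None else names
        fit.ci95 = {
            f"{k}2": _profile_ci_share(ss, model, k, fit)
            for k in names
            if k in wanted
        }
    return fit


def _profile_m2ll_share(
    ss: _SuffStats, model: str, comp: str, share: float, fit: UnivariateFit
) -> float:
    """Minimized -2logL with the standardized share of ``comp`` fixed.

    Inner parameterization: free mean, free total variance, and (for ACE)
    the share of one remaining non-E component within box bounds.
    """
    names = MODEL_PARAMS[model]
    others = [k for k in names if k != comp]
    share = min(max(share, 0.0), 1.0)

    def cov_parts(svec: dict[str, float], v: float) -> tuple[float, float]:
        a2 = svec.get("a", 0.0) * v
        c2 = svec.get("c", 0.0) * v
        return a2 + c2, 0.5 * a2 + c2

    if len(others) <= 1:
        # remaining share fully determined
        def obj(x):
            mu, logv = x
            v = np.exp(logv)
            svec = {comp: share}
            if others:
                svec[others[0]] = 1.0 - share
            cov_mz, cov_dz = cov_parts(svec, v)
            return _m2ll(ss, mu, v, cov_mz, cov_dz)

        x0 = np.array([fit.mean, np.log(fit.total_var)])
        res = optimize.minimize(obj, x0, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 4000})
        return float(res.fun)

    # ACE: one extra free share t in [0, 1-share]
    free_a, free_b = others  # e is always present; the other is a or c

    def obj(x):
        mu, logv, t_raw = x
        v = np.exp(logv)
        hi = 1.0 - share
        t = hi / (1.0 + np.exp(-t_raw))  # logistic map into (0, 1-share)
        svec = {comp: share, free_a: t, free_b: hi - t}
        cov_mz, cov_dz = cov_parts(svec, v)
        return _m2ll(ss, mu, v, cov_mz, cov_dz)

    best = np.inf
    for t0 in (-2.0, 0.0, 2.0):
        res = optimize.minimize(
            obj, np.array([fit.mean, np.log(fit.total_var), t0]), method="Nelder-Mead",
            options={"xatol": 1e-9, "fatol": 1e-10, "maxiter": 6000},
        )
        best = min(best, float(res.fun))
    return best


def _profile_ci_share(
    ss: _SuffStats, model: str, comp: str, fit: UnivariateFit
) -> tuple[float, float]:
    """95% profile-likelihood CI for one standardized variance share."""
    est = getattr(fit.components, f"{comp}2")
    target = fit.minus2logl + CHI2_95_1DF

    def excess(s: float) -> float:
        return _profile_m2ll_share(ss, model, comp, s, fit) - target

    eps = 1e-9
    lo = 0.0
    if est > eps and excess(0.0) > 0:
        lo = optimize.brentq(excess, 0.0, est, xtol=1e-5)
    hi = 1.0
    if est < 1.0 - eps and excess(1.0) > 0:
        hi = optimize.brentq(excess, est, 1.0, xtol=1e-5)
    return (float(lo), float(hi))


def compare_models(full: UnivariateFit, nested: UnivariateFit) -> ModelComparison:
    """Likelihood-ratio comparison of a nested model against a fuller one.

    ``p`` is the upper-tail chi-square probability of the -2 log L
    difference on the difference in free parameters; ``aic`` is the
    relative value ``delta - 2 * delta_df``.
    """
    full_params = set(MODEL_PARAMS[full.model])
    nested_params = set(MODEL_PARAMS[nested.model])
    if not nested_params < full_params:
        raise ValueError(f"{nested.model} is not nested within {full.model}")
    delta = nested.minus2logl - full.minus2logl
    if delta < -1e-6:
        raise FitError(
            f"nested model fits better than full by {-delta:.3g}; optimizer failure"
        )
    delta_df = len(full_params) - len(nested_params)
    p = float(stats.chi2.sf(max(delta, 0.0), delta_df))
    return ModelComparison(
        delta_minus2logl=float(delta),
        delta_df=delta_df,
        p_value=p,
        aic=float(delta - 2.0 * delta_df),
    )


def age_adjust(table: pd.DataFrame, column: str) -> pd.Series:
    """OLS residuals of a phenotype on age (intercept + linear term)."""
    age = table["age"].to_numpy(dtype=float)
    if np.std(age) == 0:
        raise FitError("age is constant; cannot age-adjust")
    y = table[column].to_numpy(dtype=float)
    mask = np.isfinite(y) & np.isfinite(age)
    design = np.column_stack([np.ones(mask.sum()), age[mask]])
    beta, *_ = np.linalg.lstsq(design, y[mask], rcond=None)
    resid = np.full_like(y, np.nan)
    resid[mask] = y[mask] - design @ beta
    return pd.Series(resid, index=table.index, name=f"{column}_age_adj")
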