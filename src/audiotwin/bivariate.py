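"""Bivariate correlated-factors twin model (AE by default).

Two traits per twin give a 4-vector per pair, modelled multivariate normal
with covariance built from per-trait additive-genetic and unique-environment
paths plus factor correlations ``r_a`` and ``r_e``:

* same trait, cross twin: ``a_t^2`` (MZ) or ``a_t^2 / 2`` (DZ)
* cross trait, same person: ``a_x a_y r_a + e_x e_y r_e``
* cross trait, cross twin: ``a_x a_y r_a`` (MZ) or half that (DZ)

An ACE variant (per-trait c paths plus ``r_c``) is available behind a flag.
Pairs with partially missing data contribute the marginal likelihood of
their observed sub-vector; singletons contribute their within-person
2-vector (or scalar).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

logger = logging.getLogger(__name__)

LOG2PI = np.log(2.0 * np.pi)


class BivariateFitError(RuntimeError):
    pass


def cubic_transform(values, mode: str = "cuberoot") -> tuple[np.ndarray, dict]:
    """Normalize a skewed score by a signed power transform about the median.

    ``cuberoot`` (default): ``sign(x - med) * |x - med|^(1/3)`` — compresses
    tails toward normality.  ``cube``: ``(x - med)^3`` (literal alternative).
    Returns the transformed array and a metadata record.
    """
    x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x[~np.isnan(x)])):
        raise ValueError("values must be finite or NaN")
    med = float(np.nanmedian(x))
    centered = x - med
    if mode == "cuberoot":
        out = np.sign(centered) * np.abs(centered) ** (1.0 / 3.0)
    elif mode == "cube":
        out = centered**3
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out, {"transform": mode, "center": "median", "median": med}


@dataclass
class BivariateFit:
    """Standardized correlated-factors estimates for two traits."""

    a_x: float
    e_x: float
    a_y: float
    e_y: float
    r_a: float
    r_e: float
    r_p: float
    prop_genetic: float | None
    minus2logl: float
    df: int
    model: str = "AE"
    c_x: float = 0.0
    c_y: float = 0.0
    r_c: float = 0.0
    ci95: dict[str, tuple[float, float]] | None = None
    boundary: bool = False
    n_obs: int | None = None
    traits: tuple[str, str] | None = None

    @property
    def a2_x(self) -> float:
        return self.a_x**2

    @property
    def a2_y(self) -> float:
        return self.a_y**2


def _pair_vectors(table: pd.DataFrame, x: str, y: str, zygosity: str) -> np.ndarray:
    """(n, 4) array (x1, y1, x2, y2) per pair; NaN marks missing entries."""
    sub = table[table["zygosity"] == zygosity]
    rows = []
    for _, grp in sub.groupby("pair_id", sort=True):
        if len(grp) != 2:
            continue
        g = grp.sort_values("subject_id")
        rows.append(
            [
                g[x].iloc[0],
                g[y].iloc[0],
                g[x].iloc[1],
                g[y].iloc[1],
            ]
        )
    return np.asarray(rows, dtype=float) if rows else np.empty((0, 4))


def _grouped_stats(vectors: np.ndarray):
    """Group rows by missingness mask; per group return (idx, n, sum, scatter)."""
    if len(vectors) == 0:
        return []
    masks = ~np.isnan(vectors)
    out = []
    for mask in {tuple(m) for m in masks}:
        idx = np.nonzero([tuple(m) == mask for m in masks])[0]
        obs_cols = np.nonzero(mask)[0]
        if obs_cols.size == 0:
            continue
        data = vectors[np.ix_(idx, obs_cols)]
        out.append((obs_cols, len(idx), data.sum(axis=0), data.T @ data))
    return out


def _sigma_blocks(params: dict[str, float], kin: float) -> tuple[np.ndarray, np.ndarray]:
    """Within-person block W and cross-twin block B for genetic sharing ``kin``."""
    a_x, e_x, a_y, e_y = params["a_x"], params["e_x"], params["a_y"], params["e_y"]
    c_x, c_y = params.get("c_x", 0.0), params.get("c_y", 0.0)
    r_a, r_e, r_c = params["r_a"], params["r_e"], params.get("r_c", 0.0)
    v_x = a_x**2 + c_x**2 + e_x**2
    v_y = a_y**2 + c_y**2 + e_y**2
    cxy = a_x * a_y * r_a + e_x * e_y * r_e + c_x * c_y * r_c
    w = np.array([[v_x, cxy], [cxy, v_y]])
    bg = kin * a_x * a_y * r_a + c_x * c_y * r_c
    b = np.array(
        [
            [kin * a_x**2 + c_x**2, bg],
            [bg, kin * a_y**2 + c_y**2],
        ]
    )
    return w, b


def _m2ll_groups(groups, sigma: np.ndarray, mu: np.ndarray) -> float:
    total = 0.0
    for obs_cols, n, svec, scatter in groups:
        sub = sigma[np.ix_(obs_cols, obs_cols)]
        mu_sub = mu[obs_cols]
        sign, logdet = np.linalg.slogdet(sub)
        if sign <= 0:
            return 1e12
        inv = np.linalg.inv(sub)
        centered = scatter - np.outer(svec, mu_sub) - np.outer(mu_sub, svec) + n * np.outer(
            mu_sub, mu_sub
        )
        total += n * (len(obs_cols) * LOG2PI + logdet) + float(np.trace(inv @ centered))
    return total


def fit_bivariate(
    table: pd.DataFrame,
    trait_x: str,
    trait_y: str,
    model: str = "AE",
    standardize: bool = True,
    complete_cases: bool = False,
    compute_ci: bool = False,
    n_restarts: int = 5,
    seed: int = 0,
) -> BivariateFit:
    """Fit the two-trait correlated-factors model by maximum likelihood.

    Both traits should be age-adjusted beforehand.  Reported paths are
    standardized per trait (``a_t^2 + e_t^2 = 1`` for the AE model); the
    implied phenotypic correlation satisfies
    ``r_p = a_x a_y r_a + e_x e_y r_e`` exactly.
    """
    if model not in ("AE", "ACE"):
        raise ValueError("model must be 'AE' or 'ACE'")
    work = table.copy()
    for col in (trait_x, trait_y):
        v = work[col].to_numpy(dtype=float)
        if standardize:
            s = np.nanstd(v, ddof=1)
            if s == 0:
                raise BivariateFitError(f"trait {col!r} is constant")
            work[col] = (v - np.nanmean(v)) / s

    data = {zyg: _pair_vectors(work, trait_x, trait_y, zyg) for zyg in ("MZ", "DZ")}
    for zyg, arr in data.items():
        complete = np.sum(~np.isnan(arr).any(axis=1)) if len(arr) else 0
        if complete < 20:
            raise BivariateFitError(
                f"need >= 20 complete {zyg} pairs, got {complete}"
            )
        if complete_cases:
            data[zyg] = arr[~np.isnan(arr).any(axis=1)]
    singles = work[work["zygosity"] == "singleton"][[trait_x, trait_y]].to_numpy(dtype=float)
    if complete_cases and len(singles):
        singles = singles[~np.isnan(singles).any(axis=1)]

    groups = {
        "MZ": _grouped_stats(data["MZ"]),
        "DZ": _grouped_stats(data["DZ"]),
        "S": _grouped_stats(singles) if len(singles) else [],
    }
    n_values = int(
        np.sum(~np.isnan(data["MZ"])) + np.sum(~np.isnan(data["DZ"]))
        + (np.sum(~np.isnan(singles)) if len(singles) else 0)
    )

    names = ["mu_x", "mu_y", "a_x", "e_x", "a_y", "e_y", "r_a", "r_e"]
    if model == "ACE":
        names += ["c_x", "c_y", "r_c"]

    def unpack(x: np.ndarray) -> dict[str, float]:
        return dict(zip(names, x))

    def objective(x: np.ndarray) -> float:
        p = unpack(x)
        w_mz, b_mz = _sigma_blocks(p, 1.0)
        w_dz, b_dz = _sigma_blocks(p, 0.5)
        mu = np.array([p["mu_x"], p["mu_y"], p["mu_x"], p["mu_y"]])
        total = 0.0
        for zyg, w, b in (("MZ", w_mz, b_mz), ("DZ", w_dz, b_dz)):
            sigma = np.block([[w, b], [b, w]])
            total += _m2ll_groups(groups[zyg], sigma, mu)
        if groups["S"]:
            total += _m2ll_groups(groups["S"], w_mz, mu[:2])
        return total

    rng = np.random.default_rng(seed)
    path_hi = 10.0
    bounds = [(None, None)] * 2 + [(0.0, path_hi)] * 4 + [(-0.999, 0.999)] * 2
    if model == "ACE":
        bounds += [(0.0, path_hi)] * 2 + [(-0.999, 0.999)]
    best = None
    for restart in range(n_restarts):
        if restart == 0:
            x0 = [0.0, 0.0, 0.7, 0.7, 0.7, 0.7, 0.0, 0.0]
            if model == "ACE":
                x0 += [0.1, 0.1, 0.0]
        else:
            x0 = [
                rng.normal(0, 0.2),
                rng.normal(0, 0.2),
                *rng.uniform(0.2, 1.0, 4),
                *rng.uniform(-0.8, 0.8, 2),
            ]
            if model == "ACE":
                x0 += [*rng.uniform(0.0, 0.6, 2), rng.uniform(-0.8, 0.8)]
        res = optimize.minimize(
            objective, np.asarray(x0, dtype=float), method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-13, "gtol": 1e-10, "maxiter": 5000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise BivariateFitError(
            f"optimization failed for ({trait_x!r}, {trait_y!r}) after {n_restarts} restarts"
        )
    p = unpack(best.x)
    v_x = p["a_x"] ** 2 + p.get("c_x", 0.0) ** 2 + p["e_x"] ** 2
    v_y = p["a_y"] ** 2 + p.get("c_y", 0.0) ** 2 + p["e_y"] ** 2
    if v_x <= 0 or v_y <= 0:
        raise BivariateFitError("degenerate fit: zero trait variance")
    sx, sy = np.sqrt(v_x), np.sqrt(v_y)
    a_x, e_x = p["a_x"] / sx, p["e_x"] / sx
    a_y, e_y = p["a_y"] / sy, p["e_y"] / sy
    c_x, c_y = p.get("c_x", 0.0) / sx, p.get("c_y", 0.0) / sy
    r_a, r_e, r_c = p["r_a"], p["r_e"], p.get("r_c", 0.0)
    r_p = a_x * a_y * r_a + e_x * e_y * r_e + c_x * c_y * r_c
    genetic_part = a_x * a_y * r_a
    prop = genetic_part / r_p if abs(r_p) > 1e-12 else None
    boundary = bool(max(abs(r_a), abs(r_e)) >= 0.999 - 1e-6)
    n_free = len(names)
    fit = BivariateFit(
        a_x=a_x,
        e_x=e_x,
        a_y=a_y,
        e_y=e_y,
        r_a=r_a,
        r_e=r_e,
        r_p=r_p,
        prop_genetic=prop,
        minus2logl=float(best.fun),
        df=n_values - n_free,
        model=model,
        c_x=c_x,
        c_y=c_y,
        r_c=r_c,
        boundary=boundary,
        n_obs=n_values,
        traits=(trait_x, trait_y),
    )
    if compute_ci:
        fit.ci95 = _wald_ci(objective, best.x, names)
    return fit


def _wald_ci(objective, x_hat: np.ndarray, names: list[str]) -> dict:
    """Wald 95% intervals from a finite-difference Hessian of -2 log L."""
    n = len(x_hat)
    h = 1e-4 * np.maximum(np.abs(x_hat), 1.0)
    hess = np.zeros((n, n))
    f0 = objective(x_hat)
    for i in range(n):
        for j in range(i, n):
            xi, xj = np.zeros(n), np.zeros(n)
            xi[i], xj[j] = h[i], h[j]
            fpp = objective(x_hat + xi + xj)
            fpm = objective(x_hat + xi - xj)
            fmp = objective(x_hat - xi + xj)
            fmm = objective(x_hat - xi - xj)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = 2.0 * np.linalg.inv(hess)  # -2logL curvature -> 2 * H^{-1}
    except np.linalg.LinAlgError:
        logger.warning("singular Hessian; Wald CIs unavailable")
        return {}
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return {nm: (float(x - 1.959964 * s), float(x + 1.959964 * s))
            for nm, x, s in zip(names, x_hat, se)}


def genetic_share(fit: BivariateFit) -> float:
    """Percentage of the phenotypic correlation attributable to genetics.

    ``100 * a_x a_y r_a / r_p``; undefined when the implied phenotypic
    correlation is zero.
    """
    if abs(fit.r_p) < 1e-12:
        raise BivariateFitError("phenotypic correlation is zero; share undefined")
    return 100.0 * (fit.a_x * fit.a_y * fit.r_a) / fit.r_p
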