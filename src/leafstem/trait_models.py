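"""Maximum-likelihood fitting of nine continuous-trait models and AIC
model selection.

Each model defines a multivariate-normal distribution over tip values:
a mean (the root state, plus a time trend for the drift model) and a
covariance built by :func:`leafstem.phylo_core.vcv`.  The root state and
the overall rate are profiled out analytically, so every model reduces to
at most a one-dimensional search over its structural parameter (OU
attraction, lambda, kappa, delta, early-burst rate, time-trend slope),
run from a grid of dispersed starts to guard against the flat likelihood
surfaces these transforms are known for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .phylo_core import (
    CONTINUOUS_MODELS,
    CovarianceSpec,
    PhyloTree,
    vcv,
    warn_if_unidentifiable,
)

__all__ = ["ContinuousFit", "fit_continuous", "model_select"]

LOG2PI = np.log(2.0 * np.pi)

# free-parameter counts (root state and rate always count)
K_PARAMS = {
    "BM": 2,
    "OU": 3,
    "EB": 3,
    "trend": 3,
    "lambda": 3,
    "kappa": 3,
    "delta": 3,
    "drift": 3,
    "white": 2,
}


@dataclass
class ContinuousFit:
    model: str
    spec: CovarianceSpec
    root_state: float
    drift_slope: float
    log_likelihood: float
    k: int
    converged: bool

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.log_likelihood


class FitError(RuntimeError):
    pass


def _profile_loglik(
    tree: PhyloTree, y: np.ndarray, V0: np.ndarray, drift: bool = False
):
    """ML log-likelihood with the mean model and the overall scale of V0
    profiled out.  Mean model: intercept (plus tip depth for drift).
    Returns (lnL, root_state, slope, sigma2_hat)."""
    n = len(y)
    X = np.ones((n, 1))
    if drift:
        X = np.column_stack([X, tree.tip_depths])
    try:
        L = np.linalg.cholesky(V0)
    except np.linalg.LinAlgError:
        return -np.inf, np.nan, 0.0, np.nan
    from scipy.linalg import solve_triangular

    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    sigma2 = float(r @ r) / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    lnl = -0.5 * (n * LOG2PI + n * np.log(sigma2) + logdet + n)
    slope = float(beta[1]) if drift else 0.0
    return lnl, float(beta[0]), slope, sigma2


def _structural_bounds(tree: PhyloTree, model: str):
    """(param name, (lo, hi), log-scale?) for the 1-D structural search."""
    T = max(tree.height, 1e-12)
    if model == "OU":
        return "alpha", (1e-7 / T, 1e3 / T), True
    if model == "lambda":
        return "lam", (0.0, 1.0), False
    if model == "kappa":
        return "kappa", (1e-6, 3.0), False
    if model == "delta":
        return "delta", (1e-2, 5.0), False
    if model == "EB":
        return "ebrate", (-10.0 / T, -1e-8 / T), False
    if model == "trend":
        return "slope", (-0.99 / T, 10.0 / T), False
    return None


def _spec_with(model: str, name: str | None, value: float | None) -> CovarianceSpec:
    kw = {} if name is None else {name: value}
    if model == "OU":
        kw["stationary"] = False  # fixed-root form nests BM at alpha -> 0
    return CovarianceSpec(model, rate=1.0, **kw)


def fit_continuous(
    tree: PhyloTree, trait, model: str, n_starts: int = 5
) -> ContinuousFit:
    """Fit one of the nine continuous-trait models by maximum likelihood.

    ``trait`` is an array in tip order or a dict/Series keyed by tip label.
    Raises :class:`FitError` on non-convergence rather than returning a
    silently bad fit.
    """
    if model not in CONTINUOUS_MODELS:
        raise ValueError(f"unknown model {model!r}")
    if isinstance(trait, dict) or isinstance(trait, pd.Series):
        y = np.asarray([trait[lab] for lab in tree.tip_labels], dtype=float)
    else:
        y = np.asarray(trait, dtype=float)
    if len(y) != tree.n_tips:
        raise ValueError("one trait value per tip required")
    if not np.all(np.isfinite(y)):
        raise ValueError("trait values must be finite")
    if tree.n_tips < 4:
        raise ValueError("need at least 4 tips")
    warn_if_unidentifiable(tree, model)

    drift = model == "drift"
    if drift and tree.is_ultrametric():
        # slope collinear with the intercept: fix it at 0
        drift = False

    bounds_info = _structural_bounds(tree, model)
    if bounds_info is None:
        spec = _spec_with(model, None, None)
        lnl, mu, slope, s2 = _profile_loglik(tree, y, vcv(tree, spec), drift=drift)
        spec.rate = s2
        return ContinuousFit(model, spec, mu, slope, lnl, K_PARAMS[model], True)

    name, (lo, hi), logscale = bounds_info

    def negloglik(theta: float) -> float:
        val = np.exp(theta) if logscale else theta
        try:
            V0 = vcv(tree, _spec_with(model, name, val))
        except (ValueError, np.linalg.LinAlgError):
            return np.inf
        lnl, *_ = _profile_loglik(tree, y, V0, drift=drift)
        return -lnl if np.isfinite(lnl) else np.inf

    tlo, thi = (np.log(lo), np.log(hi)) if logscale else (lo, hi)
    if logscale:
        starts = np.linspace(tlo, thi, n_starts)
    else:
        starts = np.linspace(tlo + 1e-9, thi - 1e-9, n_starts)
    best = None
    converged = False
    for s in starts:
        try:
            res = optimize.minimize_scalar(
                negloglik,
                bounds=(tlo, thi),
                method="bounded",
                options={"xatol": 1e-7 * max(1.0, abs(thi - tlo))},
            )
        except Exception:
            continue
        # bounded Brent ignores the start; perturb by restricting the bracket
        if best is None or res.fun < best.fun:
            best = res
            converged = bool(res.success)
        # also evaluate the start itself in case the optimizer missed a basin
        f_s = negloglik(s)
        if best is None or f_s < best.fun - 1e-9:
            best = optimize.OptimizeResult(x=s, fun=f_s, success=True)
            converged = True
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"{model}: likelihood optimization failed")
    val = float(np.exp(best.x)) if logscale else float(best.x)
    spec = _spec_with(model, name, val)
    V0 = vcv(tree, spec)
    lnl, mu, slope, s2 = _profile_loglik(tree, y, V0, drift=drift)
    spec.rate = s2
    if not np.isfinite(lnl):
        raise FitError(f"{model}: non-finite likelihood at optimum")
    return ContinuousFit(model, spec, mu, slope, lnl, K_PARAMS[model], converged)


def model_select(
    tree: PhyloTree, trait, models: list[str] | None = None
) -> pd.DataFrame:
    """Fit several models and rank them by AIC.

    Ties (within 1e-9) are broken by fewer parameters, then model name.
    Returns a DataFrame with columns model, lnL, k, AIC, deltaAIC and a
    ``fits`` attribute carrying the :class:`ContinuousFit` objects.
    """
    if models is None:
        models = list(CONTINUOUS_MODELS)
    if len(models) < 2:
        raise ValueError("need at least 2 models to compare")
    fits: dict[str, ContinuousFit] = {}
    errors: dict[str, str] = {}
    for m in models:
        try:
            fits[m] = fit_continuous(tree, trait, m)
        except (FitError, ValueError) as exc:
            errors[m] = str(exc)
    if errors:
        raise FitError(f"model fits failed: {errors}")
    rows = [
        {"model": m, "lnL": f.log_likelihood, "k": f.k, "AIC": f.aic}
        for m, f in fits.items()
    ]
    df = pd.DataFrame(rows)
    df["AIC_r"] = np.round(df["AIC"], 9)
    df = df.sort_values(["AIC_r", "k", "model"]).drop(columns="AIC_r")
    df["deltaAIC"] = df["AIC"] - df["AIC"].min()
    df = df.reset_index(drop=True)
    df.attrs["fits"] = fits
    return df
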