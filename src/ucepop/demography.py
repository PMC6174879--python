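"""Demographic inference from the folded joint SFS.

The expected joint SFS under each two-population model is computed by
Monte-Carlo coalescent expectation: genealogies are simulated with the
structured-coalescent kernel and each branch's length is added to the
cell indexed by its numbers of descendant leaves in the two populations.
Under infinite sites the expected number of SNPs in cell (i, j) is
``theta / 2`` times the expected branch length of that class, so the
model spectrum is exact at these sample sizes up to Monte-Carlo error
(this replaces a diffusion-PDE solver; there are no grid-point settings
to tune, and the construction is testable against closed forms such as
E[xi_i] = theta / i for the single-population neutral spectrum).

Fitting maximises the Poisson composite likelihood over unmasked cells,
with the spectrum scale theta profiled out analytically
(theta_hat = sum(data) / sum(model)).  Optimisation is Nelder-Mead in
log-parameter space from multiple perturbed starts, with common random
numbers (one genealogy seed per fit) so the Monte-Carlo likelihood
surface is deterministic within a fit; a fit is declared converged when
the best three starts agree within a likelihood tolerance, mirroring the
repeatability rule of running a model until several runs reach the same
maximum.  Confidence intervals come from delete-m jackknife refits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import gammaln

from .sfs import JointSFS, _corner_mask
from .simulate import MODELS, DemographicParams, expected_branch_table

__all__ = [
    "FREE_PARAMS",
    "DEFAULT_BOUNDS",
    "ExpectedSFS",
    "FitResult",
    "expected_sfs",
    "composite_log_likelihood",
    "fit_model",
    "compare_models",
    "jackknife_ci",
]

#: free parameters per model, in optimisation order
FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "neutral": (),
    "split_mig": ("nu1", "nu2", "T", "m"),
    "split_nomig": ("nu1", "nu2", "T"),
    "split_asym_mig": ("nu1", "nu2", "T", "m12", "m21"),
    "im": ("s", "nu1", "nu2", "T", "m12", "m21"),
    "im_nomig": ("s", "nu1", "nu2", "T"),
}

#: default box bounds (natural scale); optimisation runs on log10(p)
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "nu1": (1e-2, 1e2),
    "nu2": (1e-2, 1e2),
    "T": (1e-2, 10.0),
    "m": (1e-3, 20.0),
    "m12": (1e-3, 20.0),
    "m21": (1e-3, 20.0),
    "s": (0.01, 0.99),
}


def _vector_to_params(model: str, x: np.ndarray) -> DemographicParams:
    names = FREE_PARAMS[model]
    kv = dict(zip(names, (float(v) for v in x)))
    if "m" in kv:
        kv["m12"] = kv["m21"] = kv.pop("m")
    return DemographicParams(**kv)


def _params_to_vector(model: str, params: DemographicParams) -> np.ndarray:
    out = []
    for name in FREE_PARAMS[model]:
        out.append(params.m12 if name == "m" else getattr(params, name))
    return np.asarray(out, dtype=float)


@dataclass
class ExpectedSFS:
    """Folded expected SFS per unit theta (Monte-Carlo estimate)."""

    sfs: JointSFS
    model: str
    params: DemographicParams
    n_genealogies: int
    seed: int


def expected_sfs(
    model: str,
    params: DemographicParams,
    n1: int,
    n2: int,
    n_genealogies: int = 20000,
    seed: int = 0,
    folded: bool = True,
) -> ExpectedSFS:
    """Monte-Carlo expected joint SFS per unit theta (mass in cell (i, j)
    for a spectrum of scale theta is ``theta *`` this table's cell)."""
    if n_genealogies < 1000:
        raise ValueError("n_genealogies must be >= 1000 for a usable estimate")
    table = expected_branch_table(model, params, n1, n2, n_genealogies, seed) / 2.0
    raw = JointSFS(table, _corner_mask(n1, n2), False, n1, n2)
    return ExpectedSFS(
        sfs=raw.fold() if folded else raw,
        model=model,
        params=params,
        n_genealogies=n_genealogies,
        seed=seed,
    )


def composite_log_likelihood(
    data: JointSFS,
    model: JointSFS | ExpectedSFS,
    eps: float = 1e-12,
) -> tuple[float, float]:
    """Poisson composite log-likelihood and the profiled scale theta_hat.

    theta_hat = sum(data)/sum(model) over unmasked cells is the Poisson
    maximum-likelihood scaling; model cells equal to zero where data is
    positive are floored at ``eps``.
    """
    msfs = model.sfs if isinstance(model, ExpectedSFS) else model
    if msfs.data.shape != data.data.shape:
        raise ValueError("data and model dimensions differ")
    keep = ~(data.mask | msfs.mask)
    d = data.data[keep]
    m = np.maximum(msfs.data[keep], eps)
    if m.sum() <= 0:
        raise ValueError("model spectrum has no mass")
    theta = float(d.sum() / m.sum())
    lam = theta * m
    ll = float(np.sum(d * np.log(lam) - lam - gammaln(d + 1)))
    return ll, theta


@dataclass
class FitResult:
    model: str
    params: DemographicParams
    theta: float
    loglik: float
    start_logliks: list[float] = field(default_factory=list)
    converged: bool = False
    n_genealogies: int = 0
    seed: int = 0
    at_bound: list[str] = field(default_factory=list)

    def param_dict(self) -> dict[str, float]:
        out = {
            name: (self.params.m12 if name == "m" else getattr(self.params, name))
            for name in FREE_PARAMS[self.model]
        }
        out["theta"] = self.theta
        return out


def fit_model(
    data: JointSFS,
    model: str,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 3,
    n_genealogies: int = 20000,
    seed: int = 0,
    init: DemographicParams | None = None,
    ll_tol: float = 0.5,
    maxiter: int | None = None,
) -> FitResult:
    """Maximise the composite likelihood of ``data`` under ``model``.

    Nelder-Mead on log10 parameters from ``n_starts`` perturbed starts;
    out-of-bounds proposals are penalised quadratically.  ``init`` seeds
    the first start (defaults to the geometric midpoint of the bounds).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    names = FREE_PARAMS[model]
    bnds = dict(DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)
    for name in names:
        lo, hi = bnds[name]
        if not (0 < lo < hi and np.isfinite(hi)):
            raise ValueError(f"bounds for {name} must be positive and finite")
    n1, n2 = data.n1, data.n2
    gen_seed = seed % 2**31

    def model_sfs(params: DemographicParams) -> ExpectedSFS:
        return expected_sfs(model, params, n1, n2, n_genealogies, gen_seed, folded=data.folded)

    if not names:  # the neutral model has no free demographic parameters
        params = DemographicParams()
        ll, theta = composite_log_likelihood(data, model_sfs(params))
        return FitResult(model, params, theta, ll, [ll], True, n_genealogies, seed)

    lo = np.log10([bnds[n][0] for n in names])
    hi = np.log10([bnds[n][1] for n in names])

    def objective(x: np.ndarray) -> float:
        over = np.maximum(x - hi, 0.0) + np.maximum(lo - x, 0.0)
        xc = np.clip(x, lo, hi)
        ll, _ = composite_log_likelihood(data, model_sfs(_vector_to_params(model, 10.0**xc)))
        return -ll + 1e4 * float(np.sum(over**2))

    x0 = (
        np.log10(_params_to_vector(model, init))
        if init is not None
        else (lo + hi) / 2.0
    )
    x0 = np.clip(x0, lo, hi)
    rng = np.random.default_rng(seed)
    results = []
    for start in range(n_starts):
        xs = x0 if start == 0 else np.clip(x0 + rng.normal(0.0, 0.3, size=len(x0)), lo, hi)
        # explicit initial simplex: scipy's default degenerates for
        # coordinates near 0, which log10 parameters near 1 sit at
        simplex = np.vstack([xs, xs + 0.25 * np.eye(len(xs))])
        res = minimize(
            objective,
            xs,
            method="Nelder-Mead",
            options={
                "xatol": 1e-3,
                "fatol": 1e-3,
                "initial_simplex": simplex,
                "maxiter": maxiter if maxiter is not None else 200 * len(x0),
            },
        )
        results.append((float(-res.fun), np.clip(res.x, lo, hi)))
    results.sort(key=lambda t: -t[0])
    start_lls = [r[0] for r in results]
    best_ll, best_x = results[0]
    params = _vector_to_params(model, 10.0**best_x)
    _, theta = composite_log_likelihood(data, model_sfs(params))
    if len(results) >= 3:
        converged = (start_lls[0] - start_lls[2]) <= ll_tol
    else:
        converged = True
    at_bound = [
        n
        for n, xv, l, h in zip(names, best_x, lo, hi)
        if xv <= l + 1e-6 or xv >= h - 1e-6
    ]
    return FitResult(
        model, params, theta, best_ll, start_lls, converged, n_genealogies, seed, at_bound
    )


def compare_models(
    data: JointSFS,
    models: list[str] | tuple[str, ...] = MODELS,
    **fit_kwargs,
) -> tuple[pd.DataFrame, dict[str, FitResult]]:
    """Fit each model and rank by maximum log composite likelihood.

    For a model whose starts did not agree (unstable), the reported
    likelihood is the mean of its top five start likelihoods, following
    the averaging rule used for unstable models.
    """
    fits = {m: fit_model(data, m, **fit_kwargs) for m in models}
    rows = []
    for m, fit in fits.items():
        if fit.converged:
            reported = fit.loglik
        else:
            top5 = sorted(fit.start_logliks, reverse=True)[:5]
            reported = float(np.mean(top5))
        rows.append(
            {
                "model": m,
                "loglik": fit.loglik,
                "loglik_reported": reported,
                "theta": fit.theta,
                "converged": fit.converged,
                "n_free_params": len(FREE_PARAMS[m]),
            }
        )
    table = (
        pd.DataFrame(rows).sort_values("loglik_reported", ascending=False).reset_index(drop=True)
    )
    return table, fits


def delete_m_se(estimates: np.ndarray | list[float]) -> float:
    """Delete-m (grouped) jackknife standard error over g block-deletion
    estimates: sqrt((g - 1)/g * sum((est_j - mean)^2))."""
    vals = np.asarray(estimates, dtype=float)
    g = len(vals)
    if g < 2:
        raise ValueError("need at least two estimates")
    return float(np.sqrt((g - 1) / g * np.sum((vals - vals.mean()) ** 2)))


def jackknife_ci(
    replicates: list[JointSFS],
    model: str,
    full_fit: FitResult,
    n_genealogies: int | None = None,
    seed: int | None = None,
    z: float = 1.96,
    **fit_kwargs,
) -> pd.DataFrame:
    """Delete-m jackknife confidence intervals.

    Each replicate is refitted from the full-data optimum (single start)
    with a common genealogy seed, so estimate spread reflects data
    variation only, not Monte-Carlo noise (identical replicates give
    exactly zero SE); the SE over g block-deletion estimates is
    ``sqrt((g - 1)/g * sum((est_j - mean)^2))`` and the CI is the full
    estimate +/- ``z`` SE.  Non-convergent replicate fits are excluded
    and counted.
    """
    if len(replicates) < 2:
        raise ValueError("need at least two jackknife replicates")
    n_gen = n_genealogies if n_genealogies is not None else full_fit.n_genealogies
    base_seed = seed if seed is not None else full_fit.seed
    ests: list[dict[str, float]] = []
    n_failed = 0
    for r, rep in enumerate(replicates):
        fit = fit_model(
            rep,
            model,
            n_starts=1,
            n_genealogies=n_gen,
            seed=base_seed,
            init=full_fit.params,
            **fit_kwargs,
        )
        if not np.isfinite(fit.loglik):
            n_failed += 1
            continue
        ests.append(fit.param_dict())
    if len(ests) < 2:
        raise RuntimeError("too few convergent jackknife refits")
    g = len(ests)
    rows = []
    full = full_fit.param_dict()
    for name in full:
        vals = np.array([e[name] for e in ests])
        se = delete_m_se(vals)
        rows.append(
            {
                "parameter": name,
                "estimate": full[name],
                "se": se,
                "ci_lower": full[name] - z * se,
                "ci_upper": full[name] + z * se,
                "n_replicates": g,
                "n_failed": n_failed,
            }
        )
    return pd.DataFrame(rows)
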