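"""Posterior summaries in the conventions used for reporting: posterior mean
and SD, 93% credible intervals (3.5th/96.5th percentiles, linear-interpolation
quantiles), tail and interval probabilities, derived coefficients by
elementwise addition of draws, and MCMC diagnostics (rank-normalized split
R-hat and bulk ESS via ArviZ; the classic Gelman-Rubin form is available)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelSpec, PosteriorSamples


@dataclass(frozen=True)
class ParameterSummary:
    mean: float
    sd: float
    ci93_low: float
    ci93_high: float
    ess: float
    rhat: float


def _require_chain_shape(draws: np.ndarray) -> np.ndarray:
    d = np.asarray(draws, dtype=float)
    if d.ndim != 2:
        raise ValueError("draws must be (chains, iterations)")
    if d.shape[0] < 2 or d.shape[1] < 4:
        raise ValueError("diagnostics need >= 2 chains and >= 4 draws per chain")
    return d


def classic_rhat(draws: np.ndarray) -> float:
    """Original Gelman-Rubin potential scale reduction (no rank normalization)."""
    d = _require_chain_shape(draws)
    m, n = d.shape
    chain_means = d.mean(axis=1)
    B = n * chain_means.var(ddof=1)
    W = d.var(axis=1, ddof=1).mean()
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def summarize(draws: np.ndarray, ci: float = 0.93, classic: bool = False) -> ParameterSummary:
    """Summary of one parameter from (chains, iterations) draws.

    Moments and quantiles pool all chains; R-hat/ESS use the chain structure.
    """
    d = _require_chain_shape(draws)
    pooled = d.reshape(-1)
    lo, hi = (1 - ci) / 2, 1 - (1 - ci) / 2
    import arviz as az

    if classic:
        rhat = classic_rhat(d)
    elif np.ptp(pooled) == 0:
        rhat = 1.0
    else:
        rhat = float(az.rhat(d))
    ess = float(az.ess(d)) if np.ptp(pooled) > 0 else float(pooled.size)
    return ParameterSummary(
        mean=float(pooled.mean()),
        sd=float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
        ci93_low=float(np.quantile(pooled, lo)),
        ci93_high=float(np.quantile(pooled, hi)),
        ess=ess,
        rhat=rhat,
    )


def tail_probability(draws, threshold: float, direction: str) -> float:
    """Fraction of pooled draws strictly below/above a threshold."""
    d = np.asarray(draws, dtype=float).reshape(-1)
    if d.size == 0:
        raise ValueError("empty draws")
    if direction == "below":
        return float(np.mean(d < threshold))
    if direction == "above":
        return float(np.mean(d > threshold))
    raise ValueError("direction must be 'below' or 'above'")


def interval_probability(draws, low: float, high: float) -> float:
    """Fraction of pooled draws in the closed interval [low, high]."""
    if low >= high:
        raise ValueError("low must be < high")
    d = np.asarray(draws, dtype=float).reshape(-1)
    return float(np.mean((d >= low) & (d <= high)))


def combine_coefficients(posterior: PosteriorSamples, parameter_names: list[str]) -> np.ndarray:
    """Elementwise sum of named coefficient draws, keeping chain structure.

    Used e.g. for the total maternal effect = main effect + gender interaction.
    """
    if not parameter_names:
        raise ValueError("no parameter names given")
    arrs = []
    for name in parameter_names:
        if name not in posterior.coef_names:
            raise KeyError(f"coefficient {name!r} not in model")
        k = posterior.coef_names.index(name)
        arrs.append(posterior.draws["b"][:, :, k])
    return np.sum(arrs, axis=0)


_LABELS = {
    "intercept": "Intercept",
    "agency": "Agency",
    "communion": "Communion",
    "elevation": "Elevation",
    "depression": "Depressive symptoms",
    "mother": "Mother",
    "depression_x_mother": "Depressive symptoms x mother",
    "agency_x_mother": "Agency x mother",
    "communion_x_mother": "Communion x mother",
    "elevation_x_mother": "Elevation x mother",
    "age": "Adolescent age",
}


def report(posterior: PosteriorSamples, spec: ModelSpec | None = None,
           ci: float = 0.93, classic: bool = False) -> pd.DataFrame:
    """Regression-parameter table: one row per reported parameter.

    Coefficients (and intercept if present), error variance sigma^2, random
    -effect variance tau^2, and the t-likelihood degrees of freedom, each with
    Mean, SD, 93% CI, ESS and R-hat.  Dummy-coded models additionally get the
    derived total-mother coefficient rows (main effect + interaction).
    """
    spec = spec or posterior.spec
    rows: dict[str, np.ndarray] = {}
    for k, name in enumerate(posterior.coef_names):
        rows[_LABELS.get(name, name)] = posterior.draws["b"][:, :, k]
    for name in posterior.coef_names:
        if name.endswith("_x_mother"):
            base = name[: -len("_x_mother")]
            if base in posterior.coef_names:
                label = f"{_LABELS.get(base, base)} total for mothers"
                rows[label] = combine_coefficients(posterior, [base, name])
    if "sigma" in posterior.draws:
        rows["Variance of errors"] = posterior.draws["sigma"] ** 2
    if "tau" in posterior.draws:
        rows["Variance of random effects"] = posterior.draws["tau"] ** 2
    if "nu" in posterior.draws:
        rows["Degrees of freedom in t-likelihood"] = posterior.draws["nu"]

    records = []
    for label, d in rows.items():
        if np.ndim(d) == 0 or d.ndim != 2:  # fixed (non-sampled) quantity
            continue
        s = summarize(d, ci=ci, classic=classic)
        records.append(
            {
                "parameter": label,
                "mean": s.mean,
                "sd": s.sd,
                "ci93_low": s.ci93_low,
                "ci93_high": s.ci93_high,
                "ess": s.ess,
                "rhat": s.rhat,
            }
        )
    return pd.DataFrame(records).set_index("parameter")
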