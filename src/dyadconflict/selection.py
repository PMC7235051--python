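"""Exact leave-one-family-out cross-validation, ELPD comparison, stacking.

The cluster is the family (the adolescent and all their parent dyads).  For
every candidate model and every family the model is refit on all other
families; the held-out family's log predictive density is the log of the
mean over posterior draws of its per-draw item likelihood, with the new
family's random intercept at its prior mean.  The pointwise matrix feeds
both the pairwise ELPD comparison (differences to the best model with
standard errors) and stacking: simplex weights maximizing the summed
leave-one-out log score of the weighted predictive mixture.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .model import (
    ModelOptions,
    ModelSpec,
    PredictorMatrix,
    PriorSpec,
    SamplerConfig,
    fit_joint,
    loglik_family,
)


@dataclass
class LooResult:
    pointwise_lpd: np.ndarray  # (families, models)
    family_ids: list[str]
    model_ids: list[str]
    manifests: list[dict] = field(default_factory=list)
    comparable: bool = True

    @property
    def elpd(self) -> np.ndarray:
        return self.pointwise_lpd.sum(axis=0)


@dataclass
class ComparisonTable:
    table: pd.DataFrame  # index model_id; columns elpd, difference, se_difference

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.table.to_string()


@dataclass
class StackingWeights:
    weights: np.ndarray
    model_ids: list[str]
    objective: float  # achieved summed log score


def _subset_matrix(matrix: PredictorMatrix, keep: np.ndarray) -> PredictorMatrix:
    fam_ids = [f for f, k in zip(matrix.family_ids, keep) if k]
    families = sorted(set(fam_ids), key=fam_ids.index)
    lookup = {f: i for i, f in enumerate(families)}
    return PredictorMatrix(
        x=matrix.x[keep],
        mother=matrix.mother[keep],
        age_centered=matrix.age_centered[keep],
        family_ids=fam_ids,
        parent_ids=[p for p, k in zip(matrix.parent_ids, keep) if k],
        families=families,
        family_index=np.asarray([lookup[f] for f in fam_ids], dtype=int),
    )


def refit_seed(master_seed: int, model_id: str, family_id: str) -> int:
    """Deterministic per-refit seed: master seed hashed with (model, family)."""
    h = zlib.crc32(f"{model_id}|{family_id}".encode())
    ss = np.random.SeedSequence(entropy=[int(master_seed) & 0x7FFFFFFF, h])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def exact_loo(
    specs: list[ModelSpec],
    matrix: PredictorMatrix,
    y_items: np.ndarray,
    sampler: SamplerConfig,
    priors: PriorSpec = PriorSpec(),
    options: ModelOptions = ModelOptions(),
    rhat_fail: float = 1.2,
    integrate_intercept_draws: int = 0,
    plugin_posterior_mean: bool = False,
) -> LooResult:
    """Exact leave-one-family-out CV over the candidate models.

    Runs families x models refits, each seeded from the master seed and the
    (model, family) pair.  A refit whose regression parameters exceed an
    R-hat of ``rhat_fail`` is flagged as failed and the result is marked
    non-comparable; milder diagnostics are recorded in the manifests.
    """
    families = matrix.families
    if len(families) < 3:
        raise ValueError("exact leave-one-family-out needs at least 3 families")
    y = np.asarray(y_items, dtype=float)
    fam_arr = np.asarray(matrix.family_ids)
    manifests: list[dict] = []
    comparable = True

    # a family with no observed outcome data carries no predictive
    # information; it stays in every training set but is not scored
    eval_families = []
    for fam in families:
        if np.any(~np.isnan(y[fam_arr == fam])):
            eval_families.append(fam)
        else:
            manifests.append({"family": fam, "skipped": True,
                              "reason": "no observed outcome data"})
    pointwise = np.empty((len(eval_families), len(specs)))

    for k, spec in enumerate(specs):
        for i, fam in enumerate(eval_families):
            held = fam_arr == fam
            keep = ~held
            sub = _subset_matrix(matrix, keep)
            seed = refit_seed(sampler.seed, spec.model_id, fam)
            cfg = SamplerConfig(
                chains=sampler.chains,
                warmup_iterations=sampler.warmup_iterations,
                sampling_iterations=sampler.sampling_iterations,
                seed=seed,
                target_acceptance=sampler.target_acceptance,
                max_treedepth=sampler.max_treedepth,
            )
            ykw = {"y_items": y[keep]} if options.latent_outcome else {"y_cont": y[keep]}
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                post = fit_joint(
                    spec,
                    sub,
                    priors=priors,
                    options=options,
                    sampler=cfg,
                    rhat_threshold=rhat_fail,
                    ess_threshold=0.0,
                    **ykw,
                )
            issues = post.diagnostics.get("convergence_issues", [])
            failed = bool(issues)
            comparable = comparable and not failed
            manifests.append(
                {
                    "model": spec.model_id,
                    "family": fam,
                    "seed": seed,
                    "n_train_dyads": int(keep.sum()),
                    "divergences": int(sum(post.diagnostics["divergences"])),
                    "failed": failed,
                    "issues": issues,
                }
            )
            ll = loglik_family(
                post,
                spec,
                matrix.x[held],
                matrix.mother[held],
                matrix.age_centered[held],
                y[held],
                integrate_intercept_draws=integrate_intercept_draws,
                plugin_posterior_mean=plugin_posterior_mean,
                seed=seed,
            )
            pointwise[i, k] = float(logsumexp(ll) - np.log(ll.shape[0]))

    return LooResult(
        pointwise_lpd=pointwise,
        family_ids=list(eval_families),
        model_ids=[s.model_id for s in specs],
        manifests=manifests,
        comparable=comparable,
    )


def compare(loo: LooResult, allow_failed: bool = False) -> ComparisonTable:
    """ELPD comparison: differences to the best model and their SEs.

    SE of a difference is sqrt(F * Var(pointwise differences)), the standard
    cluster-count-scaled standard error; the best model's own SE is 0.
    """
    if not loo.comparable and not allow_failed:
        raise ValueError("LOO result contains failed refits; not comparable")
    if len(loo.model_ids) < 2:
        raise ValueError("need at least 2 models to compare")
    elpd = loo.elpd
    order = np.argsort(-elpd, kind="stable")
    best = order[0]
    F = loo.pointwise_lpd.shape[0]
    rows = []
    for k in order:
        diff_pw = loo.pointwise_lpd[:, best] - loo.pointwise_lpd[:, k]
        se = 0.0 if k == best else float(np.sqrt(F * diff_pw.var(ddof=1)))
        rows.append(
            {
                "model": loo.model_ids[k],
                "elpd": float(elpd[k]),
                "difference": float(elpd[best] - elpd[k]),
                "se_difference": se,
            }
        )
    return ComparisonTable(pd.DataFrame(rows).set_index("model"))


def _stack_objective(pointwise_lpd: np.ndarray, w: np.ndarray) -> float:
    shifted = pointwise_lpd + np.log(np.maximum(w, 1e-300))[None, :]
    return float(logsumexp(shifted, axis=1).sum())


def stacking(pointwise_lpd: np.ndarray, model_ids: list[str] | None = None,
             tol: float = 1e-12) -> StackingWeights:
    """Stacking weights: maximize sum_i log sum_k w_k exp(lpd_ik) on the simplex.

    The objective is concave in w; solved by SLSQP from the uniform start
    (so exact ties stay at the uniform split on the tied set).
    """
    lpd = np.asarray(pointwise_lpd, dtype=float)
    if lpd.ndim != 2:
        raise ValueError("pointwise_lpd must be (families, models)")
    F, K = lpd.shape
    if model_ids is None:
        model_ids = [f"model_{k}" for k in range(K)]
    if np.any(~np.isfinite(lpd.max(axis=1))):
        raise ValueError("a family has -inf density under every model")
    bad = np.all(~np.isfinite(lpd), axis=0)
    if np.any(bad):
        raise ValueError("a model has -inf density for every family")
    if K == 1:
        return StackingWeights(np.array([1.0]), list(model_ids), _stack_objective(lpd, np.ones(1)))

    # stabilize rows
    row_max = lpd.max(axis=1, keepdims=True)
    P = np.exp(lpd - row_max)  # (F, K), max 1 per row

    def neg_obj(w):
        mix = P @ w
        return -float(np.sum(np.log(np.maximum(mix, 1e-300))))

    def neg_grad(w):
        mix = np.maximum(P @ w, 1e-300)
        return -(P / mix[:, None]).sum(axis=0)

    w0 = np.full(K, 1.0 / K)
    res = minimize(
        neg_obj,
        w0,
        jac=neg_grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * K,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones_like(w)}],
        options={"maxiter": 1000, "ftol": tol},
    )
    w = np.clip(res.x, 0.0, None)
    w /= w.sum()
    # polish: a vertex must never beat the stack (concavity guarantees the
    # optimum dominates; guard against solver early stopping)
    obj = _stack_objective(lpd, w)
    for k in range(K):
        e = np.zeros(K)
        e[k] = 1.0
        if _stack_objective(lpd, e) > obj:
            w, obj = e, _stack_objective(lpd, e)
    return StackingWeights(w, list(model_ids), obj)
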