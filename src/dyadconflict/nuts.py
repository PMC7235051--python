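"""No-U-Turn sampler (NUTS) over a differentiable log posterior.

A compact Hamiltonian Monte Carlo engine: multinomial NUTS with slice-free
subtree sampling, dual-averaging step-size adaptation, and windowed diagonal
mass-matrix (metric) adaptation.  The target is supplied as a callable
``logp_grad(x) -> (float, ndarray)`` on an unconstrained parameter vector;
constraint transforms and their Jacobians are the model's responsibility.

The implementation follows the standard algorithm: trajectories are doubled
until a U-turn or divergence, the next state is drawn from the trajectory
with weights proportional to exp(-H), and divergences are flagged when the
Hamiltonian error exceeds 1000.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = ["NutsResult", "sample_nuts"]

_DIVERGENCE_THRESHOLD = 1000.0


@dataclass
class NutsResult:
    draws: np.ndarray  # (n_draws, dim), post-warmup
    logp: np.ndarray  # (n_draws,)
    step_size: float
    inv_metric: np.ndarray  # diagonal of M^{-1}
    n_divergent: int  # sampling phase only
    n_divergent_warmup: int
    mean_accept: float
    max_treedepth_hits: int


class _Tree:
    __slots__ = (
        "x_minus", "p_minus", "v_minus", "g_minus",
        "x_plus", "p_plus", "v_plus", "g_plus",
        "x_prop", "logp_prop", "log_sum_w", "sum_alpha", "n_alpha",
        "diverged", "turning",
    )


def _leapfrog(logp_grad, x, p, g, eps, inv_metric):
    """One leapfrog step; also returns the velocity v = M^{-1} p_new."""
    p_half = p + 0.5 * eps * g
    x_new = x + eps * inv_metric * p_half
    logp_new, g_new = logp_grad(x_new)
    p_new = p_half + 0.5 * eps * g_new
    return x_new, p_new, inv_metric * p_new, g_new, logp_new


def _build_tree(logp_grad, x, p, v, g, direction, depth, eps, h0, inv_metric, rng):
    tree = _Tree()
    if depth == 0:
        x1, p1, v1, g1, logp1 = _leapfrog(logp_grad, x, p, g, direction * eps, inv_metric)
        h1 = -logp1 + 0.5 * float(p1 @ v1) if np.isfinite(logp1) else np.inf
        delta = h0 - h1  # log weight relative to start
        tree.diverged = not np.isfinite(h1) or (h1 - h0) > _DIVERGENCE_THRESHOLD
        tree.turning = False
        tree.x_minus = tree.x_plus = x1
        tree.p_minus = tree.p_plus = p1
        tree.v_minus = tree.v_plus = v1
        tree.g_minus = tree.g_plus = g1
        tree.x_prop, tree.logp_prop = x1, logp1
        tree.log_sum_w = delta if not tree.diverged else -np.inf
        tree.sum_alpha = min(1.0, float(np.exp(min(delta, 0.0)))) if np.isfinite(delta) else 0.0
        tree.n_alpha = 1
        return tree

    first = _build_tree(logp_grad, x, p, v, g, direction, depth - 1, eps, h0, inv_metric, rng)
    if first.diverged or first.turning:
        return first
    if direction == 1:
        edge = (first.x_plus, first.p_plus, first.v_plus, first.g_plus)
    else:
        edge = (first.x_minus, first.p_minus, first.v_minus, first.g_minus)
    second = _build_tree(
        logp_grad, edge[0], edge[1], edge[2], edge[3], direction, depth - 1, eps, h0,
        inv_metric, rng,
    )

    tree = _Tree()
    tree.diverged = second.diverged
    if direction == 1:
        tree.x_minus, tree.p_minus, tree.v_minus, tree.g_minus = (
            first.x_minus, first.p_minus, first.v_minus, first.g_minus)
        tree.x_plus, tree.p_plus, tree.v_plus, tree.g_plus = (
            second.x_plus, second.p_plus, second.v_plus, second.g_plus)
    else:
        tree.x_minus, tree.p_minus, tree.v_minus, tree.g_minus = (
            second.x_minus, second.p_minus, second.v_minus, second.g_minus)
        tree.x_plus, tree.p_plus, tree.v_plus, tree.g_plus = (
            first.x_plus, first.p_plus, first.v_plus, first.g_plus)
    tree.log_sum_w = np.logaddexp(first.log_sum_w, second.log_sum_w)
    # multinomial sampling between the two halves
    if np.isfinite(second.log_sum_w) and np.log(rng.random()) < second.log_sum_w - tree.log_sum_w:
        tree.x_prop, tree.logp_prop = second.x_prop, second.logp_prop
    else:
        tree.x_prop, tree.logp_prop = first.x_prop, first.logp_prop
    tree.sum_alpha = first.sum_alpha + second.sum_alpha
    tree.n_alpha = first.n_alpha + second.n_alpha
    if second.turning:
        tree.turning = True
    else:
        dx = tree.x_plus - tree.x_minus
        tree.turning = float(dx @ tree.v_minus) < 0.0 or float(dx @ tree.v_plus) < 0.0
    return tree


def _nuts_step(logp_grad, x, logp, g, eps, inv_metric, max_treedepth, rng):
    dim = x.shape[0]
    p0 = rng.standard_normal(dim) / np.sqrt(inv_metric)
    v0 = inv_metric * p0
    h0 = -logp + 0.5 * float(p0 @ v0)

    x_minus = x_plus = x
    p_minus = p_plus = p0
    v_minus = v_plus = v0
    g_minus = g_plus = g
    x_cur, logp_cur, g_cur = x, logp, g
    log_sum_w = 0.0  # weight of the initial point relative to itself
    sum_alpha, n_alpha = 0.0, 0
    n_div = 0
    depth = 0
    hit_max = False

    while depth < max_treedepth:
        direction = 1 if rng.random() < 0.5 else -1
        if direction == 1:
            subtree = _build_tree(
                logp_grad, x_plus, p_plus, v_plus, g_plus, 1, depth, eps, h0, inv_metric, rng
            )
            if not (subtree.diverged or subtree.turning):
                x_plus, p_plus, v_plus, g_plus = (
                    subtree.x_plus, subtree.p_plus, subtree.v_plus, subtree.g_plus)
        else:
            subtree = _build_tree(
                logp_grad, x_minus, p_minus, v_minus, g_minus, -1, depth, eps, h0, inv_metric, rng
            )
            if not (subtree.diverged or subtree.turning):
                x_minus, p_minus, v_minus, g_minus = (
                    subtree.x_minus, subtree.p_minus, subtree.v_minus, subtree.g_minus)
        sum_alpha += subtree.sum_alpha
        n_alpha += subtree.n_alpha
        if subtree.diverged:
            n_div = 1
            break
        if subtree.turning:
            break
        # biased progressive sampling toward the new subtree
        if np.log(rng.random()) < subtree.log_sum_w - log_sum_w:
            x_cur, logp_cur = subtree.x_prop, subtree.logp_prop
        log_sum_w = np.logaddexp(log_sum_w, subtree.log_sum_w)
        dx = x_plus - x_minus
        if float(dx @ v_minus) < 0.0 or float(dx @ v_plus) < 0.0:
            break
        depth += 1
    else:
        hit_max = True

    # gradient at the accepted point (recompute only if moved)
    if x_cur is not x:
        _, g_cur = logp_grad(x_cur)
    accept_stat = sum_alpha / max(n_alpha, 1)
    return x_cur, logp_cur, g_cur, accept_stat, n_div, hit_max


def _find_initial_step_size(logp_grad, x, logp, g, inv_metric, rng) -> float:
    eps = 1.0
    p0 = rng.standard_normal(x.shape[0]) / np.sqrt(inv_metric)
    h0 = -logp + 0.5 * float(p0 @ (inv_metric * p0))

    def _h(eps):
        _, p1, v1, _, logp1 = _leapfrog(logp_grad, x, p0, g, eps, inv_metric)
        return -logp1 + 0.5 * float(p1 @ v1) if np.isfinite(logp1) else np.inf

    delta = h0 - _h(eps)
    direction = 1.0 if delta > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        delta = h0 - _h(eps)
        if direction == 1.0 and not delta > np.log(0.5):
            break
        if direction == -1.0 and not delta < np.log(0.5):
            break
    return eps


def _adaptation_windows(n_warmup: int) -> list[tuple[int, int]]:
    """Metric-estimation windows (start, end) within warmup, Stan-style."""
    if n_warmup < 60:
        return [(int(n_warmup * 0.2), int(n_warmup * 0.9))]
    init_buffer = min(75, int(0.15 * n_warmup))
    term_buffer = min(50, int(0.10 * n_warmup))
    windows = []
    start = init_buffer
    size = 25 if n_warmup >= 150 else max(10, (n_warmup - init_buffer - term_buffer) // 4)
    while start + size < n_warmup - term_buffer:
        end = start + size
        if end + 2 * size >= n_warmup - term_buffer:
            end = n_warmup - term_buffer
        windows.append((start, end))
        start = end
        size *= 2
    if not windows:
        windows = [(init_buffer, n_warmup - term_buffer)]
    return windows


def sample_nuts(
    logp_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    seed: int,
    target_accept: float = 0.85,
    max_treedepth: int = 10,
) -> NutsResult:
    """Run one NUTS chain; returns post-warmup draws and sampler diagnostics."""
    rng = np.random.default_rng(seed)
    x = np.asarray(x0, dtype=float).copy()
    dim = x.shape[0]
    logp, g = logp_grad(x)
    if not np.isfinite(logp):
        raise ValueError("log posterior is not finite at the initial point")

    inv_metric = np.ones(dim)
    eps = _find_initial_step_size(logp_grad, x, logp, g, inv_metric, rng)

    # dual averaging state (da_m restarts whenever the metric changes)
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = np.log(eps), 0.0
    da_m = 0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    windows = _adaptation_windows(n_warmup)
    window_idx = 0
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    n_div_warmup = 0
    n_div_total = 0
    max_hits = 0

    for i in range(n_warmup):
        x, logp, g, accept, n_div, hit = _nuts_step(
            logp_grad, x, logp, g, eps, inv_metric, max_treedepth, rng
        )
        n_div_warmup += n_div
        max_hits += hit
        # dual averaging update
        da_m += 1
        h_bar = (1 - 1 / (da_m + t0)) * h_bar + (target_accept - accept) / (da_m + t0)
        log_eps = mu - np.sqrt(da_m) / gamma * h_bar
        w = da_m ** (-kappa)
        log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
        eps = float(np.exp(log_eps))

        if window_idx < len(windows):
            start, end = windows[window_idx]
            if start <= i < end:
                welford_n += 1
                delta = x - welford_mean
                welford_mean += delta / welford_n
                welford_m2 += delta * (x - welford_mean)
            if i == end - 1 and welford_n > 1:
                var = welford_m2 / (welford_n - 1)
                # regularize toward unit metric as Stan does
                var = (welford_n / (welford_n + 5.0)) * var + 1e-3 * (5.0 / (welford_n + 5.0))
                inv_metric = np.maximum(var, 1e-10)
                welford_n = 0
                welford_mean[:] = 0.0
                welford_m2[:] = 0.0
                window_idx += 1
                # re-tune step size for the new metric
                eps = _find_initial_step_size(logp_grad, x, logp, g, inv_metric, rng)
                mu = np.log(10.0 * eps)
                log_eps_bar, h_bar = np.log(eps), 0.0
                da_m = 0

    eps = float(np.exp(log_eps_bar)) if n_warmup > 0 else eps

    draws = np.empty((n_draws, dim))
    logps = np.empty(n_draws)
    accept_sum = 0.0
    for j in range(n_draws):
        x, logp, g, accept, n_div, hit = _nuts_step(
            logp_grad, x, logp, g, eps, inv_metric, max_treedepth, rng
        )
        n_div_total += n_div
        max_hits += hit
        accept_sum += accept
        draws[j] = x
        logps[j] = logp

    return NutsResult(
        draws=draws,
        logp=logps,
        step_size=eps,
        inv_metric=inv_metric,
        n_divergent=n_div_total,
        n_divergent_warmup=n_div_warmup,
        mean_accept=accept_sum / max(n_draws, 1),
        max_treedepth_hits=max_hits,
    )
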