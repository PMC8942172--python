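"""No-U-Turn sampler with dual-averaging step-size and diagonal mass adaptation.

A self-contained gradient-based MCMC engine: multinomial NUTS (progressive
sampling over the doubling trajectory, biased toward the new subtree) with
a diagonal Euclidean metric adapted over an expanding-window warmup schedule
and step size tuned by dual averaging to a target acceptance statistic.

The target is supplied as ``logp_and_grad(z) -> (float, ndarray)``; the
sampler is otherwise agnostic of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["sample_nuts", "NutsStats"]

_DIVERGENCE_THRESHOLD = 1000.0  # energy error that flags a divergence


@dataclass
class NutsStats:
    """Per-chain sampler diagnostics."""

    divergences: int = 0
    accept_prob: float = 0.0
    step_size: float = 0.0
    inv_mass: np.ndarray | None = None
    tree_depths: list = field(default_factory=list)
    n_grad_evals: int = 0


class _Tree:
    __slots__ = (
        "q_minus", "p_minus", "g_minus", "q_plus", "p_plus", "g_plus",
        "q_prop", "logp_prop", "log_w", "turned", "diverged",
        "sum_alpha", "n_alpha",
    )

    def __init__(self, q, p, g, logp, log_w, alpha):
        self.q_minus = self.q_plus = q
        self.p_minus = self.p_plus = p
        self.g_minus = self.g_plus = g
        self.q_prop = q
        self.logp_prop = logp
        self.log_w = log_w
        self.turned = False
        self.diverged = False
        self.sum_alpha = alpha
        self.n_alpha = 1


def _uturn(q_plus, q_minus, p_plus, p_minus, m_inv):
    dq = q_plus - q_minus
    return (dq @ (m_inv * p_minus)) < 0 or (dq @ (m_inv * p_plus)) < 0


class _NutsKernel:
    def __init__(self, logp_and_grad, m_inv, max_treedepth, rng):
        self.f = logp_and_grad
        self.m_inv = m_inv
        self.max_treedepth = max_treedepth
        self.rng = rng
        self.n_evals = 0

    def _eval(self, q):
        self.n_evals += 1
        return self.f(q)

    def _leapfrog(self, q, p, g, eps):
        p = p + 0.5 * eps * g
        q = q + eps * self.m_inv * p
        logp, g = self._eval(q)
        p = p + 0.5 * eps * g
        return q, p, g, logp

    def _hamiltonian(self, logp, p):
        return -logp + 0.5 * float(p @ (self.m_inv * p))

    def _leaf(self, q, p, g, eps, direction, h0):
        q1, p1, g1, logp1 = self._leapfrog(q, p, g, direction * eps)
        if np.all(np.isfinite(g1)) and np.isfinite(logp1):
            h1 = self._hamiltonian(logp1, p1)
        else:
            h1 = np.inf
        log_w = h0 - h1  # multinomial weight of the leaf
        alpha = min(1.0, float(np.exp(min(0.0, log_w))))
        tree = _Tree(q1, p1, g1, logp1, log_w, alpha)
        if (h1 - h0) > _DIVERGENCE_THRESHOLD or not np.isfinite(h1):
            tree.diverged = True
        return tree

    def _build(self, q, p, g, eps, direction, depth, h0):
        if depth == 0:
            return self._leaf(q, p, g, eps, direction, h0)
        first = self._build(q, p, g, eps, direction, depth - 1, h0)
        if first.diverged or first.turned:
            return first
        if direction > 0:
            second = self._build(
                first.q_plus, first.p_plus, first.g_plus, eps, direction,
                depth - 1, h0,
            )
            first.q_plus = second.q_plus
            first.p_plus = second.p_plus
            first.g_plus = second.g_plus
        else:
            second = self._build(
                first.q_minus, first.p_minus, first.g_minus, eps, direction,
                depth - 1, h0,
            )
            first.q_minus = second.q_minus
            first.p_minus = second.p_minus
            first.g_minus = second.g_minus
        first.sum_alpha += second.sum_alpha
        first.n_alpha += second.n_alpha
        if second.diverged or second.turned:
            first.diverged = second.diverged
            first.turned = True
            return first
        total = np.logaddexp(first.log_w, second.log_w)
        if np.log(self.rng.uniform()) < second.log_w - total:
            first.q_prop = second.q_prop
            first.logp_prop = second.logp_prop
        first.log_w = total
        first.turned = _uturn(
            first.q_plus, first.q_minus, first.p_plus, first.p_minus,
            self.m_inv,
        )
        return first

    def step(self, q, g, logp, eps):
        """One NUTS transition; returns (q, g, logp, accept_stat, depth, div)."""
        p0 = self.rng.standard_normal(q.shape) / np.sqrt(self.m_inv)
        h0 = self._hamiltonian(logp, p0)
        q_minus = q_plus = q
        p_minus = p_plus = p0
        g_minus = g_plus = g
        q_prop, logp_prop = q, logp
        log_w = 0.0
        sum_alpha, n_alpha = 0.0, 0
        diverged = False
        depth = 0
        while depth < self.max_treedepth:
            direction = 1 if self.rng.uniform() < 0.5 else -1
            if direction > 0:
                sub = self._build(q_plus, p_plus, g_plus, eps, 1, depth, h0)
                q_plus, p_plus, g_plus = sub.q_plus, sub.p_plus, sub.g_plus
            else:
                sub = self._build(q_minus, p_minus, g_minus, eps, -1, depth, h0)
                q_minus, p_minus, g_minus = (
                    sub.q_minus, sub.p_minus, sub.g_minus,
                )
            sum_alpha += sub.sum_alpha
            n_alpha += sub.n_alpha
            if sub.diverged:
                diverged = True
                break
            if not sub.turned:
                # biased progressive sampling toward the new subtree
                if np.log(self.rng.uniform()) < sub.log_w - log_w:
                    q_prop, logp_prop = sub.q_prop, sub.logp_prop
            log_w = np.logaddexp(log_w, sub.log_w)
            depth += 1
            if sub.turned or _uturn(
                q_plus, q_minus, p_plus, p_minus, self.m_inv
            ):
                break
        accept_stat = sum_alpha / max(n_alpha, 1)
        _, g_prop = self._eval(q_prop) if q_prop is not q else (logp, g)
        return q_prop, g_prop, logp_prop, accept_stat, depth, diverged


def _find_reasonable_epsilon(kernel, q, g, logp, rng):
    eps = 1.0
    p0 = rng.standard_normal(q.shape) / np.sqrt(kernel.m_inv)
    h0 = kernel._hamiltonian(logp, p0)
    q1, p1, _, logp1 = kernel._leapfrog(q, p0, g, eps)
    h1 = kernel._hamiltonian(logp1, p1) if np.isfinite(logp1) else np.inf
    log_ratio = h0 - h1
    direction = 1.0 if log_ratio > np.log(0.5) else -1.0
    for _ in range(50):
        eps *= 2.0**direction
        q1, p1, _, logp1 = kernel._leapfrog(q, p0, g, eps)
        h1 = kernel._hamiltonian(logp1, p1) if np.isfinite(logp1) else np.inf
        if direction * (h0 - h1) < direction * np.log(0.5):
            break
    return eps


def _adaptation_windows(n_warmup):
    """(step-size-only init, list of mass windows, step-size-only tail)."""
    if n_warmup < 20:
        return n_warmup, [], 0
    init = max(1, int(round(0.15 * n_warmup)))
    term = max(1, int(round(0.10 * n_warmup)))
    middle = n_warmup - init - term
    windows = []
    w = max(1, int(round(0.10 * n_warmup)))
    pos = 0
    while pos < middle:
        if pos + w >= middle or middle - (pos + w) < w:
            windows.append(middle - pos)
            pos = middle
        else:
            windows.append(w)
            pos += w
            w *= 2
    return init, windows, term


class _Welford:
    def __init__(self, dim):
        self.n = 0
        self.mean = np.zeros(dim)
        self.m2 = np.zeros(dim)

    def update(self, x):
        self.n += 1
        d = x - self.mean
        self.mean += d / self.n
        self.m2 += d * (x - self.mean)

    def variance(self):
        if self.n < 2:
            return np.ones_like(self.mean)
        var = self.m2 / (self.n - 1)
        # regularize toward unit metric as Stan does
        return (self.n / (self.n + 5.0)) * var + 1e-3 * (5.0 / (self.n + 5.0))


def sample_nuts(
    logp_and_grad,
    init: np.ndarray,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    target_accept: float = 0.8,
    max_treedepth: int = 10,
) -> tuple[np.ndarray, NutsStats]:
    """Run one NUTS chain; returns (draws (n_samples, dim), diagnostics)."""
    q = np.asarray(init, dtype=float).copy()
    dim = q.size
    m_inv = np.ones(dim)
    kernel = _NutsKernel(logp_and_grad, m_inv, max_treedepth, rng)
    logp, g = kernel._eval(q)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")

    eps = _find_reasonable_epsilon(kernel, q, g, logp, rng)
    # dual averaging state
    mu = np.log(10.0 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75

    init_buf, windows, term_buf = _adaptation_windows(n_warmup)
    boundaries = []
    pos = init_buf
    for w in windows:
        pos += w
        boundaries.append(pos)

    welford = _Welford(dim)
    stats = NutsStats()
    da_iter = 0
    for it in range(n_warmup):
        q, g, logp, alpha, depth, div = kernel.step(q, g, logp, eps)
        da_iter += 1
        h_bar = (1 - 1 / (da_iter + t0)) * h_bar + (
            target_accept - alpha
        ) / (da_iter + t0)
        log_eps = mu - np.sqrt(da_iter) / gamma * h_bar
        eta = da_iter ** (-kappa)
        log_eps_bar = eta * log_eps + (1 - eta) * log_eps_bar
        eps = float(np.exp(log_eps))
        if init_buf <= it < n_warmup - term_buf:
            welford.update(q)
        if boundaries and it == boundaries[0] - 1:
            boundaries.pop(0)
            kernel.m_inv = welford.variance()
            welford = _Welford(dim)
            # restart step-size adaptation around the current value
            eps = _find_reasonable_epsilon(kernel, q, g, logp, rng)
            mu = np.log(10.0 * eps)
            log_eps_bar, h_bar, da_iter = 0.0, 0.0, 0

    if n_warmup > 0:
        eps = float(np.exp(log_eps_bar))

    draws = np.empty((n_samples, dim))
    accepts = []
    for it in range(n_samples):
        q, g, logp, alpha, depth, div = kernel.step(q, g, logp, eps)
        draws[it] = q
        accepts.append(alpha)
        stats.tree_depths.append(depth)
        if div:
            stats.divergences += 1
    stats.accept_prob = float(np.mean(accepts)) if accepts else 0.0
    stats.step_size = eps
    stats.inv_mass = kernel.m_inv
    stats.n_grad_evals = kernel.n_evals
    return draws, stats
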