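"""Enhanced grey-wolf optimizer (GWO) for kernel hyperparameters.

Vanilla GWO moves each non-leader agent toward a stochastic average of
the three current best agents (α, β, δ):

    θ_d(t+1) = (1/3) Σ_{l∈{α,β,δ}} [θ_d^l − A_{l,d} D_d^{l}],
    D_d^l = |C_{l,d} θ_d^l − θ_d|,  A = 2a·r1 − a,  C = 2a·r2,

with a(t) decreasing linearly from 2 to 0 and r1, r2 ~ U(0,1) drawn
fresh per leader and dimension.  Two enhancements are used here:

* elitism — a proposed move is reverted if it worsens the agent's loss,
  so the best-so-far loss is monotonically non-increasing;
* lucky-wolf promotion — every ``lucky_period`` iterations,
  ``lucky_count`` random non-leaders are teleported to (1+ε)·L, the
  slightly inflated centroid L of the three leaders (ε ~ U(0, 0.25)),
  which concentrates the pack without collapsing the search.

The noise hyperparameter σ_n² spans six decades, so it is searched in
log10 space; positions are reported back in raw space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class GWOResult:
    best_position: np.ndarray
    best_loss: float
    trace: np.ndarray  # best-so-far loss after each iteration
    n_evaluations: int


def optimize(
    loss_fn,
    bounds,
    iterations: int = 200,
    agents: int = 50,
    lucky_period: int | None = 5,
    lucky_count: int = 5,
    seed: int = 0,
) -> GWOResult:
    """Minimize ``loss_fn`` over a box; returns the best-ever position.

    ``bounds`` is a (D, 2) array of [lo, hi] per dimension.  Non-finite
    losses are treated as +inf so such agents never lead the pack.
    """
    bounds = np.asarray(bounds, float)
    dim = bounds.shape[0]
    lo, hi = bounds[:, 0], bounds[:, 1]
    rng = np.random.default_rng(seed)

    def safe_loss(x):
        v = loss_fn(x)
        return float(v) if np.isfinite(v) else np.inf

    pos = rng.uniform(lo, hi, size=(agents, dim))
    loss = np.array([safe_loss(p) for p in pos])
    n_evals = agents

    best_i = int(np.argmin(loss))
    best_pos, best_loss = pos[best_i].copy(), loss[best_i]
    trace = []

    for t in range(iterations):
        a = 2.0 * (1.0 - t / max(iterations - 1, 1))
        order = np.argsort(loss, kind="stable")
        leaders = order[:3]
        lead_pos = pos[leaders]  # (3, D)

        for w in order[3:]:
            r1 = rng.random((3, dim))
            r2 = rng.random((3, dim))
            A = 2.0 * a * r1 - a
            C = 2.0 * a * r2
            D = np.abs(C * lead_pos - pos[w])
            cand = np.clip(np.mean(lead_pos - A * D, axis=0), lo, hi)
            cand_loss = safe_loss(cand)
            n_evals += 1
            if cand_loss <= loss[w]:  # elitism: only accept improvements
                pos[w] = cand
                loss[w] = cand_loss

        if lucky_period and (t + 1) % lucky_period == 0:
            order = np.argsort(loss, kind="stable")
            non_leaders = order[3:]
            centroid = pos[order[:3]].mean(axis=0)
            k = min(lucky_count, len(non_leaders))
            if k > 0:
                lucky = rng.choice(non_leaders, size=k, replace=False)
                for w in lucky:
                    eps = rng.uniform(0.0, 0.25)
                    pos[w] = np.clip((1.0 + eps) * centroid, lo, hi)
                    loss[w] = safe_loss(pos[w])
                    n_evals += 1

        i = int(np.argmin(loss))
        if loss[i] < best_loss:
            best_loss = loss[i]
            best_pos = pos[i].copy()
        trace.append(best_loss)

    return GWOResult(best_pos, best_loss, np.asarray(trace), n_evals)


def lucky_promote(pos, loss, loss_fn, lucky_count, bounds, rng):
    """Standalone lucky-wolf promotion step (used by tests); mutates and
    returns (pos, loss, promoted indices)."""
    bounds = np.asarray(bounds, float)
    order = np.argsort(loss, kind="stable")
    non_leaders = order[3:]
    centroid = pos[order[:3]].mean(axis=0)
    k = min(lucky_count, len(non_leaders))
    lucky = rng.choice(non_leaders, size=k, replace=False) if k else np.array([], int)
    for w in lucky:
        eps = rng.uniform(0.0, 0.25)
        pos[w] = np.clip((1.0 + eps) * centroid, bounds[:, 0], bounds[:, 1])
        loss[w] = loss_fn(pos[w])
    return pos, loss, lucky


def update_position(agent, lead_pos, a, r1, r2):
    """One agent's GWO move given leader positions and the random draws
    (r1, r2 of shape (3, D)); exposed for direct arithmetic checks."""
    A = 2.0 * a * r1 - a
    C = 2.0 * a * r2
    D = np.abs(C * lead_pos - agent)
    return np.mean(lead_pos - A * D, axis=0)


def optimize_atomic_hyperparameters(
    ctx,
    iterations: int = 200,
    agents: int = 50,
    lucky_period: int = 5,
    lucky_count: int = 5,
    seed: int = 0,
):
    """Search one atom's (θ, σ_n²) against a validation-MSE context.

    Dimensions: N_feats θ values in [0, 1] plus log10 σ_n² in [−10, −4];
    the kernel pre-factor σ_f stays fixed.  Returns (θ, σ_n², trace).
    """
    F = ctx.n_feats
    bounds = np.vstack([
        np.tile([0.0, 1.0], (F, 1)),
        [[-10.0, -4.0]],
    ])

    def loss_fn(x):
        return ctx.loss(x[:F], 10.0 ** x[F])

    res = optimize(
        loss_fn, bounds, iterations=iterations, agents=agents,
        lucky_period=lucky_period, lucky_count=lucky_count, seed=seed,
    )
    return res.best_position[:F].copy(), float(10.0 ** res.best_position[F]), res.trace
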