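"""Learning rules: Hebbian weight plasticity, wiring plasticity, rewiring.

Three rule selectors are supported by :func:`train`:

* ``weight_only``  — Hebbian weight updates on a frozen connection matrix;
* ``dual_hebbian`` — weight updates plus the activity-dependent
  connection-probability rule and stochastic rewiring;
* ``approx_dual``  — weight updates plus the spine-size-driven
  approximation in which the connection probability of an existing spine
  relaxes toward ``gamma^2 * w`` and absent pairs sit at the baseline
  ``gamma^2 * w_o``.

Rewiring keeps detailed balance: a present connection is eliminated with
probability ``(1-rho)/tau_c`` per step and an absent one created with
``rho/tau_c``, so the stationary occupancy of every pair equals its
connection probability ``rho`` and creations balance eliminations without
global regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .families import GaussianFamily, PoissonFamily
from .generative import ExternalModel
from .network import Network, membrane_potentials, output_rates

__all__ = [
    "PlasticityConfig",
    "SpineHistory",
    "TrainResult",
    "weight_update",
    "prob_update_dual",
    "prob_update_approx",
    "rewire",
    "train",
]

RULES = ("weight_only", "dual_hebbian", "approx_dual")


@dataclass
class PlasticityConfig:
    """Learning-rule parameters (per-step rates, dimensionless strengths).

    Defaults follow the standard operating point: weight rate
    ``eta_x = 0.01`` (divided by ``gamma`` inside the rule since mean weight
    scales as 1/gamma), homeostatic strength ``b_h = 0.1``, wiring rate
    ``eta_rho = 0.001``, rewiring timescale ``tau_c = 1e6`` steps.
    ``w_o = rX0/gamma`` is the expected mean synaptic weight; new spines are
    born at ``(1 + sigma_w_init*N(0,1)) * w_o``.
    """

    gamma: float = 0.1
    eta_x: float = 0.01
    b_h: float = 0.1
    eta_rho: float = 0.001
    tau_c: float = 1e6
    sigma_w_init: float = 0.1
    rule: str = "dual_hebbian"
    elimination_multiplier: float = 1.0
    rX0: float = 1.0
    w_o: float | None = None
    weight_floor: float = 1e-12

    def __post_init__(self) -> None:
        if self.eta_x <= 0 or self.eta_rho <= 0:
            raise ValueError("learning rates must be positive")
        if self.tau_c < 1:
            raise ValueError("tau_c must be >= 1")
        if self.b_h < 0:
            raise ValueError("b_h must be nonnegative")
        if self.rule not in RULES:
            raise ValueError(f"rule must be one of {RULES}")
        if self.w_o is None:
            self.w_o = self.rX0 / self.gamma


class SpineHistory:
    """Creation/elimination events and per-connection birth times.

    Events are appended as ``(step, i, j)``; ``birth_step`` holds, for every
    currently existing connection, the step it was created (-1 for
    connections present from the start).
    """

    def __init__(self, C0: np.ndarray):
        self.initial_C = C0.copy()
        self.birth_step = np.where(C0 > 0, -1, np.iinfo(np.int64).min).astype(np.int64)
        self.creations: list[tuple[int, int, int]] = []
        self.eliminations: list[tuple[int, int, int]] = []

    def record(self, step: int, created: np.ndarray, eliminated: np.ndarray) -> None:
        ci, cj = np.nonzero(created)
        for i, j in zip(ci.tolist(), cj.tolist()):
            self.creations.append((step, i, j))
        ei, ej = np.nonzero(eliminated)
        for i, j in zip(ei.tolist(), ej.tolist()):
            self.eliminations.append((step, i, j))
        self.birth_step[created > 0] = step

    def counts_in_window(self, start: int, stop: int) -> tuple[int, int]:
        """(#creations, #eliminations) with start <= step < stop."""
        nc = sum(1 for s, _, _ in self.creations if start <= s < stop)
        ne = sum(1 for s, _, _ in self.eliminations if start <= s < stop)
        return nc, ne

    def events_dataframe(self) -> pd.DataFrame:
        rows = [(s, i, j, "created") for s, i, j in self.creations]
        rows += [(s, i, j, "eliminated") for s, i, j in self.eliminations]
        df = pd.DataFrame(rows, columns=["step", "i", "j", "event"])
        return df.sort_values("step", kind="stable").reset_index(drop=True)


def weight_update(
    network: Network,
    r_X: np.ndarray,
    r_Y: np.ndarray,
    family: GaussianFamily | PoissonFamily,
    cfg: PlasticityConfig,
) -> None:
    """Hebbian weight step with homeostasis, applied in place where C=1.

    dw = (eta_x/gamma) * ( r_Y,i [g(r_X,j) - alpha'(rho_bar w_ij)]
                           + b_h [rY0/N - r_Y,i] ),
    then weights are floored at a small positive value.
    """
    C, W = network.C, network.W
    gd = family.g(r_X)[None, :] - family.alpha_prime(network.rho_bar * W)
    dW = (cfg.eta_x / cfg.gamma) * (
        r_Y[:, None] * gd + cfg.b_h * (network.rY0 / network.N - r_Y)[:, None]
    )
    W += dW * C
    np.clip(W, cfg.weight_floor, None, out=W)
    W *= C


def prob_update_dual(
    network: Network,
    r_X: np.ndarray,
    r_Y: np.ndarray,
    family: GaussianFamily | PoissonFamily,
    cfg: PlasticityConfig,
) -> None:
    """Activity-dependent wiring rule, applied to every (i, j) pair.

    d rho = eta_rho * r_Y,i [g(r_X,j) - alpha'(rho_ij w_o)], clipped to [0,1].
    The probability is defined (and updated) even for absent connections.
    """
    P = network.P
    gd = family.g(r_X)[None, :] - family.alpha_prime(P * cfg.w_o)
    P += cfg.eta_rho * r_Y[:, None] * gd
    np.clip(P, 0.0, 1.0, out=P)


def prob_update_approx(network: Network, cfg: PlasticityConfig) -> None:
    """Spine-size-driven approximation of the wiring rule.

    Existing spines: rho relaxes toward ``gamma^2 * w`` at rate eta_rho.
    Absent pairs: rho is pinned at the baseline ``gamma^2 * w_o`` (random,
    activity-independent creation).
    """
    P, C, W = network.P, network.C, network.W
    on = C > 0
    P[on] += cfg.eta_rho * (cfg.gamma**2 * W[on] - P[on])
    P[~on] = cfg.gamma**2 * cfg.w_o
    np.clip(P, 0.0, 1.0, out=P)


def rewire(
    network: Network,
    cfg: PlasticityConfig,
    rng: np.random.Generator,
    step: int = 0,
    history: SpineHistory | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One step of detailed-balance spine turnover; returns (created, eliminated).

    Present connections are eliminated with probability
    ``elimination_multiplier * (1-rho)/tau_c`` and absent ones created with
    ``rho/tau_c``; new spines get weight ``(1 + sigma_w_init*zeta) * w_o``.

    Implemented by thinning: candidate pairs are drawn with the common upper
    bound ``max(1, elimination_multiplier)/tau_c`` and accepted with their
    actual probability, which is an exact per-pair Bernoulli scheme and
    cheap when ``tau_c`` is large.
    """
    C, W, P = network.C, network.W, network.P
    n_pairs = C.size
    pmax = max(1.0, cfg.elimination_multiplier) / cfg.tau_c
    created = np.zeros_like(C, dtype=bool)
    eliminated = np.zeros_like(C, dtype=bool)
    if pmax >= 0.05:
        # dense path for fast rewiring
        on = C > 0
        thresh = np.where(on, cfg.elimination_multiplier * (1.0 - P) / cfg.tau_c, P / cfg.tau_c)
        flip = rng.random(C.shape) < thresh
        eliminated[:] = flip & on
        created[:] = flip & ~on
    else:
        k = rng.binomial(n_pairs, pmax)
        if k == 0:
            return created, eliminated
        idx = rng.integers(n_pairs, size=k)
        if k > 1 and len(np.unique(idx)) != k:  # rare collision: exact fallback
            idx = rng.choice(n_pairs, size=k, replace=False)
        flatC, flatP = C.ravel(), P.ravel()
        on = flatC[idx] > 0
        prob = np.where(
            on,
            cfg.elimination_multiplier * (1.0 - flatP[idx]) / cfg.tau_c,
            flatP[idx] / cfg.tau_c,
        )
        accept = rng.random(k) < prob / pmax
        sel = idx[accept]
        on = on[accept]
        created.ravel()[sel[~on]] = True
        eliminated.ravel()[sel[on]] = True
    if eliminated.any():
        C[eliminated] = 0.0
        W[eliminated] = 0.0
    n_new = int(created.sum())
    if n_new:
        C[created] = 1.0
        W[created] = np.maximum(
            (1.0 + cfg.sigma_w_init * rng.standard_normal(n_new)) * cfg.w_o,
            cfg.weight_floor,
        )
    if history is not None and (n_new or eliminated.any()):
        history.record(step, created, eliminated)
    return created, eliminated


@dataclass
class TrainResult:
    network: Network
    history: SpineHistory
    metrics: pd.DataFrame
    activity_s: np.ndarray | None = None
    activity_rY: np.ndarray | None = None


def train(
    network: Network,
    model: ExternalModel,
    steps: int,
    cfg: PlasticityConfig,
    seed: int | np.random.Generator | None = None,
    family: GaussianFamily | PoissonFamily | None = None,
    record_every: int | None = None,
    acc_window: int = 1000,
    keep_activity: int = 0,
    model_schedule=None,
    snapshot_days: dict | None = None,
    day_length: int | None = None,
) -> TrainResult:
    """Run the full learning loop: sample -> respond -> learn -> rewire.

    Per step: draw ``(s, r_X)`` from the model, compute the softmax output,
    apply the weight rule, then the configured wiring-probability rule, then
    stochastic rewiring (``weight_only`` skips both wiring stages).

    ``record_every`` triggers periodic metric rows (bootstrap accuracy over
    the last ``2*acc_window`` steps, connectivity, event counts).
    ``model_schedule(step)`` may return a replacement ExternalModel (dynamic
    environments).  ``snapshot_days``/``day_length`` store copies of C (and
    birth steps) at day boundaries for spine statistics.
    ``keep_activity`` > 0 retains the trailing window of (s, r_Y).
    """
    from .evaluation import bootstrap_accuracy

    if steps < 1:
        raise ValueError("steps must be >= 1")
    fam = family if family is not None else model.family
    rng = np.random.default_rng(seed)
    structural = cfg.rule != "weight_only"
    if structural and network.P is None:
        network.P = np.full_like(network.C, float(network.C.mean()))
    history = SpineHistory(network.C)

    buf = max(2 * acc_window, keep_activity) if (record_every or keep_activity) else 0
    if buf:
        s_buf = np.zeros(buf, dtype=np.int64)
        rY_buf = np.zeros((buf, network.N))

    rows = []
    last_counts = (0, 0)
    theta = model.theta
    sigma = getattr(fam, "sigma", None)
    gaussian = isinstance(fam, GaussianFamily)
    N, M = network.N, network.M

    # sparse caches for the hot loop: flat indices of existing connections
    C, W = network.C, network.W
    conn = np.flatnonzero(C.ravel() > 0)
    ii, jj = np.unravel_index(conn, C.shape)
    indeg = C.sum(axis=1)
    if gaussian:
        s2_flat = np.broadcast_to(np.atleast_1d(sigma**2), (M,))
    approx = cfg.rule == "approx_dual"
    if approx:
        baseline = np.clip(cfg.gamma**2 * cfg.w_o, 0.0, 1.0)
        network.P[C.ravel().reshape(N, M) == 0] = baseline
    eta_w = cfg.eta_x / cfg.gamma
    homeo_target = network.rY0 / N

    for step in range(steps):
        if model_schedule is not None:
            new_model = model_schedule(step)
            if new_model is not None:
                model = new_model
                theta = model.theta
        s = int(rng.integers(model.p))
        if gaussian:
            r_X = theta[s] + sigma * rng.standard_normal(M)
            g = r_X
        else:
            r_X = rng.poisson(theta[s]).astype(float)
            g = r_X
        v = W @ g - network.h_w * indeg
        np.maximum(v, v.max() - abs(network.v_d), out=v)
        v -= v.max()
        r_Y = np.exp(v)
        r_Y *= network.rY0 / r_Y.sum()
        # Hebbian weight step on existing connections only
        w_flat = W.ravel()[conn]
        if gaussian:
            gd = g[jj] - s2_flat[jj] * (network.rho_bar * w_flat)
        else:
            gd = g[jj] - fam.theta_o * np.exp(network.rho_bar * w_flat)
        dw = eta_w * (r_Y[ii] * gd + cfg.b_h * (homeo_target - r_Y[ii]))
        W.ravel()[conn] = np.maximum(w_flat + dw, cfg.weight_floor)
        if structural:
            P = network.P
            if cfg.rule == "dual_hebbian":
                if gaussian:
                    gd_full = g[None, :] - (s2_flat * cfg.w_o)[None, :] * P
                else:
                    gd_full = g[None, :] - fam.theta_o * np.exp(P * cfg.w_o)
                P += cfg.eta_rho * r_Y[:, None] * gd_full
                np.clip(P, 0.0, 1.0, out=P)
            else:
                p_flat = P.ravel()[conn]
                P.ravel()[conn] = np.clip(
                    p_flat + cfg.eta_rho * (cfg.gamma**2 * W.ravel()[conn] - p_flat),
                    0.0,
                    1.0,
                )
            created, eliminated = rewire(network, cfg, rng, step, history)
            if created.any() or eliminated.any():
                if approx and eliminated.any():
                    P[eliminated] = baseline
                conn = np.flatnonzero(C.ravel() > 0)
                ii, jj = np.unravel_index(conn, C.shape)
                indeg = C.sum(axis=1)
        if buf:
            k = step % buf
            s_buf[k] = s
            rY_buf[k] = r_Y
        if record_every and (step + 1) % record_every == 0:
            acc = np.nan
            if step + 1 >= 2 * acc_window:
                idx = (np.arange(step + 1 - 2 * acc_window, step + 1)) % buf
                acc = bootstrap_accuracy(s_buf[idx], rY_buf[idx], network.p, acc_window)
            nc, ne = history.counts_in_window(0, step + 1)
            rows.append(
                {
                    "step": step + 1,
                    "accuracy": acc,
                    "connectivity": float(network.C.mean()),
                    "mean_weight": float(network.W[network.C > 0].mean())
                    if network.C.any()
                    else 0.0,
                    "created": nc - last_counts[0],
                    "eliminated": ne - last_counts[1],
                }
            )
            last_counts = (nc, ne)
        if snapshot_days is not None and day_length and (step + 1) % day_length == 0:
            day = (step + 1) // day_length
            snapshot_days[day] = {
                "C": network.C.copy(),
                "birth": history.birth_step.copy(),
                "P": None if network.P is None else network.P.copy(),
            }

    metrics = pd.DataFrame(rows)
    result = TrainResult(network=network, history=history, metrics=metrics)
    if keep_activity and buf:
        # unroll ring buffer to chronological order of the last `buf` steps
        if steps >= buf:
            idx = (np.arange(steps - buf, steps)) % buf
        else:
            idx = np.arange(steps)
        result.activity_s = s_buf[idx][-keep_activity:]
        result.activity_rY = rY_buf[idx][-keep_activity:]
    return result
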