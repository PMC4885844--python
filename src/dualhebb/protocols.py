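"""Experiment drivers: dynamic environments, training protocols, spine stats.

These wrap the training loop into the three study designs:

* :func:`run_dynamic_environment` — the variable component of the input
  structure is resampled every ``T2`` steps; early-phase (just after a
  switch) and late-phase (just before the next one) accuracies show whether
  the wiring has captured the constant component.
* :func:`run_training_protocol` — a motor-learning analogue: burn-in on a
  control input structure, then switch to a training structure; daily
  connectivity snapshots give spine survival curves for new versus
  pre-existing spines.
* :func:`spine_statistics` — long run of the approximated dual rule with
  daily snapshots of connection probabilities, ages, and survival.

A "day" is a fixed number of simulation steps (10^5 at full scale); scaled
presets shrink the day while keeping the turnover per day fixed by scaling
the rewiring timescale with it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .coding import threshold_value
from .families import GaussianFamily
from .evaluation import bootstrap_accuracy, model_error
from .generative import ExternalModel, make_mixed_model
from .network import Network, selectivity_map
from .plasticity import PlasticityConfig, train

__all__ = [
    "ProtocolConfig",
    "init_plastic_network",
    "run_dynamic_environment",
    "run_training_arms",
    "run_training_protocol",
    "survival_metrics",
    "survival_curve",
    "spine_statistics",
]


@dataclass
class ProtocolConfig:
    """Shared settings for the experiment drivers.

    ``day_length`` is the number of steps regarded as one day; ``T2`` the
    interval between environment switches.  The full-scale values are
    ``day_length = T2 = 1e5``; scaled presets divide both (and ``tau_c``)
    by the same factor so per-day turnover is preserved.
    """

    p: int = 10
    M: int = 200
    N: int = 100
    mu_M: float = 1.0
    sigma_M: float = 1.0
    sigma_X: float = 1.0
    rX0: float = 1.0
    rY0: float = 1.0
    gamma: float = 0.6
    kappa_m: float = 0.5
    T2: int = 100_000
    epochs: int = 10
    eval_window: int = 10_000
    day_length: int = 100_000
    burnin_days: int = 20
    training_days: int = 8
    elimination_multiplier: float = 1.0
    plasticity: PlasticityConfig = field(default_factory=lambda: PlasticityConfig(gamma=0.6))

    def __post_init__(self) -> None:
        if self.T2 < 1 or self.day_length < 1:
            raise ValueError("T2 and day_length must be >= 1")


def _draw_raw_component(cfg: ProtocolConfig, rng: np.random.Generator) -> np.ndarray:
    a = (0.0 - cfg.mu_M) / cfg.sigma_M
    return stats.truncnorm.rvs(
        a, np.inf, loc=cfg.mu_M, scale=cfg.sigma_M, size=(cfg.p, cfg.M), random_state=rng
    )


def init_plastic_network(
    cfg: ProtocolConfig, model: ExternalModel, rng: np.random.Generator
) -> Network:
    """Random initial network for learning runs.

    Connections are drawn at density ``gamma * mean(theta)/sigma_X^2``,
    weights at ``(1 + 0.1*zeta)/gamma``, the threshold preset is
    ``rX0/gamma`` (the mean response depends on the mixture ratio, so the
    fixed-scale preset is used), and P starts at the initial density.
    """
    rho_init = float(np.clip(cfg.gamma * model.theta.mean() / cfg.sigma_X**2, 0.0, 1.0))
    C = (rng.random((cfg.N, cfg.M)) < rho_init).astype(float)
    W = np.maximum((1.0 + 0.1 * rng.standard_normal((cfg.N, cfg.M))) / cfg.gamma, 1e-12)
    h_w = threshold_value("rX0_over_gamma", q_bar=0.0, gamma=cfg.gamma, rX0=cfg.rX0)
    return Network(
        C=C,
        W=W,
        P=np.full((cfg.N, cfg.M), rho_init),
        selectivity=selectivity_map(cfg.p, cfg.N),
        p=cfg.p,
        h_w=h_w,
        rY0=cfg.rY0,
        meta={"strategy": "learning_init", "gamma": cfg.gamma, "rho_init": rho_init},
    )


def run_dynamic_environment(
    cfg: ProtocolConfig,
    rule: str = "dual_hebbian",
    seed: int | np.random.Generator | None = None,
) -> dict:
    """Learning while the variable input component changes every T2 steps.

    Returns per-epoch early/late accuracies, the connectivity trace, final
    connectivity-derived and weight-derived model errors against the
    constant and the variable component, and the final network.
    """
    rng = np.random.default_rng(seed)
    theta_const = _draw_raw_component(cfg, rng)
    theta_var = _draw_raw_component(cfg, rng)
    model = make_mixed_model(theta_const, theta_var, cfg.kappa_m, cfg.rX0, cfg.sigma_X)
    network = init_plastic_network(cfg, model, rng)
    pcfg = replace(cfg.plasticity, rule=rule, gamma=cfg.gamma, rX0=cfg.rX0)

    win = min(cfg.eval_window, cfg.T2 // 2)
    half = win // 2
    early, late, connectivity = [], [], []
    for _ in range(cfg.epochs):
        theta_var = _draw_raw_component(cfg, rng)
        model = make_mixed_model(theta_const, theta_var, cfg.kappa_m, cfg.rX0, cfg.sigma_X)
        res = train(network, model, win, pcfg, rng, keep_activity=win, acc_window=half)
        early.append(bootstrap_accuracy(res.activity_s, res.activity_rY, cfg.p, half))
        res = train(network, model, cfg.T2 - win, pcfg, rng, keep_activity=win, acc_window=half)
        late.append(bootstrap_accuracy(res.activity_s, res.activity_rY, cfg.p, half))
        connectivity.append(float(network.C.mean()))

    const_model = make_mixed_model(theta_const, theta_var, 1.0, cfg.rX0, cfg.sigma_X)
    var_model = make_mixed_model(theta_const, theta_var, 0.0, cfg.rX0, cfg.sigma_X)
    errors = {
        f"{mode}_vs_{name}": model_error(model, network, mode, theta_ref=ref.theta)
        for mode in ("connectivity_only", "weight_only")
        for name, ref in (("const", const_model), ("var", var_model))
    }
    return {
        "early_accuracy": np.array(early),
        "late_accuracy": np.array(late),
        "connectivity": np.array(connectivity),
        "errors": errors,
        "network": network,
    }


def _unstructured_schedule(cfg: ProtocolConfig, rng: np.random.Generator):
    """Random Gaussian surrogate inputs with no hidden-state structure."""
    loc = 0.75 * cfg.mu_M
    scale = np.sqrt(cfg.sigma_X**2 + cfg.sigma_M**2)
    theta = np.full((cfg.p, cfg.M), loc)
    return ExternalModel(theta=theta, family=GaussianFamily(sigma=scale), rX0=cfg.rX0)


def run_training_protocol(
    cfg: ProtocolConfig,
    rule: str = "approx_dual",
    seed: int | np.random.Generator | None = None,
    training: bool = True,
    kappa_similarity: float = 0.0,
    unstructured_control: bool = False,
    test_phase: bool = False,
) -> dict:
    """Burn-in on a control structure, then (optionally) train on a new one.

    ``kappa_similarity`` mixes the control structure into the training one
    (1 means training equals control).  Daily connectivity snapshots start
    at the switch (day 0).  With ``training=False`` the control structure
    continues, giving the matched control arm.  ``test_phase`` appends a
    short exposure and scores the activity 2000-7000 steps after its onset.
    """
    rng = np.random.default_rng(seed)
    theta_ctrl = _draw_raw_component(cfg, rng)
    theta_new = _draw_raw_component(cfg, rng)
    control_model = make_mixed_model(theta_ctrl, theta_ctrl, 1.0, cfg.rX0, cfg.sigma_X)
    train_model = make_mixed_model(theta_ctrl, theta_new, kappa_similarity, cfg.rX0, cfg.sigma_X)
    if unstructured_control:
        burn_model = _unstructured_schedule(cfg, rng)
    else:
        burn_model = control_model
    network = init_plastic_network(cfg, burn_model, rng)
    pcfg = replace(cfg.plasticity, rule=rule, gamma=cfg.gamma, rX0=cfg.rX0)

    train(network, burn_model, cfg.burnin_days * cfg.day_length, pcfg, rng)

    phase_model = train_model if training else control_model
    snapshots: dict[int, np.ndarray] = {0: network.C.copy()}
    day_snaps: dict = {}
    if training and cfg.elimination_multiplier != 1.0:
        # enhanced elimination applies from day 1 of training onward
        train(network, phase_model, cfg.day_length, pcfg, rng)
        snapshots[1] = network.C.copy()
        pcfg = replace(pcfg, elimination_multiplier=cfg.elimination_multiplier)
        train(network, phase_model, (cfg.training_days - 1) * cfg.day_length, pcfg, rng,
              snapshot_days=day_snaps, day_length=cfg.day_length)
        for d, snap in day_snaps.items():
            snapshots[d + 1] = snap["C"]
    else:
        train(network, phase_model, cfg.training_days * cfg.day_length, pcfg, rng,
              snapshot_days=day_snaps, day_length=cfg.day_length)
        for d, snap in day_snaps.items():
            snapshots[d] = snap["C"]

    out = {
        "snapshots": snapshots,
        "network": network,
        "control_model": control_model,
        "train_model": train_model,
    }
    if test_phase:
        res = train(network, phase_model, 7000, pcfg, rng, keep_activity=5000, acc_window=2500)
        out["test_accuracy"] = bootstrap_accuracy(res.activity_s, res.activity_rY, cfg.p, 2500)
    return out


def run_training_arms(
    cfg: ProtocolConfig,
    seed: int | np.random.Generator | None,
    arm_specs: dict[str, dict],
    rule: str = "approx_dual",
) -> dict[str, dict]:
    """Run several post-switch arms from one shared burn-in.

    All arms of :func:`run_training_protocol` with the same seed share the
    burn-in trajectory bit for bit; this driver computes it once and forks
    the network and random stream per arm, which is mathematically
    identical and much cheaper.  Each value of ``arm_specs`` takes the
    keyword arguments of :func:`run_training_protocol` (``training``,
    ``kappa_similarity``).
    """
    import copy

    rng = np.random.default_rng(seed)
    theta_ctrl = _draw_raw_component(cfg, rng)
    theta_new = _draw_raw_component(cfg, rng)
    control_model = make_mixed_model(theta_ctrl, theta_ctrl, 1.0, cfg.rX0, cfg.sigma_X)
    network = init_plastic_network(cfg, control_model, rng)
    pcfg = replace(cfg.plasticity, rule=rule, gamma=cfg.gamma, rX0=cfg.rX0)
    train(network, control_model, cfg.burnin_days * cfg.day_length, pcfg, rng)

    results = {}
    for name, spec in arm_specs.items():
        training = spec.get("training", True)
        kappa = spec.get("kappa_similarity", 0.0)
        arm_net = copy.deepcopy(network)
        arm_rng = copy.deepcopy(rng)
        train_model = make_mixed_model(theta_ctrl, theta_new, kappa, cfg.rX0, cfg.sigma_X)
        phase_model = train_model if training else control_model
        arm_pcfg = pcfg
        snapshots: dict[int, np.ndarray] = {0: arm_net.C.copy()}
        day_snaps: dict = {}
        if training and cfg.elimination_multiplier != 1.0:
            train(arm_net, phase_model, cfg.day_length, arm_pcfg, arm_rng)
            snapshots[1] = arm_net.C.copy()
            arm_pcfg = replace(arm_pcfg, elimination_multiplier=cfg.elimination_multiplier)
            train(arm_net, phase_model, (cfg.training_days - 1) * cfg.day_length, arm_pcfg,
                  arm_rng, snapshot_days=day_snaps, day_length=cfg.day_length)
            for d, snap in day_snaps.items():
                snapshots[d + 1] = snap["C"]
        else:
            train(arm_net, phase_model, cfg.training_days * cfg.day_length, arm_pcfg,
                  arm_rng, snapshot_days=day_snaps, day_length=cfg.day_length)
            for d, snap in day_snaps.items():
                snapshots[d] = snap["C"]
        results[name] = {
            "snapshots": snapshots,
            "network": arm_net,
            "control_model": control_model,
            "train_model": train_model,
        }
    return results


def survival_metrics(snapshots: dict[int, np.ndarray]) -> dict[str, float]:
    """The printed day-0/2/7 spine-turnover ratios.

    * new spines formed in the first two days persisting at day 7
      (among day-7 spines),
    * total new spines at day 7 (among day-7 spines),
    * elimination of spines existing at day 0.
    """
    c0, c2, c7 = (np.asarray(snapshots[d], dtype=float) for d in (0, 2, 7))
    out = {}
    denom7 = c7.sum()
    denom0 = c0.sum()
    out["new_first_two_days_at_7"] = (
        float((c7 * (1 - c0) * c2).sum() / denom7) if denom7 else np.nan
    )
    out["total_new_at_7"] = float((c7 * (1 - c0)).sum() / denom7) if denom7 else np.nan
    out["eliminated_existing"] = float((c0 * (1 - c7)).sum() / denom0) if denom0 else np.nan
    return out


def survival_curve(
    snapshots: dict[int, np.ndarray],
    cohort: str = "new",
    days: list[int] | None = None,
) -> np.ndarray:
    """Fraction of a spine cohort still present at each requested day.

    Cohorts follow the day-0/day-2 bookkeeping: 'new' spines are absent at
    day 0 and present at day 2; 'pre' (pre-existing) spines are present at
    both.  Survival is referenced to the cohort at day 2.
    """
    c0 = np.asarray(snapshots[0], dtype=float)
    c2 = np.asarray(snapshots[2], dtype=float)
    mask = (1 - c0) * c2 if cohort == "new" else c0 * c2
    n = mask.sum()
    if days is None:
        days = sorted(d for d in snapshots if d >= 2)
    return np.array(
        [np.sum(mask * np.asarray(snapshots[d], dtype=float)) / max(n, 1.0) for d in days]
    )


def spine_statistics(
    cfg: ProtocolConfig,
    seed: int | np.random.Generator | None = None,
    n_days: int = 12,
    rule: str = "approx_dual",
) -> dict:
    """Spine-dynamics summaries from a long approximated-dual-rule run.

    Records daily snapshots of C, P, and birth steps, then summarizes
    (a) the relative change of connection probability over one day versus
    its initial value (eliminated spines count as -1), (b) mean connection
    probability versus spine age, and (c) 5-day survival versus spine age.
    """
    rng = np.random.default_rng(seed)
    theta = _draw_raw_component(cfg, rng)
    model = make_mixed_model(theta, theta, 1.0, cfg.rX0, cfg.sigma_X)
    network = init_plastic_network(cfg, model, rng)
    pcfg = replace(cfg.plasticity, rule=rule, gamma=cfg.gamma, rX0=cfg.rX0)
    # statistics are stationary quantities: converge first, then observe
    train(network, model, cfg.burnin_days * cfg.day_length, pcfg, rng)
    snaps: dict = {}
    train(network, model, n_days * cfg.day_length, pcfg, rng,
          snapshot_days=snaps, day_length=cfg.day_length)

    # columns: initial rho, relative change (-1 when eliminated), survived flag
    rel_changes: list[tuple[float, float, float]] = []
    age_rho: list[tuple[float, float]] = []
    age_survival: list[tuple[float, float]] = []
    days = sorted(snaps)
    for d in days:
        if d + 1 not in snaps:
            continue
        C0, P0, B0 = snaps[d]["C"], snaps[d]["P"], snaps[d]["birth"]
        C1, P1 = snaps[d + 1]["C"], snaps[d + 1]["P"]
        on = C0 > 0
        rho0 = P0[on]
        present = C1[on] > 0
        rel = np.where(present, (P1[on] - rho0) / np.maximum(rho0, 1e-12), -1.0)
        rel_changes.extend(zip(rho0.tolist(), rel.tolist(), present.astype(float).tolist()))
        age_days = (d * cfg.day_length - B0[on]) / cfg.day_length
        age_rho.extend(zip(age_days.tolist(), rho0.tolist()))
        if d + 5 in snaps:
            C5 = snaps[d + 5]["C"]
            age_survival.extend(zip(age_days.tolist(), C5[on].tolist()))
    return {
        "rel_change": np.array(rel_changes),
        "age_rho": np.array(age_rho),
        "age_survival": np.array(age_survival),
        "snapshots": snaps,
        "network": network,
    }
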