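"""Headline experiments: the package's end-to-end study drivers.

Each function runs one self-contained computational experiment at the
standard operating point (p = 10 hidden states, M = 200 inputs, N = 100
outputs, unit noise) and returns a dictionary of measured quantities.  The
long learning studies use time-compressed presets that keep the
dimensionless ratios of the full-scale protocols (turnover per
environment epoch, rewiring events per day) fixed while shrinking
wall-clock cost; docs/methods.md discusses the scaling.  ``scripts/acceptance.py`` and the acceptance test suite both run
these functions.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from . import coding, evaluation, generative, network, plasticity, protocols

__all__ = [
    "posterior_equivalence_study",
    "moment_study",
    "coding_sweep_study",
    "robustness_study",
    "learning_study",
    "detailed_balance_study",
    "dynamic_environment_study",
    "spine_dynamics_study",
    "capacity_study",
]


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def posterior_equivalence_study(seed: int = 0, n_inputs: int = 1000) -> dict:
    """All-to-all network with optimal weights versus the exact Bayes oracle.

    Measures the maximum absolute deviation between group-summed softmax
    output rates and the exact posterior over 1000 sampled inputs.
    """
    rng_m, rng_e = _spawn(seed, 2)
    model = generative.make_gaussian_model(seed=rng_m)
    net = network.dense_network(model, N=100)
    ep = generative.sample_episode(model, n_inputs, seed=rng_e)
    worst = 0.0
    for t in range(ep.T):
        v = network.membrane_potentials(net, ep.rX[t], model.family)
        r = network.output_rates(v, net.rY0)
        grouped = np.array([r[net.selectivity == mu].sum() for mu in range(model.p)])
        post = network.bayes_posterior(model, ep.rX[t])
        worst = max(worst, float(np.abs(grouped - post).max()))
    return {"max_abs_deviation": worst, "n": n_inputs}


def moment_study(seed: int = 0, rho: float = 0.2, n_samples: int = 100_000) -> dict:
    """Analytic membrane-potential moments versus Monte-Carlo estimates.

    Every entry of the weight-coding and connectivity-coding moment
    expressions is compared, at 10^5 sampled potentials, against the
    sampling ensemble in which its derivation is exact: means and the
    shared-noise covariance against the actual truncated-normal generator,
    variances and the full covariance against the Gaussian tuning ensemble
    (see docs/methods.md).  Returns each |z| score and the largest one.
    """
    rngs = _spawn(seed, 4)
    n_models, n_trials = 50, n_samples // 50
    zs = {}
    for k, scheme in enumerate(("weight", "connectivity")):
        actual = evaluation.simulate_membrane_moments(
            scheme, rho, n_models=n_models, n_trials=n_trials,
            seed=rngs[2 * k], tuning_dist="truncnorm",
        )
        gauss = evaluation.simulate_membrane_moments(
            scheme, rho, n_models=n_models, n_trials=n_trials,
            seed=rngs[2 * k + 1], tuning_dist="gaussian",
        )
        mo = actual["moments"]
        checks = {
            "mean_sel": (actual, mo.mean_sel),
            "mean_nonsel": (actual, mo.mean_nonsel),
            "cov_trial": (actual, mo.cov_trial),
            "var_sel": (gauss, mo.var_sel),
            "var_nonsel": (gauss, mo.var_nonsel),
        }
        # the printed covariance: trial-only (weight), full (connectivity)
        if scheme == "weight":
            checks["cov_printed"] = (actual, mo.cov)
        else:
            checks["cov_printed"] = (gauss, mo.cov)
        for name, (src, target) in checks.items():
            key = "cov_full" if name == "cov_printed" and scheme == "connectivity" else (
                "cov_trial" if name == "cov_printed" else name
            )
            value, se = src[key]
            zs[f"{scheme}_{name}_z"] = abs(value - target) / max(se, 1e-12)
    zs["max_abs_z"] = max(zs.values())
    zs["n"] = n_samples
    return zs


def _pairwise_ensemble_accuracy(
    scheme: str, rho: float, p: int, M: int, n_trials: int, rng: np.random.Generator
) -> float:
    """Accuracy (1-eps)^(p-1) with eps measured from sampled potential pairs.

    Tuning rows are i.i.d. truncated-normal scaled by the expected
    normalization (the ensemble of the analytic derivation); each trial
    redraws tuning, wiring and input noise for one selective/non-selective
    neuron pair.  The weight-coding covariance expression keeps only the
    shared-noise part, whose exact ensemble drives the distractor with an
    independent tuning copy under the same noise; the connectivity-coding
    expression carries the full covariance, realized by sharing the
    presented tuning.
    """
    mu_tr, sd_tr = generative.truncated_normal_moments(1.0, 1.0)
    mo = evaluation.analytic_moments(mu_tr, sd_tr, 1.0, 1.0, M, scheme, rho)
    scale = 1.0 / np.sqrt(mu_tr**2 + sd_tr**2)
    a = -1.0
    fails = 0
    batch = 500
    done = 0
    while done < n_trials:
        n = min(batch, n_trials - done)
        raw = stats.truncnorm.rvs(a, np.inf, loc=1.0, scale=1.0, size=(3 * n, M), random_state=rng)
        th = raw[:n] * scale
        th_o = raw[n : 2 * n] * scale
        zeta = rng.standard_normal((n, M))
        r = th + zeta
        if scheme == "weight":
            th_alt = raw[2 * n :] * scale  # independent presented-tuning copy
            r_alt = th_alt + zeta
            w_o = mo.mu_theta**2 / rho
            c = rng.random((n, M)) < rho
            c2 = rng.random((n, M)) < rho
            u = (c * (th / rho * r - w_o)).sum(axis=1)
            ul = (c2 * (th_o / rho * r_alt - w_o)).sum(axis=1)
        else:
            gamma = rho / mo.mu_theta
            c = rng.random((n, M)) < np.clip(gamma * th, 0, 1)
            c2 = rng.random((n, M)) < np.clip(gamma * th_o, 0, 1)
            u = (c * (r / gamma - mo.mu_theta / gamma)).sum(axis=1)
            ul = (c2 * (r / gamma - mo.mu_theta / gamma)).sum(axis=1)
        fails += int(np.sum(ul > u))
        done += n
    eps_hat = fails / n_trials
    return float((1.0 - eps_hat) ** (p - 1))


def coding_sweep_study(
    seed: int = 0,
    rho_grid: tuple = (0.05, 0.1, 0.2, 0.4, 0.6, 0.8),
    n_trials: int = 20_000,
    n_network_seeds: int = 5,
) -> dict:
    """Weight coding versus connectivity coding across connection densities.

    Computes, per density: the analytic accuracy, the same quantity
    measured from sampled membrane-potential pairs, and the bootstrap
    accuracy of frozen networks (mean over seeds).  Reports the largest
    analytic-vs-sampled gap (percentage points) and the sparse-regime
    ordering measured on the frozen networks.
    """
    mu_tr, sd_tr = generative.truncated_normal_moments(1.0, 1.0)
    rngs = _spawn(seed, 3)
    out = {"rho_grid": list(rho_grid)}
    max_gap = 0.0
    frozen = {s: [] for s in ("weight", "connectivity")}
    analytic = {s: [] for s in ("weight", "connectivity")}
    for scheme in ("weight", "connectivity"):
        for rho in rho_grid:
            mo = evaluation.analytic_moments(mu_tr, sd_tr, 1.0, 1.0, 200, scheme, rho)
            acc_ana = evaluation.analytic_accuracy(mo, 10)[1]
            acc_sim = _pairwise_ensemble_accuracy(scheme, rho, 10, 200, n_trials, rngs[0])
            analytic[scheme].append(acc_ana)
            max_gap = max(max_gap, abs(acc_sim - acc_ana))
            accs = []
            for k in range(n_network_seeds):
                model = generative.make_gaussian_model(seed=rngs[1])
                gamma = rho / coding.normalized_mean_response(model)
                if scheme == "weight":
                    net = coding.build_weight_coding(model, gamma, N=100, seed=rngs[1])
                else:
                    net = coding.build_connectivity_coding(model, gamma, N=100, seed=rngs[1])
                accs.append(evaluation.simulate_accuracy(net, model, T_o=1000, seed=rngs[2]))
            frozen[scheme].append(float(np.mean(accs)))
    out["max_analytic_vs_sampled_gap"] = float(max_gap)
    out["analytic"] = analytic
    out["frozen"] = frozen
    i_sparse = rho_grid.index(0.1)
    gaps = np.array(frozen["connectivity"]) - np.array(frozen["weight"])
    out["frozen_gap_at_0.1"] = float(gaps[i_sparse])
    out["frozen_gap_at_dense"] = float(gaps[-1])
    agaps = np.array(analytic["connectivity"]) - np.array(analytic["weight"])
    out["analytic_gap_at_0.1"] = float(agaps[i_sparse])
    out["analytic_gap_at_dense"] = float(agaps[-1])
    out["n"] = n_trials
    return out


def robustness_study(seed: int = 0, n_repeats: int = 30, rho: float = 0.1) -> dict:
    """Dual coding versus cut-off pruning under input-structure variability.

    Paired comparison on the constant-response model (a quarter of inputs
    respond maximally to every state, soaking up the largest weights): the
    cut-off strategy spends its whole budget on uninformative inputs while
    dual coding keeps informative ones.  The inhomogeneous-noise variant
    (per-input noise scales spanning a 16-fold range) is reported alongside.
    """
    rngs = _spawn(seed, 4)
    diffs_struct, diffs_noise = [], []
    for k in range(n_repeats):
        m = generative.make_structured_binary_model(seed=rngs[0])
        gamma = rho / coding.normalized_mean_response(m)
        nd = coding.build_dual_coding(m, gamma, N=100, seed=rngs[0])
        nc = coding.build_cutoff_coding(m, rho, N=100, seed=rngs[0])
        es = np.random.SeedSequence(int(rngs[1].integers(2**31))).spawn(2)
        ad = evaluation.simulate_accuracy(nd, m, T_o=500, seed=np.random.default_rng(es[0]))
        ac = evaluation.simulate_accuracy(nc, m, T_o=500, seed=np.random.default_rng(es[1]))
        diffs_struct.append(ad - ac)

        m2 = generative.make_gaussian_model(seed=rngs[2])
        sig = generative.make_inhomogeneous_noise(m2.M, 1.0, 4.0, seed=rngs[2])
        m2.family = generative.GaussianFamily(sigma=sig, sigma_ref=1.0)
        gamma2 = rho / coding.normalized_mean_response(m2)
        nd2 = coding.build_dual_coding(m2, gamma2, N=100, seed=rngs[2])
        nc2 = coding.build_cutoff_coding(m2, rho, N=100, seed=rngs[2])
        ad2 = evaluation.simulate_accuracy(nd2, m2, T_o=500, seed=rngs[3])
        ac2 = evaluation.simulate_accuracy(nc2, m2, T_o=500, seed=rngs[3])
        diffs_noise.append(ad2 - ac2)
    diffs_struct = np.array(diffs_struct)
    t = stats.ttest_1samp(diffs_struct, 0.0, alternative="greater")
    return {
        "dual_minus_cutoff_structured": float(diffs_struct.mean()),
        "structured_pvalue": float(t.pvalue),
        "dual_minus_cutoff_inhomog_noise": float(np.mean(diffs_noise)),
        "n": n_repeats,
    }


def learning_study(seed: int = 0, steps: int = 500_000) -> dict:
    """Dual Hebbian learning versus weight-only learning at sparse wiring.

    Both rules start from the same random network at gamma = 0.1 (mean
    connectivity ~ 0.085).  The rewiring timescale for the compressed run
    is tau_c = 1e5 (the value of the spine-example figure), keeping total
    turnover comparable to the full-length simulation.  Reports final
    bootstrap accuracies, the creation/elimination balance after burn-in,
    and the relative connectivity drift.
    """
    rng_m, rng_d, rng_w = _spawn(seed, 3)
    model = generative.make_gaussian_model(seed=rng_m)
    cfg = protocols.ProtocolConfig(gamma=0.1)
    out = {"n": steps}
    accs = {}
    for rule, tau_c, rng in (
        ("dual_hebbian", 1e5, rng_d),
        ("weight_only", 1e6, rng_w),
    ):
        net = protocols.init_plastic_network(cfg, model, np.random.default_rng(seed + 17))
        pcfg = plasticity.PlasticityConfig(gamma=0.1, tau_c=tau_c, rule=rule)
        res = plasticity.train(net, model, steps, pcfg, rng, record_every=steps // 10)
        tail = res.metrics["accuracy"].tail(3).mean()
        accs[rule] = float(tail)
        if rule == "dual_hebbian":
            half = steps // 2
            nc, ne = res.history.counts_in_window(half, steps)
            out["turnover_ratio"] = float(nc / max(ne, 1))
            rho0 = res.history.initial_C.mean()
            out["connectivity_drift_pct"] = float(
                100 * abs(net.C.mean() - rho0) / rho0
            )
    out["accuracy_dual"] = accs["dual_hebbian"]
    out["accuracy_weight_only"] = accs["weight_only"]
    out["accuracy_gain"] = accs["dual_hebbian"] - accs["weight_only"]
    return out


def detailed_balance_study(seed: int = 0, steps: int = 20_000, tau_c: float = 10.0) -> dict:
    """Occupancy of the frozen-probability rewiring chain versus P.

    With creation rate rho/tau_c and elimination rate (1-rho)/tau_c the
    stationary occupancy of each pair is rho; thinned samples (5*tau_c
    apart) are pooled into a chi-square goodness-of-fit over pairs.
    """
    rng_p, rng_c = _spawn(seed, 2)
    shape = (20, 20)
    P = rng_p.uniform(0.1, 0.9, size=shape)
    C = (rng_p.random(shape) < P).astype(float)
    net = network.Network(
        C=C, W=C.copy(), P=P, selectivity=network.selectivity_map(2, shape[0]), p=2
    )
    cfg = plasticity.PlasticityConfig(gamma=0.5, tau_c=tau_c)
    gap = int(5 * tau_c)
    counts = np.zeros(shape)
    n_samp = 0
    for step in range(steps):
        plasticity.rewire(net, cfg, rng_c, step)
        if step % gap == 0:
            counts += net.C
            n_samp += 1
    chi2 = float(np.sum((counts - n_samp * P) ** 2 / (n_samp * P * (1 - P))))
    dof = P.size
    return {
        "chi2": chi2,
        "dof": dof,
        "pvalue": float(stats.chi2.sf(chi2, dof)),
        "n": n_samp * P.size,
    }


def dynamic_environment_study(
    seed: int = 0, T2: int = 10_000, epochs: int = 20, burnin_epochs: int = 4
) -> dict:
    """Dual Hebbian versus weight-only learning in a switching environment.

    The variable half of the input structure is redrawn every T2 steps.
    The compressed preset multiplies the learning rates by the compression
    factor (eta_x = 0.1, eta_rho = 0.01) and keeps tau_c/T2 = 10, so
    learning progress and turnover per epoch match the full-scale run.
    The first epochs contain the global convergence transient, during
    which *any* rule's post-switch accuracy rises; they are excluded, and
    the early-phase (trough) trend is the difference between the last and
    first thirds of the remaining epochs.  Both rules see the same
    environment (shared seed).  Also reports the final
    connectivity-readout model errors against the constant and variable
    components.
    """
    out = {"n": T2 * epochs}
    third = max((epochs - burnin_epochs) // 3, 1)
    for rule in ("dual_hebbian", "weight_only"):
        pc = plasticity.PlasticityConfig(
            gamma=0.6, eta_x=0.1, eta_rho=0.01, tau_c=10.0 * T2, rule=rule
        )
        cfg = protocols.ProtocolConfig(
            gamma=0.6, T2=T2, epochs=epochs, eval_window=4000, kappa_m=0.5, plasticity=pc
        )
        r = protocols.run_dynamic_environment(cfg, rule, seed=seed)
        early = r["early_accuracy"][burnin_epochs:]
        tag = "dual" if rule == "dual_hebbian" else "weight_only"
        out[f"early_gain_{tag}"] = float(early[-third:].mean() - early[:third].mean())
        out[f"early_final_{tag}"] = float(early[-third:].mean())
        out[f"early_{tag}"] = r["early_accuracy"].tolist()
        if rule == "dual_hebbian":
            out["conn_error_const"] = r["errors"]["connectivity_only_vs_const"]
            out["conn_error_var"] = r["errors"]["connectivity_only_vs_var"]
    return out


def spine_dynamics_study(seed: int = 0, day_length: int = 10_000) -> dict:
    """Spine statistics and training-protocol survival under the
    approximated dual rule (compressed days; tau_c scaled with the day so
    per-day turnover matches the full-scale run).

    Reports: 5-day survival of young versus old spines, the one-day
    relative drift of connection probability for low- versus high-rho
    surviving spines, and the day-7 survival of new and pre-existing spines
    under training versus control (plus the kappa -> 1 null arm, where the
    training structure equals the control structure).
    """
    pc = plasticity.PlasticityConfig(gamma=0.6, eta_rho=1e-4, tau_c=3 * day_length, rule="approx_dual")
    cfg = protocols.ProtocolConfig(
        gamma=0.6, day_length=day_length, burnin_days=20, training_days=8, plasticity=pc
    )
    stat_cfg = protocols.ProtocolConfig(
        gamma=0.6, day_length=day_length, burnin_days=30, training_days=8, plasticity=pc
    )
    st = protocols.spine_statistics(stat_cfg, seed=seed, n_days=10)
    rc = st["rel_change"]
    surv = rc[rc[:, 2] == 1]
    # drift statements concern the surviving cloud (eliminated spines sit
    # at relative change -1 and are summarized by the elimination rates)
    drift_low = float(surv[surv[:, 0] < 0.2][:, 1].mean())
    drift_high = float(surv[surv[:, 0] >= 0.8][:, 1].mean())
    elim_low = float((rc[rc[:, 0] < 0.2][:, 2] == 0).mean())
    elim_high = float((rc[rc[:, 0] >= 0.8][:, 2] == 0).mean())
    asur = st["age_survival"]
    young = float(asur[asur[:, 0] < 2][:, 1].mean())
    old = float(asur[asur[:, 0] >= 5][:, 1].mean())

    days7 = [7]
    runs = protocols.run_training_arms(
        cfg,
        seed,
        {
            "control": dict(training=False),
            "training": dict(training=True, kappa_similarity=0.0),
            "training_kappa1": dict(training=True, kappa_similarity=1.0),
        },
    )
    arms = {
        name: {
            "new_day7": float(protocols.survival_curve(r["snapshots"], "new", days7)[0]),
            "pre_day7": float(protocols.survival_curve(r["snapshots"], "pre", days7)[0]),
        }
        for name, r in runs.items()
    }
    return {
        "survival_young": young,
        "survival_old": old,
        "drift_low_rho": drift_low,
        "drift_high_rho": drift_high,
        "elim_rate_low_rho": elim_low,
        "elim_rate_high_rho": elim_high,
        "new_effect": arms["training"]["new_day7"] - arms["control"]["new_day7"],
        "pre_effect": arms["training"]["pre_day7"] - arms["control"]["pre_day7"],
        "new_effect_kappa1": arms["training_kappa1"]["new_day7"] - arms["control"]["new_day7"],
        "arms": arms,
        "n": (cfg.burnin_days + cfg.training_days) * day_length,
    }


def capacity_study() -> dict:
    """Break-even per-synapse capacity at the sparse cortical operating point.

    At connection probability 0.06 the wiring itself stores as much
    information as weights with H(0.06)/0.06 nats (~5.46 bits) per synapse,
    above the ~4.7 bits estimated for single synapses, so connectivity is
    the dominant substrate there.
    """
    cap = evaluation.info_capacity(200, 100, 0.06)
    return {
        "break_even_bits": cap.break_even_bits,
        "break_even_b": cap.break_even_b,
        "n": 200 * 100,
    }
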