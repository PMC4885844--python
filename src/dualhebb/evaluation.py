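"""Quantitative read-outs: accuracy, transfer entropy, model error,
connectivity optimality, analytic moment theory, and information capacity.

Decoding accuracy is measured with a bootstrap: selectivity groups are
assigned from one window of activity and scored on the next.  Transfer
entropy and the KL-based connectivity optimality both use the true tuning
parameters, so they measure what the wiring itself transmits rather than
what the weights have learned.  The analytic theory approximates the
membrane potential of selective/non-selective output neurons as a bivariate
Gaussian and turns its moments into an error probability, which is how
weight coding and connectivity coding are compared without simulation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, ndtr

from .families import GaussianFamily, PoissonFamily
from .generative import ExternalModel
from .network import Network, membrane_potentials, output_rates

__all__ = [
    "assign_selectivity",
    "estimate_accuracy",
    "bootstrap_accuracy",
    "transfer_entropy",
    "model_error",
    "KLEvaluator",
    "kl_gap",
    "info_gain",
    "info_gain_profile",
    "hillclimb_connectivity",
    "Moments",
    "analytic_moments",
    "analytic_accuracy",
    "simulate_membrane_moments",
    "info_capacity",
    "te_gradient_alignment",
]

T_O_DEFAULT = 1000


# ---------------------------------------------------------------------------
# accuracy
# ---------------------------------------------------------------------------

def assign_selectivity(s: np.ndarray, rY: np.ndarray, p: int) -> np.ndarray:
    """Assign each output neuron to the state maximizing its conditional rate.

    Ties go to the lowest state index.  Returns a length-N array of states.
    """
    s = np.asarray(s)
    rY = np.asarray(rY)
    if len(s) == 0:
        raise ValueError("empty activity window")
    sums = np.zeros((p, rY.shape[1]))
    counts = np.zeros(p)
    np.add.at(sums, s, rY)
    np.add.at(counts, s, 1.0)
    means = np.where(counts[:, None] > 0, sums / np.maximum(counts[:, None], 1.0), -np.inf)
    return np.argmax(means, axis=0)


def estimate_accuracy(s: np.ndarray, rY: np.ndarray, selectivity: np.ndarray, p: int) -> float:
    """Fraction of steps whose own-state group mean strictly beats all others.

    Steps whose state has no assigned neurons count as failures; empty
    groups never win.
    """
    s = np.asarray(s)
    rY = np.asarray(rY)
    G = np.zeros((p, rY.shape[1]))
    for mu in range(p):
        members = selectivity == mu
        n = members.sum()
        if n:
            G[mu, members] = 1.0 / n
    gm = rY @ G.T  # (T, p) group-mean rates
    has = np.array([np.any(selectivity == mu) for mu in range(p)])
    gm[:, ~has] = -np.inf
    own = gm[np.arange(len(s)), s]
    other = gm.copy()
    other[np.arange(len(s)), s] = -np.inf
    best_other = other.max(axis=1)
    ok = (own > best_other) & has[s]
    return float(np.mean(ok))


def bootstrap_accuracy(s: np.ndarray, rY: np.ndarray, p: int, T_o: int = T_O_DEFAULT) -> float:
    """Assign selectivity on the first ``T_o`` steps, score on the next."""
    s = np.asarray(s)
    if len(s) < 2 * T_o:
        raise ValueError("need at least 2*T_o steps of activity")
    sel = assign_selectivity(s[:T_o], rY[:T_o], p)
    return estimate_accuracy(s[T_o : 2 * T_o], rY[T_o : 2 * T_o], sel, p)


def simulate_accuracy(
    network: Network,
    model: ExternalModel,
    T_o: int = T_O_DEFAULT,
    seed: int | np.random.Generator | None = None,
    family=None,
) -> float:
    """Run the static network for ``2*T_o`` steps and bootstrap-score it."""
    from .generative import sample_episode

    fam = family if family is not None else model.family
    rng = np.random.default_rng(seed)
    ep = sample_episode(model, 2 * T_o, rng, fam)
    rY = np.empty((ep.T, network.N))
    for t in range(ep.T):
        v = membrane_potentials(network, ep.rX[t], fam)
        rY[t] = output_rates(v, network.rY0)
    return bootstrap_accuracy(ep.s, rY, network.p, T_o)


# ---------------------------------------------------------------------------
# transfer entropy
# ---------------------------------------------------------------------------

def _group_posteriors(
    model: ExternalModel,
    C: np.ndarray,
    selectivity: np.ndarray,
    g: np.ndarray,
    family,
    normalize: bool = True,
) -> np.ndarray:
    """Group-averaged posterior p~(mu) for a batch of sufficient stats g (T, M).

    Each output neuron decodes from its own connected subset with the true
    parameters; the group estimate averages, over neurons selective for mu,
    their posterior mass on mu.  ``normalize`` renormalizes over states
    (needed when a proper distribution is required, e.g. for entropies).
    """
    p, M = model.theta.shape
    N = C.shape[0]
    q = family.h(model.theta)
    alpha_q = np.broadcast_to(family.alpha(q), (p, M))
    CQ = (C[:, None, :] * q[None, :, :]).reshape(N * p, M)
    Aterm = C @ alpha_q.T  # (N, p)
    L = (g @ CQ.T).reshape(len(g), N, p) - Aterm[None, :, :]
    L -= L.max(axis=2, keepdims=True)
    post = np.exp(L)
    post /= post.sum(axis=2, keepdims=True)
    diag = post[:, np.arange(N), selectivity]  # (T, N): own-state mass
    Gmat = np.zeros((p, N))
    for mu in range(p):
        members = selectivity == mu
        if members.any():
            Gmat[mu, members] = 1.0 / members.sum()
    ptil = diag @ Gmat.T  # (T, p)
    if normalize:
        ptil /= np.maximum(ptil.sum(axis=1, keepdims=True), 1e-300)
    return ptil


def transfer_entropy(
    model: ExternalModel,
    network: Network,
    n_samples: int = 2000,
    seed: int | np.random.Generator | None = None,
    family=None,
    batch: int = 500,
) -> float:
    """Monte-Carlo estimate of TE = <H(s) - H(s | r_X, C)> in nats.

    The conditional posterior is computed with the true tuning parameters
    (the ceiling the wiring allows, independent of learned weights).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    fam = family if family is not None else model.family
    rng = np.random.default_rng(seed)
    p = model.p
    H_cond = 0.0
    done = 0
    while done < n_samples:
        n = min(batch, n_samples - done)
        s = rng.integers(p, size=n)
        rX = fam.sample(model.theta[s], rng)
        ptil = _group_posteriors(model, network.C, network.selectivity, fam.g(rX), fam)
        H_cond += -np.sum(ptil * np.log(np.maximum(ptil, 1e-300)))
        done += n
    return float(np.log(p) - H_cond / n_samples)


# ---------------------------------------------------------------------------
# model error
# ---------------------------------------------------------------------------

def model_error(
    model: ExternalModel,
    network: Network,
    mode: str = "combined",
    selectivity: np.ndarray | None = None,
    theta_ref: np.ndarray | None = None,
) -> float:
    """Mean squared error between the rescaled read-out of the synaptic
    structure and the true tuning matrix.

    mode 'combined' reads ``sum_i c*w`` per group, 'connectivity_only' reads
    ``sum_i c``, 'weight_only' reads the mean weight over existing
    connections.  Each estimated state row is rescaled to root-mean-square
    ``rX0`` before comparison, so global weight scalings drop out.
    ``theta_ref`` overrides the comparison target (e.g. a mixture component).
    """
    if mode not in ("combined", "connectivity_only", "weight_only"):
        raise ValueError("unknown model-error mode")
    sel = selectivity if selectivity is not None else network.selectivity
    p, M = model.theta.shape
    theta_bar = np.zeros((p, M))
    for mu in range(p):
        members = np.flatnonzero(sel == mu)
        if len(members) == 0:
            raise ValueError(f"no output neurons selective for state {mu}")
        Csub = network.C[members]
        if mode == "connectivity_only":
            theta_bar[mu] = Csub.sum(axis=0)
        elif mode == "combined":
            theta_bar[mu] = (Csub * network.W[members]).sum(axis=0)
        else:
            num = (Csub * network.W[members]).sum(axis=0)
            den = Csub.sum(axis=0)
            theta_bar[mu] = np.where(den > 0, num / np.maximum(den, 1.0), 0.0)
    rms = np.sqrt(np.mean(theta_bar**2, axis=1, keepdims=True))
    theta_tilde = np.where(rms > 0, model.rX0 * theta_bar / np.maximum(rms, 1e-300), 0.0)
    target = model.theta if theta_ref is None else np.asarray(theta_ref)
    return float(np.mean((theta_tilde - target) ** 2))


# ---------------------------------------------------------------------------
# KL-divergence connectivity optimality
# ---------------------------------------------------------------------------

class KLEvaluator:
    """Closed-form evaluator of the posterior-divergence I(C_all, C).

    After integrating the Gaussian input noise, the group-averaged posterior
    given true state nu depends on C only through the per-neuron exponents
    ``E_i[mu, nu] = sum_j c_ij theta_mu_j theta_nu_j / sigma_j^2``; the
    divergence is the state-averaged KL between the dense-network posterior
    and the one obtained from C.
    """

    def __init__(self, model: ExternalModel, selectivity: np.ndarray):
        fam = model.family
        if not isinstance(fam, GaussianFamily):
            raise ValueError("closed-form divergence requires a Gaussian model")
        self.S = model.theta / fam.sigma  # (p, M) noise-scaled tuning
        self.selectivity = np.asarray(selectivity)
        self.p, self.M = model.theta.shape
        self.N = len(self.selectivity)
        E_all = self.S @ self.S.T  # (p, p)
        self.post_all = self._softmax_cols(E_all)
        self.group_size = np.array(
            [(self.selectivity == mu).sum() for mu in range(self.p)], dtype=float
        )
        if np.any(self.group_size == 0):
            raise ValueError("every state needs at least one selective neuron")

    @staticmethod
    def _softmax_cols(E: np.ndarray) -> np.ndarray:
        """Softmax over axis 0 (estimated state mu), per true state nu."""
        Z = E - E.max(axis=0, keepdims=True)
        e = np.exp(Z)
        return e / e.sum(axis=0, keepdims=True)

    def exponents(self, C: np.ndarray) -> np.ndarray:
        return np.einsum("ij,mj,nj->imn", C, self.S, self.S, optimize=True)

    def neuron_posteriors(self, E: np.ndarray) -> np.ndarray:
        Z = E - E.max(axis=1, keepdims=True)
        e = np.exp(Z)
        return e / e.sum(axis=1, keepdims=True)

    def group_posterior(self, post: np.ndarray) -> np.ndarray:
        """p~[mu, nu]: group-averaged own-state posterior mass.

        Kept unnormalized (the group averages of per-neuron posteriors sum
        only approximately to one): renormalizing changes the sign of the
        per-connection information gain and is not part of the divergence
        as defined.
        """
        ptil = np.zeros((self.p, self.p))
        for mu in range(self.p):
            members = self.selectivity == mu
            ptil[mu] = post[members, mu, :].mean(axis=0)
        return ptil

    def divergence_from_group_posterior(self, ptil: np.ndarray) -> float:
        ratio = np.log(self.post_all) - np.log(np.maximum(ptil, 1e-300))
        return float(np.mean(np.sum(self.post_all * ratio, axis=0)))

    def divergence(self, C: np.ndarray) -> float:
        post = self.neuron_posteriors(self.exponents(C))
        return self.divergence_from_group_posterior(self.group_posterior(post))


def kl_gap(
    model: ExternalModel,
    C: np.ndarray,
    selectivity: np.ndarray,
    mode: str = "closed_form",
    n_samples: int = 2000,
    seed: int | np.random.Generator | None = None,
) -> float:
    """State-averaged KL divergence between dense and sparse decoding.

    'closed_form' integrates the Gaussian noise analytically;
    'monte_carlo' averages the group posteriors over sampled inputs.
    """
    ev = KLEvaluator(model, selectivity)
    if mode == "closed_form":
        return ev.divergence(np.asarray(C, dtype=float))
    if mode != "monte_carlo":
        raise ValueError("mode must be 'closed_form' or 'monte_carlo'")
    fam = model.family
    rng = np.random.default_rng(seed)
    p = model.p
    N = C.shape[0]
    C_all = np.ones_like(np.asarray(C, dtype=float))
    ptil_sparse = np.zeros((p, p))
    ptil_dense = np.zeros((p, p))
    for nu in range(p):
        rX = fam.sample(np.broadcast_to(model.theta[nu], (n_samples, model.M)), rng)
        g = fam.g(rX)
        ptil_sparse[:, nu] = _group_posteriors(
            model, np.asarray(C, float), selectivity, g, fam, normalize=False
        ).mean(axis=0)
        ptil_dense[:, nu] = _group_posteriors(
            model, C_all, selectivity, g, fam, normalize=False
        ).mean(axis=0)
    ratio = np.log(np.maximum(ptil_dense, 1e-300)) - np.log(np.maximum(ptil_sparse, 1e-300))
    return float(np.mean(np.sum(ptil_dense * ratio, axis=0)))


def info_gain_profile(
    model: ExternalModel,
    neuron: int,
    N: int = 100,
    n_structures: int = 200,
    rho: float = 0.1,
    seed: int | np.random.Generator | None = None,
    selectivity: np.ndarray | None = None,
) -> np.ndarray:
    """Information gain of adding each single input connection to one neuron.

    For every input j, returns the mean reduction in I(C_all, C) achieved by
    adding connection (neuron, j) to random structures of density ``rho``
    (pairs already connected contribute zero, as adding is a no-op there).
    """
    from .network import selectivity_map

    if n_structures < 1:
        raise ValueError("n_structures must be >= 1")
    sel = selectivity if selectivity is not None else selectivity_map(model.p, N)
    ev = KLEvaluator(model, sel)
    rng = np.random.default_rng(seed)
    mu_i = sel[neuron]
    gains = np.zeros(model.M)
    gsize = (sel == mu_i).sum()
    for _ in range(n_structures):
        C = (rng.random((N, model.M)) < rho).astype(float)
        E = ev.exponents(C)
        post = ev.neuron_posteriors(E)
        raw = ev.group_posterior(post)
        base = ev.divergence_from_group_posterior(raw)
        for j in range(model.M):
            if C[neuron, j] == 1:
                continue
            E_i = E[neuron] + np.outer(ev.S[:, j], ev.S[:, j])
            Z = E_i - E_i.max(axis=0, keepdims=True)
            e = np.exp(Z)
            post_i = e / e.sum(axis=0, keepdims=True)
            raw2 = raw.copy()
            raw2[mu_i] += (post_i[mu_i, :] - post[neuron, mu_i, :]) / gsize
            gains[j] += base - ev.divergence_from_group_posterior(raw2)
    return gains / n_structures


def info_gain(
    model: ExternalModel,
    i: int,
    j: int,
    n_structures: int = 200,
    rho: float = 0.1,
    seed: int | np.random.Generator | None = None,
    N: int = 100,
    selectivity: np.ndarray | None = None,
) -> float:
    """Mean information gain of a single connection (i, j) over random wiring."""
    from .network import selectivity_map

    sel = selectivity if selectivity is not None else selectivity_map(model.p, N)
    ev = KLEvaluator(model, sel)
    rng = np.random.default_rng(seed)
    total = 0.0
    for _ in range(n_structures):
        C = (rng.random((N, model.M)) < rho).astype(float)
        base = ev.divergence(C)
        C2 = C.copy()
        C2[i, j] = 1.0
        total += base - ev.divergence(C2)
    return total / n_structures


def hillclimb_connectivity(
    model: ExternalModel,
    N: int,
    density: float,
    restarts: int = 3,
    seed: int | np.random.Generator | None = None,
    max_proposals: int = 2000,
    patience: int = 300,
    selectivity: np.ndarray | None = None,
) -> np.ndarray:
    """Greedy single-swap descent on I(C_all, C) at fixed connection count.

    Random swap proposals (drop one existing connection, add one absent) are
    accepted when the divergence decreases; the best structure over
    ``restarts`` random initializations is returned.  The result is a lower
    bound on what the optimal structure could achieve, not a certificate.
    """
    from .network import selectivity_map

    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    sel = selectivity if selectivity is not None else selectivity_map(model.p, N)
    ev = KLEvaluator(model, sel)
    rng = np.random.default_rng(seed)
    K = int(round(density * N * model.M))
    best_C, best_I = None, np.inf
    for _ in range(max(restarts, 1)):
        flat = rng.permutation(N * model.M)
        C = np.zeros(N * model.M)
        C[flat[:K]] = 1.0
        C = C.reshape(N, model.M)
        if K == N * model.M:
            return C
        cur = ev.divergence(C)
        stall = 0
        for _ in range(max_proposals):
            if stall >= patience:
                break
            on = np.flatnonzero(C.ravel() == 1)
            off = np.flatnonzero(C.ravel() == 0)
            a = int(on[rng.integers(len(on))])
            b = int(off[rng.integers(len(off))])
            C.ravel()[a] = 0.0
            C.ravel()[b] = 1.0
            new = ev.divergence(C)
            if new < cur:
                cur = new
                stall = 0
            else:
                C.ravel()[a] = 1.0
                C.ravel()[b] = 0.0
                stall += 1
        if cur < best_I:
            best_I, best_C = cur, C.copy()
    return best_C


# ---------------------------------------------------------------------------
# analytic moment theory (Gaussian family)
# ---------------------------------------------------------------------------

@dataclass
class Moments:
    """Bivariate-Gaussian description of (u_selective, u_nonselective).

    ``cov`` is the covariance entering the error probability; it splits into
    ``cov_trial`` (shared input noise on a single trial) and ``cov_model``
    (tuning heterogeneity across model draws).  The weight-coding expression
    keeps only the trial part; the connectivity-coding expression carries
    both.
    """

    scheme: str
    rho: float
    mu_theta: float
    sigma_theta: float
    mean_sel: float
    mean_nonsel: float
    var_sel: float
    var_nonsel: float
    cov_trial: float
    cov_model: float
    cov: float


def analytic_moments(
    mu_tuning: float,
    sigma_tuning: float,
    sigma_X: float,
    rX0: float,
    M: int,
    scheme: str,
    rho: float,
) -> Moments:
    """Moments of the membrane potential under the two coding schemes.

    ``mu_tuning``/``sigma_tuning`` are the mean and sd of the *unnormalized*
    tuning distribution (for a truncated normal, its post-truncation
    moments); per-state RMS normalization then fixes the normalized tuning
    moments to ``mu_theta = mu*rX0/sqrt(mu^2+sd^2)`` and
    ``sigma_theta^2 = sd^2*rX0^2/(mu^2+sd^2)``, so that
    ``mu_theta^2 + sigma_theta^2 = rX0^2``.
    """
    if scheme not in ("weight", "connectivity"):
        raise ValueError("scheme must be 'weight' or 'connectivity'")
    if rho <= 0:
        raise ValueError("rho must be positive")
    s2 = sigma_X**2
    norm = np.sqrt(mu_tuning**2 + sigma_tuning**2)
    mu_t = mu_tuning * rX0 / norm
    sg2 = sigma_tuning**2 * rX0**2 / norm**2
    mean_sel = M * sg2 / s2
    cov_trial = M * mu_t**2 / s2
    if scheme == "weight":
        var_sel = M * (mu_t**2 + sg2) / (rho * s2) + M * sg2 * (
            2 * (2 * mu_t**2 + sg2) + (1 - rho) * sg2
        ) / (rho * s2**2)
        var_nonsel = M * (mu_t**2 + sg2) / (rho * s2) + M * sg2 * (2 * mu_t**2 + sg2) / (
            rho * s2**2
        )
        cov_model = 2 * M * mu_t**2 * sg2 / s2**2
        cov = cov_trial
    else:
        gamma = rho * s2 / mu_t
        var_sel = M * mu_t / gamma + M * sg2 * (mu_t * s2 - gamma * sg2) / (gamma * s2**2)
        var_nonsel = M * mu_t / gamma + M * mu_t * sg2 / (gamma * s2)
        cov_model = M * mu_t**2 * sg2 / s2**2
        cov = cov_trial + cov_model
    return Moments(
        scheme=scheme,
        rho=rho,
        mu_theta=mu_t,
        sigma_theta=float(np.sqrt(sg2)),
        mean_sel=mean_sel,
        mean_nonsel=0.0,
        var_sel=var_sel,
        var_nonsel=var_nonsel,
        cov_trial=cov_trial,
        cov_model=cov_model,
        cov=cov,
    )


def analytic_accuracy(moments: Moments, p: int) -> tuple[float, float, float]:
    """(error probability, accuracy, CV) from the bivariate Gaussian.

    A trial fails against one distractor when the non-selective potential
    exceeds the selective one; with ``p-1`` independent distractors the
    accuracy is ``(1-eps_w)**(p-1)``.  CV is the signal-term coefficient of
    variation ``sqrt(var_sel)/mean_sel``.
    """
    dm = moments.mean_sel - moments.mean_nonsel
    dv = moments.var_sel + moments.var_nonsel - 2.0 * moments.cov
    if dv <= 0:
        raise ValueError("non-positive variance of the potential difference")
    eps_w = float(ndtr(-dm / np.sqrt(dv)))
    accuracy = (1.0 - eps_w) ** (p - 1)
    cv = float(np.sqrt(moments.var_sel) / moments.mean_sel)
    return eps_w, accuracy, cv


def simulate_membrane_moments(
    scheme: str,
    rho: float,
    M: int = 200,
    mu_M: float = 1.0,
    sigma_M: float = 1.0,
    sigma_X: float = 1.0,
    rX0: float = 1.0,
    n_models: int = 50,
    n_trials: int = 2000,
    seed: int | np.random.Generator | None = None,
    tuning_dist: str = "truncnorm",
) -> dict:
    """Monte-Carlo membrane-potential moments for one coding scheme.

    ``tuning_dist`` selects the ensemble the tuning rows are drawn from:
    'truncnorm' is the actual generator (truncated normal, RMS-normalized
    per row), under which the derivations of the means and of the
    shared-noise (trial) covariance are exact; 'gaussian' draws the
    normalized tuning directly from N(mu_theta, sigma_theta), the
    assumption under which the variance and full-covariance expressions
    are exact.  Trials redraw connections and input noise.  Variances are
    totals over trials and tuning draws; the trial covariance is the
    within-model covariance (shared input noise), the full covariance adds
    the between-model part.  Standard errors come from a jackknife over
    tuning draws.
    """
    from scipy import stats as st

    from .generative import truncated_normal_moments

    if tuning_dist not in ("truncnorm", "gaussian"):
        raise ValueError("tuning_dist must be 'truncnorm' or 'gaussian'")
    rng = np.random.default_rng(seed)
    s2 = sigma_X**2
    mu_tr, sd_tr = truncated_normal_moments(mu_M, sigma_M)
    mo = analytic_moments(mu_tr, sd_tr, sigma_X, rX0, M, scheme, rho)
    a = (0.0 - mu_M) / sigma_M

    per_model = []  # (mean_u, mean_ul, m2_u, m2_ul, cov_within)
    for _ in range(n_models):
        if tuning_dist == "truncnorm":
            raw = st.truncnorm.rvs(
                a, np.inf, loc=mu_M, scale=sigma_M, size=(2, M), random_state=rng
            )
            raw *= rX0 / np.sqrt(np.mean(raw**2, axis=1, keepdims=True))
        else:
            raw = mo.mu_theta + mo.sigma_theta * rng.standard_normal((2, M))
        th, th_other = raw  # presented-state row / non-selective neuron's row
        zeta = rng.standard_normal((n_trials, M))
        r = th[None, :] + sigma_X * zeta
        if scheme == "weight":
            w_sel = th / (rho * s2)
            w_non = th_other / (rho * s2)
            w_o = mo.mu_theta**2 / (rho * s2)
            c_sel = rng.random((n_trials, M)) < rho
            c_non = rng.random((n_trials, M)) < rho
            u = (c_sel * (w_sel[None, :] * r - w_o)).sum(axis=1)
            ul = (c_non * (w_non[None, :] * r - w_o)).sum(axis=1)
        else:
            gamma = rho * s2 / mo.mu_theta
            w_o = mo.mu_theta / gamma
            p_sel = np.clip(gamma * th / s2, 0.0, 1.0)
            p_non = np.clip(gamma * th_other / s2, 0.0, 1.0)
            c_sel = rng.random((n_trials, M)) < p_sel[None, :]
            c_non = rng.random((n_trials, M)) < p_non[None, :]
            u = (c_sel * (r / gamma - w_o)).sum(axis=1)
            ul = (c_non * (r / gamma - w_o)).sum(axis=1)
        per_model.append(
            (u.mean(), ul.mean(), (u**2).mean(), (ul**2).mean(),
             np.mean(u * ul) - u.mean() * ul.mean(), u.mean() * ul.mean())
        )

    per_model = np.array(per_model)  # columns: a, b, m2_u, m2_ul, cov_w, a*b

    def stat_vector(means):
        a, b, c, d, e, f = means
        return np.array([a, b, c - a**2, d - b**2, e, e + f - a * b])

    total = per_model.sum(axis=0)
    value = stat_vector(total / n_models)
    # jackknife over tuning draws: stable SEs for the nonlinear statistics
    loo = (total[None, :] - per_model) / (n_models - 1)
    jack = np.array([stat_vector(row) for row in loo])
    se = np.sqrt((n_models - 1) / n_models * np.sum((jack - jack.mean(axis=0)) ** 2, axis=0))
    keys = ["mean_sel", "mean_nonsel", "var_sel", "var_nonsel", "cov_trial", "cov_full"]
    return {k: (value[i], se[i]) for i, k in enumerate(keys)} | {"moments": mo}


# ---------------------------------------------------------------------------
# information capacity
# ---------------------------------------------------------------------------

@dataclass
class Capacity:
    I_C: float
    I_C_stirling: float
    I_w: float
    break_even_b: float
    break_even_bits: float
    boundary: bool = False


def info_capacity(M: int, N: int, rho: float, b: float = 2.0) -> Capacity:
    """Information capacities of wiring vs weights for an M x N projection.

    ``I_C = log C(MN, rho*MN)`` (exact log-binomial, nats) against
    ``I_w = rho*MN*log(b)`` for ``b`` distinguishable weight states; they
    break even at ``b* = exp(H(rho)/rho)``, i.e. ``H(rho)/rho`` nats
    (``log2`` of that in bits) per synapse.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    if b < 2:
        raise ValueError("need at least two weight states")
    MN = M * N
    if rho in (0.0, 1.0):
        return Capacity(0.0, 0.0, rho * MN * np.log(b), 1.0, 0.0, boundary=True)
    K = int(round(rho * MN))
    I_C = float(gammaln(MN + 1) - gammaln(K + 1) - gammaln(MN - K + 1))
    H = -rho * np.log(rho) - (1 - rho) * np.log(1 - rho)
    b_star = float(np.exp(H / rho))
    return Capacity(
        I_C=I_C,
        I_C_stirling=float(MN * H),
        I_w=float(rho * MN * np.log(b)),
        break_even_b=b_star,
        break_even_bits=float(np.log2(b_star)),
    )


# ---------------------------------------------------------------------------
# gradient alignment of the wiring rule with transfer entropy
# ---------------------------------------------------------------------------

def te_gradient_alignment(
    model: ExternalModel,
    network: Network,
    n_samples: int = 200,
    seed: int | np.random.Generator | None = None,
    w_o: float | None = None,
    family=None,
    aggregate: str = "per_sample",
) -> float:
    """Cosine alignment between the wiring-rule update and the gradient of
    the estimated transfer entropy (Gaussian family).

    The wiring rule moves rho along ``r_Y,i [g - alpha'(rho w_o)]``; the
    transfer-entropy gradient is
    ``(1 + log(r_Y/rY0)) r_Y [g - alpha(q)/q + B(r)/q]``.  Both share the
    Hebbian ``r_Y * g`` structure.  ``aggregate='per_sample'`` returns the
    mean of single-step cosines (noisy, dominated by non-winning neurons
    whose ``1 + log r_Y`` prefactor is negative); ``'mean_update'`` returns
    the cosine of the sample-averaged update directions, which isolates the
    systematic component and is positive for a selective network.
    """
    fam = family if family is not None else model.family
    if not isinstance(fam, GaussianFamily):
        raise ValueError("alignment check is defined for the Gaussian family")
    rng = np.random.default_rng(seed)
    if network.P is None:
        P = np.full_like(network.C, network.rho_bar)
    else:
        P = network.P
    if w_o is None:
        w_o = float(network.W[network.C > 0].mean()) if network.C.any() else 1.0
    q_sel = fam.h(model.theta)[network.selectivity]  # (N, M)
    q_safe = np.where(np.abs(q_sel) > 1e-12, q_sel, 1e-12)
    alpha_over_q = fam.alpha(q_sel) / q_safe
    if aggregate not in ("per_sample", "mean_update"):
        raise ValueError("aggregate must be 'per_sample' or 'mean_update'")
    cosines = []
    sum13 = np.zeros_like(network.C)
    sum15 = np.zeros_like(network.C)
    for _ in range(n_samples):
        s = int(rng.integers(model.p))
        rX = fam.sample(model.theta[s], rng)
        v = membrane_potentials(network, rX, fam)
        rY = output_rates(v, network.rY0)
        g = fam.g(rX)
        d13 = rY[:, None] * (g[None, :] - fam.alpha_prime(P * w_o))
        rY_safe = np.maximum(rY, 1e-300)
        pref = (1.0 + np.log(rY_safe / network.rY0)) * rY
        d15 = pref[:, None] * (g[None, :] - alpha_over_q + fam.B(rX)[None, :] / q_safe)
        sum13 += d13
        sum15 += d15
        n13 = np.linalg.norm(d13)
        n15 = np.linalg.norm(d15)
        if n13 == 0 or n15 == 0:
            continue
        cosines.append(float(np.sum(d13 * d15) / (n13 * n15)))
    if aggregate == "mean_update":
        n13, n15 = np.linalg.norm(sum13), np.linalg.norm(sum15)
        if n13 == 0 or n15 == 0:
            raise ValueError("mean update directions are zero")
        return float(np.sum(sum13 * sum15) / (n13 * n15))
    if not cosines:
        raise ValueError("all update directions were zero")
    return float(np.mean(cosines))
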