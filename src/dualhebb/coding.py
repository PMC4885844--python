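"""Static coding strategies: how tuning is laid down in weights and wiring.

Five constructors build networks that represent the normalized response
matrix ``q`` in different substrates:

* weight coding       — random wiring at density ``rho = gamma*q_bar``,
                        weights proportional to ``q``;
* connectivity coding — constant weights ``1/gamma``, wiring probability
                        proportional to ``q``;
* dual coding         — both: wiring probability and weights track ``q``;
* cut-off coding      — weight coding pruned to the ``round(M*rho_o)``
                        largest weights per output neuron;
* random coding       — weights track ``q``, wiring independent of it.

``gamma`` controls sparseness; ``q_bar`` is the grand mean of ``q``.
"""

from __future__ import annotations

import numpy as np

from .families import GaussianFamily, PoissonFamily
from .generative import ExternalModel
from .network import Network, selectivity_map

__all__ = [
    "normalized_mean_response",
    "threshold_value",
    "build_weight_coding",
    "build_connectivity_coding",
    "build_dual_coding",
    "build_cutoff_coding",
    "build_random_coding",
]


def normalized_mean_response(
    model: ExternalModel,
    family: GaussianFamily | PoissonFamily | None = None,
) -> float:
    """Grand mean ``q_bar`` of the coding response parameter.

    For Gaussian models with inhomogeneous noise the reference scale
    ``sigma_ref`` is used (``q_bar = mean(theta)/sigma_ref^2``) so a handful
    of low-noise inputs cannot dominate the normalization.
    """
    fam = family if family is not None else model.family
    if isinstance(fam, GaussianFamily):
        return float(np.mean(model.theta) / fam.sigma_ref**2)
    return float(np.mean(model.coding_response()))


def threshold_value(policy: str, *, q_bar: float, gamma: float | None = None,
                    rho_o: float | None = None, rX0: float | None = None) -> float:
    """Input-threshold presets ``h_w`` used across the different experiments."""
    if policy == "qbar_over_gamma":
        return q_bar / gamma
    if policy == "qbar_over_rho":
        return q_bar / rho_o
    if policy == "rX0_over_gamma":
        return rX0 / gamma
    if policy == "zero":
        return 0.0
    raise ValueError(f"unknown h_w policy {policy!r}")


def _base(model: ExternalModel, N: int) -> tuple[np.ndarray, np.ndarray]:
    sel = selectivity_map(model.p, N)
    q_sel = model.coding_response()[sel]  # (N, M) response of each neuron's state
    return sel, q_sel


def build_weight_coding(
    model: ExternalModel,
    gamma: float,
    N: int = 100,
    seed: int | np.random.Generator | None = None,
    family: GaussianFamily | PoissonFamily | None = None,
    h_w_policy: str = "qbar_over_gamma",
    rY0: float = 1.0,
    v_d: float = 60.0,
) -> Network:
    """Random wiring at density ``gamma*q_bar``; weights ``q/rho``."""
    fam = family if family is not None else model.family
    rng = np.random.default_rng(seed)
    sel, q_sel = _base(model, N)
    q_bar = normalized_mean_response(model, fam)
    rho = min(gamma * q_bar, 1.0)
    C = (rng.random((N, model.M)) < rho).astype(float)
    W = q_sel / rho
    h_w = threshold_value(h_w_policy, q_bar=q_bar, gamma=gamma, rho_o=rho, rX0=model.rX0)
    return Network(C=C, W=W, P=np.full((N, model.M), rho), selectivity=sel, p=model.p,
                   h_w=h_w, rY0=rY0, v_d=v_d,
                   meta={"strategy": "weight", "gamma": gamma, "rho": rho, "q_bar": q_bar})


def build_connectivity_coding(
    model: ExternalModel,
    gamma: float,
    N: int = 100,
    seed: int | np.random.Generator | None = None,
    family: GaussianFamily | PoissonFamily | None = None,
    h_w_policy: str = "qbar_over_gamma",
    rY0: float = 1.0,
    v_d: float = 60.0,
) -> Network:
    """Constant weights ``1/gamma``; wiring probability ``min(gamma*q, 1)``."""
    fam = family if family is not None else model.family
    rng = np.random.default_rng(seed)
    sel, q_sel = _base(model, N)
    q_bar = normalized_mean_response(model, fam)
    P = np.clip(gamma * q_sel, 0.0, 1.0)
    C = (rng.random((N, model.M)) < P).astype(float)
    W = np.full((N, model.M), 1.0 / gamma)
    h_w = threshold_value(h_w_policy, q_bar=q_bar, gamma=gamma,
                          rho_o=float(P.mean()), rX0=model.rX0)
    return Network(C=C, W=W, P=P, selectivity=sel, p=model.p, h_w=h_w, rY0=rY0, v_d=v_d,
                   meta={"strategy": "connectivity", "gamma": gamma, "q_bar": q_bar})


def build_dual_coding(
    model: ExternalModel,
    gamma: float,
    N: int = 100,
    seed: int | np.random.Generator | None = None,
    family: GaussianFamily | PoissonFamily | None = None,
    h_w_policy: str = "qbar_over_gamma",
    rY0: float = 1.0,
    v_d: float = 60.0,
) -> Network:
    """Wiring probability and weights both proportional to ``q``.

    Weights are ``q/rho_bar`` with ``rho_bar = gamma*q_bar`` (the slight
    overestimate of realized connectivity is kept as stated).
    """
    fam = family if family is not None else model.family
    rng = np.random.default_rng(seed)
    sel, q_sel = _base(model, N)
    q_bar = normalized_mean_response(model, fam)
    rho_bar = min(gamma * q_bar, 1.0)
    P = np.clip(gamma * q_sel, 0.0, 1.0)
    C = (rng.random((N, model.M)) < P).astype(float)
    W = q_sel / rho_bar
    h_w = threshold_value(h_w_policy, q_bar=q_bar, gamma=gamma, rho_o=rho_bar, rX0=model.rX0)
    return Network(C=C, W=W, P=P, selectivity=sel, p=model.p, h_w=h_w, rY0=rY0, v_d=v_d,
                   meta={"strategy": "dual", "gamma": gamma, "rho": rho_bar, "q_bar": q_bar})


def build_cutoff_coding(
    model: ExternalModel,
    rho_o: float,
    N: int = 100,
    seed: int | np.random.Generator | None = None,
    family: GaussianFamily | PoissonFamily | None = None,
    h_w_policy: str = "qbar_over_rho",
    rY0: float = 1.0,
    v_d: float = 60.0,
) -> Network:
    """Keep exactly the ``round(M*rho_o)`` largest weights per output neuron.

    Ties are broken uniformly at random so the inbound count is exact.
    """
    if not 0.0 < rho_o <= 1.0:
        raise ValueError("rho_o must lie in (0, 1]")
    fam = family if family is not None else model.family
    rng = np.random.default_rng(seed)
    sel, q_sel = _base(model, N)
    q_bar = normalized_mean_response(model, fam)
    W = q_sel / rho_o
    k = int(round(model.M * rho_o))
    C = np.zeros((N, model.M))
    tiebreak = rng.random((N, model.M))
    for i in range(N):
        order = np.lexsort((tiebreak[i], -W[i]))
        C[i, order[:k]] = 1.0
    h_w = threshold_value(h_w_policy, q_bar=q_bar, gamma=None, rho_o=rho_o, rX0=model.rX0)
    return Network(C=C, W=W, selectivity=sel, p=model.p, h_w=h_w, rY0=rY0, v_d=v_d,
                   meta={"strategy": "cutoff", "rho_o": rho_o, "q_bar": q_bar})


def build_random_coding(
    model: ExternalModel,
    rho_o: float,
    N: int = 100,
    seed: int | np.random.Generator | None = None,
    family: GaussianFamily | PoissonFamily | None = None,
    h_w_policy: str = "qbar_over_rho",
    rY0: float = 1.0,
    v_d: float = 60.0,
) -> Network:
    """Wiring independent of tuning: ``Pr[c]=rho_o`` i.i.d.; weights ``q/rho_o``."""
    if not 0.0 < rho_o <= 1.0:
        raise ValueError("rho_o must lie in (0, 1]")
    fam = family if family is not None else model.family
    rng = np.random.default_rng(seed)
    sel, q_sel = _base(model, N)
    q_bar = normalized_mean_response(model, fam)
    C = (rng.random((N, model.M)) < rho_o).astype(float)
    W = q_sel / rho_o
    h_w = threshold_value(h_w_policy, q_bar=q_bar, gamma=None, rho_o=rho_o, rX0=model.rX0)
    return Network(C=C, W=W, P=np.full((N, model.M), rho_o), selectivity=sel, p=model.p,
                   h_w=h_w, rY0=rY0, v_d=v_d,
                   meta={"strategy": "random", "rho_o": rho_o, "q_bar": q_bar})
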