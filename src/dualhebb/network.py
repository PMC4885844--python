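"""Output-layer dynamics: membrane potentials, softmax read-out, Bayes oracle.

The output layer implements a probabilistic winner-take-all: each neuron
accumulates the evidence from its connected inputs,

    v_i = sum_j c_ij (w_ij g(r_X,j) - h_w),

and global inhibition normalizes the population through a softmax,
``r_Y,i = rY0 * exp(v_i - logsumexp(v))``, so the total output rate is
conserved at ``rY0``.  With all-to-all connectivity and weights equal to the
natural parameters ``q`` the read-out equals the exact Bayes posterior over
hidden states.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import logsumexp

from .families import GaussianFamily, PoissonFamily, family_from_dict
from .generative import ExternalModel

__all__ = [
    "Network",
    "selectivity_map",
    "membrane_potentials",
    "output_rates",
    "optimal_dense_weights",
    "dense_network",
    "bayes_posterior",
]


def selectivity_map(p: int, N: int) -> np.ndarray:
    """Constructed selectivity: neuron i represents state floor(p*i/N)."""
    return (p * np.arange(N)) // N


@dataclass
class Network:
    """Feedforward network state: connectivity, weights, connection probabilities.

    Invariants maintained by all constructors and updates: ``C`` is binary,
    ``W >= 0`` and zero wherever ``C`` is zero, ``P`` in [0, 1].
    ``rho_bar`` is the mean connectivity measured from the initial
    connection matrix; the weight-learning rule keeps using this value.
    """

    C: np.ndarray
    W: np.ndarray
    selectivity: np.ndarray
    p: int
    h_w: float = 0.0
    rY0: float = 1.0
    v_d: float = 60.0
    P: np.ndarray | None = None
    rho_bar: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        self.W = np.asarray(self.W, dtype=float) * self.C
        if self.rho_bar is None:
            self.rho_bar = float(self.C.mean())

    @property
    def N(self) -> int:
        return self.C.shape[0]

    @property
    def M(self) -> int:
        return self.C.shape[1]

    def groups(self) -> list[np.ndarray]:
        """Indices of output neurons per represented state."""
        return [np.flatnonzero(self.selectivity == mu) for mu in range(self.p)]

    def to_dict(self) -> dict:
        return {
            "C": self.C.astype(int).tolist(),
            "W": self.W.tolist(),
            "P": None if self.P is None else self.P.tolist(),
            "selectivity": self.selectivity.tolist(),
            "p": self.p,
            "h_w": self.h_w,
            "rY0": self.rY0,
            "v_d": self.v_d,
            "rho_bar": self.rho_bar,
            "meta": self.meta,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "Network":
        return cls(
            C=np.asarray(d["C"], dtype=float),
            W=np.asarray(d["W"], dtype=float),
            P=None if d["P"] is None else np.asarray(d["P"], dtype=float),
            selectivity=np.asarray(d["selectivity"], dtype=int),
            p=int(d["p"]),
            h_w=float(d["h_w"]),
            rY0=float(d["rY0"]),
            v_d=float(d["v_d"]),
            rho_bar=d["rho_bar"],
            meta=d.get("meta", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "Network":
        return cls.from_dict(json.loads(Path(path).read_text()))


def membrane_potentials(
    network: Network,
    r_X: np.ndarray,
    family: GaussianFamily | PoissonFamily,
) -> np.ndarray:
    """Summed synaptic drive per output neuron, floored at ``max(v) - |v_d|``.

    The floor bounds how far any neuron can fall below the momentary winner,
    which keeps the softmax numerically tame without affecting the ranking.
    """
    r_X = np.asarray(r_X, dtype=float)
    if r_X.shape[-1] != network.M:
        raise ValueError("input vector length does not match network")
    g = family.g(r_X)
    v = network.W @ g - network.h_w * network.C.sum(axis=1)
    return np.maximum(v, v.max() - abs(network.v_d))


def output_rates(v: np.ndarray, rY0: float = 1.0) -> np.ndarray:
    """Softmax read-out scaled to total rate ``rY0`` (max-shifted for stability)."""
    v = np.asarray(v, dtype=float)
    z = v - v.max()
    e = np.exp(z)
    return rY0 * e / e.sum()


def optimal_dense_weights(
    model: ExternalModel,
    N: int,
    family: GaussianFamily | PoissonFamily | None = None,
) -> np.ndarray:
    """Bayes-optimal weights for an all-to-all network.

    Gaussian: ``w_ij = q_{sigma_i j} = theta/sigma_X^2``.
    Poisson:  ``w_ij = log(theta_{sigma_i j}/theta_o)``.
    """
    fam = family if family is not None else model.family
    sel = selectivity_map(model.p, N)
    if isinstance(fam, PoissonFamily):
        if fam.theta_o >= model.theta.min():
            raise ValueError("theta_o must be strictly below the smallest tuning value")
        return np.log(model.theta[sel] / fam.theta_o)
    return fam.h(model.theta)[sel]


def dense_network(
    model: ExternalModel,
    N: int,
    h_w: float = 0.0,
    rY0: float = 1.0,
    v_d: float = 60.0,
    family: GaussianFamily | PoissonFamily | None = None,
) -> Network:
    """All-to-all network with the optimal weights (the Bayes read-out)."""
    W = optimal_dense_weights(model, N, family)
    return Network(
        C=np.ones((N, model.M)),
        W=W,
        selectivity=selectivity_map(model.p, N),
        p=model.p,
        h_w=h_w,
        rY0=rY0,
        v_d=v_d,
        meta={"strategy": "dense_optimal"},
    )


def bayes_posterior(
    model: ExternalModel,
    r_X: np.ndarray,
    family: GaussianFamily | PoissonFamily | None = None,
) -> np.ndarray:
    """Exact posterior over hidden states given one input-rate vector.

    Uses the exponential-family log-likelihood
    ``sum_j [q_{mu j} g(r_j) - alpha(q_{mu j})]`` with a uniform prior; the
    ``B(r)`` terms are constant across states and cancel.
    """
    fam = family if family is not None else model.family
    r_X = np.asarray(r_X, dtype=float)
    q = fam.h(model.theta)
    loglik = q @ fam.g(r_X) - fam.alpha(q).sum(axis=1)
    return np.exp(loglik - logsumexp(loglik))
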