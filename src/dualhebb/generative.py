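"""World models driving the input layer.

A hidden state ``s`` is drawn uniformly from ``p`` discrete states at every
time step, and each of the ``M`` input neurons responds with a stochastic
rate around its tuning value ``theta[s, j]``.  Constructors build the tuning
matrix for the model variants used throughout:

* :func:`make_gaussian_model` — tuning values from a truncated normal on
  [0, inf), each state row normalized to root-mean-square rate ``rX0``.
* :func:`make_poisson_model` — tuning values from a truncated log-normal,
  each state row normalized to mean rate ``rX0``.
* :func:`make_mixed_model` — normalized convex mixture of a constant and a
  variable component (dynamic environments).
* :func:`make_structured_binary_model` — a quarter of inputs constantly
  active, the rest binary high/low per state.
* :func:`make_inhomogeneous_noise` — per-input noise scales spanning
  ``[sigma_X/sigma_r, sigma_X*sigma_r)`` log-uniformly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .families import GaussianFamily, PoissonFamily, family_from_dict

__all__ = [
    "ExternalModel",
    "Episode",
    "make_gaussian_model",
    "make_poisson_model",
    "make_mixed_model",
    "make_inhomogeneous_noise",
    "make_structured_binary_model",
    "sample_episode",
    "truncated_normal_moments",
]


@dataclass
class ExternalModel:
    """Hidden-state/tuning structure: the world the network infers.

    ``theta`` is states-by-inputs (p x M); the normalized response
    ``q = h(theta)`` is derived from the emission family.
    """

    theta: np.ndarray
    family: GaussianFamily | PoissonFamily
    rX0: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2:
            raise ValueError("theta must be a p x M matrix")

    @property
    def p(self) -> int:
        return self.theta.shape[0]

    @property
    def M(self) -> int:
        return self.theta.shape[1]

    @property
    def q(self) -> np.ndarray:
        """Normalized response parameter q_{mu j} = h(theta_{mu j})."""
        return self.family.h(self.theta)

    def coding_response(self) -> np.ndarray:
        """Nonnegative response parameter used by the coding strategies.

        Gaussian: ``theta/sigma^2`` (= q).  Poisson: ``log(theta/theta_o)``,
        the positive optimal-weight parametrization.
        """
        if isinstance(self.family, PoissonFamily):
            return np.log(self.theta / self.family.theta_o)
        return self.q

    def to_dict(self) -> dict:
        return {
            "theta": self.theta.tolist(),
            "family": self.family.to_dict(),
            "rX0": self.rX0,
            "meta": self.meta,
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_dict(cls, d: dict) -> "ExternalModel":
        return cls(
            theta=np.asarray(d["theta"], dtype=float),
            family=family_from_dict(d["family"]),
            rX0=float(d["rX0"]),
            meta=d.get("meta", {}),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ExternalModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class Episode:
    """A simulated stretch of hidden states and input rates."""

    s: np.ndarray
    rX: np.ndarray

    @property
    def T(self) -> int:
        return len(self.s)

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.rX, columns=[f"r_X_{j}" for j in range(self.rX.shape[1])])
        df.insert(0, "s", self.s)
        df.insert(0, "t", np.arange(self.T))
        df.to_csv(path, index=False)


def truncated_normal_moments(mu: float, sigma: float, lower: float = 0.0) -> tuple[float, float]:
    """Mean and standard deviation of N(mu, sigma) truncated to [lower, inf)."""
    if sigma == 0:
        return mu, 0.0
    a = (lower - mu) / sigma
    mean, var = stats.truncnorm.stats(a, np.inf, loc=mu, scale=sigma, moments="mv")
    return float(mean), float(np.sqrt(var))


def _normalize_rows_rms(theta_raw: np.ndarray, rX0: float) -> np.ndarray:
    """Scale each state row so its mean-square rate equals rX0**2."""
    rms = np.sqrt(np.mean(theta_raw**2, axis=1, keepdims=True))
    if np.any(rms == 0):
        raise ValueError("a state row is identically zero; cannot normalize")
    return theta_raw * (rX0 / rms)


def make_gaussian_model(
    p: int = 10,
    M: int = 200,
    mu_M: float = 1.0,
    sigma_M: float = 1.0,
    rX0: float = 1.0,
    seed: int | np.random.Generator | None = None,
    sigma_X: float | np.ndarray = 1.0,
) -> ExternalModel:
    """Gaussian world model with truncated-normal tuning values.

    Raw tuning values are drawn i.i.d. from N(mu_M, sigma_M) truncated to
    [0, inf); each state row is then normalized to root-mean-square rate
    ``rX0``.
    """
    if p < 2:
        raise ValueError("need at least two hidden states")
    if M < 1 or rX0 <= 0 or sigma_M < 0:
        raise ValueError("invalid model parameters")
    rng = np.random.default_rng(seed)
    if sigma_M == 0:
        theta_raw = np.full((p, M), float(mu_M))
    else:
        a = (0.0 - mu_M) / sigma_M
        theta_raw = stats.truncnorm.rvs(
            a, np.inf, loc=mu_M, scale=sigma_M, size=(p, M), random_state=rng
        )
    theta = _normalize_rows_rms(theta_raw, rX0)
    fam = GaussianFamily(sigma=sigma_X)
    return ExternalModel(
        theta=theta,
        family=fam,
        rX0=rX0,
        meta={"kind": "gaussian", "mu_M": mu_M, "sigma_M": sigma_M},
    )


def make_poisson_model(
    p: int = 10,
    M: int = 200,
    mu_Mp: float = 0.0,
    sigma_Mp: float = 1.0,
    lmin: float = 0.2,
    lmax: float = 20.0,
    rX0: float = 0.3,
    seed: int | np.random.Generator | None = None,
) -> ExternalModel:
    """Poisson world model with truncated log-normal tuning values.

    Raw values are log-normal(mu_Mp, sigma_Mp) restricted to (lmin, lmax);
    each state row is normalized to mean rate ``rX0``.  The reference rate
    is fixed at half the smallest tuning value.
    """
    if p < 2:
        raise ValueError("need at least two hidden states")
    if not (0 < lmin < lmax):
        raise ValueError("require 0 < lmin < lmax")
    if rX0 <= 0:
        raise ValueError("rX0 must be positive")
    rng = np.random.default_rng(seed)
    a = (np.log(lmin) - mu_Mp) / sigma_Mp
    b = (np.log(lmax) - mu_Mp) / sigma_Mp
    log_theta = stats.truncnorm.rvs(a, b, loc=mu_Mp, scale=sigma_Mp, size=(p, M), random_state=rng)
    theta_raw = np.exp(log_theta)
    mean = np.mean(theta_raw, axis=1, keepdims=True)
    theta = theta_raw * (rX0 / mean)
    theta_o = 0.5 * float(theta.min())
    return ExternalModel(
        theta=theta,
        family=PoissonFamily(theta_o=theta_o),
        rX0=rX0,
        meta={"kind": "poisson", "mu_Mp": mu_Mp, "sigma_Mp": sigma_Mp, "lmin": lmin, "lmax": lmax},
    )


def make_mixed_model(
    theta_const: np.ndarray,
    theta_var: np.ndarray,
    kappa_m: float,
    rX0: float = 1.0,
    sigma_X: float | np.ndarray = 1.0,
) -> ExternalModel:
    """Normalized mixture ``theta = [k*theta_const + (1-k)*theta_var]/Z``.

    ``Z`` is chosen per state so the mean-square rate equals ``rX0**2``; at
    ``kappa_m`` 1 (0) the model reduces to the normalized constant
    (variable) component.
    """
    theta_const = np.asarray(theta_const, dtype=float)
    theta_var = np.asarray(theta_var, dtype=float)
    if theta_const.shape != theta_var.shape:
        raise ValueError("component shapes differ")
    if not 0.0 <= kappa_m <= 1.0:
        raise ValueError("kappa_m must lie in [0, 1]")
    combo = kappa_m * theta_const + (1.0 - kappa_m) * theta_var
    theta = _normalize_rows_rms(combo, rX0)
    return ExternalModel(
        theta=theta,
        family=GaussianFamily(sigma=sigma_X),
        rX0=rX0,
        meta={"kind": "mixed", "kappa_m": kappa_m},
    )


def make_inhomogeneous_noise(
    M: int,
    sigma_X: float = 1.0,
    sigma_r: float = 4.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Per-input noise scales ``sigma_X * exp(2*zeta*log(sigma_r))/sigma_r``.

    With ``zeta`` uniform on [0, 1) the scales are log-uniform on
    ``[sigma_X/sigma_r, sigma_X*sigma_r)`` with geometric mean ``sigma_X``.
    """
    if sigma_r < 1.0:
        raise ValueError("sigma_r must be >= 1")
    rng = np.random.default_rng(seed)
    zeta = rng.random(M)
    return sigma_X * np.exp(2.0 * zeta * np.log(sigma_r)) / sigma_r


def make_structured_binary_model(
    p: int = 10,
    M: int = 200,
    theta_const: float = 1.2,
    theta_high: float = 1.0,
    theta_low: float = 0.2,
    rX0: float = 1.0,
    seed: int | np.random.Generator | None = None,
    sigma_X: float | np.ndarray = 1.0,
) -> ExternalModel:
    """Model with a constantly active quarter of the input population.

    The first M/4 inputs respond with ``theta_const`` to every state; the
    rest take ``theta_high`` or ``theta_low`` independently with probability
    1/2 per state.  Rows are then RMS-normalized as in the Gaussian model.
    The constant group carries no information about the state yet attracts
    the largest optimal weights, which is what defeats cut-off pruning.
    """
    if not theta_low < theta_high < theta_const:
        raise ValueError("require theta_low < theta_high < theta_const")
    rng = np.random.default_rng(seed)
    n_const = M // 4
    theta_raw = np.empty((p, M))
    theta_raw[:, :n_const] = theta_const
    choice = rng.random((p, M - n_const)) < 0.5
    theta_raw[:, n_const:] = np.where(choice, theta_high, theta_low)
    theta = _normalize_rows_rms(theta_raw, rX0)
    return ExternalModel(
        theta=theta,
        family=GaussianFamily(sigma=sigma_X),
        rX0=rX0,
        meta={"kind": "structured_binary", "n_const": n_const},
    )


def sample_episode(
    model: ExternalModel,
    T: int,
    seed: int | np.random.Generator | None = None,
    family: GaussianFamily | PoissonFamily | None = None,
) -> Episode:
    """Draw ``T`` steps of (state, input-rate) pairs from the model."""
    if T < 1:
        raise ValueError("episode length must be >= 1")
    fam = family if family is not None else model.family
    rng = np.random.default_rng(seed)
    s = rng.integers(model.p, size=T)
    rX = fam.sample(model.theta[s], rng)
    return Episode(s=s, rX=rX)
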