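"""Exponential-family emission models for the input layer.

Input neurons respond to a hidden state ``mu`` with firing rates drawn from a
one-parameter exponential family

    f(r | theta) = exp[ h(theta) g(r) - A(theta) + B(r) ],

where ``theta`` is the mean-response (tuning) parameter.  The natural
parameter ``q = h(theta)`` is what an ideal decoder weights the sufficient
statistic ``g(r)`` with, so all coding strategies and learning rules are
expressed in terms of ``q``.  Two concrete families are provided:

* Gaussian rates, ``r ~ N(theta, sigma_X)`` with ``h(theta) = theta/sigma_X^2``;
  the noise scale may be a scalar or per-input vector (inhomogeneous noise).
* Poisson counts, ``r ~ Poisson(theta)`` with ``h(theta) = log(theta)``; a
  reference rate ``theta_o`` keeps the optimal weights ``log(theta/theta_o)``
  positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

__all__ = ["GaussianFamily", "PoissonFamily", "family_from_dict"]

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class GaussianFamily:
    """Gaussian emission model with (possibly per-input) noise scale.

    Parameters
    ----------
    sigma : float or ndarray
        Firing-rate noise scale ``sigma_X``; a length-M vector models
        input-dependent (inhomogeneous) noise.
    sigma_ref : float, optional
        Reference noise scale used where a single scalar is required
        (e.g. the normalized mean response ``q_bar`` of the coding module).
        Defaults to the scalar ``sigma`` or, for vector noise, the baseline
        around which the per-input scales were generated.
    """

    sigma: float | np.ndarray = 1.0
    sigma_ref: float | None = None
    name: str = field(default="gaussian", init=False)

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.sigma <= 0):
            raise ValueError("noise scale sigma must be positive")
        if self.sigma_ref is None:
            if self.sigma.ndim == 0:
                self.sigma_ref = float(self.sigma)
            else:
                # geometric mean: the scale the multiplicative noise model
                # fluctuates around
                self.sigma_ref = float(np.exp(np.mean(np.log(self.sigma))))

    @property
    def sigma_sq(self) -> np.ndarray:
        return self.sigma**2

    def h(self, theta: np.ndarray) -> np.ndarray:
        return np.asarray(theta) / self.sigma_sq

    def h_inv(self, q: np.ndarray) -> np.ndarray:
        return np.asarray(q) * self.sigma_sq

    def g(self, r: np.ndarray) -> np.ndarray:
        return np.asarray(r)

    def A(self, theta: np.ndarray) -> np.ndarray:
        return np.asarray(theta) ** 2 / (2.0 * self.sigma_sq) + np.log(self.sigma) + _LOG_SQRT_2PI

    def B(self, r: np.ndarray) -> np.ndarray:
        return -np.asarray(r) ** 2 / (2.0 * self.sigma_sq)

    def alpha(self, q: np.ndarray) -> np.ndarray:
        return self.sigma_sq * np.asarray(q) ** 2 / 2.0 + np.log(self.sigma) + _LOG_SQRT_2PI

    def alpha_prime(self, q: np.ndarray) -> np.ndarray:
        return self.sigma_sq * np.asarray(q)

    def sample(self, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        return theta + self.sigma * rng.standard_normal(theta.shape)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "sigma": self.sigma.tolist(),
            "sigma_ref": self.sigma_ref,
        }


@dataclass
class PoissonFamily:
    """Poisson emission model; episodes are integer spike counts.

    ``theta_o`` is the reference rate dividing the tuning parameter inside
    the optimal weights ``w = log(theta/theta_o)``; any value in
    ``(0, min theta)`` is valid and ``theta_o = min(theta)/2`` keeps the
    weights at least ``log 2``.
    """

    theta_o: float = 1.0
    name: str = field(default="poisson", init=False)

    def __post_init__(self) -> None:
        if self.theta_o <= 0:
            raise ValueError("reference rate theta_o must be positive")

    def h(self, theta: np.ndarray) -> np.ndarray:
        return np.log(theta)

    def h_inv(self, q: np.ndarray) -> np.ndarray:
        return np.exp(q)

    def g(self, r: np.ndarray) -> np.ndarray:
        return np.asarray(r)

    def A(self, theta: np.ndarray) -> np.ndarray:
        return np.asarray(theta, dtype=float)

    def B(self, r: np.ndarray) -> np.ndarray:
        return -gammaln(np.asarray(r, dtype=float) + 1.0)

    def alpha(self, q: np.ndarray) -> np.ndarray:
        return np.exp(q)

    def alpha_prime(self, q: np.ndarray) -> np.ndarray:
        return np.exp(q)

    def sample(self, theta: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        return rng.poisson(np.asarray(theta, dtype=float)).astype(float)

    def to_dict(self) -> dict:
        return {"name": self.name, "theta_o": self.theta_o}


def family_from_dict(d: dict) -> GaussianFamily | PoissonFamily:
    name = d["name"]
    if name == "gaussian":
        return GaussianFamily(sigma=np.asarray(d["sigma"]), sigma_ref=d.get("sigma_ref"))
    if name == "poisson":
        return PoissonFamily(theta_o=d["theta_o"])
    raise ValueError(f"unknown family {name!r}")
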