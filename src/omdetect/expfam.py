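"""Exponential-family calculus in natural coordinates.

A family is described by its sufficient statistic phi(x), log-partition
Phi(theta) and the Fenchel dual Phi*(mu).  Densities are
f_theta(x) = exp{theta' phi(x) - Phi(theta)} dH(x); the dominating measure H
is never evaluated because every public quantity is a likelihood *ratio* or a
divergence, in which dH(x) cancels.

Three concrete families are provided:

* :class:`GaussianFamily` -- N(theta, I_d): phi(x)=x, Phi(theta)=||theta||^2/2,
  mean map is the identity.  Observations with known covariance Sigma != I
  should be whitened by the caller.
* :class:`GammaFamily` -- Gamma with fixed shape alpha=1 (i.e. exponential
  with rate beta), natural parameter theta = -beta < 0, Phi(theta)=-log(-theta).
* :class:`BernoulliFamily` -- product of d independent Bernoulli coordinates
  (e.g. the edges of an Erdos-Renyi graph), theta_c = logit(p_c),
  Phi(theta) = sum_c log(1+e^{theta_c}).

The Kullback-Leibler divergence between members is
I(theta1, theta2) = Phi(theta2) - Phi(theta1) - (theta2-theta1)' grad Phi(theta1),
and B_Phi(theta1, theta2) = I(theta2, theta1) is the Bregman divergence of Phi.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "DomainError",
    "MeanDomainError",
    "ExponentialFamily",
    "GaussianFamily",
    "GammaFamily",
    "BernoulliFamily",
    "get_family",
    "MEAN_CLIP",
    "GAMMA_THETA_MAX",
]

# Boundary guards: the working parameter sets are open, but finite-sample
# estimators can land on the boundary (e.g. a Bernoulli segment of all zeros).
MEAN_CLIP = 1e-8
GAMMA_THETA_MAX = -1e-8


class DomainError(ValueError):
    """Natural parameter outside the family's natural domain."""


class MeanDomainError(DomainError):
    """Mean parameter on or outside the boundary of the mean domain."""


def _vec(x, d: int, what: str) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(x, dtype=float))
    if arr.shape != (d,):
        raise ValueError(f"{what} must have shape ({d},), got {arr.shape}")
    return arr


class ExponentialFamily:
    """Base class holding the shared natural-parameter calculus."""

    name: str = "abstract"
    natural_domain: str = ""
    #: sigma >= 0 such that -log f_theta is sigma-strongly convex on the
    #: working domain.  Documentation only; not enforced numerically.
    strong_convexity_sigma: float = 0.0

    def __init__(self, d: int):
        if d < 1:
            raise ValueError("dimension d must be a positive integer")
        self.d = int(d)

    # -- family-specific pieces -------------------------------------------
    def phi(self, x) -> np.ndarray:
        """Sufficient statistic.  All three concrete families use phi(x)=x."""
        return _vec(x, self.d, "observation")

    def log_partition(self, theta) -> float:
        raise NotImplementedError

    def dual(self, mu) -> float:
        """Fenchel conjugate Phi*(mu)."""
        raise NotImplementedError

    def mean_map(self, theta) -> np.ndarray:
        """grad Phi: natural parameter -> mean parameter."""
        raise NotImplementedError

    def inverse_mean_map(self, mu) -> np.ndarray:
        """grad Phi*: mean parameter -> natural parameter."""
        raise NotImplementedError

    def clamp_mean(self, mu, n: int | None = None) -> np.ndarray:
        """Pull mu into the open mean domain (no-op where it is all of R^d).

        `n` is the number of samples behind the mean, where known: families
        whose mean domain has a finite boundary may widen the guard for small
        samples (see :class:`BernoulliFamily`).
        """
        return _vec(mu, self.d, "mean parameter")

    def check_natural(self, theta) -> np.ndarray:
        """Validate (and return) a natural parameter; raise DomainError."""
        return _vec(theta, self.d, "natural parameter")

    def sample(self, theta, size: int, rng: np.random.Generator) -> np.ndarray:
        """Draw `size` i.i.d. observations, shape (size, d)."""
        raise NotImplementedError

    # -- shared calculus ---------------------------------------------------
    def log_likelihood_ratio(self, theta, theta0, x) -> float:
        """log f_theta(x) - log f_theta0(x); the base measure cancels."""
        theta = self.check_natural(theta)
        theta0 = self.check_natural(theta0)
        p = self.phi(x)
        return float((theta - theta0) @ p - self.log_partition(theta) + self.log_partition(theta0))

    def kl(self, theta1, theta2) -> float:
        """KL divergence I(theta1, theta2) = E_theta1 log(f_theta1/f_theta2)."""
        theta1 = self.check_natural(theta1)
        theta2 = self.check_natural(theta2)
        mu1 = self.mean_map(theta1)
        return float(
            self.log_partition(theta2)
            - self.log_partition(theta1)
            - (theta2 - theta1) @ mu1
        )

    def bregman_phi(self, theta1, theta2) -> float:
        """B_Phi(theta1, theta2) = I(theta2, theta1)."""
        return self.kl(theta2, theta1)

    def bregman_dual(self, mu1, mu2) -> float:
        """B_{Phi*}(mu1, mu2) in mean coordinates."""
        mu1 = _vec(mu1, self.d, "mu1")
        mu2 = _vec(mu2, self.d, "mu2")
        g2 = self.inverse_mean_map(mu2)
        return float(self.dual(mu1) - self.dual(mu2) - g2 @ (mu1 - mu2))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{type(self).__name__}(d={self.d})"


class GaussianFamily(ExponentialFamily):
    """Multivariate normal N(theta, I_d) with unknown mean theta."""

    name = "gaussian"
    natural_domain = "R^d"
    strong_convexity_sigma = 1.0

    def log_partition(self, theta) -> float:
        theta = self.check_natural(theta)
        return 0.5 * float(theta @ theta)

    def dual(self, mu) -> float:
        mu = _vec(mu, self.d, "mean parameter")
        return 0.5 * float(mu @ mu)

    def mean_map(self, theta) -> np.ndarray:
        return self.check_natural(theta).copy()

    def inverse_mean_map(self, mu) -> np.ndarray:
        return _vec(mu, self.d, "mean parameter").copy()

    def sample(self, theta, size, rng):
        theta = self.check_natural(theta)
        return rng.normal(loc=theta, size=(size, self.d))


class GammaFamily(ExponentialFamily):
    """Gamma with fixed shape alpha = 1: an exponential with rate beta = -theta.

    theta = -beta lives on (-inf, 0); mean mu = -1/theta = 1/beta.
    """

    name = "gamma"
    natural_domain = "theta < 0"
    strong_convexity_sigma = 0.0  # 1/theta^2 on Theta; bounded below only on compacts

    def __init__(self, d: int = 1):
        if d != 1:
            raise ValueError("GammaFamily is one-dimensional")
        super().__init__(1)

    def check_natural(self, theta) -> np.ndarray:
        theta = _vec(theta, 1, "natural parameter")
        if not np.all(theta < 0):
            raise DomainError(f"Gamma natural parameter must be negative, got {theta}")
        return theta

    def clamp_natural(self, theta) -> np.ndarray:
        """Boundary guard theta <= -1e-8 for estimators drifting to 0."""
        return np.minimum(_vec(theta, 1, "natural parameter"), GAMMA_THETA_MAX)

    def log_partition(self, theta) -> float:
        theta = self.check_natural(theta)
        return float(-np.log(-theta[0]))

    def dual(self, mu) -> float:
        mu = self.clamp_mean(mu)
        return float(-1.0 - np.log(mu[0]))

    def mean_map(self, theta) -> np.ndarray:
        theta = self.check_natural(theta)
        return -1.0 / theta

    def inverse_mean_map(self, mu) -> np.ndarray:
        mu = _vec(mu, 1, "mean parameter")
        if mu[0] <= 0:
            raise MeanDomainError(
                f"Gamma mean must be positive, got {mu[0]}; clamp before inverting"
            )
        return -1.0 / mu

    def clamp_mean(self, mu, n: int | None = None) -> np.ndarray:
        return np.maximum(_vec(mu, 1, "mean parameter"), MEAN_CLIP)

    def sample(self, theta, size, rng):
        theta = self.check_natural(theta)
        return rng.exponential(scale=-1.0 / theta[0], size=(size, 1))


class BernoulliFamily(ExponentialFamily):
    """Product of d independent Bernoulli coordinates, theta_c = logit(p_c).

    The log-partition, dual and KL are coordinate-wise sums, so this covers
    the Erdos-Renyi edge model where each edge switches on independently.
    """

    name = "bernoulli"
    natural_domain = "R^d"
    strong_convexity_sigma = 0.0  # p(1-p) is not bounded away from 0 on all of R

    def log_partition(self, theta) -> float:
        theta = self.check_natural(theta)
        return float(np.sum(np.logaddexp(0.0, theta)))

    def dual(self, mu) -> float:
        mu = self._check_mean(mu)
        return float(np.sum(mu * np.log(mu) + (1.0 - mu) * np.log1p(-mu)))

    def mean_map(self, theta) -> np.ndarray:
        theta = self.check_natural(theta)
        # logistic, stable on both tails
        return np.where(theta >= 0, 1.0 / (1.0 + np.exp(-theta)),
                        np.exp(theta) / (1.0 + np.exp(theta)))

    def inverse_mean_map(self, mu) -> np.ndarray:
        mu = self._check_mean(mu)
        return np.log(mu) - np.log1p(-mu)

    def _check_mean(self, mu) -> np.ndarray:
        mu = _vec(mu, self.d, "mean parameter")
        if np.any(mu <= 0.0) or np.any(mu >= 1.0):
            raise MeanDomainError(
                "Bernoulli mean must lie strictly inside (0, 1); clamp first"
            )
        return mu

    def clamp_mean(self, mu, n: int | None = None) -> np.ndarray:
        """Boundary guard for plug-in estimates.

        Without a sample count the guard is the fixed MEAN_CLIP.  With a
        count n the guard widens to 1/(2(n+1)) — the Krichevsky-Trofimov
        boundary values — so a short run of identical bits is not read as
        near-certainty; away from the boundary the running mean is untouched,
        and any predictable estimate preserves the likelihood-ratio
        martingale under the null.
        """
        eps = MEAN_CLIP if n is None else max(MEAN_CLIP, 1.0 / (2.0 * (n + 1.0)))
        return np.clip(_vec(mu, self.d, "mean parameter"), eps, 1.0 - eps)

    def sample(self, theta, size, rng):
        p = self.mean_map(theta)
        return (rng.random((size, self.d)) < p).astype(float)


_FAMILIES = {
    "gaussian": GaussianFamily,
    "gamma": GammaFamily,
    "bernoulli": BernoulliFamily,
}


def get_family(name: str, d: int = 1) -> ExponentialFamily:
    """Look a family up by name ("gaussian" | "gamma" | "bernoulli")."""
    try:
        cls = _FAMILIES[name.lower()]
    except KeyError:
        raise ValueError(f"unknown family {name!r}; choose from {sorted(_FAMILIES)}") from None
    return cls(d)
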