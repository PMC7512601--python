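"""Seeded generators for the synthetic experiment streams.

A stream is i.i.d. f_theta0 up to the change time nu and i.i.d. f_theta
afterwards.  Sparse changes (a proportion p of Gaussian coordinates shifted
to 1, or n of the d Bernoulli edges switched to a new rate) redraw the
affected coordinate set independently for every Monte-Carlo trial.

RNG contract: every public entry point takes a single integer seed; trials
derive child seeds through ``numpy.random.SeedSequence(seed).spawn``, so
experiments are reproducible and can be partitioned deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expfam import ExponentialFamily, get_family

__all__ = [
    "StreamSpec",
    "make_stream",
    "make_gamma_stream",
    "sparse_gaussian_theta",
    "bernoulli_edge_theta",
    "child_seeds",
]


def child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-trial child seeds (uint32) from one root seed."""
    return np.array(
        [s.generate_state(1)[0] for s in np.random.SeedSequence(seed).spawn(n)],
        dtype=np.uint32,
    )


def sparse_gaussian_theta(d: int, p: float, rng: np.random.Generator,
                          magnitude: float = 1.0) -> np.ndarray:
    """Post-change Gaussian mean: round(p*d) coordinates set to `magnitude`,
    the rest zero, locations drawn uniformly at random."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("proportion p must lie in [0, 1]")
    k = int(round(p * d))
    theta = np.zeros(d)
    if k:
        theta[rng.choice(d, size=k, replace=False)] = magnitude
    return theta


def bernoulli_edge_theta(d: int, n_changed: int, rng: np.random.Generator,
                         p_pre: float = 0.2, p_post: float = 0.8) -> np.ndarray:
    """Post-change Bernoulli natural parameter: n of the d edges switch from
    rate p_pre to p_post, chosen uniformly at random."""
    if not 0 <= n_changed <= d:
        raise ValueError("n_changed must lie in [0, d]")
    p = np.full(d, p_pre)
    if n_changed:
        p[rng.choice(d, size=n_changed, replace=False)] = p_post
    return np.log(p / (1.0 - p))


@dataclass
class StreamSpec:
    """Description of one synthetic observation stream.

    `nu` is the change time: the first nu rows are pre-change (nu=0 gives an
    entirely post-change stream for delay runs; numpy.inf gives a pure null
    stream for run-length runs).
    """

    family: str
    d: int
    theta0: np.ndarray
    theta_post: np.ndarray | None
    nu: float
    length: int
    seed: int

    def __post_init__(self):
        self.theta0 = np.atleast_1d(np.asarray(self.theta0, float))
        if self.theta_post is not None:
            self.theta_post = np.atleast_1d(np.asarray(self.theta_post, float))
        if self.nu < 0:
            raise ValueError("change time nu must be nonnegative (inf for no change)")
        if not np.isinf(self.nu) and self.theta_post is None:
            raise ValueError("a finite change time requires theta_post")


def make_stream(spec: StreamSpec) -> np.ndarray:
    """Generate the (length x d) observation matrix for a stream spec."""
    family: ExponentialFamily = get_family(spec.family, spec.d)
    rng = np.random.default_rng(spec.seed)
    n_pre = spec.length if np.isinf(spec.nu) else min(int(spec.nu), spec.length)
    n_post = spec.length - n_pre
    parts = []
    if n_pre:
        parts.append(family.sample(spec.theta0, n_pre, rng))
    if n_post:
        parts.append(family.sample(spec.theta_post, n_post, rng))
    if not parts:
        return np.empty((0, spec.d))
    return np.vstack(parts)


def make_gamma_stream(length: int, beta_post: float, seed: int, nu: float = 0,
                      beta_pre: float = 1.0) -> np.ndarray:
    """Exponential-observation stream: rate beta_pre before the change time,
    beta_post after (rate parametrization: mean = 1/beta)."""
    if beta_post <= 0 or beta_pre <= 0:
        raise ValueError("rates must be positive")
    spec = StreamSpec(family="gamma", d=1, theta0=np.array([-beta_pre]),
                      theta_post=np.array([-beta_post]), nu=nu, length=length, seed=seed)
    return make_stream(spec)
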