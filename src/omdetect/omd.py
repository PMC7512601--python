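"""Online mirror descent over exponential families.

The estimator keeps a dual (mean-parameter) state mu_hat and, on each sample,
moves it toward the sufficient statistic:

    mu_hat_t = mu_hat_{t-1} - eta_t (mu_hat_{t-1} - phi(X_t)),

maps back to the natural parameter theta_tilde = grad Phi*(mu_hat_t), and
Bregman-projects onto a closed convex feasible set Gamma.  With the harmonic
step sizes eta_t = 1/t and Gamma the full space, the dual state is exactly the
running mean of the sufficient statistics, so for the Gaussian family the
estimator coincides with the running sample mean.

The regret of the estimator sequence is the cumulative plug-in log-loss minus
the log-loss of the best fixed parameter in hindsight; on unconstrained
harmonic-step paths it equals the weighted Bregman sum
sum_i i * B_{Phi*}(mu_hat_i, mu_hat_{i-1}).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .expfam import ExponentialFamily, GaussianFamily

__all__ = [
    "FeasibleSet",
    "OMDState",
    "RegretLedger",
    "OMDRun",
    "UnsupportedProjectionError",
    "harmonic_steps",
    "init_state",
    "omd_update",
    "bregman_project",
    "project_l1",
    "run_omd",
    "regret",
    "regret_bregman_sum",
]


class UnsupportedProjectionError(ValueError):
    """Raised for (family, feasible-set) pairs with no implemented projection."""


def harmonic_steps(t: int) -> float:
    """Default step schedule eta_t = 1/t."""
    return 1.0 / t


@dataclass(frozen=True)
class FeasibleSet:
    """Closed convex constraint set Gamma in natural-parameter space.

    kind is one of "full_space", "l1_ball" (radius > 0) or "box"
    (lo < hi coordinate-wise; +-inf allowed for one-sided intervals).
    """

    kind: str = "full_space"
    radius: float | None = None
    lo: np.ndarray | float | None = None
    hi: np.ndarray | float | None = None

    def __post_init__(self):
        if self.kind not in ("full_space", "l1_ball", "box"):
            raise ValueError(f"unknown feasible-set kind {self.kind!r}")
        if self.kind == "l1_ball":
            if self.radius is None or self.radius <= 0:
                raise ValueError("l1_ball requires radius > 0")
        if self.kind == "box":
            lo = -np.inf if self.lo is None else np.asarray(self.lo, float)
            hi = np.inf if self.hi is None else np.asarray(self.hi, float)
            if not np.all(lo < hi):
                raise ValueError("box requires lo < hi coordinate-wise")

    @classmethod
    def full_space(cls) -> "FeasibleSet":
        return cls("full_space")

    @classmethod
    def l1_ball(cls, radius: float) -> "FeasibleSet":
        return cls("l1_ball", radius=radius)

    @classmethod
    def box(cls, lo=None, hi=None) -> "FeasibleSet":
        return cls("box", lo=lo, hi=hi)

    @classmethod
    def from_config(cls, cfg: dict | None) -> "FeasibleSet":
        """Build from e.g. {"kind": "l1_ball", "radius": 5.0}."""
        if cfg is None:
            return cls.full_space()
        cfg = dict(cfg)
        kind = cfg.pop("kind")
        return cls(kind, **cfg)


@dataclass(frozen=True)
class OMDState:
    """One estimator's current position and step count."""

    theta_hat: np.ndarray
    mu_hat: np.ndarray
    t: int = 0
    step_schedule: Callable[[int], float] = harmonic_steps


def init_state(family: ExponentialFamily, theta0,
               step_schedule: Callable[[int], float] = harmonic_steps) -> OMDState:
    theta0 = family.check_natural(theta0)
    return OMDState(theta_hat=theta0.copy(), mu_hat=family.mean_map(theta0),
                    t=0, step_schedule=step_schedule)


def project_l1(v: np.ndarray, radius: float) -> np.ndarray:
    """Euclidean projection onto the l1 ball via soft-thresholding."""
    v = np.asarray(v, float)
    if np.sum(np.abs(v)) <= radius:
        return v.copy()
    a = np.sort(np.abs(v))[::-1]
    cum = np.cumsum(a)
    k = np.arange(1, a.size + 1)
    # largest k with a_k > (cum_k - radius)/k
    rho = np.nonzero(a > (cum - radius) / k)[0][-1]
    lam = (cum[rho] - radius) / (rho + 1.0)
    return np.sign(v) * np.maximum(np.abs(v) - lam, 0.0)


def bregman_project(family: ExponentialFamily, gamma: FeasibleSet, theta_tilde) -> np.ndarray:
    """argmin_{u in Gamma} B_Phi(u, theta_tilde).

    Supported pairs: any family with the full space; any of the three
    (coordinate-separable) families with a box, where the 1-D Bregman
    projection onto an interval is clipping; the Gaussian family with an
    l1 ball, where B_Phi is the squared Euclidean distance and the projection
    is soft-thresholding.
    """
    theta_tilde = family.check_natural(theta_tilde)
    if gamma.kind == "full_space":
        return theta_tilde.copy()
    if gamma.kind == "box":
        lo = -np.inf if gamma.lo is None else gamma.lo
        hi = np.inf if gamma.hi is None else gamma.hi
        return np.clip(theta_tilde, lo, hi)
    if gamma.kind == "l1_ball":
        if not isinstance(family, GaussianFamily):
            raise UnsupportedProjectionError(
                f"l1-ball Bregman projection is implemented for the Gaussian "
                f"family only, not {family.name!r}"
            )
        return project_l1(theta_tilde, gamma.radius)
    raise UnsupportedProjectionError(f"unsupported feasible set {gamma.kind!r}")


def omd_update(family: ExponentialFamily, state: OMDState, gamma: FeasibleSet, x) -> OMDState:
    """Absorb one observation (Algorithm steps: dual update, mirror, project)."""
    t_new = state.t + 1
    eta = state.step_schedule(t_new)
    p = family.phi(x)
    mu = state.mu_hat - eta * (state.mu_hat - p)
    theta_tilde = family.inverse_mean_map(family.clamp_mean(mu, t_new))
    theta_hat = bregman_project(family, gamma, theta_tilde)
    return OMDState(theta_hat=theta_hat, mu_hat=mu, t=t_new,
                    step_schedule=state.step_schedule)


@dataclass
class RegretLedger:
    """Cumulative plug-in log-loss, tracked through sufficient statistics.

    Only the base-measure-free part of each loss -log f_theta(x) =
    Phi(theta) - theta' phi(x) (- log dH) is stored; the dH terms cancel
    between the plug-in and hindsight loss sums.
    """

    family: ExponentialFamily
    n: int = 0
    phi_sum: np.ndarray | None = None
    plugin_loss: float = 0.0

    def record(self, theta_pre, x) -> None:
        """Record the loss of predicting x with the pre-update estimate."""
        theta_pre = self.family.check_natural(theta_pre)
        p = self.family.phi(x)
        self.plugin_loss += self.family.log_partition(theta_pre) - float(theta_pre @ p)
        self.phi_sum = p.copy() if self.phi_sum is None else self.phi_sum + p
        self.n += 1


def regret(family: ExponentialFamily, ledger: RegretLedger) -> float:
    """Plug-in cumulative loss minus the hindsight-minimizer loss.

    The hindsight minimizer is theta = grad Phi*(mean of phi(X_i)), with the
    mean clamped into the open mean domain so the regret is always finite
    (the unclamped Bernoulli MLE can sit at +-infinity).
    """
    if ledger.n == 0:
        raise ValueError("regret of an empty ledger is undefined")
    mean_phi = ledger.phi_sum / ledger.n
    theta_star = family.inverse_mean_map(family.clamp_mean(mean_phi, ledger.n))
    hindsight = ledger.n * family.log_partition(theta_star) - float(theta_star @ ledger.phi_sum)
    return ledger.plugin_loss - hindsight


@dataclass
class OMDRun:
    """A recorded OMD trajectory (states, dual path, regret ledger)."""

    family: ExponentialFamily
    theta_path: np.ndarray       # (t+1, d), theta_path[0] = theta0
    dual_path: np.ndarray        # (t+1, d), dual_path[0] = grad Phi(theta0)
    ledger: RegretLedger
    projection_active: bool
    harmonic: bool

    @property
    def t(self) -> int:
        return self.theta_path.shape[0] - 1


def run_omd(family: ExponentialFamily, theta0, xs: Sequence, gamma: FeasibleSet | None = None,
            step_schedule: Callable[[int], float] = harmonic_steps) -> OMDRun:
    """Run OMD over a stream, recording the trajectory and the regret ledger."""
    gamma = gamma or FeasibleSet.full_space()
    state = init_state(family, theta0, step_schedule)
    ledger = RegretLedger(family)
    thetas = [state.theta_hat.copy()]
    duals = [state.mu_hat.copy()]
    projection_active = False
    for x in xs:
        ledger.record(state.theta_hat, x)
        state = omd_update(family, state, gamma, x)
        # detect whether the projection moved the point
        theta_tilde = family.inverse_mean_map(family.clamp_mean(state.mu_hat, state.t))
        if not np.allclose(theta_tilde, state.theta_hat, rtol=0.0, atol=1e-12):
            projection_active = True
        thetas.append(state.theta_hat.copy())
        duals.append(state.mu_hat.copy())
    return OMDRun(family=family, theta_path=np.asarray(thetas),
                  dual_path=np.asarray(duals), ledger=ledger,
                  projection_active=projection_active,
                  harmonic=step_schedule is harmonic_steps)


def regret_bregman_sum(family: ExponentialFamily, run: OMDRun) -> float:
    """sum_{i=1..t} i * B_{Phi*}(mu_hat_i, mu_hat_{i-1}).

    Valid only for harmonic steps with the projection never active (on such
    paths it equals :func:`regret` exactly; with an active projection the
    identity is not guaranteed and the call is refused).
    """
    if run.projection_active:
        raise ValueError("Bregman-sum regret identity requires an inactive projection")
    if not run.harmonic:
        raise ValueError("Bregman-sum regret identity requires eta_i = 1/i")
    total = 0.0
    for i in range(1, run.dual_path.shape[0]):
        total += i * family.bregman_dual(run.dual_path[i], run.dual_path[i - 1])
    return total
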