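"""Sequential change-point detectors.

* :class:`AdaptiveDetector` -- the adaptive-CUSUM (ACM) and adaptive
  Shiryaev-Roberts (ASR) procedures.  For every hypothetical change point k
  in the window a branch keeps a non-anticipating plug-in estimator
  (initialized at theta0, step schedule restarted at eta=1) and the branch
  log likelihood ratio log Lambda_{k,t}.  The ACM statistic is the max over
  branches, the ASR statistic the log-sum-exp; both procedures alarm the
  first time the statistic strictly exceeds the threshold.
* :class:`CusumDetector` -- classical CUSUM with a fixed nominal post-change
  parameter, W_{t+1} = max(W_t + log-ratio, 0).
* :class:`GlrDetector` -- window-limited generalized likelihood ratio with
  the exact segment MLE recomputed from sufficient-statistic prefix means.

These are the readable reference implementations used by the unit tests and
small runs; the Monte-Carlo harness in :mod:`omdetect.evaluate` drives
numerically identical compiled kernels for large experiments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .expfam import ExponentialFamily, GammaFamily
from .omd import FeasibleSet, bregman_project

__all__ = [
    "StepResult",
    "BranchState",
    "AdaptiveDetector",
    "CusumDetector",
    "GlrDetector",
]


@dataclass
class StepResult:
    t: int
    statistic: float
    stopped: bool


@dataclass
class BranchState:
    """One hypothetical change point k: branch estimator state and log LR.

    The branch's first absorbed sample is X_k; `n` counts absorbed samples and
    `mean_phi` is their sufficient-statistic mean (the OMD dual state with the
    harmonic schedule restarted at the branch's birth).
    """

    k: int
    n: int = 0
    mean_phi: np.ndarray | None = None
    log_lambda: float = 0.0


def _branch_estimate(family: ExponentialFamily, branch: BranchState, theta0: np.ndarray,
                     estimator: str, feasible: FeasibleSet, shrink_scale: float) -> np.ndarray:
    """Plug-in estimate theta_hat_{k,t} from the branch state (post-absorb)."""
    if branch.n == 0:
        return theta0
    mu = family.clamp_mean(branch.mean_phi, branch.n)
    if estimator == "omd" or estimator == "mom":
        theta = family.inverse_mean_map(mu)
        return bregman_project(family, feasible, theta)
    if estimator == "shrinkage":
        # soft-threshold the running segment mean (Gaussian mean space);
        # a convenience baseline, see the methods note.
        lam = shrink_scale * np.sqrt(2.0 * np.log(family.d) / branch.n) if family.d > 1 else 0.0
        mu = np.sign(mu) * np.maximum(np.abs(mu) - lam, 0.0)
        return family.inverse_mean_map(family.clamp_mean(mu))
    raise ValueError(f"unknown estimator {estimator!r}")


class AdaptiveDetector:
    """Window-limited ACM / ASR with per-branch plug-in estimators."""

    def __init__(self, family: ExponentialFamily, theta0, *, statistic: str = "acm",
                 window: int = 100, threshold: float = np.inf,
                 feasible: FeasibleSet | None = None, estimator: str = "omd",
                 shrink_scale: float = 1.0):
        if statistic not in ("acm", "asr"):
            raise ValueError("statistic must be 'acm' or 'asr'")
        if estimator == "mom" and not isinstance(family, GammaFamily):
            raise ValueError("the method-of-moments estimator is defined for the Gamma family")
        self.family = family
        self.theta0 = family.check_natural(theta0)
        self.statistic_kind = statistic
        self.window = int(window)
        self.threshold = float(threshold)
        self.feasible = feasible or FeasibleSet.full_space()
        self.estimator = estimator
        self.shrink_scale = float(shrink_scale)
        self.t = 0
        self.branches: list[BranchState] = []

    def statistics(self) -> tuple[float, float]:
        """(ACM, ASR) statistics of the current state."""
        if not self.branches:
            return 0.0, 0.0
        logs = np.array([br.log_lambda for br in self.branches])
        return float(logs.max()), float(logsumexp(logs))

    @property
    def current_statistic(self) -> float:
        acm, asr = self.statistics()
        return acm if self.statistic_kind == "acm" else asr

    def step(self, x) -> StepResult:
        """Process one observation; returns the statistic and the stop flag."""
        self.t += 1
        p = self.family.phi(x)
        for br in self.branches:
            theta = _branch_estimate(self.family, br, self.theta0, self.estimator,
                                     self.feasible, self.shrink_scale)
            br.log_lambda += self.family.log_likelihood_ratio(theta, self.theta0, x)
            br.mean_phi = br.mean_phi + (p - br.mean_phi) / (br.n + 1)
            br.n += 1
        # the newborn branch k=t contributes a zero log-ratio (estimate theta0)
        self.branches.append(BranchState(k=self.t, n=1, mean_phi=p.copy(), log_lambda=0.0))
        self.branches = [br for br in self.branches if br.k >= self.t - self.window]
        stat = self.current_statistic
        return StepResult(t=self.t, statistic=stat, stopped=stat > self.threshold)

    def branch_log_lambdas(self) -> dict[int, float]:
        return {br.k: br.log_lambda for br in self.branches}


class CusumDetector:
    """Classical CUSUM with a fixed nominal post-change parameter theta1."""

    def __init__(self, family: ExponentialFamily, theta0, theta1, *, threshold: float = np.inf):
        self.family = family
        self.theta0 = family.check_natural(theta0)
        self.theta1 = family.check_natural(theta1)
        self.threshold = float(threshold)
        self.t = 0
        self.w = 0.0

    def step(self, x) -> StepResult:
        self.t += 1
        self.w = max(self.w + self.family.log_likelihood_ratio(self.theta1, self.theta0, x), 0.0)
        return StepResult(t=self.t, statistic=self.w, stopped=self.w > self.threshold)


class GlrDetector:
    """Window-limited GLR with exact segment MLEs from prefix means.

    The hypothetical change point k owns the segment X_{k+1}..X_t, so the
    newest branch (k=t) is an empty segment that contributes nothing until
    the next sample; the statistic is the max over nonempty segments of
    n_k * [(theta_hat - theta0)' mean_phi - Phi(theta_hat) + Phi(theta0)]
    with theta_hat the (clamped) segment MLE.
    """

    def __init__(self, family: ExponentialFamily, theta0, *, window: int = 100,
                 threshold: float = np.inf):
        self.family = family
        self.theta0 = family.check_natural(theta0)
        self.window = int(window)
        self.threshold = float(threshold)
        self.t = 0
        # segments: (k, n, mean_phi); the earliest hypothetical change is k=1,
        # whose segment X_2..X_t starts absorbing at t=2
        self.segments: list[BranchState] = []

    def step(self, x) -> StepResult:
        self.t += 1
        p = self.family.phi(x)
        for seg in self.segments:
            if seg.n == 0:
                seg.mean_phi = p.copy()
            else:
                seg.mean_phi = seg.mean_phi + (p - seg.mean_phi) / (seg.n + 1)
            seg.n += 1
        self.segments = [s for s in self.segments if s.k >= self.t - self.window]
        stat = self.current_statistic
        self.segments.append(BranchState(k=self.t, n=0, mean_phi=None))
        return StepResult(t=self.t, statistic=stat, stopped=stat > self.threshold)

    @property
    def current_statistic(self) -> float:
        fam, theta0 = self.family, self.theta0
        logpart0 = fam.log_partition(theta0)
        best = 0.0
        for seg in self.segments:
            if seg.n == 0:
                continue
            mu = fam.clamp_mean(seg.mean_phi, seg.n)
            theta = fam.inverse_mean_map(mu)
            val = seg.n * (float((theta - theta0) @ seg.mean_phi)
                           - fam.log_partition(theta) + logpart0)
            best = max(best, val)
        return best
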