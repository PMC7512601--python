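"""Point-process change detection: homogeneous Poisson to Hawkes.

Under the null the event intensity is a known constant mu; under the
alternative, events after the change time excite the intensity through an
exponential kernel,

    lambda_s = mu + theta * sum_{t_j < s} beta exp(-beta (s - t_j)),

with unknown magnitude theta > 0.  The event stream is scanned at the event
times; the events inside the sliding window [T_i - L, T_i] form the i-th
"observation" X_i.  Each hypothetical change point keeps a scalar estimate of
theta, updated by projected stochastic gradient ascent on the window
log-likelihood, and contributes the centered log-likelihood ratio
l(theta|X_i) - l(0|X_i) (which vanishes at theta = 0, where the Hawkes model
degenerates to the Poisson null).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EventStream",
    "HawkesDetectorConfig",
    "Window",
    "window_vectorize",
    "window_loglik",
    "centered_loglik",
    "loglik_grad",
    "sgd_update",
    "HawkesRun",
    "hawkes_detect",
    "hawkes_null_ladder",
    "simulate_poisson",
    "simulate_hawkes",
    "simulate_poisson_to_hawkes",
]


@dataclass
class EventStream:
    """Strictly increasing event times in (0, horizon]."""

    times: np.ndarray
    horizon: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("event times must be a 1-D array")
        if self.times.size:
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("event times must be strictly increasing")
            if self.times[0] <= 0 or self.times[-1] > self.horizon:
                raise ValueError("event times must lie in (0, horizon]")


@dataclass
class HawkesDetectorConfig:
    """Detector parameters: known baseline mu, kernel decay beta, sliding
    window length L (time units), number of retained branch estimators w,
    SGD step size, and the feasible interval [0, theta_max] for theta."""

    mu: float = 1.0
    beta: float = 1.0
    L: float = 5.0
    w: int = 50
    gamma_step: float = 0.01
    theta_max: float = 0.99

    def __post_init__(self):
        if min(self.mu, self.beta, self.L, self.gamma_step) < 0 or self.mu <= 0 \
                or self.beta <= 0 or self.L <= 0:
            raise ValueError("mu, beta, L must be positive; gamma_step nonnegative")
        if self.w < 1 or not np.isfinite(self.theta_max) or self.theta_max <= 0:
            raise ValueError("w must be >= 1 and theta_max finite positive")


@dataclass
class Window:
    """Events of the stream falling in [scan_time - L, scan_time]."""

    scan_time: float
    events: np.ndarray


def window_vectorize(events: EventStream, L: float) -> list[Window]:
    """One window per event time T_i, listing the events in [T_i - L, T_i]."""
    if L <= 0:
        raise ValueError("window length L must be positive")
    times = events.times
    out = []
    lo = 0
    for i, ti in enumerate(times):
        while times[lo] < ti - L:
            lo += 1
        out.append(Window(scan_time=ti, events=times[lo:i + 1].copy()))
    return out


def _window_terms(window: Window, mu: float, beta: float) -> tuple[np.ndarray, float]:
    """Per-event excitation A_q = sum_{t_j < t_q} beta e^{-beta(t_q - t_j)} and
    the compensator sum B = sum_q (1 - e^{-beta(T_i - t_q)})."""
    ts = window.events
    m = ts.size
    a = np.zeros(m)
    acc = 0.0
    for q in range(m):
        if q > 0:
            acc = (acc + beta) * np.exp(-beta * (ts[q] - ts[q - 1]))
            a[q] = acc
    b = float(np.sum(1.0 - np.exp(-beta * (window.scan_time - ts))))
    return a, b


def window_loglik(theta: float, window: Window, config: HawkesDetectorConfig) -> float:
    """Window log-likelihood of the Hawkes model (Poisson base measure).

    l(theta|X_i) = sum_q log(mu + theta A_q) - mu L - theta B.  At theta = 0
    this is the Poisson window log-likelihood, not zero; detectors use
    :func:`centered_loglik`.
    """
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    a, b = _window_terms(window, config.mu, config.beta)
    return float(np.sum(np.log(config.mu + theta * a)) - config.mu * config.L - theta * b)


def centered_loglik(theta: float, window: Window, config: HawkesDetectorConfig) -> float:
    """Log-likelihood ratio Hawkes(theta) vs Poisson: l(theta) - l(0)."""
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    a, b = _window_terms(window, config.mu, config.beta)
    return float(np.sum(np.log1p(theta * a / config.mu)) - theta * b)


def loglik_grad(theta: float, window: Window, config: HawkesDetectorConfig) -> float:
    """d l / d theta = sum_q A_q / (mu + theta A_q) - B."""
    a, b = _window_terms(window, config.mu, config.beta)
    return float(np.sum(a / (config.mu + theta * a)) - b)


def sgd_update(theta: float, window: Window, config: HawkesDetectorConfig) -> float:
    """Projected stochastic-gradient ascent step on the window log-likelihood."""
    g = loglik_grad(theta, window, config)
    return float(np.clip(theta + config.gamma_step * g, 0.0, config.theta_max))


@dataclass
class HawkesRun:
    stop_index: int | None          # 1-based scan index of the alarm
    stopped: bool
    statistics: np.ndarray          # statistic per scan (up to the stop)
    scan_times: np.ndarray


class _BranchArray:
    """Vectorized branch states: one theta estimate and log LR per branch."""

    def __init__(self, w: int):
        self.w = w
        self.ks: list[int] = []
        self.thetas = np.empty(0)
        self.logl = np.empty(0)

    def step(self, a: np.ndarray, b: float, i: int, config: HawkesDetectorConfig
             ) -> tuple[float, float]:
        mu, eta = config.mu, config.gamma_step
        if self.thetas.size:
            # centered increments with the pre-update estimates
            za = np.log1p(np.outer(self.thetas, a) / mu).sum(axis=1) if a.size else 0.0
            self.logl = self.logl + za - self.thetas * b
            grad = (a / (mu + np.outer(self.thetas, a))).sum(axis=1) - b if a.size \
                else np.full_like(self.thetas, -b)
            self.thetas = np.clip(self.thetas + eta * grad, 0.0, config.theta_max)
        # newborn branch k=i: estimate 0 contributes 0, then one SGD step
        g0 = float(np.sum(a / mu) - b) if a.size else -b
        theta_new = float(np.clip(eta * g0, 0.0, config.theta_max))
        self.ks.append(i)
        self.thetas = np.append(self.thetas, theta_new)
        self.logl = np.append(self.logl, 0.0)
        if len(self.ks) > self.w + 1:
            drop = len(self.ks) - (self.w + 1)
            self.ks = self.ks[drop:]
            self.thetas = self.thetas[drop:]
            self.logl = self.logl[drop:]
        mx = float(self.logl.max())
        asr = mx + float(np.log(np.sum(np.exp(self.logl - mx))))
        return mx, asr


def hawkes_detect(events: EventStream, config: HawkesDetectorConfig, b: float,
                  statistic: str = "acm") -> HawkesRun:
    """Run the ACM/ASR scan over an event stream; stop when statistic > b."""
    if statistic not in ("acm", "asr"):
        raise ValueError("statistic must be 'acm' or 'asr'")
    windows = window_vectorize(events, config.L)
    branches = _BranchArray(config.w)
    stats = []
    scan_times = []
    for i, win in enumerate(windows, start=1):
        a, cb = _window_terms(win, config.mu, config.beta)
        acm, asr = branches.step(a, cb, i, config)
        stat = acm if statistic == "acm" else asr
        stats.append(stat)
        scan_times.append(win.scan_time)
        if stat > b:
            return HawkesRun(stop_index=i, stopped=True, statistics=np.asarray(stats),
                             scan_times=np.asarray(scan_times))
    return HawkesRun(stop_index=None, stopped=False, statistics=np.asarray(stats),
                     scan_times=np.asarray(scan_times))


def hawkes_null_ladder(config: HawkesDetectorConfig, levels: np.ndarray,
                       horizon_scans: int, seeds: np.ndarray,
                       statistic: str = "acm") -> np.ndarray:
    """First scan index at which the statistic exceeds each ladder level, per
    null (Poisson) trial; 0 marks a level never hit before the scan horizon."""
    levels = np.asarray(levels, float)
    hits = np.zeros((len(seeds), levels.size), dtype=np.int64)
    for i, seed in enumerate(seeds):
        t_max = (horizon_scans + 10) / config.mu * 1.25 + 10.0 * config.L
        stream = simulate_poisson(config.mu, t_max, int(seed))
        windows = window_vectorize(stream, config.L)[:horizon_scans]
        branches = _BranchArray(config.w)
        j = 0
        for n, win in enumerate(windows, start=1):
            a, cb = _window_terms(win, config.mu, config.beta)
            acm, asr = branches.step(a, cb, n, config)
            stat = acm if statistic == "acm" else asr
            while j < levels.size and stat > levels[j]:
                hits[i, j] = n
                j += 1
            if j == levels.size:
                break
    return hits


# ---------------------------------------------------------------------------
# simulators
# ---------------------------------------------------------------------------

def simulate_poisson(mu: float, horizon: float, seed: int, start: float = 0.0) -> EventStream:
    """Homogeneous Poisson process on (start, horizon] via exponential gaps."""
    if mu <= 0:
        raise ValueError("mu must be positive")
    rng = np.random.default_rng(seed)
    times = []
    t = start
    while True:
        t += rng.exponential(1.0 / mu)
        if t > horizon:
            break
        times.append(t)
    return EventStream(times=np.asarray(times), horizon=horizon)


def simulate_hawkes(mu: float, theta: float, beta: float, horizon: float, seed: int,
                    history: np.ndarray | None = None, start: float = 0.0) -> EventStream:
    """Hawkes process with intensity mu + theta sum beta e^{-beta(s-t_j)} on
    (start, horizon], by Ogata thinning with the exponential-kernel state.

    `history` supplies earlier events that excite the process but are not
    included in the returned stream.  theta >= 1 (the explosive regime for
    the normalized kernel) is allowed but warned about; the horizon caps the
    simulation.
    """
    if mu <= 0 or beta <= 0 or theta < 0:
        raise ValueError("mu, beta must be positive and theta nonnegative")
    if theta >= 1:
        import warnings

        warnings.warn("branching ratio theta >= 1: explosive Hawkes regime; "
                      "simulation proceeds up to the horizon", RuntimeWarning)
    rng = np.random.default_rng(seed)
    t = start
    excitation = 0.0  # theta * sum beta e^{-beta (t - t_j)} over past events
    if history is not None and len(history):
        history = np.asarray(history, float)
        excitation = theta * beta * float(np.sum(np.exp(-beta * (start - history))))
    times = []
    while True:
        lam_bar = mu + excitation
        gap = rng.exponential(1.0 / lam_bar)
        t_new = t + gap
        if t_new > horizon:
            break
        decay = np.exp(-beta * gap)
        excitation *= decay
        if rng.random() <= (mu + excitation) / lam_bar:
            times.append(t_new)
            excitation += theta * beta
        t = t_new
    return EventStream(times=np.asarray(times), horizon=horizon)


def simulate_poisson_to_hawkes(mu: float, theta: float, beta: float, kappa: float,
                               horizon: float, seed: int) -> EventStream:
    """Poisson on (0, kappa], then Hawkes excited only by post-change events."""
    ss = np.random.SeedSequence(seed).spawn(2)
    pre = simulate_poisson(mu, kappa, ss[0].generate_state(1)[0])
    post = simulate_hawkes(mu, theta, beta, horizon, ss[1].generate_state(1)[0],
                           history=None, start=kappa)
    return EventStream(times=np.concatenate([pre.times, post.times]), horizon=horizon)
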