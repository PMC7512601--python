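"""Numba kernels for the Monte-Carlo experiment harness.

These re-implement the reference detectors in :mod:`omdetect.detectors` as
compiled loops so that run-length calibration (null paths of order 10^4
steps) is tractable.  Branch states live in a ring buffer of w+1 slots keyed
by birth time; the newborn branch overwrites the slot of the branch that just
left the window.  The unit tests assert step-by-step equality between these
kernels and the reference steppers.

Null-path kernels record, for a sorted ladder of thresholds, the first time
the statistic strictly exceeds each level.  Hitting times are monotone in the
level, so a single pass yields the common-random-numbers ARL(b) curve for the
whole ladder (0 in the output means the level was never hit before the
horizon).
"""

from __future__ import annotations

import numpy as np
from numba import njit

FAM_GAUSS, FAM_GAMMA, FAM_BERN = 0, 1, 2
EST_OMD, EST_L1, EST_SHRINK = 0, 1, 2
MEAN_CLIP = 1e-8
GAMMA_THETA_MAX = -1e-8

FAMILY_CODES = {"gaussian": FAM_GAUSS, "gamma": FAM_GAMMA, "bernoulli": FAM_BERN}
ESTIMATOR_CODES = {"omd": EST_OMD, "mom": EST_OMD, "l1": EST_L1, "shrinkage": EST_SHRINK}


@njit(cache=True)
def _l1_proj(v, radius, out):
    d = v.shape[0]
    total = 0.0
    for c in range(d):
        total += abs(v[c])
    if total <= radius:
        for c in range(d):
            out[c] = v[c]
        return
    a = np.sort(np.abs(v))[::-1]
    cum = 0.0
    rho = 0
    lam = 0.0
    for j in range(d):
        cum += a[j]
        if a[j] > (cum - radius) / (j + 1.0):
            rho = j
            lam = (cum - radius) / (j + 1.0)
    for c in range(d):
        av = abs(v[c]) - lam
        if av < 0.0:
            av = 0.0
        out[c] = av if v[c] >= 0.0 else -av


@njit(cache=True)
def _gen(fam, theta, x):
    d = theta.shape[0]
    if fam == FAM_GAUSS:
        for c in range(d):
            x[c] = np.random.normal() + theta[c]
    elif fam == FAM_GAMMA:
        x[0] = np.random.exponential() * (-1.0 / theta[0])
    else:
        for c in range(d):
            p = 1.0 / (1.0 + np.exp(-theta[c]))
            x[c] = 1.0 if np.random.random() < p else 0.0


@njit(cache=True)
def _adapt_sweep(fam, est, x, theta0, s_l1, shrink_scale, ks, ns, means, logl, t, w, tmp):
    """Advance the ACM/ASR branch states by one observation.

    Returns (acm, asr): max and log-sum-exp of the branch log likelihood
    ratios over the live window k in [t-w, t].
    """
    w1 = ks.shape[0]
    d = x.shape[0]
    for s in range(w1):
        k = ks[s]
        if k < t - w or k < 1:
            continue
        n = ns[s]
        m = means[s]
        inc = 0.0
        if fam == FAM_GAUSS:
            if est == EST_OMD:
                for c in range(d):
                    inc += (m[c] - theta0[c]) * x[c] - 0.5 * (m[c] * m[c] - theta0[c] * theta0[c])
            elif est == EST_L1:
                _l1_proj(m, s_l1, tmp)
                for c in range(d):
                    inc += (tmp[c] - theta0[c]) * x[c] - 0.5 * (tmp[c] * tmp[c] - theta0[c] * theta0[c])
            else:
                lam = shrink_scale * np.sqrt(2.0 * np.log(d) / n) if d > 1 else 0.0
                for c in range(d):
                    th = m[c]
                    if th > lam:
                        th -= lam
                    elif th < -lam:
                        th += lam
                    else:
                        th = 0.0
                    inc += (th - theta0[c]) * x[c] - 0.5 * (th * th - theta0[c] * theta0[c])
        elif fam == FAM_GAMMA:
            mu = m[0] if m[0] > MEAN_CLIP else MEAN_CLIP
            th = -1.0 / mu
            if th > GAMMA_THETA_MAX:
                th = GAMMA_THETA_MAX
            inc = (th - theta0[0]) * x[0] + np.log(th / theta0[0])
        else:
            eps = 0.5 / (n + 1.0)  # age-adaptive boundary guard
            if eps < MEAN_CLIP:
                eps = MEAN_CLIP
            for c in range(d):
                ph = m[c]
                if ph < eps:
                    ph = eps
                elif ph > 1.0 - eps:
                    ph = 1.0 - eps
                p0 = 1.0 / (1.0 + np.exp(-theta0[c]))
                if x[c] > 0.5:
                    inc += np.log(ph / p0)
                else:
                    inc += np.log((1.0 - ph) / (1.0 - p0))
        logl[s] = logl[s] + inc
        for c in range(d):
            m[c] += (x[c] - m[c]) / (n + 1.0)
        ns[s] = n + 1
    slot = t % w1
    ks[slot] = t
    ns[slot] = 1
    logl[slot] = 0.0
    for c in range(d):
        means[slot, c] = x[c]
    mx = -1.0e300
    for s in range(w1):
        if ks[s] >= t - w and ks[s] >= 1 and logl[s] > mx:
            mx = logl[s]
    sm = 0.0
    for s in range(w1):
        if ks[s] >= t - w and ks[s] >= 1:
            sm += np.exp(logl[s] - mx)
    return mx, mx + np.log(sm)


@njit(cache=True)
def _glr_sweep(fam, x, theta0, ks, ns, means, t, w):
    """Advance the window-limited GLR segments by one observation.

    Segment k holds X_{k+1}..X_t; the newborn (empty) segment k=t is created
    after the statistic is formed.  Returns the max segment statistic.
    """
    w1 = ks.shape[0]
    d = x.shape[0]
    for s in range(w1):
        k = ks[s]
        if k < t - w or k < 1 or k >= t:
            continue
        n = ns[s]
        m = means[s]
        if n == 0:
            for c in range(d):
                m[c] = x[c]
        else:
            for c in range(d):
                m[c] += (x[c] - m[c]) / (n + 1.0)
        ns[s] = n + 1
    best = 0.0
    for s in range(w1):
        k = ks[s]
        if k < t - w or k < 1 or k >= t or ns[s] == 0:
            continue
        n = ns[s]
        m = means[s]
        val = 0.0
        if fam == FAM_GAUSS:
            for c in range(d):
                val += (m[c] - theta0[c]) * m[c] - 0.5 * (m[c] * m[c] - theta0[c] * theta0[c])
        elif fam == FAM_GAMMA:
            mu = m[0] if m[0] > MEAN_CLIP else MEAN_CLIP
            th = -1.0 / mu
            if th > GAMMA_THETA_MAX:
                th = GAMMA_THETA_MAX
            val = (th - theta0[0]) * m[0] + np.log(th / theta0[0])
        else:
            eps = 0.5 / (n + 1.0)
            if eps < MEAN_CLIP:
                eps = MEAN_CLIP
            for c in range(d):
                ph = m[c]
                if ph < eps:
                    ph = eps
                elif ph > 1.0 - eps:
                    ph = 1.0 - eps
                th = np.log(ph / (1.0 - ph))
                val += (th - theta0[c]) * m[c] - np.log(
                    (1.0 + np.exp(th)) / (1.0 + np.exp(theta0[c]))
                )
        val *= n
        if val > best:
            best = val
    slot = t % w1
    ks[slot] = t
    ns[slot] = 0
    return best


@njit(cache=True)
def _cusum_inc(fam, x, theta0, theta1):
    d = x.shape[0]
    inc = 0.0
    if fam == FAM_GAUSS:
        for c in range(d):
            inc += (theta1[c] - theta0[c]) * x[c] - 0.5 * (
                theta1[c] * theta1[c] - theta0[c] * theta0[c]
            )
    elif fam == FAM_GAMMA:
        inc = (theta1[0] - theta0[0]) * x[0] + np.log(theta1[0] / theta0[0])
    else:
        for c in range(d):
            inc += (theta1[c] - theta0[c]) * x[c] - np.log(
                (1.0 + np.exp(theta1[c])) / (1.0 + np.exp(theta0[c]))
            )
    return inc


# ---------------------------------------------------------------------------
# driver kernels: null-path threshold ladders, delay runs, statistic paths
# ---------------------------------------------------------------------------

@njit(cache=True)
def adapt_null_ladder(fam, est, d, theta0, use_asr, w, s_l1, shrink_scale,
                      levels, horizon, seeds):
    n_trials = seeds.shape[0]
    n_levels = levels.shape[0]
    hits = np.zeros((n_trials, n_levels), np.int64)
    w1 = w + 1
    x = np.empty(d)
    tmp = np.empty(d)
    for i in range(n_trials):
        np.random.seed(seeds[i])
        ks = np.zeros(w1, np.int64)
        ns = np.zeros(w1, np.int64)
        means = np.zeros((w1, d))
        logl = np.zeros(w1)
        j = 0
        for t in range(1, horizon + 1):
            _gen(fam, theta0, x)
            acm, asr = _adapt_sweep(fam, est, x, theta0, s_l1, shrink_scale,
                                    ks, ns, means, logl, t, w, tmp)
            stat = asr if use_asr else acm
            while j < n_levels and stat > levels[j]:
                hits[i, j] = t
                j += 1
            if j == n_levels:
                break
    return hits


@njit(cache=True)
def adapt_edd(fam, est, d, theta0, theta_post, use_asr, w, s_l1, shrink_scale,
              b, horizon, seeds):
    n_trials = seeds.shape[0]
    taus = np.zeros(n_trials, np.int64)
    w1 = w + 1
    x = np.empty(d)
    tmp = np.empty(d)
    for i in range(n_trials):
        np.random.seed(seeds[i])
        ks = np.zeros(w1, np.int64)
        ns = np.zeros(w1, np.int64)
        means = np.zeros((w1, d))
        logl = np.zeros(w1)
        for t in range(1, horizon + 1):
            _gen(fam, theta_post[i], x)
            acm, asr = _adapt_sweep(fam, est, x, theta0, s_l1, shrink_scale,
                                    ks, ns, means, logl, t, w, tmp)
            stat = asr if use_asr else acm
            if stat > b:
                taus[i] = t
                break
    return taus


@njit(cache=True)
def adapt_traj(fam, est, theta0, stream, w, s_l1, shrink_scale):
    T = stream.shape[0]
    d = stream.shape[1]
    stats = np.zeros((T, 2))
    w1 = w + 1
    ks = np.zeros(w1, np.int64)
    ns = np.zeros(w1, np.int64)
    means = np.zeros((w1, d))
    logl = np.zeros(w1)
    x = np.empty(d)
    tmp = np.empty(d)
    for t in range(1, T + 1):
        for c in range(d):
            x[c] = stream[t - 1, c]
        acm, asr = _adapt_sweep(fam, est, x, theta0, s_l1, shrink_scale,
                                ks, ns, means, logl, t, w, tmp)
        stats[t - 1, 0] = acm
        stats[t - 1, 1] = asr
    return stats


@njit(cache=True)
def glr_null_ladder(fam, d, theta0, w, levels, horizon, seeds):
    n_trials = seeds.shape[0]
    n_levels = levels.shape[0]
    hits = np.zeros((n_trials, n_levels), np.int64)
    w1 = w + 1
    x = np.empty(d)
    for i in range(n_trials):
        np.random.seed(seeds[i])
        ks = np.full(w1, -1, np.int64)
        ns = np.zeros(w1, np.int64)
        means = np.zeros((w1, d))
        j = 0
        for t in range(1, horizon + 1):
            _gen(fam, theta0, x)
            stat = _glr_sweep(fam, x, theta0, ks, ns, means, t, w)
            while j < n_levels and stat > levels[j]:
                hits[i, j] = t
                j += 1
            if j == n_levels:
                break
    return hits


@njit(cache=True)
def glr_edd(fam, d, theta0, theta_post, w, b, horizon, seeds):
    n_trials = seeds.shape[0]
    taus = np.zeros(n_trials, np.int64)
    w1 = w + 1
    x = np.empty(d)
    for i in range(n_trials):
        np.random.seed(seeds[i])
        ks = np.full(w1, -1, np.int64)
        ns = np.zeros(w1, np.int64)
        means = np.zeros((w1, d))
        for t in range(1, horizon + 1):
            _gen(fam, theta_post[i], x)
            stat = _glr_sweep(fam, x, theta0, ks, ns, means, t, w)
            if stat > b:
                taus[i] = t
                break
    return taus


@njit(cache=True)
def glr_traj(fam, theta0, stream, w):
    T = stream.shape[0]
    d = stream.shape[1]
    stats = np.zeros(T)
    w1 = w + 1
    ks = np.full(w1, -1, np.int64)
    ns = np.zeros(w1, np.int64)
    means = np.zeros((w1, d))
    x = np.empty(d)
    for t in range(1, T + 1):
        for c in range(d):
            x[c] = stream[t - 1, c]
        stats[t - 1] = _glr_sweep(fam, x, theta0, ks, ns, means, t, w)
    return stats


@njit(cache=True)
def cusum_null_ladder(fam, d, theta0, theta1, levels, horizon, seeds):
    n_trials = seeds.shape[0]
    n_levels = levels.shape[0]
    hits = np.zeros((n_trials, n_levels), np.int64)
    x = np.empty(d)
    for i in range(n_trials):
        np.random.seed(seeds[i])
        wstat = 0.0
        j = 0
        for t in range(1, horizon + 1):
            _gen(fam, theta0, x)
            wstat += _cusum_inc(fam, x, theta0, theta1)
            if wstat < 0.0:
                wstat = 0.0
            while j < n_levels and wstat > levels[j]:
                hits[i, j] = t
                j += 1
            if j == n_levels:
                break
    return hits


@njit(cache=True)
def cusum_edd(fam, d, theta0, theta1, theta_post, b, horizon, seeds):
    n_trials = seeds.shape[0]
    taus = np.zeros(n_trials, np.int64)
    x = np.empty(d)
    for i in range(n_trials):
        np.random.seed(seeds[i])
        wstat = 0.0
        for t in range(1, horizon + 1):
            _gen(fam, theta_post[i], x)
            wstat += _cusum_inc(fam, x, theta0, theta1)
            if wstat < 0.0:
                wstat = 0.0
            if wstat > b:
                taus[i] = t
                break
    return taus


# ---------------------------------------------------------------------------
# Bernoulli specialization: branch increments through count tables
# ---------------------------------------------------------------------------

def bernoulli_tables(w: int, p0: float) -> tuple[np.ndarray, np.ndarray]:
    """Log-ratio lookup tables for branch plug-in estimates.

    A branch of age n with m observed ones has the clamped running mean
    p_hat = clip(m/n, eps, 1-eps); the per-coordinate increment is
    log(p_hat/p0) for x=1 and log((1-p_hat)/(1-p0)) for x=0.
    """
    n_max = w + 2
    t0 = np.zeros((n_max, n_max))
    t1 = np.zeros((n_max, n_max))
    for n in range(1, n_max):
        m = np.arange(n + 1)
        eps = max(MEAN_CLIP, 0.5 / (n + 1.0))  # age-adaptive boundary guard
        ph = np.clip(m / n, eps, 1.0 - eps)
        t1[n, : n + 1] = np.log(ph / p0)
        t0[n, : n + 1] = np.log((1.0 - ph) / (1.0 - p0))
    return t0, t1


@njit(cache=True)
def _bern_sweep(x, counts, ks, ns, logl, t0_tab, t1_tab, t, w):
    w1 = ks.shape[0]
    d = x.shape[0]
    for s in range(w1):
        k = ks[s]
        if k < t - w or k < 1:
            continue
        n = ns[s]
        inc = 0.0
        row0 = t0_tab[n]
        row1 = t1_tab[n]
        cs = counts[s]
        for c in range(d):
            if x[c] == 1:
                inc += row1[cs[c]]
                cs[c] += 1
            else:
                inc += row0[cs[c]]
        logl[s] = logl[s] + inc
        ns[s] = n + 1
    slot = t % w1
    ks[slot] = t
    ns[slot] = 1
    logl[slot] = 0.0
    for c in range(d):
        counts[slot, c] = x[c]
    mx = -1.0e300
    for s in range(w1):
        if ks[s] >= t - w and ks[s] >= 1 and logl[s] > mx:
            mx = logl[s]
    sm = 0.0
    for s in range(w1):
        if ks[s] >= t - w and ks[s] >= 1:
            sm += np.exp(logl[s] - mx)
    return mx, mx + np.log(sm)


@njit(cache=True)
def bern_null_ladder(d, p0, use_asr, w, t0_tab, t1_tab, levels, horizon, seeds):
    n_trials = seeds.shape[0]
    n_levels = levels.shape[0]
    hits = np.zeros((n_trials, n_levels), np.int64)
    w1 = w + 1
    x = np.empty(d, np.int64)
    for i in range(n_trials):
        np.random.seed(seeds[i])
        ks = np.zeros(w1, np.int64)
        ns = np.zeros(w1, np.int64)
        counts = np.zeros((w1, d), np.int64)
        logl = np.zeros(w1)
        j = 0
        for t in range(1, horizon + 1):
            for c in range(d):
                x[c] = 1 if np.random.random() < p0 else 0
            acm, asr = _bern_sweep(x, counts, ks, ns, logl, t0_tab, t1_tab, t, w)
            stat = asr if use_asr else acm
            while j < n_levels and stat > levels[j]:
                hits[i, j] = t
                j += 1
            if j == n_levels:
                break
    return hits


@njit(cache=True)
def bern_edd(d, p_post, use_asr, w, t0_tab, t1_tab, b, horizon, seeds):
    n_trials = seeds.shape[0]
    taus = np.zeros(n_trials, np.int64)
    w1 = w + 1
    x = np.empty(d, np.int64)
    for i in range(n_trials):
        np.random.seed(seeds[i])
        ks = np.zeros(w1, np.int64)
        ns = np.zeros(w1, np.int64)
        counts = np.zeros((w1, d), np.int64)
        logl = np.zeros(w1)
        for t in range(1, horizon + 1):
            for c in range(d):
                x[c] = 1 if np.random.random() < p_post[i, c] else 0
            acm, asr = _bern_sweep(x, counts, ks, ns, logl, t0_tab, t1_tab, t, w)
            stat = asr if use_asr else acm
            if stat > b:
                taus[i] = t
                break
    return taus


@njit(cache=True)
def bern_traj(stream, w, t0_tab, t1_tab):
    T = stream.shape[0]
    d = stream.shape[1]
    stats = np.zeros((T, 2))
    w1 = w + 1
    ks = np.zeros(w1, np.int64)
    ns = np.zeros(w1, np.int64)
    counts = np.zeros((w1, d), np.int64)
    logl = np.zeros(w1)
    x = np.empty(d, np.int64)
    for t in range(1, T + 1):
        for c in range(d):
            x[c] = 1 if stream[t - 1, c] > 0.5 else 0
        acm, asr = _bern_sweep(x, counts, ks, ns, logl, t0_tab, t1_tab, t, w)
        stats[t - 1, 0] = acm
        stats[t - 1, 1] = asr
    return stats
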