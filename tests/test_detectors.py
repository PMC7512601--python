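"""Change-point detectors: branch recursions, baselines, kernel parity."""

import numpy as np
import pytest

from omdetect import (
    AdaptiveDetector,
    CusumDetector,
    FeasibleSet,
    GlrDetector,
    get_family,
    init_state,
    omd_update,
)
from omdetect import _kernels as K

from conftest import random_natural


def replay_branch_log_lambda(family, stream, k, theta0, gamma=None, t_end=None):
    """Brute-force branch log LR: replay an independent estimator on X_k..X_t
    and accumulate the non-anticipating plug-in ratio terms."""
    gamma = gamma or FeasibleSet.full_space()
    t_end = len(stream) if t_end is None else t_end
    state = init_state(family, theta0)
    total = 0.0
    for i in range(k - 1, t_end):
        total += family.log_likelihood_ratio(state.theta_hat, theta0, stream[i])
        state = omd_update(family, state, gamma, stream[i])
    return total


def _stream_for(family, rng, n):
    theta = random_natural(family, rng, scale=0.5)
    return family.sample(theta, n, rng)


def test_statistics_zero_at_first_step(family, rng):
    det = AdaptiveDetector(family, random_natural(family, rng))
    res = det.step(_stream_for(family, rng, 1)[0])
    acm, asr = det.statistics()
    assert res.statistic == 0.0 and acm == 0.0 and asr == 0.0


def test_branch_recursion_matches_bruteforce_replay(family, rng):
    theta0 = random_natural(family, rng, scale=0.3)
    stream = _stream_for(family, rng, 30)
    det = AdaptiveDetector(family, theta0, window=40)
    for x in stream:
        det.step(x)
    for k, logl in det.branch_log_lambdas().items():
        ref = replay_branch_log_lambda(family, stream, k, det.theta0)
        assert logl == pytest.approx(ref, abs=1e-10)


def test_asr_statistic_dominates_acm(family, rng):
    theta0 = random_natural(family, rng, scale=0.3)
    det = AdaptiveDetector(family, theta0, window=15)
    for x in _stream_for(family, rng, 60):
        det.step(x)
        acm, asr = det.statistics()
        assert asr >= acm - 1e-12


def test_window_limits_branch_count(rng):
    fam = get_family("gaussian", 1)
    det = AdaptiveDetector(fam, [0.0], window=10)
    for x in rng.normal(size=(50, 1)):
        det.step(x)
    ks = sorted(det.branch_log_lambdas())
    assert len(ks) == 11 and ks == list(range(det.t - 10, det.t + 1))


def test_cusum_reflection_and_accumulation():
    fam = get_family("gaussian", 1)
    det = CusumDetector(fam, [0.0], [1.0])
    # log-ratio term is x - 1/2; x = -1 gives term -1.5, reflected at zero
    det.step([-1.0])
    assert det.w == 0.0
    det.step([2.0])          # term 1.5
    assert det.w == pytest.approx(1.5)
    det.step([0.8])          # term 0.3
    assert det.w == pytest.approx(1.8)


def test_cusum_matches_hand_trajectory(rng):
    fam = get_family("gaussian", 1)
    xs = rng.normal(size=10)
    det = CusumDetector(fam, [0.0], [1.0])
    w = 0.0
    for x in xs:
        res = det.step([x])
        w = max(w + (x - 0.5), 0.0)
        assert res.statistic == pytest.approx(w, abs=1e-12)


def test_glr_zero_at_first_step(rng):
    fam = get_family("gaussian", 2)
    det = GlrDetector(fam, np.zeros(2))
    assert det.step(rng.normal(size=2)).statistic == 0.0


def test_glr_single_segment_closed_form(rng):
    # one segment only (window >= t): statistic = max_k (t-k) ||mean||^2 / 2
    fam = get_family("gaussian", 1)
    xs = rng.normal(loc=0.7, size=12)
    det = GlrDetector(fam, [0.0], window=50)
    stats = [det.step([x]).statistic for x in xs]
    t = len(xs)
    best = 0.0
    for k in range(1, t):
        seg = xs[k:]
        best = max(best, seg.size * seg.mean() ** 2 / 2.0)
    assert stats[-1] == pytest.approx(best, abs=1e-12)


def test_glr_matches_bruteforce_over_change_points(family, rng):
    theta0 = random_natural(family, rng, scale=0.3)
    stream = _stream_for(family, rng, 20)
    det = GlrDetector(family, theta0, window=8)
    stats = [det.step(x).statistic for x in stream]
    t = len(stream)
    logpart0 = family.log_partition(theta0)
    best = 0.0
    for k in range(max(1, t - 8), t):
        seg = stream[k:]
        mean_phi = np.mean([family.phi(x) for x in seg], axis=0)
        th = family.inverse_mean_map(family.clamp_mean(mean_phi, len(seg)))
        val = len(seg) * (float((th - theta0) @ mean_phi)
                          - family.log_partition(th) + logpart0)
        best = max(best, val)
    assert stats[-1] == pytest.approx(best, abs=1e-10)


def test_shrinkage_zero_level_equals_plain_estimator(rng):
    fam = get_family("gaussian", 3)
    stream = rng.normal(size=(25, 3))
    a = AdaptiveDetector(fam, np.zeros(3), estimator="omd")
    b = AdaptiveDetector(fam, np.zeros(3), estimator="shrinkage", shrink_scale=0.0)
    for x in stream:
        a.step(x)
        b.step(x)
        assert a.statistics() == pytest.approx(b.statistics(), abs=1e-12)


def test_shrinkage_huge_level_pins_statistic_at_zero(rng):
    # estimates pinned at the zero vector = theta0: every ratio term vanishes
    fam = get_family("gaussian", 3)
    det = AdaptiveDetector(fam, np.zeros(3), estimator="shrinkage", shrink_scale=1e6)
    for x in rng.normal(size=(20, 3)):
        res = det.step(x)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)


def test_gamma_mom_estimate():
    # method of moments for Exp(beta): mean 0.5 -> beta = 2, theta = -2
    fam = get_family("gamma")
    det = AdaptiveDetector(fam, [-1.0], estimator="mom")
    det.step([0.4])
    det.step([0.6])
    from omdetect.detectors import _branch_estimate

    br = det.branches[0]
    est = _branch_estimate(fam, br, det.theta0, "mom", det.feasible, 1.0)
    assert est[0] == pytest.approx(-2.0)


def test_mom_requires_gamma_family():
    with pytest.raises(ValueError):
        AdaptiveDetector(get_family("gaussian", 2), np.zeros(2), estimator="mom")


# ---------------------------------------------------------------------------
# compiled kernels reproduce the reference steppers step by step
# ---------------------------------------------------------------------------

def _python_adapt_traj(fam, theta0, stream, w, **kw):
    det = AdaptiveDetector(fam, theta0, window=w, **kw)
    out = []
    for x in stream:
        det.step(x)
        out.append(det.statistics())
    return np.asarray(out)


@pytest.mark.parametrize("name,d,est,l1", [
    ("gaussian", 3, "omd", None),
    ("gaussian", 3, "omd", 1.0),
    ("gaussian", 3, "shrinkage", None),
    ("gamma", 1, "omd", None),
    ("bernoulli", 4, "omd", None),
])
def test_kernel_adaptive_matches_python(name, d, est, l1, rng):
    fam = get_family(name, d)
    theta0 = random_natural(fam, rng, scale=0.3)
    stream = fam.sample(random_natural(fam, rng, scale=0.3), 80, rng)
    kw = {"estimator": est}
    if l1 is not None:
        kw["feasible"] = FeasibleSet.l1_ball(l1)
    py = _python_adapt_traj(fam, theta0, stream, 12, **kw)
    code = K.EST_L1 if l1 is not None else K.ESTIMATOR_CODES[est]
    kt = K.adapt_traj(K.FAMILY_CODES[name], code, theta0, stream, 12, l1 or 0.0, 1.0)
    np.testing.assert_allclose(kt, py, atol=1e-9)


@pytest.mark.parametrize("name,d", [("gaussian", 3), ("gamma", 1), ("bernoulli", 4)])
def test_kernel_glr_matches_python(name, d, rng):
    fam = get_family(name, d)
    theta0 = random_natural(fam, rng, scale=0.3)
    stream = fam.sample(random_natural(fam, rng, scale=0.3), 80, rng)
    det = GlrDetector(fam, theta0, window=12)
    py = np.array([det.step(x).statistic for x in stream])
    kt = K.glr_traj(K.FAMILY_CODES[name], theta0, stream, 12)
    np.testing.assert_allclose(kt, py, atol=1e-9)


def test_kernel_bernoulli_fast_path_matches_python(rng):
    d, p0 = 6, 0.2
    fam = get_family("bernoulli", d)
    theta0 = np.full(d, np.log(p0 / (1 - p0)))
    stream = (rng.random((100, d)) < 0.35).astype(float)
    py = _python_adapt_traj(fam, theta0, stream, 9)
    t0, t1 = K.bernoulli_tables(9, p0)
    kt = K.bern_traj(stream, 9, t0, t1)
    np.testing.assert_allclose(kt, py, atol=1e-9)
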