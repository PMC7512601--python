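"""Monte-Carlo performance harness: ARL, threshold calibration, EDD, tables.

Average run length (ARL) is the mean time to a false alarm under the
no-change measure; the expected detection delay (EDD) is the mean stopping
time when the stream is post-change from its first sample (the worst-case
conditional delay is attained at change time 0, so delay runs simulate only
that case).  Thresholds are calibrated so the ARL matches a target gamma.

Calibration exploits that, on a fixed path, the first time the detection
statistic exceeds a level b is nondecreasing in b: each null path is
simulated once while recording its first-hitting time for a fine ladder of
levels, which yields the whole common-random-numbers ARL(b) curve in one
pass; the threshold is then read off the monotone curve.  Paths that never
reach a level before the truncation horizon contribute the horizon (a small,
documented downward bias on the ARL).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .expfam import get_family
from .hawkes import HawkesDetectorConfig, hawkes_null_ladder, simulate_hawkes, \
    window_vectorize, _window_terms, _BranchArray
from .simulate import bernoulli_edge_theta, child_seeds, sparse_gaussian_theta

__all__ = [
    "ProcedureSpec",
    "CalibrationResult",
    "ExperimentResult",
    "null_hit_times",
    "estimate_arl",
    "calibrate_threshold",
    "estimate_edd",
    "run_table",
    "TABLE_GAMMAS",
    "SCALES",
]

#: (calibration trials, delay trials) per scale; "mini" is the package's
#: test/desk-side scale, see docs/methods.md for the error analysis.
SCALES = {"full": (10_000, 10_000), "desk": (2_000, 2_000), "mini": (100, 400)}

TABLE_GAMMAS = {1: 10_000, 2: 10_000, 3: 10_000, 4: 5_000}


@dataclass(frozen=True)
class ProcedureSpec:
    """A detector family/procedure configuration for the harness."""

    family: str                      # gaussian | gamma | bernoulli
    d: int
    theta0: tuple | float
    procedure: str                   # acm | asr | glr | cusum
    estimator: str = "omd"           # omd | shrinkage | mom
    l1_radius: float | None = None
    window: int = 100
    theta1: tuple | float | None = None   # CUSUM nominal post-change parameter
    shrink_scale: float = 1.0

    def theta0_array(self) -> np.ndarray:
        return np.broadcast_to(np.asarray(self.theta0, float), (self.d,)).copy()

    def theta1_array(self) -> np.ndarray:
        if self.theta1 is None:
            raise ValueError("CUSUM requires a nominal post-change parameter theta1")
        return np.broadcast_to(np.asarray(self.theta1, float), (self.d,)).copy()


def _est_code(spec: ProcedureSpec) -> int:
    if spec.l1_radius is not None:
        if spec.family != "gaussian":
            raise ValueError("l1 feasible set is supported for the Gaussian family only")
        return K.EST_L1
    return K.ESTIMATOR_CODES[spec.estimator]


def _use_bern_fast(spec: ProcedureSpec) -> bool:
    if spec.family != "bernoulli" or spec.procedure not in ("acm", "asr"):
        return False
    if spec.estimator != "omd" or spec.l1_radius is not None:
        return False
    return bool(np.ptp(spec.theta0_array()) == 0.0)


def null_hit_times(spec: ProcedureSpec, levels: np.ndarray, seeds: np.ndarray,
                   horizon: int) -> np.ndarray:
    """First hitting times (trials x levels) of the statistic under the null;
    0 marks a level not reached before the horizon."""
    levels = np.asarray(levels, float)
    seeds = np.asarray(seeds, np.int64)
    theta0 = spec.theta0_array()
    fam = K.FAMILY_CODES[spec.family]
    if spec.procedure in ("acm", "asr"):
        use_asr = spec.procedure == "asr"
        if _use_bern_fast(spec):
            p0 = float(get_family("bernoulli", spec.d).mean_map(theta0)[0])
            t0, t1 = K.bernoulli_tables(spec.window, p0)
            return K.bern_null_ladder(spec.d, p0, use_asr, spec.window, t0, t1,
                                      levels, horizon, seeds)
        return K.adapt_null_ladder(fam, _est_code(spec), spec.d, theta0, use_asr,
                                   spec.window, spec.l1_radius or 0.0,
                                   spec.shrink_scale, levels, horizon, seeds)
    if spec.procedure == "glr":
        return K.glr_null_ladder(fam, spec.d, theta0, spec.window, levels, horizon, seeds)
    if spec.procedure == "cusum":
        return K.cusum_null_ladder(fam, spec.d, theta0, spec.theta1_array(),
                                   levels, horizon, seeds)
    raise ValueError(f"unknown procedure {spec.procedure!r}")


def _delay_times(spec: ProcedureSpec, theta_post: np.ndarray, b: float,
                 seeds: np.ndarray, horizon: int) -> np.ndarray:
    seeds = np.asarray(seeds, np.int64)
    theta0 = spec.theta0_array()
    fam = K.FAMILY_CODES[spec.family]
    if spec.procedure in ("acm", "asr"):
        use_asr = spec.procedure == "asr"
        if _use_bern_fast(spec):
            family = get_family("bernoulli", spec.d)
            p0 = float(family.mean_map(theta0)[0])
            t0, t1 = K.bernoulli_tables(spec.window, p0)
            p_post = np.vstack([family.mean_map(tp) for tp in theta_post])
            return K.bern_edd(spec.d, p_post, use_asr, spec.window, t0, t1,
                              b, horizon, seeds)
        return K.adapt_edd(fam, _est_code(spec), spec.d, theta0, theta_post, use_asr,
                           spec.window, spec.l1_radius or 0.0, spec.shrink_scale,
                           b, horizon, seeds)
    if spec.procedure == "glr":
        return K.glr_edd(fam, spec.d, theta0, theta_post, spec.window, b, horizon, seeds)
    if spec.procedure == "cusum":
        return K.cusum_edd(fam, spec.d, theta0, spec.theta1_array(), theta_post,
                           b, horizon, seeds)
    raise ValueError(f"unknown procedure {spec.procedure!r}")


def _arl_from_hits(hits: np.ndarray, horizon: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-level (arl, se, truncated fraction) with censoring at the horizon."""
    times = np.where(hits > 0, hits, horizon).astype(float)
    arl = times.mean(axis=0)
    se = times.std(axis=0, ddof=1) / np.sqrt(times.shape[0])
    frac = (hits == 0).mean(axis=0)
    return arl, se, frac


def estimate_arl(spec: ProcedureSpec, b: float, n_trials: int, horizon: int,
                 seed: int) -> dict:
    """Monte-Carlo ARL at a fixed threshold; truncated runs contribute the
    horizon (downward bias) and their fraction is reported (warned above 5%)."""
    seeds = child_seeds(seed, n_trials).astype(np.int64)
    hits = null_hit_times(spec, np.array([b]), seeds, horizon)
    arl, se, frac = _arl_from_hits(hits, horizon)
    return {
        "arl": float(arl[0]),
        "se": float(se[0]),
        "frac_truncated": float(frac[0]),
        "truncation_warning": bool(frac[0] > 0.05),
        "n_trials": n_trials,
        "horizon": horizon,
    }


@dataclass
class CalibrationResult:
    b: float
    target_gamma: float
    arl: float
    arl_se: float
    levels: np.ndarray
    arls: np.ndarray
    n_trials: int
    horizon: int
    achieved_tol: float


def calibrate_threshold(spec: ProcedureSpec, target_gamma: float, n_trials: int,
                        seed: int, tol: float = 0.05, horizon: int | None = None,
                        level_step: float = 0.04) -> CalibrationResult:
    """Pick the threshold whose estimated ARL is closest to the target.

    One common-random-numbers pass records the whole monotone ARL(b) curve
    on a ladder spanning [0.1 log gamma, 3 log gamma] (widened once if the
    curve does not bracket the target).  A small pilot locates the region
    where ARL reaches ~2.5 gamma so the remaining paths stop early.
    """
    if target_gamma <= 1:
        raise ValueError("target_gamma must exceed 1")
    lg = np.log(target_gamma)
    horizon = int(np.ceil(3 * target_gamma)) if horizon is None else int(horizon)
    levels = np.arange(0.1 * lg, 3.0 * lg + level_step, level_step)
    for attempt in range(2):
        result = _calibrate_on_ladder(spec, target_gamma, levels, n_trials, seed, horizon)
        if result is not None:
            arl, se, levels_used = result
            break
        if attempt == 1:
            raise RuntimeError(
                f"calibration ladder up to b={levels[-1]:.2f} does not bracket "
                f"ARL target {target_gamma}"
            )
        levels = np.arange(0.1 * lg, 6.0 * lg + level_step, level_step)
    idx = int(np.argmin(np.abs(np.log(np.maximum(arl, 1.0)) - lg)))
    achieved = abs(arl[idx] - target_gamma) / target_gamma
    return CalibrationResult(
        b=float(levels_used[idx]), target_gamma=float(target_gamma),
        arl=float(arl[idx]), arl_se=float(se[idx]), levels=levels_used, arls=arl,
        n_trials=n_trials, horizon=horizon, achieved_tol=float(achieved),
    )


def _calibrate_on_ladder(spec, target_gamma, levels, n_trials, seed, horizon):
    seeds = child_seeds(seed, n_trials).astype(np.int64)
    n_pilot = min(8, n_trials)
    hits_pilot = null_hit_times(spec, levels, seeds[:n_pilot], horizon)
    arl_p, _, _ = _arl_from_hits(hits_pilot, horizon)
    if arl_p[-1] < target_gamma:
        return None  # ladder does not bracket the target: widen
    cut = int(np.argmax(arl_p >= 2.5 * target_gamma)) if np.any(arl_p >= 2.5 * target_gamma) \
        else levels.size - 1
    levels_used = levels[: cut + 1]
    if n_trials > n_pilot:
        hits_rest = null_hit_times(spec, levels_used, seeds[n_pilot:], horizon)
        hits = np.vstack([hits_pilot[:, : cut + 1], hits_rest])
    else:
        hits = hits_pilot[:, : cut + 1]
    arl, se, _ = _arl_from_hits(hits, horizon)
    if arl[-1] < target_gamma:
        return None
    return arl, se, levels_used


def estimate_edd(spec: ProcedureSpec, b: float, theta_post, n_trials: int,
                 seed: int, horizon: int = 5_000) -> dict:
    """Monte-Carlo expected detection delay with the change at time 0.

    theta_post is either a (d,) parameter shared by all trials or an
    (n_trials, d) matrix when the change support is redrawn per trial.
    """
    theta_post = np.asarray(theta_post, float)
    if theta_post.ndim == 1:
        theta_post = np.broadcast_to(theta_post, (n_trials, theta_post.size)).copy()
    if theta_post.shape[0] != n_trials:
        raise ValueError("theta_post must have one row per trial")
    seeds = child_seeds(seed ^ 0x5EED, n_trials).astype(np.int64)
    taus = _delay_times(spec, theta_post, b, seeds, horizon)
    times = np.where(taus > 0, taus, horizon).astype(float)
    return {
        "edd": float(times.mean()),
        "se": float(times.std(ddof=1) / np.sqrt(n_trials)),
        "frac_truncated": float((taus == 0).mean()),
        "truncation_warning": bool((taus == 0).mean() > 0.05),
        "n_trials": n_trials,
        "horizon": horizon,
    }


@dataclass
class ExperimentResult:
    """One calibrated procedure evaluated over the columns of a table."""

    procedure: str
    b: float
    target_gamma: float
    arl: float
    arl_se: float
    cells: dict = field(default_factory=dict)  # column label -> (edd, se)


# ---------------------------------------------------------------------------
# experiment tables
# ---------------------------------------------------------------------------

def _table1_procedures(w: int) -> dict[str, ProcedureSpec]:
    g = dict(family="gaussian", d=20, theta0=0.0, window=w)
    return {
        "CUSUM": ProcedureSpec(procedure="cusum", theta1=1.0, **g),
        "Shrinkage": ProcedureSpec(procedure="acm", estimator="shrinkage", **g),
        "GLR": ProcedureSpec(procedure="glr", **g),
        "ASR": ProcedureSpec(procedure="asr", **g),
        "ACM": ProcedureSpec(procedure="acm", **g),
        "ASR-L1": ProcedureSpec(procedure="asr", l1_radius=5.0, **g),
        "ACM-L1": ProcedureSpec(procedure="acm", l1_radius=5.0, **g),
    }


def _table2_procedures(w: int) -> dict[str, ProcedureSpec]:
    g = dict(family="gamma", d=1, theta0=-1.0, window=w)
    return {
        "CUSUM": ProcedureSpec(procedure="cusum", theta1=-2.0, **g),
        "MOM": ProcedureSpec(procedure="acm", estimator="mom", **g),
        "GLR": ProcedureSpec(procedure="glr", **g),
        "ASR": ProcedureSpec(procedure="asr", **g),
        "ACM": ProcedureSpec(procedure="acm", **g),
    }


def _table3_procedures(w: int) -> dict[str, ProcedureSpec]:
    p_pre, p_post = 0.2, 0.8
    t0 = float(np.log(p_pre / (1 - p_pre)))
    t1 = float(np.log(p_post / (1 - p_post)))
    g = dict(family="bernoulli", d=190, theta0=t0, window=w)
    return {
        "CUSUM": ProcedureSpec(procedure="cusum", theta1=t1, **g),
        "GLR": ProcedureSpec(procedure="glr", **g),
        "ASR": ProcedureSpec(procedure="asr", **g),
        "ACM": ProcedureSpec(procedure="acm", **g),
    }


TABLE1_COLUMNS = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6)          # proportion p of shifted coords
TABLE2_COLUMNS = (0.1, 0.5, 2.0, 5.0, 10.0)              # post-change rate beta
TABLE3_COLUMNS = (78, 100, 120, 150, 170, 190)           # number n of changed edges
TABLE4_COLUMNS = (0.4, 0.5, 0.7)                         # Hawkes magnitude theta


def _table_theta_posts(table: int, column, n_trials: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(np.random.SeedSequence([seed, table, int(column * 1000)]))
    if table == 1:
        return np.vstack([sparse_gaussian_theta(20, column, rng) for _ in range(n_trials)])
    if table == 2:
        return np.full((n_trials, 1), -float(column))
    if table == 3:
        return np.vstack([bernoulli_edge_theta(190, int(column), rng) for _ in range(n_trials)])
    raise ValueError("theta_posts are defined for tables 1-3")


def run_table(table: int, scale: str = "mini", seed: int = 0, out: str | None = None,
              procedures: list[str] | None = None, columns: list | None = None,
              target_gamma: float | None = None, window: int = 100,
              edd_horizon: int = 5_000) -> pd.DataFrame:
    """Reproduce one experiment table (EDD per procedure x column).

    Each procedure is calibrated once to the table's ARL target, then its
    delay is measured for every column with the change support redrawn per
    trial.  Returns the table with `edd`, `se`, `b` and `arl` columns; also
    written as CSV when `out` is given.
    """
    if table not in (1, 2, 3, 4):
        raise ValueError("table must be 1, 2, 3 or 4")
    n_cal, n_edd = SCALES[scale]
    gamma = target_gamma or TABLE_GAMMAS[table]
    if table == 4:
        df = _run_table4(scale, seed, gamma, columns, n_cal, n_edd)
    else:
        procs = {1: _table1_procedures, 2: _table2_procedures, 3: _table3_procedures}[table](window)
        if procedures is not None:
            procs = {k: v for k, v in procs.items() if k in procedures}
        cols = list(columns if columns is not None else
                    {1: TABLE1_COLUMNS, 2: TABLE2_COLUMNS, 3: TABLE3_COLUMNS}[table])
        rows = []
        for name, spec in procs.items():
            cal = calibrate_threshold(spec, gamma, n_cal, seed)
            row = {"procedure": name, "b": cal.b, "arl_est": cal.arl, "arl_se": cal.arl_se}
            for col in cols:
                theta_post = _table_theta_posts(table, col, n_edd, seed)
                res = estimate_edd(spec, cal.b, theta_post, n_edd, seed, horizon=edd_horizon)
                row[f"edd[{col}]"] = res["edd"]
                row[f"se[{col}]"] = res["se"]
            rows.append(row)
        df = pd.DataFrame(rows).set_index("procedure")
    if out is not None:
        df.to_csv(out)
    return df


def _hawkes_edd(config: HawkesDetectorConfig, theta: float, b: float, statistic: str,
                n_trials: int, seed: int, horizon_scans: int = 2_000) -> tuple[float, float]:
    """Delay in scan steps with the change at time 0 (pure Hawkes stream)."""
    seeds = child_seeds(seed ^ 0x5EED, n_trials)
    taus = np.empty(n_trials)
    for i, s in enumerate(seeds):
        t_max = (horizon_scans + 10) / (config.mu / (1.0 - min(theta, 0.95))) + 10 * config.L
        stream = simulate_hawkes(config.mu, theta, config.beta, t_max, int(s))
        windows = window_vectorize(stream, config.L)[:horizon_scans]
        branches = _BranchArray(config.w)
        taus[i] = horizon_scans
        for n, win in enumerate(windows, start=1):
            a, cb = _window_terms(win, config.mu, config.beta)
            acm, asr = branches.step(a, cb, n, config)
            stat = acm if statistic == "acm" else asr
            if stat > b:
                taus[i] = n
                break
    return float(taus.mean()), float(taus.std(ddof=1) / np.sqrt(n_trials))


def _run_table4(scale: str, seed: int, gamma: float, columns, n_cal: int, n_edd: int
                ) -> pd.DataFrame:
    config = HawkesDetectorConfig()
    cols = list(columns if columns is not None else TABLE4_COLUMNS)
    lg = np.log(gamma)
    levels = np.arange(0.1 * lg, 3.0 * lg, 0.05)
    horizon = int(np.ceil(3 * gamma))
    rows = []
    for statistic in ("acm", "asr"):
        seeds = child_seeds(seed, n_cal)
        hits = hawkes_null_ladder(config, levels, horizon, seeds, statistic=statistic)
        arl, se, _ = _arl_from_hits(hits, horizon)
        idx = int(np.argmin(np.abs(np.log(np.maximum(arl, 1.0)) - lg)))
        b = float(levels[idx])
        row = {"procedure": statistic.upper(), "b": b, "arl_est": float(arl[idx]),
               "arl_se": float(se[idx])}
        for theta in cols:
            edd, edd_se = _hawkes_edd(config, theta, b, statistic, n_edd, seed)
            row[f"edd[{theta}]"] = edd
            row[f"se[{theta}]"] = edd_se
        rows.append(row)
    return pd.DataFrame(rows).set_index("procedure")
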