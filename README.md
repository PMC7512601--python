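# omdetect

Sequential change-point detection when the post-change distribution is
unknown.  A data stream X₁, X₂, … is i.i.d. f<sub>θ₀</sub> (known baseline)
until an unknown time ν, and i.i.d. f<sub>θ</sub> (unknown θ) afterwards —
the standard setting of statistical surveillance (biosurveillance, quality
control, network monitoring).  The goal is to alarm as soon as possible
after ν while keeping the average run length to false alarm (ARL) above a
budget γ.

Instead of the exact post-change MLE (which in general cannot be updated
recursively, e.g. under sparsity constraints or for point processes), the
detection statistics here use **non-anticipating plug-in estimators built by
online mirror descent (OMD)** over an exponential family
f_θ(x) = exp{θᵀφ(x) − Φ(θ)}:

- one-sided SPRT:  Λ_t = ∏_{i≤t} f_{θ̂ᵢ₋₁}(Xᵢ)/f_{θ₀}(Xᵢ),
  stop at τ(b) = min{t : log Λ_t ≥ b};
- adaptive CUSUM (ACM):  T = inf{t : max_{t−w≤k≤t} log Λ_{k,t} > b};
- adaptive Shiryaev–Roberts (ASR):  T = inf{t : log Σ_{t−w≤k≤t} Λ_{k,t} > b},

where each window branch k restarts an OMD estimator
μ̂ ← μ̂ − η_t(μ̂ − φ(X_t)), θ̂ = proj_Γ ∇Φ*(μ̂) at θ₀ (η_t = 1/t).  Because
θ̂_{k,t−1} never uses X_t, Λ is a null martingale, giving
P_∞(τ(b) < ∞) ≤ e^(−b) and ARL ≥ γ at b = log γ, and the delay overhead over
the oracle b/I(θ, θ₀) is governed by the estimator's (logarithmic) online
regret.  Baselines included: classical CUSUM, window-limited GLR, a
shrinkage variant and the Gamma method-of-moments plug-in.  A
Poisson-to-Hawkes detector extends the same branch construction to
self-exciting event streams.  Concrete families: Gaussian mean shift
N(θ, I_d), exponential rate change (Gamma, α = 1), and independent Bernoulli
edges (Erdős–Rényi communication rates).

## Worked example

Detect a mean shift of an unknown sparse direction in a 2-D Gaussian stream
(change injected at ν = 10, all-ones shift):

```python
import numpy as np
from omdetect import AdaptiveDetector, get_family
from omdetect.simulate import StreamSpec, make_stream

fam = get_family("gaussian", 2)
spec = StreamSpec("gaussian", 2, np.zeros(2), np.full(2, 1.0),
                  nu=10, length=30, seed=3)
det = AdaptiveDetector(fam, np.zeros(2), statistic="acm",
                       window=20, threshold=4.0)
for x in make_stream(spec):
    r = det.step(x)
    if r.stopped:
        print(f"alarm at t={r.t}, statistic={r.statistic:.2f} (change at nu=10)")
        break
```

```
alarm at t=14, statistic=5.03 (change at nu=10)
```

The alarm fires four samples after the change: the branch opened at k = 11
accumulates the plug-in log likelihood ratio of the post-change samples
until the windowed maximum crosses the threshold b = 4.

The same machinery drives Monte-Carlo experiments, e.g. the exponential-rate
change table at a reduced ARL target:

```bash
omdetect experiment 2 --scale mini --gamma 100 --seed 3
```

which calibrates each procedure's threshold to ARL ≈ 100 and prints the
expected detection delay per post-change rate β — showing, for instance, the
mismatched-CUSUM failure at β = 0.1 (delay ~2500 vs ~3 for the adaptive
procedures) and the small adaptive-vs-GLR gap.

A CLI is available for streams on disk: `omdetect simulate`, `omdetect sprt`,
`omdetect detect`, `omdetect experiment` (see `--help`).

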