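# rinatt

Rational-inattention modelling of 2AFC orientation discrimination.

Head-fixed mice viewing two oriented gratings and picking the more
vertical one are a window onto a basic question: when sensory precision is
limited *and costly*, how should a brain distribute it over stimulus space,
and does that distribution adapt to what different stimuli are worth?
`rinatt` is a research toolkit for that question. It implements, end to
end and with synthetic ground truth:

* a **Bayesian observer** with von Mises encoding noise whose concentration
  is `k(c)·g(θ)` — a Naka–Rushton contrast response times a normalized
  *resource gain function* — BLS (posterior-mean) decoding under a
  horizontal-heavy stimulus prior, and a probit choice rule with late
  (post-decoding) Gaussian noise and side/history/contrast biases;
* an **endogenous allocation optimizer** that derives the optimal `g(θ)`
  and peak precision `k_max` per stimulus–reward environment by minimizing
  reward-weighted error probability plus a precision cost `η·k̄` (or a
  mutual-information cost);
* the six **descriptive probit models** (DM1–DM6) with lapses, history,
  contrast-dependent noise, contrast bias, and reward-history terms;
* a **confidence-gated distributional RL** rule that reallocates the gain
  trial by trial via a kernel prediction error and divisive normalization;
* a **Poisson population code** with prior-proportional tuning placement,
  discrete BLS decoding, and reward-minus-spike-cost optimization;
* **maximum-likelihood fitting** (multi-start, AIC/BIC comparison,
  bootstrap CIs) of every model family, including a covariate-modulated
  readout that separates sensory from downstream precision changes;
* a **synthetic task simulator** (stimuli, choices, rewards, anti-bias
  repeat protocol) so every stage is testable without any animal data;
* **psychometric analysis**: curves, discriminability matrices, classical
  MDS geometry.

The model core, in brief: a measurement of orientation θ₀ at contrast c is
`m ~ vonMises(ψ₀, k(c)·g(θ₀))` on the doubled circle ψ = 2θ; the estimate
is `θ̂(m) = E[θ | m]`; choices follow
`P(left) = Φ((E[v̂_l] − E[v̂_r]) / √(Var_l + Var_r + σ²_late) + β₀ + β₁D + β₂Δc)`
in verticality space `v = 90 − |90 − θ|`; and the rational-inattention
agent solves `max_{g,k_max} E[reward | Ω] − η·k̄` for each reward
environment Ω (constant 5 µl; 1→8 µl increasing with verticality; the
reverse). See `docs/methods.md` for the full specification, numerical
choices, and known limitations.

## Worked example

```python
from rinatt import (SessionSpec, simulate_session, fit, compare,
                    ObserverParams, ResourceGain, ContrastResponse)

truth = ObserverParams(gain=ResourceGain.uniform(),
                       cr=ContrastResponse(k_max=20.0, q=2.0, c50=0.4),
                       sigma_late=8.0, beta2=0.4)
session = simulate_session(SessionSpec(n_trials=4000, env_id="increasing",
                                       observer=truth, seed=7))
print("accuracy:", round(session["correct"].mean(), 3),
      "| mean reward (ul):", round(session["reward"].mean(), 2))

fits = [fit(m, session, starts=6, seed=0) for m in ("DM1", "DM2", "DM3")]
print(compare(fits)[["model_id", "n_params", "log_likelihood", "delta_aic"]])
```

Output:

```
accuracy: 0.97 | mean reward (ul): 6.23
  model_id  n_params  log_likelihood  delta_aic
0      DM3         7     -315.729250   0.000000
1      DM2         6     -321.700511   9.942521
2      DM1         4     -326.995884  16.533268
```

The simulated observer has a contrast-difference bias (β₂ = 0.4), so the
descriptive model that carries that term (DM3) wins the AIC comparison over
its nested restrictions (ΔAIC ≈ 10 and 17): the fitting stack identifies,
from choices alone, which behavioral signatures the generator contained.
The mean reward of 6.23 µl per trial reflects 97 % accuracy under the
increasing (1→8 µl) reward map.

A command-line interface mirrors the library:

```bash
rinatt simulate --out trials.csv --seed 1 --n-trials 5000 --env increasing
rinatt fit --model DM3 --trials trials.csv --starts 20 --seed 1
rinatt optimize-g --env increasing --eta 0.15 --sigma-late 10
rinatt rl-run --env increasing --trials 1000 --seed 1 --out traj.csv
rinatt mds --input trials.csv --out embedding.csv
rinatt run-pipeline --config config.yaml
```

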