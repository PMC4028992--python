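# sealipid

Daily body-condition estimation for elephant seals from drift-dive
telemetry.

Adult female elephant seals (*Mirounga* spp.) spend ~8 months at sea
between the moult and the breeding haul-out, and their lipid store on
return determines how much they can invest in a pup.  Their condition
can only be measured at the two captures — but at sea they perform
*drift dives*, passive segments whose vertical rate reflects buoyancy
and hence body composition.  `sealipid` turns those drift rates into a
daily time series of lipid mass with a hierarchical Bayesian state-space
model, for ecologists studying resource acquisition, foraging-site
quality and individual variation in marine predators.

## Model

Observation model (median daily drift rate, m/s):

    D_it ~ N( α₁ + α₂ · L_it / R_it ,  τ² / h_it )

where L is the latent daily lipid mass (kg), R the fixed non-lipid
tissue series (kg), and h the number of drift dives that day.  Process
model (zero-truncated normal on the daily increment):

    L_i,t+1 ~ N₊( L_it + x_it β + w_it γ_i ,  σ² )

with covariates x (transit, drift-dive count, lipid:lean ratio,
foraging-location × behavioural-phase indicators, departure lipid
percentage, behavioural state), individual random effects γ_i ~ N(0, G),
and L conditioned on the known departure and arrival lipid masses.
Inference is Metropolis-within-Gibbs (conjugate draws with exact
truncation corrections; single-site plus whole-trajectory latent
updates); model selection uses Chib's marginal-likelihood estimator.
An association is called significant when its 95% credible interval
excludes 0.  See `docs/methods.md` for the full account.

## Worked example

Simulate a small northern-elephant-seal-like population (the generator
reproduces the full data bundle: tracks, dives, capture physiology) and
fit the model:

```python
import sealipid as sl

pop = sl.simulate_population(sl.SimulationConfig(
    n_individuals=3, trip_length_days=60, seed=1))
model = sl.LipidStateModel.from_simulation(pop)
res = model.fit(n_iterations=2000, n_burnin=500, seed=2)
print(res.summary_text())
```

```
Lipid state-space model: 3 individuals, 180 transitions, 1500 stored draws
                parameter    mean    q2.5   q97.5  significant scale
                   alpha1  -0.545  -0.627  -0.465         True
                   alpha2   1.139   0.845   1.474         True
          beta[intercept]   1.499 -11.982  15.586        False
            beta[transit]  -0.085  -0.183   0.025        False
      beta[n_drift_dives]   0.196   0.005   0.623         True
   beta[lipid_lean_ratio] -12.038 -27.451   2.705        False
beta[departure_lipid_pct]   0.092  -0.488   0.640        False
        beta[state_index]   3.774  -1.020   8.994        False
 ...
                     tau2   0.010   0.008   0.013         True
                   sigma2   4.636   2.445   8.666         True
                   G[0,0]   0.968   0.132   4.229         True
```

`alpha1`/`alpha2` are the drift-rate intercept and slope on the
lipid:lean ratio — here recovered near their generating values (−0.578,
1.214) from only three short trips, with `tau2` ≈ 0.01 (0.1 m/s
observation error) and `sigma2` ≈ 4.6 against a generating 4 (2 kg/day
process error).  The drift-dive coefficient is positive and significant:
days with more drift dives are days of faster lipid gain.  Coefficients
a 3-seal dataset cannot identify (the location × phase cells, the
lipid:lean slope) keep wide intervals, as they should.

Daily condition trajectories and their gain/loss deltas (the data
behind horizon plots):

```python
traj = res.trajectories()          # id, day_index, mean_lipid_kg, sd, delta_kg
res.diagnostics()                  # R-hat / ESS (fit with n_chains=2)
res.log_marginal_likelihood()      # Chib estimate, for model comparison
```

Candidate models (covariate sets, the six non-lipid-tissue forms) are
compared with `sl.compare_models`, which ranks them by estimated log
marginal likelihood.

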