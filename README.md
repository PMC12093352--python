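# ldcm — longitudinal dynamic causal modelling of MEG cross-spectra

`ldcm` models how the cortical circuits generating resting-state MEG change
between a baseline and a follow-up recording — the longitudinal question
posed by progressive conditions such as Alzheimer's disease, where synaptic
and regional changes in the default mode network (DMN) precede structural
ones. It is written for researchers running longitudinal or interventional
electrophysiology studies who want mechanistic (synapse- and layer-level)
readouts rather than descriptive spectral statistics.

## What it does

Each of the four DMN sources (left/right angular gyrus, medial prefrontal
cortex, precuneus) is a conductance-based microcircuit of four populations
(spiny stellate, superficial pyramidal, interneurons, deep pyramidal) with
AMPA, GABA-A and NMDA channels:

    C_p V̇ = g_L(V_L − V) + g_AMPA(V_E − V) + g_GABA(V_I − V) + g_NMDA m(V)(V_N − V)
    κ_c ġ_c = drive_c − g_c,      drive = Σ H σ(V_pre)  (+ extrinsic A, AN)

Free parameters are log-scalings θ of fixed templates (`exp(θ)·template`),
with Gaussian priors. The model predicts the complex cross-spectral density
(CSD) of the regional signals by linearising about the fixed point, with
exact per-frequency conduction delays and parameterised 1/f-like endogenous
and sensor-noise spectra. Subject data features are CSDs from 8th-order
autoregressive fits of 1-s epochs, reduced across epochs by their first
principal component.

Fitting is variational Laplace: a Gauss–Newton ascent on the free energy
F = accuracy − complexity, returning a Gaussian posterior over parameters and
F as a log-evidence bound. Disease progression is a condition-specific
perturbation θ_AF = θ_BL + X∘B, where the sensitivity mask X either opens
every connection ("ones") or a clinically informed set of 12 DMN connection
groups ("clinical12"), and B is estimated per subject. Group machinery:
Bayesian model reduction (analytic evidence for reduced models), fixed-effects
Bayesian model selection over the 2×2 variant grid (single vs dual glutamate
parameterisation × shared vs region-specific state-to-lead-field weights)
crossed with the two designs, parametric empirical Bayes (PEB) relating
condition effects to a covariate such as the change in ACE-R cognitive score,
and Bayesian model averaging. A synthetic-cohort generator reproduces the
statistical structure of such a study (29 subjects, two sessions, 1-s epochs
at 500 Hz, a declining cognitive score coupled to chosen condition effects),
so the whole pipeline is testable without access to patient data.

## Worked example

Simulate a small cohort with a planted progression effect (weakened
precuneus self-inhibition, coupled to cognitive decline), fit every subject,
and run PEB with the z-scored ACE-R change:

```python
import numpy as np
from ldcm import (CohortSpec, ModelVariant, FitOptions, fit_dcm,
                  GroupDesign, peb_fit, zscore_regressor, make_cohort)
from ldcm.longitudinal import clinical_design

variant = ModelVariant(dual_glutamate=True, regional_stl=True)
spec = CohortSpec(n_subjects=8, variant=variant, seed=7,
                  effect_mean={"3.selfinh.PCC": 0.1},
                  covariate_coupling={"3.selfinh.PCC": 0.5},
                  n_effective_trials=250)
cohort = make_cohort(spec)

posts = [fit_dcm((rec.bl, rec.af), variant, spec.design,
                 options=FitOptions(max_iterations=16, seed=0))
         for rec in cohort.subjects]
X = np.column_stack([np.ones(8),
                     zscore_regressor(cohort.covariates["delta_acer"])])
peb = peb_fit(posts, GroupDesign(X, ["mean", "delta_acer_z"]))
g = spec.design.group_names.index("3.selfinh.PCC")
print(f"F[0] = {posts[0].free_energy:.1f}, converged = {posts[0].converged}")
print(f"group-mean effect  beta = {peb.beta_matrix()[0, g]:.3f}  "
      f"P(>0) = {peb.posterior_sign_probability()[0, g]:.3f}")
print(f"covariate slope    beta = {peb.beta_matrix()[1, g]:.3f}  "
      f"P(>0) = {peb.posterior_sign_probability()[1, g]:.3f}")
```

Output (seed 7):

```
F[0] = 2400.2, converged = True
group-mean effect  beta = 0.119  P(>0) = 1.000
covariate slope    beta = 0.051  P(>0) = 0.951
```

The planted group-mean effect (+0.075 on the precuneus SP/DP self-gain) is
recovered with near-certain positive sign, and its coupling to cognitive
decline appears as a credible positive covariate slope. The same pipeline is
available from the shell:

```bash
ldcm run --seed 7 --n 8 --out results/demo
ldcm report results/demo
ldcm models            # list the 8-model comparison space
```

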