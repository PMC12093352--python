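# Methods

`ldcm` implements longitudinal dynamic causal modelling (DCM) of resting-state
MEG cross-spectral densities (CSD): a conductance-based cortical microcircuit
per source region, an analytic spectral forward model obtained by
linearisation, variational-Laplace inversion, and group-level Bayesian
machinery (model reduction, fixed-effects selection, parametric empirical
Bayes). This note records the model, the numerical choices, and what the
synthetic validation does and does not establish.

## The neuronal model

Each region is a microcircuit of four populations — spiny stellate cells (SS,
granular layer), superficial pyramidal cells (SP), inhibitory interneurons
(INH) and deep pyramidal cells (DP) — each carrying a mean membrane potential
`V` and three channel conductances (AMPA, GABA-A, NMDA). The dynamics follow
the Morris–Lecar-style mean-field form:

    C_p dV/dt   = g_L (V_L − V) + g_A (V_E − V) + g_G (V_I − V)
                  + g_N m(V) (V_N − V)
    kappa_c dg_c/dt = drive_c − g_c

with reversal potentials `V_L = −70`, `V_E = V_N = 60`, `V_I = −90` mV, a
logistic firing-rate function `sigma(V)` (slope 0.25 /mV, threshold −52 mV)
and the magnesium-block gate `m(V) = 1/(1 + 0.33 e^{−0.06 V})` on the NMDA
current. Channel time constants default to (4, 16, 100) ms for AMPA, GABA and
NMDA. A constant background drive (0.6) onto every population's AMPA
conductance sets a depolarised operating point whose linearisation carries an
oscillatory mode near 16 Hz — a resonance in the alpha/beta range, as
expected of resting cortical activity. Sigmoid slope/threshold and background
drive are this package's own calibration of quantities the conductance
literature leaves open; they are config-exposed (`CircuitConfig`).

Intrinsic coupling is a 4×4 gain template per region, partitioned into an
inhibitory part (self-inhibition and interneuron projections, driving GABA
conductances) and an excitatory part (driving AMPA and NMDA conductances).
Extrinsic coupling connects every ordered region pair through the source's SP
and DP rates onto the target's populations — AMPA-mediated (`A`) and
NMDA-mediated (`AN`), separately scaled. Synaptic couplings carry conduction
delays: 2 ms within a region, 16 ms between regions.

All free parameters are log-scalings of these templates (`exp(theta) ×
template`), with diagonal Gaussian priors (variances 1/16 for rate constants
and capacitances, 1/32 for intrinsic gains, 1/8 for extrinsic gains, 1/64 for
delays, 1/128 for spectral nuisance parameters). The lead-field gains `L` are
the exception: they enter linearly with prior N(1, 64). The model grid
crosses two re-parameterisations: `dual_glutamate` (separate intrinsic
AMPA/NMDA gain blocks instead of one shared excitatory block; the two
parameterisations coincide at the prior mean) and `regional_stl` (the
contribution weights of SS and DP voltages to the regional signal, `J_ss` and
`J_dp`, become region-specific; the SP weight is fixed at 1 as the anchor).

## Spectral forward model

The CSD prediction linearises the flow about its noise-free fixed point
(damped Newton; analytic Jacobian, cross-checked against central-difference
and complex-step derivatives in the tests). Delayed couplings enter the
transfer function exactly, per frequency:

    T(w) = O (i w I − J0 − e^{−i w tau1} J_intra − e^{−i w tau2} J_inter)^{−1} G_in

where `G_in` injects endogenous input into each region's granular (SS) AMPA
conductance and `O` is the observation map `L_r (V_SP + e^{J_ss} 0.2 V_SS +
e^{J_dp} 0.2 V_DP)`. A first-order delay correction `(I + tau∘J)^{−1} J` is
also provided (used for cheap stability gating), but it misplaces the in-band
resonance by ~1 Hz and errs by tens of percent in band power, so the exact
per-frequency form is the default for prediction. Since the delays take only
two values, the frequency-dependent matrix splits into three fixed parts and
the solves remain cheap.

The predicted spectrum is

    S(w) = Gu(w) T T^H + Gb(w) 11^T + Gc(w) I,  then  S ← S · h_f(w)

with `Gu` a power law `amp · e^{a1} f^{−e^{a2}}` shaped by a four-term cosine
basis on normalised log-frequency (coefficients `d`), `Gb`/`Gc` common and
channel-specific sensor-noise power laws, and `h_f` a smooth two-coefficient
multiplicative filtration profile (exp of the first two cosine basis
functions — the printed parameterisation states only that some frequencies
are scaled, so a smooth config-exposed profile was chosen). Default analysis
band: 1–48 Hz (below the mains notch), config-exposed to 100 Hz. Endogenous
inputs are independent across regions with a shared spectral shape, injected
into the granular layer — the convention of spectral DCM; the template input
amplitude (1e-3) keeps voltage excursions ~1 mV so the linearisation is
accurate (validated below).

Units: time constants in ms, delays in ms (converted to seconds in the
dynamics), voltages in mV, frequencies in Hz. The printed parameter tables
give none of these; the choices follow the conductance-microcircuit
literature (NMDA slow at 100 ms, AMPA fast at 4 ms).

## Data features

Per 1-s epoch, a multivariate AR(8) model is fitted by least squares and its
spectral matrix `S(f) = (2/fs) H Sigma H^H` evaluated on the analysis grid
(the one-sided density convention of `scipy.signal.welch`). Epoch spectra are
reduced to the first principal component across epochs, computed jointly on
the vectorised complex spectra (real and imaginary parts), sign-aligned with
the across-epoch mean and rescaled to its mean diagonal power. A joint PC
preserves cross-spectral coherence structure; a per-pair mode would not. An
optional variance-threshold epoch filter (reject > 5× median variance) is
available but off by default.

## Inversion

The Hermitian CSD is vectorised per frequency (real upper triangle with
diagonal, then imaginary strict upper triangle). Noise is modelled with two
diagonal precision components — auto-spectra and cross-spectra — with
log-precisions given N(4, 16) hyperpriors. Data and predictions are
prewhitened by the data's per-frequency mean spectral amplitude: spectral
sampling error is multiplicative, so this weighting makes the residuals
approximately homoscedastic within each component and prevents the 1/f-heavy
low frequencies from dominating the fit (without it, fits stall in local
optima with ~0.1 lower recovery correlations).

Optimisation is EM-style Gauss–Newton with Levenberg–Marquardt damping:
damping multiplies the curvature diagonal, grows 8× on rejected steps and
shrinks on accepted ones; log-precisions are updated by Newton steps inside
each evaluation; the posterior covariance is the inverse curvature at the
optimum. The free energy F = accuracy − complexity (Gaussian KL terms for
parameters and hyperparameters) is recomputed fully at every candidate and
never decreases over accepted steps. Convergence: |dF| < 0.01 for 3
consecutive accepted steps, maximum 128 iterations (less in the scaled
validation runs). Initialisation at the prior mean; an optional multistart
flag jitters additional starts. Parameter sensitivities are finite
differences (step 1e-4) evaluated through a linearised path: the resolvent is
LU-factorised once per frequency at the reference point and each perturbed
solution obtained by one iterative-refinement step (relative error ~1e-7,
asserted against the exact path in tests); fixed points are re-solved per
perturbation, warm-started from the reference.

Unstable parameter proposals (positive real eigenvalues of the delay-
corrected Jacobian) predict NaN and are rejected as infinite-error samples.

Two-condition (baseline/follow-up) fits stack both data vectors and invert
jointly over `(theta, B)`, where the condition design maps effects `B` onto
parameter shifts `theta_AF = theta_BL + X∘B`. The condition-effect prior is
N(0, 1/16) per group.

## Condition designs and model space

The non-informative design (`ones`) gives every modifiable parameter
(intrinsic gains, extrinsic A/AN scalings) its own group with X = 1. The
clinically informed design (`clinical12`) restricts progression to twelve
groups in the four-region default mode network (LAG, RAG, MPFC, PCC):
SP/DP self-inhibition of MPFC and of PCC; excitatory intrinsic chains
(SS→SP, SP→DP) of MPFC and of PCC; and AMPA- and NMDA-mediated projections
MPFC–PCC, PCC–LAG, MPFC–RAG, PCC–RAG (AMPA) and MPFC–PCC, PCC–RAG, MPFC–RAG,
PCC–LAG (NMDA). Clinical statements name undirected pairs, so each group
contains both directed scalings. The base model space crosses the four
variants with the two designs (8 models); nested single-group knockouts of
the full clinical model (12 more) are scored by Bayesian model reduction
from the full fit rather than refitted.

## Group level

Bayesian model reduction uses the closed-form Gaussian identities for the
reduced posterior and evidence change; exact under the Laplace assumption and
verified against direct evidence computation on conjugate problems to 1e-6.
Fixed-effects model selection sums free energies over subjects and applies a
softmax under uniform model priors. PEB places `theta_i = X beta + eps_i`,
`eps_i ~ N(0, e^{−gamma} V)` over a selected parameter block (default: the
condition effects B), with `V` = 1/16 of the first-level prior covariance and
`gamma ~ N(0, 1/16)`. Each subject's likelihood over the block is recovered
from its posterior and prior (information `Sigma_post^{-1} −
Sigma_prior^{-1}`, eigenvalue-clipped to PSD), `beta` then has a closed-form
Gaussian posterior given `gamma`, and the scalar `gamma` maximises the
hierarchical free energy numerically. Updated first-level posteriors under
the empirical prior are returned via BMR. Bayesian model averaging uses
mixture moments (law of total variance). The PEB design matrix is
`[1, z-scored ACE-R change]` in the pipeline.

## Synthetic cohorts

`make_cohort` emulates the study conditions: 29 subjects by default, paired
baseline/follow-up features, a cognitive score (ACE-R, 0–100, baseline mean
75.6, SD 10.2) declining by 5 ± 4 points between sessions, truncated to the
instrument's range. Baseline parameters are drawn from the model priors,
except the lead-field gains, drawn N(1, 0.25²): the flat inferential prior on
L (variance 64) does not describe plausible between-subject gain variability.
Condition effects are group means plus between-subject deviations (SD 0.1);
designated groups' deviations correlate with the latent cognitive decline at
a requested level. Unstable draws are redrawn (their condition effects and
covariates are kept, preserving the planted coupling).

Two data paths: the default fast path samples complex-Wishart matrices
around the analytic CSD with `n_effective_trials` degrees of freedom
(sampling error shrinking as 1/sqrt(n), emulating an n-epoch estimate); the
slow path integrates the nonlinear delayed system by a Heun scheme
(second-order, so discrete poles match `e^{lambda dt}` and the simulated
spectrum is unbiased at the resonances, unlike forward Euler) with
pre-synthesised spectrally shaped endogenous input and delayed firing-rate
ring buffers, then decimates to 500 Hz and cuts 1-s epochs.

The fast path emulates the *sampling* variability of spectral estimation but
not AR-model bias, epoch non-stationarity, artifact residue, or source-
leakage correlations of real MEG; the slow path adds the true nonlinear and
delay structure but still assumes stationarity and exact source separation.
Passing the validation suite therefore establishes internal consistency and
identifiability under the model's own assumptions — not robustness to the
mismatches of empirical recordings.

## Validation experiments and problem sizes

The validation module re-runs the main claims at sizes chosen for a
single-CPU budget of minutes:

- Forward oracle: 600 s of the four-region default model at 1 kHz vs the
  analytic CSD; log-power correlation ≥ 0.95 and worst-case auto-spectral
  relative error < 15% over 4–45 Hz.
- Inversion/BMR oracles: conjugate linear-Gaussian problems; agreement to
  1e-6 and monotone free energy.
- Recovery: 20 two-region subjects (fast CSD path, 200 effective trials);
  pooled correlation between true and posterior-mean parameters over the
  gain/lead-field blocks ≥ 0.8. Condition-effect sign recovery: 20 two-
  condition replicates with a planted effect of 0.3 condition-effect prior
  SDs; ≥ 90% correct signs.
- Group level: a 29-subject two-region cohort with a planted group effect
  coupled (r = 0.6) to the synthetic decline; PEB sign probability > 0.95 on
  both regressors. Model identification: four replicates of the full
  four-region 8-model comparison on data generated under the dual-glutamate
  + regional-STL variant with clinical effects (2000 effective trials, one
  fitted subject per replicate); the winner must carry regional STL in ≥ 70%
  of replicates. The regional-STL attribute is the identifiable one at this
  scale; the AMPA/NMDA split contributes almost no evidence on its own, so
  family membership is defined over regional STL.

## Known limitations

- The intrinsic coupling templates follow this package's parse of the
  published digit strings (chosen because inhibitory + excitatory parts sum
  exactly to the default template); alternative parses can be loaded from
  config.
- Sensor-space forward modelling, preprocessing and source inversion are out
  of scope; lead fields are scalar per-region gains.
- Fixed-effects model selection only; no random-effects BMS.
- The variational scheme shares the usual Laplace caveats: multimodal
  posteriors are summarised by a single Gaussian, and evidence differences
  below ~0.5 nat are within convergence noise at the scaled iteration
  budgets.
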