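"""Synthetic longitudinal cohorts with the statistical structure the analysis assumes.

The generator emulates the study conditions of a longitudinal resting-state
MEG cohort: ~29 subjects recorded at baseline (BL) and follow-up (AF), four
default-mode-network sources, 1-s epochs at 500 Hz, a cognitive score (ACE-R,
0-100) declining between sessions, and condition effects B on a chosen
condition design whose between-subject variation correlates with the decline.

Two data paths are provided.  The fast path (:func:`simulate_csd`) draws a
complex-Wishart-distributed sample around the analytic model CSD, emulating
the sampling variability of an n-epoch spectral estimate without integrating
the dynamics; it is the default for cohort generation.  The slow path
(:func:`simulate_epochs`) integrates the nonlinear delayed stochastic system
by Euler-Maruyama with spectrally shaped endogenous input and serves as the
independent oracle for the linearised forward model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import hashlib

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .config import CircuitConfig, default_config, SP, DP
from .exceptions import StabilityError, DesignError
from .model import (
    ModelVariant,
    ParameterVector,
    ScaledParameters,
    scale_parameters,
    default_priors,
    fixed_point,
    firing_rate,
    nmda_gate,
    get_layout,
    CH_V,
)
from .forward import (
    FrequencyGrid,
    CrossSpectrum,
    default_grid,
    predict_csd,
    input_spectrum,
    sensor_noise_spectra,
    _observation_matrix,
)
from .features import EpochSet, CSDFeature
from .longitudinal import ConditionDesign, clinical_design, apply_condition_effects


# ---------------------------------------------------------------------------
# Cohort specification
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Study-design parameters of a synthetic longitudinal cohort.

    ``effect_mean`` maps condition-design group names to the group-level mean
    of the true condition effect B (in log-scaling units, i.e. fractions of
    the typical prior standard deviation); ``effect_sd`` is the
    between-subject standard deviation of each effect; ``covariate_coupling``
    gives the correlation between a group's B and the (z-scored) ACE-R change
    between sessions.
    """

    n_subjects: int = 29
    variant: ModelVariant = field(
        default_factory=lambda: ModelVariant(dual_glutamate=True, regional_stl=True))
    design: ConditionDesign = None
    effect_mean: dict = field(default_factory=dict)
    effect_sd: float = 0.1
    covariate_coupling: dict = field(default_factory=dict)
    # Cognitive covariate (ACE-R, 0-100): cohort baseline mean/SD and the
    # mean/SD of the decline to follow-up.
    acer_mean: float = 75.6
    acer_sd: float = 10.2
    decline_mean: float = 5.0
    decline_sd: float = 4.0
    # Epoching of the simulated recordings.
    epoch_duration: float = 1.0
    sampling_rate: float = 500.0
    n_epochs: int = 250
    # Fast-path effective number of spectral averages.
    n_effective_trials: int = 100
    # Between-subject SD of the lead-field gains around 1.  The inferential
    # prior variance on L (64) is deliberately flat and does not describe a
    # plausible cohort; gains in real cohorts vary by tens of percent.
    leadfield_sd: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise DesignError("a cohort needs at least 2 subjects")
        for name, rho in self.covariate_coupling.items():
            if not -1.0 <= rho <= 1.0:
                raise DesignError(f"covariate coupling for {name!r} outside [-1, 1]")
        if self.design is None:
            self.design = clinical_design(self.variant)

    @property
    def grid(self) -> FrequencyGrid:
        return default_grid()


@dataclass
class CohortParameters:
    theta_bl: np.ndarray        # (n_subjects, n_params)
    B_true: np.ndarray          # (n_subjects, n_groups)
    covariates: pd.DataFrame    # subject_id, acer_bl, acer_af, delta_acer


@dataclass
class SubjectRecord:
    subject: str
    bl: CSDFeature
    af: CSDFeature
    theta_true: np.ndarray
    B_true: np.ndarray


@dataclass
class LongitudinalDataset:
    """Paired BL/AF CSD features per subject plus the covariate table."""

    subjects: list
    covariates: pd.DataFrame
    spec: CohortSpec = None

    def __len__(self):
        return len(self.subjects)

    def digest(self) -> str:
        """SHA-256 over all numeric content (determinism checks)."""
        h = hashlib.sha256()
        for rec in self.subjects:
            for feat in (rec.bl, rec.af):
                h.update(np.ascontiguousarray(feat.S).tobytes())
            h.update(np.ascontiguousarray(rec.theta_true).tobytes())
            h.update(np.ascontiguousarray(rec.B_true).tobytes())
        h.update(self.covariates.to_csv(index=False).encode())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# Parameter and covariate sampling
# ---------------------------------------------------------------------------

def generate_parameters(spec: CohortSpec) -> CohortParameters:
    """Sample per-subject baseline parameters, condition effects and covariates.

    Baseline parameters are drawn from the model priors (lead-field gains from
    a cohort-scale distribution around 1, see :class:`CohortSpec`); condition
    effects are group means plus between-subject deviations, with designated
    groups' deviations correlated with the latent cognitive decline.
    """
    rng = np.random.default_rng(spec.seed)
    layout = get_layout(spec.variant)
    prior = default_priors(spec.variant)
    n, p = spec.n_subjects, layout.n_params

    sd = np.sqrt(prior.variances.copy())
    sl_L = layout.blocks["L"][0]
    sd[sl_L] = spec.leadfield_sd
    theta = prior.mean + sd * rng.standard_normal((n, p))

    z = rng.standard_normal(n)                      # latent decline (higher = steeper)
    design = spec.design
    B = np.zeros((n, design.n_groups))
    for k, g in enumerate(design.groups):
        mean = spec.effect_mean.get(g.name, 0.0)
        rho = spec.covariate_coupling.get(g.name, 0.0)
        eps = rng.standard_normal(n)
        # delta_acer = -decline, so corr(B, delta_acer) = +rho uses -z.
        B[:, k] = mean + spec.effect_sd * (rho * (-z) + np.sqrt(1 - rho ** 2) * eps)

    acer_bl = np.clip(spec.acer_mean + spec.acer_sd * rng.standard_normal(n), 0, 100)
    decline = spec.decline_mean + spec.decline_sd * z
    acer_af = np.clip(acer_bl - decline, 0, 100)
    cov = pd.DataFrame({
        "subject_id": [f"sub-{i+1:02d}" for i in range(n)],
        "acer_bl": np.round(acer_bl, 1),
        "acer_af": np.round(acer_af, 1),
    })
    cov["delta_acer"] = cov["acer_af"] - cov["acer_bl"]
    return CohortParameters(theta, B, cov)


# ---------------------------------------------------------------------------
# Stochastic simulation (oracle path)
# ---------------------------------------------------------------------------

def _colored_noise(psd, N: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Real series of length N whose one-sided PSD follows ``psd(f)``."""
    f = np.fft.rfftfreq(N, 1.0 / fs)
    G = np.zeros_like(f)
    G[1:] = psd(f[1:])
    X = (rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size)) \
        * np.sqrt(G * fs * N / 4.0)
    X[0] = 0.0
    if N % 2 == 0:
        X[-1] = X[-1].real * np.sqrt(2.0)
    return np.fft.irfft(X, n=N)


def _coupling_matrices(sp: ScaledParameters):
    """Dense rate-to-drive maps over the stacked (R*4) population rate vector."""
    R = sp.n_regions
    n = 4 * R
    Ga = np.zeros((n, n)); Gg = np.zeros((n, n)); Gn = np.zeros((n, n))
    Aa = np.zeros((n, n)); An = np.zeros((n, n))
    for r in range(R):
        sl = slice(4 * r, 4 * r + 4)
        Ga[sl, sl] = sp.G_ampa[r]
        Gg[sl, sl] = sp.G_gaba[r]
        Gn[sl, sl] = sp.G_nmda[r]
    for k, (s, t) in enumerate(sp.edges):
        Aa[4 * t: 4 * t + 4, 4 * s + SP] += sp.A[k][:, 0]
        Aa[4 * t: 4 * t + 4, 4 * s + DP] += sp.A[k][:, 1]
        An[4 * t: 4 * t + 4, 4 * s + SP] += sp.AN[k][:, 0]
        An[4 * t: 4 * t + 4, 4 * s + DP] += sp.AN[k][:, 1]
    return Ga, Gg, Gn, Aa, An


def simulate_timeseries(theta, variant: ModelVariant, duration: float,
                        fs_sim: float = 2000.0, seed=0,
                        config: CircuitConfig = None, burn: float = 2.0,
                        sensor_noise: bool = True) -> tuple:
    """Euler-Maruyama integration of the nonlinear delayed system.

    Endogenous input with the parameterised fluctuation spectrum is injected
    into each region's granular population; firing rates propagate through the
    intrinsic couplings with the intrinsic delay and through extrinsic
    projections with the extrinsic delay.  Returns ``(Y, fs_sim)`` with ``Y``
    of shape (samples, regions), the observed regional signals.
    """
    cfg = config or default_config()
    rng = np.random.default_rng(seed)
    vec = theta.values if hasattr(theta, "values") else np.asarray(theta, dtype=float)
    sp = scale_parameters(vec, variant, cfg)
    R = variant.n_regions
    dt = 1.0 / fs_sim
    N = int(round((duration + burn) * fs_sim))

    U = np.stack([
        _colored_noise(lambda f: input_spectrum(sp.a, sp.d, FrequencyGrid(f), cfg),
                       N, fs_sim, rng)
        for _ in range(R)
    ], axis=1)

    st0 = fixed_point(sp)
    x = st0.values.reshape(R * 4, 4).copy()      # rows: populations; cols: V,gA,gG,gN
    Ga, Gg, Gn, Aa, An = _coupling_matrices(sp)
    rates = 1000.0 / sp.kappa
    C = np.tile(sp.C, R)
    d1 = max(int(round(sp.delays[0] * 1e-3 * fs_sim)), 1)
    d2 = max(int(round(sp.delays[1] * 1e-3 * fs_sim)), 1)
    H = max(d1, d2) + 1
    s0 = np.asarray(firing_rate(x[:, CH_V], config=cfg))
    hist = np.tile(s0, (H, 1))
    O = _observation_matrix(sp)
    obs = O.reshape(R, R, 4, 4)[:, :, :, CH_V].reshape(R, R * 4)  # V-weights only
    bg = cfg.background_drive
    u_mask = np.zeros(R * 4)
    Y = np.empty((N, R))

    gl, vl, ve, vi, vn = (cfg.leak_conductance, cfg.v_leak, cfg.v_exc,
                          cfg.v_inh, cfg.v_nmda)
    mg_a, mg_b = cfg.mg_scale, cfg.mg_slope
    slope, thresh = cfg.sigmoid_slope, cfg.sigmoid_threshold
    uvec = np.zeros(R * 4)
    ss_rows = 4 * np.arange(R)

    def deriv(xs, s_in, s_ex, u_row):
        V = xs[:, 0]; gA = xs[:, 1]; gG = xs[:, 2]; gN = xs[:, 3]
        da = Ga @ s_in + Aa @ s_ex + bg
        da[ss_rows] += u_row
        dg = Gg @ s_in
        dn = Gn @ s_in + An @ s_ex
        gate = 1.0 / (1.0 + mg_a * np.exp(-mg_b * V))
        dV = (gl * (vl - V) + gA * (ve - V) + gG * (vi - V)
              + gN * gate * (vn - V)) / C
        return np.stack([dV, (da - gA) * rates[0], (dg - gG) * rates[1],
                         (dn - gN) * rates[2]], axis=-1)

    # Heun (improved Euler) with delayed firing rates read from a ring buffer:
    # second-order accurate, so the discrete poles match e^(lambda dt) closely
    # and the simulated spectrum is not biased at oscillatory modes.
    for k in range(N):
        V = x[:, 0]
        hist[k % H] = 1.0 / (1.0 + np.exp(-slope * (V - thresh)))
        s_in1 = hist[(k - d1) % H]
        s_ex1 = hist[(k - d2) % H]
        f1 = deriv(x, s_in1, s_ex1, U[k])
        xe = x + dt * f1
        kn = min(k + 1, N - 1)
        s_in2 = hist[(k + 1 - d1) % H]
        s_ex2 = hist[(k + 1 - d2) % H]
        f2 = deriv(xe, s_in2, s_ex2, U[kn])
        x = x + 0.5 * dt * (f1 + f2)
        if not -200.0 < x[0, 0] < 100.0:
            raise StabilityError("state divergence during stochastic integration")
        Y[k] = obs @ x[:, 0]
    Y = Y[int(round(burn * fs_sim)):]
    Y = Y - Y.mean(axis=0)

    if sensor_noise:
        M = Y.shape[0]
        common = _colored_noise(
            lambda f: sensor_noise_spectra(sp.b, sp.c, FrequencyGrid(f), cfg)[0],
            M, fs_sim, rng)
        Y = Y + common[:, None]
        for r in range(R):
            Y[:, r] += _colored_noise(
                lambda f: sensor_noise_spectra(sp.b, sp.c, FrequencyGrid(f), cfg)[1],
                M, fs_sim, rng)
    return Y, fs_sim


def simulate_epochs(theta, variant: ModelVariant, n_epochs: int = 250,
                    epoch_duration: float = 1.0, sampling_rate: float = 500.0,
                    seed=0, config: CircuitConfig = None,
                    subject: str = None, condition: str = None,
                    fs_sim: float = 2000.0) -> EpochSet:
    """Simulated 1-s epochs at the recording rate (default 500 Hz)."""
    duration = n_epochs * epoch_duration
    Y, fs = simulate_timeseries(theta, variant, duration, fs_sim=fs_sim,
                                seed=seed, config=config)
    q = int(round(fs / sampling_rate))
    if q > 1:
        Y = sp_signal.decimate(Y, q, axis=0, ftype="fir", zero_phase=True)
    spc = int(round(epoch_duration * sampling_rate))
    n_avail = Y.shape[0] // spc
    data = Y[: n_avail * spc].reshape(n_avail, spc, -1)[:n_epochs]
    return EpochSet(data, sampling_rate, subject=subject, condition=condition,
                    region_labels=variant.region_labels)


# ---------------------------------------------------------------------------
# Fast CSD sampling (default cohort path)
# ---------------------------------------------------------------------------

def simulate_csd(theta, variant: ModelVariant, grid: FrequencyGrid = None,
                 n_effective_trials: int = 100, seed=0,
                 config: CircuitConfig = None,
                 subject: str = None, condition: str = None) -> CSDFeature:
    """Analytic model CSD plus complex-Wishart sampling noise.

    Each frequency's matrix is the mean of ``n_effective_trials`` rank-one
    outer products of complex-normal draws with covariance equal to the model
    CSD, so sampling fluctuations shrink as 1/sqrt(n) and vanish in the
    infinite-trial limit.
    """
    grid = grid or default_grid()
    rng = np.random.default_rng(seed)
    pred = predict_csd(theta, variant, grid, config)
    F, R = len(grid), variant.n_regions
    n = int(n_effective_trials)
    S = np.empty_like(pred.S)
    jitter = 1e-12 * np.trace(pred.S.real, axis1=1, axis2=2).mean() / R
    for k in range(F):
        Lk = np.linalg.cholesky(pred.S[k] + jitter * np.eye(R))
        Z = (rng.standard_normal((R, n)) + 1j * rng.standard_normal((R, n))) / np.sqrt(2)
        X = Lk @ Z
        S[k] = X @ X.conj().T / n
    return CSDFeature(grid, S, variant.region_labels,
                      metadata={"n_effective_trials": n, "sampler": "wishart"},
                      subject=subject, condition=condition)


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

def _subject_seed(base_seed: int, i: int, which: int) -> int:
    return int(np.random.SeedSequence([base_seed, i, which]).generate_state(1)[0] % (2 ** 31))


def make_cohort(spec: CohortSpec, max_resample: int = 50) -> LongitudinalDataset:
    """Full synthetic longitudinal dataset: BL/AF CSD features + covariates.

    BL features come from the sampled baseline parameters; AF features from
    the same parameters perturbed by the subject's true condition effects
    through the cohort's condition design.  Subjects whose baseline or
    follow-up linearisation is unstable are redrawn (a fresh seed), mirroring
    the rejection of unstable parameter samples during inversion.
    """
    params = generate_parameters(spec)
    design = spec.design
    subjects = []
    theta = params.theta_bl.copy()
    B = params.B_true.copy()
    for i in range(spec.n_subjects):
        sid = params.covariates["subject_id"].iloc[i]
        attempt = 0
        while True:
            th_bl = theta[i]
            th_af = apply_condition_effects(th_bl, design, B[i])
            try:
                bl = simulate_csd(th_bl, spec.variant, spec.grid,
                                  spec.n_effective_trials,
                                  seed=_subject_seed(spec.seed, i, 0),
                                  subject=sid, condition="BL")
                af = simulate_csd(th_af, spec.variant, spec.grid,
                                  spec.n_effective_trials,
                                  seed=_subject_seed(spec.seed, i, 1),
                                  subject=sid, condition="AF")
                break
            except StabilityError:
                attempt += 1
                if attempt > max_resample:
                    raise
                # Redraw only the baseline parameters; the condition effects
                # keep their coupling to this subject's stored covariate.
                rng = np.random.default_rng(_subject_seed(spec.seed, i, 100 + attempt))
                layout = get_layout(spec.variant)
                prior = default_priors(spec.variant)
                sd = np.sqrt(prior.variances.copy())
                sd[layout.blocks["L"][0]] = spec.leadfield_sd
                theta[i] = prior.mean + sd * rng.standard_normal(layout.n_params)
        subjects.append(SubjectRecord(sid, bl, af, theta[i].copy(), B[i].copy()))
    return LongitudinalDataset(subjects, params.covariates, spec)
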