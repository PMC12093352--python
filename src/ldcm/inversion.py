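"""Variational-Laplace inversion of the spectral generative model.

The complex cross-spectral feature is vectorised into a real data vector
(real upper triangle including the diagonal, then imaginary strict upper
triangle, per frequency) and fitted under a Gaussian observation model with
two diagonal precision components — one for auto-spectra, one for
cross-spectra — whose log-precisions are optimised alongside the parameters.

The scheme is EM-style Gauss-Newton: the posterior mean is updated with
Levenberg-Marquardt damping (damping grows on rejected steps and shrinks on
accepted ones), the posterior covariance follows in closed form from the
local curvature, and noise log-precisions maximise the variational free
energy

    F = accuracy - complexity
      = E_q[ln p(y | theta, lambda)] - KL[q(theta) || p(theta)] - KL_lambda,

which is a lower bound on the log-model evidence.  Accepted iterations never
decrease F.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import CircuitConfig, default_config
from .exceptions import DataError, DesignError, LdcmError
from .model import ModelVariant, PriorDensity, get_layout
from .forward import (CrossSpectrum, FrequencyGrid, predict_csd_batch,
                      predict_csd_linearised)
from .longitudinal import ConditionDesign

_LOG2PI = np.log(2 * np.pi)


# ---------------------------------------------------------------------------
# Data vectorisation
# ---------------------------------------------------------------------------

def vectorize_csd(feature: CrossSpectrum, hermitian_tol: float = 1e-6):
    """Stack a Hermitian CSD into a real vector plus precision-component masks.

    Returns ``(y, components)`` where ``components`` is a list of boolean
    masks over the data vector: auto-spectral entries (matrix diagonal) and
    cross-spectral entries (off-diagonal real and imaginary parts).
    """
    S = np.asarray(feature.S)
    scale = np.abs(S).max() or 1.0
    if np.abs(S - np.conj(np.swapaxes(S, -1, -2))).max() > hermitian_tol * scale:
        raise DataError("cross-spectrum is not Hermitian within tolerance")
    F, R, _ = S.shape
    y = _stack_csd(S)
    auto, cross = _component_masks(F, R)
    return y, [auto, cross]


def _stack_csd(S: np.ndarray) -> np.ndarray:
    F, R = S.shape[-3], S.shape[-1]
    iu = np.triu_indices(R)
    ius = np.triu_indices(R, k=1)
    parts = [S[..., iu[0], iu[1]].real]
    if ius[0].size:
        parts.append(S[..., ius[0], ius[1]].imag)
    return np.concatenate(parts, axis=-1).reshape(S.shape[:-3] + (-1,))


def _component_masks(F: int, R: int):
    iu = np.triu_indices(R)
    n_re = iu[0].size
    n_im = R * (R - 1) // 2
    per_f = n_re + n_im
    auto = np.zeros(F * per_f, dtype=bool)
    diag_in_upper = np.array([k for k, (i, j) in enumerate(zip(*iu)) if i == j])
    for f in range(F):
        auto[f * per_f + diag_in_upper] = True
    cross = ~auto
    return auto, cross


def devectorize_csd(y: np.ndarray, grid: FrequencyGrid, region_labels) -> CrossSpectrum:
    """Inverse of :func:`vectorize_csd` (exact round trip)."""
    R = len(region_labels)
    F = len(grid)
    iu = np.triu_indices(R)
    ius = np.triu_indices(R, k=1)
    per_f = y.reshape(F, -1)
    S = np.zeros((F, R, R), dtype=complex)
    S[:, iu[0], iu[1]] = per_f[:, : iu[0].size]
    if ius[0].size:
        S[:, ius[0], ius[1]] += 1j * per_f[:, iu[0].size:]
    S = S + np.conj(np.swapaxes(np.triu(S, k=1), -1, -2))
    return CrossSpectrum(grid, S, tuple(region_labels))


# ---------------------------------------------------------------------------
# Posterior and options
# ---------------------------------------------------------------------------

@dataclass
class Posterior:
    """Gaussian posterior, noise hyperparameters and free energy of one fit."""

    mean: np.ndarray
    covariance: np.ndarray
    hyper: np.ndarray            # log-precisions per component
    free_energy: float
    prior: PriorDensity = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.mean.size

    @property
    def converged(self) -> bool:
        return bool(self.diagnostics.get("converged", False))

    @property
    def n_theta(self) -> int:
        return int(self.diagnostics.get("n_theta", self.n))

    @property
    def theta_mean(self) -> np.ndarray:
        return self.mean[: self.n_theta]

    @property
    def B_mean(self) -> np.ndarray:
        return self.mean[self.n_theta:]


@dataclass
class FitOptions:
    """Numerical controls of the variational-Laplace scheme."""

    max_iterations: int = 128
    tolerance: float = 0.01          # |dF| threshold
    tolerance_consecutive: int = 3
    initial_damping: float = 1e-2
    damping_factor: float = 8.0
    max_trials: int = 6
    fd_step: float = 1e-4
    hyper_mean: float = 4.0
    hyper_variance: float = 16.0
    hyper_iterations: int = 8
    n_starts: int = 1
    start_jitter: float = 0.1
    seed: int = 0
    init: np.ndarray = None          # optional starting point (defaults to prior mean)
    b_prior_variance: float = 1.0 / 16
    condition_scale: float = None    # override data normalisation

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("convergence tolerance must be positive")


# ---------------------------------------------------------------------------
# Variational Laplace
# ---------------------------------------------------------------------------

def _call_predictor(predictor, thetas, base):
    try:
        return np.asarray(predictor(thetas, base=base), dtype=float)
    except TypeError:
        return np.asarray(predictor(thetas), dtype=float)


def _update_hyper(lam, e, w_diag, masks, opts: FitOptions):
    """Newton maximisation of F over component log-precisions."""
    eta, var = opts.hyper_mean, opts.hyper_variance
    lam = lam.copy()
    stats = np.array([np.sum((e ** 2 + w_diag)[m]) for m in masks])
    counts = np.array([int(m.sum()) for m in masks])
    for _ in range(opts.hyper_iterations):
        ex = np.exp(lam)
        grad = 0.5 * (counts - ex * stats) - (lam - eta) / var
        curv = -0.5 * ex * stats - 1.0 / var
        lam = np.clip(lam - grad / curv, -8.0, 32.0)
    curv = -0.5 * np.exp(lam) * stats - 1.0 / var
    c_lam = -1.0 / curv
    return lam, c_lam


def _precisions(lam, masks, ny):
    pi = np.zeros(ny)
    for q, m in enumerate(masks):
        pi[m] = np.exp(lam[q])
    return pi


def _free_energy(e, pi, d0, P0, H, lam, c_lam, opts: FitOptions):
    ny = e.size
    sign, logdet_H = np.linalg.slogdet(H)
    if sign <= 0:
        return -np.inf, None
    _, logdet_P0 = np.linalg.slogdet(P0)
    acc = -0.5 * np.sum(pi * e ** 2) + 0.5 * np.sum(np.log(pi)) - 0.5 * ny * _LOG2PI
    comp_theta = 0.5 * d0 @ P0 @ d0 + 0.5 * (logdet_H - logdet_P0)
    dl = lam - opts.hyper_mean
    comp_lam = 0.5 * np.sum(dl ** 2) / opts.hyper_variance \
        - 0.5 * np.sum(np.log(c_lam / opts.hyper_variance))
    return acc - comp_theta - comp_lam, logdet_H


def _evaluate(predictor, mu, y, masks, P0, mu0, lam, opts: FitOptions):
    """Predict, differentiate, optimise hyperparameters and score F at ``mu``."""
    n = mu.size
    g = _call_predictor(predictor, mu[None, :], base=True)[0]
    if not np.all(np.isfinite(g)):
        return None
    # The base point is re-evaluated inside the perturbation batch so the
    # finite differences are internally consistent even when the batched
    # path runs at reduced precision.
    thetas = np.vstack([mu[None, :], mu[None, :] + opts.fd_step * np.eye(n)])
    gp = _call_predictor(predictor, thetas, base=False)
    J = (gp[1:] - gp[0]) / opts.fd_step
    J = np.where(np.isfinite(J), J, 0.0).T      # (ny, n)
    e = y - g
    d0 = mu - mu0
    # Iterate hyperparameters to self-consistency with the curvature.
    w_diag = np.zeros_like(e)
    H = None
    for _ in range(3):
        lam, c_lam = _update_hyper(lam, e, w_diag, masks, opts)
        pi = _precisions(lam, masks, e.size)
        H = (J * pi[:, None]).T @ J + P0
        try:
            Cp = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None
        w_diag = np.einsum("ij,jk,ik->i", J, Cp, J)
    F, _ = _free_energy(e, pi, d0, P0, H, lam, c_lam, opts)
    if not np.isfinite(F):
        return None
    grad = J.T @ (pi * e) - P0 @ d0
    return {"g": g, "J": J, "e": e, "pi": pi, "lam": lam, "H": H, "Cp": Cp,
            "grad": grad, "F": F}


def variational_laplace(predictor, y: np.ndarray, priors: PriorDensity,
                        options: FitOptions = None) -> Posterior:
    """Fit a nonlinear Gaussian model by EM-style Gauss-Newton ascent on F.

    ``predictor`` maps a batch of parameter vectors (P, n) to predictions
    (P, ny); non-finite predictions are treated as infinite-error samples
    (rejected proposals).  ``y`` is the real data vector.  The noise precision
    is ``sum_q exp(lambda_q) Q_q`` over the diagonal component masks attached
    to ``y`` via :func:`vectorize_csd` (a single component covering
    everything is used when none are supplied).
    """
    opts = options or FitOptions()
    masks = None
    if isinstance(y, tuple):
        y, masks = y
    y = np.asarray(y, dtype=float)
    if masks is None:
        masks = [np.ones(y.size, dtype=bool)]
    mu0 = priors.mean.copy()
    P0 = np.linalg.inv(priors.covariance)

    rng = np.random.default_rng(opts.seed)
    best = None
    for start in range(max(opts.n_starts, 1)):
        if start == 0:
            mu_init = mu0.copy() if opts.init is None else np.asarray(opts.init, dtype=float).copy()
        else:
            mu_init = mu0 + opts.start_jitter * \
                np.sqrt(np.diag(priors.covariance)) * rng.standard_normal(mu0.size)
        post = _vl_single(predictor, y, masks, mu0, P0, mu_init, opts, priors)
        if best is None or post.free_energy > best.free_energy:
            best = post
    return best


def _vl_single(predictor, y, masks, mu0, P0, mu_init, opts: FitOptions,
               priors: PriorDensity) -> Posterior:
    lam0 = np.full(len(masks), float(opts.hyper_mean))
    state = _evaluate(predictor, mu_init, y, masks, P0, mu0, lam0, opts)
    if state is None:
        raise LdcmError("non-finite prediction at the initial parameters")
    mu = mu_init.copy()
    nu = opts.initial_damping
    f_trace = [state["F"]]
    consecutive = 0
    converged = False
    n_iter = 0
    n_rejected = 0
    for n_iter in range(1, opts.max_iterations + 1):
        accepted = False
        for _ in range(opts.max_trials):
            Hd = state["H"] + nu * np.diag(np.diag(state["H"]))
            try:
                step = np.linalg.solve(Hd, state["grad"])
            except np.linalg.LinAlgError:
                nu *= opts.damping_factor
                continue
            cand = mu + step
            cand_state = _evaluate(predictor, cand, y, masks, P0, mu0,
                                   state["lam"], opts)
            if cand_state is not None and cand_state["F"] >= state["F"]:
                dF = cand_state["F"] - state["F"]
                mu, state = cand, cand_state
                nu = max(nu / opts.damping_factor, 1e-8)
                f_trace.append(state["F"])
                accepted = True
                consecutive = consecutive + 1 if dF < opts.tolerance else 0
                break
            nu = min(nu * opts.damping_factor, 1e8)
            n_rejected += 1
        if not accepted:
            # Damping exhausted: local optimum within numerical resolution.
            converged = nu >= 1e8 or n_iter > 1
            break
        if consecutive >= opts.tolerance_consecutive:
            converged = True
            break
    return Posterior(
        mean=mu,
        covariance=0.5 * (state["Cp"] + state["Cp"].T),
        hyper=state["lam"],
        free_energy=state["F"],
        prior=priors,
        diagnostics={
            "iterations": n_iter,
            "converged": converged,
            "f_trace": np.asarray(f_trace),
            "rejected": n_rejected,
        },
    )


# ---------------------------------------------------------------------------
# DCM front end
# ---------------------------------------------------------------------------

def _joint_prior(variant: ModelVariant, design, opts: FitOptions,
                 priors: PriorDensity = None) -> PriorDensity:
    from .model import default_priors
    base = priors or default_priors(variant)
    if design is None:
        return base
    nb = design.n_groups
    mean = np.concatenate([base.mean, np.zeros(nb)])
    cov = np.zeros((base.n + nb, base.n + nb))
    cov[: base.n, : base.n] = base.covariance
    cov[base.n:, base.n:] = np.eye(nb) * opts.b_prior_variance
    return PriorDensity(mean, cov)


def fit_dcm(features, variant: ModelVariant, design: ConditionDesign = None,
            options: FitOptions = None, priors: PriorDensity = None,
            config: CircuitConfig = None) -> Posterior:
    """Invert one subject's CSD feature(s).

    ``features`` is a single :class:`CrossSpectrum` (one condition) or a
    (baseline, follow-up) pair, in which case a condition design is required
    and the joint predictor ``[S(theta); S(theta + X o B)]`` is inverted over
    ``(theta, B)``.
    """
    opts = options or FitOptions()
    cfg = config or default_config()
    pair = isinstance(features, (tuple, list))
    if pair:
        if len(features) != 2:
            raise DesignError("expected (baseline, follow-up) feature pair")
        if design is None:
            raise DesignError("a condition design is required for two conditions")
        bl, af = features
        if not np.array_equal(bl.freq.frequencies, af.freq.frequencies):
            raise DataError("conditions use different frequency grids")
        grid = bl.freq
        y_bl, masks_single = vectorize_csd(bl)
        y_af, _ = vectorize_csd(af)
        y = np.concatenate([y_bl, y_af])
        masks = [np.concatenate([m, m]) for m in masks_single]
    else:
        if design is not None and design.n_groups:
            design = None  # single condition: no condition effects to estimate
        grid = features.freq
        y, masks = vectorize_csd(features)

    # Per-frequency prewhitening: spectral sampling noise scales with the
    # spectrum itself (multiplicative), so data and predictions are divided by
    # the data's per-frequency amplitude.  This renders the residuals
    # approximately homoscedastic within the auto/cross precision components
    # and stops the 1/f-dominated low frequencies from swamping the fit.
    if opts.condition_scale is not None:
        weights = np.full(y.size, float(opts.condition_scale))
    else:
        feats = [bl, af] if pair else [features]
        wlist = []
        for ft in feats:
            amp = np.abs(np.einsum("frr->fr", np.asarray(ft.S))).mean(axis=1)
            amp = np.maximum(amp, 1e-12 * amp.max())
            n_entries = y.size // (len(feats) * len(ft.freq))
            wlist.append(np.repeat(1.0 / amp, n_entries))
        weights = np.concatenate(wlist)
    y_s = y * weights
    scale = weights
    layout = get_layout(variant)
    n_theta = layout.n_params
    joint_prior = _joint_prior(variant, design, opts, priors)

    fp_cache = {"bl": None, "af": None}

    def predictor(thetas, base=False):
        """Base evaluations run the full (stability-gated) forward model;
        finite-difference batches (row 0 = reference) use the linearised
        refinement path around that reference."""
        thetas = np.asarray(thetas)
        P = thetas.shape[0]
        th_bl = thetas[:, :n_theta]
        th_af = th_bl + design.expand(thetas[:, n_theta:]) if pair else None
        if base:
            stacked = np.concatenate([th_bl, th_af], axis=0) if pair else th_bl
            S, stable, fp = predict_csd_batch(stacked, variant, grid, cfg,
                                              check_stability=True,
                                              return_fp=True)
            if np.all(stable):
                fp_cache["bl"] = fp[:P].copy()
                if pair:
                    fp_cache["af"] = fp[P:].copy()
            out = _stack_csd(S)
            if pair:
                out = np.concatenate([out[:P], out[P:]], axis=1)
            if not np.all(stable):
                bad = ~stable
                if pair:
                    bad = bad[:P] | bad[P:]
                out = out.copy()
                out[bad] = np.nan
            return out * scale
        # FD batch: refine around the row-0 reference per condition.
        x0_bl = None if fp_cache["bl"] is None else fp_cache["bl"][0]
        S_bl, _ = predict_csd_linearised(th_bl[0], th_bl, variant, grid, cfg,
                                         x0_ref=x0_bl)
        out = _stack_csd(S_bl)
        if pair:
            x0_af = None if fp_cache["af"] is None else fp_cache["af"][0]
            S_af, _ = predict_csd_linearised(th_af[0], th_af, variant, grid,
                                             cfg, x0_ref=x0_af)
            out = np.concatenate([out, _stack_csd(S_af)], axis=1)
        return out * scale

    post = variational_laplace(predictor, (y_s, masks), joint_prior, opts)
    post.diagnostics.update(
        n_theta=n_theta,
        variant=variant.name,
        design=design.label if design is not None else None,
        b_names=design.group_names if design is not None else [],
        data_scale=np.asarray(scale),
        n_conditions=2 if pair else 1,
        grid=grid.frequencies.copy(),
    )
    return post
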