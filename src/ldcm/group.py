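"""Group-level machinery: model reduction, model selection and empirical Bayes.

Bayesian model reduction (BMR) re-scores a fitted model under reduced priors
analytically, exact under the Laplace (Gaussian) assumption.  Fixed-effects
Bayesian model selection pools free energies over subjects and converts them
to posterior model probabilities under uniform model priors.  Parametric
empirical Bayes (PEB) places a linear between-subject model over selected
first-level parameters,

    theta_i = X beta + eps_i,   eps_i ~ N(0, exp(-gamma) V),

estimating the group effects beta per design-matrix regressor and a shared
between-subject log-precision gamma by maximising the (BMR-based) free energy
of the hierarchical model.  Bayesian model averaging combines posteriors over
a model set by mixture moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .exceptions import DesignError, DataError
from .model import PriorDensity
from .inversion import Posterior

_LOG2PI = np.log(2 * np.pi)


# ---------------------------------------------------------------------------
# Designs and evidence tables
# ---------------------------------------------------------------------------

@dataclass
class GroupDesign:
    """Between-subject design matrix; the first column is the constant."""

    matrix: np.ndarray              # (subjects, regressors)
    names: list

    def __post_init__(self):
        X = np.asarray(self.matrix, dtype=float)
        if X.ndim != 2:
            raise DesignError("design matrix must be 2-D (subjects x regressors)")
        if not np.all(np.isfinite(X)):
            raise DesignError("design matrix contains non-finite values")
        if not np.allclose(X[:, 0], 1.0):
            raise DesignError("first design column must be the constant 1")
        if len(self.names) != X.shape[1]:
            raise DesignError("regressor names do not match design columns")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DesignError("design matrix is rank deficient")
        self.matrix = X

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]


@dataclass
class ModelEvidenceTable:
    """Per-subject free energies over a labelled model space."""

    F: np.ndarray                   # (subjects, models)
    labels: list

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float)
        if F.ndim != 2 or F.shape[1] != len(self.labels):
            raise DataError("evidence table must be (subjects x models) with labels")
        if F.size == 0:
            raise DataError("empty evidence table")
        if not np.all(np.isfinite(F)):
            raise DataError("evidence table contains non-finite free energies")
        self.F = F


def zscore_regressor(values) -> np.ndarray:
    """Standardise a covariate column to mean 0, SD 1."""
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.ptp(v) == 0:
        raise DesignError("z-scoring requires at least two distinct values")
    return (v - v.mean()) / v.std()


# ---------------------------------------------------------------------------
# Bayesian model reduction
# ---------------------------------------------------------------------------

def _gaussian_reduction(mu, C, mu0, C0, mur, Cr):
    """Core BMR identities.  Returns (reduced mean, reduced cov, dF)."""
    P = np.linalg.inv(C)
    P0 = np.linalg.inv(C0)
    Pr = np.linalg.inv(Cr)
    Pp = P + Pr - P0
    sign, logdet_Pp = np.linalg.slogdet(Pp)
    if sign <= 0:
        raise DataError("reduced-posterior precision is not positive definite")
    Cp = np.linalg.inv(Pp)
    m = Cp @ (P @ mu + Pr @ mur - P0 @ mu0)
    logdets = (np.linalg.slogdet(P)[1] + np.linalg.slogdet(Pr)[1]
               - np.linalg.slogdet(P0)[1] - logdet_Pp)
    quad = (mu @ P @ mu + mur @ Pr @ mur - mu0 @ P0 @ mu0 - m @ Pp @ m)
    dF = 0.5 * logdets - 0.5 * quad
    return m, 0.5 * (Cp + Cp.T), float(dF)


def bayesian_model_reduction(post: Posterior, prior_full: PriorDensity,
                             prior_reduced: PriorDensity):
    """Analytic posterior and log-evidence change under a reduced prior.

    Parameter removal corresponds to shrinking a prior variance towards zero
    at mean zero; ``prior_reduced == prior_full`` gives dF = 0 and an
    unchanged posterior.
    """
    if prior_full.n != post.n or prior_reduced.n != post.n:
        raise DataError("prior layouts do not match the posterior")
    for C in (post.covariance, prior_full.covariance, prior_reduced.covariance):
        if np.linalg.eigvalsh(0.5 * (C + C.T)).min() <= 0:
            raise DataError("BMR requires positive-definite covariances")
    m, Cp, dF = _gaussian_reduction(
        post.mean, post.covariance, prior_full.mean, prior_full.covariance,
        prior_reduced.mean, prior_reduced.covariance)
    reduced = Posterior(
        mean=m, covariance=Cp, hyper=post.hyper.copy(),
        free_energy=post.free_energy + dF, prior=prior_reduced,
        diagnostics={**post.diagnostics, "bmr_dF": dF},
    )
    return reduced, dF


def reduce_parameters(prior: PriorDensity, indices,
                      variance: float = 1e-8) -> PriorDensity:
    """Reduced prior with selected parameters pinned at mean zero."""
    idx = np.asarray(indices, dtype=int)
    cov = prior.covariance.copy()
    mean = prior.mean.copy()
    cov[idx, :] = 0.0
    cov[:, idx] = 0.0
    cov[idx, idx] = variance
    mean[idx] = 0.0
    return PriorDensity(mean, cov)


def exhaustive_bmr_search(post: Posterior, design, pinned_variance: float = 1e-8,
                          max_groups: int = 16):
    """Score every on/off combination of condition groups by model reduction.

    For each subset of the design's groups, the condition effects of the
    switched-off groups are pinned at zero under a reduced prior and the
    evidence change computed analytically from the full fit.  Returns a list
    of ``(mask, dF)`` sorted by decreasing evidence, where ``mask[k]`` says
    whether group ``k`` is retained.  Exhaustive enumeration is exponential
    in the group count, so it is capped (the shipped clinical design has 12).
    """
    n_groups = design.n_groups
    if n_groups > max_groups:
        raise DesignError(
            f"exhaustive search over {n_groups} groups exceeds the cap "
            f"({max_groups}); score a declared model space instead")
    offset = post.n_theta
    results = []
    for code in range(2 ** n_groups):
        mask = [(code >> k) & 1 == 1 for k in range(n_groups)]
        dropped = [offset + k for k in range(n_groups) if not mask[k]]
        if dropped:
            reduced = reduce_parameters(post.prior, dropped,
                                        variance=pinned_variance)
            _, dF = bayesian_model_reduction(post, post.prior, reduced)
        else:
            dF = 0.0
        results.append((tuple(mask), float(dF)))
    results.sort(key=lambda item: -item[1])
    return results


# ---------------------------------------------------------------------------
# Fixed-effects model selection
# ---------------------------------------------------------------------------

def fixed_effects_bms(table: ModelEvidenceTable):
    """Pooled free energies and posterior model probabilities (uniform priors).

    Fixed-effects pooling sums log-evidence over subjects; probabilities are
    the softmax of pooled F and are invariant to adding any constant.
    """
    pooled = table.F.sum(axis=0)
    z = pooled - pooled.max()
    p = np.exp(z)
    p /= p.sum()
    return {"pooled_F": pooled, "probabilities": p, "labels": list(table.labels)}


# ---------------------------------------------------------------------------
# Parametric empirical Bayes
# ---------------------------------------------------------------------------

@dataclass
class PEBResult:
    """Second-level posterior over group effects plus updated first levels."""

    beta: Posterior                   # mean (regressors x params), vectorised
    gamma: float                      # between-subject log-precision
    between_cov: np.ndarray
    free_energy: float
    design: GroupDesign = None
    parameter_indices: np.ndarray = None
    parameter_names: list = None
    updated_first_level: list = field(default_factory=list)

    def beta_matrix(self) -> np.ndarray:
        k = self.parameter_indices.size
        return self.beta.mean.reshape(self.design.n_regressors, k)

    def beta_sd_matrix(self) -> np.ndarray:
        k = self.parameter_indices.size
        return np.sqrt(np.diag(self.beta.covariance)).reshape(
            self.design.n_regressors, k)

    def posterior_sign_probability(self) -> np.ndarray:
        """P(beta > 0) per regressor and parameter, from the Gaussian marginals."""
        from scipy.stats import norm
        m = self.beta.mean
        s = np.sqrt(np.diag(self.beta.covariance))
        k = self.parameter_indices.size
        return norm.cdf(m / s).reshape(self.design.n_regressors, k)


def _clip_psd(M: np.ndarray, floor: float = 0.0) -> np.ndarray:
    w, V = np.linalg.eigh(0.5 * (M + M.T))
    return (V * np.clip(w, floor, None)) @ V.T


def peb_fit(posteriors, design: GroupDesign, parameter_indices=None,
            gamma_prior_variance: float = 1.0,
            between_scale: float = 1.0 / 16,
            gamma_bounds=(-4.0, 8.0)) -> PEBResult:
    """Hierarchical (random-effects) model over selected first-level parameters.

    Each subject's likelihood over the selected parameters is recovered from
    its Laplace posterior and prior; the second level replaces the first-level
    prior with the empirical prior N(X beta, exp(-gamma) V), where ``V`` is
    ``between_scale`` times the first-level prior covariance of the selected
    block.  ``beta`` is obtained in closed form given gamma, and the scalar
    gamma maximises the hierarchical free energy numerically.

    Defaults select the condition-effect (B) block of each posterior.
    """
    posteriors = list(posteriors)
    n = len(posteriors)
    if design.n_subjects != n:
        raise DesignError("design rows must match the number of subjects")
    p0 = posteriors[0]
    if parameter_indices is None:
        parameter_indices = np.arange(p0.n_theta, p0.n)
    sel = np.asarray(parameter_indices, dtype=int)
    if sel.size == 0:
        raise DesignError("no parameters selected for the second level")
    k = sel.size
    m_reg = design.n_regressors
    X = design.matrix

    mu0 = p0.prior.mean[sel]
    C0 = p0.prior.covariance[np.ix_(sel, sel)]
    P0 = np.linalg.inv(C0)
    V = between_scale * C0

    mus = np.stack([p.mean[sel] for p in posteriors])
    Cs = np.stack([p.covariance[np.ix_(sel, sel)] for p in posteriors])
    Ps = np.stack([np.linalg.inv(C) for C in Cs])
    # Likelihood information of each subject (clipped to PSD).
    Lam = np.stack([_clip_psd(Ps[i] - P0) for i in range(n)])
    h = np.einsum("ijk,ik->ij", Ps, mus) - (P0 @ mu0)[None, :]

    # Second-level prior over beta: first-level prior block per regressor.
    Sb = np.zeros((m_reg * k, m_reg * k))
    b0 = np.zeros(m_reg * k)
    for r in range(m_reg):
        Sb[r * k:(r + 1) * k, r * k:(r + 1) * k] = C0
    b0[:k] = mu0
    Pb_prior = np.linalg.inv(Sb)

    logdet_P0 = np.linalg.slogdet(P0)[1]
    logdet_Ps = np.array([np.linalg.slogdet(P)[1] for P in Ps])
    quad_mu = np.einsum("ij,ijk,ik->i", mus, Ps, mus)
    quad_mu0 = mu0 @ P0 @ mu0

    def score(gamma):
        Sg = np.exp(-gamma) * V
        Pr = np.linalg.inv(Sg)
        logdet_Pr = np.linalg.slogdet(Pr)[1]
        Pp = Lam + Pr[None]
        Cpp = np.linalg.inv(Pp)
        W = Pr - Pr @ Cpp @ Pr            # (n, k, k) via broadcasting
        W = np.einsum("ab,ibc,cd->iad", Pr, Cpp, Pr)
        W = Pr[None] - W
        r_lin = np.einsum("ab,ibc,ic->ia", Pr, Cpp, h)   # Pr Pp^-1 h_i
        # beta posterior
        Pb = Pb_prior.copy()
        rhs = Pb_prior @ b0
        for i in range(n):
            xi = X[i]
            Pb += np.kron(np.outer(xi, xi), W[i])
            rhs += np.kron(xi, r_lin[i])
        Cb = np.linalg.inv(Pb)
        beta = Cb @ rhs
        # free energy at beta
        F = 0.0
        for i in range(n):
            mur = (X[i][:, None] * beta.reshape(m_reg, k)).sum(axis=0)
            m_i = Cpp[i] @ (Ps[i] @ mus[i] + Pr @ mur - P0 @ mu0)
            logdets = logdet_Ps[i] + logdet_Pr - logdet_P0 \
                - np.linalg.slogdet(Pp[i])[1]
            quad = quad_mu[i] + mur @ Pr @ mur - quad_mu0 - m_i @ Pp[i] @ m_i
            F += 0.5 * logdets - 0.5 * quad
        db = beta - b0
        F += -0.5 * db @ Pb_prior @ db + 0.5 * np.linalg.slogdet(Pb_prior)[1] \
            - 0.5 * db.size * _LOG2PI
        F += 0.5 * np.linalg.slogdet(2 * np.pi * Cb)[1]
        F += -0.5 * gamma ** 2 / gamma_prior_variance
        return F, beta, Cb, Sg

    res = optimize.minimize_scalar(lambda g: -score(g)[0], bounds=gamma_bounds,
                                   method="bounded", options={"xatol": 1e-3})
    gamma = float(res.x)
    F, beta, Cb, Sg = score(gamma)

    beta_post = Posterior(
        mean=beta, covariance=0.5 * (Cb + Cb.T),
        hyper=np.array([gamma]), free_energy=float(F),
        prior=PriorDensity(b0, Sb),
        diagnostics={"level": 2, "n_subjects": n, "converged": res.success},
    )

    # Updated first-level posteriors under the empirical prior N(X beta, Sg).
    updated = []
    for i, post in enumerate(posteriors):
        mur = (X[i][:, None] * beta.reshape(m_reg, k)).sum(axis=0)
        full_mean = post.prior.mean.copy()
        full_cov = post.prior.covariance.copy()
        full_mean[sel] = mur
        full_cov[np.ix_(sel, sel)] = Sg
        try:
            red, _ = bayesian_model_reduction(
                post, post.prior, PriorDensity(full_mean, full_cov))
        except DataError:
            red = post
        updated.append(red)

    names = None
    if posteriors and "b_names" in p0.diagnostics:
        names = list(p0.diagnostics["b_names"])
    return PEBResult(beta=beta_post, gamma=gamma, between_cov=Sg,
                     free_energy=float(F), design=design,
                     parameter_indices=sel, parameter_names=names,
                     updated_first_level=updated)


# ---------------------------------------------------------------------------
# Bayesian model averaging
# ---------------------------------------------------------------------------

def bma(posteriors, weights) -> Posterior:
    """Mixture-moment average of Gaussian posteriors.

    Means are weight-averaged; covariances follow the law of total variance,
    so the averaged variance is never smaller than the within-model part.
    """
    posteriors = list(posteriors)
    w = np.asarray(weights, dtype=float)
    if w.size != len(posteriors):
        raise DataError("one weight per posterior required")
    if abs(w.sum() - 1.0) > 1e-8:
        raise DataError("weights must sum to 1")
    means = np.stack([p.mean for p in posteriors])
    mbar = w @ means
    cov = np.zeros((mbar.size, mbar.size))
    for wi, p in zip(w, posteriors):
        d = p.mean - mbar
        cov += wi * (p.covariance + np.outer(d, d))
    F = float(w @ np.array([p.free_energy for p in posteriors]))
    return Posterior(mean=mbar, covariance=cov,
                     hyper=posteriors[0].hyper.copy(), free_energy=F,
                     prior=posteriors[0].prior,
                     diagnostics={"bma_weights": w, "converged": True})
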