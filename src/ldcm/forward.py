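"""Analytic cross-spectral prediction from the linearised microcircuit.

The generative model of the cross-spectral density follows the standard
DCM-for-CSD recipe: linearise the flow about its noise-free fixed point,
correct the Jacobian for intrinsic (within-region) and extrinsic
(between-region) conduction delays, form first-order transfer functions from
the endogenous-input channels to the observed regional signals, and assemble

    S(w) = Gu(w) * T(w) T(w)^H  +  Gb(w) * 11^T  +  Gc(w) * I,

where ``Gu`` is the parameterised power-law (1/f-like) spectrum of the
endogenous neuronal fluctuations, and ``Gb``/``Gc`` are common and
channel-specific sensor-noise spectra.  A smooth multiplicative frequency
profile (the "filtration" scaling ``f``) models residual shaping by the
recording pipeline.  The result is Hermitian by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import CircuitConfig, default_config, SS, SP, DP
from .exceptions import StabilityError, LayoutError
from .model import (
    ModelVariant,
    ScaledParameters,
    scale_parameters,
    fixed_point,
    fixed_point_batch,
    flow_jacobian,
    CH_V,
    CH_AMPA,
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class FrequencyGrid:
    """Strictly increasing positive frequencies in Hz."""

    frequencies: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.frequencies, dtype=float).ravel()
        if f.size == 0 or not np.all(np.isfinite(f)):
            raise ValueError("frequency grid must be finite and non-empty")
        if f[0] <= 0 or (f.size > 1 and np.any(np.diff(f) <= 0)):
            raise ValueError("frequencies must be strictly increasing and > 0")
        self.frequencies = f

    def __len__(self):
        return self.frequencies.size

    @property
    def omega(self) -> np.ndarray:
        """Angular frequencies in rad/s."""
        return 2 * np.pi * self.frequencies

    def log_fraction(self) -> np.ndarray:
        """Normalised log-frequency coordinate in [0, 1] over the grid."""
        f = self.frequencies
        if f.size == 1 or f[-1] == f[0]:
            return np.zeros_like(f)
        lf = np.log(f)
        return (lf - lf[0]) / (lf[-1] - lf[0])


def default_grid(fmin: float = 1.0, fmax: float = 48.0, df: float = 1.0) -> FrequencyGrid:
    """Default analysis band: 1-48 Hz, below the mains-notch region."""
    return FrequencyGrid(np.arange(fmin, fmax + df / 2, df))


@dataclass
class CrossSpectrum:
    """Complex cross-spectral matrices over a frequency grid for R regions."""

    freq: FrequencyGrid
    S: np.ndarray                  # (F, R, R) complex
    region_labels: tuple
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=complex)
        if self.S.ndim != 3 or self.S.shape[0] != len(self.freq) \
                or self.S.shape[1] != self.S.shape[2]:
            raise LayoutError(f"cross-spectrum has shape {self.S.shape}; "
                              f"expected (F, R, R) with F = {len(self.freq)}")
        self.region_labels = tuple(self.region_labels)

    @property
    def n_regions(self) -> int:
        return self.S.shape[-1]

    def hermitian_defect(self) -> float:
        return float(np.abs(self.S - np.conj(np.swapaxes(self.S, -1, -2))).max())

    def diagonal_power(self) -> np.ndarray:
        """(F, R) real auto-spectra."""
        return np.real(np.einsum("frr->fr", self.S))


# ---------------------------------------------------------------------------
# Linearisation and delays
# ---------------------------------------------------------------------------

def _delay_masks(n_regions: int):
    n = 16 * n_regions
    idx = np.arange(n)
    region = idx // 16
    chan = idx % 4
    is_g = np.isin(chan, (CH_AMPA, CH_AMPA + 1, CH_AMPA + 2))
    is_v = chan == CH_V
    syn = is_g[:, None] & is_v[None, :]
    same = region[:, None] == region[None, :]
    return syn & same, syn & ~same


def delay_matrix(scaled: ScaledParameters) -> np.ndarray:
    """Per-entry synaptic delays (seconds): intrinsic within, extrinsic between regions.

    Delays attach to the firing-rate couplings (conductance states driven by
    presynaptic voltages); all other Jacobian entries are undelayed.
    """
    intra, inter = _delay_masks(scaled.n_regions)
    d = scaled.delays * 1e-3  # ms -> s
    return d[..., 0, None, None] * intra + d[..., 1, None, None] * inter


def apply_delay_correction(J: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """First-order delay operator: solve (I + tau o J) Jd = J.

    This is the linearisation of ``dx/dt = J x(t - tau)`` in the delays; zero
    delays return ``J`` unchanged.
    """
    n = J.shape[-1]
    M = np.eye(n) + tau * J
    try:
        return np.linalg.solve(M, J)
    except np.linalg.LinAlgError as exc:
        raise StabilityError(f"singular delay correction: {exc}") from exc


def system_jacobian(scaled: ScaledParameters, fp_state, method: str = "central",
                    apply_delays: bool = True) -> np.ndarray:
    """Delay-corrected Jacobian of the flow at the fixed point."""
    x = fp_state.flat if hasattr(fp_state, "flat") else np.asarray(fp_state)
    J = flow_jacobian(x, scaled, method=method)
    if not apply_delays:
        return J
    return apply_delay_correction(J, delay_matrix(scaled))


# ---------------------------------------------------------------------------
# Observation and input maps
# ---------------------------------------------------------------------------

def observation_map(scaled: ScaledParameters, variant: ModelVariant = None) -> np.ndarray:
    """Per-region observation weights over populations (SS, SP, INH, DP).

    The superficial pyramidal population contributes with fixed weight 1; the
    spiny-stellate and deep-pyramidal contributions are estimated through the
    ``J`` scalings (region-specific under the regional-STL variant), and the
    whole row is multiplied by the regional lead-field gain ``L``.
    """
    variant = variant or scaled.variant
    if variant.n_regions != scaled.n_regions:
        raise LayoutError("variant inconsistent with scaled parameters")
    R = scaled.n_regions
    W = np.zeros(scaled.batch_shape + (R, 4))
    W[..., :, SP] = 1.0
    W[..., :, SS] = scaled.w_ss
    W[..., :, DP] = scaled.w_dp
    return scaled.L[..., :, None] * W


def _observation_matrix(scaled: ScaledParameters) -> np.ndarray:
    """(..., R, n_states) map from flat states to regional signals."""
    R = scaled.n_regions
    W = observation_map(scaled)
    O = np.zeros(scaled.batch_shape + (R, 16 * R))
    for r in range(R):
        for p in range(4):
            O[..., r, 16 * r + 4 * p + CH_V] = W[..., r, p]
    return O


def _input_matrix(scaled: ScaledParameters) -> np.ndarray:
    """(..., n_states, R) injection of endogenous input into each region's
    granular (spiny stellate) AMPA conductance."""
    R = scaled.n_regions
    G = np.zeros(scaled.batch_shape + (16 * R, R))
    rate = 1000.0 / scaled.kappa[..., 0]
    for r in range(R):
        G[..., 16 * r + 4 * SS + CH_AMPA, r] = rate
    return G


# ---------------------------------------------------------------------------
# Parameterised spectra
# ---------------------------------------------------------------------------

def _power_law(log_params, amplitude, exponent, grid: FrequencyGrid):
    f = grid.frequencies
    amp = amplitude * np.exp(log_params[..., 0])
    expo = exponent * np.exp(log_params[..., 1])
    return amp[..., None] * f ** (-expo[..., None])


def input_spectrum(a, d, grid: FrequencyGrid, config: CircuitConfig = None) -> np.ndarray:
    """Endogenous fluctuation spectrum: power law times a cosine-basis shape.

    ``a`` holds log-amplitude and log-exponent scalings of the template power
    law; ``d`` holds four cosine coefficients over the normalised
    log-frequency axis.  Strictly positive by construction.
    """
    cfg = config or default_config()
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    base = _power_law(a, cfg.gu_amplitude, cfg.gu_exponent, grid)
    x = grid.log_fraction()
    k = np.arange(1, d.shape[-1] + 1)
    basis = np.cos(np.pi * k[:, None] * x[None, :])      # (4, F)
    shape = np.exp(np.einsum("...k,kf->...f", d, basis))
    return base * shape


def sensor_noise_spectra(b, c, grid: FrequencyGrid, config: CircuitConfig = None):
    """Common (``b``) and channel-specific (``c``) sensor-noise power laws."""
    cfg = config or default_config()
    gb = _power_law(np.asarray(b, dtype=float), cfg.gb_amplitude, cfg.gb_exponent, grid)
    gc = _power_law(np.asarray(c, dtype=float), cfg.gc_amplitude, cfg.gc_exponent, grid)
    return gb, gc


def filtration_profile(f_params, grid: FrequencyGrid) -> np.ndarray:
    """Smooth multiplicative frequency profile modelling data filtration."""
    f_params = np.asarray(f_params, dtype=float)
    x = grid.log_fraction()
    return np.exp(
        f_params[..., 0:1] * np.cos(np.pi * x) + f_params[..., 1:2] * np.cos(2 * np.pi * x)
    )


# ---------------------------------------------------------------------------
# Transfer functions and CSD prediction
# ---------------------------------------------------------------------------

def _transfer_batch(scaled: ScaledParameters, grid: FrequencyGrid, x0=None,
                    check_stability: bool = True, chunk: int = 64,
                    single_precision: bool = False, return_fp: bool = False):
    """Batched transfer functions with exact per-frequency delay factors.

    The delayed couplings enter as ``J o exp(-i w tau)``; since tau takes only
    two distinct values (intrinsic, extrinsic) the frequency-dependent system
    matrix decomposes into three fixed parts, and

        T(w) = O (i w I - J0 - z1(w) J_intra - z2(w) J_inter)^(-1) G_in

    is evaluated by chunked batched solves.  Returns ``(T, stable)`` with
    ``T`` of shape (..., F, R, R_in) and a boolean stability mask; stability
    is gated on the eigenvalues of the first-order delay-corrected Jacobian
    (and skipped entirely with ``check_stability=False``, e.g. for
    finite-difference parameter perturbations around a vetted point).
    """
    x, ok, _ = fixed_point_batch(scaled, x0=x0)
    J = flow_jacobian(x, scaled)
    intra, inter = _delay_masks(scaled.n_regions)
    J0 = J * ~(intra | inter)
    J1 = J * intra
    J2 = J * inter
    tau = scaled.delays * 1e-3                   # (..., 2) seconds
    if check_stability:
        Jd = apply_delay_correction(J, delay_matrix(scaled))
        w_eig = np.linalg.eigvals(Jd)
        stable = ok & (w_eig.real.max(axis=-1) < 0)
    else:
        stable = ok
    O = _observation_matrix(scaled)
    Gin = _input_matrix(scaled).astype(complex)
    n = J.shape[-1]
    F = len(grid)
    omega = grid.omega
    batch = J.shape[:-2]
    Tout = np.empty(batch + (F, scaled.n_regions, Gin.shape[-1]), dtype=complex)

    cdtype = np.complex64 if single_precision else np.complex128

    def solve_block(Jb0, Jb1, Jb2, taub, Ob, Ginb, out):
        # Jb*: (B, n, n); taub: (B, 2); out: (B, F, R, Rin)
        B = Jb0.shape[0]
        z1 = np.exp(-1j * np.outer(taub[:, 0], omega)).astype(cdtype)  # (B, F)
        z2 = np.exp(-1j * np.outer(taub[:, 1], omega)).astype(cdtype)
        J0c = (-Jb0).astype(cdtype)
        J1c = (-Jb1).astype(cdtype)
        J2c = (-Jb2).astype(cdtype)
        M = np.empty((B, F, n, n), dtype=cdtype)
        M[:] = J0c[:, None]
        M += z1[..., None, None] * J1c[:, None]
        M += z2[..., None, None] * J2c[:, None]
        didx = np.arange(n)
        M[..., didx, didx] += (1j * omega.astype(np.float64))[:, None].astype(cdtype)
        rhs = np.broadcast_to(Ginb[:, None].astype(cdtype),
                              (B, F) + Ginb.shape[1:])
        X = np.linalg.solve(M, np.ascontiguousarray(rhs))
        out[...] = np.einsum("brk,bfks->bfrs", Ob, X.astype(np.complex128))

    if batch:
        B = int(np.prod(batch))
        Jb0 = J0.reshape(B, n, n); Jb1 = J1.reshape(B, n, n); Jb2 = J2.reshape(B, n, n)
        taub = np.broadcast_to(tau, batch + (2,)).reshape(B, 2)
        Ob = np.broadcast_to(O, batch + O.shape[-2:]).reshape(B, *O.shape[-2:])
        Ginb = np.broadcast_to(Gin, batch + Gin.shape[-2:]).reshape(B, *Gin.shape[-2:])
        Tflat = Tout.reshape(B, F, scaled.n_regions, Gin.shape[-1])
        for s in range(0, B, chunk):
            e = min(s + chunk, B)
            solve_block(Jb0[s:e], Jb1[s:e], Jb2[s:e], taub[s:e], Ob[s:e],
                        Ginb[s:e], Tflat[s:e])
    else:
        solve_block(J0[None], J1[None], J2[None], tau[None], O[None], Gin[None],
                    Tout[None])
    if return_fp:
        return Tout, stable, x
    return Tout, stable


def transfer_functions(scaled: ScaledParameters, variant: ModelVariant,
                       grid: FrequencyGrid, x0=None) -> np.ndarray:
    """First-order transfer functions from endogenous inputs to regional signals."""
    T, stable = _transfer_batch(scaled, grid, x0=x0)
    if not np.all(stable):
        raise StabilityError(
            "linearised system is unstable; stationary transfer functions are "
            "undefined for these parameters"
        )
    return T


def predict_csd_batch(theta: np.ndarray, variant: ModelVariant,
                      grid: FrequencyGrid, config: CircuitConfig = None,
                      x0=None, check_stability: bool = True,
                      single_precision: bool = False, return_fp: bool = False):
    """Predict CSDs for a batch of flat parameter vectors.

    Returns ``(S, stable)`` with ``S`` of shape (..., F, R, R).  Unstable
    elements carry NaN so callers can treat them as infinite-error samples.
    ``return_fp`` additionally returns the solved fixed points, which callers
    may pass back as ``x0`` to warm-start subsequent nearby solves.
    """
    cfg = config or default_config()
    scaled = scale_parameters(theta, variant, cfg)
    res = _transfer_batch(scaled, grid, x0=x0, check_stability=check_stability,
                          single_precision=single_precision, return_fp=True)
    T, stable, fp = res
    Gu = input_spectrum(scaled.a, scaled.d, grid, cfg)          # (..., F)
    Gb, Gc = sensor_noise_spectra(scaled.b, scaled.c, grid, cfg)
    R = variant.n_regions
    S = Gu[..., :, None, None] * np.einsum("...frs,...fqs->...frq", T, np.conj(T))
    S = S + Gb[..., :, None, None] * np.ones((R, R)) \
          + Gc[..., :, None, None] * np.eye(R)
    S = S * filtration_profile(scaled.f, grid)[..., :, None, None]
    S = 0.5 * (S + np.conj(np.swapaxes(S, -1, -2)))
    if not np.all(stable):
        bad = ~stable
        S = S.copy()
        S[bad] = np.nan
    if return_fp:
        return S, stable, fp
    return S, stable


def predict_csd_linearised(theta_ref: np.ndarray, thetas: np.ndarray,
                           variant: ModelVariant, grid: FrequencyGrid,
                           config: CircuitConfig = None, x0_ref=None):
    """CSDs for a cloud of parameter vectors near a reference point.

    Used for finite-difference sensitivities during inversion: the resolvent
    is LU-factorised once per frequency at the reference and each nearby
    vector's transfer functions are obtained by a single iterative-refinement
    step,

        X_i = X_0 + M_0^{-1} (Gin_i - M_i X_0),

    which is exact to first order in the parameter perturbation (relative
    error O(||dM||^2 / ||M||^2), negligible at finite-difference step sizes).
    Fixed points are re-solved per vector (warm-started from the reference),
    so only the frequency-domain solves are approximated.  Returns
    ``(S, fp_ref)`` with ``S`` of shape (P, F, R, R).
    """
    from scipy.linalg import lu_factor, lu_solve

    cfg = config or default_config()
    ref = scale_parameters(theta_ref, variant, cfg)
    x_ref, ok_ref, _ = fixed_point_batch(ref, x0=x0_ref)
    if not np.all(ok_ref):
        P = np.asarray(thetas).shape[0]
        R = variant.n_regions
        return np.full((P, len(grid), R, R), np.nan, dtype=complex), x_ref
    J_ref = flow_jacobian(x_ref, ref)
    intra, inter = _delay_masks(ref.n_regions)
    n = J_ref.shape[-1]
    omega = grid.omega
    F = len(grid)
    tau_ref = ref.delays * 1e-3
    Gin_ref = _input_matrix(ref).astype(complex)

    # Reference LU factorisations and solutions per frequency.
    lus, X0 = [], np.empty((F, n, Gin_ref.shape[-1]), dtype=complex)
    J1r = J_ref * intra
    J2r = J_ref * inter
    J0r = J_ref - J1r - J2r
    for f in range(F):
        M0 = 1j * omega[f] * np.eye(n) - J0r \
            - np.exp(-1j * omega[f] * tau_ref[0]) * J1r \
            - np.exp(-1j * omega[f] * tau_ref[1]) * J2r
        lu = lu_factor(M0)
        lus.append(lu)
        X0[f] = lu_solve(lu, Gin_ref)

    # Perturbed systems.
    thetas = np.asarray(thetas, dtype=float)
    P = thetas.shape[0]
    scaled = scale_parameters(thetas, variant, cfg)
    x_all, _, _ = fixed_point_batch(scaled, x0=np.repeat(x_ref[None], P, 0))
    J_all = flow_jacobian(x_all, scaled)
    J1 = J_all * intra
    J2 = J_all * inter
    J0 = J_all - J1 - J2
    tau = scaled.delays * 1e-3                       # (P, 2)
    z1 = np.exp(-1j * np.outer(tau[:, 0], omega))    # (P, F)
    z2 = np.exp(-1j * np.outer(tau[:, 1], omega))
    Gin = _input_matrix(scaled)                      # (P, n, R)

    Rin = X0.shape[-1]
    X0r = X0.real
    X0i = X0.imag
    # products J* X0 for all perturbations: (P, F, n, Rin), complex via parts
    def prod(Jm):
        re = np.einsum("pnm,fmr->pfnr", Jm, X0r, optimize=True)
        im = np.einsum("pnm,fmr->pfnr", Jm, X0i, optimize=True)
        return re + 1j * im

    P0 = prod(J0)
    P1 = prod(J1)
    P2 = prod(J2)
    MX0 = (1j * omega)[None, :, None, None] * X0[None] \
        - P0 - z1[..., None, None] * P1 - z2[..., None, None] * P2
    resid = Gin[:, None] - MX0                       # (P, F, n, Rin)
    X = np.empty_like(resid)
    for f in range(F):
        rhs = resid[:, f].transpose(1, 0, 2).reshape(n, P * Rin)
        dx = lu_solve(lus[f], rhs)
        X[:, f] = X0[f] + dx.reshape(n, P, Rin).transpose(1, 0, 2)

    O = _observation_matrix(scaled)                  # (P, R, n)
    T = np.einsum("prk,pfks->pfrs", O, X)
    Gu = input_spectrum(scaled.a, scaled.d, grid, cfg)
    Gb, Gc = sensor_noise_spectra(scaled.b, scaled.c, grid, cfg)
    Rr = variant.n_regions
    S = Gu[..., :, None, None] * np.einsum("pfrs,pfqs->pfrq", T, np.conj(T))
    S = S + Gb[..., :, None, None] * np.ones((Rr, Rr)) \
          + Gc[..., :, None, None] * np.eye(Rr)
    S = S * filtration_profile(scaled.f, grid)[..., :, None, None]
    S = 0.5 * (S + np.conj(np.swapaxes(S, -1, -2)))
    return S, x_ref


def predict_csd(theta, variant: ModelVariant, grid: FrequencyGrid = None,
                config: CircuitConfig = None) -> CrossSpectrum:
    """Model cross-spectral density at one parameter vector.

    Raises :class:`StabilityError` for parameters whose linearisation is
    unstable — during inversion such proposals are rejected as
    infinite-error samples.
    """
    grid = grid or default_grid()
    vec = theta.values if hasattr(theta, "values") else np.asarray(theta, dtype=float)
    S, stable = predict_csd_batch(vec, variant, grid, config)
    if not np.all(stable):
        raise StabilityError(
            "unstable linearisation at the requested parameters; "
            "reject this parameter sample"
        )
    return CrossSpectrum(grid, S, variant.region_labels,
                         metadata={"source": "predict_csd", "variant": variant.name})
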