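"""Conductance-based cortical microcircuit: parameters, priors and dynamics.

Each modelled region is a microcircuit of four populations — spiny stellate
cells (SS), superficial pyramidal cells (SP), inhibitory interneurons (INH)
and deep pyramidal cells (DP) — with AMPA, GABA-A and NMDA channel
conductances.  The hidden state of a population is its mean depolarisation
``V`` together with the three channel conductances; the flow couples
populations through sigmoid firing rates and couples regions through
AMPA-mediated (forward-like) and NMDA-mediated (backward-like) extrinsic
projections.

All free parameters are log-scalings of fixed templates: a physical quantity
equals ``exp(theta) * template``, so ``theta = 0`` everywhere reproduces the
default model.  The lead-field gains ``L`` are the one exception — they enter
linearly with prior mean 1.

Array conventions: a flat parameter vector has shape ``(..., n_params)`` and a
flat state vector ``(..., n_states)`` with ``n_states = 16 * n_regions``
(region-major, population-minor, channel order V, gAMPA, gGABA, gNMDA).
Leading batch dimensions broadcast through every function in this module.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .config import CircuitConfig, default_config, SS, SP, INH, DP
from .exceptions import LayoutError, FixedPointError

DMN_LABELS = ("LAG", "RAG", "MPFC", "PCC")

# State channel indices within a population.
CH_V, CH_AMPA, CH_GABA, CH_NMDA = 0, 1, 2, 3


# ---------------------------------------------------------------------------
# Model variants and parameter layout
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelVariant:
    """One cell of the 2x2 model grid: glutamate parameterisation x regional STL.

    ``dual_glutamate`` replaces the single intrinsic-gain block by separate
    inhibitory / NMDA / AMPA blocks; ``regional_stl`` lets the state-to-lead
    field contribution weights (J) vary over regions.
    """

    dual_glutamate: bool = False
    regional_stl: bool = False
    n_regions: int = 4
    region_labels: tuple = None

    def __post_init__(self):
        if self.n_regions < 1:
            raise LayoutError("n_regions must be >= 1")
        labels = self.region_labels
        if labels is None:
            labels = DMN_LABELS[: self.n_regions] if self.n_regions <= 4 else tuple(
                f"R{i}" for i in range(self.n_regions)
            )
            object.__setattr__(self, "region_labels", tuple(labels))
        elif len(labels) != self.n_regions:
            raise LayoutError(
                f"{len(labels)} region labels given for {self.n_regions} regions"
            )
        else:
            object.__setattr__(self, "region_labels", tuple(labels))

    @property
    def name(self) -> str:
        glu = "dualglu" if self.dual_glutamate else "monoglu"
        stl = "rstl" if self.regional_stl else "sstl"
        return f"{glu}-{stl}"


def _nonzero_positions(template) -> list:
    t = np.asarray(template)
    return [tuple(ij) for ij in np.argwhere(t != 0)]


class ParameterLayout:
    """Block structure of the flat parameter vector for a given variant."""

    def __init__(self, variant: ModelVariant, config: CircuitConfig = None):
        cfg = config or default_config()
        R = variant.n_regions
        self.variant = variant
        self.config = cfg
        self.gaba_positions = _nonzero_positions(cfg.h_gaba)
        self.exc_positions = _nonzero_positions(cfg.h_exc)
        self.h_positions = _nonzero_positions(cfg.h_default)
        # Directed region pairs (source, target), source-major order.
        self.edges = [(s, t) for s in range(R) for t in range(R) if s != t]
        E = len(self.edges)
        blocks = [("kappa", (3,)), ("C", (4,))]
        if variant.dual_glutamate:
            blocks += [
                ("Hi", (R, len(self.gaba_positions))),
                ("Hnmda", (R, len(self.exc_positions))),
                ("Hampa", (R, len(self.exc_positions))),
            ]
        else:
            blocks += [("H", (R, len(self.h_positions)))]
        blocks += [("A", (E,)), ("AN", (E,)), ("L", (R,))]
        blocks += [("J", (R, 2) if variant.regional_stl else (2,))]
        blocks += [("a", (2,)), ("d", (4,)), ("b", (2,)), ("c", (2,)),
                   ("f", (2,)), ("D", (2,))]
        self.blocks = {}
        start = 0
        for name, shape in blocks:
            size = int(np.prod(shape))
            self.blocks[name] = (slice(start, start + size), shape)
            start += size
        self.n_params = start

    def edge_index(self, src: int, tgt: int) -> int:
        return self.edges.index((src, tgt))

    def block(self, vec: np.ndarray, name: str) -> np.ndarray:
        """View of one named block, reshaped, preserving batch dimensions."""
        sl, shape = self.blocks[name]
        return vec[..., sl].reshape(vec.shape[:-1] + shape)

    def indices(self, name: str) -> np.ndarray:
        sl, _ = self.blocks[name]
        return np.arange(sl.start, sl.stop)

    def pack(self, **named) -> np.ndarray:
        vec = np.zeros(self.n_params)
        for name, arr in named.items():
            sl, shape = self.blocks[name]
            vec[sl] = np.asarray(arr, dtype=float).reshape(-1)
        return vec


def _check_layout(layout_a: ParameterLayout, layout_b: ParameterLayout) -> None:
    for name, (sl, shape) in layout_a.blocks.items():
        other = layout_b.blocks.get(name)
        if other is None or other[1] != shape:
            raise LayoutError(
                f"parameter block {name!r} (shape {shape}) does not match the "
                f"requested model variant"
            )
    if layout_a.n_params != layout_b.n_params:
        raise LayoutError("parameter vector length does not match variant layout")


@dataclass
class ParameterVector:
    """Flat block-structured log-scaling parameters for one model variant.

    ``values`` is the flat vector; named blocks are exposed as reshaped views
    through :meth:`block`.  Condition effects ``B`` (aligned to a
    :class:`~ldcm.longitudinal.ConditionDesign`) are carried separately, since
    their length depends on the design rather than the variant.
    """

    variant: ModelVariant
    values: np.ndarray
    B: np.ndarray = None
    design_label: str = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        layout = self.layout
        if self.values.shape[-1] != layout.n_params:
            raise LayoutError(
                f"expected {layout.n_params} parameters for variant "
                f"{self.variant.name}, got {self.values.shape[-1]}"
            )

    @property
    def layout(self) -> ParameterLayout:
        return get_layout(self.variant)

    @classmethod
    def zeros(cls, variant: ModelVariant) -> "ParameterVector":
        return cls(variant, np.zeros(get_layout(variant).n_params))

    @classmethod
    def default(cls, variant: ModelVariant) -> "ParameterVector":
        """Prior-mean parameters: zero log-scalings, unit lead-field gains."""
        layout = get_layout(variant)
        vec = np.zeros(layout.n_params)
        vec[layout.blocks["L"][0]] = 1.0
        return cls(variant, vec)

    def block(self, name: str) -> np.ndarray:
        return self.layout.block(self.values, name)

    def copy(self) -> "ParameterVector":
        return replace(self, values=self.values.copy(),
                       B=None if self.B is None else np.asarray(self.B).copy())


_LAYOUT_CACHE: dict = {}


def get_layout(variant: ModelVariant, config: CircuitConfig = None) -> ParameterLayout:
    key = (variant, id(config) if config is not None else None)
    if key not in _LAYOUT_CACHE:
        _LAYOUT_CACHE[key] = ParameterLayout(variant, config)
    return _LAYOUT_CACHE[key]


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

# Prior variances per block (log-scaling parameters unless noted).
PRIOR_VARIANCES = {
    "kappa": 1.0 / 16,
    "C": 1.0 / 16,
    "H": 1.0 / 32,
    "Hi": 1.0 / 32,
    "Hnmda": 1.0 / 32,
    "Hampa": 1.0 / 32,
    "A": 1.0 / 8,
    "AN": 1.0 / 8,
    "L": 64.0,       # linear gain, prior mean 1
    "J": 1.0 / 16,
    "a": 1.0 / 128,
    "d": 1.0 / 128,
    "b": 1.0 / 128,
    "c": 1.0 / 128,
    "f": 1.0 / 128,
    "D": 1.0 / 64,
}


@dataclass
class PriorDensity:
    """Gaussian prior over a flat parameter vector (diagonal by default)."""

    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if cov.ndim == 1:
            cov = np.diag(cov)
        if cov.shape != (self.mean.size, self.mean.size):
            raise LayoutError("prior covariance shape does not match mean")
        self.covariance = cov

    @property
    def n(self) -> int:
        return self.mean.size

    @property
    def variances(self) -> np.ndarray:
        return np.diag(self.covariance)

    def sample(self, rng: np.random.Generator, size: int = 1) -> np.ndarray:
        return rng.multivariate_normal(self.mean, self.covariance, size=size,
                                       method="cholesky" if _is_pd(self.covariance) else "svd")

    def with_variances(self, indices, variances) -> "PriorDensity":
        cov = self.covariance.copy()
        idx = np.asarray(indices)
        cov[idx, idx] = variances
        return PriorDensity(self.mean.copy(), cov)

    def to_yaml(self, path) -> None:
        """Key-value serialisation; the covariance is stored row-major (the
        diagonal alone when the prior is diagonal)."""
        import yaml
        diagonal = np.allclose(self.covariance, np.diag(self.variances))
        payload = {"mean": self.mean.tolist()}
        if diagonal:
            payload["variances"] = self.variances.tolist()
        else:
            payload["covariance"] = self.covariance.tolist()
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PriorDensity":
        import yaml
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        cov = payload.get("covariance", payload.get("variances"))
        return cls(np.asarray(payload["mean"]), np.asarray(cov))


def _is_pd(cov: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(cov)
        return True
    except np.linalg.LinAlgError:
        return False


def default_priors(variant: ModelVariant, config: CircuitConfig = None) -> PriorDensity:
    """Zero-mean priors with the template variances (lead field: mean 1)."""
    layout = get_layout(variant, config)
    mean = np.zeros(layout.n_params)
    var = np.empty(layout.n_params)
    for name, (sl, _) in layout.blocks.items():
        var[sl] = PRIOR_VARIANCES[name]
    mean[layout.blocks["L"][0]] = 1.0
    return PriorDensity(mean, np.diag(var))


# ---------------------------------------------------------------------------
# Scaled physical parameters
# ---------------------------------------------------------------------------

@dataclass
class ScaledParameters:
    """Physical parameters after applying ``exp(theta) * template``.

    Arrays may carry leading batch dimensions (``batch_shape``).
    """

    variant: ModelVariant
    config: CircuitConfig
    kappa: np.ndarray        # (..., 3) channel time constants, ms
    C: np.ndarray            # (..., 4) capacitances
    G_gaba: np.ndarray       # (..., R, 4, 4)
    G_ampa: np.ndarray       # (..., R, 4, 4)
    G_nmda: np.ndarray       # (..., R, 4, 4)
    A: np.ndarray            # (..., E, 4, 2) AMPA-mediated extrinsic
    AN: np.ndarray           # (..., E, 4, 2) NMDA-mediated extrinsic
    L: np.ndarray            # (..., R) lead-field gains (linear)
    w_ss: np.ndarray         # (..., R) observation weight of SS voltage
    w_dp: np.ndarray         # (..., R) observation weight of DP voltage
    a: np.ndarray            # (..., 2) endogenous fluctuation log-parameters
    d: np.ndarray            # (..., 4) cosine coefficients
    b: np.ndarray            # (..., 2) common sensor noise log-parameters
    c: np.ndarray            # (..., 2) specific sensor noise log-parameters
    f: np.ndarray            # (..., 2) filtration log-parameters
    delays: np.ndarray       # (..., 2) intrinsic / extrinsic delay, ms
    edges: list = field(default_factory=list)

    _CORE_NDIM = {
        "kappa": 1, "C": 1, "G_gaba": 3, "G_ampa": 3, "G_nmda": 3,
        "A": 3, "AN": 3, "L": 1, "w_ss": 1, "w_dp": 1,
        "a": 1, "d": 1, "b": 1, "c": 1, "f": 1, "delays": 1,
    }

    @property
    def n_regions(self) -> int:
        return self.variant.n_regions

    @property
    def batch_shape(self) -> tuple:
        return self.kappa.shape[:-1]

    def expand(self, n_axes: int = 1) -> "ScaledParameters":
        """Insert singleton batch axes so fields broadcast against perturbed states."""
        kw = {}
        for name, core in self._CORE_NDIM.items():
            arr = getattr(self, name)
            for _ in range(n_axes):
                arr = np.expand_dims(arr, axis=arr.ndim - core)
            kw[name] = arr
        return ScaledParameters(self.variant, self.config, edges=self.edges, **kw)


def _as_theta_array(theta, variant: ModelVariant) -> np.ndarray:
    if isinstance(theta, ParameterVector):
        if theta.variant != variant:
            _check_layout(get_layout(variant), theta.layout)
        return theta.values
    arr = np.asarray(theta, dtype=float)
    layout = get_layout(variant)
    if arr.shape[-1] != layout.n_params:
        raise LayoutError(
            f"parameter vector of length {arr.shape[-1]} does not match the "
            f"{layout.n_params}-parameter layout of variant {variant.name}"
        )
    return arr


def scale_parameters(theta, variant: ModelVariant,
                     config: CircuitConfig = None) -> ScaledParameters:
    """Map log-scaling parameters onto physical model quantities.

    ``theta = 0`` in every block reproduces the configured templates exactly:
    channel time constants (4, 16, 100) ms, capacitances
    (128, 128, 256, 32)/1000, the intrinsic and extrinsic coupling templates,
    and delays (2, 16) ms.
    """
    cfg = config or default_config()
    layout = get_layout(variant, cfg)
    vec = _as_theta_array(theta, variant)
    R = variant.n_regions
    batch = vec.shape[:-1]

    kappa = np.exp(layout.block(vec, "kappa")) * np.asarray(cfg.kappa)
    C = np.exp(layout.block(vec, "C")) * np.asarray(cfg.capacitance)

    h_gaba_t = np.asarray(cfg.h_gaba)
    h_exc_t = np.asarray(cfg.h_exc)
    G_gaba = np.zeros(batch + (R, 4, 4))
    G_ampa = np.zeros(batch + (R, 4, 4))
    G_nmda = np.zeros(batch + (R, 4, 4))
    if variant.dual_glutamate:
        hi = np.exp(layout.block(vec, "Hi"))
        hn = np.exp(layout.block(vec, "Hnmda"))
        ha = np.exp(layout.block(vec, "Hampa"))
        for k, (i, j) in enumerate(layout.gaba_positions):
            G_gaba[..., :, i, j] = hi[..., :, k] * h_gaba_t[i, j]
        for k, (i, j) in enumerate(layout.exc_positions):
            G_nmda[..., :, i, j] = hn[..., :, k] * h_exc_t[i, j]
            G_ampa[..., :, i, j] = ha[..., :, k] * h_exc_t[i, j]
    else:
        h = np.exp(layout.block(vec, "H"))
        for k, (i, j) in enumerate(layout.h_positions):
            if h_gaba_t[i, j] != 0:
                G_gaba[..., :, i, j] = h[..., :, k] * h_gaba_t[i, j]
            else:
                # Excitatory entries drive AMPA and NMDA channels equally.
                G_ampa[..., :, i, j] = h[..., :, k] * h_exc_t[i, j]
                G_nmda[..., :, i, j] = h[..., :, k] * h_exc_t[i, j]

    a_t = np.asarray(cfg.a_template) * cfg.extrinsic_scale
    A = np.exp(layout.block(vec, "A"))[..., :, None, None] * a_t
    AN = np.exp(layout.block(vec, "AN"))[..., :, None, None] * a_t

    L = layout.block(vec, "L")
    J = layout.block(vec, "J")
    if variant.regional_stl:
        w_ss = np.exp(J[..., :, 0]) * cfg.obs_weight_ss
        w_dp = np.exp(J[..., :, 1]) * cfg.obs_weight_dp
    else:
        w_ss = np.broadcast_to(
            (np.exp(J[..., 0]) * cfg.obs_weight_ss)[..., None], batch + (R,)
        ).copy()
        w_dp = np.broadcast_to(
            (np.exp(J[..., 1]) * cfg.obs_weight_dp)[..., None], batch + (R,)
        ).copy()

    delays = np.exp(layout.block(vec, "D")) * np.asarray(cfg.delays)

    return ScaledParameters(
        variant=variant, config=cfg, kappa=kappa, C=C,
        G_gaba=G_gaba, G_ampa=G_ampa, G_nmda=G_nmda, A=A, AN=AN,
        L=L, w_ss=w_ss, w_dp=w_dp,
        a=layout.block(vec, "a"), d=layout.block(vec, "d"),
        b=layout.block(vec, "b"), c=layout.block(vec, "c"),
        f=layout.block(vec, "f"), delays=delays, edges=list(layout.edges),
    )


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def firing_rate(V, slope: float = None, threshold: float = None,
                config: CircuitConfig = None):
    """Expected population firing rate in [0, 1]: logistic in depolarisation."""
    cfg = config or default_config()
    slope = cfg.sigmoid_slope if slope is None else slope
    threshold = cfg.sigmoid_threshold if threshold is None else threshold
    if np.any(np.real(slope) <= 0):
        raise ValueError("sigmoid slope must be positive")
    return _expit(slope * (np.asarray(V) - threshold))


def _expit(x):
    # Complex-safe logistic (scipy.special.expit rejects complex input,
    # which the complex-step Jacobian cross-check requires).  Real inputs are
    # clipped to avoid overflow warnings on diverging states.
    if not np.iscomplexobj(x):
        x = np.clip(x, -500.0, 500.0)
    return 1.0 / (1.0 + np.exp(-x))


def nmda_gate(V, config: CircuitConfig = None):
    """Voltage-dependent magnesium-block multiplier of the NMDA channel, in (0, 1)."""
    cfg = config or default_config()
    V = np.asarray(V)
    if not np.iscomplexobj(V):
        V = np.clip(V, -2000.0, 2000.0)
    return 1.0 / (1.0 + cfg.mg_scale * np.exp(-cfg.mg_slope * V))


@dataclass
class StateVector:
    """Hidden states of all regions: per population V and channel conductances."""

    values: np.ndarray  # (R, 4, 4): region x population x (V, gAMPA, gGABA, gNMDA)
    region_labels: tuple = None

    @property
    def V(self) -> np.ndarray:
        return self.values[..., CH_V]

    @property
    def conductances(self) -> np.ndarray:
        return self.values[..., 1:]

    @property
    def flat(self) -> np.ndarray:
        return self.values.reshape(self.values.shape[:-3] + (-1,))


def n_states(variant: ModelVariant) -> int:
    return 16 * variant.n_regions


def drives_from_rates(s_intra, s_extra, sp: ScaledParameters, u=None):
    """Presynaptic drives onto each channel given population firing rates.

    ``s_intra`` feeds the within-region couplings and ``s_extra`` the
    between-region projections — they differ only when the caller applies
    conduction delays (the stochastic simulator passes rates read from a
    delay buffer; the instantaneous flow passes the same array twice).
    Returns three (..., R, 4) arrays for the AMPA, GABA and NMDA channels.
    """
    cfg = sp.config
    drive_a = np.einsum("...rpq,...rq->...rp", sp.G_ampa, s_intra)
    drive_g = np.einsum("...rpq,...rq->...rp", sp.G_gaba, s_intra)
    drive_n = np.einsum("...rpq,...rq->...rp", sp.G_nmda, s_intra)
    if sp.edges:
        pre = s_extra[..., :, [SP, DP]]                 # (..., R, 2)
        src = np.array([e[0] for e in sp.edges])
        contrib_a = np.einsum("...epc,...ec->...ep", sp.A, pre[..., src, :])
        contrib_n = np.einsum("...epc,...ec->...ep", sp.AN, pre[..., src, :])
        for t in range(sp.n_regions):
            sel = [k for k, e in enumerate(sp.edges) if e[1] == t]
            if sel:
                drive_a[..., t, :] = drive_a[..., t, :] + contrib_a[..., sel, :].sum(axis=-2)
                drive_n[..., t, :] = drive_n[..., t, :] + contrib_n[..., sel, :].sum(axis=-2)
    drive_a = drive_a + cfg.background_drive
    if u is not None:
        drive_a[..., SS] = drive_a[..., SS] + u
    return drive_a, drive_g, drive_n


def _drives(x_grid, sp: ScaledParameters, u):
    s = firing_rate(x_grid[..., CH_V], config=sp.config)
    return drives_from_rates(s, s, sp, u)


def flow(x, scaled: ScaledParameters, u=None, check_finite: bool = True):
    """Time derivative of the flat state vector (units: per second).

    Voltage dynamics are capacitance-weighted sums of channel currents
    (conductance times driving force) plus leak; channel conductances relax at
    rate 1/kappa towards the sigmoid-rate presynaptic drive, with the NMDA
    current gated by the magnesium-block nonlinearity.
    """
    x = np.asarray(x)
    if check_finite and not np.all(np.isfinite(x if not np.iscomplexobj(x) else x.real)):
        raise FloatingPointError("non-finite state passed to flow")
    cfg = scaled.config
    R = scaled.n_regions
    grid = x.reshape(x.shape[:-1] + (R, 4, 4))
    V = grid[..., CH_V]
    gA = grid[..., CH_AMPA]
    gG = grid[..., CH_GABA]
    gN = grid[..., CH_NMDA]

    drive_a, drive_g, drive_n = _drives(grid, scaled, u)

    rates = 1000.0 / scaled.kappa  # per second
    dgA = (drive_a - gA) * rates[..., None, 0:1]
    dgG = (drive_g - gG) * rates[..., None, 1:2]
    dgN = (drive_n - gN) * rates[..., None, 2:3]

    current = (
        cfg.leak_conductance * (cfg.v_leak - V)
        + gA * (cfg.v_exc - V)
        + gG * (cfg.v_inh - V)
        + gN * nmda_gate(V, cfg) * (cfg.v_nmda - V)
    )
    dV = current / scaled.C[..., None, :]

    out = np.stack([dV, dgA, dgG, dgN], axis=-1)
    return out.reshape(x.shape)


def _flow_jacobian_analytic(x, scaled: ScaledParameters):
    """Closed-form Jacobian of the flow (no delays).

    The only nonlinearities are the firing-rate sigmoid and the NMDA
    magnesium gate, both with elementary derivatives, so the Jacobian is
    assembled directly; central-difference and complex-step versions serve as
    independent cross-checks in the test suite.
    """
    cfg = scaled.config
    R = scaled.n_regions
    n = 16 * R
    batch = x.shape[:-1]
    grid = x.reshape(batch + (R, 4, 4))
    V = grid[..., CH_V]
    gA = grid[..., CH_AMPA]
    gG = grid[..., CH_GABA]
    gN = grid[..., CH_NMDA]
    s = firing_rate(V, config=cfg)
    ds = cfg.sigmoid_slope * s * (1.0 - s)              # (..., R, 4)
    m = nmda_gate(V, cfg)
    dm = cfg.mg_slope * m * (1.0 - m)
    C = scaled.C
    rates = 1000.0 / scaled.kappa                       # (..., 3)

    J = np.zeros(batch + (n, n))
    idx = np.arange(R * 4)
    iv = 4 * idx + CH_V                                 # flat V-state indices

    # Voltage row: dependence on own V and own conductances.
    Cb = C[..., None, :]                                # broadcast over regions
    dVdV = (-cfg.leak_conductance - gA - gG
            + gN * (dm * (cfg.v_nmda - V) - m)) / Cb
    J[..., iv, iv] = dVdV.reshape(batch + (-1,))
    J[..., iv, 4 * idx + CH_AMPA] = ((cfg.v_exc - V) / Cb).reshape(batch + (-1,))
    J[..., iv, 4 * idx + CH_GABA] = ((cfg.v_inh - V) / Cb).reshape(batch + (-1,))
    J[..., iv, 4 * idx + CH_NMDA] = (m * (cfg.v_nmda - V) / Cb).reshape(batch + (-1,))

    # Conductance rows: decay plus sigmoid-weighted couplings.
    for ch, rate_i in ((CH_AMPA, 0), (CH_GABA, 1), (CH_NMDA, 2)):
        J[..., 4 * idx + ch, 4 * idx + ch] = -np.broadcast_to(
            rates[..., rate_i:rate_i + 1], batch + (R * 4,))

    def add_coupling(G, ch, rate_i):
        # G: (..., R, 4, 4) intrinsic couplings; target (r, p, ch) <- V(r, q)
        W = G * ds[..., :, None, :] * rates[..., rate_i, None, None, None]
        for r in range(R):
            rows = 16 * r + 4 * np.arange(4) + ch
            cols = 16 * r + 4 * np.arange(4) + CH_V
            J[..., rows[:, None], cols[None, :]] += W[..., r, :, :]

    add_coupling(scaled.G_ampa, CH_AMPA, 0)
    add_coupling(scaled.G_gaba, CH_GABA, 1)
    add_coupling(scaled.G_nmda, CH_NMDA, 2)

    # Extrinsic projections: target conductances <- source SP/DP voltages.
    for k, (src, tgt) in enumerate(scaled.edges):
        for c, pop in enumerate((SP, DP)):
            col = 16 * src + 4 * pop + CH_V
            dpre = ds[..., src, pop]
            rows_a = 16 * tgt + 4 * np.arange(4) + CH_AMPA
            rows_n = 16 * tgt + 4 * np.arange(4) + CH_NMDA
            J[..., rows_a, col] += scaled.A[..., k, :, c] * dpre[..., None] \
                * rates[..., 0, None]
            J[..., rows_n, col] += scaled.AN[..., k, :, c] * dpre[..., None] \
                * rates[..., 2, None]
    return J


def flow_jacobian(x, scaled: ScaledParameters, u=None, method: str = "analytic",
                  step: float = 1e-4):
    """Jacobian of :func:`flow` with respect to the states.

    ``method='analytic'`` (default) assembles the closed form;
    ``method='central'`` uses central differences with step ``step`` on the
    state scale; ``method='complex'`` uses the complex-step derivative (exact
    to machine precision).  The three agree to numerical precision and the
    non-analytic routes serve as independent cross-checks in tests.
    """
    x = np.asarray(x, dtype=float)
    if method == "analytic":
        return _flow_jacobian_analytic(x, scaled)
    n = x.shape[-1]
    sp = scaled.expand() if scaled.batch_shape else scaled
    eye = np.eye(n)
    if method == "central":
        xp = x[..., None, :] + step * eye
        xm = x[..., None, :] - step * eye
        fp = flow(xp, sp, u=None if u is None else np.asarray(u)[..., None, :],
                  check_finite=False)
        fm = flow(xm, sp, u=None if u is None else np.asarray(u)[..., None, :],
                  check_finite=False)
        jac = (fp - fm) / (2 * step)
    elif method == "complex":
        h = 1e-20
        xc = x[..., None, :].astype(complex) + 1j * h * eye
        fc = flow(xc, sp, u=None if u is None else np.asarray(u)[..., None, :],
                  check_finite=False)
        jac = fc.imag / h
    else:
        raise ValueError(f"unknown jacobian method {method!r}")
    # Axis -2 indexes the perturbed state (column), axis -1 the flow component
    # (row): transpose to rows = components.
    return np.swapaxes(jac, -1, -2)


def _default_state(scaled: ScaledParameters) -> np.ndarray:
    cfg = scaled.config
    R = scaled.n_regions
    grid = np.zeros(scaled.batch_shape + (R, 4, 4))
    grid[..., CH_V] = cfg.v_leak + 5.0
    grid[..., CH_AMPA] = cfg.background_drive
    grid[..., CH_GABA] = 0.1
    grid[..., CH_NMDA] = 0.1
    return grid.reshape(scaled.batch_shape + (16 * R,))


def fixed_point_batch(scaled: ScaledParameters, x0: np.ndarray = None,
                      tol: float = 1e-9, max_iter: int = 80):
    """Damped-Newton equilibrium solve, batched over leading dimensions.

    Returns ``(x, converged, residual)`` where ``converged`` is a boolean
    array over the batch and ``residual`` the final max-abs flow.
    """
    x = _default_state(scaled).copy() if x0 is None else np.array(x0, dtype=float)
    batch = x.shape[:-1]
    for _ in range(max_iter):
        r = flow(x, scaled, check_finite=False)
        rn = np.max(np.abs(r), axis=-1)
        if np.all(rn < tol):
            break
        J = flow_jacobian(x, scaled)
        try:
            dx = -np.linalg.solve(J, r[..., :, None])[..., 0]
        except np.linalg.LinAlgError:
            dx = -np.linalg.lstsq(
                J.reshape(-1, J.shape[-2], J.shape[-1])[0], r.reshape(-1)[: J.shape[-1]],
                rcond=None,
            )[0]
            dx = np.broadcast_to(dx, x.shape)
        alpha = np.ones(batch)
        best = x.copy()
        best_rn = rn.copy()
        for _ in range(10):
            cand = x + alpha[..., None] * dx
            rc = np.max(np.abs(flow(cand, scaled, check_finite=False)), axis=-1)
            better = rc < best_rn
            if batch:
                best[better] = cand[better]
                best_rn = np.where(better, rc, best_rn)
            elif better:
                best, best_rn = cand, rc
            if np.all(best_rn < rn):
                break
            alpha = np.where(rc < rn, alpha, alpha / 2) if batch else (
                alpha if rc < rn else alpha / 2
            )
        stalled = ~(best_rn < rn)
        if np.any(stalled):
            # Pseudo-time relaxation rescues elements where Newton stalls.
            relax = x + 2e-4 * r
            if batch:
                best = np.where(stalled[..., None], relax, best)
            else:
                best = relax
        x = best
    r = flow(x, scaled, check_finite=False)
    rn = np.max(np.abs(r), axis=-1)
    return x, rn < tol, rn


def fixed_point(scaled: ScaledParameters, x0: np.ndarray = None,
                tol: float = 1e-9, max_iter: int = 80) -> StateVector:
    """Noise-free equilibrium of the flow (the linearisation point).

    Raises :class:`FixedPointError` carrying the last residual when the damped
    Newton iteration does not reach ``tol``.
    """
    if not np.all(np.isfinite(scaled.kappa)):
        raise FixedPointError("non-finite parameters", residual=np.inf)
    x, ok, rn = fixed_point_batch(scaled, x0=x0, tol=tol, max_iter=max_iter)
    if not np.all(ok):
        raise FixedPointError(
            f"fixed-point iteration did not converge (residual {np.max(rn):.3e})",
            residual=rn,
        )
    R = scaled.n_regions
    return StateVector(x.reshape(scaled.batch_shape + (R, 4, 4)),
                       region_labels=scaled.variant.region_labels)
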