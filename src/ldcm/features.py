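"""CSD data features from epoched source time series.

The data feature fitted by the inversion is a single cross-spectral matrix
per subject and condition, obtained by (i) fitting a multivariate
autoregressive model of order 8 to each 1-s epoch and evaluating its spectral
matrix on the analysis grid, and (ii) reducing the per-epoch spectra to their
first principal component across epochs (computed jointly on the vectorised
complex cross-spectra, preserving coherence structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError
from .forward import CrossSpectrum, FrequencyGrid, default_grid

DEFAULT_AR_ORDER = 8


@dataclass
class EpochSet:
    """Epoched source time series for one subject and condition."""

    data: np.ndarray          # (epochs, samples, regions)
    sampling_rate: float      # Hz
    subject: str = None
    condition: str = None     # "BL" | "AF"
    region_labels: tuple = ()

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise DataError("epoch data must be (epochs, samples, regions)")
        if not np.all(np.isfinite(self.data)):
            raise DataError("epoch data contain non-finite values")
        if self.sampling_rate <= 0:
            raise DataError("sampling rate must be positive")
        if not self.region_labels:
            self.region_labels = tuple(f"R{i}" for i in range(self.data.shape[2]))

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        """Epoch duration in seconds."""
        return self.data.shape[1] / self.sampling_rate


def filter_epochs(epochs: EpochSet, threshold: float = 5.0) -> EpochSet:
    """Drop epochs whose variance exceeds ``threshold`` times the median.

    A minimal artifact screen; disabled by default in the feature pipeline.
    """
    var = epochs.data.var(axis=(1, 2))
    keep = var <= threshold * np.median(var)
    if not np.any(keep):
        raise DataError("variance filter would reject every epoch")
    return EpochSet(epochs.data[keep], epochs.sampling_rate, epochs.subject,
                    epochs.condition, epochs.region_labels)


# ---------------------------------------------------------------------------
# Multivariate autoregressive spectra
# ---------------------------------------------------------------------------

def _fit_mvar(y: np.ndarray, order: int):
    """Least-squares fit of a vector AR(p) model; returns (coeffs, residual cov)."""
    T, R = y.shape
    p = order
    X = np.concatenate([y[p - k - 1: T - k - 1] for k in range(p)], axis=1)
    Y = y[p:]
    coef, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < p * R:
        raise DataError("rank-deficient autoregressive regression")
    resid = Y - X @ coef
    dof = max(T - p - p * R, 1)
    sigma = resid.T @ resid / dof
    A = coef.reshape(p, R, R).transpose(0, 2, 1)  # A[k] maps y[t-k-1] -> y[t]
    return A, sigma


def ar_cross_spectrum(epoch: np.ndarray, order: int = DEFAULT_AR_ORDER,
                      grid: FrequencyGrid = None, sampling_rate: float = 500.0,
                      region_labels: tuple = ()) -> CrossSpectrum:
    """Cross-spectral matrix of one epoch from a vector AR model.

    The spectral matrix is ``S(f) = (2/fs) H(f) Sigma H(f)^H`` with
    ``H(f) = (I - sum_k A_k e^(-2 pi i f k / fs))^(-1)`` — the one-sided
    density convention of :func:`scipy.signal.welch`.
    """
    if order < 1:
        raise DataError("autoregressive order must be >= 1")
    y = np.asarray(epoch, dtype=float)
    if y.ndim != 2:
        raise DataError("epoch must be (samples, regions)")
    T, R = y.shape
    if T <= 10 * order:
        raise DataError(f"epoch of {T} samples too short for AR order {order}")
    grid = grid or default_grid()
    y = y - y.mean(axis=0)
    A, sigma = _fit_mvar(y, order)
    f = grid.frequencies
    z = np.exp(-2j * np.pi * np.outer(f, np.arange(1, order + 1)) / sampling_rate)
    Af = np.einsum("fk,krs->frs", z, A.astype(complex))
    H = np.linalg.inv(np.eye(R) - Af)
    S = 2.0 / sampling_rate * np.einsum("frs,st,fqt->frq", H, sigma.astype(complex),
                                        np.conj(H))
    S = 0.5 * (S + np.conj(np.swapaxes(S, -1, -2)))
    labels = tuple(region_labels) or tuple(f"R{i}" for i in range(R))
    return CrossSpectrum(grid, S, labels, metadata={"estimator": "mvar", "order": order})


# ---------------------------------------------------------------------------
# Across-trial reduction
# ---------------------------------------------------------------------------

@dataclass
class CSDFeature(CrossSpectrum):
    """A reduced cross-spectral feature with subject/condition identity."""

    subject: str = None
    condition: str = None


def _stack(S: np.ndarray) -> np.ndarray:
    """Vectorise (F, R, R) Hermitian matrices: real upper triangle (with
    diagonal) then imaginary strict upper triangle, frequency-major."""
    F, R, _ = S.shape
    iu = np.triu_indices(R)
    ius = np.triu_indices(R, k=1)
    parts = [S[:, iu[0], iu[1]].real]
    if ius[0].size:
        parts.append(S[:, ius[0], ius[1]].imag)
    return np.concatenate(parts, axis=1).reshape(-1)

def _unstack(vec: np.ndarray, F: int, R: int) -> np.ndarray:
    iu = np.triu_indices(R)
    ius = np.triu_indices(R, k=1)
    per_f = vec.reshape(F, -1)
    S = np.zeros((F, R, R), dtype=complex)
    S[:, iu[0], iu[1]] = per_f[:, : iu[0].size]
    if ius[0].size:
        S[:, ius[0], ius[1]] += 1j * per_f[:, iu[0].size:]
    lower = np.conj(np.swapaxes(np.triu(S, k=1), -1, -2))
    return S + lower


def _leading_component(M: np.ndarray, mean_vec: np.ndarray) -> np.ndarray:
    if M.shape[0] == 1:
        return mean_vec
    _, _, Vt = np.linalg.svd(M, full_matrices=False)
    v1 = Vt[0]
    return -v1 if v1 @ mean_vec < 0 else v1


def reduce_trials(trials, subject: str = None, condition: str = None,
                  mode: str = "joint") -> CSDFeature:
    """First principal component of per-trial cross-spectra.

    With ``mode='joint'`` (default), trial spectra are vectorised (real and
    imaginary parts jointly) and the leading right singular vector across
    trials taken as the feature — preserving coherence structure across
    channel pairs.  ``mode='per-pair'`` computes the component separately for
    each channel pair.  The result is sign-aligned to correlate positively
    with the across-trial mean and rescaled so its mean diagonal power
    matches the mean spectrum's.
    """
    trials = list(trials)
    if not trials:
        raise DataError("reduce_trials needs at least one trial")
    g0 = trials[0].freq.frequencies
    labels = trials[0].region_labels
    for t in trials[1:]:
        if t.region_labels != labels or not np.array_equal(t.freq.frequencies, g0):
            raise DataError("trials have inconsistent grids or labels")
    F, R = len(trials[0].freq), trials[0].n_regions
    M = np.stack([_stack(t.S) for t in trials])
    mean_vec = M.mean(axis=0)
    if mode == "joint":
        v1 = _leading_component(M, mean_vec)
    elif mode == "per-pair":
        # reduce each channel pair separately (real and imaginary jointly)
        iu = np.triu_indices(R)
        ius = np.triu_indices(R, k=1)
        strict = {pair: m for m, pair in enumerate(zip(*ius))}
        per_f = M.shape[1] // F
        cols = M.reshape(len(trials), F, per_f)
        v1 = np.empty((F, per_f))
        mv = mean_vec.reshape(F, per_f)
        n_re = iu[0].size
        for k, (i, j) in enumerate(zip(*iu)):
            sel = [k] if i == j else [k, n_re + strict[(i, j)]]
            block = cols[:, :, sel].reshape(len(trials), -1)
            m_sel = mv[:, sel].reshape(-1)
            comp = _leading_component(block, m_sel)
            # restore this pair's scale: least-squares projection of the mean
            comp = comp * (m_sel @ comp) / (comp @ comp)
            v1[:, sel] = comp.reshape(F, len(sel))
        v1 = v1.reshape(-1)
    else:
        raise DataError(f"unknown reduction mode {mode!r}")
    S1 = _unstack(v1, F, R)
    Sm = _unstack(mean_vec, F, R)
    power = np.einsum("frr->", S1).real
    target = np.einsum("frr->", Sm).real
    if power <= 0:
        raise DataError("degenerate principal component (non-positive power)")
    S1 = S1 * (target / power)
    ridx = np.arange(R)
    S1[:, ridx, ridx] = np.maximum(S1[:, ridx, ridx].real, 0.0)
    return CSDFeature(trials[0].freq, S1, labels,
                      metadata={"n_trials": len(trials), "reduction": "pc1"},
                      subject=subject, condition=condition)


def extract_features(epochs: EpochSet, order: int = DEFAULT_AR_ORDER,
                     grid: FrequencyGrid = None,
                     reject_artifacts: bool = False) -> CSDFeature:
    """Per-epoch AR spectra reduced to one CSD feature for inversion."""
    grid = grid or default_grid()
    if reject_artifacts:
        epochs = filter_epochs(epochs)
    trials = [
        ar_cross_spectrum(epochs.data[k], order=order, grid=grid,
                          sampling_rate=epochs.sampling_rate,
                          region_labels=epochs.region_labels)
        for k in range(epochs.n_epochs)
    ]
    feat = reduce_trials(trials, subject=epochs.subject, condition=epochs.condition)
    feat.metadata.update(order=order, n_epochs=epochs.n_epochs,
                         fmin=float(grid.frequencies[0]),
                         fmax=float(grid.frequencies[-1]))
    return feat
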