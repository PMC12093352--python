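"""HDF5-style containers for epochs, spectral features, posteriors and cohorts."""

from __future__ import annotations

import json

import h5py
import numpy as np
import pandas as pd

from .exceptions import DataError
from .features import EpochSet, CSDFeature
from .forward import CrossSpectrum, FrequencyGrid
from .inversion import Posterior
from .model import PriorDensity

SCHEMA_VERSION = "1"


def _write_meta(group, meta: dict):
    safe = {}
    for k, v in (meta or {}).items():
        if isinstance(v, np.ndarray):
            safe[k] = v.tolist()
        elif isinstance(v, (np.integer, np.floating)):
            safe[k] = v.item()
        elif isinstance(v, (str, int, float, bool, list, tuple, type(None))):
            safe[k] = v
    group.attrs["meta"] = json.dumps(safe)
    group.attrs["schema"] = SCHEMA_VERSION


def _read_meta(group) -> dict:
    raw = group.attrs.get("meta", "{}")
    return json.loads(raw)


# ---------------------------------------------------------------------------
# Epochs
# ---------------------------------------------------------------------------

def save_epochs(path, epochs: EpochSet):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=epochs.data)
        fh.create_dataset("fs", data=epochs.sampling_rate)
        fh.create_dataset("labels", data=np.array(epochs.region_labels, dtype="S"))
        fh.attrs["subject"] = epochs.subject or ""
        fh.attrs["condition"] = epochs.condition or ""
        _write_meta(fh, {})


def load_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as fh:
        if "data" not in fh:
            raise DataError(f"{path} is not an epochs container")
        return EpochSet(
            data=fh["data"][()],
            sampling_rate=float(fh["fs"][()]),
            subject=fh.attrs.get("subject") or None,
            condition=fh.attrs.get("condition") or None,
            region_labels=tuple(s.decode() for s in fh["labels"][()]),
        )


# ---------------------------------------------------------------------------
# Cross-spectra
# ---------------------------------------------------------------------------

def _write_csd(group, csd: CrossSpectrum):
    group.create_dataset("freq", data=csd.freq.frequencies)
    group.create_dataset("S_real", data=csd.S.real)
    group.create_dataset("S_imag", data=csd.S.imag)
    group.create_dataset("labels", data=np.array(csd.region_labels, dtype="S"))
    meta = dict(csd.metadata or {})
    meta["subject"] = getattr(csd, "subject", None)
    meta["condition"] = getattr(csd, "condition", None)
    _write_meta(group, meta)


def _read_csd(group) -> CSDFeature:
    meta = _read_meta(group)
    subject = meta.pop("subject", None)
    condition = meta.pop("condition", None)
    return CSDFeature(
        FrequencyGrid(group["freq"][()]),
        group["S_real"][()] + 1j * group["S_imag"][()],
        tuple(s.decode() for s in group["labels"][()]),
        metadata=meta, subject=subject, condition=condition,
    )


def save_csd(path, csd: CrossSpectrum):
    with h5py.File(path, "w") as fh:
        _write_csd(fh, csd)


def load_csd(path) -> CSDFeature:
    with h5py.File(path, "r") as fh:
        if "S_real" not in fh:
            raise DataError(f"{path} is not a cross-spectrum container")
        return _read_csd(fh)


# ---------------------------------------------------------------------------
# Posteriors
# ---------------------------------------------------------------------------

def save_posterior(path, post: Posterior):
    with h5py.File(path, "w") as fh:
        fh.create_dataset("mean", data=post.mean)
        fh.create_dataset("cov", data=post.covariance)
        fh.create_dataset("F", data=post.free_energy)
        fh.create_dataset("hyper", data=post.hyper)
        if post.prior is not None:
            fh.create_dataset("prior_mean", data=post.prior.mean)
            fh.create_dataset("prior_cov", data=post.prior.covariance)
        _write_meta(fh, post.diagnostics)


def load_posterior(path) -> Posterior:
    with h5py.File(path, "r") as fh:
        prior = None
        if "prior_mean" in fh:
            prior = PriorDensity(fh["prior_mean"][()], fh["prior_cov"][()])
        diag = _read_meta(fh)
        for key in ("f_trace", "grid"):
            if key in diag and isinstance(diag[key], list):
                diag[key] = np.asarray(diag[key])
        return Posterior(
            mean=fh["mean"][()], covariance=fh["cov"][()],
            hyper=fh["hyper"][()], free_energy=float(fh["F"][()]),
            prior=prior, diagnostics=diag,
        )


# ---------------------------------------------------------------------------
# Longitudinal datasets
# ---------------------------------------------------------------------------

def save_dataset(path, dataset):
    with h5py.File(path, "w") as fh:
        fh.attrs["n_subjects"] = len(dataset.subjects)
        _write_meta(fh, {})
        for rec in dataset.subjects:
            g = fh.create_group(rec.subject)
            _write_csd(g.create_group("BL"), rec.bl)
            _write_csd(g.create_group("AF"), rec.af)
            g.create_dataset("theta_true", data=rec.theta_true)
            g.create_dataset("B_true", data=rec.B_true)
        cov = dataset.covariates
        tbl = fh.create_group("covariates")
        for col in cov.columns:
            data = cov[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            tbl.create_dataset(col, data=data)
        tbl.attrs["columns"] = json.dumps(list(cov.columns))


def load_dataset(path):
    from .synthetic import LongitudinalDataset, SubjectRecord

    with h5py.File(path, "r") as fh:
        tbl = fh["covariates"]
        cols = json.loads(tbl.attrs["columns"])
        data = {}
        for col in cols:
            arr = tbl[col][()]
            if arr.dtype.kind == "S":
                arr = np.array([s.decode() for s in arr])
            data[col] = arr
        cov = pd.DataFrame(data)
        subjects = []
        for sid in cov["subject_id"]:
            g = fh[sid]
            subjects.append(SubjectRecord(
                subject=sid,
                bl=_read_csd(g["BL"]),
                af=_read_csd(g["AF"]),
                theta_true=g["theta_true"][()],
                B_true=g["B_true"][()],
            ))
        return LongitudinalDataset(subjects, cov, spec=None)


def load_covariates(path) -> pd.DataFrame:
    """Covariate CSV with at least subject_id, acer_bl, acer_af columns."""
    df = pd.read_csv(path)
    required = {"subject_id", "acer_bl", "acer_af"}
    missing = required - set(df.columns)
    if missing:
        raise DataError(f"covariate table lacks columns: {sorted(missing)}")
    if "delta_acer" not in df.columns:
        df["delta_acer"] = df["acer_af"] - df["acer_bl"]
    return df
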