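"""Readers and writers: delimited trial matrices, JSON fits, CSV tables.

The core data contract is a plain header-free delimited text matrix, one
trial per row; sampling rate and epoch start are supplied alongside, never
embedded in the file. Fit results round-trip through a schema-versioned
JSON document.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from swale.basis import make_polynomial_basis
from swale.errors import FormatError
from swale.estimation import FitConfig, SwaleFit
from swale.model import TrialMatrix, TrialParams, Waveform
from swale.peaks import SingleTrialPeaks
from swale.simulator import SimDataset

__all__ = [
    "read_trial_matrix",
    "write_trial_matrix",
    "write_fit",
    "read_fit",
    "write_peaks",
    "write_truth",
]

FIT_SCHEMA_VERSION = 1


def read_trial_matrix(path, sfreq: float, tmin: float = 0.0) -> TrialMatrix:
    """Parse a delimited text matrix (rows = trials) into a TrialMatrix.

    The delimiter (comma, tab, semicolon or whitespace) is auto-detected.
    Ragged rows and non-numeric or non-finite cells raise a FormatError
    naming the offending position.
    """
    path = Path(path)
    first = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line
                break
    delim = next((d for d in ("\t", ",", ";") if d in first), None)
    kw = {"sep": delim} if delim else {"sep": r"\s+"}
    try:
        df = pd.read_csv(
            path,
            header=None,
            skip_blank_lines=True,
            float_precision="round_trip",
            **kw,
        )
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed rows ({exc})") from exc
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file is empty") from exc
    arr = df.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    bad = np.argwhere(~np.isfinite(arr))
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"{path}: non-numeric, missing or non-finite value at row {i}, column {j}"
        )
    return TrialMatrix.from_array(arr, sfreq=sfreq, tmin=tmin)


def write_trial_matrix(path, data: TrialMatrix, delimiter: str = ",") -> None:
    """Write the trial matrix as header-free delimited text (full precision)."""
    np.savetxt(path, data.data, delimiter=delimiter, fmt="%.17g")


def _config_dict(config: FitConfig) -> dict:
    return {
        "n_basis": config.n_basis,
        "max_iter": config.max_iter,
        "rel_tol": config.rel_tol,
        "amp_floor": config.amp_floor,
        "normalize_each_iter": config.normalize_each_iter,
    }


def write_fit(path, fit: SwaleFit, sfreq: float | None = None, extra: dict | None = None) -> None:
    """Serialize a SwaleFit (coefficients, per-trial parameters, diagnostics) to JSON."""
    doc = {
        "schema_version": FIT_SCHEMA_VERSION,
        "sfreq": sfreq,
        "time_axis_ms": fit.basis.time_axis.tolist(),
        "config": _config_dict(fit.config),
        "n_waveforms": fit.n_waveforms,
        "waveforms": [
            {
                "coeffs": w.coeffs.tolist(),
                "support_mask": w.support_mask.astype(int).tolist(),
                "values": w.values(fit.basis).tolist(),
            }
            for w in fit.waveforms
        ],
        "params": [
            {
                "amplitude": p.amplitude.tolist(),
                "rho": p.rho.tolist(),
                "latency_shift_ms": [
                    None if not np.isfinite(v) else v for v in p.latency_shift
                ],
            }
            for p in fit.params
        ],
        "rss_trace": fit.rss_trace.tolist(),
        "n_iter": int(fit.n_iter),
        "converged": bool(fit.converged),
        "aic": float(fit.aic) if np.isfinite(fit.aic) else None,
        "n_params_k": int(fit.n_params_k),
        "n_points_n": int(fit.n_points_n),
        "collinearity_fallback": bool(fit.collinearity_fallback),
    }
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=1))


def read_fit(path) -> SwaleFit:
    """Reconstruct a SwaleFit from its JSON document (basis rebuilt exactly)."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != FIT_SCHEMA_VERSION:
        raise FormatError(f"{path}: unsupported fit schema {doc.get('schema_version')!r}")
    config = FitConfig(**doc["config"])
    t_ax = np.asarray(doc["time_axis_ms"], float)
    basis = make_polynomial_basis(t_ax.size, config.n_basis, t_ax)
    waveforms = [
        Waveform(
            coeffs=np.asarray(w["coeffs"], float),
            support_mask=np.asarray(w["support_mask"], bool),
            basis_id=basis.basis_id,
        )
        for w in doc["waveforms"]
    ]
    params = [
        TrialParams(
            amplitude=np.asarray(p["amplitude"], float),
            rho=np.asarray(p["rho"], float),
            amp_floor=config.amp_floor,
        )
        for p in doc["params"]
    ]
    return SwaleFit(
        waveforms=waveforms,
        params=params,
        rss_trace=np.asarray(doc["rss_trace"], float),
        n_iter=doc["n_iter"],
        converged=doc["converged"],
        aic=doc["aic"] if doc["aic"] is not None else -np.inf,
        n_params_k=doc["n_params_k"],
        n_points_n=doc["n_points_n"],
        config=config,
        basis=basis,
        collinearity_fallback=doc.get("collinearity_fallback", False),
    )


def write_peaks(path, peaks: SingleTrialPeaks) -> None:
    """Per-trial peak table: trial, latency_ms, amplitude, at_boundary."""
    pd.DataFrame(
        {
            "trial": np.arange(peaks.n_trials),
            "latency_ms": peaks.latency,
            "amplitude": peaks.amplitude,
            "at_boundary": peaks.at_boundary.astype(int),
        }
    ).to_csv(path, index=False)


def write_truth(path, sim: SimDataset) -> None:
    """Ground-truth table: trial, peak, amplitude, latency_shift_ms."""
    npk, n = sim.truth_amplitude.shape
    pd.DataFrame(
        {
            "trial": np.tile(np.arange(n), npk),
            "peak": np.repeat(np.arange(npk), n),
            "amplitude": sim.truth_amplitude.ravel(),
            "latency_shift_ms": sim.truth_latency_shift.ravel(),
        }
    ).to_csv(path, index=False)
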