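"""Delimited-text I/O for TRES surfaces, DAS tables and fit reports.

TRES dialect: tab-separated matrix whose first row is the wavelength
grid in nm (first cell a label) and whose first column is time in ns.
Metadata travels in a JSON sidecar next to the matrix.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .globalfit import DASResult
from .kinetics import TimeAxis, TRESDataset

__all__ = [
    "write_tres_tsv",
    "read_tres_tsv",
    "write_das_csv",
    "write_fit_report",
    "read_fit_report",
]


def write_tres_tsv(data: TRESDataset, path: str, sidecar: bool = True) -> None:
    """Write a TRES matrix as TSV (+ JSON metadata sidecar)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time_ns\t" + "\t".join(f"{w:.10g}" for w in data.wavelengths_nm) + "\n")
        times = data.axis.times_ns
        for i in range(data.axis.n_channels):
            row = "\t".join(f"{v:.10g}" for v in data.counts[i])
            fh.write(f"{times[i]:.10g}\t{row}\n")
    if sidecar:
        with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
            json.dump(data.metadata, fh, indent=1, default=str)


def read_tres_tsv(path: str) -> TRESDataset:
    """Read a TRES matrix written by :func:`write_tres_tsv` (or any
    delimited matrix with the same axis headers)."""
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+|\t|,", engine="python", index_col=0)
    wavelengths = df.columns.to_numpy(dtype=float)
    times = df.index.to_numpy(dtype=float)
    counts = df.to_numpy(dtype=float)
    n = times.size
    if n > 1:
        dt = times[1] - times[0]
        window = dt * n
    else:
        window = max(times[0], 1.0)
    axis = TimeAxis(n_channels=n, window_ns=float(window))
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return TRESDataset(counts=counts, axis=axis, wavelengths_nm=wavelengths, metadata=meta)


def write_das_csv(result: DASResult, path: str) -> None:
    """DAS table: wavelength plus one amplitude column per component,
    headers carrying the lifetime in ns."""
    cols = {"wavelength_nm": result.wavelengths_nm}
    for i, tau in enumerate(result.lifetimes_ns):
        cols[f"das_tau_{tau:.6g}ns"] = result.das[i]
    pd.DataFrame(cols).to_csv(path, index=False)


def write_fit_report(result: DASResult, path: str) -> None:
    """JSON fit report: lifetimes, DAS, χ², convergence metadata."""
    report = {
        "lifetimes_ns": [float(t) for t in result.lifetimes_ns],
        "t0_ns": result.t0_ns,
        "chi2_reduced": result.chi2_reduced,
        "n_components": result.n_components,
        "converged": result.success,
        "n_function_evals": result.n_iterations,
        "irf_fwhm_ps": result.spec.irf.fwhm_ps,
        "wavelengths_nm": [float(w) for w in result.wavelengths_nm],
        "das": [[float(v) for v in row] for row in result.das],
    }
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)


def read_fit_report(path: str) -> DASResult:
    """Rehydrate a fit report into a DASResult carrying lifetimes + DAS.

    Residual/fitted surfaces are not stored in reports; the returned
    object supports yield and efficiency computations.
    """
    from .globalfit import FitSpec
    from .kinetics import IRFModel

    with open(path) as fh:
        rep = json.load(fh)
    lam = np.asarray(rep["wavelengths_nm"], dtype=float)
    das = np.asarray(rep["das"], dtype=float)
    spec = FitSpec(
        n_components=int(rep["n_components"]),
        irf=IRFModel(fwhm_ps=float(rep.get("irf_fwhm_ps", 100.0))),
    )
    return DASResult(
        lifetimes_ns=np.asarray(rep["lifetimes_ns"], dtype=float),
        das=das,
        chi2_reduced=float(rep["chi2_reduced"]),
        residuals=np.zeros((0,)),
        fitted=np.zeros((0, lam.size)),
        wavelengths_nm=lam,
        axis=TimeAxis(),
        t0_ns=float(rep.get("t0_ns", 0.0)),
        spec=spec,
        success=bool(rep.get("converged", True)),
        n_iterations=int(rep.get("n_function_evals", 0)),
        cost=float("nan"),
    )
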