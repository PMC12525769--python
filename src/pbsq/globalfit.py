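"""Global reconvolution analysis of time-resolved emission surfaces.

All wavelengths share a common set of exponential lifetimes; each
wavelength gets its own (sign-unconstrained) amplitudes.  Fitting uses
variable projection: the outer nonlinear problem over {τ_i, t0} is
solved with ``scipy.optimize.least_squares``, while the per-wavelength
amplitudes — the decay-associated spectra (DAS) — are eliminated
analytically by weighted linear least squares at every outer step.
Weights are Poisson-consistent, 1/max(counts, 1).  Negative DAS lobes
encode energy-transfer rise terms and are deliberately allowed.

The public surface is statsmodels-shaped: build a
:class:`GlobalDecayModel` from a :class:`~pbsq.kinetics.TRESDataset`
and a :class:`FitSpec`, call :meth:`~GlobalDecayModel.fit`, and work
with the returned :class:`DASResult` (``summary()``, ``plot_das()``).
The :func:`global_fit` function is a thin convenience wrapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as _signal
from scipy.optimize import least_squares

from .kinetics import IRFModel, TimeAxis, TRESDataset

__all__ = [
    "FitSpec",
    "DASResult",
    "GlobalDecayModel",
    "reconvolution_basis",
    "solve_amplitudes",
    "global_fit",
    "model_select",
]


@dataclass
class FitSpec:
    """Configuration of a global reconvolution fit."""

    n_components: int = 4
    initial_lifetimes_ns: tuple[float, ...] | None = None
    irf: IRFModel = field(default_factory=IRFModel)
    refine_t0: bool = True
    wavelength_window_nm: tuple[float, float] = (500.0, 750.0)
    time_window_ns: tuple[float, float] = (0.010, 12.5)
    weighting: str = "poisson"
    n_starts: int = 3
    seed: int = 0
    max_nfev: int = 400

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if self.initial_lifetimes_ns is not None:
            taus = np.asarray(self.initial_lifetimes_ns, dtype=float)
            if len(taus) != self.n_components:
                raise ValueError("initial lifetimes must match n_components")
            if np.any(taus <= 0):
                raise ValueError("initial lifetimes must be positive")
            if len(np.unique(taus)) != len(taus):
                raise ValueError("initial lifetimes must be distinct")

    def default_initials(self, window_ns: float) -> np.ndarray:
        """Log-spaced starting lifetimes spanning the decade range of the window."""
        if self.initial_lifetimes_ns is not None:
            return np.asarray(self.initial_lifetimes_ns, dtype=float)
        return np.geomspace(0.02 * window_ns, 0.4 * window_ns, self.n_components)


def reconvolution_basis(
    lifetimes_ns: Sequence[float], irf: IRFModel, axis: TimeAxis
) -> np.ndarray:
    """Basis matrix [time × component]: e^{−t/τ_i} ⊗ unit-sum IRF kernel."""
    taus = np.asarray(lifetimes_ns, dtype=float)
    if np.any(taus <= 0):
        raise ValueError("lifetimes must be positive")
    kernel = irf.kernel(axis)
    t = axis.times_ns
    decays = np.exp(-t[:, None] / taus[None, :])
    basis = _signal.fftconvolve(decays, kernel[:, None], mode="full", axes=0)[: axis.n_channels]
    return np.clip(basis, 0.0, None)


def solve_amplitudes(data: TRESDataset, basis: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
    """Per-wavelength weighted linear LS amplitudes, [component × wavelength].

    Weights default to the Poisson choice 1/max(counts, 1).  A
    rank-deficient basis (e.g. duplicated lifetimes) is an error that
    names the colliding columns.
    """
    counts = data.counts
    if basis.shape[0] != counts.shape[0]:
        raise ValueError("basis and data time axes differ")
    # detect collapsed columns up front for a helpful error
    norms = np.linalg.norm(basis, axis=0)
    unit = basis / np.where(norms > 0, norms, 1.0)
    gram = unit.T @ unit
    n = basis.shape[1]
    for i in range(n):
        for j in range(i + 1, n):
            if gram[i, j] > 1.0 - 1e-12:
                raise ValueError(f"basis columns {i} and {j} are (nearly) identical: duplicated lifetimes")
    if weights is None:
        weights = 1.0 / np.maximum(counts, 1.0)
    return _solve_amplitudes_fast(counts, basis, weights)


def _solve_amplitudes_fast(counts: np.ndarray, basis: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Batched weighted normal equations; SVD fallback when near-singular."""
    G = np.einsum("tc,tl,td->lcd", basis, weights, basis, optimize=True)
    rhs = np.einsum("tc,tl,tl->lc", basis, weights, counts, optimize=True)
    try:
        amps = np.linalg.solve(G, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError:
        n_lam = counts.shape[1]
        amps = np.empty((n_lam, basis.shape[1]))
        for l in range(n_lam):
            w = np.sqrt(weights[:, l])
            amps[l] = np.linalg.lstsq(basis * w[:, None], counts[:, l] * w, rcond=None)[0]
    return amps.T


@dataclass
class DASResult:
    """Results of a global reconvolution fit.

    Lifetimes are sorted ascending and the DAS rows follow that order.
    The fitted surface is ``Σ_i das_i(λ) · (e^{−t/τ_i} ⊗ IRF)`` on the
    fit windows.
    """

    lifetimes_ns: np.ndarray
    das: np.ndarray
    chi2_reduced: float
    residuals: np.ndarray
    fitted: np.ndarray
    wavelengths_nm: np.ndarray
    axis: TimeAxis
    t0_ns: float
    spec: FitSpec
    success: bool
    n_iterations: int
    cost: float

    @property
    def n_components(self) -> int:
        return len(self.lifetimes_ns)

    def summary(self) -> str:
        lines = [
            "Global reconvolution fit",
            "========================",
            f"components      : {self.n_components}",
            f"wavelengths     : {self.wavelengths_nm.size} "
            f"({self.wavelengths_nm.min():g}-{self.wavelengths_nm.max():g} nm)",
            f"time channels   : {self.fitted.shape[0]} (dt = {self.axis.dt_ns * 1e3:.3f} ps)",
            f"IRF fwhm        : {self.spec.irf.fwhm_ps:g} ps, t0 = {self.t0_ns * 1e3:.1f} ps",
            f"reduced chi^2   : {self.chi2_reduced:.4f}",
            f"converged       : {self.success} ({self.n_iterations} function evals)",
            "",
            "  #    tau (ns)    peak-|DAS| wavelength (nm)",
        ]
        for i, tau in enumerate(self.lifetimes_ns):
            lam = self.wavelengths_nm[int(np.argmax(np.abs(self.das[i])))]
            lines.append(f"  {i + 1}    {tau:8.4f}    {lam:g}")
        return "\n".join(lines)

    def plot_das(self, ax=None):
        """Plot the decay-associated spectra (one curve per lifetime)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for i, tau in enumerate(self.lifetimes_ns):
            label = f"{tau * 1e3:.0f} ps" if tau < 1 else f"{tau:.2f} ns"
            ax.plot(self.wavelengths_nm, self.das[i], label=label)
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_xlabel("wavelength (nm)")
        ax.set_ylabel("DAS amplitude (a.u.)")
        ax.legend(title="lifetime")
        return ax


class GlobalDecayModel:
    """Global multiexponential reconvolution model for a TRES dataset.

    Parameters
    ----------
    data
        The measured (or simulated) photon-count surface.
    spec
        Fit configuration; windows in ``spec`` crop the data before
        fitting.
    """

    def __init__(self, data: TRESDataset, spec: FitSpec | None = None):
        self.spec = spec or FitSpec()
        lam = data.wavelengths_nm
        lo, hi = self.spec.wavelength_window_nm
        lam_mask = (lam >= lo) & (lam <= hi)
        t = data.axis.times_ns
        tlo, thi = self.spec.time_window_ns
        t_mask = (t >= tlo) & (t <= thi)
        if lam_mask.sum() < self.spec.n_components:
            raise ValueError("need at least n_components usable wavelengths in the window")
        self.wavelengths_nm = lam[lam_mask]
        self.counts = data.counts[:, lam_mask]
        self.axis = data.axis
        self._t_mask = t_mask
        self.data = data
        self.weights = 1.0 / np.maximum(self.counts, 1.0)

    # -- residual machinery --------------------------------------------

    def _basis(self, taus: np.ndarray, t0: float) -> np.ndarray:
        irf = replace(self.spec.irf, t0_ns=t0)
        return reconvolution_basis(taus, irf, self.axis)

    def _eval(self, params: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        taus = np.exp(params[: self.spec.n_components])
        t0 = params[-1] if self.spec.refine_t0 else self.spec.irf.t0_ns
        basis = self._basis(taus, t0)[self._t_mask]
        counts = self.counts[self._t_mask]
        weights = self.weights[self._t_mask]
        das = _solve_amplitudes_fast(counts, basis, weights)
        fitted = basis @ das
        resid = np.sqrt(weights) * (counts - fitted)
        return resid, das, fitted

    def _residual_vector(self, params: np.ndarray) -> np.ndarray:
        return self._eval(params)[0].ravel()

    # -- fitting ---------------------------------------------------------

    def fit(self) -> DASResult:
        """Run the multistart variable-projection fit and return results.

        Three starts by default: the supplied/default initial lifetimes
        plus seeded ±30% lognormal perturbations; the lowest-cost
        solution wins, ties broken toward the smallest fast lifetime.
        """
        spec = self.spec
        init = spec.default_initials(self.axis.window_ns)
        rng = np.random.default_rng(spec.seed)
        starts = [init]
        for _ in range(max(spec.n_starts - 1, 0)):
            starts.append(init * rng.lognormal(0.0, 0.3, size=init.shape))

        dt = self.axis.dt_ns
        t0_0 = spec.irf.t0_ns
        nc = spec.n_components
        lo = np.full(nc, np.log(dt / 10.0))
        hi = np.full(nc, np.log(10.0 * self.axis.window_ns))
        if spec.refine_t0:
            lo = np.append(lo, t0_0 - 3.0 * dt)
            hi = np.append(hi, t0_0 + 3.0 * dt)

        best = None
        for start in starts:
            p0 = np.log(np.sort(start))
            if spec.refine_t0:
                p0 = np.append(p0, t0_0)
            p0 = np.clip(p0, lo + 1e-12, hi - 1e-12)
            sol = least_squares(
                self._residual_vector,
                p0,
                bounds=(lo, hi),
                method="trf",
                max_nfev=spec.max_nfev,
                x_scale="jac",
            )
            taus = np.exp(sol.x[:nc])
            key = (sol.cost, float(np.min(taus)))
            if best is None or key < best[0]:
                best = (key, sol)
        assert best is not None
        sol = best[1]

        taus = np.exp(sol.x[:nc])
        t0 = float(sol.x[-1]) if spec.refine_t0 else t0_0
        resid, das, fitted = self._eval(sol.x)
        order = np.argsort(taus)
        taus = taus[order]
        das = das[order]

        n_data = resid.size
        n_params = nc + (1 if spec.refine_t0 else 0) + nc * self.wavelengths_nm.size
        dof = max(n_data - n_params, 1)
        chi2_red = float((resid**2).sum() / dof)
        return DASResult(
            lifetimes_ns=taus,
            das=das,
            chi2_reduced=chi2_red,
            residuals=resid,
            fitted=fitted,
            wavelengths_nm=self.wavelengths_nm,
            axis=self.axis,
            t0_ns=t0,
            spec=spec,
            success=bool(sol.status > 0 and sol.nfev < spec.max_nfev),
            n_iterations=int(sol.nfev),
            cost=float(sol.cost),
        )


def global_fit(data: TRESDataset, spec: FitSpec | None = None) -> DASResult:
    """Fit shared lifetimes + per-wavelength DAS to a TRES dataset."""
    return GlobalDecayModel(data, spec).fit()


def model_select(
    data: TRESDataset,
    candidates: Sequence[int] = (3, 4),
    improvement_threshold: float = 0.05,
    spec: FitSpec | None = None,
) -> tuple[FitSpec, dict[int, DASResult]]:
    """Choose between candidate component counts by reduced-χ² improvement.

    The larger model is preferred only when it improves reduced χ² by
    more than ``improvement_threshold`` relative to the next smaller
    one.  Both (all) fits are returned so the conventional reporting
    choice — presenting the larger model regardless — stays available.
    """
    if not candidates:
        raise ValueError("candidates must be nonempty")
    base = spec or FitSpec()
    results: dict[int, DASResult] = {}
    for n in sorted(set(candidates)):
        s = replace(base, n_components=n, initial_lifetimes_ns=None)
        results[n] = GlobalDecayModel(data, s).fit()
    ns = sorted(results)
    chosen = ns[0]
    for n in ns[1:]:
        prev, cur = results[chosen].chi2_reduced, results[n].chi2_reduced
        if prev > 0 and (prev - cur) / prev > improvement_threshold:
            chosen = n
    return results[chosen].spec, results
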