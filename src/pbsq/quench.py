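"""OCP quenching statistics from fitted fluorescence data.

Turns decay-associated-spectra fits and macroscopic traces into the
quantities used to characterise phycobilisome quenching by orange
carotenoid proteins: per-component steady-state yields, the quenching
efficiency E (relative reduction of the nanosecond-component yield),
Jin's additivity statistic Q = E(α+β)/(Eα+Eβ−Eα·Eβ) with its
antagonism/additive/synergism classification, saturating-exponential
NPQ time-course fits (rate, plateau, time to twofold reduction), and
Arrhenius activation energies from temperature series of photocycle
time constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .globalfit import DASResult
from .kinetics import GAS_CONSTANT

__all__ = [
    "QuenchResult",
    "JinResult",
    "TimecourseFit",
    "ArrheniusResult",
    "component_yield",
    "quench_efficiency",
    "jin_q",
    "fit_npq_timecourse",
    "arrhenius_fit",
]

# Jin classification boundaries, inclusive on the additive side.
JIN_ANTAGONISM_BELOW = 0.85
JIN_SYNERGISM_FROM = 1.15


def component_yield(
    das_result: DASResult,
    component: int,
    wavelength_window_nm: tuple[float, float] | None = None,
    amplitude_only: bool = False,
) -> float:
    """Steady-state photon yield of one fitted component (a.u.).

    Default definition: Y_i = τ_i × Σ_λ max(das_i(λ), 0) Δλ over the
    window — the component's contribution to time-integrated emission.
    Negative DAS lobes are rise terms, not emitted photons, and are
    excluded.  ``amplitude_only=True`` drops the τ factor for the
    amplitude-integral convention instead.
    """
    if not 0 <= component < das_result.n_components:
        raise ValueError(f"component {component} out of range")
    lam = das_result.wavelengths_nm
    if wavelength_window_nm is None:
        mask = np.ones(lam.size, dtype=bool)
    else:
        lo, hi = wavelength_window_nm
        mask = (lam >= lo) & (lam <= hi)
    if mask.sum() == 0:
        raise ValueError("wavelength window selects no data")
    amp = np.clip(das_result.das[component, mask], 0.0, None)
    if mask.sum() > 1:
        integral = float(np.trapezoid(amp, lam[mask]))
    else:
        integral = float(amp[0])
    if amplitude_only:
        return integral
    return float(das_result.lifetimes_ns[component]) * integral


@dataclass
class QuenchResult:
    """Component yields and the slow-component quenching efficiency."""

    yields_unquenched: np.ndarray
    yields_quenched: np.ndarray
    efficiency: float
    slow_component_unquenched: int
    slow_component_quenched: int


def quench_efficiency(
    unquenched: DASResult,
    quenched: DASResult,
    wavelength_window_nm: tuple[float, float] | None = None,
) -> QuenchResult:
    """Quenching efficiency E = 1 − Y_slow(quenched)/Y_slow(unquenched).

    The slow component is selected as the largest fitted lifetime in
    each condition — never by matching a nominal value — and the two
    must agree within a factor of 3 (otherwise the fits are not
    comparable).  E is clipped to [0, 1] with a warning if it falls
    outside (possible under noise).
    """
    i_u = int(np.argmax(unquenched.lifetimes_ns))
    i_q = int(np.argmax(quenched.lifetimes_ns))
    tau_u = unquenched.lifetimes_ns[i_u]
    tau_q = quenched.lifetimes_ns[i_q]
    ratio = max(tau_u, tau_q) / min(tau_u, tau_q)
    if ratio > 3.0:
        raise ValueError(
            f"slow lifetimes differ by x{ratio:.1f} (> 3); conditions are not comparable"
        )
    y_u = np.array(
        [component_yield(unquenched, i, wavelength_window_nm) for i in range(unquenched.n_components)]
    )
    y_q = np.array(
        [component_yield(quenched, i, wavelength_window_nm) for i in range(quenched.n_components)]
    )
    if y_u[i_u] <= 0:
        raise ValueError("unquenched slow-component yield is zero; efficiency undefined")
    e = 1.0 - y_q[i_q] / y_u[i_u]
    if e < 0.0 or e > 1.0:
        warnings.warn(f"efficiency {e:.3f} outside [0, 1]; clipping", UserWarning, stacklevel=2)
        e = float(np.clip(e, 0.0, 1.0))
    return QuenchResult(
        yields_unquenched=y_u,
        yields_quenched=y_q,
        efficiency=float(e),
        slow_component_unquenched=i_u,
        slow_component_quenched=i_q,
    )


@dataclass
class JinResult:
    """Jin's additivity statistic for a two-quencher experiment."""

    e_alpha: float
    e_beta: float
    e_combined: float
    q: float
    classification: str


def jin_q(e_alpha: float, e_beta: float, e_combined: float) -> JinResult:
    """Q = E(α+β) / (Eα + Eβ − Eα·Eβ), with additivity classification.

    Q < 0.85 → antagonism; 0.85 ≤ Q ≤ 1.15 → additive; Q ≥ 1.15 →
    synergism (boundaries inclusive on the additive side, with 1.15
    counted as synergism exactly as printed).  All efficiencies must
    lie strictly inside (0, 1): a zero single-quencher effect makes the
    Bliss reference undefined.
    """
    for name, e in (("e_alpha", e_alpha), ("e_beta", e_beta), ("e_combined", e_combined)):
        if not 0.0 < e < 1.0:
            raise ValueError(f"{name}={e} must lie strictly in (0, 1)")
    denom = e_alpha + e_beta - e_alpha * e_beta
    if denom <= 0:
        raise ValueError("Bliss denominator is nonpositive; Q undefined")
    q = e_combined / denom
    if q < JIN_ANTAGONISM_BELOW:
        cls = "antagonism"
    elif q >= JIN_SYNERGISM_FROM:
        cls = "synergism"
    else:
        cls = "additive"
    return JinResult(e_alpha, e_beta, e_combined, float(q), cls)


@dataclass
class TimecourseFit:
    """Saturating-exponential NPQ time-course parameters."""

    k_act: float
    e_max: float
    t_half_s: float | None

    def predict(self, t: np.ndarray) -> np.ndarray:
        return 1.0 - self.e_max * (1.0 - np.exp(-self.k_act * np.asarray(t)))


def fit_npq_timecourse(time_s: Sequence[float], fluorescence: Sequence[float]) -> TimecourseFit:
    """Fit F(t)/F(0) = 1 − E_max(1 − e^{−k_act t}) to a quench trace.

    ``t_half`` — the time at which fluorescence has dropped twofold
    from its initial value — is computed analytically as
    −ln(1 − 0.5/E_max)/k_act and is defined only when E_max > 0.5.
    """
    t = np.asarray(time_s, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if t.size < 10:
        raise ValueError("need at least 10 points")
    if f[0] <= 0:
        raise ValueError("initial fluorescence must be positive")
    if np.any(f <= 0) and np.all(f <= 0):
        raise ValueError("trace is non-positive")
    fn = f / f[0]

    def model(tt, k, e):
        return 1.0 - e * (1.0 - np.exp(-k * tt))

    drop = float(np.clip(1.0 - fn[-1], 1e-6, 1.0 - 1e-6))
    span = t[-1] - t[0] if t[-1] > t[0] else 1.0
    p0 = (2.0 / span, drop)
    popt, _ = curve_fit(
        model, t, fn, p0=p0, bounds=([0.0, 0.0], [np.inf, 1.0]), maxfev=10000
    )
    k_act, e_max = float(popt[0]), float(popt[1])
    t_half = float(-np.log(1.0 - 0.5 / e_max) / k_act) if e_max > 0.5 and k_act > 0 else None
    return TimecourseFit(k_act=k_act, e_max=e_max, t_half_s=t_half)


@dataclass
class ArrheniusResult:
    """Activation energy from ln(1/t) vs 1000/T regression."""

    ea_kj_mol: float
    ln_a: float
    r_squared: float
    temperatures_c: np.ndarray
    rates_s: np.ndarray


def arrhenius_fit(time_constants: Sequence[tuple[float, float]]) -> ArrheniusResult:
    """Activation energy from (temperature °C, time constant s) pairs.

    Ordinary least squares of ln(1/t) on 1000/T (T in kelvin); the
    slope gives Ea = −slope × R (kJ/mol with R in J mol⁻¹ K⁻¹).  At
    least three distinct temperatures are required; duplicates are
    averaged on the ln(1/t) scale before the regression.
    """
    pairs = [(float(tc), float(tv)) for tc, tv in time_constants]
    if any(tv <= 0 for _, tv in pairs):
        raise ValueError("time constants must be positive")
    by_temp: dict[float, list[float]] = {}
    for tc, tv in pairs:
        by_temp.setdefault(tc, []).append(np.log(1.0 / tv))
    if len(by_temp) < 3:
        raise ValueError(f"need >= 3 distinct temperatures, got {len(by_temp)}")
    temps = np.array(sorted(by_temp))
    ln_k = np.array([np.mean(by_temp[tc]) for tc in temps])
    x = 1000.0 / (temps + 273.15)
    res = linregress(x, ln_k)
    ea = -res.slope * GAS_CONSTANT  # slope in K·ln-units → kJ/mol
    ln_a = float(res.intercept)
    return ArrheniusResult(
        ea_kj_mol=float(ea),
        ln_a=ln_a,
        r_squared=float(res.rvalue**2),
        temperatures_c=temps,
        rates_s=np.exp(ln_k),
    )
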