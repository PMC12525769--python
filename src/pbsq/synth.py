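"""Seeded synthetic fixtures for every pipeline stage.

Reference TRES datasets (unquenched, single-quencher, dual-quencher),
toy coordinate files with pseudo-chromophores at prescribed positions,
and Arrhenius photocycle temperature series.  Every preset embeds its
full generator parameters in the dataset metadata, so downstream
recovery tests are self-verifying, and regeneration with the same
name + seed is byte-identical.

Quenching is modelled as a mixture of particle populations: an OCP
variant binds a fraction of phycobilisomes and multiplies the AP-core
decay rate in the bound particles (shorter lifetime), leaving the EET
components untouched.  The dual-quencher preset composes the two
single-quencher presets under Bliss independence — binding events are
independent, and in doubly bound particles the two extra quenching
rate channels add.  The surviving amplitude of the unquenched 1.9-ns
component is then exactly the product of the single-quencher survival
fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import gemmi
import numpy as np

from .kinetics import (
    CompartmentModel,
    EmissionSpectra,
    IRFModel,
    PhotocycleTrace,
    TimeAxis,
    TRESDataset,
    add_poisson,
    convolve_irf,
    propagate,
    simulate_photocycle_series,
    tres_ideal,
    GAS_CONSTANT,
)

__all__ = [
    "TRES_PRESETS",
    "make_tres_preset",
    "make_toy_structure",
    "make_photocycle_preset",
    "default_toy_layout",
    "toy_group_map",
]

#: Generator lifetimes (ns) of the unquenched cascade: PE→PC (70 ps),
#: PC→AP (165 ps), AP-core emission (1.9 ns).
_BASE_LIFETIMES = (0.070, 0.165, 1.9)

#: Single-quencher parameters: (bound fraction, AP-lifetime scale in
#: bound particles).  The α variant is fast and strong, the β variant
#: slower and weaker; values are fixture choices reproducing that
#: qualitative contrast, not printed efficiencies.
_QUENCHERS = {
    "alpha": {"bound_fraction": 0.9, "ap_lifetime_scale": 0.15},
    "beta": {"bound_fraction": 0.5, "ap_lifetime_scale": 0.35},
}

TRES_PRESETS = (
    "gvipbs_unquenched",
    "gvipbs_alpha_quenched",
    "gvipbs_beta_quenched",
    "gvipbs_dual_quenched",
)


def _pool_list(name: str) -> list[tuple[float, float]]:
    """(weight, AP-lifetime scale) populations for a preset."""
    if name == "gvipbs_unquenched":
        return [(1.0, 1.0)]
    if name in ("gvipbs_alpha_quenched", "gvipbs_beta_quenched"):
        q = _QUENCHERS[name.split("_")[1]]
        f, s = q["bound_fraction"], q["ap_lifetime_scale"]
        return [(1.0 - f, 1.0), (f, s)]
    if name == "gvipbs_dual_quenched":
        qa, qb = _QUENCHERS["alpha"], _QUENCHERS["beta"]
        fa, sa = qa["bound_fraction"], qa["ap_lifetime_scale"]
        fb, sb = qb["bound_fraction"], qb["ap_lifetime_scale"]
        # rate channels add in doubly bound particles
        s_both = 1.0 / (1.0 / sa + 1.0 / sb - 1.0)
        return [
            ((1 - fa) * (1 - fb), 1.0),
            (fa * (1 - fb), sa),
            ((1 - fa) * fb, sb),
            (fa * fb, s_both),
        ]
    raise ValueError(f"unknown preset {name!r}; valid names: {list(TRES_PRESETS)}")


def make_tres_preset(
    name: str,
    seed: int = 1,
    peak_counts: float | None = 10000.0,
    axis: TimeAxis | None = None,
    spectra: EmissionSpectra | None = None,
    irf: IRFModel | None = None,
) -> TRESDataset:
    """Simulate one of the packaged TRES experiments.

    ``peak_counts=None`` returns the noiseless IRF-convolved surface
    (float intensities); otherwise the surface is scaled to the given
    expected peak count and Poisson-sampled with ``seed``.
    """
    pools = _pool_list(name)
    axis = axis or TimeAxis()
    spectra = spectra or EmissionSpectra()
    irf = irf or IRFModel()
    sig = np.zeros((axis.n_channels, spectra.wavelengths_nm.size))
    pool_lifetimes = []
    for weight, ap_scale in pools:
        taus = (_BASE_LIFETIMES[0], _BASE_LIFETIMES[1], _BASE_LIFETIMES[2] * ap_scale)
        pool_lifetimes.append(list(taus))
        model = CompartmentModel.cascade(lifetimes_ns=taus)
        conc = propagate(model, axis)
        sig += weight * tres_ideal(conc, spectra)
    sig = convolve_irf(sig, irf, axis)
    meta = {
        "preset": name,
        "seed": int(seed),
        "pools": [[w, s] for w, s in pools],
        "pool_lifetimes_ns": pool_lifetimes,
        "base_lifetimes_ns": list(_BASE_LIFETIMES),
        "irf_fwhm_ps": irf.fwhm_ps,
        "irf_t0_ns": irf.t0_ns,
        "emission_peaks_nm": list(spectra.peaks_nm),
        "peak_counts": peak_counts,
    }
    data = TRESDataset(counts=sig, axis=axis, wavelengths_nm=spectra.wavelengths_nm, metadata=meta)
    if peak_counts is None:
        return data
    return add_poisson(data, peak_counts, seed)


# ---------------------------------------------------------------------------
# toy coordinate files

# rigid pseudo-chromophore: four planar 5-atom carbon rings in a row
# (a caricature of the A-B-C-D pyrrole arrangement, not real bilin
# atom naming), centered at the origin.
def _ring_template() -> np.ndarray:
    rings = []
    for rc in (-6.0, -2.0, 2.0, 6.0):
        ang = 2.0 * np.pi * np.arange(5) / 5.0
        ring = np.stack([rc + 1.4 * np.cos(ang), 1.4 * np.sin(ang), np.zeros(5)], axis=1)
        rings.append(ring)
    tpl = np.vstack(rings)
    return tpl - tpl.mean(axis=0)


def default_toy_layout() -> list[tuple[str, str, tuple[float, float, float]]]:
    """Twelve pseudo-bilins in three groups with a planted 33.0-Å rod→core
    minimum distance (between rod site 0 and core site 0)."""
    layout: list[tuple[str, str, tuple[float, float, float]]] = []
    for i in range(4):
        layout.append(("core", "PCB", (0.0, 15.0 * i, 0.0)))
    for i in range(4):
        layout.append(("rod", "PCB", (33.0 + 12.0 * i, 0.0, 0.0)))
    for i in range(4):
        layout.append(("rx", "PEB", (0.0, -28.0 - 12.0 * i, 0.0)))
    return layout


def make_toy_structure(
    layout: Sequence[tuple[str, str, tuple[float, float, float]]],
    path: str,
    jitter: float = 0.0,
    seed: int = 0,
) -> str:
    """Write a valid PDB file with one pseudo-chromophore per layout entry.

    Each entry is (group label, bilin type, center in Å); the group
    maps to a chain, and the residue name encodes the bilin type
    (PCB → CYC, PEB/PUB → themselves) so the default ligand map of
    :func:`pbsq.structure.harvest_chromophores` picks the residues up.
    All atoms are carbon, so the mass center equals the requested
    center (plus jitter).  Returns the path and the chain→group map is
    recoverable as {chain: group} in file order (chains A, B, ... per
    distinct group).
    """
    if len(layout) == 0:
        raise ValueError("layout must contain at least one site")
    rng = np.random.default_rng(seed)
    tpl = _ring_template()
    resname_for = {"PCB": "CYC", "PEB": "PEB", "PUB": "PUB"}

    structure = gemmi.Structure()
    structure.name = "toy_pbs"
    model = gemmi.Model("1")
    chain_for_group: dict[str, gemmi.Chain] = {}
    chain_letters = iter("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    counters: dict[str, int] = {}
    for group, bilin, center in layout:
        if group not in chain_for_group:
            chain_for_group[group] = gemmi.Chain(next(chain_letters))
        chain = chain_for_group[group]
        counters[group] = counters.get(group, 0) + 1
        res = gemmi.Residue()
        res.name = resname_for.get(bilin, "UNL")
        res.seqid = gemmi.SeqId(counters[group], " ")
        res.het_flag = "H"
        offset = np.asarray(center, dtype=float)
        if jitter > 0:
            offset = offset + rng.normal(0.0, jitter, size=3)
        for i, xyz in enumerate(tpl + offset):
            atom = gemmi.Atom()
            atom.name = f"C{i + 1}"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            atom.b_iso = 20.0
            res.add_atom(atom)
        chain.add_residue(res)
    for chain in chain_for_group.values():
        model.add_chain(chain)
    structure.add_model(model)
    structure.setup_entities()
    structure.write_pdb(str(path))
    return str(path)


def toy_group_map(layout: Sequence[tuple[str, str, tuple[float, float, float]]]) -> dict[str, str]:
    """Chain-id → group mapping matching :func:`make_toy_structure`."""
    letters = iter("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
    mapping: dict[str, str] = {}
    seen: set[str] = set()
    for group, _, _ in layout:
        if group not in seen:
            seen.add(group)
            mapping[next(letters)] = group
    return mapping


def make_photocycle_preset(
    ea_kj_mol: float = 60.0,
    temps_c: Sequence[float] = (5.0, 10.0, 15.0, 20.0, 25.0),
    noise_sd: float = 0.0,
    seed: int = 1,
    rate_at_25c: float = 0.02,
) -> list[PhotocycleTrace]:
    """Temperature series of photocycle recovery traces.

    Default activation energy 60 kJ/mol with k(25 °C) = 0.02 s⁻¹
    (a ~50-s recovery time constant); both are fixture choices on the
    scale of OCP photocycles, not measured values.
    """
    ln_a = float(np.log(rate_at_25c) + ea_kj_mol * 1000.0 / (GAS_CONSTANT * 298.15))
    return simulate_photocycle_series(
        ea_kj_mol, ln_a, temps_c, noise_sd=noise_sd, seed=seed
    )
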