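# pbsq

Analysis toolkit for phycobilisome (PBS) architecture, excitation-energy-transfer
(EET) geometry, and quenching by orange carotenoid proteins (OCPs), built around
the bundle-shaped PBS of *Gloeobacter violaceus*.

## What it does, and for whom

Photosynthesis researchers working on cyanobacterial antenna complexes deal with
four recurring computations that this package bundles behind one consistent API:

1. **Composition censuses** — a PBS is a hierarchy of phycobiliprotein (PBP)
   (αβ)₃ trimers stacked into core cylinders, rods and auxiliary hexamers.
   Given the per-protomer bilin stoichiometry (AP 1+1, PC 1+2, PE 2+3 per α, β),
   `pbsq.composition` counts trimers and bilin chromophores for arbitrary
   architectures.  The built-in composite model of the bundle-shaped
   *G. violaceus* PBS (pentacylindrical AP core, six rods in two bundles,
   auxiliary Rx phycocyanin hexamers) holds **82 trimers** and **864 bilins**.
2. **EET geometry** — `pbsq.structure` harvests bilin ligands from PDB/mmCIF
   files, computes mass-center distance matrices, builds adjacency graphs at a
   distance cutoff (default 35 Å, the conventional bound for efficient
   interbilin EET), finds minimal rod→core distances, and quantifies bilin
   ring coplanarity (signed A/D-ring displacement from the fitted B–C plane).
3. **Time-resolved fluorescence** — `pbsq.kinetics` simulates the PBS
   photophysics as a compartmental cascade PE → PC → AP → ground,
   dc/dt = K·c, convolves the emission surface with a Gaussian instrument
   response function (IRF) and draws Poisson photon counts as in
   time-correlated single-photon counting (TCSPC).  `pbsq.globalfit` inverts
   such surfaces by **global reconvolution analysis**: all wavelengths share
   lifetimes {τᵢ}, each wavelength gets its own amplitudes — the
   decay-associated spectra (DAS):

   S(t, λ) = Σᵢ DASᵢ(λ) · (e^(−t/τᵢ) ⊗ IRF)

   fitted by variable projection (nonlinear search over {τᵢ, t₀} with the
   linear DAS solved exactly at every step, Poisson weights 1/max(counts, 1)).
4. **Quenching metrics** — `pbsq.quench` reduces fits and traces to the OCP
   quenching observables: component yields Yᵢ = τᵢ·∫max(DASᵢ, 0) dλ, the
   quenching efficiency E = 1 − Y_slow(quenched)/Y_slow(unquenched), Jin's
   additivity statistic for two quenchers

   Q = E(α+β) / (Eα + Eβ − Eα·Eβ),

   classified as antagonism (Q < 0.85), additive (0.85 ≤ Q ≤ 1.15) or
   synergism (Q ≥ 1.15); saturating NPQ time courses
   F(t)/F₀ = 1 − E_max(1 − e^(−k_act·t)) with the twofold-reduction time; and
   Arrhenius activation energies from ln(1/t) vs 1000/T regressions of
   photocycle recovery time constants.

`pbsq.synth` provides seeded synthetic fixtures for all of the above —
TRES presets (unquenched / α-quenched / β-quenched / dual-quenched), toy
coordinate files with pseudo-chromophores at prescribed positions, and
Arrhenius temperature series — so the full pipeline runs without any
downloads or deposited data.

## Worked example

```python
import numpy as np
from pbsq import FitSpec, GlobalDecayModel, IRFModel, make_tres_preset
from pbsq.quench import jin_q, quench_efficiency

# simulate an unquenched TCSPC measurement: 4096 channels / 12.5 ns,
# 100-ps-fwhm IRF, Poisson noise with 10^4 counts at the peak
data = make_tres_preset("gvipbs_unquenched", seed=1, peak_counts=10000)

spec = FitSpec(n_components=3, initial_lifetimes_ns=(0.05, 0.3, 2.5),
               irf=IRFModel(fwhm_ps=100.0, t0_ns=0.5), seed=1)
result = GlobalDecayModel(data, spec).fit()
print(result.summary())
```

prints

```
Global reconvolution fit
========================
components      : 3
wavelengths     : 126 (500-750 nm)
time channels   : 4092 (dt = 3.052 ps)
IRF fwhm        : 100 ps, t0 = 500.1 ps
reduced chi^2   : 0.4045
converged       : True (13 function evals)

  #    tau (ns)    peak-|DAS| wavelength (nm)
  1      0.0700    644
  2      0.1662    640
  3      1.8938    664
```

The three shared lifetimes recover the generator truth (70 ps, 165 ps,
1.9 ns) to better than 1%: the two fast components are the PE→PC and PC→AP
energy-transfer steps (their DAS carry negative lobes at the acceptor
wavelengths — rise terms), and the 1.9-ns component is the emissive AP core,
peaking near 663 nm.  `result.plot_das()` draws the spectra.

Quenching analysis composes the same pieces:

```python
def fit(name):
    ds = make_tres_preset(name, seed=1, peak_counts=None)   # noiseless
    taus = sorted({t for pool in ds.metadata["pool_lifetimes_ns"] for t in pool})
    return GlobalDecayModel(ds, FitSpec(n_components=len(taus),
        initial_lifetimes_ns=tuple(taus), irf=IRFModel(100.0, 0.5),
        n_starts=1, seed=1)).fit()

u, a, b, d = map(fit, ["gvipbs_unquenched", "gvipbs_alpha_quenched",
                       "gvipbs_beta_quenched", "gvipbs_dual_quenched"])
e_a = quench_efficiency(u, a).efficiency   # 0.900
e_b = quench_efficiency(u, b).efficiency   # 0.500
e_d = quench_efficiency(u, d).efficiency   # 0.950
print(jin_q(e_a, e_b, e_d))                # Q = 1.000, additive
```

The dual-quencher preset is built with independent (Bliss) binding of the two
quenchers, so the surviving slow-component yield is exactly the product of the
single-quencher survivals and Q = 1.

A `pbsq` console script wraps the same functionality
(`pbsq census`, `pbsq simulate-tres`, `pbsq fit-tres`, `pbsq quench`,
`pbsq jin`, `pbsq arrhenius`, `pbsq structure-distances`,
`pbsq make-fixtures`); run `pbsq --help` for details.

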