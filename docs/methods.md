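# Methods

This note records the models implemented in `pbsq`, the defaults and why they
were chosen, the numerical conventions, and what the synthetic data do and do
not emulate.

## Composition model

A PBS composition is a list of structural elements (core cylinders, rods,
auxiliary hexamers), each a stack of (PBP class, trimer count) pairs; hexamers
are represented as two trimers.  Bilin stoichiometry per αβ protomer is fixed
per class: AP (1, 1), PC (1, 2), PE (2, 3); AP and PC carry phycocyanobilin
(PCB), PE carries phycoerythrobilin/phycourobilin (PEB/PUB).  Censuses are
plain sums, additive under model concatenation.

The default composite model of the bundle-shaped *G. violaceus* PBS:

| element | kind | stacks |
|---|---|---|
| A, A′ | core cylinder | 3 AP trimers each |
| B | core cylinder | 4 AP trimers |
| C, C′ | core cylinder | 2 AP trimers each |
| R1, R1′, R3, R3′ | rod | 3 PC + 2 PE hexamers each |
| R2, R2′ | rod | 3 PC + 3 PE hexamers each |
| Rx1, Rx1′ | auxiliary | 1 PC hexamer each |

Totals: 82 trimers, 864 bilins (AP 84, PC 360, PE 420).  Choices made where
the architecture leaves room: the unresolved fourth (ApcD-containing) trimer
of the bottom cylinders is excluded (14, not 16, AP trimers, matching the
deposited composite model); tentatively placed Rx2/Rx3 hexamers are excluded
by default and available behind `include_tentative_rx=True`; the PEB/PUB split
within PE is not resolved, so PE bilins are reported as one class; Rx hexamers
are reported under their own `auxiliary_hexamer` kind rather than being folded
into "rods" or "core".

## Chromophore geometry

Bilin ligands are read from PDB/mmCIF with gemmi; the ligand-code → bilin-type
map defaults to {CYC→PCB, PEB→PEB, PUB→PUB} and is user-extensible, since
ligand codes are not standardised across depositions.  Mass centers use all
non-hydrogen atoms with standard atomic masses — robust to depositions without
hydrogens.  EET adjacency uses mass-center distance ≤ cutoff (inclusive),
default 35 Å.  Coordinates are used as-is (no symmetry expansion or assembly
generation).

Coplanarity: the B∪C pyrrole plane is fitted by total least squares (smallest
eigenvector of the centered covariance); out-of-plane values are the signed
perpendicular displacements of the A and D ring centroids.  The normal is
oriented so ring A displaces nonnegatively (ties toward +z), which makes the
sign of the D displacement meaningful (same side vs opposite side of the
plane).  Ring atom subsets are supplied by the caller per ligand code — atom
naming varies too much across depositions for a safe built-in default.
Degenerate (collinear) ring atom sets are an error, detected via the second
eigenvalue of the covariance.

Because the deposited atomic model is not bundled, the printed interbilin
distance ranges (27–31, 33–35, 37–41 Å) are not recomputed here; the distance
machinery is instead validated by brute-force oracle equivalence and by toy
fixtures with planted minima (33.0 Å rod→core in the default toy layout).

## EET cascade and TCSPC simulation

Compartment kinetics: dc/dt = K·c with K holding transfer rates off-diagonal
and −(total decay rate) on the diagonal.  The default is a unidirectional
cascade PE → PC → AP → ground with total-decay lifetimes 70 ps, 165 ps and
1.9 ns — chosen so that the observable eigen-lifetimes equal the three
components of the unquenched PBS decay.  The split of each total rate into
transfer vs loss defaults to 90% / 10% (the observable lifetimes are
insensitive to this split; only DAS amplitude ratios feel it).  Initial
excitation defaults to (1, 0, 0): short-wavelength excitation lands on the
rod PE pool.

`propagate` solves the system by eigendecomposition; when eigenvalues are
nearly degenerate (equal total rates make K defective) it falls back to a
dense DOP853 integration at rtol 1e-10.  The eigen-path is exact for the
default cascade.

Emission: per-compartment unit-peak Gaussians, defaults 578 / 646 / 663 nm
(PC and AP peaks are the measured fluorescence maxima; the PE value is a
stand-in) with 30-nm fwhm and equal brightness, on a 500–750 nm grid at 2-nm
steps.  The steady-state spectrum uses the closed-form time integral
∫c = −K⁻¹c(0), so the unquenched spectrum peaks at 663 nm (AP) and shifts to
646 nm (PC) under strong AP quenching without window-truncation artifacts.

Time axis: 4096 left-aligned, half-open channels across 12.5 ns (≈3 ps per
channel).  IRF: Gaussian, unit-sum discrete kernel, fwhm 100 ps, centered at
t₀ = 0.5 ns (a typical pre-trigger placement).  The underlying detector spec
("half-width at half-maximum … 100 ps") is ambiguous between HWHM and FWHM;
the parameter is explicitly named `fwhm_ps`, and the HWHM reading corresponds
to `fwhm_ps=200`.

Convolution is causal and linear (signal zero before t = 0), truncated to the
acquisition window.  With a unit-sum kernel the time-integrated intensity is
preserved to machine precision for signals that vanish before the window end;
for signals reaching the window edge the loss is the physical tail leakage.
Discretization convention: both simulator and fit basis convolve plainly
sampled signals, which keeps them exactly consistent; relative to the
continuous exponentially-modified-Gaussian the discrete result carries the
standard half-cell boundary term (= kernel/2), which the tests account for
explicitly.

Noise is pure Poisson on the surface scaled to a prescribed expected peak
count (TCSPC counting statistics); no afterpulsing or background by default.
All simulators are bit-reproducible under a fixed `numpy` Generator seed.

## Global reconvolution fit

Model: S(t, λ) = Σᵢ DASᵢ(λ)·(e^(−t/τᵢ) ⊗ IRF), shared τᵢ across wavelengths,
sign-unconstrained DAS (negative lobes are EET rise terms).  Estimation is
variable projection: `scipy.optimize.least_squares` (TRF, numerical Jacobian)
over {ln τᵢ, t₀}, with the DAS solved per wavelength by weighted normal
equations at every step (SVD fallback near singularity).  Weights are
1/max(counts, 1) — Poisson-consistent and finite at empty channels; note this
Neyman-style weighting carries a small O(1)-count bias in amplitudes, far
below the lifetime tolerances used here.  Fit windows default to 500–750 nm
and 10 ps–12.5 ns.  t₀ is refined within ±3 channel widths of the nominal IRF
position.  Lifetimes are bounded in [Δt/10, 10·window] in log space.

Multistart: 3 starts — the supplied initials plus two seeded ±30% lognormal
perturbations; lowest cost wins, ties broken toward the smallest fast
lifetime.  Reduced χ² counts lifetimes, t₀ and all DAS amplitudes as
parameters.  On correctly specified Poisson data over well-populated channels
χ²_red ≈ 1; fitting a full surface with many near-empty pixels pushes it
below 1 (those pixels contribute almost nothing to the weighted sum) — this
is a property of the weighting, not a fit defect.  Non-convergence at the
evaluation cap returns a result flagged unconverged rather than raising.

Model selection (3- vs 4-state) compares reduced χ² and accepts the larger
model only above a 5% relative improvement; both fits are returned because
the common reporting practice is to present the larger model uniformly.

The deconvolution resolution claim is operationalized: a 10-ps component
planted in noiseless data under the 100-ps-fwhm IRF is recovered within 20%.

## Quenching metrics

Component yield: Yᵢ = τᵢ·∫ max(DASᵢ, 0) dλ (steady-state photon
contribution); the amplitude-only convention (no τ factor) is available via
`amplitude_only=True` since the field uses both.  The slow component is
always the largest fitted lifetime, never a value match, and the two
conditions must agree within ×3.  E = 1 − Y_slow(q)/Y_slow(u), clipped to
[0, 1] with a warning when noise pushes it outside.  E is invariant under
global intensity rescaling of both datasets.

Jin's Q = E(α+β)/(Eα+Eβ−Eα·Eβ); thresholds 0.85 / 1.15 with the additive band
inclusive on both ends and 1.15 itself counted as synergism, exactly as the
convention prints them.  Zero single-quencher effects make the Bliss
reference undefined and are rejected.

NPQ time course: nonlinear LS of F(t)/F₀ = 1 − E_max(1 − e^(−k_act t));
t_half = −ln(1 − 0.5/E_max)/k_act, defined only when E_max > 0.5 (twofold
reduction relative to F(0)).

Arrhenius: OLS of ln(1/t) on 1000/T (K); Ea = −slope·R in kJ/mol, with r².
≥3 distinct temperatures are required; duplicate temperatures are averaged on
the ln(1/t) scale (geometric mean of rates), keeping the regression's linear
semantics.

## Synthetic presets — what they emulate, and what not

TRES presets share the unquenched cascade and differ in quenched-population
structure: quenching multiplies the AP total decay rate in a bound fraction
of particles (mixture model of partial quenching).  Fixture parameters:
α-quencher binds 90% of particles and shortens the AP lifetime ×0.15
(→ 285 ps); β binds 50% at ×0.35 (→ 665 ps) — a strong/fast vs weak/slow
contrast; the numbers are fixture choices, as no quenched-state lifetimes are
printed.  The dual preset composes the two with independent binding
(population weights multiply; rate channels add in doubly bound particles),
so the surviving unquenched-AP amplitude is exactly the product of the single
survivals — the Bliss identity holds by construction and Jin's Q = 1 in the
noiseless case.

The photocycle preset uses Ea = 60 kJ/mol and k(25 °C) = 0.02 s⁻¹ over
5–25 °C — realistic scales for OCP red→orange recovery, chosen once as
fixture values.  Toy structures place rigid planar 4-ring pseudo-chromophores
(all carbon, so the mass center equals the requested position) on chains per
group; they exercise harvesting, distances and coplanarity but do not mimic
real bilin atom naming or conformers.

What passing tests show: the estimators invert the simulators they are
specified against (correct likelihood, correct convolution model, exact
Bliss composition).  What they do not show: robustness to instrument effects
absent from the simulators (IRF asymmetry and drift, afterpulsing, scatter
and background, detector nonlinearity), to spectral shapes beyond Gaussians,
or to quenching heterogeneity beyond two-population mixtures.  The fourth
kinetic state sometimes needed for measured surfaces (scatter or a second AP
pool) is not generated by default; `model_select` exists for exactly that
comparison on real data.

## Problem sizes used in checks

The packaged analyses run at the native 4096 × 126 surface for the headline
lifetime-recovery and Jin computations.  Replicated noisy checks (Jin
classification across seeds, Monte-Carlo amplitude bias) run on reduced grids
(1024 channels, 10-nm wavelength steps, 10 replicates) — sizes chosen to keep
the full suite quick while leaving the statistics conclusive at the stated
tolerances.
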