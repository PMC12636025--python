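# Methods

## Scope and model

fepkit post-processes the outputs of a QM/MM mechanistic study of an
enzymatic reaction: it does not run quantum chemistry, molecular dynamics
or constant-pH sampling. Its inputs are (i) an ordered reaction path of
QM-subsystem geometries or a precomputed path coordinate, (ii) per-window
gas-phase QM energies and ensembles of QM/MM interaction energies, (iii)
Hessians at stationary points, (iv) per-step activation/reaction free
energies, (v) rate constants or progress curves, (vi) protonation records
vs pH, and (vii) Cartesian trajectories. Energies are kcal·mol⁻¹
throughout, lengths Å, masses amu, temperatures K; constants are CODATA
2018 (R = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹).

## Path coordinate

The mass-weighted arc length uses per-atom masses inside the displacement
sum. (A per-structure mass subscript sometimes appears in print for this
formula; the mass-weighted metric standard in IRC analysis is per-atom, and
that is what is implemented.) No superposition is applied between
consecutive structures: IRC frames share a common frame by construction,
and removing rigid-body drift would silently change increments. Units are
amu^{1/2}·Å with no conversion to mass-weighted atomic units; only the
relative spacing of windows matters downstream, so the unit choice is a
documented convention rather than a resolved question.

## FEP estimator

The default `zwanzig` convention uses the standard forward identity
g_i = −k_BT·ln⟨exp(−ΔE_i/k_BT)⟩_i, which reproduces the Gaussian closed
form g = μ − σ²/(2k_BT) and is validated against it in the tests. An
`as_printed` convention with the exponent sign flipped (equivalent to
evaluating the reverse perturbation) is selectable for literal
reproduction of formulas typeset that way; the two agree exactly when all
ΔE vanish and are related by g_printed(ΔE) = g_zwanzig(−ΔE).

Perturbation energies come from one of two routes. When a window stores
interaction energies re-evaluated at the neighbouring geometry over the
same MM configurations, ΔE is the per-configuration difference paired by
sample index — the faithful estimator. When only each window's own samples
exist (the common situation outside the original MD engine), a documented
surrogate is used: ΔE_k = (x_k − x̄_i) + (x̄_{i+1} − x̄_i), the window's
fluctuations about the mean shift. The surrogate preserves the window's
fluctuation spectrum and the mean increment; it cannot capture
cross-window correlation of fluctuations.

Errors: first-order propagation through g = −k_BT ln Ȳ with
Y = exp(−ΔE/k_BT) gives SE(g) = k_BT·SE(Ȳ)/Ȳ; SE(Ȳ) comes from the
scatter of block means (default 10 blocks) so that autocorrelated samples
inflate the estimate appropriately. Below 20 samples the naive i.i.d.
estimate is used with a warning. Profile errors assume independent windows
and add in quadrature; inter-window correlation is not modelled. All
exponential averages go through log-sum-exp and are safe for |ΔE| up to
10⁴ kcal·mol⁻¹.

Temperature defaults to 303 K, the bath temperature typical of the window
MD this package post-processes.

## Synthetic FEP generator

The generator emulates per-window sampling with i.i.d. Gaussian
interaction energies (optionally AR(1), default off) around a prescribed
truth profile; a `qm_fraction` knob (default 0.5) splits each truth
increment between the gas-phase term and the interaction term, since real
studies do not report that partition. One design point deserves emphasis:
for a Gaussian ΔE ~ N(δ, σ²) the exact free-energy increment is
δ − σ²/(2k_BT), not δ. The generator therefore offsets consecutive window
means by the truth share *plus* σ²/(2k_BT), so that the population value
of the exponential average equals the stored truth exactly and estimator
recovery tests measure statistical error, not a construction artefact.
At σ = 0 the compensation vanishes and the zero-noise identity is exact.

What the generator does not emulate: real force-field energetics,
anharmonicity, correlated fluctuations between windows, or slowly relaxing
environments. Passing recovery tests therefore demonstrates the estimator
and its error model, not the fidelity of any particular QM/MM protocol.

## Harmonic thermochemistry

Hessians (kcal·mol⁻¹·Å⁻²) are mass-weighted and diagonalised; eigenvalues
map to wavenumbers via sign(λ)√|λ| with explicit SI conversion, negative
wavenumbers encoding imaginary modes (0 imaginary → minimum, 1 →
transition state, ≥2 → higher-order saddle). Translation/rotation
projection is off by default — the toy block Hessians used in tests have
no rigid-body contamination — and available for molecular Hessians, where
it leaves near-zero remnants below a 5 cm⁻¹ threshold that are excluded
from thermochemistry. Real modes below a 20 cm⁻¹ floor contribute ZPE but
not the thermal term k_BT·ln(1 − e^{−hcν̃/k_BT}), whose logarithm diverges
as ν̃ → 0; the floor is configurable. Only QM-subsystem vibrations are
treated — no rotational/translational partition functions, matching the
practice of correcting stationary points of an embedded reactive region.

## Landscape assembly and effective barrier

Steps are stitched cumulatively: each reactant minimum is the previous
product minimum. A step may declare its barrier (and reaction free energy)
measured from the global reference minimum instead of its own reactant —
needed when a study quotes a barrier "from the most stable inactive
state". For the urethanase cycle shipped as the worked example, the
hydrolysis barrier (18.2) is anchored at the acyl-enzyme minimum — the
step's reactant — because that step is kinetically controlled by its
second, water-attack stage; the alternative anchoring is expressible
through the same reference enum. Sub-step features inside a single step's
profile are not stitched as separate minima.

The effective barrier is the maximal climb from any preceding minimum to a
transition state, scanned exhaustively with ties broken toward the
earliest TS. No wrap-around (turnover) formalism over periodic cycles is
applied — the quantity matches the "barrier from the most stable preceding
state" usage, not the full energetic-span model.

## TST kinetics

Eyring inversion uses transmission coefficient 1; 25 °C is 298.15 K. TOF
is the least-squares slope of the initial window (default: through the
third time point, matching sampling designs with points at 0, 1.5 and 3 h)
converted to s⁻¹ per enzyme; TTN is final titer over enzyme concentration.
The plateau fit P_∞(1 − e^{−κt}) falls back to the maximum observed value,
flagged, when convergence fails. Enzyme amount may be supplied as mass +
molar mass + volume; no default molar mass exists, deliberately —
immobilised preparations rarely report an active molar fraction, which is
also why TTN values from such experiments are not reproducible from
printed data alone.

## Titration

Base-form convention: the protonated species is the charged one and its
fraction decreases with pH; an acid-form flag inverts the sign. The Hill
coefficient is free by default (constant-pH curves often show slopes ≠ 1
from site coupling) with a hill=1 constrained mode. Initial guesses: pKa
at the fraction nearest ½, Hill 1. Binomial weighting uses a variance
floor of 10⁻⁴ per count so exact 0/1 fractions keep finite weight.
Classification thresholds 0.1/0.9 are working conventions, configurable.
Degenerate data (all fractions at one extreme, or fewer than 4 pH points)
is rejected as non-identifiable.

## Trajectory analysis

Selections are explicit index/name/residue lists — no selection
mini-language. Kabsch superposition is computed by least-squares rotation
after centroid removal; per-residue RMSD applies one global fit on a
chosen selection and then measures each residue without refitting.
Degenerate (collinear) dihedrals yield missing values rather than
arbitrary angles. Unbinding detection defaults (threshold 10 Å,
persistence 50 frames) are working conventions for distinguishing release
from transient excursions. Supported trajectory formats are multi-frame
XYZ and multi-model PDB (first alternate location, no insertion codes),
read through MDAnalysis; no binary formats.

## Problem sizes and determinism

Statistical acceptance checks run at 21 windows × 2000 samples × 200
replicates (FEP recovery), 10⁵ samples (Gaussian closed form), and 100
replicates of 5000 Bernoulli draws per pH point (titration recovery) —
sizes at which the targeted tolerances are comfortably resolvable by the
propagated error estimates themselves. All randomness flows from explicit
integer seeds through `numpy.random.default_rng`; regenerating with the
same spec is bit-identical.

## Known limitations

No BAR/MBAR or umbrella-sampling estimators; no anharmonic corrections; no
Michaelis–Menten fitting; no microkinetic ODE modelling; no multi-site
coupled titration; single-structure error models only (inter-window
independence assumed). The surrogate ΔE route is a stated approximation to
true neighbour-geometry re-evaluation.
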