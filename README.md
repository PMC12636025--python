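# fepkit

Free-energy and kinetics analysis for QM/MM studies of enzyme mechanisms —
built around the workflow used to characterise urethanases (carbamate-
hydrolysing Ser-Ser-Lys amidases), but generic to any windowed reaction
path. It is a library for computational chemists and structural
bioinformaticians who have a reaction path and sampling output in hand and
need the statistics: profiles, barriers, rates, pKa fits and trajectory
descriptors.

## What it computes

**Mass-weighted path coordinate.** An IRC-style sequence of QM-subsystem
geometries is condensed to a single coordinate
`s_i = s_{i-1} + [Σ_j m_j |r_{j,i} − r_{j,i-1}|²]^{1/2}` (amu^{1/2}·Å).

**FEP profile.** The free-energy change from the reference window s_R to
window s_j combines gas-phase QM energy differences with window-wise
exponential averages of interaction-energy differences (Zwanzig):

    ΔG(s_j) = [E⁰_QM(s_j) − E⁰_QM(s_R)] − k_B T Σ_i ln⟨exp(−ΔE_i/k_B T)⟩_i

with delta-method standard errors from block averaging, accumulated in
quadrature along the path.

**Harmonic thermochemistry.** Mass-weighted Hessian diagonalisation,
TS/minimum classification by imaginary-mode count, ZPE and the quantum
harmonic vibrational free energy used to correct stationary points.

**Landscape assembly.** Per-step (ΔG‡, ΔG_rxn) values are stitched onto a
common reference; the effective (rate-determining) barrier is the energetic
span `max_TS [G(TS) − min preceding minima]`.

**TST kinetics.** Eyring interconversion `k = (k_B T/h)·exp(−ΔG‡/RT)`,
turnover frequency/total turnover number from progress curves, inactivation
plateaus, Beer–Lambert rates.

**Titration fits.** `f_prot(pH) = 1/(1 + 10^{n(pH − pKa)})` fitted to
constant-pH simulation records with binomial weighting.

**Trajectory statistics.** Distance/dihedral series with population
histograms, Kabsch-superposed RMSD (global, subset, per-residue), water
occupancy/exchange, and persistent-threshold unbinding detection.

Every stage has a synthetic-data generator with a machine-readable ground
truth, so the whole pipeline is testable without any external downloads.

## Worked example

```bash
python examples/landscape_effective_barrier.py
```

prints the stitched four-step landscape of urethane hydrolysis:

```
stationary point            kind      G (kcal/mol)
ES                          minimum       0.00
TS_conformational           ts            4.50
conformational_product      minimum       2.60
TS_acylation                ts           21.20
acylation_product           minimum     -16.70
TS_hydrolysis               ts            1.50
hydrolysis_product          minimum     -27.80
TS_decarboxylation          ts          -15.70
decarboxylation_product     minimum     -18.70

effective barrier: 21.2 kcal/mol at TS_acylation
```

Minima and transition states are in kcal/mol relative to the resting
enzyme–substrate state ES; the effective barrier of 21.2 kcal/mol at the
acylation TS identifies the first chemical step as rate-determining.
Consistently, `examples/eyring_kinetics.py` inverts an experimental
turnover frequency of 1.77×10⁻⁴ s⁻¹ at 303 K into a phenomenological
barrier of 22.9 kcal/mol — the two numbers bracket the same rate-limiting
event. The other examples (`fep_profile_recovery.py`, `titration_pka.py`,
`harmonic_corrections.py`, `trajectory_unbinding.py`) each demonstrate one
capability on synthetic data and print the recovered vs true quantities.

A thin CLI mirrors the stages (`fepkit run|path|fep|thermo|landscape|tst|
progress|titrate|traj`); `fepkit run --seed 1 --out-dir run/` executes the
end-to-end synthetic pipeline and writes CSV/JSON reports plus the resolved
configuration.

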