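"""Estimate a free-energy profile from synthetic windowed sampling.

Generates 21 reaction-path windows around a double-well ground truth
(barrier 12, product well −10 kcal/mol), with 2000 Gaussian interaction-
energy samples per window (σ = 0.5 kcal/mol), runs the exponential-average
estimator and compares the result with the construction.
"""
import numpy as np

from fepkit import SyntheticFEPSpec, fep_profile, generate_fep_windows
from fepkit.synthetic import double_well

spec = SyntheticFEPSpec(
    n_windows=21, noise_sigma=0.5, n_samples_per_window=2000,
    truth_profile=double_well(depth=10.0, barrier=12.0), seed=42,
)
windows, truth = generate_fep_windows(spec)
profile = fep_profile(windows, temperature=spec.temperature)

print(" s      dG_est   dG_true  stderr")
for s, dg, dt, se in zip(profile.s, profile.dg, truth["dg_truth"], profile.stderr):
    print(f"{s:5.2f}  {dg:8.3f} {dt:8.3f}  {se:6.3f}")

dev = np.abs(profile.dg - np.asarray(truth["dg_truth"]))
print(f"\nmax |estimate - truth| = {dev.max():.3f} kcal/mol "
      f"(max {np.max(dev[1:] / profile.stderr[1:]):.2f} propagated standard errors)")
print("Every window should sit within ~3 standard errors of the truth: the")
print("estimator is unbiased for the profile the generator encoded.")
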