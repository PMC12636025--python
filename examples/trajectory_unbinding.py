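"""Distance series, population histogram and unbinding detection on a
synthetic trajectory with a programmed release event at frame 400."""
import numpy as np

from fepkit import (
    SyntheticTrajectorySpec,
    detect_unbinding,
    distance_series,
    generate_trajectory,
    rmsd,
)

spec = SyntheticTrajectorySpec(
    n_frames=1000, n_atoms=10,
    distance_program=((0, 3.5),), distance_noise=0.3,
    unbind_frame=400, seed=11,
)
traj, truth = generate_trajectory(spec)

series = distance_series(traj, "A", "B", bin_width=0.5)
print(f"frames: {traj.n_frames}, histogram counts sum: {series.counts.sum()}")
print(f"most populated distance bin: {series.mode_bin[0]:.1f}-{series.mode_bin[1]:.1f} Å")

frame = detect_unbinding(series, threshold=10.0, persistence=50)
print(f"unbinding detected at frame {frame} (programmed: {truth['unbind_frame']})")

r = rmsd(traj.coords[0], traj.coords[-1], superpose=True)
print(f"Kabsch RMSD first vs last frame: {r:.2f} Å")
print("Before release the pair hovers near 3.5 Å; after frame 400 it jumps")
print("beyond 15 Å and stays there, which the persistence filter reports as")
print("a single unbinding event rather than a transient excursion.")
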