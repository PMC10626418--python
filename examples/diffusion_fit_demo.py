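"""Two-population diffusion fit from single-particle trajectories.

Simulates 10,000 trajectories of a membrane protein with a 73% fast fraction
(D1 = 0.364 um^2/s) and a 27% slow fraction (D2 = 0.026 um^2/s) at a
10.5 ms frame interval, then recovers the three parameters from the pooled
step-size distributions at several time lags.
"""

from memnano import diffusion as di
from memnano import synth

model = synth.DiffusionModel(0.731, 0.364, 0.026, dt_ms=10.5)
tracks = synth.gen_trajectories(model, 10000, 10, seed=42)

msd = di.msd(tracks, dt_ms=10.5)
cdfs = di.step_cdf(tracks, lags=[1, 2, 3, 4])
fit = di.fit_binary(cdfs, dt_ms=10.5)

print(f"ensemble MSD fit      : D = {msd.d_um2_s:.3f} um^2/s "
      f"(population average; offset {msd.offset_um2:.2e} um^2)")
print(f"two-population fit    : F = {fit.fast_fraction:.3f}, "
      f"D1 = {fit.d1_um2_s:.3f}, D2 = {fit.d2_um2_s:.3f} um^2/s")
print(f"truth                 : F = 0.731, D1 = 0.364, D2 = 0.026")

# The single-D MSD fit lands near the population-weighted mean, while the
# step-size-distribution fit separates the fast and slow fractions.
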