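"""FRET yield, receptor occupancy, and the crowding-FRET control.

Computes the donor-recovery-after-acceptor-photobleaching yield and converts
it to receptor occupancy, prints the labeling-ratio combinatorics used to
plan two-color staining, and runs the crowding Monte-Carlo that asks how
much FRET random molecular proximity alone produces at high densities.
"""

import numpy as np

from memnano import fret

# DRAAP: donor channel is dimmer before acceptor ablation by the transferred energy
e = fret.fret_yield(dd_pre=90.0, dd_post=100.0, background=0.0)
occ = fret.occupancy_from_yield(e)  # empirical conversion C = 1.21
print(f"FRET yield {e:.3f} -> receptor occupancy {occ:.3f}")

for k in (1, 2, 3, 4):
    det, rec = fret.labeling_combinatorics(k)
    print(f"donor:acceptor 1:{k} -> detection efficiency {det:.1f}%, "
          f"signal recovery {rec:.1f}%")

cfg = fret.CrowdingSimConfig(densities_um2=np.arange(100.0, 1001.0, 100.0),
                             repetitions=10, roi_um=(5.0, 5.0))
res = fret.simulate_crowding_fret(cfg, seed=7)
for d, m in zip(res["density_um2"][::3], res["mean_e"][::3]):
    print(f"  crowding FRET at {d:5.0f} molecules/um^2: E = {m:.4f}")
print("Even at 1,000 molecules/um^2, random proximity yields only ~5% FRET "
      "(Forster radius 5.1 nm), far below bona fide dimer signals.")
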