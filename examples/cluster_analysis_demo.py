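"""Decide clustered vs random for a localization map, blinking-aware.

Builds two synthetic high-speed PALM maps of a membrane protein at
100 molecules/um^2 in a 3 x 3 um region -- one spatially random, one with 80%
of molecules in 60 nm nanoclusters -- each with realistic fluorophore
blinking and 51 +/- 12 nm localization precision, then runs the three
cluster tests against matched random simulations.
"""

import numpy as np

from memnano import clusters as cl
from memnano import synth

ROI = (3000.0, 3000.0)
blinks = synth.BlinkStatistics.default()

for name, spec in [("random", None), ("clustered", synth.ClusterSpec(60.0, 0.8, 10.0))]:
    pattern = synth.gen_point_pattern(100.0, ROI, spec, seed=1)
    locs = synth.gen_localizations(pattern, blinks, (51.0, 12.0), seed=2)

    curve = cl.ripley_envelope(locs, ROI, blinks, seed=3)
    cm = cl.ldv_analyze(locs, ROI)
    xy = locs[["x_nm", "y_nm"]].to_numpy()
    eps = cl.select_epsilon(xy, ROI, seed=4)
    db = cl.dbscan_summary(xy, eps)

    print(f"--- {name} map: {len(pattern)} molecules -> {len(locs)} localizations")
    print(f"  Ripley envelope verdict : {curve.verdict}")
    print(f"  LDV                     : eta={cm.eta:.3f}, rho={cm.rho_um2:.0f} um^-2")
    print(f"  DBSCAN (eps={eps:.0f} nm)   : {db.pct_in_clusters:.1f}% of points in "
          f"{db.n_clusters} clusters")

# The Ripley verdict is the blinking-aware call: the random map stays inside
# the simulated envelope even though blinking makes it look clumpy, while the
# clustered map exceeds it.  The DBSCAN percentage on random data stays at the
# ~1% calibration level of the matched null.
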