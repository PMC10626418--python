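# memnano

Single-molecule microscopy analysis of membrane-protein nanoscale
organization, mobility, stoichiometry and function — built for the question
of whether a cell-surface receptor ligand (the motivating case: peptide-loaded
MHC class II on antigen-presenting cells) exists as nanoclusters or as freely
diffusing monomers, and what that means for receptor triggering.

The package is aimed at quantitative microscopists and immunologists who work
with single-molecule localization microscopy (PALM/STED), single-particle
tracking, TOCCSL brightness analysis, FRET and ratiometric calcium imaging.
Every estimator is paired with a synthetic-data generator so the whole suite
runs, and is tested, without any experimental download.

## What it computes

**Cluster statistics with blinking-aware nulls** (`memnano.clusters`).
Localization maps overcount molecules because fluorophores blink, which
creates artifactual nanoclusters. Maps are therefore tested against
*simulated* localization maps matched in molecular density, blinking
statistics, localization precision and diffusion:

- Ripley's K: `L(r) − r` with `K(r) = (A/n²) Σ_{i≠j} 1(d_ij ≤ r)`, compared
  to a 10-simulation envelope within r ≤ 250 nm (rank-envelope verdict).
- Label-density variation: localizations rendered as σ = 35 nm Gaussians,
  thresholded; the density in the supra-threshold area ρ at relative
  clustered area η is compared to the random reference ρ = ρ₀(1 + 1.4 η⁴).
- DBSCAN (minpts = 5) with epsilon calibrated on the matched null so random
  data yields ~1% clustered molecules; plus a Resolvable / Borderline /
  Not-resolvable detectability map over cluster regimes.

**Two-population diffusion** (`memnano.diffusion`). MSD(t) = 4Dt + 4σ², and
the step-size mixture CDF
`P(r²,t) = 1 − F e^{−r²/4D₁t} − (1−F) e^{−r²/4D₂t}` fitted jointly across
lags; trajectory linking by per-frame optimal assignment; inverse-FRAP
dispersal with per-frame photobleach correction.

**TOCCSL stoichiometry** (`memnano.toccsl`). Monomer brightness pdf ρ₁(B) by
KDE; N-mer pdfs by convolution ρ_N = ρ₁ ∗ ρ_{N−1}; non-negative least-squares
mixture weights α_N with Σα_N = 1; and a Monte-Carlo of the full
bleach/recovery experiment quantifying dimer-detection efficiency.

**FRET** (`memnano.fret`). DRAAP yield `E = (DDpost − DDpre)/(DDpost − bg)`;
sensitized-emission apparent efficiency `K·DA/DDpre`; receptor occupancy
`K·DA/(DDpost·R)` or `E × C` (empirical C = 1.21); labeling-ratio
combinatorics; pair FRET `E = 1/(1 + (d/R₀)⁶)` with R₀ = 5.1 nm and the
two-acceptor combination `E = S/(1+S)`, `S = ΣE_i/(1−E_i)`; a crowding
Monte-Carlo for proximity FRET of randomly scattered molecules; and smFRET
lifetimes with photobleach correction
`app t_off = t_off·t_lag/(t_off·c_bleach + t_lag)`.

**STED autocorrelation** (`memnano.sted`). Image rendering and the
fluctuation autocorrelation `G(r) = ⟨δI δI⟩/⟨I⟩²`, whose small-lag amplitude
scales inversely with molecules per PSF, judged against rendered random
references.

**Calcium dose-response** (`memnano.calcium`). ROC-thresholded activation
classification (80% rule), logistic dose-response
`Y = Bottom + Xⁿ(Top−Bottom)/(Xⁿ + T_Aⁿ)` for the activation threshold T_A,
and a case-resampling bootstrap ratio test for comparing T_A between
conditions.

**Quantitation and I/O** (`memnano.quantitation`, `memnano.io`,
`memnano.synth`): surface densities from ensemble fluorescence, bead-MESF
copy numbers, localization-table I/O (canonical and ThunderSTORM dialects),
and all synthetic generators.

## Worked example

```bash
python examples/diffusion_fit_demo.py
```

```
ensemble MSD fit      : D = 0.273 um^2/s (population average; offset 1.20e-04 um^2)
two-population fit    : F = 0.736, D1 = 0.365, D2 = 0.026 um^2/s
truth                 : F = 0.731, D1 = 0.364, D2 = 0.026
```

10,000 trajectories are simulated from a two-population Brownian model with
a 73.1% fast fraction; the single-D MSD fit can only report the population
average, while the step-size-distribution fit separates the fast
(0.36 µm²/s) and slow (0.026 µm²/s) fractions — the mobility signature of a
freely diffusing membrane protein plus a small transiently confined pool.
The other scripts in `examples/` demonstrate the cluster verdicts, TOCCSL
mixture fitting, FRET occupancy and crowding control, and the calcium
dose-response pipeline, one capability each.

A thin CLI mirrors the library (`memnano ripley`, `memnano dbscan`,
`memnano toccsl-fit`, `memnano fret-sim`, `memnano calcium`, ...); every
subcommand takes `--seed`, `--out` and `--set key=value` overrides and
reproduces its outputs exactly for a fixed seed.

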