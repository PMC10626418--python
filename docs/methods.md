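# Methods

This note records the models, defaults, numerical choices and known
limitations behind each module. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Synthetic data: the study conditions

All estimators are exercised on synthetic inputs whose defaults are the
conditions of the motivating measurements on live antigen-presenting cells:

- **Point patterns.** Molecular surface densities of ~30–2,400 µm⁻²
  (100 µm⁻² is the default for cluster-analysis work) in rectangular ROIs
  (3 × 3 µm default). Counts are Poisson(density × area), positions uniform —
  the homogeneous Poisson process is the null every cluster test calibrates
  against. Clustered patterns place Poisson-distributed disk centers and put
  a chosen fraction of molecules uniformly inside disks of 20–100 nm radius;
  points are wrapped toroidally so the realized density is exact at edges.
- **Localization maps.** Each molecule produces N detections drawn from a
  detections-per-molecule table. The default table (mean N ≈ 2, geometric-
  like) is a stand-in for a measured photoswitching calibration and is
  user-replaceable (`BlinkStatistics`). Off gaps between detections are
  geometric with mean 2 frames, truncated at the 20-frame merge gate — the
  minimum structure needed to place detections on frames. Localization error
  is isotropic normal with a per-molecule precision drawn from 51 ± 12 nm.
  Live-cell maps add Brownian displacement between detection frames.
- **Trajectories.** Two-population Brownian motion: fast fraction F with
  coefficient D₁, remainder D₂, per-axis step variance 2 D Δt (Δt = 10.5 ms
  default), optional static localization noise σ added per position.
  Reference parameter sets: F = 0.731/0.626, D₁ = 0.364/0.263,
  D₂ = 0.026 µm²/s (dendritic cells / B-cells), and F = 0.83, D₁ = 0.284,
  D₂ = 0.046 µm²/s for the blinking-null simulations.
- **Brightness samples.** A spot of multiplicity k sums k independent
  monomer draws; the monomer law is Normal(100, 20) counts truncated at 0.
- **Calcium traces.** Activated cells step to ~2.5× baseline within the
  first frames and stay high; oscillatory cells alternate with ~50% duty so
  neither 80% rule applies; non-activated cells fluctuate around baseline
  (noise sd 0.08).

What the generators do **not** emulate: camera noise and pixelation of the
spot-fitting step (localization tables are taken as fitter output),
dye-specific photophysics beyond the empirical blink table, z-dimension,
membrane topography, and cell-to-cell heterogeneity. Passing tests therefore
demonstrate estimator correctness and calibration under the stated
statistical structure, not robustness to every instrumental artifact of real
recordings.

## Cluster analysis

**Ripley's K.** `K(r) = (A/n²) Σ_{i≠j} 1(d_ij ≤ r)` on a 10–500 nm grid
(10 nm steps), `L − r = √(K/π) − r`. No analytic edge correction is applied:
data and matched simulations are analysed identically, so the edge bias
cancels in the comparison (simulations wrap toroidally when displacing
points). Pair counting uses a k-d tree.

**Envelope verdict.** Ten simulated random maps are generated at the map's
molecular density (localization count divided by the blink-table mean),
with the map's precision, the blink table, and optionally diffusion. The
published decision rule — curve maxima "mainly above" the simulated
random band within r ≤ 250 nm — needs an operationalization. Scoring
"data above envelope mean + sd at ≥ 50% of radii" has a measured false-positive
rate of 12–14% on random maps, because adjacent radii are strongly
correlated and the sd of a 10-simulation envelope is noisy; that violates
the intended ≤ 10% false-call rate. The package instead uses the
rank-envelope form of the same idea: *clustered* iff the data curve exceeds
the pointwise **maximum** of the 10 simulations at ≥ 50% of radii in
(0, 250 nm]. Under exchangeability the false-positive probability of this
rule is bounded by 1/(n_sims + 1) ≈ 9.1% whatever the correlation across
radii; the measured rate is lower (tests assert ≥ 90% correct calls on both
random and resolvable-clustered maps over 50 seeds). The mean ± sd band is
still attached for plotting.

**Blink merging.** Greedy temporal grouping in frame order: a detection
joins the nearest open group within 100 nm of the group's running mean and
within 20 frames of its last detection; groups larger than 30 detections
are discarded as outliers. Greedy first-match with nearest-distance
tie-break mirrors the behaviour of localization-merging tools and is
deterministic.

**Label-density variation.** Each localization is rendered as a unit-peak
Gaussian, σ = 35 nm truncated at 2σ, summed on a 5 nm grid (≪ σ, keeping
discretization error below 1%), thresholded (default 1.0; the useful range
is 0.5–4.5). η = supra-threshold area / ROI area; ρ = localizations inside
the mask per µm² of clustered area. The random reference is
ρ = ρ₀(1 + 1.4 η⁴). Two points here were genuinely open:
(i) the printed form of the reference could be read as multiplication or
division by (1 + 1.4 η⁴); the multiplicative reading is adopted (both agree
in the η → 0 limit, and only the multiplicative one matches random
simulations, which rise mildly with η) with the alternative selectable via
`divide=True`; (ii) ρ₀ is the reference's calibration constant, not a
per-sample quantity — it is obtained by least squares of the reference
through (η, ρ) points of random simulations spanning label densities
(`fit_ldv_rho0`), exactly how such reference curves are constructed in
practice. Random simulations track the fitted curve within 15% over
η ≈ 0.2–0.7; clustered simulations exceed it.

**DBSCAN.** minpts = 5. The starting epsilon comes from the k-distance
graph (k = minpts), with the elbow taken as the point of maximum distance
to the chord between the sorted curve's endpoints (the published workflow
names no elbow criterion; this one is parameter-free and deterministic).
Epsilon is then decreased in 10 nm steps until DBSCAN on a matched CSR
simulation with the same point count assigns ≤ 1% of molecules to clusters.
Clustering itself is scikit-learn's DBSCAN; an O(n²) textbook implementation
serves as an independent oracle in the tests.

**Detectability map.** For each cluster regime, 10 clustered and 10 random
maps (both with blinking and localization error) give L − r bands;
*Resolvable* if the clustered lower band (mean − sd) exceeds the random
upper band (mean + sd) at some r ≤ 250 nm, *Borderline* if only the
clustered mean does, *Not resolvable* otherwise.

## Diffusion

Linking is per-frame optimal bipartite assignment (Hungarian) within a
gate (default 800 nm ≈ 4× the rms step of the fastest population at
Δt = 10.5 ms, excluding < 0.01% of true Brownian steps), with gap closing up
to a configurable number of frames and truncation at 50 steps. The published
analysis cites an external linking algorithm without details; optimal
assignment is the standard reproducible choice, and a brute-force exhaustive
matcher is the test oracle on small instances.

MSD is averaged over all tracks and start points; D comes from the first
two lag points of MSD = 4DΔt + 4σ² (slope/4), the offset estimating 4σ².
The two-population fit is a joint nonlinear least squares of the mixture
CDF across lags (each lag's empirical CDF evaluated at 200 quantiles,
all lags weighted equally), parameterized as (logit F, log D₁, log D₂) with
two starts to avoid label-swapped local minima; D₁ ≥ D₂ is enforced by
relabelling. If the fitted minority weight is below 5% the input is treated
as single-population: the result collapses onto the dominant coefficient
and is flagged `degenerate` (the second coefficient is unidentifiable).

iFRAP: mean ROI intensities, background-subtracted, divided by
(1 − b)^k with b = 3% bleach per frame; reported as the normalized decay of
the converted region and the out/in ratio.

## TOCCSL

The monomer pdf is a Silverman-bandwidth Gaussian KDE on a 1,024-point grid
spanning [0, 1.1 × max B] (the estimator is not prescribed by the source
analysis; KDE is the field standard), renormalized to unit grid integral;
degenerate (zero-variance) samples get a narrow Gaussian at the common
value. N-mer pdfs are built by discrete convolution with the support
extended to N× the monomer support. Mixture weights are fitted by
non-negative least squares of the sample's histogram density (64 bins)
against {ρ_N} and renormalized to Σα = 1 — a deterministic solution of the
constrained problem. A minimum of 180 brightness values per pdf is the
recommended sample size; smaller samples warn.

The Monte-Carlo uses the documented geometry: 10.5 × 10.5 µm² cell,
500 molecules/µm², D = 0.244 µm²/s (the population-weighted mean
0.83·0.284 + 0.17·0.046), a 7 × 7 µm² mask bleached for 750 ms, 2 s
recovery. The experimental bleach-edge profile is unpublished; it is
modeled as a logistic intensity fall-off (default width 300 nm) with
per-fluorophore survival exp(−k·I·t) integrated over the moving molecule's
path (25 bleach sub-steps; k·I_max = 20 s⁻¹ so the mask interior bleaches
to completion). Readout counts entities inside the mask shrunk by a 1 µm
margin and reports the fraction of detected spots with two surviving
fluorophores. Detection of 100%-dimer input is substantially below 100%
(partial edge ablation) and decreases monotonically with edge width. It is
**not** monotone in D: at slow diffusion the analysed interior is reached
first by partially ablated edge molecules, so the detected dimer fraction
*rises* with D toward a plateau before flattening — the simulated
efficiencies are qualitative anchors, not reproductions of specific
experimental percentages.

## FRET

The channel algebra is implemented exactly as defined
(yield, apparent efficiency with cross-excitation α and bleed-through β,
occupancy with the single-molecule intensity ratio R). Two printed-source
ambiguities are resolved and pinned by tests: the filter-based
R is (donor transmission / acceptor transmission) **divided** by the maximal
FRET efficiency 0.78 (only division reproduces the printed 1.07 from
62.1%/74.3%), and the smFRET bleach correction is
app t_off = t_off·t_lag/(t_off·c_bleach + t_lag) — the flattened printed
form is dimensionally inconsistent; the adopted form is dimensionally
correct and has the right limits (→ t_off as t_lag → ∞, → 0 as t_lag → 0),
with c_bleach acting as the per-interrogation bleach rate constant
(−ln of the per-frame survival).

Survival curves are fitted by unweighted least squares on the normalized
inverse cumulative trace-duration curve (start 1, plateau 0), as the
procedure is described, not by MLE; since every observed trace exists at
its first interrogation, the exponential is fitted against time elapsed
beyond that point (otherwise the apparent lifetime is biased high by up to
the first lag).

The crowding Monte-Carlo scatters donors and acceptors at the given ratio
in a toroidal 10 × 10 µm ROI (periodic k-d tree; edge-bias-free nearest-
acceptor search), takes each donor's two nearest acceptors, combines their
efficiencies via the additive-rate formula, and reports mean and min–max
over 20 repetitions per density on the 20–1,000 µm⁻² grid. Coincident
points are clipped at E = 1 − 10⁻¹⁵.

## STED autocorrelation

Images are sums of Gaussians (peak intensity I, width σ) on a 25 nm pixel
grid plus constant background and Poisson shot noise. The ACF uses the
fluctuation normalization ⟨δI δI⟩/⟨I⟩² — required for the amplitude ∝
1/(molecules per PSF) behaviour — computed by FFT correlation with zero
padding and overlap-count bias correction (no wrap-around on small ROIs),
radially averaged in 1-pixel (25 nm) bins; G(0) carries the shot-noise
spike and is reported separately. Cluster calls against rendered random
references use the same rank-envelope rule as Ripley's K.

## Calcium

Traces are normalized to the pooled median of a negative control (or each
trace to its own start, by flag). The activation threshold maximizes
Youden's J between positive- and negative-control per-cell summaries; the
per-cell statistic is the median of the 11-frame window starting at the
peak (the source analysis defines the ROC only up to the statistic; the
peak-window median is robust to single-frame noise and is recorded with
each classification). Cells are *activated* with ≥ 80% of frames above
threshold, *non-activated* with ≥ 80% below, else *oscillatory* — the
labels are invariant under joint monotone rescaling of traces and
threshold.

The dose-response fit profiles Bottom and Top in closed form (the model is
linear in them for fixed T_A and hill n) and minimizes over log T_A by a
vectorized coarse grid with three zoom refinements (and a 12-point hill
grid when n is free). This makes a single fit ~10⁻⁴ s, so the
1,000-replicate bootstrap and its 200-simulation type-I calibration run in
minutes. The bootstrap case-resamples cells within each dose level
(binomial resampling of per-cell activation outcomes), refits T_A for both
datasets per replicate, and reports the two-sided percentile p-value of the
log-ratio and the bootstrap sd of each T_A; it errors if more than 20% of
replicate fits fail. Fits whose data span less than half the fitted
response range are flagged as poorly constraining T_A.

## Problem sizes

Defaults used by the test suite and the acceptance script: 30,000
trajectories of 10 steps for the two-population recovery; 50 random and 50
clustered maps (10-simulation envelopes each) for the Ripley calibration;
nine (η, ρ) points over blink means 1–3 for the LDV reference; n = 500
brightness values per mixture fit; the full 50-density crowding grid at 20
repetitions; a 3 × 3 (t_off, bleach) grid with 10–20 replicates for smFRET;
and 200 null simulations with B = 1,000 bootstrap replicates for the
type-I calibration. These sizes give sampling error comfortably below each
assertion's tolerance while keeping a full run in the minutes range on one
CPU.

## Known limitations

- The default blink table is a stand-in; real analyses should substitute a
  measured detections-per-molecule distribution.
- The TOCCSL bleach-edge profile is a mechanistic model, not the measured
  laser profile; simulated detection efficiencies are qualitative.
- `fit_binary` assumes exactly two non-exchanging Brownian populations; no
  confinement model beyond the static-noise offset, no state switching
  within tracks.
- The LDV reference constant ρ₀ must be calibrated on random simulations
  matched to the imaging conditions; it is not transferable across kernel
  σ, threshold, or blink statistics.
- ROI selection, channel registration and spot fitting are upstream of this
  package: localization tables, trajectories, brightness lists and traces
  are consumed as produced by the acquisition stack.
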