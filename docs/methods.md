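# Methods

This note documents the models, defaults and numerical choices behind
`bromscreen`, and what the synthetic-data generator does and does not
emulate.

## Exact-mass arithmetic

All masses derive from a pinned isotope table (CIAAW 2021 representative
abundances, AME2020 atomic masses; version tag `ciaaw2021-ame2020`,
shipped as a packaged CSV) plus the CODATA electron mass. The table is
immutable once loaded and covers H, C, N, O, P, S, Cl and Br; per-element
abundances are validated to sum to 1 ± 1e-6.

An ion's m/z sums principal-isotope masses for its adduct-adjusted
composition, replaces the stated number of atoms by heavy isotopes (e.g.
two ⁸¹Br), and adds one electron mass per negative charge (subtracts for
positive). The deprotonated anion is therefore
`(M − H atom + e⁻) / |z|`; this convention is required to reproduce
instrument-software reference values (e.g. 604.69196 for the two-⁸¹Br
isotopologue of deprotonated TBBPS-MAE) to 1e-4 Da. Mass errors are
reported as absolute ppm with the calculated value in the denominator.

## Isotope envelopes

Two models are provided:

* **Binomial bromine envelope** — treats Br as the only polyisotopic
  element: n+1 peaks spaced by Δ = m(⁸¹Br) − m(⁷⁹Br) ≈ 1.99795 Da,
  binomially weighted. At p = 0.5 the ratios are exactly the Pascal
  coefficients; at the natural p(⁸¹Br) = 0.4931 the envelope is slightly
  asymmetric (central/monoisotopic ratio ≈ 18.4 for Br₆ rather than 20).
* **Fine structure** — element-by-element convolution of single-atom
  isotope distributions (pruned at 1e-4 relative probability by default),
  followed by Gaussian centroid merging at FWHM = m/z / resolving power
  and renormalization to a maximum of 1. At the default resolving power
  of 60,000 (Orbitrap-class; a package assumption, not a measured
  setting) the ³³S/³⁴S, ¹³C₂, ²H and ¹⁷O/¹⁸O satellites merge into the Br
  isotopologue centroids, which recovers the integer-ratio patterns
  (1:4:6:4:1 etc.) reported for these compounds to within ~20% per peak;
  the ~16%-abundance ¹³C₁ satellites remain as separate centroids between
  the Br peaks.

Integer ratio strings are derived output: abundances are rescaled so the
smallest envelope peak maps to 1, then rounded. Envelope comparison uses
a quantitative score — greedy nearest-m/z pairing within a ppm tolerance,
then `1 − mean(|obs − pred| / pred)` over matched relative abundances,
clipped to [0, 1] and defined as 0 when fewer than two predicted peaks
match. The default per-peak relative-abundance tolerance for ion-ratio
decisions is 20%.

## Chromatograms and peak integration

EICs sum centroid intensities within a symmetric ppm window (default
5 ppm) per scan. Peak integration estimates the baseline level and noise
as the median and MAD-derived sigma of the trace outside the search
window, picks the baseline-corrected local maximum nearest the expected
RT (ties toward higher intensity) within ± 0.10 min (default; retention
times are quoted to 0.01 min but no window is published, so the window is
a package choice), requires S/N ≥ 3, and integrates trapezoidally between
the points where intensity falls below `baseline + max(3σ, 0.5% of
height)`. The ~0.1–1% systematic area loss from bound truncation cancels
in external calibration because standards and samples are integrated
identically.

mzML reading is implemented directly on lxml (centroided MS1 only; 32/64
bit floats, zlib or no compression; profile spectra are rejected). The
native JSON format stores scans as parallel arrays with sample metadata;
long-format CSV (`rt, mz, intensity`) is accepted for fixtures.

## Targeted identification

A target is confirmed only if all four criteria pass, and every failure
is recorded as a flag: (1) quantifier-isotopologue peak at the expected
RT with S/N ≥ 3; (2) qualifier isotopologue co-eluting within half the RT
tolerance (same chromatographic peak); (3) qualifier/quantifier area
ratio within ±20% (relative) of the fine-structure envelope prediction;
(4) intensity-weighted observed m/z at the apex within 5 ppm of theory.
Relaxing any tolerance can only preserve detections.

## Untargeted bromine-compound discovery

Within each scan, peaks above an intensity floor are chained at
successive Δ ± 0.005 Da spacings. The next link is searched in the
window rather than taken as the next centroid, because ¹³C satellites
interleave between Br isotopologues; the tolerance is tight enough to
exclude the 2×¹³C spacing (2.00671 Da, 0.0088 Da away from Δ). Chains
that shadow a ≥2× stronger chain one carbon-isotope unit below are
dropped as satellite series. Each cluster is edge-trimmed at 2% of its
maximum — the merged ³⁴S/¹³C₂/¹⁸O satellite one spacing beyond the last
true isotopologue sits at +1.9987 Da and would otherwise mimic an extra
bromine — and its bromine count is the best least-squares fit of
normalized intensities to natural-abundance binomial envelopes with
candidates bracketing the cluster size by one (tolerating a missing edge
peak); fits worse than 0.05 mean squared deviation are rejected.
A chromatographic compound persists across adjacent scans, so clusters
seen in fewer than 3 scans are discarded as baseline coincidences; this
suppresses chance ~2 Da pairs in random background completely while
costing nothing at realistic peak widths. Surviving hits are deduplicated
by RT/m-z proximity and their monoisotopic peaks decomposed into
candidate formulas. The decreasing-mass-defect heuristic is available as
an optional coarse pre-filter, never a hard gate.

Formula decomposition searches all compositions of C, H, N, O, S, Br (and
any other bounded elements) by enumerating non-hydrogen counts with mass
pruning and solving for the hydrogen count from the mass residual — exact
over the bounds without enumerating H. Candidates are filtered by
RDBE ≥ 0 computed on the neutral (ion + |z| H for anions;
RDBE = C − (H+Br+Cl)/2 + N/2 + 1) and ranked by absolute ppm error.

## Quantification and validation

External-standard calibration is unweighted OLS of area against
concentration over seven points spanning 0.05–100 ng/mL, accepted at
R² > 0.99. A 1/x-weighted fit is available and is what the end-to-end
pipeline uses for cohort quantification: with proportional area noise the
unweighted intercept inherits the absolute scatter of the top standards
(~0.05–0.1 ng/mL equivalents), which dominates the error at the
0.05–1 ng/mL levels where environmental samples sit; 1/x weighting is the
standard remedy for trace-level work. Back-calculated solution
concentrations convert to ng/g dry weight via extract volume / dry mass;
negative back-calculations are floored at 0 and flagged, extrapolations
beyond the calibration range flagged.

Recovery is 100 × measured/spiked with sample SD (n−1) across
replicates. Matrix effect is the post-extraction matrix-spike to
solvent-standard area ratio at equal concentration. The IDL is the
smallest injected mass whose five replicates are all detected (S/N ≥ 3)
with RSD ≤ 20%; if no level qualifies, the IDL is reported as above the
highest tested mass. The MDL multiplies the sample SD of n ≥ 7 replicate
spiked analyses by the one-sided Student t at 99% confidence
(t(0.99, 9) = 2.821 for n = 10); the exact literature variant of this
replicate-spike formula is not fully specified upstream, so the
t-statistic convention is an explicit, documented assumption. Cohort
summaries count a detection only when the screening criteria passed and
the concentration is at or above the MDL; ranges, means and medians are
computed over detected samples only, with no substitution for
non-detects. Every batch must include a procedural blank; any target
detected in a blank at or above its MDL voids the batch.

The ¹³C-labelled internal standard used in the wet-lab workflow is a
recovery monitor only and never enters the concentration calculation; it
is therefore not modelled in this package.

## Synthetic-data generator

`make_run` produces centroided full-scan runs: per compound, a Gaussian
chromatographic peak (σ = 0.05 min) at its retention time (4.20, 4.56,
4.80 min for the MAE/MBAE/MDBPE derivatives) whose quantifier-trace
integral equals response factor × concentration (response factors default
to the published calibration slopes: 519149, 421073, 363618 counts·min
per ng/mL); each scan under the peak carries the compound's
fine-structure envelope with Gaussian m/z jitter (default 1.0 ppm SD — a
conservative default chosen because published mass errors are below
0.4 ppm; values above 5 ppm are rejected as making 5-ppm screening
ill-posed) and multiplicative log-normal intensity noise (CV 5%).
Baseline peaks arrive as a Poisson number per scan (mean 20), uniform in
100–1000 m/z with exponential intensities (scale 50 counts). Scans are
spaced 0.01 min over 6 min (600 scans; the real gradient and scan rate
are not published, so these are declared assumptions). Three untargeted
spikes — tetrabromobisphenol-S, tribromophenol and
2,6-dibromo-4-nitrophenol at 2.64 / 2.82 / 1.76 min — are available for
discovery tests. Everything derives from one integer seed; identical
seeds give byte-identical native JSON.

The cohort scenario draws per-sample true concentrations from a two-part
model: Bernoulli presence at the observed detection frequencies (2/38,
15/38, 36/38) then a log-normal over the reported ranges (0.1–0.2,
0.1–1.6, 0.3–4.1 ng/g dw) with the median at the geometric centre and
~95% of mass inside the range (clipped to the range) — the study reports
only ranges and frequencies, not distributions. True tissue
concentrations convert to effective solution concentrations through
dry mass / extract volume (0.5 g / 1 mL) × recovery (0.85) × matrix
suppression (0.95). The manifest records all ground truth, so
closed-loop tests compare pipeline estimates against known values after
correcting for the known recovery chain.

**What the generator does not emulate:** realistic biological-matrix
background (baseline is sparse and uniform), chromatographic tailing,
retention-time drift between runs, detector saturation, isotope-labelled
internal-standard traces, and species/year covariate effects on
concentration (the source study found none significant; hooks exist for
adding one). Passing closed-loop tests therefore demonstrate the
correctness of the algorithms under the stated noise model, not
instrument-grade robustness against matrix interference.

## Problem sizes used in tests

The suite runs the full pipeline at the study's own scale — a 38-sample
cohort of 600-scan runs, seven-point calibration series, ten-replicate
MDL spikes — and uses reduced replicate counts (e.g. 8–16 simulated runs
where a property is stated over hundreds) for the stochastic property
checks; stochastic assertions use fixed seeds and conservative bands.

## Known limitations

* Bromine-only halogen logic: chlorine/mixed-halogen envelope
  classification is out of scope in this version.
* Formula decomposition is exhaustive within bounds; very wide bounds at
  high m/z grow combinatorially.
* The fine-structure model merges centroids with a Gaussian FWHM rule and
  does not simulate profile peak shapes.
* mzML support is read-only and limited to centroided MS1 spectra.
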