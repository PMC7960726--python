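# Methods

## The experiment this package models

In serial femtosecond crystallography (SFX) at a MHz-repetition-rate XFEL,
each X-ray pulse vaporises a segment of the sample-carrying liquid microjet
and launches a shockwave that travels supersonically along the jet. The
shock reaches sample that a later pulse will probe, so it can damage
crystals *before* they are measured. The package implements the analysis
of an X-ray-pump/X-ray-probe experiment designed to quantify this: a pump
pulse strikes a ~5 um, ~50 m/s jet; after a delay Δt = 122.5 ns a probe
pulse, displaced Δx = 5 um upstream (toward the nozzle), records
diffraction from material the shock has just traversed. Because the jet
advects material downstream, the probed material sits an effective
Δt + Δx/v = 222.5 ns behind the pump — emulating the 222 ns pulse spacing
of 4.5 MHz operation.

The analysis has five stages, each a module:

1. **jet_imaging** — segment femtosecond jet snapshots (dark jet, bright
   background, vertical axis, rows increasing downstream), measure
   explosion gaps, projected width, break-up point, and jet speed from
   gap tracking, v = (y(t1) − y(t2)) / (t1 − t2).
2. **shot_filtering** — the shot-acceptance rules: pre-pulse diode noise
   (exclude if noise SD > mean + 3·SD of the clean population), pump
   leakage on the Fe-masked diode (keep if pump-window signal
   < mean + 1.5·SD), and jet morphology (width within 1 SD of the run
   median, 1–2 gaps, jet continuous upstream of the pumped segment).
   A hit is an image with ≥ 10 peaks; hit rates count all shots, indexing
   rates count indexed images among *filtered* hits.
3. **diffraction_stats** — per-image resolution (best d with
   I/σ(I) ≥ 4), probe-energy binning and distribution equalisation, and
   merged-data metrics: unweighted merging to the mmm asymmetric unit,
   Rsplit = 2^(−1/2)·Σ|I1 − I2| / (½·Σ(I1 + I2)), CC1/2 and
   CC* = sqrt(2·CC1/2/(1 + CC1/2)) on random half sets split by whole
   images, completeness against the full unique list (screw-axis
   absences excluded), Wilson B from the slope of ln⟨I⟩ vs (1/2d)²,
   and an automatic resolution cutoff at the first bin whose mean
   I/σ(I) falls to 1.0.
4. **structural_comparison** — Cα pairing by (chain, residue number),
   Kabsch superposition (proper rotations only), displacement fields
   (statistics always on unscaled vectors; the ×10 arrow scaling is
   export-only), distance-difference matrices D_ij = d_ij(B) − d_ij(A)
   with per-residue sums of relative changes as the compaction summary,
   radius of gyration, and bootstrap coordinate errors: resample the
   image pool with replacement to its original size, refine a structure
   per resample (the shipped surrogate engine is the per-atom mean of
   per-image coordinate observations; a crystallographic refinement
   program can be plugged in through the same contract), and take the
   per-atom SD over the ensemble as the coordinate error.
5. **shock_kinematics** — exact unit-rational conversions between delay,
   offset, jet speed, effective delay, equivalent repetition rate and
   shock travel distance d = v·Δt + Δx, plus an explicitly
   phenomenological power-law attenuation utility whose exponent the
   user must supply.

## The synthetic experiment (synthio)

Real detector images, refinement and indexing are out of scope, so all
inputs are generated with known ground truth. The generator's defaults
*are* the study conditions:

| parameter | default | why |
|---|---|---|
| jet diameter / speed | 5 um / 50 m/s | stated injector operating point |
| delay / offset | 122.5 ns / 5 um | stated pump-probe geometry |
| pump energy | 0.03 ± 0.02 mJ, truncated at 0 | stated mean; SD gives the observed "up to ~0.1 mJ" tail |
| probe energy | 0.87 ± 0.2 mJ, truncated at 0 | combined pulse energy ~0.9 mJ with a 0.03 mJ pump |
| energy anticorrelation | −0.7 | "strongly anti-correlated"; bivariate normal with redraw-truncation is the simplest controllable law |
| base / best resolution | 3.0 / 2.5 Å | single-pulse median per-image resolution; optics floor |
| signal coefficient | 0.5 Å/mJ | modest resolution gain with probe energy |
| damage coefficient | 12 Å/mJ | see calibration note below |
| hit probability (base) | 0.19 | single-pulse hit rate |
| hit-suppression energy | 0.08 mJ | P(crystal survives) = exp(−E_pump/0.08) reproduces the 19% → 13% hit-rate drop at the mean pump energy |
| indexing probability | 0.235 | observed 23–24% indexing rates |
| noisy-trace / leak / abnormal-jet fractions | 5% each | plausible contamination levels; large enough that the 3σ noise rule's ~0.1% false-positive floor does not dominate filter precision |
| image scale | 0.11 um/px | stated camera calibration |

Per-image true resolution follows the monotone phenomenology
`d_true = d_base − s·(E_probe − ⟨E_probe⟩) + c·E_pump`, floored at the
best resolution. No physical shock model is claimed; the form is the
simplest one under which the binned-resolution analysis, the
distribution-equalisation check and the null test (zero damage ⇒ equal
distributions in both modes) are all meaningful. Single-pulse shots draw
their probe energy from the same marginal law as pump-probe shots, so a
zero damage coefficient propagates to a null downstream effect exactly.

**Damage-coefficient calibration.** Shock-destroyed crystals leave the
hit pool, so surviving hits are biased toward low pump energies (median
~0.025 mJ rather than 0.03 mJ). The coefficient is therefore set to
12 Å/mJ so that the *observed* median resolution drop among surviving,
indexed hits is ~0.3 Å, the drop the experiment reports — 10 Å/mJ would
give ~0.25 Å once the selection effect is included.

**Stratified abnormal-jet planting.** Abnormal jets (over-wide,
pre-existing upstream gap, upstream break-up, no gaps) are planted at a
fixed per-run fraction, cycling the types, instead of i.i.d. This is a
deliberate generator choice: the width rule excludes shots more than one
SD from the run median, and for an uncontaminated Gaussian run that
excludes ~32% of perfectly normal shots. With guaranteed per-run
contamination the run SD is inflated by genuine outliers, normal jets
(2% natural width spread) sit well inside one SD, and the filter's
recall/precision on planted truth is meaningfully testable. Real runs
are messier; see limitations.

**What the generator does not emulate.** No diffraction physics (peak
lists are drawn from a parametric resolution/SNR law, not from a
structure), no detector geometry, no indexing ambiguity, no jet
hydrodynamics (gaps are drawn where the beams point; gap advection
between pump time and imaging time is folded into the planted
positions), no photon-energy drifts, and no refinement — the bootstrap
surrogate engine averages coordinate observations, so it validates the
resampling statistics, not crystallographic refinement behaviour.
Passing tests therefore demonstrate that the *analysis rules* are
implemented correctly and are well-behaved under controlled
contamination, not that they would perform identically on real LCLS
data.

## Numerical and convention choices

- **SD convention**: population SD (divisor n) in all filter rules, fixed
  for reproducibility. Threshold comparisons are strict: "larger than"
  excludes, so a value exactly at a threshold is kept.
- **Clean-trace population**: the noise rule references "noise-less
  traces", which is circular; the clean population is estimated by
  retaining per-shot noise SDs within 3 scaled MADs of their median
  before applying the mean + 3·SD rule. A zero-variance leakage
  population keeps every shot (no contrast to filter on).
- **Jet segmentation**: Otsu's threshold by default (parameter-free,
  deterministic), overridable. Minimum gap length 2 px suppresses
  single-row noise; presence runs shorter than 8 px downstream of the
  last long run are droplets, and droplet-region absences are not
  counted as gaps. Frame-edge absences are not gaps (a gap needs jet on
  both sides).
- **Upstream-continuity rule**: gaps upstream of the pump position fail
  the shot unless they match the probe position within a 3 um tolerance
  (the probe's own gap is expected upstream and "does not necessarily
  need to exist").
- **Resolution bins** are equal-volume in 1/d³ (stated in report
  headers); the automatic cutoff uses a first-crossing rule — the first
  bin whose mean I/σ(I) fails 1.0 terminates the walk even if later bins
  recover.
- **Wilson fit** uses equal-width bins in (1/2d)² restricted to
  d < 4.5 Å, avoiding the low-resolution non-Wilson regime; slope = −2B.
- **Merging** is unweighted; σ of a merged intensity is the sample SD of
  its observations over √multiplicity (undefined at multiplicity 1 and
  excluded from I/σ averages).
- **Superposition** uses proper rotations only (det = +1); mirror images
  are not superposable and report a large residual RMSD rather than a
  reflection.
- **Two-sigma check**: atoms are flagged when the reference lies more
  than 2 × the scalar per-atom SD from the bootstrap mean. The
  experiment labels 2σ "the 90% confidence level"; for a normal law 2σ
  is ≈95% per coordinate, and for a 3-D displacement norm the coverage
  differs again. The check implements 2σ literally and reports the
  fraction within, leaving the confidence-level interpretation to the
  caller.
- **Kinematics**: 1/(4.5 MHz) − (5 um)/(50 m/s) = 122.22 ns, whereas the
  experiment quotes 122.5 ns (consistent with a 222.5 ns effective
  spacing). The formula is implemented exactly; the 0.3 ns discrepancy
  is documented here rather than tuned away.
- **Randomness**: one master seed fans out through named substreams
  (energies, traces, jets, peaks, reflections, structures), so a stage's
  draws do not shift when another stage's parameters change, and
  identical seed + config gives bit-identical outputs.

## Problem sizes

Tests and the acceptance script run synthetic series of 2,000–10,000
shots (the experiment recorded ~480,000), 12–60 diffraction images per
merged data set at 2.5–4 Å resolution, bootstrap ensembles of 25–1,000
resamples over 10–200 coordinate observations, and a 574-residue
(141 + 146 + 141 + 146) four-chain Cα model standing in for the
haemoglobin tetramer. These sizes keep every statistic in its
well-behaved regime (≥ 20 shots per run for width statistics, ≥ 50 shots
for noise-population estimates, ~100+ indexed images per mode for median
resolutions) while the whole suite runs on one CPU in a couple of
minutes.

## Known limitations

- Filter recall/precision figures hold under the generator's stratified
  contamination; on real data the width rule excludes a substantial
  fraction of nominal shots by construction (1 SD ≈ 68% acceptance for a
  clean Gaussian run), as it did in the experiment.
- The deposited-model comparison (RMSD over 552 aligned residues between
  the single-pulse and pump-probe structures) requires the external PDB
  deposits; the corresponding test states what it needs and fails
  clearly when they are absent rather than silently passing.
- `attenuation_scale` is a labelled phenomenological utility; the
  package never asserts a physical attenuation exponent or pressure
  magnitude.
- The surrogate refine engine is linear, so bootstrap SDs converge to
  the closed-form σ/√m; a real refinement engine would add model bias
  the bootstrap cannot see.
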