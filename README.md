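# shockjet

Analysis toolkit for X-ray-pump/X-ray-probe serial femtosecond
crystallography (SFX) experiments that probe shockwave damage in liquid
microjets.

## The problem

At MHz-repetition-rate XFELs, each pulse vaporises a segment of the
sample-carrying microjet and launches a supersonic shockwave along the
jet. The shock intercepts microcrystals upstream before the next pulse
measures them, so data collected at high repetition rate can be
systematically damaged. A pump-probe experiment quantifies this: a pump
pulse hits the jet, and after a delay Δt a probe pulse — displaced Δx
upstream — records diffraction from shocked material. With Δt = 122.5 ns,
Δx = 5 µm and a 50 m/s jet, the effective spacing Δt + Δx/v = 222.5 ns
emulates 4.5 MHz operation.

`shockjet` implements the full analysis chain for such an experiment, for
beamline scientists and method developers:

- **`synthio`** — synthetic experiment generator with ground truth
  (anti-correlated pump/probe pulse energies, diode traces, jet snapshot
  images with explosion gaps, peak lists, reflection observations for an
  orthorhombic P2₁2₁2₁ cell, coordinate ensembles with planted
  displacement fields and compaction);
- **`jet_imaging`** — gap/width/break-up extraction from jet snapshots and
  jet-speed measurement, v = (y(t₁) − y(t₂))/(t₁ − t₂);
- **`shot_filtering`** — diode-noise, pump-leakage and jet-morphology
  acceptance rules; hit classification (≥ 10 peaks) and hit/indexing-rate
  accounting;
- **`diffraction_stats`** — per-image resolution (best d with
  I/σ(I) ≥ 4), probe-energy binning, and merged-data quality metrics:
  R<sub>split</sub> = 2^(−1/2)·Σ|I₁−I₂|/(½Σ(I₁+I₂)), CC<sub>1/2</sub>,
  CC* = √(2CC<sub>1/2</sub>/(1+CC<sub>1/2</sub>)), completeness with
  screw-axis absences, Wilson B, automatic resolution cutoff;
- **`structural_comparison`** — Cα pairing, Kabsch superposition and RMSD,
  displacement fields, distance-difference matrices
  D<sub>ij</sub> = d<sub>ij</sub>(B) − d<sub>ij</sub>(A), radius of
  gyration, and bootstrap coordinate-error estimation (resample the image
  pool with replacement, refine per resample, take the ensemble SD);
- **`shock_kinematics`** — delay/offset/speed ↔ effective delay,
  equivalent repetition rate, shock travel distance d = vΔt + Δx.

See `docs/methods.md` for the models, conventions and calibrations.

## Worked example

Kinematics of the pump-probe geometry:

```
$ shockjet kinematics --delay 122.5 --offset 5 --speed 50
{
  "effective_delay_ns": 222.5,
  "equivalent_rep_rate_mhz": 4.49438202247191,
  "shock_travel_distance_um": 11.125
}
```

The probed material lags the pump site by 222.5 ns (≈ 4.5 MHz pulse
spacing) and the shock travels 11.1 µm before reaching it.

Full synthetic pipeline (simulate → jet features → filter → statistics →
structural comparison → kinematics):

```
$ shockjet run-all --out demo --seed 1
```

From `demo/summary.json` (2000 shots at the default study conditions):

- counts: 2000 shots, 297 hits, 263 filtered hits, 59 indexed after
  filtering; pooled hit rates 12.4% (pump-probe) vs 20.5% (single-pulse)
  — the pump shock destroys a fraction of the crystals before probing;
- median per-image resolution 3.32 Å (pump-probe) vs 3.05 Å
  (single-pulse): a ~0.3 Å shock-induced resolution drop;
- merged-data metrics for the emulated single-pulse set:
  R<sub>split</sub> 5.3%, CC<sub>1/2</sub> 0.995, CC* 0.999,
  completeness 100%, Wilson B 47.5 Å² (planted 47.4);
- structural comparison of the unshocked vs shocked model pair: RMSD
  0.18 Å over 574 Cα pairs, mean displacement 0.17 Å, negative total
  relative distance change (net compaction — the shocked model is
  uniformly ~0.5% more compact plus a correlated displacement field).

Every number is traceable to a stage table written next to the summary
(`per_run_rates.tsv`, `resolution_bins_*.tsv`, `merged_bins_*.tsv`,
`shot_table.tsv`).

Library use mirrors the CLI:

```python
from shockjet import synthio, shot_filtering as sf
from shockjet.pipeline import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(sim=synthio.SimulationConfig(n_shots=2000, seed=1), seed=1))
print(report["resolution"]["median_resolution"])
```

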