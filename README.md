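# rigidsite

Analysis pipeline linking **active-site rigidity to enzyme activity** in
serine hydrolases, built around *Bacillus subtilis* lipase A (LipA) and
its thermostable 12-mutation variant "6B". The package implements the
two quantitative arms of that comparison:

1. **MD-trajectory post-analysis** — superposition-based flexibility
   metrics (RMSD time series, per-residue RMSF) and catalytic-triad
   *geometry-preservation* statistics: per-snapshot distances of the two
   triad hydrogen bonds (Ser77 Oγ···His156 Nε2 and His156 Nδ1···Asp133
   Oδ), their frequency distributions, and the RMSD of the seven
   catalytically important heavy atoms (Ser Oγ, both His imidazole N,
   both Asp carboxylate O, and the oxyanion-hole backbone N of Ile12 and
   Met78) to a transition-state-analog reference geometry.
2. **Time-resolved fluorescence** — TCSPC intensity and anisotropy decay
   analysis by IRF reconvolution. The intensity decay is the
   multiexponential

   I(t) = Σᵢ αᵢ exp(−t/τᵢ),  Σᵢ αᵢ = 1,  τ_m = Σᵢ αᵢτᵢ,

   and the anisotropy decay is biexponential,

   r(t) = r₀ [β_fast e^(−t/φ_fast) + β_slow e^(−t/φ_slow)],  β_fast+β_slow = 1,

   observed through the polarized channels
   I∥(t) = (I(t)/3)(1+2r(t)) and I⊥(t) = (I(t)/3)(1−r(t))/G, each
   convolved with the measured instrument response. The two channels are
   fitted **globally** under Poisson weighting; scalar summaries include
   the mean lifetime τ_m and the steady-state anisotropy

   r_ss = ∫r(t)I(t)dt / ∫I(t)dt = r₀ Σⱼ βⱼφⱼ/(φⱼ+τ_m)   (single effective lifetime).

A first-class **synthetic-data module** generates toy structures,
fluctuation and triad-distance trajectories, and Poisson photon-counting
decays with known ground truth, so every stage of the pipeline is
verifiable end to end without external data.

## Layout

* `src/rigidsite/` — the library: `structure_io` (PDB trajectories, atom
  selection, catalytic-atom resolution, frame windowing), `flexibility`
  (Kabsch superposition, RMSD/RMSF), `active_site` (triad distances,
  histograms, catalytic-atom RMSD, summaries), `tcspc` (reconvolution
  fitting), `synthetic_data` (generators), `refdata` (published
  parameter sets used as simulation ground truth), `pipeline`
  (config-driven end-to-end runs).
* `analysis/` — numbered narrative drivers:
  `01_simulate_datasets.py` (build the synthetic wild-type-like and
  6B-like datasets), `02_trajectory_and_fit_pipeline.py` (full pipeline
  per variant, tables under `results/`), `03_anisotropy_recovery.py`
  (seed-replicated parameter-recovery experiment).

## Worked example

```sh
python analysis/01_simulate_datasets.py
python analysis/02_trajectory_and_fit_pipeline.py
```

prints, per variant (numbers from an actual run, seed 7):

```
=== wt ===
  ser_his_distance: 6.82 +/- 1.18 A (n=597)
  his_asp_distance: 2.90 +/- 0.10 A (n=597)
  catalytic_rmsd: 1.41 +/- 0.39 A (n=597)
  phi_fast 0.20 ns (beta 0.47), phi_slow 9.34 ns (beta 0.53)
  r0 0.32, r_ss 0.13, tau_m 3.74 ns, chi2 1.06

=== 6b ===
  ser_his_distance: 4.71 +/- 0.61 A (n=597)
  his_asp_distance: 2.99 +/- 0.21 A (n=597)
  catalytic_rmsd: 0.70 +/- 0.20 A (n=597)
  phi_fast 1.27 ns (beta 0.04), phi_slow 8.39 ns (beta 0.96)
  r0 0.29, r_ss 0.21, tau_m 2.86 ns, chi2 0.84
```

Reading: the Ser–His hydrogen-bond distance of the 6B-like ensemble
(4.71 ± 0.61 Å) sits much closer to the catalytically competent crystal
geometry (2.7 Å) than the wild-type-like ensemble (6.82 ± 1.18 Å), and
its seven-atom catalytic RMSD to that reference is half as large — the
more rigid variant *preserves* the competent active-site geometry
better. On the fluorescence side the fitted r_ss rises from ≈0.13 (wild
type, large fast-depolarizing amplitude: a mobile probe) to ≈0.21 (6B,
slow tumbling dominates: a rigid site), with τ_m and χ² ≈ 1 echoing the
generating models.

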