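# Methods

## Scope and model

The package quantifies active-site rigidity of a Ser-His-Asp hydrolase
from two independent kinds of data:

* **Conformational ensembles** (MD-like trajectories over a fixed atom
  topology, coordinates in Å, timestamps in ps). Rigidity and geometry
  preservation are measured by (i) RMSD of a selection to a reference
  after optimal rigid-body superposition, (ii) per-residue RMSF about
  the window-mean structure, (iii) the heavy-atom distances of the two
  catalytic hydrogen bonds and their snapshot-frequency distributions,
  and (iv) the per-snapshot RMSD of the seven catalytic atoms to a
  transition-state-analog reference geometry.
* **TCSPC decays** (photon counts per uniform time channel, ns). The
  observed decay is the true decay convolved with the instrument
  response (IRF); fitting is by *reconvolution*: the model — a
  multiexponential intensity I(t) and, for polarized data, the pair
  I∥ = (I/3)(1+2r), I⊥ = (I/3)(1−r)/G with biexponential
  r(t) = r₀(β_f e^(−t/φ_f) + β_s e^(−t/φ_s)) — is convolved with the
  measured IRF and compared to the counts under Poisson weighting
  σ = √max(obs, 1). Parallel and perpendicular channels share all decay
  parameters and are fitted jointly (global fit).

Assumptions: uniform channel spacing shared by decays and IRF; photon
counts independent Poisson per channel; the anisotropy decay is not
lifetime-associated (r(t) multiplies the total I(t)); the G-factor is a
known constant (default 1; none was reported for the instrument
modelled here).

## Key parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| channel width | TCSPC bin (ps) | 8 | with 4096 channels spans 32.8 ns, comfortably > 3× the slowest φ ≈ 8.9 ns |
| n_channels | time channels | 4096 | as above |
| IRF FWHM | instrument response width (ps) | 40 | the modelled instrument's measured width |
| IRF t₀ | IRF centre | 25 channels | room for the fitted sub-channel time shift |
| peak counts | expected maximum of the reconstructed total intensity | 10,000 | the modelled acquisition target |
| fit window | channels used | from 1% of IRF peak to the last channel with counts ≥ background+1 | standard reconvolution practice |
| IRF shift | fitted time shift | ±5 channels, linear interpolation | corrects wavelength-dependent transit-time offsets |
| multi-start | φ_fast initialisations | geometric grid 0.05–5 ns, 5 starts | the fast/slow decomposition has well-known local minima |
| distance bins | histogram width (Å) | 0.1 (distances), 0.25 (RMSD) | resolves the narrow His-Asp distribution (SD 0.1 Å) |
| SD convention | population (÷n) | — | the snapshot series is the full population analysed |
| frame window | closed at both ends, exact stride multiples | — | three 0–20 ns runs at 1 ps then count 3 × 20,001 = 60,003 snapshots and the 2–20 ns window 3 × 18,001 = 54,003, the only convention consistent with both counts |

Catalytic-pair conventions: the Ser pair is Oγ···Nε2 (the proton-accepting
imidazole nitrogen) and the Asp pair Nδ1···carboxylate-O with the
*minimum* over the two chemically equivalent Oδ atoms; a min-over-both-
nitrogens policy is available since either imidazole nitrogen can be
meant by "the" His nitrogen. The catalytic-atom RMSD uses fit mode
"self" (superpose on the seven atoms themselves) by default — the
statistic is then pure internal active-site geometry — with a "global"
mode (fit on all shared Cα) provided.

## Synthetic data: what it emulates and what it does not

* **Fluctuation trajectories** draw i.i.d. Gaussian per-axis
  displacements about a reference with per-atom amplitude σ. They
  reproduce the *statistical* signature that RMSF measures (RMSF → σ√3
  for isotropic fluctuation) but contain no dynamics: no temporal
  correlation, no covariance between atoms, no force field, no solvent.
  Passing tests therefore validate the estimators, not any physics.
* **Triad-distance trajectories** place the Ser Oγ along the reference
  bond direction at a Gaussian-drawn distance from His Nε2 and shift the
  Asp carboxylate rigidly to a drawn Nδ1–Oδ1 distance (draws truncated
  above 0.5 Å by resampling, renormalizing the distribution). Distances
  are exact by construction; angular degrees of freedom do not vary.
* **TCSPC decays** are built with the same forward model the fitter
  uses, scaled so the reconstructed total intensity peaks at the target
  count, with independent Poisson noise per channel and a noise-off mode
  that reproduces the analytic expectation exactly. The common scale
  makes I∥ + 2I⊥ equal the magic-angle expectation channel-wise (G = 1),
  the textbook consistency relation. Real data would add a measured
  (noisy) IRF, background structure, pile-up and G ≠ 1, none of which
  are emulated.
* The **toy protein** is a helical Cα trace carrying the seven catalytic
  role atoms on its first five residues — plumbing for the geometry
  operators, with no structural realism claimed.

Because the fitter and generator share the forward model, recovery
tests are *forward/backward consistency* checks; the independent
evidence that the forward model itself is right comes from the
brute-force convolution oracles, the closed-form r_ss against numerical
integration, and the pre-convolution anisotropy reconstruction identity
(I∥ − G I⊥)/(I∥ + 2G I⊥) = r(t).

## Numerical choices

* Optimal rotations by SVD of the weighted covariance with determinant
  sign correction (always a proper rotation); configurations with a
  second singular value ≈ 0 (collinear points) are rejected rather than
  silently resolved.
* RMSF superposes frames onto the window-mean structure, iterated once
  (fit to first frame → mean → refit to mean). A fixed external
  reference can be supplied instead.
* Convolution by FFT (causal, unit-area IRF, ×Δt), equal to the direct
  double loop to ~1e-12; expectations are clipped at 0 before Poisson
  sampling to absorb FFT round-off.
* Histograms use left-closed right-open bins; the auto range
  [⌊min⌋, ⌈max⌉] grows by one bin if a value falls on the top edge, so
  counts always conserve the series length.
* Fits run bounded trust-region least squares (lmfit); intensity
  amplitudes are fitted in counts and normalized afterwards; anisotropy
  components are relabeled at output so φ_fast ≤ φ_slow. Reduced χ² is
  Σ((obs−exp)²/max(obs,1))/(N−p).
* All generators take explicit integer seeds; there is no global random
  state, and identical spec+seed is byte-identical.

## Design choices

* The published wild-type and 6B parameter sets (anisotropy columns,
  mean lifetimes, triad distance statistics, crystal distances) live in
  `refdata` and are used as *simulation ground truth*; nothing in the
  fitting path reads them.
* The steady-state anisotropy uses the full double-sum closed form when
  an intensity model is available and the single-effective-lifetime form
  r₀Σβⱼφⱼ/(φⱼ+τ_m) when only τ_m is known; benchmark comparisons use
  the τ_m form since only τ_m is tabulated for the modelled instrument.
* The pipeline is config-driven (YAML) and writes every table as TSV
  with a config-hash header; a re-run with the same config and seed is
  byte-identical. The library functions plus the `analysis/` drivers are
  the interface; no shell CLI is provided because the intended use is
  scripted analysis, not interactive tooling.
* Demo datasets use short runs (3 × 201 frames at 10 ps) — enough for
  summary statistics at ~0.05 Å precision — and the full 54,003-frame
  bookkeeping is exercised where the statistic itself is cheap
  (distance generation and summaries).

## Known limitations

* **6B fast-component identifiability.** At the modelled acquisition
  (single decay pair, ~10,000 peak counts, τ ≈ 2.87 ns intensity), the
  6B anisotropy model — (β 0.15, φ 4.04 ns) + (β 0.85, φ 8.91 ns) — is
  nearly indistinguishable from a single ≈7.7 ns component: the
  Poisson-weighted χ² separation on noiseless curves is ≈3 (computed by
  `analysis/03_anisotropy_recovery.py`), far below the noise floor.
  Individual fits therefore scatter between near-degenerate solutions
  (φ_fast → 0 with vanishing amplitude, or φ_fast → φ_slow), and the
  median recovered φ_fast is not a reliable estimate of 4.04 ns. The
  wild-type model (separation ≈2000) recovers tightly. Resolving the 6B
  decomposition would need substantially more photons or repeated
  measurements; the recovery experiment reports the scatter honestly
  rather than constraining the fit toward the known answer.
* Neyman weighting (σ² = max(obs,1)) is the field convention but is
  biased at very low counts; the fit window's tail criterion limits the
  damage but does not remove it.
* The trajectory readers handle multi-model PDB only; binary formats
  (XTC/DCD) are out of scope, as are hydrogen placement, hydrogen-bond
  angle criteria, PCA/normal modes and lifetime-distribution analyses.
* The deposited crystal structures of the real lipase are not bundled;
  the static-structure comparison is exercised on synthetic geometry
  constructed at the published distances, and accepts a residue-name
  override for the covalently modified catalytic serine when applied to
  a real transition-state-analog complex.
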