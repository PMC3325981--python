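#!/usr/bin/env python
"""Seed-replicated anisotropy parameter-recovery experiment.

Simulates polarized TCSPC decay pairs from the published wild-type and
6B anisotropy models (40 ps FWHM IRF, ~10,000 peak counts, Poisson
noise), refits each pair globally, and tabulates the recovered
correlation times against the generating truth, together with the
closed-form steady-state anisotropy of both parameter columns.

The wild-type fast component (0.21 ns, amplitude 0.47) recovers tightly.
The 6B fast component (4.04 ns, amplitude 0.15) is close to degenerate
with the 8.91 ns slow component at these photon counts: the expected
chi-square separation between the true two-component model and the best
single-component model is only ~3, so individual fits scatter between
near-degenerate solutions. The experiment reports that scatter honestly.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rigidsite import refdata as rd
from rigidsite import synthetic_data as sd
from rigidsite.tcspc import fit_anisotropy_global, steady_state_anisotropy

RESULTS = Path(__file__).resolve().parent.parent / "results"
N_SEEDS = 10


def identifiability_gap(aniso, tau_m, irf):
    """Expected chi-square separation between the true two-component
    anisotropy model and the best single-component model: the residual
    cost of a beta_fast = 0 fit to the *noiseless* forward curves."""
    intensity = rd.single_lifetime_model(tau_m)
    spec = sd.TcspcSimSpec(intensity_model=intensity,
                           anisotropy_model=aniso,
                           irf_fwhm_ps=rd.IRF_FWHM_PS,
                           peak_counts=rd.PEAK_COUNTS, seed=0)
    par, perp = sd.simulate_anisotropy_decays(spec, noise=False)
    fit = fit_anisotropy_global(par, perp, irf, intensity,
                                fixed={"beta_fast": 0.0}, n_starts=3)
    return float(np.sum(fit.residuals**2))


def main():
    RESULTS.mkdir(exist_ok=True)
    irf = sd.simulate_irf(rd.IRF_FWHM_PS)
    rows = []
    for variant, aniso, tau_m in (("wt", rd.WT_ANISOTROPY, rd.WT_TAU_M),
                                  ("6b", rd.B6_ANISOTROPY, rd.B6_TAU_M)):
        intensity = rd.single_lifetime_model(tau_m)
        for seed in range(N_SEEDS):
            spec = sd.TcspcSimSpec(intensity_model=intensity,
                                   anisotropy_model=aniso,
                                   irf_fwhm_ps=rd.IRF_FWHM_PS,
                                   peak_counts=rd.PEAK_COUNTS, seed=seed)
            par, perp = sd.simulate_anisotropy_decays(spec)
            fit = fit_anisotropy_global(par, perp, irf, intensity,
                                        n_starts=5)
            m = fit.model
            rows.append(dict(variant=variant, seed=seed,
                             phi_fast=m.phi_fast, beta_fast=m.beta_fast,
                             phi_slow=m.phi_slow, r0=m.r0,
                             chi2=fit.red_chi2))
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "anisotropy_recovery.tsv", sep="\t", index=False)

    print("closed-form steady-state anisotropy:")
    print(f"  wt: {steady_state_anisotropy(rd.WT_ANISOTROPY, rd.WT_TAU_M):.4f}"
          f"  (published 0.12)")
    print(f"  6b: {steady_state_anisotropy(rd.B6_ANISOTROPY, rd.B6_TAU_M):.4f}"
          f"  (published 0.21)")
    print(f"\nrecovery medians over {N_SEEDS} seeds:")
    for variant, aniso in (("wt", rd.WT_ANISOTROPY),
                           ("6b", rd.B6_ANISOTROPY)):
        g = df[df.variant == variant]
        print(f"  {variant}: phi_fast {g.phi_fast.median():.3f} ns "
              f"(truth {aniso.phi_fast}), "
              f"phi_slow {g.phi_slow.median():.2f} ns "
              f"(truth {aniso.phi_slow}), "
              f"IQR(phi_fast) {g.phi_fast.quantile(.25):.3f}-"
              f"{g.phi_fast.quantile(.75):.3f}")
    print("\nidentifiability: chi-square separation of the true "
          "two-component model\nfrom the best single-component model "
          "(noiseless curves, Poisson weights):")
    for variant, aniso, tau_m in (("wt", rd.WT_ANISOTROPY, rd.WT_TAU_M),
                                  ("6b", rd.B6_ANISOTROPY, rd.B6_TAU_M)):
        gap = identifiability_gap(aniso, tau_m, irf)
        print(f"  {variant}: delta chi2 = {gap:.1f}"
              + ("  (well below the noise floor: the fast component is"
                 " effectively unidentifiable at these counts)"
                 if gap < 10 else ""))
    print(f"\nfull table: {RESULTS / 'anisotropy_recovery.tsv'}")


if __name__ == "__main__":
    main()
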