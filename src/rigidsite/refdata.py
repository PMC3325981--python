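"""Published reference parameters for B. subtilis lipase (LipA).

Time-resolved fluorescence anisotropy parameters of acrylodan attached
at the catalytic serine (position 77) of the wild-type enzyme and of the
thermostable 12-mutation variant "6B", together with the active-site
distance statistics observed over molecular-dynamics ensembles and in
the transition-state-analog-bound crystal structure. These values serve
as ground truth for the synthetic-data generators and as the benchmark
the analysis pipeline is validated against.

phi values and mean lifetimes are in ns, distances in Angstrom.
"""

from .tcspc import AnisotropyModel, IntensityModel

# anisotropy decay r(t) = r0 (beta_f e^(-t/phi_f) + beta_s e^(-t/phi_s))
WT_ANISOTROPY = AnisotropyModel(
    r0=0.31, beta_fast=0.47, beta_slow=0.53, phi_fast=0.21, phi_slow=8.91
)
B6_ANISOTROPY = AnisotropyModel(
    r0=0.29, beta_fast=0.15, beta_slow=0.85, phi_fast=4.04, phi_slow=8.91
)

# mean fluorescence lifetimes from magic-angle measurements (ns)
WT_TAU_M = 3.75
B6_TAU_M = 2.87

# steady-state anisotropy estimated from the time-resolved decays
WT_R_SS = 0.12
B6_R_SS = 0.21


def single_lifetime_model(tau_m: float) -> IntensityModel:
    """Single-exponential intensity decay with the given mean lifetime."""
    return IntensityModel(alphas=[1.0], taus=[tau_m])


# active-site distance statistics over the MD ensembles (mean, SD; A)
WT_SER_HIS = (6.8, 1.1)
B6_SER_HIS = (4.7, 0.6)
WT_HIS_ASP = (2.9, 0.1)
B6_HIS_ASP = (3.0, 0.2)

# the same distances in the transition-state-analog-bound crystal (A)
CRYSTAL_SER_HIS = 2.7
CRYSTAL_HIS_ASP = 3.1

# TCSPC instrument characteristics
IRF_FWHM_PS = 40.0
PEAK_COUNTS = 10_000.0

# snapshot bookkeeping: three 20 ns runs sampled every 1 ps
N_RUNS = 3
RUN_LENGTH_PS = 20_000.0
SNAPSHOT_INTERVAL_PS = 1.0
EQUILIBRATION_PS = 2_000.0
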