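"""Time-resolved fluorescence analysis by IRF reconvolution.

Implements the standard TCSPC analysis chain for fluorescence intensity
and anisotropy decays:

* multiexponential intensity decay  I(t) = sum_i alpha_i exp(-t/tau_i),
  with sum_i alpha_i = 1 and mean lifetime tau_m = sum_i alpha_i tau_i;
* biexponential anisotropy decay
  r(t) = r0 * (beta_fast exp(-t/phi_fast) + beta_slow exp(-t/phi_slow)),
  beta_fast + beta_slow = 1, observed through the polarized channels
  I_par(t)  = (I(t)/3) (1 + 2 r(t)),
  I_perp(t) = (I(t)/3) (1 - r(t)) / G;
* reconvolution fitting: the model is convolved with the measured
  instrument response function (IRF) and compared to the observed photon
  counts under Poisson weighting, rather than deconvolving the data.

Fits are bounded nonlinear least squares (lmfit/scipy trust-region
reflective) with an optional multi-start over the fast correlation time
to avoid the well-known fast/slow local-minimum problem.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit
from scipy.signal import fftconvolve

__all__ = [
    "DecayHistogram",
    "IntensityModel",
    "AnisotropyModel",
    "FitResult",
    "read_decay_tsv",
    "write_decay_tsv",
    "convolve_irf",
    "multiexponential",
    "anisotropy_decay",
    "polarized_components",
    "mean_lifetime",
    "steady_state_anisotropy",
    "reduced_chi_square",
    "default_fit_window",
    "fit_intensity_decay",
    "fit_anisotropy_global",
]


# --------------------------------------------------------------------------
# containers


@dataclass
class DecayHistogram:
    """A binned photon-arrival histogram on a uniform time axis.

    times_ns : channel centre times in ns, uniformly spaced.
    counts   : photon counts (or expected counts / density for an IRF) per
               channel, non-negative.
    label    : one of "parallel", "perpendicular", "magic", "irf".
    """

    times_ns: np.ndarray
    counts: np.ndarray
    label: str = "magic"

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.times_ns.ndim != 1 or self.times_ns.size < 2:
            raise ValueError("decay histogram needs >= 2 channels")
        if self.counts.shape != self.times_ns.shape:
            raise ValueError("times and counts must have equal length")
        dt = np.diff(self.times_ns)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("channel times must be uniformly spaced")
        if dt[0] <= 0:
            raise ValueError("channel times must be increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def channel_width_ns(self) -> float:
        return float(self.times_ns[1] - self.times_ns[0])

    @property
    def n_channels(self) -> int:
        return self.times_ns.size


def write_decay_tsv(decay: DecayHistogram, path) -> None:
    """Write a decay as 2-column TSV (time_ns, counts) with a header line."""
    with open(path, "w") as fh:
        fh.write(f"# channel={decay.label}\ttime_ns\tcounts\n")
        for t, c in zip(decay.times_ns, decay.counts):
            fh.write(f"{t:.6f}\t{c:.6f}\n")


def read_decay_tsv(path) -> DecayHistogram:
    label = "magic"
    times, counts = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("channel="):
                        label = tok.split("=", 1)[1]
                continue
            t, c = line.split("\t")[:2]
            times.append(float(t))
            counts.append(float(c))
    return DecayHistogram(np.array(times), np.array(counts), label=label)


@dataclass
class IntensityModel:
    """Multiexponential fluorescence intensity decay parameters.

    alphas sum to 1; taus in ns; scale is the t=0 amplitude in counts;
    background in counts/channel; shift_ns is the fitted IRF time shift.
    """

    alphas: np.ndarray
    taus: np.ndarray
    scale: float = 1.0
    background: float = 0.0
    shift_ns: float = 0.0

    def __post_init__(self) -> None:
        self.alphas = np.atleast_1d(np.asarray(self.alphas, dtype=float))
        self.taus = np.atleast_1d(np.asarray(self.taus, dtype=float))
        if self.alphas.size == 0 or self.alphas.size != self.taus.size:
            raise ValueError("alphas and taus must be non-empty, equal length")
        if np.any(self.taus <= 0):
            raise ValueError("lifetimes must be positive")
        if np.any(self.alphas < 0):
            raise ValueError("amplitudes must be non-negative")
        total = self.alphas.sum()
        if total <= 0:
            raise ValueError("at least one amplitude must be positive")
        if abs(total - 1.0) > 1e-9:
            raise ValueError("amplitudes must sum to 1")


@dataclass
class AnisotropyModel:
    """Biexponential anisotropy decay parameters (r0, beta, phi in ns)."""

    r0: float
    beta_fast: float
    beta_slow: float
    phi_fast: float
    phi_slow: float
    g_factor: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.r0 <= 0.4):
            raise ValueError("r0 must lie in [0, 0.4]")
        if self.phi_fast <= 0 or self.phi_slow <= 0:
            raise ValueError("rotational correlation times must be positive")
        if self.beta_fast < 0 or self.beta_slow < 0:
            raise ValueError("beta amplitudes must be non-negative")
        if abs(self.beta_fast + self.beta_slow - 1.0) > 1e-9:
            raise ValueError("beta_fast + beta_slow must equal 1")
        if self.g_factor <= 0:
            raise ValueError("G-factor must be positive")


@dataclass
class FitResult:
    """Outcome of a reconvolution fit."""

    model: object
    stderr: dict = field(default_factory=dict)
    red_chi2: float = np.nan
    n_iter: int = 0
    converged: bool = False
    residuals: np.ndarray | None = None
    window: np.ndarray | None = None


# --------------------------------------------------------------------------
# forward model


def multiexponential(t: np.ndarray, alphas, taus) -> np.ndarray:
    """sum_i alpha_i exp(-t/tau_i), zero for t < 0."""
    t = np.asarray(t, dtype=float)
    alphas = np.atleast_1d(np.asarray(alphas, dtype=float))
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    out = np.zeros_like(t)
    pos = t >= 0
    for a, tau in zip(alphas, taus):
        out[pos] += a * np.exp(-t[pos] / tau)
    return out


def anisotropy_decay(t: np.ndarray, model: AnisotropyModel) -> np.ndarray:
    """r(t) = r0 (beta_fast e^(-t/phi_fast) + beta_slow e^(-t/phi_slow))."""
    t = np.asarray(t, dtype=float)
    return model.r0 * (
        model.beta_fast * np.exp(-np.clip(t, 0, None) / model.phi_fast)
        + model.beta_slow * np.exp(-np.clip(t, 0, None) / model.phi_slow)
    )


def polarized_components(
    t: np.ndarray, intensity: np.ndarray, aniso: AnisotropyModel
) -> tuple[np.ndarray, np.ndarray]:
    """Pre-convolution parallel/perpendicular curves from I(t) and r(t).

    Convention: I_par = (I/3)(1+2r); I_perp = (I/3)(1-r)/G. With G = 1,
    I_par + 2 I_perp == I channel-wise.
    """
    r = anisotropy_decay(t, aniso)
    par = intensity / 3.0 * (1.0 + 2.0 * r)
    perp = intensity / 3.0 * (1.0 - r) / aniso.g_factor
    return par, perp


def _normalized_irf(irf: DecayHistogram) -> np.ndarray:
    area = irf.counts.sum() * irf.channel_width_ns
    if area <= 0:
        raise ValueError("IRF has zero area")
    return irf.counts / area


def convolve_irf(model_curve, irf: DecayHistogram) -> np.ndarray:
    """Discrete causal convolution of a model curve with the unit-area IRF.

    expected[k] = sum_{j<=k} irf_norm[j] * model[k-j] * dt. The model curve
    must be sampled on the IRF's time axis.
    """
    if isinstance(model_curve, DecayHistogram):
        if model_curve.n_channels != irf.n_channels or not np.allclose(
            model_curve.times_ns, irf.times_ns, rtol=1e-9, atol=1e-9
        ):
            raise ValueError("model and IRF must share one time axis")
        model_curve = model_curve.counts
    model_curve = np.asarray(model_curve, dtype=float)
    if model_curve.shape != irf.times_ns.shape:
        raise ValueError("model and IRF must share one time axis")
    irf_norm = _normalized_irf(irf)
    n = model_curve.size
    return fftconvolve(irf_norm, model_curve)[:n] * irf.channel_width_ns


def _shifted_irf(irf: DecayHistogram, shift_ns: float) -> DecayHistogram:
    """IRF displaced by a sub-channel time shift (linear interpolation)."""
    if shift_ns == 0.0:
        return irf
    shifted = np.interp(
        irf.times_ns - shift_ns, irf.times_ns, irf.counts, left=0.0, right=0.0
    )
    return DecayHistogram(irf.times_ns, np.clip(shifted, 0.0, None), label="irf")


# --------------------------------------------------------------------------
# scalar summaries


def mean_lifetime(model: IntensityModel) -> float:
    """Amplitude-weighted mean lifetime tau_m = sum_i alpha_i tau_i (ns)."""
    return float(np.dot(model.alphas, model.taus))


def steady_state_anisotropy(aniso: AnisotropyModel, intensity) -> float:
    """Steady-state anisotropy r_ss = Int r(t) I(t) dt / Int I(t) dt.

    With a full intensity model the closed form is
        r0 * sum_ij alpha_i beta_j tau_i phi_j / (tau_i + phi_j)
           / sum_i alpha_i tau_i.
    If only a mean lifetime tau_m is supplied (a single effective
    lifetime), this collapses to r0 * sum_j beta_j phi_j / (phi_j + tau_m).
    """
    betas = np.array([aniso.beta_fast, aniso.beta_slow])
    phis = np.array([aniso.phi_fast, aniso.phi_slow])
    if isinstance(intensity, IntensityModel):
        num = 0.0
        for a, tau in zip(intensity.alphas, intensity.taus):
            num += a * np.sum(betas * tau * phis / (tau + phis))
        return float(aniso.r0 * num / mean_lifetime(intensity))
    tau_m = float(intensity)
    if tau_m <= 0:
        raise ValueError("mean lifetime must be positive")
    return float(aniso.r0 * np.sum(betas * phis / (phis + tau_m)))


def reduced_chi_square(observed, expected, n_free_params: int) -> float:
    """Poisson-weighted reduced chi^2:
    sum((obs-exp)^2 / max(obs, 1)) / (n_channels - n_free_params)."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must have equal length")
    dof = observed.size - n_free_params
    if dof <= 0:
        raise ValueError("degrees of freedom must be positive")
    w = np.maximum(observed, 1.0)
    return float(np.sum((observed - expected) ** 2 / w) / dof)


# --------------------------------------------------------------------------
# fitting


def default_fit_window(
    decay: DecayHistogram,
    irf: DecayHistogram,
    irf_threshold: float = 0.01,
    tail_margin: float = 1.0,
) -> np.ndarray:
    """Boolean channel mask: from the channel where the IRF first reaches
    irf_threshold x its peak, to the last channel with counts >=
    (estimated background + tail_margin)."""
    peak = irf.counts.max()
    above = np.nonzero(irf.counts >= irf_threshold * peak)[0]
    start = int(above[0]) if above.size else 0
    bg = float(np.median(decay.counts[:start])) if start > 2 else 0.0
    tail = np.nonzero(decay.counts >= bg + tail_margin)[0]
    end = int(tail[-1]) if tail.size else decay.n_channels - 1
    mask = np.zeros(decay.n_channels, dtype=bool)
    mask[start : end + 1] = True
    return mask


def _poisson_sigma(counts: np.ndarray) -> np.ndarray:
    return np.sqrt(np.maximum(counts, 1.0))


def _intensity_expected(t, irf, amps, taus, bg, shift):
    curve = multiexponential(t, amps, taus)
    return convolve_irf(curve, _shifted_irf(irf, shift)) + bg


def fit_intensity_decay(
    decay: DecayHistogram,
    irf: DecayHistogram,
    n_components: int = 2,
    init: dict | None = None,
    fixed: dict | None = None,
    fit_window: np.ndarray | None = None,
    max_shift_channels: float = 5.0,
) -> FitResult:
    """Reconvolution fit of a multiexponential intensity decay.

    Free parameters: per-component amplitudes (counts) and lifetimes (ns),
    background (counts/channel) and a sub-channel IRF time shift. Residuals
    are (observed - expected)/sigma with sigma = sqrt(max(observed, 1)).
    The returned IntensityModel carries normalized alphas and the total
    t=0 amplitude as `scale`; components are sorted by lifetime.
    """
    if not 1 <= n_components <= 4:
        raise ValueError("n_components must be in 1..4")
    if decay.n_channels != irf.n_channels or not np.allclose(
        decay.times_ns, irf.times_ns, rtol=1e-9, atol=1e-9
    ):
        raise ValueError("decay and IRF must share one time axis")
    t = decay.times_ns
    dt = decay.channel_width_ns
    if fit_window is None:
        fit_window = default_fit_window(decay, irf)
    obs = decay.counts
    sigma = _poisson_sigma(obs)
    init = dict(init or {})
    fixed = dict(fixed or {})

    peak = float(obs.max())
    span = t[-1] - t[0]
    params = lmfit.Parameters()
    # geometric spread of initial lifetimes over the observation window
    tau_inits = np.geomspace(span / 50.0, span / 3.0, n_components)
    for i in range(n_components):
        params.add(
            f"amp{i}", value=init.get(f"amp{i}", peak / n_components),
            min=0.0, max=1e12,
        )
        params.add(
            f"tau{i}", value=init.get(f"tau{i}", tau_inits[i]),
            min=1e-4, max=1e4,
        )
    params.add("background", value=init.get("background", 0.0), min=0.0,
               max=max(10.0 * peak, 1.0))
    params.add("shift", value=init.get("shift", 0.0),
               min=-max_shift_channels * dt, max=max_shift_channels * dt)
    for name, value in fixed.items():
        params[name].set(value=value, vary=False)

    def residual(p):
        amps = np.array([p[f"amp{i}"].value for i in range(n_components)])
        taus = np.array([p[f"tau{i}"].value for i in range(n_components)])
        exp = _intensity_expected(t, irf, amps, taus, p["background"].value,
                                  p["shift"].value)
        return ((obs - exp) / sigma)[fit_window]

    minimizer = lmfit.Minimizer(residual, params)
    out = minimizer.minimize(method="least_squares")

    amps = np.array([out.params[f"amp{i}"].value for i in range(n_components)])
    taus = np.array([out.params[f"tau{i}"].value for i in range(n_components)])
    order = np.argsort(taus)
    amps, taus = amps[order], taus[order]
    total = amps.sum()
    model = IntensityModel(
        alphas=amps / total,
        taus=taus,
        scale=total,
        background=out.params["background"].value,
        shift_ns=out.params["shift"].value,
    )
    stderr = {k: (v.stderr if v.stderr is not None else np.nan)
              for k, v in out.params.items()}
    n_free = out.nvarys
    exp_final = _intensity_expected(t, irf, amps, taus, model.background,
                                    model.shift_ns)
    red = reduced_chi_square(obs[fit_window], exp_final[fit_window], n_free)
    return FitResult(
        model=model, stderr=stderr, red_chi2=red, n_iter=out.nfev,
        converged=bool(out.success), residuals=out.residual,
        window=fit_window,
    )


def _anisotropy_expected(t, irf, intensity_shape_alphas, intensity_taus,
                         r0, beta_fast, phi_fast, phi_slow, g,
                         s_par, s_perp, bg_par, bg_perp, shift):
    aniso = AnisotropyModel(
        r0=r0, beta_fast=beta_fast, beta_slow=1.0 - beta_fast,
        phi_fast=phi_fast, phi_slow=phi_slow, g_factor=g,
    )
    intensity = multiexponential(t, intensity_shape_alphas, intensity_taus)
    par, perp = polarized_components(t, intensity, aniso)
    irf_s = _shifted_irf(irf, shift)
    exp_par = s_par * convolve_irf(par, irf_s) + bg_par
    exp_perp = s_perp * convolve_irf(perp, irf_s) + bg_perp
    return exp_par, exp_perp


def fit_anisotropy_global(
    parallel: DecayHistogram,
    perpendicular: DecayHistogram,
    irf: DecayHistogram,
    intensity_model: IntensityModel,
    init: dict | None = None,
    fixed: dict | None = None,
    g_factor: float = 1.0,
    n_starts: int = 5,
    fit_window: np.ndarray | None = None,
    max_shift_channels: float = 5.0,
) -> FitResult:
    """Global reconvolution fit of the polarized decay pair.

    The parallel and perpendicular channels are fitted jointly against
    I_par and I_perp built from the biexponential r(t), each convolved with
    the IRF, under Poisson weighting. The intensity decay shape (alphas,
    taus) comes from the magic-angle fit and is held fixed. Free: r0,
    beta_fast (beta_slow = 1 - beta_fast), phi_fast, phi_slow, per-channel
    scale and background, and a shared IRF shift. The G-factor is fixed
    from configuration. A multi-start over phi_fast initial values guards
    against the fast/slow local-minimum problem; components are relabeled
    at output so that phi_fast <= phi_slow.
    """
    for d in (parallel, perpendicular):
        if d.n_channels != irf.n_channels or not np.allclose(
            d.times_ns, irf.times_ns, rtol=1e-9, atol=1e-9
        ):
            raise ValueError("both channels and the IRF must share one axis")
    t = irf.times_ns
    dt = irf.channel_width_ns
    if fit_window is None:
        fit_window = default_fit_window(parallel, irf)
    obs_par, obs_perp = parallel.counts, perpendicular.counts
    sig_par, sig_perp = _poisson_sigma(obs_par), _poisson_sigma(obs_perp)
    init = dict(init or {})
    fixed = dict(fixed or {})
    shape_alphas = intensity_model.alphas
    shape_taus = intensity_model.taus

    peak_par = float(obs_par.max())
    base = lmfit.Parameters()
    base.add("r0", value=init.get("r0", 0.3), min=0.0, max=0.4)
    base.add("beta_fast", value=init.get("beta_fast", 0.5), min=0.0, max=1.0)
    base.add("phi_fast", value=init.get("phi_fast", 0.5), min=1e-3, max=1e3)
    base.add("phi_slow", value=init.get("phi_slow", 10.0), min=1e-3, max=1e3)
    base.add("s_par", value=init.get("s_par", 3.0 * peak_par), min=1e-6,
             max=1e12)
    base.add("s_perp", value=init.get("s_perp", 3.0 * peak_par), min=1e-6,
             max=1e12)
    base.add("bg_par", value=init.get("bg_par", 0.0), min=0.0,
             max=max(10.0 * peak_par, 1.0))
    base.add("bg_perp", value=init.get("bg_perp", 0.0), min=0.0,
             max=max(10.0 * peak_par, 1.0))
    base.add("shift", value=init.get("shift", 0.0),
             min=-max_shift_channels * dt, max=max_shift_channels * dt)
    for name, value in fixed.items():
        base[name].set(value=value, vary=False)

    def residual(p):
        exp_par, exp_perp = _anisotropy_expected(
            t, irf, shape_alphas, shape_taus,
            p["r0"].value, p["beta_fast"].value,
            p["phi_fast"].value, p["phi_slow"].value, g_factor,
            p["s_par"].value, p["s_perp"].value,
            p["bg_par"].value, p["bg_perp"].value, p["shift"].value,
        )
        return np.concatenate([
            ((obs_par - exp_par) / sig_par)[fit_window],
            ((obs_perp - exp_perp) / sig_perp)[fit_window],
        ])

    phi_fast_grid = np.geomspace(0.05, 5.0, max(1, n_starts))
    if "phi_fast" in init:
        phi_fast_grid = np.concatenate([[init["phi_fast"]], phi_fast_grid])
    best = None
    for phi0 in phi_fast_grid:
        params = base.copy()
        if params["phi_fast"].vary:
            params["phi_fast"].set(value=float(phi0))
        out = lmfit.Minimizer(residual, params).minimize(
            method="least_squares")
        cost = float(np.sum(out.residual**2))
        if best is None or cost < best[0]:
            best = (cost, out)
    out = best[1]

    r0 = out.params["r0"].value
    beta_fast = out.params["beta_fast"].value
    phi_fast = out.params["phi_fast"].value
    phi_slow = out.params["phi_slow"].value
    if phi_fast > phi_slow:  # relabel so phi_fast <= phi_slow
        phi_fast, phi_slow = phi_slow, phi_fast
        beta_fast = 1.0 - beta_fast
    model = AnisotropyModel(
        r0=r0, beta_fast=beta_fast, beta_slow=1.0 - beta_fast,
        phi_fast=phi_fast, phi_slow=phi_slow, g_factor=g_factor,
    )
    stderr = {k: (v.stderr if v.stderr is not None else np.nan)
              for k, v in out.params.items()}
    red = float(np.sum(out.residual**2)) / (out.residual.size - out.nvarys)
    if not out.success:
        warnings.warn("anisotropy fit did not converge; partial result")
    return FitResult(
        model=model, stderr=stderr, red_chi2=red, n_iter=out.nfev,
        converged=bool(out.success), residuals=out.residual,
        window=fit_window,
    )
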