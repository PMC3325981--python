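"""Ground-truth-known synthetic inputs for every analysis stage.

Generators for

* a toy single-chain protein carrying the seven catalytic role atoms of
  a Ser-His-Asp hydrolase;
* fluctuation trajectories (i.i.d. Gaussian per-axis displacements about
  a reference, a statistical stand-in for conformational fluctuation —
  no force field, no dynamics);
* triad-distance trajectories whose Ser-His and His-Asp pair distances
  are prescribed Gaussian draws, emulating the distance distributions an
  MD ensemble produces;
* TCSPC photon-counting decays: a Gaussian IRF, multiexponential
  intensity decays and polarized anisotropy decay pairs built with the
  analysis module's own forward model, scaled to a target peak count,
  with independent Poisson noise per channel (noise-off mode reproduces
  the analytic expectation exactly).

All randomness is driven by explicit seeds; identical spec + seed gives
identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import Structure, Trajectory, structure_from_arrays
from .tcspc import (
    AnisotropyModel,
    DecayHistogram,
    IntensityModel,
    convolve_irf,
    multiexponential,
    polarized_components,
)

__all__ = [
    "FluctuationSpec",
    "TriadDistanceSpec",
    "TcspcSimSpec",
    "TOY_RESIDUE_MAP",
    "simulate_irf",
    "measure_fwhm",
    "simulate_intensity_decay",
    "simulate_anisotropy_decays",
    "generate_toy_protein",
    "generate_fluctuation_trajectory",
    "generate_triad_trajectory",
]


# --------------------------------------------------------------------------
# specs


@dataclass
class FluctuationSpec:
    """Per-atom Gaussian fluctuation amplitudes (per-axis SD, Angstrom)."""

    per_atom_sigma: np.ndarray
    n_frames: int
    dt_ps: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.per_atom_sigma = np.asarray(self.per_atom_sigma, dtype=float)
        if np.any(self.per_atom_sigma < 0):
            raise ValueError("sigmas must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.dt_ps <= 0:
            raise ValueError("dt must be positive")


@dataclass
class TriadDistanceSpec:
    """Gaussian parameters for the two triad pair distances (Angstrom)."""

    ser_his_mean: float
    ser_his_sd: float
    his_asp_mean: float
    his_asp_sd: float
    n_frames: int
    dt_ps: float = 1.0
    seed: int = 0
    truncation: float = 0.5  # resample draws at or below this distance

    def __post_init__(self) -> None:
        if self.ser_his_mean <= 0 or self.his_asp_mean <= 0:
            raise ValueError("distance means must be positive")
        if self.ser_his_sd < 0 or self.his_asp_sd < 0:
            raise ValueError("distance SDs must be non-negative")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.truncation < 0:
            raise ValueError("truncation bound must be non-negative")


@dataclass
class TcspcSimSpec:
    """Everything needed to simulate one TCSPC measurement set."""

    intensity_model: IntensityModel
    anisotropy_model: AnisotropyModel | None = None
    irf_fwhm_ps: float = 40.0
    channel_width_ps: float = 8.0
    n_channels: int = 4096
    peak_counts: float = 10_000.0
    background: float = 0.0
    g_factor: float = 1.0
    irf_t0_ps: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.intensity_model is None:
            raise ValueError("an intensity model is required")
        if self.irf_fwhm_ps <= 0:
            raise ValueError("IRF FWHM must be positive")
        if self.channel_width_ps <= 0:
            raise ValueError("channel width must be positive")
        if self.n_channels < 2:
            raise ValueError("need at least 2 channels")
        if self.peak_counts <= 0:
            raise ValueError("peak counts must be positive")
        if self.background < 0:
            raise ValueError("background must be non-negative")
        if self.g_factor <= 0:
            raise ValueError("G-factor must be positive")


# --------------------------------------------------------------------------
# TCSPC generators


def simulate_irf(fwhm_ps: float, channel_width_ps: float = 8.0,
                 n_channels: int = 4096,
                 t0_ps: float | None = None) -> DecayHistogram:
    """Gaussian instrument response, area-normalized to 1 on its axis.

    t0 defaults to 25 channels into the window (room for the fitted IRF
    time shift); sigma = FWHM / (2 sqrt(2 ln 2)).
    """
    if fwhm_ps <= 0 or channel_width_ps <= 0:
        raise ValueError("FWHM and channel width must be positive")
    if n_channels < 2:
        raise ValueError("need at least 2 channels")
    dt_ns = channel_width_ps / 1000.0
    t = dt_ns * np.arange(n_channels)
    if t0_ps is None:
        t0_ps = 25.0 * channel_width_ps
    t0_ns = t0_ps / 1000.0
    if not (t[0] <= t0_ns <= t[-1]):
        raise ValueError("IRF centre t0 must lie on the time axis")
    sigma_ns = fwhm_ps / 1000.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    density = np.exp(-0.5 * ((t - t0_ns) / sigma_ns) ** 2)
    density /= density.sum() * dt_ns
    return DecayHistogram(t, density, label="irf")


def measure_fwhm(curve: DecayHistogram) -> float:
    """Full width at half maximum of a unimodal curve, by linear
    interpolation of the half-maximum crossings (same units as the axis)."""
    y = curve.counts
    t = curve.times_ns
    peak = int(np.argmax(y))
    half = y[peak] / 2.0
    left = peak
    while left > 0 and y[left] > half:
        left -= 1
    right = peak
    while right < y.size - 1 and y[right] > half:
        right += 1
    if y[left] > half or y[right] > half:
        # half-maximum not bracketed: narrower than the binning resolves
        return float(t[right] - t[left])
    tl = np.interp(half, [y[left], y[left + 1]], [t[left], t[left + 1]])
    tr = np.interp(half, [y[right], y[right - 1]], [t[right], t[right - 1]])
    return float(tr - tl)


def _spec_irf(spec: TcspcSimSpec) -> DecayHistogram:
    return simulate_irf(spec.irf_fwhm_ps, spec.channel_width_ps,
                        spec.n_channels, spec.irf_t0_ps)


def simulate_intensity_decay(spec: TcspcSimSpec,
                             noise: bool = True) -> DecayHistogram:
    """Magic-angle intensity decay: model convolved with the IRF, scaled
    so the expected maximum hits the peak-count target, plus a constant
    background, with independent Poisson counts per channel."""
    irf = _spec_irf(spec)
    t = irf.times_ns
    model = multiexponential(t, spec.intensity_model.alphas,
                             spec.intensity_model.taus)
    conv = np.clip(convolve_irf(model, irf), 0.0, None)
    scale = (spec.peak_counts - spec.background) / conv.max()
    expected = scale * conv + spec.background
    if not noise:
        return DecayHistogram(t, expected, label="magic")
    rng = np.random.default_rng(spec.seed)
    counts = rng.poisson(expected).astype(float)
    return DecayHistogram(t, counts, label="magic")


def simulate_anisotropy_decays(spec: TcspcSimSpec, noise: bool = True):
    """Polarized decay pair (parallel, perpendicular).

    Expected curves are (I/3)(1+2r) and (I/3)(1-r)/G convolved with the
    IRF, scaled with the *common* factor that brings the reconstructed
    total intensity (parallel + 2 G perpendicular) to the peak-count
    target — so with G = 1 and noise off, parallel + 2 perpendicular
    reproduces the magic-angle expectation channel by channel.
    """
    if spec.anisotropy_model is None:
        raise ValueError("spec carries no anisotropy model")
    aniso = spec.anisotropy_model
    if aniso.g_factor != spec.g_factor:
        aniso = AnisotropyModel(
            r0=aniso.r0, beta_fast=aniso.beta_fast, beta_slow=aniso.beta_slow,
            phi_fast=aniso.phi_fast, phi_slow=aniso.phi_slow,
            g_factor=spec.g_factor,
        )
    irf = _spec_irf(spec)
    t = irf.times_ns
    intensity = multiexponential(t, spec.intensity_model.alphas,
                                 spec.intensity_model.taus)
    par, perp = polarized_components(t, intensity, aniso)
    conv_total = convolve_irf(intensity, irf)
    scale = (spec.peak_counts - spec.background) / conv_total.max()
    exp_par = scale * np.clip(convolve_irf(par, irf), 0.0, None) \
        + spec.background
    exp_perp = scale * np.clip(convolve_irf(perp, irf), 0.0, None) \
        + spec.background
    if not noise:
        return (DecayHistogram(t, exp_par, label="parallel"),
                DecayHistogram(t, exp_perp, label="perpendicular"))
    rng = np.random.default_rng(spec.seed)
    par_counts = rng.poisson(exp_par).astype(float)
    perp_counts = rng.poisson(exp_perp).astype(float)
    return (DecayHistogram(t, par_counts, label="parallel"),
            DecayHistogram(t, perp_counts, label="perpendicular"))


# --------------------------------------------------------------------------
# toy structures and trajectories


# residue numbering of the catalytic machinery in the toy protein
TOY_RESIDUE_MAP = {"OXY1": 1, "OXY2": 2, "SER": 3, "ASP": 4, "HIS": 5}

_TOY_RES_NAMES = {1: "ILE", 2: "MET", 3: "SER", 4: "ASP", 5: "HIS"}


def generate_toy_protein(n_residues: int, seed: int = 0) -> Structure:
    """A single-chain toy protein hosting the 7 catalytic role atoms.

    One C-alpha per residue on a helical curve, plus: backbone N on
    residues 1 and 2 (oxyanion hole), OG on the serine (residue 3),
    OD1/OD2 on the aspartate (residue 4, OD1 nearer the histidine) and
    ND1/NE2 on the histidine (residue 5). Deterministic per seed; all
    atoms clash-free.
    """
    if n_residues < 5:
        raise ValueError("need at least 5 residues for the catalytic set")
    rng = np.random.default_rng(seed)
    theta = np.deg2rad(100.0) * np.arange(n_residues)
    ca = np.column_stack([
        1.5 * np.arange(n_residues),
        2.3 * np.cos(theta),
        2.3 * np.sin(theta),
    ])
    radial = np.column_stack([
        np.zeros(n_residues), np.cos(theta), np.sin(theta)
    ])

    coords, names, res_names, res_ids = [], [], [], []
    role_tags: dict = {}

    def add(pos, name, res_id, role=None):
        if role is not None:
            role_tags[role] = len(coords)
        coords.append(pos)
        names.append(name)
        res_ids.append(res_id)
        res_names.append(_TOY_RES_NAMES.get(res_id, "GLY"))

    his_nd1 = ca[4] + 2.0 * radial[4]
    his_ne2 = his_nd1 + np.array([2.1, 0.4, 0.0])
    asp_od1 = ca[3] + 2.1 * radial[3]
    u_od = asp_od1 - his_nd1
    u_od /= np.linalg.norm(u_od)
    asp_od2 = asp_od1 + 2.2 * u_od  # strictly farther from His ND1

    for i in range(n_residues):
        res_id = i + 1
        if res_id in (1, 2):
            add(ca[i] - 1.45 * radial[i], "N", res_id,
                role="OXY_N1" if res_id == 1 else "OXY_N2")
        add(ca[i], "CA", res_id)
        if res_id == 3:
            add(ca[i] + 2.4 * radial[i], "OG", res_id, role="SER_OG")
        elif res_id == 4:
            add(asp_od1, "OD1", res_id, role="ASP_OD1")
            add(asp_od2, "OD2", res_id, role="ASP_OD2")
        elif res_id == 5:
            add(his_nd1, "ND1", res_id, role="HIS_ND1")
            add(his_ne2, "NE2", res_id, role="HIS_NE2")

    coords = np.asarray(coords) + rng.normal(0.0, 0.05, (len(coords), 3))
    elements = [n[:1] for n in names]
    return structure_from_arrays(coords, names, res_names, res_ids,
                                 chain="A", elements=elements,
                                 role_tags=role_tags)


def generate_fluctuation_trajectory(ref: Structure,
                                    spec: FluctuationSpec) -> Trajectory:
    """Frames = reference + i.i.d. Gaussian per-axis displacement with
    each atom's sigma; timestamps k*dt starting at 0."""
    if spec.per_atom_sigma.shape != (ref.n_atoms,):
        raise ValueError("sigma list length must equal the atom count")
    rng = np.random.default_rng(spec.seed)
    disp = rng.normal(size=(spec.n_frames, ref.n_atoms, 3))
    disp *= spec.per_atom_sigma[None, :, None]
    coords = ref.coords.astype(float)[None, :, :] + disp
    times = spec.dt_ps * np.arange(spec.n_frames)
    return Trajectory(Structure(ref.atoms.copy(), dict(ref.role_tags)),
                      coords, times)


def _truncated_normal(rng, mean, sd, lower, size):
    """Gaussian draws strictly above `lower`, renormalized by resampling."""
    if sd == 0.0:
        if mean <= lower:
            raise ValueError("degenerate draw at or below truncation bound")
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = out <= lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out <= lower
    return out


def generate_triad_trajectory(ref: Structure,
                              spec: TriadDistanceSpec) -> Trajectory:
    """Trajectory whose Ser-His and His-Asp distances are Gaussian draws.

    Per frame the serine OG is placed along the reference OG->NE2 bond
    direction at the drawn Ser-His distance from His NE2, and the whole
    Asp carboxylate (OD1/OD2) is shifted along the reference ND1->OD1
    direction so that the His-Asp (ND1-OD1) distance equals its draw; the
    histidine nitrogens stay fixed and every other atom is copied from
    the reference. Draws are truncated (by resampling) above
    spec.truncation to avoid unphysical overlaps.
    """
    tags = ref.role_tags
    needed = ("SER_OG", "HIS_NE2", "HIS_ND1", "ASP_OD1", "ASP_OD2")
    missing = [r for r in needed if r not in tags]
    if missing:
        raise ValueError(f"reference lacks role tags: {missing}")
    rng = np.random.default_rng(spec.seed)
    d_sh = _truncated_normal(rng, spec.ser_his_mean, spec.ser_his_sd,
                             spec.truncation, spec.n_frames)
    d_hd = _truncated_normal(rng, spec.his_asp_mean, spec.his_asp_sd,
                             spec.truncation, spec.n_frames)

    ref_xyz = ref.coords.astype(float)
    og, ne2 = tags["SER_OG"], tags["HIS_NE2"]
    nd1, od1, od2 = tags["HIS_ND1"], tags["ASP_OD1"], tags["ASP_OD2"]
    u_sh = ref_xyz[og] - ref_xyz[ne2]
    u_sh /= np.linalg.norm(u_sh)
    u_hd = ref_xyz[od1] - ref_xyz[nd1]
    d_hd_ref = np.linalg.norm(u_hd)
    u_hd /= d_hd_ref

    coords = np.broadcast_to(ref_xyz, (spec.n_frames, *ref_xyz.shape)).copy()
    coords[:, og] = ref_xyz[ne2][None, :] + d_sh[:, None] * u_sh[None, :]
    shift = (d_hd - d_hd_ref)[:, None] * u_hd[None, :]
    coords[:, od1] = ref_xyz[od1][None, :] + shift
    coords[:, od2] = ref_xyz[od2][None, :] + shift
    times = spec.dt_ps * np.arange(spec.n_frames)
    return Trajectory(Structure(ref.atoms.copy(), dict(tags)), coords, times)
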