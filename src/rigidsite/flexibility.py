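"""Superposition-based flexibility metrics.

RMSD of a trajectory against a reference structure and per-atom /
per-residue RMSF over a time window, both built on weighted Kabsch
least-squares superposition (SVD of the weighted covariance with
determinant sign correction, so the returned rotation is always proper).

RMSD here is the deviation of matched atoms after optimally removing
rigid-body motion; RMSF is the fluctuation of each atom about its
time-averaged position after superposing all frames onto the window-mean
structure. High RMSF marks flexible residues, low RMSF rigid ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import Structure, Trajectory

__all__ = [
    "SuperpositionResult",
    "RmsfProfile",
    "kabsch_superpose",
    "apply_transform",
    "rmsd_series",
    "rmsf_profile",
]


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference.

    transformed = mobile @ rotation.T + translation; rmsd is the post-fit
    weighted RMSD in Angstrom.
    """

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float


@dataclass
class RmsfProfile:
    """Per-atom RMSF (Angstrom) over a selection, plus optional
    per-residue aggregation."""

    atom_indices: np.ndarray
    rmsf: np.ndarray
    residue_numbers: np.ndarray | None = None
    per_residue: np.ndarray | None = None
    window_ps: tuple | None = None


def kabsch_superpose(mobile_coords, reference_coords,
                     weights=None) -> SuperpositionResult:
    """Weighted least-squares rigid superposition (Kabsch algorithm).

    Returns the proper rotation R and translation t minimizing
    sum_i w_i |R x_i + t - y_i|^2, plus the minimized weighted RMSD.
    Requires >= 3 points that are not collinear.
    """
    x = np.asarray(mobile_coords, dtype=float)
    y = np.asarray(reference_coords, dtype=float)
    if x.shape != y.shape or x.ndim != 2 or x.shape[1] != 3:
        raise ValueError("coordinate arrays must both be (n, 3)")
    n = x.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative, not all zero")
    wsum = w.sum()
    cx = (w[:, None] * x).sum(axis=0) / wsum
    cy = (w[:, None] * y).sum(axis=0) / wsum
    xc, yc = x - cx, y - cy
    h = xc.T @ (w[:, None] * yc)
    u, s, vt = np.linalg.svd(h)
    # collinear/degenerate point sets leave the rotation underdetermined
    if s[1] <= 1e-10 * max(s[0], 1e-30):
        raise ValueError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = cy - rot @ cx
    fitted = x @ rot.T + trans
    rmsd = float(np.sqrt((w * ((fitted - y) ** 2).sum(axis=1)).sum() / wsum))
    return SuperpositionResult(rotation=rot, translation=trans, rmsd=rmsd)


def apply_transform(coords: np.ndarray, sup: SuperpositionResult) -> np.ndarray:
    return np.asarray(coords, dtype=float) @ sup.rotation.T + sup.translation


def _rmsd(a: np.ndarray, b: np.ndarray, weights=None) -> float:
    d2 = ((a - b) ** 2).sum(axis=1)
    if weights is None:
        return float(np.sqrt(d2.mean()))
    w = np.asarray(weights, dtype=float)
    return float(np.sqrt((w * d2).sum() / w.sum()))


def rmsd_series(traj: Trajectory, reference: Structure,
                fit_selection, calc_selection=None,
                weights=None) -> np.ndarray:
    """Per-frame RMSD (Angstrom) against a reference structure.

    Each frame is superposed onto the reference over `fit_selection`
    (topology indices, identical on both) and the RMSD is reported over
    `calc_selection` (defaults to the fit selection). The returned array
    is aligned with traj.times_ps.
    """
    fit_sel = np.asarray(fit_selection, dtype=int)
    calc_sel = (fit_sel if calc_selection is None
                else np.asarray(calc_selection, dtype=int))
    if fit_sel.size < 3:
        raise ValueError("fit selection needs at least 3 atoms")
    ref = reference.coords.astype(float)
    if ref.shape[0] != traj.n_atoms:
        raise ValueError("reference and trajectory topologies differ in size")
    out = np.empty(traj.n_frames)
    for k in range(traj.n_frames):
        sup = kabsch_superpose(traj.coords[k, fit_sel], ref[fit_sel], weights)
        fitted = apply_transform(traj.coords[k, calc_sel], sup)
        out[k] = _rmsd(fitted, ref[calc_sel])
    return out


def rmsf_profile(traj: Trajectory, selection, window_ps=None,
                 reference: Structure | None = None) -> RmsfProfile:
    """Per-atom RMSF over a time window.

    Frames in the window are superposed (over the selection) onto the
    window-average structure, iterated once: an initial fit to the first
    frame yields a mean, frames are refit to that mean, and RMSF_i is the
    root mean square deviation of atom i from its mean fitted position.
    If `reference` is given, frames are superposed onto it instead.
    The per-residue profile is the arithmetic mean of each residue's
    selected-atom RMSF values, which for a C-alpha selection is simply
    that atom's RMSF.
    """
    sel = np.asarray(selection, dtype=int)
    if sel.size < 3:
        raise ValueError("selection needs at least 3 atoms")
    if window_ps is None:
        mask = np.ones(traj.n_frames, dtype=bool)
    else:
        t0, t1 = window_ps
        mask = (traj.times_ps >= t0) & (traj.times_ps <= t1)
    frames = traj.coords[mask][:, sel, :]
    if frames.shape[0] < 2:
        raise ValueError("window must select at least 2 frames")

    if reference is not None:
        target = reference.coords.astype(float)[sel]
        fitted = np.stack([
            apply_transform(f, kabsch_superpose(f, target)) for f in frames
        ])
    else:
        target = frames[0]
        fitted = np.stack([
            apply_transform(f, kabsch_superpose(f, target)) for f in frames
        ])
        mean1 = fitted.mean(axis=0)
        fitted = np.stack([
            apply_transform(f, kabsch_superpose(f, mean1)) for f in frames
        ])
    mean = fitted.mean(axis=0)
    rmsf = np.sqrt(((fitted - mean) ** 2).sum(axis=2).mean(axis=0))

    res_ids = traj.topology.res_ids[sel]
    uniq = np.unique(res_ids)
    per_res = np.array([rmsf[res_ids == r].mean() for r in uniq])
    used = traj.times_ps[mask]
    return RmsfProfile(
        atom_indices=sel, rmsf=rmsf, residue_numbers=uniq,
        per_residue=per_res, window_ps=(float(used[0]), float(used[-1])),
    )
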