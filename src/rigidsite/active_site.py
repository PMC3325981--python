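"""Catalytic-triad geometry-preservation statistics.

For a Ser-His-Asp hydrolase, how well a trajectory preserves the
catalytically competent active-site arrangement is measured by

* per-frame heavy-atom distances of the two triad hydrogen-bond pairs
  (Ser O-gamma to a His imidazole nitrogen; a His nitrogen to an Asp
  carboxylate oxygen) and their frequency distributions;
* the per-frame RMSD of the seven catalytic atoms (Ser OG, His ND1/NE2,
  Asp OD1/OD2, the two oxyanion-hole backbone N) to a reference geometry,
  typically a transition-state-analog-bound crystal structure;
* mean +/- SD summaries of those series.

Because the His imidazole presents two nitrogens and the Asp carboxylate
two chemically equivalent oxygens, each pair spec carries an
equivalent-atom policy: a fixed atom or the minimum over equivalents.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import CatalyticAtomSet, Structure, Trajectory, ROLES
from .flexibility import kabsch_superpose, apply_transform

__all__ = [
    "PairSpec",
    "SER_HIS_PAIR",
    "HIS_ASP_PAIR",
    "DistanceHistogram",
    "SeriesSummary",
    "distance_series",
    "distance_histogram",
    "catalytic_rmsd_series",
    "summarize",
    "compare_static_structures",
]


@dataclass(frozen=True)
class PairSpec:
    """A catalytic atom pair with an equivalent-atom policy.

    roles_a / roles_b list the candidate roles on each side; with policy
    "min" the reported distance is the minimum over all candidate
    combinations, with "fixed" only the first role on each side is used.
    """

    roles_a: tuple
    roles_b: tuple
    policy: str = "fixed"
    name: str = ""

    def __post_init__(self) -> None:
        if self.policy not in ("fixed", "min"):
            raise ValueError("policy must be 'fixed' or 'min'")
        for role in (*self.roles_a, *self.roles_b):
            if role not in ROLES:
                raise ValueError(f"unknown catalytic role {role!r}")


# Ser O-gamma accepts the His N-epsilon2 proton; His N-delta1 hydrogen
# bonds to the Asp carboxylate, whose two oxygens are equivalent.
SER_HIS_PAIR = PairSpec(("SER_OG",), ("HIS_NE2",), "fixed", "SER_OG-HIS_NE2")
HIS_ASP_PAIR = PairSpec(("HIS_ND1",), ("ASP_OD1", "ASP_OD2"), "min",
                        "HIS_ND1-ASP_OD")


@dataclass
class DistanceHistogram:
    """Snapshot-count frequency distribution over distance bins."""

    bin_edges: np.ndarray
    frequencies: np.ndarray
    n_total: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=int)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if self.frequencies.size != self.bin_edges.size - 1:
            raise ValueError("need one frequency per bin")
        if self.frequencies.sum() != self.n_total:
            raise ValueError("frequencies must sum to n_total")


@dataclass
class SeriesSummary:
    """Arithmetic mean and population SD of a series."""

    mean: float
    sd: float
    n: int


def _pair_candidates(pair: PairSpec):
    if pair.policy == "fixed":
        return [(pair.roles_a[0], pair.roles_b[0])]
    return [(a, b) for a in pair.roles_a for b in pair.roles_b]


def distance_series(traj: Trajectory, catalytic_set: CatalyticAtomSet,
                    pair: PairSpec) -> np.ndarray:
    """Per-frame Euclidean distance (Angstrom) for a catalytic pair.

    No superposition is involved; under the "min" policy the reported
    value is the minimum across the equivalent-atom combinations.
    """
    combos = _pair_candidates(pair)
    dists = np.empty((len(combos), traj.n_frames))
    for i, (ra, rb) in enumerate(combos):
        delta = traj.coords[:, catalytic_set[ra]] - traj.coords[:, catalytic_set[rb]]
        dists[i] = np.linalg.norm(delta, axis=1)
    return dists.min(axis=0)


def distance_histogram(series, bin_width: float = 0.1,
                       value_range=None) -> DistanceHistogram:
    """Left-closed right-open bins of constant width covering the data.

    Auto range is [floor(min), ceil(max)]; an extra bin is appended if a
    value falls exactly on the top edge, so counts always conserve the
    series length.
    """
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("cannot histogram an empty series")
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if value_range is None:
        lo, hi = np.floor(series.min()), np.ceil(series.max())
        if hi <= lo:
            hi = lo + bin_width
    else:
        lo, hi = value_range
        if series.min() < lo or series.max() > hi:
            raise ValueError("explicit range does not cover the data")
    n_bins = int(np.ceil((hi - lo) / bin_width - 1e-12))
    edges = lo + bin_width * np.arange(n_bins + 1)
    if series.max() >= edges[-1]:
        edges = np.append(edges, edges[-1] + bin_width)
    idx = np.floor((series - lo) / bin_width).astype(int)
    idx = np.clip(idx, 0, edges.size - 2)
    freq = np.bincount(idx, minlength=edges.size - 1)
    return DistanceHistogram(edges, freq, int(series.size))


def catalytic_rmsd_series(traj: Trajectory, reference: Structure,
                          catalytic_set: CatalyticAtomSet,
                          reference_set: CatalyticAtomSet | None = None,
                          fit_mode: str = "self",
                          fit_selection=None) -> np.ndarray:
    """Per-frame RMSD of the 7 catalytic atoms to a reference geometry.

    fit_mode "self" (default) superposes each frame on the catalytic
    atoms themselves — the statistic is then pure active-site geometry,
    independent of the global frame. fit_mode "global" superposes on
    `fit_selection` (e.g. all shared C-alpha, indices valid on both
    topologies) and measures the catalytic atoms without refitting.
    """
    if fit_mode not in ("self", "global"):
        raise ValueError("fit_mode must be 'self' or 'global'")
    ref_set = reference_set if reference_set is not None else catalytic_set
    cat_traj = catalytic_set.as_array()
    cat_ref = ref_set.as_array()
    ref = reference.coords.astype(float)
    if cat_ref.max() >= ref.shape[0]:
        raise ValueError("catalytic atoms missing in reference structure")
    ref_cat = ref[cat_ref]
    out = np.empty(traj.n_frames)
    if fit_mode == "self":
        for k in range(traj.n_frames):
            out[k] = kabsch_superpose(traj.coords[k, cat_traj], ref_cat).rmsd
    else:
        if fit_selection is None:
            raise ValueError("fit_mode 'global' requires a fit selection")
        fit_sel = np.asarray(fit_selection, dtype=int)
        for k in range(traj.n_frames):
            sup = kabsch_superpose(traj.coords[k, fit_sel], ref[fit_sel])
            fitted = apply_transform(traj.coords[k, cat_traj], sup)
            out[k] = float(np.sqrt(((fitted - ref_cat) ** 2)
                                   .sum(axis=1).mean()))
    return out


def summarize(series) -> SeriesSummary:
    """Arithmetic mean and population SD (divide by n) of a series."""
    series = np.asarray(series, dtype=float)
    if series.size == 0:
        raise ValueError("cannot summarize an empty series")
    return SeriesSummary(
        mean=float(series.mean()),
        sd=float(series.std(ddof=0)),
        n=int(series.size),
    )


def compare_static_structures(a: Structure, b: Structure,
                              set_a: CatalyticAtomSet,
                              set_b: CatalyticAtomSet,
                              pairs=(SER_HIS_PAIR, HIS_ASP_PAIR)) -> dict:
    """Compare the active-site geometry of two single structures.

    Returns the triad pair distances measured in each structure and the
    7-catalytic-atom RMSD between them after self-fit superposition.
    """
    report = {"pairs": {}}
    for pair, (s, cs) in (
        [(p, ("a", set_a)) for p in pairs] + [(p, ("b", set_b)) for p in pairs]
    ):
        struct = a if s == "a" else b
        traj1 = Trajectory(struct, struct.coords[None, :, :], np.array([0.0]))
        d = float(distance_series(traj1, cs, pair)[0])
        report["pairs"].setdefault(pair.name, {})[s] = d
    traj_a = Trajectory(a, a.coords[None, :, :], np.array([0.0]))
    report["catalytic_rmsd"] = float(
        catalytic_rmsd_series(traj_a, b, set_a, set_b, fit_mode="self")[0]
    )
    return report
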