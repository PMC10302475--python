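"""Shape-reading metrics: superposition, P-RMSD, groove widths, fluctuations.

P-RMSD is the root-mean-square deviation of the phosphorus atoms of a
7-nucleotide recognition window, measured after least-squares superposition
onto the Sox-bound DNA reference conformation.  The Sox-bound state is
characterised by a 0.7-2.2 Å P-RMSD fluctuation band and a minor-groove
widening up to 22.5 Å (raw cross-strand phosphate-phosphate distance).

Superposition uses the Kabsch algorithm restricted to proper rotations
(no reflection — DNA chirality must be preserved); by default the fit atoms
are the RMSD atoms themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    ArgumentError,
    ConditioningError,
    GeometryError,
    SelectionError,
    StatisticsError,
)
from .model_io import DuplexMap, SelectionSpec, Structure, Trajectory, select_atoms

#: conversion RMSF^2 -> crystallographic temperature factor, 8 pi^2 / 3
B_FACTOR_PER_RMSF2 = 8.0 * np.pi ** 2 / 3.0

#: two phosphate-group radii subtracted by the "refined" groove convention, Å
PHOSPHATE_RADII = 5.8

#: Sox-bound-DNA P-RMSD fluctuation band, Å
BOUND_PRMSD_RANGE = (0.7, 2.2)

#: cross-strand pairing offsets scanned when tracking the minor groove
GROOVE_OFFSETS = (2, 3, 4)


@dataclass(frozen=True)
class RigidTransform:
    """Proper rotation + translation mapping mobile onto reference."""

    rotation: np.ndarray        # (3, 3)
    mobile_center: np.ndarray   # (3,)
    reference_center: np.ndarray

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - self.mobile_center) @ self.rotation.T + self.reference_center


def superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid superposition (Kabsch, proper rotation only).

    Parameters
    ----------
    mobile, reference : (n, 3) arrays, n >= 3, equal counts.

    Returns
    -------
    (transform, rmsd) : the optimal transform and the post-fit RMSD in Å.
    """
    mob = np.asarray(mobile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if mob.shape != ref.shape or mob.ndim != 2 or mob.shape[1] != 3:
        raise ArgumentError("mobile and reference must be equal-shaped (n, 3) arrays")
    n = mob.shape[0]
    if n < 3:
        raise ArgumentError("superposition needs at least 3 points")
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    a, b = mob - cm, ref - cr
    # unique proper rotation needs points spanning at least a plane
    if np.linalg.matrix_rank(a, tol=1e-8) < 2 or np.linalg.matrix_rank(b, tol=1e-8) < 2:
        raise ConditioningError("points are collinear or coincident")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # align_vectors warns on planar sets
        rot, rssd = Rotation.align_vectors(b, a)
    transform = RigidTransform(rotation=rot.as_matrix(), mobile_center=cm,
                               reference_center=cr)
    rmsd = float(rssd) / np.sqrt(n)
    return transform, rmsd


@dataclass
class PRMSDSeries:
    """Per-analyzed-frame P-RMSD values against one reference."""

    values: np.ndarray
    reference_id: str
    selection: SelectionSpec
    frame_indices: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ArgumentError("P-RMSD values must be non-negative")

    @property
    def n(self) -> int:
        return len(self.values)

    def summary(self, bin_width: float = 0.1) -> dict:
        v = self.values
        edges = np.arange(0.0, v.max() + bin_width, bin_width) if v.size else np.array([0.0])
        counts, edges = np.histogram(v, bins=edges) if v.size else (np.array([]), edges)
        return {"n": self.n, "min": float(v.min()), "max": float(v.max()),
                "mean": float(v.mean()),
                "histogram": {"bin_edges": edges.tolist(), "counts": counts.tolist()}}

    def pooled_with(self, other: "PRMSDSeries") -> "PRMSDSeries":
        """Concatenate two replicas measured against the same reference."""
        if other.reference_id != self.reference_id:
            raise ArgumentError("cannot pool series with different references")
        return PRMSDSeries(np.concatenate([self.values, other.values]),
                           reference_id=self.reference_id, selection=self.selection,
                           frame_indices=self.frame_indices + other.frame_indices)


def _selected_coords(structure: Structure, selection: SelectionSpec) -> np.ndarray:
    atoms = select_atoms(structure, selection)
    return np.array([a.position for a in atoms], dtype=float)


def p_rmsd(frame: Structure, reference: Structure, selection: SelectionSpec,
           fit_selection: SelectionSpec | None = None) -> float:
    """P-RMSD of ``frame`` to ``reference`` over ``selection``.

    The superposition is fitted on ``fit_selection`` (default: the RMSD
    atoms themselves) and the RMSD evaluated over ``selection``.
    """
    mob = _selected_coords(frame, selection)
    ref = _selected_coords(reference, selection)
    if mob.shape != ref.shape:
        raise SelectionError("selection resolves to different cardinality in frame and reference")
    if fit_selection is None:
        _, rmsd = superpose(mob, ref)
        return rmsd
    t, _ = superpose(_selected_coords(frame, fit_selection),
                     _selected_coords(reference, fit_selection))
    moved = t.apply(mob)
    return float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))


def p_rmsd_series(traj: Trajectory, reference: Structure,
                  selection: SelectionSpec, reference_id: str = "",
                  fit_selection: SelectionSpec | None = None) -> PRMSDSeries:
    """One P-RMSD value per analyzed (non-burn-in) frame."""
    idx = traj.analyzed_indices()
    vals = [p_rmsd(traj.frames[i], reference, selection, fit_selection=fit_selection)
            for i in idx]
    return PRMSDSeries(np.array(vals), reference_id=reference_id,
                       selection=selection, frame_indices=idx)


def fraction_in_range(series, lo: float = BOUND_PRMSD_RANGE[0],
                      hi: float = BOUND_PRMSD_RANGE[1]) -> float:
    """Fraction of values inside the inclusive band [lo, hi]."""
    if lo > hi:
        raise ArgumentError("lo must not exceed hi")
    values = series.values if isinstance(series, PRMSDSeries) else np.asarray(series, float)
    if values.size == 0:
        raise ArgumentError("empty series")
    return float(np.mean((values >= lo) & (values <= hi)))


@dataclass
class GrooveProfile:
    """Minor-groove width per dyad-relative forward position.

    Undefined positions (window leaving the duplex, missing phosphate) hold
    NaN and are flagged in ``defined`` — never zero-filled.
    """

    positions: np.ndarray       # dyad-relative indices
    widths: np.ndarray          # Å; NaN where undefined
    defined: np.ndarray         # bool
    convention: str             # "raw_pp" | "refined"

    def max_width(self) -> float:
        if not self.defined.any():
            raise GeometryError("no defined groove positions")
        return float(np.nanmax(self.widths))


def minor_groove_widths(frame: Structure, duplex: DuplexMap,
                        convention: str = "raw_pp") -> GrooveProfile:
    """Minor-groove width profile from cross-strand P-P distances.

    For forward position ``i`` the raw width is the minimum over
    ``k in {2, 3, 4}`` of the distance between the forward phosphate at
    ``i`` and the reverse phosphate of the nucleotide paired with ``i + k``;
    ties take the smaller k.  ``refined`` subtracts 5.8 Å (two
    phosphate-group radii), floored at 0.
    """
    if convention not in ("raw_pp", "refined"):
        raise ArgumentError(f"unknown convention {convention!r}")
    if len(duplex.pairs) < 8:
        raise ArgumentError("duplex must have at least 8 pairs")

    def phosphate(rk):
        try:
            return frame.get_atom(rk[0], rk[1], "P").position
        except SelectionError:
            return None

    fwd = duplex.forward_residues
    fwd_p = [phosphate(rk) for rk in fwd]
    rev_p = {rk: phosphate(duplex.partner(rk)) if duplex.partner(rk) else None
             for rk in fwd}

    positions, widths, defined = [], [], []
    n_missing_p = 0
    for i, rk in enumerate(fwd):
        positions.append(duplex.dyad_relative(rk))
        in_window = [i + k for k in GROOVE_OFFSETS if i + k < len(fwd)]
        if len(in_window) < len(GROOVE_OFFSETS):
            widths.append(np.nan)
            defined.append(False)       # window leaves the duplex: end effect
            continue
        best = None
        missing = False
        if fwd_p[i] is None:
            missing = i != 0        # 5'-terminal nucleotides carry no phosphate
        else:
            for j in in_window:
                rp = rev_p[fwd[j]]
                if rp is None:
                    missing = True
                    continue
                d = float(np.linalg.norm(fwd_p[i] - rp))
                if best is None or d < best:   # strict <: ties keep smaller k
                    best = d
        if best is None:
            n_missing_p += missing
            widths.append(np.nan)
            defined.append(False)
            continue
        if convention == "refined":
            best = max(best - PHOSPHATE_RADII, 0.0)
        widths.append(best)
        defined.append(True)

    interior = max(len(fwd) - max(GROOVE_OFFSETS), 1)
    if n_missing_p / interior > 0.10:
        raise GeometryError(
            f"{n_missing_p} interior positions lack phosphates (> 10% of {interior})")
    return GrooveProfile(np.array(positions), np.array(widths, dtype=float),
                         np.array(defined, dtype=bool), convention)


def max_groove_width(traj_or_frame, duplex: DuplexMap,
                     window: tuple[int, int] | None = None,
                     convention: str = "raw_pp") -> float:
    """Maximum defined width over the dyad-relative window (and frames)."""
    frames = (traj_or_frame.analyzed_frames()
              if isinstance(traj_or_frame, Trajectory) else [traj_or_frame])
    best = None
    for f in frames:
        prof = minor_groove_widths(f, duplex, convention)
        mask = prof.defined.copy()
        if window is not None:
            lo, hi = window
            if lo > hi:
                raise ArgumentError("empty window")
            mask &= (prof.positions >= lo) & (prof.positions <= hi)
        if not mask.any():
            continue
        m = float(np.nanmax(prof.widths[mask]))
        best = m if best is None else max(best, m)
    if best is None:
        raise ArgumentError("window contains no defined groove positions")
    return best


@dataclass
class FluctuationProfile:
    """Per-atom RMSF (Å) and temperature factor (Å²), B = (8 pi^2 / 3) RMSF^2."""

    atom_keys: list[tuple[str, int, str]]
    rmsf: np.ndarray

    @property
    def temperature_factor(self) -> np.ndarray:
        return B_FACTOR_PER_RMSF2 * self.rmsf ** 2


def rmsf_profile(traj: Trajectory, selection: SelectionSpec,
                 fit_selection: SelectionSpec | None = None) -> FluctuationProfile:
    """RMSF about the mean after superposing every analyzed frame.

    Frames are fitted on ``fit_selection`` (default: ``selection``) onto the
    first analyzed frame, then RMSF_i = sqrt(mean_t |x_i(t) - <x_i>|^2).
    """
    frames = traj.analyzed_frames()
    if len(frames) < 10:
        raise StatisticsError(f"need >= 10 analyzed frames, got {len(frames)}")
    fit_sel = fit_selection or selection
    ref_fit = _selected_coords(frames[0], fit_sel)
    stacked = []
    for f in frames:
        t, _ = superpose(_selected_coords(f, fit_sel), ref_fit)
        stacked.append(t.apply(_selected_coords(f, selection)))
    arr = np.array(stacked)                       # (T, n, 3)
    mean = arr.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((arr - mean) ** 2, axis=2), axis=0))
    keys = [a.key for a in select_atoms(frames[0], selection)]
    return FluctuationProfile(atom_keys=keys, rmsf=rmsf)
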