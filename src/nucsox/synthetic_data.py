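"""Synthetic fixtures: fiber B-DNA, groove deformation, thermal trajectories,
designed contact probes, and noisy titration curves.

The generators stand in for the crystallographic and MD inputs of the
analysis layer so that every pipeline stage is testable without downloads.
Every generator is a pure function of (inputs, seed); a single global seed
fans out to per-operation substreams by stable hashing of the operation
name, so streams are independent yet reproducible.

The duplex is an idealized fiber model, not sequence-dependent: nucleotides
are reduced to phosphate group (P, OP1, OP2), C1'/C2' sugar carbons, and a
small base template (glycosidic nitrogen, ring carbons, Watson-Crick edge
donors/acceptors) — sufficient for every metric in scope (groove widths,
P-RMSD, contact classes) while keeping fixtures small.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .errors import ArgumentError, PlacementError, RosterError
from .geometry import minor_groove_widths
from .model_io import Atom, DuplexMap, Structure, Trajectory, infer_duplex
from .sequence_design import NucleotideSequence
from .titration import TitrationSeries, biexponential

FORWARD_CHAIN = "I"
REVERSE_CHAIN = "J"
PROBE_CHAIN = "P"

_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def substream(seed: int, operation: str) -> np.random.Generator:
    """Independent, reproducible random stream for one generator op."""
    return np.random.default_rng([int(seed) % (2 ** 31), zlib.crc32(operation.encode())])


@dataclass(frozen=True)
class FiberParams:
    """Idealized B-DNA helix parameters."""

    rise: float = 3.38                  # Å per bp
    twist: float = 36.0                 # degrees per bp
    backbone_radius: float = 9.4        # Å, phosphate radius
    minor_groove_phase: float = 154.0   # degrees between the strands' phosphates
    c1_radius: float = 6.0              # Å, glycosidic carbon radius

    def __post_init__(self):
        if self.rise <= 0:
            raise ArgumentError("rise must be positive")
        if not 0 < self.twist <= 45:
            raise ArgumentError("twist must be in (0, 45] degrees")


# base templates: (atom_name, element, inward Å from C1', tangential Å, z Å).
# WC-edge atoms sit 3.75 Å inward so paired edges end up ~2.9 Å apart.
_BASE_TEMPLATES: dict[str, list[tuple[str, str, float, float, float]]] = {
    "DA": [("N9", "N", 1.48, 0.0, 0.0), ("C4", "C", 2.6, 0.4, 0.1),
           ("N3", "N", 3.4, 1.2, 0.1), ("N1", "N", 3.75, -0.4, 0.0),
           ("N6", "N", 3.75, -1.6, -0.1), ("N7", "N", 2.9, -1.4, 0.0)],
    "DG": [("N9", "N", 1.48, 0.0, 0.0), ("C4", "C", 2.6, 0.4, 0.1),
           ("N3", "N", 3.4, 1.2, 0.1), ("N1", "N", 3.75, -0.4, 0.0),
           ("O6", "O", 3.75, -1.6, -0.1), ("N2", "N", 3.75, 0.9, 0.1),
           ("N7", "N", 2.9, -1.4, 0.0)],
    "DT": [("N1", "N", 1.48, 0.0, 0.0), ("C2", "C", 2.6, 0.6, 0.1),
           ("O2", "O", 3.3, 1.3, 0.1), ("N3", "N", 3.75, 0.2, 0.0),
           ("O4", "O", 3.75, -1.2, -0.1), ("C5", "C", 2.9, -1.4, 0.0),
           ("C7", "C", 3.1, -2.6, -0.1)],
    "DC": [("N1", "N", 1.48, 0.0, 0.0), ("C2", "C", 2.6, 0.6, 0.1),
           ("O2", "O", 3.3, 1.3, 0.1), ("N3", "N", 3.75, 0.2, 0.0),
           ("N4", "N", 3.75, -1.2, -0.1), ("C5", "C", 2.9, -1.4, 0.0)],
}


def _cyl(radius: float, azimuth_deg: float, z: float) -> np.ndarray:
    a = np.radians(azimuth_deg)
    return np.array([radius * np.cos(a), radius * np.sin(a), z])


def build_bdna(sequence: NucleotideSequence,
               params: FiberParams = FiberParams()) -> Structure:
    """Regular-helix antiparallel duplex for a sequence of >= 8 nt.

    Forward chain ``I`` runs 5'->3' with author residue ids 1..N; reverse
    chain ``J`` is its complement, numbered 1..N along its own 5'->3'
    direction.  Phosphates are present on all nucleotides except the two
    5' ends.  Deterministic for fixed inputs.
    """
    n = len(sequence)
    if n < 8:
        raise ArgumentError("duplex sequence must be >= 8 nt")
    half_phase = params.minor_groove_phase / 2.0
    atoms: list[Atom] = []

    def nucleotide(level: int, base: str, chain: str, resid: int, sense: int,
                   with_p: bool) -> list[Atom]:
        """sense +1: forward strand; -1: reverse strand (mirrored azimuths)."""
        theta = level * params.twist
        z = level * params.rise
        resname = "D" + base
        c1 = _cyl(params.c1_radius, theta + sense * 60.0, z)
        axis_point = np.array([0.0, 0.0, z])
        inward = axis_point - c1
        inward /= np.linalg.norm(inward)
        vertical = np.array([0.0, 0.0, 1.0])
        tangent = np.cross(vertical, inward) * sense
        out = []
        if with_p:
            p = _cyl(params.backbone_radius, theta + sense * half_phase, z)
            radial = np.array([p[0], p[1], 0.0])
            radial /= np.linalg.norm(radial)
            out.append(Atom("P", resname, resid, chain, "P", p))
            out.append(Atom("OP1", resname, resid, chain, "O", p + radial * 0.8 + vertical * 1.2))
            out.append(Atom("OP2", resname, resid, chain, "O", p + radial * 0.8 - vertical * 1.2))
        out.append(Atom("C1'", resname, resid, chain, "C", c1))
        out.append(Atom("C2'", resname, resid, chain, "C",
                        c1 - inward * 1.0 + vertical * sense * 1.1))
        for name, elem, d_in, d_tan, d_z in _BASE_TEMPLATES[resname]:
            out.append(Atom(name, resname, resid, chain, elem,
                            c1 + inward * d_in + tangent * d_tan + vertical * d_z))
        return out

    for i, base in enumerate(sequence.residues):
        atoms.extend(nucleotide(i, base, FORWARD_CHAIN, i + 1, +1, with_p=(i > 0)))
    rev_atoms: list[Atom] = []
    for j in range(n):                      # reverse residue j+1 sits at level n-1-j
        level = n - 1 - j
        base = _COMPLEMENT[sequence.residues[level]]
        rev_atoms.extend(nucleotide(level, base, REVERSE_CHAIN, j + 1, -1, with_p=(j > 0)))
    atoms.extend(rev_atoms)
    return Structure(atoms, title=f"fiber duplex {sequence.name or ''}".strip())


def default_duplex_map(structure: Structure, dyad_forward_residue: int | None = None,
                       shl_period_bp: float = 10.0) -> DuplexMap:
    """Duplex map of a :func:`build_bdna` structure, dyad at the middle
    forward nucleotide unless given."""
    fwd = [rk for rk in structure.residues(FORWARD_CHAIN)]
    if dyad_forward_residue is None:
        dyad_forward_residue = fwd[len(fwd) // 2][1]
    return infer_duplex(structure, FORWARD_CHAIN, REVERSE_CHAIN,
                        dyad_forward_residue, shl_period_bp)


def deform_groove(duplex: Structure, center: int, span: int, target_width: float,
                  duplex_map: DuplexMap | None = None) -> Structure:
    """Widen the minor groove around ``center`` (dyad-relative) to
    ``target_width`` (raw P-P Å) by a cosine-windowed radially-outward
    displacement of the phosphate groups of both strands.

    The displacement amplitude is calibrated by bisection against the
    measured profile, so the width at the center matches the target within
    0.3 Å; atoms outside the span are untouched.  Assumes the fiber
    geometry of :func:`build_bdna` (helix axis = z).
    """
    dm = duplex_map or default_duplex_map(duplex)
    prof0 = minor_groove_widths(duplex, dm, "raw_pp")
    at_center = prof0.widths[np.nonzero(prof0.positions == center)[0]]
    if at_center.size == 0 or not np.isfinite(at_center[0]):
        raise ArgumentError(f"no defined groove width at position {center}")
    current = float(at_center[0])
    if target_width < current - 1e-9:
        raise ArgumentError(
            f"target {target_width} Å below current width {current:.2f} Å")
    if target_width <= current + 1e-9:
        return duplex.with_coords(duplex.coords())

    # dyad-relative level of every residue (reverse residues take the level
    # of their pairing partner's position on the forward strand)
    fwd_levels = {rk: dm.dyad_relative(rk) for rk in dm.forward_residues}
    rev_levels = {dm.partner(rk)[0:2]: lvl for rk, lvl in fwd_levels.items()
                  if dm.partner(rk) is not None}

    half = span / 2.0

    def weight(level: int) -> float:
        x = abs(level - center)
        return 0.5 * (1.0 + np.cos(np.pi * x / half)) if x < half else 0.0

    moved_names = {"P", "OP1", "OP2"}
    # the width at forward position i couples P_fwd(i) with P_rev paired at
    # level ~i+3 (the middle tracking offset); each strand is displaced
    # along that fixed cross-groove axis, measured on the undeformed duplex,
    # so every offset's distance grows monotonically with the amplitude
    rev_shift = 3
    level_of_fwd = {lvl: rk for rk, lvl in fwd_levels.items()}

    def phosphate(rk):
        try:
            return duplex.get_atom(rk[0], rk[1], "P").position
        except Exception:
            return None

    groove_axis: dict[int, np.ndarray] = {}
    for lvl, rk in level_of_fwd.items():
        partner_fwd = level_of_fwd.get(lvl + rev_shift)
        if partner_fwd is None or dm.partner(partner_fwd) is None:
            continue
        pf = phosphate(rk)
        pr = phosphate(dm.partner(partner_fwd))
        if pf is None or pr is None:
            continue
        axis = pf - pr
        groove_axis[lvl] = axis / np.linalg.norm(axis)

    def deformed(amplitude: float) -> Structure:
        coords = duplex.coords()
        for i, a in enumerate(duplex.atoms):
            if a.atom_name not in moved_names:
                continue
            if a.chain_id == FORWARD_CHAIN:
                lvl = fwd_levels.get(a.residue_key)
                sign = +0.5
            else:
                lvl = rev_levels.get((a.chain_id, a.residue_id))
                lvl = None if lvl is None else lvl - rev_shift
                sign = -0.5
            if lvl is None or lvl not in groove_axis:
                continue
            w = weight(lvl)
            if w == 0.0:
                continue
            coords[i] = a.position + groove_axis[lvl] * (sign * amplitude * w)
        return duplex.with_coords(coords)

    def width_at_center(s: Structure) -> float:
        prof = minor_groove_widths(s, dm, "raw_pp")
        return float(prof.widths[np.nonzero(prof.positions == center)[0][0]])

    lo, hi = 0.0, 1.0
    while width_at_center(deformed(hi)) < target_width and hi < 60.0:
        hi *= 2.0
    if width_at_center(deformed(hi)) < target_width:
        raise ArgumentError(f"target width {target_width} Å unreachable")
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if width_at_center(deformed(mid)) < target_width:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-6:
            break
    return deformed(hi)


@dataclass(frozen=True)
class PerturbationSpec:
    """Thermal-fluctuation stand-in: i.i.d. Gaussian displacement (sigma per
    axis) around an optional drift path toward a target conformation."""

    sigma: float = 0.0              # Å per axis
    n_frames: int = 1
    seed: int = 0
    drift_target: Structure | None = None
    drift_fractions: tuple[float, ...] | None = None   # per-frame schedule in [0, 1]

    def __post_init__(self):
        if self.sigma < 0:
            raise ArgumentError("sigma must be non-negative")
        if self.n_frames < 1:
            raise ArgumentError("n_frames must be >= 1")
        if self.drift_fractions is not None and len(self.drift_fractions) != self.n_frames:
            raise ArgumentError("drift_fractions must have one entry per frame")


def simulate_trajectory(base: Structure, spec: PerturbationSpec,
                        frame_interval_ns: float = 0.5,
                        burn_in_ns: float = 0.0) -> Trajectory:
    """Frames = drift interpolation toward the target plus Gaussian noise.

    The default drift schedule is linear from 0 at frame 0 to 1 at the last
    frame.  Reproducible from the spec seed.
    """
    rng = substream(spec.seed, "simulate_trajectory")
    base_xyz = base.coords()
    target_xyz = None
    if spec.drift_target is not None:
        if spec.drift_target.roster() != base.roster():
            raise RosterError("drift_target roster differs from base")
        target_xyz = spec.drift_target.coords()
    if spec.drift_fractions is not None:
        fracs = np.asarray(spec.drift_fractions, dtype=float)
    elif target_xyz is not None:
        fracs = (np.linspace(0.0, 1.0, spec.n_frames) if spec.n_frames > 1
                 else np.array([1.0]))
    else:
        fracs = np.zeros(spec.n_frames)
    frames = []
    for t in range(spec.n_frames):
        xyz = base_xyz.copy()
        if target_xyz is not None:
            xyz = base_xyz + fracs[t] * (target_xyz - base_xyz)
        if spec.sigma > 0:
            xyz = xyz + rng.normal(0.0, spec.sigma, size=xyz.shape)
        frames.append(base.with_coords(xyz, model_id=t + 1))
    return Trajectory(frames, frame_interval_ns=frame_interval_ns,
                      burn_in_ns=burn_in_ns)


@dataclass(frozen=True)
class ContactPlanItem:
    """One designed probe contact against a DNA residue.

    ``target`` selects base vs backbone atoms on the DNA side; the probe
    residue defaults to a class-appropriate Sox residue of interest.
    """

    contact_class: str                         # hbond | hydrophobic | ionic
    dna_chain: str
    dna_residue_id: int
    target: str = "base"                       # base | backbone
    distance: float = 2.9                      # Å
    protein_residue: tuple[str, int] | None = None

    def __post_init__(self):
        if self.contact_class not in ("hbond", "hydrophobic", "ionic"):
            raise ArgumentError(f"unknown contact class {self.contact_class!r}")
        if self.target not in ("base", "backbone"):
            raise ArgumentError("target must be 'base' or 'backbone'")
        if self.distance < 1.5:
            raise ArgumentError("plan distances must be >= 1.5 Å")


_DEFAULT_PROBE = {"hbond": ("ASN", 54), "hydrophobic": ("MET", 57),
                  "ionic": ("ARG", 51)}
_PROBE_ATOM = {("ASN", "hbond"): ("ND2", "N"), ("ARG", "hbond"): ("NH1", "N"),
               ("TYR", "hbond"): ("OH", "O"),
               ("MET", "hydrophobic"): ("CE", "C"), ("PHE", "hydrophobic"): ("CZ", "C"),
               ("ARG", "ionic"): ("NH1", "N"), ("LYS", "ionic"): ("NZ", "N")}


def place_probe(duplex: Structure, contact_plan: list[ContactPlanItem]) -> Structure:
    """Add pseudo-protein probe residues realizing each planned contact.

    Each plan item contributes one probe atom placed ``distance`` Å
    radially outward from a suitable DNA target atom.  Raises
    PlacementError when the probe would sit < 1.5 Å from any DNA atom, and
    ArgumentError when the DNA residue offers no atom of the required role.
    """
    from .contacts import BASE_ATOMS, _dna_role  # local import avoids a cycle

    atoms = list(duplex.atoms)
    for item in contact_plan:
        resname, resid = item.protein_residue or _DEFAULT_PROBE[item.contact_class]
        atom_name, element = _PROBE_ATOM.get((resname, item.contact_class),
                                             ("CB", "C"))
        dna_res = [a for a in duplex.atoms
                   if a.chain_id == item.dna_chain and a.residue_id == item.dna_residue_id]
        if not dna_res:
            raise ArgumentError(
                f"DNA residue {item.dna_chain}/{item.dna_residue_id} not found")

        def role_ok(a: Atom) -> bool:
            r = _dna_role(a)
            if not r:
                return False
            is_base = a.atom_name in BASE_ATOMS.get(a.residue_name, set())
            if (item.target == "base") != is_base:
                return False
            if item.contact_class == "hbond":
                return r["acceptor"] or r["donor"]
            if item.contact_class == "hydrophobic":
                return r["apolar"] and a.element == "C"
            return r["phosphate_o"]

        candidates = [a for a in dna_res if role_ok(a)]
        if not candidates:
            raise ArgumentError(
                f"no {item.target} atom on {item.dna_chain}/{item.dna_residue_id} "
                f"suits a {item.contact_class} contact")
        target_atom = candidates[0]
        radial = np.array([target_atom.position[0], target_atom.position[1], 0.0])
        nrm = np.linalg.norm(radial)
        direction = radial / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
        pos = target_atom.position + direction * item.distance
        for a in duplex.atoms:
            if np.linalg.norm(a.position - pos) < 1.5 - 1e-9:
                raise PlacementError(
                    f"probe {resname}{resid} clashes with {a.key} at "
                    f"{np.linalg.norm(a.position - pos):.2f} Å")
        key = (resname, resid, atom_name)
        if any(a.chain_id == PROBE_CHAIN and (a.residue_name, a.residue_id,
                                              a.atom_name) == key for a in atoms):
            raise ArgumentError(f"probe atom {key} planned twice")
        atoms.append(Atom(atom_name, resname, resid, PROBE_CHAIN, element, pos))
    return Structure(atoms, title=duplex.title)


def simulate_titration(truth: tuple[float, float, float, float], concentrations,
                       noise_sd: float = 0.0, seed: int = 0,
                       site: str = "") -> TitrationSeries:
    """Noisy biexponential decay: intensity = f1(x) * (1 + eps),
    eps ~ Normal(0, noise_sd), seeded."""
    if noise_sd < 0:
        raise ArgumentError("noise_sd must be non-negative")
    conc = np.asarray(concentrations, dtype=float)
    clean = biexponential(conc, *truth)
    if noise_sd > 0:
        rng = substream(seed, "simulate_titration")
        clean = clean * (1.0 + rng.normal(0.0, noise_sd, size=conc.shape))
    return TitrationSeries(conc, clean, site=site)
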