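"""Structure and trajectory IO, atom selection, and duplex inference.

Coordinates are Å throughout.  Structures are ordered atom lists; a
trajectory is an ordered list of structures sharing one atom roster (the
identity triple ``(chain_id, residue_id, atom_name)``).  Multi-model PDB is
the canonical trajectory interchange format; frames recorded every
``frame_interval_ns`` with an equilibration window flagged (never deleted)
via ``burn_in_ns``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .errors import (
    ArgumentError,
    DuplexInferenceError,
    PDBParseError,
    RosterError,
    SelectionError,
)

#: residue names accepted as DNA nucleotides, mapped to one-letter codes
NUCLEOTIDE_NAMES = {
    "DA": "A", "DT": "T", "DG": "G", "DC": "C",
    "A": "A", "T": "T", "G": "G", "C": "C",
}

WC_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: Watson-Crick C1'-C1' distance gate, Å
C1_GATE = (9.0, 12.0)


@dataclass(frozen=True)
class Atom:
    """One heavy (or hydrogen) atom with PDB-style identity."""

    atom_name: str
    residue_name: str
    residue_id: int
    chain_id: str
    element: str
    position: np.ndarray

    def __post_init__(self):
        if not self.atom_name:
            raise ArgumentError("atom_name must be non-empty")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ArgumentError(f"position of {self.atom_name} must be a finite 3-vector")
        object.__setattr__(self, "position", pos)

    @property
    def key(self) -> tuple[str, int, str]:
        """Identity triple (chain_id, residue_id, atom_name)."""
        return (self.chain_id, self.residue_id, self.atom_name)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_id, self.residue_name)


@dataclass
class Structure:
    """An ordered collection of atoms from one PDB model."""

    atoms: list[Atom]
    title: str = ""
    model_id: int = 1

    def __post_init__(self):
        seen = set()
        for a in self.atoms:
            if a.key in seen:
                raise ArgumentError(f"duplicate atom identity {a.key}")
            seen.add(a.key)

    def __len__(self) -> int:
        return len(self.atoms)

    def roster(self) -> tuple[tuple[str, int, str], ...]:
        return tuple(a.key for a in self.atoms)

    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coords(self, coords: np.ndarray, model_id: int | None = None) -> "Structure":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ArgumentError("coordinate array shape mismatch")
        atoms = [replace(a, position=c) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, title=self.title,
                         model_id=self.model_id if model_id is None else model_id)

    def atom_index(self) -> dict[tuple[str, int, str], int]:
        return {a.key: i for i, a in enumerate(self.atoms)}

    def get_atom(self, chain_id: str, residue_id: int, atom_name: str) -> Atom:
        for a in self.atoms:
            if a.chain_id == chain_id and a.residue_id == residue_id and a.atom_name == atom_name:
                return a
        raise SelectionError(f"atom ({chain_id}, {residue_id}, {atom_name}) not found")

    def chains(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def residues(self, chain_id: str | None = None) -> list[tuple[str, int, str]]:
        """Residue keys in atom order (first occurrence)."""
        out: list[tuple[str, int, str]] = []
        seen = set()
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            rk = a.residue_key
            if rk not in seen:
                seen.add(rk)
                out.append(rk)
        return out


@dataclass
class Trajectory:
    """Ordered frames on a fixed roster.

    Frame ``i`` carries time ``(i + 1) * frame_interval_ns``; frames whose
    time is within ``burn_in_ns`` are flagged as equilibration and excluded
    from analysis operations, but kept in ``frames``.
    """

    frames: list[Structure]
    frame_interval_ns: float = 0.5
    burn_in_ns: float = 0.0

    def __post_init__(self):
        if not self.frames:
            raise ArgumentError("trajectory needs at least one frame")
        if self.frame_interval_ns <= 0:
            raise ArgumentError("frame_interval_ns must be positive")
        if self.burn_in_ns < 0:
            raise ArgumentError("burn_in_ns must be non-negative")
        roster = self.frames[0].roster()
        for i, f in enumerate(self.frames[1:], start=1):
            if f.roster() != roster:
                diff = _first_roster_difference(roster, f.roster())
                raise RosterError(f"frame {i} roster differs from frame 0 at {diff}")

    def __len__(self) -> int:
        return len(self.frames)

    def frame_time_ns(self, i: int) -> float:
        return (i + 1) * self.frame_interval_ns

    def analyzed_indices(self) -> list[int]:
        return [i for i in range(len(self.frames))
                if self.frame_time_ns(i) > self.burn_in_ns]

    def analyzed_frames(self) -> list[Structure]:
        return [self.frames[i] for i in self.analyzed_indices()]


@dataclass(frozen=True)
class SelectionSpec:
    """Names a block of atoms: one chain (or ``'*'``), residues, atom names."""

    chain_id: str
    residue_ids: tuple[int, ...]
    atom_names: tuple[str, ...] = ("P",)

    def __post_init__(self):
        rids = tuple(self.residue_ids)
        names = tuple(self.atom_names)
        if not rids:
            raise ArgumentError("residue_ids must be non-empty")
        if len(set(rids)) != len(rids):
            raise ArgumentError("duplicate residue_ids forbidden")
        if not names or len(set(names)) != len(names):
            raise ArgumentError("atom_names must be non-empty and unique")
        object.__setattr__(self, "residue_ids", rids)
        object.__setattr__(self, "atom_names", names)


@dataclass
class DuplexMap:
    """Watson-Crick pairing of an antiparallel duplex with a dyad anchor.

    ``pairs`` maps forward-strand residue keys to reverse-strand residue
    keys.  ``forward_residues`` lists every nucleotide of the forward chain
    in chain order (paired or not), so dyad-relative coordinates are defined
    by list position: position 0 is the dyad, negative toward the forward
    strand 5' end.
    """

    pairs: list[tuple[tuple[str, int, str], tuple[str, int, str]]]
    forward_residues: list[tuple[str, int, str]]
    dyad_forward_index: int
    shl_period_bp: float = 10.0

    def __post_init__(self):
        if self.shl_period_bp <= 0:
            raise ArgumentError("shl_period_bp must be positive")
        self._pair_of = dict(self.pairs)
        self._fwd_pos = {rk: i for i, rk in enumerate(self.forward_residues)}
        if len(self._pair_of) != len(self.pairs):
            raise ArgumentError("pairing must be a bijection")

    def dyad_relative(self, forward_key: tuple[str, int, str]) -> int:
        return self._fwd_pos[forward_key] - self.dyad_forward_index

    def forward_key_at(self, dyad_relative: int) -> tuple[str, int, str]:
        i = self.dyad_forward_index + dyad_relative
        if not 0 <= i < len(self.forward_residues):
            raise SelectionError(f"dyad-relative position {dyad_relative} outside duplex")
        return self.forward_residues[i]

    def partner(self, forward_key: tuple[str, int, str]):
        return self._pair_of.get(forward_key)


def _first_roster_difference(a, b):
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            return f"index {i}: {x} vs {y}"
    return f"length {len(a)} vs {len(b)}"


# ---------------------------------------------------------------------------
# PDB reading / writing (biotite behind the module surface)
# ---------------------------------------------------------------------------

def _scan_for_malformed_records(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except (ValueError, IndexError):
                    raise PDBParseError("malformed ATOM coordinate field", lineno)
                icode = line[26:27]
                if icode not in (" ", ""):
                    raise PDBParseError("insertion codes are unsupported", lineno)


def _atoms_from_array(arr: bst.AtomArray) -> list[Atom]:
    out = []
    for i in range(arr.array_length()):
        out.append(Atom(
            atom_name=str(arr.atom_name[i]),
            residue_name=str(arr.res_name[i]),
            residue_id=int(arr.res_id[i]),
            chain_id=str(arr.chain_id[i]),
            element=str(arr.element[i]),
            position=np.asarray(arr.coord[i], dtype=float),
        ))
    return out


def read_structure(path, model_index: int | str = 1):
    """Read a PDB file.

    Parameters
    ----------
    path : path-like
    model_index : int or "all"
        1-based MODEL number, or ``"all"`` for one Structure per model.
    """
    try:
        _scan_for_malformed_records(path)
        pdb = PDBFile.read(str(path))
    except PDBParseError:
        raise
    except FileNotFoundError as e:
        raise OSError(f"cannot read {path}: {e}") from e
    n_models = pdb.get_model_count()
    title = " ".join(
        ln[10:].strip() for ln in pdb.lines if ln.startswith("TITLE")
    ).strip()

    def one(m: int) -> Structure:
        arr = pdb.get_structure(model=m)
        return Structure(_atoms_from_array(arr), title=title, model_id=m)

    if model_index == "all":
        return [one(m) for m in range(1, n_models + 1)]
    if not 1 <= int(model_index) <= n_models:
        raise ArgumentError(f"model_index {model_index} outside 1..{n_models}")
    return one(int(model_index))


def _array_from_structure(s: Structure) -> bst.AtomArray:
    arr = bst.AtomArray(len(s))
    arr.coord = s.coords().astype(np.float32)
    arr.chain_id = np.array([a.chain_id for a in s.atoms], dtype="U4")
    arr.res_id = np.array([a.residue_id for a in s.atoms], dtype=int)
    arr.res_name = np.array([a.residue_name for a in s.atoms], dtype="U5")
    arr.atom_name = np.array([a.atom_name for a in s.atoms], dtype="U6")
    arr.element = np.array([a.element for a in s.atoms], dtype="U2")
    arr.hetero = np.full(len(s), False)
    return arr


def write_structure(structure, path) -> None:
    """Write a Structure (or list of roster-identical Structures) as PDB."""
    structures = structure if isinstance(structure, (list, tuple)) else [structure]
    if not structures:
        raise ArgumentError("nothing to write")
    roster = structures[0].roster()
    for s in structures[1:]:
        if s.roster() != roster:
            raise RosterError("models to be written share no common roster")
    if len(structures) == 1:
        arrs = _array_from_structure(structures[0])
    else:
        arrs = bst.stack([_array_from_structure(s) for s in structures])
    pdb = PDBFile()
    pdb.set_structure(arrs)
    pdb.write(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    write_structure(traj.frames, path)


def load_trajectory(paths, frame_interval_ns: float, burn_in_ns: float = 0.0) -> Trajectory:
    """Load ordered frames from one or more (multi-model) PDB files.

    Frames with a permuted but identical roster are accepted: their atoms
    are re-ordered to the first frame's roster by identity triple.
    """
    frames: list[Structure] = []
    for p in paths:
        got = read_structure(p, model_index="all")
        frames.extend(got)
    if not frames:
        raise ArgumentError("no frames loaded")
    frames = canonicalize_rosters(frames)
    return Trajectory(frames, frame_interval_ns=frame_interval_ns, burn_in_ns=burn_in_ns)


def canonicalize_rosters(frames: list[Structure]) -> list[Structure]:
    """Re-order every frame's atoms to match frame 0, matching by identity."""
    ref = frames[0].roster()
    ref_set = set(ref)
    out = [frames[0]]
    for i, f in enumerate(frames[1:], start=1):
        if f.roster() == ref:
            out.append(f)
            continue
        idx = f.atom_index()
        if set(idx) != ref_set:
            diff = _first_roster_difference(tuple(sorted(ref_set)), tuple(sorted(idx)))
            raise RosterError(f"frame {i} roster differs (not a permutation) at {diff}")
        atoms = [f.atoms[idx[k]] for k in ref]
        out.append(Structure(atoms, title=f.title, model_id=f.model_id))
    return out


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def select_atoms(structure: Structure, spec: SelectionSpec) -> list[Atom]:
    """Resolve a SelectionSpec; order is spec residue order then atom-name order.

    Raises SelectionError naming the first missing key — no silent partial
    selection.
    """
    by_key: dict[tuple, Atom] = {}
    for a in structure.atoms:
        by_key[(a.chain_id, a.residue_id, a.atom_name)] = a
    wildcard = spec.chain_id == "*"
    chains = structure.chains() if wildcard else [spec.chain_id]
    out: list[Atom] = []
    for rid in spec.residue_ids:
        for name in spec.atom_names:
            hit = None
            for c in chains:
                hit = by_key.get((c, rid, name))
                if hit is not None:
                    break
            if hit is None:
                where = "any chain" if wildcard else f"chain {spec.chain_id}"
                raise SelectionError(f"atom {name} of residue {rid} not found in {where}")
            out.append(hit)
    return out


# ---------------------------------------------------------------------------
# Duplex inference
# ---------------------------------------------------------------------------

def infer_duplex(structure: Structure, forward_chain: str, reverse_chain: str,
                 dyad_forward_residue: int, shl_period_bp: float = 10.0) -> DuplexMap:
    """Pair the two strands by WC complementarity plus a C1'-C1' gate.

    Pairing requires exact A-T / G-C complementarity (wobble rejected) and a
    C1'-C1' distance within 9-12 Å; antiparallel ordering is verified.
    Fails if fewer than half the forward nucleotides pair.
    """
    def chain_nucleotides(chain):
        res = [rk for rk in structure.residues(chain) if rk[2] in NUCLEOTIDE_NAMES]
        return res

    fwd = chain_nucleotides(forward_chain)
    rev = chain_nucleotides(reverse_chain)
    if len(fwd) < 4 or len(rev) < 4:
        raise DuplexInferenceError(
            f"chains {forward_chain}/{reverse_chain} need >= 4 nucleotides each")

    def c1(rk):
        try:
            return structure.get_atom(rk[0], rk[1], "C1'").position
        except SelectionError:
            return None

    def glyco_dir(rk, c1_pos):
        """Unit vector from C1' toward the glycosidic nitrogen (base side)."""
        name = "N9" if NUCLEOTIDE_NAMES[rk[2]] in ("A", "G") else "N1"
        try:
            n = structure.get_atom(rk[0], rk[1], name).position
        except SelectionError:
            return None
        v = n - c1_pos
        nrm = np.linalg.norm(v)
        return v / nrm if nrm > 0 else None

    fwd_c1 = {rk: c1(rk) for rk in fwd}
    rev_c1 = {rk: c1(rk) for rk in rev}
    pairs = []
    used_rev: set = set()
    for frk in fwd:
        fpos = fwd_c1[frk]
        if fpos is None:
            continue
        fdir = glyco_dir(frk, fpos)
        want = WC_COMPLEMENT[NUCLEOTIDE_NAMES[frk[2]]]
        best = None
        best_d = None
        for rrk in rev:
            if rrk in used_rev or NUCLEOTIDE_NAMES[rrk[2]] != want:
                continue
            rpos = rev_c1[rrk]
            if rpos is None:
                continue
            d = float(np.linalg.norm(fpos - rpos))
            if not C1_GATE[0] <= d <= C1_GATE[1]:
                continue
            # a WC partner lies where the base points: the C1'->C1' vector
            # must align with each base's glycosidic direction (when the
            # glycosidic nitrogen is present to check)
            rdir = glyco_dir(rrk, rpos)
            sep = (rpos - fpos) / d
            if fdir is not None and float(np.dot(sep, fdir)) < 0.5:
                continue
            if rdir is not None and float(np.dot(-sep, rdir)) < 0.5:
                continue
            if best_d is None or d < best_d:
                best, best_d = rrk, d
        if best is not None:
            pairs.append((frk, best))
            used_rev.add(best)

    report = {"forward_nucleotides": len(fwd), "paired": len(pairs)}
    if len(pairs) < 0.5 * len(fwd):
        raise DuplexInferenceError(
            f"only {len(pairs)}/{len(fwd)} forward nucleotides pairable", report)

    # antiparallel check: partner positions must strictly decrease in
    # reverse-chain order as the forward position increases
    rev_pos = {rk: i for i, rk in enumerate(rev)}
    partner_order = [rev_pos[rrk] for _, rrk in pairs]
    if any(b >= a for a, b in zip(partner_order, partner_order[1:])):
        raise DuplexInferenceError("strands are not antiparallel", report)

    fwd_ids = [rk[1] for rk in fwd]
    if dyad_forward_residue not in fwd_ids:
        raise DuplexInferenceError(
            f"dyad residue {dyad_forward_residue} absent from chain {forward_chain}", report)
    return DuplexMap(pairs=pairs, forward_residues=fwd,
                     dyad_forward_index=fwd_ids.index(dyad_forward_residue),
                     shl_period_bp=shl_period_bp)
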