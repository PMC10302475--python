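"""Protein-DNA contact detection, base-specific barcodes, persistence rates.

Three non-covalent contact classes are detected geometrically per frame:
hydrogen bonds (donor-acceptor heavy-atom distance, with a D-H...A angle
check whenever hydrogens are present), hydrophobic contacts between apolar
carbons, and ionic contacts between protein cationic nitrogens and DNA
phosphate oxygens.  A contact is *base-specific* when the DNA-side atom
belongs to the nucleobase (not sugar, not phosphate) — the dichotomy that
separates sequence reading from backbone binding.

Structures without hydrogens (crystal/cryo-EM inputs, reduced synthetic
fixtures) fall back to distance-only hydrogen bonds with donor/acceptor
typing taken from residue templates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import ArgumentError
from .model_io import Atom, NUCLEOTIDE_NAMES, Structure, Trajectory

CONTACT_CLASSES = ("hbond", "hydrophobic", "ionic")

#: residues of interest, numbered as in the reference Sox11:DNA complex
DEFAULT_RESIDUES_OF_INTEREST = (51, 54, 56, 57, 118)

# --- residue templates -----------------------------------------------------
# donors/acceptors: heavy atoms carrying/accepting polar hydrogens;
# apolar: carbons not bonded to N or O; cation: positively chargeable N.

_PROTEIN_TEMPLATES: dict[str, dict[str, set[str]]] = {
    "ARG": {"donor": {"NE", "NH1", "NH2", "N"}, "acceptor": {"O"},
            "apolar": {"CB", "CG"}, "cation": {"NE", "NH1", "NH2"}},
    "LYS": {"donor": {"NZ", "N"}, "acceptor": {"O"},
            "apolar": {"CB", "CG", "CD"}, "cation": {"NZ"}},
    "HIS": {"donor": {"ND1", "NE2", "N"}, "acceptor": {"ND1", "NE2", "O"},
            "apolar": {"CB"}, "cation": {"ND1", "NE2"}},
    "ASN": {"donor": {"ND2", "N"}, "acceptor": {"OD1", "O"},
            "apolar": {"CB"}, "cation": set()},
    "GLN": {"donor": {"NE2", "N"}, "acceptor": {"OE1", "O"},
            "apolar": {"CB", "CG"}, "cation": set()},
    "PHE": {"donor": {"N"}, "acceptor": {"O"},
            "apolar": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"}, "cation": set()},
    "MET": {"donor": {"N"}, "acceptor": {"O"},
            "apolar": {"CB", "CG", "CE"}, "cation": set()},
    "TYR": {"donor": {"OH", "N"}, "acceptor": {"OH", "O"},
            "apolar": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"}, "cation": set()},
    "SER": {"donor": {"OG", "N"}, "acceptor": {"OG", "O"}, "apolar": set(), "cation": set()},
    "THR": {"donor": {"OG1", "N"}, "acceptor": {"OG1", "O"},
            "apolar": {"CG2"}, "cation": set()},
    "ASP": {"donor": {"N"}, "acceptor": {"OD1", "OD2", "O"}, "apolar": {"CB"}, "cation": set()},
    "GLU": {"donor": {"N"}, "acceptor": {"OE1", "OE2", "O"},
            "apolar": {"CB", "CG"}, "cation": set()},
    "TRP": {"donor": {"NE1", "N"}, "acceptor": {"O"},
            "apolar": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"}, "cation": set()},
    "ALA": {"donor": {"N"}, "acceptor": {"O"}, "apolar": {"CB"}, "cation": set()},
    "VAL": {"donor": {"N"}, "acceptor": {"O"}, "apolar": {"CB", "CG1", "CG2"}, "cation": set()},
    "LEU": {"donor": {"N"}, "acceptor": {"O"},
            "apolar": {"CB", "CG", "CD1", "CD2"}, "cation": set()},
    "ILE": {"donor": {"N"}, "acceptor": {"O"},
            "apolar": {"CB", "CG1", "CG2", "CD1"}, "cation": set()},
    "GLY": {"donor": {"N"}, "acceptor": {"O"}, "apolar": set(), "cation": set()},
    "PRO": {"donor": set(), "acceptor": {"O"}, "apolar": {"CB", "CG"}, "cation": set()},
}

#: nucleobase heavy atoms per nucleotide (defines base-specificity)
BASE_ATOMS: dict[str, set[str]] = {
    "DA": {"N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4"},
    "DG": {"N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4"},
    "DT": {"N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6"},
    "DC": {"N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6"},
}

_DNA_TEMPLATES: dict[str, dict[str, set[str]]] = {
    "DA": {"donor": {"N6"}, "acceptor": {"N1", "N3", "N7"}, "apolar": set()},
    "DG": {"donor": {"N1", "N2"}, "acceptor": {"O6", "N3", "N7"}, "apolar": set()},
    "DT": {"donor": {"N3"}, "acceptor": {"O2", "O4"}, "apolar": {"C5", "C7"}},
    "DC": {"donor": {"N4"}, "acceptor": {"O2", "N3"}, "apolar": {"C5"}},
}
# sugar/phosphate typing shared by all nucleotides; C2' is the only sugar
# carbon not bonded to oxygen
_DNA_BACKBONE = {
    "acceptor": {"OP1", "OP2", "O1P", "O2P", "O3'", "O4'", "O5'"},
    "apolar": {"C2'"},
    "phosphate_o": {"OP1", "OP2", "O1P", "O2P"},
}

for _short, _full in (("A", "DA"), ("T", "DT"), ("G", "DG"), ("C", "DC")):
    _DNA_TEMPLATES[_short] = _DNA_TEMPLATES[_full]
    BASE_ATOMS[_short] = BASE_ATOMS[_full]


def _dna_role(atom: Atom) -> dict[str, bool]:
    t = _DNA_TEMPLATES.get(atom.residue_name)
    if t is None:
        return {}
    name = atom.atom_name
    return {
        "donor": name in t["donor"],
        "acceptor": name in t["acceptor"] or name in _DNA_BACKBONE["acceptor"],
        "apolar": name in t["apolar"] or name in _DNA_BACKBONE["apolar"],
        "phosphate_o": name in _DNA_BACKBONE["phosphate_o"],
        "base": name in BASE_ATOMS[atom.residue_name],
    }


def _protein_role(atom: Atom) -> dict[str, bool]:
    t = _PROTEIN_TEMPLATES.get(atom.residue_name)
    if t is None:
        return {}
    name = atom.atom_name
    return {"donor": name in t["donor"], "acceptor": name in t["acceptor"],
            "apolar": name in t["apolar"], "cation": name in t["cation"]}


@dataclass(frozen=True)
class ContactCriteria:
    """Geometric thresholds for the three contact classes."""

    hbond_da_max: float = 3.5       # Å, donor-acceptor heavy-atom
    hbond_angle_min: float = 120.0  # degrees, D-H...A (when H present)
    hydrophobic_cc_max: float = 4.4  # Å, apolar carbon-carbon
    ionic_max: float = 4.0          # Å, cation N to phosphate O

    def __post_init__(self):
        if min(self.hbond_da_max, self.hydrophobic_cc_max, self.ionic_max) <= 0:
            raise ArgumentError("distance thresholds must be positive")
        if not 0 < self.hbond_angle_min <= 180:
            raise ArgumentError("hbond_angle_min must be in (0, 180]")


@dataclass(frozen=True)
class ContactEvent:
    frame_index: int
    protein_residue: tuple[str, int, str]
    dna_residue: tuple[str, int, str]
    contact_class: str
    base_specific: bool


def _hydrogens_on(structure: Structure, donor: Atom) -> list[Atom]:
    out = []
    for a in structure.atoms:
        if (a.element == "H" and a.chain_id == donor.chain_id
                and a.residue_id == donor.residue_id
                and np.linalg.norm(a.position - donor.position) <= 1.25):
            out.append(a)
    return out


def _hbond_geometry_ok(structure: Structure, donor: Atom, acceptor: Atom,
                       criteria: ContactCriteria) -> bool:
    hydrogens = _hydrogens_on(structure, donor)
    if not hydrogens:
        return True                         # hydrogen-free fallback
    for h in hydrogens:
        dh = donor.position - h.position
        ah = acceptor.position - h.position
        cosang = np.dot(dh, ah) / (np.linalg.norm(dh) * np.linalg.norm(ah))
        angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        if angle >= criteria.hbond_angle_min:
            return True
    return False


def detect_contacts(frame: Structure, protein_sel: list[Atom], dna_sel: list[Atom],
                    criteria: ContactCriteria = ContactCriteria(),
                    frame_index: int = 0) -> list[ContactEvent]:
    """All qualifying protein-DNA contacts in one frame.

    Events are deduplicated to one per (residue pair, class, base-specific
    flag, frame).  Selections must be non-empty and disjoint.
    """
    if not protein_sel or not dna_sel:
        raise ArgumentError("selections must be non-empty")
    if {a.key for a in protein_sel} & {a.key for a in dna_sel}:
        raise ArgumentError("protein and DNA selections must be disjoint")

    dna_heavy = [a for a in dna_sel if a.element != "H"]
    prot_heavy = [a for a in protein_sel if a.element != "H"]
    dna_pos = np.array([a.position for a in dna_heavy])
    tree = cKDTree(dna_pos)
    cutoff = max(criteria.hbond_da_max, criteria.hydrophobic_cc_max, criteria.ionic_max)

    events: set[ContactEvent] = set()
    for pa in prot_heavy:
        proles = _protein_role(pa)
        if not proles or not any(proles.values()):
            continue
        for j in tree.query_ball_point(pa.position, cutoff):
            da = dna_heavy[j]
            droles = _dna_role(da)
            if not droles:
                continue
            d = float(np.linalg.norm(pa.position - da.position))
            pair = (pa.residue_key, da.residue_key)
            if d <= criteria.hbond_da_max:
                if proles["donor"] and droles["acceptor"] and \
                        _hbond_geometry_ok(frame, pa, da, criteria):
                    events.add(ContactEvent(frame_index, *pair, "hbond", droles["base"]))
                if proles["acceptor"] and droles["donor"]:
                    events.add(ContactEvent(frame_index, *pair, "hbond", droles["base"]))
            if d <= criteria.hydrophobic_cc_max and proles["apolar"] and droles["apolar"] \
                    and pa.element == "C" and da.element == "C":
                events.add(ContactEvent(frame_index, *pair, "hydrophobic", droles["base"]))
            if d <= criteria.ionic_max and proles["cation"] and droles["phosphate_o"]:
                events.add(ContactEvent(frame_index, *pair, "ionic", droles["base"]))
    return sorted(events, key=lambda e: (e.protein_residue, e.dna_residue,
                                         e.contact_class, e.base_specific))


def chain_atoms(structure: Structure, chain_id: str) -> list[Atom]:
    """All atoms of one chain, in structure order."""
    return [a for a in structure.atoms if a.chain_id == chain_id]


def dna_atoms(structure: Structure) -> list[Atom]:
    return [a for a in structure.atoms if a.residue_name in NUCLEOTIDE_NAMES]


def protein_atoms(structure: Structure) -> list[Atom]:
    return [a for a in structure.atoms if a.residue_name in _PROTEIN_TEMPLATES]


@dataclass
class Barcode:
    """Residue x frame presence matrices per (class, base-specific flag).

    Row means are the persistence rates printed next to barcode plots.
    """

    residues: list[int]                       # protein residue ids of interest
    frame_indices: list[int]
    presence: dict[tuple[str, bool], np.ndarray]   # (class, base_specific) -> bool (R, T)

    def persistence(self, contact_class: str, base_specific: bool) -> np.ndarray:
        return self.presence[(contact_class, base_specific)].mean(axis=1)


def barcode(traj: Trajectory, protein_sel_fn, dna_sel_fn,
            criteria: ContactCriteria = ContactCriteria(),
            residues_of_interest=DEFAULT_RESIDUES_OF_INTEREST) -> Barcode:
    """Contact barcode over the analyzed frames of a trajectory.

    ``protein_sel_fn`` / ``dna_sel_fn`` map a frame Structure to the atom
    lists to probe (e.g. :func:`protein_atoms` / :func:`dna_atoms`).
    """
    idx = traj.analyzed_indices()
    if not idx:
        raise ArgumentError("no analyzed frames")
    residues = list(residues_of_interest)
    first_prot = protein_sel_fn(traj.frames[idx[0]])
    present_ids = {a.residue_id for a in first_prot}
    missing = [r for r in residues if r not in present_ids]
    if missing:
        raise ArgumentError(f"residues of interest {missing} absent from protein selection")

    mats = {(c, b): np.zeros((len(residues), len(idx)), dtype=bool)
            for c in CONTACT_CLASSES for b in (False, True)}
    for t, fi in enumerate(idx):
        frame = traj.frames[fi]
        events = detect_contacts(frame, protein_sel_fn(frame), dna_sel_fn(frame),
                                 criteria, frame_index=fi)
        for e in events:
            rid = e.protein_residue[1]
            if rid in residues:
                mats[(e.contact_class, e.base_specific)][residues.index(rid), t] = True
    return Barcode(residues=residues, frame_indices=idx, presence=mats)


def persistence_report(bc: Barcode) -> pd.DataFrame:
    """Long-form table (residue, class, base_specific, persistence); rows with
    zero presence are dropped.  Rates are unrounded."""
    rows = []
    for (cls, base), mat in sorted(bc.presence.items()):
        rates = mat.mean(axis=1)
        for rid, rate in zip(bc.residues, rates):
            if rate > 0:
                rows.append({"residue": rid, "contact_class": cls,
                             "base_specific": base, "persistence": float(rate)})
    return pd.DataFrame(rows, columns=["residue", "contact_class",
                                       "base_specific", "persistence"])
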