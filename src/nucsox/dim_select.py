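"""Bound-compatible conformer selection and docking-restraint emission.

Step 2 of the dynamic integrative modeling protocol: from an unbiased
trajectory of the free (motif-engineered) nucleosome, isolate the frame
whose recognition-window phosphates fit the Sox-bound DNA reference best
(lowest P-RMSD), then emit the reference protein-DNA distances as
restraints for an external docking/refinement engine.  Refinement itself is
out of scope — the contract ends at a valid restraint file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .errors import ArgumentError, SelectionError
from .geometry import p_rmsd
from .model_io import DuplexMap, SelectionSpec, Structure, Trajectory

#: FM-wedge residues of the reference Sox numbering
DEFAULT_PROTEIN_RESIDUES = (56, 57)
#: dyad-relative forward nucleotides anchoring the three sites
DEFAULT_NUCLEOTIDES = (0, 20, 41)


@dataclass(frozen=True)
class ConformerPick:
    frame_index: int
    p_rmsd: float
    site: str
    selection: SelectionSpec


def select_conformer(traj: Trajectory, reference: Structure,
                     selection: SelectionSpec, site: str = "",
                     fit_selection=None) -> ConformerPick:
    """Argmin of per-frame P-RMSD over analyzed frames; ties -> earliest frame."""
    best_i, best_v = None, None
    for i in traj.analyzed_indices():
        v = p_rmsd(traj.frames[i], reference, selection, fit_selection=fit_selection)
        if best_v is None or v < best_v - 1e-12:
            best_i, best_v = i, v
    if best_i is None:
        raise ArgumentError("trajectory has no analyzed frames")
    return ConformerPick(frame_index=best_i, p_rmsd=float(best_v),
                         site=site, selection=selection)


@dataclass(frozen=True)
class Restraint:
    protein_residue: int
    nucleotide_dyad_relative: int
    distance: float                 # Å, min heavy-atom distance in the reference
    tolerance: float

    def __post_init__(self):
        if self.distance <= 0:
            raise ArgumentError("restraint distance must be positive")


@dataclass
class RestraintSet:
    restraints: list[Restraint]
    source_reference_id: str = ""
    protein_chain: str = ""
    nucleotide_resids: dict[int, tuple[str, int]] | None = None  # dyad-rel -> (chain, resid)

    def __post_init__(self):
        seen = set()
        for r in self.restraints:
            k = (r.protein_residue, r.nucleotide_dyad_relative)
            if k in seen:
                raise ArgumentError(f"duplicate restraint pair {k}")
            seen.add(k)

    def __len__(self):
        return len(self.restraints)


def _residue_heavy_coords(structure: Structure, chain_id: str, residue_id: int) -> np.ndarray:
    pts = [a.position for a in structure.atoms
           if a.chain_id == chain_id and a.residue_id == residue_id and a.element != "H"]
    if not pts:
        raise SelectionError(f"residue {residue_id} of chain {chain_id} not found")
    return np.array(pts)


def build_restraints(reference_complex: Structure, duplex: DuplexMap,
                     protein_chain: str,
                     protein_residues=DEFAULT_PROTEIN_RESIDUES,
                     nucleotides=DEFAULT_NUCLEOTIDES,
                     tolerance: float = 0.5,
                     reference_id: str = "") -> RestraintSet:
    """One restraint per (protein residue x nucleotide).

    The target distance is the minimum heavy-atom distance measured between
    the pair in the reference complex — a minimal-assumption, auditable
    stand-in for the unspecified anchor atoms of crystal-derived distances.
    """
    out = []
    nuc_resids: dict[int, tuple[str, int]] = {}
    for rel in nucleotides:
        fk = duplex.forward_key_at(rel)
        nuc_resids[rel] = (fk[0], fk[1])
    for pr in protein_residues:
        ppts = _residue_heavy_coords(reference_complex, protein_chain, pr)
        for rel in nucleotides:
            chain, rid = nuc_resids[rel]
            npts = _residue_heavy_coords(reference_complex, chain, rid)
            d = float(np.min(np.linalg.norm(ppts[:, None, :] - npts[None, :, :], axis=2)))
            out.append(Restraint(pr, rel, d, tolerance))
    return RestraintSet(out, source_reference_id=reference_id,
                        protein_chain=protein_chain, nucleotide_resids=nuc_resids)


def export_restraints(rset: RestraintSet, dialect: str, path=None) -> str:
    """Serialize restraints as ``tsv`` or CNS/AIR-style ``cns_tbl`` text.

    Output is byte-stable for a fixed input (no timestamps).  Returns the
    text; also writes it to ``path`` when given.
    """
    if not rset.restraints:
        raise ArgumentError("empty restraint set")
    if dialect == "tsv":
        buf = io.StringIO()
        buf.write("protein_residue\tnucleotide_dyad_relative\tdistance_A\ttolerance_A\n")
        for r in rset.restraints:
            buf.write(f"{r.protein_residue}\t{r.nucleotide_dyad_relative}\t"
                      f"{r.distance:.3f}\t{r.tolerance:.3f}\n")
        text = buf.getvalue()
    elif dialect == "cns_tbl":
        lines = []
        for r in rset.restraints:
            chain, rid = ("", r.nucleotide_dyad_relative)
            if rset.nucleotide_resids and r.nucleotide_dyad_relative in rset.nucleotide_resids:
                chain, rid = rset.nucleotide_resids[r.nucleotide_dyad_relative]
            psel = f"(resid {r.protein_residue}" + \
                   (f" and segid {rset.protein_chain})" if rset.protein_chain else ")")
            nsel = f"(resid {rid}" + (f" and segid {chain})" if chain else ")")
            lines.append(f"assign {psel} {nsel} "
                         f"{r.distance:.3f} {r.tolerance:.3f} {r.tolerance:.3f}")
        text = "\n".join(lines) + "\n"
    else:
        raise ArgumentError(f"unknown dialect {dialect!r}")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_restraints_tsv(source) -> RestraintSet:
    """Parse restraints previously written with the ``tsv`` dialect."""
    text = source if isinstance(source, str) and "\n" in source else open(source).read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("protein_residue"):
        raise ArgumentError("not a restraint TSV (missing header)")
    out = []
    for ln in lines[1:]:
        pr, rel, d, tol = ln.split("\t")
        out.append(Restraint(int(pr), int(rel), float(d), float(tol)))
    return RestraintSet(out)
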