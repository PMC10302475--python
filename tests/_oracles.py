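"""Independent reference implementations used to cross-check the package.

These deliberately avoid the code paths they validate: superposition via
Horn's quaternion eigenvalue method (the package uses SVD-based Kabsch),
contact detection via a plain all-pairs double loop (the package uses a
KD-tree), motif scanning via a naive sliding window, and groove widths via
an exhaustive cross-strand phosphate scan.
"""

from __future__ import annotations

import numpy as np

from nucsox.contacts import _dna_role, _protein_role, _hbond_geometry_ok


def quaternion_rmsd(mobile: np.ndarray, reference: np.ndarray) -> float:
    """Optimal proper-rotation RMSD via Horn's quaternion method."""
    a = mobile - mobile.mean(axis=0)
    b = reference - reference.mean(axis=0)
    m = a.T @ b
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    e2 = (np.sum(a * a) + np.sum(b * b) - 2.0 * lam) / len(a)
    return float(np.sqrt(max(e2, 0.0)))


def brute_force_contacts(frame, protein_sel, dna_sel, criteria):
    """All-pairs O(n^2) contact detection with the same criteria.

    Returns the deduplicated event tuple set
    (protein_residue, dna_residue, class, base_specific).
    """
    events = set()
    for pa in protein_sel:
        if pa.element == "H":
            continue
        pr = _protein_role(pa)
        if not pr:
            continue
        for da in dna_sel:
            if da.element == "H":
                continue
            dr = _dna_role(da)
            if not dr:
                continue
            d = float(np.linalg.norm(pa.position - da.position))
            pair = (pa.residue_key, da.residue_key)
            if d <= criteria.hbond_da_max:
                if pr["donor"] and dr["acceptor"] and \
                        _hbond_geometry_ok(frame, pa, da, criteria):
                    events.add((*pair, "hbond", dr["base"]))
                if pr["acceptor"] and dr["donor"]:
                    events.add((*pair, "hbond", dr["base"]))
            if d <= criteria.hydrophobic_cc_max and pr["apolar"] and dr["apolar"] \
                    and pa.element == "C" and da.element == "C":
                events.add((*pair, "hydrophobic", dr["base"]))
            if d <= criteria.ionic_max and pr["cation"] and dr["phosphate_o"]:
                events.add((*pair, "ionic", dr["base"]))
    return events


def naive_motif_scan(sequence: str, motif: str) -> list[int]:
    """Sliding-window exact matcher."""
    return [i for i in range(len(sequence) - len(motif) + 1)
            if sequence[i:i + len(motif)] == motif]


def exhaustive_groove_scan(structure, duplex_map) -> dict[int, float]:
    """Minimum cross-strand P-P distance per forward position.

    The minor groove is the narrower groove, so for near-canonical B-DNA
    the global cross-strand minimum from each forward phosphate tracks it.
    """
    fwd_p = {}
    rev_p = []
    rev_chains = {duplex_map.partner(rk)[0] for rk in duplex_map.forward_residues
                  if duplex_map.partner(rk) is not None}
    for a in structure.atoms:
        if a.atom_name != "P":
            continue
        if a.chain_id in rev_chains:
            rev_p.append(a.position)
        else:
            fwd_p[a.residue_key] = a.position
    out = {}
    for rk in duplex_map.forward_residues:
        if rk in fwd_p and rev_p:
            pos = duplex_map.dyad_relative(rk)
            out[pos] = min(float(np.linalg.norm(fwd_p[rk] - p)) for p in rev_p)
    return out


def rigid_transform_structure(structure, seed=0):
    """Apply a random proper rotation + translation to every atom."""
    rng = np.random.default_rng(seed)
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    t = rng.normal(scale=20.0, size=3)
    return structure.with_coords(structure.coords() @ q.T + t)
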