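"""Sequence-level motif engineering and superhelical-location mapping.

The Sox consensus ``5'-GGACAATGGAGG-3'`` (core recognition heptamer
``GACAATG``, cognate ``TTGT`` on the complementary strand) is engineered
into the Widom-601 nucleosome positioning sequence at dyad-relative
windows.  Position 0 is the dyad nucleotide on the forward strand; windows
are inclusive on both ends, negative indices run toward the 5' end.
Superhelical locations (SHLs) step outward from the dyad in ~10-bp periods.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from Bio.Seq import Seq
from Bio import SeqIO

from .errors import ArgumentError

ALPHABET = set("ACGT")

#: the engineered Sox consensus sequence
SOX_CONSENSUS = "GGACAATGGAGG"
#: the 7-nt recognition window used for phosphate-RMSD measurements
SOX_CORE_7NT = "GACAATG"
#: the cognate Sox motif read on the complementary strand
SOX_COGNATE = "TTGT"

#: dyad-relative motif windows of the triple-insert design (inclusive)
MOTIF_WINDOWS = ((-4, 7), (16, 27), (37, 48))
#: dyad-relative 7-nt phosphate windows at the dyad, SHL2 and SHL4 sites
PRMSD_WINDOWS = {"dyad": (-3, 3), "SHL2": (17, 23), "SHL4": (38, 44)}


@dataclass(frozen=True)
class NucleotideSequence:
    residues: str
    name: str = ""

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ArgumentError("sequence must be non-empty")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ArgumentError(f"invalid nucleotides {sorted(bad)} in {self.name or 'sequence'}")

    def __len__(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "NucleotideSequence":
        return NucleotideSequence(str(Seq(self.residues).reverse_complement()),
                                  name=f"{self.name}_rc")


@dataclass(frozen=True)
class MotifPlacement:
    """A motif and its inclusive dyad-relative window."""

    motif: NucleotideSequence
    dyad_relative_start: int
    dyad_relative_end: int

    def __post_init__(self):
        if self.dyad_relative_end - self.dyad_relative_start + 1 != len(self.motif):
            raise ArgumentError("placement window length must equal motif length")


@dataclass(frozen=True)
class MotifHit:
    start: int                      # absolute 0-based offset
    dyad_relative: int | None = None


def insert_motif(seq: NucleotideSequence, dyad_index: int,
                 placement: MotifPlacement) -> NucleotideSequence:
    """Replace the placement window of ``seq`` with the motif (length preserved)."""
    lo = dyad_index + placement.dyad_relative_start
    hi = dyad_index + placement.dyad_relative_end
    if lo < 0 or hi >= len(seq):
        raise ArgumentError(
            f"window {placement.dyad_relative_start}..{placement.dyad_relative_end} "
            f"(absolute {lo}..{hi}) outside sequence of length {len(seq)}")
    s = seq.residues
    return NucleotideSequence(s[:lo] + placement.motif.residues + s[hi + 1:],
                              name=seq.name)


def scan_motif(seq: NucleotideSequence, motif: NucleotideSequence,
               dyad_index: int | None = None,
               include_reverse_complement: bool = False) -> list[MotifHit]:
    """All exact (possibly overlapping) forward-strand matches, ascending.

    With ``include_reverse_complement`` the reverse complement of the motif
    is scanned too (hit positions still refer to the forward strand).
    """
    if len(motif) == 0:
        raise ArgumentError("motif must be non-empty")
    if len(motif) > len(seq):
        raise ArgumentError("motif longer than sequence")
    needles = [motif.residues]
    if include_reverse_complement:
        rc = motif.reverse_complement().residues
        if rc not in needles:
            needles.append(rc)
    starts = sorted({i for n in needles for i in range(len(seq) - len(n) + 1)
                     if seq.residues.startswith(n, i)})
    return [MotifHit(i, None if dyad_index is None else i - dyad_index)
            for i in starts]


def map_shl(dyad_relative_index: int, period_bp: float = 10.0) -> tuple[float, int]:
    """Dyad-relative nucleotide index -> (real SHL, nearest integer SHL).

    Ties at half-periods round toward zero.
    """
    if period_bp <= 0:
        raise ArgumentError("period_bp must be positive")
    if abs(dyad_relative_index) > 80:
        raise ArgumentError("|dyad_relative_index| must be <= 80")
    real = dyad_relative_index / period_bp
    import math
    nearest = int(math.copysign(math.ceil(abs(real) - 0.5), real))
    return real, nearest


def validate_construct(construct: NucleotideSequence, core: NucleotideSequence,
                       motif: NucleotideSequence) -> dict:
    """Exact-string report: length, motif starts, core location, flank lengths."""
    hits = [h.start for h in scan_motif(construct, motif)] if len(motif) <= len(construct) else []
    core_at = construct.residues.find(core.residues)
    flanks = None
    if core_at >= 0:
        flanks = (core_at, len(construct) - core_at - len(core))
    return {
        "length": len(construct),
        "motif_starts": hits,
        "core_found_at": core_at if core_at >= 0 else None,
        "flank_lengths": flanks,
    }


def load_construct(name: str) -> NucleotideSequence:
    """Load one of the bundled designed constructs by record id.

    Available ids: ``Sox6-SHL0``, ``Sox6-SHL2``, ``Sox6-SHL4``,
    ``Sox6-SHL024`` (the 255-bp titration constructs) and
    ``mutated-601-core`` (the triple-motif core as printed, 144 nt).
    """
    path = resources.files("nucsox.data") / "constructs.fasta"
    with path.open() as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id == name:
                return NucleotideSequence(str(rec.seq).upper(), name=rec.id)
    raise ArgumentError(f"unknown construct {name!r}")


def list_constructs() -> list[str]:
    path = resources.files("nucsox.data") / "constructs.fasta"
    with path.open() as fh:
        return [rec.id for rec in SeqIO.parse(fh, "fasta")]


def read_sequence(path, name: str | None = None) -> NucleotideSequence:
    """Read a FASTA (first record) or plain-text sequence file."""
    with open(path) as fh:
        text = fh.read()
    if text.lstrip().startswith(">"):
        from io import StringIO
        rec = next(SeqIO.parse(StringIO(text), "fasta"))
        return NucleotideSequence(str(rec.seq).upper(), name=name or rec.id)
    seq = "".join(text.split()).upper()
    return NucleotideSequence(seq, name=name or "")
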