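"""Sequence primitives, CRISPR effector definitions and PAM/protospacer site arithmetic.

Coordinate conventions used throughout the package
--------------------------------------------------
* All internal coordinates are 0-based, half-open on the + strand of the
  reference/amplicon.  Human-readable reports convert to 1-based inclusive.
* Protospacer offsets are 0-based in the 5'->3' direction *of the protospacer
  strand* (the strand the guide RNA base-pairs with is the opposite one; the
  protospacer reads like the spacer).  Two 1-based numbering schemes are
  derived from this for reports:

  - PAM-proximal numbering (seed logic): position 1 is the protospacer base
    nearest the PAM.  For a 5' PAM effector (AsCas12a) this is the 5' end of
    the protospacer; for a 3' PAM effector (SpCas9) it is the 3' end.
  - PAM-distal numbering (adenine-base-editor window): position 1 is the base
    farthest from the PAM.  The canonical ABE editing window is positions
    3-9 in this numbering.

* ``N`` in a reference sequence never matches any PAM or protospacer base.
  This is deliberately conservative: ambiguous reference stretches cannot
  spawn phantom candidate sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "IUPAC",
    "NucSequence",
    "EffectorSpec",
    "GuideSite",
    "EFFECTOR_PRESETS",
    "Substitution",
    "Deletion",
    "Insertion",
    "WildType",
    "Mutation",
    "revcomp",
    "iupac_match",
    "iupac_base_match",
    "find_pam_sites",
    "apply_mutation",
    "read_fasta",
    "write_fasta",
]

# IUPAC degenerate nucleotide classes (DNA alphabet).
IUPAC: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")
_VALID_SEQ = frozenset("ACGTN")


@dataclass(frozen=True)
class NucSequence:
    """An uppercase DNA sequence over {A,C,G,T,N} with a text label."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        norm = self.seq.upper()
        if not norm:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(norm) - _VALID_SEQ
        if bad:
            raise ValueError(
                f"record {self.id!r} contains non-ACGTN characters: {sorted(bad)}"
            )
        object.__setattr__(self, "seq", norm)

    def __len__(self) -> int:
        return len(self.seq)


def revcomp(s: Union[str, NucSequence]) -> Union[str, NucSequence]:
    """Watson-Crick reverse complement; ``N`` maps to ``N``.

    Accepts a plain string or a :class:`NucSequence` and returns the same type.
    """
    if isinstance(s, NucSequence):
        return replace(s, seq=_revcomp_str(s.seq))
    return _revcomp_str(s)


def _revcomp_str(s: str) -> str:
    up = s.upper()
    for ch in up:
        if ch not in IUPAC:
            raise ValueError(f"non-IUPAC character {ch!r} in sequence")
    return up.translate(_COMPLEMENT)[::-1]


def iupac_base_match(pattern_char: str, base: str) -> bool:
    """True iff ``base`` (a concrete A/C/G/T) belongs to the IUPAC class.

    A reference ``N`` matches nothing (conservative ambiguity handling).
    """
    try:
        klass = IUPAC[pattern_char]
    except KeyError:
        raise ValueError(f"invalid IUPAC pattern character {pattern_char!r}")
    return base in "ACGT" and base in klass


def iupac_match(pattern: str, seq: str) -> bool:
    """Match a concrete DNA string against an equal-length IUPAC pattern."""
    if len(pattern) != len(seq):
        raise ValueError(
            f"pattern length {len(pattern)} != sequence length {len(seq)}"
        )
    return all(iupac_base_match(p, b) for p, b in zip(pattern, seq))


@dataclass(frozen=True)
class EffectorSpec:
    """Recognition model of a CRISPR effector.

    Parameters
    ----------
    pam : IUPAC pattern of the protospacer-adjacent motif.
    pam_side : ``"five_prime"`` if the PAM sits 5' of the protospacer
        (Cas12a family) or ``"three_prime"`` (Cas9 family).
    spacer_len : protospacer length in nt.
    seed_len : length of the PAM-proximal seed region in nt, where mismatches
        most strongly abolish cleavage.
    cut_offset : nominal cut position, counted in nt from the PAM-proximal
        protospacer end; the cut falls *after* protospacer position
        ``cut_offset`` in PAM-proximal numbering.  Only used to centre the
        indel-calling window; configurable.
    """

    name: str
    pam: str
    pam_side: str
    spacer_len: int
    seed_len: int
    cut_offset: int

    def __post_init__(self) -> None:
        pam = self.pam.upper()
        for ch in pam:
            if ch not in IUPAC:
                raise ValueError(f"invalid IUPAC character {ch!r} in PAM {pam!r}")
        object.__setattr__(self, "pam", pam)
        if self.pam_side not in ("five_prime", "three_prime"):
            raise ValueError(f"pam_side must be five_prime/three_prime, got {self.pam_side!r}")
        if not (self.spacer_len > self.seed_len > 0):
            raise ValueError("require spacer_len > seed_len > 0")
        if not (0 <= self.cut_offset <= self.spacer_len):
            raise ValueError("cut_offset outside protospacer")

    @property
    def pam_len(self) -> int:
        return len(self.pam)

    def seed_slice(self) -> slice:
        """Seed region as a slice in 0-based 5'->3' protospacer offsets."""
        if self.pam_side == "five_prime":
            return slice(0, self.seed_len)
        return slice(self.spacer_len - self.seed_len, self.spacer_len)

    def to_pam_proximal(self, offset5: int) -> int:
        """Convert a 0-based 5'->3' protospacer offset to 1-based PAM-proximal."""
        if self.pam_side == "five_prime":
            return offset5 + 1
        return self.spacer_len - offset5

    def to_pam_distal(self, offset5: int) -> int:
        """Convert a 0-based 5'->3' protospacer offset to 1-based PAM-distal."""
        if self.pam_side == "five_prime":
            return self.spacer_len - offset5
        return offset5 + 1

    def from_pam_distal(self, pos: int) -> int:
        """Inverse of :meth:`to_pam_distal` (1-based in, 0-based 5'->3' out)."""
        if self.pam_side == "five_prime":
            return self.spacer_len - pos
        return pos - 1


EFFECTOR_PRESETS: dict[str, EffectorSpec] = {
    # AsCas12a: 5' T-rich PAM, 23-nt protospacer, staggered cut modelled as a
    # single nominal position after PAM-proximal position 18.
    "AsCas12a": EffectorSpec(
        name="AsCas12a", pam="TTTN", pam_side="five_prime",
        spacer_len=23, seed_len=6, cut_offset=18,
    ),
    # SpCas9: 3' NGG PAM, 20-nt protospacer, blunt cut 3 nt from the PAM
    # (between protospacer positions 17/18 in 5'->3' numbering).
    "SpCas9": EffectorSpec(
        name="SpCas9", pam="NGG", pam_side="three_prime",
        spacer_len=20, seed_len=8, cut_offset=3,
    ),
}


@dataclass(frozen=True)
class GuideSite:
    """A protospacer+PAM occurrence on a reference.

    ``start``/``end`` are 0-based half-open + strand coordinates of the
    protospacer.  ``protospacer_seq`` and ``pam_seq`` read 5'->3' on the
    protospacer strand (``strand``).  ``mismatches`` holds
    ``(offset5, ref_base, guide_base)`` triples with ``offset5`` the 0-based
    5'->3' protospacer offset.
    """

    ref_id: str
    start: int
    end: int
    strand: str
    pam_seq: str
    protospacer_seq: str
    mismatches: tuple[tuple[int, str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if len(self.protospacer_seq) != self.end - self.start:
            raise ValueError("protospacer_seq length inconsistent with coordinates")
        offs = [m[0] for m in self.mismatches]
        if len(set(offs)) != len(offs):
            raise ValueError("duplicate mismatch positions")
        if any(not (0 <= o < len(self.protospacer_seq)) for o in offs):
            raise ValueError("mismatch position outside protospacer")

    # --- site geometry on the + strand of the reference -------------------
    def protospacer_interval(self) -> tuple[int, int]:
        return (self.start, self.end)

    def pam_interval(self, effector: EffectorSpec) -> tuple[int, int]:
        p = effector.pam_len
        five = self.pam_side_is_left(effector)
        return (self.start - p, self.start) if five else (self.end, self.end + p)

    def pam_side_is_left(self, effector: EffectorSpec) -> bool:
        """True if the PAM lies left of the protospacer on the + strand."""
        if self.strand == "+":
            return effector.pam_side == "five_prime"
        return effector.pam_side == "three_prime"

    def footprint(self, effector: EffectorSpec) -> tuple[int, int]:
        """Protospacer plus PAM span on the + strand."""
        ps, pe = self.pam_interval(effector)
        return (min(self.start, ps), max(self.end, pe))

    def amplicon_pos(self, offset5: int) -> int:
        """+ strand position of the protospacer base at 5'->3' offset ``offset5``."""
        if self.strand == "+":
            return self.start + offset5
        return self.end - 1 - offset5

    def pam_amplicon_pos(self, pam_index: int, effector: EffectorSpec) -> int:
        """+ strand position of PAM pattern index ``pam_index`` (0-based 5'->3'
        on the protospacer strand)."""
        ps, pe = self.pam_interval(effector)
        if self.strand == "+":
            return ps + pam_index
        return pe - 1 - pam_index

    def cut_position(self, effector: EffectorSpec) -> int:
        """Nominal cut site as a 0-based gap index on the + strand."""
        if effector.pam_side == "five_prime":
            offset5 = effector.cut_offset
        else:
            offset5 = effector.spacer_len - effector.cut_offset
        if self.strand == "+":
            return self.start + offset5
        return self.end - offset5

    def seed_positions(self, effector: EffectorSpec) -> list[int]:
        """+ strand positions of the seed-region protospacer bases."""
        sl = effector.seed_slice()
        return sorted(self.amplicon_pos(o) for o in range(sl.start, sl.stop))


def find_pam_sites(ref: NucSequence, effector: EffectorSpec) -> list[GuideSite]:
    """All positions on both strands where the effector's PAM matches and a
    full-length protospacer fits inside the reference.

    Returned sites are perfect-PAM occurrences with an empty mismatch list;
    coordinates refer to the + strand of ``ref``.  Sorted by (start, strand).
    """
    sites = list(_scan_pam_windows(ref, effector.pam, effector))
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def _scan_pam_windows(
    ref: NucSequence, pam: str, effector: EffectorSpec
) -> Iterable[GuideSite]:
    L = effector.spacer_len
    p = len(pam)
    n = len(ref.seq)
    for strand, seq in (("+", ref.seq), ("-", _revcomp_str(ref.seq))):
        for i in range(0, n - (L + p) + 1):
            if effector.pam_side == "five_prime":
                pam_obs = seq[i : i + p]
                proto = seq[i + p : i + p + L]
                proto_lo = i + p
            else:
                proto = seq[i : i + L]
                pam_obs = seq[i + L : i + L + p]
                proto_lo = i
            if not iupac_match(pam, pam_obs):
                continue
            if strand == "+":
                start = proto_lo
            else:
                start = n - (proto_lo + L)
            yield GuideSite(
                ref_id=ref.id, start=start, end=start + L, strand=strand,
                pam_seq=pam_obs, protospacer_seq=proto,
            )


# --------------------------------------------------------------------------
# Mutation descriptors shared by the enrichment model, the quantifier and the
# synthetic read generator.  Coordinates are + strand amplicon coordinates;
# deletion size is measured on the reference, insertion size on the read.
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Substitution:
    position: int
    ref: str
    alt: str


@dataclass(frozen=True)
class Deletion:
    start: int
    size: int

    @property
    def end(self) -> int:
        return self.start + self.size


@dataclass(frozen=True)
class Insertion:
    position: int  # gap index: inserted bases go before this reference position
    size: int
    seq: str = ""

    def __post_init__(self) -> None:
        if self.seq and len(self.seq) != self.size:
            raise ValueError("insertion seq length != size")


@dataclass(frozen=True)
class WildType:
    pass


Mutation = Union[Substitution, Deletion, Insertion, WildType]


def apply_mutation(seq: str, mutation: Mutation) -> str:
    """Apply one mutation descriptor to a reference string."""
    if isinstance(mutation, WildType):
        return seq
    if isinstance(mutation, Substitution):
        if not (0 <= mutation.position < len(seq)):
            raise ValueError("substitution position outside sequence")
        if seq[mutation.position] != mutation.ref:
            raise ValueError(
                f"reference base mismatch at {mutation.position}: "
                f"expected {mutation.ref}, found {seq[mutation.position]}"
            )
        return seq[: mutation.position] + mutation.alt + seq[mutation.position + 1 :]
    if isinstance(mutation, Deletion):
        if not (0 <= mutation.start and mutation.end <= len(seq)):
            raise ValueError("deletion span outside sequence")
        return seq[: mutation.start] + seq[mutation.end :]
    if isinstance(mutation, Insertion):
        if not (0 <= mutation.position <= len(seq)):
            raise ValueError("insertion position outside sequence")
        ins = mutation.seq or "A" * mutation.size
        return seq[: mutation.position] + ins + seq[mutation.position :]
    raise TypeError(f"unknown mutation type {type(mutation)!r}")


# --------------------------------------------------------------------------
# FASTA I/O (Biopython-backed; multi-record, wrapped or unwrapped, any case).
# --------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> list[NucSequence]:
    records = [
        NucSequence(id=rec.id, seq=str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: Sequence[NucSequence], path: Union[str, Path]) -> None:
    recs = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    SeqIO.write(recs, str(path), "fasta")
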