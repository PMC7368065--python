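"""Amplicon-read mutation quantification.

Reads are orientation-normalised against the amplicon, globally aligned with
affine gap penalties, and classified by whether an insertion/deletion overlaps
a window around the nominal cut site.  The locus-level outputs are the indel
frequency (%), per-position substitution profiles (for base-editor loci),
deletion/insertion size spectra, and fold increases across enrichment rounds::

    indel frequency (%) = 100 * n_indel / (n_total - n_discarded)

Indel calling is window-restricted by default (cut site +/- 3 nt; the 3-9
protospacer span for ABE loci) so that locus frequencies are not inflated by
background events elsewhere on the amplicon; full-amplicon counting is
available behind a flag.

Alignment contract: optimal global alignment under the configured scores
(gap of length k costs ``gap_open + k * gap_extend``), with deterministic
leftmost gap placement on ties.  Deletion sizes are measured on the
reference, insertion sizes on the read.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import edlib
import numpy as np
import pandas as pd

from .seqcore import (
    Deletion,
    Insertion,
    Mutation,
    NucSequence,
    Substitution,
    _revcomp_str,
)

__all__ = [
    "QuantConfig",
    "Alignment",
    "MutationCall",
    "QuantResult",
    "align_read",
    "gotoh_align",
    "call_mutation",
    "indel_frequency",
    "substitution_profile",
    "fold_increase",
    "format_fold",
    "deletion_size_spectrum",
    "insertion_size_spectrum",
    "quantify_reads",
    "read_fastq",
]

_NEG = np.int64(-(2**40))


@dataclass(frozen=True)
class QuantConfig:
    """Quantification parameters.

    window_halfwidth : nt around the nominal cut site inside which an indel
        is attributed to the locus (default 3).
    min_read_len_frac : reads shorter than this fraction of the amplicon are
        discarded (default 0.8).
    substitution_window : optional 0-based half-open amplicon interval used
        for base-editor profiling and for the substitution_only class.
    match/mismatch/gap_open/gap_extend : integer alignment scores; a gap of
        length k costs gap_open + k*gap_extend.
    full_amplicon_indels : count indels anywhere on the amplicon.
    """

    window_halfwidth: int = 3
    min_read_len_frac: float = 0.8
    substitution_window: tuple[int, int] | None = None
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -1
    full_amplicon_indels: bool = False

    def __post_init__(self) -> None:
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.mismatch >= self.match:
            raise ValueError("mismatch score must be below match score")
        if not (0.0 <= self.min_read_len_frac <= 1.0):
            raise ValueError("min_read_len_frac outside [0, 1]")


@dataclass(frozen=True)
class Alignment:
    """A global read-vs-amplicon alignment reduced to its edit operations."""

    read_id: str
    score: int
    strand: str  # orientation the read was aligned in
    ops: tuple[Mutation, ...]
    read_len: int


@dataclass(frozen=True)
class MutationCall:
    """Per-read classification.

    ``cls`` is one of ``wild_type``, ``indel``, ``substitution_only`` or
    ``discarded``; ``details`` lists every edit operation of the alignment;
    ``window_indels`` the subset of indels attributed to the calling window;
    ``reason`` explains a discard.
    """

    read_id: str
    cls: str
    details: tuple[Mutation, ...] = ()
    window_indels: tuple[Mutation, ...] = ()
    reason: str | None = None


# ---------------------------------------------------------------------------
# Affine-gap global alignment (Gotoh), numpy row-vectorised, integer scores.
# ---------------------------------------------------------------------------

def gotoh_align(
    read: str,
    ref: str,
    match: int = 2,
    mismatch: int = -3,
    gap_open: int = -5,
    gap_extend: int = -1,
) -> tuple[int, tuple[Mutation, ...]]:
    """Optimal global alignment; returns (score, edit operations).

    Three-state dynamic programme: M (aligned pair), I (insertion: read base
    against a gap), D (deletion: reference base against a gap).  Direct I<->D
    transitions are disallowed.  Traceback prefers M over D over I and gap
    extension over gap opening on score ties, which places co-optimal gaps
    leftmost on the reference.
    """
    n, m = len(read), len(ref)
    if n == 0 or m == 0:
        raise ValueError("empty read or reference")
    r = np.frombuffer(read.encode(), dtype=np.uint8)
    q = np.frombuffer(ref.encode(), dtype=np.uint8)
    go, ge = np.int64(gap_open), np.int64(gap_extend)

    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    I = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    D = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    M[0, 0] = 0
    jj = np.arange(1, m + 1, dtype=np.int64)
    D[0, 1:] = go + ge * jj
    ii = np.arange(1, n + 1, dtype=np.int64)
    I[1:, 0] = go + ge * ii

    # D within a row via a running-max ("accumulate") reformulation:
    #   D[i,j] = ge*j + max_{k<j}( M[i,k] + go - ge*k )
    karr = np.arange(0, m, dtype=np.int64)
    for i in range(1, n + 1):
        best_prev = np.maximum(np.maximum(M[i - 1], I[i - 1]), D[i - 1])
        s = np.where(r[i - 1] == q, match, mismatch).astype(np.int64)
        M[i, 1:] = best_prev[:-1] + s
        I[i, 1:] = np.maximum(M[i - 1, 1:] + go + ge, I[i - 1, 1:] + ge)
        t = M[i, :-1] + go - ge * karr
        D[i, 1:] = np.maximum.accumulate(t) + ge * jj

    end_scores = {"M": M[n, m], "D": D[n, m], "I": I[n, m]}
    state = max(("M", "D", "I"), key=lambda k: (end_scores[k], k == "M", k == "D"))
    score = int(end_scores[state])

    # traceback
    steps: list[tuple[str, int, int]] = []  # (state, i, j) after the step
    i, j = n, m
    while i > 0 or j > 0:
        steps.append((state, i, j))
        if state == "M":
            s = match if read[i - 1] == ref[j - 1] else mismatch
            target = M[i, j] - s
            if M[i - 1, j - 1] == target:
                state = "M"
            elif D[i - 1, j - 1] == target:
                state = "D"
            else:
                state = "I"
            i, j = i - 1, j - 1
        elif state == "D":
            # prefer gap extension on ties: pushes the gap start leftward
            if j > 1 and D[i, j - 1] + ge == D[i, j]:
                state = "D"
            else:
                state = "M"
            j -= 1
        else:  # I
            if i > 1 and I[i - 1, j] + ge == I[i, j]:
                state = "I"
            else:
                state = "M"
            i -= 1
    steps.reverse()

    ops: list[Mutation] = []
    for st, si, sj in steps:
        if st == "M":
            rb, qb = ref[sj - 1], read[si - 1]
            if rb != qb:
                ops.append(Substitution(sj - 1, rb, qb))
        elif st == "D":
            last = ops[-1] if ops else None
            if isinstance(last, Deletion) and last.end == sj - 1:
                ops[-1] = Deletion(last.start, last.size + 1)
            else:
                ops.append(Deletion(sj - 1, 1))
        else:  # I: read[si-1] inserted before ref position sj
            last = ops[-1] if ops else None
            if isinstance(last, Insertion) and last.position == sj:
                ops[-1] = Insertion(sj, last.size + 1, last.seq + read[si - 1])
            else:
                ops.append(Insertion(sj, 1, read[si - 1]))
    return score, tuple(ops)


def align_read(
    read: Union[str, tuple[str, str]],
    amplicon_ref: Union[str, NucSequence],
    config: QuantConfig = QuantConfig(),
) -> Alignment:
    """Orientation-normalise and globally align one read against the amplicon.

    The read orientation (forward vs reverse complement) is chosen by edit
    distance before the scored alignment, so classification is invariant to
    sequencing orientation.  Ties go to the forward orientation.
    """
    if isinstance(read, tuple):
        read_id, seq = read
    else:
        read_id, seq = "read", read
    ref = amplicon_ref.seq if isinstance(amplicon_ref, NucSequence) else amplicon_ref
    seq = seq.upper()
    fwd = edlib.align(seq, ref, mode="NW", task="distance")["editDistance"]
    rc = _revcomp_str(seq)
    rev = edlib.align(rc, ref, mode="NW", task="distance")["editDistance"]
    if rev < fwd:
        oriented, strand = rc, "-"
    else:
        oriented, strand = seq, "+"
    score, ops = gotoh_align(
        oriented, ref, config.match, config.mismatch, config.gap_open, config.gap_extend
    )
    return Alignment(read_id=read_id, score=score, strand=strand, ops=ops,
                     read_len=len(seq))


def call_mutation(
    alignment: Alignment, cut_site: int, config: QuantConfig = QuantConfig()
) -> MutationCall:
    """Classify one aligned read.

    A read is ``indel`` iff an insertion/deletion overlaps the calling window
    ``[cut_site - w, cut_site + w]`` (deletions count by span overlap;
    insertions by their gap index).  Substitutions are recorded regardless of
    class; a read with no window indel but a substitution inside the
    substitution window (or anywhere, if no window is configured) is
    ``substitution_only``.
    """
    w = config.window_halfwidth
    lo, hi = cut_site - w, cut_site + w
    window_indels = []
    for op in alignment.ops:
        if isinstance(op, Deletion):
            if config.full_amplicon_indels or (op.start < hi and op.end > lo):
                window_indels.append(op)
        elif isinstance(op, Insertion):
            if config.full_amplicon_indels or (lo <= op.position <= hi):
                window_indels.append(op)
    if window_indels:
        cls = "indel"
    else:
        subs = [op for op in alignment.ops if isinstance(op, Substitution)]
        if config.substitution_window is not None:
            a, b = config.substitution_window
            subs = [s for s in subs if a <= s.position < b]
        cls = "substitution_only" if subs else "wild_type"
    return MutationCall(
        read_id=alignment.read_id, cls=cls, details=alignment.ops,
        window_indels=tuple(window_indels),
    )


def indel_frequency(calls: Sequence[MutationCall]) -> float:
    """``100 * n_indel / (n_total - n_discarded)`` in percent."""
    used = [c for c in calls if c.cls != "discarded"]
    if not used:
        raise ValueError("all reads discarded; indel frequency undefined")
    n_indel = sum(1 for c in used if c.cls == "indel")
    return 100.0 * n_indel / len(used)


def substitution_profile(
    calls: Sequence[MutationCall],
    amplicon_ref: Union[str, NucSequence],
    window: tuple[int, int],
) -> pd.DataFrame:
    """Per-position, per-base-change percentages inside ``window``.

    For each window position and observed base change: 100 * (reads carrying
    the change) / (reads whose alignment covers the position with a base,
    i.e. not deleted there).  Columns: position (0-based amplicon),
    window_pos (1-based within the window), ref_base, alt_base, n_reads,
    n_cover, percent.
    """
    ref = amplicon_ref.seq if isinstance(amplicon_ref, NucSequence) else amplicon_ref
    lo, hi = window
    if not (0 <= lo < hi <= len(ref)):
        raise ValueError("substitution window outside amplicon")
    used = [c for c in calls if c.cls != "discarded"]
    cover = {p: 0 for p in range(lo, hi)}
    counts: dict[tuple[int, str], int] = {}
    for c in used:
        deleted = set()
        for op in c.details:
            if isinstance(op, Deletion):
                deleted.update(range(op.start, op.end))
        for p in range(lo, hi):
            if p not in deleted:
                cover[p] += 1
        for op in c.details:
            if isinstance(op, Substitution) and lo <= op.position < hi:
                key = (op.position, op.alt)
                counts[key] = counts.get(key, 0) + 1
    rows = []
    for p in range(lo, hi):
        alts = sorted({alt for (pos, alt) in counts if pos == p})
        for alt in alts or []:
            n = counts[(p, alt)]
            rows.append(
                dict(
                    position=p, window_pos=p - lo + 1, ref_base=ref[p], alt_base=alt,
                    n_reads=n, n_cover=cover[p],
                    percent=100.0 * n / cover[p] if cover[p] else float("nan"),
                )
            )
        if not alts:
            rows.append(
                dict(position=p, window_pos=p - lo + 1, ref_base=ref[p],
                     alt_base=".", n_reads=0, n_cover=cover[p], percent=0.0)
            )
    return pd.DataFrame(rows)


def fold_increase(pre_percent: float, post_percent: float) -> float:
    """post/pre frequency ratio; NaN (reported "NC") when pre is zero."""
    if pre_percent < 0 or post_percent < 0:
        raise ValueError("negative frequency")
    if pre_percent == 0:
        return float("nan")
    return post_percent / pre_percent


def format_fold(x: float) -> str:
    return "NC" if math.isnan(x) else f"{x:.2f}"


def deletion_size_spectrum(calls: Sequence[MutationCall]) -> dict[int, int]:
    """Counts of window-attributed deletions keyed by size (nt)."""
    hist: dict[int, int] = {}
    for c in calls:
        for op in c.window_indels:
            if isinstance(op, Deletion):
                hist[op.size] = hist.get(op.size, 0) + 1
    return dict(sorted(hist.items()))


def insertion_size_spectrum(calls: Sequence[MutationCall]) -> dict[int, int]:
    hist: dict[int, int] = {}
    for c in calls:
        for op in c.window_indels:
            if isinstance(op, Insertion):
                hist[op.size] = hist.get(op.size, 0) + 1
    return dict(sorted(hist.items()))


@dataclass(frozen=True)
class QuantResult:
    """Locus-level summary of one read set."""

    n_total: int
    n_indel: int
    n_wild_type: int
    n_substitution_only: int
    n_discarded: int
    indel_frequency: float
    substitution_profile: pd.DataFrame | None
    deletion_size_histogram: dict[int, int]
    insertion_size_histogram: dict[int, int]
    calls: tuple[MutationCall, ...] = field(repr=False, default=())

    def __post_init__(self) -> None:
        if (
            self.n_total
            != self.n_indel + self.n_wild_type + self.n_substitution_only + self.n_discarded
        ):
            raise ValueError("class counts do not add up to n_total")


def quantify_reads(
    reads: Iterable[tuple[str, str]],
    amplicon: NucSequence,
    cut_site: int,
    config: QuantConfig = QuantConfig(),
) -> QuantResult:
    """Align, call and summarise a read set against one amplicon locus."""
    min_len = config.min_read_len_frac * len(amplicon)
    calls: list[MutationCall] = []
    for read_id, seq in reads:
        if len(seq) < min_len:
            calls.append(MutationCall(read_id=read_id, cls="discarded",
                                      reason="too short"))
            continue
        aln = align_read((read_id, seq), amplicon, config)
        calls.append(call_mutation(aln, cut_site, config))
    n = {
        cls: sum(1 for c in calls if c.cls == cls)
        for cls in ("indel", "wild_type", "substitution_only", "discarded")
    }
    profile = (
        substitution_profile(calls, amplicon, config.substitution_window)
        if config.substitution_window is not None
        else None
    )
    return QuantResult(
        n_total=len(calls),
        n_indel=n["indel"],
        n_wild_type=n["wild_type"],
        n_substitution_only=n["substitution_only"],
        n_discarded=n["discarded"],
        indel_frequency=indel_frequency(calls),
        substitution_profile=profile,
        deletion_size_histogram=deletion_size_spectrum(calls),
        insertion_size_histogram=insertion_size_spectrum(calls),
        calls=tuple(calls),
    )


def read_fastq(path: Union[str, Path]) -> list[tuple[str, str]]:
    """Load a FASTQ (optionally gzipped) as (id, sequence) pairs."""
    from Bio import SeqIO

    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(fh, "fastq")]
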