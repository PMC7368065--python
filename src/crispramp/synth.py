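"""Synthetic test-data generation with exact truth tables.

Every pipeline stage is testable without any external data: this module
fabricates amplicon read sets with planted mutations at specified fractions
and error rates, reference sequences with planted off-target sites at
specified mismatch counts, and serial dilution series of allele pools.

Allele counts are assigned by largest-remainder rounding of the requested
fractions rather than multinomial sampling, so worked examples are exact
(a 0.077 fraction of 1000 reads is exactly 77 reads); a multinomial mode
exists for statistical tests.  The sequencing error model is substitution-only
by default so indel-frequency truth is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .offtarget import SearchParams, enumerate_offtargets
from .seqcore import (
    Deletion,
    EffectorSpec,
    IUPAC,
    Insertion,
    Mutation,
    NucSequence,
    Substitution,
    WildType,
    _revcomp_str,
    apply_mutation,
    iupac_match,
)

__all__ = [
    "ReadSetSpec",
    "PlantedSite",
    "PlantedGenomeSpec",
    "generate_reads",
    "write_fastq",
    "generate_planted_genome",
    "generate_dilution_series",
    "largest_remainder_counts",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class ReadSetSpec:
    """Specification of one synthetic amplicon read set.

    ``alleles`` lists (label, mutation, fraction); the remaining fraction is
    wild type.  ``error_rate`` is the per-base substitution probability
    applied after allele construction (capped at 5%: beyond that the reads no
    longer resemble amplicon sequencing).
    """

    amplicon: NucSequence
    alleles: tuple[tuple[str, Mutation, float], ...]
    n_reads: int
    error_rate: float = 0.0
    seed: int = 0
    counts_mode: str = "exact"  # "exact" | "multinomial"

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not (0.0 <= self.error_rate <= 0.05):
            raise ValueError("error_rate outside [0, 0.05]")
        total = sum(f for _, _, f in self.alleles)
        if total > 1.0 + 1e-12 or any(f < 0 for _, _, f in self.alleles):
            raise ValueError("allele fractions must be nonnegative and sum to <= 1")
        if self.counts_mode not in ("exact", "multinomial"):
            raise ValueError("counts_mode must be 'exact' or 'multinomial'")
        for label, mut, _ in self.alleles:
            apply_mutation(self.amplicon.seq, mut)  # validates bounds


def largest_remainder_counts(fractions: Sequence[float], n: int) -> list[int]:
    """Integer counts summing to n, proportional to ``fractions`` (which must
    sum to <= 1; the remainder is appended as a final count)."""
    fr = list(fractions) + [1.0 - sum(fractions)]
    raw = [f * n for f in fr]
    counts = [math.floor(x) for x in raw]
    short = n - sum(counts)
    order = sorted(range(len(fr)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def generate_reads(
    spec: ReadSetSpec,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Generate reads and their truth table.

    Returns ``(records, truth)`` where records are (read_id, sequence,
    quality) triples in deterministic order (allele blocks, wild type last)
    and ``truth`` tabulates per-allele label, mutation, requested fraction and
    exact count.  Byte-identical under identical seeds.
    """
    rng = np.random.default_rng(spec.seed)
    fracs = [f for _, _, f in spec.alleles]
    if spec.counts_mode == "exact":
        counts = largest_remainder_counts(fracs, spec.n_reads)
    else:
        counts = list(rng.multinomial(spec.n_reads, fracs + [1.0 - sum(fracs)]))

    blocks: list[tuple[str, Mutation, int, str]] = []
    for (label, mut, frac), cnt in zip(spec.alleles, counts[:-1]):
        blocks.append((label, mut, cnt, apply_mutation(spec.amplicon.seq, mut)))
    blocks.append(("wild_type", WildType(), counts[-1], spec.amplicon.seq))

    records: list[tuple[str, str, str]] = []
    ridx = 0
    for label, _, cnt, allele_seq in blocks:
        for _ in range(cnt):
            seq = allele_seq
            if spec.error_rate > 0:
                seq = _inject_substitution_errors(seq, spec.error_rate, rng)
            records.append((f"r{ridx:06d}_{label}", seq, "I" * len(seq)))
            ridx += 1

    truth = pd.DataFrame(
        [
            dict(label=label, mutation=repr(mut), count=cnt,
                 requested_fraction=frac)
            for (label, mut, frac), cnt in zip(
                list(spec.alleles) + [("wild_type", WildType(), 1.0 - sum(fracs))],
                counts,
            )
        ]
    )
    return records, truth


def _inject_substitution_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def write_fastq(records: Sequence[tuple[str, str, str]], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


@dataclass(frozen=True)
class PlantedSite:
    """One site to plant: mismatch count, strand, and whether its PAM is kept
    valid (a mutated-PAM plant must not appear in search output)."""

    n_mismatches: int
    strand: str = "+"
    pam_valid: bool = True


@dataclass(frozen=True)
class PlantedGenomeSpec:
    length: int
    guide: str
    effector: EffectorSpec
    planted: tuple[PlantedSite, ...]
    seed: int = 0
    max_retries: int = 50

    def __post_init__(self) -> None:
        if len(self.guide) != self.effector.spacer_len:
            raise ValueError("guide length != effector spacer_len")
        need = len(self.planted) * (self.effector.spacer_len + self.effector.pam_len + 10)
        if self.length < need + 20:
            raise ValueError(f"length {self.length} too short to plant "
                             f"{len(self.planted)} sites")


def _concretize_pam(pam: str, rng: np.random.Generator) -> str:
    return "".join(IUPAC[ch][rng.integers(len(IUPAC[ch]))] for ch in pam)


def _break_pam(pam: str, pattern: str, rng: np.random.Generator) -> str:
    """Mutate one constrained PAM base to a non-matching one."""
    constrained = [i for i, ch in enumerate(pattern) if IUPAC[ch] != "ACGT"]
    i = constrained[rng.integers(len(constrained))]
    bad = [b for b in "ACGT" if b not in IUPAC[pattern[i]]]
    return pam[:i] + bad[rng.integers(len(bad))] + pam[i + 1 :]


def generate_planted_genome(
    spec: PlantedGenomeSpec,
) -> tuple[NucSequence, pd.DataFrame]:
    """Random background with planted protospacer+PAM sites; exact truth table.

    The background is rejection-sampled so that, at a search budget equal to
    the largest planted mismatch count, the off-target scan returns exactly
    the valid-PAM planted sites — the truth table is exact by construction.
    """
    rng = np.random.default_rng(spec.seed)
    eff = spec.effector
    budget = max((p.n_mismatches for p in spec.planted), default=0)
    unit = eff.spacer_len + eff.pam_len

    for _attempt in range(spec.max_retries):
        bg = rng.choice(_BASES, size=spec.length).tobytes().decode()
        # non-overlapping slots with >= 5 nt spacing, in random order
        n_slots = len(spec.planted)
        gap = (spec.length - n_slots * unit) // (n_slots + 1)
        starts = [gap * (k + 1) + unit * k for k in range(n_slots)]
        seq = bg
        truth_rows = []
        for site_spec, pos in zip(spec.planted, starts):
            proto = list(spec.guide)
            mm_pos = rng.choice(eff.spacer_len, size=site_spec.n_mismatches,
                                replace=False)
            for i in mm_pos:
                others = [b for b in "ACGT" if b != proto[i]]
                proto[i] = others[rng.integers(3)]
            pam = _concretize_pam(eff.pam, rng)
            if not site_spec.pam_valid:
                pam = _break_pam(pam, eff.pam, rng)
            construct = pam + "".join(proto) if eff.pam_side == "five_prime" \
                else "".join(proto) + pam
            if site_spec.strand == "-":
                construct = _revcomp_str(construct)
            seq = seq[:pos] + construct + seq[pos + unit :]
            proto_off = eff.pam_len if eff.pam_side == "five_prime" else 0
            if site_spec.strand == "+":
                start = pos + proto_off
            else:
                start = pos + (unit - proto_off - eff.spacer_len)
            if site_spec.pam_valid:
                truth_rows.append(
                    dict(ref_id="planted", start=start, end=start + eff.spacer_len,
                         strand=site_spec.strand,
                         n_mismatches=int(site_spec.n_mismatches))
                )
        genome = NucSequence(id="planted", seq=seq)
        truth = pd.DataFrame(
            truth_rows, columns=["ref_id", "start", "end", "strand", "n_mismatches"]
        ).sort_values(["start", "strand"]).reset_index(drop=True)

        found = enumerate_offtargets(
            [genome], spec.guide, eff, SearchParams(max_mismatches=budget)
        )
        found_keys = sorted((c.site.start, c.site.strand, c.n_mismatches) for c in found)
        truth_keys = sorted(
            (int(r.start), r.strand, int(r.n_mismatches)) for r in truth.itertuples()
        )
        if found_keys == truth_keys:
            return genome, truth
    raise RuntimeError(
        f"could not plant sites without spurious matches after "
        f"{spec.max_retries} attempts"
    )


def generate_dilution_series(base_pool, factors: Sequence[float]) -> list:
    """Serial dilutions of the mutant classes of an allele pool.

    Each factor divides every mutant-class fraction; wild type absorbs the
    remainder (mimicking dilution of edited genomic DNA into wild-type DNA).
    """
    from dataclasses import replace

    out = []
    for f in factors:
        if f < 1:
            raise ValueError("dilution factors must be >= 1")
        new_fracs = []
        mut_total = 0.0
        for a, frac in zip(base_pool.classes, base_pool.fractions):
            if a.is_wild_type:
                new_fracs.append(None)  # fill below
            else:
                new_fracs.append(frac / f)
                mut_total += frac / f
        wt = 1.0 - mut_total
        n_wt = sum(1 for x in new_fracs if x is None)
        new_fracs = [wt / n_wt if x is None else x for x in new_fracs]
        out.append(replace(base_pool, fractions=tuple(new_fracs)))
    return out
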