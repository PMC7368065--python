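"""Exhaustive PAM-constrained mismatch search for candidate off-target sites.

The in-silico prediction stage: every window on either strand of a reference
set whose PAM matches the effector's motif and whose protospacer lies within a
Hamming-distance budget of the guide is reported as a candidate.  Mismatches
are counted in the protospacer only; the PAM is a hard constraint, mirroring
how PAM disruption abolishes recognition outright while protospacer mismatches
degrade it.  DNA/RNA bulges are not searched.

The scan is a linear window sweep intended for amplicon panels and desk-scale
references, not genome-scale indexes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

from .seqcore import (
    EffectorSpec,
    GuideSite,
    NucSequence,
    _revcomp_str,
    iupac_match,
)

__all__ = [
    "SearchParams",
    "OfftargetCandidate",
    "enumerate_offtargets",
    "rank_candidates",
    "mismatch_string",
    "write_candidates_tsv",
]


@dataclass(frozen=True)
class SearchParams:
    """Search budget and PAM handling.

    max_mismatches : protospacer Hamming-distance budget (default 3).
    require_pam : if False, windows are reported regardless of PAM match.
    pam_override : optional IUPAC pattern replacing the effector's PAM
        (e.g. relax AsCas12a TTTN to TTN).
    """

    max_mismatches: int = 3
    require_pam: bool = True
    pam_override: str | None = None


@dataclass(frozen=True)
class OfftargetCandidate:
    site: GuideSite
    n_mismatches: int
    seed_mismatches: int

    def __post_init__(self) -> None:
        if self.seed_mismatches > self.n_mismatches:
            raise ValueError("seed_mismatches exceeds n_mismatches")


def enumerate_offtargets(
    refs: Sequence[NucSequence],
    guide: str,
    effector: EffectorSpec,
    params: SearchParams = SearchParams(),
) -> list[OfftargetCandidate]:
    """Enumerate every candidate site within the mismatch budget.

    The guide is given as the protospacer-strand DNA sequence (5'->3').
    Perfect on-target matches are included with ``n_mismatches == 0``.
    Results are sorted by (n_mismatches, ref_id, start, strand).  A reference
    ``N`` matches no guide base and counts as a mismatch.
    """
    guide = guide.upper()
    if len(guide) != effector.spacer_len:
        raise ValueError(
            f"guide length {len(guide)} != effector spacer_len {effector.spacer_len}"
        )
    if not (0 <= params.max_mismatches <= effector.spacer_len):
        raise ValueError("max_mismatches outside [0, spacer_len]")
    pam = (params.pam_override or effector.pam).upper()
    seed = effector.seed_slice()

    out: list[OfftargetCandidate] = []
    for ref in refs:
        for site in _candidate_windows(ref, pam, effector, params.require_pam):
            mms = tuple(
                (i, rb, gb)
                for i, (rb, gb) in enumerate(zip(site.protospacer_seq, guide))
                if rb != gb
            )
            if len(mms) > params.max_mismatches:
                continue
            annotated = GuideSite(
                ref_id=site.ref_id, start=site.start, end=site.end,
                strand=site.strand, pam_seq=site.pam_seq,
                protospacer_seq=site.protospacer_seq, mismatches=mms,
            )
            n_seed = sum(1 for i, _, _ in mms if seed.start <= i < seed.stop)
            out.append(OfftargetCandidate(annotated, len(mms), n_seed))
    out.sort(key=lambda c: (c.n_mismatches, c.site.ref_id, c.site.start, c.site.strand))
    return out


def _candidate_windows(ref, pam, effector, require_pam):
    """All windows with room for protospacer+PAM; PAM-filtered if required."""
    L = effector.spacer_len
    p = len(pam)
    n = len(ref.seq)
    for strand, seq in (("+", ref.seq), ("-", _revcomp_str(ref.seq))):
        for i in range(0, n - (L + p) + 1):
            if effector.pam_side == "five_prime":
                pam_obs, proto, proto_lo = seq[i : i + p], seq[i + p : i + p + L], i + p
            else:
                proto, pam_obs, proto_lo = seq[i : i + L], seq[i + L : i + L + p], i
            if require_pam and not iupac_match(pam, pam_obs):
                continue
            start = proto_lo if strand == "+" else n - (proto_lo + L)
            yield GuideSite(
                ref_id=ref.id, start=start, end=start + L, strand=strand,
                pam_seq=pam_obs, protospacer_seq=proto,
            )


def rank_candidates(cands: Sequence[OfftargetCandidate]) -> list[OfftargetCandidate]:
    """Stable prioritisation: fewest total mismatches, then fewest seed
    mismatches, then (ref_id, start); equal keys keep input order."""
    return sorted(
        cands,
        key=lambda c: (c.n_mismatches, c.seed_mismatches, c.site.ref_id, c.site.start),
    )


def mismatch_string(cand: OfftargetCandidate, effector: EffectorSpec) -> str:
    """Render mismatches as e.g. ``"5:A>G;12:T>C"`` (ref>guide) in 1-based
    PAM-proximal protospacer numbering."""
    parts = sorted(
        (effector.to_pam_proximal(i), rb, gb) for i, rb, gb in cand.site.mismatches
    )
    return ";".join(f"{p}:{rb}>{gb}" for p, rb, gb in parts)


def write_candidates_tsv(
    cands: Sequence[OfftargetCandidate],
    effector: EffectorSpec,
    path: Union[str, Path],
) -> None:
    """TSV report; coordinates are 1-based inclusive."""
    cols = [
        "ref_id", "start", "end", "strand", "protospacer", "pam",
        "n_mismatches", "seed_mismatches", "mismatch_string",
    ]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for c in cands:
            s = c.site
            fh.write(
                "\t".join(
                    map(
                        str,
                        [
                            s.ref_id, s.start + 1, s.end, s.strand,
                            s.protospacer_seq, s.pam_seq,
                            c.n_mismatches, c.seed_mismatches,
                            mismatch_string(c, effector),
                        ],
                    )
                )
                + "\n"
            )
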