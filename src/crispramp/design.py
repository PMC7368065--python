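"""Design of enrichment crRNAs that cleave wild-type DNA while sparing mutants.

The enrichment step depends on a guide that matches the *wild-type* amplicon
perfectly, so that unedited molecules are cleaved every round while edited
molecules escape.  Two placement strategies are implemented:

* indel-type edits (nuclease editors): place the enrichment guide so the
  expected mutation window (around the editor's cut site) overlaps the
  enrichment effector's PAM or seed region, where a lesion most strongly
  abolishes re-cleavage;
* single-base edits (adenine base editor): place the enrichment effector's
  PAM over the editing window so that the expected A>G (or complementary T>C)
  change converts a constrained PAM base into a non-matching one — PAM
  disruption gives all-or-none escape, which is why such designs are ranked
  above seed-overlap designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .seqcore import (
    EFFECTOR_PRESETS,
    EffectorSpec,
    GuideSite,
    IUPAC,
    NucSequence,
    find_pam_sites,
    iupac_base_match,
    iupac_match,
    _revcomp_str,
)

__all__ = [
    "EditingLocus",
    "EnrichmentGuide",
    "GuideReport",
    "NoDesignError",
    "design_indel_enrichment_guide",
    "design_base_edit_enrichment_guide",
    "validate_enrichment_guide",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# Canonical adenine-base-editor activity window, 1-based positions counted
# from the PAM-distal end of the protospacer (inclusive).
ABE_WINDOW_PAM_DISTAL = (3, 9)


class NoDesignError(ValueError):
    """No enrichment-guide placement satisfies the design rule.

    ``nearest_sites`` lists the closest wild-type-matching sites (indel mode);
    ``fallback`` carries seed-overlap designs when PAM disruption is
    impossible (base-edit mode).
    """

    def __init__(self, msg, nearest_sites=(), fallback=()):
        super().__init__(msg)
        self.nearest_sites = list(nearest_sites)
        self.fallback = list(fallback)


@dataclass(frozen=True)
class EditingLocus:
    """An amplicon together with the site edited in cells.

    ``expected_mutation_window`` is a 0-based half-open interval of amplicon
    positions where the edit is expected: cut site +/- w for nucleases, the
    ABE 3-9 window (PAM-distal numbering) for base editors.
    """

    amplicon: NucSequence
    editor_site: GuideSite
    editor_effector: EffectorSpec
    editor_type: str  # "nuclease" | "base_editor"
    expected_mutation_window: tuple[int, int]

    def __post_init__(self) -> None:
        if self.editor_type not in ("nuclease", "base_editor"):
            raise ValueError(f"unknown editor_type {self.editor_type!r}")
        lo, hi = self.expected_mutation_window
        if not (0 <= lo < hi <= len(self.amplicon)):
            raise ValueError("expected_mutation_window outside amplicon")

    @classmethod
    def for_nuclease(
        cls,
        amplicon: NucSequence,
        editor_site: GuideSite,
        editor_effector: EffectorSpec,
        window_halfwidth: int = 3,
    ) -> "EditingLocus":
        """Window = nominal cut site +/- ``window_halfwidth`` nt."""
        cut = editor_site.cut_position(editor_effector)
        lo = max(0, cut - window_halfwidth)
        hi = min(len(amplicon), cut + window_halfwidth)
        return cls(amplicon, editor_site, editor_effector, "nuclease", (lo, hi))

    @classmethod
    def for_base_editor(
        cls,
        amplicon: NucSequence,
        editor_site: GuideSite,
        editor_effector: EffectorSpec,
        window: tuple[int, int] = ABE_WINDOW_PAM_DISTAL,
    ) -> "EditingLocus":
        """Window = protospacer positions ``window`` (1-based, PAM-distal
        numbering, inclusive) mapped to amplicon coordinates."""
        offs = [
            editor_site.amplicon_pos(editor_effector.from_pam_distal(p))
            for p in range(window[0], window[1] + 1)
        ]
        return cls(
            amplicon, editor_site, editor_effector, "base_editor",
            (min(offs), max(offs) + 1),
        )

    def edited_adenine_positions(self) -> list[int]:
        """Amplicon + strand positions inside the window holding an adenine on
        the editor's protospacer strand (the substrate of an ABE)."""
        lo, hi = self.expected_mutation_window
        target = "A" if self.editor_site.strand == "+" else "T"
        return [p for p in range(lo, hi) if self.amplicon.seq[p] == target]


@dataclass(frozen=True)
class EnrichmentGuide:
    """A wild-type-matching guide for the enrichment effector.

    ``rationale`` is one of ``indel_in_seed``, ``indel_at_cut``,
    ``pam_disruption`` or ``sub_in_seed`` (base-edit fallback);
    ``disrupted_positions`` are amplicon positions whose expected mutation
    abolishes cleavage of the mutant allele.
    """

    effector: EffectorSpec
    site: GuideSite
    rationale: str
    disrupted_positions: tuple[int, ...] = ()


@dataclass
class GuideReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _pam_and_seed_span(site: GuideSite, eff: EffectorSpec) -> list[tuple[int, int]]:
    ps, pe = site.pam_interval(eff)
    seed = site.seed_positions(eff)
    return [(ps, pe), (seed[0], seed[-1] + 1)]


def design_indel_enrichment_guide(
    locus: EditingLocus,
    enrichment_effector: EffectorSpec,
    max_candidates: int | None = None,
) -> list[EnrichmentGuide]:
    """Enrichment guides for a nuclease-edited locus.

    Returns every wild-type-matching site of the enrichment effector whose
    protospacer-or-PAM footprint overlaps the expected mutation window,
    ranked by overlap of the window with (PAM u seed) descending, then by
    distance of the window centre to the PAM ascending.
    """
    if locus.editor_type != "nuclease":
        raise ValueError("indel designer requires a nuclease-edited locus")
    win = locus.expected_mutation_window
    win_centre = (win[0] + win[1]) / 2
    sites = find_pam_sites(locus.amplicon, enrichment_effector)
    hits = [s for s in sites if _overlap(s.footprint(enrichment_effector), win) > 0]
    if not hits:
        nearest = sorted(
            sites,
            key=lambda s: abs(
                (s.footprint(enrichment_effector)[0] + s.footprint(enrichment_effector)[1]) / 2
                - win_centre
            ),
        )[:3]
        raise NoDesignError(
            f"no enrichment site of {enrichment_effector.name} overlaps the "
            f"expected mutation window {win}",
            nearest_sites=nearest,
        )

    def keyfun(s: GuideSite):
        spans = _pam_and_seed_span(s, enrichment_effector)
        critical = sum(_overlap(sp, win) for sp in spans)
        ps, pe = s.pam_interval(enrichment_effector)
        return (-critical, abs((ps + pe) / 2 - win_centre), s.start, s.strand)

    hits.sort(key=keyfun)
    guides = []
    for s in hits:
        spans = _pam_and_seed_span(s, enrichment_effector)
        in_critical = sum(_overlap(sp, win) for sp in spans) > 0
        rationale = "indel_in_seed" if in_critical else "indel_at_cut"
        ps, pe = s.pam_interval(enrichment_effector)
        pam_positions = [
            s.pam_amplicon_pos(i, enrichment_effector)
            for i, ch in enumerate(enrichment_effector.pam)
            if IUPAC[ch] != "ACGT"
        ]
        disrupted = tuple(sorted(set(pam_positions) | set(s.seed_positions(enrichment_effector))))
        guides.append(EnrichmentGuide(enrichment_effector, s, rationale, disrupted))
    return guides[:max_candidates] if max_candidates else guides


def design_base_edit_enrichment_guide(
    locus: EditingLocus,
    enrichment_effector: EffectorSpec,
) -> list[EnrichmentGuide]:
    """PAM-disruption designs for an ABE-edited locus.

    A design is returned for every enrichment site with at least one
    constrained PAM base inside the editing window whose expected A>G
    (protospacer strand) / T>C (opposite strand) change converts that base to
    a non-matching one.  If no such placement exists a :class:`NoDesignError`
    is raised carrying seed-overlap fallback designs.
    """
    if locus.editor_type != "base_editor":
        raise ValueError("base-edit designer requires a base_editor locus")
    amp = locus.amplicon.seq
    edited = set(locus.edited_adenine_positions())
    sites = find_pam_sites(locus.amplicon, enrichment_effector)

    designs: list[EnrichmentGuide] = []
    for s in sites:
        disrupted = []
        for i, patt_ch in enumerate(enrichment_effector.pam):
            if IUPAC[patt_ch] == "ACGT":
                continue  # N constrains nothing; an edit there never disrupts
            ap = s.pam_amplicon_pos(i, enrichment_effector)
            if ap not in edited:
                continue
            # A>G on the editor's protospacer strand, expressed on + strand:
            plus_after = "G" if locus.editor_site.strand == "+" else "C"
            pam_strand_after = plus_after if s.strand == "+" else _COMP[plus_after]
            if not iupac_base_match(patt_ch, pam_strand_after):
                disrupted.append(ap)
        if disrupted:
            designs.append(
                EnrichmentGuide(
                    enrichment_effector, s, "pam_disruption", tuple(sorted(disrupted))
                )
            )
    if designs:
        designs.sort(key=lambda g: (-len(g.disrupted_positions), g.site.start, g.site.strand))
        return designs

    win = locus.expected_mutation_window
    fallback = []
    for s in sites:
        seed = s.seed_positions(enrichment_effector)
        seed_hit = sorted(set(seed) & edited)
        if seed_hit:
            fallback.append(
                EnrichmentGuide(enrichment_effector, s, "sub_in_seed", tuple(seed_hit))
            )
    raise NoDesignError(
        f"no PAM-disrupting placement of {enrichment_effector.name} inside the "
        f"editing window {win}",
        fallback=fallback,
    )


def validate_enrichment_guide(g: EnrichmentGuide, amplicon: NucSequence) -> GuideReport:
    """Check a design against the wild-type amplicon.

    Confirms (1) perfect wild-type match of protospacer and PAM, (2) the
    protospacer occurs at exactly one effector site on the amplicon, and
    (3) every listed disrupted position lies under a constrained PAM base or
    inside the seed region, i.e. mutating it abolishes PAM match or creates a
    seed mismatch.  Failures are reported, not raised.
    """
    rep = GuideReport()
    eff, s = g.effector, g.site
    n = len(amplicon)

    # (1) wild-type match
    lo, hi = s.footprint(eff)
    if lo < 0 or hi > n:
        rep.violations.append("site footprint extends beyond the amplicon")
        return rep
    obs_proto = amplicon.seq[s.start : s.end]
    if s.strand == "-":
        obs_proto = _revcomp_str(obs_proto)
    if obs_proto != s.protospacer_seq or s.mismatches:
        rep.violations.append("protospacer does not perfectly match the wild-type amplicon")
    ps, pe = s.pam_interval(eff)
    obs_pam = amplicon.seq[ps:pe]
    if s.strand == "-":
        obs_pam = _revcomp_str(obs_pam)
    if obs_pam != s.pam_seq:
        rep.violations.append("recorded PAM differs from the amplicon")
    elif not iupac_match(eff.pam, obs_pam):
        rep.violations.append(f"PAM {obs_pam!r} does not match pattern {eff.pam!r}")

    # (2) uniqueness among effector sites on the amplicon
    same = [
        t for t in find_pam_sites(amplicon, eff) if t.protospacer_seq == s.protospacer_seq
    ]
    if len(same) == 0:
        rep.violations.append("site not found among effector sites on the amplicon")
    elif len(same) > 1:
        rep.violations.append(
            f"protospacer occurs at {len(same)} effector sites; design is ambiguous"
        )

    # (3) disrupted positions must hit constrained PAM bases or the seed
    constrained_pam = {
        s.pam_amplicon_pos(i, eff) for i, ch in enumerate(eff.pam) if IUPAC[ch] != "ACGT"
    }
    seed = set(s.seed_positions(eff))
    for p in g.disrupted_positions:
        if p not in constrained_pam and p not in seed:
            rep.violations.append(
                f"disrupted position {p} lies outside constrained PAM bases and seed"
            )
    if g.rationale == "pam_disruption" and not (set(g.disrupted_positions) & constrained_pam):
        rep.violations.append("pam_disruption design lists no constrained PAM position")
    return rep
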