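# Methods

This note documents the models, parameter choices and numerical conventions
behind `crispramp`, and what the synthetic-data tests do and do not
demonstrate about real sequencing data.

## Enrichment model

One enrichment round is modelled as independent cleavage exposure followed by
saturating re-amplification. Allele class `a` survives exposure with
probability `w(a) = 1 − c·(1 − π(a))`, where `c ∈ [0,1]` is the per-round
wild-type cleavage efficiency and `π(a) ∈ [0,1]` the class's escape
probability (`π = 0` for wild type by definition — it is the substrate).
Post-round fractions are the survival-reweighted fractions renormalised to 1.
PCR is treated as exact renormalisation: no length or sequence bias, no
per-class efficiency differences (a per-class amplification-weight hook
exists in the pool structure via `π`-like weights but defaults to uniform).
This is the minimal formalisation consistent with the observed exponential
gain in sensitivity; the experimental literature does not separate cleavage
escape from PCR bias, and we deliberately attribute the whole effect to
escape. Consequences of that choice (e.g. deletion-size spectra across
rounds) are model-dependent and labelled as such in pipeline reports.

Degenerate inputs: `c = 1` with all `π = 0` would annihilate the pool and
raises a "complete depletion" error rather than returning NaNs. A pool
starting at mutant fraction 0 stays at 0 for every parameter setting, and its
fold increase is reported as 1 by convention (the laboratory convention for
such samples is "NC", not defined).

### Stochastic variant

The finite-template simulator adds the carryover bottleneck: only
`ceil(carryover·N)` molecules (default carryover 0.02, i.e. the 2% v/v of a
reaction typically re-seeded) are drawn multinomially from the pool, each
survives with `w(a)`, and the survivors are renormalised back to `N`
(saturating PCR). Loss of every molecule raises a "stochastic dropout" error
— a real failure mode at extreme dilution, not an artifact. Seeds are
mandatory; there is no hidden global random state. The replicate mean
converges to the deterministic recurrence as `N` grows (verified at
N = 1e3, 1e4, 1e6).

### Escape probabilities

`escape_probability` is rule-based with these defaults (all exposed in
`EscapeParams`):

| mutation | π | reasoning |
|---|---|---|
| substitution breaking a constrained PAM base | 1.0 | no PAM, no recognition — all-or-none escape |
| indel ≥ `s_big` = 2 bp overlapping protospacer/PAM | `pi_big` = 1.0 | large lesions abolish pairing; large deletions dominate late rounds |
| 1-bp indel in protospacer | `pi_small` = 0.3 | a 1-bp change leaves a near-perfect target with high re-cleavage probability |
| substitution in seed | `pi_seed` = 0.9 | seed mismatches strongly impair cleavage |
| substitution elsewhere in protospacer (incl. under a PAM `N`) | `pi_distal` = 0.1 | PAM-distal mismatches are largely tolerated |
| mutation not overlapping the site | 0 | unaffected substrate |

The π values are modelling choices, not measurements; only their *ordering*
is empirically anchored (1-bp deletions enrich markedly less than 10-bp
deletions at the same locus). Every downstream quantity that depends on them
is model-dependent.

### Round cap and detection limit

Defaults: `rounds_max = 3` (repeated amplification accumulates polymerase and
sequencing errors, so deeper enrichment is untrustworthy — the pipeline
refuses more rounds unless explicitly overridden) and `detection_limit =
0.5%`, the customary amplicon-sequencing floor below which real mutations are
indistinguishable from sequencing error.

### Fitting c

`fit_cleavage_efficiency` inverts the two-class recurrence by bounded 1-D
least squares (`scipy.optimize.minimize_scalar`, `xatol = 1e-10`; endpoint
values checked explicitly because the bounded method never evaluates them).
With π fixed at 1 a decreasing trajectory is inconsistent with every `c` and
is returned as the best attainable fit plus a warning; a constant trajectory
fits `c = 0` and is flagged as π-confounded.

## Off-target search

The search is an exhaustive window scan on both strands: the PAM is a hard
constraint (match or no candidate) and mismatches are counted in the
protospacer only, because PAM disruption abolishes recognition outright while
protospacer mismatches merely degrade it. Defaults: `max_mismatches = 3`.
Bulges are out of scope. An `N` in the reference matches no base — neither in
the PAM nor the protospacer — so ambiguous reference stretches cannot create
phantom candidates. The scan is linear (no FM-index); it is intended for
amplicon panels and test-scale references, and is verified against a naive
window-by-window oracle up to 10 kb for budgets 0–4.

## Guide design

Seed lengths: PAM-proximal 6 nt for AsCas12a and 8 nt for SpCas9 (common
literature values; configurable — the underlying biology is invoked
qualitatively, without committed lengths). Expected mutation window for
nuclease loci: nominal cut site ± 3 nt (configurable; nothing pins where an
indel must fall to confer escape). Nominal cuts: SpCas9 blunt between
protospacer positions 17/18 (3 nt from the PAM), AsCas12a staggered cut
approximated by a single position after position 18 (PAM-proximal numbering);
both only centre the indel-calling window.

ABE window: protospacer positions 3–9 counted from the **PAM-distal** end.
Two 1-based numbering schemes coexist deliberately (PAM-proximal for seed
logic, PAM-distal for the editing window); both are defined once in
`EffectorSpec` and inter-convert exactly, preventing off-by-one drift.

Ranking places PAM-overlap designs above seed-overlap designs because PAM
disruption is all-or-none while seed-mismatch escape is graded; among
PAM/seed-overlapping candidates the tie-break is distance of the window
centre to the PAM. The objective function is this package's own choice — the
experimental practice it formalises ("ideally designed to cleave wild-type
DNA") names no explicit criterion. Base-editor designs require the expected
A>G (or complementary T>C) change to convert a constrained PAM base into a
non-matching one; an edit under the `N` of TTTN disrupts nothing and is
rejected. When no PAM-disrupting placement exists, seed-overlap fallbacks are
reported separately under the rationale `sub_in_seed`.

Every emitted design passes `validate_enrichment_guide` (perfect wild-type
match, site uniqueness on the amplicon, each claimed disrupted position under
a constrained PAM base or in the seed) — enforced as a test invariant.

## Read quantification

Reads are orientation-normalised by edit distance (edlib) and then globally
aligned by an affine-gap Gotoh dynamic programme (numpy row-vectorised,
integer scores; gap of length k costs `gap_open + k·gap_extend`, defaults
+2/−3/−5/−1). Direct insertion↔deletion transitions are disallowed; with the
default scores an adjacent ins+del can never beat a substitution. Traceback
prefers aligned pairs over deletions over insertions and gap extension over
opening on exact score ties, which places co-optimal gaps leftmost — the
canonical convention, so repeated runs and reimplementations agree on indel
coordinates. Optimal scores are cross-checked against Biopython's
`PairwiseAligner` in the test suite; the implementation itself is
independent.

Indel calling is window-restricted: a read is `indel` iff an ins/del overlaps
cut site ± 3 nt (deletions by span overlap, insertions by gap index;
full-amplicon counting behind a flag). Substitution-only reads form their own
class and never enter the indel frequency, so nuclease and base-editor
metrics cannot contaminate each other. Reads shorter than 80% of the amplicon
are discarded with a recorded reason and excluded from denominators; the
discard count is always reported so denominators stay auditable.

`indel frequency (%) = 100 · n_indel / (n_total − n_discarded)`; per-position
substitution percentages use as denominator the reads actually covering the
position with a base (deletions subtract coverage). Deletion sizes are
measured on the reference, insertion sizes on the read. Fold increase is
post/pre frequency; a zero pre-enrichment frequency yields "NC".

## Synthetic data

The generator emulates: single-end full-length amplicon reads, mutant alleles
at exact fractions (largest-remainder rounding, so a 0.077 fraction of 1000
reads is exactly 77 — worked examples are deterministic; a multinomial mode
exists for statistical tests), substitution-only sequencing error (default
0, capped at 5%), planted off-target sites at specified mismatch counts with
rejection-sampled backgrounds guaranteeing the truth table is exhaustive, and
serial dilution of allele pools. It does **not** emulate quality-score-
dependent error profiles, homopolymer indel errors, read-length variation,
adapter contamination, paired-end structure or chimeric reads. Passing the
recovery tests therefore shows the *computational* chain is exact under its
stated error model — not that real libraries are free of artifacts the model
omits.

## Problem sizes in tests and the acceptance script

The closed-form targets are instantaneous. Property suites use: one 10-kb
reference (budgets 0–4) plus several 2–3-kb references for the search oracle;
alignment oracle pairs up to 200 nt; 200 stochastic replicates at N = 1e6 for
the mean-convergence check; 50 replicates at N = 1e5 for cleavage-efficiency
recovery; 1000-read sets for the worked-example quantifications; pipeline
runs at 300–400 reads per round. These sizes make every property statistical
enough to be meaningful while keeping the whole suite under a minute on one
CPU.

## Known limitations

- Escape probabilities are class-level constants; no sequence context, no
  enzyme kinetics, no thermal-cycling mechanics.
- PCR bias (length- or GC-dependent) is not modelled; the deletion-size
  preference is attributed entirely to cleavage escape.
- Whether insertions have intrinsically lower escape or lower amplification
  is unresolved; insertions share the generic indel π classes and can be
  reconfigured.
- The off-target scan does not model DNA/RNA bulges and is not built for
  whole-genome indexes.
- CBE (C>T) base editors are structurally supported by the design machinery
  but have no dedicated defaults.
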