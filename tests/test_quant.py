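"""Alignment, mutation calling and locus-level quantification."""

import math

import numpy as np
import pytest
from Bio import Align

from crispramp.quant import (
    QuantConfig,
    align_read,
    call_mutation,
    deletion_size_spectrum,
    fold_increase,
    format_fold,
    gotoh_align,
    indel_frequency,
    insertion_size_spectrum,
    quantify_reads,
    read_fastq,
    substitution_profile,
)
from crispramp.seqcore import (
    Deletion,
    Insertion,
    NucSequence,
    Substitution,
    apply_mutation,
    revcomp,
)
from crispramp.synth import ReadSetSpec, generate_reads, write_fastq

from conftest import random_dna


def biopython_score(read, ref, cfg=QuantConfig()):
    """Independent optimal-score oracle (Biopython pairwise aligner)."""
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = cfg.match
    a.mismatch_score = cfg.mismatch
    a.open_gap_score = cfg.gap_open + cfg.gap_extend
    a.extend_gap_score = cfg.gap_extend
    return a.score(ref, read)


class TestGotohAlign:
    def test_identical_read(self, rng):
        ref = random_dna(rng, 120)
        score, ops = gotoh_align(ref, ref)
        assert ops == () and score == 2 * len(ref)

    def test_internal_deletion_leftmost(self):
        # 40-nt toy pair: removing an internal 5-mer must yield one 5-bp
        # deletion placed leftmost among co-optimal positions
        ref = "ACGTACGTGGATCCTTAGCAACGGTCATTGACCGGAATCC"
        read = ref[:12] + ref[17:]
        score, ops = gotoh_align(read, ref)
        assert ops == (Deletion(12, 5),)

    def test_homopolymer_gap_leftmost(self):
        assert gotoh_align("AAA", "AAAA")[1] == (Deletion(0, 1),)
        assert gotoh_align("AAAAA", "AAAA")[1] == (Insertion(0, 1, "A"),)

    def test_single_mismatch_no_gaps(self, rng):
        ref = random_dna(rng, 80)
        alt = "A" if ref[40] != "A" else "C"
        read = ref[:40] + alt + ref[41:]
        score, ops = gotoh_align(read, ref)
        assert ops == (Substitution(40, ref[40], alt),)

    def test_score_equals_dp_oracle_on_random_pairs(self, rng):
        # optimal-score equivalence with an independent full-DP aligner on
        # pairs up to 200 nt with random indels and substitutions
        for _ in range(15):
            ref = random_dna(rng, int(rng.integers(40, 201)))
            read = ref
            for _ in range(rng.integers(0, 4)):
                kind = rng.integers(3)
                pos = int(rng.integers(0, max(1, len(read) - 12)))
                if kind == 0:
                    read = read[:pos] + read[pos + int(rng.integers(1, 11)):]
                elif kind == 1:
                    read = read[:pos] + random_dna(rng, int(rng.integers(1, 6))) + read[pos:]
                else:
                    read = read[:pos] + "ACGT"[int(rng.integers(4))] + read[pos + 1:]
            if not read:
                continue
            score, _ = gotoh_align(read, ref)
            assert score == biopython_score(read, ref)

    def test_ops_reconstruct_the_read(self, rng):
        # applying the reported ops to the reference must rebuild the read
        for _ in range(10):
            ref = random_dna(rng, 150)
            read = ref[:30] + ref[38:100] + "TTAGC" + ref[100:]
            _, ops = gotoh_align(read, ref)
            rebuilt = ref
            for op in sorted(ops, key=lambda o: getattr(o, "position",
                                                        getattr(o, "start", 0)),
                             reverse=True):
                rebuilt = apply_mutation(rebuilt, op)
            assert rebuilt == read


class TestOrientation:
    def test_reverse_complement_read_classified_identically(self, rng):
        ref = random_dna(rng, 150)
        read = ref[:70] + ref[75:]  # 5-bp deletion
        fwd = align_read(("f", read), ref)
        rev = align_read(("r", str(revcomp(read))), ref)
        assert fwd.ops == rev.ops
        assert (fwd.strand, rev.strand) == ("+", "-")


class TestCallMutation:
    REF = None

    @pytest.fixture(autouse=True)
    def _ref(self, rng):
        self.ref = random_dna(rng, 160)
        self.cut = 80

    def _call(self, read, **cfg):
        config = QuantConfig(**cfg)
        aln = align_read(("r", read), self.ref, config)
        return call_mutation(aln, self.cut, config)

    def test_one_bp_insertion_at_cut_is_indel(self):
        read = self.ref[:80] + "A" + self.ref[80:]
        assert self._call(read).cls == "indel"

    def test_distant_deletion_is_background(self):
        read = self.ref[:30] + self.ref[32:]  # 2-bp deletion 50 nt from cut
        call = self._call(read)
        assert call.cls == "wild_type"
        assert call.details and not call.window_indels

    def test_distant_deletion_counts_with_full_amplicon_flag(self):
        read = self.ref[:30] + self.ref[32:]
        assert self._call(read, full_amplicon_indels=True).cls == "indel"

    def test_substitution_in_window_is_substitution_only(self):
        alt = "G" if self.ref[84] != "G" else "T"
        read = self.ref[:84] + alt + self.ref[85:]
        call = self._call(read, substitution_window=(82, 89))
        assert call.cls == "substitution_only"

    def test_substitution_outside_configured_window_ignored(self):
        alt = "G" if self.ref[10] != "G" else "T"
        read = self.ref[:10] + alt + self.ref[11:]
        assert self._call(read, substitution_window=(82, 89)).cls == "wild_type"

    def test_deletion_spanning_window_boundary_counts_by_overlap(self):
        # window [77, 83); deletion [75, 79) overlaps it
        read = self.ref[:75] + self.ref[79:]
        assert self._call(read).cls == "indel"


class TestFrequencies:
    def test_indel_frequency_worked_example(self, rng):
        # 77 of 1000 reads carrying a cut-site deletion -> 7.7%
        amp = NucSequence("amp", random_dna(rng, 140))
        cut = 70
        spec = ReadSetSpec(amplicon=amp, alleles=(("mut", Deletion(69, 3), 0.077),),
                           n_reads=1000, seed=5)
        records, _ = generate_reads(spec)
        res = quantify_reads(((r, s) for r, s, _ in records), amp, cut)
        assert res.indel_frequency == pytest.approx(7.7, abs=1e-12)
        assert res.n_indel == 77 and res.n_discarded == 0
        assert res.deletion_size_histogram == {3: 77}

    def test_substitution_profile_worked_example(self, rng):
        # 756 of 1000 reads with A>G at one window position -> 75.6%
        amp_seq = random_dna(rng, 120)
        amp_seq = amp_seq[:60] + "A" + amp_seq[61:]
        amp = NucSequence("amp", amp_seq)
        spec = ReadSetSpec(
            amplicon=amp, alleles=(("abe", Substitution(60, "A", "G"), 0.756),),
            n_reads=1000, seed=6,
        )
        records, _ = generate_reads(spec)
        cfg = QuantConfig(substitution_window=(57, 64))
        res = quantify_reads(((r, s) for r, s, _ in records), amp, 60, cfg)
        prof = res.substitution_profile
        hit = prof[(prof.position == 60) & (prof.alt_base == "G")]
        assert hit.percent.iloc[0] == pytest.approx(75.6, abs=1e-12)
        assert (prof[prof.position != 60].n_reads == 0).all()
        assert res.n_substitution_only == 756

    def test_error_free_wild_type_gives_zero_profile(self, rng):
        amp = NucSequence("amp", random_dna(rng, 100))
        reads = [(f"r{i}", amp.seq) for i in range(50)]
        res = quantify_reads(reads, amp, 50,
                             QuantConfig(substitution_window=(40, 47)))
        assert res.indel_frequency == 0.0
        assert (res.substitution_profile.percent == 0).all()

    def test_uniform_noise_profile_near_error_rate(self, rng):
        # 1% per-base substitution noise: each position shows ~1% aggregate
        # substitution frequency (within a generous binomial envelope)
        amp = NucSequence("amp", random_dna(rng, 100))
        spec = ReadSetSpec(amplicon=amp, alleles=(), n_reads=2000,
                           error_rate=0.01, seed=8)
        records, _ = generate_reads(spec)
        res = quantify_reads(((r, s) for r, s, _ in records), amp, 50,
                             QuantConfig(substitution_window=(30, 40)))
        per_pos = res.substitution_profile.groupby("position")["n_reads"].sum()
        # binomial(2000, 0.01): mean 20, sd ~4.5
        assert ((per_pos > 2) & (per_pos < 45)).all()

    def test_all_reads_discarded_raises(self, rng):
        amp = NucSequence("amp", random_dna(rng, 100))
        reads = [("r0", amp.seq[:20])]  # below the 80% length filter
        with pytest.raises(ValueError, match="discarded"):
            quantify_reads(reads, amp, 50)

    def test_short_reads_discarded_and_counted(self, rng):
        amp = NucSequence("amp", random_dna(rng, 100))
        reads = [("short", amp.seq[:50])] + [(f"r{i}", amp.seq) for i in range(9)]
        res = quantify_reads(reads, amp, 50)
        assert res.n_discarded == 1
        assert res.indel_frequency == 0.0  # denominator excludes the discard


class TestFoldIncrease:
    def test_worked_example(self):
        assert fold_increase(7.7, 98.816) == pytest.approx(12.83, abs=5e-3)

    def test_identity(self):
        assert fold_increase(4.2, 4.2) == 1.0

    def test_zero_pre_is_nc(self):
        f = fold_increase(0.0, 5.0)
        assert math.isnan(f) and format_fold(f) == "NC"


class TestSpectra:
    def test_generator_truth_histogram(self, rng):
        amp = NucSequence("amp", random_dna(rng, 160))
        cut = 80
        spec = ReadSetSpec(
            amplicon=amp,
            alleles=(("d1", Deletion(79, 1), 0.1), ("d10", Deletion(75, 10), 0.05),
                     ("i2", Insertion(80, 2, "GG"), 0.05)),
            n_reads=100, seed=9,
        )
        records, _ = generate_reads(spec)
        res = quantify_reads(((r, s) for r, s, _ in records), amp, cut)
        assert res.deletion_size_histogram == {1: 10, 10: 5}
        assert res.insertion_size_histogram == {2: 5}

    def test_empty_calls_empty_histogram(self):
        assert deletion_size_spectrum([]) == {}
        assert insertion_size_spectrum([]) == {}

    def test_large_deletion_proportion_grows_with_rounds(self, rng):
        # end-to-end: simulate enrichment of a -1/-10 deletion mixture where
        # the large deletion is better protected, generate reads per round,
        # and check the -10 bp share of mutant reads rises monotonically
        from crispramp.enrichment import AlleleClass, AllelePool, RoundParams, \
            enrich_round
        from crispramp.seqcore import WildType

        amp = NucSequence("amp", random_dna(rng, 160))
        cut = 80
        d1, d10 = Deletion(79, 1), Deletion(75, 10)
        pool = AllelePool(
            classes=(AlleleClass("wild_type", WildType(), 0.0),
                     AlleleClass("d1", d1, 0.3), AlleleClass("d10", d10, 1.0)),
            fractions=(0.9, 0.05, 0.05),
        )
        shares = []
        for k in range(4):
            spec = ReadSetSpec(
                amplicon=amp,
                alleles=(("d1", d1, pool.fraction_of("d1")),
                         ("d10", d10, pool.fraction_of("d10"))),
                n_reads=400, seed=100 + k,
            )
            records, _ = generate_reads(spec)
            res = quantify_reads(((r, s) for r, s, _ in records), amp, cut)
            hist = res.deletion_size_histogram
            shares.append(hist.get(10, 0) / max(1, hist.get(1, 0) + hist.get(10, 0)))
            pool = enrich_round(pool, RoundParams(c=0.9))
        assert all(b >= a for a, b in zip(shares, shares[1:]))
        assert shares[-1] > shares[0]


class TestFastqIO:
    def test_roundtrip_plain_and_gzip(self, tmp_path, rng):
        import gzip

        amp = NucSequence("amp", random_dna(rng, 90))
        spec = ReadSetSpec(amplicon=amp, alleles=(), n_reads=5, seed=1)
        records, _ = generate_reads(spec)
        p = tmp_path / "r.fastq"
        write_fastq(records, p)
        assert read_fastq(p) == [(r, s) for r, s, _ in records]
        gz = tmp_path / "r.fastq.gz"
        gz.write_bytes(gzip.compress(p.read_bytes()))
        assert read_fastq(gz) == read_fastq(p)
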