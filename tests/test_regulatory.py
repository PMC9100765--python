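"""Phase-1 unit tests: MAF handling, promoter windows, MATCH-style scoring
and Gain/Loss classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pleioscan import regulatory as reg
from pleioscan import synthdata as sd


def _pwm(rows, name="P"):
    return reg.PWM(name=name, freq=np.array(rows, dtype=float))


def random_pwm(rng, length=8, name="R"):
    freq = rng.dirichlet(np.full(4, 0.5), size=length)
    return reg.PWM(name=name, freq=freq)


class TestMAF:
    def test_monomorphic_is_zero(self):
        assert reg.compute_maf([0] * 10) == 0.0

    def test_counting(self):
        # 3 alt-homozygote lines among 10 -> p = 0.3
        assert reg.compute_maf([2] * 3 + [0] * 7) == pytest.approx(0.3)

    def test_folding_above_half(self):
        assert reg.compute_maf([2] * 8 + [0] * 2) == pytest.approx(0.2)

    def test_missing_excluded_from_denominator(self):
        assert reg.compute_maf([2, 0, np.nan, np.nan]) == pytest.approx(0.5)

    def test_all_missing_raises(self):
        with pytest.raises(ValueError):
            reg.compute_maf([np.nan, np.nan])

    def test_filter_keeps_boundary(self):
        def snp(i, maf):
            n_alt = int(round(maf * 100))
            return reg.SNPRecord(
                id=f"s{i}", chrom="c", pos=100 + i, ref="A", alt="G",
                dosages=[2] * n_alt + [0] * (100 - n_alt),
            )

        snps = [snp(0, 0.04), snp(1, 0.05), snp(2, 0.30)]
        kept = reg.filter_snps_by_maf(snps, floor=0.05)
        assert [s.id for s in kept] == ["s1", "s2"]
        assert reg.filter_snps_by_maf(snps, floor=0.0) == snps
        assert reg.filter_snps_by_maf([], floor=0.05) == []


class TestPromoterWindow:
    @staticmethod
    def _snp(pos):
        return reg.SNPRecord(id=f"s{pos}", chrom="c1", pos=pos, ref="A", alt="G", dosages=[0, 2])

    @pytest.mark.parametrize(
        "strand,tss,pos,included",
        [
            ("+", 10_000, 9_500, True),   # offset -500: boundary in
            ("+", 10_000, 9_499, False),  # offset -501
            ("+", 10_000, 10_100, True),  # offset +100: boundary in
            ("+", 10_000, 10_101, False),
            ("-", 10_000, 10_100, True),  # transcription offset -100
            ("-", 10_000, 10_500, True),  # transcription offset -500: boundary
            ("-", 10_000, 10_501, False),
            ("-", 10_000, 9_900, True),   # transcription offset +100: boundary
            ("-", 10_000, 9_899, False),
        ],
    )
    def test_boundaries_both_strands(self, strand, tss, pos, included):
        if strand == "+":
            ann = reg.GeneAnnotation("g", "c1", tss, tss + 500, "+")
        else:
            ann = reg.GeneAnnotation("g", "c1", tss - 500, tss, "-")
        pairs = reg.select_promoter_snps([self._snp(pos)], [ann])
        assert bool(pairs) == included

    def test_snp_may_pair_with_multiple_genes(self):
        a1 = reg.GeneAnnotation("g1", "c1", 10_000, 10_500, "+")
        a2 = reg.GeneAnnotation("g2", "c1", 9_600, 9_950, "-")
        pairs = reg.select_promoter_snps([self._snp(9_960)], [a1, a2])
        assert {g for _, g in pairs} == {"g1", "g2"}

    def test_unknown_strand_skipped(self):
        ann = reg.GeneAnnotation("g", "c1", 10_000, 10_500, ".")
        assert reg.select_promoter_snps([self._snp(10_000)], [ann]) == []


class TestFlankExtraction:
    def test_window_is_51_and_central(self):
        contig = "".join(np.random.default_rng(0).choice(list("ACGT"), 200))
        snp = reg.SNPRecord(
            id="s", chrom="c", pos=100, ref=contig[99],
            alt=[b for b in "ACGT" if b != contig[99]][0], dosages=[0, 2],
        )
        pair = reg.extract_allele_sequences(snp, {"c": contig})
        assert len(pair.ref_seq) == len(pair.alt_seq) == 51
        assert pair.snp_index == 26
        assert pair.ref_seq[25] == snp.ref and pair.alt_seq[25] == snp.alt
        assert pair.ref_seq[:25] == pair.alt_seq[:25]
        assert pair.ref_seq[26:] == pair.alt_seq[26:]

    def test_window_at_contig_edge(self):
        contig = "A" * 100
        snp = reg.SNPRecord(id="s", chrom="c", pos=26, ref="A", alt="G", dosages=[0])
        pair = reg.extract_allele_sequences(snp, {"c": contig})
        assert len(pair.ref_seq) == 51  # spans contig positions 1..51

    def test_insufficient_context_raises(self):
        snp = reg.SNPRecord(id="s", chrom="c", pos=10, ref="A", alt="G", dosages=[0])
        with pytest.raises(IndexError):
            reg.extract_allele_sequences(snp, {"c": "A" * 100})

    def test_ref_mismatch_names_snp(self):
        contig = "A" * 100
        snp = reg.SNPRecord(id="badsnp", chrom="c", pos=50, ref="G", alt="T", dosages=[0])
        with pytest.raises(ValueError, match="badsnp"):
            reg.extract_allele_sequences(snp, {"c": contig})


class TestInformationVector:
    @pytest.mark.parametrize(
        "row,expected",
        [
            ((0.25, 0.25, 0.25, 0.25), 0.0),
            ((1, 0, 0, 0), np.log(4)),
            ((0.5, 0.5, 0, 0), np.log(2)),
        ],
    )
    def test_reference_values(self, row, expected):
        assert reg.information_vector(np.array([row]))[0] == pytest.approx(expected)

    def test_nonnegative_on_random_frequencies(self, rng):
        freq = rng.dirichlet(np.ones(4), size=50)
        assert np.all(reg.information_vector(freq) >= -1e-12)


class TestMatrixSimilarityScore:
    def test_consensus_scores_one(self, rng):
        for _ in range(10):
            pwm = random_pwm(rng)
            mss, core = reg.matrix_similarity_score(pwm, pwm.consensus())
            assert mss == pytest.approx(1.0)
            assert core == pytest.approx(1.0)

    def test_minimum_base_scores_zero(self, rng):
        pwm = random_pwm(rng)
        worst = "".join(reg.BASES[i] for i in np.argmin(pwm.freq, axis=1))
        mss, _ = reg.matrix_similarity_score(pwm, worst)
        assert mss == pytest.approx(0.0)

    def test_hand_computed_oracle(self):
        # termwise evaluation of Current/Min/Max for a 3-position matrix on "AAT"
        rows = [(0.7, 0.1, 0.1, 0.1), (0.25, 0.25, 0.25, 0.25), (0.1, 0.1, 0.1, 0.7)]
        pwm = _pwm(rows)
        info = [sum(f * np.log(4 * f) for f in r if f > 0) for r in rows]
        current = info[0] * 0.7 + info[1] * 0.25 + info[2] * 0.7
        lo = sum(i * min(r) for i, r in zip(info, rows))
        hi = sum(i * max(r) for i, r in zip(info, rows))
        expected = (current - lo) / (hi - lo)
        mss, _ = reg.matrix_similarity_score(pwm, "AAT")
        assert mss == pytest.approx(expected, abs=1e-12)

    def test_unscorable_uniform_matrix(self):
        pwm = _pwm([[0.25] * 4] * 6)
        assert not pwm.is_scorable
        with pytest.raises(ValueError):
            reg.matrix_similarity_score(pwm, "ACGTAC")

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_scores_bounded(self, seed):
        r = np.random.default_rng(seed)
        pwm = random_pwm(r, length=int(r.integers(6, 12)))
        seq = "".join(r.choice(list("ACGT"), pwm.length))
        mss, core = reg.matrix_similarity_score(pwm, seq)
        assert 0.0 <= mss <= 1.0 and 0.0 <= core <= 1.0


class TestScan:
    def test_planted_consensus_found_at_offset(self, rng):
        pwm = random_pwm(rng)
        seq = "".join(rng.choice(list("ACGT"), 51))
        seq = seq[:10] + pwm.consensus() + seq[10 + pwm.length:]
        hits = reg.scan_sequence(seq, pwm, mss_cutoff=1.0, core_cutoff=1.0)
        assert any(h.offset == 10 and h.mss == pytest.approx(1.0) for h in hits)

    def test_too_short_sequence_empty(self, rng):
        pwm = random_pwm(rng, length=8)
        assert reg.scan_sequence("ACGT", pwm) == []

    def test_strand_symmetry(self, rng):
        """Scanning the reverse complement yields the same scores with
        strands flipped and offsets mirrored."""
        for _ in range(5):
            pwm = random_pwm(rng)
            seq = "".join(rng.choice(list("ACGT"), 51))
            fwd = reg.scan_sequence(seq, pwm, mss_cutoff=0.3, core_cutoff=0.0)
            rev = reg.scan_sequence(reg.reverse_complement(seq), pwm, mss_cutoff=0.3, core_cutoff=0.0)
            key_f = sorted((round(h.mss, 9), h.strand, h.offset) for h in fwd)
            key_r = sorted(
                (round(h.mss, 9), "+" if h.strand == "-" else "-", 51 - pwm.length - h.offset)
                for h in rev
            )
            assert key_f == key_r

    def test_high_cutoff_on_random_sequence_empty(self, rng):
        pwm = random_pwm(rng)
        seq = "".join(rng.choice(list("ACGT"), 51))
        hits = reg.scan_sequence(seq, pwm, mss_cutoff=1.0, core_cutoff=1.0)
        assert all(h.mss == pytest.approx(1.0) for h in hits)

    def test_windows_with_ambiguous_bases_emit_no_hits(self, rng):
        pwm = random_pwm(rng, length=6)
        seq = "N".join(["ACG", "TAC", "GTA", "CGT"])  # every 6-mer contains an N
        assert reg.scan_sequence(seq, pwm, mss_cutoff=0.0, core_cutoff=0.0) == []


class TestClassification:
    @staticmethod
    def _planted_pair(rng, effect):
        pwm = sd.generate_pwm_library(1, (8, 8), seed=int(rng.integers(1 << 20)))[0]
        kill = sd._best_kill_position(pwm)
        cons = pwm.consensus()
        weak = reg.BASES[int(np.argmin(pwm.freq[kill]))]
        flank_left = "".join(rng.choice(list("ACGT"), 25 - kill))
        flank_right = "".join(rng.choice(list("ACGT"), 51 - (25 - kill) - pwm.length))
        strong = flank_left + cons + flank_right
        weak_seq = strong[:25] + weak + strong[26:]
        if effect == reg.LOSS:
            return reg.FlankingPair("s", strong, weak_seq), pwm
        return reg.FlankingPair("s", weak_seq, strong), pwm

    def test_loss_gain_no_effect(self, rng):
        pair, pwm = self._planted_pair(rng, reg.LOSS)
        assert reg.classify_consequence(pair, pwm).effect == reg.LOSS
        pair, pwm = self._planted_pair(rng, reg.GAIN)
        assert reg.classify_consequence(pair, pwm).effect == reg.GAIN
        # hits present in both alleles (or neither) -> no strong effect
        both = reg.FlankingPair("s", pair.ref_seq, pair.ref_seq[:25] + "A" + pair.ref_seq[26:])
        assert (
            reg.classify_consequence(both, pwm, mss_cutoff=0.0, core_cutoff=0.0).effect
            == reg.NO_STRONG_EFFECT
        )

    def test_allele_swap_antisymmetry(self, rng):
        for effect in (reg.LOSS, reg.GAIN):
            pair, pwm = self._planted_pair(rng, effect)
            swapped = reg.FlankingPair(pair.snp_id, pair.alt_seq, pair.ref_seq)
            a = reg.classify_consequence(pair, pwm).effect
            b = reg.classify_consequence(swapped, pwm).effect
            assert {a, b} == {reg.LOSS, reg.GAIN}

    def test_hits_outside_snp_have_equal_scores(self, rng):
        """A motif window not covering the SNP position scores identically
        on both alleles, so only SNP-overlapping sites can cause Gain/Loss."""
        pwm = random_pwm(rng, length=8)
        seq = "".join(rng.choice(list("ACGT"), 51))
        alt_base = [b for b in "ACGT" if b != seq[25]][0]
        pair = reg.FlankingPair("s", seq, seq[:25] + alt_base + seq[26:])
        ref_hits = {(h.offset, h.strand): h.mss for h in reg.scan_sequence(pair.ref_seq, pwm, 0.0, 0.0)}
        alt_hits = {(h.offset, h.strand): h.mss for h in reg.scan_sequence(pair.alt_seq, pwm, 0.0, 0.0)}
        for (off, strand), mss in ref_hits.items():
            if not (off <= 25 <= off + pwm.length - 1):
                assert alt_hits[(off, strand)] == pytest.approx(mss)


class TestIdentifyRsnps:
    def test_planted_events_recovered(self, small_dataset):
        ds = small_dataset
        kept = reg.filter_snps_by_maf(ds.snps)
        cons = reg.identify_rsnps(kept, ds.genome, ds.annotations, ds.pwms)
        found = {(c.snp_id, c.pwm_name, c.effect) for c in cons}
        for p in ds.truth.planted_rsnps:
            assert (p.snp_id, p.pwm_names[0], p.effect) in found
        assert all(c.effect in (reg.GAIN, reg.LOSS) for c in cons)

    def test_empty_pwm_library(self, small_dataset):
        ds = small_dataset
        assert reg.identify_rsnps(ds.snps[:10], ds.genome, ds.annotations, []) == []

    def test_deterministic_ordering(self, small_dataset):
        ds = small_dataset
        kept = reg.filter_snps_by_maf(ds.snps)[:50]
        a = reg.identify_rsnps(kept, ds.genome, ds.annotations, ds.pwms)
        b = reg.identify_rsnps(list(reversed(kept)), ds.genome, ds.annotations, ds.pwms)
        assert [(c.snp_id, c.pwm_name, c.effect) for c in a] == [
            (c.snp_id, c.pwm_name, c.effect) for c in b
        ]
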