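"""PWM parsing, exact score distributions, allele-aware scoring, density profiles."""

import itertools
from collections import defaultdict

import numpy as np
import pytest

from finelocus.motif import (
    PWM,
    MotifError,
    _score_distribution,
    allele_best_scores,
    density_profile,
    parse_jaspar,
    relative_score,
    scan_sequences,
    score_pvalue,
    shuffle_pwm,
    write_jaspar,
)


@pytest.fixture
def toy_pwm(rng):
    return PWM(counts=rng.integers(0, 30, size=(4, 5)).astype(float))


JASPAR_RECORD = """>MA0000.1 TESTMOTIF
A [ 10  2  0 25 ]
C [  5  1  0  0 ]
G [  3 25  0  0 ]
T [  2  2 30  5 ]
"""


class TestParseJaspar:
    def test_two_column_roundtrip(self):
        pwm = PWM(counts=np.array([[1.0, 2], [3, 4], [5, 6], [7, 8]]))
        back = parse_jaspar(write_jaspar(pwm))
        np.testing.assert_array_equal(back.counts, pwm.counts)

    def test_bracketed_record_matches_hand_read_counts(self):
        pwm = parse_jaspar(JASPAR_RECORD)
        expect = np.array(
            [[10, 2, 0, 25], [5, 1, 0, 0], [3, 25, 0, 0], [2, 2, 30, 5]], dtype=float
        )
        np.testing.assert_array_equal(pwm.counts, expect)
        assert pwm.name == "MA0000.1 TESTMOTIF"

    def test_ragged_rows_rejected(self):
        bad = ">x\nA [ 1 2 ]\nC [ 3 ]\nG [ 4 5 ]\nT [ 6 7 ]\n"
        with pytest.raises(MotifError, match="unequal"):
            parse_jaspar(bad)

    def test_missing_base_row(self):
        bad = ">x\nA [ 1 2 ]\nC [ 3 4 ]\nG [ 4 5 ]\n"
        with pytest.raises(MotifError, match="T"):
            parse_jaspar(bad)


class TestRelativeScore:
    def test_consensus_scores_exactly_one(self, toy_pwm):
        assert relative_score(toy_pwm, toy_pwm.consensus()) == 1.0

    def test_anti_consensus_scores_exactly_zero(self, toy_pwm):
        anti = "".join("ACGT"[i] for i in toy_pwm.log_odds.argmin(axis=0))
        assert relative_score(toy_pwm, anti) == 0.0

    def test_hand_computed_two_column_value(self):
        pwm = PWM(
            counts=np.array([[8.0, 0], [0, 8], [0, 0], [0, 0]]), pseudocount=0.8
        )
        lo = pwm.log_odds
        expect = (lo[0, 0] + lo[3, 1] - pwm.score_min) / (
            pwm.score_max - pwm.score_min
        )
        assert abs(relative_score(pwm, "AT") - expect) < 1e-12

    def test_non_acgt_position_reported(self, toy_pwm):
        with pytest.raises(MotifError, match="position 2"):
            relative_score(toy_pwm, "ACNGT")

    def test_wrong_length_rejected(self, toy_pwm):
        with pytest.raises(MotifError, match="length"):
            relative_score(toy_pwm, "ACGT")


class TestScoreDistribution:
    @pytest.mark.parametrize("length", [3, 5, 8])
    def test_dp_equals_brute_force_enumeration(self, length, rng):
        pwm = PWM(
            counts=rng.integers(0, 20, size=(4, length)).astype(float),
            background=np.array([0.29, 0.21, 0.21, 0.29]),
        )
        gran = 1e-3
        offset, probs, _ = _score_distribution(pwm, gran)
        iscores = np.round(pwm.log_odds / gran).astype(int)
        brute = defaultdict(float)
        for seq in itertools.product(range(4), repeat=length):
            s = sum(iscores[b, i] for i, b in enumerate(seq))
            brute[s] += float(np.prod([pwm.background[b] for b in seq]))
        tv = 0.5 * sum(
            abs(brute.get(offset + i, 0.0) - probs[i]) for i in range(len(probs))
        )
        extra = 0.5 * sum(
            v for k, v in brute.items() if not offset <= k < offset + len(probs)
        )
        assert tv + extra < 1e-12

    def test_total_mass_one_at_any_granularity(self, toy_pwm):
        for gran in (1e-2, 1e-3, 1e-4):
            _, probs, _ = _score_distribution(toy_pwm, gran)
            assert abs(probs.sum() - 1.0) < 1e-9

    def test_consensus_pvalue_closed_form_uniform_bg(self):
        # unambiguous consensus, uniform background: p(S_max) = 0.25^L
        pwm = PWM(counts=np.array([[9.0, 0, 0], [0, 9, 0], [0, 0, 9], [0, 0, 0]]))
        p = score_pvalue(pwm, pwm.score_max)
        assert abs(p - 0.25**3) < 1e-12

    def test_minimal_score_pvalue_one(self, toy_pwm):
        assert score_pvalue(toy_pwm, toy_pwm.score_min) == 1.0


class TestScan:
    def test_planted_consensus_found_at_offset(self, rng):
        pwm = PWM(counts=np.diag([30.0] * 4)[:4] @ np.eye(4))
        pwm = PWM(counts=np.array([[30.0, 0, 0, 0], [0, 30, 0, 0],
                                   [0, 0, 30, 0], [0, 0, 0, 30]]))
        cons = pwm.consensus()
        bg = "".join(rng.choice(["A", "C"], size=300))  # consensus cannot arise
        seq = bg[:100] + cons + bg[100:]
        hits = scan_sequences({"s": seq}, pwm, p_cutoff=1e-2, both_strands=False)
        assert len(hits) == 1
        assert hits[0].start == 100

    def test_background_hit_count_within_poisson_band(self, rng):
        pwm = PWM(counts=rng.integers(0, 12, size=(4, 8)).astype(float))
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        hits = scan_sequences(
            {"s": seq}, pwm, p_cutoff=1e-4, both_strands=True, non_overlapping=False
        )
        # ~2e4 windows at p<=1e-4: expect about 2 hits; 99% band upper tail
        from scipy.stats import poisson

        assert len(hits) <= poisson.ppf(0.995, 2 * 10_000 * 1e-4) + 1

    def test_reverse_complement_symmetry(self, rng):
        pwm = PWM(counts=rng.integers(0, 15, size=(4, 6)).astype(float))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        seq = "".join(rng.choice(list("ACGT"), size=400))
        rc = "".join(comp[b] for b in reversed(seq))
        fwd = scan_sequences({"s": seq}, pwm, p_cutoff=0.05, non_overlapping=False)
        rev = scan_sequences({"s": rc}, pwm, p_cutoff=0.05, non_overlapping=False)
        # mirrored: a +-strand hit at i maps to a --strand hit at L-6-i
        fwd_set = {(h.start, h.strand, round(h.score, 9)) for h in fwd}
        mirrored = {
            (len(seq) - 6 - h.start, {"+": "-", "-": "+"}[h.strand], round(h.score, 9))
            for h in rev
        }
        assert fwd_set == mirrored

    def test_non_overlapping_greedy_keeps_best(self):
        pwm = PWM(counts=np.array([[30.0, 0], [0, 30], [0, 0], [0, 0]]))
        # overlapping AC at 0 and 2 within ACAC; both windows score, greedy keeps both
        hits = scan_sequences({"s": "ACACGG"}, pwm, p_cutoff=1.0, both_strands=False)
        starts = [h.start for h in hits]
        assert 0 in starts and 2 in starts


class TestAlleleScores:
    def test_identical_alleles_zero_delta(self, toy_pwm):
        ref, alt, delta = allele_best_scores(toy_pwm, "ACGTA", "CC", "CC", "TGCAT")
        assert delta == 0.0
        assert ref.score == alt.score

    def test_indel_destroys_planted_site(self):
        pwm = PWM(counts=np.array([[30.0, 0, 0, 0], [0, 30, 0, 0],
                                   [0, 0, 30, 0], [0, 0, 0, 30]]))
        # ref haplotype contains consensus ACGT across the allele; alt deletes the C
        ref_hit, alt_hit, delta = allele_best_scores(pwm, "AAAA", "CG", "G", "TAAA")
        assert ref_hit.rel_score == 1.0
        assert alt_hit.rel_score < 1.0
        assert delta > 0

    def test_matches_exhaustive_window_enumeration(self, rng):
        pwm = PWM(counts=rng.integers(0, 20, size=(4, 4)).astype(float))
        flank5, ref, alt, flank3 = "ACGTA", "TA", "T", "GGCAT"
        for allele, hit in zip(
            (ref, alt), allele_best_scores(pwm, flank5, ref, alt, flank3)[:2]
        ):
            hap = flank5 + allele + flank3
            comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
            best = -np.inf
            for start in range(len(hap) - 3):
                win = hap[start : start + 4]
                if start + 4 <= len(flank5) or start >= len(flank5) + len(allele):
                    continue  # window must overlap the allele
                rc = "".join(comp[b] for b in reversed(win))
                best = max(best, relative_score(pwm, win), relative_score(pwm, rc))
            assert hit.rel_score == pytest.approx(best, abs=1e-12)

    def test_short_flank_rejected(self, toy_pwm):
        with pytest.raises(MotifError, match="at least 4"):
            allele_best_scores(toy_pwm, "ACG", "T", "TA", "ACGTA")


class TestShuffle:
    def test_column_multiset_preserved(self, toy_pwm):
        shuf = shuffle_pwm(toy_pwm, seed=1)
        orig = sorted(map(tuple, toy_pwm.counts.T.tolist()))
        new = sorted(map(tuple, shuf.counts.T.tolist()))
        assert orig == new

    def test_information_content_unchanged(self, toy_pwm):
        shuf = shuffle_pwm(toy_pwm, seed=2)
        assert shuf.information_content() == pytest.approx(
            toy_pwm.information_content()
        )

    def test_seeds_give_different_orders(self, rng):
        pwm = PWM(counts=rng.integers(1, 20, size=(4, 8)).astype(float))
        a = shuffle_pwm(pwm, seed=1)
        b = shuffle_pwm(pwm, seed=2)
        assert not np.array_equal(a.counts, b.counts)
        c = shuffle_pwm(pwm, seed=1)
        assert np.array_equal(a.counts, c.counts)


class TestDensityProfile:
    def test_uniform_targets_fold_change_one(self, rng):
        genome = 2_000_000
        refs = rng.integers(10_000, genome - 10_000, size=300)
        targets = rng.integers(0, genome, size=100_000)
        prof = density_profile(refs, targets, 10_000, 500, genome)
        assert len(prof.fold_change) == 40
        assert np.all(np.abs(prof.fold_change - 1.0) < 0.1)

    def test_centered_targets_peak_in_central_bin(self, rng):
        genome = 1_000_000
        refs = rng.integers(20_000, genome - 20_000, size=500)
        prof = density_profile(refs, refs, 10_000, 500, genome)
        assert int(np.argmax(prof.fold_change)) == prof.central_bin()

    def test_zero_targets_warns_all_zero(self):
        with pytest.warns(UserWarning):
            prof = density_profile(np.array([50_000]), np.array([]), 10_000, 500, 10**6)
        assert np.all(prof.fold_change == 0)

    def test_window_must_divide_range(self):
        with pytest.raises(ValueError):
            density_profile(np.array([0]), np.array([1]), 10_000, 300, 10**6)
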