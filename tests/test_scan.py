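import numpy as np
import pytest

from _oracles import brute_survival
from regvar import scan as sc
from regvar.background import estimate_markov, revcomp
from regvar.types import PWMMatrix, VariantWindow


class TestPwmFrequencies:
    def test_no_pseudocount(self):
        f = sc.pwm_frequencies(np.array([[10, 0, 0, 0]]), 0.0)
        np.testing.assert_allclose(f, [[1, 0, 0, 0]])

    def test_uniform_column_stays_uniform(self):
        f = sc.pwm_frequencies(np.array([[1, 1, 1, 1]]), 3.7)
        np.testing.assert_allclose(f, 0.25)

    def test_additive_smoothing_arithmetic(self):
        f = sc.pwm_frequencies(np.array([[3, 1, 0, 0]]), 1.0)
        np.testing.assert_allclose(f, np.array([[3.25, 1.25, 0.25, 0.25]]) / 5.0)
        assert f.sum() == pytest.approx(1.0)


class TestSiteWeight:
    def test_uniform_pwm_uniform_background_is_zero(self, uniform_bg):
        freqs = np.full((5, 4), 0.25)
        assert sc.site_weight(freqs, uniform_bg, "ACGTA") == pytest.approx(0.0)

    def test_consensus_matches_hand_sum(self, uniform_bg):
        freqs = sc.pwm_frequencies(
            np.array([[8, 0, 1, 1], [0, 9, 1, 0], [1, 0, 9, 0], [0, 1, 0, 9]]), 1.0
        )
        got = sc.site_weight(freqs, uniform_bg, "ACGT")
        want = sum(np.log2(freqs[i, i] / 0.25) for i in range(4))
        assert got == pytest.approx(want)

    def test_ambiguous_base_returns_none(self, uniform_bg, caplog):
        freqs = np.full((4, 4), 0.25)
        with caplog.at_level("WARNING"):
            assert sc.site_weight(freqs, uniform_bg, "ACNT") is None

    def test_palindromic_pwm_equal_on_both_strands(self, uniform_bg):
        counts = np.array([[9, 1, 1, 1], [1, 1, 1, 9]], dtype=float)  # A..T palindrome
        freqs = sc.pwm_frequencies(counts, 1.0)
        site = "AT"
        assert sc.site_weight(freqs, uniform_bg, site) == pytest.approx(
            sc.site_weight(freqs, uniform_bg, revcomp(site))
        )


@pytest.fixture(scope="module")
def setup():
    rng = np.random.default_rng(5)
    seqs = ["".join(rng.choice(list("ACGT"), size=300))]
    bg = estimate_markov(seqs, order=1, pseudocount=1.0)
    counts = rng.integers(1, 30, size=(4, 4)).astype(float)
    freqs = sc.pwm_frequencies(counts, 1.0)
    return freqs, bg, sc.ScoreDistribution(freqs, bg)


class TestWeightPvalue:
    def test_below_minimum_is_one(self, setup):
        _, _, dist = setup
        assert dist.pvalue(-1e6) == 1.0
        assert dist.pvalue(-np.inf) == 1.0

    def test_above_maximum_is_floor(self, setup):
        _, _, dist = setup
        assert dist.pvalue(1e6) == dist.p_floor
        assert dist.p_floor > 0

    def test_monotone_nonincreasing_in_weight(self, setup):
        _, _, dist = setup
        ws = np.linspace(-20, 20, 100)
        ps = [dist.pvalue(w) for w in ws]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_matches_exhaustive_enumeration(self, setup):
        """Thresholds are drawn inside the achievable score range, where the
        survival function is well defined."""
        from _oracles import brute_score_distribution

        freqs, bg, dist = setup
        W, P = brute_score_distribution(freqs, bg)
        achievable = W[np.isfinite(W) & (P > 0)]
        for q in (0.05, 0.3, 0.6, 0.9, 0.99):
            w = float(np.quantile(achievable, q))
            p = dist.pvalue(w)
            lo = brute_survival(freqs, bg, w + 0.02)
            hi = brute_survival(freqs, bg, w - 0.02)
            assert lo - 1e-12 <= p <= hi + 1e-12


def _window(ref, alt, offset):
    return VariantWindow("v", ref, alt, (len(ref) - 1) // 2, offset)


@pytest.fixture(scope="module")
def bg():
    rng = np.random.default_rng(9)
    return estimate_markov(
        ["".join(rng.choice(list("ACGT"), size=400))], order=2, pseudocount=1.0
    )


class TestScanVariant:
    def test_planted_disruption_detected(self, bg, rng):
        # sharp motif; ref window carries the consensus, alt flips one base
        consensus = "ACGTACGT"
        counts = np.full((8, 4), 1.0)
        for j, b in enumerate(consensus):
            counts[j, "ACGT".index(b)] = 60
        pwm = PWMMatrix("M", "TF", counts)
        flank = "".join(rng.choice(list("ACGT"), size=12))
        flank2 = "".join(rng.choice(list("ACGT"), size=12))
        ref = flank + consensus + flank2
        offset = len(flank) + 3  # variant at consensus column 3 (T -> G)
        alt = ref[:offset] + "G" + ref[offset + 1 :]
        res = sc.scan_variant(pwm, bg, _window(ref, alt, offset))
        assert res.effect == "disrupt"
        assert res.weight_diff > 1
        assert res.pval_ratio > 10
        assert res.best_ref.offset <= offset < res.best_ref.offset + 8

    def test_matrix_longer_than_window_skipped(self, bg, caplog):
        pwm = PWMMatrix("M", "TF", np.full((9, 4), 1.0))
        with caplog.at_level("WARNING"):
            res = sc.scan_variant(pwm, bg, _window("ACGTA", "ACTTA", 2))
        assert res is None

    def test_variant_neutral_matrix_gives_unit_ratio(self, uniform_bg):
        pwm = PWMMatrix("M", "TF", np.full((3, 4), 2.0))  # indifferent matrix
        res = sc.scan_variant(pwm, uniform_bg, _window("ACGTACG", "ACTTACG", 2))
        assert res.weight_diff == pytest.approx(0.0)
        assert res.pval_ratio == pytest.approx(1.0)
        assert res.effect == "none"

    def test_tie_broken_to_plus_strand_lowest_offset(self, uniform_bg):
        pwm = PWMMatrix("M", "TF", np.full((2, 4), 1.0))  # all sites tie at 0
        res = sc.scan_variant(pwm, uniform_bg, _window("ACGTACG", "ACTTACG", 2))
        assert res.best_ref.strand == "+"
        assert res.best_ref.offset == 1  # lowest offset covering the variant

    def test_reverse_complement_window_symmetry(self, bg, rng):
        counts = rng.integers(1, 50, size=(6, 4)).astype(float)
        pwm = PWMMatrix("M", "TF", counts)
        ref = "".join(rng.choice(list("ACGT"), size=21))
        alt = ref[:10] + ("A" if ref[10] != "A" else "C") + ref[11:]
        res_fwd = sc.scan_variant(pwm, bg, _window(ref, alt, 10))
        res_rev = sc.scan_variant(pwm, bg, _window(revcomp(ref), revcomp(alt), 10))
        assert res_fwd.best_ref.weight == pytest.approx(res_rev.best_ref.weight, abs=1e-9)
        assert res_fwd.best_alt.weight == pytest.approx(res_rev.best_alt.weight, abs=1e-9)
        assert res_fwd.best_ref.strand != res_rev.best_ref.strand or (
            res_fwd.best_ref.weight == res_fwd.best_alt.weight
        )


def _result(w_max, diff, p_min, ratio):
    from regvar.types import ScanHit, VariantMatrixResult

    hit_hi = ScanHit("v", "m", "ref", 0, "+", w_max, p_min)
    hit_lo = ScanHit("v", "m", "alt", 0, "+", w_max - diff, p_min * ratio)
    return VariantMatrixResult("v", "m", hit_hi, hit_lo, diff, ratio, "disrupt")


class TestScanFilters:
    def test_all_thresholds_cleared(self):
        assert sc.apply_scan_filters([_result(5, 2, 1e-4, 50)]) != []

    def test_ratio_boundary_is_strict(self):
        assert sc.apply_scan_filters([_result(5, 2, 1e-4, 10.0)]) == []

    def test_zero_weight_difference_dropped(self):
        assert sc.apply_scan_filters([_result(5, 0.0, 1e-4, 1.0)]) == []

    def test_weak_site_dropped(self):
        assert sc.apply_scan_filters([_result(0.9, 2, 1e-4, 50)]) == []

    def test_insignificant_site_dropped(self):
        assert sc.apply_scan_filters([_result(5, 2, 1e-3, 50)]) == []
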