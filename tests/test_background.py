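import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import markov_counts_by_hand
from regvar import background as bgm
from regvar.types import ValidationError, Variant

DNA = st.text(alphabet="ACGT", min_size=10, max_size=60)


class TestEstimateMarkov:
    def test_order0_single_base_single_strand(self):
        bg = bgm.estimate_markov(["AAAA"], order=0, pseudocount=0, both_strands=False)
        assert bg.cond[0, 0] == 1.0
        assert bg.sequence_logprob("AAA") == 0.0

    def test_order0_acgt_uniform(self):
        bg = bgm.estimate_markov(["ACGT"], order=0, pseudocount=0)
        np.testing.assert_allclose(bg.cond[0], 0.25)

    def test_order2_matches_hand_counting(self):
        seq = "ACGTACGGCCATTAGGCCAA"  # 20 bp
        bg = bgm.estimate_markov([seq], order=2, pseudocount=0.0)
        hand = markov_counts_by_hand([seq], order=2)
        for (ctx, nxt), n in hand.items():
            ci = sum("ACGT".index(b) * 4**(1 - i) for i, b in enumerate(ctx))
            row_total = sum(hand.get((ctx, b), 0) for b in "ACGT")
            assert bg.cond[ci, "ACGT".index(nxt)] == pytest.approx(n / row_total)
        # observed contexts have normalized rows; unseen ones are empty at
        # zero pseudocount
        row_sums = bg.cond.sum(axis=1)
        assert np.allclose(row_sums[row_sums > 0], 1.0)

    def test_order_longer_than_sequences_rejected(self):
        with pytest.raises(ValidationError):
            bgm.estimate_markov(["ACG"], order=3, pseudocount=1)

    def test_ambiguous_characters_skipped(self):
        bg = bgm.estimate_markov(["ACNGT" * 10], order=1, pseudocount=0.0)
        assert np.isfinite(bg.cond[bg.cond > 0]).all()

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(DNA, min_size=1, max_size=3), st.integers(0, 2), DNA)
    def test_strand_symmetry(self, seqs, order, probe):
        """The fitted model gives a sequence and its reverse complement the
        same probability, exactly."""
        bg = bgm.estimate_markov(seqs, order=order, pseudocount=0.5)
        a = bg.sequence_logprob(probe)
        b = bg.sequence_logprob(bgm.revcomp(probe))
        assert a == pytest.approx(b, abs=1e-9)

    @pytest.mark.parametrize("order", [0, 1, 2])
    def test_total_probability_is_one(self, order, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=80)) for _ in range(3)]
        bg = bgm.estimate_markov(seqs, order=order, pseudocount=1.0)
        L = 6
        total = sum(
            2.0 ** bg.sequence_logprob("".join(w))
            for w in itertools.product("ACGT", repeat=L)
        )
        assert total == pytest.approx(1.0, abs=1e-9)


def test_sequence_logprob_matches_manual_chain():
    bg = bgm.estimate_markov(["ACACACAC"], order=1, pseudocount=0.0, both_strands=False)
    # chain: stationary("A") * P(C|A) * P(A|C)
    want = math.log2(bg.stationary[0]) + math.log2(bg.cond[0, 1]) + math.log2(bg.cond[1, 0])
    assert bg.sequence_logprob("ACA") == pytest.approx(want)


def test_uniform_logprob_value(uniform_bg):
    assert uniform_bg.sequence_logprob("ACGT") == pytest.approx(-8.0)


class TestVariantWindows:
    GENOME = {"chr1": "A" * 30 + "ACGTAGG" + "C" * 30}

    def test_default_flank_geometry(self):
        v = Variant("rs1", "chr1", 33, "G", "T")
        (w,) = bgm.build_variant_windows(self.GENOME, [v], flank=30)
        assert len(w.ref_seq) == 61
        assert w.variant_offset == 30
        assert w.ref_seq[30] == "G" and w.alt_seq[30] == "T"

    def test_small_flank_substitution(self):
        genome = {"chr1": "AACGTAA"}
        v = Variant("rs1", "chr1", 4, "G", "T")
        (w,) = bgm.build_variant_windows(genome, [v], flank=2)
        assert w.ref_seq == "ACGTA"
        assert w.alt_seq == "ACTTA"
        assert w.variant_offset == 2

    def test_reference_mismatch_names_variant(self):
        v = Variant("rs_bad", "chr1", 33, "C", "T")
        with pytest.raises(ValidationError, match="rs_bad"):
            bgm.build_variant_windows(self.GENOME, [v], flank=3)

    def test_truncated_at_chromosome_start(self, caplog):
        v = Variant("rs1", "chr1", 2, "A", "G")
        with caplog.at_level("WARNING"):
            (w,) = bgm.build_variant_windows(self.GENOME, [v], flank=5)
        assert w.variant_offset == 1
        assert len(w.ref_seq) == 7
        assert "truncated" in caplog.text


def test_backgrounds_for_sets_fallback():
    seqs = {"a": ["ACGT" * 800], "b": ["ACGT" * 3]}
    models = bgm.backgrounds_for_sets(seqs, order=1, min_total_bp=1000)
    assert models["a"].set_label == "a"
    assert models["b"].set_label == "global"  # thin set falls back


def test_background_serialization_roundtrip(tmp_path, rng):
    seqs = ["".join(rng.choice(list("ACGT"), size=100))]
    bg = bgm.estimate_markov(seqs, order=2, pseudocount=1.0, set_label="c")
    bgm.write_background(bg, tmp_path / "bg.tsv")
    back = bgm.read_background(tmp_path / "bg.tsv")
    assert back.order == 2 and back.set_label == "c"
    np.testing.assert_allclose(back.cond, bg.cond, atol=1e-9)
    np.testing.assert_allclose(back.stationary, bg.stationary, atol=1e-9)
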