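import numpy as np
import pytest
from scipy import stats

from regvar import controls as ctl
from regvar.types import GeneAnnotation, PWMMatrix, Variant


class TestPermuteMatrix:
    @pytest.fixture()
    def pwm(self, rng):
        return PWMMatrix("M", "TF", rng.integers(1, 40, size=(7, 4)).astype(float))

    def test_length_one_permutes_cell_values_only(self):
        pwm = PWMMatrix("M", "TF", np.array([[5.0, 1.0, 2.0, 0.5]]))
        for perm in ctl.permute_matrix(pwm, 5, seed=3):
            assert sorted(perm.counts[0]) == sorted(pwm.counts[0])

    def test_information_content_conserved(self, pwm):
        for perm in ctl.permute_matrix(pwm, 5, seed=1):
            assert perm.information_content() == pytest.approx(
                pwm.information_content(), abs=1e-9
            )

    def test_column_value_multisets_conserved(self, pwm):
        for perm in ctl.permute_matrix(pwm, 5, seed=1):
            got = sorted(map(tuple, np.sort(perm.counts, axis=1)))
            want = sorted(map(tuple, np.sort(pwm.counts, axis=1)))
            assert got == want

    def test_same_seed_reproduces(self, pwm):
        a = ctl.permute_matrix(pwm, 3, seed=7)
        b = ctl.permute_matrix(pwm, 3, seed=7)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.counts, y.counts)


def _gene(gid, chrom, start, end, tss):
    return GeneAnnotation(gid, gid, chrom, start, end, "+", tss)


class TestMatchAttributes:
    def test_tss_distance_and_density(self):
        genes = [
            _gene("g1", "chr1", 10_000, 12_000, 10_000),
            _gene("g2", "chr1", 40_000, 45_000, 40_000),
            _gene("g3", "chr1", 90_000, 95_000, 90_000),
            _gene("g4", "chr2", 10_000, 12_000, 10_000),
        ]
        v = Variant("rs1", "chr1", 11_000, "A", "G")
        attrs = ctl.compute_match_attributes([v], genes, {})
        a = attrs["rs1"]
        assert a.tss_distance == 1000
        assert a.gene_density == 3  # all chr1 genes within 100 kbp
        assert a.coding_class == "non-coding"

    def test_ld_count_at_r2_cutoff(self):
        v = Variant("rs1", "chr1", 500, "A", "G")
        ld = {"rs1": {"x": 0.15, "y": 0.09}}
        attrs = ctl.compute_match_attributes([v], [_gene("g", "chr1", 100, 300, 100)], ld)
        assert attrs["rs1"].ld_count == 1

    def test_no_genes_on_chromosome_gives_sentinel(self):
        v = Variant("rs1", "chrX", 500, "A", "G")
        attrs = ctl.compute_match_attributes([v], [_gene("g", "chr1", 100, 300, 100)], {})
        assert attrs["rs1"].tss_distance is None


def _clone_pool(target_pos, n, chrom="chr1"):
    genes = [_gene("g1", chrom, 50_000, 55_000, 50_000)]
    target = Variant("t", chrom, target_pos, "A", "G")
    pool = [Variant(f"c{i}", chrom, target_pos + 500 + 37 * i, "A", "G") for i in range(n)]
    return target, pool, genes


class TestMatchedSampling:
    def test_clone_pool_fills_ratio_within_windows(self):
        target, pool, genes = _clone_pool(52_000, 30)
        attrs = ctl.compute_match_attributes([target] + pool, genes, {})
        (a,) = ctl.sample_matched_controls(["t"], [v.id for v in pool], attrs, "strict", 10, 0)
        assert len(a.control_variant_ids) == 10
        t = attrs["t"]
        for cid in a.control_variant_ids:
            c = attrs[cid]
            assert abs(c.tss_distance - t.tss_distance) <= 5000
            assert abs(c.gene_density - t.gene_density) <= 5
            assert abs(c.ld_count - t.ld_count) <= 50
            assert c.coding_class == t.coding_class and c.variant_type == t.variant_type

    def test_targets_never_selected_as_controls(self):
        target, pool, genes = _clone_pool(52_000, 12)
        attrs = ctl.compute_match_attributes([target] + pool, genes, {})
        (a,) = ctl.sample_matched_controls(
            ["t"], ["t"] + [v.id for v in pool], attrs, "relaxed", 1000, 0
        )
        assert "t" not in a.control_variant_ids

    def test_shortfall_takes_all_eligible(self, caplog):
        target, pool, genes = _clone_pool(52_000, 4)
        attrs = ctl.compute_match_attributes([target] + pool, genes, {})
        (a,) = ctl.sample_matched_controls(["t"], [v.id for v in pool], attrs, "strict", 10, 0)
        assert sorted(a.control_variant_ids) == sorted(v.id for v in pool)

    def test_same_seed_identical_assignment(self):
        target, pool, genes = _clone_pool(52_000, 30)
        attrs = ctl.compute_match_attributes([target] + pool, genes, {})
        a = ctl.sample_matched_controls(["t"], [v.id for v in pool], attrs, "strict", 10, 123)
        b = ctl.sample_matched_controls(["t"], [v.id for v in pool], attrs, "strict", 10, 123)
        assert a[0].control_variant_ids == b[0].control_variant_ids

    def test_strict_requires_same_chromosome(self):
        genes = [_gene("g1", "chr1", 50_000, 55_000, 50_000), _gene("g2", "chr2", 50_000, 55_000, 50_000)]
        target = Variant("t", "chr1", 52_000, "A", "G")
        other = Variant("c0", "chr2", 52_000, "A", "G")
        attrs = ctl.compute_match_attributes([target, other], genes, {})
        (strict,) = ctl.sample_matched_controls(["t"], ["c0"], attrs, "strict", 10, 0)
        (relaxed,) = ctl.sample_matched_controls(["t"], ["c0"], attrs, "relaxed", 10, 0)
        assert strict.control_variant_ids == []
        assert relaxed.control_variant_ids == ["c0"]


class TestWilcoxonGreater:
    def test_enumerated_small_case(self):
        assert ctl.wilcoxon_greater([10, 11], [1, 2]) == pytest.approx(1 / 6)

    def test_identical_samples_not_significant(self):
        p = ctl.wilcoxon_greater([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p >= 0.5

    def test_exact_agrees_with_scipy_exact(self, rng):
        for n, m in [(2, 3), (4, 4), (5, 5), (3, 7), (6, 6)]:
            obs = rng.normal(size=n)
            con = rng.normal(size=m)
            mine = ctl.wilcoxon_greater(obs, con)
            ref = stats.mannwhitneyu(obs, con, alternative="greater", method="exact").pvalue
            if n + m <= 12:
                assert mine == pytest.approx(ref, abs=1e-12)
            else:
                assert mine == pytest.approx(ref, abs=0.02)

    def test_exact_close_to_asymptotic(self, rng):
        obs = rng.normal(0.8, 1, size=6)
        con = rng.normal(0, 1, size=6)
        exact = ctl.wilcoxon_greater(list(obs), list(con))
        approx = stats.mannwhitneyu(obs, con, alternative="greater", method="asymptotic").pvalue
        assert exact == pytest.approx(approx, abs=0.02)

    def test_empty_sample_rejected(self):
        with pytest.raises(Exception):
            ctl.wilcoxon_greater([], [1.0])


class TestShapiroCheck:
    def test_heavy_tailed_ratios_rejected_as_normal(self, rng):
        hits = 0
        for _ in range(20):
            vals = np.exp(rng.normal(0, 2, size=100))  # log-normal ratios
            if ctl.shapiro_wilk_check(vals) < 0.05:
                hits += 1
        assert hits >= 19

    def test_constant_sample_not_applicable(self):
        assert ctl.shapiro_wilk_check([3.0, 3.0, 3.0, 3.0]) is None

    def test_too_small_sample_not_applicable(self):
        assert ctl.shapiro_wilk_check([1.0, 2.0]) is None


def _fake_results(matrix_id, ratios):
    from regvar.types import ScanHit, VariantMatrixResult

    out = []
    for i, r in enumerate(ratios):
        hit = ScanHit(f"v{i}", matrix_id, "ref", 0, "+", 5.0, 1e-4)
        alt = ScanHit(f"v{i}", matrix_id, "alt", 0, "+", 2.0, 1e-4 * r)
        out.append(VariantMatrixResult(f"v{i}", matrix_id, hit, alt, 3.0, r, "disrupt"))
    return out


class TestConfirmMotifPairs:
    def test_shifted_motif_confirmed(self, rng):
        obs = _fake_results("M1", list(rng.uniform(50, 200, size=20)))
        null = {"M1": list(rng.uniform(1, 3, size=100))}
        confirmed, conf = ctl.confirm_motif_pairs(obs, null, null, null)
        assert conf["M1"].confirmed
        assert len(confirmed) == len(obs)

    def test_null_motif_rarely_confirmed(self):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            obs = _fake_results("M1", list(r.uniform(1, 30, size=15)))
            null = {"M1": list(r.uniform(1, 30, size=100))}
            _, conf = ctl.confirm_motif_pairs(obs, null, null, null)
            hits += conf["M1"].confirmed
        assert hits <= 2  # ~alpha^2 under the two-stage rule

    def test_stage_two_never_rescues_stage_one_rejection(self, rng):
        obs = _fake_results("M1", list(rng.uniform(1, 2, size=10)))
        strong_null = {"M1": list(rng.uniform(100, 200, size=50))}
        weak_null = {"M1": [1.0] * 50}
        _, conf = ctl.confirm_motif_pairs(obs, strong_null, strong_null, weak_null)
        assert not conf["M1"].stage1_confirmed
        assert not conf["M1"].confirmed
        assert conf["M1"].p_matched1000 is None  # stage 2 not even evaluated

    def test_missing_controls_flagged_unconfirmable(self, rng, caplog):
        obs = _fake_results("M1", list(rng.uniform(50, 200, size=10)))
        with caplog.at_level("WARNING"):
            _, conf = ctl.confirm_motif_pairs(obs, {}, {}, None)
        assert conf["M1"].confirmed is False
        assert conf["M1"].p_permuted is None

    def test_bh_adjustment_monotone(self, rng):
        results = []
        nulls = {}
        for i, shift in enumerate([100, 50, 5, 1]):
            mid = f"M{i}"
            results.extend(_fake_results(mid, list(rng.uniform(shift, shift + 10, size=10))))
            nulls[mid] = list(rng.uniform(1, 3, size=60))
        _, conf = ctl.confirm_motif_pairs(results, nulls, nulls, nulls)
        for c in conf.values():
            assert c.q_permuted >= c.p_permuted - 1e-12
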