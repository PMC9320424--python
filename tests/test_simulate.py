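import hashlib
import json
from collections import defaultdict
from pathlib import Path

import numpy as np
import pytest

from regvar import scan as sc
from regvar.background import estimate_markov
from regvar.simulate import (
    SimulationConfig,
    cpg_observed_expected,
    load_dataset,
    null_config,
    simulate,
)
from regvar.types import VariantWindow


def _tree_digest(d: Path) -> dict:
    return {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest()
        for p in sorted(d.iterdir())
    }


def test_same_seed_identical_file_tree(tmp_path):
    cfg = null_config(seed=5)
    a, b = tmp_path / "a", tmp_path / "b"
    simulate(cfg).write(a)
    simulate(cfg).write(b)
    assert _tree_digest(a) == _tree_digest(b)


def test_config_echo(sim_default):
    cfg = sim_default.config
    assert len(sim_default.genes) == cfg.n_genes
    assert len(sim_default.motifs) == cfg.n_motifs
    assert len({g.chrom for g in sim_default.genes}) == cfg.n_chromosomes
    for g in sim_default.genes:
        assert 1 <= g.start <= g.end <= len(sim_default.genome[g.chrom])


def test_cpg_depletion_ratio(sim_default):
    ratio = cpg_observed_expected(sim_default.genome["chr1"])
    assert ratio == pytest.approx(sim_default.config.cpg_depletion, abs=0.05)


def test_motif_information_content_in_range(sim_default):
    lo, hi = sim_default.config.motif_ic_range
    for m in sim_default.motifs:
        max_attainable = m.length * 1.76  # 0.97-consensus column cap
        assert lo - 0.5 <= m.information_content() <= min(hi, max_attainable) + 0.5


def test_locus_probability_structure(sim_default):
    by_locus = defaultdict(list)
    for r in sim_default.gwas_pics:
        by_locus[r.locus_id].append(r.pics_prob)
    planted = set(sim_default.truth.planted_causal)
    for locus, probs in by_locus.items():
        assert sum(probs) == pytest.approx(1.0, abs=1e-9)
        n_above = sum(p > 0.10 for p in probs)
        assert n_above == (1 if locus in planted else 0)


def test_planted_disruption_scores_under_true_motif(sim_default):
    """Planted variants carry a detectable allele effect for their motif,
    by direct scoring against the true PWM (no pipeline involved)."""
    data = sim_default
    by_id = data.variants_by_id()
    motif_by_id = {m.matrix_id: m for m in data.motifs}
    bg = estimate_markov([data.genome["chr1"][:40_000]], order=2)
    checked = 0
    for d in data.truth.planted_binding[:12]:
        v = by_id[d["variant_id"]]
        m = motif_by_id[d["matrix_id"]]
        seq = data.genome[v.chrom]
        ref = seq[v.pos - 31 : v.pos + 30]
        assert ref[30] == v.ref
        alt = ref[:30] + v.alt + ref[31:]
        win = VariantWindow(v.id, ref, alt, 30, 30)
        res = sc.scan_variant(m, bg, win)
        assert res.weight_diff > 1
        assert res.effect == d["effect"]
        checked += 1
    assert checked == 12


def test_planted_coloc_product_bound(sim_default):
    gwas = {r.variant_id: r.pics_prob for r in sim_default.gwas_pics}
    eqtl = {(r.variant_id, r.egene): r.pics_prob for r in sim_default.eqtl_pics}
    for d in sim_default.truth.planted_coloc:
        g = gwas[d["variant_id"]]
        e = eqtl[(d["variant_id"], d["egene"])]
        assert g > 0.4 and e > 0.4
        assert g * e > 0.10


def test_planted_triple_support_is_complete(sim_default):
    data = sim_default
    tf_targets = {(t.tf_name, t.target_gene, t.tissue) for t in data.tftargets}
    eqtl = {(r.variant_id, r.egene) for r in data.eqtl_pics}
    binding = {(d["variant_id"], d["matrix_id"]) for d in data.truth.planted_binding}
    tf_by_matrix = {m.matrix_id: m.tf_name for m in data.motifs}
    brain = [t for t in data.expression.columns if t.startswith("Brain")]
    for d in data.truth.planted_triples:
        assert (d["variant_id"], d["egene"]) in eqtl
        assert ("brain") in {t for tf, g, t in tf_targets if tf == d["tf"] and g == d["egene"]}
        assert any(
            (d["variant_id"], mid) in binding
            for mid, tf in tf_by_matrix.items()
            if tf == d["tf"]
        )
        assert (data.expression.loc[d["tf"], brain] >= 2).any()


def test_distractor_eqtls_avoid_gwas_variants(sim_default):
    gwas = set(sim_default.gwas_variant_ids)
    planted = {d["variant_id"] for d in sim_default.truth.planted_coloc}
    for r in sim_default.eqtl_pics:
        if r.variant_id not in planted:
            assert r.variant_id not in gwas


def test_manifest_entities_exist_in_emitted_files(sim_default, tmp_path):
    out = tmp_path / "ds"
    sim_default.write(out)
    payload = json.loads((out / "truth.json").read_text())
    variants_tsv = (out / "variants.tsv").read_text()
    gwas_tsv = (out / "gwas_pics.tsv").read_text()
    eqtl_tsv = (out / "eqtl_pics.tsv").read_text()
    for vid in payload["truth"]["planted_causal"]:
        assert vid in variants_tsv and vid in gwas_tsv
    for d in payload["truth"]["planted_coloc"]:
        assert d["variant_id"] in eqtl_tsv
    motif_text = (out / "motifs.jaspar").read_text()
    for d in payload["truth"]["planted_binding"]:
        assert d["matrix_id"] in motif_text


def test_write_load_roundtrip(tmp_path, sim_default):
    out = tmp_path / "ds"
    sim_default.write(out)
    back = load_dataset(out)
    assert back.genome.keys() == sim_default.genome.keys()
    assert back.genome["chr1"] == sim_default.genome["chr1"]
    assert len(back.variants) == len(sim_default.variants)
    assert back.truth.planted_causal == sim_default.truth.planted_causal
    assert sorted(back.gwas_variant_ids) == sorted(sim_default.gwas_variant_ids)
    np.testing.assert_allclose(back.motifs[0].counts, sim_default.motifs[0].counts)


def test_null_config_has_no_planted_effects():
    data = simulate(null_config(seed=2))
    assert data.truth.planted_causal == []
    assert data.truth.planted_binding == []
    assert data.truth.planted_triples == []
    assert all(r.pics_prob <= 0.10 for r in data.gwas_pics)


def test_invalid_config_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(n_planted_causal=5, n_loci=3)
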