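"""End-to-end orchestration: fine-mapping through mechanistic evidence.

Stage order: significance filter / PICS -> colocalization -> consequence
sets -> per-set backgrounds -> allele-specific scan -> negative controls
(permuted matrices; matched variants 1:10 and 1:1000) -> per-motif
confirmation -> chromatin-state and TF-expression filters -> evidence
triples.  The report records the funnel counts and every intermediate of
interest.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import annotation, chromatin, colocalization as coloc, controls, fine_mapping as fm, scan as scanning
from .background import MarkovBackground, backgrounds_for_sets, build_variant_windows, fetch_sequence
from .simulate import SimulatedData
from .types import (
    ColocPair,
    EvidenceTriple,
    PWMMatrix,
    Variant,
    VariantMatrixResult,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """Every threshold of the replication surface, in one place."""

    alpha_gwas: float = 5e-8
    pics_threshold: float = 0.10
    clpp_threshold: float = 0.10
    scan: scanning.ScanParams = field(default_factory=scanning.ScanParams)
    background_order: int = 2
    background_pseudocount: float = 1.0
    pwm_pseudocount: float = 1.0
    flank: int = 30
    tpm_threshold: float = 2.0
    cadd_cutoff: float = 15.0
    wilcoxon_alpha: float = 0.05
    n_perm: int = 5
    ratio_strict: int = 10
    ratio_relaxed: int = 1000
    min_background_bp: int = 10_000
    seed: int = 0


@dataclass
class PipelineReport:
    seed: int
    n_associations: int = 0
    n_significant: int = 0
    n_gwas_pics: int = 0
    n_causal: int = 0
    n_coloc_candidates: int = 0
    n_coloc_pairs: int = 0
    fisher_p: float | None = None
    n_scanned_variants: int = 0
    n_scan_results: int = 0
    n_filter_passing: int = 0
    n_confirmed_motifs: int = 0
    n_confirmed_pairs: int = 0
    n_active_variants: int = 0
    n_expressed_tfs: int = 0
    n_triples: int = 0
    coloc_pairs: list[ColocPair] = field(default_factory=list)
    scan_results: list[VariantMatrixResult] = field(default_factory=list)
    filter_passing: list[VariantMatrixResult] = field(default_factory=list)
    confirmed_pairs: list[VariantMatrixResult] = field(default_factory=list)
    confirmations: dict = field(default_factory=dict)
    triples: list[EvidenceTriple] = field(default_factory=list)


def _variants_in_peaks(variants: Sequence[Variant], peaks: Sequence[tuple]) -> list[Variant]:
    spans = defaultdict(list)
    for chrom, s, e, *_ in peaks:
        spans[chrom].append((int(s), int(e)))
    out = []
    for v in variants:
        if any(s <= v.pos - 1 < e for s, e in spans[v.chrom]):
            out.append(v)
    return out


def _peak_sequences_by_set(
    genome: Mapping[str, str],
    peaks: Sequence[tuple],
    variants: Sequence[Variant],
    set_of: Mapping[str, set[str]],
) -> dict[str, list[str]]:
    """Training corpus per consequence set: peak sequences overlapping that
    set's variants."""
    by_set: dict[str, list[str]] = defaultdict(list)
    for chrom, s, e, *_ in peaks:
        seq = fetch_sequence(genome, chrom, int(s) + 1, int(e))
        sets_here: set[str] = set()
        for v in variants:
            if v.chrom == chrom and int(s) <= v.pos - 1 < int(e):
                sets_here |= set_of.get(v.id, set())
        for label in sets_here:
            by_set[label].append(seq)
    return dict(by_set)


def _scan_variant_set(
    windows_by_set: Mapping[str, list],
    matrices: Sequence[PWMMatrix],
    backgrounds: Mapping[str, MarkovBackground],
    pwm_pseudocount: float,
) -> list[VariantMatrixResult]:
    results = []
    for label, windows in sorted(windows_by_set.items()):
        scanner = scanning.MotifScanner(
            matrices, backgrounds.get(label, backgrounds["global"]), pwm_pseudocount
        )
        results.extend(scanner.scan_windows(windows))
    return results


def run_pipeline(data: SimulatedData, params: PipelineParams | None = None) -> PipelineReport:
    """Run every stage on a dataset (typically a simulator output)."""
    p = params or PipelineParams()
    report = PipelineReport(seed=p.seed)
    by_id = data.variants_by_id()

    # --- stage 1: fine-mapping (snapshot mode: consume the PICS table) ---
    report.n_associations = len(data.associations)
    significant = fm.filter_genomewide_significant(data.associations, p.alpha_gwas)
    report.n_significant = len(significant)
    significant_loci = {a.variant_id for a in significant}
    gwas_pics = [r for r in data.gwas_pics if r.locus_id in significant_loci]
    report.n_gwas_pics = len(gwas_pics)
    causal = fm.filter_pics(gwas_pics, p.pics_threshold)
    report.n_causal = len(causal)

    # --- stage 2: colocalization + eQTL enrichment ---
    candidates = coloc.overlap_pics(gwas_pics, data.eqtl_pics, p.pics_threshold)
    report.n_coloc_candidates = len(candidates)
    pairs = coloc.dedup_best_tissue(coloc.filter_clpp(candidates, p.clpp_threshold))
    report.coloc_pairs = pairs
    report.n_coloc_pairs = len(pairs)
    universe = {r.variant_id for r in gwas_pics}
    eqtl_ids = {r.variant_id for r in data.eqtl_pics}
    causal_ids = {r.variant_id for r in causal}
    k = len(causal_ids & eqtl_ids)
    if universe:
        report.fisher_p = coloc.enrichment_fisher(
            k, len(causal_ids), len(eqtl_ids & universe), len(universe)
        )

    # --- stage 3: consequence sets for the scanned (peak-overlapping) GVs ---
    gwas_variants = [by_id[v] for v in data.gwas_variant_ids if v in by_id]
    scan_variants = _variants_in_peaks(gwas_variants, data.peaks)
    report.n_scanned_variants = len(scan_variants)
    set_of = {v.id: annotation.assign_consequence_sets(v) for v in scan_variants}

    # --- stage 4: TF expression filter on the matrix library ---
    brain_tissues = [t for t in data.expression.columns if t.startswith("Brain")] or list(
        data.expression.columns
    )
    expressed = set(
        chromatin.tf_expression_filter(
            [m.tf_name for m in data.motifs], data.expression, brain_tissues, p.tpm_threshold
        )
    )
    matrices = [m for m in data.motifs if m.tf_name in expressed]
    report.n_expressed_tfs = len(matrices)

    # --- stage 5: per-set backgrounds from peak sequences ---
    seqs_by_set = _peak_sequences_by_set(data.genome, data.peaks, scan_variants, set_of)
    backgrounds = backgrounds_for_sets(
        seqs_by_set, p.background_order, p.background_pseudocount, p.min_background_bp
    )

    # --- stage 6: allele-specific scan, per consequence set ---
    windows = {
        w.variant_id: w for w in build_variant_windows(data.genome, scan_variants, p.flank)
    }
    windows_by_set: dict[str, list] = defaultdict(list)
    for vid, sets in set_of.items():
        if vid not in windows:
            continue
        for label in sorted(sets):
            from dataclasses import replace

            windows_by_set[label].append(replace(windows[vid], consequence_set=label))
    results = _scan_variant_set(windows_by_set, matrices, backgrounds, p.pwm_pseudocount)
    report.scan_results = results
    report.n_scan_results = len(results)
    passing = scanning.apply_scan_filters(results, p.scan)
    report.filter_passing = passing
    report.n_filter_passing = len(passing)

    # --- stage 7: negative controls ---
    rng = np.random.default_rng(p.seed)
    # (a) permuted matrices over the same windows
    perm_matrices = []
    for m in matrices:
        perm_matrices.extend(controls.permute_matrix(m, p.n_perm, rng))
    perm_results = _scan_variant_set(windows_by_set, perm_matrices, backgrounds, p.pwm_pseudocount)
    perm_ratios = controls.ratios_by_matrix(perm_results)
    # (b) matched random variants
    pool_variants = [by_id[v] for v in data.pool_variant_ids if v in by_id]
    ld_index = fm.build_ld_index(data.ld_records)
    attrs = controls.compute_match_attributes(
        list(scan_variants) + pool_variants, data.genes, ld_index
    )
    target_ids = [v.id for v in scan_variants]
    pool_ids = [v.id for v in pool_variants]
    gwas_ids = set(data.gwas_variant_ids)
    assign10 = controls.sample_matched_controls(
        target_ids, pool_ids, attrs, "strict", p.ratio_strict, rng, exclude=gwas_ids
    )
    assign1000 = controls.sample_matched_controls(
        target_ids, pool_ids, attrs, "relaxed", p.ratio_relaxed, rng, exclude=gwas_ids
    )
    needed: dict[str, set[str]] = defaultdict(set)  # control -> sets it must mimic
    for assignments in (assign10, assign1000):
        for a in assignments:
            for cid in a.control_variant_ids:
                needed[cid] |= set_of.get(a.target_variant_id, {"a"})
    ctl_windows = {
        w.variant_id: w
        for w in build_variant_windows(
            data.genome, [by_id[c] for c in needed], p.flank
        )
    }
    ctl_by_set: dict[str, list] = defaultdict(list)
    from dataclasses import replace

    for cid, sets in needed.items():
        if cid not in ctl_windows:
            continue
        for label in sorted(sets):
            ctl_by_set[label].append(replace(ctl_windows[cid], consequence_set=label))
    ctl_results = _scan_variant_set(ctl_by_set, matrices, backgrounds, p.pwm_pseudocount)
    ctl_ratio_lookup: dict[tuple[str, str], float] = {}
    for r in ctl_results:
        ctl_ratio_lookup[(r.variant_id, r.matrix_id)] = r.pval_ratio

    def matched_ratios(assignments) -> dict[str, list[float]]:
        chosen = sorted({c for a in assignments for c in a.control_variant_ids})
        out: dict[str, list[float]] = defaultdict(list)
        for cid in chosen:
            for m in matrices:
                ratio = ctl_ratio_lookup.get((cid, m.matrix_id))
                if ratio is not None:
                    out[m.matrix_id].append(ratio)
        return dict(out)

    # --- stage 8: per-motif confirmation ---
    confirmed_pairs, confirmations = controls.confirm_motif_pairs(
        results,
        perm_ratios,
        matched_ratios(assign10),
        matched_ratios(assign1000),
        alpha=p.wilcoxon_alpha,
        filter_passing=passing,
    )
    report.confirmations = confirmations
    report.n_confirmed_motifs = sum(1 for c in confirmations.values() if c.confirmed)
    report.confirmed_pairs = confirmed_pairs
    report.n_confirmed_pairs = len(confirmed_pairs)

    # --- stage 9: chromatin-state filter in brain biosamples ---
    from .types import ChromatinSegment

    segments = [
        ChromatinSegment(c, int(s), int(e), label, data.segment_biosample)
        for c, s, e, label in data.chromhmm
    ]
    confirmed_variants = sorted({r.variant_id for r in confirmed_pairs})
    active = chromatin.active_region_filter(
        [by_id[v] for v in confirmed_variants], segments,
        biosamples=[data.segment_biosample],
    )
    active_ids = {v.id for v in active}
    report.n_active_variants = len(active_ids)
    active_pairs = [r for r in confirmed_pairs if r.variant_id in active_ids]

    # --- stage 10: mechanistic evidence triples ---
    tf_by_matrix = {m.matrix_id: m.tf_name for m in data.motifs}
    report.triples = chromatin.mechanistic_evidence(
        active_pairs, tf_by_matrix, data.eqtl_pics, data.tftargets,
        eqtl_threshold=p.pics_threshold,
    )
    report.n_triples = len(report.triples)
    return report


def report_summary(report: PipelineReport) -> dict:
    """Machine-readable funnel for the JSON report."""
    return {
        "seed": report.seed,
        "associations": report.n_associations,
        "genome_wide_significant": report.n_significant,
        "gwas_pics_records": report.n_gwas_pics,
        "causal_variants": report.n_causal,
        "coloc_candidates": report.n_coloc_candidates,
        "coloc_pairs": report.n_coloc_pairs,
        "fisher_p": report.fisher_p,
        "expressed_tfs": report.n_expressed_tfs,
        "scanned_variants": report.n_scanned_variants,
        "scan_results": report.n_scan_results,
        "filter_passing": report.n_filter_passing,
        "confirmed_motifs": report.n_confirmed_motifs,
        "confirmed_pairs": report.n_confirmed_pairs,
        "active_variants": report.n_active_variants,
        "evidence_triples": report.n_triples,
    }
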