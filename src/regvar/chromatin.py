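"""Chromatin-state filtering, TF expression filtering, and evidence triples.

Variants surviving the binding analysis are kept only when they fall in an
active chromatin state (18-state model) of at least one selected brain
biosample; TFs must be expressed (TPM >= 2) in at least one selected brain
tissue.  Mechanistic GV -> TF -> eGene hypotheses require the variant to be
a confirmed binding-alteration pair, an eQTL for the eGene, and a
ChIP-seq-supported TF -> eGene link in an equivalent tissue.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .types import (
    ACTIVE_STATES,
    BRAIN_BIOSAMPLES,
    CHROMHMM_STATES,
    ChromatinSegment,
    EvidenceTriple,
    PICSRecord,
    TFTargetRecord,
    ValidationError,
    Variant,
)

log = logging.getLogger(__name__)

TPM_THRESHOLD = 2.0

#: Default tissue-equivalence mapping across the three vocabularies:
#: segmentation biosamples, expression tissue names, and TF-target tissue
#: labels.  Editable by passing a custom mapping.
DEFAULT_TISSUE_GROUPS: dict[str, frozenset[str]] = {
    "brain": frozenset(
        {b.lower() for b in BRAIN_BIOSAMPLES}
        | {
            "brain", "brain_cortex", "brain_cerebellum", "brain_cerebellar_hemisphere",
            "brain_hippocampus", "brain_putamen_basal_ganglia", "brain_amygdala",
            "brain_frontal_cortex", "brain_substantia_nigra", "astrocytes",
        }
    ),
}


def tissues_equivalent(
    t1: str, t2: str, groups: Mapping[str, frozenset[str]] = DEFAULT_TISSUE_GROUPS
) -> bool:
    """True when the two names match directly or share an equivalence group."""
    a, b = t1.strip().lower(), t2.strip().lower()
    if a == b:
        return True
    return any(a in members and b in members for members in groups.values())


def active_region_filter(
    variants: Sequence[Variant],
    segments: Sequence[ChromatinSegment],
    active_states: Iterable[str] = ACTIVE_STATES,
    biosamples: Iterable[str] | None = None,
) -> list[Variant]:
    """Variants overlapping an active-state segment in a selected biosample.

    Overlap uses the variant's single base (1-based) against 0-based
    half-open segments, so a variant at a segment's ``end`` is outside.
    """
    active = set(active_states)
    unknown = active - set(CHROMHMM_STATES)
    if unknown:
        raise ValidationError(f"unknown chromatin state label(s): {sorted(unknown)}")
    wanted = set(biosamples) if biosamples is not None else None
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for seg in segments:
        if seg.state_label not in active:
            continue
        if wanted is not None and seg.biosample not in wanted:
            continue
        trees[seg.chrom].addi(seg.start, seg.end)
    return [v for v in variants if trees[v.chrom].overlaps_point(v.pos - 1)]


def tf_expression_filter(
    tf_names: Sequence[str],
    expression: pd.DataFrame,
    tissues: Sequence[str],
    threshold: float = TPM_THRESHOLD,
    keep_unresolvable: bool = True,
) -> list[str]:
    """TFs with TPM >= threshold in at least one selected tissue.

    ``expression`` is genes x tissues.  TFs missing from the matrix are
    retained with a warning by default (configurable).
    """
    if not tissues:
        raise ValidationError("empty tissue selection")
    missing_tissues = [t for t in tissues if t not in expression.columns]
    usable = [t for t in tissues if t in expression.columns]
    if missing_tissues:
        log.warning("tissues absent from expression matrix: %s", missing_tissues)
    if not usable:
        raise ValidationError("none of the selected tissues is in the expression matrix")
    kept = []
    for tf in tf_names:
        if tf not in expression.index:
            log.warning("TF %s not resolvable in the expression matrix", tf)
            if keep_unresolvable:
                kept.append(tf)
            continue
        if (expression.loc[tf, usable] >= threshold).any():
            kept.append(tf)
    return kept


def mechanistic_evidence(
    confirmed_pairs: Sequence,  # VariantMatrixResult-like with variant_id/matrix fields
    tf_by_matrix: Mapping[str, str],
    eqtl_records: Sequence[PICSRecord],
    tftarget_records: Sequence[TFTargetRecord],
    tissue_groups: Mapping[str, frozenset[str]] = DEFAULT_TISSUE_GROUPS,
    eqtl_threshold: float = 0.10,
) -> list[EvidenceTriple]:
    """Assemble GV -> TF -> eGene triples with tissue-matched support.

    One triple per (variant, tf, egene, eqtl tissue, tftarget tissue) where
    the variant carries a confirmed binding alteration for the TF, is an
    eQTL (above threshold) for the eGene in tissue T1, and the TF targets
    the eGene in tissue T2 with T1 ~ T2 under the equivalence mapping.
    Provenance lists the supporting record identifiers.
    """
    eqtl_by_variant: dict[str, list[PICSRecord]] = defaultdict(list)
    for r in eqtl_records:
        if r.source == "eqtl" and r.pics_prob > eqtl_threshold:
            eqtl_by_variant[r.variant_id].append(r)
    targets_by_tf: dict[str, list[TFTargetRecord]] = defaultdict(list)
    for t in tftarget_records:
        targets_by_tf[t.tf_name].append(t)
    triples = []
    seen = set()
    for pair in confirmed_pairs:
        tf = tf_by_matrix.get(pair.matrix_id, pair.matrix_id)
        for eq in eqtl_by_variant.get(pair.variant_id, []):
            for tt in targets_by_tf.get(tf, []):
                if tt.target_gene != eq.egene:
                    continue
                if not tissues_equivalent(eq.tissue, tt.tissue, tissue_groups):
                    continue
                key = (pair.variant_id, tf, eq.egene, eq.tissue, tt.tissue)
                if key in seen:
                    continue
                seen.add(key)
                direction = getattr(pair, "effect", "")
                triples.append(
                    EvidenceTriple(
                        variant_id=pair.variant_id,
                        tf_name=tf,
                        egene=eq.egene,
                        eqtl_tissue=eq.tissue,
                        tftarget_tissue=tt.tissue,
                        direction=direction,
                        provenance=[
                            f"scan:{pair.variant_id}:{pair.matrix_id}",
                            f"eqtl:{eq.variant_id}:{eq.egene}:{eq.tissue}",
                            f"tftarget:{tt.tf_name}:{tt.target_gene}:{tt.tissue}",
                        ],
                    )
                )
    return triples
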