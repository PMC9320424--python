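"""Consequence-set assignment, proximal-gene mapping, and CADD flags.

Variants are grouped into four functional sets by their Sequence Ontology
consequence terms: (a) intergenic and UTR, (b) intronic, (c) regulatory,
(d) non-coding transcript.  A variant with terms in several sets belongs
to all of them, which is why set sizes can sum past the variant count.
"""
from __future__ import annotations

import logging
from typing import Mapping, Sequence

from .types import GeneAnnotation, Variant

log = logging.getLogger(__name__)

CONSEQUENCE_SETS = ("a", "b", "c", "d")

#: Default Sequence-Ontology term -> set mapping; an editable assumption.
DEFAULT_TERM_MAP: dict[str, str] = {
    "intergenic_variant": "a",
    "upstream_gene_variant": "a",
    "downstream_gene_variant": "a",
    "5_prime_UTR_variant": "a",
    "3_prime_UTR_variant": "a",
    "intron_variant": "b",
    "regulatory_region_variant": "c",
    "TF_binding_site_variant": "c",
    "promoter_variant": "c",
    "enhancer_variant": "c",
    "non_coding_transcript_variant": "d",
    "non_coding_transcript_exon_variant": "d",
    "lincRNA_variant": "d",
}

PGENE_WINDOW = 5000
CADD_CUTOFF = 15.0


def assign_consequence_sets(
    variant: Variant, term_map: Mapping[str, str] = DEFAULT_TERM_MAP
) -> set[str]:
    """Union of mapped sets over the variant's consequence terms."""
    sets = set()
    for term in variant.consequence_terms:
        if term in term_map:
            sets.add(term_map[term])
        else:
            log.info("unmapped consequence term %r on %s", term, variant.id)
    if not variant.consequence_terms:
        log.warning("variant %s carries no consequence terms", variant.id)
    return sets


def pgene_assignment(
    variant: Variant, genes: Sequence[GeneAnnotation], window: int = PGENE_WINDOW
) -> list[str]:
    """Genes whose span, widened by the window, contains the variant."""
    return [
        g.gene_id
        for g in genes
        if g.chrom == variant.chrom and g.start - window <= variant.pos <= g.end + window
    ]


def cadd_flag(variants: Sequence[Variant], cutoff: float = CADD_CUTOFF) -> list[Variant]:
    """Variants with CADD PHRED >= cutoff; missing scores are unflagged."""
    flagged = []
    for v in variants:
        if v.cadd_phred is None:
            log.info("variant %s has no CADD score; unflagged", v.id)
            continue
        if v.cadd_phred >= cutoff:
            flagged.append(v)
    return flagged
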