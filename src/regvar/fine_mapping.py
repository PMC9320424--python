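"""LD expansion of GWAS index variants and PICS-style fine-mapping.

Given only index variants (no full summary statistics), each associated
locus is expanded with LD partners and every member receives a causal
probability.  The probability model follows the PICS idea: if member *i*
were causal, the observed association strength of the index variant,
S = -log10(p_index), would be approximately Gaussian with mean r²·S and a
spread that shrinks as LD with the index tightens.  Member probabilities
are the normalized densities of the observed S under each member-causal
hypothesis.
"""
from __future__ import annotations

import logging
import math
from collections import defaultdict
from typing import Iterable, Sequence

import numpy as np

from .types import AssociationRecord, FineMapResult, LDRecord, Locus, PICSRecord

log = logging.getLogger(__name__)

GENOME_WIDE_ALPHA = 5e-8
PICS_K_DEFAULT = 0.5
PICS_C_DEFAULT = 3.2
SIGMA_FLOOR = 1e-6


def filter_genomewide_significant(
    records: Sequence[AssociationRecord], alpha: float = GENOME_WIDE_ALPHA
) -> list[AssociationRecord]:
    """Keep associations with p <= alpha, preserving input order."""
    return [r for r in records if r.p_value <= alpha]


def build_ld_index(ld_records: Iterable[LDRecord]) -> dict[str, dict[str, float]]:
    """Symmetric variant -> {partner: r2} lookup."""
    index: dict[str, dict[str, float]] = defaultdict(dict)
    for rec in ld_records:
        index[rec.variant_a][rec.variant_b] = rec.r2
        index[rec.variant_b][rec.variant_a] = rec.r2
    return dict(index)


def ld_expand(
    index_variant: AssociationRecord,
    ld_index: dict[str, dict[str, float]],
    r2_min: float = 0.5,
) -> Locus:
    """Locus = index variant plus all partners with r2 >= r2_min."""
    vid = index_variant.variant_id
    partners = ld_index.get(vid)
    members = {vid: 1.0}
    if partners is None:
        log.warning("index variant %s absent from LD table; locus of size 1", vid)
    else:
        for other, r2 in partners.items():
            if r2 >= r2_min:
                members[other] = r2
    members[vid] = 1.0
    return Locus(
        locus_id=vid,
        index_variant_id=vid,
        index_logp=-math.log10(index_variant.p_value),
        members=members,
    )


def pics_probabilities(
    locus: Locus, k: float = PICS_K_DEFAULT, c: float = PICS_C_DEFAULT
) -> FineMapResult:
    """Per-member causal probabilities for one locus.

    With S the index -log10 p, member i (LD r_i = sqrt(r²_i)) causal implies
    an expected index association mu_i = r²_i·S with spread
    sigma_i = k·sqrt(S)·sqrt(1 - r_i^c).  Probabilities are the Gaussian
    densities of S under each hypothesis, normalized per locus.  Members in
    perfect LD with the index (sigma at the numerical floor) share
    probability equally.
    """
    ids = list(locus.members)
    if len(ids) == 1:
        return FineMapResult(locus.locus_id, {ids[0]: 1.0})
    s = locus.index_logp
    r2 = np.array([locus.members[v] for v in ids], dtype=float)
    r = np.sqrt(r2)
    sigma = k * math.sqrt(s) * np.sqrt(np.clip(1.0 - r**c, 0.0, None))
    sigma = np.maximum(sigma, SIGMA_FLOOR)
    logdens = -np.log(sigma) - (s - r2 * s) ** 2 / (2.0 * sigma**2)
    logdens -= logdens.max()
    dens = np.exp(logdens)
    probs = dens / dens.sum()
    return FineMapResult(locus.locus_id, dict(zip(ids, probs.tolist())))


def fine_map(
    associations: Sequence[AssociationRecord],
    ld_records: Iterable[LDRecord],
    alpha: float = GENOME_WIDE_ALPHA,
    r2_min: float = 0.5,
    k: float = PICS_K_DEFAULT,
    c: float = PICS_C_DEFAULT,
) -> list[PICSRecord]:
    """Full path: significance filter -> LD expansion -> PICS per locus."""
    ld_index = build_ld_index(ld_records)
    out: list[PICSRecord] = []
    for index_rec in filter_genomewide_significant(associations, alpha):
        locus = ld_expand(index_rec, ld_index, r2_min)
        result = pics_probabilities(locus, k=k, c=c)
        out.extend(
            PICSRecord(variant_id=v, locus_id=locus.locus_id, pics_prob=p, source="gwas")
            for v, p in result.probabilities.items()
        )
    return out


def filter_pics(records: Sequence[PICSRecord], threshold: float = 0.10) -> list[PICSRecord]:
    """Strictly-greater-than threshold on the causal probability."""
    return [r for r in records if r.pics_prob > threshold]
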