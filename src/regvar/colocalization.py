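"""GWAS x eQTL colocalization by product of causal probabilities (CLPP).

Variants that pass the causal-probability threshold in both the GWAS and
the best-eQTL-per-gene fine-mapping are candidate colocalizations; assuming
independence of the two causal processes, the colocalization posterior
probability is the product of the two probabilities.
"""
from __future__ import annotations

from typing import Sequence

from scipy.stats import hypergeom

from .types import ColocPair, PICSRecord, ValidationError

PICS_THRESHOLD = 0.10
CLPP_THRESHOLD = 0.10


def clpp(gwas_p: float, eqtl_p: float) -> float:
    """Colocalization posterior probability: the product of the two."""
    for name, p in (("gwas_p", gwas_p), ("eqtl_p", eqtl_p)):
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"{name} outside [0,1]: {p}")
    return gwas_p * eqtl_p


def overlap_pics(
    gwas_records: Sequence[PICSRecord],
    eqtl_records: Sequence[PICSRecord],
    threshold: float = PICS_THRESHOLD,
) -> list[ColocPair]:
    """One candidate per (variant, egene, tissue) passing the threshold in both sources."""
    gwas_best: dict[str, float] = {}
    for r in gwas_records:
        if r.pics_prob > threshold:
            gwas_best[r.variant_id] = max(gwas_best.get(r.variant_id, 0.0), r.pics_prob)
    pairs = []
    for r in eqtl_records:
        g = gwas_best.get(r.variant_id)
        if g is None or r.pics_prob <= threshold:
            continue
        pairs.append(
            ColocPair(
                variant_id=r.variant_id,
                egene=r.egene,
                tissue=r.tissue,
                gwas_pics=g,
                eqtl_pics=r.pics_prob,
                clpp=clpp(g, r.pics_prob),
            )
        )
    return pairs


def filter_clpp(pairs: Sequence[ColocPair], threshold: float = CLPP_THRESHOLD) -> list[ColocPair]:
    return [p for p in pairs if p.clpp > threshold]


def dedup_best_tissue(pairs: Sequence[ColocPair]) -> list[ColocPair]:
    """Best tissue per (variant, egene) for headline counts; ties keep first."""
    best: dict[tuple[str, str], ColocPair] = {}
    for p in pairs:
        key = (p.variant_id, p.egene)
        if key not in best or p.clpp > best[key].clpp:
            best[key] = p
    return list(best.values())


def enrichment_fisher(
    k_overlap: int, n_gwas: int, n_eqtl_universe: int, n_universe: int
) -> float:
    """One-sided (greater) Fisher test for eQTL enrichment of causal variants.

    Hypergeometric tail: probability of >= k_overlap eQTL variants among
    n_gwas draws from a universe of n_universe containing n_eqtl_universe.
    """
    if not (
        0 <= k_overlap <= min(n_gwas, n_eqtl_universe)
        and max(n_gwas, n_eqtl_universe) <= n_universe
    ):
        raise ValidationError(
            f"inconsistent contingency counts: k={k_overlap}, n_gwas={n_gwas}, "
            f"n_eqtl={n_eqtl_universe}, N={n_universe}"
        )
    return float(hypergeom.sf(k_overlap - 1, n_universe, n_eqtl_universe, n_gwas))
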