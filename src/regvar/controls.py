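"""Negative-control systems and per-motif confirmation statistics.

Two control systems validate the scan results: (1) permuted matrices with
identical nucleotide composition and information content, and (2) matched
random variants sampled at 1:10 (strict attribute matching) and 1:1000
(relaxed).  Per motif, the observed p-value ratios are compared with each
control distribution by a one-sided Wilcoxon rank-sum test ("greater"); a
Shapiro-Wilk check documents why the nonparametric route is taken.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .types import (
    ControlAssignment,
    GeneAnnotation,
    MatchAttributes,
    PWMMatrix,
    ValidationError,
    Variant,
    VariantMatrixResult,
)

log = logging.getLogger(__name__)

DEFAULT_N_PERM = 5
STRICT_TSS_WINDOW = 5000
STRICT_DENSITY_WINDOW = 5
STRICT_LD_WINDOW = 50
LD_R2_CUTOFF = 0.1
DENSITY_RADIUS = 100_000  # genes counted within 100 kbp
CODING_TERMS = frozenset(
    {"missense_variant", "synonymous_variant", "stop_gained", "stop_lost",
     "start_lost", "coding_sequence_variant", "frameshift_variant",
     "inframe_insertion", "inframe_deletion"}
)


# ---------------------------------------------------------------------------
# permuted-matrix control

def permute_matrix(
    pwm: PWMMatrix, n_perm: int = DEFAULT_N_PERM, seed: int | np.random.Generator = 0
) -> list[PWMMatrix]:
    """Randomized matrices preserving composition and information content.

    Each replicate shuffles the column order and, within every column, the
    four cell values; per-column value multisets are preserved exactly, so
    the total information content is unchanged.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for i in range(n_perm):
        perm = rng.permutation(pwm.length)
        counts = pwm.counts[perm].copy()
        for col in counts:
            rng.shuffle(col)
        out.append(
            PWMMatrix(
                matrix_id=f"{pwm.matrix_id}_perm{i + 1}",
                tf_name=pwm.tf_name,
                counts=counts,
                source_db=pwm.source_db,
            )
        )
    return out


# ---------------------------------------------------------------------------
# matched-variant control

def compute_match_attributes(
    variants: Sequence[Variant],
    genes: Sequence[GeneAnnotation],
    ld_index: Mapping[str, Mapping[str, float]],
) -> dict[str, MatchAttributes]:
    """vSampler-style matching attributes for every variant."""
    by_chrom: dict[str, list[GeneAnnotation]] = defaultdict(list)
    for g in genes:
        by_chrom[g.chrom].append(g)
    out = {}
    for v in variants:
        chrom_genes = by_chrom.get(v.chrom, [])
        if chrom_genes:
            tss_distance = min(abs(v.pos - g.tss) for g in chrom_genes)
        else:
            tss_distance = None  # unmatched sentinel
        density = sum(
            1
            for g in chrom_genes
            if g.start - DENSITY_RADIUS <= v.pos <= g.end + DENSITY_RADIUS
        )
        ld_count = sum(
            1 for r2 in ld_index.get(v.id, {}).values() if r2 >= LD_R2_CUTOFF
        )
        coding = "coding" if v.consequence_terms & CODING_TERMS else "non-coding"
        out[v.id] = MatchAttributes(
            variant_id=v.id,
            chrom=v.chrom,
            tss_distance=tss_distance,
            gene_density=density,
            ld_count=ld_count,
            coding_class=coding,
            variant_type="SNV" if v.is_snv else "other",
        )
    return out


def _strict_eligible(t: MatchAttributes, c: MatchAttributes) -> bool:
    if t.tss_distance is None or c.tss_distance is None:
        return False
    return (
        c.chrom == t.chrom  # strict mode samples across the chromosome
        and abs(c.tss_distance - t.tss_distance) <= STRICT_TSS_WINDOW
        and abs(c.gene_density - t.gene_density) <= STRICT_DENSITY_WINDOW
        and abs(c.ld_count - t.ld_count) <= STRICT_LD_WINDOW
        and c.coding_class == t.coding_class
        and c.variant_type == t.variant_type
    )


def _relaxed_eligible(t: MatchAttributes, c: MatchAttributes) -> bool:
    return c.coding_class == t.coding_class and c.variant_type == t.variant_type


def sample_matched_controls(
    targets: Sequence[str],
    pool: Sequence[str],
    attributes: Mapping[str, MatchAttributes],
    mode: str = "strict",
    ratio: int = 10,
    seed: int | np.random.Generator = 0,
    exclude: Iterable[str] = (),
) -> list[ControlAssignment]:
    """Seeded sampling of matched control variants per target.

    Strict mode enforces all five attribute windows on the same chromosome;
    relaxed mode only matches coding class and variant type, across
    chromosomes.  Targets and ``exclude`` (typically all input variants)
    are never selected.  When fewer than ``ratio`` eligible controls exist
    all of them are taken and the shortfall is logged.
    """
    if mode not in ("strict", "relaxed"):
        raise ValidationError(f"unknown matching mode {mode!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eligible_fn = _strict_eligible if mode == "strict" else _relaxed_eligible
    banned = set(targets) | set(exclude)
    usable_pool = [p for p in pool if p not in banned and p in attributes]
    out = []
    for tid in targets:
        t = attributes.get(tid)
        if t is None or (mode == "strict" and t.tss_distance is None):
            log.warning("target %s lacks matching attributes; unmatched", tid)
            out.append(ControlAssignment(tid, [], mode, ratio))
            continue
        eligible = [p for p in usable_pool if eligible_fn(t, attributes[p])]
        if not eligible:
            log.warning("no eligible %s-mode controls for %s", mode, tid)
            out.append(ControlAssignment(tid, [], mode, ratio))
            continue
        if len(eligible) <= ratio:
            if len(eligible) < ratio:
                log.info(
                    "only %d/%d controls available for %s", len(eligible), ratio, tid
                )
            chosen = list(eligible)
        else:
            chosen = list(rng.choice(eligible, size=ratio, replace=False))
        out.append(ControlAssignment(tid, [str(c) for c in chosen], mode, ratio))
    return out


# ---------------------------------------------------------------------------
# rank-based statistics

def _exact_rank_sum_greater(observed: np.ndarray, control: np.ndarray) -> float:
    """Exact one-sided rank-sum p by enumeration (tie-free samples only)."""
    pooled = np.concatenate([observed, control])
    ranks = stats.rankdata(pooled)
    n = len(observed)
    obs_sum = ranks[:n].sum()
    total = 0
    at_least = 0
    for combo in combinations(range(len(pooled)), n):
        total += 1
        if ranks[list(combo)].sum() >= obs_sum - 1e-9:
            at_least += 1
    return at_least / total


def wilcoxon_greater(
    observed: Sequence[float], control: Sequence[float]
) -> float:
    """P-value that ``observed`` stochastically dominates ``control``.

    Exact enumeration over rank assignments when n+m <= 12 with no ties;
    otherwise the normal approximation with tie and continuity correction.
    """
    obs = np.asarray(observed, dtype=float)
    ctl = np.asarray(control, dtype=float)
    if len(obs) == 0 or len(ctl) == 0:
        raise ValidationError("wilcoxon_greater requires non-empty samples")
    pooled = np.concatenate([obs, ctl])
    tie_free = len(np.unique(pooled)) == len(pooled)
    if len(pooled) <= 12 and tie_free:
        return _exact_rank_sum_greater(obs, ctl)
    res = stats.mannwhitneyu(obs, ctl, alternative="greater", method="asymptotic")
    return float(res.pvalue)


def shapiro_wilk_check(values: Sequence[float]) -> float | None:
    """Shapiro-Wilk normality p-value; None when n < 3 or degenerate."""
    arr = np.asarray(values, dtype=float)
    if len(arr) < 3:
        return None
    if np.ptp(arr) == 0:
        return None  # constant sample: test undefined
    if len(arr) > 5000:
        arr = arr[:5000]
    return float(stats.shapiro(arr).pvalue)


# ---------------------------------------------------------------------------
# per-motif confirmation

@dataclass
class MotifConfirmation:
    matrix_id: str
    p_permuted: float | None
    p_matched10: float | None
    p_matched1000: float | None
    q_permuted: float | None = None
    q_matched10: float | None = None
    q_matched1000: float | None = None
    stage1_confirmed: bool = False
    confirmed: bool = False
    shapiro_p: float | None = None


def _bh_adjust(pvals: list[float | None]) -> list[float | None]:
    idx = [i for i, p in enumerate(pvals) if p is not None]
    if not idx:
        return list(pvals)
    arr = np.array([pvals[i] for i in idx])
    order = np.argsort(arr)
    m = len(arr)
    adj = np.empty(m)
    running = 1.0
    for rank_pos in range(m - 1, -1, -1):
        i = order[rank_pos]
        running = min(running, arr[i] * m / (rank_pos + 1))
        adj[i] = running
    out: list[float | None] = list(pvals)
    for j, i in enumerate(idx):
        out[i] = float(adj[j])
    return out


def ratios_by_matrix(results: Iterable[VariantMatrixResult]) -> dict[str, list[float]]:
    by: dict[str, list[float]] = defaultdict(list)
    for r in results:
        by[r.matrix_id].append(r.pval_ratio)
    return dict(by)


def confirm_motif_pairs(
    scan_results: Sequence[VariantMatrixResult],
    permuted_ratios: Mapping[str, Sequence[float]],
    matched10_ratios: Mapping[str, Sequence[float]],
    matched1000_ratios: Mapping[str, Sequence[float]] | None = None,
    alpha: float = 0.05,
    filter_passing: Sequence[VariantMatrixResult] | None = None,
) -> tuple[list[VariantMatrixResult], dict[str, MotifConfirmation]]:
    """Two-stage motif confirmation and the confirmed pair list.

    A motif is stage-1 confirmed when its observed ratio distribution
    dominates both the permuted-matrix and matched-1:10 control ratios
    (Wilcoxon "greater", raw p < alpha); stage-1 survivors are re-tested
    against the matched-1:1000 system when provided.  Confirmed pairs are
    the filter-passing results of confirmed motifs.  BH-adjusted values are
    reported alongside, per control system.  Permuted-ratio keys may be the
    base matrix id or its ``_permN`` replicates (pooled).
    """
    observed = ratios_by_matrix(scan_results)
    perm_pool: dict[str, list[float]] = defaultdict(list)
    for mid, ratios in permuted_ratios.items():
        base = mid.split("_perm")[0]
        perm_pool[base].extend(ratios)
    confirmations: dict[str, MotifConfirmation] = {}
    for mid, obs in sorted(observed.items()):
        perm = perm_pool.get(mid, [])
        m10 = list(matched10_ratios.get(mid, []))
        if not perm or not m10:
            log.warning("motif %s has no control observations; unconfirmable", mid)
            confirmations[mid] = MotifConfirmation(mid, None, None, None)
            continue
        p_perm = wilcoxon_greater(obs, perm)
        p_m10 = wilcoxon_greater(obs, m10)
        conf = MotifConfirmation(
            matrix_id=mid,
            p_permuted=p_perm,
            p_matched10=p_m10,
            p_matched1000=None,
            shapiro_p=shapiro_wilk_check(obs),
        )
        conf.stage1_confirmed = p_perm < alpha and p_m10 < alpha
        if conf.stage1_confirmed:
            if matched1000_ratios is None:
                conf.confirmed = True
            else:
                m1000 = list(matched1000_ratios.get(mid, []))
                if not m1000:
                    log.warning("motif %s lacks 1:1000 controls; unconfirmable", mid)
                    conf.confirmed = False
                else:
                    conf.p_matched1000 = wilcoxon_greater(obs, m1000)
                    conf.confirmed = conf.p_matched1000 < alpha
        confirmations[mid] = conf
    ordered = sorted(confirmations)
    for attr_p, attr_q in (
        ("p_permuted", "q_permuted"),
        ("p_matched10", "q_matched10"),
        ("p_matched1000", "q_matched1000"),
    ):
        adj = _bh_adjust([getattr(confirmations[m], attr_p) for m in ordered])
        for m, q in zip(ordered, adj):
            setattr(confirmations[m], attr_q, q)
    source = filter_passing if filter_passing is not None else scan_results
    confirmed_pairs = [
        r for r in source if confirmations.get(r.matrix_id, MotifConfirmation(r.matrix_id, None, None, None)).confirmed
    ]
    return confirmed_pairs, confirmations
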