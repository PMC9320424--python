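"""Allele-specific PWM scanning against Markov backgrounds.

For each variant both allele windows are scored with every matrix on both
strands at every offset whose site covers the variant base.  A site's
weight is log2 P(site | PWM) - log2 P(site | background conditioned on the
preceding context within the window); the p-value of a weight is the
probability of an equal-or-better score under the background, computed by
dynamic programming on a discretized score grid with the order-k context
marginalized through the stationary distribution.

Retention filters mirror the published thresholds: best site weight > 1,
weight difference between alleles > 1, best site p-value < 1e-3, and
p-value ratio between alleles > 10.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .background import MarkovBackground, encode_seq
from .types import PWMMatrix, ScanHit, ValidationError, VariantMatrixResult, VariantWindow

log = logging.getLogger(__name__)

DEFAULT_GRID = 0.01  # log2 units per reported score-grid bin
_SUBBINS = 4  # internal resolution: grid/4 keeps accumulated rounding << 1 bin


@dataclass(frozen=True)
class ScanParams:
    """Retention thresholds; all strict comparisons."""

    min_weight: float = 1.0
    min_weight_diff: float = 1.0
    max_site_p: float = 1e-3
    min_pval_ratio: float = 10.0


def pwm_frequencies(counts: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """Per-column base frequencies: (count + p/4) / (column_total + p)."""
    counts = np.asarray(counts, dtype=float)
    tot = counts.sum(axis=1, keepdims=True)
    return (counts + pseudocount / 4.0) / (tot + pseudocount)


def _pwm_log2(freqs: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log2(freqs)


def site_weight(
    pwm_freqs: np.ndarray,
    background: MarkovBackground,
    site_seq: str,
    window_context: str = "",
) -> float | None:
    """Weight of one site given its preceding context (may be shorter than
    the model order; missing context is marginalized via the stationary
    distribution).  Returns None for sites with ambiguous bases."""
    L = pwm_freqs.shape[0]
    if len(site_seq) != L:
        raise ValidationError(f"site length {len(site_seq)} != matrix length {L}")
    arr = encode_seq(site_seq)
    if (arr < 0).any():
        log.warning("ambiguous base in site %r; skipped", site_seq)
        return None
    ctx_arr = encode_seq(window_context) if window_context else np.zeros(0, dtype=np.int16)
    logf = _pwm_log2(pwm_freqs)
    k = background.order
    full = np.concatenate([ctx_arr, arr])
    off = len(ctx_arr)
    total = 0.0
    for j in range(L):
        total += float(logf[j, arr[j]])
        p = off + j
        if k == 0:
            total -= background.conditional_log2(0, int(arr[j]))
        elif p >= k and (full[p - k : p] >= 0).all():
            powers = 4 ** np.arange(k - 1, -1, -1)
            ctx = int(full[p - k : p] @ powers)
            total -= background.conditional_log2(ctx, int(arr[j]))
        else:
            total -= background.marginal_log2(int(arr[j]))
    return total


class ScoreDistribution:
    """Exact distribution of site weights under the background, on a grid.

    States are (context, score bin); transitions follow the background
    chain while scores accumulate log2 f/b per position.  Sites whose PWM
    probability is zero carry weight -inf and are excluded from the finite
    survival mass (they only matter at w = -inf, where the p-value is 1).
    """

    def __init__(
        self, pwm_freqs: np.ndarray, background: MarkovBackground, grid: float = DEFAULT_GRID
    ):
        self.grid = grid
        sub = grid / _SUBBINS
        logf = _pwm_log2(pwm_freqs)
        L = logf.shape[0]
        k = background.order
        n_ctx = background.n_contexts
        logb = background._log_cond  # (n_ctx, 4)
        # per-position integer score offsets s[j, c, b] in sub-bin units
        s = np.empty((L, n_ctx, 4))
        for j in range(L):
            s[j] = logf[j][None, :] - logb
        finite = np.isfinite(s)
        smin = np.where(finite, s, np.inf).min(axis=(1, 2))
        smax = np.where(finite, s, -np.inf).max(axis=(1, 2))
        lo = int(np.floor(smin.sum() / sub)) - L
        hi = int(np.ceil(smax.sum() / sub)) + L
        nbins = hi - lo + 1
        self._origin = lo * sub
        self._sub = sub
        top = 4 ** (k - 1) if k > 1 else 1
        prob = np.zeros((n_ctx, nbins))
        start = -lo  # bin index of score 0
        prob[:, start] = background.stationary
        underflow = 0.0
        for j in range(L):
            new = np.zeros_like(prob)
            for c in range(n_ctx):
                row = prob[c]
                if not row.any():
                    continue
                for b in range(4):
                    trans = background.cond[c, b]
                    if trans == 0.0:
                        continue
                    if not np.isfinite(s[j, c, b]):
                        underflow += row.sum() * trans
                        continue
                    shift = int(round(s[j, c, b] / sub))
                    nc = (c % top) * 4 + b if k > 1 else (b if k == 1 else 0)
                    if shift >= 0:
                        new[nc, shift:] += row[: nbins - shift] * trans
                    else:
                        new[nc, : nbins + shift] += row[-shift:] * trans
            prob = new
        mass = prob.sum(axis=0)
        self._survival = mass[::-1].cumsum()[::-1]
        self._underflow = underflow
        positive = self._survival[self._survival > 0]
        self.p_floor = float(positive.min()) if len(positive) else 1e-300

    def pvalue(self, w: float) -> float:
        """Right-continuous P(weight >= w), clamped to [p_floor, 1]."""
        if not np.isfinite(w):
            return 1.0 if w < 0 else self.p_floor
        idx = int(np.ceil((w - self._origin) / self._sub - 1e-9))
        if idx < 0:
            return 1.0
        if idx >= len(self._survival):
            return self.p_floor
        return float(min(1.0, max(self._survival[idx], self.p_floor)))


def weight_pvalue(
    pwm_freqs: np.ndarray,
    background: MarkovBackground,
    w: float,
    grid: float = DEFAULT_GRID,
) -> float:
    """One-shot p-value; prefer ScoreDistribution when querying repeatedly."""
    return ScoreDistribution(pwm_freqs, background, grid).pvalue(w)


def _window_bg_logs(bg: MarkovBackground, arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-position background log2 conditionals for both strands.

    plus[p] = log2 P(base_p | k preceding window bases); minus[p] is the
    same for the complementary base conditioned on its minus-strand
    context (the complements of the k following bases).  Positions without
    full context fall back to the stationary-marginalized probability.
    """
    k = bg.order
    W = len(arr)
    plus = np.empty(W)
    minus = np.empty(W)
    powers = 4 ** np.arange(k - 1, -1, -1) if k > 0 else None
    for p in range(W):
        b = int(arr[p])
        if k == 0:
            plus[p] = bg.conditional_log2(0, b)
            minus[p] = bg.conditional_log2(0, 3 - b)
            continue
        if p >= k:
            ctx = int(arr[p - k : p] @ powers)
            plus[p] = bg.conditional_log2(ctx, b)
        else:
            plus[p] = bg.marginal_log2(b)
        if p + k < W:
            # minus-strand context: complements of bases p+k .. p+1 (5'->3')
            ctx_bases = 3 - arr[p + 1 : p + k + 1][::-1]
            ctx = int(ctx_bases @ powers)
            minus[p] = bg.conditional_log2(ctx, 3 - b)
        else:
            minus[p] = bg.marginal_log2(3 - b)
    return plus, minus


def _allele_best_hit(
    variant_id: str,
    matrix_id: str,
    logf: np.ndarray,
    arr: np.ndarray,
    cs_p: np.ndarray,
    cs_m: np.ndarray,
    variant_offset: int,
    allele: str,
    dist: ScoreDistribution,
) -> ScanHit:
    """Best hit among all (offset, strand) sites covering the variant base.

    ``cs_p``/``cs_m`` are cumulative sums of the per-position background
    log-conditionals (plus/minus strand) with a leading zero.
    """
    L = logf.shape[0]
    W = len(arr)
    offsets = np.arange(max(0, variant_offset - L + 1), min(W - L, variant_offset) + 1)
    sites = np.lib.stride_tricks.sliding_window_view(arr, L)[offsets]
    cols = np.arange(L)
    pw_plus = logf[cols, sites].sum(axis=1)
    pw_minus = logf[cols, (3 - sites)[:, ::-1]].sum(axis=1)
    w_plus = pw_plus - (cs_p[offsets + L] - cs_p[offsets])
    w_minus = pw_minus - (cs_m[offsets + L] - cs_m[offsets])
    allw = np.concatenate([w_plus, w_minus])
    best = int(np.argmax(allw))  # ties: + strand then lowest offset (array order)
    strand = "+" if best < len(offsets) else "-"
    offset = int(offsets[best % len(offsets)])
    weight = float(allw[best])
    return ScanHit(
        variant_id=variant_id,
        matrix_id=matrix_id,
        allele=allele,
        offset=offset,
        strand=strand,
        weight=weight,
        p_value=dist.pvalue(weight),
    )


class MotifScanner:
    """Scans variant windows against a matrix library under one background.

    Score distributions (the expensive DP) are computed once per matrix and
    reused across windows.
    """

    def __init__(
        self,
        matrices: Sequence[PWMMatrix],
        background: MarkovBackground,
        pwm_pseudocount: float = 1.0,
        grid: float = DEFAULT_GRID,
    ):
        self.background = background
        self.matrices = list(matrices)
        self._logf = {m.matrix_id: _pwm_log2(pwm_frequencies(m.counts, pwm_pseudocount)) for m in self.matrices}
        self._freqs = {m.matrix_id: pwm_frequencies(m.counts, pwm_pseudocount) for m in self.matrices}
        self.grid = grid
        self._dists: dict[str, ScoreDistribution] = {}

    def distribution(self, matrix_id: str) -> ScoreDistribution:
        if matrix_id not in self._dists:
            self._dists[matrix_id] = ScoreDistribution(
                self._freqs[matrix_id], self.background, self.grid
            )
        return self._dists[matrix_id]

    def scan_window(self, window: VariantWindow) -> list[VariantMatrixResult]:
        out = []
        W = len(window.ref_seq)
        allele_state = {}
        for allele, seq in (("ref", window.ref_seq), ("alt", window.alt_seq)):
            arr = encode_seq(seq)
            if arr.min() < 0:
                log.warning("ambiguous bases in window for %s; skipped", window.variant_id)
                return out
            bg_plus, bg_minus = _window_bg_logs(self.background, arr)
            cs_p = np.concatenate([[0.0], bg_plus.cumsum()])
            cs_m = np.concatenate([[0.0], bg_minus.cumsum()])
            allele_state[allele] = (arr, cs_p, cs_m)
        for m in self.matrices:
            if m.length > W:
                log.warning("matrix %s longer than window; skipped", m.matrix_id)
                continue
            dist = self.distribution(m.matrix_id)
            logf = self._logf[m.matrix_id]
            hits = {}
            for allele in ("ref", "alt"):
                arr, cs_p, cs_m = allele_state[allele]
                hits[allele] = _allele_best_hit(
                    window.variant_id, m.matrix_id, logf, arr, cs_p, cs_m,
                    window.variant_offset, allele, dist,
                )
            br, ba = hits["ref"], hits["alt"]
            p_hi, p_lo = max(br.p_value, ba.p_value), min(br.p_value, ba.p_value)
            effect = "disrupt" if br.weight > ba.weight else (
                "create" if ba.weight > br.weight else "none"
            )
            out.append(
                VariantMatrixResult(
                    variant_id=window.variant_id,
                    matrix_id=m.matrix_id,
                    best_ref=br,
                    best_alt=ba,
                    weight_diff=abs(br.weight - ba.weight),
                    pval_ratio=p_hi / p_lo,
                    effect=effect,
                    consequence_set=window.consequence_set,
                )
            )
        return out

    def scan_windows(self, windows: Sequence[VariantWindow]) -> list[VariantMatrixResult]:
        results = []
        for w in windows:
            results.extend(self.scan_window(w))
        return results


def scan_variant(
    pwm: PWMMatrix,
    background: MarkovBackground,
    window: VariantWindow,
    pwm_pseudocount: float = 1.0,
    grid: float = DEFAULT_GRID,
) -> VariantMatrixResult | None:
    """Single (variant, matrix) scan; None when the matrix does not fit."""
    res = MotifScanner([pwm], background, pwm_pseudocount, grid).scan_window(window)
    return res[0] if res else None


def passes_filters(r: VariantMatrixResult, params: ScanParams = ScanParams()) -> bool:
    return (
        max(r.best_ref.weight, r.best_alt.weight) > params.min_weight
        and r.weight_diff > params.min_weight_diff
        and min(r.best_ref.p_value, r.best_alt.p_value) < params.max_site_p
        and r.pval_ratio > params.min_pval_ratio
    )


def apply_scan_filters(
    results: Sequence[VariantMatrixResult], params: ScanParams = ScanParams()
) -> list[VariantMatrixResult]:
    """Published retention rule; every comparison strict."""
    return [r for r in results if passes_filters(r, params)]


def results_to_table(results: Sequence[VariantMatrixResult]):
    import pandas as pd

    rows = []
    for r in results:
        rows.append(
            {
                "variant_id": r.variant_id,
                "matrix_id": r.matrix_id,
                "set": r.consequence_set,
                "ref_weight": r.best_ref.weight,
                "alt_weight": r.best_alt.weight,
                "ref_p": r.best_ref.p_value,
                "alt_p": r.best_alt.p_value,
                "ref_offset": r.best_ref.offset,
                "alt_offset": r.best_alt.offset,
                "ref_strand": r.best_ref.strand,
                "alt_strand": r.best_alt.strand,
                "weight_diff": r.weight_diff,
                "pval_ratio": r.pval_ratio,
                "effect": r.effect,
            }
        )
    return pd.DataFrame(rows)
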