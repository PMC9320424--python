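"""Independent oracles used by the tests.

These deliberately avoid the library code paths they check: the score
distribution is enumerated word by word, hypergeometric tails are summed
from a Pascal triangle, and the rank-sum p-value is enumerated over rank
assignments via scipy's exact method.
"""
from __future__ import annotations

import itertools

import numpy as np


def brute_score_distribution(freqs: np.ndarray, bg) -> tuple[np.ndarray, np.ndarray]:
    """All (initial context, word) weights and probabilities by enumeration."""
    L = freqs.shape[0]
    k = bg.order
    with np.errstate(divide="ignore"):
        logf = np.log2(freqs)
    words = np.array(list(itertools.product(range(4), repeat=L)))
    weights_all, probs_all = [], []
    top = 4 ** (k - 1) if k > 1 else 1
    for c0 in range(4**k):
        stat = bg.stationary[c0]
        probs = np.full(len(words), stat)
        weights = np.zeros(len(words))
        c = np.full(len(words), c0)
        for j in range(L):
            b = words[:, j]
            pb = bg.cond[c, b]
            probs = probs * pb
            with np.errstate(divide="ignore", invalid="ignore"):
                weights = weights + logf[j, b] - np.log2(pb)
            if k > 1:
                c = (c % top) * 4 + b
            elif k == 1:
                c = b
        weights_all.append(weights)
        probs_all.append(probs)
    return np.concatenate(weights_all), np.concatenate(probs_all)


def brute_survival(freqs: np.ndarray, bg, w: float) -> float:
    W, P = brute_score_distribution(freqs, bg)
    finite = np.isfinite(W) & (P > 0)
    return float(P[finite & (W >= w)].sum())


def pascal_hypergeom_tail(k: int, n_draws: int, n_success: int, n_total: int) -> float:
    """P(X >= k) by direct summation over a Pascal triangle."""
    C = np.zeros((n_total + 1, n_total + 1))
    C[:, 0] = 1.0
    for i in range(1, n_total + 1):
        C[i, 1 : i + 1] = C[i - 1, : i] + C[i - 1, 1 : i + 1]
    denom = C[n_total, n_draws]
    total = 0.0
    for j in range(k, min(n_draws, n_success) + 1):
        if n_draws - j > n_total - n_success:
            continue
        total += C[n_success, j] * C[n_total - n_success, n_draws - j] / denom
    return total


def markov_counts_by_hand(seqs, order: int, both_strands: bool = True):
    """(k+1)-mer counting with circular wrap, written independently."""
    from regvar.background import revcomp

    counts: dict[tuple[str, str], float] = {}
    for seq in seqs:
        strands = [seq, revcomp(seq)] if both_strands else [seq]
        for s in strands:
            circ = s + s[:order]
            for i in range(len(s)):
                w = circ[i : i + order + 1]
                if any(ch not in "ACGT" for ch in w):
                    continue
                key = (w[:order], w[order])
                counts[key] = counts.get(key, 0) + 1
    return counts
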