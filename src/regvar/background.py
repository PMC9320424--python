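"""Markov background models of non-functional sequence, and variant windows.

Backgrounds are estimated per consequence set (intergenic/UTR, intronic,
regulatory, non-coding) from the ChIP-seq peak sequences overlapping that
set's variants; order 2 captures CpG depletion.  Counting runs over each
training sequence and its reverse complement with per-sequence circular
wrap-around, which makes prefix and suffix context marginals identical and
hence the fitted model exactly strand-symmetric.  All logs are base 2.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import fetch_sequence
from .types import ValidationError, Variant, VariantWindow

log = logging.getLogger(__name__)

DEFAULT_ORDER = 2
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_FLANK = 30
MIN_TRAINING_BP = 10_000

_ENCODE = np.full(256, -100, dtype=np.int16)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _ENCODE[_b] = _i


def encode_seq(seq: str) -> np.ndarray:
    """Sequence -> int array, A/C/G/T -> 0..3, anything else negative."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def kmer_string(code: int, k: int) -> str:
    if k == 0:
        return ""
    out = []
    for _ in range(k):
        out.append("ACGT"[code % 4])
        code //= 4
    return "".join(reversed(out))


@dataclass
class MarkovBackground:
    """Order-k Markov model over A/C/G/T.

    ``cond`` has shape (4**order, 4): P(next base | context), contexts
    encoded base-4 with the earliest base most significant.  ``stationary``
    is the context distribution used to start chains and to marginalize
    context where none is available.
    """

    order: int
    cond: np.ndarray
    stationary: np.ndarray
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    set_label: str = "global"
    _log_cond: np.ndarray = field(init=False, repr=False)
    _log_marginal: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.cond = np.asarray(self.cond, dtype=float)
        self.stationary = np.asarray(self.stationary, dtype=float)
        n_ctx = 4**self.order
        if self.cond.shape != (n_ctx, 4):
            raise ValidationError(f"cond must be ({n_ctx}, 4)")
        with np.errstate(divide="ignore"):
            self._log_cond = np.log2(self.cond)
            marginal = self.stationary @ self.cond
            self._log_marginal = np.log2(marginal)

    @property
    def n_contexts(self) -> int:
        return 4**self.order

    def conditional_log2(self, ctx_code: int, base: int) -> float:
        return float(self._log_cond[ctx_code, base])

    def marginal_log2(self, base: int) -> float:
        """log2 P(base) with the context marginalized over the stationary."""
        return float(self._log_marginal[base])

    def sequence_logprob(self, seq: str) -> float:
        """log2 P(seq) = log2 stationary(first context) + sum of transitions.

        Zero-probability transitions yield ``-inf``.
        """
        k = self.order
        if len(seq) <= k:
            raise ValidationError(f"sequence shorter than order+1 ({len(seq)} <= {k})")
        arr = encode_seq(seq)
        if (arr < 0).any():
            raise ValidationError("sequence_logprob requires pure A/C/G/T input")
        if k == 0:
            with np.errstate(divide="ignore"):
                return float(self._log_cond[0, arr].sum())
        powers = 4 ** np.arange(k - 1, -1, -1)
        ctx0 = int(arr[:k] @ powers)
        with np.errstate(divide="ignore"):
            total = float(np.log2(self.stationary[ctx0])) if self.stationary[ctx0] > 0 else -np.inf
        ctx = ctx0
        top = 4 ** (k - 1)
        for j in range(k, len(arr)):
            total += float(self._log_cond[ctx, arr[j]])
            ctx = (ctx % top) * 4 + int(arr[j]) if k > 1 else int(arr[j])
        return total


def estimate_markov(
    sequences: Sequence[str],
    order: int = DEFAULT_ORDER,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    set_label: str = "global",
    both_strands: bool = True,
) -> MarkovBackground:
    """Fit an order-k model from (k+1)-mer counts on both strands.

    Windows containing non-A/C/G/T characters are skipped together with
    their contexts.  Per-sequence circular wrap-around keeps the model
    exactly strand-symmetric (see module docstring).  ``both_strands=False``
    counts the given strand only (no symmetry guarantee).
    """
    if order < 0:
        raise ValidationError("order must be >= 0")
    if not sequences:
        raise ValidationError("no training sequences")
    k = order
    if max(len(s) for s in sequences) < k + 1:
        raise ValidationError(f"order {k} exceeds every training sequence length")
    n_ctx = 4**k
    counts = np.zeros((n_ctx, 4), dtype=float)
    powers = 4 ** np.arange(k - 1, -1, -1) if k > 0 else np.zeros(0, dtype=int)
    for seq in sequences:
        if len(seq) < k + 1:
            continue
        for strand_seq in (seq, revcomp(seq)) if both_strands else (seq,):
            arr = encode_seq(strand_seq)
            ext = np.concatenate([arr, arr[:k]]) if k > 0 else arr
            wins = np.lib.stride_tricks.sliding_window_view(ext, k + 1)
            valid = (wins >= 0).all(axis=1)
            wins = wins[valid]
            if not len(wins):
                continue
            ctx = wins[:, :k] @ powers if k > 0 else np.zeros(len(wins), dtype=int)
            np.add.at(counts, (ctx.astype(int), wins[:, k]), 1.0)
    counts += pseudocount
    row_tot = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cond = np.where(row_tot[:, None] > 0, counts / row_tot[:, None], 0.0)
    total = row_tot.sum()
    stationary = row_tot / total if total > 0 else np.full(n_ctx, 1.0 / n_ctx)
    return MarkovBackground(
        order=k, cond=cond, stationary=stationary, pseudocount=pseudocount, set_label=set_label
    )


def backgrounds_for_sets(
    sequences_by_set: Mapping[str, Sequence[str]],
    order: int = DEFAULT_ORDER,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    min_total_bp: int = MIN_TRAINING_BP,
) -> dict[str, MarkovBackground]:
    """One background per consequence set, pooled-global fallback when thin.

    A set whose training sequences total fewer than ``min_total_bp`` bases
    uses the model pooled over every set.
    """
    all_seqs = [s for seqs in sequences_by_set.values() for s in seqs]
    global_bg = estimate_markov(all_seqs, order, pseudocount, set_label="global")
    out: dict[str, MarkovBackground] = {"global": global_bg}
    for label, seqs in sequences_by_set.items():
        total = sum(len(s) for s in seqs)
        if total >= min_total_bp:
            out[label] = estimate_markov(seqs, order, pseudocount, set_label=label)
        else:
            log.info(
                "set %s has %d bp of training sequence (< %d); using global background",
                label, total, min_total_bp,
            )
            out[label] = global_bg
    return out


def build_variant_windows(
    genome: Mapping[str, str],
    variants: Iterable[Variant],
    flank: int = DEFAULT_FLANK,
) -> list[VariantWindow]:
    """Reference/alternate windows of 2*flank+1 bases around each SNV.

    Windows are truncated (with a warning) at chromosome ends; the genome
    base must equal the declared reference allele.  Non-SNV variants are
    skipped: length-changing alleles are unsupported by the scanner.
    """
    windows = []
    for v in variants:
        if not v.is_snv:
            log.warning("variant %s is not a SNV; skipped by the scanner", v.id)
            continue
        chrom_len = len(genome[v.chrom])
        start = max(1, v.pos - flank)
        end = min(chrom_len, v.pos + flank)
        if end - start + 1 != 2 * flank + 1:
            log.warning("window for %s truncated to %d-%d", v.id, start, end)
        ref_seq = fetch_sequence(genome, v.chrom, start, end)
        offset = v.pos - start
        if ref_seq[offset] != v.ref:
            raise ValidationError(
                f"reference mismatch for {v.id} at {v.chrom}:{v.pos}: "
                f"genome has {ref_seq[offset]}, variant declares {v.ref}"
            )
        alt_seq = ref_seq[:offset] + v.alt + ref_seq[offset + 1 :]
        windows.append(
            VariantWindow(
                variant_id=v.id,
                ref_seq=ref_seq,
                alt_seq=alt_seq,
                flank=flank,
                variant_offset=offset,
            )
        )
    return windows


def write_background(bg: MarkovBackground, path: str | Path) -> None:
    """Serialize as TSV: header comment, then context/stationary/A/C/G/T rows."""
    with open(path, "w") as fh:
        fh.write(
            f"# order={bg.order}\tpseudocount={bg.pseudocount:g}\tset_label={bg.set_label}\n"
        )
        fh.write("context\tstationary\tA\tC\tG\tT\n")
        for code in range(bg.n_contexts):
            row = "\t".join(f"{p:.10g}" for p in bg.cond[code])
            fh.write(f"{kmer_string(code, bg.order) or '.'}\t{bg.stationary[code]:.10g}\t{row}\n")


def read_background(path: str | Path) -> MarkovBackground:
    lines = Path(path).read_text().splitlines()
    meta = dict(item.split("=", 1) for item in lines[0].lstrip("# ").split("\t"))
    order = int(meta["order"])
    cond = np.zeros((4**order, 4))
    stationary = np.zeros(4**order)
    for i, line in enumerate(lines[2:]):
        fields = line.split("\t")
        stationary[i] = float(fields[1])
        cond[i] = [float(x) for x in fields[2:6]]
    return MarkovBackground(
        order=order,
        cond=cond,
        stationary=stationary,
        pseudocount=float(meta["pseudocount"]),
        set_label=meta["set_label"],
    )
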