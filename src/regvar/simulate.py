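"""Self-consistent synthetic dataset with planted ground truth.

Generates a small genome, gene annotation, GWAS loci with LD structure and
per-locus causal-probability tables, ChIP-seq-style peaks containing
planted motif instances, variants whose alternate allele destroys or
creates a planted binding site, eQTL tables, chromatin-state tracks, a TPM
matrix, and TF-target records — plus a manifest of everything planted, so
every pipeline stage can be scored against known truth without downloads.

Everything is driven by one seeded generator; two runs with the same seed
produce identical file trees.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .types import (
    ACTIVE_STATES,
    CHROMHMM_STATES,
    AssociationRecord,
    GeneAnnotation,
    LDRecord,
    PICSRecord,
    PWMMatrix,
    TFTargetRecord,
    Variant,
)

BRAIN_SEGMENTATION_BIOSAMPLE = "Brain Dorsolateral Prefrontal Cortex"
EXPRESSION_TISSUES = ("Brain_Cortex", "Brain_Cerebellar_Hemisphere", "Liver", "Lung")
EQTL_TISSUE = "Brain_Cortex"
TFTARGET_BRAIN_TISSUE = "brain"
INACTIVE_STATES = tuple(s for s in CHROMHMM_STATES if s not in ACTIVE_STATES)
_ACTIVE = tuple(sorted(ACTIVE_STATES))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic dataset (defaults are the study)."""

    seed: int = 0
    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    n_genes: int = 60
    n_loci: int = 20
    locus_size: int = 15
    n_null_loci: int = 3  # extra loci below genome-wide significance
    n_motifs: int = 12
    motif_length_range: tuple[int, int] = (8, 14)
    motif_ic_range: tuple[float, float] = (10.0, 16.0)
    n_planted_causal: int = 10
    planted_coloc_fraction: float = 0.6
    planted_triple_count: int = 4
    n_planted_motifs: int = 4
    planted_per_motif: int = 30
    n_decoy_peak_variants: int = 20
    peak_width: int = 800  # ChIP-seq regions run 100-1000 bp
    active_state_fraction: float = 0.5
    gc_content: float = 0.41
    cpg_depletion: float = 0.2
    flank: int = 30
    control_clones_per_target: int = 12
    n_scattered_pool: int = 1000
    n_distractor_eqtl: int = 40
    n_distractor_tftarget: int = 30

    def __post_init__(self) -> None:
        if self.n_planted_causal > self.n_loci:
            raise ValueError("n_planted_causal must be <= n_loci")
        for name in ("genome_length", "n_genes", "n_loci", "locus_size", "peak_width"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_loci > self.n_planted_causal and self.locus_size < 12:
            # n probabilities all strictly below 0.10 need n >= 11 plus jitter room
            raise ValueError("locus_size must be >= 12 when non-planted loci exist")


def null_config(seed: int = 0, **overrides) -> SimulationConfig:
    """A configuration with zero planted effects (type-I error studies)."""
    base = dict(
        seed=seed,
        genome_length=600_000,
        n_genes=24,
        n_loci=8,
        locus_size=12,
        n_motifs=6,
        n_planted_causal=0,
        planted_coloc_fraction=0.0,
        planted_triple_count=0,
        n_planted_motifs=0,
        planted_per_motif=0,
        n_decoy_peak_variants=40,
        n_scattered_pool=350,
        n_distractor_eqtl=10,
        n_distractor_tftarget=8,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@dataclass
class GroundTruth:
    """Manifest of planted entities, for recovery scoring."""

    planted_causal: list[str] = field(default_factory=list)
    planted_binding: list[dict] = field(default_factory=list)  # variant/matrix/effect
    planted_coloc: list[dict] = field(default_factory=list)  # variant/egene/tissue
    planted_triples: list[dict] = field(default_factory=list)  # variant/tf/egene
    motif_instances: list[dict] = field(default_factory=list)


@dataclass
class SimulatedData:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneAnnotation]
    variants: list[Variant]
    gwas_variant_ids: list[str]
    scan_variant_ids: list[str]
    pool_variant_ids: list[str]
    associations: list[AssociationRecord]
    ld_records: list[LDRecord]
    gwas_pics: list[PICSRecord]
    eqtl_pics: list[PICSRecord]
    peaks: list[tuple]
    chromhmm: list[tuple]
    segment_biosample: str
    motifs: list[PWMMatrix]
    expression: pd.DataFrame
    tftargets: list[TFTargetRecord]
    truth: GroundTruth

    def variants_by_id(self) -> dict[str, Variant]:
        return {v.id: v for v in self.variants}

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        rio.write_fasta(self.genome, out / "genome.fa")
        rio.write_genes(self.genes, out / "genes.tsv")
        rio.write_variants(self.variants, out / "variants.tsv")
        rio.write_associations(self.associations, out / "associations.tsv")
        rio.write_ld_table(self.ld_records, out / "ld.tsv")
        rio.write_pics_table(self.gwas_pics, out / "gwas_pics.tsv")
        rio.write_pics_table(self.eqtl_pics, out / "eqtl_pics.tsv")
        rio.write_bed(self.peaks, out / "peaks.bed")
        rio.write_bed(self.chromhmm, out / "chromhmm.bed")
        rio.write_matrix_library(self.motifs, out / "motifs.jaspar")
        rio.write_gct(self.expression, out / "tpm.gct")
        rio.write_tftargets(self.tftargets, out / "tftarget.tsv")
        meta = {
            "scan_variant_ids": self.scan_variant_ids,
            "pool_variant_ids": self.pool_variant_ids,
            "gwas_variant_ids": self.gwas_variant_ids,
            "segment_biosample": self.segment_biosample,
        }
        (out / "truth.json").write_text(
            json.dumps({"truth": asdict(self.truth), "meta": meta}, indent=1)
        )


# ---------------------------------------------------------------------------
# genome

def _simulate_chromosome(rng: np.random.Generator, length: int, gc: float, depletion: float) -> np.ndarray:
    """I.i.d. draw then CpG thinning: each G following a C is replaced by A/T
    with a probability tuned so the realized observed/expected CpG ratio is
    close to ``depletion``."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    arr = rng.choice(4, size=length, p=p).astype(np.int8)
    if depletion >= 1.0:
        return arr
    p_c = gc / 2
    keep = depletion * (1 - p_c * (1 - depletion))
    cg = np.flatnonzero((arr[:-1] == 1) & (arr[1:] == 2))
    replace = cg[rng.random(len(cg)) >= keep] + 1
    # A or T proportional to their base frequencies (equal here)
    arr[replace] = np.where(rng.random(len(replace)) < 0.5, 0, 3).astype(np.int8)
    return arr


def _decode(arr: np.ndarray) -> str:
    return "".join("ACGT"[b] for b in arr)


def cpg_observed_expected(seq: str) -> float:
    """Observed CpG dinucleotide frequency over the mononucleotide expectation."""
    n = len(seq)
    c = seq.count("C") / n
    g = seq.count("G") / n
    cg = sum(seq.count("CG", i, n) for i in [0]) / (n - 1)
    return cg / (c * g)


# ---------------------------------------------------------------------------
# motifs

def _column_ic(q: float) -> float:
    rest = (1 - q) / 3
    h = q * np.log2(q) + 3 * rest * np.log2(rest) if 0 < q < 1 else 0.0
    return 2.0 + h


_Q_CAP = 0.97


def _q_for_column_ic(target_col: float) -> float:
    """Consensus-base probability q giving the requested column IC."""
    lo, hi = 0.25 + 1e-6, _Q_CAP
    target_col = min(max(target_col, 0.0), _column_ic(hi))
    for _ in range(60):
        mid = (lo + hi) / 2
        if _column_ic(mid) < target_col:
            lo = mid
        else:
            hi = mid
    return hi


def _column_ics(rng: np.random.Generator, L: int, target_ic: float) -> np.ndarray:
    """Heterogeneous per-column information, like real motifs: one column at
    the sharpness cap (the plantable core) and the rest Dirichlet-allocated,
    with overflow redistributed below the cap."""
    cap = _column_ic(_Q_CAP)
    # keep a soft fraction: fully saturated matrices have staircase score
    # distributions whose flat treads defeat the p-value-ratio contrast
    target_ic = min(target_ic, 0.8 * L * cap)
    ics = np.zeros(L)
    core = int(rng.integers(L))
    ics[core] = cap
    rest = np.delete(np.arange(L), core)
    ics[rest] = rng.dirichlet(np.ones(L - 1)) * max(target_ic - cap, 0.0)
    for _ in range(20):
        over = np.clip(ics - cap, 0.0, None)
        excess = over.sum()
        if excess <= 1e-9:
            break
        ics = np.minimum(ics, cap)
        under = ics < cap - 1e-9
        if not under.any():
            break
        ics[under] += excess / under.sum()
    return ics


def _simulate_motifs(rng: np.random.Generator, cfg: SimulationConfig) -> list[PWMMatrix]:
    out = []
    lo, hi = cfg.motif_length_range
    for i in range(cfg.n_motifs):
        L = int(rng.integers(lo, hi + 1))
        target = float(rng.uniform(*cfg.motif_ic_range))
        consensus = rng.integers(0, 4, size=L)
        freqs = np.empty((L, 4))
        for j, col_ic in enumerate(_column_ics(rng, L, target)):
            q = _q_for_column_ic(col_ic)
            freqs[j] = (1 - q) / 3
            freqs[j, consensus[j]] = q
        out.append(
            PWMMatrix(
                matrix_id=f"M{i + 1:02d}",
                tf_name=f"TF{i + 1:02d}",
                counts=freqs * 100.0,
                source_db="synthetic",
            )
        )
    return out


# ---------------------------------------------------------------------------
# main generator

def simulate(config: SimulationConfig | None = None, seed: int | None = None) -> SimulatedData:
    cfg = config or SimulationConfig()
    if seed is not None:
        cfg = SimulationConfig(**{**asdict(cfg), "seed": seed})
    rng = np.random.default_rng(cfg.seed)

    clen = cfg.genome_length // cfg.n_chromosomes
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    genome_arr = {
        c: _simulate_chromosome(rng, clen, cfg.gc_content, cfg.cpg_depletion) for c in chroms
    }

    # --- genes (non-overlapping; first n_motifs double as the TF genes) ---
    genes: list[GeneAnnotation] = []
    spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    attempts = 0
    while len(genes) < cfg.n_genes:
        attempts += 1
        if attempts > 50 * cfg.n_genes:
            raise ValueError("cannot place genes at this density")
        chrom = chroms[int(rng.integers(cfg.n_chromosomes))]
        glen = int(rng.integers(2000, 8001))
        start = int(rng.integers(1000, clen - glen - 1000))
        end = start + glen - 1
        if any(s <= end + 500 and start <= e + 500 for s, e in spans[chrom]):
            continue
        spans[chrom].append((start, end))
        strand = "+" if rng.random() < 0.5 else "-"
        idx = len(genes)
        name = f"TF{idx + 1:02d}" if idx < cfg.n_motifs else f"GENE{idx + 1:03d}"
        genes.append(
            GeneAnnotation(
                gene_id=name, gene_name=name, chrom=chrom, start=start, end=end,
                strand=strand, tss=start if strand == "+" else end,
            )
        )

    motifs = _simulate_motifs(rng, cfg)
    truth = GroundTruth()

    # --- loci: index + members with decaying r2; association p-values ---
    used: dict[str, set[int]] = {c: set() for c in chroms}

    def reserve(chrom: str, pos: int, clearance: int = 200) -> bool:
        taken = used[chrom]
        if any((pos + d) in taken for d in range(-clearance, clearance + 1)):
            return False
        taken.add(pos)
        return True

    associations: list[AssociationRecord] = []
    ld_records: list[LDRecord] = []
    gwas_pics: list[PICSRecord] = []
    locus_members: list[list[tuple[str, str, int]]] = []  # per locus: (vid, chrom, pos)
    variant_info: dict[str, dict] = {}
    n_total_loci = cfg.n_loci + cfg.n_null_loci
    for li in range(n_total_loci):
        chrom = chroms[li % cfg.n_chromosomes]
        positions: list[int] = []
        for _attempt in range(100):
            center = int(rng.integers(20_000, clen - 40_000))
            candidate = [center]
            pos = center
            for _ in range(cfg.locus_size - 1):
                pos += int(rng.integers(200, 1200))
                candidate.append(pos)
            if candidate[-1] >= clen - 10_000:
                continue
            taken = used[chrom]
            if any(
                (q + d) in taken for q in candidate for d in range(-200, 201)
            ):
                continue
            for q in candidate:
                taken.add(q)
            positions = candidate
            break
        if not positions:
            raise ValueError("cannot place association loci at this density")
        center = positions[0]
        members = []
        index_id = f"rs{li + 1:03d}_00"
        significant = li < cfg.n_loci
        index_p = 10.0 ** -rng.uniform(8.5, 15) if significant else 10.0 ** -rng.uniform(4, 7)
        associations.append(AssociationRecord(index_id, chrom, center, index_p, is_index=True))
        for mi, p in enumerate(positions):
            vid = index_id if mi == 0 else f"rs{li + 1:03d}_{mi:02d}"
            members.append((vid, chrom, p))
            variant_info[vid] = {"chrom": chrom, "pos": p, "locus": li}
            if mi > 0:
                dist = abs(p - center)
                r2 = float(np.clip(1.0 - dist / 60_000 + rng.normal(0, 0.03), 0.02, 0.999))
                ld_records.append(LDRecord(index_id, vid, round(r2, 4)))
        locus_members.append(members)
        if not significant:
            continue
        planted = li < cfg.n_planted_causal
        ids = [m[0] for m in members]
        if planted:
            index_prob = float(rng.uniform(0.55, 0.85))
            rest = 1.0 - index_prob
            w = 1.0 + rng.random(len(ids) - 1) * 0.4
            probs = [index_prob] + list(rest * w / w.sum())
            truth.planted_causal.append(index_id)
        else:
            # jitter 0.2 bounds the max at 1.2/(n-1+1.2) < 0.10 for n >= 12
            w = 1.0 + rng.random(len(ids)) * 0.2
            probs = list(w / w.sum())
        for vid, prob in zip(ids, probs):
            gwas_pics.append(PICSRecord(vid, index_id, float(prob), "gwas"))

    # --- planted binding variants and decoys inside peaks ---
    planted_motifs = motifs[: cfg.n_planted_motifs]
    coloc_ids = truth.planted_causal[
        : int(round(cfg.planted_coloc_fraction * len(truth.planted_causal)))
    ]
    triple_ids = coloc_ids[: cfg.planted_triple_count]
    # binding targets: triples first, then other significant-locus members
    candidate_ids = list(triple_ids)
    for members in locus_members[: cfg.n_loci]:
        for vid, _, _ in members:
            if vid not in candidate_ids:
                candidate_ids.append(vid)
    n_binding = cfg.n_planted_motifs * cfg.planted_per_motif
    binding_ids = candidate_ids[:n_binding]
    # triples must map to distinct planted motifs
    assignment: dict[str, PWMMatrix] = {}
    for i, vid in enumerate(triple_ids):
        assignment[vid] = planted_motifs[i % max(1, cfg.n_planted_motifs)]
    others = [v for v in binding_ids if v not in assignment]
    for i, vid in enumerate(others):
        assignment[vid] = planted_motifs[i % cfg.n_planted_motifs]

    peaks: list[tuple] = []
    scan_variant_ids: list[str] = []
    alleles: dict[str, tuple[str, str]] = {}
    half = cfg.peak_width // 2
    for i, vid in enumerate(assignment):
        m = assignment[vid]
        info = variant_info[vid]
        chrom, pos = info["chrom"], info["pos"]
        freqs = m.counts / m.counts.sum(axis=1, keepdims=True)
        col = int(np.argmax(freqs.max(axis=1)))  # highest-information column
        consensus = freqs.argmax(axis=1)
        minimum = freqs.argmin(axis=1)
        effect = "disrupt" if i % 2 == 0 else "create"
        # instance sampled from an annealed PWM (freqs squared, renormalized):
        # sharp columns stay consensus, soft columns vary, so windows of the
        # same motif are diverse while sites remain near full strength
        annealed = freqs**2 / (freqs**2).sum(axis=1, keepdims=True)
        instance = np.array(
            [rng.choice(4, p=annealed[j]) for j in range(m.length)]
        )
        instance[col] = consensus[col]
        if effect == "disrupt":
            ref_b, alt_b = int(consensus[col]), int(minimum[col])
        else:
            instance[col] = minimum[col]
            ref_b, alt_b = int(minimum[col]), int(consensus[col])
        start0 = pos - 1 - col  # 0-based start of instance so variant sits at `col`
        genome_arr[chrom][start0 : start0 + m.length] = instance.astype(np.int8)
        alleles[vid] = ("ACGT"[ref_b], "ACGT"[alt_b])
        peaks.append((chrom, max(0, pos - 1 - half), min(clen, pos - 1 + half), f"peak_{vid}"))
        scan_variant_ids.append(vid)
        truth.planted_binding.append(
            {"variant_id": vid, "matrix_id": m.matrix_id, "effect": effect}
        )
        truth.motif_instances.append(
            {"matrix_id": m.matrix_id, "chrom": chrom, "start0": start0, "peak": f"peak_{vid}"}
        )

    decoy_pool = [v for v in candidate_ids[n_binding:]]
    decoys = decoy_pool[: cfg.n_decoy_peak_variants]
    for vid in decoys:
        info = variant_info[vid]
        chrom, pos = info["chrom"], info["pos"]
        m = motifs[int(rng.integers(cfg.n_motifs))]
        side = 1 if rng.random() < 0.5 else -1
        gap = int(rng.integers(25, 80))
        start0 = pos - 1 + side * gap - (m.length if side < 0 else 0)
        consensus = (m.counts / m.counts.sum(axis=1, keepdims=True)).argmax(axis=1)
        genome_arr[chrom][start0 : start0 + m.length] = consensus.astype(np.int8)
        peaks.append((chrom, max(0, pos - 1 - half), min(clen, pos - 1 + half), f"peak_{vid}"))
        scan_variant_ids.append(vid)
        truth.motif_instances.append(
            {"matrix_id": m.matrix_id, "chrom": chrom, "start0": start0, "peak": f"peak_{vid}"}
        )

    peak_spans: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for chrom, s, e, _ in peaks:
        peak_spans[chrom].append((s, e))

    def in_peak(chrom: str, pos: int) -> bool:
        return any(s <= pos - 1 < e for s, e in peak_spans[chrom])

    # --- matched-control pool: near-clones per scanned variant + scatter ---
    pool_variant_ids: list[str] = []
    for vid in scan_variant_ids:
        info = variant_info[vid]
        chrom, pos = info["chrom"], info["pos"]
        placed = 0
        tries = 0
        while placed < cfg.control_clones_per_target and tries < 200:
            tries += 1
            off = int(rng.integers(300, 4000)) * (1 if rng.random() < 0.5 else -1)
            p = pos + off
            if not 1000 < p < clen - 1000 or in_peak(chrom, p):
                continue
            if not reserve(chrom, p, clearance=60):
                continue
            cid = f"ctl_{vid}_{placed}"
            variant_info[cid] = {"chrom": chrom, "pos": p, "locus": None}
            pool_variant_ids.append(cid)
            placed += 1
    for i in range(cfg.n_scattered_pool):
        chrom = chroms[int(rng.integers(cfg.n_chromosomes))]
        p = int(rng.integers(2000, clen - 2000))
        if in_peak(chrom, p) or not reserve(chrom, p, clearance=60):
            continue
        cid = f"pool_{i:04d}"
        variant_info[cid] = {"chrom": chrom, "pos": p, "locus": None}
        pool_variant_ids.append(cid)

    # --- finalize variant records (alleles from the finished genome) ---
    genome = {c: _decode(a) for c, a in genome_arr.items()}
    term_pool = (
        "intergenic_variant", "intron_variant",
        "regulatory_region_variant", "non_coding_transcript_variant",
    )
    variants: list[Variant] = []
    gwas_variant_ids = [m[0] for members in locus_members for m in members]
    for vid, info in variant_info.items():
        chrom, pos = info["chrom"], info["pos"]
        ref_base = genome[chrom][pos - 1]
        if vid in alleles:
            ref, alt = alleles[vid]
        else:
            ref = ref_base
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        terms = {term_pool[int(rng.integers(4))]}
        if rng.random() < 0.3:
            terms.add(term_pool[int(rng.integers(4))])
        cadd = float(rng.uniform(0, 25)) if rng.random() < 0.8 else None
        variants.append(
            Variant(
                id=vid, chrom=chrom, pos=pos, ref=ref, alt=alt,
                allele_freq=float(rng.uniform(0.01, 0.5)),
                consequence_terms=frozenset(terms),
                cadd_phred=cadd,
            )
        )

    # --- chromatin segmentation: tiles, planted peaks forced active ---
    chromhmm: list[tuple] = []
    tile = 5000
    planted_peak_ids = set(scan_variant_ids[: len(assignment)])
    forced: set[tuple[str, int]] = set()
    for chrom, s, e, name in peaks:
        if name.removeprefix("peak_") in planted_peak_ids:
            for t in range(s // tile * tile, e, tile):
                forced.add((chrom, t))
    for chrom in chroms:
        for s in range(0, clen, tile):
            e = min(s + tile, clen)
            if (chrom, s) in forced or rng.random() < cfg.active_state_fraction:
                state = _ACTIVE[int(rng.integers(len(_ACTIVE)))]
            else:
                state = INACTIVE_STATES[int(rng.integers(len(INACTIVE_STATES)))]
            chromhmm.append((chrom, s, e, state))

    # --- expression: planted TFs expressed in brain; one decoy TF silenced ---
    gene_names = [g.gene_id for g in genes]
    tpm = rng.lognormal(mean=1.0, sigma=1.2, size=(len(gene_names), len(EXPRESSION_TISSUES)))
    expression = pd.DataFrame(
        np.round(tpm, 3), index=gene_names, columns=list(EXPRESSION_TISSUES)
    )
    brain_cols = [t for t in EXPRESSION_TISSUES if t.startswith("Brain")]
    for m in planted_motifs:
        expression.loc[m.tf_name, brain_cols] = np.round(rng.uniform(5, 50, len(brain_cols)), 3)
    if cfg.n_planted_motifs < cfg.n_motifs:
        silenced = motifs[-1].tf_name  # exercises the expression filter
        expression.loc[silenced, brain_cols] = 0.5

    # --- eQTL tables, TF targets, ground-truth triples ---
    eqtl_pics: list[PICSRecord] = []
    gene_by_chrom: dict[str, list[GeneAnnotation]] = {c: [] for c in chroms}
    for g in genes:
        gene_by_chrom[g.chrom].append(g)

    def nearest_gene(chrom: str, pos: int) -> GeneAnnotation:
        return min(gene_by_chrom[chrom], key=lambda g: abs(g.tss - pos))

    tftargets: list[TFTargetRecord] = []
    for vid in coloc_ids:
        info = variant_info[vid]
        egene = nearest_gene(info["chrom"], info["pos"]).gene_id
        prob = float(rng.uniform(0.5, 0.7))
        eqtl_pics.append(
            PICSRecord(vid, f"eqtl_{vid}", round(prob, 6), "eqtl", EQTL_TISSUE, egene)
        )
        truth.planted_coloc.append(
            {"variant_id": vid, "egene": egene, "tissue": EQTL_TISSUE}
        )
        if vid in triple_ids:
            tf = assignment[vid].tf_name
            tftargets.append(TFTargetRecord(tf, egene, TFTARGET_BRAIN_TISSUE))
            truth.planted_triples.append({"variant_id": vid, "tf": tf, "egene": egene})
    gwas_set = set(gwas_variant_ids)
    distractor_pool = [v for v in pool_variant_ids if v not in gwas_set]
    for i in range(min(cfg.n_distractor_eqtl, len(distractor_pool))):
        vid = distractor_pool[i]
        info = variant_info[vid]
        egene = nearest_gene(info["chrom"], info["pos"]).gene_id
        eqtl_pics.append(
            PICSRecord(
                vid, f"eqtl_{vid}", round(float(rng.uniform(0.02, 0.9)), 6), "eqtl",
                EQTL_TISSUE if rng.random() < 0.5 else "Liver", egene,
            )
        )
    for _ in range(cfg.n_distractor_tftarget):
        tf = motifs[int(rng.integers(cfg.n_motifs))].tf_name
        gene = gene_names[int(rng.integers(len(gene_names)))]
        tftargets.append(TFTargetRecord(tf, gene, "liver"))

    return _finalize(cfg, genome, genes, variants, gwas_variant_ids, scan_variant_ids,
                     pool_variant_ids, associations, ld_records, gwas_pics, eqtl_pics,
                     peaks, chromhmm, motifs, expression, tftargets, truth)


def _finalize(cfg, genome, genes, variants, gwas_variant_ids, scan_variant_ids,
              pool_variant_ids, associations, ld_records, gwas_pics, eqtl_pics,
              peaks, chromhmm, motifs, expression, tftargets, truth) -> SimulatedData:
    return SimulatedData(
        config=cfg,
        genome=genome,
        genes=genes,
        variants=variants,
        gwas_variant_ids=gwas_variant_ids,
        scan_variant_ids=scan_variant_ids,
        pool_variant_ids=pool_variant_ids,
        associations=associations,
        ld_records=ld_records,
        gwas_pics=gwas_pics,
        eqtl_pics=eqtl_pics,
        peaks=peaks,
        chromhmm=chromhmm,
        segment_biosample=BRAIN_SEGMENTATION_BIOSAMPLE,
        motifs=motifs,
        expression=expression,
        tftargets=tftargets,
        truth=truth,
    )


def load_dataset(indir: str | Path) -> SimulatedData:
    """Rebuild a dataset from a directory written by :meth:`SimulatedData.write`.

    User-supplied directories with the same file names work too; the
    ground-truth manifest is optional.
    """
    d = Path(indir)
    genome = rio.read_fasta(d / "genome.fa")
    variants = rio.read_variants(d / "variants.tsv")
    associations = rio.read_associations(d / "associations.tsv")
    ld_records = rio.read_ld_table(d / "ld.tsv")
    gwas_pics = rio.read_pics_table(d / "gwas_pics.tsv")
    eqtl_pics = rio.read_pics_table(d / "eqtl_pics.tsv")
    truth = GroundTruth()
    meta: dict = {}
    truth_path = d / "truth.json"
    if truth_path.exists():
        payload = json.loads(truth_path.read_text())
        truth = GroundTruth(**payload["truth"])
        meta = payload.get("meta", {})
    gwas_ids = meta.get("gwas_variant_ids") or sorted(
        {r.variant_id for r in gwas_pics}
        | {a.variant_id for a in associations}
        | {r.variant_a for r in ld_records}
        | {r.variant_b for r in ld_records}
    )
    gwas_set = set(gwas_ids)
    pool_ids = meta.get("pool_variant_ids") or [v.id for v in variants if v.id not in gwas_set]
    return _finalize(
        SimulationConfig(),
        genome,
        rio.read_genes(d / "genes.tsv"),
        variants,
        list(gwas_ids),
        meta.get("scan_variant_ids", []),
        list(pool_ids),
        associations,
        ld_records,
        gwas_pics,
        eqtl_pics,
        rio.read_bed(d / "peaks.bed"),
        rio.read_bed(d / "chromhmm.bed"),
        rio.read_matrix_library(d / "motifs.jaspar", "jaspar"),
        rio.read_expression_matrix(d / "tpm.gct"),
        rio.read_tftargets(d / "tftarget.tsv"),
        truth,
    )
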