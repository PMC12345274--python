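"""Promoter-window peak assignment, target classification, and motif scanning.

A gene counts as a putative direct target of the regulator when a ChIP
peak falls within the promoter window, defined as the ``window`` bases
strictly upstream of the translation start site (1.5 kb by default). The
window is strand-aware: for a plus-strand gene it is
``[translation_start - window, translation_start)``; for a minus-strand
gene it mirrors to ``[translation_start + 1, translation_start + 1 + window)``,
both in 0-based half-open coordinates and clipped at chromosome bounds.

Direct targets are the intersection of the bound set with the DEG set;
the associated set is their union.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from intervaltree import IntervalTree

from .config import PipelineConfig
from .models import GeneModel, NsdgrnError, Peak, TargetClassification, as_frozenset

logger = logging.getLogger("nsdgrn.chip")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def promoter_window(
    gene: GeneModel,
    window: int,
    chrom_length: Optional[int] = None,
) -> Tuple[int, int]:
    """The strictly-upstream promoter interval of a gene (0-based half-open).

    The translation start base itself is excluded. Clipped to
    ``[0, chrom_length)`` when a chromosome length is supplied.
    """
    if window <= 0:
        raise NsdgrnError(f"promoter window must be positive, got {window}")
    if gene.strand == "+":
        lo, hi = gene.translation_start - window, gene.translation_start
    else:
        lo, hi = gene.translation_start + 1, gene.translation_start + 1 + window
    lo = max(lo, 0)
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return lo, hi


def assign_peaks_to_genes(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    config: PipelineConfig | None = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> Tuple[Set[str], Dict[str, List[Peak]]]:
    """Assign ChIP peaks to genes by promoter-window overlap.

    In the default ``interval`` mode a gene is bound iff at least one peak
    interval overlaps its promoter window by >= 1 base; in ``summit`` mode
    the peak's summit must lie inside the window. A peak may bind several
    genes (every overlapped promoter is assigned; no nearest-gene
    tie-breaking). Peaks on chromosomes absent from the annotation are
    skipped with a warning.

    Returns the bound gene set and a per-gene peak list (peaks sorted by
    coordinate, so output is independent of input order).
    """
    config = config or PipelineConfig()
    window = config.promoter_window
    trees: Dict[str, IntervalTree] = defaultdict(IntervalTree)
    for gene in genes:
        length = chrom_lengths.get(gene.chrom) if chrom_lengths else None
        lo, hi = promoter_window(gene, window, length)
        if lo < hi:
            trees[gene.chrom].addi(lo, hi, gene.gene_id)

    per_gene: Dict[str, List[Peak]] = defaultdict(list)
    skipped = 0
    for peak in peaks:
        tree = trees.get(peak.chrom)
        if tree is None:
            skipped += 1
            continue
        if config.peak_mode == "summit":
            hits = tree.at(peak.summit)
        else:
            hits = tree.overlap(peak.start, peak.end)
        for iv in hits:
            per_gene[iv.data].append(peak)
    if skipped:
        logger.warning("assign_peaks_to_genes: %d peaks on unknown chromosomes skipped", skipped)
    for gene_id in per_gene:
        per_gene[gene_id].sort(key=lambda p: (p.chrom, p.start, p.end, p.name))
    bound = set(per_gene)
    logger.info(
        "assign_peaks_to_genes: %d of %d genes bound (%d peaks, window %d, mode %s)",
        len(bound), len(genes), len(peaks), window, config.peak_mode,
    )
    return bound, dict(per_gene)


def classify_targets(
    putative_direct: Iterable[str],
    degs: Iterable[str],
    universe: Iterable[str],
) -> TargetClassification:
    """Integrate ChIP-bound and DEG sets into the four target classes.

    direct = bound AND differentially expressed; indirect = DEG only;
    associated = bound OR DEG. Both input sets must lie inside the
    universe (hard error listing offenders otherwise).
    """
    classification = TargetClassification(
        putative_direct=as_frozenset(set(putative_direct)),
        degs=as_frozenset(set(degs)),
        universe=as_frozenset(set(universe)),
    )
    s = classification.summary()
    logger.info(
        "classify_targets: bound=%d (%.1f%%) degs=%d direct=%d associated=%d of %d genes",
        s["n_putative_direct"], s["pct_putative_direct"], s["n_degs"],
        s["n_direct"], s["n_associated"], s["n_universe"],
    )
    return classification


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def _count_overlapping(seq: str, motif: str) -> int:
    count = 0
    for i in range(len(seq) - len(motif) + 1):
        if seq[i : i + len(motif)] == motif:
            count += 1
    return count


def scan_motif(sequences: Mapping[str, str], motif: str) -> Dict[str, Dict[str, int]]:
    """Count overlapping motif occurrences on both strands of each sequence.

    Scans the forward sequence for the motif and for its reverse
    complement (reverse-strand hits). Non-ACGT characters simply never
    match (they are logged once per scan). Returns per-sequence counts:
    ``{seq_id: {"forward": f, "reverse": r, "total": f + r, "length": L}}``.
    """
    if not motif:
        raise NsdgrnError("scan_motif: empty motif")
    motif = motif.upper()
    rc = reverse_complement(motif)
    out: Dict[str, Dict[str, int]] = {}
    n_ambiguous = 0
    for name, seq in sequences.items():
        seq = seq.upper()
        if set(seq) - set("ACGT"):
            n_ambiguous += 1
        fwd = _count_overlapping(seq, motif)
        rev = _count_overlapping(seq, rc)
        out[name] = {"forward": fwd, "reverse": rev, "total": fwd + rev, "length": len(seq)}
    if n_ambiguous:
        logger.info("scan_motif: %d sequences contain non-ACGT characters (treated as mismatches)", n_ambiguous)
    return out


def occurrence_rates_per_kb(
    counts: Sequence[float], lengths_bp: Optional[Sequence[float]] = None
) -> np.ndarray:
    """Per-sequence motif occurrence rates per kilobase."""
    counts_arr = np.asarray(counts, dtype=float)
    if lengths_bp is None:
        lengths = np.full_like(counts_arr, 1000.0)
    else:
        lengths = np.asarray(lengths_bp, dtype=float)
    return counts_arr / (lengths / 1000.0)


def motif_enrichment(
    bound_counts: Sequence[float],
    background_counts: Sequence[float],
    bound_lengths: Optional[Sequence[float]] = None,
    background_lengths: Optional[Sequence[float]] = None,
    n_permutations: int = 1000,
    seed: Optional[int] = None,
) -> Tuple[float, float]:
    """Permutation test for motif excess in bound vs background promoters.

    The statistic is the difference of mean per-kb occurrence rates
    (bound minus background). The p-value is the upper-tail permutation
    probability with group labels shuffled, using the (r + 1) / (n + 1)
    estimator. Returns ``(statistic, p_value)``.
    """
    if len(bound_counts) == 0 or len(background_counts) == 0:
        raise NsdgrnError("motif_enrichment: both groups must be non-empty")
    if n_permutations < 100:
        import warnings

        warnings.warn("motif_enrichment: fewer than 100 permutations gives a coarse p-value")
    bound_rates = occurrence_rates_per_kb(bound_counts, bound_lengths)
    bg_rates = occurrence_rates_per_kb(background_counts, background_lengths)
    statistic = float(bound_rates.mean() - bg_rates.mean())

    pooled = np.concatenate([bound_rates, bg_rates])
    n_bound = len(bound_rates)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        stat = perm[:n_bound].mean() - perm[n_bound:].mean()
        if stat >= statistic:
            exceed += 1
    p_value = (exceed + 1) / (n_permutations + 1)
    logger.info(
        "motif_enrichment: statistic=%.4f per kb, p=%.4g (%d permutations)",
        statistic, p_value, n_permutations,
    )
    return statistic, p_value
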