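"""Promoter windows, peak assignment, target classification, motif scan."""

import numpy as np
import pytest

from nsdgrn.chip import (
    assign_peaks_to_genes,
    classify_targets,
    motif_enrichment,
    promoter_window,
    reverse_complement,
    scan_motif,
)
from nsdgrn.config import PipelineConfig
from nsdgrn.models import GeneModel, NsdgrnError, Peak, percent_of_universe


def gene(gene_id, strand, translation_start, chrom="chr1"):
    if strand == "+":
        start, end = translation_start, translation_start + 2000
    else:
        start, end = max(0, translation_start - 1999), translation_start + 1
    return GeneModel(gene_id, chrom, start, end, strand, translation_start)


# ---------------------------------------------------------------------------
# promoter windows
# ---------------------------------------------------------------------------


def test_plus_strand_window_is_strictly_upstream():
    assert promoter_window(gene("g", "+", 5000), 1500) == (3500, 5000)


def test_minus_strand_window_mirrors():
    assert promoter_window(gene("g", "-", 5000), 1500) == (5001, 6501)


def test_window_clipped_at_chromosome_start():
    assert promoter_window(gene("g", "+", 200), 1500) == (0, 200)


def test_window_clipped_at_chromosome_end():
    g = gene("g", "-", 5000)
    assert promoter_window(g, 1500, chrom_length=6000) == (5001, 6000)


# ---------------------------------------------------------------------------
# peak assignment
# ---------------------------------------------------------------------------


def test_overlapping_peak_binds():
    g = gene("gA", "+", 5000)
    peak = Peak("chr1", 4900, 5050, 4975)
    bound, per_gene = assign_peaks_to_genes([peak], [g])
    assert bound == {"gA"}
    assert per_gene["gA"] == [peak]


def test_half_open_boundary_peak_does_not_bind():
    # peak [3400, 3500) touches the window [3500, 5000) only at the boundary
    g = gene("gA", "+", 5000)
    bound, _ = assign_peaks_to_genes([Peak("chr1", 3400, 3500, 3450)], [g])
    assert bound == set()


def test_summit_mode_requires_summit_inside_window():
    g = gene("gA", "+", 5000)
    # interval overlaps the window but the summit sits outside it
    peak = Peak("chr1", 3400, 3600, 3450)
    config = PipelineConfig(peak_mode="summit")
    bound_interval, _ = assign_peaks_to_genes([peak], [g])
    bound_summit, _ = assign_peaks_to_genes([peak], [g], config)
    assert bound_interval == {"gA"}
    assert bound_summit == set()


def test_peak_on_unknown_chromosome_skipped():
    g = gene("gA", "+", 5000)
    bound, _ = assign_peaks_to_genes([Peak("chrX", 4900, 5050, 4975)], [g])
    assert bound == set()


def brute_force_assignment(peaks, genes, window=1500, mode="interval"):
    """All-pairs interval-overlap oracle."""
    bound = set()
    for g in genes:
        if g.strand == "+":
            lo, hi = max(0, g.translation_start - window), g.translation_start
        else:
            lo, hi = g.translation_start + 1, g.translation_start + 1 + window
        for p in peaks:
            if p.chrom != g.chrom:
                continue
            if mode == "summit":
                hit = lo <= p.summit < hi
            else:
                hit = p.start < hi and lo < p.end
            if hit:
                bound.add(g.gene_id)
    return bound


def random_instance(seed):
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(50):
        strand = "+" if rng.random() < 0.5 else "-"
        ts = int(rng.integers(2000, 100_000))
        chrom = f"chr{int(rng.integers(1, 3))}"
        genes.append(gene(f"g{i:02d}", strand, ts, chrom))
    peaks = []
    for i in range(200):
        start = int(rng.integers(0, 100_000))
        width = int(rng.integers(50, 2000))
        chrom = f"chr{int(rng.integers(1, 4))}"  # chr3 exercises the skip path
        peaks.append(Peak(chrom, start, start + width, start + width // 2, f"p{i}"))
    return genes, peaks


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
@pytest.mark.parametrize("mode", ["interval", "summit"])
def test_assignment_matches_all_pairs_oracle(seed, mode):
    genes, peaks = random_instance(seed)
    config = PipelineConfig(peak_mode=mode)
    bound, _ = assign_peaks_to_genes(peaks, genes, config)
    assert bound == brute_force_assignment(peaks, genes, mode=mode)


def test_assignment_is_input_order_invariant():
    genes, peaks = random_instance(99)
    fwd, _ = assign_peaks_to_genes(peaks, genes)
    rev, _ = assign_peaks_to_genes(list(reversed(peaks)), list(reversed(genes)))
    assert fwd == rev


def test_strand_reversal_changes_bound_set_as_oracle_predicts(default_species):
    """Flipping every gene's strand must move the windows to the other side:
    a strand-ignoring implementation cannot pass both this and recovery."""
    sp = default_species
    flipped = [
        GeneModel(g.gene_id, g.chrom, g.start, g.end,
                  "-" if g.strand == "+" else "+",
                  # keep the anchor inside the gene body after the flip
                  g.translation_start)
        for g in sp.genes
    ]
    bound_flipped, _ = assign_peaks_to_genes(sp.peaks, flipped)
    oracle = brute_force_assignment(sp.peaks, flipped)
    assert bound_flipped == oracle
    assert bound_flipped != sp.truth.bound_genes


def test_planted_bound_genes_fully_recovered_no_decoys(default_species):
    sp = default_species
    bound, _ = assign_peaks_to_genes(sp.peaks, sp.genes)
    assert bound == sp.truth.bound_genes
    assert not bound & sp.truth.decoy_genes


# ---------------------------------------------------------------------------
# target classification
# ---------------------------------------------------------------------------


def make_sets(n_chip, n_deg, n_overlap, n_universe):
    universe = [f"g{i:05d}" for i in range(n_universe)]
    overlap = universe[:n_overlap]
    chip = set(overlap) | set(universe[n_overlap : n_overlap + n_chip - n_overlap])
    deg_start = n_chip
    degs = set(overlap) | set(universe[deg_start : deg_start + n_deg - n_overlap])
    return chip, degs, set(universe)


def test_union_cardinality_on_worked_example_sizes():
    chip, degs, universe = make_sets(502, 1052, 68, 10_988)
    cls = classify_targets(chip, degs, universe)
    assert len(cls.direct) == 68
    assert len(cls.associated) == 1486
    chip2, degs2, universe2 = make_sets(674, 1964, 126, 13_485)
    cls2 = classify_targets(chip2, degs2, universe2)
    assert len(cls2.associated) == 2512


def test_percent_of_universe_one_decimal_reporting():
    assert percent_of_universe(502, 10_988) == 4.6
    assert percent_of_universe(674, 13_485) == 5.0


def test_disjoint_sets_follow_inclusion_exclusion():
    chip = {"a", "b"}
    degs = {"c", "d", "e"}
    cls = classify_targets(chip, degs, chip | degs | {"f"})
    assert cls.direct == frozenset()
    assert len(cls.associated) == 5


def test_chip_subset_of_degs_makes_all_bound_genes_direct():
    chip = {"a", "b"}
    degs = {"a", "b", "c"}
    cls = classify_targets(chip, degs, {"a", "b", "c", "d"})
    assert cls.direct == cls.putative_direct


def test_set_outside_universe_is_hard_error():
    with pytest.raises(NsdgrnError, match="rogue"):
        classify_targets({"rogue"}, set(), {"a"})


@pytest.mark.parametrize("seed", range(20))
def test_inclusion_exclusion_identity_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    universe = [f"g{i}" for i in range(200)]
    chip = set(rng.choice(universe, size=rng.integers(0, 100), replace=False))
    degs = set(rng.choice(universe, size=rng.integers(0, 150), replace=False))
    cls = classify_targets(chip, degs, universe)
    assert len(cls.associated) == len(chip) + len(degs) - len(cls.direct)
    assert cls.indirect == cls.degs - cls.putative_direct
    assert cls.direct <= cls.putative_direct


# ---------------------------------------------------------------------------
# motif scanning & enrichment
# ---------------------------------------------------------------------------


def test_forward_motif_counted():
    counts = scan_motif({"s": "GATCT"}, "GATCT")
    assert counts["s"]["forward"] == 1 and counts["s"]["reverse"] == 0


def test_reverse_complement_hit_counted():
    # AGATC is the reverse complement of GATCT
    assert reverse_complement("GATCT") == "AGATC"
    counts = scan_motif({"s": "AGATC"}, "GATCT")
    assert counts["s"]["reverse"] == 1 and counts["s"]["forward"] == 0


def naive_overlapping_count(seq, motif):
    return sum(1 for i in range(len(seq)) if seq[i : i + len(motif)] == motif)


@pytest.mark.parametrize("k", [1, 3, 7])
def test_tandem_repeats_match_sliding_window_oracle(k):
    seq = "GATCTGATCT" * k  # each repeat unit holds 2 forward copies
    counts = scan_motif({"s": seq}, "GATCT")
    assert counts["s"]["forward"] == naive_overlapping_count(seq, "GATCT") == 2 * k
    assert counts["s"]["reverse"] == naive_overlapping_count(seq, "AGATC")


def test_ambiguous_bases_never_match():
    counts = scan_motif({"s": "GANCTGATCT"}, "GATCT")
    assert counts["s"]["forward"] == 1


def test_identical_groups_give_large_p():
    counts = [2, 3, 1, 4, 2, 3, 1, 4]
    stat, p = motif_enrichment(counts, list(counts), n_permutations=500, seed=0)
    assert stat == 0.0
    assert p > 0.3


def test_planted_motif_excess_detected():
    rng = np.random.default_rng(3)
    background = rng.poisson(2, size=200)
    bound = rng.poisson(10, size=50)  # 5x planted rate
    stat, p = motif_enrichment(bound, background, n_permutations=1000, seed=3)
    assert stat > 0
    assert p < 0.01


def test_swapping_groups_negates_statistic():
    a, b = [5, 6, 7], [1, 2, 3]
    stat_ab, _ = motif_enrichment(a, b, n_permutations=200, seed=1)
    stat_ba, _ = motif_enrichment(b, a, n_permutations=200, seed=1)
    assert stat_ab == pytest.approx(-stat_ba)
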