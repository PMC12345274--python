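"""Synthetic two-species multi-omics datasets with planted ground truth.

Every downstream stage of the pipeline is testable without the original
sequencing data: the generator emits the processed forms the pipeline
consumes (GFF3 annotation, narrowPeak ChIP peaks, replicate FPKM
matrices, promoter FASTA, a STRING-style PPI table, a one-to-one
ortholog map, metabolite feature tables and a compound library),
together with the planted truth (which genes are differential, which
promoters are bound, where motif copies were placed, which metabolite
features shifted).

The planted conditions mirror the statistical structure the analysis
assumes: log-normal FPKM baselines with multiplicative replicate noise
and >= 4-fold planted effects at n = 3 replicates (high power under the
twofold + t-test screen); ChIP peaks placed strand-correctly inside the
1.5 kb promoter window for bound genes and >= 2 kb upstream for decoys,
so a strand-ignoring window rule is falsified by construction; a
stochastic-block-model PPI graph whose within-module confidences sit
above the 150 floor while between-module confidences straddle it.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd

from . import io as nio
from .chip import promoter_window
from .models import GeneModel, NsdgrnError, Peak

BASES = np.array(list("ACGT"))


@dataclass
class SyntheticSpec:
    """Knobs of the synthetic study; defaults are the study conditions."""

    # genome layout
    n_genes: int = 2000
    n_chromosomes: int = 2
    gene_length: int = 1200
    intergenic: int = 5000  # guarantees >= 3 kb spacing and non-overlapping windows
    cds_offset: int = 150  # 5' UTR length: translation start offset from the gene 5' end
    chromosome_length: Optional[int] = None  # None -> auto-sized to fit

    # expression
    n_replicates: int = 3
    deg_up_fraction: float = 0.05  # planted up-in-mutant genes
    deg_down_fraction: float = 0.05
    deg_effect_fold: float = 4.0  # >= 4 so the twofold + t screen has high power at n=3
    fpkm_meanlog: float = 2.0
    fpkm_sdlog: float = 1.0
    noise_sdlog: float = 0.25  # multiplicative log-normal replicate noise
    dropout_fraction: float = 0.01  # non-planted genes given one zero sample

    # ChIP peaks / promoters
    bound_fraction: float = 0.05
    decoy_fraction: float = 0.05
    peak_width: int = 300
    decoy_offset: int = 2000  # decoy peaks end at least this far upstream
    promoter_length: int = 1500
    motif_count_bound: int = 3  # planted copies per bound promoter (>= 2)
    motif_background_rate: float = 0.3  # Poisson mean of extra copies, background
    nre_motif: str = "GATCT"

    # PPI
    ppi_n_modules: int = 10
    ppi_module_size: int = 30
    ppi_p_within: float = 0.3
    ppi_p_between: float = 0.01

    # orthologs
    ortholog_shared_fraction: float = 0.6

    # metabolome
    n_features: int = 600
    metab_shift_log2: float = 2.0  # planted |log2| shifts >= 2
    metab_diff_fraction: float = 0.1
    n_wt_only: int = 10
    n_mutant_only: int = 5
    library_size: int = 80
    library_hit_fraction: float = 0.1

    rng_seed: int = 7

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        fractions = {
            "deg_up_fraction": self.deg_up_fraction,
            "deg_down_fraction": self.deg_down_fraction,
            "bound_fraction": self.bound_fraction,
            "decoy_fraction": self.decoy_fraction,
            "dropout_fraction": self.dropout_fraction,
            "ppi_p_within": self.ppi_p_within,
            "ppi_p_between": self.ppi_p_between,
            "ortholog_shared_fraction": self.ortholog_shared_fraction,
            "metab_diff_fraction": self.metab_diff_fraction,
            "library_hit_fraction": self.library_hit_fraction,
        }
        for name, value in fractions.items():
            if not 0.0 <= value <= 1.0:
                raise NsdgrnError(f"synthetic spec: {name} must be in [0, 1], got {value}")
        if self.n_replicates < 2:
            raise NsdgrnError("synthetic spec: n_replicates must be >= 2")
        if self.deg_effect_fold <= 1.0:
            raise NsdgrnError("synthetic spec: deg_effect_fold must exceed 1")
        if self.metab_shift_log2 <= 0:
            raise NsdgrnError("synthetic spec: metab_shift_log2 must be positive")
        if self.intergenic < 3000:
            raise NsdgrnError("synthetic spec: intergenic spacing must be >= 3000 bases")
        if self.deg_up_fraction + self.deg_down_fraction > 1.0:
            raise NsdgrnError("synthetic spec: DEG fractions sum above 1")
        if self.bound_fraction + self.decoy_fraction > 1.0:
            raise NsdgrnError("synthetic spec: bound + decoy fractions sum above 1")
        needed = self.decoy_offset + self.peak_width + 100 + self.promoter_length
        if self.intergenic < needed:
            raise NsdgrnError(
                f"synthetic spec: intergenic spacing {self.intergenic} cannot host "
                f"decoy peaks clear of promoter windows (need >= {needed})"
            )
        if self.peak_width >= self.promoter_length:
            raise NsdgrnError("synthetic spec: peak_width must be below promoter_length")

    def replace(self, **overrides) -> "SyntheticSpec":
        return dataclasses.replace(self, **overrides)


@dataclass
class SpeciesTruth:
    """Planted ground truth for one pseudo-species."""

    deg_up: Set[str]  # up in the mutant (negative log2 WT/mutant)
    deg_down: Set[str]
    bound_genes: Set[str]
    decoy_genes: Set[str]
    motif_positions: Dict[str, List[int]]
    chrom_lengths: Dict[str, int]

    def to_jsonable(self) -> dict:
        return {
            "deg_up": sorted(self.deg_up),
            "deg_down": sorted(self.deg_down),
            "bound_genes": sorted(self.bound_genes),
            "decoy_genes": sorted(self.decoy_genes),
            "motif_positions": {k: self.motif_positions[k] for k in sorted(self.motif_positions)},
            "chrom_lengths": dict(sorted(self.chrom_lengths.items())),
        }


@dataclass
class SpeciesDataset:
    label: str
    genes: List[GeneModel]
    chrom_lengths: Dict[str, int]
    peaks: List[Peak]
    promoters: Dict[str, str]
    fpkm_wt: pd.DataFrame
    fpkm_mut: pd.DataFrame
    truth: SpeciesTruth

    @property
    def gene_ids(self) -> List[str]:
        return [g.gene_id for g in self.genes]

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nio.write_annotation(self.genes, outdir / "annotation.gff3")
        nio.write_peaks(self.peaks, outdir / "peaks.narrowPeak", fmt="narrowPeak")
        nio.write_fasta(self.promoters, outdir / "promoters.fasta")
        nio.write_expression(self.fpkm_wt, outdir / "fpkm_wt.tsv")
        nio.write_expression(self.fpkm_mut, outdir / "fpkm_mutant.tsv")
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(self.truth.to_jsonable(), fh, indent=1, sort_keys=True)


def _species_rng(spec: SyntheticSpec, species_label: str, stream: str) -> np.random.Generator:
    """Deterministic per-species, per-stream generator derived from the spec seed."""
    tag = zlib.crc32(f"{species_label}/{stream}".encode())
    return np.random.default_rng(np.random.SeedSequence([spec.rng_seed, tag]))


# ---------------------------------------------------------------------------
# genome + expression + peaks + promoters
# ---------------------------------------------------------------------------


def _tile_genes(spec: SyntheticSpec, label: str, rng: np.random.Generator
                ) -> Tuple[List[GeneModel], Dict[str, int]]:
    pitch = spec.gene_length + spec.intergenic
    per_chrom = -(-spec.n_genes // spec.n_chromosomes)  # ceil
    margin = 3000
    needed_length = margin + per_chrom * pitch + margin
    if spec.chromosome_length is not None and spec.chromosome_length < needed_length:
        raise NsdgrnError(
            f"spacing constraint unsatisfiable: {per_chrom} genes per chromosome at "
            f"pitch {pitch} need {needed_length} bases, chromosome_length is "
            f"{spec.chromosome_length}"
        )
    chrom_length = spec.chromosome_length or needed_length
    genes: List[GeneModel] = []
    chrom_lengths: Dict[str, int] = {}
    strands = rng.choice(["+", "-"], size=spec.n_genes)
    for i in range(spec.n_genes):
        c, j = divmod(i, per_chrom)
        chrom = f"{label}_chr{c + 1}"
        chrom_lengths[chrom] = chrom_length
        start = margin + j * pitch
        end = start + spec.gene_length
        strand = str(strands[i])
        if strand == "+":
            translation_start = start + spec.cds_offset
        else:
            translation_start = end - 1 - spec.cds_offset
        genes.append(
            GeneModel(
                gene_id=f"{label}_g{i:05d}",
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                translation_start=translation_start,
            )
        )
    return genes, chrom_lengths


def _plant_peaks(spec: SyntheticSpec, genes: Sequence[GeneModel],
                 bound: Set[str], decoys: Set[str], rng: np.random.Generator
                 ) -> List[Peak]:
    peaks: List[Peak] = []
    by_id = {g.gene_id: g for g in genes}
    for idx, gene_id in enumerate(sorted(bound)):
        gene = by_id[gene_id]
        lo, hi = promoter_window(gene, spec.promoter_length)
        offset = int(rng.integers(0, hi - lo - spec.peak_width + 1))
        start = lo + offset
        end = start + spec.peak_width
        peaks.append(Peak(chrom=gene.chrom, start=start, end=end,
                          summit=(start + end) // 2, name=f"bound_{idx:04d}",
                          score=float(rng.integers(100, 1000))))
    for idx, gene_id in enumerate(sorted(decoys)):
        gene = by_id[gene_id]
        jitter = int(rng.integers(0, 100))
        if gene.strand == "+":
            end = gene.translation_start - spec.decoy_offset - jitter
            start = end - spec.peak_width
        else:
            start = gene.translation_start + 1 + spec.decoy_offset + jitter
            end = start + spec.peak_width
        peaks.append(Peak(chrom=gene.chrom, start=start, end=end,
                          summit=(start + end) // 2, name=f"decoy_{idx:04d}",
                          score=float(rng.integers(100, 1000))))
    peaks.sort(key=lambda p: (p.chrom, p.start, p.end, p.name))
    return peaks


def _random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(BASES, size=length)


def _plant_motif(seq: np.ndarray, motif: str, n_copies: int,
                 rng: np.random.Generator) -> List[int]:
    """Plant non-overlapping motif copies at random positions; return positions."""
    m = len(motif)
    positions: List[int] = []
    taken: Set[int] = set()
    attempts = 0
    while len(positions) < n_copies and attempts < 200:
        attempts += 1
        pos = int(rng.integers(0, len(seq) - m + 1))
        if any(p in taken for p in range(pos - m + 1, pos + m)):
            continue
        seq[pos : pos + m] = list(motif)
        taken.update(range(pos, pos + m))
        positions.append(pos)
    return sorted(positions)


def _make_promoters(spec: SyntheticSpec, genes: Sequence[GeneModel],
                    bound: Set[str], rng: np.random.Generator
                    ) -> Tuple[Dict[str, str], Dict[str, List[int]]]:
    promoters: Dict[str, str] = {}
    planted: Dict[str, List[int]] = {}
    for gene in genes:
        seq = _random_sequence(spec.promoter_length, rng)
        if gene.gene_id in bound:
            n_copies = spec.motif_count_bound
        else:
            n_copies = int(rng.poisson(spec.motif_background_rate))
        positions = _plant_motif(seq, spec.nre_motif, n_copies, rng) if n_copies else []
        promoters[gene.gene_id] = "".join(seq)
        planted[gene.gene_id] = positions
    return promoters, planted


def _make_fpkm(spec: SyntheticSpec, gene_ids: Sequence[str],
               deg_up: Set[str], deg_down: Set[str], rng: np.random.Generator
               ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    n = len(gene_ids)
    baseline = rng.lognormal(spec.fpkm_meanlog, spec.fpkm_sdlog, size=n)
    effect = np.ones(n)
    idx = {g: i for i, g in enumerate(gene_ids)}
    for g in deg_up:
        effect[idx[g]] = spec.deg_effect_fold  # higher in the mutant
    for g in deg_down:
        effect[idx[g]] = 1.0 / spec.deg_effect_fold

    def replicate_matrix(mean: np.ndarray) -> np.ndarray:
        noise = rng.lognormal(0.0, spec.noise_sdlog, size=(n, spec.n_replicates))
        return mean[:, None] * noise

    wt = replicate_matrix(baseline)
    mut = replicate_matrix(baseline * effect)

    # sprinkle zero samples on non-planted genes so the coverage filter bites
    planted = deg_up | deg_down
    eligible = [i for i, g in enumerate(gene_ids) if g not in planted]
    n_drop = int(round(spec.dropout_fraction * n))
    if n_drop and eligible:
        drop_rows = rng.choice(eligible, size=min(n_drop, len(eligible)), replace=False)
        for row in drop_rows:
            col = int(rng.integers(0, 2 * spec.n_replicates))
            if col < spec.n_replicates:
                wt[row, col] = 0.0
            else:
                mut[row, col - spec.n_replicates] = 0.0

    wt_df = pd.DataFrame(wt, index=list(gene_ids),
                         columns=[f"WT_{r + 1}" for r in range(spec.n_replicates)])
    mut_df = pd.DataFrame(mut, index=list(gene_ids),
                          columns=[f"MUT_{r + 1}" for r in range(spec.n_replicates)])
    return wt_df, mut_df


def generate_species(spec: SyntheticSpec, species_label: str) -> SpeciesDataset:
    """Generate one pseudo-species: annotation, peaks, promoters, FPKM, truth.

    Deterministic in (spec, species_label): the same inputs always yield
    byte-identical output files.
    """
    layout_rng = _species_rng(spec, species_label, "layout")
    genes, chrom_lengths = _tile_genes(spec, species_label, layout_rng)
    gene_ids = [g.gene_id for g in genes]

    pick_rng = _species_rng(spec, species_label, "planting")
    n_up = int(round(spec.deg_up_fraction * spec.n_genes))
    n_down = int(round(spec.deg_down_fraction * spec.n_genes))
    deg_pick = pick_rng.choice(gene_ids, size=n_up + n_down, replace=False)
    deg_up, deg_down = set(deg_pick[:n_up]), set(deg_pick[n_up:])
    n_bound = int(round(spec.bound_fraction * spec.n_genes))
    n_decoy = int(round(spec.decoy_fraction * spec.n_genes))
    chip_pick = pick_rng.choice(gene_ids, size=n_bound + n_decoy, replace=False)
    bound, decoys = set(chip_pick[:n_bound]), set(chip_pick[n_bound:])

    peaks = _plant_peaks(spec, genes, bound, decoys,
                         _species_rng(spec, species_label, "peaks"))
    promoters, motif_positions = _make_promoters(
        spec, genes, bound, _species_rng(spec, species_label, "promoters"))
    fpkm_wt, fpkm_mut = _make_fpkm(spec, gene_ids, deg_up, deg_down,
                                   _species_rng(spec, species_label, "fpkm"))

    truth = SpeciesTruth(
        deg_up=deg_up,
        deg_down=deg_down,
        bound_genes=bound,
        decoy_genes=decoys,
        motif_positions=motif_positions,
        chrom_lengths=chrom_lengths,
    )
    return SpeciesDataset(
        label=species_label,
        genes=genes,
        chrom_lengths=chrom_lengths,
        peaks=peaks,
        promoters=promoters,
        fpkm_wt=fpkm_wt,
        fpkm_mut=fpkm_mut,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# PPI
# ---------------------------------------------------------------------------


def generate_ppi(
    spec: SyntheticSpec,
    node_universe: Sequence[str],
    species_label: str = "A",
) -> Tuple[pd.DataFrame, List[Set[str]]]:
    """Stochastic-block-model PPI table with a confidence column.

    Within-module edges draw confidence ~ Uniform(150, 999), between-module
    (and module-to-background) edges ~ Uniform(50, 400), so the standard
    confidence floor of 150 keeps all module structure and a predictable
    5/7 of between-module edges. Undirected, no self-loops, each unordered
    pair at most once. Returns (edge table, planted modules).
    """
    if len(node_universe) == 0:
        raise NsdgrnError("generate_ppi: empty node universe")
    rng = _species_rng(spec, species_label, "ppi")
    nodes = np.asarray(list(node_universe))
    n = len(nodes)
    n_module_nodes = min(spec.ppi_n_modules * spec.ppi_module_size, n)
    perm = rng.permutation(n)
    labels = np.full(n, -1, dtype=int)
    for m in range(spec.ppi_n_modules):
        members = perm[m * spec.ppi_module_size : (m + 1) * spec.ppi_module_size]
        labels[members] = m
        if (m + 1) * spec.ppi_module_size >= n_module_nodes:
            break
    modules = [set(nodes[labels == m]) for m in range(spec.ppi_n_modules) if (labels == m).any()]

    iu, ju = np.triu_indices(n, k=1)
    same = (labels[iu] >= 0) & (labels[iu] == labels[ju])
    p = np.where(same, spec.ppi_p_within, spec.ppi_p_between)
    keep = rng.random(len(iu)) < p
    iu, ju, same = iu[keep], ju[keep], same[keep]
    conf = np.where(
        same,
        rng.uniform(150.0, 999.0, size=len(iu)),
        rng.uniform(50.0, 400.0, size=len(iu)),
    )
    edges = pd.DataFrame(
        {"node_a": nodes[iu], "node_b": nodes[ju], "confidence": np.round(conf, 1)}
    )
    edges = edges.sort_values(["node_a", "node_b"], kind="stable", ignore_index=True)
    return edges, modules


# ---------------------------------------------------------------------------
# orthologs
# ---------------------------------------------------------------------------


def generate_ortholog_map(
    universe_a: Sequence[str],
    universe_b: Sequence[str],
    shared_fraction: float,
    seed: int = 0,
) -> List[Tuple[str, str]]:
    """One-to-one ortholog pairs covering a fraction of the smaller universe.

    |pairs| = round(shared_fraction * min(|A|, |B|)).
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise NsdgrnError(f"shared_fraction must be in [0, 1], got {shared_fraction}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(b"orthologs")]))
    n_pairs = int(round(shared_fraction * min(len(universe_a), len(universe_b))))
    picks_a = rng.choice(np.asarray(list(universe_a)), size=n_pairs, replace=False)
    picks_b = rng.choice(np.asarray(list(universe_b)), size=n_pairs, replace=False)
    pairs = sorted(zip(picks_a.tolist(), picks_b.tolist()))
    return pairs


# ---------------------------------------------------------------------------
# metabolome
# ---------------------------------------------------------------------------


@dataclass
class MetabolomeTruth:
    increased_in_mutant: Set[str]
    decreased_in_mutant: Set[str]
    wt_only: Set[str]
    mutant_only: Set[str]
    library_hits: Dict[str, str]  # feature -> planted compound

    def to_jsonable(self) -> dict:
        return {
            "increased_in_mutant": sorted(self.increased_in_mutant),
            "decreased_in_mutant": sorted(self.decreased_in_mutant),
            "wt_only": sorted(self.wt_only),
            "mutant_only": sorted(self.mutant_only),
            "library_hits": dict(sorted(self.library_hits.items())),
        }


@dataclass
class MetabolomeDataset:
    table: pd.DataFrame  # feature_id index; mz, rt, per-sample intensities
    wt_cols: List[str]
    mut_cols: List[str]
    library: pd.DataFrame
    truth: MetabolomeTruth

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nio.write_feature_table(self.table, outdir / "features.tsv")
        self.library.to_csv(outdir / "compound_library.tsv", sep="\t", index=False)
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(self.truth.to_jsonable(), fh, indent=1, sort_keys=True)


def generate_metabolome(spec: SyntheticSpec, species_label: str = "A") -> MetabolomeDataset:
    """Metabolite feature tables with planted shifts, absences and library hits."""
    rng = _species_rng(spec, species_label, "metabolome")
    n = spec.n_features
    feature_ids = [f"{species_label}_m{i:04d}" for i in range(n)]

    # compound library; half the entries carry a reference retention time
    lib_masses = np.sort(rng.uniform(150.0, 1500.0, size=spec.library_size))
    lib_rt = rng.uniform(1.0, 20.0, size=spec.library_size)
    has_rt = rng.random(spec.library_size) < 0.5
    library = pd.DataFrame(
        {
            "compound": [f"compound_{i:03d}" for i in range(spec.library_size)],
            "mass": np.round(lib_masses, 4),
            "rt": np.where(has_rt, np.round(lib_rt, 2), np.nan),
        }
    )

    n_hits = int(round(spec.library_hit_fraction * n))
    if n_hits > spec.library_size:
        raise NsdgrnError("library_hit_fraction demands more hits than library entries")
    hit_features = rng.choice(n, size=n_hits, replace=False)
    hit_compounds = rng.choice(spec.library_size, size=n_hits, replace=False)

    mz = np.empty(n)
    rt = rng.uniform(1.0, 20.0, size=n)
    masses = library["mass"].to_numpy()
    for i in range(n):
        while True:
            candidate = rng.uniform(150.0, 1500.0)
            if np.abs(masses - candidate).min() > 0.0015:  # keep decoys clear of the library
                mz[i] = candidate
                break
    for f_idx, c_idx in zip(hit_features, hit_compounds):
        mz[f_idx] = masses[c_idx] + rng.uniform(-0.0005, 0.0005)
        if not np.isnan(library.at[int(c_idx), "rt"]):
            rt[f_idx] = library.at[int(c_idx), "rt"] + rng.uniform(-0.5, 0.5)
    library_hits = {
        feature_ids[int(f)]: library.at[int(c), "compound"]
        for f, c in zip(hit_features, hit_compounds)
    }

    baseline = 10.0 ** rng.uniform(5.2, 8.0, size=n)
    effect = np.ones(n)
    detectable = np.nonzero(baseline > 2e6)[0]
    n_diff = int(round(spec.metab_diff_fraction * n))
    special = rng.choice(detectable, size=min(n_diff + spec.n_wt_only + spec.n_mutant_only,
                                              len(detectable)), replace=False)
    diff_idx = special[:n_diff]
    wt_only_idx = special[n_diff : n_diff + spec.n_wt_only]
    mut_only_idx = special[n_diff + spec.n_wt_only :]
    up_mask = rng.random(len(diff_idx)) < 0.5
    shift = 2.0 ** spec.metab_shift_log2
    effect[diff_idx[up_mask]] = shift  # higher in the mutant
    effect[diff_idx[~up_mask]] = 1.0 / shift

    def noisy(mean: np.ndarray) -> np.ndarray:
        return mean[:, None] * rng.lognormal(0.0, 0.25, size=(n, spec.n_replicates))

    wt = noisy(baseline)
    mut = noisy(baseline * effect)
    wt[mut_only_idx, :] = 0.0
    mut[wt_only_idx, :] = 0.0

    wt_cols = [f"WT_{r + 1}" for r in range(spec.n_replicates)]
    mut_cols = [f"MUT_{r + 1}" for r in range(spec.n_replicates)]
    table = pd.DataFrame(
        np.column_stack([mz, rt, wt, mut]),
        index=feature_ids,
        columns=["mz", "rt"] + wt_cols + mut_cols,
    )
    table["mz"] = table["mz"].round(4)
    table["rt"] = table["rt"].round(2)
    truth = MetabolomeTruth(
        increased_in_mutant={feature_ids[i] for i in diff_idx[up_mask]},
        decreased_in_mutant={feature_ids[i] for i in diff_idx[~up_mask]},
        wt_only={feature_ids[i] for i in wt_only_idx},
        mutant_only={feature_ids[i] for i in mut_only_idx},
        library_hits=library_hits,
    )
    return MetabolomeDataset(table=table, wt_cols=wt_cols, mut_cols=mut_cols,
                             library=library, truth=truth)


# ---------------------------------------------------------------------------
# GO annotation + whole dataset
# ---------------------------------------------------------------------------


def generate_go_annotation(
    universe: Sequence[str], seed: int = 0, n_terms: int = 40
) -> pd.DataFrame:
    """Random flat gene -> term annotation table (gene, term, name)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, zlib.crc32(b"go")]))
    genes = np.asarray(list(universe))
    rows = []
    for t in range(n_terms):
        term = f"GO:{t + 1:07d}"
        size = int(rng.integers(5, max(6, len(genes) // 25)))
        for g in rng.choice(genes, size=min(size, len(genes)), replace=False):
            rows.append({"gene": g, "term": term, "name": f"synthetic process {t + 1}"})
    return pd.DataFrame(rows, columns=["gene", "term", "name"])


@dataclass
class Dataset:
    """A self-contained two-species synthetic study."""

    spec: SyntheticSpec
    species_a: SpeciesDataset
    species_b: SpeciesDataset
    ppi_a: pd.DataFrame
    ppi_b: pd.DataFrame
    modules_a: List[Set[str]]
    modules_b: List[Set[str]]
    orthologs: List[Tuple[str, str]]
    metabolome_a: MetabolomeDataset
    metabolome_b: MetabolomeDataset
    go_a: pd.DataFrame
    go_b: pd.DataFrame

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        for species, ppi, metab, go in (
            (self.species_a, self.ppi_a, self.metabolome_a, self.go_a),
            (self.species_b, self.ppi_b, self.metabolome_b, self.go_b),
        ):
            d = outdir / f"species_{species.label}"
            species.write(d)
            ppi.to_csv(d / "ppi.tsv", sep="\t", index=False)
            go.to_csv(d / "go_annotation.tsv", sep="\t", index=False)
            metab.write(d / "metabolome")
        nio.write_ortholog_map(self.orthologs, outdir / "orthologs.tsv")
        self.spec_to_yaml(outdir / "synthetic_spec.yaml")

    def spec_to_yaml(self, path: Union[str, Path]) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self.spec), fh, sort_keys=True)


def generate_dataset(spec: SyntheticSpec, label_a: str = "An", label_b: str = "Af") -> Dataset:
    """Generate the full two-species study from one spec, deterministically."""
    species_a = generate_species(spec, label_a)
    species_b = generate_species(spec, label_b)
    ppi_a, modules_a = generate_ppi(spec, species_a.gene_ids, label_a)
    ppi_b, modules_b = generate_ppi(spec, species_b.gene_ids, label_b)
    orthologs = generate_ortholog_map(
        species_a.gene_ids, species_b.gene_ids, spec.ortholog_shared_fraction,
        seed=spec.rng_seed,
    )
    return Dataset(
        spec=spec,
        species_a=species_a,
        species_b=species_b,
        ppi_a=ppi_a,
        ppi_b=ppi_b,
        modules_a=modules_a,
        modules_b=modules_b,
        orthologs=orthologs,
        metabolome_a=generate_metabolome(spec, label_a),
        metabolome_b=generate_metabolome(spec, label_b),
        go_a=generate_go_annotation(species_a.gene_ids, seed=spec.rng_seed),
        go_b=generate_go_annotation(species_b.gene_ids, seed=spec.rng_seed + 1),
    )
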