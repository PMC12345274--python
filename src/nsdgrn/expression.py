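"""Differential expression from FPKM matrices.

The calling rule is the classical two-threshold screen: a two-tailed
equal-variance (Student's) t-test on quantile-normalized FPKM, combined
with a greater-than-twofold change computed on the *raw* FPKM condition
means. Fold changes follow the wild-type-over-mutant sign convention:

    log2FC = log2(mean FPKM in WT / mean FPKM in mutant)

so a negative log2FC means the gene is UP in the deletion mutant (the
regulator represses it in the wild type), and a positive log2FC means it
is DOWN in the mutant (the regulator activates it).

Both criteria are strict inequalities: a gene at exactly P = 0.05 or
exactly |log2FC| = 1 is never called.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Mapping, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .models import NsdgrnError

logger = logging.getLogger("nsdgrn.expression")

UP_IN_MUTANT = "up_in_mutant"
DOWN_IN_MUTANT = "down_in_mutant"
NOT_SIGNIFICANT = "ns"


def filter_expressed(matrix: pd.DataFrame) -> pd.DataFrame:
    """Keep genes with FPKM > 0 in every sample (100% coverage across samples).

    Row order is preserved. An empty result is a warning, not an error.
    """
    if (matrix.to_numpy() < 0).any():
        raise NsdgrnError("filter_expressed: negative FPKM values")
    keep = (matrix > 0).all(axis=1)
    out = matrix.loc[keep]
    if out.empty:
        warnings.warn("filter_expressed: no gene has full coverage across samples")
    logger.info("filter_expressed: %d of %d genes retained", len(out), len(matrix))
    return out


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to a common distribution.

    After normalization every column's sorted value vector equals the
    per-rank cross-column mean of the input. Ties within a column receive
    the mean of the normalized values of their tied ranks (the
    mean-of-tied-ranks dialect).

    A single-column matrix is returned unchanged with a warning.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile_normalize: fewer than 2 columns, returning input unchanged")
        return matrix.copy()
    arr = matrix.to_numpy(dtype=float)
    n, m = arr.shape
    order = np.argsort(arr, axis=0, kind="stable")
    ref = np.take_along_axis(arr, order, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(m):
        sorted_col = arr[order[:, j], j]
        # average the reference over runs of tied values
        _, inverse = np.unique(sorted_col, return_inverse=True)
        sums = np.bincount(inverse, weights=ref)
        counts = np.bincount(inverse)
        out[order[:, j], j] = (sums / counts)[inverse]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def call_degs(
    wt: pd.DataFrame,
    mutant: pd.DataFrame,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Call differentially expressed genes between wild type and mutant.

    Both matrices are genes x replicate-samples and must share the gene
    universe. Genes lacking full coverage (an FPKM of zero in any sample)
    are screened out first. The t-test runs on quantile-normalized values
    (all samples normalized together) unless ``deg_test_on_normalized`` is
    off; the fold change always uses raw condition means with the
    configured pseudocount added to both means.

    Returns a DataFrame indexed by gene_id with columns ``log2fc``,
    ``p_value`` and ``call``, sorted by ascending p-value (ties broken by
    gene id for determinism).
    """
    config = config or PipelineConfig()
    if wt.shape[1] < 2 or mutant.shape[1] < 2:
        raise NsdgrnError("call_degs: each condition needs >=2 replicates")
    if set(wt.index) != set(mutant.index):
        raise NsdgrnError("call_degs: WT and mutant matrices must share the gene universe")
    mutant = mutant.loc[wt.index]

    combined = pd.concat([wt, mutant], axis=1)
    expressed = filter_expressed(combined)
    wt_raw = expressed.iloc[:, : wt.shape[1]]
    mut_raw = expressed.iloc[:, wt.shape[1]:]

    if config.deg_test_on_normalized:
        normed = quantile_normalize(expressed)
        wt_test = normed.iloc[:, : wt.shape[1]].to_numpy()
        mut_test = normed.iloc[:, wt.shape[1]:].to_numpy()
    else:
        wt_test = wt_raw.to_numpy()
        mut_test = mut_raw.to_numpy()

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-identical rows (possible after quantile normalization) trigger
        # a scipy precision warning; those rows are ns by construction
        warnings.filterwarnings("ignore", message="Precision loss", category=RuntimeWarning)
        _, pvals = stats.ttest_ind(wt_test, mut_test, axis=1, equal_var=True)
    pvals = np.where(np.isnan(pvals), 1.0, pvals)

    eps = config.deg_pseudocount
    log2fc = np.log2(
        (wt_raw.mean(axis=1).to_numpy() + eps) / (mut_raw.mean(axis=1).to_numpy() + eps)
    )

    effective_p = pvals
    if config.deg_fdr:
        from statsmodels.stats.multitest import multipletests

        effective_p = multipletests(pvals, method="fdr_bh")[1]

    log2_threshold = np.log2(config.deg_fold_threshold)
    significant = (effective_p < config.deg_p_threshold) & (
        np.abs(log2fc) > log2_threshold
    )
    call = np.where(
        significant,
        np.where(log2fc < 0, UP_IN_MUTANT, DOWN_IN_MUTANT),
        NOT_SIGNIFICANT,
    )

    result = pd.DataFrame(
        {"log2fc": log2fc, "p_value": pvals, "call": call}, index=expressed.index
    )
    # ascending p, ties broken by gene id so output is order-deterministic
    result = result.sort_index(kind="stable").sort_values(by="p_value", kind="stable")
    n_up = int((result["call"] == UP_IN_MUTANT).sum())
    n_down = int((result["call"] == DOWN_IN_MUTANT).sum())
    logger.info(
        "call_degs: %d genes tested, %d up_in_mutant, %d down_in_mutant "
        "(p<%g, fold>%g)",
        len(result), n_up, n_down, config.deg_p_threshold, config.deg_fold_threshold,
    )
    return result


def deg_sets(deg_table: pd.DataFrame) -> Dict[str, Set[str]]:
    """Direction-labelled gene sets from a call table: {'up': ..., 'down': ...}.

    Directions are relative to the mutant ('up' = up_in_mutant).
    """
    return {
        "up": set(deg_table.index[deg_table["call"] == UP_IN_MUTANT]),
        "down": set(deg_table.index[deg_table["call"] == DOWN_IN_MUTANT]),
    }


@dataclass(frozen=True)
class DirectionSummary:
    n_cross: int  # genes called in the cross-complemented comparison
    n_overlap: int  # of those also called (same direction) vs WT
    n_wt_specific: int  # called vs WT but not in the cross set


@dataclass(frozen=True)
class RescueSummary:
    """Cross-complementation set accounting per direction."""

    per_direction: Dict[str, DirectionSummary]


def classify_rescue(
    deg_wt_vs_mut: Mapping[str, Set[str]],
    deg_cross_vs_mut: Mapping[str, Set[str]],
) -> RescueSummary:
    """Quantify how much of the WT expression response a cross-complemented
    strain restores.

    Both inputs map a direction label ('up'/'down', relative to the
    mutant) to a gene set called against the same mutant baseline. For
    each direction the summary reports the cross set size, the overlap
    with the WT profile, and the WT-specific remainder (WT set minus the
    cross set).
    """
    valid = {"up", "down"}
    for name, sets in (("WT", deg_wt_vs_mut), ("cross", deg_cross_vs_mut)):
        bad = set(sets) - valid
        if bad:
            raise NsdgrnError(
                f"classify_rescue: {name} has direction labels outside {{up, down}}: {sorted(bad)}"
            )
    out: Dict[str, DirectionSummary] = {}
    for direction in sorted(valid):
        wt_set = set(deg_wt_vs_mut.get(direction, set()))
        cross_set = set(deg_cross_vs_mut.get(direction, set()))
        out[direction] = DirectionSummary(
            n_cross=len(cross_set),
            n_overlap=len(cross_set & wt_set),
            n_wt_specific=len(wt_set - cross_set),
        )
    return RescueSummary(per_direction=out)
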