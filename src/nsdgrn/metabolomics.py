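"""Metabolite differential abundance, presence/absence, and identification.

Feature tables are post-processing LC-MS output: one row per feature
(m/z, retention time) with per-sample intensity columns. Differential
calling mirrors the transcriptome screen: a two-sample two-tailed
Student's t-test on log10(intensity + 1), gated on a minimum mean peak
intensity (> 1e6 in at least one condition) and |log2FC| > 1 computed on
condition means with a pseudocount of 1. Fold changes follow the same
WT-over-mutant sign convention as the expression module.

Identification matches feature m/z against a compound library at
+/-0.001 Da (inclusive) and, when the library supplies a reference
retention time, +/-1.5 retention-time units.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .models import NsdgrnError

logger = logging.getLogger("nsdgrn.metabolomics")

INCREASED = "increased_in_mutant"
DECREASED = "decreased_in_mutant"
NOT_SIGNIFICANT = "ns"


def _check_columns(table: pd.DataFrame, cols: Sequence[str], label: str) -> None:
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise NsdgrnError(f"feature table missing {label} columns: {missing}")
    if len(cols) < 2:
        raise NsdgrnError(f"need >=2 replicates per condition, got {len(cols)} for {label}")


def call_differential(
    table: pd.DataFrame,
    wt_cols: Sequence[str],
    mut_cols: Sequence[str],
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Differential-abundance calls for every feature.

    Features are eligible when their mean intensity exceeds the gate
    (> 1e6) in at least one condition; ineligible features are reported
    with ``eligible=False`` and call 'ns'. All thresholds are strict
    inequalities. Returns a DataFrame indexed like the input with columns
    mean_wt, mean_mut, log2fc, p_value, eligible, call.
    """
    config = config or PipelineConfig()
    _check_columns(table, wt_cols, "WT")
    _check_columns(table, mut_cols, "mutant")
    wt = table[list(wt_cols)].to_numpy(dtype=float)
    mut = table[list(mut_cols)].to_numpy(dtype=float)
    if (wt < 0).any() or (mut < 0).any():
        raise NsdgrnError("call_differential: negative intensities")

    mean_wt = wt.mean(axis=1)
    mean_mut = mut.mean(axis=1)
    eligible = (mean_wt > config.metab_min_intensity) | (
        mean_mut > config.metab_min_intensity
    )
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Precision loss", category=RuntimeWarning)
        _, pvals = stats.ttest_ind(
            np.log10(wt + 1.0), np.log10(mut + 1.0), axis=1, equal_var=True
        )
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    log2fc = np.log2((mean_wt + 1.0) / (mean_mut + 1.0))

    significant = (
        eligible
        & (pvals < config.metab_p_threshold)
        & (np.abs(log2fc) > config.metab_log2fc_threshold)
    )
    call = np.where(
        significant, np.where(log2fc < 0, INCREASED, DECREASED), NOT_SIGNIFICANT
    )
    out = pd.DataFrame(
        {
            "mean_wt": mean_wt,
            "mean_mut": mean_mut,
            "log2fc": log2fc,
            "p_value": pvals,
            "eligible": eligible,
            "call": call,
        },
        index=table.index,
    )
    logger.info(
        "call_differential: %d features, %d eligible, %d increased, %d decreased",
        len(out), int(eligible.sum()),
        int((call == INCREASED).sum()), int((call == DECREASED).sum()),
    )
    return out


def classify_presence(
    table: pd.DataFrame,
    wt_cols: Sequence[str],
    mut_cols: Sequence[str],
    config: Optional[PipelineConfig] = None,
) -> pd.Series:
    """Presence/absence class per feature: wt_only, mutant_only, both, neither.

    A feature counts as detected in a condition when its mean intensity
    exceeds the detection threshold (the differential-intensity gate by
    default).
    """
    config = config or PipelineConfig()
    _check_columns(table, wt_cols, "WT")
    _check_columns(table, mut_cols, "mutant")
    threshold = config.metab_min_intensity
    in_wt = table[list(wt_cols)].mean(axis=1) > threshold
    in_mut = table[list(mut_cols)].mean(axis=1) > threshold
    classes = np.select(
        [in_wt & in_mut, in_wt & ~in_mut, ~in_wt & in_mut],
        ["both", "wt_only", "mutant_only"],
        default="neither",
    )
    out = pd.Series(classes, index=table.index, name="presence")
    counts = out.value_counts()
    logger.info("classify_presence: %s", counts.to_dict())
    return out


def identify_compounds(
    table: pd.DataFrame,
    library: pd.DataFrame,
    config: Optional[PipelineConfig] = None,
) -> pd.DataFrame:
    """Exact-mass (and optional retention-time) compound identification.

    A feature matches a compound iff |feature m/z - library mass| <=
    mass_tolerance (0.001 Da, inclusive) and, when the library entry
    carries a reference retention time, |delta RT| <= rt_tolerance. A
    feature may match several compounds; every match is reported, sorted
    by ascending absolute mass error (ties broken by feature then
    compound id), independent of feature and library order.
    """
    config = config or PipelineConfig()
    if library.empty:
        raise NsdgrnError("identify_compounds: empty compound library")
    for col in ("mz", "rt"):
        if col not in table.columns:
            raise NsdgrnError(f"identify_compounds: feature table missing {col!r}")
    mz = table["mz"].to_numpy(dtype=float) + config.mass_adduct_shift
    rt = table["rt"].to_numpy(dtype=float)
    feature_ids = np.asarray(table.index)

    rows = []
    for entry in library.itertuples(index=False):
        mass_error = mz - float(entry.mass)
        hits = np.abs(mass_error) <= config.mass_tolerance
        lib_rt = float(entry.rt) if not pd.isna(entry.rt) else None
        if lib_rt is not None:
            hits &= np.abs(rt - lib_rt) <= config.rt_tolerance
        for i in np.nonzero(hits)[0]:
            rows.append(
                {
                    "feature_id": feature_ids[i],
                    "compound": entry.compound,
                    "feature_mz": float(mz[i]),
                    "library_mass": float(entry.mass),
                    "mass_error": float(mass_error[i]),
                    "rt_error": float(rt[i] - lib_rt) if lib_rt is not None else np.nan,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["feature_id", "compound", "feature_mz", "library_mass",
                 "mass_error", "rt_error"],
    )
    if not out.empty:
        out = out.assign(_abs=out["mass_error"].abs()).sort_values(
            by=["_abs", "feature_id", "compound"], kind="stable", ignore_index=True
        ).drop(columns="_abs")
    logger.info("identify_compounds: %d matches for %d features against %d compounds",
                len(out), len(table), len(library))
    return out
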