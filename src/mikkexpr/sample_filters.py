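"""QC and design-completeness filtering of the sample set.

Three stages, applied in pipeline order qc -> MAD outlier -> (SNP check,
separate module) -> completeness:

* ``qc_filter`` drops samples that failed strandedness, mapped < 50%
  of reads uniquely, or have an unusual GC content (robust z-score
  against the cohort median/MAD).
* ``mad_outlier_filter`` drops whole-transcriptome outliers on the
  per-sample median of log2(TPM+1), scored in MAD units.
* ``completeness_filter`` keeps only lines with at least one sample in
  every sex x season cell and exactly one sample per cell thereafter.

Each stage returns (retained, removal_log); the log names the first
rule that fired per removed sample.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MIN_PCT_UNIQUE = 50.0
DEFAULT_GC_Z_THRESHOLD = 3.0
DEFAULT_MAD_K = 5.0

_LOG_COLUMNS = ["sample_id", "stage", "rule", "value"]


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame(columns=_LOG_COLUMNS)


def qc_filter(
    metadata: pd.DataFrame,
    min_pct_uniquely_mapped: float = DEFAULT_MIN_PCT_UNIQUE,
    gc_z_threshold: float = DEFAULT_GC_Z_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read-level QC: strandedness, unique-mapping rate, GC content.

    Mapping below ``min_pct_uniquely_mapped`` is removed strictly, so a
    sample at exactly the cutoff is retained.  "Unusual GC" is a
    heuristic convention: |gc - median| / (1.4826 * MAD) > threshold,
    computed against the cohort passed in.
    """
    required = {"sample_id", "strandedness_pass", "pct_uniquely_mapped", "gc_content"}
    missing_cols = required - set(metadata.columns)
    if missing_cols:
        raise ValueError(f"metadata missing QC columns: {sorted(missing_cols)}")
    for col in ("strandedness_pass", "pct_uniquely_mapped", "gc_content"):
        bad = metadata.loc[metadata[col].isna(), "sample_id"]
        if len(bad):
            raise ValueError(f"missing {col} for sample(s): {list(bad[:5])}")

    gc = metadata["gc_content"].to_numpy(dtype=float)
    gc_med = np.median(gc)
    gc_mad = np.median(np.abs(gc - gc_med))
    if gc_mad > 0:
        gc_z = np.abs(gc - gc_med) / (1.4826 * gc_mad)
    else:
        gc_z = np.zeros_like(gc)

    records = []
    for i, rec in enumerate(metadata.itertuples(index=False)):
        if not rec.strandedness_pass:
            records.append((rec.sample_id, "qc", "strandedness_fail", 0.0))
        elif rec.pct_uniquely_mapped < min_pct_uniquely_mapped:
            records.append(
                (rec.sample_id, "qc", "low_unique_mapping", rec.pct_uniquely_mapped)
            )
        elif gc_z[i] > gc_z_threshold:
            records.append((rec.sample_id, "qc", "unusual_gc", round(float(gc_z[i]), 4)))
    log = pd.DataFrame(records, columns=_LOG_COLUMNS)
    retained = metadata[~metadata["sample_id"].isin(log["sample_id"])].reset_index(drop=True)
    return retained, log


def mad_outlier_filter(
    expression: pd.DataFrame, k: float = DEFAULT_MAD_K
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove whole-sample expression outliers in MAD units.

    ``expression`` is genes x samples on the TPM scale.  Each sample is
    summarised as s = median over genes of log2(TPM+1); the sample is
    removed iff |s - median(s)| / (1.4826 * MAD(s)) > k.  A zero MAD
    (e.g. identical samples) removes nobody.

    Returns the retained expression table (columns subset) and the log.
    """
    if expression.shape[1] < 3:
        raise ValueError(
            f"MAD outlier filter needs >= 3 samples, got {expression.shape[1]}"
        )
    s = np.log2(expression.to_numpy(dtype=float) + 1.0)
    summary = pd.Series(np.median(s, axis=0), index=expression.columns)
    med = summary.median()
    mad = (summary - med).abs().median()
    if mad == 0:
        return expression, _empty_log()
    z = (summary - med).abs() / (1.4826 * mad)
    out = z[z > k]
    log = pd.DataFrame(
        {
            "sample_id": out.index,
            "stage": "mad_outlier",
            "rule": "median_log2_tpm_outlier",
            "value": out.round(4).to_numpy(),
        },
        columns=_LOG_COLUMNS,
    )
    retained = expression.drop(columns=out.index)
    return retained, log


def completeness_filter(
    metadata: pd.DataFrame,
) -> tuple[list[str], pd.DataFrame, pd.DataFrame]:
    """Keep lines observed in all four sex x season cells, one sample each.

    A line is retained iff each of (F, summer), (F, winter), (M, summer),
    (M, winter) holds at least one sample.  Within each cell of a
    retained line exactly one sample survives — the lexicographically
    smallest sample_id — so the output always has 4 samples per line.

    Returns (retained line ids, retained metadata, removal log).
    """
    if metadata.empty:
        raise ValueError("metadata is empty")
    counts = metadata.groupby(["line_id", "sex", "season"]).size()
    cells_per_line = counts.groupby("line_id").size()
    complete = sorted(cells_per_line.index[cells_per_line == 4])
    if not complete:
        logger.warning("no line has all four sex x season cells; analysis set is empty")

    records = []
    keep_ids = []
    for line in sorted(metadata["line_id"].unique()):
        line_meta = metadata[metadata["line_id"] == line]
        if line not in complete:
            for sid in line_meta["sample_id"]:
                records.append((sid, "completeness", "incomplete_line", np.nan))
            continue
        for (sex, season), cell in line_meta.groupby(["sex", "season"]):
            ordered = cell.sort_values("sample_id")
            keep_ids.append(ordered["sample_id"].iloc[0])
            if len(ordered) > 1:
                logger.warning(
                    "line %s cell (%s, %s) holds %d samples; keeping %s",
                    line, sex, season, len(ordered), ordered["sample_id"].iloc[0],
                )
                for sid in ordered["sample_id"].iloc[1:]:
                    records.append((sid, "completeness", "extra_in_cell", np.nan))
    retained = metadata[metadata["sample_id"].isin(keep_ids)].reset_index(drop=True)
    log = pd.DataFrame(records, columns=_LOG_COLUMNS)
    return complete, retained, log
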