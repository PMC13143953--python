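"""Sample-identity verification via SNP genotype concordance.

In a near-isogenic panel every line is (almost) a single genotype, so a
sample's RNA-seq allele counts at a set of high-confidence exonic SNPs
identify which line it really came from.  The pipeline: select usable
SNPs from the panel, call a genotype per SNP from the sample's allele
counts, compute the fraction of calls matching each line's expected
genotypes, and retain the sample only if its assigned line's match
proportion is within the retention threshold of the best-matching
line's (difference > -0.005 by default, strict).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import HET, HOM_ALT, HOM_REF

logger = logging.getLogger(__name__)

NO_CALL = -1

#: columns of a SNP panel that are annotation rather than per-line genotypes
PANEL_FIXED_COLUMNS = ("snp_id", "chrom", "pos", "region", "mean_depth")

DEFAULT_RETENTION_THRESHOLD = -0.005
DEFAULT_MIN_MEAN_DEPTH = 10.0
DEFAULT_MIN_SITE_DEPTH = 5
DEFAULT_HOM_FRACTION = 0.9
DEFAULT_EXCLUDED_CHROMS = frozenset({"2"})


def panel_lines(panel: pd.DataFrame) -> list[str]:
    """Line identifiers = every panel column that is not fixed annotation."""
    return [c for c in panel.columns if c not in PANEL_FIXED_COLUMNS]


@dataclass
class SnpCheckResult:
    """Per-sample identity-check outcome."""

    sample_id: str
    assigned_line: str
    proportions: pd.Series  # per-line match proportion, NaN if un-checkable
    n_callable: int
    best_line: str | None
    tied_best: list[str] = field(default_factory=list)
    diff: float = float("nan")
    retained: bool = False
    checkable: bool = True


def select_snps(
    panel: pd.DataFrame,
    min_mean_depth: float = DEFAULT_MIN_MEAN_DEPTH,
    excluded_chroms: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CHROMS,
    required_region: str = "exon",
) -> pd.DataFrame:
    """High-confidence subset: deep, in the required region class, and not
    on an excluded chromosome.  Row order is preserved."""
    if panel.empty:
        raise ValueError("SNP panel is empty")
    keep = (
        (panel["mean_depth"] >= min_mean_depth)
        & (panel["region"] == required_region)
        & ~panel["chrom"].astype(str).isin({str(c) for c in excluded_chroms})
    )
    selected = panel.loc[keep]
    if selected.empty:
        warnings.warn("SNP selection produced an empty panel", stacklevel=2)
    return selected


def call_genotype(
    ref_count: int,
    alt_count: int,
    min_site_depth: int = DEFAULT_MIN_SITE_DEPTH,
    hom_fraction: float = DEFAULT_HOM_FRACTION,
) -> int:
    """Hard genotype call from allele counts at one site.

    no-call below ``min_site_depth``; hom-alt at alt fraction >=
    ``hom_fraction``; hom-ref at alt fraction <= 1 - hom_fraction; het
    in between.
    """
    if hom_fraction <= 0.5:
        raise ValueError(f"hom_fraction must exceed 0.5, got {hom_fraction}")
    if ref_count < 0 or alt_count < 0:
        raise ValueError("allele counts must be non-negative")
    depth = ref_count + alt_count
    if depth < min_site_depth or depth == 0:
        return NO_CALL
    # compare each allele's own fraction against hom_fraction (rather
    # than alt against 1 - hom_fraction) so the boundary is float-exact
    if alt_count / depth >= hom_fraction:
        return HOM_ALT
    if ref_count / depth >= hom_fraction:
        return HOM_REF
    return HET


def _call_genotypes_vectorized(
    ref: np.ndarray, alt: np.ndarray, min_site_depth: int, hom_fraction: float
) -> np.ndarray:
    if hom_fraction <= 0.5:
        raise ValueError(f"hom_fraction must exceed 0.5, got {hom_fraction}")
    depth = ref + alt
    safe = np.maximum(depth, 1)
    calls = np.full(ref.shape, HET, dtype=int)
    calls[alt / safe >= hom_fraction] = HOM_ALT
    calls[ref / safe >= hom_fraction] = HOM_REF
    calls[(depth < min_site_depth) | (depth == 0)] = NO_CALL
    return calls


def match_proportions(
    sample_counts: pd.DataFrame,
    panel: pd.DataFrame,
    min_site_depth: int = DEFAULT_MIN_SITE_DEPTH,
    hom_fraction: float = DEFAULT_HOM_FRACTION,
) -> tuple[pd.Series, int]:
    """Fraction of callable SNPs whose call matches each line's genotype.

    ``sample_counts`` holds one sample's rows (snp_id, ref_count,
    alt_count).  The denominator is the number of callable SNPs for
    this sample, not the panel size, so low-depth samples are not
    penalised for no-calls.  With zero callable SNPs all proportions
    are NaN and the caller must treat the sample as un-checkable.
    """
    lines = panel_lines(panel)
    unknown = set(sample_counts["snp_id"]) - set(panel["snp_id"])
    if unknown:
        raise ValueError(
            f"allele counts reference SNPs absent from the panel: {sorted(unknown)[:5]}"
        )
    merged = panel[["snp_id", *lines]].merge(
        sample_counts[["snp_id", "ref_count", "alt_count"]], on="snp_id", how="inner"
    )
    calls = _call_genotypes_vectorized(
        merged["ref_count"].to_numpy(),
        merged["alt_count"].to_numpy(),
        min_site_depth,
        hom_fraction,
    )
    callable_mask = calls != NO_CALL
    n_callable = int(callable_mask.sum())
    if n_callable == 0:
        return pd.Series(np.nan, index=lines), 0
    expected = merged.loc[callable_mask, lines].to_numpy()
    matches = (expected == calls[callable_mask, None]).sum(axis=0)
    return pd.Series(matches / n_callable, index=lines), n_callable


def retention_decision(
    sample_id: str,
    assigned_line: str,
    proportions: pd.Series,
    n_callable: int,
    threshold: float = DEFAULT_RETENTION_THRESHOLD,
) -> SnpCheckResult:
    """Retain the sample iff proportion(assigned) - max proportion > threshold.

    The best line is the argmax over all candidate lines; ties are all
    reported but do not change the decision, which uses the maximum
    value only.  An un-checkable sample (no callable SNPs) is not
    retained.
    """
    if assigned_line not in proportions.index:
        raise ValueError(f"assigned line {assigned_line!r} absent from the panel")
    if n_callable == 0 or proportions.isna().all():
        logger.warning("sample %s has no callable SNPs; un-checkable", sample_id)
        return SnpCheckResult(
            sample_id=sample_id,
            assigned_line=assigned_line,
            proportions=proportions,
            n_callable=0,
            best_line=None,
            checkable=False,
            retained=False,
        )
    best_value = proportions.max()
    tied = list(proportions.index[proportions == best_value])
    if len(tied) > 1:
        logger.info("sample %s: %d lines tie at the best match", sample_id, len(tied))
    diff = float(proportions[assigned_line] - best_value)
    return SnpCheckResult(
        sample_id=sample_id,
        assigned_line=assigned_line,
        proportions=proportions,
        n_callable=n_callable,
        best_line=tied[0],
        tied_best=tied,
        diff=diff,
        retained=diff > threshold,
    )


def run_snp_check(
    panel: pd.DataFrame,
    allele_counts: pd.DataFrame,
    metadata: pd.DataFrame,
    threshold: float = DEFAULT_RETENTION_THRESHOLD,
    min_mean_depth: float = DEFAULT_MIN_MEAN_DEPTH,
    excluded_chroms: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CHROMS,
    required_region: str = "exon",
    min_site_depth: int = DEFAULT_MIN_SITE_DEPTH,
    hom_fraction: float = DEFAULT_HOM_FRACTION,
) -> pd.DataFrame:
    """Full identity check for every sample in the metadata.

    Returns the report table (sample_id, assigned_line, best_line,
    p_assigned, p_best, diff, n_callable, retained).
    """
    unknown = set(allele_counts["snp_id"]) - set(panel["snp_id"])
    if unknown:
        raise ValueError(
            f"allele counts reference SNPs absent from the panel: {sorted(unknown)[:5]}"
        )
    selected = select_snps(panel, min_mean_depth, excluded_chroms, required_region)
    allele_counts = allele_counts[allele_counts["snp_id"].isin(set(selected["snp_id"]))]
    rows = []
    counts_by_sample = dict(tuple(allele_counts.groupby("sample_id", sort=False)))
    for _, rec in metadata.iterrows():
        sample_counts = counts_by_sample.get(
            rec["sample_id"], allele_counts.iloc[0:0]
        )
        props, n_callable = match_proportions(
            sample_counts, selected, min_site_depth, hom_fraction
        )
        result = retention_decision(
            rec["sample_id"], rec["line_id"], props, n_callable, threshold
        )
        rows.append(
            {
                "sample_id": result.sample_id,
                "assigned_line": result.assigned_line,
                "best_line": result.best_line,
                "p_assigned": (
                    float(props[result.assigned_line]) if result.checkable else np.nan
                ),
                "p_best": float(props.max()) if result.checkable else np.nan,
                "diff": result.diff,
                "n_callable": result.n_callable,
                "retained": result.retained,
            }
        )
    return pd.DataFrame(rows)
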