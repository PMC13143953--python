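"""Per-line seasonal and sexual divergence indexes with bootstrap flagging.

For each line the seasonal index is (mean_summer - mean_winter) /
mean_summer and the sexual index is (mean_female - mean_male) /
mean_female, each mean pooling the line's samples on that side
(in the four-sample design: two per side).  Positive values mean
summer-higher / female-higher.  The population envelope is the
percentile bootstrap CI of the mean of the observed indexes (1000
resamples, 95% by default); lines strictly outside the envelope are
flagged above/below.

The procedure flags divergence from the population *mean*: as the
number of lines grows at fixed dispersion the CI of the mean narrows
and the expected flagged fraction approaches one even for exchangeable
lines.  This is a property of the method, documented and pinned by a
test, not a defect of the implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_N_BOOT = 1000
DEFAULT_LEVEL = 0.95

INDEX_SIDES = {
    "season": ("season", "summer", "winter"),
    "sex": ("sex", "F", "M"),
}


@dataclass(frozen=True)
class DivergenceIndex:
    line_id: str
    index_type: str  # "season" | "sex"
    value: float  # NaN when undefined (non-positive reference mean)
    n_numerator_side: int
    n_denominator_side: int

    @property
    def defined(self) -> bool:
        return bool(np.isfinite(self.value))


@dataclass(frozen=True)
class BootstrapEnvelope:
    index_type: str
    mean: float
    ci_low: float
    ci_high: float
    n_boot: int
    level: float
    seed: int


def _line_index(
    values: pd.Series, meta: pd.DataFrame, line_id: str, index_type: str
) -> DivergenceIndex:
    column, ref_side, other_side = INDEX_SIDES[index_type]
    ref = values[meta[column] == ref_side]
    other = values[meta[column] == other_side]
    if len(ref) == 0 or len(other) == 0:
        raise ValueError(
            f"line {line_id!r} lacks samples on one {column} side"
        )
    ref_mean = float(ref.mean())
    if ref_mean <= 0:
        logger.warning(
            "line %s: non-positive %s-side mean; %s index undefined",
            line_id, ref_side, index_type,
        )
        value = float("nan")
    else:
        value = (ref_mean - float(other.mean())) / ref_mean
    return DivergenceIndex(
        line_id=line_id,
        index_type=index_type,
        value=value,
        n_numerator_side=len(ref),
        n_denominator_side=len(other),
    )


def seasonal_index(
    values: pd.Series, meta: pd.DataFrame, line_id: str = ""
) -> DivergenceIndex:
    """(mean_summer - mean_winter) / mean_summer for one line's samples.

    ``values`` are the line's expression values indexed like ``meta``
    (which provides the season label per sample, pooling both sexes).
    """
    return _line_index(values, meta, line_id, "season")


def sexual_index(
    values: pd.Series, meta: pd.DataFrame, line_id: str = ""
) -> DivergenceIndex:
    """(mean_female - mean_male) / mean_female, pooling seasons."""
    return _line_index(values, meta, line_id, "sex")


def line_indexes(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    gene: str,
    index_type: str,
) -> list[DivergenceIndex]:
    """One divergence index per line for the given gene and type."""
    if index_type not in INDEX_SIDES:
        raise ValueError(f"index_type must be one of {sorted(INDEX_SIDES)}")
    values = expression.loc[gene]
    out = []
    for line_id, meta in metadata.groupby("line_id", sort=True):
        out.append(
            _line_index(values[meta["sample_id"]].set_axis(meta.index), meta, line_id, index_type)
        )
    return out


def bootstrap_envelope(
    indexes: np.ndarray | list[float],
    n_boot: int = DEFAULT_N_BOOT,
    level: float = DEFAULT_LEVEL,
    seed: int = 0,
    index_type: str = "",
) -> BootstrapEnvelope:
    """Percentile bootstrap CI for the mean of the index vector.

    Draws ``n_boot`` resamples of the same size as the input with
    replacement, takes each resample's mean, and returns the
    (1-level)/2 and 1-(1-level)/2 empirical percentiles (linear
    interpolation).  Undefined (NaN) indexes must be excluded by the
    caller; season and sex envelopes are resampled independently.
    """
    values = np.asarray(indexes, dtype=float)
    if np.isnan(values).any():
        raise ValueError("index vector contains undefined (NaN) entries")
    if len(values) < 2:
        raise ValueError(f"need >= 2 defined indexes, got {len(values)}")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0 <= level < 1:
        raise ValueError(f"level must be in [0, 1), got {level}")
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, len(values), size=(n_boot, len(values)))
    means = values[draws].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    ci_low, ci_high = np.percentile(means, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapEnvelope(
        index_type=index_type,
        mean=float(values.mean()),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_boot=n_boot,
        level=level,
        seed=seed,
    )


def flag_divergent(
    indexes: list[DivergenceIndex], envelope: BootstrapEnvelope
) -> pd.DataFrame:
    """Flag each line above/below/within the bootstrap envelope.

    Comparisons are strict, so a line exactly on a bound counts as
    within.  Undefined indexes are reported with flag "undefined" and
    excluded from the counts of flagged lines.
    """
    rows = []
    for idx in indexes:
        if not idx.defined:
            flag = "undefined"
        elif idx.value > envelope.ci_high:
            flag = "above"
        elif idx.value < envelope.ci_low:
            flag = "below"
        else:
            flag = "within"
        rows.append(
            {
                "line_id": idx.line_id,
                "index_type": idx.index_type or envelope.index_type,
                "value": idx.value,
                "ci_low": envelope.ci_low,
                "ci_high": envelope.ci_high,
                "flag": flag,
            }
        )
    return pd.DataFrame(rows)


def summarize_flags(report: pd.DataFrame) -> dict:
    """Counts per flag and, among flagged lines, per sign.

    A flagged negative seasonal index is a "winter-higher" line; a
    flagged negative sexual index is "male-higher".
    """
    flagged = report[report["flag"].isin(["above", "below"])]
    return {
        "n_lines": int(len(report)),
        "n_undefined": int((report["flag"] == "undefined").sum()),
        "n_above": int((report["flag"] == "above").sum()),
        "n_below": int((report["flag"] == "below").sum()),
        "n_within": int((report["flag"] == "within").sum()),
        "n_flagged": int(len(flagged)),
        "n_flagged_positive": int((flagged["value"] > 0).sum()),
        "n_flagged_negative": int((flagged["value"] < 0).sum()),
    }


def divergence_analysis(
    expression: pd.DataFrame,
    metadata: pd.DataFrame,
    gene: str,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = DEFAULT_LEVEL,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Both index types end to end: indexes, envelopes, flags, summaries.

    The two index types use independent resampling streams derived from
    the seed.
    """
    reports = []
    summary = {}
    for offset, index_type in enumerate(sorted(INDEX_SIDES)):
        indexes = line_indexes(expression, metadata, gene, index_type)
        defined = [i.value for i in indexes if i.defined]
        envelope = bootstrap_envelope(
            defined, n_boot=n_boot, level=level, seed=seed + offset, index_type=index_type
        )
        report = flag_divergent(indexes, envelope)
        reports.append(report)
        summary[index_type] = {
            **summarize_flags(report),
            "mean": envelope.mean,
            "ci_low": envelope.ci_low,
            "ci_high": envelope.ci_high,
            "n_boot": n_boot,
            "level": level,
        }
    return pd.concat(reports, ignore_index=True), summary
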