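"""Synthetic data generation for the MIKK-style expression analysis.

Emulates the structure of a near-isogenic inbred panel experiment: each
line contributes one brain sample per sex x season (photoperiod) cell,
expression of a focal gene (default ``bdnf``) carries a between-line
random intercept plus season/sex fixed effects and line-specific
seasonal/sexual deviations, and sample identity can be verified against
a mostly-homozygous SNP panel with injectable sample swaps.

Expression is generated on the natural-log scale and exponentiated to a
strictly positive TPM-like scale (set ``back_transform=False`` on the
config to keep log-scale values).  All generators are deterministic for
a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

GENE = "bdnf"
SEXES = ("F", "M")
SEASONS = ("summer", "winter")

# genotype encoding used across the package: 0 = hom-ref, 1 = het, 2 = hom-alt
HOM_REF, HET, HOM_ALT = 0, 1, 2

_META_COLUMNS = [
    "sample_id",
    "line_id",
    "sex",
    "season",
    "pct_uniquely_mapped",
    "gc_content",
    "strandedness_pass",
]


@dataclass(frozen=True)
class GenerativeConfig:
    """Parameters of the generative model.

    Defaults reproduce the study conditions the analysis assumes: 25
    near-isogenic lines, one sample per sex x season cell (100 samples),
    a line random intercept explaining 30% of the log-scale variance
    (sigma_line^2 = 0.03, sigma_resid^2 = 0.07), a summer-positive
    average season effect and a null average sex effect, with
    line-specific seasonal/sexual deviations large enough that some
    lines genuinely invert the population trend.  The SNP panel defaults
    to 1377 fully homozygous exome-like SNPs read at ~30x.
    """

    n_lines: int = 25
    samples_per_cell: int = 1
    mu: float = 3.0
    sigma_line: float = 0.03**0.5
    sigma_resid: float = 0.07**0.5
    beta_season: float = 0.12
    beta_sex: float = 0.0
    sigma_line_season: float = 0.15
    sigma_line_sex: float = 0.12
    n_snps: int = 1377
    maf_profile: tuple[float, float] = (0.1, 0.9)
    het_rate: float = 0.0
    depth_mean: float = 30.0
    error_rate: float = 0.005
    swap_fraction: float = 0.0
    n_decoy_genes: int = 19
    back_transform: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lines <= 0:
            raise ValueError(f"n_lines must be positive, got {self.n_lines}")
        if self.samples_per_cell <= 0:
            raise ValueError(
                f"samples_per_cell must be positive, got {self.samples_per_cell}"
            )
        for field in ("sigma_line", "sigma_resid", "sigma_line_season", "sigma_line_sex"):
            value = getattr(self, field)
            if value < 0:
                raise ValueError(f"{field} must be >= 0, got {value}")
        if self.depth_mean <= 0:
            raise ValueError(f"depth_mean must be > 0, got {self.depth_mean}")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError(f"error_rate must be in [0, 0.5), got {self.error_rate}")
        if not 0 <= self.swap_fraction <= 1:
            raise ValueError(
                f"swap_fraction must be in [0, 1], got {self.swap_fraction}"
            )
        if not 0 <= self.het_rate <= 1:
            raise ValueError(f"het_rate must be in [0, 1], got {self.het_rate}")
        lo, hi = self.maf_profile
        if not 0 < lo <= hi < 1:
            raise ValueError(f"maf_profile must satisfy 0 < lo <= hi < 1, got {self.maf_profile}")
        if self.n_decoy_genes < 0:
            raise ValueError(f"n_decoy_genes must be >= 0, got {self.n_decoy_genes}")

    def replace(self, **kwargs) -> "GenerativeConfig":
        return dataclasses.replace(self, **kwargs)

    @property
    def expected_icc(self) -> float:
        """ICC implied by the variance components (zero fixed effects)."""
        denom = self.sigma_line**2 + self.sigma_resid**2
        return 0.0 if denom == 0 else self.sigma_line**2 / denom


def _line_ids(n_lines: int) -> list[str]:
    width = max(2, len(str(n_lines)))
    return [f"L{i:0{width}d}" for i in range(1, n_lines + 1)]


def _qc_columns(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    """Plausible clean QC metrics; tests inject failures by editing columns."""
    return {
        "pct_uniquely_mapped": np.clip(rng.normal(85.0, 3.0, n), 0.0, 100.0).round(2),
        "gc_content": rng.normal(0.47, 0.01, n).round(4),
        "strandedness_pass": np.ones(n, dtype=bool),
    }


def generate_expression(config: GenerativeConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the expression table and sample metadata.

    The focal gene follows, on the log scale,

        y = mu + b_line + beta_season * I(summer) + beta_sex * I(female)
              + g_line * I(summer) + d_line * I(female) + eps

    with b ~ N(0, sigma_line^2), g ~ N(0, sigma_line_season^2),
    d ~ N(0, sigma_line_sex^2) drawn once per line and
    eps ~ N(0, sigma_resid^2) per sample.  Decoy genes carry no line
    structure and exist so per-sample summaries (e.g. the MAD outlier
    statistic) have more than one gene to work with.

    Returns
    -------
    expression : DataFrame, genes x samples (TPM-like if back_transform)
    metadata : DataFrame, one row per sample with design and QC columns
    """
    rng = np.random.default_rng(config.seed)
    lines = _line_ids(config.n_lines)

    rows = []
    for line in lines:
        for sex in SEXES:
            for season in SEASONS:
                for rep in range(config.samples_per_cell):
                    suffix = "" if config.samples_per_cell == 1 else f"_r{rep + 1}"
                    rows.append(
                        {
                            "sample_id": f"{line}_{sex}_{season[:3]}{suffix}",
                            "line_id": line,
                            "sex": sex,
                            "season": season,
                        }
                    )
    meta = pd.DataFrame(rows)
    n = len(meta)

    b = rng.normal(0.0, config.sigma_line, config.n_lines)
    g = rng.normal(0.0, config.sigma_line_season, config.n_lines)
    d = rng.normal(0.0, config.sigma_line_sex, config.n_lines)
    eps = rng.normal(0.0, config.sigma_resid, n)

    line_index = meta["line_id"].map({l: i for i, l in enumerate(lines)}).to_numpy()
    is_summer = (meta["season"] == "summer").to_numpy()
    is_female = (meta["sex"] == "F").to_numpy()

    y = (
        config.mu
        + b[line_index]
        + config.beta_season * is_summer
        + config.beta_sex * is_female
        + g[line_index] * is_summer
        + d[line_index] * is_female
        + eps
    )

    gene_rows = {GENE: np.exp(y) if config.back_transform else y}
    for j in range(config.n_decoy_genes):
        mu_g = rng.uniform(0.5, 6.0)
        yg = mu_g + rng.normal(0.0, 0.3, n)
        gene_rows[f"decoy{j + 1:02d}"] = np.exp(yg) if config.back_transform else yg

    expression = pd.DataFrame(gene_rows, index=meta["sample_id"]).T
    expression.index.name = "gene_id"

    for col, values in _qc_columns(rng, n).items():
        meta[col] = values
    return expression, meta[_META_COLUMNS]


_REGION_CYCLE = ("exon", "exon", "exon", "intron", "intergenic")
_N_CHROMS = 24  # medaka karyotype; labels include "2" so the chr-2 filter is exercised


def generate_snp_data(
    config: GenerativeConfig, metadata: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw the SNP panel, per-sample allele counts, and the swap log.

    Each line gets a homozygous genotype per SNP (hets injected at
    ``het_rate``); chromosome labels cycle over 1..24 and regions over a
    mostly-exonic cycle so the panel selection filter has work to do.
    A ``swap_fraction`` subset of samples has its counts generated from
    a uniformly chosen *different* line; the swap log records the truth.
    """
    if config.n_snps <= 0:
        raise ValueError(f"n_snps must be positive, got {config.n_snps}")
    required = {"sample_id", "line_id"}
    if not required.issubset(metadata.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")

    lines = _line_ids(config.n_lines)
    unknown = set(metadata["line_id"]) - set(lines)
    if unknown:
        raise ValueError(f"metadata lines absent from config's panel: {sorted(unknown)}")

    rng = np.random.default_rng(config.seed + 1)
    m = config.n_snps

    lo, hi = config.maf_profile
    alt_freq = rng.uniform(lo, hi, m)
    genotypes = np.where(
        rng.random((m, config.n_lines)) < alt_freq[:, None], HOM_ALT, HOM_REF
    )
    if config.het_rate > 0:
        het_mask = rng.random((m, config.n_lines)) < config.het_rate
        genotypes = np.where(het_mask, HET, genotypes)

    panel = pd.DataFrame(
        {
            "snp_id": [f"snp{i + 1:05d}" for i in range(m)],
            "chrom": [str(i % _N_CHROMS + 1) for i in range(m)],
            "pos": np.arange(1, m + 1) * 1000,
            "region": [_REGION_CYCLE[i % len(_REGION_CYCLE)] for i in range(m)],
            "mean_depth": np.maximum(rng.gamma(10.0, config.depth_mean / 10.0, m), 0.1).round(2),
        }
    )
    for j, line in enumerate(lines):
        panel[line] = genotypes[:, j]

    sample_ids = metadata["sample_id"].to_numpy()
    assigned = metadata["line_id"].to_numpy()
    n = len(sample_ids)

    n_swaps = int(round(config.swap_fraction * n))
    swap_positions = rng.choice(n, size=n_swaps, replace=False) if n_swaps else np.array([], dtype=int)
    source = assigned.copy()
    for pos in swap_positions:
        others = [l for l in lines if l != assigned[pos]]
        source[pos] = others[rng.integers(len(others))]

    line_col = {l: j for j, l in enumerate(lines)}
    counts = []
    for i in range(n):
        geno = genotypes[:, line_col[source[i]]]
        depth = rng.poisson(config.depth_mean, m)
        p_alt = geno / 2.0
        p_read = p_alt * (1.0 - config.error_rate) + (1.0 - p_alt) * config.error_rate
        alt = rng.binomial(depth, p_read)
        counts.append(
            pd.DataFrame(
                {
                    "sample_id": sample_ids[i],
                    "snp_id": panel["snp_id"],
                    "ref_count": depth - alt,
                    "alt_count": alt,
                }
            )
        )
    allele_counts = pd.concat(counts, ignore_index=True)

    swap_log = pd.DataFrame(
        {
            "sample_id": sample_ids[swap_positions],
            "assigned_line": assigned[swap_positions],
            "true_line": source[swap_positions],
        }
    ).sort_values("sample_id", ignore_index=True)
    return panel, allele_counts, swap_log


def generate_incomplete_metadata(
    n_lines: int, complete_lines: int, seed: int
) -> pd.DataFrame:
    """Metadata where only some lines fill all four sex x season cells.

    Exactly ``complete_lines`` lines (chosen at random) carry one sample
    per cell; every other line is missing at least one cell.
    """
    if n_lines < 0 or complete_lines < 0:
        raise ValueError("counts must be non-negative")
    if complete_lines > n_lines:
        raise ValueError(
            f"complete_lines ({complete_lines}) cannot exceed n_lines ({n_lines})"
        )
    rng = np.random.default_rng(seed)
    lines = _line_ids(n_lines)
    complete = set(rng.choice(lines, size=complete_lines, replace=False)) if n_lines else set()

    cells = [(sex, season) for sex in SEXES for season in SEASONS]
    rows = []
    for line in lines:
        if line in complete:
            keep = cells
        else:
            n_missing = int(rng.integers(1, len(cells)))
            drop = set(map(tuple, rng.choice(cells, size=n_missing, replace=False)))
            keep = [c for c in cells if c not in drop]
        for sex, season in keep:
            rows.append(
                {
                    "sample_id": f"{line}_{sex}_{season[:3]}",
                    "line_id": line,
                    "sex": sex,
                    "season": season,
                }
            )
    meta = pd.DataFrame(rows, columns=["sample_id", "line_id", "sex", "season"])
    qc_rng = np.random.default_rng(seed + 1)
    for col, values in _qc_columns(qc_rng, len(meta)).items():
        meta[col] = values
    return meta
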