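"""End-to-end pipeline: inputs -> QC -> outliers -> SNP check ->
completeness -> variance partition -> divergence, with every
intermediate table written to a run directory.

Stage order is fixed (qc -> MAD outlier -> SNP identity check ->
completeness); the removal log records, per removed sample, the first
rule that fired.  Runs are fully determined by the configuration and
the seed: repeating a run reproduces byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import sample_filters, snp_check, synthetic_data
from .divergence import divergence_analysis
from .synthetic_data import GenerativeConfig
from .variance_partition import analyze_gene

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.10g"


class PipelineError(RuntimeError):
    """A stage rejected its input; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Run configuration; exactly one of ``inputs`` / ``synthetic`` is set.

    ``inputs`` maps the four table roles (expression, metadata,
    snp_panel, allele_counts) to TSV paths; ``synthetic`` holds
    GenerativeConfig field overrides.  All stage parameters default to
    the documented conventions of their modules.
    """

    inputs: dict[str, str] | None = None
    synthetic: dict | None = None
    seed: int = 0
    output_dir: str = "mikkexpr_run"
    gene: str = "bdnf"
    # snp check
    snp_threshold: float = snp_check.DEFAULT_RETENTION_THRESHOLD
    min_mean_depth: float = snp_check.DEFAULT_MIN_MEAN_DEPTH
    excluded_chroms: list[str] = field(default_factory=lambda: ["2"])
    min_site_depth: int = snp_check.DEFAULT_MIN_SITE_DEPTH
    hom_fraction: float = snp_check.DEFAULT_HOM_FRACTION
    # qc / outliers
    min_pct_uniquely_mapped: float = sample_filters.DEFAULT_MIN_PCT_UNIQUE
    gc_z_threshold: float = sample_filters.DEFAULT_GC_Z_THRESHOLD
    mad_k: float = sample_filters.DEFAULT_MAD_K
    # models
    interaction_alpha: float = 0.05
    # divergence
    n_boot: int = 1000
    level: float = 0.95

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synthetic is None):
            raise ValueError("exactly one of 'inputs' and 'synthetic' must be given")
        if not 0 <= self.level < 1:
            raise ValueError(f"level must be in [0, 1), got {self.level}")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def study_preset(**overrides) -> PipelineConfig:
    """Configuration with the study's documented defaults filled in:
    1000 bootstrap resamples at the 95% level, retention threshold
    -0.005, 50% unique-mapping cutoff, four-condition completeness."""
    base = dict(
        synthetic={},
        n_boot=1000,
        level=0.95,
        snp_threshold=-0.005,
        min_pct_uniquely_mapped=50.0,
    )
    base.update(overrides)
    return PipelineConfig(**base)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def _load_inputs(
    config: PipelineConfig, run_dir: Path
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    if config.synthetic is not None:
        gen = GenerativeConfig(**{"seed": config.seed, **config.synthetic})
        expression, metadata = synthetic_data.generate_expression(gen)
        panel, counts, swap_log = synthetic_data.generate_snp_data(gen, metadata)
        _write_tsv(expression, run_dir / "expression.tsv", index=True)
        _write_tsv(metadata, run_dir / "metadata.tsv")
        _write_tsv(panel, run_dir / "snp_panel.tsv")
        _write_tsv(counts, run_dir / "allele_counts.tsv")
        _write_tsv(swap_log, run_dir / "swap_log.tsv")
        return expression, metadata, panel, counts
    paths = config.inputs
    required = {"expression", "metadata", "snp_panel", "allele_counts"}
    missing = required - set(paths)
    if missing:
        raise PipelineError("inputs", f"missing input paths: {sorted(missing)}")
    expression = pd.read_csv(paths["expression"], sep="\t", index_col=0)
    metadata = pd.read_csv(paths["metadata"], sep="\t")
    panel = pd.read_csv(paths["snp_panel"], sep="\t", dtype={"chrom": str})
    counts = pd.read_csv(paths["allele_counts"], sep="\t")
    return expression, metadata, panel, counts


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None) -> Path:
    """Execute every stage and write all outputs into the run directory.

    Outputs: the (possibly generated) input tables, per-stage removal
    log, SNP-check report, the analysis metadata/expression tables, a
    model-comparison table (Model, Random effect, R2, AIC), the full
    model report JSON, divergence report TSV + summary JSON, and a
    manifest (config, config hash, seed, version, stage counts).
    """
    run_dir = Path(output_dir if output_dir is not None else config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    expression, metadata, panel, counts = _load_inputs(config, run_dir)
    n0 = len(metadata)
    logs = []

    # --- QC stage
    try:
        meta_qc, log_qc = sample_filters.qc_filter(
            metadata, config.min_pct_uniquely_mapped, config.gc_z_threshold
        )
    except ValueError as exc:
        raise PipelineError("qc", str(exc)) from exc
    logs.append(log_qc)

    # --- MAD outlier stage (on QC survivors)
    try:
        expr_qc = expression[meta_qc["sample_id"]]
        expr_mad, log_mad = sample_filters.mad_outlier_filter(expr_qc, config.mad_k)
    except ValueError as exc:
        raise PipelineError("mad_outlier", str(exc)) from exc
    logs.append(log_mad)
    meta_mad = meta_qc[meta_qc["sample_id"].isin(expr_mad.columns)].reset_index(drop=True)

    # --- SNP identity check
    try:
        snp_report = snp_check.run_snp_check(
            panel,
            counts[counts["sample_id"].isin(meta_mad["sample_id"])],
            meta_mad,
            threshold=config.snp_threshold,
            min_mean_depth=config.min_mean_depth,
            excluded_chroms=set(config.excluded_chroms),
            min_site_depth=config.min_site_depth,
            hom_fraction=config.hom_fraction,
        )
    except ValueError as exc:
        raise PipelineError("snp_check", str(exc)) from exc
    _write_tsv(snp_report, run_dir / "snp_check_report.tsv")
    removed_snp = snp_report.loc[~snp_report["retained"]]
    logs.append(
        pd.DataFrame(
            {
                "sample_id": removed_snp["sample_id"],
                "stage": "snp_check",
                "rule": "identity_mismatch",
                "value": removed_snp["diff"],
            }
        )
    )
    meta_snp = meta_mad[
        meta_mad["sample_id"].isin(snp_report.loc[snp_report["retained"], "sample_id"])
    ].reset_index(drop=True)

    # --- design completeness
    try:
        lines, meta_final, log_complete = sample_filters.completeness_filter(meta_snp)
    except ValueError as exc:
        raise PipelineError("completeness", str(exc)) from exc
    logs.append(log_complete)
    non_empty = [l for l in logs if not l.empty]
    removal_log = (
        pd.concat(non_empty, ignore_index=True) if non_empty else logs[0].iloc[0:0]
    )
    _write_tsv(removal_log, run_dir / "removal_log.tsv")
    _write_tsv(meta_final, run_dir / "metadata_analysis.tsv")
    expr_final = expression[meta_final["sample_id"]]
    _write_tsv(expr_final, run_dir / "expression_analysis.tsv", index=True)

    if meta_final.empty:
        raise PipelineError("completeness", "analysis set is empty: no complete line")

    # --- variance partition
    try:
        model = analyze_gene(
            expr_final, meta_final, gene=config.gene,
            interaction_alpha=config.interaction_alpha,
        )
    except ValueError as exc:
        raise PipelineError("variance_partition", str(exc)) from exc
    comparison = pd.DataFrame(
        [
            {
                "Model": "Linear model",
                "Random effect": "None",
                "R2": round(model["r2_multiple"], 4),
                "AIC": round(model["aic_linear"], 4),
            },
            {
                "Model": "Linear mixed-effects model",
                "Random effect": "Medaka line",
                "R2": round(model["r2_conditional"], 4),
                "AIC": round(model["aic_mixed"], 4),
            },
        ]
    )
    _write_tsv(comparison, run_dir / "model_comparison.tsv")
    model_json = {
        "gene": model["gene"],
        "interaction_p": model["interaction_p"],
        "interaction_kept": model["interaction_kept"],
        "r2_multiple": model["r2_multiple"],
        "r2_marginal": model["r2_marginal"],
        "r2_conditional": model["r2_conditional"],
        "icc": model["icc"],
        "sigma2_line": model["mixed_reml"].sigma2_line,
        "sigma2_resid": model["mixed_reml"].sigma2_resid,
        "aic_linear": model["aic_linear"],
        "aic_mixed": model["aic_mixed"],
        "loglik_linear_ml": model["linear"].loglik,
        "loglik_mixed_ml": model["mixed_ml"].loglik,
        "lrt": model["lrt"],
        "coefficients": {
            name: {"estimate": float(model["mixed_reml"].beta[name]),
                   "se": float(model["mixed_reml"].bse[name])}
            for name in model["mixed_reml"].exog_names
        },
        "terms": model["terms"].to_dict(orient="records"),
    }
    (run_dir / "model_report.json").write_text(json.dumps(model_json, indent=2, sort_keys=True))

    # --- divergence
    try:
        div_report, div_summary = divergence_analysis(
            expr_final, meta_final, config.gene,
            n_boot=config.n_boot, level=config.level, seed=config.seed,
        )
    except ValueError as exc:
        raise PipelineError("divergence", str(exc)) from exc
    _write_tsv(div_report, run_dir / "divergence_report.tsv")
    (run_dir / "divergence_summary.json").write_text(
        json.dumps(div_summary, indent=2, sort_keys=True)
    )

    config_dict = config.to_dict()
    config_blob = json.dumps(config_dict, sort_keys=True)
    manifest = {
        "package": "mikkexpr",
        "version": __version__,
        "seed": config.seed,
        "config": config_dict,
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "counts": {
            "input_samples": n0,
            "after_qc": len(meta_qc),
            "after_mad": len(meta_mad),
            "after_snp_check": len(meta_snp),
            "analysis_lines": len(lines),
            "analysis_samples": len(meta_final),
        },
    }
    (run_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return run_dir


def _per_line_summary(expression: pd.DataFrame, metadata: pd.DataFrame, gene: str) -> pd.DataFrame:
    values = expression.loc[gene, metadata["sample_id"]]
    df = pd.DataFrame(
        {"line_id": metadata["line_id"].to_numpy(), "value": values.to_numpy()}
    )
    summary = (
        df.groupby("line_id")["value"]
        .agg(median="median", mean="mean", min="min", max="max", n="size")
        .reset_index()
        .sort_values(["median", "line_id"], kind="mergesort", ignore_index=True)
    )
    return summary


def report_summaries(run_dir: str | Path, figures: bool = True) -> dict[str, Path]:
    """Render the per-line, per-season/sex and divergence summaries.

    Tables are always written as TSV; figures (per-line boxplot ordered
    by median expression, divergence dot plots with CI band) are
    optional so the numeric outputs never depend on a display stack.
    """
    run_dir = Path(run_dir)
    needed = {
        "expression": run_dir / "expression_analysis.tsv",
        "metadata": run_dir / "metadata_analysis.tsv",
        "divergence": run_dir / "divergence_report.tsv",
        "manifest": run_dir / "manifest.json",
    }
    for stage, path in needed.items():
        if not path.exists():
            raise PipelineError("report", f"missing output of stage {stage!r}: {path.name}")
    expression = pd.read_csv(needed["expression"], sep="\t", index_col=0)
    metadata = pd.read_csv(needed["metadata"], sep="\t")
    divergence = pd.read_csv(needed["divergence"], sep="\t")
    gene = json.loads((run_dir / "manifest.json").read_text())["config"]["gene"]

    outputs: dict[str, Path] = {}
    line_summary = _per_line_summary(expression, metadata, gene)
    outputs["line_summary"] = run_dir / "line_summary.tsv"
    _write_tsv(line_summary, outputs["line_summary"])

    values = expression.loc[gene, metadata["sample_id"]].to_numpy()
    panel_rows = []
    for factor in ("season", "sex"):
        for level_name, group in metadata.groupby(factor):
            sel = values[(metadata[factor] == level_name).to_numpy()]
            panel_rows.append(
                {
                    "factor": factor,
                    "level": level_name,
                    "mean": sel.mean(),
                    "median": float(pd.Series(sel).median()),
                    "n": len(sel),
                }
            )
    outputs["condition_summary"] = run_dir / "condition_summary.tsv"
    _write_tsv(pd.DataFrame(panel_rows), outputs["condition_summary"])

    if figures:
        outputs.update(_render_figures(run_dir, expression, metadata, divergence, gene, line_summary))
    return outputs


def _render_figures(run_dir, expression, metadata, divergence, gene, line_summary):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outputs = {}
    order = line_summary["line_id"].tolist()
    values = expression.loc[gene, metadata["sample_id"]]
    by_line = {
        line: values[(metadata["line_id"] == line).to_numpy()].to_numpy()
        for line in order
    }
    fig, ax = plt.subplots(figsize=(max(6, 0.35 * len(order)), 4))
    ax.boxplot([by_line[line] for line in order], tick_labels=order)
    ax.set_xlabel("line (ordered by median expression)")
    ax.set_ylabel(f"{gene} expression (TPM)")
    ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    outputs["line_boxplot"] = run_dir / "line_expression.png"
    fig.savefig(outputs["line_boxplot"], dpi=120)
    plt.close(fig)

    for index_type, sub in divergence.groupby("index_type"):
        sub = sub.sort_values("value", ignore_index=True)
        fig, ax = plt.subplots(figsize=(max(6, 0.3 * len(sub)), 4))
        ax.axhline(sub["ci_low"].iloc[0], color="black", lw=1)
        ax.axhline(sub["ci_high"].iloc[0], color="black", lw=1)
        colors = sub["flag"].map(
            {"above": "tab:red", "below": "tab:blue", "within": "tab:gray"}
        ).fillna("black")
        ax.scatter(range(len(sub)), sub["value"], c=colors)
        ax.set_xticks(range(len(sub)))
        ax.set_xticklabels(sub["line_id"], rotation=90)
        ax.set_ylabel(f"{index_type} divergence index")
        fig.tight_layout()
        key = f"divergence_{index_type}"
        outputs[key] = run_dir / f"divergence_{index_type}.png"
        fig.savefig(outputs[key], dpi=120)
        plt.close(fig)
    return outputs
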