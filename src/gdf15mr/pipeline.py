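"""Orchestrate the full MR analysis across outcomes, plus the CLI.

Instrument selection runs once on the exposure study; harmonization and
estimation run per outcome.  Outcomes are isolated: a failure in one (e.g.
no shared SNPs) marks that row failed and the run continues.  The headline
(forest-plot) estimate per outcome is IVW.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .estimators import (
    EstimationError,
    MRResult,
    ivw,
    mr_egger,
    wald_ratio,
    weighted_median,
)
from .harmonize import HarmonizationError, harmonize_sets
from .instruments import select_instruments, SelectionReport
from .sumstats_io import (
    read_exclusion_list,
    read_ld_matrix,
    read_sumstats,
    write_ld_matrix,
    write_results_table,
    write_sumstats,
)
from .synthgwas import SimulationConfig, gdf15_fixture, simulate_pair

logger = logging.getLogger("gdf15mr")


@dataclass
class AnalysisConfig:
    """Everything one multi-outcome MR run needs."""

    exposure_path: str
    outcome_paths: dict[str, str]  # label -> path, order = report order
    ld_path: str
    exclusion_path: str | None = None
    p_threshold: float = 5e-8
    r2_threshold: float = 0.8
    wald_order: str = "first"
    ivw_model: str = "fixed"
    palindrome_policy: str = "frequency"
    n_boot: int = 1000
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if not self.outcome_paths:
            raise ValueError("at least one outcome is required")
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        if not 0 <= self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in [0, 1]")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass(frozen=True)
class ForestRow:
    """One forest-plot line: an outcome's headline OR with its 95% CI."""

    outcome: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    pval: float
    method: str = "IVW"

    def __post_init__(self) -> None:
        if not self.ci_low < self.ci_high:
            raise ValueError(f"{self.outcome}: CI bounds out of order")


@dataclass
class MRRunResult:
    """Everything `run_mr` produced for one configuration."""

    results: dict[str, dict[str, MRResult]]
    selection_report: SelectionReport
    harmonization_reports: dict[str, pd.DataFrame]
    forest_rows: list[ForestRow]
    failed_outcomes: dict[str, str] = field(default_factory=dict)


def analyze_outcome(
    instruments_stats,
    outcome_stats,
    wald_order: str = "first",
    ivw_model: str = "fixed",
    palindrome_policy: str = "frequency",
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, MRResult], pd.DataFrame]:
    """Harmonize one outcome against the selected instruments and run all
    applicable estimators.  With fewer than 3 harmonized instruments only IVW
    is reported (sensitivity methods need >= 3)."""
    harmonized, report = harmonize_sets(
        instruments_stats, outcome_stats, palindrome_policy
    )
    if not harmonized:
        raise HarmonizationError(
            f"no instruments survive harmonization for {outcome_stats.trait_name!r}"
        )
    ratios = [wald_ratio(h, order=wald_order) for h in harmonized]
    by_method: dict[str, MRResult] = {"IVW": ivw(ratios, model=ivw_model)}
    if len(harmonized) >= 3:
        by_method["weighted_median"] = weighted_median(ratios, n_boot=n_boot, seed=seed)
        by_method["MR_Egger"] = mr_egger(harmonized)
    return by_method, report


def run_mr(
    config: AnalysisConfig,
    exposure=None,
    outcomes=None,
    ld=None,
    exclude: list[str] | None = None,
) -> MRRunResult:
    """Run the full analysis described by ``config``.

    Inputs may be passed as in-memory objects (``exposure``, ``outcomes`` as
    a label->SummaryStatsSet mapping, ``ld``, ``exclude``); anything not
    supplied is read from the paths in ``config``.
    """
    if exposure is None:
        exposure, n_rej = read_sumstats(
            config.exposure_path, trait_name="exposure", trait_type="continuous"
        )
        if n_rej:
            logger.warning("exposure: %d row(s) rejected at read time", n_rej)
    if ld is None:
        ld = read_ld_matrix(config.ld_path)
    if exclude is None:
        exclude = (
            read_exclusion_list(config.exclusion_path) if config.exclusion_path else []
        )
    if outcomes is None:
        outcomes = {}
        for label, path in config.outcome_paths.items():
            outcomes[label], _ = read_sumstats(path, trait_name=label)

    instruments_stats, selection = select_instruments(
        exposure,
        ld,
        p_threshold=config.p_threshold,
        r2_threshold=config.r2_threshold,
        exclude=exclude,
    )
    logger.info(
        "selection: %d/%d instruments kept (%d p-value, %d LD, %d excluded)",
        len(selection.kept), selection.n_input, len(selection.dropped_pvalue),
        len(selection.dropped_ld), len(selection.dropped_excluded),
    )

    rng = np.random.default_rng(config.seed)
    results: dict[str, dict[str, MRResult]] = {}
    harmonization_reports: dict[str, pd.DataFrame] = {}
    forest_rows: list[ForestRow] = []
    failed: dict[str, str] = {}
    for label in config.outcome_paths if outcomes is None else outcomes:
        try:
            by_method, hreport = analyze_outcome(
                instruments_stats,
                outcomes[label],
                wald_order=config.wald_order,
                ivw_model=config.ivw_model,
                palindrome_policy=config.palindrome_policy,
                n_boot=config.n_boot,
                seed=rng,
            )
        except (HarmonizationError, EstimationError) as exc:
            logger.warning("outcome %s failed: %s", label, exc)
            failed[label] = str(exc)
            continue
        results[label] = by_method
        harmonization_reports[label] = hreport
        head = by_method["IVW"]
        forest_rows.append(
            ForestRow(
                outcome=label,
                odds_ratio=head.odds_ratio,
                ci_low=head.ci_low,
                ci_high=head.ci_high,
                pval=head.pval,
            )
        )
        logger.info(
            "%s: %d instruments, IVW OR %.3f (p %.3g)",
            label, head.n_snps, head.odds_ratio, head.pval,
        )
    return MRRunResult(
        results=results,
        selection_report=selection,
        harmonization_reports=harmonization_reports,
        forest_rows=forest_rows,
        failed_outcomes=failed,
    )


def forest_frame(rows: list[ForestRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "outcome": r.outcome,
                "odds_ratio": f"{r.odds_ratio:.3f}",
                "ci_low": f"{r.ci_low:.3f}",
                "ci_high": f"{r.ci_high:.3f}",
                "pval": f"{r.pval:.3f}",
                "method": r.method,
            }
            for r in rows
        ],
        columns=["outcome", "odds_ratio", "ci_low", "ci_high", "pval", "method"],
    )


def write_run_outputs(run: MRRunResult, config: AnalysisConfig) -> dict[str, Path]:
    """Serialize the grid, reports, forest rows and a run manifest."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "results": outdir / "mr_results.tsv",
        "forest": outdir / "forest_rows.tsv",
        "selection": outdir / "selection_report.tsv",
        "manifest": outdir / "run_manifest.json",
    }
    write_results_table(run.results, paths["results"])
    forest_frame(run.forest_rows).to_csv(paths["forest"], sep="\t", index=False)
    run.selection_report.write(paths["selection"])
    for label, rep in run.harmonization_reports.items():
        rep.to_csv(outdir / f"harmonization_{label}.tsv", sep="\t", index=False)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "p_threshold": config.p_threshold,
        "r2_threshold": config.r2_threshold,
        "wald_order": config.wald_order,
        "ivw_model": config.ivw_model,
        "n_boot": config.n_boot,
        "outcomes": list(config.outcome_paths),
        "failed_outcomes": run.failed_outcomes,
        "multiple_testing_correction": "none",
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths


# ---------------------------------------------------------------- CLI


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Log at DEBUG level.")
def cli(verbose: bool) -> None:
    """Two-sample Mendelian randomization from GWAS summary statistics."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), default=None,
              help="YAML/JSON SimulationConfig; defaults used if omitted.")
@click.option("--seed", type=int, default=None, help="Override the config seed.")
@click.option("--out", "outdir", type=click.Path(), required=True)
def simulate(config_path, seed, outdir) -> None:
    """Generate a synthetic exposure/outcome pair with its truth record."""
    raw = {}
    if config_path:
        with open(config_path) as fh:
            raw = yaml.safe_load(fh) or {}
    if seed is not None:
        raw["seed"] = seed
    for key in ("gamma_range", "se_x_range", "se_y_range", "eaf_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    cfg = SimulationConfig(**raw)
    exposure, outcome, truth = simulate_pair(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_sumstats(exposure, outdir / "exposure.tsv")
    write_sumstats(outcome, outdir / "outcome.tsv")
    truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    click.echo(f"wrote {cfg.n_snps}-SNP pair to {outdir}")


@cli.command()
@click.option("--exposure", "exposure_path", type=click.Path(exists=True), required=True)
@click.option("--ld", "ld_path", type=click.Path(exists=True), required=True)
@click.option("--exclude", "exclusion_path", type=click.Path(exists=True), default=None)
@click.option("--p-threshold", type=float, default=5e-8, show_default=True)
@click.option("--r2-threshold", type=float, default=0.8, show_default=True)
@click.option("--out", "out_path", type=click.Path(), required=True)
def select(exposure_path, ld_path, exclusion_path, p_threshold, r2_threshold, out_path):
    """Run instrument selection and write the selection report."""
    exposure, _ = read_sumstats(exposure_path, trait_type="continuous")
    ld = read_ld_matrix(ld_path)
    exclude = read_exclusion_list(exclusion_path) if exclusion_path else []
    kept, report = select_instruments(
        exposure, ld, p_threshold=p_threshold, r2_threshold=r2_threshold,
        exclude=exclude,
    )
    report.write(out_path)
    click.echo(f"kept {len(kept)}/{report.n_input} instruments -> {out_path}")


@cli.command()
@click.option("--config", "config_path", type=click.Path(exists=True), required=True)
@click.option("--seed", type=int, default=None, help="Override the config seed.")
@click.option("--out", "outdir", type=click.Path(), default=None,
              help="Override the config output_dir.")
def analyze(config_path, seed, outdir) -> None:
    """Run the full multi-outcome MR analysis from a YAML config."""
    config = AnalysisConfig.from_file(config_path)
    if seed is not None:
        config.seed = seed
    if outdir is not None:
        config.output_dir = outdir
    run = run_mr(config)
    paths = write_run_outputs(run, config)
    click.echo(f"results grid -> {paths['results']}")
    if run.failed_outcomes:
        click.echo(f"failed outcomes: {', '.join(run.failed_outcomes)}", err=True)


@cli.command()
@click.option("--out", "outdir", type=click.Path(), required=True)
def fixture(outdir) -> None:
    """Emit the nine-SNP GDF-15 candidate fixture (synthetic numerics)."""
    exposure, ld, outcomes = gdf15_fixture()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_sumstats(exposure, outdir / "exposure_gdf15.tsv")
    write_ld_matrix(ld, outdir / "ld.tsv")
    for label, stats in outcomes.items():
        write_sumstats(stats, outdir / f"outcome_{label}.tsv")
    click.echo(f"fixture written to {outdir}")


if __name__ == "__main__":
    cli()
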