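"""End-to-end screen pipeline: score blots, filter on growth, call
phenotypes, run enrichment and (optionally) FCOP concordance.

The stage order is fixed — growth QC runs before phenotype calling so that
apparent phenotypes driven by poor growth or lysis never enter the call
set — and every exclusion is written to an audit file, so the tested strain
list partitions exactly into growth-excluded + replicate-rejected + called.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import blot, calls, enrichment, growth
from .io import PipelineConfig, read_table, write_table

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    scores: pd.DataFrame
    rejects: pd.DataFrame
    growth_status: pd.DataFrame
    calls: pd.DataFrame
    summary: dict
    enrichment: pd.DataFrame | None = None
    concordance: enrichment.ConcordanceResult | None = None
    fcop_values: pd.DataFrame | None = None


def _stage(name: str):
    logger.info("[%s] starting", name)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis on the tables named in ``config``.

    Reads the blot and growth tables (both mandatory), and the annotation
    and FCOP tables when configured.  Writes scores, growth status, calls,
    audit files and a summary JSON into ``config.out_dir``.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    _stage("blot_quant")
    measurements = read_table(config.blot, "blot")
    scores, rejects = blot.score_strains(
        measurements, min_replicates=config.min_replicates,
        log_average=config.log_average)
    tested = sorted(measurements["strain"].unique())

    _stage("growth_qc")
    curves = read_table(config.growth, "growth")
    fits = growth.fit_growth_table(curves, log_od=config.log_od)
    status = growth.classify_growth(fits, r2_min=config.r2_min,
                                    n_sd=config.n_sd_growth,
                                    pooled=config.pooled_rates)
    passed = set(status.loc[status["passed"], "strain"])
    # Tested strains with no growth data at all cannot pass the mandatory
    # growth filter; they are audited as growth-excluded.
    no_growth = sorted(set(tested) - set(status["strain"]))
    if no_growth:
        logger.warning("%d tested strains have no growth curves; excluded",
                       len(no_growth))
        status = pd.concat([status, pd.DataFrame({
            "strain": no_growth, "mean_rate": float("nan"),
            "n_usable_trials": 0, "passed": False,
            "reason": "no_growth_data"})], ignore_index=True)

    _stage("phenotype_call")
    scores_pass = scores[scores["strain"].isin(passed)].reset_index(drop=True)
    call_table, call_summary = calls.call_phenotypes(
        scores_pass, passed, n_sd=config.n_sd_call)
    mean_cv = blot.collection_cv_summary(scores_pass)

    excluded = status[~status["passed"] & status["strain"].isin(tested)]
    rejects_pass = rejects[rejects["strain"].isin(passed)]
    summary = {
        "n_strains_tested": len(tested),
        "n_growth_excluded": int(len(excluded)),
        "n_growth_passing": int(len(set(tested) & passed)),
        "n_replicate_rejected": int(len(rejects_pass)),
        "n_scored": int(len(scores_pass)),
        "mean_log10_score": call_summary["mean"],
        "sd_log10_score": call_summary["sd"],
        "cutoff_low": call_summary["cutoff_low"],
        "cutoff_high": call_summary["cutoff_high"],
        "n_over": call_summary["n_over"],
        "n_under": call_summary["n_under"],
        "n_significant": call_summary["n_total_significant"],
        "mean_cv": mean_cv,
    }

    result = PipelineResult(scores=scores, rejects=rejects,
                            growth_status=status, calls=call_table,
                            summary=summary)

    if config.annotation is not None:
        _stage("enrichment_stats")
        annotation = read_table(config.annotation, "annotation")
        ann = enrichment.AnnotationSet.from_frame(annotation, set(tested))
        significant = set(
            call_table.loc[call_table["call"] != "normal", "strain"])
        result.enrichment = enrichment.enrich_categories(
            significant, ann, alpha=config.alpha)
        summary["n_enriched_categories"] = int(
            result.enrichment["enriched"].sum()) if len(result.enrichment) \
            else 0

    if config.fcop is not None:
        _stage("concordance")
        fcop_df = read_table(config.fcop, "fcop")
        values = enrichment.fcop_vesiculation(fcop_df, config.wt_label)
        result.fcop_values = values
        htp = scores.set_index("strain")["log10_score"]
        fcop_series = values[values["strain"] != config.wt_label] \
            .set_index("strain")["fcop_value"]
        result.concordance = enrichment.method_concordance(
            htp, fcop_series, method=config.correlation)
        summary["concordance_r"] = result.concordance.correlation
        summary["concordance_p"] = result.concordance.p_value
        summary["fcop_sign_agree"] = result.concordance.sign_agree
        summary["fcop_sign_total"] = result.concordance.sign_total

    _write_outputs(result, config, out_dir)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig,
                   out_dir: Path) -> None:
    write_table(result.scores, out_dir / "scores.tsv")
    write_table(result.rejects, out_dir / "replicate_rejects.tsv")
    write_table(result.growth_status, out_dir / "growth_status.tsv")
    write_table(result.growth_status[~result.growth_status["passed"]],
                out_dir / "growth_excluded.tsv")
    write_table(result.calls, out_dir / "calls.tsv")
    if result.enrichment is not None:
        write_table(result.enrichment, out_dir / "enrichment.tsv")
    if result.fcop_values is not None:
        write_table(result.fcop_values, out_dir / "fcop_values.tsv")
    (out_dir / "summary.json").write_text(
        json.dumps(result.summary, indent=2, sort_keys=True) + "\n")
    if config.histogram:
        plot_score_histogram(
            result.calls, out_dir / "score_histogram.png")
    logger.info("outputs written to %s", out_dir)


def audit_partition(result: PipelineResult) -> dict[str, set[str]]:
    """Partition of the tested strain list implied by the audit trail.

    Returns the three disjoint sets whose union is the tested strains:
    growth-excluded, replicate-rejected (among growth-passing) and called.
    """
    excluded = set(result.growth_status.loc[
        ~result.growth_status["passed"], "strain"])
    called = set(result.calls["strain"])
    rejected = set(result.rejects["strain"]) - excluded
    return {"growth_excluded": excluded, "replicate_rejected": rejected,
            "called": called}


def plot_score_histogram(call_table: pd.DataFrame, path) -> None:
    """Histogram of log10 vesiculation scores with the call cutoffs drawn
    as dashed lines (the screen's headline distribution figure)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(call_table["log10_score"], bins=60, color="#4878a8")
    for cut in (call_table["cutoff_low"].iloc[0],
                call_table["cutoff_high"].iloc[0]):
        ax.axvline(cut, linestyle="--", color="black")
    ax.set_xlabel("log10 vesiculation score")
    ax.set_ylabel("strains")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
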