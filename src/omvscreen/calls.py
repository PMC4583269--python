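"""Phenotype calling by a two-standard-deviation rule.

The collection of log10 vesiculation scores of growth-passing strains is
approximately normal; a strain is called over-vesiculating when its score is
strictly above mean + 2 sd of the collection, under-vesiculating strictly
below mean - 2 sd, and normal otherwise.  Scores exactly on a cutoff are
normal (the rule is "greater than / less than").
"""

from __future__ import annotations

import logging
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class Cutoffs(NamedTuple):
    mean: float
    sd: float
    low: float
    high: float


def compute_cutoffs(scores, n_sd: float = 2.0) -> Cutoffs:
    """Collection mean, sample sd and the mean +/- n_sd*sd call cutoffs.

    ``scores`` are the log10 vesiculation scores of the strains the
    collection statistics should be computed on (by convention the
    growth-passing set).  Requires at least 3 scores with positive spread.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.ndim != 1 or len(arr) < 3:
        raise ValueError("need at least 3 scores to compute cutoffs")
    if n_sd < 0:
        raise ValueError("n_sd must be nonnegative")
    m = float(arr.mean())
    s = float(np.std(arr, ddof=1))
    if s == 0.0:
        raise ValueError("score collection is degenerate (zero sd)")
    return Cutoffs(m, s, m - n_sd * s, m + n_sd * s)


def call_phenotypes(scores: pd.DataFrame, passed_strains: Iterable[str],
                    n_sd: float = 2.0, cutoffs: Cutoffs | None = None
                    ) -> tuple[pd.DataFrame, dict]:
    """Classify each growth-passing strain as over / under / normal.

    ``scores`` is the vesiculation score table (restricted upstream to
    strains that passed growth QC — a scored strain missing from
    ``passed_strains`` is a pipeline-ordering error).  Cutoffs default to
    mean +/- ``n_sd`` sample sd of the supplied scores; precomputed cutoffs
    (e.g. from a larger collection) can be passed instead.

    Returns the per-strain call table (strain, log10_score, call,
    cutoff_low, cutoff_high) and a summary dict with the collection mean,
    sd, cutoffs and call counts.
    """
    passed = set(passed_strains)
    stray = set(scores["strain"]) - passed
    if stray:
        raise ValueError(
            "scores contain strains that did not pass growth QC "
            f"(pipeline ordering violated): {sorted(stray)[:5]}")

    if cutoffs is None:
        cutoffs = compute_cutoffs(scores["log10_score"].to_numpy(), n_sd=n_sd)

    s = scores["log10_score"].to_numpy()
    call = np.where(s > cutoffs.high, "over",
                    np.where(s < cutoffs.low, "under", "normal"))
    out = pd.DataFrame({
        "strain": scores["strain"].to_numpy(),
        "log10_score": s,
        "call": call,
        "cutoff_low": cutoffs.low,
        "cutoff_high": cutoffs.high,
    })
    n_over = int((call == "over").sum())
    n_under = int((call == "under").sum())
    summary = {
        "mean": cutoffs.mean, "sd": cutoffs.sd,
        "cutoff_low": cutoffs.low, "cutoff_high": cutoffs.high,
        "n_over": n_over, "n_under": n_under,
        "n_normal": int((call == "normal").sum()),
        "n_total_significant": n_over + n_under,
    }
    logger.info("phenotype calls: %d over, %d under, %d normal",
                n_over, n_under, summary["n_normal"])
    return out, summary
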