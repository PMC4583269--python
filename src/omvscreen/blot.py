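"""Dot-blot densitometry scoring.

Raw per-well intensities are normalized to the mean of their membrane
(removing day-to-day blotting scale), replicates are averaged on the linear
scale, and the per-strain score is the log10 of that mean.  The coefficient
of variation of the unlogged normalized replicates is kept as a
replicate-reproducibility metric.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

BLOT_COLUMNS = ("strain", "membrane_id", "replicate", "raw_intensity")


def normalize_membrane(intensities) -> np.ndarray:
    """Normalize one membrane's raw intensities to its mean.

    Nonpositive wells (background-subtraction artifacts) are excluded from
    the mean and returned as NaN; the mean over the included wells of the
    output is exactly 1.  Raises if no well on the membrane is positive.
    """
    raw = np.asarray(intensities, dtype=float)
    ok = raw > 0
    if not ok.any():
        raise ValueError("membrane has no positive intensities")
    out = np.full(raw.shape, np.nan)
    out[ok] = raw[ok] / raw[ok].mean()
    return out


def score_strains(measurements: pd.DataFrame, min_replicates: int = 2,
                  log_average: bool = False
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Turn raw blot measurements into per-strain vesiculation scores.

    Normalizes each membrane to its mean, then aggregates per strain:
    ``mean_linear`` is the arithmetic mean of the normalized replicate
    values, ``log10_score`` its log10 (or, with ``log_average=True``, the
    mean of per-replicate log10 values), and ``cv`` the sample sd/mean of
    the unlogged normalized replicates.  Strains with fewer than
    ``min_replicates`` usable values go to a rejects table instead.

    Returns ``(scores, rejects)``; scores has columns strain, n_replicates,
    mean_linear, log10_score, cv and rejects has strain, n_replicates,
    reason.
    """
    missing = set(BLOT_COLUMNS) - set(measurements.columns)
    if missing:
        raise ValueError(f"blot table missing columns: {sorted(missing)}")
    dup = measurements.duplicated(subset=["strain", "membrane_id", "replicate"])
    if dup.any():
        first = measurements[dup].iloc[0]
        raise ValueError(
            "duplicate measurement for strain "
            f"{first['strain']!r} on membrane {first['membrane_id']!r} "
            f"replicate {first['replicate']}")

    df = measurements.copy()
    df["norm"] = np.nan
    for membrane, idx in df.groupby("membrane_id").groups.items():
        raw = df.loc[idx, "raw_intensity"]
        try:
            df.loc[idx, "norm"] = normalize_membrane(raw)
        except ValueError as exc:
            raise ValueError(f"membrane {membrane!r}: {exc}") from None
    n_dropped = int(df["norm"].isna().sum())
    if n_dropped:
        logger.warning("%d nonpositive wells excluded from normalization",
                       n_dropped)

    scores, rejects = [], []
    for strain, grp in df.groupby("strain", sort=True):
        vals = grp["norm"].dropna().to_numpy()
        if len(vals) < min_replicates:
            rejects.append({"strain": strain, "n_replicates": len(vals),
                            "reason": "insufficient replicates"})
            continue
        mean_linear = float(vals.mean())
        log10_score = float(np.log10(vals).mean()) if log_average \
            else float(np.log10(mean_linear))
        cv = float(np.std(vals, ddof=1) / mean_linear)
        scores.append({"strain": strain, "n_replicates": len(vals),
                       "mean_linear": mean_linear, "log10_score": log10_score,
                       "cv": cv})
    score_cols = ["strain", "n_replicates", "mean_linear", "log10_score", "cv"]
    reject_cols = ["strain", "n_replicates", "reason"]
    return (pd.DataFrame(scores, columns=score_cols),
            pd.DataFrame(rejects, columns=reject_cols))


def collection_cv_summary(scores: pd.DataFrame,
                          include: set[str] | None = None) -> float:
    """Mean replicate CV over the included strains (all strains by default)."""
    if include is not None:
        sub = scores[scores["strain"].isin(include)]
    else:
        sub = scores
    if len(sub) == 0:
        raise ValueError("no strains included in CV summary")
    return float(sub["cv"].mean())
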