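"""Hypergeometric enrichment, FCOP normalization and method concordance.

The enrichment unit is a flat annotation category (a named gene set, GO
style).  For a significant set of n genes drawn from a universe of N, a
category with K members and k of them significant is scored with the exact
upper-tail hypergeometric probability P(X >= k), computed in log space.
The same tail probability measures overlap between two gene lists against a
common universe.  The orthogonal flask-culture assay (FCOP) is normalized
as fluorescence/CFU relative to wild type, and concordance between the two
assays is summarized by a correlation on log scores plus a direction
(sign) agreement count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import pearsonr, spearmanr

logger = logging.getLogger(__name__)


@dataclass
class AnnotationSet:
    """Flat category -> gene-set annotation over a gene universe.

    Category genes outside the universe are dropped at construction with a
    logged count.
    """

    categories: dict[str, set[str]]
    universe: set[str]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        dropped = 0
        for cid, genes in self.categories.items():
            inside = genes & self.universe
            dropped += len(genes) - len(inside)
            self.categories[cid] = inside
        if dropped:
            logger.warning("%d category-gene memberships outside the "
                           "universe were dropped", dropped)

    @classmethod
    def from_frame(cls, annotation: pd.DataFrame,
                   universe: set[str]) -> "AnnotationSet":
        """Build from a long table with columns category_id, category_name,
        gene (one row per membership)."""
        required = {"category_id", "category_name", "gene"}
        missing = required - set(annotation.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        cats: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for row in annotation.itertuples(index=False):
            cats.setdefault(row.category_id, set()).add(row.gene)
            names.setdefault(row.category_id, row.category_name)
        return cls(categories=cats, universe=set(universe), names=names)


def hypergeom_upper_tail(N: int, K: int, n: int, k):
    """Exact upper-tail hypergeometric probability P(X >= k).

    X counts category members among n draws without replacement from a
    universe of N genes containing K category members.  The tail is an
    exact sum of the mass function accumulated in log space (log-gamma
    binomial coefficients + cumulative logaddexp) for numerical stability
    far into the tail.  ``k`` may be a scalar or an integer array.
    """
    N, K, n = int(N), int(K), int(n)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= K <= N and 0 <= n <= N, "
                         f"got N={N}, K={K}, n={n}")
    k_arr = np.atleast_1d(np.asarray(k, dtype=int))
    hi = min(K, n)
    lo = max(0, n - (N - K))
    if np.any(k_arr < 0) or np.any(k_arr > hi):
        raise ValueError(f"k must lie in [0, min(K, n)] = [0, {hi}]")

    j = np.arange(lo, hi + 1)
    log_pmf = (gammaln(K + 1) - gammaln(j + 1) - gammaln(K - j + 1)
               + gammaln(N - K + 1) - gammaln(n - j + 1)
               - gammaln(N - K - n + j + 1)
               - (gammaln(N + 1) - gammaln(n + 1) - gammaln(N - n + 1)))
    log_tail = np.logaddexp.accumulate(log_pmf[::-1])[::-1]

    p = np.empty(k_arr.shape, dtype=float)
    below = k_arr <= lo
    p[below] = 1.0  # whole support, exactly
    idx = np.clip(k_arr, lo, hi) - lo
    p[~below] = np.minimum(np.exp(log_tail[idx[~below]]), 1.0)
    return float(p[0]) if np.isscalar(k) or np.ndim(k) == 0 else p


def enrich_categories(significant: set[str], annotation: AnnotationSet,
                      alpha: float = 0.05,
                      max_jaccard: float | None = None) -> pd.DataFrame:
    """Hypergeometric enrichment of every annotation category.

    Significant genes outside the universe are dropped with a warning.
    Returns one row per nonempty category (category_id, category_name, N,
    K, n, k, p, enriched) sorted by ascending p; no multiplicity correction
    is applied (raw p <= alpha flags enrichment, mirroring a plain
    hypergeometric screen).  An empty significant set yields an empty
    table.  With ``max_jaccard`` set, a category whose gene-set Jaccard
    overlap with a more significant kept category exceeds the threshold is
    dropped as redundant.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    sig = set(significant) & annotation.universe
    outside = len(set(significant)) - len(sig)
    if outside:
        logger.warning("%d significant genes outside the universe dropped",
                       outside)
    cols = ["category_id", "category_name", "N", "K", "n", "k", "p", "enriched"]
    if not sig:
        return pd.DataFrame(columns=cols)

    N = len(annotation.universe)
    n = len(sig)
    rows = []
    for cid in sorted(annotation.categories):
        members = annotation.categories[cid]
        K = len(members)
        if K == 0:
            continue
        k = len(members & sig)
        p = hypergeom_upper_tail(N, K, n, k)
        rows.append({"category_id": cid,
                     "category_name": annotation.names.get(cid, cid),
                     "N": N, "K": K, "n": n, "k": k, "p": p,
                     "enriched": p <= alpha})
    out = pd.DataFrame(rows, columns=cols)
    out = out.sort_values(["p", "category_id"], kind="mergesort",
                          ignore_index=True)

    if max_jaccard is not None:
        kept: list[set[str]] = []
        keep_mask = []
        for cid in out["category_id"]:
            members = annotation.categories[cid]
            redundant = any(
                len(members & prev) / len(members | prev) > max_jaccard
                for prev in kept if members | prev)
            keep_mask.append(not redundant)
            if not redundant:
                kept.append(members)
        out = out[np.array(keep_mask)].reset_index(drop=True)
    return out


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap of two gene sets against a universe."""

    N: int
    K: int
    n: int
    k: int
    p: float


def overlap_significance(set_a: set[str], set_b: set[str],
                         universe: set[str]) -> OverlapResult:
    """Upper-tail probability of observing at least the actual overlap
    between two gene sets drawn from a shared universe."""
    if not universe:
        raise ValueError("universe must not be empty")
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("both gene sets must be subsets of the universe")
    N, K, n = len(universe), len(set_a), len(set_b)
    k = len(set_a & set_b)
    return OverlapResult(N, K, n, k, hypergeom_upper_tail(N, K, n, k))


def fcop_vesiculation(measurements: pd.DataFrame,
                      wt_label: str) -> pd.DataFrame:
    """Normalize FCOP measurements to wild type.

    Each replicate's vesiculation readout is FM4-64 fluorescence divided by
    CFU; a strain's value is its mean ratio divided by the wild-type mean
    ratio (so wild type itself is exactly 1).  Requires the wild-type
    control with >= 3 replicates and strictly positive CFU everywhere.

    Returns columns strain, n_replicates, fcop_value.
    """
    required = {"strain", "replicate", "fm464", "cfu"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"FCOP table missing columns: {sorted(missing)}")
    bad = measurements["cfu"] <= 0
    if bad.any():
        row = measurements[bad].iloc[0]
        raise ValueError(f"nonpositive CFU for strain {row['strain']!r} "
                         f"replicate {row['replicate']}")
    if (measurements["fm464"] < 0).any():
        raise ValueError("FM4-64 fluorescence must be nonnegative")

    ratios = measurements.assign(
        ratio=measurements["fm464"] / measurements["cfu"])
    wt = ratios[ratios["strain"] == wt_label]
    if len(wt) == 0:
        raise ValueError(f"wild-type control {wt_label!r} missing from "
                         "FCOP measurements")
    if len(wt) < 3:
        raise ValueError(f"wild-type control {wt_label!r} needs >= 3 "
                         f"replicates, found {len(wt)}")
    wt_mean = float(wt["ratio"].mean())

    agg = ratios.groupby("strain", sort=True)["ratio"].agg(["mean", "size"])
    return pd.DataFrame({
        "strain": agg.index,
        "n_replicates": agg["size"].to_numpy(dtype=int),
        "fcop_value": agg["mean"].to_numpy() / wt_mean,
    }).reset_index(drop=True)


@dataclass(frozen=True)
class ConcordanceResult:
    """Agreement between the high-throughput and FCOP assays."""

    n_pairs: int
    correlation: float
    p_value: float
    sign_agree: int
    sign_total: int


def method_concordance(htp: pd.Series, fcop: pd.Series,
                       method: str = "pearson") -> ConcordanceResult:
    """Correlate high-throughput log10 scores with log10 FCOP values.

    ``htp`` maps strain -> log10 vesiculation score and ``fcop`` maps
    strain -> wild-type-normalized FCOP value (> 0).  Strains present in
    only one series are dropped with a warning.  The correlation (Pearson
    on log10 values by default, Spearman optional) is tested one-sided for
    positive association (t distribution, n-2 df).  Sign agreement counts
    pairs whose vesiculation direction matches across assays; an exact zero
    on either side agrees with anything.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    htp = pd.Series(htp).astype(float)
    fcop = pd.Series(fcop).astype(float)
    common = htp.index.intersection(fcop.index)
    dropped = (len(htp) - len(common)) + (len(fcop) - len(common))
    if dropped:
        logger.warning("%d unpaired strains dropped from concordance",
                       dropped)
    if len(common) < 3:
        raise ValueError("need at least 3 paired strains for concordance")
    x = htp.loc[common].to_numpy()
    f = fcop.loc[common].to_numpy()
    if np.any(f <= 0):
        raise ValueError("FCOP values must be positive to take logs")
    y = np.log10(f)

    if method == "pearson":
        r, p = pearsonr(x, y, alternative="greater")
    else:
        r, p = spearmanr(x, y, alternative="greater")

    agree = int(np.sum((np.sign(x) == np.sign(y)) | (x == 0) | (y == 0)))
    return ConcordanceResult(n_pairs=len(common), correlation=float(r),
                             p_value=float(p), sign_agree=agree,
                             sign_total=len(common))
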