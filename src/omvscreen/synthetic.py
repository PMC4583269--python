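"""Synthetic screen data with known ground truth.

Emulates a genome-wide arrayed knockout vesiculation screen: ~3,900 strains
laid out on 96-well plates, each plate blotted onto one membrane, with a
per-membrane (day-to-day) intensity scale factor, multiplicative well noise,
a subset of strains with planted over-/under-vesiculation effects, a small
growth-defective subpopulation, and flat GO-style annotation categories some
of which are preferentially filled with effect genes.  Every dataset is
reproducible from an explicit seed, and the generating truth is kept so
downstream hit calling and enrichment can be scored for recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .growth import gompertz

PLATE_SIZE = 96

#: Base densitometry intensity of a neutral strain, arbitrary units.
BASE_INTENSITY = 1000.0

#: Extra-replicate subsets at full library scale: how many strains get
#: 3, 4 and 5 biological replicates on top of the default 2.
EXTRA_REPLICATE_COUNTS = {3: 272, 4: 138, 5: 76}

DEFAULT_N_GENES = 3905
DEFAULT_FRAC_OVER = 0.02
DEFAULT_FRAC_UNDER = 0.025
DEFAULT_EFFECT_DELTA = 0.6
DEFAULT_FRAC_GROWTH_DEFECTIVE = 0.0269
DEFAULT_WELL_NOISE_CV = 0.278
DEFAULT_MEMBRANE_SCALE_SD = 0.3


@dataclass
class TrueLibrary:
    """Ground truth for one synthetic knockout library.

    ``true_log_effect`` is the planted log10 vesiculation shift per gene
    (0 for neutral genes); ``true_growth_params`` holds each gene's
    generating Gompertz parameters (columns y0, A, mu_max, lag);
    ``category_membership`` maps gene -> set of category ids and
    ``categories`` the inverse; ``planted_categories`` lists the ids that
    were preferentially filled with effect genes.
    """

    genes: list[str]
    true_log_effect: pd.Series
    growth_defective: pd.Series
    true_growth_params: pd.DataFrame
    category_membership: dict[str, set[str]]
    planted_categories: list[str]
    categories: dict[str, set[str]] = field(default_factory=dict)
    category_names: dict[str, str] = field(default_factory=dict)

    @property
    def over_genes(self) -> set[str]:
        return set(self.true_log_effect.index[self.true_log_effect > 0])

    @property
    def under_genes(self) -> set[str]:
        return set(self.true_log_effect.index[self.true_log_effect < 0])

    @property
    def effect_genes(self) -> set[str]:
        return self.over_genes | self.under_genes

    def truth_frame(self) -> pd.DataFrame:
        """Ground-truth table: gene, true_log_effect, growth_defective,
        planted-category memberships (semicolon-joined)."""
        planted = set(self.planted_categories)
        rows = [{
            "gene": g,
            "true_log_effect": float(self.true_log_effect[g]),
            "growth_defective": bool(self.growth_defective[g]),
            "planted_categories": ";".join(
                sorted(self.category_membership.get(g, set()) & planted)),
        } for g in self.genes]
        return pd.DataFrame(rows)


def generate_library(n_genes: int = DEFAULT_N_GENES,
                     frac_over: float = DEFAULT_FRAC_OVER,
                     frac_under: float = DEFAULT_FRAC_UNDER,
                     effect_delta: float = DEFAULT_EFFECT_DELTA,
                     frac_growth_defective: float = DEFAULT_FRAC_GROWTH_DEFECTIVE,
                     n_categories: int = 40,
                     category_size_range: tuple[int, int] = (10, 60),
                     n_planted_categories: int = 4,
                     planted_effect_fraction: float = 0.75,
                     mean_rate: float = 0.5,
                     rate_sd: float = 0.015,
                     defect_rate_multiple: float = 20.0,
                     defect_direction: str = "slow",
                     *, seed: int) -> TrueLibrary:
    """Generate a knockout library with planted effects and annotations.

    ``frac_over``/``frac_under`` genes get a +/- ``effect_delta`` log10
    vesiculation shift; ``frac_growth_defective`` genes (assigned
    independently of the vesiculation effects) get a maximum growth rate
    displaced by ``defect_rate_multiple`` times the normal-strain rate
    spread ``rate_sd`` (low by default, high with ``defect_direction="fast"``).
    Each planted category draws ``planted_effect_fraction`` of its members
    from the effect genes; the remaining categories are uniform draws.
    Deterministic given ``seed``.
    """
    if n_genes < PLATE_SIZE:
        raise ValueError(f"n_genes must be >= {PLATE_SIZE} (one full plate)")
    for name, frac in (("frac_over", frac_over), ("frac_under", frac_under),
                       ("frac_growth_defective", frac_growth_defective),
                       ("planted_effect_fraction", planted_effect_fraction)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {frac}")
    if frac_over + frac_under > 1.0:
        raise ValueError("frac_over + frac_under must not exceed 1")
    if effect_delta < 0:
        raise ValueError("effect_delta must be nonnegative")
    lo_size, hi_size = category_size_range
    if not 1 <= lo_size <= hi_size:
        raise ValueError("category_size_range must satisfy 1 <= low <= high")
    if hi_size > n_genes:
        raise ValueError("category sizes cannot exceed n_genes")
    if n_planted_categories > n_categories:
        raise ValueError("n_planted_categories cannot exceed n_categories")
    if defect_direction not in ("slow", "fast"):
        raise ValueError("defect_direction must be 'slow' or 'fast'")

    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]

    n_over = round(frac_over * n_genes)
    n_under = round(frac_under * n_genes)
    effect_pick = rng.choice(n_genes, size=n_over + n_under, replace=False)
    log_effect = np.zeros(n_genes)
    log_effect[effect_pick[:n_over]] = effect_delta
    log_effect[effect_pick[n_over:]] = -effect_delta

    n_defective = round(frac_growth_defective * n_genes)
    defective = np.zeros(n_genes, dtype=bool)
    defective[rng.choice(n_genes, size=n_defective, replace=False)] = True

    y0 = np.clip(rng.normal(0.05, 0.005, n_genes), 0.01, None)
    A = np.clip(rng.normal(1.0, 0.05, n_genes), 0.2, None)
    mu = np.clip(rng.normal(mean_rate, rate_sd, n_genes), 0.05, None)
    shift = defect_rate_multiple * rate_sd
    mu[defective] = np.clip(
        mu[defective] + (shift if defect_direction == "fast" else -shift),
        0.02, None)
    lag = np.clip(rng.normal(2.0, 0.3, n_genes), 0.1, None)
    params = pd.DataFrame({"y0": y0, "A": A, "mu_max": mu, "lag": lag},
                          index=genes)

    effect_list = [genes[i] for i in effect_pick]
    neutral_list = [g for g in genes if g not in set(effect_list)]
    categories: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    planted_ids = []
    for c in range(n_categories):
        cid = f"CAT{c:03d}"
        size = int(rng.integers(lo_size, hi_size + 1))
        if c < n_planted_categories:
            n_eff = min(round(planted_effect_fraction * size), len(effect_list))
            members = list(rng.choice(effect_list, size=n_eff, replace=False))
            members += list(rng.choice(neutral_list, size=size - n_eff,
                                       replace=False))
            planted_ids.append(cid)
            names[cid] = f"planted category {c}"
        else:
            members = list(rng.choice(genes, size=size, replace=False))
            names[cid] = f"background category {c}"
        categories[cid] = set(members)

    membership: dict[str, set[str]] = {}
    for cid, members in categories.items():
        for g in members:
            membership.setdefault(g, set()).add(cid)

    return TrueLibrary(
        genes=genes,
        true_log_effect=pd.Series(log_effect, index=genes),
        growth_defective=pd.Series(defective, index=genes),
        true_growth_params=params,
        category_membership=membership,
        planted_categories=planted_ids,
        categories=categories,
        category_names=names,
    )


def _truncated_mult_noise(rng: np.random.Generator, cv: float,
                          size: int) -> np.ndarray:
    """Multiplicative noise term eps ~ N(0, cv) truncated to eps > -1,
    so intensities stay strictly positive."""
    if cv == 0.0:
        return np.zeros(size)
    eps = rng.normal(0.0, cv, size)
    bad = eps <= -1.0
    while bad.any():
        eps[bad] = rng.normal(0.0, cv, int(bad.sum()))
        bad = eps <= -1.0
    return eps


def default_replicate_plan(library: TrueLibrary, *,
                           seed: int) -> dict[str, int]:
    """Default replicate plan: 2 biological replicates per strain, with
    randomly chosen disjoint subsets run 3, 4 and 5 times.  Subset sizes are
    the full-scale counts (272/138/76) scaled to the library size."""
    n = len(library.genes)
    rng = np.random.default_rng(seed)
    plan = {g: 2 for g in library.genes}
    scale = n / DEFAULT_N_GENES
    wanted = {reps: round(count * scale)
              for reps, count in EXTRA_REPLICATE_COUNTS.items()}
    pool = list(rng.permutation(library.genes))
    pos = 0
    for reps, count in wanted.items():
        for g in pool[pos:pos + count]:
            plan[g] = reps
        pos += count
    return plan


def simulate_blot_dataset(library: TrueLibrary,
                          replicate_plan: dict[str, int] | None = None,
                          membrane_scale_sd: float = DEFAULT_MEMBRANE_SCALE_SD,
                          well_noise_cv: float = DEFAULT_WELL_NOISE_CV,
                          *, seed: int) -> pd.DataFrame:
    """Simulate raw dot-blot densitometry for every strain.

    Each replicate round arrays the participating strains in library order
    onto 96-well membranes; a replicate of a given strain always lands on a
    different membrane than its other replicates (each round has its own
    membranes, modelling day-to-day batches).  Raw intensity is

        I = base * S_m * 10**true_log_effect * (1 + eps)

    with S_m a per-membrane lognormal scale (sigma ``membrane_scale_sd``)
    and eps truncated-normal multiplicative noise with coefficient of
    variation ``well_noise_cv``.

    Returns a long table with columns strain, membrane_id, replicate,
    raw_intensity.
    """
    if well_noise_cv < 0:
        raise ValueError("well_noise_cv must be nonnegative")
    if membrane_scale_sd < 0:
        raise ValueError("membrane_scale_sd must be nonnegative")

    rng = np.random.default_rng(seed)
    if replicate_plan is None:
        replicate_plan = default_replicate_plan(
            library, seed=int(rng.integers(2**31)))
    unknown = set(replicate_plan) - set(library.genes)
    if unknown:
        raise ValueError(f"replicate plan names unknown genes: {sorted(unknown)[:5]}")

    theta = 10.0 ** library.true_log_effect
    max_rep = max(replicate_plan.values())
    records: list[pd.DataFrame] = []
    for rep in range(1, max_rep + 1):
        strains = [g for g in library.genes if replicate_plan.get(g, 0) >= rep]
        if not strains:
            continue
        n_membranes = -(-len(strains) // PLATE_SIZE)
        scales = np.exp(rng.normal(0.0, membrane_scale_sd, n_membranes)) \
            if membrane_scale_sd > 0 else np.ones(n_membranes)
        eps = _truncated_mult_noise(rng, well_noise_cv, len(strains))
        membrane_idx = np.arange(len(strains)) // PLATE_SIZE
        intensity = (BASE_INTENSITY * scales[membrane_idx]
                     * theta[strains].to_numpy() * (1.0 + eps))
        records.append(pd.DataFrame({
            "strain": strains,
            "membrane_id": [f"R{rep}-M{m + 1:03d}" for m in membrane_idx],
            "replicate": rep,
            "raw_intensity": intensity,
        }))
    return pd.concat(records, ignore_index=True)


def simulate_growth_dataset(library: TrueLibrary, t_end: float = 18.0,
                            dt: float = 0.5, n_trials: int = 3,
                            od_noise_sd: float = 0.01,
                            *, seed: int) -> pd.DataFrame:
    """Simulate OD600 growth curves for every strain.

    Trajectories follow each gene's true Gompertz parameters sampled every
    ``dt`` hours from 0 to ``t_end`` inclusive, plus additive Gaussian read
    noise (clipped at 0 so readings stay physical).  Long format: strain,
    trial, time_h, od600.
    """
    if od_noise_sd < 0:
        raise ValueError("od_noise_sd must be nonnegative")
    n_steps = t_end / dt
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("dt must evenly divide t_end")
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")

    rng = np.random.default_rng(seed)
    times = np.round(np.arange(round(n_steps) + 1) * dt, 9)
    p = library.true_growth_params
    clean = gompertz(times[None, :], p["y0"].to_numpy()[:, None],
                     p["A"].to_numpy()[:, None],
                     p["mu_max"].to_numpy()[:, None],
                     p["lag"].to_numpy()[:, None])
    n_genes, n_t = clean.shape
    frames = []
    for trial in range(1, n_trials + 1):
        noise = rng.normal(0.0, od_noise_sd, clean.shape) if od_noise_sd > 0 \
            else 0.0
        od = np.maximum(clean + noise, 0.0)
        frames.append(pd.DataFrame({
            "strain": np.repeat(library.genes, n_t),
            "trial": trial,
            "time_h": np.tile(times, n_genes),
            "od600": od.ravel(),
        }))
    return pd.concat(frames, ignore_index=True)


def simulate_fcop_dataset(library: TrueLibrary, strain_subset: list[str],
                          n_replicates: int = 3, wt_label: str = "WT",
                          noise_cv: float = 0.15,
                          *, seed: int) -> pd.DataFrame:
    """Simulate flask-culture OMV prep (FCOP) measurements.

    For the wild-type control plus each strain in ``strain_subset``, draws
    ``n_replicates`` (FM4-64 fluorescence, CFU) pairs whose ratio is
    proportional to the strain's true linear vesiculation effect with
    multiplicative noise; CFU counts are lognormal around 1e9.
    """
    if not strain_subset:
        raise ValueError("strain_subset must not be empty")
    if n_replicates < 3:
        raise ValueError("FCOP requires at least 3 replicates")
    if noise_cv < 0:
        raise ValueError("noise_cv must be nonnegative")
    unknown = set(strain_subset) - set(library.genes)
    if unknown:
        raise ValueError(f"unknown strains in subset: {sorted(unknown)[:5]}")
    if wt_label in set(library.genes):
        raise ValueError("wt_label must not collide with a library gene")

    rng = np.random.default_rng(seed)
    base_ratio = 2e-6  # fluorescence units per CFU for a neutral strain
    rows = []
    for strain in [wt_label] + list(strain_subset):
        theta = 1.0 if strain == wt_label \
            else float(10.0 ** library.true_log_effect[strain])
        eps = _truncated_mult_noise(rng, noise_cv, n_replicates)
        cfu = rng.lognormal(np.log(1e9), 0.2, n_replicates)
        ratio = base_ratio * theta * (1.0 + eps)
        for r in range(n_replicates):
            rows.append({"strain": strain, "replicate": r + 1,
                         "fm464": ratio[r] * cfu[r], "cfu": cfu[r]})
    return pd.DataFrame(rows)
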