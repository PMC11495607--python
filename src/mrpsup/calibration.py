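"""Calibration simulations for the decision rules.

Two false-positive assessments run under a null in which the paired items
are exchangeable (a shared respondent intercept plus independent latent
noise per item, identical cutpoints), so any declared difference is a false
positive:

* ``simulate_rope_fpr`` -- the fraction of null comparisons whose 95% PSup
  HDI falls entirely outside the .47-.53 ROPE.  The default "fast posterior"
  replaces the full MRP fit with the conjugate Dirichlet(1,1,1) posterior
  over the greater/equal/less counts, which under the null carries the same
  information (covariates are uninformative); the full-MRP path is
  available for cross-checking on small grids.
* ``simulate_permutation_fdr`` -- the expected percentage of comparisons
  selected per set of null pairwise comparisons under the ascending
  cumulative c-value budget rule with 1000-permutation randomization tests.

Both metrics are reported with Monte-Carlo standard errors.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .decisions import RopeConfig, randomization_test, rope_classify, select_within_budget
from .psup import PSupResult
from .models import summarize_posterior

__all__ = [
    "CalibrationConfig",
    "CalibrationResult",
    "simulate_rope_fpr",
    "simulate_permutation_fdr",
    "null_item_ratings",
]


@dataclass
class CalibrationConfig:
    """Settings for one calibration scenario.

    Defaults mirror the study's own scales: public-sample size 1500 on a
    7-point scale for the ROPE assessment; personnel-sample size 20 on a
    5-point scale with 7 items (21 pairs) for the permutation-budget
    assessment (overridden per call below).
    """

    replicates: int = 500
    n_respondents: int = 1500
    scale: int = 7
    n_items: int = 2
    respondent_sd: float = 1.0  # latent correlation between paired items
    seed: int = 0
    fast_posterior: bool = True
    posterior_draws: int = 4000
    permutations: int = 1000
    budget: float = 0.05
    rope: RopeConfig = field(default_factory=RopeConfig)

    def __post_init__(self) -> None:
        if self.replicates < 1 or self.n_respondents < 1 or self.n_items < 2:
            raise ValueError("counts must be positive (and n_items >= 2)")
        if self.scale < 3:
            raise ValueError("scale must be K >= 3")


@dataclass
class CalibrationResult:
    metric: str
    value: float  # percentage
    mc_se: float  # Monte-Carlo standard error, percentage points
    replicates: int
    config: CalibrationConfig


def null_item_ratings(
    rng: np.random.Generator, n: int, k: int, n_items: int, respondent_sd: float
) -> np.ndarray:
    """Exchangeable null ratings, shape (n, n_items).

    Latent value = shared respondent intercept + unit normal noise, cut at
    standard-normal quantiles scaled to the total latent sd so all K
    categories carry mass.
    """
    total_sd = np.sqrt(1.0 + respondent_sd**2)
    cuts = norm.ppf(np.arange(1, k) / k) * total_sd
    b = rng.normal(0.0, respondent_sd, size=(n, 1))
    latent = b + rng.standard_normal((n, n_items))
    return 1 + np.searchsorted(cuts, latent.ravel()).reshape(n, n_items)


def _dirichlet_psup_hdi(
    rng: np.random.Generator,
    counts: np.ndarray,
    n_draws: int,
) -> PSupResult:
    """Conjugate fast posterior: Dirichlet(1,1,1) over (less, equal,
    greater) counts; PSup draw = p_greater + 0.5 p_equal."""
    p = rng.dirichlet(1.0 + counts, size=n_draws)
    draws = p[:, 2] + 0.5 * p[:, 1]
    mean, hdi = summarize_posterior(draws)
    return PSupResult(
        value=mean, draws=draws, hdi=hdi, tie_proportion=float(p[:, 1].mean())
    )


def _comparison_counts(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.array([np.sum(a < b), np.sum(a == b), np.sum(a > b)], dtype=float)


def simulate_rope_fpr(
    cfg: CalibrationConfig,
    method: str = "dirichlet",
    mrp_kwargs: dict | None = None,
) -> CalibrationResult:
    """False-positive percentage of the ROPE rule under the null.

    A false positive is a null comparison whose 95% PSup HDI lies entirely
    outside the ROPE.  ``method="dirichlet"`` uses the conjugate fast
    posterior; ``method="mrp"`` runs the full categorical-MRP pipeline per
    replicate on a small synthetic population (slow; for cross-checks).
    """
    rng = np.random.default_rng(cfg.seed)
    hits = 0
    if method == "dirichlet":
        for _ in range(cfg.replicates):
            ratings = null_item_ratings(
                rng, cfg.n_respondents, cfg.scale, 2, cfg.respondent_sd
            )
            counts = _comparison_counts(ratings[:, 0], ratings[:, 1])
            res = _dirichlet_psup_hdi(rng, counts, cfg.posterior_draws)
            if rope_classify(res, cfg.rope).reliable:
                hits += 1
    elif method == "mrp":
        hits = _rope_fpr_mrp(cfg, mrp_kwargs or {})
    else:
        raise ValueError(f"unknown method {method!r}")
    frac = hits / cfg.replicates
    se = float(np.sqrt(frac * (1 - frac) / cfg.replicates))
    return CalibrationResult(
        metric="rope_false_positive_pct",
        value=100.0 * frac,
        mc_se=100.0 * se,
        replicates=cfg.replicates,
        config=cfg,
    )


def _rope_fpr_mrp(cfg: CalibrationConfig, mrp_kwargs: dict) -> int:
    """Full-pipeline ROPE calibration: selection-unbiased synthetic sample,
    categorical MRP on the paired comparison, poststratified PSup HDI."""
    from .models import FormulaSpec, SamplerConfig
    from .psup import psup_mrp
    from .synthetic import (
        TruthSpec, build_poststrat_table, default_population_spec,
        sample_respondents, simulate_paired_responses,
    )

    pop = default_population_spec(total_population=200_000)
    table = build_poststrat_table(pop, seed=cfg.seed + 7)
    formula = mrp_kwargs.pop(
        "formula",
        FormulaSpec(fixed=("sex",), varying=("age_band", "state"), interactions=()),
    )
    sampler = mrp_kwargs.pop(
        "sampler",
        SamplerConfig(chains=2, draws=500, warmup=300, check_convergence=False),
    )
    cuts = norm.ppf(np.arange(1, cfg.scale) / cfg.scale) * np.sqrt(
        1 + cfg.respondent_sd**2
    )
    truth = TruthSpec(cutpoints=cuts)
    hits = 0
    for r in range(cfg.replicates):
        roster = sample_respondents(table, cfg.n_respondents, seed=cfg.seed + 100 + r)
        ds = simulate_paired_responses(
            roster, truth, truth, cfg.scale, seed=cfg.seed + 500 + r,
            respondent_sd=cfg.respondent_sd,
        )
        sampler_r = SamplerConfig(
            chains=sampler.chains, draws=sampler.draws, warmup=sampler.warmup,
            seed=cfg.seed + 900 + r, check_convergence=sampler.check_convergence,
        )
        res = psup_mrp(
            ds, ("item_a", "item_b"), formula, table, sampler=sampler_r
        )
        if rope_classify(res, cfg.rope).reliable:
            hits += 1
    return hits


def _pairwise_c_values(
    ratings: np.ndarray, permutations: int, rng: np.random.Generator
) -> dict[str, float]:
    out = {}
    m = ratings.shape[1]
    for i, j in itertools.combinations(range(m), 2):
        res = randomization_test(
            ratings[:, i], ratings[:, j], permutations=permutations,
            seed=int(rng.integers(2**31 - 1)), label=f"{i}-{j}",
        )
        out[res.label] = res.c_value
    return out


def simulate_permutation_fdr(cfg: CalibrationConfig) -> CalibrationResult:
    """Expected percentage of null comparisons selected per comparison set
    under the cumulative c-value budget rule."""
    rng = np.random.default_rng(cfg.seed)
    n_pairs = cfg.n_items * (cfg.n_items - 1) // 2
    fractions = np.empty(cfg.replicates)
    for r in range(cfg.replicates):
        ratings = null_item_ratings(
            rng, cfg.n_respondents, cfg.scale, cfg.n_items, cfg.respondent_sd
        )
        cvals = _pairwise_c_values(ratings, cfg.permutations, rng)
        selected = select_within_budget(cvals, budget=cfg.budget)
        fractions[r] = len(selected) / n_pairs
    pct = 100.0 * float(fractions.mean())
    se = 100.0 * float(fractions.std(ddof=1) / np.sqrt(cfg.replicates))
    return CalibrationResult(
        metric="budget_false_positive_pct",
        value=pct,
        mc_se=se,
        replicates=cfg.replicates,
        config=cfg,
    )
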