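"""Within-subject Probability of Superiority (PSup).

PSup is a probability-scale effect size for paired ordinal ratings: the
probability that a randomly chosen respondent rates item A above item B,
with ties counted one-half, so .5 means equivalence and PSup(A,B) +
PSup(B,A) = 1 exactly.  Three estimators are provided:

* ``psup_point`` -- the sample value [#(a>b) + 0.5 #(a=b)] / n;
* ``psup_mrp`` -- a population posterior: the paired greater/equal/less
  category is modeled with a categorical multilevel regression, each
  posterior draw is poststratified against population cell counts, and
  PSup = P(greater) + 0.5 P(equal) per draw, so the 95% HDI reflects full
  posterior uncertainty;
* ``psup_pop_vs_fixed`` -- a posterior population response distribution
  against a fixed small sample (the research-personnel comparison): per
  draw, PSup = sum_{i>j} p_i q_j + 0.5 sum_i p_i q_i with q the fixed
  sample's empirical frequencies, which are not resampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["PSupResult", "psup_point", "psup_mrp", "psup_pop_vs_fixed"]


@dataclass
class PSupResult:
    """Point value or posterior for a paired probability of superiority."""

    value: float
    pair: tuple[str, str] = ("A", "B")
    draws: np.ndarray | None = None
    hdi: tuple[float, float] | None = None
    tie_proportion: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("PSup must lie in [0, 1]")
        if self.draws is not None:
            self.draws = np.asarray(self.draws, dtype=float)
            if ((self.draws < 0) | (self.draws > 1)).any():
                raise ValueError("PSup draws must lie in [0, 1]")


def psup_point(
    a: Sequence[float], b: Sequence[float], pair: tuple[str, str] = ("A", "B")
) -> PSupResult:
    """Sample PSup for pairwise-complete paired ratings."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired ratings must be 1-d and of equal length")
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    n = len(a)
    if n < 1:
        raise ValueError("need at least one complete pair")
    greater = float(np.sum(a > b))
    ties = float(np.sum(a == b))
    return PSupResult(
        value=(greater + 0.5 * ties) / n, pair=pair, tie_proportion=ties / n
    )


def psup_mrp(
    data,
    pair: tuple[str, str],
    formula,
    table,
    priors=None,
    sampler=None,
) -> PSupResult:
    """Population PSup by MRP on the paired greater/equal/less category.

    ``data`` is a SurveyDataset containing both items of ``pair`` on a
    shared scale; the derived 3-level comparison is fitted with a
    categorical multilevel model and poststratified against ``table``.
    """
    from .models import fit_categorical_mrp, poststratify, summarize_posterior
    from .surveys import COMPARISON_LEVELS, SurveyDataset, derive_comparison

    item_a, item_b = pair
    k = data.items[item_a]
    if data.items.get(item_b) != k:
        raise ValueError(f"items {pair} are not on a shared scale")
    cc = data.complete_case([item_a, item_b])
    comp = derive_comparison(cc.df[item_a], cc.df[item_b], k=k)
    df = cc.df.copy()
    col = f"_cmp_{item_a}_vs_{item_b}"
    df[col] = comp
    ds = SurveyDataset(
        df=df,
        items=dict(cc.items),
        demographics=list(cc.demographics),
        levels={**cc.levels, col: list(COMPARISON_LEVELS)},
    )
    fit = fit_categorical_mrp(
        ds, col, formula, priors=priors, sampler=sampler,
        categories=list(COMPARISON_LEVELS),
    )
    est = poststratify(fit, table, estimand="category_probs")
    probs = est.draws  # draws x (less, equal, greater)
    draws = probs[:, 2] + 0.5 * probs[:, 1]
    mean, hdi = summarize_posterior(draws)
    return PSupResult(
        value=mean,
        pair=pair,
        draws=draws,
        hdi=hdi,
        tie_proportion=float(probs[:, 1].mean()),
    )


def psup_pop_vs_fixed(pop, fixed: Sequence[float], pair=("population", "sample")) -> PSupResult:
    """PSup of a posterior population response distribution over a fixed
    sample's raw ratings (the fixed side is never resampled).

    ``pop`` is a PopulationEstimate of K category probabilities (draws x K)
    or a bare draws array; ``fixed`` are raw 1..K ratings.
    """
    from .models import summarize_posterior

    p = np.asarray(getattr(pop, "draws", pop), dtype=float)
    if p.ndim != 2:
        raise ValueError("population estimate must be draws x K category probabilities")
    k = p.shape[1]
    fixed = np.asarray(fixed, dtype=float)
    fixed = fixed[~np.isnan(fixed)]
    if len(fixed) == 0:
        raise ValueError("fixed sample is empty")
    if ((fixed < 1) | (fixed > k) | (fixed != np.round(fixed))).any():
        raise ValueError(f"fixed ratings must be integers in 1..{k}")
    q = np.bincount(fixed.astype(int) - 1, minlength=k) / len(fixed)
    cumq = np.cumsum(q)
    below = cumq - q  # P(fixed < category i)
    draws = p @ below + 0.5 * (p @ q)
    mean, hdi = summarize_posterior(draws)
    return PSupResult(
        value=mean,
        pair=pair,
        draws=draws,
        hdi=hdi,
        tie_proportion=float((p @ q).mean()),
    )
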