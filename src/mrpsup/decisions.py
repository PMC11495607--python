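"""ROPE classification and permutation machinery for paired comparisons.

Two decision layers are implemented:

* for posterior probability-of-superiority (PSup) estimates, a range of
  practical equivalence (ROPE) of .47-.53: a comparison is a "reliable
  difference" only when the whole 95% HDI falls outside the ROPE, with
  graded effect-size thresholds at .53 (non-negligible), .60 (supermajority),
  .67 (2:1) and .75 (3:1), mirrored below .5 for effects in the other
  direction;
* for the small fixed research-personnel sample, a randomization test that
  swaps each respondent's paired scores with probability one half, reports
  the chance (c) value -- the fraction of permutations with a PSup as or
  more extreme (two-sided around .5) than observed -- and selects
  comparisons in ascending c order while the running sum of selected
  c-values stays within a cumulative 5% budget, bounding the expected
  false-positive percentage per comparison set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .psup import PSupResult, psup_point

__all__ = [
    "RopeConfig",
    "RopeDecision",
    "RandomizationResult",
    "rope_classify",
    "randomization_test",
    "select_within_budget",
]


@dataclass
class RopeConfig:
    """ROPE interval and graded thresholds on the PSup scale."""

    lower: float = 0.47
    upper: float = 0.53
    thresholds: tuple[float, ...] = (0.53, 0.60, 0.67, 0.75)

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower < self.upper <= 1.0):
            raise ValueError("ROPE must satisfy 0 <= lower < upper <= 1")
        self.thresholds = tuple(sorted(self.thresholds))
        if any(not 0.5 < t <= 1.0 for t in self.thresholds):
            raise ValueError("graded thresholds must lie in (0.5, 1]")


@dataclass
class RopeDecision:
    """Outcome of ROPE classification for one comparison."""

    reliable: bool
    direction: str | None  # "up", "down", or None when not reliable
    threshold_flags: dict[float, bool]
    hdi: tuple[float, float]


def rope_classify(psup: PSupResult, cfg: RopeConfig | None = None) -> RopeDecision:
    """Classify a posterior PSup against the ROPE and graded thresholds.

    A reliable difference requires the HDI entirely outside the ROPE; each
    graded threshold t is flagged when the HDI lies entirely beyond t in the
    effect's direction (above t going up, below 1-t going down).
    """
    cfg = cfg or RopeConfig()
    lo, hi = psup.hdi
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"HDI {psup.hdi} outside the [0, 1] PSup scale")
    up = lo > cfg.upper
    down = hi < cfg.lower
    reliable = up or down
    direction = "up" if up else "down" if down else None
    flags = {}
    for t in cfg.thresholds:
        if up:
            flags[t] = lo > t
        elif down:
            flags[t] = hi < 1.0 - t
        else:
            flags[t] = False
    return RopeDecision(
        reliable=reliable, direction=direction, threshold_flags=flags, hdi=(lo, hi)
    )


@dataclass
class RandomizationResult:
    """Observed PSup, permutation c-value, and budget-selection status."""

    observed: float
    c_value: float
    permutations: int
    label: str | None = None
    selected: bool | None = None


def randomization_test(
    a: Sequence[float],
    b: Sequence[float],
    permutations: int = 1000,
    seed: int = 0,
    label: str | None = None,
) -> RandomizationResult:
    """Paired-swap randomization test for PSup(A, B).

    Each permutation independently swaps each respondent's (a, b) pair with
    probability one half (the full 2^n sign-flip space); extremeness is
    two-sided distance of PSup from .5.  The c-value is the fraction of
    permutations with |PSup - .5| at least the observed distance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired ratings must be 1-d and of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    obs = psup_point(a, b).value
    g = (a > b).astype(float)
    l = (a < b).astype(float)
    ties = float(n - g.sum() - l.sum())
    rng = np.random.default_rng(seed)
    swap = rng.random((permutations, n)) < 0.5
    # swapping a pair exchanges its greater/less contribution; ties persist
    n_greater = g.sum() - swap @ g + swap @ l
    ps = (n_greater + 0.5 * ties) / n
    c = float(np.mean(np.abs(ps - 0.5) >= abs(obs - 0.5) - 1e-12))
    return RandomizationResult(
        observed=obs, c_value=c, permutations=permutations, label=label
    )


def select_within_budget(
    c_values: Mapping[str, float] | Sequence[RandomizationResult],
    budget: float = 0.05,
) -> list[str]:
    """Select comparisons in ascending c-value order under a cumulative budget.

    Comparisons are sorted ascending (ties broken by label) and included
    while the running sum of included c-values stays at or below the budget;
    the result is always a prefix of that ordering.  Accepts either a
    label -> c mapping or a sequence of RandomizationResult (whose
    ``selected`` flags are filled in place).
    """
    results: list[RandomizationResult] | None = None
    if isinstance(c_values, Mapping):
        pairs = [(float(c), str(lab)) for lab, c in c_values.items()]
    else:
        results = list(c_values)
        pairs = [
            (float(r.c_value), r.label if r.label is not None else str(i))
            for i, r in enumerate(results)
        ]
    for c, lab in pairs:
        if not 0.0 <= c <= 1.0:
            raise ValueError(f"c-value {c} for {lab!r} outside [0, 1]")
    order = sorted(range(len(pairs)), key=lambda i: pairs[i])
    chosen: list[str] = []
    chosen_idx: set[int] = set()
    running = 0.0
    for i in order:
        c, lab = pairs[i]
        if running + c > budget + 1e-12:
            break
        running += c
        chosen.append(lab)
        chosen_idx.add(i)
    if results is not None:
        for i, r in enumerate(results):
            r.selected = i in chosen_idx
    return chosen
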