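"""Synthetic population, sample, and ordinal-response generator.

Everything downstream of this module (multilevel regression and
poststratification, probability-of-superiority estimation, decision rules,
calibration) is exercised against data produced here, where the ground truth
is known exactly:

* a census-style cross-tabulation of sex x age band x education x income x
  race x state (with a state -> region map and a continuous state-level
  covariate), extended with party identification drawn from a multinomial
  logit conditional on demographics;
* a selection-biased respondent roster, drawn from the population cells with
  inclusion probability proportional to ``count * exp(bias score)``, so raw
  sample means are biased while model-based poststratified estimates remain
  consistent;
* ordinal Likert responses from a latent-normal cumulative model: the latent
  value is the sum of the respondent's demographic effect values plus unit
  normal noise, and the observed category is one plus the number of cutpoints
  below the latent value;
* closed-form population estimands (category probabilities, mean response,
  paired probability of superiority) obtained by enumerating cells and
  integrating the probit model exactly, used as oracles in recovery tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import norm

from .surveys import PoststratTable, SurveyDataset, zscore_state_covariate

__all__ = [
    "PartyModel",
    "PopulationSpec",
    "TruthSpec",
    "SelectionBiasSpec",
    "default_population_spec",
    "default_truth",
    "build_poststrat_table",
    "sample_respondents",
    "simulate_ordinal_responses",
    "simulate_paired_responses",
    "true_population_value",
]

# Stratifiers of the cross-tabulation, in canonical column order.
STRATIFIERS = ("sex", "age_band", "education", "income", "race", "state")


@dataclass
class PartyModel:
    """Multinomial logit for party identification given demographics.

    ``logit_p(cell) = intercepts[p] + sum_f coefficients[p][f][level_f]``;
    probabilities are the softmax over parties, hence they sum to one by
    construction.
    """

    parties: tuple[str, ...] = ("Democrat", "Independent", "Republican")
    intercepts: dict[str, float] = field(default_factory=dict)
    # party -> factor -> level -> additive log-odds contribution
    coefficients: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)

    def logits(self, cell: Mapping[str, str]) -> np.ndarray:
        out = np.zeros(len(self.parties))
        for j, p in enumerate(self.parties):
            out[j] = self.intercepts.get(p, 0.0)
            for factor, levels in self.coefficients.get(p, {}).items():
                out[j] += levels.get(str(cell[factor]), 0.0)
        return out

    def probs(self, cell: Mapping[str, str]) -> np.ndarray:
        z = self.logits(cell)
        z -= z.max()
        e = np.exp(z)
        return e / e.sum()


@dataclass
class PopulationSpec:
    """Ground-truth population: level sets, geography, counts, party model."""

    levels: dict[str, tuple[str, ...]]
    state_region: dict[str, str]
    state_covariate: dict[str, float]
    total_population: int
    party_model: PartyModel = field(default_factory=PartyModel)
    # per-factor marginal cell probabilities (cells are independent across
    # factors); None means uniform
    marginals: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        for f in STRATIFIERS:
            if f not in self.levels or len(self.levels[f]) == 0:
                raise ValueError(f"empty or missing level set for {f!r}")
        for s in self.levels["state"]:
            if s not in self.state_region:
                raise ValueError(f"state {s!r} has no region")
            if s not in self.state_covariate:
                raise ValueError(f"state {s!r} has no covariate value")
        if self.total_population <= 0:
            raise ValueError("total_population must be a positive integer")
        if self.marginals is not None:
            for f, m in self.marginals.items():
                m = np.asarray(m, dtype=float)
                if len(m) != len(self.levels[f]):
                    raise ValueError(f"marginals for {f!r} have wrong length")
                if abs(m.sum() - 1.0) > 1e-9 or (m < 0).any():
                    raise ValueError(f"marginals for {f!r} are not a distribution")

    @property
    def regions(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for s in self.levels["state"]:
            seen.setdefault(self.state_region[s], None)
        return tuple(seen)

    def factor_levels(self, factor: str) -> tuple[str, ...]:
        if factor == "party":
            return tuple(self.party_model.parties)
        if factor == "region":
            return self.regions
        return tuple(self.levels[factor])


def default_population_spec(
    total_population: int = 1_000_000,
    n_states: int = 8,
) -> PopulationSpec:
    """Default synthetic geography: 8 states in 4 regions.

    Small enough for fast model fits, large enough to exercise the
    state/region/covariate structure.  Marginals are mildly non-uniform so
    that no two cells are exchangeable by accident.
    """
    levels = {
        "sex": ("Female", "Male"),
        "age_band": ("18-24", "25-34", "35-44", "45-64", "65+"),
        "education": ("HS or less", "Some college", "College grad", "Graduate degree"),
        "income": ("<20k", "20-50k", "50-80k", "80-100k", "100-150k", ">150k"),
        "race": ("Asian", "Black", "Hispanic", "White", "Other"),
        "state": tuple(f"S{i+1}" for i in range(n_states)),
    }
    regions = ("Northeast", "Midwest", "South", "West")
    state_region = {s: regions[i % len(regions)] for i, s in enumerate(levels["state"])}
    # hesitancy rates spread over a plausible range, one per state
    rates = np.linspace(0.06, 0.27, n_states)
    state_covariate = {s: float(r) for s, r in zip(levels["state"], rates)}

    def _tilt(k: int) -> np.ndarray:
        w = 1.0 + 0.25 * np.arange(k)
        return w / w.sum()

    marginals = {f: _tilt(len(levels[f])) for f in STRATIFIERS}
    party = PartyModel(
        intercepts={"Democrat": 0.1, "Independent": -0.4, "Republican": 0.0},
        coefficients={
            "Democrat": {
                "race": {"Black": 0.9, "Hispanic": 0.4, "Asian": 0.3},
                "education": {"Graduate degree": 0.4},
                "age_band": {"18-24": 0.4, "25-34": 0.2},
            },
            "Republican": {
                "race": {"White": 0.4},
                "age_band": {"45-64": 0.3, "65+": 0.5},
                "income": {">150k": 0.2, "100-150k": 0.1},
            },
        },
    )
    return PopulationSpec(
        levels=levels,
        state_region=state_region,
        state_covariate=state_covariate,
        total_population=total_population,
        party_model=party,
        marginals=marginals,
    )


@dataclass
class TruthSpec:
    """Latent-model truth for the cumulative-probit response generator.

    The latent value for a respondent is the sum of the effect values for
    each of their demographic levels plus standard normal noise (residual
    scale fixed at 1, the usual probit identification).  ``cutpoints`` are
    the K-1 strictly increasing thresholds of a K-point scale.
    """

    cutpoints: np.ndarray
    sex: dict[str, float] = field(default_factory=dict)
    region: dict[str, float] = field(default_factory=dict)
    hesitancy_slope: float = 0.0
    # factor -> level -> effect (age_band, education, income, race, party, state)
    group: dict[str, dict[str, float]] = field(default_factory=dict)
    # (factor_a, factor_b) -> (level_a, level_b) -> effect
    interactions: dict[tuple[str, str], dict[tuple[str, str], float]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        self.cutpoints = np.asarray(self.cutpoints, dtype=float)
        if self.cutpoints.ndim != 1 or len(self.cutpoints) < 1:
            raise ValueError("cutpoints must be a 1-d array of length K-1 >= 1")
        if not np.all(np.diff(self.cutpoints) > 0):
            raise ValueError("cutpoints must be strictly increasing")

    @property
    def k(self) -> int:
        return len(self.cutpoints) + 1

    def latent_mean(self, rows: pd.DataFrame) -> np.ndarray:
        """Deterministic part of the latent value, vectorized over rows."""
        eta = np.zeros(len(rows))
        eta += rows["sex"].map(lambda v: self.sex.get(v, 0.0)).to_numpy(float)
        if self.region:
            eta += rows["region"].map(lambda v: self.region.get(v, 0.0)).to_numpy(float)
        if self.hesitancy_slope != 0.0:
            eta += self.hesitancy_slope * rows["state_hesitancy_z"].to_numpy(float)
        for factor, effs in self.group.items():
            eta += rows[factor].map(lambda v: effs.get(v, 0.0)).to_numpy(float)
        for (fa, fb), effs in self.interactions.items():
            pairs = list(zip(rows[fa], rows[fb]))
            eta += np.array([effs.get(p, 0.0) for p in pairs])
        return eta


def default_truth(
    k: int = 7,
    seed: int | None = None,
    scale: float = 0.4,
    spec: PopulationSpec | None = None,
) -> TruthSpec:
    """A mildly structured truth on a K-point scale.

    With ``seed`` given, effects are drawn N(0, scale^2) per level so recovery
    sweeps can iterate over many distinct truths; without, a fixed example.
    Cutpoints are standard-normal quantiles of equal category masses, widened
    so the outer categories are not empty.
    """
    cuts = norm.ppf(np.arange(1, k) / k) * 1.2
    if seed is None:
        return TruthSpec(
            cutpoints=cuts,
            sex={"Male": 0.25},
            region={"West": 0.15, "South": -0.1},
            hesitancy_slope=-0.3,
            group={
                "age_band": {"18-24": 0.3, "65+": -0.25},
                "education": {"Graduate degree": 0.2, "HS or less": -0.2},
                "party": {"Democrat": 0.3, "Republican": -0.3},
            },
        )
    rng = np.random.default_rng(seed)
    spec = spec or default_population_spec()

    def draw(levels: Sequence[str]) -> dict[str, float]:
        e = rng.normal(0.0, scale, len(levels))
        return {lv: float(v) for lv, v in zip(levels, e - e.mean())}

    return TruthSpec(
        cutpoints=cuts,
        sex={"Male": float(rng.normal(0, scale))},
        region=draw(spec.regions),
        hesitancy_slope=float(rng.normal(0, scale)),
        group={
            f: draw(spec.factor_levels(f))
            for f in ("age_band", "education", "income", "race", "party", "state")
        },
    )


@dataclass
class SelectionBiasSpec:
    """Additive log-odds of sample inclusion per demographic level.

    Inclusion probability for a cell is proportional to
    ``count * exp(sum of its levels' log-odds)``; all-zero bias reduces to
    proportional (representative) sampling.
    """

    logodds: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for factor, levels in self.logodds.items():
            for lv, v in levels.items():
                if not np.isfinite(v):
                    raise ValueError(f"non-finite bias for {factor}={lv}")

    def score(self, rows: pd.DataFrame) -> np.ndarray:
        s = np.zeros(len(rows))
        for factor, levels in self.logodds.items():
            s += rows[factor].map(lambda v: levels.get(v, 0.0)).to_numpy(float)
        return s


def build_poststrat_table(spec: PopulationSpec, seed: int) -> PoststratTable:
    """Cross-tabulate the population and draw integer cell counts.

    Cells are the full cross of the stratifiers; counts are a single
    multinomial draw over cells with probabilities given by the product of
    the per-factor marginals, then each cell is split over parties by a
    multinomial draw from the party model.  Counts therefore always sum to
    ``total_population`` exactly.
    """
    rng = np.random.default_rng(seed)
    factors = list(STRATIFIERS)
    level_lists = [spec.levels[f] for f in factors]
    cells = pd.DataFrame(
        list(itertools.product(*level_lists)), columns=factors, dtype=object
    )

    w = np.ones(len(cells))
    for f in factors:
        if spec.marginals is None:
            m = np.full(len(spec.levels[f]), 1.0 / len(spec.levels[f]))
        else:
            m = np.asarray(spec.marginals[f], dtype=float)
        lut = {lv: m[i] for i, lv in enumerate(spec.levels[f])}
        w *= cells[f].map(lut).to_numpy(float)
    w /= w.sum()
    counts = rng.multinomial(spec.total_population, w)

    parties = list(spec.party_model.parties)
    # party probabilities depend only on the factors the model references
    pprob = np.empty((len(cells), len(parties)))
    for i, row in enumerate(cells.itertuples(index=False)):
        pprob[i] = spec.party_model.probs(dict(zip(factors, row)))
    party_counts = np.empty((len(cells), len(parties)), dtype=np.int64)
    for i in range(len(cells)):
        party_counts[i] = rng.multinomial(counts[i], pprob[i])

    rep = cells.loc[cells.index.repeat(len(parties))].reset_index(drop=True)
    rep["party"] = parties * len(cells)
    rep["count"] = party_counts.reshape(-1)
    rep["region"] = rep["state"].map(spec.state_region)
    if len(set(spec.state_covariate.values())) > 1:
        z = zscore_state_covariate(spec.state_covariate)
    else:  # degenerate geography: the covariate carries no information
        z = {s: 0.0 for s in spec.state_covariate}
    rep["state_hesitancy_z"] = rep["state"].map(z)
    return PoststratTable(
        df=rep,
        demographics=factors + ["party"],
        cell_covariates=["region", "state_hesitancy_z"],
    )


def sample_respondents(
    table: PoststratTable,
    n: int,
    bias: SelectionBiasSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a (possibly selection-biased) respondent roster from the table.

    Each respondent is an independent draw over cells with probability
    proportional to ``count * exp(bias score)``.  Returns a roster DataFrame
    carrying the cell demographics and covariates plus a respondent_id.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    df = table.df
    if len(df) == 0 or df["count"].sum() == 0:
        raise ValueError("poststratification table is empty")
    bias = bias or SelectionBiasSpec()
    score = bias.score(df)
    score -= score.max()  # guard exp overflow; weights are relative
    w = df["count"].to_numpy(float) * np.exp(score)
    w /= w.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(df), size=n, replace=True, p=w)
    roster = df.iloc[idx].drop(columns="count").reset_index(drop=True)
    roster.insert(0, "respondent_id", np.arange(n))
    return roster


def _responses_from_latent(latent: np.ndarray, cutpoints: np.ndarray) -> np.ndarray:
    return 1 + np.searchsorted(cutpoints, latent, side="left").astype(np.int64)


def simulate_ordinal_responses(
    roster: pd.DataFrame,
    truth: TruthSpec,
    k: int,
    seed: int,
    item: str = "item",
) -> SurveyDataset:
    """Generate one ordinal item for every respondent on the roster."""
    if k < 2:
        raise ValueError("K must be >= 2")
    if len(truth.cutpoints) != k - 1:
        raise ValueError(f"truth has {len(truth.cutpoints)} cutpoints; need {k - 1}")
    rng = np.random.default_rng(seed)
    latent = truth.latent_mean(roster) + rng.standard_normal(len(roster))
    df = roster.copy()
    df[item] = _responses_from_latent(latent, truth.cutpoints)
    demo = [c for c in df.columns if c not in ("respondent_id", item)]
    return SurveyDataset(df=df, items={item: k}, demographics=demo)


def simulate_paired_responses(
    roster: pd.DataFrame,
    truth_a: TruthSpec,
    truth_b: TruthSpec,
    k: int,
    seed: int,
    respondent_sd: float = 0.0,
    items: tuple[str, str] = ("item_a", "item_b"),
) -> SurveyDataset:
    """Two items for the same respondents, optionally with a shared
    respondent intercept (latent correlation between the paired ratings)."""
    if len(truth_a.cutpoints) != k - 1 or len(truth_b.cutpoints) != k - 1:
        raise ValueError("both truths must have K-1 cutpoints")
    rng = np.random.default_rng(seed)
    b = rng.normal(0.0, respondent_sd, len(roster)) if respondent_sd > 0 else 0.0
    la = truth_a.latent_mean(roster) + b + rng.standard_normal(len(roster))
    lb = truth_b.latent_mean(roster) + b + rng.standard_normal(len(roster))
    df = roster.copy()
    df[items[0]] = _responses_from_latent(la, truth_a.cutpoints)
    df[items[1]] = _responses_from_latent(lb, truth_b.cutpoints)
    demo = [c for c in df.columns if c not in ("respondent_id", *items)]
    return SurveyDataset(df=df, items={items[0]: k, items[1]: k}, demographics=demo)


def _cell_category_probs(
    table: PoststratTable, truth: TruthSpec, shift: float = 0.0
) -> np.ndarray:
    """Exact per-cell category probabilities under the probit truth."""
    eta = truth.latent_mean(table.df) + shift
    c = truth.cutpoints
    cdf = ndtr(c[None, :] - eta[:, None])  # cells x (K-1)
    probs = np.diff(
        np.concatenate(
            [np.zeros((len(eta), 1)), cdf, np.ones((len(eta), 1))], axis=1
        ),
        axis=1,
    )
    return probs


def true_population_value(
    table: PoststratTable,
    truth: TruthSpec,
    estimand: str = "category_probs",
    truth_b: TruthSpec | None = None,
    respondent_sd: float = 0.0,
    gh_points: int = 40,
):
    """Exact population estimand by cell enumeration and probit integration.

    estimand:
        ``"category_probs"`` -- length-K vector of population category
        probabilities; ``"mean"`` -- population mean response; ``"psup"`` --
        paired probability of superiority of item A (this truth) over item B
        (``truth_b``), with ties counted one-half.  With ``respondent_sd > 0``
        the shared respondent intercept is integrated out by Gauss-Hermite
        quadrature (only relevant for ``"psup"``; marginals on a single item
        fold the intercept into the residual and are handled the same way).
    """
    w = table.df["count"].to_numpy(float)
    if w.sum() <= 0:
        raise ValueError("table has zero total count")
    w = w / w.sum()

    if respondent_sd > 0:
        nodes, weights = np.polynomial.hermite_e.hermegauss(gh_points)
        weights = weights / weights.sum()
        shifts = nodes * respondent_sd
    else:
        shifts, weights = np.array([0.0]), np.array([1.0])

    if estimand in ("category_probs", "mean"):
        probs = np.zeros((len(table.df), truth.k))
        for s, wt in zip(shifts, weights):
            probs += wt * _cell_category_probs(table, truth, shift=s)
        pop = w @ probs
        if estimand == "category_probs":
            return pop
        return float(pop @ np.arange(1, truth.k + 1))

    if estimand == "psup":
        if truth_b is None:
            raise ValueError("psup estimand needs truth_b")
        total = 0.0
        for s, wt in zip(shifts, weights):
            pa = _cell_category_probs(table, truth, shift=s)
            pb = _cell_category_probs(table, truth_b, shift=s)
            # greater_c = sum_k pa_k * P_b(< k) = sum_k pa_k * (cum_b(k) - pb_k)
            cum_b = np.cumsum(pb, axis=1)
            greater = np.einsum("ck,ck->c", pa, cum_b - pb)
            equal = np.einsum("ck,ck->c", pa, pb)
            total += wt * float(w @ (greater + 0.5 * equal))
        return total

    raise ValueError(f"unknown estimand {estimand!r}")
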