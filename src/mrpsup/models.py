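"""Multilevel regression and poststratification (MRP).

The regression stage fits, per outcome, a multilevel model with the study's
formula structure::

    outcome ~ sex + region + state_hesitancy_z
              + (1 | age_band) + (1 | education) + (1 | income) + (1 | race)
              + (1 | party) + (1 | state) + (1 | sex:race)
              + (1 | education:age_band)

as a cumulative ordinal probit (Likert items) or a categorical logit
(unordered outcomes, one fixed reference category).  Priors are weakly
informative: normal(0, 2) fixed effects, normal(0, 4) cutpoints/intercepts,
half-normal(1) group standard deviations; all scales are configurable.
Sampling is exact MCMC (see ``_gibbs``); convergence is gated on split-Rhat.

The poststratification stage turns posterior draws into population
estimands: per draw, every cell of a population cross-tabulation gets its
predicted category probabilities, and the population value is the
cell-count-weighted average.  Demographic levels that are declared (or
appear in the table) but were never observed in the sample receive effects
drawn from the fitted group-effect distribution, the standard
partial-pooling prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import ndtr

from ._gibbs import GroupBlock, categorical_gibbs_chain, ordinal_gibbs_chain
from .surveys import PoststratTable, SurveyDataset

__all__ = [
    "FormulaSpec",
    "PriorSpec",
    "SamplerConfig",
    "PosteriorFit",
    "PopulationEstimate",
    "ConvergenceError",
    "default_formula",
    "fit_ordinal_mrp",
    "fit_categorical_mrp",
    "poststratify",
    "summarize_posterior",
    "extend_table_with_party",
    "save_fit",
    "load_fit",
]


class ConvergenceError(RuntimeError):
    """Raised when the sampler fails the split-Rhat convergence gate."""


@dataclass
class FormulaSpec:
    """Additive structure: fixed effects, varying intercepts, interactions."""

    fixed: tuple[str, ...] = ("sex", "region", "state_hesitancy_z")
    varying: tuple[str, ...] = (
        "age_band", "education", "income", "race", "party", "state",
    )
    interactions: tuple[tuple[str, str], ...] = (
        ("sex", "race"), ("education", "age_band"),
    )

    def factors(self) -> list[str]:
        out = list(self.fixed) + list(self.varying)
        for fa, fb in self.interactions:
            for f in (fa, fb):
                if f not in out:
                    out.append(f)
        return out

    def validate_against(self, df: pd.DataFrame) -> None:
        for f in self.factors():
            if f not in df.columns:
                raise ValueError(f"formula factor {f!r} not in the data")
        declared = set(self.fixed) | set(self.varying)
        for fa, fb in self.interactions:
            if fa not in declared or fb not in declared:
                raise ValueError(
                    f"interaction ({fa}, {fb}) references undeclared factors"
                )


def default_formula() -> FormulaSpec:
    return FormulaSpec()


@dataclass
class PriorSpec:
    """Prior scales; all must be positive."""

    fixed_scale: float = 2.0
    intercept_scale: float = 4.0  # cutpoints and categorical intercepts
    group_sd_scale: float = 1.0  # half-normal on group standard deviations

    def __post_init__(self) -> None:
        if min(self.fixed_scale, self.intercept_scale, self.group_sd_scale) <= 0:
            raise ValueError("all prior scales must be positive")


@dataclass
class SamplerConfig:
    chains: int = 4
    draws: int = 1000
    warmup: int = 1000
    seed: int = 0
    rhat_max: float = 1.01
    check_convergence: bool = True
    cutpoint_steps: int = 3


@dataclass
class _DesignInfo:
    columns: list[str]
    fixed_prec: np.ndarray  # prior precision per column (group cols are
    # placeholders, overwritten by sampled group sds)
    blocks: list[GroupBlock]
    # block name -> list of level keys, aligned with the block's columns
    block_levels: dict[str, list[str]]
    include_intercept: bool


def _level_key(factor, level) -> str:
    return f"{factor}={level}"


def _resolve_levels(data: SurveyDataset, formula: FormulaSpec) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for f in formula.factors():
        if f == "state_hesitancy_z" or pd.api.types.is_numeric_dtype(data.df[f]):
            continue
        declared = data.levels.get(f)
        observed = sorted(map(str, data.df[f].dropna().unique()))
        if declared:
            out[f] = list(declared)
            extra = set(observed) - set(declared)
            if extra:
                raise ValueError(f"undeclared levels {sorted(extra)} for {f!r}")
        else:
            out[f] = observed
    return out


def _build_design(
    df: pd.DataFrame,
    formula: FormulaSpec,
    levels_map: dict[str, list[str]],
    priors: PriorSpec,
    include_intercept: bool,
    check_levels: bool = True,
) -> tuple[np.ndarray, _DesignInfo, dict[str, np.ndarray]]:
    """Design matrix + metadata.

    Returns (X, info, unknown) where ``unknown`` maps level keys absent from
    the fitted level sets (only allowed when check_levels is False, i.e. at
    prediction time) to boolean row masks; those rows carry zeros in the
    block's columns and get effects drawn from the group distribution.
    """
    n = len(df)
    cols: list[np.ndarray] = []
    names: list[str] = []
    prec: list[float] = []
    blocks: list[GroupBlock] = []
    block_levels: dict[str, list[str]] = {}
    unknown: dict[str, np.ndarray] = {}

    if include_intercept:
        cols.append(np.ones(n))
        names.append("intercept")
        prec.append(priors.intercept_scale ** -2)

    for f in formula.fixed:
        if f not in levels_map:  # numeric covariate
            cols.append(df[f].to_numpy(float))
            names.append(f)
            prec.append(priors.fixed_scale ** -2)
            continue
        levels = levels_map[f]
        vals = df[f].astype(str)
        if check_levels:
            if vals.nunique() < 2:
                raise ValueError(
                    f"fixed factor {f!r} has a single observed level"
                )
        else:
            bad = set(vals.unique()) - set(levels)
            if bad:
                raise ValueError(
                    f"fixed factor {f!r} has levels {sorted(bad)} unseen at fit"
                )
        for lv in levels[1:]:  # first level is the reference
            cols.append((vals == lv).to_numpy(float))
            names.append(_level_key(f, lv))
            prec.append(priors.fixed_scale ** -2)

    def add_block(name: str, keys: list[str], cell_keys: pd.Series) -> None:
        start = len(names)
        known = set(keys)
        for key in keys:
            cols.append((cell_keys == key).to_numpy(float))
            names.append(key)
            prec.append(1.0)  # placeholder; replaced by the group sd
        blocks.append(GroupBlock(name=name, idx=np.arange(start, len(names))))
        block_levels[name] = list(keys)
        for key in pd.unique(cell_keys):
            if key not in known:
                if check_levels:
                    raise ValueError(f"undeclared level {key!r} in block {name!r}")
                unknown[key] = (cell_keys == key).to_numpy(bool)

    for f in formula.varying:
        if check_levels and df[f].astype(str).nunique() < 2:
            raise ValueError(f"varying factor {f!r} has a single observed level")
        keys = [_level_key(f, lv) for lv in levels_map[f]]
        add_block(f, keys, df[f].astype(str).map(lambda v: _level_key(f, v)))

    for fa, fb in formula.interactions:
        name = f"{fa}:{fb}"
        keys = [
            _level_key(name, f"{la}|{lb}")
            for la in levels_map[fa]
            for lb in levels_map[fb]
        ]
        cell = (df[fa].astype(str) + "|" + df[fb].astype(str)).map(
            lambda v: _level_key(name, v)
        )
        add_block(name, keys, cell)

    X = np.column_stack(cols) if cols else np.empty((n, 0))
    info = _DesignInfo(
        columns=names,
        fixed_prec=np.asarray(prec),
        blocks=blocks,
        block_levels=block_levels,
        include_intercept=include_intercept,
    )
    return X, info, unknown


@dataclass
class PosteriorFit:
    """Posterior draws for one fitted outcome, plus sampler diagnostics.

    ``theta`` is (chains, draws, p) for ordinal fits and
    (chains, draws, p, n_categories) for categorical fits (reference
    category column identically zero).  ``group_sd`` carries one standard
    deviation per varying-intercept block (and per non-reference category
    for categorical fits); ``cutpoints`` are strictly increasing within
    every draw of an ordinal fit.
    """

    family: str
    formula: FormulaSpec
    priors: PriorSpec
    sampler: SamplerConfig
    info: _DesignInfo
    levels_map: dict[str, list[str]]
    outcome: str
    k: int  # scale size (ordinal) or number of categories (categorical)
    categories: list[str] | None
    theta: np.ndarray
    group_sd: np.ndarray
    cutpoints: np.ndarray | None
    diagnostics: dict

    @property
    def n_draws(self) -> int:
        return self.theta.shape[0] * self.theta.shape[1]

    def stacked(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape((arr.shape[0] * arr.shape[1],) + arr.shape[2:])


def _diagnose(draws: dict[str, np.ndarray]) -> dict:
    clean = {k: v for k, v in draws.items() if v.size and np.ptp(v) > 0}
    idata = az.from_dict(posterior=clean)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    rhat_max = float(
        max(np.nanmax(rhat[v].values) for v in clean) if clean else 1.0
    )
    ess_min = float(min(np.nanmin(ess[v].values) for v in clean) if clean else np.inf)
    return {"rhat_max": rhat_max, "ess_min": ess_min, "divergences": 0}


def _gate(diag: dict, cfg: SamplerConfig, outcome: str) -> None:
    if cfg.check_convergence and diag["rhat_max"] > cfg.rhat_max:
        raise ConvergenceError(
            f"fit for {outcome!r} failed convergence: split-Rhat "
            f"{diag['rhat_max']:.4f} > {cfg.rhat_max} "
            "(increase draws/warmup or set check_convergence=False)"
        )


def fit_ordinal_mrp(
    data: SurveyDataset,
    item: str,
    formula: FormulaSpec | None = None,
    priors: PriorSpec | None = None,
    sampler: SamplerConfig | None = None,
) -> PosteriorFit:
    """Fit the cumulative ordinal probit multilevel model for one item."""
    formula = formula or default_formula()
    priors = priors or PriorSpec()
    sampler = sampler or SamplerConfig()
    if item not in data.items:
        raise ValueError(f"unknown item {item!r}")
    k = data.items[item]
    if k < 3:
        raise ValueError("ordinal fits need a scale with K >= 3")
    cc = data.complete_case([item])
    formula.validate_against(cc.df)
    levels_map = _resolve_levels(cc, formula)
    X, info, _ = _build_design(cc.df, formula, levels_map, priors, False)
    y = cc.df[item].to_numpy(int)

    seeds = np.random.SeedSequence(sampler.seed).generate_state(sampler.chains)
    chains = [
        ordinal_gibbs_chain(
            X, y, k, info.blocks, info.fixed_prec,
            priors.intercept_scale, priors.group_sd_scale,
            sampler.warmup, sampler.draws, int(s) % (2**31 - 1),
            cut_steps=sampler.cutpoint_steps,
        )
        for s in seeds
    ]
    theta = np.stack([c["theta"] for c in chains])
    sds = np.stack([c["group_sd"] for c in chains])
    cuts = np.stack([c["cutpoints"] for c in chains])
    diag = _diagnose({"theta": theta, "group_sd": sds, "cutpoints": cuts})
    diag["cutpoint_accept_rate"] = float(
        np.mean([c["accept_rate"] for c in chains])
    )
    _gate(diag, sampler, item)
    return PosteriorFit(
        family="ordinal-probit", formula=formula, priors=priors, sampler=sampler,
        info=info, levels_map=levels_map, outcome=item, k=k, categories=None,
        theta=theta, group_sd=sds, cutpoints=cuts, diagnostics=diag,
    )


def fit_categorical_mrp(
    data: SurveyDataset,
    item: str,
    formula: FormulaSpec | None = None,
    priors: PriorSpec | None = None,
    sampler: SamplerConfig | None = None,
    categories: Sequence[str] | None = None,
) -> PosteriorFit:
    """Fit the categorical-logit multilevel model for a 2-3 category outcome.

    The first category is the fixed reference; its coefficients are zero.
    """
    formula = formula or default_formula()
    priors = priors or PriorSpec()
    sampler = sampler or SamplerConfig()
    cc = data.complete_case([item]) if item in data.items else data
    df = cc.df.dropna(subset=[item]).reset_index(drop=True)
    formula.validate_against(df)
    if categories is None:
        categories = data.levels.get(item) or sorted(map(str, df[item].unique()))
    categories = [str(c) for c in categories]
    if not 2 <= len(categories) <= 3:
        raise ValueError("categorical fits support 2-3 categories")
    codes = df[item].astype(str).map({c: i for i, c in enumerate(categories)})
    if codes.isna().any():
        bad = sorted(set(df[item].astype(str)) - set(categories))
        raise ValueError(f"responses {bad} outside declared categories")
    cc = SurveyDataset(
        df=df, items=dict(cc.items), demographics=list(cc.demographics),
        levels=dict(cc.levels),
    )
    levels_map = _resolve_levels(cc, formula)
    X, info, _ = _build_design(df, formula, levels_map, priors, True)
    y = codes.to_numpy(int)

    seeds = np.random.SeedSequence(sampler.seed).generate_state(sampler.chains)
    chains = [
        categorical_gibbs_chain(
            X, y, len(categories), info.blocks, info.fixed_prec,
            priors.group_sd_scale, sampler.warmup, sampler.draws,
            int(s) % (2**31 - 1),
        )
        for s in seeds
    ]
    theta = np.stack([c["theta"] for c in chains])  # chains,draws,p,C
    sds = np.stack([c["group_sd"] for c in chains])
    diag = _diagnose({"theta": theta[..., 1:], "group_sd": sds})
    _gate(diag, sampler, item)
    return PosteriorFit(
        family="categorical-logit", formula=formula, priors=priors,
        sampler=sampler, info=info, levels_map=levels_map, outcome=item,
        k=len(categories), categories=list(categories), theta=theta,
        group_sd=sds, cutpoints=None, diagnostics=diag,
    )


@dataclass
class PopulationEstimate:
    """Posterior draws of a poststratified population estimand."""

    draws: np.ndarray  # (S,) or (S, K)
    mean: np.ndarray | float
    hdi: tuple[float, float] | list[tuple[float, float]]
    labels: list[str] | None = None


def summarize_posterior(draws: np.ndarray, level: float = 0.95):
    """Posterior mean and highest-density interval (narrowest interval
    holding the requested mass) of a 1-d draw vector."""
    draws = np.asarray(draws, dtype=float).ravel()
    if len(draws) < 100:
        raise ValueError("need at least 100 draws to summarize")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lo, hi = az.hdi(draws, hdi_prob=level)
    return float(draws.mean()), (float(lo), float(hi))


def _unknown_effects(
    fit: PosteriorFit, unknown: dict[str, np.ndarray], info_fit: _DesignInfo
) -> dict[str, tuple[int, np.ndarray]]:
    """For each unknown level key, the owning block index and a per-draw
    standard-normal innovation (deterministic per level and fit seed)."""
    out = {}
    s = fit.theta.shape[0] * fit.theta.shape[1]
    for key, mask in unknown.items():
        block_name = key.split("=", 1)[0]
        bidx = next(
            i for i, b in enumerate(info_fit.blocks) if b.name == block_name
        )
        rng = np.random.default_rng(
            abs(hash((fit.sampler.seed, key))) % (2**31 - 1)
        )
        out[key] = (bidx, rng.standard_normal(s))
    return out


def _cell_probs_ordinal(cuts: np.ndarray, eta: np.ndarray) -> np.ndarray:
    """Category probabilities given cutpoint draws (S x K-1) and linear
    predictors (S x cells); returns S x cells x K."""
    s, n_cells = eta.shape
    cdf = ndtr(cuts[:, None, :] - eta[:, :, None])
    return np.diff(
        np.concatenate(
            [np.zeros((s, n_cells, 1)), cdf, np.ones((s, n_cells, 1))], axis=2,
        ),
        axis=2,
    )


def poststratify(
    fit: PosteriorFit,
    table: PoststratTable,
    estimand: str = "category_probs",
    chunk: int = 200,
) -> PopulationEstimate:
    """Population estimand: per draw, cell predictions weighted by counts.

    estimand: ``"category_probs"`` (default), ``"mean_response"`` (ordinal),
    or ``"collapse_support"`` (ordinal 7-point items collapsed to
    oppose/neutral/support).
    """
    if len(table) == 0 or table.total <= 0:
        raise ValueError("empty poststratification table")
    df = table.df
    cellX, info_pred, unknown = _build_design(
        df, fit.formula, fit.levels_map, fit.priors,
        fit.info.include_intercept, check_levels=False,
    )
    w = df["count"].to_numpy(float)
    w = w / w.sum()
    s = fit.n_draws
    extras = _unknown_effects(fit, unknown, fit.info)
    sds = fit.stacked(fit.group_sd)

    if fit.family == "ordinal-probit":
        theta = fit.stacked(fit.theta)  # S x p
        cuts = fit.stacked(fit.cutpoints)
        out = np.empty((s, fit.k))
        for start in range(0, s, chunk):
            sl = slice(start, min(start + chunk, s))
            eta = theta[sl] @ cellX.T  # S' x cells
            for key, (bidx, eps) in extras.items():
                mask = unknown[key]
                eta[:, mask] += (sds[sl, bidx] * eps[sl])[:, None]
            probs = _cell_probs_ordinal(cuts[sl], eta)  # S' x cells x K
            out[sl] = np.einsum("c,sck->sk", w, probs)
        labels = [str(i) for i in range(1, fit.k + 1)]
    elif fit.family == "categorical-logit":
        theta = fit.stacked(fit.theta)  # S x p x C
        out = np.empty((s, fit.k))
        for start in range(0, s, chunk):
            sl = slice(start, min(start + chunk, s))
            psi = np.einsum("cp,spj->csj", cellX, theta[sl])  # cells,S',C
            for key, (bidx, eps) in extras.items():
                mask = unknown[key]
                for j in range(1, fit.k):
                    psi[mask, :, j] += sds[sl, bidx, j - 1] * eps[sl]
            psi -= psi.max(axis=2, keepdims=True)
            e = np.exp(psi)
            probs = e / e.sum(axis=2, keepdims=True)  # cells,S',C
            out[sl] = np.einsum("c,csk->sk", w, probs)
        labels = list(fit.categories or [])
    else:
        raise ValueError(f"unknown family {fit.family!r}")

    if estimand == "category_probs":
        draws = out
    elif estimand == "mean_response":
        if fit.family != "ordinal-probit":
            raise ValueError("mean_response needs an ordinal fit")
        draws = out @ np.arange(1, fit.k + 1)
    elif estimand == "collapse_support":
        if fit.family != "ordinal-probit" or fit.k != 7:
            raise ValueError("collapse_support needs a 7-point ordinal fit")
        draws = np.column_stack(
            [out[:, :3].sum(1), out[:, 3], out[:, 4:].sum(1)]
        )
        labels = ["oppose", "neutral", "support"]
    else:
        raise ValueError(f"unknown estimand {estimand!r}")

    if draws.ndim == 1:
        mean, hdi = summarize_posterior(draws)
        return PopulationEstimate(draws=draws, mean=mean, hdi=hdi)
    summ = [summarize_posterior(draws[:, j]) for j in range(draws.shape[1])]
    return PopulationEstimate(
        draws=draws,
        mean=np.array([m for m, _ in summ]),
        hdi=[h for _, h in summ],
        labels=labels,
    )


def extend_table_with_party(
    table: PoststratTable,
    party_fit: PosteriorFit,
    party_factor: str = "party",
) -> PoststratTable:
    """Split every cell over party using posterior-mean party probabilities.

    Mirrors extending a census cross-tabulation with party identification
    estimated from an auxiliary election-study model; total count is
    conserved exactly because the probabilities sum to one.
    """
    if party_fit.family != "categorical-logit":
        raise ValueError("party extension needs a categorical fit")
    for f in party_fit.formula.factors():
        if f not in table.df.columns:
            raise ValueError(f"party model factor {f!r} missing from table")
    df = table.df
    cellX, _, unknown = _build_design(
        df, party_fit.formula, party_fit.levels_map, party_fit.priors,
        True, check_levels=False,
    )
    theta = party_fit.stacked(party_fit.theta)  # S x p x C
    sds = party_fit.stacked(party_fit.group_sd)
    extras = _unknown_effects(party_fit, unknown, party_fit.info)
    s = theta.shape[0]
    probs = np.zeros((len(df), party_fit.k))
    chunk = 200
    for start in range(0, s, chunk):
        sl = slice(start, min(start + chunk, s))
        psi = np.einsum("cp,spj->csj", cellX, theta[sl])
        for key, (bidx, eps) in extras.items():
            mask = unknown[key]
            for j in range(1, party_fit.k):
                psi[mask, :, j] += sds[sl, bidx, j - 1] * eps[sl]
        psi -= psi.max(axis=2, keepdims=True)
        e = np.exp(psi)
        probs += (e / e.sum(axis=2, keepdims=True)).sum(axis=1)
    probs /= s

    parties = list(party_fit.categories or [])
    rep = df.loc[df.index.repeat(len(parties))].reset_index(drop=True)
    rep[party_factor] = parties * len(df)
    rep["count"] = (
        df["count"].to_numpy(float)[:, None] * probs
    ).reshape(-1)
    return PoststratTable(
        df=rep,
        demographics=list(table.demographics) + [party_factor],
        cell_covariates=list(table.cell_covariates),
    )


def save_fit(fit: PosteriorFit, base: str) -> None:
    """Serialize a fit: posterior draws as an arviz InferenceData netcdf
    (``<base>.nc``) plus a JSON metadata sidecar (``<base>.meta.json``)."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    post = {"theta": fit.theta, "group_sd": fit.group_sd}
    if fit.cutpoints is not None:
        post["cutpoints"] = fit.cutpoints
    az.from_dict(posterior=post).to_netcdf(f"{base}.nc")
    meta = {
        "family": fit.family,
        "outcome": fit.outcome,
        "k": fit.k,
        "categories": fit.categories,
        "formula": {
            "fixed": list(fit.formula.fixed),
            "varying": list(fit.formula.varying),
            "interactions": [list(i) for i in fit.formula.interactions],
        },
        "priors": asdict(fit.priors),
        "sampler": asdict(fit.sampler),
        "levels_map": fit.levels_map,
        "info": {
            "columns": fit.info.columns,
            "fixed_prec": fit.info.fixed_prec.tolist(),
            "blocks": {b.name: b.idx.tolist() for b in fit.info.blocks},
            "block_levels": fit.info.block_levels,
            "include_intercept": fit.info.include_intercept,
        },
        "diagnostics": fit.diagnostics,
    }
    Path(f"{base}.meta.json").write_text(json.dumps(meta, indent=1, default=float))


def load_fit(base: str) -> PosteriorFit:
    """Inverse of :func:`save_fit`."""
    import json
    from pathlib import Path

    meta = json.loads(Path(f"{base}.meta.json").read_text())
    idata = az.from_netcdf(f"{base}.nc")
    post = idata.posterior
    info = _DesignInfo(
        columns=list(meta["info"]["columns"]),
        fixed_prec=np.asarray(meta["info"]["fixed_prec"]),
        blocks=[
            GroupBlock(name=n, idx=np.asarray(ix, dtype=int))
            for n, ix in meta["info"]["blocks"].items()
        ],
        block_levels={k: list(v) for k, v in meta["info"]["block_levels"].items()},
        include_intercept=bool(meta["info"]["include_intercept"]),
    )
    fd = meta["formula"]
    return PosteriorFit(
        family=meta["family"],
        formula=FormulaSpec(
            fixed=tuple(fd["fixed"]),
            varying=tuple(fd["varying"]),
            interactions=tuple(tuple(i) for i in fd["interactions"]),
        ),
        priors=PriorSpec(**meta["priors"]),
        sampler=SamplerConfig(**meta["sampler"]),
        info=info,
        levels_map={k: list(v) for k, v in meta["levels_map"].items()},
        outcome=meta["outcome"],
        k=int(meta["k"]),
        categories=meta["categories"],
        theta=post["theta"].values,
        group_sd=post["group_sd"].values,
        cutpoints=post["cutpoints"].values if "cutpoints" in post else None,
        diagnostics=dict(meta["diagnostics"]),
    )
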