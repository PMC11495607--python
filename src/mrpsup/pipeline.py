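"""End-to-end orchestration: prepare -> fit -> poststratify -> psup ->
decide (-> calibrate), from a single YAML config.

The pipeline mirrors the study's analysis surfaces: poststratified
category-probability and collapsed support tables per outcome, a pairwise
population PSup table with ROPE flags, and a descriptive personnel table
(sample PSup, permutation c-values, cumulative-budget selection).  Every
stage seed is derived from the single run seed, so two runs with the same
config produce identical tables; a JSON manifest records versions, seeds
and sampler diagnostics.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from ._version import __version__
from .decisions import RopeConfig, randomization_test, rope_classify, select_within_budget
from .models import (
    FormulaSpec,
    PosteriorFit,
    PriorSpec,
    SamplerConfig,
    fit_ordinal_mrp,
    poststratify,
)
from .psup import psup_mrp, psup_point
from .surveys import PoststratTable, SurveyDataset, apply_exclusions

__all__ = ["RunConfig", "run_pipeline", "report_support_summary", "psup_flag_table"]


def _formula_from_dict(d: Mapping[str, Any] | None) -> FormulaSpec:
    if not d:
        return FormulaSpec()
    return FormulaSpec(
        fixed=tuple(d.get("fixed", FormulaSpec.fixed)),
        varying=tuple(d.get("varying", FormulaSpec.varying)),
        interactions=tuple(tuple(i) for i in d.get("interactions", FormulaSpec.interactions)),
    )


def _priors_from_dict(d: Mapping[str, Any] | None) -> PriorSpec:
    return PriorSpec(**(d or {}))


def _sampler_from_dict(d: Mapping[str, Any] | None, seed: int) -> SamplerConfig:
    cfg = SamplerConfig(**(d or {}))
    cfg.seed = seed
    return cfg


def _rope_from_dict(d: Mapping[str, Any] | None) -> RopeConfig:
    if not d:
        return RopeConfig()
    return RopeConfig(
        lower=d.get("lower", 0.47),
        upper=d.get("upper", 0.53),
        thresholds=tuple(d.get("thresholds", (0.53, 0.60, 0.67, 0.75))),
    )


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    survey: str
    poststrat: str
    outcomes: list[dict] = field(default_factory=list)  # {item: str, collapse: bool}
    psup_pairs: list[tuple[str, str]] = field(default_factory=list)
    personnel_survey: str | None = None
    personnel_pairs: list[tuple[str, str]] = field(default_factory=list)
    formula: FormulaSpec = field(default_factory=FormulaSpec)
    priors: PriorSpec = field(default_factory=PriorSpec)
    sampler: dict = field(default_factory=dict)
    rope: RopeConfig = field(default_factory=RopeConfig)
    permutations: int = 1000
    budget: float = 0.05
    seed: int = 0
    output_dir: str = "mrpsup_results"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("survey", "poststrat"):
            if key not in raw:
                raise ValueError(f"config is missing required key {key!r}")
        base = Path(path).parent

        def respath(p):
            p = Path(p)
            return str(p if p.is_absolute() else base / p)

        return cls(
            survey=respath(raw["survey"]),
            poststrat=respath(raw["poststrat"]),
            outcomes=list(raw.get("outcomes", [])),
            psup_pairs=[tuple(p) for p in raw.get("psup_pairs", [])],
            personnel_survey=(
                respath(raw["personnel_survey"]) if raw.get("personnel_survey") else None
            ),
            personnel_pairs=[tuple(p) for p in raw.get("personnel_pairs", [])],
            formula=_formula_from_dict(raw.get("formula")),
            priors=_priors_from_dict(raw.get("priors")),
            sampler=dict(raw.get("sampler", {})),
            rope=_rope_from_dict(raw.get("rope")),
            permutations=int(raw.get("permutations", 1000)),
            budget=float(raw.get("budget", 0.05)),
            seed=int(raw.get("seed", 0)),
            output_dir=respath(raw.get("output_dir", "mrpsup_results")),
        )

    def validate(self) -> None:
        for p in filter(None, (self.survey, self.poststrat, self.personnel_survey)):
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input {p} does not exist")


def report_support_summary(
    fits: Mapping[str, PosteriorFit], table: PoststratTable
) -> pd.DataFrame:
    """Collapsed oppose/neutral/support population table per outcome.

    Per draw the three category masses sum to one; each is summarized by
    its posterior mean and 95% HDI.
    """
    rows = []
    for use, fit in fits.items():
        est = poststratify(fit, table, estimand="collapse_support")
        for j, cat in enumerate(est.labels):
            lo, hi = est.hdi[j]
            rows.append(
                {"outcome": use, "category": cat, "mean": est.mean[j],
                 "hdi_low": lo, "hdi_high": hi}
            )
    return pd.DataFrame(rows)


def psup_flag_table(results, rope: RopeConfig) -> pd.DataFrame:
    """Tidy matrix of PSup results with ROPE/threshold flags."""
    rows = []
    for res in results:
        dec = rope_classify(res, rope)
        row = {
            "item_a": res.pair[0], "item_b": res.pair[1], "psup": res.value,
            "hdi_low": res.hdi[0], "hdi_high": res.hdi[1],
            "tie_proportion": res.tie_proportion,
            "reliable": dec.reliable, "direction": dec.direction,
        }
        for t, flag in dec.threshold_flags.items():
            row[f"beyond_{t:.2f}"] = flag
        rows.append(row)
    return pd.DataFrame(rows)


def _stage_seed(base: int, stage: int) -> int:
    return int(np.random.SeedSequence([base, stage]).generate_state(1)[0] % (2**31 - 1))


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every configured stage; returns the result tables and manifest."""
    cfg.validate()
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "mrpsup_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "fits": {},
    }
    results: dict[str, Any] = {}

    survey = apply_exclusions(SurveyDataset.read_csv(cfg.survey), mode="public")
    table = PoststratTable.read_csv(cfg.poststrat)
    manifest["n_respondents"] = len(survey)
    manifest["poststrat_cells"] = len(table)

    # ordinal outcomes -> category probabilities (+ collapsed support)
    cat_rows, support_fits = [], {}
    for i, spec in enumerate(cfg.outcomes):
        item = spec["item"] if isinstance(spec, Mapping) else str(spec)
        collapse = bool(spec.get("collapse", False)) if isinstance(spec, Mapping) else False
        sampler = _sampler_from_dict(cfg.sampler, _stage_seed(cfg.seed, 10 + i))
        fit = fit_ordinal_mrp(survey, item, cfg.formula, cfg.priors, sampler)
        manifest["fits"][item] = dict(fit.diagnostics)
        est = poststratify(fit, table, estimand="category_probs")
        for j, lab in enumerate(est.labels):
            lo, hi = est.hdi[j]
            cat_rows.append(
                {"outcome": item, "category": lab, "mean": est.mean[j],
                 "hdi_low": lo, "hdi_high": hi}
            )
        if collapse:
            support_fits[item] = fit
    if cat_rows:
        results["population_categories"] = pd.DataFrame(cat_rows)
    if support_fits:
        results["support_summary"] = report_support_summary(support_fits, table)

    # pairwise population PSup with ROPE flags
    psup_results = []
    for i, pair in enumerate(cfg.psup_pairs):
        sampler = _sampler_from_dict(cfg.sampler, _stage_seed(cfg.seed, 100 + i))
        res = psup_mrp(survey, tuple(pair), cfg.formula, table,
                       priors=cfg.priors, sampler=sampler)
        psup_results.append(res)
    if psup_results:
        results["psup_population"] = psup_flag_table(psup_results, cfg.rope)

    # personnel: descriptive PSup + permutation tests + budget selection
    if cfg.personnel_survey and cfg.personnel_pairs:
        personnel = apply_exclusions(
            SurveyDataset.read_csv(cfg.personnel_survey),
            mode="personnel", outcome_context="ratings",
        )
        tests = []
        for i, (a, b) in enumerate(cfg.personnel_pairs):
            df = personnel.df.dropna(subset=[a, b])
            tests.append(
                randomization_test(
                    df[a], df[b], permutations=cfg.permutations,
                    seed=_stage_seed(cfg.seed, 200 + i), label=f"{a}|{b}",
                )
            )
        select_within_budget(tests, budget=cfg.budget)
        results["personnel_randomization"] = pd.DataFrame(
            [
                {"item_a": t.label.split("|")[0], "item_b": t.label.split("|")[1],
                 "psup": t.observed, "c_value": t.c_value, "selected": t.selected}
                for t in tests
            ]
        )

    for name, df in results.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, default=float))
    results["manifest"] = manifest
    return results
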