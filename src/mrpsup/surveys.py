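"""Survey and poststratification tables: containers, I/O, recodes.

Two thin DataFrame wrappers with validated invariants, CSV round-tripping
with a JSON sidecar declaring item scale sizes and level orderings, the
study's exclusion rules (comprehension-check failures and non-binary
respondents for the public sample; the conducted-HCT filter for research
personnel on the support/interest outcomes), and the derived variables used
by the models: the 3-level support collapse, the paired greater/equal/less
comparison, and the z-scored state covariate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "SurveyDataset",
    "PoststratTable",
    "apply_exclusions",
    "collapse_support",
    "derive_comparison",
    "zscore_state_covariate",
    "COMPARISON_LEVELS",
    "SUPPORT_LEVELS",
]

SUPPORT_LEVELS = ("oppose", "neutral", "support")
COMPARISON_LEVELS = ("less", "equal", "greater")

# personnel outcomes for which the conducted-HCT filter applies
_PERSONNEL_FILTERED_CONTEXTS = {"support", "allowed", "interest_barriers"}


@dataclass
class SurveyDataset:
    """Respondent-level table: demographics plus ordinal item responses.

    ``items`` maps each item column to its scale size K; responses must lie
    in 1..K (NaN allowed, handled complete-case per analysis downstream).
    """

    df: pd.DataFrame
    items: dict[str, int]
    demographics: list[str] = field(default_factory=list)
    levels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for item, k in self.items.items():
            if item not in self.df.columns:
                raise ValueError(f"item column {item!r} missing from data")
            vals = self.df[item].dropna()
            if len(vals) and ((vals < 1) | (vals > k)).any():
                raise ValueError(f"responses for {item!r} outside 1..{k}")
        for col, lv in self.levels.items():
            if col in self.df.columns:
                bad = set(self.df[col].dropna()) - set(lv)
                if bad:
                    raise ValueError(f"undeclared levels {sorted(bad)} in {col!r}")

    def __len__(self) -> int:
        return len(self.df)

    def complete_case(self, items: Iterable[str]) -> "SurveyDataset":
        cols = list(items)
        keep = self.df.dropna(subset=cols)
        return SurveyDataset(
            df=keep.reset_index(drop=True),
            items=dict(self.items),
            demographics=list(self.demographics),
            levels=dict(self.levels),
        )

    def write_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.df.to_csv(path, index=False)
        sidecar = {
            "items": self.items,
            "demographics": self.demographics,
            "levels": self.levels,
        }
        path.with_suffix(".dict.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read_csv(cls, path: str | Path) -> "SurveyDataset":
        path = Path(path)
        meta = json.loads(path.with_suffix(".dict.json").read_text())
        df = pd.read_csv(path)
        return cls(
            df=df,
            items={k: int(v) for k, v in meta["items"].items()},
            demographics=list(meta.get("demographics", [])),
            levels={k: list(v) for k, v in meta.get("levels", {}).items()},
        )


@dataclass
class PoststratTable:
    """Population cross-tabulation: one row per demographic cell plus count.

    ``demographics`` are the cross-tabulated factors (cells must be unique on
    them); ``cell_covariates`` are additional deterministic per-cell columns
    (region, z-scored state covariate).  Counts may be fractional after a
    model-based extension (e.g. splitting cells over party by posterior-mean
    probabilities) but are always finite and non-negative.
    """

    df: pd.DataFrame
    demographics: list[str]
    cell_covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if "count" not in self.df.columns:
            raise ValueError("poststratification table needs a 'count' column")
        cnt = self.df["count"].to_numpy(float)
        if not np.isfinite(cnt).all() or (cnt < 0).any():
            raise ValueError("counts must be finite and non-negative")
        for c in self.demographics:
            if c not in self.df.columns:
                raise ValueError(f"demographic column {c!r} missing")
        if self.df.duplicated(subset=self.demographics).any():
            raise ValueError("duplicate demographic cells in table")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total(self) -> float:
        return float(self.df["count"].sum())

    def marginalize(self, drop: str) -> "PoststratTable":
        """Sum counts over one factor (e.g. drop party to get the raw
        census-style table before the party extension)."""
        keep = [c for c in self.demographics if c != drop]
        agg = {"count": "sum", **{c: "first" for c in self.cell_covariates}}
        out = self.df.groupby(keep, as_index=False, sort=False, observed=True).agg(agg)
        return PoststratTable(
            df=out, demographics=keep, cell_covariates=list(self.cell_covariates)
        )

    def write_csv(self, path: str | Path) -> None:
        path = Path(path)
        self.df.to_csv(path, index=False)
        sidecar = {
            "demographics": self.demographics,
            "cell_covariates": self.cell_covariates,
        }
        path.with_suffix(".dict.json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def read_csv(cls, path: str | Path) -> "PoststratTable":
        path = Path(path)
        meta = json.loads(path.with_suffix(".dict.json").read_text())
        return cls(
            df=pd.read_csv(path),
            demographics=list(meta["demographics"]),
            cell_covariates=list(meta.get("cell_covariates", [])),
        )


def apply_exclusions(
    raw: SurveyDataset,
    mode: str = "public",
    outcome_context: str | None = None,
) -> SurveyDataset:
    """Apply the study's exclusion rules.

    public: drop respondents failing any comprehension check and those
    identifying as non-binary (the census cross-tabulation is binary on sex,
    so they cannot be poststratified).  personnel: keep only respondents who
    have not conducted an HCT, but only for the general-support /
    allowed / interest-and-barriers outcomes; importance and acceptability
    ratings retain everyone.  Idempotent, never adds rows.
    """
    df = raw.df
    if mode == "public":
        for col in ("comprehension_pass", "sex"):
            if col not in df.columns:
                raise ValueError(f"required column {col!r} missing for exclusions")
        keep = df["comprehension_pass"].astype(bool) & df["sex"].isin(
            ["Male", "Female"]
        )
    elif mode == "personnel":
        if outcome_context in _PERSONNEL_FILTERED_CONTEXTS:
            if "conducted_hct" not in df.columns:
                raise ValueError("required column 'conducted_hct' missing for exclusions")
            keep = ~df["conducted_hct"].astype(bool)
        else:
            keep = pd.Series(True, index=df.index)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return SurveyDataset(
        df=df[keep].reset_index(drop=True),
        items=dict(raw.items),
        demographics=list(raw.demographics),
        levels=dict(raw.levels),
    )


def collapse_support(rating):
    """Collapse a 7-point support scale to oppose (1-3) / neutral (4) /
    support (5-7)."""
    arr = np.asarray(rating)
    scalar = arr.ndim == 0
    arr = np.atleast_1d(arr)
    if np.isnan(arr.astype(float)).any() or ((arr < 1) | (arr > 7)).any():
        raise ValueError("support ratings must lie in 1..7")
    out = np.where(arr <= 3, "oppose", np.where(arr == 4, "neutral", "support"))
    return out[0] if scalar else out


def derive_comparison(a, b, k: int | None = None):
    """Paired comparison category: item A greater than / equal to / less than
    item B per respondent.  Both items must share one K-point scale."""
    scalar = np.ndim(a) == 0 and np.ndim(b) == 0
    a = np.atleast_1d(np.asarray(a, dtype=float))
    b = np.atleast_1d(np.asarray(b, dtype=float))
    if a.shape != b.shape:
        raise ValueError("paired ratings must have equal length")
    if k is not None:
        for v in (a, b):
            ok = np.isnan(v) | ((v >= 1) & (v <= k))
            if not ok.all():
                raise ValueError(f"ratings outside shared 1..{k} scale")
    d = np.sign(a - b)
    out = np.where(d > 0, "greater", np.where(d < 0, "less", "equal")).astype(object)
    out[np.isnan(a) | np.isnan(b)] = None
    return out[0] if scalar else out


def zscore_state_covariate(rates: Mapping[str, float]) -> dict[str, float]:
    """Z-score a state-level covariate across states (sample sd, n-1)."""
    states = list(rates)
    vals = np.array([rates[s] for s in states], dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 states to z-score")
    sd = vals.std(ddof=1)
    if sd == 0:
        raise ValueError("state covariate is constant; cannot z-score")
    z = (vals - vals.mean()) / sd
    return {s: float(v) for s, v in zip(states, z)}
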