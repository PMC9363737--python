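"""Goal-aware phenotype normalization.

Each trait carries a breeding goal: *larger-the-better*, *smaller-the-better*
or *nominal-the-best* (optimum at a breeder-specified target value). Raw
phenotypes y_i are normalized per trait as

    w_i = (y_i - delta * 1_n) / s_i

where delta is the sample mean for larger/smaller goals and the target value
for nominal goals, and s_i is the sample standard deviation (n-1 denominator).
The stored (delta, s) pair back-transforms model outputs to trait units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .genome_io import PhenotypeTable

GOALS = ("larger", "smaller", "nominal")

_GOAL_ALIASES = {
    "larger": "larger",
    "larger-the-better": "larger",
    "smaller": "smaller",
    "smaller-the-better": "smaller",
    "nominal": "nominal",
    "nominal-the-best": "nominal",
}


def canonical_goal(goal: str) -> str:
    try:
        return _GOAL_ALIASES[goal.lower()]
    except KeyError:
        raise ValueError(f"unknown breeding goal {goal!r}; expected one of {GOALS}") from None


@dataclass(frozen=True)
class TraitSpec:
    """Breeding goal, optional nominal target, and selection-index weight for one trait."""

    name: str
    goal: str
    index_weight: float = 1.0
    target: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "goal", canonical_goal(self.goal))
        if self.goal == "nominal" and self.target is None:
            raise ValueError(f"trait {self.name!r}: nominal-the-best goal requires a target value")
        if self.goal != "nominal" and self.target is not None:
            raise ValueError(f"trait {self.name!r}: target is only meaningful for nominal goals")
        if not 0.0 <= self.index_weight <= 1.0:
            raise ValueError(f"trait {self.name!r}: index weight must lie in [0, 1]")


def validate_specs(specs: list[TraitSpec]) -> None:
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate trait names in specs")
    total = sum(s.index_weight for s in specs)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"index weights must sum to 1, got {total}")


@dataclass(frozen=True)
class TraitScaling:
    """Per-trait (delta, s) normalization constants, trait units."""

    delta: dict[str, float]
    s: dict[str, float]

    def __post_init__(self) -> None:
        for trait, sd in self.s.items():
            if not sd > 0:
                raise ValueError(f"trait {trait!r}: scale s must be positive, got {sd}")

    def traits(self) -> list[str]:
        return list(self.delta)


class GoalNormalizer(TransformerMixin, BaseEstimator):
    """Per-trait goal-aware centering and scaling, as an sklearn transformer.

    Parameters
    ----------
    specs : list of TraitSpec
        One spec per trait column, in column order of the fitted data.

    Attributes
    ----------
    scaling_ : TraitScaling
        delta and s per trait, learned from the fitted phenotypes.
    trait_names_ : list of str
    """

    def __init__(self, specs: list[TraitSpec] | None = None):
        self.specs = specs

    def _frame(self, X) -> pd.DataFrame:
        if isinstance(X, PhenotypeTable):
            return X.frame
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        if self.specs is None:
            raise ValueError("specs are required when X carries no column names")
        return pd.DataFrame(X, columns=[s.name for s in self.specs])

    def fit(self, X, y=None) -> "GoalNormalizer":
        if self.specs is None:
            raise ValueError("GoalNormalizer requires trait specs")
        frame = self._frame(X)
        missing = [s.name for s in self.specs if s.name not in frame.columns]
        if missing:
            raise ValueError(f"phenotype data lacks trait columns {missing}")
        if len(frame) < 2:
            raise ValueError("need at least two accessions to estimate scale")
        delta: dict[str, float] = {}
        scale: dict[str, float] = {}
        for spec in self.specs:
            y_i = frame[spec.name].to_numpy(dtype=float)
            s_i = float(np.std(y_i, ddof=1))
            if s_i <= 0:
                raise ValueError(f"trait {spec.name!r} is constant; cannot normalize (s = 0)")
            delta[spec.name] = float(spec.target) if spec.goal == "nominal" else float(np.mean(y_i))
            scale[spec.name] = s_i
        self.scaling_ = TraitScaling(delta, scale)
        self.trait_names_ = [s.name for s in self.specs]
        return self

    def transform(self, X) -> pd.DataFrame:
        self._check_fitted()
        frame = self._frame(X)
        out = {}
        for trait in self.trait_names_:
            out[trait] = (frame[trait].to_numpy(dtype=float) - self.scaling_.delta[trait]) / self.scaling_.s[trait]
        return pd.DataFrame(out, index=frame.index)

    def inverse_transform(self, W) -> pd.DataFrame:
        self._check_fitted()
        frame = W if isinstance(W, pd.DataFrame) else pd.DataFrame(np.asarray(W, dtype=float), columns=self.trait_names_)
        out = {}
        for trait in frame.columns:
            out[trait] = frame[trait].to_numpy(dtype=float) * self.scaling_.s[trait] + self.scaling_.delta[trait]
        return pd.DataFrame(out, index=frame.index)

    def _check_fitted(self) -> None:
        if not hasattr(self, "scaling_"):
            raise ValueError("GoalNormalizer is not fitted")


def normalize_traits(phenos: PhenotypeTable, specs: list[TraitSpec]) -> tuple[pd.DataFrame, TraitScaling]:
    """Normalize raw phenotypes per trait; returns (normalized matrix w, scaling)."""
    validate_specs(specs)
    norm = GoalNormalizer(specs).fit(phenos)
    return norm.transform(phenos), norm.scaling_


def back_transform(values, scaling: TraitScaling, trait: str):
    """Map normalized-scale values back to trait units: values * s + delta."""
    if trait not in scaling.delta:
        raise KeyError(f"unknown trait {trait!r}; scaling covers {scaling.traits()}")
    arr = np.asarray(values, dtype=float)
    out = arr * scaling.s[trait] + scaling.delta[trait]
    return float(out) if np.isscalar(values) or arr.ndim == 0 else out
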