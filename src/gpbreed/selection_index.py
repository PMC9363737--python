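"""Breeding-goal-aware selection index.

A normalized GEBV is turned into a goal-aligned score Z per trait:
Z = GEBV (larger-the-better), Z = -GEBV (smaller-the-better),
Z = -|GEBV| (nominal-the-best; the normalized optimum is 0, i.e. the
phenotype equals the target after back-transform). The composite index is
SI = sum_i w_i Z_i with pre-specified non-negative weights summing to 1;
larger SI means better composite performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalization import TraitSpec, canonical_goal


@dataclass(frozen=True)
class IndexWeights:
    """Per-trait index weights; non-negative, summing to 1."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()), dtype=float)
        if (vals < 0).any():
            raise ValueError("index weights must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-12:
            raise ValueError(f"index weights must sum to 1 (got {vals.sum()!r})")

    @classmethod
    def from_specs(cls, specs: list[TraitSpec]) -> "IndexWeights":
        return cls({s.name: s.index_weight for s in specs})

    def aligned(self, traits: list[str]) -> np.ndarray:
        missing = set(traits) ^ set(self.weights)
        if missing:
            raise ValueError(f"weight/trait mismatch on {sorted(missing)}")
        return np.array([self.weights[t] for t in traits], dtype=float)


def trait_score(gebv, goal: str):
    """Goal-aligned score Z for normalized GEBV(s); larger Z is always better."""
    goal = canonical_goal(goal)
    arr = np.asarray(gebv, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("GEBV values must be finite")
    if goal == "larger":
        out = arr
    elif goal == "smaller":
        out = -arr
    else:  # nominal
        out = -np.abs(arr)
    return float(out) if out.ndim == 0 else out


def selection_index(Z, weights) -> np.ndarray | pd.Series:
    """Composite index SI = Z @ w over aligned trait columns."""
    if isinstance(Z, pd.DataFrame):
        w = weights.aligned(list(Z.columns)) if isinstance(weights, IndexWeights) else np.asarray(weights, float)
        if len(w) != Z.shape[1]:
            raise ValueError(f"{len(w)} weights for {Z.shape[1]} traits")
        return pd.Series(Z.to_numpy(dtype=float) @ w, index=Z.index, name="SI")
    Zv = np.atleast_2d(np.asarray(Z, dtype=float))
    if isinstance(weights, IndexWeights):
        raise ValueError("IndexWeights require a labelled DataFrame of scores")
    w = np.asarray(weights, dtype=float)
    if Zv.shape[1] != len(w):
        raise ValueError(f"{len(w)} weights for {Zv.shape[1]} traits")
    return Zv @ w


def compute_selection_index(gebv: pd.DataFrame, specs: list[TraitSpec]) -> pd.Series:
    """SI per individual from normalized GEBVs and trait specs (goal + weight)."""
    missing = [s.name for s in specs if s.name not in gebv.columns]
    if missing:
        raise ValueError(f"GEBV table lacks traits {missing}")
    Z = pd.DataFrame(
        {s.name: trait_score(gebv[s.name].to_numpy(dtype=float), s.goal) for s in specs},
        index=gebv.index,
    )
    w = np.array([s.index_weight for s in specs], dtype=float)
    return pd.Series(Z.to_numpy() @ w, index=gebv.index, name="SI")


def improvement_rate(gebv_multi: float, gebv_single: float) -> float:
    """Percent change of the multi-trait-selected GEBV relative to single-trait selection.

    IR = (GEBV_multi - GEBV_single) / GEBV_single * 100.
    """
    if gebv_single == 0:
        raise ZeroDivisionError("single-trait reference GEBV is zero; improvement rate undefined")
    return (gebv_multi - gebv_single) / gebv_single * 100.0


def rank_by_index(si: pd.Series) -> pd.Series:
    """SI sorted best-first; ties broken by accession id (deterministic reporting)."""
    order = sorted(si.index, key=lambda i: (-si[i], str(i)))
    return si.loc[order]
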