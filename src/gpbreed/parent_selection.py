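"""Parental-subset selection strategies.

Three strategies pick ``n_parents`` accessions from the candidates:

* GEBV-O — the top ``n_parents`` by selection index (pure truncation).
* GD-O — from the above-average-SI pool S_c, the subset maximizing the
  D-score, the determinant of the genomic relationship submatrix (a
  trait-independent diversity measure).
* GEBV-GD — the top ``n_keep`` accessions by SI are fixed, and the rest of
  the subset is chosen from S_c to maximize the D-score of the whole subset.

Subset search is exhaustive when the number of combinations is small enough,
otherwise greedy forward selection on marginal log-determinant gain followed
by steepest-ascent single-swap exchange. Log-determinants are compared via
(rank, logdet) so rank-deficient (zero-determinant) subsets always lose.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-10


@dataclass(frozen=True)
class SelectionResult:
    strategy: str
    chosen: list[str]
    d_score: float
    si_values: dict[str, float]
    search_mode: str = "exhaustive"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"accession": self.chosen, "SI": [self.si_values[c] for c in self.chosen]}
        ).assign(strategy=self.strategy, d_score=self.d_score)


def _as_kframe(K, ids=None) -> pd.DataFrame:
    if isinstance(K, pd.DataFrame):
        return K
    K = np.asarray(K, dtype=float)
    if ids is None:
        raise ValueError("ids are required when K is a bare array")
    return pd.DataFrame(K, index=list(ids), columns=list(ids))


def candidate_set(si: pd.Series) -> list[str]:
    """S_c: ids whose selection index is strictly above the candidate mean."""
    if len(si) < 1:
        raise ValueError("empty selection-index vector")
    mean = float(si.mean())
    return [str(i) for i in si.index[si.to_numpy(dtype=float) > mean]]


def d_score(K, subset, ids=None) -> float:
    """Determinant of the principal submatrix of K for the given accession ids."""
    Kf = _as_kframe(K, ids)
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    unknown = [s for s in subset if s not in Kf.index]
    if unknown:
        raise KeyError(f"ids not in relationship matrix: {unknown}")
    sub = Kf.loc[subset, subset].to_numpy(dtype=float)
    return float(np.linalg.det(sub))


def _subset_key(Ksub: np.ndarray) -> tuple[int, float]:
    """(rank, log-determinant) ranking key; singular subsets sort below any PD subset."""
    vals = np.linalg.eigvalsh((Ksub + Ksub.T) / 2.0)
    tol = _EIG_TOL * max(1.0, float(abs(vals).max()))
    pos = vals[vals > tol]
    rank = int(len(pos))
    logdet = float(np.sum(np.log(pos))) if rank else -np.inf
    if rank < Ksub.shape[0]:
        return (rank, logdet)
    return (Ksub.shape[0], logdet)


def _exhaustive_best(K: np.ndarray, free: list[int], k_free: int, fixed: list[int]) -> list[int]:
    best_key = None
    best: list[int] | None = None
    for combo in combinations(free, k_free):
        idx = fixed + list(combo)
        key = _subset_key(K[np.ix_(idx, idx)])
        if best_key is None or key > best_key:
            best_key, best = key, list(combo)
    assert best is not None
    return best


def _greedy_exchange_best(K: np.ndarray, free: list[int], k_free: int, fixed: list[int]) -> list[int]:
    chosen: list[int] = []
    # greedy forward: add the candidate with the best marginal (rank, logdet) gain
    for _ in range(k_free):
        best_key, best_j = None, None
        for j in free:
            if j in chosen:
                continue
            idx = fixed + chosen + [j]
            key = _subset_key(K[np.ix_(idx, idx)])
            if best_key is None or key > best_key:
                best_key, best_j = key, j
        chosen.append(best_j)
    # steepest-ascent 1-swap exchange to a local optimum
    current_key = _subset_key(K[np.ix_(fixed + chosen, fixed + chosen)])
    improved = True
    while improved:
        improved = False
        best_key, best_swap = current_key, None
        for pos, out in enumerate(chosen):
            for j in free:
                if j in chosen:
                    continue
                trial = chosen[:pos] + [j] + chosen[pos + 1 :]
                idx = fixed + trial
                key = _subset_key(K[np.ix_(idx, idx)])
                if key > best_key:
                    best_key, best_swap = key, (pos, j)
        if best_swap is not None:
            pos, j = best_swap
            chosen[pos] = j
            current_key = best_key
            improved = True
    return chosen


def _max_dscore_subset(
    Kf: pd.DataFrame,
    pool: list[str],
    k_free: int,
    fixed_ids: list[str],
    exhaustive_cap: int,
) -> tuple[list[str], str]:
    ids = fixed_ids + [p for p in pool if p not in fixed_ids]
    K = Kf.loc[ids, ids].to_numpy(dtype=float)
    pos = {a: i for i, a in enumerate(ids)}
    fixed = [pos[a] for a in fixed_ids]
    free = sorted(pos[a] for a in pool if a not in fixed_ids)  # deterministic candidate order
    if comb(len(free), k_free) <= exhaustive_cap:
        chosen = _exhaustive_best(K, free, k_free, fixed)
        mode = "exhaustive"
    else:
        chosen = _greedy_exchange_best(K, free, k_free, fixed)
        mode = "greedy-exchange"
        logger.info(
            "D-score search: C(%d,%d) exceeds cap %d; using greedy+exchange heuristic",
            len(free), k_free, exhaustive_cap,
        )
    inv = {i: a for a, i in pos.items()}
    return [inv[i] for i in fixed + sorted(chosen)], mode


def _si_order(si: pd.Series) -> list[str]:
    return sorted((str(i) for i in si.index), key=lambda i: (-float(si[i]), i))


def select_gebv_o(si: pd.Series, n_parents: int) -> SelectionResult:
    """GEBV-O: the n_parents accessions with the highest selection index."""
    if len(si) < n_parents:
        raise ValueError(f"only {len(si)} candidates for n_parents={n_parents}")
    chosen = _si_order(si)[:n_parents]
    return SelectionResult(
        strategy="GEBV-O",
        chosen=chosen,
        d_score=np.nan,
        si_values={c: float(si[c]) for c in chosen},
    )


def attach_d_score(result: SelectionResult, K, ids=None) -> SelectionResult:
    return SelectionResult(
        result.strategy, result.chosen, d_score(K, result.chosen, ids), result.si_values, result.search_mode
    )


def select_gd_o(
    si: pd.Series,
    K,
    n_parents: int,
    ids=None,
    exhaustive_cap: int = 1_000_000,
) -> SelectionResult:
    """GD-O: the subset of S_c maximizing the D-score."""
    Kf = _as_kframe(K, ids)
    sc = candidate_set(si)
    if len(sc) < n_parents:
        raise ValueError(
            f"candidate set S_c has {len(sc)} accessions, fewer than n_parents={n_parents}"
        )
    chosen, mode = _max_dscore_subset(Kf, sc, n_parents, [], exhaustive_cap)
    chosen = sorted(chosen)
    return SelectionResult(
        strategy="GD-O",
        chosen=chosen,
        d_score=d_score(Kf, chosen),
        si_values={c: float(si[c]) for c in chosen},
        search_mode=mode,
    )


def select_gebv_gd(
    si: pd.Series,
    K,
    n_parents: int,
    n_keep: int = 2,
    ids=None,
    exhaustive_cap: int = 1_000_000,
) -> SelectionResult:
    """GEBV-GD: fix the top n_keep by SI, fill the rest from S_c by maximal D-score."""
    if not 0 < n_keep < n_parents:
        raise ValueError(f"n_keep must satisfy 0 < n_keep < n_parents (got {n_keep}/{n_parents})")
    Kf = _as_kframe(K, ids)
    sc = candidate_set(si)
    if len(sc) < n_parents:
        raise ValueError(
            f"candidate set S_c has {len(sc)} accessions, fewer than n_parents={n_parents}"
        )
    fixed = _si_order(si)[:n_keep]
    pool = [c for c in sc if c not in fixed]
    chosen, mode = _max_dscore_subset(Kf, pool, n_parents - n_keep, fixed, exhaustive_cap)
    chosen = fixed + sorted(c for c in chosen if c not in fixed)
    return SelectionResult(
        strategy="GEBV-GD",
        chosen=chosen,
        d_score=d_score(Kf, chosen),
        si_values={c: float(si[c]) for c in chosen},
        search_mode=mode,
    )
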