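"""Breeding-program orchestration.

Pipeline, per strategy: (1) normalize phenotypes and fit the multi-trait
GBLUP model on the training accessions; (2) rank candidates by selection
index and pick a parental subset; (3) cross all parent pairs (half-diallel)
into F1, self each F1 into F2; (4) repeat predict -> truncation-select ->
self until the final generation of presumed-fixed inbred lines; (5) repeat
the stochastic progeny phase across independent repetitions and summarize
genetic gains with LSD mean comparisons.

All selection during the cycle uses the normalized-scale selection index;
every reported GEBV is back-transformed to trait units. Variance components
and the parental subsets are computed once (they are deterministic given the
training data); only the progeny simulation is replicated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .gblup import MultiTraitGBLUP
from .genome_io import GenotypeMatrix, LinkageMap, PhenotypeTable
from .normalization import GoalNormalizer, TraitSpec, validate_specs
from .parent_selection import (
    SelectionResult,
    attach_d_score,
    select_gebv_gd,
    select_gebv_o,
    select_gd_o,
)
from .progeny_sim import Population, half_diallel, phase_accession, self_pollinate
from .selection_index import compute_selection_index, improvement_rate

logger = logging.getLogger(__name__)

STRATEGIES = ("GEBV-O", "GD-O", "GEBV-GD")


@dataclass(frozen=True)
class BreedingConfig:
    """Experimental constants of the breeding design.

    Defaults follow the standard design: 10 parents, top-2 retention for
    GEBV-GD, 45 selected individuals per generation each selfed into 60
    offspring (so 2,700 individuals per generation from F2 on), termination
    at F10, 30 repetitions.
    """

    n_parents: int = 10
    n_keep: int = 2
    n_select_per_gen: int = 45
    n_offspring: int = 60
    final_generation: int = 10
    n_repetitions: int = 30
    strategies: tuple[str, ...] = STRATEGIES
    exhaustive_cap: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_select_per_gen < 1 or self.n_offspring < 1:
            raise ValueError("n_select_per_gen and n_offspring must be >= 1")
        if self.final_generation < 2:
            raise ValueError("final generation must be F2 or later")
        unknown = set(self.strategies) - set(STRATEGIES)
        if unknown:
            raise ValueError(f"unknown strategies {sorted(unknown)}")


@dataclass
class CycleResult:
    """One repetition of the progeny phase for one parental subset."""

    final_population: Population
    trace: pd.DataFrame  # per generation: best-line + mean GEBVs, trait units
    f10_gebv: pd.DataFrame  # back-transformed GEBVs of the final population
    best_f10_gebv: pd.Series  # back-transformed GEBVs of the max-SI final line


@dataclass
class GainReport:
    """Summary of a full multi-repetition experiment."""

    summary: pd.DataFrame  # per (strategy, weights, trait): GEBV_P, GEBV_F10, gain, letter
    parent_gebv: pd.DataFrame  # per (strategy, weights): parental mean GEBVs, trait units
    best_f10: pd.DataFrame  # per (strategy, weights, repetition, trait): best-line GEBV
    traces: pd.DataFrame  # per-generation best-line trace, all cells and repetitions
    improvement: pd.DataFrame | None  # Eq.-style IR between weight settings, if >= 2
    lsd_letters: dict[str, dict[str, str]]  # trait -> cell -> letters
    config: BreedingConfig


# ---------------------------------------------------------------------------
# genetic gain
# ---------------------------------------------------------------------------


def genetic_gain(gebv_parents, gebv_f10) -> float:
    """mean(GEBV_F10) - mean(GEBV_P), on the original trait scale."""
    return float(np.mean(gebv_f10) - np.mean(gebv_parents))


def genetic_gain_nominal(gebv_parents, gebv_f10, target: float) -> float:
    """mean(|GEBV_F10 - target|) - mean(|GEBV_P - target|); negative is improvement."""
    return float(np.mean(np.abs(np.asarray(gebv_f10, dtype=float) - target))
                 - np.mean(np.abs(np.asarray(gebv_parents, dtype=float) - target)))


def gain_for_spec(spec: TraitSpec, gebv_parents, gebv_f10) -> float:
    if spec.goal == "nominal":
        return genetic_gain_nominal(gebv_parents, gebv_f10, spec.target)
    return genetic_gain(gebv_parents, gebv_f10)


# ---------------------------------------------------------------------------
# LSD comparisons
# ---------------------------------------------------------------------------


def lsd_compare(groups: dict[str, np.ndarray], alpha: float = 0.01) -> tuple[dict[str, str], float]:
    """Least-significant-difference mean comparison with compact letters.

    One-way ANOVA pooled MSE; LSD = t_{1-alpha/2, N-k} * sqrt(2 MSE / n);
    means within LSD of each other share a letter. Groups must have equal
    replication. Letters are assigned greatest-mean-first via maximal runs
    of mutually non-significant means (exact for a distance-threshold test).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    sizes = {k: len(np.asarray(v)) for k, v in groups.items()}
    n = next(iter(sizes.values()))
    if any(s != n for s in sizes.values()):
        raise ValueError(f"unequal group sizes {sizes}; LSD assumes balanced groups")
    k = len(groups)
    df_err = k * (n - 1)
    means = {g: float(np.mean(v)) for g, v in groups.items()}
    if df_err <= 0:
        lsd = 0.0
    else:
        sse = sum(float(np.sum((np.asarray(v, float) - means[g]) ** 2)) for g, v in groups.items())
        mse = sse / df_err
        lsd = float(stats.t.ppf(1 - alpha / 2, df_err) * np.sqrt(2 * mse / n))

    order = sorted(means, key=lambda g: (-means[g], g))
    runs: list[tuple[int, int]] = []
    for i in range(k):
        j = i
        while j + 1 < k and means[order[i]] - means[order[j + 1]] <= lsd:
            j += 1
        if not runs or runs[-1][1] < j or runs[-1][0] > i:
            if runs and runs[-1][0] <= i and runs[-1][1] >= j:
                continue
            runs.append((i, j))
    letters = {g: "" for g in order}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for letter_idx, (lo, hi) in enumerate(runs):
        for g in order[lo : hi + 1]:
            letters[g] += alphabet[letter_idx % len(alphabet)]
    return letters, lsd


# ---------------------------------------------------------------------------
# breeding cycle
# ---------------------------------------------------------------------------


def _predict_si(pop: Population, model: MultiTraitGBLUP, specs: list[TraitSpec]):
    geno = pop.genotype_matrix(markers=model.marker_ids_)
    gebv = model.predict(geno)
    si = compute_selection_index(gebv, specs)
    return gebv, si


def _truncate(pop: Population, si: pd.Series, n_select: int) -> list:
    order = sorted(range(len(pop)), key=lambda i: (-float(si.iloc[i]), pop.individuals[i].id))
    return [pop.individuals[i] for i in order[:n_select]]


def advance_generation(
    pop: Population,
    model: MultiTraitGBLUP,
    specs: list[TraitSpec],
    cfg: BreedingConfig,
    lmap: LinkageMap,
    rng: np.random.Generator,
    generation: str,
) -> Population:
    """Predict GEBVs, truncation-select the top by SI, self each selectee."""
    _, si = _predict_si(pop, model, specs)
    n_select = cfg.n_select_per_gen
    if len(pop) < n_select:
        logger.warning("population of %d smaller than n_select_per_gen=%d; selecting all", len(pop), n_select)
        n_select = len(pop)
    selected = _truncate(pop, si, n_select)
    offspring = []
    for ind in selected:
        offspring.extend(self_pollinate(ind, lmap, cfg.n_offspring, rng, generation=generation).individuals)
    return Population(offspring, generation)


def _trace_row(pop: Population, model, specs, normalizer: GoalNormalizer, generation: str) -> dict:
    gebv, si = _predict_si(pop, model, specs)
    back = normalizer.inverse_transform(gebv)
    best = si.idxmax() if si.is_unique else si.sort_values(ascending=False).index[0]
    row = {"generation": generation, "best_id": str(best)}
    for trait in back.columns:
        row[f"best_{trait}"] = float(back.loc[best, trait])
        row[f"mean_{trait}"] = float(back[trait].mean())
    return row


def run_breeding_cycle(
    parents: Population,
    model: MultiTraitGBLUP,
    specs: list[TraitSpec],
    cfg: BreedingConfig,
    lmap: LinkageMap,
    rng: np.random.Generator,
    normalizer: GoalNormalizer,
) -> CycleResult:
    """Half-diallel F1, selfed F2, then truncation-selected selfing to the final generation."""
    trace_rows = [_trace_row(parents, model, specs, normalizer, "P")]

    f1 = half_diallel(parents, lmap, rng)
    trace_rows.append(_trace_row(f1, model, specs, normalizer, "F1"))

    f2_inds = []
    for ind in f1.individuals:
        f2_inds.extend(self_pollinate(ind, lmap, cfg.n_offspring, rng, generation="F2").individuals)
    pop = Population(f2_inds, "F2")
    trace_rows.append(_trace_row(pop, model, specs, normalizer, "F2"))

    for gen_number in range(3, cfg.final_generation + 1):
        gen = f"F{gen_number}"
        pop = advance_generation(pop, model, specs, cfg, lmap, rng, generation=gen)
        trace_rows.append(_trace_row(pop, model, specs, normalizer, gen))

    gebv, si = _predict_si(pop, model, specs)
    back = normalizer.inverse_transform(gebv)
    best = si.sort_values(ascending=False).index[0]
    return CycleResult(
        final_population=pop,
        trace=pd.DataFrame(trace_rows),
        f10_gebv=back,
        best_f10_gebv=back.loc[best],
    )


# ---------------------------------------------------------------------------
# full experiment
# ---------------------------------------------------------------------------


def select_parents(
    strategy: str,
    si: pd.Series,
    K: pd.DataFrame,
    cfg: BreedingConfig,
) -> SelectionResult:
    if strategy == "GEBV-O":
        return attach_d_score(select_gebv_o(si, cfg.n_parents), K)
    if strategy == "GD-O":
        return select_gd_o(si, K, cfg.n_parents, exhaustive_cap=cfg.exhaustive_cap)
    if strategy == "GEBV-GD":
        return select_gebv_gd(si, K, cfg.n_parents, n_keep=cfg.n_keep, exhaustive_cap=cfg.exhaustive_cap)
    raise ValueError(f"unknown strategy {strategy!r}")


def _weights_label(specs: list[TraitSpec]) -> str:
    return "(" + ", ".join(f"{s.index_weight:g}" for s in specs) + ")"


def run_experiment(
    geno: GenotypeMatrix,
    lmap: LinkageMap,
    phenos: PhenotypeTable,
    specs: list[TraitSpec],
    cfg: BreedingConfig,
    weight_settings: list[tuple[float, ...]] | None = None,
) -> GainReport:
    """Train once, select parents per strategy and weight setting, replicate the
    stochastic progeny phase, and summarize gains with LSD letters.

    ``weight_settings`` overrides the specs' index weights; with two or more
    settings an improvement-rate table is computed for each setting relative
    to the last one (conventionally the single-trait baseline).
    """
    validate_specs(specs)
    if weight_settings is None:
        weight_settings = [tuple(s.index_weight for s in specs)]

    # --- Step 1: normalize + fit (deterministic, shared by all cells)
    normalizer = GoalNormalizer(specs).fit(phenos)
    W = normalizer.transform(phenos)
    train_geno = geno.select_accessions(phenos.accessions)
    model = MultiTraitGBLUP().fit(train_geno, W)
    gebv_train = model.fitted_values()
    K = pd.DataFrame(model.K_, index=train_geno.accessions, columns=train_geno.accessions)

    root_seq = np.random.SeedSequence(cfg.seed)
    phase_rng = np.random.default_rng(root_seq.spawn(1)[0])

    summary_rows = []
    best_rows = []
    trace_frames = []
    parent_rows = []
    gains_by_cell: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    best_means: dict[tuple[str, str], dict[str, float]] = {}

    for w_idx, weights in enumerate(weight_settings):
        if len(weights) != len(specs):
            raise ValueError(f"weight setting {weights} has wrong arity for {len(specs)} traits")
        cell_specs = [replace(s, index_weight=w) for s, w in zip(specs, weights)]
        label = _weights_label(cell_specs)
        si = compute_selection_index(gebv_train, cell_specs)

        for s_idx, strategy in enumerate(cfg.strategies):
            result = select_parents(strategy, si, K, cfg)
            parents = Population(
                [
                    phase_accession(
                        acc,
                        train_geno.codes[train_geno.accessions.index(acc)],
                        phase_rng,
                    )
                    for acc in result.chosen
                ],
                "P",
            )
            parent_back = normalizer.inverse_transform(gebv_train.loc[result.chosen])
            parent_rows.append(
                {"strategy": strategy, "weights": label, "d_score": result.d_score,
                 **{t: float(parent_back[t].mean()) for t in parent_back.columns}}
            )

            rep_gains: dict[str, list[float]] = {s.name: [] for s in specs}
            rep_best: dict[str, list[float]] = {s.name: [] for s in specs}
            f10_means: dict[str, list[float]] = {s.name: [] for s in specs}
            for rep in range(cfg.n_repetitions):
                rng = np.random.default_rng(
                    np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1 + w_idx, s_idx, rep))
                )
                cycle = run_breeding_cycle(parents, model, cell_specs, cfg, lmap, rng, normalizer)
                for spec in cell_specs:
                    gain = gain_for_spec(spec, parent_back[spec.name], cycle.f10_gebv[spec.name])
                    rep_gains[spec.name].append(gain)
                    rep_best[spec.name].append(float(cycle.best_f10_gebv[spec.name]))
                    f10_means[spec.name].append(float(cycle.f10_gebv[spec.name].mean()))
                    best_rows.append(
                        {"strategy": strategy, "weights": label, "repetition": rep,
                         "trait": spec.name, "best_f10_gebv": float(cycle.best_f10_gebv[spec.name])}
                    )
                trace_frames.append(
                    cycle.trace.assign(strategy=strategy, weights=label, repetition=rep)
                )

            cell = (strategy, label)
            gains_by_cell[cell] = {t: np.asarray(v) for t, v in rep_gains.items()}
            best_means[cell] = {t: float(np.mean(v)) for t, v in rep_best.items()}
            for spec in cell_specs:
                summary_rows.append(
                    {
                        "strategy": strategy,
                        "weights": label,
                        "trait": spec.name,
                        "goal": spec.goal,
                        "gebv_p": float(parent_back[spec.name].mean())
                        if spec.goal != "nominal"
                        else float(np.mean(np.abs(parent_back[spec.name] - spec.target))),
                        "gebv_f10": float(np.mean(f10_means[spec.name]))
                        if spec.goal != "nominal"
                        else float(np.mean([g + np.mean(np.abs(parent_back[spec.name] - spec.target))
                                            for g in rep_gains[spec.name]])),
                        "gain": float(np.mean(rep_gains[spec.name])),
                        "best_f10_mean": best_means[cell][spec.name],
                    }
                )

    summary = pd.DataFrame(summary_rows)

    # --- LSD letters on per-repetition gains, per trait across cells
    lsd_letters: dict[str, dict[str, str]] = {}
    cells = list(gains_by_cell)
    if len(cells) >= 2 and cfg.n_repetitions >= 2:
        for spec in specs:
            groups = {f"{s} {w}": gains_by_cell[(s, w)][spec.name] for s, w in cells}
            letters, _ = lsd_compare(groups, alpha=0.01)
            lsd_letters[spec.name] = letters
            summary.loc[summary["trait"] == spec.name, "letter"] = [
                letters[f"{r.strategy} {r.weights}"]
                for r in summary[summary["trait"] == spec.name].itertuples()
            ]

    # --- improvement rate between weight settings (multi vs the last setting)
    improvement = None
    if len(weight_settings) >= 2:
        base_label = _weights_label([replace(s, index_weight=w) for s, w in zip(specs, weight_settings[-1])])
        rows = []
        for (strategy, label), means in best_means.items():
            if label == base_label:
                continue
            base = best_means.get((strategy, base_label))
            if base is None:
                continue
            for trait, m in means.items():
                if base[trait] != 0:
                    rows.append(
                        {"strategy": strategy, "weights": label, "baseline": base_label,
                         "trait": trait, "IR_percent": improvement_rate(m, base[trait])}
                    )
        improvement = pd.DataFrame(rows)

    return GainReport(
        summary=summary,
        parent_gebv=pd.DataFrame(parent_rows),
        best_f10=pd.DataFrame(best_rows),
        traces=pd.concat(trace_frames, ignore_index=True),
        improvement=improvement,
        lsd_letters=lsd_letters,
        config=cfg,
    )
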