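"""Meiosis, crossing and self-pollination under the Haldane mapping function.

Individuals are phased: two haplotypes per individual, each a per-marker
allele vector coded +1 (major allele) / -1 (minor allele), so the genotype
code at a locus is (allele1 + allele2)/2 in {-1, 0, 1}.

Gametes are generated chromosome by chromosome as a two-state Markov chain
along the marker order: the starting haplotype is chosen with probability
1/2, and between adjacent markers at map distance d Morgans the chain
switches haplotypes with probability r = (1 - exp(-2d))/2 — the Haldane
recombination fraction, which assumes no crossover interference. Independent
switch events between intervals are exactly the no-interference model, so no
explicit crossover-count sampling is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .genome_io import GenotypeMatrix, LinkageMap


def haldane_r(d) -> float | np.ndarray:
    """Recombination fraction r = (1 - exp(-2d))/2 for map distance d in Morgans."""
    arr = np.asarray(d, dtype=float)
    if np.any(arr < 0):
        raise ValueError("map distance must be non-negative")
    r = (1.0 - np.exp(-2.0 * arr)) / 2.0
    return float(r) if r.ndim == 0 else r


@dataclass(frozen=True)
class PhasedIndividual:
    """Two haplotypes (+1/-1 allele vectors) plus pedigree metadata."""

    id: str
    hap1: np.ndarray
    hap2: np.ndarray
    generation: str = "P"
    parents: tuple[str, str] | None = None

    def __post_init__(self) -> None:
        h1 = np.asarray(self.hap1, dtype=np.int8)
        h2 = np.asarray(self.hap2, dtype=np.int8)
        if h1.shape != h2.shape or h1.ndim != 1:
            raise ValueError("haplotypes must be 1-D arrays of equal length")
        for h in (h1, h2):
            if not np.isin(h, (-1, 1)).all():
                raise ValueError("haplotype alleles must be +1 or -1")
        object.__setattr__(self, "hap1", h1)
        object.__setattr__(self, "hap2", h2)

    @property
    def p(self) -> int:
        return len(self.hap1)

    def genotype_codes(self) -> np.ndarray:
        return ((self.hap1.astype(np.int16) + self.hap2) // 2).astype(np.int8)

    def heterozygosity(self) -> float:
        return float(np.mean(self.hap1 != self.hap2))


@dataclass(frozen=True)
class Population:
    individuals: list[PhasedIndividual]
    generation: str

    def __post_init__(self) -> None:
        if not self.individuals:
            raise ValueError("population must be non-empty")
        p = self.individuals[0].p
        if any(ind.p != p for ind in self.individuals):
            raise ValueError("individuals carry differing marker counts")

    def __len__(self) -> int:
        return len(self.individuals)

    @property
    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def genotype_matrix(self, markers: list[str] | None = None) -> GenotypeMatrix:
        codes = np.stack([ind.genotype_codes() for ind in self.individuals])
        if markers is None:
            markers = [f"m{j}" for j in range(codes.shape[1])]
        return GenotypeMatrix(self.ids, markers, codes)

    def mean_heterozygosity(self) -> float:
        return float(np.mean([ind.heterozygosity() for ind in self.individuals]))

    def pedigree(self) -> list[tuple[str, str, str, str]]:
        return [
            (ind.id, *(ind.parents or ("", "")), ind.generation) for ind in self.individuals
        ]


def phase_accession(accession_id: str, codes, rng: np.random.Generator, generation: str = "P") -> PhasedIndividual:
    """Phase a coded genotype row: homozygotes deterministic, heterozygotes random phase."""
    codes = np.asarray(codes, dtype=np.int8)
    if not np.isin(codes, (-1, 0, 1)).all():
        raise ValueError("genotype codes must be -1/0/1")
    hap1 = np.where(codes != 0, codes, 0).astype(np.int8)
    hap2 = hap1.copy()
    het = codes == 0
    if het.any():
        flips = rng.integers(0, 2, size=int(het.sum())).astype(np.int8)
        hap1[het] = np.where(flips == 1, 1, -1)
        hap2[het] = -hap1[het]
    return PhasedIndividual(accession_id, hap1, hap2, generation=generation)


def switch_probabilities(lmap: LinkageMap) -> np.ndarray:
    """Per-marker haplotype-switch probability for the gamete Markov chain.

    r_j = haldane_r(d_j) within a chromosome; 1/2 at each chromosome start,
    which both randomizes the starting haplotype and makes chromosomes
    independent.
    """
    r = haldane_r(lmap.adjacent_distances_morgans())
    r = np.asarray(r, dtype=float).copy()
    r[lmap.chrom_start_mask()] = 0.5
    return r


def make_gametes(ind: PhasedIndividual, lmap: LinkageMap, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n gametes (n x p, alleles +1/-1) from a phased individual."""
    if lmap.n_markers != ind.p:
        raise ValueError(f"linkage map has {lmap.n_markers} markers, individual has {ind.p}")
    q = switch_probabilities(lmap)
    switches = rng.random((n, ind.p)) < q[None, :]
    # cumulative XOR: state 0/1 picks hap1/hap2; Bern(1/2) at chromosome
    # starts re-randomizes the state, decoupling chromosomes
    state = np.cumsum(switches, axis=1) % 2
    return np.where(state == 0, ind.hap1[None, :], ind.hap2[None, :]).astype(np.int8)


def make_gamete(ind: PhasedIndividual, lmap: LinkageMap, rng: np.random.Generator) -> np.ndarray:
    """Draw a single gamete haplotype."""
    return make_gametes(ind, lmap, 1, rng)[0]


def cross(
    p1: PhasedIndividual,
    p2: PhasedIndividual,
    lmap: LinkageMap,
    n_offspring: int,
    rng: np.random.Generator,
    generation: str = "F1",
) -> Population:
    """Cross two parents; each offspring receives one gamete from each."""
    if n_offspring < 1:
        raise ValueError("n_offspring must be at least 1")
    if p1.p != p2.p:
        raise ValueError("parents carry differing marker counts")
    g1 = make_gametes(p1, lmap, n_offspring, rng)
    g2 = make_gametes(p2, lmap, n_offspring, rng)
    offspring = [
        PhasedIndividual(
            id=f"{p1.id}x{p2.id}/{i}",
            hap1=g1[i],
            hap2=g2[i],
            generation=generation,
            parents=(p1.id, p2.id),
        )
        for i in range(n_offspring)
    ]
    return Population(offspring, generation)


def self_pollinate(
    ind: PhasedIndividual,
    lmap: LinkageMap,
    n_offspring: int,
    rng: np.random.Generator,
    generation: str | None = None,
) -> Population:
    """Self an individual: each offspring gets two independent gametes from it."""
    if n_offspring < 1:
        raise ValueError("n_offspring must be at least 1")
    gen = generation or f"{ind.generation}-self"
    g = make_gametes(ind, lmap, 2 * n_offspring, rng)
    offspring = [
        PhasedIndividual(
            id=f"{ind.id}/s{i}",
            hap1=g[2 * i],
            hap2=g[2 * i + 1],
            generation=gen,
            parents=(ind.id, ind.id),
        )
        for i in range(n_offspring)
    ]
    return Population(offspring, gen)


def half_diallel(
    parents: Population,
    lmap: LinkageMap,
    rng: np.random.Generator,
    n_offspring_per_cross: int = 1,
) -> Population:
    """Cross every unordered pair of parents once (no selfs, no reciprocals).

    k parents yield C(k,2) crosses; with one offspring per cross the F1
    population has k(k-1)/2 hybrids.
    """
    inds = parents.individuals
    if len(inds) < 2:
        raise ValueError("half-diallel needs at least two parents")
    offspring: list[PhasedIndividual] = []
    for i in range(len(inds)):
        for j in range(i + 1, len(inds)):
            pop = cross(inds[i], inds[j], lmap, n_offspring_per_cross, rng, generation="F1")
            offspring.extend(pop.individuals)
    return Population(offspring, "F1")
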