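"""Synthetic founder genomes and phenotypes with known variance components.

The generator emulates the structure the GBLUP model assumes: a panel of
(mostly inbred) founder accessions genotyped at mapped biallelic SNPs, with
multivariate additive genetic values covarying across individuals through
the genomic relationship matrix K and across traits through a chosen
Sigma_A, plus iid multivariate residuals with covariance Sigma_e. True
genetic values are returned so that variance-component recovery and
prediction accuracy can be tested against a known truth. Two genetic
architectures are available: dense (genetic values drawn directly from
MVN(0, Sigma_A (x) K)) and sparse (a set of QTL markers with correlated
effects, rescaled so the realized genetic covariance equals Sigma_A).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import GenotypeMatrix, LinkageMap, PhenotypeTable
from .progeny_sim import PhasedIndividual, Population

_DEFAULT_SIGMA_A = ((1.0, 0.4), (0.4, 1.0))
_DEFAULT_SIGMA_E = ((0.5, 0.0), (0.0, 0.5))


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of a synthetic breeding panel.

    Defaults give a compact two-trait panel (50 founders, 3 chromosomes x
    100 markers of 100 cM each, inbred founders) on which the full pipeline
    runs in minutes.
    """

    n_founders: int = 50
    n_chromosomes: int = 3
    markers_per_chrom: int = 100
    chrom_length_cm: float = 100.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    sigma_A: tuple = _DEFAULT_SIGMA_A
    sigma_E: tuple = _DEFAULT_SIGMA_E
    trait_means: tuple = (0.0, 0.0)
    n_qtl: int | None = None  # None -> dense MVN architecture
    inbred: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        SA = np.atleast_2d(np.asarray(self.sigma_A, dtype=float))
        SE = np.atleast_2d(np.asarray(self.sigma_E, dtype=float))
        for name, S in (("sigma_A", SA), ("sigma_E", SE)):
            if not np.allclose(S, S.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(S).min() < -1e-10:
                raise ValueError(f"{name} must be positive semi-definite")
        if SA.shape != SE.shape:
            raise ValueError("sigma_A and sigma_E must have the same shape")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if self.n_founders < 2 or self.markers_per_chrom < 1 or self.n_chromosomes < 1:
            raise ValueError("degenerate scenario: need >=2 founders and >=1 marker")
        object.__setattr__(self, "sigma_A", SA)
        object.__setattr__(self, "sigma_E", SE)
        means = np.asarray(self.trait_means, dtype=float)
        if means.shape[0] != SA.shape[0]:
            means = np.zeros(SA.shape[0])
        object.__setattr__(self, "trait_means", means)

    @property
    def t(self) -> int:
        return self.sigma_A.shape[0]

    @property
    def p(self) -> int:
        return self.n_chromosomes * self.markers_per_chrom

    def trait_names(self) -> list[str]:
        return [f"trait{i + 1}" for i in range(self.t)]


def generate_founders(
    scenario: SyntheticScenario,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeMatrix, LinkageMap, Population]:
    """Generate founder genotypes, their linkage map, and the phased founders.

    Marker positions are uniform on each chromosome (then sorted). Per locus
    a major-allele frequency 1 - MAF is sampled from the scenario's MAF
    range; inbred founders draw one allele per locus (homozygous
    everywhere), outbred founders draw two.
    """
    rng = np.random.default_rng(scenario.seed) if rng is None else rng

    rows = []
    for c in range(scenario.n_chromosomes):
        pos = np.sort(rng.uniform(0, scenario.chrom_length_cm, size=scenario.markers_per_chrom))
        for k, cm in enumerate(pos):
            rows.append((f"c{c + 1}_m{k + 1}", f"chr{c + 1}", float(cm)))
    lmap = LinkageMap(
        pd.DataFrame(rows, columns=["marker", "chrom", "cM"]).set_index("marker")
    )

    p = scenario.p
    lo, hi = scenario.maf_range
    maf = rng.uniform(lo, hi, size=p)
    major_freq = 1.0 - maf

    n = scenario.n_founders
    if scenario.inbred:
        hap = np.where(rng.random((n, p)) < major_freq[None, :], 1, -1).astype(np.int8)
        hap1, hap2 = hap, hap.copy()
    else:
        hap1 = np.where(rng.random((n, p)) < major_freq[None, :], 1, -1).astype(np.int8)
        hap2 = np.where(rng.random((n, p)) < major_freq[None, :], 1, -1).astype(np.int8)

    ids = [f"acc{i + 1:03d}" for i in range(n)]
    founders = Population(
        [
            PhasedIndividual(ids[i], hap1[i], hap2[i], generation="P")
            for i in range(n)
        ],
        "P",
    )
    geno = founders.genotype_matrix(markers=lmap.markers)
    return geno, lmap, founders


def _psd_factor(S: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((S + S.T) / 2.0)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def generate_phenotypes(
    geno: GenotypeMatrix,
    scenario: SyntheticScenario,
    rng: np.random.Generator | None = None,
) -> tuple[PhenotypeTable, pd.DataFrame]:
    """Simulate phenotypes y = mean + g + e with known Sigma_A / Sigma_e.

    Returns the phenotype table and the true genetic values (both in trait
    units). Dense architecture: vec(G) ~ MVN(0, Sigma_A (x) K). Sparse
    architecture (``n_qtl`` set): QTL effects drawn with cross-trait
    covariance then whitened/recolored so the realized sample covariance of
    G equals Sigma_A exactly.
    """
    rng = np.random.default_rng(scenario.seed + 1) if rng is None else rng
    n, t = geno.n, scenario.t
    K = geno.codes.astype(float) @ geno.codes.T.astype(float) / geno.p
    L_A = _psd_factor(scenario.sigma_A)
    L_E = _psd_factor(scenario.sigma_E)

    if scenario.n_qtl is None:
        L_K = _psd_factor(K)
        G = L_K @ rng.standard_normal((n, t)) @ L_A.T
    else:
        if scenario.n_qtl > geno.p:
            raise ValueError("n_qtl exceeds the number of markers")
        qtl = rng.choice(geno.p, size=scenario.n_qtl, replace=False)
        effects = rng.standard_normal((scenario.n_qtl, t)) @ L_A.T
        G_raw = geno.codes[:, qtl].astype(float) @ effects
        G_c = G_raw - G_raw.mean(axis=0)
        C = np.cov(G_c, rowvar=False, ddof=1).reshape(t, t)
        W = np.linalg.solve(_psd_factor(C).T, L_A.T)  # whiten then recolor
        G = G_c @ W

    E = rng.standard_normal((n, t)) @ L_E.T
    Y = scenario.trait_means[None, :] + G + E
    traits = scenario.trait_names()
    tbv = pd.DataFrame(G, index=geno.accessions, columns=traits)
    phenos = PhenotypeTable(pd.DataFrame(Y, index=geno.accessions, columns=traits))
    return phenos, tbv


def generate_dataset(scenario: SyntheticScenario):
    """Convenience: founders + map + phased population + phenotypes + true values."""
    rng = np.random.default_rng(scenario.seed)
    geno, lmap, founders = generate_founders(scenario, rng)
    phenos, tbv = generate_phenotypes(geno, scenario, rng)
    return geno, lmap, founders, phenos, tbv
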