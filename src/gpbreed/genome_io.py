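"""Genotype, linkage-map and phenotype I/O.

SNP genotypes are coded additively per marker: ``1`` homozygous for the
major allele, ``-1`` homozygous for the minor allele, ``0`` heterozygous.
The major allele is defined by sample frequency, not by reference status.
Missing calls are imputed as ``1`` (major homozygote) after coding — a
deliberate, documented convention of the framework this package implements
(it biases rare missing calls toward the common class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_CODES = (-1, 0, 1)


class ParseError(ValueError):
    """Raised when an input file fails validation; message names the offending location."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LinkageMap:
    """Ordered marker positions, in centimorgans, grouped by chromosome.

    Markers are stored sorted by (chromosome, position); the frame index is
    the marker id. Adjacent-marker distances on this map drive the
    recombination model of :mod:`gpbreed.progeny_sim`.
    """

    frame: pd.DataFrame  # columns: chrom (str), cM (float); index: marker id

    def __post_init__(self) -> None:
        frame = self.frame
        if not {"chrom", "cM"}.issubset(frame.columns):
            raise ParseError("linkage map requires columns 'chrom' and 'cM'")
        if frame.index.duplicated().any():
            dup = frame.index[frame.index.duplicated()][0]
            raise ParseError(f"duplicate marker id {dup!r} in linkage map")
        if (frame["cM"] < 0).any():
            raise ParseError("linkage map positions must be non-negative")
        ordered = frame.sort_values(["chrom", "cM"], kind="stable")
        object.__setattr__(self, "frame", ordered)

    @property
    def markers(self) -> list[str]:
        return list(self.frame.index)

    @property
    def n_markers(self) -> int:
        return len(self.frame)

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))

    def chrom_start_mask(self) -> np.ndarray:
        """Boolean mask, True at the first marker of each chromosome."""
        chrom = self.frame["chrom"].to_numpy()
        mask = np.ones(len(chrom), dtype=bool)
        mask[1:] = chrom[1:] != chrom[:-1]
        return mask

    def adjacent_distances_morgans(self) -> np.ndarray:
        """Distance (Morgans) from the previous marker; 0 at chromosome starts."""
        pos = self.frame["cM"].to_numpy(dtype=float) / 100.0
        d = np.zeros(len(pos))
        d[1:] = pos[1:] - pos[:-1]
        d[self.chrom_start_mask()] = 0.0
        return d

    def subset(self, marker_ids: Sequence[str]) -> "LinkageMap":
        keep = [m for m in self.markers if m in set(marker_ids)]
        return LinkageMap(self.frame.loc[keep].copy())

    def to_csv(self, path: str | Path) -> None:
        out = self.frame.reset_index()
        out.columns = ["marker", "chrom", "cM"]
        out.to_csv(path, index=False)


@dataclass(frozen=True)
class GenotypeMatrix:
    """Accession x marker coding matrix M with entries in {-1, 0, 1}."""

    accessions: list[str]
    markers: list[str]
    codes: np.ndarray  # shape (n, p), int8

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.ndim != 2 or codes.shape != (len(self.accessions), len(self.markers)):
            raise ValueError(
                f"codes shape {codes.shape} inconsistent with "
                f"{len(self.accessions)} accessions x {len(self.markers)} markers"
            )
        bad = ~np.isin(codes, VALID_CODES)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ParseError(
                f"invalid genotype code {codes[i, j]!r} for accession "
                f"{self.accessions[i]!r}, marker {self.markers[j]!r} (expected -1/0/1)"
            )
        if len(set(self.accessions)) != len(self.accessions):
            raise ParseError("duplicate accession ids in genotype matrix")
        if len(set(self.markers)) != len(self.markers):
            raise ParseError("duplicate marker ids in genotype matrix")
        object.__setattr__(self, "codes", codes.astype(np.int8))
        object.__setattr__(self, "accessions", list(self.accessions))
        object.__setattr__(self, "markers", list(self.markers))

    @property
    def n(self) -> int:
        return len(self.accessions)

    @property
    def p(self) -> int:
        return len(self.markers)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.codes, index=self.accessions, columns=self.markers)

    def select_markers(self, marker_ids: Sequence[str]) -> "GenotypeMatrix":
        idx = {m: j for j, m in enumerate(self.markers)}
        cols = [idx[m] for m in marker_ids]
        return GenotypeMatrix(self.accessions, list(marker_ids), self.codes[:, cols])

    def select_accessions(self, ids: Sequence[str]) -> "GenotypeMatrix":
        idx = {a: i for i, a in enumerate(self.accessions)}
        rows = [idx[a] for a in ids]
        return GenotypeMatrix(list(ids), self.markers, self.codes[rows, :])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().rename_axis("accession").to_csv(path)


@dataclass(frozen=True)
class PhenotypeTable:
    """One phenotypic value per accession per trait, original trait units."""

    frame: pd.DataFrame  # index: accession id, columns: trait names

    def __post_init__(self) -> None:
        if self.frame.index.duplicated().any():
            dup = self.frame.index[self.frame.index.duplicated()][0]
            raise ParseError(f"duplicate accession id {dup!r} in phenotype table")
        if self.frame.isna().any().any():
            raise ParseError("phenotype table contains missing values after ingestion")

    @property
    def accessions(self) -> list[str]:
        return list(self.frame.index)

    @property
    def traits(self) -> list[str]:
        return list(self.frame.columns)

    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def to_csv(self, path: str | Path) -> None:
        self.frame.rename_axis("accession").to_csv(path)


# ---------------------------------------------------------------------------
# coding / imputation
# ---------------------------------------------------------------------------

_MISSING_CALLS = {None, "", "NA", "NN", "./.", ".|.", "--"}


def _is_missing(call) -> bool:
    return call is None or (isinstance(call, float) and np.isnan(call)) or str(call) in _MISSING_CALLS


def code_and_impute(
    raw_calls,
    accessions: Sequence[str] | None = None,
    markers: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Code raw biallelic genotype calls additively and impute missing as major homozygote.

    Parameters
    ----------
    raw_calls : array-like of str, shape (n, p), or DataFrame
        Each entry is a two-allele call such as ``"AA"``, ``"AG"``; missing
        entries are ``None``/``""``/``"NA"``. A DataFrame supplies
        accession/marker labels from its index/columns.
    accessions, markers
        Labels, required when ``raw_calls`` is a bare array.

    Per marker, the major allele is the most frequent allele among observed
    calls (ties broken toward the lexicographically smaller allele). Coding:
    homozygous major -> 1, homozygous minor -> -1, heterozygous -> 0,
    missing -> 1 (imputed).
    """
    if isinstance(raw_calls, pd.DataFrame):
        accessions = list(raw_calls.index)
        markers = list(raw_calls.columns)
        raw = raw_calls.to_numpy(dtype=object)
    else:
        raw = np.asarray(raw_calls, dtype=object)
        if raw.ndim != 2:
            raise ValueError("raw_calls must be 2-dimensional")
        if accessions is None:
            accessions = [f"acc{i}" for i in range(raw.shape[0])]
        if markers is None:
            markers = [f"m{j}" for j in range(raw.shape[1])]

    n, p = raw.shape
    codes = np.ones((n, p), dtype=np.int8)  # missing defaults to 1
    n_imputed = 0
    for j in range(p):
        counts: dict[str, int] = {}
        for i in range(n):
            call = raw[i, j]
            if _is_missing(call):
                continue
            s = str(call)
            if len(s) != 2:
                raise ParseError(f"malformed call {call!r} at accession {accessions[i]!r}, marker {markers[j]!r}")
            for allele in s:
                counts[allele] = counts.get(allele, 0) + 1
        if not counts:
            raise ParseError(f"marker {markers[j]!r}: all calls missing, major allele undefined")
        if len(counts) > 2:
            raise ParseError(f"marker {markers[j]!r}: more than two alleles observed")
        # major by frequency; lexicographic tie-break
        major = min(counts, key=lambda a: (-counts[a], a))
        for i in range(n):
            call = raw[i, j]
            if _is_missing(call):
                n_imputed += 1
                continue
            a, b = str(call)[0], str(call)[1]
            if a == b:
                codes[i, j] = 1 if a == major else -1
            else:
                codes[i, j] = 0
    if n_imputed:
        logger.info("code_and_impute: imputed %d missing calls as major homozygote (code 1)", n_imputed)
    return GenotypeMatrix(list(accessions), list(markers), codes)


def filter_markers_qc(
    raw_calls: pd.DataFrame,
    max_missing_rate: float = 0.05,
    min_maf: float = 0.05,
) -> pd.DataFrame:
    """Drop markers with missing rate above threshold or minor-allele frequency below threshold."""
    keep = []
    n = len(raw_calls.index)
    for marker in raw_calls.columns:
        col = raw_calls[marker]
        missing = sum(_is_missing(c) for c in col)
        if n and missing / n > max_missing_rate:
            continue
        counts: dict[str, int] = {}
        for c in col:
            if _is_missing(c):
                continue
            for allele in str(c):
                counts[allele] = counts.get(allele, 0) + 1
        total = sum(counts.values())
        if total == 0:
            continue
        maf = min(counts.values()) / total if len(counts) == 2 else 0.0
        if maf < min_maf:
            continue
        keep.append(marker)
    dropped = len(raw_calls.columns) - len(keep)
    if dropped:
        logger.info("filter_markers_qc: dropped %d of %d markers", dropped, len(raw_calls.columns))
    return raw_calls[keep]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_genotypes(path: str | Path, dialect: str = "coded-csv") -> GenotypeMatrix:
    """Read a genotype matrix.

    dialect ``"coded-csv"``: first column accession id, header row marker
    ids, body entries in {-1,0,1} or empty for missing (missing imputed
    as 1). dialect ``"vcf"``: biallelic SNP records read via cyvcf2 and run
    through :func:`code_and_impute`; non-biallelic records are skipped with
    a logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "coded-csv":
        return _read_coded_csv(path)
    if dialect == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_coded_csv(path: Path) -> GenotypeMatrix:
    frame = pd.read_csv(path, index_col=0)
    if frame.empty:
        raise ParseError(f"{path}: empty genotype file")
    codes = np.ones(frame.shape, dtype=np.int8)
    values = frame.to_numpy()
    n_missing = 0
    for i in range(frame.shape[0]):
        for j in range(frame.shape[1]):
            v = values[i, j]
            if v is None or (isinstance(v, float) and np.isnan(v)):
                n_missing += 1
                continue
            try:
                iv = int(v)
            except (TypeError, ValueError):
                iv = None
            if iv not in VALID_CODES:
                raise ParseError(
                    f"{path}: invalid code {v!r} at row {frame.index[i]!r}, column {frame.columns[j]!r}"
                )
            codes[i, j] = iv
    if n_missing:
        logger.info("%s: imputed %d missing coded entries as 1", path, n_missing)
    return GenotypeMatrix([str(a) for a in frame.index], [str(m) for m in frame.columns], codes)


def _read_vcf(path: Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError("VCF ingestion requires cyvcf2 (install extra 'vcf')") from exc

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    calls: list[list[str | None]] = []
    marker_ids: list[str] = []
    for variant in vcf:
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            logger.warning("skipping non-biallelic-SNP record at %s:%s", variant.CHROM, variant.POS)
            continue
        ref, alt = variant.REF, variant.ALT[0]
        col: list[str | None] = []
        for gt in variant.genotypes:  # [allele1, allele2, phased]
            a1, a2 = gt[0], gt[1]
            if a1 < 0 or a2 < 0:
                col.append(None)
            else:
                col.append((ref if a1 == 0 else alt) + (ref if a2 == 0 else alt))
        calls.append(col)
        marker_ids.append(variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}_{variant.POS}")
    if not marker_ids:
        raise ParseError(f"{path}: no usable biallelic SNP records")
    raw = np.array(calls, dtype=object).T  # samples x markers
    return code_and_impute(raw, accessions=samples, markers=marker_ids)


def read_linkage_map(path: str | Path) -> LinkageMap:
    """Read a linkage map CSV with columns marker, chrom, cM; returns it sorted."""
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.empty:
        raise ParseError(f"{path}: empty linkage map")
    required = {"marker", "chrom", "cM"}
    if not required.issubset(frame.columns):
        raise ParseError(f"{path}: linkage map must have columns {sorted(required)}, got {list(frame.columns)}")
    frame = frame[["marker", "chrom", "cM"]].copy()
    frame["marker"] = frame["marker"].astype(str)
    frame["chrom"] = frame["chrom"].astype(str)
    frame["cM"] = pd.to_numeric(frame["cM"], errors="raise")
    return LinkageMap(frame.set_index("marker"))


def read_phenotypes(path: str | Path, traits: Sequence[str] | None = None) -> PhenotypeTable:
    """Read a phenotype CSV (columns: accession, <trait...>).

    Accessions with any missing value among the modeled traits are dropped
    listwise, with the drop count logged.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if frame.empty:
        raise ParseError(f"{path}: empty phenotype file")
    if "accession" not in frame.columns:
        raise ParseError(f"{path}: phenotype file must have an 'accession' column")
    frame = frame.set_index("accession")
    frame.index = frame.index.astype(str)
    if traits is not None:
        unknown = set(traits) - set(frame.columns)
        if unknown:
            raise ParseError(f"{path}: unknown trait columns {sorted(unknown)}")
        frame = frame[list(traits)]
    complete = frame.dropna()
    dropped = len(frame) - len(complete)
    if dropped:
        logger.info("%s: dropped %d of %d accessions with missing trait values", path, dropped, len(frame))
    if complete.empty:
        raise ParseError(f"{path}: no accession has complete trait data")
    return PhenotypeTable(complete.astype(float))


# ---------------------------------------------------------------------------
# marker thinning
# ---------------------------------------------------------------------------


def thin_markers(lmap: LinkageMap, interval_cm: float, rng: np.random.Generator) -> list[str]:
    """Choose one marker uniformly at random per `interval_cm` bin on each chromosome.

    Bins are half-open ``[k*interval, (k+1)*interval)`` anchored at 0 cM per
    chromosome; every occupied bin contributes exactly one marker. Output
    preserves map order.
    """
    if interval_cm <= 0:
        raise ValueError("interval_cm must be positive")
    chosen: list[str] = []
    frame = lmap.frame
    for chrom in lmap.chromosomes():
        sub = frame[frame["chrom"] == chrom]
        bins = np.floor(sub["cM"].to_numpy(dtype=float) / interval_cm).astype(int)
        for b in dict.fromkeys(bins.tolist()):  # preserves positional order
            members = sub.index[bins == b]
            chosen.append(str(members[rng.integers(len(members))]))
    order = {m: i for i, m in enumerate(lmap.markers)}
    chosen.sort(key=order.__getitem__)
    return chosen
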