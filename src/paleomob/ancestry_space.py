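"""Genetic distances, sample filtering and ancestry-component derivation.

Pairwise identity-by-state (IBS) distances between genotype vectors, the
quality-control and relatedness filters applied before interpolation, and
classical (Torgerson) multidimensional scaling to low-dimensional ancestry
components.  "Ancestry component" here means an orthogonal MDS axis, not an
admixture proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genio import MISSING, GenotypeMatrix, MolecularSex, SampleRecord

__all__ = [
    "DistanceMatrix",
    "AncestryCoordinates",
    "ibs_distance_matrix",
    "qc_filter",
    "relatedness_filter",
    "ld_region_mask",
    "classical_mds",
    "write_coordinates",
    "read_coordinates",
]

# QC defaults: minimum recovered autosomal SNPs on the panel; maximum
# X-chromosome contamination for males; relatedness distance cutoff below
# which samples are treated as duplicates/close relatives.
DEFAULT_SNP_MIN = 25_000
DEFAULT_CONTAM_MAX = 0.1
DEFAULT_RELATEDNESS_THRESHOLD = 0.245
DEFAULT_MIN_OVERLAP = 1_000


@dataclass
class DistanceMatrix:
    """Symmetric pairwise genetic distances in [0, 1].

    Pairs with zero overlapping loci are NaN (missing), never silently zero.
    ``n_overlapping_loci`` records the pairwise-complete locus counts.
    """

    sample_ids: list[str]
    d: np.ndarray
    n_overlapping_loci: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.sample_ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape inconsistent with sample_ids")
        if not np.allclose(np.nan_to_num(self.d), np.nan_to_num(self.d.T)):
            raise ValueError("distance matrix must be symmetric")

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.d).any())


@dataclass
class AncestryCoordinates:
    """Per-sample values of k reduced ancestry components (C1..Ck)."""

    sample_ids: list[str]
    coords: np.ndarray  # n x k
    eigenvalues: np.ndarray  # k, descending

    def component_names(self) -> list[str]:
        return [f"C{i + 1}" for i in range(self.coords.shape[1])]

    def row(self, sample_id: str) -> np.ndarray:
        return self.coords[self.sample_ids.index(sample_id)]


def ibs_distance_matrix(G: GenotypeMatrix) -> DistanceMatrix:
    """1 - mean proportion of alleles identical by state, per sample pair.

    The per-locus IBS share for diploid dosages g_i, g_j is
    1 - |g_i - g_j| / 2 (so 0 vs 2 shares nothing, 0 vs 1 shares half),
    averaged over mutually non-missing loci.
    """
    calls = G.calls.astype(float)
    calls[G.calls == MISSING] = np.nan
    n = len(G.sample_ids)
    d = np.zeros((n, n))
    overlap = np.zeros((n, n), dtype=int)
    valid = ~np.isnan(calls)
    np.fill_diagonal(overlap, valid.sum(axis=0))
    missing_pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[:, i] & valid[:, j]
            m = int(both.sum())
            overlap[i, j] = overlap[j, i] = m
            if m == 0:
                d[i, j] = d[j, i] = np.nan
                missing_pairs.append((G.sample_ids[i], G.sample_ids[j]))
                continue
            share = 1.0 - np.abs(calls[both, i] - calls[both, j]) / 2.0
            dist = 1.0 - share.mean()
            d[i, j] = d[j, i] = dist
    if missing_pairs:
        warnings.warn(
            f"pairs with zero overlapping loci set to missing: {missing_pairs}",
            stacklevel=2,
        )
    return DistanceMatrix(list(G.sample_ids), d, overlap)


def qc_filter(
    records: Sequence[SampleRecord],
    snp_min: int = DEFAULT_SNP_MIN,
    contam_max: float = DEFAULT_CONTAM_MAX,
) -> tuple[list[SampleRecord], list[tuple[str, str]]]:
    """Quality filter: SNP count, determinable sex, male contamination.

    A sample is kept iff it has at least ``snp_min`` autosomal SNPs, a
    determined molecular sex, and — for males — an X-chromosome
    contamination estimate below ``contam_max``.  Returns (kept, rejections)
    where each rejection is (sample_id, reason).
    """
    kept, rejected = [], []
    for rec in records:
        if rec.n_autosomal_snps is None or rec.n_autosomal_snps < snp_min:
            rejected.append((rec.sample_id, "snp_count"))
        elif rec.molecular_sex is MolecularSex.UNDETERMINED:
            rejected.append((rec.sample_id, "undetermined_sex"))
        elif rec.molecular_sex is MolecularSex.MALE and not (
            rec.x_contamination is not None and rec.x_contamination < contam_max
        ):
            rejected.append((rec.sample_id, "contamination"))
        else:
            kept.append(rec)
    return kept, rejected


def relatedness_filter(
    D: DistanceMatrix,
    quality: Mapping[str, int],
    threshold: float = DEFAULT_RELATEDNESS_THRESHOLD,
) -> list[str]:
    """Keep the best-preserved sample per group of closely related samples.

    Samples with pairwise distance below ``threshold`` form edges of a
    graph; within each connected component exactly one sample is kept — the
    one with the most autosomal SNPs, ties broken by lexicographically
    smallest sample_id.
    """
    for sid in D.sample_ids:
        if sid not in quality:
            raise KeyError(f"sample {sid!r} missing from the quality map")
    n = len(D.sample_ids)
    with np.errstate(invalid="ignore"):
        adj = np.nan_to_num(D.d, nan=np.inf) < threshold
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    kept = []
    for comp in range(n_comp):
        members = [D.sample_ids[i] for i in np.flatnonzero(labels == comp)]
        members.sort(key=lambda sid: (-quality[sid], sid))
        kept.append(members[0])
    return sorted(kept, key=D.sample_ids.index)


def ld_region_mask(
    loci: Sequence[tuple[str, str, int]],
    regions: Sequence[tuple[str, int, int]],
) -> list[tuple[str, str, int]]:
    """Drop loci falling in listed high-LD regions.

    ``regions`` are (chromosome, start, end) intervals, 1-based inclusive
    start, exclusive end.
    """
    for chrom, start, end in regions:
        if start >= end:
            raise ValueError(
                f"malformed LD region {chrom}:[{start}, {end}): start >= end"
            )
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in regions:
        by_chrom.setdefault(str(chrom), []).append((start, end))
    kept = []
    for locus in loci:
        _, chrom, pos = locus
        if any(start <= pos < end for start, end in by_chrom.get(str(chrom), ())):
            continue
        kept.append(locus)
    return kept


def read_ld_regions(path: str | Path) -> list[tuple[str, int, int]]:
    """BED-like TSV: chromosome, start, end (1-based start, exclusive end)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end"], dtype={"chrom": str},
    )
    return [(r.chrom, int(r.start), int(r.end)) for r in df.itertuples()]


def classical_mds(D: DistanceMatrix, k: int = 2) -> AncestryCoordinates:
    """Torgerson scaling of a complete distance matrix.

    Squares the distances, double-centers (B = -1/2 J D^2 J), and takes the
    top-k positive eigenpairs; coordinates are eigenvectors scaled by the
    square root of their eigenvalue.  Sign convention: each column's
    largest-magnitude entry is positive, making output reproducible across
    platforms.
    """
    if D.has_missing:
        raise ValueError(
            "distance matrix has missing entries; resolve zero-overlap pairs "
            "(see relatedness/overlap handling) before MDS"
        )
    n = len(D.sample_ids)
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    d2 = D.d ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    n_pos = int((evals > 1e-10 * max(evals[0], 1.0)).sum())
    if n_pos < k:
        raise ValueError(
            f"only {n_pos} positive eigenvalues available, cannot embed in "
            f"{k} dimensions"
        )
    evals, evecs = evals[:k], evecs[:, :k]
    coords = evecs * np.sqrt(evals)
    # deterministic sign: largest-|.| entry of each column made positive
    flip = np.sign(coords[np.abs(coords).argmax(axis=0), np.arange(k)])
    coords = coords * np.where(flip == 0, 1.0, flip)
    return AncestryCoordinates(list(D.sample_ids), coords, evals)


def write_coordinates(ac: AncestryCoordinates, path: str | Path) -> None:
    df = pd.DataFrame(ac.coords, columns=ac.component_names())
    df.insert(0, "sample_id", ac.sample_ids)
    df.to_csv(path, sep="\t", index=False)


def read_coordinates(path: str | Path) -> AncestryCoordinates:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    comp_cols = [c for c in df.columns if c != "sample_id"]
    coords = df[comp_cols].to_numpy(dtype=float)
    return AncestryCoordinates(
        df["sample_id"].tolist(), coords, np.full(len(comp_cols), np.nan)
    )
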