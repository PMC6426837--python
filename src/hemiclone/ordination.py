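"""PCoA ordination of individual genotypes and F1-intermediacy scoring.

Principal Co-ordinates Analysis (metric MDS) of a pairwise individual
distance matrix separates sexual species and hemi-clonal hybrid lineages
into clusters; a true F1-like hybrid is expected to sit half-way between
its two parental clusters in the leading axes. The
:func:`intermediacy` statistic quantifies that expectation on taxon
centroids: the projection fraction ``t`` of the hybrid centroid onto the
parent-to-parent axis (0.5 for a perfect midpoint) and the scaled
midpoint displacement ``D_mid``.

Distances are Euclidean on per-locus allele dosage. Missing data is
handled by pairwise-complete rescaling: squared differences are averaged
over mutually non-missing features and multiplied by the total feature
count, which preserves expected distances under per-taxon
missingness-at-random, rather than imputing means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .genodata import MISSING, GenotypeDataset


@dataclass
class Ordination:
    """PCoA result: coordinates, eigenvalues, variance shares."""

    individual_ids: list[str]
    coordinates: np.ndarray  # (n, k), axes by decreasing eigenvalue
    eigenvalues: np.ndarray  # (k,), positive
    percent_variance: np.ndarray  # (k,), of the positive-eigenvalue total
    metric: str = "euclidean-dosage"
    taxon_map: dict[str, str] | None = None

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def taxon_centroid(self, taxon: str, k: int) -> np.ndarray:
        if self.taxon_map is None:
            raise ValueError("ordination carries no taxon map")
        idx = [
            i
            for i, ind in enumerate(self.individual_ids)
            if self.taxon_map.get(ind) == taxon
        ]
        if not idx:
            raise ValueError(f"taxon {taxon!r} absent from ordination")
        return self.coordinates[idx, :k].mean(axis=0)


@dataclass
class IntermediacyResult:
    """Placement of a putative hybrid relative to two parent taxa.

    ``t`` is the projection fraction of the hybrid centroid onto the
    segment from parent A (t=0) to parent B (t=1); ``D_mid`` is the
    distance from the hybrid centroid to the parents' midpoint, scaled
    by the parent-to-parent distance.
    """

    hybrid: str
    parent_a: str
    parent_b: str
    t: float
    D_mid: float
    k: int


def dosage_matrix(ds: GenotypeDataset) -> np.ndarray:
    """Per-locus allele dosage features, nan where missing.

    Biallelic loci contribute one column: the count (0/1/2) of the
    reference allele (code 0). Loci with more than two registered
    alleles (allozymes) are expanded to one dosage column per allele.
    """
    n, L = ds.n_individuals, ds.n_loci
    cols: list[np.ndarray] = []
    miss = ds.missing_mask
    for j, m in enumerate(ds.loci):
        pair = ds.calls[:, j]
        if len(m.alleles) <= 2:
            d = (pair == 0).sum(axis=1).astype(float)
            d[miss[:, j]] = np.nan
            cols.append(d)
        else:
            for code in range(len(m.alleles)):
                d = (pair == code).sum(axis=1).astype(float)
                d[miss[:, j]] = np.nan
                cols.append(d)
    return np.column_stack(cols) if cols else np.empty((n, 0))


def genotype_distance_matrix(ds: GenotypeDataset) -> np.ndarray:
    """Pairwise Euclidean distance between individuals on dosage features.

    For each pair, squared differences are averaged over mutually
    non-missing features and multiplied by the total feature count
    (missing-data rescaling). A pair with no shared feature raises,
    naming the pair.
    """
    if ds.n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    X = dosage_matrix(ds)
    F = X.shape[1]
    W = (~np.isnan(X)).astype(float)
    A = np.where(np.isnan(X), 0.0, X)
    A2 = A * A
    # sum over shared features of (x_i - x_j)^2, each term masked by both
    ss = A2 @ W.T + W @ A2.T - 2.0 * (A @ A.T)
    counts = W @ W.T
    empty = counts == 0
    if empty.any():
        i, j = np.argwhere(empty)[0]
        raise ValueError(
            f"individuals {ds.individuals[i]!r} and {ds.individuals[j]!r} "
            "share no genotyped locus"
        )
    D2 = np.maximum(ss, 0.0) / counts * F
    np.fill_diagonal(D2, 0.0)
    D = np.sqrt(D2)
    return (D + D.T) / 2.0


def pcoa(
    dist: np.ndarray,
    individual_ids: list[str] | None = None,
    taxon_map: dict[str, str] | None = None,
    metric: str = "euclidean-dosage",
) -> Ordination:
    """Principal Co-ordinates Analysis of a distance matrix.

    Gower double-centering of -D^2/2 followed by eigendecomposition;
    coordinates are eigenvectors scaled by sqrt(eigenvalue), axes
    ordered by decreasing eigenvalue. Axes with non-positive
    eigenvalues are dropped; negative eigenvalues beyond numerical
    noise trigger a warning recording their magnitude (the input was
    not Euclidean-embeddable).
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have a zero diagonal")
    if (D < -1e-12).any():
        raise ValueError("distance matrix must be non-negative")
    n = D.shape[0]
    if individual_ids is None:
        individual_ids = [str(i) for i in range(n)]
    G = -0.5 * D * D
    G = G - G.mean(axis=0) - G.mean(axis=1)[:, None] + G.mean()
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    lam1 = max(eigval[0], 0.0)
    tol = 1e-10 * max(lam1, 1.0)
    neg = eigval[eigval < -tol]
    if neg.size:
        warnings.warn(
            f"dropping {neg.size} negative eigenvalue axes "
            f"(most negative {neg.min():.3g}); the distance matrix is not "
            "Euclidean-embeddable",
            stacklevel=2,
        )
    keep = eigval > tol
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    coords = eigvec * np.sqrt(eigval)
    pct = 100.0 * eigval / eigval.sum() if eigval.size else eigval
    return Ordination(
        individual_ids=list(individual_ids),
        coordinates=coords,
        eigenvalues=eigval,
        percent_variance=pct,
        metric=metric,
        taxon_map=dict(taxon_map) if taxon_map else None,
    )


def pcoa_from_dataset(ds: GenotypeDataset) -> Ordination:
    """Convenience: dosage distance matrix then PCoA, taxon map attached."""
    return pcoa(
        genotype_distance_matrix(ds),
        individual_ids=ds.individuals,
        taxon_map=ds.taxon_map,
    )


def intermediacy(
    ordn: Ordination,
    hybrid: str,
    parent_a: str,
    parent_b: str,
    k: int = 2,
) -> IntermediacyResult:
    """Quantify half-way placement of a hybrid between two parent taxa.

    Uses taxon centroids in the first ``k`` axes. ``t`` near 0.5 and
    small ``D_mid`` indicate the midpoint placement expected of an F1.
    Coincident parent centroids raise (the axis is undefined).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, ordn.n_axes)
    h = ordn.taxon_centroid(hybrid, k)
    a = ordn.taxon_centroid(parent_a, k)
    b = ordn.taxon_centroid(parent_b, k)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        raise ValueError(
            f"parent centroids of {parent_a!r} and {parent_b!r} coincide"
        )
    t = float((h - a) @ ab) / denom
    D_mid = float(np.linalg.norm(h - (a + b) / 2.0)) / np.sqrt(denom)
    return IntermediacyResult(hybrid, parent_a, parent_b, t, D_mid, k)
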