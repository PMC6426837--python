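"""Per-taxon allele profiles and pairwise taxon statistics.

Implements the summary statistics used to separate sexual species from
hemi-clonal hybrid lineages and to compare populations:

* observed heterozygosity H_O — mean over loci of the heterozygote
  fraction among genotyped individuals; elevated ("fixed heterozygosity")
  in F1-like hybridogens, low in sexual species;
* absolute fixed differences — loci at which two taxa share no alleles
  among all genotyped individuals (tolerance ``tloc = 0``); a relaxed
  ``tloc`` admits shared alleles up to that frequency in one taxon;
* Euclidean genetic distance between allele-frequency profiles;
* Nei's (1972) standard genetic distance D.

All statistics are computed from :class:`AlleleProfile` objects: per-
taxon, per-locus observed allele sets and frequencies over non-missing
calls. None of them uses phase, individual order, or allele labels
beyond per-locus identity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeDataset


@dataclass
class AlleleProfile:
    """Observed allele frequencies of one taxon.

    Attributes
    ----------
    taxon : str
    freqs : ndarray (n_loci, n_allele_codes)
        Per-locus allele frequencies over non-missing calls; rows of a
        no-data locus are all zero.
    n_nonmissing : ndarray (n_loci,)
        Count of individuals with a non-missing call per locus.
    locus_ids : list of str
    """

    taxon: str
    freqs: np.ndarray
    n_nonmissing: np.ndarray
    locus_ids: list[str]

    @property
    def has_data(self) -> np.ndarray:
        return self.n_nonmissing > 0

    def allele_set(self, locus_index: int) -> frozenset[int]:
        return frozenset(np.nonzero(self.freqs[locus_index] > 0)[0])


@dataclass
class HeterozygosityResult:
    taxon: str
    H_O: float  # nan when undefined (no locus with data)
    n_individuals: int
    n_loci_used: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.H_O)


@dataclass
class PairwiseTaxonStats:
    """Pairwise summary between two taxa (fixed differences + distances)."""

    taxon_a: str
    taxon_b: str
    n_loci_compared: int
    fixed_diff_count: int
    fixed_diff_locus_ids: list[str]
    tloc: float
    min_n: int
    euclidean_distance: float | None = None
    nei_distance: float | None = None


def allele_profile(ds: GenotypeDataset, taxon: str) -> AlleleProfile:
    """Per-locus allele sets and frequencies for one taxon.

    Frequencies are over non-missing calls only; a locus with no data in
    the taxon gets an all-zero frequency row (flagged via
    ``n_nonmissing == 0``).
    """
    idx = ds.taxon_indices(taxon)
    calls = ds.calls[idx]  # (n, L, 2)
    L = ds.n_loci
    n_codes = max((len(m.alleles) for m in ds.loci), default=1)
    counts = np.zeros((L, n_codes), dtype=np.int64)
    flat = calls.reshape(-1, L, 2)
    nonmiss = flat[:, :, 0] != MISSING
    for ploid in (0, 1):
        a = flat[:, :, ploid]
        valid = nonmiss
        loc_idx = np.broadcast_to(np.arange(L), a.shape)[valid]
        np.add.at(counts, (loc_idx, a[valid].astype(np.int64)), 1)
    totals = counts.sum(axis=1)
    freqs = np.zeros_like(counts, dtype=float)
    np.divide(counts, totals[:, None], out=freqs, where=totals[:, None] > 0)
    return AlleleProfile(
        taxon=taxon,
        freqs=freqs,
        n_nonmissing=nonmiss.sum(axis=0),
        locus_ids=ds.locus_ids,
    )


def observed_heterozygosity(
    ds: GenotypeDataset, taxon: str
) -> HeterozygosityResult:
    """Mean over loci of the heterozygote fraction within ``taxon``.

    Per locus, h = heterozygous calls / non-missing calls; H_O is the
    unweighted mean of h over loci with at least one non-missing call.
    A taxon with no data at any locus yields ``H_O = nan`` (flagged),
    never a silent zero.
    """
    idx = ds.taxon_indices(taxon)
    calls = ds.calls[idx]
    nonmiss = calls[:, :, 0] != MISSING
    het = (calls[:, :, 0] != calls[:, :, 1]) & nonmiss
    n = nonmiss.sum(axis=0)
    used = n > 0
    if not used.any():
        return HeterozygosityResult(taxon, float("nan"), idx.size, 0)
    h = het.sum(axis=0)[used] / n[used]
    return HeterozygosityResult(
        taxon, float(h.mean()), idx.size, int(used.sum())
    )


def _fixed_diff_mask(
    pa: AlleleProfile, pb: AlleleProfile, tloc: float, min_n: int
) -> tuple[np.ndarray, np.ndarray]:
    """(compared, fixed) boolean masks over loci.

    A locus is compared iff both taxa have >= min_n non-missing calls.
    With ``tloc = 0`` it is a fixed difference iff the observed allele
    sets are disjoint; with ``tloc > 0``, iff every allele present in
    both taxa has frequency <= tloc in at least one of them.
    """
    compared = (pa.n_nonmissing >= min_n) & (pb.n_nonmissing >= min_n)
    # an allele violates fixity iff its frequency exceeds tloc in BOTH taxa
    violating = (pa.freqs > tloc) & (pb.freqs > tloc)
    fixed = compared & ~violating.any(axis=1)
    return compared, fixed


def fixed_difference_count(
    ds: GenotypeDataset,
    taxon_a: str,
    taxon_b: str,
    tloc: float = 0.0,
    min_n: int = 1,
) -> PairwiseTaxonStats:
    """Count loci showing an absolute fixed difference between two taxa.

    ``tloc`` is the tolerated frequency of a shared allele (0 demands
    strictly disjoint observed allele sets); ``min_n`` is the minimum
    number of genotyped individuals per taxon for a locus to enter the
    comparison. Symmetric in the two taxa.
    """
    if not 0.0 <= tloc < 0.5:
        raise ValueError(f"tloc {tloc} outside [0, 0.5)")
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    pa = allele_profile(ds, taxon_a)
    pb = allele_profile(ds, taxon_b)
    compared, fixed = _fixed_diff_mask(pa, pb, tloc, min_n)
    ids = [lid for lid, f in zip(ds.locus_ids, fixed, strict=True) if f]
    return PairwiseTaxonStats(
        taxon_a=taxon_a,
        taxon_b=taxon_b,
        n_loci_compared=int(compared.sum()),
        fixed_diff_count=int(fixed.sum()),
        fixed_diff_locus_ids=ids,
        tloc=tloc,
        min_n=min_n,
    )


def euclidean_distance(
    profile_a: AlleleProfile,
    profile_b: AlleleProfile,
    normalize: bool = False,
) -> float:
    """Euclidean distance between allele-frequency profiles.

    d = sqrt( sum over shared-data loci of (p_A - p_B)^2 ), with p the
    frequency of a fixed reference allele (code 0) per locus; loci
    lacking data in either taxon are excluded. With ``normalize`` the
    root-sum-of-squares is divided by sqrt(n shared loci).
    """
    shared = profile_a.has_data & profile_b.has_data
    if not shared.any():
        raise ValueError(
            f"no locus with data in both {profile_a.taxon!r} and "
            f"{profile_b.taxon!r}"
        )
    diff = profile_a.freqs[shared, 0] - profile_b.freqs[shared, 0]
    ss = float(np.sum(diff * diff))
    if normalize:
        ss /= shared.sum()
    return math.sqrt(ss)


def nei_distance(profile_a: AlleleProfile, profile_b: AlleleProfile) -> float:
    """Nei's (1972) standard genetic distance D.

    Per shared-data locus, jx = sum p_a^2, jy = sum q_a^2,
    jxy = sum p_a q_a; these are averaged across loci (Jx, Jy, Jxy) and
    D = -ln( Jxy / sqrt(Jx Jy) ). Fully disjoint profiles give
    Jxy = 0 and D = +infinity.
    """
    shared = profile_a.has_data & profile_b.has_data
    if not shared.any():
        raise ValueError(
            f"no locus with data in both {profile_a.taxon!r} and "
            f"{profile_b.taxon!r}"
        )
    p = profile_a.freqs[shared]
    q = profile_b.freqs[shared]
    Jx = float(np.mean(np.sum(p * p, axis=1)))
    Jy = float(np.mean(np.sum(q * q, axis=1)))
    Jxy = float(np.mean(np.sum(p * q, axis=1)))
    if Jxy == 0.0:
        return float("inf")
    return -math.log(Jxy / math.sqrt(Jx * Jy))


def pairwise_stats(
    ds: GenotypeDataset,
    taxa: list[str] | None = None,
    tloc: float = 0.0,
    min_n: int = 1,
    with_nei: bool = True,
) -> dict[tuple[str, str], PairwiseTaxonStats]:
    """All pairwise statistics among ``taxa`` (default: all mapped taxa)."""
    taxa = taxa if taxa is not None else ds.taxa
    profiles = {t: allele_profile(ds, t) for t in taxa}
    out: dict[tuple[str, str], PairwiseTaxonStats] = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            stats = fixed_difference_count(ds, a, b, tloc=tloc, min_n=min_n)
            stats.euclidean_distance = euclidean_distance(
                profiles[a], profiles[b]
            )
            if with_nei:
                stats.nei_distance = nei_distance(profiles[a], profiles[b])
            out[(a, b)] = stats
    return out


def summary_table(
    ds: GenotypeDataset,
    taxa: list[str] | None = None,
    tloc: float = 0.0,
    min_n: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-taxon H_O plus a combined pairwise matrix.

    Returns ``(het_table, matrix)`` where ``matrix`` holds fixed-
    difference counts in the lower triangle and Euclidean distances in
    the upper triangle — the conventional two-in-one presentation for
    pairwise population summaries.
    """
    taxa = taxa if taxa is not None else ds.taxa
    het = pd.DataFrame(
        [
            {
                "taxon": r.taxon,
                "H_O": r.H_O,
                "n_individuals": r.n_individuals,
                "n_loci_used": r.n_loci_used,
            }
            for r in (observed_heterozygosity(ds, t) for t in taxa)
        ]
    ).set_index("taxon")
    stats = pairwise_stats(ds, taxa, tloc=tloc, min_n=min_n, with_nei=False)
    mat = pd.DataFrame(np.nan, index=taxa, columns=taxa)
    for (a, b), s in stats.items():
        mat.loc[b, a] = s.fixed_diff_count  # lower triangle
        mat.loc[a, b] = s.euclidean_distance  # upper triangle
    return het, mat
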