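"""Independent brute-force oracles, deliberately naive.

Every function here recomputes a pipeline statistic with plain Python
loops over cells, sharing no code path with the implementation.
"""

from __future__ import annotations

import math

from hemiclone.genodata import MISSING, GenotypeDataset


def cell(ds: GenotypeDataset, i: int, j: int):
    a, b = ds.calls[i, j]
    if a == MISSING:
        return None
    return int(a), int(b)


def missing_fraction(ds: GenotypeDataset, individuals=None) -> float:
    rows = (
        range(ds.n_individuals)
        if individuals is None
        else [ds.individuals.index(x) for x in individuals]
    )
    total = miss = 0
    for i in rows:
        for j in range(ds.n_loci):
            total += 1
            if cell(ds, i, j) is None:
                miss += 1
    return miss / total


def taxon_rows(ds: GenotypeDataset, taxon: str):
    return [
        i
        for i, ind in enumerate(ds.individuals)
        if ds.taxon_map.get(ind) == taxon
    ]


def allele_freqs(ds: GenotypeDataset, taxon: str, j: int) -> dict[int, float]:
    counts: dict[int, int] = {}
    for i in taxon_rows(ds, taxon):
        g = cell(ds, i, j)
        if g is None:
            continue
        for a in g:
            counts[a] = counts.get(a, 0) + 1
    total = sum(counts.values())
    return {a: c / total for a, c in counts.items()} if total else {}


def n_nonmissing(ds: GenotypeDataset, taxon: str, j: int) -> int:
    return sum(
        1 for i in taxon_rows(ds, taxon) if cell(ds, i, j) is not None
    )


def observed_het(ds: GenotypeDataset, taxon: str) -> float:
    hs = []
    for j in range(ds.n_loci):
        het = n = 0
        for i in taxon_rows(ds, taxon):
            g = cell(ds, i, j)
            if g is None:
                continue
            n += 1
            if g[0] != g[1]:
                het += 1
        if n > 0:
            hs.append(het / n)
    return sum(hs) / len(hs) if hs else float("nan")


def fixed_diff(
    ds: GenotypeDataset, ta: str, tb: str, tloc: float = 0.0, min_n: int = 1
) -> tuple[int, int]:
    """(count, n_loci_compared) by per-locus set/frequency inspection."""
    count = compared = 0
    for j in range(ds.n_loci):
        if n_nonmissing(ds, ta, j) < min_n or n_nonmissing(ds, tb, j) < min_n:
            continue
        compared += 1
        fa = allele_freqs(ds, ta, j)
        fb = allele_freqs(ds, tb, j)
        fixed = True
        for a in set(fa) & set(fb):
            if fa[a] > tloc and fb[a] > tloc:
                fixed = False
                break
        if fixed:
            count += 1
    return count, compared


def euclidean(ds: GenotypeDataset, ta: str, tb: str) -> float:
    ss = 0.0
    any_shared = False
    for j in range(ds.n_loci):
        fa = allele_freqs(ds, ta, j)
        fb = allele_freqs(ds, tb, j)
        if not fa or not fb:
            continue
        any_shared = True
        ss += (fa.get(0, 0.0) - fb.get(0, 0.0)) ** 2
    assert any_shared
    return math.sqrt(ss)


def nei(ds: GenotypeDataset, ta: str, tb: str) -> float:
    jx = jy = jxy = 0.0
    n = 0
    for j in range(ds.n_loci):
        fa = allele_freqs(ds, ta, j)
        fb = allele_freqs(ds, tb, j)
        if not fa or not fb:
            continue
        n += 1
        jx += sum(p * p for p in fa.values())
        jy += sum(q * q for q in fb.values())
        jxy += sum(fa[a] * fb.get(a, 0.0) for a in fa)
    assert n > 0
    Jx, Jy, Jxy = jx / n, jy / n, jxy / n
    if Jxy == 0.0:
        return float("inf")
    return -math.log(Jxy / math.sqrt(Jx * Jy))


def dosage(ds: GenotypeDataset, i: int, j: int):
    g = cell(ds, i, j)
    if g is None:
        return None
    return (g[0] == 0) + (g[1] == 0)


def genotype_distance(ds: GenotypeDataset, i: int, k: int) -> float:
    """Biallelic-only pairwise distance with pairwise-complete rescaling."""
    ss = 0.0
    shared = 0
    for j in range(ds.n_loci):
        di, dk = dosage(ds, i, j), dosage(ds, k, j)
        if di is None or dk is None:
            continue
        shared += 1
        ss += (di - dk) ** 2
    assert shared > 0
    return math.sqrt(ss / shared * ds.n_loci)
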