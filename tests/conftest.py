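"""Shared fixtures and dataset builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from hemiclone.genodata import MISSING, GenotypeDataset, LocusMeta


def make_dataset(
    genotypes: list[list[str]],
    individuals: list[str] | None = None,
    taxa: dict[str, str] | list[str] | None = None,
    alleles: tuple[str, ...] = ("0", "1"),
    tags: list[str] | None = None,
    repavg: list[float] | float | None = 1.0,
    locus_ids: list[str] | None = None,
) -> GenotypeDataset:
    """Build a dataset from genotype strings like ``"0/1"`` or ``"-"``.

    ``genotypes`` is individuals x loci. Taxa may be given per
    individual as a list or dict.
    """
    n = len(genotypes)
    L = len(genotypes[0]) if n else 0
    individuals = individuals or [f"ind{i}" for i in range(n)]
    locus_ids = locus_ids or [f"loc{j}" for j in range(L)]
    calls = np.full((n, L, 2), MISSING, dtype=np.int16)
    for i, row in enumerate(genotypes):
        for j, g in enumerate(row):
            if g in ("-", "./."):
                continue
            a, b = g.split("/")
            calls[i, j] = (int(a), int(b))
    if isinstance(repavg, (int, float)) or repavg is None:
        repavg = [repavg] * L
    tags = tags or locus_ids
    loci = [
        LocusMeta(
            locus_id=locus_ids[j],
            alleles=alleles,
            tag_id=tags[j],
            reproducibility=repavg[j],
        )
        for j in range(L)
    ]
    if isinstance(taxa, list):
        taxa = dict(zip(individuals, taxa, strict=True))
    return GenotypeDataset(individuals, loci, calls, taxa)


def random_dataset(
    rng: np.random.Generator,
    n: int,
    L: int,
    missing_rate: float = 0.1,
    taxa: list[str] | None = None,
) -> GenotypeDataset:
    """Random biallelic dataset with missing calls, for oracle tests."""
    calls = rng.integers(0, 2, size=(n, L, 2)).astype(np.int16)
    miss = rng.random((n, L)) < missing_rate
    calls[miss] = MISSING
    individuals = [f"i{k}" for k in range(n)]
    loci = [
        LocusMeta(f"L{j}", ("0", "1"), f"t{j}", 1.0) for j in range(L)
    ]
    tmap = None
    if taxa is not None:
        tmap = {
            ind: taxa[k % len(taxa)] for k, ind in enumerate(individuals)
        }
    return GenotypeDataset(individuals, loci, calls, tmap)


@pytest.fixture
def toy_ds() -> GenotypeDataset:
    """3 individuals x 3 loci, one missing call, two taxa."""
    return make_dataset(
        [
            ["0/0", "0/1", "1/1"],
            ["0/1", "-", "1/1"],
            ["1/1", "0/0", "0/1"],
        ],
        individuals=["a", "b", "c"],
        taxa={"a": "T1", "b": "T1", "c": "T2"},
    )
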