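"""SNP locus filtering: reproducibility, call rate, secondaries, monomorphics.

The canonical chain for reduced-representation SNP data, applied in the
order reproducibility -> call rate -> secondaries -> monomorphics:

1. keep loci with reproducibility (RepAvg) >= threshold (default 0.99);
2. keep loci genotyped in at least ``min_callrate`` of individuals
   (default 0.95, i.e. remove loci with more than 5% missing calls);
3. thin "secondaries" — multiple SNPs called on the same sequenced tag —
   to one randomly chosen SNP per tag (seeded for reproducibility);
4. drop loci that are monomorphic over the non-missing calls (or
   entirely missing), e.g. after individuals or populations are removed.

Threshold comparisons are inclusive (>=). Only loci are filtered, never
individuals. Every step appends to a :class:`FilterReport` whose totals
reconcile (loci_out = loci_in - loci_removed at every step).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .genodata import MISSING, GenotypeDataset


class FilterError(ValueError):
    pass


@dataclass
class FilterStep:
    name: str
    params: dict[str, Any]
    n_in: int
    n_removed: int
    n_out: int
    removed_ids: list[str]

    def __post_init__(self) -> None:
        assert self.n_out == self.n_in - self.n_removed


@dataclass
class FilterReport:
    """Ordered record of filtering steps and their locus counts."""

    steps: list[FilterStep] = field(default_factory=list)

    def record(
        self,
        name: str,
        params: dict[str, Any],
        before: GenotypeDataset,
        after: GenotypeDataset,
    ) -> None:
        removed = sorted(set(before.locus_ids) - set(after.locus_ids))
        self.steps.append(
            FilterStep(
                name=name,
                params=params,
                n_in=before.n_loci,
                n_removed=len(removed),
                n_out=after.n_loci,
                removed_ids=removed,
            )
        )

    @property
    def n_loci_in(self) -> int | None:
        return self.steps[0].n_in if self.steps else None

    @property
    def n_loci_out(self) -> int | None:
        return self.steps[-1].n_out if self.steps else None

    def to_dict(self) -> dict:
        return {
            "steps": [
                {
                    "name": s.name,
                    "params": s.params,
                    "loci_in": s.n_in,
                    "loci_removed": s.n_removed,
                    "loci_out": s.n_out,
                    "removed_locus_ids": s.removed_ids,
                }
                for s in self.steps
            ],
            "loci_in": self.n_loci_in,
            "loci_out": self.n_loci_out,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def filter_reproducibility(
    ds: GenotypeDataset,
    threshold: float = 0.99,
    report: FilterReport | None = None,
) -> GenotypeDataset:
    """Retain loci with reproducibility >= ``threshold``.

    Every locus must carry a reproducibility score; if the metadata is
    absent the caller should skip this step explicitly rather than let
    it silently pass everything.
    """
    if not 0.0 <= threshold <= 1.0:
        raise FilterError(f"threshold {threshold} outside [0, 1]")
    missing_meta = [m.locus_id for m in ds.loci if m.reproducibility is None]
    if missing_meta:
        raise FilterError(
            f"{len(missing_meta)} loci lack reproducibility metadata "
            f"(e.g. {missing_meta[:5]}); skip this step explicitly if the "
            "data has no RepAvg scores"
        )
    keep = [m.locus_id for m in ds.loci if m.reproducibility >= threshold]
    out = ds.subset(loci=keep)
    if report is not None:
        report.record("reproducibility", {"threshold": threshold}, ds, out)
    return out


def filter_callrate(
    ds: GenotypeDataset,
    min_callrate: float = 0.95,
    report: FilterReport | None = None,
) -> GenotypeDataset:
    """Retain loci whose fraction of non-missing calls >= ``min_callrate``."""
    if not 0.0 <= min_callrate <= 1.0:
        raise FilterError(f"min_callrate {min_callrate} outside [0, 1]")
    callrate = 1.0 - ds.missing_mask.mean(axis=0)
    keep = [
        m.locus_id
        for m, cr in zip(ds.loci, callrate, strict=True)
        if cr >= min_callrate
    ]
    out = ds.subset(loci=keep)
    if report is not None:
        report.record("callrate", {"min_callrate": min_callrate}, ds, out)
    return out


def filter_secondaries(
    ds: GenotypeDataset,
    seed: int = 0,
    report: FilterReport | None = None,
) -> GenotypeDataset:
    """Retain exactly one randomly chosen locus per sequenced tag.

    Loci whose tag is unique are untouched; within a multi-SNP tag the
    retained SNP is drawn uniformly at random, reproducibly under
    ``seed``.
    """
    no_tag = [m.locus_id for m in ds.loci if not m.tag_id]
    if no_tag:
        raise FilterError(
            f"{len(no_tag)} loci lack a tag_id (e.g. {no_tag[:5]}); "
            "secondaries filtering needs tag metadata"
        )
    rng = np.random.default_rng(seed)
    by_tag: dict[str, list[str]] = {}
    for m in ds.loci:
        by_tag.setdefault(m.tag_id, []).append(m.locus_id)
    keep = set()
    for tag in sorted(by_tag):
        members = by_tag[tag]
        keep.add(members[rng.integers(len(members))])
    out = ds.subset(loci=[lid for lid in ds.locus_ids if lid in keep])
    if report is not None:
        report.record("secondaries", {"seed": seed}, ds, out)
    return out


def drop_monomorphic(
    ds: GenotypeDataset, report: FilterReport | None = None
) -> GenotypeDataset:
    """Remove loci with at most one distinct allele among non-missing calls.

    A locus whose calls are all missing is also removed.
    """
    calls = ds.calls
    keep = []
    for j, m in enumerate(ds.loci):
        col = calls[:, j].ravel()
        obs = np.unique(col[col != MISSING])
        if obs.size > 1:
            keep.append(m.locus_id)
    out = ds.subset(loci=keep)
    if report is not None:
        report.record("monomorphic", {}, ds, out)
    return out


def apply_filter_chain(
    ds: GenotypeDataset,
    repavg: float | None = 0.99,
    min_callrate: float | None = 0.95,
    secondaries_seed: int | None = 0,
    drop_mono: bool = True,
) -> tuple[GenotypeDataset, FilterReport]:
    """Run the full chain in the canonical order; ``None`` skips a step."""
    report = FilterReport()
    if repavg is not None:
        ds = filter_reproducibility(ds, repavg, report)
    if min_callrate is not None:
        ds = filter_callrate(ds, min_callrate, report)
    if secondaries_seed is not None:
        ds = filter_secondaries(ds, secondaries_seed, report)
    if drop_mono:
        ds = drop_monomorphic(ds, report)
    return ds, report
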