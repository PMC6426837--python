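"""Core genotype data model and file I/O.

The universal substrate of the pipeline is a :class:`GenotypeDataset`:
an individuals x loci matrix of diploid calls, with per-locus metadata
(sequenced-tag ID, reproducibility score, registered alleles) and an
individual -> taxon/site map.

Calls are stored as *unordered* allele pairs, integer-coded per locus in
first-seen order (SNP alleles are {0, 1}; allozyme alleles are arbitrary
symbols mapped to integers). Phase is never used anywhere downstream, so
``0/1`` and ``1/0`` are the same call. A missing call is ``(-1, -1)``;
half-missing VCF calls such as ``./0`` are treated as fully missing.

Supported dialects
------------------
* VCF 4.x — biallelic SNP records, GT field only (read via cyvcf2).
* DArT-style CSV — one-row-per-locus dosage coding (0/1/2, ``-`` missing)
  or two-row-per-allele presence coding; both normalise to allele pairs.
* Allozyme CSV — genotypes as two-letter strings (``ab``; a single letter
  is a homozygote), loci as columns.
* Taxon map TSV — columns ``individual_id``, ``taxon``, optional ``site``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING = -1

_BASES = ("A", "C", "G", "T")


class GenodataError(ValueError):
    """Base class for data-model errors."""


class ParseError(GenodataError):
    """A file failed to parse under the named dialect."""


class ValidationError(GenodataError):
    """Structurally invalid dataset (duplicate IDs, bad ploidy, ...)."""


@dataclass(frozen=True)
class LocusMeta:
    """Metadata for one locus.

    Parameters
    ----------
    locus_id
        Unique locus identifier.
    alleles
        Registered allele symbols; the integer code of an allele is its
        index in this tuple (first-seen order).
    tag_id
        Sequenced-tag / clone identifier, used by secondaries filtering.
    reproducibility
        DArT ``RepAvg``-style score in [0, 1], used by the
        reproducibility filter; ``None`` when unavailable.
    """

    locus_id: str
    alleles: tuple[str, ...] = ("0", "1")
    tag_id: str | None = None
    reproducibility: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self) -> None:
        if self.reproducibility is not None and not (
            0.0 <= self.reproducibility <= 1.0
        ):
            raise ValidationError(
                f"locus {self.locus_id}: reproducibility "
                f"{self.reproducibility} outside [0, 1]"
            )


class GenotypeDataset:
    """Individuals x loci diploid genotype matrix with metadata.

    Attributes
    ----------
    individuals : list of str
        Ordered individual IDs.
    loci : list of LocusMeta
        Ordered locus metadata.
    calls : ndarray of shape (n_individuals, n_loci, 2), dtype int16
        Unordered allele-code pairs, sorted so ``calls[..., 0] <=
        calls[..., 1]``; missing is ``(-1, -1)``.
    taxon_map : dict
        Individual ID -> taxon label; may cover a subset of individuals.
    site_map : dict
        Individual ID -> site label (optional).
    """

    def __init__(
        self,
        individuals: Sequence[str],
        loci: Sequence[LocusMeta],
        calls: np.ndarray,
        taxon_map: Mapping[str, str] | None = None,
        site_map: Mapping[str, str] | None = None,
    ) -> None:
        self.individuals = list(individuals)
        self.loci = list(loci)
        calls = np.asarray(calls, dtype=np.int16)
        if calls.shape != (len(self.individuals), len(self.loci), 2):
            raise ValidationError(
                f"calls shape {calls.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        # normalise to unordered (sorted) pairs; (-1, x) -> fully missing
        calls = np.sort(calls, axis=2)
        half = (calls[:, :, 0] == MISSING) ^ (calls[:, :, 1] == MISSING)
        calls[half] = MISSING
        self.calls = calls
        self.taxon_map = dict(taxon_map or {})
        self.site_map = dict(site_map or {})
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _validate(self) -> None:
        if len(set(self.individuals)) != len(self.individuals):
            dupes = _duplicates(self.individuals)
            raise ValidationError(f"duplicate individual IDs: {dupes}")
        ids = [m.locus_id for m in self.loci]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate locus IDs: {_duplicates(ids)}")
        n_alleles = np.array([len(m.alleles) for m in self.loci])
        hi = self.calls.max(axis=(0, 2), initial=MISSING)
        bad = np.nonzero(hi >= n_alleles)[0]
        if bad.size:
            raise ValidationError(
                "allele codes exceed registered alleles at loci: "
                + ", ".join(ids[i] for i in bad[:10])
            )
        unknown = set(self.taxon_map) - set(self.individuals)
        if unknown:
            warnings.warn(
                f"taxon map references unknown individuals: {sorted(unknown)}",
                stacklevel=3,
            )
            for k in unknown:
                self.taxon_map.pop(k)
                self.site_map.pop(k, None)

    # -- basic properties -----------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [m.locus_id for m in self.loci]

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (individuals x loci) mask of missing calls."""
        return self.calls[:, :, 0] == MISSING

    @property
    def taxa(self) -> list[str]:
        """Taxon labels in first-appearance order over individuals."""
        seen: dict[str, None] = {}
        for ind in self.individuals:
            t = self.taxon_map.get(ind)
            if t is not None:
                seen.setdefault(t, None)
        return list(seen)

    def taxon_of(self, individual: str) -> str | None:
        return self.taxon_map.get(individual)

    def individuals_of(self, taxon: str) -> list[str]:
        return [i for i in self.individuals if self.taxon_map.get(i) == taxon]

    def taxon_indices(self, taxon: str) -> np.ndarray:
        idx = np.array(
            [
                k
                for k, i in enumerate(self.individuals)
                if self.taxon_map.get(i) == taxon
            ],
            dtype=int,
        )
        if idx.size == 0:
            raise GenodataError(f"unknown or empty taxon: {taxon!r}")
        return idx

    # -- operations -----------------------------------------------------------

    def subset(
        self,
        individuals: Iterable[str] | None = None,
        loci: Iterable[str] | None = None,
    ) -> "GenotypeDataset":
        """Order-preserving subset by individual and/or locus IDs.

        Selector order does not matter: the original dataset order is kept.
        Unknown IDs raise with the full offender list.
        """
        if individuals is None:
            ind_idx = np.arange(self.n_individuals)
        else:
            want = set(individuals)
            unknown = want - set(self.individuals)
            if unknown:
                raise GenodataError(
                    f"unknown individual IDs: {sorted(unknown)}"
                )
            ind_idx = np.array(
                [k for k, i in enumerate(self.individuals) if i in want],
                dtype=int,
            )
        if loci is None:
            loc_idx = np.arange(self.n_loci)
        else:
            want = set(loci)
            unknown = want - set(self.locus_ids)
            if unknown:
                raise GenodataError(f"unknown locus IDs: {sorted(unknown)}")
            loc_idx = np.array(
                [k for k, m in enumerate(self.loci) if m.locus_id in want],
                dtype=int,
            )
        inds = [self.individuals[k] for k in ind_idx]
        return GenotypeDataset(
            inds,
            [self.loci[k] for k in loc_idx],
            self.calls[np.ix_(ind_idx, loc_idx)],
            {i: self.taxon_map[i] for i in inds if i in self.taxon_map},
            {i: self.site_map[i] for i in inds if i in self.site_map},
        )

    def subset_taxa(self, taxa: Iterable[str]) -> "GenotypeDataset":
        """Keep only individuals mapped to the given taxa."""
        taxa = set(taxa)
        return self.subset(
            individuals=[
                i for i in self.individuals if self.taxon_map.get(i) in taxa
            ]
        )

    def drop_loci(self, locus_ids: Iterable[str]) -> "GenotypeDataset":
        drop = set(locus_ids)
        return self.subset(
            loci=[lid for lid in self.locus_ids if lid not in drop]
        )

    def missingness_summary(self, by_taxon: bool = False) -> pd.DataFrame:
        """Fractions of missing calls, overall and (optionally) per taxon.

        Returns a DataFrame indexed by ``"overall"`` plus, when
        ``by_taxon`` is set, one row per taxon, with columns
        ``missing_fraction``, ``n_individuals`` and ``n_calls``. An empty
        dataset raises; a taxon with no individuals never appears.
        """
        if self.n_individuals == 0 or self.n_loci == 0:
            raise GenodataError("missingness_summary on empty dataset")
        mask = self.missing_mask
        rows = {
            "overall": (
                float(mask.mean()),
                self.n_individuals,
                mask.size,
            )
        }
        if by_taxon:
            for taxon in self.taxa:
                idx = self.taxon_indices(taxon)
                sub = mask[idx]
                rows[taxon] = (float(sub.mean()), idx.size, sub.size)
        return pd.DataFrame.from_dict(
            rows,
            orient="index",
            columns=["missing_fraction", "n_individuals", "n_calls"],
        )

    def equals(self, other: "GenotypeDataset") -> bool:
        """Content equality: IDs, metadata, unordered calls, maps."""
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and np.array_equal(self.calls, other.calls)
            and self.taxon_map == other.taxon_map
            and self.site_map == other.site_map
        )


def _duplicates(items: Sequence[str]) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for x in items:
        if x in seen and x not in out:
            out.append(x)
        seen.add(x)
    return out


# ---------------------------------------------------------------------------
# Taxon map
# ---------------------------------------------------------------------------


def load_taxon_map(path: str | Path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a taxon map TSV (individual_id, taxon, optional site)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    for required in ("individual_id", "taxon"):
        if required not in cols:
            raise ParseError(
                f"{path}: taxon map lacks required column {required!r}"
            )
    taxon_map = dict(
        zip(df[cols["individual_id"]], df[cols["taxon"]], strict=True)
    )
    site_map: dict[str, str] = {}
    if "site" in cols:
        site = df[cols["site"]]
        site_map = {
            i: s
            for i, s in zip(df[cols["individual_id"]], site, strict=True)
            if isinstance(s, str) and s
        }
    return taxon_map, site_map


def write_taxon_map(ds: GenotypeDataset, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("individual_id\ttaxon\tsite\n")
        for ind in ds.individuals:
            fh.write(
                f"{ind}\t{ds.taxon_map.get(ind, '')}\t"
                f"{ds.site_map.get(ind, '')}\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _load_vcf(path: str | Path) -> GenotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    loci: list[LocusMeta] = []
    rows: list[np.ndarray] = []
    for k, var in enumerate(vcf):
        if len(var.ALT) != 1:
            raise ValidationError(
                f"{path}: record {var.CHROM}:{var.POS} is not biallelic"
            )
        lid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        loci.append(
            LocusMeta(
                locus_id=lid,
                alleles=(var.REF, var.ALT[0]),
                chrom=var.CHROM,
                pos=var.POS,
            )
        )
        col = np.full((len(individuals), 2), MISSING, dtype=np.int16)
        for i, gt in enumerate(var.genotypes):
            if len(gt) - 1 != 2:
                raise ValidationError(
                    f"{path}: sample {individuals[i]} at {lid} has ploidy "
                    f"{len(gt) - 1}, expected 2"
                )
            a, b = gt[0], gt[1]
            if a >= 0 and b >= 0:
                col[i] = (a, b)
        rows.append(col)
    calls = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(individuals), 0, 2), dtype=np.int16)
    )
    return GenotypeDataset(individuals, loci, calls)


def _write_vcf(ds: GenotypeDataset, path: str | Path) -> None:
    """Minimal biallelic GT-only VCF 4.2 writer.

    Allele symbols that are not valid bases are substituted with A/C and
    the original symbols recorded in the INFO field.
    """
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=SYM,Number=.,Type=String,'
            'Description="Original allele symbols">\n'
        )
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(ds.individuals)
            + "\n"
        )
        for j, m in enumerate(ds.loci):
            if len(m.alleles) != 2:
                raise ValidationError(
                    f"VCF output requires biallelic loci; {m.locus_id} has "
                    f"{len(m.alleles)} alleles"
                )
            symbols = m.alleles
            if all(a in _BASES for a in symbols) and symbols[0] != symbols[1]:
                ref, alt, info = symbols[0], symbols[1], "."
            else:
                ref, alt = "A", "C"
                info = f"SYM={symbols[0]},{symbols[1]}"
            chrom = m.chrom or "1"
            pos = m.pos if m.pos is not None else j + 1
            gts = []
            for i in range(ds.n_individuals):
                a, b = ds.calls[i, j]
                gts.append("./." if a == MISSING else f"{a}/{b}")
            fh.write(
                f"{chrom}\t{pos}\t{m.locus_id}\t{ref}\t{alt}\t.\t.\t{info}"
                f"\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# DArT-style CSV
# ---------------------------------------------------------------------------

_DART_META = {"locus_id", "allele", "tag_id", "repavg"}


def _write_dart_csv(
    ds: GenotypeDataset, path: str | Path, coding: str = "dosage"
) -> None:
    """Write a DArT-style wide CSV.

    ``dosage`` coding: one row per locus, cells count the second
    (alternate) allele, ``-`` for missing. ``presence`` coding: two rows
    per locus (one per allele), cells 1/0 for allele presence.
    """
    if coding not in ("dosage", "presence"):
        raise ValueError(f"unknown DArT coding {coding!r}")
    with open(path, "w", encoding="utf-8") as fh:
        meta_cols = (
            ["locus_id", "allele", "tag_id", "repavg"]
            if coding == "presence"
            else ["locus_id", "tag_id", "repavg"]
        )
        fh.write(",".join(meta_cols + ds.individuals) + "\n")
        for j, m in enumerate(ds.loci):
            if len(m.alleles) != 2:
                raise ValidationError(
                    f"DArT output requires biallelic loci; {m.locus_id} has "
                    f"{len(m.alleles)} alleles"
                )
            tag = m.tag_id or ""
            rep = "" if m.reproducibility is None else f"{m.reproducibility}"
            col = ds.calls[:, j]
            if coding == "dosage":
                cells = [
                    "-" if a == MISSING else str(int(a == 1) + int(b == 1))
                    for a, b in col
                ]
                fh.write(
                    ",".join([m.locus_id, tag, rep] + cells) + "\n"
                )
            else:
                for code, sym in enumerate(m.alleles):
                    cells = [
                        "-"
                        if a == MISSING
                        else str(int(a == code or b == code))
                        for a, b in col
                    ]
                    fh.write(
                        ",".join([m.locus_id, sym, tag, rep] + cells) + "\n"
                    )


def _parse_float(cell: str, what: str, lineno: int, path) -> float | None:
    if cell in ("", "-", "NA"):
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise ParseError(f"{path} line {lineno}: bad {what} {cell!r}") from exc


def _load_dart_csv(path: str | Path) -> GenotypeDataset:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    cols = {c.lower(): c for c in df.columns}
    # header synonyms seen in DArT exports
    alias = {"alleleid": "locus_id", "cloneid": "tag_id", "repavg": "repavg"}
    cols = {alias.get(k, k): v for k, v in cols.items()}
    if "locus_id" not in cols:
        raise ParseError(f"{path}: no locus_id/AlleleID column")
    presence = "allele" in cols
    ind_cols = [
        c
        for c in df.columns
        if c.lower() not in _DART_META
        and alias.get(c.lower(), c.lower()) not in _DART_META
    ]
    if not ind_cols:
        raise ParseError(f"{path}: no individual columns found")
    if not presence and df[cols["locus_id"]].duplicated().any():
        raise ValidationError(
            f"{path}: duplicate locus IDs in dosage-coded table"
        )

    loci: list[LocusMeta] = []
    call_cols: list[np.ndarray] = []
    n = len(ind_cols)
    if presence:
        groups = df.groupby(cols["locus_id"], sort=False)
        for lid, grp in groups:
            if len(grp) != 2:
                raise ParseError(
                    f"{path}: presence-coded locus {lid} has {len(grp)} rows,"
                    " expected 2"
                )
            alleles = tuple(grp[cols["allele"]])
            rep = _parse_float(
                grp.iloc[0][cols["repavg"]] if "repavg" in cols else "",
                "repavg",
                int(grp.index[0]) + 2,
                path,
            )
            tag = grp.iloc[0][cols["tag_id"]] if "tag_id" in cols else lid
            pres = np.empty((2, n), dtype=np.int16)
            miss = np.zeros(n, dtype=bool)
            for r in range(2):
                for i, c in enumerate(ind_cols):
                    cell = grp.iloc[r][c].strip()
                    if cell in ("-", "", "NA"):
                        miss[i] = True
                        pres[r, i] = 0
                    elif cell in ("0", "1"):
                        pres[r, i] = int(cell)
                    else:
                        raise ParseError(
                            f"{path} line {int(grp.index[r]) + 2}: bad "
                            f"presence value {cell!r}"
                        )
            col = np.full((n, 2), MISSING, dtype=np.int16)
            for i in range(n):
                if miss[i] or (pres[0, i] == 0 and pres[1, i] == 0):
                    continue
                if pres[0, i] and pres[1, i]:
                    col[i] = (0, 1)
                elif pres[0, i]:
                    col[i] = (0, 0)
                else:
                    col[i] = (1, 1)
            loci.append(
                LocusMeta(str(lid), alleles, str(tag), rep)
            )
            call_cols.append(col)
    else:
        for r in range(len(df)):
            row = df.iloc[r]
            lid = row[cols["locus_id"]]
            rep = _parse_float(
                row[cols["repavg"]] if "repavg" in cols else "",
                "repavg",
                r + 2,
                path,
            )
            tag = row[cols["tag_id"]] if "tag_id" in cols else lid
            col = np.full((n, 2), MISSING, dtype=np.int16)
            for i, c in enumerate(ind_cols):
                cell = str(row[c]).strip()
                if cell in ("-", "", "NA", "./."):
                    continue
                if cell == "0":
                    col[i] = (0, 0)
                elif cell == "1":
                    col[i] = (0, 1)
                elif cell == "2":
                    col[i] = (1, 1)
                else:
                    raise ParseError(
                        f"{path} line {r + 2}: bad dosage value {cell!r}"
                    )
            loci.append(LocusMeta(str(lid), ("0", "1"), str(tag), rep))
            call_cols.append(col)
    calls = (
        np.stack(call_cols, axis=1)
        if call_cols
        else np.empty((n, 0, 2), dtype=np.int16)
    )
    return GenotypeDataset(ind_cols, loci, calls)


# ---------------------------------------------------------------------------
# Allozyme CSV
# ---------------------------------------------------------------------------


def _load_allozyme_csv(path: str | Path) -> GenotypeDataset:
    """Read an allozyme table: rows = individuals, columns = loci.

    Genotypes are letter strings: ``ab`` heterozygote, ``a`` or ``aa``
    homozygote; empty / ``-`` / ``NA`` missing. Allele integer codes are
    assigned per locus in first-seen order; symbols are retained.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False, index_col=0)
    individuals = [str(i) for i in df.index]
    locus_names = [str(c) for c in df.columns]
    n, L = len(individuals), len(locus_names)
    calls = np.full((n, L, 2), MISSING, dtype=np.int16)
    alleles: list[dict[str, int]] = [dict() for _ in range(L)]
    for j in range(L):
        reg = alleles[j]
        for i in range(n):
            cell = df.iat[i, j].strip()
            if cell in ("", "-", "NA", "."):
                continue
            if len(cell) == 1:
                pair = (cell, cell)
            elif len(cell) == 2:
                pair = (cell[0], cell[1])
            else:
                raise ParseError(
                    f"{path} line {i + 2}: bad allozyme genotype {cell!r} "
                    f"at locus {locus_names[j]}"
                )
            codes = []
            for sym in pair:
                if sym not in reg:
                    reg[sym] = len(reg)
                codes.append(reg[sym])
            calls[i, j] = codes
    loci = [
        LocusMeta(locus_names[j], tuple(alleles[j]) or ("a",), None, None)
        for j in range(L)
    ]
    return GenotypeDataset(individuals, loci, calls)


def _write_allozyme_csv(ds: GenotypeDataset, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("individual_id," + ",".join(ds.locus_ids) + "\n")
        for i, ind in enumerate(ds.individuals):
            cells = []
            for j, m in enumerate(ds.loci):
                a, b = ds.calls[i, j]
                cells.append("-" if a == MISSING else m.alleles[a] + m.alleles[b])
            fh.write(ind + "," + ",".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Public dispatch
# ---------------------------------------------------------------------------

FORMATS = ("vcf", "dart_csv", "allozyme_csv")


def load_dataset(
    path: str | Path,
    format: str,
    taxon_map_path: str | Path | None = None,
) -> GenotypeDataset:
    """Load a genotype dataset in one of the supported dialects.

    Parameters
    ----------
    path
        Genotype file.
    format
        One of ``vcf``, ``dart_csv``, ``allozyme_csv``.
    taxon_map_path
        Optional taxon map TSV; IDs it mentions that are absent from the
        genotype file produce a warning, not an error.
    """
    path = Path(path)
    if not path.exists():
        raise GenodataError(f"no such file: {path}")
    if format == "vcf":
        ds = _load_vcf(path)
    elif format == "dart_csv":
        ds = _load_dart_csv(path)
    elif format == "allozyme_csv":
        ds = _load_allozyme_csv(path)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if taxon_map_path is not None:
        taxon_map, site_map = load_taxon_map(taxon_map_path)
        known = set(ds.individuals)
        unknown = set(taxon_map) - known
        if unknown:
            warnings.warn(
                f"taxon map references {len(unknown)} unknown individuals "
                f"(e.g. {sorted(unknown)[:5]})",
                stacklevel=2,
            )
        ds.taxon_map = {k: v for k, v in taxon_map.items() if k in known}
        ds.site_map = {k: v for k, v in site_map.items() if k in known}
    return ds


def write_dataset(
    ds: GenotypeDataset, path: str | Path, format: str, **kwargs
) -> None:
    """Write a dataset in one of the supported dialects."""
    if format == "vcf":
        _write_vcf(ds, path)
    elif format == "dart_csv":
        _write_dart_csv(ds, path, **kwargs)
    elif format == "allozyme_csv":
        _write_allozyme_csv(ds, path)
    else:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")


def with_taxon_map(
    ds: GenotypeDataset, taxon_map: Mapping[str, str]
) -> GenotypeDataset:
    """Return a copy of ``ds`` with a replaced taxon map."""
    return GenotypeDataset(
        ds.individuals, ds.loci, ds.calls.copy(), taxon_map, ds.site_map
    )
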