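"""Hybridogenesis simulator: synthetic genotype data with known truth.

Generates biallelic SNP datasets reproducing the statistical structure
that the inference pipeline assumes:

* several divergent sexual species, with allele frequencies drawn from
  a Balding–Nichols model (Beta-distributed around a shared ancestral
  frequency, divergence parameter F) and an optional number of forced
  diagnostic loci per species pair (frequencies 1 vs 0);
* hemi-clonal hybridogen lineages: each lineage clonally transmits one
  haploid genome drawn once from its "clonal" species at founding,
  while the other haploid genome is a fresh gamete from the sexual
  host species every generation — the host is a genetic parent but
  never a genetic grandparent of the offspring;
* resurrection crosses: offspring combining the clonal haplotypes of
  two lineages that carry the same ghost species' genome;
* drifted remnant populations of a ghost species (Balding–Nichols
  drift from the founding frequencies, then Hardy–Weinberg sampling);
* a missingness regime of per-taxon locus dropout (restriction-site
  mutation knocks a locus out for a whole population), per-call random
  missingness, and symmetric allele-flip genotyping error.

Every simulated individual has a truth-table row: class, species of
origin or parent pair, clonal haplotype ID, and maternal (mtDNA-like)
clade label. Everything is reproducible from the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .genodata import MISSING, GenotypeDataset, LocusMeta


class ScenarioError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Scenario specification
# ---------------------------------------------------------------------------


@dataclass
class LineageSpec:
    """One hybridogen lineage: clonal genome from ``clonal_species``,
    fresh gametes from ``host_species`` each generation."""

    name: str
    clonal_species: str
    host_species: str
    n: int
    generations: int = 1
    maternal_side: str | None = None  # default: the host species
    n_founder_clones: int = 1

    @property
    def maternal(self) -> str:
        return self.maternal_side or self.host_species


@dataclass
class ResurrectionSpec:
    """Cross between two lineages carrying the same ghost genome."""

    name: str
    lineage1: str
    lineage2: str
    n: int


@dataclass
class RemnantSpec:
    """Drifted remnant population of a (ghost) species."""

    name: str
    species: str
    f_drift: float
    n: int


@dataclass
class SimScenario:
    """Full simulator configuration; the seed is mandatory."""

    seed: int
    species: list[str] = field(default_factory=lambda: ["A", "B", "X"])
    n_loci: int = 4000
    divergence_f: float = 0.8
    ancestral_low: float = 0.05
    ancestral_high: float = 0.95
    # forced diagnostic-locus counts per species pair, e.g. {("A","B"): 40}
    diagnostic_counts: dict[tuple[str, str], int] = field(default_factory=dict)
    # sexual sample sizes by species; species absent here are unsampled
    # (ghost species persisting only inside lineages / remnants)
    sexual_n: dict[str, int] = field(default_factory=dict)
    lineages: list[LineageSpec] = field(default_factory=list)
    resurrections: list[ResurrectionSpec] = field(default_factory=list)
    remnants: list[RemnantSpec] = field(default_factory=list)
    dropout_by_taxon: dict[str, float] = field(default_factory=dict)
    call_missing_rate: float = 0.0
    genotyping_error_rate: float = 0.0

    def validate(self) -> None:
        for r in (
            [self.call_missing_rate, self.genotyping_error_rate]
            + list(self.dropout_by_taxon.values())
        ):
            if not 0.0 <= r <= 1.0:
                raise ScenarioError(f"rate {r} outside [0, 1]")
        if not 0.0 < self.divergence_f < 1.0:
            raise ScenarioError(
                f"divergence F {self.divergence_f} outside (0, 1)"
            )
        for pair, k in self.diagnostic_counts.items():
            if k > self.n_loci:
                raise ScenarioError(
                    f"forced diagnostic count {k} for {pair} exceeds "
                    f"{self.n_loci} loci"
                )
            for sp in pair:
                if sp not in self.species:
                    raise ScenarioError(f"unknown species {sp!r} in {pair}")
        known = set(self.species)
        for sp in self.sexual_n:
            if sp not in known:
                raise ScenarioError(f"unknown sexual species {sp!r}")
        lineage_names = set()
        for ln in self.lineages:
            if ln.clonal_species not in known or ln.host_species not in known:
                raise ScenarioError(
                    f"lineage {ln.name}: unknown species "
                    f"({ln.clonal_species!r}, {ln.host_species!r})"
                )
            lineage_names.add(ln.name)
        for rs in self.resurrections:
            if rs.lineage1 not in lineage_names or rs.lineage2 not in lineage_names:
                raise ScenarioError(
                    f"resurrection {rs.name}: unknown lineage"
                )
        for rm in self.remnants:
            if rm.species not in known:
                raise ScenarioError(f"remnant {rm.name}: unknown species")
            if not 0.0 < rm.f_drift < 1.0:
                raise ScenarioError(
                    f"remnant {rm.name}: f_drift {rm.f_drift} outside (0, 1)"
                )


def default_scenario(seed: int) -> SimScenario:
    """Six-taxon default: a carp-gudgeon-like sexual/unisexual complex.

    Two sampled sexual species (A, B), a drifted remnant of the ghost
    species X, and the three F1 hybridogen lineages (host x clonal*):
    AxB*, AxX*, BxX*. The remnant taxon suffers heavy per-taxon locus
    dropout (restriction-site divergence), everything gets light random
    missingness and a small genotyping error rate.
    """
    return SimScenario(
        seed=seed,
        species=["A", "B", "X"],
        n_loci=4000,
        divergence_f=0.8,
        diagnostic_counts={
            ("A", "B"): 40,
            ("A", "X"): 40,
            ("B", "X"): 40,
        },
        sexual_n={"A": 20, "B": 20},
        lineages=[
            LineageSpec("AxB", clonal_species="B", host_species="A", n=20),
            LineageSpec("AxX", clonal_species="X", host_species="A", n=20),
            LineageSpec("BxX", clonal_species="X", host_species="B", n=20),
        ],
        remnants=[RemnantSpec("X", species="X", f_drift=0.05, n=20)],
        dropout_by_taxon={"X": 0.30},
        call_missing_rate=0.015,
        genotyping_error_rate=0.001,
    )


# ---------------------------------------------------------------------------
# Frequency and genotype sampling
# ---------------------------------------------------------------------------


def _balding_nichols(
    rng: np.random.Generator, ancestral: np.ndarray, F: float
) -> np.ndarray:
    """Draw drifted frequencies around ``ancestral`` with divergence F."""
    c = (1.0 - F) / F
    return rng.beta(ancestral * c, (1.0 - ancestral) * c)


def simulate_ancestral_frequencies(
    scenario: SimScenario, rng: np.random.Generator | None = None
) -> dict[str, np.ndarray]:
    """Per-species allele-1 frequencies at every locus.

    Ancestral frequencies are Uniform(low, high); each species drifts
    independently under the Balding–Nichols model. Forced diagnostic
    loci for a species pair are then overwritten with (1, 0): the
    designated pair is fixed for opposite alleles there. Forced blocks
    for different pairs occupy disjoint locus ranges.
    """
    scenario.validate()
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    L = scenario.n_loci
    anc = rng.uniform(scenario.ancestral_low, scenario.ancestral_high, L)
    freqs = {
        sp: _balding_nichols(rng, anc, scenario.divergence_f)
        for sp in scenario.species
    }
    total_forced = sum(scenario.diagnostic_counts.values())
    if total_forced > L:
        raise ScenarioError(
            f"forced diagnostic loci ({total_forced}) exceed n_loci ({L})"
        )
    start = 0
    for (sp1, sp2), k in scenario.diagnostic_counts.items():
        block = slice(start, start + k)
        freqs[sp1][block] = 1.0
        freqs[sp2][block] = 0.0
        start += k
    return freqs


def sample_sexual_population(
    freqs: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Hardy–Weinberg genotypes: two independent gametes per locus.

    Returns an (n, L, 2) array of allele codes in {0, 1}.
    """
    if n < 1:
        raise ScenarioError("n must be >= 1")
    return (
        rng.random((n, freqs.size, 2)) < freqs[None, :, None]
    ).astype(np.int16)


def draw_haplotype(
    freqs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One gamete: Bernoulli(p) per locus."""
    return (rng.random(freqs.size) < freqs).astype(np.int16)


def found_hybridogen_lineage(
    clonal_freqs: np.ndarray,
    host_freqs: np.ndarray,
    n: int,
    rng: np.random.Generator,
    generations: int = 1,
    n_founder_clones: int = 1,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate a hemi-clonal lineage.

    A founding clonal haplotype is drawn once from the clonal species'
    frequencies (optionally several founding clones, assigned to
    individuals at random) and transmitted unchanged through every
    generation; each individual's other haploid genome is a fresh host
    gamete. Extra generations only redraw the host gamete — the host
    genome is discarded at gametogenesis, so the host is never a
    genetic grandparent.

    Returns ``(genotypes (n, L, 2), clone_haplotypes (n_clones, L),
    clone_assignment (n,))``.
    """
    if n < 1 or generations < 1:
        raise ScenarioError("n and generations must be >= 1")
    clones = np.stack(
        [draw_haplotype(clonal_freqs, rng) for _ in range(n_founder_clones)]
    )
    assignment = (
        np.zeros(n, dtype=int)
        if n_founder_clones == 1
        else rng.integers(n_founder_clones, size=n)
    )
    for _ in range(generations):
        host = (
            rng.random((n, host_freqs.size)) < host_freqs[None, :]
        ).astype(np.int16)
    geno = np.stack([clones[assignment], host], axis=2)
    return geno, clones, assignment


def simulate_resurrection_cross(
    clone1: np.ndarray, clone2: np.ndarray, n: int
) -> np.ndarray:
    """Offspring of a cross between two hemi-clones of the same ghost.

    Every offspring is clonal haplotype 1 + clonal haplotype 2; absent
    genotyping error all offspring are genetically identical, and each
    shares an allele with either founder lineage at every locus.
    """
    if clone1.shape != clone2.shape:
        raise ScenarioError("founder haplotypes differ in length")
    geno = np.stack([clone1, clone2], axis=1)  # (L, 2)
    return np.broadcast_to(geno, (n, *geno.shape)).astype(np.int16).copy()


def simulate_remnant_population(
    ghost_freqs: np.ndarray,
    f_drift: float,
    n: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Drifted remnant of the ghost species.

    Frequencies drift from the founding ghost frequencies by a
    Balding–Nichols step with parameter ``f_drift``, then genotypes are
    Hardy–Weinberg samples. Returns ``(genotypes, drifted_freqs)``.
    """
    if not 0.0 < f_drift < 1.0:
        raise ScenarioError(f"f_drift {f_drift} outside (0, 1)")
    # Beta parameters blow up at p in {0, 1}; fixed loci stay fixed
    clipped = np.clip(ghost_freqs, 1e-9, 1.0 - 1e-9)
    drifted = _balding_nichols(rng, clipped, f_drift)
    drifted[ghost_freqs == 0.0] = 0.0
    drifted[ghost_freqs == 1.0] = 1.0
    return sample_sexual_population(drifted, n, rng), drifted


def apply_missingness_and_error(
    calls: np.ndarray,
    taxa: np.ndarray,
    dropout_by_taxon: Mapping[str, float],
    call_missing_rate: float,
    error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Degrade genotypes: locus dropout, random missingness, allele flips.

    Order: (1) per-taxon locus dropout — with probability delta a locus
    becomes MISSING for every individual of that taxon; (2) per-call
    missingness with probability eps; (3) symmetric allele-flip
    genotyping error with probability ``error_rate`` per call (one of
    the two alleles flips).
    """
    calls = np.array(calls, dtype=np.int16, copy=True)
    n, L, _ = calls.shape
    if len(taxa) != n:
        raise ScenarioError("taxa vector does not match genotype rows")
    for taxon, delta in dropout_by_taxon.items():
        rows = np.asarray(taxa) == taxon
        if not rows.any():
            continue
        dropped = rng.random(L) < delta
        calls[np.ix_(rows, dropped)] = MISSING
    if call_missing_rate > 0:
        calls[rng.random((n, L)) < call_missing_rate] = MISSING
    if error_rate > 0:
        flip = rng.random((n, L)) < error_rate
        which = rng.integers(2, size=(n, L))
        nonmiss = calls[:, :, 0] != MISSING
        flip &= nonmiss
        idx = np.nonzero(flip)
        calls[idx[0], idx[1], which[flip]] ^= 1
    return calls


# ---------------------------------------------------------------------------
# Scenario driver
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = [
    "individual",
    "taxon",
    "truth_class",
    "origin",
    "clonal_haplotype_id",
    "maternal_clade",
]


def simulate_dataset(
    scenario: SimScenario,
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Assemble the full synthetic dataset plus its truth table.

    Populations are generated in order: sexual species, hybridogen
    lineages, resurrection crosses, remnants; then the missingness and
    error regime is applied. Individual IDs are ``<taxon>_<k>``. Fully
    reproducible from the scenario seed.
    """
    scenario.validate()
    rng = np.random.default_rng(scenario.seed)
    freqs = simulate_ancestral_frequencies(scenario, rng)

    blocks: list[np.ndarray] = []
    taxa: list[str] = []
    truth_rows: list[dict] = []
    clone_store: dict[str, np.ndarray] = {}
    lineage_ghost: dict[str, str] = {}

    def add(taxon: str, geno: np.ndarray, rows: list[dict]) -> None:
        blocks.append(geno)
        taxa.extend([taxon] * geno.shape[0])
        truth_rows.extend(rows)

    for sp, n in scenario.sexual_n.items():
        geno = sample_sexual_population(freqs[sp], n, rng)
        add(
            sp,
            geno,
            [
                {
                    "taxon": sp,
                    "truth_class": "sexual",
                    "origin": sp,
                    "clonal_haplotype_id": "",
                    "maternal_clade": sp,
                }
                for _ in range(n)
            ],
        )
    for ln in scenario.lineages:
        geno, clones, assignment = found_hybridogen_lineage(
            freqs[ln.clonal_species],
            freqs[ln.host_species],
            ln.n,
            rng,
            generations=ln.generations,
            n_founder_clones=ln.n_founder_clones,
        )
        clone_store[ln.name] = clones[0]
        lineage_ghost[ln.name] = ln.clonal_species
        add(
            ln.name,
            geno,
            [
                {
                    "taxon": ln.name,
                    "truth_class": "hybridogen",
                    "origin": f"{ln.host_species}x{ln.clonal_species}",
                    "clonal_haplotype_id": f"{ln.name}.c{assignment[i]}",
                    "maternal_clade": ln.maternal,
                }
                for i in range(ln.n)
            ],
        )
    for rs in scenario.resurrections:
        if lineage_ghost[rs.lineage1] != lineage_ghost[rs.lineage2]:
            raise ScenarioError(
                f"resurrection {rs.name}: lineages carry different ghost "
                "species"
            )
        geno = simulate_resurrection_cross(
            clone_store[rs.lineage1], clone_store[rs.lineage2], rs.n
        )
        ghost = lineage_ghost[rs.lineage1]
        add(
            rs.name,
            geno,
            [
                {
                    "taxon": rs.name,
                    "truth_class": "resurrected",
                    "origin": ghost,
                    "clonal_haplotype_id": (
                        f"{rs.lineage1}.c0+{rs.lineage2}.c0"
                    ),
                    "maternal_clade": ghost,
                }
                for _ in range(rs.n)
            ],
        )
    for rm in scenario.remnants:
        geno, _ = simulate_remnant_population(
            freqs[rm.species], rm.f_drift, rm.n, rng
        )
        add(
            rm.name,
            geno,
            [
                {
                    "taxon": rm.name,
                    "truth_class": "remnant",
                    "origin": rm.species,
                    "clonal_haplotype_id": "",
                    "maternal_clade": rm.species,
                }
                for _ in range(rm.n)
            ],
        )
    if not blocks:
        raise ScenarioError("scenario defines no populations")

    calls = np.concatenate(blocks, axis=0)
    taxa_arr = np.array(taxa)
    calls = apply_missingness_and_error(
        calls,
        taxa_arr,
        scenario.dropout_by_taxon,
        scenario.call_missing_rate,
        scenario.genotyping_error_rate,
        rng,
    )

    counters: dict[str, int] = {}
    individuals = []
    for t in taxa:
        counters[t] = counters.get(t, 0) + 1
        individuals.append(f"{t}_{counters[t]:03d}")
    width = len(str(scenario.n_loci))
    loci = [
        LocusMeta(
            locus_id=f"L{j + 1:0{width}d}",
            alleles=("A", "C"),
            tag_id=f"tag{j + 1:0{width}d}",
            reproducibility=1.0,
            chrom="1",
            pos=j + 1,
        )
        for j in range(scenario.n_loci)
    ]
    ds = GenotypeDataset(
        individuals,
        loci,
        calls,
        taxon_map=dict(zip(individuals, taxa, strict=True)),
    )
    truth = pd.DataFrame(
        [
            {"individual": ind, **row}
            for ind, row in zip(individuals, truth_rows, strict=True)
        ],
        columns=TRUTH_COLUMNS,
    ).set_index("individual")
    return ds, truth


# ---------------------------------------------------------------------------
# Scenario (de)serialisation for the CLI
# ---------------------------------------------------------------------------


def scenario_to_dict(scenario: SimScenario) -> dict:
    d = asdict(scenario)
    d["diagnostic_counts"] = {
        f"{a},{b}": k for (a, b), k in scenario.diagnostic_counts.items()
    }
    return d


def scenario_from_dict(d: dict) -> SimScenario:
    d = dict(d)
    diag = {}
    for key, k in (d.pop("diagnostic_counts", {}) or {}).items():
        a, b = [s.strip() for s in key.split(",")]
        diag[(a, b)] = int(k)
    lineages = [LineageSpec(**x) for x in d.pop("lineages", [])]
    resurrections = [ResurrectionSpec(**x) for x in d.pop("resurrections", [])]
    remnants = [RemnantSpec(**x) for x in d.pop("remnants", [])]
    return SimScenario(
        diagnostic_counts=diag,
        lineages=lineages,
        resurrections=resurrections,
        remnants=remnants,
        **d,
    )
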