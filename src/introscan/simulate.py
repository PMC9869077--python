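"""Synthetic two-species genotype data with known ground truth.

Three generators:

* :func:`simulate_rsb` — a forward-in-time Wright–Fisher simulator of
  secondary contact in the spirit of the recurrent-selection-and-backcross
  picture of speciation with gene flow.  Two species start fixed for
  alternative alleles at every marker (so every marker is a d-site with
  F_ST = 1 in allopatry); each generation the sympatric demes receive
  migrants (continuous rate and/or pulses), reproduce by Wright–Fisher
  sampling with Poisson crossovers on the genetic map, and offspring
  survive with multiplicative viability (1-s) per heterospecific copy at
  each speciation locus.  Ancestry is tracked as exact junction lists per
  haplotype, so the simulator emits the true introgressed tracts of every
  sampled genome.

* :func:`plant_tracts` — plants introgressed tracts of known coordinates
  directly onto a fixed two-species background, with optional symmetric
  per-call miscall noise; the ground truth is exact by construction.

* :func:`simulate_neutral_panmictic` / :func:`simulate_species_pair` —
  thin msprime wrappers for the neutral coalescent scenarios (diversity
  calibration, allopatric F_ST spectra, LD-decay controls) where mutation
  and deep coalescent history matter and the forward machinery does not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix, PopulationManifest

logger = logging.getLogger(__name__)

M_LABEL, S_LABEL = 0, 1  # ancestry labels; the S allele is the alternate allele
SYMPATRIC_DEMES = ("m1", "s1")


class ExtinctionError(RuntimeError):
    """Viability selection rejected offspring indefinitely; lower s or raise N."""


# ---------------------------------------------------------------------------
# parameters and truth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Pulse:
    """A single hybridization pulse: a fraction of a deme replaced by
    migrants of the other species at one generation."""

    generation: int
    fraction: float
    deme: str  # "m1" or "s1"

    def __post_init__(self) -> None:
        if not 0 <= self.fraction <= 1:
            raise ValueError("pulse fraction must be in [0, 1]")
        if self.deme not in SYMPATRIC_DEMES:
            raise ValueError(f"pulse deme must be one of {SYMPATRIC_DEMES}")


@dataclass(frozen=True)
class SpeciationLocus:
    """A locus under viability selection against heterospecific alleles."""

    chromosome: int  # index into SimParams.chromosomes
    pos: int         # bp, 0-based physical coordinate
    s: float         # selection coefficient per heterospecific copy

    def __post_init__(self) -> None:
        if not 0 <= self.s <= 1:
            raise ValueError("selection coefficient must be in [0, 1]")


@dataclass
class SimParams:
    """Forward-simulation parameters.

    ``chromosomes`` is a list of (genetic length in Morgans, physical
    length in bp); the physical<->genetic map is linear per chromosome.
    ``markers_per_chromosome`` places that many uniformly spaced markers,
    unless ``marker_positions`` gives explicit 1-based positions.
    ``migration_rate`` is the per-generation probability that a resident
    of a sympatric deme is replaced by a pure migrant of the other
    species (continuous gene flow); ``pulses`` add episodic hybridization.
    """

    chromosomes: list[tuple[float, int]] = field(default_factory=lambda: [(1.0, 1_000_000)])
    markers_per_chromosome: int = 500
    marker_positions: list[np.ndarray] | None = None
    deme_size: int = 200
    migration_rate: float = 0.0
    pulses: list[Pulse] = field(default_factory=list)
    speciation_loci: list[SpeciationLocus] = field(default_factory=list)
    generations: int = 50
    samples_per_pool: dict[str, int] = field(
        default_factory=lambda: {"m_allo": 5, "s_allo": 5, "m1": 5, "s1": 5}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0 <= self.migration_rate <= 1:
            raise ValueError("migration_rate must be in [0, 1]")
        for morgans, bp in self.chromosomes:
            if morgans < 0 or bp <= 0:
                raise ValueError("chromosome maps must be positive")

    def positions(self) -> list[np.ndarray]:
        """1-based marker positions per chromosome."""
        if self.marker_positions is not None:
            out = []
            for pos, (_, bp) in zip(self.marker_positions, self.chromosomes):
                p = np.asarray(pos, dtype=np.int64)
                if p.size and ((p < 1).any() or (p > bp).any() or (np.diff(p) <= 0).any()):
                    raise ValueError("marker positions must be sorted within [1, length]")
                out.append(p)
            return out
        out = []
        k = self.markers_per_chromosome
        for _, bp in self.chromosomes:
            p = np.unique(np.round((np.arange(k) + 0.5) * bp / k).astype(np.int64))
            out.append(np.clip(p, 1, bp))
        return out

    def contig_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chromosomes))]


@dataclass(frozen=True)
class TruthTract:
    """A simulator-known introgressed ancestry segment (0-based half-open)."""

    sample: str
    haplotype: int  # 0 or 1
    contig: str
    start: int
    end: int
    donor: str  # "M" or "S"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("tract start must be < end")


# ---------------------------------------------------------------------------
# haplotype machinery (junction lists)
# ---------------------------------------------------------------------------
# A haplotype on one chromosome is (breaks, labels): ``breaks`` are the
# integer bp end positions of the piecewise-constant ancestry segments
# (last element = chromosome length), ``labels`` their ancestry (0=M, 1=S).

Hap = tuple[np.ndarray, np.ndarray]


def _pure_hap(length: int, label: int) -> Hap:
    return (np.array([length], dtype=np.int64), np.array([label], dtype=np.int8))


def _hap_is_pure(h: Hap) -> bool:
    return h[1].size == 1


def _label_at(h: Hap, pos: int) -> int:
    """Ancestry label at 0-based bp coordinate ``pos``."""
    return int(h[1][np.searchsorted(h[0], pos, side="right")])


def _recombine(h1: Hap, h2: Hap, xo: np.ndarray, start_first: bool, length: int) -> Hap:
    """Form a gamete from two haplotypes with crossovers at ``xo`` (sorted,
    strictly inside (0, length))."""
    haps = (h1, h2)
    cur = 0 if start_first else 1
    out_br: list[int] = []
    out_la: list[int] = []
    prev = 0
    for x in [*xo.tolist(), length]:
        br, la = haps[cur]
        i = int(np.searchsorted(br, prev, side="right"))
        p = prev
        while p < x:
            e = min(int(br[i]), x)
            lab = int(la[i])
            if out_la and out_la[-1] == lab:
                out_br[-1] = e
            else:
                out_br.append(e)
                out_la.append(lab)
            p = e
            i += 1
        prev = x
        cur ^= 1
    return (np.asarray(out_br, dtype=np.int64), np.asarray(out_la, dtype=np.int8))


# An individual is a list over chromosomes of (hapA, hapB).
Individual = list[tuple[Hap, Hap]]


def _gamete(ind: Individual, chrom: int, morgans: float, length: int,
            rng: np.random.Generator) -> Hap:
    h1, h2 = ind[chrom]
    if _hap_is_pure(h1) and _hap_is_pure(h2) and h1[1][0] == h2[1][0]:
        return h1  # identical ancestry whatever the crossovers
    k = int(rng.poisson(morgans))
    if k == 0:
        return h1 if rng.integers(2) == 0 else h2
    xo = np.unique((rng.random(k) * length).astype(np.int64))
    xo = xo[(xo > 0) & (xo < length)]
    if xo.size == 0:
        return h1 if rng.integers(2) == 0 else h2
    return _recombine(h1, h2, xo, bool(rng.integers(2) == 0), length)


def _fitness(child: Individual, own: int, loci: Sequence[SpeciationLocus]) -> float:
    w = 1.0
    for locus in loci:
        h1, h2 = child[locus.chromosome]
        copies = int(_label_at(h1, locus.pos) != own) + int(_label_at(h2, locus.pos) != own)
        if copies:
            w *= (1.0 - locus.s) ** copies
    return w


def _evolve_deme(
    own: int,
    params: SimParams,
    rng: np.random.Generator,
) -> list[Individual]:
    """Run one sympatric deme forward for ``params.generations``."""
    deme_name = "m1" if own == M_LABEL else "s1"
    other = S_LABEL if own == M_LABEL else M_LABEL
    N = params.deme_size
    lengths = [bp for _, bp in params.chromosomes]
    morgans = [m for m, _ in params.chromosomes]
    n_chrom = len(params.chromosomes)

    pulses = {p.generation: p.fraction for p in params.pulses if p.deme == deme_name}
    if params.migration_rate == 0 and not pulses:
        # no gene flow: ancestry stays pure, drift is invisible to it
        return [
            [( _pure_hap(lengths[c], own), _pure_hap(lengths[c], own))
             for c in range(n_chrom)]
            for _ in range(N)
        ]

    pop: list[Individual] = [
        [( _pure_hap(lengths[c], own), _pure_hap(lengths[c], own))
         for c in range(n_chrom)]
        for _ in range(N)
    ]
    migrant: Individual = [
        (_pure_hap(lengths[c], other), _pure_hap(lengths[c], other))
        for c in range(n_chrom)
    ]
    loci = params.speciation_loci

    for t in range(params.generations):
        # (1) migrant replacement
        expected = params.migration_rate * N + pulses.get(t, 0.0) * N
        if expected > 0:
            n_mig = min(int(rng.poisson(expected)), N)
            if n_mig:
                for i in rng.choice(N, size=n_mig, replace=False):
                    pop[i] = list(migrant)
        # (2)-(4) Wright-Fisher reproduction, recombination, viability
        new: list[Individual] = []
        rejections = 0
        while len(new) < N:
            pa = pop[int(rng.integers(N))]
            pb = pop[int(rng.integers(N))]
            child: Individual = [
                (_gamete(pa, c, morgans[c], lengths[c], rng),
                 _gamete(pb, c, morgans[c], lengths[c], rng))
                for c in range(n_chrom)
            ]
            w = _fitness(child, own, loci) if loci else 1.0
            if w >= 1.0 or rng.random() < w:
                new.append(child)
            else:
                rejections += 1
                if rejections > 2000 * N:
                    raise ExtinctionError(
                        f"deme {deme_name}: selection rejected {rejections} "
                        "offspring; reduce s or the number of selected loci"
                    )
        pop = new
    return pop


# ---------------------------------------------------------------------------
# output assembly
# ---------------------------------------------------------------------------

def _default_manifest(samples_per_pool: dict[str, int]) -> tuple[PopulationManifest, dict[str, list[str]]]:
    rows = []
    pool_samples: dict[str, list[str]] = {}
    meta = {
        "m_allo": ("m2", "M", "allopatric"),
        "s_allo": ("s2", "S", "allopatric"),
        "m1": ("m1", "M", "sympatric"),
        "s1": ("s1", "S", "sympatric"),
    }
    for pool, count in samples_per_pool.items():
        popn, species, context = meta[pool]
        names = [f"{popn}_{i}" for i in range(count)]
        pool_samples[pool] = names
        rows += [
            {"sample": s, "population": popn, "species": species, "context": context}
            for s in names
        ]
    return PopulationManifest(pd.DataFrame(rows)), pool_samples


def _hap_alleles(h: Hap, pos_1based: np.ndarray) -> np.ndarray:
    """Alternate-allele (= S-ancestry) indicator at the given markers."""
    idx = np.searchsorted(h[0], pos_1based - 1, side="right")
    return h[1][idx].astype(np.int8)


def _tracts_of(h: Hap, own: int, sample: str, hap_index: int, contig: str) -> list[TruthTract]:
    br, la = h
    donor = "S" if own == M_LABEL else "M"
    out = []
    start = 0
    for e, lab in zip(br.tolist(), la.tolist()):
        if lab != own:
            out.append(TruthTract(sample, hap_index, contig, start, int(e), donor))
        start = int(e)
    return out


@dataclass
class RsbResult:
    """Forward-simulation output; iterable as (genotypes, manifest, tracts)."""

    genotypes: GenotypeMatrix
    manifest: PopulationManifest
    truth_tracts: list[TruthTract]
    params: SimParams
    _demes: dict[str, list[Individual]] = field(repr=False, default_factory=dict)

    def __iter__(self) -> Iterator:
        return iter((self.genotypes, self.manifest, self.truth_tracts))

    def deme_ancestry_freq(self, deme: str, chromosome: int, pos: int) -> float:
        """Heterospecific-ancestry frequency at a bp position in a full deme
        (not just the sampled individuals)."""
        own = M_LABEL if deme == "m1" else S_LABEL
        pop = self._demes[deme]
        het = sum(
            int(_label_at(h, pos) != own)
            for ind in pop
            for h in ind[chromosome]
        )
        return het / (2 * len(pop))

    def deme_ancestry_profile(self, deme: str, chromosome: int, grid: np.ndarray) -> np.ndarray:
        """Heterospecific-ancestry frequency at each grid position (bp)."""
        return np.array([self.deme_ancestry_freq(deme, chromosome, int(p)) for p in grid])


def simulate_rsb(params: SimParams) -> RsbResult:
    """Forward-simulate secondary contact and return genotypes, manifest and
    the exact introgressed tracts of every sampled haplotype.

    Species M is fixed for the reference allele and species S for the
    alternate allele at every marker, so in allopatry every marker is a
    fully divergent d-site.  Allopatric demes receive no migrants and are
    emitted as pure individuals.
    """
    rng = np.random.default_rng(params.seed)
    demes = {
        "m1": _evolve_deme(M_LABEL, params, rng),
        "s1": _evolve_deme(S_LABEL, params, rng),
    }
    manifest, pool_samples = _default_manifest(params.samples_per_pool)
    positions = params.positions()
    names = params.contig_names()
    lengths = [bp for _, bp in params.chromosomes]

    sampled: dict[str, Individual] = {}
    for pool in ("m_allo", "s_allo", "m1", "s1"):
        want = pool_samples.get(pool, [])
        if not want:
            continue
        if pool in demes:
            pick = rng.choice(len(demes[pool]), size=len(want), replace=False)
            for s, i in zip(want, pick):
                sampled[s] = demes[pool][int(i)]
        else:
            label = M_LABEL if pool == "m_allo" else S_LABEL
            for s in want:
                sampled[s] = [
                    (_pure_hap(lengths[c], label), _pure_hap(lengths[c], label))
                    for c in range(len(lengths))
                ]

    samples = manifest.samples
    n_sites = sum(p.size for p in positions)
    calls = np.empty((len(samples), n_sites), dtype=np.int8)
    tracts: list[TruthTract] = []
    species_of = dict(zip(manifest.entries["sample"], manifest.entries["species"]))
    context_of = dict(zip(manifest.entries["sample"], manifest.entries["context"]))
    for row, s in enumerate(samples):
        ind = sampled[s]
        own = M_LABEL if species_of[s] == "M" else S_LABEL
        gt = []
        for c, pos in enumerate(positions):
            a = _hap_alleles(ind[c][0], pos)
            b = _hap_alleles(ind[c][1], pos)
            gt.append(a + b)
            if context_of[s] == "sympatric":
                tracts += _tracts_of(ind[c][0], own, s, 0, names[c])
                tracts += _tracts_of(ind[c][1], own, s, 1, names[c])
        calls[row] = np.concatenate(gt) if gt else np.empty(0, dtype=np.int8)

    contig_col = np.concatenate(
        [np.full(p.size, names[c], dtype=object) for c, p in enumerate(positions)]
    ) if n_sites else np.empty(0, dtype=object)
    pos_col = np.concatenate(positions) if n_sites else np.empty(0, dtype=np.int64)
    g = GenotypeMatrix(
        samples=samples,
        contigs=names,
        contig=contig_col,
        pos=pos_col,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        calls=calls,
    )
    return RsbResult(g, manifest, tracts, params, demes)


# ---------------------------------------------------------------------------
# tract planting
# ---------------------------------------------------------------------------

def plant_tracts(
    contigs: Sequence[tuple[str, int]],
    marker_spacing: int,
    *,
    n_tracts: int,
    mean_length: float,
    target_pool: str = "m1",
    carriers: int = 9,
    noise: float = 0.0,
    samples_per_pool: int = 5,
    length_distribution: str = "exponential",
    edge_margin: int | None = None,
    seed: int = 0,
) -> tuple[GenotypeMatrix, PopulationManifest, list[TruthTract]]:
    """Plant introgressed tracts with exact known coordinates.

    Starts from the fixed two-species configuration (markers every
    ``marker_spacing`` bp), draws ``n_tracts`` mutually disjoint tracts
    (exponential or fixed lengths, mean ``mean_length``), copies the donor
    allele onto ``carriers`` of the target pool's ``2 * samples_per_pool``
    haplotypes over each tract, then applies independent symmetric
    per-call miscalls at rate ``noise``.  Tracts keep ``edge_margin`` bp
    (default: one marker spacing) clear of contig ends so every tract
    boundary is bracketed by markers.
    """
    if target_pool not in SYMPATRIC_DEMES:
        raise ValueError(f"target_pool must be one of {SYMPATRIC_DEMES}")
    rng = np.random.default_rng(seed)
    if edge_margin is None:
        edge_margin = marker_spacing
    n_hap = 2 * samples_per_pool
    if not 0 <= carriers <= n_hap:
        raise ValueError(f"carriers must be in [0, {n_hap}]")

    names = [c for c, _ in contigs]
    lengths = {c: n for c, n in contigs}
    weights = np.array([n for _, n in contigs], dtype=float)
    weights /= weights.sum()

    # draw disjoint tracts (0-based half-open)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in names}
    tract_list: list[tuple[str, int, int]] = []
    attempts = 0
    while len(tract_list) < n_tracts:
        attempts += 1
        if attempts > 200 * max(n_tracts, 1):
            raise ValueError(
                "could not place disjoint tracts; reduce n_tracts or mean_length"
            )
        if length_distribution == "exponential":
            tlen = max(1, int(rng.exponential(mean_length)))
        elif length_distribution == "fixed":
            tlen = int(mean_length)
        else:
            raise ValueError(f"unknown length_distribution {length_distribution!r}")
        c = names[int(rng.choice(len(names), p=weights))]
        hi = lengths[c] - edge_margin - tlen
        if hi <= edge_margin:
            continue
        start = int(rng.integers(edge_margin, hi))
        end = start + tlen
        if any(start < e and b < end for b, e in placed[c]):
            continue
        placed[c].append((start, end))
        tract_list.append((c, start, end))

    manifest, pool_samples = _default_manifest(
        {p: samples_per_pool for p in ("m_allo", "s_allo", "m1", "s1")}
    )
    positions = {
        c: np.arange(marker_spacing, lengths[c] + 1, marker_spacing, dtype=np.int64)
        for c in names
    }
    n_sites = sum(p.size for p in positions.values())
    samples = manifest.samples
    species = dict(zip(manifest.entries["sample"], manifest.entries["species"]))

    # haplotype allele matrices: S allele = 1
    hap_alleles = {
        s: [
            np.full(n_sites, S_LABEL if species[s] == "S" else M_LABEL, dtype=np.int8)
            for _ in range(2)
        ]
        for s in samples
    }

    offsets = {}
    off = 0
    for c in names:
        offsets[c] = off
        off += positions[c].size

    donor_label = S_LABEL if target_pool == "m1" else M_LABEL
    donor_name = "S" if target_pool == "m1" else "M"
    target_samples = pool_samples[target_pool]
    truth: list[TruthTract] = []
    for c, start, end in sorted(tract_list):
        pos = positions[c]
        lo = offsets[c] + int(np.searchsorted(pos, start, side="right"))  # pos-1 >= start
        hi = offsets[c] + int(np.searchsorted(pos, end, side="right"))    # pos-1 < end
        chosen = rng.choice(n_hap, size=carriers, replace=False)
        for h in chosen:
            s = target_samples[h // 2]
            hap_alleles[s][h % 2][lo:hi] = donor_label
            truth.append(TruthTract(s, h % 2, c, start, end, donor_name))

    if noise > 0:
        for s in samples:
            for h in range(2):
                flip = rng.random(n_sites) < noise
                hap_alleles[s][h] = np.where(
                    flip, 1 - hap_alleles[s][h], hap_alleles[s][h]
                ).astype(np.int8)

    calls = np.stack([hap_alleles[s][0] + hap_alleles[s][1] for s in samples])
    contig_col = np.concatenate(
        [np.full(positions[c].size, c, dtype=object) for c in names]
    ) if n_sites else np.empty(0, dtype=object)
    pos_col = np.concatenate([positions[c] for c in names]) if n_sites else np.empty(0, dtype=np.int64)
    g = GenotypeMatrix(
        samples=samples,
        contigs=list(names),
        contig=contig_col,
        pos=pos_col,
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        calls=calls,
    )
    truth.sort(key=lambda t: (t.sample, t.haplotype, t.contig, t.start))
    return g, manifest, truth


def export_truth(tracts: Sequence[TruthTract], path: str | Path) -> None:
    """Write truth tracts as BED with sample/haplotype/donor in the name column."""
    by_hap: dict[tuple[str, int, str], list[TruthTract]] = {}
    for t in tracts:
        by_hap.setdefault((t.sample, t.haplotype, t.contig), []).append(t)
    for key, group in by_hap.items():
        group = sorted(group, key=lambda t: t.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping truth tracts on haplotype {key}")
    ordered = sorted(tracts, key=lambda t: (t.contig, t.start, t.sample, t.haplotype))
    with open(path, "w") as fh:
        fh.write("#contig\tstart\tend\tname\n")
        for t in ordered:
            fh.write(f"{t.contig}\t{t.start}\t{t.end}\t{t.sample}|h{t.haplotype}|{t.donor}\n")


# ---------------------------------------------------------------------------
# neutral coalescent scenarios (msprime)
# ---------------------------------------------------------------------------

def _ts_to_genotype_matrix(ts, samples: list[str], contig: str = "chr1") -> GenotypeMatrix:
    gm = ts.genotype_matrix()  # (sites, haploids)
    pos = np.array([int(v.position) + 1 for v in ts.variants()], dtype=np.int64)
    # collapse duplicate integer positions (finite-sites projection)
    keep = np.concatenate([[True], np.diff(pos) > 0]) if pos.size else np.array([], bool)
    gm = gm[keep]
    pos = pos[keep]
    biallelic = (gm.max(axis=1) <= 1) if gm.size else np.array([], bool)
    gm = gm[biallelic]
    pos = pos[biallelic]
    calls = (gm[:, 0::2] + gm[:, 1::2]).T.astype(np.int8)
    n = pos.size
    return GenotypeMatrix(
        samples=samples,
        contigs=[contig],
        contig=np.full(n, contig, dtype=object),
        pos=pos,
        ref=np.full(n, "A", dtype=object),
        alt=np.full(n, "C", dtype=object),
        calls=calls,
    )


def simulate_neutral_panmictic(
    n_diploids: int = 10,
    Ne: float = 10_000,
    length: int = 500_000,
    mu: float = 1e-8,
    r: float = 1e-8,
    seed: int = 1,
) -> tuple[GenotypeMatrix, list[str]]:
    """Neutral constant-size panmictic sample (msprime); returns the
    genotype matrix and the sample pool."""
    import msprime

    ts = msprime.sim_ancestry(
        samples=n_diploids, ploidy=2, population_size=Ne,
        sequence_length=length, recombination_rate=r, random_seed=max(1, seed),
    )
    ts = msprime.sim_mutations(
        ts, rate=mu, random_seed=max(1, seed) + 1,
        model=msprime.BinaryMutationModel(),
    )
    samples = [f"n_{i}" for i in range(n_diploids)]
    return _ts_to_genotype_matrix(ts, samples), samples


def simulate_species_pair(
    n_per_pop: int = 8,
    Ne: float = 20_000,
    split_generations: float = 400_000,
    migration_rate: float = 0.0,
    contact_generations: float = 0.0,
    length: int = 500_000,
    mu: float = 1e-8,
    r: float = 1e-8,
    context: str = "allopatric",
    seed: int = 1,
) -> tuple[GenotypeMatrix, PopulationManifest]:
    """Two populations split ``split_generations`` ago, optionally exchanging
    migrants at ``migration_rate`` for the most recent
    ``contact_generations`` (secondary contact).  Deep splits with no
    contact emulate the allopatric species pair (U-shaped F_ST spectrum);
    adding contact erodes the divergent sites (L-shaped spectrum) and
    builds a high-diversity admixed deme for LD comparisons.
    """
    import msprime

    dem = msprime.Demography()
    dem.add_population(name="M", initial_size=Ne)
    dem.add_population(name="S", initial_size=Ne)
    dem.add_population(name="anc", initial_size=Ne)
    if migration_rate > 0 and contact_generations > 0:
        dem.set_migration_rate("M", "S", migration_rate)
        dem.set_migration_rate("S", "M", migration_rate)
        dem.add_migration_rate_change(
            time=contact_generations, rate=0.0, source="M", dest="S"
        )
        dem.add_migration_rate_change(
            time=contact_generations, rate=0.0, source="S", dest="M"
        )
    dem.add_population_split(time=split_generations, derived=["M", "S"], ancestral="anc")
    dem.sort_events()
    ts = msprime.sim_ancestry(
        samples={"M": n_per_pop, "S": n_per_pop}, ploidy=2, demography=dem,
        sequence_length=length, recombination_rate=r, random_seed=max(1, seed),
    )
    ts = msprime.sim_mutations(
        ts, rate=mu, random_seed=max(1, seed) + 1,
        model=msprime.BinaryMutationModel(),
    )
    samples = [f"M_{i}" for i in range(n_per_pop)] + [f"S_{i}" for i in range(n_per_pop)]
    g = _ts_to_genotype_matrix(ts, samples)
    rows = [
        {"sample": s, "population": "Mpop" if s.startswith("M") else "Spop",
         "species": s[0], "context": context}
        for s in samples
    ]
    return g, PopulationManifest(pd.DataFrame(rows))
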