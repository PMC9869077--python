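"""Input/output layer: VCF genotypes, population manifests, contig tables,
GFF3 gene models and BED/TSV writers.

Internal coordinate convention: site positions are 1-based (VCF convention).
Block intervals are stored 0-based half-open so that BED emission is a plain
column dump; the conversion happens once, at block construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing diploid genotype call.
MISSING: int = -1

MANIFEST_COLUMNS = ("sample", "population", "species", "context")
VALID_SPECIES = ("M", "S")
VALID_CONTEXTS = ("allopatric", "sympatric")


class InputError(ValueError):
    """Raised when an input file violates its contract."""


# ---------------------------------------------------------------------------
# core containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid genotypes for all samples at all biallelic SNP sites.

    ``calls`` is an ``(n_samples, n_sites)`` int8 array holding the count of
    alternate-allele copies (0, 1, 2) or :data:`MISSING`.  Sites are grouped
    by contig (in ``contigs`` order) and strictly increasing in position
    within each contig; positions are 1-based.
    """

    samples: list[str]
    contigs: list[str]
    contig: np.ndarray  # per-site contig name, dtype=object
    pos: np.ndarray     # per-site 1-based position, int64
    ref: np.ndarray     # per-site reference allele (single nucleotide)
    alt: np.ndarray     # per-site alternate allele (single nucleotide)
    calls: np.ndarray   # (n_samples, n_sites) int8

    def __post_init__(self) -> None:
        self.contig = np.asarray(self.contig, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        if self.calls.shape != (len(self.samples), self.pos.size):
            raise InputError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {self.pos.size} sites"
            )
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            bad = np.unique(self.calls[~ok])
            raise InputError(f"invalid genotype codes {bad.tolist()}")
        for c in self.contigs:
            p = self.pos[self.contig == c]
            if p.size and not (np.diff(p) > 0).all():
                raise InputError(f"positions not strictly increasing on {c}")

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_indices(self, pool: Iterable[str]) -> np.ndarray:
        """Row indices of the given samples (order of ``pool``)."""
        lookup = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.asarray([lookup[s] for s in pool], dtype=np.intp)
        except KeyError as exc:
            raise InputError(f"sample {exc.args[0]!r} not in genotype matrix") from None

    def pool_calls(self, pool: Iterable[str]) -> np.ndarray:
        """Genotype sub-matrix for a sample pool, shape (len(pool), n_sites)."""
        return self.calls[self.sample_indices(pool)]

    def contig_slice(self, contig: str) -> slice:
        """Contiguous site slice of one contig (sites are grouped by contig)."""
        idx = np.flatnonzero(self.contig == contig)
        if idx.size == 0:
            return slice(0, 0)
        return slice(int(idx[0]), int(idx[-1]) + 1)


@dataclass
class PopulationManifest:
    """Sample -> (population, species, context) assignment.

    The four derived pools drive the whole analysis: ``m_allo``/``s_allo``
    are the allopatric reference panels of each species and ``m1``/``s1``
    the sympatric pair tested for introgression.
    """

    entries: pd.DataFrame  # columns: sample, population, species, context

    def __post_init__(self) -> None:
        df = self.entries
        missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
        if missing:
            raise InputError(f"manifest missing column(s): {missing}")
        dup = df["sample"][df["sample"].duplicated()]
        if len(dup):
            raise InputError(f"duplicate sample(s) in manifest: {sorted(set(dup))}")
        bad_sp = sorted(set(df["species"]) - set(VALID_SPECIES))
        if bad_sp:
            raise InputError(
                f"invalid species {bad_sp}; allowed values: {list(VALID_SPECIES)}"
            )
        bad_cx = sorted(set(df["context"]) - set(VALID_CONTEXTS))
        if bad_cx:
            raise InputError(
                f"invalid context {bad_cx}; allowed values: {list(VALID_CONTEXTS)}"
            )
        self.entries = df.reset_index(drop=True)

    def _pool(self, species: str, context: str) -> list[str]:
        df = self.entries
        sel = (df["species"] == species) & (df["context"] == context)
        return df.loc[sel, "sample"].tolist()

    @property
    def m_allo(self) -> list[str]:
        return self._pool("M", "allopatric")

    @property
    def s_allo(self) -> list[str]:
        return self._pool("S", "allopatric")

    @property
    def m1(self) -> list[str]:
        return self._pool("M", "sympatric")

    @property
    def s1(self) -> list[str]:
        return self._pool("S", "sympatric")

    @property
    def samples(self) -> list[str]:
        return self.entries["sample"].tolist()

    def require_full(self) -> None:
        """Check that every (species, context) pool is non-empty."""
        for name in ("m_allo", "s_allo", "m1", "s1"):
            if not getattr(self, name):
                raise InputError(f"manifest pool {name!r} is empty")

    def swap_species(self) -> "PopulationManifest":
        """Relabel M<->S (used for symmetry checks)."""
        df = self.entries.copy()
        df["species"] = df["species"].map({"M": "S", "S": "M"})
        return PopulationManifest(df)


@dataclass
class ContigTable:
    """Contig lengths in bp; denominator of the percent-of-genome summaries."""

    lengths: dict[str, int]

    def __post_init__(self) -> None:
        for c, n in self.lengths.items():
            if n <= 0:
                raise InputError(f"contig {c!r} has non-positive length {n}")

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def require_contigs(self, contigs: Iterable[str]) -> None:
        absent = [c for c in contigs if c not in self.lengths]
        if absent:
            raise InputError(f"contig(s) absent from contig table: {absent}")


@dataclass(frozen=True)
class GeneModel:
    """One gene feature from a GFF3 annotation (1-based inclusive)."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise InputError(
                f"gene {self.gene_id!r}: start {self.start} > end {self.end}"
            )


@dataclass(frozen=True)
class Block:
    """A contiguous i-block or j-block.

    ``start``/``end`` are 0-based half-open bp coordinates (BED-ready);
    ``sites`` are the 1-based positions of the member d-sites.
    """

    contig: str
    start: int
    end: int
    kind: str  # i_m1 | i_s1 | j
    sites: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError(f"block {self}: start >= end")
        for p in self.sites:
            if not (self.start < p <= self.end):
                raise InputError(f"block {self}: member site {p} outside interval")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def is_singleton(self) -> bool:
        return len(self.sites) == 1

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_manifest(path: str | Path) -> PopulationManifest:
    """Read the population manifest TSV (columns: sample, population, species, context)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return PopulationManifest(df)


def read_contigs(path: str | Path) -> ContigTable:
    """Read a two-column TSV ``contig<TAB>length``."""
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "length": np.int64})
    if not {"contig", "length"} <= set(df.columns):
        raise InputError("contig table needs columns 'contig' and 'length'")
    return ContigTable(dict(zip(df["contig"], df["length"].astype(int))))


_NUCS = frozenset("ACGT")


def read_vcf(path: str | Path, manifest: PopulationManifest) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF 4.x file into a :class:`GenotypeMatrix`.

    Indels, multiallelic records and non-SNP alleles are dropped (and counted
    in the log).  Every manifest sample must be present in the VCF header.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    header_samples = list(vcf.samples)
    absent = [s for s in manifest.samples if s not in header_samples]
    if absent:
        raise InputError(f"manifest sample(s) missing from VCF: {absent}")

    contigs: list[str] = []
    contig_col: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    calls: list[np.ndarray] = []
    dropped = 0
    last_pos: dict[str, int] = {}

    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            dropped += 1
            continue
        if v.REF not in _NUCS or v.ALT[0] not in _NUCS:
            dropped += 1
            continue
        c = v.CHROM
        if c not in last_pos:
            if c in contigs:
                raise InputError(f"VCF not sorted: contig {c!r} appears twice")
            contigs.append(c)
        elif v.POS <= last_pos[c]:
            raise InputError(
                f"VCF not sorted: {c}:{v.POS} after {c}:{last_pos[c]}"
            )
        last_pos[c] = v.POS
        contig_col.append(c)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        # gts012: 0/1/2 = alt copies, 3 = unknown
        g = v.gt_types.astype(np.int8)
        g[g == 3] = MISSING
        calls.append(g)

    if dropped:
        logger.info("read_vcf: dropped %d non-biallelic-SNP record(s)", dropped)
    logger.info("read_vcf: %d biallelic SNP site(s), %d sample(s)",
                len(pos), len(header_samples))

    call_matrix = (
        np.stack(calls, axis=1) if calls
        else np.empty((len(header_samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        samples=header_samples,
        contigs=contigs,
        contig=np.asarray(contig_col, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        calls=call_matrix,
    )


def read_gff_genes(path: str | Path) -> list[GeneModel]:
    """Extract gene features from a GFF3 file; all other features are ignored."""
    import gffutils

    # coordinate sanity pass with line numbers (gffutils does not report them)
    n_features = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            n_features += 1
            if cols[2] == "gene":
                try:
                    start, end = int(cols[3]), int(cols[4])
                except ValueError:
                    raise InputError(f"{path}:{lineno}: malformed coordinates")
                if end < start:
                    raise InputError(
                        f"{path}:{lineno}: gene end {end} < start {start}"
                    )

    if n_features == 0:
        return []
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        genes.append(
            GeneModel(
                gene_id=feat.id,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand or ".",
            )
        )
    return genes


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    g: GenotypeMatrix,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write the genotype matrix as a minimal VCF 4.2 file (GT only)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=introscan\n")
        for c in g.contigs:
            if contig_lengths and c in contig_lengths:
                fh.write(f"##contig=<ID={c},length={contig_lengths[c]}>\n")
            else:
                fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples) + "\n"
        )
        for k in range(g.n_sites):
            gts = "\t".join(_GT_STRING[int(v)] for v in g.calls[:, k])
            fh.write(
                f"{g.contig[k]}\t{g.pos[k]}\t.\t{g.ref[k]}\t{g.alt[k]}\t.\tPASS\t.\tGT\t{gts}\n"
            )

def _check_disjoint(blocks: Sequence[Block]) -> None:
    by_key: dict[tuple[str, str], list[Block]] = {}
    for b in blocks:
        by_key.setdefault((b.contig, b.kind), []).append(b)
    for (contig, kind), group in by_key.items():
        group = sorted(group, key=lambda b: b.start)
        for prev, nxt in zip(group, group[1:]):
            if nxt.start < prev.end:
                raise InputError(
                    f"overlapping {kind} blocks on {contig}: "
                    f"[{prev.start},{prev.end}) and [{nxt.start},{nxt.end})"
                )


def write_blocks_bed(blocks: Sequence[Block], path: str | Path) -> None:
    """Write blocks as BED (0-based half-open); name = kind, score = n_sites."""
    _check_disjoint(blocks)
    ordered = sorted(blocks, key=lambda b: (b.contig, b.start))
    with open(path, "w") as fh:
        fh.write("#contig\tstart\tend\tkind\tn_sites\n")
        for b in ordered:
            fh.write(f"{b.contig}\t{b.start}\t{b.end}\t{b.kind}\t{b.n_sites}\n")


def read_blocks_bed(path: str | Path, site_table: pd.DataFrame | None = None) -> list[Block]:
    """Read a block BED written by :func:`write_blocks_bed`.

    If ``site_table`` (the site-class table) is given, member sites are
    reconstituted; otherwise blocks carry no member positions (an interior
    representative position is synthesised to satisfy the invariant).
    """
    blocks: list[Block] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            contig, start, end, kind, n = line.rstrip("\n").split("\t")
            start_i, end_i = int(start), int(end)
            if site_table is not None:
                sel = (
                    (site_table["contig"] == contig)
                    & (site_table["pos"] > start_i)
                    & (site_table["pos"] <= end_i)
                    & (site_table["cls"] == kind)
                )
                sites = tuple(int(p) for p in site_table.loc[sel, "pos"])
            else:
                sites = tuple([end_i])
            blocks.append(Block(contig, start_i, end_i, kind, sites))
    return blocks


def write_site_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-d-site classification table as TSV."""
    table.to_csv(path, sep="\t", index=False)


def read_site_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str, "cls": str})
    return df
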