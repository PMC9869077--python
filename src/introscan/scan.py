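"""The introgression scan: d-site calling, diagnostic alleles, i-allele
counting, the asymmetric i/j/undefined site classification, block
delineation by the midpoint rule, genotype painting and Table-style
summaries.

The scan answers one question per divergent SNP (d-site, F_ST > 0.8
between the two species' allopatric panels): in the sympatric pair of
populations, does the *other* species' diagnostic allele (the i-allele)
occur at high, strongly asymmetric frequency (an introgressed i-site), is
it essentially absent from both sides (a non-introgressable j-site), or is
the evidence intermediate (undefined)?  Maximal runs of same-class sites
along the d-site sequence form i-blocks and j-blocks, whose physical
boundaries are the midpoints between the outermost member site and the
nearest interrupting d-site.

The :class:`IntrogressionScan` model and :class:`IntrogressionScanResults`
wrap the individual steps in a fit/results interface; every step is also a
plain function for use in pipelines and tests.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    Block,
    ContigTable,
    GeneModel,
    GenotypeMatrix,
    PopulationManifest,
)
from . import popgen_stats as ps

logger = logging.getLogger(__name__)

BLOCK_KINDS = ("i_m1", "i_s1", "j")
SITE_CLASSES = ("i_m1", "i_s1", "j", "undefined")


# ---------------------------------------------------------------------------
# d-sites and diagnostic alleles
# ---------------------------------------------------------------------------

def call_d_sites(fst: np.ndarray, threshold: float = 0.8) -> np.ndarray:
    """Indices of divergent sites: F_ST strictly above ``threshold``.

    ``fst`` must be the per-site F_ST between the allopatric panels
    (M_allo vs S_allo); unscored sites (NaN) are never d-sites.
    """
    with np.errstate(invalid="ignore"):
        mask = np.nan_to_num(np.asarray(fst, dtype=float), nan=-np.inf) > threshold
    return np.flatnonzero(mask)


@dataclass
class DiagnosticAlleles:
    """Species-diagnostic alleles at each retained d-site.

    ``m_diag_is_alt[k]`` is True when the allele diagnostic of species M at
    d-site k is the alternate allele (S-diagnostic is then the reference,
    and vice versa — the two always differ).  ``site_idx`` indexes into the
    genotype matrix; d-sites with coincident majority alleles or an exact
    50/50 tie in a panel are dropped (and logged) before this table.
    """

    site_idx: np.ndarray      # intp, into GenotypeMatrix sites
    m_diag_is_alt: np.ndarray  # bool
    p_alt_m_allo: np.ndarray
    p_alt_s_allo: np.ndarray


def diagnostic_alleles(
    g: GenotypeMatrix,
    manifest: PopulationManifest,
    d_sites: np.ndarray,
) -> DiagnosticAlleles:
    """Call the M- and S-diagnostic allele at each d-site by majority rule
    in the allopatric panels."""
    pm = ps.allele_freqs(g, manifest.m_allo).p[d_sites]
    pss = ps.allele_freqs(g, manifest.s_allo).p[d_sites]
    tie = (pm == 0.5) | (pss == 0.5)
    m_is_alt = pm > 0.5
    s_is_alt = pss > 0.5
    coincident = m_is_alt == s_is_alt
    keep = ~(tie | coincident | np.isnan(pm) | np.isnan(pss))
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info(
            "diagnostic_alleles: dropped %d d-site(s) (tie or coincident "
            "majority allele)", n_drop,
        )
    return DiagnosticAlleles(
        site_idx=np.asarray(d_sites)[keep],
        m_diag_is_alt=m_is_alt[keep],
        p_alt_m_allo=pm[keep],
        p_alt_s_allo=pss[keep],
    )


# ---------------------------------------------------------------------------
# i-allele counts and site classification
# ---------------------------------------------------------------------------

def _copies_of_alt(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(alt copies, called copies) per site for a pool's call matrix."""
    called = calls != MISSING
    n_called = 2 * called.sum(axis=0).astype(np.int64)
    alt = np.where(called, calls, 0).sum(axis=0).astype(np.int64)
    return alt, n_called


def count_i_alleles(
    g: GenotypeMatrix,
    manifest: PopulationManifest,
    diag: DiagnosticAlleles,
) -> pd.DataFrame:
    """Count i-allele copies in each sympatric pool at each d-site.

    In m1 (sympatric M) the i-allele is the S-diagnostic allele; in s1 it
    is the M-diagnostic allele.  Missing diploid calls reduce the called
    copies.  Returns a frame with contig, pos, counts and called copies.
    """
    idx = diag.site_idx
    cm = g.pool_calls(manifest.m1)[:, idx]
    cs = g.pool_calls(manifest.s1)[:, idx]
    alt_m, called_m = _copies_of_alt(cm)
    alt_s, called_s = _copies_of_alt(cs)
    # S-diagnostic allele is alt where M-diag is ref, and vice versa
    s_diag_is_alt = ~diag.m_diag_is_alt
    count_m1 = np.where(s_diag_is_alt, alt_m, called_m - alt_m)
    count_s1 = np.where(diag.m_diag_is_alt, alt_s, called_s - alt_s)
    return pd.DataFrame(
        {
            "contig": g.contig[idx],
            "pos": g.pos[idx],
            "count_m1": count_m1,
            "count_s1": count_s1,
            "called_m1": called_m,
            "called_s1": called_s,
        }
    )


def occurrence_histogram(counts: pd.DataFrame, max_copies: int) -> pd.DataFrame:
    """Histogram of i-allele occurrences 0..max_copies in each pool."""
    occ = np.arange(max_copies + 1)
    hm = np.bincount(counts["count_m1"], minlength=max_copies + 1)[: max_copies + 1]
    hs = np.bincount(counts["count_s1"], minlength=max_copies + 1)[: max_copies + 1]
    return pd.DataFrame({"occurrence": occ, "m1": hm, "s1": hs})


def classify_sites(
    counts: pd.DataFrame,
    n: int = 8,
    reciprocal_max: int = 1,
    fst: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assign each d-site its class: ``i_m1``, ``i_s1``, ``j`` or ``undefined``.

    The asymmetric rule: a site is introgressed toward a pool when the
    i-allele reaches >= ``n`` copies there while the reciprocal pool holds
    <= ``reciprocal_max`` copies; it is non-introgressable (j) when both
    pools hold <= ``reciprocal_max`` copies.  A pool with fewer than ``n``
    called copies cannot support any of these calls, so such sites are
    ``undefined`` — missing data never counts as evidence of absence.
    """
    max_called = int(max(counts["called_m1"].max(), counts["called_s1"].max()))
    if n > max_called:
        raise ValueError(f"n={n} exceeds the {max_called} haploid copies available")
    if n < 2:
        raise ValueError("n must be >= 2")
    cm = counts["count_m1"].to_numpy()
    cs = counts["count_s1"].to_numpy()
    km = counts["called_m1"].to_numpy()
    ks = counts["called_s1"].to_numpy()

    enough = (km >= n) & (ks >= n)
    i_m1 = enough & (cm >= n) & (cs <= reciprocal_max)
    i_s1 = enough & (cs >= n) & (cm <= reciprocal_max)
    j = enough & (cm <= reciprocal_max) & (cs <= reciprocal_max)
    cls = np.full(len(counts), "undefined", dtype=object)
    cls[j] = "j"
    cls[i_m1] = "i_m1"
    cls[i_s1] = "i_s1"

    out = counts.copy()
    if fst is not None:
        out.insert(2, "fst", np.asarray(fst, dtype=float))
    out["cls"] = cls
    for label, k in zip(*np.unique(cls, return_counts=True)):
        logger.info("classify_sites: %s = %d", label, k)
    return out


# ---------------------------------------------------------------------------
# block delineation
# ---------------------------------------------------------------------------

def scan_blocks(
    table: pd.DataFrame,
    kind: str,
    drop_singletons: bool = True,
) -> list[Block]:
    """Delineate blocks of one kind by the midpoint rule.

    A block is a maximal run of consecutive ``kind`` sites along the
    d-site sequence of a contig; any d-site of a different class breaks a
    run.  The physical boundary on each side is floor((a+b)/2) between the
    outermost member site and the nearest interrupting d-site; with no
    flanking d-site the boundary falls back to the member site itself.
    Boundaries are stored 0-based half-open.  ``drop_singletons`` removes
    single-site blocks from the returned list.
    """
    if kind not in BLOCK_KINDS:
        raise ValueError(f"unknown block kind {kind!r}")
    blocks: list[Block] = []
    for contig, sub in table.groupby("contig", sort=False):
        pos = sub["pos"].to_numpy()
        if pos.size and not (np.diff(pos) > 0).all():
            raise ValueError(f"site table not sorted on {contig}")
        cls = sub["cls"].to_numpy()
        is_kind = cls == kind
        k = 0
        n = pos.size
        while k < n:
            if not is_kind[k]:
                k += 1
                continue
            j = k
            while j + 1 < n and is_kind[j + 1]:
                j += 1
            first, last = int(pos[k]), int(pos[j])
            if k > 0:
                start = (int(pos[k - 1]) + first) // 2
            else:
                start = first - 1  # 0-based position of the member site
            if j + 1 < n:
                end = (last + int(pos[j + 1])) // 2
            else:
                end = last
            blocks.append(
                Block(
                    contig=str(contig),
                    start=start,
                    end=end,
                    kind=kind,
                    sites=tuple(int(p) for p in pos[k : j + 1]),
                )
            )
            k = j + 1
    if drop_singletons:
        blocks = [b for b in blocks if not b.is_singleton]
    return blocks


# ---------------------------------------------------------------------------
# genotype painting
# ---------------------------------------------------------------------------

def paint_genotypes(
    g: GenotypeMatrix,
    manifest: PopulationManifest,
    diag: DiagnosticAlleles,
    samples: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Label each individual's genotype at each d-site as MM / MS / SS.

    MM = homozygous for the M-diagnostic allele, SS = homozygous
    S-diagnostic, MS = heterozygous, UNKNOWN = missing call.  Long format:
    sample, contig, pos, label.
    """
    if samples is None:
        samples = manifest.m1 + manifest.s1
    idx = diag.site_idx
    calls = g.pool_calls(samples)[:, idx]
    # copies of the M-diagnostic allele: calls where M-diag = alt, 2 - calls otherwise
    m_copies = np.where(diag.m_diag_is_alt[None, :], calls, 2 - calls)
    label = np.full(calls.shape, "UNKNOWN", dtype=object)
    label[m_copies == 2] = "MM"
    label[m_copies == 1] = "MS"
    label[m_copies == 0] = "SS"
    label[calls == MISSING] = "UNKNOWN"
    n_sites = idx.size
    return pd.DataFrame(
        {
            "sample": np.repeat(list(samples), n_sites),
            "contig": np.tile(g.contig[idx], len(samples)),
            "pos": np.tile(g.pos[idx], len(samples)),
            "label": label.ravel(),
        }
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class BlockSummary:
    """Aggregate description of one block kind (one table column)."""

    kind: str
    n_blocks: int
    n_contigs: int
    min_length: int
    mean_length: float
    max_length: int
    min_sites: int
    max_sites: int
    total_sites: int
    total_length: int            # excluding singletons
    total_length_with_singletons: int
    pct_genome: float            # total_length / genome length * 100
    pct_genome_with_singletons: float
    n_genes_overlapped: int | None = None  # j only, needs annotation
    n_genes_with_sites: int | None = None

    def to_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


def _gene_overlap_counts(
    blocks: Sequence[Block],
    site_positions: dict[str, np.ndarray],
    genes: Sequence[GeneModel],
    min_sites_in_gene: int = 1,
) -> tuple[int, int]:
    """(genes overlapping any block, genes containing >= min_sites_in_gene sites)."""
    by_contig: dict[str, list[Block]] = {}
    for b in blocks:
        by_contig.setdefault(b.contig, []).append(b)
    n_overlap = 0
    n_with_sites = 0
    for gene in genes:
        hit = False
        for b in by_contig.get(gene.contig, ()):  # genes are few; linear is fine
            if b.start < gene.end and gene.start - 1 < b.end:
                hit = True
                break
        if hit:
            n_overlap += 1
        pos = site_positions.get(gene.contig)
        if pos is not None:
            k = int(
                np.searchsorted(pos, gene.end, side="right")
                - np.searchsorted(pos, gene.start, side="left")
            )
            if k >= min_sites_in_gene:
                n_with_sites += 1
    return n_overlap, n_with_sites


def summarize_blocks(
    blocks: Sequence[Block],
    table: pd.DataFrame,
    contigs: ContigTable,
    genes: Sequence[GeneModel] | None = None,
) -> BlockSummary:
    """Aggregate one kind's block list into a Table-style summary column.

    ``blocks`` should include singleton blocks; headline length totals
    exclude them (singletons are reported separately, as in the source
    tables), and ``total_length_with_singletons`` includes them.
    """
    if not blocks:
        return BlockSummary(
            kind="none", n_blocks=0, n_contigs=0, min_length=0, mean_length=0.0,
            max_length=0, min_sites=0, max_sites=0, total_sites=0,
            total_length=0, total_length_with_singletons=0,
            pct_genome=0.0, pct_genome_with_singletons=0.0,
        )
    kinds = {b.kind for b in blocks}
    if len(kinds) != 1:
        raise ValueError(f"summarize_blocks expects one kind, got {kinds}")
    kind = kinds.pop()
    multi = [b for b in blocks if not b.is_singleton]
    genome = contigs.total_length
    total_len = sum(b.length for b in multi)
    total_all = sum(b.length for b in blocks)
    summary = BlockSummary(
        kind=kind,
        n_blocks=len(multi),
        n_contigs=len({b.contig for b in multi}),
        min_length=min((b.length for b in multi), default=0),
        mean_length=float(np.mean([b.length for b in multi])) if multi else 0.0,
        max_length=max((b.length for b in multi), default=0),
        min_sites=min((b.n_sites for b in multi), default=0),
        max_sites=max((b.n_sites for b in multi), default=0),
        total_sites=sum(b.n_sites for b in multi),
        total_length=total_len,
        total_length_with_singletons=total_all,
        pct_genome=100.0 * total_len / genome,
        pct_genome_with_singletons=100.0 * total_all / genome,
    )
    if genes is not None and kind == "j":
        sites = table[table["cls"] == "j"]
        site_positions = {
            str(c): np.sort(sub["pos"].to_numpy())
            for c, sub in sites.groupby("contig")
        }
        summary.n_genes_overlapped, summary.n_genes_with_sites = _gene_overlap_counts(
            blocks, site_positions, genes
        )
    return summary


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class IntrogressionScan:
    """Model object for the genomic introgression scan.

    Parameters
    ----------
    genotypes
        Biallelic SNP genotypes for all samples.
    manifest
        Population manifest defining the allopatric panels (M_allo, S_allo)
        and the sympatric pair (m1, s1).
    fst_threshold
        d-site threshold on per-site allopatric F_ST (strict >, default 0.8).
    n
        Minimum i-allele copies in the focal sympatric pool for an i-site
        (default 8 of 10 haploid genomes).
    reciprocal_max
        Maximum i-allele copies tolerated in the reciprocal pool (default 1).
    min_call_rate
        Minimum fraction of called copies per pool for a site to be scored
        for F_ST.
    estimator
        "hudson" (default) or "weir_cockerham".
    """

    def __init__(
        self,
        genotypes: GenotypeMatrix,
        manifest: PopulationManifest,
        *,
        fst_threshold: float = 0.8,
        n: int = 8,
        reciprocal_max: int = 1,
        min_call_rate: float = 0.8,
        estimator: str = "hudson",
    ) -> None:
        manifest.require_full()
        self.genotypes = genotypes
        self.manifest = manifest
        self.fst_threshold = fst_threshold
        self.n = n
        self.reciprocal_max = reciprocal_max
        self.min_call_rate = min_call_rate
        self.estimator = estimator

    def fit(self) -> "IntrogressionScanResults":
        g, man = self.genotypes, self.manifest
        fa = ps.allele_freqs(g, man.m_allo)
        fb = ps.allele_freqs(g, man.s_allo)
        fst = ps.site_fst(
            fa, fb,
            estimator=self.estimator,
            min_call_rate=self.min_call_rate,
            max_copies=(2 * len(man.m_allo), 2 * len(man.s_allo)),
        )
        d_idx = call_d_sites(fst, self.fst_threshold)
        logger.info("scan: %d d-site(s) of %d scored sites", d_idx.size, g.n_sites)
        diag = diagnostic_alleles(g, man, d_idx)
        counts = count_i_alleles(g, man, diag)
        table = classify_sites(
            counts, n=self.n, reciprocal_max=self.reciprocal_max,
            fst=fst[diag.site_idx],
        )
        return IntrogressionScanResults(model=self, fst=fst, diag=diag, site_classes=table)


@dataclass
class IntrogressionScanResults:
    """Fitted scan: per-site classes plus block/summary/painting accessors."""

    model: IntrogressionScan
    fst: np.ndarray               # per input site, NaN where unscored
    diag: DiagnosticAlleles
    site_classes: pd.DataFrame    # contig, pos, fst, counts, called, cls

    def blocks(self, kind: str, drop_singletons: bool | None = None) -> list[Block]:
        if drop_singletons is None:
            drop_singletons = kind != "j"
        return scan_blocks(self.site_classes, kind, drop_singletons=drop_singletons)

    def all_blocks(self) -> dict[str, list[Block]]:
        return {k: self.blocks(k, drop_singletons=False) for k in BLOCK_KINDS}

    def paint(self, samples: Sequence[str] | None = None) -> pd.DataFrame:
        return paint_genotypes(self.model.genotypes, self.model.manifest, self.diag, samples)

    def class_counts(self) -> pd.Series:
        return self.site_classes["cls"].value_counts().reindex(SITE_CLASSES, fill_value=0)

    def occurrence_histogram(self) -> pd.DataFrame:
        max_copies = int(
            max(
                self.site_classes["called_m1"].max(),
                self.site_classes["called_s1"].max(),
            )
        )
        return occurrence_histogram(self.site_classes, max_copies)

    def summary_frame(
        self,
        contigs: ContigTable,
        genes: Sequence[GeneModel] | None = None,
    ) -> pd.DataFrame:
        rows = []
        for kind in BLOCK_KINDS:
            blocks = self.blocks(kind, drop_singletons=False)
            rows.append(summarize_blocks(blocks, self.site_classes, contigs, genes).to_series())
        df = pd.DataFrame(rows)
        df.insert(0, "kind_label", BLOCK_KINDS)
        return df.drop(columns=["kind"])

    def summary(self, contigs: ContigTable | None = None) -> str:
        """Human-readable summary of the fitted scan."""
        buf = io.StringIO()
        m = self.model
        cc = self.class_counts()
        print("Introgression scan", file=buf)
        print("=" * 60, file=buf)
        print(f"d-site F_ST threshold : > {m.fst_threshold} ({m.estimator})", file=buf)
        print(f"i-site rule           : >= {m.n} i-alleles, "
              f"<= {m.reciprocal_max} reciprocal", file=buf)
        print(f"d-sites classified    : {len(self.site_classes)}", file=buf)
        for k in SITE_CLASSES:
            print(f"  {k:<12}: {int(cc[k])}", file=buf)
        if contigs is not None:
            for kind in BLOCK_KINDS:
                blocks = self.blocks(kind, drop_singletons=False)
                s = summarize_blocks(blocks, self.site_classes, contigs)
                print(
                    f"{kind:<5} blocks: {s.n_blocks} (>=2 sites), "
                    f"mean {s.mean_length/1000:.2f} Kb, "
                    f"total {s.total_length/1e6:.3f} Mb "
                    f"({s.pct_genome:.2f}% of genome; "
                    f"{s.pct_genome_with_singletons:.2f}% with singletons)",
                    file=buf,
                )
        return buf.getvalue()
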