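"""Diversity, divergence and gene-flow statistics.

Per-site Hudson F_ST (with a Weir–Cockerham alternative), the F_ST spectrum
and its U/L shape call, D_xy, theta_pi, Watterson's theta_w, Patterson's D
with a block jackknife, the modified f_d ratio, and unphased-genotype LD r²
decay.  All statistics work from allele frequencies with explicit
called-copy counts, so missing genotypes simply reduce the sample size at a
site and never masquerade as reference calls.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix

__all__ = [
    "AlleleFreqs",
    "FstSpectrum",
    "LdDecayCurve",
    "allele_freqs",
    "site_fst",
    "fst_spectrum",
    "dxy",
    "theta_pi",
    "theta_w",
    "harmonic_number",
    "patterson_d",
    "f_d",
    "ld_decay",
]


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class AlleleFreqs:
    """Alternate-allele frequency and called haploid copies per site.

    ``p`` is NaN at sites where no copies were called (frequency undefined,
    never silently 0).
    """

    p: np.ndarray         # float64, NaN = undefined
    n_called: np.ndarray  # int64 haploid copies

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.p)


def allele_freqs(g: GenotypeMatrix, pool: Iterable[str]) -> AlleleFreqs:
    """Alternate-allele frequencies of a sample pool at every site."""
    calls = g.pool_calls(pool)
    if calls.shape[0] == 0:
        raise ValueError("empty sample pool")
    called = calls != MISSING
    n_called = 2 * called.sum(axis=0).astype(np.int64)
    alt = np.where(called, calls, 0).sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_called > 0, alt / n_called, np.nan)
    return AlleleFreqs(p=p, n_called=n_called)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

def site_fst(
    a: AlleleFreqs,
    b: AlleleFreqs,
    estimator: str = "hudson",
    min_call_rate: float = 0.8,
    max_copies: tuple[int, int] | None = None,
) -> np.ndarray:
    """Per-site F_ST between two pools.

    Hudson's estimator (default)::

        F_ST = [ (pa-pb)^2 - pa(1-pa)/(na-1) - pb(1-pb)/(nb-1) ]
               / [ pa(1-pb) + pb(1-pa) ]

    Values may be negative and are not capped.  A site is not scored (NaN)
    when either pool has < 2 called copies, when its call rate in either
    pool is below ``min_call_rate`` (fraction of the pool's maximum copy
    number; pass ``max_copies`` to override the maxima observed in the
    data), or when both pools are monomorphic for the same allele
    (denominator 0).
    """
    pa, pb = a.p, b.p
    na = a.n_called.astype(np.float64)
    nb = b.n_called.astype(np.float64)
    max_a = float(max_copies[0]) if max_copies else float(na.max(initial=0))
    max_b = float(max_copies[1]) if max_copies else float(nb.max(initial=0))

    scored = (
        a.defined & b.defined
        & (na >= 2) & (nb >= 2)
        & (na >= min_call_rate * max_a)
        & (nb >= min_call_rate * max_b)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        if estimator == "hudson":
            num = (
                (pa - pb) ** 2
                - pa * (1 - pa) / (na - 1)
                - pb * (1 - pb) / (nb - 1)
            )
            den = pa * (1 - pb) + pb * (1 - pa)
        elif estimator == "weir_cockerham":
            # two-population Weir & Cockerham theta from allele counts
            # (variance-components form, r = 2, no within-individual term)
            r = 2.0
            n_bar = (na + nb) / r
            n_c = (na + nb - (na**2 + nb**2) / (na + nb)) / (r - 1)
            p_bar = (na * pa + nb * pb) / (na + nb)
            s2 = (na * (pa - p_bar) ** 2 + nb * (pb - p_bar) ** 2) / ((r - 1) * n_bar)
            h = p_bar * (1 - p_bar)
            num = s2 - (h - (r - 1) / r * s2) / (n_bar - 1)
            den = (n_c - 1) / (n_bar - 1) * h + (
                1 + (r - 1) * (n_bar - n_c) / (n_bar - 1)
            ) * s2 / r
        else:
            raise ValueError(f"unknown F_ST estimator {estimator!r}")
        fst = np.where(scored & (den != 0), num / den, np.nan)
    return fst


@dataclass
class FstSpectrum:
    """Histogram of per-site F_ST in ten 0.1-wide bins over [0, 1]."""

    edges: np.ndarray
    counts: np.ndarray
    shape: str  # "U" | "L" | "other"


def fst_spectrum(fst: np.ndarray) -> FstSpectrum:
    """Bin scored F_ST values and call the spectrum shape.

    Negative values are clamped into the first bin for binning only.  The
    shape is **U** when both extreme bins exceed every interior bin, **L**
    when the first bin exceeds every other bin and the last bin does not
    exceed the interior mean, and **other** otherwise.
    """
    vals = np.asarray(fst, dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError("no scored sites to bin")
    edges = np.linspace(0.0, 1.0, 11)
    counts, _ = np.histogram(np.clip(vals, 0.0, 1.0), bins=edges)
    interior = counts[1:9]
    if (counts[0] > interior).all() and (counts[9] > interior).all():
        shape = "U"
    elif (counts[0] > counts[1:]).all() and counts[9] <= interior.mean():
        shape = "L"
    else:
        shape = "other"
    return FstSpectrum(edges=edges, counts=counts, shape=shape)


# ---------------------------------------------------------------------------
# divergence and diversity
# ---------------------------------------------------------------------------

def dxy(a: AlleleFreqs, b: AlleleFreqs, accessible_length: int) -> tuple[np.ndarray, float]:
    """Per-variant-site divergence d = pa(1-pb) + pb(1-pa) and genome-wide
    D_xy = sum(d) / accessible_length.

    ``accessible_length`` is the number of bp with data in both pools; the
    invariant (monomorphic) sites contribute 0 to the numerator.
    """
    if accessible_length <= 0:
        raise ValueError("accessible_length must be positive")
    d = a.p * (1 - b.p) + b.p * (1 - a.p)
    total = float(np.nansum(d))
    return d, total / accessible_length


def theta_pi(g: GenotypeMatrix, pool: Iterable[str], accessible_length: int) -> float:
    """Nucleotide diversity per Kb: 1000 * sum_site 2p(1-p) n/(n-1) / L."""
    if accessible_length <= 0:
        raise ValueError("accessible_length must be positive")
    af = allele_freqs(g, pool)
    pi = per_site_pi(af)
    return 1000.0 * float(np.nansum(pi)) / accessible_length


def per_site_pi(af: AlleleFreqs) -> np.ndarray:
    """Unbiased per-site heterozygosity 2p(1-p)*n/(n-1); NaN where n < 2."""
    n = af.n_called.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, 2.0 * af.p * (1 - af.p) * n / (n - 1), np.nan)
    return pi


def harmonic_number(k: int) -> float:
    """a_k = sum_{i=1}^{k} 1/i (Watterson's normalizer uses a_{n-1})."""
    if k < 1:
        raise ValueError("harmonic number needs k >= 1")
    return float(np.sum(1.0 / np.arange(1, k + 1)))


def theta_w(g: GenotypeMatrix, pool: Iterable[str], accessible_length: int) -> float:
    """Watterson's theta per Kb: 1000 * S / (a_{n-1} * L).

    ``n`` is the nominal haploid sample size, 2 x diploids in the pool;
    ``S`` counts sites segregating within the pool.
    """
    if accessible_length <= 0:
        raise ValueError("accessible_length must be positive")
    pool = list(pool)
    n = 2 * len(pool)
    if n < 2:
        raise ValueError("theta_w needs >= 2 haploid copies")
    af = allele_freqs(g, pool)
    seg = segregating(af)
    return 1000.0 * int(seg.sum()) / (harmonic_number(n - 1) * accessible_length)


def segregating(af: AlleleFreqs) -> np.ndarray:
    """Boolean mask of sites polymorphic within the pool."""
    with np.errstate(invalid="ignore"):
        return af.defined & (af.p > 0) & (af.p < 1)


def theta_diff_jackknife(
    g: GenotypeMatrix,
    pool: Iterable[str],
    accessible_length: int,
    n_blocks: int = 50,
) -> tuple[float, float]:
    """theta_pi - theta_w (per Kb) with a site-block jackknife SE.

    Sites are split into ``n_blocks`` contiguous blocks; each delete-one
    replicate rescales both estimators to the reduced accessible length.
    """
    pool = list(pool)
    af = allele_freqs(g, pool)
    pi = np.nan_to_num(per_site_pi(af))
    seg = segregating(af).astype(float)
    a_n1 = harmonic_number(2 * len(pool) - 1)

    nb = min(n_blocks, max(2, g.n_sites))
    block_of = np.minimum((np.arange(g.n_sites) * nb) // max(g.n_sites, 1), nb - 1)
    pi_sum = np.bincount(block_of, weights=pi, minlength=nb)
    s_sum = np.bincount(block_of, weights=seg, minlength=nb)
    L_block = accessible_length / nb  # sites evenly attributed

    reps = np.empty(nb)
    for i in range(nb):
        L_i = accessible_length - L_block
        pi_i = 1000.0 * (pi_sum.sum() - pi_sum[i]) / L_i
        w_i = 1000.0 * (s_sum.sum() - s_sum[i]) / (a_n1 * L_i)
        reps[i] = pi_i - w_i
    diff = 1000.0 * pi.sum() / accessible_length - 1000.0 * seg.sum() / (
        a_n1 * accessible_length
    )
    se = float(np.sqrt((nb - 1) / nb * np.sum((reps - reps.mean()) ** 2)))
    return float(diff), se


# ---------------------------------------------------------------------------
# ABBA-BABA statistics
# ---------------------------------------------------------------------------

def _polarize(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray, po: np.ndarray,
    max_outgroup_freq: float = 0.2,
) -> tuple[np.ndarray, ...]:
    """Orient frequencies so the outgroup major allele is ancestral.

    Sites whose outgroup frequency lies in (max_outgroup_freq,
    1 - max_outgroup_freq) are unpolarizable and dropped.
    """
    usable = ~(np.isnan(p1) | np.isnan(p2) | np.isnan(p3) | np.isnan(po))
    usable &= (po <= max_outgroup_freq) | (po >= 1 - max_outgroup_freq)
    flip = po >= 0.5
    out = []
    for p in (p1, p2, p3, po):
        q = np.where(flip, 1.0 - p, p)
        out.append(q[usable])
    return tuple(out)


def _abba_baba(p1, p2, p3, po) -> tuple[np.ndarray, np.ndarray]:
    abba = (1 - p1) * p2 * p3 * (1 - po)
    baba = p1 * (1 - p2) * p3 * (1 - po)
    return abba, baba


def patterson_d(
    p1: AlleleFreqs,
    p2: AlleleFreqs,
    p3: AlleleFreqs,
    po: AlleleFreqs,
    contig: np.ndarray | None = None,
    pos: np.ndarray | None = None,
    block_size: int = 1_000_000,
) -> tuple[float, float, float]:
    """Patterson's D for a (((P1,P2),P3),O) genealogy with jackknife SE/Z.

    D = sum(ABBA - BABA) / sum(ABBA + BABA) over polarizable sites; the
    standard error comes from a delete-one block jackknife over contiguous
    genomic blocks of ``block_size`` bp (when coordinates are given; else
    over 20 equal site blocks).  Returns (D, SE, Z); D is NaN when no site
    is informative.
    """
    usable = ~(
        np.isnan(p1.p) | np.isnan(p2.p) | np.isnan(p3.p) | np.isnan(po.p)
    )
    usable &= (po.p <= 0.2) | (po.p >= 0.8)
    flip = po.p >= 0.5
    q1, q2, q3, qo = (np.where(flip, 1 - p.p, p.p) for p in (p1, p2, p3, po))
    abba, baba = _abba_baba(q1, q2, q3, qo)
    abba = np.where(usable, abba, 0.0)
    baba = np.where(usable, baba, 0.0)

    denom = float((abba + baba).sum())
    if denom == 0:
        return float("nan"), float("nan"), float("nan")
    d = float((abba - baba).sum()) / denom

    if contig is not None and pos is not None:
        keys = pd.factorize(
            pd.Series(contig).astype(str) + ":" + (np.asarray(pos) // block_size).astype(str)
        )[0]
    else:
        n = abba.size
        nb = min(20, max(2, n))
        keys = np.minimum((np.arange(n) * nb) // max(n, 1), nb - 1)
    nb = int(keys.max()) + 1
    num_b = np.bincount(keys, weights=abba - baba, minlength=nb)
    den_b = np.bincount(keys, weights=abba + baba, minlength=nb)
    keep = (den_b > 0) & (den_b < denom)  # informative, and delete-one leaves signal
    num_b, den_b = num_b[keep], den_b[keep]
    g_ = num_b.size
    if g_ < 2:
        return d, float("nan"), float("nan")
    # weighted delete-one block jackknife (blocks carry unequal ABBA+BABA weight)
    theta_j = (num_b.sum() - num_b) / (den_b.sum() - den_b)
    h = denom / den_b
    theta_jack = g_ * d - float(((1 - 1 / h) * theta_j).sum())
    pseudo = h * d - (h - 1) * theta_j
    var = float(np.sum((pseudo - theta_jack) ** 2 / (h - 1)) / g_)
    se = float(np.sqrt(var))
    z = d / se if se > 0 else float("nan")
    return d, se, z


def f_d(
    p1: AlleleFreqs,
    p2: AlleleFreqs,
    p3: AlleleFreqs,
    po: AlleleFreqs,
) -> float:
    """Modified f_d over a window of sites.

    f_d = S(p1, p2, p3, pO) / S(p1, pD, pD, pO), where S is the ABBA-BABA
    numerator and pD = max(p2, p3) site-wise.  Reported NaN (undefined)
    when the window's D <= 0 or the denominator is 0.
    """
    usable = ~(
        np.isnan(p1.p) | np.isnan(p2.p) | np.isnan(p3.p) | np.isnan(po.p)
    )
    usable &= (po.p <= 0.2) | (po.p >= 0.8)
    flip = po.p >= 0.5
    q1, q2, q3, qo = (np.where(flip, 1 - p.p, p.p) for p in (p1, p2, p3, po))
    abba, baba = _abba_baba(q1, q2, q3, qo)
    num = float(np.where(usable, abba - baba, 0.0).sum())
    dden = float(np.where(usable, abba + baba, 0.0).sum())
    if dden == 0 or num <= 0:  # window D <= 0 -> undefined
        return float("nan")
    qd = np.maximum(q2, q3)
    abba_d, baba_d = _abba_baba(q1, qd, qd, qo)
    den = float(np.where(usable, abba_d - baba_d, 0.0).sum())
    if den == 0:
        return float("nan")
    return num / den


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

@dataclass
class LdDecayCurve:
    """Mean genotype r² per physical-distance bin."""

    edges: np.ndarray       # bin edges in bp, len = n_bins + 1
    mean_r2: np.ndarray     # NaN for empty bins
    pair_counts: np.ndarray

    @property
    def empty_bins(self) -> np.ndarray:
        return self.pair_counts == 0

    def decay_distance(self, level: float = 0.1) -> float:
        """Midpoint of the first bin whose mean r² drops below ``level``."""
        mids = (self.edges[:-1] + self.edges[1:]) / 2
        ok = ~np.isnan(self.mean_r2)
        below = ok & (self.mean_r2 < level)
        if not below.any():
            return float("inf")
        return float(mids[np.argmax(below)])


def ld_decay(
    g: GenotypeMatrix,
    pool: Iterable[str],
    max_dist: int = 300_000,
    bin_width: int = 1_000,
) -> LdDecayCurve:
    """Unphased-genotype LD decay: squared Pearson correlation of 0/1/2
    genotype vectors for all intra-contig site pairs within ``max_dist``.

    Pairs are restricted to samples called at both sites; zero-variance
    pairs are skipped.
    """
    calls = g.pool_calls(pool).astype(np.float64)
    calls[calls == MISSING] = np.nan
    n_bins = int(np.ceil(max_dist / bin_width))
    edges = np.arange(n_bins + 1, dtype=np.int64) * bin_width
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    for c in g.contigs:
        sl = g.contig_slice(c)
        pos = g.pos[sl]
        sub = calls[:, sl]
        for i in range(pos.size - 1):
            j_hi = int(np.searchsorted(pos, pos[i] + max_dist, side="right"))
            if j_hi <= i + 1:
                continue
            x = sub[:, i]
            Y = sub[:, i + 1:j_hi]
            valid = ~np.isnan(x)[:, None] & ~np.isnan(Y)
            nv = valid.sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                xm = np.where(valid, x[:, None], 0.0)
                ym = np.where(valid, Y, 0.0)
                sx = xm.sum(axis=0)
                sy = ym.sum(axis=0)
                sxx = (xm * xm).sum(axis=0)
                syy = (ym * ym).sum(axis=0)
                sxy = (xm * ym).sum(axis=0)
                cov = sxy - sx * sy / nv
                vx = sxx - sx * sx / nv
                vy = syy - sy * sy / nv
                r2 = np.where((vx > 0) & (vy > 0), cov**2 / (vx * vy), np.nan)
            dist = pos[i + 1:j_hi] - pos[i]
            bins = np.minimum((dist - 1) // bin_width, n_bins - 1).astype(np.intp)
            ok = (~np.isnan(r2)) & (nv >= 2)
            np.add.at(sums, bins[ok], r2[ok])
            np.add.at(counts, bins[ok], 1)

    with np.errstate(invalid="ignore", divide="ignore"):
        mean_r2 = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return LdDecayCurve(edges=edges, mean_r2=mean_r2, pair_counts=counts)
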