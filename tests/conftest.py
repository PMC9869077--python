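"""Shared fixtures: tiny genotype matrices, manifests and text-format inputs
built programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from introscan import GenotypeMatrix, PopulationManifest
from introscan.genotype_io import MISSING


def make_matrix(calls, positions=None, contig="chr1", samples=None) -> GenotypeMatrix:
    """Build a one-contig GenotypeMatrix from a (samples x sites) call array."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if positions is None:
        positions = np.arange(1, n_sites + 1) * 100
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    return GenotypeMatrix(
        samples=list(samples),
        contigs=[contig],
        contig=np.full(n_sites, contig, dtype=object),
        pos=np.asarray(positions, dtype=np.int64),
        ref=np.full(n_sites, "A", dtype=object),
        alt=np.full(n_sites, "T", dtype=object),
        calls=calls,
    )


def make_manifest(n_per_pool: int = 5) -> PopulationManifest:
    rows = []
    for pool, (pop, sp, cx) in {
        "m_allo": ("m2", "M", "allopatric"),
        "s_allo": ("s2", "S", "allopatric"),
        "m1": ("m1", "M", "sympatric"),
        "s1": ("s1", "S", "sympatric"),
    }.items():
        rows += [
            {"sample": f"{pop}_{i}", "population": pop, "species": sp, "context": cx}
            for i in range(n_per_pool)
        ]
    return PopulationManifest(pd.DataFrame(rows))


@pytest.fixture
def small_manifest() -> PopulationManifest:
    return make_manifest(2)


@pytest.fixture
def vcf_text() -> str:
    """3-sample VCF: 2 biallelic SNPs, 1 indel, 1 multiallelic, one ./. call."""
    return (
        "##fileformat=VCFv4.2\n"
        "##contig=<ID=chr1,length=10000>\n"
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta\tb\tc\n"
        "chr1\t100\t.\tA\tT\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        "chr1\t200\t.\tG\tGA\t.\tPASS\t.\tGT\t0/0\t0/0\t0/1\n"
        "chr1\t300\t.\tC\tA,G\t.\tPASS\t.\tGT\t0/0\t1/2\t0/0\n"
        "chr1\t400\t.\tT\tC\t.\tPASS\t.\tGT\t./.\t0/0\t1/1\n"
    )


@pytest.fixture
def vcf_file(tmp_path, vcf_text):
    p = tmp_path / "small.vcf"
    p.write_text(vcf_text)
    return p


@pytest.fixture
def three_sample_manifest() -> PopulationManifest:
    return PopulationManifest(
        pd.DataFrame(
            {
                "sample": ["a", "b", "c"],
                "population": ["p1", "p1", "p2"],
                "species": ["M", "M", "S"],
                "context": ["allopatric", "allopatric", "sympatric"],
            }
        )
    )
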