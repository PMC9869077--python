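"""End-to-end pipeline: inputs -> F_ST -> d-sites -> i/j classification ->
blocks -> summaries, with a JSON run manifest for reproducibility.

Given identical inputs and configuration, every tabular output is
byte-identical between runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import popgen_stats as ps
from .genotype_io import (
    ContigTable,
    GenotypeMatrix,
    PopulationManifest,
    read_contigs,
    read_gff_genes,
    read_manifest,
    read_vcf,
    write_blocks_bed,
    write_site_table,
)
from .scan import BLOCK_KINDS, IntrogressionScan

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Everything a full run needs; defaults match the headline settings
    (F_ST threshold 0.8, n = 8, reciprocal_max = 1)."""

    vcf: str
    manifest: str
    contigs: str
    out_dir: str
    gff: str | None = None
    fst_threshold: float = 0.8
    n: int = 8
    reciprocal_max: int = 1
    min_call_rate: float = 0.8
    estimator: str = "hudson"
    drop_singletons: bool = True
    d_block_size: int = 1_000_000
    ld_max_dist: int = 300_000
    ld_bin_width: int = 1_000
    ld_pools: tuple[str, ...] = ("m1", "s1", "m_allo", "s_allo")
    d_pools: dict | None = None  # {"p1": pop, "p2": pop, "p3": pop, "outgroup": pop}
    seed: int = 0


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                logger.info("stage %s: start", name)
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raise with stage name
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(
    config: RunConfig,
    genotypes: GenotypeMatrix | None = None,
    manifest: PopulationManifest | None = None,
    contig_table: ContigTable | None = None,
) -> Path:
    """Run the whole analysis and write all artifacts under ``config.out_dir``.

    In-memory inputs may be passed directly (the CLI passes paths only);
    any provided object overrides the corresponding path in ``config``.
    Returns the output directory.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    checksums = {}
    if manifest is None:
        manifest = _stage("read_manifest")(read_manifest)(config.manifest)
        checksums["manifest"] = _sha256(config.manifest)
    if genotypes is None:
        genotypes = _stage("read_vcf")(read_vcf)(config.vcf, manifest)
        checksums["vcf"] = _sha256(config.vcf)
    if contig_table is None:
        contig_table = _stage("read_contigs")(read_contigs)(config.contigs)
        checksums["contigs"] = _sha256(config.contigs)
    contig_table.require_contigs(genotypes.contigs)
    genes = None
    if config.gff:
        genes = _stage("read_gff")(read_gff_genes)(config.gff)
        checksums["gff"] = _sha256(config.gff)
    else:
        logger.info("no GFF given; gene-overlap columns will be NA")

    model = IntrogressionScan(
        genotypes,
        manifest,
        fst_threshold=config.fst_threshold,
        n=config.n,
        reciprocal_max=config.reciprocal_max,
        min_call_rate=config.min_call_rate,
        estimator=config.estimator,
    )
    res = _stage("scan")(model.fit)()

    # per-site F_ST table
    fst_df = pd.DataFrame(
        {
            "contig": genotypes.contig,
            "pos": genotypes.pos,
            "fst": np.round(res.fst, 10),
        }
    )
    fst_df.to_csv(out / "site_fst.tsv", sep="\t", index=False, na_rep="NA")

    spec = ps.fst_spectrum(res.fst)
    pd.DataFrame(
        {
            "bin_low": np.round(spec.edges[:-1], 1),
            "bin_high": np.round(spec.edges[1:], 1),
            "count": spec.counts,
        }
    ).to_csv(out / "fst_spectrum.tsv", sep="\t", index=False)
    (out / "fst_spectrum_shape.txt").write_text(spec.shape + "\n")

    write_site_table(res.site_classes, out / "site_classes.tsv")
    (out / "i_allele_histogram.tsv").write_text(
        res.occurrence_histogram().to_csv(sep="\t", index=False)
    )

    for kind in BLOCK_KINDS:
        drop = config.drop_singletons if kind != "j" else False
        blocks = res.blocks(kind, drop_singletons=drop)
        write_blocks_bed(blocks, out / f"blocks_{kind}.bed")

    summary = res.summary_frame(contig_table, genes)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False, na_rep="NA")

    res.paint().to_csv(out / "painting.tsv", sep="\t", index=False)

    # Patterson's D / f_d need a (((P1,P2),P3),O) pool assignment
    if config.d_pools:
        pools = {
            k: manifest.entries.loc[
                manifest.entries["population"] == v, "sample"
            ].tolist()
            for k, v in config.d_pools.items()
        }
        freqs = {k: ps.allele_freqs(genotypes, v) for k, v in pools.items()}
        d, se, z = ps.patterson_d(
            freqs["p1"], freqs["p2"], freqs["p3"], freqs["outgroup"],
            contig=genotypes.contig, pos=genotypes.pos,
            block_size=config.d_block_size,
        )
        fd = ps.f_d(freqs["p1"], freqs["p2"], freqs["p3"], freqs["outgroup"])
        pd.DataFrame(
            [{"D": d, "SE": se, "Z": z, "f_d": fd}]
        ).round(6).to_csv(out / "d_fd.tsv", sep="\t", index=False, na_rep="NA")
    else:
        logger.info("no d_pools configured; skipping Patterson's D / f_d")

    pool_map = {
        "m1": manifest.m1, "s1": manifest.s1,
        "m_allo": manifest.m_allo, "s_allo": manifest.s_allo,
    }
    ld_rows = []
    for pool_name in config.ld_pools:
        pool = pool_map.get(pool_name, [])
        if len(pool) < 2:
            continue
        curve = ps.ld_decay(
            genotypes, pool, max_dist=config.ld_max_dist,
            bin_width=config.ld_bin_width,
        )
        for lo, hi, r2, k in zip(
            curve.edges[:-1], curve.edges[1:], curve.mean_r2, curve.pair_counts
        ):
            if k > 0:
                ld_rows.append(
                    {"pool": pool_name, "bin_low": int(lo), "bin_high": int(hi),
                     "mean_r2": round(float(r2), 6), "n_pairs": int(k)}
                )
    pd.DataFrame(
        ld_rows, columns=["pool", "bin_low", "bin_high", "mean_r2", "n_pairs"]
    ).to_csv(out / "ld_decay.tsv", sep="\t", index=False)

    run_manifest = {
        "package": "introscan",
        "version": __version__,
        "parameters": {
            k: v for k, v in asdict(config).items()
            if k not in ("vcf", "manifest", "contigs", "gff", "out_dir")
        },
        "inputs": checksums,
        "n_sites": genotypes.n_sites,
        "n_d_sites": int(len(res.site_classes)),
        "class_counts": {k: int(v) for k, v in res.class_counts().items()},
    }
    (out / "run_manifest.json").write_text(
        json.dumps(run_manifest, indent=2, sort_keys=True) + "\n"
    )
    logger.info("pipeline complete: %s", out)
    return out
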