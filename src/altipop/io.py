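"""Readers and writers for the formats the pipeline touches.

VCF (v4.x, GT field) plus a sample->population map feed the genotype-based
modules; scan results, null distributions, and cline tables are written as
headered TSV with ``NA`` for undefined statistics; every stochastic output
gets a JSON sidecar recording version, seed, and configuration.  All
coordinates are 1-based as in VCF.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from .popgen_core import MISSING, GenotypeMatrix

logger = logging.getLogger("altipop")

__all__ = [
    "read_popmap",
    "read_vcf",
    "write_vcf",
    "write_scan_tsv",
    "write_null_distribution",
    "write_sidecar",
    "read_gene_set",
    "read_counts_tsv",
    "write_counts_tsv",
]


def read_popmap(path) -> dict[str, str]:
    """Sample -> population TSV (two columns, no header)."""
    popmap = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 2 tab-separated "
                                 f"columns, got {len(parts)}")
            popmap[parts[0]] = parts[1]
    if not popmap:
        raise ValueError(f"{path}: empty population map")
    return popmap


def read_vcf(path, popmap_path) -> GenotypeMatrix:
    """Load biallelic SNP genotypes from a VCF into a GenotypeMatrix.

    Multi-allelic and non-SNP records are skipped (counts logged); missing
    genotypes become ``MISSING``.  Samples absent from the population map
    are an error listing the offenders.
    """
    from cyvcf2 import VCF

    popmap = read_popmap(popmap_path)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in popmap]
    if missing_samples:
        raise ValueError("samples absent from popmap: "
                         + ", ".join(missing_samples))

    cols = []
    site_ids = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        gt = rec.gt_types.astype(np.int8)  # gts012: 0/1/2, 3 = unknown
        gt[gt == 3] = MISSING
        cols.append(gt)
        site_ids.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    if n_skipped:
        logger.info("read_vcf: skipped %d multi-allelic/non-SNP records",
                    n_skipped)
    dosages = (np.stack(cols, axis=1) if cols
               else np.empty((len(samples), 0), dtype=np.int8))
    gm = GenotypeMatrix(
        dosages=dosages,
        sample_ids=samples,
        pop_labels=[popmap[s] for s in samples],
        site_ids=site_ids,
    )
    gm.n_skipped = n_skipped
    return gm


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a GT-only VCF v4.2 for a genotype matrix."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=altipop\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = []
        for s in gm.site_ids:
            if s[0] not in contigs:
                contigs.append(s[0])
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for j, (chrom, pos, ref, alt) in enumerate(gm.site_ids):
            gts = "\t".join(gt_str[int(d)] for d in gm.dosages[:, j])
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")


def write_popmap(gm: GenotypeMatrix, path) -> None:
    with open(path, "w") as fh:
        for s, p in zip(gm.sample_ids, gm.pop_labels):
            fh.write(f"{s}\t{p}\n")


def write_scan_tsv(df, path) -> None:
    """Scan results TSV: chrom, pos, fst_ab, fst_ac, fst_bc, pbs, outlier."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA",
              float_format="%.6g")


def write_null_distribution(null, path_tsv, path_json=None) -> None:
    """One-column PBS TSV plus a JSON metadata sidecar."""
    with open(path_tsv, "w") as fh:
        fh.write("pbs\n")
        for v in null.pbs:
            fh.write(f"{v:.6g}\n")
    meta = {
        "n_snps": int(null.n_snps),
        "seed": null.seed,
        "estimator": null.estimator,
        "model": null.model.to_dict(),
    }
    sidecar = path_json or (str(path_tsv) + ".json")
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1)


def write_sidecar(path, config: dict, seed=None) -> None:
    """JSON sidecar with package version, seed and a config hash."""
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str)
    meta = {
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_sha1": hashlib.sha1(blob.encode()).hexdigest(),
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(meta, fh, indent=1, default=str)


def read_gene_set(path) -> list[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    with open(path) as fh:
        ids = [ln.strip() for ln in fh
               if ln.strip() and not ln.startswith("#")]
    if not ids:
        raise ValueError(f"{path}: empty gene set")
    return ids


def read_counts_tsv(path, genotype_row: str = "genotype"):
    """Gene x sample count TSV whose first row after the header gives
    per-sample genotype labels (row id ``genotype``)."""
    import pandas as pd

    from .geneset_shift import ExpressionCounts

    df = pd.read_csv(path, sep="\t", index_col=0)
    if genotype_row not in df.index:
        raise ValueError(f"{path}: no '{genotype_row}' row")
    genotypes = df.loc[genotype_row].astype(str).tolist()
    counts = df.drop(index=genotype_row).astype(int)
    return ExpressionCounts(
        counts=counts.to_numpy(),
        gene_ids=counts.index.astype(str).tolist(),
        sample_ids=counts.columns.astype(str).tolist(),
        genotypes=genotypes,
    )


def write_counts_tsv(ec, path) -> None:
    import pandas as pd

    df = pd.DataFrame(ec.counts, index=ec.gene_ids, columns=ec.sample_ids)
    geno = pd.DataFrame([ec.genotypes], index=["genotype"],
                        columns=ec.sample_ids)
    pd.concat([geno, df]).to_csv(path, sep="\t")
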