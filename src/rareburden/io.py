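"""Read and write cohorts in the pipeline's plain-text input formats.

A cohort directory holds:

* ``genotypes.vcf``     -- VCF v4.2, GT-only, one ALT per record; male X
  genotypes are haploid (``0`` / ``1``).
* ``annotation.tsv``    -- chrom, pos, ref, alt, gene, class, gnomad_af,
  cadd, blof, bp_flag.
* ``samples.tsv``       -- sample_id, status, sex, age, ancestry, pipeline,
  auto_ab.
* ``msc.tsv``           -- gene, msc.
* ``gene_features.tsv`` -- gene, pli, cones.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .cohort import Cohort

CONTIGS = [str(i) for i in range(1, 23)] + ["X"]

__all__ = ["write_cohort", "read_cohort"]


def _gt_string(dosage: int, ploidy: int) -> str:
    if dosage < 0:
        return "./." if ploidy == 2 else "."
    if ploidy == 1:
        return str(dosage)
    return ["0/0", "0/1", "1/1"][dosage]


def write_cohort(cohort: Cohort, directory) -> dict[str, Path]:
    """Write a cohort to ``directory``; returns the emitted file paths."""
    cohort.validate()
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {name: directory / fname for name, fname in [
        ("vcf", "genotypes.vcf"), ("annotation", "annotation.tsv"),
        ("samples", "samples.tsv"), ("msc", "msc.tsv"),
        ("gene_features", "gene_features.tsv")]}

    bad = set(cohort.variants["chrom"].astype(str)) - set(CONTIGS)
    if bad:
        raise ValueError(f"chromosome labels not in the VCF contig list: {sorted(bad)}")

    ploidy = cohort.ploidy()
    sample_ids = list(cohort.samples.index)
    order = cohort.variants.sort_values(["chrom", "pos"],
                                        key=lambda c: c.map(_chrom_key) if c.name == "chrom" else c)
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in CONTIGS:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(sample_ids) + "\n")
        col_of = {vid: k for k, vid in enumerate(cohort.variants.index)}
        for vid, row in order.iterrows():
            j = col_of[vid]
            gts = "\t".join(_gt_string(int(cohort.genotypes[i, j]), int(ploidy[i, j]))
                            for i in range(len(sample_ids)))
            fh.write(f"{row['chrom']}\t{row['pos']}\t{vid}\t{row['ref']}\t"
                     f"{row['alt']}\t.\tPASS\t.\tGT\t{gts}\n")

    ann = cohort.variants.rename(columns={"vclass": "class"})
    ann.to_csv(paths["annotation"], sep="\t", index_label="variant_id")
    cohort.samples.to_csv(paths["samples"], sep="\t", index_label="sample_id")
    cohort.msc.rename("msc").to_csv(paths["msc"], sep="\t", index_label="gene")
    cohort.gene_features.to_csv(paths["gene_features"], sep="\t", index_label="gene")
    return paths


def _chrom_key(label: str) -> int:
    return CONTIGS.index(str(label))


def read_cohort(directory) -> Cohort:
    """Load a cohort directory written by :func:`write_cohort`."""
    directory = Path(directory)
    samples = pd.read_csv(directory / "samples.tsv", sep="\t", index_col="sample_id",
                          dtype={"status": str, "sex": str, "ancestry": str,
                                 "pipeline": str, "auto_ab": str})
    ann = pd.read_csv(directory / "annotation.tsv", sep="\t", index_col="variant_id",
                      dtype={"chrom": str})
    ann = ann.rename(columns={"class": "vclass"})
    msc = pd.read_csv(directory / "msc.tsv", sep="\t", index_col="gene")["msc"]
    feats = pd.read_csv(directory / "gene_features.tsv", sep="\t", index_col="gene")

    n, m = len(samples), len(ann)
    genotypes = np.zeros((n, m), dtype=np.int8)
    col_of = {vid: j for j, vid in enumerate(ann.index)}
    sample_pos = {s: i for i, s in enumerate(samples.index)}
    with pysam.VariantFile(str(directory / "genotypes.vcf")) as vf:
        vcf_samples = list(vf.header.samples)
        if set(vcf_samples) != set(samples.index):
            raise ValueError("VCF samples do not match the sample sheet")
        for rec in vf:
            vid = rec.id
            if vid not in col_of:
                raise ValueError(f"VCF record {vid} absent from annotation table")
            j = col_of[vid]
            for s in vcf_samples:
                alleles = rec.samples[s]["GT"]
                if alleles is None or all(a is None for a in alleles):
                    genotypes[sample_pos[s], j] = -1
                else:
                    genotypes[sample_pos[s], j] = sum(a or 0 for a in alleles)
    return Cohort(samples, ann, genotypes, feats, msc).validate()
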