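"""Trio VCF round-trip via pysam.

Writes plain-text multi-sample VCF 4.2 with a GT-only FORMAT and samples in
child/mother/father order; reads any VCF back into a :class:`TrioGenotypeSet`
(trio mode insists on exactly three samples).
"""
from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam

from .containers import TrioGenotypeSet


def write_trio_vcf(
    trio: TrioGenotypeSet,
    path: str | os.PathLike,
    chrom_lengths: dict[str, int] | None = None,
) -> None:
    """Serialize a trio genotype set to an uncompressed VCF file."""
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lengths = chrom_lengths or {}
    pos_by_chrom = trio.sites.groupby("chrom", sort=False)["pos"].max()
    for chrom in trio.chroms:
        length = int(lengths.get(chrom, pos_by_chrom[chrom]))
        header.contigs.add(str(chrom), length=length)
    for sample in trio.samples:
        header.add_sample(sample)

    _ALLELE_PAIRS = {0: (0, 0), 1: (0, 1), 2: (1, 1), -1: (None, None)}
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for i in range(trio.n_sites):
            row = trio.sites.iloc[i]
            rec = vcf.new_record(
                contig=str(row["chrom"]),
                start=int(row["pos"]) - 1,  # pysam is 0-based internally
                alleles=(str(row["ref"]), str(row["alt"])),
            )
            for j, sample in enumerate(trio.samples):
                rec.samples[sample]["GT"] = _ALLELE_PAIRS[int(trio.genotypes[i, j])]
                rec.samples[sample].phased = False
            vcf.write(rec)


def read_trio_vcf(path: str | os.PathLike) -> TrioGenotypeSet:
    """Read a multi-sample VCF as a trio (exactly three samples required).

    Only biallelic SNV records are accepted; genotypes are collapsed to the
    unphased dosage codes used throughout the package.
    """
    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    codes: list[list[int]] = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = tuple(vcf.header.samples)
        if len(samples) != 3:
            raise ValueError(
                f"trio mode requires exactly 3 samples, found {len(samples)}"
            )
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                raise ValueError(
                    f"non-biallelic record at {rec.contig}:{rec.pos}"
                )
            chroms.append(rec.contig)
            pos.append(rec.pos)  # pysam exposes 1-based pos
            ref.append(rec.ref)
            alt.append(rec.alts[0])
            row = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    row.append(-1)
                else:
                    row.append(int(sum(gt)))
            codes.append(row)
    sites = pd.DataFrame({"chrom": chroms, "pos": pos, "ref": ref, "alt": alt})
    return TrioGenotypeSet(sites, np.array(codes, dtype=np.int8).reshape(-1, 3), samples)
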