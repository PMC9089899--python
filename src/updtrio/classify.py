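"""Per-site trio inheritance-pattern classification.

Each biallelic site of a child/mother/father trio falls into exactly one
class, decided by two constructibility questions:

* *biparental*: can the child's unphased genotype be assembled from one allele
  of the mother and one allele of the father?
* *single-parent P*: can it be assembled from two alleles of parent P alone —
  two copies of one allele P carries (isodisomy-like) or P's exact genotype
  (heterodisomy-like)?

A site is UPD-informative for parent P when the single-parent-P construction
works and the biparental one does not. Within that, the *iso-informative*
pattern has parent P heterozygous and the child homozygous (e.g. mother 0/1,
father 0/0, child 1/1 — the hallmark of maternal isodisomy), while the
*evidence* pattern has both parents homozygous for opposite alleles with the
child matching parent P (the hallmark visible under heterodisomy as well).
Sites inconsistent with both biparental and single-parent transmission (e.g.
child 0/1 with both parents 0/0) are Mendelian errors of other origin; any
missing member makes the site unclassifiable.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .containers import HET, TrioGenotypeSet


class TrioSiteClass(enum.IntEnum):
    BIPARENTAL_CONSISTENT = 0
    UPD_MAT_ISO_INFORMATIVE = 1
    UPD_MAT_EVIDENCE = 2
    UPD_PAT_ISO_INFORMATIVE = 3
    UPD_PAT_EVIDENCE = 4
    MENDELIAN_ERROR_OTHER = 5
    MISSING = 6


#: classes that are inconsistent with biparental transmission
MENDELIAN_INCONSISTENT = frozenset(
    {
        TrioSiteClass.UPD_MAT_ISO_INFORMATIVE,
        TrioSiteClass.UPD_MAT_EVIDENCE,
        TrioSiteClass.UPD_PAT_ISO_INFORMATIVE,
        TrioSiteClass.UPD_PAT_EVIDENCE,
        TrioSiteClass.MENDELIAN_ERROR_OTHER,
    }
)

MATERNAL_INFORMATIVE = frozenset(
    {TrioSiteClass.UPD_MAT_ISO_INFORMATIVE, TrioSiteClass.UPD_MAT_EVIDENCE}
)
PATERNAL_INFORMATIVE = frozenset(
    {TrioSiteClass.UPD_PAT_ISO_INFORMATIVE, TrioSiteClass.UPD_PAT_EVIDENCE}
)


def _alleles(code: int) -> tuple[int, ...]:
    return {0: (0,), 1: (0, 1), 2: (1,)}[code]


def _biparental_ok(gm: int, gf: int, gc: int) -> bool:
    return gc in {a + b for a in _alleles(gm) for b in _alleles(gf)}


def _single_parent_ok(gp: int, gc: int) -> bool:
    return gc in {a + b for a, b in product(_alleles(gp), repeat=2)}


def _classify_complete(gm: int, gf: int, gc: int) -> TrioSiteClass:
    if _biparental_ok(gm, gf, gc):
        return TrioSiteClass.BIPARENTAL_CONSISTENT
    mat = _single_parent_ok(gm, gc)
    pat = _single_parent_ok(gf, gc)
    # mat and pat cannot both hold when biparental fails: a child genotype
    # constructible from each parent alone is constructible from both jointly
    if mat:
        if gm == HET:
            return TrioSiteClass.UPD_MAT_ISO_INFORMATIVE
        return TrioSiteClass.UPD_MAT_EVIDENCE
    if pat:
        if gf == HET:
            return TrioSiteClass.UPD_PAT_ISO_INFORMATIVE
        return TrioSiteClass.UPD_PAT_EVIDENCE
    return TrioSiteClass.MENDELIAN_ERROR_OTHER


def _build_lut() -> np.ndarray:
    lut = np.empty((4, 4, 4), dtype=np.int8)
    lut[:] = TrioSiteClass.MISSING
    for gm in (0, 1, 2):
        for gf in (0, 1, 2):
            for gc in (0, 1, 2):
                lut[gm + 1, gf + 1, gc + 1] = _classify_complete(gm, gf, gc)
    return lut


_LUT = _build_lut()


def classify_trio_site(gt_mother: int, gt_father: int, gt_child: int) -> TrioSiteClass:
    """Classify one site from the three genotype codes (missing = -1)."""
    for g in (gt_mother, gt_father, gt_child):
        if g not in (-1, 0, 1, 2):
            raise ValueError(f"genotype code {g!r} outside the domain")
    return TrioSiteClass(_LUT[gt_mother + 1, gt_father + 1, gt_child + 1])


@dataclass
class TrioClassCounts:
    """Per-chromosome counts of every trio site class.

    ``per_chrom`` is a DataFrame indexed by chromosome with one column per
    class name; rows sum to the number of sites on the chromosome.
    """

    per_chrom: pd.DataFrame

    @property
    def totals(self) -> pd.Series:
        return self.per_chrom.sum(axis=0)

    def informative(self, parent: str, chrom=None) -> int:
        classes = MATERNAL_INFORMATIVE if parent == "mother" else PATERNAL_INFORMATIVE
        frame = self.per_chrom if chrom is None else self.per_chrom.loc[[chrom]]
        return int(frame[[c.name for c in classes]].to_numpy().sum())


def classify_all(trio: TrioGenotypeSet) -> tuple[np.ndarray, TrioClassCounts]:
    """Classify every site; returns the per-site class-code vector and the
    per-chromosome count table."""
    gm = trio.gt("mother")
    gf = trio.gt("father")
    gc = trio.gt("child")
    codes = _LUT[gm + 1, gf + 1, gc + 1]
    names = [c.name for c in TrioSiteClass]
    rows = {}
    for chrom in trio.chroms:
        mask = trio.chrom_mask(chrom)
        rows[chrom] = np.bincount(codes[mask], minlength=len(names))
    per_chrom = pd.DataFrame.from_dict(rows, orient="index", columns=names)
    per_chrom.index.name = "chrom"
    return codes, TrioClassCounts(per_chrom)


def mendelian_error_rate(counts: TrioClassCounts) -> tuple[pd.Series, float]:
    """Mendelian-inconsistency rate per chromosome and genome-wide.

    The rate is the fraction of classified (non-missing) sites whose class is
    inconsistent with biparental transmission.
    """
    frame = counts.per_chrom
    inconsistent = frame[[c.name for c in MENDELIAN_INCONSISTENT]].sum(axis=1)
    classified = frame.sum(axis=1) - frame[TrioSiteClass.MISSING.name]
    if int(classified.sum()) == 0:
        raise ValueError("no classified sites: cannot form a rate")
    per_chrom = inconsistent / classified.replace(0, np.nan)
    genome = float(inconsistent.sum() / classified.sum())
    return per_chrom, genome
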