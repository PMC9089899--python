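"""Genotype containers shared by every inference stage.

Genotypes for biallelic SNVs are held as small integer codes:

====  =========  ==============
code  GT string  meaning
====  =========  ==============
0     0/0        homozygous ref
1     0/1        heterozygous
2     1/1        homozygous alt
-1    ./.        missing call
====  =========  ==============

The dosage coding makes Mendelian arithmetic trivial: an unphased child
genotype is the sum of one transmitted allele (0 or 1) from each parent.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HOM_REF: int = 0
HET: int = 1
HOM_ALT: int = 2
MISSING: int = -1

#: canonical sample order in every trio object and trio VCF
TRIO_SAMPLES: tuple[str, str, str] = ("child", "mother", "father")

_CODE_TO_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
_GT_TO_CODE = {
    "0/0": 0, "0|0": 0,
    "0/1": 1, "1/0": 1, "0|1": 1, "1|0": 1,
    "1/1": 2, "1|1": 2,
    "./.": -1, ".|.": -1, ".": -1,
}

SITE_COLUMNS = ("chrom", "pos", "ref", "alt")


def code_to_gt(code: int) -> str:
    """Render an integer genotype code as an unphased VCF GT string."""
    try:
        return _CODE_TO_GT[int(code)]
    except KeyError:
        raise ValueError(f"unknown genotype code {code!r}") from None


def gt_to_code(gt: str) -> int:
    """Parse a GT string (``0/0``, ``0/1``, ``1/1``, ``./.``) to its code."""
    try:
        return _GT_TO_CODE[gt.strip()]
    except KeyError:
        raise ValueError(f"genotype {gt!r} outside the biallelic domain") from None


def validate_sites(sites: pd.DataFrame) -> None:
    """Check the site frame: required columns, positive positions, and strict
    (chrom, pos) ordering with contiguous chromosome blocks."""
    for col in SITE_COLUMNS:
        if col not in sites.columns:
            raise ValueError(f"site table lacks required column {col!r}")
    pos = sites["pos"].to_numpy()
    if len(pos) and pos.min() < 1:
        raise ValueError("positions must be 1-based (>= 1)")
    chroms = sites["chrom"].to_numpy()
    seen: list = []
    for c in chroms:
        if not seen or seen[-1] != c:
            if c in seen:
                raise ValueError(f"chromosome {c!r} appears in non-contiguous blocks")
            seen.append(c)
    for c in seen:
        p = pos[chroms == c]
        if np.any(np.diff(p) <= 0):
            raise ValueError(f"positions on chromosome {c!r} not strictly increasing")


@dataclass
class TrioGenotypeSet:
    """Per-site unphased genotypes for a child/mother/father trio.

    Parameters
    ----------
    sites : pandas.DataFrame
        One row per variant with columns ``chrom, pos, ref, alt``; sorted by
        (chrom, pos), positions 1-based.
    genotypes : numpy.ndarray
        ``(n_sites, 3)`` int8 array of genotype codes, columns ordered
        child, mother, father.
    samples : tuple of str
        Sample labels matching the genotype columns.
    """

    sites: pd.DataFrame
    genotypes: np.ndarray
    samples: tuple[str, str, str] = field(default=TRIO_SAMPLES)

    def __post_init__(self) -> None:
        validate_sites(self.sites)
        gts = np.asarray(self.genotypes, dtype=np.int8)
        if gts.ndim != 2 or gts.shape[1] != 3:
            raise ValueError("genotypes must be an (n_sites, 3) array")
        if gts.shape[0] != len(self.sites):
            raise ValueError("genotype rows do not match the site table")
        bad = ~np.isin(gts, (-1, 0, 1, 2))
        if bad.any():
            raise ValueError("genotype codes outside {-1, 0, 1, 2}")
        if len(self.samples) != 3:
            raise ValueError("a trio needs exactly three samples")
        self.genotypes = gts
        self.sites = self.sites.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def chroms(self) -> list:
        """Chromosome labels in order of appearance."""
        out: list = []
        for c in self.sites["chrom"]:
            if not out or out[-1] != c:
                out.append(c)
        return out

    def gt(self, sample: str) -> np.ndarray:
        """Genotype-code vector for one sample (view, do not mutate)."""
        return self.genotypes[:, self.samples.index(sample)]

    def chrom_mask(self, chrom) -> np.ndarray:
        return (self.sites["chrom"] == chrom).to_numpy()

    def subset(self, mask: np.ndarray) -> "TrioGenotypeSet":
        return TrioGenotypeSet(
            self.sites.loc[mask].reset_index(drop=True),
            self.genotypes[mask],
            self.samples,
        )

    def equals(self, other: "TrioGenotypeSet") -> bool:
        """Identity on (chrom, pos, ref, alt) and the three genotype vectors."""
        same_sites = self.sites[list(SITE_COLUMNS)].astype({"pos": np.int64}).equals(
            other.sites[list(SITE_COLUMNS)].astype({"pos": np.int64})
        )
        return bool(same_sites and np.array_equal(self.genotypes, other.genotypes))
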