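"""Exome-scale annotated-variant table simulator.

Generates a whole-exome-like table of annotated trio variants (default
90,000 rows) so the filter funnel can be exercised with exact ground truth:
a configurable list of *engineered survivors* — variants constructed to pass
every funnel stage, validated against the stage predicates at build time —
is planted in an otherwise background table in which every row is guaranteed
to fail at least one stage. Background rows that would survive all four
stages by chance are re-drawn to a common population allele frequency, which
fails the rarity stage deterministically; the ground-truth survivor flag is
carried in the ``engineered`` column.

Distributions are chosen to look exome-like: consequence classes dominated by
coding and near-coding annotations, per-class deleteriousness scores on a
PHRED-like scale with only the non-synonymous and splice classes reaching
high scores regularly, and a population-frequency mixture of novel variants
(point mass at zero) plus a long-tailed common component.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .filtering import (
    ANNOTATION_COLUMNS,
    CONSEQUENCE_CLASSES,
    DEFAULT_FILTER_CONFIG,
    FilterConfig,
    passes_funnel,
)

#: approximate GRCh38 autosome lengths for scattering annotation rows (bp)
_AUTOSOME_LENGTHS = {
    str(i): length
    for i, length in enumerate(
        [
            248_956_422, 242_193_529, 198_295_559, 190_214_555, 181_538_259,
            170_805_979, 159_345_973, 145_138_636, 138_394_717, 133_797_422,
            135_086_622, 133_275_309, 114_364_328, 107_043_718, 101_991_189,
            90_338_345, 83_257_441, 80_373_285, 58_617_616, 64_444_167,
            46_709_983, 50_818_468,
        ],
        start=1,
    )
}

_BASES = np.array(list("ACGT"))

DEFAULT_CONSEQUENCE_PROBS = {
    "exonic_nonsynonymous": 0.17,
    "exonic_synonymous": 0.11,
    "splice_site": 0.02,
    "intronic": 0.45,
    "UTR": 0.13,
    "intergenic": 0.12,
}

# (mean, sd) of a clipped-normal PHRED-like score per consequence class
DEFAULT_CADD_PARAMS = {
    "exonic_nonsynonymous": (18.0, 8.0),
    "exonic_synonymous": (8.0, 6.0),
    "splice_site": (20.0, 10.0),
    "intronic": (3.0, 3.0),
    "UTR": (4.0, 3.0),
    "intergenic": (2.0, 2.0),
}


@dataclass(frozen=True)
class EngineeredVariant:
    """An explicit annotation row planted as a ground-truth funnel survivor."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    cadd_phred: float
    pop_maf: float
    gt_child: str
    gt_mother: str
    gt_father: str

    def as_row(self) -> dict:
        return {c: getattr(self, c) for c in ANNOTATION_COLUMNS}


def default_engineered_survivors() -> list[EngineeredVariant]:
    """Four survivors in four distinct genes; the ENPP1 entry mirrors the
    proband configuration of interest (child homozygous, mother heterozygous,
    father homozygous reference, score 22.8, population frequency 4e-4)."""
    return [
        EngineeredVariant("4", 159_200_000, "G", "A", "RAPGEF2",
                          "exonic_nonsynonymous", 24.1, 0.0, "0/1", "0/1", "0/0"),
        EngineeredVariant("6", 131_850_000, "G", "C", "ENPP1",
                          "exonic_nonsynonymous", 22.8, 0.0004, "1/1", "0/1", "0/0"),
        EngineeredVariant("17", 38_600_000, "C", "T", "SRCIN1",
                          "exonic_nonsynonymous", 25.6, 0.0, "0/1", "0/0", "0/1"),
        EngineeredVariant("1", 17_280_000, "A", "G", "MRPH8",
                          "splice_site", 23.4, 0.0002, "0/1", "0/1", "0/0"),
    ]


@dataclass
class AnnotationSimConfig:
    n_variants: int = 90_000
    consequence_probs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONSEQUENCE_PROBS)
    )
    cadd_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CADD_PARAMS)
    )
    maf_zero_prob: float = 0.10
    maf_beta: tuple[float, float] = (0.8, 3.0)
    n_genes: int = 8000
    engineered_survivors: list[EngineeredVariant] = field(
        default_factory=default_engineered_survivors
    )
    filter_config: FilterConfig = field(default_factory=lambda: DEFAULT_FILTER_CONFIG)
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_variants < 0:
            raise ValueError("n_variants must be non-negative")
        if set(self.consequence_probs) != set(CONSEQUENCE_CLASSES):
            raise ValueError("consequence_probs must cover the closed vocabulary")
        if abs(sum(self.consequence_probs.values()) - 1.0) > 1e-9:
            raise ValueError("consequence probabilities must sum to 1")
        if not 0.0 <= self.maf_zero_prob < 1.0:
            raise ValueError("maf_zero_prob must lie in [0, 1)")
        if len(self.engineered_survivors) > self.n_variants:
            raise ValueError("more engineered survivors than table rows")


def _validate_survivors(
    survivors: list[EngineeredVariant], config: FilterConfig
) -> None:
    if not survivors:
        return
    frame = pd.DataFrame([s.as_row() for s in survivors])
    ok = passes_funnel(frame, config)
    if not ok.all():
        bad = frame.loc[~ok, "gene"].tolist()
        raise ValueError(
            f"engineered survivors fail a funnel stage predicate: {bad}"
        )


def _draw_trio_gts(
    rng: np.random.Generator, maf: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Trio genotype strings per row. Common rows get Hardy-Weinberg parents
    with Mendelian transmission; rare/novel rows get a single carrier parent
    transmitting with probability one half; a row with no carrier at all gets
    a heterozygous child so every tabulated variant is seen in the trio."""
    n = len(maf)
    f = np.clip(maf, 0.0, 0.5)
    common = f > 0.01
    gm = np.zeros(n, dtype=np.int8)
    gf = np.zeros(n, dtype=np.int8)
    # Hardy-Weinberg parents at the population frequency for common rows
    for g in (gm, gf):
        u = rng.random(n)
        g[common & (u < f**2)] = 2
        g[common & (u >= f**2) & (u < f**2 + 2 * f * (1 - f))] = 1
    # rare rows: one parent heterozygous, chosen at random
    rare = ~common
    pick_mother = rng.random(n) < 0.5
    gm[rare & pick_mother] = 1
    gf[rare & ~pick_mother] = 1
    # Mendelian child
    tm = np.where(gm == 1, (rng.random(n) < 0.5).astype(np.int8), (gm // 2))
    tf = np.where(gf == 1, (rng.random(n) < 0.5).astype(np.int8), (gf // 2))
    gc = (tm + tf).astype(np.int8)
    nobody = (gm == 0) & (gf == 0) & (gc == 0)
    gc[nobody] = 1
    strings = np.array(["0/0", "0/1", "1/1"])
    return strings[gc], strings[gm], strings[gf]


def simulate_annotated_variants(config: AnnotationSimConfig) -> pd.DataFrame:
    """Build the annotated trio variant table.

    Returns a DataFrame with the eleven interface columns plus a boolean
    ``engineered`` column marking the ground-truth funnel survivors; exactly
    the engineered rows pass all four stage predicates.
    """
    _validate_survivors(config.engineered_survivors, config.filter_config)
    rng = np.random.default_rng(config.seed)
    n_bg = config.n_variants - len(config.engineered_survivors)
    if config.n_variants == 0:
        return pd.DataFrame(columns=list(ANNOTATION_COLUMNS) + ["engineered"])

    chrom_labels = np.array(list(_AUTOSOME_LENGTHS))
    lengths = np.array(list(_AUTOSOME_LENGTHS.values()), dtype=float)
    chrom_idx = rng.choice(len(chrom_labels), size=n_bg, p=lengths / lengths.sum())
    pos = (rng.random(n_bg) * lengths[chrom_idx]).astype(np.int64) + 1

    classes = list(config.consequence_probs)
    probs = np.array([config.consequence_probs[c] for c in classes])
    cons = rng.choice(classes, size=n_bg, p=probs)

    mean = np.array([config.cadd_params[c][0] for c in cons])
    sd = np.array([config.cadd_params[c][1] for c in cons])
    cadd = np.clip(rng.normal(mean, sd), 0.0, None).round(2)

    a, b = config.maf_beta
    maf = rng.beta(a, b, size=n_bg) * 0.5
    maf[rng.random(n_bg) < config.maf_zero_prob] = 0.0

    ref_idx = rng.integers(0, 4, size=n_bg)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_bg)) % 4
    genes = np.array([f"GENE{i:05d}" for i in rng.integers(0, config.n_genes, size=n_bg)])

    gt_c, gt_m, gt_f = _draw_trio_gts(rng, maf)

    background = pd.DataFrame(
        {
            "chrom": chrom_labels[chrom_idx],
            "pos": pos,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "gene": genes,
            "consequence": cons,
            "cadd_phred": cadd,
            "pop_maf": maf,
            "gt_child": gt_c,
            "gt_mother": gt_m,
            "gt_father": gt_f,
            "engineered": False,
        }
    )
    # ground-truth guarantee: background rows never survive the whole funnel —
    # chance survivors are re-drawn as common-population variants
    lucky = passes_funnel(background, config.filter_config)
    background.loc[lucky, "pop_maf"] = rng.uniform(0.05, 0.45, size=int(lucky.sum()))

    planted = pd.DataFrame([s.as_row() for s in config.engineered_survivors])
    planted["engineered"] = True
    table = pd.concat([background, planted], ignore_index=True)
    chrom_order = {c: i for i, c in enumerate(_AUTOSOME_LENGTHS)}
    table["_order"] = table["chrom"].map(chrom_order)
    table = (
        table.sort_values(["_order", "pos"], kind="mergesort")
        .drop(columns="_order")
        .reset_index(drop=True)
    )
    assert int(passes_funnel(table, config.filter_config).sum()) == len(
        config.engineered_survivors
    )
    return table


def write_annotation_table(table: pd.DataFrame, path) -> None:
    """Tab-delimited serialization of the eleven interface columns."""
    table[list(ANNOTATION_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_annotation_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table lacks columns {missing}")
    return table
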