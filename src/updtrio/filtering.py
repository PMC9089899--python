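"""Stepwise rare-variant filter funnel with per-stage survivor accounting.

The funnel applies four per-row predicates to an annotated trio variant
table, in a fixed order:

1. ``exonic_splice`` — keep exonic (synonymous or non-synonymous) and
   splice-site variants; drop intronic/UTR/intergenic rows.
2. ``synonymous_cadd`` — drop synonymous variants and any variant whose
   PHRED-scaled deleteriousness (CADD-style) score is strictly below
   ``cadd_min`` (default 20, the conventional top-1% threshold). An
   alternative reading, in which the score cutoff applies to synonymous rows
   only, is available via ``synonymous_cadd_only``.
3. ``maf`` — drop variants whose population minor allele frequency is
   strictly above ``maf_max`` (default 0.001); absent frequency records are
   treated as novel (0).
4. ``parent_shared`` — drop variants whose alternate allele is carried by
   both parents (in any zygosity); a variant heterozygous in one parent and
   absent from the other survives. Rows with missing parental genotypes are
   retained and flagged.

All four predicates are per-row, so the final survivor set is invariant to
stage order; the intermediate counts of the report are not, which is why the
order is fixed and recorded.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONSEQUENCE_CLASSES = (
    "exonic_nonsynonymous",
    "exonic_synonymous",
    "splice_site",
    "intronic",
    "UTR",
    "intergenic",
)
_EXONIC_SPLICE = {"exonic_nonsynonymous", "exonic_synonymous", "splice_site"}

ANNOTATION_COLUMNS = (
    "chrom", "pos", "ref", "alt", "gene", "consequence",
    "cadd_phred", "pop_maf", "gt_child", "gt_mother", "gt_father",
)

STAGE_NAMES = ("exonic_splice", "synonymous_cadd", "maf", "parent_shared")


@dataclass(frozen=True)
class FilterConfig:
    cadd_min: float = 20.0
    maf_max: float = 0.001
    synonymous_cadd_only: bool = False  # alternative reading of stage 2

    def __post_init__(self) -> None:
        if self.cadd_min <= 0 or self.maf_max <= 0:
            raise ValueError("thresholds must be positive")


DEFAULT_FILTER_CONFIG = FilterConfig()


@dataclass
class GeneCutoffMap:
    """Gene-specific deleteriousness cutoffs (mutation-significance-cutoff
    style); ships with the ENPP1 entry of 13.13. Genes absent from the map
    fall back to the global ``cadd_min`` and are flagged."""

    cutoffs: dict[str, float] = field(default_factory=lambda: {"ENPP1": 13.13})
    fallback: float = 20.0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.cutoffs.values()) or self.fallback < 0:
            raise ValueError("cutoffs must be non-negative")


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"annotation table lacks columns {missing}")
    unknown = set(table["consequence"].unique()) - set(CONSEQUENCE_CLASSES)
    if unknown:
        raise ValueError(f"unknown consequence labels {sorted(unknown)}")


def _carries_alt(gt: pd.Series) -> np.ndarray:
    return gt.isin(["0/1", "1/0", "1/1"]).to_numpy()


def _gt_missing(gt: pd.Series) -> np.ndarray:
    return ~gt.isin(["0/0", "0/1", "1/0", "1/1"]).to_numpy()


# -- per-row predicates (True = keep) -----------------------------------------

def mask_exonic_splice(table: pd.DataFrame) -> np.ndarray:
    return table["consequence"].isin(_EXONIC_SPLICE).to_numpy()


def mask_synonymous_cadd(table: pd.DataFrame, config: FilterConfig) -> np.ndarray:
    synonymous = (table["consequence"] == "exonic_synonymous").to_numpy()
    low_cadd = (table["cadd_phred"].to_numpy() < config.cadd_min)
    if config.synonymous_cadd_only:
        return ~(synonymous & low_cadd)
    return ~synonymous & ~low_cadd


def mask_maf(table: pd.DataFrame, config: FilterConfig) -> np.ndarray:
    maf = table["pop_maf"].to_numpy(dtype=float)
    if np.nanmin(maf, initial=0.0) < 0:
        raise ValueError("negative population MAF")
    maf = np.nan_to_num(maf, nan=0.0)  # absent record = novel
    return maf <= config.maf_max


def mask_parent_shared(table: pd.DataFrame) -> np.ndarray:
    shared = _carries_alt(table["gt_mother"]) & _carries_alt(table["gt_father"])
    missing = _gt_missing(table["gt_mother"]) | _gt_missing(table["gt_father"])
    return ~shared | missing  # missing parental genotypes: retain (flagged)


# -- stage operations ---------------------------------------------------------

def stage_exonic_splice(table: pd.DataFrame) -> pd.DataFrame:
    _check_table(table)
    return table.loc[mask_exonic_splice(table)]


def stage_synonymous_cadd(
    table: pd.DataFrame, config: FilterConfig = DEFAULT_FILTER_CONFIG
) -> pd.DataFrame:
    return table.loc[mask_synonymous_cadd(table, config)]


def stage_maf(
    table: pd.DataFrame, config: FilterConfig = DEFAULT_FILTER_CONFIG
) -> pd.DataFrame:
    return table.loc[mask_maf(table, config)]


def stage_parent_shared(table: pd.DataFrame) -> pd.DataFrame:
    out = table.loc[mask_parent_shared(table)].copy()
    out["parent_gt_missing"] = _gt_missing(out["gt_mother"]) | _gt_missing(out["gt_father"])
    return out


def passes_funnel(
    table: pd.DataFrame, config: FilterConfig = DEFAULT_FILTER_CONFIG
) -> np.ndarray:
    """Conjunction of all four per-row predicates (no staging)."""
    _check_table(table)
    return (
        mask_exonic_splice(table)
        & mask_synonymous_cadd(table, config)
        & mask_maf(table, config)
        & mask_parent_shared(table)
    )


@dataclass
class FunnelStage:
    name: str
    n_in: int
    n_removed: int
    n_out: int


@dataclass
class FunnelReport:
    stages: list[FunnelStage]
    candidates_by_gene: dict[str, int]

    def __post_init__(self) -> None:
        for s in self.stages:
            if s.n_in != s.n_removed + s.n_out:
                raise ValueError(f"stage {s.name!r} counts do not reconcile")
        for a, b in zip(self.stages, self.stages[1:]):
            if a.n_out != b.n_in:
                raise ValueError("stage outputs and inputs do not chain")

    @property
    def n_input(self) -> int:
        return self.stages[0].n_in if self.stages else 0

    @property
    def n_candidates(self) -> int:
        return self.stages[-1].n_out if self.stages else 0

    def to_dict(self) -> dict:
        return {
            "stages": [vars(s) for s in self.stages],
            "candidates_by_gene": dict(self.candidates_by_gene),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def run_funnel(
    table: pd.DataFrame, config: FilterConfig = DEFAULT_FILTER_CONFIG
) -> tuple[pd.DataFrame, FunnelReport]:
    """Apply the four stages in fixed order and account for every row."""
    _check_table(table)
    stages: list[FunnelStage] = []
    current = table
    ops = (
        ("exonic_splice", lambda t: stage_exonic_splice(t)),
        ("synonymous_cadd", lambda t: stage_synonymous_cadd(t, config)),
        ("maf", lambda t: stage_maf(t, config)),
        ("parent_shared", lambda t: stage_parent_shared(t)),
    )
    for name, op in ops:
        n_in = len(current)
        current = op(current)
        stages.append(FunnelStage(name, n_in, n_in - len(current), len(current)))
    by_gene = current["gene"].value_counts().to_dict() if len(current) else {}
    return current.reset_index(drop=True), FunnelReport(stages, by_gene)


def exceeds_gene_cutoff(
    variant: pd.Series | dict, cutoffs: GeneCutoffMap
) -> tuple[bool, float, bool]:
    """Compare a variant's deleteriousness score against its gene-specific
    cutoff (strict "greater than").

    Returns ``(exceeds, margin, used_fallback)`` where ``margin`` is
    score minus cutoff and ``used_fallback`` marks genes absent from the map.
    """
    gene = variant["gene"]
    score = float(variant["cadd_phred"])
    used_fallback = gene not in cutoffs.cutoffs
    cutoff = cutoffs.fallback if used_fallback else cutoffs.cutoffs[gene]
    return score > cutoff, score - cutoff, used_fallback
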