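"""Within-family kinship estimation from shared genotype counts.

The estimator is the within-family form of the KING-robust family of kinship
statistics, built from four tallies over sites called in both samples:

    phi = (N_het,het - 2 * N_opposite_hom) / (N_het_i + N_het_j)

where ``N_het,het`` counts sites at which both samples are heterozygous and
``N_opposite_hom`` counts sites at which one sample is homozygous reference
and the other homozygous alternate. Under Hardy-Weinberg sites the estimator
has expectation 0.5 for a sample against itself (or a monozygotic twin), 0.25
for parent-offspring, and 0 for unrelated pairs; sampling noise can push
unrelated pairs slightly negative.

Degree classification uses the standard powers-of-sqrt(2) ladder of phi
intervals: first-degree relationships occupy (0.177, 0.354].
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .containers import HET, HOM_ALT, HOM_REF


class UndefinedKinshipError(ValueError):
    """Raised when neither sample has a heterozygous call (zero denominator)."""


@dataclass(frozen=True)
class PairCounts:
    """Shared-genotype tallies for one sample pair over co-called sites."""

    n_het_het: int
    n_opp_hom: int
    n_het_i: int
    n_het_j: int
    n_used: int

    def __post_init__(self) -> None:
        for name in ("n_het_het", "n_opp_hom", "n_het_i", "n_het_j", "n_used"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_het_het > min(self.n_het_i, self.n_het_j):
            raise ValueError("n_het_het cannot exceed either per-sample het count")
        for name in ("n_het_het", "n_opp_hom", "n_het_i", "n_het_j"):
            if getattr(self, name) > self.n_used:
                raise ValueError(f"{name} cannot exceed n_used")


@dataclass(frozen=True)
class KinshipEstimate:
    phi: float
    counts: PairCounts


@dataclass(frozen=True)
class DegreeThresholds:
    """Phi interval boundaries (closed upper bounds, strictly decreasing)."""

    duplicate: float = 0.354
    first_degree: float = 0.177
    second_degree: float = 0.0884
    third_degree: float = 0.0442

    def __post_init__(self) -> None:
        ladder = (self.duplicate, self.first_degree, self.second_degree, self.third_degree)
        if any(a <= b for a, b in zip(ladder, ladder[1:])):
            raise ValueError("thresholds must be strictly decreasing")


DEFAULT_THRESHOLDS = DegreeThresholds()


def count_pair_genotypes(gts_i: np.ndarray, gts_j: np.ndarray) -> PairCounts:
    """Tally the pair over sites non-missing in both samples."""
    gi = np.asarray(gts_i)
    gj = np.asarray(gts_j)
    if gi.shape != gj.shape:
        raise ValueError("genotype vectors differ in length")
    used = (gi >= 0) & (gj >= 0)
    gi, gj = gi[used], gj[used]
    return PairCounts(
        n_het_het=int(np.sum((gi == HET) & (gj == HET))),
        n_opp_hom=int(
            np.sum(((gi == HOM_REF) & (gj == HOM_ALT)) | ((gi == HOM_ALT) & (gj == HOM_REF)))
        ),
        n_het_i=int(np.sum(gi == HET)),
        n_het_j=int(np.sum(gj == HET)),
        n_used=int(used.sum()),
    )


def estimate_kinship(counts: PairCounts) -> KinshipEstimate:
    """phi = (n_het_het - 2 n_opp_hom) / (n_het_i + n_het_j)."""
    denom = counts.n_het_i + counts.n_het_j
    if denom == 0:
        raise UndefinedKinshipError(
            "kinship undefined: no heterozygous calls in either sample"
        )
    phi = (counts.n_het_het - 2.0 * counts.n_opp_hom) / denom
    return KinshipEstimate(phi=phi, counts=counts)


def classify_degree(
    phi: float, thresholds: DegreeThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Map phi to a relationship degree label (upper bounds closed, so a phi
    exactly at a boundary falls in the lower interval)."""
    if not np.isfinite(phi):
        raise ValueError("phi must be finite")
    t = thresholds
    if phi > t.duplicate:
        return "duplicate/monozygotic"
    if phi > t.first_degree:
        return "first-degree"
    if phi > t.second_degree:
        return "second-degree"
    if phi > t.third_degree:
        return "third-degree"
    return "unrelated"


def jackknife_se(
    gts_i: np.ndarray, gts_j: np.ndarray, n_blocks: int = 50
) -> float:
    """Delete-one-block jackknife standard error of phi over site blocks."""
    gi = np.asarray(gts_i)
    n = len(gi)
    if n < n_blocks:
        n_blocks = max(2, n)
    edges = np.linspace(0, n, n_blocks + 1, dtype=int)
    full = estimate_kinship(count_pair_genotypes(gts_i, gts_j)).phi
    reps = []
    for a, b in zip(edges[:-1], edges[1:]):
        keep = np.ones(n, dtype=bool)
        keep[a:b] = False
        try:
            reps.append(
                estimate_kinship(count_pair_genotypes(gts_i[keep], gts_j[keep])).phi
            )
        except UndefinedKinshipError:
            continue
    reps = np.asarray(reps)
    if len(reps) < 2:
        return float("nan")
    m = len(reps)
    return float(np.sqrt((m - 1) / m * np.sum((reps - reps.mean()) ** 2)))


def kinship_matrix(
    genotypes: np.ndarray,
    samples: tuple[str, ...] | list[str],
    thresholds: DegreeThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """All pairwise kinship estimates for an (n_sites, n_samples) array.

    Returns one row per unordered pair with columns
    ``sample_i, sample_j, n_used, phi, degree``.
    """
    if genotypes.ndim != 2 or genotypes.shape[1] != len(samples):
        raise ValueError("genotype columns do not match sample labels")
    if len(samples) < 2:
        raise ValueError("need at least two samples")
    rows = []
    for i, j in combinations(range(len(samples)), 2):
        est = estimate_kinship(count_pair_genotypes(genotypes[:, i], genotypes[:, j]))
        rows.append(
            {
                "sample_i": samples[i],
                "sample_j": samples[j],
                "n_used": est.counts.n_used,
                "phi": est.phi,
                "degree": classify_degree(est.phi, thresholds),
            }
        )
    return pd.DataFrame(rows)
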