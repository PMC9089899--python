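"""Runs-of-homozygosity detection by a deterministic greedy scan.

A run is grown left to right through homozygous calls. Missing calls are
skipped (they neither extend nor break a run and are not counted). Isolated
heterozygous calls may be absorbed into a run, subject to two tolerances
checked at the moment of absorption: at most ``max_consecutive_het`` hets in
a row, and an absorbed-het fraction of the run no larger than
``max_het_fraction``. A het that cannot be absorbed closes the run at its
last homozygous site. Closed runs are reported when their physical span
strictly exceeds ``min_span_bp`` (the screening default of 4 Mb is read as
"more than 4 Mb") and they contain at least ``min_sites`` counted sites.

Run coordinates are the positions of the first and last homozygous site of
the run (no interpolation toward the flanking heterozygotes), 1-based
inclusive; ``span_bp = end_bp - start_bp + 1``.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import HET, MISSING


@dataclass(frozen=True)
class ROHConfig:
    min_span_bp: int = 4_000_000  # strict: reported spans must exceed this
    min_sites: int = 25
    max_het_fraction: float = 0.02
    max_consecutive_het: int = 1

    def __post_init__(self) -> None:
        if self.min_span_bp <= 0:
            raise ValueError("min_span_bp must be positive")
        if self.min_sites < 1:
            raise ValueError("min_sites must be at least 1")
        if not 0.0 <= self.max_het_fraction < 1.0:
            raise ValueError("max_het_fraction must lie in [0, 1)")
        if self.max_consecutive_het < 0:
            raise ValueError("max_consecutive_het must be non-negative")


DEFAULT_ROH_CONFIG = ROHConfig()


@dataclass(frozen=True)
class ROHRun:
    chrom: str
    start_bp: int
    end_bp: int
    n_sites: int  # homozygous plus absorbed heterozygous sites
    n_het_absorbed: int

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def contains(self, pos) -> np.ndarray:
        p = np.asarray(pos)
        return (p >= self.start_bp) & (p <= self.end_bp)


def _scan_chrom(
    chrom: str, positions: np.ndarray, gts: np.ndarray, config: ROHConfig
) -> list[ROHRun]:
    runs: list[ROHRun] = []
    start = last = -1  # indices of first/last homozygous member
    n_hom = n_het = 0
    pending = 0  # consecutive unabsorbed hets since the last hom

    def close() -> None:
        nonlocal start, last, n_hom, n_het, pending
        if start >= 0:
            span = int(positions[last] - positions[start] + 1)
            if span > config.min_span_bp and (n_hom + n_het) >= config.min_sites:
                runs.append(
                    ROHRun(
                        chrom=chrom,
                        start_bp=int(positions[start]),
                        end_bp=int(positions[last]),
                        n_sites=n_hom + n_het,
                        n_het_absorbed=n_het,
                    )
                )
        start = last = -1
        n_hom = n_het = 0
        pending = 0

    for idx in range(len(positions)):
        g = gts[idx]
        if g == MISSING:
            continue
        if g == HET:
            if start >= 0:
                pending += 1
                if pending > config.max_consecutive_het:
                    close()
            continue
        # homozygous call
        if start < 0:
            start = last = idx
            n_hom = 1
        elif pending:
            # absorbing the pending hets must keep the run's het fraction legal
            frac = (n_het + pending) / (n_hom + n_het + pending + 1)
            if frac <= config.max_het_fraction:
                n_het += pending
                n_hom += 1
                last = idx
                pending = 0
            else:
                close()
                start = last = idx
                n_hom = 1
        else:
            n_hom += 1
            last = idx
    close()
    return runs


def detect_roh(
    sites: pd.DataFrame, gts: np.ndarray, config: ROHConfig = DEFAULT_ROH_CONFIG
) -> list[ROHRun]:
    """Detect ROH runs for one sample over an ordered site frame.

    Parameters
    ----------
    sites : DataFrame with ``chrom`` and ``pos`` columns, sorted by (chrom, pos).
    gts : genotype-code vector aligned with ``sites``.
    """
    gts = np.asarray(gts)
    if len(gts) != len(sites):
        raise ValueError("genotype vector does not match site table")
    runs: list[ROHRun] = []
    chrom_col = sites["chrom"].to_numpy()
    pos_col = sites["pos"].to_numpy()
    seen: list = []
    for c in chrom_col:
        if not seen or seen[-1] != c:
            seen.append(c)
    for chrom in seen:
        idx = np.flatnonzero(chrom_col == chrom)
        positions = pos_col[idx]
        if np.any(np.diff(positions) <= 0):
            raise ValueError(f"sites on chromosome {chrom!r} not strictly increasing")
        runs.extend(_scan_chrom(chrom, positions, gts[idx], config))
    return runs


def roh_summary(
    runs: list[ROHRun], chrom_lengths: dict[str, int]
) -> pd.DataFrame:
    """Per-chromosome run count, total span, and coverage fraction."""
    rows = []
    by_chrom: dict[str, list[ROHRun]] = {}
    for r in runs:
        if r.chrom not in chrom_lengths:
            raise ValueError(f"run on unknown chromosome {r.chrom!r}")
        by_chrom.setdefault(r.chrom, []).append(r)
    for chrom, length in chrom_lengths.items():
        members = by_chrom.get(chrom, [])
        total = sum(r.span_bp for r in members)
        rows.append(
            {
                "chrom": chrom,
                "n_runs": len(members),
                "total_span_bp": total,
                "coverage": total / length,
            }
        )
    return pd.DataFrame(rows).set_index("chrom")


def runs_to_frame(runs: list[ROHRun]) -> pd.DataFrame:
    """Tab-friendly detail table (1-based inclusive coordinates)."""
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "span_bp": r.span_bp,
                "n_sites": r.n_sites,
                "n_het_absorbed": r.n_het_absorbed,
            }
            for r in runs
        ],
        columns=["chrom", "start_bp", "end_bp", "span_bp", "n_sites", "n_het_absorbed"],
    )


def runs_to_bed(runs: list[ROHRun]) -> pd.DataFrame:
    """BED representation: 0-based half-open intervals."""
    return pd.DataFrame(
        [
            {"chrom": r.chrom, "start": r.start_bp - 1, "end": r.end_bp}
            for r in runs
        ],
        columns=["chrom", "start", "end"],
    )
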