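"""Per-chromosome uniparental-disomy calling.

Evidence from three sources is combined per chromosome:

* trio site classes — counts of maternal- versus paternal-UPD-informative
  sites, split by whether the site falls inside a child ROH run;
* ROH runs for all three samples — the child's runs carry the isodisomy
  signal, parental runs at the same position flag autozygosity/consanguinity
  as the alternative explanation;
* allele matching — for each child ROH run, the fraction of the child's
  homozygous alleles carried by each parent ("identical to the mother"
  reads as a maternal match fraction of ~1), and, outside the runs, the
  observed-versus-expected rate of *obligate* other-parent alleles (sites
  where the child carries an allele one parent lacks, which must have come
  from the other parent — the signature of genuine biparental inheritance).

A call is emitted for a chromosome only when four gates all pass: enough
informative sites, near-unanimous laterality toward one parent, a high
parent-match fraction inside every child ROH run, and no majority overlap of
child runs by parental runs. The mode is isodisomy (ROH carries essentially
all the signal and spans the chromosome), heterodisomy (laterality without
ROH), segmental (signal confined to ROH with a demonstrably biparental
remainder), or mixed otherwise. Nomenclature follows the upd(<chrom>)mat /
upd(<chrom>)pat convention.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .classify import (
    MATERNAL_INFORMATIVE,
    MENDELIAN_INCONSISTENT,
    PATERNAL_INFORMATIVE,
    TrioSiteClass,
)
from .containers import HET, HOM_ALT, HOM_REF, MISSING, TrioGenotypeSet
from .roh import ROHRun


@dataclass(frozen=True)
class UPDCallConfig:
    min_informative: int = 10
    laterality_ratio: float = 0.95
    match_threshold: float = 0.98
    biparental_threshold: float = 0.5
    error_concentration_factor: float = 5.0
    iso_informative_fraction: float = 0.9
    iso_chrom_coverage: float = 0.9
    parental_overlap_max: float = 0.5

    def __post_init__(self) -> None:
        if self.min_informative < 1:
            raise ValueError("min_informative must be >= 1")
        for name in (
            "laterality_ratio",
            "match_threshold",
            "biparental_threshold",
            "iso_informative_fraction",
            "iso_chrom_coverage",
        ):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")


DEFAULT_CALL_CONFIG = UPDCallConfig()


@dataclass
class RunMatch:
    """Parent allele-match fractions for one child ROH run."""

    run: ROHRun
    mother_match: float
    father_match: float
    n_used: int


@dataclass
class EvidenceSummary:
    """Everything the caller looks at for one chromosome."""

    chrom: str
    n_sites: int
    mat_inside: int
    mat_outside: int
    pat_inside: int
    pat_outside: int
    child_runs: list[ROHRun] = field(default_factory=list)
    mother_runs: list[ROHRun] = field(default_factory=list)
    father_runs: list[ROHRun] = field(default_factory=list)
    run_matches: list[RunMatch] = field(default_factory=list)
    # obligate other-parent evidence outside child ROH: observed and expected
    obligate_father_outside: tuple[float, float] = (0.0, 0.0)
    obligate_mother_outside: tuple[float, float] = (0.0, 0.0)
    me_rate_chrom: float = 0.0
    me_rate_background: float = 0.0
    chrom_length: int | None = None

    @property
    def n_mat(self) -> int:
        return self.mat_inside + self.mat_outside

    @property
    def n_pat(self) -> int:
        return self.pat_inside + self.pat_outside

    @property
    def me_concentration(self) -> float:
        if self.me_rate_background == 0:
            return float("inf") if self.me_rate_chrom > 0 else 1.0
        return self.me_rate_chrom / self.me_rate_background


@dataclass
class UPDCall:
    chrom: str
    parent_of_origin: str  # "maternal" | "paternal"
    mode: str  # "isodisomy" | "heterodisomy" | "segmental" | "mixed"
    segments: list[ROHRun]
    evidence: EvidenceSummary
    error_concentration_ok: bool = True

    @property
    def nomenclature(self) -> str:
        return format_upd_nomenclature(self)


def format_upd_nomenclature(call: UPDCall) -> str:
    suffix = "mat" if call.parent_of_origin == "maternal" else "pat"
    return f"upd({call.chrom}){suffix}"


def parse_upd_nomenclature(s: str) -> tuple[str, str]:
    """Inverse of :func:`format_upd_nomenclature`: returns (chrom, parent)."""
    m = re.fullmatch(r"upd\((?P<chrom>[^)]+)\)(?P<p>mat|pat)", s)
    if not m:
        raise ValueError(f"unparseable UPD nomenclature {s!r}")
    return m.group("chrom"), "maternal" if m.group("p") == "mat" else "paternal"


def match_roh_to_parent(
    child_gts: np.ndarray,
    parent_gts: np.ndarray,
    positions: np.ndarray,
    run: ROHRun,
) -> float:
    """Fraction of the run's child-homozygous sites whose allele the parent
    carries. Sites missing in child or parent are excluded; an empty run after
    exclusion is an error."""
    inside = run.contains(positions)
    c = np.asarray(child_gts)[inside]
    p = np.asarray(parent_gts)[inside]
    usable = (c != MISSING) & (c != HET) & (p != MISSING)
    c, p = c[usable], p[usable]
    if len(c) == 0:
        raise ValueError("no usable homozygous child sites in run")
    carries = np.where(c == HOM_REF, p <= HET, p >= HET)
    return float(np.mean(carries))


def _obligate_other_parent(
    gc: np.ndarray, g_this: np.ndarray, g_other: np.ndarray
) -> tuple[float, float]:
    """Observed and expected counts of sites where the child carries an allele
    ``g_this`` (the putative UPD parent) lacks — evidence that the other
    parent did transmit.

    Expected counts assume Mendelian biparental transmission given both
    parental genotypes; only complete trio sites contribute.
    """
    ok = (gc != MISSING) & (g_this != MISSING) & (g_other != MISSING)
    gc, g_this, g_other = gc[ok], g_this[ok], g_other[ok]
    lacks_alt = g_this == HOM_REF
    lacks_ref = g_this == HOM_ALT
    observed = float(np.sum(lacks_alt & (gc >= HET)) + np.sum(lacks_ref & (gc <= HET)))
    # P(other parent transmits the allele this parent lacks) = dosage/2
    expected = float(
        np.sum(g_other[lacks_alt] / 2.0) + np.sum((2 - g_other[lacks_ref]) / 2.0)
    )
    return observed, expected


def _overlap_bp(run: ROHRun, others: list[ROHRun]) -> int:
    total = 0
    for o in others:
        if o.chrom != run.chrom:
            continue
        lo = max(run.start_bp, o.start_bp)
        hi = min(run.end_bp, o.end_bp)
        if hi >= lo:
            total += hi - lo + 1
    return total


def summarize_evidence(
    trio: TrioGenotypeSet,
    class_codes: np.ndarray,
    child_runs: list[ROHRun],
    mother_runs: list[ROHRun],
    father_runs: list[ROHRun],
    chrom_lengths: dict[str, int] | None = None,
) -> dict[str, EvidenceSummary]:
    """Assemble the per-chromosome evidence the UPD caller consumes."""
    if len(class_codes) != trio.n_sites:
        raise ValueError("class vector does not match the trio site frame")
    codes = np.asarray(class_codes)
    gc = trio.gt("child")
    gm = trio.gt("mother")
    gf = trio.gt("father")
    pos_all = trio.sites["pos"].to_numpy()

    mat_codes = np.isin(codes, [int(c) for c in MATERNAL_INFORMATIVE])
    pat_codes = np.isin(codes, [int(c) for c in PATERNAL_INFORMATIVE])
    incons = np.isin(codes, [int(c) for c in MENDELIAN_INCONSISTENT])
    classified = codes != int(TrioSiteClass.MISSING)

    out: dict[str, EvidenceSummary] = {}
    for chrom in trio.chroms:
        mask = trio.chrom_mask(chrom)
        pos = pos_all[mask]
        runs_c = [r for r in child_runs if r.chrom == chrom]
        inside = np.zeros(len(pos), dtype=bool)
        for r in runs_c:
            inside |= r.contains(pos)

        n_cl_chrom = int(classified[mask].sum())
        n_cl_rest = int(classified.sum()) - n_cl_chrom
        me_chrom = int(incons[mask].sum()) / n_cl_chrom if n_cl_chrom else 0.0
        me_rest = (int(incons.sum()) - int(incons[mask].sum())) / n_cl_rest if n_cl_rest else 0.0

        run_matches = []
        for r in runs_c:
            run_matches.append(
                RunMatch(
                    run=r,
                    mother_match=match_roh_to_parent(gc[mask], gm[mask], pos, r),
                    father_match=match_roh_to_parent(gc[mask], gf[mask], pos, r),
                    n_used=int(
                        np.sum(r.contains(pos) & (gc[mask] != MISSING) & (gc[mask] != HET))
                    ),
                )
            )

        outside = ~inside
        obl_f = _obligate_other_parent(gc[mask][outside], gm[mask][outside], gf[mask][outside])
        obl_m = _obligate_other_parent(gc[mask][outside], gf[mask][outside], gm[mask][outside])

        out[chrom] = EvidenceSummary(
            chrom=str(chrom),
            n_sites=int(mask.sum()),
            mat_inside=int(np.sum(mat_codes[mask] & inside)),
            mat_outside=int(np.sum(mat_codes[mask] & outside)),
            pat_inside=int(np.sum(pat_codes[mask] & inside)),
            pat_outside=int(np.sum(pat_codes[mask] & outside)),
            child_runs=runs_c,
            mother_runs=[r for r in mother_runs if r.chrom == chrom],
            father_runs=[r for r in father_runs if r.chrom == chrom],
            run_matches=run_matches,
            obligate_father_outside=obl_f,
            obligate_mother_outside=obl_m,
            me_rate_chrom=me_chrom,
            me_rate_background=me_rest,
            chrom_length=(chrom_lengths or {}).get(chrom),
        )
    return out


def call_upd(
    evidence: EvidenceSummary, config: UPDCallConfig = DEFAULT_CALL_CONFIG
) -> UPDCall | None:
    """Apply the four decision gates to one chromosome's evidence; returns a
    call or ``None`` (no-call is a value, not an error)."""
    n_mat, n_pat = evidence.n_mat, evidence.n_pat
    if n_mat >= n_pat:
        parent, n_win, n_tot = "maternal", n_mat, n_mat + n_pat
    else:
        parent, n_win, n_tot = "paternal", n_pat, n_mat + n_pat

    # gate (a): enough informative sites for the winning parent
    if n_win < config.min_informative:
        return None
    # gate (b): near-unanimous laterality
    if n_win / n_tot < config.laterality_ratio:
        return None
    # gate (c): inside every child ROH run the winning parent carries the
    # child's homozygous allele at nearly every site
    for rm in evidence.run_matches:
        match = rm.mother_match if parent == "maternal" else rm.father_match
        if match < config.match_threshold:
            return None
    # gate (d): consanguinity/autozygosity guard — child runs must not be
    # majority-overlapped by runs in either parent
    parental = evidence.mother_runs + evidence.father_runs
    for r in evidence.child_runs:
        if r.span_bp and _overlap_bp(r, parental) / r.span_bp > config.parental_overlap_max:
            return None

    mode = _assign_mode(evidence, parent, n_win, config)
    return UPDCall(
        chrom=evidence.chrom,
        parent_of_origin=parent,
        mode=mode,
        segments=list(evidence.child_runs),
        evidence=evidence,
        error_concentration_ok=(
            evidence.me_concentration >= config.error_concentration_factor
        ),
    )


def _assign_mode(
    evidence: EvidenceSummary, parent: str, n_win: int, config: UPDCallConfig
) -> str:
    if not evidence.child_runs:
        return "heterodisomy"
    inside = evidence.mat_inside if parent == "maternal" else evidence.pat_inside
    frac_in_roh = inside / n_win if n_win else 0.0
    if evidence.chrom_length:
        coverage = sum(r.span_bp for r in evidence.child_runs) / evidence.chrom_length
    else:
        coverage = 1.0  # unknown length: treat ROH as chromosome-wide
    if frac_in_roh >= config.iso_informative_fraction:
        obs, exp = (
            evidence.obligate_father_outside
            if parent == "maternal"
            else evidence.obligate_mother_outside
        )
        biparental_outside = exp >= 1.0 and (obs / exp) >= config.biparental_threshold
        if biparental_outside and coverage < config.iso_chrom_coverage:
            return "segmental"
        return "isodisomy"
    return "mixed"


def call_all(
    evidence: dict[str, EvidenceSummary],
    config: UPDCallConfig = DEFAULT_CALL_CONFIG,
) -> list[UPDCall]:
    calls = []
    for chrom in evidence:
        call = call_upd(evidence[chrom], config)
        if call is not None:
            calls.append(call)
    return calls
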