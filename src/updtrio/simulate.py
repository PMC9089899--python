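"""Synthetic trio genotype generator with implantable uniparental disomy.

The generator builds a trio from first principles so that every downstream
inference stage has exact ground truth to recover:

1. biallelic SNV sites are scattered over GRCh-like autosomes, each with a
   population alternate-allele frequency drawn from a configurable range;
2. parental haplotypes are independent Bernoulli draws at those frequencies,
   which puts parental genotypes in Hardy-Weinberg proportions;
3. the child receives one maternal and one paternal haplotype per chromosome
   (optionally with Poisson-distributed crossovers), and the full transmission
   record is retained;
4. uniparental-disomy segments — isodisomy (two copies of a single parental
   homolog, hence a run of homozygosity) or heterodisomy (both homologs of one
   parent, hence genotypes identical to that parent) — are implanted over the
   biparental background;
5. genotypes are read off the haplotypes and optionally perturbed with a
   symmetric genotyping-error model and a missingness mask.

Every step consumes an independent substream spawned from the one config seed,
so output is bit-identical for a fixed configuration.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import TRIO_SAMPLES, TrioGenotypeSet, validate_sites

#: GRCh38-like autosome lengths used by default (bp)
DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    "1": 248_956_422,
    "2": 242_193_529,
    "3": 198_295_559,
    "6": 170_805_979,
}

_BASES = np.array(list("ACGT"))

# transmission-source codes: which parental homolog each child haplotype copies
SRC_M0, SRC_M1, SRC_F0, SRC_F1 = 0, 1, 2, 3


@dataclass(frozen=True)
class SiteSpec:
    """A single biallelic SNV site with its population alternate-allele
    frequency. Used for explicit single-site construction; bulk site sets are
    carried as a DataFrame with the same fields."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    alt_freq: float

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based coordinates)")
        if not 0.0 < self.alt_freq < 1.0:
            raise ValueError("alt_freq must lie strictly inside (0, 1)")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class TrioSimConfig:
    """Configuration of the trio simulator.

    Defaults target a small exome-like fixture: a handful of long autosomes
    with a few thousand sites each, allele frequencies uniform on (0.05, 0.5)
    so most sites are informative, no recombination, and clean genotypes.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHROM_LENGTHS)
    )
    sites_per_chrom: int = 3000
    alt_freq_range: tuple[float, float] = (0.05, 0.5)
    recombination: bool = False
    crossovers_per_chrom: float = 1.0
    error_rate: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.alt_freq_range = tuple(self.alt_freq_range)  # YAML yields lists
        if not self.chrom_lengths:
            raise ValueError("at least one chromosome is required")
        for c, length in self.chrom_lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {c!r} has non-positive length")
        if self.sites_per_chrom <= 0:
            raise ValueError("sites_per_chrom must be positive")
        lo, hi = self.alt_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("alt_freq_range must satisfy 0 < low <= high < 1")
        for name in ("error_rate", "missing_rate"):
            r = getattr(self, name)
            if not 0.0 <= r < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.crossovers_per_chrom < 0:
            raise ValueError("crossovers_per_chrom must be non-negative")


@dataclass
class UPDSegmentSpec:
    """Ground-truth uniparental-disomy segment to implant in the child.

    ``mode='isodisomy'`` copies homolog ``source_homolog`` (1 or 2) of
    ``parent`` into both child haplotypes — homozygous across the segment.
    ``mode='heterodisomy'`` copies both homologs of ``parent`` — the child's
    genotype equals that parent's genotype across the segment.
    """

    chrom: str
    start_bp: int
    end_bp: int
    parent: str  # "mother" | "father"
    mode: str  # "isodisomy" | "heterodisomy"
    source_homolog: int = 1

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")
        if self.parent not in ("mother", "father"):
            raise ValueError("parent must be 'mother' or 'father'")
        if self.mode not in ("isodisomy", "heterodisomy"):
            raise ValueError("mode must be 'isodisomy' or 'heterodisomy'")
        if self.source_homolog not in (1, 2):
            raise ValueError("source_homolog must be 1 or 2")

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class ParentalGenome:
    """Two haplotypes per chromosome for one individual.

    ``haplotypes[chrom]`` is a ``(2, n_sites_on_chrom)`` int8 array of alleles
    (0 = ref, 1 = alt) aligned with the site table."""

    label: str
    haplotypes: dict[str, np.ndarray]

    def genotype_codes(self, chrom: str) -> np.ndarray:
        h = self.haplotypes[chrom]
        return (h[0] + h[1]).astype(np.int8)

    def copy(self) -> "ParentalGenome":
        return ParentalGenome(
            self.label, {c: h.copy() for c, h in self.haplotypes.items()}
        )


@dataclass
class SimulatedTrio:
    """A complete simulated trio: sites, haplotype-level genomes, the emitted
    genotype set, the transmission record and the implanted UPD ground truth."""

    config: TrioSimConfig
    sites: pd.DataFrame
    mother: ParentalGenome
    father: ParentalGenome
    child: ParentalGenome
    transmission: dict[str, np.ndarray]  # (2, n_sites) source codes per chrom
    upd_specs: tuple[UPDSegmentSpec, ...]
    clean_genotypes: np.ndarray  # (n_sites, 3) before error/missingness
    trio: TrioGenotypeSet


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def draw_sites(config: TrioSimConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the ordered site frame: ``chrom, pos, ref, alt, alt_freq``.

    Positions are distinct uniform integers in [1, chrom length]; alt-allele
    frequencies are uniform on ``config.alt_freq_range``.
    """
    if rng is None:
        rng = _spawn(config.seed, 4)[0]
    lo, hi = config.alt_freq_range
    frames = []
    for chrom, length in config.chrom_lengths.items():
        n = config.sites_per_chrom
        if n > length:
            raise ValueError(f"more sites than base pairs on chromosome {chrom!r}")
        pos = np.unique(rng.integers(1, length + 1, size=n + max(16, n // 10)))
        while len(pos) < n:  # top up after deduplication (rare for sparse sites)
            extra = rng.integers(1, length + 1, size=n)
            pos = np.unique(np.concatenate([pos, extra]))
        if len(pos) > n:
            pos = np.sort(rng.choice(pos, size=n, replace=False))
        ref_idx = rng.integers(0, 4, size=n)
        alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos.astype(np.int64),
                    "ref": _BASES[ref_idx],
                    "alt": _BASES[alt_idx],
                    "alt_freq": rng.uniform(lo, hi, size=n),
                }
            )
        )
    sites = pd.concat(frames, ignore_index=True)
    validate_sites(sites)
    if ((sites["alt_freq"] <= 0) | (sites["alt_freq"] >= 1)).any():
        raise ValueError("alt_freq must lie strictly inside (0, 1)")
    return sites


def simulate_parental_genomes(
    sites: pd.DataFrame, config: TrioSimConfig, rng: np.random.Generator | None = None
) -> tuple[ParentalGenome, ParentalGenome]:
    """Draw mother and father haplotypes independently site by site.

    Each haplotype allele is Bernoulli(alt_freq), which yields Hardy-Weinberg
    genotype proportions p^2 : 2pq : q^2 in each parent.
    """
    if rng is None:
        rng = _spawn(config.seed, 4)[1]
    genomes = []
    for label in ("mother", "father"):
        haps: dict[str, np.ndarray] = {}
        for chrom in config.chrom_lengths:
            f = sites.loc[sites["chrom"] == chrom, "alt_freq"].to_numpy()
            haps[chrom] = (rng.random((2, len(f))) < f).astype(np.int8)
        genomes.append(ParentalGenome(label, haps))
    return genomes[0], genomes[1]


def _transmit_one(
    positions: np.ndarray,
    length: int,
    config: TrioSimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Source-homolog index (0/1) per site for one transmitted haplotype."""
    start = int(rng.integers(0, 2))
    if not config.recombination:
        return np.full(len(positions), start, dtype=np.int8)
    n_x = rng.poisson(config.crossovers_per_chrom)
    if n_x == 0:
        return np.full(len(positions), start, dtype=np.int8)
    breaks = np.sort(rng.integers(1, length + 1, size=n_x))
    switches = np.searchsorted(breaks, positions, side="left")
    return ((start + switches) % 2).astype(np.int8)


def transmit_biparental(
    mother: ParentalGenome,
    father: ParentalGenome,
    sites: pd.DataFrame,
    config: TrioSimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[ParentalGenome, dict[str, np.ndarray]]:
    """Form the child genome: one maternal plus one paternal haplotype per
    chromosome, with optional crossovers, and record the source of every
    transmitted allele.

    Returns the child genome and a transmission record mapping chromosome to a
    ``(2, n_sites)`` array of source codes (0/1 = maternal homolog 1/2,
    2/3 = paternal homolog 1/2); row 0 is the maternally derived haplotype.
    """
    if set(mother.haplotypes) != set(father.haplotypes):
        raise ValueError("parents cover different chromosomes")
    if rng is None:
        rng = _spawn(config.seed, 4)[2]
    haps: dict[str, np.ndarray] = {}
    record: dict[str, np.ndarray] = {}
    for chrom in config.chrom_lengths:
        if mother.haplotypes[chrom].shape != father.haplotypes[chrom].shape:
            raise ValueError(f"parental site mismatch on chromosome {chrom!r}")
        positions = sites.loc[sites["chrom"] == chrom, "pos"].to_numpy()
        length = config.chrom_lengths[chrom]
        m_src = _transmit_one(positions, length, config, rng)
        f_src = _transmit_one(positions, length, config, rng)
        idx = np.arange(len(positions))
        hap_m = mother.haplotypes[chrom][m_src, idx]
        hap_f = father.haplotypes[chrom][f_src, idx]
        haps[chrom] = np.stack([hap_m, hap_f]).astype(np.int8)
        record[chrom] = np.stack([m_src, f_src + 2]).astype(np.int8)
    return ParentalGenome("child", haps), record


def apply_upd(
    child: ParentalGenome,
    mother: ParentalGenome,
    father: ParentalGenome,
    specs: tuple[UPDSegmentSpec, ...] | list[UPDSegmentSpec],
    sites: pd.DataFrame,
    transmission: dict[str, np.ndarray] | None = None,
) -> tuple[ParentalGenome, dict[str, np.ndarray] | None]:
    """Overwrite the child's haplotypes inside each UPD segment.

    Isodisomy places two copies of the designated parental homolog (the child
    is homozygous at every segment site); heterodisomy places both homologs of
    the designated parent (the child's genotype equals that parent's).
    Transmission codes are updated in step so the record always reconciles
    with the emitted haplotypes.
    """
    by_chrom: dict[str, list[UPDSegmentSpec]] = {}
    for s in specs:
        if s.chrom not in child.haplotypes:
            raise ValueError(f"UPD segment on unknown chromosome {s.chrom!r}")
        by_chrom.setdefault(s.chrom, []).append(s)
    for chrom, segs in by_chrom.items():
        segs.sort(key=lambda s: s.start_bp)
        for a, b in zip(segs, segs[1:]):
            if b.start_bp <= a.end_bp:
                raise ValueError(f"overlapping UPD segments on chromosome {chrom!r}")

    new_child = child.copy()
    new_record = (
        {c: r.copy() for c, r in transmission.items()} if transmission is not None else None
    )
    for chrom, segs in by_chrom.items():
        positions = sites.loc[sites["chrom"] == chrom, "pos"].to_numpy()
        for s in segs:
            mask = (positions >= s.start_bp) & (positions <= s.end_bp)
            donor = mother if s.parent == "mother" else father
            base = SRC_M0 if s.parent == "mother" else SRC_F0
            if s.mode == "isodisomy":
                h = s.source_homolog - 1
                allele = donor.haplotypes[chrom][h, mask]
                new_child.haplotypes[chrom][0, mask] = allele
                new_child.haplotypes[chrom][1, mask] = allele
                if new_record is not None:
                    new_record[chrom][:, mask] = base + h
            else:  # heterodisomy: both homologs of the one parent
                new_child.haplotypes[chrom][0, mask] = donor.haplotypes[chrom][0, mask]
                new_child.haplotypes[chrom][1, mask] = donor.haplotypes[chrom][1, mask]
                if new_record is not None:
                    new_record[chrom][0, mask] = base
                    new_record[chrom][1, mask] = base + 1
    return new_child, new_record


def genotype_with_error(
    genotypes: np.ndarray,
    error_rate: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Perturb clean genotype codes with the observation model.

    Each call is independently set missing with probability ``missing_rate``,
    otherwise replaced with probability ``error_rate`` by one of the two other
    non-missing genotypes, chosen uniformly.
    """
    for name, r in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not 0.0 <= r < 1.0:
            raise ValueError(f"{name} must lie in [0, 1)")
    out = np.asarray(genotypes, dtype=np.int8).copy()
    u = rng.random(out.shape)
    # offsets drawn for every cell to keep the stream layout config-independent
    offsets = rng.integers(1, 3, size=out.shape)
    err = (u < error_rate) & (out >= 0)
    out[err] = (out[err] + offsets[err]) % 3
    miss = (u >= error_rate) & (u < error_rate + missing_rate)
    out[miss] = -1
    return out


def _stack_trio_genotypes(
    sites: pd.DataFrame,
    child: ParentalGenome,
    mother: ParentalGenome,
    father: ParentalGenome,
) -> np.ndarray:
    cols = []
    for g in (child, mother, father):
        cols.append(np.concatenate([g.genotype_codes(c) for c in _chrom_order(sites)]))
    return np.stack(cols, axis=1).astype(np.int8)


def _chrom_order(sites: pd.DataFrame) -> list:
    order: list = []
    for c in sites["chrom"]:
        if not order or order[-1] != c:
            order.append(c)
    return order


def simulate_trio(
    config: TrioSimConfig,
    upd_specs: tuple[UPDSegmentSpec, ...] | list[UPDSegmentSpec] = (),
) -> SimulatedTrio:
    """Run the full generator: sites, parents, transmission, UPD overrides,
    and the observed trio genotype set. Deterministic for a fixed config."""
    rngs = _spawn(config.seed, 4)
    sites = draw_sites(config, rngs[0])
    mother, father = simulate_parental_genomes(sites, config, rngs[1])
    child, record = transmit_biparental(mother, father, sites, config, rngs[2])
    if upd_specs:
        child, record = apply_upd(child, mother, father, upd_specs, sites, record)
    clean = _stack_trio_genotypes(sites, child, mother, father)
    observed = genotype_with_error(clean, config.error_rate, config.missing_rate, rngs[3])
    trio = TrioGenotypeSet(sites[["chrom", "pos", "ref", "alt"]].copy(), observed, TRIO_SAMPLES)
    return SimulatedTrio(
        config=config,
        sites=sites,
        mother=mother,
        father=father,
        child=child,
        transmission=record,
        upd_specs=tuple(upd_specs),
        clean_genotypes=clean,
        trio=trio,
    )


def reconstruct_from_transmission(sim: SimulatedTrio) -> np.ndarray:
    """Rebuild the child's clean genotypes from the transmission record and the
    parental haplotypes — ground-truth reconciliation for tests and audits."""
    out = []
    for chrom in _chrom_order(sim.sites):
        rec = sim.transmission[chrom]
        n = rec.shape[1]
        idx = np.arange(n)
        alleles = np.zeros((2, n), dtype=np.int8)
        for row in (0, 1):
            src = rec[row]
            from_mother = src < 2
            alleles[row, from_mother] = sim.mother.haplotypes[chrom][
                src[from_mother], idx[from_mother]
            ]
            alleles[row, ~from_mother] = sim.father.haplotypes[chrom][
                src[~from_mother] - 2, idx[~from_mother]
            ]
        out.append(alleles.sum(axis=0).astype(np.int8))
    return np.concatenate(out)


def duo_config(config: TrioSimConfig | None = None, **overrides) -> TrioSimConfig:
    """Convenience: a config for duo-style studies (the duo is just a trio from
    which one pair of samples is read)."""
    base = config or TrioSimConfig()
    return replace(base, **overrides)
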