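"""Model/results surface for trio uniparental-disomy analysis.

:class:`TrioUPDModel` is built from a trio genotype set (from a VCF, a
simulation, or a prepared :class:`~updtrio.containers.TrioGenotypeSet`) and
holds the analysis configuration; ``fit()`` runs kinship estimation,
per-site inheritance classification, ROH screening and UPD calling, and
returns a :class:`TrioUPDResults` carrying the estimates, their
uncertainties and diagnostics, with a ``summary()`` table and a
per-chromosome evidence plot.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import TrioClassCounts, classify_all, mendelian_error_rate
from .containers import HET, MISSING, TrioGenotypeSet
from .kinship import (
    DEFAULT_THRESHOLDS,
    DegreeThresholds,
    classify_degree,
    count_pair_genotypes,
    estimate_kinship,
    jackknife_se,
)
from .roh import DEFAULT_ROH_CONFIG, ROHConfig, detect_roh, runs_to_frame
from .upd import DEFAULT_CALL_CONFIG, UPDCall, UPDCallConfig, call_all, summarize_evidence


class TrioUPDModel:
    """Trio UPD analysis model.

    Parameters
    ----------
    trio : TrioGenotypeSet
        Child/mother/father genotypes over ordered biallelic sites.
    chrom_lengths : dict, optional
        Physical chromosome lengths (bp); used for ROH coverage and mode
        assignment. When omitted, the last site position stands in.
    roh_config, call_config, degree_thresholds : optional
        Stage configurations; defaults follow the package-wide screening
        conventions (ROH span strictly above 4 Mb, first-degree kinship in
        (0.177, 0.354], four UPD gates).
    """

    def __init__(
        self,
        trio: TrioGenotypeSet,
        chrom_lengths: dict[str, int] | None = None,
        roh_config: ROHConfig = DEFAULT_ROH_CONFIG,
        call_config: UPDCallConfig = DEFAULT_CALL_CONFIG,
        degree_thresholds: DegreeThresholds = DEFAULT_THRESHOLDS,
    ) -> None:
        self.trio = trio
        self.chrom_lengths = chrom_lengths
        self.roh_config = roh_config
        self.call_config = call_config
        self.degree_thresholds = degree_thresholds

    @classmethod
    def from_vcf(cls, path, **kwargs) -> "TrioUPDModel":
        from .vcfio import read_trio_vcf

        return cls(read_trio_vcf(path), **kwargs)

    @classmethod
    def from_simulation(cls, sim_config, upd_segments=(), **kwargs) -> "TrioUPDModel":
        from .simulate import simulate_trio

        sim = simulate_trio(sim_config, upd_segments)
        kwargs.setdefault("chrom_lengths", dict(sim_config.chrom_lengths))
        model = cls(sim.trio, **kwargs)
        model._sim = sim
        return model

    def fit(self) -> "TrioUPDResults":
        """Run every inference stage and assemble the results object."""
        trio = self.trio
        rows = []
        from itertools import combinations

        for i, j in combinations(range(3), 2):
            gi, gj = trio.genotypes[:, i], trio.genotypes[:, j]
            est = estimate_kinship(count_pair_genotypes(gi, gj))
            rows.append(
                {
                    "sample_i": trio.samples[i],
                    "sample_j": trio.samples[j],
                    "n_used": est.counts.n_used,
                    "phi": est.phi,
                    "phi_se": jackknife_se(gi, gj),
                    "degree": classify_degree(est.phi, self.degree_thresholds),
                }
            )
        kinship = pd.DataFrame(rows)

        codes, counts = classify_all(trio)
        me_chrom, me_genome = mendelian_error_rate(counts)
        roh = {s: detect_roh(trio.sites, trio.gt(s), self.roh_config) for s in trio.samples}
        child, mother, father = trio.samples
        evidence = summarize_evidence(
            trio, codes, roh[child], roh[mother], roh[father], self.chrom_lengths
        )
        calls = call_all(evidence, self.call_config)
        return TrioUPDResults(
            model=self,
            kinship=kinship,
            class_codes=codes,
            class_counts=counts,
            me_rate_per_chrom=me_chrom,
            me_rate_genome=me_genome,
            roh=roh,
            evidence=evidence,
            upd_calls=calls,
        )


@dataclass
class TrioUPDResults:
    """Fitted results: kinship estimates with jackknife standard errors,
    per-chromosome class counts and Mendelian-inconsistency rates, ROH runs
    per sample, the assembled evidence, and the UPD calls."""

    model: TrioUPDModel
    kinship: pd.DataFrame
    class_codes: np.ndarray
    class_counts: TrioClassCounts
    me_rate_per_chrom: pd.Series
    me_rate_genome: float
    roh: dict[str, list]
    evidence: dict
    upd_calls: list[UPDCall] = field(default_factory=list)

    def summary(self) -> str:
        """Human-readable summary table in the statsmodels tradition."""
        trio = self.model.trio
        width = 78
        lines = [
            "Trio UPD Analysis Results".center(width),
            "=" * width,
            f"No. sites: {trio.n_sites:>10}    Chromosomes: {len(trio.chroms)}"
            f"    Mendelian-inconsistency rate: {self.me_rate_genome:.5f}",
            "-" * width,
            "Kinship (within-family estimator)",
        ]
        frame = self.kinship.copy()
        frame["phi"] = frame["phi"].map(lambda v: f"{v:.4f}")
        frame["phi_se"] = frame["phi_se"].map(lambda v: f"{v:.4f}")
        lines += [frame.to_string(index=False), "-" * width, "Runs of homozygosity"]
        for sample, runs in self.roh.items():
            if runs:
                detail = ", ".join(
                    f"{r.chrom}:{r.start_bp}-{r.end_bp} ({r.span_bp/1e6:.1f} Mb)"
                    for r in runs
                )
            else:
                detail = "none"
            lines.append(f"  {sample:<8} {detail}")
        lines += ["-" * width, "UPD calls"]
        if self.upd_calls:
            for c in self.upd_calls:
                lines.append(
                    f"  {c.nomenclature:<12} mode={c.mode:<12} "
                    f"informative mat/pat = {c.evidence.n_mat}/{c.evidence.n_pat}  "
                    f"segments={len(c.segments)}"
                )
        else:
            lines.append("  none")
        lines.append("=" * width)
        return "\n".join(lines)

    def plot_chromosome(self, chrom, ax=None):
        """Plot child heterozygosity along one chromosome with detected child
        ROH runs shaded and implanted/called segments annotated."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 2.5))
        trio = self.model.trio
        mask = trio.chrom_mask(chrom)
        pos = trio.sites.loc[mask, "pos"].to_numpy() / 1e6
        gc = trio.gt("child")[mask]
        called = gc != MISSING
        ax.scatter(
            pos[called], (gc[called] == HET).astype(float),
            s=2, alpha=0.4, color="0.3", label="child het (1) / hom (0)",
        )
        for r in self.roh.get(trio.samples[0], []):
            if r.chrom == chrom:
                ax.axvspan(r.start_bp / 1e6, r.end_bp / 1e6, color="tab:blue", alpha=0.25)
        for c in self.upd_calls:
            if c.chrom == str(chrom):
                ax.set_title(f"{c.nomenclature} ({c.mode})")
        ax.set_xlabel(f"chromosome {chrom} position (Mb)")
        ax.set_ylabel("heterozygous")
        ax.set_ylim(-0.15, 1.15)
        return ax
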