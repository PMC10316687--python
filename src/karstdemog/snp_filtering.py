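"""Stacks `populations`-style locus/SNP filters.

The filters mirror the command-line options used to produce reduced-
representation SNP panels: a per-population presence requirement (-p/-r),
a pooled minor-allele-frequency floor (--min-maf), a pooled observed-
heterozygosity ceiling (--max-obs-het) and first-SNP-per-locus thinning
(--write-single-snp).  Each step returns a fresh matrix plus a
:class:`FilterReport` entry so counts are conserved and auditable.

Fixed application order for the full chain: presence → single-SNP →
MAF → heterozygosity (presence is a locus-level test; the per-SNP tests
follow, as `populations` applies them after locus selection).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap


@dataclass
class FilterConfig:
    """Thresholds for the standard filter chain."""

    min_populations: int = 1  # -p
    percent_samples: float = 0.0  # -r, fraction of samples per population
    min_maf: float = 0.0
    max_obs_het: float = 1.0
    single_snp_per_locus: bool = False

    def __post_init__(self):
        if not 0.0 <= self.percent_samples <= 1.0:
            raise ValueError("percent_samples (r) must be in [0, 1]")
        if not 0.0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if not 0.0 <= self.max_obs_het <= 1.0:
            raise ValueError("max_obs_het must be in [0, 1]")
        if self.min_populations < 1:
            raise ValueError("min_populations (p) must be >= 1")


@dataclass
class FilterStep:
    name: str
    n_in: int
    n_retained: int

    @property
    def n_removed(self) -> int:
        return self.n_in - self.n_retained


@dataclass
class FilterReport:
    steps: list[FilterStep] = field(default_factory=list)

    def add(self, name: str, n_in: int, n_retained: int) -> None:
        self.steps.append(FilterStep(name, n_in, n_retained))

    def extend(self, other: "FilterReport") -> None:
        self.steps.extend(other.steps)

    def to_dict(self) -> list[dict]:
        return [
            {
                "filter": s.name,
                "in": s.n_in,
                "retained": s.n_retained,
                "removed": s.n_removed,
            }
            for s in self.steps
        ]


def filter_presence(
    gm: GenotypeMatrix, popmap: PopulationMap, p: int, r: float
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep SNPs genotyped in ≥ ``r`` of samples in each of ≥ ``p`` populations.

    Ties at exactly ``r`` count as present (the test is ≥).
    """
    pops = popmap.populations
    if p > len(pops):
        raise ValueError(f"p={p} exceeds population count {len(pops)}")
    present = np.zeros(gm.n_loci, dtype=int)
    for pop in pops:
        idx = gm.sample_indices(popmap.samples_in_pop(pop))
        called = (gm.calls[idx, :] != MISSING).sum(axis=0)
        # strict fraction comparison with a tolerance-free rational test:
        # called / n >= r  <=>  called >= r * n (floating point is fine here
        # because r*n is exact for the r values in use; use a tiny epsilon
        # to guard against representation error like 0.8*5 = 4.000000001)
        ok = called >= r * len(idx) - 1e-9
        present += ok.astype(int)
    keep = present >= p
    report = FilterReport()
    report.add(f"presence(p={p},r={r})", gm.n_loci, int(keep.sum()))
    return gm.subset_loci(keep), report


def _maf(gm: GenotypeMatrix) -> np.ndarray:
    calls = gm.calls
    obs = calls != MISSING
    alt = np.where(obs, calls, 0).sum(axis=0)
    genes = 2 * obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(genes > 0, alt / np.maximum(genes, 1), 0.0)
    return np.minimum(freq, 1.0 - freq)


def filter_maf(
    gm: GenotypeMatrix, min_maf: float
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep SNPs whose pooled minor-allele frequency is ≥ ``min_maf``."""
    keep = _maf(gm) >= min_maf - 1e-12
    report = FilterReport()
    report.add(f"maf(min={min_maf})", gm.n_loci, int(keep.sum()))
    return gm.subset_loci(keep), report


def _obs_het(gm: GenotypeMatrix) -> np.ndarray:
    calls = gm.calls
    obs = calls != MISSING
    het = (calls == 1).sum(axis=0)
    n = obs.sum(axis=0)
    return np.where(n > 0, het / np.maximum(n, 1), 0.0)


def filter_obs_het(
    gm: GenotypeMatrix, max_obs_het: float
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep SNPs whose pooled observed heterozygosity is ≤ ``max_obs_het``."""
    keep = _obs_het(gm) <= max_obs_het + 1e-12
    report = FilterReport()
    report.add(f"obs_het(max={max_obs_het})", gm.n_loci, int(keep.sum()))
    return gm.subset_loci(keep), report


def first_snp_per_locus(gm: GenotypeMatrix) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep, per stack, only the SNP with the smallest within-stack index."""
    best: dict[str, int] = {}
    for j, rec in enumerate(gm.loci):
        cur = best.get(rec.locus_id)
        if cur is None or rec.site_index < gm.loci[cur].site_index:
            best[rec.locus_id] = j
    keep = np.zeros(gm.n_loci, dtype=bool)
    keep[list(best.values())] = True
    report = FilterReport()
    report.add("single_snp_per_locus", gm.n_loci, int(keep.sum()))
    return gm.subset_loci(keep), report


def apply_filters(
    gm: GenotypeMatrix, popmap: PopulationMap, cfg: FilterConfig
) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the full chain: presence → single-SNP → MAF → heterozygosity."""
    report = FilterReport()
    gm, rep = filter_presence(gm, popmap, cfg.min_populations, cfg.percent_samples)
    report.extend(rep)
    if cfg.single_snp_per_locus:
        gm, rep = first_snp_per_locus(gm)
        report.extend(rep)
    gm, rep = filter_maf(gm, cfg.min_maf)
    report.extend(rep)
    gm, rep = filter_obs_het(gm, cfg.max_obs_het)
    report.extend(rep)
    return gm, report
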