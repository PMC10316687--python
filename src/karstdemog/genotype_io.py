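"""Genotype matrix I/O and the sample → population → cluster hierarchy.

The in-memory substrate for the whole pipeline is a dense matrix of diploid
SNP genotypes coded as alternate-allele counts (0, 1, 2) with ``MISSING``
(−1) for no-calls.  VCF 4.2 with a GT-only FORMAT field is the interchange
format; a two/three-column whitespace-delimited popmap carries the sample
assignments and optional population coordinates.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

import numpy as np
from cyvcf2 import VCF

log = logging.getLogger(__name__)

#: sentinel for a missing diploid genotype
MISSING: int = -1


@dataclass(frozen=True)
class LocusRecord:
    """A single SNP: which stack (locus) it sits on and where.

    ``site_index`` is the 0-based position of the SNP within the stack;
    ``chrom``/``pos`` keep the original VCF coordinates for round-trips.
    """

    locus_id: str
    site_index: int
    ref_allele: str = "A"
    alt_allele: str = "T"
    chrom: str | None = None
    pos: int | None = None

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"locus {self.locus_id}: ref and alt alleles must differ"
            )


@dataclass
class PopulationMap:
    """Sample → population and population → cluster assignments.

    Clusters are symbolic labels (the study design uses exactly two, "I"
    and "II"); more are tolerated for diversity statistics but rejected by
    the demographic-fitting layer.  ``coords`` maps population →
    (lat, lon) in decimal degrees when isolation-by-distance is wanted.
    """

    sample_to_pop: dict[str, str]
    pop_to_cluster: dict[str, str]
    coords: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        missing = {p for p in self.sample_to_pop.values()} - set(self.pop_to_cluster)
        if missing:
            raise ValueError(f"populations without a cluster: {sorted(missing)}")

    @property
    def populations(self) -> list[str]:
        return sorted(self.pop_to_cluster)

    @property
    def clusters(self) -> list[str]:
        return sorted(set(self.pop_to_cluster.values()))

    def samples_in_pop(self, pop: str) -> list[str]:
        return [s for s, p in self.sample_to_pop.items() if p == pop]

    def samples_in_cluster(self, cluster: str) -> list[str]:
        return [
            s
            for s, p in self.sample_to_pop.items()
            if self.pop_to_cluster[p] == cluster
        ]

    def cluster_of_sample(self, sample: str) -> str:
        return self.pop_to_cluster[self.sample_to_pop[sample]]


@dataclass
class GenotypeMatrix:
    """Dense diploid genotype calls, samples × loci.

    ``calls[i, j]`` is the alternate-allele count of sample ``i`` at SNP
    ``j`` (0, 1, 2) or :data:`MISSING`.  ``total_sites`` optionally carries
    the number of sequenced sites (monomorphic + variant) the SNPs were
    extracted from, which downstream likelihoods need for absolute scaling.
    """

    samples: list[str]
    loci: list[LocusRecord]
    calls: np.ndarray
    total_sites: int | None = None
    ploidy: int = 2

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.loci)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.loci)})"
            )
        bad = ~np.isin(self.calls, (MISSING, 0, 1, 2))
        if bad.any():
            raise ValueError(f"invalid genotype codes: {np.unique(self.calls[bad])}")
        keys = [(l.locus_id, l.site_index) for l in self.loci]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (locus_id, site_index) pairs")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def sample_indices(self, names: list[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        return np.array([pos[n] for n in names], dtype=np.intp)

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            loci=[self.loci[k] for k in keep],
            calls=self.calls[:, keep].copy(),
            total_sites=self.total_sites,
        )

    def __eq__(self, other):
        # loci compare on identity fields only; chrom/pos are VCF plumbing
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        key = lambda l: (l.locus_id, l.site_index, l.ref_allele, l.alt_allele)
        return (
            self.samples == other.samples
            and [key(l) for l in self.loci] == [key(l) for l in other.loci]
            and np.array_equal(self.calls, other.calls)
        )


def read_popmap(path: str) -> PopulationMap:
    """Read `sample  population  cluster  [lat  lon]` lines.

    Lines starting with ``#`` are comments; fields are whitespace- or
    tab-delimited.  Duplicate sample rows are an error.  ``lat``/``lon``
    must agree across samples of one population.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    sample_to_pop: dict[str, str] = {}
    pop_to_cluster: dict[str, str] = {}
    coords: dict[str, tuple[float, float]] = {}
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (3, 5):
                raise ValueError(
                    f"{path}:{lineno}: expected 3 or 5 fields, got {len(fields)}"
                )
            sample, pop, cluster = fields[:3]
            if sample in sample_to_pop:
                raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
            if pop in pop_to_cluster and pop_to_cluster[pop] != cluster:
                raise ValueError(
                    f"{path}:{lineno}: population {pop!r} assigned to two clusters"
                )
            sample_to_pop[sample] = pop
            pop_to_cluster[pop] = cluster
            if len(fields) == 5:
                latlon = (float(fields[3]), float(fields[4]))
                if pop in coords and coords[pop] != latlon:
                    raise ValueError(
                        f"{path}:{lineno}: conflicting coordinates for {pop!r}"
                    )
                coords[pop] = latlon
    return PopulationMap(sample_to_pop, pop_to_cluster, coords)


def _parse_locus(chrom: str, pos: int, vid: str | None) -> tuple[str, int]:
    # Stacks-style convention: CHROM is the stack id, POS the 1-based offset
    # of the SNP within the stack.
    return str(chrom), int(pos) - 1


def read_vcf(path: str, popmap: PopulationMap) -> GenotypeMatrix:
    """Load biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic and non-SNP records are skipped with a warning; phase
    separators are ignored; any genotype with a missing allele (``./.`` or
    half-calls like ``0/.``) becomes :data:`MISSING`.  Every VCF sample
    must appear in ``popmap``.
    """
    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    unmapped = [s for s in samples if s not in popmap.sample_to_pop]
    if unmapped:
        raise ValueError(f"VCF samples absent from popmap: {unmapped}")

    loci: list[LocusRecord] = []
    columns: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = np.asarray(var.genotype.array())  # (n_samples, ploidy+1)
        alleles = gts[:, :2]
        col = alleles.sum(axis=1).astype(np.int8)
        col[(alleles < 0).any(axis=1)] = MISSING
        locus_id, site_index = _parse_locus(var.CHROM, var.POS, var.ID)
        loci.append(
            LocusRecord(
                locus_id=locus_id,
                site_index=site_index,
                ref_allele=var.REF,
                alt_allele=var.ALT[0],
                chrom=var.CHROM,
                pos=var.POS,
            )
        )
        columns.append(col)
    if n_skipped:
        log.warning("skipped %d non-biallelic/non-SNP records", n_skipped)

    total_sites = None
    for h in vcf.raw_header.splitlines():
        if h.startswith("##total_sites="):
            total_sites = int(h.split("=", 1)[1])
    calls = (
        np.column_stack(columns)
        if columns
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        samples=samples, loci=loci, calls=calls, total_sites=total_sites
    )


def write_vcf(gm: GenotypeMatrix, path: str) -> str:
    """Write a minimal VCF 4.2 (GT-only FORMAT) readable by :func:`read_vcf`."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if gm.total_sites is not None:
            fh.write(f"##total_sites={gm.total_sites}\n")
        chroms = []
        for rec in gm.loci:
            c = rec.chrom if rec.chrom is not None else rec.locus_id
            if c not in chroms:
                chroms.append(c)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, rec in enumerate(gm.loci):
            chrom = rec.chrom if rec.chrom is not None else rec.locus_id
            pos = rec.pos if rec.pos is not None else rec.site_index + 1
            gts = "\t".join(gt_str[int(c)] for c in gm.calls[:, j])
            fh.write(
                f"{chrom}\t{pos}\t.\t{rec.ref_allele}\t{rec.alt_allele}"
                f"\t.\tPASS\t.\tGT\t{gts}\n"
            )
    return str(path)


def write_popmap(popmap: PopulationMap, path: str) -> str:
    with open(path, "w") as fh:
        for sample, pop in popmap.sample_to_pop.items():
            cluster = popmap.pop_to_cluster[pop]
            if pop in popmap.coords:
                lat, lon = popmap.coords[pop]
                fh.write(f"{sample}\t{pop}\t{cluster}\t{lat:.6f}\t{lon:.6f}\n")
            else:
                fh.write(f"{sample}\t{pop}\t{cluster}\n")
    return str(path)
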