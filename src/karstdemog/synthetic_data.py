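"""Study-shaped synthetic datasets with known ground truth.

Generates diploid SNP datasets that mirror the real sampling design —
14 populations in two genetic clusters of 106 and 81 individuals,
~1753 short loci, per-genotype missingness, populations strung along a
geographic transect — from a known demographic model, so every pipeline
stage can be tested end-to-end without the archived sequence data.

Within-cluster population substructure is deliberately *not* simulated
(the demographic models have two demes); population labels are a random
partition of the cluster's simulated diploids.  Coordinates are laid on
a 1D transect so isolation-by-distance tests have signal by construction
at the cluster level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import study
from .coalescent import DemographicModel, LocusSpec, simulate_genotypes
from .genotype_io import (
    GenotypeMatrix,
    PopulationMap,
    write_popmap,
    write_vcf,
)


@dataclass
class StudyShape:
    """Sampling design + data geometry of a synthetic dataset."""

    pops_cluster_i: dict[str, int] = field(
        default_factory=lambda: dict(study.CLUSTER_I_POPS)
    )
    pops_cluster_ii: dict[str, int] = field(
        default_factory=lambda: dict(study.CLUSTER_II_POPS)
    )
    n_loci: int = study.N_LOCI
    locus_length: int = study.LOCUS_LENGTH_BP
    missingness: float = 0.10
    #: transect anchor (lat, lon) and per-population spacing in degrees
    transect_origin: tuple[float, float] = (37.18, 128.46)
    transect_step: float = 0.035

    @property
    def n1(self) -> int:
        return sum(self.pops_cluster_i.values())

    @property
    def n2(self) -> int:
        return sum(self.pops_cluster_ii.values())

    def locus_spec(self, mu: float = study.MU) -> LocusSpec:
        return LocusSpec(n_loci=self.n_loci, locus_length=self.locus_length, mu=mu)


def default_model() -> DemographicModel:
    """The isolation-with-migration history at the study's best-fit values."""
    m = dict(study.BEST_MLE)
    return DemographicModel(
        n_cli_0=m["n_cli_0"],
        n_clii_0=m["n_clii_0"],
        n_cli_1=m["n_cli_1"],
        n_clii_1=m["n_clii_1"],
        n_anc=m["n_anc"],
        t1=m["t1"],
        t2=m["t2"],
        nm_i_ii=m["nm_i_ii"],
        nm_ii_i=m["nm_ii_i"],
        migration_window="full",
    )


@dataclass
class TruthRecord:
    """Everything needed to recompute a dataset bit-exactly."""

    model: dict
    shape: dict
    mu: float
    seed: int
    n_snps: int
    realized_missing_fraction: float

    def to_json(self, path: str) -> str:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
        return str(path)


def _popmap_for_shape(shape: StudyShape, rng: np.random.Generator) -> PopulationMap:
    sample_to_pop: dict[str, str] = {}
    pop_to_cluster: dict[str, str] = {}
    coords: dict[str, tuple[float, float]] = {}
    lat0, lon0 = shape.transect_origin
    step = shape.transect_step

    pop_offset = 0
    for cluster, pops in (("I", shape.pops_cluster_i), ("II", shape.pops_cluster_ii)):
        # assign cluster members to populations by random partition
        names = []
        for pop, n in pops.items():
            pop_to_cluster[pop] = cluster
            names.extend([pop] * n)
        names = [names[i] for i in rng.permutation(len(names))]
        for i, pop in enumerate(names):
            sample_to_pop[f"{cluster}_{i:03d}"] = pop
        for k, pop in enumerate(pops):
            coords[pop] = (lat0 - (pop_offset + k) * step, lon0 - (pop_offset + k) * step / 2)
        pop_offset += len(pops) + 2  # gap between clusters on the transect
    return PopulationMap(sample_to_pop, pop_to_cluster, coords)


def make_dataset(
    shape: StudyShape,
    model: DemographicModel,
    seed: int,
    mu: float = study.MU,
    out_dir: str | Path | None = None,
) -> tuple[GenotypeMatrix, PopulationMap, TruthRecord]:
    """Simulate a dataset; optionally write VCF + popmap + truth JSON."""
    rng = np.random.default_rng(seed)
    popmap = _popmap_for_shape(shape, rng)
    gm = simulate_genotypes(
        model,
        popmap,
        shape.locus_spec(mu),
        missingness=shape.missingness,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    from .genotype_io import MISSING

    miss_frac = (
        float((gm.calls == MISSING).mean()) if gm.calls.size else 0.0
    )
    truth = TruthRecord(
        model={**{k: getattr(model, k) for k in (
            "n_cli_0", "n_clii_0", "n_cli_1", "n_clii_1", "n_anc",
            "t1", "t2", "nm_i_ii", "nm_ii_i")},
            "migration_window": model.migration_window},
        shape={
            "pops_cluster_i": shape.pops_cluster_i,
            "pops_cluster_ii": shape.pops_cluster_ii,
            "n_loci": shape.n_loci,
            "locus_length": shape.locus_length,
            "missingness": shape.missingness,
        },
        mu=mu,
        seed=seed,
        n_snps=gm.n_loci,
        realized_missing_fraction=miss_frac,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_vcf(gm, out / "synthetic.vcf")
        write_popmap(popmap, out / "popmap.tsv")
        truth.to_json(out / "truth.json")
    return gm, popmap, truth


# ---------------------------------------------------------------------------
# curated fixtures


def toy_filter_matrix(seed: int) -> tuple[GenotypeMatrix, PopulationMap]:
    """Small 3-population matrix with staged missingness for filter tests."""
    rng = np.random.default_rng(seed)
    pops = {"P1": 6, "P2": 5, "P3": 4}
    sample_to_pop = {}
    for pop, n in pops.items():
        for i in range(n):
            sample_to_pop[f"{pop}_s{i}"] = pop
    popmap = PopulationMap(
        sample_to_pop, {"P1": "I", "P2": "I", "P3": "II"}
    )
    n_samples = sum(pops.values())
    n_snps = 60
    freqs = rng.uniform(0.0, 0.5, size=n_snps)
    calls = rng.binomial(2, freqs, size=(n_samples, n_snps)).astype(np.int8)
    miss = rng.random((n_samples, n_snps)) < rng.uniform(0, 0.5, size=n_snps)
    calls[miss] = -1
    from .genotype_io import LocusRecord

    loci = []
    for j in range(n_snps):
        loci.append(
            LocusRecord(locus_id=f"stack_{j // 3:03d}", site_index=int(rng.integers(0, 100)) * 3 + j % 3)
        )
    samples = list(sample_to_pop)
    return GenotypeMatrix(samples=samples, loci=loci, calls=calls), popmap


def two_island_fixture(seed: int, nm: float = 1.0):
    """Symmetric two-island equilibrium-ish dataset for F_ST checks.

    With Nm migrant gene copies per generation in each direction and a
    divergence time far older than coalescence, the Weir–Cockerham θ
    expectation is 1/(1 + 4·Nm).
    """
    N = 500.0
    model = DemographicModel(
        n_cli_0=N, n_clii_0=N, n_cli_1=N, n_clii_1=N, n_anc=N,
        t1=100.0, t2=2.0e5, nm_i_ii=nm, nm_ii_i=nm,
        migration_window="full",
    )
    shape = StudyShape(
        pops_cluster_i={"A1": 8, "A2": 8},
        pops_cluster_ii={"B1": 8, "B2": 8},
        n_loci=500,
        locus_length=138,
        missingness=0.0,
    )
    gm, popmap, truth = make_dataset(shape, model, seed, mu=1.2e-6)
    return gm, popmap, truth


def panmictic_fixture(seed: int):
    """Single panmictic population labelled as two clusters: F_ST null."""
    N = 500.0
    model = DemographicModel(
        n_cli_0=N, n_clii_0=N, n_cli_1=N, n_clii_1=N, n_anc=N,
        t1=1.0, t2=2.0, migration_window="none",
    )
    shape = StudyShape(
        pops_cluster_i={"A1": 8, "A2": 8},
        pops_cluster_ii={"B1": 8, "B2": 8},
        n_loci=500,
        locus_length=138,
        missingness=0.0,
    )
    gm, popmap, truth = make_dataset(shape, model, seed, mu=1.2e-6)
    return gm, popmap, truth


def reduced_mle_fixture(seed: int, n_loci: int = 300):
    """Study-MLE model at full sample sizes but a reduced locus count.

    The workhorse for fit/recovery tests: 106 + 81 diploids, ``n_loci``
    loci of 138 bp at the study mutation rate.
    """
    model = default_model()
    shape = StudyShape(n_loci=n_loci, missingness=0.0)
    gm, popmap, truth = make_dataset(shape, model, seed)
    return gm, popmap, truth


def make_fixture_suite(seed: int) -> dict:
    """All curated fixtures, keyed by letter."""
    return {
        "a_toy_filter": toy_filter_matrix(seed),
        "b_two_island": two_island_fixture(seed + 1),
        "c_panmictic": panmictic_fixture(seed + 2),
        "d_reduced_mle": reduced_mle_fixture(seed + 3),
    }
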