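"""Folded two-dimensional minor-allele site frequency spectrum.

The fitting target of the demographic analysis is the joint spectrum of
minor-allele copy numbers in two population clusters.  Missing genotypes
are first filled by a within-cluster bootstrap: each missing gene copy is
resampled i.i.d. from the cluster's observed gene copies at that SNP, so
the expected imputed allele frequency equals the observed cluster
frequency.  The spectrum is then folded on the *global* minor allele:
a site with alternate-copy counts (i, j) summing past half the total gene
count is recorded as its complement (2n₁−i, 2n₂−j); an exact half-count
tie contributes ½ to both complementary cells.

Cell (0, 0) stores the monomorphic-site count (total sites − variant
sites) when a total-site count is known, which the composite likelihood
uses for absolute parameter scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap


def _cluster_index_pair(gm: GenotypeMatrix, popmap: PopulationMap):
    clusters = popmap.clusters
    if len(clusters) != 2:
        raise ValueError(f"exactly two clusters required, got {clusters}")
    idx1 = gm.sample_indices(
        [s for s in gm.samples if popmap.cluster_of_sample(s) == clusters[0]]
    )
    idx2 = gm.sample_indices(
        [s for s in gm.samples if popmap.cluster_of_sample(s) == clusters[1]]
    )
    return clusters, idx1, idx2


def impute_missing(
    gm: GenotypeMatrix, popmap: PopulationMap, seed: int
) -> GenotypeMatrix:
    """Within-cluster bootstrap imputation of missing genotypes.

    Each missing diploid call becomes the sum of two gene copies drawn
    i.i.d. (with replacement) from the cluster's observed gene copies at
    that SNP.  Non-missing calls are never altered.  Fully deterministic
    given ``seed``.
    """
    rng = np.random.default_rng(seed)
    _, idx1, idx2 = _cluster_index_pair(gm, popmap)
    calls = gm.calls.copy()
    for idx in (idx1, idx2):
        sub = calls[idx, :]
        obs = sub != MISSING
        alt = np.where(obs, sub, 0).sum(axis=0)
        genes = 2 * obs.sum(axis=0)
        bad = np.flatnonzero(genes == 0)
        if bad.size:
            names = [gm.loci[j].locus_id for j in bad[:5]]
            raise ValueError(
                f"{bad.size} SNP(s) with a cluster entirely missing "
                f"(first: {names}); cannot impute"
            )
        freq = alt / genes
        miss_rows, miss_cols = np.nonzero(~obs)
        if miss_rows.size:
            p = freq[miss_cols]
            draws = rng.binomial(2, p).astype(np.int8)
            sub = sub.copy()
            sub[miss_rows, miss_cols] = draws
            calls[idx, :] = sub
    return GenotypeMatrix(
        samples=list(gm.samples),
        loci=list(gm.loci),
        calls=calls,
        total_sites=gm.total_sites,
    )


@dataclass
class Folded2DSFS:
    """Joint folded spectrum: counts[i, j] over minor-allele copy numbers.

    Shape is (2·n1 + 1) × (2·n2 + 1) for n1/n2 diploids per cluster.
    Half-integer counts arise from exact-half folding ties.
    """

    counts: np.ndarray
    n1: int
    n2: int
    total_sites: int | None = None
    seed: int | None = None
    cluster_labels: tuple[str, str] = ("I", "II")

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        expected = (2 * self.n1 + 1, 2 * self.n2 + 1)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")

    @property
    def polymorphic_mask(self) -> np.ndarray:
        m = np.ones_like(self.counts, dtype=bool)
        m[0, 0] = False
        m[-1, -1] = False
        return m

    @property
    def n_variant(self) -> float:
        return float(self.counts[self.polymorphic_mask].sum())

    def marginals(self) -> tuple[np.ndarray, np.ndarray]:
        """Folded 1D spectra per cluster (row/column sums, re-folded).

        Each margin is re-folded on its own minor allele; exact-half bins
        stay in place.  Sums over polymorphic bins are preserved.
        """
        out = []
        for axis, n in ((1, self.n1), (0, self.n2)):
            m = self.counts.sum(axis=axis)
            size = 2 * n + 1
            folded = np.zeros(size)
            for i, v in enumerate(m):
                comp = 2 * n - i
                if i < comp:
                    folded[i] += v
                elif i > comp:
                    folded[comp] += v
                else:
                    folded[i] += v
            out.append(folded)
        return out[0], out[1]

    # -- serialization ----------------------------------------------------

    def to_tsv(self, path: str) -> str:
        header = "\t".join(f"d{self.cluster_labels[1]}_{j}" for j in range(2 * self.n2 + 1))
        np.savetxt(
            path,
            self.counts,
            delimiter="\t",
            header=header,
            comments="",
            fmt="%.2f",
        )
        return str(path)

    def to_obs_text(self, path: str) -> str:
        """fastsimcoal2 joint-MAF observed-spectrum text layout.

        One observation block; rows labelled by deme-1 copy number,
        columns by deme-0 copy number.
        """
        with open(path, "w") as fh:
            fh.write("1 observations. No. of demes and sample sizes are on next line\n")
            fh.write(f"2\t{2 * self.n1}\t{2 * self.n2}\n")
            fh.write(
                "\t" + "\t".join(f"d0_{i}" for i in range(2 * self.n1 + 1)) + "\n"
            )
            for j in range(2 * self.n2 + 1):
                row = "\t".join(f"{self.counts[i, j]:g}" for i in range(2 * self.n1 + 1))
                fh.write(f"d1_{j}\t{row}\n")
        return str(path)

    @classmethod
    def from_obs_text(cls, path: str, total_sites: int | None = None) -> "Folded2DSFS":
        with open(path) as fh:
            fh.readline()
            sizes = fh.readline().split()
            g1, g2 = int(sizes[1]), int(sizes[2])
            fh.readline()
            counts = np.zeros((g1 + 1, g2 + 1))
            for j in range(g2 + 1):
                fields = fh.readline().split()
                counts[:, j] = [float(x) for x in fields[1:]]
        return cls(counts=counts, n1=g1 // 2, n2=g2 // 2, total_sites=total_sites)


def fold_joint(counts: np.ndarray) -> np.ndarray:
    """Fold an unfolded joint spectrum on the global minor allele.

    Idempotent: folding a folded spectrum returns it unchanged.
    """
    counts = np.asarray(counts, dtype=float)
    g1, g2 = counts.shape[0] - 1, counts.shape[1] - 1
    half = (g1 + g2) / 2.0
    out = np.zeros_like(counts)
    for i in range(g1 + 1):
        for j in range(g2 + 1):
            v = counts[i, j]
            if v == 0:
                continue
            tot = i + j
            if tot < half:
                out[i, j] += v
            elif tot > half:
                out[g1 - i, g2 - j] += v
            else:
                out[i, j] += v / 2.0
                out[g1 - i, g2 - j] += v / 2.0
    return out


def build_folded_2dsfs(
    gm: GenotypeMatrix, popmap: PopulationMap, seed: int | None = None
) -> Folded2DSFS:
    """Tally the folded joint spectrum from a complete genotype matrix.

    Requires no missing calls (run :func:`impute_missing` first) and
    exactly two clusters.  SNPs that are monomorphic within the sampled
    genotypes fall into the (0, 0) cell along with the monomorphic-site
    count from ``gm.total_sites`` when present.
    """
    if (gm.calls == MISSING).any():
        raise ValueError("matrix contains missing calls; impute first")
    clusters, idx1, idx2 = _cluster_index_pair(gm, popmap)
    n1, n2 = len(idx1), len(idx2)
    i_counts = gm.calls[idx1, :].sum(axis=0)
    j_counts = gm.calls[idx2, :].sum(axis=0)
    unfolded = np.zeros((2 * n1 + 1, 2 * n2 + 1))
    np.add.at(unfolded, (i_counts, j_counts), 1.0)
    counts = fold_joint(unfolded)
    if gm.total_sites is not None:
        counts[0, 0] += gm.total_sites - gm.n_loci
    return Folded2DSFS(
        counts=counts,
        n1=n1,
        n2=n2,
        total_sites=gm.total_sites,
        seed=seed,
        cluster_labels=(clusters[0], clusters[1]),
    )
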