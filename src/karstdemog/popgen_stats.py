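"""Diversity and differentiation statistics for diploid SNP panels.

Implements the classic per-population summaries (observed/expected
heterozygosity, inbreeding coefficient, private alleles, rarefied allelic
richness, nucleotide diversity), Weir–Cockerham variance-components
F\\_ST, Nei (1972) standard genetic distance, great-circle geographic
distances and a permutation Mantel test for isolation by distance.

Conventions (fixed and documented rather than configurable):

* F_IS is the per-locus (H_E − H_O)/H_E averaged over loci with H_E > 0.
* Allelic richness uses hypergeometric rarefaction to ``g`` gene copies;
  ``g`` defaults per locus to the smallest per-group non-missing gene
  count (the FSTAT convention).
* The multilocus Weir–Cockerham estimate is the ratio of summed variance
  components Σa / Σ(a+b+c), not the mean of per-locus ratios.
* The Mantel statistic is the squared Pearson correlation of the
  vectorized upper triangles; the p-value is one-tailed,
  (1 + #{permuted ≥ observed}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

EARTH_RADIUS_KM = 6371.0088


# ---------------------------------------------------------------------------
# per-group allele bookkeeping


def _group_calls(gm: GenotypeMatrix, samples: list[str]) -> np.ndarray:
    if not samples:
        raise ValueError("empty sample group")
    return gm.calls[gm.sample_indices(samples), :]


def _allele_counts(calls: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (alt gene copies, total non-missing gene copies) per locus."""
    obs = calls != MISSING
    alt = np.where(obs, calls, 0).sum(axis=0)
    genes = 2 * obs.sum(axis=0)
    return alt, genes


def observed_heterozygosity(
    gm: GenotypeMatrix, samples: list[str]
) -> tuple[np.ndarray, float, float]:
    """Per-locus H_O (het fraction among non-missing calls), mean and SE.

    Loci with no non-missing call in the group are excluded (NaN per
    locus) and do not enter the mean.
    """
    calls = _group_calls(gm, samples)
    obs = calls != MISSING
    n = obs.sum(axis=0)
    het = (calls == 1).sum(axis=0)
    with np.errstate(invalid="ignore"):
        ho = np.where(n > 0, het / np.maximum(n, 1), np.nan)
    valid = ho[~np.isnan(ho)]
    mean = float(valid.mean()) if valid.size else float("nan")
    se = float(valid.std(ddof=1) / np.sqrt(valid.size)) if valid.size > 1 else float("nan")
    return ho, mean, se


def expected_heterozygosity(
    gm: GenotypeMatrix, samples: list[str]
) -> tuple[np.ndarray, float, float]:
    """Per-locus H_E = 1 − p² − q² from group allele frequencies, mean, SE."""
    calls = _group_calls(gm, samples)
    alt, genes = _allele_counts(calls)
    with np.errstate(invalid="ignore"):
        p = np.where(genes > 0, alt / np.maximum(genes, 1), np.nan)
    he = 1.0 - p**2 - (1.0 - p) ** 2
    valid = he[~np.isnan(he)]
    mean = float(valid.mean()) if valid.size else float("nan")
    se = float(valid.std(ddof=1) / np.sqrt(valid.size)) if valid.size > 1 else float("nan")
    return he, mean, se


def inbreeding_coefficient(gm: GenotypeMatrix, samples: list[str]) -> float:
    """Mean over loci of (H_E − H_O)/H_E, restricted to loci with H_E > 0."""
    ho, _, _ = observed_heterozygosity(gm, samples)
    he, _, _ = expected_heterozygosity(gm, samples)
    ok = ~np.isnan(he) & ~np.isnan(ho) & (he > 0)
    if not ok.any():
        raise ValueError("F_IS undefined: no polymorphic locus in group")
    f = (he[ok] - ho[ok]) / he[ok]
    return float(f.mean())


def mean_alleles_per_locus(gm: GenotypeMatrix, samples: list[str]) -> float:
    """N_A: mean number of observed alleles per locus (1 or 2 for SNPs)."""
    calls = _group_calls(gm, samples)
    alt, genes = _allele_counts(calls)
    n_alleles = np.where(
        genes > 0, (alt > 0).astype(int) + (alt < genes).astype(int), np.nan
    )
    valid = n_alleles[~np.isnan(n_alleles)]
    return float(valid.mean()) if valid.size else float("nan")


def private_alleles(
    gm: GenotypeMatrix, popmap: PopulationMap, level: str = "population"
) -> dict[str, int]:
    """Count alleles present in exactly one group at the given level."""
    if level == "population":
        groups = {p: popmap.samples_in_pop(p) for p in popmap.populations}
    elif level == "cluster":
        groups = {c: popmap.samples_in_cluster(c) for c in popmap.clusters}
    else:
        raise ValueError(f"unknown level {level!r}")
    if len(groups) < 2:
        raise ValueError("private alleles need at least two groups")
    names = list(groups)
    # presence[g, j, a]: allele a (0=ref, 1=alt) observed in group g at SNP j
    presence = np.zeros((len(names), gm.n_loci, 2), dtype=bool)
    for gi, name in enumerate(names):
        alt, genes = _allele_counts(_group_calls(gm, groups[name]))
        presence[gi, :, 0] = alt < genes  # ref seen
        presence[gi, :, 1] = alt > 0  # alt seen
    n_groups_with = presence.sum(axis=0)  # (n_loci, 2)
    out = {}
    for gi, name in enumerate(names):
        private = presence[gi] & (n_groups_with == 1)
        out[name] = int(private.sum())
    return out


def allelic_richness(
    gm: GenotypeMatrix,
    samples: list[str],
    g: int | np.ndarray | None = None,
) -> float:
    """Mean rarefied allele count per locus at ``g`` gene copies.

    Per locus, A_R = Σ_alleles [1 − C(2n−n_a, g) / C(2n, g)] — the expected
    number of distinct alleles in a hypergeometric draw of ``g`` of the
    ``2n`` observed gene copies.  ``g`` may be a scalar or per-locus array;
    loci where ``g`` exceeds the observed gene count are skipped.
    """
    calls = _group_calls(gm, samples)
    alt, genes = _allele_counts(calls)
    if g is None:
        raise ValueError("g (rarefaction size in gene copies) is required here; "
                         "use diversity_table for the per-locus FSTAT default")
    g = np.broadcast_to(np.asarray(g), alt.shape)
    if (g < 2).any():
        raise ValueError("rarefaction size g must be >= 2")
    vals = []
    for a, n2, gg in zip(alt, genes, g):
        if n2 == 0 or gg > n2:
            continue
        ar = 0.0
        for n_a in (a, n2 - a):  # ref and alt copy counts
            if n_a > 0:
                ar += 1.0 - _hyper_zero_prob(n2, n_a, gg)
        vals.append(ar)
    if not vals:
        return float("nan")
    return float(np.mean(vals))


def _hyper_zero_prob(n_genes: int, n_copies: int, g: int) -> float:
    """P(no copy of an allele with n_copies among n_genes in a draw of g)."""
    if n_genes - n_copies < g:
        return 0.0
    # C(n_genes - n_copies, g) / C(n_genes, g) via log-gammas
    def logc(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    return float(np.exp(logc(n_genes - n_copies, g) - logc(n_genes, g)))


def nucleotide_diversity(gm: GenotypeMatrix, samples: list[str]) -> float:
    """π over variant sites: mean of (n/(n−1))·(1 − Σ p_i²) per site."""
    calls = _group_calls(gm, samples)
    alt, genes = _allele_counts(calls)
    ok = genes >= 2
    if not ok.any():
        raise ValueError("pi undefined: no site with >= 2 gene copies")
    n = genes[ok].astype(float)
    p = alt[ok] / n
    pi_site = n / (n - 1.0) * (1.0 - p**2 - (1.0 - p) ** 2)
    return float(pi_site.mean())


# ---------------------------------------------------------------------------
# Weir–Cockerham F_ST


def _wc_components(
    gm: GenotypeMatrix, groups: list[list[str]]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus Weir–Cockerham (1984) variance components (a, b, c).

    Computed for the alternate allele; for biallelic data the two alleles
    give proportional components, so the θ ratio is unchanged.
    """
    r = len(groups)
    if r < 2:
        raise ValueError("F_ST needs at least two populations")
    n_loci = gm.n_loci
    n_i = np.zeros((r, n_loci))
    p_i = np.zeros((r, n_loci))
    h_i = np.zeros((r, n_loci))
    for gi, samples in enumerate(groups):
        calls = _group_calls(gm, samples)
        obs = calls != MISSING
        n = obs.sum(axis=0).astype(float)
        alt = np.where(obs, calls, 0).sum(axis=0)
        het = (calls == 1).sum(axis=0)
        n_i[gi] = n
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[gi] = np.where(n > 0, alt / (2 * np.maximum(n, 1)), np.nan)
            h_i[gi] = np.where(n > 0, het / np.maximum(n, 1), np.nan)

    valid = (n_i > 0).all(axis=0)
    nbar = n_i.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i**2).sum(axis=0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / (r * nbar)

        a = (nbar / nc) * (
            s2
            - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar)
            - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
    a = np.where(valid, a, np.nan)
    b = np.where(valid, b, np.nan)
    c = np.where(valid, c, np.nan)
    return a, b, c


@dataclass
class FstResult:
    per_locus: np.ndarray  # per-locus θ (NaN where undefined)
    overall: float  # Σa / Σ(a+b+c)
    pairwise: pd.DataFrame | None = None


def wc_fst(
    gm: GenotypeMatrix, popmap: PopulationMap, pairwise: bool = True
) -> FstResult:
    """Weir–Cockerham θ per locus, multilocus (ratio of sums), and pairwise."""
    pops = popmap.populations
    groups = [popmap.samples_in_pop(p) for p in pops]
    a, b, c = _wc_components(gm, groups)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = np.where(np.abs(denom) > 0, a / denom, np.nan)
    ok = ~np.isnan(denom) & (np.abs(denom) > 0)
    overall = float(np.nansum(a[ok]) / np.nansum(denom[ok]))

    pw = None
    if pairwise and len(pops) > 2:
        pw = pd.DataFrame(0.0, index=pops, columns=pops)
        for p1, p2 in combinations(pops, 2):
            aa, bb, cc = _wc_components(
                gm, [popmap.samples_in_pop(p1), popmap.samples_in_pop(p2)]
            )
            dd = aa + bb + cc
            okk = ~np.isnan(dd) & (np.abs(dd) > 0)
            val = float(np.nansum(aa[okk]) / np.nansum(dd[okk]))
            pw.loc[p1, p2] = pw.loc[p2, p1] = val
    elif pairwise:
        pw = pd.DataFrame(
            [[0.0, overall], [overall, 0.0]], index=pops, columns=pops
        )
    return FstResult(per_locus=per_locus, overall=overall, pairwise=pw)


# ---------------------------------------------------------------------------
# distances and isolation by distance


def nei_distance(gm: GenotypeMatrix, popmap: PopulationMap) -> pd.DataFrame:
    """Nei (1972) standard genetic distance between populations.

    D = −ln( J̄xy / sqrt(J̄x · J̄y) ) with identities averaged over loci.
    """
    pops = popmap.populations
    freqs = {}
    for p in pops:
        alt, genes = _allele_counts(_group_calls(gm, popmap.samples_in_pop(p)))
        with np.errstate(invalid="ignore"):
            freqs[p] = np.where(genes > 0, alt / np.maximum(genes, 1), np.nan)
    D = pd.DataFrame(0.0, index=pops, columns=pops)
    for p1, p2 in combinations(pops, 2):
        x, y = freqs[p1], freqs[p2]
        ok = ~np.isnan(x) & ~np.isnan(y)
        jx = (x[ok] ** 2 + (1 - x[ok]) ** 2).mean()
        jy = (y[ok] ** 2 + (1 - y[ok]) ** 2).mean()
        jxy = (x[ok] * y[ok] + (1 - x[ok]) * (1 - y[ok])).mean()
        d = float(-np.log(jxy / np.sqrt(jx * jy)))
        D.loc[p1, p2] = D.loc[p2, p1] = d
    return D


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km between two (lat, lon) points in degrees."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2 - lon1)
    h = np.sin(dphi / 2) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


def geographic_distance(popmap: PopulationMap) -> pd.DataFrame:
    """Pairwise great-circle distances (km) between population coordinates."""
    pops = [p for p in popmap.populations if p in popmap.coords]
    if len(pops) < 2:
        raise ValueError("need coordinates for at least two populations")
    D = pd.DataFrame(0.0, index=pops, columns=pops)
    for p1, p2 in combinations(pops, 2):
        d = haversine_km(*popmap.coords[p1], *popmap.coords[p2])
        D.loc[p1, p2] = D.loc[p2, p1] = d
    return D


@dataclass
class MantelResult:
    r_squared: float
    p_value: float
    n_permutations: int
    seed: int | None


def _mantel_stat(x: np.ndarray, y: np.ndarray) -> float:
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def mantel_test(
    genetic: pd.DataFrame | np.ndarray,
    geographic: pd.DataFrame | np.ndarray,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    Permutations relabel the objects of the second matrix (rows and
    columns jointly).  With ``exact=True`` all n! relabelings are
    enumerated instead (feasible only for tiny matrices) and the p-value
    is #{stat ≥ observed}/n! over all permutations including identity.
    """
    X = np.asarray(genetic, dtype=float)
    Y = np.asarray(geographic, dtype=float)
    if X.shape != Y.shape or X.shape[0] != X.shape[1] or X.shape[0] < 3:
        raise ValueError("matrices must be square, equal-shaped, size >= 3")
    iu = np.triu_indices(X.shape[0], k=1)
    x = X[iu]
    if np.allclose(x, x[0]) or np.allclose(Y[iu], Y[iu][0]):
        raise ValueError("constant distance matrix: Mantel statistic undefined")
    obs = _mantel_stat(x, Y[iu])

    n = X.shape[0]
    if exact:
        from itertools import permutations as iperm

        stats = []
        for perm in iperm(range(n)):
            P = Y[np.ix_(perm, perm)]
            stats.append(_mantel_stat(x, P[iu]))
        stats = np.array(stats)
        p = float((stats >= obs - 1e-12).sum() / stats.size)
        return MantelResult(obs, p, stats.size, seed)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        P = Y[np.ix_(perm, perm)]
        if _mantel_stat(x, P[iu]) >= obs - 1e-12:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MantelResult(obs, p, n_perm, seed)


# ---------------------------------------------------------------------------
# Table-1-shaped summary


def diversity_table(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    rarefaction_g: int | None = None,
) -> pd.DataFrame:
    """Per-population and pooled-cluster diversity summary.

    ``rarefaction_g`` defaults, per locus, to the smallest per-population
    non-missing gene count (≥2) across populations, so allelic richness
    is comparable across rows.
    """
    pops = popmap.populations
    if rarefaction_g is None:
        min_genes = None
        for p in pops:
            _, genes = _allele_counts(_group_calls(gm, popmap.samples_in_pop(p)))
            min_genes = genes if min_genes is None else np.minimum(min_genes, genes)
        g = np.maximum(min_genes, 2)
    else:
        g = np.full(gm.n_loci, rarefaction_g)

    pa_pop = private_alleles(gm, popmap, level="population")
    pa_cl = (
        private_alleles(gm, popmap, level="cluster")
        if len(popmap.clusters) >= 2
        else {}
    )

    rows = []

    def _row(name, samples, pa):
        _, ho, ho_se = observed_heterozygosity(gm, samples)
        _, he, he_se = expected_heterozygosity(gm, samples)
        rows.append(
            {
                "group": name,
                "N": len(samples),
                "N_A": round(mean_alleles_per_locus(gm, samples), 3),
                "P_A": pa,
                "A_R": round(allelic_richness(gm, samples, g=g), 3),
                "H_O": round(ho, 3),
                "H_O_SE": round(ho_se, 3),
                "H_E": round(he, 3),
                "H_E_SE": round(he_se, 3),
                "pi": round(nucleotide_diversity(gm, samples), 3),
                "F_IS": round(inbreeding_coefficient(gm, samples), 3),
            }
        )

    for p in pops:
        _row(p, popmap.samples_in_pop(p), pa_pop[p])
    for c in popmap.clusters:
        _row(f"cluster_{c}", popmap.samples_in_cluster(c), pa_cl.get(c, 0))
    return pd.DataFrame(rows).set_index("group")
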