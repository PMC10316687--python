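"""Structured-coalescent simulator for two-deme divergence models.

The model family covers four histories of a pair of population clusters
that split from a common ancestor at time T₂ (backwards in time):

* model 1 — isolation, no gene flow;
* model 2 — isolation with continuous migration (present → T₂);
* model 3 — ancient migration only (T₁ → T₂);
* model 4 — secondary contact, recent migration only (present → T₁);

with independent deme sizes in the two epochs [0, T₁) and [T₁, T₂) and a
single ancestral size beyond T₂.  All sizes are *diploid* effective sizes
(a deme of size N holds 2N gene copies, so a pair coalesces at rate
1/(2N) per generation).  Migration strength is parameterized as Nm, the
expected number of migrant gene copies per generation, forward in time
from deme j into deme i; backwards in time a lineage currently in deme i
jumps to deme j at rate Nm_{i←j} / (2N_i).

Genealogies are generated by an exponential race over coalescence and
migration events with piecewise-constant rates; at T₂ the demes merge.
Two consumers exist:

* an expected-SFS accumulator that credits each branch's length to the
  joint (descendants-in-I, descendants-in-II) cell — a Rao-Blackwellized
  Monte-Carlo estimate of the expected branch length per frequency class,
  from which expected spectra and Poisson-realized spectra follow;
* a full-topology recorder used to emit per-locus site patterns and
  diploid genotypes under infinite-sites mutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .genotype_io import MISSING, GenotypeMatrix, LocusRecord, PopulationMap
from .sfs import Folded2DSFS, fold_joint

MIGRATION_WINDOWS = ("none", "full", "ancient", "recent")
MODEL_WINDOW = {1: "none", 2: "full", 3: "ancient", 4: "recent"}


@dataclass(frozen=True)
class DemographicModel:
    """Two-deme divergence history (sizes diploid, times in generations).

    ``n_cli_0``/``n_clii_0`` apply on [0, T₁), ``n_cli_1``/``n_clii_1`` on
    [T₁, T₂), ``n_anc`` beyond T₂.  ``nm_i_ii`` is the forward migrant
    count into cluster I from cluster II (and vice versa); the window in
    which migration is active selects the model.
    """

    n_cli_0: float
    n_clii_0: float
    n_cli_1: float
    n_clii_1: float
    n_anc: float
    t1: float
    t2: float
    nm_i_ii: float = 0.0
    nm_ii_i: float = 0.0
    migration_window: str = "none"

    def __post_init__(self):
        if not (0 < self.t1 < self.t2):
            raise ValueError(f"need 0 < T1 < T2, got T1={self.t1}, T2={self.t2}")
        for name in ("n_cli_0", "n_clii_0", "n_cli_1", "n_clii_1", "n_anc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.nm_i_ii < 0 or self.nm_ii_i < 0:
            raise ValueError("Nm must be >= 0")
        if self.migration_window not in MIGRATION_WINDOWS:
            raise ValueError(f"unknown migration window {self.migration_window!r}")
        if self.migration_window == "none" and (self.nm_i_ii or self.nm_ii_i):
            raise ValueError("model 1 requires Nm == 0 in both directions")

    @property
    def model_id(self) -> int:
        return {v: k for k, v in MODEL_WINDOW.items()}[self.migration_window]

    @classmethod
    def for_model(cls, model_id: int, **params) -> "DemographicModel":
        return cls(migration_window=MODEL_WINDOW[model_id], **params)

    def _epoch_arrays(self):
        """(sizes[2 epochs, 2 demes], backward mig rates[2 epochs, 2 demes])."""
        sizes = np.array(
            [[self.n_cli_0, self.n_clii_0], [self.n_cli_1, self.n_clii_1]],
            dtype=np.float64,
        )
        active = {
            "none": (False, False),
            "full": (True, True),
            "ancient": (False, True),
            "recent": (True, False),
        }[self.migration_window]
        mig = np.zeros((2, 2), dtype=np.float64)
        for e in range(2):
            if active[e]:
                mig[e, 0] = self.nm_i_ii / (2.0 * sizes[e, 0])
                mig[e, 1] = self.nm_ii_i / (2.0 * sizes[e, 1])
        return sizes, mig


@dataclass(frozen=True)
class LocusSpec:
    """Geometry and mutation model of the simulated loci."""

    n_loci: int = 1753
    locus_length: int = 138
    mu: float = 5.39e-8

    def __post_init__(self):
        if self.n_loci < 1 or self.locus_length < 1 or self.mu <= 0:
            raise ValueError("invalid locus spec")

    @property
    def total_sites(self) -> int:
        return self.n_loci * self.locus_length


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=True)
def _run_race(
    k1,
    k2,
    sizes,
    mig,
    t1,
    t2,
    n_anc,
    deme,
    c1,
    c2,
    birth,
    members,
    counts,
    node_time,
    node_left,
    node_right,
    acc,
    record,
):
    """Simulate one genealogy; accumulate branch lengths into ``acc`` and,
    when ``record`` is true, fill coalescence-node arrays.

    Work arrays (deme, c1, c2, birth, members, counts) are caller-provided
    to avoid reallocation.  Lineage slots: 0..k-1 leaves, internal nodes
    appended at k, k+1, ...  Returns the number of nodes created.
    """
    k = k1 + k2
    # initialize lineages
    for i in range(k):
        if i < k1:
            deme[i] = 0
            c1[i] = 1
            c2[i] = 0
        else:
            deme[i] = 1
            c1[i] = 0
            c2[i] = 1
        birth[i] = 0.0
    counts[0] = k1
    counts[1] = k2
    for i in range(k1):
        members[0, i] = i
    for i in range(k2):
        members[1, i] = k1 + i

    t = 0.0
    epoch = 0  # 0: [0,t1), 1: [t1,t2), 2: merged
    n_active = k
    next_node = k
    while n_active > 1:
        if epoch == 0:
            boundary = t1
            N0, N1 = sizes[0, 0], sizes[0, 1]
            m0, m1 = mig[0, 0], mig[0, 1]
        elif epoch == 1:
            boundary = t2
            N0, N1 = sizes[1, 0], sizes[1, 1]
            m0, m1 = mig[1, 0], mig[1, 1]
        else:
            boundary = 1.0e300
            N0, N1 = n_anc, n_anc
            m0, m1 = 0.0, 0.0

        k0 = counts[0]
        kk1 = counts[1]
        rate_c0 = k0 * (k0 - 1) / 2.0 / (2.0 * N0)
        rate_c1 = kk1 * (kk1 - 1) / 2.0 / (2.0 * N1)
        rate_m0 = k0 * m0
        rate_m1 = kk1 * m1
        total = rate_c0 + rate_c1 + rate_m0 + rate_m1

        if total <= 0.0:
            t = boundary
        else:
            dt = np.random.exponential(1.0 / total)
            if t + dt >= boundary:
                t = boundary
            else:
                t = t + dt
                u = np.random.random() * total
                if u < rate_c0 or (u < rate_c0 + rate_c1):
                    d = 0 if u < rate_c0 else 1
                    kd = counts[d]
                    ia = np.random.randint(kd)
                    ib = np.random.randint(kd - 1)
                    if ib >= ia:
                        ib += 1
                    a = members[d, ia]
                    b = members[d, ib]
                    # credit both child branches
                    acc[c1[a], c2[a]] += t - birth[a]
                    acc[c1[b], c2[b]] += t - birth[b]
                    # new lineage in slot `next_node`
                    deme[next_node] = d
                    c1[next_node] = c1[a] + c1[b]
                    c2[next_node] = c2[a] + c2[b]
                    birth[next_node] = t
                    if record:
                        node_time[next_node] = t
                        node_left[next_node - k] = a
                        node_right[next_node - k] = b
                    # replace a with the new node, swap-remove b
                    members[d, ia] = next_node
                    members[d, ib] = members[d, kd - 1]
                    counts[d] = kd - 1
                    n_active -= 1
                    next_node += 1
                else:
                    d = 0 if u < rate_c0 + rate_c1 + rate_m0 else 1
                    o = 1 - d
                    kd = counts[d]
                    ia = np.random.randint(kd)
                    lin = members[d, ia]
                    members[d, ia] = members[d, kd - 1]
                    counts[d] = kd - 1
                    members[o, counts[o]] = lin
                    counts[o] += 1
                    deme[lin] = o
                continue  # event handled; rates recomputed next loop

        # hit a boundary without an event
        if epoch == 0:
            epoch = 1
        elif epoch == 1:
            # merge: move all deme-1 lineages to deme 0
            for i in range(counts[1]):
                lin = members[1, i]
                members[0, counts[0]] = lin
                counts[0] += 1
                deme[lin] = 0
            counts[1] = 0
            epoch = 2
        # epoch 2 with total<=0 impossible once n_active > 1

    return next_node


@njit(cache=True)
def _branch_sfs(
    n_trees, k1, k2, sizes, mig, t1, t2, n_anc, seed
):
    """Mean branch length per unfolded joint frequency cell, over trees."""
    np.random.seed(seed)
    k = k1 + k2
    acc = np.zeros((k1 + 1, k2 + 1))
    deme = np.empty(2 * k, dtype=np.int64)
    c1 = np.empty(2 * k, dtype=np.int64)
    c2 = np.empty(2 * k, dtype=np.int64)
    birth = np.empty(2 * k, dtype=np.float64)
    members = np.empty((2, k), dtype=np.int64)
    counts = np.empty(2, dtype=np.int64)
    node_time = np.empty(1, dtype=np.float64)
    node_lr = np.empty(1, dtype=np.int64)
    for _ in range(n_trees):
        _run_race(
            k1, k2, sizes, mig, t1, t2, n_anc,
            deme, c1, c2, birth, members, counts,
            node_time, node_lr, node_lr, acc, False,
        )
    return acc / n_trees


@njit(cache=True)
def _one_tree(k1, k2, sizes, mig, t1, t2, n_anc, node_time, node_left, node_right):
    """Record one genealogy's topology (seed must be set by the caller)."""
    k = k1 + k2
    acc = np.zeros((k1 + 1, k2 + 1))
    deme = np.empty(2 * k, dtype=np.int64)
    c1 = np.empty(2 * k, dtype=np.int64)
    c2 = np.empty(2 * k, dtype=np.int64)
    birth = np.empty(2 * k, dtype=np.float64)
    members = np.empty((2, k), dtype=np.int64)
    counts = np.empty(2, dtype=np.int64)
    _run_race(
        k1, k2, sizes, mig, t1, t2, n_anc,
        deme, c1, c2, birth, members, counts,
        node_time, node_left, node_right, acc, True,
    )
    return acc


@njit(cache=True)
def _seed_numba(seed):
    np.random.seed(seed)


# ---------------------------------------------------------------------------
# python-facing API


@dataclass
class Genealogy:
    """An ultrametric coalescent tree over k1 + k2 gene copies.

    Leaves 0..k1-1 belong to cluster I, k1..k-1 to cluster II.  Internal
    node ``k + i`` joins ``left[i]`` and ``right[i]`` at ``node_time[k+i]``.
    """

    k1: int
    k2: int
    node_time: np.ndarray
    left: np.ndarray
    right: np.ndarray

    @property
    def n_leaves(self) -> int:
        return self.k1 + self.k2

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    @property
    def tmrca(self) -> float:
        return float(self.node_time[self.root])

    def parent_array(self) -> np.ndarray:
        k = self.n_leaves
        parent = np.full(2 * k - 1, -1, dtype=np.int64)
        for i in range(k - 1):
            parent[self.left[i]] = k + i
            parent[self.right[i]] = k + i
        return parent

    def branch_lengths(self) -> np.ndarray:
        parent = self.parent_array()
        bl = np.zeros(2 * self.n_leaves - 1)
        has_parent = parent >= 0
        bl[has_parent] = self.node_time[parent[has_parent]] - self.node_time[has_parent]
        return bl

    def leaf_masks(self) -> np.ndarray:
        """Boolean (2k−1, k) matrix: descendants of every node."""
        k = self.n_leaves
        masks = np.zeros((2 * k - 1, k), dtype=bool)
        masks[np.arange(k), np.arange(k)] = True
        for i in range(k - 1):
            masks[k + i] = masks[self.left[i]] | masks[self.right[i]]
        return masks

    def total_length(self) -> float:
        return float(self.branch_lengths().sum())


def _check_sizes(n1: int, n2: int):
    if n1 < 0 or n2 < 0 or n1 + n2 < 1:
        raise ValueError("need at least one sampled diploid")


def simulate_genealogy(
    model: DemographicModel, n1: int, n2: int, seed: int,
    units: str = "diploids",
) -> Genealogy:
    """Simulate one genealogy for n1 + n2 diploids (2n1 + 2n2 gene copies).

    ``units="genes"`` interprets n1/n2 directly as gene-copy counts,
    which is convenient for closed-form checks on small samples.
    """
    _check_sizes(n1, n2)
    sizes, mig = model._epoch_arrays()
    if units == "genes":
        k1, k2 = n1, n2
    elif units == "diploids":
        k1, k2 = 2 * n1, 2 * n2
    else:
        raise ValueError(f"unknown units {units!r}")
    k = k1 + k2
    node_time = np.zeros(2 * k - 1)
    left = np.zeros(k - 1, dtype=np.int64)
    right = np.zeros(k - 1, dtype=np.int64)
    _seed_numba(int(seed) % (2**32))
    _one_tree(k1, k2, sizes, mig, model.t1, model.t2, model.n_anc,
              node_time, left, right)
    return Genealogy(k1=k1, k2=k2, node_time=node_time, left=left, right=right)


def drop_mutations(
    genealogy: Genealogy, locus_length: int, mu: float, seed: int
) -> np.ndarray:
    """Place Poisson infinite-sites mutations; return site patterns.

    Returns a boolean (n_sites, k) array: carriers of the derived allele
    at each segregating site.  Expected site count is
    total branch length × mu × locus_length.
    """
    rng = np.random.default_rng(seed)
    bl = genealogy.branch_lengths()
    n_mut = rng.poisson(bl * mu * locus_length)
    total = int(n_mut.sum())
    if total == 0:
        return np.zeros((0, genealogy.n_leaves), dtype=bool)
    masks = genealogy.leaf_masks()
    patterns = np.repeat(masks, n_mut, axis=0)
    return patterns


def expected_branch_sfs(
    model: DemographicModel, n1: int, n2: int, n_trees: int, seed: int
) -> np.ndarray:
    """Mean branch length per unfolded joint cell, over ``n_trees`` trees.

    ``out[i, j]`` estimates E[length of branches with i descendant gene
    copies in cluster I and j in cluster II], in generations.  Multiplying
    by mu gives the per-site probability of a segregating site in that
    cell (infinite-sites, small-mu regime).
    """
    _check_sizes(n1, n2)
    sizes, mig = model._epoch_arrays()
    return _branch_sfs(
        int(n_trees), 2 * n1, 2 * n2, sizes, mig,
        model.t1, model.t2, model.n_anc, int(seed) % (2**32),
    )


def expected_folded_sfs(
    model: DemographicModel,
    n1: int,
    n2: int,
    n_trees: int,
    seed: int,
    mu: float,
) -> np.ndarray:
    """Per-site probability of each folded joint cell; (0,0) holds the
    monomorphic probability 1 − Σ polymorphic."""
    acc = expected_branch_sfs(model, n1, n2, n_trees, seed)
    probs = fold_joint(acc * mu)
    probs[0, 0] = 0.0
    probs[-1, -1] = 0.0
    total = probs.sum()
    if total >= 1.0:
        # pathological corner (enormous trees × mu); renormalize
        probs = probs / (total + 1e-12) * 0.999999
        total = probs.sum()
    probs[0, 0] = 1.0 - total
    return probs


def simulate_realized_sfs(
    model: DemographicModel,
    n1: int,
    n2: int,
    spec: LocusSpec,
    seed: int,
) -> Folded2DSFS:
    """Realized folded joint spectrum of one simulated dataset.

    Simulates ``spec.n_loci`` genealogies and draws Poisson mutation
    counts per branch (infinite sites); cell (0, 0) holds the remaining
    monomorphic sites out of ``spec.total_sites``.
    """
    sizes, mig = model._epoch_arrays()
    rng = np.random.default_rng(seed)
    acc = _branch_sfs(
        int(spec.n_loci), 2 * n1, 2 * n2, sizes, mig,
        model.t1, model.t2, model.n_anc, int(seed) % (2**32),
    )
    # acc is the per-tree mean; mean × n_loci is the branch-length total
    # over the locus set, so the Poisson mean per cell is
    lam = acc * spec.n_loci * spec.mu * spec.locus_length
    realized_unfolded = rng.poisson(lam).astype(float)
    realized = fold_joint(realized_unfolded)
    n_poly = realized.sum() - realized[0, 0] - realized[-1, -1]
    realized[0, 0] = spec.total_sites - n_poly
    realized[-1, -1] = 0.0
    return Folded2DSFS(
        counts=realized, n1=n1, n2=n2, total_sites=spec.total_sites, seed=seed
    )


def simulate_sfs(
    model: DemographicModel,
    n1: int,
    n2: int,
    spec: LocusSpec,
    n_reps: int,
    seed: int,
) -> tuple[Folded2DSFS, Folded2DSFS]:
    """Expected and realized folded joint spectra.

    The *expected* spectrum uses ``n_reps`` genealogies and reports, per
    polymorphic cell, the expected SNP count over the full locus set
    (plus the expected monomorphic count in (0, 0)).  The *realized*
    spectrum simulates ``spec.n_loci`` genealogies and draws Poisson
    mutation counts per branch — the spectrum a finite dataset would show.
    """
    probs = expected_folded_sfs(model, n1, n2, n_reps, seed, spec.mu)
    L = spec.total_sites
    expected = Folded2DSFS(
        counts=probs * L, n1=n1, n2=n2, total_sites=L, seed=seed
    )
    realized = simulate_realized_sfs(model, n1, n2, spec, seed + 1)
    return expected, realized


def simulate_genotypes(
    model: DemographicModel,
    popmap: PopulationMap,
    spec: LocusSpec,
    missingness: float,
    seed: int,
) -> GenotypeMatrix:
    """Simulate a study-shaped diploid SNP matrix.

    Gene copies are simulated per locus under ``model``, randomly paired
    into diploids within each cluster, and per-call missingness applied
    i.i.d. at the given rate.  SNP columns are emitted only for
    segregating sites; ``total_sites`` records the full sequenced length.
    """
    if not 0.0 <= missingness < 1.0:
        raise ValueError("missingness must be in [0, 1)")
    clusters = popmap.clusters
    if len(clusters) != 2:
        raise ValueError("exactly two clusters required")
    samples1 = popmap.samples_in_cluster(clusters[0])
    samples2 = popmap.samples_in_cluster(clusters[1])
    n1, n2 = len(samples1), len(samples2)
    rng = np.random.default_rng(seed)

    sizes, mig = model._epoch_arrays()
    k1, k2 = 2 * n1, 2 * n2
    k = k1 + k2
    node_time = np.zeros(2 * k - 1)
    left = np.zeros(k - 1, dtype=np.int64)
    right = np.zeros(k - 1, dtype=np.int64)

    sample_order = samples1 + samples2
    columns: list[np.ndarray] = []
    loci: list[LocusRecord] = []
    bases = np.array(["A", "C", "G", "T"])
    for li in range(spec.n_loci):
        _seed_numba(int(rng.integers(0, 2**32 - 1)))
        _one_tree(k1, k2, sizes, mig, model.t1, model.t2, model.n_anc,
                  node_time, left, right)
        tree = Genealogy(k1=k1, k2=k2, node_time=node_time.copy(),
                         left=left.copy(), right=right.copy())
        patterns = drop_mutations(
            tree, spec.locus_length, spec.mu,
            int(rng.integers(0, 2**32 - 1)),
        )
        n_sites = patterns.shape[0]
        if n_sites == 0:
            continue
        # random pairing of gene copies into diploids, per cluster
        perm1 = rng.permutation(k1)
        perm2 = k1 + rng.permutation(k2)
        order = np.concatenate([perm1, perm2])
        genes = patterns[:, order]  # (n_sites, k)
        diploid = genes[:, 0::2].astype(np.int8) + genes[:, 1::2].astype(np.int8)
        site_pos = np.sort(
            rng.choice(spec.locus_length, size=min(n_sites, spec.locus_length),
                       replace=False)
        )
        for s in range(min(n_sites, spec.locus_length)):
            ref, alt = rng.choice(4, size=2, replace=False)
            loci.append(
                LocusRecord(
                    locus_id=f"locus_{li:05d}",
                    site_index=int(site_pos[s]),
                    ref_allele=str(bases[ref]),
                    alt_allele=str(bases[alt]),
                )
            )
            columns.append(diploid[s])

    calls = (
        np.column_stack(columns)
        if columns
        else np.zeros((n1 + n2, 0), dtype=np.int8)
    )
    if missingness > 0 and calls.size:
        mask = rng.random(calls.shape) < missingness
        calls = calls.copy()
        calls[mask] = MISSING
    return GenotypeMatrix(
        samples=sample_order,
        loci=loci,
        calls=calls,
        total_sites=spec.total_sites,
    )
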