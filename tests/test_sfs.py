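"""Folded joint spectrum construction, folding laws and bootstrap imputation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karstdemog import (
    MISSING,
    Folded2DSFS,
    GenotypeMatrix,
    LocusRecord,
    PopulationMap,
    build_folded_2dsfs,
    fold_joint,
    impute_missing,
)


def _matrix(calls, n1, n2, total_sites=None):
    calls = np.asarray(calls, dtype=np.int8)
    samples = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    loci = [LocusRecord(f"l{j}", 0) for j in range(calls.shape[1])]
    gm = GenotypeMatrix(samples=samples, loci=loci, calls=calls,
                        total_sites=total_sites)
    popmap = PopulationMap(
        {s: ("PA" if s.startswith("a") else "PB") for s in samples},
        {"PA": "I", "PB": "II"},
    )
    return gm, popmap


class TestImputation:
    def test_identity_without_missing(self):
        gm, popmap = _matrix([[1, 0], [2, 1], [0, 2], [1, 1]], 2, 2)
        out = impute_missing(gm, popmap, seed=1)
        assert out == gm

    def test_never_changes_observed_calls(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(8, 30)).astype(np.int8)
        miss = rng.random(calls.shape) < 0.3
        calls[miss] = MISSING
        gm, popmap = _matrix(calls, 4, 4)
        out = impute_missing(gm, popmap, seed=9)
        obs = calls != MISSING
        assert np.array_equal(out.calls[obs], calls[obs])
        assert (out.calls != MISSING).all()
        # deterministic given the seed
        out2 = impute_missing(gm, popmap, seed=9)
        assert np.array_equal(out.calls, out2.calls)

    def test_monomorphic_cluster_forces_allele(self):
        calls = [[2], [2], [MISSING], [0], [1], [0]]
        gm, popmap = _matrix(calls, 3, 3)
        out = impute_missing(gm, popmap, seed=3)
        assert out.calls[2, 0] == 2

    def test_fully_missing_cluster_is_an_error(self):
        calls = [[MISSING], [MISSING], [1], [0]]
        gm, popmap = _matrix(calls, 2, 2)
        with pytest.raises(ValueError, match="entirely missing"):
            impute_missing(gm, popmap, seed=1)

    def test_expected_imputed_frequency_matches_cluster(self):
        # cluster I observed alt-gene frequency 0.25 (one het in two
        # typed diploids... use 2 diploids with calls {1, 0} -> 1/4)
        calls = [[1], [0], [MISSING], [1], [1]]
        gm, popmap = _matrix(calls, 3, 2)
        draws = [
            int(impute_missing(gm, popmap, seed=s).calls[2, 0])
            for s in range(10_000)
        ]
        mean_alt_fraction = np.mean(draws) / 2.0
        se = np.sqrt(0.25 * 0.75 / 2 / 10_000)
        assert abs(mean_alt_fraction - 0.25) < 4 * se


class TestFolding:
    def test_single_snp_examples(self):
        # singleton in cluster I -> cell (1, 0)
        gm, popmap = _matrix([[1], [0], [0], [0]], 2, 2)
        s = build_folded_2dsfs(gm, popmap)
        assert s.counts[1, 0] == 1 and s.n_variant == 1
        # alt counts (2n1 - 1, 2n2) fold to (1, 0)
        gm, popmap = _matrix([[1], [2], [2], [2]], 2, 2)
        s = build_folded_2dsfs(gm, popmap)
        assert s.counts[1, 0] == 1

    def test_exact_half_tie_splits(self):
        # alt counts (2, 2) of 8 genes total: i+j == half -> 1/2 each cell
        gm, popmap = _matrix([[1], [1], [1], [1]], 2, 2)
        s = build_folded_2dsfs(gm, popmap)
        assert s.counts[2, 2] == pytest.approx(1.0)  # self-complementary
        gm, popmap = _matrix([[2], [2], [0], [0]], 2, 2)
        s = build_folded_2dsfs(gm, popmap)
        assert s.counts[4, 0] == pytest.approx(0.5)
        assert s.counts[0, 4] == pytest.approx(0.5)

    def test_bruteforce_tally(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 3, size=(7, 20)).astype(np.int8)
        gm, popmap = _matrix(calls, 4, 3, total_sites=1000)
        s = build_folded_2dsfs(gm, popmap)
        # oracle: per-site fold by explicit rule
        expect = np.zeros((9, 7))
        for j in range(20):
            i = int(calls[:4, j].sum())
            jj = int(calls[4:, j].sum())
            half = (8 + 6) / 2
            if i + jj > half:
                expect[8 - i, 6 - jj] += 1
            elif i + jj == half:
                expect[i, jj] += 0.5
                expect[8 - i, 6 - jj] += 0.5
            else:
                expect[i, jj] += 1
        expect[0, 0] += 1000 - 20
        assert np.allclose(s.counts, expect)
        assert s.n_variant == pytest.approx(
            expect.sum() - expect[0, 0] - expect[-1, -1]
        )

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_fold_is_idempotent_and_conserving(self, seed):
        rng = np.random.default_rng(seed)
        g1, g2 = int(rng.integers(2, 9)), int(rng.integers(2, 9))
        counts = rng.poisson(2.0, size=(g1 + 1, g2 + 1)).astype(float)
        folded = fold_joint(counts)
        assert folded.sum() == pytest.approx(counts.sum())
        assert np.allclose(fold_joint(folded), folded)
        # every populated cell obeys the minor-allele rule (or the tie)
        half = (g1 + g2) / 2
        for i in range(g1 + 1):
            for j in range(g2 + 1):
                if folded[i, j] > 0:
                    assert i + j <= half + 1e-9


class TestMarginals:
    def test_single_cell(self):
        counts = np.zeros((5, 5))
        counts[1, 0] = 3
        s = Folded2DSFS(counts=counts, n1=2, n2=2)
        m1, m2 = s.marginals()
        assert m1[1] == 3 and m2[0] == 3

    def test_conservation_and_independent_construction(self):
        rng = np.random.default_rng(8)
        calls = rng.integers(0, 3, size=(6, 25)).astype(np.int8)
        gm, popmap = _matrix(calls, 3, 3)
        s = build_folded_2dsfs(gm, popmap)
        m1, m2 = s.marginals()
        assert m1.sum() == pytest.approx(s.counts.sum())
        assert m2.sum() == pytest.approx(s.counts.sum())


def test_obs_text_round_trip(tmp_path):
    rng = np.random.default_rng(5)
    counts = rng.poisson(3.0, size=(7, 5)).astype(float)
    counts = fold_joint(counts)
    s = Folded2DSFS(counts=counts, n1=3, n2=2, total_sites=500)
    path = tmp_path / "sfs.obs"
    s.to_obs_text(path)
    back = Folded2DSFS.from_obs_text(path, total_sites=500)
    assert np.allclose(back.counts, s.counts)
    assert (back.n1, back.n2) == (3, 2)
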