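"""Composite likelihood arithmetic, AIC selection, bootstrap machinery."""

import math

import numpy as np
import pytest

from karstdemog import (
    BootstrapEnsemble,
    DemographicModel,
    FitConfig,
    Folded2DSFS,
    LocusSpec,
    aic,
    composite_loglik,
    derive_quantities,
    fit_model,
    model_param_names,
    multinomial_ll_bound,
    parametric_bootstrap,
    select_model,
)
from karstdemog.coalescent import expected_folded_sfs
from karstdemog.demography import params_to_model
from karstdemog import study


def _small_model():
    return DemographicModel(
        n_cli_0=800.0, n_clii_0=600.0, n_cli_1=1000.0, n_clii_1=900.0,
        n_anc=700.0, t1=200.0, t2=3000.0, nm_i_ii=1.0, nm_ii_i=1.0,
        migration_window="full",
    )


def _obs_from(model, n1, n2, spec, seed):
    from karstdemog import simulate_realized_sfs

    return simulate_realized_sfs(model, n1, n2, spec, seed)


class TestCompositeLoglik:
    def test_matches_direct_sum_over_cells(self):
        model = _small_model()
        spec = LocusSpec(n_loci=150, locus_length=138, mu=1e-6)
        obs = _obs_from(model, 4, 4, spec, seed=31)
        ll = composite_loglik(obs, model, spec.mu, n_sims=2000, seed=5)
        # oracle: recompute the cell probabilities with the same seed and
        # take sum(m * log10 p) by hand
        probs = expected_folded_sfs(model, 4, 4, 2000, 5, spec.mu)
        mask = obs.polymorphic_mask
        floor = 1.0 / (10 * 2000 * mask.sum())
        expect = float(
            (obs.counts[mask] * np.log10(np.maximum(probs[mask], floor))).sum()
        )
        expect += obs.counts[0, 0] * math.log10(max(probs[0, 0], floor))
        assert ll == pytest.approx(expect, rel=1e-12)

    def test_never_exceeds_multinomial_bound(self):
        model = _small_model()
        spec = LocusSpec(n_loci=150, locus_length=138, mu=1e-6)
        obs = _obs_from(model, 4, 4, spec, seed=37)
        bound = multinomial_ll_bound(obs)
        for seed in (1, 2, 3):
            assert composite_loglik(obs, model, spec.mu, 3000, seed) <= bound

    def test_polymorphic_only_mode_normalizes(self):
        # without the monomorphic cell the polymorphic probabilities are
        # renormalized, so a spectrum concentrated on one likely cell has
        # a small |LL|
        model = _small_model()
        spec = LocusSpec(n_loci=150, locus_length=138, mu=1e-6)
        obs = _obs_from(model, 4, 4, spec, seed=41)
        ll_poly = composite_loglik(obs, model, spec.mu, 2000, 5,
                                   with_monomorphic=False)
        ll_full = composite_loglik(obs, model, spec.mu, 2000, 5,
                                   with_monomorphic=True)
        # the monomorphic term only ever subtracts likelihood mass
        assert ll_poly >= ll_full


class TestAicSelection:
    def test_aic_identity_on_reported_values(self):
        # NP=9, LL=-21,240 -> ~97,832; NP=7, LL=-21,333 -> ~98,256
        assert aic(9, -21_240) == pytest.approx(97_832, abs=1.0)
        assert aic(7, -21_333) == pytest.approx(98_256, abs=1.0)

    def test_parameter_penalty(self):
        # equal LL: the 7-parameter model wins by exactly 4 AIC units
        assert aic(9, -100.0) - aic(7, -100.0) == pytest.approx(4.0)

    def test_select_model_ranks_by_aic(self):
        from karstdemog.demography import FitResult

        fits = [
            FitResult(model_id=i, params={}, ll=ll, n_params=np_,
                      aic=aic(np_, ll), trace=[], seed=0, n_sims=0, mu=0)
            for i, (np_, ll) in enumerate([(7, -110.0), (9, -100.0),
                                           (9, -105.0)], start=1)
        ]
        table = select_model(fits)
        assert table.iloc[0]["model"] == 2
        assert bool(table.iloc[0]["best"])
        assert table["AIC"].is_monotonic_increasing


class TestDerivedQuantities:
    def _ensemble_at_mle(self):
        names = model_param_names(2)
        mle = dict(study.BEST_MLE)
        mle["dt"] = mle.pop("t2") - mle["t1"]
        row = [mle[n] for n in names]
        # tiny jitter so percentiles are well-defined
        est = np.array([row, [v * 1.001 for v in row], [v * 0.999 for v in row]])
        return BootstrapEnsemble(param_names=names, estimates=est, mle=mle,
                                 seeds=[1, 2, 3])

    def test_reported_ratio_arithmetic(self):
        d = derive_quantities(self._ensemble_at_mle(), generation_years=20.0)
        assert round(d.point["ratio_n_cli_0_over_n_cli_1"], 3) == 0.531
        assert round(d.point["ratio_n_clii_0_over_n_clii_1"], 3) == 0.232
        assert round(d.point["ratio_n_cli_1_over_n_anc"], 3) == 2.105
        assert round(d.point["ratio_n_clii_1_over_n_anc"], 3) == 1.696

    def test_time_conversion(self):
        d = derive_quantities(self._ensemble_at_mle(), generation_years=20.0)
        # 24,500 generations at 20 y/generation -> 490 ka
        assert d.point["t2_ka"] == pytest.approx(490.0)
        assert d.point["t1_ka"] == pytest.approx(2.6)

    def test_significance_flags(self):
        d = derive_quantities(self._ensemble_at_mle())
        # size reductions and migration are away from 1.0 in this ensemble
        assert d.significant["ratio_n_clii_0_over_n_clii_1"]
        assert d.significant["nm_ii_i"]


class TestBootstrap:
    def test_percentiles_equal_direct_sort(self):
        est = np.arange(1.0, 101.0).reshape(-1, 1)
        ens = BootstrapEnsemble(param_names=["t1"], estimates=est,
                                mle={"t1": 50.0}, seeds=list(range(100)))
        lo, hi = ens.ci()["t1"]
        assert lo == pytest.approx(np.percentile(est, 2.5))
        assert hi == pytest.approx(np.percentile(est, 97.5))

    def test_single_rep_ci_collapses(self):
        ens = BootstrapEnsemble(param_names=["t1"],
                                estimates=np.array([[7.0]]),
                                mle={"t1": 7.0}, seeds=[1])
        lo, hi = ens.ci()["t1"]
        assert lo == hi == 7.0

    def test_end_to_end_small_bootstrap(self):
        from karstdemog.demography import FitResult

        model = _small_model()
        spec = LocusSpec(n_loci=120, locus_length=138, mu=1e-6)
        names = model_param_names(2)
        params = {
            "n_cli_0": 800.0, "n_clii_0": 600.0, "n_cli_1": 1000.0,
            "n_clii_1": 900.0, "n_anc": 700.0, "t1": 200.0, "dt": 2800.0,
            "nm_i_ii": 1.0, "nm_ii_i": 1.0,
        }
        best = FitResult(model_id=2, params=params, ll=-1000.0, n_params=9,
                         aic=aic(9, -1000.0), trace=[], seed=1, n_sims=500,
                         mu=spec.mu)
        cfg = FitConfig(n_starts=1, n_ecm_cycles=2, n_coal_sims=500, seed=3)
        ens = parametric_bootstrap(best, n1=6, n2=6, spec=spec, n_reps=4,
                                   cfg_boot=cfg, seed=17)
        assert ens.n_reps == 4
        assert ens.estimates.shape == (4, len(names))
        ci = ens.ci()
        assert all(lo <= hi for lo, hi in ci.values())
        # refits stay within the searched ranges
        for k, name in enumerate(names):
            lo, hi = cfg.ranges[name]
            assert (ens.estimates[:, k] >= lo).all()
            assert (ens.estimates[:, k] <= hi).all()


def test_fit_config_yaml_round_trip(tmp_path):
    path = tmp_path / "fit.yaml"
    path.write_text(
        "n_starts: 2\nn_ecm_cycles: 3\nn_coal_sims: 400\nseed: 9\n"
        "ranges:\n  t1: [100, 1000]\n"
    )
    cfg = FitConfig.from_yaml(path)
    assert cfg.n_starts == 2 and cfg.n_coal_sims == 400
    assert cfg.ranges["t1"] == (100, 1000)
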