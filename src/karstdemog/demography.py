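"""Composite-likelihood fitting of two-deme divergence models.

The observed folded joint SFS is treated as a multinomial sample over
frequency-class cells; expected cell probabilities come from Monte-Carlo
coalescent simulation (:func:`karstdemog.coalescent.expected_folded_sfs`).
The monomorphic cell is included by default — without it the model family
is scale-invariant (scaling every size and time by a constant leaves the
normalized polymorphic spectrum unchanged) and absolute sizes/times are
unidentifiable.  Likelihoods are reported in log₁₀ units and model choice
uses AIC = 2·NP − 2·ln(10)·LL.

Optimization follows an expectation-conditional-maximization flavour:
from each random start, parameters are maximized one at a time by a
bracketed step search on the log₁₀ scale, one full pass per cycle, with
common random numbers so each evaluation is a deterministic function of
the parameter vector.  Confidence intervals come from a parametric
bootstrap: datasets simulated at the MLE with the observed geometry are
each refit (started at the MLE, reduced cycles) and percentiles taken.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .coalescent import (
    MODEL_WINDOW,
    DemographicModel,
    LocusSpec,
    expected_folded_sfs,
    simulate_realized_sfs,
)
from .sfs import Folded2DSFS

LN10 = math.log(10.0)

_SHARED_PARAMS = ["n_cli_0", "n_clii_0", "n_cli_1", "n_clii_1", "n_anc", "t1", "dt"]
_MIG_PARAMS = ["nm_i_ii", "nm_ii_i"]

DEFAULT_RANGES: dict[str, tuple[float, float]] = {
    "n_cli_0": (1e2, 1e6),
    "n_clii_0": (1e2, 1e6),
    "n_cli_1": (1e2, 1e6),
    "n_clii_1": (1e2, 1e6),
    "n_anc": (1e2, 1e6),
    "t1": (1e2, 1e7),
    "dt": (1e2, 1e7),
    "nm_i_ii": (1e-2, 1e2),
    "nm_ii_i": (1e-2, 1e2),
}


def model_param_names(model_id: int) -> list[str]:
    """Free parameters: 7 for the no-migration model, 9 otherwise.

    T₂ is reparameterized as T₁ + ΔT so the ordering constraint holds by
    construction.
    """
    if model_id == 1:
        return list(_SHARED_PARAMS)
    return list(_SHARED_PARAMS) + list(_MIG_PARAMS)


def params_to_model(model_id: int, params: dict[str, float]) -> DemographicModel:
    kwargs = {k: params[k] for k in _SHARED_PARAMS if k != "dt"}
    kwargs["t2"] = params["t1"] + params["dt"]
    if model_id != 1:
        kwargs["nm_i_ii"] = params["nm_i_ii"]
        kwargs["nm_ii_i"] = params["nm_ii_i"]
    return DemographicModel(migration_window=MODEL_WINDOW[model_id], **kwargs)


def model_to_params(model: DemographicModel) -> dict[str, float]:
    p = {
        "n_cli_0": model.n_cli_0,
        "n_clii_0": model.n_clii_0,
        "n_cli_1": model.n_cli_1,
        "n_clii_1": model.n_clii_1,
        "n_anc": model.n_anc,
        "t1": model.t1,
        "dt": model.t2 - model.t1,
    }
    if model.model_id != 1:
        p["nm_i_ii"] = model.nm_i_ii
        p["nm_ii_i"] = model.nm_ii_i
    return p


@dataclass
class FitConfig:
    """Search effort and ranges for one fit.

    Defaults are desk-scale; the study-scale analysis used 50 starts,
    40 cycles and 100,000 simulations per likelihood evaluation.
    """

    n_starts: int = 5
    n_ecm_cycles: int = 10
    n_coal_sims: int = 2000
    seed: int = 0
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RANGES)
    )
    with_monomorphic: bool = True
    step0: float = 0.5  # initial step, log10 units
    step_shrink: float = 0.75

    def __post_init__(self):
        if min(self.n_starts, self.n_ecm_cycles, self.n_coal_sims) < 1:
            raise ValueError("counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str) -> "FitConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "ranges" in raw:
            raw["ranges"] = {k: tuple(v) for k, v in raw["ranges"].items()}
        return cls(**raw)


def composite_loglik(
    obs: Folded2DSFS,
    model: DemographicModel,
    mu: float,
    n_sims: int,
    seed: int,
    with_monomorphic: bool = True,
) -> float:
    """Multinomial composite log-likelihood (log₁₀) of the observed SFS.

    Cells with zero simulated probability but observed counts are floored
    at p_floor = 1 / (10 · n_sims · n_cells) to keep the likelihood
    finite under finite simulation.
    """
    probs = expected_folded_sfs(model, obs.n1, obs.n2, n_sims, seed, mu)
    if probs.shape != obs.counts.shape:
        raise ValueError(
            f"spectrum shape mismatch: obs {obs.counts.shape}, model {probs.shape}"
        )
    mask = obs.polymorphic_mask
    n_cells = int(mask.sum())
    p_floor = 1.0 / (10.0 * n_sims * n_cells)

    m_poly = obs.counts[mask]
    p_poly = probs[mask]
    if not with_monomorphic:
        total = p_poly.sum()
        p_poly = p_poly / total if total > 0 else p_poly
    p_poly = np.maximum(p_poly, p_floor)
    ll = float((m_poly * np.log10(p_poly)).sum())
    if with_monomorphic:
        m0 = obs.counts[0, 0]
        if m0 > 0:
            ll += float(m0 * np.log10(max(probs[0, 0], p_floor)))
    return ll


def multinomial_ll_bound(obs: Folded2DSFS, with_monomorphic: bool = True) -> float:
    """Entropy bound Σ m·log10(m/M): the maximum any model can reach."""
    m = obs.counts[obs.polymorphic_mask]
    if with_monomorphic:
        m = np.append(m, obs.counts[0, 0])
    m = m[m > 0]
    M = m.sum()
    return float((m * np.log10(m / M)).sum())


@dataclass
class FitResult:
    model_id: int
    params: dict[str, float]
    ll: float  # log10 composite log-likelihood
    n_params: int
    aic: float
    trace: list[list[float]]  # per start, per cycle best LL
    seed: int
    n_sims: int
    mu: float

    @property
    def model(self) -> DemographicModel:
        return params_to_model(self.model_id, self.params)

    def to_json(self, path: str) -> str:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
        return str(path)

    @classmethod
    def from_json(cls, path: str) -> "FitResult":
        with open(path) as fh:
            return cls(**json.load(fh))


def aic(n_params: int, ll_log10: float) -> float:
    """AIC from a log₁₀ likelihood: 2·NP − 2·ln(10)·LL."""
    return 2.0 * n_params - 2.0 * LN10 * ll_log10


_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def _golden_line(loglik, x, k, lo, hi, n_evals, cache):
    """Golden-section maximization of parameter k on [lo, hi] (log10)."""
    a, b = lo, hi
    c = b - _GOLDEN * (b - a)
    d = a + _GOLDEN * (b - a)

    def f(v):
        cand = x.copy()
        cand[k] = v
        key = round(v, 6)
        if key not in cache:
            cache[key] = loglik(cand)
        return cache[key]

    fc, fd = f(c), f(d)
    for _ in range(max(0, n_evals - 2)):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - _GOLDEN * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + _GOLDEN * (b - a)
            fd = f(d)
    return (c, fc) if fc >= fd else (d, fd)


def _ecm_search(
    loglik_at,
    x0: np.ndarray,
    bounds: np.ndarray,
    n_cycles: int,
    n_sims_full: int,
    coarse_frac: float = 0.6,
    window0: float = 1.2,
    shrink: float = 0.75,
    line_evals: int = 6,
) -> tuple[np.ndarray, float, list[float]]:
    """Cyclic conditional maximization, one bracketed golden-section line
    search per parameter per cycle, on the log10 scale.

    Early cycles run at a quarter of the simulation effort, final cycles
    at full effort; within a fidelity level the evaluations share common
    random numbers, so the per-cycle trace is non-decreasing there.
    """
    x = x0.copy()
    n_coarse = int(coarse_frac * n_cycles)
    coarse_sims = max(200, n_sims_full // 4)
    trace = []
    best = -np.inf
    for cycle in range(n_cycles):
        n_sims = coarse_sims if cycle < n_coarse else n_sims_full

        def loglik(v, _n=n_sims):
            return loglik_at(v, _n)

        if cycle == 0 or cycle == n_coarse:
            best = loglik(x)  # fidelity changed: rebase
        window = max(0.12, window0 * shrink**cycle)
        for k in range(x.size):
            lo = max(bounds[k, 0], x[k] - window)
            hi = min(bounds[k, 1], x[k] + window)
            cache = {round(float(x[k]), 6): best}
            v, val = _golden_line(loglik, x, k, lo, hi, line_evals, cache)
            if val > best:
                x = x.copy()
                x[k] = v
                best = val
        trace.append(best)
    return x, best, trace


def informed_starts(
    obs: Folded2DSFS, model_id: int, mu: float
) -> list[dict[str, float]]:
    """Data-driven starting points for the search.

    Sizes start at Watterson-type estimates from the within-cluster
    marginal segregating-site counts (θ_W = S / (a_n · L) and N = θ_W/4μ);
    the divergence time is swept over a log-spaced grid in units of the
    average size, since it is the least-identified axis; migration starts
    at one migrant per generation.
    """
    L = obs.total_sites if obs.total_sites else int(obs.counts.sum())
    mI, mII = obs.marginals()
    s1 = float(mI[1:].sum()) if mI.size > 1 else 1.0
    s2 = float(mII[1:].sum()) if mII.size > 1 else 1.0
    a1 = float(np.sum(1.0 / np.arange(1, 2 * obs.n1)))
    a2 = float(np.sum(1.0 / np.arange(1, 2 * obs.n2)))
    n1_hat = max(200.0, s1 / (a1 * L) / (4 * mu))
    n2_hat = max(200.0, s2 / (a2 * L) / (4 * mu))
    s_tot = obs.n_variant
    a12 = float(np.sum(1.0 / np.arange(1, 2 * (obs.n1 + obs.n2))))
    na_hat = max(200.0, s_tot / (a12 * L) / (4 * mu))
    nbar = 0.5 * (n1_hat + n2_hat)
    starts = []
    for dt_mult in (0.5, 2.0, 8.0, 32.0):
        p = {
            "n_cli_0": n1_hat,
            "n_clii_0": n2_hat,
            "n_cli_1": n1_hat,
            "n_clii_1": n2_hat,
            "n_anc": na_hat,
            "t1": max(150.0, 0.05 * nbar),
            "dt": max(200.0, dt_mult * nbar),
        }
        if model_id != 1:
            p["nm_i_ii"] = 1.0
            p["nm_ii_i"] = 1.0
        starts.append(p)
    return starts


def fit_model(
    obs: Folded2DSFS,
    model_id: int,
    cfg: FitConfig,
    mu: float = 5.39e-8,
    start_params: dict[str, float] | None = None,
) -> FitResult:
    """Maximize the composite likelihood of one model.

    Starts are drawn log-uniformly from ``cfg.ranges`` (or a single
    user-supplied start).  All evaluations within the search share one
    simulation seed (common random numbers); the reported LL is a fresh
    evaluation at an independent seed so model comparisons are unbiased
    by search-time noise adaptation.
    """
    names = model_param_names(model_id)
    bounds = np.array([np.log10(cfg.ranges[n]) for n in names])
    rng = np.random.default_rng(cfg.seed)
    crn_seed = int(rng.integers(0, 2**31 - 1))
    eval_seed = int(rng.integers(0, 2**31 - 1))

    def loglik_at(logx: np.ndarray, n_sims: int) -> float:
        params = {n: 10.0 ** v for n, v in zip(names, logx)}
        model = params_to_model(model_id, params)
        return composite_loglik(
            obs, model, mu, n_sims, crn_seed, cfg.with_monomorphic
        )

    starts: list[np.ndarray] = []
    if start_params is not None:
        starts.append(np.array([np.log10(start_params[n]) for n in names]))
    else:
        # optimize every data-informed start (they bracket the divergence-
        # time axis, the least-identified direction) plus the best of a
        # screened pool of log-uniform random candidates
        for p in informed_starts(obs, model_id, mu):
            starts.append(
                np.clip(
                    np.array([np.log10(p[n]) for n in names]),
                    bounds[:, 0],
                    bounds[:, 1],
                )
            )
        n_cand = 10 * cfg.n_starts
        cand = rng.uniform(bounds[:, 0], bounds[:, 1], size=(n_cand, len(names)))
        screen_sims = max(200, cfg.n_coal_sims // 4)
        scores = np.array([loglik_at(c, screen_sims) for c in cand])
        for idx in np.argsort(scores)[::-1][: cfg.n_starts]:
            starts.append(cand[idx])

    best_x, best_ll = None, -np.inf
    traces = []
    for x0 in starts:
        x, ll, trace = _ecm_search(
            loglik_at, x0, bounds, cfg.n_ecm_cycles, cfg.n_coal_sims,
            shrink=cfg.step_shrink,
        )
        traces.append(trace)
        if ll > best_ll:
            best_x, best_ll = x, ll
    if not np.isfinite(best_ll):
        raise RuntimeError(
            "non-finite likelihood at every start; widen the search ranges"
        )

    params = {n: float(10.0**v) for n, v in zip(names, best_x)}
    final_model = params_to_model(model_id, params)
    final_ll = composite_loglik(
        obs, final_model, mu, cfg.n_coal_sims, eval_seed, cfg.with_monomorphic
    )
    np_free = len(names)
    return FitResult(
        model_id=model_id,
        params=params,
        ll=final_ll,
        n_params=np_free,
        aic=aic(np_free, final_ll),
        trace=traces,
        seed=cfg.seed,
        n_sims=cfg.n_coal_sims,
        mu=mu,
    )


def select_model(fits: list[FitResult]):
    """Rank fitted models by AIC (ascending); lowest AIC is best."""
    import pandas as pd

    if len(fits) < 2:
        raise ValueError("model selection needs at least two fits")
    rows = [
        {
            "model": f.model_id,
            "NP": f.n_params,
            "LL": f.ll,
            "AIC": f.aic,
        }
        for f in fits
    ]
    df = pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)
    df["delta_AIC"] = df["AIC"] - df["AIC"].iloc[0]
    df["best"] = df.index == 0
    return df


@dataclass
class BootstrapEnsemble:
    param_names: list[str]
    estimates: np.ndarray  # (n_reps, n_params), natural scale
    mle: dict[str, float]
    seeds: list[int]
    n_failed: int = 0

    @property
    def n_reps(self) -> int:
        return self.estimates.shape[0]

    def ci(self, level: float = 0.95) -> dict[str, tuple[float, float]]:
        lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
        out = {}
        for k, name in enumerate(self.param_names):
            out[name] = (
                float(np.percentile(self.estimates[:, k], lo)),
                float(np.percentile(self.estimates[:, k], hi)),
            )
        return out

    def to_json(self, path: str) -> str:
        with open(path, "w") as fh:
            json.dump(
                {
                    "param_names": self.param_names,
                    "estimates": self.estimates.tolist(),
                    "mle": self.mle,
                    "seeds": self.seeds,
                    "n_failed": self.n_failed,
                },
                fh,
                indent=2,
            )
        return str(path)


def parametric_bootstrap(
    best: FitResult,
    n1: int,
    n2: int,
    spec: LocusSpec,
    n_reps: int,
    cfg_boot: FitConfig,
    seed: int,
) -> BootstrapEnsemble:
    """Percentile CIs by simulate-at-MLE-and-refit.

    Each replicate simulates a realized SFS with the observed geometry
    (``n1``/``n2`` diploids, ``spec`` loci) at the MLE, then refits the
    same model starting from the MLE with the reduced ``cfg_boot`` effort.
    """
    names = model_param_names(best.model_id)
    mle_model = best.model
    rng = np.random.default_rng(seed)
    estimates = []
    seeds = []
    n_failed = 0
    for rep in range(n_reps):
        rep_seed = int(rng.integers(0, 2**31 - 1))
        realized = simulate_realized_sfs(mle_model, n1, n2, spec, rep_seed)
        cfg_rep = FitConfig(
            n_starts=1,
            n_ecm_cycles=cfg_boot.n_ecm_cycles,
            n_coal_sims=cfg_boot.n_coal_sims,
            seed=rep_seed,
            ranges=cfg_boot.ranges,
            with_monomorphic=cfg_boot.with_monomorphic,
            step0=cfg_boot.step0,
            step_shrink=cfg_boot.step_shrink,
        )
        try:
            fit = fit_model(
                realized, best.model_id, cfg_rep, mu=best.mu,
                start_params=best.params,
            )
        except RuntimeError:
            n_failed += 1
            continue
        estimates.append([fit.params[n] for n in names])
        seeds.append(rep_seed)
    if not estimates:
        raise RuntimeError("every bootstrap replicate failed")
    return BootstrapEnsemble(
        param_names=names,
        estimates=np.array(estimates),
        mle=dict(best.params),
        seeds=seeds,
        n_failed=n_failed,
    )


@dataclass
class DerivedQuantities:
    """Size-change ratios, event times in ka, and significance flags."""

    point: dict[str, float]
    ci: dict[str, tuple[float, float]]
    significant: dict[str, bool]  # 95% CI excludes 1.0 (ratios, Nm)
    generation_years: float


def derive_quantities(
    ens: BootstrapEnsemble, generation_years: float = 20.0
) -> DerivedQuantities:
    """Ratios and calendar times from a bootstrap ensemble.

    Ratios are computed per replicate, then summarized; times convert
    generations → ka via the generation time.  A quantity is flagged
    significant when its 95% CI excludes 1.0.
    """
    idx = {n: k for k, n in enumerate(ens.param_names)}
    per_rep: dict[str, np.ndarray] = {}
    E = ens.estimates
    per_rep["ratio_n_cli_0_over_n_cli_1"] = E[:, idx["n_cli_0"]] / E[:, idx["n_cli_1"]]
    per_rep["ratio_n_clii_0_over_n_clii_1"] = (
        E[:, idx["n_clii_0"]] / E[:, idx["n_clii_1"]]
    )
    per_rep["ratio_n_cli_1_over_n_anc"] = E[:, idx["n_cli_1"]] / E[:, idx["n_anc"]]
    per_rep["ratio_n_clii_1_over_n_anc"] = E[:, idx["n_clii_1"]] / E[:, idx["n_anc"]]
    ka = generation_years / 1000.0
    per_rep["t1_ka"] = E[:, idx["t1"]] * ka
    per_rep["t2_ka"] = (E[:, idx["t1"]] + E[:, idx["dt"]]) * ka
    for nm in _MIG_PARAMS:
        if nm in idx:
            per_rep[nm] = E[:, idx[nm]]

    mle = ens.mle
    point = {
        "ratio_n_cli_0_over_n_cli_1": mle["n_cli_0"] / mle["n_cli_1"],
        "ratio_n_clii_0_over_n_clii_1": mle["n_clii_0"] / mle["n_clii_1"],
        "ratio_n_cli_1_over_n_anc": mle["n_cli_1"] / mle["n_anc"],
        "ratio_n_clii_1_over_n_anc": mle["n_clii_1"] / mle["n_anc"],
        "t1_ka": mle["t1"] * ka,
        "t2_ka": (mle["t1"] + mle["dt"]) * ka,
    }
    for nm in _MIG_PARAMS:
        if nm in mle:
            point[nm] = mle[nm]

    ci = {}
    significant = {}
    for name, vals in per_rep.items():
        lo, hi = float(np.percentile(vals, 2.5)), float(np.percentile(vals, 97.5))
        ci[name] = (lo, hi)
        if name.startswith("ratio_") or name.startswith("nm_"):
            significant[name] = bool(hi < 1.0 or lo > 1.0)
    return DerivedQuantities(
        point=point, ci=ci, significant=significant,
        generation_years=generation_years,
    )
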