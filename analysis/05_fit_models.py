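#!/usr/bin/env python
"""Fit the four divergence models to the observed spectrum; select by AIC.

Maximizes the composite likelihood of each model (no-migration,
isolation-with-migration, ancient-migration, secondary-contact) on the
spectrum from 04_build_sfs.py at desk-scale search effort, then ranks by
AIC.  Writes the model table and the best fit.
"""

import time
from pathlib import Path

from karstdemog import Folded2DSFS, FitConfig, fit_model, select_model
from karstdemog import study

BASE = Path(__file__).resolve().parent.parent / "results"
SEED = 20260920


def main() -> None:
    obs = Folded2DSFS.from_obs_text(BASE / "observed_sfs.obs",
                                    total_sites=study.N_TOTAL_SITES)
    cfg = FitConfig(n_starts=1, n_ecm_cycles=8, n_coal_sims=4000, seed=SEED)
    fits = []
    for model_id in (1, 2, 3, 4):
        t0 = time.time()
        fit = fit_model(obs, model_id, cfg, mu=study.MU)
        fits.append(fit)
        fit.to_json(BASE / f"fit_model{model_id}.json")
        print(f"model {model_id}: LL = {fit.ll:.1f} (log10), "
              f"AIC = {fit.aic:.1f}  [{time.time() - t0:.0f}s]")

    table = select_model(fits)
    table.to_csv(BASE / "model_selection.tsv", sep="\t", index=False)
    best = int(table.iloc[0]["model"])
    print(f"\nbest model by AIC: {best}")
    print(table)


if __name__ == "__main__":
    main()
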