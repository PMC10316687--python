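"""Published study inputs: sampling design, data geometry and estimates.

These constants are the *inputs* the synthetic-data generator and the
reproduction scripts consume: the per-population sample sizes of the two
genetic clusters, the reduced-representation data geometry, the
sequencing totals, and the reported model table (parameter counts,
log₁₀ likelihoods, AIC, maximum-likelihood estimates with 95% CIs).
"""

from __future__ import annotations

#: diploid individuals per population, by cluster
CLUSTER_I_POPS: dict[str, int] = {
    "KY_H1": 6,
    "KY_B2": 16,
    "KY_B4": 17,
    "KY_B5": 9,
    "KY_B6": 14,
    "KY_C2": 22,
    "KY_C5": 15,
    "CJ_S6": 7,
}
CLUSTER_II_POPS: dict[str, int] = {
    "CD_M1": 7,
    "CD_M3": 8,
    "CD_M4": 23,
    "CD_M5": 10,
    "CD_M6": 7,
    "CD_M7": 26,
}

N_CLUSTER_I = sum(CLUSTER_I_POPS.values())  # 106
N_CLUSTER_II = sum(CLUSTER_II_POPS.values())  # 81
N_SAMPLES = N_CLUSTER_I + N_CLUSTER_II  # 187

#: SFS input-data geometry (re-extracted SNP set)
N_TOTAL_SITES = 242_107
N_VARIANT_SITES = 4_178
N_LOCI = 1_753
LOCUS_LENGTH_BP = 138  # ≈ round(242107 / 1753)

#: sequencing totals
TOTAL_RAW_READS = 462_669_080
MEAN_READS_PER_SAMPLE = 2_474_166

#: mutation rate per site per generation and generation time
MU = 5.39e-8
GENERATION_YEARS = 20.0

#: model-comparison table: parameter count, log10 likelihood, AIC
MODEL_TABLE: dict[int, dict[str, float]] = {
    1: {"NP": 7, "LL": -21_333, "AIC": 98_256},
    2: {"NP": 9, "LL": -21_240, "AIC": 97_832},
    3: {"NP": 9, "LL": -21_246, "AIC": 97_860},
    4: {"NP": 9, "LL": -21_243, "AIC": 97_846},
}
BEST_MODEL_ID = 2

#: best-model (isolation-with-migration) MLEs; times in generations
BEST_MLE: dict[str, float] = {
    "n_cli_0": 5008,
    "n_clii_0": 1766,
    "n_cli_1": 9429,
    "n_clii_1": 7598,
    "n_anc": 4480,
    "t1": 2.6e3 / GENERATION_YEARS,  # 2.6 ka -> 130 generations
    "t2": 490e3 / GENERATION_YEARS,  # 490 ka -> 24,500 generations
    "nm_i_ii": 1.777,
    "nm_ii_i": 2.141,
}

#: 95% CIs of the best model, natural units (sizes diploid, times ka, Nm)
BEST_CI: dict[str, tuple[float, float]] = {
    "n_cli_0": (3266, 6873),
    "n_clii_0": (1185, 2673),
    "n_cli_1": (7794, 11_432),
    "n_clii_1": (5581, 10_148),
    "n_anc": (1602, 8036),
    "t1_ka": (1.3, 5.1),
    "t2_ka": (292, 671),
    "nm_i_ii": (1.437, 2.202),
    "nm_ii_i": (1.744, 2.353),
}

#: reported size-change ratios of the best model (3 dp)
BEST_RATIOS: dict[str, float] = {
    "ratio_n_cli_0_over_n_cli_1": 0.531,
    "ratio_n_clii_0_over_n_clii_1": 0.232,
    "ratio_n_cli_1_over_n_anc": 2.105,
    "ratio_n_clii_1_over_n_anc": 1.696,
}
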