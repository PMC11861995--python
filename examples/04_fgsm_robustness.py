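"""FGSM adversarial sensitivity of an enriched-trained GCN.

Trains the simple GCN under the enriched regime, then perturbs each fold's
pediatric test subjects with that fold's own model (white-box) across a grid
of perturbation sizes and prints the accuracy curve.
"""

from connectogcn import AttackConfig, ModelSpec, TrainConfig, generate_dataset, robustness_sweep, run_regime
from connectogcn.synthetic import benchmark_config

data = generate_dataset(benchmark_config(seed=0))
report = run_regime("enriched", [ModelSpec(name="gcn_simple", n_regions=60)], data,
                    TrainConfig(seed=0))
models = {fold: m for (_, fold), m in report.models.items()}
result = robustness_sweep(models, data, report.plans["deep"], AttackConfig())

print("epsilon      accuracy (%)   AUC")
for _, row in result.summary().iterrows():
    print(f"{row.epsilon:9.1e}   {row.accuracy_mean:6.1f} ± {row.accuracy_sd:4.1f}"
          f"   {row.auc_mean:.2f}")
# The epsilon=0 row is the clean evaluation; accuracy decays (or at worst
# stays flat) as the perturbation budget grows toward 1e-3.
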