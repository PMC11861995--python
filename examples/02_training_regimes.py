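"""Train and evaluate classifiers under the cohort-transfer regimes.

Compares pediatric-only training against adult-enriched training for the
simple GCN and a random-forest baseline on a synthetic benchmark with a
subtle planted sex effect.  The pediatric-stratum accuracy gain under
enrichment is the few-shot transfer effect the pipeline is built to measure.
"""

from connectogcn import ModelSpec, TrainConfig, generate_dataset, run_regime
from connectogcn.synthetic import benchmark_config

data = generate_dataset(benchmark_config(seed=7))
specs = [ModelSpec(name="gcn_simple", n_regions=60), ModelSpec(name="rf", n_regions=60)]
config = TrainConfig(seed=7)

for regime, stratum in (("pediatric_pediatric", "overall"), ("enriched", "pediatric")):
    report = run_regime(regime, specs, data, config)
    s = report.summary()
    print(f"\n{regime} (pediatric test subjects):")
    for _, row in s[s.stratum == stratum].iterrows():
        auc = f"{row.auc_mean:.2f}" if row.auc_mean == row.auc_mean else " n/a"
        print(f"  {row.model:>10}: accuracy {row.accuracy_mean:5.1f} ± {row.accuracy_sd:4.1f} %"
              f"   AUC {auc}")
# Accuracies are mean ± sample SD over the five cross-validation folds;
# enriched training typically lifts the pediatric stratum by several points.
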