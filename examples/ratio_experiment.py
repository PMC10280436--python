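"""Class-ratio experiment: does training at 1:10 beat undersampling to 1:1?

Both arms are evaluated on the SAME untouched 1:10 test partition (the
ratio found in real data); only the training ratio differs. Five seeded
repetitions stand in for cross-validation, which chromosome-holdout splits
rule out.
"""

from tsskit.cascade import CascadeConfig, WDKernel
from tsskit.experiments import CascadeSVMClassifier, ExperimentConfig, run_ratio_experiment
from tsskit.studies import build_learnability_split

split = build_learnability_split(seed=1)
factories = {
    "svm_wd": lambda: CascadeSVMClassifier(CascadeConfig(n_subsets=4, kernel=WDKernel()))
}
config = ExperimentConfig(experiment="ratio", n_repeats=5, base_seed=1)
report = run_ratio_experiment(split, factories, config)

table = report.aggregate()
test_rows = table[table.partition == "test"]
print(test_rows[["classifier", "cell", "accuracy", "bc", "f1", "auc_roc"]].to_string(index=False))
# Each row aggregates five seeded repeats of one training arm; the test
# partition (identical instances in both arms) stays at 1:10 throughout.
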