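"""Train the LSTM sequence classifier on the strong planted-motif fixture.

Protocol: Adam, learning rate 0.001, batch size 32, binary cross-entropy,
at most 100 epochs with early stopping after 10 epochs without validation
improvement (best weights restored).
"""

from tsskit.metrics import evaluate
from tsskit.nn import TrainingConfig, build_architecture, predict_proba, train
from tsskit.studies import LEARNABILITY_WINDOW, build_learnability_split

split = build_learnability_split(seed=1)
spec, network = build_architecture("lstm", LEARNABILITY_WINDOW.length, seed=1)
print(f"architecture: {spec.name}, {network.n_parameters():,} parameters, "
      f"input {spec.input_length} x 4")

history = train(network, split, TrainingConfig(seed=1))
print(f"stopped at epoch {history.stopped_epoch} "
      f"(best validation loss at epoch {history.best_epoch})")

report = evaluate(split.validation.labels(),
                  predict_proba(network, split.validation.sequences()))
print(f"validation: Acc={report.accuracy:.4f} BC={report.binary_cross_entropy:.4f} "
      f"F1={report.f1:.4f} AUC={report.auc_roc:.4f}")
# AUC >= 0.9 shows the recurrent model recovered the planted TSS motif from
# ~60 positive examples at a 1:10 class ratio.
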