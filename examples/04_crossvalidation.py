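"""Stratified 5-fold cross-validation comparing two embedding methods.

Identical folds and classifier seeds across methods, imbalance-aware
metrics per fold, and paired one-sided t-tests across folds for each
method pair.
"""

import lipidte as lt
from lipidte.classify import GBTConfig

records = lt.generate_lipid_library(lt.SynthConfig(seed=0))
embeddings = {
    "cfp": lt.embed_records(records, "cfp"),
    "expert": lt.embed_records(records, "expert"),
}

config = GBTConfig(depth=5, learning_rate=0.05, iterations=300, loss="binary")
report = lt.crossval_experiment(
    records, embeddings, k=5, seed=0, config=config, label_kind="binary"
)

for method, ms in report.aggregate().items():
    print(f"{method:7s} AUC={ms.auc:.3f}  bal.acc={ms.balanced_accuracy:.3f}  "
          f"wF1={ms.weighted_f1:.3f}  MCC={ms.mcc:.3f}")

print("\npaired one-sided t-tests (alternative: first method better):")
for (a, b), metric, p in report.comparisons:
    print(f"  {a} > {b} on {metric:17s} p = {p:.3f}")
# AUC near 1 is expected: the planted tail-count effect is directly visible
# in substructure counts; p-values near 1 mean no direction of improvement.
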