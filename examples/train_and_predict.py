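"""Train an easy-ensemble on a synthetic proteome and call RLBPs.

Generates a labeled proteome with strong class separation (effect size 2,
nucleic-acid-binding rates 0.8 vs 0.1), runs the real featurizer, trains
a 5-model ensemble of balanced random forests, averages the per-protein
probabilities, and applies the candidate (mean >= 0.5) and
high-confidence (mean > 0.8) thresholds.
"""

import rlooppred as rp

spec = rp.SyntheticSpec(n_pos=60, n_neg=600, effect_size=2.0,
                        nucleic_binding_rates=(0.8, 0.1), seed=7)
table, labels = rp.make_benchmark(spec)
positives = set(labels.index[labels == 1])
print(f"feature table: {table.shape[0]} proteins x "
      f"{table.shape[1] - 1} features, {len(positives)} positives")

config = rp.EnsembleConfig(n_models=5, n_negatives_per_model=60,
                           n_trees=100, base_seed=7)
ensemble = rp.train_ensemble(table, positives, config)
print("\nheld-out performance (mean +/- sd across the 5 members):")
print(ensemble.summary().round(3).to_string())

pred = rp.predict_proteome(ensemble, table)
tp = len(pred.high_confidence_ids & positives)
fp = len(pred.high_confidence_ids - positives)
print(f"\ncandidates (mean >= 0.5):       {int(pred.candidate.sum())}")
print(f"high-confidence (mean > 0.8):   {int(pred.high_confidence.sum())}"
      f"  ({tp} true positives, {fp} background)")
print("High held-out MCC plus high-confidence calls dominated by true "
      "positives shows the ensemble recovers the planted class signal.")
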