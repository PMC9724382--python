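"""Train the tree model on epigenetic + energy features and rank them
by SHAP importance.

End-to-end: synthetic corpus -> scores -> stratified split -> balanced
bootstrap training -> held-out correlations -> per-feature SHAP, with
each computed score's 23 positional attributions summed per data point.
"""

import nucleoff as nf
from nucleoff.synthetic import synthetic_adapter_scores

cfg = nf.SyntheticConfig(seed=6, n_studies=2, sites_per_study=400, genome_length=150_000)
ds, truth = nf.generate_dataset(cfg)
nf.score_dataset(ds, adapter_scores=synthetic_adapter_scores(ds, seed=6))

train_ds, test_ds = nf.stratified_split(ds, nf.SplitSpec(seed=6))
train_fm = nf.build_feature_matrix(train_ds)
test_fm = nf.build_feature_matrix(test_ds)

model = nf.train_model(train_fm, nf.ModelConfig.reduced("gbt", seed=6))
rs, rp = nf.evaluate(model, test_fm)
print(f"held-out Spearman={rs:.3f} Pearson={rp:.3f} on {len(test_fm.y)} records\n")

summary = nf.shap_summarize(model, test_fm, sample_size=300, seed=6)
print("SHAP feature importance (mean |summed SHAP|), top 8:")
for i, feat in enumerate(summary.ranking[:8], 1):
    print(f"  {i}. {feat:18s} {summary.importance[feat]:.4f}")
print(
    "\nThe planted complexity signal surfaces through Nucleotide/"
    "Strong-Weak BDM; energies carry the gRNA-target mismatch signal; "
    "the uninformative experimental tracks rank near the bottom."
)
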