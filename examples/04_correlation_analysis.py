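"""Correlate the 19 epigenetic features with cleavage activity.

Generates a small synthetic corpus with a planted complexity-activity
link, computes all scores, and prints the stratified Spearman table —
the planted covariate's analogue (Nucleotide BDM) should dominate.
"""

import nucleoff as nf
from nucleoff.association import STRATUM_ALL, correlation_table, distribution_summary
from nucleoff.synthetic import synthetic_adapter_scores

cfg = nf.SyntheticConfig(seed=4, n_studies=2, sites_per_study=200, genome_length=80_000)
ds, truth = nf.generate_dataset(cfg)
adapters = synthetic_adapter_scores(ds, seed=4)
nf.score_dataset(ds, adapter_scores=adapters)

table = correlation_table(ds, extra_features={"Planted": truth.planted_covariate})
print(f"{len(ds)} records; pooled Spearman correlations with CA:")
cells = [(f, table.cells[(STRATUM_ALL, f)]) for f in table.features]
for feat, cell in sorted(cells, key=lambda fc: -abs(fc[1].spearman if fc[1] else 0)):
    if cell is not None:
        print(f"  {feat:18s} {cell.spearman:+.3f} (n={cell.n})")

summary = distribution_summary(ds, "Nucleotide BDM")
print("\nNucleotide BDM mean per activity bin:")
for b, st in summary.stats.items():
    print(f"  {b:7s} n={st['count']:4d} mean={st['mean']:.2f}")
print(
    "\nLow-complexity (low-BDM) sites concentrate in the lowest-activity "
    "bin, the planted analogue of nucleosome-blocked loci."
)
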