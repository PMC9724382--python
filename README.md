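# nucleoff

Nucleosome-organization and epigenetic descriptors of CRISPR-Cas9
off-target cleavage activity.

Cas9 off-target cleavage is shaped not only by gRNA-DNA sequence
complementarity but by the chromatin context of the locus — above all
by nucleosomes, which physically block Cas9 binding. `nucleoff` is a
library for analyzing that relationship on off-target corpora of
gRNA-target pairs (23 bp target centered in a 169 bp context). It
provides:

* **Computed nucleosome scores at base-pair resolution.** Sliding a
  147 bp nucleosomal window across the context gives 23 windows, one
  per target base. Training-free scorers: GC content (GC147),
  rotational (W/S) and translational (YR) positioning schemes, Block
  Decomposition Method complexity on the nucleotide and strong/weak
  alphabets (BDM = Σ over distinct blocks of complexity +
  log₂ multiplicity), and hard-rod statistical mechanics
  (Percus/Vanderlick) occupancy with a dinucleotide-periodicity energy
  (N = 147, B = 0.16, p = 10.1 bp, μ = -0.6 kT). Adapter contracts
  batch contexts for external dHMM/neural predictors (NuPoP, nuCpos,
  LeNup) and align their per-base output back onto each target.
* **Cross-study activity normalization.** Per-study Box-Cox to a
  Gaussian with mean 0 and σ = 2, clipped to CA ∈ [-4, 4]; rates below
  the assay floor 1e-5 pin to -4. Putative (assumed-inactive) sites —
  genomic windows within <7 mismatches of an experimental target —
  are found by a strand-aware Hamming scan and carry CA = -4.
* **Association analysis.** Per-site aggregation (mean, median for
  binary scores), stratified Spearman/Pearson correlation tables
  (per cell line, gene body vs not, pooled) and activity-binned
  (CA = -4 / ≤2 / >2) distribution summaries.
* **Models + SHAP.** An XGBoost tree model and a small convolutional
  network predict CA from 3 binding-energy features (E_RNA-DNA,
  E_RNA-DNA^corr, E_gRNAfold, with ΔG_B = δ_PAM(ΔG_H − ΔG_U − ΔG_O)),
  6 experimental epigenetic scalars and 13 computed scores × 23
  positions, trained on class-balanced bootstrap batches; SHAP
  attributions (exact TreeSHAP for the tree model, permutation-sampling
  Shapley for the network) are summed per computed score and ranked.
* **A synthetic-data generator** that emulates the corpus shape
  (52% putative, rates over several orders of magnitude, per-cell-line
  tracks, gene bodies) with a planted complexity-activity link for
  end-to-end recovery testing — no downloads needed.

See `docs/methods.md` for models, parameters and limitations.

## Worked example

```bash
python examples/05_train_and_explain.py
```

generates a 2,000-record synthetic corpus with a planted link between
sequence complexity and cleavage rate, computes all 19 features,
trains the tree model and prints:

```
held-out Spearman=0.579 Pearson=0.578 on 333 records

SHAP feature importance (mean |summed SHAP|), top 8:
  1. Nucleotide BDM     1.1500
  2. e_rna_dna          0.4383
  3. W/S scheme         0.2938
  4. Strong-Weak BDM    0.2061
  ...
```

Held-out Spearman/Pearson measure how well the model ranks and fits
unseen sites' activity. The SHAP ranking recovers the planted
structure: Nucleotide BDM — the closest analogue of the planted
complexity covariate — dominates, the hybridization energy carries the
gRNA-target mismatch signal, and the deliberately uninformative
experimental tracks fall to the bottom. The other examples
(`examples/01`–`04`) walk through single-site scoring, rate
normalization, putative-site augmentation and the correlation tables.

A thin CLI wraps the same stages:

```bash
nucleoff simulate --out run/ --seed 1
nucleoff score    --dataset run/dataset.parquet --out run/scored.parquet --synthetic-adapters
nucleoff analyze  --dataset run/scored.parquet --out run/analysis
nucleoff train    --dataset run/scored.parquet --out run/model --model gbt
```

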