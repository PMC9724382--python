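# Methods

`nucleoff` quantifies how epigenetic and nucleosome-organization
descriptors relate to CRISPR-Cas9 off-target cleavage activity. This
note documents the models, the parameters that matter, the numerical
choices, and what the synthetic test corpus does and does not show.

## Site geometry

Every gRNA-(off-)target pair carries a 23 bp target duplex (20 nt
protospacer + 3 nt PAM) centered in a 169 bp sequence context
(169 = 73 + 23 + 73). All coordinates are 0-based half-open; the target
occupies context offsets [73, 96). Sliding a 147 bp nucleosomal window
across the context yields exactly 23 windows, and window *i* centers
its dyad on target base *i*, so every windowed scorer produces one
value per target base pair. Reverse-strand records store the context
already reverse-complemented into gRNA orientation, which keeps all
scorers strand-agnostic. Contexts containing `N` are dropped at load
time (the complexity scorers are undefined on them); the drop count is
logged.

## Cross-study activity normalization

Assays report cleavage frequencies on incompatible scales spanning
several orders of magnitude. Each study is harmonized independently:

1. **Box-Cox transform.** Lambda is chosen by maximum likelihood over
   the grid [-2, 2] in steps of 0.01 (the fitting procedure is not
   pinned down elsewhere; a grid MLE is reproducible and adequate at
   0.01 resolution). Only rates strictly above the assay floor
   participate in the fit.
2. **Affine rescale** so the transformed fitting rates have sample
   mean 0 and sample standard deviation 2 (ddof = 1).
3. **Floor, then clip.** Rates below the lowest reported assay
   accuracy, 1e-5 (including the exact zeros of putative sites), map
   to CA = -4 before any transform; everything else is clipped to
   [-4, 4] (= +-2 sigma). The floor precedes and overrides the
   transform.

The resulting cleavage activity (CA) is monotone nondecreasing in the
raw rate. Activity bins: *lowest* (CA = -4), *low* (-4 < CA <= 2),
*high* (CA > 2); "CA <= 2" is inclusive for *low*.

Per-study transforms are fitted and applied before pooling; pooling
never refits.

## Putative-site augmentation

Datasets are augmented with putative off-target loci: 23 bp windows on
either genomic strand within Hamming distance < 7 of any experimental
target, assumed inactive (CA = -4). The scan uses plain Hamming
distance over the full 23 bp — no PAM-proximal weighting — because
that rule is exactly reproducible and checkable against an exhaustive
oracle. Windows within 73 bp of a contig end (no full context) and
windows at a seed's own locus are excluded. The scan is O(genome x
seeds) by design; large corpora should use an indexed aligner upstream
and feed the results through the same record contract.

## Computed nucleosome-organization scores

Thirteen computed scores per site; six are produced in-package:

* **GC147** — G+C fraction of the 147 bp window.
* **W/S scheme** (rotational positioning) — weak (A/T) bases count +1,
  strong (G/C) -1, weighted by a dyad-centered cosine of period
  10.0 bp and normalized by window length. The exact published
  weighting lives in supplementary material we do not ship; the
  template (phases and weights) is a versioned TSV
  (`nucleoff/data/ws_template.tsv`) with golden-value tests, so the
  convention is frozen and documented rather than guessed.
* **YR scheme** (translational positioning) — pyrimidine-purine
  dinucleotide steps scored against a dyad-centered period-10.1
  template (`yr_template.tsv`), same versioning policy.
* **Nucleotide BDM / Strong-Weak BDM** — Block Decomposition Method
  approximation of algorithmic complexity. The window is cut into
  non-overlapping blocks of 12 symbols (trailing remainder dropped);
  BDM = sum over distinct blocks of (block complexity +
  log2 multiplicity). The Strong-Weak variant first maps G,C -> S and
  A,T -> W. The default block-complexity backend is an **entropy
  surrogate** (block length x per-symbol Shannon entropy, bits): the
  Coding-Theorem-Method lookup tables are an external dataset, so the
  build stays download-free; a `ctm-table` backend loads a
  user-supplied TSV for exact replication. The surrogate preserves the
  property the analysis relies on — repetitive sequences (e.g.
  "ATATAT...") score far below random ones — and the aggregation law
  is tested against a brute-force grouping oracle.
* **VanDerHeijden** — equilibrium statistical mechanics of hard rods
  (nucleosomes) on the padded sequence. The context is padded with 73
  `A` per side (315 bp), giving exactly 169 admissible dyad positions
  aligned to the unpadded context. Each dinucleotide step at offset x
  from a prospective dyad contributes log-weight log(1 + 4B cos(2 pi
  x / p)) if weak-weak, log(1 - 4B cos(.)) if strong-strong, 0 if
  mixed — i.e. the dinucleotide preference p(x) = 0.25 + B cos(.)
  expressed as a relative weight, with the phase origin at the dyad.
  Defaults: footprint N = 147, amplitude B = 0.16, period p = 10.1 bp,
  chemical potential mu = -0.6 kT. Per-base occupancy comes from the
  Percus/Vanderlick forward-backward recursion, computed in log space
  to avoid underflow on long padded sequences; the recursion is tested
  against brute-force enumeration of all rod configurations on toy
  lattices (rod length 5, lattice <= 40).

The remaining seven scores (NuPoP and nuCpos affinity/occupancy/
Viterbi, LeNup) come from external trained predictors that are out of
scope here. The package implements their batching contract — contexts
concatenated with 147 `A` spacers (length 147 + 316 n, with leading
and trailing spacers against end effects; full-scale chunks of 31,645
contexts) — and the alignment of their per-base TSV output back onto
each target. The adapter settings echoed in run manifests are NuPoP
species=1, model=4 and nuCpos species="c", smoothHBA=FALSE,
ActLikePredNuPoP=TRUE. Absent adapter scores are flagged, never
silently zeroed at scoring time.

## Binding-energy features

The biophysical model's four inputs (delta_PAM, dG_H, dG_U, dG_O)
combine into dG_B = delta_PAM (dG_H - dG_U - dG_O) and the three model
features E_RNA-DNA = delta_PAM dG_H, E_RNA-DNA^corr = delta_PAM (dG_H
- dG_O), E_gRNAfold = dG_U. Units are carried opaquely. Datasets that
store only the three derived features bypass the derivation.

## Association analysis

Base-pair scores aggregate to one value per site: mean across the 23
positions for continuous scores, median for binary ones (the Viterbi
state paths are marked binary in the feature registry; all other
scores are continuous). Spearman (average ranks on ties) and Pearson
correlations with CA are tabulated per cell line, gene-body vs
non-gene-body, and pooled. Putative records are included by default
(they are part of the augmented corpus and of the distribution
figures); a flag excludes them for sensitivity analysis. Undefined
cells (constant feature or constant CA, or an empty stratum) are
reported as missing, never as 0. The pooled row uses all records; the
per-site experimental feature value is the coverage-weighted mean of
its track over the 23 bp target (uncovered bases contribute 0; sites
in cell lines without a track get 0). Replicate MNase tracks are
averaged position-wise over the union of covered positions (absent
coverage counts 0 after coverage is logged), min-max rescaled to [0,1]
per cell line (a constant track maps to 0, matching the missing-data
convention), and combined into one feature keyed by cell line.

## Models and SHAP

Two regressors predict CA from the 3 energy features + 6 experimental
scalars + 13 computed scores at base-pair resolution (13 channels x 23
positions, plus 13 presence masks for adapter-backed scores); sequence
identity is deliberately excluded so importances reflect the
descriptors alone. The split is 80/20, stratified on the putative flag
(ratio preserved to +-1 record); every training epoch draws a fresh
bootstrap batch with equal numbers of active (CA > -4) and inactive
(CA = -4) rows (counts differ by at most 1 for odd batch sizes).

* **gbt** — XGBoost, eta 0.5, colsample_bytree 0.7, max_depth 7, one
  boosting round per epoch for 70 epochs (full-scale batch 50,000;
  desk-scale default 5,000). SHAP values are exact TreeSHAP via
  XGBoost's `pred_contribs`.
* **cnn** — a compact numpy-implemented 1-D CNN: conv 13->32->64
  (kernel 3, same padding), batch norm (momentum 0.1), ReLU, global
  average pooling, concatenation with the scalar block, dense 64->1;
  Adam at lr 0.001, minibatches of 256 within each epoch batch
  (full-scale 35,000; desk-scale 2,000), early stopping on a 10%
  validation carve-out with patience 5 (the stopping criterion was an
  open choice; a carve-out with small patience is the conventional
  one). SHAP values come from the in-package permutation-sampling
  Shapley explainer over the 22 feature groups, which is exactly
  additive per row by construction (marginal contributions of one
  ordering telescope).

For every computed score, the 23 positional attributions (plus its
presence mask) are summed into one per-datapoint value; features are
ranked by mean absolute summed SHAP. SHAP summaries default to 2,000
sampled test rows (10,000 is the full-scale setting; both are config
options).

## Synthetic corpus

The generator produces a crisprSQL-shaped corpus testable without any
download. Defaults are the study conditions: 52% putative fraction,
per-study log-normal rates spanning several orders of magnitude with
per-study intercepts a_s ~ N(-10, 0.5) (generating Box-Cox lambda 0),
effect size 2.0, noise sd 1.0, three cell lines, 40% GC, gene bodies
covering ~40% of the genome, one smooth positive MNase-like track per
cell line.

The planted signal: log rate = a_s + effect_size * z + eps, where z is
the Shannon entropy of the dinucleotide distribution of the context's
central 147 bp — a cheap analogue of Nucleotide BDM, so recovery tests
exercise the whole pipeline without depending on the BDM backend. The
genome is a mosaic of 300 bp blocks with bimodal period-2
repetitiveness (repeat units drawn from the background composition so
GC stays roughly uncorrelated with z). Putative records are mutated
copies (Hamming 0-6) of experimental targets planted into the genome —
by construction exactly the acceptance set of the Hamming-scan
augmenter, constructed directly so generation scales to n = 10,000
(the scan itself is verified against an exhaustive oracle on 20 kb
genomes). Both the placement slots and the choice of which target gets
copied are biased toward low-entropy regions (weight e^(-3 (z -
z_min))): putative sites concentrating at low-complexity,
nucleosome-favorable loci is the phenomenon the real corpus shows, and
it gives the pooled lowest-activity bin its low-complexity character.
The other five experimental features (CTCF, DNase I, DRIP, H3K4me3,
RRBS) are uninformative uniform noise; adapter-backed scores are
stationary smoothed noise passed through the real batching/parsing
contract (stationarity matters: drifting noise would encode a record's
position in the batch and leak the class label). Energy terms reward
protospacer matches (-0.5 per matched base), which partially separates
putative copies (0-6 mismatches to a seed target) from experimental
gRNAs (0-3) — a deliberate, realistic secondary signal.

What passing recovery tests shows: the pipeline end-to-end can detect
a planted monotone sequence-complexity-activity link at realistic
noise, ranks its in-model analogue first, and leaves uninformative
features near zero. What it does not show: anything about real Cas9
biophysics, real chromatin tracks, or the real corpus's correlation
magnitudes — those require the deposited data and are out of scope.

## Problem sizes and determinism

Recovery runs use n = 10,000 records (3 studies x 1,600 experimental
sites, 52% putative, 500 kb genome) over five seeds with the
desk-scale model constants; unit tests use a few hundred records. All
randomness in a stage derives from a single integer seed
(`numpy.random.default_rng`); identical config + seed reproduces a
byte-identical dataset, and gbt training (single thread) is
run-to-run reproducible.

## Known limitations

* The entropy-surrogate BDM backend matches the CTM-based published
  scores in ordering behavior, not in absolute value; exact replication
  needs a user-supplied CTM table.
* W/S and YR template weights are this package's documented
  convention, not a byte-level reproduction of the web-platform
  implementations.
* The hard-rod model treats nucleosomes as rigid 147 bp rods with a
  two-category (WW/SS) periodic energy; no breathing, remodeling or
  higher-order structure.
* The Hamming augmenter is quadratic and intended for small genomes
  and contract testing, not genome-scale alignment.
* The CNN is a small stand-in at the scale described for the published
  architecture's epigenetics arm, not a reproduction of it.
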