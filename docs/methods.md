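# Methods

## Model overview

`modsplice` decomposes the splicing impact of a genetic variant into
contributions from five sequence regions, each scored by a dedicated
module, and combines those contributions with small interpretable
models. The decomposition reflects the biology: splice-site strength is
read from narrow consensus windows at the exon-intron junctions, while
enhancer/silencer content is read from the exon body and the proximal
intron. Because the modules are separate, each can be trained on the
data source that probes its region best — annotated junctions for the
splice-site classifiers, random-sequence reporter (MPRA-style)
libraries for the exon and intron regressors — and the only parameters
ever fitted to variant-effect data are the few coefficients of the
composition model.

### Scoring modules

All modules consume one-hot encoded sequence (columns A, C, G, T; `N`
encodes as an all-zero row) and emit the pre-sigmoid activation of
their network as the score `S`, so score differences live on the logit
scale.

| module | input | architecture |
|---|---|---|
| donor | 18 nt (5 exonic + 13 intronic) | MLP, two hidden ReLU layers (64, 32), batch norm + dropout 0.2, sigmoid head |
| acceptor | 53 nt (50 intronic + 3 exonic) | conv 32×15 (valid) → conv 32×1, batch norm + dropout 0.2, dense sigmoid head |
| exon 5′ / exon 3′ | any length | one shared conv 128×15 (same padding) → ReLU → global average pooling → per-head dense |
| intron 5′ / intron 3′ | any length | as exon pair but 256 filters |

The donor hidden sizes are a default, not a constraint; they are
configurable and the parameter count is available from
`ScoringModule.parameter_count()`. The acceptor window is taken as
53 nt; the boundary counting of the intron/exon split is configurable
through `WindowSpec`. Same-padding before global average pooling lets
the 15-wide filters score exons shorter than the filter; the pooling
makes exon and intron modules length-free. The exon (and intron) pair
is trained as a two-headed network with a shared convolution trunk so
that both reporter libraries inform the same filters; `split()` hands
the trunk to the two single-head modules *by reference*, so the shared
weights remain identical objects.

Training uses the binary cross-entropy form
`−(ψ log ψ̂ + (1−ψ) log(1−ψ̂))`, which accepts fractional Ψ targets
unchanged, with Adam (lr 1e-3), an 80/20 train/validation split, and
selection of the epoch with the smallest validation loss; early
stopping waits 5 epochs. Batch normalization follows the activation and
precedes dropout (the order is a free choice; it is fixed for
reproducibility). All training is bit-reproducible on one device given
the seed. Hyperparameter selection, where wanted, is a seeded random
search minimizing validation loss (`random_search`); the selection
criterion is the same as for any single training run.

The neural layers themselves (dense, 1-D convolution via an im2col
matrix product, batch norm, dropout, global average pooling, Adam) are
implemented in `modsplice/nn.py` on numpy in float64. Gradient
correctness is covered by the training tests; the layer set is exactly
what the module architectures need and nothing more.

### Splice-site training data

Positive donor/acceptor examples are the unique annotated splice
junctions — boundaries between consecutive exons of a gene; terminal
exon ends are transcript ends, not splice sites, and are excluded.
Non-canonical junctions are kept as positives. Negatives are sampled
uniformly within the genes that contributed positives (so base
composition is matched), at least one window-length away from any
positive boundary, with a configurable fraction (default 50%) carrying
the canonical GT/AG dinucleotide at the would-be junction so the
classifier cannot reduce to a dinucleotide detector. The default
negative:positive ratio is 1.5.

### Variant processing

A variant is paired with every exon whose window (exon ± the intronic
flanks, `L_a = L_d = 100` nt by default) its reference-allele interval
intersects; an insertion occupies its single anchor base. Each pair is
processed independently against the pristine reference; multi-allelic
records are decomposed first. Alternative sequences preserve the
reference structure exactly — one exon of flexible length flanked by
`L_a` and `L_d` intronic nucleotides:

- SNVs substitute in place;
- insertions/deletions confined to one segment stretch or shrink it,
  and the affected flank is re-extracted to full length;
- a deletion overlapping a splice site removes the deleted span and
  relocates the splice site to the deletion boundary (an exon boundary
  falling strictly inside a length-changing variant maps to the end of
  the alternative allele);
- insertions at a splice site are assigned exonic or intronic by their
  anchor base;
- a deletion that removes an exon entirely is rejected — there is no
  exon left to score;
- minus-strand loci are reverse-complemented into transcript
  orientation inside the extraction layer, so modules never see strand.

Exons shorter than a splice-site window's exonic part are padded with
`N` rather than rejected, keeping very short assay exons scorable.

### Composition models

The nine-parameter Δlogit(Ψ) design (intercept, five ΔS terms, three
indicator × ΔS interactions) is fitted by minimizing the Huber loss
(transition at `huber_delta`, default 1.0) via
`scipy.optimize.least_squares`; this formulation has no auxiliary scale
parameter, so a noise-free design is recovered to machine precision,
and gross outliers enter only linearly. The module weights are never
updated during composition fitting. Zero-variance design columns (for
example when no variant in a small training set touches an exonic
splice-site window) are reported as a warning: the corresponding
coefficients are unidentifiable and take arbitrary values.

Ψ enters and leaves the logit scale through a single clipping point:
`clip_psi` confines values to `[1e-5, 1 − 1e-5]` and `logit` refuses
unclipped boundary values. The competition model for alternative
acceptors (Ψ5) or donors (Ψ3) differences the Δlogit(Ψ) predictions of
the two candidate exons; assuming equal allelic expression, the
heterozygous effect is algebraically half the homozygous one. Splicing
efficiency uses the identical linear machinery with the allelic
log-ratio as response (a pseudocount is available for zero read
counts). Pathogenicity is an unpenalized logistic regression over the
five ΔS values and three indicators (nine parameters); an extended
feature set adds the five reference-allele scores (fourteen
parameters), letting the classifier condition on how strong the
affected elements were to begin with. Splice-disrupting-variant calls
rank by |ΔΨ| — effect magnitude, not direction.

Where one variant affects several exons, per-pair predictions are
always reported; for variant-level evaluation the maximum-|effect| pair
is the intended aggregate.

### Evaluation statistics

Pearson r, RMSE, auROC, and auPR are standard; the precision-recall
curve points come from scikit-learn and the area is integrated with the
trapezoidal rule (deliberately, to match the curve definition used for
reporting, and distinct from average-precision step integration). Model
comparisons resample the paired test items with replacement B = 999
times and report the one-sided basic-bootstrap P value
`(1 + #{d* ≤ 0}) / (B + 1)`, whose floor is 1/(B+1) = 0.001.
Confidence intervals are percentile-bootstrap (B = 1000, 2.5th/97.5th
percentiles, linear interpolation between closest ranks). Resamples on
which a metric is undefined (a single-class draw, a zero-variance
draw) are redrawn and counted.

## Synthetic data generators

The generators exist so every claim in the test suite is checked
against a known ground truth; each is a pure function of its arguments
including the seed, and all outputs re-parse through the standard
readers.

**Mini genome.** A single contig carrying non-overlapping multi-exon
genes on both strands, written as FASTA + GTF. Junction dinucleotides
are GT/AG with probability `canonical_rate` (default 1.0). Defaults —
40-nt exons, 120-nt introns, 150-nt gene margins — keep 100-nt flanks
on-contig and give introns long enough that most intronic variants map
to a single exon while some map to two.

**MPRA-like library.** Random 25-nt sequences in which 0, 1, or 2
copies of a consensus motif (default `GAAGAA`, an exonic-enhancer-like
hexamer) are planted with probabilities (0.5, 0.3, 0.2); the label is
`σ(strength × occurrences + Normal(0, noise_sd))` with strength 4.0 and
noise 0.3 by default. Labels are generated on the logit scale and
squashed deliberately: the truth is then exactly representable by a
conv → ReLU → global-pooling → dense network, so planted-signal
recovery tests have a well-specified optimum, and the three-level truth
makes rank correlation informative despite ties. A motif-free sequence
has noise-free Ψ of exactly σ(0) = 0.5.

**Variant truth set.** SNVs and indels (≤ 10 nt; 5% of indels are
deletions forced across a splice site to exercise boundary relocation)
placed uniformly over exons and their 100-nt flanks. The true
Δlogit(Ψ) is the nine-parameter model with known coefficients applied
to the *actual* module score differences of the generated variant, plus
declared noise; Ψ_ref is drawn uniformly from (0.1, 0.9). Untrained
(seeded) modules suffice here: recovery of the composition coefficients
does not require meaningful module scores, only deterministic ones.

What these generators do **not** emulate: real splice-site consensus
beyond the GT/AG dinucleotide, branchpoints and polypyrimidine tracts,
co-evolved enhancer/silencer grammars, tissue specificity, and
RNA-seq measurement error structure. Passing the planted-signal tests
demonstrates that the architecture and training machinery recover
signals of the assumed form at the assumed strength — not that the
modules trained on these fixtures transfer to real genomes.

## Problem sizes and numerical choices

The test suite and acceptance runs use desk-scale sizes chosen as the
package's own defaults: 12–60 genes for genome fixtures, 300–1500
splice-site examples, a 20,000-sequence exon library with a
5,000-sequence partner library for the two-headed training, 250–2000
variants for recovery tests, and 200 repetitions for bootstrap null
calibration. The planted-signal thresholds (donor validation
AUROC ≥ 0.95, exon held-out Spearman ≥ 0.8 against the noise-free
truth) are comfortably cleared at these sizes (typical values ≈ 1.00
and ≈ 0.92).

Other fixed choices: float64 throughout; He initialization; batch-norm
epsilon 1e-5 and momentum 0.9; BCE on logits in the numerically stable
max-form; ties in SDV ranking broken stably by input order; `N`-padding
(all-zero one-hot rows) contributes nothing to convolution activations;
an empty intronic flank scores 0 by definition.

## Known limitations

- The module architectures are faithful in kind (MLP / conv / shared
  trunk, dropout, batch normalization) but the exact hidden sizes of
  the donor module are a documented default, not a reconstruction.
- Pathogenicity feature sets beyond the fourteen-parameter extended
  design (e.g., conservation-score ensembles) are out of scope.
- Deep-intronic variants (beyond the flanks) are deliberately not
  scored; the flank length caps the model's reach.
- Phasing and compound heterozygotes are not modeled; each variant is
  applied to the pristine reference independently.
- The splicing-efficiency and competition models share the Δlogit(Ψ)
  machinery; no separate architecture is fitted for them beyond the
  response change.
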