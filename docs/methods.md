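# Methods

## Problem and model

Transcriptional infidelity — transcribed RNA differing from its DNA template
beyond classical RNA editing — is treated here as a purely positional label
on the genome: a site either was or was not observed to transcribe
unfaithfully.  The classifier learns to predict, from DNA context alone,
(i) whether a 200 nt window contains at least one infidelity site and
(ii) which subregions of the window contain one.

The architecture is a bidirectional transformer encoder over BPE tokens with
ALiBi positional biases, a CLS sequence head, and a token-merging subregion
head; the exact formulation (attention with per-head linear distance
penalties, mean/max pooling concatenation projected by W^C, the weighted
token loss, and the λ-mixed objective) is given in the README.  Points the
architecture leaves genuinely open, and how this implementation resolves
them:

* **ALiBi direction.** ALiBi is usually stated for causal decoders.  A
  bidirectional encoder needs a symmetric variant; we use the negated
  absolute distance −slopeᵢ·|q−k| with slopes 2^(−8i/h).  A signed-distance
  variant would only require changing `alibi_bias`.
* **Encoder block internals.** Post-norm residual blocks with a GELU
  feed-forward of width 4·d_h, matching the architecture's BERT lineage.
* **What gets pooled.** The merge excludes only CLS.  SEP and PAD positions
  are carried through the pooling windows, but their hidden states are
  zeroed first, so padding content can never affect a subregion score; a
  subregion is *valid* only if at least one of its tokens is a real sequence
  token.  The final pooling window may be partial and is kept.
* **Subregion ground truth.** The training data define a subregion as
  positive when the union of the character spans of its merged tokens
  overlaps at least one site.  This is the only definition consistent with
  nucleotide-resolution region identification, and it makes the invariant
  "sequence label = OR of valid subregion labels" hold for every pooling
  size m, which the suite tests.
* **Attention masking.** PAD keys are masked out of attention (standard
  practice).  With nₜ = 60 and a median of ~40 effective tokens, about a
  third of positions are padding.
* **Probability clamping.** All probabilities are clamped to
  [10⁻⁷, 1−10⁻⁷] before any log or logit, so perturbation Δlogits are
  always finite.
* **Numerics.** Training runs in float32 on a small reverse-mode autograd
  engine over NumPy written for this package (`tirem.autograd`); gradients
  of every op are validated against central finite differences in float64.
  The engine releases computation graphs eagerly after each backward pass so
  long training loops run at constant memory.

## Tokenizer

Classical BPE: start from the unique corpus characters, repeatedly merge
the most frequent adjacent pair until the vocabulary (characters included)
reaches the target size or no pair occurs twice.  Frequency ties are broken
by the lexicographically smallest merged string, making training fully
deterministic.  Encoding applies merges greedily in learned order
(equivalently: repeatedly apply the lowest-rank merge present — a merge can
only create pairs of later rank).  The vocabulary target of 4096 counts
non-special tokens; CLS/SEP/PAD/UNK live outside it (if a downstream
vocabulary counts specials inside 4096, the comparison is off by four).
Sequences that tokenize beyond nₜ raise an error rather than truncate,
because truncation would silently drop labelled nucleotides.  On uniform
DNA a 4096-token vocabulary yields mean token length ≈ 5, hence a median of
~40 effective tokens per 200 nt sequence; the acceptance script recomputes
this number from scratch.

## Training recipe

The recipe is this package's own: AdamW (weight decay 0.01), learning rate
1e-3 for the tiny preset (3e-4 default, 1e-4 recommended at 768-d scale),
linear warmup over the first 5% of steps, gradient-norm clipping at 1.0,
dropout 0.1, early stopping on validation AUROC, every random consumer
seeded.  λ = 0.2 and m = 20 are the package defaults.  The interpretation
model is retrained *sequence-level only* on the 201 nt site-centered
dataset; the two-layer checkpoint is not reused.

## Synthetic data: what it emulates and what it does not

`tirem.syndata` emulates the statistical situation of a genome annotated
with infidelity calls:

* **Background**: i.i.d. bases with P(G)=P(C)=gc_content/2 (default 0.5) —
  the simplest null consistent with composition analyses.
* **Sites**: independent per-base Bernoulli events.  The default density is
  10⁻³/nt, the magnitude reported for strongly elevated infidelity in
  hybrid lineages.  Sites are uniform (no clustering model) and carry no
  substitution type, since the classifier's labels are positional.
* **Coding intervals**: exponential lengths (mean 300 nt, clipped to
  [60, 2000]) with exponential gaps tuned to the requested coverage
  (default 0.35).  Most intervals are shorter than a 200 nt window, which
  is why negative windows — drawn from coding regions only, as the sampling
  scheme prescribes — are the scarce class in candidate extraction.
* **Planted motif**: with probability `motif_placement_prob` per site, the
  motif is written at a uniform offset in `motif_offset_range` (default
  start offsets −30…+24, i.e. wholly within ±30 nt of the site).

It does **not** emulate polyploid genome structure, homeologous duplicates,
RNA-editing-like substitution processes, site clustering, strand effects,
or realistic k-mer composition.  Passing tests therefore demonstrate that
the pipeline recovers a planted, localized sequence determinant under
honest train/test separation — not that real infidelity has such
determinants.  One caveat is accepted deliberately in the sampling design:
with a 10 nt step and 200 nt windows, overlapping windows share sites, so
train and test windows are not genomically disjoint; we keep all candidates
before sampling and flag the leakage here.

### The planted-motif benchmark

The end-to-end tests use a 1 Mb genome (20 × 50 kb) with CACCTG planted at
80% of sites and site density 5·10⁻³/nt — above the generator default.
The density was fixed by a signal-ceiling analysis *before any training
run*: a positive window must usually contain a planted copy for window
labels to be learnable from the motif at all.  At density d and window
L = 200, positives carry Poisson(dL | ≥1) sites, so
P(no planted copy | positive) = (e^(−0.8·dL) − e^(−dL))/(1 − e^(−dL));
at d = 10⁻³ an ideal motif detector tops out near AUROC 0.89, below the
0.90 acceptance bar — the dataset, not the model, would fail.  At
d = 5·10⁻³ the ceiling is ≈ 0.93, so the bar genuinely measures the model.
Desk-scale sizes (stated as the package's own choices): 2 500 windows per
class split 8:1:1; vocabulary 1024 (a 4096 vocabulary cannot be estimated
from 1 Mb, and 512 tokenizes tail sequences past nₜ = 60); tiny preset;
six epochs.  The direction-only sweeps retrain at windows {100, 300} and at
λ ∈ {0.1, 0.9} on reduced sets, with one shared vocabulary across window
lengths; sweep models are trained to convergence so that the architectural
effect, not residual undertraining, sets the direction.  The attribution
benchmark perturbs 8 motif-bearing, correctly-predicted centered sequences
(196 positions × 100 replacements each) and ranks the planted motif against
20 random-hexamer decoy PFMs by summed |IS^TF|.

## Interpretation stack: numerical choices

* Replacement hexamers are uniform over the 4095 non-identical hexamers,
  with an independent seeded stream per (sequence, position).
* Natural log throughout (logit, PWM log-odds).
* The sigmoid standardization of PWM scores makes the 0.999 cutoff a fixed
  raw-score threshold ln 999 ≈ 6.907 *independent of motif length*, which
  intrinsically favours long motifs; the rule is implemented literally and
  this bias should be kept in mind when comparing motifs of different
  lengths.
* Only the forward strand is scanned by default (`reverse_complement=True`
  is available); upstream site calling is assumed strand-resolved.
* Motifs shorter than 6 nt have no hexamer window inside their footprint
  and are skipped with a warning.
* Group (family/class) tracks are binding-count-weighted means; positions a
  group never binds are reported as missing, never zero-filled.
* Smoothing ("window 10") uses a centered triangular kernel spanning
  2·⌊w/2⌋+1 positions with edge and missing-value renormalization;
  window 1 is the identity.
* Hexamer-track positions are reported 1-based in [1, 196] to match the
  j-indexing convention of the formulas, with 0-based genomic coordinates
  available alongside.

## Known limitations

* Full-scale (768-d, 12-layer) training is implemented but impractical
  without an accelerated backend; the tiny preset is the tested path.
* No masked-language-model pretraining: models train from scratch, so the
  transfer-learning benefit a pretrained DNA language model would bring is
  absent.
* `filter_and_balance` warns and takes all samples when a class cannot fill
  its quota, which silently unbalances very small genomes.
* AUPRC is step-interpolated average precision (conservative); trapezoidal
  PR integration would read slightly higher.
* The subregion-validity rule treats UNK like a real token; datasets filter
  'N' upstream, so UNK in training data indicates a pipeline bug rather
  than a modelling choice.
* On planted-motif data the window-length sweep cannot fully decouple the
  two trends it probes: lengthening the window raises the expected number
  of planted copies per positive window and increases the overlap between
  step-10 windows, so subregion detectability improves alongside sequence
  detectability and can offset the prevalence dilution that drives the
  subregion-level trend downward on real data.  The sequence-level
  direction (AUROC non-decreasing in window length) reproduces at desk
  scale; the subregion-level direction should only be expected on data
  whose per-window signal is length-independent.
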