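# tirem — transcriptional-infidelity region modelling

`tirem` identifies genomic regions prone to **transcriptional infidelity** —
RNA–DNA sequence differences that arise when transcription departs from
strict complementary base pairing — from DNA context alone, and explains
*why* the model calls a region infidelity-prone in terms of position-specific
hexamers and transcription-factor binding motifs.  It is aimed at
regulatory-genomics researchers studying RNA–DNA differences (for example in
hybrid/polyploid lineages, where infidelity rates can reach ~10⁻³ per base)
who have a reference genome and a table of infidelity site calls but no
mechanistic picture of the surrounding sequence determinants.

## The model

Input windows of 200 nt are BPE-tokenized (vocabulary 4096, learned from the
genome; a 200 nt window compresses to a median of ~40 effective tokens),
framed as `[CLS] t₁ … t_k [SEP] [PAD]…` to a fixed nₜ = 60 tokens, and
embedded into **M** ∈ ℝ^{nₜ×d_h}.  A stack of transformer encoder blocks
(d_h = 768, 12 layers, 12 heads at full scale; a 64/2/4 "tiny" preset trains
from scratch on a CPU) contextualizes the tokens.  Position enters only
through **ALiBi**: head *i* adds −slopeᵢ·|q−k| to its attention logits,
slopeᵢ = 2^(−8i/h), symmetric because the encoder is bidirectional:

    Headᵢ = softmax(QᵢKᵢᵀ/√d_k + Bᵢ) Vᵢ

Two heads make the classifier *two-layer* in the label sense:

* **sequence level** — the CLS state → linear + sigmoid → pᵢ, trained with
  plain binary cross-entropy ℓ_sequence;
* **subregion level** — the remaining token states Mᵗ are merged m = 20 at a
  time (non-overlapping mean- *and* max-pooling, concatenated, projected by
  W^C ∈ ℝ^{2d_h×d_h}), each merged "m-token" → linear + sigmoid → p_{i,t},
  trained with a validity-masked, positive-reweighted cross-entropy ℓ_token
  whose positive weight w is the valid-negative/valid-positive count ratio.

The joint objective is `L = λ·ℓ_sequence + (1−λ)·ℓ_token` with λ = 0.2.
Sequence-level performance is reported as AUROC (balanced data), subregion
level as AUPRC (imbalanced data).

The interpretability stack perturbs each hexamer of a 201 nt site-centered
sequence 100 times and takes the median log-odds drop as its importance
IS^hexamer; PWM scanning (JASPAR PFMs, pseudocount 0.5, uniform background,
sigmoid-standardized scores cut at 0.999) lifts hexamer tracks to TF-level
scores IS^TF, and binding-count-weighted averaging aggregates those into
family/class tracks IS^Family/Class.

Because real infidelity site tables of this kind are rarely public, the
package ships a first-class synthetic-genome simulator (`tirem.syndata`): i.i.d.
background sequence, point infidelity sites at a configurable density,
coding intervals, and an optional motif planted near sites — a benchmark
with a known ground truth that the whole pipeline, training through
attribution, is tested against.

## Worked example

```bash
tirem simulate --n-contigs 4 --contig-length 20000 --site-density 0.005 \
    --planted-motif CACCTG --motif-placement-prob 0.8 --seed 1 --out run/genome
# contigs=4 sites=391 coding_intervals=104

tirem build-dataset --fasta run/genome/genome.fa --sites run/genome/sites.bed \
    --coding run/genome/coding.bed --n-per-class 500 --seed 1 --out run/data
# (warns: only 489 negative windows in 80 kb of coding sequence)
# train=791 validation=99 test=99

tirem train-tokenizer --fasta run/genome/genome.fa --vocab-size 1024 \
    --seed 1 --out run/vocab
# vocabulary=1024 merges=1020

tirem train --data run/data --fasta run/genome/genome.fa \
    --sites run/genome/sites.bed --coding run/genome/coding.bed \
    --vocab run/vocab --preset tiny --epochs 4 --seed 1 --out run/model
# best val AUROC=0.9596

tirem evaluate --checkpoint run/model/checkpoint.npz --vocab run/vocab \
    --data run/data --fasta run/genome/genome.fa --sites run/genome/sites.bed \
    --coding run/genome/coding.bed --out run/eval
# auroc_seq=0.9478 auprc_sub=0.6860
```

The vocabulary directory holds two plain-text files: `tokens.txt` (one
token string per line, the first four being the single characters) and
`merges.txt` (one space-separated merge pair per line, in learned order) —
any vocabulary in this format, including one exported from another DNA
language model, can be dropped in.

`auroc_seq` is the probability that a held-out infidelity window outranks a
held-out clean window; `auprc_sub` is average precision over all valid
subregions (three ~67 nt thirds of each window at m = 20), whose positive
prevalence here is ~0.25 — so 0.69 means the model localizes sites well
inside the windows it flags.  `tirem interpret` then writes per-position
hexamer importance tracks and a TF binding-hit table, and `tirem aggregate`
turns those into smoothed family/class importance curves.

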