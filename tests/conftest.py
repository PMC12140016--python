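"""Shared fixtures: the planted-motif benchmark and models trained on it.

The benchmark genome plants the CACCTG motif near 80% of its infidelity
sites at an elevated site density (5e-3/nt) so that positive windows carry,
on average, more than one site and the planted signal — not background
fluctuation — determines the labels.  All expensive artifacts (BPE
vocabulary, trained classifiers, perturbation tracks) are session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from tirem import datasets as ds
from tirem import interpret as itp
from tirem import syndata
from tirem import tokenizer as tk
from tirem import training_eval as tev
from tirem.model import ModelConfig

BENCH_SIM = syndata.SimConfig(
    n_contigs=20, contig_length=50_000, gc_content=0.5, site_density=5e-3,
    coding_fraction=0.35, planted_motif="CACCTG", motif_placement_prob=0.8,
    seed=11)
BENCH_VOCAB_SIZE = 1024
BENCH_N_PER_CLASS = 2500
PLANTED = "CACCTG"


def subset(enc: tev.EncodedData, idx) -> tev.EncodedData:
    return tev.EncodedData(enc.ids[idx], enc.mask[idx], enc.y_seq[idx],
                           enc.y_sub[idx], enc.V[idx])


@pytest.fixture(scope="session")
def bench_genome() -> syndata.SyntheticGenome:
    return syndata.simulate_genome(BENCH_SIM)


@pytest.fixture(scope="session")
def bench_vocab(bench_genome) -> tk.Vocabulary:
    corpus = [bench_genome.contigs[f"contig{i}"] for i in range(1, 7)]
    return tk.train_bpe(corpus, vocab_size=BENCH_VOCAB_SIZE)


@pytest.fixture(scope="session")
def bench_split(bench_genome) -> ds.DatasetSplit:
    pos, neg = ds.training_candidates(bench_genome)
    balanced = ds.filter_and_balance(pos, neg, n_per_class=BENCH_N_PER_CLASS,
                                     seed=3)
    return ds.split(balanced, seed=3)


@pytest.fixture(scope="session")
def bench_encoded(bench_split, bench_vocab) -> dict[str, tev.EncodedData]:
    return {name: tev.encode_windows(getattr(bench_split, name),
                                     bench_vocab, 60, 20)
            for name in ("train", "validation", "test")}


@pytest.fixture(scope="session")
def trained_model(bench_encoded, bench_vocab):
    """Tiny two-layer classifier trained on the planted-motif windows."""
    cfg = ModelConfig.tiny(vocab_size=bench_vocab.size, seed=7)
    recipe = tev.TrainRecipe(epochs=6, batch_size=64, lr=1e-3, seed=7,
                             patience=2)
    model, history = tev.train(bench_encoded["train"],
                               bench_encoded["validation"], cfg, recipe)
    return model, history


@pytest.fixture(scope="session")
def interp_setup(bench_genome, bench_vocab):
    """Sequence-level-only model on 201 nt centered sequences, plus scorer."""
    positives, negatives = ds.build_interpretation_set(
        bench_genome, n_pos=1500, n_neg=1500, seed=5)
    enc = tev.encode_centered(positives, negatives, bench_vocab, 60, 20)
    rng = np.random.default_rng(5)
    order = rng.permutation(len(enc))
    n_val = len(enc) // 10
    train_enc = subset(enc, order[n_val:])
    val_enc = subset(enc, order[:n_val])
    cfg = ModelConfig.tiny(vocab_size=bench_vocab.size, seed=9)
    recipe = tev.TrainRecipe(epochs=4, batch_size=64, lr=1e-3, seed=9,
                             patience=2)
    model, history = tev.train(train_enc, val_enc, cfg, recipe,
                               sequence_only=True)
    scorer = itp.make_scorer(model, bench_vocab)
    return {"model": model, "scorer": scorer, "positives": positives,
            "history": history}


def motif_occurrences(sequence: str, motif: str = PLANTED) -> list[int]:
    out, start = [], 0
    while True:
        j = sequence.find(motif, start)
        if j < 0:
            return out
        out.append(j)
        start = j + 1


@pytest.fixture(scope="session")
def hexamer_benchmark(interp_setup):
    """Perturbation tracks for motif-bearing, correctly-predicted positives."""
    scorer = interp_setup["scorer"]
    chosen: list[tuple[str, list[int]]] = []
    for s in interp_setup["positives"]:
        occ = motif_occurrences(s.sequence)
        if occ and float(scorer([s.sequence])[0]) >= 0.5:
            chosen.append((s.sequence, occ))
        if len(chosen) == 8:
            break
    assert len(chosen) >= 4, "benchmark needs motif-bearing valid positives"
    tracks = [itp.hexamer_importance(scorer, seq, C=100, seed=101 + i,
                                     seq_id=i)
              for i, (seq, _) in enumerate(chosen)]
    return {"sequences": [seq for seq, _ in chosen],
            "occurrences": [occ for _, occ in chosen],
            "tracks": tracks}
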