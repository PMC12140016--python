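"""Training loop, AUROC/AUPRC evaluation, and parameter-sweep harnesses.

Sequence-level performance is summarized by AUROC (the dataset is balanced
by construction); subregion-level performance by AUPRC (subregion labels are
heavily imbalanced), pooled over all valid subregions of the evaluated
sequences.  AUROC is the Mann–Whitney probability that a random positive
outscores a random negative (ties at half credit); AUPRC is step-interpolated
average precision.

Training uses AdamW with linear warmup, gradient-norm clipping and early
stopping on validation AUROC; every random consumer is seeded so a rerun with
the same recipe reproduces the history exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import (average_precision_score,
                             precision_recall_curve, roc_auc_score, roc_curve)

from . import datasets as ds
from .model import (Model, ModelConfig, combined_loss, sequence_loss,
                    token_loss)
from .tokenizer import Vocabulary, encode


# -- metrics --------------------------------------------------------------
def auroc(labels, scores) -> float:
    """P(random positive outscores random negative), ties counted half."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUROC requires both classes present")
    return float(roc_auc_score(labels, scores))


def auprc(labels, scores) -> float:
    """Average precision (step interpolation of the PR curve)."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("AUPRC requires at least one positive")
    return float(average_precision_score(labels, scores))


@dataclass
class EvalReport:
    auroc_seq: float
    auprc_sub: float
    n_pos_seq: int
    n_neg_seq: int
    n_pos_sub: int
    n_neg_sub: int
    roc_points: Optional[dict] = None  # fpr/tpr/threshold arrays
    pr_points: Optional[dict] = None   # precision/recall/threshold arrays

    def to_json(self, path: Path | str) -> None:
        d = asdict(self)
        for key in ("roc_points", "pr_points"):
            if d[key] is not None:
                d[key] = {k: np.asarray(v).tolist() for k, v in d[key].items()}
        Path(path).write_text(json.dumps(d, indent=2))


# -- encoding -------------------------------------------------------------
@dataclass
class EncodedData:
    """Token matrices plus both label layers for a set of sequences."""

    ids: np.ndarray     # (N, n_t) int32
    mask: np.ndarray    # (N, n_t) int8
    y_seq: np.ndarray   # (N,)
    y_sub: np.ndarray   # (N, n_subregions)
    V: np.ndarray       # (N, n_subregions)

    def __len__(self) -> int:
        return self.ids.shape[0]


def encode_windows(samples: Sequence[ds.WindowSample], vocab: Vocabulary,
                   n_t: int, m: int) -> EncodedData:
    n_sub = -(-(n_t - 1) // m)
    N = len(samples)
    ids = np.zeros((N, n_t), dtype=np.int32)
    mask = np.zeros((N, n_t), dtype=np.int8)
    y_seq = np.zeros(N, dtype=np.int8)
    y_sub = np.zeros((N, n_sub), dtype=np.int8)
    V = np.zeros((N, n_sub), dtype=np.int8)
    for i, w in enumerate(samples):
        tok = encode(w.sequence, vocab, n_t)
        ids[i] = tok.ids
        mask[i] = tok.attention_mask
        y_seq[i] = w.label
        y_sub[i], V[i] = ds.subregion_labels(w, tok, m)
    return EncodedData(ids, mask, y_seq, y_sub, V)


def encode_centered(positives: Sequence[ds.CenteredSequence],
                    negatives: Sequence[ds.CenteredSequence],
                    vocab: Vocabulary, n_t: int, m: int) -> EncodedData:
    """Centered 201 nt sequences for sequence-level-only training."""
    n_sub = -(-(n_t - 1) // m)
    seqs = list(positives) + list(negatives)
    N = len(seqs)
    ids = np.zeros((N, n_t), dtype=np.int32)
    mask = np.zeros((N, n_t), dtype=np.int8)
    y_seq = np.zeros(N, dtype=np.int8)
    for i, s in enumerate(seqs):
        tok = encode(s.sequence, vocab, n_t)
        ids[i] = tok.ids
        mask[i] = tok.attention_mask
        y_seq[i] = int(s.center_is_site)
    return EncodedData(ids, mask, y_seq,
                       np.zeros((N, n_sub), dtype=np.int8),
                       np.ones((N, n_sub), dtype=np.int8))


# -- optimizer ------------------------------------------------------------
class AdamW:
    def __init__(self, params: dict, lr: float = 3e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self, lr_scale: float = 1.0) -> None:
        self.t += 1
        lr = self.lr * lr_scale
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            p.data = p.data - lr * (mhat / (np.sqrt(vhat) + self.eps)
                                    + self.wd * p.data)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


@dataclass
class TrainRecipe:
    epochs: int = 10
    batch_size: int = 64
    lr: float = 3e-4           # 1e-4 is preferred at full (768-d) scale
    weight_decay: float = 0.01
    warmup_frac: float = 0.05
    grad_clip: float = 1.0
    patience: int = 3          # early-stopping patience on validation AUROC
    seed: int = 0
    log_path: Optional[str] = None


def _clip_grads(params: dict, max_norm: float) -> None:
    total = 0.0
    for p in params.values():
        if p.grad is not None:
            total += float((p.grad ** 2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm:
        scale = max_norm / (norm + 1e-12)  # python float: no dtype promotion
        for p in params.values():
            if p.grad is not None:
                p.grad = p.grad * scale


def train(train_data: EncodedData, val_data: EncodedData, cfg: ModelConfig,
          recipe: TrainRecipe = TrainRecipe(),
          sequence_only: bool = False) -> tuple[Model, list[dict]]:
    """Train a model; returns the best-validation-AUROC parameters.

    ``sequence_only`` optimizes the plain sequence BCE alone (the setting
    used for the interpretation model on centered sequences).
    """
    if len(train_data) == 0 or len(val_data) == 0:
        raise ValueError("train and validation sets must be non-empty")
    model = Model(cfg)
    opt = AdamW(model.params, lr=recipe.lr, weight_decay=recipe.weight_decay)
    rng = np.random.default_rng(recipe.seed)
    drop_rng = np.random.default_rng(recipe.seed + 1)
    n = len(train_data)
    steps_per_epoch = max(1, -(-n // recipe.batch_size))
    total_steps = steps_per_epoch * recipe.epochs
    warmup = max(1, int(total_steps * recipe.warmup_frac))

    history: list[dict] = []
    best = (-np.inf, None)
    bad_epochs = 0
    step = 0
    for epoch in range(recipe.epochs):
        order = rng.permutation(n)
        sums = np.zeros(3)
        for a in range(0, n, recipe.batch_size):
            idx = order[a:a + recipe.batch_size]
            p_seq, p_sub = model.forward_tensors(
                train_data.ids[idx], train_data.mask[idx],
                training=True, rng=drop_rng)
            l_seq = sequence_loss(train_data.y_seq[idx], p_seq)
            if sequence_only:
                loss = l_seq
                l_tok_val = 0.0
            else:
                l_tok = token_loss(train_data.y_sub[idx], p_sub,
                                   train_data.V[idx])
                loss = combined_loss(l_seq, l_tok, cfg.lam)
                l_tok_val = float(l_tok)
            if not np.isfinite(float(loss)):
                raise RuntimeError(
                    f"training diverged: non-finite loss at step {step} "
                    f"(epoch {epoch}); lower the learning rate")
            opt.zero_grad()
            loss.backward()
            _clip_grads(model.params, recipe.grad_clip)
            step += 1
            opt.step(lr_scale=min(1.0, step / warmup))
            sums += (float(loss), float(l_seq), l_tok_val)

        preds = model.predict(val_data.ids, val_data.mask)
        val_auroc = auroc(val_data.y_seq, preds.p_seq)
        valid = val_data.V.reshape(-1) > 0
        sub_labels = val_data.y_sub.reshape(-1)[valid]
        val_auprc = (auprc(sub_labels, preds.p_sub.reshape(-1)[valid])
                     if not sequence_only and sub_labels.sum() > 0 else None)
        rec = {"epoch": epoch, "loss": sums[0] / steps_per_epoch,
               "l_sequence": sums[1] / steps_per_epoch,
               "l_token": sums[2] / steps_per_epoch,
               "val_auroc": val_auroc, "val_auprc": val_auprc}
        history.append(rec)
        if recipe.log_path:
            with open(recipe.log_path, "a") as fh:
                fh.write(json.dumps(rec) + "\n")
        if val_auroc > best[0]:
            best = (val_auroc, model.state_dict())
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs > recipe.patience:
                break
    if best[1] is not None:
        model.load_state_dict(best[1])
    return model, history


def evaluate(model: Model, test_data: EncodedData,
             macro_average_sub: bool = False) -> EvalReport:
    """Sequence AUROC over p_seq and subregion AUPRC over valid subregions.

    By default subregion scores are pooled across sequences; with
    ``macro_average_sub`` the AUPRC is averaged per sequence instead.
    """
    if len(test_data) == 0:
        raise ValueError("empty test set")
    preds = model.predict(test_data.ids, test_data.mask)
    y = test_data.y_seq
    a_seq = auroc(y, preds.p_seq)
    fpr, tpr, thr = roc_curve(y, preds.p_seq)

    valid = test_data.V > 0
    ys = test_data.y_sub[valid]
    ps = preds.p_sub[valid]
    if macro_average_sub:
        per_seq = []
        for i in range(len(test_data)):
            vi = test_data.V[i] > 0
            yi = test_data.y_sub[i][vi]
            if 0 < yi.sum():
                per_seq.append(auprc(yi, preds.p_sub[i][vi]))
        a_sub = float(np.mean(per_seq))
        prec = rec_ = thr2 = np.array([])
    else:
        a_sub = auprc(ys, ps)
        prec, rec_, thr2 = precision_recall_curve(ys, ps)
    return EvalReport(
        auroc_seq=a_seq, auprc_sub=a_sub,
        n_pos_seq=int(y.sum()), n_neg_seq=int((1 - y).sum()),
        n_pos_sub=int(ys.sum()), n_neg_sub=int((1 - ys).sum()),
        roc_points={"fpr": fpr, "tpr": tpr, "threshold": thr},
        pr_points={"precision": prec, "recall": rec_, "threshold": thr2})


def curves_to_tsv(report: EvalReport, roc_path: Path | str,
                  pr_path: Path | str) -> None:
    with open(roc_path, "w") as fh:
        fh.write("fpr\ttpr\tthreshold\n")
        for f, t, th in zip(report.roc_points["fpr"], report.roc_points["tpr"],
                            report.roc_points["threshold"]):
            fh.write(f"{f}\t{t}\t{th}\n")
    with open(pr_path, "w") as fh:
        fh.write("precision\trecall\tthreshold\n")
        p = report.pr_points
        for i in range(len(p["threshold"])):
            fh.write(f"{p['precision'][i]}\t{p['recall'][i]}\t{p['threshold'][i]}\n")


# -- sweep harnesses ------------------------------------------------------
def n_t_for_window(window: int) -> int:
    """Token budget for a window length: ~0.3 tokens/nt plus framing."""
    return max(16, int(np.ceil(window * 0.3)) + 2)


def run_length_sweep(genome, vocab: Vocabulary, windows: Sequence[int],
                     cfg_base: ModelConfig, recipe: TrainRecipe,
                     n_per_class: int, seed: int = 0) -> list[dict]:
    """Retrain at several window lengths; one vocabulary reused throughout."""
    out = []
    for w in windows:
        pos, neg = ds.training_candidates(genome, window=w)
        balanced = ds.filter_and_balance(pos, neg, n_per_class, seed=seed)
        sp = ds.split(balanced, seed=seed)
        n_t = n_t_for_window(w)
        cfg = ModelConfig(**{**asdict(cfg_base), "n_t": n_t})
        tr = encode_windows(sp.train, vocab, n_t, cfg.m)
        va = encode_windows(sp.validation, vocab, n_t, cfg.m)
        te = encode_windows(sp.test, vocab, n_t, cfg.m)
        model, _ = train(tr, va, cfg, recipe)
        rep = evaluate(model, te)
        out.append({"window": w, "auroc_seq": rep.auroc_seq,
                    "auprc_sub": rep.auprc_sub})
    return out


def run_lambda_sweep(train_data: EncodedData, val_data: EncodedData,
                     test_data: EncodedData, cfg_base: ModelConfig,
                     recipe: TrainRecipe, lams: Sequence[float]) -> list[dict]:
    """Retrain at several loss-mix values on one fixed dataset."""
    out = []
    for lam in lams:
        cfg = ModelConfig(**{**asdict(cfg_base), "lam": lam})
        model, _ = train(train_data, val_data, cfg, recipe)
        rep = evaluate(model, test_data)
        out.append({"lambda": lam, "auroc_seq": rep.auroc_seq,
                    "auprc_sub": rep.auprc_sub})
    return out
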