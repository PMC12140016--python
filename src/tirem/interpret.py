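"""Attribution of model predictions to hexamers, TF motifs and TF groups.

The unit of attribution is the hexamer: for each position j of a 201 nt
site-centered sequence, the hexamer starting at j is replaced C times by a
random different hexamer and the median drop in prediction log-odds is the
importance score IS^hexamer_{i,j}.  Only sequences the model itself calls
positive (P >= 0.5) contribute; others are gated to zero.

Hexamer tracks are lifted to transcription factors by scanning each sequence
with JASPAR-derived position weight matrices (pseudocount 0.5, uniform 0.25
background, natural log); a window is a binding hit when the sigmoid of its
PWM score reaches 0.999 (equivalently, raw score >= ln 999).  A TF's
importance at a hit is the mean of the hexamer scores whose windows fall
inside the motif footprint, and family/class tracks are binding-count-
weighted means over all valid hits of the group's members.

Note the sigmoid standardization makes the 0.999 cutoff a fixed raw-score
threshold regardless of motif length, which intrinsically favours long
motifs; the rule is implemented literally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs

from .model import Model, logit
from .tokenizer import Vocabulary, encode

HEXAMER = 6
SEQ_LEN = 201
N_HEX_POSITIONS = SEQ_LEN - HEXAMER + 1  # 196 positions, j in [1, L-5] 1-based
SCAN_THRESHOLD = 0.999
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}
_BASES = np.array(list("ACGT"))


# -- model scorer ---------------------------------------------------------
def make_scorer(model: Model, vocab: Vocabulary,
                batch_size: int = 1024) -> Callable[[Sequence[str]], np.ndarray]:
    """Wrap a trained model as sequence -> P(infidelity) on string batches."""
    n_t = model.cfg.n_t

    def scorer(seqs: Sequence[str]) -> np.ndarray:
        out = np.empty(len(seqs))
        for a in range(0, len(seqs), batch_size):
            chunk = seqs[a:a + batch_size]
            ids = np.zeros((len(chunk), n_t), dtype=np.int32)
            mask = np.zeros((len(chunk), n_t), dtype=np.int8)
            for i, s in enumerate(chunk):
                tok = encode(s, vocab, n_t)
                ids[i] = tok.ids
                mask[i] = tok.attention_mask
            out[a:a + len(chunk)] = model.predict(ids, mask).p_seq
        return out
    return scorer


# -- hexamer perturbation -------------------------------------------------
@dataclass
class HexamerImportanceTrack:
    """IS^hexamer values for one sequence (196 positions, 0-based index j-1)."""

    seq_id: int
    values: np.ndarray     # (196,)
    valid: int             # 1 iff the model called the sequence positive
    base_probability: float

    def __post_init__(self) -> None:
        if self.valid == 0 and np.any(self.values):
            raise ValueError("invalid sequence must carry all-zero values")


def _hexamer_index(hexamer: str) -> int:
    idx = 0
    for c in hexamer:
        idx = idx * 4 + _BASE_INDEX[c]
    return idx


def _index_hexamer(idx: int) -> str:
    out = []
    for _ in range(HEXAMER):
        out.append("ACGT"[idx % 4])
        idx //= 4
    return "".join(reversed(out))


def hexamer_importance(model_scorer: Callable[[Sequence[str]], np.ndarray],
                       sequence: str, C: int = 100, seed: int = 0,
                       seq_id: int = 0) -> HexamerImportanceTrack:
    """Median log-odds drop under C random hexamer replacements per position.

    Replacements are drawn uniformly from the 4095 hexamers different from
    the original, with an independent stream per (seed, position).
    """
    if len(sequence) != SEQ_LEN:
        raise ValueError(f"sequence must be {SEQ_LEN} nt, got {len(sequence)}")
    p0 = float(model_scorer([sequence])[0])
    valid = 1 if p0 >= 0.5 else 0
    values = np.zeros(N_HEX_POSITIONS)
    if valid == 0:
        return HexamerImportanceTrack(seq_id=seq_id, values=values, valid=0,
                                      base_probability=p0)
    perturbed: list[str] = []
    for j in range(N_HEX_POSITIONS):
        rng = np.random.default_rng([seed, j])
        orig = _hexamer_index(sequence[j:j + HEXAMER])
        draws = rng.integers(0, 4 ** HEXAMER - 1, size=C)
        draws[draws >= orig] += 1  # uniform over the 4095 non-identical
        for d in draws:
            perturbed.append(sequence[:j] + _index_hexamer(int(d))
                             + sequence[j + HEXAMER:])
    probs = np.asarray(model_scorer(perturbed)).reshape(N_HEX_POSITIONS, C)
    delta = logit(p0) - logit(probs)
    values = np.median(delta, axis=1)
    return HexamerImportanceTrack(seq_id=seq_id, values=values, valid=1,
                                  base_probability=p0)


# -- motif models ---------------------------------------------------------
@dataclass
class MotifModel:
    """PFM/PPM/PWM triplet for one transcription factor."""

    tf_id: str
    tf_name: str
    family: str
    tf_class: str
    pfm: np.ndarray   # (4, L_n) counts, rows A,C,G,T
    ppm: np.ndarray = field(init=False)
    pwm: np.ndarray = field(init=False)
    alpha: float = 0.5
    background: float = 0.25

    def __post_init__(self) -> None:
        self.ppm, self.pwm = pfm_to_pwm(self.pfm, self.alpha, self.background)

    @property
    def length(self) -> int:
        return self.pfm.shape[1]


def pfm_to_pwm(pfm: np.ndarray, alpha: float = 0.5,
               background: float = 0.25) -> tuple[np.ndarray, np.ndarray]:
    """Counts -> probabilities (pseudocount alpha) -> natural-log odds."""
    pfm = np.asarray(pfm, dtype=float)
    if pfm.ndim != 2 or pfm.shape[0] != 4 or np.any(pfm < 0):
        raise ValueError("PFM must be a non-negative 4 x L matrix")
    col = (pfm + alpha).sum(axis=0)
    if np.any(col == 0):
        raise ValueError("all-zero PFM column with zero pseudocount")
    ppm = (pfm + alpha) / col
    pwm = np.log(ppm / background)
    return ppm, pwm


def read_jaspar(pfm_file: Path | str,
                metadata_table: Path | str | None = None) -> list[MotifModel]:
    """Read JASPAR-format PFMs plus an optional TF->family/class TSV.

    Both the bracketed (``A [ 4 19 ... ]``) and raw four-row count dialects
    are accepted.  TFs missing from the metadata get family/class "unknown".
    """
    meta: dict[str, tuple[str, str]] = {}
    if metadata_table is not None:
        df = pd.read_csv(metadata_table, sep="\t", dtype=str).fillna("unknown")
        required = {"tf_id", "family", "class"}
        if not required <= set(df.columns):
            raise ValueError(f"metadata table needs columns {sorted(required)}")
        meta = {row["tf_id"]: (row["family"], row["class"])
                for _, row in df.iterrows()}
    out: list[MotifModel] = []
    with open(pfm_file) as fh:
        text = fh.read()
    if not text.strip():
        return out
    try:
        parsed = bio_motifs.parse(_reopen(text), "jaspar")
    except Exception as exc:  # pragma: no cover - format diagnostics
        raise ValueError(f"malformed JASPAR PFM file {pfm_file}: {exc}") from exc
    for mot in parsed:
        pfm = np.array([mot.counts[b] for b in "ACGT"], dtype=float)
        tf_id = mot.matrix_id or mot.name
        family, tf_class = meta.get(tf_id, ("unknown", "unknown"))
        out.append(MotifModel(tf_id=tf_id, tf_name=mot.name or tf_id,
                              family=family, tf_class=tf_class, pfm=pfm))
    return out


def _reopen(text: str):
    import io
    return io.StringIO(text)


def write_jaspar(motifs: Sequence[MotifModel], path: Path | str) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.tf_id} {m.tf_name}\n")
            for b, row in zip("ACGT", m.pfm):
                cells = " ".join(f"{int(c):6d}" if float(c).is_integer()
                                 else f"{c:8.2f}" for c in row)
                fh.write(f"{b}  [ {cells} ]\n")


# -- scanning -------------------------------------------------------------
@dataclass
class MotifHit:
    seq_id: int
    start: int          # 0-based offset of the motif window
    tf_id: str
    score: float
    standardized: float  # sigmoid(score)


def scan(motif: MotifModel, sequence: str, threshold: float = SCAN_THRESHOLD,
         seq_id: int = 0, reverse_complement: bool = False) -> list[MotifHit]:
    """Slide the PWM with stride 1; keep windows with sigmoid(score) >= threshold.

    Equivalent to a raw-score cutoff of ln(threshold / (1 - threshold))
    (~6.907 at the default).  Forward strand only unless asked otherwise.
    """
    if set(sequence) - set("ACGT"):
        raise ValueError("sequence contains characters outside ACGT")
    L_n = motif.length
    if L_n > len(sequence):
        return []
    idx = np.fromiter((_BASE_INDEX[c] for c in sequence), dtype=np.intp,
                      count=len(sequence))
    hits = _scan_indices(motif.pwm, idx, threshold, seq_id, motif.tf_id)
    if reverse_complement:
        rc = 3 - idx[::-1]
        for h in _scan_indices(motif.pwm, rc, threshold, seq_id, motif.tf_id):
            h.start = len(sequence) - h.start - L_n
            hits.append(h)
    return hits


def _scan_indices(pwm: np.ndarray, idx: np.ndarray, threshold: float,
                  seq_id: int, tf_id: str) -> list[MotifHit]:
    L_n = pwm.shape[1]
    n_win = idx.size - L_n + 1
    windows = np.lib.stride_tricks.sliding_window_view(idx, L_n)
    scores = pwm[windows, np.arange(L_n)].sum(axis=1)
    std = 1.0 / (1.0 + np.exp(-scores))
    keep = np.flatnonzero(std >= threshold)
    return [MotifHit(seq_id=seq_id, start=int(j), tf_id=tf_id,
                     score=float(scores[j]), standardized=float(std[j]))
            for j in keep]


# -- TF and group importance ---------------------------------------------
def tf_importance(track: HexamerImportanceTrack, hit: MotifHit,
                  L_n: int) -> float:
    """Mean of the L_n - 5 hexamer scores inside the motif footprint."""
    if L_n < HEXAMER:
        raise ValueError("motif shorter than a hexamer has no hexamer windows")
    j = hit.start
    if j + L_n - HEXAMER >= N_HEX_POSITIONS:
        raise ValueError("motif footprint exceeds the hexamer track")
    return float(track.values[j: j + L_n - HEXAMER + 1].mean())


def hit_table(tracks: Sequence[HexamerImportanceTrack],
              motif_models: Sequence[MotifModel],
              sequences: Sequence[str],
              threshold: float = SCAN_THRESHOLD) -> pd.DataFrame:
    """Scan every sequence with every motif and attach IS^TF per hit.

    Motifs shorter than 6 nt are skipped with a warning (their footprint
    holds no hexamer window).  Hits on model-invalid sequences carry
    IS^TF = 0 and valid = 0.
    """
    by_id = {t.seq_id: t for t in tracks}
    rows = []
    for m in motif_models:
        if m.length < HEXAMER:
            warnings.warn(f"motif {m.tf_id} shorter than 6 nt; skipped")
            continue
        for sid, seq in enumerate(sequences):
            track = by_id.get(sid)
            if track is None:
                continue
            for hit in scan(m, seq, threshold, seq_id=sid):
                rows.append({
                    "seq_id": sid, "j": hit.start, "tf_id": m.tf_id,
                    "family": m.family, "class": m.tf_class,
                    "score": hit.score, "standardized": hit.standardized,
                    "is_tf": tf_importance(track, hit, m.length),
                    "valid": track.valid,
                })
    return pd.DataFrame(rows, columns=["seq_id", "j", "tf_id", "family",
                                       "class", "score", "standardized",
                                       "is_tf", "valid"])


@dataclass
class AggregateTrack:
    """Position-specific group importance; NaN where the group never binds."""

    group: str
    values: np.ndarray     # (196,)
    n_bindings: int


def aggregate(hits: pd.DataFrame,
              grouping: Literal["family", "class"]) -> list[AggregateTrack]:
    """Binding-count-weighted mean of IS^TF per group and position."""
    if grouping not in ("family", "class"):
        raise ValueError("grouping must be 'family' or 'class'")
    if hits.empty or hits[grouping].nunique() == 0:
        raise ValueError("no hits / empty grouping metadata")
    out = []
    valid = hits[hits["valid"] == 1]
    for group, sub in valid.groupby(grouping, sort=True):
        values = np.full(N_HEX_POSITIONS, np.nan)
        agg = sub.groupby("j")["is_tf"].mean()
        values[agg.index.to_numpy()] = agg.to_numpy()
        out.append(AggregateTrack(group=str(group), values=values,
                                  n_bindings=int(len(sub))))
    return out


def select_tracks(tracks: Sequence[AggregateTrack],
                  mode: Literal["top_individual", "cumulative",
                                "positive_everywhere"],
                  k: int = 6) -> list[AggregateTrack]:
    """Report filters over aggregate tracks.

    top_individual: k groups with the highest single-position value;
    cumulative: k groups with the highest summed value;
    positive_everywhere: groups positive at every position they bind.
    """
    if mode == "top_individual":
        key = lambda t: -np.nanmax(t.values)
        return sorted(tracks, key=key)[:k]
    if mode == "cumulative":
        key = lambda t: -np.nansum(t.values)
        return sorted(tracks, key=key)[:k]
    if mode == "positive_everywhere":
        return [t for t in tracks
                if np.all(t.values[~np.isnan(t.values)] > 0)
                and np.any(~np.isnan(t.values))]
    raise ValueError(f"unknown mode {mode!r}")


# -- smoothing ------------------------------------------------------------
def smooth(values: np.ndarray, window: int = 10) -> np.ndarray:
    """Centered triangular-weighted moving average, NaN-aware.

    The kernel spans 2*floor(window/2)+1 positions with linearly decaying
    weights; at the edges (and around missing values) the weight sum is
    renormalized over the positions actually present.  window=1 is identity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    values = np.asarray(values, dtype=float)
    half = window // 2
    if half == 0:
        return values.copy()
    kernel = np.concatenate([np.arange(1, half + 2),
                             np.arange(half, 0, -1)]).astype(float)
    present = ~np.isnan(values)
    filled = np.where(present, values, 0.0)
    num = np.convolve(filled, kernel, mode="same")
    den = np.convolve(present.astype(float), kernel, mode="same")
    out = np.full_like(values, np.nan)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    out[~present] = np.nan  # missing positions stay missing
    return out


# -- composition and consensus -------------------------------------------
def composition_features(seq_set_a: Sequence[str],
                         seq_set_b: Sequence[str]) -> dict:
    """Mono/di/tri-nucleotide proportions, ranks, and signed rank changes.

    Rank 1 is the most frequent k-mer within a set; rank_change is
    rank_in_a - rank_in_b (positive: the k-mer climbed from b to a).
    """
    if not seq_set_a or not seq_set_b:
        raise ValueError("both sequence sets must be non-empty")

    def props(seqs: Sequence[str], k: int) -> pd.Series:
        counts: dict[str, int] = {}
        for s in seqs:
            for i in range(len(s) - k + 1):
                kmer = s[i:i + k]
                counts[kmer] = counts.get(kmer, 0) + 1
        ser = pd.Series(counts, dtype=float)
        return ser / ser.sum()

    report: dict[int, pd.DataFrame] = {}
    for k in (1, 2, 3):
        pa, pb = props(seq_set_a, k), props(seq_set_b, k)
        df = pd.DataFrame({"prop_a": pa, "prop_b": pb}).fillna(0.0)
        df = df.sort_index()
        df["rank_a"] = df["prop_a"].rank(ascending=False, method="first"
                                         ).astype(int)
        df["rank_b"] = df["prop_b"].rank(ascending=False, method="first"
                                         ).astype(int)
        df["rank_change"] = df["rank_a"] - df["rank_b"]
        report[k] = df
    return report


def consensus(motif: MotifModel, degeneracy_threshold: float = 0.25) -> str:
    """Degenerate consensus: bases within the threshold of the column max
    are reported together as "[X/Y]" (ordered by probability)."""
    out = []
    for col in motif.ppm.T:
        order = np.argsort(-col)
        top = col[order[0]]
        members = [("ACGT"[i], col[i]) for i in order
                   if top - col[i] < degeneracy_threshold]
        if len(members) == 1:
            out.append(members[0][0])
        else:
            out.append("[" + "/".join(b for b, _ in members) + "]")
    return "".join(out)


# -- TSV output -----------------------------------------------------------
def tracks_to_tsv(tracks: Sequence[HexamerImportanceTrack],
                  path: Path | str,
                  origins: Optional[Sequence[tuple[str, int]]] = None) -> None:
    """Per-position hexamer importance, 1-based j in [1, 196].

    ``origins`` optionally supplies (contig, center) per track, adding
    0-based genomic coordinates of each hexamer start in extra columns
    (position j covers genomic [center - 100 + j - 1, ... + 6)).
    """
    with open(path, "w") as fh:
        if origins is None:
            fh.write("seq_id\tj\tis_hexamer\tvalid\n")
            for t in tracks:
                for j, v in enumerate(t.values, start=1):
                    fh.write(f"{t.seq_id}\t{j}\t{v}\t{t.valid}\n")
            return
        fh.write("seq_id\tj\tcontig\tgenomic_start\tis_hexamer\tvalid\n")
        for t, (contig, center) in zip(tracks, origins):
            for j, v in enumerate(t.values, start=1):
                gstart = center - (SEQ_LEN // 2) + j - 1
                fh.write(f"{t.seq_id}\t{j}\t{contig}\t{gstart}\t{v}"
                         f"\t{t.valid}\n")


def aggregates_to_tsv(tracks: Sequence[AggregateTrack], path: Path | str,
                      smoothing_window: int = 0) -> None:
    with open(path, "w") as fh:
        fh.write("group\tj\tis_group\tn_bindings\n")
        for t in tracks:
            vals = smooth(t.values, smoothing_window) if smoothing_window \
                else t.values
            for j, v in enumerate(vals, start=1):
                sval = "" if np.isnan(v) else repr(float(v))
                fh.write(f"{t.group}\t{j}\t{sval}\t{t.n_bindings}\n")
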