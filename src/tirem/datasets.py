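"""Window datasets for training and centered sequences for interpretation.

Training samples are 200 nt windows slid with a 10 nt step: positive
candidates come from the whole genome (windows overlapping at least one
infidelity site), negative candidates only from coding regions (windows
overlapping none).  The asymmetry is deliberate: many coding intervals are
shorter than a window, so restricting positives to coding regions would
discard real sites.  After removing windows containing 'N', each class is
down-sampled to a common size and split 8:1:1 (label-stratified).

The interpretation dataset instead centers each sequence on a site: 100 nt
of flank on both sides gives a 201 nt sequence whose central base is a known
infidelity position; matched negatives are site-free 201 nt coding windows.

Subregion ground truth is defined by overlap between the character spans of
a subregion's merged tokens and the window's site mask; a subregion is valid
when at least one of its merged tokens is a real sequence token.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from Bio import SeqIO

from .syndata import SyntheticGenome
from .tokenizer import TokenizedSample

WINDOW = 200
STEP = 10
FLANK = 100


@dataclass
class WindowSample:
    """A labelled window; ``site_mask[k]`` marks an infidelity site at
    ``start + k``.  label == 1 iff the mask contains at least one 1."""

    contig: str
    start: int
    sequence: str
    label: int
    site_mask: np.ndarray

    def __post_init__(self) -> None:
        if bool(self.site_mask.any()) != bool(self.label):
            raise ValueError("label inconsistent with site_mask")


@dataclass
class DatasetSplit:
    train: list[WindowSample]
    validation: list[WindowSample]
    test: list[WindowSample]
    ratios: tuple[int, int, int] = (8, 1, 1)
    seed: int = 0


@dataclass
class CenteredSequence:
    """A 201 nt sequence; for positives the central base is a recorded site."""

    contig: str
    center: int
    sequence: str
    center_is_site: bool

    def __post_init__(self) -> None:
        if len(self.sequence) != 2 * FLANK + 1:
            raise ValueError(f"centered sequence must be {2 * FLANK + 1} nt")


# -- readers --------------------------------------------------------------
def read_fasta(path: Path | str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def read_bed3(path: Path | str) -> list[tuple[str, int, int]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track", "browser")):
            continue
        contig, start, end = line.split("\t")[:3]
        out.append((contig, int(start), int(end)))
    return out


def read_gff3_coding(path: Path | str) -> list[tuple[str, int, int]]:
    """CDS features (gene features if no CDS present) as 0-based half-open
    intervals, merged where overlapping."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="merge",
                            keep_order=True)
    feats = list(db.features_of_type("CDS"))
    if not feats:
        feats = list(db.features_of_type("gene"))
    raw = [(f.seqid, f.start - 1, f.end) for f in feats]
    return merge_intervals(raw)


def merge_intervals(ivs: list[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    for contig, start, end in sorted(ivs):
        if out and out[-1][0] == contig and start <= out[-1][2]:
            out[-1] = (contig, out[-1][1], max(end, out[-1][2]))
        else:
            out.append((contig, start, end))
    return out


def read_genome(fasta: Path | str, sites_bed: Path | str,
                coding: Path | str) -> SyntheticGenome:
    """Assemble a genome object from FASTA + sites BED3 + coding BED3/GFF3."""
    contigs = read_fasta(fasta)
    sites = [(c, s) for c, s, _ in read_bed3(sites_bed)]
    coding_path = str(coding)
    if coding_path.endswith((".gff", ".gff3")):
        coding_ivs = read_gff3_coding(coding)
    else:
        coding_ivs = merge_intervals(read_bed3(coding))
    g = SyntheticGenome(contigs=contigs, coding_intervals=coding_ivs,
                        sites=sites)
    g.validate()
    return g


# -- window extraction ----------------------------------------------------
def _window_mask(site_pos: np.ndarray, start: int, window: int) -> np.ndarray:
    mask = np.zeros(window, dtype=np.uint8)
    lo = np.searchsorted(site_pos, start)
    hi = np.searchsorted(site_pos, start + window)
    mask[site_pos[lo:hi] - start] = 1
    return mask


def extract_windows(g: SyntheticGenome,
                    template: Literal["whole_genome", "coding_only"],
                    window: int = WINDOW, step: int = STEP
                    ) -> list[WindowSample]:
    """Slide ``window`` nt with ``step`` nt stride over the chosen template.

    Returns every window with its label; callers keep label-1 windows from
    the whole-genome template (positive candidates) and label-0 windows from
    the coding template (negative candidates).
    """
    sites = g.sites_by_contig()
    out: list[WindowSample] = []
    if template == "whole_genome":
        regions = [(name, 0, len(seq)) for name, seq in g.contigs.items()]
    elif template == "coding_only":
        if not g.coding_intervals:
            raise ValueError("coding_only template requires coding intervals")
        regions = list(g.coding_intervals)
    else:
        raise ValueError(f"unknown template {template!r}")

    for contig, rstart, rend in regions:
        seq = g.contigs[contig]
        pos = sites[contig]
        for start in range(rstart, rend - window + 1, step):
            mask = _window_mask(pos, start, window)
            out.append(WindowSample(contig=contig, start=start,
                                    sequence=seq[start:start + window],
                                    label=int(mask.any()),
                                    site_mask=mask))
    return out


def training_candidates(g: SyntheticGenome, window: int = WINDOW,
                        step: int = STEP
                        ) -> tuple[list[WindowSample], list[WindowSample]]:
    """(positive candidates, negative candidates) per the sampling scheme."""
    pos = [w for w in extract_windows(g, "whole_genome", window, step)
           if w.label == 1]
    neg = [w for w in extract_windows(g, "coding_only", window, step)
           if w.label == 0]
    return pos, neg


def filter_and_balance(pos: Sequence[WindowSample], neg: Sequence[WindowSample],
                       n_per_class: int = 10_000, seed: int = 0
                       ) -> list[WindowSample]:
    """Drop windows containing 'N', then down-sample each class to
    ``min(n_per_class, available)`` uniformly without replacement."""
    pos = [w for w in pos if "N" not in w.sequence]
    neg = [w for w in neg if "N" not in w.sequence]
    if not pos or not neg:
        raise ValueError("a class is empty after N-filtering")
    rng = np.random.default_rng(seed)
    out: list[WindowSample] = []
    for name, group in (("positive", pos), ("negative", neg)):
        if len(group) < n_per_class:
            warnings.warn(f"only {len(group)} {name} samples available "
                          f"(requested {n_per_class}); taking all")
            chosen = list(range(len(group)))
        else:
            chosen = sorted(rng.choice(len(group), size=n_per_class,
                                       replace=False))
        out.extend(group[i] for i in chosen)
    return out


def split(dataset: Sequence[WindowSample],
          ratios: tuple[int, int, int] = (8, 1, 1),
          seed: int = 0) -> DatasetSplit:
    """Disjoint, exhaustive, label-stratified split by integer ratios."""
    total = sum(ratios)
    if total <= 0 or any(r < 0 for r in ratios):
        raise ValueError("ratios must be non-negative with a positive sum")
    if len(dataset) < total:
        raise ValueError(f"need at least {total} samples to split {ratios}")
    rng = np.random.default_rng(seed)
    parts: tuple[list, list, list] = ([], [], [])
    for label in (0, 1):
        idx = [i for i, w in enumerate(dataset) if w.label == label]
        if not idx:
            continue
        rng.shuffle(idx)
        n = len(idx)
        # largest-remainder apportionment keeps counts within rounding
        quotas = [n * r / total for r in ratios]
        counts = [int(q) for q in quotas]
        rem = n - sum(counts)
        order = sorted(range(3), key=lambda k: quotas[k] - counts[k],
                       reverse=True)
        for k in order[:rem]:
            counts[k] += 1
        a = 0
        for part, c in zip(parts, counts):
            part.extend(dataset[i] for i in idx[a:a + c])
            a += c
    return DatasetSplit(train=parts[0], validation=parts[1], test=parts[2],
                        ratios=ratios, seed=seed)


# -- interpretation set ---------------------------------------------------
def build_interpretation_set(g: SyntheticGenome, n_pos: int = 10_000,
                             n_neg: int = 10_000, flank: int = FLANK,
                             seed: int = 0
                             ) -> tuple[list[CenteredSequence],
                                        list[CenteredSequence]]:
    """Site-centered positives and site-free coding negatives, 2*flank+1 nt.

    Sites closer than ``flank`` to a contig edge are excluded (the
    perturbation arithmetic assumes a full window of real sequence).
    """
    length = 2 * flank + 1
    rng = np.random.default_rng(seed)

    candidates = []
    for contig, pos in g.sites:
        if pos >= flank and pos + flank < len(g.contigs[contig]):
            seq = g.contigs[contig][pos - flank: pos + flank + 1]
            if "N" not in seq:
                candidates.append(CenteredSequence(
                    contig=contig, center=pos, sequence=seq,
                    center_is_site=True))
    if n_pos < len(candidates):
        idx = sorted(rng.choice(len(candidates), size=n_pos, replace=False))
        positives = [candidates[i] for i in idx]
    else:
        positives = candidates[:]

    if n_neg > 0:
        neg_windows = [w for w in extract_windows(g, "coding_only",
                                                  window=length, step=STEP)
                       if w.label == 0 and "N" not in w.sequence]
    else:
        neg_windows = []
    if n_neg < len(neg_windows):
        idx = sorted(rng.choice(len(neg_windows), size=n_neg, replace=False))
        neg_windows = [neg_windows[i] for i in idx]
    negatives = [CenteredSequence(contig=w.contig, center=w.start + flank,
                                  sequence=w.sequence, center_is_site=False)
                 for w in neg_windows]
    return positives, negatives


# -- subregion ground truth ----------------------------------------------
def subregion_labels(sample: WindowSample, tokenized: TokenizedSample,
                     m: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-subregion labels y_{i,t} and validity V_{i,t}.

    Subregion ``t`` merges tokens [1 + t*m, 1 + (t+1)*m) of the framed
    sequence (CLS excluded).  y = 1 iff the union of its tokens' character
    spans overlaps a site; V = 1 iff at least one merged token carries a
    span (i.e. is a real sequence token, not SEP/PAD).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    spans = tokenized.spans
    n_t = tokenized.n_t
    real = [s for s in spans if s is not None]
    if real:
        covered = sorted(real)
        if covered[0][0] != 0 or covered[-1][1] != len(sample.sequence) or any(
                a[1] != b[0] for a, b in zip(covered, covered[1:])):
            raise ValueError("token spans do not partition the sequence")
    site_pos = np.flatnonzero(sample.site_mask)
    n_sub = -(-(n_t - 1) // m)
    y = np.zeros(n_sub, dtype=np.int8)
    V = np.zeros(n_sub, dtype=np.int8)
    for t in range(n_sub):
        toks = spans[1 + t * m: min(1 + (t + 1) * m, n_t)]
        tok_spans = [s for s in toks if s is not None]
        if not tok_spans:
            continue
        V[t] = 1
        lo = min(s[0] for s in tok_spans)
        hi = max(s[1] for s in tok_spans)
        if np.any((site_pos >= lo) & (site_pos < hi)):
            y[t] = 1
    if sample.label == 0 and y.any():
        raise ValueError("label-0 sample produced a positive subregion")
    return y, V


# -- manifests ------------------------------------------------------------
def write_manifest(samples: Sequence[WindowSample], path: Path | str) -> None:
    """TSV manifest (id, contig, start, label, sequence); .gz supported."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        fh.write("sample_id\tcontig\tstart\tlabel\tsequence\n")
        for i, w in enumerate(samples):
            fh.write(f"s{i}\t{w.contig}\t{w.start}\t{w.label}\t{w.sequence}\n")


def read_manifest(path: Path | str, g: SyntheticGenome) -> list[WindowSample]:
    opener = gzip.open if str(path).endswith(".gz") else open
    sites = g.sites_by_contig()
    out = []
    with opener(path, "rt") as fh:
        next(fh)
        for line in fh:
            _, contig, start, label, seq = line.rstrip("\n").split("\t")
            start = int(start)
            mask = _window_mask(sites[contig], start, len(seq))
            out.append(WindowSample(contig=contig, start=start, sequence=seq,
                                    label=int(label), site_mask=mask))
    return out
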