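"""Synthetic genomes with point "infidelity" sites and planted motifs.

Emulates the statistical structure of a genome annotated with
transcriptional-infidelity sites (RNA–DNA differences): multi-contig
i.i.d. background sequence at a configurable GC content, single-nucleotide
sites at a configurable density, non-overlapping coding intervals covering
a configurable fraction of each contig, and an optional motif planted near
sites so that attribution methods have a known ground truth to recover.

Sites are positional events only; the substitution type (A-to-G etc.) is
not modelled because the classifier's labels are purely positional.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
MIN_CONTIG_LENGTH = 201  # shortest contig usable for a centered 201 nt sequence

# Interval lengths are exponential: most coding intervals end up shorter than
# a 200 nt window, mirroring genomes where the majority of CDS pieces cannot
# host a full-length window.
_CODING_LEN_MEAN = 300.0
_CODING_LEN_MIN = 60
_CODING_LEN_MAX = 2000


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated genome."""

    n_contigs: int = 10
    contig_length: int = 100_000
    gc_content: float = 0.5
    site_density: float = 1e-3  # infidelity events per nt; elevated-infidelity lines sit near 1e-3
    coding_fraction: float = 0.35
    planted_motif: Optional[str] = None
    motif_offset_range: tuple[int, int] = (-30, 24)  # motif start relative to site
    motif_placement_prob: float = 0.0
    n_rate: float = 0.0  # per-base probability of an 'N' (exercises the N-filter)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 1:
            raise ValueError("n_contigs must be positive")
        if self.contig_length < MIN_CONTIG_LENGTH:
            raise ValueError(
                f"contig_length must be >= {MIN_CONTIG_LENGTH}, got {self.contig_length}"
            )
        for name in ("gc_content", "site_density", "coding_fraction",
                     "motif_placement_prob", "n_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.planted_motif is not None:
            m = self.planted_motif
            if len(m) < 6 or set(m) - set("ACGT"):
                raise ValueError("planted_motif must be >= 6 nt over {A,C,G,T}")
        lo, hi = self.motif_offset_range
        if lo > hi:
            raise ValueError("motif_offset_range must be (lo, hi) with lo <= hi")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SimConfig":
        d = json.loads(text)
        if d.get("motif_offset_range") is not None:
            d["motif_offset_range"] = tuple(d["motif_offset_range"])
        return cls(**d)


@dataclass
class SyntheticGenome:
    """Contigs plus coding annotation and infidelity-site calls.

    Coordinates are 0-based half-open throughout; ``sites`` are single
    positions, ``coding_intervals`` are (contig, start, end) and
    non-overlapping within each contig.
    """

    contigs: dict[str, str]
    coding_intervals: list[tuple[str, int, int]]
    sites: list[tuple[str, int]]
    config: Optional[SimConfig] = None

    def sites_by_contig(self) -> dict[str, np.ndarray]:
        out: dict[str, list[int]] = {name: [] for name in self.contigs}
        for contig, pos in self.sites:
            out[contig].append(pos)
        return {k: np.asarray(sorted(v), dtype=np.int64) for k, v in out.items()}

    def coding_by_contig(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {name: [] for name in self.contigs}
        for contig, start, end in self.coding_intervals:
            out[contig].append((start, end))
        return {k: sorted(v) for k, v in out.items()}

    def validate(self) -> None:
        for contig, pos in self.sites:
            if not 0 <= pos < len(self.contigs[contig]):
                raise ValueError(f"site {contig}:{pos} outside contig")
        for contig, ivs in self.coding_by_contig().items():
            prev_end = -1
            for start, end in ivs:
                if start < prev_end or start < 0 or end > len(self.contigs[contig]):
                    raise ValueError(f"bad coding interval {contig}:{start}-{end}")
                prev_end = end


def random_dna(rng: np.random.Generator, length: int,
               gc_content: float = 0.5) -> str:
    """An i.i.d. DNA string with P(G)+P(C) = gc_content."""
    p = np.array([(1 - gc_content) / 2, gc_content / 2, gc_content / 2,
                  (1 - gc_content) / 2])
    return _BASES[rng.choice(4, size=length, p=p)].tobytes().decode("ascii")


def _random_contig(rng: np.random.Generator, length: int, gc: float,
                   n_rate: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = _BASES[rng.choice(4, size=length, p=p)]
    if n_rate > 0:
        seq = seq.copy()
        seq[rng.random(length) < n_rate] = ord("N")
    return seq


def _coding_intervals(rng: np.random.Generator, length: int,
                      fraction: float) -> list[tuple[int, int]]:
    if fraction <= 0:
        return []
    # alternate exponential gaps and interval lengths; the gap mean is set so
    # the expected covered fraction matches the request
    gap_mean = _CODING_LEN_MEAN * (1 - fraction) / max(fraction, 1e-9)
    out = []
    pos = int(rng.exponential(gap_mean / 2))
    while pos < length:
        ln = int(np.clip(rng.exponential(_CODING_LEN_MEAN),
                         _CODING_LEN_MIN, _CODING_LEN_MAX))
        end = min(pos + ln, length)
        if end - pos >= _CODING_LEN_MIN:
            out.append((pos, end))
        pos = end + 1 + int(rng.exponential(gap_mean))
    return out


def simulate_genome(config: SimConfig) -> SyntheticGenome:
    """Draw a genome deterministically from ``config.seed``.

    Background bases are i.i.d. with P(G)=P(C)=gc_content/2; sites are
    independent per-base Bernoulli(site_density); when a motif is planted it
    is written, with probability ``motif_placement_prob`` per site, at a
    uniform offset drawn from ``motif_offset_range`` relative to the site
    (offsets that would run past a contig edge are skipped).
    """
    rng = np.random.default_rng(config.seed)
    contigs: dict[str, str] = {}
    coding: list[tuple[str, int, int]] = []
    sites: list[tuple[str, int]] = []

    motif = (np.frombuffer(config.planted_motif.encode(), dtype=np.uint8)
             if config.planted_motif else None)
    lo, hi = config.motif_offset_range

    for c in range(config.n_contigs):
        name = f"contig{c + 1}"
        seq = _random_contig(rng, config.contig_length, config.gc_content,
                             config.n_rate).copy()
        if config.site_density > 0:
            positions = np.flatnonzero(
                rng.random(config.contig_length) < config.site_density)
        else:
            positions = np.empty(0, dtype=np.int64)
        if motif is not None and config.motif_placement_prob > 0:
            place = rng.random(positions.size) < config.motif_placement_prob
            offsets = rng.integers(lo, hi + 1, size=positions.size)
            for pos, do_place, off in zip(positions, place, offsets):
                start = int(pos) + int(off)
                if do_place and 0 <= start and start + motif.size <= seq.size:
                    seq[start:start + motif.size] = motif
        contigs[name] = seq.tobytes().decode("ascii")
        sites.extend((name, int(p)) for p in positions)
        coding.extend((name, s, e)
                      for s, e in _coding_intervals(rng, config.contig_length,
                                                    config.coding_fraction))

    g = SyntheticGenome(contigs=contigs, coding_intervals=coding, sites=sites,
                        config=config)
    g.validate()
    return g


def write_genome(g: SyntheticGenome, fasta: Path | str, sites_bed: Path | str,
                 coding_bed: Path | str,
                 config_json: Path | str | None = None) -> None:
    """Write FASTA + BED3 (sites as length-1 intervals) + BED3 (coding).

    A JSON sidecar records the SimConfig when the genome carries one.
    """
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in g.contigs.items()]
    with open(fasta, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    with open(sites_bed, "w") as fh:
        for contig, pos in g.sites:
            fh.write(f"{contig}\t{pos}\t{pos + 1}\n")
    with open(coding_bed, "w") as fh:
        for contig, start, end in g.coding_intervals:
            fh.write(f"{contig}\t{start}\t{end}\n")
    if config_json is not None and g.config is not None:
        Path(config_json).write_text(g.config.to_json())
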