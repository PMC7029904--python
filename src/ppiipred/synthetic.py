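"""Synthetic fixtures: backbone structures with planted conformational
segments, and labelled sequence corpora with a planted learnable rule.

Everything is seed-deterministic so tests and benchmarks need no
external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .ppii_label import LabelledSequence, PPIISegment
from .structgeom import BackboneChain, build_backbone

#: Canonical backbone dihedrals (phi, psi, omega) per conformation.
CANONICAL_ANGLES = {
    "ppii": (-75.0, 145.0, 180.0),
    "alpha": (-60.0, -45.0, 180.0),
    "beta": (-120.0, 130.0, 180.0),
}


@dataclass
class SegmentSpec:
    conformation: str  # "ppii" | "alpha" | "beta" | "custom"
    length: int
    angles: Optional[tuple] = None  # (phi, psi, omega) when custom

    def __post_init__(self):
        if self.length < 1:
            raise ValueError("segment length must be >= 1")
        if self.conformation == "custom":
            if self.angles is None:
                raise ValueError("custom segment needs explicit angles")
        elif self.conformation not in CANONICAL_ANGLES:
            raise ValueError(f"unknown conformation {self.conformation!r}")


@dataclass
class StructureSpec:
    segments: list[SegmentSpec]
    angle_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.angle_noise_sd < 0:
            raise ValueError("angle_noise_sd must be >= 0")


def make_structure(spec: StructureSpec):
    """Build a chain concatenating the requested segments.

    Returns ``(chain, truth)`` where truth is a 0/1 list marking residues
    of the planted ppii segments.  Gaussian noise (spec.angle_noise_sd
    degrees) is added to every dihedral.  Residues in ppii segments get
    amino acid P, all others A.
    """
    rng = np.random.default_rng(spec.seed)
    angles = []
    truth = []
    seq = []
    for seg in spec.segments:
        if seg.conformation == "custom":
            phi, psi, omega = seg.angles
        else:
            phi, psi, omega = CANONICAL_ANGLES[seg.conformation]
        is_ppii = seg.conformation == "ppii"
        for _ in range(seg.length):
            noise = rng.normal(0.0, spec.angle_noise_sd, size=3) \
                if spec.angle_noise_sd > 0 else np.zeros(3)
            angles.append({"phi": phi + noise[0], "psi": psi + noise[1],
                           "omega": omega + noise[2]})
            truth.append(1 if is_ppii else 0)
            seq.append("P" if is_ppii else "A")
    chain = build_backbone(angles, sequence="".join(seq))
    return chain, truth


# ---------------------------------------------------------------------------
# Labelled sequence corpus with a planted rule.

#: Background amino-acid frequencies: near-uniform with proline scarce, so
#: that planted proline-enriched stretches carry signal.
DEFAULT_BACKGROUND = {aa: 1.0 for aa in "ACDEFGHIKLMNQRSTVWY"}
DEFAULT_BACKGROUND["P"] = 0.5

#: Residues (other than proline) enriched inside planted stretches; chosen
#: among side chains that extend from the backbone.
ENRICHED_SET = "ALKE"


@dataclass
class CorpusSpec:
    n_sequences: int = 500
    length_range: tuple = (30, 60)
    background: dict = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    target_positive_fraction: float = 0.024
    run_length_range: tuple = (3, 6)
    p_proline_in_run: float = 0.4
    seed: int = 0

    def __post_init__(self):
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if not (0 < self.target_positive_fraction < 1):
            raise ValueError("target_positive_fraction must be in (0, 1)")


def make_corpus(spec: CorpusSpec) -> list[LabelledSequence]:
    """Generate labelled sequences with planted positive stretches.

    Background residues are drawn from ``spec.background``.  Positive
    stretches (length >= 3) are proline-enriched — each position is P
    with probability ``p_proline_in_run`` and otherwise drawn from a
    small set of extended-side-chain residues — and every residue of a
    planted stretch is labelled positive.  The expected positive
    fraction matches ``target_positive_fraction``; the realized fraction
    concentrates around it for corpora of a few hundred sequences.
    """
    rng = np.random.default_rng(spec.seed)
    letters = np.array(list(spec.background.keys()))
    weights = np.array([spec.background[a] for a in letters], float)
    weights /= weights.sum()
    mean_len = (spec.length_range[0] + spec.length_range[1]) / 2.0
    mean_run = (spec.run_length_range[0] + spec.run_length_range[1]) / 2.0
    runs_per_seq = spec.target_positive_fraction * mean_len / mean_run

    out = []
    for i in range(spec.n_sequences):
        n = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        seq = rng.choice(letters, size=n, p=weights)
        labels = np.zeros(n, dtype=int)
        n_runs = rng.poisson(runs_per_seq)
        for _ in range(n_runs):
            rl = int(rng.integers(spec.run_length_range[0],
                                  spec.run_length_range[1] + 1))
            if rl > n:
                continue
            start = int(rng.integers(0, n - rl + 1))
            for k in range(start, start + rl):
                if rng.random() < spec.p_proline_in_run:
                    seq[k] = "P"
                else:
                    seq[k] = ENRICHED_SET[rng.integers(0, len(ENRICHED_SET))]
                labels[k] = 1
        segments = _runs_to_segments(labels)
        out.append(LabelledSequence(id=f"syn{i:04d}", seq="".join(seq),
                                    labels=labels.tolist(), segments=segments))
    return out


def _runs_to_segments(labels) -> list[PPIISegment]:
    segs = []
    n = len(labels)
    i = 0
    while i < n:
        if labels[i]:
            j = i
            while j + 1 < n and labels[j + 1]:
                j += 1
            segs.append(PPIISegment(start=i + 1, end=j + 1, regularity=0.0))
            i = j + 1
        else:
            i += 1
    return segs


def corpus_positive_fraction(corpus) -> float:
    pos = sum(sum(s.labels) for s in corpus)
    tot = sum(len(s.labels) for s in corpus)
    return pos / tot


def write_corpus_fasta(corpus, fasta_path, labels_path) -> None:
    """Emit FASTA plus a per-residue label TSV (id, position, aa, label)."""
    with open(fasta_path, "w") as fh:
        for rec in corpus:
            fh.write(f">{rec.id}\n{rec.seq}\n")
    with open(labels_path, "w") as fh:
        fh.write("id\tposition\taa\tlabel\n")
        for rec in corpus:
            for j, (aa, lab) in enumerate(zip(rec.seq, rec.labels), start=1):
                fh.write(f"{rec.id}\t{j}\t{aa}\t{lab}\n")
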