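"""Per-residue input encoding for the recurrent predictor.

Each residue j is encoded as a vector laid out as
``[20 one-hot | length | charge | (20 profile | gap) | iupred | espritz]``,
giving width 24 without an alignment and 45 with one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

#: Fixed alphabet order; changing it is a model-breaking change.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

GAP_CHARS = frozenset("-.")

#: Sequence length is normalized by this cap.
LENGTH_CAP = 2000

WIDTH_NO_MSA = 24
WIDTH_MSA = 45


@dataclass
class DisorderTrack:
    """Per-residue disorder scores (both in [0, 1])."""

    id: str
    iupred_long: np.ndarray
    espritz_nmr: np.ndarray

    def __post_init__(self):
        self.iupred_long = np.clip(np.asarray(self.iupred_long, float), 0.0, 1.0)
        self.espritz_nmr = np.clip(np.asarray(self.espritz_nmr, float), 0.0, 1.0)
        if self.iupred_long.shape != self.espritz_nmr.shape:
            raise ValueError(f"disorder track {self.id}: length mismatch")


@dataclass
class FeatureMatrix:
    id: str
    rows: np.ndarray  # (N, width)

    @property
    def width(self) -> int:
        return self.rows.shape[1]

    def __len__(self) -> int:
        return self.rows.shape[0]


def one_hot(aa: str) -> np.ndarray:
    """Unit vector over the 20-letter alphabet; zeros for anything else."""
    v = np.zeros(20)
    idx = _AA_INDEX.get(aa.upper())
    if idx is not None:
        v[idx] = 1.0
    return v


def charge_input(aa: str, d_e_charge: float = -1.0) -> float:
    """+1 for R/K, d_e_charge (default -1) for D/E, 0 otherwise."""
    aa = aa.upper()
    if aa in "RK":
        return 1.0
    if aa in "DE":
        return d_e_charge
    return 0.0


def length_input(n: int) -> float:
    """Sequence length capped at LENGTH_CAP and scaled to [0, 1]."""
    if n < 1:
        raise ValueError("sequence length must be >= 1")
    return min(n, LENGTH_CAP) / LENGTH_CAP


def msa_profile(alignment: Sequence[str]) -> np.ndarray:
    """Residue + gap frequency profile over query (non-gap) columns.

    ``alignment`` holds equal-length aligned rows, query first.  For each
    column where the query has a residue, returns the frequency of each of
    the 20 standard residues plus the gap frequency, normalized over the
    symbols counted (non-standard letters count toward neither).
    Output shape: (query_length, 21).
    """
    if not alignment:
        raise ValueError("empty alignment")
    width = len(alignment[0])
    if any(len(row) != width for row in alignment):
        raise ValueError("ragged alignment: rows differ in length")
    query = alignment[0]
    cols = []
    for ci in range(width):
        if query[ci] in GAP_CHARS:
            continue
        counts = np.zeros(21)
        for row in alignment:
            ch = row[ci].upper()
            if ch in GAP_CHARS:
                counts[20] += 1
            else:
                idx = _AA_INDEX.get(ch)
                if idx is not None:
                    counts[idx] += 1
        total = counts.sum()
        if total > 0:
            counts /= total
        cols.append(counts)
    return np.array(cols) if cols else np.zeros((0, 21))


def encode_sequence(seq: str, msa: Optional[Sequence[str]] = None,
                    disorder: Optional[DisorderTrack] = None,
                    seq_id: str = "", d_e_charge: float = -1.0) -> FeatureMatrix:
    """Build the feature matrix for one sequence.

    Width is 24 without an MSA and 45 with one; absent disorder scores
    leave both disorder channels at zero.
    """
    n = len(seq)
    if n == 0:
        raise ValueError(f"empty sequence {seq_id!r}")
    width = WIDTH_MSA if msa is not None else WIDTH_NO_MSA
    rows = np.zeros((n, width))
    lv = length_input(n)
    for j, aa in enumerate(seq):
        rows[j, :20] = one_hot(aa)
        rows[j, 20] = lv
        rows[j, 21] = charge_input(aa, d_e_charge)
    if msa is not None:
        profile = msa_profile(msa)
        if profile.shape[0] != n:
            raise ValueError(
                f"{seq_id or 'sequence'}: MSA query has {profile.shape[0]} "
                f"residues but sequence has {n}")
        rows[:, 22:43] = profile
    if disorder is not None:
        if len(disorder.iupred_long) != n:
            raise ValueError(
                f"{seq_id or disorder.id}: disorder track length "
                f"{len(disorder.iupred_long)} != sequence length {n}")
        rows[:, width - 2] = disorder.iupred_long
        rows[:, width - 1] = disorder.espritz_nmr
    return FeatureMatrix(id=seq_id, rows=rows)


def read_disorder_tsv(path) -> dict[str, DisorderTrack]:
    """Read disorder tracks from TSV columns: id, position, iupred, espritz."""
    data: dict[str, list[tuple[float, float]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("id"):
            raise ValueError(f"{path}: expected header starting with 'id'")
        for line in fh:
            if not line.strip():
                continue
            sid, _pos, iu, es = line.rstrip("\n").split("\t")
            data.setdefault(sid, []).append((float(iu), float(es)))
    return {
        sid: DisorderTrack(id=sid,
                           iupred_long=np.array([v[0] for v in vals]),
                           espritz_nmr=np.array([v[1] for v in vals]))
        for sid, vals in data.items()
    }
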