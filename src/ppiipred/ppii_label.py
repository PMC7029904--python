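"""Polyproline-II helix (PPIIH) residue labelling from dihedral records.

Two definitions are supported: a *strict* one that constrains both psi and
phi, and a *non-strict* one that drops the phi constraint.  Candidate
residues must also pass a trans filter on the CA pseudo-torsion, and runs
of candidates are kept only when long enough and geometrically regular.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .structgeom import BackboneChain, DihedralRecord, chain_dihedrals


@dataclass
class PPIICriteria:
    """Filter thresholds for PPIIH assignment.

    ``mode`` is "strict" (phi band applied) or "non_strict" (phi band
    dropped).  The trans filter bounds the CA pseudo-torsion; setting
    ``trans_filter="omega"`` tests |omega| > 150 instead, and
    ``trans_filter="off"`` disables it.
    """

    mode: str = "strict"
    trans_lo: float = -145.0
    trans_hi: float = -70.0
    psi_band1: tuple = (-180.0, -160.0)
    psi_band2: tuple = (90.0, 180.0)
    phi_band: tuple = (-105.0, -45.0)
    regularity_max: Optional[float] = 30.0
    min_len: int = 3
    trans_filter: str = "ca_pseudo"  # "ca_pseudo" | "omega" | "off"
    omega_trans_min: float = 150.0

    def __post_init__(self):
        if self.mode not in ("strict", "non_strict"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.trans_filter not in ("ca_pseudo", "omega", "off"):
            raise ValueError(f"unknown trans_filter {self.trans_filter!r}")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass
class PPIISegment:
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    regularity: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class LabelledSequence:
    id: str
    seq: str
    labels: list[int] = field(default_factory=list)
    segments: list[PPIISegment] = field(default_factory=list)


def passes_dihedral_filter(rec: DihedralRecord, crit: PPIICriteria) -> bool:
    """True iff psi lies in one of the two psi bands and, in strict mode,
    phi lies in the phi band.  Undefined required angles fail."""
    if rec.psi is None:
        return False
    lo1, hi1 = crit.psi_band1
    lo2, hi2 = crit.psi_band2
    psi_ok = (lo1 < rec.psi < hi1) or (lo2 < rec.psi < hi2)
    if not psi_ok:
        return False
    if crit.mode == "strict":
        if rec.phi is None:
            return False
        lo, hi = crit.phi_band
        return lo < rec.phi < hi
    return True


def passes_trans_filter(rec: DihedralRecord, crit: PPIICriteria) -> bool:
    """Trans test: CA pseudo-torsion in (trans_lo, trans_hi) by default,
    or |omega| > omega_trans_min in omega mode.  Disabled mode passes all."""
    if crit.trans_filter == "off":
        return True
    if crit.trans_filter == "omega":
        return rec.omega is not None and abs(rec.omega) > crit.omega_trans_min
    return rec.ca_pseudo is not None and crit.trans_lo < rec.ca_pseudo < crit.trans_hi


def _wrap_diff(a: float, b: float) -> float:
    """Smallest signed angular difference a - b in degrees."""
    d = (a - b + 180.0) % 360.0 - 180.0
    return d


def segment_regularity(records: Sequence[DihedralRecord]) -> float:
    """Mean (psi, phi) step length over consecutive residue pairs.

    Returns (1/n) * sum over the n-1 adjacent pairs of
    sqrt(dpsi^2 + dphi^2) with wrapped angular differences, n being the
    number of records.  Division by n (not n-1) is intentional.  Pairs
    with an undefined phi or psi on either side are skipped.
    """
    n = len(records)
    if n < 2:
        raise ValueError("segment_regularity needs at least 2 records")
    total = 0.0
    for a, b in zip(records[:-1], records[1:]):
        if None in (a.psi, b.psi, a.phi, b.phi):
            continue
        total += math.hypot(_wrap_diff(a.psi, b.psi), _wrap_diff(a.phi, b.phi))
    return total / n


def assign_ppii(chain: BackboneChain, crit: PPIICriteria,
                records: Optional[Sequence[DihedralRecord]] = None) -> LabelledSequence:
    """Label PPIIH residues of a chain.

    Marks residues passing both the trans and dihedral filters, forms
    maximal runs, drops runs shorter than ``min_len`` or with mean step
    regularity above ``regularity_max``, and derives binary labels from
    the surviving segments.
    """
    n = len(chain.residues)
    out = LabelledSequence(id=chain.chain_id, seq=chain.sequence,
                           labels=[0] * n)
    if n == 0:
        return out
    if records is None:
        records = chain_dihedrals(chain)
    marked = [passes_trans_filter(r, crit) and passes_dihedral_filter(r, crit)
              for r in records]
    i = 0
    while i < n:
        if not marked[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and marked[j + 1]:
            j += 1
        run = records[i:j + 1]
        if len(run) >= crit.min_len:
            reg = segment_regularity(run) if len(run) >= 2 else 0.0
            if crit.regularity_max is None or reg <= crit.regularity_max:
                out.segments.append(PPIISegment(start=i + 1, end=j + 1,
                                                regularity=reg))
        i = j + 1
    for seg in out.segments:
        for k in range(seg.start - 1, seg.end):
            out.labels[k] = 1
    return out


def write_residue_tsv(chain: BackboneChain, labelled: LabelledSequence,
                      records: Sequence[DihedralRecord], path) -> None:
    """Per-residue TSV: id, res_index, aa, phi, psi, omega, ca_pseudo, label."""
    def fmt(x):
        return "NA" if x is None else f"{x:.3f}"

    with open(path, "w") as fh:
        fh.write("id\tres_index\taa\tphi\tpsi\tomega\tca_pseudo\tlabel\n")
        for res, rec, lab in zip(chain.residues, records, labelled.labels):
            fh.write(f"{labelled.id}\t{res.res_index}\t{res.aa}\t"
                     f"{fmt(rec.phi)}\t{fmt(rec.psi)}\t{fmt(rec.omega)}\t"
                     f"{fmt(rec.ca_pseudo)}\t{lab}\n")


def write_segment_bed(labelled: LabelledSequence, path) -> None:
    """Segments as a BED-like file with 0-based half-open coordinates."""
    with open(path, "w") as fh:
        for seg in labelled.segments:
            fh.write(f"{labelled.id}\t{seg.start - 1}\t{seg.end}\t"
                     f"{seg.length}\t{seg.regularity:.3f}\n")
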