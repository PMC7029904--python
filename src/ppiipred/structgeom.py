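"""Backbone geometry: PDB I/O, dihedral angles, and internal-to-Cartesian
chain construction.

Coordinates are in Angstrom, angles in degrees, residue indices 1-based.
Torsions follow the IUPAC sign convention (cis = 0, trans = 180) and are
reported in the half-open interval (-180, 180].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# Peptide-bond length threshold: C(i)-N(i+1) further apart than this marks
# a chain break, and angles spanning the break are undefined.
CHAIN_BREAK_DISTANCE = 2.0

#: Ideal backbone geometry used by :func:`build_backbone`.  One config block
#: so that generated fixtures are reproducible bit-for-bit.
IDEAL_GEOMETRY = {
    "bond_n_ca": 1.458,
    "bond_ca_c": 1.525,
    "bond_c_n": 1.329,
    "angle_n_ca_c": 111.2,
    "angle_ca_c_n": 116.2,
    "angle_c_n_ca": 121.7,
}

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_AA1TO3 = {v: k for k, v in _AA3TO1.items()}


@dataclass
class Residue:
    """One residue's backbone atoms; a missing atom is ``None``."""

    res_index: int
    aa: str = "A"
    n: Optional[np.ndarray] = None
    ca: Optional[np.ndarray] = None
    c: Optional[np.ndarray] = None
    icode: str = ""


@dataclass
class BackboneChain:
    """Ordered backbone residues of a single chain."""

    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)


@dataclass
class DihedralRecord:
    """Per-residue phi/psi/omega and the CA pseudo-torsion, or None if
    undefined (chain terminus, break or missing atom)."""

    res_index: int
    phi: Optional[float] = None
    psi: Optional[float] = None
    omega: Optional[float] = None
    ca_pseudo: Optional[float] = None


def _wrap_half_open(deg: float) -> float:
    """Map an angle in degrees into (-180, 180]."""
    deg = (deg + 180.0) % 360.0 - 180.0
    if deg == -180.0:
        deg = 180.0
    return deg


def dihedral_angle(p1, p2, p3, p4) -> Optional[float]:
    """Signed torsion p1-p2-p3-p4 in degrees, in (-180, 180].

    Returns ``None`` when the quadruple is degenerate (consecutive
    difference vectors zero or parallel), instead of raising.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    b2n = np.linalg.norm(b2)
    if b2n < 1e-12 or np.linalg.norm(n1) < 1e-9 or np.linalg.norm(n2) < 1e-9:
        return None
    m1 = np.cross(n1, b2 / b2n)
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    # atan2(y, x) yields the torsion with inverted handedness; negate to
    # match the IUPAC convention (right-handed rotation positive).
    return _wrap_half_open(-math.degrees(math.atan2(y, x)))


def _bond_ok(c_atom: Optional[np.ndarray], n_atom: Optional[np.ndarray]) -> bool:
    if c_atom is None or n_atom is None:
        return False
    return float(np.linalg.norm(n_atom - c_atom)) < CHAIN_BREAK_DISTANCE


def chain_dihedrals(chain: BackboneChain) -> list[DihedralRecord]:
    """Compute phi/psi/omega and CA pseudo-torsion for every residue.

    phi_i  : C(i-1), N(i), CA(i), C(i)
    psi_i  : N(i), CA(i), C(i), N(i+1)
    omega_i: CA(i-1), C(i-1), N(i), CA(i)   (peptide bond preceding i)
    ca_i   : CA(i-1), CA(i), CA(i+1), CA(i+2)

    Angles spanning a chain break (C-N distance >= 2 A) or a missing atom
    are undefined (None).
    """
    res = chain.residues
    n = len(res)
    # bonded[i] is True when residue i and i+1 are covalently connected
    bonded = [_bond_ok(res[i].c, res[i + 1].n) for i in range(n - 1)]
    records = []
    for i in range(n):
        r = res[i]
        rec = DihedralRecord(res_index=r.res_index)
        prev = res[i - 1] if i > 0 and bonded[i - 1] else None
        nxt = res[i + 1] if i < n - 1 and bonded[i] else None
        def defined(*atoms):
            return all(a is not None for a in atoms)

        if prev is not None and defined(prev.c, r.n, r.ca, r.c):
            rec.phi = dihedral_angle(prev.c, r.n, r.ca, r.c)
        if nxt is not None and defined(r.n, r.ca, r.c, nxt.n):
            rec.psi = dihedral_angle(r.n, r.ca, r.c, nxt.n)
        if prev is not None and defined(prev.ca, prev.c, r.n, r.ca):
            rec.omega = dihedral_angle(prev.ca, prev.c, r.n, r.ca)
        # CA pseudo-torsion needs residues i-1 .. i+2 all present and bonded
        if 1 <= i <= n - 3:
            span_ok = bonded[i - 1] and bonded[i] and bonded[i + 1]
            cas = [res[j].ca for j in (i - 1, i, i + 1, i + 2)]
            if span_ok and all(a is not None for a in cas):
                rec.ca_pseudo = dihedral_angle(*cas)
        if (rec.phi is None and prev is not None) or (rec.psi is None and nxt is not None):
            # only warn when an angle that should exist is missing
            if not defined(r.n, r.ca, r.c):
                logger.warning(
                    "chain %s residue %d: missing backbone atom, angles undefined",
                    chain.chain_id, r.res_index,
                )
        records.append(rec)
    return records


def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Natural-extension placement of atom D given A, B, C, the C-D bond
    length, the B-C-D angle and the A-B-C-D torsion."""
    theta = math.radians(angle_deg)
    chi = math.radians(torsion_deg)
    d_local = np.array([
        -bond * math.cos(theta),
        bond * math.sin(theta) * math.cos(chi),
        bond * math.sin(theta) * math.sin(chi),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    nrm = np.cross(ab, bc)
    nrm /= np.linalg.norm(nrm)
    m = np.column_stack([bc, np.cross(nrm, bc), nrm])
    return c + m @ d_local


def build_backbone(angles: Sequence[dict], geometry: Optional[dict] = None,
                   chain_id: str = "A", sequence: Optional[str] = None) -> BackboneChain:
    """Build N/CA/C coordinates from per-residue ``{"phi","psi","omega"}``.

    The first residue's phi and the last residue's psi are placeholders
    (they do not constrain any atom).  Recomputing dihedrals on the result
    reproduces the requested interior angles.
    """
    if not angles:
        raise ValueError("angles list must be nonempty")
    geo = dict(IDEAL_GEOMETRY)
    if geometry:
        geo.update(geometry)
    seq = sequence or "A" * len(angles)
    if len(seq) != len(angles):
        raise ValueError("sequence length must match angle list")

    # seed frame for residue 1
    n0 = np.zeros(3)
    ca0 = np.array([geo["bond_n_ca"], 0.0, 0.0])
    th = math.radians(geo["angle_n_ca_c"])
    c0 = ca0 + geo["bond_ca_c"] * np.array([-math.cos(th), math.sin(th), 0.0])
    atoms = [n0, ca0, c0]  # flat N,CA,C per residue

    for i in range(1, len(angles)):
        psi_prev = angles[i - 1].get("psi", 180.0)
        omega = angles[i].get("omega", 180.0)
        phi = angles[i].get("phi", -120.0)
        if psi_prev is None:
            psi_prev = 180.0
        n_i = _place_atom(atoms[-3], atoms[-2], atoms[-1],
                          geo["bond_c_n"], geo["angle_ca_c_n"], psi_prev)
        ca_i = _place_atom(atoms[-2], atoms[-1], n_i,
                           geo["bond_n_ca"], geo["angle_c_n_ca"], omega)
        c_i = _place_atom(atoms[-1], n_i, ca_i,
                          geo["bond_ca_c"], geo["angle_n_ca_c"], phi)
        atoms.extend([n_i, ca_i, c_i])

    residues = [
        Residue(res_index=i + 1, aa=seq[i],
                n=atoms[3 * i], ca=atoms[3 * i + 1], c=atoms[3 * i + 2])
        for i in range(len(angles))
    ]
    return BackboneChain(chain_id=chain_id, residues=residues)


# ---------------------------------------------------------------------------
# PDB I/O — ATOM records for N/CA/C only.


def read_pdb(path) -> list[BackboneChain]:
    """Parse backbone N/CA/C atoms from PDB ATOM records.

    First altloc wins; insertion codes participate in residue ordering;
    malformed ATOM lines are skipped with a logged line number.
    """
    chains: list[BackboneChain] = []
    chain_map: dict[str, BackboneChain] = {}
    res_map: dict[tuple, Residue] = {}
    saw_atom = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("ATOM"):
                continue
            saw_atom = True
            try:
                name = line[12:16].strip()
                altloc = line[16]
                resname = line[17:20].strip()
                chain_id = line[21].strip() or "A"
                resseq = int(line[22:26])
                icode = line[26].strip()
                xyz = np.array([float(line[30:38]), float(line[38:46]),
                                float(line[46:54])])
            except (ValueError, IndexError):
                logger.warning("%s:%d malformed ATOM record skipped", path, lineno)
                continue
            if name not in ("N", "CA", "C"):
                continue
            key = (chain_id, resseq, icode)
            if chain_id not in chain_map:
                chain_map[chain_id] = BackboneChain(chain_id=chain_id)
                chains.append(chain_map[chain_id])
            if key not in res_map:
                res_map[key] = Residue(res_index=resseq, icode=icode,
                                       aa=_AA3TO1.get(resname, "X"))
                chain_map[chain_id].residues.append(res_map[key])
            residue = res_map[key]
            attr = name.lower()
            if getattr(residue, attr) is None:  # keep first altloc
                setattr(residue, attr, xyz)
            elif altloc not in (" ", "", "A"):
                pass
    if not saw_atom:
        logger.warning("%s: no ATOM records found", path)
    return chains


def write_pdb(chains: Iterable[BackboneChain], path) -> None:
    """Write chains as PDB ATOM records (read_pdb round-trips the output)."""
    serial = 1
    with open(path, "w") as fh:
        for chain in chains:
            for r in chain.residues:
                for name, atom in (("N", r.n), ("CA", r.ca), ("C", r.c)):
                    if atom is None:
                        continue
                    resname = _AA1TO3.get(r.aa, "UNK")
                    fh.write(
                        "ATOM  {:5d} {:^4s} {:>3s} {:1s}{:4d}{:1s}   "
                        "{:8.3f}{:8.3f}{:8.3f}{:6.2f}{:6.2f}\n".format(
                            serial, name, resname, chain.chain_id[:1],
                            r.res_index, r.icode or " ",
                            atom[0], atom[1], atom[2], 1.0, 0.0)
                    )
                    serial += 1
            fh.write("TER\n")
        fh.write("END\n")


def write_tsv(chain: BackboneChain, path) -> None:
    """Serialize a fixture chain to TSV (res_index, aa, atom, x, y, z)."""
    with open(path, "w") as fh:
        fh.write("res_index\taa\tatom\tx\ty\tz\n")
        for r in chain.residues:
            for name, atom in (("N", r.n), ("CA", r.ca), ("C", r.c)):
                if atom is None:
                    continue
                fh.write(f"{r.res_index}\t{r.aa}\t{name}\t"
                         f"{atom[0]:.6f}\t{atom[1]:.6f}\t{atom[2]:.6f}\n")
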