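"""Dihedral angles and glycosidic (phi, psi) torsions.

Glycosidic linkage torsions follow the IUPAC heavy-atom definitions for a
1->X linkage between donor residue i and acceptor residue i-1::

    phi = O5_i - C1_i - OX_{i-1} - CX_{i-1}
    psi = C1_i - OX_{i-1} - CX_{i-1} - C(X-1)_{i-1}

with X = 3 for a 1-3 linkage and X = 4 for a 1-4 linkage.  In NMR practice
the terminal heavy atoms are often replaced by the anomeric/aglycone
hydrogens; that convention is available through ``convention="hydrogen"``.

All angles are in degrees, wrapped to (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Literal

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .structures import StructureModel

__all__ = [
    "LinkageSpec",
    "TorsionPair",
    "dihedral",
    "periodic_diff",
    "phi_psi",
    "wrap_angle",
]


def wrap_angle(a):
    """Wrap an angle (degrees) to the interval (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return wrapped.item() if wrapped.ndim == 0 else wrapped


def periodic_diff(a, b):
    """Minimal signed difference a - b on the circle, in (-180, 180]."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    Sign follows the IUPAC convention: looking along p2 -> p3, a clockwise
    rotation of the far bond relative to the near bond is positive.

    Raises ``ValueError`` for coincident consecutive points or collinear
    bonded triples, where the torsion is undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-10:
            raise ValueError("degenerate torsion: coincident consecutive points")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("degenerate torsion: collinear triple")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    return wrap_angle(np.degrees(np.arctan2(y, x)))


@dataclass(frozen=True)
class LinkageSpec:
    """A glycosidic linkage: donor residue i provides C1/O5, acceptor i-1
    provides the attachment carbon CX (X in {3, 4}) and bridging oxygen."""

    donor_residue_id: tuple
    acceptor_residue_id: tuple
    linkage_x: int = 4

    def __post_init__(self):
        if self.linkage_x not in (3, 4):
            raise ValueError(f"linkage X must be 3 or 4, got {self.linkage_x}")
        if self.donor_residue_id == self.acceptor_residue_id:
            raise ValueError("donor and acceptor residues must be distinct")


@dataclass(frozen=True)
class TorsionPair:
    phi: float
    psi: float

    def __post_init__(self):
        object.__setattr__(self, "phi", float(wrap_angle(self.phi)))
        object.__setattr__(self, "psi", float(wrap_angle(self.psi)))


def phi_psi(
    structure: "StructureModel",
    spec: LinkageSpec,
    convention: Literal["iupac", "hydrogen"] = "iupac",
) -> TorsionPair:
    """Measure the glycosidic (phi, psi) of one linkage in a structure.

    The bridging oxygen is located by a covalent-distance search (C-O below
    1.7 A) between the donor C1 and the acceptor CX rather than trusting
    residue assignment, since PDB dialects disagree about which residue owns
    the glycosidic oxygen.

    ``convention="hydrogen"`` replaces O5_i by H1_i and C(X-1)_{i-1} by
    HX_{i-1} (the NMR-style definition); those hydrogens must be present.
    """
    x = spec.linkage_x
    don = spec.donor_residue_id
    acc = spec.acceptor_residue_id

    c1 = structure.atom_coord(don, "C1")
    cx = structure.atom_coord(acc, f"C{x}")
    missing = []
    if c1 is None:
        missing.append(f"C1 in donor {don}")
    if cx is None:
        missing.append(f"C{x} in acceptor {acc}")
    if missing:
        raise KeyError("missing linkage atoms: " + "; ".join(missing))

    bridge = structure.bridging_oxygen(don, acc, x)
    if bridge is None:
        raise KeyError(
            f"no bridging oxygen within covalent distance between C1 of {don} "
            f"and C{x} of {acc}"
        )

    if convention == "iupac":
        first = structure.atom_coord(don, "O5")
        last = structure.atom_coord(acc, f"C{x - 1}")
        names = (f"O5 in donor {don}", f"C{x - 1} in acceptor {acc}")
    elif convention == "hydrogen":
        first = structure.atom_coord(don, "H1")
        last = structure.atom_coord(acc, f"H{x}")
        names = (f"H1 in donor {don}", f"H{x} in acceptor {acc}")
    else:
        raise ValueError(f"unknown torsion convention {convention!r}")

    missing = [n for n, p in zip(names, (first, last)) if p is None]
    if missing:
        raise KeyError("missing linkage atoms: " + "; ".join(missing))

    phi = dihedral(first, c1, bridge, cx)
    psi = dihedral(c1, bridge, cx, last)
    return TorsionPair(phi=phi, psi=psi)
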