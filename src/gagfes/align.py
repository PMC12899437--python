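"""Snapshot selection and rigid superposition of conformers.

Conformers drawn from free-energy basins are compared by aligning their
reducing-end anomeric centers (default atoms C1, O1, C2, O5 of the
reducing-end residue) with a least-squares proper rotation (Kabsch), then
measuring how the non-reducing-end exocyclic C-O bond — the bond that
would extend the glycan chain — diverges in direction and position.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np

from .torsions import TorsionPair, periodic_diff

__all__ = [
    "AlignmentResult",
    "DEFAULT_ALIGNMENT_ATOMS",
    "nearest_snapshot",
    "superpose",
    "apply_alignment",
    "bond_vector_divergence",
]

#: Reducing-end anomeric-center atoms used for alignment by default.
DEFAULT_ALIGNMENT_ATOMS = ("C1", "O1", "C2", "O5")


@dataclass(frozen=True)
class AlignmentResult:
    """Proper rotation (det +1), translation (A), and post-fit RMSD (A)
    over the alignment atoms, mapping mobile onto reference coordinates as
    ``x @ rotation.T + translation``."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def nearest_snapshot(series: Sequence[tuple], target: TorsionPair) -> int:
    """Frame id of the series entry nearest the target in periodic
    Euclidean (phi, psi) distance; ties go to the lowest frame id.

    ``series`` holds (frame_id, phi, psi) triples.
    """
    if len(series) == 0:
        raise ValueError("empty snapshot series")
    best_id, best_d = None, np.inf
    for frame_id, phi, psi in series:
        d = float(np.hypot(periodic_diff(phi, target.phi),
                           periodic_diff(psi, target.psi)))
        if d < best_d - 1e-12 or (abs(d - best_d) <= 1e-12
                                  and (best_id is None or frame_id < best_id)):
            best_id, best_d = frame_id, d
    return best_id


def _kabsch(mobile: np.ndarray, reference: np.ndarray,
            degeneracy_gap: float = 1e-8) -> AlignmentResult:
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    h = (mobile - mob_c).T @ (reference - ref_c)
    u, s, vt = np.linalg.svd(h)
    # near-collinear atom sets leave the rotation about the line undefined
    scale = max(s[0], 1.0)
    if s[1] / scale < degeneracy_gap:
        raise ValueError(
            "degenerate alignment: atom set is (near-)collinear, rotation "
            "is not determined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = ref_c - rot @ mob_c
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return AlignmentResult(rotation=rot, translation=trans, rmsd=rmsd)


def superpose(mobile, reference,
              atom_names: Sequence[str] = DEFAULT_ALIGNMENT_ATOMS,
              residue_id=None) -> AlignmentResult:
    """Least-squares superposition of named atoms of two structures.

    ``mobile`` and ``reference`` are structure models (see
    ``gagfes.structures``); ``residue_id`` restricts the named-atom lookup
    to one residue (default: the first residue containing all the names).
    Raises on missing atoms, fewer than three atoms, or a degenerate
    (near-collinear) atom set.
    """
    if len(atom_names) < 3:
        raise ValueError("superposition requires at least three atoms")
    pairs = []
    for name in atom_names:
        a = _find_named(mobile, name, residue_id)
        b = _find_named(reference, name, residue_id)
        if a is None or b is None:
            which = "mobile" if a is None else "reference"
            raise KeyError(f"atom {name!r} not found in {which} structure")
        pairs.append((a, b))
    mob = np.array([p[0] for p in pairs])
    ref = np.array([p[1] for p in pairs])
    return _kabsch(mob, ref)


def _find_named(structure, name, residue_id):
    if residue_id is not None:
        return structure.atom_coord(residue_id, name)
    for rid in structure.residue_ids():
        c = structure.atom_coord(rid, name)
        if c is not None:
            return c
    return None


def apply_alignment(structure, result: AlignmentResult):
    """Return a copy of the structure with transformed coordinates."""
    return structure.with_coords(result.transform(structure.coords()))


def bond_vector_divergence(a, b, bond: Tuple[str, str],
                           residue_id=None) -> tuple:
    """(angle degrees, origin displacement A) between the same bond in two
    already-superposed structures.

    The angle is between the two bond unit vectors; the displacement is the
    Euclidean distance between the bond-origin atoms.  Typical bonds are
    C4-O4 (1->4 context) or C3-O3 (1->3 context) at the non-reducing end.
    """
    o1, o2 = bond
    va = _bond_vec(a, o1, o2, residue_id)
    vb = _bond_vec(b, o1, o2, residue_id)
    na, nb = np.linalg.norm(va[1] - va[0]), np.linalg.norm(vb[1] - vb[0])
    if na < 1e-8 or nb < 1e-8:
        raise ValueError("zero-length bond")
    ua = (va[1] - va[0]) / na
    ub = (vb[1] - vb[0]) / nb
    angle = float(np.degrees(np.arccos(np.clip(np.dot(ua, ub), -1.0, 1.0))))
    displacement = float(np.linalg.norm(va[0] - vb[0]))
    return angle, displacement


def divergence_table(rows, path=None) -> str:
    """Delimited-text table of per-pair bond-vector divergences.

    ``rows`` holds (label_a, label_b, angle_deg, displacement_A) tuples;
    writes to ``path`` when given and returns the text.
    """
    lines = ["mobile\treference\tangle_deg\tdisplacement_A"]
    for a, b, angle, disp in rows:
        lines.append(f"{a}\t{b}\t{angle:.2f}\t{disp:.3f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def _bond_vec(structure, origin_name, tip_name, residue_id):
    o = _find_named(structure, origin_name, residue_id)
    t = _find_named(structure, tip_name, residue_id)
    if o is None or t is None:
        missing = origin_name if o is None else tip_name
        raise KeyError(f"bond atom {missing!r} not found")
    return np.asarray(o), np.asarray(t)
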