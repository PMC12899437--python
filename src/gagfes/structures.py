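"""Multi-model PDB ingestion, carbohydrate residue/linkage discovery, and
idealized-geometry oligosaccharide fixture builders.

Real structures are read with gemmi (fixed-column PDB, MODEL/ENDMDL,
carbohydrates as HETATM).  Fixture builders construct disaccharides and
longer glycosaminoglycan chains with idealized bond lengths and angles
(C-C 1.52 A, C-O 1.43 A, tetrahedral angles), an iduronate ring generated
at any prescribed Cremer-Pople pucker, and the glycosidic torsions set
exactly to requested (phi, psi) — they serve torsion and pucker logic, not
energetics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import gemmi
import numpy as np

from .pucker import (IDOA_REFERENCE_GEOMETRIES, PuckerState, RingConformer,
                     canonical_state, cremer_pople, inverse_cremer_pople,
                     pucker_name)
from .torsions import LinkageSpec, phi_psi

__all__ = [
    "Atom",
    "StructureModel",
    "read_pdb_models",
    "write_pdb_models",
    "find_glycosidic_linkages",
    "classify_residue_puckers",
    "consensus_linkage_torsions",
    "build_disaccharide_fixture",
    "build_heparin_dodecasaccharide",
    "DISACCHARIDE_TEMPLATES",
    "SULFATION_CODES",
]

#: Atom-name synonyms seen in legacy carbohydrate PDB entries, applied
#: case-insensitively after stripping primes; unknown names pass through.
_NAME_SYNONYMS = {
    "O5'": "O5", "O1'": "O1", "O2'": "O2", "O3'": "O3", "O4'": "O4",
    "O6'": "O6", "C1'": "C1", "C2'": "C2", "C3'": "C3", "C4'": "C4",
    "C5'": "C5", "C6'": "C6",
}

#: Bond-inference cutoff for C/O covalent pairs, Angstrom.
BOND_CUTOFF = 1.85
#: Glycosidic C-O covalent search distance, Angstrom.
GLYCOSIDIC_CO_CUTOFF = 1.7

RING_NAMES = ("O5", "C1", "C2", "C3", "C4", "C5")


def _canonical_name(name: str) -> str:
    n = name.strip().upper()
    return _NAME_SYNONYMS.get(n, n)


@dataclass(frozen=True)
class Atom:
    serial: int
    name: str
    residue_name: str
    chain: str
    residue_number: int
    coords: np.ndarray
    element: str = ""


class StructureModel:
    """One coordinate model: a flat atom list with (chain, residue number,
    atom name) lookup and distance-based connectivity helpers."""

    def __init__(self, model_id: int, atoms: Sequence[Atom]):
        self.model_id = model_id
        self.atoms = list(atoms)
        self._index: Dict[tuple, Atom] = {}
        self._residues: List[tuple] = []
        self._resnames: Dict[tuple, str] = {}
        for a in self.atoms:
            if not np.all(np.isfinite(a.coords)):
                raise ValueError(f"non-finite coordinates for atom {a}")
            rid = (a.chain, a.residue_number)
            key = (rid, _canonical_name(a.name))
            if key in self._index:
                raise ValueError(
                    f"duplicate atom {a.name!r} in residue {rid} of model "
                    f"{model_id}")
            self._index[key] = a
            if rid not in self._resnames:
                self._residues.append(rid)
                self._resnames[rid] = a.residue_name

    def residue_ids(self) -> List[tuple]:
        return list(self._residues)

    def residue_name(self, rid: tuple) -> str:
        return self._resnames[rid]

    def atom(self, rid: tuple, name: str) -> Optional[Atom]:
        return self._index.get((rid, _canonical_name(name)))

    def atom_coord(self, rid: tuple, name: str) -> Optional[np.ndarray]:
        a = self.atom(rid, name)
        return None if a is None else a.coords

    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [replace(a, coords=c.copy()) for a, c in zip(self.atoms, coords)]
        return StructureModel(self.model_id, atoms)

    def bridging_oxygen(self, donor_rid: tuple, acceptor_rid: tuple,
                        x: int) -> Optional[np.ndarray]:
        """Oxygen within covalent distance of both the donor C1 and the
        acceptor CX, regardless of which residue the PDB assigns it to."""
        c1 = self.atom_coord(donor_rid, "C1")
        cx = self.atom_coord(acceptor_rid, f"C{x}")
        if c1 is None or cx is None:
            return None
        best, best_d = None, np.inf
        for a in self.atoms:
            if not _canonical_name(a.name).startswith("O"):
                continue
            d1 = np.linalg.norm(a.coords - c1)
            d2 = np.linalg.norm(a.coords - cx)
            if d1 < GLYCOSIDIC_CO_CUTOFF and d2 < GLYCOSIDIC_CO_CUTOFF:
                if d1 + d2 < best_d:
                    best, best_d = a.coords, d1 + d2
        return best


def read_pdb_models(path) -> List[StructureModel]:
    """All coordinate models of a PDB file (one model when there are no
    MODEL records).  Malformed fixed-column records raise a parse error
    carrying the offending line number (via gemmi)."""
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"PDB parse error in {path}: {exc}") from exc
    models = []
    for im, model in enumerate(st, start=1):
        atoms = []
        serial = 0
        for chain in model:
            for res in chain:
                for at in res:
                    serial += 1
                    atoms.append(Atom(
                        serial=serial, name=at.name.strip(),
                        residue_name=res.name.strip(),
                        chain=chain.name.strip() or "A",
                        residue_number=res.seqid.num,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        element=at.element.name))
        raw = getattr(model, "num", None) or getattr(model, "name", None)
        try:
            model_id = int(raw)
        except (ValueError, TypeError):
            model_id = im
        models.append(StructureModel(model_id=model_id, atoms=atoms))
    if not models:
        raise ValueError(f"{path}: no coordinate models found")
    return models


def write_pdb_models(models: Sequence[StructureModel], path) -> None:
    """Write fixed-column PDB text (HETATM records, MODEL/ENDMDL framing
    when more than one model); coordinates at format precision (3
    decimals)."""
    lines = []
    multi = len(models) > 1
    for m in models:
        if multi:
            lines.append(f"MODEL     {m.model_id:4d}")
        for a in m.atoms:
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            el = (a.element or a.name[0]).rjust(2)
            x, y, z = a.coords
            lines.append(
                f"HETATM{a.serial:5d} {name:<4.4s} {a.residue_name:<3.3s} "
                f"{a.chain[:1]}{a.residue_number:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el}")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def find_glycosidic_linkages(model: StructureModel) -> List[LinkageSpec]:
    """Glycosidic linkages by connectivity: for every inter-residue
    C1-O-CX bridge (X in {3, 4}) within covalent distance, a
    ``LinkageSpec`` with the C1 owner as donor.  Ambiguous connectivity is
    reported as a warning, never silently dropped."""
    oxygens = [a for a in model.atoms
               if _canonical_name(a.name).startswith("O")]
    found: List[LinkageSpec] = []
    for donor in model.residue_ids():
        c1 = model.atom_coord(donor, "C1")
        if c1 is None:
            continue
        bonded_o = [a for a in oxygens
                    if np.linalg.norm(a.coords - c1) < GLYCOSIDIC_CO_CUTOFF]
        candidates = []
        for o in bonded_o:
            for acceptor in model.residue_ids():
                if acceptor == donor:
                    continue
                for x in (3, 4):
                    cx = model.atom_coord(acceptor, f"C{x}")
                    if cx is None:
                        continue
                    if np.linalg.norm(o.coords - cx) < GLYCOSIDIC_CO_CUTOFF:
                        candidates.append(LinkageSpec(
                            donor_residue_id=donor,
                            acceptor_residue_id=acceptor, linkage_x=x))
        if len(candidates) > 1:
            warnings.warn(
                f"residue {donor}: C1 bridges to {len(candidates)} acceptor "
                f"carbons; keeping all", stacklevel=2)
        found.extend(candidates)
    return found


def classify_residue_puckers(model: StructureModel) -> List[tuple]:
    """Per-residue (residue id, PuckerParams, canonical name) for every
    residue with a resolvable six-membered O5, C1..C5 ring; residues with
    missing or broken rings are skipped with a warning."""
    out = []
    for rid in model.residue_ids():
        coords = [model.atom_coord(rid, n) for n in RING_NAMES]
        if any(c is None for c in coords):
            missing = [n for n, c in zip(RING_NAMES, coords) if c is None]
            warnings.warn(f"residue {rid} ({model.residue_name(rid)}): "
                          f"missing ring atoms {missing}; skipped",
                          stacklevel=2)
            continue
        try:
            ring = RingConformer(atom_labels=RING_NAMES,
                                 coords=np.array(coords),
                                 source_tag=f"model{model.model_id}:{rid}")
            params = cremer_pople(ring)
            name = pucker_name(params)
        except ValueError as exc:
            warnings.warn(f"residue {rid}: {exc}; skipped", stacklevel=2)
            continue
        out.append((rid, params, name))
    return out


def consensus_linkage_torsions(model: StructureModel) -> dict:
    """Per-linkage (phi, psi) plus a circular-mean consensus grouped by
    donor->acceptor residue-name pair.

    Returns ``{"linkages": [...], "consensus": {(donor_name, acceptor_name):
    (phi, psi)}}``; angles in degrees.
    """
    rows = []
    groups: Dict[tuple, list] = {}
    for spec in find_glycosidic_linkages(model):
        tp = phi_psi(model, spec)
        dname = model.residue_name(spec.donor_residue_id)
        aname = model.residue_name(spec.acceptor_residue_id)
        rows.append({"donor": spec.donor_residue_id,
                     "acceptor": spec.acceptor_residue_id,
                     "x": spec.linkage_x, "donor_name": dname,
                     "acceptor_name": aname, "phi": tp.phi, "psi": tp.psi})
        groups.setdefault((dname, aname), []).append((tp.phi, tp.psi))

    def circ_mean(vals):
        r = np.radians(vals)
        return float(np.degrees(np.arctan2(np.mean(np.sin(r)),
                                           np.mean(np.cos(r)))))

    consensus = {k: (circ_mean([p for p, _ in v]),
                     circ_mean([q for _, q in v]))
                 for k, v in groups.items()}
    return {"linkages": rows, "consensus": consensus}


# ---------------------------------------------------------------------------
# Fixture construction
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Position of atom d bonded to c with |cd| = bond, angle(b,c,d) =
    angle, and torsion(a,b,c,d) = torsion (degrees)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    n = np.cross(b - a, bc_hat)
    n_hat = n / np.linalg.norm(n)
    m = np.cross(n_hat, bc_hat)
    ang = np.radians(angle)
    tor = np.radians(torsion)
    d = c + bond * (-np.cos(ang) * bc_hat
                    + np.sin(ang) * (np.cos(tor) * m + np.sin(tor) * n_hat))
    return d


_CC, _CO, _OS, _CN = 1.52, 1.43, 1.60, 1.47
_TET = 109.47


@dataclass(frozen=True)
class _ResidueChem:
    """Chemical flavor of a fixture residue: base name and which ring
    carbons get exocyclic O/N decorations."""
    base: str
    oxygens: tuple      # ring-carbon numbers that carry a free hydroxyl O
    nitrogen: Optional[int] = None  # ring carbon with an amino N (GlcN/GalN)


_CHEM = {
    "IdoA": _ResidueChem(base="IDO", oxygens=(2, 3)),
    "GlcNS": _ResidueChem(base="SGN", oxygens=(3, 6), nitrogen=2),
    "GalNAc": _ResidueChem(base="NGA", oxygens=(4, 6), nitrogen=2),
}

#: Disaccharide templates: (donor residue, acceptor residue, attachment X,
#: which residue is the iduronate).  The acceptor is the reducing end and
#: carries the O-methyl aglycone.
DISACCHARIDE_TEMPLATES = {
    "HS1": ("IdoA", "GlcNS", 4),
    "HS2": ("GlcNS", "IdoA", 4),
    "DS1": ("IdoA", "GalNAc", 3),
    "DS2": ("GalNAc", "IdoA", 4),
}

#: Sulfation codes: positions receiving -OSO3(-) per pattern key.  R1 is
#: the hexosamine 3-O (HS) / GalNAc 4-O (DS), R2 the iduronate 2-O (HS) /
#: GalNAc 6-O (DS), R3 the hexosamine 6-O (HS) / iduronate 2-O (DS).
SULFATION_CODES = {
    "HS": {"1": (), "2": ("R3",), "3": ("R2", "R3"), "4": ("R1", "R2", "R3")},
    "DS": {"a": ("R1",), "b": ("R1", "R3"), "d": ("R2", "R3"),
           "e": ("R1", "R2")},
}

_SULFATION_SITES = {
    "HS": {"R1": ("GlcNS", 3), "R2": ("IdoA", 2), "R3": ("GlcNS", 6)},
    "DS": {"R1": ("GalNAc", 4), "R2": ("GalNAc", 6), "R3": ("IdoA", 2)},
}


def _ring_coords(pucker: "PuckerState | str", Q: float = 0.55) -> dict:
    """Ring-atom coordinates at a prescribed pucker, keyed by name."""
    if isinstance(pucker, PuckerState):
        state = pucker
    else:
        state = IDOA_REFERENCE_GEOMETRIES.get(pucker) or canonical_state(pucker)
    theta = state.theta_ideal
    phi = state.phi_ideal if state.phi_ideal is not None else 0.0
    ring = inverse_cremer_pople(Q, theta, phi)
    return dict(zip(ring.atom_labels, ring.coords))


class _FixtureBuilder:
    def __init__(self):
        self.atoms: List[Atom] = []
        self._serial = 0

    def add(self, name, resname, resnum, coords, chain="A", element=None):
        self._serial += 1
        el = element or name[0]
        self.atoms.append(Atom(serial=self._serial, name=name,
                               residue_name=resname, chain=chain,
                               residue_number=resnum,
                               coords=np.asarray(coords, dtype=float),
                               element=el))
        return self.atoms[-1]

    def model(self, model_id=1) -> StructureModel:
        return StructureModel(model_id=model_id, atoms=self.atoms)


def _decorate(builder, ring: dict, chem: _ResidueChem, resname, resnum,
              sulfated: Sequence[int], skip_oxygens: Sequence[int] = ()):
    """Add exocyclic substituents (hydroxyl O, amino N, sulfate S) to a
    placed ring with idealized geometry."""
    for n in chem.oxygens:
        if n in skip_oxygens:
            continue
        if n == 6:  # primary alcohol: C6 on C5, then O6 anti to O5
            carbon = _place_atom(ring["C4"], ring["C5"], ring["O5"],
                                 _CC, _TET, -120.0)
            builder.add("C6", resname, resnum, carbon)
            pos = _place_atom(ring["O5"], ring["C5"], carbon,
                              _CO, _TET, 180.0)
        else:  # secondary hydroxyl on ring carbon n
            carbon = ring[f"C{n}"]
            prev2 = ring[RING_NAMES[n - 2]] if n >= 2 else ring["O5"]
            prev1 = ring[RING_NAMES[n - 1]]
            pos = _place_atom(prev2, prev1, carbon, _CO, _TET, 120.0)
        o = builder.add(f"O{n}", resname, resnum, pos)
        if n in sulfated:  # sulfate S collinear with the C-O bond
            s = o.coords + _OS * _unit(o.coords - carbon)
            builder.add(f"S{n}", resname, resnum, s, element="S")
    if chem.nitrogen is not None:
        n = chem.nitrogen
        prev2 = ring[RING_NAMES[n - 2]] if n >= 2 else ring["O5"]
        pos = _place_atom(prev2, ring[RING_NAMES[n - 1]], ring[f"C{n}"],
                          _CN, _TET, -120.0)
        builder.add(f"N{n}", resname, resnum, pos, element="N")


def _unit(v):
    return v / np.linalg.norm(v)


def _attach_donor_ring(acceptor_ring: dict, x: int, phi: float, psi: float,
                       donor_template: dict) -> tuple:
    """Place a donor ring onto an acceptor through a 1->X linkage with the
    glycosidic torsions set exactly; returns (bridge O coords, placed donor
    ring dict)."""
    cx = acceptor_ring[f"C{x}"]
    cxm1 = acceptor_ring[f"C{x - 1}"]
    cxm2 = acceptor_ring[f"C{x - 2}"]
    # bridge oxygen OX on the acceptor CX
    ox = _place_atom(cxm2, cxm1, cx, _CO, _TET, 120.0)
    # donor C1 from psi = C1-OX-CX-C(X-1)
    c1 = _place_atom(cxm1, cx, ox, _CO, 116.0, psi)
    # donor O5 from phi = O5-C1-OX-CX
    t = donor_template
    d_c1o5 = np.linalg.norm(t["C1"] - t["O5"])
    o5 = _place_atom(cx, ox, c1, d_c1o5, _TET, phi)
    # donor C5 fixes the ring spin about C1-O5; -175 deg keeps chains
    # extended (anomeric-substituent-like placement, no self-contact)
    d_o5c5 = np.linalg.norm(t["O5"] - t["C5"])
    ang_c1_o5_c5 = _angle(t["C1"], t["O5"], t["C5"])
    c5 = _place_atom(ox, c1, o5, d_o5c5, ang_c1_o5_c5, -175.0)
    # rigid map of the template onto the placed (C1, O5, C5) triple
    src = np.array([t["C1"], t["O5"], t["C5"]])
    dst = np.array([c1, o5, c5])
    rot, trans = _rigid_fit(src, dst)
    placed = {n: rot @ t[n] + trans for n in RING_NAMES}
    return ox, placed


def _angle(a, b, c) -> float:
    u, v = _unit(a - b), _unit(c - b)
    return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1, 1))))


def _rigid_fit(src: np.ndarray, dst: np.ndarray) -> tuple:
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    h = (src - sc).T @ (dst - dc)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, dc - rot @ sc


def _resname(chem: _ResidueChem, sulfated: Sequence[int]) -> str:
    if chem.base == "IDO":
        return "IDS" if 2 in sulfated else "IDR"
    if chem.base == "SGN":
        return "SGN"
    return "ASG" if 4 in sulfated else "NGA"


def build_disaccharide_fixture(template: str, sulfation: str,
                               pucker: "PuckerState | str",
                               phi: float, psi: float,
                               model_id: int = 1) -> StructureModel:
    """Idealized-geometry disaccharide with the iduronate ring at the
    requested pucker and the glycosidic (phi, psi) set exactly.

    ``template`` is HS1/HS2/DS1/DS2 and ``sulfation`` one of that family's
    four biologically relevant codes (HS: 1-4; DS: a/b/d/e).  The reducing
    (acceptor) residue is number 1 and carries an O-methyl aglycone;
    ``phi_psi`` on the built structure round-trips the inputs exactly.
    """
    if template not in DISACCHARIDE_TEMPLATES:
        raise ValueError(f"unknown template {template!r}; "
                         f"known: {sorted(DISACCHARIDE_TEMPLATES)}")
    family = template[:2]
    codes = SULFATION_CODES[family]
    if sulfation not in codes:
        raise ValueError(f"unknown sulfation code {sulfation!r} for "
                         f"{family}; known: {sorted(codes)}")
    donor_kind, acceptor_kind, x = DISACCHARIDE_TEMPLATES[template]
    sulf_by_kind: Dict[str, list] = {donor_kind: [], acceptor_kind: []}
    for r in codes[sulfation]:
        kind, pos = _SULFATION_SITES[family][r]
        sulf_by_kind[kind].append(pos)

    donor_pucker = pucker if donor_kind == "IdoA" else "4C1"
    acceptor_pucker = pucker if acceptor_kind == "IdoA" else "4C1"

    b = _FixtureBuilder()
    acc_ring = _ring_coords(acceptor_pucker)
    acc_chem = _CHEM[acceptor_kind]
    acc_name = _resname(acc_chem, sulf_by_kind[acceptor_kind])
    for n in RING_NAMES:
        b.add(n, acc_name, 1, acc_ring[n])
    # O-methyl aglycone on the reducing-end anomeric carbon (frame C3-C2-C1)
    o1 = _place_atom(acc_ring["C3"], acc_ring["C2"], acc_ring["C1"],
                     _CO, _TET, -120.0)
    b.add("O1", acc_name, 1, o1)
    b.add("CM", acc_name, 1, o1 + _CO * _unit(o1 - acc_ring["C1"]))
    _decorate(b, acc_ring, acc_chem, acc_name, 1,
              sulfated=sulf_by_kind[acceptor_kind], skip_oxygens=(x,))

    don_template = _ring_coords(donor_pucker)
    ox, don_ring = _attach_donor_ring(acc_ring, x, phi, psi, don_template)
    b.add(f"O{x}", acc_name, 1, ox)  # bridge O belongs to the acceptor
    don_chem = _CHEM[donor_kind]
    don_name = _resname(don_chem, sulf_by_kind[donor_kind])
    for n in RING_NAMES:
        b.add(n, don_name, 2, don_ring[n])
    # free hydroxyl at the non-reducing end on the position the next
    # residue would occupy in the polymer (O3 for GalNAc, O4 otherwise)
    nr = 3 if donor_kind == "GalNAc" else 4
    prev = don_ring[f"C{nr - 2}"] if nr - 2 >= 1 else don_ring["O5"]
    o_nr = _place_atom(prev, don_ring[f"C{nr - 1}"], don_ring[f"C{nr}"],
                       _CO, _TET, 120.0)
    b.add(f"O{nr}", don_name, 2, o_nr)
    _decorate(b, don_ring, don_chem, don_name, 2,
              sulfated=sulf_by_kind[donor_kind], skip_oxygens=(nr,))
    return b.model(model_id=model_id)


def build_heparin_dodecasaccharide(
    idoa_pucker: "PuckerState | str",
    phipsi_ido_glc: Tuple[float, float],
    phipsi_glc_ido: Tuple[float, float],
    n_disaccharides: int = 6,
    model_id: int = 1,
) -> StructureModel:
    """SYNTHETIC stand-in for the heparin [-4IdoA2S(a1-4)GlcNS6S(a1-)]n
    NMR dodecasaccharide: an idealized-geometry helix with every IdoA2S
    ring at ``idoa_pucker``, every IdoA2S->GlcNS6S linkage at
    ``phipsi_ido_glc``, and every GlcNS6S->IdoA2S linkage at
    ``phipsi_glc_ido`` (all 1->4).

    This is constructed geometry, not experimental coordinates: it encodes
    the uniform-helix description of the NMR models (pucker state per model
    and one (phi, psi) pair per linkage type) so the parse -> classify ->
    measure pipeline can be exercised without the PDB entry itself.
    Residues alternate GlcNS6S (SGN, odd numbers, reducing end first) and
    IdoA2S (IDS, even numbers).
    """
    b = _FixtureBuilder()
    glc_chem = _CHEM["GlcNS"]
    ido_chem = _CHEM["IdoA"]

    rings = []  # (resnum, kind, ring dict)
    ring = _ring_coords("4C1")
    b_resnum = 1
    for n in RING_NAMES:
        b.add(n, "SGN", b_resnum, ring[n])
    o1 = _place_atom(ring["C3"], ring["C2"], ring["C1"], _CO, _TET, -120.0)
    b.add("O1", "SGN", b_resnum, o1)
    _decorate(b, ring, glc_chem, "SGN", b_resnum, sulfated=[6],
              skip_oxygens=(4,))
    rings.append((b_resnum, "GlcNS", ring))

    for k in range(2 * n_disaccharides - 1):
        prev_num, prev_kind, prev_ring = rings[-1]
        resnum = prev_num + 1
        if prev_kind == "GlcNS":  # add IdoA2S donor: IdoA2S a1-4 GlcNS6S
            kind, resname, chem = "IdoA", "IDS", ido_chem
            pucker = idoa_pucker
            phi, psi = phipsi_ido_glc
            sulf = [2]
        else:  # add GlcNS6S donor: GlcNS6S a1-4 IdoA2S
            kind, resname, chem = "GlcNS", "SGN", glc_chem
            pucker = "4C1"
            phi, psi = phipsi_glc_ido
            sulf = [6]
        template = _ring_coords(pucker)
        ox, placed = _attach_donor_ring(prev_ring, 4, phi, psi, template)
        prev_name = "SGN" if prev_kind == "GlcNS" else "IDS"
        b.add("O4", prev_name, prev_num, ox)
        for n in RING_NAMES:
            b.add(n, resname, resnum, placed[n])
        _decorate(b, placed, chem, resname, resnum, sulfated=sulf)
        if k == 2 * n_disaccharides - 2:  # free O4 at the non-reducing end
            o4 = _place_atom(placed["C2"], placed["C3"], placed["C4"],
                             _CO, _TET, 120.0)
            b.add("O4", resname, resnum, o4)
        rings.append((resnum, kind, placed))
    return b.model(model_id=model_id)
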