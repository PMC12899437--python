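"""Cremer-Pople ring puckering for six-membered (pyranose) rings.

The ring is described by the out-of-plane displacements ``z_j`` of its six
atoms from the Cremer-Pople mean plane.  For a six-membered ring these
displacements carry exactly three puckering degrees of freedom, expressed
as an amplitude/direction triple (Q, theta, phi)::

    q2 cos(phi2) =  sqrt(2/6) * sum_j z_j cos(2*pi*2*j/6)
    q2 sin(phi2) = -sqrt(2/6) * sum_j z_j sin(2*pi*2*j/6)
    q3          =  sqrt(1/6) * sum_j (-1)^j z_j
    Q = sqrt(q2^2 + q3^2),  cos(theta) = q3 / Q

Atoms are ordered O5, C1, C2, C3, C4, C5 (j = 0..5) and the mean-plane
normal follows the standard Cremer-Pople construction, so that the 4C1
chair maps to theta = 0, the 1C4 chair to theta = 180, the 2SO twist-boat
to (90, 150) and the B3,O boat to (90, 180).  phi (the azimuth) is
undefined at the poles and for planar rings.

The canonical conformer catalogue (2 chairs, 6 boats, 6 twist-boats,
12 envelopes, 12 half-chairs = 38 forms) is generated from the idealized
displacement pattern of each form, so names, vertices, and the forward
transform share one convention by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .torsions import dihedral, periodic_diff

__all__ = [
    "RingConformer",
    "PuckerParams",
    "PuckerState",
    "CANONICAL_STATES",
    "IDOA_REFERENCE_GEOMETRIES",
    "cremer_pople",
    "inverse_cremer_pople",
    "pucker_name",
    "idealness_score",
    "select_most_ideal",
    "ring_dihedrals",
]

RING_ATOM_ORDER = ("O5", "C1", "C2", "C3", "C4", "C5")

#: Planarity tolerance: below this puckering amplitude (Angstrom) the
#: puckering direction is considered undefined.
PLANARITY_TOL = 1e-4

#: Polar tolerance (degrees): within this distance of theta = 0 or 180 the
#: azimuth phi is reported as undefined.
POLE_TOL = 1e-6


@dataclass
class RingConformer:
    """Six ordered ring atoms (O5, C1..C5 convention) with coordinates in A."""

    atom_labels: tuple
    coords: np.ndarray
    source_tag: str = ""

    def __post_init__(self):
        self.atom_labels = tuple(self.atom_labels)
        self.coords = np.asarray(self.coords, dtype=float)
        if len(self.atom_labels) != 6 or self.coords.shape != (6, 3):
            raise ValueError("a ring conformer requires exactly six labelled atoms")
        if len(set(self.atom_labels)) != 6:
            raise ValueError("ring atom labels must be unique")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("ring coordinates must be finite")
        d = np.linalg.norm(self.coords - np.roll(self.coords, -1, axis=0), axis=1)
        if np.any(d < 0.5) or np.any(d > 2.5):
            raise ValueError(
                "consecutive ring atoms must be 0.5-2.5 A apart (bonded ring); "
                f"got distances {np.round(d, 3)}"
            )


@dataclass(frozen=True)
class PuckerParams:
    """Cremer-Pople amplitude and direction.

    ``phi`` is stored in [0, 360) and is meaningful only when
    ``phi_defined`` is true (theta away from the poles, Q above the
    planarity tolerance).
    """

    Q: float
    theta: float
    phi: float = 0.0
    phi_defined: bool = True

    def __post_init__(self):
        if self.Q < 0:
            raise ValueError("puckering amplitude Q must be >= 0")
        if not 0.0 <= self.theta <= 180.0:
            raise ValueError("theta must lie in [0, 180]")
        object.__setattr__(self, "phi", float(np.mod(self.phi, 360.0)))


@dataclass(frozen=True)
class PuckerState:
    """A named canonical pucker with its ideal (theta, phi) vertex.

    ``Phi0`` optionally carries six reference ring dihedrals (degrees) of a
    concrete geometry at this pucker, and ``theta0_phi0`` the Cremer-Pople
    values of that geometry; both are used by the ring restraint.
    """

    name: str
    theta_ideal: float
    phi_ideal: Optional[float] = None
    Phi0: Optional[tuple] = None
    theta0_phi0: Optional[tuple] = None

    @property
    def is_chair(self) -> bool:
        return self.phi_ideal is None


def _params_from_z(z: np.ndarray) -> tuple:
    """(q2, phi2_deg_in_[0,360), q3) from six displacements."""
    j = np.arange(6)
    ang = 2.0 * np.pi * 2.0 * j / 6.0
    q2c = np.sqrt(2.0 / 6.0) * float(np.sum(z * np.cos(ang)))
    q2s = -np.sqrt(2.0 / 6.0) * float(np.sum(z * np.sin(ang)))
    q3 = np.sqrt(1.0 / 6.0) * float(np.sum(((-1.0) ** j) * z))
    q2 = float(np.hypot(q2c, q2s))
    phi2 = float(np.mod(np.degrees(np.arctan2(q2s, q2c)), 360.0))
    return q2, phi2, q3


def _theta_phi_from_z(z: np.ndarray) -> tuple:
    q2, phi2, q3 = _params_from_z(z)
    Q = float(np.hypot(q2, q3))
    theta = float(np.degrees(np.arctan2(q2, q3)))
    return Q, theta, phi2


def cremer_pople(conformer: RingConformer) -> PuckerParams:
    """Forward Cremer-Pople transform of a six-membered ring.

    Raises ``ValueError`` for a planar ring (amplitude below
    ``PLANARITY_TOL``), where the puckering direction is undefined.
    """
    r = conformer.coords - conformer.coords.mean(axis=0)
    j = np.arange(6)
    s = np.sin(2.0 * np.pi * j / 6.0)
    c = np.cos(2.0 * np.pi * j / 6.0)
    rp = (r * s[:, None]).sum(axis=0)
    rpp = (r * c[:, None]).sum(axis=0)
    n = np.cross(rp, rpp)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("degenerate ring: cannot define a mean plane")
    n /= nn
    z = r @ n
    Q, theta, phi2 = _theta_phi_from_z(z)
    if Q < PLANARITY_TOL:
        raise ValueError("planar ring: undefined pucker direction")
    phi_defined = POLE_TOL < theta < 180.0 - POLE_TOL
    return PuckerParams(Q=Q, theta=theta, phi=phi2 if phi_defined else 0.0,
                        phi_defined=phi_defined)


#: In-plane hexagon radius (A) used by the inverse transform; a typical
#: pyranose ring-projection radius.  Only the out-of-plane harmonic content
#: matters for round-tripping.
HEXAGON_RADIUS = 1.46


def inverse_cremer_pople(
    Q: float,
    theta: float,
    phi: float = 0.0,
    radius: float = HEXAGON_RADIUS,
    atom_labels: Sequence[str] = RING_ATOM_ORDER,
    source_tag: str = "",
) -> RingConformer:
    """Build a ring with prescribed Cremer-Pople parameters.

    The ring projects to a regular hexagon in the mean plane; out-of-plane
    displacements carry only the m = 2 and m = 3 puckering harmonics, so the
    mean plane is exact and ``cremer_pople`` recovers (Q, theta, phi) to
    floating-point accuracy.
    """
    if Q <= 0:
        raise ValueError("puckering amplitude Q must be > 0")
    if not 0.0 <= theta <= 180.0:
        raise ValueError("theta must lie in [0, 180]")
    j = np.arange(6)
    th = np.radians(theta)
    ph2 = np.radians(phi)
    q2 = Q * np.sin(th)
    q3 = Q * np.cos(th)
    z = (np.sqrt(2.0 / 6.0) * q2 * np.cos(ph2 + 2.0 * np.pi * 2.0 * j / 6.0)
         + np.sqrt(1.0 / 6.0) * q3 * ((-1.0) ** j))
    # Vertex order chosen so the standard CP normal is +z and the chair
    # ring-dihedral signs match alpha-iduronate reference geometries.
    x = radius * np.sin(2.0 * np.pi * j / 6.0)
    y = radius * np.cos(2.0 * np.pi * j / 6.0)
    return RingConformer(atom_labels=tuple(atom_labels),
                         coords=np.column_stack([x, y, z]),
                         source_tag=source_tag)


def ring_dihedrals(conformer: RingConformer) -> np.ndarray:
    """The six cyclic ring dihedrals Phi_1..Phi_6 in degrees.

    Phi_i is the torsion about bond i-(i+1): Phi_1 = O5-C1-C2-C3,
    Phi_2 = C1-C2-C3-C4, ..., Phi_6 = C5-O5-C1-C2 (indices cyclic).
    """
    c = conformer.coords
    out = np.empty(6)
    for i in range(6):
        out[i] = dihedral(c[i % 6], c[(i + 1) % 6], c[(i + 2) % 6], c[(i + 3) % 6])
    return out


# ---------------------------------------------------------------------------
# Canonical conformer catalogue
# ---------------------------------------------------------------------------

def _pattern_vertex(z_pattern) -> tuple:
    """(theta, phi) vertex of an idealized displacement pattern."""
    z = np.asarray(z_pattern, dtype=float)
    z = z - z.mean()
    _, theta, phi2 = _theta_phi_from_z(z)
    return round(theta, 6), round(phi2, 6)


def _build_catalogue() -> tuple:
    """All 38 canonical pyranose forms from their displacement patterns.

    Atom index j: 0=O5, 1=C1, ..., 5=C5; in names the ring oxygen is 'O'.
    Superscript atoms (before the letter) are displaced above the plane,
    subscript atoms (after) below.
    """
    sym = ["O", "1", "2", "3", "4", "5"]
    states = []

    def add(name, z):
        theta, phi = _pattern_vertex(z)
        at_pole = theta < 1e-6 or theta > 180.0 - 1e-6
        states.append(PuckerState(name=name, theta_ideal=theta,
                                  phi_ideal=None if at_pole else phi))

    # Chairs: alternating displacements; 4C1 has C4 up / C1 down.
    add("4C1", [1, -1, 1, -1, 1, -1])
    add("1C4", [-1, 1, -1, 1, -1, 1])
    # Boats: atoms m and m+3 displaced together; subscript pair is down.
    for m in range(6):
        z = np.full(6, 0.5)
        z[m] = z[(m + 3) % 6] = -1.0
        lo, hi = sorted([m, (m + 3) % 6])
        add(f"B{sym[lo]}{sym[hi]}" if lo else f"B{sym[hi]}{sym[lo]}", z)
        add((f"{sym[lo]}{sym[hi]}B" if lo else f"{sym[hi]}{sym[lo]}B"), -z)
    # Twist-boats aS_b: atoms a and a+3 up, b and b+3 down; the canonical
    # representative pair (a, b) for each of the six forms:
    for a, b in ((3, 1), (5, 1), (2, 0), (1, 3), (1, 5), (0, 2)):
        z = np.zeros(6)
        z[a] = z[(a + 3) % 6] = np.sqrt(3.0) / 2.0
        z[b] = z[(b + 3) % 6] = -np.sqrt(3.0) / 2.0
        add(f"{sym[a]}S{sym[b]}", z)
    # Envelopes jE (atom j up) and E_j (atom j down).
    for m in range(6):
        z = np.zeros(6)
        z[m] = 1.0
        add(f"{sym[m]}E", z)
        add(f"E{sym[m]}", -z)
    # Half-chairs aH_b: adjacent atoms, a up and b down.
    for a in range(6):
        for b in ((a + 1) % 6, (a - 1) % 6):
            z = np.zeros(6)
            z[a], z[b] = 1.0, -1.0
            add(f"{sym[a]}H{sym[b]}", z)

    # De-duplicate boats produced twice by the +/- construction.
    seen, unique = set(), []
    for s in states:
        if s.name not in seen:
            seen.add(s.name)
            unique.append(s)
    assert len(unique) == 38, f"catalogue has {len(unique)} forms, expected 38"
    return tuple(unique)


CANONICAL_STATES: tuple = _build_catalogue()
_CANONICAL_BY_NAME = {s.name: s for s in CANONICAL_STATES}


def canonical_state(name: str) -> PuckerState:
    """Look up a canonical form (e.g. ``"1C4"``, ``"2SO"``) by name."""
    try:
        return _CANONICAL_BY_NAME[name]
    except KeyError:
        raise KeyError(f"unknown canonical pucker {name!r}; "
                       f"known: {sorted(_CANONICAL_BY_NAME)}") from None


#: Reference alpha-iduronate geometries used to parameterize the ring
#: restraint: near-ideal Cremer-Pople values (theta0, phi0) and the six ring
#: dihedrals Phi_0,i of concrete conformers at each of the four pucker
#: states relevant to iduronate.
IDOA_REFERENCE_GEOMETRIES = {
    "1C4": PuckerState(
        name="1C4", theta_ideal=180.0, phi_ideal=None,
        Phi0=(-61.4, 57.4, -58.2, 65.5, -65.1, 61.6),
        theta0_phi0=(179.72, None)),
    "2SO": PuckerState(
        name="2SO", theta_ideal=90.0, phi_ideal=150.0,
        Phi0=(27.7, -56.4, 26.5, 29.5, -60.1, 29.1),
        theta0_phi0=(89.92, 149.87)),
    "B3O": PuckerState(
        name="B3O", theta_ideal=90.0, phi_ideal=180.0,
        Phi0=(-2.6, -53.9, 54.7, 0.6, -60.8, 62.5),
        theta0_phi0=(90.07, 180.03)),
    "4C1": PuckerState(
        name="4C1", theta_ideal=0.0, phi_ideal=None,
        Phi0=(68.1, -62.6, 66.2, -70.6, 67.3, -69.6),
        theta0_phi0=(0.17, None)),
}


def great_circle_distance(theta_a, phi_a, theta_b, phi_b) -> float:
    """Angular distance (degrees) between two points on the CP sphere.

    ``phi`` may be ``None`` at a pole, where the azimuth is irrelevant.
    """
    ta, tb = np.radians(theta_a), np.radians(theta_b)
    if phi_a is None or phi_b is None:
        return float(abs(theta_a - theta_b))
    dphi = np.radians(phi_a - phi_b)
    cosd = np.cos(ta) * np.cos(tb) + np.sin(ta) * np.sin(tb) * np.cos(dphi)
    return float(np.degrees(np.arccos(np.clip(cosd, -1.0, 1.0))))


def pucker_name(params: PuckerParams) -> str:
    """Name of the canonical conformer nearest on the CP sphere.

    Ties are broken by the fixed catalogue ordering.  A ``PuckerParams``
    with undefined azimuth away from the poles cannot be disambiguated and
    raises ``ValueError``.
    """
    phi = params.phi if params.phi_defined else None
    if phi is None and 30.0 < params.theta < 150.0:
        raise ValueError(
            "undefined azimuth with equatorial theta: cannot disambiguate "
            "boat/twist-boat forms")
    best_name, best_d = None, np.inf
    for s in CANONICAL_STATES:
        d = great_circle_distance(params.theta, phi, s.theta_ideal, s.phi_ideal)
        if d < best_d - 1e-12:
            best_name, best_d = s.name, d
    return best_name


def idealness_score(params: PuckerParams, target: PuckerState) -> float:
    """Squared angular deviation (deg^2) from a target ideal pucker.

    Chair targets use the theta term only, ``(theta - theta_ideal)^2``;
    equatorial targets add the azimuth term with a minimal-image periodic
    difference on phi: ``(theta - theta_ideal)^2 + (phi - phi_ideal)^2``.
    """
    d_theta = params.theta - target.theta_ideal
    if target.is_chair:
        return float(d_theta * d_theta)
    if not params.phi_defined:
        raise ValueError("cannot score an undefined azimuth against an "
                         "equatorial target")
    d_phi = periodic_diff(params.phi, target.phi_ideal)
    return float(d_theta * d_theta + d_phi * d_phi)


def select_most_ideal(ensemble: Sequence[RingConformer],
                      target: PuckerState) -> tuple:
    """(index, conformer) of the ensemble member closest to the target
    pucker by ``idealness_score``; ties go to the lowest index."""
    if len(ensemble) == 0:
        raise ValueError("cannot select from an empty ensemble")
    best_i, best_s = 0, np.inf
    for i, conf in enumerate(ensemble):
        s = idealness_score(cremer_pople(conf), target)
        if s < best_s - 1e-15:
            best_i, best_s = i, s
    return best_i, ensemble[best_i]
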