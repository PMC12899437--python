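"""Ring-dihedral restraining potential and pucker-retention diagnostics.

During biased sampling of the glycosidic torsions, the iduronate ring must
be held in one chosen pucker state while remaining free to deform
moderately.  The restraint is harmonic in the six ring dihedrals::

    E(Phi) = (1/2) * k * sum_i ((Phi_i - Phi0_i) / w)^2

with defaults k = 1 kcal/mol and width w = 5 degrees, referenced to the
ring dihedrals of a near-ideal conformer at the target pucker state.
Differences are wrap-aware (minimal image on the circle), which matters for
dihedrals near +/-180 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .pucker import (IDOA_REFERENCE_GEOMETRIES, PuckerParams, cremer_pople,
                     great_circle_distance, inverse_cremer_pople,
                     ring_dihedrals)
from .torsions import periodic_diff

__all__ = [
    "RestraintSpec",
    "restraint_energy",
    "restraint_gradient",
    "pucker_retention",
    "sample_restrained_pucker",
    "colvars_harmonic_block",
]


@dataclass(frozen=True)
class RestraintSpec:
    """Six reference dihedrals Phi0 (degrees), force constant k (kcal/mol)
    and width w (degrees)."""

    Phi0: tuple
    k: float = 1.0
    w: float = 5.0

    def __post_init__(self):
        object.__setattr__(
            self, "Phi0",
            tuple(float(p) if -180.0 < p <= 180.0
                  else float(periodic_diff(p, 0.0)) for p in self.Phi0))
        if len(self.Phi0) != 6:
            raise ValueError("a ring restraint requires six reference dihedrals")
        if self.w <= 0:
            raise ValueError("restraint width w must be > 0")
        if self.k < 0:
            raise ValueError("force constant k must be >= 0")

    @classmethod
    def for_pucker(cls, target: "PuckerState | str",
                   k: float = 1.0, w: float = 5.0) -> "RestraintSpec":
        """Default restraint for one of the four iduronate pucker states,
        using its reference ring dihedrals."""
        if isinstance(target, str):
            target = IDOA_REFERENCE_GEOMETRIES[target]
        if target.Phi0 is None:
            raise ValueError(f"pucker state {target.name} carries no reference "
                             "ring dihedrals")
        return cls(Phi0=target.Phi0, k=k, w=w)


def _deltas(Phi: Sequence[float], spec: RestraintSpec) -> np.ndarray:
    Phi = np.asarray(Phi, dtype=float)
    if Phi.shape != (6,):
        raise ValueError("expected six ring dihedrals")
    return np.asarray(periodic_diff(Phi, np.asarray(spec.Phi0)))


def restraint_energy(Phi: Sequence[float], spec: RestraintSpec) -> float:
    """Restraint energy in kcal/mol for six ring dihedrals (degrees)."""
    d = _deltas(Phi, spec)
    return float(0.5 * spec.k * np.sum((d / spec.w) ** 2))


def restraint_gradient(Phi: Sequence[float], spec: RestraintSpec) -> np.ndarray:
    """dE/dPhi_i in kcal/mol/degree (analytic)."""
    d = _deltas(Phi, spec)
    return spec.k * d / spec.w**2


def pucker_retention(theta_phi_series: Sequence[PuckerParams],
                     target: "PuckerState | str",
                     radius: float = 30.0) -> float:
    """Fraction of a pucker-parameter series within ``radius`` degrees
    (great-circle, on the CP sphere) of the target's ideal point.

    For chair targets the distance reduces to the theta separation.  The
    default radius of 30 degrees separates the four iduronate states, which
    are at least 41 degrees apart except 2SO/B3O at 30 degrees.
    """
    if isinstance(target, str):
        target = IDOA_REFERENCE_GEOMETRIES[target]
    if len(theta_phi_series) == 0:
        raise ValueError("empty pucker series")
    n_in = 0
    for p in theta_phi_series:
        phi = p.phi if p.phi_defined else None
        d = great_circle_distance(p.theta, phi if not target.is_chair else None,
                                  target.theta_ideal, target.phi_ideal)
        if d <= radius:
            n_in += 1
    return n_in / len(theta_phi_series)


def sample_restrained_pucker(
    target: "PuckerState | str",
    spec: Optional[RestraintSpec] = None,
    n_samples: int = 2000,
    temperature: float = 298.0,
    Q: float = 0.6,
    step: float = 4.0,
    seed: int = 0,
) -> list:
    """Metropolis sampling of (theta, phi) under the ring restraint at the
    given temperature; a desk-scale emulation of restrained ring dynamics.

    The restraint energy is evaluated on idealized rings built at each
    trial (theta, phi) with fixed amplitude Q, so the stationary density is
    exp(-E_restraint/kT) over pucker direction.  Returns a list of
    ``PuckerParams`` suitable for :func:`pucker_retention`.
    """
    if isinstance(target, str):
        target = IDOA_REFERENCE_GEOMETRIES[target]
    if spec is None:
        spec = RestraintSpec.for_pucker(target)
    kT = 0.0019872041 * temperature  # kcal/mol per K

    def energy(theta, phi):
        ring = inverse_cremer_pople(Q, theta, phi)
        return restraint_energy(ring_dihedrals(ring), spec)

    rng = np.random.default_rng(seed)
    theta = target.theta_ideal
    phi = target.phi_ideal if target.phi_ideal is not None else 0.0
    theta = min(max(theta, 1.0), 179.0)  # keep azimuth defined at the poles
    e = energy(theta, phi)
    out = []
    for _ in range(n_samples):
        t_new = theta + step * rng.standard_normal()
        p_new = (phi + step * rng.standard_normal()) % 360.0
        if 0.5 <= t_new <= 179.5:
            e_new = energy(t_new, p_new)
            if e_new <= e or rng.random() < np.exp(-(e_new - e) / kT):
                theta, phi, e = t_new, p_new, e_new
        out.append(cremer_pople(inverse_cremer_pople(Q, theta, phi)))
    return out


def colvars_harmonic_block(spec: RestraintSpec, name: str = "ringRestraint") -> str:
    """Text of an equivalent Colvars-style harmonic restraint block.

    Documentation aid for transferring the restraint to an MD engine; the
    block is emitted, never executed, by this package.
    """
    centers = " ".join(f"{p:.1f}" for p in spec.Phi0)
    lines = [f"harmonic {{", f"    name {name}", f"    colvars ringDihedrals",
             f"    centers ({centers})",
             f"    forceConstant {spec.k:g}  # kcal/mol per (width)^2",
             f"    width {spec.w:g}  # degrees", "}"]
    return "\n".join(lines) + "\n"
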