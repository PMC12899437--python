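"""Cremer-Pople transforms, canonical naming, and idealness scoring."""

import numpy as np
import pytest

from gagfes.pucker import (CANONICAL_STATES, IDOA_REFERENCE_GEOMETRIES,
                           PuckerParams, RingConformer, canonical_state,
                           cremer_pople, great_circle_distance,
                           idealness_score, inverse_cremer_pople, pucker_name,
                           ring_dihedrals, select_most_ideal)
from gagfes.torsions import periodic_diff
from gagfes.toy import make_ring_ensemble


def _hexagon(z=None):
    j = np.arange(6)
    x = 1.46 * np.sin(2 * np.pi * j / 6)
    y = 1.46 * np.cos(2 * np.pi * j / 6)
    zz = np.zeros(6) if z is None else np.asarray(z, float)
    return RingConformer(atom_labels=("O5", "C1", "C2", "C3", "C4", "C5"),
                         coords=np.column_stack([x, y, zz]))


class TestForwardInverse:
    def test_round_trip_random(self, rng):
        """forward(inverse) is the identity over the whole CP sphere."""
        for _ in range(1000):
            Q = rng.uniform(0.3, 0.9)
            theta = rng.uniform(0.5, 179.5)
            phi = rng.uniform(0.0, 360.0)
            p = cremer_pople(inverse_cremer_pople(Q, theta, phi))
            assert abs(p.Q - Q) < 1e-9
            assert abs(p.theta - theta) < 1e-6
            assert abs(periodic_diff(p.phi, phi)) < 1e-6

    def test_chair_has_no_azimuth(self):
        p = cremer_pople(inverse_cremer_pople(0.57, 180.0, 0.0))
        assert p.theta == pytest.approx(180.0, abs=1e-9)
        assert not p.phi_defined

    def test_planar_ring_rejected(self):
        with pytest.raises(ValueError, match="planar"):
            cremer_pople(_hexagon())

    def test_inverse_rejects_zero_amplitude(self):
        with pytest.raises(ValueError):
            inverse_cremer_pople(0.0, 90.0, 0.0)

    def test_displacements_sum_to_zero(self, rng):
        """The generated harmonics exclude the m=0 (translation) mode."""
        for _ in range(20):
            ring = inverse_cremer_pople(rng.uniform(0.3, 0.9),
                                        rng.uniform(0, 180),
                                        rng.uniform(0, 360))
            assert abs(ring.coords[:, 2].sum()) < 1e-12

    def test_chair_displacement_alternates(self):
        ring = inverse_cremer_pople(0.5, 0.0, 0.0)
        z = ring.coords[:, 2]
        assert np.allclose(z, z[0] * (-1.0) ** np.arange(6))

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation
        ring = inverse_cremer_pople(0.76, 90.0, 150.0)
        rot = Rotation.random(rng=42).as_matrix()
        moved = RingConformer(atom_labels=ring.atom_labels,
                              coords=ring.coords @ rot.T + [3.0, -2.0, 7.0])
        a, b = cremer_pople(ring), cremer_pople(moved)
        assert abs(a.Q - b.Q) < 1e-9
        assert abs(a.theta - b.theta) < 1e-9
        assert abs(periodic_diff(a.phi, b.phi)) < 1e-9

    def test_orientation_reversal_maps_theta(self):
        """Traversing the ring in the opposite direction from the same
        start atom flips the CP pole: theta -> 180 - theta."""
        ring = inverse_cremer_pople(0.6, 40.0, 70.0)
        rev = RingConformer(atom_labels=ring.atom_labels,
                            coords=ring.coords[[0, 5, 4, 3, 2, 1]])
        assert cremer_pople(rev).theta == pytest.approx(140.0, abs=1e-9)


class TestValidation:
    def test_requires_six_atoms(self):
        with pytest.raises(ValueError):
            RingConformer(atom_labels=("A", "B", "C"), coords=np.zeros((3, 3)))

    def test_rejects_broken_ring(self):
        coords = np.array([[0, 0, 0], [10, 0, 0], [11, 0, 0], [12, 0, 0],
                           [13, 0, 0], [1, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="0.5-2.5"):
            RingConformer(atom_labels=list("ABCDEF"), coords=coords)


class TestNaming:
    @pytest.mark.parametrize("name,theta,phi", [
        ("1C4", 180.0, None), ("4C1", 0.0, None),
        ("2SO", 90.0, 150.0), ("B3O", 90.0, 180.0), ("OS2", 90.0, 330.0),
    ])
    def test_reference_vertices(self, name, theta, phi):
        s = canonical_state(name)
        assert s.theta_ideal == pytest.approx(theta, abs=1e-4)
        if phi is None:
            assert s.phi_ideal is None
        else:
            assert s.phi_ideal == pytest.approx(phi, abs=1e-4)

    def test_every_canonical_form_names_itself(self):
        for s in CANONICAL_STATES:
            p = PuckerParams(Q=0.6, theta=s.theta_ideal,
                             phi=s.phi_ideal or 0.0,
                             phi_defined=s.phi_ideal is not None)
            assert pucker_name(p) == s.name

    def test_nearest_matches_brute_force(self, rng):
        for _ in range(200):
            p = PuckerParams(Q=0.6, theta=rng.uniform(1, 179),
                             phi=rng.uniform(0, 360))
            dists = [(great_circle_distance(p.theta, p.phi, s.theta_ideal,
                                            s.phi_ideal), i)
                     for i, s in enumerate(CANONICAL_STATES)]
            best = min(dists)[1]
            assert pucker_name(p) == CANONICAL_STATES[best].name

    def test_equatorial_without_azimuth_is_ambiguous(self):
        with pytest.raises(ValueError, match="disambiguate"):
            pucker_name(PuckerParams(Q=0.6, theta=89.0, phi_defined=False))


class TestIdealness:
    def test_exact_chair_scores_zero(self):
        p = PuckerParams(Q=0.6, theta=180.0, phi_defined=False)
        assert idealness_score(p, IDOA_REFERENCE_GEOMETRIES["1C4"]) == 0.0

    def test_near_chair_theta_term(self):
        # theta 179.72 vs the 1C4 ideal of 180: (0.28)^2
        p = PuckerParams(Q=0.6, theta=179.72, phi_defined=False)
        score = idealness_score(p, IDOA_REFERENCE_GEOMETRIES["1C4"])
        assert score == pytest.approx(0.0784, abs=1e-10)

    def test_equatorial_two_term_score(self):
        # (89.92, 149.87) vs (90, 150): 0.08^2 + 0.13^2
        p = PuckerParams(Q=0.6, theta=89.92, phi=149.87)
        score = idealness_score(p, IDOA_REFERENCE_GEOMETRIES["2SO"])
        assert score == pytest.approx(0.08**2 + 0.13**2, abs=1e-10)

    def test_phi_difference_is_periodic(self):
        p = PuckerParams(Q=0.6, theta=90.0, phi=359.0)
        target = canonical_state("3OB")  # ideal (90, 0)
        assert idealness_score(p, target) == pytest.approx(1.0, abs=1e-9)

    def test_reference_rows_score_minimal_against_own_target(self):
        """Each near-ideal reference geometry is closest to its own pucker
        state among the four restraint targets."""
        targets = IDOA_REFERENCE_GEOMETRIES
        for name, state in targets.items():
            theta0, phi0 = state.theta0_phi0
            p = PuckerParams(Q=0.6, theta=theta0, phi=phi0 or 0.0,
                             phi_defined=phi0 is not None)
            own = idealness_score(p, state)
            for other_name, other in targets.items():
                if other_name == name:
                    continue
                if phi0 is None and not other.is_chair:
                    continue  # chair row cannot be scored on an equatorial target
                assert own < idealness_score(p, other)


class TestSelection:
    def test_exact_ideal_member_wins(self):
        target = IDOA_REFERENCE_GEOMETRIES["2SO"]
        ensemble = make_ring_ensemble(target, n=20, jitter_deg=5.0, seed=3)
        ensemble.append(inverse_cremer_pople(0.6, 90.0, 150.0))
        idx, best = select_most_ideal(ensemble, target)
        assert idx == len(ensemble) - 1
        assert idealness_score(cremer_pople(best), target) < 1e-12

    def test_tie_goes_to_lowest_index(self):
        ring = inverse_cremer_pople(0.6, 92.0, 151.0)
        dup = inverse_cremer_pople(0.6, 92.0, 151.0)
        idx, _ = select_most_ideal([ring, dup],
                                   IDOA_REFERENCE_GEOMETRIES["2SO"])
        assert idx == 0

    def test_matches_exhaustive_scan(self):
        target = IDOA_REFERENCE_GEOMETRIES["2SO"]
        ensemble = make_ring_ensemble(target, n=100, jitter_deg=4.0, seed=7)
        scores = [idealness_score(cremer_pople(c), target) for c in ensemble]
        idx, _ = select_most_ideal(ensemble, target)
        assert idx == int(np.argmin(scores))

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            select_most_ideal([], IDOA_REFERENCE_GEOMETRIES["1C4"])


class TestRingDihedrals:
    def test_chair_alternating_signs(self):
        phis = ring_dihedrals(inverse_cremer_pople(0.57, 180.0, 0.0))
        signs = np.sign(phis)
        assert np.allclose(signs, [-1, 1, -1, 1, -1, 1])

    def test_deterministic(self):
        ring = inverse_cremer_pople(0.6, 60.0, 200.0)
        assert np.array_equal(ring_dihedrals(ring), ring_dihedrals(ring))

    def test_matches_reference_geometry_pattern(self):
        """A ring built at the 2SO vertex reproduces the reference ring
        dihedral pattern of the near-ideal iduronate conformer."""
        phis = ring_dihedrals(inverse_cremer_pople(0.76, 90.0, 150.0))
        ref = IDOA_REFERENCE_GEOMETRIES["2SO"].Phi0
        assert np.allclose(phis, ref, atol=5.0)
        assert np.allclose(np.sign(phis), np.sign(ref))
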