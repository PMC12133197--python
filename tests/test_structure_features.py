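"""Geometry features and compartmentalization scores."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from maxcomp.structure_features import (contact_score, distance_score,
                                        interchrom_contacts, radial_position,
                                        radial_variability, radius_of_gyration,
                                        speckle_variability)
from maxcomp.trace_io import ChromatinTrace, Locus


def _trace(coords, cell="c", chrom="chr1", homolog=0):
    coords = np.asarray(coords, dtype=float)
    loci = [Locus(chrom, i * 100, (i + 1) * 100, i) for i in range(len(coords))]
    return ChromatinTrace(cell, chrom, loci, coords, homolog=homolog)


class TestRadialPosition:
    def test_center_and_surface(self):
        assert radial_position(np.zeros(3))[0] == 0.0
        assert radial_position(np.array([0, 0, 5000.0]))[0] == pytest.approx(1.0)

    def test_three_four_five(self):
        # 3-4-5 triangle at the default 5 um nuclear radius
        assert radial_position(np.array([3000.0, 4000.0, 0.0]))[0] == pytest.approx(1.0)

    def test_custom_center(self):
        r = radial_position(np.array([1000.0, 0, 0]),
                            nucleus_center=np.array([1000.0, 0, 0]))
        assert r[0] == 0.0


class TestRadialVariability:
    def test_uniform_spread_is_zero(self, rng):
        base = rng.uniform(0, 1, 10)
        radial = base + rng.normal(0, 0.1, (50, 10))
        dr = radial_variability(radial)
        assert np.abs(dr).max() < 0.5
        # identity: sum of 2^dr * sigma_bar equals sum of sigma
        sigma = radial.std(axis=0)
        np.testing.assert_allclose((2.0 ** dr * sigma.mean()).sum(), sigma.sum())

    def test_widening_one_bin_raises_only_its_value(self, rng):
        radial = rng.normal(0.5, 0.1, (200, 6))
        widened = radial.copy()
        widened[:, 2] = rng.normal(0.5, 0.3, 200)
        a, b = radial_variability(radial), radial_variability(widened)
        assert b[2] > a[2]
        # the others move only through the shared normalization
        assert np.all(b[[0, 1, 3, 4, 5]] < a[[0, 1, 3, 4, 5]] + 0.05)


class TestRadiusOfGyration:
    def test_coincident_beads(self):
        g = radius_of_gyration(_trace(np.zeros((5, 3))))
        np.testing.assert_allclose(g, 0.0)

    def test_closed_form_window(self):
        coords = [[-2, 0, 0], [-1, 0, 0], [0, 0, 0], [1, 0, 0], [2, 0, 0]]
        g = radius_of_gyration(_trace(coords))
        assert g[2] == pytest.approx(np.sqrt(2.0))  # mean square distance 2

    def test_rigid_motion_invariance(self, rng):
        coords = rng.normal(size=(12, 3)) * 100
        rot = Rotation.from_rotvec([0.3, -1.2, 0.7]).as_matrix()
        moved = coords @ rot.T + np.array([500.0, -300.0, 80.0])
        np.testing.assert_allclose(radius_of_gyration(_trace(coords)),
                                   radius_of_gyration(_trace(moved)), atol=1e-8)


class TestInterchromContacts:
    def test_separated_chromosomes_zero(self):
        a = _trace(np.zeros((4, 3)), chrom="chr1")
        b = _trace(np.full((4, 3), 5000.0), chrom="chr2")
        counts = interchrom_contacts([a, b])
        assert all(v.sum() == 0 for v in counts.values())

    def test_boundary_inclusion_and_symmetry(self):
        a = _trace([[0, 0, 0]], chrom="chr1")
        b = _trace([[999.0, 0, 0], [1500.0, 0, 0]], chrom="chr2")
        counts = interchrom_contacts([a, b])
        assert counts[a.key][0] == 1
        assert counts[b.key].tolist() == [1, 0]
        assert counts[a.key].sum() == counts[b.key].sum()

    def test_single_chromosome_undefined(self):
        assert interchrom_contacts([_trace(np.zeros((3, 3)))]) == {}


class TestContactScore:
    def test_single_compartment_is_one(self):
        tr = _trace([[0, 0, 0], [100, 0, 0], [200, 0, 0]])
        assert contact_score(tr, np.array([1, 1, 1])) == 1.0

    def test_direct_ratio(self):
        # chain of 4 beads 100 nm apart, labels A A B B:
        # contacts within 300 nm: all 6 pairs -> 2 intra-A + 2 intra-B...
        tr = _trace([[0, 0, 0], [100, 0, 0], [200, 0, 0], [300, 0, 0]])
        c = np.array([1, 1, 0, 0])
        s = contact_score(tr, c, cutoff_factor=3.0, r_bead=100.0)
        # pairs and distances: all six pairwise distances <= 300
        # intra: (0,1),(2,3); inter: (0,2),(0,3),(1,2),(1,3) -> 2/6
        assert s == pytest.approx(2 / 6)

    def test_no_contacts_is_nan(self):
        tr = _trace([[0, 0, 0], [5000.0, 0, 0]])
        assert np.isnan(contact_score(tr, np.array([1, 0]),
                                      include_adjacent=False))

    def test_planted_labels_beat_permuted(self, strong_population, strong_calls, rng):
        pop, _ = strong_population
        sub = list(zip(pop.traces, strong_calls))[:30]
        planted = np.mean([contact_score(tr, p.c, r_bead=200.0)
                           for tr, p in sub])
        permuted = np.mean([contact_score(tr, rng.permutation(p.c), r_bead=200.0)
                            for tr, p in sub])
        assert planted > permuted


class TestDistanceScore:
    def test_two_cluster_fixture(self, rng):
        a = rng.normal(0, 10, (5, 3))
        b = rng.normal(0, 10, (5, 3)) + np.array([1000.0, 0, 0])
        tr = _trace(np.vstack([a, b]))
        c = np.array([1] * 5 + [0] * 5)
        s = distance_score(tr, c)
        assert 0 < s < 0.5  # intra distances are a small share

    def test_label_swap_invariance(self, rng):
        tr = _trace(rng.normal(size=(8, 3)) * 100)
        c = rng.integers(0, 2, 8)
        c[0], c[1] = 0, 1
        assert distance_score(tr, c) == pytest.approx(distance_score(tr, 1 - c))

    def test_degenerate_inputs_are_nan(self):
        tr = _trace(np.zeros((4, 3)))
        assert np.isnan(distance_score(tr, np.array([1, 1, 1, 1])))  # one side empty
        assert np.isnan(distance_score(tr, np.array([1, 1, 0, 0])))  # 0/0


def test_speckle_variability_closed_form():
    spd = np.array([[100.0, 50.0], [300.0, 50.0]])
    np.testing.assert_allclose(speckle_variability(spd), [100.0, 0.0])
    np.testing.assert_allclose(speckle_variability(spd[::-1]),
                               speckle_variability(spd))
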