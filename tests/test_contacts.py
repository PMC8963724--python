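import numpy as np
import pytest

from emsyn.contacts import (
    Contact,
    contact_area,
    contact_location,
    extract_contacts,
    fill_background,
    filter_small_contacts,
)
from emsyn.core import SegmentationVolume, VoxelGeometry, boundary_mask

from _oracles import bf_contacts, bf_fill_background, random_voronoi_labels


def as_key_set(contacts):
    return {
        (c.pair, frozenset(map(tuple, c.voxels.tolist())), c.face_counts) for c in contacts
    }


class TestFillBackground:
    def test_saturated_volume_is_fixed_point(self, two_cubes):
        assert fill_background(two_cubes) is two_cubes

    def test_single_segment_fills_everything(self):
        labels = np.zeros((4, 4, 4), dtype=np.int32)
        labels[0, 0, 0] = 9
        filled = fill_background(SegmentationVolume(labels))
        assert (filled.labels == 9).all()

    def test_all_background_rejected(self):
        with pytest.raises(ValueError):
            fill_background(SegmentationVolume(np.zeros((3, 3, 3), dtype=np.int32)))

    def test_gap_split_by_physical_distance_with_tie_to_smaller_id(self):
        # slabs at x<2 and x>4; the gap column x=3 is equidistant -> ID 1 wins
        labels = np.zeros((7, 3, 3), dtype=np.int32)
        labels[:2] = 1
        labels[5:] = 2
        seg = SegmentationVolume(labels)
        filled = fill_background(seg)
        expected = bf_fill_background(labels, seg.geometry.pitch)
        assert (filled.labels == expected).all()
        assert (filled.labels[3] == 1).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_nearest_site(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.zeros((6, 6, 5), dtype=np.int32)
        n_sites = 4
        for sid in range(1, n_sites + 1):
            x, y, z = (rng.integers(0, d) for d in labels.shape)
            labels[x, y, z] = sid
        seg = SegmentationVolume(labels)
        expected = bf_fill_background(labels, seg.geometry.pitch)
        assert (fill_background(seg).labels == expected).all()


class TestExtractContacts:
    def test_uniform_volume_yields_nothing(self):
        seg = SegmentationVolume(np.ones((5, 5, 5), dtype=np.int32))
        assert extract_contacts(seg) == []

    def test_unsaturated_volume_rejected(self):
        labels = np.ones((4, 4, 4), dtype=np.int32)
        labels[0, 0, 0] = 0
        with pytest.raises(ValueError):
            extract_contacts(SegmentationVolume(labels))

    def test_two_abutting_cubes(self, two_cubes):
        contacts = extract_contacts(two_cubes)
        assert len(contacts) == 1
        c = contacts[0]
        assert c.pair == (1, 2)
        assert c.voxel_count == 200  # both sides of the 10x10 face
        assert c.face_counts == (0, 0, 100)

    def test_three_segments_in_a_row(self, three_in_row):
        contacts = extract_contacts(three_in_row)
        assert sorted(c.pair for c in contacts) == [(1, 2), (2, 3)]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        labels = random_voronoi_labels(rng, (9, 8, 7), n_segments=4)
        contacts = extract_contacts(SegmentationVolume(labels))
        expected = {
            (d["pair"], d["voxels"], d["face_counts"]) for d in bf_contacts(labels)
        }
        assert as_key_set(contacts) == expected

    def test_face_count_conservation(self):
        # total per-axis face counts equal the global differing-pair count
        rng = np.random.default_rng(42)
        labels = random_voronoi_labels(rng, (12, 11, 10), n_segments=5)
        contacts = extract_contacts(SegmentationVolume(labels))
        totals = np.sum([c.face_counts for c in contacts], axis=0)
        for axis in range(3):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = slice(None, -1)
            hi[axis] = slice(1, None)
            assert totals[axis] == (labels[tuple(lo)] != labels[tuple(hi)]).sum()

    def test_relabel_invariance_and_translation_equivariance(self):
        rng = np.random.default_rng(5)
        labels = random_voronoi_labels(rng, (8, 8, 8), n_segments=3)
        base = extract_contacts(SegmentationVolume(labels))
        relabeled = extract_contacts(SegmentationVolume((labels * 10).astype(np.int32)))
        assert {frozenset(map(tuple, c.voxels.tolist())) for c in base} == {
            frozenset(map(tuple, c.voxels.tolist())) for c in relabeled
        }
        # translation: rolling the volume one voxel along x shifts every
        # contact far from the wrap seam by exactly (1, 0, 0)
        base_sets = {frozenset(map(tuple, (c.voxels + [1, 0, 0]).tolist())) for c in base}
        moved = extract_contacts(SegmentationVolume(np.roll(labels, 1, axis=0)))
        moved_sets = {frozenset(map(tuple, c.voxels.tolist())) for c in moved}
        nx = labels.shape[0]
        interior = {s for s in base_sets if all(1 < v[0] < nx - 2 for v in s)}
        assert interior <= moved_sets

    def test_same_pair_contacts_are_disjoint(self):
        # two separate interfaces between the same pair
        labels = np.ones((4, 4, 12), dtype=np.int32)
        labels[:, :, 3:6] = 2
        labels[:, :, 9:] = 2
        contacts = extract_contacts(SegmentationVolume(labels))
        pairs_12 = [c for c in contacts if c.pair == (1, 2)]
        assert len(pairs_12) == 3
        seen: set = set()
        for c in pairs_12:
            vox = set(map(tuple, c.voxels.tolist()))
            assert not (vox & seen)
            seen |= vox

    def test_boundary_mask_equals_union_of_contact_voxels(self):
        rng = np.random.default_rng(11)
        labels = random_voronoi_labels(rng, (9, 9, 9), n_segments=4)
        seg = SegmentationVolume(labels)
        union = set()
        for c in extract_contacts(seg):
            union |= set(map(tuple, c.voxels.tolist()))
        assert union == set(map(tuple, np.argwhere(boundary_mask(seg)).tolist()))


class TestSizeFilter:
    def _contact(self, n):
        vox = np.stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)], axis=1)
        return Contact(0, (1, 2), vox, (n, 0, 0), 0.0)

    def test_threshold_boundary_inclusive_on_removal(self):
        at, above = self._contact(200), self._contact(201)
        assert filter_small_contacts([at]) == []
        assert filter_small_contacts([above]) == [above]

    def test_empty_and_order_preserved(self):
        assert filter_small_contacts([]) == []
        a, b = self._contact(300), self._contact(250)
        assert filter_small_contacts([a, b]) == [a, b]

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_small_contacts([], min_voxels=-1)


class TestContactArea:
    def test_single_face_areas(self):
        geo = VoxelGeometry()
        vox = np.array([[0, 0, 0], [1, 0, 0]])
        x_face = Contact(0, (1, 2), vox, (1, 0, 0), 0.0)
        z_face = Contact(0, (1, 2), vox, (0, 0, 1), 0.0)
        assert contact_area(x_face, geo) == 600.0
        assert contact_area(z_face, geo) == 144.0

    def test_matches_exhaustive_face_enumeration(self):
        rng = np.random.default_rng(8)
        labels = random_voronoi_labels(rng, (8, 8, 8), n_segments=3)
        seg = SegmentationVolume(labels)
        geo = seg.geometry
        face_area = {0: geo.dy * geo.dz, 1: geo.dx * geo.dz, 2: geo.dx * geo.dy}
        from _oracles import bf_faces

        expected_total = sum(face_area[axis] for _, axis, _, _ in bf_faces(labels))
        total = sum(contact_area(c, geo) for c in extract_contacts(seg))
        assert total == pytest.approx(expected_total)


class TestContactLocation:
    def test_single_voxel(self):
        c = Contact(0, (1, 2), np.array([[3, 4, 5]]), (1, 0, 0), 0.0)
        assert contact_location(c) == (3, 4, 5)

    def test_odd_count_median(self):
        vox = np.array([[0, 0, z] for z in range(10, 21)])
        c = Contact(0, (1, 2), vox, (0, 0, 11), 0.0)
        assert contact_location(c)[2] == 15

    def test_even_count_ties_toward_lower(self):
        vox = np.array([[0, 0, 4], [0, 0, 5]])
        c = Contact(0, (1, 2), vox, (0, 0, 2), 0.0)
        assert contact_location(c)[2] == 4
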