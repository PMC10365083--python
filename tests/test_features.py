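"""Geometric predictors: volume, shortest distance, contact area."""

import numpy as np
import pytest

from koosgrade import (
    LabelVolume,
    Side,
    contact_area,
    extract_features,
    extract_full_features,
    shortest_distance,
    structure_volume,
    to_ipsi_contra,
)
from koosgrade.errors import DegenerateInputError, SchemeError, StateError
from koosgrade.features import contact_shell, feature_name
from koosgrade.schemes import (
    BACKGROUND,
    IPSI_CEREBELLUM,
    LEFT_CEREBELLUM,
    RIGHT_CEREBELLUM,
    VS,
    LabelScheme,
    canonical_scheme,
)

from conftest import make_label_volume


def brute_force_min_distance(vol, a, b):
    """All-pairs Euclidean minimum over voxel centers — the exact oracle."""
    pa = vol.voxel_coords(vol.mask(a))
    pb = vol.voxel_coords(vol.mask(b))
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def random_blob_volume(seed, n_voxels=200, shape=(20, 20, 20), spacing=0.9):
    """Two random blobs labelled VS (1) and pons (2)."""
    rng = np.random.default_rng(seed)
    data = np.zeros(shape, dtype=np.int32)
    for label in (1, 2):
        flat = rng.choice(np.prod(shape), size=n_voxels, replace=False)
        data.reshape(-1)[flat] = label
    return make_label_volume(data, spacing=spacing)


class TestStructureVolume:
    def test_count_times_voxel_volume(self):
        data = np.zeros((10, 10, 10), dtype=np.int32)
        data.reshape(-1)[:100] = 1
        vol = make_label_volume(data, spacing=0.8)
        assert structure_volume(vol, VS) == pytest.approx(51.2)

    def test_absent_structure_is_zero(self):
        vol = make_label_volume(np.zeros((4, 4, 4)))
        assert structure_volume(vol, VS) == 0.0

    def test_unknown_structure_rejected(self):
        vol = make_label_volume(np.zeros((4, 4, 4)))
        with pytest.raises(SchemeError):
            structure_volume(vol, "amygdala")

    def test_digitized_sphere_matches_analytic(self):
        r, s = 8.0, 0.8
        n = 30
        centers = (np.indices((n, n, n)) * s - (n - 1) * s / 2)
        sphere = (centers**2).sum(axis=0) <= r**2
        vol = make_label_volume(sphere.astype(np.int32), spacing=s)
        analytic = 4 / 3 * np.pi * r**3
        assert structure_volume(vol, VS) == pytest.approx(analytic, rel=0.03)

    def test_additive_over_disjoint_structures(self):
        data = np.zeros((6, 6, 6), dtype=np.int32)
        data[:2] = 2
        data[4:] = 3
        vol = make_label_volume(data, spacing=1.1)
        total = structure_volume(vol, "pons") + structure_volume(vol, "brainstem")
        assert total == pytest.approx((data != 0).sum() * 1.1**3)


class TestShortestDistance:
    def test_face_adjacent_unit_spacing(self):
        data = np.zeros((4, 4, 4), dtype=np.int32)
        data[1, 1, 1] = 1
        data[2, 1, 1] = 2
        assert shortest_distance(make_label_volume(data), VS, "pons") == pytest.approx(1.0)

    def test_3_4_5_triangle(self):
        data = np.zeros((8, 8, 8), dtype=np.int32)
        data[0, 0, 0] = 1
        data[3, 4, 0] = 2
        assert shortest_distance(make_label_volume(data), VS, "pons") == pytest.approx(5.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_exactly(self, seed):
        vol = random_blob_volume(seed)
        fast = shortest_distance(vol, VS, "pons")
        assert fast == brute_force_min_distance(vol, VS, "pons")

    def test_symmetric_in_structures(self):
        vol = random_blob_volume(99)
        assert shortest_distance(vol, VS, "pons") == shortest_distance(vol, "pons", VS)

    def test_empty_structure_sentinel_and_error(self):
        data = np.zeros((4, 4, 4), dtype=np.int32)
        data[0, 0, 0] = 1
        vol = make_label_volume(data)
        assert shortest_distance(vol, VS, "pons", sentinel=100.0) == 100.0
        with pytest.raises(DegenerateInputError):
            shortest_distance(vol, VS, "pons")


def planar_interface_volume(a, b, spacing=0.8):
    """VS slab on top of a cerebellum slab sharing an a x b voxel face."""
    data = np.zeros((a + 4, b + 4, 8), dtype=np.int32)
    data[2 : 2 + a, 2 : 2 + b, 2:4] = 7  # left cerebellum
    data[2 : 2 + a, 2 : 2 + b, 4:6] = 1  # VS
    return make_label_volume(data, spacing=spacing)


def exposed_face_area(shell, spacing):
    """Face-count oracle: exposed faces of the shell times per-face area."""
    faces = 0
    padded = np.pad(shell, 1)
    for ax in range(3):
        for shift in (1, -1):
            faces += (padded & ~np.roll(padded, shift, axis=ax)).sum()
    return faces * spacing**2


class TestContactArea:
    def test_separated_structures_have_zero_contact(self):
        data = np.zeros((9, 9, 9), dtype=np.int32)
        data[1:3] = 1
        data[5:7] = 7  # one background slab in between
        vol = make_label_volume(data)
        assert contact_area(vol, VS, LEFT_CEREBELLUM) == 0.0

    def test_doubling_interface_side_quadruples_area(self):
        small = contact_area(planar_interface_volume(6, 6), VS, LEFT_CEREBELLUM)
        large = contact_area(planar_interface_volume(12, 12), VS, LEFT_CEREBELLUM)
        assert large / small == pytest.approx(4.0, rel=0.10)

    @pytest.mark.parametrize("a,b", [(6, 6), (10, 4), (12, 12)])
    def test_matches_face_count_oracle(self, a, b):
        """Closed mesh around the one-voxel shell ~ exposed-face area
        (~2x the geometric interface plus rim terms)."""
        vol = planar_interface_volume(a, b)
        shell = contact_shell(vol, VS, LEFT_CEREBELLUM)
        oracle = exposed_face_area(shell, vol.spacing[0])
        assert contact_area(vol, VS, LEFT_CEREBELLUM) == pytest.approx(oracle, rel=0.25)

    def test_monotone_in_interface_size(self):
        areas = [
            contact_area(planar_interface_volume(k, k), VS, LEFT_CEREBELLUM)
            for k in (4, 6, 8, 10)
        ]
        assert all(a2 > a1 for a1, a2 in zip(areas, areas[1:]))


class TestExtractFeatures:
    def _ipsi_volume(self, origin=(0.0, 0.0, 0.0)):
        data = np.zeros((14, 14, 14), dtype=np.int32)
        data[6:8, 6:8, 6:8] = 1  # VS
        data[2:4, 6:8, 6:8] = 2
        data[4:6, 6:8, 6:8] = 3
        data[8:10, 2:4, 6:8] = 4
        data[8:10, 4:6, 6:8] = 5
        data[8:10, 6:8, 2:4] = 6
        data[10:12, 6:8, 6:8] = 7
        data[0:2, 6:8, 6:8] = 8
        vol = make_label_volume(data, spacing=0.8, origin=origin)
        return to_ipsi_contra(vol, Side.RIGHT)

    def test_nine_finite_predictors(self):
        fv = self._ipsi_volume()
        series = extract_features(fv, "caseA").to_series()
        assert len(series) == 9
        assert np.isfinite(series.to_numpy()).all()

    def test_left_right_scheme_rejected(self):
        data = np.zeros((4, 4, 4), dtype=np.int32)
        data[0, 0, 0] = 1
        with pytest.raises(StateError):
            extract_features(make_label_volume(data), "caseB")

    def test_empty_tumor_rejected(self):
        vol = to_ipsi_contra(make_label_volume(np.zeros((4, 4, 4))), Side.LEFT)
        with pytest.raises(DegenerateInputError):
            extract_features(vol, "caseC")

    def test_missing_structure_gets_sentinel_plus_warning(self):
        data = np.zeros((6, 6, 6), dtype=np.int32)
        data[2:4, 2:4, 2:4] = 1
        vol = to_ipsi_contra(make_label_volume(data), Side.LEFT)
        fv = extract_features(vol, "caseD", sentinel_distance=100.0)
        assert all(d == 100.0 for d in fv.distances.values())
        assert fv.warnings

    def test_translation_invariance(self):
        a = extract_features(self._ipsi_volume(), "t0").to_series()
        b = extract_features(self._ipsi_volume(origin=(5.0, -3.0, 11.0)), "t0").to_series()
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_mirror_plus_side_flip_is_invariant(self, cohort):
        """Mirroring the anatomy and flipping the side yields the same
        tumor-relative features."""
        case = cohort[120]  # a grade III phantom
        vol = case.volumes["ceT1"]
        direct = extract_features(to_ipsi_contra(vol, case.side), case.case_id)
        mirrored_vox = vol.voxels[::-1].copy()
        left, right = vol.scheme.label_of(LEFT_CEREBELLUM), vol.scheme.label_of(RIGHT_CEREBELLUM)
        swapped = mirrored_vox.copy()
        swapped[mirrored_vox == left] = right
        swapped[mirrored_vox == right] = left
        mirrored = LabelVolume(swapped, vol.affine, scheme=vol.scheme)
        flipped = extract_features(
            to_ipsi_contra(mirrored, case.side.opposite), case.case_id
        )
        np.testing.assert_allclose(
            direct.to_series().to_numpy(), flipped.to_series().to_numpy(), atol=1e-6
        )


class TestExtractFullFeatures:
    def _extended_volume(self):
        entries = {0: BACKGROUND, 1: VS}
        for k in range(2, 11):
            entries[k] = f"structure {k}"
        entries[11] = LEFT_CEREBELLUM
        entries[12] = RIGHT_CEREBELLUM
        scheme = LabelScheme(entries)
        rng = np.random.default_rng(3)
        data = np.zeros((16, 16, 16), dtype=np.int32)
        for k in range(1, 13):
            i, j, l = rng.integers(0, 14, size=3)
            data[i : i + 2, j : j + 2, l : l + 2] = k
        return make_label_volume(data, scheme=scheme)

    def test_predictor_arity(self):
        """m foreground structures -> 3*(m-1) + 1 predictors."""
        series = extract_full_features(self._extended_volume(), "ext")
        assert len(series) == 3 * 11 + 1

    def test_merged_structure_volume_is_sum_of_parts(self):
        vol = self._extended_volume()
        series = extract_full_features(vol, "ext")
        v2 = series[feature_name("volume", "structure 2")]
        v3 = series[feature_name("volume", "structure 3")]
        merged_vox = vol.voxels.copy()
        merged_vox[merged_vox == 3] = 2
        entries = {k: v for k, v in vol.scheme.entries.items() if k != 3}
        merged = make_label_volume(merged_vox, scheme=LabelScheme(entries))
        merged_series = extract_full_features(merged, "ext")
        assert merged_series[feature_name("volume", "structure 2")] == pytest.approx(v2 + v3)

    def test_merged_structure_distance_is_min_of_parts(self):
        vol = self._extended_volume()
        d2 = brute_force_min_distance(vol, VS, "structure 2")
        d3 = brute_force_min_distance(vol, VS, "structure 3")
        merged_vox = vol.voxels.copy()
        merged_vox[merged_vox == 3] = 2
        entries = {k: v for k, v in vol.scheme.entries.items() if k != 3}
        merged = make_label_volume(merged_vox, scheme=LabelScheme(entries))
        series = extract_full_features(merged, "ext")
        assert series[feature_name("distance_to_vs", "structure 2")] == pytest.approx(
            min(d2, d3)
        )
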