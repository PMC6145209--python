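"""FCM clustering, tissue-role assignment and seeded region growing."""

import numpy as np
import pytest

from glioseg.metrics import dice
from glioseg.pipeline import segment_modality
from glioseg.segmentation import (
    TissueClassMap,
    assign_tissue_classes,
    extract_abnormal_mask,
    fcm_cluster,
    region_grow,
)
from glioseg.volumes import BinaryMask, Modality, ScalarVolume


def vol_from(values) -> ScalarVolume:
    return ScalarVolume(np.asarray(values, float), (1, 1, 1))


# ---------------------------------------------------------------------------
# independent oracles

def flood_fill_oracle(values, seed, tolerance, offsets, domain=None):
    """Plain-Python re-implementation of the growth rule: FIFO frontier,
    fixed neighbour order, permanent rejection, incremental region mean."""
    shape = values.shape
    if domain is None:
        domain = np.ones(shape, bool)
    accepted = {seed}
    visited = {seed}
    total, count = float(values[seed]), 1
    queue = [seed]
    while queue:
        x, y, z = queue.pop(0)
        for dx, dy, dz in offsets:
            p = (x + dx, y + dy, z + dz)
            if not all(0 <= c < n for c, n in zip(p, shape)):
                continue
            if p in visited or not domain[p]:
                continue
            visited.add(p)
            if abs(values[p] - total / count) <= tolerance:
                accepted.add(p)
                total += float(values[p])
                count += 1
                queue.append(p)
    out = np.zeros(shape, bool)
    for p in accepted:
        out[p] = True
    return out


def fcm_updates(x, u, c, m):
    """The two FCM fixed-point equations, recomputed from scratch."""
    um = u**m
    c_new = um.T @ x / um.sum(axis=0)
    d = np.abs(x[:, None] - c[None, :])
    with np.errstate(divide="ignore"):
        inv = d ** (-2.0 / (m - 1.0))
    u_new = inv / inv.sum(axis=1, keepdims=True)
    return u_new, c_new


ALL_OFFSETS = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]


# ---------------------------------------------------------------------------

class TestFCM:
    def test_separable_two_population_case(self):
        v = np.concatenate([np.full(500, 0.2), np.full(500, 0.8)])
        res = fcm_cluster(vol_from(v.reshape(10, 10, 10)), n_clusters=2)
        np.testing.assert_allclose(np.sort(res.centroids), [0.2, 0.8], atol=1e-6)
        hard = res.memberships.reshape(-1, 2).max(axis=1)
        assert np.all(hard > 0.99)

    def test_converged_state_satisfies_both_update_equations(self, rng):
        """Plug-in oracle: re-applying the membership and centroid updates to
        the converged state must reproduce it within the stopping tolerance."""
        for _ in range(20):
            x = rng.uniform(size=60)
            res = fcm_cluster(vol_from(x.reshape(60, 1, 1)), n_clusters=3, tol=1e-7)
            u = res.memberships.reshape(-1, 3)
            u_new, c_new = fcm_updates(x, u, res.centroids, res.fuzziness)
            assert np.max(np.abs(c_new - res.centroids)) < 1e-4
            assert np.max(np.abs(u_new - u)) < 1e-3

    def test_objective_beats_random_memberships(self, rng):
        """Random-restart oracle on a 30-voxel instance: the converged
        objective is no worse than 1000 random membership matrices."""
        x = rng.uniform(size=30)
        res = fcm_cluster(vol_from(x.reshape(30, 1, 1)), n_clusters=2, fuzziness=2.0)
        best = np.inf
        for _ in range(1000):
            u = rng.dirichlet(np.ones(2), size=30)
            um = u**2.0
            c = um.T @ x / um.sum(axis=0)
            best = min(best, float(np.sum(um * (x[:, None] - c[None, :]) ** 2)))
        assert res.objective <= best + 1e-12

    def test_memberships_sum_to_one_and_objective_monotone(self, rng):
        v = rng.uniform(size=(12, 10, 4))
        res = fcm_cluster(vol_from(v), n_clusters=4)
        sums = res.memberships.sum(axis=-1)
        np.testing.assert_allclose(sums[res.mask], 1.0, atol=1e-9)
        np.testing.assert_allclose(sums[~res.mask], 0.0, atol=0)
        assert np.all(np.diff(res.objective_history) <= 1e-10)

    def test_near_crisp_fuzziness_matches_kmeans(self, rng):
        """With fuzziness -> 1 on well-separated data, hard FCM labels agree
        with k-means (independent sklearn oracle)."""
        from sklearn.cluster import KMeans

        x = np.concatenate(
            [rng.normal(0.2, 0.02, 40), rng.normal(0.5, 0.02, 40), rng.normal(0.8, 0.02, 40)]
        )
        res = fcm_cluster(vol_from(x.reshape(-1, 1, 1)), n_clusters=3, fuzziness=1.05)
        ours = np.argsort(np.argsort(res.centroids))[
            np.argmax(res.memberships.reshape(-1, 3), axis=1)
        ]
        km = KMeans(n_clusters=3, n_init=10, random_state=0).fit(x[:, None])
        theirs = np.argsort(np.argsort(km.cluster_centers_.ravel()))[km.labels_]
        assert np.array_equal(ours, theirs)

    def test_too_few_distinct_intensities_raises(self):
        with pytest.raises(ValueError, match="distinct"):
            fcm_cluster(vol_from(np.zeros((4, 4, 2))), n_clusters=4)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            fcm_cluster(vol_from(np.random.rand(3, 3, 3)), brain_mask=np.zeros((3, 3, 3), bool))


class TestAssignTissueClasses:
    def _fcm_with_centroids(self, centroids, labels):
        """Build an FCMResult-shaped stub with crisp memberships."""
        from glioseg.segmentation import FCMResult

        c = np.asarray(centroids, float)
        lab = np.asarray(labels)
        memb = np.eye(len(c))[lab][..., :]
        return FCMResult(
            memberships=memb,
            centroids=c,
            mask=np.ones(lab.shape, bool),
            n_iterations=1,
            objective=0.0,
            objective_history=np.array([0.0]),
            fuzziness=2.0,
        )

    def test_t2_four_class_listing(self):
        """Brightest->darkest on T2: lesion hyper, CSF+edema, WM/GM/scalp, skull/background."""
        fcm = self._fcm_with_centroids([0.9, 0.6, 0.3, 0.05], np.zeros((2, 2, 2), int))
        cm = assign_tissue_classes(fcm, Modality.T2)
        assert cm.class_semantics == {0: "hyper", 1: "csf_edema", 2: "normal", 3: "background"}
        np.testing.assert_allclose(cm.centroids_by_rank, [0.9, 0.6, 0.3, 0.05])

    def test_rank_invariance_under_cluster_permutation(self):
        labels = np.arange(8).reshape(2, 2, 2) % 4
        fcm_a = self._fcm_with_centroids([0.9, 0.6, 0.3, 0.05], labels)
        perm = [2, 0, 3, 1]
        inv = np.argsort(perm)
        fcm_b = self._fcm_with_centroids(
            np.array([0.9, 0.6, 0.3, 0.05])[perm], inv[labels]
        )
        a = assign_tissue_classes(fcm_a, Modality.FLAIR)
        b = assign_tissue_classes(fcm_b, Modality.FLAIR)
        assert np.array_equal(a.labels, b.labels)

    def test_membership_tie_goes_to_lower_cluster_index(self):
        from glioseg.segmentation import FCMResult

        memb = np.full((1, 1, 1, 4), 0.0)
        memb[0, 0, 0, :2] = 0.4
        memb[0, 0, 0, 2:] = 0.1
        fcm = FCMResult(memb, np.array([0.9, 0.6, 0.3, 0.05]), np.ones((1, 1, 1), bool),
                        1, 0.0, np.array([0.0]), 2.0)
        cm = assign_tissue_classes(fcm, Modality.T2)
        assert cm.labels[0, 0, 0] == 0  # cluster 0 is also rank 0 here

    def test_wrong_cluster_count_raises(self):
        fcm = self._fcm_with_centroids([0.8, 0.2], np.zeros((1, 1, 1), int))
        with pytest.raises(ValueError, match="4"):
            assign_tissue_classes(fcm, Modality.T2)


class TestRegionGrow:
    def test_uniform_image_fills_everything(self):
        v = vol_from(np.full((8, 8, 4), 0.5))
        out = region_grow(v, (3, 3, 1), tolerance=0.01)
        assert out.values.all()

    def test_two_constant_regions_split(self):
        values = np.full((20, 10, 3), 0.2)
        values[10:] = 0.8
        out = region_grow(vol_from(values), (15, 5, 1), tolerance=0.1)
        assert out.values[10:].all() and not out.values[:10].any()

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_flood_fill_oracle_on_random_blobs(self, rng, connectivity):
        from glioseg.segmentation import _neighbor_offsets

        offsets = _neighbor_offsets(connectivity)
        for _ in range(10):
            from scipy.ndimage import gaussian_filter

            v = gaussian_filter(rng.uniform(size=(12, 12, 4)), 1.2)
            seed = tuple(int(s) for s in (rng.integers(12), rng.integers(12), rng.integers(4)))
            tol = float(rng.uniform(0.01, 0.08))
            ours = region_grow(vol_from(v), seed, tol, connectivity=connectivity)
            oracle = flood_fill_oracle(v, seed, tol, offsets)
            assert np.array_equal(ours.values, oracle)

    def test_seed_outside_domain_raises(self):
        v = vol_from(np.zeros((4, 4, 2)) + 0.5)
        dom = np.zeros((4, 4, 2), bool)
        dom[0, 0, 0] = True
        with pytest.raises(ValueError, match="domain|brain"):
            region_grow(v, (2, 2, 1), 0.1, domain=dom)

    def test_seed_out_of_bounds_raises(self):
        with pytest.raises(ValueError, match="outside volume"):
            region_grow(vol_from(np.zeros((4, 4, 2))), (9, 0, 0), 0.1)


def class_map(labels, modality=Modality.FLAIR):
    sem = {0: "hyper", 1: "edema", 2: "normal", 3: "background"}
    return TissueClassMap(np.asarray(labels), sem, modality, np.array([0.9, 0.6, 0.3, 0.05]))


class TestExtractAbnormalMask:
    def test_connected_candidate_equals_component(self):
        labels = np.full((12, 12, 4), 2)
        labels[3:7, 3:7, 1:3] = 0
        v = np.where(labels == 0, 0.9, 0.3)
        mask = extract_abnormal_mask(class_map(labels), vol_from(v), (4, 4, 1), tolerance=0.1)
        assert np.array_equal(mask.values, labels == 0)

    def test_disjoint_second_lesion_is_excluded(self):
        labels = np.full((20, 10, 4), 2)
        labels[2:5, 2:5, 1:3] = 0
        labels[14:18, 2:6, 1:3] = 0
        v = np.where(labels == 0, 0.9, 0.3)
        mask = extract_abnormal_mask(class_map(labels), vol_from(v), (3, 3, 1), tolerance=0.1)
        assert mask.values[2:5, 2:5, 1:3].all()
        assert not mask.values[14:18, 2:6, 1:3].any()

    def test_seed_in_normal_tissue_raises(self):
        labels = np.full((8, 8, 2), 2)
        labels[2:4, 2:4, :] = 0
        with pytest.raises(ValueError, match="normal-tissue"):
            extract_abnormal_mask(class_map(labels), vol_from(np.zeros((8, 8, 2))), (6, 6, 0))

    def test_core_hole_is_filled_when_seeded_in_rim(self):
        """Rim (edema role) around a bright core: growing from the rim must
        return rim + core after hole filling."""
        labels = np.full((16, 16, 6), 2)
        labels[4:12, 4:12, 1:5] = 1          # edema rim block
        labels[6:10, 6:10, 2:4] = 0          # enclosed core
        v = np.where(labels == 1, 0.6, np.where(labels == 0, 0.95, 0.3))
        mask = extract_abnormal_mask(class_map(labels), vol_from(v), (5, 5, 2), tolerance=0.1)
        assert mask.values[4:12, 4:12, 1:5].all()

    @pytest.mark.parametrize("modality", list(Modality))
    def test_phantom_lesion_recovered(self, small_phantom, modality):
        """End-to-end on a noisy phantom: Dice vs ground truth >= 0.9."""
        res = segment_modality(
            small_phantom.volumes[modality], small_phantom.suggested_seeds[modality]
        )
        res.abnormal_mask.frame_of_reference = small_phantom.truth_masks[modality].frame_of_reference
        assert dice(res.abnormal_mask, small_phantom.truth_masks[modality]) >= 0.9
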