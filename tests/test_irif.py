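import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.segmentation import watershed

from _oracles import flood_watershed, mser_bruteforce
from irifkit import synthetic as syn
from irifkit.irif import (
    IrifConfig,
    IrifSeed,
    colocalization_image,
    detect_foci,
    mser_foreground,
    propose_seeds,
    segment_irifs,
)
from irifkit.nucseg import segment_nuclei
from irifkit.stack_io import LabelMap

VOXEL = (0.1, 0.1, 0.1)


def _blob(shape, center, sigma, amplitude=1.0):
    grids = np.indices(shape, dtype=float)
    q = sum(((g - c) / sigma) ** 2 for g, c in zip(grids, center))
    return amplitude * np.exp(-0.5 * q)


class TestColocalizationImage:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (np.zeros((2, 2, 2)), np.full((2, 2, 2), 0.7), np.zeros((2, 2, 2))),
            (
                np.array([[[0.0, 0.5, 1.0]]]),
                np.array([[[0.0, 0.5, 1.0]]]),
                np.array([[[0.0, 0.25, 1.0]]]),
            ),
        ],
        ids=["annihilator", "elementwise-square"],
    )
    def test_known_products(self, a, b, expected):
        assert np.allclose(colocalization_image(a, b), expected)

    def test_matches_elementwise_oracle(self, rng):
        a = rng.random((4, 4, 4))
        b = rng.random((4, 4, 4))
        expected = np.array(
            [a[i] * b[i] for i in np.ndindex(a.shape)]
        ).reshape(a.shape)
        assert np.array_equal(colocalization_image(a, b), expected)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shapes differ"):
            colocalization_image(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))


class TestMserForeground:
    def test_constant_volume_has_no_extremal_structure(self):
        assert not mser_foreground(np.full((8, 8, 8), 3.0)).any()
        assert not mser_foreground(np.zeros((8, 8, 8))).any()

    def test_single_blob_covers_fwhm_support(self):
        vol = _blob((24, 24, 24), (12, 12, 12), 3.0)
        fg = mser_foreground(vol, min_size=5)
        lab, n = ndi.label(fg, structure=np.ones((3, 3, 3), dtype=int))
        assert n == 1
        assert fg[vol >= 0.5].all()

    def test_two_blobs_two_regions(self):
        vol = _blob((16, 16, 32), (8, 8, 8), 2.0) + _blob((16, 16, 32), (8, 8, 24), 2.0)
        fg = mser_foreground(vol, min_size=5)
        _, n = ndi.label(fg, structure=np.ones((3, 3, 3), dtype=int))
        assert n == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_threshold_sweep_oracle(self, seed):
        """Voxel-for-voxel equality with the exhaustive component-tree sweep
        on a smooth random phantom."""
        rng = np.random.default_rng(seed)
        vol = ndi.gaussian_filter(rng.random((20, 20, 20)), 2.0)
        q = np.clip(
            np.floor((vol - vol.min()) / np.ptp(vol) * 255), 0, 255
        ).astype(np.uint8)
        ours = mser_foreground(q, delta=5, min_size=5, max_size=None, max_variation=0.5)
        oracle = mser_bruteforce(q, delta=5, min_size=5, max_size=None, max_variation=0.5)
        assert np.array_equal(ours, oracle)

    def test_rejects_negative_input(self):
        with pytest.raises(ValueError, match="non-negative"):
            mser_foreground(np.full((4, 4, 4), -1.0))


class TestProposeSeeds:
    def _nuclei(self, shape, mask=None):
        lab = np.ones(shape, dtype=np.int32)
        if mask is not None:
            lab = np.where(mask, 1, 0).astype(np.int32)
        return LabelMap(labels=lab, voxel_size=VOXEL)

    def test_single_blob_single_seed_at_peak(self):
        vol = _blob((16, 16, 16), (8, 8, 8), 2.0)
        seeds = propose_seeds(vol, vol > 0.1, self._nuclei(vol.shape), min_prominence=0.1)
        assert len(seeds) == 1
        assert seeds[0].position == (8, 8, 8)

    def test_blob_outside_nuclei_discarded(self):
        vol = _blob((16, 16, 16), (8, 8, 8), 2.0)
        nuclei = self._nuclei(vol.shape, mask=np.zeros(vol.shape, dtype=bool))
        assert propose_seeds(vol, vol > 0.1, nuclei) == []

    def test_close_maxima_suppressed_keeping_brighter(self):
        # two peaks 2 voxels = 0.2 µm apart, min_distance 0.5 µm
        vol = _blob((16, 16, 16), (8, 8, 7), 1.5, amplitude=0.8)
        vol += _blob((16, 16, 16), (8, 8, 9), 1.5, amplitude=1.0)
        seeds = propose_seeds(
            vol, vol > 0.05, self._nuclei(vol.shape),
            min_distance_um=0.5, min_prominence=0.05,
        )
        assert len(seeds) == 1
        # the retained seed is the brighter maximum
        assert seeds[0].position[2] >= 8

    def test_empty_foreground_empty_list(self):
        vol = _blob((8, 8, 8), (4, 4, 4), 2.0)
        assert propose_seeds(vol, np.zeros(vol.shape, bool), self._nuclei(vol.shape)) == []


class TestSegmentIrifs:
    def test_one_seed_floods_whole_blob(self):
        vol = _blob((16, 16, 16), (8, 8, 8), 2.0)
        fg = vol > 0.1
        seeds = [IrifSeed(position=(8, 8, 8), coloc_value=1.0, nucleus_id=1)]
        labels = segment_irifs(vol, seeds, fg, VOXEL)
        assert np.array_equal(labels.labels > 0, fg)
        assert labels.n_labels == 1

    def test_zero_seeds_zero_labels(self):
        vol = _blob((8, 8, 8), (4, 4, 4), 2.0)
        labels = segment_irifs(vol, [], vol > 0.1, VOXEL)
        assert labels.n_labels == 0

    def test_dumbbell_splits_on_the_ridge(self):
        """Two lobes joined by a dim neck: the label boundary must sit at the
        intensity minimum along the neck (the watershed ridge)."""
        vol = _blob((16, 16, 33), (8, 8, 8), 2.5) + _blob((16, 16, 33), (8, 8, 24), 2.5)
        fg = vol > 0.02
        seeds = [
            IrifSeed(position=(8, 8, 8), coloc_value=1.0, nucleus_id=1),
            IrifSeed(position=(8, 8, 24), coloc_value=1.0, nucleus_id=1),
        ]
        labels = segment_irifs(vol, seeds, fg, VOXEL)
        assert labels.n_labels == 2
        ridge_x = int(np.argmin(vol[8, 8, 9:24])) + 9
        lab = labels.labels
        xs1 = np.nonzero(lab == 1)[2]
        xs2 = np.nonzero(lab == 2)[2]
        assert xs1.max() <= ridge_x + 1
        assert xs2.min() >= ridge_x - 1

    @pytest.mark.parametrize("seed", [3, 4])
    def test_agrees_with_flood_oracle(self, seed):
        """Voxel-for-voxel equality with explicit priority flooding."""
        rng = np.random.default_rng(seed)
        vol = ndi.gaussian_filter(rng.random((18, 18, 18)), 2.0)
        fg = vol > np.percentile(vol, 55)
        flat = np.argsort(vol.ravel())[::-1]
        markers = np.zeros(vol.shape, dtype=np.int32)
        placed = 0
        for f in flat:
            idx = np.unravel_index(f, vol.shape)
            if fg[idx]:
                placed += 1
                markers[idx] = placed
                if placed == 3:
                    break
        ours = watershed(-vol, markers=markers, mask=fg, connectivity=3)
        oracle = flood_watershed(-vol, markers, fg)
        assert np.array_equal(ours, oracle)

    def test_seed_outside_foreground_rejected(self):
        vol = _blob((8, 8, 8), (4, 4, 4), 2.0)
        seeds = [IrifSeed(position=(0, 0, 0), coloc_value=1.0, nucleus_id=1)]
        with pytest.raises(ValueError, match="outside the foreground"):
            segment_irifs(vol, seeds, vol > 0.5, VOXEL)


class TestDetectionInvariants:
    def test_one_label_per_seed_and_containment(self, detected_cell):
        seeds = detected_cell["seeds"]
        foci = detected_cell["foci"]
        nuclei = detected_cell["nuclei"]
        assert foci.n_labels == len(seeds)
        inside = foci.labels > 0
        assert (nuclei.labels[inside] > 0).all()

    def test_seed_positions_match_ground_truth(self, detected_cell):
        truth = detected_cell["truth"]
        vs = np.asarray(detected_cell["stack"].voxel_size)
        det = np.array([s.position for s in detected_cell["seeds"]]) * vs
        tru = truth[["z_vox", "y_vox", "x_vox"]].to_numpy() * vs
        assert len(det) == len(tru)
        d = np.linalg.norm(det[:, None] - tru[None, :], axis=2)
        assert (d.min(axis=1) <= 0.5).all()

    def test_adding_bright_focus_never_decreases_seed_count(self, small_geometry):
        nucleus = syn.NucleusSpec(center=(10, 32, 32), semi_axes=(2.2, 1.9, 1.9))
        rng = np.random.default_rng(5)
        centers = syn.sample_focus_centers(nucleus, 4, rng, small_geometry,
                                           min_separation_um=1.2)
        counts = []
        for k in (3, 4):
            foci = [syn.FocusSpec(center=c, nucleus_id=1) for c in centers[:k]]
            stack, _ = syn.generate_nucleus_stack(
                [nucleus], foci, geometry=small_geometry, noise=syn.NOISELESS
            )
            nuclei = segment_nuclei(stack)
            seeds, _, _ = detect_foci(stack, nuclei)
            counts.append(len(seeds))
        assert counts[1] >= counts[0]
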