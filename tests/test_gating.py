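"""Retrospective gating: grayscale, localization, SSD matching, reordering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from picowash import (
    DropletLocalization,
    ReferencePatch,
    Roi,
    build_scene,
    locate_centroid,
    locate_template,
    reconstruct_sequence,
    render_short_exposure,
    ssd_profile,
    to_grayscale,
)


def brute_force_ssd(frame, ref):
    """Independent double-loop oracle for the sum-square difference."""
    h, w = ref.shape
    n_pos = frame.shape[1] - w + 1
    E = np.zeros(n_pos)
    for x in range(n_pos):
        for i in range(h):
            for j in range(w):
                E[x] += (frame[i, x + j] - ref[i, j]) ** 2
    return E


class TestToGrayscale:
    def test_rgb_mean(self):
        frame = np.array([[[30.0, 60.0, 90.0]]])
        assert to_grayscale(frame)[0, 0] == pytest.approx(60.0)

    def test_equal_planes_idempotent(self, rng):
        plane = rng.uniform(0, 255, (5, 7))
        rgb = np.stack([plane] * 3, axis=-1)
        assert np.allclose(to_grayscale(rgb), plane)

    def test_gray_passthrough(self, rng):
        plane = rng.uniform(0, 255, (5, 7))
        assert to_grayscale(plane) is plane

    def test_bad_plane_count(self, rng):
        with pytest.raises(ValueError):
            to_grayscale(rng.uniform(0, 255, (5, 7, 4)))


class TestLocateCentroid:
    def test_symmetric_plug_centered(self):
        frame = np.full((20, 200), 200.0)
        frame[:, 85:116] = 50.0  # dark plug centered on column 100
        loc = locate_centroid(frame, Roi(0, 20, 0, 200), threshold=100.0)
        assert loc.valid
        assert loc.x_ref == pytest.approx(100.0, abs=0.5)

    def test_blank_frame_invalid(self):
        loc = locate_centroid(np.full((10, 50), 200.0), Roi(0, 10, 0, 50))
        assert not loc.valid

    def test_largest_component_wins(self):
        """Two plugs of 900 and 400 px: centroid follows the larger."""
        frame = np.full((30, 300), 200.0)
        frame[:30, 20:50] = 50.0  # 900 px at center column 34.5
        frame[:20, 200:220] = 50.0  # 400 px
        loc = locate_centroid(frame, Roi(0, 30, 0, 300), threshold=100.0)
        assert loc.x_ref == pytest.approx(34.5, abs=0.01)

    def test_min_area_floor(self):
        frame = np.full((20, 100), 200.0)
        frame[5:8, 40:43] = 50.0
        loc = locate_centroid(frame, Roi(0, 20, 0, 100), threshold=100.0, min_area=25)
        assert not loc.valid

    def test_empty_roi_errors(self):
        with pytest.raises(ValueError):
            Roi(0, 0, 0, 10)


class TestSSDProfile:
    def test_exact_translate_has_zero_minimum(self, rng):
        ref = rng.uniform(0, 255, (6, 10))
        frame = rng.uniform(0, 255, (6, 40))
        shift = 17
        frame[:, shift : shift + 10] = ref
        profile = ssd_profile(frame, Roi(0, 6, 0, 40), ReferencePatch(ref))
        assert profile.at(shift) == 0.0
        mask = np.ones(profile.E.shape, dtype=bool)
        mask[shift] = False
        assert (profile.E[mask] > 0).all()

    def test_patch_as_wide_as_roi(self, rng):
        frame = rng.uniform(0, 255, (4, 12))
        profile = ssd_profile(frame, Roi(0, 4, 0, 12), ReferencePatch(frame.copy()))
        assert profile.E.shape == (1,)
        assert profile.valid_range == (0, 1)
        assert profile.at(0) == 0.0

    def test_matches_brute_force_oracle(self, rng):
        frame = rng.uniform(0, 255, (8, 8))
        ref = rng.uniform(0, 255, (8, 3))
        profile = ssd_profile(frame, Roi(0, 8, 0, 8), ReferencePatch(ref))
        assert profile.E.shape == (6,)
        assert np.allclose(profile.E, brute_force_ssd(frame, ref), rtol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 2**31 - 1),
        rows=st.integers(1, 8),
        cols=st.integers(2, 12),
        pw_=st.integers(1, 6),
    )
    def test_oracle_equivalence_property(self, seed, rows, cols, pw_):
        """Vectorized SSD equals the naive double loop on random instances."""
        pw_ = min(pw_, cols)
        rng = np.random.default_rng(seed)
        frame = rng.uniform(0, 255, (rows, cols))
        ref = rng.uniform(0, 255, (rows, pw_))
        profile = ssd_profile(frame, Roi(0, rows, 0, cols), ReferencePatch(ref))
        assert np.allclose(profile.E, brute_force_ssd(frame, ref), rtol=1e-12)

    def test_patch_larger_than_roi_errors(self, rng):
        frame = rng.uniform(0, 255, (4, 8))
        with pytest.raises(ValueError, match="exceeds"):
            ssd_profile(frame, Roi(0, 4, 0, 8), ReferencePatch(rng.uniform(0, 1, (4, 9))))


class TestLocateTemplate:
    @pytest.fixture
    def translate_fixture(self, rng):
        ref = rng.uniform(0, 255, (6, 10))
        frame = rng.uniform(0, 255, (6, 60))
        frame[:, 23:33] = ref
        return frame, ReferencePatch(ref)

    def test_recovers_shift(self, translate_fixture):
        frame, ref = translate_fixture
        loc = locate_template(frame, Roi(0, 6, 0, 60), ref, bounds=(10, 45))
        assert loc.valid and loc.x_ref == 23

    def test_bounds_restrict_argmin(self, translate_fixture):
        frame, ref = translate_fixture
        profile = ssd_profile(frame, Roi(0, 6, 0, 60), ref)
        loc = locate_template(frame, Roi(0, 6, 0, 60), ref, bounds=(30, 50))
        expected = 30 + int(np.argmin(profile.E[30:50]))
        assert loc.x_ref == expected != 23

    def test_flat_profile_takes_smallest_x(self):
        frame = np.full((4, 30), 128.0)
        ref = ReferencePatch(np.full((4, 5), 128.0))
        loc = locate_template(frame, Roi(0, 4, 0, 30), ref, bounds=(7, 20))
        assert loc.x_ref == 7

    def test_mismatch_ceiling_invalidates(self, translate_fixture):
        frame, ref = translate_fixture
        loc = locate_template(frame, Roi(0, 6, 0, 60), ref, bounds=(40, 50),
                              mismatch_ceiling=1.0)
        assert not loc.valid

    def test_empty_bounds_error(self, translate_fixture):
        frame, ref = translate_fixture
        with pytest.raises(ValueError, match="empty"):
            locate_template(frame, Roi(0, 6, 0, 60), ref, bounds=(20, 20))


class TestReconstructSequence:
    @staticmethod
    def _locs(positions, valid=None):
        valid = valid or [True] * len(positions)
        return [
            DropletLocalization(i, x, "template", v)
            for i, (x, v) in enumerate(zip(positions, valid))
        ]

    def test_already_sorted_identity(self):
        seq = reconstruct_sequence(None, self._locs([1.0, 2.0, 5.0]))
        assert np.array_equal(seq.ordering, [0, 1, 2])

    def test_sorts_and_drops_invalid(self):
        seq = reconstruct_sequence(
            None, self._locs([5.0, 1.0, 3.0, 2.0], [True, True, False, True])
        )
        assert np.array_equal(seq.ordering, [1, 3, 0])
        assert seq.n_dropped == 1
        assert np.all(np.diff(seq.positions) >= 0)

    def test_ties_keep_frame_order(self):
        seq = reconstruct_sequence(None, self._locs([2.0, 2.0, 1.0]))
        assert np.array_equal(seq.ordering, [2, 0, 1])

    def test_pseudo_times_from_velocity(self):
        seq = reconstruct_sequence(
            None, self._locs([10.0, 30.0]), velocity_um_per_ms=100.0, px_size=0.5
        )
        assert seq.pseudo_times_ms == pytest.approx([0.0, 0.1])

    def test_too_few_valid_frames(self):
        with pytest.raises(ValueError, match="2 valid"):
            reconstruct_sequence(None, self._locs([1.0, 2.0], [True, False]))


@pytest.fixture(scope="module")
def gating_setup():
    cfg = {
        "channel": {"length_px": 1100, "height_px": 47, "px_size": 0.425,
                    "width_um": 20.0, "height_um": 60.0, "flow_rate": 2.0},
        "train": {"L_drop": 85.0, "L_space": 85.0, "n_droplets": 3},
    }
    scene = build_scene(cfg, seed=7)
    period = scene.train.period_um
    n = 120
    order = np.random.default_rng(11).permutation(n)
    phases = order * (period / n)  # one phase per distinct pixel offset
    roi = Roi(13, 33, 0, 1100)
    ref_frame = render_short_exposure(scene, 1, phases=[0.0]).frames[0]
    patch = ReferencePatch(Roi(13, 33, 400, 610).crop(ref_frame))
    return scene, phases, roi, patch


class TestSceneReconstruction:
    """Reordering of rendered randomly-phased frames against ground truth."""

    def test_noiseless_ordering_is_exact(self, gating_setup):
        scene, phases, roi, patch = gating_setup
        stack = render_short_exposure(scene, len(phases), seed=5, phases=phases)
        locs = [
            locate_template(f, roi, patch, bounds=(400, 800), frame_index=i)
            for i, f in enumerate(stack.frames)
        ]
        seq = reconstruct_sequence(stack, locs)
        assert np.array_equal(seq.ordering, np.argsort(phases, kind="stable"))

    def test_noisy_ordering_spearman(self, gating_setup):
        from scipy.stats import spearmanr
        import dataclasses

        scene, phases, roi, patch = gating_setup
        noisy = dataclasses.replace(scene, noise_sd=3.0)  # 2% of the dynamic range
        stack = render_short_exposure(noisy, len(phases), seed=5, phases=phases)
        locs = [
            locate_template(f, roi, patch, bounds=(400, 800), frame_index=i)
            for i, f in enumerate(stack.frames)
        ]
        seq = reconstruct_sequence(stack, locs)
        rho = spearmanr(phases[seq.ordering], np.arange(len(phases))).statistic
        assert rho >= 0.99
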