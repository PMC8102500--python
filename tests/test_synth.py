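"""Generator contracts: determinism, exact ground truth, model limits."""

import numpy as np
import pytest

import nequant as nq
from _oracles import masked_mean_loop, flood_fill_components


def _scene(**kw):
    base = dict(image_shape=(64, 64),
                nuclei=[nq.NucleusSpec((32, 32), (22, 18), 10.0)],
                rim_contrast=2.0, noise_sigma=0.0, seed=5)
    base.update(kw)
    return nq.SceneSpec(**base)


class TestNucleusScene:
    def test_contrast_one_gives_uniform_marker(self):
        stack, truth = nq.make_nucleus_scene(_scene(rim_contrast=1.0))
        marker = stack.channel(1).data
        inside = truth.masks["labels"] > 0
        assert np.ptp(marker[inside]) == 0
        assert truth.per_nucleus["true_ratio"].iloc[0] == 1.0

    def test_true_mask_ratio_is_exactly_contrast(self):
        stack, truth = nq.make_nucleus_scene(_scene(rim_contrast=2.0))
        marker = stack.channel(1).data
        # brute-force masked means on the generated array
        rim_mean = masked_mean_loop(marker, truth.masks["rim"])
        core_mean = masked_mean_loop(marker, truth.masks["nucleoplasm"])
        assert rim_mean / core_mean == pytest.approx(2.0, abs=1e-12)

    def test_noise_applied_last_leaves_masks_exact(self):
        stack, truth = nq.make_nucleus_scene(_scene(noise_sigma=5.0))
        assert truth.masks["labels"].max() == 1
        assert truth.masks["rim"].sum() > 0 and truth.masks["nucleoplasm"].sum() > 0
        assert not np.any(truth.masks["rim"] & truth.masks["nucleoplasm"])

    def test_rim_wider_than_minor_semi_axis_rejected(self):
        with pytest.raises(ValueError, match="rim band"):
            nq.make_nucleus_scene(_scene(rim_width_px=18))

    def test_overlapping_nuclei_rejected(self):
        spec = _scene(nuclei=[nq.NucleusSpec((32, 30), (20, 16)),
                              nq.NucleusSpec((32, 40), (20, 16))])
        with pytest.raises(ValueError, match="overlap"):
            nq.make_nucleus_scene(spec)


class TestDeterminism:
    @pytest.mark.parametrize("factory", [
        lambda: nq.make_nucleus_scene(_scene(noise_sigma=4.0, seed=9)),
        lambda: nq.make_frap_series(
            nq.FrapSpec(noise_sigma=2.0, n_postbleach_frames=30, seed=9),
            _scene()),
        lambda: nq.make_coloc_pair(0.5, _scene(noise_sigma=2.0, seed=9)),
        lambda: nq.make_foci_stack(
            nq.SceneSpec(image_shape=(16, 48, 48),
                         nuclei=[nq.NucleusSpec((24, 24), (18, 16))],
                         foci_count=3, foci_volume_voxels=12,
                         noise_sigma=2.0, seed=9)),
    ], ids=["scene", "frap", "coloc", "foci"])
    def test_same_seed_bit_identical(self, factory):
        a, _ = factory()
        b, _ = factory()
        assert np.array_equal(a.data, b.data)


class TestFrapSeries:
    def test_immobile_pool_stays_at_postbleach_level(self):
        spec = nq.FrapSpec(mobile_fraction=0.0, acquisition_bleach_rate=0.0,
                           n_postbleach_frames=40, seed=1)
        series, truth = nq.make_frap_series(spec, _scene())
        bleach = truth.masks["bleach"]
        post = [series.frame(i).data[bleach].mean()
                for i in range(spec.n_prebleach_frames, series.n("time"))]
        D = spec.postbleach_depth * spec.prebleach_level + spec.background_level
        assert np.allclose(post, D, atol=1e-9)

    def test_full_recovery_approaches_prebleach(self):
        spec = nq.FrapSpec(mobile_fraction=1.0, rate=0.05,
                           n_postbleach_frames=300, seed=1)
        series, truth = nq.make_frap_series(spec, _scene())
        final = series.frame(series.n("time") - 1).data[truth.masks["bleach"]].mean()
        P = spec.prebleach_level + spec.background_level
        assert final == pytest.approx(P, rel=1e-3)

    def test_acquisition_bleaching_decays_total_at_rate_beta(self):
        beta = 0.004
        spec = nq.FrapSpec(mobile_fraction=0.0, acquisition_bleach_rate=beta,
                           background_level=0.0, n_postbleach_frames=200, seed=1)
        series, truth = nq.make_frap_series(spec, _scene())
        struct = truth.masks["structure"]
        n_pre = spec.n_prebleach_frames
        tot = np.array([series.frame(i).data[struct].sum()
                        for i in range(n_pre, series.n("time"))])
        t = np.arange(len(tot)) * spec.frame_interval
        slope = np.polyfit(t, np.log(tot), 1)[0]
        assert -slope == pytest.approx(beta, rel=1e-6)

    def test_conservation_without_acquisition_bleaching(self):
        spec = nq.FrapSpec(mobile_fraction=0.7, acquisition_bleach_rate=0.0,
                           background_level=0.0, n_postbleach_frames=80, seed=1)
        series, truth = nq.make_frap_series(spec, _scene())
        struct = truth.masks["structure"]
        n_pre = spec.n_prebleach_frames
        totals = [series.frame(i).data[struct].sum()
                  for i in range(n_pre, series.n("time"))]
        assert np.ptp(totals) < 1e-6 * totals[0]

    def test_invalid_depth_rejected(self):
        with pytest.raises(ValueError, match="postbleach_depth"):
            nq.make_frap_series(nq.FrapSpec(postbleach_depth=1.5), _scene())

    def test_drift_translates_frames(self):
        spec = nq.FrapSpec(n_postbleach_frames=5, drift_per_frame=(1.0, 2.0), seed=1)
        series, truth = nq.make_frap_series(spec, _scene())
        f0, f3 = series.frame(0).data, series.frame(3).data
        assert np.array_equal(np.roll(f0, (3, 6), axis=(0, 1)), f3)


class TestColocPair:
    def test_perfect_correlation_is_exact(self):
        stack, truth = nq.make_coloc_pair(1.0, _scene())
        pcc = nq.compute_pcc(stack.channel(0), stack.channel(1), truth.masks["cell"])
        assert pcc == pytest.approx(1.0, abs=1e-12)

    def test_zero_correlation_within_sampling_bound(self):
        geom = _scene(image_shape=(160, 160),
                      nuclei=[nq.NucleusSpec((80, 80), (70, 62))])
        stack, truth = nq.make_coloc_pair(0.0, geom, seed=21)
        assert truth.masks["cell"].sum() >= 10_000
        pcc = nq.compute_pcc(stack.channel(0), stack.channel(1), truth.masks["cell"])
        assert abs(pcc) < 0.05  # ~2/sqrt(n)

    def test_target_rho_recovered_empirically(self):
        geom = _scene(image_shape=(160, 160),
                      nuclei=[nq.NucleusSpec((80, 80), (70, 62))])
        stack, truth = nq.make_coloc_pair(0.6, geom, seed=3)
        pcc = nq.compute_pcc(stack.channel(0), stack.channel(1), truth.masks["cell"])
        assert pcc == pytest.approx(0.6, abs=0.08)

    def test_anisotropy_elongates_texture_along_y(self):
        stack, truth = nq.make_coloc_pair(0.8, _scene(), anisotropy=True)
        ch1 = stack.channel(0).data
        mask = truth.masks["cell"]
        core = mask & np.roll(mask, 1, 0) & np.roll(mask, 1, 1)
        drow = np.mean((ch1 - np.roll(ch1, 1, axis=0))[core] ** 2)
        dcol = np.mean((ch1 - np.roll(ch1, 1, axis=1))[core] ** 2)
        # slow variation along y (small row-to-row increments) = y-elongated
        assert drow < dcol / 4

    def test_degenerate_mask_rejected(self):
        geom = _scene(nuclei=[nq.NucleusSpec((32, 32), (1.2, 1.1))], rim_width_px=1)
        with pytest.raises(ValueError, match="degenerate mask"):
            nq.make_coloc_pair(0.5, geom)

    def test_rho_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            nq.make_coloc_pair(1.5, _scene())


class TestFociStack:
    def _spec(self, **kw):
        base = dict(image_shape=(24, 96, 96),
                    nuclei=[nq.NucleusSpec((48, 48), (40, 36))],
                    noise_sigma=0.0, seed=13)
        base.update(kw)
        return nq.SceneSpec(**base)

    def test_requested_volumes_in_truth_table(self):
        _, truth = nq.make_foci_stack(self._spec(), volumes=[5, 50, 2500])
        assert sorted(truth.foci_table["volume_voxels"]) == [5, 50, 2500]

    def test_zero_foci_means_no_suprathreshold_component(self):
        stack, truth = nq.make_foci_stack(self._spec(), volumes=[])
        inside = stack.data[truth.masks["nucleus"]]
        assert np.ptp(inside) == 0

    def test_zero_volume_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            nq.make_foci_stack(self._spec(), volumes=[0])

    def test_placed_foci_are_distinct_components(self):
        _, truth = nq.make_foci_stack(self._spec(), volumes=[30] * 6)
        vols = flood_fill_components(truth.masks["foci_labels"] > 0)
        assert vols == [30] * 6

    def test_grow_component_exact_volume_and_connectivity(self):
        allowed = np.ones((12, 12, 12), dtype=bool)
        blob = nq.grow_component(allowed, (6, 6, 6), 47)
        assert blob.sum() == 47
        assert flood_fill_components(blob) == [47]

    def test_components_one_voxel_apart_stay_distinct(self):
        allowed = np.ones((10, 20, 10), dtype=bool)
        a = nq.grow_component(allowed, (5, 4, 5), 9)
        # forbid the first blob plus a one-voxel moat, then grow the second
        from scipy import ndimage
        moat = ndimage.binary_dilation(a, ndimage.generate_binary_structure(3, 3))
        b = nq.grow_component(allowed & ~moat, (5, 14, 5), 9)
        assert flood_fill_components(a | b) == [9, 9]
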