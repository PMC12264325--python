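"""Weighted log subtraction, ACNR, CNR and weighting-factor selection.

The central oracle is Beer-Lambert algebra on an analytic two-material
projection: a bone step over a soft-tissue background cancels exactly at
ws* = mu_bone(HE)/mu_bone(LE).
"""

import numpy as np
import pytest

from detrack.dual_energy import (
    DualEnergyError,
    ROIPair,
    acnr,
    bone_image,
    cnr,
    gaussian_highpass,
    log_subtract,
    select_wb,
    select_ws,
)
from detrack.projector import ProjectionImage

# analytic two-material coefficients (1/mm) — any physical values work
MU_SOFT = {"LE": 0.0268, "HE": 0.0193}
MU_BONE = {"LE": 0.0470, "HE": 0.0259}
WS_STAR = MU_BONE["HE"] / MU_BONE["LE"]
WB_STAR = MU_SOFT["HE"] / MU_SOFT["LE"]


def analytic_pair(shape=(40, 40), i0=1e6, bone_rows=slice(0, 20), bone_mm=10.0,
                  soft_pattern=None):
    """Noiseless HE/LE images of a soft background plus a bone step."""
    soft = np.full(shape, 100.0)
    if soft_pattern is not None:
        soft = soft + soft_pattern
    bone = np.zeros(shape)
    bone[bone_rows, :] = bone_mm
    imgs = {}
    for e in ("HE", "LE"):
        pix = i0 * np.exp(-MU_SOFT[e] * soft - MU_BONE[e] * bone)
        imgs[e] = ProjectionImage(pixels=pix, view="A", energy_label=e, mAs=1.0)
    return imgs["HE"], imgs["LE"]


class TestLogSubtract:
    def test_ws_zero_returns_log_he(self):
        he, le = analytic_pair()
        de = log_subtract(he, le, 0.0)
        assert np.allclose(de.log_pixels, np.log(he.pixels))

    def test_identical_inputs_ws_one_gives_zero(self):
        he, _ = analytic_pair()
        de = log_subtract(he, he, 1.0)
        assert np.all(de.log_pixels == 0)

    def test_exact_bone_cancellation_at_ws_star(self):
        he, le = analytic_pair()
        de = log_subtract(he, le, WS_STAR)
        # bone step contrast vanishes to machine precision
        step = de.log_pixels[:20].mean() - de.log_pixels[20:].mean()
        assert abs(step) < 1e-10

    def test_swap_order_cancels_at_inverse_ratio(self):
        he, le = analytic_pair()
        de = log_subtract(he, le, 1.0 / WS_STAR, swap_order=True)
        step = de.log_pixels[:20].mean() - de.log_pixels[20:].mean()
        assert abs(step) < 1e-10

    def test_shape_and_view_mismatch_rejected(self):
        he, le = analytic_pair()
        other = ProjectionImage(pixels=np.ones((8, 8)), view="A",
                                energy_label="LE", mAs=1.0)
        with pytest.raises(DualEnergyError):
            log_subtract(he, other, 1.0)
        wrong_view = ProjectionImage(pixels=le.pixels, view="B",
                                     energy_label="LE", mAs=1.0)
        with pytest.raises(DualEnergyError):
            log_subtract(he, wrong_view, 1.0)


class TestBoneImage:
    def test_soft_tissue_cancellation_at_wb_star(self):
        ramp = np.tile(np.linspace(0, 30, 40), (40, 1))
        he, le = analytic_pair(soft_pattern=ramp)
        bi = bone_image(he, le, WB_STAR)
        # soft ramp contrast vanishes in the bone-free half
        half = bi.log_pixels[20:]
        assert half.max() - half.min() < 1e-10

    def test_identity_inputs_wb_one(self):
        he, _ = analytic_pair()
        bi = bone_image(he, he, 1.0)
        assert np.all(bi.log_pixels == 0)

    def test_bone_step_visible_away_from_cancelling_weight(self):
        he, le = analytic_pair()
        bi = bone_image(he, le, WB_STAR)
        step = bi.log_pixels[:20].mean() - bi.log_pixels[20:].mean()
        assert abs(step) > 1e-3


class TestGaussianHighpass:
    def test_constant_image_zeroed(self):
        out = gaussian_highpass(np.full((32, 32), 7.0), 0.2)
        assert np.allclose(out, 0.0, atol=1e-10)

    @pytest.mark.parametrize("freq,expected,tol", [(0.2, 0.5, 0.01), (0.45, 0.97, 0.03)])
    def test_sinusoid_response_matches_closed_form(self, freq, expected, tol):
        # closed form: H(f) = 1 - exp(-f^2 ln2 / cutoff^2)
        n = 128
        x = np.arange(n)
        img = np.sin(2 * np.pi * freq * x)[None, :] * np.ones((n, 1))
        out = gaussian_highpass(img, 0.2)
        gain = out[:, 32:96].std() / img[:, 32:96].std()
        closed = 1 - np.exp(-(freq**2) * np.log(2) / 0.2**2)
        assert gain == pytest.approx(closed, abs=tol)
        if freq == 0.2:
            assert gain == pytest.approx(expected, abs=0.01)
        else:
            assert gain >= 0.95

    def test_cutoff_out_of_range(self):
        with pytest.raises(DualEnergyError):
            gaussian_highpass(np.ones((8, 8)), 0.0)
        with pytest.raises(DualEnergyError):
            gaussian_highpass(np.ones((8, 8)), 0.6)


class TestACNR:
    def _de(self, arr, view="A"):
        from detrack.dual_energy import DEImage

        return DEImage(log_pixels=arr, view=view)

    def test_wn_zero_identity(self):
        rng = np.random.default_rng(0)
        soft = self._de(rng.normal(size=(32, 32)))
        bone = self._de(rng.normal(size=(32, 32)))
        out = acnr(soft, bone, wn=0.0)
        assert np.allclose(out.log_pixels, soft.log_pixels)

    def test_constant_bone_image_has_no_effect(self):
        rng = np.random.default_rng(1)
        soft = self._de(rng.normal(size=(32, 32)))
        bone = self._de(np.full((32, 32), 3.0))
        out = acnr(soft, bone, wn=0.9)
        assert np.allclose(out.log_pixels, soft.log_pixels, atol=1e-10)

    def test_linear_in_wn(self):
        rng = np.random.default_rng(2)
        soft = self._de(rng.normal(size=(16, 16)))
        bone = self._de(rng.normal(size=(16, 16)))
        o1 = acnr(soft, bone, wn=0.3).log_pixels - soft.log_pixels
        o2 = acnr(soft, bone, wn=0.6).log_pixels - soft.log_pixels
        assert np.allclose(2 * o1, o2, atol=1e-12)

    def test_anticorrelated_noise_suppressed(self):
        # noise_bone = -noise_soft: ACNR at wn=1 should cut the residual
        # high-frequency noise sd by at least half (20 seeded repeats)
        reductions = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noise = rng.normal(0, 1.0, size=(64, 64))
            soft = self._de(noise)
            bone = self._de(-noise)
            out0 = gaussian_highpass(acnr(soft, bone, wn=0.0).log_pixels, 0.2)
            out1 = gaussian_highpass(acnr(soft, bone, wn=1.0).log_pixels, 0.2)
            reductions.append(out1.std() / out0.std())
        assert np.mean(reductions) < 0.5


class TestCNR:
    ROIS = ROIPair(bone=((0, 8), (0, 8)), soft=((0, 8), (10, 18)))

    def test_identical_statistics_zero(self):
        rng = np.random.default_rng(0)
        patch = rng.normal(size=(8, 8))
        img = np.zeros((8, 20))
        img[:, 0:8] = patch
        img[:, 10:18] = patch
        assert cnr(img, self.ROIS) == 0.0

    def test_two_sigma_step(self):
        rng = np.random.default_rng(1)
        img = np.zeros((8, 20))
        noise = rng.normal(0, 1.0, size=(8, 8))
        noise = (noise - noise.mean()) / noise.std()  # exact sd 1
        img[:, 10:18] = noise
        img[:, 0:8] = 2.0
        assert cnr(img, self.ROIS) == pytest.approx(2.0)

    def test_monotone_in_step_amplitude(self):
        rng = np.random.default_rng(2)
        noise = rng.normal(0, 1.0, size=(8, 8))
        values = []
        for amp in (4.0, 2.0, 1.0, 0.5):
            img = np.zeros((8, 20))
            img[:, 10:18] = noise
            img[:, 0:8] = amp
            values.append(cnr(img, self.ROIS))
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_zero_sd_raises_unless_eps(self):
        img = np.zeros((8, 20))
        img[:, 0:8] = 1.0
        with pytest.raises(DualEnergyError):
            cnr(img, self.ROIS)
        assert cnr(img, self.ROIS, eps=1e-6) > 0

    def test_overlapping_or_small_rois_rejected(self):
        with pytest.raises(DualEnergyError):
            ROIPair(bone=((0, 8), (0, 8)), soft=((4, 12), (4, 12)))
        with pytest.raises(DualEnergyError):
            ROIPair(bone=((0, 4), (0, 4)), soft=((10, 14), (10, 14)))


class TestSelectWs:
    ROIS = ROIPair(bone=((0, 20), (0, 40)), soft=((20, 40), (0, 40)))

    def _structured_pair(self):
        # soft-thickness ramp along columns (identical in both ROIs) plus a
        # bone slab in the bone ROI: CNR numerator isolates the bone step
        ramp = np.tile(np.linspace(0, 20, 40), (40, 1))
        return analytic_pair(soft_pattern=ramp, bone_rows=slice(0, 20))

    def test_recovers_analytic_cancelling_weight(self):
        he, le = self._structured_pair()
        ws = select_ws(he, le, self.ROIS, grid=(0.2, 2.5, 0.01))
        assert ws == pytest.approx(WS_STAR, abs=0.01)

    def test_flat_profile_returns_grid_minimum(self):
        # identical ROI statistics for every ws -> documented degenerate
        # fallback to the grid minimum
        rng = np.random.default_rng(3)
        patch = rng.uniform(1000, 2000, size=(20, 40))
        pix = np.vstack([patch, patch])
        he = ProjectionImage(pixels=pix, view="A", energy_label="HE", mAs=1.0)
        le = ProjectionImage(pixels=pix**1.3, view="A", energy_label="LE", mAs=1.0)
        ws = select_ws(he, le, self.ROIS, grid=(0.5, 1.5, 0.1))
        assert ws == pytest.approx(0.5)

    def test_invariant_to_intensity_rescaling(self):
        he, le = self._structured_pair()
        ws1 = select_ws(he, le, self.ROIS, grid=(0.2, 1.5, 0.01))
        he2 = ProjectionImage(pixels=3.7 * he.pixels, view="A",
                              energy_label="HE", mAs=1.0)
        le2 = ProjectionImage(pixels=0.9 * le.pixels, view="A",
                              energy_label="LE", mAs=1.0)
        ws2 = select_ws(he2, le2, self.ROIS, grid=(0.2, 1.5, 0.01))
        assert ws1 == ws2

    def test_empty_grid_rejected(self):
        he, le = self._structured_pair()
        with pytest.raises(DualEnergyError):
            select_ws(he, le, self.ROIS, grid=(1.0, 0.5, 0.1))


class TestSelectWb:
    ROIS = ROIPair(bone=((0, 20), (0, 40)), soft=((20, 40), (0, 40)))

    def test_recovers_soft_cancelling_weight(self):
        ramp = np.tile(np.linspace(0, 20, 40), (40, 1))
        he, le = analytic_pair(soft_pattern=ramp, bone_rows=slice(0, 20))
        wb = select_wb(he, le, self.ROIS, grid=(0.2, 2.5, 0.01))
        assert wb == pytest.approx(WB_STAR, abs=0.01)

    def test_degenerate_no_structure_returns_grid_minimum(self):
        he, le = analytic_pair()  # uniform soft, no structure in soft ROI
        wb = select_wb(he, le, self.ROIS, grid=(0.4, 1.2, 0.1))
        assert wb == pytest.approx(0.4)
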