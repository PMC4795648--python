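"""Stimulus generator and transform contracts."""

import numpy as np
import pytest

import holoface as hf
from holoface.config import StimulusConfig
from holoface.stimuli import PartSpec, crop_to_region, shift_image


class TestGenerator:
    def test_deterministic_for_fixed_identity_and_seed(self):
        a = hf.generate_identity(3, 1)
        b = hf.generate_identity(3, 1)
        assert a.parts == b.parts
        assert a.shading == b.shading
        np.testing.assert_array_equal(a.texture[0][0], b.texture[0][0])
        np.testing.assert_array_equal(
            hf.render(a).pixels, hf.render(b).pixels
        )

    def test_identities_differ_in_top_and_bottom_halves(self):
        a = hf.generate_identity(3, 1)
        b = hf.generate_identity(4, 1)
        eyes_differ = any(
            a.parts[p] != b.parts[p] for p in ("left_eye", "right_eye", "left_brow", "right_brow")
        )
        bottom_differ = any(a.parts[p] != b.parts[p] for p in ("nose", "mouth"))
        assert eyes_differ and bottom_differ

    def test_negative_identity_rejected(self):
        with pytest.raises(ValueError):
            hf.generate_identity(-1, 1)

    def test_pixel_statistics_normalized_across_identities(self):
        cfg = StimulusConfig()
        for i in range(0, 100, 7):
            img = hf.render(hf.generate_identity(i, 1))
            vals = img.pixels[img.pixels > 0]
            assert abs(vals.mean() - cfg.norm_mean) < 1e-6
            assert abs(vals.std() - cfg.norm_std) < 1e-6

    def test_render_geometry(self):
        img = hf.render(hf.generate_identity(0, 1))
        assert img.pixels.shape == (256, 256)
        assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0
        mask = img.pixels > 0
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
        # faces are 80 px wide and 120 px tall on a black background
        assert abs((rows[-1] - rows[0] + 1) - 120) <= 2
        assert abs((cols[-1] - cols[0] + 1) - 80) <= 2
        # everything outside the oval is exactly black
        cy, cx = 128, 128
        yy, xx = np.mgrid[:256, :256]
        outside = ((yy - cy) / 60.0) ** 2 + ((xx - cx) / 40.0) ** 2 > 1.1
        assert np.all(img.pixels[outside] == 0.0)

    def test_part_outside_oval_raises(self):
        spec = hf.generate_identity(0, 1)
        bad = dict(spec.parts)
        bad["mouth"] = PartSpec(cy=186.0, cx=128.0, ry=6.0, rx=14.0, intensity=0.2)
        from dataclasses import replace

        with pytest.raises(ValueError, match="outside the face oval"):
            hf.render(replace(spec, parts=bad))

    def test_degenerate_contrast_raises(self):
        from dataclasses import replace

        cfg = replace(
            StimulusConfig(),
            base_intensity=0.0,
            texture_amp=0.0,
            shading_amp=0.0,
            shading_sd=0.0,
            parts={
                k: replace(v, intensity=0.0, intensity_sd=0.0)
                for k, v in StimulusConfig().parts.items()
            },
        )
        spec = hf.generate_identity(0, 1, cfg)
        with pytest.raises(ValueError, match="degenerate"):
            hf.render(spec, cfg)


@pytest.fixture(scope="module")
def two_faces():
    return hf.render(hf.generate_identity(0, 1)), hf.render(hf.generate_identity(2, 1))


class TestComposites:

    def test_self_composite_identical_except_gap(self, two_faces):
        a, _ = two_faces
        comp = hf.make_composite(a, a, aligned=True)
        gap0 = 128 - 1
        assert np.all(comp.pixels[gap0 : gap0 + 2] == 0.0)
        rest = np.ones(256, dtype=bool)
        rest[gap0 : gap0 + 2] = False
        np.testing.assert_array_equal(comp.pixels[rest], a.pixels[rest])

    def test_top_half_taken_from_top_source(self, two_faces):
        a, b = two_faces
        comp = hf.make_composite(a, b, aligned=True)
        np.testing.assert_array_equal(comp.pixels[:127], a.pixels[:127])

    def test_misaligned_bottom_centroid_shift(self, two_faces):
        a, b = two_faces
        cfg = StimulusConfig()
        ali = hf.make_composite(a, b, aligned=True)
        mis = hf.make_composite(a, b, aligned=False)

        def centroid_x(img):
            bottom = img.pixels[129:]
            total = bottom.sum()
            return (bottom * np.arange(256)[None, :]).sum() / total

        shift = centroid_x(mis) - centroid_x(ali)
        assert abs(shift - cfg.misalign_offset) < 1.0

    def test_shape_mismatch_rejected(self, two_faces):
        a, _ = two_faces
        small = hf.StimulusImage(np.zeros((128, 128)))
        with pytest.raises(ValueError):
            hf.make_composite(a, small)


class TestAttentionAndInversion:
    def test_identity_when_factor_one(self):
        img = hf.render(hf.generate_identity(0, 1))
        out = hf.apply_attention(img, (68, 127, 88, 168), factor=1.0, recenter=False)
        np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_complement_scaled_by_factor(self):
        img = hf.render(hf.generate_identity(0, 1))
        region = (68, 127, 88, 168)
        out = hf.apply_attention(img, region, factor=0.1, recenter=False)
        np.testing.assert_allclose(out.pixels[160:], 0.1 * img.pixels[160:])
        np.testing.assert_array_equal(
            out.pixels[68:127, 88:168], img.pixels[68:127, 88:168]
        )

    def test_recenter_places_region_center_at_image_center(self):
        img = hf.render(hf.generate_identity(0, 1))
        region = (68, 116, 88, 168)
        out = hf.apply_attention(img, region, factor=0.5, recenter=True)
        r0, r1, c0, c1 = out.meta["attended_region"]
        assert abs((r0 + r1) / 2 - 128) <= 1 and abs((c0 + c1) / 2 - 128) <= 1

    def test_region_outside_bounds_rejected(self):
        img = hf.render(hf.generate_identity(0, 1))
        with pytest.raises(ValueError):
            hf.apply_attention(img, (0, 300, 0, 100), 0.5)

    def test_inversion_involution_and_row_reversal(self):
        img = hf.render(hf.generate_identity(0, 1))
        inv = hf.invert(img)
        np.testing.assert_array_equal(inv.pixels[7], img.pixels[255 - 7])
        np.testing.assert_array_equal(hf.invert(inv).pixels, img.pixels)
        assert inv.pixels.mean() == pytest.approx(img.pixels.mean())


class TestWholePart:
    def test_self_blend_is_identity(self):
        a = hf.render(hf.generate_identity(0, 1))
        whole, _ = hf.make_whole_part_pair(a, a)
        np.testing.assert_allclose(whole.pixels, a.pixels, atol=1e-12)

    def test_part_zero_outside_eye_region(self):
        cfg = StimulusConfig()
        a = hf.render(hf.generate_identity(0, 1))
        b = hf.render(hf.generate_identity(2, 1))
        _, part = hf.make_whole_part_pair(a, b)
        r0, r1, c0, c1 = cfg.derived_eye_region()
        outside = np.ones((256, 256), dtype=bool)
        outside[r0:r1, c0:c1] = False
        assert np.all(part.pixels[outside] == 0.0)

    def test_whole_non_eye_region_equals_base(self):
        cfg = StimulusConfig()
        a = hf.render(hf.generate_identity(0, 1))
        b = hf.render(hf.generate_identity(2, 1))
        whole, _ = hf.make_whole_part_pair(a, b)
        r0, r1, c0, c1 = cfg.derived_eye_region()
        outside = np.ones((256, 256), dtype=bool)
        outside[r0:r1, c0:c1] = False
        np.testing.assert_array_equal(whole.pixels[outside], b.pixels[outside])

    def test_transform_outputs_stay_in_unit_range(self):
        a = hf.render(hf.generate_identity(0, 1))
        b = hf.render(hf.generate_identity(2, 1))
        outputs = [
            hf.make_composite(a, b, aligned=False),
            hf.apply_attention(a, (68, 116, 88, 168), 0.1, recenter=True, soften_px=8),
            hf.invert(a),
            *hf.make_whole_part_pair(a, b),
            crop_to_region(a, (100, 120, 100, 156)),
        ]
        for out in outputs:
            assert out.pixels.shape == (256, 256)
            assert out.pixels.min() >= 0.0 and out.pixels.max() <= 1.0


def test_shift_image_zero_fill():
    px = np.arange(16, dtype=float).reshape(4, 4)
    out = shift_image(px, 1, -1)
    assert out[0].sum() == 0 and out[:, -1].sum() == 0
    assert out[1, 0] == px[0, 1]


def test_png_roundtrip(tmp_path):
    img = hf.render(hf.generate_identity(0, 1))
    path = tmp_path / "face.png"
    from holoface.stimuli import load_png, save_png

    save_png(img, path)
    back = load_png(path)
    assert back.meta["identity_ids"] == [0]
    np.testing.assert_allclose(back.pixels, img.pixels, atol=1 / 255)
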