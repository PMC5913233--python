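"""Rendering, rotational alignment, classification and transforms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

import paintqc as pq
from paintqc import align as al
from paintqc import locio
from paintqc import simulate as sim


def _rot(deg):
    a = np.radians(deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


@pytest.fixture(scope="module")
def bs6_template(bs_pair):
    _, bs6 = bs_pair
    return pq.render_template(bs6, pq.TemplateSpec(render_sigma=1.0, bin_size=1.0))


@pytest.fixture(scope="module")
def bs6_points(bs_pair):
    _, bs6 = bs_pair
    return np.vstack([bs6.probed_sites, bs6.alignment_sites])


class TestRenderStructure:
    def test_counts_preserved_before_blur(self, rng):
        xy = rng.normal(scale=10.0, size=(100, 2))
        img = al.render_structure(xy, bin_size=1.0, blur_sigma=0.0)
        assert img.data.sum() == pytest.approx(100)

    def test_point_source_occupies_single_bin(self):
        img = al.render_structure(np.zeros((50, 2)), bin_size=1.0, blur_sigma=0.0)
        assert (img.data > 0).sum() == 1
        assert img.data.max() == 50

    def test_simulated_grid_shows_12_blobs(self, grid_field, grid_pattern):
        table, truth = grid_field
        regions = locio.pick_structures(
            table, expected_radius_nm=grid_pattern.radius() + 40
        )
        locs = locio.extract(table, regions[0])
        img = al.render_structure(locs, bin_size=1.0, blur_sigma=2.0)
        local_max = (
            ndimage.maximum_filter(img.data, size=11) == img.data
        ) & (img.data > 0.3 * img.data.max())
        assert local_max.sum() == 12

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            al.render_structure(np.empty((0, 2)))


class TestAlignToTemplate:
    def test_self_alignment_is_identity(self, bs6_points, bs6_template):
        res = al.align_to_template(bs6_points, bs6_template)
        assert res.angle == 0.0
        assert res.shift == (0.0, 0.0)
        assert res.correlation > 0.9

    def test_known_rotation_recovered(self, bs6_points, bs6_template):
        res = al.align_to_template(bs6_points @ _rot(37.0).T, bs6_template)
        assert res.angle == pytest.approx(323.0, abs=1.0)
        assert max(abs(s) for s in res.shift) <= bs6_template.bin_size

    def test_known_shift_recovered(self, bs6_points, bs6_template):
        res = al.align_to_template(bs6_points + [5.0, -3.0], bs6_template)
        assert res.angle == 0.0
        assert res.shift[0] == pytest.approx(-5.0, abs=1.0)
        assert res.shift[1] == pytest.approx(3.0, abs=1.0)

    def test_mirror_detected_when_searched(self, bs6_points, bs6_template):
        mirrored = bs6_points * [-1.0, 1.0]
        with_mirror = al.align_to_template(mirrored, bs6_template, try_mirror=True)
        without = al.align_to_template(mirrored, bs6_template, try_mirror=False)
        straight = al.align_to_template(bs6_points, bs6_template)
        assert with_mirror.mirror
        assert with_mirror.correlation == pytest.approx(straight.correlation, rel=0.05)
        assert without.correlation < with_mirror.correlation

    def test_degenerate_inputs_rejected(self, bs6_points, bs6_template):
        from paintqc.designs import TemplateImage

        zero = TemplateImage(
            data=np.zeros((10, 10)), bin_size=1.0, origin=(-5.0, -5.0), render_sigma=1.0
        )
        with pytest.raises(ValueError):
            al.align_to_template(bs6_points, zero)
        with pytest.raises(ValueError):
            al.align_to_template(np.empty((0, 2)), bs6_template)


class TestClassify:
    def test_single_template_library_reduces_to_align(self, bs6_points, bs6_template):
        direct = al.align_to_template(bs6_points, bs6_template)
        via_lib = al.classify_template(bs6_points, [bs6_template])
        assert via_lib.correlation == direct.correlation
        assert via_lib.assigned

    def test_simulated_variant_assigned_to_its_template(self, variant_library):
        pat = variant_library[6]  # an arbitrary interior variant
        spec = pq.TemplateSpec(render_sigma=1.0, bin_size=1.0)
        templates = [pq.render_template(p, spec) for p in variant_library]
        pop = sim.StructurePopulation(pattern=pat, n_structures=1)
        table, _ = sim.simulate_field(
            pop, imaging=sim.ImagingModel(n_frames=3000), seed=77
        )
        regions = locio.pick_structures(table, expected_radius_nm=pat.radius() + 40)
        locs = locio.extract(table, regions[0])
        res = al.classify_template(locs, templates, max_shift_nm=40.0)
        assert res.template == pat.name
        assert res.assigned

    def test_uniform_noise_unassigned(self, variant_library, rng):
        spec = pq.TemplateSpec(render_sigma=1.0, bin_size=1.0)
        templates = [pq.render_template(p, spec) for p in variant_library[:4]]
        r = rng.uniform(0, 70, 2000)
        th = rng.uniform(0, 2 * np.pi, 2000)
        noise = np.column_stack([r * np.cos(th), r * np.sin(th)])
        res = al.classify_template(noise, templates, max_shift_nm=40.0)
        assert not res.assigned

    def test_empty_library_rejected(self, bs6_points):
        with pytest.raises(ValueError):
            al.classify_template(bs6_points, [])


class TestTransformLocs:
    def test_identity_is_noop(self, bs6_points):
        ident = al.AlignmentResult(angle=0.0, shift=(0.0, 0.0), mirror=False, correlation=1.0)
        np.testing.assert_allclose(al.transform_locs(bs6_points, ident), bs6_points)

    @settings(derandomize=True, max_examples=30)
    @given(
        angle=st.floats(0.0, 360.0, allow_nan=False),
        dx=st.floats(-50.0, 50.0),
        dy=st.floats(-50.0, 50.0),
        mirror=st.booleans(),
    )
    def test_roundtrip_inverse(self, angle, dx, dy, mirror):
        pts = np.array([[1.0, 2.0], [-30.0, 14.5], [7.25, -9.0]])
        res = al.AlignmentResult(
            angle=angle, shift=(dx, dy), mirror=mirror, correlation=1.0
        )
        back = al.transform_locs(al.transform_locs(pts, res), res, inverse=True)
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_aligned_simulated_sites_land_on_design(self, grid_field, grid_pattern, grid_template):
        """After alignment, the mean localization position near each present
        site lies within 2 nm of the designed position."""
        table, truth = grid_field
        regions = locio.pick_structures(
            table, expected_radius_nm=grid_pattern.radius() + 40
        )
        locs = locio.extract(table, regions[0])
        res = al.align_to_template(locs, grid_template, max_shift_nm=50.0)
        aligned = al.transform_locs(locs, res)
        ok = 0
        for site in grid_pattern.sites:
            d = np.hypot(*(aligned.xy - site).T)
            sel = d < 8.0
            assert sel.sum() > 20
            # grid symmetry may permute site labels, but positions must match
            assert np.hypot(*(aligned.xy[sel].mean(axis=0) - site)) < 2.0
            ok += 1
        assert ok == 12
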