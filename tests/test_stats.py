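"""Two-color coincidence algebra, saturation fit and heatmap assembly."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import paintqc as pq
from paintqc import designs, stats

# the published two-color category fractions (both / only-3' / only-5' / none)
TALLY = stats.TwoColorTally(0.785, 0.050, 0.072, 0.093, n_sites=1200)


class TestTally:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            stats.TwoColorTally(0.5, 0.2, 0.2, 0.2, n_sites=10)

    def test_negative_fraction_rejected(self):
        with pytest.raises(ValueError):
            stats.TwoColorTally(1.2, -0.2, 0.0, 0.0, n_sites=10)

    def test_all_both(self):
        t = stats.coincidence_tally(np.ones((4, 3), bool), np.ones((4, 3), bool))
        assert (t.f_both, t.f_only3, t.f_only5, t.f_none) == (1.0, 0.0, 0.0, 0.0)

    def test_identical_channels_have_no_single_color(self, rng):
        det = rng.random((20, 12)) < 0.8
        t = stats.coincidence_tally(det, det)
        assert t.f_only3 == 0.0 and t.f_only5 == 0.0
        assert t.f_both + t.f_none == pytest.approx(1.0)

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            stats.coincidence_tally(np.ones((4, 3), bool), np.ones((4, 4), bool))

    def test_generative_model_reproduces_published_fractions(self, rng):
        """Incorporation 0.907 with channel miss rates 0.084 / 0.060
        reproduces the published tally within multinomial error."""
        n = 120000  # large n to beat multinomial noise
        inc = rng.random(n) < 0.9116
        det3 = inc & (rng.random(n) < 1 - 0.084)
        det5 = inc & (rng.random(n) < 1 - 0.060)
        t = stats.coincidence_tally(det3[None], det5[None])
        assert t.f_both == pytest.approx(0.785, abs=0.01)
        assert t.f_only3 == pytest.approx(0.050, abs=0.01)
        assert t.f_only5 == pytest.approx(0.072, abs=0.01)
        assert t.f_none == pytest.approx(0.093, abs=0.01)


class TestIndependenceEstimate:
    def test_published_chance_none(self):
        est = stats.independence_estimate(TALLY)
        assert est.chance_none == pytest.approx((0.072 + 0.093) * (0.050 + 0.093))
        assert 100 * est.chance_none == pytest.approx(2.4, abs=0.1)

    def test_published_offset(self):
        est = stats.independence_estimate(TALLY)
        assert est.offset == pytest.approx((1 - 0.093) - (0.785 + 0.050))
        assert 100 * est.offset == pytest.approx(7.2, abs=0.1)

    def test_perfect_detection(self):
        est = stats.independence_estimate(
            stats.TwoColorTally(1.0, 0.0, 0.0, 0.0, n_sites=10)
        )
        assert est.chance_none == 0.0
        assert est.incorporated == 1.0
        assert est.offset == 0.0

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.01, 1.0), min_size=4, max_size=4))
    def test_algebraic_invariants(self, raw):
        f = np.array(raw) / np.sum(raw)
        t = stats.TwoColorTally(*np.round(f, 12), n_sites=100)
        # renormalize rounding residue into f_both if needed
        est = stats.independence_estimate(t)
        assert est.chance_none <= min(est.miss3, est.miss5) + 1e-12
        assert 0.0 <= est.incorporated <= 1.0
        assert est.offset == pytest.approx(est.incorporated - est.det3)

    def test_end_to_end_recovery_at_1200_sites(self, rng):
        """Simulated two-color data (100 structures x 12 sites) recover the
        true incorporation fraction within 2 percentage points."""
        f_true, q3, q5 = 0.9116, 0.084, 0.060
        n = 1200
        inc = rng.random(n) < f_true
        det3 = inc & (rng.random(n) < 1 - q3)
        det5 = inc & (rng.random(n) < 1 - q5)
        est = stats.independence_estimate(
            stats.coincidence_tally(det3.reshape(100, 12), det5.reshape(100, 12))
        )
        assert est.incorporated == pytest.approx(f_true, abs=0.02)
        assert est.chance_none < 0.05


class TestDetectionToIncorporation:
    @pytest.mark.parametrize(
        "eff,offset,expected",
        [(0.41, 0.07, 0.48), (0.77, 0.07, 0.84), (0.97, 0.07, 1.00)],
    )
    def test_offset_translation(self, eff, offset, expected):
        assert stats.detection_to_incorporation(eff, offset) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            stats.detection_to_incorporation(1.2, 0.07)


class TestMichaelisMenten:
    X = np.array([10.0, 25.0, 50.0, 100.0, 250.0, 500.0])

    def test_noiseless_recovery(self):
        y = 80.0 * self.X / (20.0 + self.X)
        fit = stats.fit_michaelis_menten(self.X, y)
        assert fit.vmax == pytest.approx(80.0, rel=1e-4)
        assert fit.km == pytest.approx(20.0, rel=1e-4)
        assert not fit.degenerate

    def test_noisy_recovery_within_5_percent(self, rng):
        y = 80.0 * self.X / (20.0 + self.X)
        y_noisy = y * (1 + rng.normal(0, 0.01, size=y.shape))
        fit = stats.fit_michaelis_menten(self.X, y_noisy)
        assert fit.vmax == pytest.approx(80.0, rel=0.05)
        assert fit.km == pytest.approx(20.0, rel=0.05)

    def test_two_points_underdetermined(self):
        with pytest.raises(ValueError):
            stats.fit_michaelis_menten([10.0, 100.0], [50.0, 70.0])

    def test_constant_efficiencies_flagged_degenerate(self):
        fit = stats.fit_michaelis_menten(self.X, np.full(6, 80.0))
        assert fit.degenerate

    def test_nonpositive_excess_rejected(self):
        with pytest.raises(ValueError):
            stats.fit_michaelis_menten([0.0, 10.0, 20.0], [1.0, 2.0, 3.0])


class TestHeatmap:
    def test_single_variant_placed(self):
        layout = designs.rectangle_layout()
        labels = layout.detection_labels[:12]
        hm = stats.build_heatmap(
            {"v": [(lab, 0.8, 100) for lab in labels]}, layout
        )
        assert len(hm.values) == 12
        assert all(hm.values[lab] == 0.8 for lab in labels)

    def test_weighted_merge(self):
        layout = designs.rectangle_layout()
        lab = layout.detection_labels[0]
        hm = stats.build_heatmap(
            {"a": [(lab, 0.7, 100)], "b": [(lab, 0.9, 300)]}, layout
        )
        assert hm.values[lab] == pytest.approx(0.85)

    def test_excluded_label_rejected(self):
        layout = designs.rectangle_layout()
        bad = layout.excluded_labels[0]
        with pytest.raises(ValueError, match="excluded"):
            stats.build_heatmap({"v": [(bad, 0.5, 10)]}, layout)

    def test_full_library_coverage(self, variant_library):
        layout = designs.rectangle_layout()
        per_variant = {
            pat.name: [
                (lab, 0.8, 50)
                for lab, p in zip(pat.site_labels, pat.probe_mask)
                if p
            ]
            for pat in variant_library
        }
        hm = stats.build_heatmap(per_variant, layout)
        assert len(hm.values) == 168

    def test_csv_roundtrip_rows(self, tmp_path):
        layout = designs.rectangle_layout()
        labels = layout.detection_labels[:3]
        hm = stats.build_heatmap({"v": [(lab, 0.5, 10) for lab in labels]}, layout)
        path = tmp_path / "hm.csv"
        hm.save_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "label,row,col,value,n_structures"
        assert len(lines) == 1 + 168 + len(layout.excluded_labels)
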