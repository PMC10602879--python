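import math

import numpy as np
import pytest

from terrafoci import foci3d, io_core, synthetic_data as sd
from terrafoci.foci3d import Focus, NucleusModel

from conftest import make_focus


def ball_mask(shape, center_vox, radii_vox):
    zz, yy, xx = np.ogrid[:shape[0], :shape[1], :shape[2]]
    rz, ry, rx = radii_vox
    cz, cy, cx = center_vox
    return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


class TestSphereFit:
    def test_digital_ball_radius_within_half_voxel(self):
        mask = ball_mask((25, 25, 25), (12, 12, 12), (10, 10, 10))
        (cx, cy, cz), r = foci3d.fit_nucleus_sphere(mask, (0.1, 0.1, 0.1))
        assert r == pytest.approx(1.0, abs=0.05)
        assert (cx, cy, cz) == pytest.approx((1.25, 1.25, 1.25), abs=1e-9)

    def test_single_voxel_closed_form(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        _, r = foci3d.fit_nucleus_sphere(mask, (0.1, 0.1, 0.1))
        assert r == pytest.approx((3 * 0.001 / (4 * math.pi)) ** (1 / 3), rel=1e-12)

    def test_ellipsoid_equal_volume_radius(self):
        mask = ball_mask((45, 25, 25), (22, 12, 12), (20, 10, 10))  # 2:1:1 ellipsoid
        _, r = foci3d.fit_nucleus_sphere(mask, (0.1, 0.1, 0.1))
        expected = (2.0 * 1.0 * 1.0) ** (1 / 3)  # equal-volume radius of the ellipsoid
        assert r == pytest.approx(expected, abs=0.05)

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            foci3d.fit_nucleus_sphere(np.zeros((3, 3, 3), dtype=bool), (0.1, 0.1, 0.1))


class TestSegmentNuclei:
    def test_recovers_disjoint_spheres(self):
        stack, truth, _ = sd.generate_nuclei_stack(3, seed=0)[0], None, None
        stack, truth_nuclei, _ = sd.generate_nuclei_stack(3, seed=0)
        nuclei = foci3d.segment_nuclei(stack)
        assert len(nuclei) == 3
        for t in truth_nuclei:
            best = min(nuclei, key=lambda n: math.dist(n.centroid, t.center))
            assert math.dist(best.centroid, t.center) < 0.25  # within one voxel diagonal
            assert best.radius == pytest.approx(t.radius, rel=0.15)

    def test_blank_noise_stack_gives_no_nuclei(self):
        rng = np.random.default_rng(1)
        stack = io_core.ImageStack3D(
            rng.normal(100, 10, size=(1, 20, 80, 80)).clip(min=0),
            (0.2, 0.1, 0.1), ("dna",))
        assert foci3d.segment_nuclei(stack) == []

    def test_constant_image_warns_and_returns_empty(self):
        stack = io_core.ImageStack3D(np.full((1, 10, 40, 40), 50.0), (0.2, 0.1, 0.1), ("dna",))
        with pytest.warns(UserWarning, match="constant"):
            assert foci3d.segment_nuclei(stack) == []

    def test_watershed_splits_touching_nuclei(self):
        # two spheres fused by a thin neck
        img = np.zeros((40, 120, 120))
        for cy in (35, 84):
            img[ball_mask(img.shape, (20, cy, 60), (11, 23, 23))] = 150.0
        img[18:23, 55:65, 57:63] = 150.0  # neck
        stack = io_core.ImageStack3D(img[None] + 10.0, (0.2, 0.1, 0.1), ("dna",))
        merged = foci3d.segment_nuclei(stack, watershed_split=False)
        split = foci3d.segment_nuclei(stack, watershed_split=True, max_volume_um3=300.0)
        assert len(merged) <= 1  # single fused component (or filtered by size)
        assert len(split) == 2


class TestDetectFoci:
    def test_recovers_rendered_foci(self, small_stack):
        stack, _, truth, clean = small_stack
        nuclei = foci3d.segment_nuclei(stack)
        foci = foci3d.detect_foci(stack, "terra", nuclei)
        assert len(foci) == len(truth) == 5
        cimg = clean.channel("terra")
        for t in truth:
            f = min(foci, key=lambda f: math.dist(f.centroid, t.center))
            # within one voxel diagonal of the truth
            assert math.dist(f.centroid, t.center) < 0.25
            rendered = cimg[tuple(f.voxel_indices.T)].sum()
            assert f.integrated_density == pytest.approx(rendered, rel=0.10)
            assert f.compartment == "nuclear"

    def test_noise_only_channel_is_clean(self):
        n_false = 0
        for seed in range(5):
            stack, *_ = sd.generate_nuclei_stack(
                1, shape=(30, 100, 100), radius_range=(1.8, 2.0),
                foci_per_channel={"terra": {"n": 0}}, noise_sd=10.0, seed=200 + seed)
            n_false += len(foci3d.detect_foci(stack, "terra"))
        assert n_false <= 1

    def test_resolution_merge_behavior(self):
        """Foci 4 sigma apart resolve into two; 1 sigma apart merge into one."""
        sigma = 0.15
        for sep_sigmas, expected in ((4.0, 2), (1.0, 1)):
            img = np.full((30, 100, 100), 100.0)
            zc = (np.arange(30) + 0.5) * 0.2
            yc = (np.arange(100) + 0.5) * 0.1
            xc = (np.arange(100) + 0.5) * 0.1
            for k in (-0.5, 0.5):
                cx = 5.0 + k * sep_sigmas * sigma
                sd._render_gaussian(img, np.array([cx, 5.0, 3.0]), sigma, 100.0, (zc, yc, xc))
            img += np.random.default_rng(0).normal(0, 5.0, img.shape)
            stack = io_core.ImageStack3D(img.clip(min=0)[None], (0.2, 0.1, 0.1), ("terra",))
            foci = foci3d.detect_foci(stack, "terra", dna_channel=None)
            assert len(foci) == expected, f"separation {sep_sigmas} sigma"

    def test_intensity_linearity(self, small_stack):
        """Scaling intensities scales density measures and preserves geometry."""
        stack, *_ = small_stack
        scaled = io_core.ImageStack3D(stack.voxels * 3.0, stack.voxel_size, stack.channel_names)
        f1 = foci3d.detect_foci(stack, "terra")
        f2 = foci3d.detect_foci(scaled, "terra")
        assert len(f1) == len(f2)
        for a, b in zip(f1, f2):
            assert b.integrated_density == pytest.approx(3 * a.integrated_density, rel=1e-9)
            assert b.average_intensity == pytest.approx(3 * a.average_intensity, rel=1e-9)
            assert b.volume == a.volume
            assert b.centroid == pytest.approx(a.centroid, abs=1e-9)

    def test_bad_sigma_rejected(self, small_stack):
        with pytest.raises(ValueError):
            foci3d.detect_foci(small_stack[0], "terra", sigma_um=0.0)

    def test_focus_channel_equal_dna_warns(self, small_stack):
        with pytest.warns(UserWarning, match="DNA"):
            foci3d.detect_foci(small_stack[0], "dna", dna_channel="dna")


class TestCompartmentAndRadialPosition:
    nucleus = NucleusModel(nucleus_id=1, centroid=(5.0, 5.0, 3.0), radius=2.0)

    def test_center_is_nuclear(self):
        f = make_focus(1, None, (5.0, 5.0, 3.0))
        comp, nid = foci3d.classify_compartment(f, [self.nucleus], (0.2, 0.1, 0.1))
        assert (comp, nid) == ("nuclear", 1)

    def test_far_focus_is_cytoplasmic(self):
        f = make_focus(1, None, (9.0, 5.0, 3.0))
        comp, nid = foci3d.classify_compartment(f, [self.nucleus], (0.2, 0.1, 0.1))
        assert (comp, nid) == ("cytoplasmic", None)

    def test_boundary_voxel_is_inclusive(self):
        mask = ball_mask((30, 100, 100), (15, 50, 50), (10, 20, 20))
        nuc = NucleusModel(nucleus_id=2, centroid=(5.0, 5.0, 3.0), radius=2.0, mask=mask)
        # a point inside the outermost mask voxel along +x
        f = make_focus(1, None, (7.04, 5.05, 3.1))
        comp, nid = foci3d.classify_compartment(f, [nuc], (0.2, 0.1, 0.1))
        assert (comp, nid) == ("nuclear", 2)

    def test_radial_position_identities(self):
        f_center = make_focus(1, 1, self.nucleus.centroid)
        d_c, d_e, rho, clamped = foci3d.radial_position(f_center, self.nucleus)
        assert (d_c, d_e, rho, clamped) == (0.0, 2.0, 0.0, False)

        f_edge = make_focus(2, 1, (7.0, 5.0, 3.0))
        d_c, d_e, rho, clamped = foci3d.radial_position(f_edge, self.nucleus)
        assert (d_c, rho) == (2.0, 1.0)
        assert d_e == pytest.approx(0.0, abs=1e-12)

    def test_outside_sphere_clamps_and_flags(self):
        f = make_focus(3, 1, (7.2, 5.0, 3.0))  # 1.1 r
        d_c, d_e, rho, clamped = foci3d.radial_position(f, self.nucleus)
        assert rho == 1.0 and clamped
        assert d_e == pytest.approx(-0.2, abs=1e-12)

    def test_d_center_plus_d_edge_equals_radius(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = np.array(self.nucleus.centroid) + rng.normal(scale=1.0, size=3)
            d_c, d_e, _, _ = foci3d.radial_position(make_focus(9, 1, p), self.nucleus)
            assert d_c + d_e == pytest.approx(self.nucleus.radius, abs=1e-6)


class TestZones:
    @pytest.mark.parametrize("rho,zone", [
        (0.9, 1), (0.7, 2), (0.0, 3),
        (math.sqrt(2 / 3) + 1e-9, 1), (math.sqrt(2 / 3), 2),
        (math.sqrt(1 / 3), 3), (1.0, 1),
    ])
    def test_equal_area_boundaries(self, rho, zone):
        assert foci3d.assign_zone(rho) == zone

    def test_equal_volume_boundaries(self):
        assert foci3d.assign_zone(0.69, "equal_volume") == 3  # (1/3)^(1/3) ~ 0.693
        assert foci3d.assign_zone(0.80, "equal_volume") == 2
        assert foci3d.assign_zone(0.90, "equal_volume") == 1  # (2/3)^(1/3) ~ 0.874

    def test_invalid_rho_rejected(self):
        for rho in (-0.1, 1.1):
            with pytest.raises(ValueError):
                foci3d.assign_zone(rho)

    def test_zone_fractions_uniform_points(self):
        rng = np.random.default_rng(1)
        rho = rng.uniform(size=10_000) ** (1 / 3)
        foci = [make_focus(i, 1, (0, 0, 0)) for i in range(len(rho))]
        from dataclasses import replace
        foci = [replace(f, zone=foci3d.assign_zone(r)) for f, r in zip(foci, rho)]
        frac = foci3d.zone_fractions(foci)
        assert frac[1] == pytest.approx(45.57, abs=2.0)
        assert frac[2] == pytest.approx(35.18, abs=2.0)
        assert frac[3] == pytest.approx(19.25, abs=2.0)
        assert sum(frac.values()) == pytest.approx(100.0, abs=1e-9)

    def test_zone_fraction_degenerate_cases(self):
        from dataclasses import replace
        center = [replace(make_focus(i, 1, (0, 0, 0)), zone=3) for i in range(4)]
        assert foci3d.zone_fractions(center) == {1: 0.0, 2: 0.0, 3: 100.0}
        one = [replace(make_focus(1, 1, (0, 0, 0)), zone=1)]
        assert foci3d.zone_fractions(one) == {1: 100.0, 2: 0.0, 3: 0.0}
        with pytest.raises(ValueError, match="no zoned"):
            foci3d.zone_fractions([])


class TestGroupSummary:
    @staticmethod
    def _nuclei(n):
        return [NucleusModel(nucleus_id=i + 1, centroid=(3.0 * i, 0, 0), radius=1.0)
                for i in range(n)]

    def test_positive_fraction(self):
        nuclei = self._nuclei(10)
        foci = [make_focus(i + 1, i + 1, (3.0 * i, 0, 0)) for i in range(4)]
        df = foci3d.summarize_by_group(nuclei, foci)
        assert df.loc[0, "pct_positive"] == pytest.approx(40.0)
        assert df.loc[0, "n_nuclei"] == 10

    def test_identical_groups_identical_summaries(self):
        nuclei = self._nuclei(4)
        groups = {1: "z1", 2: "z1", 3: "z2", 4: "z2"}
        foci = [make_focus(1, 1, (0, 0, 0)), make_focus(2, 3, (6.0, 0, 0))]
        df = foci3d.summarize_by_group(nuclei, foci, groups).set_index("group")
        a, b = df.loc["z1"], df.loc["z2"]
        assert a["pct_positive"] == b["pct_positive"] == 50.0
        assert a["foci_per_nucleus_mean"] == b["foci_per_nucleus_mean"]

    def test_unknown_nucleus_in_groups_raises(self):
        with pytest.raises(KeyError):
            foci3d.summarize_by_group(self._nuclei(2), [], {5: "z1"})

    def test_truth_roundtrip_counts(self):
        """Counts summarized from a truth-rendered stack match the generator truth."""
        stack, truth_nuclei, truth = sd.generate_nuclei_stack(
            2, shape=(40, 140, 140), foci_per_channel={"terra": {"n": 3, "amplitude": 100.0}},
            seed=4)
        nuclei = foci3d.segment_nuclei(stack)
        foci = foci3d.detect_foci(stack, "terra", nuclei)
        foci = foci3d.measure_foci_in_nuclei(foci, nuclei, stack.voxel_size)
        df = foci3d.summarize_by_group(nuclei, foci)
        assert df.loc[0, "pct_positive"] == 100.0
        assert df.loc[0, "foci_per_nucleus_mean"] == pytest.approx(3.0)
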