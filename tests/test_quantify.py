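"""Quantification tests: assignment, densities, partitions, gradient table."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from immunogold import (
    NoiseModel,
    PointProcessRecord,
    Scene,
    assign_particles,
    background_correct,
    classify_membrane,
    compute_density,
    density_gradient_table,
    detect_particles,
    rasterize,
    split_presynaptic,
)
from immunogold.compartments import CompartmentClass, Klass, Layer
from immunogold.geometry import ProfileGeometry
from immunogold.quantify import density_records_frame
from immunogold.raster import QUIET
from immunogold.simulate import _particles_frame, sample_point_pattern

from conftest import square_profile


def frame(xy):
    return _particles_frame(np.asarray(xy, float), "scattered", "")


def ray_casting_contains(poly_xy, x, y):
    """Independent even-odd ray-casting point-in-polygon oracle."""
    inside = False
    n = len(poly_xy)
    for i in range(n):
        x1, y1 = poly_xy[i]
        x2, y2 = poly_xy[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_int = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_int:
                inside = not inside
    return inside


class TestAssign:
    def test_centroid_assigned(self, unit_square):
        pts = assign_particles(frame([(500.0, 500.0)]), [unit_square])
        assert pts["profile_id"][0] == "sq"

    def test_outside_flagged(self, unit_square):
        pts = assign_particles(frame([(5000.0, 5000.0)]), [unit_square])
        assert pts["profile_id"][0] == "outside"

    def test_overlap_rejected(self):
        a = square_profile(1000.0, "a")
        b = square_profile(1000.0, "b", origin=(500.0, 0.0))
        with pytest.raises(ValueError, match="a and b"):
            assign_particles(frame([(10.0, 10.0)]), [a, b])

    def test_matches_ray_casting_oracle(self, rng):
        from immunogold import radial_polygon

        profiles = [
            ProfileGeometry(
                id=f"p{i}",
                polygon=radial_polygon(0.5, rng, center_nm=(i * 3000.0, 0.0)),
            )
            for i in range(5)
        ]
        pts_xy = np.column_stack(
            [rng.uniform(-2000, 14000, 1000), rng.uniform(-2000, 2000, 1000)]
        )
        assigned = assign_particles(frame(pts_xy), profiles)["profile_id"]
        from shapely.geometry import Point

        for k, (x, y) in enumerate(pts_xy):
            expect = "outside"
            for p in profiles:
                if ray_casting_contains(
                    np.asarray(p.polygon.exterior.coords)[:-1], x, y
                ):
                    expect = p.id
                    break
            # points within the 1 nm boundary-tolerance zone are excluded
            if all(p.polygon.exterior.distance(Point(x, y)) > 1.5 for p in profiles):
                assert assigned[k] == expect


class TestDensity:
    def test_exact_ratio(self):
        prof = square_profile(np.sqrt(0.5) * 1000.0, "h")  # 0.5 um^2
        pts = assign_particles(frame([(100.0 + i, 100.0) for i in range(5)]), [prof])
        rec = compute_density(pts, prof)
        assert rec.density_per_um2 == pytest.approx(10.0)

    def test_zero_particles(self, unit_square):
        rec = compute_density(assign_particles(frame([]), [unit_square]), unit_square)
        assert rec.density_per_um2 == 0.0

    def test_homogeneous_estimator_unbiased_at_reported_intensity(self):
        # planted 42.97 / um^2 pooled over many profiles
        lam = 42.97
        rec = PointProcessRecord(0.0, 6.0, 20.0, lam, 0.0)
        dens = []
        for seed in range(100):
            prof = square_profile(1000.0, "p0")
            pts = sample_point_pattern(prof, rec, np.random.default_rng(seed))
            dens.append(len(pts) / prof.area_um2)
        se = np.std(dens, ddof=1) / np.sqrt(len(dens))
        assert abs(np.mean(dens) - lam) < 3 * se

    def test_pipeline_equality_truth_vs_noiseless_detection(self):
        # densities from truth coordinates equal densities from detections
        # on a noiseless raster
        prof = square_profile(800.0, "p0")
        rec = PointProcessRecord(4.0, 6.0, 20.0, 10.0, 0.0)
        particles = sample_point_pattern(prof, rec, np.random.default_rng(11))
        scene = Scene(profiles=[prof], particles=particles, seed=11)
        img = rasterize(scene, 1.0, QUIET, np.random.default_rng(11))
        det = detect_particles(img, 1.0, origin_nm=scene.raster_origin_nm)
        det_assigned = assign_particles(det, [prof])
        d_truth = compute_density(particles, prof).density_per_um2
        d_det = compute_density(det_assigned, prof).density_per_um2
        assert d_det == pytest.approx(d_truth)


class TestBackground:
    @pytest.mark.parametrize(
        "p,e,expect,flag", [(10, 0, 10, False), (10, 3, 7, False), (2, 5, 0, True)]
    )
    def test_cases(self, p, e, expect, flag):
        corrected, flagged = background_correct(p, e)
        assert corrected == expect
        assert flagged is flag

    def test_corrected_never_exceeds_raw(self, rng):
        for _ in range(100):
            p, e = rng.uniform(0, 100, 2)
            corrected, _ = background_correct(p, e)
            assert 0 <= corrected <= p


class TestPresynapticSplit:
    def make_terminal(self):
        outer = Polygon([(0, 0), (1000, 0), (1000, 1000), (0, 1000)])
        az = Polygon([(0, 0), (500, 0), (500, 1000), (0, 1000)])  # half the area
        return ProfileGeometry(
            id="t",
            polygon=outer,
            compartment=CompartmentClass(Layer.SR_PROX, Klass.AXON_TERMINAL),
            subregions={"active_zone": az},
        )

    def test_all_in_az(self):
        prof = self.make_terminal()
        pts = assign_particles(frame([(100.0, 100.0), (200.0, 800.0)]), [prof])
        part, dens = split_presynaptic(pts, prof)
        assert part.counts == {"az": 2, "extrasynaptic": 0}
        assert dens["extrasynaptic"].density_per_um2 == 0.0

    def test_uniform_pattern_equal_densities(self, rng):
        prof = self.make_terminal()
        n = 4000
        xy = np.column_stack([rng.uniform(0, 1000, n), rng.uniform(0, 1000, n)])
        pts = assign_particles(frame(xy), [prof])
        _, dens = split_presynaptic(pts, prof)
        a, b = dens["az"].density_per_um2, dens["extrasynaptic"].density_per_um2
        assert abs(a - b) / (a + b) < 0.05  # sampling error at n = 4000

    def test_counts_conserved(self, rng):
        prof = self.make_terminal()
        xy = np.column_stack([rng.uniform(0, 1000, 500), rng.uniform(0, 1000, 500)])
        pts = assign_particles(frame(xy), [prof])
        part, _ = split_presynaptic(pts, prof)
        assert part.total == 500


class TestMembrane:
    def test_particle_on_contour_is_membrane(self, unit_square):
        pts = assign_particles(frame([(0.0, 500.0)]), [unit_square])
        part, _ = classify_membrane(pts, unit_square, 25.0)
        assert part.counts["membrane"] == 1

    def test_infinite_threshold_all_membrane(self, unit_square, rng):
        xy = np.column_stack([rng.uniform(0, 1000, 200), rng.uniform(0, 1000, 200)])
        pts = assign_particles(frame(xy), [unit_square])
        part, _ = classify_membrane(pts, unit_square, 1e9)
        assert part.percentages["membrane"] == 100.0

    def test_monotone_in_threshold(self, unit_square, rng):
        xy = np.column_stack([rng.uniform(0, 1000, 300), rng.uniform(0, 1000, 300)])
        pts = assign_particles(frame(xy), [unit_square])
        counts = [
            classify_membrane(pts, unit_square, d)[0].counts["membrane"]
            for d in (5.0, 25.0, 100.0, 400.0)
        ]
        assert counts == sorted(counts)

    def test_recovers_generating_percentage(self, cal):
        # 1-month APP/PS1 sr: generating membrane fraction 65.52%
        from immunogold.pipeline import recover_membrane_fraction

        r = recover_membrane_fraction(cal, "APP_PS1", 1, "sr", 12, min_particles=2000)
        assert r["n_particles"] >= 2000
        assert abs(r["membrane_pct"] - 65.52) < 3.0


class TestGradientTable:
    def make_records(self, rows):
        return pd.DataFrame(
            rows, columns=["genotype", "compartment", "animal_id", "density_per_um2"]
        )

    def test_single_animal_sem_flagged(self):
        rec = self.make_records(
            [("WT", "slm/spine", "a1", d) for d in (10.0, 20.0, 30.0)]
        )
        table = density_gradient_table(rec)
        assert table["mean_density_per_um2"][0] == pytest.approx(20.0)
        assert not table["sem_defined"][0]
        assert np.isnan(table["sem"][0])

    def test_textbook_sem_across_animals(self):
        rec = self.make_records(
            [
                ("WT", "slm/spine", a, d)
                for a, d in (("a1", 10.0), ("a2", 20.0), ("a3", 30.0))
            ]
        )
        table = density_gradient_table(rec)
        assert table["mean_density_per_um2"][0] == pytest.approx(20.0)
        assert table["sem"][0] == pytest.approx(5.7735, abs=1e-3)

    def test_ordering_follows_gradient_layout(self):
        rows = []
        for comp in ("slm/spine", "sp/soma", "sr_prox/oblique_dendrite"):
            for a in ("a1", "a2"):
                rows.append(("WT", comp, a, 10.0))
        table = density_gradient_table(self.make_records(rows))
        assert list(table["compartment"]) == [
            "sp/soma",
            "sr_prox/oblique_dendrite",
            "slm/spine",
        ]

    def test_six_month_dataset_differs_only_in_slm(self, cal):
        # genotype difference confined to slm oblique dendrites and spines
        from immunogold.groupstats import bonferroni_pairwise
        from immunogold.pipeline import gradient_dataset

        records = gradient_dataset(cal, 6, 5)
        pw = bonferroni_pairwise(records, m=11)
        sig = set(pw.loc[pw["p_adj"] < 0.05, "compartment"])
        assert sig == {"slm/oblique_dendrite", "slm/spine"}


def test_density_records_frame_roundtrip(unit_square):
    pts = assign_particles(frame([(500.0, 500.0)] * 3), [unit_square])
    rec = compute_density(pts, unit_square, condition={"genotype": "WT"})
    df = density_records_frame([rec])
    assert df.loc[0, "n_particles"] == 3
    assert df.loc[0, "genotype"] == "WT"
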