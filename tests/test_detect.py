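import math

import numpy as np
import pandas as pd
import pytest
from scipy import integrate

from sbrd.detect import (
    BilliardDetector,
    CellFit,
    apply_shape_filters,
    background_filter,
    detect_cells,
    initial_guess,
    refine_mle,
    refine_mle_dividing,
)
from sbrd.geometry import Billiard, RegionLabel, Spherocylinder


def thickness_weighted_cloud(billiard, n, rng):
    """Project uniform-in-3D samples: 2D density proportional to thickness."""
    sc = Spherocylinder(billiard)
    return billiard.to_lab(sc.sample_uniform(n, rng)[:, :2])


class TestBackgroundFilter:
    def test_empty_input(self):
        assert background_filter(np.empty((0, 2))) == []

    def test_uniform_noise_yields_no_cell_sized_clouds_at_3_sigma(self):
        # Poisson-uniform noise: only scattered single bins clear median + 3 SD
        # (upper-tail mass of Poisson at +3 sigma is ~1e-3 per bin), and none
        # of the resulting clouds approaches the size of a cell
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 10, (20000, 2))
        clouds = background_filter(pts, n_sigma=3.0)
        assert len(clouds) < 0.01 * 100 * 100  # far fewer than 1% of bins
        assert all(len(c.points) < 30 for c in clouds)

    def test_single_cell_with_sparse_noise(self):
        rng = np.random.default_rng(1)
        b = Billiard.from_center((5, 5), 2.2, 0.45, 0.4)
        cell_pts = thickness_weighted_cloud(b, 6000, rng)
        noise = rng.uniform(0, 10, (1500, 2))
        clouds = background_filter(np.vstack([cell_pts, noise]))
        assert len(clouds) == 1
        # at least 95% of the cell's points end up in the cloud
        assert len(clouds[0].points) >= 0.95 * len(cell_pts)

    def test_dataframe_input(self):
        rng = np.random.default_rng(2)
        b = Billiard.from_center((3, 3), 2.0, 0.4, 0.0)
        pts = np.vstack([thickness_weighted_cloud(b, 4000, rng), rng.uniform(0, 6, (600, 2))])
        df = pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1], "frame": 0, "movie": 0})
        assert len(background_filter(df)) == 1


class TestInitialGuess:
    def test_angle_recovery_30_degrees(self):
        rng = np.random.default_rng(3)
        b = Billiard.from_center((1, 2), 2.4, 0.42, math.radians(30))
        g = initial_guess(thickness_weighted_cloud(b, 2000, rng))
        assert math.degrees(g.angle) == pytest.approx(30, abs=3)

    def test_axis_aligned_symmetric_cloud(self):
        rng = np.random.default_rng(4)
        b = Billiard.from_center((0, 0), 2.2, 0.45, 0.0)
        g = initial_guess(thickness_weighted_cloud(b, 4000, rng))
        assert abs(g.angle) < math.radians(3)
        np.testing.assert_allclose(g.center_lab, [0, 0], atol=0.05)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 50), np.zeros(50)])
        with pytest.raises(ValueError):
            initial_guess(pts)


class TestRefineMLE:
    def test_mixture_density_normalized(self, std_billiard):
        # the signal half of the per-point probability, h/V, integrates to 1
        sc = Spherocylinder(std_billiard)
        b = std_billiard
        val, _ = integrate.dblquad(
            lambda y, x: sc.thickness([[x, y]])[0] / sc.volume(),
            b.cx_left - b.radius,
            b.cx_right + b.radius,
            b.cy - b.radius,
            b.cy + b.radius,
            epsabs=1e-6,
        )
        assert val == pytest.approx(1.0, abs=1e-4)

    def test_parameter_recovery_5000_points(self):
        rng = np.random.default_rng(5)
        true = Billiard.from_center((3.0, 4.0), 2.4, 0.42, math.radians(25))
        fit = refine_mle(thickness_weighted_cloud(true, 5000, rng))
        fb = fit.billiard
        assert fb.length == pytest.approx(true.length, rel=0.05)
        assert fb.radius == pytest.approx(true.radius, rel=0.05)
        assert math.degrees(abs(fb.angle - true.angle)) < 3

    def test_loglik_at_fit_not_below_guess(self):
        rng = np.random.default_rng(6)
        true = Billiard.from_center((0, 0), 2.0, 0.4, 0.3)
        pts = thickness_weighted_cloud(true, 3000, rng)
        guess = initial_guess(pts)
        from sbrd.detect import _nll_single, _params_of

        fit = refine_mle(pts, guess)
        assert fit.loglik >= -_nll_single(_params_of(guess), pts) - 1e-6

    def test_noise_only_cloud_bounded(self):
        # pure noise: likelihood flattens to the (1/2N) floor; the optimizer
        # must stay within bounds and return a finite fit
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 8, (500, 2))
        fit = refine_mle(pts)
        assert np.isfinite(fit.loglik)
        assert 0.3 <= fit.billiard.length <= 6.0


class TestDividing:
    def make_pair(self, rng, daughter_length=1.8, overlap=0.3, angle=0.0):
        off = daughter_length / 2 - overlap / 2
        axis = np.array([math.cos(angle), math.sin(angle)])
        c = np.array([5.0, 5.0])
        b1 = Billiard.from_center(c - off * axis, daughter_length, 0.45, angle)
        b2 = Billiard.from_center(c + off * axis, daughter_length, 0.45, angle)
        pts = np.vstack(
            [thickness_weighted_cloud(b1, 4000, rng), thickness_weighted_cloud(b2, 4000, rng)]
        )
        return b1, b2, pts

    def test_pair_recovery(self):
        rng = np.random.default_rng(8)
        b1, b2, pts = self.make_pair(rng)
        guess1 = Billiard.from_center(b1.center_lab + [0.05, -0.03], 1.7, 0.4, 0.05)
        guess2 = Billiard.from_center(b2.center_lab + [-0.04, 0.02], 1.7, 0.4, -0.05)
        f1, f2 = refine_mle_dividing(pts, guess1, guess2)
        assert f1.billiard.length == pytest.approx(b1.length, rel=0.07)
        assert f2.billiard.length == pytest.approx(b2.length, rel=0.07)
        # septum line within 50 nm of the true mid-plane at x = 5.0
        from sbrd.geometry import intersect_dividing

        inter = intersect_dividing(f1.billiard, f2.billiard)
        assert abs(inter.septum_point[0] - 5.0) < 0.05

    def test_new_poles_face_each_other(self):
        rng = np.random.default_rng(9)
        b1, b2, pts = self.make_pair(rng)
        f1, f2 = refine_mle_dividing(pts, b1, b2)
        assert f1.divided and f2.divided
        # left daughter's new pole is its right cap and vice versa
        assert f1.new_pole_side is RegionLabel.POLE_RIGHT
        assert f2.new_pole_side is RegionLabel.POLE_LEFT

    def test_short_pair_flagged(self):
        rng = np.random.default_rng(10)
        b1, b2, pts = self.make_pair(rng, daughter_length=1.3, overlap=0.25)
        f1, f2 = refine_mle_dividing(pts, b1, b2)
        if f1.billiard.length + f2.billiard.length < 3.0:
            assert "manual_reject" in f1.qc_flags

    def test_separated_cells_reduce_to_independent_terms(self):
        # V_int = 0: the joint density equals two independent single-cell
        # densities over the union (compare likelihood values directly)
        from sbrd.detect import _nll_pair, _params_of
        from sbrd.geometry import Spherocylinder as SC

        rng = np.random.default_rng(11)
        b1 = Billiard.from_center((0, 0), 1.8, 0.45, 0.0)
        b2 = Billiard.from_center((4.0, 0), 1.8, 0.45, 0.0)
        pts = np.vstack(
            [thickness_weighted_cloud(b1, 500, rng), thickness_weighted_cloud(b2, 500, rng)]
        )
        p = np.concatenate([_params_of(b1), _params_of(b2)])
        nll = _nll_pair(p, pts)
        h = SC(b1).thickness(b1.to_frame(pts)) + SC(b2).thickness(b2.to_frame(pts))
        v = SC(b1).volume() + SC(b2).volume()
        expect = -np.sum(np.log((h / v + 1 / len(pts)) / 2))
        assert nll == pytest.approx(expect, rel=1e-12)


class TestShapeFilters:
    @pytest.mark.parametrize(
        "length, radius, flag",
        [
            (0.5, 0.2, "too_short"),
            (2.0, 0.8, "too_wide"),
            (3.2, 0.45, "split_candidate"),
        ],
    )
    def test_worked_examples(self, length, radius, flag):
        fit = CellFit(Billiard.from_center((0, 0), length, radius, 0.0), 0.0, 100)
        assert flag in apply_shape_filters(fit).qc_flags

    def test_interior_cell_passes(self):
        fit = CellFit(Billiard.from_center((0, 0), 2.2, 0.45, 0.0), 0.0, 100)
        assert apply_shape_filters(fit).passed_qc


class TestDetectCells:
    def test_long_cloud_split_into_divided_pair(self):
        rng = np.random.default_rng(12)
        off = 0.75
        b1 = Billiard.from_center((5 - off, 5.0), 1.8, 0.45, 0.0)
        b2 = Billiard.from_center((5 + off, 5.0), 1.8, 0.45, 0.0)
        pts = np.vstack(
            [
                thickness_weighted_cloud(b1, 5000, rng),
                thickness_weighted_cloud(b2, 5000, rng),
                rng.uniform(0, 10, (1000, 2)),
            ]
        )
        cells = detect_cells(pts)
        divided = [c for c in cells if c.divided]
        assert len(divided) == 2
        assert divided[0].sibling == divided[1].cell_id

    def test_touching_pair_separated_where_naive_clustering_merges(self):
        # two abutting cells form one connected cloud (a nearest-neighbour /
        # connected-component clustering would merge them); the billiard MLE
        # splits them via the over-length rule
        rng = np.random.default_rng(13)
        b1 = Billiard.from_center((4.1, 5.0), 1.9, 0.45, 0.0)
        b2 = Billiard.from_center((5.95, 5.0), 1.9, 0.45, 0.0)
        pts = np.vstack(
            [
                thickness_weighted_cloud(b1, 5000, rng),
                thickness_weighted_cloud(b2, 5000, rng),
                rng.uniform(0, 10, (800, 2)),
            ]
        )
        clouds = background_filter(pts)
        assert len(clouds) == 1  # naive connectivity sees a single object
        cells = [c for c in detect_cells(pts) if c.passed_qc]
        assert len(cells) == 2

    def test_detector_estimator_interface(self):
        rng = np.random.default_rng(14)
        b = Billiard.from_center((3, 3), 2.2, 0.45, 0.7)
        pts = np.vstack([thickness_weighted_cloud(b, 5000, rng), rng.uniform(0, 6, (500, 2))])
        det = BilliardDetector().fit(pts)
        assert det.n_cells_ == 1
        labels = det.predict(pts[:5000])
        assert (labels == 0).mean() > 0.95

    def test_cellfit_roundtrip(self):
        fit = CellFit(Billiard.from_center((1, 1), 2.0, 0.4, 0.1), -12.5, 321, {"too_short"})
        again = CellFit.from_dict(fit.to_dict())
        assert again.billiard == fit.billiard
        assert again.qc_flags == {"too_short"}
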