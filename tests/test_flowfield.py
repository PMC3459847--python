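"""Flow-field geometry: image sums, the closed-form oracle, advection."""

import numpy as np
import pytest

from omgrowth.flowfield import (
    AreaConservationError,
    CylinderGeom,
    FlowSource,
    InvalidPolygonError,
    Patch,
    SingularDistanceError,
    advect,
    closed_form_velocity,
    mean_axial_velocity,
    polygon_area,
    regular_polygon,
    unwrap_ring,
    velocity_field,
)
from omgrowth.kinetics import KineticParams
from omgrowth.simulator import init_state

from conftest import make_source


def brute_force_periodic_velocity(point, source, geom, K=10_000):
    """Independent oracle: huge symmetric image sum with its analytic
    integral remainder (the naive sum converges only like 1/K)."""
    Q = source.strength
    P = geom.P
    dx = point[0] - source.position[0]
    dy = point[1] - source.position[1]
    k = np.arange(-K, K + 1) * P
    ddy = dy - k
    r2 = dx**2 + ddy**2
    vx = Q / (2 * np.pi) * np.sum(dx / r2)
    vy = Q / (2 * np.pi) * np.sum(ddy / r2)
    U = (K + 0.5) * P
    if dx != 0:
        vx += (
            Q
            / (2 * np.pi * P)
            * (
                (np.pi / 2 - np.arctan((U - dy) / abs(dx)))
                + (np.pi / 2 - np.arctan((U + dy) / abs(dx)))
            )
            * np.sign(dx)
        )
    vy += Q / (4 * np.pi * P) * np.log((dx**2 + (U - dy) ** 2) / (dx**2 + (U + dy) ** 2))
    return np.array([vx, vy])


class TestClosedForm:
    def test_matches_brute_force_image_sum(self, geom):
        rng = np.random.default_rng(42)
        src = make_source(0.37, 1.1, Q=0.00064)
        for _ in range(25):
            pt = np.array(
                [rng.uniform(-3 * geom.P, 3 * geom.P), rng.uniform(0, geom.P)]
            )
            ve = closed_form_velocity(pt, [src], geom)
            vb = brute_force_periodic_velocity(pt, src, geom)
            assert np.linalg.norm(ve - vb) / np.linalg.norm(ve) < 1e-10

    def test_far_field_uniform_axial_outflow(self, geom):
        src = make_source(0.0, 1.0, Q=0.01)
        v = closed_form_velocity(np.array([50.0, 0.3]), [src], geom)
        assert v[0] == pytest.approx(0.01 / (2 * geom.P), rel=1e-12)
        assert v[1] == pytest.approx(0.0, abs=1e-15)

    def test_symmetry_point_opposite_source(self, geom):
        src = make_source(0.0, 0.0, Q=0.01)
        v = closed_form_velocity(np.array([0.0, geom.P / 2]), [src], geom)
        assert np.allclose(v, 0.0, atol=1e-15)


class TestVelocityField:
    def test_near_field_matches_free_space_monopole(self, geom):
        # close to the source the periodic images contribute little
        src = make_source(0.0, 1.0, Q=0.00064)
        d = 0.05
        v = velocity_field(np.array([d, 1.0]), [src], geom, n_images=21)
        free = 0.00064 / (2 * np.pi * d)
        assert np.linalg.norm(v) == pytest.approx(free, rel=3e-3)
        assert free == pytest.approx(2.04e-3, rel=2e-2)

    def test_axial_velocity_vanishes_opposite_source(self, geom):
        src = make_source(0.0, 0.0, Q=0.02)
        v = velocity_field(np.array([0.0, geom.P / 2]), [src], geom)
        assert v[0] == pytest.approx(0.0, abs=1e-12)

    def test_far_field_limit(self, geom):
        src = make_source(0.0, 1.0, Q=0.02)
        v = velocity_field(np.array([30.0, 2.0]), [src], geom)
        assert v[0] == pytest.approx(0.02 / (2 * geom.P), rel=1e-4)

    def test_superposition_is_exact(self, geom):
        rng = np.random.default_rng(1)
        sources = [
            make_source(rng.uniform(-1, 1), rng.uniform(0, geom.P), Q=q, source_id=i)
            for i, q in enumerate((0.001, 0.003, 0.0007))
        ]
        pts = np.column_stack([rng.uniform(-2, 2, 40), rng.uniform(0, geom.P, 40)])
        total = velocity_field(pts, sources, geom)
        parts = sum(velocity_field(pts, [s], geom) for s in sources)
        assert np.allclose(total, parts, rtol=0, atol=1e-18)

    def test_agrees_with_closed_form_across_strip(self, geom):
        """21 image terms (with analytic remainder) vs the exact periodic sum."""
        rng = np.random.default_rng(7)
        src = make_source(0.3, 1.2, Q=0.00064)
        pts = np.column_stack(
            [rng.uniform(-5 * geom.P, 5 * geom.P, 3000), rng.uniform(0, geom.P, 3000)]
        )
        v21 = velocity_field(pts, [src], geom, n_images=21)
        vex = closed_form_velocity(pts, [src], geom)
        rel = np.linalg.norm(v21 - vex, axis=1) / np.linalg.norm(vex, axis=1)
        assert rel.max() < 1e-3

    def test_naive_truncation_converges_with_more_images(self, geom):
        src = make_source(0.0, 1.0, Q=0.01)
        pt = np.array([geom.P, 1.4])
        vex = closed_form_velocity(pt, [src], geom)
        errs = [
            np.linalg.norm(
                velocity_field(pt, [src], geom, n_images=n, tail_correction=False) - vex
            )
            for n in (21, 201, 2001)
        ]
        assert errs[0] > errs[1] > errs[2]

    def test_invalid_image_count_rejected(self, geom):
        src = make_source(0.0, 1.0, Q=0.01)
        with pytest.raises(ValueError):
            velocity_field(np.array([1.0, 1.0]), [src], geom, n_images=20)
        with pytest.raises(ValueError):
            velocity_field(np.array([1.0, 1.0]), [src], geom, n_images=-3)

    def test_singular_distance_guard(self, geom):
        src = make_source(0.0, 1.0, Q=0.01)
        with pytest.raises(SingularDistanceError):
            velocity_field(np.array([0.0, 1.0 + 1e-6]), [src], geom)


class TestPolygonArea:
    def test_unit_square(self, geom):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert polygon_area(sq, geom) == pytest.approx(1.0)

    def test_periodicity_invariance(self, geom):
        sq = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert polygon_area(sq + [0, geom.P], geom) == pytest.approx(1.0)

    def test_regular_hexagon_closed_form(self, geom):
        r = 0.2
        hexagon = r * np.array(
            [[np.cos(a), np.sin(a)] for a in np.linspace(0, 2 * np.pi, 7)[:-1]]
        )
        assert polygon_area(hexagon, geom) == pytest.approx(3 * np.sqrt(3) / 2 * r**2)

    def test_ring_straddling_seam_is_unwrapped(self, geom):
        # square crossing y = 0 with wrapped coordinates
        sq = np.array([[0, geom.P - 0.1], [0.2, geom.P - 0.1], [0.2, 0.1], [0, 0.1]])
        assert polygon_area(sq, geom) == pytest.approx(0.04)

    def test_self_intersection_detected(self, geom):
        bow = np.array([[0, 0], [1, 1], [1, 0], [0, 1]], dtype=float)
        with pytest.raises(InvalidPolygonError):
            polygon_area(bow, geom, check=True)

    def test_regular_polygon_constructor_area(self):
        v = regular_polygon(np.array([0.3, 0.4]), 0.05, 17)
        assert polygon_area(v) == pytest.approx(0.05)

    def test_unwrap_ring_makes_y_continuous(self, geom):
        sq = np.array([[0, geom.P - 0.1], [0.2, geom.P - 0.1], [0.2, 0.1], [0, 0.1]])
        u = unwrap_ring(sq, geom.P)
        assert np.abs(np.diff(u[:, 1])).max() < geom.P / 2


class TestAdvect:
    def test_no_sources_is_identity(self, headline_params):
        st = init_state(None, headline_params, 0)
        st.patches.append(
            Patch(vertices=regular_polygon(np.array([0.2, 1.0]), 0.01, 8))
        )
        before = st.patches[0].vertices.copy()
        advect(st, 0.5)
        assert np.array_equal(st.patches[0].vertices, before)

    @pytest.mark.parametrize("dt,tol", [(0.5, 2e-3), (0.1, 5e-4)])
    def test_passive_polygon_area_conserved(self, headline_params, dt, tol):
        """Incompressibility: a far-away passive patch keeps its area over
        100 steps, improving under dt refinement."""
        st = init_state(CylinderGeom(0.5, -3, 3), headline_params, 0)
        st.sources = [make_source(0.0, 1.0, Q=0.01)]
        st.patches = [
            Patch(vertices=regular_polygon(np.array([1.5, 0.5]), 0.01, 16), source_id=99)
        ]
        a0 = st.patches[0].area()
        for _ in range(100):
            advect(st, dt)
        assert abs(st.patches[0].area() - a0) / a0 < tol

    def test_area_tolerance_violation_raises(self, headline_params):
        st = init_state(CylinderGeom(0.5, -3, 3), headline_params, 0)
        st.sources = [make_source(0.0, 1.0, Q=0.05)]
        st.patches = [
            Patch(vertices=regular_polygon(np.array([0.15, 1.0]), 0.02, 4), source_id=99)
        ]
        with pytest.raises(AreaConservationError):
            for _ in range(200):
                advect(st, 2.0, area_tolerance=1e-6)

    def test_flux_conservation_grows_domain(self, headline_params):
        """An active source of flux Q elongates the domain at rate Q/P."""
        st = init_state(None, headline_params, 0)
        Q = 0.01
        st.sources = [make_source(0.0, 1.0, Q=Q)]
        L0 = st.geom.length
        T = 50.0
        for _ in range(100):
            advect(st, T / 100)
        assert st.geom.length - L0 == pytest.approx(Q * T / st.geom.P, rel=1e-9)

    def test_mean_axial_velocity_sign_and_magnitude(self, geom):
        src = make_source(0.0, 1.0, Q=0.01)
        assert mean_axial_velocity(5.0, [src], geom) == pytest.approx(
            0.01 / (2 * geom.P)
        )
        assert mean_axial_velocity(-5.0, [src], geom) == pytest.approx(
            -0.01 / (2 * geom.P)
        )


class TestTypes:
    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            CylinderGeom(-0.5, 0, 1)
        with pytest.raises(ValueError):
            CylinderGeom(0.5, 1.0, 1.0)

    def test_source_validation(self):
        with pytest.raises(ValueError):
            FlowSource(position=np.zeros(2), strength=-1.0, t_start=0, duration=10)
        with pytest.raises(ValueError):
            FlowSource(position=np.zeros(2), strength=1.0, t_start=0, duration=0.0)

    def test_patch_needs_three_vertices(self):
        with pytest.raises(InvalidPolygonError):
            Patch(vertices=np.array([[0, 0], [1, 1]]))
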