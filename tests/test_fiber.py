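"""Coarse-grained fiber assembly, dimensions, persistence and WLC metrics."""

import numpy as np
import pytest

from nucarray.errors import InvalidArgumentError, TooShortError
from nucarray.fiber import (
    CoarseNcpUnit,
    RH_OVER_RG,
    UNIT_RADIUS_A,
    build_fiber,
    fiber_dimensions,
    persistence_length,
    sample_unit,
    wlc_metrics,
    _smoothed_centerline,
)
from nucarray.synthetic import CLASH_DISTANCE_A, load_preset

from tests.conftest import fixed_params


def collinear_unit(half_span_A=100.0):
    """Test-only unit whose entry/exit arms run through the center along +x,
    so chained placement degenerates to pure translation (a straight fiber)."""
    v = np.array([1.0, 0.0, 0.0])
    return CoarseNcpUnit(
        entry_k=0, exit_k=146,
        entry_vec=-v, exit_vec=v,
        alpha_entry=0, alpha_exit=0, beta_entry=0, beta_exit=0,
        delta_entry=0, delta_exit=0,
    )


class StraightUnit(CoarseNcpUnit):
    @property
    def entry_origin(self):
        return np.array([-100.0, 0.0, 0.0])

    @property
    def exit_origin(self):
        return np.array([100.0, 0.0, 0.0])


def straight_unit():
    v = np.array([1.0, 0.0, 0.0])
    return StraightUnit(
        entry_k=0, exit_k=146, entry_vec=-v, exit_vec=v,
        alpha_entry=0, alpha_exit=0, beta_entry=0, beta_exit=0,
        delta_entry=0, delta_exit=0,
    )


class TestSampleUnit:
    def test_zero_variance_arms_along_tangents(self):
        params = fixed_params(alpha=0.0, beta=0.0)
        rng = np.random.default_rng(0)
        u = sample_unit(params, rng)
        from nucarray import superhelix as sh

        t_exit = sh.inplane_tangent(u.exit_origin, np.array([0.0, 0, 1]), np.zeros(3), True)
        assert np.allclose(u.exit_vec, t_exit, atol=1e-6)
        t_entry = sh.inplane_tangent(u.entry_origin, np.array([0.0, 0, 1]), np.zeros(3), False)
        assert np.allclose(u.entry_vec, t_entry, atol=1e-6)

    def test_same_seed_identical(self):
        params = load_preset("tetra_5mM")
        u1 = sample_unit(params, np.random.default_rng(42))
        u2 = sample_unit(params, np.random.default_rng(42))
        assert u1.alpha_entry == u2.alpha_entry
        assert np.array_equal(u1.exit_vec, u2.exit_vec)
        assert u1.delta_exit == u2.delta_exit

    def test_sampled_angles_match_generating_distribution(self):
        """KS self-consistency of 1000 sampled units against the preset."""
        from scipy.stats import kstest

        params = load_preset("tetra_50mM")
        rng = np.random.default_rng(7)
        units = [sample_unit(params, rng) for _ in range(1000)]
        alphas = np.array([u.alpha_exit for u in units])
        res = kstest(alphas, params.alpha_exit.cdf)
        assert res.pvalue > 0.01

    def test_no_unwrap_fixes_origins(self):
        params = load_preset("tetra_5mM")
        rng = np.random.default_rng(1)
        units = [sample_unit(params, rng, sample_unwrap=False) for _ in range(5)]
        assert len({u.delta_entry for u in units}) == 1
        assert units[0].delta_entry == round(params.delta_entry.mean_bp)


class TestBuildFiber:
    def test_collinear_units_make_straight_fiber(self):
        f = build_fiber(None, n_ncp=50, rng_seed=0, unit_source=lambda rng: straight_unit())
        c = f.centers
        spacing = np.linalg.norm(c[1] - c[0])
        end_to_end = np.linalg.norm(c[-1] - c[0])
        assert end_to_end == pytest.approx(49 * spacing, rel=1e-6)

    def test_clash_freedom(self):
        f = build_fiber(load_preset("tetra_50mM"), n_ncp=40, rng_seed=3)
        c = f.centers
        d = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
        iu = np.triu_indices(len(c), 1)
        assert d[iu].min() >= CLASH_DISTANCE_A

    def test_seeded_determinism_and_seed_sensitivity(self):
        p = load_preset("tetra_5mM")
        f1 = build_fiber(p, n_ncp=20, rng_seed=5)
        f2 = build_fiber(p, n_ncp=20, rng_seed=5)
        f3 = build_fiber(p, n_ncp=20, rng_seed=6)
        assert np.array_equal(f1.centers, f2.centers)
        assert not np.array_equal(f1.centers, f3.centers)

    def test_too_few_units_rejected(self):
        with pytest.raises(InvalidArgumentError):
            build_fiber(load_preset("tetra_5mM"), n_ncp=1, rng_seed=0)


class TestFiberDimensions:
    def test_straight_fiber_analytic(self):
        f = build_fiber(None, n_ncp=100, rng_seed=0, unit_source=lambda rng: straight_unit())
        spacing_nm = np.linalg.norm(f.centers[1] - f.centers[0]) / 10.0
        L, W = fiber_dimensions(f)
        assert L == pytest.approx(99 * spacing_nm, rel=0.01)
        assert W == pytest.approx(2 * UNIT_RADIUS_A / 10.0, abs=0.01)

    def test_single_unit_too_short(self):
        f = build_fiber(None, n_ncp=4, rng_seed=0, unit_source=lambda rng: straight_unit())
        with pytest.raises(TooShortError):
            fiber_dimensions(f)


class TestPersistenceLength:
    def test_straight_line_reports_cap(self):
        line = np.outer(np.arange(100), [15.0, 0, 0])
        assert persistence_length(line) == 1e5

    def test_two_point_centerline_too_short(self):
        with pytest.raises(TooShortError):
            persistence_length(np.array([[0.0, 0, 0], [15.0, 0, 0]]))

    def test_known_persistence_recovered_within_15_percent(self):
        """Discrete worm-like chains, P_true = 50 nm, d = 15 nm, 100 chains of
        1500 nm contour: two transverse Gaussian tilts of variance d/P per
        segment give tangent correlation exp(-s/P)."""
        d, p_true, n_seg, n_chains = 15.0, 50.0, 100, 100
        chains = []
        rng = np.random.default_rng(123)
        for _ in range(n_chains):
            t = np.array([0.0, 0.0, 1.0])
            pts = [np.zeros(3)]
            for _ in range(n_seg):
                # rotate the tangent by small random tilts about two axes
                # perpendicular to it
                a = np.cross(t, [1.0, 0, 0])
                if np.linalg.norm(a) < 1e-6:
                    a = np.cross(t, [0, 1.0, 0])
                a /= np.linalg.norm(a)
                b = np.cross(t, a)
                th1, th2 = rng.normal(0.0, np.sqrt(d / p_true), 2)
                # exact rotations: <t_new . t_old> = <cos th1><cos th2>
                # = exp(-d/2P)^2 = exp(-d/P)
                from scipy.spatial.transform import Rotation as Rot

                t = Rot.from_rotvec(th2 * b).apply(Rot.from_rotvec(th1 * a).apply(t))
                t /= np.linalg.norm(t)
                pts.append(pts[-1] + d * t)
            chains.append(np.array(pts))
        p_hat = persistence_length(chains, d_nm=d)
        assert p_hat == pytest.approx(p_true, rel=0.15)


class TestWlcMetrics:
    def test_flexible_chain_limit(self):
        """L = 1000 P: R_g^2 approaches the ideal-coil value P L / 3."""
        m = wlc_metrics(P_nm=1.0, contour_L_nm=1000.0, n_ncp=100)
        assert m.gyration_radius_nm**2 == pytest.approx(1000.0 / 3.0, rel=0.01)

    def test_direct_evaluation(self):
        m = wlc_metrics(P_nm=50.0, contour_L_nm=50.0, n_ncp=10)
        assert m.gyration_radius_nm == pytest.approx(17.51, abs=0.01)

    def test_hydrodynamic_ratio_exact(self):
        for P, L in ((1.0, 10.0), (50.0, 50.0), (200.0, 1500.0)):
            m = wlc_metrics(P, L, 100)
            assert m.hydrodynamic_radius_nm / m.gyration_radius_nm == RH_OVER_RG

    def test_density_formula(self):
        m = wlc_metrics(50.0, 1500.0, 100)
        vol = 4.0 / 3.0 * np.pi * m.gyration_radius_nm**3
        assert m.density_per_nm3 == pytest.approx(100 / vol)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidArgumentError):
            wlc_metrics(-1.0, 10.0, 5)


PRESET_PAIR = ("tetra_5mM", "tetra_50mM")  # (low salt, high salt)


@pytest.fixture(scope="module")
def preset_pair():
    return PRESET_PAIR


@pytest.fixture(scope="module")
def ensembles(preset_pair):
    out = {}
    for name in preset_pair:
        p = load_preset(name)
        metrics = []
        for s in range(20):
            f = build_fiber(p, n_ncp=100, rng_seed=4000 + s)
            L, W = fiber_dimensions(f)
            P = persistence_length(_smoothed_centerline(f.centers / 10.0))
            metrics.append(wlc_metrics(P, L, f.n_ncp, W))
        out[name] = metrics
    return out


class TestSaltResponse:
    """Directional claims: raising ionic strength compacts the fibers."""

    def test_high_salt_fibers_shorter(self, ensembles, preset_pair):
        low, high = preset_pair
        assert np.mean([m.contour_length_nm for m in ensembles[high]]) < np.mean(
            [m.contour_length_nm for m in ensembles[low]]
        )

    def test_high_salt_fibers_narrower(self, ensembles, preset_pair):
        low, high = preset_pair
        assert np.mean([m.width_nm for m in ensembles[high]]) < np.mean(
            [m.width_nm for m in ensembles[low]]
        )

    def test_high_salt_fibers_denser(self, ensembles, preset_pair):
        low, high = preset_pair
        assert np.mean([m.density_uM for m in ensembles[high]]) > np.mean(
            [m.density_uM for m in ensembles[low]]
        )

    def test_unwrap_sampling_materially_changes_ensemble(self, preset_pair):
        """Freezing breathing at the distribution means changes the fiber
        ensemble: lengths shift (here: frozen ensembles come out shorter,
        since sampled breathing adds linker-length variance whose extended
        tail survives clash rejection — see the methods note for why the
        direction is model-dependent) and the frozen ensemble loses its
        between-fiber linker variability."""
        low, _ = preset_pair
        p = load_preset(low)
        lengths = {}
        for unwrap in (True, False):
            Ls = []
            for s in range(10):
                f = build_fiber(p, n_ncp=60, rng_seed=7000 + s, sample_unwrap=unwrap)
                Ls.append(fiber_dimensions(f)[0])
            lengths[unwrap] = np.asarray(Ls)
        # distributions are materially different in mean
        pooled_sd = np.sqrt((lengths[True].var() + lengths[False].var()) / 2)
        assert abs(lengths[True].mean() - lengths[False].mean()) > 0.5 * pooled_sd
        # frozen units share one delta pair -> every unit's wrap is identical
        f = build_fiber(p, n_ncp=10, rng_seed=1, sample_unwrap=False)
        assert len({(u.delta_entry, u.delta_exit) for u in f.units}) == 1
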