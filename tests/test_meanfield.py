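"""Mean-field tests: the overlap dynamics against an independently coded
zero-load oracle, Jacobian and Sherman-Morrison closed forms against
numerical differentiation/inversion, the Heaviside and zero-sparsity
limits, background self-consistency, and the bifurcation machinery."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.special import expit

from engrams import meanfield as mfm

FIG1 = dict(gamma=0.002, b_hat=100.0, h0_hat=0.25)


def _mf(C=0.0, **kw):
    base = dict(FIG1)
    base.update(kw)
    return mfm.MeanField(mfm.MeanFieldParams(C=C, **base))


# --------------------------------------------------------------------------
# the zero-load RHS against an independently coded oracle
# --------------------------------------------------------------------------

def _rhs_oracle(m1, m2, gamma, C, b_hat, h0_hat, I1=0.0, I2=0.0):
    """Hand-expanded two-pattern zero-load overlap dynamics (independent of
    the vectorized implementation): population probabilities from (gamma, C)
    and the four sigmoid terms written out explicitly."""
    phi = lambda h: expit(b_hat * (h - h0_hat))
    P11 = gamma**2 + gamma * (1 - gamma) * C
    P10 = P01 = gamma * (1 - gamma) * (1 - C)
    P00 = (1 - gamma) ** 2 + gamma * (1 - gamma) * C
    g = gamma * (1 - gamma)
    f1 = (P11 * (1 - gamma) * phi((1 - gamma) * (m1 + m2) + I1 + I2)
          + P10 * (1 - gamma) * phi((1 - gamma) * m1 - gamma * m2 + I1)
          - P01 * gamma * phi(-gamma * m1 + (1 - gamma) * m2 + I2)
          - P00 * gamma * phi(-gamma * (m1 + m2))) / g
    f2 = (P11 * (1 - gamma) * phi((1 - gamma) * (m1 + m2) + I1 + I2)
          - P10 * gamma * phi((1 - gamma) * m1 - gamma * m2 + I1)
          + P01 * (1 - gamma) * phi(-gamma * m1 + (1 - gamma) * m2 + I2)
          - P00 * gamma * phi(-gamma * (m1 + m2))) / g
    return np.array([-m1 + f1, -m2 + f2])


@pytest.mark.parametrize("C", [0.0, 0.05, 0.2])
def test_rhs_matches_explicit_zero_load_forms(C):
    mf = _mf(C=C)
    rng = np.random.default_rng(0)
    for _ in range(25):
        m = rng.uniform(-0.2, 1.2, size=2)
        I = rng.uniform(0.0, 0.3, size=2)
        expected = _rhs_oracle(m[0], m[1], 0.002, C, 100.0, 0.25, *I)
        np.testing.assert_allclose(mf.rhs(m, I=I), expected, atol=1e-12)


def test_rhs_relabeling_symmetry():
    mf = _mf(C=0.1)
    rng = np.random.default_rng(1)
    for _ in range(10):
        m = rng.uniform(-0.2, 1.2, size=2)
        d = mf.rhs(m)
        d_swapped = mf.rhs(m[::-1])
        # F1(m1, m2) == F2(m2, m1)
        assert d[0] + m[0] == pytest.approx(d_swapped[1] + m[0], abs=1e-13)


def test_three_pattern_mode_symmetry_and_resting():
    mf = _mf(C=0.1, n_corr=3)
    m = np.array([0.3, 0.3, 0.3])
    d = mf.rhs(m)
    assert np.allclose(d, d[0])
    fps = mf.find_fixed_points()
    rest = min(fps, key=lambda f: np.abs(f.m).max())
    assert np.abs(rest.m).max() < 1e-3 and rest.is_stable


# --------------------------------------------------------------------------
# Jacobian: analytic vs central differences, and symmetry
# --------------------------------------------------------------------------

@pytest.mark.parametrize("J0", [None, 0.5])
def test_jacobian_matches_finite_differences(J0):
    mf = _mf(C=0.1, h0_hat=0.25 if J0 is None else 0.0)
    rng = np.random.default_rng(2)
    for _ in range(8):
        m = rng.uniform(0.0, 1.0, size=2)
        J = mf.jacobian(m, J0=J0)
        h = 1e-6
        J_fd = np.empty((2, 2))
        for j in range(2):
            dm = np.zeros(2)
            dm[j] = h
            J_fd[:, j] = (mf.rhs(m + dm, J0=J0) - mf.rhs(m - dm, J0=J0)) / (2 * h)
        np.testing.assert_allclose(J, J_fd, atol=1e-5)


def test_jacobian_exchange_symmetry():
    mf = _mf(C=0.15)
    rng = np.random.default_rng(3)
    for _ in range(6):
        m1, m2 = rng.uniform(0, 1, size=2)
        J_a = mf.jacobian(np.array([m1, m2]))
        J_b = mf.jacobian(np.array([m2, m1]))
        assert J_a[1, 1] == pytest.approx(J_b[0, 0], abs=1e-12)
        assert J_a[1, 0] == pytest.approx(J_b[0, 1], abs=1e-12)


# --------------------------------------------------------------------------
# fixed-point structure in the reference regime
# --------------------------------------------------------------------------

def test_four_stable_states_at_chance_level():
    fps = _mf(C=0.002).find_fixed_points()
    stable = [f for f in fps if f.is_stable]
    assert len(stable) == 4
    ms = np.array(sorted(tuple(np.round(f.m, 2)) for f in stable))
    np.testing.assert_allclose(ms[0], [0, 0], atol=0.02)       # resting
    assert any(f.m[0] > 0.9 and f.m[1] < 0.1 for f in stable)  # retrieve 1
    assert any(f.m[1] > 0.9 and f.m[0] < 0.1 for f in stable)  # retrieve 2
    assert any(abs(f.m[0] - f.m[1]) < 0.01 and f.m[0] > 0.9
               for f in stable)                                # symmetric
    # every reported point satisfies the equations on re-evaluation
    assert all(f.residual < 1e-8 for f in fps)


def test_only_two_states_beyond_cmax():
    stable = [f for f in _mf(C=0.25).find_fixed_points() if f.is_stable]
    assert len(stable) == 2
    kinds = sorted(round(float(f.m.max()), 1) for f in stable)
    assert kinds[0] == 0.0 and kinds[1] == 1.0


def test_fixed_point_set_symmetric_under_exchange():
    fps = _mf(C=0.1).find_fixed_points()
    ms = {tuple(np.round(f.m, 5)) for f in fps}
    assert all((b, a) in ms for a, b in ms)


# --------------------------------------------------------------------------
# background self-consistency (alpha > 0)
# --------------------------------------------------------------------------

def test_solve_R_reconsistency_and_grid_agreement():
    params = mfm.MeanFieldParams(C=0.05, alpha=0.05, **FIG1)
    m = np.array([1.0, 0.05])
    out = mfm.solve_self_consistent_R(m, params)
    assert out is not None
    R, q, p = out["R"], out["q"], out["p"]
    assert R == pytest.approx(p / (1 - q) ** 2, abs=1e-8)
    accepted = mfm.scan_R_grid(m, params, resolution=400)
    # the damped iteration lands inside the grid-acceptance set
    assert accepted.size > 0
    assert np.min(np.abs(accepted - R)) < 2 * params.R_max / 400


def test_alpha_zero_background_inert():
    params = mfm.MeanFieldParams(C=0.05, alpha=0.0, **FIG1)
    out = mfm.solve_self_consistent_R(np.array([0.5, 0.1]), params)
    assert out["R"] == 0.0


def test_cmax_weakly_depends_on_load():
    p0 = mfm.MeanFieldParams(C=0.0, alpha=0.0, **FIG1)
    p1 = mfm.MeanFieldParams(C=0.0, alpha=0.1, **FIG1)
    c0 = mfm.extract_c_max(p0, coarse=2e-3, refine=1e-3).c_crit
    c1 = mfm.extract_c_max(p1, coarse=2e-3, refine=1e-3).c_crit
    assert abs(c1 - c0) < 0.04


# --------------------------------------------------------------------------
# correlated-background R correction
# --------------------------------------------------------------------------

def test_background_correction_reduces_to_standard():
    # C = 0 recovers R = p/(1-q)^2 for any group size
    for g in (2, 3, 5):
        assert mfm.background_R_correction(0.3, 0.4, 0.0, g) == pytest.approx(
            0.3 / 0.36)
    # positive background correlation inflates the effective noise
    assert mfm.background_R_correction(0.3, 0.4, 0.3, 2) > 0.3 / 0.36


@pytest.mark.parametrize("g", [2, 3, 4, 5])
def test_sherman_morrison_matches_dense_inverse(g):
    rng = np.random.default_rng(g)
    for _ in range(20):
        q = rng.uniform(0.0, 0.8)
        C = rng.uniform(0.0, 0.9)
        D = 1.0 - q
        if abs(D - (g - 1) * q * C) < 1e-3:
            continue
        M = D * np.eye(g) - q * C * (np.ones((g, g)) - np.eye(g))
        np.testing.assert_allclose(
            mfm.sherman_morrison_inverse(D, q * C, g), np.linalg.inv(M),
            atol=1e-10)


def test_pair_closed_form_equals_group_formula():
    rng = np.random.default_rng(7)
    for _ in range(20):
        q = rng.uniform(0.0, 0.7)
        C = rng.uniform(0.0, 0.8)
        p = rng.uniform(0.01, 0.5)
        assert mfm.background_pair_R(p, q, C) == pytest.approx(
            mfm.background_R_correction(p, q, C, 2), rel=1e-10)


def test_singular_group_matrix_rejected():
    # D = (g-1) qC makes the coupling matrix singular
    with pytest.raises(ValueError, match="singular"):
        mfm.sherman_morrison_inverse(0.5, 0.25, 3)


def test_all_patterns_correlated_flagged_divergent():
    with pytest.raises(ValueError, match="diverges"):
        mfm.background_R_correction(0.3, 0.4, 0.2, None)
    # C = 0 with all patterns is just the independent case
    assert mfm.background_R_correction(0.3, 0.4, 0.0, None) == pytest.approx(
        0.3 / 0.36)


# --------------------------------------------------------------------------
# Heaviside limit
# --------------------------------------------------------------------------

def test_heaviside_converges_to_steep_sigmoid_alpha0():
    rng = np.random.default_rng(8)
    sup = []
    for b in (200.0, 1000.0, 5000.0):
        mf_s = _mf(C=0.1, b_hat=b, heaviside=False)
        mf_h = _mf(C=0.1, b_hat=b, heaviside=True)
        errs = []
        for _ in range(40):
            m = rng.uniform(-0.1, 1.1, size=2)
            errs.append(np.max(np.abs(mf_s.rhs(m) - mf_h.rhs(m))))
        sup.append(np.median(errs))
    assert sup[0] > sup[-1]  # decreasing in b_hat (away from thresholds)


def test_heaviside_erfc_path_matches_sigmoid_at_high_steepness():
    # with background noise the erfc closed forms replace the quadrature
    pa = mfm.MeanFieldParams(C=0.1, alpha=0.05, b_hat=5000.0,
                             heaviside=False, gamma=0.002, h0_hat=0.25,
                             quad_nodes=201)
    ph = replace(pa, heaviside=True)
    mfa, mfh = mfm.MeanField(pa), mfm.MeanField(ph)
    m = np.array([1.0, 0.08])
    R = mfm.solve_self_consistent_R(m, ph)["R"]
    np.testing.assert_allclose(
        mfa.rhs(m, R=R), mfh.rhs(m, R=R), atol=1e-3)


def test_heaviside_auto_switch():
    assert mfm.MeanFieldParams(b_hat=5000.0, **{k: v for k, v in FIG1.items()
                                                if k != "b_hat"}).heaviside
    assert not mfm.MeanFieldParams(**FIG1).heaviside


def test_heaviside_enumeration_fixed_points():
    mf = _mf(C=0.1, heaviside=True)
    fps = mf.find_fixed_points()
    assert any(f.m[0] > 0.95 and abs(f.m[1] - 0.1) < 0.02 for f in fps)
    assert any(np.abs(f.m).max() < 1e-9 for f in fps)


# --------------------------------------------------------------------------
# self-interaction exclusion
# --------------------------------------------------------------------------

def test_self_interaction_correction():
    # alpha = 0: correction vanishes identically
    m = np.array([0.7, 0.1])
    p0 = mfm.MeanFieldParams(C=0.1, alpha=0.0, exclude_self=True, **FIG1)
    q0 = mfm.MeanFieldParams(C=0.1, alpha=0.0, exclude_self=False, **FIG1)
    np.testing.assert_allclose(mfm.MeanField(p0).rhs(m),
                               mfm.MeanField(q0).rhs(m), atol=1e-14)
    # finite alpha: the recursive mean-input solution satisfies its equation
    pa = mfm.MeanFieldParams(C=0.1, alpha=0.1, exclude_self=True, **FIG1)
    mf = mfm.MeanField(pa)
    base = mf._raw_inputs(m)
    q = 0.08
    h = mf._self_corrected(base, q)
    np.testing.assert_allclose(
        h, base + q * pa.alpha * mf._phi(h) / (1 - q), atol=1e-8)
    # Heaviside limit: constant alpha/2 shift
    phv = replace(pa, heaviside=True)
    mfh = mfm.MeanField(phv)
    np.testing.assert_allclose(mfh._self_corrected(base, q),
                               base + pa.alpha / 2, atol=1e-14)


# --------------------------------------------------------------------------
# zero-sparsity analytic limit and the c_max bound
# --------------------------------------------------------------------------

@pytest.mark.parametrize("C", [0.02, 0.1, 0.2, 0.2499])
def test_second_overlap_equals_C_below_threshold(C):
    assert mfm.heaviside_second_overlap(C, 0.25) == pytest.approx(C, abs=1e-14)


def test_no_single_retrieval_beyond_threshold():
    with pytest.raises(ValueError, match="no single-retrieval"):
        mfm.heaviside_second_overlap(0.26, 0.25)


def test_extracted_cmax_converges_to_threshold():
    assert mfm.extract_cmax_zero_sparsity(0.25) == pytest.approx(0.25, abs=1e-8)
    assert mfm.extract_cmax_zero_sparsity(0.4) == pytest.approx(0.4, abs=1e-8)


def test_analytic_bound_values():
    assert mfm.analytic_cmax_bound(0.002, 0.25) == pytest.approx(0.2515)
    assert mfm.analytic_cmax_bound(1e-9, 0.25) == pytest.approx(0.25, abs=1e-6)
    assert mfm.analytic_cmax_bound(1.0, 0.7) == pytest.approx(1.0)


# --------------------------------------------------------------------------
# phase plane
# --------------------------------------------------------------------------

def test_nullcline_intersections_near_fixed_points():
    params = mfm.MeanFieldParams(C=0.002, **FIG1)
    pp = mfm.phase_plane(params, n_grid=81)
    fps = mfm.find_fixed_points(params)
    step = (pp["m1"].max() - pp["m1"].min()) / 80
    # every fixed point lies close to both nullcline families
    for f in fps:
        for key in ("nullclines_m1", "nullclines_m2"):
            dmin = min(
                np.min(np.hypot(seg[:, 0] - f.m[0], seg[:, 1] - f.m[1]))
                for seg in pp[key]
            )
            assert dmin < 2 * step


# --------------------------------------------------------------------------
# minimal stimulation and dynamics with adaptation
# --------------------------------------------------------------------------

def test_min_stimulation_curve_monotone_and_vanishes_past_cmax():
    params = mfm.MeanFieldParams(C=0.0, **FIG1)
    c_grid = [0.002, 0.05, 0.1, 0.15, 0.25]
    curve = mfm.min_stimulation_curve(params, c_grid)
    assert curve[0] > 0.0                      # chance level needs a push
    assert curve[-1] == 0.0                    # beyond c_max: free recall
    diffs = np.diff(curve)
    assert np.all(diffs <= 1e-6)               # non-increasing in c


def test_adaptation_dynamics_reduces_to_static_without_drive():
    # D_theta = 0 and constant J0: the quasi-static trajectory just sits on
    # the static fixed point
    params = mfm.MeanFieldParams(C=0.2, gamma=0.002, b_hat=100.0, h0_hat=0.0)
    traj = mfm.mf_dynamics_adaptation(
        params, lambda t: 0.7, duration=20.0, D_theta_hat=0.0,
        tau_theta_hat=45.0, dt=0.5, m_init=np.array([1.0, 0.2]))
    mf = mfm.MeanField(params)
    final = traj["m"][-1]
    assert np.max(np.abs(mf.rhs(final, J0=0.7))) < 1e-6
    assert np.max(np.abs(traj["m"][5:] - final)) < 1e-4


def test_adaptation_oscillation_alternates_correlated_patterns():
    params = mfm.MeanFieldParams(C=0.2, gamma=0.002, b_hat=100.0, h0_hat=0.0)
    sched = lambda t: 0.25 * np.sin(2 * np.pi * t / 25.0 - np.pi / 2) + 0.95
    traj = mfm.mf_dynamics_adaptation(
        params, sched, duration=60.0, tau_theta_hat=45.0, D_theta_hat=0.1,
        dt=0.25)
    m = traj["m"]
    # pattern 1 starts retrieved; pattern 2 must take over within the run
    assert m[0, 0] > 0.9
    assert np.any((m[:, 1] > 0.9) & (m[:, 0] < 0.5))


def test_chain_bounds_above_chance():
    params = mfm.MeanFieldParams(C=0.0, gamma=0.002, b_hat=50.0, h0_hat=0.0)
    bounds = mfm.chain_correlation_bounds(params, coarse=4e-3, refine=2e-3)
    assert bounds["c_min_prime"] is not None
    assert bounds["c_max_prime"] is not None
    assert bounds["c_min_prime"] > params.gamma      # strictly above chance
    assert bounds["c_max_prime"] > bounds["c_min_prime"]
    # below c_max', the low-inhibition phase has rest + both single retrievals
    C_mid = mfm.fraction_to_pearson(
        0.5 * (bounds["c_min_prime"] + bounds["c_max_prime"]), params.gamma)
    fps = mfm.MeanField(replace(params, C=C_mid)).find_fixed_points(J0=0.7)
    stable = [f for f in fps if f.is_stable]
    assert sum(np.abs(f.m).max() < 0.05 for f in stable) == 1
    assert sum(f.m[0] > 0.5 and f.m[1] < f.m[0] - 0.3 for f in stable) == 1
    assert sum(f.m[1] > 0.5 and f.m[0] < f.m[1] - 0.3 for f in stable) == 1
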