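"""Kinetic quantification methods: SRTM family, graphical models, SUVr."""

import numpy as np
import pytest

from petkin.exceptions import (
    CollinearityError,
    ConfigurationError,
    DegenerateDesignError,
    InsufficientDataError,
)
from petkin.models import (
    SRTM,
    SRTMBasis,
    logan_ref,
    logan_ref_k2p,
    make_basis,
    mrtm,
    mrtm2,
    srtm2_basis,
    srtm2_nls,
    srtm_asl,
    srtm_basis,
    srtm_nls,
    suvr,
)
from petkin.reference import interp_linear
from petkin.tac import TAC, FrameSchedule


def wls_oracle(X, y, w):
    """Generic weighted normal equations: (X'WX) beta = X'Wy."""
    W = np.diag(w)
    return np.linalg.solve(X.T @ W @ X, X.T @ W @ y)


def cumtrapz_matrix(mid):
    """Matrix L with (L v)_j = trapezoid integral of v over (0, mid_j], v(0)=0."""
    n = mid.size
    t = np.concatenate([[0.0], mid])
    L = np.zeros((n, n))
    for j in range(n):
        for i in range(1, j + 2):
            h = t[i] - t[i - 1]
            if i - 1 >= 1:
                L[j, i - 2] += h / 2
            L[j, i - 1] += h / 2
    return L


# ---------------------------------------------------------------------------
# SRTM basis
# ---------------------------------------------------------------------------

class TestSrtmBasis:
    def test_target_equal_reference_gives_unity(self, identity_tac, fine_basis):
        res = srtm_basis(identity_tac, fine_basis)
        assert res.r1 == pytest.approx(1.0, abs=1e-8)
        assert res.bp_nd == pytest.approx(0.0, abs=1e-8)
        assert res.k2 == pytest.approx(res.k2a, rel=1e-8)

    def test_noiseless_parameter_recovery(self, noiseless, truth_curve, schedule):
        for lab in (3, 6, 11):
            p = noiseless.truth[lab]
            # fine log-spaced grid whose geometric centre is the true k2a
            basis = make_basis(truth_curve, schedule, n_basis=65,
                               k2a_range=(p.k2a / 4, p.k2a * 4), step=0.01)
            res = srtm_basis(noiseless.noiseless_targets[lab], basis)
            assert res.r1 == pytest.approx(p.r1, rel=1e-3)
            assert res.k2 == pytest.approx(p.k2, rel=1e-3)
            assert res.bp_nd == pytest.approx(p.bp_nd, rel=1e-3)

    def test_selected_grid_point_matches_exhaustive_oracle(self, noiseless, default_basis):
        tac = noiseless.noiseless_targets[5]
        res = srtm_basis(tac, default_basis)
        y = tac.values
        best = (np.inf, None)
        for i, k2a in enumerate(default_basis.k2a_grid):
            X = np.column_stack([default_basis.cr, default_basis.B[:, i]])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            rss = float(np.sum((y - X @ beta) ** 2))
            if rss < best[0]:
                best = (rss, k2a)
        assert res.k2a == best[1]

    def test_final_solve_matches_normal_equations_oracle(self, noiseless, default_basis, rng):
        tac = noiseless.noiseless_targets[7]
        w = rng.uniform(0.5, 2.0, len(tac))
        res = srtm_basis(tac, default_basis, w)
        i = int(np.argmin(np.abs(default_basis.k2a_grid - res.k2a)))
        X = np.column_stack([default_basis.cr, default_basis.B[:, i]])
        beta = wls_oracle(X, tac.values, w)
        assert res.r1 == pytest.approx(beta[0], rel=1e-10)

    def test_zero_reference_raises(self, schedule, noiseless):
        zero = interp_linear(TAC(schedule, np.zeros(schedule.n_frames)))
        basis = make_basis(zero, schedule, n_basis=4)
        with pytest.raises(DegenerateDesignError):
            srtm_basis(noiseless.noiseless_targets[3], basis)

    def test_result_internal_consistency(self, noiseless, default_basis):
        res = srtm_basis(noiseless.noiseless_targets[9], default_basis)
        assert res.dvr == pytest.approx(res.bp_nd + 1.0, abs=1e-12)
        assert res.bp_nd == pytest.approx(res.k2 / res.k2a - 1.0, abs=1e-12)


class TestSrtm2Basis:
    def test_recovery_with_matching_k2p(self, noiseless, truth_curve, schedule, spec0):
        for lab in (4, 10):
            p = spec0.regions[lab]
            k2p = p.k2 / p.r1  # the k2' implied by the generating SRTM model
            basis = make_basis(truth_curve, schedule, n_basis=65,
                               k2a_range=(p.k2a / 4, p.k2a * 4), k2p=k2p, step=0.01)
            res = srtm2_basis(noiseless.noiseless_targets[lab], basis)
            assert res.r1 == pytest.approx(p.r1, rel=1e-3)
            assert res.bp_nd == pytest.approx(p.bp_nd, rel=1e-3)

    def test_identity_with_k2p_on_grid(self, identity_tac, truth_curve, schedule):
        # grid contains k2p exactly, so C_T == C_R is fitted exactly by R1=1, k2a=k2p
        basis = make_basis(truth_curve, schedule, n_basis=129, k2a_range=(0.01, 1.0),
                           k2p=0.1, step=0.01)
        res = srtm2_basis(identity_tac, basis)
        assert res.r1 == pytest.approx(1.0, abs=1e-8)
        assert res.bp_nd == pytest.approx(0.0, abs=1e-6)

    def test_matches_grid_search_oracle(self, noiseless, truth_curve, schedule):
        basis = make_basis(truth_curve, schedule, k2p=0.15)
        tac = noiseless.noiseless_targets[8]
        res = srtm2_basis(tac, basis)
        rss = [
            float(np.sum((tac.values - (np.dot(B, tac.values) / np.dot(B, B)) * B) ** 2))
            for B in basis.B.T
        ]
        assert res.k2a == basis.k2a_grid[int(np.argmin(rss))]

    def test_requires_k2p_basis(self, noiseless, default_basis):
        with pytest.raises(ConfigurationError):
            srtm2_basis(noiseless.noiseless_targets[3], default_basis)


# ---------------------------------------------------------------------------
# nonlinear SRTM family
# ---------------------------------------------------------------------------

class TestSrtmNls:
    def test_identity(self, identity_tac, truth_curve):
        res = srtm_nls(identity_tac, truth_curve, step=0.01)
        assert res.r1 == pytest.approx(1.0, abs=1e-6)
        assert res.bp_nd == pytest.approx(0.0, abs=1e-5)

    def test_noiseless_recovery_tight(self, noiseless, truth_curve):
        for lab in (5, 9):
            p = noiseless.truth[lab]
            res = srtm_nls(noiseless.noiseless_targets[lab], truth_curve, step=0.01)
            assert res.r1 == pytest.approx(p.r1, rel=1e-4)
            assert res.k2 == pytest.approx(p.k2, rel=1e-4)
            assert res.bp_nd == pytest.approx(p.bp_nd, rel=1e-4)

    def test_nested_model_rss_ordering(self, noiseless, fine_basis, truth_curve):
        # continuous k2a (NLS) >= grid (basis) >= fixed-k2p constrained, in fit quality
        tac = noiseless.noiseless_targets[6]
        r_basis = srtm_basis(tac, fine_basis)
        r_nls = srtm_nls(tac, truth_curve, step=0.01, init=(r_basis.r1, r_basis.k2, r_basis.k2a))
        basis2 = make_basis(truth_curve, tac.schedule, n_basis=256, k2a_range=(0.01, 1.0),
                            k2p=0.2, step=0.01)
        r_s2 = srtm2_basis(tac, basis2)
        assert r_nls.rss <= r_basis.rss * (1 + 1e-9)
        assert r_basis.rss <= r_s2.rss * (1 + 1e-9)

    def test_agreement_with_basis_on_dense_grid(self, noiseless, fine_basis, truth_curve):
        tac = noiseless.noiseless_targets[4]
        r_b = srtm_basis(tac, fine_basis)
        r_n = srtm_nls(tac, truth_curve, step=0.01)
        assert abs(r_n.bp_nd - r_b.bp_nd) < 1e-3
        assert abs(r_n.r1 - r_b.r1) < 1e-3


class TestSrtm2Nls:
    def test_equivalent_to_srtm_when_k2p_matches(self, noiseless, truth_curve):
        tac = noiseless.noiseless_targets[7]
        r = srtm_nls(tac, truth_curve, step=0.01)
        r2 = srtm2_nls(tac, truth_curve, k2p=r.k2 / r.r1, step=0.01)
        # the two models coincide at k2p = k2/R1: identical fitted curves
        assert np.allclose(r2.fitted_values, r.fitted_values, rtol=1e-6, atol=1e-8)

    def test_noiseless_recovery(self, noiseless, truth_curve, spec0):
        lab = 8
        p = spec0.regions[lab]
        res = srtm2_nls(noiseless.noiseless_targets[lab], truth_curve, k2p=p.k2 / p.r1, step=0.01)
        assert res.r1 == pytest.approx(p.r1, rel=1e-4)
        assert res.k2a == pytest.approx(p.k2a, rel=1e-4)
        assert res.bp_nd == pytest.approx(p.bp_nd, rel=1e-4)

    def test_invalid_k2p(self, noiseless, truth_curve):
        with pytest.raises(ConfigurationError):
            srtm2_nls(noiseless.noiseless_targets[3], truth_curve, k2p=-0.1)


# ---------------------------------------------------------------------------
# SRTM-ASL
# ---------------------------------------------------------------------------

class TestSrtmAsl:
    def test_true_r1_matches_srtm_basis(self, noiseless, fine_basis, truth_curve, spec0):
        for lab in (5, 11):
            p = spec0.regions[lab]
            r_b = srtm_basis(noiseless.noiseless_targets[lab], fine_basis)
            r_a = srtm_asl(noiseless.noiseless_targets[lab], truth_curve, p.r1, fine_basis)
            assert abs(r_a.bp_nd - r_b.bp_nd) < 1e-3

    def test_no_specific_binding_flagged(self, noiseless, default_basis, truth_curve):
        tac = TAC(noiseless.schedule, 0.9 * default_basis.cr)  # C_T = R1 C_R exactly
        res = srtm_asl(tac, truth_curve, 0.9, default_basis)
        assert res.status == "no_specific_binding"
        assert res.bp_nd == 0.0

    def test_late_window_regression_against_full_scan(self, noiseless, truth_curve, spec0):
        # 20-min late window with true R1 reproduces the full-scan binding estimates
        sched = spec0.schedule
        late = sched.start_min >= 90.0 - 1e-9
        full = make_basis(truth_curve, sched, step=0.01)
        lateb = make_basis(truth_curve, sched.subset(late), n_basis=128,
                           k2a_range=(0.01, 0.3), step=0.01)
        bp_full, bp_asl = [], []
        for lab in sorted(spec0.regions):
            r_f = srtm_basis(noiseless.noiseless_targets[lab], full)
            r_a = srtm_asl(
                noiseless.noiseless_targets[lab].subset(late), truth_curve,
                spec0.regions[lab].r1, lateb,
            )
            bp_full.append(r_f.bp_nd)
            bp_asl.append(r_a.bp_nd)
        slope, _ = np.polyfit(bp_full, bp_asl, 1)
        resid = np.array(bp_asl) - np.polyval(np.polyfit(bp_full, bp_asl, 1), bp_full)
        r2 = 1.0 - np.sum(resid**2) / np.sum((bp_asl - np.mean(bp_asl)) ** 2)
        assert 0.95 <= slope <= 1.05
        assert r2 >= 0.99

    def test_invalid_r1(self, noiseless, default_basis, truth_curve):
        with pytest.raises(ConfigurationError):
            srtm_asl(noiseless.noiseless_targets[3], truth_curve, 0.0, default_basis)


# ---------------------------------------------------------------------------
# Logan family
# ---------------------------------------------------------------------------

class TestLogan:
    def test_identity_target(self, noiseless):
        tac = noiseless.noiseless_ref
        ref = interp_linear(tac)  # curve(midtimes) == tac.values exactly
        res = logan_ref(tac, ref, t_star=40.0)
        assert res.dvr == pytest.approx(1.0, abs=1e-10)
        assert res.intercept == pytest.approx(0.0, abs=1e-8)

    def test_doubled_target_gives_dvr_two(self, noiseless):
        ref_tac = noiseless.noiseless_ref
        ref = interp_linear(ref_tac)
        tac = TAC(ref_tac.schedule, 2.0 * ref_tac.values)
        res = logan_ref(tac, ref, t_star=40.0)
        assert res.dvr == pytest.approx(2.0, abs=1e-10)
        assert res.intercept == pytest.approx(0.0, abs=1e-8)
        assert res.bp_nd == pytest.approx(1.0, abs=1e-10)

    def test_recovery_within_two_percent(self, noiseless, truth_curve):
        for lab in (5, 11):  # BP 0.6 and 2.0
            p = noiseless.truth[lab]
            res = logan_ref(noiseless.noiseless_targets[lab], truth_curve, t_star=60.0)
            assert res.bp_nd == pytest.approx(p.bp_nd, rel=0.02)

    def test_nonpositive_frames_excluded_with_warning(self, noiseless, truth_curve):
        tac = noiseless.noiseless_targets[5]
        vals = tac.values.copy()
        vals[-1] = -0.3
        bad = TAC(tac.schedule, vals)
        with pytest.warns(UserWarning, match="excluded 1"):
            res = logan_ref(bad, truth_curve, t_star=60.0)
        assert res.n_used == np.sum(tac.midtimes_min >= 60.0) - 1

    def test_insufficient_late_frames(self, noiseless, truth_curve):
        with pytest.raises(InsufficientDataError):
            logan_ref(noiseless.noiseless_targets[5], truth_curve, t_star=108.0)

    def test_regression_matches_weighted_ls_oracle(self, noiseless, truth_curve, rng):
        tac = noiseless.noiseless_targets[6]
        w = rng.uniform(0.2, 3.0, len(tac))
        res = logan_ref_k2p(tac, truth_curve, k2p=0.15, t_star=60.0, weights=w)
        mid = tac.midtimes_min
        use = mid >= 60.0
        crm = truth_curve(mid)
        t0 = np.concatenate([[0.0], mid])
        ict = np.array([np.trapezoid(np.concatenate([[0.0], tac.values])[: j + 2], t0[: j + 2])
                        for j in range(len(mid))])
        icr = np.array([np.trapezoid(np.concatenate([[0.0], crm])[: j + 2], t0[: j + 2])
                        for j in range(len(mid))])
        x = (icr[use] + crm[use] / 0.15) / tac.values[use]
        yv = ict[use] / tac.values[use]
        beta = wls_oracle(np.column_stack([x, np.ones_like(x)]), yv, w[use])
        assert res.dvr == pytest.approx(beta[0], rel=1e-10)
        assert res.intercept == pytest.approx(beta[1], rel=1e-8)

    def test_logan2_approaches_logan_for_large_k2p(self, noiseless, truth_curve):
        tac = noiseless.noiseless_targets[7]
        r1 = logan_ref(tac, truth_curve, t_star=60.0)
        r2 = logan_ref_k2p(tac, truth_curve, k2p=1e9, t_star=60.0)
        assert r2.dvr == pytest.approx(r1.dvr, rel=1e-8)

    def test_logan2_identity_near_unity(self, noiseless):
        tac = noiseless.noiseless_ref
        ref = interp_linear(tac)
        res = logan_ref_k2p(tac, ref, k2p=0.15, t_star=60.0)
        assert res.dvr == pytest.approx(1.0, rel=0.02)


# ---------------------------------------------------------------------------
# MRTM family
# ---------------------------------------------------------------------------

class TestMrtm:
    def test_exact_gamma_recovery_from_constructed_tac(self, noiseless, truth_curve):
        # build C_T satisfying the multilinear relation exactly by solving the
        # implicit linear system (I - g2 L) ct = g1 int_CR + g3 CR
        mid = noiseless.schedule.midtimes_min
        crm = truth_curve(mid)
        L = cumtrapz_matrix(mid)
        g = (0.03, -0.02, 1.4)
        ct = np.linalg.solve(np.eye(mid.size) - g[1] * L, g[0] * (L @ crm) + g[2] * crm)
        tac = TAC(noiseless.schedule, ct)
        res = mrtm(tac, truth_curve, t_star=0.0)
        assert res.gamma1 == pytest.approx(g[0], rel=1e-9)
        assert res.gamma2 == pytest.approx(g[1], rel=1e-9)
        assert res.gamma3 == pytest.approx(g[2], rel=1e-9)

    def test_recovery_within_two_percent(self, noiseless, truth_curve):
        p = noiseless.truth[5]
        res = mrtm(noiseless.noiseless_targets[5], truth_curve, t_star=60.0)
        assert res.bp_nd == pytest.approx(p.bp_nd, rel=0.02)
        assert res.bp_nd == pytest.approx(-(res.gamma1 / res.gamma2 + 1.0), abs=1e-12)

    def test_target_equal_reference_raises_collinearity(self, noiseless):
        tac = noiseless.noiseless_ref
        ref = interp_linear(tac)
        with pytest.raises(CollinearityError, match="int_C"):
            mrtm(tac, ref, t_star=20.0)


class TestMrtm2:
    def test_exact_gamma_recovery(self, noiseless, truth_curve):
        mid = noiseless.schedule.midtimes_min
        crm = truth_curve(mid)
        L = cumtrapz_matrix(mid)
        g1, g2, k2p = 0.05, -0.03, 0.12
        ct = np.linalg.solve(np.eye(mid.size) - g2 * L, g1 * (L @ crm + crm / k2p))
        res = mrtm2(TAC(noiseless.schedule, ct), truth_curve, k2p=k2p, t_star=0.0)
        assert res.gamma1 == pytest.approx(g1, rel=1e-9)
        assert res.gamma2 == pytest.approx(g2, rel=1e-9)

    def test_chained_k2p_agrees_with_mrtm(self, noiseless, truth_curve):
        for lab in (4, 9):
            tac = noiseless.noiseless_targets[lab]
            r1 = mrtm(tac, truth_curve, t_star=60.0)
            r2 = mrtm2(tac, truth_curve, k2p=r1.k2p, t_star=60.0)
            assert abs(r2.bp_nd - r1.bp_nd) < 1e-3

    def test_recovery_within_two_percent(self, noiseless, truth_curve):
        p = noiseless.truth[6]
        tac = noiseless.noiseless_targets[6]
        k2p = mrtm(tac, truth_curve, t_star=60.0).k2p
        res = mrtm2(tac, truth_curve, k2p=k2p, t_star=60.0)
        assert res.bp_nd == pytest.approx(p.bp_nd, rel=0.02)


# ---------------------------------------------------------------------------
# SUVr
# ---------------------------------------------------------------------------

class TestSuvr:
    def test_identity_and_scaling(self, noiseless):
        ref = noiseless.noiseless_ref
        assert suvr(ref, ref, (90.0, 110.0)) == 1.0
        doubled = TAC(ref.schedule, 2.0 * ref.values)
        assert suvr(doubled, ref, (90.0, 110.0)) == pytest.approx(2.0, rel=1e-14)

    def test_unequal_durations_duration_weighted(self):
        sched = FrameSchedule([0.0, 60.0], [60.0, 300.0])  # 1 min and 4 min frames
        target = TAC(sched, [10.0, 20.0])
        ref = TAC(sched, [5.0, 5.0])
        # hand arithmetic: target mean = (10*1 + 20*4)/5 = 18; ref mean = 5
        assert suvr(target, ref, (0.0, 5.0)) == pytest.approx(18.0 / 5.0, rel=1e-14)

    def test_empty_window(self, noiseless):
        with pytest.raises(InsufficientDataError):
            suvr(noiseless.noiseless_ref, noiseless.noiseless_ref, (108.5, 109.0))

    def test_zero_reference(self):
        sched = FrameSchedule([0.0], [60.0])
        with pytest.raises(ZeroDivisionError):
            suvr(TAC(sched, [1.0]), TAC(sched, [0.0]), (0.0, 1.0))


# ---------------------------------------------------------------------------
# cross-cutting properties
# ---------------------------------------------------------------------------

class TestInvariances:
    @pytest.mark.parametrize("c", [0.25, 3.7])
    def test_scale_equivariance(self, noiseless, truth_curve, schedule, c):
        """Scaling C_T and C_R jointly leaves all rate/binding estimates unchanged."""
        from petkin.reference import ReferenceCurve

        lab = 6
        tac = noiseless.noiseless_targets[lab]
        scaled_tac = TAC(schedule, c * tac.values)
        scaled_curve = ReferenceCurve(
            truth_curve.tag, lambda t: c * np.asarray(truth_curve(t)), knots=truth_curve.knots
        )
        b1 = make_basis(truth_curve, schedule)
        b2 = make_basis(scaled_curve, schedule)
        for attr, r_a, r_b in [
            ("bp_nd", srtm_basis(tac, b1), srtm_basis(scaled_tac, b2)),
            ("bp_nd", logan_ref(tac, truth_curve, 60.0), logan_ref(scaled_tac, scaled_curve, 60.0)),
            ("bp_nd", mrtm(tac, truth_curve, 60.0), mrtm(scaled_tac, scaled_curve, 60.0)),
        ]:
            assert getattr(r_b, attr) == pytest.approx(getattr(r_a, attr), rel=1e-9)
        r_a = srtm_basis(tac, b1)
        r_b = srtm_basis(scaled_tac, b2)
        assert r_b.r1 == pytest.approx(r_a.r1, rel=1e-9)
        assert r_b.k2 == pytest.approx(r_a.k2, rel=1e-9)

    def test_weight_rescaling_leaves_estimates_unchanged(self, noiseless, default_basis,
                                                         truth_curve, rng):
        tac = noiseless.noiseless_targets[8]
        w = rng.uniform(0.5, 2.0, len(tac))
        for fit in (
            lambda wt: srtm_basis(tac, default_basis, wt),
            lambda wt: logan_ref(tac, truth_curve, 60.0, wt),
            lambda wt: mrtm(tac, truth_curve, 60.0, wt),
        ):
            a, b = fit(w), fit(17.0 * w)
            assert b.bp_nd == pytest.approx(a.bp_nd, rel=1e-10)
            assert b.rss == pytest.approx(17.0 * a.rss, rel=1e-8)


class TestModelClasses:
    def test_class_wrapper_equals_function(self, noiseless, default_basis, truth_curve):
        tac = noiseless.noiseless_targets[5]
        res_fn = srtm_basis(tac, default_basis)
        res_cls = SRTMBasis(tac, truth_curve, basis=default_basis).fit()
        assert res_cls.bp_nd == res_fn.bp_nd
        assert res_cls.r1 == res_fn.r1

    def test_summary_lists_estimates(self, noiseless, truth_curve):
        res = SRTM(noiseless.noiseless_targets[5], truth_curve, step=0.01).fit()
        text = res.summary()
        assert "srtm" in text and "bp_nd" in text and "r1" in text

    def test_plot_returns_axis(self, noiseless, default_basis, truth_curve):
        import matplotlib

        matplotlib.use("Agg")
        tac = noiseless.noiseless_targets[5]
        res = srtm_basis(tac, default_basis)
        ax = res.plot(tac)
        assert ax.get_xlabel() == "time (min)"
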