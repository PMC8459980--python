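"""Fisher information, CRLB and the greedy design search."""

import numpy as np
import pytest

from ivim_bopt import (
    BValueScheme,
    IVIMParams,
    PALETTE,
    crlb,
    fisher_information,
    ivim_jacobian,
    optimize_for_scan_time,
    optimize_scheme,
)
from ivim_bopt.crlb import exhaustive_scheme_search

from conftest import random_truth

GM_TRUTH = IVIMParams(S0=1.0, f=0.06, D=0.85e-3, Dstar=10e-3)


def fd_jacobian(truth: IVIMParams, b, h=1e-6):
    """Central finite differences of the signal w.r.t. (S0, f, D, Dstar).

    Returns (jacobian, roundoff) where roundoff[i, j] bounds the cancellation
    error eps*S/(2*step) of each FD entry; differences below that floor are
    not resolvable by central differences at this step size.
    """
    from ivim_bopt.ivim import _signal

    th = truth.as_array()
    b = np.asarray(b, float)
    out = np.zeros((b.size, 4))
    roundoff = np.zeros((b.size, 4))
    s = _signal(b, *th)
    for j in range(4):
        step = h * abs(th[j])
        tp, tm = th.copy(), th.copy()
        tp[j] += step
        tm[j] -= step
        out[:, j] = (_signal(b, *tp) - _signal(b, *tm)) / (2 * step)
        roundoff[:, j] = np.finfo(float).eps * np.abs(s) / (2 * step)
    return out, roundoff


class TestFisher:
    def test_analytic_jacobian_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            truth = random_truth(rng)
            b = np.sort(rng.choice(PALETTE, size=6, replace=False)).astype(float)
            ja = ivim_jacobian(truth, b)
            jf, roundoff = fd_jacobian(truth, b)
            # 1e-6 relative wherever FD can resolve the derivative at all
            assert np.all(np.abs(ja - jf) <= 1e-6 * np.abs(jf) + 4 * roundoff)

    def test_linearity_in_averages(self):
        scheme = BValueScheme(bvalues=PALETTE)
        f1 = fisher_information(scheme, GM_TRUTH, 0.01)
        f2 = fisher_information(scheme.with_averages(2), GM_TRUTH, 0.01)
        assert np.allclose(f2, 2 * f1)

    def test_inverse_square_noise_scaling(self):
        scheme = BValueScheme(bvalues=PALETTE)
        f1 = fisher_information(scheme, GM_TRUTH, 0.01)
        f2 = fisher_information(scheme, GM_TRUTH, 0.02)
        assert np.allclose(f2, f1 / 4)

    def test_zero_sigma_rejected(self):
        scheme = BValueScheme(bvalues=(0, 200, 900))
        with pytest.raises(ValueError):
            fisher_information(scheme, GM_TRUTH, 0.0)


class TestCRLB:
    def test_replication_divides_bounds(self):
        scheme = BValueScheme(bvalues=PALETTE)
        r1 = crlb(scheme, GM_TRUTH, 0.01)
        r3 = crlb(scheme.with_averages(3), GM_TRUTH, 0.01)
        for name in r1.variances:
            assert r3.variances[name] == pytest.approx(r1.variances[name] / 3)

    def test_rank_deficient_flagged_not_raised(self):
        r = crlb(BValueScheme(bvalues=(0, 200, 900)), GM_TRUTH, 0.01)
        assert r.singular
        assert all(np.isinf(v) for v in r.variances.values())

    def test_order_invariance(self):
        b = (0, 110, 400, 700, 900)
        n = (2, 1, 3, 1, 2)
        r1 = crlb(BValueScheme(bvalues=b, averages=n), GM_TRUTH, 0.01)
        # same measurements described via a noise mapping keyed by b
        sig = {bb: 0.01 for bb in b}
        r2 = crlb(BValueScheme(bvalues=b, averages=n), GM_TRUTH, sig)
        for name in r1.variances:
            assert r1.variances[name] == pytest.approx(r2.variances[name])

    def test_monotonicity_adding_measurements(self):
        rng = np.random.default_rng(4)
        base = BValueScheme(bvalues=(0, 110, 400, 900))
        r0 = crlb(base, GM_TRUTH, 0.01)
        for b_new in (10, 200, 500, 800):
            grown = BValueScheme(
                bvalues=tuple(sorted(set(base.bvalues) | {float(b_new)})),
                averages=None,
            )
            r1 = crlb(grown, GM_TRUTH, 0.01)
            for name in r0.variances:
                assert r1.variances[name] <= r0.variances[name] * (1 + 1e-9)

    def test_two_point_monoexponential_closed_form(self):
        """CRLB for D in the S0*exp(-b*D) submodel vs a symbolic inverse."""
        import sympy as sp

        s0, d, b1, b2, sig = sp.symbols("s0 d b1 b2 sig", positive=True)
        g = sp.Matrix([[sp.exp(-b1 * d), -s0 * b1 * sp.exp(-b1 * d)],
                       [sp.exp(-b2 * d), -s0 * b2 * sp.exp(-b2 * d)]])
        fim = (g.T @ g) / sig**2
        crlb_d = sp.simplify(fim.inv()[1, 1])
        vals = {s0: 1.3, d: 0.9e-3, b1: 300.0, b2: 900.0, sig: 0.01}
        expected = float(crlb_d.subs(vals))

        truth = IVIMParams(S0=1.3, f=0.0, D=0.9e-3, Dstar=9e-3)
        r = crlb(BValueScheme(bvalues=(300, 900)), truth, 0.01, free=("S0", "D"))
        assert r.variances["D"] == pytest.approx(expected, rel=1e-8)


class TestOptimize:
    def test_budget_conserved_and_path_monotone(self):
        scheme, path = optimize_scheme(PALETTE, 20, GM_TRUTH, 0.01)
        assert scheme.n_measurements == 20
        finite = path[np.isfinite(path)]
        assert np.all(np.diff(finite) <= 1e-9 * np.abs(finite[:-1]))

    def test_greedy_matches_exhaustive_on_small_palette(self):
        """Degenerate palette {0, 200, 900}: identifiable as the stage-2
        (S0, f, Dstar) model with D known."""
        free = ("S0", "f", "Dstar")
        weights = {"f": 1.0, "Dstar": 1.0}
        for budget in (4, 6, 8):
            g, _ = optimize_scheme((0, 200, 900), budget, GM_TRUTH, 0.01,
                                   weights=weights, free=free)
            e, _ = exhaustive_scheme_search((0, 200, 900), budget, GM_TRUTH, 0.01,
                                            weights=weights, free=free)
            assert g.bvalues == e.bvalues
            assert g.averages == e.averages

    def test_low_budget_rejected(self):
        with pytest.raises(ValueError, match="budget"):
            optimize_scheme(PALETTE, 3, GM_TRUTH, 0.01)

    def test_physiological_noise_pulls_averages_to_low_b(self):
        flat = {b: 0.01 for b in PALETTE}
        phys = {b: 0.01 * np.sqrt(1 + (3 * np.exp(-b / 400)) ** 2) for b in PALETTE}
        g_flat, _ = optimize_scheme(PALETTE, 30, GM_TRUTH, flat)
        g_phys, _ = optimize_scheme(PALETTE, 30, GM_TRUTH, phys)

        def low_alloc(s):
            return sum(n for b, n in zip(s.bvalues, s.averages) if 0 < b < 200)

        assert low_alloc(g_phys) > low_alloc(g_flat)

    def test_scan_time_budget_respected(self):
        from ivim_bopt import scan_time

        scheme, _ = optimize_for_scan_time(PALETTE, 3.0, GM_TRUTH, 0.01,
                                           tr=4.0, directions=3)
        assert scan_time(scheme, tr=4.0, directions=3) <= 180.0
        assert len(scheme) >= 4
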