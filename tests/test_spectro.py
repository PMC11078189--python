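"""Spectroscopic parameter extraction, aggregation and group comparison."""

import itertools

import numpy as np
import pytest

from wbshear.datatypes import MeasurementContext, MSDCurve
from wbshear.reconstruct import spectrum_from_msd
from wbshear.spectro import (
    aggregate_replicates,
    compare_groups,
    extract_parameters,
)

CTX = MeasurementContext(radius=1e-7, temperature=295.0)


def composite_spectrum(A=1e-15, tau=1e-3, D6=1e-14, scale=1.0, n=300):
    """Trapped network + weak diffusion: one crossover and one plateau."""
    t = np.logspace(-5, 1, n)
    msd = scale * (A * (1 - np.exp(-t / tau)) + D6 * t)
    return spectrum_from_msd(MSDCurve(t=t, msd=msd, valid=np.ones(n, bool)), CTX)


def closed_form_alpha(t, A, tau, D6):
    """Analytic log-derivative of the composite MSD."""
    m = A * (1 - np.exp(-t / tau)) + D6 * t
    dm = A / tau * np.exp(-t / tau) + D6
    return t * dm / m


class TestExtraction:
    def test_pure_power_law_single_regime(self):
        t = np.logspace(-5, 0, 300)
        spec = spectrum_from_msd(
            MSDCurve(t=t, msd=1e-16 * t ** 0.7, valid=np.ones(300, bool)), CTX
        )
        params = extract_parameters(spec)
        assert params.crossings == []
        assert params.plateaus == []
        assert len(params.regimes) == 1
        assert params.regimes[0].gamma == pytest.approx(0.7, abs=0.01)
        assert params.regimes[0].alpha_exp == pytest.approx(0.7, abs=0.01)

    def test_composite_matches_dense_grid_closed_form(self):
        """Crossing and plateau locations agree with brute-force evaluation
        of the analytic MSD log-derivative on a 10^4-point grid."""
        A, tau, D6 = 1e-15, 1e-3, 1e-14
        params = extract_parameters(composite_spectrum(A, tau, D6))

        tg = np.logspace(-5, 1, 10_000)
        af = closed_form_alpha(tg, A, tau, D6)
        # in lag time alpha falls through 0.5 (trap onset) then rises back
        # (terminal flow); on the omega = 1/t axis the rise is the downward
        # fluid-to-solid crossing and the fall the upward one
        i_fall = np.nonzero((af[:-1] > 0.5) & (af[1:] <= 0.5))[0][0]
        w_up = 1.0 / tg[i_fall]
        i_rise = np.nonzero((af[:-1] <= 0.5) & (af[1:] > 0.5))[0][0]
        w_dn = 1.0 / tg[i_rise]
        # oracle plateau: local minimum of alpha -> omega = 1/t at minimum
        i_min = np.nonzero((np.diff(af[:-1]) < 0) & (np.diff(af[1:]) > 0))[0][0] + 1
        w_min = 1.0 / tg[i_min]

        down = [c for c in params.crossings if c.direction == "down"]
        up = [c for c in params.crossings if c.direction == "up"]
        assert down and up, "expected both crossing directions"
        assert down[0].omega == pytest.approx(w_dn, rel=0.05)
        assert up[0].omega == pytest.approx(w_up, rel=0.05)
        assert len(params.plateaus) == 1
        # the prescribed 15-point smoothing of the asymmetric alpha valley
        # shifts its minimum by a fraction of the half-decade window
        assert params.plateaus[0].omega0 == pytest.approx(w_min, rel=0.20)
        # plateau modulus ~ kBT / (pi a A) at the alpha minimum
        g0_oracle = CTX.kBT / (np.pi * CTX.radius * (A + D6 * tg[i_min]))
        assert params.plateaus[0].G0 == pytest.approx(g0_oracle, rel=0.10)

    def test_narrow_band_rejected(self):
        from wbshear.reconstruct import gser_reconstruct

        omega = np.logspace(1, 2, 40)  # a single decade
        spec = gser_reconstruct(
            omega, np.full(40, 0.5), np.full(40, 1e-16), CTX, smooth=False
        )
        with pytest.raises(ValueError, match="decade"):
            extract_parameters(spec)

    def test_extraction_idempotent(self):
        spec = composite_spectrum()
        a = extract_parameters(spec)
        b = extract_parameters(spec)
        assert a.scalar_dict() == b.scalar_dict()

    def test_grid_refinement_stability(self):
        """Doubling the grid density moves omega_T and omega0 by less than
        half a (coarse) grid step."""
        coarse = extract_parameters(composite_spectrum(n=300))
        fine = extract_parameters(composite_spectrum(n=600))
        step = 10 ** (6.0 / 300)  # coarse grid ratio per point
        for pc, pf in zip(coarse.plateaus, fine.plateaus):
            assert abs(np.log10(pc.omega0 / pf.omega0)) < 0.5 * np.log10(step) + 1e-9
        cc = [c.omega for c in coarse.crossings if c.direction == "down"]
        cf = [c.omega for c in fine.crossings if c.direction == "down"]
        assert abs(np.log10(cc[0] / cf[0])) < 0.5 * np.log10(step) + 1e-9

    def test_scale_equivariance(self):
        """MSD x c scales moduli by 1/c; frequencies and exponents unchanged."""
        base = extract_parameters(composite_spectrum(scale=1.0))
        scaled = extract_parameters(composite_spectrum(scale=7.5))
        for pb, ps in zip(base.plateaus, scaled.plateaus):
            assert ps.omega0 == pytest.approx(pb.omega0, rel=1e-9)
            assert ps.G0 == pytest.approx(pb.G0 / 7.5, rel=1e-9)
        for rb, rs in zip(base.regimes, scaled.regimes):
            assert rs.gamma == pytest.approx(rb.gamma, abs=1e-9)
            assert rs.alpha_exp == pytest.approx(rb.alpha_exp, abs=1e-9)
        for cb, cs in zip(base.crossings, scaled.crossings):
            assert cs.omega == pytest.approx(cb.omega, rel=1e-9)


class TestAggregation:
    def test_identical_replicates_zero_dispersion(self):
        out = aggregate_replicates([{"G0_1": 5.0}] * 4, "mean_sd")
        assert out["G0_1"] == (5.0, 0.0, 4)

    def test_mean_sd_arithmetic(self):
        out = aggregate_replicates([{"x": 10.0}, {"x": 20.0}, {"x": 30.0}], "mean_sd")
        center, disp, n = out["x"]
        assert center == pytest.approx(20.0)
        assert disp == pytest.approx(np.sqrt(200.0 / 3))
        assert n == 3

    def test_median_mad(self):
        out = aggregate_replicates([{"x": 1.0}, {"x": 2.0}, {"x": 100.0}], "median_mad")
        assert out["x"] == (2.0, 1.0, 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_replicates([])


def exact_ranksum_p(a, b):
    """Brute-force two-sided rank-sum p by enumerating group assignments."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = rankdata(pooled)
    obs = ranks[:n_a].sum()
    stats = [
        ranks[list(idx)].sum()
        for idx in itertools.combinations(range(len(pooled)), n_a)
    ]
    stats = np.array(stats)
    p_low = np.mean(stats <= obs)
    p_high = np.mean(stats >= obs)
    return min(1.0, 2 * min(p_low, p_high))


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        p, sig = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0
        assert not sig

    def test_separated_triplets_exact_p(self):
        p, sig = compare_groups([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)
        assert not sig

    @pytest.mark.parametrize("n_a,n_b,seed", [(3, 3, 0), (4, 5, 1), (6, 6, 2), (2, 6, 3)])
    def test_exact_p_equals_permutation_oracle(self, n_a, n_b, seed):
        rng = np.random.default_rng(seed)
        a = rng.permutation(np.arange(1, n_a + n_b + 1))[:n_a].astype(float)
        b = np.setdiff1d(np.arange(1, n_a + n_b + 1, dtype=float), a)
        p, _ = compare_groups(a, b)
        assert p == pytest.approx(exact_ranksum_p(a, b), abs=1e-10)

    def test_all_tied_degenerate_p_one(self):
        p, sig = compare_groups([2.0, 2.0], [2.0, 2.0, 2.0])
        assert p == 1.0 and not sig

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([], [1.0])
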