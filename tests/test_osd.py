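"""Burr Type III sensitivity distributions and hazardous concentrations."""

import numpy as np
import pytest
from scipy import stats as sps

from osdtox.osd import (
    BurrFitError,
    BurrIIIParams,
    Ec20Record,
    HcEstimate,
    bootstrap_hc,
    burr3_cdf,
    burr3_quantile,
    compare_treatments,
    fit_burr3,
    hazardous_concentration,
    osd_plot_data,
)
from osdtox.osd import _moment_inits, _negloglik_grad


def sample_burr3(params, rng, size):
    """Inverse-CDF sampling from the generating distribution."""
    return burr3_quantile(params, rng.uniform(size=size))


class TestDistribution:
    def test_cdf_examples(self):
        assert burr3_cdf(BurrIIIParams(7.5, 2.0, 1.0), 7.5) == pytest.approx(0.5)
        assert burr3_cdf(BurrIIIParams(10, 2, 0.5), 10) == pytest.approx(2 ** -0.5)
        p = BurrIIIParams(10, 2, 0.5)
        assert burr3_cdf(p, 1e-9) < 1e-8
        assert burr3_cdf(p, 1e12) > 1 - 1e-8

    def test_cdf_strictly_increasing(self):
        p = BurrIIIParams(12, 1.8, 0.9)
        grid = np.geomspace(1e-3, 1e5, 400)
        vals = burr3_cdf(p, grid)
        assert np.all(np.diff(vals) > 0)

    def test_cdf_matches_scipy_burr(self):
        # independent oracle: scipy's burr is Burr III with cdf (1+x^-c)^-d
        p = BurrIIIParams(12.0, 1.8, 0.9)
        grid = np.geomspace(0.1, 1e3, 50)
        want = sps.burr.cdf(grid, c=p.shape_c, d=p.shape_k, scale=p.scale_b)
        np.testing.assert_allclose(burr3_cdf(p, grid), want, rtol=1e-12)

    def test_quantile_examples(self):
        assert burr3_quantile(BurrIIIParams(7.5, 2.0, 1.0), 0.5) == pytest.approx(7.5)
        assert burr3_quantile(BurrIIIParams(10, 2, 0.5), 2 ** -0.5) == pytest.approx(10.0)

    def test_roundtrip_identity(self):
        ps = np.arange(1, 100) / 100.0
        for params in [BurrIIIParams(10, 2, 0.5), BurrIIIParams(0.3, 0.7, 4.0),
                       BurrIIIParams(150, 5, 1.3)]:
            x = burr3_quantile(params, ps)
            np.testing.assert_allclose(burr3_cdf(params, x), ps, atol=1e-10)

    def test_domain_errors(self):
        p = BurrIIIParams(10, 2, 0.5)
        with pytest.raises(ValueError):
            burr3_cdf(p, 0.0)
        with pytest.raises(ValueError):
            burr3_quantile(p, 1.0)
        with pytest.raises(ValueError):
            BurrIIIParams(-1, 2, 0.5)


class TestFit:
    def test_parameter_recovery_hc5(self):
        true = BurrIIIParams(12, 1.8, 0.9)
        rng = np.random.default_rng(0)
        fit = fit_burr3(sample_burr3(true, rng, 400))
        hc5_fit = burr3_quantile(fit, 0.05)
        hc5_true = burr3_quantile(true, 0.05)
        assert abs(hc5_fit - hc5_true) / hc5_true < 0.20

    def test_ks_distance_small_at_n400(self):
        true = BurrIIIParams(12, 1.8, 0.9)
        rng = np.random.default_rng(1)
        ds = []
        for _ in range(20):
            x = sample_burr3(true, rng, 400)
            fit = fit_burr3(x)
            grid = np.geomspace(x.min(), x.max(), 500)
            ds.append(np.max(np.abs(burr3_cdf(fit, grid) - burr3_cdf(true, grid))))
        assert np.median(ds) < 0.08

    def test_optimizer_beats_moment_init(self):
        rng = np.random.default_rng(2)
        x = sample_burr3(BurrIIIParams(5, 1.2, 1.5), rng, 60)
        fit = fit_burr3(x)
        logx = np.log(x)
        for init in _moment_inits(x):
            nll_init, _ = _negloglik_grad(init, logx)
            assert -fit.log_likelihood <= nll_init + 1e-9

    def test_small_sample_refused(self):
        with pytest.raises(ValueError, match=">= 8"):
            fit_burr3([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])

    def test_degenerate_identical_values(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_burr3([3.0] * 20)

    def test_accepts_records(self):
        rng = np.random.default_rng(3)
        vals = sample_burr3(BurrIIIParams(8, 2, 1), rng, 30)
        recs = [Ec20Record(otu_id=f"o{i}", treatment="Ag+", ec20=v)
                for i, v in enumerate(vals)]
        fit = fit_burr3(recs)
        assert fit.scale_b > 0


class TestHazardousConcentrations:
    def test_hc50_is_scale_when_k1(self):
        p = BurrIIIParams(9.0, 2.5, 1.0)
        assert hazardous_concentration(p, 50).value == pytest.approx(9.0)

    def test_hc_monotone_in_protection(self):
        p = BurrIIIParams(10, 2, 0.5)
        hcs = [hazardous_concentration(p, q).value for q in (5, 10, 20, 80)]
        assert np.all(np.diff(hcs) > 0)

    def test_quantile_matches_bisection_oracle(self):
        p = BurrIIIParams(10, 2, 0.5)
        for prot in (5, 20, 80):
            want = sps.burr.ppf(prot / 100, c=p.shape_c, d=p.shape_k, scale=p.scale_b)
            got = hazardous_concentration(p, prot).value
            assert got == pytest.approx(want, rel=1e-8)


@pytest.fixture(scope="module")
def ec20_sample():
    rng = np.random.default_rng(4)
    return sample_burr3(BurrIIIParams(12, 1.8, 0.9), rng, 50)


class TestBootstrap:

    def test_deterministic_under_seed(self, ec20_sample):
        a = bootstrap_hc(ec20_sample, (5.0, 20.0), n_boot=50, seed=9)
        b = bootstrap_hc(ec20_sample, (5.0, 20.0), n_boot=50, seed=9)
        for x, y in zip(a, b):
            assert x.value == y.value and x.ci_low == y.ci_low and x.ci_high == y.ci_high

    def test_point_inside_ci(self, ec20_sample):
        for hc in bootstrap_hc(ec20_sample, (5.0, 10.0, 20.0, 80.0), n_boot=100, seed=0):
            assert hc.ci_low <= hc.value <= hc.ci_high
            assert hc.n_ec20 == 50

    def test_single_resample_degenerate(self, ec20_sample):
        hc = bootstrap_hc(ec20_sample, (5.0,), n_boot=1, seed=0)[0]
        assert hc.degenerate_ci
        assert hc.ci_low == hc.ci_high

    def test_ci_width_shrinks_with_n(self):
        true = BurrIIIParams(12, 1.8, 0.9)
        rng = np.random.default_rng(5)
        widths = {}
        for n in (50, 400):
            ws = []
            for rep in range(5):
                x = sample_burr3(true, rng, n)
                hc = bootstrap_hc(x, (5.0,), n_boot=60, seed=rep)[0]
                ws.append(hc.ci_high - hc.ci_low)
            widths[n] = np.median(ws)
        assert widths[400] < widths[50]


class TestCompareTreatments:
    def _hc(self, value, lo, hi, p=20.0):
        return HcEstimate(protection_percent=p, value=value, ci_low=lo, ci_high=hi)

    def test_disjoint_cis_significant(self):
        a = self._hc(5.9, 4.4, 8.1)
        b = self._hc(1.4, 1.2, 1.7)
        assert compare_treatments(a, b) == "significant"
        assert compare_treatments(b, a) == "significant"

    def test_overlapping_cis_not_significant(self):
        a = self._hc(0.49, 0.32, 0.73, p=5.0)
        b = self._hc(0.25, 0.13, 0.47, p=5.0)
        assert compare_treatments(a, b) == "not_significant"
        assert compare_treatments(b, a) == "not_significant"

    def test_identical_not_significant(self):
        a = self._hc(2.0, 1.5, 2.5)
        assert compare_treatments(a, a) == "not_significant"

    def test_level_mismatch_and_missing_ci(self):
        a = self._hc(2.0, 1.5, 2.5, p=5.0)
        b = self._hc(2.0, 1.5, 2.5, p=20.0)
        with pytest.raises(ValueError):
            compare_treatments(a, b)
        c = HcEstimate(protection_percent=5.0, value=2.0)
        with pytest.raises(ValueError):
            compare_treatments(a, c)


class TestPlotData:
    def test_empirical_ranks_and_fitted_curve(self):
        rng = np.random.default_rng(6)
        x = sample_burr3(BurrIIIParams(10, 2, 1), rng, 40)
        params = fit_burr3(x)
        df = osd_plot_data(x, params, n_curve=100)
        emp = df[df["kind"] == "empirical"]
        assert len(emp) == 40
        # Hazen plotting positions
        np.testing.assert_allclose(
            emp["cumulative_fraction"].to_numpy(), (np.arange(1, 41) - 0.5) / 40
        )
        assert emp["concentration"].is_monotonic_increasing
        fitted = df[df["kind"] == "fitted"]
        assert len(fitted) == 100
        assert fitted["cumulative_fraction"].is_monotonic_increasing
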