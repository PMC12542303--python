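"""GEMM exposure-response curve: closed-form oracle, clamping, monotonicity."""

import math

import numpy as np
import pytest

from pm_hia import (
    GemmParameterSet,
    gemm_transform,
    load_gemm_parameters,
    relative_risk,
)
from pm_hia.ages import AGE_BANDS


def oracle_transform(c, alpha, mu, nu, cf):
    """Independent direct evaluation of the supra-linear transform."""
    z = max(0.0, c - cf)
    omega = 1.0 / (1.0 + math.exp(-(z - mu) / nu))
    return math.log(1.0 + z / alpha) * omega


def make_params(theta=0.2, se=0.05, alpha=2.0, mu=10.0, nu=5.0, cf=2.4):
    return GemmParameterSet(
        cause="TOY",
        entries={b: (theta, se) for b in AGE_BANDS},
        alpha=alpha,
        mu=mu,
        nu=nu,
        counterfactual_conc=cf,
    )


class TestTransform:
    def test_hand_evaluated_value(self, toy_params):
        # ln(11) * logistic(2) at 20 µg/m³ above the counterfactual
        expected = math.log(11.0) / (1.0 + math.exp(-2.0))
        assert gemm_transform(22.4, toy_params) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.11206, abs=5e-6)

    @pytest.mark.parametrize("conc", [0.0, 1.0, 2.3999, 2.4])
    def test_zero_at_or_below_counterfactual(self, toy_params, conc):
        assert gemm_transform(conc, toy_params) == 0.0

    def test_strictly_increasing_above_counterfactual(self, toy_params):
        grid = np.linspace(2.4, 120.0, 2000)
        t = gemm_transform(grid, toy_params)
        assert np.all(np.diff(t) > 0)

    def test_negative_concentration_rejected(self, toy_params):
        with pytest.raises(ValueError, match="-3"):
            gemm_transform(-3.0, toy_params)

    def test_oracle_equivalence_on_random_draws(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            theta = rng.uniform(0.0, 0.3)
            alpha = rng.uniform(0.5, 10.0)
            mu = rng.uniform(1.0, 30.0)
            nu = rng.uniform(1.0, 60.0)
            cf = rng.uniform(0.0, 5.0)
            c = rng.uniform(0.0, 100.0)
            params = make_params(theta=theta, alpha=alpha, mu=mu, nu=nu, cf=cf)
            expected = oracle_transform(c, alpha, mu, nu, cf)
            got = gemm_transform(c, params)
            assert got == pytest.approx(expected, rel=1e-12, abs=1e-15)
            rr = relative_risk(c, "45-49", params).rr
            assert rr == pytest.approx(math.exp(theta * expected), rel=1e-12)


class TestRelativeRisk:
    def test_hand_evaluated_value(self, toy_params):
        t = gemm_transform(22.4, toy_params)
        est = relative_risk(22.4, "60-64", toy_params)
        assert est.rr == pytest.approx(math.exp(0.2 * t), rel=1e-12)
        assert est.rr == pytest.approx(1.5257, abs=2e-4)
        assert est.rr_low == pytest.approx(math.exp((0.2 - 1.96 * 0.05) * t), rel=1e-12)
        assert est.rr_high == pytest.approx(math.exp((0.2 + 1.96 * 0.05) * t), rel=1e-12)

    def test_unity_at_counterfactual_all_bands(self, ihd_params):
        for band in AGE_BANDS:
            est = relative_risk(ihd_params.counterfactual_conc, band, ihd_params)
            assert (est.rr, est.rr_low, est.rr_high) == (1.0, 1.0, 1.0)

    def test_zero_theta_gives_unit_point_risk(self):
        params = make_params(theta=0.0, se=0.05)
        est = relative_risk(30.0, "25-29", params)
        t = gemm_transform(30.0, params)
        assert est.rr == 1.0
        assert est.rr_low == pytest.approx(math.exp(-1.96 * 0.05 * t))
        assert est.rr_high == pytest.approx(math.exp(1.96 * 0.05 * t))

    def test_unknown_band_lists_valid_ones(self, toy_params):
        with pytest.raises(KeyError, match="80\\+"):
            relative_risk(20.0, "85+", toy_params)

    def test_nondecreasing_in_concentration_all_bands(self, ihd_params):
        grid = np.linspace(0.0, 80.0, 400)
        for band in AGE_BANDS:
            rr = np.array([relative_risk(c, band, ihd_params).rr for c in grid])
            assert np.all(np.diff(rr) >= 0)

    def test_supra_linear_flattening_at_high_concentration(self, ihd_params):
        # well above mu the transform is concave: the per-µg/m³ RR increment
        # shrinks as concentration rises
        def increment(c, band="65-69", delta=1.0):
            return (
                relative_risk(c + delta, band, ihd_params).rr
                - relative_risk(c, band, ihd_params).rr
            )

        assert increment(40.0) < increment(25.0)
        assert increment(80.0) < increment(40.0)


class TestParameterFile:
    def test_packaged_ihd_file(self, ihd_params):
        assert ihd_params.cause == "IHD"
        assert set(ihd_params.entries) == set(AGE_BANDS)
        assert ihd_params.counterfactual_conc == 2.4
        # coefficients decline with age for this cause
        thetas = [ihd_params.theta(b)[0] for b in AGE_BANDS]
        assert thetas == sorted(thetas, reverse=True)

    def test_missing_band_rejected(self, tmp_path):
        src = load_gemm_parameters.__globals__["default_parameter_path"]()
        lines = [
            ln for ln in src.read_text().splitlines() if not ln.startswith("IHD,80+")
        ]
        bad = tmp_path / "bad.csv"
        bad.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="missing"):
            load_gemm_parameters(bad)

    def test_negative_se_rejected(self, tmp_path):
        src = load_gemm_parameters.__globals__["default_parameter_path"]()
        text = src.read_text().replace("IHD,80+,0.0474,0.0037", "IHD,80+,0.0474,-0.1")
        bad = tmp_path / "bad.csv"
        bad.write_text(text)
        with pytest.raises(ValueError, match="theta_se"):
            load_gemm_parameters(bad)

    def test_duplicate_band_rejected(self, tmp_path):
        src = load_gemm_parameters.__globals__["default_parameter_path"]()
        text = src.read_text() + "IHD,80+,0.05,0.004\n"
        bad = tmp_path / "bad.csv"
        bad.write_text(text)
        with pytest.raises(ValueError, match="duplicate"):
            load_gemm_parameters(bad)

    def test_non_numeric_theta_rejected(self, tmp_path):
        src = load_gemm_parameters.__globals__["default_parameter_path"]()
        text = src.read_text().replace("IHD,80+,0.0474", "IHD,80+,abc")
        bad = tmp_path / "bad.csv"
        bad.write_text(text)
        with pytest.raises(ValueError, match="row"):
            load_gemm_parameters(bad)
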